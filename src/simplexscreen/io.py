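"""Tabular formats, validation and the end-to-end pipeline runner.

Contracts (all UTF-8, ``.`` decimal, comma-separated; result tables TSV):

* plate map:   ``well,role[,mutant_ids]`` — 96/384 coordinates, roles from
  the fixed vocabulary, duplicates rejected, coordinates case-insensitive
  on input and canonical uppercase on output;
* traces:      long format ``well,time_s,a578`` (optionally ``plate_id``);
* amplification table: ``reaction_volume_ul,n_wells,n_amplified``;
* deactivation curve:  ``exposure_volume_ul,residual_activity[,sd]``.

Every output of :func:`run_pipeline` is reproducible from the manifest it
writes (config echo, seed, package version); all randomness flows from the
single configured seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from . import assay, synthetic
from .config import RunConfig, dump_config_json
from .hitcalling import Role, ScreenModel

logger = logging.getLogger("simplexscreen")

_WELL_RE = re.compile(r"^([A-Pa-p])([0-9]{1,2})$")
_ROLES = {r.value for r in Role}


def canonical_well(well: str, plate_size: int = 96) -> str:
    """Validate and canonicalise a well coordinate (A1..H12 or A1..P24)."""
    m = _WELL_RE.match(well.strip())
    if not m:
        raise ValueError(f"malformed well coordinate {well!r}")
    row, col = m.group(1).upper(), int(m.group(2))
    max_row, max_col = ("H", 12) if plate_size == 96 else ("P", 24)
    if row > max_row or not 1 <= col <= max_col:
        raise ValueError(f"well {well!r} outside a {plate_size}-well plate")
    return f"{row}{col}"


def read_plate_map(path: str | Path, plate_size: int = 96) -> pd.DataFrame:
    """Read and validate a plate-map CSV ``well,role[,mutant_ids]``."""
    df = pd.read_csv(path, dtype=str)
    if "well" not in df.columns or "role" not in df.columns:
        raise ValueError("plate map needs 'well' and 'role' columns")
    df["well"] = [canonical_well(w, plate_size) for w in df["well"]]
    dupes = df["well"][df["well"].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate well {dupes.iloc[0]!r} in plate map")
    bad = set(df["role"]) - _ROLES
    if bad:
        raise ValueError(f"unknown roles {sorted(bad)}; expected one of "
                         f"{sorted(_ROLES)}")
    if "mutant_ids" not in df.columns:
        df["mutant_ids"] = ""
    return df[["well", "role", "mutant_ids"]]


def write_plate_map(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("well", "role", "mutant_ids") if c in df.columns]
    df[cols].to_csv(path, index=False)


def read_traces(path: str | Path, assay_volume_ul: float = 200.0,
                mv_concentration_mM: float = 2.0) -> list[assay.AbsorbanceTrace]:
    """Read long-format trace CSV ``well,time_s,a578`` into per-well traces.

    Rows are grouped by well and sorted by time; duplicate timestamps
    within a well are rejected.  An empty file yields an empty list with a
    warning rather than an error.
    """
    df = pd.read_csv(path)
    if df.empty:
        logger.warning("trace file %s is empty", path)
        return []
    missing = {"well", "time_s", "a578"} - set(df.columns)
    if missing:
        raise ValueError(f"trace file missing columns: {sorted(missing)}")
    for col in ("time_s", "a578"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            rows = (df.index[bad] + 2).tolist()[:5]  # 1-based + header
            raise ValueError(f"non-numeric {col!r} values at rows {rows}")
        df[col] = pd.to_numeric(df[col])
    traces = []
    for well, sub in df.groupby("well", sort=True):
        sub = sub.sort_values("time_s")
        if sub["time_s"].duplicated().any():
            raise ValueError(f"well {well}: duplicate timestamps")
        traces.append(assay.AbsorbanceTrace(
            str(well), sub["time_s"].to_numpy(float),
            sub["a578"].to_numpy(float), assay_volume_ul, mv_concentration_mM))
    return traces


def write_traces(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("plate_id", "well", "time_s", "a578") if c in df.columns]
    df[cols].to_csv(path, index=False, float_format="%.6g")


def measurements_frame(measurements: list[assay.ActivityMeasurement]) -> pd.DataFrame:
    return pd.DataFrame([{
        "well_id": m.well_id,
        "slope_au_min": m.slope_au_per_min,
        "mv_rate_mm_min": m.mv_rate_mM_per_min,
        "h2_rate_pmol_min": m.h2_rate_pmol_per_min,
        "activity_per_ul": m.activity_per_ul,
        "rsquared": m.rsquared,
        "background_dominated": m.background_dominated,
    } for m in measurements])


def _config_hash(run: RunConfig) -> str:
    return hashlib.sha256(dump_config_json(run).encode()).hexdigest()[:16]


def run_pipeline(run: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Execute simulate → assay → analyze on a synthetic campaign.

    Writes, under the output directory: the plate map and trace CSVs per
    plate, the activity-measurement TSVs, the scored well table, tolerance
    and activity hit lists, the screen summary, the truth table, and a
    manifest (config echo + hash, seed, versions) from which the run can be
    replayed exactly.  All outputs are deterministic for a fixed config.
    """
    from . import __version__

    out = Path(out_dir if out_dir is not None else run.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = run.screen
    seeds = np.random.SeedSequence(cfg.seed).spawn(3)
    lib_seed, screen_seed, trace_seed = (int(s.generate_state(1)[0] % (2 ** 31))
                                         for s in seeds)

    logger.info("stage simulate: %d mutants, %d plates", run.n_mutants, run.n_plates)
    try:
        library = synthetic.simulate_library(run.n_mutants, seed=lib_seed)
        screen = synthetic.simulate_screen(
            library, run.n_plates, cfg, plate_size=run.plate_size,
            n_wildtype=run.n_wildtype_controls,
            n_no_template=run.n_no_template_controls, n_cat=run.n_cat_controls,
            seed=screen_seed)
        pre_tr, post_tr = synthetic.screen_to_traces(screen, run, seed=trace_seed)
    except Exception as exc:
        raise RuntimeError(f"stage simulate failed: {exc}") from exc

    layout = screen.layout.copy()
    write_plate_map(layout, out / "plate_map.csv")
    write_traces(pre_tr, out / "traces_pre.csv")
    write_traces(post_tr, out / "traces_post.csv")
    screen.truth.to_csv(out / "truth_table.tsv", sep="\t", index=False)
    library.to_csv(out / "library.tsv", sep="\t", index=False)

    logger.info("stage assay: fitting slopes for %d wells", len(screen.wells))
    try:
        well_rows = []
        for which, tr_df in (("pre", pre_tr), ("post", post_tr)):
            for (plate_id, well), sub in tr_df.groupby(["plate_id", "well"],
                                                       sort=False):
                trace = assay.AbsorbanceTrace(
                    str(well), sub["time_s"].to_numpy(float),
                    sub["a578"].to_numpy(float), cfg.assay_volume_ul,
                    cfg.mv_concentration_mM)
                meas = assay.trace_to_activity(
                    trace, 1.0, cfg.conversion_coefficient, cfg.electrons_per_h2)
                well_rows.append({"plate_id": plate_id, "well_id": str(well),
                                  "which": which,
                                  "activity": meas.activity_per_ul,
                                  "slope_au_min": meas.slope_au_per_min})
        meas_df = pd.DataFrame(well_rows)
        meas_df.to_csv(out / "measurements.tsv", sep="\t", index=False,
                       float_format="%.8g")
    except Exception as exc:
        raise RuntimeError(f"stage assay failed: {exc}") from exc

    logger.info("stage analyze: scoring and hit calling")
    try:
        wide = meas_df.pivot_table(index=["plate_id", "well_id"], columns="which",
                                   values="activity").reset_index()
        wide = wide.rename(columns={"pre": "pre_activity", "post": "post_activity"})
        role_map = dict(zip(layout["well"], layout["role"]))
        wide["role"] = wide["well_id"].map(role_map)
        results = ScreenModel(wide, cfg).fit()
    except Exception as exc:
        raise RuntimeError(f"stage analyze failed: {exc}") from exc

    header = (f"# config_hash={_config_hash(run)} seed={cfg.seed} "
              f"sd_multiplier={cfg.sd_multiplier:g} "
              f"qc_fraction={cfg.min_pre_activity_fraction_of_wt:g} "
              f"volume_factor={cfg.volume_factor_post_over_pre:g}\n")
    for name, frame in (("scored_wells.tsv", results.records),
                        ("hits_tolerance.tsv", results.hits("tolerance")),
                        ("hits_activity.tsv", results.hits("activity"))):
        with open(out / name, "w") as fh:
            fh.write(header)
            frame.to_csv(fh, sep="\t", index=False, float_format="%.8g")
    summary = {
        "config_hash": _config_hash(run), "seed": cfg.seed,
        "n_tolerance_hits": results.screen_summary.n_tolerance_hits,
        "n_activity_hits": results.screen_summary.n_activity_hits,
        "n_qc_failed": results.screen_summary.n_qc_failed,
        "pooled_cv_ratio": results.screen_summary.pooled_cv_ratio,
        "pooled_cv_pre": results.screen_summary.pooled_cv_pre,
        "per_plate": results.screen_summary.to_frame().to_dict("records"),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    manifest = {
        "package": "simplexscreen", "version": __version__,
        "config": json.loads(dump_config_json(run)),
        "config_hash": _config_hash(run), "seed": cfg.seed,
        "outputs": sorted(p.name for p in out.iterdir()
                          if p.name != "manifest.json"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", out)
    return out


def replay_manifest(manifest_path: str | Path, out_dir: str | Path) -> Path:
    """Re-run a pipeline from its manifest; reproduces all outputs exactly."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    run = RunConfig.model_validate(manifest["config"])
    return run_pipeline(run, out_dir)
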