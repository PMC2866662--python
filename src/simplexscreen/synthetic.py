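"""Synthetic screening campaigns with the statistical structure the analysis assumes.

The generator emulates, stage by stage, what the wet protocol produces:

* a mutant library with 2–10 DNA mutations per gene and invented effect
  distributions over activity and oxygen tolerance (multiplicative factors
  on the wild-type specific activity and decay constant; the real library's
  effect spectrum is unknown — defaults make detectable tolerance
  improvements vanishingly rare, matching the screen's empirical outcome,
  while rare large activity improvements do occur);
* Poisson gene deposition at λ molecules/well (empty wells at e^−λ), with
  co-occupied wells averaging their members' signals;
* lognormal CFPS yield variation (shared by a well's pre- and post-exposure
  reads, since both assay the same synthesis product);
* exponential oxygen deactivation exp(−tolerance_factor·k·V) per member;
* multiplicative lognormal measurement noise per read, calibrated so that
  the wild-type residual-activity-ratio CV equals the configured target;
* a small additive background (extract absorbance drift) on every read,
  which is what inflates the ratios of low-activity wells before QC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import assay
from .config import RunConfig, ScreenConfig
from .hitcalling import Role

BACKGROUND_FRACTION_OF_WT = 0.05  # background read as a fraction of the WT pre-read


@dataclass(frozen=True)
class EffectModel:
    """Distributions of mutational effects in the simulated library.

    ``activity_sigma`` / ``tolerance_sigma`` are log-scale SDs of lognormal
    multiplicative factors with median 1.  Inactive mutants (probability
    ``p_inactive``) have activity factor exactly 0.  Tolerance factors below
    1 mean slower deactivation (more oxygen-tolerant).
    """

    p_inactive: float = 0.70
    activity_sigma: float = 0.30
    tolerance_sigma: float = 0.05
    mutations_min: int = 2
    mutations_max: int = 10

    def __post_init__(self) -> None:
        if not 0 <= self.p_inactive <= 1:
            raise ValueError("p_inactive must be a probability")
        if self.activity_sigma < 0 or self.tolerance_sigma < 0:
            raise ValueError("effect sigmas must be nonnegative")
        if not 1 <= self.mutations_min <= self.mutations_max:
            raise ValueError("bad mutation range")


def simulate_library(n_mutants: int, effect_model: EffectModel | None = None,
                     seed: int = 0) -> pd.DataFrame:
    """Draw a mutant library: id, mutation count and effect factors."""
    if n_mutants < 1:
        raise ValueError("need at least one mutant")
    em = effect_model or EffectModel()
    rng = np.random.default_rng(seed)
    n_mut = rng.integers(em.mutations_min, em.mutations_max + 1, n_mutants)
    inactive = rng.random(n_mutants) < em.p_inactive
    act = np.exp(rng.normal(0.0, em.activity_sigma, n_mutants))
    act[inactive] = 0.0
    tol = np.exp(rng.normal(0.0, em.tolerance_sigma, n_mutants))
    return pd.DataFrame({
        "mutant_id": [f"m{i:06d}" for i in range(n_mutants)],
        "n_mutations": n_mut,
        "activity_factor": act,
        "tolerance_factor": tol,
    })


def well_names(plate_size: int) -> list[str]:
    """Canonical well order A1..H12 (96) or A1..P24 (384), row-major."""
    if plate_size == 96:
        rows, cols = "ABCDEFGH", 12
    elif plate_size == 384:
        rows, cols = "ABCDEFGHIJKLMNOP", 24
    else:
        raise ValueError("plate size must be 96 or 384")
    return [f"{r}{c}" for r in rows for c in range(1, cols + 1)]


def build_layout(plate_size: int = 96, n_wildtype: int = 8, n_no_template: int = 2,
                 n_cat: int = 2) -> pd.DataFrame:
    """Assign roles to wells: controls first (column 1 onward), then samples.

    Every plate carries wild-type control wells — the per-plate
    normalisation baseline — plus no-template and CAT (chloramphenicol
    acetyltransferase) negative controls that define the background band.
    """
    wells = well_names(plate_size)
    n_ctrl = n_wildtype + n_no_template + n_cat
    if n_ctrl >= len(wells):
        raise ValueError("controls fill the whole plate")
    roles = ([Role.WILDTYPE.value] * n_wildtype
             + [Role.NO_TEMPLATE.value] * n_no_template
             + [Role.CAT.value] * n_cat
             + [Role.SAMPLE.value] * (len(wells) - n_ctrl))
    return pd.DataFrame({"well": wells, "role": roles})


@dataclass
class SimulatedScreen:
    """A simulated campaign: measured well table plus the generating truth."""

    wells: pd.DataFrame       # plate_id, well_id, role, pre_activity, post_activity
    truth: pd.DataFrame       # per-well membership and true (noise-free) values
    config: ScreenConfig
    library: pd.DataFrame
    layout: pd.DataFrame = field(default_factory=pd.DataFrame)


def simulate_screen(library: pd.DataFrame, n_plates: int = 1,
                    config: ScreenConfig | None = None, *, plate_size: int = 96,
                    n_wildtype: int = 8, n_no_template: int = 2, n_cat: int = 2,
                    seed: int = 0,
                    planted: dict[tuple[str, str], list[str]] | None = None
                    ) -> SimulatedScreen:
    """Simulate a screening campaign at the measured-activity level.

    Sample wells draw their gene count from Poisson(λ) and their members
    uniformly from the library (with replacement across wells).  The well's
    true pre-exposure activity is the *mean* of its members' activities —
    the signal-averaging that degrades co-occupied wells — and each member
    decays with its own tolerance factor during oxygen exposure.

    ``planted`` pins the membership of chosen wells, e.g.
    ``{("plate1", "B2"): ["m000007"]}``, for power/recovery experiments.

    Noise calibration: per-read lognormal noise with CV = cv/√2 makes the
    wild-type pre/post ratio CV equal the configured ``cv``; CFPS yield
    variation (also CV = cv/√2) cancels in the ratio but gives single
    pre-exposure reads a replicate CV of ≈ cv as well.
    """
    cfg = config or ScreenConfig()
    if cfg.lambda_ <= 0:
        raise ValueError("lambda must be positive")
    if cfg.cv < 0:
        raise ValueError("cv must be nonnegative")
    rng = np.random.default_rng(seed)
    layout = build_layout(plate_size, n_wildtype, n_no_template, n_cat)
    lib = library.set_index("mutant_id", drop=False)

    wt_act = cfg.wt_activity_per_ul                       # pmol H2/min/µL CFPS
    residual_wt = np.exp(-cfg.decay_rate_per_ul * cfg.exposure_volume_ul)
    bg = BACKGROUND_FRACTION_OF_WT * wt_act               # per-µL-equivalent read floor
    cv_read = cfg.cv / np.sqrt(2.0)
    cv_yield = cfg.cv / np.sqrt(2.0)
    sig_read = np.sqrt(np.log1p(cv_read ** 2))
    sig_yield = np.sqrt(np.log1p(cv_yield ** 2))
    vf = cfg.volume_factor_post_over_pre
    kV = cfg.decay_rate_per_ul * cfg.exposure_volume_ul

    rows: list[dict] = []
    truth_rows: list[dict] = []
    for p in range(1, n_plates + 1):
        plate_id = f"plate{p}"
        for well, role in layout.itertuples(index=False):
            members: list[str] = []
            if role == Role.SAMPLE.value:
                key = (plate_id, well)
                if planted and key in planted:
                    members = list(planted[key])
                else:
                    k = int(rng.poisson(cfg.lambda_))
                    if k > 0:
                        members = list(rng.choice(lib["mutant_id"].to_numpy(),
                                                  size=k, replace=True))
                if members:
                    af = lib.loc[members, "activity_factor"].to_numpy(float)
                    tf = lib.loc[members, "tolerance_factor"].to_numpy(float)
                    true_pre = wt_act * af.mean()
                    true_post = wt_act * float(np.mean(af * np.exp(-tf * kV)))
                else:
                    true_pre = true_post = 0.0
            elif role == Role.WILDTYPE.value:
                true_pre, true_post = wt_act, wt_act * residual_wt
            else:  # no-template / CAT: background only
                true_pre = true_post = 0.0

            yield_factor = float(np.exp(rng.normal(-sig_yield ** 2 / 2, sig_yield))) \
                if role in (Role.SAMPLE.value, Role.WILDTYPE.value) else 1.0
            eps_pre = float(np.exp(rng.normal(-sig_read ** 2 / 2, sig_read)))
            eps_post = float(np.exp(rng.normal(-sig_read ** 2 / 2, sig_read)))
            pre_meas = (true_pre * yield_factor + bg) * eps_pre
            post_meas = (true_post * yield_factor * vf + bg) * eps_post

            rows.append({"plate_id": plate_id, "well_id": well, "role": role,
                         "pre_activity": pre_meas, "post_activity": post_meas})
            truth_rows.append({
                "plate_id": plate_id, "well_id": well, "role": role,
                "n_genes": len(members), "mutant_ids": ";".join(members),
                "true_pre_activity": true_pre, "true_post_activity": true_post,
                "true_residual": true_post / true_pre if true_pre > 0 else np.nan,
                "yield_factor": yield_factor,
            })
    return SimulatedScreen(pd.DataFrame(rows), pd.DataFrame(truth_rows), cfg,
                           library, layout)


@dataclass(frozen=True)
class GeneratedTrace:
    """A synthetic plate-reader trace plus its generating truth."""

    trace: assay.AbsorbanceTrace
    true_slope_au_per_min: float
    saturated: bool = False


def activity_to_slope(activity_per_ul: float, cfps_volume_ul: float,
                      config: ScreenConfig) -> float:
    """Push an activity backward through the assay conversions to AU/min."""
    h2_rate = activity_per_ul * cfps_volume_ul                    # pmol H2/min
    mv_rate = h2_rate * config.electrons_per_h2 / (config.assay_volume_ul * 1e3)
    return mv_rate * config.conversion_coefficient


def generate_trace(true_activity_per_ul: float, cfps_volume_ul: float,
                   config: ScreenConfig | None = None, seed: int = 0, *,
                   well_id: str = "A1", n_points: int = 13,
                   duration_s: float = 120.0, read_noise_au: float = 0.002,
                   background_slope_au_per_min: float | None = None,
                   start_au: float = 0.2) -> GeneratedTrace:
    """Generate one A578 time series for a well of given true activity.

    The slope is the activity pushed backward through the Beer's-law
    conversion chain, plus a small background slope (default 5% of the
    wild-type 1 µL slope — extract drift, which is what negative-control
    wells show) and Gaussian read noise per point.  Slopes that would
    reduce more methyl viologen than the 2 mM pool over the read are
    clipped and flagged saturated.
    """
    if true_activity_per_ul < 0:
        raise ValueError("activity must be nonnegative")
    cfg = config or ScreenConfig()
    if background_slope_au_per_min is None:
        background_slope_au_per_min = (BACKGROUND_FRACTION_OF_WT
                                       * activity_to_slope(cfg.wt_activity_per_ul,
                                                           cfg.pre_cfps_volume_ul, cfg))
    slope = activity_to_slope(true_activity_per_ul, cfps_volume_ul, cfg) \
        + background_slope_au_per_min
    # mass balance: cannot reduce more MV than the pool holds during the read
    max_slope = cfg.mv_concentration_mM * cfg.conversion_coefficient \
        / (duration_s / 60.0)
    saturated = slope > max_slope
    if saturated:
        slope = max_slope
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, duration_s, n_points)
    a = start_au + slope * t / 60.0
    if read_noise_au > 0:
        a = a + rng.normal(0.0, read_noise_au, n_points)
    trace = assay.AbsorbanceTrace(well_id, t, a, cfg.assay_volume_ul,
                                  cfg.mv_concentration_mM)
    return GeneratedTrace(trace, slope, saturated)


def screen_to_traces(screen: SimulatedScreen, run: RunConfig | None = None,
                     seed: int = 1) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render a simulated screen as pre/post trace tables (long CSV format).

    The measured activities already carry the calibrated noise, so traces
    are generated with only instrument read noise on top.  Returns
    ``(pre_traces, post_traces)`` DataFrames with columns
    ``plate_id, well, time_s, a578``.
    """
    cfg = screen.config
    child = np.random.SeedSequence(seed).spawn(len(screen.wells))
    pre_parts, post_parts = [], []
    for (row, ss) in zip(screen.wells.itertuples(index=False), child):
        s_pre, s_post = ss.spawn(2)
        g_pre = generate_trace(row.pre_activity, 1.0, cfg,
                               seed=int(s_pre.generate_state(1)[0] % (2**31)),
                               well_id=row.well_id, background_slope_au_per_min=0.0)
        # post_activity is the raw read at vf µL, already per-assay
        g_post = generate_trace(row.post_activity, 1.0, cfg,
                                seed=int(s_post.generate_state(1)[0] % (2**31)),
                                well_id=row.well_id, background_slope_au_per_min=0.0)
        for g, parts in ((g_pre, pre_parts), (g_post, post_parts)):
            parts.append(pd.DataFrame({
                "plate_id": row.plate_id, "well": row.well_id,
                "time_s": g.trace.times_s, "a578": g.trace.a578}))
    return pd.concat(pre_parts, ignore_index=True), \
        pd.concat(post_parts, ignore_index=True)
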