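"""Hit calling for the oxygen-tolerance screen.

Each well is assayed twice: once before oxygen exposure (1 µL of CFPS
product) and once after (5 µL, to bring the deactivated slope back into the
readable range).  The oxygen-tolerance score is the volume-normalised
residual-activity ratio (post/5)/pre.  Wells with too little pre-exposure
activity are disqualified — their ratios are noise-inflated — and the
surviving scores are normalised to the same plate's wild-type controls,
which absorb plate-to-plate and day-to-day variation in CFPS performance
and exposure effectiveness.  A well is a hit when its normalised score
exceeds the wild-type mean by ``sd_multiplier`` wild-type standard
deviations (strict inequality, one-tailed: the screen looks for
improvement only).

The same machinery runs on the pre-exposure activities themselves
(normalised activity), which is how activity-improved mutants are found
even in a tolerance screen.

Detectability arithmetic: with a threshold m·SD above the mean and
wild-type coefficient of variance CV, the smallest improvement whose
expected score sits exactly at the threshold is m × CV — so a 2-SD rule at
CV 15–25% resolves ~30–50% improvements, each detected with probability
~50% under symmetric noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .config import ScreenConfig


class Role(str, Enum):
    SAMPLE = "sample"
    WILDTYPE = "wildtype_control"
    NO_TEMPLATE = "no_template_control"
    CAT = "CAT_control"


class PlateRejectedError(ValueError):
    """A plate without >= 2 usable wild-type controls cannot be normalised."""


@dataclass
class WellRecord:
    """One well's identity, activities, QC state and normalised scores."""

    well_id: str
    role: Role
    pre_activity_per_ul: float
    post_activity_raw: float
    plate_id: str = "plate1"
    residual_ratio: float = np.nan
    qc_pass: bool = False
    normalized_tolerance: float = np.nan
    normalized_activity: float = np.nan
    tolerance_hit: bool = False
    activity_hit: bool = False


def cv(values: Sequence[float] | np.ndarray) -> float:
    """Coefficient of variance: sample SD (n−1 denominator) over the mean."""
    x = np.asarray(values, float)
    if len(x) < 2:
        raise ValueError("CV needs at least 2 values")
    m = x.mean()
    if m <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(x.std(ddof=1) / m)


def residual_ratio(pre_measurement: float, post_measurement: float,
                   volume_factor: float = 5.0) -> float:
    """Volume-normalised oxygen-tolerance score, (post/volume_factor)/pre.

    The post-exposure assay uses ``volume_factor`` times as much CFPS
    product, so dividing by it puts both activities on a per-µL-CFPS basis.
    Requires pre > 0; low-activity wells must be disqualified before the
    ratio is formed.
    """
    if volume_factor <= 0:
        raise ValueError("volume factor must be positive")
    if pre_measurement <= 0:
        raise ValueError("residual ratio undefined for pre-activity <= 0; "
                         "the well must fail QC instead")
    return (post_measurement / volume_factor) / pre_measurement


def qc_filter(records: pd.DataFrame, min_pre_activity: float) -> pd.DataFrame:
    """Set qc_pass from the minimum pre-exposure activity cutoff.

    A well exactly at the threshold passes (>= convention).  Disqualified
    wells keep NaN ratios and never receive hit flags.
    """
    if min_pre_activity < 0:
        raise ValueError("cutoff must be nonnegative")
    out = records.copy()
    out["qc_pass"] = (out["pre_activity"] >= min_pre_activity) & (out["pre_activity"] > 0)
    out.loc[~out["qc_pass"], ["residual_ratio", "normalized_tolerance",
                              "normalized_activity"]] = np.nan
    return out


def detectable_improvement(cv_value: float, sd_multiplier: float = 2.0) -> float:
    """Minimal detectable fractional improvement, sd_multiplier × CV.

    At this improvement the mutant's expected normalised score equals the
    hit threshold, so it is detected with probability ~50% under symmetric
    measurement noise.
    """
    if cv_value < 0:
        raise ValueError("CV must be nonnegative")
    return sd_multiplier * cv_value


def power_curve(improvement_grid, cv_value: float, n_replicates: int = 1,
                sd_multiplier: float = 2.0, seed: int = 0, n_draws: int = 10_000,
                noise: str = "normal") -> np.ndarray:
    """Monte-Carlo detection probability against the m·SD threshold.

    For each fractional improvement on the grid, a mutant's normalised score
    is drawn with multiplicative noise of coefficient of variance ``cv_value``
    (mean over ``n_replicates`` single reads; the protocol reads each well
    once) and compared with the threshold 1 + sd_multiplier·CV.  ``noise``
    is ``"normal"`` (symmetric) or ``"lognormal"``.
    """
    grid = np.atleast_1d(np.asarray(improvement_grid, float))
    if np.any(grid < 0):
        raise ValueError("improvements must be nonnegative")
    if cv_value < 0:
        raise ValueError("CV must be nonnegative")
    rng = np.random.default_rng(seed)
    threshold = 1.0 + sd_multiplier * cv_value
    probs = np.empty(len(grid))
    for i, imp in enumerate(grid):
        mean_score = 1.0 + imp
        if noise == "normal":
            reads = mean_score * (1.0 + cv_value *
                                  rng.standard_normal((n_draws, n_replicates)))
        elif noise == "lognormal":
            sigma = np.sqrt(np.log1p(cv_value ** 2))
            reads = mean_score * rng.lognormal(-sigma ** 2 / 2, sigma,
                                               (n_draws, n_replicates))
        else:
            raise ValueError(f"unknown noise model {noise!r}")
        probs[i] = np.mean(reads.mean(axis=1) > threshold)
    return probs


@dataclass
class PlateStats:
    """Wild-type control statistics for one plate."""

    plate_id: str
    n_wt: int
    wt_mean_pre: float
    wt_sd_pre: float
    wt_mean_ratio: float
    wt_sd_ratio: float
    degenerate: bool = False  # zero WT variance

    @property
    def cv_pre(self) -> float:
        return self.wt_sd_pre / self.wt_mean_pre

    @property
    def cv_ratio(self) -> float:
        return self.wt_sd_ratio / self.wt_mean_ratio


@dataclass
class ScreenSummary:
    """Per-plate and pooled wild-type statistics, thresholds and hit counts."""

    plate_stats: list[PlateStats]
    sd_multiplier: float
    min_pre_activity_fraction: float
    pooled_cv_ratio: float
    pooled_cv_pre: float
    n_tolerance_hits: int
    n_activity_hits: int
    n_qc_failed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "plate_id": s.plate_id, "n_wt": s.n_wt,
            "wt_mean_pre": s.wt_mean_pre, "wt_cv_pre": s.cv_pre,
            "wt_mean_ratio": s.wt_mean_ratio, "wt_cv_ratio": s.cv_ratio,
            "degenerate": s.degenerate,
        } for s in self.plate_stats])


class ScreenModel:
    """Hit-calling model over a table of well measurements.

    Parameters
    ----------
    wells : DataFrame
        Columns ``plate_id, well_id, role, pre_activity, post_activity``:
        pre-exposure activity per µL CFPS (1 µL assayed) and the raw
        post-exposure activity (``volume_factor`` µL assayed).
    config : ScreenConfig
        Thresholds and protocol constants.
    pool_plates : bool
        If True, threshold statistics pool wild-type wells across plates.
        Off by default: replicate experiments show between-day drift, which
        is exactly what per-plate controls exist to absorb.
    """

    REQUIRED = ("plate_id", "well_id", "role", "pre_activity", "post_activity")

    def __init__(self, wells: pd.DataFrame, config: ScreenConfig | None = None,
                 *, pool_plates: bool = False):
        missing = set(self.REQUIRED) - set(wells.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        self.wells = wells.copy()
        self.config = config or ScreenConfig()
        self.pool_plates = pool_plates

    @classmethod
    def from_measurements(cls, pre: pd.DataFrame, post: pd.DataFrame,
                          plate_map: pd.DataFrame, config: ScreenConfig | None = None
                          ) -> "ScreenModel":
        """Join pre/post activity tables (well_id, activity_per_ul-style
        columns) with a plate map (well, role)."""
        def _prep(df: pd.DataFrame, name: str) -> pd.DataFrame:
            col = "activity_per_ul" if "activity_per_ul" in df.columns else "activity"
            out = df[["well_id", col]].rename(columns={col: name})
            return out
        m = plate_map.rename(columns={"well": "well_id"})
        if "plate_id" not in m.columns:
            m = m.assign(plate_id="plate1")
        merged = (m[["plate_id", "well_id", "role"]]
                  .merge(_prep(pre, "pre_activity"), on="well_id")
                  .merge(_prep(post, "post_activity"), on="well_id"))
        return cls(merged, config)

    def fit(self) -> "ScreenResults":
        cfg = self.config
        df = self.wells.copy()
        vf = cfg.volume_factor_post_over_pre

        with np.errstate(divide="ignore", invalid="ignore"):
            df["residual_ratio"] = np.where(
                df["pre_activity"] > 0,
                (df["post_activity"] / vf) / df["pre_activity"], np.nan)

        # per-plate QC cutoff: a fraction of the plate's wild-type mean
        # pre-exposure activity (sits above the CAT / no-template background)
        plate_groups = df.groupby("plate_id", sort=False)
        stats_rows: list[PlateStats] = []
        parts: list[pd.DataFrame] = []
        for plate_id, sub in plate_groups:
            wt = sub[sub["role"] == Role.WILDTYPE.value]
            if len(wt) < 2:
                raise PlateRejectedError(
                    f"plate {plate_id!r}: needs >= 2 wild-type control wells "
                    "for normalisation")
            cutoff = cfg.min_pre_activity_fraction_of_wt * wt["pre_activity"].mean()
            sub = qc_filter(sub, cutoff)
            wt_ok = sub[(sub["role"] == Role.WILDTYPE.value) & sub["qc_pass"]]
            if len(wt_ok) < 2:
                raise PlateRejectedError(
                    f"plate {plate_id!r}: fewer than 2 wild-type controls "
                    "pass QC")
            mean_pre = wt_ok["pre_activity"].mean()
            mean_ratio = wt_ok["residual_ratio"].mean()
            sub["normalized_tolerance"] = sub["residual_ratio"] / mean_ratio
            sub["normalized_activity"] = sub["pre_activity"] / mean_pre
            sub.loc[~sub["qc_pass"], ["normalized_tolerance",
                                      "normalized_activity"]] = np.nan
            stats_rows.append(PlateStats(
                str(plate_id), len(wt_ok), float(mean_pre),
                float(wt_ok["pre_activity"].std(ddof=1)), float(mean_ratio),
                float(wt_ok["residual_ratio"].std(ddof=1))))
            parts.append(sub)
        df = pd.concat(parts)

        # thresholds on the normalised scale, from wild-type wells
        df["tolerance_hit"] = False
        df["activity_hit"] = False
        if self.pool_plates:
            thresholds = {s.plate_id: self._pooled_thresholds(df) for s in stats_rows}
        else:
            thresholds = {}
        for s in stats_rows:
            sub_idx = df["plate_id"].astype(str) == s.plate_id
            wt = df[sub_idx & (df["role"] == Role.WILDTYPE.value) & df["qc_pass"]]
            if self.pool_plates:
                thr_tol, thr_act = thresholds[s.plate_id]
            else:
                sd_tol = wt["normalized_tolerance"].std(ddof=1)
                sd_act = wt["normalized_activity"].std(ddof=1)
                if sd_tol == 0 or sd_act == 0:
                    s.degenerate = True
                thr_tol = wt["normalized_tolerance"].mean() + cfg.sd_multiplier * sd_tol
                thr_act = wt["normalized_activity"].mean() + cfg.sd_multiplier * sd_act
            ok = sub_idx & df["qc_pass"]
            df.loc[ok, "tolerance_hit"] = df.loc[ok, "normalized_tolerance"] > thr_tol
            df.loc[ok, "activity_hit"] = df.loc[ok, "normalized_activity"] > thr_act

        is_sample = df["role"] == Role.SAMPLE.value
        pooled_ratio = [s.cv_ratio for s in stats_rows]
        pooled_pre = [s.cv_pre for s in stats_rows]
        summary = ScreenSummary(
            plate_stats=stats_rows,
            sd_multiplier=cfg.sd_multiplier,
            min_pre_activity_fraction=cfg.min_pre_activity_fraction_of_wt,
            pooled_cv_ratio=float(np.mean(pooled_ratio)),
            pooled_cv_pre=float(np.mean(pooled_pre)),
            n_tolerance_hits=int((df["tolerance_hit"] & is_sample).sum()),
            n_activity_hits=int((df["activity_hit"] & is_sample).sum()),
            n_qc_failed=int((~df["qc_pass"]).sum()),
        )
        return ScreenResults(self, df, summary)

    def _pooled_thresholds(self, df: pd.DataFrame) -> tuple[float, float]:
        wt = df[(df["role"] == Role.WILDTYPE.value) & df["qc_pass"]]
        m = self.config.sd_multiplier
        return (wt["normalized_tolerance"].mean() + m * wt["normalized_tolerance"].std(ddof=1),
                wt["normalized_activity"].mean() + m * wt["normalized_activity"].std(ddof=1))


@dataclass
class ScreenResults:
    """Scored wells, hit lists and wild-type variability summary."""

    model: ScreenModel
    records: pd.DataFrame
    screen_summary: ScreenSummary
    _hits_cache: dict = field(default_factory=dict, repr=False)

    def hits(self, kind: str = "tolerance") -> pd.DataFrame:
        """Sample wells flagged as hits; ``kind`` is tolerance or activity."""
        col = {"tolerance": "tolerance_hit", "activity": "activity_hit"}[kind]
        df = self.records
        return df[(df["role"] == Role.SAMPLE.value) & df[col]].copy()

    def summary(self) -> str:
        s = self.screen_summary
        lines = [
            "Oxygen-tolerance screen results",
            "=" * 64,
            f"wells analysed        : {len(self.records)}"
            f"  (QC-failed: {s.n_qc_failed})",
            f"hit threshold         : wild-type mean + "
            f"{s.sd_multiplier:g} SD (per plate)",
            f"QC cutoff             : pre-activity >= "
            f"{s.min_pre_activity_fraction:.0%} of plate WT mean",
            f"tolerance hits        : {s.n_tolerance_hits}",
            f"activity hits         : {s.n_activity_hits}",
            f"pooled WT ratio CV    : {s.pooled_cv_ratio:.3f}",
            f"pooled WT activity CV : {s.pooled_cv_pre:.3f}",
            f"detectable improvement: "
            f"{detectable_improvement(s.pooled_cv_ratio, s.sd_multiplier):.0%} "
            "(tolerance score)",
            "-" * 64,
            "per-plate wild-type controls:",
        ]
        for p in s.plate_stats:
            flag = "  [degenerate: zero WT variance]" if p.degenerate else ""
            lines.append(f"  {p.plate_id}: n={p.n_wt}, ratio CV={p.cv_ratio:.3f}, "
                         f"activity CV={p.cv_pre:.3f}{flag}")
        return "\n".join(lines)
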