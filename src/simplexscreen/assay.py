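"""Methyl viologen kinetics: absorbance slopes to hydrogenase activities.

Methyl viologen (MV) is clear when oxidised and blue when reduced; as
hydrogenase oxidises H2 it reduces MV, and the A578 slope of the assay
solution is proportional to activity.  The chain of conversions is

    slope (AU/min)
      ÷ conversion coefficient (9.78 AU per mM reduced MV)  → mM MV/min
      × assay volume (µL), ×10^3                            → pmol MV/min
      ÷ electrons per H2 (2 single-electron reductions)     → pmol H2/min
      ÷ CFPS volume assayed (µL)                            → pmol H2/min/µL
      ÷ protein mass (ng)                                   → pmol H2/min/ng

The printed coefficient is treated as a lumped, path-length-inclusive
constant: whether it assumes a 1 cm cuvette or folds in the plate depth is
not specified, so it is configurable everywhere it appears.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

DEFAULT_CONVERSION_COEFFICIENT = 9.78  # AU per mM reduced MV
NONLINEARITY_R2 = 0.9


@dataclass(frozen=True)
class AbsorbanceTrace:
    """One well's A578 time series from the plate reader."""

    well_id: str
    times_s: np.ndarray
    a578: np.ndarray
    assay_volume_ul: float = 200.0
    mv_concentration_mM: float = 2.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, float)
        a = np.asarray(self.a578, float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "a578", a)
        if t.shape != a.shape:
            raise ValueError(f"{self.well_id}: times and absorbances must align")
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError(f"{self.well_id}: times must be strictly increasing")

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1] - self.times_s[0]) if len(self.times_s) else 0.0


@dataclass(frozen=True)
class SlopeFit:
    slope_au_per_min: float
    intercept_au: float
    rsquared: float
    stderr_au_per_min: float
    linear: bool  # R² >= 0.9 (or degenerate flat trace)


def fit_slope(trace: AbsorbanceTrace, window_s: tuple[float, float] | None = None,
              ) -> SlopeFit:
    """Ordinary least-squares slope of A578 against time, in AU/min.

    Fits the full trace by default, or a ``(start, stop)`` window in
    seconds.  Traces with R² below 0.9 are flagged nonlinear.
    """
    t, a = trace.times_s, trace.a578
    if window_s is not None:
        keep = (t >= window_s[0]) & (t <= window_s[1])
        t, a = t[keep], a[keep]
    if len(t) < 3:
        raise ValueError(f"{trace.well_id}: need >= 3 points to fit a slope")
    tm = t / 60.0
    slope, intercept = np.polyfit(tm, a, 1)
    fitted = slope * tm + intercept
    ss_res = float(((a - fitted) ** 2).sum())
    ss_tot = float(((a - a.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = len(t) - 2
    sxx = float(((tm - tm.mean()) ** 2).sum())
    se = float(np.sqrt(ss_res / dof / sxx)) if dof > 0 and sxx > 0 else np.nan
    return SlopeFit(float(slope), float(intercept), r2, se,
                    linear=r2 >= NONLINEARITY_R2)


def best_linear_window(trace: AbsorbanceTrace, min_points: int = 5) -> SlopeFit:
    """Initial-window selector for saturating traces: the prefix (>= 5
    points) maximising R².  Optional; the protocol fits the full 2-minute
    read."""
    if len(trace.times_s) < min_points:
        raise ValueError("trace shorter than the minimum window")
    best: SlopeFit | None = None
    for stop in range(min_points, len(trace.times_s) + 1):
        sub = AbsorbanceTrace(trace.well_id, trace.times_s[:stop],
                              trace.a578[:stop], trace.assay_volume_ul,
                              trace.mv_concentration_mM)
        fit = fit_slope(sub)
        if best is None or fit.rsquared > best.rsquared:
            best = fit
    assert best is not None
    return best


def slope_to_mv_rate(slope_au_per_min: float,
                     conversion_coefficient: float = DEFAULT_CONVERSION_COEFFICIENT
                     ) -> float:
    """AU/min → mM reduced MV per minute via the lumped Beer's-law constant."""
    if conversion_coefficient <= 0:
        raise ValueError("conversion coefficient must be positive")
    return slope_au_per_min / conversion_coefficient


def mv_rate_to_h2_rate(mv_rate_mM_per_min: float, assay_volume_ul: float = 200.0,
                       electrons_per_h2: int = 2) -> float:
    """mM MV/min → pmol H2/min.

    mM × µL = nmol; ×10³ → pmol; each H2 provides two single-electron MV
    reductions, so pmol H2 = pmol MV / electrons_per_h2.
    """
    if assay_volume_ul <= 0:
        raise ValueError("assay volume must be positive")
    return mv_rate_mM_per_min * assay_volume_ul * 1e3 / electrons_per_h2


@dataclass(frozen=True)
class ActivityMeasurement:
    """One well's activity: slope, converted rates and per-µL-CFPS activity."""

    well_id: str
    slope_au_per_min: float
    mv_rate_mM_per_min: float
    h2_rate_pmol_per_min: float
    cfps_volume_assayed_ul: float
    rsquared: float = np.nan
    background_dominated: bool = False  # negative slope in a consumption assay

    @property
    def activity_per_ul(self) -> float:
        """pmol H2/min per µL of CFPS product assayed."""
        return self.h2_rate_pmol_per_min / self.cfps_volume_assayed_ul


def trace_to_activity(trace: AbsorbanceTrace, cfps_volume_assayed_ul: float,
                      conversion_coefficient: float = DEFAULT_CONVERSION_COEFFICIENT,
                      electrons_per_h2: int = 2) -> ActivityMeasurement:
    """Full conversion pipeline for one trace.

    Sign convention: H2 consumption reduces MV, so the slope is positive;
    a negative slope is kept but flagged background-dominated.
    """
    fit = fit_slope(trace)
    mv = slope_to_mv_rate(fit.slope_au_per_min, conversion_coefficient)
    h2 = mv_rate_to_h2_rate(mv, trace.assay_volume_ul, electrons_per_h2)
    return ActivityMeasurement(trace.well_id, fit.slope_au_per_min, mv, h2,
                               cfps_volume_assayed_ul, fit.rsquared,
                               background_dominated=fit.slope_au_per_min < 0)


@dataclass(frozen=True)
class SpecificActivity:
    """Enzymatic rate per mass of enzyme, pmol H2/min/ng."""

    rate_pmol_per_min: float
    protein_mass_ng: float
    direction: Literal["consumption", "production"] = "consumption"

    def __post_init__(self) -> None:
        if self.protein_mass_ng <= 0:
            raise ValueError("protein mass must be positive")

    @property
    def value(self) -> float:
        return self.rate_pmol_per_min / self.protein_mass_ng


def specific_activity(rate_pmol_per_min: float, protein_mass_ng: float,
                      direction: Literal["consumption", "production"] = "consumption"
                      ) -> SpecificActivity:
    """Specific activity = rate / protein mass (pmol H2/min/ng)."""
    return SpecificActivity(rate_pmol_per_min, protein_mass_ng, direction)


def fold_improvement(mutant: SpecificActivity, wildtype: SpecificActivity,
                     expression_similarity_band: float = 0.25) -> float:
    """Mutant / wild-type specific-activity ratio.

    Because the matured (active) fraction of hydrogenase depends on the
    expression level, the ratio is only meaningful when the two samples'
    protein yields are similar; yields differing by more than the band
    (default ±25%) raise an error rather than returning a biased ratio.
    """
    if mutant.direction != wildtype.direction:
        raise ValueError("cannot compare specific activities measured in "
                         "different reaction directions")
    if wildtype.value <= 0:
        raise ValueError("wild-type specific activity must be positive")
    rel = abs(mutant.protein_mass_ng - wildtype.protein_mass_ng) / wildtype.protein_mass_ng
    if rel > expression_similarity_band:
        raise ValueError(
            f"expression levels differ by {rel:.0%} (> ±{expression_similarity_band:.0%}); "
            "specific activities are only comparable at similar yields")
    return mutant.value / wildtype.value


def protein_mass_from_counts(counts_per_min: float, counting_efficiency: float,
                             leucine_specific_radioactivity_dpm_per_pmol: float,
                             leucines_per_protein: int,
                             protein_molar_mass_g_per_mol: float) -> float:
    """Radiolabel counting arithmetic → protein mass (ng).

    Pure unit conversion for 14C-leucine incorporation measurements: counts
    are corrected for counting efficiency to disintegrations, divided by the
    label's specific radioactivity to pmol leucine, by the leucines per
    chain to pmol protein, and scaled by the molar mass to ng.  All
    parameters are user-supplied; the counting chemistry itself is out of
    scope.
    """
    if not 0 < counting_efficiency <= 1:
        raise ValueError("counting efficiency must be in (0, 1]")
    dpm = counts_per_min / counting_efficiency
    pmol_leu = dpm / leucine_specific_radioactivity_dpm_per_pmol
    pmol_protein = pmol_leu / leucines_per_protein
    return pmol_protein * protein_molar_mass_g_per_mol * 1e-3  # pmol × g/mol = pg ×1e-3 → ng
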