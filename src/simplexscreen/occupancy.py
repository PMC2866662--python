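"""Poisson statistics of limiting dilution and single-molecule PCR.

In a limiting-dilution screen, template molecules are distributed over the
wells of a PCR plate so that gene counts per well follow a Poisson
distribution with mean λ (molecules/well).  The operating point λ = 2.3
leaves e^−2.3 ≈ 10% of wells empty.  The fraction of wells in which a PCR
amplifies (≥ 1 template) estimates λ through the zero class:
λ̂ = −ln(1 − f) — the most-probable-number (MPN) estimator.  Running the
same template mix at several reaction volumes and checking the implied
per-volume concentrations for agreement validates single-molecule
amplification; that check is a likelihood-ratio test fitted by
:class:`DilutionSeriesModel`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats


class EstimateSaturatedError(ValueError):
    """All wells amplified: the zero class is empty and λ has no MLE."""


class DegenerateFitError(ValueError):
    """All rows empty or all saturated: the common concentration is not identifiable."""


@dataclass(frozen=True)
class OccupancyModel:
    """Poisson occupancy design: mean molecules per well at a reference volume."""

    mean_molecules_per_well: float
    reference_volume: float = 5.0  # µL of template mix per well

    def __post_init__(self) -> None:
        if self.mean_molecules_per_well < 0:
            raise ValueError("mean molecules per well must be >= 0")
        if self.reference_volume <= 0:
            raise ValueError("reference volume must be positive")

    @property
    def p_empty(self) -> float:
        """Probability a well receives no template, e^−λ."""
        return math.exp(-self.mean_molecules_per_well)

    @classmethod
    def from_empty_fraction(cls, p_empty: float, reference_volume: float = 5.0
                            ) -> "OccupancyModel":
        """Design from a target empty-well fraction: λ = −ln P(0)."""
        if not 0 < p_empty <= 1:
            raise ValueError("empty-well fraction must be in (0, 1]")
        return cls(-math.log(p_empty), reference_volume)


def occupancy_pmf(model: OccupancyModel, k_max: int) -> tuple[np.ndarray, float]:
    """Poisson occupancy probabilities P(k) for k = 0..k_max.

    Returns ``(pmf, tail)`` where ``tail`` is the truncated mass P(k > k_max).
    """
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    lam = model.mean_molecules_per_well
    k = np.arange(k_max + 1)
    pmf = stats.poisson.pmf(k, lam)
    tail = float(stats.poisson.sf(k_max, lam))
    return pmf, tail


def multi_gene_fraction(model: OccupancyModel) -> float:
    """Fraction of occupied wells holding two or more genes, P(k≥2 | k≥1).

    Wells with multiple genes average the signals of their member mutants,
    which distorts the screen's per-gene readout; this is the design
    trade-off against empty wells.
    """
    lam = model.mean_molecules_per_well
    if lam == 0:
        return 0.0
    p0 = math.exp(-lam)
    p1 = lam * p0
    return (1.0 - p0 - p1) / (1.0 - p0)


@dataclass(frozen=True)
class AmplificationTable:
    """Amplification outcomes of a graded-volume dilution series.

    One row per reaction volume: how many wells were run and how many
    amplified.  ``n_amplified`` may be real-valued so that a published
    percent-amplified figure can be used directly (quasi-likelihood).
    """

    reaction_volume_ul: tuple[float, ...]
    n_wells: tuple[int, ...]
    n_amplified: tuple[float, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.reaction_volume_ul, float)
        n = np.asarray(self.n_wells)
        a = np.asarray(self.n_amplified, float)
        if not (len(v) == len(n) == len(a)):
            raise ValueError("ragged table")
        if np.any(v <= 0):
            raise ValueError("reaction volumes must be positive")
        if np.any(n <= 0):
            raise ValueError("n_wells must be positive")
        if np.any(a < 0) or np.any(a > n):
            raise ValueError("n_amplified must lie in [0, n_wells]")

    @property
    def fraction_amplified(self) -> np.ndarray:
        return (np.asarray(self.n_amplified, float)
                / np.asarray(self.n_wells, float))

    @classmethod
    def from_fractions(cls, volumes: Sequence[float], fractions: Sequence[float],
                       n_wells: int | Sequence[int] = 31) -> "AmplificationTable":
        """Build from printed percent-amplified values (as fractions).

        Default 31 wells/row: a 96-well plate split into thirds minus three
        no-template controls.
        """
        volumes = tuple(float(v) for v in volumes)
        if np.isscalar(n_wells):
            n = tuple([int(n_wells)] * len(volumes))
        else:
            n = tuple(int(x) for x in n_wells)  # type: ignore[union-attr]
        amp = tuple(f * m for f, m in zip(fractions, n))
        return cls(volumes, n, amp)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AmplificationTable":
        df = pd.read_csv(path)
        required = {"reaction_volume_ul", "n_wells", "n_amplified"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        return cls(tuple(df["reaction_volume_ul"].astype(float)),
                   tuple(df["n_wells"].astype(int)),
                   tuple(df["n_amplified"].astype(float)))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "reaction_volume_ul": self.reaction_volume_ul,
            "n_wells": self.n_wells,
            "n_amplified": self.n_amplified,
        }).to_csv(path, index=False)


@dataclass(frozen=True)
class LambdaEstimate:
    """Zero-class (MPN) estimate of mean molecules per reaction."""

    lambda_hat: float
    ci_low: float
    ci_high: float
    reaction_volume: float
    reference_volume: float = 5.0
    saturated: bool = False

    @property
    def lambda_per_reference(self) -> float:
        return self.lambda_hat * self.reference_volume / self.reaction_volume

    def scale_to_reference(self, reference_volume: float) -> "LambdaEstimate":
        """Rescale the estimate (and CI) to a reference reaction volume."""
        if reference_volume <= 0:
            raise ValueError("reference volume must be positive")
        r = reference_volume / self.reaction_volume
        return LambdaEstimate(self.lambda_hat * r, self.ci_low * r,
                              self.ci_high * r, reference_volume,
                              reference_volume, self.saturated)


def estimate_lambda(n_amplified: float, n_wells: int, reaction_volume: float = 5.0,
                    reference_volume: float = 5.0, alpha: float = 0.05
                    ) -> LambdaEstimate:
    """MPN estimate λ̂ = −ln(1 − f) from the fraction of amplified wells.

    The confidence interval is a Clopper–Pearson binomial interval on f
    pushed through the monotone map −ln(1−f), which behaves sensibly as f
    approaches 0 or 1.  A fully amplified row (f = 1) has no point estimate;
    a one-sided lower bound is returned with ``saturated=True``.
    """
    if n_wells <= 0:
        raise ValueError("n_wells must be positive")
    if not 0 <= n_amplified <= n_wells:
        raise ValueError("n_amplified must lie in [0, n_wells]")
    f = n_amplified / n_wells
    lo, hi = _clopper_pearson(n_amplified, n_wells, alpha)
    ci_low = -math.log1p(-lo)
    if f >= 1.0:
        return LambdaEstimate(math.inf, ci_low, math.inf, reaction_volume,
                              reference_volume, saturated=True)
    ci_high = math.inf if hi >= 1.0 else -math.log1p(-hi)
    return LambdaEstimate(-math.log1p(-f), ci_low, ci_high, reaction_volume,
                          reference_volume)


def _clopper_pearson(x: float, n: int, alpha: float) -> tuple[float, float]:
    # non-integer x supported by the beta quantile form
    lo = 0.0 if x <= 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x >= n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lo, hi


class DilutionSeriesModel:
    """Common-concentration model for a graded-volume amplification series.

    Under successful single-molecule PCR, every row of the series sees the
    same template concentration c (molecules/µL), so the amplified fraction
    follows f_i = 1 − e^(−c·V_i).  ``fit`` estimates c by maximum
    (quasi-)likelihood and tests the common-c model against the saturated
    per-row model with a likelihood-ratio statistic on rows − 1 degrees of
    freedom.  Agreement (a large p-value) is the published consistency check
    for successful smPCR.
    """

    def __init__(self, table: AmplificationTable, reference_volume: float = 5.0):
        if len(table.reaction_volume_ul) < 2:
            raise ValueError("need at least 2 rows")
        if len(set(table.reaction_volume_ul)) != len(table.reaction_volume_ul):
            raise ValueError("reaction volumes must be distinct")
        self.table = table
        self.reference_volume = reference_volume

    def loglike(self, c: float) -> float:
        v = np.asarray(self.table.reaction_volume_ul, float)
        n = np.asarray(self.table.n_wells, float)
        a = np.asarray(self.table.n_amplified, float)
        with np.errstate(divide="ignore", invalid="ignore"):
            logp = np.log(-np.expm1(-c * v))
        terms = np.where(a > 0, a * logp, 0.0) + (n - a) * (-c * v)
        return float(terms.sum())

    def fit(self, alpha: float = 0.05) -> "DilutionSeriesResults":
        a = np.asarray(self.table.n_amplified, float)
        n = np.asarray(self.table.n_wells, float)
        if np.all(a == 0) or np.all(a == n):
            raise DegenerateFitError(
                "all rows empty or all saturated; concentration not identifiable")
        v = np.asarray(self.table.reaction_volume_ul, float)
        f = self.table.fraction_amplified
        # bracket from per-row MPN estimates
        per_row = -np.log1p(-np.clip(f, 0, 1 - 1e-12)) / v
        c0 = max(per_row.mean(), 1e-9)
        res = optimize.minimize_scalar(
            lambda c: -self.loglike(c),
            bounds=(c0 * 1e-3, max(c0 * 1e3, 1e-6)), method="bounded",
            options={"xatol": 1e-12})
        c_hat = float(res.x)
        ll_common = self.loglike(c_hat)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll_sat = float(np.sum(np.where(a > 0, a * np.log(f), 0.0)
                                  + np.where(n - a > 0, (n - a) * np.log1p(-f), 0.0)))
        lr = max(2.0 * (ll_sat - ll_common), 0.0)
        df = len(v) - 1
        p = float(stats.chi2.sf(lr, df))
        rows = [estimate_lambda(ai, int(ni), vi, self.reference_volume, alpha)
                for ai, ni, vi in zip(a, self.table.n_wells, v)]
        return DilutionSeriesResults(self, c_hat, lr, df, p, rows, alpha)


@dataclass
class DilutionSeriesResults:
    """Fitted common concentration and the consistency likelihood-ratio test."""

    model: DilutionSeriesModel
    concentration_per_ul: float
    lr_statistic: float
    df: int
    p_value: float
    row_estimates: list[LambdaEstimate] = field(default_factory=list)
    alpha: float = 0.05

    @property
    def common_lambda_per_reference(self) -> float:
        return self.concentration_per_ul * self.model.reference_volume

    def consistent(self, level: float = 0.05) -> bool:
        return self.p_value >= level

    def summary(self) -> str:
        ref = self.model.reference_volume
        lines = [
            "Dilution series: common-concentration fit",
            "=" * 57,
            f"{'volume (µL)':>12} {'f amplified':>12} {'λ/reaction':>11} "
            f"{'λ/' + format(ref, 'g') + ' µL':>10}",
        ]
        for est, frac in zip(self.row_estimates,
                             self.model.table.fraction_amplified):
            lam = "sat." if est.saturated else f"{est.lambda_hat:.2f}"
            per = "sat." if est.saturated else f"{est.lambda_per_reference:.2f}"
            lines.append(f"{est.reaction_volume:>12g} {frac:>12.3f} "
                         f"{lam:>11} {per:>10}")
        lines += [
            "-" * 57,
            f"common concentration: {self.concentration_per_ul:.4f} molecules/µL "
            f"({self.common_lambda_per_reference:.2f} per {ref:g} µL)",
            f"LR consistency test:  X2 = {self.lr_statistic:.3f}, "
            f"df = {self.df}, p = {self.p_value:.3f}",
            ("rows consistent with a single concentration"
             if self.consistent() else
             "rows NOT consistent with a single concentration (p < 0.05)"),
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "reaction_volume_ul": [e.reaction_volume for e in self.row_estimates],
            "fraction_amplified": self.model.table.fraction_amplified,
            "lambda_hat": [e.lambda_hat for e in self.row_estimates],
            "ci_low": [e.ci_low for e in self.row_estimates],
            "ci_high": [e.ci_high for e in self.row_estimates],
            "lambda_per_reference": [e.lambda_per_reference
                                     for e in self.row_estimates],
            "saturated": [e.saturated for e in self.row_estimates],
        })


def consistency_check(table: AmplificationTable, reference_volume: float = 5.0
                      ) -> DilutionSeriesResults:
    """Fit the common-concentration model and run the LR consistency test."""
    return DilutionSeriesModel(table, reference_volume).fit()


@dataclass(frozen=True)
class DilutionStep:
    ratio: float
    cumulative_factor: float


def plan_dilution(stock_concentration: float, target_concentration: float,
                  step_ratio: float = 1001.0, recovery_per_step: float = 1.0
                  ) -> list[DilutionStep]:
    """Plan a serial dilution from stock to a working concentration.

    Steps of equal ratio (default 1001x: 1 µL into 1 mL) are taken until the
    cumulative factor covers stock/target; the final step's ratio is adjusted
    to land exactly on target.  ``recovery_per_step`` (< 1) models template
    lost per transfer, e.g. to tube-wall adsorption, inflating the effective
    dilution of each step.
    """
    if stock_concentration <= 0 or target_concentration <= 0:
        raise ValueError("concentrations must be positive")
    if step_ratio <= 1:
        raise ValueError("step ratio must exceed 1")
    if not 0 < recovery_per_step <= 1:
        raise ValueError("recovery per step must be in (0, 1]")
    if target_concentration >= stock_concentration:
        return []
    factor_needed = stock_concentration / target_concentration
    eff_step = step_ratio / recovery_per_step
    n_steps = math.ceil(math.log(factor_needed) / math.log(eff_step))
    steps: list[DilutionStep] = []
    cum = 1.0
    for _ in range(n_steps - 1):
        cum *= eff_step
        steps.append(DilutionStep(step_ratio, cum))
    final_eff = factor_needed / cum
    steps.append(DilutionStep(final_eff * recovery_per_step, factor_needed))
    return steps
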