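"""Oxygen deactivation of hydrogenase as exponential decay in exposure volume.

The screen deactivates hydrogenase by adding a volume V of air-equilibrated
buffer (~0.25 mM dissolved O2) to each well.  Residual activity, normalised
to the unexposed slope, is modelled as R(V) = exp(−k·V): the dose variable
is the buffer volume itself, because the O2 concentration profile during the
10-minute incubation (loss to the anaerobic atmosphere, scavenging by the
extract) is not quantitatively known.  The decay constant k lets the
exposure be tuned to the screen's 15–20% residual-activity operating band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize


@dataclass(frozen=True)
class OxygenDose:
    """Oxygen delivered by a volume of air-equilibrated buffer."""

    exposure_volume_ul: float
    dissolved_o2_mM: float = 0.25

    @property
    def o2_nmol(self) -> float:
        # µL × mM = nmol
        return self.exposure_volume_ul * self.dissolved_o2_mM


def o2_dose(exposure_volume_ul: float, concentration_mM: float = 0.25) -> float:
    """Amount of dissolved O2 (nmol) in an exposure volume (µL) at a given mM."""
    if exposure_volume_ul < 0 or concentration_mM < 0:
        raise ValueError("volume and concentration must be nonnegative")
    return exposure_volume_ul * concentration_mM


class ExponentialDecayModel:
    """Exponential deactivation model R(V) = exp(−k·V).

    Parameters
    ----------
    exposure_volume_ul : array-like
        Volumes of air-equilibrated buffer added, µL.
    residual_activity : array-like
        Activity after exposure as a fraction of the unexposed activity.
        Values slightly above 1 are tolerated (measurement noise at V = 0).
    sd : array-like, optional
        Replicate standard deviations, used as weights if given.
    free_intercept : bool
        If True fit R(V) = A·exp(−k·V) instead of pinning R(0) = 1.  The
        default pins the intercept because residual activities are already
        normalised to the unexposed slope.
    plateau : bool
        If True fit R(V) = (1−c)·exp(−k·V) + c, allowing an oxygen-tolerant
        asymptote.  Off by default: no tolerant fraction has been observed.
    """

    def __init__(self, exposure_volume_ul, residual_activity, sd=None, *,
                 free_intercept: bool = False, plateau: bool = False):
        v = np.asarray(exposure_volume_ul, float)
        r = np.asarray(residual_activity, float)
        if v.shape != r.shape:
            raise ValueError("volumes and residuals must align")
        if len(np.unique(v)) < 2:
            raise ValueError("need observations at >= 2 distinct volumes")
        keep = r > 0
        if not keep.all():
            warnings.warn(f"excluding {int((~keep).sum())} non-positive "
                          "residual activities", stacklevel=2)
        self.exposure_volume_ul = v[keep]
        self.residual_activity = r[keep]
        self.sd = None if sd is None else np.asarray(sd, float)[keep]
        self.free_intercept = free_intercept
        self.plateau = plateau

    def fit(self, *, log_linear: bool = False) -> "DecayResults":
        """Nonlinear least squares on the linear scale (default).

        ``log_linear=True`` instead regresses ln R on V — simpler, but it
        amplifies noise at small residuals, so it is a fallback only.
        """
        v, r = self.exposure_volume_ul, self.residual_activity
        if log_linear:
            if self.free_intercept:
                b, a = np.polyfit(v, np.log(r), 1)
                k, amp, c = -b, float(np.exp(a)), 0.0
            else:
                # regression through the origin of ln R on V
                k = float(-(v @ np.log(r)) / (v @ v))
                amp, c = 1.0, 0.0
        else:
            k0 = self._k_start()
            sigma = self.sd if self.sd is not None and np.all(self.sd > 0) else None
            if self.plateau:
                def f(V, k, c):
                    return (1 - c) * np.exp(-k * V) + c
                p, _ = optimize.curve_fit(f, v, r, p0=[k0, 0.0], sigma=sigma,
                                          bounds=([0, 0], [np.inf, 1]),
                                          maxfev=10000)
                k, c, amp = float(p[0]), float(p[1]), 1.0
            elif self.free_intercept:
                def f(V, k, A):
                    return A * np.exp(-k * V)
                p, _ = optimize.curve_fit(f, v, r, p0=[k0, 1.0], sigma=sigma,
                                          maxfev=10000)
                k, amp, c = float(p[0]), float(p[1]), 0.0
            else:
                def f(V, k):
                    return np.exp(-k * V)
                p, _ = optimize.curve_fit(f, v, r, p0=[k0], sigma=sigma,
                                          bounds=(0, np.inf), maxfev=10000)
                k, amp, c = float(p[0]), 1.0, 0.0
        if np.allclose(r, 1.0):
            k = 0.0  # no decay: the optimiser has nothing to fit
        fitted = amp * (1 - c) * np.exp(-k * v) + amp * c
        resid = r - fitted
        ss_res = float(resid @ resid)
        ss_tot = float(((r - r.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        at_boundary = k <= 0 or np.allclose(r, 1.0)
        return DecayResults(self, k, amp, c, resid, r2, at_boundary)

    def _k_start(self) -> float:
        v, r = self.exposure_volume_ul, self.residual_activity
        pos = v > 0
        if not pos.any():
            return 0.1
        return float(max(np.median(-np.log(r[pos]) / v[pos]), 1e-6))


@dataclass
class DecayResults:
    """Fitted deactivation curve: decay constant, residuals and fit quality."""

    model: ExponentialDecayModel
    rate_per_ul: float
    amplitude: float
    plateau: float
    resid: np.ndarray
    rsquared: float
    at_boundary: bool = False

    def predict(self, exposure_volume_ul) -> np.ndarray:
        v = np.asarray(exposure_volume_ul, float)
        return (self.amplitude * (1 - self.plateau) * np.exp(-self.rate_per_ul * v)
                + self.amplitude * self.plateau)

    def volume_for_target(self, target_residual: float,
                          o2_concentration_mM: float = 0.25
                          ) -> tuple[float, OxygenDose]:
        """Exposure volume achieving a target residual activity.

        V* = −ln(target)/k for the pinned-intercept model; returns the
        volume and the oxygen dose it delivers.
        """
        return volume_for_target(self, target_residual, o2_concentration_mM)

    def summary(self) -> str:
        lines = [
            "Exponential oxygen-deactivation fit  R(V) = exp(-k V)",
            "=" * 53,
            f"decay constant k : {self.rate_per_ul:.4f} per µL",
            f"R-squared        : {self.rsquared:.4f}",
            f"n observations   : {len(self.model.residual_activity)}",
        ]
        if self.model.free_intercept:
            lines.insert(3, f"intercept A      : {self.amplitude:.4f}")
        if self.model.plateau:
            lines.insert(3, f"plateau c        : {self.plateau:.4f}")
        if self.at_boundary:
            lines.append("WARNING: k at boundary (no decay detected)")
        for tgt in (0.20, 0.15):
            if self.rate_per_ul > 0:
                v, dose = self.volume_for_target(tgt)
                lines.append(f"V for {tgt:.0%} residual: {v:.1f} µL "
                             f"({dose.o2_nmol:.2f} nmol O2)")
        return "\n".join(lines)


def fit_decay(exposure_volume_ul, residual_activity, sd=None, **kwargs
              ) -> DecayResults:
    """Fit R(V) = exp(−k·V) to residual-activity observations."""
    fit_kwargs = {k: kwargs.pop(k) for k in ("log_linear",) if k in kwargs}
    return ExponentialDecayModel(exposure_volume_ul, residual_activity, sd,
                                 **kwargs).fit(**fit_kwargs)


def volume_for_target(curve: DecayResults, target_residual: float,
                      o2_concentration_mM: float = 0.25
                      ) -> tuple[float, OxygenDose]:
    """Closed-form exposure volume for a target residual activity."""
    if not 0 < target_residual < 1:
        raise ValueError("target residual must be in (0, 1)")
    if curve.rate_per_ul <= 0:
        raise ValueError("fitted decay rate must be positive")
    v = -np.log(target_residual) / curve.rate_per_ul
    return float(v), OxygenDose(float(v), o2_concentration_mM)
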