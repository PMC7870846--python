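"""Ratiometric pH analysis.

Two-excitation fluorescence ratios, ratio fold-change statistics, logistic
calibration curves F_ratio(pH) = A / (1 + exp(-/+ k*(pH - pH0))), and
closed-form inversion of a fitted calibration back to pH.

The ratio uses emission from the redshifted excitation peak as numerator and
emission from the blueshifted excitation peak as denominator, computed on
background-subtracted, unnormalized intensities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "RatiometricMeasurement",
    "RatiometricCalibration",
    "LogisticCalibration",
    "f_ratio",
    "ratio_fold_change",
    "fit_logistic_calibration",
    "invert_ph",
]

Direction = Literal["increasing", "decreasing"]


@dataclass
class RatiometricMeasurement:
    """One two-excitation measurement at a known pH (background-subtracted)."""

    f_blue: float  # emission from the blueshifted excitation peak
    f_red: float  # emission from the redshifted excitation peak
    ph: float | None = None
    background_subtracted: bool = True


@dataclass
class RatiometricCalibration:
    """Logistic calibration F_ratio(pH) = A / (1 + exp(-s*k*(pH - pH0))).

    ``steepness`` is the positive magnitude k (per pH unit); ``direction``
    carries the sign s (+1 increasing as for the mFAP_pH-DFHBI complex,
    -1 decreasing as for pHRed and pHluorin2).
    """

    amplitude: float  # A
    steepness: float  # k > 0
    midpoint: float  # pH0
    direction: Direction = "increasing"
    valid_ph_range: tuple[float, float] = (3.6, 8.4)

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.steepness <= 0:
            raise ValueError("steepness magnitude must be > 0; use direction for sign")

    @property
    def signed_steepness(self) -> float:
        return self.steepness if self.direction == "increasing" else -self.steepness

    def evaluate(self, ph) -> np.ndarray | float:
        ph_arr = np.asarray(ph, dtype=float)
        val = self.amplitude / (1.0 + np.exp(-self.signed_steepness * (ph_arr - self.midpoint)))
        return float(val) if np.isscalar(ph) or ph_arr.ndim == 0 else val

    def to_record(self) -> dict:
        return {
            "amplitude": self.amplitude,
            "steepness": self.steepness,
            "midpoint": self.midpoint,
            "direction": self.direction,
            "valid_range": list(self.valid_ph_range),
        }


def f_ratio(m: RatiometricMeasurement) -> float:
    """Ratiometric fluorescence: redshifted-excitation over blueshifted-excitation emission."""
    if m.f_blue <= 0:
        raise ValueError("blueshifted-excitation emission must be > 0 for a ratio")
    return m.f_red / m.f_blue


def ratio_fold_change(
    f_low_blue: float,
    f_low_red: float,
    f_high_blue: float,
    f_high_red: float,
    backgrounds: tuple[float, float, float, float] | None = None,
) -> float:
    """Fluorescence ratio fold-change from low to high pH.

    (F_low^blue / F_low^red) / (F_high^blue / F_high^red), optionally after
    per-channel background subtraction.  Invariant to rescaling all four
    inputs by a common factor.
    """
    vals = [f_low_blue, f_low_red, f_high_blue, f_high_red]
    if backgrounds is not None:
        vals = [v - b for v, b in zip(vals, backgrounds)]
    lb, lr, hb, hr = vals
    if lr == 0 or hb == 0 or hr == 0:
        raise ValueError("zero denominator in ratio fold-change")
    return (lb / lr) / (hb / hr)


class LogisticCalibration(BaseEstimator):
    """Three-parameter logistic calibration of F_ratio against pH.

    Fits A, k, pH0 in F_ratio = A / (1 + exp(-s*k*(pH - pH0))) by nonlinear
    least squares.  The direction sign s is auto-detected from the Spearman
    rank correlation of the data unless given.  Points that reverse the
    monotone trend beyond ``monotone_tol`` times the data range (the
    ambiguous-calibration region where one ratio maps to two pH values) are
    flagged and excluded from the fit.

    Attributes
    ----------
    amplitude_, steepness_, midpoint_ : float
        Fitted logistic parameters (steepness is the positive magnitude).
    direction_ : str
        'increasing' or 'decreasing'.
    excluded_ : ndarray of int
        Indices of points dropped by the monotonicity rule.
    residuals_ : ndarray
        Fit residuals on the retained points.
    """

    def __init__(self, direction: Direction | None = None, monotone_tol: float = 0.05):
        self.direction = direction
        self.monotone_tol = monotone_tol

    def fit(self, X, y=None):
        ph = np.asarray(X, dtype=float).reshape(-1)
        ratio = np.asarray(y, dtype=float).reshape(-1)
        if ph.size < 5:
            raise ValueError("need >= 5 calibration points")
        order = np.argsort(ph)
        ph, ratio = ph[order], ratio[order]

        if self.direction is None:
            rho = stats.spearmanr(ph, ratio).statistic
            if not np.isfinite(rho) or abs(rho) < 0.5:
                raise RuntimeError("calibration points are not monotone in the majority")
            direction: Direction = "increasing" if rho > 0 else "decreasing"
        else:
            direction = self.direction
        sign = 1.0 if direction == "increasing" else -1.0

        keep = self._monotone_mask(ratio, sign, self.monotone_tol)
        if keep.sum() < 5:
            raise RuntimeError("fewer than 5 points remain after monotonicity exclusion")

        a0 = float(ratio.max()) * 1.05
        # midpoint guess: pH of the point closest to half-amplitude
        ph0 = float(ph[keep][np.argmin(np.abs(ratio[keep] - 0.5 * ratio.max()))])

        def model(x, log_a, log_k, mid):
            return np.exp(log_a) / (1.0 + np.exp(-sign * np.exp(log_k) * (x - mid)))

        popt, _ = optimize.curve_fit(
            model,
            ph[keep],
            ratio[keep],
            p0=[np.log(a0), 0.0, ph0],
            maxfev=20000,
        )
        self.amplitude_ = float(np.exp(popt[0]))
        self.steepness_ = float(np.exp(popt[1]))
        self.midpoint_ = float(popt[2])
        self.direction_ = direction
        self.excluded_ = np.flatnonzero(~keep)
        self.residuals_ = ratio[keep] - model(ph[keep], *popt)
        self._ph_range = (float(ph.min()), float(ph.max()))
        return self

    @staticmethod
    def _monotone_mask(ratio: np.ndarray, sign: float, rel_tol: float) -> np.ndarray:
        """Drop points that reverse the expected trend beyond tolerance.

        A pair (i < j) is in conflict when the later point lies below the
        earlier one (for an increasing trend) by more than the tolerance;
        the point involved in the most conflicts is removed greedily until
        the retained set is monotone within tolerance.
        """
        tol = rel_tol * (ratio.max() - ratio.min())
        n = ratio.size
        keep = np.ones(n, dtype=bool)
        while True:
            idx = np.flatnonzero(keep)
            r = ratio[idx]
            # conflict matrix over retained points
            diff = sign * (r[None, :] - r[:, None])  # expected >= -tol for j > i
            conflicts = np.triu(diff < -tol, k=1)
            counts = conflicts.sum(axis=0) + conflicts.sum(axis=1)
            if counts.max(initial=0) == 0:
                return keep
            keep[idx[np.argmax(counts)]] = False

    def predict(self, X) -> np.ndarray:
        return self.calibration_().evaluate(np.asarray(X, dtype=float))

    def inverse(self, f_ratio_obs) -> np.ndarray | float:
        return invert_ph(self.calibration_(), f_ratio_obs)

    def calibration_(self) -> RatiometricCalibration:
        return RatiometricCalibration(
            amplitude=self.amplitude_,
            steepness=self.steepness_,
            midpoint=self.midpoint_,
            direction=self.direction_,
            valid_ph_range=getattr(self, "_ph_range", (3.6, 8.4)),
        )


def fit_logistic_calibration(
    ph: Sequence[float], f_ratio_values: Sequence[float], direction: Direction | None = None
) -> RatiometricCalibration:
    """Fit the logistic pH calibration curve to (pH, F_ratio) points."""
    est = LogisticCalibration(direction=direction)
    est.fit(np.asarray(ph, dtype=float), np.asarray(f_ratio_values, dtype=float))
    return est.calibration_()


def invert_ph(cal: RatiometricCalibration, f_ratio_obs) -> np.ndarray | float:
    """Closed-form inverse of the logistic calibration.

    pH = pH0 - s/k * ln(A / F_ratio - 1), with s = +1 for an increasing and
    -1 for a decreasing calibration; exact inverse of ``cal.evaluate`` for
    0 < F_ratio < A.
    """
    obs = np.asarray(f_ratio_obs, dtype=float)
    if np.any(obs <= 0) or np.any(obs >= cal.amplitude):
        lo, hi = 0.0, cal.amplitude
        raise ValueError(
            f"observed ratio outside the invertible range ({lo:.3g}, {hi:.3g}); "
            f"nearest bound: {float(np.clip(np.atleast_1d(obs)[0], lo, hi)):.3g}"
        )
    s = 1.0 if cal.direction == "increasing" else -1.0
    ph = cal.midpoint - (s / cal.steepness) * np.log(cal.amplitude / obs - 1.0)
    return float(ph) if np.isscalar(f_ratio_obs) else ph
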