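"""Photophysics bookkeeping and photobleaching analysis.

Beer's-law extinction coefficients, relative/absolute quantum yields,
brightness (epsilon * phi), percent-bound accounting for quantum-yield
preparations, fluorescence activation folds, and plateau fits of
monophasic photobleach decays.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

from .equilibria import BinaryBindingSystem, bimolecular_complex, fraction_bound_excess

__all__ = [
    "PhotophysicsRecord",
    "BleachFit",
    "BleachDecay",
    "extinction_coefficient",
    "brightness",
    "relative_quantum_yield",
    "absolute_quantum_yield",
    "activation_fold",
    "percent_bound",
    "normalized_frame_intensity",
    "fit_bleach",
    "photostability_ratio",
    "round_sig",
]


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (reporting convention)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


@dataclass
class PhotophysicsRecord:
    """Scalar photophysics bookkeeping for one protein-chromophore complex."""

    lambda_abs: float | None = None  # nm
    lambda_ex: float | None = None
    lambda_em: float | None = None
    absorbance: float | None = None  # dimensionless A
    path_length: float = 1.0  # cm
    conc: float | None = None  # M
    extinction: float | None = None  # M^-1 cm^-1
    phi_abs: float | None = None  # absolute quantum yield
    phi_rel: float | None = None
    brightness: float | None = None  # M^-1 cm^-1
    percent_bound: float | None = None
    refractive_index: float | None = None

    def __post_init__(self) -> None:
        for phi in (self.phi_abs, self.phi_rel):
            if phi is not None and not (0.0 <= phi <= 1.0):
                warnings.warn(f"quantum yield {phi} outside [0, 1]", stacklevel=2)
        for v, name in ((self.extinction, "extinction"), (self.brightness, "brightness")):
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class BleachFit:
    """Monophasic photobleach decay F = h + (1-h)*exp(-k*t)."""

    h: float  # plateau fraction, (0, 1]
    k: float  # decay rate, per frame or per second depending on time base
    frame_period: float = 1.0  # s

    def __post_init__(self) -> None:
        if not (0.0 < self.h <= 1.0 + 1e-12):
            raise ValueError("plateau h must be in (0, 1]")
        if self.k < 0:
            raise ValueError("decay rate must be >= 0")


def extinction_coefficient(absorbance: float, path_cm: float, conc_M: float) -> float:
    """Beer's law: epsilon = A / (b * c), in M^-1 cm^-1."""
    if path_cm <= 0 or conc_M <= 0:
        raise ValueError("path length and concentration must be > 0")
    if absorbance < 0:
        raise ValueError("absorbance must be >= 0")
    return absorbance / (path_cm * conc_M)


def brightness(extinction: float, phi_abs: float, report: bool = True) -> float:
    """Molecular brightness = extinction coefficient x absolute quantum yield.

    Rounded to 3 significant figures when ``report`` (the tabulation
    convention); pass ``report=False`` for the raw product.
    """
    if extinction < 0 or phi_abs < 0:
        raise ValueError("extinction and quantum yield must be >= 0")
    b = extinction * phi_abs
    return round_sig(b, 3) if report else b


def relative_quantum_yield(
    phi_ref: float,
    a_ref: float,
    a_complex: float,
    em_complex: Sequence[float] | float,
    em_ref: Sequence[float] | float,
    n_complex: float,
    n_ref: float,
    wavelength_grid: Sequence[float] | None = None,
) -> float:
    """Relative quantum yield against a reference standard.

    phi_c = phi_r * (1 - 10^-A_r)/(1 - 10^-A_c) * (int F_c / int F_r)
                  * (n_c^2 / n_r^2)

    ``em_complex``/``em_ref`` may be pre-integrated scalars or emission
    spectra sampled on a shared ``wavelength_grid`` (trapezoid quadrature).
    """
    if a_ref < 0 or a_complex < 0:
        raise ValueError("absorbances must be >= 0")
    if a_complex == 0:
        raise ZeroDivisionError("sample absorbance is zero: absorption factor undefined")
    if n_complex <= 0 or n_ref <= 0:
        raise ValueError("refractive indices must be > 0")

    def integral(em) -> float:
        arr = np.atleast_1d(np.asarray(em, dtype=float))
        if arr.size == 1:
            val = float(arr[0])
        else:
            if wavelength_grid is None:
                raise ValueError("spectra require a wavelength_grid")
            grid = np.asarray(wavelength_grid, dtype=float)
            if grid.size != arr.size:
                raise ValueError("spectrum and wavelength grid lengths differ")
            val = float(np.trapezoid(arr, grid))
        if val <= 0:
            raise ValueError("emission integral must be > 0")
        return val

    absorption_factor = (1.0 - 10.0 ** (-a_ref)) / (1.0 - 10.0 ** (-a_complex))
    return (
        phi_ref
        * absorption_factor
        * (integral(em_complex) / integral(em_ref))
        * (n_complex**2 / n_ref**2)
    )


def absolute_quantum_yield(f_em: float, f_abs: float) -> float:
    """Absolute quantum yield: emitted photon flux over absorbed photon flux."""
    if f_abs <= 0:
        raise ValueError("absorbed photon flux must be > 0")
    phi = f_em / f_abs
    if phi > 1.0:
        warnings.warn(f"quantum yield {phi:.3g} > 1 is unphysical", stacklevel=2)
    return phi


def activation_fold(phi_bound: float, phi_free: float, report: bool = True) -> float:
    """Fluorescence activation: bound-state over free-chromophore quantum yield."""
    if phi_free <= 0:
        raise ValueError("free-chromophore quantum yield must be > 0")
    fold = phi_bound / phi_free
    return round_sig(fold, 3) if report else fold


def percent_bound(
    protein_conc_uM: float,
    chromophore_conc_uM: float,
    kd_uM: float,
    mode: Literal["excess", "exact"] = "excess",
) -> float:
    """Percent of chromophore protein-bound in a quantum-yield preparation.

    ``excess`` uses P/(P+Kd) (protein in large excess over chromophore,
    the tabulation convention); ``exact`` solves the bimolecular quadratic
    and reports complex/chromophore_total.  One-decimal rounding.
    """
    if mode == "excess":
        frac = fraction_bound_excess(protein_conc_uM, kd_uM)
    else:
        if chromophore_conc_uM <= 0:
            raise ValueError("exact mode requires chromophore_conc_uM > 0")
        c = bimolecular_complex(
            BinaryBindingSystem(protein_conc_uM, chromophore_conc_uM, kd_uM)
        )
        frac = c / chromophore_conc_uM
    return round(100.0 * frac, 1)


def normalized_frame_intensity(frame_pixel_sums: Sequence[float]) -> np.ndarray:
    """Frame pixel sums divided by the first frame's sum.

    Saturated pixels (detector maximum) must already be excluded from the
    sums upstream.
    """
    sums = np.asarray(frame_pixel_sums, dtype=float)
    if sums.size == 0:
        raise ValueError("empty frame series")
    if sums[0] <= 0:
        raise ValueError("first frame sum must be > 0")
    return sums / sums[0]


class BleachDecay(BaseEstimator):
    """Monophasic photobleach decay fit F(t) = h + (1-h)*exp(-k*t).

    The plateau ``h`` is the asymptotic fraction of initial intensity under
    continuous illumination; ratios of ``h`` between probes quantify relative
    photostability.  h in (0, 1] is enforced by a logit parameterization and
    k >= 0 by a log parameterization.

    Attributes
    ----------
    h_ : float
        Plateau fraction.
    k_ : float
        Decay rate in the units of the supplied time base (frame^-1 when t
        is in frames, s^-1 when in seconds).
    """

    def __init__(self, frame_period: float = 1.0):
        self.frame_period = frame_period

    def fit(self, X, y=None):
        t = np.asarray(X, dtype=float).reshape(-1)
        f = np.asarray(y, dtype=float).reshape(-1)
        if t.size < 10:
            raise ValueError("need >= 10 frames to fit a bleach decay")
        if t.size != f.size:
            raise ValueError("time and intensity lengths differ")

        span = float(f.max() - f.min())
        if span < 1e-12:  # constant series: no bleaching
            self.h_ = 1.0
            self.k_ = 0.0
            return self

        h0 = float(np.clip(f[-1], 1e-3, 1.0 - 1e-3))
        k0 = 1.0 / max(t[-1] - t[0], 1.0) * 3.0

        def model(t, logit_h, log_k):
            h = 1.0 / (1.0 + np.exp(-logit_h))
            k = np.exp(log_k)
            return h + (1.0 - h) * np.exp(-k * t)

        popt, _ = optimize.curve_fit(
            model, t, f, p0=[np.log(h0 / (1 - h0)), np.log(k0)], maxfev=20000
        )
        self.h_ = float(1.0 / (1.0 + np.exp(-popt[0])))
        self.k_ = float(np.exp(popt[1]))
        return self

    def predict(self, X) -> np.ndarray:
        t = np.asarray(X, dtype=float).reshape(-1)
        return self.h_ + (1.0 - self.h_) * np.exp(-self.k_ * t)

    def result_(self) -> BleachFit:
        return BleachFit(h=self.h_, k=self.k_, frame_period=self.frame_period)


def fit_bleach(
    series: Sequence[float], frame_period_s: float = 1.13, time_base: Literal["frames", "seconds"] = "frames"
) -> BleachFit:
    """Fit a normalized bleach series to F = h + (1-h)*exp(-k*t).

    t runs in frames by default (k in frame^-1); ``time_base='seconds'``
    converts via ``frame_period_s`` (k in s^-1).
    """
    f = np.asarray(series, dtype=float)
    t = np.arange(f.size, dtype=float)
    if time_base == "seconds":
        t = t * frame_period_s
    est = BleachDecay(frame_period=frame_period_s)
    est.fit(t, f)
    return est.result_()


def photostability_ratio(h_probe: float, h_reference: float) -> float:
    """Fold improvement in photostability: plateau ratio h_probe / h_reference."""
    if h_reference <= 0:
        raise ValueError("reference plateau must be > 0")
    return h_probe / h_reference
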