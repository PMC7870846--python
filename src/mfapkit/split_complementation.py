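"""Reversible split-fragment complementation models.

A fluorogen-activating beta-barrel split into two fragments reconstitutes
fluorescence when the fragments are driven together by fused high-affinity
binding partners.  This module implements the association titration model
(exact bimolecular binding of titrant into a fixed partner), the composite
dissociation constant from Gibbs-energy additivity, folded-fraction fitting,
min-max normalization against a saturating-titrant theoretical maximum, and
monophasic kinetic fits of assembly/competition time courses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

from .equilibria import (
    BinaryBindingSystem,
    CompetitionSystem,
    bimolecular_complex,
    solve_competition,
)

__all__ = [
    "SplitPairModel",
    "KineticTrace",
    "MonophasicExponential",
    "FoldedFraction",
    "GAS_CONSTANT_KCAL",
    "normalize_min_max",
    "plateau_f_max",
    "composite_kd",
    "association_signal",
    "fit_folded_fraction",
    "fold_change_trace",
    "fit_monophasic",
    "competition_endpoint",
]

#: Gas constant in kcal mol^-1 K^-1 (for delta-G reporting at 298.15 K)
GAS_CONSTANT_KCAL = 1.987204259e-3
STANDARD_T_K = 298.15

#: Saturating titrant concentration anchoring the normalization maximum (M).
#: A normalization device, not a physical condition.
EXCESS_TITRANT_M = 10.0


@dataclass
class SplitPairModel:
    """Parameters of one split-fragment pair driven by fused binders.

    ``kd_fragments`` is the fragment-fragment Kd in uM; ``kd_binder`` the
    fused binder-partner Kd in M; ``kd_composite`` their product in M
    (Gibbs-energy additivity).  ``p_folded`` is the fraction of the partner
    fusion competent to form the fluorescent complex.
    """

    kd_fragments_uM: float
    kd_binder_M: float
    p_folded: float = 1.0
    partner_total_uM: float = 0.0
    excess_conc_M: float = EXCESS_TITRANT_M

    def __post_init__(self) -> None:
        if self.kd_fragments_uM <= 0 or self.kd_binder_M <= 0:
            raise ValueError("dissociation constants must be > 0")
        if not (0.0 < self.p_folded <= 1.0):
            raise ValueError("p_folded must be in (0, 1]")

    @property
    def kd_composite_M(self) -> float:
        return self.kd_binder_M * self.kd_fragments_uM * 1e-6


@dataclass
class KineticTrace:
    """One fluorescence time course and its derived fold-change series."""

    time: np.ndarray  # s, strictly increasing
    f: np.ndarray  # RFU
    f0: float = field(init=False)
    fold_change: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.time.size != self.f.size:
            raise ValueError("time and fluorescence lengths differ")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.f[0] == 0:
            raise ValueError("first measurement F0 must be nonzero")
        self.f0 = float(self.f[0])
        self.fold_change = (self.f - self.f0) / self.f0


def normalize_min_max(
    f: Sequence[float], f_min: float, f_max: float, clip: bool = False
) -> np.ndarray:
    """(F - F_min) / (F_max - F_min); maps f_min to 0 and f_max to 1.

    Noisy values may fall slightly outside [0, 1]; they are kept unless
    ``clip`` is set.
    """
    if f_max <= f_min:
        raise ValueError("degenerate normalization range: f_max <= f_min")
    out = (np.asarray(f, dtype=float) - f_min) / (f_max - f_min)
    return np.clip(out, 0.0, 1.0) if clip else out


def plateau_f_max(rfu: Sequence[float], n_top: int = 4) -> float:
    """Constant fit (mean) of the readings at the ``n_top`` highest titrant
    concentrations -- the plateau estimate used for F_max."""
    arr = np.asarray(rfu, dtype=float)
    if arr.size < n_top:
        raise ValueError(f"need at least {n_top} points for the plateau fit")
    return float(arr[-n_top:].mean())


def composite_kd(kd_binder_M: float, kd_fragments_M: float) -> dict:
    """Composite Kd from Gibbs-energy additivity of the two interfaces.

    Kd_composite = Kd_binder * Kd_fragments (both in M), equivalently
    dG_total = dG_binder + dG_fragments with dG = RT ln Kd at 298.15 K.
    Returns the product plus a delta-G report (kcal/mol).
    """
    if kd_binder_M <= 0 or kd_fragments_M <= 0:
        raise ValueError("dissociation constants must be > 0")
    rt = GAS_CONSTANT_KCAL * STANDARD_T_K
    kd = kd_binder_M * kd_fragments_M
    return {
        "kd_composite_M": kd,
        "dG_total_kcal": rt * math.log(kd),
        "dG_binder_kcal": rt * math.log(kd_binder_M),
        "dG_fragments_kcal": rt * math.log(kd_fragments_M),
    }


def association_signal(
    titrant_total_uM,
    partner_total_uM: float,
    p_folded: float,
    kd_composite_M: float,
    excess_conc_M: float = EXCESS_TITRANT_M,
) -> np.ndarray | float:
    """Normalized fluorescence of a titrant-into-partner association series.

    The fluorescent complex concentration comes from the exact bimolecular
    solution with the folded partner concentration p_folded * partner_total;
    the normalizing theoretical maximum is the same expression evaluated at
    the saturating titrant concentration (10.0 M by convention), so the
    signal approaches 1 at excess titrant by construction.
    """
    if not (0.0 < p_folded <= 1.0):
        raise ValueError("p_folded must be in (0, 1]")
    kd_uM = kd_composite_M * 1e6
    folded = p_folded * partner_total_uM
    excess_uM = excess_conc_M * 1e6

    c_max = bimolecular_complex(BinaryBindingSystem(excess_uM, folded, kd_uM))
    if c_max <= 0:
        raise ValueError("theoretical maximum complex is zero")

    titrant = np.asarray(titrant_total_uM, dtype=float)
    out = np.empty(titrant.shape if titrant.ndim else (1,))
    for i, t in enumerate(np.atleast_1d(titrant)):
        out[i] = bimolecular_complex(BinaryBindingSystem(float(t), folded, kd_uM)) / c_max
    return float(out[0]) if titrant.ndim == 0 else out


class FoldedFraction(BaseEstimator):
    """Fit the folded fraction of the partner fusion to a normalized titration.

    The composite Kd is held fixed (only p_folded is free); p_folded in
    (0, 1] is enforced by a logit parameterization.

    Attributes
    ----------
    p_folded_ : float
    p_folded_sd_ : float
        Standard deviation from the fit covariance (delta method).
    folded_conc_uM_ : float
        p_folded * partner_total.
    """

    def __init__(
        self,
        partner_total_uM: float = 1.0,
        kd_composite_M: float = 1e-12,
        excess_conc_M: float = EXCESS_TITRANT_M,
    ):
        self.partner_total_uM = partner_total_uM
        self.kd_composite_M = kd_composite_M
        self.excess_conc_M = excess_conc_M

    def fit(self, X, y=None):
        titrant = np.asarray(X, dtype=float).reshape(-1)
        signal = np.asarray(y, dtype=float).reshape(-1)
        if titrant.size < 5:
            raise ValueError("need >= 5 titrant levels")
        if titrant.size != signal.size:
            raise ValueError("titrant and signal lengths differ")

        def model(t, logit_p):
            p = 1.0 / (1.0 + np.exp(-logit_p))
            return association_signal(
                t, self.partner_total_uM, p, self.kd_composite_M, self.excess_conc_M
            )

        popt, pcov = optimize.curve_fit(model, titrant, signal, p0=[0.0], maxfev=20000)
        p = float(1.0 / (1.0 + np.exp(-popt[0])))
        sd_logit = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else 0.0
        self.p_folded_ = p
        self.p_folded_sd_ = p * (1.0 - p) * sd_logit  # d p / d logit = p(1-p)
        self.folded_conc_uM_ = p * self.partner_total_uM
        return self

    def predict(self, X) -> np.ndarray:
        return np.asarray(
            association_signal(
                np.asarray(X, dtype=float),
                self.partner_total_uM,
                self.p_folded_,
                self.kd_composite_M,
                self.excess_conc_M,
            )
        )


def fit_folded_fraction(
    titrant_uM: Sequence[float],
    normalized_signal: Sequence[float],
    partner_total_uM: float,
    kd_composite_M: float,
) -> tuple[float, float]:
    """Least-squares folded fraction (value, sd) at fixed composite Kd."""
    est = FoldedFraction(partner_total_uM=partner_total_uM, kd_composite_M=kd_composite_M)
    est.fit(np.asarray(titrant_uM, dtype=float), np.asarray(normalized_signal, dtype=float))
    return est.p_folded_, est.p_folded_sd_


def fold_change_trace(time_s: Sequence[float], f: Sequence[float]) -> KineticTrace:
    """Fluorescence fold-change dF/F0 with F0 = the first measurement."""
    return KineticTrace(time=np.asarray(time_s, dtype=float), f=np.asarray(f, dtype=float))


class MonophasicExponential(BaseEstimator):
    """Monophasic exponential fit y(t) = plateau + (start - plateau)*exp(-k*t).

    Handles rising (assembly) and falling (competition/displacement) traces;
    the rate k > 0 is enforced by a log parameterization.  Initialization:
    start = first point, plateau = last point, k = 3 / time span.

    Attributes
    ----------
    plateau_, rate_, start_ : float
    """

    def fit(self, X, y=None):
        t = np.asarray(X, dtype=float).reshape(-1)
        f = np.asarray(y, dtype=float).reshape(-1)
        if t.size < 8:
            raise ValueError("need >= 8 timepoints")
        if t.size != f.size:
            raise ValueError("time and signal lengths differ")
        if float(f.max() - f.min()) < 1e-12 * max(abs(f).max(), 1.0):
            raise RuntimeError("flat trace: nothing to fit")

        span = max(t[-1] - t[0], 1e-9)

        def model(t, plateau, start, log_k):
            return plateau + (start - plateau) * np.exp(-np.exp(log_k) * t)

        popt, _ = optimize.curve_fit(
            model, t, f, p0=[f[-1], f[0], np.log(3.0 / span)], maxfev=20000
        )
        self.plateau_ = float(popt[0])
        self.start_ = float(popt[1])
        self.rate_ = float(np.exp(popt[2]))
        return self

    def predict(self, X) -> np.ndarray:
        t = np.asarray(X, dtype=float).reshape(-1)
        return self.plateau_ + (self.start_ - self.plateau_) * np.exp(-self.rate_ * t)


def fit_monophasic(trace: KineticTrace, use_fold_change: bool = True) -> tuple[float, float, float]:
    """Fit a monophasic exponential to a kinetic trace.

    Returns (plateau, rate s^-1, start); fits the dF/F0 series by default.
    """
    y = trace.fold_change if use_fold_change else trace.f
    est = MonophasicExponential()
    est.fit(trace.time, y)
    return est.plateau_, est.rate_, est.start_


def competition_endpoint(
    receptor_total_uM: float,
    cognate_total_uM: float,
    noncognate_total_uM: float,
    kd_cognate_uM: float,
    kd_noncognate_uM: float,
    signal_per_complex: float = 1.0,
) -> float:
    """Predicted equilibrium fluorescence when a competitor displaces the
    fluorescent fragment fusion.

    Fluorescence is proportional to the fragment-pair-bridging complex (the
    'cognate' complex); the unfused competitor forms a dark complex.  The
    signal is normalized to the competitor-free endpoint, so it is 1 at zero
    competitor and decreases monotonically with competitor concentration.
    """
    cognate, _ = solve_competition(
        CompetitionSystem(
            receptor_total=receptor_total_uM,
            ligand_totals=(cognate_total_uM, noncognate_total_uM),
            kds=(kd_cognate_uM, kd_noncognate_uM),
        )
    )
    reference = bimolecular_complex(
        BinaryBindingSystem(receptor_total_uM, cognate_total_uM, kd_cognate_uM)
    )
    if reference <= 0:
        raise ValueError("no fluorescent complex forms without competitor")
    return signal_per_complex * cognate / reference
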