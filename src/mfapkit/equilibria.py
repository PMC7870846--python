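"""Binding-equilibrium models for fluorogen-activating protein sensors.

Single-site isotherms, exact bimolecular binding, Hill-1 analyte titrations,
the ternary (chromophore x analyte) allosteric coupling cycle, and competitive
binding of two ligands for one receptor.

All concentrations are micromolar (uM) unless a name says otherwise; molar
values are converted at I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

__all__ = [
    "TitrationSeries",
    "IsothermFit",
    "BinaryBindingSystem",
    "TernaryAllosterySystem",
    "CompetitionSystem",
    "SingleSiteIsotherm",
    "fraction_bound_excess",
    "bimolecular_complex",
    "fit_single_site_isotherm",
    "fit_analyte_titration",
    "ternary_state_fractions",
    "optimal_label_concentration",
    "solve_competition",
    "dynamic_range",
]

Direction = Literal["increasing", "decreasing"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class TitrationSeries:
    """One plate-reader titration: analyte concentrations x replicate RFU.

    Parameters
    ----------
    analyte_conc
        Concentrations in uM, including one zero (no-analyte) condition.
        Nonzero concentrations must be strictly increasing.
    rfu
        Fluorescence readings, one row per concentration, one column per
        technical replicate.
    blanks
        Optional matched background readings (same row order); subtracted
        per concentration before fitting.
    """

    analyte_conc: np.ndarray
    rfu: np.ndarray
    blanks: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.analyte_conc = np.asarray(self.analyte_conc, dtype=float)
        self.rfu = np.atleast_2d(np.asarray(self.rfu, dtype=float))
        if self.rfu.shape[0] != self.analyte_conc.size:
            raise ValueError(
                f"rfu has {self.rfu.shape[0]} rows but there are "
                f"{self.analyte_conc.size} concentrations"
            )
        if np.any(self.analyte_conc < 0):
            raise ValueError("concentrations must be >= 0")
        nz = self.analyte_conc[self.analyte_conc > 0]
        if nz.size and np.any(np.diff(nz) <= 0):
            raise ValueError("nonzero concentrations must be strictly increasing")
        if self.blanks is not None:
            self.blanks = np.atleast_2d(np.asarray(self.blanks, dtype=float))
            if self.blanks.shape[0] != self.analyte_conc.size:
                raise ValueError("blank table must match concentration rows one-to-one")

    @property
    def n_replicates(self) -> int:
        return self.rfu.shape[1]

    def mean_response(self) -> np.ndarray:
        """Per-concentration replicate means, blank-subtracted when blanks exist."""
        means = self.rfu.mean(axis=1)
        if self.blanks is not None:
            means = means - self.blanks.mean(axis=1)
        return means

    def replicate_sd(self) -> np.ndarray:
        return self.rfu.std(axis=1, ddof=1) if self.n_replicates > 1 else np.zeros(
            self.analyte_conc.size
        )


@dataclass
class IsothermFit:
    """Result of a single-binding-site (Hill-1 by default) isotherm fit."""

    kd: float  # uM
    f_max: float  # RFU
    f_min: float  # RFU
    hill: float = 1.0
    kd_sd: float = 0.0
    is_lower_bound: bool = False
    direction: Direction = "increasing"
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("kd must be > 0")
        if self.kd_sd < 0:
            raise ValueError("kd_sd must be >= 0")

    def to_record(self) -> dict:
        return {
            "kd_uM": self.kd,
            "kd_sd": self.kd_sd,
            "f_min": self.f_min,
            "f_max": self.f_max,
            "hill": self.hill,
            "is_lower_bound": self.is_lower_bound,
            "n_points": self.n_points,
        }

    def report_kd(self) -> str:
        """Human-readable Kd with the '>=' lower-bound convention."""
        prefix = "≥" if self.is_lower_bound else ""
        return f"{prefix}{self.kd:.3g} µM"


@dataclass
class BinaryBindingSystem:
    """Two species A + B <-> AB with dissociation constant kd (all uM)."""

    a_total: float
    b_total: float
    kd: float

    def __post_init__(self) -> None:
        if self.a_total < 0 or self.b_total < 0 or self.kd < 0:
            raise ValueError("totals and kd must be >= 0")


@dataclass
class TernaryAllosterySystem:
    """Two-site thermodynamic cycle: sensor binds chromophore and analyte.

    ``kd_chromophore_apo`` is Kd- (chromophore Kd of the analyte-free sensor),
    ``kd_chromophore_holo`` is Kd+ (analyte-bound).  The coupling factor
    c = Kd-/Kd+ exceeds 1 for positive allostery.  The analyte Kd of the
    chromophore-bound sensor follows from cycle closure:
    kd_analyte_holo = kd_analyte_apo / c.
    """

    kd_chromophore_apo: float  # Kd- (uM)
    kd_chromophore_holo: float  # Kd+ (uM)
    kd_analyte_apo: float  # uM
    brightness_weights: tuple[float, float] = (1.0, 1.0)  # (chromophore-only, doubly bound)

    def __post_init__(self) -> None:
        for v in (self.kd_chromophore_apo, self.kd_chromophore_holo, self.kd_analyte_apo):
            if v <= 0:
                raise ValueError("all dissociation constants must be > 0")

    @property
    def coupling(self) -> float:
        return self.kd_chromophore_apo / self.kd_chromophore_holo

    @property
    def kd_analyte_holo(self) -> float:
        return self.kd_analyte_apo / self.coupling

    @property
    def is_positive_allostery(self) -> bool:
        return self.coupling > 1.0


@dataclass
class CompetitionSystem:
    """One receptor, two ligands competing for the same site (all uM)."""

    receptor_total: float
    ligand_totals: tuple[float, float]
    kds: tuple[float, float]

    def __post_init__(self) -> None:
        if self.receptor_total < 0 or min(self.ligand_totals) < 0:
            raise ValueError("totals must be >= 0")
        if min(self.kds) <= 0:
            raise ValueError("kds must be > 0")


# ---------------------------------------------------------------------------
# closed-form equilibria
# ---------------------------------------------------------------------------


def fraction_bound_excess(protein_conc: float, kd: float) -> float:
    """Bound fraction of a trace species when the binder is in large excess.

    P/(P + Kd): the standard approximation used for '% bound' bookkeeping in
    quantum-yield preparations where protein >> chromophore.
    """
    if kd <= 0:
        raise ValueError("kd must be > 0")
    if protein_conc < 0:
        raise ValueError("protein_conc must be >= 0")
    return protein_conc / (protein_conc + kd)


def bimolecular_complex(system: BinaryBindingSystem) -> float:
    """Exact complex concentration for A + B <-> AB at equilibrium.

    C = 0.5*(A0 + B0 + Kd) - 0.5*sqrt((A0 + B0 + Kd)^2 - 4*A0*B0).
    """
    a, b, kd = system.a_total, system.b_total, system.kd
    s = a + b + kd
    disc = s * s - 4.0 * a * b
    if disc < 0:  # impossible for valid inputs barring FP error
        if disc < -1e-9 * max(s * s, 1.0):
            raise ArithmeticError("negative discriminant in bimolecular solve")
        disc = 0.0
    # conjugate form 2ab/(s + sqrt(disc)) avoids the catastrophic
    # cancellation of 0.5*(s - sqrt(disc)) when kd << a + b
    denom = s + math.sqrt(disc)
    c = 2.0 * a * b / denom if denom > 0 else 0.0
    return float(min(max(c, 0.0), min(a, b)))


def optimal_label_concentration(kd_plus: float, kd_minus: float) -> float:
    """Geometric-mean chromophore concentration sqrt(Kd+ * Kd-).

    Labeling at this concentration balances detection sensitivity and
    photostability against fluorescence dynamic range for an allosteric
    sensor with chromophore Kd+ (analyte-bound) and Kd- (analyte-free).
    """
    if kd_plus <= 0 or kd_minus <= 0:
        raise ValueError("both dissociation constants must be > 0")
    return math.sqrt(kd_plus * kd_minus)


def ternary_state_fractions(
    system: TernaryAllosterySystem,
    chromophore_conc: float,
    analyte_conc: float,
    mode: Literal["excess", "exact"] = "excess",
    sensor_total: float | None = None,
) -> tuple[float, float, float, float]:
    """Fractions of sensor in the four states of the allosteric cycle.

    Returns (apo, chromophore-bound, analyte-bound, doubly-bound); the four
    fractions are nonnegative and sum to 1.

    In ``excess`` mode the supplied concentrations are treated as free ligand
    (valid when both ligands are in large excess over the sensor).  In
    ``exact`` mode they are totals and the free concentrations are found by
    root-finding on the two ligand conservation equations (``sensor_total``
    required).
    """
    if chromophore_conc < 0 or analyte_conc < 0:
        raise ValueError("concentrations must be >= 0")
    if mode == "exact":
        if sensor_total is None or sensor_total < 0:
            raise ValueError("exact mode requires sensor_total >= 0")
        c_free, a_free = _solve_free_ligands(
            system, chromophore_conc, analyte_conc, sensor_total
        )
        return _fractions_at_free(system, c_free, a_free)
    return _fractions_at_free(system, chromophore_conc, analyte_conc)


def _fractions_at_free(
    system: TernaryAllosterySystem, c: float, a: float
) -> tuple[float, float, float, float]:
    # statistical weights relative to the apo state
    w_c = c / system.kd_chromophore_apo
    w_a = a / system.kd_analyte_apo
    w_ca = w_a * (c / system.kd_chromophore_holo)  # == w_c * a / kd_analyte_holo
    z = 1.0 + w_c + w_a + w_ca
    return (1.0 / z, w_c / z, w_a / z, w_ca / z)


def _solve_free_ligands(
    system: TernaryAllosterySystem,
    chromophore_total: float,
    analyte_total: float,
    sensor_total: float,
) -> tuple[float, float]:
    """Free chromophore/analyte from totals via nested 1-D bisection."""

    def bound_ligands(c_free: float, a_free: float) -> tuple[float, float]:
        _, f_c, f_a, f_ca = _fractions_at_free(system, c_free, a_free)
        return sensor_total * (f_c + f_ca), sensor_total * (f_a + f_ca)

    def a_residual(a_free: float, c_free: float) -> float:
        _, bound_a = bound_ligands(c_free, a_free)
        return a_free + bound_a - analyte_total

    def c_residual(c_free: float) -> float:
        if analyte_total == 0:
            a_free = 0.0
        else:
            a_free = optimize.brentq(
                a_residual, 0.0, analyte_total, args=(c_free,), xtol=1e-15, rtol=1e-14
            )
        bound_c, _ = bound_ligands(c_free, a_free)
        return c_free + bound_c - chromophore_total

    if chromophore_total == 0:
        c_free = 0.0
    else:
        c_free = optimize.brentq(c_residual, 0.0, chromophore_total, xtol=1e-15, rtol=1e-14)
    if analyte_total == 0:
        a_free = 0.0
    else:
        a_free = optimize.brentq(
            a_residual, 0.0, analyte_total, args=(c_free,), xtol=1e-15, rtol=1e-14
        )
    return c_free, a_free


def solve_competition(system: CompetitionSystem) -> tuple[float, float]:
    """Equilibrium complex concentrations for two ligands sharing one receptor.

    Reduces the coupled mass-action system to a single monotone equation in
    free receptor r:  r + sum_i Li_total * r / (Kdi + r) = R_total, solved by
    bisection (Brent).  Returns (complex_1, complex_2) in uM.
    """
    r_tot = system.receptor_total
    l1, l2 = system.ligand_totals
    k1, k2 = system.kds
    if r_tot == 0:
        return (0.0, 0.0)

    def conservation(r: float) -> float:
        return r + l1 * r / (k1 + r) + l2 * r / (k2 + r) - r_tot

    r_free = optimize.brentq(conservation, 0.0, r_tot, xtol=1e-16, rtol=1e-15)
    c1 = l1 * r_free / (k1 + r_free)
    c2 = l2 * r_free / (k2 + r_free)
    # verify mass-action residuals (free ligand = total - complex)
    for c, l_tot, kd in ((c1, l1, k1), (c2, l2, k2)):
        if c > 0:
            resid = abs(r_free * (l_tot - c) / c - kd) / kd
            if resid > 1e-8:
                raise ArithmeticError(
                    f"competition solver residual {resid:.2e} exceeds tolerance"
                )
    return (float(c1), float(c2))


def dynamic_range(system: TernaryAllosterySystem, chromophore_conc: float) -> float:
    """Signed fluorescence fold-change dF/F0 from zero to saturating analyte.

    Fluorescence is proportional to the brightness-weighted chromophore-bound
    occupancy.  With equal state brightness this is
    (c + Kd-)/(c + Kd+) - 1: it approaches coupling - 1 for c << Kd+ and 0
    for c >> Kd-, the trade-off motivating labeling at sqrt(Kd+ * Kd-).
    """
    if chromophore_conc <= 0:
        raise ValueError("chromophore_conc must be > 0")
    w1, w2 = system.brightness_weights
    c = chromophore_conc
    f0 = w1 * c / (c + system.kd_chromophore_apo)
    f_sat = w2 * c / (c + system.kd_chromophore_holo)
    return f_sat / f0 - 1.0


# ---------------------------------------------------------------------------
# isotherm fitting
# ---------------------------------------------------------------------------


class SingleSiteIsotherm(BaseEstimator):
    """Single-binding-site isotherm fitted by nonlinear least squares.

    Model (increasing): f(L) = f_min + (f_max - f_min) * L^n / (L^n + Kd^n)
    with the Hill exponent n fixed at 1 by default.  Decreasing fits use the
    reflected occupancy Kd^n / (L^n + Kd^n) so that ``f_max`` is always the
    bright plateau.

    Positivity of Kd is enforced by fitting log(Kd).  Kd is initialised at
    the geometric mean of the nonzero tested concentrations, f_max at the
    maximum mean and f_min at the zero-condition mean.

    Parameters
    ----------
    direction : 'increasing' | 'decreasing'
        Whether signal rises or falls with ligand.
    fix_hill : bool
        Fit with Hill exponent 1 (default) or free (diagnostic mode).
    flat_eps : float
        Signal range below ``flat_eps`` times the maximum absolute mean is
        treated as a flat titration and raises.

    Attributes
    ----------
    kd_ : float
        Fitted dissociation constant (uM).
    kd_sd_ : float
        Standard deviation of the fitted Kd from the fit covariance.
    f_min_, f_max_ : float
        Fitted plateaus on the original RFU scale.
    hill_ : float
        Hill exponent (1.0 when fixed).
    is_lower_bound_ : bool
        True when the fitted Kd exceeds the largest tested concentration.
    """

    def __init__(
        self,
        direction: Direction = "increasing",
        fix_hill: bool = True,
        flat_eps: float = 1e-3,
    ):
        self.direction = direction
        self.fix_hill = fix_hill
        self.flat_eps = flat_eps

    # -- model ------------------------------------------------------------

    def _occupancy(self, conc: np.ndarray, kd: float, hill: float) -> np.ndarray:
        ln = np.power(conc, hill)
        kn = kd**hill
        occ = ln / (ln + kn)
        if self.direction == "decreasing":
            occ = 1.0 - occ
        return occ

    def fit(self, X, y=None):
        """Fit the isotherm to concentrations X (uM) and responses y (RFU).

        X may be a 1-D array or an (n, 1) column; y are the per-concentration
        response means (replicates should be averaged before fitting).
        """
        conc = np.asarray(X, dtype=float).reshape(-1)
        resp = np.asarray(y, dtype=float).reshape(-1)
        if conc.size != resp.size:
            raise ValueError("X and y must have the same length")
        nonzero = conc > 0
        if np.unique(conc[nonzero]).size < 4:
            raise ValueError("need >= 4 distinct nonzero concentrations")

        span = resp.max() - resp.min()
        scale = max(np.abs(resp).max(), 1.0)
        if span < self.flat_eps * scale:
            raise RuntimeError("flat titration: signal range below noise floor")

        # min-max normalize the means; rescale fitted plateaus afterwards
        lo, hi = resp.min(), resp.max()
        norm = (resp - lo) / span

        kd0 = float(np.exp(np.mean(np.log(conc[nonzero]))))
        if self.direction == "increasing":
            fmin0 = norm[conc == 0].mean() if np.any(conc == 0) else norm[np.argmin(conc)]
            fmax0 = norm.max()
        else:
            fmin0 = norm.min()
            fmax0 = norm[conc == 0].mean() if np.any(conc == 0) else norm.max()

        if self.fix_hill:
            def model(L, log_kd, f_min, f_max):
                return f_min + (f_max - f_min) * self._occupancy(L, np.exp(log_kd), 1.0)

            p0 = [np.log(kd0), fmin0, fmax0]
        else:
            def model(L, log_kd, f_min, f_max, log_hill):
                return f_min + (f_max - f_min) * self._occupancy(
                    L, np.exp(log_kd), np.exp(log_hill)
                )

            p0 = [np.log(kd0), fmin0, fmax0, 0.0]

        popt, pcov = optimize.curve_fit(model, conc, norm, p0=p0, maxfev=20000)
        log_kd = popt[0]
        kd = float(np.exp(log_kd))
        log_kd_sd = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else 0.0
        kd_sd = kd * log_kd_sd  # delta method for the log parameterization

        self.kd_ = kd
        self.kd_sd_ = kd_sd
        self.f_min_ = float(lo + span * popt[1])
        self.f_max_ = float(lo + span * popt[2])
        self.hill_ = 1.0 if self.fix_hill else float(np.exp(popt[3]))
        self.is_lower_bound_ = bool(kd > conc.max())
        self.n_points_ = int(conc.size)
        return self

    def predict(self, X) -> np.ndarray:
        conc = np.asarray(X, dtype=float).reshape(-1)
        occ = self._occupancy(conc, self.kd_, self.hill_)
        return self.f_min_ + (self.f_max_ - self.f_min_) * occ

    def result_(self) -> IsothermFit:
        return IsothermFit(
            kd=self.kd_,
            f_max=self.f_max_,
            f_min=self.f_min_,
            hill=self.hill_,
            kd_sd=self.kd_sd_,
            is_lower_bound=self.is_lower_bound_,
            direction=self.direction,
            n_points=self.n_points_,
        )


def fit_single_site_isotherm(series: TitrationSeries, fix_hill: bool = True) -> IsothermFit:
    """Fit the chromophore-titration isotherm to a plate-reader series.

    Blanks are subtracted per concentration when present and replicate
    readings are averaged per concentration before fitting (the means are
    what gets fit); the reported plateaus are on the scale of the maximum
    mean.
    """
    means = series.mean_response()
    est = SingleSiteIsotherm(direction="increasing", fix_hill=fix_hill)
    est.fit(series.analyte_conc, means)
    return est.result_()


def fit_analyte_titration(
    series: TitrationSeries, direction: Direction = "increasing", fix_hill: bool = True
) -> IsothermFit:
    """Fit a Hill-1 analyte (e.g. Ca2+) titration at constant excess chromophore.

    ``direction='increasing'`` fits the sigmoid of positive allostery,
    ``'decreasing'`` the reflected inverse sigmoid of negative allostery.
    """
    means = series.mean_response()
    est = SingleSiteIsotherm(direction=direction, fix_hill=fix_hill)
    est.fit(series.analyte_conc, means)
    return est.result_()
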