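"""Seeded synthetic-data generators emulating the assay designs the fitting
modules consume.

Every generator is a pure function of its parameters and an integer seed:
serial-dilution titration plates (sqrt(10) steps, technical replicates, a
zero condition), chromophore x Ca2+ titration surfaces, ratiometric pH
sweeps, split-complementation kinetic traces, photobleach series, and ROI
cohorts with a stimulation frame.

Noise model: multiplicative Gaussian with coefficient of variation ``cv``
plus an additive floor, reproducible per seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .equilibria import TernaryAllosterySystem, TitrationSeries, ternary_state_fractions
from .ph_sensing import RatiometricCalibration
from .split_complementation import SplitPairModel, association_signal
from .timecourse import RoiTrace

__all__ = [
    "NoiseModel",
    "gen_titration_plate",
    "gen_ca_surface",
    "gen_ph_sweep",
    "gen_split_timecourse",
    "gen_bleach_series",
    "gen_roi_cohort",
]

SQRT10 = float(np.sqrt(10.0))


@dataclass
class NoiseModel:
    """Multiplicative CV noise plus an additive RFU floor."""

    cv: float = 0.05
    additive_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.cv < 0 or self.additive_floor < 0:
            raise ValueError("noise parameters must be >= 0")

    def apply(self, clean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        noisy = clean * (1.0 + rng.normal(0.0, self.cv, clean.shape) if self.cv > 0 else 1.0)
        if self.additive_floor > 0:
            noisy = noisy + rng.normal(0.0, self.additive_floor, clean.shape)
        return noisy


NOISELESS = NoiseModel(cv=0.0, additive_floor=0.0)


def _dilution_ladder(top_conc: float, n_dilutions: int, factor: float) -> np.ndarray:
    """Serial dilutions top/factor^i (ascending) plus a zero condition first."""
    if factor <= 1:
        raise ValueError("dilution factor must be > 1")
    concs = top_conc / factor ** np.arange(n_dilutions - 1, -1, -1, dtype=float)
    return np.concatenate(([0.0], concs))


def gen_titration_plate(
    kd: float,
    f_min: float,
    f_max: float,
    top_conc: float,
    n_dilutions: int = 10,
    factor: float = SQRT10,
    replicates: int = 8,
    noise: NoiseModel = NOISELESS,
    seed: int = 0,
    direction: Literal["increasing", "decreasing"] = "increasing",
) -> TitrationSeries:
    """One serial-dilution titration plate on a Hill-1 isotherm.

    Concentrations are ``top_conc / factor**i`` for i = n-1..0 plus a zero
    condition; each concentration gets ``replicates`` noisy readings.
    """
    rng = np.random.default_rng(seed)
    conc = _dilution_ladder(top_conc, n_dilutions, factor)
    occ = conc / (conc + kd)
    if direction == "decreasing":
        occ = 1.0 - occ
    clean = f_min + (f_max - f_min) * occ
    readings = noise.apply(np.repeat(clean[:, None], replicates, axis=1), rng)
    return TitrationSeries(
        analyte_conc=conc,
        rfu=readings,
        meta={"kd_true": kd, "seed": seed, "direction": direction},
    )


def gen_ca_surface(
    system: TernaryAllosterySystem,
    chromophore_top: float = 316.0,
    n_chromophore: int = 8,
    analyte_top: float = 9000.0,
    n_analyte: int = 11,
    factor: float = SQRT10,
    noise: NoiseModel = NOISELESS,
    seed: int = 0,
) -> dict:
    """Chromophore x analyte titration surface of normalized readings.

    Rows follow the chromophore ladder, columns the analyte ladder (both with
    a zero condition).  Readings are brightness-weighted bound-state
    fractions, min-max normalized to [0, 1] over the clean surface.
    """
    rng = np.random.default_rng(seed)
    c_grid = _dilution_ladder(chromophore_top, n_chromophore, factor)
    a_grid = _dilution_ladder(analyte_top, n_analyte, factor)
    w1, w2 = system.brightness_weights
    clean = np.empty((c_grid.size, a_grid.size))
    for i, c in enumerate(c_grid):
        for j, a in enumerate(a_grid):
            _, f_c, _, f_ca = ternary_state_fractions(system, c, a)
            clean[i, j] = w1 * f_c + w2 * f_ca
    rng_ = clean.max() - clean.min()
    norm = (clean - clean.min()) / rng_ if rng_ > 0 else np.zeros_like(clean)
    return {
        "chromophore_uM": c_grid,
        "analyte_uM": a_grid,
        "surface": noise.apply(norm, rng),
        "seed": seed,
    }


def gen_ph_sweep(
    cal: RatiometricCalibration,
    ph_grid: Sequence[float] | None = None,
    replicates: int = 3,
    f_blue_scale: float = 1000.0,
    blank_level: float = 25.0,
    noise: NoiseModel = NOISELESS,
    seed: int = 0,
):
    """Two-channel pH sweep table consistent with a logistic calibration.

    The blueshifted channel is held at ``f_blue_scale`` and the redshifted
    channel at ``f_blue_scale * F_ratio(pH)``; matched blank wells carry the
    constant ``blank_level`` offset, which is added to both channels so that
    blank subtraction recovers the target ratio exactly in the noiseless
    case.  Returns a pandas DataFrame with columns
    pH, replicate, f_blue, f_red, blank_blue, blank_red.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    if ph_grid is None:
        ph_grid = np.linspace(3.6, 8.4, 13)
    ph_grid = np.asarray(ph_grid, dtype=float)
    rows = []
    for ph in ph_grid:
        ratio = cal.evaluate(float(ph))
        for rep in range(replicates):
            f_blue = noise.apply(np.array([f_blue_scale]), rng)[0]
            f_red = noise.apply(np.array([f_blue_scale * ratio]), rng)[0]
            rows.append(
                {
                    "pH": float(ph),
                    "replicate": rep,
                    "f_blue": f_blue + blank_level,
                    "f_red": f_red + blank_level,
                    "blank_blue": blank_level,
                    "blank_red": blank_level,
                }
            )
    return pd.DataFrame(rows)


def gen_split_timecourse(
    plateau: float,
    k_obs: float,
    start: float = 0.0,
    t_step_s: float = 30.0,
    t_end_s: float = 2700.0,
    f0_rfu: float = 1000.0,
    noise: NoiseModel = NOISELESS,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Monophasic association/competition fluorescence time course.

    The underlying fold-change is plateau + (start - plateau)*exp(-k*t) with
    the first point exactly ``start`` (0 for assembly from mixing); raw RFU
    are reconstructed as F0*(1 + fold_change) so the derived dF/F0 series of
    the clean trace begins at zero.  Returns (time_s, rfu).
    """
    if k_obs <= 0:
        raise ValueError("k_obs must be > 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_end_s + 0.5 * t_step_s, t_step_s)
    fold = plateau + (start - plateau) * np.exp(-k_obs * t)
    rfu = f0_rfu * (1.0 + fold)
    noisy = noise.apply(rfu, rng)
    noisy[0] = rfu[0]  # the F0 anchor is the first measurement by definition
    return t, noisy


def gen_bleach_series(
    h: float,
    k: float,
    n_frames: int = 200,
    frame_rate_hz: float = 0.885,
    noise: NoiseModel = NOISELESS,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized photobleach series h + (1-h)*exp(-k*t), t in frames.

    Returns (frame_times_s, normalized_intensity); the first frame is ~1.
    """
    if not (0.0 < h <= 1.0):
        raise ValueError("plateau h must be in (0, 1]")
    rng = np.random.default_rng(seed)
    frames = np.arange(n_frames, dtype=float)
    clean = h + (1.0 - h) * np.exp(-k * frames)
    return frames / frame_rate_hz, noise.apply(clean, rng)


def gen_roi_cohort(
    n_rois: int,
    stim_frame: int = 25,
    amplitude_mean: float = 0.42,
    amplitude_sd: float = 0.14,
    sign: int = -1,
    n_frames: int = 150,
    frame_rate: float = 5.0,
    baseline_rfu: float = 500.0,
    background_rfu: float = 80.0,
    decay_s: float = 5.0,
    noise: NoiseModel = NOISELESS,
    seed: int = 0,
) -> list[RoiTrace]:
    """Cohort of ROI traces with exponential-shaped post-stimulus responses.

    Each ROI draws a response amplitude from N(amplitude_mean, amplitude_sd)
    truncated at zero; ``sign=-1`` gives fluorescence decreases (negative
    allostery reporting a Ca2+ rise).  Background channels are included.
    """
    if n_rois < 1:
        raise ValueError("n_rois must be >= 1")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) / frame_rate
    traces = []
    for i in range(n_rois):
        amp = max(rng.normal(amplitude_mean, amplitude_sd), 0.0)
        response = np.zeros(n_frames)
        post = np.arange(n_frames - stim_frame - 1, dtype=float) / frame_rate
        # fast rise, slow recovery; shape normalized so its peak equals amp
        shape = (1.0 - np.exp(-post / 0.4)) * np.exp(-post / decay_s)
        if shape.size and shape.max() > 0:
            shape = shape / shape.max()
        response[stim_frame + 1 :] = amp * shape
        f = baseline_rfu * (1.0 + sign * response)
        sig = noise.apply(f, rng) + background_rfu
        bg = np.full(n_frames, background_rfu) + (
            rng.normal(0.0, noise.additive_floor, n_frames) if noise.additive_floor > 0 else 0.0
        )
        traces.append(
            RoiTrace(
                time=t,
                signal=sig,
                background=bg,
                stim_frame=stim_frame,
                frame_rate=frame_rate,
                meta={"amplitude_true": amp, "roi_id": i, "seed": seed},
            )
        )
    return traces
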