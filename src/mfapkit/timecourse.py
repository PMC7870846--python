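"""ROI-level live-cell time-course analysis.

Background subtraction, pre-stimulus baseline F0, dF/F0 traces,
peak-response extraction after a stimulation frame, baseline-shift
statistics, and contraction-cycle lag statistics for cardiomyocyte
recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sp_signal

__all__ = [
    "RoiTrace",
    "background_subtract",
    "baseline_f0",
    "dff0_trace",
    "peak_response",
    "baseline_shift",
    "cycle_lag",
    "cohort_peak_summary",
]


@dataclass
class RoiTrace:
    """One region-of-interest trace with its matched background ROI."""

    time: np.ndarray  # s
    signal: np.ndarray  # RFU (raw ROI mean)
    background: np.ndarray  # RFU (proximal non-fluorescent ROI)
    stim_frame: int | None = None
    frame_rate: float = 5.0  # Hz
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if not (self.time.size == self.signal.size == self.background.size):
            raise ValueError("time, signal and background must have equal lengths")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")


def background_subtract(trace: RoiTrace) -> np.ndarray:
    """Elementwise ROI signal minus matched background ROI."""
    return trace.signal - trace.background


def baseline_f0(trace: RoiTrace, stim_frame: int | None = None, window_s: float = 1.0) -> float:
    """Baseline F0: mean background-subtracted signal over the ``window_s``
    seconds immediately preceding the stimulation frame.

    At 5 Hz with the default 1 s window this is the mean of exactly 5 frames.
    """
    stim = trace.stim_frame if stim_frame is None else stim_frame
    if stim is None:
        raise ValueError("a stimulation frame is required")
    n_window = int(round(window_s * trace.frame_rate))
    if n_window < 1:
        raise ValueError("window shorter than one frame")
    if stim < n_window:
        raise ValueError(
            f"need {n_window} pre-stimulus frames, have {stim}"
        )
    corrected = background_subtract(trace)
    return float(corrected[stim - n_window : stim].mean())


def dff0_trace(trace: RoiTrace, stim_frame: int | None = None, window_s: float = 1.0) -> np.ndarray:
    """dF/F0 with F0 = the pre-stimulus baseline mean."""
    f0 = baseline_f0(trace, stim_frame, window_s)
    if f0 == 0:
        raise ValueError("baseline F0 is zero")
    corrected = background_subtract(trace)
    return (corrected - f0) / f0


def peak_response(fold_change: Sequence[float], stim_frame: int) -> tuple[float, int]:
    """Maximum |dF/F0| strictly after the stimulation frame.

    Returns (peak magnitude, frame index of its first occurrence).
    """
    arr = np.asarray(fold_change, dtype=float)
    if stim_frame >= arr.size - 1:
        raise ValueError("stimulation frame at or beyond the end of the trace")
    post = np.abs(arr[stim_frame + 1 :])
    idx = int(np.argmax(post))
    return float(post[idx]), stim_frame + 1 + idx


def baseline_shift(
    trace: RoiTrace, event_frame: int, window_s: float = 10.0
) -> float:
    """Post/pre window-mean difference of the background-subtracted signal.

    A sustained-baseline statistic (e.g. SERCA-pump inhibition raising
    compartmental Ca2+): mean over ``window_s`` after ``event_frame`` minus
    mean over ``window_s`` before it.
    """
    n = int(round(window_s * trace.frame_rate))
    if event_frame < n or event_frame + n > trace.time.size:
        raise ValueError("insufficient frames around the event for the window")
    corrected = background_subtract(trace)
    return float(corrected[event_frame : event_frame + n].mean() - corrected[event_frame - n : event_frame].mean())


def _detect_peaks(
    y: np.ndarray, frame_rate: float, min_separation_s: float, prominence_frac: float
) -> np.ndarray:
    rng = float(y.max() - y.min())
    if rng == 0:
        return np.array([], dtype=int)
    distance = max(int(round(min_separation_s * frame_rate)), 1)
    peaks, _ = sp_signal.find_peaks(y, distance=distance, prominence=prominence_frac * rng)
    return peaks


def cycle_lag(
    time_s: Sequence[float],
    fluorescence: Sequence[float],
    contraction: Sequence[float],
    n_cycles: int | None = None,
    frame_rate: float | None = None,
    min_separation_s: float = 0.3,
    prominence_frac: float = 0.2,
) -> tuple[float, float, int]:
    """Mean and s.d. of the per-cycle lag between fluorescence and contraction
    peaks, in milliseconds.

    Peaks are local maxima with a configurable minimum separation and
    prominence; peaks are paired by nearest-cycle matching and the lag of
    each cycle is time(peak fluorescence) - time(peak contraction), so the
    statistic is antisymmetric under swapping the two traces.

    Returns (mean_lag_ms, sd_lag_ms, n_cycles_used).
    """
    t = np.asarray(time_s, dtype=float)
    f = np.asarray(fluorescence, dtype=float)
    c = np.asarray(contraction, dtype=float)
    if not (t.size == f.size == c.size):
        raise ValueError("traces must share the time base")
    if frame_rate is None:
        frame_rate = 1.0 / float(np.median(np.diff(t)))

    pf = _detect_peaks(f, frame_rate, min_separation_s, prominence_frac)
    pc = _detect_peaks(c, frame_rate, min_separation_s, prominence_frac)
    if pf.size == 0 or pc.size == 0:
        raise ValueError("no detectable peaks in one or both traces")
    if n_cycles is not None and (pf.size < n_cycles or pc.size < n_cycles):
        raise ValueError(
            f"requested {n_cycles} cycles but detected {pf.size} fluorescence "
            f"and {pc.size} contraction peaks"
        )
    if abs(pf.size - pc.size) > max(2, 0.2 * max(pf.size, pc.size)):
        raise ValueError(
            f"cycle counts differ beyond tolerance ({pf.size} vs {pc.size})"
        )

    # nearest-cycle pairing: for each contraction peak take the closest
    # fluorescence peak; drop duplicate matches keeping the closer one
    lags: dict[int, float] = {}
    for ci in pc:
        fi = pf[np.argmin(np.abs(pf - ci))]
        lag = (t[fi] - t[ci]) * 1e3
        key = int(fi)
        if key not in lags or abs(lag) < abs(lags[key]):
            lags[key] = lag
    vals = np.array(list(lags.values()))
    if n_cycles is not None:
        vals = vals[:n_cycles]
    return float(vals.mean()), float(vals.std(ddof=1)) if vals.size > 1 else 0.0, int(vals.size)


def cohort_peak_summary(
    traces: Sequence[RoiTrace], window_s: float = 1.0
) -> dict:
    """Per-cohort mean and s.d. of peak |dF/F0| over ROIs (summary-table style)."""
    peaks = []
    for tr in traces:
        if tr.stim_frame is None:
            raise ValueError("every trace needs a stimulation frame")
        fc = dff0_trace(tr, window_s=window_s)
        peak, _ = peak_response(fc, tr.stim_frame)
        peaks.append(peak)
    arr = np.asarray(peaks)
    return {
        "peak_abs_dff0_mean": float(arr.mean()),
        "peak_abs_dff0_sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        "n_rois": int(arr.size),
    }
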