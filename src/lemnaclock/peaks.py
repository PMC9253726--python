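"""Peak-time estimation by local quadratic curve fitting.

Candidate peaks are local maxima of a lightly smoothed copy of the trace;
each candidate is refined by an ordinary least-squares quadratic fit to the
raw points within a fixed half-width, and the vertex of the parabola gives
the peak time.  The first peak after release into constant light, measured
from the final entrained dawn, is the phase phenotype of a strain: a longer
free-running period delays it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from lemnaclock.preprocess import LuminescenceTrace, NormalizedTrace, window_points

__all__ = ["PeakEstimate", "detect_peaks", "first_peak_in_ll"]

Trace = LuminescenceTrace | NormalizedTrace


@dataclass(frozen=True)
class PeakEstimate:
    """One fitted peak: vertex time, fitted height, and curvature (< 0)."""

    time_h: float
    height: float
    curvature: float
    fit_halfwidth_h: float


def _smooth(values: np.ndarray, n: int) -> np.ndarray:
    """Centered moving average keeping length (edges use shrunken windows)."""
    half = n // 2
    kernel = np.ones(n) / n
    out = np.convolve(values, kernel, mode="same")
    # fix edge windows to use only observed points
    for i in range(half):
        out[i] = values[: i + half + 1].mean()
        out[-(i + 1)] = values[-(i + half + 1):].mean()
    return out


def detect_peaks(
    trace: Trace,
    smooth_window_h: float = 2.0,
    fit_halfwidth_h: float = 2.0,
    min_separation_h: float = 12.0,
) -> list[PeakEstimate]:
    """Ordered peak estimates for a uniformly sampled trace.

    Local maxima of the ``smooth_window_h`` moving-average-smoothed series
    seed quadratic fits on the raw points within ``fit_halfwidth_h`` of the
    candidate; fits with non-negative curvature or a vertex outside the
    fitted window are dropped.  Peaks closer than ``min_separation_h`` are
    resolved by keeping the higher fitted peak (earlier time on ties).
    """
    t = np.asarray(trace.times_h, dtype=float)
    y = np.asarray(trace.values, dtype=float)
    dt = float(t[1] - t[0])
    n_fit = int(round(fit_halfwidth_h / dt))
    if len(t) < 2 * n_fit + 1:
        raise ValueError("trace shorter than the quadratic fit window")
    n_smooth = window_points(smooth_window_h, dt)
    s = _smooth(y, n_smooth)
    interior = (s[1:-1] > s[:-2]) & (s[1:-1] >= s[2:])
    candidates = np.nonzero(interior)[0] + 1

    fitted: list[PeakEstimate] = []
    for idx in candidates:
        lo, hi = idx - n_fit, idx + n_fit + 1
        if lo < 0 or hi > len(t):
            continue  # window falls off the trace edge
        tw, yw = t[lo:hi], y[lo:hi]
        tc = tw - t[idx]  # center for conditioning
        a, b, c = np.polyfit(tc, yw, 2)
        if a >= 0:
            continue
        vertex = -b / (2.0 * a)
        if abs(vertex) > fit_halfwidth_h:
            continue
        time_h = float(t[idx] + vertex)
        height = float(a * vertex**2 + b * vertex + c)
        fitted.append(PeakEstimate(time_h, height, float(a), fit_halfwidth_h))

    fitted.sort(key=lambda p: p.time_h)
    kept: list[PeakEstimate] = []
    for pk in fitted:
        if kept and pk.time_h - kept[-1].time_h < min_separation_h:
            if pk.height > kept[-1].height:
                kept[-1] = pk
        else:
            kept.append(pk)
    return kept


def first_peak_in_ll(peaks: list[PeakEstimate], trace: Trace) -> float:
    """Time of the earliest peak in constant light, hours since final dawn.

    Returns NaN when no peak falls at or after the release into constant
    light (arrhythmic or truncated trace).
    """
    for pk in peaks:
        if pk.time_h >= trace.ll_start_h:
            return pk.time_h - trace.final_dawn_h
    return float("nan")
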