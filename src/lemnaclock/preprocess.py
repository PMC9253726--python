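"""Detrending and amplitude normalization of luminescence traces.

Reporter traces from growing fronds carry a growth trend and a slowly
changing oscillation amplitude on top of the circadian signal.  Both are
removed with centered 24-h moving statistics: the moving average is
subtracted (detrend) and the result is divided by the moving population
standard deviation (amplitude normalization), leaving a dimensionless
oscillation of roughly unit amplitude.  Windows are full-window-only: the
half-window at each edge is trimmed rather than padded, because downstream
period analysis uses an interior time window where edges never matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "LuminescenceTrace",
    "NormalizedTrace",
    "window_points",
    "moving_average_detrend",
    "moving_sd_normalize",
    "preprocess_trace",
]

#: relative tolerance for grid-uniformity validation
_GRID_RTOL = 1e-9


@dataclass
class LuminescenceTrace:
    """One replicate's uniformly sampled reporter signal.

    Times are hours since the first lights-on of entrainment.  ``ll_start_h``
    marks the release into constant light (the moment the last entrained
    dark period would have begun); ``entrain_photoperiod_h`` is the light
    portion of the entraining cycle, so the final entrained dawn is at
    ``ll_start_h - entrain_photoperiod_h``.
    """

    strain_id: str
    replicate_id: str
    times_h: np.ndarray
    values: np.ndarray
    ll_start_h: float
    entrain_photoperiod_h: float = 15.0

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_h.ndim != 1 or self.times_h.shape != self.values.shape:
            raise ValueError("times_h and values must be 1-D arrays of equal length")
        if len(self.times_h) < 2:
            raise ValueError("trace needs at least two samples")
        dt = np.diff(self.times_h)
        if np.any(dt <= 0):
            raise ValueError(
                f"trace {self.strain_id}/{self.replicate_id}: "
                "times must be strictly increasing"
            )
        if np.max(np.abs(dt - dt[0])) > _GRID_RTOL * dt[0]:
            raise ValueError(
                f"trace {self.strain_id}/{self.replicate_id}: non-uniform sampling grid"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(
                f"trace {self.strain_id}/{self.replicate_id}: non-finite values"
            )
        if not (self.times_h[0] <= self.ll_start_h <= self.times_h[-1]):
            raise ValueError(
                f"trace {self.strain_id}/{self.replicate_id}: "
                "ll_start_h outside the sampled time range"
            )

    @property
    def sampling_interval_h(self) -> float:
        return float(self.times_h[1] - self.times_h[0])

    @property
    def final_dawn_h(self) -> float:
        """Time of the last entrained lights-on before constant light."""
        return self.ll_start_h - self.entrain_photoperiod_h


@dataclass
class NormalizedTrace:
    """Edge-trimmed, detrended and amplitude-normalized trace."""

    strain_id: str
    replicate_id: str
    times_h: np.ndarray
    values: np.ndarray
    ll_start_h: float
    entrain_photoperiod_h: float
    window_h: float = 24.0
    detrended_only: bool = field(default=False, repr=False)

    @property
    def sampling_interval_h(self) -> float:
        return float(self.times_h[1] - self.times_h[0])

    @property
    def final_dawn_h(self) -> float:
        return self.ll_start_h - self.entrain_photoperiod_h


def window_points(window_h: float, sampling_interval_h: float) -> int:
    """Odd number of samples spanning at most ``window_h``, inclusive ends.

    At 20-min sampling a 24-h window is 73 points (±36 samples).
    """
    if window_h <= 0 or sampling_interval_h <= 0:
        raise ValueError("window and sampling interval must be positive")
    half = int(np.floor(window_h / (2.0 * sampling_interval_h) + 1e-9))
    n = 2 * half + 1
    if n < 3:
        raise ValueError("window spans fewer than 3 samples")
    return n


def _moving(values: np.ndarray, n: int) -> np.ndarray:
    return sliding_window_view(values, n)


def moving_average_detrend(trace: LuminescenceTrace, window_h: float = 24.0) -> NormalizedTrace:
    """Subtract the centered ``window_h`` moving average.

    Output exists only where the full window fits; (n-1)/2 points are
    trimmed at each edge.
    """
    n = window_points(window_h, trace.sampling_interval_h)
    if len(trace.values) < n:
        raise ValueError(
            f"trace {trace.strain_id}/{trace.replicate_id}: shorter than one "
            f"{window_h}-h window ({n} points)"
        )
    half = n // 2
    detr = trace.values[half:-half] - _moving(trace.values, n).mean(axis=1)
    return NormalizedTrace(
        strain_id=trace.strain_id,
        replicate_id=trace.replicate_id,
        times_h=trace.times_h[half:-half].copy(),
        values=detr,
        ll_start_h=trace.ll_start_h,
        entrain_photoperiod_h=trace.entrain_photoperiod_h,
        window_h=window_h,
        detrended_only=True,
    )


def moving_sd_normalize(detrended: NormalizedTrace, window_h: float = 24.0) -> NormalizedTrace:
    """Divide by the centered moving population SD (N denominator).

    A second edge trim of (n-1)/2 points per side is applied.  A zero SD in
    any retained window (locally constant signal) is an error.
    """
    dt = detrended.sampling_interval_h
    n = window_points(window_h, dt)
    if len(detrended.values) < n:
        raise ValueError("detrended trace shorter than one window")
    half = n // 2
    sd = _moving(detrended.values, n).std(axis=1)  # population SD (ddof=0)
    if np.any(sd == 0):
        t_bad = detrended.times_h[half:-half][np.nonzero(sd == 0)[0][0]]
        raise ValueError(
            f"zero moving SD at t={t_bad:g} h "
            f"({detrended.strain_id}/{detrended.replicate_id}): constant segment"
        )
    return NormalizedTrace(
        strain_id=detrended.strain_id,
        replicate_id=detrended.replicate_id,
        times_h=detrended.times_h[half:-half].copy(),
        values=detrended.values[half:-half] / sd,
        ll_start_h=detrended.ll_start_h,
        entrain_photoperiod_h=detrended.entrain_photoperiod_h,
        window_h=window_h,
    )


def preprocess_trace(trace: LuminescenceTrace, window_h: float = 24.0) -> NormalizedTrace:
    """Detrend then normalize; trims 2·(window points − 1) samples in total."""
    return moving_sd_normalize(moving_average_detrend(trace, window_h), window_h)
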