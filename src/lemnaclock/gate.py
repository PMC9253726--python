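"""A minimal external-coincidence gate model linking FRP to CDL.

Floral induction in a short-day plant is taken to be gated by the
circadian clock and permitted only in darkness: the gate opens a fixed
delay after dusk, and flowering occurs when the night is long enough to
contain the gate.  The gate delay is d0 at a 24-h free-running period and
shifts by k hours per hour of period deviation, so

    predicted CDL = 24 - (d0 + k * (tau - 24))

A longer period delays the gate and shortens the critical day length,
giving the negative FRP-CDL dependence with slope -k.  The model is a toy
quantitative rendering of the coincidence hypothesis, not an inference
about mechanism; fitting it to a strain panel is an exact reparameterization
of the Deming regression line of CDL on FRP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from lemnaclock.stats import deming_fit

__all__ = ["GateModel", "predicted_cdl", "fit_gate_model"]


@dataclass(frozen=True)
class GateModel:
    """Gate delay after dusk: d0 at tau = 24 h, changing k h per h of tau."""

    d0_h: float
    k: float
    consistent: bool = True  # False when fitted k < 0 (anti-gate direction)

    def __post_init__(self) -> None:
        if not (0 < self.d0_h < 24):
            raise ValueError("d0_h must be in (0, 24)")


def predicted_cdl(model: GateModel, tau_h) -> np.ndarray | float:
    """Predicted critical day length for free-running period ``tau_h``.

    CDL = 24 - (d0 + k*(tau - 24)); the 50 % flowering boundary sits where
    night length equals the gate delay.  Predictions are clamped into
    (0, 24) with a warning, since a gate outside one day is meaningless.
    """
    tau = np.asarray(tau_h, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("tau_h must be positive")
    cdl = 24.0 - (model.d0_h + model.k * (tau - 24.0))
    eps = 1e-9
    if np.any(cdl <= 0) or np.any(cdl >= 24):
        warnings.warn("predicted CDL outside (0, 24) h; clamped")
        cdl = np.clip(cdl, eps, 24.0 - eps)
    return float(cdl) if np.isscalar(tau_h) else cdl


def fit_gate_model(tau_h, cdl_h, delta: float = 1.0) -> tuple[GateModel, dict]:
    """Fit (d0, k) from observed (tau, CDL) pairs.

    The Deming line cdl = intercept + slope * tau maps exactly to
    k = -slope and d0 = 24 - (intercept + 24 * slope), so
    ``predicted_cdl`` of the fitted model reproduces the Deming line.  A
    positive Deming slope yields k < 0, which contradicts the gate
    hypothesis; the fit is returned anyway with ``consistent=False``.
    """
    fit = deming_fit(tau_h, cdl_h, delta=delta)
    if fit.degenerate:
        raise ValueError("degenerate panel: no covariance between tau and CDL")
    k = -fit.slope
    d0 = 24.0 - (fit.intercept + 24.0 * fit.slope)
    consistent = k >= 0
    if not consistent:
        warnings.warn("fitted k < 0: panel slope inconsistent with the gate hypothesis")
    model = GateModel(d0_h=d0, k=k, consistent=consistent)
    summary = {
        "deming_slope": fit.slope,
        "deming_intercept": fit.intercept,
        "delta": fit.delta,
        "n": int(np.sum(np.isfinite(np.asarray(tau_h, dtype=float))
                        & np.isfinite(np.asarray(cdl_h, dtype=float)))),
    }
    return model, summary
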