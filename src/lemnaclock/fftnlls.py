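"""Free-running period estimation by FFT-seeded multicomponent cosine fits.

The model for a normalized trace on the analysis window is

    y(t) = c0 + sum_k A_k * cos(2*pi*(t - phi_k) / tau_k)

Components are added one at a time, each seeded from the largest remaining
peak of the discrete Fourier periodogram of the residuals and refined
jointly by damped (Levenberg-Marquardt-type) nonlinear least squares.  A
newly added component is kept only while its amplitude is significantly
positive; the rhythm's statistical quality is summarized by the relative
amplitude error (RAE), the ratio of the amplitude confidence-interval
half-width to the amplitude itself, which runs from 0 (perfectly determined
rhythm) to 1 (statistically insignificant).

The circadian component of a fit is the one with period inside the
configured circadian range having the largest amplitude.  Replicates are
aggregated per strain and strains with a high mean RAE or an unstable
period (high SD across replicates) are flagged for exclusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from lemnaclock.preprocess import NormalizedTrace

__all__ = [
    "RhythmConfig",
    "CosineComponent",
    "FitDiagnostics",
    "FRPEstimate",
    "StrainRhythm",
    "periodogram_seeds",
    "fit_multicomponent_cosine",
    "rae",
    "estimate_frp",
    "aggregate_replicates",
]


@dataclass(frozen=True)
class RhythmConfig:
    """Tuning knobs for period estimation and the exclusion rule.

    The analysis window [60, 132] h restricts fitting to constant light and
    away from the moving-window edge trims; the circadian range [15, 35] h
    brackets plausible free-running periods with margin; a strain is
    excluded when its mean RAE exceeds ``rae_threshold`` or the SD of its
    replicate periods exceeds ``sd_frp_threshold_h`` (either criterion can
    be toggled off).
    """

    analysis_window_h: tuple[float, float] = (60.0, 132.0)
    circadian_range_h: tuple[float, float] = (15.0, 35.0)
    max_components: int = 4
    rae_threshold: float = 0.1
    sd_frp_threshold_h: float = 1.5
    exclude_on_rae: bool = True
    exclude_on_sd: bool = True
    confidence_level: float = 0.95
    convergence_tol: float = 1e-10
    max_iterations: int = 200

    def __post_init__(self) -> None:
        if self.analysis_window_h[0] >= self.analysis_window_h[1]:
            raise ValueError("analysis window lower bound must be below upper")
        if self.circadian_range_h[0] >= self.circadian_range_h[1]:
            raise ValueError("circadian range lower bound must be below upper")
        if min(self.rae_threshold, self.sd_frp_threshold_h) <= 0:
            raise ValueError("thresholds must be positive")
        if not (0 < self.confidence_level < 1):
            raise ValueError("confidence_level must be in (0, 1)")


@dataclass(frozen=True)
class CosineComponent:
    tau_h: float
    amplitude: float
    phase_h: float  # peak-time offset, wrapped to [0, tau_h)
    amplitude_ci_halfwidth: float

    def __post_init__(self) -> None:
        if self.tau_h <= 0:
            raise ValueError("tau_h must be positive")


@dataclass
class FitDiagnostics:
    c0: float
    rss: float
    n_points: int
    n_params: int
    converged: bool
    rss_trajectory: list[float] = field(default_factory=list)


@dataclass
class FRPEstimate:
    """Per-replicate circadian period estimate with rhythm quality."""

    strain_id: str
    replicate_id: str
    tau_h: float  # NaN when no circadian component was found
    rae: float
    amplitude: float
    phase_h: float
    n_components_fitted: int
    rss: float
    converged: bool

    @property
    def has_circadian_component(self) -> bool:
        return np.isfinite(self.tau_h)


@dataclass
class StrainRhythm:
    """Per-strain aggregate across replicates with the exclusion flag."""

    strain_id: str
    estimates: list[FRPEstimate]
    mean_frp_h: float
    sd_frp_h: float
    mean_rae: float
    excluded: bool
    exclusion_reason: str = ""
    first_peak_mean_h: float = float("nan")


def periodogram_seeds(
    values: np.ndarray,
    sampling_interval_h: float,
    k: int = 1,
) -> list[tuple[float, float, float]]:
    """The k strongest periodogram lines as (tau, amplitude, phase) seeds.

    Phases are returned as peak-time offsets relative to the first sample,
    so callers fitting on an absolute time axis must add the window start.
    Ordered by descending spectral power; the zero frequency is excluded.
    """
    y = np.asarray(values, dtype=float)
    if len(y) < 16:
        raise ValueError("need at least 16 points for periodogram seeding")
    if np.all(y == 0):
        raise ValueError("all-zero input")
    n = len(y)
    spec = np.fft.rfft(y - y.mean())
    freqs = np.fft.rfftfreq(n, d=sampling_interval_h)
    power = np.abs(spec) ** 2
    order = np.argsort(power[1:])[::-1] + 1  # skip zero frequency
    seeds = []
    for idx in order[:k]:
        tau = 1.0 / freqs[idx]
        amplitude = 2.0 * np.abs(spec[idx]) / n
        # spec[idx] = (n/2) A exp(-i 2 pi phi / tau) for y = A cos(2 pi (t - phi)/tau)
        phase = (-np.angle(spec[idx]) / (2.0 * np.pi)) * tau % tau
        seeds.append((float(tau), float(amplitude), float(phase)))
    return seeds


def _model(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    c0 = params[0]
    y = np.full_like(t, c0)
    for j in range((len(params) - 1) // 3):
        a, tau, phi = params[1 + 3 * j: 4 + 3 * j]
        y = y + a * np.cos(2.0 * np.pi * (t - phi) / tau)
    return y


def _canonicalize(params: np.ndarray) -> np.ndarray:
    """Flip negative amplitudes into a half-period phase shift; wrap phases."""
    out = params.copy()
    for j in range((len(params) - 1) // 3):
        i = 1 + 3 * j
        a, tau, phi = out[i], out[i + 1], out[i + 2]
        tau = abs(tau)  # the cosine is even in tau
        if a < 0:
            a, phi = -a, phi + tau / 2.0
        out[i], out[i + 1], out[i + 2] = a, tau, phi % tau
    return out


def _amplitude_ci_halfwidths(
    params: np.ndarray,
    jac: np.ndarray,
    rss: float,
    confidence_level: float,
) -> np.ndarray:
    """Half-widths of linearized t-intervals for each component amplitude.

    Covariance = sigma^2 (J^T J)^(-1) with sigma^2 = RSS/(n - p); a singular
    normal matrix yields infinite half-widths (RAE caps at 1 downstream).
    """
    n, p = jac.shape
    dof = n - p
    if dof <= 0:
        return np.full((len(params) - 1) // 3, np.inf)
    sigma2 = max(rss, 0.0) / dof
    jtj = jac.T @ jac
    try:
        cov = sigma2 * np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        warnings.warn("singular normal matrix in amplitude CI; RAE capped at 1")
        return np.full((len(params) - 1) // 3, np.inf)
    tq = stats.t.ppf(0.5 + confidence_level / 2.0, dof)
    amp_idx = 1 + 3 * np.arange((len(params) - 1) // 3)
    var = np.clip(np.diag(cov)[amp_idx], 0.0, None)
    return tq * np.sqrt(var)


def fit_multicomponent_cosine(
    times: np.ndarray,
    values: np.ndarray,
    seeds: list[tuple[float, float, float]] | None = None,
    config: RhythmConfig = RhythmConfig(),
) -> tuple[list[CosineComponent], FitDiagnostics]:
    """Fit y = c0 + sum A_k cos(2 pi (t - phi_k)/tau_k) by damped least squares.

    Components are added greedily from residual-periodogram seeds (or the
    caller-provided ``seeds`` for the first components); after each addition
    all parameters are refit jointly.  Addition stops when the new
    component's amplitude confidence interval includes zero, when the
    residuals become spectrally featureless, or at ``max_components``; a
    non-significant component is discarded.  RSS is non-increasing across
    accepted additions.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be 1-D arrays of equal length")
    dt = float(t[1] - t[0])
    t0 = float(t[0])

    params = np.array([y.mean()])
    rss = float(np.sum((y - params[0]) ** 2))
    traj = [rss]
    jac = np.ones((len(y), 1))
    converged = True
    provided = list(seeds) if seeds else []

    baseline_ss = float(np.sum((y - y.mean()) ** 2))
    while (len(params) - 1) // 3 < config.max_components:
        resid = y - _model(params, t)
        if float(np.sum(resid**2)) <= 1e-18 * max(baseline_ss, 1e-300):
            break  # residuals at round-off level: model is exact
        if provided:
            tau0, a0, phi0 = provided.pop(0)
        else:
            try:
                (tau0, a0, phi0), = periodogram_seeds(resid, dt, k=1)
            except ValueError:
                break  # residuals exactly zero: nothing left to fit
            phi0 += t0  # seed phase is relative to the window start
        if a0 == 0:
            break
        trial = np.concatenate([params, [a0, tau0, phi0 % tau0]])
        res = optimize.least_squares(
            lambda p: _model(p, t) - y,
            trial,
            method="lm",
            xtol=config.convergence_tol,
            ftol=config.convergence_tol,
            gtol=1e-14,
            max_nfev=config.max_iterations * len(trial),
        )
        new_params = _canonicalize(res.x)
        new_rss = float(2.0 * res.cost)
        if new_rss > rss * (1 + 1e-12):
            break  # damped step could not improve the fit; keep previous model
        ci = _amplitude_ci_halfwidths(
            new_params, res.jac, new_rss, config.confidence_level
        )
        new_amp = new_params[1 + 3 * ((len(new_params) - 1) // 3 - 1)]
        if not res.success:
            converged = False
        if new_amp <= ci[-1]:
            break  # newest component not significantly > 0: discard it
        params, rss, jac = new_params, new_rss, res.jac
        traj.append(rss)

    n_comp = (len(params) - 1) // 3
    if n_comp == 0:
        ci = np.array([])
    else:
        ci = _amplitude_ci_halfwidths(params, jac, rss, config.confidence_level)
    components = [
        CosineComponent(
            tau_h=float(params[2 + 3 * j]),
            amplitude=float(params[1 + 3 * j]),
            phase_h=float(params[3 + 3 * j]),
            amplitude_ci_halfwidth=float(ci[j]),
        )
        for j in range(n_comp)
    ]
    diagnostics = FitDiagnostics(
        c0=float(params[0]),
        rss=rss,
        n_points=len(y),
        n_params=len(params),
        converged=converged,
        rss_trajectory=traj,
    )
    return components, diagnostics


def rae(component: CosineComponent) -> float:
    """Relative amplitude error: CI half-width over amplitude, capped at 1."""
    if component.amplitude <= 0:
        return 1.0
    if not np.isfinite(component.amplitude_ci_halfwidth):
        return 1.0
    return float(min(component.amplitude_ci_halfwidth / component.amplitude, 1.0))


def estimate_frp(trace: NormalizedTrace, config: RhythmConfig = RhythmConfig()) -> FRPEstimate:
    """Estimate the free-running period of one normalized replicate trace.

    Restricts to the analysis window, runs the seeded multicomponent fit,
    and reports the circadian component (largest amplitude with period
    inside the circadian range).  With no circadian component the estimate
    carries a NaN period and RAE 1.
    """
    lo, hi = config.analysis_window_h
    if trace.times_h[0] > lo or trace.times_h[-1] < hi:
        raise ValueError(
            f"trace {trace.strain_id}/{trace.replicate_id} spans "
            f"[{trace.times_h[0]:g}, {trace.times_h[-1]:g}] h, "
            f"not the analysis window [{lo:g}, {hi:g}] h"
        )
    sel = (trace.times_h >= lo - 1e-9) & (trace.times_h <= hi + 1e-9)
    t, y = trace.times_h[sel], trace.values[sel]
    components, diag = fit_multicomponent_cosine(t, y, config=config)
    circ = [
        c for c in components
        if config.circadian_range_h[0] <= c.tau_h <= config.circadian_range_h[1]
    ]
    if not circ:
        return FRPEstimate(
            strain_id=trace.strain_id,
            replicate_id=trace.replicate_id,
            tau_h=float("nan"),
            rae=1.0,
            amplitude=float("nan"),
            phase_h=float("nan"),
            n_components_fitted=len(components),
            rss=diag.rss,
            converged=diag.converged,
        )
    best = max(circ, key=lambda c: c.amplitude)
    return FRPEstimate(
        strain_id=trace.strain_id,
        replicate_id=trace.replicate_id,
        tau_h=best.tau_h,
        rae=rae(best),
        amplitude=best.amplitude,
        phase_h=best.phase_h,
        n_components_fitted=len(components),
        rss=diag.rss,
        converged=diag.converged,
    )


def aggregate_replicates(
    estimates: list[FRPEstimate],
    config: RhythmConfig = RhythmConfig(),
    first_peaks_h: list[float] | None = None,
) -> StrainRhythm:
    """Per-strain mean/SD of replicate periods, mean RAE, exclusion flag.

    A strain is excluded when any replicate lacks a circadian component,
    when the mean RAE exceeds the threshold, or when the sample SD of the
    replicate periods exceeds the threshold (the latter two toggleable in
    the config).
    """
    if not estimates:
        raise ValueError("no replicate estimates to aggregate")
    strain_id = estimates[0].strain_id
    taus = np.array([e.tau_h for e in estimates])
    raes = np.array([e.rae for e in estimates])
    mean_rae = float(raes.mean())
    reasons = []
    if np.any(~np.isfinite(taus)):
        mean_frp = float("nan")
        sd_frp = float("nan")
        reasons.append("no_circadian_component")
    else:
        mean_frp = float(taus.mean())
        sd_frp = float(taus.std(ddof=1)) if len(taus) > 1 else float("nan")
        if config.exclude_on_rae and mean_rae > config.rae_threshold:
            reasons.append("rae")
        if (config.exclude_on_sd and np.isfinite(sd_frp)
                and sd_frp > config.sd_frp_threshold_h):
            reasons.append("sd_frp")
    first_peak_mean = float("nan")
    if first_peaks_h is not None:
        fp = np.asarray(first_peaks_h, dtype=float)
        if np.any(np.isfinite(fp)):
            first_peak_mean = float(np.nanmean(fp))
    return StrainRhythm(
        strain_id=strain_id,
        estimates=list(estimates),
        mean_frp_h=mean_frp,
        sd_frp_h=sd_frp,
        mean_rae=mean_rae,
        excluded=bool(reasons),
        exclusion_reason="+".join(reasons),
        first_peak_mean_h=first_peak_mean,
    )
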