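"""Synthetic luminescence traces, flowering assays, and strain panels.

The generators emulate the experimental design the analysis modules are
built for: duckweed fronds carrying a morning-phased luciferase reporter are
entrained to long days (15 h light / 9 h dark), released into constant
light (LL) at the end of the last photoperiod, and sampled every 20 min;
flowering of short-day strains is assayed over a grid of day lengths and
scored as flowering fronds out of total fronds; a strain panel programs a
linear dependence of true critical day length (CDL) on the free-running
period (tau) so that recovery of the association can be scored against
ground truth.

Signal model for a trace::

    y(t) = exp(g t) * [M + A D(t) cos(theta(t))] + eps_t

with mesor M, amplitude A, exponential growth g, Gaussian noise eps, and a
damping envelope D(t) that is 1 during entrainment and decays at rate
``damping_per_h`` in LL.  The phase theta is continuous, advancing at
2*pi/24 per hour while entrained (anchored so a cosine peak falls
``entrained_peak_offset_h`` after each lights-on) and at 2*pi/tau after
release -- i.e. the entrained phase carries into free run with no jump, so
the first LL peak comes later in long-tau strains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from lemnaclock.preprocess import LuminescenceTrace
from lemnaclock.cdl import FloweringAssay

__all__ = [
    "DEFAULT_DAY_LENGTH_GRID",
    "TraceSimSpec",
    "PanelSimSpec",
    "simulate_luminescence",
    "simulate_flowering_assay",
    "simulate_strain_panel",
]

#: day-length grid (hours) of the reference flowering protocol
DEFAULT_DAY_LENGTH_GRID: tuple[float, ...] = (
    9.0, 11.0, 11.5, 12.0, 12.5, 13.0, 13.5, 14.0, 14.5, 15.0,
)


@dataclass
class TraceSimSpec:
    """Parameters of one simulated luminescence trace.

    Defaults reproduce the reference monitoring protocol: two days of 15L9D
    entrainment, 132 h of data after the nominal entrainment block, 20-min
    sampling, a morning peak 2 h after lights-on, and signal-to-noise
    (amplitude / noise SD) of 5.
    """

    tau_h: float = 24.0
    entrain_photoperiod_h: float = 15.0
    entrain_days: int = 2
    ll_duration_h: float = 132.0
    sampling_interval_h: float = 1.0 / 3.0
    entrained_peak_offset_h: float = 2.0
    amplitude: float = 50.0
    mesor: float = 100.0
    growth_rate_per_h: float = 0.005
    damping_per_h: float = 0.005
    noise_sd: float = 10.0
    seed: int = 0
    strain_id: str = "sim"
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        for name in (
            "tau_h", "entrain_photoperiod_h", "ll_duration_h",
            "sampling_interval_h", "entrained_peak_offset_h", "amplitude",
            "mesor", "growth_rate_per_h", "damping_per_h", "noise_sd",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite parameter: {name}")
        if self.sampling_interval_h <= 0:
            raise ValueError("sampling_interval_h must be positive")
        if self.tau_h <= 0:
            raise ValueError("tau_h must be positive")
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise_sd must be non-negative")
        if self.entrain_days < 1 or self.ll_duration_h < 0:
            raise ValueError("negative or empty durations")
        if not (0 < self.entrain_photoperiod_h < 24):
            raise ValueError("entrain_photoperiod_h must be in (0, 24)")

    @property
    def ll_start_h(self) -> float:
        """Release into LL: lights stay on at the end of the last photoperiod."""
        return 24.0 * (self.entrain_days - 1) + self.entrain_photoperiod_h

    @property
    def total_duration_h(self) -> float:
        return 24.0 * self.entrain_days + self.ll_duration_h


@dataclass
class PanelSimSpec:
    """A strain panel with a programmed linear tau -> CDL relationship.

    ``tau_i ~ N(tau_mean, tau_sd)``; ``true_cdl_i = cdl_intercept +
    cdl_slope * tau_i + N(0, cdl_noise_sd)``.  Optional measurement noise
    (``frp_meas_sd_h``, ``cdl_meas_sd_h``) produces observed phenotypes with
    errors in both variables, the setting Deming regression is built for.
    """

    n_strains: int = 72
    tau_mean_h: float = 24.5
    tau_sd_h: float = 1.5
    cdl_intercept_h: float = 25.25
    cdl_slope_per_h: float = -0.5
    cdl_noise_sd_h: float = 0.0
    frp_meas_sd_h: float = 0.0
    cdl_meas_sd_h: float = 0.0
    latitude_range: tuple[float, float] = (31.5, 43.8)
    n_populations: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 2:
            raise ValueError("n_strains must be at least 2")
        if min(self.tau_sd_h, self.cdl_noise_sd_h,
               self.frp_meas_sd_h, self.cdl_meas_sd_h) < 0:
            raise ValueError("noise SDs must be non-negative")


def simulate_luminescence(spec: TraceSimSpec) -> LuminescenceTrace:
    """Simulate one reporter trace; same seed gives an identical trace."""
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.total_duration_h + spec.sampling_interval_h / 2,
                  spec.sampling_interval_h)
    t_ll = spec.ll_start_h
    # phase continuous at release: entrained rate 2*pi/24, free-running 2*pi/tau
    theta = np.where(
        t <= t_ll,
        2.0 * np.pi * (t - spec.entrained_peak_offset_h) / 24.0,
        2.0 * np.pi * (t_ll - spec.entrained_peak_offset_h) / 24.0
        + 2.0 * np.pi * (t - t_ll) / spec.tau_h,
    )
    damping = np.where(t <= t_ll, 1.0, np.exp(-spec.damping_per_h * np.maximum(t - t_ll, 0.0)))
    clean = np.exp(spec.growth_rate_per_h * t) * (
        spec.mesor + spec.amplitude * damping * np.cos(theta)
    )
    y = clean + rng.normal(0.0, spec.noise_sd, size=t.shape) if spec.noise_sd > 0 else clean
    return LuminescenceTrace(
        strain_id=spec.strain_id,
        replicate_id=spec.replicate_id,
        times_h=t,
        values=y,
        ll_start_h=t_ll,
        entrain_photoperiod_h=spec.entrain_photoperiod_h,
    )


def flowering_probability(
    day_length_h: np.ndarray | float,
    true_cdl_h: float,
    fmax_pct: float = 100.0,
    transition_width_h: float = 1.0,
) -> np.ndarray | float:
    """Programmed flowering probability: a symmetric linear ramp.

    Full response (fmax) for day lengths below ``true_cdl_h - w/2``, zero
    above ``true_cdl_h + w/2``, linear in between, so the 50 %-of-Fmax day
    length equals ``true_cdl_h`` by construction.
    """
    dl = np.asarray(day_length_h, dtype=float)
    w = transition_width_h
    ramp = np.clip((true_cdl_h + w / 2.0 - dl) / w, 0.0, 1.0)
    return (fmax_pct / 100.0) * ramp


def simulate_flowering_assay(
    true_cdl_h: float,
    fmax_pct: float = 100.0,
    transition_width_h: float = 1.0,
    day_lengths: tuple[float, ...] = DEFAULT_DAY_LENGTH_GRID,
    n_fronds_per_well: int = 20,
    n_replicates: int = 2,
    seed: int = 0,
    strain_id: str = "sim",
) -> FloweringAssay:
    """Binomial frond counts over a day-length grid with a known CDL."""
    if not np.isfinite(true_cdl_h):
        raise ValueError("true_cdl_h must be finite")
    if not (0 < fmax_pct <= 100):
        raise ValueError("fmax_pct must be in (0, 100]")
    if transition_width_h <= 0:
        raise ValueError("transition_width_h must be positive")
    if n_fronds_per_well < 1:
        raise ValueError("n_fronds_per_well must be at least 1")
    if len(day_lengths) == 0:
        raise ValueError("day_lengths must be non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    for dl in day_lengths:
        p = float(flowering_probability(dl, true_cdl_h, fmax_pct, transition_width_h))
        for rep in range(1, n_replicates + 1):
            k = int(rng.binomial(n_fronds_per_well, p))
            rows.append((dl, f"r{rep}", k, n_fronds_per_well))
    records = pd.DataFrame(
        rows, columns=["day_length_h", "replicate_id", "n_flowering", "n_total"]
    )
    return FloweringAssay(strain_id=strain_id, records=records)


def simulate_strain_panel(spec: PanelSimSpec) -> pd.DataFrame:
    """Ground-truth table plus per-strain simulation specs for a panel.

    Returns a DataFrame with one row per strain: ids, population and
    latitude, true tau and true CDL, observed (measurement-noised) tau and
    CDL, and attached ``trace_spec`` objects so full traces can be simulated
    downstream when needed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_strains
    tau = rng.normal(spec.tau_mean_h, spec.tau_sd_h, size=n)
    true_cdl = (
        spec.cdl_intercept_h
        + spec.cdl_slope_per_h * tau
        + (rng.normal(0.0, spec.cdl_noise_sd_h, size=n) if spec.cdl_noise_sd_h > 0 else 0.0)
    )
    obs_tau = tau + (rng.normal(0.0, spec.frp_meas_sd_h, size=n) if spec.frp_meas_sd_h > 0 else 0.0)
    obs_cdl = true_cdl + (rng.normal(0.0, spec.cdl_meas_sd_h, size=n) if spec.cdl_meas_sd_h > 0 else 0.0)
    pop = np.arange(n) % spec.n_populations
    lat_lo, lat_hi = spec.latitude_range
    latitudes = lat_lo + (lat_hi - lat_lo) * pop / max(spec.n_populations - 1, 1)
    trace_seeds = rng.integers(0, 2**31 - 1, size=n)
    df = pd.DataFrame(
        {
            "strain_id": [f"S{i:03d}" for i in range(n)],
            "population_id": [f"P{p:02d}" for p in pop],
            "latitude_deg": latitudes,
            "true_tau_h": tau,
            "true_cdl_h": true_cdl,
            "obs_tau_h": obs_tau,
            "obs_cdl_h": obs_cdl,
        }
    )
    df["trace_spec"] = [
        TraceSimSpec(tau_h=float(tau[i]), seed=int(trace_seeds[i]),
                     strain_id=f"S{i:03d}")
        for i in range(n)
    ]
    return df
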