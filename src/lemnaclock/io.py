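"""Delimited-text readers/writers and the end-to-end analysis pipeline.

All tabular I/O is plain comma-separated UTF-8 text.  Luminescence tables
are long format (one row per sample) with columns ``strain, replicate,
time_h, signal, ll_start_h`` and an optional ``entrain_photoperiod_h``;
flowering tables carry ``strain, day_length_h, replicate, n_flowering,
n_total``.  Readers validate rather than coerce: a duplicated or missing
timestamp, a negative signal, or a flowering count above the frond total is
an error naming the offending strain/replicate or row.  Writers prepend
``#``-comment header lines recording the seed and a configuration hash so a
result table is traceable to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from lemnaclock.cdl import FloweringAssay, estimate_cdl, pooled_rates
from lemnaclock.fftnlls import RhythmConfig, aggregate_replicates, estimate_frp
from lemnaclock.gate import fit_gate_model
from lemnaclock.peaks import detect_peaks, first_peak_in_ll
from lemnaclock.preprocess import LuminescenceTrace, moving_average_detrend, preprocess_trace
from lemnaclock.stats import panel_association

logger = logging.getLogger("lemnaclock")

__all__ = [
    "read_luminescence_table",
    "write_luminescence_table",
    "read_flowering_table",
    "write_flowering_table",
    "write_table",
    "PipelineResult",
    "run_rhythm_stage",
    "run_cdl_stage",
    "run_pipeline",
]

_LUM_COLUMNS = ["strain", "replicate", "time_h", "signal", "ll_start_h"]
_FLW_COLUMNS = ["strain", "day_length_h", "replicate", "n_flowering", "n_total"]


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_luminescence_table(path: str | Path) -> list[LuminescenceTrace]:
    """One LuminescenceTrace per (strain, replicate), sorted and validated."""
    df = _read_csv(path, _LUM_COLUMNS)
    if (df["signal"] < 0).any():
        row = int(df.index[df["signal"] < 0][0])
        raise ValueError(f"{path}: negative signal at row {row}")
    traces = []
    for (strain, rep), g in df.groupby(["strain", "replicate"], sort=True):
        g = g.sort_values("time_h")
        t = g["time_h"].to_numpy(dtype=float)
        dup = np.nonzero(np.diff(t) == 0)[0]
        if dup.size:
            raise ValueError(
                f"{path}: duplicated timestamp t={t[dup[0]]:g} h "
                f"for {strain}/{rep}"
            )
        photoperiod = (
            float(g["entrain_photoperiod_h"].iloc[0])
            if "entrain_photoperiod_h" in g.columns
            else 15.0
        )
        try:
            traces.append(
                LuminescenceTrace(
                    strain_id=str(strain),
                    replicate_id=str(rep),
                    times_h=t,
                    values=g["signal"].to_numpy(dtype=float),
                    ll_start_h=float(g["ll_start_h"].iloc[0]),
                    entrain_photoperiod_h=photoperiod,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    return traces


def write_luminescence_table(
    traces: list[LuminescenceTrace], path: str | Path, seed: int | None = None
) -> None:
    frames = [
        pd.DataFrame(
            {
                "strain": tr.strain_id,
                "replicate": tr.replicate_id,
                "time_h": tr.times_h,
                "signal": tr.values,
                "ll_start_h": tr.ll_start_h,
                "entrain_photoperiod_h": tr.entrain_photoperiod_h,
            }
        )
        for tr in traces
    ]
    write_table(pd.concat(frames, ignore_index=True), path, seed=seed)


def read_flowering_table(path: str | Path) -> list[FloweringAssay]:
    """One validated FloweringAssay per strain; empty file gives []."""
    try:
        df = _read_csv(path, _FLW_COLUMNS)
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty flowering table", path)
        return []
    if df.empty:
        logger.warning("%s: empty flowering table", path)
        return []
    bad = df["n_flowering"] > df["n_total"]
    if bad.any():
        raise ValueError(
            f"{path}: n_flowering > n_total at row {int(df.index[bad][0])}"
        )
    assays = []
    for strain, g in df.groupby("strain", sort=True):
        assays.append(
            FloweringAssay(
                strain_id=str(strain),
                records=g.rename(columns={"replicate": "replicate_id"})[
                    ["day_length_h", "replicate_id", "n_flowering", "n_total"]
                ].reset_index(drop=True),
            )
        )
    return assays


def write_flowering_table(
    assays: list[FloweringAssay], path: str | Path, seed: int | None = None
) -> None:
    frames = []
    for assay in assays:
        g = assay.records.rename(columns={"replicate_id": "replicate"}).copy()
        g.insert(0, "strain", assay.strain_id)
        frames.append(g)
    write_table(pd.concat(frames, ignore_index=True), path, seed=seed)


def _config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(repr(obj), sort_keys=True).encode()
    ).hexdigest()[:12]


def write_table(
    df: pd.DataFrame, path: str | Path, seed: int | None = None, config=None
) -> None:
    """CSV with ``#`` header lines recording seed and config hash."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        if config is not None:
            fh.write(f"# config_hash={_config_hash(config)}\n")
        df.to_csv(fh, index=False)


@dataclass
class PipelineResult:
    """Bundle of result tables from the end-to-end analysis."""

    replicate_rhythms: pd.DataFrame
    strain_rhythms: pd.DataFrame
    cdl_table: pd.DataFrame
    strain_records: pd.DataFrame
    association: pd.DataFrame | None = None
    gate_model: dict | None = None


def run_rhythm_stage(
    traces: list[LuminescenceTrace],
    config: RhythmConfig = RhythmConfig(),
    peaks_on: str = "detrended",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Traces -> per-replicate FRP/RAE table and per-strain aggregate table.

    Peak times for the first-LL-peak phenotype are measured on the
    detrended trace by default (``peaks_on`` in {"detrended", "raw"}).
    """
    rep_rows = []
    by_strain: dict[str, list] = {}
    peaks_by_strain: dict[str, list[float]] = {}
    for trace in traces:
        peak_source = (
            moving_average_detrend(trace) if peaks_on == "detrended" else trace
        )
        fp = first_peak_in_ll(detect_peaks(peak_source), peak_source)
        est = estimate_frp(preprocess_trace(trace), config)
        rep_rows.append(
            {
                "strain": est.strain_id,
                "replicate": est.replicate_id,
                "tau_h": est.tau_h,
                "rae": est.rae,
                "amplitude": est.amplitude,
                "phase_h": est.phase_h,
                "first_peak_h": fp,
                "n_components": est.n_components_fitted,
                "converged": est.converged,
            }
        )
        by_strain.setdefault(est.strain_id, []).append(est)
        peaks_by_strain.setdefault(est.strain_id, []).append(fp)
    strain_rows = []
    for strain_id, ests in by_strain.items():
        agg = aggregate_replicates(ests, config, peaks_by_strain[strain_id])
        if agg.excluded:
            logger.info("strain %s excluded (%s)", strain_id, agg.exclusion_reason)
        strain_rows.append(
            {
                "strain": strain_id,
                "n_replicates": len(ests),
                "mean_frp_h": agg.mean_frp_h,
                "sd_frp_h": agg.sd_frp_h,
                "mean_rae": agg.mean_rae,
                "first_peak_h": agg.first_peak_mean_h,
                "excluded": agg.excluded,
                "reason": agg.exclusion_reason,
            }
        )
    return pd.DataFrame(rep_rows), pd.DataFrame(strain_rows)


def run_cdl_stage(assays: list[FloweringAssay], mode: str = "pool") -> pd.DataFrame:
    """Flowering assays -> per-strain CDL table with censoring flags."""
    rows = []
    for assay in assays:
        res = estimate_cdl(pooled_rates(assay, mode=mode), strain_id=assay.strain_id)
        rows.append(
            {
                "strain": res.strain_id,
                "fmax_pct": res.fmax_pct,
                "cdl_h": res.cdl_h,
                "censored": res.censored,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    traces: list[LuminescenceTrace],
    assays: list[FloweringAssay],
    rhythm_config: RhythmConfig = RhythmConfig(),
    cdl_mode: str = "pool",
    delta: float = 1.0,
    metadata: pd.DataFrame | None = None,
    min_strains_for_association: int = 3,
) -> PipelineResult:
    """Run rhythm quantification, CDL estimation, and the association stage.

    ``metadata`` (optional) is merged on ``strain`` to carry population and
    latitude columns into the strain records.  The association report and
    gate-model fit are skipped (None) when fewer than
    ``min_strains_for_association`` usable strains remain.
    """
    rep_df, strain_df = run_rhythm_stage(traces, rhythm_config)
    cdl_df = run_cdl_stage(assays, mode=cdl_mode)
    records = strain_df.merge(cdl_df, on="strain", how="outer")
    if metadata is not None:
        records = records.merge(metadata, on="strain", how="left")
    records["excluded"] = records["excluded"].fillna(True).astype(bool)

    association = None
    gate = None
    usable = records[~records["excluded"] & np.isfinite(records["cdl_h"])]
    if len(usable) >= min_strains_for_association:
        association = panel_association(records, delta=delta)
        model, summary = fit_gate_model(
            usable["mean_frp_h"], usable["cdl_h"], delta=delta
        )
        gate = {"d0_h": model.d0_h, "k": model.k,
                "consistent": model.consistent, **summary}
    else:
        logger.warning(
            "association stage skipped: only %d usable strains", len(usable)
        )
    return PipelineResult(
        replicate_rhythms=rep_df,
        strain_rhythms=strain_df,
        cdl_table=cdl_df,
        strain_records=records,
        association=association,
        gate_model=gate,
    )
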