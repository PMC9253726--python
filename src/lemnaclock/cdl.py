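"""Critical day length (CDL) from photoperiodic flowering assays.

A short-day strain flowers when days are shorter than its critical day
length.  Frond counts (flowering / total) per tested day length are pooled
across replicates into percentage rates; the piecewise-linear function
through the pooled rates is read off at half the maximum rate (Fmax/2), and
the day length of the first downward crossing at or after the maximum is
the CDL.  Responses that never fall to Fmax/2 within the tested grid are
censored rather than extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FloweringAssay",
    "CDLResult",
    "pooled_rates",
    "estimate_cdl",
    "critical_night_length",
]


@dataclass
class FloweringAssay:
    """Frond counts by day length for one strain.

    ``records`` columns: ``day_length_h``, ``replicate_id``,
    ``n_flowering``, ``n_total``.
    """

    strain_id: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"day_length_h", "replicate_id", "n_flowering", "n_total"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"assay records missing columns: {sorted(missing)}")
        r = self.records
        if (r["n_total"] < 1).any():
            raise ValueError(f"assay {self.strain_id}: n_total must be >= 1")
        bad = r["n_flowering"].lt(0) | r["n_flowering"].gt(r["n_total"])
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise ValueError(
                f"assay {self.strain_id}, record {row}: "
                "n_flowering outside [0, n_total]"
            )


@dataclass
class CDLResult:
    """CDL estimate for one strain.

    ``cdl_h`` is NaN when censored or undefined; ``censored`` is ``">"``
    (response never falls to Fmax/2 within the grid), ``"<"`` (already
    below Fmax/2 at the shortest tested day length with no maximum before
    it), or ``""`` for a proper interior estimate.  ``crossing_segment``
    brackets the interpolated crossing.
    """

    strain_id: str
    fmax_pct: float
    cdl_h: float
    censored: str = ""
    crossing_segment: tuple[float, float] | None = None
    rates_by_daylength: pd.Series = field(default=None, repr=False)

    @property
    def is_censored(self) -> bool:
        return self.censored != ""


def pooled_rates(assay: FloweringAssay, mode: str = "pool") -> pd.Series:
    """Flowering rate (%) per day length.

    ``mode="pool"`` (default) pools counts across replicates,
    100 * sum(n_flowering) / sum(n_total), weighting wells by frond number;
    ``mode="average"`` averages the per-replicate percentages instead.
    """
    g = assay.records.groupby("day_length_h")
    if mode == "pool":
        rates = 100.0 * g["n_flowering"].sum() / g["n_total"].sum()
    elif mode == "average":
        per_rep = 100.0 * assay.records["n_flowering"] / assay.records["n_total"]
        rates = per_rep.groupby(assay.records["day_length_h"]).mean()
    else:
        raise ValueError(f"unknown pooling mode: {mode!r}")
    return rates.sort_index()


def estimate_cdl(rates: pd.Series, strain_id: str = "") -> CDLResult:
    """CDL = day length of the first downward crossing of Fmax/2 after Fmax.

    The flowering response is taken as the piecewise-linear interpolation of
    the pooled rates over the sorted tested day lengths.  Non-monotone
    responses can cross the half-maximum more than once; the first crossing
    at or after the day length attaining the maximum is used, because in a
    short-day plant the descending limb is the photoperiodic boundary.
    """
    rates = rates.sort_index()
    if len(rates) < 2:
        raise ValueError("need at least 2 distinct day lengths")
    dl = rates.index.to_numpy(dtype=float)
    r = rates.to_numpy(dtype=float)
    fmax = float(r.max())
    if fmax == 0.0:
        return CDLResult(strain_id, 0.0, np.nan, censored="undefined",
                         rates_by_daylength=rates)
    half = fmax / 2.0
    i_max = int(np.argmax(r))
    for i in range(i_max, len(r) - 1):
        if r[i] > half >= r[i + 1]:
            if r[i + 1] == half:
                cdl = float(dl[i + 1])
            else:
                cdl = float(dl[i] + (dl[i + 1] - dl[i]) * (r[i] - half) / (r[i] - r[i + 1]))
            return CDLResult(strain_id, fmax, cdl,
                             crossing_segment=(float(dl[i]), float(dl[i + 1])),
                             rates_by_daylength=rates)
    return CDLResult(strain_id, fmax, np.nan, censored=">",
                     rates_by_daylength=rates)


def critical_night_length(cdl_h: float) -> float:
    """Critical night length, 24 − CDL (hours)."""
    return 24.0 - cdl_h
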