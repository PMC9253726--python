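"""Association statistics: Pearson tests, Deming regression, pairwise
Wilcoxon rank-sum tests with Holm adjustment, and compact letter displays.

Deming regression fits a line when both variables carry measurement error
(here the free-running period and the critical day length are both
estimated phenotypes on an hours scale), avoiding the attenuation toward
zero that ordinary least squares suffers.  Pairwise group comparisons use
the two-sided Wilcoxon rank-sum test -- exact by enumeration of the
rank-sum distribution for small tie-free samples, a tie-corrected normal
approximation with continuity correction otherwise -- with Holm's
step-down multiplicity adjustment, summarized as a compact letter display
(groups sharing a letter are not significantly different).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DemingFit",
    "PairwiseResult",
    "pearson_test",
    "deming_fit",
    "wilcoxon_rank_sum",
    "holm_adjust",
    "pairwise_wilcoxon",
    "compact_letters",
    "panel_association",
]


@dataclass(frozen=True)
class DemingFit:
    """Errors-in-variables line fit with error-variance ratio delta."""

    slope: float
    intercept: float
    delta: float
    degenerate: bool = False


@dataclass
class PairwiseResult:
    """All pairwise two-sided Wilcoxon tests among labelled groups."""

    labels: list[str]
    p_raw: pd.DataFrame
    p_adjusted: pd.DataFrame
    letters: dict[str, str]
    alpha: float


def pearson_test(x, y) -> tuple[float, float, int]:
    """Pearson r with the two-sided t-test p-value and the pair count.

    Pairs with a missing value in either variable are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), n


def deming_fit(x, y, delta: float = 1.0) -> DemingFit:
    """Deming regression of y on x with error-variance ratio ``delta``.

    delta = var(y errors) / var(x errors); delta = 1 is orthogonal
    regression.  slope = (s_yy - d*s_xx + sqrt((s_yy - d*s_xx)^2 +
    4*d*s_xy^2)) / (2*s_xy), sharing the sign of s_xy; intercept puts the
    line through the centroid.  s_xy = 0 is degenerate (no linear
    association to orient the line) and is flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if delta <= 0:
        raise ValueError("delta must be positive")
    s_xx = np.var(x, ddof=1)
    s_yy = np.var(y, ddof=1)
    s_xy = np.cov(x, y, ddof=1)[0, 1]
    if s_xy == 0:
        return DemingFit(float("nan"), float("nan"), delta, degenerate=True)
    disc = s_yy - delta * s_xx
    slope = (disc + np.sqrt(disc**2 + 4.0 * delta * s_xy**2)) / (2.0 * s_xy)
    intercept = y.mean() - slope * x.mean()
    return DemingFit(float(slope), float(intercept), delta)


@lru_cache(maxsize=None)
def _ranksum_counts(n_a: int, n_total: int) -> tuple[np.ndarray, int]:
    """Distribution of the rank sum of a size-``n_a`` subset of ranks 1..n.

    counts[w] = number of n_a-subsets of {1..n_total} summing to w, by the
    classic subset-sum recurrence.  Returns (counts, total = C(n, n_a)).
    """
    max_sum = n_total * (n_total + 1) // 2
    # dp[k][w]: subsets of size k with rank sum w
    dp = np.zeros((n_a + 1, max_sum + 1), dtype=np.int64)
    dp[0, 0] = 1
    for rank in range(1, n_total + 1):
        for k in range(min(rank, n_a), 0, -1):
            dp[k, rank:] += dp[k - 1, : max_sum + 1 - rank]
    counts = dp[n_a]
    return counts, int(counts.sum())


def wilcoxon_rank_sum(a, b, exact_max_n: int = 12) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact when the combined sample size is at most ``exact_max_n`` and the
    data are tie-free: p = min(1, 2*min(P(W <= w), P(W >= w))) over the
    exact null distribution of the rank sum W of the first group.
    Otherwise a normal approximation with tie-corrected variance and a 0.5
    continuity correction is used.  Identical constant samples give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    ranks = sps.rankdata(pooled)
    w = float(ranks[:n_a].sum())
    has_ties = len(np.unique(pooled)) < n

    if n <= exact_max_n and not has_ties:
        counts, total = _ranksum_counts(n_a, n)
        wi = int(round(w))
        p_le = counts[: wi + 1].sum() / total
        p_ge = counts[wi:].sum() / total
        return float(min(1.0, 2.0 * min(p_le, p_ge)))

    mean_w = n_a * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var_w = n_a * n_b / 12.0 * (n + 1 - tie_term)
    if var_w == 0:
        return 1.0
    z = (abs(w - mean_w) - 0.5) / np.sqrt(var_w)  # continuity correction
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * sps.norm.sf(z)))


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def pairwise_wilcoxon(
    groups: dict[str, np.ndarray],
    alpha: float = 0.05,
) -> PairwiseResult:
    """All pairwise rank-sum tests with Holm adjustment and letters."""
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    pairs = [(i, j) for i in range(len(labels)) for j in range(i + 1, len(labels))]
    raw = [wilcoxon_rank_sum(groups[labels[i]], groups[labels[j]]) for i, j in pairs]
    adj = holm_adjust(raw)
    p_raw = pd.DataFrame(np.ones((len(labels), len(labels))), index=labels, columns=labels)
    p_adj = p_raw.copy()
    for (i, j), pr, pa in zip(pairs, raw, adj):
        p_raw.iloc[i, j] = p_raw.iloc[j, i] = pr
        p_adj.iloc[i, j] = p_adj.iloc[j, i] = pa
    letters = compact_letters(p_adj, alpha=alpha)
    return PairwiseResult(labels, p_raw, p_adj, letters, alpha)


def compact_letters(p_adjusted: pd.DataFrame, alpha: float = 0.05) -> dict[str, str]:
    """Compact letter display by the insert-and-absorb algorithm.

    Two groups share a letter iff their adjusted p-value is >= alpha.
    Deterministic given the row order of ``p_adjusted``; letter columns are
    ordered by their first member.
    """
    labels = list(p_adjusted.index)
    k = len(labels)
    pmat = p_adjusted.to_numpy(dtype=float)
    if not np.allclose(pmat, pmat.T, equal_nan=True):
        raise ValueError("adjusted p matrix must be symmetric")
    columns: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if pmat[i, j] < alpha:
                for col in [c for c in columns if i in c and j in c]:
                    columns.remove(col)
                    c1, c2 = col - {j}, col - {i}
                    # absorb: drop any new column contained in an existing one
                    for c_new in (c1, c2):
                        if not any(c_new <= other for other in columns):
                            columns.append(c_new)
    columns = [c for c in columns if c]
    # final absorb pass: a column contained in another is redundant
    columns = [
        c for idx, c in enumerate(columns)
        if not any(c < other or (c == other and idx2 < idx)
                   for idx2, other in enumerate(columns) if idx2 != idx)
    ]
    columns.sort(key=lambda c: (min(c), sorted(c)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lab: "" for lab in labels}
    for letter_idx, col in enumerate(columns):
        letter = (
            alphabet[letter_idx]
            if letter_idx < 26
            else alphabet[letter_idx // 26 - 1] + alphabet[letter_idx % 26]
        )
        for i in sorted(col):
            out[labels[i]] += letter
    return out


def panel_association(
    records: pd.DataFrame,
    delta: float = 1.0,
    frp_col: str = "mean_frp_h",
    peak_col: str = "first_peak_h",
    cdl_col: str = "cdl_h",
    excluded_col: str = "excluded",
) -> pd.DataFrame:
    """Pearson and Deming summaries for the three phenotype pairings.

    Analyses involving the free-running period drop strains flagged as
    excluded (unstable rhythms); the peak-time vs CDL analysis keeps every
    strain with both phenotypes.  Censored or missing CDLs drop out via the
    finiteness filter inside each test.
    """
    df = records.copy()
    if excluded_col in df.columns:
        usable = df[~df[excluded_col].astype(bool)]
    else:
        usable = df
    pairings = [
        ("frp_vs_peak", frp_col, peak_col, usable),
        ("frp_vs_cdl", frp_col, cdl_col, usable),
        ("peak_vs_cdl", peak_col, cdl_col, df),
    ]
    rows = []
    for name, xcol, ycol, source in pairings:
        x = source[xcol].to_numpy(dtype=float)
        y = source[ycol].to_numpy(dtype=float)
        r, p, n = pearson_test(x, y)
        fit = deming_fit(x, y, delta=delta)
        rows.append(
            {
                "pair": name, "x": xcol, "y": ycol, "n": n,
                "pearson_r": r, "pearson_p": p,
                "deming_slope": fit.slope, "deming_intercept": fit.intercept,
                "deming_delta": fit.delta,
            }
        )
    return pd.DataFrame(rows)
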