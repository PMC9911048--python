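"""Per-position two-sample tests between native and WGA signal tables.

This reimplements, at the event-table level, the statistic layer of
Nanodisco-style modification detection: for every genomic position with
sufficient coverage in both samples, a two-sided Mann-Whitney U test and a
Welch t test compare the native signal observations against the WGA
(unmethylated control) observations, and the per-position records are merged
into a genome-wide difference table with the columns
(position, cov_native, cov_wga, mean_diff, u_pvalue, t_pvalue).

U-test conventions (declared once, used everywhere):

* midranks for ties;
* exact two-sided p-value by enumeration when both sample sizes are <= 8
  (a cached no-tie null distribution of U; explicit enumeration of all
  C(n+m, n) label assignments when ties are present), using the
  symmetric-tail form P(|U - nm/2| >= |u_obs - nm/2|);
* otherwise the normal approximation with tie-corrected variance and a 0.5
  continuity correction.

Welch t at zero variance: p = 1 when both groups are constant and equal,
p = machine epsilon when constant and unequal.
"""

from __future__ import annotations

import itertools
import math
import warnings
from functools import lru_cache
from typing import Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import stdtr
from scipy.stats import rankdata

__all__ = [
    "CoverageError",
    "PositionTest",
    "position_test",
    "difference_table",
    "site_min_pvalues",
    "summarize_titration",
]

_EPS = float(np.finfo(float).eps)

#: Columns of a merged difference table.
DIFF_COLUMNS = ("position", "cov_native", "cov_wga", "mean_diff", "u_pvalue", "t_pvalue")


class CoverageError(ValueError):
    """Raised when a per-position test is asked to run on an empty sample."""


class PositionTest(NamedTuple):
    u_pvalue: float
    t_pvalue: float
    mean_diff: float


@lru_cache(maxsize=None)
def _exact_u_counts(n: int, m: int) -> np.ndarray:
    """Null distribution of U for tie-free samples: counts over U = 0..n*m.

    Subset-sum dynamic program over which n of the N = n+m ranks belong to the
    first sample; U = (rank sum) - n(n+1)/2.
    """
    N = n + m
    max_sum = N * (N + 1) // 2
    dp = np.zeros((n + 1, max_sum + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for r in range(1, N + 1):
        for k in range(min(r, n), 0, -1):
            dp[k, r:] += dp[k - 1, :-r] if r > 0 else dp[k - 1]
    lo = n * (n + 1) // 2
    return dp[n, lo : lo + n * m + 1].copy()


def _u_pvalue_exact_ties(ranks: np.ndarray, n: int, u_obs: float) -> float:
    """Exact two-sided p with ties: enumerate all C(N, n) label assignments."""
    N = ranks.size
    center = n * (N - n) / 2.0
    offset = n * (n + 1) / 2.0
    dev_obs = abs(u_obs - center)
    combos = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(N), n)),
        dtype=np.intp,
    ).reshape(-1, n)
    u_all = ranks[combos].sum(axis=1) - offset
    return float(np.mean(np.abs(u_all - center) >= dev_obs - 1e-9))


def _u_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    n, m = x.size, y.size
    N = n + m
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    u = ranks[:n].sum() - n * (n + 1) / 2.0
    center = n * m / 2.0

    if n <= 8 and m <= 8:
        has_ties = np.unique(combined).size < N
        if not has_ties:
            counts = _exact_u_counts(n, m)
            dev = abs(u - center)
            support = np.arange(n * m + 1, dtype=float)
            mask = np.abs(support - center) >= dev - 1e-9
            return float(counts[mask].sum() / counts.sum())
        return _u_pvalue_exact_ties(ranks, n, u)

    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float((tie_counts.astype(float) ** 3 - tie_counts).sum())
    var = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0.0:
        return 1.0
    z = max(abs(u - center) - 0.5, 0.0) / math.sqrt(var)
    return min(1.0, math.erfc(z / math.sqrt(2.0)))


def _welch_pvalue(x: np.ndarray, y: np.ndarray, mean_diff: float) -> float:
    n, m = x.size, y.size
    vx = float(x.var(ddof=1)) if n > 1 else 0.0
    vy = float(y.var(ddof=1)) if m > 1 else 0.0
    se2 = vx / n + vy / m
    if se2 == 0.0:
        return 1.0 if mean_diff == 0.0 else _EPS
    t = mean_diff / math.sqrt(se2)
    denom = 0.0
    if vx > 0.0 and n > 1:
        denom += (vx / n) ** 2 / (n - 1)
    if vy > 0.0 and m > 1:
        denom += (vy / m) ** 2 / (m - 1)
    if denom == 0.0:
        return 1.0 if mean_diff == 0.0 else _EPS
    df = se2**2 / denom
    return float(2.0 * stdtr(df, -abs(t)))


def position_test(
    native_signals: Sequence[float], wga_signals: Sequence[float]
) -> PositionTest:
    """Two-sample tests at one genomic position.

    Returns the two-sided Mann-Whitney U p-value, the Welch t p-value, and
    mean(native) - mean(wga).  Raises :class:`CoverageError` on empty input.
    """
    x = np.asarray(native_signals, dtype=float)
    y = np.asarray(wga_signals, dtype=float)
    if x.size == 0 or y.size == 0:
        raise CoverageError("both samples must have at least one observation")
    mean_diff = float(x.mean() - y.mean())
    return PositionTest(_u_pvalue(x, y), _welch_pvalue(x, y, mean_diff), mean_diff)


def _group_by_position(events: pd.DataFrame):
    pos = events["position"].to_numpy(dtype=np.int64)
    sig = events["signal"].to_numpy(dtype=float)
    order = np.argsort(pos, kind="stable")
    pos, sig = pos[order], sig[order]
    upos, starts, counts = np.unique(pos, return_index=True, return_counts=True)
    return upos, starts, counts, sig


def difference_table(
    native: pd.DataFrame,
    wga: pd.DataFrame,
    min_cov: int = 5,
    positions: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Merge per-position tests into a genome-wide difference table.

    One record per position with coverage >= ``min_cov`` in BOTH samples,
    sorted by position.  ``positions`` optionally restricts the computation
    to a subset of genomic positions.  Disjoint position ranges produce a
    warning and an empty table.
    """
    np_pos, np_start, np_count, np_sig = _group_by_position(native)
    wg_pos, wg_start, wg_count, wg_sig = _group_by_position(wga)

    common, i_nat, i_wga = np.intersect1d(np_pos, wg_pos, return_indices=True)
    if common.size == 0:
        warnings.warn("native and wga event tables cover disjoint positions")
        return pd.DataFrame({c: [] for c in DIFF_COLUMNS}).astype(
            {"position": np.int64, "cov_native": np.int64, "cov_wga": np.int64}
        )
    keep = (np_count[i_nat] >= min_cov) & (wg_count[i_wga] >= min_cov)
    if positions is not None:
        keep &= np.isin(common, np.asarray(positions, dtype=np.int64))
    common, i_nat, i_wga = common[keep], i_nat[keep], i_wga[keep]

    n = common.size
    u_p = np.empty(n)
    t_p = np.empty(n)
    md = np.empty(n)
    for j in range(n):
        a = np_sig[np_start[i_nat[j]] : np_start[i_nat[j]] + np_count[i_nat[j]]]
        b = wg_sig[wg_start[i_wga[j]] : wg_start[i_wga[j]] + wg_count[i_wga[j]]]
        md[j] = a.mean() - b.mean()
        u_p[j] = _u_pvalue(a, b)
        t_p[j] = _welch_pvalue(a, b, md[j])

    return pd.DataFrame(
        {
            "position": common,
            "cov_native": np_count[i_nat],
            "cov_wga": wg_count[i_wga],
            "mean_diff": md,
            "u_pvalue": u_p,
            "t_pvalue": t_p,
        }
    )


def site_min_pvalues(diff: pd.DataFrame, focal_positions: Sequence[int]) -> np.ndarray:
    """Minimum u_pvalue over {focal-1, focal, focal+1} for each focal position.

    Positions absent from the difference table are skipped; a site with none
    of the three positions present gets NaN (the missing-data sentinel).
    """
    lookup = pd.Series(
        diff["u_pvalue"].to_numpy(), index=diff["position"].to_numpy(), dtype=float
    )
    f = np.asarray(focal_positions, dtype=np.int64)
    cols = [lookup.reindex(f + d).to_numpy() for d in (-1, 0, 1)]
    mat = np.column_stack(cols)
    all_nan = np.isnan(mat).all(axis=1)
    out = np.full(f.size, np.nan)
    if (~all_nan).any():
        out[~all_nan] = np.nanmin(mat[~all_nan], axis=1)
    return out


def summarize_titration(
    diff_tables: Mapping[float, pd.DataFrame],
    motif_sites: Mapping[str, Sequence[int]],
) -> pd.DataFrame:
    """Quartile summary of site p-values across an in-silico titration grid.

    ``diff_tables`` maps fraction-of-native-reads to a difference table (the
    grid must include 0 and 1); ``motif_sites`` maps motif name to focal
    positions.  Returns one row per (motif, fraction) with the site count and
    the 25th/50th/75th percentiles of the min-over-±1 site p-values.
    """
    fracs = sorted(diff_tables)
    if not any(abs(f) < 1e-12 for f in fracs) or not any(
        abs(f - 1.0) < 1e-12 for f in fracs
    ):
        raise ValueError("titration fraction grid must include 0 and 1")
    rows = []
    for motif, focals in motif_sites.items():
        for frac in fracs:
            pv = site_min_pvalues(diff_tables[frac], focals)
            pv = pv[np.isfinite(pv)]
            if pv.size == 0:
                rows.append((motif, frac, 0, np.nan, np.nan, np.nan))
                continue
            q25, q50, q75 = np.percentile(pv, [25, 50, 75])
            rows.append((motif, frac, int(pv.size), q25, q50, q75))
    return pd.DataFrame(
        rows, columns=["motif", "fraction_native", "n_sites", "p25", "median", "p75"]
    )
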