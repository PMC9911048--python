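"""Windowed methylation fractions and their correlations across conditions.

The unit of comparison is the fraction of motif sites classified as
methylated within fixed 10-kb genome windows (windows containing no motif
sites are excluded — they would divide by zero).  Condition pairs are
compared by Pearson correlation of window fractions, or by a partial
correlation that first regresses out sequencing-coverage covariates, since
coverage affects the likelihood that a site is detected as modified.  A
long-range scan computes correlations between windows of increasing size at
increasing separations — an autocorrelation-like probe for periodic or
origin/terminus-scale structure in methylation levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import stdtr
from scipy.stats import pearsonr as _scipy_pearsonr
from statsmodels.stats.multitest import multipletests

from .coverage_normalization import CoverageTrack
from .motif_analysis import MotifSite

__all__ = [
    "WindowProfile",
    "CorrelationResult",
    "LongRangeGrid",
    "InsufficientDataError",
    "CollinearityError",
    "window_fractions",
    "normalize_profile",
    "pearson",
    "partial_correlation",
    "pairwise_condition_matrix",
    "long_range_scan",
]


class InsufficientDataError(ValueError):
    """A condition pair shares too few windows to correlate."""


class CollinearityError(ValueError):
    """The covariate design matrix is rank-deficient."""


@dataclass
class WindowProfile:
    """Per-window motif-site counts and methylated fractions for one condition.

    ``table`` columns: start, n_sites, n_methylated, fraction,
    mean_cov_native, mean_cov_wga (coverage columns NaN when no tracks were
    supplied).  ``excluded_windows`` lists the starts of zero-site windows.
    """

    condition: str
    motif: str
    window_size: int
    table: pd.DataFrame
    excluded_windows: list = field(default_factory=list)
    normalized: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    condition_a: str
    condition_b: str
    motif: str
    r: float
    pvalue: float
    covariates: tuple
    n_windows: int


@dataclass
class LongRangeGrid:
    """Correlation of window fractions by (window size, separation)."""

    window_sizes: np.ndarray
    separations: np.ndarray
    r: np.ndarray  # shape (len(window_sizes), len(separations))
    n_pairs: np.ndarray


def _counts_per_window(
    calls: pd.DataFrame,
    sites: Sequence[MotifSite],
    genome_length: int,
    window: int,
):
    n_windows = -(-genome_length // window)
    focal_all = np.array([s.focal_position for s in sites], dtype=np.int64)
    n_sites = np.bincount(focal_all // window, minlength=n_windows)
    meth = calls.loc[calls["methylated"], "focal_position"].to_numpy(dtype=np.int64)
    n_meth = np.bincount(meth // window, minlength=n_windows)
    return n_windows, n_sites, n_meth


def window_fractions(
    calls: pd.DataFrame,
    sites: Sequence[MotifSite],
    genome_length: int,
    window: int = 10_000,
    coverage_native: Optional[CoverageTrack] = None,
    coverage_wga: Optional[CoverageTrack] = None,
    condition: str = "",
    motif: str = "",
) -> WindowProfile:
    """Fraction of motif sites called methylated in each tiling window.

    The denominator is the number of motif sites in the window (all known
    sites, whether or not scorable); the numerator the number of sites called
    methylated.  Windows tile [0, genome_length) with the last window
    possibly short; zero-site windows are excluded from the table.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    n_windows, n_sites, n_meth = _counts_per_window(calls, sites, genome_length, window)
    starts = np.arange(n_windows, dtype=np.int64) * window
    included = n_sites > 0

    def _cov(track: Optional[CoverageTrack]) -> np.ndarray:
        if track is None:
            return np.full(n_windows, np.nan)
        if track.window_size != window or len(track.values) != n_windows:
            raise ValueError("coverage track window grid does not match")
        return np.asarray(track.values, dtype=float)

    table = pd.DataFrame(
        {
            "start": starts[included],
            "n_sites": n_sites[included],
            "n_methylated": n_meth[included],
            "fraction": n_meth[included] / n_sites[included],
            "mean_cov_native": _cov(coverage_native)[included],
            "mean_cov_wga": _cov(coverage_wga)[included],
        }
    )
    return WindowProfile(
        condition=condition,
        motif=motif or (str(calls["motif"].iloc[0]) if len(calls) else ""),
        window_size=window,
        table=table,
        excluded_windows=starts[~included].tolist(),
    )


def normalize_profile(profile: WindowProfile) -> WindowProfile:
    """Divide each window fraction by the genome-wide mean of included windows.

    The normalized fractions have mean exactly 1 and are no longer bounded by
    1 (nor equal to n_methylated / n_sites).
    """
    frac = profile.table["fraction"].to_numpy(dtype=float)
    if frac.size == 0:
        raise ValueError("profile has no included windows")
    mean = frac.mean()
    if mean == 0.0:
        raise ValueError("all window fractions are zero; normalization is degenerate")
    table = profile.table.copy()
    table["fraction"] = frac / mean
    return WindowProfile(
        condition=profile.condition,
        motif=profile.motif,
        window_size=profile.window_size,
        table=table,
        excluded_windows=list(profile.excluded_windows),
        normalized=True,
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("correlation undefined for a zero-variance vector")
    r, p = _scipy_pearsonr(x, y)
    return float(r), float(p)


def partial_correlation(
    x: Sequence[float],
    y: Sequence[float],
    covariates: Sequence[Sequence[float]] = (),
    covariate_names: Optional[Sequence[str]] = None,
) -> tuple[float, float]:
    """Pearson correlation of x and y after regressing out covariates.

    Both vectors are residualized by least squares on an intercept plus the
    covariates; the returned p-value uses n - 2 - k degrees of freedom for k
    covariates.  With no covariates this reduces exactly to :func:`pearson`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    covs = [np.asarray(c, dtype=float) for c in covariates]
    n = x.size
    if y.size != n or any(c.size != n for c in covs):
        raise ValueError("all vectors must have equal length")
    k = len(covs)
    if n <= k + 2:
        raise ValueError("need more observations than covariates + 2")
    names = list(covariate_names) if covariate_names else [f"cov{i}" for i in range(k)]

    design = np.column_stack([np.ones(n)] + covs)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = []
        rank = 1
        cur = design[:, :1]
        for j, c in enumerate(covs):
            trial = np.column_stack([cur, c])
            r2 = np.linalg.matrix_rank(trial)
            if r2 == rank:
                bad.append(names[j])
            else:
                cur, rank = trial, r2
        raise CollinearityError(f"collinear covariates: {', '.join(bad)}")

    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    scale = max(np.abs(x).max(), np.abs(y).max(), 1.0)
    if rx.std() <= 1e-12 * scale or ry.std() <= 1e-12 * scale:
        raise ValueError("correlation undefined: residual variance is zero")
    r = float(np.dot(rx, ry) / (np.linalg.norm(rx) * np.linalg.norm(ry)))
    df = n - 2 - k
    if abs(r) >= 1.0:
        return math.copysign(1.0, r), 0.0
    t = r * math.sqrt(df / (1.0 - r * r))
    p = float(2.0 * stdtr(df, -abs(t)))
    return r, p


def pairwise_condition_matrix(
    profiles: Mapping[str, WindowProfile],
    covariates: str = "coverage",
    adjust: str = "none",
) -> list[CorrelationResult]:
    """All pairwise (partial) correlations between condition profiles.

    Only windows included in BOTH profiles of a pair enter.  With
    ``covariates="coverage"`` the partial correlation controls for each
    condition's native coverage plus the mean WGA coverage (skipped when a
    profile has no coverage tracks); ``covariates="none"`` gives plain
    Pearson.  ``adjust="bh"`` applies Benjamini-Hochberg across the pair
    p-values.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two condition profiles")
    conds = list(profiles)
    motifs = {profiles[c].motif for c in conds}
    if len(motifs) > 1:
        raise ValueError(f"profiles mix motifs: {sorted(motifs)}")
    motif = motifs.pop()
    results = []
    for a, b in combinations(conds, 2):
        ta = profiles[a].table.set_index("start")
        tb = profiles[b].table.set_index("start")
        shared = ta.index.intersection(tb.index)
        if len(shared) < 3:
            raise InsufficientDataError(
                f"conditions {a!r} and {b!r} share only {len(shared)} windows"
            )
        x = ta.loc[shared, "fraction"].to_numpy()
        y = tb.loc[shared, "fraction"].to_numpy()
        cov_vectors = []
        cov_names: list[str] = []
        if covariates == "coverage":
            na = ta.loc[shared, "mean_cov_native"].to_numpy()
            nb = tb.loc[shared, "mean_cov_native"].to_numpy()
            wa = ta.loc[shared, "mean_cov_wga"].to_numpy()
            wb = tb.loc[shared, "mean_cov_wga"].to_numpy()
            for vec, name in (
                (na, f"cov_native_{a}"),
                (nb, f"cov_native_{b}"),
                ((wa + wb) / 2.0, "cov_wga"),
            ):
                if np.isfinite(vec).all() and np.std(vec) > 0:
                    cov_vectors.append(vec)
                    cov_names.append(name)
        elif covariates != "none":
            raise ValueError("covariates must be 'coverage' or 'none'")
        r, p = partial_correlation(x, y, cov_vectors, cov_names)
        results.append(
            CorrelationResult(a, b, motif, r, p, tuple(cov_names), len(shared))
        )
    if adjust == "bh" and results:
        _, padj, *_ = multipletests([r.pvalue for r in results], method="fdr_bh")
        results = [
            CorrelationResult(
                r.condition_a, r.condition_b, r.motif, r.r, float(q), r.covariates, r.n_windows
            )
            for r, q in zip(results, padj)
        ]
    elif adjust not in {"none", "bh"}:
        raise ValueError("adjust must be 'none' or 'bh'")
    return results


def long_range_scan(
    calls: pd.DataFrame,
    sites: Sequence[MotifSite],
    genome_length: int,
    window_sizes: Sequence[int],
    separations: Sequence[int],
) -> LongRangeGrid:
    """Autocorrelation-like scan: r between window fractions at a separation.

    For each window size w the genome is tiled at step w; the cell (w, d)
    correlates fraction(window at x) with fraction(window at x + w + d),
    i.e. d is the gap between the end of the first window and the start of
    the second (d = 0 means adjacent; d = -w is the degenerate self-lag).
    Separations are snapped to the tiling grid.  Zero-site windows are
    dropped pairwise; a cell with fewer than 3 valid pairs is NaN.
    """
    window_sizes = np.asarray(window_sizes, dtype=np.int64)
    separations = np.asarray(separations, dtype=np.int64)
    if (window_sizes <= 0).any():
        raise ValueError("window sizes must be positive")
    if window_sizes.max() > genome_length / 4 or separations.max() > genome_length / 4:
        raise ValueError("window sizes and separations must be <= genome_length / 4")
    r_mat = np.full((window_sizes.size, separations.size), np.nan)
    n_mat = np.zeros((window_sizes.size, separations.size), dtype=np.int64)
    for wi, w in enumerate(window_sizes):
        _, n_sites, n_meth = _counts_per_window(calls, sites, genome_length, int(w))
        frac = np.full(n_sites.size, np.nan)
        inc = n_sites > 0
        frac[inc] = n_meth[inc] / n_sites[inc]
        for di, d in enumerate(separations):
            koff = int(round((w + d) / w))
            if koff < 0:
                continue
            a = frac if koff == 0 else frac[:-koff]
            b = frac if koff == 0 else frac[koff:]
            ok = np.isfinite(a) & np.isfinite(b)
            n_mat[wi, di] = int(ok.sum())
            if ok.sum() < 3:
                continue
            aa, bb = a[ok], b[ok]
            if aa.std() == 0.0 or bb.std() == 0.0:
                continue
            r_mat[wi, di] = float(np.corrcoef(aa, bb)[0, 1])
    return LongRangeGrid(window_sizes, separations, r_mat, n_mat)
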