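"""Coverage standardization before testing.

The likelihood that a site is detected as modified depends on its coverage,
so before testing, read sets are subsampled to a common target: the chosen
percentile (default the 5th, under the nearest-rank-lower rule) of pooled
per-window coverage across samples, drawing reads *originating within* each
10-kb window so that reads-per-window x mean read length matches the target.
If the realized coverage misses the target (e.g. irregular read-length
distributions), the mean read length is re-estimated from the drawn subsample
and the draw repeated, keeping the best iterate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic_data import ReadSet
from .util import nearest_rank_lower

__all__ = [
    "CoverageTrack",
    "SubsamplePlan",
    "coverage_track",
    "target_coverage",
    "reads_per_window",
    "subsample",
]


@dataclass(frozen=True)
class CoverageTrack:
    """Per-window mean fold coverage along one genome for one sample."""

    window_size: int
    values: np.ndarray

    def __post_init__(self):
        if (np.asarray(self.values) < 0).any():
            raise ValueError("coverage values must be non-negative")


@dataclass(frozen=True)
class SubsamplePlan:
    target_coverage: float
    mean_read_length: float
    reads_per_window: np.ndarray
    iterations_used: int
    median_relative_error: float


def coverage_track(reads: ReadSet, window: int = 10_000) -> CoverageTrack:
    """Per-window mean per-base coverage implied by a read set."""
    if window <= 0:
        raise ValueError("window must be positive")
    L = reads.genome_length
    depth_delta = np.zeros(L + 1)
    starts = reads.reads["start"].to_numpy()
    ends = starts + reads.reads["length"].to_numpy()
    np.add.at(depth_delta, starts, 1.0)
    np.add.at(depth_delta, ends, -1.0)
    depth = np.cumsum(depth_delta[:-1])
    n_windows = -(-L // window)
    sums = np.add.reduceat(depth, np.arange(0, L, window))
    sizes = np.minimum(np.arange(n_windows) * window + window, L) - np.arange(
        n_windows
    ) * window
    return CoverageTrack(window, sums / sizes)


def target_coverage(tracks: Sequence[CoverageTrack], percentile: float = 5.0) -> float:
    """The stated percentile of pooled per-window coverage over all samples."""
    if not tracks:
        raise ValueError("at least one coverage track is required")
    pooled = np.concatenate([np.asarray(t.values, dtype=float) for t in tracks])
    return nearest_rank_lower(pooled, percentile)


def reads_per_window(target: float, window: int, mean_read_length: float) -> int:
    """round(target * window / mean_read_length): e.g. 100x, 10 kb, 2 kb -> 500."""
    if target < 0:
        raise ValueError("target coverage must be non-negative")
    if window <= 0:
        raise ValueError("window must be positive")
    if mean_read_length <= 0:
        raise ValueError("mean read length must be positive")
    return int(np.floor(target * window / mean_read_length + 0.5))


def subsample(
    reads: ReadSet,
    target: float,
    window: int = 10_000,
    tol: float = 0.1,
    max_iter: int = 5,
    seed: int = 0,
) -> tuple[ReadSet, SubsamplePlan]:
    """Standardize coverage by drawing reads originating within each window.

    Iteratively: estimate the mean read length, draw
    ``reads_per_window(target, window_size, mean_length)`` reads per window
    without replacement (all of them, with a warning, if a window is short of
    reads), measure the realized per-window coverage, and if the median
    relative error exceeds ``tol`` re-estimate the mean length from the drawn
    subsample and redraw.  Stops after ``max_iter`` iterations returning the
    best iterate.  The output is always a subset of the input reads.
    """
    if target <= 0:
        raise ValueError("target coverage must be positive")
    if reads.coverage < target:
        raise ValueError(
            f"input coverage {reads.coverage:.1f}x is below the target {target}x"
        )
    L = reads.genome_length
    n_windows = -(-L // window)
    win_sizes = np.minimum(np.arange(n_windows) * window + window, L) - np.arange(
        n_windows
    ) * window
    starts = reads.reads["start"].to_numpy()
    win_of_read = starts // window
    by_window = [np.nonzero(win_of_read == w)[0] for w in range(n_windows)]

    rng = np.random.default_rng(seed)
    mean_len = reads.mean_read_length
    best: tuple[float, np.ndarray, np.ndarray, int] | None = None
    shortfalls = 0
    it = 0
    for it in range(1, max_iter + 1):
        rpw = np.array(
            [reads_per_window(target, int(ws), mean_len) for ws in win_sizes],
            dtype=np.int64,
        )
        chosen: list[np.ndarray] = []
        for w in range(n_windows):
            pool = by_window[w]
            k = min(rpw[w], pool.size)
            if k < rpw[w]:
                shortfalls += 1
            if k > 0:
                chosen.append(rng.choice(pool, size=k, replace=False))
        idx = np.sort(np.concatenate(chosen)) if chosen else np.array([], dtype=np.int64)
        sub = ReadSet(
            reads=reads.reads.iloc[idx].reset_index(drop=True),
            marks=reads.marks[
                reads.marks["read_id"].isin(set(reads.reads["read_id"].iloc[idx]))
            ].reset_index(drop=True),
            genome_length=L,
        )
        realized = coverage_track(sub, window).values
        err = float(np.median(np.abs(realized - target) / target))
        if best is None or err < best[0]:
            best = (err, idx, rpw, it)
        if err <= tol:
            break
        mean_len = float(reads.reads["length"].iloc[idx].mean()) if idx.size else mean_len

    if shortfalls:
        warnings.warn(
            f"{shortfalls} window draw(s) had fewer originating reads than requested; "
            "sampled all available reads in those windows"
        )
    err, idx, rpw, best_it = best
    out = ReadSet(
        reads=reads.reads.iloc[idx].reset_index(drop=True),
        marks=reads.marks[
            reads.marks["read_id"].isin(set(reads.reads["read_id"].iloc[idx]))
        ].reset_index(drop=True),
        genome_length=L,
    )
    plan = SubsamplePlan(
        target_coverage=float(target),
        mean_read_length=float(mean_len),
        reads_per_window=rpw,
        iterations_used=it,
        median_relative_error=err,
    )
    return out, plan
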