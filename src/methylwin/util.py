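"""Small shared numerics: the package-wide quantile rule and seed plumbing."""

from __future__ import annotations

import math

import numpy as np


def nearest_rank_lower(values, percentile: float) -> float:
    """Nearest-rank-lower quantile: sorted[ceil(p/100 * n) - 1], floored at the minimum.

    This single declared rule is used for every percentile in the package
    (coverage targets, empirical-null thresholds) so that worked examples are
    exact: values 1..100 at the 5th percentile give 5; ten values at the 10th
    percentile give the smallest.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("cannot take a percentile of an empty collection")
    if not 0.0 < percentile <= 100.0:
        raise ValueError(f"percentile must be in (0, 100], got {percentile}")
    k = max(int(math.ceil(percentile / 100.0 * v.size)), 1)
    return float(v[k - 1])


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Derive n independent, reproducible generators from one integer seed."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]
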