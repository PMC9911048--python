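"""Motif-site location, site p-values, the empirical null, and binary calls.

A motif site's p-value is the minimum two-sided U-test p-value over the focal
(modified) base and its two neighbors — the pore reads several bases at once,
so the strongest signal deviation is not always at the modified base itself.
The classification threshold is empirical: the same min-over-±1 score at
random genomic positions (presumed unmethylated) in the first 1 Mbp forms a
null distribution, and a motif site is called methylated when its p-value is
strictly below the null's 10th percentile — by construction a ~10% false
positive rate on truly unmethylated sites.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

from .signal_stats import site_min_pvalues
from .synthetic_data import Genome, MotifDefinition
from .util import nearest_rank_lower

__all__ = [
    "MotifSite",
    "NullDistribution",
    "scan_motifs",
    "site_pvalue",
    "build_null",
    "classify_sites",
    "extract_candidate_regions",
]


@dataclass(frozen=True)
class MotifSite:
    motif: str
    start: int
    strand: str
    focal_position: int


@dataclass(frozen=True)
class NullDistribution:
    """Empirical null of min-over-±1 p-values at random genomic positions."""

    pvalues: np.ndarray
    region: tuple
    n_sites: int
    threshold_percentile: float
    threshold: float


def _iupac_regex(pattern: str) -> str:
    parts = []
    for ch in pattern.upper():
        try:
            bases = ambiguous_dna_values[ch]
        except KeyError:
            raise ValueError(f"invalid IUPAC symbol {ch!r} in motif pattern") from None
        parts.append(ch if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


def scan_motifs(genome: Genome, motif: MotifDefinition) -> list[MotifSite]:
    """All occurrences of a motif, sorted by start.

    Patterns closed under reverse complement are scanned on the forward
    strand only (each double-stranded locus appears once); other patterns are
    scanned in both orientations with the strand recorded and the focal
    position mirrored on the minus strand.  Overlapping occurrences are all
    reported.
    """
    seq = genome.sequence
    plen = len(motif.iupac)
    sites = []
    fwd = re.compile(f"(?=({_iupac_regex(motif.iupac)}))")
    for m in fwd.finditer(seq):
        s = m.start()
        sites.append(MotifSite(motif.name, s, "+", s + motif.focal_offset))
    if not motif.rc_closed:
        rc_pat = reverse_complement(motif.iupac)
        rev = re.compile(f"(?=({_iupac_regex(rc_pat)}))")
        for m in rev.finditer(seq):
            s = m.start()
            sites.append(
                MotifSite(motif.name, s, "-", s + plen - 1 - motif.focal_offset)
            )
    sites.sort(key=lambda x: (x.start, x.strand))
    return sites


def site_pvalue(diff: pd.DataFrame, focal_position: int) -> float:
    """Min u_pvalue over {focal-1, focal, focal+1}; NaN if all three absent."""
    return float(site_min_pvalues(diff, [focal_position])[0])


def build_null(
    diff: pd.DataFrame,
    genome: Union[Genome, int],
    n_sites: int,
    region_end: int = 1_000_000,
    seed: int = 0,
    threshold_percentile: float = 10.0,
    positions: Optional[Sequence[int]] = None,
) -> NullDistribution:
    """Empirical null from random positions in [0, region_end).

    Positions are drawn uniformly without replacement and scored with the
    same min-over-±1 rule as motif sites; unscorable draws (no difference-
    table coverage near the position) are replaced by further draws so that
    exactly ``n_sites`` p-values result whenever the region allows it.
    ``positions`` bypasses the internal draw with a caller-supplied set.
    The threshold is the nearest-rank-lower ``threshold_percentile`` of the
    null p-values; strictly fewer than that fraction of the null's own
    p-values fall below it (checked on every build).
    """
    genome_length = genome.length if isinstance(genome, Genome) else int(genome)
    if region_end > genome_length:
        raise ValueError("region_end exceeds genome length")
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    if n_sites > region_end:
        raise ValueError("n_sites exceeds the null region size")

    if positions is not None:
        pv = site_min_pvalues(diff, positions)
        pv = pv[np.isfinite(pv)]
    else:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(region_end)
        collected: list[np.ndarray] = []
        have = 0
        offset = 0
        chunk = max(n_sites, 1024)
        while have < n_sites and offset < region_end:
            cand = perm[offset : offset + chunk]
            offset += chunk
            scores = site_min_pvalues(diff, cand)
            scores = scores[np.isfinite(scores)]
            collected.append(scores)
            have += scores.size
        pv = np.concatenate(collected)[:n_sites] if collected else np.array([])
        if pv.size < n_sites:
            warnings.warn(
                f"null region exhausted: only {pv.size} of {n_sites} random "
                "positions were scorable"
            )
    if pv.size == 0:
        raise ValueError("no scorable null positions; difference table too sparse")
    threshold = nearest_rank_lower(pv, threshold_percentile)
    frac_below = float((pv < threshold).mean())
    if frac_below > threshold_percentile / 100.0:
        raise AssertionError(
            "null-threshold tautology violated: "
            f"{frac_below:.3f} of null p-values fall below the threshold"
        )
    return NullDistribution(
        pvalues=pv,
        region=(0, int(region_end)),
        n_sites=int(pv.size),
        threshold_percentile=float(threshold_percentile),
        threshold=float(threshold),
    )


def classify_sites(
    sites: Sequence[MotifSite],
    diff: pd.DataFrame,
    null: NullDistribution,
    condition: str = "",
) -> pd.DataFrame:
    """Binary methylated/unmethylated designation for every scorable site.

    methylated <=> site p-value strictly below the null threshold (sites whose
    p-value ties the threshold are unmethylated).  Sites with no coverage at
    the focal base or either neighbor are dropped.
    """
    if not sites:
        return pd.DataFrame(
            columns=[
                "condition",
                "motif",
                "start",
                "strand",
                "focal_position",
                "site_pvalue",
                "methylated",
            ]
        )
    focals = np.array([s.focal_position for s in sites], dtype=np.int64)
    pv = site_min_pvalues(diff, focals)
    ok = np.isfinite(pv)
    df = pd.DataFrame(
        {
            "condition": condition,
            "motif": [s.motif for s in sites],
            "start": [s.start for s in sites],
            "strand": [s.strand for s in sites],
            "focal_position": focals,
            "site_pvalue": pv,
        }
    )[ok]
    df["methylated"] = df["site_pvalue"] < null.threshold
    return df.reset_index(drop=True)


def extract_candidate_regions(
    diff: pd.DataFrame,
    genome: Genome,
    subsample_bp: int = 100_000,
    top_n: int = 5_000,
    flank: int = 10,
    seed: int = 0,
) -> list[SeqRecord]:
    """Flanks of the lowest-p positions from a random genomic subsample.

    Uniformly samples ``subsample_bp`` positions (from those present in the
    difference table), ranks them by u_pvalue ascending with seeded random
    tie-breaking, keeps the ``top_n`` lowest, and emits each as the sequence
    [pos - flank, pos + flank] (clipped to the genome) — the input one would
    hand to an external motif-discovery tool.
    """
    if subsample_bp > genome.length:
        raise ValueError("subsample_bp exceeds genome length")
    if top_n > subsample_bp:
        raise ValueError("top_n exceeds subsample_bp")
    if flank >= genome.length:
        raise ValueError("flank exceeds genome length")
    pool = diff["position"].to_numpy()
    pvals = diff["u_pvalue"].to_numpy()
    if pool.size < subsample_bp:
        raise ValueError(
            f"difference table covers {pool.size} positions; "
            f"cannot sample {subsample_bp}"
        )
    rng = np.random.default_rng(seed)
    take = rng.choice(pool.size, size=subsample_bp, replace=False)
    sampled_pos = pool[take]
    sampled_p = pvals[take]
    order = np.lexsort((rng.random(subsample_bp), sampled_p))[:top_n]
    records = []
    for i in order:
        pos = int(sampled_pos[i])
        lo = max(0, pos - flank)
        hi = min(genome.length, pos + flank + 1)
        records.append(
            SeqRecord(
                Seq(genome.sequence[lo:hi]),
                id=f"{genome.contig_id}:{lo}-{hi}",
                description=f"pos={pos} u_pvalue={sampled_p[i]:.4g}",
            )
        )
    return records
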