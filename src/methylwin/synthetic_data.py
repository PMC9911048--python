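"""Synthetic genomes, methylation landscapes, reads and nanopore-like signal tables.

This module generates data with the statistical structure the downstream
analysis assumes, so that the full pipeline — per-position native-vs-WGA
signal testing, empirical-null motif calling, coverage standardization and
window correlation — runs end to end without any sequencing data.

The generative model, briefly:

* a genome is an i.i.d. base sequence with a configurable GC fraction;
* each motif site carries a per-molecule methylation probability ``theta``
  that is the base level of its 10-kb window plus small site-level noise;
  window base levels mix a profile shared across growth conditions with a
  condition-specific profile (weight ``rho``), which is what makes
  inter-condition window correlations tunable;
* reads start uniformly on the genome with geometric lengths, and each
  native molecule draws an independent Bernoulli(theta) methylation state at
  every motif site it covers (WGA reads carry no marks);
* the measured signal at a position is a fixed per-position baseline (shared
  exactly between the native and WGA samples) plus Gaussian noise, shifted by
  a modification-specific delta within ``halfwidth_k`` bases of a methylated
  focal base.  The 5mC shift is larger than the 6mA shift by default, which
  reproduces the empirically observed asymmetry in test sensitivity between
  CCWGG and GATC sites.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Genome",
    "MotifDefinition",
    "MethylationLandscape",
    "ReadSet",
    "SignalModel",
    "DAM",
    "DCM",
    "generate_genome",
    "build_landscape",
    "simulate_reads",
    "simulate_signals",
    "mix_reads",
]

_ACGT = re.compile(r"[ACGT]*\Z")

#: Columns of an event table (one row per read per covered position).
EVENT_COLUMNS = ("position", "read_id", "sample", "signal")


@dataclass(frozen=True)
class Genome:
    """A single contig over the alphabet {A, C, G, T}."""

    contig_id: str
    sequence: str

    def __post_init__(self):
        if not _ACGT.match(self.sequence):
            raise ValueError("genome sequence must contain only A/C/G/T")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifDefinition:
    """A methyltransferase target motif.

    ``focal_offset`` is the 0-based index of the modified base within the
    pattern; ``rc_closed`` marks patterns whose site set is closed under
    reverse complement (palindromic under IUPAC), which are scanned on the
    forward strand only so each double-stranded locus is counted once.
    """

    name: str
    iupac: str
    focal_offset: int
    modification: str = "6mA"
    rc_closed: bool = True

    def __post_init__(self):
        if not 0 <= self.focal_offset < len(self.iupac):
            raise ValueError("focal_offset must index into the pattern")
        base = self.iupac[self.focal_offset].upper()
        expected = "A" if self.modification == "6mA" else "C"
        if base != expected:
            raise ValueError(
                f"focal base of a {self.modification} motif must be {expected}, got {base}"
            )
        if self.modification not in {"6mA", "5mC", "4mC"}:
            raise ValueError(f"unknown modification {self.modification!r}")


#: Canonical E. coli Dam motif: G-A-T-C with 6mA at the adenine.
DAM = MotifDefinition("DAM", "GATC", 1, "6mA", True)
#: Canonical E. coli Dcm motif: C-C-W-G-G with 5mC at the second cytosine.
DCM = MotifDefinition("DCM", "CCWGG", 1, "5mC", True)


@dataclass
class MethylationLandscape:
    """Ground-truth per-site methylation probabilities for one condition."""

    condition: str
    theta: dict  # focal position -> probability a molecule is methylated
    modifications: dict  # focal position -> modification label ("6mA"/"5mC"/"4mC")
    window_base_levels: np.ndarray
    window: int
    params: dict = field(default_factory=dict)

    def site_positions(self) -> np.ndarray:
        return np.fromiter(self.theta.keys(), dtype=np.int64)


@dataclass
class ReadSet:
    """Simulated reads plus their per-molecule methylation marks.

    ``reads`` has columns (read_id, sample, start, length); ``marks`` has
    columns (read_id, position, modification) and lists only the motif sites
    at which a given molecule IS methylated.  WGA read sets carry no marks.
    """

    reads: pd.DataFrame
    marks: pd.DataFrame
    genome_length: int

    def __post_init__(self):
        ends = self.reads["start"].to_numpy() + self.reads["length"].to_numpy()
        if len(ends) and ends.max() > self.genome_length:
            raise ValueError("read extends past the end of the genome")

    @property
    def n_reads(self) -> int:
        return len(self.reads)

    @property
    def mean_read_length(self) -> float:
        return float(self.reads["length"].mean())

    @property
    def coverage(self) -> float:
        """Mean fold coverage implied by total read bases."""
        return float(self.reads["length"].sum()) / self.genome_length


@dataclass(frozen=True)
class SignalModel:
    """Fixed-baseline Gaussian shift model for per-position signal levels.

    The baseline is a seeded function of genome position only, so the native
    and WGA samples share it exactly; methylation adds ``delta`` (per
    modification type) to every position within ``halfwidth_k`` bases of the
    modified focal base, emulating the multi-base footprint of the pore.
    Units are arbitrary current units.
    """

    sigma: float = 1.0
    delta_6mA: float = 0.5
    delta_5mC: float = 1.2
    delta_4mC: float = 0.9
    halfwidth_k: int = 2
    baseline_seed: int = 20201
    baseline_loc: float = 90.0
    baseline_spread: float = 8.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.halfwidth_k < 1:
            raise ValueError("halfwidth_k must be >= 1")

    def delta_for(self, modification: str) -> float:
        return {"6mA": self.delta_6mA, "5mC": self.delta_5mC, "4mC": self.delta_4mC}[
            modification
        ]

    def baseline(self, genome_length: int) -> np.ndarray:
        """Deterministic per-position baseline signal, identical across samples."""
        rng = np.random.default_rng(self.baseline_seed)
        return rng.normal(self.baseline_loc, self.baseline_spread, genome_length)


def generate_genome(
    length: int,
    gc_fraction: float = 0.5,
    seed: int = 0,
    contig_id: str = "sim_contig",
) -> Genome:
    """Generate an i.i.d. random genome with the given GC fraction.

    P(G) = P(C) = gc_fraction / 2 and P(A) = P(T) = (1 - gc_fraction) / 2;
    the same seed always yields the identical sequence.
    """
    if length <= 0:
        raise ValueError(f"genome length must be positive, got {length}")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    idx = rng.choice(4, size=length, p=[at, gc, gc, at])
    lookup = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = lookup[idx].tobytes().decode("ascii")
    return Genome(contig_id, seq)


def build_landscape(
    genome: Genome,
    sites: Mapping[str, Sequence[int]],
    conditions: Sequence[str],
    window: int = 10_000,
    rho: float = 0.7,
    seed: int = 0,
    beta_a: float = 2.0,
    beta_b: float = 2.0,
    site_noise: float = 0.05,
) -> list[MethylationLandscape]:
    """Draw per-condition methylation probabilities for the given motif sites.

    ``sites`` maps a modification label ("6mA", "5mC", "4mC") to the focal
    positions of that modification's motif sites.  Each condition's window
    base level is ``rho * shared + (1 - rho) * condition_specific``, with both
    profiles drawn i.i.d. Beta(beta_a, beta_b) per window; a site's theta is
    its window's base level plus clipped Normal(0, site_noise) noise.  With
    rho=1 all conditions share identical base levels; with rho=0 they are
    independent; in between, the expected correlation of two conditions'
    base-level vectors is rho^2 / (rho^2 + (1-rho)^2).
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must be in [0, 1]")
    if window <= 0:
        raise ValueError("window must be positive")
    all_pos: list[int] = []
    all_mod: list[str] = []
    for mod, positions in sites.items():
        if mod not in {"6mA", "5mC", "4mC"}:
            raise ValueError(f"unknown modification label {mod!r}")
        for p in positions:
            all_pos.append(int(p))
            all_mod.append(mod)
    if not all_pos:
        raise ValueError("site list is empty")
    pos_arr = np.asarray(all_pos, dtype=np.int64)
    if pos_arr.min() < 0 or pos_arr.max() >= genome.length:
        raise ValueError("site positions must lie within the genome")
    order = np.argsort(pos_arr, kind="stable")
    pos_arr = pos_arr[order]
    mod_arr = [all_mod[i] for i in order]

    n_windows = -(-genome.length // window)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(1 + 2 * len(conditions))
    shared = np.random.default_rng(children[0]).beta(beta_a, beta_b, n_windows)

    win_idx = pos_arr // window
    out = []
    for i, cond in enumerate(conditions):
        rng_prof = np.random.default_rng(children[1 + 2 * i])
        rng_site = np.random.default_rng(children[2 + 2 * i])
        specific = rng_prof.beta(beta_a, beta_b, n_windows)
        base = rho * shared + (1.0 - rho) * specific
        theta = np.clip(base[win_idx] + rng_site.normal(0.0, site_noise, pos_arr.size), 0.0, 1.0)
        out.append(
            MethylationLandscape(
                condition=str(cond),
                theta={int(p): float(t) for p, t in zip(pos_arr, theta)},
                modifications={int(p): m for p, m in zip(pos_arr, mod_arr)},
                window_base_levels=base,
                window=window,
                params={
                    "rho": rho,
                    "beta_a": beta_a,
                    "beta_b": beta_b,
                    "site_noise": site_noise,
                    "seed": seed,
                },
            )
        )
    return out


def simulate_reads(
    genome: Genome,
    landscape: Optional[MethylationLandscape],
    coverage: float,
    read_length_mean: int = 5_000,
    seed: int = 0,
    read_prefix: Optional[str] = None,
) -> ReadSet:
    """Simulate uniformly placed reads; native molecules draw Bernoulli marks.

    The read count is round(coverage * genome_length / read_length_mean);
    lengths are geometric with the given mean, truncated at the contig end
    (no circular wrap).  When ``landscape`` is None the sample is "wga" and
    carries no methylation marks.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if read_length_mean > genome.length:
        raise ValueError("mean read length exceeds genome length")
    L = genome.length
    sample = "wga" if landscape is None else "native"
    prefix = read_prefix if read_prefix is not None else (
        sample if landscape is None else f"native.{landscape.condition}"
    )
    rng = np.random.default_rng(seed)
    n_reads = int(round(coverage * L / read_length_mean))
    starts = rng.integers(0, L, size=n_reads)
    lengths = rng.geometric(1.0 / read_length_mean, size=n_reads)
    lengths = np.minimum(lengths, L - starts)
    read_ids = np.array([f"{prefix}_{i:07d}" for i in range(n_reads)], dtype=object)

    mark_reads: list = []
    mark_pos: list = []
    mark_mod: list = []
    if landscape is not None:
        site_pos = landscape.site_positions()
        order = np.argsort(site_pos)
        site_pos = site_pos[order]
        site_theta = np.array([landscape.theta[int(p)] for p in site_pos])
        site_mod = np.array([landscape.modifications[int(p)] for p in site_pos], dtype=object)
        for i in range(n_reads):
            lo, hi = np.searchsorted(site_pos, [starts[i], starts[i] + lengths[i]])
            if hi > lo:
                hit = rng.random(hi - lo) < site_theta[lo:hi]
                if hit.any():
                    sel = np.nonzero(hit)[0] + lo
                    mark_reads.extend([read_ids[i]] * sel.size)
                    mark_pos.extend(site_pos[sel].tolist())
                    mark_mod.extend(site_mod[sel].tolist())

    reads = pd.DataFrame(
        {
            "read_id": read_ids,
            "sample": sample,
            "start": starts.astype(np.int64),
            "length": lengths.astype(np.int64),
        }
    )
    marks = pd.DataFrame(
        {
            "read_id": np.asarray(mark_reads, dtype=object),
            "position": np.asarray(mark_pos, dtype=np.int64),
            "modification": np.asarray(mark_mod, dtype=object),
        }
    )
    return ReadSet(reads=reads, marks=marks, genome_length=L)


def simulate_signals(
    reads: ReadSet,
    model: SignalModel,
    seed: int = 0,
    positions: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Emit one signal observation per (read, covered position).

    signal = baseline(position) + delta * 1[within halfwidth_k of a methylated
    focal base on this molecule] + Normal(0, sigma).  ``positions`` optionally
    restricts output to a sorted subset of genomic positions (e.g. motif
    neighborhoods), which changes nothing statistically — each emitted
    observation is identical in law to the unrestricted case.
    """
    base = model.baseline(reads.genome_length)
    rng = np.random.default_rng(seed)
    pos_sel = None
    if positions is not None:
        pos_sel = np.unique(np.asarray(positions, dtype=np.int64))

    marks_by_read: dict = {}
    if len(reads.marks):
        for rid, grp in reads.marks.groupby("read_id", sort=False):
            marks_by_read[rid] = (
                grp["position"].to_numpy(),
                grp["modification"].to_numpy(),
            )

    k = model.halfwidth_k
    pos_chunks: list = []
    sig_chunks: list = []
    counts = np.zeros(len(reads.reads), dtype=np.int64)
    starts = reads.reads["start"].to_numpy()
    lengths = reads.reads["length"].to_numpy()
    rids = reads.reads["read_id"].to_numpy()
    for i in range(len(rids)):
        s, ln = int(starts[i]), int(lengths[i])
        if pos_sel is None:
            p = np.arange(s, s + ln, dtype=np.int64)
        else:
            lo, hi = np.searchsorted(pos_sel, [s, s + ln])
            p = pos_sel[lo:hi]
        if p.size == 0:
            continue
        sig = base[p] + rng.normal(0.0, model.sigma, p.size)
        m = marks_by_read.get(rids[i])
        if m is not None:
            for f, mod in zip(m[0], m[1]):
                lo2, hi2 = np.searchsorted(p, [f - k, f + k + 1])
                if hi2 > lo2:
                    sig[lo2:hi2] += model.delta_for(mod)
        pos_chunks.append(p)
        sig_chunks.append(sig)
        counts[i] = p.size

    if not pos_chunks:
        return pd.DataFrame(
            {"position": np.array([], dtype=np.int64), "read_id": [], "sample": [], "signal": []}
        )
    read_codes = np.repeat(np.arange(len(rids)), counts)
    sample_col = pd.Categorical(reads.reads["sample"].to_numpy()[read_codes])
    return pd.DataFrame(
        {
            "position": np.concatenate(pos_chunks),
            "read_id": pd.Categorical.from_codes(read_codes, categories=list(rids)),
            "sample": sample_col,
            "signal": np.concatenate(sig_chunks),
        }
    )


def mix_reads(
    native: ReadSet,
    wga: ReadSet,
    fraction_native: float,
    target_coverage: float,
    seed: int = 0,
) -> ReadSet:
    """In-silico titration mix: draw reads from each pool to hit a coverage target.

    The number of reads drawn from each pool is chosen from that pool's mean
    read length so that the expected fold coverage is ``target_coverage`` with
    a native share of ``fraction_native`` (by depth).  Draws are without
    replacement; an informative error names the pool that is too small.
    """
    if not 0.0 <= fraction_native <= 1.0:
        raise ValueError("fraction_native must be in [0, 1]")
    if native.genome_length != wga.genome_length:
        raise ValueError("native and wga read sets must share a genome")
    L = native.genome_length
    rng = np.random.default_rng(seed)

    def _need(pool: ReadSet, share: float, name: str) -> int:
        if share == 0.0:
            return 0
        n = int(round(share * target_coverage * L / pool.mean_read_length))
        if n > pool.n_reads:
            raise ValueError(
                f"{name} pool has {pool.n_reads} reads but {n} are required "
                f"for {share:.0%} of {target_coverage}x coverage"
            )
        return n

    n_nat = _need(native, fraction_native, "native")
    n_wga = _need(wga, 1.0 - fraction_native, "wga")

    parts_reads = []
    parts_marks = []
    for pool, n in ((native, n_nat), (wga, n_wga)):
        if n == 0:
            continue
        idx = rng.choice(pool.n_reads, size=n, replace=False)
        sel = pool.reads.iloc[np.sort(idx)]
        parts_reads.append(sel)
        if len(pool.marks):
            keep = pool.marks["read_id"].isin(set(sel["read_id"]))
            parts_marks.append(pool.marks[keep])

    reads = (
        pd.concat(parts_reads, ignore_index=True)
        if parts_reads
        else native.reads.iloc[0:0].copy()
    )
    marks = (
        pd.concat(parts_marks, ignore_index=True)
        if parts_marks
        else native.marks.iloc[0:0].copy()
    )
    return ReadSet(reads=reads, marks=marks, genome_length=L)
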