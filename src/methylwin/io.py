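"""Readers and writers for the package's plain-text interchange formats.

Everything is TSV (optionally gzipped, inferred from the .gz suffix), FASTA,
or BED/bedGraph, so outputs from real preprocessing tools can be converted
in and results inspected with standard command-line tools.  The difference-
table columns mirror the merged per-position schema of Nanodisco-style
tools: position, cov_native, cov_wga, mean_diff, u_pvalue, t_pvalue.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coverage_normalization import CoverageTrack
from .motif_analysis import MotifSite, NullDistribution
from .synthetic_data import Genome, MethylationLandscape, ReadSet
from .window_analysis import CorrelationResult, LongRangeGrid, WindowProfile


def write_genome_fasta(genome: Genome, path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(genome.sequence), id=genome.contig_id, description="")],
        str(path),
        "fasta",
    )


def read_genome_fasta(path) -> Genome:
    record = next(SeqIO.parse(str(path), "fasta"))
    return Genome(record.id, str(record.seq).upper())


def write_candidates_fasta(records: Iterable[SeqRecord], path) -> None:
    SeqIO.write(list(records), str(path), "fasta")


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["read_id"] = df["read_id"].astype("category")
    df["sample"] = df["sample"].astype("category")
    return df


def write_readset(rs: ReadSet, reads_path, marks_path=None) -> None:
    with open(reads_path, "w") as fh:
        fh.write(f"# genome_length={rs.genome_length}\n")
        rs.reads.to_csv(fh, sep="\t", index=False)
    if marks_path is not None:
        rs.marks.to_csv(marks_path, sep="\t", index=False)


def read_readset(reads_path, marks_path=None) -> ReadSet:
    with open(reads_path) as fh:
        header = fh.readline().strip()
        genome_length = int(header.split("=", 1)[1])
        reads = pd.read_csv(fh, sep="\t")
    if marks_path is not None and Path(marks_path).exists():
        marks = pd.read_csv(marks_path, sep="\t")
        if len(marks) == 0:
            marks = _empty_marks()
    else:
        marks = _empty_marks()
    return ReadSet(reads=reads, marks=marks, genome_length=genome_length)


def _empty_marks() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": pd.Series([], dtype=object),
            "position": pd.Series([], dtype=np.int64),
            "modification": pd.Series([], dtype=object),
        }
    )


def write_marks_bed(rs: ReadSet, path, contig_id: str) -> None:
    """Methylated-molecule marks as BED4 (one row per read x methylated site)."""
    with open(path, "w") as fh:
        for row in rs.marks.itertuples(index=False):
            fh.write(f"{contig_id}\t{row.position}\t{row.position + 1}\t{row.read_id}\n")


def write_landscapes(landscapes: Sequence[MethylationLandscape], path) -> None:
    rows = []
    for ls in landscapes:
        for pos, theta in ls.theta.items():
            rows.append((ls.condition, pos, ls.modifications[pos], theta))
    pd.DataFrame(
        rows, columns=["condition", "focal_position", "modification", "theta"]
    ).to_csv(path, sep="\t", index=False)


def write_diff(diff: pd.DataFrame, path) -> None:
    diff.to_csv(path, sep="\t", index=False)


def read_diff(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_null(null: NullDistribution, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# threshold={null.threshold!r}\n")
        fh.write(f"# threshold_percentile={null.threshold_percentile}\n")
        fh.write(f"# region={null.region[0]}-{null.region[1]}\n")
        pd.DataFrame({"pvalue": null.pvalues}).to_csv(fh, sep="\t", index=False)


def read_null(path) -> NullDistribution:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, val = line[1:].strip().split("=", 1)
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        pv = pd.read_csv(fh, sep="\t")["pvalue"].to_numpy()
    lo, hi = meta["region"].split("-")
    return NullDistribution(
        pvalues=pv,
        region=(int(lo), int(hi)),
        n_sites=pv.size,
        threshold_percentile=float(meta["threshold_percentile"]),
        threshold=float(meta["threshold"]),
    )


def write_calls_tsv(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_calls_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_calls_bed(calls: pd.DataFrame, path, contig_id: str, motif_length: int) -> None:
    """SiteCalls as BED6+2: chrom start end motif score(-log10 p) strand p methylated."""
    with open(path, "w") as fh:
        for row in calls.itertuples(index=False):
            score = -np.log10(max(row.site_pvalue, 1e-300))
            fh.write(
                f"{contig_id}\t{row.start}\t{row.start + motif_length}\t{row.motif}"
                f"\t{score:.4f}\t{row.strand}\t{row.site_pvalue:.6g}"
                f"\t{int(row.methylated)}\n"
            )


def write_sites_tsv(sites: Sequence[MotifSite], path) -> None:
    pd.DataFrame(
        [(s.motif, s.start, s.strand, s.focal_position) for s in sites],
        columns=["motif", "start", "strand", "focal_position"],
    ).to_csv(path, sep="\t", index=False)


def read_sites_tsv(path) -> list[MotifSite]:
    df = pd.read_csv(path, sep="\t")
    return [
        MotifSite(r.motif, int(r.start), r.strand, int(r.focal_position))
        for r in df.itertuples(index=False)
    ]


def write_profile(profile: WindowProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# condition={profile.condition}\tmotif={profile.motif}"
            f"\twindow_size={profile.window_size}\tnormalized={profile.normalized}\n"
        )
        profile.table.to_csv(fh, sep="\t", index=False)


def write_profile_bedgraph(profile: WindowProfile, path, contig_id: str) -> None:
    with open(path, "w") as fh:
        for row in profile.table.itertuples(index=False):
            end = row.start + profile.window_size
            fh.write(f"{contig_id}\t{row.start}\t{end}\t{row.fraction:.6g}\n")


def write_coverage_bedgraph(track: CoverageTrack, path, contig_id: str, genome_length: int) -> None:
    with open(path, "w") as fh:
        for i, v in enumerate(track.values):
            start = i * track.window_size
            end = min(start + track.window_size, genome_length)
            fh.write(f"{contig_id}\t{start}\t{end}\t{v:.6g}\n")


def write_correlations(results: Sequence[CorrelationResult], path) -> None:
    pd.DataFrame(
        [
            (
                r.condition_a,
                r.condition_b,
                r.motif,
                r.r,
                r.pvalue,
                ";".join(r.covariates),
                r.n_windows,
            )
            for r in results
        ],
        columns=[
            "condition_a",
            "condition_b",
            "motif",
            "r",
            "pvalue",
            "covariates",
            "n_windows",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_grid(grid: LongRangeGrid, path) -> None:
    rows = []
    for wi, w in enumerate(grid.window_sizes):
        for di, d in enumerate(grid.separations):
            rows.append((int(w), int(d), grid.r[wi, di], int(grid.n_pairs[wi, di])))
    pd.DataFrame(rows, columns=["window_size", "separation", "r", "n_pairs"]).to_csv(
        path, sep="\t", index=False
    )
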