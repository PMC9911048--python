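"""End-to-end orchestration: simulate -> subsample -> signals -> diff -> call -> windows.

A single YAML (or dict) config is the source of truth for every stage
parameter; a run writes all primary tables under the output directory plus a
``manifest.json`` recording, per stage, the inputs, outputs and the config
hash.  Reruns with an unchanged config and intact outputs skip completed
stages unless forced.  Every stage re-reads its inputs from the previous
stage's files, so a config plus its seed fully determines every output table
byte for byte.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from . import io as mio
from . import __version__
from .coverage_normalization import coverage_track, subsample, target_coverage
from .motif_analysis import MotifSite, build_null, classify_sites, scan_motifs
from .signal_stats import difference_table, summarize_titration
from .synthetic_data import (
    Genome,
    MotifDefinition,
    build_landscape,
    generate_genome,
    mix_reads,
    simulate_reads,
    simulate_signals,
    SignalModel,
)
from .window_analysis import (
    InsufficientDataError,
    long_range_scan,
    pairwise_condition_matrix,
    window_fractions,
)

logger = logging.getLogger("methylwin")

__all__ = ["ConfigError", "RunConfig", "RunManifest", "validate_config", "run_pipeline"]


class ConfigError(ValueError):
    """Raised with the full list of config problems, not just the first."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid config:\n  " + "\n  ".join(self.problems))


DEFAULTS: dict = {
    "genome": {"length": 500_000, "gc": 0.5, "contig_id": "sim_contig", "fasta": None},
    "motifs": [
        {"name": "DAM", "iupac": "GATC", "focal_offset": 1, "modification": "6mA", "rc_closed": True},
        {"name": "DCM", "iupac": "CCWGG", "focal_offset": 1, "modification": "5mC", "rc_closed": True},
    ],
    "conditions": ["condition_1", "condition_2"],
    "landscape": {"window": 10_000, "rho": 0.7, "beta_a": 2.0, "beta_b": 2.0, "site_noise": 0.05},
    "coverage": {"native": 25.0, "wga": 50.0, "read_length_mean": 5_000},
    "signal": {
        "sigma": 1.0,
        "delta_6mA": 0.5,
        "delta_5mC": 1.2,
        "halfwidth_k": 2,
        "baseline_seed": 20201,
    },
    "subsample": {"enabled": False, "percentile": 5.0, "window": 10_000, "tol": 0.1, "max_iter": 5},
    "diff": {"min_cov": 5},
    "null": {"n_sites": 1_000, "region_end": 1_000_000, "percentile": 10.0},
    "windows": {"size": 10_000},
    "titration": {
        "enabled": False,
        "fractions": [0.0, 0.25, 0.5, 0.75, 1.0],
        "target_coverage": 50.0,
    },
    "scan": {"enabled": False, "window_sizes": [10_000], "separations": [0, 10_000, 50_000]},
    "seed": None,
    "outdir": ".",
}


@dataclass(frozen=True)
class RunConfig:
    data: dict
    config_hash: str

    def __getitem__(self, key):
        return self.data[key]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: dict = field(default_factory=dict)

    def record(self, name, inputs, outputs, status):
        self.stages[name] = {
            "inputs": [str(p) for p in inputs],
            "outputs": [str(p) for p in outputs],
            "parameter_hash": self.config_hash,
            "status": status,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "config_hash": self.config_hash,
                    "version": self.version,
                    "stages": self.stages,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        raw = json.loads(Path(path).read_text())
        return cls(raw["config_hash"], raw["version"], raw["stages"])


def _merge(defaults, user, prefix, problems):
    if not isinstance(user, Mapping):
        problems.append(f"{prefix or 'config'}: expected a mapping")
        return copy.deepcopy(defaults)
    out = copy.deepcopy(defaults)
    for key, val in user.items():
        path = f"{prefix}.{key}" if prefix else key
        if key not in defaults:
            problems.append(f"unknown key {path}")
            continue
        if isinstance(defaults[key], Mapping):
            out[key] = _merge(defaults[key], val, path, problems)
        else:
            out[key] = copy.deepcopy(val)
    return out


def validate_config(config: Union[str, dict]) -> RunConfig:
    """Parse, fill defaults, and validate; reports every problem at once."""
    if isinstance(config, str):
        import yaml

        parsed = yaml.safe_load(config) or {}
    else:
        parsed = config
    problems: list[str] = []
    cfg = _merge(DEFAULTS, parsed, "", problems)

    def check(ok: bool, msg: str):
        if not ok:
            problems.append(msg)

    g = cfg["genome"]
    if g["fasta"] is None:
        check(isinstance(g["length"], int) and g["length"] > 0, "genome.length must be a positive integer")
        check(0.0 <= g["gc"] <= 1.0, "genome.gc must be in [0, 1]")
        check(cfg["seed"] is not None, "seed is mandatory for simulation-backed runs")
    if cfg["seed"] is not None:
        check(isinstance(cfg["seed"], int), "seed must be an integer")

    check(
        isinstance(cfg["conditions"], list) and len(cfg["conditions"]) >= 1,
        "conditions must be a non-empty list",
    )
    if isinstance(cfg["conditions"], list):
        names = [str(c) for c in cfg["conditions"]]
        check(len(set(names)) == len(names), "conditions must have unique names")

    for i, mdict in enumerate(cfg["motifs"]):
        try:
            MotifDefinition(
                mdict["name"],
                mdict["iupac"],
                int(mdict["focal_offset"]),
                mdict.get("modification", "6mA"),
                bool(mdict.get("rc_closed", True)),
            )
        except (KeyError, ValueError) as exc:
            problems.append(f"motifs[{i}]: {exc}")

    ls = cfg["landscape"]
    check(0.0 <= ls["rho"] <= 1.0, "landscape.rho must be in [0, 1]")
    check(ls["window"] > 0, "landscape.window must be positive")
    cov = cfg["coverage"]
    check(cov["native"] > 0, "coverage.native must be positive")
    check(cov["wga"] > 0, "coverage.wga must be positive")
    check(cov["read_length_mean"] > 0, "coverage.read_length_mean must be positive")
    sig = cfg["signal"]
    check(sig["sigma"] > 0, "signal.sigma must be positive")
    check(sig["halfwidth_k"] >= 1, "signal.halfwidth_k must be >= 1")
    sub = cfg["subsample"]
    check(0.0 < sub["percentile"] <= 100.0, "subsample.percentile must be in (0, 100]")
    check(sub["tol"] > 0, "subsample.tol must be positive")
    check(sub["max_iter"] >= 1, "subsample.max_iter must be >= 1")
    check(cfg["diff"]["min_cov"] >= 1, "diff.min_cov must be >= 1")
    nl = cfg["null"]
    check(nl["n_sites"] >= 1, "null.n_sites must be >= 1")
    check(0.0 < nl["percentile"] <= 100.0, "null.percentile must be in (0, 100]")
    check(nl["region_end"] >= 1, "null.region_end must be >= 1")
    check(cfg["windows"]["size"] > 0, "windows.size must be positive")
    ti = cfg["titration"]
    fr = ti["fractions"]
    check(
        isinstance(fr, list) and all(0.0 <= float(f) <= 1.0 for f in fr),
        "titration.fractions must be a list of values in [0, 1]",
    )
    if isinstance(fr, list):
        check(
            any(abs(float(f)) < 1e-12 for f in fr) and any(abs(float(f) - 1) < 1e-12 for f in fr),
            "titration.fractions must include 0 and 1 (required by the titration summary)",
        )
    check(ti["target_coverage"] > 0, "titration.target_coverage must be positive")
    sc = cfg["scan"]
    check(
        all(int(w) > 0 for w in sc["window_sizes"]), "scan.window_sizes must be positive"
    )
    check(
        all(int(d) >= -max(int(w) for w in sc["window_sizes"]) for d in sc["separations"]),
        "scan.separations must be >= -max(window size)",
    )

    if problems:
        raise ConfigError(problems)
    canonical = json.dumps(cfg, sort_keys=True, default=str)
    return RunConfig(cfg, hashlib.sha256(canonical.encode()).hexdigest())


def _motif_defs(cfg) -> list[MotifDefinition]:
    return [
        MotifDefinition(
            m["name"], m["iupac"], int(m["focal_offset"]),
            m.get("modification", "6mA"), bool(m.get("rc_closed", True)),
        )
        for m in cfg["motifs"]
    ]


def run_pipeline(config: RunConfig, force: bool = False) -> RunManifest:
    """Execute all configured stages in dependency order; returns the manifest."""
    cfg = config.data
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    manifest = RunManifest(config.config_hash, __version__)
    manifest_path = outdir / "manifest.json"
    previous: Optional[RunManifest] = None
    if manifest_path.exists():
        try:
            previous = RunManifest.from_json(manifest_path)
        except (json.JSONDecodeError, KeyError):
            previous = None

    master = np.random.default_rng(cfg["seed"] if cfg["seed"] is not None else 0)
    stage_seeds = {
        name: int(s)
        for name, s in zip(
            ["genome", "landscape", "reads", "signals", "subsample", "null", "titration"],
            master.integers(0, 2**31 - 1, size=7),
        )
    }
    conditions = [str(c) for c in cfg["conditions"]]
    motif_defs = _motif_defs(cfg)

    def _should_skip(name, outputs) -> bool:
        if force or previous is None:
            return False
        prev = previous.stages.get(name)
        return (
            prev is not None
            and prev.get("parameter_hash") == config.config_hash
            and prev.get("status") in {"completed", "skipped"}
            and all(Path(p).exists() for p in map(str, outputs))
        )

    def _run_stage(name, inputs, outputs, fn):
        if _should_skip(name, outputs):
            logger.info("stage %s: skipped (outputs up to date)", name)
            manifest.record(name, inputs, outputs, "skipped")
            return
        t0 = time.monotonic()
        try:
            fn()
        except Exception as exc:
            manifest.record(name, inputs, outputs, "failed")
            manifest.to_json(manifest_path)
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        logger.info("stage %s: completed in %.1fs", name, time.monotonic() - t0)
        manifest.record(name, inputs, outputs, "completed")
        manifest.to_json(manifest_path)

    # ---- stage: simulate (genome, motif sites, landscapes, reads) ----
    genome_path = outdir / "genome.fasta"
    sites_paths = {m.name: outdir / f"sites_{m.name}.tsv" for m in motif_defs}
    landscape_path = outdir / "landscape.tsv"
    reads_paths = {c: (outdir / f"reads_{c}.tsv", outdir / f"marks_{c}.tsv") for c in conditions}
    wga_reads_path = (outdir / "reads_wga.tsv", outdir / "marks_wga.tsv")
    sim_outputs = (
        [genome_path, landscape_path, *wga_reads_path]
        + list(sites_paths.values())
        + [p for pair in reads_paths.values() for p in pair]
    )

    def _simulate():
        if cfg["genome"]["fasta"]:
            genome = mio.read_genome_fasta(cfg["genome"]["fasta"])
        else:
            genome = generate_genome(
                cfg["genome"]["length"], cfg["genome"]["gc"],
                stage_seeds["genome"], cfg["genome"]["contig_id"],
            )
        mio.write_genome_fasta(genome, genome_path)
        site_map: dict[str, list[int]] = {}
        for mdef in motif_defs:
            sites = scan_motifs(genome, mdef)
            mio.write_sites_tsv(sites, sites_paths[mdef.name])
            site_map.setdefault(mdef.modification, []).extend(
                s.focal_position for s in sites
            )
        landscapes = build_landscape(
            genome, site_map, conditions,
            window=cfg["landscape"]["window"], rho=cfg["landscape"]["rho"],
            seed=stage_seeds["landscape"],
            beta_a=cfg["landscape"]["beta_a"], beta_b=cfg["landscape"]["beta_b"],
            site_noise=cfg["landscape"]["site_noise"],
        )
        mio.write_landscapes(landscapes, landscape_path)
        read_rng = np.random.default_rng(stage_seeds["reads"])
        for ls in landscapes:
            rs = simulate_reads(
                genome, ls, cfg["coverage"]["native"],
                cfg["coverage"]["read_length_mean"], int(read_rng.integers(2**31)),
            )
            mio.write_readset(rs, *reads_paths[ls.condition])
        wga = simulate_reads(
            genome, None, cfg["coverage"]["wga"],
            cfg["coverage"]["read_length_mean"], int(read_rng.integers(2**31)),
        )
        mio.write_readset(wga, *wga_reads_path)

    _run_stage("simulate", [], sim_outputs, _simulate)

    # ---- stage: subsample (optional coverage standardization) ----
    samples = list(conditions) + ["wga"]
    final_reads_paths = dict(reads_paths)
    final_reads_paths["wga"] = wga_reads_path
    if cfg["subsample"]["enabled"]:
        sub_paths = {
            s: (outdir / f"reads_sub_{s}.tsv", outdir / f"marks_sub_{s}.tsv")
            for s in samples
        }
        sub_outputs = [p for pair in sub_paths.values() for p in pair] + [
            outdir / "subsample_plan.tsv"
        ]

        def _subsample():
            rsets = {s: mio.read_readset(*final_reads_paths[s]) for s in samples}
            w = cfg["subsample"]["window"]
            tracks = [coverage_track(rs, w) for rs in rsets.values()]
            tgt = target_coverage(tracks, cfg["subsample"]["percentile"])
            logger.info("subsample target coverage: %.2fx", tgt)
            sub_rng = np.random.default_rng(stage_seeds["subsample"])
            plans = []
            for s in samples:
                rs_sub, plan = subsample(
                    rsets[s], tgt, w, cfg["subsample"]["tol"],
                    cfg["subsample"]["max_iter"], int(sub_rng.integers(2**31)),
                )
                mio.write_readset(rs_sub, *sub_paths[s])
                plans.append(
                    (s, plan.target_coverage, plan.mean_read_length,
                     plan.iterations_used, plan.median_relative_error)
                )
            pd.DataFrame(
                plans,
                columns=["sample", "target_coverage", "mean_read_length",
                         "iterations_used", "median_relative_error"],
            ).to_csv(outdir / "subsample_plan.tsv", sep="\t", index=False)

        _run_stage("subsample", [p for pair in final_reads_paths.values() for p in pair],
                   sub_outputs, _subsample)
        final_reads_paths = sub_paths

    # ---- stage: signals (event tables) ----
    events_paths = {s: outdir / f"events_{s}.tsv.gz" for s in samples}
    model = SignalModel(
        sigma=cfg["signal"]["sigma"], delta_6mA=cfg["signal"]["delta_6mA"],
        delta_5mC=cfg["signal"]["delta_5mC"], halfwidth_k=cfg["signal"]["halfwidth_k"],
        baseline_seed=cfg["signal"]["baseline_seed"],
    )

    def _signals():
        sig_rng = np.random.default_rng(stage_seeds["signals"])
        for s in samples:
            rs = mio.read_readset(*final_reads_paths[s])
            events = simulate_signals(rs, model, int(sig_rng.integers(2**31)))
            mio.write_events(events, events_paths[s])

    _run_stage("signals", [p for pair in final_reads_paths.values() for p in pair],
               list(events_paths.values()), _signals)

    # ---- stage: diff (per-condition difference tables) ----
    diff_paths = {c: outdir / f"diff_{c}.tsv" for c in conditions}

    def _diff():
        wga_events = mio.read_events(events_paths["wga"])
        for c in conditions:
            native_events = mio.read_events(events_paths[c])
            diff = difference_table(native_events, wga_events, cfg["diff"]["min_cov"])
            logger.info("diff %s: %d positions", c, len(diff))
            mio.write_diff(diff, diff_paths[c])

    _run_stage("diff", list(events_paths.values()), list(diff_paths.values()), _diff)

    # ---- stage: call (empirical null + binary site calls) ----
    null_paths = {c: outdir / f"null_{c}.tsv" for c in conditions}
    call_paths = {
        (c, m.name): outdir / f"calls_{c}_{m.name}.tsv"
        for c in conditions for m in motif_defs
    }
    bed_paths = {
        (c, m.name): outdir / f"calls_{c}_{m.name}.bed"
        for c in conditions for m in motif_defs
    }

    def _call():
        genome = mio.read_genome_fasta(genome_path)
        region_end = min(cfg["null"]["region_end"], genome.length)
        null_rng = np.random.default_rng(stage_seeds["null"])
        for c in conditions:
            diff = mio.read_diff(diff_paths[c])
            null = build_null(
                diff, genome, cfg["null"]["n_sites"], region_end,
                int(null_rng.integers(2**31)), cfg["null"]["percentile"],
            )
            mio.write_null(null, null_paths[c])
            for mdef in motif_defs:
                sites = mio.read_sites_tsv(sites_paths[mdef.name])
                calls = classify_sites(sites, diff, null, c)
                mio.write_calls_tsv(calls, call_paths[(c, mdef.name)])
                mio.write_calls_bed(
                    calls, bed_paths[(c, mdef.name)], genome.contig_id, len(mdef.iupac)
                )

    _run_stage("call", list(diff_paths.values()),
               list(null_paths.values()) + list(call_paths.values()) + list(bed_paths.values()),
               _call)

    # ---- stage: windows (profiles + pairwise correlations) ----
    profile_paths = {
        (c, m.name): outdir / f"windows_{c}_{m.name}.tsv"
        for c in conditions for m in motif_defs
    }
    corr_paths = (
        {m.name: outdir / f"correlations_{m.name}.tsv" for m in motif_defs}
        if len(conditions) >= 2
        else {}
    )

    def _windows():
        genome = mio.read_genome_fasta(genome_path)
        w = cfg["windows"]["size"]
        profiles: dict[str, dict] = {m.name: {} for m in motif_defs}
        for c in conditions:
            rs = mio.read_readset(*final_reads_paths[c])
            wga_rs = mio.read_readset(*final_reads_paths["wga"])
            cov_n = coverage_track(rs, w)
            cov_w = coverage_track(wga_rs, w)
            for mdef in motif_defs:
                sites = mio.read_sites_tsv(sites_paths[mdef.name])
                calls = mio.read_calls_tsv(call_paths[(c, mdef.name)])
                prof = window_fractions(
                    calls, sites, genome.length, w, cov_n, cov_w, c, mdef.name
                )
                mio.write_profile(prof, profile_paths[(c, mdef.name)])
                profiles[mdef.name][c] = prof
        for mdef in motif_defs:
            if len(conditions) < 2:
                continue
            try:
                results = pairwise_condition_matrix(profiles[mdef.name])
            except InsufficientDataError as exc:
                logger.warning("correlation matrix for %s skipped: %s", mdef.name, exc)
                continue
            except ValueError as exc:
                # too few windows for the coverage covariates (or collinear
                # tracks on a tiny genome): fall back to plain Pearson
                logger.warning(
                    "coverage-adjusted correlations for %s unavailable (%s); "
                    "reporting plain Pearson", mdef.name, exc,
                )
                try:
                    results = pairwise_condition_matrix(
                        profiles[mdef.name], covariates="none"
                    )
                except InsufficientDataError as exc2:
                    logger.warning(
                        "correlation matrix for %s skipped: %s", mdef.name, exc2
                    )
                    continue
            mio.write_correlations(results, corr_paths[mdef.name])

    _run_stage("windows", list(call_paths.values()),
               list(profile_paths.values()) + list(corr_paths.values()), _windows)

    # ---- stage: titrate (optional in-silico mixing) ----
    if cfg["titration"]["enabled"]:
        titration_path = outdir / "titration.tsv"

        def _titrate():
            genome = mio.read_genome_fasta(genome_path)
            native = mio.read_readset(*reads_paths[conditions[0]])
            wga = mio.read_readset(*wga_reads_path)
            motif_sites = {
                m.name: [s.focal_position for s in mio.read_sites_tsv(sites_paths[m.name])]
                for m in motif_defs
            }
            focus = np.unique(
                np.concatenate(
                    [np.asarray(v, dtype=np.int64) + d
                     for v in motif_sites.values() for d in (-1, 0, 1)]
                )
            )
            focus = focus[(focus >= 0) & (focus < genome.length)]
            ti_rng = np.random.default_rng(stage_seeds["titration"])
            tgt = cfg["titration"]["target_coverage"]
            control = mix_reads(native, wga, 0.0, tgt, int(ti_rng.integers(2**31)))
            control_ev = simulate_signals(
                control, model, int(ti_rng.integers(2**31)), positions=focus
            )
            tables = {}
            for frac in cfg["titration"]["fractions"]:
                mixed = mix_reads(native, wga, float(frac), tgt, int(ti_rng.integers(2**31)))
                ev = simulate_signals(
                    mixed, model, int(ti_rng.integers(2**31)), positions=focus
                )
                tables[float(frac)] = difference_table(ev, control_ev, cfg["diff"]["min_cov"])
            summary = summarize_titration(tables, motif_sites)
            summary.to_csv(titration_path, sep="\t", index=False)

        _run_stage("titrate", [genome_path], [titration_path], _titrate)

    # ---- stage: scan (optional long-range correlation grid) ----
    if cfg["scan"]["enabled"]:
        scan_paths = {
            (c, m.name): outdir / f"longrange_{c}_{m.name}.tsv"
            for c in conditions for m in motif_defs
        }

        def _scan():
            genome = mio.read_genome_fasta(genome_path)
            for c in conditions:
                for mdef in motif_defs:
                    sites = mio.read_sites_tsv(sites_paths[mdef.name])
                    calls = mio.read_calls_tsv(call_paths[(c, mdef.name)])
                    grid = long_range_scan(
                        calls, sites, genome.length,
                        [int(w) for w in cfg["scan"]["window_sizes"]],
                        [int(d) for d in cfg["scan"]["separations"]],
                    )
                    mio.write_grid(grid, scan_paths[(c, mdef.name)])

        _run_stage("scan", list(call_paths.values()), list(scan_paths.values()), _scan)

    manifest.to_json(manifest_path)
    logger.removeHandler(handler)
    handler.close()
    return manifest
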