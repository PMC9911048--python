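# methylwin

Quantitative, windowed analysis of bacterial DNA methylation from nanopore
sequencing, based on comparing the raw-signal levels of **native** DNA
(possibly methylated) against **whole-genome-amplified (WGA)** DNA, which
carries no modifications.

`methylwin` is for microbial epigenomics work of the kind where one asks not
*"is this site methylated?"* but *"which regions of the genome are more or
less methylated, and does that pattern depend on the growth condition?"* It
implements:

* **Per-position signal testing** — for every genomic position with
  sufficient coverage in both samples, a two-sided Mann–Whitney *U* test and
  a Welch *t* test compare native vs WGA signal observations, merged into a
  per-position difference table (`position`, `cov_native`, `cov_wga`,
  `mean_diff`, `u_pvalue`, `t_pvalue`).
* **Motif-site scoring and empirical-null calling** — each methyltransferase
  motif site (e.g. Dam `GATC` with 6mA at the adenine, Dcm `CCWGG` with 5mC
  at the second cytosine) is scored by
  `p_site = min(p_{f-1}, p_f, p_{f+1})` around the focal (modified) base,
  because the pore senses several bases at once. Sites are called
  *methylated* when `p_site` falls strictly below the 10th percentile of the
  same score at random genomic positions in the first 1 Mbp — an empirical
  null that fixes the false-positive rate at ~10% by design.
* **Coverage standardization** — detection power depends on coverage, so
  reads are subsampled per 10-kb window to a common target (the 5th
  percentile of per-window coverage across samples), drawing
  `round(target x window / mean_read_length)` reads originating in each
  window, with re-estimation of the mean read length if the realized
  coverage misses the target.
* **In-silico titration** — mixtures of 0/25/50/75/100% native reads at
  fixed coverage demonstrate that site p-values track the fraction of
  methylated molecules.
* **Window profiles and condition comparisons** — the fraction of motif
  sites called methylated in 10-kb windows (zero-site windows excluded),
  Pearson and coverage-adjusted partial correlations between growth
  conditions, the full pairwise condition matrix, and an
  autocorrelation-like long-range scan over window sizes and separations.
* **A synthetic-data module** — seeded generation of genomes, per-condition
  methylation landscapes (window base levels mixing shared and
  condition-specific profiles), reads with per-molecule Bernoulli
  methylation states, and Gaussian-shift signal tables, so the entire
  pipeline runs and is tested without any sequencing data.

## Worked example

```python
import methylwin as mw
from methylwin.signal_stats import difference_table
from methylwin.motif_analysis import build_null, classify_sites, scan_motifs
from methylwin.window_analysis import pairwise_condition_matrix, window_fractions

genome = mw.generate_genome(500_000, gc_fraction=0.5, seed=42)
dam_sites = scan_motifs(genome, mw.DAM)
print(f"GATC sites: {len(dam_sites)}")

landscapes = mw.build_landscape(
    genome, {"6mA": [s.focal_position for s in dam_sites]},
    ["m9_rep1", "m9_rep2"], window=10_000, rho=0.8, seed=42,
)
model = mw.SignalModel(delta_6mA=2.0)
wga = mw.simulate_reads(genome, None, coverage=50, seed=1)
ev_wga = mw.simulate_signals(wga, model, seed=2)

profiles = {}
for i, ls in enumerate(landscapes):
    native = mw.simulate_reads(genome, ls, coverage=50, seed=10 + i)
    ev = mw.simulate_signals(native, model, seed=20 + i)
    diff = difference_table(ev, ev_wga, min_cov=5)
    null = build_null(diff, genome, n_sites=1_000, region_end=genome.length, seed=30 + i)
    calls = classify_sites(dam_sites, diff, null, ls.condition)
    print(f"{ls.condition}: {calls['methylated'].mean():.1%} of "
          f"{len(calls)} sites called methylated "
          f"(null threshold p < {null.threshold:.3g})")
    profiles[ls.condition] = window_fractions(
        calls, dam_sites, genome.length, 10_000,
        condition=ls.condition, motif="DAM",
    )

(res,) = pairwise_condition_matrix(profiles, covariates="none")
print(f"window-fraction correlation r = {res.r:.2f} "
      f"(p = {res.pvalue:.2g}, {res.n_windows} windows)")
```

Output:

```
GATC sites: 1986
m9_rep1: 91.7% of 1979 sites called methylated (null threshold p < 0.0253)
m9_rep2: 91.0% of 1979 sites called methylated (null threshold p < 0.0272)
window-fraction correlation r = 0.85 (p = 6.3e-15, 50 windows)
```

Reading this: the two simulated replicate conditions share 80% of their
window-level methylation structure (`rho=0.8`), and the recovered
window-fraction profiles correlate strongly (r = 0.85 over the 50 10-kb
windows). "Methylated" here means *more methylated than the random-site
null* — with a strong 6mA signal shift, even sites with intermediate
per-molecule methylation probabilities clear the 10th-percentile threshold,
so the per-site call rate (≈91%) is a sensitivity statement, not a molecule
count.

## Command line

A `methylwin` console script exposes the stages individually
(`simulate`, `subsample`, `diff`, `call`, `compare`, `scan`, `titrate`) and
end to end (`run`), driven by one YAML config:

```bash
methylwin run --config config.yaml --seed 11 --outdir results/ --verbose
```

Every run writes a `manifest.json`; reruns with an unchanged config skip
completed stages unless `--force` is given, and a config plus its seed
reproduces every output table byte for byte.

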