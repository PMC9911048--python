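# Methods

## Overview

`methylwin` quantifies bacterial DNA methylation by contrasting nanopore
signal levels between a native sample and a whole-genome-amplified (WGA)
control. WGA erases all base modifications, so any reproducible per-position
signal difference between the two samples is evidence of a modification in
the native DNA. The analysis proceeds in five layers: per-position
two-sample tests, motif-site scoring, empirical-null binary classification,
coverage standardization, and windowed comparison across growth conditions.
A sixth component, the synthetic-data generator, produces inputs with the
statistical structure the analysis assumes and is the basis of the test
suite.

## Per-position testing

At every genomic position with at least `min_cov` observations (default 5)
in both samples, the native and WGA signal values are compared with a
two-sided Mann–Whitney *U* test and a Welch *t* test; the per-position
records (coverages, mean signal difference, both p-values) form the
difference table. Conventions, declared once and used everywhere:

* **Ties** take midranks, with the tie-corrected rank variance
  `var = nm/12 * ((N+1) - sum(t^3 - t)/(N(N-1)))`.
* **Small samples** (both n, m ≤ 8) use the exact two-sided p-value
  `P(|U - nm/2| >= |u_obs - nm/2|)` — from a cached tie-free null
  distribution of U (a subset-sum dynamic program over rank assignments),
  or, when ties are present, by explicit enumeration of all C(n+m, n)
  group-label assignments. The symmetric-tail form reproduces the textbook
  result p = 2/20 for n = m = 3 with complete separation.
* **Large samples** use the normal approximation with a 0.5 continuity
  correction. Both corrections are standard practice and improve small-n
  calibration; on split-sample null data the p-values are uniform to
  KS D < 0.02 at 10,000 positions (verified in the test suite).
* **Welch t at zero variance**: p = 1 when both groups are constant and
  equal, p = machine epsilon when constant and unequal.
* Strand is not a dimension: all reads contribute to one test per genomic
  position, giving one p-value per location.

## Motif sites and the empirical null

Motifs are IUPAC patterns with a declared focal (modified) base — Dam
`GATC` (6mA at offset 1) and Dcm `CCWGG` (5mC at offset 1) are built in.
Patterns closed under reverse complement are scanned on the forward strand
only, so each double-stranded locus is counted once; non-palindromic motifs
are scanned in both orientations with the focal position mirrored on the
minus strand.

Because the pore senses ~5 bases at once, the strongest signal deviation
need not sit exactly on the modified base. A site's score is therefore the
minimum *U*-test p-value over the focal base and its two neighbors. The
classification threshold is empirical: the same min-over-±1 score is
computed at random positions drawn uniformly without replacement from the
first 1 Mbp (assumed overwhelmingly unmethylated), and the threshold is the
10th percentile of those null scores. A site is called *methylated* when
its score is **strictly below** the threshold, which by construction yields
a ~10% false-positive rate on truly unmethylated sites; this calibration is
asserted at 3 binomial standard deviations in the acceptance tests. Random
null positions are *not* excluded from motif neighborhoods (they are
presumed unmethylated as drawn); an exclusion option exists for purified
nulls. One null is built per condition and reused across motifs.

The binary call is deliberately modest in meaning: it separates *more*
methylated from *less* methylated sites relative to background, not
methylated molecules from unmethylated ones, and it cannot distinguish
hemi-methylation from heterogeneous methylation across molecules.

## Quantile convention

Every percentile in the package (the coverage target, the null threshold)
uses a single declared rule, nearest-rank-lower: `sorted[ceil(p/100 * n) - 1]`.
This makes the worked examples exact — the 5th percentile of the values
1..100 is 5, and the 10th percentile of ten values is the smallest — and
guarantees that strictly fewer than p% of a null's own scores fall below
its threshold.

## Coverage standardization

The probability of detecting a modification rises with coverage, so read
sets are subsampled before testing. The target is the 5th percentile of
pooled per-window coverage across samples (per-window, not per-base; the
choice is parameterized). For each 10-kb window,
`round(target x window / mean_read_length)` reads *originating within* the
window (start coordinate inside it) are drawn without replacement — e.g.
500 reads for a 100x target with 2-kb reads. Because reads extend past
their window, coverage deliberately bleeds downstream. If the realized
median per-window relative error exceeds `tol` (default 0.1), the mean read
length is re-estimated from the drawn subsample and the draw repeated, up
to `max_iter` (default 5) iterations, keeping the best iterate; windows
with too few originating reads contribute everything they have and log a
warning rather than failing.

## Windowed analysis

For each condition and motif, the genome is tiled into 10-kb windows
(the last window may be short). A window's denominator is the number of
motif sites it contains, the numerator the number called methylated;
windows with no sites are excluded (division by zero), and the weighted
mean of included windows equals the genome-wide methylated fraction
exactly. An optional normalization divides each fraction by the
genome-wide mean of included windows (output mean exactly 1).

Condition pairs are compared on the intersection of their included
windows, by Pearson correlation or by a partial correlation that
residualizes both fraction vectors on an intercept plus coverage
covariates (each condition's per-window native coverage and the mean WGA
coverage — three vectors by default, configurable). The partial-correlation
p-value uses n − 2 − k degrees of freedom; with no covariates it reduces
exactly to Pearson. Correlations are computed on raw fractions by default
(normalization is a presentation aid); the pairwise matrix reports
unadjusted p-values with an optional Benjamini–Hochberg flag. Collinear
covariates raise an error naming the offending columns; in the end-to-end
pipeline, runs with too few windows to support the covariates fall back to
plain Pearson with a logged warning.

The long-range scan generalizes this to an autocorrelation-like probe: for
each window size w, fractions are computed on a tiling of step w, and each
cell (w, d) correlates `fraction(x)` with `fraction(x + w + d)` — d is the
gap between the end of the first window and the start of the second, so
d = 0 means adjacent windows and d = −w is the degenerate self-lag
(r = 1). Separations are snapped to the tiling grid; zero-site windows are
dropped pairwise and cells with fewer than 3 valid pairs are reported as
missing rather than raising.

## In-silico titration

To show that p-values track the fraction of methylated molecules, read
pools are mixed at native fractions {0, 0.25, 0.5, 0.75, 1} to a common
50x coverage target (read counts chosen from each pool's mean read length)
and each mixture is tested against a pure-WGA control of the same depth.
The summary reports quartiles of site p-values per (motif, fraction); the
median is non-increasing in the native fraction, and the 5mC (Dcm) medians
fall far below the 6mA (Dam) medians at full native fraction because the
cytosine modification perturbs the signal more strongly.

## The synthetic-data generator

The generator emulates exactly the features the analysis relies on and
nothing more:

* **Genome**: i.i.d. bases with configurable GC fraction. Real genomes have
  k-mer structure and motif clustering; none of the analyses here depend on
  that, only on motif counts and positions.
* **Methylation landscape**: each condition's per-window base level is
  `rho * shared + (1 - rho) * specific`, with both profiles i.i.d.
  Beta(2, 2) per 10-kb window and `rho` the shared-structure weight; a
  site's per-molecule methylation probability theta is its window's base
  level plus clipped Normal(0, 0.05) site noise. Beta(2, 2) puts most mass
  at intermediate levels with meaningful window-to-window spread — the
  regime in which window fractions are informative; for equal-variance
  profiles the expected correlation between two conditions' base levels is
  `rho^2 / (rho^2 + (1-rho)^2)`, verified by simulation. Sites are
  independent across molecules; hemi-methylation and strand identity are
  not modeled (the classifier cannot resolve them anyway).
* **Reads**: uniform start positions, geometric lengths (mean 5 kb by
  default) truncated at the contig end, no circular wrap. Native molecules
  draw an independent Bernoulli(theta) methylation state at every covered
  site; WGA reads carry no marks.
* **Signals**: `signal = baseline(pos) + delta * 1[methylated focal within
  k bases] + Normal(0, sigma)`. The baseline is a seeded function of
  position only (Normal(90, 8) in arbitrary current units), shared exactly
  between samples, standing in for sequence-dependent pore current; it is
  not a k-mer pore model. Defaults sigma = 1.0, delta_5mC = 1.2,
  delta_6mA = 0.5, halfwidth k = 2: the 5mC/6mA asymmetry reproduces the
  empirically observed difference in test sensitivity between Dcm and Dam
  sites at 50x coverage, and k = 2 reflects the multi-base pore footprint.
  The shift magnitudes are calibration choices for the generator, not
  measured pore physics.

Consequently, passing tests demonstrate that the *statistical machinery* is
correct and calibrated under its own assumptions (binomial sampling, local
Gaussian shifts, coverage variation); they do not validate pore chemistry,
basecalling, alignment, or sequence-context effects on methyltransferase
activity, none of which the generator models.

## Numerical and design choices

* Coordinates are 0-based, half-open throughout; window k covers
  `[k*W, (k+1)*W)`.
* Ties at the classification threshold are *not* methylated (strict `<`);
  ties in candidate-region ranking are broken by a seeded shuffle.
* Candidate-region export samples positions from those present in the
  difference table (positions without a p-value cannot be ranked), ranks
  by u_pvalue ascending, and emits ±10 bp flanks by default (flank width
  configurable) for external motif-discovery tools; motif discovery itself
  is out of scope.
* Unscorable random null draws (no coverage near the position) are replaced
  by further draws so the null always has its requested size when the
  region allows.
* The end-to-end pipeline derives all stage seeds from the single config
  seed, iterates conditions and motifs in config order, and re-reads each
  stage's inputs from the previous stage's files, so a config fully
  determines every output byte.
* Event tables can be simulated on a restricted position set (e.g. motif
  neighborhoods ± 1 plus null positions) — each emitted observation is
  identical in law to the unrestricted case, and the restriction keeps
  genome-scale calibration runs to seconds.

## Problem sizes used in the checks

The false-positive calibration runs on a 1-Mbp genome at 50x native + 50x
WGA with a 1,000-position null and all (~3,900) GATC sites; motif density
and window tiling use a 5-Mbp genome; titration uses a 100-kb genome with
a fully methylated landscape at 50x; correlation recovery uses a 2-Mbp
genome (200 windows, ~40 GATC sites per window) at 50x with a strong
(delta = 2) shift; the end-to-end pipeline tests use a 30-kb genome. These
sizes keep every run deterministic and small while leaving the binomial
tolerances meaningful.

## Known limitations

* The signal model is a fixed-baseline Gaussian shift, not a k-mer pore
  model; absolute p-value magnitudes in simulation should not be read as
  predictions for real flowcells.
* Modification chemistry is assumed known per motif (6mA vs 5mC typing is
  out of scope), and methylation states are per-molecule, not per-strand.
* The classifier's "methylated" is relative to the random-site null; it is
  a ranking device with a designed 10% false-positive rate, not a
  molecule-fraction estimate.
* Whether real preprocessing pipelines pool strands in their per-position
  tests is tool-dependent; this package pools.
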