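"""Motif scanning, site scoring, the empirical null, and binary calls."""

import numpy as np
import pandas as pd
import pytest

import methylwin as mw
from methylwin import DAM, DCM, Genome, MotifDefinition, SignalModel
from methylwin.motif_analysis import (
    NullDistribution,
    build_null,
    classify_sites,
    extract_candidate_regions,
    scan_motifs,
    site_pvalue,
)
from methylwin.signal_stats import difference_table


def _diff_from_pvalues(pvals: dict) -> pd.DataFrame:
    pos = np.array(sorted(pvals), dtype=np.int64)
    return pd.DataFrame(
        {
            "position": pos,
            "cov_native": 20,
            "cov_wga": 20,
            "mean_diff": 0.0,
            "u_pvalue": [pvals[p] for p in pos],
            "t_pvalue": [pvals[p] for p in pos],
        }
    )


class TestScanMotifs:
    def test_dam_site_in_ggatcc(self):
        sites = scan_motifs(Genome("c", "GGATCC"), DAM)
        assert len(sites) == 1
        assert (sites[0].start, sites[0].focal_position, sites[0].strand) == (1, 2, "+")

    def test_dcm_site_with_w_degeneracy(self):
        sites = scan_motifs(Genome("c", "ACCAGGT"), DCM)
        assert len(sites) == 1
        assert (sites[0].start, sites[0].focal_position) == (1, 2)

    def test_non_palindromic_motif_scanned_on_both_strands(self):
        motif = MotifDefinition("GAGCC", "GAGCC", 1, "6mA", rc_closed=False)
        sites = scan_motifs(Genome("c", "GAGCC" + "GGCTC"), motif)
        assert [(s.start, s.strand, s.focal_position) for s in sites] == [
            (0, "+", 1),
            (5, "-", 8),
        ]

    def test_invalid_iupac_symbol_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            scan_motifs(Genome("c", "ACGT"), MotifDefinition("Z", "AZC", 0, "6mA"))

    def test_reverse_complement_symmetry(self, genome_20k):
        from Bio.Seq import reverse_complement

        fwd = scan_motifs(genome_20k, DAM)
        rc_genome = Genome("rc", reverse_complement(genome_20k.sequence))
        rev = scan_motifs(rc_genome, DAM)
        assert len(fwd) == len(rev)
        L = genome_20k.length
        mirrored = sorted(L - s.start - len(DAM.iupac) for s in rev)
        assert mirrored == [s.start for s in fwd]

    def test_sites_sorted_and_overlaps_reported(self):
        sites = scan_motifs(Genome("c", "GATCGATC" + "AA" + "GATC"), DAM)
        starts = [s.start for s in sites]
        assert starts == sorted(starts)
        assert len(sites) == 3


class TestSitePvalue:
    def test_minimum_over_three_positions(self):
        d = _diff_from_pvalues({99: 0.2, 100: 0.5, 101: 0.05})
        assert site_pvalue(d, 100) == pytest.approx(0.05)

    def test_sentinel_when_uncovered(self):
        d = _diff_from_pvalues({0: 0.9})
        assert np.isnan(site_pvalue(d, 500))


class TestBuildNull:
    def test_exact_count_contract(self):
        rng = np.random.default_rng(1)
        d = _diff_from_pvalues({p: rng.uniform() for p in range(1_000)})
        null = build_null(d, 1_000, n_sites=100, region_end=1_000, seed=2)
        assert null.n_sites == len(null.pvalues) == 100

    def test_percentile_rule_on_ten_values(self):
        # p-values 0.05..0.95 at isolated positions; 10th pct -> lowest value
        pv = {10 * i: 0.05 + 0.1 * i for i in range(10)}
        d = _diff_from_pvalues(pv)
        null = build_null(
            d, 1_000, n_sites=10, region_end=1_000, seed=3,
            positions=list(pv.keys()),
        )
        assert null.threshold == pytest.approx(0.05)

    def test_uniform_null_threshold_converges(self):
        rng = np.random.default_rng(4)
        positions = np.arange(0, 30_000, 3)[:10_000]
        d = _diff_from_pvalues({int(p): rng.uniform() for p in positions})
        null = build_null(d, 30_000, n_sites=10_000, region_end=30_000, seed=5,
                          positions=positions)
        assert null.threshold == pytest.approx(0.10, abs=0.01)

    def test_threshold_tautology_holds_on_random_builds(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            d = _diff_from_pvalues({p: rng.uniform() for p in range(2_000)})
            null = build_null(d, 2_000, n_sites=333, region_end=2_000, seed=seed)
            assert (null.pvalues < null.threshold).mean() <= 0.10

    def test_region_and_size_preconditions(self):
        d = _diff_from_pvalues({0: 0.5})
        with pytest.raises(ValueError):
            build_null(d, 500, n_sites=10, region_end=1_000, seed=1)
        with pytest.raises(ValueError):
            build_null(d, 1_000, n_sites=0, region_end=1_000, seed=1)


class TestClassifySites:
    def _null(self, threshold):
        return NullDistribution(np.linspace(0, 1, 100), (0, 1_000), 100, 10.0, threshold)

    def test_strictly_below_threshold_is_methylated(self):
        sites = [mw.MotifSite("DAM", 99, "+", 100), mw.MotifSite("DAM", 199, "+", 200),
                 mw.MotifSite("DAM", 299, "+", 300)]
        d = _diff_from_pvalues({100: 0.01, 200: 0.05, 300: 0.5})
        calls = classify_sites(sites, d, self._null(0.05), "c1")
        got = dict(zip(calls["focal_position"], calls["methylated"]))
        assert got == {100: True, 200: False, 300: False}  # tie is NOT methylated

    def test_uncovered_sites_dropped(self):
        sites = [mw.MotifSite("DAM", 99, "+", 100), mw.MotifSite("DAM", 899, "+", 900)]
        d = _diff_from_pvalues({100: 0.01})
        calls = classify_sites(sites, d, self._null(0.05), "c1")
        assert calls["focal_position"].tolist() == [100]

    def test_empty_site_list_gives_empty_frame(self):
        calls = classify_sites([], _diff_from_pvalues({0: 0.5}), self._null(0.1))
        assert len(calls) == 0

    def test_full_methylation_power_dcm(self):
        # theta=1 DCM landscape at 50x with the default 5mC shift: >90% called
        genome = mw.generate_genome(100_000, 0.5, seed=6)
        dcm_sites = scan_motifs(genome, DCM)
        focals = np.array([s.focal_position for s in dcm_sites])
        ls = mw.MethylationLandscape(
            "full", {int(p): 1.0 for p in focals}, {int(p): "5mC" for p in focals},
            np.ones(10), 10_000,
        )
        rng = np.random.default_rng(7)
        null_pos = rng.choice(100_000, 400, replace=False)
        focus = np.unique(
            np.concatenate([focals + d for d in (-1, 0, 1)]
                           + [null_pos + d for d in (-1, 0, 1)])
        )
        focus = focus[(focus >= 0) & (focus < 100_000)]
        nat = mw.simulate_reads(genome, ls, 50, 5_000, seed=8)
        wga = mw.simulate_reads(genome, None, 50, 5_000, seed=9)
        model = SignalModel()
        diff = difference_table(
            mw.simulate_signals(nat, model, 10, positions=focus),
            mw.simulate_signals(wga, model, 11, positions=focus),
            min_cov=5,
        )
        null = build_null(diff, genome, 400, region_end=100_000, positions=null_pos)
        calls = classify_sites(dcm_sites, diff, null, "full")
        assert calls["methylated"].mean() > 0.9


class TestExtractCandidateRegions:
    def test_count_contract_and_tie_degeneracy(self):
        d = _diff_from_pvalues({p: 0.5 for p in range(5_000)})
        genome = mw.generate_genome(5_000, 0.5, seed=1)
        recs_a = extract_candidate_regions(d, genome, 2_000, 500, flank=5, seed=1)
        recs_b = extract_candidate_regions(d, genome, 2_000, 500, flank=5, seed=2)
        assert len(recs_a) == 500
        # all p equal: the selection is a seeded random subset, so seeds differ
        assert {r.id for r in recs_a} != {r.id for r in recs_b}

    def test_flank_clipping_at_genome_bounds(self):
        d = _diff_from_pvalues({0: 0.001, 10: 0.5, 20: 0.9})
        genome = Genome("c", "ACGT" * 10)
        (rec,) = extract_candidate_regions(d, genome, 3, 1, flank=5, seed=1)
        assert rec.id == "c:0-6"
        assert len(rec.seq) == 6

    def test_planted_methylation_enriches_gatc_in_top_flanks(self, genome_20k):
        # fully methylated GATC landscape: GATC should be over-represented in
        # the lowest-p flanks relative to the sampled background
        dam_sites = scan_motifs(genome_20k, DAM)
        focals = np.array([s.focal_position for s in dam_sites])
        ls = mw.MethylationLandscape(
            "full", {int(p): 1.0 for p in focals}, {int(p): "6mA" for p in focals},
            np.ones(2), 10_000,
        )
        nat = mw.simulate_reads(genome_20k, ls, 30, 2_000, seed=2)
        wga = mw.simulate_reads(genome_20k, None, 30, 2_000, seed=3)
        model = SignalModel(delta_6mA=2.0)
        diff = difference_table(
            mw.simulate_signals(nat, model, 4),
            mw.simulate_signals(wga, model, 5),
            min_cov=5,
        )
        top = extract_candidate_regions(diff, genome_20k, 10_000, 300, flank=10, seed=6)
        rate_top = np.mean(["GATC" in str(r.seq) for r in top])
        rng = np.random.default_rng(7)
        background = rng.integers(10, genome_20k.length - 10, 2_000)
        rate_bg = np.mean(
            ["GATC" in genome_20k.sequence[p - 10 : p + 11] for p in background]
        )
        assert rate_top > 3 * rate_bg

    def test_preconditions(self):
        d = _diff_from_pvalues({p: 0.5 for p in range(100)})
        genome = mw.generate_genome(100, 0.5, seed=1)
        with pytest.raises(ValueError):
            extract_candidate_regions(d, genome, 200, 10, flank=5, seed=1)
        with pytest.raises(ValueError):
            extract_candidate_regions(d, genome, 50, 60, flank=5, seed=1)
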