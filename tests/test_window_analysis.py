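"""Window fractions, normalization, (partial) correlations, and the scan."""

import numpy as np
import pandas as pd
import pytest

from methylwin.motif_analysis import MotifSite
from methylwin.window_analysis import (
    CollinearityError,
    InsufficientDataError,
    long_range_scan,
    normalize_profile,
    pairwise_condition_matrix,
    partial_correlation,
    pearson,
    window_fractions,
)


def _sites(focals, motif="DAM"):
    return [MotifSite(motif, int(f) - 1, "+", int(f)) for f in focals]


def _calls(focals, methylated, condition="c", motif="DAM"):
    return pd.DataFrame(
        {
            "condition": condition,
            "motif": motif,
            "start": np.asarray(focals) - 1,
            "strand": "+",
            "focal_position": np.asarray(focals, dtype=np.int64),
            "site_pvalue": 0.5,
            "methylated": np.asarray(methylated, dtype=bool),
        }
    )


class TestWindowFractions:
    def test_fraction_arithmetic(self):
        focals = np.arange(100, 4_100, 100)  # 40 sites in window 0
        meth = np.zeros(40, dtype=bool)
        meth[:10] = True
        prof = window_fractions(_calls(focals, meth), _sites(focals), 10_000, 10_000)
        assert prof.table["fraction"].tolist() == [0.25]
        assert prof.table["n_sites"].tolist() == [40]

    def test_zero_site_window_excluded(self):
        focals = [500, 25_000]  # windows 0 and 2; window 1 has no sites
        prof = window_fractions(
            _calls(focals, [True, False]), _sites(focals), 30_000, 10_000
        )
        assert prof.table["start"].tolist() == [0, 20_000]
        assert prof.excluded_windows == [10_000]

    def test_five_mbp_genome_tiles_five_hundred_windows(self):
        focals = np.arange(5_000, 5_000_000, 10_000)
        prof = window_fractions(
            _calls(focals, np.ones(len(focals), bool)), _sites(focals),
            5_000_000, 10_000,
        )
        assert len(prof.table) + len(prof.excluded_windows) == 500

    def test_weighted_mean_conservation_exact(self):
        rng = np.random.default_rng(1)
        focals = np.sort(rng.choice(200_000, 800, replace=False))
        meth = rng.random(800) < 0.3
        prof = window_fractions(_calls(focals, meth), _sites(focals), 200_000, 10_000)
        t = prof.table
        genome_wide = meth.sum() / 800
        assert t["n_methylated"].sum() / t["n_sites"].sum() == pytest.approx(
            genome_wide, abs=1e-15
        )

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError):
            window_fractions(_calls([5], [True]), _sites([5]), 100, 0)


class TestNormalizeProfile:
    def _profile(self, fractions):
        focals = np.arange(len(fractions)) * 10_000 + 100
        meth = np.ones(len(fractions), bool)
        prof = window_fractions(
            _calls(focals, meth), _sites(focals), len(fractions) * 10_000, 10_000
        )
        prof.table["fraction"] = fractions
        return prof

    def test_worked_example(self):
        out = normalize_profile(self._profile([0.5, 1.0]))
        assert out.table["fraction"].tolist() == pytest.approx([2 / 3, 4 / 3])

    def test_constant_profile_maps_to_ones(self):
        out = normalize_profile(self._profile([0.4, 0.4, 0.4]))
        assert out.table["fraction"].tolist() == pytest.approx([1.0, 1.0, 1.0])

    def test_output_mean_is_one(self):
        rng = np.random.default_rng(2)
        out = normalize_profile(self._profile(rng.random(50)))
        assert out.table["fraction"].mean() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_fractions_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalize_profile(self._profile([0.0, 0.0]))


class TestPearson:
    def test_affine_invariance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, _ = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        r, _ = pearson([1, 2, 3, 4], [4, 3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_hand_computed_half(self):
        r, _ = pearson([1, 2, 3], [1, 3, 2])
        assert r == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 1, 1], [1, 2, 3])


class TestPartialCorrelation:
    def test_no_covariates_reduces_to_pearson(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=30), rng.normal(size=30)
        r0, p0 = pearson(x, y)
        r1, p1 = partial_correlation(x, y, [])
        assert r1 == pytest.approx(r0, abs=1e-12)
        assert p1 == pytest.approx(p0, rel=1e-9)

    def test_closed_form_one_third(self):
        # exact sample correlations r_xy = r_xz = r_yz = 0.5 constructed from
        # centered orthonormal vectors; partial r = (0.5 - 0.25) / 0.75 = 1/3
        rng = np.random.default_rng(4)
        M = rng.normal(size=(12, 3))
        M -= M.mean(axis=0)
        Q, _ = np.linalg.qr(M)
        u1, u2, u3 = Q[:, 0], Q[:, 1], Q[:, 2]
        x = u1
        y = 0.5 * u1 + np.sqrt(0.75) * u2
        c2 = 0.25 / np.sqrt(0.75)
        z = 0.5 * u1 + c2 * u2 + np.sqrt(1 - 0.25 - c2**2) * u3
        r, _ = partial_correlation(x, y, [z])
        assert r == pytest.approx(1 / 3, abs=1e-10)

    def test_degenerate_residual_rejected(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        z = rng.normal(size=20)
        with pytest.raises(ValueError, match="residual variance"):
            partial_correlation(x, z.copy(), [z])

    def test_collinear_covariates_named(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=20), rng.normal(size=20)
        z = rng.normal(size=20)
        with pytest.raises(CollinearityError, match="dup"):
            partial_correlation(x, y, [z, 2 * z], covariate_names=["z", "dup"])


def _profile_from_fractions(fractions, condition, cov=None, wga_cov=None, motif="DAM"):
    focals = (np.arange(len(fractions)) * 10_000 + 100).astype(np.int64)
    prof = window_fractions(
        _calls(focals, np.ones(len(fractions), bool), condition, motif),
        _sites(focals, motif),
        len(fractions) * 10_000,
        10_000,
        condition=condition,
        motif=motif,
    )
    prof.table["fraction"] = np.asarray(fractions, dtype=float)
    if cov is not None:
        prof.table["mean_cov_native"] = cov
        prof.table["mean_cov_wga"] = wga_cov if wga_cov is not None else cov
    return prof


class TestPairwiseConditionMatrix:
    def test_six_conditions_fifteen_pairs(self):
        rng = np.random.default_rng(7)
        profiles = {
            f"c{i}": _profile_from_fractions(rng.random(30), f"c{i}") for i in range(6)
        }
        results = pairwise_condition_matrix(profiles, covariates="none")
        assert len(results) == 15

    def test_self_pair_correlation_is_one(self):
        rng = np.random.default_rng(8)
        frac = rng.random(25)
        profiles = {
            "a": _profile_from_fractions(frac, "a"),
            "b": _profile_from_fractions(frac, "b"),
        }
        (res,) = pairwise_condition_matrix(profiles, covariates="none")
        assert res.r == pytest.approx(1.0)
        assert res.n_windows == 25

    def test_too_few_shared_windows_raises(self):
        profiles = {
            "a": _profile_from_fractions([0.1, 0.5], "a"),
            "b": _profile_from_fractions([0.2, 0.6], "b"),
        }
        with pytest.raises(InsufficientDataError):
            pairwise_condition_matrix(profiles, covariates="none")

    def test_replicates_beat_cross_condition_pairs(self):
        # two profiles sharing 90% of their structure correlate more strongly
        # than either does with a 30%-shared profile, in >=95/100 trials
        wins = 0
        for trial in range(100):
            rng = np.random.default_rng(trial)
            shared = rng.normal(size=200)
            rep1 = 0.9 * shared + np.sqrt(1 - 0.81) * rng.normal(size=200)
            rep2 = 0.9 * shared + np.sqrt(1 - 0.81) * rng.normal(size=200)
            cross = 0.3 * shared + np.sqrt(1 - 0.09) * rng.normal(size=200)
            r_rep, _ = pearson(rep1, rep2)
            r_cross, _ = pearson(rep1, cross)
            wins += r_rep > r_cross
        assert wins >= 95

    def test_coverage_covariates_used_when_available(self):
        rng = np.random.default_rng(9)
        profiles = {
            "a": _profile_from_fractions(
                rng.random(40), "a",
                cov=rng.uniform(20, 60, 40), wga_cov=rng.uniform(40, 80, 40),
            ),
            "b": _profile_from_fractions(
                rng.random(40), "b",
                cov=rng.uniform(20, 60, 40), wga_cov=rng.uniform(40, 80, 40),
            ),
        }
        (res,) = pairwise_condition_matrix(profiles, covariates="coverage")
        assert set(res.covariates) == {"cov_native_a", "cov_native_b", "cov_wga"}

    def test_bh_adjustment_keeps_r_and_bounds_p(self):
        rng = np.random.default_rng(10)
        profiles = {
            f"c{i}": _profile_from_fractions(rng.random(30), f"c{i}") for i in range(4)
        }
        raw = pairwise_condition_matrix(profiles, covariates="none")
        adj = pairwise_condition_matrix(profiles, covariates="none", adjust="bh")
        for r0, r1 in zip(raw, adj):
            assert r1.r == r0.r
            assert r1.pvalue >= r0.pvalue - 1e-15


class TestLongRangeScan:
    def _data(self, frac_per_window, w=1_000, sites_per_window=5):
        focals, meth = [], []
        for i, f in enumerate(frac_per_window):
            k = int(round(f * sites_per_window))
            for j in range(sites_per_window):
                focals.append(i * w + 100 + j * 10)
                meth.append(j < k)
        return _calls(focals, meth), _sites(focals), len(frac_per_window) * w

    def test_self_lag_gives_unit_correlation(self):
        rng = np.random.default_rng(11)
        calls, sites, L = self._data(rng.random(100))
        grid = long_range_scan(calls, sites, L, [1_000], [-1_000])
        assert grid.r[0, 0] == pytest.approx(1.0)

    def test_iid_windows_show_no_long_range_structure(self):
        rng = np.random.default_rng(12)
        calls, sites, L = self._data(rng.random(1_200), sites_per_window=20)
        grid = long_range_scan(calls, sites, L, [1_000], [0, 5_000, 20_000])
        assert (grid.n_pairs >= 200).all()
        assert (np.abs(grid.r) < 0.1).all()

    def test_planted_periodicity_recovered(self):
        period = 10  # windows
        i = np.arange(600)
        frac = 0.5 + 0.4 * np.sin(2 * np.pi * i / period)
        calls, sites, L = self._data(frac, sites_per_window=20)
        seps = [(k - 1) * 1_000 for k in (3, 5, 10, 15, 20)]
        grid = long_range_scan(calls, sites, L, [1_000], seps)
        r = grid.r[0]
        assert r[2] > r[0] and r[2] > r[1]  # maximum at the planted period
        assert r[4] > r[1]  # and again at twice the period

    def test_sparse_cells_marked_missing(self):
        # sites only in the first two windows: no valid pair at a long lag
        focals = [100, 1_100]
        calls, sites, L = _calls(focals, [True, False]), _sites(focals), 20_000
        grid = long_range_scan(calls, sites, L, [1_000], [4_000])
        assert np.isnan(grid.r[0, 0])
        assert grid.n_pairs[0, 0] < 3

    def test_scale_preconditions(self):
        calls, sites, L = self._data([0.5] * 10)
        with pytest.raises(ValueError):
            long_range_scan(calls, sites, L, [L], [0])
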