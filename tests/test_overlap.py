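"""Overlap statistics, Fisher tests in log space, GSEA-style enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vmrkit import (
    expected_overlap,
    feature_distribution,
    fisher_overlap,
    fold_vs_expected,
    gsea_enrichment,
    overlap_test,
    overlap_with_track,
    signed_fold,
)


class TestExpectedOverlapAndFold:
    def test_mouse_vmr_age_overlap_counts(self):
        # universe 48,948 windows; 2,566 and 3,248 VMRs; expectation under
        # independence is nA*nB/N
        e = expected_overlap(2566, 3248, 48948)
        assert e == pytest.approx(170.27, abs=0.005)  # 2566*3248/48948
        assert fold_vs_expected(1345, e, round_to=0) == 8

    def test_rat_vmr_age_overlap_counts(self):
        e = expected_overlap(9872, 17418, 279439)
        assert e == pytest.approx(615.34, abs=0.005)
        assert fold_vs_expected(3589, e, round_to=0) == 6

    def test_empty_set_expects_zero(self):
        assert expected_overlap(0, 1000, 5000) == 0.0

    def test_saturated_sets_expect_universe(self):
        assert expected_overlap(100, 100, 100) == 100.0

    def test_observed_equal_expected_is_unit_fold(self):
        assert fold_vs_expected(170.28, 170.28) == pytest.approx(1.0)

    def test_invalid_universe_rejected(self):
        with pytest.raises(ValueError):
            expected_overlap(5, 5, 0)
        with pytest.raises(ValueError):
            fold_vs_expected(10, 0.0)


class TestSignedFold:
    @pytest.mark.parametrize(
        "frac_a, frac_b, digits, expected",
        [
            (44.2, 42.9, 2, 1.03),   # near-unity enrichment
            (4.51, 2.56, 2, 1.76),   # clear enrichment
            (6.14, 2.3, 1, 2.7),     # enrichment orientation of the same pair
            (2.3, 6.14, 1, -2.7),    # depletion is the negative reciprocal
            (0.31, 1.15, 1, -3.7),
            (7.5, 7.5, 2, 1.0),
        ],
    )
    def test_signed_convention(self, frac_a, frac_b, digits, expected):
        assert signed_fold(frac_a, frac_b, round_to=digits) == expected

    def test_zero_denominator_is_infinite_enrichment(self):
        assert signed_fold(5.0, 0.0) == math.inf
        assert signed_fold(0.0, 5.0) == -math.inf

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError):
            signed_fold(-1.0, 2.0)


class TestFisherOverlap:
    def test_unit_table_two_sided_p_one(self):
        p, _ = fisher_overlap(1, 2, 2, 4, sided="two-sided")
        assert p == pytest.approx(1.0)

    def test_full_overlap_small_universe_enumeration(self):
        # O=5 of nA=nB=5 in N=10: P(X=5) = C(5,5)C(5,0)/C(10,5) = 1/252
        p, log10_p = fisher_overlap(5, 5, 5, 10, sided="greater")
        assert p == pytest.approx(1 / 252)
        assert log10_p == pytest.approx(math.log10(1 / 252))

    def test_mouse_headline_table_extremely_significant(self):
        p, log10_p = fisher_overlap(1345, 2566, 3248, 48948, sided="greater")
        assert p < 1e-5
        assert log10_p < -100  # survives in log space far past float underflow

    def test_symmetric_in_the_two_sets(self):
        for sided in ("greater", "two-sided"):
            p1, _ = fisher_overlap(30, 100, 200, 1000, sided=sided)
            p2, _ = fisher_overlap(30, 200, 100, 1000, sided=sided)
            assert p1 == pytest.approx(p2)

    def test_two_sided_matches_scipy(self):
        for O, n_a, n_b, N in [(30, 100, 200, 1000), (3, 20, 15, 60), (0, 8, 8, 40)]:
            table = [[O, n_a - O], [n_b - O, N - n_a - n_b + O]]
            expected = stats.fisher_exact(table).pvalue
            p, _ = fisher_overlap(O, n_a, n_b, N, sided="two-sided")
            assert p == pytest.approx(expected, rel=1e-9)

    def test_inconsistent_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_overlap(10, 5, 20, 100)


class TestOverlapTest:
    def test_self_overlap_fold_and_ordering(self):
        universe = range(100)
        a = list(range(20))
        t_self = overlap_test(a, a, universe)
        assert t_self.observed == 20
        assert t_self.fold == pytest.approx(100 / 20)
        b = list(range(10, 30))  # half-overlapping set of equal size
        t_half = overlap_test(a, b, universe)
        assert t_self.p <= t_half.p
        assert t_self.log10_p <= t_half.log10_p

    def test_fold_sign_matches_direction(self):
        universe = range(100)
        depleted = overlap_test(range(50), range(50, 100), universe)
        assert depleted.observed == 0
        assert depleted.fold == -math.inf or depleted.fold < 0

    def test_subset_violation_rejected(self):
        with pytest.raises(ValueError):
            overlap_test([1, 200], [2], range(100))


class TestTrackOverlap:
    def test_one_bp_intersection_counts(self):
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        track = pd.DataFrame({"chrom": ["chr1"], "start": [99], "end": [200]})
        n, pct = overlap_with_track(regions, track)
        assert (n, pct) == (1, 100.0)

    def test_half_open_touching_does_not_count(self):
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        track = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})
        n, pct = overlap_with_track(regions, track)
        assert (n, pct) == (0, 0.0)

    def test_three_of_four_is_75_percent(self):
        regions = pd.DataFrame(
            {"chrom": "chr1", "start": [0, 100, 200, 300], "end": [100, 200, 300, 400]}
        )
        track = pd.DataFrame({"chrom": ["chr1"], "start": [50], "end": [250]})
        n, pct = overlap_with_track(regions, track)
        assert (n, pct) == (3, 75.0)


class TestGseaEnrichment:
    def test_running_sum_matches_brute_force(self):
        ids = np.arange(40)
        members = set(range(20))  # exactly the top half of the ranking
        curve = gsea_enrichment(ids, members, n_perm=100, seed=0)
        # independent recomputation of the unweighted running sum
        inc = np.array([1 / 20 if i in members else -1 / 20 for i in ids])
        expected = np.concatenate([[0.0], np.cumsum(inc)])
        np.testing.assert_allclose(curve.running, expected)
        assert curve.es == pytest.approx(1.0)  # peak after the last member
        assert curve.running[0] == 0.0
        assert curve.running[-1] == pytest.approx(0.0)
        assert abs(curve.es) <= 1.0 + 1e-9
        assert set(curve.leading_edge) == members

    def test_permutation_p_reproducible_and_seed_sensitive(self):
        rng = np.random.default_rng(5)
        ids = np.arange(100)
        members = rng.choice(100, 10, replace=False).tolist()
        c1 = gsea_enrichment(ids, members, n_perm=100, seed=3)
        c2 = gsea_enrichment(ids, members, n_perm=100, seed=3)
        assert c1.p_es == c2.p_es and c1.p_extremes == c2.p_extremes

    def test_null_p_values_uniform(self):
        # random membership: empirical ES p-value should be U(0, 1]
        rng = np.random.default_rng(8)
        pvals = []
        for _ in range(200):
            ids = np.arange(200)
            members = rng.choice(200, 20, replace=False).tolist()
            curve = gsea_enrichment(
                ids, members, n_perm=199, seed=int(rng.integers(2**31))
            )
            pvals.append(curve.p_es)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_empty_member_set_rejected(self):
        with pytest.raises(ValueError):
            gsea_enrichment(np.arange(10), [], n_perm=100)
        with pytest.raises(ValueError):
            gsea_enrichment(np.arange(10), [99], n_perm=100)

    def test_variance_inflation_concentrates_vmrs_at_both_extremes(self):
        from vmrkit import (
            call_dmrs,
            call_vmrs,
            dmr_test,
            filter_coverage,
            generate_truth,
            rank_by_change,
            simulate_counts,
            variance_threshold,
            window_variance,
        )

        truth = generate_truth(2000, 0.1, seed=2)
        sim = simulate_counts(truth, n_per_group=8, group_effect=3.0, seed=2002)
        mat = filter_coverage(sim.to_matrix())
        prof = window_variance(mat, "young")
        variance_threshold(prof)
        vmr, _ = call_vmrs(prof)
        ranked = rank_by_change(call_dmrs(dmr_test(mat, "young", "old")))
        curve = gsea_enrichment(ranked.index.to_numpy(), list(vmr), n_perm=499, seed=2)
        assert curve.p_extremes < 0.01
        # members pile up at both ends, not only one
        flags = curve.member_flags
        k = curve.extreme_k
        assert flags[:k].sum() > 0 and flags[-k:].sum() > 0


class TestFeatureDistribution:
    def _annotation(self):
        return pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr1"],
                "start": [0, 150, 150],
                "end": [200, 400, 300],
                "name": ["promoter", "exon", "enhancer"],
            }
        )

    def test_containment_counts_label(self):
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [10], "end": [90]})
        dist = feature_distribution(regions, self._annotation())
        assert dist.loc["promoter", "frac_multi"] == 1.0

    def test_fallback_label_for_orphans(self):
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [900], "end": [1000]})
        dist = feature_distribution(regions, self._annotation())
        assert dist.loc["intergenic", "frac_exclusive"] == 1.0

    def test_multi_assignment_counts_every_label(self):
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [160], "end": [190]})
        dist = feature_distribution(regions, self._annotation())
        for label in ("promoter", "exon", "enhancer"):
            assert dist.loc[label, "n_multi"] == 1
        # exclusive assignment resolves by priority (annotation order)
        assert dist.loc["promoter", "n_exclusive"] == 1
        assert dist.loc["exon", "n_exclusive"] == 0

    def test_empty_annotation_rejected(self):
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10]})
        with pytest.raises(ValueError):
            feature_distribution(regions, self._annotation().iloc[:0])
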