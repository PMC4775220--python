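import numpy as np
import pandas as pd
import pytest

import ripcall as rc
from oracles import exact_test_p
from ripcall.enrichment import (
    CONTROL_UP,
    RIP_UP,
    bh_adjust,
    count_in_peaks,
    estimate_dispersion,
    nb_exact_test,
    run_enrichment,
    significant_peaks,
    size_factors,
)
from ripcall.peaks import Peak
from ripcall.simulate import FragmentSet


def fragset(frags, sample_id="s1", condition="RIP", rep=1):
    df = pd.DataFrame(frags, columns=["chrom", "start", "end"])
    return FragmentSet(sample_id, condition, rep, df)


def peak(start, end, chrom="chr1"):
    return Peak(chrom, start, end, start, 1.0, 10.0)


class TestCountInPeaks:
    def test_midpoint_inside_counts(self):
        m = count_in_peaks([peak(150, 250)], [fragset([("chr1", 100, 300)])])
        assert m.counts[0, 0] == 1

    def test_midpoint_outside_not_counted(self):
        m = count_in_peaks([peak(250, 400)], [fragset([("chr1", 100, 300)])])
        assert m.counts[0, 0] == 0

    def test_column_conservation(self):
        frags = [("chr1", 100 + i, 200 + i) for i in range(10)]
        sets = [
            fragset(frags, "RIP_1", "RIP", 1),
            fragset([], "IgG_1", "control", 1),
        ]
        m = count_in_peaks([peak(100, 250)], sets)
        assert m.counts[:, 0].sum() == 10
        assert m.counts[:, 1].sum() == 0

    def test_each_fragment_in_at_most_one_peak(self):
        frags = [("chr1", 140, 260)]  # midpoint 200, on a peak boundary
        m = count_in_peaks([peak(100, 200), peak(200, 300)], [fragset(frags)])
        assert m.counts.sum() == 1

    def test_overlapping_peaks_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            count_in_peaks([peak(100, 250), peak(200, 300)], [fragset([])])


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = np.array([[5, 5], [9, 9], [2, 2]])
        np.testing.assert_allclose(size_factors(counts), [1.0, 1.0])

    def test_worked_example(self):
        counts = np.array([[2, 4], [6, 12], [10, 20]])
        np.testing.assert_allclose(
            size_factors(counts), [0.7071, 1.4142], atol=5e-5
        )

    def test_doubling_a_column_doubles_its_factor(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(50, size=(30, 3)) + 1
        s = size_factors(counts)
        doubled = counts.copy()
        doubled[:, 1] *= 2
        s2 = size_factors(doubled)
        # geometric means shift by 2^(1/3); other columns rescale accordingly
        np.testing.assert_allclose(s2[1] / s[1] / (s2[0] / s[0]), 2.0, rtol=1e-9)

    def test_all_zero_row_matrix_rejected(self):
        with pytest.raises(ValueError, match="all-positive"):
            size_factors(np.array([[0, 5], [3, 0]]))


class TestEstimateDispersion:
    CONDS = ["RIP", "RIP", "control", "control"]

    def test_poisson_counts_give_near_zero_dispersion(self):
        counts, conds = rc.simulate_count_matrix(4000, nb_dispersion=0.0, seed=1)
        alpha = estimate_dispersion(counts, np.ones(4), conds)
        assert np.median(alpha) <= 0.02

    def test_known_dispersion_recovered(self):
        counts, conds = rc.simulate_count_matrix(
            2000, mean_range=(150.0, 250.0), nb_dispersion=0.2, seed=2
        )
        alpha = estimate_dispersion(counts, np.ones(4), conds)
        assert 0.1 <= np.median(alpha) <= 0.3

    def test_constant_counts_zero_before_trend(self):
        counts = np.full((5, 4), 40)
        alpha = estimate_dispersion(counts, np.ones(4), self.CONDS)
        np.testing.assert_allclose(alpha, 0.0, atol=1e-12)

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError, match="replicates"):
            estimate_dispersion(
                np.ones((3, 2)), np.ones(2), ["RIP", "control"]
            )


class TestExactTest:
    def test_balanced_counts_p_one(self):
        p = nb_exact_test(
            np.array([5, 5]), np.array([5, 5]), np.ones(2), np.ones(2), 0.1
        )
        assert p == pytest.approx(1.0)

    def test_poisson_limit_is_conditional_binomial(self):
        """alpha=0, equal sizes, observed (0, 10): p = 2 * 2^-10."""
        p = nb_exact_test(
            np.array([0]), np.array([10]), np.ones(1), np.ones(1), 0.0
        )
        assert p == pytest.approx(2 / 1024, rel=1e-9)

    def test_condition_swap_symmetry(self):
        k_a, k_b = np.array([3, 7]), np.array([18, 22])
        s = np.array([1.0, 1.3])
        p1 = nb_exact_test(k_a, k_b, s, s, 0.05)
        p2 = nb_exact_test(k_b, k_a, s, s, 0.05)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_zero_total_p_one(self):
        assert nb_exact_test(
            np.array([0, 0]), np.array([0, 0]), np.ones(2), np.ones(2), 0.1
        ) == 1.0

    @pytest.mark.parametrize("alpha", [0.0, 0.08])
    @pytest.mark.parametrize("split", [(0, 12), (4, 8), (10, 30), (25, 5)])
    def test_matches_enumeration_oracle(self, alpha, split):
        a, b = split
        s_a, s_b = np.array([0.9, 1.1]), np.array([1.2, 0.8])
        k_a = np.array([a // 2, a - a // 2])
        k_b = np.array([b // 2, b - b // 2])
        ours = nb_exact_test(k_a, k_b, s_a, s_b, alpha)
        oracle = exact_test_p(list(k_a), list(k_b), list(s_a), list(s_b), alpha)
        assert ours == pytest.approx(oracle, rel=1e-10)


class TestBH:
    def test_worked_step_up(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])),
            [0.04, 0.04, 0.04, 0.04],
        )

    def test_all_ones(self):
        np.testing.assert_array_equal(bh_adjust(np.ones(5)), np.ones(5))

    def test_single_p_identity(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.03])), [0.03])

    def test_monotone_in_ranked_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=100)
        fdr = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(fdr[order]) >= -1e-12).all()


class TestSignificance:
    def frame(self, fdr, direction):
        return pd.DataFrame(
            {"peak_id": [f"p{i}" for i in range(len(fdr))],
             "fdr": fdr, "direction": direction}
        )

    def test_control_direction_excluded(self):
        df = self.frame([0.01], [CONTROL_UP])
        assert significant_peaks(df).empty

    def test_strict_threshold(self):
        df = self.frame([0.049, 0.05], [RIP_UP, RIP_UP])
        kept = significant_peaks(df, 0.05)
        assert list(kept["peak_id"]) == ["p0"]

    def test_empty_input(self):
        assert significant_peaks(pd.DataFrame()).empty


class TestRunEnrichment:
    def test_planted_enrichment_detected_null_not(self):
        rng_factor = np.ones(300)
        rng_factor[:30] = 8.0  # first 30 "peaks" enriched in RIP
        counts, conds = rc.simulate_count_matrix(
            300, enrichment=rng_factor, nb_dispersion=0.05, seed=4
        )
        matrix = rc.PeakCountMatrix(
            [f"peak_{i}" for i in range(300)],
            ["RIP_1", "RIP_2", "IgG_1", "IgG_2"],
            conds,
            counts,
        )
        # size factors from the (mostly null) matrix itself
        res = run_enrichment(matrix)
        sig = significant_peaks(res)
        hit = {int(p.split("_")[1]) for p in sig["peak_id"]}
        assert len(hit & set(range(30))) >= 27
        assert all(res.loc[res.index[:30], "direction"] == RIP_UP)
        false = hit - set(range(30))
        assert len(false) <= 3
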