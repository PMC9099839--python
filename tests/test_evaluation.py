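"""Metric suite: published-table recomputation, enumeration oracles, dCor nulls."""

import itertools

import numpy as np
import pytest
from scipy import stats

from nirqc.evaluation import (
    distance_correlation,
    regression_metrics,
    rpd,
    wilcoxon_rank_sum,
)
from nirqc.published import PUBLISHED_VALIDATION_SUMMARY, SYSTEMS, validation_arrays


class TestRegressionMetrics:
    def test_identity_prediction(self, rng):
        y = rng.uniform(1, 5, 10)
        m = regression_metrics(y, y)
        assert m == {"R": 1.0, "RMSE": 0.0, "RSE": 0.0}

    def test_published_geniposide_validation_row(self):
        y, yh = validation_arrays("traditional", "geniposide")
        m = regression_metrics(y, yh)
        assert m["RMSE"] == pytest.approx(0.540, abs=0.0005)
        assert m["RSE"] == pytest.approx(11.0, abs=0.05)
        assert m["R"] == pytest.approx(0.9516, abs=0.005)

    def test_published_baicalin_through_vial_row(self):
        y, yh = validation_arrays("non_invasive", "baicalin")
        m = regression_metrics(y, yh)
        assert m["R"] == pytest.approx(0.9670, abs=0.0005)
        assert m["RMSE"] == pytest.approx(0.174, abs=0.0005)

    def test_residual_r_not_pearson(self):
        # the two conventions disagree for the traditional geniposide table
        y, yh = validation_arrays("traditional", "geniposide")
        pearson = np.corrcoef(y, yh)[0, 1]
        assert regression_metrics(y, yh)["R"] != pytest.approx(pearson, abs=0.005)

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            regression_metrics([1.0, 1.0, 1.0], [1.0, 1.1, 0.9])

    def test_worse_than_mean_clamps_r_to_zero(self, rng):
        y = rng.uniform(0, 1, 20)
        m = regression_metrics(y, y.mean() + 10 * (y - y.mean()))
        assert m["R"] == 0.0


class TestRPD:
    def test_rmsep_equal_to_sd_gives_one(self, rng):
        y = rng.uniform(0, 3, 15)
        sd = float(np.std(y, ddof=1))
        assert rpd(y, sd)["RPD"] == pytest.approx(1.0)

    def test_printed_inputs_give_five_point_zero_three(self):
        # sd 1.609 / RMSEP 0.320 as printed for the traditional geniposide model
        assert 1.609 / 0.320 == pytest.approx(5.03, abs=0.005)

    def test_pass_flag_at_threshold_three(self, rng):
        y = rng.uniform(0, 3, 15)
        sd = float(np.std(y, ddof=1))
        assert rpd(y, sd / 4)["passes"] is True
        assert rpd(y, sd / 2)["passes"] is False

    def test_nonpositive_rmsep_rejected(self):
        with pytest.raises(ValueError):
            rpd([1.0, 2.0], 0.0)


class TestWilcoxonRankSum:
    def test_identical_multisets_p_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        _, p = wilcoxon_rank_sum(a, a.copy())
        assert p == pytest.approx(1.0)

    def test_small_sample_matches_enumeration(self):
        """Exact two-sided p for [1,2] vs [3,4] equals 1/3 by full enumeration
        of all C(4,2) rank assignments."""
        a, b = np.array([1.0, 2.0]), np.array([3.0, 4.0])
        w_obs, p = wilcoxon_rank_sum(a, b)
        ranks = [1, 2, 3, 4]
        sums = [sum(c) for c in itertools.combinations(ranks, 2)]
        mean_w = np.mean(sums)
        extreme = sum(abs(s - mean_w) >= abs(w_obs - mean_w) for s in sums)
        assert p == pytest.approx(extreme / len(sums))
        assert p == pytest.approx(1 / 3)

    @pytest.mark.parametrize("system", SYSTEMS)
    @pytest.mark.parametrize("indicator", ["anti_no", "epigoitrin", "geniposide", "baicalin"])
    def test_published_pairs_show_no_shift(self, system, indicator):
        y, yh = validation_arrays(system, indicator)
        _, p = wilcoxon_rank_sum(y, yh)
        assert p > 0.05

    def test_shifted_samples_detected(self, rng):
        a = rng.normal(0, 1, 30)
        _, p = wilcoxon_rank_sum(a, a + 3)
        assert p < 1e-6

    def test_agrees_with_scipy_asymptotic_on_ties(self):
        a = np.array([1.0, 2.0, 2.0, 3.0] * 8)  # ties + n > 20 -> asymptotic
        b = np.array([2.0, 2.5, 3.0, 3.5] * 8)
        _, p = wilcoxon_rank_sum(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        assert p == pytest.approx(ref)


def dcor_naive(x, y):
    """From-definition double loop (independent of the vectorized path)."""
    n = len(x)
    ax = np.array([[abs(x[i] - x[j]) for j in range(n)] for i in range(n)])
    ay = np.array([[abs(y[i] - y[j]) for j in range(n)] for i in range(n)])

    def center(d):
        return d - d.mean(0) - d.mean(1)[:, None] + d.mean()

    A, B = center(ax), center(ay)
    dcov2 = (A * B).mean()
    return np.sqrt(max(0.0, dcov2) / np.sqrt((A * A).mean() * (B * B).mean()))


class TestDistanceCorrelation:
    def test_perfect_linear_dependence(self, rng):
        a = rng.uniform(0, 1, 30)
        d, _ = distance_correlation(a, 2 * a + 1)
        assert d == pytest.approx(1.0)

    def test_matches_naive_definition(self, rng):
        a = rng.uniform(0, 1, 25)
        b = np.sin(3 * a) + rng.normal(0, 0.2, 25)
        d, _ = distance_correlation(a, b)
        assert d == pytest.approx(dcor_naive(a, b), rel=1e-10)

    def test_independent_inputs_near_zero(self, rng):
        a = rng.uniform(0, 1, 200)
        b = rng.uniform(0, 1, 200)
        d, _ = distance_correlation(a, b)
        assert d < 0.15

    def test_permutation_p_small_under_dependence(self, rng):
        a = rng.uniform(0, 1, 60)
        d, p = distance_correlation(a, a**2, n_perm=199, seed=0)
        assert p < 0.01

    def test_permutation_p_uniform_under_null(self):
        """KS test over 200 null replicates does not reject uniformity at 0.01."""
        rng = np.random.default_rng(42)
        pvals = []
        for i in range(200):
            a = rng.uniform(0, 1, 24)
            b = rng.uniform(0, 1, 24)
            _, p = distance_correlation(a, b, n_perm=99, seed=i)
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_constant_input_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            d, p = distance_correlation(np.ones(5), np.arange(5.0), n_perm=9)
        assert d == 0.0 and p == 1.0


def test_published_summary_table_is_internally_consistent():
    """Every printed Rv/RMSEV/RSEV cell is reproduced from its printed pairs."""
    for system in SYSTEMS:
        for indicator, expected in PUBLISHED_VALIDATION_SUMMARY[system].items():
            y, yh = validation_arrays(system, indicator)
            m = regression_metrics(y, yh)
            assert m["R"] == pytest.approx(expected["Rv"], abs=0.005)
            assert m["RMSE"] == pytest.approx(expected["RMSEV"], abs=0.005)
            assert m["RSE"] == pytest.approx(expected["RSEV"], abs=0.05)
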