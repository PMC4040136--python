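"""Statistical suite against closed forms, enumeration oracles, and scipy-free arithmetic."""

import numpy as np
import pytest
from scipy import stats

from efscore import cohortstats as cs


def table(counts):
    return cs.ContingencyTable.from_counts(counts)


def fisher_enumeration_p(counts) -> float:
    """Independent oracle: sum hypergeometric probabilities over every table
    with the observed margins that is no more probable than the observed one."""
    (a, b), (c, d) = counts
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    pmf = [stats.hypergeom.pmf(k, n, r1, c1) for k in range(max(0, c1 - r2), min(r1, c1) + 1)]
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    return float(sum(p for p in pmf if p <= p_obs * (1 + 1e-9)))


class TestFisherExact:
    @pytest.mark.parametrize(
        "counts,printed_p",
        [
            ([[3, 3], [27, 1]], 0.012),   # fine crackles 3/6 vs 27/28
            ([[4, 2], [1, 27]], 0.002),   # pneumothorax 4/6 vs 1/28
        ],
    )
    def test_reproduces_published_clinical_table_rows(self, counts, printed_p):
        p = cs.fisher_exact_2x2(table(counts)).p_two_sided
        assert round(p, 3) == printed_p

    def test_identical_rows_give_p_one(self):
        assert cs.fisher_exact_2x2(table([[5, 5], [5, 5]])).p_two_sided == 1.0

    def test_zero_margin_degenerate(self):
        with pytest.warns(UserWarning):
            res = cs.fisher_exact_2x2(table([[0, 0], [3, 4]]))
        assert res.p_two_sided == 1.0

    def test_matches_enumeration_oracle_on_random_small_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(60):
            counts = rng.integers(0, 6, size=(2, 2)).tolist()
            if min(np.sum(counts, axis=0).min(), np.sum(counts, axis=1).min()) == 0:
                continue
            p = cs.fisher_exact_2x2(table(counts)).p_two_sided
            assert p == pytest.approx(fisher_enumeration_p(counts), abs=1e-9)


class TestChiSquare:
    def test_reproduces_published_smoking_row(self):
        # current/ex/never 0/3/3 vs 13/13/2
        res = cs.chi_square_rxc(table([[0, 3, 3], [13, 13, 2]]))
        assert round(res.p_two_sided, 3) == 0.011
        assert res.df == 2

    def test_proportional_rows_give_zero_statistic(self):
        res = cs.chi_square_rxc(table([[2, 4, 6], [3, 6, 9]]))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_2x2_closed_form_identity(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            a, b, c, d = rng.integers(1, 20, size=4)
            res = cs.chi_square_rxc(table([[a, b], [c, d]]))
            n = a + b + c + d
            expected = (a * d - b * c) ** 2 * n / ((a + b) * (c + d) * (a + c) * (b + d))
            assert res.statistic == pytest.approx(expected)

    def test_permutation_invariance(self):
        t1 = cs.chi_square_rxc(table([[1, 5, 2], [7, 3, 4]]))
        t2 = cs.chi_square_rxc(table([[5, 1, 2], [3, 7, 4]]))
        t3 = cs.chi_square_rxc(table([[7, 3, 4], [1, 5, 2]]))
        assert t1.statistic == pytest.approx(t2.statistic) == pytest.approx(t3.statistic)

    def test_zero_expected_count_rejected(self):
        with pytest.raises(ValueError):
            cs.chi_square_rxc(table([[0, 1], [0, 2]]))


class TestCategoricalRouting:
    def test_small_expected_counts_route_to_fisher(self):
        res = cs.choose_categorical_test(table([[3, 3], [27, 1]]))
        assert res.method == "fisher_exact"

    def test_large_2x2_routes_to_chi_square(self):
        res = cs.choose_categorical_test(table([[30, 40], [35, 45]]))
        assert res.method == "chi_square"


def sample_with_moments(mean, sd, n, seed):
    """Raw sample whose first two moments match the targets exactly."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z


class TestStudentT:
    @pytest.mark.parametrize(
        "a,b,printed_p",
        [
            ((62.7, 10.9, 6), (88.6, 21.9, 28), 0.009),  # FVC % predicted
            ((29.3, 33.1, 6), (66.8, 97.4, 28), 0.363),  # pack-years
            ((73.3, 46.1, 6), (29.7, 34.3, 28), 0.012),  # detection-to-specimen, months
        ],
    )
    def test_reproduces_published_summary_rows(self, a, b, printed_p):
        res = cs.t_test_from_summary(cs.SummaryStat(*a), cs.SummaryStat(*b))
        assert round(res.p_two_sided, 3) == printed_p

    def test_equal_means_give_p_one(self):
        res = cs.t_test_from_summary(cs.SummaryStat(5, 2, 10), cs.SummaryStat(5, 3, 12))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_degenerate_zero_sds(self):
        equal = cs.t_test_from_summary(cs.SummaryStat(5, 0, 5), cs.SummaryStat(5, 0, 5))
        assert equal.p_two_sided == 1.0
        with pytest.warns(UserWarning):
            diff = cs.t_test_from_summary(cs.SummaryStat(5, 0, 5), cs.SummaryStat(6, 0, 5))
        assert diff.p_two_sided == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_summary_equals_raw_on_moment_matched_samples(self, seed):
        rng = np.random.default_rng(100 + seed)
        mean_a, mean_b = rng.normal(0, 10, 2)
        sd_a, sd_b = rng.uniform(0.5, 5, 2)
        n_a, n_b = rng.integers(3, 30, 2)
        x = sample_with_moments(mean_a, sd_a, n_a, seed)
        y = sample_with_moments(mean_b, sd_b, n_b, seed + 1)
        from_raw = cs.t_test_raw(x, y)
        from_summary = cs.t_test_from_summary(
            cs.SummaryStat(mean_a, sd_a, int(n_a)), cs.SummaryStat(mean_b, sd_b, int(n_b))
        )
        assert from_raw.statistic == pytest.approx(from_summary.statistic)
        assert from_raw.p_two_sided == pytest.approx(from_summary.p_two_sided)

    def test_paired_on_known_differences(self):
        # differences (1, 2, 3): mean 2, sd 1, t = 2 sqrt(3), df = 2
        res = cs.t_test_raw([2, 3, 4], [1, 1, 1], paired=True)
        assert res.statistic == pytest.approx(2 * np.sqrt(3))
        assert res.df == 2

    def test_paired_identical_samples(self):
        res = cs.t_test_raw([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
        assert res.statistic == 0.0
        assert res.p_two_sided == 1.0


class TestMannWhitney:
    def test_single_tied_values(self):
        res = cs.mann_whitney_u([5.0], [5.0])
        assert res.statistic == 0.5
        assert res.p_two_sided == 1.0

    def test_complete_separation_exact_p(self):
        # all C(4,2) = 6 rank splits; the two extreme ones give p = 2/6
        res = cs.mann_whitney_u([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.p_two_sided == pytest.approx(1 / 3)

    def test_exact_and_normal_branches_agree(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x = rng.normal(0, 1, 8)
            y = rng.normal(0.5, 1, 8)
            exact = cs.mann_whitney_u(x, y)
            assert exact.method == "mann_whitney_u_exact"
            approx = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            assert abs(exact.p_two_sided - approx.pvalue) < 0.02


class TestCorrelation:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        assert cs.pearson_r(x, 2 * x + 1).coefficient == pytest.approx(1.0)

    def test_perfect_negative_relation(self):
        x = np.arange(5.0)
        assert cs.pearson_r(x, -x).coefficient == pytest.approx(-1.0)
        assert cs.spearman_rho(x, -x).coefficient == pytest.approx(-1.0)

    def test_spearman_hand_example(self):
        assert cs.spearman_rho([1, 2, 3], [3, 1, 2]).coefficient == pytest.approx(-0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cs.pearson_r([1, 1, 1], [1, 2, 3])


class TestSurvival:
    def test_all_censored_curve_stays_at_one(self):
        curve = cs.km_estimate([3, 5, 9], [False, False, False])
        assert (curve.survival == 1.0).all()

    def test_product_limit_by_hand(self):
        curve = cs.km_estimate([1, 2], [True, True])
        assert curve.at(0.5) == 1.0
        assert curve.at(1.0) == 0.5
        assert curve.at(2.0) == 0.0

    def test_identical_groups_logrank_null(self):
        t = [2, 4, 6, 8]
        e = [True, True, False, True]
        res = cs.logrank(t, e, t, e)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            cs.logrank([1, 2], [False, False], [3, 4], [False, False])


def test_all_p_values_are_probabilities():
    rng = np.random.default_rng(77)
    for _ in range(10):
        x = rng.normal(size=6)
        y = rng.normal(size=9)
        ps = [
            cs.t_test_raw(x, y).p_two_sided,
            cs.mann_whitney_u(x, y).p_two_sided,
            cs.pearson_r(x[:6], y[:6]).p_two_sided,
            cs.fisher_exact_2x2(table(rng.integers(1, 9, (2, 2)).tolist())).p_two_sided,
        ]
        assert all(0 <= p <= 1 for p in ps)
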