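import numpy as np
import pytest
from scipy import stats

from crcpod.evaluation import (
    anova_oneway,
    chi_square_rxc,
    compare_pod,
    fisher_exact_2x2,
    format_p,
    proportion,
    roc_auc,
    t_test,
    t_test_from_stats,
)


def brute_force_auc(scores, labels):
    """Pairwise oracle: P(case > control) + 0.5 P(tie) over all pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    case, ctrl = scores[labels], scores[~labels]
    wins = (case[:, None] > ctrl[None, :]).sum()
    ties = (case[:, None] == ctrl[None, :]).sum()
    return (wins + 0.5 * ties) / (case.size * ctrl.size)


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([0.9, 0.8, 0.2, 0.1], [True, True, False, False])
        assert res.auc == 1.0

    def test_all_ties(self):
        assert roc_auc([0.5] * 6, [True] * 3 + [False] * 3).auc == 0.5

    def test_hand_counted_pairs(self):
        # cases (0.9, 0.8, 0.4), controls (0.7, 0.3): 5 wins of 6 pairs
        res = roc_auc([0.9, 0.8, 0.4, 0.7, 0.3], [1, 1, 1, 0, 0])
        assert res.auc == pytest.approx(5 / 6, abs=1e-12)

    def test_matches_brute_force_with_ties(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 60))
            scores = rng.integers(0, 10, n) / 10.0  # heavy ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            assert roc_auc(scores, labels).auc == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_flip_identity(self, rng):
        scores = rng.random(40)
        labels = rng.random(40) < 0.4
        labels[0], labels[1] = True, False
        a = roc_auc(scores, labels).auc
        b = roc_auc(scores, ~labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [True, True])


class TestFisherExact:
    def test_antidiagonal_table(self):
        # only the two extreme tables are as improbable: 2 / C(10,5)
        assert fisher_exact_2x2([[0, 5], [5, 0]]) == pytest.approx(2 / 252)

    def test_zero_margin_convention(self):
        assert fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0

    def test_matches_scipy_oracle(self, rng):
        """Independent implementation check on random tables with N <= 60."""
        for _ in range(200):
            t = rng.integers(0, 16, size=(2, 2))
            p_mine = fisher_exact_2x2(t)
            p_scipy = stats.fisher_exact(t)[1]
            assert p_mine == pytest.approx(p_scipy, rel=1e-9, abs=1e-12)

    def test_non_2x2_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, 2, 3], [4, 5, 6]])


class TestTTest:
    def test_identical_groups(self):
        assert t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_zero_variance_conventions(self):
        assert t_test([2.0, 2.0], [2.0, 2.0]) == 1.0
        assert t_test([0.0, 0.0], [1.0, 1.0]) == 0.0

    def test_separated_with_jitter(self, rng):
        a = rng.normal(0, 1e-3, 4)
        b = 1.0 + rng.normal(0, 1e-3, 4)
        assert t_test(a, b) < 1e-4

    def test_summary_stat_mode_matches_direct(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1.2, 40)
        direct = t_test(a, b)
        summary = t_test_from_stats(a.mean(), a.std(ddof=1), 30,
                                    b.mean(), b.std(ddof=1), 40)
        assert summary == pytest.approx(direct, rel=1e-12)

    def test_welch_differs_under_unequal_variance(self, rng):
        a = rng.normal(0, 0.1, 10)
        b = rng.normal(0.5, 3.0, 50)
        assert t_test(a, b, welch=True) != t_test(a, b, welch=False)


class TestChiSquare:
    def test_independence_expectation_gives_p_one(self):
        # exactly proportional rows: statistic 0
        assert chi_square_rxc([[10, 20], [20, 40]]) == pytest.approx(1.0)

    def test_diagonal_table_closed_form(self):
        # all four cells deviate by 5 from expected 5: X2 = 4 * 25/5 = 20
        p = chi_square_rxc([[10, 0], [0, 10]])
        assert p == pytest.approx(stats.chi2.sf(20, 1), rel=1e-9)
        assert p == pytest.approx(7.7e-6, rel=0.01)

    def test_invariant_under_permutation(self, rng):
        t = rng.integers(1, 30, size=(3, 4))
        p = chi_square_rxc(t)
        assert chi_square_rxc(t[::-1]) == pytest.approx(p)
        assert chi_square_rxc(t[:, ::-1]) == pytest.approx(p)
        assert chi_square_rxc(t.T) == pytest.approx(p)

    def test_zero_expected_cell_suggests_fisher(self):
        with pytest.raises(ValueError, match="fisher"):
            chi_square_rxc([[0, 0], [5, 5]])


class TestAnova:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0]
        assert anova_oneway([g, g, g]) == pytest.approx(1.0)

    def test_two_groups_equals_squared_t(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(0.7, 1, 25)
        assert anova_oneway([a, b]) == pytest.approx(t_test(a, b), rel=1e-10)

    def test_degenerate_groups(self):
        assert anova_oneway([[1.0, 1.0], [1.0, 1.0]]) == 1.0
        assert anova_oneway([[1.0, 1.0], [2.0, 2.0]]) == 0.0


class TestProportion:
    @pytest.mark.parametrize("num, den, expected", [(9, 11, 81.82), (4, 8, 50.00), (0, 5, 0.00)])
    def test_values(self, num, den, expected):
        assert proportion(num, den) == expected

    def test_errors(self):
        with pytest.raises(ValueError):
            proportion(6, 5)
        with pytest.raises(ValueError):
            proportion(1, 0)


class TestComparePod:
    def test_identical_groups_p_one(self):
        res = compare_pod({"CRC": [0.5, 0.6, 0.7], "Control": [0.5, 0.6, 0.7]})
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_three_groups_three_pairs(self, rng):
        res = compare_pod({g: rng.random(10) for g in ("CRC", "Control", "Relative")})
        assert len(res) == 3
        assert set(zip(res["group_a"], res["group_b"])) == {
            ("CRC", "Control"), ("CRC", "Relative"), ("Control", "Relative")
        }

    def test_separated_pod_significant(self):
        cases = np.linspace(0.7, 0.95, 20)
        controls = np.linspace(0.05, 0.3, 20)
        res = compare_pod({"CRC": cases, "Control": controls})
        assert res["p_value"].iloc[0] < 0.01


def test_p_display_convention():
    assert format_p(0.0004) == "<0.001"
    assert format_p(0.0024528) == "0.002"
    assert format_p(1.0) == "1.000"
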