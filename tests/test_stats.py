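"""Evaluation statistics: accuracy, ROC/AUC, MI, transforms, learning trends."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st

from triadbci.game import SessionLog, make_session_plan
from triadbci.stats import (
    accuracy,
    angular_transform,
    binomial_test,
    block_beta,
    block_correlation,
    evaluate,
    mi_bias,
    mutual_information,
    power_comparison,
    roc_single_point,
    transformed_tests,
    trend_z,
)


def make_log(outcomes, exclusion=frozenset()):
    return SessionLog(plan=make_session_plan(0), outcomes=list(outcomes), exclusion_mask=frozenset(exclusion))


class TestAccuracy:
    def test_thirteen_of_sixteen(self):
        log = make_log(["cleared"] * 13 + ["failed"] * 3)
        assert accuracy(log) == 0.8125

    def test_perfect(self):
        assert accuracy(make_log(["cleared"] * 16)) == 1.0

    def test_exclusion_mask_arithmetic(self):
        # 16 trials, 5 excluded, all 11 remaining cleared
        outcomes = ["cleared"] * 11 + ["failed"] * 5
        log = make_log(outcomes, exclusion={11, 12, 13, 14, 15})
        assert accuracy(log) == 1.0

    def test_rejects_fully_excluded_log(self):
        with pytest.raises(ValueError, match="no included"):
            accuracy(make_log(["cleared"] * 16, exclusion=set(range(16))))


class TestBinomialTest:
    def test_known_values_against_exact_summation(self):
        # closed-form / exact-summation oracles
        assert binomial_test(16, 16) == pytest.approx(1 / 65536)
        exact = sum(Fraction(math.comb(16, k), 2**16) for k in range(8, 17))
        assert binomial_test(8, 16) == pytest.approx(float(exact))
        assert binomial_test(0, 16) == 1.0

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            binomial_test(17, 16)


class TestPowerComparison:
    def test_identical_groups_give_zero(self):
        t, p = power_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0

    def test_label_swap_negates_t(self):
        a, b = [3.0, 4.0, 5.0], [1.0, 1.5, 2.0]
        t1, _ = power_comparison(a, b)
        t2, _ = power_comparison(b, a)
        assert t1 == pytest.approx(-t2)
        assert t1 > 0

    def test_task_epochs_beat_baseline(self):
        # simulation oracle: target-frequency epoch powers during a
        # high-SNR task vs idle baseline epochs
        from triadbci.decoder import bandlimit, epochs, welch_power
        from triadbci.synth_eeg import SSVEPSpec, generate_idle, generate_ssvep

        task, idle = [], []
        for seed in range(8):
            rec = bandlimit(generate_ssvep(SSVEPSpec(17.0, snr=4.0, seed=seed), 10, 250))
            task.extend(welch_power(e).power_at(17.0) for e in epochs(rec))
            base = bandlimit(generate_idle(3, 250, seed=1000 + seed))
            idle.extend(welch_power(e).power_at(17.0) for e in epochs(base))
        t, p = power_comparison(task, idle)
        assert t > 0 and p < 0.01

    def test_degenerate_variance_flagged(self):
        with pytest.raises(ValueError, match="degenerate"):
            power_comparison([1.0, 1.0], [2.0, 2.0])


class TestROC:
    def test_ideal_observer(self):
        truth = [0, 1] * 8
        r = roc_single_point(truth, truth)
        assert r.auc == 1.0 and r.tpr == 1.0 and r.fpr == 0.0

    def test_complement_is_antisymmetric(self):
        truth = np.array([0, 1] * 8)
        r = roc_single_point(1 - truth, truth)
        assert r.auc == 0.0

    def test_matches_trapezoid_oracle(self):
        # trapezoid through (0,0) -> (fpr,tpr) -> (1,1)
        decisions = [1] * 9 + [0] * 1 + [1] * 4 + [0] * 6
        truth = [1] * 10 + [0] * 10
        r = roc_single_point(decisions, truth)
        assert (r.tpr, r.fpr) == (0.9, 0.4)
        xs, ys = [0.0, r.fpr, 1.0], [0.0, r.tpr, 1.0]
        assert r.auc == pytest.approx(np.trapezoid(ys, xs))
        assert r.auc == pytest.approx(0.75)

    def test_rejects_single_class_truth(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_single_point([0, 1], [1, 1])


class TestAngularTransform:
    @pytest.mark.parametrize("x,expected", [(0.0, 0.0), (1.0, math.pi / 2), (0.5, math.pi / 4)])
    def test_closed_forms(self, x, expected):
        assert angular_transform(x) == pytest.approx(expected)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_strictly_increasing(self, a, b):
        if a < b:
            assert angular_transform(a) < angular_transform(b)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            angular_transform(1.2)


class TestTransformedTests:
    def test_values_equal_reference_give_zero_t(self):
        out = transformed_tests([0.5, 0.5, 0.5], reference=0.5)
        assert out["t"] == 0.0

    def test_five_aucs_above_chance_give_v_15(self):
        out = transformed_tests([0.7, 0.8, 0.83, 0.9, 0.75], reference=0.5)
        # all five differences positive: signed-rank sum of positive ranks
        assert out["w"] == 15.0

    def test_power_at_the_design_operating_point(self):
        # Monte-Carlo oracle: five triad AUCs built from binomial TPR/FPR
        # draws at the realized operating point should reject chance in
        # >= 90% of runs via the angular-transformed t-test
        rng = np.random.default_rng(0)
        rejections = 0
        n_runs = 100
        for _ in range(n_runs):
            tpr = rng.binomial(16, 0.82, size=5) / 16
            fpr = rng.binomial(16, 0.18, size=5) / 16
            aucs = (1 + tpr - fpr) / 2
            out = transformed_tests(list(aucs), reference=0.5)
            rejections += out["t_p"] < 0.05
        assert rejections >= 90

    def test_two_sample_paired_and_unpaired(self):
        a, b = [0.8, 0.85, 0.9, 0.7, 0.75], [0.5, 0.55, 0.6, 0.45, 0.5]
        paired = transformed_tests(a, second_group=b, paired=True)
        unpaired = transformed_tests(a, second_group=b, paired=False)
        assert paired["t_p"] < 0.05 and unpaired["t_p"] < 0.05


class TestMutualInformation:
    def test_identical_balanced_vectors_give_one_bit(self):
        v = [0] * 16 + [1] * 16
        assert mutual_information(v, v).mi == pytest.approx(1.0)

    def test_independent_joint_gives_zero(self):
        r = [0] * 16 + [1] * 16
        s = ([0] * 8 + [1] * 8) * 2
        # counts are 8 in each (r, s) cell
        res = mutual_information(r, s)
        assert np.all(res.joint_counts == 8)
        assert res.mi == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_formula_on_asymmetric_joint(self):
        # brute-force oracle for joint counts ((12,4),(4,12)) over 32
        r = [0] * 16 + [1] * 16
        s = [0] * 12 + [1] * 4 + [0] * 4 + [1] * 12
        res = mutual_information(r, s)
        expected = 0.0
        for pj, pr, ps in [(12 / 32, 0.5, 0.5), (4 / 32, 0.5, 0.5), (4 / 32, 0.5, 0.5), (12 / 32, 0.5, 0.5)]:
            expected += pj * math.log2(pj / (pr * ps))
        assert res.mi == pytest.approx(expected)
        assert res.mi == pytest.approx(0.18872, abs=1e-4)

    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=1, max_size=64))
    def test_symmetry_and_bounds(self, pairs):
        r = [p[0] for p in pairs]
        s = [p[1] for p in pairs]
        a = mutual_information(r, s).mi
        b = mutual_information(s, r).mi
        assert a == pytest.approx(b)
        assert -1e-12 <= a <= 1.0 + 1e-12

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            mutual_information([0, 1], [0])


class TestMIBias:
    def test_paper_operating_point(self):
        assert mi_bias(2, 32) == pytest.approx(-0.045, abs=5e-4)

    def test_direct_formula_at_half_samples(self):
        assert mi_bias(2, 16) == pytest.approx(-2 / (2 * 16 * math.log(2)))
        assert mi_bias(2, 16) == pytest.approx(-0.0902, abs=1e-4)

    def test_vanishes_in_large_samples(self):
        assert mi_bias(2, 10**9) == pytest.approx(0.0, abs=1e-8)


class TestBlockRegression:
    def test_identity_and_orthogonal(self):
        assert block_beta([1, 1, 0, 1], [1, 1, 0, 1]) == 1.0
        assert block_beta([1, 0, 0, 0], [0, 1, 1, 0]) == 0.0

    def test_hand_least_squares_case(self):
        assert block_beta([1, 1, 0, 1], [1, 0, 0, 1]) == 1.0  # sum sr / sum s^2 = 2/2

    def test_fuzz_against_generic_lstsq(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(4, 30)
            s = rng.integers(0, 2, size=n)
            if s.sum() == 0:
                s[0] = 1
            r = rng.integers(0, 2, size=n)
            expected = np.linalg.lstsq(s[:, None].astype(float), r.astype(float), rcond=None)[0][0]
            assert block_beta(r, s) == pytest.approx(expected)

    def test_rejects_all_zero_sender(self):
        with pytest.raises(ValueError, match="all-zero"):
            block_beta([1, 0], [0, 0])


class TestBlockCorrelation:
    def test_limits(self):
        assert block_correlation([1, 1, 0, 0], [1, 1, 0, 0]) == pytest.approx(1.0)
        assert block_correlation([1, 1, 0, 0], [0, 0, 1, 1]) == pytest.approx(-1.0)
        assert block_correlation([1, 1, 0, 0], [1, 0, 1, 0]) == pytest.approx(0.0)

    def test_rejects_constant_vector(self):
        with pytest.raises(ValueError, match="constant"):
            block_correlation([1, 1, 1, 1], [1, 0, 1, 0])


class TestTrendZ:
    def test_identical_series_give_zero(self):
        series = [0.1, 0.35, 0.42, 0.7]
        assert trend_z(series, series).z == 0.0

    def test_swap_negates_z(self):
        g = [0.12, 0.28, 0.55, 0.61]
        b = [0.4, 0.35, 0.42, 0.3]
        assert trend_z(g, b).z == pytest.approx(-trend_z(b, g).z)
        assert trend_z(g, b).z > 0

    def test_matches_statsmodels_ols(self):
        # textbook OLS oracle for slopes and standard errors
        import statsmodels.api as sm

        g = [0.12, 0.28, 0.55, 0.61]
        b = [0.4, 0.35, 0.42, 0.3]
        x = sm.add_constant(np.arange(1, 5, dtype=float))
        fg = sm.OLS(np.array(g), x).fit()
        fb = sm.OLS(np.array(b), x).fit()
        expected = (fg.params[1] - fb.params[1]) / math.sqrt(fg.bse[1] ** 2 + fb.bse[1] ** 2)
        assert trend_z(g, b).z == pytest.approx(expected)

    def test_rejects_two_point_series(self):
        with pytest.raises(ValueError, match="three"):
            trend_z([0.1, 0.2], [0.2, 0.1])


class TestEvaluate:
    def test_ideal_sessions_hit_ceiling(self, trusting_ideal_session):
        result = evaluate([trusting_ideal_session] * 5)
        assert result.accuracy_mean == 1.0
        assert result.mean_auc == 1.0
        # the Receiver's decisions equal the good Sender's transmitted
        # decisions sample for sample, so MI reaches the entropy ceiling of
        # the (unbalanced, round-2-heavy) decision distribution
        for m in result.mi_good:
            p1 = m.joint_counts[1].sum() / m.n_samples
            entropy = -(p1 * math.log2(p1) + (1 - p1) * math.log2(1 - p1))
            assert m.mi == pytest.approx(entropy)

    def test_empty_mask_is_identity(self, default_session):
        import dataclasses

        masked = dataclasses.replace(default_session, exclusion_mask=frozenset())
        a = evaluate([default_session])
        b = evaluate([masked])
        assert a.accuracy_per_triad == b.accuracy_per_triad
        assert [r.auc for r in a.roc_triad] == [r.auc for r in b.roc_triad]

    def test_default_design_separates_senders(self, default_session):
        result = evaluate([default_session])
        assert result.mean_mi_good > result.mean_mi_bad
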