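"""Perturbation-fragment correlations, group tests, phases, ANOVA."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from taskmodules import (
    compare_across_experiments,
    group_correlation_test,
    perturbation_correlation,
    phase_average,
)
from taskmodules.adaptation import _correct


class TestPerturbationCorrelation:
    def test_compensating_fragment_is_minus_one(self, rng):
        p = rng.standard_normal(30)
        yhat = (-2.0 * p)[:, None]
        assert perturbation_correlation(yhat, p)[0] == pytest.approx(-1.0)

    def test_independent_fragment_near_zero(self):
        rng = np.random.default_rng(0)
        p = rng.standard_normal(5000)
        yhat = rng.standard_normal((5000, 1))
        assert abs(perturbation_correlation(yhat, p)[0]) < 0.05

    def test_matches_textbook_formula(self, rng):
        p = rng.standard_normal(25)
        y = rng.standard_normal((25, 2))
        rho = perturbation_correlation(y, p)
        for r in range(2):
            num = np.sum((p - p.mean()) * (y[:, r] - y[:, r].mean()))
            den = np.sqrt(np.sum((p - p.mean()) ** 2) * np.sum((y[:, r] - y[:, r].mean()) ** 2))
            assert rho[r] == pytest.approx(num / den)

    def test_trial_subset_restricts_trials(self, rng):
        p = np.r_[np.zeros(10), rng.standard_normal(20)]
        y = rng.standard_normal((30, 1))
        sub = np.arange(10, 30)
        rho = perturbation_correlation(y, p, trial_subset=sub)
        assert rho[0] == pytest.approx(
            scipy.stats.pearsonr(p[sub], y[sub, 0]).statistic
        )

    def test_constant_series_errors(self, rng):
        with pytest.raises(ValueError, match="constant"):
            perturbation_correlation(rng.standard_normal((10, 1)), np.ones(10))
        with pytest.raises(ValueError, match="3 trials"):
            perturbation_correlation(rng.standard_normal((2, 1)), np.array([0.0, 1.0]))


class TestGroupCorrelationTest:
    def test_symmetric_correlations_not_significant(self):
        rho = np.array([[0.4], [-0.4], [0.2], [-0.2]])
        stats = group_correlation_test(rho, correction="none")
        assert stats.p_raw[0] > 0.9

    def test_consistent_sign_p_shrinks_with_subjects(self):
        rng = np.random.default_rng(1)
        p5 = group_correlation_test(-0.5 + 0.05 * rng.standard_normal((5, 1))).p_raw[0]
        p20 = group_correlation_test(-0.5 + 0.05 * rng.standard_normal((20, 1))).p_raw[0]
        assert p20 < p5 < 0.05

    def test_identical_correlations_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            group_correlation_test(np.full((6, 1), -0.7))

    def test_matches_sign_flip_permutation_oracle(self):
        """Rejection decision agrees with a sign-flip permutation test at alpha=.05."""
        rng = np.random.default_rng(2)
        for shift in [0.0, -0.6]:
            rho = (shift + 0.3 * rng.standard_normal(13))[:, None]
            t_obs = abs(scipy.stats.ttest_1samp(rho[:, 0], 0.0).statistic)
            flips = rng.choice([-1.0, 1.0], size=(4000, 13))
            perm = flips * rho[:, 0]
            t_perm = np.abs(
                perm.mean(axis=1) / (perm.std(axis=1, ddof=1) / np.sqrt(13))
            )
            p_perm = (np.sum(t_perm >= t_obs) + 1) / (4000 + 1)
            p_t = group_correlation_test(rho, correction="none").p_raw[0]
            assert (p_t < 0.05) == (p_perm < 0.05)

    def test_correction_never_below_raw(self, rng):
        rho = rng.uniform(-0.5, 0.5, size=(8, 4))
        for method in ["bonferroni", "holm"]:
            stats = group_correlation_test(rho, correction=method)
            assert np.all(stats.p_corrected >= stats.p_raw)
            assert np.all(stats.p_corrected <= 1.0)


def test_correction_arithmetic():
    p = np.array([0.01, 0.04, 0.03])
    np.testing.assert_allclose(_correct(p, "bonferroni"), [0.03, 0.12, 0.09])
    # holm: sorted (0.01, 0.03, 0.04) -> (0.03, 0.06, 0.04) -> step-up max
    np.testing.assert_allclose(_correct(p, "holm"), [0.03, 0.06, 0.06])
    np.testing.assert_allclose(_correct(p, "none"), p)
    with pytest.raises(ValueError):
        _correct(p, "fdr")


class TestPhaseAverage:
    def test_sixty_frames_three_equal_phases(self):
        t = np.arange(60.0)
        means = phase_average(t, 3)
        np.testing.assert_allclose(means, [np.mean(range(20)), np.mean(range(20, 40)), np.mean(range(40, 60))])

    def test_constant_module_equal_phases(self):
        np.testing.assert_allclose(phase_average(np.full(13, 2.5), 3), [2.5] * 3)

    def test_earlier_blocks_larger_when_indivisible(self):
        t = np.arange(7.0)
        means = phase_average(t, 3)  # blocks 3/2/2
        np.testing.assert_allclose(means, [1.0, 3.5, 5.5])

    def test_matches_blockwise_recomputation(self, rng):
        t = rng.standard_normal(31)
        got = phase_average(t, 4)
        blocks = np.array_split(t, 4)
        np.testing.assert_allclose(got, [b.mean() for b in blocks])

    def test_too_many_phases_errors(self):
        with pytest.raises(ValueError):
            phase_average(np.arange(3.0), 4)


def _feature_table(groups_by_experiment, feature="knee"):
    rows = []
    for exp, values in groups_by_experiment.items():
        for s, v in enumerate(values):
            rows.append({"subject": s, "experiment": exp, "feature": feature, "value": v})
    return pd.DataFrame(rows)


class TestCompareAcrossExperiments:
    def test_identical_groups_no_effect(self):
        vals = [0.1, 0.5, 0.9, 0.3]
        table = _feature_table({"e1": vals, "e2": vals, "e3": vals})
        cmp = compare_across_experiments(table)
        assert cmp.table["anova_F"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert cmp.table["anova_p"].iloc[0] == pytest.approx(1.0)

    def test_shifted_group_flagged_by_tukey(self):
        rng = np.random.default_rng(3)
        base = 0.05 * rng.standard_normal(6)
        table = _feature_table(
            {"e1": base, "e2": base + 0.02, "e3": base + 5.0}
        )
        cmp = compare_across_experiments(table)
        tk = cmp.tukey["knee"]
        assert tk.loc["e1", "e3"] < 0.001
        assert tk.loc["e2", "e3"] < 0.001
        assert tk.loc["e1", "e2"] > 0.05

    def test_f_statistic_matches_sums_of_squares(self, rng):
        groups = {e: rng.standard_normal(5).tolist() for e in ["a", "b", "c"]}
        cmp = compare_across_experiments(_feature_table(groups))
        allv = np.concatenate([groups[e] for e in ["a", "b", "c"]])
        grand = allv.mean()
        ss_between = sum(5 * (np.mean(groups[e]) - grand) ** 2 for e in groups)
        ss_within = sum(
            np.sum((np.asarray(groups[e]) - np.mean(groups[e])) ** 2) for e in groups
        )
        F = (ss_between / 2) / (ss_within / 12)
        assert cmp.table["anova_F"].iloc[0] == pytest.approx(F)

    def test_degenerate_inputs_rejected(self):
        table = _feature_table({"e1": [1.0, 2.0]})
        with pytest.raises(ValueError, match="2 experiments"):
            compare_across_experiments(table)
        table = _feature_table({"e1": [1.0, 2.0], "e2": [1.0]})
        with pytest.raises(ValueError, match=">= 2 subjects"):
            compare_across_experiments(table)
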