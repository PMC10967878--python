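import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hdieeg.stats import (
    choose_two_group_test,
    friedman,
    pairwise_posthoc,
    rm_corr,
)


def _long(wide):
    rows = []
    for s, row in enumerate(wide):
        for c, v in enumerate(row):
            rows.append({"subject": f"S{s}", "condition": f"C{c}", "value": v})
    return pd.DataFrame(rows)


class TestTwoGroupGate:
    def test_gaussian_samples_take_t_path(self, rng):
        x = rng.normal(0, 1, 50)
        y = rng.normal(0.2, 1, 50)
        res = choose_two_group_test(x, y)
        assert res.name == "t-test"
        assert all(p > 0.05 for p in res.shapiro_p)

    def test_heavy_tail_takes_mannwhitney_path(self, rng):
        x = rng.standard_cauchy(60)
        y = rng.normal(0, 1, 60)
        res = choose_two_group_test(x, y)
        assert res.name == "mann-whitney"

    def test_paired_alternative_uses_wilcoxon(self, rng):
        x = rng.standard_cauchy(40)
        y = x + rng.normal(0, 0.5, 40)
        res = choose_two_group_test(x, y, paired_alternative=True)
        assert res.name == "wilcoxon"

    def test_identical_samples_not_significant(self, rng):
        x = rng.normal(0, 1, 30)
        res = choose_two_group_test(x, x.copy())
        assert res.p > 0.9

    def test_path_deterministic(self, rng):
        x, y = rng.normal(0, 1, (2, 30))
        assert choose_two_group_test(x, y).name == choose_two_group_test(x, y).name

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            choose_two_group_test([1.0, 2.0], [1.0, 2.0, 3.0])


class TestFriedman:
    def test_all_equal_values_give_zero_statistic(self):
        table = _long(np.ones((6, 3)))
        res = friedman(table)
        assert res.chi_squared == pytest.approx(0.0)
        assert res.eta_squared == pytest.approx(0.0)

    def test_matches_rank_sum_formula_without_ties(self, rng):
        """chi2 = 12/(n k (k+1)) * sum R_j^2 - 3 n (k+1), R_j = rank sums."""
        wide = rng.normal(size=(5, 3))
        res = friedman(_long(wide))
        ranks = np.apply_along_axis(sps.rankdata, 1, wide)
        r = ranks.sum(axis=0)
        n, k = wide.shape
        chi2 = 12.0 / (n * k * (k + 1)) * np.sum(r**2) - 3 * n * (k + 1)
        assert res.chi_squared == pytest.approx(chi2)
        assert res.eta_squared == pytest.approx(chi2 / (n * (k - 1)))

    def test_invariant_under_monotone_transform(self, rng):
        wide = rng.uniform(0.5, 3.0, size=(8, 4))
        a = friedman(_long(wide))
        b = friedman(_long(np.exp(wide)))
        assert a.chi_squared == pytest.approx(b.chi_squared)
        assert a.p == pytest.approx(b.p)

    def test_unbalanced_design_rejected(self, rng):
        table = _long(rng.normal(size=(5, 3))).iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            friedman(table)

    def test_fewer_than_three_conditions_rejected(self, rng):
        with pytest.raises(ValueError, match="3 conditions"):
            friedman(_long(rng.normal(size=(5, 2))))

    def test_shifted_condition_detected(self, rng):
        wide = rng.normal(size=(20, 3))
        wide[:, 2] += 1.5
        assert friedman(_long(wide)).p < 0.05

    def test_posthoc_flags_the_shifted_pair(self, rng):
        wide = rng.normal(size=(25, 3))
        wide[:, 2] += 2.0
        out = pairwise_posthoc(_long(wide))
        flagged = out[out["significant"]]
        assert set(flagged["b"]) | set(flagged["a"]) >= {"C2"}


class TestRmCorr:
    def test_perfect_within_subject_relation(self, rng):
        rows = []
        for s in range(5):
            x = rng.normal(size=10)
            for xi in x:
                rows.append({"subject": f"S{s}", "x": xi, "y": xi + 10 * s})
        res = rm_corr(pd.DataFrame(rows))
        assert res.r == pytest.approx(1.0, abs=1e-9)
        assert res.dof == 5 * 10 - 5 - 1

    def test_matches_subject_intercept_ancova(self, rng):
        """Cross-check against explicit OLS with subject dummies."""
        import statsmodels.formula.api as smf

        rows = []
        for s in range(6):
            x = rng.normal(size=8)
            y = 0.7 * x + rng.normal(0, 1, 8) + 2 * s
            rows.extend(
                {"subject": f"S{s}", "x": xi, "y": yi} for xi, yi in zip(x, y)
            )
        df = pd.DataFrame(rows)
        res = rm_corr(df)
        fit = smf.ols("y ~ C(subject) + x", data=df).fit()
        reduced = smf.ols("y ~ C(subject)", data=df).fit()
        ss_x = reduced.ssr - fit.ssr
        r_manual = np.sign(fit.params["x"]) * np.sqrt(ss_x / (ss_x + fit.ssr))
        assert res.r == pytest.approx(r_manual, abs=1e-8)

    def test_null_correlation_small(self, rng):
        count = 0
        for _ in range(40):
            rows = []
            for s in range(25):
                rows.extend(
                    {"subject": f"S{s}", "x": xi, "y": yi}
                    for xi, yi in zip(rng.normal(size=8), rng.normal(size=8))
                )
            res = rm_corr(pd.DataFrame(rows))
            count += abs(res.r) < 0.2
        assert count >= 38  # >= 95% of null runs

    def test_subjects_with_single_observation_dropped(self, rng):
        rows = [
            {"subject": "S0", "x": 0.0, "y": 0.0},  # only one observation
        ]
        for s in (1, 2):
            for xi in rng.normal(size=5):
                rows.append({"subject": f"S{s}", "x": xi, "y": xi + s})
        with pytest.warns(UserWarning, match="S0"):
            res = rm_corr(pd.DataFrame(rows))
        assert res.n_subjects == 2
        assert res.r == pytest.approx(1.0)
        assert res.dof == 10 - 2 - 1

    def test_too_few_subjects_rejected(self, rng):
        rows = [
            {"subject": "S0", "x": xi, "y": xi} for xi in rng.normal(size=5)
        ]
        with pytest.raises(ValueError, match="2 subjects"):
            rm_corr(pd.DataFrame(rows))
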