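"""Gibbs sampler, group means and pairwise credibility intervals."""

import numpy as np
import pandas as pd
import pytest

import lampvision as lv
from lampvision.bayes import mc_standard_error
from lampvision.errors import DesignError, ValidationError


class TestGibbsSampler:
    def test_constant_response_recovers_constant(self):
        y = np.full(20, 7.0) + 1e-6 * np.random.default_rng(0).standard_normal(20)
        X = np.ones((20, 1))
        draws = lv.gibbs_linear_regression(y, X, burnin=500, samples=4000, seed=1)
        assert draws.mean() == pytest.approx(7.0, abs=0.05)

    def test_matches_ols_within_mc_error(self):
        """Posterior mean of the slope agrees with the closed-form
        least-squares estimate on the same data."""
        rng = np.random.default_rng(123)
        x = rng.uniform(0, 10, 100)
        y = 3.0 * x + rng.standard_normal(100)
        X = x[:, None]
        draws = lv.gibbs_linear_regression(y, X, burnin=1000, samples=10000, seed=5)
        ols = float(np.linalg.lstsq(X, y, rcond=None)[0][0])
        mcse = float(mc_standard_error(draws)[0])
        assert abs(draws.mean() - ols) < 2 * max(mcse, 1e-6)

    def test_two_chains_agree_within_mc_error(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 5, 80)
        y = 2.0 - 0.5 * x + 0.8 * rng.standard_normal(80)
        X = np.column_stack([np.ones(80), x])
        d1 = lv.gibbs_linear_regression(y, X, burnin=500, samples=8000, seed=101)
        d2 = lv.gibbs_linear_regression(y, X, burnin=500, samples=8000, seed=202)
        # both chains contribute Monte-Carlo error to the difference
        se = np.sqrt(mc_standard_error(d1) ** 2 + mc_standard_error(d2) ** 2)
        assert np.all(np.abs(d1.mean(axis=0) - d2.mean(axis=0)) < 3 * se)

    def test_seed_reproducibility(self):
        y = np.random.default_rng(0).standard_normal(30)
        X = np.ones((30, 1))
        a = lv.gibbs_linear_regression(y, X, burnin=100, samples=500, seed=7)
        b = lv.gibbs_linear_regression(y, X, burnin=100, samples=500, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_rank_deficient_design_rejected(self):
        X = np.ones((20, 2))  # duplicated column
        with pytest.raises(DesignError):
            lv.gibbs_linear_regression(np.zeros(20), X)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValidationError):
            lv.gibbs_linear_regression(np.zeros(2), np.ones((2, 2)))


def _frame(levels_and_values):
    rows = [{"lamp_type": lev, "class": "X", "percent_stimulated": v}
            for lev, vals in levels_and_values.items() for v in vals]
    return pd.DataFrame(rows)


class TestGroupMeans:
    def test_single_level_mean_and_narrow_ci(self):
        rng = np.random.default_rng(2)
        df = _frame({"A": 50.0 + 0.1 * rng.standard_normal(30)})
        (s,) = lv.group_means(df, "percent_stimulated", "lamp_type",
                              burnin=300, samples=3000, seed=3)
        assert s.mean == pytest.approx(50.0, abs=0.1)
        assert s.ci_high - s.ci_low < 0.5
        assert s.ci_low <= s.mean <= s.ci_high

    def test_equal_data_gives_equal_means(self):
        rng = np.random.default_rng(4)
        vals = 40 + rng.standard_normal(25)
        df = _frame({"A": vals, "B": vals})
        a, b = lv.group_means(df, "percent_stimulated", "lamp_type",
                              burnin=300, samples=5000, seed=6)
        assert a.mean == pytest.approx(b.mean, abs=0.5)

    def test_level_means_match_sample_means(self, synthetic_fleet):
        """Zero-intercept cell means with vague priors land on the per-level
        sample means within Monte-Carlo error."""
        entries, _, lamps = synthetic_fleet
        table = lv.overlap_table(entries[:60], lamps)
        summaries = lv.group_means(table, "percent_stimulated",
                                   ["class", "lamp_type"],
                                   burnin=500, samples=5000, seed=8)
        table = table.copy()
        table["_lev"] = table["class"] + " x " + table["lamp_type"]
        sample_means = table.groupby("_lev")["percent_stimulated"].mean()
        for s in summaries:
            assert s.mean == pytest.approx(sample_means[s.level_label], abs=0.5)

    def test_singleton_level_excluded(self):
        df = _frame({"A": [1.0, 2.0, 3.0], "B": [9.0]})
        summaries = lv.group_means(df, "percent_stimulated", "lamp_type",
                                   burnin=100, samples=500, seed=1)
        assert [s.level_label for s in summaries] == ["A"]


class TestPairwise:
    def test_identical_levels_not_credible(self):
        rng = np.random.default_rng(12)
        vals = 30 + rng.standard_normal(40)
        df = _frame({"A": vals, "B": vals})
        pw = lv.pairwise_differences(df, "percent_stimulated", "lamp_type",
                                     burnin=300, samples=4000, seed=2)
        row = pw.iloc[0]
        assert abs(row.diff_mean) < 0.5
        assert not row.credible

    def test_constant_shift_recovered_and_credible(self):
        rng = np.random.default_rng(13)
        base = 30 + rng.standard_normal(40)
        df = _frame({"A": base, "B": base + 10.0})
        pw = lv.pairwise_differences(df, "percent_stimulated", "lamp_type",
                                     burnin=300, samples=4000, seed=2)
        row = pw[(pw.level_a == "A") & (pw.level_b == "B")].iloc[0]
        assert row.diff_mean == pytest.approx(10.0, abs=0.5)
        assert row.credible

    def test_antisymmetry_under_relabelling(self):
        """Swapping the level labels flips the sign of the difference within
        Monte-Carlo error."""
        rng = np.random.default_rng(14)
        df = _frame({"A": 20 + rng.standard_normal(30),
                     "B": 24 + rng.standard_normal(30)})
        fwd = lv.pairwise_differences(df, "percent_stimulated", "lamp_type",
                                      burnin=500, samples=8000, seed=3)
        flipped = df.copy()
        flipped["lamp_type"] = flipped["lamp_type"].map({"A": "Z", "B": "A"})
        rev = lv.pairwise_differences(flipped, "percent_stimulated", "lamp_type",
                                      burnin=500, samples=8000, seed=4)
        assert fwd.iloc[0].diff_mean == pytest.approx(-rev.iloc[0].diff_mean, abs=0.3)

    def test_pairwise_matches_sample_mean_differences(self, synthetic_fleet):
        entries, _, lamps = synthetic_fleet
        table = lv.overlap_table(entries[:40], lamps)
        pw = lv.pairwise_differences(table, "percent_stimulated", "lamp_type",
                                     burnin=500, samples=5000, seed=9)
        means = table.groupby("lamp_type")["percent_stimulated"].mean()
        for row in pw.itertuples():
            expected = means[row.level_b] - means[row.level_a]
            assert row.diff_mean == pytest.approx(expected, abs=0.6)

    def test_formatted_table_marks_credible_pairs(self):
        rng = np.random.default_rng(15)
        df = _frame({"A": 20 + rng.standard_normal(30),
                     "B": 40 + rng.standard_normal(30)})
        pw = lv.pairwise_differences(df, "percent_stimulated", "lamp_type",
                                     burnin=200, samples=2000, seed=5)
        formatted = lv.format_pairwise_table(pw)
        assert formatted.loc["B", "A"].endswith("*")
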