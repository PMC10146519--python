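import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gcvolatiles import (
    OrderNorm,
    compact_letters,
    fdr_adjust,
    fit_line_model,
    marginal_means,
    pairwise_letters,
    pairwise_significance,
    screen_dataset,
    spearman_screen,
)
from gcvolatiles.linestats import LineModelFit

from conftest import make_table


class TestOrderNorm:
    def test_three_values_hit_normal_quantiles(self):
        scores = OrderNorm().fit_transform([5, 1, 9])
        expected = stats.norm.ppf([3 / 6, 1 / 6, 5 / 6])
        np.testing.assert_allclose(scores, expected, atol=1e-9)

    @pytest.mark.parametrize("n", [5, 20, 101])
    def test_training_scores_standardised(self, n):
        rng = np.random.default_rng(n)
        scores = OrderNorm().fit_transform(rng.lognormal(3, 1, n))
        assert abs(scores.mean()) < 1e-9
        # variance of normal scores approaches 1 with the n/(n-1) correction
        assert scores.var(ddof=1) == pytest.approx(1.0, abs=0.12)

    def test_round_trip_identity_on_training_values(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(0, 1e5, 100)
        on = OrderNorm().fit(values)
        np.testing.assert_allclose(on.inverse_transform(on.transform(values)), values, rtol=1e-9)

    def test_rank_preserving(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=50)
        scores = OrderNorm().fit_transform(values)
        np.testing.assert_array_equal(np.argsort(values), np.argsort(scores))

    def test_ties_share_scores(self):
        scores = OrderNorm().fit_transform([0, 0, 0, 5, 9])
        assert len(set(np.round(scores[:3], 12))) == 1

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            OrderNorm().fit([2.0, 2.0, 2.0])


class TestLineModel:
    def test_brute_force_sums_of_squares(self):
        # classic one-way layout checked against explicit SS computation
        values = np.array([6.9, 5.4, 5.8, 4.6, 4.0, 8.3, 6.8, 7.8, 9.2, 6.5,
                           8.0, 10.5, 8.1, 6.9, 9.3], dtype=float)
        lines = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        fit = fit_line_model(values, lines)
        grand = values.mean()
        ss_b = sum(5 * (values[i:i + 5].mean() - grand) ** 2 for i in (0, 5, 10))
        ss_w = sum(((values[i:i + 5] - values[i:i + 5].mean()) ** 2).sum() for i in (0, 5, 10))
        expected_f = (ss_b / 2) / (ss_w / 12)
        assert fit.F == pytest.approx(expected_f, abs=1e-9)
        assert (fit.df_between, fit.df_within) == (2, 12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_oneway(self, seed):
        rng = np.random.default_rng(seed)
        sizes = rng.integers(2, 7, 4)
        groups = [rng.normal(rng.normal(), 1, s) for s in sizes]
        values = np.concatenate(groups)
        lines = np.repeat([f"L{i}" for i in range(4)], sizes)
        fit = fit_line_model(values, lines)
        oracle = stats.f_oneway(*groups)
        assert fit.F == pytest.approx(float(oracle.statistic), rel=1e-12)
        assert fit.p == pytest.approx(float(oracle.pvalue), rel=1e-9)

    def test_zero_within_variance_flagged_degenerate(self):
        fit = fit_line_model([0, 0, 1, 1], ["a", "a", "b", "b"])
        assert np.isinf(fit.F) and fit.degenerate and fit.p == 0.0

    def test_no_replication_is_error(self):
        with pytest.raises(ValueError, match="replication"):
            fit_line_model([1.0, 2.0], ["a", "b"])

    def test_invariance_to_sample_order_and_line_names(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=20)
        lines = np.repeat(list("abcd"), 5)
        perm = rng.permutation(20)
        renamed = np.char.add("x_", lines[perm].astype(str))
        assert fit_line_model(values, lines).F == pytest.approx(
            fit_line_model(values[perm], renamed).F, rel=1e-12
        )


class TestFdr:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.5]), [0.03, 0.03, 0.5])

    def test_single_and_tied_p_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.2]), [0.2])
        np.testing.assert_allclose(fdr_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_fdr_significant_subset_of_raw(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200) ** 2
        q = fdr_adjust(p)
        assert set(np.flatnonzero(q < 0.05)) <= set(np.flatnonzero(p < 0.05))


class TestMarginalMeans:
    def _fit(self, means, n_per=4, sd=1.0, seed=0):
        rng = np.random.default_rng(seed)
        values = np.concatenate([rng.normal(m, sd, n_per) for m in means])
        lines = np.repeat([f"L{i}" for i in range(len(means))], n_per)
        return fit_line_model(values, lines), values, lines

    def test_balanced_emmean_equals_group_mean(self):
        fit, values, lines = self._fit([0, 1, 2])
        em = marginal_means(fit)
        for i, line in enumerate(["L0", "L1", "L2"]):
            assert em.loc[line, "emmean"] == pytest.approx(values[4 * i:4 * i + 4].mean())

    def test_backtransform_returns_area_scale(self):
        rng = np.random.default_rng(1)
        areas = rng.lognormal(8, 2, 30)
        on = OrderNorm().fit(areas)
        fit = fit_line_model(on.transform(areas), np.repeat(list("abcdef"), 5))
        em = marginal_means(fit, on)
        assert (em["emmean_backtransformed"] > 0).all()
        # back-transform of a training score returns the original area
        np.testing.assert_allclose(on.inverse_transform(on.transform(areas[:3])), areas[:3])

    def test_ci_width_shrinks_like_sqrt_n(self):
        fit4, _, _ = self._fit([0, 0, 0], n_per=4, seed=2)
        fit16, _, _ = self._fit([0, 0, 0], n_per=16, seed=2)
        w4 = (marginal_means(fit4)["upper"] - marginal_means(fit4)["lower"]).mean()
        w16 = (marginal_means(fit16)["upper"] - marginal_means(fit16)["lower"]).mean()
        assert w16 < w4 / 1.5  # ~2x shrink expected, allow noise


class TestLetters:
    def test_no_significant_pairs_single_letter(self):
        letters = compact_letters(["a", "b", "c"], [])
        assert set(letters.values()) == {"a"}

    def test_two_separated_groups(self):
        rng = np.random.default_rng(5)
        values = np.concatenate([rng.normal(0, 1, 20), rng.normal(10, 1, 20)])
        lines = np.repeat(["lo1", "lo2", "hi1", "hi2"], 10)
        letters = pairwise_letters(fit_line_model(values, lines))
        assert letters["hi1"] == letters["hi2"]
        assert letters["lo1"] == letters["lo2"]
        assert letters["hi1"] != letters["lo1"]

    @pytest.mark.parametrize("seed", range(25))
    def test_letters_encode_significance_partition(self, seed):
        # oracle: shared letter <=> pair not significant, on random 5-line fits
        rng = np.random.default_rng(seed)
        means = rng.uniform(0, 4, 5)
        values = np.concatenate([rng.normal(m, 1, 4) for m in means])
        lines = np.repeat([f"L{i}" for i in range(5)], 4)
        fit = fit_line_model(values, lines)
        contrasts = pairwise_significance(fit)
        letters = pairwise_letters(fit)
        for row in contrasts.itertuples():
            shared = set(letters[row.line_a]) & set(letters[row.line_b])
            assert bool(shared) == (not row.significant)


class TestSpearman:
    def test_perfect_and_reversed(self):
        lm = pd.DataFrame(
            [[1, 2, 3, 4, 5], [2, 4, 6, 8, 10], [5, 4, 3, 2, 1]],
            index=[4.61, 5.20, 6.30],
            columns=list("abcde"),
        )
        out = spearman_screen(lm).set_index(["peak_a", "peak_b"])
        assert out.loc[(4.61, 5.20), "rho"] == pytest.approx(1.0)
        assert out.loc[(4.61, 6.30), "rho"] == pytest.approx(-1.0)

    def test_matches_rank_formula(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=10), rng.normal(size=10)
        lm = pd.DataFrame([a, b], index=[1.0, 2.0], columns=[f"l{i}" for i in range(10)])
        out = spearman_screen(lm)
        d = stats.rankdata(a) - stats.rankdata(b)
        rho_closed = 1 - 6 * (d**2).sum() / (10 * 99)
        assert out.loc[0, "rho"] == pytest.approx(rho_closed, abs=1e-9)

    def test_constant_vector_reported_missing(self):
        lm = pd.DataFrame([[1, 1, 1, 1], [1, 2, 3, 4]], index=[1.0, 2.0],
                          columns=list("abcd"))
        out = spearman_screen(lm)
        assert np.isnan(out.loc[0, "rho"])

    def test_excluding_a_line_drops_its_column(self):
        lm = pd.DataFrame(
            np.arange(8).reshape(2, 4), index=[1.0, 2.0], columns=["S06", "a", "b", "c"]
        )
        out = spearman_screen(lm, exclude_line="S06")
        assert len(out) == 1  # still computed on the remaining 3 lines


class TestScreen:
    def test_screen_output_structure(self, sim_male_mixed):
        res = screen_dataset(sim_male_mixed)
        assert {"peak_label", "F", "p_raw", "p_fdr", "significant"} <= set(res.table.columns)
        assert (res.table["p_fdr"] >= res.table["p_raw"] - 1e-12).all()
        for label in res.emmeans:
            assert set(res.letters[label]) == set(res.emmeans[label].index)

    def test_screen_recovers_injected_line_effects(self, sim_study):
        tables, truth = sim_study
        res = screen_dataset(tables[("male", "mixed")])
        found = set(res.table.loc[res.table["significant"], "peak_label"])
        affected = set(truth.peaks.loc[truth.peaks["line_affected"], "rt"])
        # most discoveries are real injected effects
        assert len(found & affected) >= 0.8 * len(found)
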