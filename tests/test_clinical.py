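import numpy as np
import pandas as pd
import pytest

from scmetgrade import (
    BulkSimConfig,
    GeneSetCollection,
    cox_univariate,
    group_tests,
    intersect_screens,
    km_median_split,
    prognostic_screen,
    score_samples,
    sim_bulk_cohort,
)


@pytest.fixture(scope="module")
def expr_frame():
    rng = np.random.default_rng(12)
    genes = [f"g{i}" for i in range(400)]
    return pd.DataFrame(
        rng.normal(size=(60, 400)), columns=genes,
        index=[f"S{i}" for i in range(60)],
    )


class TestScoreSamples:
    def test_top_genes_score_positive(self, expr_frame):
        sample = expr_frame.iloc[[0, 1]]
        top = sample.iloc[0].nlargest(10).index.tolist()
        gs = GeneSetCollection({"TOP": top})
        scores = score_samples(sample, gs)
        assert scores.iloc[0, 0] > 0

    def test_identical_samples_identical_scores(self, expr_frame):
        dup = pd.concat([expr_frame.iloc[[0]], expr_frame.iloc[[0]]])
        dup.index = ["a", "b"]
        gs = GeneSetCollection({"P": list(expr_frame.columns[:20])})
        scores = score_samples(dup, gs)
        assert scores.iloc[0, 0] == scores.iloc[1, 0]

    def test_monotone_transform_invariance(self, expr_frame):
        gs = GeneSetCollection({"P": list(expr_frame.columns[5:35])})
        base = score_samples(expr_frame, gs)
        transformed = score_samples(np.exp(expr_frame / 2), gs)
        np.testing.assert_allclose(base.to_numpy(), transformed.to_numpy(), atol=1e-12)

    def test_random_set_scores_centered_at_zero(self, expr_frame):
        rng = np.random.default_rng(3)
        members = list(rng.choice(expr_frame.columns, 40, replace=False))
        gs = GeneSetCollection({"RAND": members})
        scores = score_samples(expr_frame, gs)["RAND"]
        se = scores.std() / np.sqrt(len(scores))
        assert abs(scores.mean()) < 2 * se

    def test_unmeasured_pathway_missing_with_warning(self, expr_frame):
        gs = GeneSetCollection({"P": ["g0"], "GONE": ["nope1", "nope2"]})
        with pytest.warns(UserWarning, match="no measured genes"):
            scores = score_samples(expr_frame, gs)
        assert scores["GONE"].isna().all()


class TestGroupTests:
    def test_three_level_anova_power(self):
        rng = np.random.default_rng(7)
        vals = np.concatenate([rng.normal(m, 1, 50) for m in (0, 1, 2)])
        factor = ["II"] * 50 + ["III"] * 50 + ["IV"] * 50
        res = group_tests(pd.Series(vals), pd.Series(factor))
        assert res["test"] == "anova" and res["pval"] < 1e-6

    def test_two_levels_use_welch(self):
        rng = np.random.default_rng(8)
        vals = pd.Series(rng.normal(size=40))
        factor = pd.Series(["A"] * 20 + ["B"] * 20)
        assert group_tests(vals, factor)["test"] == "welch_t"

    def test_singleton_level_dropped_with_warning(self):
        vals = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0])
        factor = pd.Series(["A", "A", "B", "B", "C"])
        with pytest.warns(UserWarning, match="C"):
            res = group_tests(vals, factor)
        assert res["levels"] == ["A", "B"]

    def test_single_usable_level_errors(self):
        vals = pd.Series([1.0, 2.0, 3.0])
        factor = pd.Series(["A", "A", "B"])
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                group_tests(vals, factor)


class TestSurvival:
    def test_km_identical_groups_p_one(self):
        # two groups carrying byte-identical survival data
        time = np.tile([5.0, 10.0, 15.0, 20.0, 25.0, 30.0], 2)
        event = np.tile([1, 0, 1, 1, 0, 1], 2)
        values = np.repeat([0.0, 1.0], 6)
        _, p, curves = km_median_split(values, time, event)
        assert p == pytest.approx(1.0)
        assert curves["low"]["survival"][0] == 1.0

    def test_km_ties_at_median_go_low(self):
        values = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0, 11.0])
        time = np.linspace(1, 11, 11)
        event = np.ones(11, int)
        labels, _, _ = km_median_split(values, time, event)
        assert (labels == "low").sum() == 6  # odd n: extra sample to low

    def test_km_constant_values_error(self):
        with pytest.raises(ValueError, match="split"):
            km_median_split(np.ones(12), np.arange(1.0, 13.0), np.ones(12, int))

    def test_km_curve_non_increasing_matches_empirical_no_censoring(self):
        rng = np.random.default_rng(4)
        time = rng.exponential(10, 40)
        event = np.ones(40, int)
        values = rng.normal(size=40)
        _, _, curves = km_median_split(values, time, event)
        for c in curves.values():
            s = np.array(c["survival"])
            assert s[0] == 1.0 and (np.diff(s) <= 1e-12).all()
        # without censoring KM equals the empirical survival function
        low = values <= np.median(values)
        t_low = np.sort(time[low])
        s_emp = 1 - np.arange(1, low.sum() + 1) / low.sum()
        km_s = np.array(curves["low"]["survival"])[1:]
        np.testing.assert_allclose(km_s, s_emp, atol=1e-12)

    def test_cox_constant_covariate_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            cox_univariate(np.ones(50), np.arange(1.0, 51.0), np.ones(50, int))

    def test_cox_zero_events_errors(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError, match="events"):
            cox_univariate(rng.normal(size=30), np.ones(30), np.zeros(30, int))

    def test_cox_scale_equivariance_per_sd(self):
        co = sim_bulk_cohort(
            BulkSimConfig(n_samples=200, n_genes=5, seed=6,
                          prognostic_genes=[("G1", 0.5)])
        )
        t = co.clinical["os_time"].to_numpy()
        e = co.clinical["os_event"].to_numpy()
        x = co.expr["G1"].to_numpy()
        r1 = cox_univariate(x, t, e)
        r2 = cox_univariate(x * 100.0, t, e)
        assert r1.hr == pytest.approx(r2.hr, rel=1e-8)
        assert r1.direction == "unfavorable"


class TestScreen:
    def make_screen(self, seed, beta=0.8):
        co = sim_bulk_cohort(
            BulkSimConfig(n_samples=250, n_genes=30, seed=seed,
                          prognostic_genes=[("G01", beta)])
        )
        gs = GeneSetCollection(
            {"HIT": ["G01", "G02", "G03"],
             "MISS": [f"G{i:02d}" for i in range(10, 20)]}
        )
        scores = score_samples(co, gs)
        return prognostic_screen(scores, co), co

    def test_screen_reports_both_tests_and_padj(self):
        res, _ = self.make_screen(11)
        assert {"hr", "wald_p", "logrank_p", "wald_padj", "logrank_padj"} <= set(res)
        assert res["n"].eq(250).all()

    def test_intersection_direction_agreement(self):
        res_a, _ = self.make_screen(21)
        res_b, _ = self.make_screen(22)
        inter = intersect_screens(res_a, res_b, alpha=0.2)
        if len(inter):
            assert {"direction_agrees"} <= set(inter.columns)

    def test_single_cohort_yields_results_without_intersection(self):
        res, _ = self.make_screen(31)
        inter = intersect_screens(res, res.iloc[0:0], alpha=0.05)
        assert inter.empty
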