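"""Binomial GLM engine: IRLS correctness, nested testing, simplification,
factor collapsing and influence diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from yeastclim import glm
from yeastclim.glm import (
    BinomialGLM, GlmError, ModelSpec, RankDeficientError,
    collapse_factor, cooks_distance, lrt, percent_deviance_explained,
    refit_without, stepwise_simplify,
)

from ._oracles import newton_ml_fit
from .conftest import random_small_glm_dataset


class TestModelSpec:
    def test_formula_round_trip(self):
        spec = ModelSpec.from_formula(
            "n_sp_positive/n_samples ~ girth_m * region + other_yeast_freq")
        assert set(spec.terms) == {("girth_m",), ("region",),
                                   ("girth_m", "region"),
                                   ("other_yeast_freq",)}
        again = ModelSpec.from_formula(spec.formula())
        assert set(again.terms) == set(spec.terms)

    def test_full_factorial_size(self):
        spec = ModelSpec.full_factorial(["a", "b", "c", "d"])
        assert len(spec.terms) == 15  # all non-empty subsets

    def test_removable_respects_marginality(self):
        spec = ModelSpec.from_formula("y/n ~ a * b + c")
        assert set(spec.removable_terms()) == {("a", "b"), ("c",)}
        reduced = spec.drop(("a", "b"))
        assert set(reduced.removable_terms()) == {("a",), ("b",), ("c",)}

    def test_drop_unknown_term_rejected(self):
        with pytest.raises(GlmError):
            ModelSpec.from_formula("y/n ~ a").drop(("b",))


class TestFit:
    def test_intercept_only_closed_form(self):
        # pooled rate 25% -> intercept = logit(0.25)
        data = pd.DataFrame({"n_samples": [4] * 8,
                             "n_sp_positive": [1] * 8})
        m = BinomialGLM(spec=ModelSpec()).fit(data)
        assert m.coef_[0] == pytest.approx(math.log(0.25 / 0.75), abs=1e-8)

    def test_saturated_model_zero_deviance(self):
        data = pd.DataFrame({
            "n_samples": [10, 10, 10],
            "n_sp_positive": [2, 5, 9],
            "tree": ["a", "b", "c"],
        })
        m = BinomialGLM(spec=ModelSpec(terms=(("tree",),))).fit(data)
        assert m.deviance_ == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_newton_oracle(self, seed):
        rng = np.random.default_rng(seed)
        data = random_small_glm_dataset(rng)
        m = BinomialGLM(spec=ModelSpec(terms=(("x",),))).fit(data)
        X, y, n, _, _, _ = glm.build_design(ModelSpec(terms=(("x",),)), data)
        oracle = newton_ml_fit(X, y, n)
        np.testing.assert_allclose(m.coef_, oracle, atol=1e-6)

    def test_score_equations_hold_at_optimum(self, fitted_final_model):
        m = fitted_final_model
        score = m._design_.T @ (m._y_ - m._n_ * m.fitted_p_)
        assert np.abs(score).max() < 1e-6

    def test_deviance_invariant_to_covariate_rescaling(self):
        rng = np.random.default_rng(3)
        data = random_small_glm_dataset(rng, n_obs=30)
        spec = ModelSpec(terms=(("x",),))
        m1 = BinomialGLM(spec=spec).fit(data)
        scaled = data.assign(x=data["x"] * 100.0)
        m2 = BinomialGLM(spec=spec).fit(scaled)
        assert m2.deviance_ == pytest.approx(m1.deviance_, abs=1e-8)
        assert m2.coef_[1] == pytest.approx(m1.coef_[1] / 100.0, rel=1e-6)

    def test_rank_deficient_design_names_alias(self):
        rng = np.random.default_rng(0)
        data = random_small_glm_dataset(rng, n_obs=20)
        data["x2"] = 2.0 * data["x"]
        spec = ModelSpec(terms=(("x",), ("x2",)))
        with pytest.raises(RankDeficientError, match="x2"):
            BinomialGLM(spec=spec).fit(data)

    def test_missing_girth_rows_excluded(self, default_survey):
        spec = ModelSpec(terms=(("girth_m",),))
        m = BinomialGLM(spec=spec).fit(default_survey)
        n_complete = default_survey["girth_m"].notna().sum()
        assert m.result_.n_obs == n_complete == 104

    def test_estimator_params_round_trip(self):
        # sklearn protocol: get_params/set_params/clone compatibility
        from sklearn.base import clone

        est = BinomialGLM(spec="y/n ~ x", max_iter=50)
        cloned = clone(est)
        assert cloned.get_params()["max_iter"] == 50
        assert cloned.get_params()["spec"] == "y/n ~ x"


class TestLrt:
    def test_identical_specs_give_p_one(self, default_survey, final_model_spec):
        frame = default_survey.dropna(subset=["girth_m"])
        f = glm.fit(final_model_spec, frame)
        res = lrt(f, f)
        assert res.delta_deviance == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == 1.0

    def test_chi_square_tail_value(self):
        # upper-tail probability of 6.63 on 1 df, against direct integration
        from scipy.integrate import quad

        dd, df = 6.63, 1
        dens = lambda u: stats.chi2.pdf(u, df)
        expected, _ = quad(dens, dd, np.inf)
        assert stats.chi2.sf(dd, df) == pytest.approx(expected, rel=1e-8)
        assert expected == pytest.approx(0.0100, abs=5e-4)

    def test_delta_matches_oracle_refits(self):
        rng = np.random.default_rng(7)
        data = random_small_glm_dataset(rng, n_obs=25)
        data["z"] = rng.normal(size=25)
        full_spec = ModelSpec(terms=(("x",), ("z",)))
        red_spec = ModelSpec(terms=(("x",),))
        f_full = glm.fit(full_spec, data)
        f_red = glm.fit(red_spec, data)
        res = lrt(f_red, f_full)
        # oracle: refit both by Newton and recompute deviances
        Xf, y, n, _, _, _ = glm.build_design(full_spec, data)
        Xr = Xf[:, :2]
        bf = newton_ml_fit(Xf, y, n)
        br = newton_ml_fit(Xr, y, n)
        dev = lambda X, b: glm.binomial_deviance(
            y, n, 1 / (1 + np.exp(-(X @ b))))
        assert res.delta_deviance == pytest.approx(
            dev(Xr, br) - dev(Xf, bf), abs=1e-6)

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(1)
        data = random_small_glm_dataset(rng, n_obs=20)
        data["z"] = rng.normal(size=20)
        fa = glm.fit(ModelSpec(terms=(("x",),)), data)
        fb = glm.fit(ModelSpec(terms=(("z",),)), data)
        with pytest.raises(GlmError, match="nested"):
            lrt(fa, fb)

    def test_adding_terms_never_increases_deviance(self, default_survey):
        frame = default_survey.dropna(subset=["girth_m"])
        spec = ModelSpec(terms=())
        prev = glm.fit(spec, frame).deviance
        for term in [("girth_m",), ("region",), ("tmax_c",),
                     ("girth_m", "region"), ("tmax_c", "region")]:
            spec = ModelSpec(terms=spec.terms + (term,))
            cur = glm.fit(spec, frame).deviance
            assert cur <= prev + 1e-8
            prev = cur


class TestStepwise:
    def test_alpha_one_deletes_everything(self, default_survey):
        start = ModelSpec.from_formula(
            "n_sp_positive/n_samples ~ girth_m * region")
        final, log = stepwise_simplify(start, default_survey, alpha=1.0)
        assert final.terms == ()
        assert log["deleted"].sum() == 3

    def test_null_covariate_is_dropped(self, default_survey):
        start = ModelSpec.from_formula(
            "n_sp_positive/n_samples ~ girth_m * region + tmax_c * region"
            " + other_yeast_freq")
        final, log = stepwise_simplify(start, default_survey)
        assert all("other_yeast_freq" not in t for t in final.terms)
        tested = log[log["term"] == "other_yeast_freq"]
        assert len(tested) >= 1

    def test_log_records_every_tested_deletion(self, default_survey):
        start = ModelSpec.from_formula(
            "n_sp_positive/n_samples ~ girth_m + other_yeast_freq")
        final, log = stepwise_simplify(start, default_survey)
        assert {"round", "term", "delta_deviance", "delta_df", "p_value",
                "percent_null_deviance", "deleted"} <= set(log.columns)
        assert (log["delta_deviance"] >= -1e-8).all()
        assert log["p_value"].between(0, 1).all()


class TestCollapseFactor:
    def test_merge_nothing_is_noop(self, default_survey):
        spec = ModelSpec(terms=(("oak_type",),))
        res, collapsed, _ = collapse_factor(
            spec, default_survey, "oak_type",
            {"robur-like": "a", "frainetto-like": "b", "ilex": "c"})
        assert res.delta_deviance == pytest.approx(0.0, abs=1e-7)
        assert res.p_value == pytest.approx(1.0)

    def test_equivalent_levels_collapse_accepted(self):
        # south oak types have identical true effects by construction, so
        # within the full interaction structure, collapsing the three oak
        # types to north/south removes 3 parameters (main + two interaction
        # dummies) and should be accepted at the null rate
        from yeastclim import synthetic

        spec = ModelSpec.from_formula(
            "n_sp_positive/n_samples ~ girth_m * oak_type + tmax_c * oak_type")
        accepted = 0
        for seed in range(20):
            sv = synthetic.simulate_survey(synthetic.SurveyParams(seed=seed))
            res, _, _ = collapse_factor(
                spec, sv, "oak_type",
                {"robur-like": "north", "frainetto-like": "south",
                 "ilex": "south"}, collapsed_name="region2")
            assert res.delta_df == 3
            accepted += res.p_value > 0.05
        assert accepted >= 16  # ~95% expected under a true null

    def test_distinct_levels_collapse_rejected_with_power(self):
        # merging a northern with a southern oak type is genuinely wrong;
        # the rejection rate must grow with survey size
        from yeastclim import synthetic

        grouping = {"robur-like": "one", "frainetto-like": "one",
                    "ilex": "two"}
        spec = ModelSpec(terms=(("oak_type",),))

        def rejections(trees_per_site):
            count = 0
            for seed in range(10):
                sv = synthetic.simulate_survey(synthetic.SurveyParams(
                    seed=seed, trees_per_site=trees_per_site))
                res, _, _ = collapse_factor(spec, sv, "oak_type", grouping)
                count += res.p_value < 0.05
            return count

        small, large = rejections(5), rejections(60)
        assert large >= 9
        assert large >= small

    def test_non_surjective_grouping_rejected(self, default_survey):
        spec = ModelSpec(terms=(("oak_type",),))
        with pytest.raises(GlmError, match="cover"):
            collapse_factor(spec, default_survey, "oak_type",
                            {"robur-like": "north"})


class TestInfluence:
    def test_duplicated_trees_have_equal_influence(self):
        base = pd.DataFrame({
            "x": [0.0, 1.0, 2.0] * 4,
            "n_samples": [5] * 12,
            "n_sp_positive": [1, 2, 4] * 4,
        })
        m = BinomialGLM(spec=ModelSpec(terms=(("x",),))).fit(base)
        d = cooks_distance(m)
        for k in range(3):
            np.testing.assert_allclose(d[k::3], d[k], rtol=1e-9)

    def test_one_step_tracks_exact_leave_one_out(self, fitted_final_model):
        m = fitted_final_model
        d = cooks_distance(m)
        dev_changes = []
        for i in range(m.result_.n_obs):
            loo = refit_without(m, i)
            dev_changes.append(abs(loo.deviance - m.deviance_))
        rho = stats.spearmanr(d, dev_changes).statistic
        assert rho > 0.5

    def test_removing_top_influence_keeps_signs(self, fitted_final_model):
        m = fitted_final_model
        top = int(np.argmax(cooks_distance(m)))
        loo = refit_without(m, top)
        # directions of the statistically meaningful effects survive
        # single-point deletion (near-zero estimates may wobble in sign)
        meaningful = np.abs(m.coef_ / m.bse_) > 2.0
        assert meaningful.any()
        assert np.all(np.sign(loo.beta[meaningful])
                      == np.sign(m.coef_[meaningful]))


class TestPercentDeviance:
    def test_null_and_saturated_extremes(self, default_survey):
        frame = default_survey.dropna(subset=["girth_m"])
        null = glm.fit(ModelSpec(terms=()), frame)
        assert percent_deviance_explained(null) == pytest.approx(0.0, abs=1e-8)
        sat = glm.fit(ModelSpec(terms=(("tree",),)), frame)
        assert percent_deviance_explained(sat) == pytest.approx(100.0, abs=1e-6)

    def test_matches_deviances_from_oracle(self, fitted_final_model):
        m = fitted_final_model
        expected = 100 * (m.null_deviance_ - m.deviance_) / m.null_deviance_
        assert percent_deviance_explained(m.result_) == pytest.approx(expected)


class TestWaldCoverage:
    def test_wald_interval_coverage_near_nominal(self):
        # 200 replicates at n=150: true slope inside beta +/- 1.96 se ~95%
        rng = np.random.default_rng(42)
        true = np.array([-1.0, 0.8])
        covered = 0
        spec = ModelSpec(terms=(("x",),))
        for _ in range(200):
            x = rng.normal(size=150)
            n = np.full(150, 4)
            p = 1 / (1 + np.exp(-(true[0] + true[1] * x)))
            y = rng.binomial(n, p)
            data = pd.DataFrame({"x": x, "n_samples": n, "n_sp_positive": y})
            m = BinomialGLM(spec=spec).fit(data)
            lo = m.coef_[1] - 1.96 * m.bse_[1]
            hi = m.coef_[1] + 1.96 * m.bse_[1]
            covered += lo <= true[1] <= hi
        assert 0.90 <= covered / 200 <= 0.99
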