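import numpy as np
import pandas as pd
import pytest

from domus.models import fit_multinomial
from domus.multimodel import (ModelSpec, akaike_weights, average_model,
                              build_design, complete_cases, crosstab_percent,
                              effect_profile, enumerate_models,
                              fit_candidates, relative_importance)


def toy_data(seed=0, n=400, with_interaction=False):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "temperature_harshness": rng.normal(size=n),
        "xeric_harshness": rng.normal(size=n),
        "political_complexity": rng.integers(1, 6, n).astype(float),
        "polygyny": rng.choice(["none", "occasional", "frequent"], n),
        "language_family": rng.choice([f"f{i}" for i in range(12)], n),
        "lon": rng.uniform(-180, 180, n),
        "lat": rng.uniform(-60, 60, n),
    })
    eta = 1.2 * df["temperature_harshness"].to_numpy()
    if with_interaction:
        eta = df["temperature_harshness"].to_numpy() * \
            (df["political_complexity"].to_numpy() - 3.0)
    df["resp"] = np.where(rng.random(n) < 1 / (1 + np.exp(-eta)),
                          "one", "zero")
    return df


class TestEnumerate:
    def test_powerset_of_three_toggles(self):
        full = ModelSpec("resp", ("a", "b", "c"))
        specs = enumerate_models(full)
        assert len(specs) == 8
        sizes = sorted(len(s.predictors) for s in specs)
        assert sizes[0] == 0 and sizes[-1] == 3

    def test_hierarchy_rule(self):
        full = ModelSpec("resp", ("a", "b", "a:b"))
        specs = enumerate_models(full)
        # 4 subsets of {a,b} + 1 with the interaction
        assert len(specs) == 5
        for s in specs:
            if "a:b" in s.predictors:
                assert "a" in s.predictors and "b" in s.predictors

    def test_random_effect_toggled_and_duplicate_free(self):
        full = ModelSpec("resp", ("a", "b"), random_effect=True)
        specs = enumerate_models(full)
        assert len(specs) == 8
        keys = {(s.predictors, s.random_effect) for s in specs}
        assert len(keys) == len(specs)

    def test_deterministic_order(self):
        full = ModelSpec("resp", ("a", "b", "c"), random_effect=True)
        assert enumerate_models(full) == enumerate_models(full)

    def test_interaction_without_mains_rejected(self):
        with pytest.raises(ValueError, match="interaction"):
            ModelSpec("resp", ("a:b",))


class TestAkaikeWeights:
    def test_equal_aiccs_give_uniform_weights(self):
        w = akaike_weights([100.0] * 5)
        np.testing.assert_allclose(w, 0.2)

    def test_delta_two_closed_form(self):
        w = akaike_weights([10.0, 12.0])
        expect = np.array([1.0, np.exp(-1.0)])
        expect /= expect.sum()
        np.testing.assert_allclose(w, expect, atol=1e-12)

    def test_sum_one_and_order_equivariance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.uniform(50, 150, 7)
            w = akaike_weights(a)
            assert w.sum() == pytest.approx(1.0, abs=1e-12)
            perm = rng.permutation(7)
            np.testing.assert_allclose(akaike_weights(a[perm]), w[perm])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            akaike_weights([])


class TestFitCandidates:
    def test_all_specs_fit_same_n(self):
        df = toy_data(1)
        full = ModelSpec("resp", ("temperature_harshness", "xeric_harshness"),
                         ref_category="zero")
        cc = complete_cases(df, full)
        specs = enumerate_models(full)
        fits = fit_candidates(specs, cc, categories=["zero", "one"])
        assert len(fits) == len(specs)
        assert len({f.n_obs for f in fits}) == 1
        assert all(f.converged for f in fits)

    def test_degenerate_predictor_flagged_not_fatal(self):
        df = toy_data(2)
        df["dead"] = 1.0  # constant: collinear with the intercept
        full = ModelSpec("resp", ("temperature_harshness", "dead"),
                         ref_category="zero")
        specs = enumerate_models(full)
        fits = fit_candidates(specs, df, categories=["zero", "one"])
        for s, f in zip(specs, fits):
            if "dead" in s.predictors:
                assert not f.converged
            else:
                assert f.converged

    def test_complete_cases_drop_missing_and_excluded(self):
        df = toy_data(3, n=50)
        df.loc[0, "temperature_harshness"] = np.nan
        df.loc[1, "resp"] = "missing"
        full = ModelSpec("resp", ("temperature_harshness",),
                         ref_category="zero")
        cc = complete_cases(df, full)
        assert len(cc) == 48


class TestAverage:
    def _fits(self, seed=4):
        df = toy_data(seed)
        full = ModelSpec("resp", ("temperature_harshness", "xeric_harshness"),
                         ref_category="zero")
        specs = enumerate_models(full)
        fits = fit_candidates(specs, df, categories=["zero", "one"])
        return df, full, specs, fits

    def test_single_model_average_is_identity(self):
        df = toy_data(5)
        full = ModelSpec("resp", ("temperature_harshness",),
                         ref_category="zero")
        X, names = build_design(df, full.predictors)
        fit = fit_multinomial(X, df["resp"], ref="zero",
                              categories=["zero", "one"], term_names=names,
                              spec=full)
        avg = average_model([fit], df, full)
        np.testing.assert_allclose(avg.avg_coef.to_numpy(), fit.coef)
        np.testing.assert_allclose(avg.uncond_se.to_numpy(), fit.se,
                                   atol=1e-12)
        np.testing.assert_allclose(avg.avg_prob, fit.fitted_prob)

    def test_identical_models_have_no_spread_term(self):
        df = toy_data(6)
        full = ModelSpec("resp", ("temperature_harshness",),
                         ref_category="zero")
        X, names = build_design(df, full.predictors)
        fit = fit_multinomial(X, df["resp"], ref="zero",
                              categories=["zero", "one"], term_names=names,
                              spec=full)
        avg = average_model([fit, fit], df, full,
                            weights=np.array([0.3, 0.7]))
        np.testing.assert_allclose(avg.uncond_se.to_numpy(), fit.se,
                                   atol=1e-12)

    def test_matches_term_by_term_oracle(self):
        df, full, specs, fits = self._fits()
        avg = average_model(fits, df, full)
        w = akaike_weights([f.aicc for f in fits])
        cols = list(avg.avg_coef.columns)
        # spreadsheet-style recomputation, term by term
        for c in cols:
            est = 0.0
            for wi, f in zip(w, fits):
                names = list(f.term_names)
                est += wi * (f.coef[0, names.index(c)] if c in names else 0.0)
            assert avg.avg_coef.loc["one", c] == pytest.approx(est, abs=1e-12)
            var = 0.0
            for wi, f in zip(w, fits):
                names = list(f.term_names)
                if c in names:
                    j = names.index(c)
                    var += wi * (f.se[0, j] ** 2 + (f.coef[0, j] - est) ** 2)
                else:
                    var += wi * est ** 2
            assert avg.uncond_se.loc["one", c] == pytest.approx(
                np.sqrt(var), abs=1e-12)

    def test_order_invariance(self):
        df, full, specs, fits = self._fits()
        a = average_model(fits, df, full)
        b = average_model(fits[::-1], df, full)
        pd.testing.assert_frame_equal(a.avg_coef, b.avg_coef)
        assert a.accuracy == b.accuracy

    def test_weights_sum_to_one(self):
        df, full, specs, fits = self._fits()
        avg = average_model(fits, df, full)
        assert avg.weights.sum() == pytest.approx(1.0, abs=1e-12)


class TestImportance:
    def test_bounds_and_counting(self):
        s1 = ModelSpec("r", ("a", "b"))
        s2 = ModelSpec("r", ("a",))
        imp = relative_importance([s1, s2], [0.5, 0.5])
        assert imp["a"] == pytest.approx(1.0)
        assert imp["b"] == pytest.approx(0.5)

    def test_absent_predictor_scores_zero(self):
        s1 = ModelSpec("r", ("a",))
        imp = relative_importance([s1], [1.0], all_terms={"a", "z"})
        assert imp["z"] == 0.0

    def test_random_effect_counts_as_predictor(self):
        s1 = ModelSpec("r", ("a",), random_effect=True)
        s2 = ModelSpec("r", ("a",), random_effect=False)
        imp = relative_importance([s1, s2], [0.25, 0.75])
        assert imp["language_family"] == pytest.approx(0.25)


class TestEffectProfile:
    def test_monotone_curve_for_positive_slope(self):
        df = toy_data(7)
        full = ModelSpec("resp", ("temperature_harshness",),
                         ref_category="zero")
        X, names = build_design(df, full.predictors)
        fit = fit_multinomial(X, df["resp"], ref="zero",
                              categories=["zero", "one"], term_names=names,
                              spec=full)
        avg = average_model([fit], df, full)
        prof = effect_profile(avg, "temperature_harshness",
                              np.linspace(-2, 2, 15))
        p = prof["one"].to_numpy()
        assert (np.diff(p) > 0).all()
        np.testing.assert_allclose(
            prof[["zero", "one"]].sum(axis=1), 1.0, atol=1e-12)

    def test_interaction_flips_slope_across_strata(self):
        df = toy_data(8, n=1500, with_interaction=True)
        full = ModelSpec("resp", ("temperature_harshness",
                                  "political_complexity",
                                  "temperature_harshness:political_complexity"),
                         ref_category="zero")
        specs = enumerate_models(full)
        fits = fit_candidates(specs, df, categories=["zero", "one"])
        avg = average_model(fits, df, full)
        prof = effect_profile(avg, "temperature_harshness",
                              np.linspace(-2, 2, 9),
                              by="political_complexity", by_levels=(1.0, 5.0))
        lo = prof[prof["political_complexity"] == 1.0]["one"].to_numpy()
        hi = prof[prof["political_complexity"] == 5.0]["one"].to_numpy()
        # generative slope is (pc - 3): negative at pc=1, positive at pc=5
        assert lo[-1] < lo[0]
        assert hi[-1] > hi[0]

    def test_unknown_composite_rejected(self):
        df, full = toy_data(9), ModelSpec("resp", ("temperature_harshness",),
                                          ref_category="zero")
        X, names = build_design(df, full.predictors)
        fit = fit_multinomial(X, df["resp"], ref="zero",
                              categories=["zero", "one"], term_names=names,
                              spec=full)
        avg = average_model([fit], df, full)
        with pytest.raises(ValueError, match="unknown composite"):
            effect_profile(avg, "nope", [0.0])


class TestCrosstab:
    def test_rows_sum_to_hundred(self):
        rng = np.random.default_rng(10)
        a = rng.choice(["x", "y", "z"], 100)
        b = rng.choice(["p", "q"], 100)
        pct, counts = crosstab_percent(a, b)
        np.testing.assert_allclose(pct.sum(axis=1), 100.0, atol=1e-9)
        assert counts.to_numpy().sum() == 100

    def test_hand_tally(self):
        a = ["m", "m", "m", "p", "p", "p"]
        b = ["round", "round", "angular", "round", "angular", "angular"]
        pct, counts = crosstab_percent(a, b)
        assert pct.loc["m", "round"] == pytest.approx(200 / 3)
        assert pct.loc["p", "angular"] == pytest.approx(200 / 3)
        assert counts.loc["m", "round"] == 2

    def test_absent_category_kept_as_zero(self):
        pct, counts = crosstab_percent(["m", "p"], ["round", "round"],
                                       b_levels=["round", "angular"])
        assert pct.loc["m", "angular"] == 0.0
        assert counts.loc["p", "angular"] == 0

    def test_missing_dropped_pairwise_and_empty_rejected(self):
        pct, _ = crosstab_percent(["m", "missing", "p"],
                                  ["round", "round", "missing"])
        assert pct.shape == (1, 1)
        with pytest.raises(ValueError):
            crosstab_percent(["missing"], ["round"])
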