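"""PLS engine: OLS limits, VIP identities, LOO selection, equation export."""

import numpy as np
import pandas as pd
import pytest

from scar16.equations import LinearEquation
from scar16.models import (
    BIOCHEM_INPUT_DISTS,
    OPTIMIZED_BIOCHEM_INPUTS,
    reference_aoo_equation,
    reference_sara_biochem_equation,
    reference_sara_clinical_equation,
)
from scar16.pls import (
    PLSVIPRegressor,
    encode_design,
    fit_pls,
    loo_select,
    reduce_and_refit,
)
from scar16.synthetic import generate_from_equation

SIM_VARS = ["pct_hsp70_ub", "pct_chain", "kd", "bmax"]


class TestEncodeDesign:
    def test_continuous_standardized(self, rng):
        df = pd.DataFrame({"x": rng.normal(3, 2, 30)})
        d = encode_design(df, ["x"])
        assert d.X[:, 0].mean() == pytest.approx(0.0, abs=1e-12)
        assert d.X[:, 0].std(ddof=1) == pytest.approx(1.0)

    def test_binary_factor_symmetric_columns(self):
        df = pd.DataFrame({"g": ["Y", "N", "Y", "N"]})
        d = encode_design(df, ["g"])
        assert d.columns == ["g[N]", "g[Y]"]
        np.testing.assert_allclose(d.X[:, 0], -d.X[:, 1])

    def test_five_level_factor_keeps_all_levels(self):
        df = pd.DataFrame({"anc": ["AMR", "SAS", "MENA", "EUR", "EAS"] * 3})
        d = encode_design(df, ["anc"])
        assert d.n_columns == 5
        assert d.factor_levels["anc"] == ["AMR", "EAS", "EUR", "MENA", "SAS"]

    def test_constant_column_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            encode_design(pd.DataFrame({"x": [2.0, 2.0, 2.0]}), ["x"])
        with pytest.raises(ValueError, match="single level"):
            encode_design(pd.DataFrame({"g": ["a", "a", "a"]}), ["g"])


class TestFitPLS:
    def test_single_predictor_single_factor_equals_ols(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=25)})
        y = pd.Series(2.0 * df.x.to_numpy() + rng.normal(size=25), name="y")
        model = fit_pls(encode_design(df, ["x"]), y, 1)
        slope, intercept = np.polyfit(df.x, y, 1)
        np.testing.assert_allclose(
            model.predict(df)[:, 0], intercept + slope * df.x, rtol=1e-9
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_full_factor_predictions_equal_ols(self, seed):
        rng = np.random.default_rng(seed)
        n, p = int(rng.integers(12, 50)), int(rng.integers(2, 7))
        df = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{i}" for i in range(p)])
        y = pd.Series(rng.normal(size=n), name="y")
        model = fit_pls(encode_design(df, list(df.columns)), y, p)
        X1 = np.column_stack([np.ones(n), df.to_numpy()])
        beta = np.linalg.lstsq(X1, y.to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(model.predict(df)[:, 0], X1 @ beta, atol=1e-8)

    def test_matches_sklearn_nipals_at_reduced_rank(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        df = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
        y = pd.Series(rng.normal(size=30), name="y")
        ours = fit_pls(encode_design(df, list(df.columns)), y, 2)
        ref = PLSRegression(n_components=2, scale=True).fit(df, y)
        np.testing.assert_allclose(
            ours.predict(df)[:, 0], ref.predict(df).ravel(), atol=1e-10
        )

    def test_scores_orthogonal(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        y = pd.DataFrame({"u": rng.normal(size=20), "v": rng.normal(size=20)})
        model = fit_pls(encode_design(df, list(df.columns)), y, 3)
        G = model.T.T @ model.T
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0.0, atol=1e-10)

    def test_too_many_factors_rejected(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 2)), columns=list("ab"))
        y = pd.Series(rng.normal(size=10), name="y")
        with pytest.raises(ValueError, match="n_factors"):
            fit_pls(encode_design(df, ["a", "b"]), y, 5)


class TestVIP:
    def test_single_predictor_is_one(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=20)})
        y = pd.Series(df.x * 3 + rng.normal(size=20), name="y")
        model = fit_pls(encode_design(df, ["x"]), y, 1)
        assert model.vip_[0] == pytest.approx(1.0)

    def test_mean_square_is_one(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 6)), columns=list("abcdef"))
        y = pd.Series(rng.normal(size=30), name="y")
        for A in (1, 3, 6):
            model = fit_pls(encode_design(df, list(df.columns)), y, A)
            assert (model.vip_**2).mean() == pytest.approx(1.0, rel=1e-9)

    def test_equal_weight_predictors_share_vip(self, rng):
        z = rng.normal(size=200)
        df = pd.DataFrame({"a": z + rng.normal(0, 1e-6, 200),
                           "b": z + rng.normal(0, 1e-6, 200)})
        y = pd.Series(z, name="y")
        model = fit_pls(encode_design(df, ["a", "b"]), y, 1)
        np.testing.assert_allclose(model.vip_, [1.0, 1.0], rtol=1e-3)


class TestLOOSelection:
    def test_perfect_single_factor_selects_one(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=24)})
        y = pd.Series(4.0 * df.x + 1.0, name="y")
        A, press = loo_select(df, y, ["x"])
        assert A == 1
        assert press[1] < press[0]

    def test_pure_noise_selects_nothing_informative(self):
        small_a = 0
        for seed in range(8):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(rng.normal(size=(24, 4)), columns=list("abcd"))
            y = pd.Series(rng.normal(size=24), name="y")
            A, press = loo_select(df, y, list(df.columns))
            small_a += A <= 1
            # intercept-only PRESS is the scaled total SS, and no factor
            # count looks much better than it under pure noise
            assert press[0] == pytest.approx(24 * (24 / 23), rel=1e-9)
            assert press[A] > 0.7 * press[0]
        assert small_a >= 6


class TestReduceAndRefit:
    def test_all_predictors_retained_refit_is_initial(self, rng):
        z1, z2 = rng.normal(size=(2, 100))
        df = pd.DataFrame({"a": z1, "b": z2})
        y = pd.Series(3 * z1 + 3 * z2 + rng.normal(0, 0.5, 100), name="y")
        est = PLSVIPRegressor().fit(df, y)
        assert set(est.support_) == {"a", "b"}
        assert est.model_ is est.initial_model_

    def test_noise_predictor_dropped(self, rng):
        z = rng.normal(size=150)
        df = pd.DataFrame({"signal": z, "noise": rng.normal(size=150)})
        y = pd.Series(5 * z + rng.normal(0, 0.8, 150), name="y")
        model, equations = reduce_and_refit(df, y, ["signal", "noise"])
        assert [t.name for t in equations["y"].continuous] == ["signal"]

    def test_reduction_never_inflates_factor_count(self, cohort_df):
        data = cohort_df.dropna(subset=["aoo"]).copy()
        data["homozygous"] = data["homozygous"].map({True: "Y", False: "N"})
        est = PLSVIPRegressor().fit(
            data[["sex", "ancestry", "homozygous", "cd", "tr", "aoo"]],
            data["sara"].rename("sara"),
        )
        assert est.n_components_ <= est.initial_model_.n_factors

    def test_sklearn_params_roundtrip(self):
        est = PLSVIPRegressor(vip_cutoff=0.9)
        assert est.get_params()["vip_cutoff"] == 0.9
        est.set_params(n_components=2)
        assert est.n_components == 2


class TestEquationExport:
    def test_export_evaluates_identically_to_model(self, rng):
        df = pd.DataFrame({
            "x": rng.normal(size=40),
            "g": rng.choice(["A", "B", "C"], size=40),
        })
        y = pd.Series(rng.normal(size=40) + (df.g == "A") * 2, name="y")
        model = fit_pls(encode_design(df, ["x", "g"]), y, 2)
        eq = model.equation("y")
        got = np.array([eq.evaluate(r) for r in df.to_dict("records")])
        np.testing.assert_allclose(got, model.predict(df)[:, 0], atol=1e-10)

    def test_offsets_sum_to_zero_and_intercept_is_center_value(self, rng):
        df = pd.DataFrame({
            "x": rng.normal(size=40),
            "g": rng.choice(["A", "B"], size=40),
        })
        y = pd.Series(rng.normal(size=40), name="y")
        eq = fit_pls(encode_design(df, ["x", "g"]), y, 2).equation("y")
        (factor,) = eq.categorical
        assert sum(factor.offsets.values()) == pytest.approx(0.0, abs=1e-10)
        # at centered continuous inputs, averaging over levels recovers the intercept
        (cont,) = eq.continuous
        vals = [eq.evaluate({"x": cont.center, "g": lvl}) for lvl in factor.offsets]
        assert np.mean(vals) == pytest.approx(eq.intercept, abs=1e-10)

    def test_json_roundtrip(self, tmp_path):
        eq = reference_sara_clinical_equation()
        eq.to_json(tmp_path / "eq.json")
        back = LinearEquation.from_json(tmp_path / "eq.json")
        assert back == eq

    def test_reference_clinical_equation_arithmetic(self):
        eq = reference_sara_clinical_equation()
        val = eq.evaluate({"cd": "Y", "ancestry": "EUR", "tr": "Y"})
        assert val == pytest.approx(17.2 + 5.6 + 4.7 + 2.7)
        with pytest.raises(KeyError, match="unknown level"):
            eq.evaluate({"cd": "Y", "ancestry": "ATLANTIS", "tr": "Y"})

    def test_reference_biochem_equations_at_published_optimum(self):
        assert reference_aoo_equation().evaluate(
            OPTIMIZED_BIOCHEM_INPUTS
        ) == pytest.approx(27.698, abs=1e-3)
        assert reference_sara_biochem_equation().evaluate(
            OPTIMIZED_BIOCHEM_INPUTS
        ) == pytest.approx(10.608, abs=1e-3)


class TestParameterRecovery:
    def test_raw_scale_coefficients_recovered(self):
        eq = reference_aoo_equation()
        good_seeds = 0
        for seed in range(10):
            df = generate_from_equation(eq, BIOCHEM_INPUT_DISTS, n=500,
                                        noise_sd=5, seed=seed)
            est = PLSVIPRegressor(n_components=4, vip_cutoff=None)
            est.fit(df[SIM_VARS], df["aoo"])
            fit_eq = est.equations_["aoo"]
            slopes = {t.name: t.coefficient / t.scale for t in fit_eq.continuous}
            truth = {t.name: t.coefficient / t.scale for t in eq.continuous}
            if all(abs(slopes[k] - truth[k]) <= 0.15 * abs(truth[k]) for k in truth):
                good_seeds += 1
        assert good_seeds >= 8

    def test_multiresponse_sign_pattern(self):
        eqs = [reference_aoo_equation(), reference_sara_biochem_equation()]
        df = generate_from_equation(eqs, BIOCHEM_INPUT_DISTS, n=400,
                                    noise_sd={"aoo": 4, "sara": 2}, seed=1)
        est = PLSVIPRegressor(n_components=4, vip_cutoff=None)
        est.fit(df[SIM_VARS], df[["aoo", "sara"]])
        for eq in eqs:
            fit_eq = est.equations_[eq.response]
            fit_coef = {t.name: t.coefficient for t in fit_eq.continuous}
            for t in eq.continuous:
                assert np.sign(fit_coef[t.name]) == np.sign(t.coefficient)
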