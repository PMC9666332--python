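"""Model variants, priors, likelihood and the maximum-likelihood oracle."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sensmed as sm
from sensmed.errors import InvalidParameterError, SchemaError
from sensmed.models import build_design


@pytest.fixture()
def tiny_data():
    rng = np.random.default_rng(42)
    cols = ["permissive", "es", "rumination", "depression_9", "depression_12"]
    return sm.Dataset(pd.DataFrame(rng.normal(size=(5, 5)), columns=cols))


@pytest.fixture(scope="module")
def sim_data(permissive_truth):
    return sm.generate_structural(
        sm.StructuralScenario(permissive_truth, n=100_000, seed=10)
    )


class TestDefaultPriors:
    @pytest.mark.parametrize(
        "style,variant,path,loc,scale",
        [
            ("permissive", "interaction", "k", 0.3, 0.1),
            ("authoritarian", "interaction", "k", 0.0, 1.0),
            ("authoritative", "interaction", "k", 0.0, 1.0),
            ("authoritative", "mediation", "a", -0.1, 0.1),
            ("permissive", "mediation", "a", 0.1, 0.1),
            ("authoritarian", "mediation", "c1", 0.1, 0.1),
            ("authoritative", "mediation", "c2", -0.05, 0.1),
            ("permissive", "mediation", "b1", 0.50, 0.10),
            ("permissive", "mediation", "b2", 0.35, 0.10),
            ("permissive", "additive", "w", 0.0, 0.2),
        ],
    )
    def test_printed_prior_values(self, style, variant, path, loc, scale):
        priors = sm.default_priors(style, variant)
        assert priors.paths[path].loc == pytest.approx(loc)
        assert priors.paths[path].scale == pytest.approx(scale)

    def test_variant_excludes_paths(self):
        med = sm.default_priors("permissive", "mediation")
        add = sm.default_priors("permissive", "additive")
        assert "w" not in med.paths and "k" not in med.paths
        assert "w" in add.paths and "k" not in add.paths
        assert sm.default_priors("permissive", "null").paths == {}

    def test_residual_prior_is_gamma_1_05(self):
        pr = sm.default_priors("permissive", "interaction").resid
        assert (pr.shape, pr.rate) == (1.0, 0.5)

    def test_unknown_style_rejected(self):
        with pytest.raises(InvalidParameterError):
            sm.default_priors("neglectful", "mediation")


class TestLogLikelihood:
    def test_null_model_closed_form(self, exact_data):
        spec = sm.PathModelSpec(variant="null", parenting_style="permissive")
        ml = sm.fit_ml(spec, exact_data)
        n = exact_data.n
        # each z-scored variable at its ML variance contributes -n/2(log 2πv + 1)
        expected = sum(
            -0.5 * n * (math.log(2 * math.pi * v) + 1) for v in ml.resid_var.values()
        )
        assert sm.log_likelihood(spec, ml, exact_data) == pytest.approx(expected)

    def test_matches_per_row_oracle(self, tiny_data):
        spec = sm.PathModelSpec(variant="mediation", parenting_style="permissive")
        params = sm.PathParams(
            a=0.3, b1=0.5, b2=0.1, c1=-0.2, c2=0.4,
            resid_var={"rumination": 0.8, "depression_9": 1.3, "depression_12": 0.5},
        )
        df = tiny_data.df
        z = {c: stats.zscore(df[c], ddof=1) for c in df.columns}
        expected = 0.0
        expected += stats.norm.logpdf(
            z["rumination"], 0.3 * z["permissive"], math.sqrt(0.8)
        ).sum()
        expected += stats.norm.logpdf(
            z["depression_9"], -0.2 * z["permissive"] + 0.5 * z["rumination"],
            math.sqrt(1.3),
        ).sum()
        expected += stats.norm.logpdf(
            z["depression_12"], 0.4 * z["permissive"] + 0.1 * z["rumination"],
            math.sqrt(0.5),
        ).sum()
        assert sm.log_likelihood(spec, params, tiny_data) == pytest.approx(expected)

    def test_ml_solution_is_likelihood_maximum_over_paths(self, exact_data):
        spec = sm.PathModelSpec(variant="additive", parenting_style="authoritarian")
        ml = sm.fit_ml(spec, exact_data)
        base = sm.log_likelihood(spec, ml, exact_data)
        rng = np.random.default_rng(0)
        for _ in range(20):
            perturbed = sm.PathParams.from_dict(ml.to_dict())
            path = rng.choice(["a", "w", "b1", "c1", "b2", "c2"])
            setattr(perturbed, path, getattr(ml, path) + rng.uniform(-0.1, 0.1))
            assert sm.log_likelihood(spec, perturbed, exact_data) <= base

    def test_nested_variants_agree_when_extra_path_is_zero(self, tiny_data):
        base = dict(a=0.2, b1=0.4, b2=0.3, c1=0.1, c2=0.0)
        rv = {"rumination": 1.0, "depression_9": 1.0, "depression_12": 1.0}
        add = sm.PathParams(**base, w=0.25, k=0.0, resid_var=rv)
        inter = sm.PathParams(**base, w=0.25, k=0.0, resid_var=rv)
        med = sm.PathParams(**base, w=0.0, resid_var=rv)
        s_int = sm.PathModelSpec(variant="interaction", parenting_style="permissive")
        s_add = sm.PathModelSpec(variant="additive", parenting_style="permissive")
        s_med = sm.PathModelSpec(variant="mediation", parenting_style="permissive")
        assert sm.log_likelihood(s_int, inter, tiny_data) == pytest.approx(
            sm.log_likelihood(s_add, add, tiny_data)
        )
        add0 = sm.PathParams(**base, w=0.0, resid_var=rv)
        assert sm.log_likelihood(s_add, add0, tiny_data) == pytest.approx(
            sm.log_likelihood(s_med, med, tiny_data)
        )

    def test_missing_column_raises_schema_error(self):
        df = pd.DataFrame(np.random.default_rng(1).normal(size=(10, 2)),
                          columns=["permissive", "rumination"])
        spec = sm.PathModelSpec(variant="mediation", parenting_style="permissive")
        with pytest.raises(SchemaError):
            build_design(spec, sm.Dataset(df))

    def test_nonpositive_residual_variance_raises(self, tiny_data):
        spec = sm.PathModelSpec(variant="mediation", parenting_style="permissive")
        bad = sm.PathParams(resid_var={"rumination": 0.0, "depression_9": 1.0,
                                       "depression_12": 1.0})
        with pytest.raises(ValueError):
            sm.log_likelihood(spec, bad, tiny_data)


class TestLogPrior:
    def test_value_at_mode_matches_normal_density(self):
        priors = sm.default_priors("permissive", "mediation")
        params = sm.PathParams(
            a=0.1, b1=0.5, b2=0.35, c1=0.1, c2=0.05,
            resid_var={"rumination": 1.0, "depression_9": 1.0, "depression_12": 1.0},
        )
        lp = sm.log_prior(params, priors)
        expected = sum(
            stats.norm.logpdf(pr.loc, pr.loc, pr.scale)
            for pr in priors.paths.values()
        ) + 3 * stats.gamma.logpdf(1.0, 1.0, scale=2.0)
        assert lp == pytest.approx(expected)

    def test_additive_in_single_path_changes(self):
        priors = sm.default_priors("permissive", "interaction")
        rv = {"rumination": 1.0, "depression_9": 1.0, "depression_12": 1.0}
        p0 = sm.PathParams(resid_var=rv)
        p1 = sm.PathParams(b1=0.2, resid_var=rv)
        delta = sm.log_prior(p1, priors) - sm.log_prior(p0, priors)
        pr = priors.paths["b1"]
        assert delta == pytest.approx(
            stats.norm.logpdf(0.2, pr.loc, pr.scale)
            - stats.norm.logpdf(0.0, pr.loc, pr.scale)
        )

    def test_far_tail_interaction_value(self):
        priors = sm.default_priors("permissive", "interaction")
        rv = {"rumination": 1.0, "depression_9": 1.0, "depression_12": 1.0}
        params = sm.PathParams(k=10.0, resid_var=rv)
        assert sm.log_prior(params, priors) < -4000

    def test_outside_support_is_minus_inf(self):
        priors = sm.default_priors("permissive", "mediation")
        params = sm.PathParams(resid_var={"rumination": -0.5, "depression_9": 1.0,
                                          "depression_12": 1.0})
        assert sm.log_prior(params, priors) == -math.inf

    def test_precision_parameterization_integrates_jacobian(self):
        # same gamma prior placed on sd vs precision gives different densities
        sd = sm.PriorSet({}, resid_parameterization="sd")
        prec = sm.PriorSet({}, resid_parameterization="precision")
        assert sd.log_prior_sigma(0.9) != pytest.approx(prec.log_prior_sigma(0.9))


class TestFitML:
    def test_simple_regression_equals_printed_correlation(self, exact_data):
        # mediation variant: rumination ~ authoritative only, slope = r = −0.14
        spec = sm.PathModelSpec(variant="mediation", parenting_style="authoritative")
        ml = sm.fit_ml(spec, exact_data)
        assert ml.a == pytest.approx(-0.14, abs=1e-10)

    def test_matches_statsmodels_ols(self, sim_data):
        import statsmodels.api as sma

        spec = sm.PathModelSpec(variant="interaction", parenting_style="permissive")
        ml = sm.fit_ml(spec, sim_data)
        design = build_design(spec, sim_data)
        y, X, names = design.equations["rumination"]
        res = sma.OLS(y, X).fit()
        for coef, path in zip(res.params, names):
            assert getattr(ml, path) == pytest.approx(coef, abs=1e-10)

    def test_normal_equations_satisfied(self, exact_data):
        spec = sm.PathModelSpec(variant="additive", parenting_style="permissive")
        ml = sm.fit_ml(spec, exact_data)
        design = build_design(spec, exact_data)
        for endo, (y, X, names) in design.equations.items():
            beta = np.array([ml.path(p) for p in names])
            resid = y - X @ beta
            assert np.abs(X.T @ resid).max() < 1e-10

    def test_zero_path_consistency_at_large_n(self):
        pp = sm.PathParams()
        ds = sm.generate_structural(sm.StructuralScenario(pp, n=100_000, seed=20))
        spec = sm.PathModelSpec(variant="interaction", parenting_style="permissive")
        ml = sm.fit_ml(spec, ds)
        for path in ("a", "w", "k", "b1", "c1", "b2", "c2"):
            assert abs(ml.path(path)) < 0.02

    def test_interaction_recovery_at_large_n(self, sim_data, permissive_truth):
        spec = sm.PathModelSpec(variant="interaction", parenting_style="permissive")
        ml = sm.fit_ml(spec, sim_data)
        assert ml.k == pytest.approx(permissive_truth.k, abs=0.02)
        assert ml.b1 == pytest.approx(permissive_truth.b1, abs=0.02)

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {
                "permissive": rng.normal(size=50),
                "es": rng.normal(size=50),
                "rumination": rng.normal(size=50),
                "depression_12": rng.normal(size=50),
            }
        )
        df["depression_9"] = df["rumination"]  # second equation collinear response ok;
        # make predictors collinear instead: parenting duplicated as es
        df["es"] = df["permissive"]
        spec = sm.PathModelSpec(variant="interaction", parenting_style="permissive")
        # product of identical z-scores is fine, but a == w column duplicates
        from sensmed.errors import SingularDesignError

        with pytest.raises(SingularDesignError):
            sm.fit_ml(spec, sm.Dataset(df))


def test_spec_from_config_overrides_priors():
    from sensmed.models import spec_from_config

    spec, priors = spec_from_config(
        {"style": "authoritative", "variant": "additive",
         "priors": {"w": [0.1, 0.05]}}
    )
    assert spec.parenting_style == "authoritative"
    assert priors.paths["w"].loc == 0.1
    assert priors.paths["w"].scale == 0.05
    with pytest.raises(SchemaError):
        spec_from_config({"variant": "mediation", "priors": {"k": [0, 1]}})
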