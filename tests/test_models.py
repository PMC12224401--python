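"""Mixed logistic estimator: oracles, reductions, invariances, AIC."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from foodenv.models import (
    ConstantColumnError,
    ModelSpec,
    _MarginalLikelihood,
    compare_aic,
    exposure_or_table,
    fit_ri_logistic,
    prepare_analytic,
    progressive_fit,
    standardize,
)

from conftest import brute_force_loglik, simulate_ri_logistic


class TestStandardize:
    def test_closed_form(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        out, params = standardize(df, ["x"])
        assert np.allclose(out["x"], [-1.22474487, 0.0, 1.22474487])
        assert params["x"] == (2.0, pytest.approx(np.sqrt(2 / 3)))

    def test_idempotent_and_centred(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.exponential(3, 500)})
        z1, _ = standardize(df, ["x"])
        z2, _ = standardize(z1, ["x"])
        assert np.allclose(z1["x"], z2["x"])
        assert abs(z1["x"].mean()) < 1e-10
        assert z1["x"].std(ddof=0) == pytest.approx(1.0)

    def test_constant_column_named(self):
        df = pd.DataFrame({"flat": [2.0, 2.0, 2.0]})
        with pytest.raises(ConstantColumnError, match="flat"):
            standardize(df, ["flat"])


class TestLikelihoodOracle:
    def test_aghq_matches_dense_integration_tiny(self):
        """3 groups x 4 obs: AGHQ log-likelihood vs brute-force trapezoid."""
        rng = np.random.default_rng(1)
        df = simulate_ri_logistic(rng, 12, 3, (-1.0, 0.5), 0.8)
        X = np.column_stack([np.ones(len(df)), df["x"]])
        ml = _MarginalLikelihood(df["y"].to_numpy(), X, df["g"].to_numpy(), 15)
        for beta, sigma in [
            (np.array([-1.0, 0.5]), 0.8),
            (np.array([0.3, -0.2]), 0.1),
            (np.array([-2.0, 1.0]), 1.5),
        ]:
            aghq = ml.loglik(beta, sigma)
            brute = brute_force_loglik(df, beta, sigma)
            assert abs(aghq - brute) < 1e-6

    def test_aghq_matches_dense_integration_moderate(self):
        rng = np.random.default_rng(2)
        df = simulate_ri_logistic(rng, 200, 10, (-0.5, 0.3), 0.6)
        X = np.column_stack([np.ones(len(df)), df["x"]])
        ml = _MarginalLikelihood(df["y"].to_numpy(), X, df["g"].to_numpy(), 15)
        beta = np.array([-0.5, 0.3])
        assert abs(ml.loglik(beta, 0.6) - brute_force_loglik(df, beta, 0.6)) < 1e-6


class TestReductions:
    def test_sigma_zero_equals_plain_logistic(self):
        """sigma_u fixed at 0 reproduces ordinary logistic regression."""
        import statsmodels.api as sm
        rng = np.random.default_rng(3)
        df = simulate_ri_logistic(rng, 600, 30, (-1.2, 0.4), 0.0)
        fit = fit_ri_logistic(
            df, ModelSpec(outcome="y", exposure="x", group="g", fix_sigma_u=0.0)
        )
        X = np.column_stack([np.ones(len(df)), df["x"]])
        oracle = sm.Logit(df["y"], X).fit(disp=0)
        got = np.array([fit.coefficients["intercept"], fit.coefficients["x"]])
        assert np.max(np.abs(got - oracle.params.to_numpy())) < 1e-4
        assert fit.log_likelihood == pytest.approx(oracle.llf, abs=1e-6)

    def test_boundary_detected_when_truth_is_zero(self):
        rng = np.random.default_rng(4)
        df = simulate_ri_logistic(rng, 2000, 50, (-1.0, 0.3), 0.0)
        fit = fit_ri_logistic(df, ModelSpec(outcome="y", exposure="x", group="g"))
        # either a genuine tiny estimate or an explicit boundary refit
        assert fit.sigma_u < 0.15 or fit.boundary


class TestQuadrature:
    def test_node_count_stability(self):
        """Estimates at 15 vs 25 nodes agree to 1e-4 relative."""
        rng = np.random.default_rng(5)
        df = simulate_ri_logistic(rng, 1500, 75, (-1.0, 0.35), 0.6)
        f15 = fit_ri_logistic(df, ModelSpec(outcome="y", exposure="x", group="g",
                                            quadrature_nodes=15))
        f25 = fit_ri_logistic(df, ModelSpec(outcome="y", exposure="x", group="g",
                                            quadrature_nodes=25))
        for term in f15.coefficients:
            a, b = f15.coefficients[term], f25.coefficients[term]
            assert abs(a - b) / max(abs(b), 1.0) < 1e-4
        assert abs(f15.sigma_u - f25.sigma_u) / f25.sigma_u < 1e-3


class TestInvariances:
    def test_or_invariant_under_exposure_rescaling(self):
        """The OR per SD of a z-scored exposure ignores raw linear rescaling."""
        rng = np.random.default_rng(6)
        df = simulate_ri_logistic(rng, 1200, 60, (-1.0, 0.3), 0.5)
        df["raw"] = 3.0 + 10.0 * df["x"]
        z1, _ = standardize(df.assign(e=df["raw"]), ["e"])
        z2, _ = standardize(df.assign(e=1000.0 - 0.02 * df["raw"]), ["e"])
        f1 = fit_ri_logistic(z1, ModelSpec(outcome="y", exposure="e", group="g"))
        f2 = fit_ri_logistic(z2, ModelSpec(outcome="y", exposure="e", group="g"))
        assert abs(abs(f1.coefficients["e"]) - abs(f2.coefficients["e"])) < 1e-5


class TestAIC:
    def test_definition_k_plus_one(self):
        rng = np.random.default_rng(7)
        df = simulate_ri_logistic(rng, 400, 20, (-1.0, 0.4), 0.4)
        fit = fit_ri_logistic(df, ModelSpec(outcome="y", exposure="x", group="g"))
        k = len(fit.coefficients) + 1  # + variance parameter
        assert fit.aic == pytest.approx(2 * k - 2 * fit.log_likelihood)

    def test_truth_model_preferred_on_strong_effect(self):
        rng = np.random.default_rng(8)
        df = simulate_ri_logistic(rng, 2000, 80, (-1.0, 0.8), 0.5)
        null = fit_ri_logistic(df, ModelSpec(outcome="y", exposure=None, group="g"))
        full = fit_ri_logistic(df, ModelSpec(outcome="y", exposure="x", group="g"))
        t = compare_aic({"null": null, "full": full})
        assert t.iloc[0]["model"] == "full"
        assert t.loc[t["model"] == "null", "delta_aic"].iloc[0] > 2

    def test_mixed_samples_rejected(self):
        rng = np.random.default_rng(9)
        d1 = simulate_ri_logistic(rng, 200, 10, (-1.0, 0.3), 0.4)
        d2 = simulate_ri_logistic(rng, 300, 10, (-1.0, 0.3), 0.4)
        f1 = fit_ri_logistic(d1, ModelSpec(outcome="y", exposure="x", group="g"))
        f2 = fit_ri_logistic(d2, ModelSpec(outcome="y", exposure="x", group="g"))
        with pytest.raises(ValueError, match="identical"):
            compare_aic({"a": f1, "b": f2})


def test_cross_check_against_glmer(tmp_path):
    """Independent mixed-model routine (lme4::glmer, 15-node AGHQ) agrees."""
    rng = np.random.default_rng(10)
    df = simulate_ri_logistic(rng, 600, 40, (-1.0, 0.4), 0.6)
    fit = fit_ri_logistic(df, ModelSpec(outcome="y", exposure="x", group="g"))
    csv = tmp_path / "d.csv"
    df.to_csv(csv, index=False)
    script = (
        'suppressMessages(library(lme4)); '
        f'd <- read.csv("{csv}"); '
        'm <- glmer(y ~ x + (1|g), data=d, family=binomial, nAGQ=15); '
        'cat(fixef(m), sqrt(unlist(VarCorr(m))), logLik(m), sep="\\n")'
    )
    res = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, timeout=600)
    assert res.returncode == 0, res.stderr[-500:]
    b0, b1, sd, ll = (float(v) for v in res.stdout.split())
    assert fit.coefficients["intercept"] == pytest.approx(b0, abs=2e-4)
    assert fit.coefficients["x"] == pytest.approx(b1, abs=2e-4)
    assert fit.sigma_u == pytest.approx(sd, abs=2e-3)
    assert fit.log_likelihood == pytest.approx(ll, abs=1e-4)


@pytest.fixture(scope="module")
def analytic():
    from foodenv.config import CityConfig
    from foodenv.classify import classify_frame
    from foodenv.geo import assign_points, build_metrics
    from foodenv.survey import apply_exclusions, derive_outcome_frame
    from foodenv.synthetic import (
        generate_establishments,
        generate_neighbourhoods,
        generate_participants,
    )
    cfg = CityConfig(n_neighbourhoods=150, city_weights=(100, 30, 20),
                     n_participants=900, n_survey_neighbourhoods=90, seed=23)
    nb = generate_neighbourhoods(cfg)
    est = generate_establishments(nb, cfg)
    cls = classify_frame(est)
    metrics = build_metrics(nb, cls, assign_points(cls, nb))
    part, _ = apply_exclusions(generate_participants(nb, cfg, establishments=est))
    return prepare_analytic(derive_outcome_frame(part), metrics)


class TestProgressive:
    def test_three_models_identical_sample(self, analytic):
        fits = progressive_fit(analytic, "density_total")
        assert set(fits) == {"model1", "model2", "model3"}
        assert len({f.n_obs for f in fits.values()}) == 1
        assert len(fits["model1"].coefficients) == 2      # intercept + exposure
        assert len(fits["model3"].coefficients) == 7

    def test_or_table_layout_nine_exposures(self, analytic):
        from foodenv.pipeline import EXPOSURES
        table, fits = exposure_or_table(analytic, EXPOSURES)
        assert len(table) == 9
        assert {"model1", "model2", "model3"} <= set(table.columns)
        for expo in EXPOSURES:
            assert expo in set(table["exposure"])

    def test_null_exposure_or_near_one(self, analytic):
        """A density column the outcome never saw: OR ~ 1 across models."""
        rng = np.random.default_rng(11)
        analytic = analytic.copy()
        analytic["z_noise"] = rng.normal(size=len(analytic))
        fits = progressive_fit(analytic, "z_noise")
        for fit in fits.values():
            line = fit.or_table.set_index("term").loc["z_noise"]
            assert 0.75 < line["or"] < 1.30
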