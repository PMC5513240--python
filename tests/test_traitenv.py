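import numpy as np
import pandas as pd
import pytest

from niche_coexist import simulate, traitenv
from niche_coexist._errors import (ContractError, DegenerateDataError,
                                   DomainError)


# ---------------------------------------------------------------------------
# allometric size adjustment

class TestAllometricAdjust:
    def test_flat_relationship_collapses_to_log_y(self):
        # y independent of x: slope 0, so M_adj = log10 y
        df = pd.DataFrame({"y": [10.0, 10.0, 10.0, 10.0],
                           "x": [10.0, 20.0, 40.0, 80.0],
                           "group": ["g"] * 4})
        adj, beta = traitenv.allometric_adjust(df)
        assert beta == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(adj, 1.0)

    def test_geometric_mean_individual_unchanged(self):
        # perfect allometry y = x/10: slope 1; the record at the geometric
        # mean of x keeps M_adj = log10 y
        df = pd.DataFrame({"y": [0.1, 1.0, 10.0], "x": [1.0, 10.0, 100.0],
                           "group": ["g"] * 3})
        adj, beta = traitenv.allometric_adjust(df)
        assert beta == pytest.approx(1.0)
        assert adj.iloc[1] == pytest.approx(np.log10(1.0), abs=1e-12)
        # and the worked value: y=10, x=100, geometric-mean x = 10
        assert adj.iloc[2] == pytest.approx(0.0, abs=1e-12)

    def test_per_group_mode_returns_slope_per_species(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(20, 80, 12)
        df = pd.DataFrame({
            "x": x,
            "y": np.where(np.arange(12) < 6, x**0.8, x**1.2) * 0.3,
            "group": ["a"] * 6 + ["b"] * 6,
        })
        adj, betas = traitenv.allometric_adjust(df, slope_mode="per_group")
        assert betas["a"] == pytest.approx(0.8, abs=1e-9)
        assert betas["b"] == pytest.approx(1.2, abs=1e-9)

    def test_zero_x_variance_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0], "x": [5.0, 5.0, 5.0],
                           "group": ["g"] * 3})
        with pytest.raises(DegenerateDataError):
            traitenv.allometric_adjust(df)


# ---------------------------------------------------------------------------
# spatial autocorrelation

def path_graph_weights(n=4):
    w = np.zeros((n, n))
    for i in range(n - 1):
        w[i, i + 1] = w[i + 1, i] = 1.0
    return traitenv.SpatialWeights(w)


class TestSpatialAutocorrelation:
    def test_moran_hand_value_on_path_graph(self):
        stat, _ = traitenv.spatial_autocorrelation_test(
            np.array([1.0, 1.0, 0.0, 0.0]), path_graph_weights(),
            statistic="moran", n_perm=99, seed=0)
        assert stat == pytest.approx(1 / 3, abs=1e-12)

    def test_geary_hand_value_on_path_graph(self):
        stat, _ = traitenv.spatial_autocorrelation_test(
            np.array([1.0, 1.0, 0.0, 0.0]), path_graph_weights(),
            statistic="geary", n_perm=99, seed=0)
        assert stat == pytest.approx(0.5, abs=1e-12)

    def test_null_mean_matches_theory(self):
        # E[I] under the randomization null is -1/(n-1)
        rng = np.random.default_rng(1)
        n = 20
        x = rng.normal(size=n)
        w = traitenv.inverse_distance_weights(np.arange(n))
        null = []
        for _ in range(3000):
            z = rng.permutation(x) - x.mean()
            null.append((n / w.w.sum()) * (z @ w.w @ z) / (z**2).sum())
        assert np.mean(null) == pytest.approx(-1 / (n - 1), abs=0.01)

    def test_constant_values_rejected(self):
        with pytest.raises(DegenerateDataError):
            traitenv.spatial_autocorrelation_test(
                np.ones(5), path_graph_weights(5), n_perm=99, seed=0)

    def test_strong_gradient_detected(self):
        stat, p = traitenv.spatial_autocorrelation_test(
            np.arange(30, dtype=float), traitenv.inverse_distance_weights(
                np.arange(30)), statistic="moran", n_perm=199, seed=2)
        assert stat > 0 and p <= 0.01

    def test_location_invariance_of_moran(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=15)
        w = traitenv.inverse_distance_weights(np.arange(15))
        s1, _ = traitenv.spatial_autocorrelation_test(x, w, n_perm=99, seed=4)
        s2, _ = traitenv.spatial_autocorrelation_test(x + 100.0, w,
                                                      n_perm=99, seed=4)
        assert s1 == pytest.approx(s2, abs=1e-9)

    def test_weight_matrix_invariants_enforced(self):
        with pytest.raises(DomainError):
            traitenv.SpatialWeights(np.array([[1.0, 0.5], [0.5, 0.0]]))
        with pytest.raises(DomainError):
            traitenv.SpatialWeights(np.array([[0.0, -1.0], [-1.0, 0.0]]))


# ---------------------------------------------------------------------------
# design construction

class TestDesign:
    def test_cross_product_rows(self, toy_dataset):
        spec, long = traitenv.build_trait_env_design(
            toy_dataset, "depth", "caudal_peduncle_depth")
        assert len(long) == 4 * 2
        assert spec.env_cols == ["depth"]

    def test_categorical_substratum_dummy_coded(self, toy_dataset):
        spec, long = traitenv.build_trait_env_design(
            toy_dataset, "substratum", "caudal_peduncle_depth")
        # 3 levels present (boulder, cobble, gravel): first sorted level
        # is the reference, so 2 dummies
        assert spec.env_cols == ["substratum[cobble]", "substratum[gravel]"]

    def test_mouth_position_codes_inferior_as_one(self, toy_dataset):
        _, long = traitenv.build_trait_env_design(
            toy_dataset, "depth", "mouth_position")
        coded = long.drop_duplicates("species").set_index("species")
        assert coded.loc["A", "mouth_position"] == 1.0   # inferior
        assert coded.loc["B", "mouth_position"] == 0.0   # terminal

    def test_unknown_variable_rejected(self, toy_dataset):
        with pytest.raises(KeyError):
            traitenv.build_trait_env_design(toy_dataset, "velocity",
                                            "mouth_position")


# ---------------------------------------------------------------------------
# GLMM fitting

def interaction_config(n_sites, beta2=0.8):
    cfg = simulate.default_habitat_config()
    cfg.n_sites = n_sites
    cfg.alpha1 = {"habitat": 0.3}
    cfg.beta1 = {"mouth_position": 0.2}
    cfg.beta2 = {("habitat", "mouth_position"): beta2}
    return cfg


class TestGlmmFit:
    def test_recovers_interaction_on_one_seed(self):
        ds, _ = simulate.gen_habitat_dataset(interaction_config(150), seed=21)
        spec, long = traitenv.build_trait_env_design(
            ds, "habitat_type", "mouth_position")
        fit = traitenv.fit_trait_env_glmm(spec, long)
        assert fit.converged
        est = fit.params["habitat_type[riffle]:mouth_position"]
        se = fit.se["habitat_type[riffle]:mouth_position"]
        # generator codes pool = 1, the design uses riffle as the dummy,
        # so the fitted interaction is the negated coefficient
        assert abs(est - (-0.8)) < 2 * se

    def test_null_effects_within_wald_bands(self):
        cfg = interaction_config(120, beta2=0.0)
        cfg.alpha1 = {}
        cfg.beta1 = {}
        ds, _ = simulate.gen_habitat_dataset(cfg, seed=22)
        spec, long = traitenv.build_trait_env_design(
            ds, "habitat_type", "mouth_position")
        fit = traitenv.fit_trait_env_glmm(spec, long)
        est = fit.params["habitat_type[riffle]:mouth_position"]
        se = fit.se["habitat_type[riffle]:mouth_position"]
        assert abs(est) < 3 * se

    def test_zero_random_sds_give_near_zero_variances(self):
        cfg = interaction_config(120)
        cfg.site_random_sd = 0.0
        cfg.species_random_sd = 0.0
        # equal baselines: every species-level difference is then carried
        # by the trait terms, so the species variance should vanish
        for sp in cfg.species:
            sp.baseline = float(np.log(5.0))
        ds, _ = simulate.gen_habitat_dataset(cfg, seed=23)
        spec, long = traitenv.build_trait_env_design(
            ds, "habitat_type", "mouth_position")
        fit = traitenv.fit_trait_env_glmm(spec, long)
        assert fit.var_site <= 0.05
        assert fit.var_species <= 0.05

    def test_aic_identity_and_wald_tables(self):
        ds, _ = simulate.gen_habitat_dataset(interaction_config(60), seed=24)
        spec, long = traitenv.build_trait_env_design(
            ds, "habitat_type", "mouth_position")
        fit = traitenv.fit_trait_env_glmm(spec, long)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.df_model,
                                        abs=1e-9)
        assert "interaction" in fit.wald_tests
        assert fit.wald_tests["interaction"]["df"] == 1


class TestModelComparison:
    @staticmethod
    def stub_fit(loglik, df, label):
        empty = pd.Series(dtype=float)
        return traitenv.ModelFit(
            params=empty, se=empty, z=empty, p_values=empty,
            var_site=0.1, var_species=0.1, loglik=loglik,
            aic=-2 * loglik + 2 * df, df_model=df, n_obs=100,
            converged=True, label=label)

    def test_equal_aic_splits_weights(self):
        null = self.stub_fit(-50.0, 3, "null")
        fits = [self.stub_fit(-48.0, 5, "m1"), self.stub_fit(-48.0, 5, "m2")]
        table = traitenv.compare_models(fits, null)
        np.testing.assert_allclose(table["weight"], [0.5, 0.5])

    def test_delta_two_weights(self):
        null = self.stub_fit(-50.0, 3, "null")
        fits = [self.stub_fit(-48.0, 5, "m1"), self.stub_fit(-49.0, 5, "m2")]
        table = traitenv.compare_models(fits, null)
        np.testing.assert_allclose(table["weight"], [0.7311, 0.2689],
                                   atol=5e-5)

    def test_weights_invariant_to_aic_shift(self):
        null = self.stub_fit(-50.0, 3, "null")
        f1 = [self.stub_fit(-48.0, 5, "a"), self.stub_fit(-49.5, 6, "b")]
        f2 = [self.stub_fit(-148.0, 5, "a"), self.stub_fit(-149.5, 6, "b")]
        t1 = traitenv.compare_models(f1, null)
        t2 = traitenv.compare_models(f2, null)
        np.testing.assert_allclose(t1["weight"], t2["weight"], atol=1e-12)
        assert t1["weight"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_lrt_of_identical_models_is_zero(self):
        null = self.stub_fit(-50.0, 3, "null")
        full = self.stub_fit(-50.0, 5, "full")
        chi2, df, p = traitenv.lrt(full, null)
        assert chi2 == 0.0 and df == 2 and p == 1.0

    def test_lrt_requires_nesting(self):
        null = self.stub_fit(-50.0, 5, "null")
        small = self.stub_fit(-49.0, 3, "small")
        with pytest.raises(ContractError):
            traitenv.lrt(small, null)

    def test_lrt_nonnegative_on_real_fits(self):
        ds, _ = simulate.gen_habitat_dataset(interaction_config(60), seed=25)
        spec, long = traitenv.build_trait_env_design(
            ds, "habitat_type", "mouth_position")
        full = traitenv.fit_trait_env_glmm(spec, long)
        null = traitenv.fit_trait_env_glmm(spec.without_interaction(), long)
        chi2, df, _ = traitenv.lrt(full, null)
        assert chi2 >= -1e-6 and df == 1


class TestCBeta:
    @pytest.mark.parametrize("resid, total, expected", [
        (0.8, 0.8, 0.0), (0.0, 0.8, 1.0), (0.2, 0.8, 0.75),
    ])
    def test_worked_values(self, resid, total, expected):
        assert traitenv.c_beta(resid, total) == pytest.approx(expected)

    def test_negative_value_warned_not_clipped(self):
        with pytest.warns(UserWarning):
            value = traitenv.c_beta(1.0, 0.5)
        assert value == pytest.approx(-1.0)

    def test_zero_total_rejected(self):
        with pytest.raises(DomainError):
            traitenv.c_beta(0.1, 0.0)


class TestReferenceImplementationAgreement:
    def test_laplace_fit_matches_glmer(self, tmp_path):
        """Dual-route check: the profiled-Laplace fit should agree with an
        independent mixed-model implementation (lme4::glmer, Poisson,
        crossed random intercepts) on coefficients, SEs and variances."""
        import json
        import subprocess

        ds, _ = simulate.gen_habitat_dataset(interaction_config(40), seed=7)
        spec, long = traitenv.build_trait_env_design(
            ds, "habitat_type", "mouth_position")
        fit = traitenv.fit_trait_env_glmm(spec, long)

        csv = tmp_path / "design.csv"
        long.to_csv(csv, index=False)
        rscript = tmp_path / "fit.R"
        rscript.write_text(f"""
suppressMessages(library(lme4))
d <- read.csv("{csv}")
d$riffle <- as.numeric(d$habitat_type == "riffle")
m <- glmer(count ~ riffle * mouth_position + (1 | site_id) + (1 | species),
           data = d, family = poisson)
vc <- as.data.frame(VarCorr(m))
out <- list(coef = as.numeric(fixef(m)),
            se = as.numeric(sqrt(diag(vcov(m)))),
            loglik = as.numeric(logLik(m)),
            var_site = vc$vcov[vc$grp == "site_id"],
            var_species = vc$vcov[vc$grp == "species"])
cat(jsonlite::toJSON(out, auto_unbox = TRUE))
""")
        res = subprocess.run(["Rscript", str(rscript)], capture_output=True,
                             text=True, timeout=300)
        assert res.returncode == 0, res.stderr
        ref = json.loads(res.stdout)

        # glmer order: intercept, riffle, mouth, riffle:mouth
        ours = fit.params[["intercept", "habitat_type[riffle]",
                           "mouth_position",
                           "habitat_type[riffle]:mouth_position"]]
        np.testing.assert_allclose(ours, ref["coef"], atol=0.05)
        np.testing.assert_allclose(
            fit.se[ours.index], ref["se"], atol=0.01)
        assert fit.loglik == pytest.approx(ref["loglik"], abs=0.05)
        assert fit.var_site == pytest.approx(ref["var_site"], abs=0.02)
        assert fit.var_species == pytest.approx(ref["var_species"], abs=0.02)
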