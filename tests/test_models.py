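"""Driver model fits: OLS, AICc search, alternatives, MEM, pGLS, diagnostics."""

import dendropy
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from lifecyclegeo import models
from lifecyclegeo.models import ModelSpec
from lifecyclegeo.synth import generate_brownian_traits


def make_table(rng, n=200, coefs=(0.2, 0.01, -0.05), noise=0.02):
    """Region table with quarterly climate columns and a response generated
    from (bio10, log(bio18+1))."""
    t = pd.DataFrame(
        {
            "bio8": rng.uniform(5, 25, n),
            "bio9": rng.uniform(-5, 20, n),
            "bio10": rng.uniform(0, 30, n),
            "bio11": rng.uniform(-15, 10, n),
            "bio16": rng.uniform(100, 900, n),
            "bio17": rng.uniform(0, 150, n),
            "bio18": rng.uniform(5, 500, n),
            "bio19": rng.uniform(10, 400, n),
            "bio1": rng.uniform(-5, 25, n),
            "bio12": rng.uniform(100, 2500, n),
        }
    )
    a, bT, bP = coefs
    t["p_annual_herb"] = a + bT * t["bio10"] + bP * np.log(t["bio18"] + 1) + rng.normal(0, noise, n)
    return t


class TestFitLinear:
    def test_exact_recovery_without_noise(self, rng):
        t = make_table(rng, noise=0.0)
        fit = models.fit_linear(ModelSpec("p_annual_herb", ("bio10", "log(bio18+1)")), t)
        assert fit.params["const"] == pytest.approx(0.2, abs=1e-10)
        assert fit.params["bio10"] == pytest.approx(0.01, abs=1e-12)
        assert fit.params["log(bio18+1)"] == pytest.approx(-0.05, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_slope_ci_calibration_under_null(self):
        """Response independent of predictor: the 95% CI covers 0 at the
        nominal rate over Monte-Carlo replicates."""
        from scipy import stats

        cover = 0
        n, reps = 80, 300
        for s in range(reps):
            r = np.random.default_rng(1000 + s)
            t = pd.DataFrame({"x": r.normal(size=n), "y": r.normal(size=n)})
            fit = models.fit_linear(ModelSpec("y", ("x",)), t)
            tcrit = stats.t.ppf(0.975, fit.df_resid)
            lo = fit.params["x"] - tcrit * fit.bse["x"]
            hi = fit.params["x"] + tcrit * fit.bse["x"]
            cover += lo <= 0 <= hi
        assert 0.92 < cover / reps < 0.98

    def test_interaction_term_and_df(self, rng):
        t = make_table(rng)
        fit = models.fit_linear(ModelSpec("p_annual_herb", ("bio1", "bio12", "bio1:bio12")), t)
        assert fit.df_resid == fit.n - 4
        assert set(fit.params) == {"const", "bio1", "bio12", "bio1:bio12"}

    def test_rank_deficient_design_names_collinear_column(self, rng):
        t = make_table(rng)
        t["bio10_copy"] = t["bio10"]
        with pytest.raises(ValueError, match="bio10_copy"):
            models.fit_linear(ModelSpec("p_annual_herb", ("bio10", "bio10_copy")), t)

    def test_aicc_matches_closed_form_from_rss(self, rng):
        t = make_table(rng, n=40)
        fit = models.fit_linear(ModelSpec("p_annual_herb", ("bio10", "log(bio18+1)")), t)
        X = sm.add_constant(
            np.column_stack([t["bio10"], np.log(t["bio18"] + 1)])
        )
        beta, *_ = np.linalg.lstsq(X, t["p_annual_herb"], rcond=None)
        rss = float(((t["p_annual_herb"] - X @ beta) ** 2).sum())
        n, k = len(t), 4  # intercept + 2 slopes + residual variance
        llf = -n / 2 * (np.log(2 * np.pi * rss / n) + 1)
        aicc = -2 * llf + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        assert fit.aicc == pytest.approx(aicc, rel=1e-10)

    def test_missing_rows_dropped(self, rng):
        t = make_table(rng, n=50)
        t.loc[:4, "bio10"] = np.nan
        fit = models.fit_linear(ModelSpec("p_annual_herb", ("bio10",)), t)
        assert fit.n == 45


class TestQuarterlySearch:
    def test_has_34_candidates(self):
        assert len(models.quarterly_specs()) == 34

    def test_zero_noise_generating_model_strictly_best(self, rng):
        t = make_table(rng, noise=0.0)
        res = models.quarterly_search(t)
        assert set(res.best.spec.predictors) == {"bio10", "log(bio18+1)"}
        assert res.ranking["delta_aicc"].iloc[1] > 1.0

    def test_ranking_sorted_and_delta_zero_at_top(self, rng):
        t = make_table(rng)
        res = models.quarterly_search(t)
        assert (res.ranking["aicc"].diff().dropna() >= 0).all()
        assert res.ranking["delta_aicc"].iloc[0] == 0.0

    def test_delta_aicc_matches_independent_refit(self, rng):
        """Re-fit the top two models outside the search harness."""
        t = make_table(rng)
        res = models.quarterly_search(t)
        refits = [models.fit_linear(f.spec, t) for f in res.fits[:2]]
        delta = refits[1].aicc - refits[0].aicc
        assert res.ranking["delta_aicc"].iloc[1] == pytest.approx(delta, abs=1e-8)


class TestExtendModel:
    def test_base_vs_base_delta_zero(self, rng):
        t = make_table(rng)
        res = models.extend_model(ModelSpec("p_annual_herb", ("bio10",)), (), t)
        assert res.delta_aicc == 0.0 and res.delta_r2 == 0.0

    def test_true_predictor_improves_fit(self, rng):
        t = make_table(rng, noise=0.01)
        res = models.extend_model(
            ModelSpec("p_annual_herb", ("bio10",)), ("log(bio18+1)",), t
        )
        assert res.delta_aicc < 0 and res.delta_r2 > 0

    def test_noise_column_r2_nondecreasing_aicc_typically_worse(self):
        worse = 0
        for s in range(40):
            r = np.random.default_rng(2000 + s)
            t = make_table(r, n=150, noise=0.05)
            t["junk"] = r.normal(size=len(t))
            res = models.extend_model(
                ModelSpec("p_annual_herb", ("bio10", "log(bio18+1)")), ("junk",), t
            )
            assert res.delta_r2 >= -1e-12
            worse += res.delta_aicc > 0
        assert worse >= 30  # AICc penalizes pure noise most of the time

    def test_identical_case_set_for_nested_pair(self, rng):
        t = make_table(rng)
        t.loc[:9, "ipv"] = np.nan
        t.loc[10:, "ipv"] = rng.random(len(t) - 10)
        res = models.extend_model(ModelSpec("p_annual_herb", ("bio10",)), ("ipv",), t)
        assert res.base.n == res.extended.n == len(t) - 10


class TestPerFamily:
    def test_shared_truth_gives_same_sign_pattern(self):
        fits = {}
        tables = {}
        for i, fam in enumerate(("Asteraceae", "Brassicaceae", "Fabaceae", "Poaceae")):
            tables[fam] = make_table(np.random.default_rng(300 + i), n=120, noise=0.02)
        spec = ModelSpec("p_annual_herb", ("bio10", "log(bio18+1)"))
        fits = models.fit_per_family(tables, spec)
        assert set(fits) == set(tables)
        for f in fits.values():
            assert f.params["bio10"] > 0 and f.params["log(bio18+1)"] < 0

    def test_small_family_skipped_with_warning(self, rng):
        tables = {"Tiny": make_table(rng, n=5)}
        with pytest.warns(UserWarning, match="Tiny"):
            fits = models.fit_per_family(tables, ModelSpec("p_annual_herb", ("bio10",)))
        assert fits == {}


class TestAlternatives:
    def make_counts(self, rng, n=200):
        t = make_table(rng, n=n, noise=0.0)
        t["p_annual_herb"] = t["p_annual_herb"].clip(0.02, 0.95)
        t["n_herb_species"] = rng.integers(10, 80, n)
        t["n_annual_herb"] = rng.binomial(t["n_herb_species"], t["p_annual_herb"])
        return t

    def test_smoothed_logit_symmetric_at_half(self):
        assert models.smoothed_logit(pd.Series([5.0]), pd.Series([10.0]))[0] == pytest.approx(0.0, abs=1e-12)
        # shrinkage vanishes with n
        big = models.smoothed_logit(pd.Series([5000.0]), pd.Series([10000.0]))[0]
        assert big == pytest.approx(0.0, abs=1e-12)

    def test_boundary_proportions_stay_finite(self):
        vals = models.smoothed_logit(pd.Series([0.0, 10.0]), pd.Series([10.0, 10.0]))
        assert np.isfinite(vals).all()

    def test_slope_signs_agree_across_families(self, rng):
        t = self.make_counts(rng)
        alts = models.fit_alternatives(t, ("bio10", "log(bio18+1)"))
        lin = models.fit_linear(ModelSpec("p_annual_herb", ("bio10", "log(bio18+1)")), t)
        for key in ("bio10", "log(bio18+1)"):
            assert np.sign(alts["logit"].params[key]) == np.sign(lin.params[key])
            assert np.sign(alts["poisson"].params[key]) == np.sign(lin.params[key])

    def test_poisson_fitted_counts_conserve_total(self, rng):
        """Log-link GLM with intercept: score equations force the fitted
        means to sum to the observed total."""
        t = self.make_counts(rng)
        alts = models.fit_alternatives(t, ("bio10", "log(bio18+1)"))
        fitted_sum = float(alts["poisson"].extra["fitted"].sum())
        assert fitted_sum == pytest.approx(float(t["n_annual_herb"].sum()), rel=1e-6)

    def test_zero_total_regions_excluded(self, rng):
        t = self.make_counts(rng, n=50)
        t.loc[:4, "n_herb_species"] = 0
        alts = models.fit_alternatives(t, ("bio10",))
        assert alts["poisson"].n == 45


class TestSpatialEigenvectors:
    def test_basis_centered_orthonormal(self, rng):
        mem = models.spatial_eigenvectors(rng.uniform(0, 40, 80), rng.uniform(-30, 30, 80))
        V = mem.vectors.to_numpy()
        gram = V.T @ V
        assert np.abs(gram - np.eye(V.shape[1])).max() < 1e-8
        assert np.abs(V.mean(axis=0)).max() < 1e-8
        assert mem.variance_share >= 0.8

    def test_collinear_points_leading_vector_monotone(self):
        lon = np.array([0.0, 1.0, 2.0, 3.0])
        lat = np.zeros(4)
        mem = models.spatial_eigenvectors(lon, lat)
        lead = mem.vectors["mem1"].to_numpy()
        diffs = np.diff(lead)
        assert (diffs > 0).all() or (diffs < 0).all()

    def test_duplicate_centroids_rejected_or_jittered(self):
        lon = np.array([0.0, 0.0, 1.0, 2.0])
        lat = np.array([0.0, 0.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="duplicate"):
            models.spatial_eigenvectors(lon, lat)
        mem = models.spatial_eigenvectors(lon, lat, duplicates="jitter")
        assert mem.vectors.shape[0] == 4

    def test_mem_covariates_absorb_spatial_autocorrelation(self, rng):
        from lifecyclegeo._geometry import haversine_matrix

        n = 100
        lon, lat = rng.uniform(0, 30, n), rng.uniform(0, 30, n)
        D = haversine_matrix(lon, lat)
        C = np.exp(-D / 800.0)
        y = np.linalg.cholesky(C + 1e-8 * np.eye(n)) @ rng.normal(size=n)
        mem = models.spatial_eigenvectors(lon, lat)
        t = pd.concat([pd.DataFrame({"y": y}), mem.vectors], axis=1)
        fit = models.fit_linear(ModelSpec("y", tuple(mem.vectors.columns)), t)
        resid = t["y"] - fit.predict(t)
        before = abs(models.morans_i(y, lon, lat))
        after = abs(models.morans_i(resid.to_numpy(), lon, lat))
        assert after < 0.5 * before


def two_clade_tree(n_per_clade=10, clade_depth=0.1):
    """Deep split, shallow within-clade structure: states clumped by clade."""
    names = [f"t{i}" for i in range(2 * n_per_clade)]
    taxa = dendropy.TaxonNamespace(names)
    tree = dendropy.Tree(taxon_namespace=taxa)
    left = tree.seed_node.new_child(edge_length=1.0 - clade_depth)
    right = tree.seed_node.new_child(edge_length=1.0 - clade_depth)
    for i, t in enumerate(taxa):
        parent = left if i < n_per_clade else right
        child = parent.new_child(edge_length=clade_depth)
        child.taxon = t
    return tree, names


class TestPGLS:
    def test_clumped_states_inflate_pgls_se(self):
        tree, names = two_clade_tree()
        rng = np.random.default_rng(7)
        table = pd.DataFrame(
            {
                "annual": [1] * 10 + [0] * 10,
                "resp": rng.normal(0, 1, 20) + np.repeat([1.0, 0.0], 10),
            },
            index=pd.Index(names, name="species"),
        )
        pgls, ols = models.fit_pgls(tree, table, "resp")
        assert pgls.bse["annual"] > ols.bse["annual"]

    def test_recovers_state_effect_on_brownian_data(self):
        from lifecyclegeo.synth import _simulate_tree

        tree = _simulate_tree([f"s{i}" for i in range(120)], seed=21)
        betas = []
        for s in range(40):
            df = generate_brownian_traits(tree, sigma2=1.0, beta=3.0, seed=500 + s)
            if df["state"].nunique() < 2:
                continue
            table = df.rename(columns={"trait": "resp", "state": "annual"})
            pgls, _ = models.fit_pgls(tree, table, "resp")
            betas.append(pgls.params["annual"])
        mean = np.mean(betas)
        se = np.std(betas, ddof=1) / np.sqrt(len(betas))
        assert abs(mean - 3.0) < 4 * se + 0.05

    def test_singular_covariance_rejected(self):
        tree = dendropy.Tree.get(data="((a:0,b:0):1,c:1);", schema="newick")
        table = pd.DataFrame(
            {"annual": [0, 1, 0], "resp": [0.0, 1.0, 2.0]},
            index=pd.Index(["a", "b", "c"], name="species"),
        )
        with pytest.raises(ValueError, match="singular"):
            models.fit_pgls(tree, table, "resp")


def test_star_tree_pgls_equals_ols():
    """With V proportional to identity the whitening is a no-op."""
    from test_synth import star_tree

    tree = star_tree(30, depth=2.0)
    rng = np.random.default_rng(3)
    table = pd.DataFrame(
        {"annual": rng.integers(0, 2, 30), "resp": rng.normal(size=30)},
        index=pd.Index([f"t{i}" for i in range(30)], name="species"),
    )
    pgls, ols = models.fit_pgls(tree, table, "resp")
    for key in ("const", "annual"):
        assert pgls.params[key] == pytest.approx(ols.params[key], abs=1e-10)
        assert pgls.bse[key] == pytest.approx(ols.bse[key], abs=1e-10)


class TestBiasDiagnostics:
    def make(self, rng, n=120):
        return pd.DataFrame(
            {
                "p_annual": rng.uniform(0, 0.5, n),
                "p_annual_herb": rng.uniform(0, 0.6, n),
                "log10_total_obs": rng.uniform(2, 6, n),
                "n_species": rng.integers(10, 500, n),
            }
        )

    def test_independent_sampling_slope_ci_covers_zero(self):
        from scipy import stats

        cover = 0
        reps = 200
        for s in range(reps):
            rng = np.random.default_rng(4000 + s)
            t = self.make(rng)
            fit = models.bias_diagnostics(t)["p_annual~log10_total_obs"]
            tcrit = stats.t.ppf(0.975, fit.df_resid)
            b, se = fit.params["log10_total_obs"], fit.bse["log10_total_obs"]
            cover += (b - tcrit * se) <= 0 <= (b + tcrit * se)
        assert 0.91 < cover / reps < 0.99

    def test_doubling_observations_leaves_slope_unchanged(self, rng):
        t = self.make(rng)
        fit1 = models.bias_diagnostics(t)["p_annual~log10_total_obs"]
        t2 = t.assign(log10_total_obs=t["log10_total_obs"] + np.log10(2))
        fit2 = models.bias_diagnostics(t2)["p_annual~log10_total_obs"]
        assert fit1.params["log10_total_obs"] == pytest.approx(
            fit2.params["log10_total_obs"], rel=1e-10
        )

    def test_perfectly_proportional_sampling_zero_slope(self):
        t = pd.DataFrame(
            {
                "p_annual": 0.25,
                "p_annual_herb": 0.4,
                "log10_total_obs": np.linspace(2, 6, 50),
                "n_species": np.arange(50, 100),
            }
        )
        fit = models.bias_diagnostics(t)["p_annual~log10_total_obs"]
        assert fit.params["log10_total_obs"] == pytest.approx(0.0, abs=1e-12)
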