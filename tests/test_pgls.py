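"""GLS estimation, variance-component likelihood fitting, ensembles."""

import numpy as np
import pytest
import statsmodels.api as sm

from coopcare.pgls import (FitOptions, PGLSVCModel, build_covariance,
                           ensemble_fit, fit_ml, gls_estimate, r_squared,
                           _profile_loglik)
from coopcare.phylo import PhyloCov, read_newick, vcv
from coopcare.simulate import SyntheticConfig, simulate_dataset, simulate_tree
from conftest import gls_by_explicit_inverse

ML = FitOptions(criterion="ml", compute_r2=False, adjust_se="none")


def small_instance(n=10, seed=0, gamma=(0.8, 0.2, 0.0), lam=0.8, sigma2=0.3):
    ds = simulate_dataset(SyntheticConfig(
        n_species=n, n_trees=1, seed=seed, gamma=gamma, lam=lam, sigma2=sigma2,
        beta=(1.0, 1.5, -0.01, 0.05, 0.0)))
    C = vcv(ds.trees[0], [r.species_id for r in ds.records])
    X = ds.X_raw[:, :3]    # intercept + two predictors keeps n >> p
    return PGLSVCModel(y=ds.y, X=X, C=C, quality=ds.quality), ds


class TestBuildCovariance:
    def test_reduces_to_plain_pgls_when_gamma_zero(self, worked_tree):
        C = vcv(worked_tree)
        V = build_covariance(C, 1.0, (0, 0, 0), [1, 2, 3])
        assert np.allclose(V, C.C)

    def test_reduces_to_identity_for_ols_corner(self, worked_tree):
        C = vcv(worked_tree)
        V = build_covariance(C, 0.0, (0, 0, 0), [1, 2, 3])
        assert np.allclose(V, np.eye(3))

    def test_quality_variance_added_on_diagonal(self, worked_tree):
        C = vcv(worked_tree, ["A", "B", "C"])
        V = build_covariance(C, 1.0, (2.0, 0.0, 0.0), [1, 2, 3])
        expected = C.C.copy()
        expected[0, 0] += 2.0
        assert np.allclose(V, expected)
        assert V[0, 0] == pytest.approx(3.0)

    def test_lambda_scale_ridge_identity(self, worked_tree):
        # V(lam, gamma) = lam * V(1, (1+gamma)/lam - 1): the lambda/scale
        # ridge along which the likelihood is exactly flat
        C = vcv(worked_tree)
        lam, gamma = 0.4, np.array([0.5, 0.2, 0.0])
        q = [1, 2, 3]
        left = build_covariance(C, lam, gamma, q)
        right = lam * build_covariance(C, 1.0, (1.0 + gamma) / lam - 1.0, q)
        assert np.allclose(left, right, atol=1e-12)

    def test_negative_gamma_rejected(self, worked_tree):
        with pytest.raises(ValueError, match="negative"):
            build_covariance(vcv(worked_tree), 1.0, (-1.0, 0, 0), [1, 2, 3])


class TestGlsEstimate:
    def test_identity_covariance_equals_ols(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(12), rng.normal(size=(12, 2))])
        y = rng.normal(size=12)
        g = gls_estimate(y, X, np.eye(12))
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(g.beta, ols, atol=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_explicit_inverse_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 9
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = rng.normal(size=n)
        A = rng.normal(size=(n, n))
        V = A @ A.T + n * np.eye(n)
        g = gls_estimate(y, X, V)
        assert np.allclose(g.beta, gls_by_explicit_inverse(y, X, V), atol=1e-10)

    def test_matches_statsmodels_gls_loglik(self):
        rng = np.random.default_rng(5)
        n = 8
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        A = rng.normal(size=(n, n))
        V = A @ A.T + n * np.eye(n)
        res = sm.GLS(y, X, sigma=V).fit()
        g = gls_estimate(y, X, V, criterion="ml")
        assert np.allclose(g.beta, res.params, atol=1e-10)
        assert g.loglik == pytest.approx(res.llf, abs=1e-8)

    def test_hand_solved_weighted_system(self):
        # V = diag(1,1,1,4), x = 0..3, y = (0,1,2,4): beta = (-2/19, 22/19)
        X = np.column_stack([np.ones(4), np.arange(4.0)])
        y = np.array([0.0, 1.0, 2.0, 4.0])
        V = np.diag([1.0, 1.0, 1.0, 4.0])
        g = gls_estimate(y, X, V)
        assert np.allclose(g.beta, [-2 / 19, 22 / 19], atol=1e-12)

    def test_not_positive_definite_rejected(self):
        X = np.column_stack([np.ones(3), np.arange(3.0)])
        V = np.array([[1.0, 2.0, 0.0], [2.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        with pytest.raises(Exception, match="positive definite|eigenvalue"):
            gls_estimate(np.zeros(3), X, V)


class TestFitML:
    def test_matches_dense_grid_oracle(self):
        model, _ = small_instance(n=10, seed=3)
        fit = fit_ml(model, ML)
        free = sorted(set(model.quality.tolist()))
        grid_best = -np.inf
        for lam in np.linspace(0, 1, 11):
            for g1 in (0.0, 0.3, 0.8, 1.5, 3.0):
                for g2 in (0.0, 0.3, 0.8):
                    for g3 in (0.0, 0.3, 0.8):
                        gv = np.array([g1, g2, g3][:len(free)])
                        ll = _profile_loglik(model, lam, gv, free, "ml")
                        grid_best = max(grid_best, ll)
        assert fit.loglik >= grid_best - 1e-4

    def test_single_quality_class_collapses_to_one_gamma(self):
        model, ds = small_instance(n=12, seed=5)
        one = PGLSVCModel(y=model.y, X=model.X, C=model.C,
                          quality=np.full(12, 2))
        relabeled = PGLSVCModel(y=model.y, X=model.X, C=model.C,
                                quality=np.full(12, 1))
        f1 = fit_ml(one, ML)
        f2 = fit_ml(relabeled, ML)
        assert f1.gamma[1] == 0.0 and f1.gamma[3] == 0.0
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)
        assert np.allclose(f1.beta, f2.beta, atol=1e-6)
        assert f1.gamma[2] == pytest.approx(f2.gamma[1], abs=1e-4)

    @pytest.mark.parametrize("seed", range(10))
    def test_lambda_profile_matches_statsmodels_reference(self, seed):
        """With gamma = 0 the lambda profile likelihood must equal an
        independent whitening-based PGLS implementation (statsmodels GLS)."""
        rng = np.random.default_rng(seed)
        tree = simulate_tree(8, seed=seed)
        C = vcv(tree)
        X = np.column_stack([np.ones(8), rng.normal(size=8)])
        y = rng.normal(size=8)
        model = PGLSVCModel(y=y, X=X, C=C, quality=np.ones(8, dtype=int))
        for lam in (0.0, 0.25, 0.5, 0.75, 1.0):
            ours = _profile_loglik(model, lam, np.array([]), [], "ml")
            Vlam = build_covariance(C, lam, (0, 0, 0), model.quality)
            ref = sm.GLS(y, X, sigma=Vlam).fit().llf
            assert ours == pytest.approx(ref, abs=1e-8)

    def test_scale_equivariance_of_estimates(self):
        model, _ = small_instance(n=12, seed=9)
        f = fit_ml(model, ML)
        c = 3.7
        scaled = PGLSVCModel(y=c * model.y, X=model.X, C=model.C,
                             quality=model.quality)
        fc = fit_ml(scaled, ML)
        assert np.allclose(fc.beta, c * f.beta, rtol=1e-4, atol=1e-6)
        assert fc.sigma2 == pytest.approx(c**2 * f.sigma2, rel=1e-3)
        assert fc.lam == pytest.approx(f.lam, abs=1e-3)
        for k in (1, 2, 3):
            assert fc.gamma[k] == pytest.approx(f.gamma[k], rel=1e-2, abs=1e-3)

    def test_species_permutation_invariance(self):
        model, ds = small_instance(n=12, seed=13)
        fit = fit_ml(model, ML)
        rng = np.random.default_rng(0)
        perm = rng.permutation(12)
        taxa = [model.C.taxa[i] for i in perm]
        ds_tree_cov = vcv(ds.trees[0], taxa)
        permuted = PGLSVCModel(y=model.y[perm], X=model.X[perm], C=ds_tree_cov,
                               quality=model.quality[perm])
        fit_p = fit_ml(permuted, ML)
        assert np.allclose(fit_p.beta, fit.beta, atol=1e-6)
        assert fit_p.loglik == pytest.approx(fit.loglik, abs=1e-6)

    def test_free_gamma_fits_report_canonical_lambda(self):
        # with a variance ratio per class, lambda merges with the scale;
        # fits must come back as the lambda = 1 (or exactly 0) representative
        for seed in (3, 9, 13):
            model, _ = small_instance(n=12, seed=seed)
            fit = fit_ml(model, ML)
            assert fit.lam == 1.0 or fit.lam <= 1e-8
            free = sorted(set(model.quality.tolist()))
            gvec = np.array([fit.gamma[k] for k in free])
            ll = _profile_loglik(model, fit.lam, gvec, free, "ml")
            assert ll == pytest.approx(fit.loglik, abs=1e-6)

    def test_too_few_observations_rejected(self):
        model, _ = small_instance(n=10, seed=1)
        tiny = PGLSVCModel(y=model.y[:6], X=model.X[:6],
                           C=PhyloCov(taxa=model.C.taxa[:6], C=model.C.C[:6, :6],
                                      height=model.C.height),
                           quality=np.array([1, 2, 3, 1, 2, 3]))
        with pytest.raises(ValueError, match="few observations|variance parameters"):
            fit_ml(tiny, ML)

    def test_boundary_lambda_flagged_with_zero_se(self):
        ds = simulate_dataset(SyntheticConfig(n_species=24, n_trees=1, seed=17,
                                              lam=1.0, gamma=(0, 0, 0),
                                              sigma2=0.4))
        C = vcv(ds.trees[0], [r.species_id for r in ds.records])
        model = PGLSVCModel(y=ds.y, X=ds.X_raw[:, :2], C=C, quality=ds.quality)
        fit = fit_ml(model, ML)
        if fit.boundary_flags.get("lambda"):
            assert fit.lam_se == 0.0


class TestRSquared:
    def test_zero_when_no_improvement(self):
        model, _ = small_instance(n=12, seed=21)
        f = fit_ml(model, ML)
        assert r_squared(f, f) == 0.0

    def test_nesting_violation_rejected(self):
        model, _ = small_instance(n=12, seed=21)
        f = fit_ml(model, ML)
        import copy
        worse = copy.deepcopy(f)
        worse.loglik = f.loglik + 5.0
        with pytest.raises(ValueError, match="nesting"):
            r_squared(f, worse)

    def test_ols_special_case_matches_classical_r2(self):
        rng = np.random.default_rng(8)
        n = 20
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        beta = np.array([1.0, 2.0, -1.0])
        y = X @ beta + rng.normal(scale=0.8, size=n)
        eye = PhyloCov(taxa=tuple(f"s{i}" for i in range(n)), C=np.eye(n), height=1.0)
        q = np.ones(n, dtype=int)
        opts = FitOptions(criterion="ml", compute_r2=False, adjust_se="none")
        full = fit_ml(PGLSVCModel(y=y, X=X, C=eye, quality=q), opts,
                      free_lambda=False, free_gamma=False, fixed_lambda=0.0)
        null = fit_ml(PGLSVCModel(y=y, X=X[:, :1], C=eye, quality=q), opts,
                      free_lambda=False, free_gamma=False, fixed_lambda=0.0)
        r2 = r_squared(full, null)
        classical = sm.OLS(y, X).fit().rsquared
        assert r2 == pytest.approx(classical, abs=1e-8)


class TestEnsembleFit:
    def builder_for(self, ds, X):
        taxa = [r.species_id for r in ds.records]

        def build(tree):
            return PGLSVCModel(y=ds.y, X=X, C=vcv(tree, taxa), quality=ds.quality)
        return build

    def test_identical_trees_have_zero_spread(self):
        ds = simulate_dataset(SyntheticConfig(n_species=12, n_trees=1, seed=31,
                                              gamma=(0.5, 0.1, 0), sigma2=0.2))
        X = ds.X_raw[:, :3]
        build = self.builder_for(ds, X)
        ens = ensemble_fit(build, [ds.trees[0]] * 4, ML)
        single = fit_ml(build(ds.trees[0]), ML)
        assert np.allclose(ens.aggregate["beta"], single.beta, atol=1e-8)
        assert np.allclose(ens.aggregate["beta_sd_across_trees"], 0, atol=1e-8)

    def test_two_tree_aggregate_is_mean(self):
        ds = simulate_dataset(SyntheticConfig(n_species=12, n_trees=2, seed=37,
                                              gamma=(0.5, 0.1, 0), sigma2=0.2))
        X = ds.X_raw[:, :3]
        build = self.builder_for(ds, X)
        ens = ensemble_fit(build, ds.trees, ML)
        f0, f1 = (fit_ml(build(t), ML) for t in ds.trees)
        assert np.allclose(ens.aggregate["beta"], (f0.beta + f1.beta) / 2, atol=1e-8)

    def test_median_aggregation_option(self):
        ds = simulate_dataset(SyntheticConfig(n_species=12, n_trees=3, seed=41,
                                              gamma=(0.5, 0.1, 0), sigma2=0.2))
        X = ds.X_raw[:, :3]
        ens = ensemble_fit(self.builder_for(ds, X), ds.trees, ML,
                           aggregation="median")
        betas = np.array([f.beta for f in ens.fits])
        assert np.allclose(ens.aggregate["beta"], np.median(betas, axis=0))

    def test_failing_tree_skipped_and_counted(self):
        ds = simulate_dataset(SyntheticConfig(n_species=12, n_trees=2, seed=43,
                                              gamma=(0.5, 0.1, 0), sigma2=0.2))
        X = ds.X_raw[:, :3]
        bad_tree = simulate_tree(5, seed=0)   # lacks the species
        ens = ensemble_fit(self.builder_for(ds, X), [ds.trees[0], bad_tree], ML)
        assert len(ens.fits) == 1
        assert len(ens.failures) == 1

    def test_all_failures_raise(self):
        ds = simulate_dataset(SyntheticConfig(n_species=12, n_trees=1, seed=47,
                                              gamma=(0.5, 0.1, 0), sigma2=0.2))
        X = ds.X_raw[:, :3]
        bad_tree = simulate_tree(5, seed=0)
        with pytest.raises(RuntimeError, match="all .* failed"):
            ensemble_fit(self.builder_for(ds, X), [bad_tree], ML)

    def test_empty_tree_list_rejected(self):
        ds = simulate_dataset(SyntheticConfig(n_species=12, n_trees=1, seed=53,
                                              gamma=(0.5, 0.1, 0), sigma2=0.2))
        with pytest.raises(ValueError, match="at least one"):
            ensemble_fit(self.builder_for(ds, ds.X_raw[:, :3]), [], ML)
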