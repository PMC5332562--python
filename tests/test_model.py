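"""ICAR model: prior density, Gibbs sampler correctness, DIC, predictions."""

import numpy as np
import pytest
import scipy.linalg as sla
from scipy import stats

from voromap.model import IcarModel, IcarResults, log_icar_prior
from voromap.synthetic import SyntheticConfig, sample_icar_field, simulate_dataset
from conftest import make_grid_support, support_from_graph


def exact_constrained_posterior(model, tau_s, tau_e):
    """Independent dense oracle for the fixed-precision Gaussian posterior.

    Reparameterizes x = B u on the sum-to-zero subspace and works entirely
    from the model's raw ingredients (y, X, R, priors), not its templates.
    """
    obs = np.flatnonzero(model.obs)
    Xo = model.X[obs]
    yo = model.y[obs]
    p1, n = model.p1, model.n
    A = np.zeros((model.n_components, n))
    for c in range(model.n_components):
        A[c, model.components == c] = 1.0
    B = sla.null_space(A)
    nb = B.shape[1]
    # joint precision over (beta_std, u)
    Rd = model.R.toarray()
    Bo = B[obs]
    Q = np.zeros((p1 + nb, p1 + nb))
    Q[:p1, :p1] = tau_e * Xo.T @ Xo + np.eye(p1) / model.beta_prior_var
    Q[:p1, p1:] = tau_e * Xo.T @ Bo
    Q[p1:, :p1] = Q[:p1, p1:].T
    Q[p1:, p1:] = tau_s * B.T @ Rd @ B + tau_e * Bo.T @ Bo
    b = np.concatenate([tau_e * Xo.T @ yo, tau_e * Bo.T @ yo])
    cov = np.linalg.inv(Q)
    mean = cov @ b
    full_mean = np.concatenate([mean[:p1], B @ mean[p1:]])
    T = np.zeros((p1 + n, p1 + nb))
    T[:p1, :p1] = np.eye(p1)
    T[p1:, p1:] = B
    full_cov = T @ cov @ T.T
    # betas back to original covariate scale
    L = np.eye(p1 + n)
    if p1 > 1:
        L[0, 1:p1] = -model._mu / model._sd
        L[np.arange(1, p1), np.arange(1, p1)] = 1.0 / model._sd
    return L @ full_mean, L @ full_cov @ L.T


@pytest.fixture(scope="module")
def spatial_dataset():
    return simulate_dataset(
        SyntheticConfig(n_towers_urban=0, n_towers_rural=60, n_urban_centres=0, seed=21)
    )


class TestIcarPrior:
    def test_constant_field_has_zero_penalty(self):
        support = make_grid_support(3, 3)
        x = np.full(9, 2.7)
        lp = log_icar_prior(x, support.structure_matrix, tau=1.0)
        assert abs(lp) < 1e-12  # rank term vanishes at tau=1; quadratic is 0

    def test_two_node_matches_pair_sum_form(self):
        support = support_from_graph(2, [(0, 1)])
        x = np.array([1.0, -1.0])
        lp = log_icar_prior(x, support.structure_matrix, tau=1.0)
        pair_sum = -0.5 * (x[0] - x[1]) ** 2
        assert abs(lp - pair_sum) < 1e-12  # x'Rx = 4 -> -2

    def test_tau_scaling_of_density(self):
        support = make_grid_support(2, 3)
        rng = np.random.default_rng(0)
        x = rng.normal(size=6)
        x -= x.mean()
        R = support.structure_matrix
        lp1 = log_icar_prior(x, R, 1.0)
        lp2 = log_icar_prior(x, R, 2.0)
        rank = 5
        quad = float(x @ (R @ x))
        assert abs((lp2 - lp1) - (0.5 * rank * np.log(2.0) - 0.5 * quad)) < 1e-10

    def test_nonpositive_tau_rejected(self):
        support = support_from_graph(2, [(0, 1)])
        with pytest.raises(ValueError):
            log_icar_prior(np.zeros(2), support.structure_matrix, 0.0)


class TestSamplerCorrectness:
    def test_intercept_only_collapses_to_normal_mean(self):
        support = make_grid_support(10, 10)
        rng = np.random.default_rng(1)
        sigma = 0.5
        y = 1.8 + rng.normal(scale=sigma, size=100)
        model = IcarModel(y, np.empty((100, 0)), structure_matrix=support.structure_matrix,
                          components=support.components)
        res = model.fit(n_iter=2500, n_burn=500, n_chains=2, seed=0,
                        tau_fixed=(1e8, None))
        b0 = res._flat("beta")[:, 0]
        assert abs(b0.mean() - y.mean()) < 0.05 * sigma
        assert abs(b0.std(ddof=1) - sigma / 10) < 0.05 * (sigma / 10) + 0.01

    def test_fixed_precision_posterior_matches_dense_oracle(self, spatial_dataset):
        ds = spatial_dataset
        model = IcarModel.from_support(ds.outcomes, ds.covariates, ds.support)
        tau_s, tau_e = 4.0, 25.0
        mean, cov = exact_constrained_posterior(model, tau_s, tau_e)
        # package closed form agrees with the independent oracle
        m2, c2 = model.exact_gaussian_posterior(tau_s, tau_e)
        assert np.allclose(mean, m2, atol=1e-8)
        assert np.allclose(cov, c2, atol=1e-8)
        # sampler agrees within Monte-Carlo error
        res = model.fit(n_iter=4000, n_burn=1000, n_chains=2, seed=5,
                        tau_fixed=(tau_s, tau_e))
        beta = res._flat("beta")
        fld = res._flat("field")
        draws = np.hstack([beta, fld])
        n_eff = len(draws) / 5.0  # conservative: blocked Gibbs, low autocorrelation
        z = (draws.mean(0) - mean) / np.sqrt(np.diag(cov) / n_eff)
        assert np.all(np.abs(z[: model.p1]) < 4.0)
        assert np.mean(np.abs(z) < 3.0) > 0.9
        sd_ratio = draws.std(0, ddof=1) / np.sqrt(np.diag(cov))
        assert np.all(np.abs(sd_ratio - 1.0) < 0.2)

    def test_nonspatial_matches_conjugate_closed_form(self):
        rng = np.random.default_rng(2)
        n, p = 150, 2
        X = rng.normal(size=(n, p))
        y = 1.0 + X @ [0.5, -1.0] + rng.normal(scale=0.3, size=n)
        model = IcarModel(y, X, include_spatial=False)
        tau_e = 1.0 / 0.09
        mean, cov = model.exact_gaussian_posterior(None, tau_e)
        Xi = np.column_stack([np.ones(n), X])
        res = model.fit(n_iter=4000, n_burn=500, n_chains=2, seed=1,
                        tau_fixed=(None, tau_e))
        beta = res._flat("beta")
        z = (beta.mean(0) - mean[: p + 1]) / np.sqrt(np.diag(cov)[: p + 1] / (len(beta) / 2))
        assert np.all(np.abs(z) < 4.0)
        # with a vague prior the posterior mean is essentially OLS
        ols = np.linalg.lstsq(Xi, y, rcond=None)[0]
        assert np.allclose(beta.mean(0), ols, atol=0.02)

    def test_per_draw_sum_to_zero(self, spatial_dataset):
        ds = spatial_dataset
        model = IcarModel.from_support(ds.outcomes, ds.covariates, ds.support)
        res = model.fit(n_iter=300, n_burn=100, n_chains=1, seed=2)
        fld = res._flat("field")
        assert np.max(np.abs(fld.sum(axis=1))) < 1e-8

    def test_label_permutation_equivariance_closed_form(self, spatial_dataset):
        ds = spatial_dataset
        model = IcarModel.from_support(ds.outcomes, ds.covariates, ds.support)
        mean, _ = model.exact_gaussian_posterior(3.0, 20.0)
        rng = np.random.default_rng(3)
        perm = rng.permutation(model.n)
        R2 = model.R.toarray()[np.ix_(perm, perm)]
        model2 = IcarModel(
            model.y[perm],
            ds.covariates.design_matrix()[perm],
            structure_matrix=R2,
            components=model.components[perm],
            feature_names=model.feature_names,
        )
        mean2, _ = model2.exact_gaussian_posterior(3.0, 20.0)
        p1 = model.p1
        assert np.allclose(mean2[:p1], mean[:p1], atol=1e-8)
        assert np.allclose(mean2[p1:], mean[p1:][perm], atol=1e-8)

    def test_input_validation(self, spatial_dataset):
        ds = spatial_dataset
        X = ds.covariates.design_matrix()
        y = ds.outcomes.values.copy()
        with pytest.raises(ValueError, match="rank deficient"):
            IcarModel(y, np.column_stack([X, X[:, 0]]), support=ds.support)
        y_bad = y.copy()
        y_bad[0] = np.inf
        with pytest.raises(ValueError):
            IcarModel(y_bad, X, support=ds.support)
        with pytest.raises(ValueError, match="at least one observed"):
            IcarModel(np.full(ds.support.n_polygons, np.nan), X, support=ds.support)


class TestDic:
    def test_degenerate_posterior_has_zero_pd(self):
        support = make_grid_support(2, 2)
        y = np.array([1.0, 2.0, 3.0, 4.0])
        model = IcarModel(y, np.empty((4, 0)), structure_matrix=support.structure_matrix,
                          components=support.components)
        # constant draws -> plug-in deviance equals every per-draw deviance
        eta = np.tile(y, (1, 120, 1))
        draws = {
            "beta": np.full((1, 120, 1), y.mean()),
            "tau_noise": np.full((1, 120), 4.0),
            "tau_spatial": np.full((1, 120), 1.0),
            "field": eta - y.mean(),
            "eta": eta,
            "replicate": eta,
            "deviance": np.full(
                (1, 120), -2.0 * np.sum(stats.norm.logpdf(y, y, 0.5))
            ),
        }
        res = IcarResults(model, draws, n_iter=120, n_burn=0, n_chains=1, seed=0)
        d = res.compute_dic()
        assert abs(d["p_d"]) < 1e-9
        assert abs(d["dic"] - d["mean_deviance"]) < 1e-9

    def test_pd_close_to_free_parameter_count(self):
        rng = np.random.default_rng(4)
        n, p = 200, 3
        X = rng.normal(size=(n, p))
        y = 0.5 + X @ [1.0, -0.5, 0.2] + rng.normal(scale=0.4, size=n)
        model = IcarModel(y, X, include_spatial=False)
        res = model.fit(n_iter=4000, n_burn=1000, n_chains=2, seed=3,
                        tau_fixed=(None, 1.0 / 0.16))
        pd_val = res.compute_dic()["p_d"]
        assert abs(pd_val - (p + 1)) < 0.2 * (p + 1)

    def test_noise_covariate_barely_moves_dic(self):
        rng = np.random.default_rng(5)
        diffs = []
        for _ in range(20):
            n = 120
            X = rng.normal(size=(n, 1))
            y = 1.0 + 0.8 * X[:, 0] + rng.normal(scale=0.5, size=n)
            noise_col = rng.normal(size=(n, 1))
            m1 = IcarModel(y, X, include_spatial=False)
            m2 = IcarModel(y, np.hstack([X, noise_col]), include_spatial=False)
            r1 = m1.fit(n_iter=900, n_burn=300, n_chains=1, seed=7)
            r2 = m2.fit(n_iter=900, n_burn=300, n_chains=1, seed=7)
            diffs.append(r2.dic - r1.dic)
        assert abs(np.mean(diffs)) < 4.0

    def test_few_draws_warns(self, spatial_dataset):
        ds = spatial_dataset
        model = IcarModel.from_support(ds.outcomes, ds.covariates, ds.support)
        res = model.fit(n_iter=80, n_burn=40, n_chains=1, seed=0)
        with pytest.warns(UserWarning, match="100"):
            res.compute_dic()


class TestPredictions:
    def test_zero_noise_limit_interpolates_observations(self):
        support = make_grid_support(4, 4)
        rng = np.random.default_rng(6)
        y = rng.normal(size=16)
        model = IcarModel(y, np.empty((16, 0)), structure_matrix=support.structure_matrix,
                          components=support.components)
        res = model.fit(n_iter=1200, n_burn=400, n_chains=1, seed=1,
                        tau_fixed=(1.0, 1e8))
        pred = res.predict("latent_mean")
        assert np.max(np.abs(pred["mean"].to_numpy() - y)) < 1e-3

    def test_unobserved_polygons_get_finite_uncertainty(self):
        support = make_grid_support(5, 5)
        y = np.full(25, np.nan)
        rng = np.random.default_rng(7)
        y[:15] = rng.normal(size=15)
        model = IcarModel(y, np.empty((25, 0)), structure_matrix=support.structure_matrix,
                          components=support.components)
        res = model.fit(n_iter=600, n_burn=200, n_chains=1, seed=2)
        pred = res.predict("latent_mean")
        assert np.isfinite(pred["mean"]).all() and np.isfinite(pred["sd"]).all()
        assert (pred["sd"] > 0).all()

    def test_observed_sd_below_unobserved_sd(self):
        support = make_grid_support(4, 10)
        rng = np.random.default_rng(8)
        y = rng.normal(size=40)
        y[17] = np.nan  # unobserved polygon surrounded by data
        model = IcarModel(y, np.empty((40, 0)), structure_matrix=support.structure_matrix,
                          components=support.components)
        res = model.fit(n_iter=1500, n_burn=500, n_chains=1, seed=3,
                        tau_fixed=(2.0, 100.0))
        sd = res.predict("latent_mean")["sd"]
        assert sd[16] < sd[17]

    def test_replicate_sd_exceeds_latent_sd(self, spatial_dataset):
        ds = spatial_dataset
        model = IcarModel.from_support(ds.outcomes, ds.covariates, ds.support)
        res = model.fit(n_iter=500, n_burn=200, n_chains=1, seed=4)
        lat = res.predict("latent_mean")["sd"].to_numpy()
        rep = res.predict("replicate")["sd"].to_numpy()
        # var(replicate) = var(latent) + noise variance; allow MC wiggle where
        # field uncertainty dominates both
        assert np.all(rep > 0.9 * lat)
        assert np.mean(rep**2 - lat**2) > 0

    def test_unknown_predictive_kind_rejected(self, spatial_dataset):
        ds = spatial_dataset
        model = IcarModel.from_support(ds.outcomes, ds.covariates, ds.support)
        res = model.fit(n_iter=120, n_burn=60, n_chains=1, seed=0)
        with pytest.raises(ValueError):
            res.predict("nope")


class TestResultsSurface:
    def test_summary_and_diagnostics_cover_all_parameters(self, spatial_dataset):
        ds = spatial_dataset
        model = IcarModel.from_support(ds.outcomes, ds.covariates, ds.support)
        res = model.fit(n_iter=400, n_burn=150, n_chains=2, seed=5)
        diag = res.diagnostics()
        assert set(diag.index) == {"intercept", "rs_0", "rs_1", "cdr_0",
                                   "tau_noise", "tau_spatial"}
        text = res.summary()
        assert "DIC" in text and "Besag" in text
        frame = res.summary_frame()
        assert {"mean", "sd", "q2.5", "q97.5"} <= set(frame.columns)

    def test_from_dataframe_constructor(self, spatial_dataset):
        import pandas as pd

        ds = spatial_dataset
        df = ds.covariates.values.copy()
        df["y"] = ds.outcomes.values
        model = IcarModel.from_dataframe(df, "y", ds.covariates.feature_names,
                                         support=ds.support)
        assert model.n == ds.support.n_polygons
        assert model.feature_names == ds.covariates.feature_names
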