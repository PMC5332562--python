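"""Bayesian Gaussian regression with a Besag ICAR spatial random effect.

The model for an outcome y over n areal units (Voronoi polygons) with design
matrix X (intercept + covariates) is

    y_i | eta_i, tau_noise  ~  Normal(eta_i, 1/tau_noise),   i observed,
    eta = X beta + x,
    x | tau_spatial  ~  ICAR(tau_spatial * R),

where R is the (optionally variance-scaled) graph Laplacian of the polygon
adjacency.  The ICAR prior is intrinsic — its density is proportional to
tau^(rank(R)/2) exp(-tau/2 x' R x) — and is made proper by a sum-to-zero
constraint on x within each connected component.  Hyperpriors are loggamma
on each log-precision theta = log tau, i.e. Gamma(a, b) on tau itself, so
both precisions admit conjugate gamma updates.  beta has a vague Normal
prior.

Inference is a blocked Gibbs sampler: (beta, x) jointly from their Gaussian
full conditional (Cholesky solve), the constraint imposed by conditioning by
kriging, and the two precisions from their gamma conditionals.  Unobserved
polygons receive posterior predictive draws, so predictions with uncertainty
exist everywhere.  A model without the spatial effect (plain Bayesian linear
regression) is obtained with ``include_spatial=False``; the two are compared
by DIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from scipy import stats

from .aggregate import CovariateTable, OutcomeVector
from .support import PolygonSupport

__all__ = ["IcarModel", "IcarResults", "log_icar_prior"]

_LOG2PI = float(np.log(2.0 * np.pi))


def log_icar_prior(x: np.ndarray, R, tau: float) -> float:
    """Unnormalized ICAR log-density: (rank(R)/2) log tau - (tau/2) x'Rx.

    For an unscaled R this equals the sum over neighbour pairs of
    -(tau/2)(x_i - x_j)^2 plus the log-tau term.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    x = np.asarray(x, dtype=float)
    Rd = R.toarray() if sp.issparse(R) else np.asarray(R, dtype=float)
    w = np.linalg.eigvalsh(Rd)
    rank = int((w > w.max() * 1e-10).sum()) if w.max() > 0 else 0
    quad = float(x @ (Rd @ x))
    return 0.5 * rank * np.log(tau) - 0.5 * tau * quad


class IcarModel:
    """Spatial (Besag ICAR) or non-spatial Bayesian Gaussian regression.

    Parameters
    ----------
    outcome : OutcomeVector or array with NaN at unobserved polygons.
    design : (n, p) covariate matrix, without intercept (added internally).
    structure_matrix, components : Besag structure R and connected-component
        labels; both are taken from ``support`` when given.
    include_spatial : drop the ICAR term to get the non-spatial comparison
        model.
    hyper_spatial, hyper_noise : (a, b) of the loggamma prior on each
        log-precision (equivalently Gamma(a, b) on the precision).  Defaults
        (1, 5e-5) follow the convention of the spatial-modelling software
        ecosystem this model family comes from.
    beta_prior_var : variance of the exchangeable Normal prior on each
        coefficient, applied after internal standardization of covariates.
    """

    def __init__(
        self,
        outcome,
        design,
        *,
        support: PolygonSupport | None = None,
        structure_matrix=None,
        components=None,
        feature_names: list[str] | None = None,
        include_spatial: bool = True,
        hyper_spatial: tuple[float, float] = (1.0, 5e-5),
        hyper_noise: tuple[float, float] = (1.0, 5e-5),
        beta_prior_var: float = 1e6,
        standardize: bool = True,
    ):
        if isinstance(outcome, OutcomeVector):
            self.outcome_kind = outcome.kind
            y = outcome.values
        else:
            self.outcome_kind = "score"
            y = np.asarray(outcome, dtype=float)
        self.y = y
        self.obs = ~np.isnan(y)  # NaN marks an unobserved polygon
        if not np.isfinite(y[self.obs]).all():
            raise ValueError("non-finite outcome values")
        if self.obs.sum() < 1:
            raise ValueError("need at least one observed polygon")

        design = np.asarray(design, dtype=float)
        if design.ndim == 1:
            design = design[:, None]
        if design.shape[0] != len(y):
            raise ValueError("design rows must match outcome length")
        self.n = len(y)
        p = design.shape[1]
        self.feature_names = list(feature_names) if feature_names else [f"x{j}" for j in range(p)]
        if len(self.feature_names) != p:
            raise ValueError("feature_names length mismatch")

        self.include_spatial = bool(include_spatial)
        if support is not None:
            structure_matrix = support.structure_matrix
            components = support.components
        if self.include_spatial:
            if structure_matrix is None or components is None:
                raise ValueError("spatial model needs structure_matrix and components")
            if structure_matrix.shape[0] != self.n:
                raise ValueError("structure matrix dimension must match polygon count")
            self.R = sp.csr_matrix(structure_matrix)
            self.components = np.asarray(components, dtype=int)
            self.n_components = int(self.components.max()) + 1
            self.rank_R = self.n - self.n_components
        else:
            self.R = None
            self.components = None
            self.n_components = 0
            self.rank_R = 0

        # standardize covariates for conditioning; report on the original scale
        self.standardize = bool(standardize)
        self._mu = design.mean(axis=0) if standardize and p else np.zeros(p)
        sd = design.std(axis=0, ddof=0) if p else np.ones(0)
        sd = np.where(sd > 0, sd, 1.0) if p else sd
        self._sd = sd if standardize else np.ones(p)
        Xs = (design - self._mu) / self._sd if p else design
        self.X = np.column_stack([np.ones(self.n), Xs])
        self.p1 = self.X.shape[1]
        if np.linalg.matrix_rank(self.X[self.obs]) < self.p1:
            raise ValueError("design is rank deficient on observed rows")

        self.hyper_spatial = tuple(hyper_spatial)
        self.hyper_noise = tuple(hyper_noise)
        self.beta_prior_var = float(beta_prior_var)
        self._build_templates()

    # ------------------------------------------------------------------ setup
    @classmethod
    def from_support(
        cls,
        outcome,
        covariates: CovariateTable,
        support: PolygonSupport,
        features: list[str] | None = None,
        **kwargs,
    ) -> "IcarModel":
        feats = features if features is not None else covariates.feature_names
        return cls(
            outcome,
            covariates.design_matrix(list(feats)),
            support=support,
            feature_names=list(feats),
            **kwargs,
        )

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        outcome_col: str,
        feature_cols: list[str],
        support: PolygonSupport | None = None,
        **kwargs,
    ) -> "IcarModel":
        return cls(
            data[outcome_col].to_numpy(dtype=float),
            data[list(feature_cols)].to_numpy(dtype=float),
            support=support,
            feature_names=list(feature_cols),
            **kwargs,
        )

    def _build_templates(self) -> None:
        """Precompute the sum-to-zero-basis design blocks used every iteration.

        The spatial field is parameterized as x = B u with B an orthonormal
        null-space basis of the per-component sum-to-zero constraints, so
        every draw satisfies the constraints exactly and all linear algebra
        happens on the (p1 + n - k)-dimensional free space.
        """
        obs_idx = np.flatnonzero(self.obs)
        self._obs_idx = obs_idx
        Xo = self.X[obs_idx]
        yo = self.y[obs_idx]
        p1, n = self.p1, self.n
        self._yy = float(yo @ yo)

        if self.include_spatial:
            A = np.zeros((self.n_components, n))
            for c in range(self.n_components):
                A[c, self.components == c] = 1.0
            self._A = A
            B = sla.null_space(A)
            self._B = B
            Rd = self.R.toarray()
            self._Rd = Rd
            G = np.hstack([Xo, B[obs_idx]])  # observed-row design over (beta, u)
            qr = p1 + B.shape[1]
            Ts = np.zeros((qr, qr))
            Ts[p1:, p1:] = B.T @ Rd @ B
            self._Ts = Ts
        else:
            self._A = None
            self._B = None
            G = Xo
            qr = p1
            self._Ts = None
        self.q = qr
        self._Tn = G.T @ G
        self._bb = G.T @ yo
        Tp = np.zeros((qr, qr))
        Tp[np.arange(p1), np.arange(p1)] = 1.0 / self.beta_prior_var
        self._Tp = Tp

    # ------------------------------------------------------------- inference
    def fit(
        self,
        n_iter: int = 5000,
        n_burn: int = 2500,
        n_chains: int = 4,
        seed: int = 0,
        tau_fixed: tuple[float, float] | None = None,
        thin: int = 1,
    ) -> "IcarResults":
        """Run the blocked Gibbs sampler; deterministic given ``seed``.

        tau_fixed = (tau_spatial, tau_noise) freezes both precisions (used
        for conjugate-limit checks); either entry may be None to sample it.
        """
        if n_burn >= n_iter:
            raise ValueError("n_burn must be < n_iter")
        seeds = np.random.SeedSequence(seed).spawn(n_chains)
        chains = [self._run_chain(n_iter, n_burn, thin, np.random.default_rng(s), tau_fixed)
                  for s in seeds]
        draws = {k: np.stack([c[k] for c in chains]) for k in chains[0]}
        return IcarResults(self, draws, n_iter=n_iter, n_burn=n_burn,
                           n_chains=n_chains, seed=seed)

    def _factor(self, tau_s, tau_e):
        """Cholesky of the free-space posterior precision and its mean solve."""
        Qr = tau_e * self._Tn + self._Tp
        if self.include_spatial:
            Qr = Qr + tau_s * self._Ts
        try:
            c_lo = sla.cho_factor(Qr, lower=True, check_finite=False)
        except np.linalg.LinAlgError as err:
            raise RuntimeError(
                f"divergent sampler state: tau_spatial={tau_s}, tau_noise={tau_e}"
            ) from err
        br = tau_e * self._bb
        mu = sla.cho_solve(c_lo, br, check_finite=False)
        return c_lo, mu, br

    def _log_marginal(self, tau_s, tau_e, c_lo, mu, br):
        """log p(y | tau) + log prior(tau), up to tau-independent constants.

        The Gaussian block (beta, u) is integrated out analytically:
        m/2 log tau_e - tau_e/2 y'y + rank(R)/2 log tau_s
        - log det(Q)^(1/2) + 1/2 b'Q^-1 b, plus the Gamma(a, b) log-priors.
        """
        m = len(self._obs_idx)
        lm = 0.5 * m * np.log(tau_e) - 0.5 * tau_e * self._yy
        lm -= float(np.sum(np.log(np.diag(c_lo[0]))))
        lm += 0.5 * float(br @ mu)
        a_e, b_e = self.hyper_noise
        lm += a_e * np.log(tau_e) - b_e * tau_e  # Gamma prior via theta = log tau
        if self.include_spatial:
            lm += 0.5 * self.rank_R * np.log(tau_s)
            a_s, b_s = self.hyper_spatial
            lm += a_s * np.log(tau_s) - b_s * tau_s
        return lm

    def _run_chain(self, n_iter, n_burn, thin, rng, tau_fixed, mh_step=0.7):
        p1, n, qr = self.p1, self.n, self.q
        obs_idx = self._obs_idx
        yo = self.y[obs_idx]
        m = len(obs_idx)
        a_e, b_e = self.hyper_noise

        fix_s = tau_fixed[0] if tau_fixed is not None else None
        fix_e = tau_fixed[1] if tau_fixed is not None else None
        # initialize both precisions at the OLS residual precision: an even
        # split of residual variation between field and noise, well inside the
        # dominant basin of the marginal posterior for smooth and iid data alike
        coef, *_ = np.linalg.lstsq(self.X[obs_idx], yo, rcond=None)
        v = max(float(np.var(yo - self.X[obs_idx] @ coef)), 1e-12)
        tau_e = fix_e if fix_e is not None else 1.0 / v
        tau_s = (fix_s if fix_s is not None else 1.0 / v) if self.include_spatial else None

        kept = (n_iter - n_burn) // thin
        out = {
            "beta": np.empty((kept, p1)),
            "tau_noise": np.empty(kept),
            "deviance": np.empty(kept),
            "eta": np.empty((kept, n)),
            "replicate": np.empty((kept, n)),
        }
        if self.include_spatial:
            out["tau_spatial"] = np.empty(kept)
            out["field"] = np.empty((kept, n))

        state = self._factor(tau_s, tau_e)
        lm = (
            self._log_marginal(tau_s, tau_e, *state)
            if self.include_spatial
            else None
        )
        k_out = 0
        for it in range(n_iter):
            if self.include_spatial:
                # precisions move through their marginal posterior (the Gaussian
                # block integrated out): a joint random-walk on the log scale.
                # Conditional-on-field updates are an absorbing trap here — once
                # the field collapses, tau_spatial can never come back down.
                if fix_s is None or fix_e is None:
                    prop_s = tau_s if fix_s is not None else float(
                        tau_s * np.exp(mh_step * rng.standard_normal())
                    )
                    prop_e = tau_e if fix_e is not None else float(
                        tau_e * np.exp(mh_step * rng.standard_normal())
                    )
                    cand = self._factor(prop_s, prop_e)
                    lm_prop = self._log_marginal(prop_s, prop_e, *cand)
                    # symmetric proposal on theta = log tau
                    if np.log(rng.random()) < lm_prop - lm:
                        tau_s, tau_e, state, lm = prop_s, prop_e, cand, lm_prop
            else:
                # conjugate Gibbs: beta | tau_e then tau_e | beta
                state = self._factor(None, tau_e)

            c_lo, mu, _ = state
            u = mu + sla.solve_triangular(
                c_lo[0].T, rng.standard_normal(qr), lower=False, check_finite=False
            )
            beta_s = u[:p1]
            x = self._B @ u[p1:] if self.include_spatial else np.zeros(n)

            if not self.include_spatial and fix_e is None:
                resid = yo - self.X[obs_idx] @ beta_s
                tau_e = rng.gamma(
                    a_e + 0.5 * m, 1.0 / (b_e + 0.5 * float(resid @ resid))
                )
            if not np.isfinite(tau_e) or (
                self.include_spatial and not np.isfinite(tau_s)
            ):
                raise RuntimeError(
                    f"divergent sampler (non-finite precision) at iteration {it}"
                )

            if it >= n_burn and (it - n_burn) % thin == 0:
                eta_all = self.X @ beta_s + x
                dev = -2.0 * float(
                    np.sum(stats.norm.logpdf(yo, eta_all[obs_idx], 1.0 / np.sqrt(tau_e)))
                )
                out["beta"][k_out] = self._beta_original(beta_s)
                out["tau_noise"][k_out] = tau_e
                out["deviance"][k_out] = dev
                if self.include_spatial:
                    out["tau_spatial"][k_out] = tau_s
                    out["field"][k_out] = x
                out["eta"][k_out] = eta_all
                out["replicate"][k_out] = eta_all + rng.normal(
                    scale=1.0 / np.sqrt(tau_e), size=n
                )
                k_out += 1
        return out

    def _beta_original(self, beta_s: np.ndarray) -> np.ndarray:
        """Map coefficients from the standardized to the original scale."""
        out = beta_s.copy()
        if self.p1 > 1:
            slopes = beta_s[1:] / self._sd
            out[0] = beta_s[0] - float(slopes @ self._mu)
            out[1:] = slopes
        return out

    # ------------------------------------------------------- closed-form path
    def exact_gaussian_posterior(
        self, tau_spatial: float | None, tau_noise: float
    ) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and covariance of (beta, x) with both precisions fixed.

        Direct dense linear algebra on the sum-to-zero subspace: x = B u with
        B an orthonormal null-space basis of the constraint rows, so no
        regularization or sampling is involved.  beta is returned on the
        original covariate scale; x entries follow the beta block.
        """
        p1, n = self.p1, self.n
        Qr = tau_noise * self._Tn + self._Tp
        if self.include_spatial:
            Qr = Qr + tau_spatial * self._Ts
            T = np.zeros((p1 + n, self.q))
            T[:p1, :p1] = np.eye(p1)
            T[p1:, p1:] = self._B
        else:
            T = np.eye(p1)
        cov_r = np.linalg.inv(Qr)
        mean = T @ (cov_r @ (tau_noise * self._bb))
        cov = T @ cov_r @ T.T
        # back-transform the beta block to the original covariate scale
        L = np.eye(T.shape[0])
        if self.p1 > 1:
            L[0, 1 : self.p1] = -self._mu / self._sd
            L[np.arange(1, self.p1), np.arange(1, self.p1)] = 1.0 / self._sd
        return L @ mean, L @ cov @ L.T


@dataclass
class IcarResults:
    """Posterior draws, predictions, DIC and diagnostics for an IcarModel fit."""

    model: IcarModel
    draws: dict
    n_iter: int
    n_burn: int
    n_chains: int
    seed: int

    # ------------------------------------------------------------- accessors
    @property
    def param_names(self) -> list[str]:
        names = ["intercept"] + self.model.feature_names
        names.append("tau_noise")
        if self.model.include_spatial:
            names.append("tau_spatial")
        return names

    def _flat(self, key: str) -> np.ndarray:
        d = self.draws[key]
        return d.reshape(-1, *d.shape[2:])

    @property
    def beta_mean(self) -> np.ndarray:
        return self._flat("beta").mean(axis=0)

    @property
    def beta_sd(self) -> np.ndarray:
        return self._flat("beta").std(axis=0, ddof=1)

    def beta_interval(self, level: float = 0.90) -> np.ndarray:
        """(p1, 2) equal-tailed posterior credible intervals for beta."""
        a = (1.0 - level) / 2.0
        return np.quantile(self._flat("beta"), [a, 1 - a], axis=0).T

    @property
    def field_mean(self) -> np.ndarray:
        if not self.model.include_spatial:
            return np.zeros(self.model.n)
        return self._flat("field").mean(axis=0)

    # ------------------------------------------------------------ predictions
    def predict(self, which: str = "latent_mean") -> pd.DataFrame:
        """Per-polygon posterior (mean, sd) of the latent mean or a replicate.

        ``latent_mean`` is eta = X beta + x (the noise-free surface);
        ``replicate`` adds observation noise, i.e. the posterior predictive
        for a new areal observation.  Available for every polygon, observed
        or not.
        """
        if which not in ("latent_mean", "replicate"):
            raise ValueError(f"unknown predictive quantity {which!r}")
        d = self._flat("eta" if which == "latent_mean" else "replicate")
        return pd.DataFrame(
            {
                "mean": d.mean(axis=0),
                "sd": d.std(axis=0, ddof=1),
                "observed": self.model.obs,
            }
        )

    # ------------------------------------------------------------------- DIC
    @property
    def dic(self) -> float:
        return self.compute_dic()["dic"]

    def compute_dic(self) -> dict:
        """DIC = mean deviance + p_D with p_D = mean deviance - plug-in deviance.

        The plug-in deviance is evaluated at the posterior means of the
        coefficients, the spatial field and the noise precision.
        """
        dev = self._flat("deviance")
        if len(dev) < 100:
            warnings.warn("fewer than 100 retained draws: p_D may be unstable")
        dbar = float(dev.mean())
        m = self.model
        obs = m.obs
        eta_mean = self._flat("eta").mean(axis=0)
        tau_e = float(self._flat("tau_noise").mean())
        dhat = -2.0 * float(
            np.sum(stats.norm.logpdf(m.y[obs], eta_mean[obs], 1.0 / np.sqrt(tau_e)))
        )
        p_d = dbar - dhat
        return {"dic": dbar + p_d, "mean_deviance": dbar, "p_d": p_d}

    # ------------------------------------------------------------ diagnostics
    def diagnostics(self) -> pd.DataFrame:
        """Split-chain R-hat and bulk ESS for every scalar parameter."""
        import arviz as az

        post = {"beta": self.draws["beta"], "tau_noise": self.draws["tau_noise"]}
        if self.model.include_spatial:
            post["tau_spatial"] = self.draws["tau_spatial"]
        idata = az.from_dict(posterior=post)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = az.rhat(idata)
            ess = az.ess(idata)
        rows = []
        names = ["intercept"] + self.model.feature_names
        for j, nm in enumerate(names):
            rows.append((nm, float(rhat["beta"][j]), float(ess["beta"][j])))
        rows.append(("tau_noise", float(rhat["tau_noise"]), float(ess["tau_noise"])))
        if self.model.include_spatial:
            rows.append(("tau_spatial", float(rhat["tau_spatial"]), float(ess["tau_spatial"])))
        return pd.DataFrame(rows, columns=["param", "r_hat", "ess_bulk"]).set_index("param")

    # ---------------------------------------------------------------- summary
    def summary_frame(self) -> pd.DataFrame:
        beta = self._flat("beta")
        names = ["intercept"] + self.model.feature_names
        rows = {}
        for j, nm in enumerate(names):
            rows[nm] = beta[:, j]
        rows["tau_noise"] = self._flat("tau_noise")
        if self.model.include_spatial:
            rows["tau_spatial"] = self._flat("tau_spatial")
        recs = []
        for nm, d in rows.items():
            lo, hi = np.quantile(d, [0.025, 0.975])
            recs.append((nm, d.mean(), d.std(ddof=1), lo, hi))
        return pd.DataFrame(
            recs, columns=["param", "mean", "sd", "q2.5", "q97.5"]
        ).set_index("param")

    def summary(self) -> str:
        kind = "spatial (Besag ICAR)" if self.model.include_spatial else "non-spatial"
        diag = self.diagnostics()
        tab = self.summary_frame().join(diag)
        dic = self.compute_dic()
        lines = [
            "Bayesian areal regression — " + kind,
            f"polygons: {self.model.n} ({int(self.model.obs.sum())} observed)   "
            f"chains: {self.n_chains}   draws/chain: {self.draws['beta'].shape[1]}",
            "",
            tab.to_string(float_format=lambda v: f"{v:0.4f}"),
            "",
            f"DIC: {dic['dic']:0.2f}   mean deviance: {dic['mean_deviance']:0.2f}   "
            f"p_D: {dic['p_d']:0.2f}",
        ]
        return "\n".join(lines)

    def to_draws_frame(self) -> pd.DataFrame:
        """Long-format (parameter, chain, iter, value) table of scalar draws."""
        recs = []
        names = ["intercept"] + self.model.feature_names
        C, D, _ = self.draws["beta"].shape
        for c in range(C):
            for j, nm in enumerate(names):
                recs.append(
                    pd.DataFrame(
                        {
                            "parameter": nm,
                            "chain": c,
                            "iter": np.arange(D),
                            "value": self.draws["beta"][c, :, j],
                        }
                    )
                )
            recs.append(
                pd.DataFrame(
                    {
                        "parameter": "tau_noise",
                        "chain": c,
                        "iter": np.arange(D),
                        "value": self.draws["tau_noise"][c],
                    }
                )
            )
            if self.model.include_spatial:
                recs.append(
                    pd.DataFrame(
                        {
                            "parameter": "tau_spatial",
                            "chain": c,
                            "iter": np.arange(D),
                            "value": self.draws["tau_spatial"][c],
                        }
                    )
                )
        return pd.concat(recs, ignore_index=True)
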