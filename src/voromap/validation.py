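"""Hold-out metrics, stratified runs, admin-level re-aggregation, stratum t-test.

Model performance is judged on a 20% hold-out: Pearson r (Spearman's rho when
fewer than 100 test polygons), r^2, RMSE and MAE of observed vs predicted
polygon outcomes, plus DIC for the spatial / non-spatial comparison.
Predictions can be re-aggregated to coarser administrative units and
correlated against reference small-area estimates (negative correlations are
expected when the reference measures the share of people below a poverty line
while the outcome measures wealth), and two groups of polygons (e.g. slum vs
non-slum) are compared with a pooled-variance two-sample t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .model import IcarModel
from .selection import exhaustive_aic, prune_collinear, split_train_test

__all__ = [
    "ValidationReport",
    "holdout_metrics",
    "stratum_ttest",
    "aggregate_to_admin",
    "stratified_run",
]

SPEARMAN_N = 100  # below this test size, rank correlation replaces Pearson


@dataclass
class ValidationReport:
    n_test: int
    pearson_r: float
    spearman_rho: float
    r2: float
    rmse: float
    mae: float
    metric_used: str
    zero_variance: bool = False
    dic_spatial: float | None = None
    dic_nonspatial: float | None = None
    stratum: str = "national"
    seed: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def holdout_metrics(
    observed: np.ndarray,
    predicted: np.ndarray,
    *,
    stratum: str = "national",
    seed: int | None = None,
    r2_definition: str = "squared_correlation",
) -> ValidationReport:
    """Out-of-sample validation statistics on paired (observed, predicted).

    r^2 is the squared Pearson correlation by default (switchable to
    1 - SSE/SST via ``r2_definition="explained_variance"``); the headline
    correlation is Spearman's rho when n < 100, Pearson's r otherwise.
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.ndim != 1:
        raise ValueError("observed and predicted must be equal-length vectors")
    if len(o) < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.isfinite(o).all() and np.isfinite(p).all()):
        raise ValueError("missing values in observed/predicted pairs")
    err = o - p
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    zero_var = o.std() == 0 or p.std() == 0
    if zero_var:
        warnings.warn("zero variance: correlation undefined")
        r = rho = r2 = float("nan")
    else:
        r = float(stats.pearsonr(o, p).statistic)
        rho = float(stats.spearmanr(o, p).statistic)
        if r2_definition == "squared_correlation":
            r2 = r * r
        elif r2_definition == "explained_variance":
            r2 = float(1.0 - (err @ err) / ((o - o.mean()) @ (o - o.mean())))
        else:
            raise ValueError(f"unknown r2 definition {r2_definition!r}")
    return ValidationReport(
        n_test=len(o),
        pearson_r=r,
        spearman_rho=rho,
        r2=r2,
        rmse=rmse,
        mae=mae,
        metric_used="spearman" if len(o) < SPEARMAN_N else "pearson",
        zero_variance=bool(zero_var),
        stratum=stratum,
        seed=seed,
    )


def stratum_ttest(group_a: np.ndarray, group_b: np.ndarray, level: float = 0.95):
    """Pooled-variance two-sample Student t-test with a CI for the mean difference.

    df = n_a + n_b - 2 (the pooled form, matching df arithmetic like 617
    observations -> 615 degrees of freedom).  Returns (t, df, p, (lo, hi)).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 values")
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = (((na - 1) * a.var(ddof=1)) + ((nb - 1) * b.var(ddof=1))) / df
    if sp2 <= 0:
        warnings.warn("zero pooled variance: t undefined")
        return float("nan"), df, float("nan"), (float("nan"), float("nan"))
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    diff = a.mean() - b.mean()
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    tcrit = stats.t.ppf(0.5 + level / 2.0, df)
    return float(t), int(df), float(p), (float(diff - tcrit * se), float(diff + tcrit * se))


def aggregate_to_admin(
    predictions: np.ndarray,
    polygons: list,
    admin_polygons: list,
    *,
    weights: str = "area",
    population: np.ndarray | None = None,
    reference: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Re-aggregate polygon predictions to coarser admin units by weighted mean.

    Weights are polygon-admin intersection areas (optionally multiplied by a
    per-polygon population when ``weights="population"``).  Admin units with
    zero intersection get NaN.  When a ``reference`` table is supplied (one
    row per admin unit, numeric columns such as upper/lower poverty-line
    shares), the Pearson correlation of the aggregate against each reference
    column is attached as frame metadata ``result.attrs["reference_r"]`` —
    negative values are expected when the reference is a poverty share and
    the prediction a wealth level.
    """
    predictions = np.asarray(predictions, dtype=float)
    if weights not in ("area", "population"):
        raise ValueError(f"unknown weights {weights!r}")
    if weights == "population" and population is None:
        raise ValueError("population weights requested but no population given")
    vals = np.full(len(admin_polygons), np.nan)
    wsum = np.zeros(len(admin_polygons))
    for k, adm in enumerate(admin_polygons):
        tot, acc = 0.0, 0.0
        for i, poly in enumerate(polygons):
            w = adm.intersection(poly).area
            if weights == "population":
                w *= population[i]
            if w > 0:
                tot += w
                acc += w * predictions[i]
        if tot > 0:
            vals[k] = acc / tot
            wsum[k] = tot
    out = pd.DataFrame({"admin_id": np.arange(len(admin_polygons)), "aggregate": vals,
                        "weight": wsum})
    if reference is not None:
        corr = {}
        ok = np.isfinite(vals)
        for col in reference.columns:
            ref = reference[col].to_numpy(dtype=float)
            corr[col] = float(stats.pearsonr(vals[ok], ref[ok]).statistic)
        out.attrs["reference_r"] = corr
    return out


def stratified_run(
    outcome,
    covariates,
    support,
    strata: np.ndarray,
    *,
    seed: int = 0,
    fraction: float = 0.8,
    threshold: float = 0.70,
    tie_window: float = 2.0,
    n_iter: int = 1500,
    n_burn: int = 500,
    n_chains: int = 2,
    min_observed: int = 20,
) -> dict[str, ValidationReport]:
    """Selection -> spatial & non-spatial fit -> hold-out metrics, per stratum.

    Runs the full pipeline nationally and for each stratum label (e.g. urban
    and rural).  A stratum with fewer than ``min_observed`` observed polygons
    is skipped with a warning.  The same seed drives each stratum's split.
    """
    strata = np.asarray(strata)
    if len(strata) != support.n_polygons:
        raise ValueError("every polygon needs a stratum label")
    reports: dict[str, ValidationReport] = {}
    groups = {"national": np.ones(len(strata), dtype=bool)}
    for s in np.unique(strata):
        groups[str(s)] = strata == s
    for name, mask in groups.items():
        rep = _single_run(
            outcome, covariates, support, mask,
            seed=seed, fraction=fraction, threshold=threshold,
            tie_window=tie_window, n_iter=n_iter, n_burn=n_burn,
            n_chains=n_chains, min_observed=min_observed, stratum=name,
        )
        if rep is not None:
            reports[name] = rep
    return reports


def _single_run(outcome, covariates, support, mask, *, seed, fraction, threshold,
                tie_window, n_iter, n_burn, n_chains, min_observed, stratum):
    obs_mask = outcome.observed & mask
    obs_idx = np.flatnonzero(obs_mask)
    if len(obs_idx) < min_observed:
        warnings.warn(f"stratum {stratum!r}: only {len(obs_idx)} observed polygons; skipped")
        return None

    pruned = prune_collinear(
        covariates.values.iloc[obs_idx], threshold, covariates.generalizability_rank
    )
    feats = pruned.kept_features
    train_loc, test_loc = split_train_test(len(obs_idx), fraction, seed)
    sel = exhaustive_aic(
        covariates.values[feats].iloc[obs_idx],
        outcome.values[obs_idx],
        train_indices=train_loc,
        tie_window=tie_window,
        result=pruned,
    )
    chosen = list(sel.chosen_model)

    # hold the test polygons out of the fit: the model predicts them as
    # unobserved polygons, which is how the spatial effect helps
    test_idx = obs_idx[test_loc]
    y_fit = outcome.values.copy()
    y_fit[~mask] = np.nan
    y_fit[test_idx] = np.nan

    design = covariates.design_matrix(chosen) if chosen else np.empty((support.n_polygons, 0))
    common = dict(feature_names=chosen)
    fits = {}
    for label, spatial in (("spatial", True), ("nonspatial", False)):
        model = IcarModel(
            y_fit, design, support=support, include_spatial=spatial, **common
        )
        fits[label] = model.fit(n_iter=n_iter, n_burn=n_burn, n_chains=n_chains, seed=seed)
    pred = fits["spatial"].predict("latent_mean")["mean"].to_numpy()
    rep = holdout_metrics(
        outcome.values[test_idx], pred[test_idx], stratum=stratum, seed=seed
    )
    rep.dic_spatial = fits["spatial"].dic
    rep.dic_nonspatial = fits["nonspatial"].dic
    return rep
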