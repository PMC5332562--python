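"""Covariate selection: collinearity pruning, stepwise pre-reduction, exhaustive AIC.

The selection stage mirrors common practice for poverty-mapping covariate
sets: log-transformed features are first pruned for multicollinearity
(|Pearson r| > 0.70, keeping the more generalizable member of each pair);
very large feature sets (e.g. ~150 CDR aggregates) are pre-reduced by
bidirectional stepwise selection at p = 0.05 to at most ~30; the survivors
are searched exhaustively with Gaussian linear models ranked by AIC on a
random 80% training split, preferring the fewest covariates among models
within a small AIC window.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "SelectionResult",
    "prune_collinear",
    "stepwise_reduce",
    "exhaustive_aic",
    "split_train_test",
    "gaussian_aic",
]


@dataclass
class SelectionResult:
    kept_features: list[str] = field(default_factory=list)
    dropped_collinear: list[tuple[str, str, float]] = field(default_factory=list)
    stepwise_path: list[tuple[str, str, float]] = field(default_factory=list)
    candidate_models: list[tuple[tuple[str, ...], float]] = field(default_factory=list)
    chosen_model: tuple[str, ...] = ()
    split_seed: int | None = None
    train_indices: np.ndarray | None = None
    test_indices: np.ndarray | None = None
    skipped_subsets: list[tuple[str, ...]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "kept_features": list(self.kept_features),
            "dropped_collinear": [
                {"kept": k, "dropped": d, "r": float(r)} for k, d, r in self.dropped_collinear
            ],
            "stepwise_path": [
                {"action": a, "feature": f, "p_value": float(p)} for a, f, p in self.stepwise_path
            ],
            "candidate_models": [
                {"features": list(fs), "aic": float(a)} for fs, a in self.candidate_models
            ],
            "chosen_model": list(self.chosen_model),
            "split_seed": self.split_seed,
            "train_indices": None if self.train_indices is None else self.train_indices.tolist(),
            "test_indices": None if self.test_indices is None else self.test_indices.tolist(),
        }


def prune_collinear(
    values: pd.DataFrame,
    threshold: float = 0.70,
    ranks: dict[str, int] | None = None,
) -> SelectionResult:
    """Drop the less generalizable member of each highly correlated pair.

    Pairwise-complete Pearson correlations; pairs are processed in
    descending |r|; a feature that has already been dropped cannot trigger
    further drops.  Missing/tied generalizability ranks fall back to
    dropping the later feature in name order (with a warning for missing
    ranks).
    """
    if values.shape[1] < 2:
        raise ValueError("need at least 2 features to prune")
    corr = values.corr(method="pearson")  # pairwise-complete
    names = list(values.columns)
    pairs = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            r = corr.loc[a, b]
            if np.isfinite(r) and abs(r) > threshold:
                pairs.append((abs(r), a, b, float(r)))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))

    alive = set(names)
    dropped = []
    for _, a, b, r in pairs:
        if a not in alive or b not in alive:
            continue
        if ranks is None or a not in ranks or b not in ranks:
            if ranks is not None:
                warnings.warn(f"missing generalizability rank for pair ({a}, {b}); using name order")
            keep, drop = sorted([a, b])
        elif ranks[a] == ranks[b]:
            keep, drop = sorted([a, b])
        else:
            keep, drop = (a, b) if ranks[a] < ranks[b] else (b, a)
        alive.discard(drop)
        dropped.append((keep, drop, r))
    return SelectionResult(
        kept_features=[n for n in names if n in alive],
        dropped_collinear=dropped,
    )


def _ols_pvalues(X: pd.DataFrame, y: np.ndarray, features: list[str]) -> pd.Series:
    design = sm.add_constant(X[features].to_numpy(), has_constant="add")
    fit = sm.OLS(y, design).fit()
    return pd.Series(fit.pvalues[1:], index=features)


def stepwise_reduce(
    X: pd.DataFrame,
    y: np.ndarray,
    alpha: float = 0.05,
    max_keep: int = 30,
    *,
    result: SelectionResult | None = None,
) -> list[str]:
    """Bidirectional stepwise selection on partial t-test p-values.

    Forward step adds the most significant excluded feature when its p-value
    is below ``alpha`` (alphabetical tie-break); backward step then removes
    included features whose p-value has risen to ``alpha`` or above, worst
    first.  Iterates to a fixed point, capped at ``max_keep`` features.
    Features that make the design singular are dropped with a warning.
    """
    y = np.asarray(y, dtype=float)
    names = sorted(X.columns)
    included: list[str] = []
    path = [] if result is None else result.stepwise_path
    banned: set[str] = set()

    changed = True
    while changed:
        changed = False
        # forward
        if len(included) < max_keep:
            best_p, best_f = np.inf, None
            for f in names:
                if f in included or f in banned:
                    continue
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        pvals = _ols_pvalues(X, y, included + [f])
                except Exception:
                    banned.add(f)
                    warnings.warn(f"feature {f!r} made the design singular; dropped")
                    continue
                p = pvals[f]
                if not np.isfinite(p):
                    banned.add(f)
                    warnings.warn(f"feature {f!r} made the design singular; dropped")
                    continue
                if p < best_p - 1e-15 or (abs(p - best_p) <= 1e-15 and f < (best_f or "~")):
                    best_p, best_f = p, f
            if best_f is not None and best_p < alpha:
                included.append(best_f)
                path.append(("add", best_f, float(best_p)))
                changed = True
        # backward
        while len(included) > 1:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pvals = _ols_pvalues(X, y, included)
            worst = pvals.idxmax()
            if pvals[worst] >= alpha:
                included.remove(worst)
                path.append(("drop", worst, float(pvals[worst])))
                changed = True
            else:
                break
    return included


def gaussian_aic(X: np.ndarray, y: np.ndarray) -> float:
    """AIC of the Gaussian MLE linear fit: 2k - 2 max log-likelihood.

    k counts the intercept, the slopes and the residual variance.  Closed
    form from the residual sum of squares:
    AIC = n log(2 pi RSS / n) + n + 2k.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    design = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    rss = float(((y - design @ coef) ** 2).sum())
    if rss <= 0:
        rss = np.finfo(float).tiny
    k = design.shape[1] + 1  # + residual variance
    return n * np.log(2 * np.pi * rss / n) + n + 2 * k


def exhaustive_aic(
    X: pd.DataFrame,
    y: np.ndarray,
    *,
    train_indices: np.ndarray | None = None,
    tie_window: float = 2.0,
    max_features: int = 20,
    result: SelectionResult | None = None,
) -> SelectionResult:
    """Fit every covariate subset on the training split; pick by AIC.

    Among models whose AIC lies within ``tie_window`` of the minimum, the
    chosen model is the one with the fewest covariates, breaking remaining
    ties alphabetically on the sorted feature tuple.  Subsets that leave no
    residual degrees of freedom are skipped and logged.
    """
    names = sorted(X.columns)
    if len(names) > max_features:
        raise ValueError(f"{len(names)} candidate features exceed the 2^{max_features} cap")
    y = np.asarray(y, dtype=float)
    if train_indices is None:
        train_indices = np.arange(len(y))
    Xt = X.iloc[train_indices]
    yt = y[train_indices]
    n = len(yt)

    res = result if result is not None else SelectionResult(kept_features=list(names))
    res.candidate_models = []
    res.skipped_subsets = []
    for size in range(len(names) + 1):
        for subset in itertools.combinations(names, size):
            k = size + 2  # intercept + slopes + variance
            if n <= k:
                res.skipped_subsets.append(subset)
                continue
            aic = gaussian_aic(Xt[list(subset)].to_numpy(), yt)
            res.candidate_models.append((subset, aic))
    if not res.candidate_models:
        raise ValueError("no estimable subset (training set too small)")
    best_aic = min(a for _, a in res.candidate_models)
    in_window = [
        (len(fs), tuple(sorted(fs)), a) for fs, a in res.candidate_models if a <= best_aic + tie_window
    ]
    in_window.sort(key=lambda t: (t[0], t[1]))
    res.chosen_model = in_window[0][1]
    res.train_indices = np.asarray(train_indices)
    return res


def split_train_test(
    n: int,
    fraction: float = 0.8,
    seed: int = 0,
    strata: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Random train/test partition, optionally stratified, seeded.

    |train| = round(fraction * n) overall (per stratum when stratified).
    """
    if n < 5:
        raise ValueError("need n >= 5 to split")
    rng = np.random.default_rng(seed)
    if strata is None:
        perm = rng.permutation(n)
        k = int(round(fraction * n))
        return np.sort(perm[:k]), np.sort(perm[k:])
    strata = np.asarray(strata)
    train, test = [], []
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        perm = rng.permutation(len(idx))
        k = int(round(fraction * len(idx)))
        train.append(idx[perm[:k]])
        test.append(idx[perm[k:]])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))
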