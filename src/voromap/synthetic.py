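"""Synthetic study generator: tower geometry, covariates, ICAR field, outcomes.

Emulates the structure of a national poverty-mapping study built on mobile
towers: towers cluster tightly in a few urban centres and thin out over rural
space, so Voronoi cells are small in cities and large in the countryside.
Per-polygon covariates come in two flavours — smooth, spatially autocorrelated
"RS-like" layers (night lights, vegetation, access) and noisy "CDR-like"
aggregates (top-ups, call volumes).  Outcomes are generated from the same
likelihood the ICAR model fits:

    y_i = beta0 + x_i' beta + u_i + eps_i,   u ~ ICAR(tau_spatial R),
    eps_i ~ N(0, 1 / tau_noise),

with u constrained to sum to zero per connected component.  Three outcome
flavours mirror common poverty metrics: an unbounded asset-index score, a
percentage clamped to [0, 100], and a latent USD income reported through
ascending bins and re-expanded by bin midpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, box

from .aggregate import CovariateTable, OutcomeVector, log_transform
from .support import PolygonSupport, TowerSet, build_voronoi

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "sample_towers",
    "sample_covariates",
    "sample_icar_field",
    "generate_outcomes",
    "simulate_dataset",
]

# Default income bin edges in USD.  Income-bracket questionnaires typically
# publish only the overall range (here 0-1285 USD), not the edges, so edges
# are a config parameter; these defaults use roughly geometric spacing.
DEFAULT_INCOME_EDGES = (0.0, 50.0, 100.0, 200.0, 400.0, 800.0, 1285.0)


@dataclass
class SyntheticConfig:
    """Generating parameters for one synthetic study.

    Defaults describe the emulated study conditions: ~300 polygons with a
    2:1 rural:urban tower split around a few dense centres, three covariates
    (two RS-like, one CDR-like), moderate spatial autocorrelation and
    observation noise, and 85% of polygons carrying survey observations.
    """

    n_towers_urban: int = 100
    n_towers_rural: int = 200
    n_urban_centres: int = 3
    cluster_sd: float = 0.04
    boundary: Polygon = field(default_factory=lambda: box(0.0, 0.0, 1.0, 1.0))
    n_rs_features: int = 2
    n_cdr_features: int = 1
    beta: tuple = (0.5, 0.8, -0.6, 0.4)  # intercept first; outcome units per log-covariate unit
    tau_spatial: float = 4.0
    tau_noise: float = 25.0
    outcome_kind: str = "score"  # score | percentage | income_bins
    income_bin_edges: tuple = DEFAULT_INCOME_EDGES
    observed_fraction: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_towers_urban + self.n_towers_rural < 4:
            raise ValueError("need at least 4 towers in total")
        if self.tau_spatial <= 0 or self.tau_noise <= 0:
            raise ValueError("precisions must be positive")
        edges = np.asarray(self.income_bin_edges, dtype=float)
        if len(edges) < 2 or (np.diff(edges) <= 0).any() or edges[0] < 0:
            raise ValueError("income_bin_edges must be ascending with first edge >= 0")
        if self.outcome_kind not in ("score", "percentage", "income_bins"):
            raise ValueError(f"unknown outcome_kind {self.outcome_kind!r}")
        if self.boundary.area <= 0:
            raise ValueError("boundary must have positive area")
        if len(self.beta) != 1 + self.n_rs_features + self.n_cdr_features:
            raise ValueError("len(beta) must equal n covariates + 1 (intercept)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["boundary"] = shapely.geometry.mapping(self.boundary)
        d["beta"] = list(self.beta)
        d["income_bin_edges"] = list(self.income_bin_edges)
        return d


@dataclass
class SyntheticDataset:
    """One generated study: support, covariates, truth and observed outcomes."""

    towers: TowerSet
    support: PolygonSupport
    covariates: CovariateTable
    true_field: np.ndarray
    latent: np.ndarray
    outcomes: OutcomeVector
    strata: np.ndarray  # per-polygon "urban"/"rural"
    truth: dict
    clamp_fraction: float = 0.0


def sample_towers(config: SyntheticConfig) -> TowerSet:
    """Draw urban (Gaussian-cluster) and rural (uniform) tower locations.

    All points land strictly inside the boundary; cluster points falling
    outside are redrawn, and a configuration needing more than 1000 attempts
    for a point is rejected.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    bnd = config.boundary
    minx, miny, maxx, maxy = bnd.bounds

    def _uniform(n: int) -> np.ndarray:
        out = np.empty((n, 2))
        got = 0
        attempts = 0
        while got < n:
            if attempts > 1000 * max(n, 1):
                raise ValueError("boundary rejection sampling exceeded 1000 attempts per point")
            m = n - got
            cand = np.column_stack(
                [rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)]
            )
            ok = shapely.contains_xy(bnd, cand[:, 0], cand[:, 1])
            k = int(ok.sum())
            out[got : got + k] = cand[ok]
            got += k
            attempts += m
        return out

    pts = []
    if config.n_towers_urban > 0:
        if config.n_urban_centres < 1:
            raise ValueError("urban towers requested but no urban centres")
        centres = _uniform(config.n_urban_centres)
        which = rng.integers(0, config.n_urban_centres, config.n_towers_urban)
        for i in range(config.n_towers_urban):
            for attempt in range(1001):
                if attempt == 1000:
                    raise ValueError(
                        "cluster scale forces >1000 resampling attempts inside boundary"
                    )
                p = centres[which[i]] + rng.normal(scale=config.cluster_sd, size=2)
                if shapely.contains_xy(bnd, p[0], p[1]):
                    pts.append(p)
                    break
    if config.n_towers_rural > 0:
        pts.extend(_uniform(config.n_towers_rural))
    return TowerSet(points=np.asarray(pts), crs_note="planar-synthetic")


def tower_strata(config: SyntheticConfig) -> np.ndarray:
    """Stratum label per tower: urban towers come first in ``sample_towers``."""
    return np.array(
        ["urban"] * config.n_towers_urban + ["rural"] * config.n_towers_rural
    )


def sample_covariates(
    support: PolygonSupport,
    *,
    n_rs: int = 2,
    n_cdr: int = 1,
    seed: int = 0,
    cdr_noise_sd: float = 0.8,
) -> CovariateTable:
    """Positive-valued per-polygon covariates with controllable smoothness.

    RS-like features are smooth low-frequency surfaces of the cell centroid
    (mixtures of a few random sinusoids) with little noise; CDR-like features
    share a weaker spatial signal buried in heavy lognormal noise.  Values are
    exponentiated so the downstream log transform is meaningful.
    """
    rng = np.random.default_rng(seed)
    cents = np.array([[p.centroid.x, p.centroid.y] for p in support.polygons])
    span = cents.max(0) - cents.min(0)
    span[span == 0] = 1.0
    u = (cents - cents.min(0)) / span  # unit-square coords

    def _smooth_surface() -> np.ndarray:
        z = np.zeros(len(u))
        for _ in range(3):
            freq = rng.uniform(0.5, 2.0, 2)
            phase = rng.uniform(0, 2 * np.pi, 2)
            amp = rng.normal(scale=0.6)
            z += amp * np.sin(2 * np.pi * freq[0] * u[:, 0] + phase[0]) * np.sin(
                2 * np.pi * freq[1] * u[:, 1] + phase[1]
            )
        return z

    data, fclass = {}, {}
    for k in range(n_rs):
        name = f"rs_{k}"
        data[name] = np.exp(_smooth_surface() + rng.normal(scale=0.1, size=len(u)))
        fclass[name] = "rs"
    for k in range(n_cdr):
        name = f"cdr_{k}"
        data[name] = np.exp(
            0.5 * _smooth_surface() + rng.normal(scale=cdr_noise_sd, size=len(u))
        )
        fclass[name] = "cdr"
    table = CovariateTable(values=pd.DataFrame(data), feature_class=fclass)
    return table


def sample_icar_field(
    support: PolygonSupport,
    tau_spatial: float,
    seed: int | np.random.Generator = 0,
    *,
    islands: str = "constrain-to-zero",
) -> np.ndarray:
    """Draw one ICAR field under the per-component sum-to-zero constraint.

    Sampling is constructive: per connected component, eigendecompose the
    structure-matrix block, drop the null eigenvector (the constant), and
    scale independent normals by 1/sqrt(tau * lambda) along the remaining
    eigenvectors — i.e. a draw from the pseudo-inverse covariance restricted
    to the sum-to-zero subspace.  Isolated polygons get exactly zero under
    the default islands policy, and raise otherwise.
    """
    if tau_spatial <= 0:
        raise ValueError("tau_spatial must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    R = support.structure_matrix
    if R is None:
        raise ValueError("structure matrix not built")
    x = np.zeros(support.n_polygons)
    for c in range(support.n_components):
        idx = np.flatnonzero(support.components == c)
        if len(idx) == 1:
            if islands != "constrain-to-zero":
                raise ValueError(
                    f"isolated polygon {int(idx[0])} and islands policy {islands!r}"
                )
            continue
        sub = R[np.ix_(idx, idx)].toarray()
        w, V = np.linalg.eigh(sub)
        pos = w > w.max() * 1e-10
        z = rng.standard_normal(int(pos.sum()))
        xc = V[:, pos] @ (z / np.sqrt(tau_spatial * w[pos]))
        x[idx] = xc - xc.mean()  # exact sum-to-zero against round-off
    return x


def generate_outcomes(
    support: PolygonSupport,
    covariates: CovariateTable,
    fieldvals: np.ndarray,
    config: SyntheticConfig,
    *,
    rng: np.random.Generator | None = None,
    observed_mask: np.ndarray | None = None,
) -> tuple[OutcomeVector, np.ndarray, float]:
    """Outcomes from the linear predictor + field + Gaussian noise.

    Returns (outcomes, latent, clamp_fraction).  ``percentage`` outcomes are
    clamped to [0, 100]; ``income_bins`` latent USD values are binned by
    ``config.income_bin_edges`` and re-expanded by bin midpoints (values
    beyond the last edge fall in the top bin).
    """
    X = covariates.design_matrix()
    beta = np.asarray(config.beta, dtype=float)
    if X.shape[1] + 1 != len(beta):
        raise ValueError(
            f"design has {X.shape[1]} columns but beta has {len(beta) - 1} slopes"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = support.n_polygons
    eps = rng.normal(scale=1.0 / np.sqrt(config.tau_noise), size=n)
    latent = beta[0] + X @ beta[1:] + np.asarray(fieldvals) + eps

    clamp_fraction = 0.0
    if config.outcome_kind == "percentage":
        clamped = np.clip(latent, 0.0, 100.0)
        clamp_fraction = float(np.mean(clamped != latent))
        values = clamped
        kind = "percentage"
    elif config.outcome_kind == "income_bins":
        values = bin_to_midpoint(latent, np.asarray(config.income_bin_edges))
        kind = "income"
    else:
        values = latent.copy()
        kind = "score"

    if observed_mask is None:
        n_obs = max(1, int(round(config.observed_fraction * n)))
        obs_idx = rng.choice(n, size=n_obs, replace=False)
        observed_mask = np.zeros(n, dtype=bool)
        observed_mask[obs_idx] = True
    vals = np.where(observed_mask, values, np.nan)
    outcomes = OutcomeVector(
        values=vals, n_points=observed_mask.astype(int), kind=kind
    )
    return outcomes, latent, clamp_fraction


def bin_to_midpoint(latent_usd: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Report a latent USD amount through income bins re-expanded by midpoints."""
    mids = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.searchsorted(edges, latent_usd, side="right") - 1, 0, len(mids) - 1)
    return mids[idx]


def simulate_dataset(config: SyntheticConfig, *, scale_R: bool = True) -> SyntheticDataset:
    """End-to-end generation: towers -> Voronoi -> covariates -> field -> outcomes.

    Covariates are log-transformed before entering the linear predictor, so
    ``config.beta`` is in outcome units per log-covariate unit — the same
    design the fitting stage sees.  Bit-deterministic given the config.
    """
    towers = sample_towers(config)
    support = build_voronoi(towers, config.boundary, scale=scale_R)
    raw = sample_covariates(
        support,
        n_rs=config.n_rs_features,
        n_cdr=config.n_cdr_features,
        seed=config.seed + 10,
    )
    covs = log_transform(raw)
    rng = np.random.default_rng(config.seed + 1)
    fieldvals = sample_icar_field(support, config.tau_spatial, rng)
    outcomes, latent, clamp_fraction = generate_outcomes(
        support, covs, fieldvals, config, rng=rng
    )
    return SyntheticDataset(
        towers=towers,
        support=support,
        covariates=covs,
        true_field=fieldvals,
        latent=latent,
        outcomes=outcomes,
        strata=tower_strata(config),
        truth={
            "beta": list(config.beta),
            "tau_spatial": config.tau_spatial,
            "tau_noise": config.tau_noise,
            "outcome_kind": config.outcome_kind,
        },
        clamp_fraction=clamp_fraction,
    )
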