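"""Align survey points, raster grids and tabular features to the polygon support.

Survey outcomes (wealth-index scores, poverty-likelihood percentages, USD
incomes) arrive as georeferenced points and are averaged per polygon.
Covariate layers arrive either as per-polygon tables or as rasters, which are
summarized zonally (mean / sum / mode of the raster cells whose centres fall
in each polygon).  Covariates are log-transformed before modelling; zeros are
handled with a half-minimum-positive offset recorded per feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.strtree import STRtree

from .support import PolygonSupport

__all__ = [
    "CovariateTable",
    "OutcomeVector",
    "assign_points_to_polygons",
    "zonal_summarize",
    "log_transform",
    "locate_points",
]


@dataclass
class CovariateTable:
    """Per-polygon design table with feature provenance and transform state.

    values : DataFrame, one row per polygon, one column per feature.
    feature_class : per-feature tag, "rs" (remote-sensing-like, smooth) or
        "cdr" (call-detail-record-like, noisy).
    transform : "none" or "log"; log_offsets records the delta used.
    generalizability_rank : lower = preferred when pruning collinear pairs.
    """

    values: pd.DataFrame
    feature_class: dict[str, str] = field(default_factory=dict)
    transform: dict[str, str] = field(default_factory=dict)
    summary_rule: dict[str, str] = field(default_factory=dict)
    generalizability_rank: dict[str, int] = field(default_factory=dict)
    log_offsets: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.values.columns:
            self.feature_class.setdefault(name, "rs")
            self.transform.setdefault(name, "none")
            self.summary_rule.setdefault(name, "mean")
            self.generalizability_rank.setdefault(name, 0)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def design_matrix(self, features: list[str] | None = None) -> np.ndarray:
        cols = features if features is not None else self.feature_names
        return self.values[cols].to_numpy(dtype=float)

    def subset(self, features: list[str]) -> "CovariateTable":
        return CovariateTable(
            values=self.values[features].copy(),
            feature_class={f: self.feature_class[f] for f in features},
            transform={f: self.transform[f] for f in features},
            summary_rule={f: self.summary_rule[f] for f in features},
            generalizability_rank={f: self.generalizability_rank[f] for f in features},
            log_offsets={f: v for f, v in self.log_offsets.items() if f in features},
        )


@dataclass
class OutcomeVector:
    """Per-polygon aggregated outcome; NaN where no survey point contributed."""

    values: np.ndarray
    n_points: np.ndarray
    kind: str = "score"  # score | percentage | income

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.n_points = np.asarray(self.n_points, dtype=int)
        if self.kind not in ("score", "percentage", "income"):
            raise ValueError(f"unknown outcome kind {self.kind!r}")
        obs = self.n_points >= 1
        if np.isnan(self.values[obs]).any() or not np.isnan(self.values[~obs]).all():
            raise ValueError("values must be present exactly where n_points >= 1")
        if self.kind == "percentage":
            v = self.values[obs]
            if ((v < 0) | (v > 100)).any():
                raise ValueError("percentage outcomes must lie in [0, 100]")

    @property
    def observed(self) -> np.ndarray:
        return self.n_points >= 1


def locate_points(xy: np.ndarray, support: PolygonSupport, *, strict: bool = True) -> np.ndarray:
    """Polygon index for each point; ties on shared edges go to the lower index.

    Returns -1 for points outside every polygon when ``strict`` is False;
    with ``strict`` those points raise an error listing their indices.
    """
    xy = np.asarray(xy, dtype=float)
    pts = shapely.points(xy[:, 0], xy[:, 1])
    tree = STRtree(support.polygons)
    pt_row, poly_row = tree.query(pts, predicate="intersects")  # (input idx, tree idx)
    assign = np.full(len(xy), -1, dtype=int)
    for a, b in zip(pt_row, poly_row):
        i_pt, i_poly = int(a), int(b)
        if assign[i_pt] == -1 or i_poly < assign[i_pt]:
            assign[i_pt] = i_poly
    if strict and (assign == -1).any():
        bad = np.flatnonzero(assign == -1).tolist()
        raise ValueError(f"points outside the polygon support at indices {bad}")
    return assign


def assign_points_to_polygons(
    xy: np.ndarray,
    values: np.ndarray,
    support: PolygonSupport,
    *,
    kind: str = "score",
) -> OutcomeVector:
    """Mean-aggregate point outcomes per polygon (survey points -> areal outcome)."""
    values = np.asarray(values, dtype=float)
    assign = locate_points(xy, support, strict=True)
    n = support.n_polygons
    counts = np.bincount(assign, minlength=n)
    sums = np.bincount(assign, weights=values, minlength=n)
    out = np.full(n, np.nan)
    obs = counts >= 1
    out[obs] = sums[obs] / counts[obs]
    return OutcomeVector(values=out, n_points=counts, kind=kind)


def zonal_summarize(
    grid: np.ndarray,
    transform: tuple[float, float, float, float, float, float],
    support: PolygonSupport,
    rule: str = "mean",
    *,
    nodata: float | None = None,
    grid_crs_note: str | None = None,
) -> pd.Series:
    """Per-polygon statistic of raster cells whose centres fall in the polygon.

    ``transform`` is the GDAL-style affine (a, b, c, d, e, f):
    x = a*(col+0.5) + b*(row+0.5) + c, y = d*(col+0.5) + e*(row+0.5) + f.
    Nodata cells are excluded.  Polygons covered by no cell centre get NaN
    (their count is reported in a warning).  For ``rule="mode"`` ties are
    broken toward the smaller class value.
    """
    if rule not in ("mean", "sum", "mode"):
        raise ValueError(f"unknown rule {rule!r}")
    if grid_crs_note is not None and grid_crs_note != support.towers.crs_note:
        raise ValueError(
            f"CRS mismatch: raster {grid_crs_note!r} vs support {support.towers.crs_note!r}"
        )
    grid = np.asarray(grid, dtype=float)
    a, b, c, d, e, f = transform
    nrow, ncol = grid.shape
    rows, cols = np.mgrid[0:nrow, 0:ncol]
    xs = a * (cols + 0.5) + b * (rows + 0.5) + c
    ys = d * (cols + 0.5) + e * (rows + 0.5) + f
    vals = grid.ravel()
    xs, ys = xs.ravel(), ys.ravel()
    keep = np.isfinite(vals)
    if nodata is not None:
        keep &= vals != nodata
    assign = locate_points(np.column_stack([xs[keep], ys[keep]]), support, strict=False)
    vals = vals[keep][assign >= 0]
    assign = assign[assign >= 0]

    n = support.n_polygons
    out = np.full(n, np.nan)
    if rule == "mean":
        counts = np.bincount(assign, minlength=n)
        sums = np.bincount(assign, weights=vals, minlength=n)
        got = counts >= 1
        out[got] = sums[got] / counts[got]
    elif rule == "sum":
        got = np.bincount(assign, minlength=n) >= 1
        out[got] = np.bincount(assign, weights=vals, minlength=n)[got]
    else:  # mode
        df = pd.DataFrame({"poly": assign, "val": vals})
        for poly, sub in df.groupby("poly"):
            counts = sub["val"].value_counts()
            top = counts.max()
            out[poly] = min(v for v, k in counts.items() if k == top)
    n_missing = int(np.isnan(out).sum())
    if n_missing:
        warnings.warn(f"{n_missing} polygons have no raster coverage")
    return pd.Series(out, name=rule)


def log_transform(
    table: CovariateTable,
    features: list[str] | None = None,
) -> CovariateTable:
    """Log-transform features for normality: x -> log(x + delta).

    delta = 0 when min(x) > 0, else half the smallest positive value
    (recorded per feature).  An all-zero/negative feature cannot be
    transformed and raises.  Features already tagged "log" are skipped.
    """
    out = table.subset(table.feature_names)
    todo = features if features is not None else out.feature_names
    for name in todo:
        if out.transform.get(name) == "log":
            continue
        x = out.values[name].to_numpy(dtype=float)
        finite = x[np.isfinite(x)]
        if finite.min() > 0:
            delta = 0.0
        else:
            pos = finite[finite > 0]
            if len(pos) == 0:
                raise ValueError(f"feature {name!r} has no positive values; cannot log-transform")
            delta = 0.5 * pos.min()
        if (finite + delta <= 0).any():
            raise ValueError(f"feature {name!r} has values <= -delta; cannot log-transform")
        out.values[name] = np.log(x + delta)
        out.transform[name] = "log"
        out.log_offsets[name] = delta
    return out
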