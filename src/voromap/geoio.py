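"""Standard-format I/O: GeoJSON geometries, CSV tables, Matrix-Market, YAML.

Geometries travel as GeoJSON FeatureCollections (text, diffable), the sparse
Besag structure matrix as a Matrix-Market file, tabular data as CSV and
configuration as YAML.  Every artifact directory gets a manifest with SHA-256
checksums and the config hash so outputs from different configs never mix
silently.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp
import yaml
from shapely.geometry import mapping, shape

from .aggregate import CovariateTable, OutcomeVector
from .support import PolygonSupport, TowerSet, build_adjacency, build_structure_matrix

__all__ = [
    "write_towers_geojson", "read_towers_geojson",
    "write_polygons_geojson", "read_polygons_geojson",
    "write_edges_csv", "read_edges_csv",
    "write_structure_matrix", "read_structure_matrix",
    "write_covariates_csv", "read_covariates_csv",
    "write_outcomes_csv", "read_outcomes_csv",
    "write_yaml", "read_yaml",
    "write_json", "config_hash", "write_manifest",
]

MAX_GEOGRAPHIC_SPAN_DEG = 6.0  # wider lon/lat boundaries must be projected first


def check_planar(bounds: tuple, crs_note: str) -> None:
    """Refuse boundaries that look like wide unprojected lon/lat extents."""
    minx, miny, maxx, maxy = bounds
    looks_geographic = "lon" in crs_note.lower() or "wgs84" in crs_note.lower() or crs_note == "EPSG:4326"
    if looks_geographic and (maxx - minx > MAX_GEOGRAPHIC_SPAN_DEG):
        raise ValueError(
            "boundary spans more than 6 degrees of longitude in a geographic CRS; "
            "project to planar coordinates first"
        )


# ----------------------------------------------------------------- geometries
def write_towers_geojson(path, towers: TowerSet) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
            "properties": {"tower_id": i},
        }
        for i, (x, y) in enumerate(towers.points)
    ]
    fc = {
        "type": "FeatureCollection",
        "features": features,
        "crs_note": towers.crs_note,
    }
    Path(path).write_text(json.dumps(fc, sort_keys=True))


def read_towers_geojson(path) -> TowerSet:
    fc = json.loads(Path(path).read_text())
    feats = sorted(fc["features"], key=lambda f: f["properties"].get("tower_id", 0))
    pts = np.array([f["geometry"]["coordinates"] for f in feats], dtype=float)
    return TowerSet(points=pts, crs_note=fc.get("crs_note", "planar"))


def write_polygons_geojson(path, polygons: list, properties: pd.DataFrame | None = None,
                           crs_note: str = "planar") -> None:
    features = []
    for i, poly in enumerate(polygons):
        props = {"polygon_id": i}
        if properties is not None:
            for col in properties.columns:
                v = properties.iloc[i][col]
                props[col] = None if (isinstance(v, float) and np.isnan(v)) else (
                    float(v) if isinstance(v, (int, float, np.floating, np.integer)) else v
                )
        features.append(
            {"type": "Feature", "geometry": mapping(poly), "properties": props}
        )
    fc = {"type": "FeatureCollection", "features": features, "crs_note": crs_note}
    Path(path).write_text(json.dumps(fc, sort_keys=True))


def read_polygons_geojson(path) -> tuple[list, pd.DataFrame]:
    fc = json.loads(Path(path).read_text())
    feats = sorted(fc["features"], key=lambda f: f["properties"]["polygon_id"])
    polys = [shape(f["geometry"]) for f in feats]
    props = pd.DataFrame([f["properties"] for f in feats])
    return polys, props


def write_boundary_geojson(path, boundary, crs_note: str = "planar") -> None:
    Path(path).write_text(
        json.dumps(
            {"type": "Feature", "geometry": mapping(boundary),
             "properties": {}, "crs_note": crs_note},
            sort_keys=True,
        )
    )


def read_boundary_geojson(path):
    obj = json.loads(Path(path).read_text())
    geom = obj["geometry"] if obj.get("type") == "Feature" else obj
    bnd = shape(geom)
    check_planar(bnd.bounds, obj.get("crs_note", "planar"))
    return bnd


# ---------------------------------------------------------------- graph parts
def write_edges_csv(path, support: PolygonSupport) -> None:
    pd.DataFrame(support.adjacency, columns=["i", "j"]).to_csv(path, index=False)


def read_edges_csv(path) -> list[tuple[int, int]]:
    df = pd.read_csv(path)
    return [(int(i), int(j)) for i, j in zip(df["i"], df["j"])]


def write_structure_matrix(path, support: PolygonSupport) -> None:
    sio.mmwrite(str(path), sp.coo_matrix(support.structure_matrix))


def read_structure_matrix(path) -> sp.csr_matrix:
    return sp.csr_matrix(sio.mmread(str(path)))


def load_support(towers_path, boundary_path, polygons_path, *, scale: bool = True) -> PolygonSupport:
    towers = read_towers_geojson(towers_path)
    boundary = read_boundary_geojson(boundary_path)
    polys, _ = read_polygons_geojson(polygons_path)
    support = PolygonSupport(towers=towers, polygons=polys, boundary=boundary)
    build_adjacency(support)
    build_structure_matrix(support, scale=scale)
    return support


# -------------------------------------------------------------------- tables
def write_covariates_csv(path, table: CovariateTable) -> None:
    df = table.values.copy()
    df.insert(0, "polygon_id", np.arange(len(df)))
    df.to_csv(path, index=False)
    meta = {
        "feature_class": table.feature_class,
        "transform": table.transform,
        "summary_rule": table.summary_rule,
        "generalizability_rank": table.generalizability_rank,
        "log_offsets": table.log_offsets,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, sort_keys=True))


def read_covariates_csv(path) -> CovariateTable:
    df = pd.read_csv(path).drop(columns=["polygon_id"])
    meta_path = Path(str(path) + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return CovariateTable(
        values=df,
        feature_class=meta.get("feature_class", {}),
        transform=meta.get("transform", {}),
        summary_rule=meta.get("summary_rule", {}),
        generalizability_rank=meta.get("generalizability_rank", {}),
        log_offsets=meta.get("log_offsets", {}),
    )


def write_outcomes_csv(path, outcome: OutcomeVector) -> None:
    pd.DataFrame(
        {
            "polygon_id": np.arange(len(outcome.values)),
            "value": outcome.values,
            "n_points": outcome.n_points,
            "kind": outcome.kind,
        }
    ).to_csv(path, index=False)


def read_outcomes_csv(path) -> OutcomeVector:
    df = pd.read_csv(path)
    return OutcomeVector(
        values=df["value"].to_numpy(dtype=float),
        n_points=df["n_points"].to_numpy(dtype=int),
        kind=str(df["kind"].iloc[0]),
    )


# --------------------------------------------------------------- config et al.
def write_yaml(path, obj: dict) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_json(path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=2, allow_nan=True))


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_manifest(outdir, config: dict, inputs: list[str | Path]) -> None:
    checksums = {}
    for p in inputs:
        p = Path(p)
        if p.exists():
            checksums[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    write_json(
        Path(outdir) / "manifest.json",
        {"config_hash": config_hash(config), "config": config, "checksums": checksums},
    )
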