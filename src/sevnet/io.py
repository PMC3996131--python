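"""Readers and writers for the formats the pipeline touches.

Networks and areal units travel as GeoJSON (RFC 7946 structure, but with
projected metric coordinates); link-metric tables and unit outcomes as
CSV with a header row.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Hashable, Iterable

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .network import ArealUnit, SpatialNetwork, build_network, DEFAULT_SNAP_TOLERANCE_M

__all__ = [
    "read_network_geojson",
    "write_network_geojson",
    "read_units_geojson",
    "write_units_geojson",
    "read_outcomes_csv",
    "write_outcomes_csv",
    "write_metrics_csv",
    "read_metrics_csv",
    "attach_outcomes",
]

OUTCOME_COLUMNS = ("cohesion", "deprivation", "urban")


def _feature_id(feature: dict, fallback: int) -> Hashable:
    props = feature.get("properties") or {}
    if "id" in props:
        return props["id"]
    if "id" in feature:
        return feature["id"]
    return fallback


def read_network_geojson(
    path, snap_tolerance_m: float = DEFAULT_SNAP_TOLERANCE_M
) -> SpatialNetwork:
    """Read a LineString FeatureCollection into a :class:`SpatialNetwork`.

    MultiLineString features are split into their parts with derived ids
    (``<id>#<part>``) and a warning, a common dialect in exported road data.
    """
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a FeatureCollection")
    features = []
    for k, feat in enumerate(gj.get("features", [])):
        geom = feat.get("geometry") or {}
        gtype = geom.get("type")
        fid = _feature_id(feat, k)
        if gtype == "LineString":
            features.append((fid, geom["coordinates"]))
        elif gtype == "MultiLineString":
            warnings.warn(
                f"feature {fid!r}: MultiLineString split into "
                f"{len(geom['coordinates'])} parts",
                stacklevel=2,
            )
            for p, part in enumerate(geom["coordinates"]):
                features.append((f"{fid}#{p}", part))
        else:
            raise ValueError(f"feature {fid!r}: unsupported geometry type {gtype}")
    return build_network(features, snap_tolerance_m=snap_tolerance_m)


def write_network_geojson(net: SpatialNetwork, path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"id": lid},
            "geometry": {
                "type": "LineString",
                "coordinates": [list(map(float, p)) for p in link.geometry.points],
            },
        }
        for lid, link in sorted(net.links.items(), key=lambda kv: str(kv[0]))
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_units_geojson(path) -> list[ArealUnit]:
    """Read Polygon (or MultiPolygon) areal units; attributes via CSV, not here."""
    with open(path) as fh:
        gj = json.load(fh)
    units = []
    for k, feat in enumerate(gj.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") not in ("Polygon", "MultiPolygon"):
            raise ValueError(
                f"unit feature {k}: unsupported geometry type {geom.get('type')}"
            )
        poly = shape(geom)
        if poly.is_empty or not poly.is_valid:
            raise ValueError(f"unit feature {k}: invalid or empty polygon")
        units.append(ArealUnit(id=_feature_id(feat, k), polygon=poly))
    ids = [u.id for u in units]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate unit ids")
    return units


def write_units_geojson(units: Iterable[ArealUnit], path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"id": u.id},
            "geometry": mapping(u.polygon),
        }
        for u in units
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_outcomes_csv(path) -> pd.DataFrame:
    """Unit outcomes table: unit_id, cohesion, deprivation, urban."""
    df = pd.read_csv(path)
    if "unit_id" not in df.columns:
        raise ValueError("outcomes CSV missing required column 'unit_id'")
    for col in OUTCOME_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"outcomes CSV missing required column {col!r}")
    if df["unit_id"].duplicated().any():
        raise ValueError("outcomes CSV has duplicate unit_id values")
    return df


def write_outcomes_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def attach_outcomes(units: list[ArealUnit], outcomes: pd.DataFrame) -> list[ArealUnit]:
    """Join the outcomes table onto units by id (all units must be covered)."""
    table = outcomes.set_index("unit_id")
    for u in units:
        if u.id not in table.index:
            raise ValueError(f"unit {u.id!r} missing from outcomes table")
        row = table.loc[u.id]
        u.attributes.update({c: row[c] for c in OUTCOME_COLUMNS})
    return units


def write_metrics_csv(rows: pd.DataFrame, path) -> None:
    """Link-metric table: link_id, radius_m, then the 16 metric columns."""
    rows.to_csv(path, index=False)


def read_metrics_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("link_id", "radius_m"):
        if col not in df.columns:
            raise ValueError(f"metrics CSV missing required column {col!r}")
    return df
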