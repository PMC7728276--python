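"""Plain-text artifact I/O: GeoJSON feature collections, GAL weights and the
CSV schemas shared across pipeline stages."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from shapely.geometry import shape
from shapely.geometry import mapping as shapely_mapping
from shapely.geometry.base import BaseGeometry

__all__ = [
    "write_geojson",
    "read_geojson",
    "write_run_meta",
    "config_hash",
]


def write_geojson(
    path: str | Path,
    polygons: Sequence[BaseGeometry],
    ids: Sequence[str],
    properties: Mapping[str, Sequence] | None = None,
) -> None:
    """FeatureCollection with an "id" property per feature plus any extra
    property columns; raises listing orphans on an id/geometry mismatch."""
    if len(polygons) != len(ids):
        longer = ids[len(polygons):] or [f"<geometry {i}>" for i in
                                         range(len(ids), len(polygons))]
        raise ValueError(
            f"geometry/id mismatch: {len(polygons)} geometries vs {len(ids)} "
            f"ids; orphans: {list(longer)[:10]}"
        )
    props = dict(properties or {})
    for key, col in props.items():
        if len(col) != len(ids):
            raise ValueError(f"property {key!r} has {len(col)} values for "
                             f"{len(ids)} features")
    features = []
    for i, (poly, fid) in enumerate(zip(polygons, ids)):
        prop = {"id": fid}
        for key, col in props.items():
            v = col[i]
            prop[key] = v.item() if hasattr(v, "item") else v
        features.append(
            {
                "type": "Feature",
                "geometry": shapely_mapping(poly),
                "properties": prop,
            }
        )
    fc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(fc))


def read_geojson(path: str | Path) -> tuple[list[BaseGeometry], pd.DataFrame]:
    """Returns (geometries, properties table).  A malformed file raises with
    the file name and parse position."""
    text = Path(path).read_text()
    try:
        fc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(
            f"{path}: invalid GeoJSON at position {exc.pos} "
            f"(line {exc.lineno}, column {exc.colno}): {exc.msg}"
        ) from exc
    if fc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a FeatureCollection")
    geoms, props = [], []
    for feat in fc["features"]:
        geoms.append(shape(feat["geometry"]))
        props.append(feat.get("properties", {}))
    return geoms, pd.DataFrame(props)


def config_hash(payload: Mapping) -> str:
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_run_meta(
    outdir: str | Path, stage: str, seed: int, cfg_hash: str, counts: Mapping[str, int]
) -> None:
    """Sidecar recording config hash, seed and per-artifact row counts for
    every file a stage writes (one run_meta.json per output directory)."""
    path = Path(outdir) / "run_meta.json"
    meta = {}
    if path.exists():
        meta = json.loads(path.read_text())
    meta[stage] = {"seed": seed, "config_hash": cfg_hash, "artifacts": dict(counts)}
    path.write_text(json.dumps(meta, indent=2, sort_keys=True))
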