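"""Readers and writers for the pipeline's file formats.

Geometry comes in as GeoJSON (the natural OSM-extract carrier) or CSV with
WKT; results go out as CSV with fixed headers ("." decimal, UTF-8) so
regression diffs stay readable. Every writer emits a leading ``#`` comment
header carrying the seed and config hash; readers skip and preserve such
headers. P-median solutions and run manifests are JSON.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml
from shapely import wkt as shapely_wkt

from .allocation import PMedianSolution, solution_to_dict
from .network import RoadNetwork, make_segment
from .routing import CarePathResult, HealthFacility, PopulatedPlace, make_place


class LayerFormatError(ValueError):
    """Malformed input layer (bad geometry, duplicate ids, unknown enums)."""


# ---------------------------------------------------------------------------
# headers
# ---------------------------------------------------------------------------


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _header_lines(meta: dict | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in sorted(meta.items()))


def read_csv(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a CSV, tolerating leading ``#`` comment headers."""
    return pd.read_csv(path, comment="#", **kwargs)


def write_csv(df: pd.DataFrame, path: str | Path, meta: dict | None = None, **kwargs) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_header_lines(meta))
        df.to_csv(fh, **kwargs)


# ---------------------------------------------------------------------------
# road and point layers
# ---------------------------------------------------------------------------


def read_roads(path: str | Path) -> list[tuple[str, str, list[tuple[float, float]]]]:
    """Read road polylines from GeoJSON (LineString features with a
    ``highway`` property) or CSV (``segment_id,highway,wkt``)."""
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        data = json.loads(path.read_text())
        rows = []
        for i, feat in enumerate(data.get("features", [])):
            geom = feat.get("geometry") or {}
            if geom.get("type") != "LineString":
                raise LayerFormatError(f"feature {i}: expected LineString, got {geom.get('type')}")
            props = feat.get("properties") or {}
            if "highway" not in props:
                raise LayerFormatError(f"feature {i}: missing 'highway' property")
            sid = str(props.get("segment_id", props.get("id", f"R{i:05d}")))
            coords = [(float(x), float(y)) for x, y in geom["coordinates"]]
            rows.append((sid, str(props["highway"]), coords))
    else:
        df = read_csv(path, dtype={"segment_id": str})
        for col in ("segment_id", "highway", "wkt"):
            if col not in df.columns:
                raise LayerFormatError(f"roads CSV missing column {col!r}")
        rows = []
        for i, rec in df.iterrows():
            try:
                line = shapely_wkt.loads(rec["wkt"])
            except Exception as exc:
                raise LayerFormatError(f"row {i}: bad WKT: {exc}") from None
            if line.geom_type != "LineString":
                raise LayerFormatError(f"row {i}: expected LINESTRING, got {line.geom_type}")
            rows.append((str(rec["segment_id"]), str(rec["highway"]), list(line.coords)))
    _check_unique([r[0] for r in rows], "segment")
    return rows


def write_roads_csv(
    roads: Sequence[tuple[str, str, Sequence[tuple[float, float]]]],
    path: str | Path,
    meta: dict | None = None,
) -> None:
    from shapely.geometry import LineString

    df = pd.DataFrame(
        {
            "segment_id": [r[0] for r in roads],
            "highway": [r[1] for r in roads],
            "wkt": [LineString(r[2]).wkt for r in roads],
        }
    )
    write_csv(df, path, meta, index=False)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise LayerFormatError(f"duplicate {what} id {i!r}")
        seen.add(i)


def read_places(path: str | Path) -> list[PopulatedPlace]:
    """Read places from GeoJSON Points or CSV ``id,x,y,type[,population]``.

    A missing population is filled from the settlement-type default. Unknown
    types raise row-level errors.
    """
    rows = _read_points(path)
    places = []
    for i, rec in enumerate(rows):
        try:
            places.append(
                make_place(rec["id"], rec["x"], rec["y"], rec["type"], rec.get("population"))
            )
        except ValueError as exc:
            raise LayerFormatError(f"places row {i} (id={rec.get('id')!r}): {exc}") from None
    _check_unique([p.id for p in places], "place")
    return places


def read_facilities(path: str | Path) -> list[HealthFacility]:
    """Read facilities from GeoJSON Points or CSV ``id,x,y,type[,has_poct]``."""
    rows = _read_points(path)
    facs = []
    for i, rec in enumerate(rows):
        has_poct = str(rec.get("has_poct", "")).strip().lower() in ("1", "true", "yes")
        try:
            facs.append(
                HealthFacility(str(rec["id"]), float(rec["x"]), float(rec["y"]), str(rec["type"]), has_poct)
            )
        except ValueError as exc:
            raise LayerFormatError(f"facilities row {i} (id={rec.get('id')!r}): {exc}") from None
    _check_unique([f.id for f in facs], "facility")
    return facs


def _read_points(path: str | Path) -> list[dict]:
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        data = json.loads(path.read_text())
        rows = []
        for i, feat in enumerate(data.get("features", [])):
            geom = feat.get("geometry") or {}
            if geom.get("type") != "Point":
                raise LayerFormatError(f"feature {i}: expected Point, got {geom.get('type')}")
            props = dict(feat.get("properties") or {})
            x, y = geom["coordinates"][:2]
            rows.append({"id": props.pop("id", f"N{i:05d}"), "x": x, "y": y, **props})
        return rows
    df = read_csv(path, dtype={"id": str})
    for col in ("id", "x", "y", "type"):
        if col not in df.columns:
            raise LayerFormatError(f"points CSV missing column {col!r}")
    recs = df.to_dict("records")
    for rec in recs:
        if isinstance(rec.get("population"), float) and math.isnan(rec["population"]):
            rec["population"] = None
    return recs


def write_places_csv(places: Sequence[PopulatedPlace], path: str | Path, meta: dict | None = None) -> None:
    df = pd.DataFrame(
        [
            {"id": p.id, "x": p.x, "y": p.y, "type": p.place_type, "population": p.population}
            for p in places
        ]
    )
    write_csv(df, path, meta, index=False)


def write_facilities_csv(facs: Sequence[HealthFacility], path: str | Path, meta: dict | None = None) -> None:
    df = pd.DataFrame(
        [
            {"id": f.id, "x": f.x, "y": f.y, "type": f.kind, "has_poct": int(f.has_poct)}
            for f in facs
        ]
    )
    write_csv(df, path, meta, index=False)


def read_layers(
    roads_path: str | Path, places_path: str | Path, facilities_path: str | Path
) -> tuple[list, list[PopulatedPlace], list[HealthFacility]]:
    """Read and validate the three input layers."""
    return read_roads(roads_path), read_places(places_path), read_facilities(facilities_path)


# ---------------------------------------------------------------------------
# network serialization (junctions.csv + segments.csv)
# ---------------------------------------------------------------------------


def write_network(net: RoadNetwork, directory: str | Path, meta: dict | None = None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    jdf = pd.DataFrame(
        [{"id": j.id, "x": j.x, "y": j.y} for j in net.junctions.values()]
    ).sort_values("id")
    sdf = pd.DataFrame(
        [
            {
                "id": s.id,
                "u": s.u,
                "v": s.v,
                "class": s.highway_class,
                "length_m": s.length_m,
                "speed_mph": s.speed_mph,
                "travel_time_min": s.travel_time_min,
                "wkt": s.line.wkt,
            }
            for s in net.segments.values()
        ]
    ).sort_values("id")
    adf = pd.DataFrame(
        sorted(net.attachment.items()), columns=["point_id", "junction_id"]
    )
    write_csv(jdf, directory / "junctions.csv", meta, index=False)
    write_csv(sdf, directory / "segments.csv", meta, index=False)
    write_csv(adf, directory / "attachments.csv", meta, index=False)


def read_network(directory: str | Path) -> RoadNetwork:
    from shapely import wkt as _wkt

    directory = Path(directory)
    net = RoadNetwork()
    jdf = read_csv(directory / "junctions.csv", dtype={"id": str})
    for rec in jdf.to_dict("records"):
        net.add_junction(rec["x"], rec["y"], jid=rec["id"])
    sdf = read_csv(directory / "segments.csv", dtype={"id": str, "u": str, "v": str})
    for rec in sdf.to_dict("records"):
        coords = list(_wkt.loads(rec["wkt"]).coords)
        net.add_segment(
            make_segment(rec["id"], rec["u"], rec["v"], coords, rec["class"])
        )
    apath = directory / "attachments.csv"
    if apath.exists():
        adf = read_csv(apath, dtype=str)
        net.attachment.update(dict(zip(adf["point_id"], adf["junction_id"])))
    return net


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


def write_care_paths(paths: Sequence[CarePathResult], path: str | Path, meta: dict | None = None) -> None:
    df = pd.DataFrame(
        [
            {
                "origin_id": p.origin_id,
                "diag_id": p.diagnosis_facility_id,
                "t_diag_min": p.t_diag_min,
                "t_care_min": p.t_care_min,
                "t_total_min": p.t_total_min,
            }
            for p in paths
        ]
    )
    write_csv(df, path, meta, index=False)


def write_histogram(counts: Sequence[int], path: str | Path, meta: dict | None = None) -> None:
    df = pd.DataFrame(
        {"bin_start_min": [15 * i for i in range(len(counts))], "count": list(counts)}
    )
    write_csv(df, path, meta, index=False)


def write_solution(sol: PMedianSolution, path: str | Path, meta: dict | None = None) -> None:
    payload = solution_to_dict(sol)
    if meta:
        payload["meta"] = dict(sorted(meta.items()))
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_manifest(path: str | Path, inputs: dict, seed: int, config: dict) -> None:
    """Machine-readable run manifest: inputs, config hash, seed, versions."""
    import networkx, numpy, pandas, shapely

    from . import __version__

    payload = {
        "inputs": inputs,
        "seed": seed,
        "config": config,
        "config_hash": config_hash(config),
        "versions": {
            "scpath": __version__,
            "numpy": numpy.__version__,
            "pandas": pandas.__version__,
            "networkx": networkx.__version__,
            "shapely": shapely.__version__,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}
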