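"""Road-network construction for travel-time routing.

Builds a connected, undirected travel-time network from raw road polylines:
vertices within a snap tolerance are merged into shared junctions, each road
class carries an estimated speed, and off-network points (populated places,
health facilities) are attached through straight "connector" segments to the
nearest road segment.

Units are planar meters for coordinates and lengths, miles per hour for
speeds (as conventionally tabulated for OpenStreetMap road classes), and
minutes for travel time, converted with 1 mile = 1609.344 m.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import shapely
from shapely.geometry import LineString, Point
from shapely.ops import substring

logger = logging.getLogger(__name__)

METERS_PER_MILE = 1609.344

#: Estimated travel speed (mph) per OpenStreetMap highway class.
#: "connector" is the synthetic straight-line class used to join off-network
#: points (places, facilities) to the nearest road segment.
SPEED_TABLE_MPH: dict[str, float] = {
    "trunk": 65.0,
    "primary": 55.0,
    "secondary": 45.0,
    "tertiary": 30.0,
    "unclassified": 25.0,
    "residential": 25.0,
    "service": 15.0,
    "living_street": 25.0,
    "road": 35.0,
    "connector": 35.0,
}

CONNECTOR_CLASS = "connector"

#: Default snap tolerance (m) used when integrating raw road segments.
DEFAULT_SNAP_TOLERANCE_M = 10.0

#: Distance (m) below which a point is considered coincident with a junction.
COINCIDENCE_EPS_M = 1e-6


class NetworkConfigError(ValueError):
    """Raised for invalid road classes or malformed network inputs."""


def assign_speed(highway_class: str, speed_table: Mapping[str, float] | None = None) -> float:
    """Return the estimated speed in mph for a road class label.

    The label is case-normalized ("Living street" -> "living_street").
    Unknown labels raise :class:`NetworkConfigError` rather than defaulting,
    so data errors surface early.
    """
    table = SPEED_TABLE_MPH if speed_table is None else speed_table
    key = str(highway_class).strip().lower().replace(" ", "_").replace("-", "_")
    try:
        return float(table[key])
    except KeyError:
        raise NetworkConfigError(
            f"unknown highway class {highway_class!r}; known classes: {sorted(table)}"
        ) from None


def travel_time_min(length_m: float, speed_mph: float) -> float:
    """Travel time in minutes for ``length_m`` meters at ``speed_mph``."""
    return (length_m / METERS_PER_MILE) / speed_mph * 60.0


def _arc_length(coords: Sequence[tuple[float, float]]) -> float:
    a = np.asarray(coords, dtype=float)
    return float(np.sqrt(((a[1:] - a[:-1]) ** 2).sum(axis=1)).sum())


@dataclass(frozen=True)
class Junction:
    """A network node: where segments meet and where travel can change edges."""

    id: str
    x: float
    y: float

    @property
    def coord(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class RoadSegment:
    """An undirected network edge with geometry and travel-time weight."""

    id: str
    u: str  # junction id of one endpoint
    v: str  # junction id of the other endpoint
    geometry: tuple[tuple[float, float], ...]
    highway_class: str
    length_m: float
    speed_mph: float
    travel_time_min: float

    @property
    def line(self) -> LineString:
        return LineString(self.geometry)


def make_segment(
    seg_id: str,
    u: str,
    v: str,
    coords: Sequence[tuple[float, float]],
    highway_class: str,
    speed_table: Mapping[str, float] | None = None,
) -> RoadSegment:
    """Build a RoadSegment, deriving length, speed and travel time."""
    speed = assign_speed(highway_class, speed_table)
    length = _arc_length(coords)
    return RoadSegment(
        id=seg_id,
        u=u,
        v=v,
        geometry=tuple((float(x), float(y)) for x, y in coords),
        highway_class=highway_class,
        length_m=length,
        speed_mph=speed,
        travel_time_min=travel_time_min(length, speed),
    )


class RoadNetwork:
    """An undirected routable road network.

    Holds junctions, segments (possibly parallel between the same junction
    pair) and an ``attachment`` map from external point ids (places,
    facilities) to junction ids. No turn restrictions exist: travel may turn
    in any direction at any junction.
    """

    def __init__(self) -> None:
        self.junctions: dict[str, Junction] = {}
        self.segments: dict[str, RoadSegment] = {}
        self.attachment: dict[str, str] = {}
        self.graph = nx.MultiGraph()
        self._junction_seq = 0

    # -- construction -------------------------------------------------

    def _new_junction_id(self) -> str:
        jid = f"J{self._junction_seq}"
        self._junction_seq += 1
        return jid

    def add_junction(self, x: float, y: float, jid: str | None = None) -> str:
        if jid is None:
            jid = self._new_junction_id()
        if jid in self.junctions:
            raise NetworkConfigError(f"duplicate junction id {jid!r}")
        self.junctions[jid] = Junction(jid, float(x), float(y))
        self.graph.add_node(jid)
        return jid

    def add_segment(self, segment: RoadSegment) -> None:
        for end in (segment.u, segment.v):
            if end not in self.junctions:
                raise NetworkConfigError(f"segment {segment.id!r} references unknown junction {end!r}")
        if segment.id in self.segments:
            raise NetworkConfigError(f"duplicate segment id {segment.id!r}")
        self.segments[segment.id] = segment
        self.graph.add_edge(
            segment.u, segment.v, key=segment.id, travel_time_min=segment.travel_time_min
        )

    def remove_segment(self, seg_id: str) -> RoadSegment:
        seg = self.segments.pop(seg_id)
        self.graph.remove_edge(seg.u, seg.v, key=seg_id)
        return seg

    # -- queries -------------------------------------------------------

    def resolve(self, point_or_junction_id: str) -> str:
        """Map an attached point id (or a junction id) to its junction."""
        if point_or_junction_id in self.attachment:
            return self.attachment[point_or_junction_id]
        if point_or_junction_id in self.junctions:
            return point_or_junction_id
        raise KeyError(f"id {point_or_junction_id!r} is not attached to the network")

    def total_length_m(self) -> float:
        return sum(s.length_m for s in self.segments.values())

    def connectors(self) -> list[RoadSegment]:
        return [s for s in self.segments.values() if s.highway_class == CONNECTOR_CLASS]

    def junction_at(self, x: float, y: float, eps: float = COINCIDENCE_EPS_M) -> str | None:
        """Return the id of a junction within ``eps`` of (x, y), if any."""
        best = None
        best_d = eps
        for j in self.junctions.values():
            d = math.hypot(j.x - x, j.y - y)
            if d <= best_d:
                best, best_d = j.id, d
        return best


# ---------------------------------------------------------------------------
# build_network: snap/integrate raw polylines into a routable network
# ---------------------------------------------------------------------------


def _cluster_vertices(
    vertices: np.ndarray, tolerance_m: float
) -> np.ndarray:
    """Group vertices whose pairwise distance is below tolerance.

    Returns an array of cluster labels (connected components of the
    within-tolerance proximity graph), mirroring the behaviour of GIS
    "integrate" tools.
    """
    n = len(vertices)
    if n == 0:
        return np.empty(0, dtype=int)
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    if tolerance_m > 0:
        from scipy.spatial import cKDTree

        tree = cKDTree(vertices)
        for i, j in tree.query_pairs(r=tolerance_m):
            union(i, j)
    else:
        # exact coincidence only
        seen: dict[tuple[float, float], int] = {}
        for i, (x, y) in enumerate(vertices):
            key = (float(x), float(y))
            if key in seen:
                union(seen[key], i)
            else:
                seen[key] = i
    roots = np.array([find(i) for i in range(n)])
    # relabel roots to consecutive ints in order of first appearance
    _, labels = np.unique(roots, return_inverse=True)
    return labels


def build_network(
    polylines: Iterable[tuple[str, str, Sequence[tuple[float, float]]]],
    tolerance_m: float = DEFAULT_SNAP_TOLERANCE_M,
    speed_table: Mapping[str, float] | None = None,
) -> RoadNetwork:
    """Integrate raw road polylines into a routable :class:`RoadNetwork`.

    Parameters
    ----------
    polylines
        Iterable of ``(segment_id, highway_class, coords)`` where ``coords``
        is an ordered list of (x, y) planar meters with at least 2 vertices.
    tolerance_m
        Vertices (of any polyline) closer than this are merged into a shared
        junction, making the segments mutually traversable there. Default
        10 m. With tolerance 0, only exactly coincident vertices merge.

    Polyline endpoints always become junctions. Interior vertices become
    junctions only when they merge with a vertex of another polyline (a
    crossing), in which case the polyline is split there. Zero-length
    segments after merging are dropped with a logged warning.
    """
    if tolerance_m < 0:
        raise NetworkConfigError("tolerance_m must be >= 0")
    polys = []
    for seg_id, hclass, coords in polylines:
        coords = [(float(x), float(y)) for x, y in coords]
        if len(coords) < 2:
            raise NetworkConfigError(f"polyline {seg_id!r} has fewer than 2 vertices")
        assign_speed(hclass, speed_table)  # validate class early
        polys.append((str(seg_id), hclass, coords))
    polys.sort(key=lambda p: p[0])

    # index every vertex of every polyline
    vert_owner: list[tuple[int, int]] = []  # (polyline index, vertex index)
    vert_coords: list[tuple[float, float]] = []
    for pi, (_, _, coords) in enumerate(polys):
        for vi, c in enumerate(coords):
            vert_owner.append((pi, vi))
            vert_coords.append(c)
    labels = _cluster_vertices(np.asarray(vert_coords, dtype=float), tolerance_m)

    # cluster -> canonical coordinate (centroid) and membership
    n_clusters = int(labels.max()) + 1 if len(labels) else 0
    members: list[list[tuple[int, int]]] = [[] for _ in range(n_clusters)]
    for (pi, vi), lab in zip(vert_owner, labels):
        members[lab].append((pi, vi))
    coords_arr = np.asarray(vert_coords, dtype=float)
    centroids = np.zeros((n_clusters, 2))
    for lab in range(n_clusters):
        idx = [k for k, l in enumerate(labels) if l == lab]
        centroids[lab] = coords_arr[idx].mean(axis=0)

    # a cluster is a junction if it holds a polyline endpoint or vertices
    # from more than one polyline (a crossing)
    is_junction = np.zeros(n_clusters, dtype=bool)
    for lab, mem in enumerate(members):
        owners = {pi for pi, _ in mem}
        has_endpoint = any(vi == 0 or vi == len(polys[pi][2]) - 1 for pi, vi in mem)
        if has_endpoint or len(owners) > 1 or len(mem) > 1:
            is_junction[lab] = True

    net = RoadNetwork()
    cluster_junction: dict[int, str] = {}
    vertex_label: dict[tuple[int, int], int] = {
        (pi, vi): int(lab) for (pi, vi), lab in zip(vert_owner, labels)
    }

    def junction_for(lab: int) -> str:
        if lab not in cluster_junction:
            cluster_junction[lab] = net.add_junction(*centroids[lab])
        return cluster_junction[lab]

    for pi, (seg_id, hclass, coords) in enumerate(polys):
        # snapped coordinates: junction vertices take their cluster centroid
        snapped = []
        cut_points = []  # indices into snapped where a junction sits
        for vi, c in enumerate(coords):
            lab = vertex_label[(pi, vi)]
            if is_junction[lab]:
                snapped.append(tuple(centroids[lab]))
                cut_points.append((vi, lab))
            else:
                snapped.append(c)
        # consecutive duplicate coordinates (merged within one polyline) collapse
        pieces = []
        for (vi_a, lab_a), (vi_b, lab_b) in zip(cut_points[:-1], cut_points[1:]):
            piece = snapped[vi_a : vi_b + 1]
            # drop consecutive exact duplicates inside the piece
            dedup = [piece[0]]
            for c in piece[1:]:
                if c != dedup[-1]:
                    dedup.append(c)
            pieces.append((dedup, lab_a, lab_b))
        multi = len(pieces) > 1
        for k, (piece, lab_a, lab_b) in enumerate(pieces):
            pid = f"{seg_id}.{k}" if multi else seg_id
            if len(piece) < 2 or _arc_length(piece) <= 0:
                logger.warning("dropping zero-length segment %s after snapping", pid)
                continue
            u, v = junction_for(lab_a), junction_for(lab_b)
            net.add_segment(make_segment(pid, u, v, piece, hclass, speed_table))
    return net


# ---------------------------------------------------------------------------
# connect_point: attach off-network points via connector segments
# ---------------------------------------------------------------------------


def _nearest_segment(
    net: RoadNetwork, point: Point, exclude_connectors: bool = True
) -> tuple[RoadSegment, float]:
    """Nearest non-connector segment to a point; ties by smallest segment id."""
    candidates = [
        s
        for s in net.segments.values()
        if not (exclude_connectors and s.highway_class == CONNECTOR_CLASS)
    ]
    if not candidates:
        raise NetworkConfigError("network has no road segments to attach to")
    candidates.sort(key=lambda s: s.id)
    lines = np.array([s.line for s in candidates], dtype=object)
    dists = shapely.distance(point, lines)
    best = int(np.argmin(dists))  # argmin returns the first (smallest-id) tie
    return candidates[best], float(dists[best])


def _split_segment_at(net: RoadNetwork, seg: RoadSegment, chainage: float) -> str:
    """Split ``seg`` at the given chainage, returning the new junction id.

    Total length is preserved (the two pieces partition the geometry). If the
    chainage falls on an endpoint (within coincidence epsilon), no split
    happens and the endpoint junction id is returned.
    """
    line = seg.line
    if chainage <= COINCIDENCE_EPS_M:
        return seg.u
    if chainage >= line.length - COINCIDENCE_EPS_M:
        return seg.v
    foot = line.interpolate(chainage)
    net.remove_segment(seg.id)
    jid = net.add_junction(foot.x, foot.y)
    part1 = substring(line, 0.0, chainage)
    part2 = substring(line, chainage, line.length)
    net.add_segment(
        make_segment(f"{seg.id}.a", seg.u, jid, list(part1.coords), seg.highway_class)
    )
    net.add_segment(
        make_segment(f"{seg.id}.b", jid, seg.v, list(part2.coords), seg.highway_class)
    )
    return jid


def connect_point(
    net: RoadNetwork,
    point_id: str,
    coord: tuple[float, float],
    connector_class: str = CONNECTOR_CLASS,
    coincidence_eps_m: float = COINCIDENCE_EPS_M,
) -> str:
    """Attach an off-network point to the nearest road segment.

    A straight connector segment (class "connector", 35 mph by default) is
    created from the point to the nearest point on the nearest road segment;
    the target segment is split at the foot point so routing can leave in
    either direction. Connector segments themselves are never targets. If the
    point coincides with an existing junction (within ``coincidence_eps_m``),
    it is attached directly and no connector is created.

    Returns the junction id the point is attached to and records it in
    ``net.attachment[point_id]``.
    """
    if point_id in net.attachment:
        raise NetworkConfigError(f"point {point_id!r} is already attached")
    x, y = float(coord[0]), float(coord[1])
    existing = net.junction_at(x, y, eps=coincidence_eps_m)
    if existing is not None:
        net.attachment[point_id] = existing
        return existing
    pt = Point(x, y)
    seg, dist = _nearest_segment(net, pt)
    chainage = seg.line.project(pt)
    foot_jid = _split_segment_at(net, seg, chainage)
    if dist <= coincidence_eps_m:
        # point lies on the segment itself: the split junction is the attachment
        net.attachment[point_id] = foot_jid
        return foot_jid
    pjid = net.add_junction(x, y)
    foot = net.junctions[foot_jid]
    net.add_segment(
        make_segment(
            f"conn:{point_id}", pjid, foot_jid, [(x, y), (foot.x, foot.y)], connector_class
        )
    )
    net.attachment[point_id] = pjid
    return pjid


def connect_points(
    net: RoadNetwork, points: Iterable[tuple[str, tuple[float, float]]]
) -> None:
    """Attach many points, in sorted-id order for determinism."""
    for pid, coord in sorted(points, key=lambda p: str(p[0])):
        connect_point(net, str(pid), coord)


# ---------------------------------------------------------------------------
# reporting / validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConnectorReport:
    """Summary of the synthetic connector segments in a network (miles)."""

    count: int
    total_miles: float
    mean_miles: float
    max_miles: float
    empty: bool = False


def connector_report(net: RoadNetwork) -> ConnectorReport:
    """Count, total, mean and max length of connector segments, in miles."""
    lengths = [s.length_m / METERS_PER_MILE for s in net.connectors()]
    return summarize_connector_lengths(lengths)


def summarize_connector_lengths(lengths_miles: Sequence[float]) -> ConnectorReport:
    if not lengths_miles:
        return ConnectorReport(0, 0.0, 0.0, 0.0, empty=True)
    total = float(sum(lengths_miles))
    return ConnectorReport(
        count=len(lengths_miles),
        total_miles=total,
        mean_miles=total / len(lengths_miles),
        max_miles=float(max(lengths_miles)),
    )


def validate_connectivity(
    net: RoadNetwork, origin_ids: Sequence[str], destination_ids: Sequence[str]
) -> list[tuple[str, str]]:
    """List (origin, destination) pairs that cannot reach each other.

    Report-only: an empty list means every origin reaches every destination.
    """
    comp_of: dict[str, int] = {}
    for ci, comp in enumerate(nx.connected_components(net.graph)):
        for node in comp:
            comp_of[node] = ci
    bad = []
    for o in origin_ids:
        for d in destination_ids:
            if comp_of.get(net.resolve(o)) != comp_of.get(net.resolve(d)):
                bad.append((o, d))
    return bad
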