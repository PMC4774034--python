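"""Synthetic study regions for pipeline testing and benchmarking.

Generates self-contained regions — a road network, populated places with
OpenStreetMap-style settlement types, a hospital / health-promoting-hospital
facility roster, a single tertiary care center, and a current POCT
assignment — with the statistical structure of a rural health-access study
area, so every pipeline stage runs without any external download.

Two deterministic hand-sized fixtures are also provided: one whose P-median
optima are certified by exhaustive enumeration, and one engineered to show
the backtracking phenomenon (nearest diagnosis opposite the direction of
care).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .network import RoadNetwork, build_network, connect_points
from .routing import (
    PLACE_TYPE_POPULATION,
    HealthFacility,
    PopulatedPlace,
    make_place,
    shortest_time,
    time_matrix,
)

#: Settlement-type mixture proportional to the observed counts in a rural
#: northeast-Thailand study region (1 city, 1 suburb, 5 towns, 1303
#: villages, 83 hamlets).
DEFAULT_PLACE_MIXTURE: dict[str, float] = {
    "city": 1 / 1393,
    "suburb": 1 / 1393,
    "town": 5 / 1393,
    "village": 1303 / 1393,
    "hamlet": 83 / 1393,
}

#: Road-class mixture for synthetic networks: a thin arterial skeleton over
#: a mostly minor-road fabric, loosely matching rural OSM class frequencies.
DEFAULT_CLASS_MIXTURE: dict[str, float] = {
    "trunk": 0.03,
    "primary": 0.07,
    "secondary": 0.10,
    "tertiary": 0.15,
    "unclassified": 0.25,
    "residential": 0.30,
    "service": 0.05,
    "living_street": 0.03,
    "road": 0.02,
}

#: Grid spacing between adjacent junctions (m) in synthetic networks.
GRID_SPACING_M = 2000.0


@dataclass(frozen=True)
class RegionConfig:
    """Configuration of a synthetic study region.

    Facility defaults keep roughly the 1 hospital : 7.9 health-promoting-
    hospital ratio observed in the emulated study region, scaled down to a
    desk-sized instance. ``n_current_poct`` (default 14) stands in for a
    surveyed roster of existing devices and is a free parameter, not an
    observed count.
    """

    seed: int
    network_kind: str = "grid"  # "grid" | "random_planar"
    n_junctions: int = 144
    class_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIXTURE)
    )
    n_places: int = 80
    place_type_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PLACE_MIXTURE)
    )
    n_hospitals: int = 16
    n_hph: int = 40
    n_current_poct: int = 14
    care_site_rule: str = "farthest_hospital"  # or an explicit facility id

    def __post_init__(self) -> None:
        if self.network_kind not in ("grid", "random_planar"):
            raise ValueError(f"unknown network kind {self.network_kind!r}")
        for name, mix in (("class", self.class_mixture), ("place", self.place_type_mixture)):
            total = sum(mix.values())
            if not math.isclose(total, 1.0, rel_tol=1e-6):
                raise ValueError(f"{name} mixture probabilities sum to {total}, not 1")
        if min(self.n_junctions, self.n_places, self.n_hospitals, self.n_hph) <= 0:
            raise ValueError("counts must be positive")
        if self.n_current_poct < 1:
            raise ValueError("n_current_poct must be >= 1")
        if self.n_current_poct > self.n_hospitals - 1:
            raise ValueError(
                "n_current_poct must leave room in the hospital roster "
                "(one hospital becomes the care center)"
            )


@dataclass(frozen=True)
class Region:
    """A generated study region, ready for routing and optimization."""

    network: RoadNetwork
    places: tuple[PopulatedPlace, ...]
    facilities: tuple[HealthFacility, ...]
    current_poct: frozenset[str]
    care_site: str

    @property
    def candidate_sites(self) -> tuple[str, ...]:
        """All facilities except the care center, as POCT candidates."""
        return tuple(sorted(f.id for f in self.facilities if f.kind != "care_center"))

    def demand(self) -> tuple[tuple[str, float], ...]:
        return tuple((p.id, p.population) for p in self.places)


# ---------------------------------------------------------------------------
# network generation
# ---------------------------------------------------------------------------


def _grid_polylines(n_junctions: int, mixture: dict[str, float], rng: np.random.Generator):
    m = max(2, int(round(math.sqrt(n_junctions))))
    classes = sorted(mixture)
    probs = np.array([mixture[c] for c in classes])
    probs = probs / probs.sum()
    polylines = []
    sid = 0

    def coord(i: int, j: int) -> tuple[float, float]:
        return (i * GRID_SPACING_M, j * GRID_SPACING_M)

    for i in range(m):
        for j in range(m):
            for di, dj in ((1, 0), (0, 1)):
                if i + di < m and j + dj < m:
                    cls = str(rng.choice(classes, p=probs))
                    polylines.append(
                        (f"R{sid:05d}", cls, [coord(i, j), coord(i + di, j + dj)])
                    )
                    sid += 1
    return polylines


def _random_planar_polylines(
    n_junctions: int, mixture: dict[str, float], rng: np.random.Generator
):
    """Delaunay triangulation of random junctions, thinned while keeping
    connectivity (spanning tree plus a random subset of the remaining edges)."""
    from scipy.spatial import Delaunay

    side = math.sqrt(n_junctions) * GRID_SPACING_M
    pts = rng.uniform(0, side, size=(n_junctions, 2))
    tri = Delaunay(pts)
    edges = set()
    for simplex in tri.simplices:
        for a, b in itertools.combinations(sorted(simplex), 2):
            edges.add((int(a), int(b)))
    edges = sorted(edges)
    order = rng.permutation(len(edges))
    parent = list(range(n_junctions))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    keep = []
    extra = []
    for k in order:
        a, b = edges[k]
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            keep.append((a, b))
        else:
            extra.append((a, b))
    for a, b in extra:
        if rng.random() < 0.5:
            keep.append((a, b))
    keep.sort()
    classes = sorted(mixture)
    probs = np.array([mixture[c] for c in classes])
    probs = probs / probs.sum()
    polylines = []
    for sid, (a, b) in enumerate(keep):
        cls = str(rng.choice(classes, p=probs))
        polylines.append(
            (f"R{sid:05d}", cls, [tuple(pts[a]), tuple(pts[b])])
        )
    return polylines


# ---------------------------------------------------------------------------
# region generation
# ---------------------------------------------------------------------------


def generate_region(config: RegionConfig) -> Region:
    """Generate a deterministic synthetic region from a config.

    Places are jittered off sampled junctions and carry type-default
    populations; facilities sample junctions with probability proportional
    to local place density (facilities cluster near settlements); exactly
    one hospital becomes the care center per ``care_site_rule``; current
    POCT devices are drawn from the remaining hospitals.
    """
    rng = np.random.default_rng(config.seed)
    if config.network_kind == "grid":
        polylines = _grid_polylines(config.n_junctions, config.class_mixture, rng)
    else:
        polylines = _random_planar_polylines(
            config.n_junctions, config.class_mixture, rng
        )
    net = build_network(polylines)
    junction_ids = sorted(net.junctions)
    jxy = np.array([net.junctions[j].coord for j in junction_ids])
    n_j = len(junction_ids)
    n_fac = config.n_hospitals + config.n_hph
    if config.n_places > n_j or n_fac > n_j:
        raise ValueError(
            f"region infeasible: {config.n_places} places / {n_fac} facilities "
            f"exceed the {n_j} available junctions"
        )

    # places: jittered off distinct junctions, typed by the mixture
    place_j = rng.choice(n_j, size=config.n_places, replace=False)
    ptypes = sorted(config.place_type_mixture)
    pprobs = np.array([config.place_type_mixture[t] for t in ptypes])
    pprobs = pprobs / pprobs.sum()
    places = []
    for k, ji in enumerate(sorted(place_j)):
        jit = rng.uniform(-300, 300, size=2)
        ptype = str(rng.choice(ptypes, p=pprobs))
        places.append(
            make_place(f"P{k:04d}", jxy[ji, 0] + jit[0], jxy[ji, 1] + jit[1], ptype)
        )

    # facilities: junctions weighted by local place density
    from scipy.spatial import cKDTree

    pxy = np.array([[p.x, p.y] for p in places])
    tree = cKDTree(pxy)
    density = np.array(
        [len(tree.query_ball_point(jxy[i], r=2.5 * GRID_SPACING_M)) for i in range(n_j)],
        dtype=float,
    )
    fw = density + 1.0
    fw = fw / fw.sum()
    fac_j = rng.choice(n_j, size=n_fac, replace=False, p=fw)
    fac_j = [int(j) for j in fac_j]
    rng.shuffle(fac_j)
    facilities: list[HealthFacility] = []
    for k, ji in enumerate(fac_j):
        jit = rng.uniform(-100, 100, size=2)
        kind = "hospital" if k < config.n_hospitals else "health_promoting_hospital"
        fid = f"H{k:03d}" if kind == "hospital" else f"F{k:03d}"
        facilities.append(
            HealthFacility(fid, jxy[ji, 0] + jit[0], jxy[ji, 1] + jit[1], kind)
        )

    connect_points(
        net,
        [(p.id, p.coord) for p in places] + [(f.id, f.coord) for f in facilities],
    )

    # care center: per rule, chosen among hospitals and relabelled
    hospitals = [f for f in facilities if f.kind == "hospital"]
    if config.care_site_rule == "farthest_hospital":
        care_id = _farthest_hospital(net, places, hospitals)
    else:
        if config.care_site_rule not in {f.id for f in hospitals}:
            raise ValueError(
                f"care_site_rule {config.care_site_rule!r} is not a hospital id"
            )
        care_id = config.care_site_rule
    facilities = [
        replace(f, kind="care_center") if f.id == care_id else f for f in facilities
    ]

    # current POCT: drawn from hospitals (excluding the care center)
    pool = sorted(f.id for f in facilities if f.kind == "hospital")
    current = frozenset(
        str(s) for s in rng.choice(pool, size=config.n_current_poct, replace=False)
    )
    facilities = [replace(f, has_poct=(f.id in current)) for f in facilities]
    return Region(net, tuple(places), tuple(facilities), current, care_id)


def _farthest_hospital(net, places, hospitals) -> str:
    """Hospital maximizing network time from the population-weighted
    centroid place (the place nearest the weighted mean coordinate)."""
    w = np.array([p.population for p in places], dtype=float)
    xy = np.array([[p.x, p.y] for p in places])
    centroid = (xy * w[:, None]).sum(axis=0) / w.sum()
    d2 = ((xy - centroid) ** 2).sum(axis=1)
    center_place = places[int(np.argmin(d2))]
    best_id, best_t = None, -1.0
    for h in sorted(hospitals, key=lambda f: f.id):
        t = shortest_time(net, center_place.id, h.id)
        if math.isfinite(t) and t > best_t:
            best_id, best_t = h.id, t
    if best_id is None:
        raise ValueError("no hospital reachable from the centroid place")
    return best_id


# ---------------------------------------------------------------------------
# certified fixtures
# ---------------------------------------------------------------------------


def _enumerate_optimum(
    times: pd.DataFrame, weights: dict[str, float], k: int, candidates: list[str]
) -> tuple[frozenset[str], float]:
    """Plain exhaustive enumeration oracle, independent of the solver."""
    best_obj, best_set = math.inf, None
    for combo in itertools.combinations(sorted(candidates), k):
        obj = 0.0
        for pid, w in weights.items():
            obj += w * min(times.at[pid, c] for c in combo)
        if obj < best_obj:
            best_obj, best_set = obj, frozenset(combo)
    return best_set, best_obj


def known_optimum_fixture() -> tuple[Region, pd.DataFrame, dict[int, tuple[frozenset[str], float]]]:
    """A hand-sized region with enumeration-certified P-median optima.

    Returns ``(region, time_matrix, optima)`` where ``optima[k]`` is the
    certified ``(site set, objective)`` for each budget k in 1..4, computed
    here by plain exhaustive enumeration over all candidate subsets
    (independent of the solvers under test).
    """
    region = generate_region(
        RegionConfig(
            seed=20160301,
            network_kind="grid",
            n_junctions=49,
            n_places=24,
            n_hospitals=6,
            n_hph=7,
            n_current_poct=3,
        )
    )
    candidates = list(region.candidate_sites)
    assert len(candidates) <= 12
    tm = time_matrix(region.network, [p.id for p in region.places], candidates)
    weights = {p.id: p.population for p in region.places}
    optima = {
        k: _enumerate_optimum(tm, weights, k, candidates) for k in (1, 2, 3, 4)
    }
    return region, tm, optima


def backtracking_region() -> Region:
    """A region certifying the backtracking phenomenon.

    The care center sits at the west end of a trunk corridor; the only
    current POCT device is east of the mid-corridor settlements, so those
    settlements must first travel east (away from care) for diagnosis and
    then backtrack west past their own origin — total time strictly exceeds
    the direct origin-to-care time. A near-side (western) hospital without a
    device is included so placement improvements can be demonstrated.
    """
    mile = 1609.344
    xs = [0.0, 10 * mile, 20 * mile, 30 * mile]
    polylines = [
        (f"R{k}", "trunk", [(xs[k], 0.0), (xs[k + 1], 0.0)]) for k in range(3)
    ]
    net = build_network(polylines)
    facilities = (
        HealthFacility("C0", xs[0], 0.0, "care_center"),
        HealthFacility("H1", 12 * mile, 0.0, "hospital", has_poct=False),
        HealthFacility("H2", xs[3], 0.0, "hospital", has_poct=True),
    )
    places = (
        make_place("P000", xs[1], 0.0, "village"),
        make_place("P001", xs[2], 0.0, "village"),
        make_place("P002", xs[3], 0.0, "hamlet"),
    )
    connect_points(
        net,
        [(p.id, p.coord) for p in places] + [(f.id, f.coord) for f in facilities],
    )
    return Region(net, places, facilities, frozenset({"H2"}), "C0")
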