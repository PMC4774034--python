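"""Shared fixtures: tiny hand-built networks and cached synthetic regions."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from scpath.network import METERS_PER_MILE, RoadNetwork, build_network
from scpath.synth import RegionConfig, generate_region, known_optimum_fixture

MILE = METERS_PER_MILE


@pytest.fixture
def straight_segment_net() -> RoadNetwork:
    """A single 200 m trunk segment along the x-axis."""
    return build_network([("S", "trunk", [(0.0, 0.0), (200.0, 0.0)])])


@pytest.fixture
def two_mile_chain() -> RoadNetwork:
    """Two 1-mile trunk segments in a line: J0 - J1 - J2."""
    return build_network(
        [
            ("A", "trunk", [(0.0, 0.0), (MILE, 0.0)]),
            ("B", "trunk", [(MILE, 0.0), (2 * MILE, 0.0)]),
        ]
    )


def random_small_network(rng: np.random.Generator, max_junctions: int = 10):
    """A random connected multigraph road network with <= max_junctions.

    Junctions sit at distinct lattice coordinates; polylines join random
    junction pairs (a random spanning tree first, then extra edges), with
    random road classes. Built through build_network at tolerance 0 so
    coincident endpoints merge into shared junctions.
    """
    n = int(rng.integers(3, max_junctions + 1))
    coords = rng.choice(50 * 50, size=n, replace=False)
    pts = [(float(c % 50) * 500.0, float(c // 50) * 500.0) for c in coords]
    classes = ["trunk", "primary", "secondary", "tertiary", "residential", "service"]
    order = rng.permutation(n)
    polylines = []
    sid = 0
    for a, b in zip(order[:-1], order[1:]):  # spanning tree (path)
        polylines.append((f"E{sid:03d}", str(rng.choice(classes)), [pts[a], pts[b]]))
        sid += 1
    n_extra = int(rng.integers(0, n))
    pairs = list(itertools.combinations(range(n), 2))
    for k in rng.choice(len(pairs), size=min(n_extra, len(pairs)), replace=False):
        a, b = pairs[int(k)]
        polylines.append((f"E{sid:03d}", str(rng.choice(classes)), [pts[a], pts[b]]))
        sid += 1
    return build_network(polylines, tolerance_m=0.0)


def brute_force_time(net: RoadNetwork, a: str, b: str) -> float:
    """Exhaustive-enumeration shortest travel time over all simple paths."""
    import networkx as nx

    ja, jb = net.resolve(a), net.resolve(b)
    if ja == jb:
        return 0.0
    best = math.inf
    for path in nx.all_simple_paths(net.graph, ja, jb):
        t = 0.0
        for u, v in zip(path[:-1], path[1:]):
            t += min(d["travel_time_min"] for d in net.graph[u][v].values())
        best = min(best, t)
    return best


@pytest.fixture(scope="session")
def small_region():
    """A small synthetic region shared across tests (read-only)."""
    return generate_region(
        RegionConfig(
            seed=11,
            n_junctions=49,
            n_places=20,
            n_hospitals=5,
            n_hph=8,
            n_current_poct=3,
        )
    )


@pytest.fixture(scope="session")
def certified_fixture():
    """(region, time matrix, enumeration-certified optima) — read-only."""
    return known_optimum_fixture()


def tiny_region_config(seed: int) -> RegionConfig:
    """Config for the many-random-regions property suites."""
    return RegionConfig(
        seed=seed,
        n_junctions=36,
        n_places=14,
        n_hospitals=4,
        n_hph=4,
        n_current_poct=2,
    )
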