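"""Two-stage care-path routing and population-weighted access summaries.

Health-care access is modelled as a spatial care path: the fastest route
from a populated place to its closest diagnostic site (stage 1), then from
that site to the single tertiary care center (stage 2). Access across a
region is summarized as the mean (SD) travel time of each stage, optionally
weighted by place population, plus a 15-minute-bin histogram of total time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .network import RoadNetwork

logger = logging.getLogger(__name__)

#: Default population per settlement type when no count is recorded,
#: following the conventional OpenStreetMap place-tag magnitudes.
PLACE_TYPE_POPULATION: dict[str, int] = {
    "city": 100_000,
    "suburb": 100_000,
    "town": 20_000,
    "village": 10_000,
    "hamlet": 200,
}

PLACE_TYPES = tuple(PLACE_TYPE_POPULATION)
FACILITY_KINDS = ("hospital", "health_promoting_hospital", "care_center")


@dataclass(frozen=True)
class PopulatedPlace:
    """A demand point: where a patient's journey to care begins."""

    id: str
    x: float
    y: float
    place_type: str
    population: float

    def __post_init__(self) -> None:
        if self.place_type not in PLACE_TYPE_POPULATION:
            raise ValueError(
                f"unknown place type {self.place_type!r}; expected one of {PLACE_TYPES}"
            )
        if self.population < 0:
            raise ValueError(f"place {self.id!r} has negative population")

    @property
    def coord(self) -> tuple[float, float]:
        return (self.x, self.y)


def make_place(
    pid: str, x: float, y: float, place_type: str, population: float | None = None
) -> PopulatedPlace:
    """Create a place, filling a missing population from the type default."""
    if population is None or (isinstance(population, float) and math.isnan(population)):
        if place_type not in PLACE_TYPE_POPULATION:
            raise ValueError(f"unknown place type {place_type!r}")
        population = PLACE_TYPE_POPULATION[place_type]
    return PopulatedPlace(str(pid), float(x), float(y), place_type, float(population))


@dataclass(frozen=True)
class HealthFacility:
    """A diagnostic candidate site or the single definitive-care destination."""

    id: str
    x: float
    y: float
    kind: str
    has_poct: bool = False

    def __post_init__(self) -> None:
        if self.kind not in FACILITY_KINDS:
            raise ValueError(f"unknown facility kind {self.kind!r}; expected {FACILITY_KINDS}")

    @property
    def coord(self) -> tuple[float, float]:
        return (self.x, self.y)


def care_center_of(facilities: Iterable[HealthFacility]) -> HealthFacility:
    """The single care-center facility; raises if there is not exactly one."""
    centers = [f for f in facilities if f.kind == "care_center"]
    if len(centers) != 1:
        raise ValueError(f"expected exactly one care_center facility, found {len(centers)}")
    return centers[0]


@dataclass(frozen=True)
class CarePathResult:
    """Per-origin outcome of the two-stage routing."""

    origin_id: str
    diagnosis_facility_id: str
    t_diag_min: float
    t_care_min: float

    @property
    def t_total_min(self) -> float:
        return self.t_diag_min + self.t_care_min


class UnreachableError(RuntimeError):
    """Raised when a required route does not exist on the network."""


# ---------------------------------------------------------------------------
# shortest paths
# ---------------------------------------------------------------------------


def shortest_time(net: RoadNetwork, a: str, b: str) -> float:
    """Minimum travel time in minutes between two attached ids.

    Returns ``math.inf`` if no path exists. Ids may be attached point ids or
    junction ids.
    """
    ja, jb = net.resolve(a), net.resolve(b)
    if ja == jb:
        return 0.0
    try:
        return float(
            nx.shortest_path_length(net.graph, ja, jb, weight="travel_time_min")
        )
    except nx.NetworkXNoPath:
        return math.inf


def times_from(net: RoadNetwork, source: str) -> dict[str, float]:
    """Travel time in minutes from ``source`` to every reachable junction."""
    return nx.single_source_dijkstra_path_length(
        net.graph, net.resolve(source), weight="travel_time_min"
    )


def time_matrix(
    net: RoadNetwork, origin_ids: Sequence[str], facility_ids: Sequence[str]
) -> pd.DataFrame:
    """Origin x facility travel-time matrix (minutes; inf if unreachable).

    One single-source shortest-path pass per facility.
    """
    origin_ids = [str(o) for o in origin_ids]
    cols = {}
    for fid in sorted(str(f) for f in facility_ids):
        lengths = times_from(net, fid)
        cols[fid] = [lengths.get(net.resolve(o), math.inf) for o in origin_ids]
    return pd.DataFrame(cols, index=pd.Index(origin_ids, name="origin_id"))


def closest_facility(
    net: RoadNetwork, origin: str, facility_ids: Iterable[str]
) -> tuple[str, float]:
    """The facility with the minimum travel time from ``origin``.

    Ties are broken by the smallest facility id. Raises
    :class:`UnreachableError` if no facility is reachable.
    """
    fids = sorted(str(f) for f in facility_ids)
    if not fids:
        raise ValueError("facility set is empty")
    best_id, best_t = None, math.inf
    for fid in fids:
        t = shortest_time(net, origin, fid)
        if t < best_t:
            best_id, best_t = fid, t
    if best_id is None:
        raise UnreachableError(f"no facility reachable from origin {origin!r}")
    return best_id, best_t


def spatial_care_path(
    net: RoadNetwork,
    origin: str,
    poct_sites: Iterable[str],
    care_site: str,
) -> CarePathResult:
    """Route an origin through diagnosis to care.

    Stage 1 picks the closest POCT-equipped site (the care center itself may
    carry POCT, yielding a zero-length second stage); stage 2 routes from that
    site to the care center. Raises :class:`UnreachableError` naming the
    failing stage.
    """
    try:
        diag_id, t_diag = closest_facility(net, origin, poct_sites)
    except UnreachableError:
        raise UnreachableError(
            f"stage 1 (origin -> diagnosis) unreachable for origin {origin!r}"
        ) from None
    t_care = shortest_time(net, diag_id, care_site)
    if math.isinf(t_care):
        raise UnreachableError(
            f"stage 2 (diagnosis -> care) unreachable from site {diag_id!r}"
        )
    return CarePathResult(str(origin), diag_id, t_diag, t_care)


def care_paths(
    net: RoadNetwork,
    places: Sequence[PopulatedPlace],
    poct_sites: Iterable[str],
    care_site: str,
    time_matrix_df: pd.DataFrame | None = None,
) -> list[CarePathResult]:
    """Spatial care path for every place.

    When a precomputed origin x facility ``time_matrix_df`` is supplied it is
    used instead of per-origin Dijkstra passes (columns must cover the POCT
    sites and the care site; stage-2 times are taken from the care-site
    column, valid because the network is undirected).
    """
    sites = sorted(str(s) for s in poct_sites)
    if not sites:
        raise ValueError("poct_sites is empty")
    if time_matrix_df is not None:
        care_times = times_from(net, care_site)
        site_to_care = {s: care_times.get(net.resolve(s), math.inf) for s in sites}
        sub = time_matrix_df[sites]
        out = []
        for place in places:
            row = sub.loc[place.id]
            t_diag = float(row.min())
            if math.isinf(t_diag):
                raise UnreachableError(
                    f"stage 1 (origin -> diagnosis) unreachable for origin {place.id!r}"
                )
            diag_id = str(row.index[int(np.argmin(row.to_numpy()))])
            t_care = site_to_care[diag_id]
            if math.isinf(t_care):
                raise UnreachableError(
                    f"stage 2 (diagnosis -> care) unreachable from site {diag_id!r}"
                )
            out.append(CarePathResult(place.id, diag_id, t_diag, t_care))
        return out
    return [spatial_care_path(net, p.id, sites, care_site) for p in places]


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AccessSummary:
    """Mean (SD) travel time per care-path stage, plus a 15-min histogram."""

    n_routes: int
    mean_diag_min: float
    sd_diag_min: float
    mean_care_min: float
    sd_care_min: float
    mean_total_min: float
    sd_total_min: float
    weighted: bool
    histogram_15min: tuple[int, ...]
    n_excluded: int = 0


def _weighted_mean_sd(values: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    """Frequency-weighted mean and SD (population as replication count)."""
    wsum = weights.sum()
    mean = float((weights * values).sum() / wsum)
    var = float((weights * (values - mean) ** 2).sum() / wsum)
    return mean, math.sqrt(max(var, 0.0))


def histogram_15min(paths: Sequence[CarePathResult]) -> tuple[int, ...]:
    """Counts of total travel time in [0,15), [15,30), ... minute bins."""
    times = [p.t_total_min for p in paths if math.isfinite(p.t_total_min)]
    if not times:
        return ()
    n_bins = int(max(times) // 15) + 1
    counts = np.zeros(n_bins, dtype=int)
    for t in times:
        counts[int(t // 15)] += 1
    return tuple(int(c) for c in counts)


def summarize_access(
    paths: Sequence[CarePathResult],
    places: Sequence[PopulatedPlace],
    weighted: bool = True,
) -> AccessSummary:
    """Summarize care paths as mean (SD) per stage.

    ``weighted=True`` weights each origin by its place population
    (frequency weights: a place of 10 000 counts as 10 000 identical
    travellers). Routes with infinite times are excluded with a logged count.
    """
    pop = {p.id: p.population for p in places}
    missing = [p.origin_id for p in paths if p.origin_id not in pop]
    if missing:
        raise ValueError(f"paths reference unknown places: {missing[:5]}")
    finite = [p for p in paths if math.isfinite(p.t_total_min)]
    n_excluded = len(paths) - len(finite)
    if n_excluded:
        logger.warning("excluding %d unreachable routes from summary", n_excluded)
    if not finite:
        raise ValueError("no finite care paths to summarize")
    t_diag = np.array([p.t_diag_min for p in finite])
    t_care = np.array([p.t_care_min for p in finite])
    t_total = t_diag + t_care
    w = (
        np.array([pop[p.origin_id] for p in finite], dtype=float)
        if weighted
        else np.ones(len(finite))
    )
    if w.sum() <= 0:
        raise ValueError("total weight is zero")
    md, sd_d = _weighted_mean_sd(t_diag, w)
    mc, sd_c = _weighted_mean_sd(t_care, w)
    mt, sd_t = _weighted_mean_sd(t_total, w)
    return AccessSummary(
        n_routes=len(finite),
        mean_diag_min=md,
        sd_diag_min=sd_d,
        mean_care_min=mc,
        sd_care_min=sd_c,
        mean_total_min=mt,
        sd_total_min=sd_t,
        weighted=weighted,
        histogram_15min=histogram_15min(finite),
        n_excluded=n_excluded,
    )


def percent_decrease(current: float, alternative: float, ndigits: int | None = 1) -> float:
    """Percent decrease of ``alternative`` relative to ``current``.

    100 x (current - alternative) / current, rounded to ``ndigits`` decimals
    (1 by default, matching conventional table precision; pass ``None`` for
    the unrounded value). ``current`` must be positive.
    """
    if current <= 0:
        raise ValueError(f"current value must be > 0, got {current}")
    value = 100.0 * (current - alternative) / current
    return value if ndigits is None else round(value, ndigits)
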