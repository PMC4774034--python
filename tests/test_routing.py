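"""Two-stage routing, closest-facility logic, and access summaries."""

import math

import numpy as np
import pytest

from conftest import brute_force_time, random_small_network
from scpath.network import METERS_PER_MILE, build_network, connect_point
from scpath.routing import (
    CarePathResult,
    UnreachableError,
    closest_facility,
    histogram_15min,
    make_place,
    percent_decrease,
    shortest_time,
    spatial_care_path,
    summarize_access,
    time_matrix,
)

MILE = METERS_PER_MILE


class TestShortestTime:
    def test_identity_is_zero(self, two_mile_chain):
        j = sorted(two_mile_chain.junctions)[0]
        assert shortest_time(two_mile_chain, j, j) == 0.0

    def test_single_mile_trunk_edge(self):
        net = build_network([("A", "trunk", [(0, 0), (MILE, 0)])])
        a, b = sorted(net.junctions)
        assert shortest_time(net, a, b) == pytest.approx(60 / 65, rel=1e-9)

    def test_unreachable_is_infinite(self):
        net = build_network(
            [("A", "trunk", [(0, 0), (100, 0)]), ("B", "trunk", [(0, 500), (100, 500)])],
            tolerance_m=0,
        )
        js = sorted(net.junctions)
        assert math.isinf(shortest_time(net, js[0], js[3]))

    def test_unattached_id_raises(self, two_mile_chain):
        with pytest.raises(KeyError):
            shortest_time(two_mile_chain, "nope", sorted(two_mile_chain.junctions)[0])

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            net = random_small_network(rng, max_junctions=8)
            js = sorted(net.junctions)
            a, b = rng.choice(js, size=2, replace=False)
            assert shortest_time(net, a, b) == pytest.approx(
                brute_force_time(net, a, b), rel=1e-12
            )

    def test_symmetry(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            net = random_small_network(rng, max_junctions=8)
            js = sorted(net.junctions)
            a, b = rng.choice(js, size=2, replace=False)
            assert shortest_time(net, a, b) == pytest.approx(
                shortest_time(net, b, a), abs=1e-12
            )


class TestClosestFacility:
    def _line_net(self):
        # junctions at 0, 10, 20, 30 miles along a trunk line
        net = build_network(
            [(f"R{k}", "trunk", [(k * 10 * MILE, 0), ((k + 1) * 10 * MILE, 0)]) for k in range(3)]
        )
        for pid, x in [("O", 0.0), ("F1", 10 * MILE), ("F2", 30 * MILE)]:
            connect_point(net, pid, (x, 0.0))
        return net

    def test_coincident_facility_wins_at_zero(self):
        net = self._line_net()
        connect_point(net, "F0", (0.0, 0.0))
        fid, t = closest_facility(net, "O", ["F0", "F1", "F2"])
        assert (fid, t) == ("F0", 0.0)

    def test_nearer_facility_wins(self):
        net = self._line_net()
        fid, _ = closest_facility(net, "O", ["F1", "F2"])
        assert fid == "F1"

    def test_tie_broken_by_smallest_id(self):
        net = build_network([("R", "trunk", [(-10 * MILE, 0), (10 * MILE, 0)])])
        for pid, x in [("O", 0.0), ("B", 10 * MILE), ("A", -10 * MILE)]:
            connect_point(net, pid, (x, 0.0))
        fid, _ = closest_facility(net, "O", ["B", "A"])
        assert fid == "A"

    def test_all_unreachable_names_origin(self):
        net = build_network(
            [("A", "trunk", [(0, 0), (100, 0)]), ("B", "trunk", [(0, 500), (100, 500)])],
            tolerance_m=0,
        )
        connect_point(net, "O", (0.0, 0.0))
        connect_point(net, "F", (0.0, 500.0))
        with pytest.raises(UnreachableError, match="O"):
            closest_facility(net, "O", ["F"])


class TestSpatialCarePath:
    def test_origin_at_poct_care_site(self):
        net = build_network([("R", "trunk", [(0, 0), (MILE, 0)])])
        connect_point(net, "O", (0.0, 0.0))
        connect_point(net, "C", (0.0, 0.0))
        r = spatial_care_path(net, "O", ["C"], "C")
        assert (r.t_diag_min, r.t_care_min, r.t_total_min) == (0.0, 0.0, 0.0)

    def test_chain_origin_poct_care(self):
        # O --10mi-- A(POCT) --20mi-- CARE, all trunk (60/65 min per 10 mi... scaled)
        net = build_network(
            [
                ("R0", "trunk", [(0, 0), (10 * MILE, 0)]),
                ("R1", "trunk", [(10 * MILE, 0), (30 * MILE, 0)]),
            ]
        )
        for pid, x in [("O", 0.0), ("A", 10 * MILE), ("CARE", 30 * MILE)]:
            connect_point(net, pid, (x, 0.0))
        r = spatial_care_path(net, "O", ["A"], "CARE")
        per_mile = 60 / 65
        assert r.t_diag_min == pytest.approx(10 * per_mile, rel=1e-9)
        assert r.t_care_min == pytest.approx(20 * per_mile, rel=1e-9)
        assert r.t_total_min == pytest.approx(r.t_diag_min + r.t_care_min, abs=1e-9)

    def test_backtracking_exceeds_direct_route(self):
        # care west of origin, only POCT east: the path doubles back
        net = build_network([("R", "trunk", [(0, 0), (40 * MILE, 0)])])
        for pid, x in [("CARE", 0.0), ("O", 20 * MILE), ("E", 30 * MILE)]:
            connect_point(net, pid, (x, 0.0))
        r = spatial_care_path(net, "O", ["E"], "CARE")
        direct = shortest_time(net, "O", "CARE")
        assert r.t_total_min > direct
        assert r.t_total_min == pytest.approx(direct + 2 * shortest_time(net, "O", "E"), rel=1e-9)

    def test_care_path_lower_bound_on_random_networks(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            net = random_small_network(rng, max_junctions=9)
            js = sorted(net.junctions)
            origin, care = js[0], js[-1]
            sites = list(rng.choice(js, size=min(3, len(js)), replace=False))
            try:
                r = spatial_care_path(net, origin, sites, care)
            except UnreachableError:
                continue
            assert r.t_total_min >= shortest_time(net, origin, care) - 1e-9


class TestSummaries:
    def _paths(self, times):
        return [CarePathResult(f"P{i}", "F", t / 2, t / 2) for i, t in enumerate(times)]

    def _places(self, pops):
        return [make_place(f"P{i}", 0, 0, "village", p) for i, p in enumerate(pops)]

    def test_equal_weights_mean(self):
        s = summarize_access(self._paths([10, 30]), self._places([1, 1]), weighted=True)
        assert s.mean_total_min == pytest.approx(20.0)

    def test_population_weighted_mean(self):
        s = summarize_access(self._paths([10, 30]), self._places([3, 1]), weighted=True)
        assert s.mean_total_min == pytest.approx(15.0)  # (3*10 + 1*30) / 4

    def test_single_route_sd_zero(self):
        s = summarize_access(self._paths([42]), self._places([7]), weighted=True)
        assert s.sd_total_min == 0.0

    def test_weighted_equals_unweighted_when_populations_equal(self):
        paths = self._paths([5, 25, 60, 90])
        places = self._places([200, 200, 200, 200])
        w = summarize_access(paths, places, weighted=True)
        u = summarize_access(paths, places, weighted=False)
        for f in ("mean_diag_min", "sd_diag_min", "mean_total_min", "sd_total_min"):
            assert getattr(w, f) == pytest.approx(getattr(u, f), abs=1e-9)

    def test_infinite_routes_excluded_with_count(self):
        paths = self._paths([10, 30]) + [CarePathResult("P2", "F", math.inf, 0.0)]
        places = self._places([1, 1, 1])
        s = summarize_access(paths, places, weighted=False)
        assert s.n_routes == 2 and s.n_excluded == 1

    def test_frequency_weighted_sd_matches_replication(self):
        # weights as replication counts: SD over [10, 10, 10, 30]
        s = summarize_access(self._paths([10, 30]), self._places([3, 1]), weighted=True)
        rep = np.array([10, 10, 10, 30], dtype=float)
        assert s.mean_total_min == pytest.approx(rep.mean())
        assert s.sd_total_min == pytest.approx(rep.std())


class TestHistogram15Min:
    def test_boundary_convention(self):
        paths = [CarePathResult(f"P{i}", "F", t, 0.0) for i, t in enumerate([0, 14.99, 15])]
        assert histogram_15min(paths) == (2, 1)

    def test_empty(self):
        assert histogram_15min([]) == ()

    def test_counts_conserved(self):
        rng = np.random.default_rng(3)
        times = rng.uniform(0, 60, size=1000)
        paths = [CarePathResult(f"P{i}", "F", t, 0.0) for i, t in enumerate(times)]
        h = histogram_15min(paths)
        assert len(h) == 4
        assert sum(h) == 1000


class TestPercentDecrease:
    @pytest.mark.parametrize(
        "current,alt,expected",
        [(49.9, 13.9, 72.1), (218.5, 173.7, 20.5), (100.0, 100.0, 0.0)],
    )
    def test_values(self, current, alt, expected):
        assert percent_decrease(current, alt) == expected

    def test_nonpositive_current_rejected(self):
        with pytest.raises(ValueError):
            percent_decrease(0.0, 1.0)

    def test_unrounded_mode(self):
        assert percent_decrease(3.0, 1.0, ndigits=None) == pytest.approx(200 / 3)


class TestTimeMatrix:
    def test_matrix_matches_pairwise_queries(self, small_region):
        region = small_region
        places = [p.id for p in region.places][:5]
        facs = list(region.candidate_sites)[:4]
        tm = time_matrix(region.network, places, facs)
        for p in places:
            for f in facs:
                assert tm.at[p, f] == pytest.approx(
                    shortest_time(region.network, p, f), rel=1e-9
                )
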