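"""Network construction: speeds, snapping, connectors, connectivity."""

import networkx as nx
import numpy as np
import pytest

from scpath.network import (
    METERS_PER_MILE,
    NetworkConfigError,
    SPEED_TABLE_MPH,
    assign_speed,
    build_network,
    connect_point,
    connector_report,
    summarize_connector_lengths,
    validate_connectivity,
)

MILE = METERS_PER_MILE


class TestAssignSpeed:
    @pytest.mark.parametrize(
        "label,mph",
        [
            ("trunk", 65),
            ("primary", 55),
            ("secondary", 45),
            ("tertiary", 30),
            ("unclassified", 25),
            ("residential", 25),
            ("service", 15),
            ("living_street", 25),
            ("road", 35),
            ("connector", 35),
        ],
    )
    def test_estimated_speeds(self, label, mph):
        assert assign_speed(label) == mph

    def test_case_normalization(self):
        assert assign_speed("Living street") == 25
        assert assign_speed(" TRUNK ") == 65

    def test_unknown_class_rejected_by_name(self):
        with pytest.raises(NetworkConfigError, match="motorway_link"):
            assign_speed("motorway_link")

    def test_speed_table_override(self):
        assert assign_speed("trunk", {"trunk": 50.0}) == 50.0


class TestBuildNetwork:
    def test_snap_within_tolerance_shares_junction(self):
        net = build_network(
            [("A", "trunk", [(0, 0), (100, 0)]), ("B", "trunk", [(105, 0), (200, 0)])],
            tolerance_m=10,
        )
        assert len(net.junctions) == 3
        assert len(net.segments) == 2
        assert nx.number_connected_components(net.graph) == 1

    def test_outside_tolerance_stays_disconnected(self):
        net = build_network(
            [("A", "trunk", [(0, 0), (100, 0)]), ("B", "trunk", [(105, 0), (200, 0)])],
            tolerance_m=1,
        )
        assert len(net.junctions) == 4
        assert nx.number_connected_components(net.graph) == 2

    def test_one_mile_trunk_travel_time(self):
        net = build_network([("A", "trunk", [(0, 0), (MILE, 0)])])
        (seg,) = net.segments.values()
        assert seg.travel_time_min == pytest.approx(60 / 65, rel=1e-9)
        assert seg.length_m == pytest.approx(MILE, rel=1e-6)
        assert seg.speed_mph == SPEED_TABLE_MPH["trunk"]

    def test_interior_crossing_becomes_junction(self):
        # vertical road's interior vertex touches horizontal road's interior vertex
        net = build_network(
            [
                ("H", "trunk", [(0, 0), (100, 0), (200, 0)]),
                ("V", "trunk", [(100, -100), (100, 0), (100, 100)]),
            ],
            tolerance_m=1,
        )
        # both polylines split at the shared crossing
        assert len(net.segments) == 4
        assert len(net.junctions) == 5
        assert nx.number_connected_components(net.graph) == 1

    def test_zero_tolerance_merges_only_coincident(self):
        net = build_network(
            [("A", "trunk", [(0, 0), (100, 0)]), ("B", "trunk", [(100, 0), (200, 0)])],
            tolerance_m=0,
        )
        assert len(net.junctions) == 3

    def test_idempotent_rebuild(self):
        net = build_network(
            [("A", "trunk", [(0, 0), (100, 0)]), ("B", "primary", [(103, 0), (200, 0)])],
            tolerance_m=10,
        )
        rebuilt = build_network(
            [(s.id, s.highway_class, list(s.geometry)) for s in net.segments.values()],
            tolerance_m=10,
        )
        assert len(rebuilt.junctions) == len(net.junctions)
        assert len(rebuilt.segments) == len(net.segments)
        assert rebuilt.total_length_m() == pytest.approx(net.total_length_m(), rel=1e-9)

    def test_invariants_on_random_networks(self):
        rng = np.random.default_rng(5)
        from conftest import random_small_network

        for _ in range(20):
            net = random_small_network(rng)
            for seg in net.segments.values():
                assert seg.speed_mph == SPEED_TABLE_MPH[seg.highway_class]
                expect = (seg.length_m / MILE) / seg.speed_mph * 60
                assert seg.travel_time_min == pytest.approx(expect, rel=1e-9)
                assert seg.u in net.junctions and seg.v in net.junctions

    def test_rejects_single_vertex_polyline(self):
        with pytest.raises(NetworkConfigError):
            build_network([("A", "trunk", [(0, 0)])])

    def test_rejects_unknown_class(self):
        with pytest.raises(NetworkConfigError, match="cycleway"):
            build_network([("A", "cycleway", [(0, 0), (1, 1)])])


class TestConnectPoint:
    def test_perpendicular_foot_splits_segment(self, straight_segment_net):
        net = straight_segment_net
        before = net.total_length_m()
        connect_point(net, "P1", (100.0, 100.0))
        conns = net.connectors()
        assert len(conns) == 1
        assert conns[0].length_m == pytest.approx(100.0)
        # original segment split into two halves, total length conserved
        halves = sorted(s.length_m for s in net.segments.values() if s.id.startswith("S."))
        assert halves == pytest.approx([100.0, 100.0])
        assert net.total_length_m() == pytest.approx(before + 100.0, rel=1e-6)

    def test_point_on_existing_junction_attaches_directly(self, straight_segment_net):
        net = straight_segment_net
        n_seg = len(net.segments)
        jid = connect_point(net, "P1", (0.0, 0.0))
        assert jid in net.junctions
        assert len(net.segments) == n_seg  # no connector created
        assert net.attachment["P1"] == jid

    def test_tie_broken_by_smallest_segment_id(self):
        net = build_network(
            [("A", "trunk", [(0, 10), (100, 10)]), ("B", "trunk", [(0, -10), (100, -10)])],
            tolerance_m=0,
        )
        connect_point(net, "P1", (50.0, 0.0))  # exactly 10 m from both
        (conn,) = net.connectors()
        foot = net.junctions[conn.v if conn.u == net.attachment["P1"] else conn.u]
        assert foot.y == pytest.approx(10.0)  # segment "A" < "B"

    def test_connectors_are_never_targets(self, straight_segment_net):
        net = straight_segment_net
        connect_point(net, "P1", (100.0, 100.0))
        # P2 is nearer the connector than the road, but must attach to the road
        connect_point(net, "P2", (110.0, 50.0))
        conn2 = net.segments["conn:P2"]
        foot = net.junctions[conn2.v]
        assert foot.y == pytest.approx(0.0)

    def test_empty_network_rejected(self):
        from scpath.network import RoadNetwork

        with pytest.raises(NetworkConfigError):
            connect_point(RoadNetwork(), "P1", (0, 0))


class TestConnectorReport:
    def test_two_connectors(self):
        rep = summarize_connector_lengths([1.0, 3.0])
        assert (rep.count, rep.total_miles, rep.mean_miles, rep.max_miles) == (2, 4.0, 2.0, 3.0)

    def test_mean_length_from_totals(self):
        # 2331 connectors totalling 738.3 miles average 0.32 miles
        mean = 738.3 / 2331
        assert round(mean, 2) == 0.32

    def test_empty_is_flagged(self):
        rep = summarize_connector_lengths([])
        assert rep.empty and rep.count == 0 and rep.mean_miles == 0.0

    def test_report_from_network(self, straight_segment_net):
        net = straight_segment_net
        connect_point(net, "P1", (100.0, 100.0))
        rep = connector_report(net)
        assert rep.count == 1
        assert rep.total_miles == pytest.approx(100.0 / MILE)


class TestValidateConnectivity:
    def test_connected_grid_is_clean(self, two_mile_chain):
        js = sorted(two_mile_chain.junctions)
        assert validate_connectivity(two_mile_chain, js[:1], js[-1:]) == []

    def test_split_components_reported_then_fixed(self):
        net = build_network(
            [("A", "trunk", [(0, 0), (100, 0)]), ("B", "trunk", [(0, 500), (100, 500)])],
            tolerance_m=0,
        )
        connect_point(net, "O", (0.0, 0.0))
        connect_point(net, "D", (0.0, 500.0))
        assert validate_connectivity(net, ["O"], ["D"]) == [("O", "D")]
        # join the components and re-check
        connect_point(net, "BRIDGE", (50.0, 250.0))
        bridge_junction = net.attachment["BRIDGE"]
        from scpath.network import make_segment

        # add an explicit road joining the bridge point to the other component
        other = net.segments["B.a"] if "B.a" in net.segments else net.segments["B"]
        net.add_segment(
            make_segment("LINK", bridge_junction, other.u,
                         [net.junctions[bridge_junction].coord, net.junctions[other.u].coord],
                         "road")
        )
        assert validate_connectivity(net, ["O"], ["D"]) == []
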