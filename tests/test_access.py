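"""Drive-time model: segment times, edge-expanded turn penalties, service
areas against brute-force enumeration, and population coverage."""

import math

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import clinic_at, enumerate_arrival_times, lattice_network, line_network
from raredx.access import (Clinic, Node, RoadSegment, TurnPenaltyTable,
                           assign_coverage, build_travel_graph,
                           compute_service_area, coverage_profile,
                           segment_travel_time)
from raredx.errors import ConfigurationError, DataError
from raredx.prevalence import CensusUnit


def seg(**kw):
    base = dict(segment_id="s", from_node="a", to_node="b", length_m=1000.0,
                speed_kmh=60.0, road_class="local")
    base.update(kw)
    return RoadSegment(**base)


# ------------------------------------------------------------ segment time

@pytest.mark.parametrize("length,speed,rise,beta,expected", [
    (1000.0, 60.0, 0.0, 2.0, 60.0),      # flat: pure unit conversion
    (500.0, 30.0, 0.0, 0.0, 60.0),
    (1000.0, 60.0, 50.0, 2.0, 66.0),     # 5% climb, beta=2: +10%
    (1000.0, 60.0, -50.0, 2.0, 60.0),    # downhill is free
    (1000.0, 60.0, 50.0, 0.0, 60.0),     # beta=0 disables elevation
])
def test_segment_travel_time(length, speed, rise, beta, expected):
    s = seg(length_m=length, speed_kmh=speed)
    assert segment_travel_time(s, 100.0, 100.0 + rise, beta) == pytest.approx(expected)


@settings(derandomize=True, max_examples=200)
@given(length=st.floats(1.0, 1e5), speed=st.floats(5.0, 120.0),
       rise=st.floats(-500.0, 500.0), beta=st.floats(0.0, 10.0))
def test_segment_time_closed_form_property(length, speed, rise, beta):
    """Traversal time equals the closed form, is strictly positive, and
    never decreases with extra climb."""
    s = seg(length_m=length, speed_kmh=speed)
    t = segment_travel_time(s, 0.0, rise, beta)
    expected = 3.6 * length / speed * (1 + beta * max(0.0, rise / length))
    assert t == pytest.approx(expected, rel=1e-12)
    assert t > 0
    assert segment_travel_time(s, 0.0, rise + 10.0, beta) >= t


def test_segment_validation():
    with pytest.raises(DataError):
        seg(length_m=0.0)
    with pytest.raises(DataError):
        seg(speed_kmh=-5.0)


# ----------------------------------------------------------- penalty table

def test_turn_penalty_table_contracts():
    t = TurnPenaltyTable()
    assert t("left", "primary") == 30.0
    with pytest.raises(ConfigurationError):
        TurnPenaltyTable({("straight", "local"): 5.0})  # incomplete
    with pytest.raises(ConfigurationError):
        TurnPenaltyTable({(m, c): 60.0 for m in ("straight", "right", "left")
                          for c in ("primary", "secondary", "local")})
    assert TurnPenaltyTable.zero()("left", "primary") == 0.0


# ------------------------------------------------------------ travel graph

def test_oneway_segment_has_single_state():
    nodes, segments = line_network([60.0, 60.0])
    segments[0] = seg(segment_id="s0", from_node="n0", to_node="n1",
                      length_m=segments[0].length_m, oneway="forward_only")
    g = build_travel_graph(nodes, segments, TurnPenaltyTable.zero())
    assert ("s0", "F") in g.state_time
    assert ("s0", "R") not in g.state_time


def test_dangling_endpoint_rejected():
    nodes, segments = line_network([60.0])
    segments.append(seg(segment_id="sX", from_node="n1", to_node="missing"))
    with pytest.raises(DataError):
        build_travel_graph(nodes, segments)


def test_unpenalized_model_reduces_to_plain_shortest_paths():
    """With all turn penalties 0 and beta=0, edge-expanded times equal
    ordinary node-graph shortest paths on a 4x4 lattice."""
    nodes, segments = lattice_network(4, 4)
    g = build_travel_graph(nodes, segments, TurnPenaltyTable.zero(), grade_beta=0.0)
    plain = nx.Graph()
    for s in segments:
        plain.add_edge(s.from_node, s.to_node,
                       weight=3.6 * s.length_m / s.speed_kmh)
    for origin in ("n0_0", "n1_2", "n3_3"):
        want = nx.single_source_dijkstra_path_length(plain, origin, weight="weight")
        got = g.arrival_times([clinic_at(nodes, origin)])
        assert set(got) == set(want)
        for n in want:
            assert got[n] == pytest.approx(want[n], abs=1e-9)


def test_two_left_turns_hand_summed():
    """A staircase path with two left turns onto local roads costs the sum
    of segment times plus two 15 s left-onto-local penalties."""
    nodes = [Node("a", 0, 0, 0), Node("b", 1000, 0, 0),
             Node("c", 1000, 1000, 0), Node("d", 0, 1000, 0)]
    segments = [seg(segment_id="s0", from_node="a", to_node="b"),
                seg(segment_id="s1", from_node="b", to_node="c"),
                seg(segment_id="s2", from_node="c", to_node="d")]
    g = build_travel_graph(nodes, segments)  # default penalties: left/local = 15
    times = g.arrival_times([clinic_at(nodes, "a")])
    assert times["d"] == pytest.approx(60.0 * 3 + 15.0 * 2)


def test_line_graph_cumulative_sums_and_enumeration():
    per_edge = [50.0, 70.0, 30.0, 90.0]
    nodes, segments = line_network(per_edge)
    g = build_travel_graph(nodes, segments, TurnPenaltyTable.zero())
    clinic = [clinic_at(nodes, "n0")]
    times = g.arrival_times(clinic)
    cum = 0.0
    for i, t in enumerate(per_edge):
        cum += t
        assert times[f"n{i+1}"] == pytest.approx(cum)
    assert times == pytest.approx(enumerate_arrival_times(g, clinic))


@pytest.mark.parametrize("rows,cols", [(2, 2), (2, 3), (2, 4)])
def test_enumeration_oracle_on_small_lattices(rows, cols):
    """Dijkstra on the edge-expanded graph equals exhaustive simple-path
    enumeration, including turn penalties and elevation grades."""
    elev = {(r, c): 30.0 * ((r + c) % 3) for r in range(rows) for c in range(cols)}
    nodes, segments = lattice_network(rows, cols, elevations=elev)
    g = build_travel_graph(nodes, segments)  # default penalties, beta=2
    clinics = [clinic_at(nodes, "n0_0"), clinic_at(nodes, f"n{rows-1}_{cols-1}", "c1")]
    got = g.arrival_times(clinics)
    want = enumerate_arrival_times(g, clinics)
    assert set(got) == set(want)
    for n in want:
        assert got[n] == pytest.approx(want[n], abs=1e-9)


# ------------------------------------------------------------ service area

def _simple_world():
    nodes, segments = lattice_network(3, 3)
    g = build_travel_graph(nodes, segments, TurnPenaltyTable.zero())
    return nodes, g


def test_tiny_threshold_reaches_only_clinic_anchor():
    nodes, g = _simple_world()
    area = compute_service_area(g, [clinic_at(nodes, "n1_1")], 1e-6)
    assert area.reachable == {"n1_1": 0.0}


def test_multi_source_equals_union_of_single_sources():
    nodes, g = _simple_world()
    c0, c1 = clinic_at(nodes, "n0_0", "c0"), clinic_at(nodes, "n2_2", "c1")
    t = 90.0
    multi = compute_service_area(g, [c0, c1], t).reachable
    a = compute_service_area(g, [c0], t).reachable
    b = compute_service_area(g, [c1], t).reachable
    assert set(multi) == set(a) | set(b)
    for n in multi:
        assert multi[n] == pytest.approx(min(a.get(n, math.inf), b.get(n, math.inf)))


def test_service_area_nesting_and_threshold_independence():
    nodes, g = _simple_world()
    c = [clinic_at(nodes, "n0_0")]
    small = compute_service_area(g, c, 60.0)
    large = compute_service_area(g, c, 200.0)
    assert set(small.reachable) <= set(large.reachable)
    for n, t in small.reachable.items():
        assert large.reachable[n] == t  # arrival times don't depend on threshold


def test_adding_clinic_never_increases_times():
    nodes, segments = lattice_network(3, 3)
    g = build_travel_graph(nodes, segments)
    one = g.arrival_times([clinic_at(nodes, "n0_0")])
    two = g.arrival_times([clinic_at(nodes, "n0_0"), clinic_at(nodes, "n2_2", "c1")])
    for n, t in one.items():
        assert two[n] <= t + 1e-12


def test_raising_turn_penalty_never_decreases_times():
    nodes, segments = lattice_network(3, 3)
    base = build_travel_graph(nodes, segments)
    bumped_table = dict(TurnPenaltyTable().items())
    bumped_table[("left", "local")] = 30.0
    bumped = build_travel_graph(nodes, segments, TurnPenaltyTable(bumped_table))
    c = [clinic_at(nodes, "n0_0")]
    t0, t1 = base.arrival_times(c), bumped.arrival_times(c)
    for n in t0:
        assert t1[n] >= t0[n] - 1e-12


def test_unknown_clinic_anchor_rejected():
    nodes, g = _simple_world()
    with pytest.raises(DataError):
        g.arrival_times([Clinic("cX", "nope", 0.0, 0.0)])


# ---------------------------------------------------------------- coverage

def _unit(uid, pop, x, y):
    return CensusUnit(unit_id=uid, unit_type="DA", centroid=(x, y),
                      population_by_decade={"20-29": pop})


def test_coverage_fixture_arithmetic():
    """Only the 600-person unit sits on a reachable node: 60% coverage."""
    nodes, g = _simple_world()
    area = compute_service_area(g, [clinic_at(nodes, "n0_0")], 1e-6)
    units = [_unit("a", 100, 50_000.0, 0.0), _unit("b", 300, 0.0, 50_000.0),
             _unit("c", 600, 0.0, 0.0)]
    cov = assign_coverage(area, units, snap_radius_m=500.0)
    assert (cov.covered_population, cov.total_population) == (600, 1000)
    assert cov.percent == pytest.approx(60.0)


def test_coverage_extremes():
    nodes, g = _simple_world()
    area = compute_service_area(g, [clinic_at(nodes, "n0_0")], 10_000.0)
    on_nodes = [_unit(n.node_id, 10, n.x, n.y) for n in nodes]
    assert assign_coverage(area, on_nodes).percent == pytest.approx(100.0)

    empty = compute_service_area(g, [clinic_at(nodes, "n0_0")], 1e-6)
    far = [_unit("far", 10, 9e6, 9e6)]
    assert assign_coverage(empty, far).percent == 0.0

    with pytest.raises(ConfigurationError):
        assign_coverage(area, on_nodes, snap_radius_m=-1.0)


def test_coverage_profile_monotone_and_validated():
    nodes, segments = lattice_network(3, 3)
    g = build_travel_graph(nodes, segments)
    units = [_unit(n.node_id, 10, n.x, n.y) for n in nodes]
    c = [clinic_at(nodes, "n0_0")]
    profile = coverage_profile(g, c, [30.0, 120.0, 600.0], units)
    pcts = [p.percent for p in profile]
    assert pcts == sorted(pcts)
    assert profile[-1].percent == pytest.approx(100.0)

    with pytest.raises(ConfigurationError):
        coverage_profile(g, c, [120.0, 60.0], units)
    with pytest.raises(ConfigurationError):
        coverage_profile(g, c, [60.0, 60.0], units)
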