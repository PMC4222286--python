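"""Drive-time accessibility model for specialist clinics.

Travel times are modelled on a road network: per-segment times from speed
limit, length and (uphill-only) elevation change; one-way restrictions; and
fixed intersection turn impedances that depend on the maneuver (straight,
right, left) and the class of road being entered.  Service areas are the
sets of network nodes reachable from any clinic within a time threshold,
and population coverage counts the census units whose centroid lies near a
reachable node.

The network is evaluated on an *edge-expanded* (line-graph) representation:
the states of the shortest-path problem are directed traversals of road
segments, so that the cost of entering a segment can include the turn
penalty implied by the previous segment's bearing.  Any exact non-negative
shortest-path method is acceptable; Dijkstra via networkx is used here.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError, DataError

ROAD_CLASSES = ("primary", "secondary", "local")
MANEUVERS = ("straight", "right", "left")

#: Default speed limit (km/h) by road class, non-rush-hour.
DEFAULT_SPEED_BY_CLASS = {"primary": 80.0, "secondary": 60.0, "local": 40.0}

#: Default intersection impedances (seconds), keyed by (maneuver, entered
#: road class).  Values respect the conventional 5-30 s range and increase
#: with maneuver difficulty and road class.
DEFAULT_TURN_PENALTIES: dict[tuple[str, str], float] = {
    ("straight", "local"): 5.0, ("right", "local"): 10.0, ("left", "local"): 15.0,
    ("straight", "secondary"): 10.0, ("right", "secondary"): 20.0, ("left", "secondary"): 25.0,
    ("straight", "primary"): 15.0, ("right", "primary"): 25.0, ("left", "primary"): 30.0,
}


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Node:
    """A network intersection with planar metre coordinates and elevation."""
    node_id: str
    x: float
    y: float
    elevation_m: float = 0.0


@dataclass(frozen=True)
class RoadSegment:
    """A travel edge between two intersections.

    ``oneway`` is one of ``both`` (two-way), ``forward_only`` (from->to) or
    ``reverse_only`` (to->from).
    """
    segment_id: str
    from_node: str
    to_node: str
    length_m: float
    speed_kmh: float
    road_class: str
    oneway: str = "both"

    def __post_init__(self) -> None:
        if self.length_m <= 0:
            raise DataError(f"segment {self.segment_id}: length_m must be positive")
        if self.speed_kmh <= 0:
            raise DataError(f"segment {self.segment_id}: speed_kmh must be positive")
        if self.road_class not in ROAD_CLASSES:
            raise DataError(f"segment {self.segment_id}: unknown road class {self.road_class!r}")
        if self.oneway not in ("both", "forward_only", "reverse_only"):
            raise DataError(f"segment {self.segment_id}: unknown oneway value {self.oneway!r}")


@dataclass(frozen=True)
class Clinic:
    """A specialist clinic anchored to a network node."""
    clinic_id: str
    node_id: str
    x: float
    y: float


class TurnPenaltyTable:
    """Complete table of intersection impedances.

    Maps (maneuver, entered road class) to a penalty in seconds.  All nine
    entries must be present; values outside the conventional [5, 30] s range
    are rejected unless ``allow_out_of_range`` is set (used e.g. to switch
    penalties off entirely).
    """

    def __init__(self, penalties: Mapping[tuple[str, str], float] | None = None,
                 allow_out_of_range: bool = False):
        table = dict(DEFAULT_TURN_PENALTIES if penalties is None else penalties)
        expected = {(m, c) for m in MANEUVERS for c in ROAD_CLASSES}
        missing = expected - set(table)
        if missing:
            raise ConfigurationError(f"turn-penalty table incomplete; missing {sorted(missing)}")
        for key, sec in table.items():
            if key not in expected:
                raise ConfigurationError(f"unknown turn-penalty key {key!r}")
            if sec < 0:
                raise ConfigurationError(f"negative turn penalty for {key!r}")
            if not allow_out_of_range and not (5.0 <= sec <= 30.0):
                raise ConfigurationError(
                    f"turn penalty {sec}s for {key!r} outside [5, 30]; "
                    "pass allow_out_of_range=True to override")
        self._table = table

    @classmethod
    def zero(cls) -> "TurnPenaltyTable":
        """A table with every impedance set to 0 (unpenalized model)."""
        return cls({(m, c): 0.0 for m in MANEUVERS for c in ROAD_CLASSES},
                   allow_out_of_range=True)

    def __call__(self, maneuver: str, road_class: str) -> float:
        return self._table[(maneuver, road_class)]

    def items(self):
        return self._table.items()

    def __eq__(self, other) -> bool:
        return isinstance(other, TurnPenaltyTable) and self._table == other._table


@dataclass
class ServiceArea:
    """Nodes reachable from any source clinic within a time threshold.

    ``node_coords`` carries the planar coordinates of the reachable nodes so
    coverage can be assigned without re-consulting the travel graph.
    """
    threshold_s: float
    reachable: dict[str, float]          # node_id -> minimal arrival time (s)
    clinics: frozenset[str]              # source clinic ids
    node_coords: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {n: t for n, t in self.reachable.items() if t > self.threshold_s}
        if bad:
            raise DataError(f"arrival times exceed threshold for nodes {sorted(bad)}")


@dataclass
class CoverageResult:
    """Population coverage of one service-area threshold."""
    threshold_s: float
    covered_population: int
    total_population: int

    @property
    def percent(self) -> float:
        if self.total_population == 0:
            return 0.0
        return 100.0 * self.covered_population / self.total_population


# --------------------------------------------------------------------------
# per-segment travel time
# --------------------------------------------------------------------------

def segment_travel_time(segment: RoadSegment, elev_from: float, elev_to: float,
                        grade_beta: float = 2.0) -> float:
    """Directed traversal time of one segment, in seconds.

    Base time is length over speed limit; a positive (uphill) grade
    multiplies the time by ``1 + grade_beta * grade``, downhill travel is
    not rewarded.  With the default ``grade_beta=2`` a 5% climb adds 10% to
    the traversal time; ``grade_beta=0`` disables the elevation effect.
    """
    if segment.length_m <= 0 or segment.speed_kmh <= 0:
        raise DataError(f"segment {segment.segment_id}: non-positive length or speed")
    if grade_beta < 0:
        raise ConfigurationError("grade_beta must be >= 0")
    base = 3.6 * segment.length_m / segment.speed_kmh
    grade = max(0.0, (elev_to - elev_from) / segment.length_m)
    return base * (1.0 + grade_beta * grade)


# --------------------------------------------------------------------------
# edge-expanded travel graph
# --------------------------------------------------------------------------

def _classify_maneuver(turn_deg: float) -> str | None:
    """Classify a signed turn angle (degrees, counterclockwise positive).

    |angle| <= 30 is straight; (30, 150] is a left turn; [-150, -30) a right
    turn; sharper than 150 degrees is a reversal, which is forbidden (no
    transition), so same-segment U-turns never occur.
    """
    if abs(turn_deg) <= 30.0:
        return "straight"
    if 30.0 < turn_deg <= 150.0:
        return "left"
    if -150.0 <= turn_deg < -30.0:
        return "right"
    return None


class TravelGraph:
    """Edge-expanded directed travel graph.

    States are directed segment traversals ``(segment_id, 'F'|'R')``; the
    cost of a transition between consecutive traversals is the arriving
    segment's travel time plus the turn penalty for the maneuver and the
    class of road entered.  One-way segments contribute a single state.
    """

    def __init__(self, nodes: Sequence[Node], segments: Sequence[RoadSegment],
                 penalties: TurnPenaltyTable | None = None, grade_beta: float = 2.0):
        self.penalties = penalties if penalties is not None else TurnPenaltyTable()
        self.grade_beta = grade_beta
        self.nodes: dict[str, Node] = {n.node_id: n for n in nodes}
        if len(self.nodes) != len(nodes):
            raise DataError("duplicate node ids in network")
        self.segments: dict[str, RoadSegment] = {s.segment_id: s for s in segments}

        self.state_time: dict[tuple[str, str], float] = {}
        self.state_tail: dict[tuple[str, str], str] = {}
        self.state_head: dict[tuple[str, str], str] = {}
        self._bearing: dict[tuple[str, str], float] = {}
        self.states_out: dict[str, list[tuple[str, str]]] = defaultdict(list)
        self.states_in: dict[str, list[tuple[str, str]]] = defaultdict(list)

        for seg in segments:
            for end in (seg.from_node, seg.to_node):
                if end not in self.nodes:
                    raise DataError(f"segment {seg.segment_id}: dangling endpoint {end!r}")
            a, b = self.nodes[seg.from_node], self.nodes[seg.to_node]
            directions = []
            if seg.oneway in ("both", "forward_only"):
                directions.append(("F", a, b))
            if seg.oneway in ("both", "reverse_only"):
                directions.append(("R", b, a))
            for tag, tail, head in directions:
                state = (seg.segment_id, tag)
                self.state_time[state] = segment_travel_time(
                    seg, tail.elevation_m, head.elevation_m, grade_beta)
                self.state_tail[state] = tail.node_id
                self.state_head[state] = head.node_id
                self._bearing[state] = math.degrees(
                    math.atan2(head.y - tail.y, head.x - tail.x))
                self.states_out[tail.node_id].append(state)
                self.states_in[head.node_id].append(state)

        self.G = nx.DiGraph()
        self.G.add_nodes_from(self.state_time)
        for u, t_u in self.state_time.items():
            junction = self.state_head[u]
            for v in self.states_out[junction]:
                turn = (self._bearing[v] - self._bearing[u] + 180.0) % 360.0 - 180.0
                maneuver = _classify_maneuver(turn)
                if maneuver is None:
                    continue  # reversal forbidden
                cls = self.segments[v[0]].road_class
                cost = self.state_time[v] + self.penalties(maneuver, cls)
                self.G.add_edge(u, v, weight=cost)

    # -- shortest paths ---------------------------------------------------
    def arrival_times(self, clinics: Iterable[Clinic]) -> dict[str, float]:
        """Minimal drive time (s) from any clinic to every reachable node.

        Multi-source: all clinic anchor nodes start at time 0; entering the
        first segment costs its travel time but no turn penalty.
        """
        clinics = list(clinics)
        for c in clinics:
            if c.node_id not in self.nodes:
                raise DataError(f"clinic {c.clinic_id} anchored to unknown node {c.node_id!r}")
        if not clinics:
            return {}
        src = ("__source__", "")
        G = self.G.copy()
        for c in clinics:
            for s in self.states_out[c.node_id]:
                w = self.state_time[s]
                prev = G.get_edge_data(src, s)
                if prev is None or w < prev["weight"]:
                    G.add_edge(src, s, weight=w)
        dist = nx.single_source_dijkstra_path_length(G, src, weight="weight")
        times: dict[str, float] = {c.node_id: 0.0 for c in clinics}
        for state, d in dist.items():
            if state == src:
                continue
            head = self.state_head[state]
            if d < times.get(head, math.inf):
                times[head] = d
        return times


def build_travel_graph(nodes: Sequence[Node], segments: Sequence[RoadSegment],
                       penalties: TurnPenaltyTable | None = None,
                       grade_beta: float = 2.0) -> TravelGraph:
    """Construct the edge-expanded travel graph (see :class:`TravelGraph`)."""
    return TravelGraph(nodes, segments, penalties, grade_beta)


def compute_service_area(graph: TravelGraph, clinics: Sequence[Clinic],
                         threshold_s: float,
                         _times: Mapping[str, float] | None = None) -> ServiceArea:
    """Nodes reachable from any clinic within ``threshold_s`` seconds.

    Multi-source union semantics: the result equals the node-wise union of
    per-clinic service areas.  ``_times`` lets callers reuse a precomputed
    arrival-time map (arrival times do not depend on the threshold).
    """
    if threshold_s <= 0:
        raise ConfigurationError("threshold_s must be positive")
    times = dict(_times) if _times is not None else graph.arrival_times(clinics)
    reachable = {n: t for n, t in times.items() if t <= threshold_s}
    coords = {n: (graph.nodes[n].x, graph.nodes[n].y) for n in reachable}
    return ServiceArea(threshold_s=threshold_s, reachable=reachable,
                       clinics=frozenset(c.clinic_id for c in clinics),
                       node_coords=coords)


def assign_coverage(area: ServiceArea, units: Sequence,
                    snap_radius_m: float = 500.0) -> CoverageResult:
    """Population coverage of a service area over census-unit centroids.

    A unit is covered iff its centroid lies within ``snap_radius_m``
    (Euclidean, planar metres) of at least one reachable network node; the
    covered population is the sum of covered units' adult populations, and
    the percentage is taken against the adult population of *all* units.
    """
    if snap_radius_m < 0:
        raise ConfigurationError("snap_radius_m must be non-negative")
    total = int(sum(u.adult_population for u in units))
    if not area.reachable:
        return CoverageResult(area.threshold_s, 0, total)
    node_xy = np.array([area.node_coords[n] for n in area.reachable], dtype=float)
    tree = cKDTree(node_xy)
    covered = 0
    for u in units:
        d, _ = tree.query([u.centroid[0], u.centroid[1]])
        if d <= snap_radius_m:
            covered += int(u.adult_population)
    return CoverageResult(area.threshold_s, covered, total)


def coverage_profile(graph: TravelGraph, clinics: Sequence[Clinic],
                     thresholds_s: Sequence[float], units: Sequence,
                     snap_radius_m: float = 500.0) -> list[CoverageResult]:
    """One CoverageResult per threshold from a single shortest-path pass.

    Arrival times are computed once and thresholded repeatedly; the
    resulting coverage percentages are non-decreasing in the threshold.
    """
    thresholds = list(thresholds_s)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ConfigurationError("thresholds must be strictly increasing")
    times = graph.arrival_times(clinics)
    results = []
    for t in thresholds:
        area = compute_service_area(graph, clinics, t, _times=times)
        results.append(assign_coverage(area, units, snap_radius_m))
    return results
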