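"""Shared fixtures-in-code for the test suite: tiny hand-built networks and
independent brute-force oracles kept free of the implementation's shortest
path machinery."""

from __future__ import annotations

import math

from raredx.access import Clinic, Node, RoadSegment, TravelGraph


def line_network(times_s, speed_kmh=60.0, road_class="local"):
    """A straight west-east line of nodes whose per-segment travel times (at
    zero grade) equal ``times_s`` exactly.  Returns (nodes, segments)."""
    nodes = [Node("n0", 0.0, 0.0, 0.0)]
    segments = []
    x = 0.0
    for i, t in enumerate(times_s):
        length = t * speed_kmh / 3.6
        x += length
        nodes.append(Node(f"n{i+1}", x, 0.0, 0.0))
        segments.append(RoadSegment(f"s{i}", f"n{i}", f"n{i+1}", length,
                                    speed_kmh, road_class))
    return nodes, segments


def lattice_network(rows, cols, cell=1000.0, speed_kmh=60.0, road_class="local",
                    elevations=None):
    """A flat rows x cols lattice with uniform segments (no jitter)."""
    nodes = []
    for r in range(rows):
        for c in range(cols):
            elev = 0.0 if elevations is None else elevations.get((r, c), 0.0)
            nodes.append(Node(f"n{r}_{c}", c * cell, r * cell, elev))
    segments = []
    k = 0
    for r in range(rows):
        for c in range(cols):
            for dr, dc in ((0, 1), (1, 0)):
                rr, cc = r + dr, c + dc
                if rr < rows and cc < cols:
                    segments.append(RoadSegment(
                        f"s{k}", f"n{r}_{c}", f"n{rr}_{cc}", cell, speed_kmh, road_class))
                    k += 1
    return nodes, segments


def clinic_at(nodes, node_id, clinic_id="c0"):
    n = {x.node_id: x for x in nodes}[node_id]
    return Clinic(clinic_id, node_id, n.x, n.y)


def enumerate_arrival_times(graph: TravelGraph, clinics) -> dict[str, float]:
    """Exhaustive simple-path enumeration over the edge-expanded state
    space.  Independent of Dijkstra: explores every simple state path from
    every clinic's outgoing traversal and records the best arrival time per
    node.  Only usable on small graphs."""
    best: dict[str, float] = {c.node_id: 0.0 for c in clinics}

    def visit(state, cost, on_path):
        head = graph.state_head[state]
        if cost < best.get(head, math.inf):
            best[head] = cost
        for nxt in graph.G.successors(state):
            if nxt in on_path:
                continue
            visit(nxt, cost + graph.G[state][nxt]["weight"], on_path | {nxt})

    for c in clinics:
        for s in graph.states_out[c.node_id]:
            visit(s, graph.state_time[s], frozenset({s}))
    return best


def chi_square_oracle(count_a, pop_a, count_b, pop_b) -> float:
    """Textbook Pearson statistic sum((O-E)^2 / E) on the 2x2 table."""
    obs = [[count_a, pop_a - count_a], [count_b, pop_b - count_b]]
    n = pop_a + pop_b
    col = [obs[0][0] + obs[1][0], obs[0][1] + obs[1][1]]
    row = [pop_a, pop_b]
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = row[i] * col[j] / n
            stat += (obs[i][j] - e) ** 2 / e
    return stat


def ols_oracle(x, y):
    """Closed-form normal-equations OLS: slope, intercept, r_squared."""
    n = len(x)
    sx = sum(x); sy = sum(y)
    sxx = sum(v * v for v in x); sxy = sum(a * b for a, b in zip(x, y))
    syy = sum(v * v for v in y)
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    ss_tot = syy - sy * sy / n
    ss_res = sum((yi - slope * xi - intercept) ** 2 for xi, yi in zip(x, y))
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return slope, intercept, r2
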