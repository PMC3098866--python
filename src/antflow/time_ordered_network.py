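"""Time-ordered interaction networks and their windowed aggregations.

A time-ordered network has one node per (individual, event time) at which
that individual participates, plus virtual start/end nodes at t = 0 and
t = duration; directed temporal links join an individual to itself at
successive times and an undirected interaction link joins the two
participants of each event.  Paths that move forward along temporal links
and across interaction links are exactly the causally permitted routes for
information flow (no back-propagation in time).

Aggregating events within a window collapses this structure to a static
weighted graph (:class:`TimeAggregatedNetwork`) on which the classical
metrics — unique-partner in/out-degree, betweenness, diameter — are defined.
"""

from __future__ import annotations

import csv
from bisect import bisect_left, bisect_right
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .event_io import EventLog, InteractionEvent

__all__ = [
    "TimeOrderedNetwork",
    "TimeAggregatedNetwork",
    "build_time_ordered",
    "aggregate",
    "degree_distribution_over_windows",
    "write_edge_list",
    "write_graphml",
]


@dataclass(frozen=True)
class TimeOrderedNetwork:
    """Event log viewed as a time-ordered graph.

    The node/link structure is implicit in the sorted event sequence; the
    flow and latency algorithms sweep the events directly, and
    :meth:`to_graph` materialises the explicit graph when needed (e.g. for
    drawing or cross-checks).
    """

    log: EventLog

    @property
    def individuals(self) -> tuple[str, ...]:
        return self.log.metadata.individuals

    @property
    def m(self) -> int:
        return self.log.metadata.m

    @property
    def duration(self) -> float:
        return self.log.metadata.duration

    @property
    def events(self) -> tuple[InteractionEvent, ...]:
        return self.log.events

    def event_times(self) -> np.ndarray:
        return self.log.times()

    def groups_by_time(self) -> list[tuple[float, list[InteractionEvent]]]:
        """Events grouped by identical timestamp, in time order."""
        groups: list[tuple[float, list[InteractionEvent]]] = []
        for e in self.events:
            if groups and groups[-1][0] == e.time:
                groups[-1][1].append(e)
            else:
                groups.append((e.time, [e]))
        return groups

    def to_graph(self) -> nx.DiGraph:
        """Materialise the explicit time-ordered graph.

        Nodes are ``(individual, time)`` pairs including virtual start and
        end nodes at t = 0 and t = duration.  Temporal links are directed
        edges with ``kind='temporal'``; each interaction contributes a pair
        of antiparallel directed edges with ``kind='interaction'`` (the
        undirected link, traversable both ways).
        """
        g = nx.DiGraph()
        times: dict[str, list[float]] = {i: [0.0] for i in self.individuals}
        for e in self.events:
            for who in (e.initiator, e.target):
                if times[who][-1] != e.time:
                    times[who].append(e.time)
        for i in self.individuals:
            if times[i][-1] != self.duration:
                times[i].append(self.duration)
            for t0, t1 in zip(times[i], times[i][1:]):
                g.add_edge((i, t0), (i, t1), kind="temporal")
            if len(times[i]) == 1:  # duration == 0 degenerate case
                g.add_node((i, times[i][0]))
        for e in self.events:
            g.add_edge((e.initiator, e.time), (e.target, e.time), kind="interaction")
            g.add_edge((e.target, e.time), (e.initiator, e.time), kind="interaction")
        return g

    def aggregate(self, t0: float, t1: float) -> "TimeAggregatedNetwork":
        return aggregate(self, t0, t1)


@dataclass(frozen=True)
class TimeAggregatedNetwork:
    """Static weighted graph of interactions within a window.

    ``directed_weights[(i, j)]`` counts events with initiator i and target
    j in the window; the undirected edge weight is the sum of both
    directions.  The window is half-open ``[t0, t1)`` except that the full
    aggregation ``[0, duration]`` also includes events at exactly
    t = duration.
    """

    individuals: tuple[str, ...]
    window: tuple[float, float]
    directed_weights: Mapping[tuple[str, str], int]
    queen: str | None = None

    @property
    def m(self) -> int:
        return len(self.individuals)

    @property
    def n_events(self) -> int:
        return sum(self.directed_weights.values())

    def undirected_weights(self) -> dict[frozenset, int]:
        out: Counter = Counter()
        for (i, j), w in self.directed_weights.items():
            out[frozenset((i, j))] += w
        return dict(out)

    def weight(self, i: str, j: str) -> int:
        """Undirected interaction count between i and j in the window."""
        return self.directed_weights.get((i, j), 0) + self.directed_weights.get((j, i), 0)

    def _check(self, individual: str) -> None:
        if individual not in self.individuals:
            raise KeyError(f"unknown individual {individual!r}")

    def out_degree(self, individual: str) -> int:
        """Number of unique individuals this one initiated contact with."""
        self._check(individual)
        return len({j for (i, j) in self.directed_weights if i == individual})

    def in_degree(self, individual: str) -> int:
        """Number of unique individuals that initiated contact with this one."""
        self._check(individual)
        return len({i for (i, j) in self.directed_weights if j == individual})

    def out_degrees(self) -> dict[str, int]:
        partners: dict[str, set] = {i: set() for i in self.individuals}
        for (i, j) in self.directed_weights:
            partners[i].add(j)
        return {i: len(s) for i, s in partners.items()}

    def in_degrees(self) -> dict[str, int]:
        partners: dict[str, set] = {i: set() for i in self.individuals}
        for (i, j) in self.directed_weights:
            partners[j].add(i)
        return {i: len(s) for i, s in partners.items()}

    def skeleton(self) -> nx.Graph:
        """Undirected unweighted graph with an edge wherever weight > 0.

        All roster individuals appear as nodes, including isolates.
        """
        g = nx.Graph()
        g.add_nodes_from(self.individuals)
        for pair in self.undirected_weights():
            i, j = tuple(pair)
            g.add_edge(i, j)
        return g

    def betweenness(self, individual: str) -> float:
        """Shortest-path betweenness on the unweighted skeleton.

        Normalised by (m-1)(m-2)/2, so a node on every geodesic of a path
        graph scores 1.
        """
        self._check(individual)
        return self.betweenness_all()[individual]

    def betweenness_all(self) -> dict[str, float]:
        return nx.betweenness_centrality(self.skeleton(), normalized=True)

    def diameter(self) -> int:
        """Longest shortest path (hops) on the largest connected component.

        Raises ``ValueError`` on an edgeless network, where the diameter is
        undefined.
        """
        skeleton = self.skeleton()
        if skeleton.number_of_edges() == 0:
            raise ValueError("diameter undefined for an edgeless network")
        component = max(nx.connected_components(skeleton), key=len)
        return nx.diameter(skeleton.subgraph(component))


def build_time_ordered(log: EventLog) -> TimeOrderedNetwork:
    """Wrap a validated event log as a time-ordered network."""
    return TimeOrderedNetwork(log)


def aggregate(net: TimeOrderedNetwork, t0: float, t1: float) -> TimeAggregatedNetwork:
    """Accumulate interactions within [t0, t1) into a static weighted graph.

    The window is half-open so that disjoint windows partition the events
    additively; as the single exception, aggregating the full recording
    (t0 = 0, t1 = duration) also counts events at exactly t = duration.
    """
    if not 0.0 <= t0 < t1 <= net.duration:
        raise ValueError(
            f"window must satisfy 0 <= t0 < t1 <= duration, got [{t0}, {t1})"
        )
    include_right = t1 == net.duration and t0 == 0.0
    weights: Counter = Counter()
    times = net.event_times()
    lo = bisect_left(times.tolist(), t0)
    hi = bisect_right(times.tolist(), t1) if include_right else bisect_left(times.tolist(), t1)
    for e in net.events[lo:hi]:
        weights[(e.initiator, e.target)] += 1
    return TimeAggregatedNetwork(
        individuals=net.individuals,
        window=(t0, t1),
        directed_weights=dict(weights),
        queen=net.log.metadata.queen,
    )


def degree_distribution_over_windows(
    net: TimeOrderedNetwork, fractions: Sequence[float]
) -> dict[float, dict]:
    """Out-degree histograms and means over growing aggregation windows.

    For each fraction f in (0, 1], aggregate [0, f * duration) (f = 1 uses
    the full recording including its final instant) and return
    ``{f: {"histogram": counts of length m, "mean": mean out-degree}}``.
    Because unique-partner sets only grow, means are non-decreasing in f.
    """
    if len(fractions) == 0:
        raise ValueError("fractions must be non-empty")
    if any(not 0.0 < f <= 1.0 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    out: dict[float, dict] = {}
    for f in sorted(fractions):
        agg = aggregate(net, 0.0, f * net.duration)
        degrees = np.array(list(agg.out_degrees().values()), dtype=int)
        histogram = np.bincount(degrees, minlength=net.m)
        out[f] = {"histogram": histogram, "mean": float(degrees.mean())}
    return out


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def write_edge_list(net: TimeAggregatedNetwork, path: str | Path) -> None:
    """Weighted edge list CSV: source,target,weight,directed_weight_st,directed_weight_ts.

    One row per undirected edge; ``source < target`` lexicographically and
    rows sorted for reproducibility.
    """
    rows = []
    for pair, w in net.undirected_weights().items():
        i, j = sorted(pair)
        rows.append(
            (i, j, w, net.directed_weights.get((i, j), 0), net.directed_weights.get((j, i), 0))
        )
    rows.sort()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "target", "weight", "directed_weight_st", "directed_weight_ts"])
        writer.writerows(rows)


def write_graphml(net: TimeAggregatedNetwork, path: str | Path) -> None:
    """Export the weighted undirected graph (isolates included) as GraphML."""
    g = nx.Graph()
    g.add_nodes_from(net.individuals)
    for pair, w in net.undirected_weights().items():
        i, j = sorted(pair)
        g.add_edge(
            i,
            j,
            weight=w,
            directed_weight_st=net.directed_weights.get((i, j), 0),
            directed_weight_ts=net.directed_weights.get((j, i), 0),
        )
    nx.write_graphml(g, path)
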