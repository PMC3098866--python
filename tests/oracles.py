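"""Independent brute-force oracles for the causal-flow algorithms.

These deliberately avoid the package's sweep implementations: reachability
is solved by fixed-point relaxation over explicit strictly-increasing-time
relay rules, latencies by exhaustive enumeration of time-respecting paths,
and the aggregated-network metrics by naive tallies / path enumeration.
"""

import itertools
import math

import networkx as nx


def reachability_oracle(log, focal, lag):
    """Set of individuals informed within ``lag`` of the focal seed.

    Fixed-point relaxation of earliest-informed times: a carrier informed
    strictly before an event's timestamp (or the focal individual at or
    after its seed time) relays across that event.
    """
    who, t0 = focal
    earliest = {i: math.inf for i in log.metadata.individuals}
    earliest[who] = t0
    changed = True
    while changed:
        changed = False
        for e in log.events:
            if e.time < t0 or e.time > t0 + lag:
                continue
            for a, b in ((e.initiator, e.target), (e.target, e.initiator)):
                can_relay = earliest[a] < e.time or (a == who and t0 <= e.time)
                if can_relay and e.time < earliest[b]:
                    earliest[b] = e.time
                    changed = True
    return {i for i, t in earliest.items() if t <= t0 + lag}


def latency_oracle(log, eval_time):
    """Latency matrix by exhaustive time-respecting-path enumeration.

    latency(i, j) = eval_time - (latest first-event time over paths
    j -> ... -> i with strictly increasing event times).  Only feasible for
    tiny logs (m <= 6, E <= 12).
    """
    events = [e for e in log.events if e.time <= eval_time]
    roster = log.metadata.individuals

    def best_start(j, i):
        # maximise the first event's time over all causal paths j -> i
        best = -math.inf

        def extend(carrier, after, start):
            nonlocal best
            if carrier == i:
                best = max(best, start)
                return
            if start <= best:
                return  # cannot improve
            for e in events:
                if e.time <= after:
                    continue
                if carrier == e.initiator:
                    extend(e.target, e.time, start)
                elif carrier == e.target:
                    extend(e.initiator, e.time, start)

        for e in events:
            partner = None
            if e.initiator == j:
                partner = e.target
            elif e.target == j:
                partner = e.initiator
            if partner is None:
                continue
            if partner == i:
                best = max(best, e.time)
            else:
                extend(partner, e.time, e.time)
        return best

    matrix = {}
    for i in roster:
        for j in roster:
            if i == j:
                matrix[(i, j)] = 0.0
            else:
                start = best_start(j, i)
                matrix[(i, j)] = eval_time - start if start > -math.inf else math.inf
    return matrix


def aggregate_oracle(log, t0, t1, include_right=False):
    """Naive tally of directed event counts within the window."""
    counts = {}
    for e in log.events:
        inside = t0 <= e.time < t1 or (include_right and e.time == t1)
        if inside:
            counts[(e.initiator, e.target)] = counts.get((e.initiator, e.target), 0) + 1
    return counts


def degree_oracle(log, t0, t1, include_right=False):
    """Unique-partner out/in degrees by brute-force set construction."""
    out = {i: set() for i in log.metadata.individuals}
    into = {i: set() for i in log.metadata.individuals}
    for e in log.events:
        inside = t0 <= e.time < t1 or (include_right and e.time == t1)
        if inside:
            out[e.initiator].add(e.target)
            into[e.target].add(e.initiator)
    return (
        {i: len(s) for i, s in out.items()},
        {i: len(s) for i, s in into.items()},
    )


def betweenness_oracle(graph, m):
    """Normalised betweenness by enumerating all shortest paths.

    Uses plain path enumeration (nx.all_simple_paths as a graph-walk
    utility only); independent of Brandes' algorithm.
    """
    nodes = list(graph.nodes)
    scores = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        try:
            d = nx.shortest_path_length(graph, s, t)
        except nx.NetworkXNoPath:
            continue
        paths = [
            p for p in nx.all_simple_paths(graph, s, t, cutoff=d) if len(p) - 1 == d
        ]
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            scores[v] += through / len(paths)
    norm = (m - 1) * (m - 2) / 2.0
    if norm == 0:
        return {v: 0.0 for v in scores}
    return {v: score / norm for v, score in scores.items()}
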