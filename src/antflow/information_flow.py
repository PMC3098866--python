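"""Causal information flow on time-ordered networks.

Two complementary measures:

* **Reachability tracing** — seed a message at a focal (individual, time)
  and sweep forward through the event sequence; at every interaction where
  exactly one participant already carries the message, the other acquires
  it.  The informed count n(t) is an upper bound on information spread
  assuming perfect transmission at every contact.

* **Vector-clock latencies** — for every ordered pair (i, j) at evaluation
  time t, the elapsed time since the freshest information originating at j
  that could have causally reached i.  Maintained with the classic
  vector-clock update: when a and b interact at time s, each learns the
  other's clock component-wise (phi_a(b) = phi_b(a) = s, then both take the
  component maximum).

Simultaneous events are handled conservatively: a message traverses at most
one interaction link per distinct timestamp, i.e. causal paths must use
strictly increasing event times.  Both algorithms implement this by
processing equal-timestamp events against the state snapshot taken before
the timestamp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps
import statsmodels.api as sm

from .event_io import EventLog
from .time_ordered_network import TimeOrderedNetwork

__all__ = [
    "FlowTrace",
    "FlowCurves",
    "LatencyMatrix",
    "trace_reachability",
    "sample_flow_curves",
    "vector_clock_latencies",
    "receiver_mean_latencies",
    "grand_mean_latency",
    "individual_quantile",
    "latency_vs_distance",
]


@dataclass(frozen=True)
class FlowTrace:
    """Informed-count trajectory from one focal seed.

    ``counts[k]`` is the number of unique informed individuals (including
    the focal one) at lag ``checkpoints[k]`` after the seed time.
    """

    focal: tuple[str, float]
    horizon: float
    checkpoints: np.ndarray
    counts: np.ndarray


@dataclass(frozen=True)
class FlowCurves:
    """Summary of informed-count trajectories over many focal seeds."""

    checkpoints: np.ndarray
    mean: np.ndarray
    median: np.ndarray
    q05: np.ndarray
    q95: np.ndarray
    samples: np.ndarray  # (n_samples, n_checkpoints)
    seed: int
    focal_mode: str


def trace_reachability(
    net: TimeOrderedNetwork,
    focal: tuple[str, float],
    horizon: float,
    checkpoints: Sequence[float],
) -> FlowTrace:
    """Count individuals causally reachable from a focal seed over time.

    The focal individual is informed at the focal time; sweeping events in
    time order (events at exactly the focal time included), any interaction
    with exactly one informed participant informs the other.  Equal
    timestamps are processed against the pre-timestamp informed set, so a
    message crosses at most one interaction link per instant.  Counts are
    reported at each checkpoint lag (informed set after all events with
    time <= focal_time + lag).
    """
    individual, t_focal = focal
    if individual not in net.individuals:
        raise KeyError(f"unknown focal individual {individual!r}")
    if not 0.0 <= t_focal <= net.duration:
        raise ValueError(f"focal time {t_focal} outside [0, {net.duration}]")
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    lags = np.asarray(sorted(checkpoints), dtype=float)
    if lags.size == 0 or lags[0] < 0:
        raise ValueError("checkpoints must be non-negative lags")

    informed = {individual}
    counts = np.empty(lags.size, dtype=int)
    next_checkpoint = 0
    for t, group in net.groups_by_time():
        if t < t_focal:
            continue
        if t > t_focal + horizon:
            break
        while next_checkpoint < lags.size and t_focal + lags[next_checkpoint] < t:
            counts[next_checkpoint] = len(informed)
            next_checkpoint += 1
        snapshot = informed.copy()
        for e in group:
            a_in, b_in = e.initiator in snapshot, e.target in snapshot
            if a_in != b_in:
                informed.add(e.target if a_in else e.initiator)
    counts[next_checkpoint:] = len(informed)
    return FlowTrace(focal=focal, horizon=horizon, checkpoints=lags, counts=counts)


def sample_flow_curves(
    net: TimeOrderedNetwork,
    n_samples: int,
    rng_seed: int,
    checkpoints: Sequence[float],
    focal_mode: Literal["event", "time"] = "event",
) -> FlowCurves:
    """Mean and quantile informed-count curves over random focal seeds.

    ``focal_mode="event"`` draws focal seeds uniformly with replacement from
    all (event, participant) pairs — random focal events, weighting
    individuals by their activity, as in empirical tracing.  The focal event
    itself transmits, so counts jump to 2 immediately.
    ``focal_mode="time"`` draws a uniform individual at a uniform start time
    in [0, duration - horizon]; this matches the diffusion model's boundary
    condition n(0) = 1 and is the mode to use when comparing against the
    logistic prediction.
    """
    if len(net.events) == 0:
        raise ValueError("cannot sample focal events from an empty log")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(rng_seed)
    lags = np.asarray(sorted(checkpoints), dtype=float)
    horizon = float(lags[-1]) if lags[-1] > 0 else net.duration
    samples = np.empty((n_samples, lags.size), dtype=int)
    for s in range(n_samples):
        if focal_mode == "event":
            e = net.events[rng.integers(len(net.events))]
            who = e.initiator if rng.random() < 0.5 else e.target
            focal = (who, e.time)
        elif focal_mode == "time":
            who = net.individuals[rng.integers(net.m)]
            t0_max = max(net.duration - horizon, 0.0)
            focal = (who, float(rng.uniform(0.0, t0_max)))
        else:
            raise ValueError(f"unknown focal_mode {focal_mode!r}")
        samples[s] = trace_reachability(net, focal, horizon, lags).counts
    return FlowCurves(
        checkpoints=lags,
        mean=samples.mean(axis=0),
        median=np.median(samples, axis=0),
        q05=np.quantile(samples, 0.05, axis=0),
        q95=np.quantile(samples, 0.95, axis=0),
        samples=samples,
        seed=rng_seed,
        focal_mode=focal_mode,
    )


@dataclass(frozen=True)
class LatencyMatrix:
    """Vector-clock latencies at a fixed evaluation time.

    ``matrix[i, j]`` (roster order) is eval_time minus the latest time at
    which information originating at j could have causally reached i;
    ``inf`` when no causal path exists, 0 on the diagonal.
    """

    individuals: tuple[str, ...]
    eval_time: float
    matrix: np.ndarray

    def latency(self, receiver: str, source: str) -> float:
        i = self.individuals.index(receiver)
        j = self.individuals.index(source)
        return float(self.matrix[i, j])


def vector_clock_latencies(net: TimeOrderedNetwork, eval_time: float) -> LatencyMatrix:
    """Vector-clock latency matrix after processing events up to eval_time.

    Each individual i keeps a clock phi_i(j) = latest departure time from j
    of information that has reached i (-inf until any path exists,
    phi_i(i) = current time).  An interaction (a, b) at time s <= eval_time
    sets phi_a(b) = phi_b(a) = s and merges the clocks component-wise.
    Latency(i, j) = eval_time - phi_i(j).  Equal-timestamp events are merged
    from the pre-timestamp snapshot (strictly increasing-time paths only).
    """
    if not 0.0 < eval_time <= net.duration:
        raise ValueError(f"eval_time must lie in (0, duration], got {eval_time}")
    index = {who: k for k, who in enumerate(net.individuals)}
    m = net.m
    clocks = np.full((m, m), -np.inf)
    for t, group in net.groups_by_time():
        if t > eval_time:
            break
        participants = {index[e.initiator] for e in group} | {
            index[e.target] for e in group
        }
        snapshot = {k: clocks[k].copy() for k in participants}
        for e in group:
            a, b = index[e.initiator], index[e.target]
            merged_a = np.maximum(snapshot[a], snapshot[b])
            merged_b = merged_a.copy()
            merged_a[b] = t
            merged_b[a] = t
            np.maximum(clocks[a], merged_a, out=clocks[a])
            np.maximum(clocks[b], merged_b, out=clocks[b])
    latencies = eval_time - clocks
    np.fill_diagonal(latencies, 0.0)
    return LatencyMatrix(individuals=net.individuals, eval_time=eval_time, matrix=latencies)


def receiver_mean_latencies(latency: LatencyMatrix) -> dict[str, float]:
    """Per-individual mean of finite off-diagonal latencies as receiver.

    Individuals that no information from any other individual has reached
    are omitted.  Infinite (unreached) pairs are excluded from the mean; the
    number excluded per receiver is available from the matrix directly.
    """
    out: dict[str, float] = {}
    m = latency.matrix.shape[0]
    for k, who in enumerate(latency.individuals):
        row = np.delete(latency.matrix[k], k)
        finite = row[np.isfinite(row)]
        if finite.size:
            out[who] = float(finite.mean())
    return out


def grand_mean_latency(
    logs: Sequence[EventLog],
    eval_times: Sequence[float] | None = None,
) -> tuple[float, float]:
    """Grand mean vector-clock latency across recordings, with standard error.

    Per recording, latencies are evaluated at the end of filming
    (eval_time = duration) by default, or averaged over the supplied
    ``eval_times`` grid (per-recording times capped at that recording's
    duration).  Per-individual receiver means are averaged within a
    recording, recording means are averaged across recordings, and the
    standard error is computed over the pooled per-individual means.

    Raises ``ValueError`` when every off-diagonal latency is infinite.
    """
    if len(logs) == 0:
        raise ValueError("need at least one event log")
    per_log_means = []
    pooled: list[float] = []
    for log in logs:
        net = TimeOrderedNetwork(log)
        times = [log.metadata.duration] if eval_times is None else [
            min(t, log.metadata.duration) for t in eval_times if t > 0
        ]
        by_individual: dict[str, list[float]] = {}
        for t in times:
            for who, value in receiver_mean_latencies(vector_clock_latencies(net, t)).items():
                by_individual.setdefault(who, []).append(value)
        means = [float(np.mean(vals)) for vals in by_individual.values()]
        if means:
            per_log_means.append(float(np.mean(means)))
            pooled.extend(means)
    if not pooled:
        raise ValueError("all latencies infinite; no information flow in any log")
    grand = float(np.mean(per_log_means))
    se = float(np.std(pooled, ddof=1) / math.sqrt(len(pooled))) if len(pooled) > 1 else 0.0
    return grand, se


def individual_quantile(
    values: dict[str, float], individual: str
) -> float:
    """Mid-rank quantile of one individual's value among all individuals.

    Ties receive their average rank; the quantile is (rank - 0.5) / n, so a
    unique minimum among n individuals scores 0.5/n and an all-tied group
    scores 0.5.  ``values`` maps every comparable individual to its
    statistic (e.g. mean receiver latency, out-degree, betweenness, from
    :func:`receiver_mean_latencies`, ``TimeAggregatedNetwork.out_degrees``
    or ``betweenness_all``).
    """
    if individual not in values:
        raise KeyError(f"no statistic for individual {individual!r}")
    names = list(values)
    data = np.array([values[name] for name in names], dtype=float)
    ranks = sps.rankdata(data, method="average")
    rank = ranks[names.index(individual)]
    return float((rank - 0.5) / len(names))


@dataclass(frozen=True)
class LatencyDistanceResult:
    """Per-individual spatial position vs information latency, with OLS fit."""

    individuals: tuple[str, ...]
    distances: np.ndarray
    latencies: np.ndarray
    slope: float
    intercept: float
    p_value: float


def latency_vs_distance(log: EventLog) -> LatencyDistanceResult:
    """Regress mean receiver latency on mean distance from the nest centre.

    For each individual with at least one positioned event and a finite
    receiver latency at eval_time = duration: x = mean Euclidean distance of
    its recorded positions from the nest-rectangle centre, y = mean finite
    receiver latency.  Returns the OLS slope, intercept and the p-value of
    the slope = 0 test.  The kinetic-gas model predicts no relationship
    (spatially homogeneous mixing); spatially structured colonies show
    better-informed centres (positive slope).
    """
    if not log.has_positions:
        raise ValueError("log has no positioned events")
    net = TimeOrderedNetwork(log)
    lat = receiver_mean_latencies(
        vector_clock_latencies(net, log.metadata.duration)
    )
    cx, cy = log.metadata.nest_center
    names, xs, ys = [], [], []
    for who in log.metadata.individuals:
        fixes = log.positions_of(who)
        if not fixes or who not in lat:
            continue
        d = float(np.mean([math.hypot(x - cx, y - cy) for _, x, y in fixes]))
        names.append(who)
        xs.append(d)
        ys.append(lat[who])
    xs_arr, ys_arr = np.array(xs), np.array(ys)
    if len(names) < 3:
        raise ValueError("need at least 3 individuals with positions and latencies")
    if np.std(xs_arr) == 0:
        raise ValueError("zero variance in distance; slope undefined")
    model = sm.OLS(ys_arr, sm.add_constant(xs_arr)).fit()
    return LatencyDistanceResult(
        individuals=tuple(names),
        distances=xs_arr,
        latencies=ys_arr,
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        p_value=float(model.pvalues[1]),
    )
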