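"""Kinetic-gas diffusion model: closed-form predictions and a 2-D simulator.

The model treats individuals as identical disks moving at constant speed in
straight lines inside a rectangular arena, bouncing off walls and recording
an interaction whenever two disk centres come within the interaction radius
``D``.  Five parameters specify everything: group size ``m``, arena area
``A`` (width x height), interaction radius ``D``, speed ``v`` and elapsed
time ``t``.  Kinetic theory for equal-speed random directions in 2-D gives a
mean relative speed of 4v/pi and hence a per-individual contact rate

    lambda_ind = 8 m v D / (A pi)

with per-pair rate lambda_pair = 8 v D / (A pi) (the per-individual formula
absorbs the m ~ m-1 approximation).  From this rate follow:

* Poisson-distributed per-individual interaction counts,
* group interaction count m lambda_ind t / 2,
* exponential waiting times between an individual's interactions,
* sqrt(t) growth of expected displacement (2-D diffusive scaling),
* binomial out-degree with exponentially saturating success probability,
* logistic SI information spread n(t) = m / (1 + (m-1) exp(-lambda_ind t)).

The simulator (:func:`simulate_gas`) realises exactly this physics and emits
an :class:`~antflow.event_io.EventLog`; it doubles as the package's
synthetic-data generator.  :func:`simulate_structured` adds spatial fidelity
(personal home-range disks) and reduced speed — a negative control whose
flow is slower than the gas prediction and whose waiting times are heavy
tailed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps

from .event_io import ColonyMetadata, EventLog, InteractionEvent

__all__ = [
    "GasModelParams",
    "interaction_count_pmf",
    "group_interaction_count",
    "waiting_time_survival",
    "expected_displacement",
    "displacement_valid",
    "degree_pmf",
    "mean_degree",
    "si_flow",
    "rescale_flow",
    "RescaledFlow",
    "simulate_gas",
    "simulate_structured",
]


@dataclass(frozen=True)
class GasModelParams:
    """Parameters of the kinetic-gas model.

    ``m`` individuals in a ``width`` x ``height`` arena (body lengths),
    interaction radius ``D`` (contact when centre separation <= D) and speed
    ``v`` (body lengths / second).  ``packing_fraction_max`` bounds the disk
    packing m pi (D/2)^2 / A accepted by the simulator (default 0.2: beyond
    that, the dilute-gas rate formula and initial-placement rejection
    sampling both degrade).
    """

    m: int
    width: float
    height: float
    v: float
    D: float = 1.0
    packing_fraction_max: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1 or self.m != int(self.m):
            raise ValueError(f"m must be a positive integer, got {self.m!r}")
        for name in ("width", "height", "v", "D"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be positive and finite, got {value!r}")

    @property
    def A(self) -> float:
        return self.width * self.height

    @property
    def lambda_pair(self) -> float:
        """Per-pair contact rate 8 v D / (A pi), per second."""
        return 8.0 * self.v * self.D / (self.A * math.pi)

    @property
    def lambda_ind(self) -> float:
        """Per-individual contact rate 8 m v D / (A pi), per second."""
        return self.m * self.lambda_pair

    @property
    def packing_fraction(self) -> float:
        return self.m * math.pi * (self.D / 2.0) ** 2 / self.A

    def check_packing(self) -> None:
        if self.packing_fraction >= self.packing_fraction_max:
            raise ValueError(
                f"disk packing fraction {self.packing_fraction:.3f} exceeds "
                f"threshold {self.packing_fraction_max}; enlarge the arena or "
                f"reduce m"
            )


# ---------------------------------------------------------------------------
# Closed-form predictions
# ---------------------------------------------------------------------------

def interaction_count_pmf(params: GasModelParams, t: float, i) -> float | np.ndarray:
    """P(individual has exactly i interactions by time t): Poisson(lambda_ind t)."""
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    if np.any(np.asarray(i) < 0):
        raise ValueError("interaction count i must be >= 0")
    return sps.poisson.pmf(i, params.lambda_ind * t)


def group_interaction_count(params: GasModelParams, t: float) -> float:
    """Expected total interactions in the whole group by time t.

    Mean per-individual count times m, halved to undo double counting.
    (At m = 1 the formula still returns lambda_ind*t/2 although no partner
    exists; the approximation m ~ m-1 underlying lambda_ind is degenerate
    there.)
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    return params.m * params.lambda_ind * t / 2.0


def waiting_time_survival(params: GasModelParams, t) -> float | np.ndarray:
    """P(no interaction for an individual within a window of length t)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = np.exp(-params.lambda_ind * t)
    return float(out) if out.ndim == 0 else out


def expected_displacement(params: GasModelParams, t) -> float | np.ndarray:
    """Expected distance from the start position after time t.

    Speed times mean free time times the square root of the expected number
    of direction changes: v * (1/lambda_ind) * sqrt(lambda_ind t)
    = v sqrt(t / lambda_ind).  Valid only before the arena boundary caps the
    walk (see :func:`displacement_valid`).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = params.v * np.sqrt(t / params.lambda_ind)
    return float(out) if out.ndim == 0 else out


def displacement_valid(params: GasModelParams, t) -> bool | np.ndarray:
    """True while the sqrt(t) displacement prediction is boundary-unlimited.

    The prediction stops being meaningful once it reaches the half-width of
    the arena's shorter side, i.e. for t < lambda_ind (min(w,h)/(2v))^2.
    """
    limit = min(params.width, params.height) / 2.0
    out = np.asarray(expected_displacement(params, t)) < limit
    return bool(out) if out.ndim == 0 else out


def degree_pmf(params: GasModelParams, t: float, n) -> float | np.ndarray:
    """P(exactly n unique partners by time t): Binomial(m-1, p).

    The success probability p = 1 - exp(-lambda_pair t) is the chance that a
    given other individual has been met at least once; the m-1 possible
    partners are independent trials (self excluded).
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    n_arr = np.asarray(n)
    if np.any(n_arr < 0) or np.any(n_arr > params.m - 1):
        raise ValueError(f"degree n must lie in [0, m-1] = [0, {params.m - 1}]")
    p = 1.0 - math.exp(-params.lambda_pair * t)
    return sps.binom.pmf(n, params.m - 1, p)


def mean_degree(params: GasModelParams, t) -> float | np.ndarray:
    """Expected number of unique partners by time t: (m-1)(1 - e^(-lambda_pair t))."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = (params.m - 1) * (1.0 - np.exp(-params.lambda_pair * t))
    return float(out) if out.ndim == 0 else out


def si_flow(params: GasModelParams, t) -> float | np.ndarray:
    """Expected informed count n(t) under SI spread from one informed individual.

    Logistic solution of dn/dt = lambda_ind n (m-n)/m with n(0) = 1:
    n(t) = m / (1 + (m-1) exp(-lambda_ind t)).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = params.m / (1.0 + (params.m - 1) * np.exp(-params.lambda_ind * t))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class RescaledFlow:
    """Flow curves linearised onto the model's universal 1:1 axes.

    ``x`` is the dimensionless time lambda_ind * t (equal to the linearised
    model prediction), ``y`` the same transform of the observed counts:
    y = ln(n (m-1) / (m - n)), which maps the logistic exactly onto y = x.
    ``clipped`` flags points where the observed n had saturated at m and was
    mapped to the last finite transform value.
    """

    x: np.ndarray
    y: np.ndarray
    clipped: np.ndarray


def rescale_flow(params: GasModelParams, times, counts) -> RescaledFlow:
    """Linearise an empirical informed-count curve for the slope-1 test.

    Under the logistic prediction, y = ln(n(m-1)/(m-n)) plotted against
    x = lambda_ind t falls on the 1:1 line; model-true data therefore have
    SMA slope 1, and slower-than-predicted flow has slope < 1.

    Counts must lie in [1, m]; entries at exactly m (transform infinite) are
    replaced by the largest finite transformed value and flagged.
    """
    if params.m <= 1:
        raise ValueError("rescale_flow undefined for m <= 1")
    times = np.asarray(times, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if times.shape != counts.shape:
        raise ValueError("times and counts must have equal shape")
    if np.any(counts < 1.0) or np.any(counts > params.m):
        raise ValueError("informed counts must lie in [1, m]")
    x = params.lambda_ind * times
    m = params.m
    clipped = counts >= m
    with np.errstate(divide="ignore"):
        y = np.log(counts * (m - 1) / (m - counts))
    if clipped.any():
        finite = y[~clipped]
        if finite.size == 0:
            raise ValueError("all counts saturated at m; transform undefined")
        y = y.copy()
        y[clipped] = finite.max()
    return RescaledFlow(x=x, y=y, clipped=clipped)


# ---------------------------------------------------------------------------
# Simulator
# ---------------------------------------------------------------------------

def _initial_positions(params: GasModelParams, rng: np.random.Generator) -> np.ndarray:
    """Uniform non-overlapping initial centres (pairwise separation > D)."""
    params.check_packing()
    pos = np.empty((params.m, 2))
    placed = 0
    attempts = 0
    max_attempts = 10_000 * params.m
    while placed < params.m:
        candidate = rng.uniform((0.0, 0.0), (params.width, params.height))
        if placed == 0 or np.all(
            np.sum((pos[:placed] - candidate) ** 2, axis=1) > params.D**2
        ):
            pos[placed] = candidate
            placed += 1
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                "could not place non-overlapping disks; arena too crowded"
            )
    return pos


def _random_velocities(
    n: int, speed: float, rng: np.random.Generator
) -> np.ndarray:
    theta = rng.uniform(0.0, 2.0 * math.pi, size=n)
    return speed * np.column_stack((np.cos(theta), np.sin(theta)))


def _reflect_walls(pos: np.ndarray, vel: np.ndarray, width: float, height: float) -> None:
    """Specular reflection at the arena walls, in place.

    Steps are tiny relative to the arena, so a single fold per axis suffices.
    """
    for axis, limit in ((0, width), (1, height)):
        below = pos[:, axis] < 0.0
        if below.any():
            pos[below, axis] = -pos[below, axis]
            vel[below, axis] = -vel[below, axis]
        above = pos[:, axis] > limit
        if above.any():
            pos[above, axis] = 2.0 * limit - pos[above, axis]
            vel[above, axis] = -vel[above, axis]


def _simulate(
    params: GasModelParams,
    duration: float,
    rng_seed: int,
    record_positions: bool,
    *,
    variant: str,
    fidelity_radius: float | None = None,
    speed_factor: float = 1.0,
) -> EventLog:
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(rng_seed)
    speed = params.v * speed_factor
    pos = _initial_positions(params, rng)
    vel = _random_velocities(params.m, speed, rng)

    if variant == "fidelity":
        assert fidelity_radius is not None
        centers = rng.uniform(
            (0.0, 0.0), (params.width, params.height), size=(params.m, 2)
        )

    # step small enough that a crossing of the contact shell cannot be skipped
    h = min(params.D / (10.0 * params.v), 0.05)
    n_steps = int(math.ceil(duration / h))
    iu, ju = np.triu_indices(params.m, k=1)
    d2 = np.sum((pos[iu] - pos[ju]) ** 2, axis=1)
    in_contact = d2 <= params.D**2

    events: list[InteractionEvent] = []
    t = 0.0
    for _ in range(n_steps):
        step = min(h, duration - t)
        t += step
        pos += vel * step
        if variant == "fidelity":
            offset = pos - centers
            dist = np.hypot(offset[:, 0], offset[:, 1])
            out = dist > fidelity_radius
            if out.any():
                normal = offset[out] / dist[out, None]
                # fold the overshoot back inside the home-range disk and
                # reflect the velocity about the circle normal
                pos[out] -= 2.0 * (dist[out] - fidelity_radius)[:, None] * normal
                v_n = np.sum(vel[out] * normal, axis=1)
                vel[out] -= 2.0 * v_n[:, None] * normal
        _reflect_walls(pos, vel, params.width, params.height)

        d2 = np.sum((pos[iu] - pos[ju]) ** 2, axis=1)
        close = d2 <= params.D**2
        onsets = np.flatnonzero(close & ~in_contact)
        if onsets.size:
            redirect: set[int] = set()
            for k in onsets:
                a, b = int(iu[k]), int(ju[k])
                # the gas model does not distinguish initiator and target:
                # assign roles with a fair seeded coin
                if rng.random() < 0.5:
                    a, b = b, a
                position = None
                if record_positions:
                    position = (
                        float(np.clip(pos[b, 0], 0.0, params.width)),
                        float(np.clip(pos[b, 1], 0.0, params.height)),
                    )
                events.append(
                    InteractionEvent(t, _ant_id(a), _ant_id(b), position)
                )
                redirect.update((a, b))
            idx = sorted(redirect)
            new_v = _random_velocities(len(idx), speed, rng)
            vel[idx] = new_v
        in_contact = close

    meta = ColonyMetadata(
        colony_id=f"{variant}-m{params.m}-seed{rng_seed}",
        nest_width=params.width,
        nest_height=params.height,
        duration=duration,
        individuals=tuple(_ant_id(i) for i in range(params.m)),
        D=params.D,
        v=params.v,
    )
    return EventLog(meta, tuple(events))


def _ant_id(index: int) -> str:
    return f"A{index + 1:03d}"


def simulate_gas(
    params: GasModelParams,
    duration: float,
    rng_seed: int,
    record_positions: bool = True,
) -> EventLog:
    """Simulate the 2-D kinetic gas and return the resulting event log.

    Disks start at uniform non-overlapping positions with uniform random
    headings, all at speed ``v`` exactly.  Motion is integrated with step
    ``min(D/(10 v), 0.05)`` s; walls reflect specularly (no event recorded);
    a contact onset (centre separation first <= D) records one event, after
    which both participants take fresh independent uniform headings at
    unchanged speed.  A pair must separate beyond D before it can produce a
    new event.  Initiator/target roles are assigned by a fair seeded coin
    and the target's position is recorded when ``record_positions``.

    Identical seeds yield identical logs.
    """
    return _simulate(params, duration, rng_seed, record_positions, variant="gas")


def simulate_structured(
    params: GasModelParams,
    duration: float,
    fidelity_radius: float,
    speed_factor: float,
    rng_seed: int,
    record_positions: bool = True,
) -> EventLog:
    """Gas simulation with spatial fidelity and reduced mobility.

    Each individual is confined to a personal home-range disk of radius
    ``fidelity_radius`` around a random centre (reflected at its boundary)
    and moves at ``speed_factor * v``.  With small radii and low speed the
    resulting logs show the signatures of constrained colonies: information
    flow slower than the gas prediction, heavy-tailed waiting times, and
    sub-sqrt(t) displacement.
    """
    if not fidelity_radius > params.D:
        raise ValueError("fidelity_radius must exceed the interaction radius D")
    if not 0.0 < speed_factor <= 1.0:
        raise ValueError("speed_factor must lie in (0, 1]")
    return _simulate(
        params,
        duration,
        rng_seed,
        record_positions,
        variant="fidelity",
        fidelity_radius=fidelity_radius,
        speed_factor=speed_factor,
    )
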