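import numpy as np
import pytest

from antflow.diffusion_model import GasModelParams, simulate_gas
from antflow.event_io import ColonyMetadata, EventLog, InteractionEvent


def make_log(
    events,
    m=None,
    duration=None,
    width=20.0,
    height=20.0,
    queen=None,
    individuals=None,
):
    """Build a small EventLog from (time, initiator, target[, x, y]) tuples."""
    evs = []
    for row in events:
        if len(row) == 3:
            t, a, b = row
            evs.append(InteractionEvent(t, a, b))
        else:
            t, a, b, x, y = row
            evs.append(InteractionEvent(t, a, b, (x, y)))
    if individuals is None:
        names = sorted({e.initiator for e in evs} | {e.target for e in evs})
        if m is not None and m > len(names):
            extra = [f"X{k}" for k in range(m - len(names))]
            names = names + extra
        individuals = tuple(names)
    if duration is None:
        duration = max([e.time for e in evs], default=0.0) + 1.0
    meta = ColonyMetadata(
        colony_id="test",
        nest_width=width,
        nest_height=height,
        duration=duration,
        individuals=tuple(individuals),
        queen=queen,
    )
    return EventLog(meta, tuple(evs))


def random_log(rng, m_max=8, e_max=40, duration=100.0, with_positions=False,
               tie_fraction=0.3):
    """Random small log with deliberate timestamp ties for oracle testing."""
    m = int(rng.integers(2, m_max + 1))
    n_events = int(rng.integers(0, e_max + 1))
    names = [f"W{k}" for k in range(m)]
    # a coarse time grid produces genuine ties with probability tie_fraction
    n_slots = max(int(n_events / max(tie_fraction, 1e-9) / 4), 1)
    times = np.sort(rng.choice(np.linspace(0.0, duration, n_slots + 1), size=n_events))
    events = []
    for t in times:
        a, b = rng.choice(m, size=2, replace=False)
        if with_positions:
            events.append((float(t), names[a], names[b],
                           float(rng.uniform(0, 20)), float(rng.uniform(0, 20))))
        else:
            events.append((float(t), names[a], names[b]))
    return make_log(events, duration=duration, individuals=names)


@pytest.fixture
def chain_log():
    """A-B at t=1 then B-C at t=2: the canonical hand-traceable chain."""
    return make_log([(1.0, "A", "B"), (2.0, "B", "C")], duration=10.0)


@pytest.fixture(scope="session")
def gas_log():
    """One medium gas simulation shared across tests (m=30, 20x20, 600 s)."""
    params = GasModelParams(m=30, width=20.0, height=20.0, v=1.0)
    return simulate_gas(params, 600.0, rng_seed=12345)


@pytest.fixture(scope="session")
def gas_params():
    return GasModelParams(m=30, width=20.0, height=20.0, v=1.0)
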