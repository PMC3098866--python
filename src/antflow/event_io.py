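"""Interaction-event logs: domain types, validated I/O, and mobility summaries.

An *interaction event* is one timestamped antennal contact between two
uniquely identified individuals: an initiator touches a target.  Optionally
the position of the target's head at contact onset is recorded.  All
distances are expressed in units of mean worker body length and all times in
seconds from the start of the recording; unit conversions (mm, pixels) are
the caller's responsibility at ingest.

The :class:`EventLog` — a time-sorted event sequence plus colony metadata —
is the interchange object consumed by every downstream module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "InteractionEvent",
    "ColonyMetadata",
    "EventLog",
    "EventLogError",
    "read_event_log",
    "write_event_log",
    "read_metadata",
    "write_metadata",
    "mean_speed",
    "displacement_series",
]

#: Default mean body length in millimetres (Temnothorax-scale worker).
DEFAULT_BODY_LENGTH_MM = 3.0

#: Default slack, in body lengths, allowed for positions just outside the
#: nest rectangle (digitisation jitter at the walls).
DEFAULT_POSITION_TOLERANCE = 0.5


class EventLogError(ValueError):
    """Raised for malformed or inconsistent event logs / metadata."""


@dataclass(frozen=True)
class InteractionEvent:
    """One initiator→target contact at a given time.

    Parameters
    ----------
    time
        Seconds from recording start; non-negative and finite.
    initiator
        ID of the individual whose antenna made the contact.
    target
        ID of the individual that was touched.
    position
        Optional ``(x, y)`` of the target's head at contact onset, in body
        lengths, origin at the nest's lower-left corner.
    """

    time: float
    initiator: str
    target: str
    position: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.time) and self.time >= 0):
            raise EventLogError(f"event time must be finite and >= 0, got {self.time!r}")
        if not self.initiator or not self.target:
            raise EventLogError("initiator and target IDs must be non-empty")
        if self.initiator == self.target:
            raise EventLogError(
                f"self-interaction not allowed (initiator == target == {self.initiator!r})"
            )
        if self.position is not None:
            x, y = self.position
            if not (math.isfinite(x) and math.isfinite(y)):
                raise EventLogError(f"non-finite position {self.position!r}")
            object.__setattr__(self, "position", (float(x), float(y)))
        object.__setattr__(self, "time", float(self.time))

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.initiator, self.target))


@dataclass(frozen=True)
class ColonyMetadata:
    """Colony-level context for an event log.

    ``m`` (colony size) must equal the roster length; the nest rectangle is
    ``nest_width`` x ``nest_height`` body lengths with area ``A``; ``D`` is
    the interaction radius (contact when centre separation <= D, default one
    body length); ``v`` is the mean walking speed in body lengths/second, or
    ``None`` when it must be estimated from positions or borrowed from other
    recordings.
    """

    colony_id: str
    nest_width: float
    nest_height: float
    duration: float
    individuals: tuple[str, ...]
    body_length_mm: float = DEFAULT_BODY_LENGTH_MM
    D: float = 1.0
    v: float | None = None
    queen: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "individuals", tuple(self.individuals))
        if len(set(self.individuals)) != len(self.individuals):
            raise EventLogError("duplicate IDs in roster")
        if len(self.individuals) < 1:
            raise EventLogError("roster must contain at least one individual")
        for name in ("nest_width", "nest_height", "duration", "body_length_mm", "D"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise EventLogError(f"{name} must be positive and finite, got {value!r}")
        if self.v is not None and not (math.isfinite(self.v) and self.v > 0):
            raise EventLogError(f"v must be positive when given, got {self.v!r}")
        if self.queen is not None and self.queen not in self.individuals:
            raise EventLogError(f"queen {self.queen!r} not in roster")

    @property
    def m(self) -> int:
        """Number of individuals in the colony."""
        return len(self.individuals)

    @property
    def A(self) -> float:
        """Nest area in squared body lengths."""
        return self.nest_width * self.nest_height

    @property
    def nest_center(self) -> tuple[float, float]:
        return (self.nest_width / 2.0, self.nest_height / 2.0)


@dataclass(frozen=True)
class EventLog:
    """Time-sorted interaction events plus colony metadata.

    Events are stably sorted by time (input order preserved within ties).
    Every participant must appear in the metadata roster and no event may
    occur after ``metadata.duration``.
    """

    metadata: ColonyMetadata
    events: tuple[InteractionEvent, ...]
    position_tolerance: float = DEFAULT_POSITION_TOLERANCE

    def __post_init__(self) -> None:
        events = tuple(self.events)
        times = [e.time for e in events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            # stable sort; callers may pass unsorted sequences
            order = np.argsort(times, kind="stable")
            events = tuple(events[i] for i in order)
        object.__setattr__(self, "events", events)

        roster = set(self.metadata.individuals)
        unknown = sorted(
            {i for e in events for i in (e.initiator, e.target) if i not in roster}
        )
        if unknown:
            raise EventLogError(f"participants not in roster: {', '.join(unknown)}")
        late = [e.time for e in events if e.time > self.metadata.duration]
        if late:
            raise EventLogError(
                f"{len(late)} event(s) after recording end (duration "
                f"{self.metadata.duration}), first at t={late[0]}"
            )
        tol = self.position_tolerance
        for e in events:
            if e.position is None:
                continue
            x, y = e.position
            if not (-tol <= x <= self.metadata.nest_width + tol
                    and -tol <= y <= self.metadata.nest_height + tol):
                raise EventLogError(
                    f"position {e.position} outside nest rectangle "
                    f"{self.metadata.nest_width} x {self.metadata.nest_height} "
                    f"(tolerance {tol}) at t={e.time}"
                )

    def __len__(self) -> int:
        return len(self.events)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventLog):
            return NotImplemented
        return self.metadata == other.metadata and self.events == other.events

    def __hash__(self) -> int:  # frozen dataclass with custom __eq__
        return hash((self.metadata, self.events))

    @property
    def has_positions(self) -> bool:
        return any(e.position is not None for e in self.events)

    def times(self) -> np.ndarray:
        return np.array([e.time for e in self.events], dtype=float)

    def positions_of(self, individual: str) -> list[tuple[float, float, float]]:
        """(time, x, y) tuples for every positioned event the individual joins.

        Only the target's head position is digitised per event; both
        participants are assigned that position for mobility purposes — an
        approximation, since initiator and target are at most D apart.
        """
        if individual not in self.metadata.individuals:
            raise KeyError(f"unknown individual {individual!r}")
        out = []
        for e in self.events:
            if e.position is not None and individual in (e.initiator, e.target):
                out.append((e.time, e.position[0], e.position[1]))
        return out

    def to_frame(self) -> pd.DataFrame:
        """Events as a DataFrame with columns time_s, initiator, target[, x, y]."""
        rows = {
            "time_s": [e.time for e in self.events],
            "initiator": [e.initiator for e in self.events],
            "target": [e.target for e in self.events],
        }
        if self.has_positions:
            rows["x"] = [e.position[0] if e.position else np.nan for e in self.events]
            rows["y"] = [e.position[1] if e.position else np.nan for e in self.events]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("time_s", "initiator", "target")


def read_metadata(path: str | Path) -> ColonyMetadata:
    """Read colony metadata from YAML or JSON.

    Expected keys: colony_id, nest_width, nest_height, duration_s,
    individuals (list), and optionally body_length_mm, D, v, queen, m.
    An explicit ``m`` is cross-checked against the roster length.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())  # YAML is a JSON superset
    if not isinstance(raw, Mapping):
        raise EventLogError(f"metadata file {path} did not parse to a mapping")
    try:
        meta = ColonyMetadata(
            colony_id=str(raw["colony_id"]),
            nest_width=float(raw["nest_width"]),
            nest_height=float(raw["nest_height"]),
            duration=float(raw["duration_s"]),
            individuals=tuple(str(i) for i in raw["individuals"]),
            body_length_mm=float(raw.get("body_length_mm", DEFAULT_BODY_LENGTH_MM)),
            D=float(raw.get("D", 1.0)),
            v=None if raw.get("v") is None else float(raw["v"]),
            queen=None if raw.get("queen") is None else str(raw["queen"]),
        )
    except KeyError as exc:
        raise EventLogError(f"metadata file {path} missing key {exc}") from exc
    if "m" in raw and int(raw["m"]) != meta.m:
        raise EventLogError(
            f"metadata m={raw['m']} does not match roster size {meta.m}"
        )
    return meta


def write_metadata(meta: ColonyMetadata, path: str | Path) -> None:
    """Write colony metadata as YAML (readable back by :func:`read_metadata`)."""
    doc = {
        "colony_id": meta.colony_id,
        "m": meta.m,
        "nest_width": meta.nest_width,
        "nest_height": meta.nest_height,
        "body_length_mm": meta.body_length_mm,
        "D": meta.D,
        "v": meta.v,
        "duration_s": meta.duration,
        "individuals": list(meta.individuals),
        "queen": meta.queen,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_event_log(
    path: str | Path,
    metadata_path: str | Path,
    *,
    position_tolerance: float = DEFAULT_POSITION_TOLERANCE,
) -> EventLog:
    """Read a CSV event file plus its metadata file into a validated EventLog.

    The event file must have a header row with at least ``time_s, initiator,
    target``; ``x`` and ``y`` columns are optional and attached as positions
    when both parse to numbers.  Rows are stably sorted by time.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype={"initiator": str, "target": str})
    except Exception as exc:  # pandas raises several parser error types
        raise EventLogError(f"could not parse {path}: {exc}") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise EventLogError(f"{path} missing required column(s): {', '.join(missing)}")

    meta = read_metadata(metadata_path)
    has_xy = "x" in frame.columns and "y" in frame.columns
    events = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            t = float(getattr(row, "time_s"))
        except (TypeError, ValueError) as exc:
            raise EventLogError(f"{path}:{row_number}: bad time {getattr(row, 'time_s')!r}") from exc
        position = None
        if has_xy:
            x, y = getattr(row, "x"), getattr(row, "y")
            if pd.notna(x) and pd.notna(y):
                position = (float(x), float(y))
        try:
            events.append(
                InteractionEvent(t, str(row.initiator), str(row.target), position)
            )
        except EventLogError as exc:
            raise EventLogError(f"{path}:{row_number}: {exc}") from exc
    return EventLog(meta, tuple(events), position_tolerance=position_tolerance)


def write_event_log(log: EventLog, path: str | Path) -> None:
    """Write an EventLog as CSV with header ``time_s,initiator,target[,x,y]``.

    Times are printed with 6 decimal places so a write→read round trip
    reproduces IDs exactly and times to well within 1e-6 s; position columns
    are emitted only when at least one event carries a position.
    """
    path = Path(path)
    lines = []
    if log.has_positions:
        lines.append("time_s,initiator,target,x,y")
        for e in log.events:
            if e.position is None:
                lines.append(f"{e.time:.6f},{e.initiator},{e.target},,")
            else:
                lines.append(
                    f"{e.time:.6f},{e.initiator},{e.target},"
                    f"{e.position[0]:.6f},{e.position[1]:.6f}"
                )
    else:
        lines.append("time_s,initiator,target")
        for e in log.events:
            lines.append(f"{e.time:.6f},{e.initiator},{e.target}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Mobility summaries
# ---------------------------------------------------------------------------

def mean_speed(
    log: EventLog, roles: str = "target"
) -> tuple[dict[str, float], float]:
    """Per-individual and grand mean walking speed from event positions.

    For each individual, speed is the mean over consecutive positioned
    events of straight-line displacement divided by elapsed time (linearly
    interpolated chords between interaction fixes); pairs with zero time gap
    are skipped.  Individuals with fewer than two positioned events are
    omitted from the returned mapping.  The grand mean is the unweighted
    mean over reported individuals.

    ``roles="target"`` (default) uses only events where the individual was
    the target, i.e. only its own digitised head positions.  ``roles="both"``
    additionally assigns the target's position to the initiator; that
    approximation places fixes up to D body lengths from the initiator's
    true position, and dividing such offsets by short inter-fix gaps
    inflates speeds severely, so it is not the default.

    Returns
    -------
    (per_individual, grand_mean)

    Raises
    ------
    EventLogError
        If no individual has two or more positioned events: callers should
        then supply ``v`` in the metadata (e.g. the grand mean over other
        recordings).
    """
    if roles not in ("target", "both"):
        raise ValueError("roles must be 'target' or 'both'")
    per_individual: dict[str, float] = {}
    for individual in log.metadata.individuals:
        if roles == "target":
            fixes = [
                (e.time, e.position[0], e.position[1])
                for e in log.events
                if e.target == individual and e.position is not None
            ]
        else:
            fixes = log.positions_of(individual)
        if len(fixes) < 2:
            continue
        speeds = []
        for (t0, x0, y0), (t1, x1, y1) in zip(fixes, fixes[1:]):
            dt = t1 - t0
            if dt <= 0:
                continue
            speeds.append(math.hypot(x1 - x0, y1 - y0) / dt)
        if speeds:
            per_individual[individual] = float(np.mean(speeds))
    if not per_individual:
        raise EventLogError(
            "no individual has two positioned events; supply v in metadata "
            "(e.g. the grand mean speed over other recordings)"
        )
    return per_individual, float(np.mean(list(per_individual.values())))


def displacement_series(log: EventLog, individual: str) -> np.ndarray:
    """Elapsed time and straight-line displacement from the first fix.

    Returns an array of shape (k, 2): for each positioned event after the
    individual's first one, ``(elapsed seconds, Euclidean distance in body
    lengths from the first recorded position)``.  Length 0 when only one
    positioned event exists.

    Raises
    ------
    KeyError
        Unknown individual.
    EventLogError
        No positioned event for the individual.
    """
    fixes = log.positions_of(individual)
    if not fixes:
        raise EventLogError(f"no positioned events for {individual!r}")
    t0, x0, y0 = fixes[0]
    out = [(t - t0, math.hypot(x - x0, y - y0)) for t, x, y in fixes[1:]]
    return np.array(out, dtype=float).reshape(-1, 2)
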