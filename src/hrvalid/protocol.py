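"""Phased exercise protocol: timeline, transition windows, state labelling.

The protocol is an ordered list of activity phases (name, duration, ordinal
load level).  Phase boundaries define *transition onsets*; a transition
window spans a fixed pre/post interval around each onset (default 10 s
before to 60 s after).  Every timestamp is either inside exactly one
transition window ("transition") or outside all of them ("steady").
Onsets come from the protocol timing, applied identically to all subjects —
no per-subject event detection.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "Phase",
    "ProtocolSpec",
    "TransitionWindow",
    "TransitionWindows",
    "State",
    "StateLabel",
    "build_default_protocol",
    "derive_transitions",
    "label_timestamps",
    "label_array",
]


@dataclass(frozen=True)
class Phase:
    """One activity phase.

    Parameters
    ----------
    name : str
        Human-readable label, e.g. ``"walk4"``.
    duration_s : float
        Phase length in seconds; must be strictly positive.
    load : int
        Ordinal activity level (rest < stand < walk ...); used only for
        ordering/plotting and for mapping subjects' steady-state targets.
    """

    name: str
    duration_s: float
    load: int

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValueError(f"phase {self.name!r}: duration must be > 0, got {self.duration_s}")


@dataclass(frozen=True)
class ProtocolSpec:
    """Ordered, contiguous activity phases starting at ``start_time`` seconds."""

    phases: tuple[Phase, ...]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "phases", tuple(self.phases))
        if len(self.phases) == 0:
            raise ValueError("protocol needs at least one phase")

    @property
    def total_duration(self) -> float:
        return float(sum(p.duration_s for p in self.phases))

    @property
    def end_time(self) -> float:
        return self.start_time + self.total_duration

    @property
    def phase_change_times(self) -> np.ndarray:
        """Interior phase-boundary times (the transition onsets)."""
        durs = np.array([p.duration_s for p in self.phases], dtype=float)
        return self.start_time + np.cumsum(durs)[:-1]

    def phase_at(self, t: float) -> Phase:
        """Phase active at time ``t`` (boundaries belong to the later phase)."""
        if not (self.start_time <= t <= self.end_time):
            raise ValueError(f"t={t} outside protocol span [{self.start_time}, {self.end_time}]")
        edges = np.concatenate([[self.start_time], self.start_time + np.cumsum([p.duration_s for p in self.phases])])
        idx = int(np.searchsorted(edges, t, side="right") - 1)
        idx = min(idx, len(self.phases) - 1)
        return self.phases[idx]

    def phase_index_of_times(self, t: np.ndarray) -> np.ndarray:
        edges = np.concatenate([[self.start_time], self.start_time + np.cumsum([p.duration_s for p in self.phases])])
        idx = np.searchsorted(edges, np.asarray(t, dtype=float), side="right") - 1
        return np.clip(idx, 0, len(self.phases) - 1)

    # ------------------------------------------------------------------ I/O
    def to_dict(self) -> dict:
        return {
            "start_time": self.start_time,
            "phases": [{"name": p.name, "duration_s": p.duration_s, "load": p.load} for p in self.phases],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolSpec":
        phases = tuple(Phase(p["name"], float(p["duration_s"]), int(p["load"])) for p in d["phases"])
        return cls(phases=phases, start_time=float(d.get("start_time", 0.0)))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ProtocolSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ProtocolSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class TransitionWindow:
    transition_id: int
    onset: float
    start: float
    end: float


@dataclass(frozen=True)
class TransitionWindows:
    """Closed windows ``[onset - pre_span, onset + post_span]`` around each onset."""

    windows: tuple[TransitionWindow, ...]
    pre_span: float
    post_span: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "windows", tuple(self.windows))
        onsets = [w.onset for w in self.windows]
        if sorted(onsets) != onsets:
            raise ValueError("windows must be sorted by onset")

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(w.transition_id, w.onset, w.start, w.end) for w in self.windows],
            columns=["transition_id", "onset_s", "start_s", "end_s"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class State(str, Enum):
    steady = "steady"
    transition = "transition"


@dataclass(frozen=True)
class StateLabel:
    """Condition of one timestamp: steady, or transition k (1-based)."""

    value: State
    transition_id: Optional[int] = None

    def __post_init__(self) -> None:
        if (self.value is State.transition) != (self.transition_id is not None):
            raise ValueError("transition_id must be present iff state is 'transition'")


STEADY = StateLabel(State.steady)


def build_default_protocol() -> ProtocolSpec:
    """Six-phase 20 min treadmill protocol.

    Sit 3 min, stand 3 min, walk 4 km/h 4 min, walk 6 km/h 4 min,
    walk 6 km/h at 5 % incline 4 min, stand 2 min — 1200 s in total,
    with an abrupt stop into the final standing phase.
    """
    return ProtocolSpec(
        phases=(
            Phase("sit", 180, 0),
            Phase("stand", 180, 1),
            Phase("walk4", 240, 2),
            Phase("walk6", 240, 3),
            Phase("walk6_incline", 240, 4),
            Phase("stand_recovery", 120, 1),
        )
    )


def derive_transitions(
    protocol: ProtocolSpec, pre_span: float = 10.0, post_span: float = 60.0
) -> TransitionWindows:
    """One window per phase boundary, clipped to the protocol span.

    A single-phase protocol has no boundaries and yields an empty set.
    """
    if pre_span < 0 or post_span < 0:
        raise ValueError("pre_span and post_span must be >= 0")
    onsets = protocol.phase_change_times
    windows = []
    for k, onset in enumerate(onsets, start=1):
        start = max(float(onset) - pre_span, protocol.start_time)
        end = min(float(onset) + post_span, protocol.end_time)
        windows.append(TransitionWindow(k, float(onset), start, end))
    return TransitionWindows(tuple(windows), pre_span, post_span)


def label_array(timestamps: Sequence[float], tw: TransitionWindows) -> np.ndarray:
    """Vectorised labelling: 0 for steady, k (1-based) for transition k.

    Window bounds are closed on both ends.  A timestamp covered by two
    overlapping windows is assigned to the earlier-onset window (logged).
    """
    t = np.asarray(timestamps, dtype=float)
    out = np.zeros(t.shape, dtype=int)
    overlap_hits = 0
    # Iterate from the latest window backwards so earlier windows win ties.
    for w in reversed(tw.windows):
        mask = (t >= w.start) & (t <= w.end)
        overlap_hits += int(np.count_nonzero(mask & (out > 0)))
        out[mask] = w.transition_id
    if overlap_hits:
        logger.warning("label_array: %d timestamps fell in overlapping windows; assigned to the earlier onset", overlap_hits)
        warnings.warn(f"{overlap_hits} timestamps in overlapping transition windows; earlier window wins", stacklevel=2)
    return out


def label_timestamps(timestamps: Iterable[float], tw: TransitionWindows) -> list[StateLabel]:
    """Label each timestamp steady or transition-k.  Labels partition the input."""
    codes = label_array(list(timestamps), tw)
    return [STEADY if c == 0 else StateLabel(State.transition, int(c)) for c in codes]
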