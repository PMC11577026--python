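"""Scored behavior events (ethogram) and their phase statistics.

The territorial ethogram comprises four manually scored agonistic
behaviors — attack, chase, flight and defensive upright posture — stored as
timed bouts per mouse. Sessions are analysed in an early phase (first
20 min after the gate opens) and a late phase (by default the last 20 min
of the 120-min challenge; the 100–110 min variant used in some published
panels is selectable), optionally subdivided into 10-min subintervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BEHAVIORS",
    "EthogramEvent",
    "PhaseWindows",
    "events_to_frame",
    "read_events",
    "write_events",
    "behavior_counts",
    "pair_difference",
    "attack_penetrance",
    "difference_evolution",
]

#: fixed ethogram vocabulary
BEHAVIORS = ("attack", "chase", "flight", "upright")


@dataclass(frozen=True)
class EthogramEvent:
    """One scored behavior bout."""

    mouse_id: str
    behavior: str
    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if self.behavior not in BEHAVIORS:
            raise ValueError(f"unknown behavior {self.behavior!r}; expected one of {BEHAVIORS}")
        if self.offset_s < self.onset_s:
            raise ValueError("offset_s must be >= onset_s")


@dataclass(frozen=True)
class PhaseWindows:
    """Early/late observation windows of a session, in seconds.

    ``late_mode='last20'`` uses the final 20 min of the session;
    ``late_mode='100-110'`` uses the 100–110 min window instead.
    """

    session_s: float = 120 * 60.0
    early: tuple[float, float] = (0.0, 20 * 60.0)
    late_mode: str = "last20"
    subinterval_s: float = 10 * 60.0

    @property
    def late(self) -> tuple[float, float]:
        if self.late_mode == "last20":
            return (self.session_s - 20 * 60.0, self.session_s)
        if self.late_mode == "100-110":
            return (100 * 60.0, 110 * 60.0)
        raise ValueError(f"unknown late_mode {self.late_mode!r}")

    def subintervals(self, phase: str) -> list[tuple[float, float]]:
        lo, hi = {"early": self.early, "late": self.late}[phase]
        edges = np.arange(lo, hi + 1e-9, self.subinterval_s)
        return [(float(a), float(b)) for a, b in zip(edges[:-1], edges[1:])]


# ---------------------------------------------------------------------------
# event table IO (tidy CSV: mouse_id, behavior, onset_s, offset_s)

def events_to_frame(events: Iterable[EthogramEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.mouse_id, e.behavior, e.onset_s, e.offset_s) for e in events],
        columns=["mouse_id", "behavior", "onset_s", "offset_s"],
    )


def events_from_frame(df: pd.DataFrame) -> list[EthogramEvent]:
    return [
        EthogramEvent(str(r.mouse_id), str(r.behavior), float(r.onset_s), float(r.offset_s))
        for r in df.itertuples(index=False)
    ]


def write_events(events: Iterable[EthogramEvent], path: str | Path) -> None:
    events_to_frame(events).to_csv(path, index=False)


def read_events(path: str | Path) -> list[EthogramEvent]:
    df = pd.read_csv(path)
    missing = {"mouse_id", "behavior", "onset_s", "offset_s"} - set(df.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    return events_from_frame(df)


# ---------------------------------------------------------------------------
# statistics

def behavior_counts(
    events: Iterable[EthogramEvent],
    mouse_id: str,
    behavior: str,
    window: tuple[float, float],
) -> int:
    """Number of events of one behavior whose ONSET falls in [start, end).

    Onset-based assignment: a bout straddling a window edge counts once,
    in the window containing its onset.
    """
    if behavior not in BEHAVIORS:
        raise ValueError(f"unknown behavior {behavior!r}")
    lo, hi = window
    return sum(
        1
        for e in events
        if e.mouse_id == mouse_id and e.behavior == behavior and lo <= e.onset_s < hi
    )


def pair_difference(
    values: Mapping[str, float], pair: tuple[str, str], absolute: bool = True
) -> float:
    """Within-pair difference of a per-mouse value (first minus second)."""
    for m in pair:
        if m not in values:
            raise KeyError(f"no value for pair member {m!r}")
    d = values[pair[0]] - values[pair[1]]
    return abs(d) if absolute else d


def attack_penetrance(
    events: Iterable[EthogramEvent], pairs: Sequence[tuple[str, str]]
) -> float:
    """Fraction of pairs in which either member attacked at least once."""
    if not pairs:
        raise ValueError("need at least one pair")
    attackers = {e.mouse_id for e in events if e.behavior == "attack"}
    hit = sum(1 for a, b in pairs if a in attackers or b in attackers)
    return hit / len(pairs)


def difference_evolution(
    events: Iterable[EthogramEvent],
    pairs: Sequence[tuple[str, str]],
    dominant: Mapping[str, str],
    phases: PhaseWindows,
    behaviors: Sequence[str] = BEHAVIORS,
) -> pd.DataFrame:
    """Dominant-minus-subordinate count differences per 10-min subinterval.

    For every behavior and every subinterval of the early and late phases,
    returns one row per pair with the difference in onset-based counts
    between the pair's dominant and subordinate member. ``dominant`` maps
    pair id (the first member's id is used as the pair key) or a
    representative member to the dominant mouse id; here it maps each
    pair tuple's key ``pair[0]|pair[1]`` — callers normally obtain it from
    the dominance results' ``ranks`` table.
    """
    events = list(events)
    rows = []
    for pair in pairs:
        key = f"{pair[0]}|{pair[1]}"
        if key not in dominant:
            raise KeyError(f"pair {key!r} has no dominance label")
        dom = dominant[key]
        if dom not in pair:
            raise ValueError(f"dominant {dom!r} is not a member of pair {key!r}")
        sub = pair[1] if dom == pair[0] else pair[0]
        for phase in ("early", "late"):
            for k, win in enumerate(phases.subintervals(phase)):
                for beh in behaviors:
                    d = behavior_counts(events, dom, beh, win) - behavior_counts(
                        events, sub, beh, win
                    )
                    rows.append(
                        {
                            "pair": key,
                            "phase": phase,
                            "subinterval": k,
                            "start_s": win[0],
                            "end_s": win[1],
                            "behavior": beh,
                            "dom_minus_sub": d,
                        }
                    )
    return pd.DataFrame(rows)
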