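"""Behavior-matrix assembly and tabular IO.

The analysis matrix holds, per mouse, the seven late-phase behaviors:
event counts (attacks, chases, flights, uprights), locomotion in cm, and
the fractions of the phase spent exploring and hiding. It can be
assembled from scored events plus trajectory metrics, read/written as
tidy CSV, or imported from an article-style scoring workbook with one
sheet per measure.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .dominance import BEHAVIOR_COLUMNS
from .ethogram import EthogramEvent, behavior_counts
from .metrics import TrajectoryMetrics

__all__ = [
    "build_behavior_matrix",
    "read_behavior_matrix",
    "write_behavior_matrix",
    "read_scoring_workbook",
]

#: workbook sheet name -> matrix column
_SHEET_MAP = {
    "attacks": "attacks",
    "chases": "chases",
    "flights": "flights",
    "uprights": "uprights",
    "upright postures": "uprights",
    "locomotion": "locomotion_cm",
    "exploration": "exploration_frac",
    "hiding": "hiding_frac",
}


def build_behavior_matrix(
    events: Iterable[EthogramEvent],
    metrics: Mapping[str, TrajectoryMetrics],
    pairs: Sequence[tuple[str, str]],
    window: tuple[float, float],
    strain: str | None = None,
) -> pd.DataFrame:
    """Assemble the 7-behavior matrix for one phase window.

    ``metrics`` maps mouse id to that mouse's trajectory summary over the
    same window; exploration and hiding enter as fractions of the window
    length.
    """
    events = list(events)
    span = window[1] - window[0]
    if span <= 0:
        raise ValueError("window must have positive length")
    rows = []
    for k, pair in enumerate(pairs):
        for mid in pair:
            if mid not in metrics:
                raise KeyError(f"no trajectory metrics for mouse {mid!r}")
            tm = metrics[mid]
            rows.append(
                {
                    "mouse_id": mid,
                    "pair_id": f"pair_{k}",
                    **({"strain": strain} if strain else {}),
                    "attacks": behavior_counts(events, mid, "attack", window),
                    "chases": behavior_counts(events, mid, "chase", window),
                    "flights": behavior_counts(events, mid, "flight", window),
                    "uprights": behavior_counts(events, mid, "upright", window),
                    "locomotion_cm": tm.locomotion_cm,
                    "exploration_frac": tm.exploration_s / span,
                    "hiding_frac": tm.hiding_s / span,
                }
            )
    return pd.DataFrame(rows)


def write_behavior_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write as tidy long CSV (mouse_id, pair_id[, strain], behavior, value)."""
    ids = [c for c in ("mouse_id", "pair_id", "strain", "phase") if c in matrix.columns]
    tidy = matrix.melt(id_vars=ids, value_vars=list(BEHAVIOR_COLUMNS), var_name="behavior")
    tidy.to_csv(path, index=False)


def read_behavior_matrix(path: str | Path) -> pd.DataFrame:
    """Read the tidy long CSV back into the wide analysis matrix."""
    tidy = pd.read_csv(path)
    need = {"mouse_id", "pair_id", "behavior", "value"}
    missing = need - set(tidy.columns)
    if missing:
        raise ValueError(f"behavior matrix CSV missing columns: {sorted(missing)}")
    ids = [c for c in ("mouse_id", "pair_id", "strain", "phase") if c in tidy.columns]
    wide = tidy.pivot_table(index=ids, columns="behavior", values="value").reset_index()
    wide.columns.name = None
    return wide


def read_scoring_workbook(path: str | Path) -> pd.DataFrame:
    """Import a scoring workbook with one sheet per behavioral measure.

    Each sheet must carry ``mouse_id`` (plus optional ``pair_id`` and
    ``strain``) and a single value column; sheet names are matched
    case-insensitively against the known measures. Returns the wide
    analysis matrix.
    """
    sheets = pd.read_excel(path, sheet_name=None)
    out: pd.DataFrame | None = None
    for name, df in sheets.items():
        key = name.strip().lower()
        if key not in _SHEET_MAP:
            continue
        col = _SHEET_MAP[key]
        ids = [c for c in ("mouse_id", "pair_id", "strain") if c in df.columns]
        if "mouse_id" not in ids:
            raise ValueError(f"sheet {name!r} lacks a mouse_id column")
        value_cols = [c for c in df.columns if c not in ids]
        if len(value_cols) != 1:
            raise ValueError(f"sheet {name!r} must have exactly one value column")
        part = df[ids + value_cols].rename(columns={value_cols[0]: col})
        out = part if out is None else out.merge(part, on=ids, how="outer")
    if out is None:
        raise ValueError("workbook contains no recognised measure sheets")
    missing = set(BEHAVIOR_COLUMNS) - set(out.columns)
    if missing:
        raise ValueError(f"workbook missing measures: {sorted(missing)}")
    return out
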