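"""ROI dwell metrics: occupancy bouts, the sub-second filter, hiding,
exploration, proximity and per-phase trajectory summaries.

All dwell quantities are computed on frame masks (half-open, 0-based frame
intervals) and converted to seconds at the end, so no float time
accumulates. Occupancy bouts shorter than 1 s are discarded per ROI before
any summation — short crossings of a region boundary are tracking
artifacts, not visits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arena import ArenaLayout, roi_labels
from .tracks import PoseTrack, locomotion, speed_series

__all__ = [
    "DwellBout",
    "TrajectoryMetrics",
    "dwell_bouts",
    "min_dwell_filter",
    "hiding_time",
    "exploration_time",
    "proximity_time",
    "compute_trajectory_metrics",
]


@dataclass(frozen=True)
class DwellBout:
    """A maximal run of consecutive frames inside one ROI, [start, end)."""

    roi_name: str
    start_frame: int
    end_frame: int
    frame_rate_hz: float

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise ValueError("end_frame must exceed start_frame")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz


def _as_bool(col) -> np.ndarray:
    """Nullable-boolean column -> plain bool array; NA counts as outside."""
    return np.asarray(pd.array(col, dtype="boolean").fillna(False), dtype=bool)


def dwell_bouts(labels: pd.DataFrame, roi_name: str, frame_rate_hz: float) -> list[DwellBout]:
    """Run-length encode a membership column into maximal occupancy bouts."""
    if roi_name not in labels.columns:
        raise KeyError(f"no membership column for ROI {roi_name!r}")
    inside = _as_bool(labels[roi_name])
    if not inside.any():
        return []
    change = np.flatnonzero(np.diff(inside.astype(np.int8)))
    starts = np.r_[0, change + 1]
    ends = np.r_[change + 1, len(inside)]
    return [
        DwellBout(roi_name, int(s), int(e), frame_rate_hz)
        for s, e in zip(starts, ends)
        if inside[s]
    ]


def min_dwell_filter(bouts: list[DwellBout], min_s: float = 1.0) -> list[DwellBout]:
    """Discard bouts strictly shorter than ``min_s`` (default: < 1 s)."""
    if min_s < 0:
        raise ValueError("min_s must be >= 0")
    return [b for b in bouts if b.duration_s >= min_s]


def _bout_mask(bouts: list[DwellBout], n_frames: int) -> np.ndarray:
    mask = np.zeros(n_frames, dtype=bool)
    for b in bouts:
        mask[b.start_frame : b.end_frame] = True
    return mask


def filtered_roi_mask(
    labels: pd.DataFrame, roi_names: list[str], frame_rate_hz: float, min_s: float = 1.0
) -> np.ndarray:
    """Frame mask of the union of >= min_s occupancy bouts over given ROIs.

    The sub-second filter is applied per ROI independently before the
    union, so a frame belonging to a retained bout of any listed ROI is in.
    """
    n = len(labels)
    mask = np.zeros(n, dtype=bool)
    for name in roi_names:
        bouts = min_dwell_filter(dwell_bouts(labels, name, frame_rate_hz), min_s)
        mask |= _bout_mask(bouts, n)
    return mask


def _window_slice(window: tuple[float, float] | None, n: int, fps: float) -> slice:
    if window is None:
        return slice(0, n)
    i0 = max(0, int(np.ceil(window[0] * fps)))
    i1 = min(n, int(np.ceil(window[1] * fps)))
    return slice(i0, max(i0, i1))


def hiding_time(
    labels: pd.DataFrame,
    layout: ArenaLayout,
    window: tuple[float, float] | None = None,
    min_s: float = 1.0,
) -> float:
    """Seconds spent in the 12 hiding refuges within a time window.

    Sum over the union of retained (>= 1 s) bouts across the refuge ROIs;
    a frame inside several refuges at once counts once.
    """
    fps = layout.frame_rate_hz
    names = [r.name for r in layout.hiding_rois]
    mask = filtered_roi_mask(labels, names, fps, min_s)
    sl = _window_slice(window, len(mask), fps)
    return float(mask[sl].sum()) / fps


def exploration_time(
    labels: pd.DataFrame,
    layout: ArenaLayout,
    own_compartment_id: int,
    window: tuple[float, float] | None = None,
    min_s: float = 1.0,
) -> float:
    """Seconds in the opponent's compartment outside its hiding refuges.

    Time in the opponent compartment (after the sub-second filter) minus
    the time simultaneously inside that compartment's refuges; never
    negative by construction (frame-mask subtraction).
    """
    if own_compartment_id not in (1, 2):
        raise ValueError("own_compartment_id must be 1 or 2")
    opp = 2 if own_compartment_id == 1 else 1
    fps = layout.frame_rate_hz
    comp_name = layout.compartment_roi(opp).name
    comp_mask = filtered_roi_mask(labels, [comp_name], fps, min_s)
    hide_names = [r.name for r in layout.hiding_rois if r.compartment_id == opp]
    hide_mask = filtered_roi_mask(labels, hide_names, fps, min_s)
    sl = _window_slice(window, len(comp_mask), fps)
    frames = (comp_mask & ~hide_mask)[sl]
    return float(frames.sum()) / fps


def compartment_time(
    labels: pd.DataFrame,
    layout: ArenaLayout,
    compartment_id: int,
    window: tuple[float, float] | None = None,
    min_s: float = 1.0,
) -> float:
    """Filtered seconds inside one compartment over a window."""
    fps = layout.frame_rate_hz
    name = layout.compartment_roi(compartment_id).name
    mask = filtered_roi_mask(labels, [name], fps, min_s)
    sl = _window_slice(window, len(mask), fps)
    return float(mask[sl].sum()) / fps


def proximity_time(
    track_a: PoseTrack,
    track_b: PoseTrack,
    layout: ArenaLayout,
    anchor: str = "middle back",
    threshold_cm: float = 10.0,
    window: tuple[float, float] | None = None,
    min_s: float = 1.0,
) -> float:
    """Seconds the two mice spend < threshold apart within the same ROI.

    The ROI set is the proximity list (each compartment, each cage top,
    each food-column top); each mouse's occupancy of each such ROI is
    sub-second-filtered first. Frames with a missing anchor in either
    track are excluded. Symmetric in the two tracks.
    """
    if track_a.n_frames != track_b.n_frames:
        raise ValueError("tracks must share the frame grid")
    fps = layout.frame_rate_hz
    rois = layout.proximity_rois
    la = roi_labels(track_a, layout, anchor, rois=rois)
    lb = roi_labels(track_b, layout, anchor, rois=rois)
    n = track_a.n_frames
    same_roi = np.zeros(n, dtype=bool)
    for r in rois:
        ma = filtered_roi_mask(la, [r.name], fps, min_s)
        mb = filtered_roi_mask(lb, [r.name], fps, min_s)
        same_roi |= ma & mb
    pa, pb = track_a.xy(anchor), track_b.xy(anchor)
    ok = np.isfinite(pa).all(axis=1) & np.isfinite(pb).all(axis=1)
    dist = np.hypot(*(pa - pb).T)
    close = ok & (dist < threshold_cm)
    sl = _window_slice(window, n, fps)
    return float((same_roi & close)[sl].sum()) / fps


@dataclass(frozen=True)
class TrajectoryMetrics:
    """Per-mouse trajectory summary over one phase window."""

    mouse_id: str
    window: tuple[float, float]
    locomotion_cm: float
    hiding_s: float
    exploration_s: float
    mean_speed_cm_s: float
    per_roi_dwell_s: dict[str, float]

    def __post_init__(self) -> None:
        for name, v in (
            ("locomotion_cm", self.locomotion_cm),
            ("hiding_s", self.hiding_s),
            ("exploration_s", self.exploration_s),
        ):
            if v < 0:
                raise ValueError(f"{name} must be nonnegative")


def compute_trajectory_metrics(
    track: PoseTrack,
    layout: ArenaLayout,
    own_compartment_id: int,
    window: tuple[float, float],
    anchor: str = "middle back",
    min_s: float = 1.0,
) -> TrajectoryMetrics:
    """All trajectory-derived measures of one mouse over one window."""
    fps = layout.frame_rate_hz
    labels = roi_labels(track, layout, anchor)
    sl = _window_slice(window, track.n_frames, fps)
    per_roi = {}
    for r in layout.rois:
        mask = filtered_roi_mask(labels, [r.name], fps, min_s)
        per_roi[r.name] = float(mask[sl].sum()) / fps
    v = speed_series(track, anchor)[sl]
    return TrajectoryMetrics(
        mouse_id=track.mouse_id,
        window=window,
        locomotion_cm=locomotion(track, anchor, window),
        hiding_s=hiding_time(labels, layout, window, min_s),
        exploration_s=exploration_time(labels, layout, own_compartment_id, window, min_s),
        mean_speed_cm_s=float(np.nanmean(v)) if np.isfinite(v).any() else float("nan"),
        per_roi_dwell_s=per_roi,
    )
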