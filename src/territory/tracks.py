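"""Pose-track ingestion and cleaning.

Tracks arrive as per-frame (x, y, likelihood) triplets for 8 body parts per
animal, exported by markerless pose-estimation software as a CSV with a
multi-row header (scorer / [individuals] / bodyparts / coords). Recording is
at 45 frames/s from overhead cameras; coordinates are in cm once the
pixel-to-cm scale is applied.

Cleaning follows the standard recipe for such data: drop low-likelihood
detections, bridge short gaps by linear interpolation, leave long gaps
missing, then smooth with a centred moving average.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "BODYPARTS",
    "PoseTrack",
    "read_pose_table",
    "write_pose_table",
    "clean_track",
    "speed_series",
    "locomotion",
]

#: the 8 annotated body parts
BODYPARTS = (
    "nose",
    "right ear",
    "left ear",
    "middle back",
    "right side",
    "left side",
    "tail base",
    "tail end",
)


@dataclass
class PoseTrack:
    """Per-frame 2-D pose of one mouse.

    ``data`` has MultiIndex columns (bodypart, field) with fields ``x``,
    ``y`` (cm; NaN = missing) and ``likelihood`` (in [0, 1]; NaN where the
    tracker reported none).
    """

    mouse_id: str
    frame_rate_hz: float
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        lik = self.data.xs("likelihood", axis=1, level=1, drop_level=False)
        vals = lik.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("likelihood values must lie in [0, 1]")

    @property
    def bodyparts(self) -> tuple[str, ...]:
        return tuple(self.data.columns.get_level_values(0).unique())

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    def xy(self, bodypart: str) -> np.ndarray:
        """(n_frames, 2) float array of the body part's coordinates."""
        if bodypart not in self.bodyparts:
            raise KeyError(f"unknown body part {bodypart!r}")
        return self.data[bodypart][["x", "y"]].to_numpy(dtype=float)

    def likelihood(self, bodypart: str) -> np.ndarray:
        return self.data[bodypart]["likelihood"].to_numpy(dtype=float)


def _build_frame(
    coords: Mapping[str, np.ndarray], likelihood: Mapping[str, np.ndarray] | None
) -> pd.DataFrame:
    cols = {}
    for bp, xy in coords.items():
        xy = np.asarray(xy, dtype=float)
        cols[(bp, "x")] = xy[:, 0]
        cols[(bp, "y")] = xy[:, 1]
        lik = None if likelihood is None else likelihood.get(bp)
        cols[(bp, "likelihood")] = (
            np.ones(len(xy)) if lik is None else np.asarray(lik, dtype=float)
        )
    df = pd.DataFrame(cols)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["bodyparts", "coords"])
    return df


def track_from_arrays(
    mouse_id: str,
    frame_rate_hz: float,
    coords: Mapping[str, np.ndarray],
    likelihood: Mapping[str, np.ndarray] | None = None,
) -> PoseTrack:
    """Assemble a PoseTrack from per-bodypart (n, 2) coordinate arrays."""
    return PoseTrack(mouse_id, frame_rate_hz, _build_frame(coords, likelihood))


# ---------------------------------------------------------------------------
# multi-header CSV dialect

def read_pose_table(
    path: str | Path,
    frame_rate_hz: float = 45.0,
    px_per_cm: float | None = None,
) -> dict[str, PoseTrack]:
    """Read a tracking-table CSV into one PoseTrack per animal.

    Accepts both the single-animal dialect (header rows scorer / bodyparts /
    coords) and the multi-animal dialect (scorer / individuals / bodyparts /
    coords). The first column is the frame index. If ``px_per_cm`` is given,
    coordinates are divided by it (likelihoods untouched).
    """
    path = Path(path)
    with open(path) as fh:
        head = [fh.readline().rstrip("\n") for _ in range(4)]
    labels = [line.split(",", 1)[0] for line in head]
    if "individuals" in labels:
        header_rows = [0, 1, 2, 3]
    elif "bodyparts" in labels[:3]:
        header_rows = [0, 1, 2]
    else:
        raise ValueError(
            f"{path.name}: header does not declare 'bodyparts' rows "
            "(expected tracking-table dialect)"
        )
    df = pd.read_csv(path, header=header_rows, index_col=0)
    if df.isna().all(axis=1).any() and df.shape[1] == 0:
        raise ValueError(f"{path.name}: no data columns")
    # drop the scorer level; keep (individual,) bodyparts, coords
    df.columns = df.columns.droplevel(0)
    if len(header_rows) == 3:
        df.columns = pd.MultiIndex.from_tuples(
            [("animal_0", bp, c) for bp, c in df.columns],
            names=["individuals", "bodyparts", "coords"],
        )
    else:
        df.columns = df.columns.set_names(["individuals", "bodyparts", "coords"])

    tracks: dict[str, PoseTrack] = {}
    for ind in df.columns.get_level_values(0).unique():
        sub = df[ind].copy()
        for bp in sub.columns.get_level_values(0).unique():
            have = set(sub[bp].columns)
            for needed in ("x", "y"):
                if needed not in have:
                    raise ValueError(
                        f"{path.name}: body part {bp!r} of {ind!r} is missing "
                        f"its {needed!r} column"
                    )
            if "likelihood" not in have:
                sub[(bp, "likelihood")] = 1.0
        sub = sub.sort_index(axis=1)
        if px_per_cm is not None:
            xy_cols = sub.columns.get_level_values(1).isin(["x", "y"])
            sub.loc[:, xy_cols] = sub.loc[:, xy_cols] / px_per_cm
        sub = sub.reset_index(drop=True)
        sub.columns = sub.columns.set_names(["bodyparts", "coords"])
        tracks[str(ind)] = PoseTrack(str(ind), frame_rate_hz, sub)
    return tracks


def write_pose_table(
    tracks: Mapping[str, PoseTrack], path: str | Path, scorer: str = "territory"
) -> None:
    """Write tracks in the multi-animal multi-header CSV dialect."""
    frames = []
    for mid, tr in tracks.items():
        df = tr.data.copy()
        df.columns = pd.MultiIndex.from_tuples(
            [(scorer, mid, bp, c) for bp, c in df.columns],
            names=["scorer", "individuals", "bodyparts", "coords"],
        )
        frames.append(df)
    out = pd.concat(frames, axis=1)
    out.index.name = None
    out.to_csv(path, index=True)


# ---------------------------------------------------------------------------
# cleaning

def _interpolate_short_gaps(a: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly fill interior NaN runs of length <= max_gap frames."""
    a = a.copy()
    if max_gap <= 0:
        return a
    isnan = np.isnan(a)
    if not isnan.any() or isnan.all():
        return a
    idx = np.arange(len(a))
    # run-length encode the NaN mask
    change = np.flatnonzero(np.diff(isnan.astype(int)))
    starts = np.r_[0, change + 1]
    ends = np.r_[change + 1, len(a)]
    for s, e in zip(starts, ends):
        if not isnan[s]:
            continue
        if s == 0 or e == len(a):  # edge gaps cannot be interpolated
            continue
        if e - s <= max_gap:
            a[s:e] = np.interp(idx[s:e], [s - 1, e], [a[s - 1], a[e]])
    return a


def _centered_moving_average(a: np.ndarray, window: int) -> np.ndarray:
    """NaN-aware centred moving mean; NaNs in the input stay NaN."""
    if window <= 1:
        return a.copy()
    s = pd.Series(a)
    sm = s.rolling(window, center=True, min_periods=1).mean().to_numpy()
    sm[np.isnan(a)] = np.nan
    return sm


def clean_track(
    track: PoseTrack,
    confidence_threshold: float = 0.6,
    max_gap_s: float = 0.5,
    smooth_window_s: float = 5 / 45,
) -> PoseTrack:
    """Standard cleaning: mask, interpolate, smooth.

    Coordinates whose likelihood falls below ``confidence_threshold`` are
    set missing; interior missing runs no longer than ``max_gap_s`` are
    linearly interpolated; remaining gaps stay missing; both coordinate
    series are then smoothed with a centred moving average of
    ``smooth_window_s`` (rounded to an odd number of frames). Output length
    equals input length. An entirely-missing track passes through unchanged.
    """
    if max_gap_s < 0 or smooth_window_s < 0:
        raise ValueError("max_gap_s and smooth_window_s must be >= 0")
    fps = track.frame_rate_hz
    max_gap = int(round(max_gap_s * fps))
    window = max(1, int(round(smooth_window_s * fps)))
    if window % 2 == 0:
        window += 1
    df = track.data.copy()
    for bp in track.bodyparts:
        lik = df[(bp, "likelihood")].to_numpy(dtype=float)
        bad = np.isfinite(lik) & (lik < confidence_threshold)
        for c in ("x", "y"):
            a = df[(bp, c)].to_numpy(dtype=float)
            a[bad] = np.nan
            a = _interpolate_short_gaps(a, max_gap)
            a = _centered_moving_average(a, window)
            df[(bp, c)] = a
    return replace(track, data=df)


# ---------------------------------------------------------------------------
# kinematic primitives

def speed_series(track: PoseTrack, anchor: str = "middle back") -> np.ndarray:
    """Per-frame speed (cm/s) of the anchor by centred finite differences.

    ``v[i] = |p[i+1] - p[i-1]| * fps / 2``; NaN at both ends and wherever a
    neighbouring frame is missing.
    """
    xy = track.xy(anchor)
    v = np.full(len(xy), np.nan)
    if len(xy) >= 3:
        d = xy[2:] - xy[:-2]
        v[1:-1] = np.hypot(d[:, 0], d[:, 1]) * track.frame_rate_hz / 2.0
    return v


def locomotion(
    track: PoseTrack,
    anchor: str = "middle back",
    window: tuple[float, float] | None = None,
) -> float:
    """Total path length (cm) of the anchor over a time window.

    Sums inter-frame displacements; steps with a missing endpoint are
    skipped. ``window`` is (start_s, end_s), half-open, defaulting to the
    whole recording.
    """
    xy = track.xy(anchor)
    fps = track.frame_rate_hz
    if window is not None:
        i0 = max(0, int(np.ceil(window[0] * fps)))
        i1 = min(len(xy), int(np.ceil(window[1] * fps)))
        xy = xy[i0:i1]
    if len(xy) < 2:
        return 0.0
    d = np.diff(xy, axis=0)
    step = np.hypot(d[:, 0], d[:, 1])
    return float(np.nansum(step))
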