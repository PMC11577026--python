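"""Flight-aligned peri-event kinematics.

Flights are sudden accelerations away from the opponent. To characterise
their kinematic signature, each flight's moment of peak acceleration is
located as the steepest positive slope of the (smoothed) speed trace
within an asymmetric window around the scored onset (30 s before to 60 s
after); symmetric 8-s windows centred on those frames are then cut from
both the speed and the inter-mouse distance traces and averaged
frame-by-frame across all flights of all mice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .ethogram import EthogramEvent

__all__ = ["KinematicsConfig", "FlightKinematics", "flight_aligned_kinematics"]


@dataclass(frozen=True)
class KinematicsConfig:
    """Windows for flight-aligned averaging (seconds)."""

    pre_s: float = 30.0
    post_s: float = 60.0
    window_s: float = 8.0
    smooth_s: float = 0.5

    def __post_init__(self) -> None:
        if min(self.pre_s, self.post_s, self.window_s) <= 0 or self.smooth_s < 0:
            raise ValueError("window parameters must be positive")


@dataclass(frozen=True)
class FlightKinematics:
    """Mean +/- SEM peri-flight traces and the per-flight alignment centers."""

    time_s: np.ndarray
    speed_mean: np.ndarray
    speed_sem: np.ndarray
    distance_mean: np.ndarray
    distance_sem: np.ndarray
    n_per_frame: np.ndarray
    centers: list[int]
    skipped: list[int]

    def plot(self, ax=None):
        """Mean +/- SEM speed (left axis) and distance (right axis) traces."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3))
        ax.plot(self.time_s, self.speed_mean, c="tab:blue", label="speed")
        ax.fill_between(
            self.time_s,
            self.speed_mean - self.speed_sem,
            self.speed_mean + self.speed_sem,
            color="tab:blue", alpha=0.3, lw=0,
        )
        ax.axvline(0.0, c="0.6", ls="--", lw=1)
        ax.set_xlabel("time from peak acceleration (s)")
        ax.set_ylabel("speed (cm/s)", color="tab:blue")
        ax2 = ax.twinx()
        ax2.plot(self.time_s, self.distance_mean, c="tab:orange", label="distance")
        ax2.fill_between(
            self.time_s,
            self.distance_mean - self.distance_sem,
            self.distance_mean + self.distance_sem,
            color="tab:orange", alpha=0.3, lw=0,
        )
        ax2.set_ylabel("inter-mouse distance (cm)", color="tab:orange")
        return ax

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "speed_mean": self.speed_mean,
                "speed_sem": self.speed_sem,
                "distance_mean": self.distance_mean,
                "distance_sem": self.distance_sem,
                "n": self.n_per_frame,
            }
        )


def _smooth(a: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return a
    if window % 2 == 0:
        window += 1
    s = pd.Series(a).rolling(window, center=True, min_periods=1).mean().to_numpy()
    s[np.isnan(a)] = np.nan
    return s


def steepest_slope_frame(
    speed: np.ndarray, lo: int, hi: int, frame_rate_hz: float, smooth_s: float = 0.5
) -> int:
    """Frame of maximum speed slope within [lo, hi) by centred differences.

    The speed trace is smoothed first; the slope at frame i is
    ``(v[i+1] - v[i-1]) * fps / 2``. Ties (including an all-flat trace,
    slope 0 everywhere) resolve to the earliest frame.
    """
    lo = max(1, lo)
    hi = min(len(speed) - 1, hi)
    if hi <= lo:
        raise ValueError("window contains no interior frames")
    v = _smooth(speed, int(round(smooth_s * frame_rate_hz)))
    slope = (v[lo + 1 : hi + 1] - v[lo - 1 : hi - 1]) * frame_rate_hz / 2.0
    if not np.isfinite(slope).any():
        raise ValueError("speed trace entirely missing in window")
    slope = np.where(np.isfinite(slope), slope, -np.inf)
    return lo + int(np.argmax(slope))  # argmax takes the first maximum


def _collect_window(a: np.ndarray, center: int, half: int) -> np.ndarray:
    """Window a[center-half : center+half+1], NaN-padded at the edges."""
    out = np.full(2 * half + 1, np.nan)
    lo = max(0, center - half)
    hi = min(len(a), center + half + 1)
    out[lo - (center - half) : hi - (center - half)] = a[lo:hi]
    return out


def flight_aligned_kinematics(
    flights: Iterable[EthogramEvent],
    speed_by_mouse: dict[str, np.ndarray],
    distance: np.ndarray,
    frame_rate_hz: float,
    cfg: KinematicsConfig = KinematicsConfig(),
) -> FlightKinematics:
    """Average speed and distance around the peak acceleration of flights.

    For each flight event, the steepest positive speed slope of the fleeing
    mouse within [onset - pre_s, onset + post_s] defines the alignment
    center; 8-s windows around the same centers are cut from both the
    mouse's speed trace and the shared inter-mouse distance trace and
    averaged frame-by-frame (missing-aware) across flights. Windows
    partially outside the recording contribute their available frames;
    flights whose search window lies entirely outside are skipped.
    """
    flights = [f for f in flights if f.behavior == "flight"]
    half = int(round(cfg.window_s / 2 * frame_rate_hz))
    n_frames = len(distance)
    speed_wins, dist_wins, centers, skipped = [], [], [], []
    for i, f in enumerate(flights):
        if f.mouse_id not in speed_by_mouse:
            raise KeyError(f"no speed series for mouse {f.mouse_id!r}")
        v = speed_by_mouse[f.mouse_id]
        onset = int(round(f.onset_s * frame_rate_hz))
        lo = onset - int(round(cfg.pre_s * frame_rate_hz))
        hi = onset + int(round(cfg.post_s * frame_rate_hz))
        if hi <= 1 or lo >= n_frames - 1:
            skipped.append(i)
            continue
        try:
            c = steepest_slope_frame(
                v, max(1, lo), min(n_frames - 1, hi), frame_rate_hz, cfg.smooth_s
            )
        except ValueError:
            skipped.append(i)
            continue
        centers.append(c)
        speed_wins.append(_collect_window(v, c, half))
        dist_wins.append(_collect_window(distance, c, half))
    if not centers:
        raise ValueError("no usable flights")
    sw = np.vstack(speed_wins)
    dw = np.vstack(dist_wins)
    n = np.isfinite(sw).sum(axis=0)

    def _mean_sem(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        k = np.isfinite(w).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            m = np.nanmean(w, axis=0)
            sd = np.nanstd(w, axis=0, ddof=1)
        sem = np.where(k > 1, sd / np.sqrt(k), np.where(k == 1, 0.0, np.nan))
        return m, sem

    sm, ssem = _mean_sem(sw)
    dm, dsem = _mean_sem(dw)
    t = (np.arange(2 * half + 1) - half) / frame_rate_hz
    return FlightKinematics(t, sm, ssem, dm, dsem, n, centers, skipped)
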