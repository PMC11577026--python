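"""Seeded synthetic cohorts for exercising the full analysis pipeline.

Real recordings of the assay are two-mouse trajectories in the
two-compartment arena over a 2-h challenge, manually scored agonistic
events, and floor photographs of dye-labelled urine marks. This module
emulates all three with known ground truth so every pipeline stage can be
tested end-to-end without external data.

The cohort-level knob is the divergence ``delta`` in [0, 1]:

* ``delta = 0`` — a null cohort: the two pair members are statistically
  exchangeable throughout (no rank divergence, sustained proximity),
  emulating strains that fail to form a hierarchy.
* ``delta = 1`` — a strongly diverging cohort: event rates, hiding,
  exploration and marking ramp linearly from parity at gate opening to
  full dominant/subordinate asymmetry by the late phase, emulating
  outbred pairs that form robust hierarchies.

The movement model is a two-mode (roam/hide) waypoint walk with
rank- and time-dependent mode switching plus scripted high-speed flight
bursts (> 50 cm/s at peak against a < 20 cm/s roaming baseline). It is a
test harness, not a behavioral model claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .arena import ArenaLayout, default_layout, save_layout
from .ethogram import BEHAVIORS, EthogramEvent, write_events
from .marking import FloorImage
from .tracks import BODYPARTS, PoseTrack, track_from_arrays, write_pose_table

__all__ = [
    "CohortSpec",
    "SimulatedPair",
    "simulate_pair",
    "simulate_cohort",
    "simulate_behavior_matrix",
    "render_mark_image",
]


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of a synthetic cohort.

    Event base rates are per mouse per 20 min at parity; the dominant's
    attack/chase rates scale by ``1 + delta * ramp(t)`` and the
    subordinate's by ``1 - delta * ramp(t)`` (flight/upright reversed),
    with a linear ramp from 0 at gate opening to 1 at ``ramp_full_min``.
    """

    n_pairs: int = 10
    session_min: float = 120.0
    frame_rate_hz: float = 45.0
    delta: float = 1.0
    # event rates per 20 min per mouse at parity
    attack_rate: float = 11.0
    chase_rate: float = 8.0
    flight_rate: float = 10.0
    upright_rate: float = 5.0
    ramp_full_min: float = 100.0
    # movement model
    roam_speed_cm_s: float = 8.0
    max_roam_speed_cm_s: float = 14.0
    flight_peak_cm_s: float = 70.0
    flight_duration_s: float = 1.2
    # hiding model: P(next bout is a hide bout)
    base_hide_prob: float = 0.25
    hide_bout_mean_s: float = 25.0
    roam_bout_mean_s: float = 35.0
    # marking model (percent of floor area per dye)
    dominant_mark_pct: float = 3.0
    subordinate_mark_pct: float = 0.2
    null_mark_pct: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        for r in (self.attack_rate, self.chase_rate, self.flight_rate, self.upright_rate):
            if r < 0:
                raise ValueError("event rates must be >= 0")

    @property
    def session_s(self) -> float:
        return self.session_min * 60.0

    def ramp(self, t_s: np.ndarray | float) -> np.ndarray | float:
        return np.minimum(np.asarray(t_s, float) / (self.ramp_full_min * 60.0), 1.0)


@dataclass
class SimulatedPair:
    """One simulated pair: tracks, events and the planted ground truth."""

    tracks: tuple[PoseTrack, PoseTrack]
    events: list[EthogramEvent]
    truth: dict


def _pair_rngs(seed: int, n_pairs: int) -> list[np.random.Generator]:
    """Independent per-pair generators spawned from the cohort seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_pairs)]


# ---------------------------------------------------------------------------
# events

def _rate_multiplier(role: str, behavior: str, delta: float, ramp: np.ndarray) -> np.ndarray:
    """Dominants attack/chase more and flee/rear less; subordinates mirror."""
    sign = 1.0 if behavior in ("attack", "chase") else -1.0
    if role == "sub":
        sign = -sign
    return np.clip(1.0 + sign * delta * ramp, 0.0, None)


def _draw_events(
    rng: np.random.Generator, mouse_id: str, role: str, spec: CohortSpec
) -> list[EthogramEvent]:
    base = {
        "attack": spec.attack_rate,
        "chase": spec.chase_rate,
        "flight": spec.flight_rate,
        "upright": spec.upright_rate,
    }
    events = []
    bin_s = 60.0
    edges = np.arange(0.0, spec.session_s, bin_s)
    mids = edges + bin_s / 2
    ramp = spec.ramp(mids)
    for beh in BEHAVIORS:
        rate_per_s = base[beh] / (20.0 * 60.0)
        lam = rate_per_s * _rate_multiplier(role, beh, spec.delta, ramp) * bin_s
        counts = rng.poisson(lam)
        for t0, k in zip(edges, counts):
            for _ in range(int(k)):
                onset = t0 + rng.uniform(0.0, bin_s)
                dur = rng.uniform(0.5, 2.5)
                events.append(
                    EthogramEvent(mouse_id, beh, onset, min(onset + dur, spec.session_s))
                )
    events.sort(key=lambda e: e.onset_s)
    return events


# ---------------------------------------------------------------------------
# trajectories

def _hide_targets(layout: ArenaLayout, compartment_id: int) -> list[np.ndarray]:
    out = []
    for r in layout.hiding_rois:
        if r.compartment_id == compartment_id:
            c = r.polygon.centroid
            out.append(np.array([c.x, c.y]))
    return out


_PASSAGE_XY = np.array([60.0, 60.0])


def _compartment_box(compartment_id: int, margin: float = 2.0) -> tuple[float, float, float, float]:
    y0 = 0.0 if compartment_id == 1 else 60.0
    return (margin, 120.0 - margin, y0 + margin, y0 + 60.0 - margin)


def _simulate_path(
    rng: np.random.Generator,
    spec: CohortSpec,
    layout: ArenaLayout,
    role: str,
    own_compartment: int,
    flight_onsets: Sequence[float],
) -> tuple[np.ndarray, list[tuple[float, float, str]]]:
    """Middle-back path at frame resolution plus the scheduled hide bouts.

    Returns (positions (n, 2), hide_schedule [(start_s, end_s, roi-side)]).
    """
    fps = spec.frame_rate_hz
    n = int(round(spec.session_s * fps))
    pos = np.empty((n, 2))
    x0, x1, ylo, yhi = _compartment_box(own_compartment)
    cur = np.array([rng.uniform(x0, x1), rng.uniform(ylo, yhi)])
    hide_targets = {1: _hide_targets(layout, 1), 2: _hide_targets(layout, 2)}
    hide_schedule: list[tuple[float, float, str]] = []
    flights = sorted(flight_onsets)
    fi = 0
    i = 0  # current frame
    comp = own_compartment

    def _next_flight_frame() -> int:
        return int(round(flights[fi] * fps)) if fi < len(flights) else n

    def _fill_travel(
        i: int, cur: np.ndarray, target: np.ndarray, speed: float, stop: int
    ) -> tuple[int, np.ndarray]:
        d = target - cur
        dist = float(np.hypot(*d))
        k = max(1, int(round(dist / speed * fps)))
        k_full = k
        k = min(k, n - i, max(1, stop - i))
        if k <= 0 or i >= n:
            return i, cur
        frac = np.arange(1, k + 1) / k_full  # partial if truncated by `stop`
        seg = cur + np.outer(frac, d)
        pos[i : i + k] = seg
        return i + k, seg[-1].copy()

    while i < n:
        t = i / fps
        comp = 1 if cur[1] < 60.0 else 2
        ramp = float(spec.ramp(t))
        # mode choice: subordinates hide more as divergence ramps up
        p_hide = spec.base_hide_prob
        if role == "sub":
            p_hide = min(0.95, p_hide + 0.6 * spec.delta * ramp)
        else:
            p_hide = max(0.05, p_hide * (1.0 - 0.6 * spec.delta * ramp))
        # flight burst due?
        if fi < len(flights) and i >= _next_flight_frame() - int(0.5 * fps):
            fi += 1
            # sinusoidal speed burst toward the compartment centre
            kf = int(round(spec.flight_duration_s * fps))
            kf = min(kf, n - i)
            if kf > 0:
                comp_now = 1 if cur[1] < 60.0 else 2
                fx0, fx1, fylo, fyhi = _compartment_box(comp_now)
                cx = (fx0 + fx1) / 2 + rng.uniform(-20, 20)
                cy = (fylo + fyhi) / 2 + rng.uniform(-10, 10)
                d = np.array([cx, cy]) - cur
                nd = np.hypot(*d)
                u = d / nd if nd > 1e-6 else np.array([1.0, 0.0])
                tt = (np.arange(kf) + 1) / fps
                sp = spec.flight_peak_cm_s * np.sin(np.pi * tt / spec.flight_duration_s) ** 2
                step = np.cumsum(sp / fps)
                seg = cur + np.outer(step, u)
                seg[:, 0] = np.clip(seg[:, 0], fx0, fx1)
                seg[:, 1] = np.clip(seg[:, 1], fylo, fyhi)
                pos[i : i + kf] = seg
                i += kf
                cur = seg[-1]
            continue
        stop = _next_flight_frame()
        if rng.uniform() < p_hide:
            # hide bout in the own compartment's refuges
            dur = rng.exponential(
                spec.hide_bout_mean_s
                * (1.0 + (2.0 * spec.delta * ramp if role == "sub" else 0.0))
            )
            dur = float(np.clip(dur, 3.0, 300.0))
            targets = hide_targets[own_compartment]
            target = targets[rng.integers(len(targets))]
            if comp != own_compartment:
                i, cur = _fill_travel(i, cur, _PASSAGE_XY, 10.0, stop)
                comp = own_compartment
            i, cur = _fill_travel(i, cur, target, 12.0, stop)
            t_start = i / fps
            k = min(int(round(dur * fps)), n - i, max(1, stop - i))
            if k > 0 and i < n:
                jit = rng.normal(0.0, 0.4, size=(k, 2)).cumsum(axis=0)
                jit -= np.linspace(0, 1, k)[:, None] * jit[-1]  # bridge back
                jit = np.clip(jit, -1.5, 1.5)
                pos[i : i + k] = target + 0.2 * jit
                i += k
                cur = pos[i - 1].copy()
                hide_schedule.append((t_start, i / fps, f"compartment_{own_compartment}"))
        else:
            # roam bout: waypoint walk, possibly exploring the opponent side
            dur = float(np.clip(rng.exponential(spec.roam_bout_mean_s), 3.0, 200.0))
            t_end = min(t + dur, n / fps, stop / fps)
            p_explore = 0.2 + (
                0.2 * spec.delta * ramp if role == "dom" else -0.18 * spec.delta * ramp
            )
            while i / fps < t_end and i < n:
                explore = rng.uniform() < p_explore
                want = (3 - own_compartment) if explore else own_compartment
                if want != comp:
                    i, cur = _fill_travel(i, cur, _PASSAGE_XY, 10.0, stop)
                    comp = want
                bx0, bx1, bylo, byhi = _compartment_box(comp)
                wp = np.array([rng.uniform(bx0, bx1), rng.uniform(bylo, byhi)])
                v = float(
                    np.clip(rng.normal(spec.roam_speed_cm_s, 2.5), 3.0, spec.max_roam_speed_cm_s)
                )
                i, cur = _fill_travel(i, cur, wp, v, stop)
                if i >= stop:
                    break
    return pos, hide_schedule


def _dress_bodyparts(
    rng: np.random.Generator, mb: np.ndarray, fps: float
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Derive the 8 body parts from the middle-back path + heading."""
    vel = np.gradient(mb, axis=0) * fps
    sp = np.hypot(*vel.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(sp[:, None] > 1e-6, vel / np.maximum(sp[:, None], 1e-6), 0.0)
    # carry last heading through standstills
    for k in range(1, len(u)):
        if np.hypot(*u[k]) < 1e-6:
            u[k] = u[k - 1]
    perp = np.stack([-u[:, 1], u[:, 0]], axis=1)
    offsets = {
        "nose": 3.5 * u,
        "right ear": 2.5 * u + 1.0 * perp,
        "left ear": 2.5 * u - 1.0 * perp,
        "middle back": 0.0 * u,
        "right side": 1.5 * perp,
        "left side": -1.5 * perp,
        "tail base": -3.0 * u,
        "tail end": -6.5 * u,
    }
    n = len(mb)
    coords, lik = {}, {}
    for bp in BODYPARTS:
        noise = rng.normal(0.0, 0.05, size=(n, 2))
        coords[bp] = mb + offsets[bp] + noise
        base = np.clip(rng.normal(0.97, 0.02, size=n), 0.0, 1.0)
        # occasional low-confidence dropouts (~1.5 per minute, 2-8 frames)
        n_drop = rng.poisson(1.5 * n / fps / 60.0)
        for _ in range(int(n_drop)):
            s = rng.integers(0, max(1, n - 8))
            base[s : s + rng.integers(2, 9)] = rng.uniform(0.0, 0.3)
        lik[bp] = base
    return coords, lik


def simulate_pair(spec: CohortSpec, pair_rng: np.random.Generator | int, pair_id: str = "pair_0") -> SimulatedPair:
    """Simulate one pair: two pose tracks, scored events and ground truth.

    The planted dominant is drawn at random between the two members; at
    ``delta = 0`` the roles have identical statistics so the label is a
    formality. Ground truth carries the dominant id, each mouse's home
    compartment and the scheduled hide bouts.
    """
    rng = (
        np.random.default_rng(pair_rng) if isinstance(pair_rng, (int, np.integer)) else pair_rng
    )
    layout = default_layout(frame_rate_hz=spec.frame_rate_hz)
    ids = [f"{pair_id}_m1", f"{pair_id}_m2"]
    dom_idx = int(rng.integers(2))
    roles = ["sub", "sub"]
    roles[dom_idx] = "dom"
    comps = [1, 2]
    tracks, events, hide_truth = [], [], {}
    for mid, role, comp in zip(ids, roles, comps):
        ev = _draw_events(rng, mid, role, spec)
        events.extend(ev)
        flights = [e.onset_s for e in ev if e.behavior == "flight"]
        mb, hide_sched = _simulate_path(rng, spec, layout, role, comp, flights)
        coords, lik = _dress_bodyparts(rng, mb, spec.frame_rate_hz)
        tracks.append(track_from_arrays(mid, spec.frame_rate_hz, coords, lik))
        hide_truth[mid] = hide_sched
    events.sort(key=lambda e: e.onset_s)
    truth = {
        "pair_id": pair_id,
        "dominant": ids[dom_idx],
        "subordinate": ids[1 - dom_idx],
        "home_compartment": dict(zip(ids, comps)),
        "hide_schedule": hide_truth,
        "delta": spec.delta,
    }
    return SimulatedPair(tracks=(tracks[0], tracks[1]), events=events, truth=truth)


def simulate_cohort(
    spec: CohortSpec, out_dir: str | Path | None = None
) -> list[SimulatedPair]:
    """Simulate independent pairs under per-pair seeds derived from the
    cohort seed; optionally write every standard input file the pipeline
    reads (layout YAML, pose CSV and event CSV per pair)."""
    rngs = _pair_rngs(spec.seed, spec.n_pairs)
    pairs = [
        simulate_pair(spec, rng, pair_id=f"pair_{k}") for k, rng in enumerate(rngs)
    ]
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_layout(default_layout(frame_rate_hz=spec.frame_rate_hz), out / "layout.yml")
        for p in pairs:
            pid = p.truth["pair_id"]
            write_pose_table({t.mouse_id: t for t in p.tracks}, out / f"{pid}_poses.csv")
            write_events(p.events, out / f"{pid}_events.csv")
    return pairs


# ---------------------------------------------------------------------------
# matrix-level generator (for statistical calibration at scale)

def simulate_behavior_matrix(
    n_pairs: int, delta: float, seed: int, strain: str = "synthetic"
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Draw a late-phase 7-behavior matrix directly, without trajectories.

    Counts are Poisson at the late-phase rates of the full generator;
    locomotion, exploration and hiding are drawn from role-shifted
    distributions with the same direction of divergence. Returns the
    matrix plus the planted dominant per pair id. Fast enough for
    hundreds of cohorts, used for permutation-test calibration and
    rank-recovery curves.
    """
    spec = CohortSpec(n_pairs=n_pairs, delta=delta, seed=seed)
    rng = np.random.default_rng(seed)
    base = {
        "attacks": spec.attack_rate,
        "chases": spec.chase_rate,
        "flights": spec.flight_rate,
        "uprights": spec.upright_rate,
    }
    rows, truth = [], {}
    for k in range(n_pairs):
        dom_first = bool(rng.integers(2))
        pid = f"pair_{k}"
        for j in range(2):
            role = "dom" if (j == 0) == dom_first else "sub"
            sgn = 1.0 if role == "dom" else -1.0
            row = {"mouse_id": f"{pid}_m{j + 1}", "pair_id": pid, "strain": strain}
            for beh, col in (
                ("attack", "attacks"),
                ("chase", "chases"),
                ("flight", "flights"),
                ("upright", "uprights"),
            ):
                mult = float(_rate_multiplier(role, beh, delta, 1.0))
                row[col] = int(rng.poisson(base[col] * mult))
            row["locomotion_cm"] = float(
                np.clip(rng.normal(6000 * (1 + 0.25 * sgn * delta), 700), 100, None)
            )
            row["exploration_frac"] = float(
                np.clip(rng.normal(0.25 * (1 + 0.7 * sgn * delta), 0.06), 0.0, 1.0)
            )
            row["hiding_frac"] = float(
                np.clip(rng.normal(0.30 * (1 - 0.6 * sgn * delta), 0.07), 0.0, 1.0)
            )
            if role == "dom":
                truth[pid] = row["mouse_id"]
            rows.append(row)
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# floor images

_FLUO_RGB = np.array([225, 225, 55], dtype=float)
_ERYT_RGB = np.array([235, 60, 140], dtype=float)
_FLOOR_RGB = np.array([242, 240, 236], dtype=float)


def render_mark_image(
    target_pct: dict[str, float],
    px_per_cm: float = 2.0,
    arena_cm: tuple[float, float] = (120.0, 120.0),
    seed: int = 0,
    noise_sd: float = 4.0,
    illumination_gradient: float = 0.0,
) -> tuple[FloorImage, np.ndarray]:
    """Render a floor photograph with known per-dye marked areas.

    Spots (discs) and streaks (elongated stadium shapes) of each dye are
    painted until the requested percent of the floor area is covered; the
    returned truth raster holds the painted labels (1 = fluorescein,
    2 = erythrosin). ``noise_sd`` adds Gaussian pixel noise and
    ``illumination_gradient`` (0..~0.3) a linear shading across the image.
    """
    rng = np.random.default_rng(seed)
    H = int(round(arena_cm[1] * px_per_cm))
    W = int(round(arena_cm[0] * px_per_cm))
    truth = np.zeros((H, W), dtype=np.uint8)
    yy, xx = np.mgrid[0:H, 0:W]
    total = H * W
    for lab, dye in ((1, "fluorescein"), (2, "erythrosin")):
        want = int(round(target_pct.get(dye, 0.0) / 100.0 * total))
        guard = 0
        while int((truth == lab).sum()) < want and guard < 10_000:
            guard += 1
            cx, cy = rng.uniform(5, W - 5), rng.uniform(5, H - 5)
            if rng.uniform() < 0.5:  # spot
                r = rng.uniform(1.0, 3.0) * px_per_cm
                m = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
            else:  # streak: capsule along a random direction
                L = rng.uniform(4.0, 12.0) * px_per_cm
                w = rng.uniform(0.6, 1.4) * px_per_cm
                th = rng.uniform(0, np.pi)
                ux, uy = np.cos(th), np.sin(th)
                dx, dy = xx - cx, yy - cy
                along = np.clip(dx * ux + dy * uy, -L / 2, L / 2)
                m = (dx - along * ux) ** 2 + (dy - along * uy) ** 2 <= w**2
            m &= truth == 0
            # avoid overshooting the target badly
            if int((truth == lab).sum()) + int(m.sum()) > want + int(0.002 * total):
                continue
            truth[m] = lab
    img = np.tile(_FLOOR_RGB, (H, W, 1))
    img[truth == 1] = _FLUO_RGB
    img[truth == 2] = _ERYT_RGB
    if illumination_gradient:
        shade = 1.0 - illumination_gradient * (xx / max(W - 1, 1))
        img = img * shade[..., None]
    if noise_sd:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    floor = FloorImage(image=img, px_per_cm=px_per_cm, mask=np.ones((H, W), dtype=bool))
    return floor, truth
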