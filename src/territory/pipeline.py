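"""End-to-end pipeline: inputs (or simulation) -> metrics -> dominance ->
statistics -> tidy outputs with a JSON metadata sidecar.

Deterministic given the config and seed; every defaulted convention is
recorded in the sidecar so a run can be audited and reproduced.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .arena import default_layout, load_layout
from .dominance import (
    BEHAVIOR_COLUMNS,
    DominanceModel,
    behavior_correlations,
    repairing_permutation_test,
)
from .ethogram import PhaseWindows, read_events
from .io import build_behavior_matrix, write_behavior_matrix
from .kinematics import KinematicsConfig, flight_aligned_kinematics
from .metrics import compute_trajectory_metrics, proximity_time
from .synthetic import CohortSpec, simulate_cohort
from .tracks import clean_track, read_pose_table, speed_series

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated configuration of one analysis run."""

    out_dir: str
    seed: int = 0
    # either simulate a cohort ...
    simulate: bool = True
    n_pairs: int = 5
    delta: float = 1.0
    session_min: float = 120.0
    frame_rate_hz: float = 45.0
    # ... or consume files: [(pair_id, poses_csv, events_csv), ...]
    inputs: list[tuple[str, str, str]] = field(default_factory=list)
    layout_path: str | None = None
    # conventions
    anchor: str = "middle back"
    confidence_threshold: float = 0.6
    max_gap_s: float = 0.5
    min_dwell_s: float = 1.0
    proximity_cm: float = 10.0
    late_mode: str = "last20"
    n_perm: int = 10_000
    alpha: float = 0.05
    correlation_method: str = "pearson"

    def validate(self) -> None:
        if not self.simulate and not self.inputs:
            raise ValueError("config error: either simulate=True or inputs must be given")
        if self.simulate and self.n_pairs < 1:
            raise ValueError("config error: n_pairs must be >= 1")
        if self.late_mode not in ("last20", "100-110"):
            raise ValueError("config error: late_mode must be 'last20' or '100-110'")
        if not self.simulate:
            for pid, poses, events in self.inputs:
                for p in (poses, events):
                    if not Path(p).exists():
                        raise ValueError(f"config error: input for {pid!r} missing: {p}")
        if self.layout_path and not Path(self.layout_path).exists():
            raise ValueError(f"config error: layout file missing: {self.layout_path}")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write tidy CSV outputs plus metadata.

    Returns the result bundle: behavior matrix, fitted dominance results,
    permutation results per behavior, correlation analysis, flight-aligned
    kinematics and proximity summary.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout = load_layout(cfg.layout_path) if cfg.layout_path else default_layout(
        frame_rate_hz=cfg.frame_rate_hz
    )
    phases = PhaseWindows(session_s=cfg.session_min * 60.0, late_mode=cfg.late_mode)

    # ------------------------------------------------ inputs
    stage = "input"
    try:
        if cfg.simulate:
            spec = CohortSpec(
                n_pairs=cfg.n_pairs,
                delta=cfg.delta,
                session_min=cfg.session_min,
                frame_rate_hz=cfg.frame_rate_hz,
                seed=cfg.seed,
            )
            sim = simulate_cohort(spec)
            cohort = [
                (p.truth["pair_id"], list(p.tracks), p.events, p.truth) for p in sim
            ]
        else:
            cohort = []
            for pid, poses, evpath in cfg.inputs:
                tracks = list(
                    read_pose_table(poses, frame_rate_hz=cfg.frame_rate_hz).values()
                )
                if len(tracks) != 2:
                    raise ValueError(f"{poses}: expected exactly 2 animals")
                cohort.append((pid, tracks, read_events(evpath), None))

        # -------------------------------------------- trajectory metrics
        stage = "trajectory_metrics"
        late = phases.late
        metrics, prox_rows = {}, []
        clean_pairs = []
        for pid, tracks, events, truth in cohort:
            cleaned = [
                clean_track(t, cfg.confidence_threshold, cfg.max_gap_s)
                for t in tracks
            ]
            clean_pairs.append((pid, cleaned, events, truth))
            for comp_id, tr in enumerate(cleaned, start=1):
                metrics[tr.mouse_id] = compute_trajectory_metrics(
                    tr, layout, comp_id, late, cfg.anchor, cfg.min_dwell_s
                )
            for phase_name, win in (("early", phases.early), ("late", late)):
                prox_rows.append(
                    {
                        "pair_id": pid,
                        "phase": phase_name,
                        "proximity_s": proximity_time(
                            cleaned[0], cleaned[1], layout, cfg.anchor,
                            cfg.proximity_cm, win, cfg.min_dwell_s,
                        ),
                    }
                )
        proximity = pd.DataFrame(prox_rows)

        # -------------------------------------------- behavior matrix
        stage = "behavior_matrix"
        pairs = [
            (tracks[0].mouse_id, tracks[1].mouse_id) for _, tracks, _, _ in clean_pairs
        ]
        all_events = [e for _, _, events, _ in clean_pairs for e in events]
        matrix = build_behavior_matrix(all_events, metrics, pairs, late)

        # -------------------------------------------- dominance
        stage = "dominance"
        results = DominanceModel(matrix).fit()

        # -------------------------------------------- permutation tests
        stage = "permutation"
        perms = {}
        for k, col in enumerate(BEHAVIOR_COLUMNS):
            perms[col] = repairing_permutation_test(
                matrix.set_index("mouse_id")[col],
                pairs,
                behavior=col,
                n_perm=cfg.n_perm,
                seed=cfg.seed + 17 * (k + 1),
            )

        # -------------------------------------------- correlations
        stage = "correlations"
        corr = behavior_correlations(
            matrix[list(BEHAVIOR_COLUMNS)], cfg.correlation_method, cfg.alpha
        )

        # -------------------------------------------- flight kinematics
        stage = "kinematics"
        kin = None
        kcfg = KinematicsConfig()
        kin_frames = []
        for pid, tracks, events, _ in clean_pairs:
            speeds = {t.mouse_id: speed_series(t, cfg.anchor) for t in tracks}
            pa, pb = (t.xy(cfg.anchor) for t in tracks)
            dist = np.hypot(*(pa - pb).T)
            lo, hi = late
            fl = [e for e in events if e.behavior == "flight" and lo <= e.onset_s < hi]
            if fl:
                try:
                    kin = flight_aligned_kinematics(
                        fl, speeds, dist, layout.frame_rate_hz, kcfg
                    )
                    kf = kin.to_frame()
                    kf.insert(0, "pair_id", pid)
                    kin_frames.append(kf)
                except ValueError:
                    pass
        kinematics = pd.concat(kin_frames, ignore_index=True) if kin_frames else None
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    # ------------------------------------------------ outputs
    write_behavior_matrix(matrix, out / "behavior_matrix.csv")
    results.loadings.to_csv(out / "dominance_loadings.csv")
    results.scores.to_csv(out / "dominance_scores.csv", index=False)
    results.ranks.to_csv(out / "dominance_ranks.csv", index=False)
    pd.DataFrame(
        [
            {
                "behavior": p.behavior,
                "observed": p.observed,
                "p_value": p.p_value,
                "n_permutations": p.n_permutations,
                "exhaustive": p.exhaustive,
            }
            for p in perms.values()
        ]
    ).to_csv(out / "permutation_tests.csv", index=False)
    corr["corr"].to_csv(out / "correlations.csv")
    corr["p"].to_csv(out / "correlation_pvalues.csv")
    proximity.to_csv(out / "proximity.csv", index=False)
    if kinematics is not None:
        kinematics.to_csv(out / "flight_kinematics.csv", index=False)
    meta = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "conventions": {
            "anchor": cfg.anchor,
            "min_dwell_s": cfg.min_dwell_s,
            "proximity_cm": cfg.proximity_cm,
            "zscore_ddof": 1,
            "pc_orientation": "attacks loading positive",
            "permutation_rule": "p = #(null >= observed) / n",
            "late_window_s": list(phases.late),
        },
        "variance_explained": results.explained_variance_ratio.tolist(),
    }
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2))
    return {
        "matrix": matrix,
        "results": results,
        "permutations": perms,
        "correlations": corr,
        "proximity": proximity,
        "kinematics": kinematics,
        "truth": {pid: truth for pid, _, _, truth in clean_pairs if truth},
    }
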