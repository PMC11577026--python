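"""Dual-color urine-mark quantification from arena-floor photographs.

Each mouse of a pair is injected with a different systemic dye —
fluorescein (yellow marks) or erythrosin b (fuchsia marks) — so that the
urine deposited by the two animals can be told apart on a single
photograph of the arena floor. Segmentation here is a deterministic
color-space rule classifier: after white-balance normalisation, pixels are
assigned to a dye by hue/saturation windows, speckles below a minimum blob
area are removed by morphological opening, and each dye's marked area is
reported as a percentage of the arena floor. Users with their own trained
pixel classifier can bypass the rule stage by supplying per-pixel
probability rasters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import color as skcolor
from skimage import measure, morphology

from .dominance import behavior_correlations

__all__ = [
    "DyeThresholds",
    "FloorImage",
    "MarkQuant",
    "segment_dyes",
    "percent_marked_area",
    "marking_vs_behavior",
    "PROTOCOL_METADATA",
]

#: dye-injection protocol constants, carried as metadata only
PROTOCOL_METADATA = {
    "fluorescein_dose_mg_per_kg": 39.0,
    "erythrosin_b_dose_mg_per_kg": 54.0,
    "visibility_latency_min": 25.0,
    "visibility_persistence_h": 12.0,
}

LABEL_BACKGROUND, LABEL_FLUORESCEIN, LABEL_ERYTHROSIN = 0, 1, 2


@dataclass(frozen=True)
class DyeThresholds:
    """Hue/saturation windows of the rule classifier (hue in [0, 1])."""

    fluorescein_hue: tuple[float, float] = (0.10, 0.33)  # yellow-green
    erythrosin_hue: tuple[float, float] = (0.83, 0.02)  # pink-red, wraps past 1
    min_saturation: float = 0.25
    min_value: float = 0.15
    min_blob_cm2: float = 0.05

    def hue_centroid(self, dye: str) -> float:
        lo, hi = self.fluorescein_hue if dye == "fluorescein" else self.erythrosin_hue
        if hi < lo:  # wrapped window
            c = (lo + hi + 1.0) / 2.0
            return c - 1.0 if c >= 1.0 else c
        return (lo + hi) / 2.0


@dataclass
class FloorImage:
    """An RGB photograph of one arena floor with its scale and mask."""

    image: np.ndarray  # (H, W, 3), uint8 or float in [0, 1]
    px_per_cm: float
    mask: np.ndarray | None = None  # boolean (H, W); None = whole raster

    def __post_init__(self) -> None:
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("expected an RGB image of shape (H, W, 3)")
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive")
        if self.mask is not None and self.mask.shape != self.image.shape[:2]:
            raise ValueError("mask must match the image raster")

    @property
    def mask_bool(self) -> np.ndarray:
        if self.mask is None:
            return np.ones(self.image.shape[:2], dtype=bool)
        return self.mask.astype(bool)


@dataclass
class MarkQuant:
    """Per-dye marked area and blob statistics for one floor image."""

    pixel_counts: dict[str, int]
    percent_area: dict[str, float]
    blob_counts: dict[str, int]
    blob_areas_cm2: dict[str, list[float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dye": list(self.percent_area),
                "pixels": [self.pixel_counts[d] for d in self.percent_area],
                "percent_area": [self.percent_area[d] for d in self.percent_area],
                "blobs": [self.blob_counts[d] for d in self.percent_area],
            }
        )


def _in_hue_window(h: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if hi < lo:  # wraps through 1.0
        return (h >= lo) | (h <= hi)
    return (h >= lo) & (h <= hi)


def _circular_hue_distance(h: np.ndarray, centroid: float) -> np.ndarray:
    d = np.abs(h - centroid)
    return np.minimum(d, 1.0 - d)


def white_balance(rgb: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Gray-world normalisation over the masked floor region."""
    img = rgb.astype(float)
    if img.max() > 1.0:
        img = img / 255.0
    means = img[mask].reshape(-1, 3).mean(axis=0)
    means = np.where(means <= 0, 1.0, means)
    img = img * (means.mean() / means)
    return np.clip(img, 0.0, 1.0)


def segment_dyes(
    floor: FloorImage, thresholds: DyeThresholds = DyeThresholds()
) -> np.ndarray:
    """Classify each pixel as fluorescein, erythrosin b, or background.

    White-balances the image, applies the hue/saturation windows, assigns
    pixels matching both windows to the nearer hue centroid, then removes
    specks: connected components smaller than ``min_blob_cm2`` are dropped
    per dye. Component-area filtering (rather than erosion) preserves the
    outlines of genuine marks exactly.
    """
    img = np.asarray(floor.image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("segment_dyes requires an RGB image (grayscale not supported)")
    mask = floor.mask_bool
    hsv = skcolor.rgb2hsv(white_balance(img, mask))
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    colored = (s >= thresholds.min_saturation) & (v >= thresholds.min_value) & mask
    fluo = colored & _in_hue_window(h, thresholds.fluorescein_hue)
    eryt = colored & _in_hue_window(h, thresholds.erythrosin_hue)
    both = fluo & eryt
    if both.any():
        df = _circular_hue_distance(h, thresholds.hue_centroid("fluorescein"))
        de = _circular_hue_distance(h, thresholds.hue_centroid("erythrosin"))
        fluo = fluo & (~both | (df <= de))
        eryt = eryt & (~both | (de < df))
    min_px = max(1, int(round(thresholds.min_blob_cm2 * floor.px_per_cm**2)))
    labels = np.zeros(img.shape[:2], dtype=np.uint8)
    for lab, m in ((LABEL_FLUORESCEIN, fluo), (LABEL_ERYTHROSIN, eryt)):
        m = morphology.remove_small_objects(m, max_size=min_px - 1, connectivity=2)
        labels[m] = lab
    return labels


def percent_marked_area(
    labels: np.ndarray, mask: np.ndarray, px_per_cm: float = 1.0
) -> MarkQuant:
    """Marked area per dye as a percentage of the arena floor.

    Blob statistics use 8-connectivity connected components.
    """
    mask = mask.astype(bool)
    if labels.shape != mask.shape:
        raise ValueError("labels and mask must be aligned")
    total = int(mask.sum())
    if total == 0:
        raise ValueError("empty arena mask")
    counts, pct, blobs, areas = {}, {}, {}, {}
    for dye, lab in (("fluorescein", LABEL_FLUORESCEIN), ("erythrosin", LABEL_ERYTHROSIN)):
        m = (labels == lab) & mask
        counts[dye] = int(m.sum())
        pct[dye] = 100.0 * counts[dye] / total
        cc = measure.label(m, connectivity=2)
        props = measure.regionprops(cc)
        blobs[dye] = len(props)
        areas[dye] = [p.area / px_per_cm**2 for p in props]
    return MarkQuant(counts, pct, blobs, areas)


def marking_vs_behavior(
    marks: pd.DataFrame, behavior_matrix: pd.DataFrame, method: str = "pearson", alpha: float = 0.05
) -> dict:
    """Correlate per-mouse marked-area percent with the seven behaviors.

    ``marks`` needs columns ``mouse_id`` and ``percent_area``; rows are
    matched to the behavior matrix by mouse id (mismatches are an error)
    and the marking percentage enters the standard behavior-correlation
    analysis as an eighth variable.
    """
    if not set(marks["mouse_id"]) == set(behavior_matrix["mouse_id"]):
        raise ValueError("mouse ids of marks and behavior matrix do not match")
    merged = behavior_matrix.merge(marks[["mouse_id", "percent_area"]], on="mouse_id")
    cols = [c for c in merged.columns if c not in ("mouse_id", "pair_id", "strain", "phase")]
    return behavior_correlations(merged[cols], method=method, alpha=alpha)
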