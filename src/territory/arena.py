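"""Two-compartment territorial arena: layout geometry and ROI membership.

The apparatus is a 120 x 120 cm open-top box split into two side-by-side
120 x 60 cm compartments by a wall with a 4 cm passage. Each compartment
holds a roofless central home cage (with water dispenser) containing a
10 cm diameter food column, plus four 8 x 8 cm corner refuges. Twelve
regions — 8 corners, 2 cage tops, 2 food-column tops — are designated
"hiding" refuges for dwell-time analysis.

Coordinates are in cm with the origin at the arena's outer top-left corner,
x rightward and y downward (the frame of an overhead camera image).
Compartment 1 occupies y in [0, 60], compartment 2 occupies y in [60, 120].
Polygon boundaries count as inside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
import yaml
from shapely.geometry import Point, Polygon

__all__ = [
    "ROI",
    "ArenaLayout",
    "HIDING_CATEGORIES",
    "PROXIMITY_CATEGORIES",
    "default_layout",
    "point_in_roi",
    "roi_labels",
    "load_layout",
    "save_layout",
]

ROI_CATEGORIES = frozenset(
    {"compartment", "corner", "cage_top", "food_top", "water_top", "passage", "custom"}
)
#: categories whose ROIs count as refuges for hiding-time quantification
HIDING_CATEGORIES = frozenset({"corner", "cage_top", "food_top", "water_top"})
#: categories entering the same-ROI clause of the proximity metric
PROXIMITY_CATEGORIES = frozenset({"compartment", "cage_top", "food_top"})


@dataclass(frozen=True)
class ROI:
    """A named polygonal region of the arena floor.

    Parameters
    ----------
    name : str
        Short identifier, unique within a layout.
    category : str
        One of ``compartment, corner, cage_top, food_top, water_top,
        passage, custom``.
    vertices : sequence of (x, y)
        Ordered polygon vertices in cm; implicitly closed.
    compartment_id : int
        Which compartment (1 or 2) the region belongs to.
    """

    name: str
    category: str
    vertices: tuple[tuple[float, float], ...]
    compartment_id: int

    def __post_init__(self) -> None:
        if self.category not in ROI_CATEGORIES:
            raise ValueError(f"unknown ROI category {self.category!r}")
        if len(self.vertices) < 3:
            raise ValueError(f"ROI {self.name!r}: polygon needs >= 3 vertices")
        if self.compartment_id not in (1, 2):
            raise ValueError(f"ROI {self.name!r}: compartment_id must be 1 or 2")
        poly = Polygon(self.vertices)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError(f"ROI {self.name!r}: degenerate or self-intersecting polygon")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area_cm2(self) -> float:
        return self.polygon.area

    @property
    def is_hiding(self) -> bool:
        return self.category in HIDING_CATEGORIES


@dataclass(frozen=True)
class ArenaLayout:
    """The full apparatus: compartment geometry plus a set of ROIs."""

    compartment_size_cm: tuple[float, float] = (120.0, 60.0)
    wall_height_cm: float = 70.0
    passage_width_cm: float = 4.0
    frame_rate_hz: float = 45.0
    rois: tuple[ROI, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [r.name for r in self.rois]
        if len(names) != len(set(names)):
            raise ValueError("ROI names must be unique")
        w, h = self.bounding_box_cm
        for r in self.rois:
            xs, ys = zip(*r.vertices)
            if min(xs) < -1e-9 or min(ys) < -1e-9 or max(xs) > w + 1e-9 or max(ys) > h + 1e-9:
                raise ValueError(f"ROI {r.name!r} extends outside the arena bounding box")

    @property
    def bounding_box_cm(self) -> tuple[float, float]:
        """(width, height) of the full floor: two compartments stacked on y."""
        w, h = self.compartment_size_cm
        return (w, 2 * h)

    def roi(self, name: str) -> ROI:
        for r in self.rois:
            if r.name == name:
                return r
        raise KeyError(f"no ROI named {name!r}")

    @property
    def hiding_rois(self) -> tuple[ROI, ...]:
        return tuple(r for r in self.rois if r.is_hiding)

    @property
    def proximity_rois(self) -> tuple[ROI, ...]:
        return tuple(r for r in self.rois if r.category in PROXIMITY_CATEGORIES)

    def compartment_roi(self, compartment_id: int) -> ROI:
        for r in self.rois:
            if r.category == "compartment" and r.compartment_id == compartment_id:
                return r
        raise KeyError(f"no compartment ROI for compartment {compartment_id}")


def _rect(x0: float, y0: float, w: float, h: float) -> tuple[tuple[float, float], ...]:
    return ((x0, y0), (x0 + w, y0), (x0 + w, y0 + h), (x0, y0 + h))


def _disc(cx: float, cy: float, r: float, n: int = 32) -> tuple[tuple[float, float], ...]:
    ang = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return tuple((float(cx + r * np.cos(a)), float(cy + r * np.sin(a))) for a in ang)


def default_layout(
    *,
    corner_cm: float = 8.0,
    cage_cm: float = 25.0,
    food_diameter_cm: float = 10.0,
    frame_rate_hz: float = 45.0,
) -> ArenaLayout:
    """Build the canonical apparatus layout.

    Two 120 x 60 cm compartments share their long wall (the divider runs
    horizontally at y = 60 with a 4 cm passage centred at x = 60). Per
    compartment: four 8 x 8 cm corner refuges, a 25 x 25 cm central cage
    footprint (water-dispenser top merged into the cage top) and a 10 cm
    diameter food-column disc at the cage centre. Twelve ROIs are
    hiding-designated in total.

    The cage footprint depth and corner placement are configuration
    defaults, not measured constants; override them via the keyword
    arguments or by editing a saved layout file.
    """
    comp_w, comp_h = 120.0, 60.0
    rois: list[ROI] = []
    for cid, y0 in ((1, 0.0), (2, comp_h)):
        rois.append(
            ROI(f"compartment_{cid}", "compartment", _rect(0.0, y0, comp_w, comp_h), cid)
        )
        cx, cy = comp_w / 2, y0 + comp_h / 2
        for tag, (px, py) in {
            "tl": (0.0, y0),
            "tr": (comp_w - corner_cm, y0),
            "bl": (0.0, y0 + comp_h - corner_cm),
            "br": (comp_w - corner_cm, y0 + comp_h - corner_cm),
        }.items():
            rois.append(
                ROI(f"corner_{cid}_{tag}", "corner", _rect(px, py, corner_cm, corner_cm), cid)
            )
        rois.append(
            ROI(
                f"cage_top_{cid}",
                "cage_top",
                _rect(cx - cage_cm / 2, cy - cage_cm / 2, cage_cm, cage_cm),
                cid,
            )
        )
        rois.append(ROI(f"food_top_{cid}", "food_top", _disc(cx, cy, food_diameter_cm / 2), cid))
    # passage: 4 cm wide opening straddling the divider at y = 60
    rois.append(
        ROI("passage", "passage", _rect(comp_w / 2 - 2.0, comp_h - 2.0, 4.0, 4.0), 1)
    )
    layout = ArenaLayout(
        compartment_size_cm=(comp_w, comp_h),
        wall_height_cm=70.0,
        passage_width_cm=4.0,
        frame_rate_hz=frame_rate_hz,
        rois=tuple(rois),
    )
    assert len(layout.hiding_rois) == 12
    return layout


def point_in_roi(p: Sequence[float], roi: ROI) -> bool:
    """True iff point ``p`` (cm) lies inside or on the boundary of the ROI."""
    x, y = float(p[0]), float(p[1])
    if not (np.isfinite(x) and np.isfinite(y)):
        return False
    return bool(roi.polygon.covers(Point(x, y)))


def roi_labels(
    track,
    layout: ArenaLayout,
    anchor: str = "middle back",
    rois: Iterable[ROI] | None = None,
) -> pd.DataFrame:
    """Per-frame ROI membership of a pose track's anchor body part.

    Returns a boolean DataFrame (frames x ROI names) using the nullable
    boolean dtype; frames whose anchor coordinates are missing are ``pd.NA``
    in every column. Boundary points count as inside.
    """
    if anchor not in track.bodyparts:
        raise KeyError(f"unknown anchor body part {anchor!r}")
    xy = track.xy(anchor)
    return points_in_rois(xy, layout, rois=rois)


def points_in_rois(
    xy: np.ndarray, layout: ArenaLayout, rois: Iterable[ROI] | None = None
) -> pd.DataFrame:
    """Vectorised membership of an (n, 2) coordinate array in each ROI."""
    xy = np.asarray(xy, dtype=float)
    missing = ~np.isfinite(xy).all(axis=1)
    pts = shapely.points(np.where(np.isfinite(xy), xy, 0.0))
    use = tuple(layout.rois if rois is None else rois)
    out = pd.DataFrame(index=pd.RangeIndex(len(xy)))
    for r in use:
        inside = shapely.covers(r.polygon, pts)
        col = pd.array(inside, dtype="boolean")
        col[missing] = pd.NA
        out[r.name] = col
    return out


# ---------------------------------------------------------------------------
# layout file format (YAML)

def layout_to_dict(layout: ArenaLayout) -> dict:
    return {
        "compartment_size_cm": list(layout.compartment_size_cm),
        "wall_height_cm": layout.wall_height_cm,
        "passage_width_cm": layout.passage_width_cm,
        "frame_rate_hz": layout.frame_rate_hz,
        "rois": [
            {
                "name": r.name,
                "category": r.category,
                "compartment_id": r.compartment_id,
                "vertices": [[float(x), float(y)] for x, y in r.vertices],
            }
            for r in layout.rois
        ],
    }


def layout_from_dict(d: dict) -> ArenaLayout:
    try:
        rois = tuple(
            ROI(
                name=r["name"],
                category=r["category"],
                vertices=tuple((float(x), float(y)) for x, y in r["vertices"]),
                compartment_id=int(r["compartment_id"]),
            )
            for r in d["rois"]
        )
        return ArenaLayout(
            compartment_size_cm=tuple(float(v) for v in d["compartment_size_cm"]),
            wall_height_cm=float(d["wall_height_cm"]),
            passage_width_cm=float(d["passage_width_cm"]),
            frame_rate_hz=float(d["frame_rate_hz"]),
            rois=rois,
        )
    except KeyError as e:
        raise ValueError(f"layout file missing required field: {e}") from e


def save_layout(layout: ArenaLayout, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(layout_to_dict(layout), sort_keys=False))


def load_layout(path: str | Path) -> ArenaLayout:
    return layout_from_dict(yaml.safe_load(Path(path).read_text()))
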