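"""AOI and ROI assignment, ROI area fractions, and gaze heat maps.

AOI assignment labels a fixation centroid as ``face``, ``agr`` or ``off`` by
point-in-rectangle against the trial's two image windows (half-open edges, so
labelling is total and unambiguous).  Within the face window, fixations are
assigned to one of four hand-drawn regions of interest — forehead, eyes, nose,
mouth — by point-in-polygon with a fixed precedence order resolving overlaps;
anything else in the window is ``other``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from shapely.geometry import Point, Polygon

from .trace_io import Rect

ROI_NAMES = ("forehead", "eyes", "nose", "mouth")  # also the precedence order
AOI_LABELS = ("face", "agr", "off")


class RoiError(ValueError):
    pass


@dataclass
class RoiMap:
    """Named facial ROI polygons within an image window.

    Polygon vertices are in window coordinates: degrees relative to the window
    centre, so one map can serve an image wherever the window lands on screen.
    """

    image_id: str
    window: Rect  # width/height of the image window (centre ignored for ROIs)
    polygons: dict[str, Polygon] = field(default_factory=dict)

    def __post_init__(self) -> None:
        w, h = self.window.width, self.window.height
        for name, poly in self.polygons.items():
            if name not in ROI_NAMES:
                raise RoiError(f"unknown ROI name {name!r}")
            if not poly.is_valid:
                raise RoiError(f"ROI {name!r} polygon is invalid (self-intersecting?)")
            minx, miny, maxx, maxy = poly.bounds
            if minx < -w / 2 or maxx > w / 2 or miny < -h / 2 or maxy > h / 2:
                raise RoiError(f"ROI {name!r} extends beyond the image window")


def assign_aoi(x: float, y: float, face_window: Rect, agr_window: Rect) -> str:
    """Label a centroid as face / agr / off by half-open point-in-rectangle."""
    if face_window.contains(x, y):
        return "face"
    if agr_window.contains(x, y):
        return "agr"
    return "off"


def assign_roi(x: float, y: float, roi_map: RoiMap, window_centre: tuple[float, float]) -> str:
    """Assign a face-window centroid to an ROI (precedence: forehead, eyes,
    nose, mouth; polygon boundaries inclusive; fallback ``other``).

    ``window_centre`` is the on-screen centre of the face window; the centroid
    is converted to window coordinates before the polygon tests.
    """
    wx = x - window_centre[0]
    wy = y - window_centre[1]
    w, h = roi_map.window.width, roi_map.window.height
    if not (-w / 2 <= wx <= w / 2 and -h / 2 <= wy <= h / 2):
        raise RoiError(f"centroid ({x:.2f},{y:.2f}) lies outside the face window")
    pt = Point(wx, wy)
    for name in ROI_NAMES:
        poly = roi_map.polygons.get(name)
        if poly is not None and poly.covers(pt):  # covers: boundary inclusive
            return name
    return "other"


def roi_area_fractions(roi_map: RoiMap) -> dict[str, float]:
    """Fraction of the window area covered by each named ROI, plus ``other``.

    Overlaps are resolved by the same precedence as point assignment, so the
    five fractions sum to 1 exactly.
    """
    window_area = roi_map.window.area
    fractions: dict[str, float] = {}
    claimed: Polygon | None = None
    for name in ROI_NAMES:
        poly = roi_map.polygons.get(name)
        if poly is None:
            fractions[name] = 0.0
            continue
        effective = poly if claimed is None else poly.difference(claimed)
        fractions[name] = effective.area / window_area
        claimed = poly if claimed is None else claimed.union(poly)
    fractions["other"] = 1.0 - sum(fractions.values())
    return fractions


# ---------------------------------------------------------------------------
# Heat maps


@dataclass
class HeatmapGrid:
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray  # raw integer counts, shape (n_bins, n_bins)
    density: np.ndarray | None = None  # smoothed, sums to 1


def gaze_heatmap(
    x: np.ndarray,
    y: np.ndarray,
    window: Rect,
    n_bins: int = 50,
    smoothing_sigma_bins: float = 1.0,
) -> HeatmapGrid:
    """Bin in-window gaze samples on an n_bins x n_bins grid.

    Raw counts conserve the sample count exactly.  With a positive smoothing
    sigma a Gaussian-smoothed density normalised to sum 1 is attached.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x_edges = np.linspace(window.x0, window.x1, n_bins + 1)
    y_edges = np.linspace(window.y0, window.y1, n_bins + 1)
    counts, _, _ = np.histogram2d(
        np.clip(x, window.x0, np.nextafter(window.x1, -np.inf)),
        np.clip(y, window.y0, np.nextafter(window.y1, -np.inf)),
        bins=[x_edges, y_edges],
    )
    counts = counts.astype(np.int64)
    density = None
    if smoothing_sigma_bins > 0 and counts.sum() > 0:
        density = ndimage.gaussian_filter(counts.astype(float), sigma=smoothing_sigma_bins)
        density /= density.sum()
    return HeatmapGrid(x_edges=x_edges, y_edges=y_edges, counts=counts, density=density)


# ---------------------------------------------------------------------------
# JSON round-trip and a default synthetic map


def save_roi_map(roi_map: RoiMap, path: str | Path) -> None:
    payload = {
        "image_id": roi_map.image_id,
        "window": roi_map.window.to_list(),
        "rois": {
            name: [list(xy) for xy in poly.exterior.coords[:-1]]
            for name, poly in roi_map.polygons.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_roi_map(path: str | Path) -> RoiMap:
    raw = json.loads(Path(path).read_text())
    return RoiMap(
        image_id=raw["image_id"],
        window=Rect(*raw["window"]),
        polygons={name: Polygon(coords) for name, coords in raw["rois"].items()},
    )


def default_roi_map(image_id: str = "synthetic-face", window_deg: float = 8.0) -> RoiMap:
    """A synthetic macaque-face ROI map used by the generator and tests.

    Rectangular stand-ins for the hand-drawn regions, laid out like a frontal
    face: forehead band on top, eye band beneath it, nose column, mouth band.
    Forehead and eyes together cover about 10% of the window area, matching
    the scale of hand-drawn maps on real face photographs.
    """
    w = window_deg
    rect = lambda x0, y0, x1, y1: Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])
    polygons = {
        "forehead": rect(-1.6 * w / 8, 1.8 * w / 8, 1.6 * w / 8, 3.0 * w / 8),
        "eyes": rect(-1.8 * w / 8, 0.7 * w / 8, 1.8 * w / 8, 1.4 * w / 8),
        "nose": rect(-0.7 * w / 8, -0.8 * w / 8, 0.7 * w / 8, 0.5 * w / 8),
        "mouth": rect(-1.2 * w / 8, -2.2 * w / 8, 1.2 * w / 8, -1.2 * w / 8),
    }
    return RoiMap(image_id=image_id, window=Rect(0.0, 0.0, w, w), polygons=polygons)
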