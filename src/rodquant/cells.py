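"""Rod-cell detection and morphometry from fluorescence micrographs.

The measurement algorithm has three stages: (i) automatic tuning of the blur
sigma and threshold over a small grid, choosing the combination that maximizes
the ratio of shape-accepted cells to area-accepted candidates; (ii) detection
of connected components filtered by area, elongation (length/width of the
minimum-area rotated bounding rectangle) and shape complexity (convex hull
area / region area); (iii) morphometry, where the rotated minimum-area
bounding rectangle of each accepted component defines the cell's length,
width and orientation.

Pixel-extent convention: each pixel is treated as a unit square, so the
rectangle is fitted to the four corners of every pixel and a noiseless
axis-aligned bar 50 pixels long measures exactly 50.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import ConvexHull, QhullError
from skimage.filters import threshold_isodata
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.segmentation import clear_border, relabel_sequential

__all__ = [
    "DetectionLimits",
    "TuningResult",
    "CellMeasurement",
    "RotatedRect",
    "NoCellsFoundError",
    "candidate_components",
    "shape_complexity",
    "min_area_rect",
    "auto_tune",
    "measure_cells",
    "measurements_to_dataframe",
]

DEFAULT_BLUR_SIGMAS: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0)
DEFAULT_THRESHOLD_OFFSETS: tuple[float, ...] = (-0.10, -0.05, 0.0, 0.05, 0.10)
NOISE_FLOOR_PX = 5  # components below this area are specks, never candidates

_CORNER_OFFSETS = np.array(
    [[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]], dtype=float
)


class NoCellsFoundError(RuntimeError):
    """No tuning grid point produced any candidate component."""


@dataclass(frozen=True)
class DetectionLimits:
    """Acceptance window for detected components.

    Elongation is the length/width ratio of the minimum-area rotated
    rectangle; complexity is convex-hull area over region area (1 for convex
    shapes, larger for concave or clumped objects).
    """

    min_area: float
    max_area: float
    min_elongation: float = 1.0
    max_elongation: float = math.inf
    max_complexity: float = math.inf

    def __post_init__(self) -> None:
        if not (0 < self.min_area < self.max_area):
            raise ValueError("require 0 < min_area < max_area")
        if not (1.0 <= self.min_elongation <= self.max_elongation):
            raise ValueError("require 1 <= min_elongation <= max_elongation")
        if self.max_complexity < 1.0:
            raise ValueError("max_complexity must be >= 1")


@dataclass(frozen=True)
class TuningResult:
    blur_sigma: float
    threshold: float
    detected: int
    candidates: int

    @property
    def ratio(self) -> float:
        return self.detected / self.candidates if self.candidates > 0 else 0.0


class RotatedRect(NamedTuple):
    """Minimum-area rotated bounding rectangle: length >= width, angle of the
    length axis in degrees from the x axis (y down), in [0, 180)."""

    length: float
    width: float
    angle: float


@dataclass(frozen=True)
class CellMeasurement:
    label: int
    area: int  # px²
    hull_ratio: float
    length_px: float
    width_px: float
    length_um: float
    width_um: float
    angle: float  # degrees in [0, 180)
    centroid: tuple[float, float]  # (x, y) px


def candidate_components(
    image: np.ndarray,
    blur_sigma: float,
    threshold: float,
    noise_floor: int = NOISE_FLOOR_PX,
    exclude_border: bool = True,
) -> np.ndarray:
    """Smooth, binarize and label an intensity image.

    Components are 8-connected; components touching the image border are
    removed (truncated cells would bias length), as are specks below
    ``noise_floor`` px².  An all-background image yields zero components.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D intensity image")
    smooth = gaussian_filter(img, blur_sigma) if blur_sigma > 0 else img
    return _label_mask(smooth > threshold, noise_floor, exclude_border)


def _label_mask(mask: np.ndarray, noise_floor: int, exclude_border: bool) -> np.ndarray:
    labeled = sk_label(mask, connectivity=2)
    if exclude_border:
        labeled = clear_border(labeled)
    if noise_floor > 0 and labeled.max() > 0:
        counts = np.bincount(labeled.ravel())
        small = np.flatnonzero(counts < noise_floor)
        if small.size:
            labeled[np.isin(labeled, small)] = 0
    return relabel_sequential(labeled)[0]


def _pixel_corners(coords: np.ndarray) -> np.ndarray:
    """Expand (row, col) pixel coordinates to the 4 unit-square corners, as (x, y)."""
    pts = (coords[:, None, :] + _CORNER_OFFSETS[None, :, :]).reshape(-1, 2)
    return pts[:, ::-1]  # (x=col, y=row)


def shape_complexity(component: np.ndarray) -> float:
    """Convex-hull area over region area for one component.

    Accepts a boolean mask or an (N, 2) array of (row, col) pixel coordinates.
    Both areas use the unit-square pixel model, so the ratio is exactly 1 for
    filled convex rectangles and >= 1 in general.  Components of fewer than
    3 pixels are defined to have ratio 1.
    """
    comp = np.asarray(component)
    coords = np.argwhere(comp) if comp.dtype == bool or comp.ndim != 2 or comp.shape[1] != 2 else comp
    n = len(coords)
    if n < 3:
        return 1.0
    hull = ConvexHull(_pixel_corners(np.asarray(coords, dtype=float)))
    return float(hull.volume) / n


def min_area_rect(points: Sequence) -> RotatedRect:
    """Minimum-area rotated rectangle enclosing a point set, via rotating calipers.

    An optimal rectangle has a side collinear with a convex-hull edge, so it
    suffices to test one orientation per hull edge.  Area ties are broken by
    the smaller angle.  Degenerate (collinear) inputs give width 0; a single
    point gives (0, 0, 0).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise ValueError("expected a non-empty (N, 2) point array")
    if len(pts) == 1:
        return RotatedRect(0.0, 0.0, 0.0)
    try:
        hull = ConvexHull(pts)
        hp = pts[hull.vertices]
    except QhullError:
        return _collinear_rect(pts)

    edges = np.roll(hp, -1, axis=0) - hp
    thetas = np.arctan2(edges[:, 1], edges[:, 0])
    cos, sin = np.cos(thetas), np.sin(thetas)
    # rotate hull points by -theta for every edge at once: (n_edges, n_pts)
    xs = cos[:, None] * hp[None, :, 0] + sin[:, None] * hp[None, :, 1]
    ys = -sin[:, None] * hp[None, :, 0] + cos[:, None] * hp[None, :, 1]
    w = xs.max(axis=1) - xs.min(axis=1)
    h = ys.max(axis=1) - ys.min(axis=1)
    areas = w * h

    amin = areas.min()
    tol = 1e-9 * (amin + 1.0)
    best: RotatedRect | None = None
    for i in np.flatnonzero(areas <= amin + tol):
        deg = math.degrees(thetas[i])
        if w[i] >= h[i]:
            cand = RotatedRect(float(w[i]), float(h[i]), deg % 180.0)
        else:
            cand = RotatedRect(float(h[i]), float(w[i]), (deg + 90.0) % 180.0)
        if best is None or cand.angle < best.angle:
            best = cand
    assert best is not None
    return best


def _collinear_rect(pts: np.ndarray) -> RotatedRect:
    centered = pts - pts.mean(axis=0)
    norms = np.einsum("ij,ij->i", centered, centered)
    if np.max(norms) == 0.0:
        return RotatedRect(0.0, 0.0, 0.0)
    v = centered[int(np.argmax(norms))]
    v = v / np.linalg.norm(v)
    proj = centered @ v
    length = float(proj.max() - proj.min())
    angle = math.degrees(math.atan2(v[1], v[0])) % 180.0
    return RotatedRect(length, 0.0, angle)


def _region_shape(region) -> tuple[RotatedRect, float]:
    """Rectangle and hull ratio of one labeled region, on pixel corners."""
    corners = _pixel_corners(region.coords.astype(float))
    hull = ConvexHull(corners)
    rect = min_area_rect(corners[hull.vertices])
    return rect, float(hull.volume) / region.area


def _passes_shape(rect: RotatedRect, hull_ratio: float, limits: DetectionLimits) -> bool:
    elong = rect.length / rect.width if rect.width > 0 else math.inf
    return (
        limits.min_elongation <= elong <= limits.max_elongation
        and hull_ratio <= limits.max_complexity
    )


def auto_tune(
    image: np.ndarray,
    limits: DetectionLimits,
    blur_sigmas: Sequence[float] = DEFAULT_BLUR_SIGMAS,
    threshold_offsets: Sequence[float] = DEFAULT_THRESHOLD_OFFSETS,
    noise_floor: int = NOISE_FLOOR_PX,
) -> TuningResult:
    """Search the (blur, threshold) grid for the best detected/candidates ratio.

    For each grid point, *candidates* are the components inside the area
    window and *detected* are those additionally passing the elongation and
    complexity limits.  The base threshold at each blur level is the isodata
    (iterative intermeans) level of the smoothed image; offsets are fractions
    of the robust dynamic range (1st-99th percentile span).  Ties are broken
    by larger detected count, then smaller blur, then the offset closest to
    the unmodified isodata level (large offsets bias the measured extents).

    Raises
    ------
    NoCellsFoundError
        If no grid point yields a single candidate.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if not blur_sigmas or not len(threshold_offsets):
        raise ValueError("empty tuning grid")
    lo, hi = np.percentile(img, [1.0, 99.0])
    span = float(hi - lo)

    results: list[tuple[TuningResult, float]] = []
    for sigma in blur_sigmas:
        smooth = gaussian_filter(img, sigma) if sigma > 0 else img
        if smooth.max() == smooth.min():
            continue
        base = float(threshold_isodata(smooth))
        for off in threshold_offsets:
            thr = base + off * span
            labeled = _label_mask(smooth > thr, noise_floor, exclude_border=True)
            ncand = ndet = 0
            for region in regionprops(labeled):
                if not (limits.min_area <= region.area <= limits.max_area):
                    continue
                ncand += 1
                rect, hull_ratio = _region_shape(region)
                if _passes_shape(rect, hull_ratio, limits):
                    ndet += 1
            results.append((TuningResult(float(sigma), thr, ndet, ncand), abs(off)))

    if not any(r.candidates > 0 for r, _ in results):
        raise NoCellsFoundError("no cells found at any tuning grid point")
    return min(
        results,
        key=lambda item: (
            -item[0].ratio,
            -item[0].detected,
            item[0].blur_sigma,
            item[1],
            item[0].threshold,
        ),
    )[0]


def measure_cells(
    image: np.ndarray,
    limits: DetectionLimits,
    pixel_size: float = 1.0,
    tuning: TuningResult | None = None,
    blur_sigma: float | None = None,
    threshold: float | None = None,
    blur_sigmas: Sequence[float] = DEFAULT_BLUR_SIGMAS,
    threshold_offsets: Sequence[float] = DEFAULT_THRESHOLD_OFFSETS,
) -> list[CellMeasurement]:
    """Measure every component passing all detection limits.

    Detection parameters come from, in order of precedence: explicit
    ``blur_sigma``/``threshold``, a precomputed ``tuning`` result, or a fresh
    :func:`auto_tune` run.  Lengths are reported both in pixels and in µm
    (pixels × ``pixel_size``).  Output is ordered by component label.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    if blur_sigma is None or threshold is None:
        if tuning is None:
            tuning = auto_tune(image, limits, blur_sigmas, threshold_offsets)
        blur_sigma, threshold = tuning.blur_sigma, tuning.threshold

    labeled = candidate_components(image, blur_sigma, threshold)
    out: list[CellMeasurement] = []
    for region in regionprops(labeled):
        if not (limits.min_area <= region.area <= limits.max_area):
            continue
        rect, hull_ratio = _region_shape(region)
        if not _passes_shape(rect, hull_ratio, limits):
            continue
        cy, cx = region.centroid
        out.append(
            CellMeasurement(
                label=int(region.label),
                area=int(region.area),
                hull_ratio=hull_ratio,
                length_px=rect.length,
                width_px=rect.width,
                length_um=rect.length * pixel_size,
                width_um=rect.width * pixel_size,
                angle=rect.angle,
                centroid=(float(cx), float(cy)),
            )
        )
    out.sort(key=lambda m: m.label)
    return out


def measurements_to_dataframe(measurements: Sequence[CellMeasurement]):
    """Tabulate measurements as a pandas DataFrame (one row per cell)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "label": [m.label for m in measurements],
            "area_px2": [m.area for m in measurements],
            "hull_ratio": [m.hull_ratio for m in measurements],
            "length_px": [m.length_px for m in measurements],
            "width_px": [m.width_px for m in measurements],
            "length_um": [m.length_um for m in measurements],
            "width_um": [m.width_um for m in measurements],
            "angle_deg": [m.angle for m in measurements],
            "x": [m.centroid[0] for m in measurements],
            "y": [m.centroid[1] for m in measurements],
        }
    )
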