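"""ROI geometry, rasterization, landmark-square construction and placement.

Coordinate convention (used everywhere in the package): 0-based, ``x`` is the
column index, ``y`` the row index, and rows increase downward.  Pixel
``(row i, col j)`` has its center at the point ``(x=j, y=i)``.  A pixel
belongs to an ROI iff its center satisfies the ROI's inclusion test; centers
exactly on an oval/polygon boundary are included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence, Tuple, Union

import numpy as np
from scipy import ndimage

from .errors import (
    EmptyROIError,
    LandmarkDetectionError,
    PlacementError,
    ValidationError,
)

__all__ = [
    "RectROI",
    "OvalROI",
    "PolygonROI",
    "LandmarkSquare",
    "ROISet",
    "PlacementConfig",
    "DetectConfig",
    "rasterize",
    "mean_counts",
    "place_semiautomatic_rois",
    "detect_landmark_square",
]


@dataclass(frozen=True)
class RectROI:
    """Axis-aligned rectangle: half-open pixel-index ranges.

    Pixel (i, j) is inside iff ``x0 <= j < x0 + w`` and ``y0 <= i < y0 + h``.
    For integral ``x0, y0, w, h`` fully inside the image the mask has exactly
    ``w * h`` pixels.
    """

    x0: float
    y0: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise ValidationError(f"rectangle needs w > 0 and h > 0, got {self.w}x{self.h}")

    @property
    def center(self) -> Tuple[float, float]:
        return (self.x0 + self.w / 2.0, self.y0 + self.h / 2.0)


@dataclass(frozen=True)
class OvalROI:
    """Ellipse with center ``(cx, cy)`` and semi-axes ``(rx, ry)`` in pixels.

    Pixel (i, j) is inside iff ``((j-cx)/rx)**2 + ((i-cy)/ry)**2 <= 1``.
    """

    cx: float
    cy: float
    rx: float
    ry: float

    def __post_init__(self) -> None:
        if not (self.rx > 0 and self.ry > 0):
            raise ValidationError(f"oval needs rx > 0 and ry > 0, got {self.rx}, {self.ry}")

    @property
    def bounding_box(self) -> Tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max) of the continuous ellipse."""
        return (self.cx - self.rx, self.cy - self.ry, self.cx + self.rx, self.cy + self.ry)


def _segments_intersect(p1, p2, p3, p4) -> bool:
    """True if open segments p1-p2 and p3-p4 properly intersect."""

    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        return (v > 1e-12) - (v < -1e-12)

    o1, o2 = orient(p1, p2, p3), orient(p1, p2, p4)
    o3, o4 = orient(p3, p4, p1), orient(p3, p4, p2)
    return o1 != o2 and o3 != o4 and 0 not in (o1, o2, o3, o4)


@dataclass(frozen=True)
class PolygonROI:
    """Simple polygon given by an ordered vertex list of ``(x, y)`` pairs.

    Membership uses the even-odd rule; pixel centers on an edge are included.
    """

    vertices: Tuple[Tuple[float, float], ...]

    def __init__(self, vertices: Sequence[Sequence[float]]):
        verts = tuple((float(x), float(y)) for x, y in vertices)
        if len(verts) < 3:
            raise ValidationError(f"polygon needs >= 3 vertices, got {len(verts)}")
        if not _is_simple(verts):
            raise ValidationError("polygon is self-intersecting")
        object.__setattr__(self, "vertices", verts)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


def _is_simple(verts: Tuple[Tuple[float, float], ...]) -> bool:
    n = len(verts)
    edges = [(verts[i], verts[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if j == i + 1 or (i == 0 and j == n - 1):
                continue  # adjacent edges share a vertex
            if _segments_intersect(*edges[i], *edges[j]):
                return False
    return True


ROI = Union[RectROI, OvalROI, PolygonROI]


@dataclass(frozen=True)
class LandmarkSquare:
    """Bounding square from anatomical landmarks.

    ``top`` = lung-apex row, ``bottom`` = upper-cardiac-border row,
    ``left``/``right`` = medial lung-contour columns.
    """

    top: float
    bottom: float
    left: float
    right: float

    def __post_init__(self) -> None:
        if not (self.top < self.bottom):
            raise ValidationError(f"square needs top < bottom, got {self.top} >= {self.bottom}")
        if not (self.left < self.right):
            raise ValidationError(f"square needs left < right, got {self.left} >= {self.right}")

    @property
    def width(self) -> float:
        return self.right - self.left

    @property
    def height(self) -> float:
        return self.bottom - self.top

    def shifted(self, dx: float, dy: float) -> "LandmarkSquare":
        return LandmarkSquare(self.top + dy, self.bottom + dy, self.left + dx, self.right + dx)


@dataclass(frozen=True)
class ROISet:
    """Cardiac + mediastinal ROI pair attributed to a rater and a method."""

    cardiac: ROI
    mediastinal: ROI
    method: str = "semiautomatic"
    rater: str = ""

    def __post_init__(self) -> None:
        if self.method not in ("manual", "semiautomatic"):
            raise ValidationError(f"unknown method {self.method!r}")


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def rasterize(roi: ROI, image_shape: Tuple[int, int]) -> np.ndarray:
    """Boolean pixel mask of ``image_shape`` for *roi*.

    Pixels outside the image are dropped; an all-empty mask after clipping
    raises :class:`EmptyROIError`.
    """
    nrows, ncols = int(image_shape[0]), int(image_shape[1])
    if nrows <= 0 or ncols <= 0:
        raise ValidationError(f"invalid image shape {image_shape}")
    mask = np.zeros((nrows, ncols), dtype=bool)

    if isinstance(roi, RectROI):
        j0 = max(0, int(math.ceil(roi.x0)))
        j1 = min(ncols, int(math.ceil(roi.x0 + roi.w)))
        i0 = max(0, int(math.ceil(roi.y0)))
        i1 = min(nrows, int(math.ceil(roi.y0 + roi.h)))
        if j1 > j0 and i1 > i0:
            mask[i0:i1, j0:j1] = True
    elif isinstance(roi, OvalROI):
        i0 = max(0, int(math.floor(roi.cy - roi.ry)))
        i1 = min(nrows, int(math.ceil(roi.cy + roi.ry)) + 1)
        j0 = max(0, int(math.floor(roi.cx - roi.rx)))
        j1 = min(ncols, int(math.ceil(roi.cx + roi.rx)) + 1)
        if i1 > i0 and j1 > j0:
            ii, jj = np.mgrid[i0:i1, j0:j1]
            inside = ((jj - roi.cx) / roi.rx) ** 2 + ((ii - roi.cy) / roi.ry) ** 2 <= 1.0
            mask[i0:i1, j0:j1] = inside
    elif isinstance(roi, PolygonROI):
        mask = _polygon_mask(roi.vertices, (nrows, ncols))
    else:  # pragma: no cover - defensive
        raise TypeError(f"unknown ROI type {type(roi).__name__}")

    if not mask.any():
        raise EmptyROIError(f"{type(roi).__name__} rasterizes to an empty mask on {image_shape}")
    return mask


def _polygon_mask(verts: Tuple[Tuple[float, float], ...], shape: Tuple[int, int]) -> np.ndarray:
    nrows, ncols = shape
    xs = np.array([v[0] for v in verts])
    ys = np.array([v[1] for v in verts])
    i0 = max(0, int(math.floor(ys.min())))
    i1 = min(nrows, int(math.ceil(ys.max())) + 1)
    j0 = max(0, int(math.floor(xs.min())))
    j1 = min(ncols, int(math.ceil(xs.max())) + 1)
    mask = np.zeros((nrows, ncols), dtype=bool)
    if i1 <= i0 or j1 <= j0:
        return mask
    ii, jj = np.mgrid[i0:i1, j0:j1]
    px = jj.astype(float).ravel()
    py = ii.astype(float).ravel()
    inside = np.zeros(px.size, dtype=bool)
    on_edge = np.zeros(px.size, dtype=bool)
    n = len(verts)
    for k in range(n):
        x1, y1 = verts[k]
        x2, y2 = verts[(k + 1) % n]
        # even-odd crossing test
        crosses = (y1 > py) != (y2 > py)
        if np.any(crosses):
            with np.errstate(divide="ignore", invalid="ignore"):
                xint = (x2 - x1) * (py - y1) / (y2 - y1) + x1
            inside ^= crosses & (px < xint)
        # boundary inclusion: point within 1e-9 of the closed segment
        dx, dy = x2 - x1, y2 - y1
        seg2 = dx * dx + dy * dy
        if seg2 == 0:
            d2 = (px - x1) ** 2 + (py - y1) ** 2
            on_edge |= d2 <= 1e-18
        else:
            t = np.clip(((px - x1) * dx + (py - y1) * dy) / seg2, 0.0, 1.0)
            d2 = (px - (x1 + t * dx)) ** 2 + (py - (y1 + t * dy)) ** 2
            on_edge |= d2 <= 1e-18
    mask[i0:i1, j0:j1] = (inside | on_edge).reshape(ii.shape)
    return mask


def mean_counts(image, roi: ROI) -> float:
    """Arithmetic mean of image counts over the rasterized ROI."""
    counts = np.asarray(getattr(image, "counts", image), dtype=float)
    mask = rasterize(roi, counts.shape)
    return float(counts[mask].mean())


# ---------------------------------------------------------------------------
# Semi-automatic placement from the landmark square
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlacementConfig:
    """Fixed ROI sizes and options for the landmark-square placement.

    ``mediastinal_size`` is (width, height); ``cardiac_axes`` is the full
    (width, height) of the oval bounding box, so semi-axes are half of it.
    ``flip_horizontal`` mirrors the cardiac quadrant for the opposite display
    convention (heart on viewer's left).
    """

    mediastinal_size: Tuple[float, float] = (13.0, 20.0)
    cardiac_axes: Tuple[float, float] = (60.0, 70.0)
    flip_horizontal: bool = False
    refine: bool = False
    max_shift: float = 3.0


def place_semiautomatic_rois(
    square: LandmarkSquare,
    config: PlacementConfig | None = None,
    image=None,
) -> Tuple[RectROI, OvalROI]:
    """Place the fixed-size mediastinal rectangle and cardiac oval.

    The rectangle is centered at the midpoint of the upper half of the
    square; the oval at the centroid of the lower-right quadrant (lower-left
    when ``flip_horizontal``).  The oval may extend beyond the square.  With
    ``config.refine`` and an image, the oval is shifted by up to
    ``max_shift`` pixels to maximize mean cardiac counts.
    """
    cfg = config or PlacementConfig()
    mw, mh = cfg.mediastinal_size
    if square.width < mw or square.height < mh:
        raise PlacementError(
            f"landmark square {square.width:g}x{square.height:g} smaller than "
            f"mediastinal ROI {mw:g}x{mh:g}"
        )
    med_cx = (square.left + square.right) / 2.0
    med_cy = square.top + square.height / 4.0
    med = RectROI(x0=med_cx - mw / 2.0, y0=med_cy - mh / 2.0, w=mw, h=mh)

    fx = 0.25 if cfg.flip_horizontal else 0.75
    card_cx = square.left + fx * square.width
    card_cy = square.top + 0.75 * square.height
    ow, oh = cfg.cardiac_axes
    oval = OvalROI(cx=card_cx, cy=card_cy, rx=ow / 2.0, ry=oh / 2.0)

    if cfg.refine and image is not None:
        counts = np.asarray(getattr(image, "counts", image), dtype=float)
        best, best_mean = oval, -np.inf
        shifts = range(-int(cfg.max_shift), int(cfg.max_shift) + 1)
        for dy in shifts:
            for dx in shifts:
                cand = replace(oval, cx=oval.cx + dx, cy=oval.cy + dy)
                try:
                    m = mean_counts(counts, cand)
                except EmptyROIError:
                    continue
                if m > best_mean:
                    best, best_mean = cand, m
        oval = best
    return med, oval


# ---------------------------------------------------------------------------
# Landmark-square detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectConfig:
    smooth_sigma: float = 1.0
    lung_fraction: float = 0.9  # lung threshold as fraction of the image median
    heart_fraction: float = 0.6  # cardiac threshold as fraction of the image max
    min_component_px: int = 50


def detect_landmark_square(image, config: DetectConfig | None = None) -> LandmarkSquare:
    """Detect the landmark square from lung fields and the cardiac blob.

    Deterministic: smooth, threshold below ``lung_fraction x median`` for the
    two lateral lung fields (top border and medial borders), threshold above
    ``heart_fraction x max`` for the cardiac blob (bottom border).
    """
    cfg = config or DetectConfig()
    counts = np.asarray(getattr(image, "counts", image), dtype=float)
    sm = ndimage.gaussian_filter(counts, sigma=cfg.smooth_sigma)

    lung_mask = sm < cfg.lung_fraction * np.median(sm)
    labels, nlab = ndimage.label(lung_mask)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, nlab + 1))
    big = [lab + 1 for lab, s in enumerate(sizes) if s >= cfg.min_component_px]
    big.sort(key=lambda lab: -sizes[lab - 1])
    if len(big) < 2:
        raise LandmarkDetectionError(
            f"found {len(big)} candidate lung fields, need 2 (image may lack structure)"
        )
    lungs = big[:2]
    cent = ndimage.center_of_mass(lung_mask, labels, lungs)
    if cent[0][1] <= cent[1][1]:
        left_lab, right_lab = lungs[0], lungs[1]
    else:
        left_lab, right_lab = lungs[1], lungs[0]

    heart_mask = sm > cfg.heart_fraction * sm.max()
    hlabels, hnlab = ndimage.label(heart_mask)
    if hnlab < 1:
        raise LandmarkDetectionError("no cardiac blob above threshold")
    hsizes = ndimage.sum_labels(np.ones_like(hlabels), hlabels, index=range(1, hnlab + 1))
    heart_lab = int(np.argmax(hsizes)) + 1
    heart_rows = np.nonzero(hlabels == heart_lab)[0]

    lung_rows_l = np.nonzero(labels == left_lab)[0]
    lung_rows_r = np.nonzero(labels == right_lab)[0]
    top = int(min(lung_rows_l.min(), lung_rows_r.min()))
    bottom = int(heart_rows.min())
    if bottom <= top:
        raise LandmarkDetectionError("upper cardiac border not below lung apexes")

    # medial borders over the upper thorax rows (between apexes and the heart)
    rows = slice(top, bottom + 1)
    sub = labels[rows, :]
    left_cols = np.nonzero((sub == left_lab).any(axis=0))[0]
    right_cols = np.nonzero((sub == right_lab).any(axis=0))[0]
    if left_cols.size == 0 or right_cols.size == 0:
        raise LandmarkDetectionError("lung fields absent from the upper thorax rows")
    left = int(left_cols.max()) + 1  # first non-lung column medial to the left lung
    right = int(right_cols.min())    # first lung column of the right lung
    if left >= right:
        raise LandmarkDetectionError("medial lung contours overlap")
    return LandmarkSquare(top=top, bottom=bottom, left=left, right=right)
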