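"""Synthetic anterior-view thoracic planar phantoms with known ground truth.

The phantom composites simple organ shapes onto a count-rate map (expected
counts/pixel): two elliptical low-uptake lung fields, a mediastinal band
between them, a half-elliptical liver, and a high-uptake myocardial annulus
around a lower-intensity left-ventricular cavity.  The early image is a
Poisson draw of the map (or the exact expectation with noise off); the late
image applies a per-organ multiplicative washout factor to the expectation
before the draw.  The anterior-view display convention puts the heart on the
viewer's right; ``flip_horizontal`` mirrors it.

Ground truth stores the anatomical landmark square derived analytically from
the organ geometry, anatomical cardiac/mediastinal ROIs, and the
heart-to-mediastinum ratios of the noise-free maps.  Simulated raters
re-place ROIs from the true landmarks with Gaussian jitter whose magnitude
encodes rater experience.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import GeometryError, PlacementError, ValidationError
from .io import PlanarImage, read_planar, write_planar
from .roi import (
    LandmarkSquare,
    OvalROI,
    PlacementConfig,
    PolygonROI,
    RectROI,
    ROISet,
    place_semiautomatic_rois,
    rasterize,
)

__all__ = [
    "PhantomGeometry",
    "PhantomParams",
    "GroundTruth",
    "RaterProfile",
    "CohortRecord",
    "default_profiles",
    "generate_phantom",
    "generate_cohort",
    "simulate_rater_rois",
    "save_cohort",
    "load_cohort",
]

ORGANS = ("background", "lung", "mediastinum", "myocardium", "cavity", "liver")

DEFAULT_WASHOUT: Dict[str, float] = {
    "background": 0.85,
    "lung": 0.80,
    "mediastinum": 0.85,
    "myocardium": 0.75,
    "cavity": 0.75,
    "liver": 0.95,
}


def scaled_placement_config(matrix_size: int, flip: bool = False) -> PlacementConfig:
    """Fixed ROI sizes are defined on a 256 matrix; scale them with it."""
    f = matrix_size / 256.0
    return PlacementConfig(
        mediastinal_size=(13.0 * f, 20.0 * f),
        cardiac_axes=(60.0 * f, 70.0 * f),
        flip_horizontal=flip,
    )


@dataclass(frozen=True)
class PhantomGeometry:
    """Organ geometry in pixel units (x = column, y = row).

    Defaults are stated for a 256-pixel matrix and scale linearly with it.
    """

    lung_left_center: Tuple[float, float] = (78.0, 130.0)
    lung_right_center: Tuple[float, float] = (178.0, 130.0)
    lung_semi: Tuple[float, float] = (38.0, 60.0)
    heart_center: Tuple[float, float] = (135.0, 155.0)
    heart_semi: Tuple[float, float] = (45.0, 45.0)
    wall_thickness: float = 10.0
    liver_center: Tuple[float, float] = (75.0, 196.0)
    liver_semi: Tuple[float, float] = (45.0, 30.0)
    mediastinum_cols: Tuple[float, float] = (100.0, 156.0)
    mediastinum_rows: Tuple[float, float] = (50.0, 206.0)
    manual_rect_size: Tuple[float, float] = (16.0, 24.0)
    contour_vertices: int = 16

    @classmethod
    def scaled(cls, matrix_size: int) -> "PhantomGeometry":
        f = matrix_size / 256.0
        sc = lambda t: tuple(v * f for v in t)
        return cls(
            lung_left_center=sc(cls.lung_left_center),
            lung_right_center=sc(cls.lung_right_center),
            lung_semi=sc(cls.lung_semi),
            heart_center=sc(cls.heart_center),
            heart_semi=sc(cls.heart_semi),
            wall_thickness=cls.wall_thickness * f,
            liver_center=sc(cls.liver_center),
            liver_semi=sc(cls.liver_semi),
            mediastinum_cols=sc(cls.mediastinum_cols),
            mediastinum_rows=sc(cls.mediastinum_rows),
            manual_rect_size=cls.manual_rect_size,
        )


@dataclass(frozen=True)
class PhantomParams:
    """Full parameterization of one synthetic acquisition."""

    matrix_size: int = 256
    lambda_background: float = 6.0
    lambda_lung: float = 3.0
    lambda_mediastinum: float = 10.0
    lambda_myocardium: float = 25.0
    lambda_cavity: float = 10.0
    lambda_liver: float = 14.0
    acquisition_scale: float = 50.0
    washout: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WASHOUT))
    poisson_noise: bool = True
    mediastinum_gradient: float = 0.0  # relative top-to-bottom slope of the band
    flip_horizontal: bool = False
    geometry: Optional[PhantomGeometry] = None
    # lung/mediastinum contrast is required for landmark detectability; the
    # check can be waived for deliberately structureless test configurations
    validate_detectability: bool = True

    def __post_init__(self) -> None:
        if self.matrix_size < 64:
            raise ValidationError(f"matrix_size must be >= 64, got {self.matrix_size}")
        for name in ORGANS:
            lam = getattr(self, f"lambda_{name}")
            if lam < 0:
                raise ValidationError(f"lambda_{name} must be >= 0, got {lam}")
        if self.validate_detectability and not self.lambda_lung < self.lambda_mediastinum:
            raise ValidationError(
                "lambda_lung must be < lambda_mediastinum for the landmarks to be detectable"
            )
        if self.acquisition_scale <= 0:
            raise ValidationError("acquisition_scale must be > 0")
        for organ, w in self.washout.items():
            if organ not in ORGANS:
                raise ValidationError(f"unknown washout organ {organ!r}")
            if not (0 < w <= 1.5):
                raise ValidationError(f"washout[{organ!r}] must lie in (0, 1.5], got {w}")
        geo = self.geometry or PhantomGeometry.scaled(self.matrix_size)
        object.__setattr__(self, "geometry", geo)
        if geo.wall_thickness <= 0:
            raise GeometryError("myocardial wall thickness must be > 0 (myocardium mask empty)")
        if geo.wall_thickness >= min(geo.heart_semi):
            raise GeometryError(
                "wall thickness >= heart semi-axis leaves no left-ventricular cavity"
            )
        s = self.matrix_size
        for cx, cy, rx, ry in (
            (*geo.lung_left_center, *geo.lung_semi),
            (*geo.lung_right_center, *geo.lung_semi),
            (*geo.heart_center, *geo.heart_semi),
            (*geo.liver_center, *geo.liver_semi),
        ):
            if cx - rx < 0 or cx + rx > s or cy - ry < 0 or cy + ry > s:
                raise ValidationError("organ geometry extends outside the image bounds")


@dataclass(frozen=True)
class GroundTruth:
    """Generator-side truth: landmarks, anatomical ROIs, noise-free ratios."""

    square: LandmarkSquare
    cardiac_roi: OvalROI          # whole-heart ellipse (myocardium + cavity)
    mediastinal_roi: RectROI      # fixed-size rectangle at the true placement
    manual_contour: PolygonROI    # true myocardial contour for the manual method
    manual_rect: RectROI
    true_early_hm: float
    true_late_hm: float
    matrix_size: int

    def __post_init__(self) -> None:
        if not (self.true_early_hm > 0 and self.true_late_hm > 0):
            raise ValidationError("true H/M ratios must be > 0")
        shape = (self.matrix_size, self.matrix_size)
        card = rasterize(self.cardiac_roi, shape)
        med = rasterize(self.mediastinal_roi, shape)
        if (card & med).any():
            raise ValidationError("true cardiac and mediastinal masks overlap")

    def cardiac_mask(self) -> np.ndarray:
        return rasterize(self.cardiac_roi, (self.matrix_size, self.matrix_size))

    def mediastinal_mask(self) -> np.ndarray:
        return rasterize(self.mediastinal_roi, (self.matrix_size, self.matrix_size))


@dataclass(frozen=True)
class RaterProfile:
    """Operator-variability model for one rater.

    Gaussian jitter SDs model within-rater imprecision per placement action.
    ``bias_contour_scale`` models the rater's systematic freehand drawing
    style for the manual method: their cardiac polygon is radially scaled
    about its centroid by this constant factor on every subject (1.0 =
    unbiased).  Fixed-size ROIs have no such systematic component — that is
    precisely what anchoring them to landmarks removes.
    """

    label: str
    sigma_landmark: float  # px, semi-automatic landmark-square coordinates
    sigma_vertex: float    # px, manual polygon vertices
    sigma_rect: float      # px, manual mediastinal rectangle position
    sigma_rect_frac: float = 0.0  # relative manual rectangle size jitter
    bias_contour_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_landmark", "sigma_vertex", "sigma_rect", "sigma_rect_frac"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.bias_contour_scale <= 0:
            raise ValidationError("bias_contour_scale must be > 0")


def default_profiles() -> List[RaterProfile]:
    """Shipped expert <= moderate <= inexpert variability profiles."""
    return [
        RaterProfile("expert", sigma_landmark=0.5, sigma_vertex=1.0, sigma_rect=1.0,
                     sigma_rect_frac=0.03, bias_contour_scale=1.0, seed=11),
        RaterProfile("moderate", sigma_landmark=1.0, sigma_vertex=2.0, sigma_rect=2.0,
                     sigma_rect_frac=0.06, bias_contour_scale=0.90, seed=22),
        RaterProfile("inexpert", sigma_landmark=2.0, sigma_vertex=4.0, sigma_rect=3.0,
                     sigma_rect_frac=0.12, bias_contour_scale=0.78, seed=33),
    ]


@dataclass(frozen=True)
class CohortRecord:
    subject_id: str
    early: PlanarImage
    late: PlanarImage
    ground_truth: GroundTruth

    def __post_init__(self) -> None:
        if self.early.shape != self.late.shape:
            raise ValidationError("early and late images must share matrix size")


# ---------------------------------------------------------------------------
# Expectation-map model
# ---------------------------------------------------------------------------

class _PhantomModel:
    """Precomputed organ masks and expectation maps for one geometry.

    The heart contribution is kept separate so that the myocardium/cavity
    rates can be rescaled per subject without repainting.
    """

    def __init__(self, params: PhantomParams):
        self.params = params
        s = params.matrix_size
        geo = params.geometry
        shape = (s, s)

        def ellipse(center, semi):
            return rasterize(OvalROI(center[0], center[1], semi[0], semi[1]), shape)

        lungs = ellipse(geo.lung_left_center, geo.lung_semi) | ellipse(
            geo.lung_right_center, geo.lung_semi
        )
        c0, c1 = geo.mediastinum_cols
        r0, r1 = geo.mediastinum_rows
        ii, jj = np.mgrid[0:s, 0:s]
        strip = (jj >= c0) & (jj < c1) & (ii >= r0) & (ii < r1)
        liver_full = ellipse(geo.liver_center, geo.liver_semi)
        liver = liver_full & (ii >= geo.liver_center[1])
        heart = ellipse(geo.heart_center, geo.heart_semi)
        cavity = ellipse(
            geo.heart_center,
            (geo.heart_semi[0] - geo.wall_thickness, geo.heart_semi[1] - geo.wall_thickness),
        )
        myocardium = heart & ~cavity
        if not myocardium.any():
            raise GeometryError("organ definitions leave an empty myocardium mask")

        # paint order: later organs overwrite earlier ones (projection stand-in)
        p = params
        base = np.full(shape, float(p.lambda_background))
        wash = np.full(shape, p.washout.get("background", 1.0))
        med_profile = np.full(shape, float(p.lambda_mediastinum))
        if p.mediastinum_gradient:
            rel = np.clip((ii - r0) / max(r1 - r0, 1.0), 0.0, 1.0)
            med_profile = p.lambda_mediastinum * (1.0 + p.mediastinum_gradient * (1.0 - 2.0 * rel))
        base[strip] = med_profile[strip]
        wash[strip] = p.washout.get("mediastinum", 1.0)
        base[lungs] = p.lambda_lung
        wash[lungs] = p.washout.get("lung", 1.0)
        base[liver] = p.lambda_liver
        wash[liver] = p.washout.get("liver", 1.0)

        heart_base = np.zeros(shape)
        heart_base[myocardium] = p.lambda_myocardium
        heart_base[cavity] = p.lambda_cavity
        base[heart] = 0.0
        wash[myocardium] = p.washout.get("myocardium", 1.0)
        wash[cavity] = p.washout.get("cavity", 1.0)

        if p.flip_horizontal:
            base, wash, heart_base = (np.fliplr(a) for a in (base, wash, heart_base))
            heart = np.fliplr(heart)

        self.nonheart = base
        self.heart_base = heart_base
        self.washout_map = wash
        self.heart_mask = heart
        self.square = self._true_square()
        self.truth_rois = self._truth_rois()

    # -- geometry-derived truth ------------------------------------------------

    def _mirror_x(self, x: float) -> float:
        return (self.params.matrix_size - 1) - x

    def _true_square(self) -> LandmarkSquare:
        geo = self.params.geometry
        top = geo.lung_left_center[1] - geo.lung_semi[1]
        bottom = geo.heart_center[1] - geo.heart_semi[1]
        dy = (bottom - geo.lung_left_center[1]) / geo.lung_semi[1]
        half = geo.lung_semi[0] * math.sqrt(max(0.0, 1.0 - dy * dy))
        left = geo.lung_left_center[0] + half
        right = geo.lung_right_center[0] - half
        if self.params.flip_horizontal:
            left, right = self._mirror_x(right), self._mirror_x(left)
        return LandmarkSquare(top=top, bottom=bottom, left=left, right=right)

    def _truth_rois(self):
        p = self.params
        geo = p.geometry
        hx, hy = geo.heart_center
        if p.flip_horizontal:
            hx = self._mirror_x(hx)
        cardiac = OvalROI(hx, hy, geo.heart_semi[0], geo.heart_semi[1])

        cfg = scaled_placement_config(p.matrix_size, flip=p.flip_horizontal)
        med_rect, _ = place_semiautomatic_rois(self.square, cfg)

        n = geo.contour_vertices
        angles = 2 * math.pi * np.arange(n) / n
        verts = [
            (hx + geo.heart_semi[0] * math.cos(a), hy + geo.heart_semi[1] * math.sin(a))
            for a in angles
        ]
        contour = PolygonROI(verts)

        mw, mh = geo.manual_rect_size
        mcx, mcy = med_rect.center
        manual_rect = RectROI(mcx - mw / 2.0, mcy - mh / 2.0, mw, mh)
        return cardiac, med_rect, contour, manual_rect

    # -- maps ------------------------------------------------------------------

    def expected_maps(self, heart_scale: float = 1.0) -> Tuple[np.ndarray, np.ndarray]:
        """(early, late) noise-free expected-count maps."""
        p = self.params
        early = (self.nonheart + heart_scale * self.heart_base) * p.acquisition_scale
        late = early * self.washout_map
        return early, late

    def ground_truth(self, heart_scale: float = 1.0) -> GroundTruth:
        early, late = self.expected_maps(heart_scale)
        cardiac, med, contour, manual_rect = self.truth_rois
        shape = early.shape
        cmask = rasterize(cardiac, shape)
        mmask = rasterize(med, shape)
        true_early = early[cmask].mean() / early[mmask].mean()
        true_late = late[cmask].mean() / late[mmask].mean()
        return GroundTruth(
            square=self.square,
            cardiac_roi=cardiac,
            mediastinal_roi=med,
            manual_contour=contour,
            manual_rect=manual_rect,
            true_early_hm=float(true_early),
            true_late_hm=float(true_late),
            matrix_size=self.params.matrix_size,
        )

    def heart_scale_for_target(self, target_early_hm: float) -> float:
        """Heart-rate multiplier giving the requested true early H/M ratio.

        The true cardiac mask contains only heart-painted pixels, so the
        cardiac mean is exactly proportional to the multiplier.
        """
        if target_early_hm <= 0:
            raise ValidationError(f"target H/M must be > 0, got {target_early_hm}")
        early, _ = self.expected_maps(1.0)
        cardiac, med, _, _ = self.truth_rois
        cmask = rasterize(cardiac, early.shape)
        mmask = rasterize(med, early.shape)
        num_base = early[cmask].mean()
        den = early[mmask].mean()
        if num_base <= 0:
            raise GeometryError("cardiac rates are zero; cannot reach a positive target")
        return target_early_hm * den / num_base


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _draw(expected: np.ndarray, poisson: bool, rng: np.random.Generator) -> np.ndarray:
    if poisson:
        return rng.poisson(expected).astype(float)
    return expected.copy()


def generate_phantom(
    params: Optional[PhantomParams] = None,
    seed: Union[int, np.random.SeedSequence, None] = 0,
    subject_id: str = "phantom",
    _model: Optional[_PhantomModel] = None,
    _heart_scale: float = 1.0,
) -> Tuple[PlanarImage, PlanarImage, GroundTruth]:
    """Generate one early/late image pair plus its ground truth.

    Deterministic in ``(params, seed)``; with ``poisson_noise`` off the
    images equal the expected-count maps exactly.
    """
    params = params or PhantomParams()
    model = _model or _PhantomModel(params)
    rng = np.random.default_rng(seed)
    early_exp, late_exp = model.expected_maps(_heart_scale)
    early = PlanarImage(_draw(early_exp, params.poisson_noise, rng), "early", subject_id)
    late = PlanarImage(_draw(late_exp, params.poisson_noise, rng), "late", subject_id)
    return early, late, model.ground_truth(_heart_scale)


HMSpec = Union[None, Tuple, Sequence[float]]

DEFAULT_HM_RANGE = (1.2, 5.0)


def _resolve_targets(hm_spec: HMSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if hm_spec is None:
        hm_spec = ("uniform",) + DEFAULT_HM_RANGE
    if isinstance(hm_spec, tuple) and hm_spec and isinstance(hm_spec[0], str):
        kind = hm_spec[0]
        if kind == "uniform":
            lo, hi = float(hm_spec[1]), float(hm_spec[2])
            if not (0 < lo <= hi):
                raise ValidationError(f"invalid uniform H/M range ({lo}, {hi})")
            return rng.uniform(lo, hi, size=n)
        if kind == "point":
            v = float(hm_spec[1])
            if v <= 0:
                raise ValidationError(f"point-mass H/M must be > 0, got {v}")
            return np.full(n, v)
        raise ValidationError(f"unknown hm_spec kind {kind!r}")
    targets = np.asarray(hm_spec, dtype=float)
    if targets.shape != (n,):
        raise ValidationError(f"explicit hm_spec must have length {n}")
    if (targets <= 0).any():
        raise ValidationError("hm_spec targets must be > 0")
    return targets


def generate_cohort(
    n: int = 35,
    hm_spec: HMSpec = None,
    params: Optional[PhantomParams] = None,
    seed: Union[int, np.random.SeedSequence] = 0,
) -> List[CohortRecord]:
    """Generate *n* phantom subjects with independent noise.

    ``hm_spec`` controls the distribution of true early H/M targets:
    ``None`` (uniform over :data:`DEFAULT_HM_RANGE`), ``("uniform", lo, hi)``,
    ``("point", v)`` or an explicit length-``n`` sequence.  Seeding is
    hierarchical: subject ``i`` uses the spawn key ``(i,)`` of the master
    seed, so earlier subjects are unaffected by increasing ``n``.
    """
    if n < 1:
        raise ValidationError(f"cohort size must be >= 1, got {n}")
    params = params or PhantomParams()
    model = _PhantomModel(params)
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    target_rng = np.random.default_rng(master.spawn(1)[0])
    targets = _resolve_targets(hm_spec, n, target_rng)
    records = []
    width = max(2, len(str(n)))
    for i in range(n):
        child = np.random.SeedSequence(entropy=master.entropy, spawn_key=(1000 + i,))
        scale = model.heart_scale_for_target(targets[i])
        sid = f"S{i + 1:0{width}d}"
        early, late, gt = generate_phantom(
            params, seed=child, subject_id=sid, _model=model, _heart_scale=scale
        )
        records.append(CohortRecord(sid, early, late, gt))
    return records


# ---------------------------------------------------------------------------
# Simulated raters
# ---------------------------------------------------------------------------

def simulate_rater_rois(
    record: CohortRecord,
    profile: RaterProfile,
    method: str,
    seed: Union[int, np.random.SeedSequence, None] = None,
) -> ROISet:
    """Simulate one rater's ROI placement on one subject.

    Semi-automatic: each landmark-square coordinate gets N(0, sigma_landmark)
    jitter, then the fixed-size ROIs are placed from the jittered square.
    Manual: the true myocardial contour gets per-vertex N(0, sigma_vertex)
    jitter (resampled if the polygon self-intersects) and the mediastinal
    rectangle gets position and relative-size jitter.
    """
    if method not in ("manual", "semiautomatic"):
        raise ValidationError(f"unknown method {method!r}")
    rng = np.random.default_rng(profile.seed if seed is None else seed)
    gt = record.ground_truth
    shape = record.early.shape

    if method == "semiautomatic":
        sq = gt.square
        d = rng.normal(0.0, profile.sigma_landmark, size=4) if profile.sigma_landmark else np.zeros(4)
        try:
            jittered = LandmarkSquare(
                top=sq.top + d[0], bottom=sq.bottom + d[1],
                left=sq.left + d[2], right=sq.right + d[3],
            )
            flip = gt.cardiac_roi.cx < (gt.matrix_size / 2)
            med, oval = place_semiautomatic_rois(
                jittered, scaled_placement_config(gt.matrix_size, flip=flip)
            )
        except (ValidationError, PlacementError) as exc:
            raise PlacementError(f"jittered landmark square is unusable: {exc}") from exc
        _check_inside(med, shape)
        _check_inside(oval, shape)
        return ROISet(cardiac=oval, mediastinal=med, method=method, rater=profile.label)

    # manual
    verts = np.array(gt.manual_contour.vertices)
    if profile.bias_contour_scale != 1.0:
        centroid = verts.mean(axis=0)
        verts = centroid + profile.bias_contour_scale * (verts - centroid)
    poly = None
    for _ in range(20):
        jit = verts + rng.normal(0.0, profile.sigma_vertex, size=verts.shape)
        try:
            poly = PolygonROI(jit)
            break
        except ValidationError:
            continue
    if poly is None:
        raise PlacementError("could not draw a simple jittered cardiac polygon")
    r = gt.manual_rect
    dx, dy = rng.normal(0.0, profile.sigma_rect, size=2)
    fw, fh = 1.0 + rng.normal(0.0, profile.sigma_rect_frac, size=2)
    w = max(2.0, r.w * fw)
    h = max(2.0, r.h * fh)
    cx, cy = r.center
    rect = RectROI((cx + dx) - w / 2.0, (cy + dy) - h / 2.0, w, h)
    _check_inside(poly, shape)
    _check_inside(rect, shape)
    return ROISet(cardiac=poly, mediastinal=rect, method=method, rater=profile.label)


def _check_inside(roi, shape) -> None:
    from .errors import EmptyROIError

    try:
        rasterize(roi, shape)
    except EmptyROIError as exc:
        raise PlacementError(f"jittered ROI falls entirely outside the image: {exc}") from exc


# ---------------------------------------------------------------------------
# Cohort persistence (images + JSON ground-truth sidecar per subject)
# ---------------------------------------------------------------------------

def _roi_dict(roi) -> dict:
    from .io import _roi_to_dict

    return _roi_to_dict(roi)


def _roi_undict(d: dict):
    from .io import _roi_from_dict

    return _roi_from_dict(d)


def save_cohort(records: Sequence[CohortRecord], outdir: str, format: str = "text") -> None:
    os.makedirs(outdir, exist_ok=True)
    ext = "txt" if format == "text" else "dcm"
    for rec in records:
        for img in (rec.early, rec.late):
            write_planar(img, os.path.join(outdir, f"{rec.subject_id}_{img.phase}.{ext}"), format)
        gt = rec.ground_truth
        doc = {
            "subject_id": rec.subject_id,
            "matrix_size": gt.matrix_size,
            "square": {
                "top": gt.square.top, "bottom": gt.square.bottom,
                "left": gt.square.left, "right": gt.square.right,
            },
            "cardiac_roi": _roi_dict(gt.cardiac_roi),
            "mediastinal_roi": _roi_dict(gt.mediastinal_roi),
            "manual_contour": _roi_dict(gt.manual_contour),
            "manual_rect": _roi_dict(gt.manual_rect),
            "true_early_hm": gt.true_early_hm,
            "true_late_hm": gt.true_late_hm,
        }
        with open(os.path.join(outdir, f"{rec.subject_id}_truth.json"), "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
            fh.write("\n")


def load_cohort(indir: str, format: str = "text") -> List[CohortRecord]:
    ext = "txt" if format == "text" else "dcm"
    sidecars = sorted(f for f in os.listdir(indir) if f.endswith("_truth.json"))
    records = []
    for name in sidecars:
        with open(os.path.join(indir, name)) as fh:
            doc = json.load(fh)
        sid = doc["subject_id"]
        sq = doc["square"]
        gt = GroundTruth(
            square=LandmarkSquare(sq["top"], sq["bottom"], sq["left"], sq["right"]),
            cardiac_roi=_roi_undict(doc["cardiac_roi"]),
            mediastinal_roi=_roi_undict(doc["mediastinal_roi"]),
            manual_contour=_roi_undict(doc["manual_contour"]),
            manual_rect=_roi_undict(doc["manual_rect"]),
            true_early_hm=doc["true_early_hm"],
            true_late_hm=doc["true_late_hm"],
            matrix_size=doc["matrix_size"],
        )
        early = read_planar(os.path.join(indir, f"{sid}_early.{ext}"), format, phase="early",
                            subject_id=sid)
        late = read_planar(os.path.join(indir, f"{sid}_late.{ext}"), format, phase="late",
                           subject_id=sid)
        records.append(CohortRecord(sid, early, late, gt))
    return records
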