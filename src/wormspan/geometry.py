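"""Worm straightening, unit-worm warping, and longitudinal registration.

A worm image plus its centerline geometry is resampled into a "straightened"
frame whose rows run head to tail along the centerline and whose columns are
perpendicular offsets.  Straightened frames of different animals/ages are
rescaled onto a common "unit worm" grid (the average size and shape for each
age), then brought into finer longitudinal register with a monotone
5-control-point stretch/compress warp fitted by penalized hill climbing, and
mutually aligned across a population with an expectation-maximization loop
(mean image <-> per-image warp).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import map_coordinates

from .types import ImageFrame, WormGeometry, resample_polyline

__all__ = [
    "StraightenedImage", "UnitWormStandard", "LongitudinalWarp",
    "straighten", "warp_to_unit", "apply_longitudinal_warp",
    "longitudinal_align", "em_align_population", "STANDARD_GRID",
]

#: standard unit-worm grid: rows (head->tail arc samples) x cols (offsets)
STANDARD_GRID = (100, 24)


@dataclass
class StraightenedImage:
    """Intensity grid sampled along the centerline.

    Row 0 is the head tip; columns are signed perpendicular offsets.
    ``valid`` flags pixels that fell inside the worm outline and frame.
    """

    data: np.ndarray
    valid: np.ndarray
    channel: str = "brightfield"
    age_days: float = 3.0
    animal_id: Optional[str] = None
    vulva_row_fraction: Optional[float] = None

    @property
    def shape(self):
        return self.data.shape


@dataclass
class UnitWormStandard:
    """Average arc length and width profile per integer age, plus the shared
    grid shape all images are warped onto."""

    arc_length_by_age: Dict[int, float]
    width_profile_by_age: Dict[int, np.ndarray]
    grid_shape: Tuple[int, int] = STANDARD_GRID

    def nearest_age(self, age_days: float) -> int:
        ages = sorted(self.arc_length_by_age)
        return min(ages, key=lambda a: abs(a - age_days))

    @classmethod
    def from_geometries(cls, geoms: Sequence[WormGeometry],
                        ages: Sequence[float],
                        grid_shape: Tuple[int, int] = STANDARD_GRID):
        by_age: Dict[int, list] = {}
        for g, a in zip(geoms, ages):
            by_age.setdefault(int(round(a)), []).append(g)
        arc, width = {}, {}
        n_s = grid_shape[0]
        for a, gs in by_age.items():
            arc[a] = float(np.mean([g.arc_length for g in gs]))
            profs = []
            for g in gs:
                s = np.linspace(0, 1, g.half_widths.size)
                profs.append(np.interp(np.linspace(0, 1, n_s), s,
                                       g.half_widths))
            width[a] = np.mean(profs, axis=0)
        return cls(arc, width, grid_shape)


def straighten(image: ImageFrame, geom: WormGeometry,
               n_cols: Optional[int] = None) -> StraightenedImage:
    """Resample the frame along perpendiculars to the centerline.

    Bilinear interpolation; samples outside the flank outline (|offset| >
    half-width) or outside the frame are flagged invalid.
    """
    pixels = image.pixels
    center = resample_polyline(geom.centerline, spacing=1.0)
    n = center.shape[0]
    if geom.half_widths is not None:
        s_half = np.interp(np.linspace(0, 1, n),
                           np.linspace(0, 1, geom.half_widths.size),
                           geom.half_widths)
    else:
        s_half = np.full(n, 8.0)
    if n_cols is None:
        n_cols = 2 * int(np.ceil(s_half.max())) + 1
    half_span = (n_cols - 1) / 2.0
    offsets = np.linspace(-half_span, half_span, n_cols)

    tangent = np.gradient(center, axis=0)
    tangent /= np.maximum(np.linalg.norm(tangent, axis=1, keepdims=True),
                          1e-12)
    normal = np.column_stack([-tangent[:, 1], tangent[:, 0]])

    rows = center[:, 0][:, None] + normal[:, 0][:, None] * offsets[None, :]
    cols = center[:, 1][:, None] + normal[:, 1][:, None] * offsets[None, :]
    if rows.min() < -1 or cols.min() < -1 or \
            rows.max() > pixels.shape[0] or cols.max() > pixels.shape[1]:
        raise ValueError("geometry extends outside the frame")
    data = map_coordinates(pixels, [rows, cols], order=1, mode="nearest")
    inside_frame = ((rows >= 0) & (rows <= pixels.shape[0] - 1)
                    & (cols >= 0) & (cols <= pixels.shape[1] - 1))
    valid = inside_frame & (np.abs(offsets)[None, :] <= s_half[:, None])

    vulva_frac = None
    if geom.vulva is not None:
        d = np.linalg.norm(center - np.asarray(geom.vulva, float), axis=1)
        vulva_frac = float(np.argmin(d)) / (n - 1)
    return StraightenedImage(data=data, valid=valid, channel=image.channel,
                             age_days=image.age_days,
                             animal_id=image.animal_id,
                             vulva_row_fraction=vulva_frac)


def _resize_bilinear(arr: np.ndarray, shape: Tuple[int, int]) -> np.ndarray:
    r = np.linspace(0, arr.shape[0] - 1, shape[0])
    c = np.linspace(0, arr.shape[1] - 1, shape[1])
    rr, cc = np.meshgrid(r, c, indexing="ij")
    return map_coordinates(arr.astype(float), [rr, cc], order=1,
                           mode="nearest")


def warp_to_unit(straight: StraightenedImage,
                 standard: UnitWormStandard) -> StraightenedImage:
    """Rescale a straightened image onto the standard unit-worm grid."""
    age = int(round(straight.age_days))
    if age not in standard.arc_length_by_age:
        nearest = standard.nearest_age(straight.age_days)
        warnings.warn(f"no unit-worm standard for age {age}; "
                      f"using nearest age {nearest}", stacklevel=2)
    data = _resize_bilinear(straight.data, standard.grid_shape)
    valid = _resize_bilinear(straight.valid.astype(float),
                             standard.grid_shape) > 0.5
    return replace(straight, data=data, valid=valid)


@dataclass
class LongitudinalWarp:
    """Monotone 5-control-point longitudinal stretch/compress.

    ``control_points`` are normalized arc positions (endpoints included and
    fixed); ``displacements`` move each control point along the arc.  The
    warped positions must remain strictly increasing.
    """

    control_points: np.ndarray = field(
        default_factory=lambda: np.linspace(0, 1, 5))
    displacements: np.ndarray = field(default_factory=lambda: np.zeros(5))
    penalty_weight: float = 1.0

    def warped_positions(self) -> np.ndarray:
        return self.control_points + self.displacements

    def is_monotone(self) -> bool:
        return bool(np.all(np.diff(self.warped_positions()) > 0))


def apply_longitudinal_warp(img: StraightenedImage,
                            warp: LongitudinalWarp) -> StraightenedImage:
    """Resample rows so content at control point ``c_i`` moves to
    ``c_i + d_i``; columns are untouched (longitudinal-only warp)."""
    if not warp.is_monotone():
        raise ValueError("warp is not monotone")
    n_rows = img.data.shape[0]
    u = np.linspace(0, 1, n_rows)
    # output position u shows source content at g(u)
    src = np.interp(u, warp.warped_positions(), warp.control_points)
    src_rows = src * (n_rows - 1)
    cols = np.arange(img.data.shape[1])
    rr, cc = np.meshgrid(src_rows, cols, indexing="ij")
    data = map_coordinates(img.data, [rr, cc], order=1, mode="nearest")
    valid = map_coordinates(img.valid.astype(float), [rr, cc], order=1,
                            mode="nearest") > 0.5
    return replace(img, data=data, valid=valid)


def _masked_corr(a: StraightenedImage, b: StraightenedImage) -> float:
    m = a.valid & b.valid
    if m.sum() < 8:
        return 0.0
    x = a.data[m]
    y = b.data[m]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


def longitudinal_align(image: StraightenedImage,
                       reference: StraightenedImage,
                       penalty: float = 1.0,
                       initial_displacements: Optional[np.ndarray] = None,
                       step_init: float = 0.05, step_min: float = 0.005,
                       ) -> Tuple[StraightenedImage, LongitudinalWarp]:
    """Fit the 5-point warp maximizing ``corr(image o warp, reference) -
    penalty * sum(d^2)`` by coordinate-wise hill climbing.

    The step starts at 0.05 of arc length and halves whenever no
    single-coordinate move improves the objective, stopping below 0.005.
    Endpoints stay fixed; when the image carries a vulva anchor and the
    reference one too, their offset initializes the middle control point.
    """
    if image.shape != reference.shape:
        raise ValueError("image and reference grids differ")
    d = np.zeros(5)
    if initial_displacements is not None:
        d = np.asarray(initial_displacements, dtype=float).copy()
    elif image.vulva_row_fraction is not None and \
            reference.vulva_row_fraction is not None:
        d[2] = np.clip(reference.vulva_row_fraction
                       - image.vulva_row_fraction, -0.2, 0.2)
    base_corr = _masked_corr(image, reference)
    if np.isnan(base_corr):
        warnings.warn("constant-intensity image: correlation undefined; "
                      "returning identity warp", stacklevel=2)
        return image, LongitudinalWarp(penalty_weight=penalty)

    def objective(disp):
        w = LongitudinalWarp(displacements=disp, penalty_weight=penalty)
        if not w.is_monotone():
            return -np.inf, None
        warped = apply_longitudinal_warp(image, w)
        c = _masked_corr(warped, reference)
        if np.isnan(c):
            return -np.inf, None
        return c - penalty * float(np.sum(disp ** 2)), warped

    best, best_img = objective(d)
    if best == -np.inf:  # bad initialization; restart from identity
        d = np.zeros(5)
        best, best_img = objective(d)
    step = step_init
    while step >= step_min:
        improved = False
        for i in (1, 2, 3):  # endpoints fixed
            for delta in (+step, -step):
                trial = d.copy()
                trial[i] += delta
                val, img_t = objective(trial)
                if val > best + 1e-12:
                    d, best, best_img = trial, val, img_t
                    improved = True
        if not improved:
            step /= 2.0
    warp = LongitudinalWarp(displacements=d, penalty_weight=penalty)
    return (best_img if best_img is not None else image), warp


def em_align_population(images: Sequence[StraightenedImage],
                        penalty: float = 1.0, max_iter: int = 10,
                        tol: float = 1e-2,
                        ) -> Tuple[List[StraightenedImage], np.ndarray, int]:
    """Mutually align a population: mean image (E step) then per-image warp
    to the mean (M step), until the mean stabilizes.

    Returns (aligned images, mean image, iterations used).  The mean is a
    validity-weighted pixel mean.
    """
    if len(images) < 2:
        raise ValueError("need at least two images")
    shapes = {im.shape for im in images}
    if len(shapes) != 1:
        raise ValueError("images must share a grid")

    def mean_image(ims):
        num = np.zeros(ims[0].shape)
        den = np.zeros(ims[0].shape)
        for im in ims:
            num += np.where(im.valid, im.data, 0.0)
            den += im.valid
        return np.where(den > 0, num / np.maximum(den, 1), 0.0), den > 0

    aligned = list(images)
    prev_mean = None
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        m, mvalid = mean_image(aligned)
        if prev_mean is not None:
            scale = max(np.ptp(m), 1e-12)
            if np.max(np.abs(m - prev_mean)) < tol * scale:
                n_iter -= 1  # mean unchanged; previous iteration converged
                break
        prev_mean = m
        ref = StraightenedImage(data=m, valid=mvalid)
        aligned = [longitudinal_align(im, ref, penalty=penalty)[0]
                   for im in images]
    final_mean, _ = mean_image(aligned)
    return aligned, final_mean, n_iter
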