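"""Phenomenological biomarker measurements.

Covers: calibration of fluorescence frames (dark field, flat field, exposure
normalization); body size from the centerline/width geometry (length, and
volume / surface area by solid of revolution); percentile fluorescence
summaries over the whole body or head region; the four-statistic motion score
(fraction of in-animal pixels changing relative intensity by more than 18%,
and the mean pixel-wise coefficient of variation, each before and after
light stimulation) mapped to days of life remaining by nu-SVR; and
texton-dictionary texture signatures with the same SVR mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.cluster import KMeans
from sklearn.model_selection import KFold, cross_val_predict
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import NuSVR

from .types import ImageFrame, WormGeometry, polyline_arc_length

__all__ = [
    "FluorescenceCalibration", "MotionStatistics", "TextonDictionary",
    "TextureSignature", "SvrScoreModel", "correct_fluorescence",
    "measure_size", "fluorescence_summary", "motion_statistics",
    "fit_days_remaining_svr", "build_texton_dictionary", "texture_signature",
    "extract_patches", "MOTION_SVR_PARAMS", "TEXTURE_SVR_PARAMS",
    "AGE_BINS", "PATCH_SIZE",
]

#: SVR hyperparameters for the motion and texture scores
MOTION_SVR_PARAMS = {"C": 10.0, "nu": 0.8, "gamma": 0.3}
TEXTURE_SVR_PARAMS = {"C": 5.0, "nu": 0.6, "gamma": 0.004}

#: consecutive 2-day age bins, day 3-4 through 15-16
AGE_BINS: Tuple[Tuple[int, int], ...] = tuple(
    (a, a + 1) for a in range(3, 16, 2))
PATCH_SIZE = 17
TEXTONS_PER_BIN = 30
RELATIVE_CHANGE_THRESHOLD = 0.18


@dataclass
class FluorescenceCalibration:
    """Dark-field and flat-field frames plus the acquisition exposure."""

    dark_field: np.ndarray
    flat_field: np.ndarray
    exposure_ms: float = 10.0


def correct_fluorescence(raw: ImageFrame,
                         cal: FluorescenceCalibration) -> ImageFrame:
    """Calibrated frame: ``(raw - dark) / normalized flat / exposure``.

    The flat field is dark-subtracted and normalized to unit mean so the
    correction removes vignetting without changing the overall scale;
    negative values (noise below the dark level) are clipped to zero.
    """
    if raw.pixels.shape != cal.dark_field.shape or \
            raw.pixels.shape != cal.flat_field.shape:
        raise ValueError("calibration frames must match the image shape")
    exposure = raw.exposure_ms if raw.exposure_ms else cal.exposure_ms
    if exposure <= 0:
        raise ValueError("exposure must be positive")
    flat = cal.flat_field - cal.dark_field
    if np.any(flat <= 0):
        raise ValueError("flat field must be strictly positive after dark "
                         "subtraction")
    flat = flat / flat.mean()
    out = (raw.pixels - cal.dark_field) / flat / exposure
    out = np.clip(out, 0.0, None)
    return ImageFrame(pixels=out, channel=raw.channel, exposure_ms=exposure,
                      age_days=raw.age_days, animal_id=raw.animal_id)


def measure_size(geom: WormGeometry) -> Tuple[float, float, float]:
    """(length, volume, surface area) in pixel units.

    Length is the centerline arc length; volume and surface area come from a
    solid of revolution of the half-width profile about the centerline:
    ``V = pi * int w^2 ds`` and ``A = 2 pi * int w ds`` (trapezoid rule).
    """
    length = geom.arc_length
    if geom.half_widths is None:
        raise ValueError("geometry carries no width profile")
    n = geom.centerline.shape[0]
    s = np.linspace(0.0, length, n)
    w = np.interp(np.linspace(0, 1, n),
                  np.linspace(0, 1, geom.half_widths.size), geom.half_widths)
    volume = float(np.pi * np.trapezoid(w ** 2, s))
    area = float(2.0 * np.pi * np.trapezoid(w, s))
    return float(length), volume, area


def _region_mask_from_geometry(shape, geom: WormGeometry,
                               region: str) -> np.ndarray:
    from scipy.spatial import cKDTree

    center = geom.centerline
    n = center.shape[0]
    w = np.interp(np.linspace(0, 1, n),
                  np.linspace(0, 1, geom.half_widths.size), geom.half_widths)
    tree = cKDTree(center)
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    pix = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    dist, idx = tree.query(pix, workers=-1)
    inside = (dist <= w[idx]).reshape(shape)
    if region == "whole":
        return inside
    if region == "head":
        k = max(1, int(round(geom.head_fraction * n)))
        return inside & (idx.reshape(shape) < k)
    raise ValueError(f"unknown region {region!r}")


def fluorescence_summary(image, region: str = "whole",
                         percentile: float = 95.0,
                         geom: Optional[WormGeometry] = None) -> float:
    """Percentile intensity over the in-region pixels (default 95th).

    ``image`` may be a straightened image (region = rows, using validity
    flags) or a raw/calibrated frame together with a worm geometry.
    Percentile interpolation is linear (numpy default), documented and fixed.
    """
    from .geometry import StraightenedImage

    if isinstance(image, StraightenedImage):
        valid = image.valid.copy()
        if region == "head":
            k = max(1, int(round(0.20 * image.data.shape[0])))
            valid[k:, :] = False
        elif region != "whole":
            raise ValueError(f"unknown region {region!r}")
        vals = image.data[valid]
    else:
        pixels = image.pixels if isinstance(image, ImageFrame) else image
        if geom is None:
            raise ValueError("raw-frame summaries need a worm geometry")
        mask = _region_mask_from_geometry(pixels.shape, geom, region)
        vals = pixels[mask]
    if vals.size == 0:
        raise ValueError("empty region")
    return float(np.percentile(vals, percentile))


@dataclass
class MotionStatistics:
    """Four motion statistics over the in-animal region."""

    frac_changed_pre: float
    frac_changed_post: float
    cv_pre: float
    cv_post: float

    def as_array(self) -> np.ndarray:
        return np.array([self.frac_changed_pre, self.frac_changed_post,
                         self.cv_pre, self.cv_post])


def _frame_set_stats(frames: Sequence[np.ndarray], mask: np.ndarray,
                     eps: float = 1e-9) -> Tuple[float, float]:
    if len(frames) < 2:
        raise ValueError("need at least two frames per condition")
    shape = frames[0].shape
    for f in frames:
        if f.shape != shape:
            raise ValueError("mismatched frame shapes")
    stack = np.stack([f[mask] for f in frames])  # (k, n_pixels)
    # fraction changed: average over unordered frame pairs of the fraction of
    # pixels whose relative change |a-b| / max(mean(a,b), eps) exceeds 18%
    k = stack.shape[0]
    fracs = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = stack[i], stack[j]
            rel = np.abs(a - b) / np.maximum(0.5 * (a + b), eps)
            fracs.append(np.mean(rel > RELATIVE_CHANGE_THRESHOLD))
    frac = float(np.mean(fracs))
    sd = stack.std(axis=0, ddof=1)
    mean = stack.mean(axis=0)
    cv = float(np.mean(sd / np.maximum(np.abs(mean), eps)))
    return frac, cv


def motion_statistics(pre_frames: Sequence[np.ndarray],
                      post_frames: Sequence[np.ndarray],
                      mask: np.ndarray) -> MotionStatistics:
    """Motion statistics from pre- and post-stimulation brightfield sets.

    The relative-change baseline is the symmetric pair mean,
    ``|a - b| / max(mean(a, b), eps)``; CV is the per-pixel SD/mean across
    the frame set (sample SD), averaged over the animal region.
    """
    pre = [f.pixels if isinstance(f, ImageFrame) else np.asarray(f, float)
           for f in pre_frames]
    post = [f.pixels if isinstance(f, ImageFrame) else np.asarray(f, float)
            for f in post_frames]
    mask = np.asarray(mask, bool)
    frac_pre, cv_pre = _frame_set_stats(pre, mask)
    frac_post, cv_post = _frame_set_stats(post, mask)
    return MotionStatistics(frac_pre, frac_post, cv_pre, cv_post)


@dataclass
class SvrScoreModel:
    """nu-SVR (RBF kernel) mapping image statistics to days of life
    remaining; the cross-validated held-out prediction is the score."""

    params: Dict[str, float]
    n_folds: int
    pipeline: object = None

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.pipeline.predict(np.asarray(features, dtype=float))


def fit_days_remaining_svr(features, days_remaining,
                           params: Optional[Dict[str, float]] = None,
                           n_folds: int = 100, seed: int = 0,
                           ) -> Tuple[SvrScoreModel, np.ndarray]:
    """Fit the days-remaining nu-SVR and return fold-held-out predictions.

    Each row's prediction comes only from models not trained on its fold
    (no peeking); features are standardized inside each training fold.
    ``n_folds`` defaults to 100 and is clipped at the row count.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(days_remaining, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if n_folds > X.shape[0]:
        raise ValueError(f"folds ({n_folds}) exceed rows ({X.shape[0]})")
    p = dict(MOTION_SVR_PARAMS if params is None else params)
    pipe = make_pipeline(StandardScaler(),
                         NuSVR(kernel="rbf", C=p["C"], nu=p["nu"],
                               gamma=p["gamma"]))
    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = cross_val_predict(pipe, X, y, cv=cv)
    pipe.fit(X, y)
    return SvrScoreModel(params=p, n_folds=n_folds, pipeline=pipe), scores


@dataclass
class TextonDictionary:
    """30 k-means centroid patches (17x17, per-patch mean removed) per 2-day
    age bin, 210 overall."""

    centroids: np.ndarray                     # (210, 17*17)
    bins: Tuple[Tuple[int, int], ...] = AGE_BINS
    patch_size: int = PATCH_SIZE

    def __post_init__(self):
        expected = TEXTONS_PER_BIN * len(self.bins)
        if self.centroids.shape != (expected, self.patch_size ** 2):
            raise ValueError(
                f"expected {expected} centroids of {self.patch_size}^2 "
                f"pixels, got {self.centroids.shape}")


@dataclass
class TextureSignature:
    """Normalized 210-bin histogram of nearest-texton patch assignments."""

    histogram: np.ndarray

    def __post_init__(self):
        if abs(self.histogram.sum() - 1.0) > 1e-9:
            raise ValueError("signature must sum to 1")


def extract_patches(image: np.ndarray, mask: np.ndarray,
                    patch_size: int = PATCH_SIZE, stride: int = 4,
                    rng: Optional[np.random.Generator] = None,
                    n_samples: Optional[int] = None) -> np.ndarray:
    """Flattened, mean-removed patches fully inside the animal mask.

    Deterministic stride-grid extraction by default; with ``rng`` and
    ``n_samples``, that many patch centers are sampled uniformly instead.
    """
    img = np.asarray(image, dtype=float)
    mask = np.asarray(mask, bool)
    r = patch_size // 2
    from scipy.ndimage import minimum_filter
    interior = minimum_filter(mask.astype(np.uint8), size=patch_size,
                              mode="constant") > 0
    ok = np.argwhere(interior)
    if ok.size == 0:
        raise ValueError("no patch fits inside the animal outline")
    if rng is not None and n_samples is not None:
        centers = ok[rng.integers(0, ok.shape[0], size=n_samples)]
    else:
        # stride grid anchored at the first valid center so that stride ==
        # patch_size tiles the region without overlap
        keep = ((ok[:, 0] - r) % stride == 0) & ((ok[:, 1] - r) % stride == 0)
        centers = ok[keep]
        if centers.shape[0] == 0:
            centers = ok[:1]
    patches = np.empty((centers.shape[0], patch_size * patch_size))
    for k, (i, j) in enumerate(centers):
        patches[k] = img[i - r:i + r + 1, j - r:j + r + 1].ravel()
    patches -= patches.mean(axis=1, keepdims=True)
    return patches


def build_texton_dictionary(images: Sequence[Tuple[np.ndarray, np.ndarray,
                                                   float]],
                            n_samples_per_bin: int = 20000,
                            seed: int = 0,
                            bins: Tuple[Tuple[int, int], ...] = AGE_BINS,
                            ) -> TextonDictionary:
    """k-means texton dictionary from (image, mask, age) triples.

    Patches are sampled within the animal outlines of each 2-day age bin and
    clustered (k = 30) after per-patch mean removal.  Every bin must be
    represented.  Ages beyond the last bin fall into it.
    """
    rng = np.random.default_rng(seed)
    by_bin: Dict[int, list] = {i: [] for i in range(len(bins))}
    for img, mask, age in images:
        idx = None
        for i, (lo, hi) in enumerate(bins):
            if lo <= age <= hi:
                idx = i
                break
        if idx is None and age > bins[-1][1]:
            idx = len(bins) - 1
        if idx is not None:
            by_bin[idx].append((img, mask))
    empty = [bins[i] for i, v in by_bin.items() if not v]
    if empty:
        raise ValueError(f"age bins with zero images: {empty}")

    all_centroids = []
    for i in range(len(bins)):
        pool = []
        per_img = max(1, n_samples_per_bin // len(by_bin[i]))
        for img, mask in by_bin[i]:
            pool.append(extract_patches(img, mask, rng=rng,
                                        n_samples=per_img))
        patches = np.vstack(pool)
        km = KMeans(n_clusters=TEXTONS_PER_BIN, n_init=3,
                    random_state=int(rng.integers(0, 2 ** 31 - 1)))
        km.fit(patches)
        all_centroids.append(km.cluster_centers_)
    return TextonDictionary(centroids=np.vstack(all_centroids), bins=bins)


def texture_signature(image: np.ndarray, mask: np.ndarray,
                      dictionary: TextonDictionary,
                      stride: int = 4) -> TextureSignature:
    """Nearest-texton histogram over all in-outline patches (Euclidean
    distance over the 210 centroids), normalized to sum to one."""
    patches = extract_patches(image, mask, dictionary.patch_size,
                              stride=stride)
    # squared Euclidean distances via the expansion trick
    c = dictionary.centroids
    d2 = (np.sum(patches ** 2, axis=1)[:, None]
          - 2.0 * patches @ c.T + np.sum(c ** 2, axis=1)[None, :])
    nearest = np.argmin(d2, axis=1)
    hist = np.bincount(nearest, minlength=c.shape[0]).astype(float)
    return TextureSignature(histogram=hist / hist.sum())
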