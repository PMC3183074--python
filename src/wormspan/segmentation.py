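"""Locating the animal in brightfield frames.

Stages: a patch-level logistic pixel classifier produces an in-animal
probability map; the largest above-threshold connected component (holes
filled) is the mask; the mask's Euclidean distance transform forms "valleys"
whose least-cost head-to-tail path (8-connected, Dijkstra-type search) is the
centerline; flanks are offset perpendicular to the centerline by an
age-average half-width; brightfield frames are paired to fluorescence frames
by maximal mutual information of the joint intensity histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage import graph as skgraph
from skimage import measure
from sklearn.linear_model import LogisticRegression

from .types import ImageFrame, WormGeometry, resample_polyline

__all__ = [
    "PixelClassifier", "NoAnimalFoundError", "patch_features",
    "feature_stack", "train_pixel_classifier", "classify_and_mask",
    "extract_centerline", "build_outline", "mutual_information",
    "pair_brightfield_to_fluorescence", "mask_endpoints", "dice",
]

PATCH_RADIUS = 4
FEATURE_NAMES = ("mean", "sd", "min", "max", "center")


class NoAnimalFoundError(RuntimeError):
    """No above-threshold region was found in the frame."""


@dataclass
class PixelClassifier:
    """Logistic model over per-patch intensity statistics.

    Features (in order): patch mean, patch SD, patch min, patch max and the
    center-pixel value, over a square patch of radius ``patch_radius``.
    """

    patch_radius: int = PATCH_RADIUS
    feature_names: Tuple[str, ...] = FEATURE_NAMES
    weights: np.ndarray = field(default_factory=lambda: np.zeros(5))
    intercept: float = 0.0
    threshold: float = 0.5
    training_accuracy: Optional[float] = None

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        z = features @ self.weights + self.intercept
        return 1.0 / (1.0 + np.exp(-z))


def feature_stack(image: np.ndarray,
                  radius: int = PATCH_RADIUS) -> np.ndarray:
    """Per-pixel patch features for a whole frame, shape (H, W, 5).

    Computed with uniform/min/max filters so classification of a full frame
    is vectorized.
    """
    img = np.asarray(image, dtype=float)
    size = 2 * radius + 1
    mean = ndimage.uniform_filter(img, size=size, mode="nearest")
    mean_sq = ndimage.uniform_filter(img ** 2, size=size, mode="nearest")
    sd = np.sqrt(np.maximum(mean_sq - mean ** 2, 0.0))
    mn = ndimage.minimum_filter(img, size=size, mode="nearest")
    mx = ndimage.maximum_filter(img, size=size, mode="nearest")
    return np.stack([mean, sd, mn, mx, img], axis=-1)


def patch_features(image: np.ndarray, centers: np.ndarray,
                   radius: int = PATCH_RADIUS) -> np.ndarray:
    """Features of the patches centered at the given (row, col) points."""
    stack = feature_stack(image, radius)
    centers = np.asarray(centers, dtype=int)
    return stack[centers[:, 0], centers[:, 1]]


def train_pixel_classifier(features: np.ndarray, inside: np.ndarray,
                           patch_radius: int = PATCH_RADIUS,
                           ) -> PixelClassifier:
    """Fit the logistic in-animal classifier by maximum likelihood."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(inside, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training set must contain both classes")
    lr = LogisticRegression(C=np.inf, max_iter=2000)
    lr.fit(X, y)
    acc = float(lr.score(X, y))
    return PixelClassifier(patch_radius=patch_radius,
                           weights=lr.coef_.ravel().copy(),
                           intercept=float(lr.intercept_[0]),
                           training_accuracy=acc)


def classify_and_mask(image: ImageFrame | np.ndarray,
                      clf: PixelClassifier) -> np.ndarray:
    """Probability-threshold mask: largest connected component, holes filled."""
    pixels = image.pixels if isinstance(image, ImageFrame) else image
    if min(pixels.shape) < 2 * clf.patch_radius + 1:
        raise ValueError("image smaller than the classifier patch")
    stack = feature_stack(pixels, clf.patch_radius)
    prob = clf.predict_proba(stack.reshape(-1, stack.shape[-1]))
    above = prob.reshape(pixels.shape) > clf.threshold
    if not above.any():
        raise NoAnimalFoundError("no animal found")
    labels = measure.label(above, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == np.argmax(counts)
    return ndimage.binary_fill_holes(mask)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 2.0 * np.logical_and(a, b).sum() / denom if denom else 1.0


def _centerline_cost(mask: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Valley cost: (max distance value - distance transform) + eps inside
    the mask, infinite outside.

    A light Gaussian smoothing of the distance transform breaks the exact
    ties that occur on chamfer plateaus, pulling the path onto the medial
    ridge instead of letting it wander within a flat-cost band.
    """
    dt = ndimage.distance_transform_edt(mask)
    dts = ndimage.gaussian_filter(dt, sigma=1.0)
    cost = np.where(mask, dts.max() - dts + eps, np.inf)
    return cost


def extract_centerline(mask: np.ndarray, head: Sequence[float],
                       tail: Sequence[float],
                       spacing: float = 1.0) -> np.ndarray:
    """Least-cost 8-connected head-to-tail path along the distance-transform
    valley, resampled to uniform arc spacing.

    The path cost is the sum of per-pixel node costs
    ``(max(DT) - DT) + 1e-3``; the small constant gives a mild shortness bias
    so the global interior ridge is the optimum.
    """
    mask = np.asarray(mask, bool)
    head = tuple(int(round(v)) for v in head)
    tail = tuple(int(round(v)) for v in tail)
    if head == tail:
        raise ValueError("head and tail points coincide")
    for name, pt in (("head", head), ("tail", tail)):
        if not (0 <= pt[0] < mask.shape[0] and 0 <= pt[1] < mask.shape[1]) \
                or not mask[pt]:
            raise ValueError(f"{name} point {pt} outside the mask")
    cost = _centerline_cost(mask)
    mcp = skgraph.MCP(cost, fully_connected=True)
    costs, _ = mcp.find_costs([head], [tail])
    if not np.isfinite(costs[tail]):
        raise ValueError("head and tail are not connected within the mask")
    path = np.asarray(mcp.traceback(tail), dtype=float)
    if path.shape[0] >= 7:
        # counteract 8-connected staircase inflation of the arc length;
        # endpoints stay pinned at the seeds
        ends = path[[0, -1]].copy()
        path = ndimage.uniform_filter1d(path, size=5, axis=0, mode="nearest")
        path[[0, -1]] = ends
    return resample_polyline(path, spacing=spacing)


def mask_endpoints(mask: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Default head/tail seeds: the two mask pixels at maximal geodesic
    distance (double sweep of geodesic distances from an arbitrary pixel)."""
    mask = np.asarray(mask, bool)
    cost = np.where(mask, 1.0, np.inf)
    start = tuple(np.argwhere(mask)[0])

    def farthest(src):
        mcp = skgraph.MCP(cost, fully_connected=True)
        d, _ = mcp.find_costs([src])
        d = np.where(mask, d, -np.inf)
        return tuple(np.unravel_index(np.argmax(d), d.shape))

    a = farthest(start)
    b = farthest(a)
    return np.asarray(a, float), np.asarray(b, float)


def build_outline(centerline: np.ndarray, age_days: float,
                  width_model: Callable[[float, np.ndarray], np.ndarray],
                  head_fraction: float = 0.20) -> WormGeometry:
    """Flank outlines offset perpendicular to the centerline.

    ``width_model(age, s)`` returns the age-average half-width at normalized
    arc positions ``s``; ages without a model entry should be resolved to the
    nearest available age by the model itself.
    """
    center = np.asarray(centerline, dtype=float)
    if center.shape[0] < 2:
        raise ValueError("degenerate (zero-length) centerline")
    center = resample_polyline(center, spacing=1.0)
    n = center.shape[0]
    s = np.linspace(0.0, 1.0, n)
    half = np.asarray(width_model(age_days, s), dtype=float)
    tangent = np.gradient(center, axis=0)
    tangent /= np.maximum(np.linalg.norm(tangent, axis=1, keepdims=True),
                          1e-12)
    normal = np.column_stack([-tangent[:, 1], tangent[:, 0]])
    left = center + normal * half[:, None]
    right = center - normal * half[:, None]
    vulva = None
    return WormGeometry(centerline=center, left_flank=left, right_flank=right,
                        vulva=vulva, head_fraction=head_fraction,
                        half_widths=half)


def mutual_information(a: np.ndarray, b: np.ndarray,
                       bins: int = 64) -> float:
    """Mutual information of the joint intensity histogram (nats)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def pair_brightfield_to_fluorescence(candidates: Sequence[ImageFrame],
                                     fluor: ImageFrame,
                                     bins: int = 64) -> int:
    """Index of the candidate with maximum MI with the fluorescence frame.

    Ties resolve to the earliest index.
    """
    if len(candidates) == 0:
        raise ValueError("empty candidate list")
    fp = fluor.pixels
    best_idx, best_mi = 0, -np.inf
    for i, cand in enumerate(candidates):
        if cand.pixels.shape != fp.shape:
            raise ValueError("candidate and fluorescence shapes differ")
        mi = mutual_information(cand.pixels, fp, bins=bins)
        if mi > best_mi + 1e-15:
            best_idx, best_mi = i, mi
    return best_idx
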