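"""Eigen-image analysis of aligned fluorescence expression patterns.

After unit-worm warping, longitudinal alignment and per-image mean-intensity
subtraction, the remaining inter-image variability reflects only the spatial
distribution of reporter expression.  PCA of these images yields
eigen-images; each image's projection onto a component, divided by the
training-score SD, is its "PC score" in standard-deviation units.  The first
component is oriented so that positive scores indicate head(/vulva/tail)-
specific expression and negative scores diffuse whole-body expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .geometry import StraightenedImage
from .types import BiomarkerTimecourse

__all__ = ["ExpressionPcaModel", "PcScoreTimecourse", "fit_expression_pca",
           "score_images"]

HEAD_ROW_FRACTION = 0.20


@dataclass
class ExpressionPcaModel:
    """Mean image plus orthonormal eigen-images and their score scales."""

    mean_image: np.ndarray
    components: np.ndarray          # (k, n_pixels), rows orthonormal
    score_sd: np.ndarray            # training-score SD per component
    variance_fraction: np.ndarray
    grid_shape: Tuple[int, int] = (100, 24)

    def component_image(self, i: int) -> np.ndarray:
        return self.components[i].reshape(self.grid_shape)


@dataclass
class PcScoreTimecourse:
    animal_id: str
    component: int
    ages: np.ndarray
    scores: np.ndarray

    def as_timecourse(self) -> BiomarkerTimecourse:
        return BiomarkerTimecourse(self.animal_id,
                                   f"pc{self.component + 1}_score",
                                   self.ages, self.scores)


def _prepare(images: Sequence[StraightenedImage]) -> Tuple[np.ndarray, tuple]:
    shape = images[0].shape
    rows = []
    for im in images:
        if im.shape != shape:
            raise ValueError("images must share a grid")
        x = np.where(im.valid, im.data, np.nan)
        mu = np.nanmean(x) if np.isfinite(x).any() else 0.0
        # per-image mean subtracted; invalid pixels contribute 0 afterwards
        x = np.where(im.valid, im.data - mu, 0.0)
        rows.append(x.ravel())
    return np.asarray(rows), shape


def fit_expression_pca(images: Sequence[StraightenedImage],
                       n_components: Optional[int] = None,
                       ) -> ExpressionPcaModel:
    """Eigendecomposition of the image covariance.

    Per-image mean subtraction is verified/re-applied before centering.  With
    far more pixels than images, the decomposition runs through the SVD of
    the centered image matrix (equivalent to the Gram-matrix trick).  Each
    component is signed so its mean head-region loading is positive.
    """
    if len(images) < 2:
        raise ValueError("need at least two images")
    X, shape = _prepare(images)
    mean = X.mean(axis=0)
    Xc = X - mean
    # economy SVD: components = right singular vectors
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    n = X.shape[0]
    var = S ** 2 / (n - 1)
    total = var.sum()
    k = n_components or min(n - 1, Vt.shape[0])
    comps = Vt[:k].copy()
    scores = U[:, :k] * S[:k]

    head_rows = max(1, int(round(HEAD_ROW_FRACTION * shape[0])))
    head_flat = np.zeros(shape, bool)
    head_flat[:head_rows] = True
    head_flat = head_flat.ravel()
    for i in range(k):
        if comps[i][head_flat].mean() < 0:
            comps[i] = -comps[i]
            scores[:, i] = -scores[:, i]
    sd = scores.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return ExpressionPcaModel(mean_image=mean.reshape(shape),
                              components=comps, score_sd=sd,
                              variance_fraction=var[:k] / total,
                              grid_shape=shape)


def score_images(model: ExpressionPcaModel,
                 images_by_animal: Dict[str, Sequence[StraightenedImage]],
                 component: int = 0,
                 window: Optional[Tuple[float, float]] = None,
                 ) -> List[PcScoreTimecourse]:
    """Per-animal PC-score timecourses in SD units.

    ``score = projection onto the component / training-score SD``; with a
    window given, only images at ages inside it are scored.
    """
    out = []
    for animal_id, imgs in images_by_animal.items():
        ages, scores = [], []
        for im in imgs:
            if window is not None and not \
                    (window[0] <= im.age_days <= window[1]):
                continue
            if im.shape != model.grid_shape:
                raise ValueError("image grid does not match the model")
            x = np.where(im.valid, im.data, np.nan)
            mu = np.nanmean(x) if np.isfinite(x).any() else 0.0
            flat = np.where(im.valid, im.data - mu, 0.0).ravel()
            proj = float((flat - model.mean_image.ravel())
                         @ model.components[component])
            ages.append(im.age_days)
            scores.append(proj / model.score_sd[component])
        out.append(PcScoreTimecourse(animal_id, component,
                                     np.asarray(ages), np.asarray(scores)))
    return out
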