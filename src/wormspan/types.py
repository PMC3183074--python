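"""Shared containers for the individual-nematode longevity pipeline.

Conventions used throughout the package:

* image coordinates are 0-based ``(row, col)`` with row 0 at the top;
* polylines are ``(N, 2)`` float arrays sampled at ~1-px arc spacing;
* ages and lifespans are in days post slide preparation unless a function
  explicitly says hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ImageFrame",
    "WormGeometry",
    "AnimalRecord",
    "BiomarkerTimecourse",
    "polyline_arc_length",
    "resample_polyline",
]


def polyline_arc_length(points: np.ndarray) -> float:
    """Total arc length of a polyline given as an (N, 2) array."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def resample_polyline(points: np.ndarray, spacing: float = 1.0,
                      n_points: Optional[int] = None) -> np.ndarray:
    """Resample a polyline to uniform arc spacing (or a fixed point count).

    Linear interpolation along the cumulative chord length; endpoints are
    always preserved.
    """
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        raise ValueError("degenerate (zero-length) polyline")
    if n_points is None:
        n_points = max(2, int(round(total / spacing)) + 1)
    si = np.linspace(0.0, total, n_points)
    return np.column_stack([np.interp(si, s, pts[:, 0]), np.interp(si, s, pts[:, 1])])


@dataclass
class ImageFrame:
    """A single grayscale frame with acquisition metadata.

    ``pixels`` is a 2-D float array; ``channel`` is one of ``"brightfield"``,
    ``"gfp"``, ``"tritc"`` (or any user-defined label); ``exposure_ms`` is the
    exposure time used, so fluorescence intensities can be normalized to a
    per-millisecond scale.
    """

    pixels: np.ndarray
    channel: str = "brightfield"
    exposure_ms: float = 10.0
    age_days: float = 3.0
    animal_id: Optional[str] = None

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


@dataclass
class WormGeometry:
    """Centerline + flank outlines (+ optional vulva anchor) for one frame.

    The centerline is ordered head -> tail. The head region is the initial
    ``head_fraction`` of the centerline arc length (default 20%).
    """

    centerline: np.ndarray
    left_flank: Optional[np.ndarray] = None
    right_flank: Optional[np.ndarray] = None
    vulva: Optional[np.ndarray] = None
    head_fraction: float = 0.20
    half_widths: Optional[np.ndarray] = None  # per centerline sample

    @property
    def arc_length(self) -> float:
        return polyline_arc_length(self.centerline)

    def head_slice(self) -> slice:
        """Index slice of centerline samples belonging to the head region."""
        n = self.centerline.shape[0]
        k = max(1, int(round(self.head_fraction * n)))
        return slice(0, k)


@dataclass
class AnimalRecord:
    """One individual: identity, estimated lifespan and observation history."""

    animal_id: str
    dataset_id: str = "d0"
    lifespan_days: Optional[float] = None
    censored: bool = False
    observation_ages: Sequence[float] = field(default_factory=list)
    excluded: bool = False
    exclusion_reason: Optional[str] = None


@dataclass
class BiomarkerTimecourse:
    """Per-animal (age, value) series for one named biomarker."""

    animal_id: str
    biomarker: str
    ages: np.ndarray = field(default_factory=lambda: np.empty(0))
    values: np.ndarray = field(default_factory=lambda: np.empty(0))

    def in_window(self, window=(3.0, 7.0)):
        """Return (ages, values) restricted to the closed day window."""
        a = np.asarray(self.ages, dtype=float)
        v = np.asarray(self.values, dtype=float)
        m = (a >= window[0]) & (a <= window[1])
        return a[m], v[m]
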