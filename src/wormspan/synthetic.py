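"""Seeded synthetic cohorts and procedural worm image series.

Two generators live here:

* :func:`generate_cohort` draws a cohort of individually-tracked animals with a
  truncated-Gaussian lifespan distribution and, for each requested biomarker, a
  per-animal day-window slope that is linearly related to lifespan at an exact
  planted R-squared.  Daily biomarker values are the line through the window
  midpoint with that slope, plus independent Gaussian measurement noise, so the
  downstream least-squares window summary has real estimation error to cope
  with.

* :func:`generate_worm_image_series` renders a procedural nematode (dark body
  on a bright background in brightfield; hotspot Gaussians over a dim body in
  fluorescence) together with pixel-level ground truth (mask, centerline,
  vulva, hotspot centers), so the segmentation / straightening / measurement
  stages can be scored against a known answer.

Everything is reproducible bit-for-bit from the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .types import (AnimalRecord, BiomarkerTimecourse, ImageFrame,
                    polyline_arc_length, resample_polyline)

__all__ = [
    "SyntheticCohortConfig",
    "SyntheticWormSpec",
    "GroundTruth",
    "TruncationWarning",
    "generate_cohort",
    "generate_worm_image_series",
    "default_worm_spec",
    "default_width_profile",
    "paper_like_config",
    "cohort_to_frames",
]


class TruncationWarning(UserWarning):
    """Raised when lifespan truncation removes a non-negligible mass."""


# --------------------------------------------------------------------------
# Tabular cohort generator
# --------------------------------------------------------------------------

#: Default biomarker panel.  Values are the slope-vs-lifespan planted
#: R-squared and sign of the association; they emulate the strengths of the
#: day-3-7 associations observed for a wild-type reporter cohort: size
#: maintenance ~0.27 (+), age-pigment accumulation ~0.27 (-), motion ~0.20 (+),
#: texture decrepitude ~0.26 (-), and three microRNA reporters at ~0.30 (+),
#: 0.20 (+) and 0.10 (-).
DEFAULT_PANEL: Dict[str, Tuple[float, int]] = {
    "length": (0.27, +1),
    "autofluorescence": (0.27, -1),
    "motion": (0.20, +1),
    "texture": (0.26, -1),
    "mir71": (0.30, +1),
    "mir246": (0.20, +1),
    "mir239": (0.10, -1),
}


@dataclass
class SyntheticCohortConfig:
    """Parameters of a simulated single-animal longevity cohort.

    ``planted_r2[m]`` is the fraction of lifespan-linked variance in the true
    day-window slope of biomarker ``m``; ``slope_sign[m]`` its direction.
    ``noise_sd`` is per-day measurement noise in biomarker units (the slope
    across the 5-day default window has SD ``slope_scale`` = 1 across animals,
    so the default noise of 0.3 leaves the recovered R-squared within ~1% of
    the planted value).
    """

    n_animals: int = 463
    lifespan_mean: float = 10.7
    lifespan_sd: float = 1.9
    sample_interval: float = 1.0
    window: Tuple[float, float] = (3.0, 7.0)
    planted_r2: Dict[str, float] = field(default_factory=lambda: {"length": 0.27})
    slope_sign: Dict[str, int] = field(default_factory=dict)
    noise_sd: float = 0.3
    baseline: float = 10.0
    slope_scale: float = 1.0
    first_observation_day: float = 1.0
    dataset_id: str = "d0"
    seed: int = 0

    def validate(self) -> None:
        if self.n_animals < 10:
            raise ValueError("n_animals < 10: regression stages undefined")
        if self.lifespan_sd <= 0:
            raise ValueError("lifespan_sd must be > 0")
        t0, t1 = self.window
        if not (t0 < t1):
            raise ValueError("window must be a nondegenerate closed interval")
        if self.first_observation_day > t0:
            raise ValueError("window must lie within the observation span")
        for name, r2 in self.planted_r2.items():
            if not (0.0 <= r2 < 1.0):
                raise ValueError(f"planted_r2[{name!r}] = {r2} outside [0, 1)")


def paper_like_config(n_animals: int = 463, seed: int = 0,
                      **overrides) -> SyntheticCohortConfig:
    """A cohort config emulating the study conditions of the source data."""
    cfg = SyntheticCohortConfig(
        n_animals=n_animals,
        planted_r2={k: v[0] for k, v in DEFAULT_PANEL.items()},
        slope_sign={k: v[1] for k, v in DEFAULT_PANEL.items()},
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def _calibrate_truncnorm(mean: float, sd: float, lower: float):
    """Underlying (mu, sigma) of a lower-truncated Gaussian whose
    post-truncation mean and SD equal the requested values."""

    def moments(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        a = (lower - mu) / sigma
        m, v = stats.truncnorm.stats(a, np.inf, loc=mu, scale=sigma,
                                     moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.fsolve(moments, [mean, np.log(sd)], full_output=False)
    mu, sigma = sol[0], float(np.exp(sol[1]))
    return mu, sigma


def generate_cohort(config: SyntheticCohortConfig,
                    ) -> Tuple[List[AnimalRecord], List[BiomarkerTimecourse]]:
    """Draw a seeded cohort of animals and their biomarker timecourses.

    Lifespans follow a Gaussian truncated below at ``window end +
    sample_interval`` (every animal survives the full measurement window),
    with the underlying parameters calibrated so the *post-truncation* moments
    match the requested mean/SD.  For each biomarker the true slope is
    ``s_i = a + b * L_i + eps_i`` with ``Var(b L) / Var(s)`` equal to the
    planted R-squared; daily values are the line through (window midpoint,
    baseline) with slope ``s_i`` plus ``noise_sd`` jitter.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lower = config.window[1] + config.sample_interval

    mu, sigma = _calibrate_truncnorm(config.lifespan_mean, config.lifespan_sd,
                                     lower)
    removed = stats.norm.cdf((lower - mu) / sigma)
    a_std = (lower - mu) / sigma
    lifespans = stats.truncnorm.rvs(a_std, np.inf, loc=mu, scale=sigma,
                                    size=config.n_animals, random_state=rng)
    if removed > 0.05:
        warnings.warn(
            "lifespan truncation removes "
            f"{removed:.1%} of the underlying Gaussian mass; achieved moments "
            f"mean={lifespans.mean():.3f} sd={lifespans.std(ddof=1):.3f}",
            TruncationWarning, stacklevel=2)

    mid = 0.5 * (config.window[0] + config.window[1])
    animals: List[AnimalRecord] = []
    courses: List[BiomarkerTimecourse] = []

    # per-biomarker slope model shared across animals
    slope_models = {}
    for name, r2 in config.planted_r2.items():
        sign = config.slope_sign.get(name, +1)
        b = sign * np.sqrt(r2) * config.slope_scale / config.lifespan_sd
        eps_sd = config.slope_scale * np.sqrt(1.0 - r2)
        a = -b * config.lifespan_mean  # mean slope 0 across the cohort
        slope_models[name] = (a, b, eps_sd)

    for i in range(config.n_animals):
        L = float(lifespans[i])
        last_day = np.floor(L / config.sample_interval) * config.sample_interval
        ages = np.arange(config.first_observation_day,
                         last_day + 0.5 * config.sample_interval,
                         config.sample_interval)
        aid = f"{config.dataset_id}_a{i:04d}"
        animals.append(AnimalRecord(animal_id=aid, dataset_id=config.dataset_id,
                                    lifespan_days=L,
                                    observation_ages=ages.tolist()))
        for name, (a, b, eps_sd) in slope_models.items():
            s_i = a + b * L + rng.normal(0.0, eps_sd)
            values = (config.baseline + s_i * (ages - mid)
                      + rng.normal(0.0, config.noise_sd, size=ages.size))
            courses.append(BiomarkerTimecourse(animal_id=aid, biomarker=name,
                                               ages=ages, values=values))
    return animals, courses


def cohort_to_frames(animals: Sequence[AnimalRecord],
                     courses: Sequence[BiomarkerTimecourse]):
    """Cohort as (animal table, long-format timecourse table) DataFrames.

    The long format (animal_id, age_days, biomarker, value) is deliberately
    the same one the supplementary-table reader consumes.
    """
    import pandas as pd

    adf = pd.DataFrame([{
        "animal_id": a.animal_id, "dataset_id": a.dataset_id,
        "lifespan_days": a.lifespan_days, "censored": a.censored,
    } for a in animals])
    rows = []
    for c in courses:
        for age, val in zip(c.ages, c.values):
            rows.append((c.animal_id, float(age), c.biomarker, float(val)))
    tdf = pd.DataFrame(rows, columns=["animal_id", "age_days", "biomarker",
                                      "value"])
    return adf, tdf


# --------------------------------------------------------------------------
# Procedural worm images
# --------------------------------------------------------------------------

#: normalized arc positions used for region-anchored hotspots
REGION_ARC = {"head": 0.08, "vulva": None, "tail": 0.92, "body": 0.5}


@dataclass
class Hotspot:
    region: str  # head | vulva | tail | body
    intensity: float = 1.0
    radius: float = 6.0


@dataclass
class SyntheticWormSpec:
    """Geometry and appearance of one procedural worm.

    ``centerline_points`` are coarse (row, col) control points interpolated by
    a cubic spline; ``width_profile`` maps normalized arc position in [0, 1]
    to half-width in pixels (zero at both ends, positive inside);
    ``texture_roughness`` scales interior brightfield speckle (stands in for
    age-related tissue decrepitude); ``motion_displacement`` rigidly shifts
    sequential frames (pixels along the canvas columns).
    """

    centerline_points: np.ndarray
    width_profile: Callable[[np.ndarray], np.ndarray]
    vulva_position: float = 0.55
    hotspots: List[Hotspot] = field(default_factory=list)
    texture_roughness: float = 0.2
    motion_displacement: float = 0.0
    canvas_shape: Tuple[int, int] = (120, 480)
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.vulva_position < 1.0):
            raise ValueError("vulva_position must be strictly inside (0, 1)")
        s = np.linspace(0.05, 0.95, 19)
        if np.any(self.width_profile(s) <= 0):
            raise ValueError("width profile must be positive in the interior")


@dataclass
class GroundTruth:
    """Pixel-level truth for a rendered worm (frame 0 of a series)."""

    mask: np.ndarray
    centerline: np.ndarray
    arc_length: float
    vulva_pixel: np.ndarray
    hotspot_centers: List[np.ndarray]
    half_widths: np.ndarray = None


def default_width_profile(max_half_width: float = 9.0):
    """Tapered half-width: zero at the tips, ~max in the mid-body."""

    def profile(s):
        s = np.asarray(s, dtype=float)
        return max_half_width * np.sin(np.pi * np.clip(s, 0, 1)) ** 0.6

    return profile


def default_worm_spec(seed: int = 0, age_days: float = 3.0,
                      arc_length: float = 300.0,
                      bend_amplitude: Optional[float] = None,
                      canvas_shape: Tuple[int, int] = (120, 480),
                      hotspots: Optional[List[Hotspot]] = None,
                      **kwargs) -> SyntheticWormSpec:
    """A randomized but seeded worm posture filling the default canvas.

    Texture roughness grows linearly with age, emulating progressive tissue
    decrepitude in brightfield appearance.
    """
    rng = np.random.default_rng(seed)
    h, w = canvas_shape
    if bend_amplitude is None:
        bend_amplitude = rng.uniform(8.0, float(h) / 2 - 25.0)
    n_ctrl = 7
    x = np.linspace((w - arc_length * 0.95) / 2,
                    (w + arc_length * 0.95) / 2, n_ctrl)
    phase = rng.uniform(0, 2 * np.pi)
    n_waves = rng.uniform(0.8, 1.6)
    y = h / 2 + bend_amplitude * np.sin(
        np.linspace(0, n_waves * 2 * np.pi, n_ctrl) + phase)
    pts = np.column_stack([y, x])
    if hotspots is None:
        hotspots = [Hotspot("head", 1.0, 6.0), Hotspot("vulva", 0.8, 5.0),
                    Hotspot("tail", 0.7, 5.0)]
    roughness = 0.08 + 0.015 * age_days
    return SyntheticWormSpec(centerline_points=pts,
                             width_profile=default_width_profile(),
                             hotspots=hotspots,
                             texture_roughness=kwargs.pop(
                                 "texture_roughness", roughness),
                             canvas_shape=canvas_shape, seed=seed, **kwargs)


def _dense_centerline(spec: SyntheticWormSpec) -> np.ndarray:
    pts = np.asarray(spec.centerline_points, dtype=float)
    chord = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    cs_r = CubicSpline(chord, pts[:, 0])
    cs_c = CubicSpline(chord, pts[:, 1])
    t = np.linspace(0, chord[-1], max(64, int(chord[-1] * 4)))
    dense = np.column_stack([cs_r(t), cs_c(t)])
    return resample_polyline(dense, spacing=1.0)


def render_ground_truth(spec: SyntheticWormSpec) -> GroundTruth:
    """Rasterize the worm mask and assemble pixel-level ground truth."""
    spec.validate()
    center = _dense_centerline(spec)
    h, w = spec.canvas_shape
    n = center.shape[0]
    s_norm = np.linspace(0, 1, n)
    half = spec.width_profile(s_norm)
    margin = float(half.max()) + 2
    if (center[:, 0].min() < margin or center[:, 0].max() > h - margin
            or center[:, 1].min() < margin or center[:, 1].max() > w - margin):
        raise ValueError("worm exits canvas")

    tree = cKDTree(center)
    rr, cc = np.mgrid[0:h, 0:w]
    pix = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    dist, idx = tree.query(pix, workers=-1)
    mask = (dist <= half[idx]).reshape(h, w)

    vi = int(round(spec.vulva_position * (n - 1)))
    centers = []
    for hs in spec.hotspots:
        if hs.region == "vulva":
            ci = vi
        else:
            ci = int(round(REGION_ARC.get(hs.region, 0.5) * (n - 1)))
        centers.append(center[ci].copy())
    return GroundTruth(mask=mask, centerline=center,
                       arc_length=polyline_arc_length(center),
                       vulva_pixel=center[vi].copy(),
                       hotspot_centers=centers, half_widths=half)


def _shift_truth(gt: GroundTruth, spec: SyntheticWormSpec,
                 dc: float) -> GroundTruth:
    shifted = SyntheticWormSpec(
        centerline_points=np.asarray(spec.centerline_points, float)
        + np.array([0.0, dc]),
        width_profile=spec.width_profile, vulva_position=spec.vulva_position,
        hotspots=spec.hotspots, texture_roughness=spec.texture_roughness,
        canvas_shape=spec.canvas_shape, seed=spec.seed)
    return render_ground_truth(shifted)


def make_speckle(spec: SyntheticWormSpec,
                 rng: np.random.Generator) -> np.ndarray:
    """The worm's fixed interior texture field (one per animal, not per
    frame: it travels rigidly with the body between frames)."""
    speckle = gaussian_filter(rng.standard_normal(spec.canvas_shape),
                              sigma=1.3)
    return speckle / max(speckle.std(), 1e-12)


def render_brightfield(gt: GroundTruth, spec: SyntheticWormSpec,
                       rng: np.random.Generator,
                       speckle: Optional[np.ndarray] = None,
                       noise: bool = True) -> np.ndarray:
    """Dark worm on a bright background with interior speckle."""
    h, w = gt.mask.shape
    img = np.full((h, w), 0.85)
    img[gt.mask] = 0.35
    if speckle is None:
        speckle = make_speckle(spec, rng)
    img[gt.mask] += spec.texture_roughness * 0.5 * speckle[gt.mask]
    if noise:
        img += rng.normal(0.0, 0.01, size=img.shape)
    return img


def render_fluorescence(gt: GroundTruth, spec: SyntheticWormSpec,
                        rng: np.random.Generator,
                        noise: bool = True) -> np.ndarray:
    """Hotspot Gaussians over a dim body background plus camera noise."""
    h, w = gt.mask.shape
    img = np.zeros((h, w))
    img[gt.mask] = 0.05
    rr, cc = np.mgrid[0:h, 0:w]
    for hs, ctr in zip(spec.hotspots, gt.hotspot_centers):
        if hs.region == "body":
            # diffuse whole-body elevation rather than a focal peak
            img[gt.mask] += hs.intensity * 0.5
            continue
        d2 = (rr - ctr[0]) ** 2 + (cc - ctr[1]) ** 2
        img += hs.intensity * np.exp(-d2 / (2.0 * hs.radius ** 2))
    if noise:
        img += rng.normal(0.0, 0.003, size=img.shape)
    return img


def generate_worm_image_series(spec: SyntheticWormSpec, n_frames: int = 3,
                               fluorescence: bool = True,
                               age_days: float = 3.0,
                               ) -> Tuple[List[ImageFrame], GroundTruth]:
    """Render a short acquisition series for one worm.

    Returns ``n_frames`` brightfield frames (sequential frames rigidly
    displaced by ``motion_displacement`` pixels) followed, when requested, by
    one fluorescence frame at the frame-0 pose, plus the frame-0 ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    gt0 = render_ground_truth(spec)
    speckle0 = make_speckle(spec, rng)
    frames: List[ImageFrame] = []
    for k in range(n_frames):
        dc = k * spec.motion_displacement
        if k == 0 or spec.motion_displacement == 0:
            gt_k, speckle_k = gt0, speckle0
        else:
            gt_k = _shift_truth(gt0, spec, dc)
            speckle_k = np.roll(speckle0, int(round(dc)), axis=1)
        frames.append(ImageFrame(
            pixels=render_brightfield(gt_k, spec, rng, speckle=speckle_k),
            channel="brightfield", exposure_ms=10.0, age_days=age_days))
    if fluorescence:
        frames.append(ImageFrame(pixels=render_fluorescence(gt0, spec, rng),
                                 channel="gfp", exposure_ms=100.0,
                                 age_days=age_days))
    return frames, gt0
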