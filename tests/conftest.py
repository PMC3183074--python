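import warnings

import numpy as np
import pytest

from wormspan import geometry as geo
from wormspan import segmentation as seg
from wormspan import stats as wstats
from wormspan import synthetic as syn
from wormspan.types import WormGeometry


@pytest.fixture(autouse=True)
def _quiet_truncation():
    # the default cohort config legitimately warns about truncation mass;
    # tests assert on it explicitly where it matters
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", syn.TruncationWarning)
        yield


@pytest.fixture(scope="session")
def small_cohort():
    cfg = syn.SyntheticCohortConfig(n_animals=200,
                                    planted_r2={"length": 0.27},
                                    seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", syn.TruncationWarning)
        return syn.generate_cohort(cfg)


@pytest.fixture(scope="session")
def rendered_worm():
    spec = syn.default_worm_spec(seed=3)
    frames, gt = syn.generate_worm_image_series(spec, n_frames=2)
    return spec, frames, gt


def geometry_from_truth(gt) -> WormGeometry:
    return WormGeometry(centerline=gt.centerline, half_widths=gt.half_widths,
                        vulva=gt.vulva_pixel)


def straightened_fluor(seed, hotspots, age=3.0, grid=(100, 24)):
    """Unit-worm-warped fluorescence image of one synthetic worm."""
    spec = syn.default_worm_spec(seed=seed, hotspots=hotspots, age_days=age)
    frames, gt = syn.generate_worm_image_series(spec, n_frames=1)
    st = geo.straighten(frames[-1], geometry_from_truth(gt))
    n = gt.half_widths.size
    std = geo.UnitWormStandard(
        {int(round(age)): gt.arc_length},
        {int(round(age)): np.interp(np.linspace(0, 1, grid[0]),
                                    np.linspace(0, 1, n), gt.half_widths)},
        grid_shape=grid)
    return geo.warp_to_unit(st, std)


@pytest.fixture(scope="session")
def trained_classifier(rendered_worm):
    _, frames, gt = rendered_worm
    img = frames[0].pixels
    rng = np.random.default_rng(0)
    inside = np.argwhere(gt.mask)
    outside = np.argwhere(~gt.mask)
    pts = np.vstack([inside[rng.integers(0, len(inside), 300)],
                     outside[rng.integers(0, len(outside), 300)]])
    pts = np.clip(pts, 4, np.array(img.shape) - 5)
    labels = np.concatenate([np.ones(300), np.zeros(300)])
    X = seg.patch_features(img, pts)
    return seg.train_pixel_classifier(X, labels)
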