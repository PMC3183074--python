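"""Fluorescence correction, size, motion, SVR scores and texture textons."""

import numpy as np
import pytest

from wormspan import biomarkers as bm
from wormspan import synthetic as syn
from wormspan.types import ImageFrame, WormGeometry

from conftest import geometry_from_truth


class TestFluorescenceCorrection:
    def _cal(self, shape=(30, 30), exposure=10.0):
        dark = np.full(shape, 0.1)
        flat = dark + 1.0
        return bm.FluorescenceCalibration(dark, flat, exposure)

    def test_raw_equals_dark_gives_zero(self):
        cal = self._cal()
        out = bm.correct_fluorescence(ImageFrame(np.full((30, 30), 0.1),
                                                 exposure_ms=10.0), cal)
        np.testing.assert_array_equal(out.pixels, 0.0)

    def test_exposure_linearity(self):
        cal10 = self._cal(exposure=10.0)
        scene = np.linspace(0, 1, 900).reshape(30, 30)
        img10 = ImageFrame(0.1 + scene * 10.0, exposure_ms=10.0)
        img100 = ImageFrame(0.1 + scene * 100.0, exposure_ms=100.0)
        out10 = bm.correct_fluorescence(img10, cal10)
        out100 = bm.correct_fluorescence(img100, cal10)
        np.testing.assert_allclose(out10.pixels, out100.pixels, atol=1e-6)

    def test_vignetting_removed(self):
        rr, cc = np.mgrid[0:40, 0:40]
        vignette = 1.0 - 0.4 * ((rr - 20) ** 2 + (cc - 20) ** 2) / 800.0
        dark = np.full((40, 40), 0.05)
        cal = bm.FluorescenceCalibration(dark, dark + vignette, 10.0)
        raw = ImageFrame(dark + 3.0 * vignette, exposure_ms=10.0)
        out = bm.correct_fluorescence(raw, cal)
        assert out.pixels.std() / out.pixels.mean() < 0.01

    def test_nonpositive_flat_rejected(self):
        dark = np.full((10, 10), 0.2)
        cal = bm.FluorescenceCalibration(dark, dark.copy(), 10.0)
        with pytest.raises(ValueError, match="flat"):
            bm.correct_fluorescence(ImageFrame(dark), cal)


class TestSize:
    def _straight_geom(self, length=100.0, w=5.0, n=101):
        center = np.column_stack([np.full(n, 20.0), np.linspace(0, length, n)])
        return WormGeometry(centerline=center, half_widths=np.full(n, w))

    def test_closed_form_cylinder(self):
        L, w = 100.0, 5.0
        length, vol, area = bm.measure_size(self._straight_geom(L, w))
        assert length == pytest.approx(L, rel=1e-6)
        assert vol == pytest.approx(np.pi * w ** 2 * L, rel=0.01)
        assert area == pytest.approx(2 * np.pi * w * L, rel=0.01)

    def test_dimensional_scaling(self):
        g1 = self._straight_geom(80.0, 4.0)
        g2 = WormGeometry(centerline=g1.centerline * 2,
                          half_widths=g1.half_widths * 2)
        l1, v1, a1 = bm.measure_size(g1)
        l2, v2, a2 = bm.measure_size(g2)
        assert l2 / l1 == pytest.approx(2, rel=1e-6)
        assert a2 / a1 == pytest.approx(4, rel=1e-6)
        assert v2 / v1 == pytest.approx(8, rel=1e-6)

    def test_synthetic_worm_length_within_3pct(self, rendered_worm):
        _, _, gt = rendered_worm
        length, _, _ = bm.measure_size(geometry_from_truth(gt))
        assert abs(length - gt.arc_length) < 0.03 * gt.arc_length


class TestFluorescenceSummary:
    def test_constant_image_any_percentile(self, rendered_worm):
        _, _, gt = rendered_worm
        img = np.full(gt.mask.shape, 7.5)
        geom = geometry_from_truth(gt)
        for p in (5, 50, 95):
            assert bm.fluorescence_summary(img, "whole", p, geom=geom) == 7.5

    def test_percentile_interpolation_linear(self):
        # 100 pixels valued 1..100: the linearly interpolated 95th
        # percentile lies in [95, 96]
        vals = np.arange(1.0, 101.0)
        assert 95.0 <= np.percentile(vals, 95) <= 96.0

    def test_head_hotspot_head_summary_exceeds_body(self):
        spec = syn.default_worm_spec(
            seed=1, hotspots=[syn.Hotspot("head", 1.0, 6.0)])
        frames, gt = syn.generate_worm_image_series(spec, n_frames=1)
        geom = geometry_from_truth(gt)
        head = bm.fluorescence_summary(frames[-1], "head", geom=geom)
        whole = bm.fluorescence_summary(frames[-1], "whole", geom=geom)
        assert head > whole

    def test_empty_region_rejected(self, rendered_worm):
        _, _, gt = rendered_worm
        geom = geometry_from_truth(gt)
        img = np.full(gt.mask.shape, 1.0)
        with pytest.raises(ValueError, match="unknown region"):
            bm.fluorescence_summary(img, "gonad", geom=geom)


class TestMotion:
    def test_identical_frames_all_zero(self):
        a = np.random.default_rng(0).random((30, 30)) + 0.5
        mask = np.ones((30, 30), bool)
        ms = bm.motion_statistics([a, a.copy()], [a, a.copy()], mask)
        assert ms.as_array().tolist() == [0, 0, 0, 0]

    def test_scaled_copy_fraction_is_one(self):
        a = np.random.default_rng(1).random((30, 30)) + 0.5
        mask = np.ones((30, 30), bool)
        # |1.25x - x| / mean = 0.25/1.125 = 2/9 > 0.18 at every pixel
        ms = bm.motion_statistics([a, a.copy()], [a, 1.25 * a], mask)
        assert ms.frac_changed_pre == 0.0
        assert ms.frac_changed_post == 1.0

    def test_monotone_in_displacement(self):
        means = []
        for disp in (0, 1, 2, 4):
            vals = []
            for s in range(6):
                spec = syn.default_worm_spec(seed=s,
                                             motion_displacement=float(disp))
                frames, gt = syn.generate_worm_image_series(
                    spec, n_frames=3, fluorescence=False)
                ms = bm.motion_statistics([f.pixels for f in frames[:2]],
                                          [f.pixels for f in frames[1:]],
                                          gt.mask)
                vals.append(ms.frac_changed_pre + ms.cv_pre)
            means.append(np.mean(vals))
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bm.motion_statistics([np.ones((5, 5)), np.ones((6, 6))],
                                 [np.ones((5, 5))] * 2, np.ones((5, 5), bool))


class TestSvr:
    def test_noiseless_linear_high_cv_r2(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 200)
        y = 2.0 * x + 1.0
        _, scores = bm.fit_days_remaining_svr(x[:, None], y, n_folds=20)
        r2 = 1 - np.sum((scores - y) ** 2) / np.sum((y - y.mean()) ** 2)
        assert r2 >= 0.9

    def test_permuted_labels_no_signal(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 10, 150)
        y = rng.permutation(2.0 * x + 1.0)
        _, scores = bm.fit_days_remaining_svr(x[:, None], y, n_folds=10)
        r2 = 1 - np.sum((scores - y) ** 2) / np.sum((y - y.mean()) ** 2)
        assert r2 < 0.1

    def test_default_hyperparameters(self):
        assert bm.MOTION_SVR_PARAMS == {"C": 10.0, "nu": 0.8, "gamma": 0.3}
        assert bm.TEXTURE_SVR_PARAMS == {"C": 5.0, "nu": 0.6, "gamma": 0.004}

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            bm.fit_days_remaining_svr(np.ones((5, 1)), np.arange(5.0),
                                      n_folds=10)


def _textured_image(seed, rough, shape=(80, 80)):
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    base = 0.5 + rough * gaussian_filter(rng.standard_normal(shape), 1.0)
    return base, np.ones(shape, bool)


@pytest.fixture(scope="module")
def dictionary():
    images = []
    for age in (3, 5, 7, 9, 11, 13, 15):
        img, mask = _textured_image(age, 0.02 + 0.01 * age)
        images.append((img, mask, float(age)))
    return bm.build_texton_dictionary(images, n_samples_per_bin=1500, seed=0)


class TestTextons:
    def test_dictionary_totals_210(self, dictionary):
        assert dictionary.centroids.shape == (210, 17 * 17)

    def test_missing_bin_rejected(self):
        img, mask = _textured_image(0, 0.05)
        with pytest.raises(ValueError, match="zero images"):
            bm.build_texton_dictionary([(img, mask, 3.0)])

    def test_signature_sums_to_one(self, dictionary):
        img, mask = _textured_image(42, 0.1)
        sig = bm.texture_signature(img, mask, dictionary)
        assert sig.histogram.sum() == pytest.approx(1.0, abs=1e-9)
        assert (sig.histogram >= 0).all()

    def test_tiled_centroid_maps_to_its_bin(self, dictionary):
        # an image built by tiling one centroid patch lands on that bin
        patch = dictionary.centroids[17].reshape(17, 17)
        img = np.tile(patch, (5, 5))
        mask = np.ones_like(img, bool)
        sig = bm.texture_signature(img, mask, dictionary, stride=17)
        assert sig.histogram[17] >= 0.99

    def test_nearest_texton_matches_bruteforce(self, dictionary):
        rng = np.random.default_rng(5)
        img, mask = _textured_image(5, 0.1)
        patches = bm.extract_patches(img, mask, rng=rng, n_samples=50)
        c = dictionary.centroids
        brute = np.array([np.argmin(((p - c) ** 2).sum(axis=1))
                          for p in patches])
        d2 = (np.sum(patches ** 2, axis=1)[:, None]
              - 2 * patches @ c.T + np.sum(c ** 2, axis=1)[None, :])
        assert np.array_equal(np.argmin(d2, axis=1), brute)

    def test_two_texture_classes_separate(self):
        # two pure periodic textures (17-px period, so patches align with
        # the stride grid): k-means with k = 2 separates them cleanly
        rr, cc = np.mgrid[0:17, 0:17]
        pat_smooth = np.sin(2 * np.pi * rr / 17.0)
        pat_rough = np.where((rr + cc) % 2 == 0, 1.0, -1.0)
        smooth = np.tile(pat_smooth, (7, 7))
        rough = np.tile(pat_rough, (7, 7))
        mask = np.ones_like(smooth, bool)
        p_smooth = bm.extract_patches(smooth, mask, stride=17)
        p_rough = bm.extract_patches(rough, mask, stride=17)
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=2, n_init=5, random_state=0)
        labels = km.fit_predict(np.vstack([p_smooth, p_rough]))
        n1 = len(p_smooth)
        purity = (max(labels[:n1].mean(), 1 - labels[:n1].mean())
                  + max(labels[n1:].mean(), 1 - labels[n1:].mean())) / 2
        assert purity >= 0.95

    def test_age_separates_signatures(self, dictionary):
        young, old = [], []
        for s in range(6):
            iy, my = _textured_image(100 + s, 0.05)
            io, mo = _textured_image(200 + s, 0.25)
            young.append(bm.texture_signature(iy, my, dictionary).histogram)
            old.append(bm.texture_signature(io, mo, dictionary).histogram)

        def l1(a, b):
            return np.abs(a - b).sum()

        inter = np.mean([l1(a, b) for a in young for b in old])
        intra = np.mean([l1(a, b) for g in (young, old)
                         for i, a in enumerate(g) for b in g[i + 1:]])
        assert inter > intra
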