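"""Image statistics: heterogeneity, beads, colocalization, clusters."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from vermicelli import images
from vermicelli.errors import (
    DegenerateInputError,
    InsufficientDataError,
    ParameterError,
)
from vermicelli.images import (
    BoxDistribution,
    bead_spacings,
    compute_box_intensities,
    detect_beads,
    fit_double_gaussian,
    heterogeneity_level,
    line_profile,
    mask_and_rescale,
    pearson_colocalization,
    segment_clusters,
)
from vermicelli.io import NucleusImage
from vermicelli.simulate import ImageSimParams, simulate_nucleus_image


class TestMaskAndRescale:
    def test_constant_image_rescaled_to_target(self, constant_image):
        out = mask_and_rescale(constant_image(50.0), target_mean=100.0)
        assert np.allclose(out.intensity, 100.0)

    def test_scale_invariance(self, constant_image):
        rng = np.random.default_rng(0)
        base = rng.uniform(10, 90, (40, 40))
        a = NucleusImage(intensity=base, pixel_size=0.05)
        b = NucleusImage(intensity=3 * base, pixel_size=0.05)
        ra = mask_and_rescale(a, 100.0).intensity
        rb = mask_and_rescale(b, 100.0).intensity
        assert np.allclose(ra, rb)

    def test_empty_nucleus_raises(self):
        img = NucleusImage(intensity=np.ones((10, 10)), pixel_size=0.05,
                           nucleus_mask=np.zeros((10, 10), dtype=bool))
        with pytest.raises(DegenerateInputError):
            mask_and_rescale(img)

    def test_excluded_pixels_zeroed(self, constant_image):
        img = constant_image(50.0)
        img.exclusion_mask[:10, :10] = True
        out = mask_and_rescale(img, 100.0)
        assert np.all(out.intensity[:10, :10] == 0)


class TestBoxIntensities:
    def test_constant_tiles(self, constant_image):
        img = constant_image(7.0, shape=(10, 10))
        dist = compute_box_intensities(img, box=5, stride=5)
        assert len(dist.values) == 4
        assert np.allclose(dist.values, 7.0)

    def test_zeroed_quadrant_discarded(self):
        arr = np.full((10, 10), 7.0)
        arr[:5, :5] = 0.0
        arr[0, 0] = 1.0  # make it a partially-masked box, not empty
        img = NucleusImage(intensity=arr, pixel_size=0.05)
        dist = compute_box_intensities(img, box=5, stride=5)
        assert len(dist.values) == 3
        assert dist.n_discarded == 1

    def test_matches_brute_force_tiling(self):
        rng = np.random.default_rng(2)
        arr = rng.uniform(1, 100, (50, 50))
        img = NucleusImage(intensity=arr, pixel_size=0.05)
        dist = compute_box_intensities(img, box=5, stride=5)
        brute = [arr[y:y + 5, x:x + 5].mean()
                 for y in range(0, 46, 5) for x in range(0, 46, 5)]
        assert len(dist.values) == 100
        assert np.allclose(np.sort(dist.values), np.sort(brute))

    def test_box_larger_than_image_rejected(self, constant_image):
        with pytest.raises(ParameterError):
            compute_box_intensities(constant_image(shape=(4, 4)), box=5)


class TestDoubleGaussian:
    def test_two_population_separation_recovered(self):
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            vals = np.concatenate([rng.normal(50, 5, 300),
                                   rng.normal(150, 5, 300)])
            res = fit_double_gaussian(BoxDistribution(vals, 5, 5, 0))
            errs.append(res.heterogeneity - 100.0)
        assert abs(np.mean(errs)) < 3.0
        assert np.max(np.abs(errs)) < 6.0

    def test_constant_values_give_zero(self):
        res = fit_double_gaussian(BoxDistribution(np.full(100, 42.0), 5, 5, 0))
        assert res.heterogeneity < 1e-6
        assert res.unimodal

    def test_unimodal_bounded_and_agrees_with_em(self):
        # single-population data: separation stays below 2 sigma, and the
        # two-component EM fit on raw values finds a comparable split
        from sklearn.mixture import GaussianMixture
        rng = np.random.default_rng(5)
        vals = rng.normal(100, 10, 500)
        res = fit_double_gaussian(BoxDistribution(vals, 5, 5, 0))
        assert res.heterogeneity <= 2 * 10.0
        gm = GaussianMixture(2, random_state=0).fit(vals.reshape(-1, 1))
        em_sep = abs(gm.means_[1, 0] - gm.means_[0, 0])
        assert res.heterogeneity == pytest.approx(em_sep, abs=10.0)

    def test_coincident_peaks_flagged_unimodal(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(100, 10, 500)
        res = fit_double_gaussian(BoxDistribution(vals, 5, 5, 0))
        pooled = np.sqrt(res.weight1 * res.sigma1 ** 2
                         + (1 - res.weight1) * res.sigma2 ** 2)
        assert res.unimodal == (res.heterogeneity < pooled)

    def test_em_cross_check_on_bimodal_data(self):
        from sklearn.mixture import GaussianMixture
        rng = np.random.default_rng(7)
        vals = np.concatenate([rng.normal(60, 8, 400),
                               rng.normal(140, 8, 400)])
        res = fit_double_gaussian(BoxDistribution(vals, 5, 5, 0))
        gm = GaussianMixture(2, random_state=0).fit(vals.reshape(-1, 1))
        em_sep = abs(gm.means_[1, 0] - gm.means_[0, 0])
        assert res.heterogeneity == pytest.approx(em_sep, abs=5.0)

    def test_insufficient_data_raises(self):
        with pytest.raises(InsufficientDataError):
            fit_double_gaussian(BoxDistribution(np.ones(49), 5, 5, 0))


class TestHeterogeneityLevel:
    # heterogeneity is a whole-nucleus statistic; the fibrous condition is
    # simulated dense (n_fibers=30), the way the phenotype fills the nucleus

    def test_vermicelli_exceeds_uniform_in_paired_seeds(self):
        wins = 0
        for seed in range(20):
            iu, _, _ = simulate_nucleus_image(ImageSimParams(
                mode="uniform", seed=seed))
            iv, _, _ = simulate_nucleus_image(ImageSimParams(
                mode="vermicelli", n_fibers=30, seed=seed))
            hu = heterogeneity_level(iu).heterogeneity
            hv = heterogeneity_level(iv).heterogeneity
            wins += hv > hu
        assert wins >= 19

    def test_monotone_in_bead_amplitude(self):
        meds = []
        for amp in (50.0, 150.0, 400.0):
            hs = [heterogeneity_level(simulate_nucleus_image(ImageSimParams(
                n_fibers=30, bead_amplitude=amp, seed=s))[0]).heterogeneity
                for s in range(5)]
            meds.append(np.median(hs))
        assert meds[0] <= meds[1] <= meds[2]

    def test_intensity_scale_invariance(self):
        img, _, _ = simulate_nucleus_image(ImageSimParams(seed=9))
        h1 = heterogeneity_level(img).heterogeneity
        scaled = NucleusImage(intensity=img.intensity * 4.0,
                              pixel_size=img.pixel_size,
                              nucleus_mask=img.nucleus_mask,
                              exclusion_mask=img.exclusion_mask)
        h2 = heterogeneity_level(scaled).heterogeneity
        assert h1 == pytest.approx(h2, rel=1e-3)

    def test_constant_image_near_zero(self, constant_image):
        res = heterogeneity_level(constant_image(80.0))
        assert res.heterogeneity < 1e-6
        assert res.mean_intensity == pytest.approx(80.0)


def _match(det_coords, truth, tol=1.5):
    tree = cKDTree(truth)
    d, idx = tree.query(det_coords)
    matched = d <= tol
    tp = len(set(idx[matched]))
    return tp / len(truth), matched.mean() if len(det_coords) else 0.0


class TestBeadDetection:
    def test_noise_free_single_fiber_all_found(self):
        # straight fiber, beads every 10 px, no noise: exact recovery
        arr = np.full((64, 128), 5.0)
        truth = np.array([[32.0, x] for x in range(14, 114, 10)])
        yy, xx = np.mgrid[0:64, 0:128]
        for cy, cx in truth:
            arr += 200 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 4))
        img = NucleusImage(intensity=arr, pixel_size=0.05)
        det = detect_beads(img, psf_sigma=0.1, expected_spacing=0.5)
        recall, precision = _match(det.coords, truth)
        assert recall == 1.0 and precision == 1.0

    def test_single_spot_gives_one_bead_no_spacing(self):
        arr = np.full((64, 64), 5.0)
        yy, xx = np.mgrid[0:64, 0:64]
        arr += 200 * np.exp(-((yy - 30) ** 2 + (xx - 30) ** 2) / 8)
        img = NucleusImage(intensity=arr, pixel_size=0.05)
        det = detect_beads(img)
        assert len(det.coords) == 1
        assert bead_spacings(det)["empty"]

    def test_high_snr_recall_precision(self):
        recs, precs = [], []
        for seed in range(20):
            img, beads, _ = simulate_nucleus_image(ImageSimParams(seed=seed))
            det = detect_beads(img)
            r, p = _match(det.coords, beads)
            recs.append(r)
            precs.append(p)
        assert np.mean(recs) >= 0.95
        assert np.mean(precs) >= 0.95

    def test_no_cross_fiber_spacing(self):
        # two parallel straight fibers far apart: chains stay separate
        arr = np.full((80, 120), 5.0)
        yy, xx = np.mgrid[0:80, 0:120]
        t1 = np.array([[20.0, x] for x in range(20, 100, 8)])
        t2 = np.array([[60.0, x] for x in range(20, 100, 8)])
        for cy, cx in np.vstack([t1, t2]):
            arr += 200 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / 8)
        img = NucleusImage(intensity=arr, pixel_size=0.05)
        det = detect_beads(img, expected_spacing=0.4)
        sp = bead_spacings(det)["spacings"]
        # 8 px = 0.4 um; a cross-fiber link would appear as 40/… px >> 0.4
        assert np.all(sp < 0.6)

    def test_spacing_arithmetic(self):
        from vermicelli.images import BeadSet
        beads = BeadSet(coords=np.array([[0.0, 0.0], [0.0, 10.0],
                                         [0.0, 20.0]]),
                        fiber=np.zeros(3, dtype=int),
                        order=np.arange(3), pixel_size=0.034)
        sp = bead_spacings(beads)
        assert np.allclose(sp["spacings"], [0.34, 0.34])


class TestColocalization:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        a = NucleusImage(rng.uniform(1, 10, (30, 30)), 0.05)
        assert pearson_colocalization(a, a) == pytest.approx(1.0)

    def test_anti_correlation_is_minus_one(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(1, 10, (30, 30))
        a = NucleusImage(base, 0.05)
        b = NucleusImage(20.0 - base, 0.05)
        assert pearson_colocalization(a, b) == pytest.approx(-1.0)

    def test_independent_channels_near_zero(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = NucleusImage(rng.uniform(1, 10, (100, 100)), 0.05)
            b = NucleusImage(rng.uniform(1, 10, (100, 100)), 0.05)
            hits += abs(pearson_colocalization(a, b)) < 0.05
        assert hits >= 95

    def test_affine_invariance_and_symmetry(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(1, 10, (40, 40))
        y = rng.uniform(1, 10, (40, 40))
        a, b = NucleusImage(x, 0.05), NucleusImage(y, 0.05)
        c = NucleusImage(2.5 * x + 7.0, 0.05)
        assert pearson_colocalization(a, b) == pytest.approx(
            pearson_colocalization(b, a))
        assert pearson_colocalization(c, b) == pytest.approx(
            pearson_colocalization(a, b))

    def test_constant_channel_rejected(self, constant_image):
        rng = np.random.default_rng(0)
        a = NucleusImage(rng.uniform(1, 10, (60, 60)), 0.05)
        with pytest.raises(DegenerateInputError):
            pearson_colocalization(a, constant_image(5.0))


class TestClusters:
    def test_two_blocks_found(self):
        arr = np.zeros((40, 40))
        arr[5:9, 5:9] = 100.0
        arr[25:29, 25:29] = 100.0
        img = NucleusImage(arr, pixel_size=0.2)
        cs = segment_clusters(img, threshold=25.0, min_diameter=0.492)
        assert len(cs.areas_um2) == 2
        assert np.allclose(cs.pixel_counts, 16)

    def test_small_blob_removed(self):
        arr = np.zeros((40, 40))
        arr[10, 10] = 100.0  # one pixel: diameter ~0.23 um < 0.492
        img = NucleusImage(arr, pixel_size=0.2)
        cs = segment_clusters(img, threshold=25.0, min_diameter=0.492)
        assert len(cs.areas_um2) == 0

    def test_disc_areas_within_ten_percent(self):
        yy, xx = np.mgrid[0:120, 0:120]
        arr = np.zeros((120, 120))
        for cy, cx, r in ((30, 30, 5), (30, 90, 8), (90, 60, 12)):
            arr[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = 100.0
        img = NucleusImage(arr, pixel_size=0.1)
        cs = segment_clusters(img, threshold=25.0, min_diameter=0.492)
        got = np.sort(cs.areas_um2)
        want = np.sort([np.pi * (r * 0.1) ** 2 for r in (5, 8, 12)])
        assert np.all(np.abs(got - want) / want < 0.10)


class TestLineProfile:
    def test_constant_image_flat_at_one(self, constant_image):
        lp = line_profile(constant_image(9.0), (30, 5), (30, 55), width=3)
        assert np.allclose(lp.profiles, 1.0)

    def test_mirrored_image_reverses_profile(self):
        rng = np.random.default_rng(1)
        arr = rng.uniform(1, 10, (40, 60))
        img = NucleusImage(arr, 0.05)
        mirr = NucleusImage(arr[:, ::-1].copy(), 0.05)
        lp = line_profile(img, (20, 5), (20, 54), width=1)
        lpm = line_profile(mirr, (20, 59 - 5), (20, 59 - 54), width=1)
        assert np.allclose(lp.profiles, lpm.profiles, atol=1e-9)

    def test_two_channel_flank_peaks_at_planted_offsets(self):
        # a central blob in channel 1 flanked by two spots in channel 2
        yy, xx = np.mgrid[0:60, 0:100]
        ch1 = 5 + 200 * np.exp(-((yy - 30) ** 2 + (xx - 50) ** 2) / 50)
        ch2 = np.full((60, 100), 5.0)
        for cx in (35, 65):
            ch2 += 200 * np.exp(-((yy - 30) ** 2 + (xx - cx) ** 2) / 8)
        lp = line_profile([NucleusImage(ch1, 0.05), NucleusImage(ch2, 0.05)],
                          (30, 20), (30, 80), width=3)
        pos_px = lp.positions_um / 0.05
        prof2 = lp.profiles[1]
        from scipy.signal import find_peaks
        peaks, _ = find_peaks(prof2, height=0.5)
        assert len(peaks) == 2
        assert np.allclose(20 + pos_px[peaks], [35, 65], atol=1.0)

    def test_zero_length_segment_rejected(self, constant_image):
        with pytest.raises(ParameterError):
            line_profile(constant_image(), (10, 10), (10, 10))
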