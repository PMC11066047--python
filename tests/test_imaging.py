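"""Background subtraction, Otsu masks, Manders, profiles and ROI statistics."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from xlorg import imaging, synthetic
from xlorg.imaging import (
    ImageChannel,
    line_profile,
    manders,
    marker_region_intensity,
    membrane_cytosol_ratio,
    otsu_threshold,
    otsu_value,
    subtract_background,
)


def otsu_exhaustive_oracle(pixels, nbins=256):
    """Naive per-level search: for each candidate bin split recompute class
    weights and means from the histogram and maximize between-class variance."""
    pixels = np.asarray(pixels, dtype=float).ravel()
    counts, edges = np.histogram(pixels, bins=nbins, range=(pixels.min(), pixels.max()))
    centers = (edges[:-1] + edges[1:]) / 2.0
    best_value, best_threshold = -1.0, centers[0]
    for split in range(nbins):
        w0 = counts[: split + 1].sum()
        w1 = counts[split + 1 :].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[: split + 1] * centers[: split + 1]).sum() / w0
        mu1 = (counts[split + 1 :] * centers[split + 1 :]).sum() / w1
        variance = w0 * w1 * (mu0 - mu1) ** 2
        if variance > best_value:
            best_value, best_threshold = variance, centers[split]
    return best_threshold


class TestBackgroundSubtraction:
    def test_constant_image_maps_to_zero(self):
        channel = ImageChannel(np.full((40, 40), 37.0))
        out = subtract_background(channel, radius=10)
        assert np.allclose(out.pixels, 0.0, atol=1e-6)

    def test_radius_larger_than_image_errors(self):
        with pytest.raises(ValueError, match="radius"):
            subtract_background(ImageChannel(np.zeros((20, 20))), radius=30)

    def test_narrow_peak_preserved(self):
        image = np.full((60, 60), 20.0)
        peak = np.zeros_like(image)
        peak[30, 30] = 1.0
        peak = gaussian_filter(peak, 1.5)
        peak *= 150.0 / peak.max()
        channel = ImageChannel(image + peak)
        out = subtract_background(channel, radius=15)
        assert out.pixels.max() == pytest.approx(150.0, rel=0.05)

    def test_gradient_background_contrast_increases(self):
        rows = np.linspace(0, 80, 64)[:, None]
        gradient = np.broadcast_to(rows, (64, 64)).copy()
        punctum = np.zeros_like(gradient)
        punctum[32, 32] = 1.0
        punctum = gaussian_filter(punctum, 1.5)
        punctum *= 100.0 / punctum.max()
        image = gradient + punctum
        out = subtract_background(ImageChannel(image), radius=12).pixels
        # local background taken down-gradient of the punctum
        contrast_before = image[32, 32] - np.median(image[45:55, 25:40])
        contrast_after = out[32, 32] - np.median(out[45:55, 25:40])
        assert contrast_after > contrast_before


class TestOtsu:
    def test_bimodal_separates_exactly(self, rng):
        pixels = np.full(1000, 10.0)
        bright = rng.choice(1000, size=100, replace=False)
        pixels[bright] = 200.0
        image = pixels.reshape(25, 40)
        mask = otsu_threshold(ImageChannel(image))
        assert np.array_equal(mask, image == 200.0)

    def test_constant_image_errors(self):
        with pytest.raises(ValueError, match="constant"):
            otsu_value(np.full((5, 5), 3.0))

    def test_matches_exhaustive_oracle_on_random_images(self, rng):
        for _ in range(20):
            image = rng.uniform(0, 255, size=(32, 32))
            assert otsu_value(image) == pytest.approx(
                otsu_exhaustive_oracle(image), abs=1e-12
            )

    def test_matches_reference_library(self, rng):
        from skimage.filters import threshold_otsu

        for _ in range(10):
            image = rng.normal(100, 30, size=(48, 48)).clip(0)
            bin_width = (image.max() - image.min()) / 256
            assert abs(otsu_value(image) - threshold_otsu(image, nbins=256)) <= bin_width

    def test_inversion_complements_classes(self, rng):
        """Inverting intensities swaps foreground and background; with a
        continuous histogram the split bin itself may change side, so pixels
        within one bin width of the threshold are exempt."""
        pixels = np.full(1000, 10.0)
        pixels[rng.choice(1000, size=100, replace=False)] = 200.0
        image = pixels.reshape(25, 40)
        mask = image > otsu_value(image)
        inverted = image.max() - image
        assert np.array_equal(inverted > otsu_value(inverted), ~mask)

        image = rng.uniform(0, 1, size=(40, 40))
        threshold = otsu_value(image)
        mask = image > threshold
        inverted = image.max() - image
        mask_inverted = inverted > otsu_value(inverted)
        bin_width = (image.max() - image.min()) / 256
        disagreement = image[mask_inverted != ~mask]
        assert np.all(np.abs(disagreement - threshold) <= bin_width)


class TestManders:
    def test_identical_channels_give_one(self, rng):
        image = rng.uniform(1, 10, size=(20, 20))
        mask = image > 5
        result = manders(image, mask, image, mask)
        assert result.m1 == pytest.approx(1.0)
        assert result.m2 == pytest.approx(1.0)

    def test_disjoint_masks_give_zero(self, rng):
        image = rng.uniform(1, 10, size=(20, 20))
        mask_a = np.zeros((20, 20), bool)
        mask_b = np.zeros((20, 20), bool)
        mask_a[:10] = True
        mask_b[10:] = True
        result = manders(image, mask_a, image, mask_b)
        assert result.m1 == 0.0 and result.m2 == 0.0

    def test_empty_mask_leaves_coefficient_undefined(self, rng):
        image = rng.uniform(1, 10, size=(8, 8))
        empty = np.zeros((8, 8), bool)
        full = np.ones((8, 8), bool)
        result = manders(image, empty, image, full)
        assert result.m1 is None and result.m2 is not None

    def test_scale_invariance(self, rng):
        a = rng.uniform(0, 100, size=(30, 30))
        b = rng.uniform(0, 100, size=(30, 30))
        mask_a, mask_b = a > 50, b > 50
        r1 = manders(a, mask_a, b, mask_b)
        r2 = manders(a * 7.3, mask_a, b * 0.2, mask_b)
        assert r1.m1 == pytest.approx(r2.m1) and r1.m2 == pytest.approx(r2.m2)
        assert 0 <= r1.m1 <= 1 and 0 <= r1.m2 <= 1

    def test_planted_overlap_recovered(self):
        channel_a, channel_b, truth = synthetic.make_coloc_images(
            overlap_fraction=0.5, seed=3
        )
        mask_a = otsu_threshold(channel_a)
        mask_b = otsu_threshold(channel_b)
        result = manders(channel_a, mask_a, channel_b, mask_b)
        assert result.m1 == pytest.approx(truth["overlap_fraction"], abs=0.02)
        assert result.m2 == pytest.approx(truth["overlap_fraction"], abs=0.02)


class TestLineProfile:
    def test_constant_image_gives_flat_zero_profile(self):
        channels = {"c": ImageChannel(np.full((20, 20), 5.0))}
        profile = line_profile(channels, [(5, 2), (5, 17)], step=1.0)
        assert np.allclose(profile.intensities["c"], 0.0)

    def test_linear_ramp_profile_matches_pixel_oracle(self):
        ramp = np.tile(np.arange(32, dtype=float), (32, 1))
        profile = line_profile({"c": ImageChannel(ramp)}, [(10, 0), (10, 31)], step=1.0)
        expected = np.arange(32) / 31.0
        assert np.allclose(profile.intensities["c"], expected, atol=1e-12)
        assert profile.intensities["c"].max() == 1.0

    def test_ring_crossed_by_diameter_has_two_peaks(self):
        channel, rois, _ = synthetic.make_membrane_image(
            size=128, ring_radius=40, noise_sd=1e-6, seed=4
        )
        center = 64.0
        profile = line_profile(
            {"m": channel}, [(center, 4), (center, 123)], step=1.0
        )
        values = profile.intensities["m"]
        positions = profile.positions
        left_peak = positions[np.argmax(values[: len(values) // 2])]
        right_half = len(values) // 2 + np.argmax(values[len(values) // 2 :])
        right_peak = positions[right_half]
        assert left_peak == pytest.approx((center - 4) - 40, abs=1.0)
        assert right_peak == pytest.approx((center - 4) + 40, abs=1.0)

    def test_zero_length_polyline_errors(self):
        with pytest.raises(ValueError, match="zero-length"):
            line_profile({"c": ImageChannel(np.ones((5, 5)))}, [(2, 2), (2, 2)])


class TestMembraneCytosolRatio:
    def test_uniform_image_ratio_one(self):
        channel = ImageChannel(np.full((64, 64), 80.0))
        ratio = membrane_cytosol_ratio(
            channel,
            [(32, 10), (32, 50)],
            [((10, 10), 4), ((50, 10), 4), ((50, 50), 4)],
        )
        assert ratio == pytest.approx(1.0)

    def test_arithmetic(self):
        image = np.full((64, 64), 50.0)
        image[32, :] = 200.0
        ratio = membrane_cytosol_ratio(
            ImageChannel(image),
            [(32, 5), (32, 58)],
            [((10, 10), 3), ((10, 50), 3), ((50, 30), 3)],
        )
        assert ratio == pytest.approx(4.0)

    def test_wrong_disk_count_errors(self):
        channel = ImageChannel(np.ones((32, 32)))
        with pytest.raises(ValueError, match="3 cytosol disks"):
            membrane_cytosol_ratio(channel, [(5, 5), (5, 20)], [((10, 10), 2)])

    def test_scale_invariance(self):
        channel, rois, _ = synthetic.make_membrane_image(seed=6)
        disks = [(d["center"], d["radius"]) for d in rois["cytosol_disks"]]
        r1 = membrane_cytosol_ratio(channel, rois["membrane_polyline"], disks)
        scaled = ImageChannel(channel.pixels * 11.0)
        r2 = membrane_cytosol_ratio(scaled, rois["membrane_polyline"], disks)
        assert r1 == pytest.approx(r2)

    def test_planted_enrichment_recovered(self):
        channel, rois, truth = synthetic.make_membrane_image(
            enrichment_ratio=4.0, noise_sd=0.5, seed=10
        )
        disks = [(d["center"], d["radius"]) for d in rois["cytosol_disks"]]
        ratio = membrane_cytosol_ratio(channel, rois["membrane_polyline"], disks)
        assert 3.6 <= ratio <= 4.4


class TestMarkerRegions:
    @staticmethod
    def _blob(image, center, radius, value):
        rows, cols = np.ogrid[: image.shape[0], : image.shape[1]]
        image[(rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius**2] = value

    def test_uniform_signal_inside_single_blob(self):
        marker = np.zeros((40, 40))
        self._blob(marker, (20, 20), 5, 100.0)
        signal = np.full((40, 40), 100.0)
        regions = marker_region_intensity(
            ImageChannel(signal), ImageChannel(marker)
        )
        assert len(regions) == 1
        assert regions[0]["mean_intensity"] == pytest.approx(100.0)

    def test_two_blobs_with_planted_means(self):
        marker = np.zeros((60, 60))
        self._blob(marker, (15, 15), 5, 100.0)
        self._blob(marker, (45, 45), 5, 100.0)
        signal = np.zeros((60, 60))
        self._blob(signal, (15, 15), 8, 50.0)
        self._blob(signal, (45, 45), 8, 150.0)
        regions = marker_region_intensity(ImageChannel(signal), ImageChannel(marker))
        means = sorted(r["mean_intensity"] for r in regions)
        assert means == pytest.approx([50.0, 150.0])

    def test_small_blob_excluded(self):
        marker = np.zeros((40, 40))
        self._blob(marker, (10, 10), 5, 100.0)
        marker[30, 30] = 100.0  # single-pixel speck, below min_size
        regions = marker_region_intensity(
            ImageChannel(np.ones((40, 40))), ImageChannel(marker), min_size=5
        )
        assert len(regions) == 1
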