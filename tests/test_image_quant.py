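"""Image pipeline: bandpass physics, thresholding, morphology, %SAC."""

import numpy as np
import pytest

from thromboprofile.image_quant import (BandpassSpec, BinaryMask, ImageFrame,
                                        MorphologySpec, average_run, compute_sac,
                                        fft_bandpass, gray_morphology_chain,
                                        quantify_frame, threshold_mask)
from thromboprofile.image_quant import _bandpass_gain
from thromboprofile.synthetic import (ImageSimConfig,
                                      benchmark_fluorescence_config,
                                      gen_thrombus_image)


def direct_dft_filter(img, spec):
    """Oracle: apply the bandpass gain with explicit DFT matrices.

    Builds the forward/inverse DFT as dense matrix products (O(N^3), tiny
    images only) so the check does not share numpy's FFT code path.
    """
    h, w = img.shape
    jh = np.arange(h)
    jw = np.arange(w)
    Fh = np.exp(-2j * np.pi * np.outer(jh, jh) / h)
    Fw = np.exp(-2j * np.pi * np.outer(jw, jw) / w)
    gain = _bandpass_gain(img.shape, spec)
    mean = img.mean()
    spectrum = Fh @ (img - mean) @ Fw
    back = (Fh.conj() @ (gain * spectrum) @ Fw.conj()).real / (h * w)
    return np.clip(back + mean, 0, 255)


def brute_force_dilate(mask, footprint):
    """Set dilation straight from the definition (loop over offsets)."""
    h, w = mask.shape
    r = footprint.shape[0] // 2
    out = np.zeros_like(mask)
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            if not footprint[dy + r, dx + r]:
                continue
            shifted = np.zeros_like(mask)
            ys = slice(max(0, dy), min(h, h + dy))
            yd = slice(max(0, -dy), min(h, h - dy))
            xs = slice(max(0, dx), min(w, w + dx))
            xd = slice(max(0, -dx), min(w, w - dx))
            shifted[yd, xd] = mask[ys, xs]
            out |= shifted
    return out


def brute_force_close(mask, footprint):
    """Closing = erosion of the dilation, with background outside the frame."""
    pad = footprint.shape[0]
    padded = np.pad(mask, pad)
    dilated = brute_force_dilate(padded, footprint)
    # erosion as complement-dilate-complement with the reflected footprint
    eroded = ~brute_force_dilate(~dilated, footprint[::-1, ::-1])
    return eroded[pad:-pad, pad:-pad]


class TestBandpass:
    def test_constant_frame_passes_unchanged(self):
        frame = ImageFrame(np.full((64, 64), 128.0), channel="GFP")
        out = fft_bandpass(frame, BandpassSpec(40))
        assert np.all(np.abs(out.pixels - 128.0) <= 1.0)

    def test_large_sinusoid_suppressed(self):
        # 500-px-period illumination stripe vs a 100-px cutoff; the grid
        # holds whole periods so leakage does not contaminate the residual
        x = np.arange(1000)
        img = np.tile(100 + 50 * np.sin(2 * np.pi * x / 500), (128, 1))
        out = fft_bandpass(ImageFrame(img, channel="GFP"), BandpassSpec(100))
        resid = out.pixels - out.pixels.mean()
        assert (resid.max() - resid.min()) / 2 <= 0.10 * 50

    def test_small_disk_contrast_retained(self):
        img = np.full((256, 256), 60.0)
        yy, xx = np.ogrid[:256, :256]
        img[(yy - 128) ** 2 + (xx - 128) ** 2 <= 100] = 140  # 20-px disk
        out = fft_bandpass(ImageFrame(img, channel="GFP"), BandpassSpec(100))
        contrast = out.pixels[128, 128] - np.median(out.pixels)
        assert contrast >= 0.60 * 80

    def test_matches_direct_dft_oracle(self, rng):
        img = rng.uniform(0, 255, (48, 40))
        spec = BandpassSpec(20, 3)
        ours = fft_bandpass(ImageFrame(img, channel="RFP"), spec).pixels
        oracle = direct_dft_filter(img, spec)
        assert np.allclose(ours, oracle, atol=1e-8)

    def test_translation_equivariance(self, rng):
        img = rng.uniform(0, 255, (64, 96))
        spec = BandpassSpec(30)
        f = lambda a: fft_bandpass(ImageFrame(a, channel="GFP"), spec).pixels
        shifted_out = f(np.roll(img, (5, 7), axis=(0, 1)))
        assert np.allclose(np.roll(f(img), (5, 7), axis=(0, 1)), shifted_out,
                           atol=1e-9)

    def test_cutoff_larger_than_frame_rejected(self):
        frame = ImageFrame(np.zeros((50, 200)), channel="GFP")
        with pytest.raises(ValueError, match="shorter side"):
            fft_bandpass(frame, BandpassSpec(60))

    def test_small_cutoff_must_be_below_large(self):
        with pytest.raises(ValueError):
            BandpassSpec(60, 80)


class TestThreshold:
    def test_binary_frame_recovers_bright_set(self, rng):
        img = np.where(rng.random((40, 40)) < 0.3, 255.0, 0.0)
        for offset in (0.0, -0.4, 100.0):
            mask = threshold_mask(ImageFrame(img, channel="GFP"),
                                  manual_offset=offset)
            assert np.array_equal(mask.pixels, img == 255)

    def test_offset_monotonicity(self, rng):
        img = rng.uniform(0, 255, (64, 64))
        frame = ImageFrame(img, channel="GFP")
        counts = [threshold_mask(frame, manual_offset=off).pixels.sum()
                  for off in (-50, -10, 0, 10, 50)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_bimodal_frame_high_jaccard(self, rng):
        truth = rng.random((128, 128)) < 0.3
        img = np.clip(np.where(truth, 200.0, 40.0) + rng.normal(0, 10, truth.shape),
                      0, 255)
        mask = threshold_mask(ImageFrame(img, channel="GFP"))
        inter = np.logical_and(mask.pixels, truth).sum()
        union = np.logical_or(mask.pixels, truth).sum()
        assert inter / union >= 0.95

    def test_flat_frame_degenerates_to_empty_mask(self):
        frame = ImageFrame(np.full((32, 32), 77.0), channel="GFP")
        with pytest.warns(UserWarning, match="flat frame"):
            mask = threshold_mask(frame)
        assert not mask.pixels.any()
        assert mask.provenance["degenerate"]

    def test_brightfield_inversion_detects_dark_objects(self):
        img = np.full((64, 64), 200.0)
        img[20:40, 20:40] = 50.0
        mask = threshold_mask(ImageFrame(img, channel="brightfield"))
        assert mask.pixels[30, 30] and not mask.pixels[5, 5]

    def test_threshold_recorded_in_provenance(self, rng):
        img = rng.uniform(0, 255, (32, 32))
        mask = threshold_mask(ImageFrame(img, channel="GFP"), manual_offset=5)
        assert mask.provenance["threshold"] is not None
        assert mask.provenance["manual_offset"] == 5


class TestMorphology:
    def test_empty_mask_stays_empty(self):
        mask = BinaryMask(np.zeros((64, 64), dtype=bool))
        out = gray_morphology_chain(mask)
        assert not out.pixels.any()

    def test_chain_is_extensive(self, rng):
        for _ in range(5):
            mask = BinaryMask(rng.random((64, 64)) < 0.2)
            out = gray_morphology_chain(mask)
            assert np.all(out.pixels[mask.pixels])
            assert compute_sac(out).value >= compute_sac(mask).value

    def test_closings_are_idempotent(self, rng):
        from thromboprofile.image_quant import _pad_close
        from skimage.morphology import diamond, disk
        mask = rng.random((64, 64)) < 0.25
        for fp in (diamond(5), disk(3)):
            once = _pad_close(mask, fp)
            assert np.array_equal(_pad_close(once, fp), once)

    def test_stripe_gap_filled_matches_brute_force(self):
        # two foreground bands separated by a 1-px stripe gap
        mask = np.zeros((32, 32), dtype=bool)
        mask[8:24, 10:15] = True
        mask[8:24, 16:21] = True
        from skimage.morphology import diamond
        closed = brute_force_close(mask, diamond(3))
        assert closed[10, 15]  # the gap column is bridged
        from thromboprofile.image_quant import _pad_close
        assert np.array_equal(_pad_close(mask, diamond(3)), closed)

    def test_oversized_structuring_element_rejected(self):
        mask = BinaryMask(np.zeros((8, 8), dtype=bool))
        with pytest.raises(ValueError, match="larger than image"):
            gray_morphology_chain(mask, MorphologySpec(10, 3, 1))

    def test_radius_ordering_enforced(self):
        with pytest.raises(ValueError):
            MorphologySpec(3, 5, 1)


class TestSacAndAveraging:
    def test_all_false_and_all_true(self):
        assert compute_sac(BinaryMask(np.zeros((10, 10), dtype=bool))).value == 0.0
        assert compute_sac(BinaryMask(np.ones((10, 10), dtype=bool))).value == 100.0

    def test_matches_pixel_count_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            m = rng.random((37, 53)) < rng.random()
            expected = 100.0 * sum(1 for v in m.ravel() if v) / m.size
            assert compute_sac(BinaryMask(m)).value == expected

    @pytest.mark.parametrize("values,expected", [
        ([10.0], 10.0),
        ([0.0, 100.0], 50.0),
        ([12.5, 15.0, 17.5], 15.0),
    ])
    def test_average_run(self, values, expected):
        assert average_run(values) == pytest.approx(expected)

    def test_average_run_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            average_run([])

    def test_average_run_mixed_channels_rejected(self):
        from thromboprofile.image_quant import SacValue
        with pytest.raises(ValueError, match="mixed channels"):
            average_run([SacValue(10, "GFP"), SacValue(20, "RFP")])


class TestQuantifyFrame:
    def test_blank_fluorescence_frame_is_zero(self):
        frame = ImageFrame(np.full((128, 128), 30.0), channel="GFP")
        with pytest.warns(UserWarning):
            sac = quantify_frame(frame, bandpass=BandpassSpec(60))
        assert sac.value == 0.0

    def test_fluorescence_recovery_within_tolerance(self):
        cfg = benchmark_fluorescence_config(target_coverage=25.0, seed=42)
        frame, truth = gen_thrombus_image(cfg)
        sac = quantify_frame(frame, bandpass=BandpassSpec(100))
        assert abs(sac.value - truth.coverage_percent) <= 5.0
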