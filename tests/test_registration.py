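"""Cross-correlation registration: oracle agreement and shift recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hifish import (
    GrayImage,
    apply_translation,
    cross_correlate,
    cross_correlate_direct,
    estimate_translation,
    register_acquisition,
    SimulationConfig,
    simulate_field,
)
from conftest import gray


class TestCrossCorrelate:
    def test_autocorrelation_peaks_at_zero_lag(self, rng):
        img = gray(rng.random((32, 32)) + 1.0)
        surf = cross_correlate(img, img, max_shift=5)
        iy, ix = np.unravel_index(np.argmax(surf.values), surf.values.shape)
        assert (iy, ix) == (5, 5)  # Cauchy-Schwarz: peak at (0, 0)

    def test_zero_image_gives_zero_surface(self, rng):
        zeros = gray(np.zeros((20, 20)))
        other = gray(rng.random((20, 20)))
        surf = cross_correlate(zeros, other, max_shift=4)
        assert np.allclose(surf.values, 0.0, atol=1e-12)

    def test_fast_equals_direct_sum_oracle(self, rng):
        a = gray(rng.random((16, 16)))
        b = gray(rng.random((16, 16)))
        fast = cross_correlate(a, b, max_shift=3).values
        direct = cross_correlate_direct(a, b, max_shift=3).values
        assert np.allclose(fast, direct, rtol=1e-9, atol=1e-12)

    def test_dimension_mismatch_names_both_shapes(self):
        with pytest.raises(ValueError, match=r"\(8, 8\).*\(9, 9\)"):
            cross_correlate(gray(np.ones((8, 8))), gray(np.ones((9, 9))), 2)

    def test_max_shift_too_large_rejected(self):
        with pytest.raises(ValueError, match="max_shift"):
            cross_correlate(gray(np.ones((8, 8))), gray(np.ones((8, 8))), 8)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(6, 24), st.integers(1, 4))
    def test_fast_direct_agreement_property(self, seed, size, window):
        r = np.random.default_rng(seed)
        a = gray(r.random((size, size)) * 100)
        b = gray(r.random((size, size)) * 100)
        fast = cross_correlate(a, b, window).values
        direct = cross_correlate_direct(a, b, window).values
        scale = max(np.abs(direct).max(), 1.0)
        assert np.abs(fast - direct).max() / scale < 1e-9


class TestEstimateTranslation:
    def test_identical_images_give_zero_shift(self, textured_nuclei_image):
        v = estimate_translation(textured_nuclei_image, textured_nuclei_image, 10)
        assert (v.dx, v.dy) == (0, 0)

    def test_known_shift_with_zero_fill(self, textured_nuclei_image):
        shifted = apply_translation(textured_nuclei_image, (5, -3))
        v = estimate_translation(textured_nuclei_image, shifted, 10)
        assert (v.dx, v.dy) == (5, -3)
        assert v.confidence >= 1.0

    def test_simulator_injected_shift_with_noise(self):
        cfg = SimulationConfig(seed=21, image_size=256, n_nuclei=2,
                               nucleus_radius_range=(28, 34), pixel_size=0.216,
                               sequential_shift=(-7, 2))
        (dna_acq, rna_acq), _ = simulate_field(cfg, mode="sequential")
        v = estimate_translation(dna_acq["DAPI"], rna_acq["DAPI"], 12)
        assert (v.dx, v.dy) == (-7, 2)

    def test_constant_image_rejected(self):
        flat = gray(np.full((32, 32), 7.0))
        with pytest.raises(ValueError, match="no registration content"):
            estimate_translation(flat, flat, 5)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(-5, 5), st.integers(-5, 5))
    def test_roundtrip_recovery_property(self, dx, dy):
        # estimate(a, apply(a, v)) == v for |v| <= max_shift/2
        cfg = SimulationConfig(seed=3, image_size=200, n_nuclei=2,
                               nucleus_radius_range=(24, 28), pixel_size=0.216)
        acqs, _ = simulate_field(cfg)
        a = acqs[0]["DAPI"]
        v = estimate_translation(a, apply_translation(a, (dx, dy)), 10)
        assert (v.dx, v.dy) == (dx, dy)


class TestApplyTranslation:
    def test_zero_shift_is_identity(self, textured_nuclei_image):
        out = apply_translation(textured_nuclei_image, (0, 0))
        assert np.array_equal(out.pixels, textured_nuclei_image.pixels)

    def test_single_bright_pixel_moves_as_mapped(self):
        img = np.zeros((30, 30))
        img[10, 10] = 5.0  # (y, x)
        out = apply_translation(gray(img), (2, 4))
        assert out.pixels[14, 12] == 5.0
        assert out.pixels.sum() == 5.0

    def test_shift_and_unshift_restores_interior(self, textured_nuclei_image):
        fwd = apply_translation(textured_nuclei_image, (5, -3))
        back = apply_translation(fwd, (-5, 3))
        orig = textured_nuclei_image.pixels
        assert np.array_equal(back.pixels[5:, :-5], orig[5:, :-5])
        # exposed border band is zero
        assert np.all(back.pixels[:3, :] == 0) or np.all(back.pixels[-3:, :] == 0)

    def test_intensity_conserved_up_to_border(self, textured_nuclei_image, rng):
        total = textured_nuclei_image.pixels.sum()
        for dx, dy in [(0, 0), (3, 7), (-9, 4), (15, -15)]:
            out = apply_translation(textured_nuclei_image, (dx, dy))
            assert out.pixels.sum() <= total + 1e-6
            if (dx, dy) == (0, 0):
                assert out.pixels.sum() == pytest.approx(total)


class TestRegisterAcquisition:
    def test_sequential_field_rna_lands_on_truth(self):
        cfg = SimulationConfig(seed=5, image_size=300, n_nuclei=2,
                               nucleus_radius_range=(30, 36), pixel_size=0.216,
                               p_active=1.0, sequential_shift=(4, 4))
        (dna_acq, rna_acq), gt = simulate_field(cfg, mode="sequential")
        merged = register_acquisition(dna_acq, rna_acq, max_shift=10)
        assert merged.metadata["registration"]["dx"] == 4
        assert merged.metadata["registration"]["dy"] == 4
        rna = merged["RNA"].pixels
        for a in gt.alleles:
            if a.active:
                # brightest pixel near the ground-truth RNA position
                win = rna[a.rna_y - 2 : a.rna_y + 3, a.rna_x - 2 : a.rna_x + 3]
                assert win.max() > cfg.background_level + cfg.spot_amplitude / 3

    def test_missing_dapi_is_error(self, small_field):
        (acq,), _ = small_field
        from hifish import Acquisition

        no_dapi = Acquisition({"RNA": acq["RNA"]}, well=acq.well, field=acq.field)
        with pytest.raises(ValueError, match="DAPI"):
            register_acquisition(acq, no_dapi, 5)
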