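"""Reconstruction algorithms: normalization, GHR/GS/GA/IGA behavior,
Gaussian filter pair, and wavelength rescaling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.ndimage import gaussian_filter

from gaborholo.metrics import background_std, rms_error
from gaborholo.optics import GridSpec
from gaborholo.reconstruct import (
    ReconstructionSettings,
    ga,
    gaussian_highpass,
    gaussian_lowpass,
    ghr,
    gs,
    iga,
    normalize_hologram,
    rescale_phase_wavelength,
)
from gaborholo.simulate import (
    Hologram,
    NoiseSpec,
    make_amplitude_object,
    make_text_phase_object,
    record_hologram,
    record_stack,
)


def _hologram(intensity, grid, z=2e-3, lam=500e-9):
    return Hologram(intensity, z, lam, grid)


class TestNormalize:
    def test_uniform_maps_to_ones(self, grid64):
        h = _hologram(np.full(grid64.shape, 3.7), grid64)
        assert np.allclose(normalize_hologram(h, "sqrt"), 1.0)
        assert np.allclose(normalize_hologram(h, "identity"), 1.0)

    def test_sqrt_mode_unit_power(self, grid64, rng):
        h = _hologram(rng.random(grid64.shape) + 0.1, grid64)
        a = normalize_hologram(h, "sqrt")
        assert np.mean(a**2) == pytest.approx(1.0, abs=1e-12)

    def test_two_valued_closed_form(self):
        grid = GridSpec(2, 2, 2e-6)
        h = _hologram(np.array([[1.0, 4.0], [4.0, 1.0]]), grid)
        a = normalize_hologram(h, "sqrt")
        np.testing.assert_allclose(np.unique(a), [np.sqrt(0.4), np.sqrt(1.6)])

    def test_zero_hologram_rejected(self, grid64):
        h = _hologram(np.zeros(grid64.shape), grid64)
        with pytest.raises(ValueError):
            normalize_hologram(h)


class TestGHR:
    def test_empty_object_reconstructs_flat_phase(self, grid64):
        obj = make_text_phase_object("A", grid64, 0.0, 0.0)
        h = record_hologram(obj, 2e-3)
        out = ghr(h)
        assert np.std(out.phase) < 1e-6

    def test_twin_image_leaves_residual_error(self, grid128):
        obj = make_amplitude_object("IGA", grid128)
        h = record_hologram(obj, 2e-3)
        err = rms_error(ghr(h).amplitude, obj.amplitude)
        assert err > 1e-3

    def test_deterministic(self, grid64):
        obj = make_text_phase_object("A", grid64)
        h = record_hologram(obj, 2e-3)
        assert np.array_equal(ghr(h).values, ghr(h).values)


class TestGS:
    def test_single_frame_one_iteration_equals_ghr(self, grid64):
        obj = make_text_phase_object("A", grid64)
        stack = record_stack(obj, distances=(2e-3,))
        s = ReconstructionSettings(method="gs", iterations=1)
        u_gs = gs(stack, s)
        u_ghr = ghr(stack.frames[0], s)
        assert np.max(np.abs(u_gs.values - u_ghr.values)) < 1e-10

    def test_noise_free_multiframe_beats_ghr(self, grid128):
        obj = make_amplitude_object("IGA", grid128)
        stack = record_stack(obj, distances=(2e-3, 3e-3))
        s = ReconstructionSettings(method="gs", iterations=40)
        e_gs = rms_error(gs(stack, s).amplitude, obj.amplitude)
        e_ghr = rms_error(ghr(stack.frames[0], s).amplitude, obj.amplitude)
        assert e_gs < e_ghr

    def test_callback_sees_every_cycle(self, grid64):
        obj = make_text_phase_object("A", grid64)
        stack = record_stack(obj, distances=(2e-3, 3e-3))
        seen = []
        gs(stack, ReconstructionSettings(method="gs", iterations=5),
           callback=lambda t, f: seen.append(t))
        assert seen == [0, 1, 2, 3, 4]

    def test_wavelength_mode_beats_single_frame(self, grid128):
        obj = make_text_phase_object("IGA", grid128)
        stack = record_stack(obj, wavelengths=(450e-9, 532e-9, 635e-9), distance=3e-3)
        s = ReconstructionSettings(method="gs", iterations=20)
        u_gs = rescale_phase_wavelength(gs(stack, s), 500e-9)
        u_ghr = rescale_phase_wavelength(ghr(stack.frames[0], s), 500e-9)
        e_gs = rms_error(u_gs.phase, obj.phase, remove_piston=True)
        e_ghr = rms_error(u_ghr.phase, obj.phase, remove_piston=True)
        assert e_gs < e_ghr


class TestGA:
    def test_single_frame_equals_ghr(self, grid64):
        obj = make_text_phase_object("A", grid64)
        h = record_hologram(obj, 2e-3)
        assert np.max(np.abs(ga([h]).values - ghr(h).values)) < 1e-12

    def test_identical_frames_average_to_ghr(self, grid64):
        obj = make_text_phase_object("A", grid64)
        h = record_hologram(obj, 2e-3)
        assert np.max(np.abs(ga([h] * 4).values - ghr(h).values)) < 1e-12

    def test_independent_noise_averages_down(self, grid128):
        obj = make_amplitude_object("A", grid128, 0.9, 1.0)
        frames = [
            record_hologram(obj, 3e-3, noise=NoiseSpec("poisson", 0.2, 100 + k))
            for k in range(4)
        ]
        roi = (2, 25, 2, 25)
        s1 = background_std(ga(frames[:1]).phase, roi)
        s4 = background_std(ga(frames).phase, roi)
        assert s4 < 0.75 * s1


class TestGaussianFilters:
    @given(sigma=st.floats(min_value=0.3, max_value=8.0))
    def test_complementary_pair_is_exact(self, sigma):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((48, 48))
        recon = gaussian_lowpass(x, sigma) + gaussian_highpass(x, sigma)
        assert np.max(np.abs(recon - x)) < 1e-14

    def test_constant_image_preserved_and_nulled(self):
        c = np.full((32, 32), 2.5)
        assert np.max(np.abs(gaussian_lowpass(c, 2.0) - c)) < 1e-12
        assert np.max(np.abs(gaussian_highpass(c, 2.0))) < 1e-12

    def test_tiny_sigma_is_identity(self, rng):
        x = rng.standard_normal((32, 32))
        assert np.max(np.abs(gaussian_lowpass(x, 1e-6) - x)) < 1e-9

    def test_highpass_has_zero_mean(self, rng):
        x = rng.random((40, 40))
        assert abs(np.mean(gaussian_highpass(x, 2.0))) < 1e-12

    def test_matches_spatial_gaussian_convolution(self, rng):
        # independent route: truncated spatial kernel with periodic wrap
        x = rng.standard_normal((64, 64))
        ours = gaussian_lowpass(x, 2.0)
        ref = gaussian_filter(x, sigma=2.0, mode="wrap", truncate=8.0)
        assert np.max(np.abs(ours - ref)) < 1e-6

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_lowpass(np.ones((8, 8)), 0.0)


class TestIGA:
    def test_sigma_to_zero_limit_recovers_gs(self, grid128):
        obj = make_text_phase_object("IGA", grid128)
        stack = record_stack(obj, distances=(2e-3, 3e-3, 4e-3))
        u_gs = gs(stack, ReconstructionSettings(method="gs", iterations=10))
        u_iga = iga(stack, ReconstructionSettings(method="iga", iterations=10, sigma=1e-6))
        rms = np.sqrt(np.mean(np.abs(u_iga.values - u_gs.values) ** 2))
        assert rms < 1e-6

    def test_noise_free_accuracy_between_gs_and_ga(self, grid128):
        obj = make_text_phase_object("IGA", grid128)
        stack = record_stack(obj, distances=(2e-3, 3e-3, 4e-3))
        kw = dict(iterations=20, sigma=2.0)
        e = {
            m: rms_error(
                fn(stack, ReconstructionSettings(method=m, **kw)).phase,
                obj.phase,
                remove_piston=True,
            )
            for m, fn in [("gs", gs), ("ga", ga), ("iga", iga)]
        }
        assert e["iga"] <= 1.2 * e["gs"]
        assert e["iga"] < e["ga"]

    def test_noisy_background_matches_ga_not_gs(self, grid128):
        obj = make_text_phase_object("IGA", grid128)
        stack = record_stack(
            obj, distances=(2e-3, 3e-3, 4e-3), noise=NoiseSpec("poisson", 0.2, 11)
        )
        kw = dict(iterations=20, sigma=2.0)
        roi = (2, 30, 2, 30)
        s = {
            m: background_std(fn(stack, ReconstructionSettings(method=m, **kw)).phase, roi)
            for m, fn in [("gs", gs), ("ga", ga), ("iga", iga)]
        }
        assert s["iga"] <= 1.2 * s["ga"]
        assert s["iga"] < s["gs"]

    def test_requires_multiple_frames(self, grid64):
        obj = make_text_phase_object("A", grid64)
        stack = record_stack(obj, distances=(2e-3,))
        with pytest.raises(ValueError):
            iga(stack)

    def test_deterministic(self, grid64):
        obj = make_text_phase_object("A", grid64)
        stack = record_stack(obj, distances=(2e-3, 3e-3))
        s = ReconstructionSettings(method="iga", iterations=3)
        assert np.array_equal(iga(stack, s).values, iga(stack, s).values)


class TestRescalePhase:
    def test_identity_at_same_wavelength(self, grid64, rng):
        from conftest import random_bandlimited_field

        u = random_bandlimited_field(grid64, 450e-9, rng)
        out = rescale_phase_wavelength(u, 450e-9)
        assert np.array_equal(out.values, u.values)

    def test_involution_without_wrap(self, grid64, rng):
        from gaborholo.optics import ComplexField

        phi = 0.5 * np.tanh(rng.standard_normal(grid64.shape))
        u = ComplexField(np.exp(1j * phi), grid64, 450e-9)
        back = rescale_phase_wavelength(rescale_phase_wavelength(u, 635e-9), 450e-9)
        assert np.max(np.abs(back.values - u.values)) < 1e-12

    def test_closed_form_scaling(self, grid64):
        from gaborholo.optics import ComplexField

        u = ComplexField(np.full(grid64.shape, np.exp(1j * 0.1)), grid64, 450e-9)
        out = rescale_phase_wavelength(u, 635e-9)
        assert out.phase[0, 0] == pytest.approx(0.1 * 450 / 635, rel=1e-12)
        assert out.wavelength == 635e-9

    def test_invalid_target_rejected(self, grid64):
        from gaborholo.optics import ComplexField

        u = ComplexField(np.ones(grid64.shape, complex), grid64, 450e-9)
        with pytest.raises(ValueError):
            rescale_phase_wavelength(u, 0.0)
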