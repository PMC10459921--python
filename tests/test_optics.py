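import numpy as np
import pytest

from fpmdetect.optics import (
    AcquisitionStack,
    CoherentTransferFunction,
    ComplexField,
    LEDArray,
    NoiseSpec,
    WaveVector,
    apply_ctf,
    capture_intensity,
    compute_wave_vector,
    modulate_sample,
    simulate_stack,
)


def uniform_field(side=64, pitch=0.4, value=1.0):
    return ComplexField(np.full((side, side), value, dtype=complex), pitch)


class TestComputeWaveVector:
    def test_center_led_is_on_axis(self):
        array = LEDArray(rows=13, cols=13)
        k = compute_wave_vector(array, 6, 6, "green")
        assert k.kx == 0.0 and k.ky == 0.0
        assert k.led_index == 1

    def test_mirror_symmetric_leds(self):
        array = LEDArray(rows=13, cols=13)
        k1 = compute_wave_vector(array, 2, 3, "red")
        k2 = compute_wave_vector(array, 10, 9, "red")
        assert k1.kx == pytest.approx(-k2.kx)
        assert k1.ky == pytest.approx(-k2.ky)
        assert k1.magnitude == pytest.approx(k2.magnitude)

    def test_hand_trigonometry(self):
        # offset 50 mm, distance 86.602 mm → sin 30° = 0.5 → k = 1.0 cyc/µm
        array = LEDArray(
            rows=1, cols=3, pitch=50.0, distance_to_sample=86.602,
            wavelengths={"green": 0.5},
        )
        k = compute_wave_vector(array, 0, 2, "green")
        assert k.kx == pytest.approx(1.0, abs=1e-4)
        assert k.ky == 0.0

    def test_magnitude_below_inverse_wavelength(self):
        array = LEDArray(rows=13, cols=13)
        for (r, c) in [(0, 0), (12, 12), (0, 12)]:
            k = compute_wave_vector(array, r, c, "blue")
            assert k.magnitude <= 1 / 0.470

    def test_out_of_range(self):
        array = LEDArray(rows=3, cols=3)
        with pytest.raises(IndexError):
            compute_wave_vector(array, 3, 0, "red")


class TestModulateSample:
    def test_zero_k_identity(self):
        f = uniform_field()
        k = WaveVector(0.0, 0.0, 1, "green")
        np.testing.assert_array_equal(modulate_sample(f, k).values, f.values)

    def test_magnitude_preserved(self):
        rng = np.random.default_rng(0)
        f = ComplexField(rng.normal(size=(32, 32)) + 1j * rng.normal(size=(32, 32)), 0.5)
        k = WaveVector(0.31, -0.17, 5, "green")
        out = modulate_sample(f, k)
        np.testing.assert_allclose(np.abs(out.values), np.abs(f.values), rtol=1e-12)

    def test_spectrum_shift_theorem(self):
        rng = np.random.default_rng(1)
        side, pitch = 64, 0.5
        f = ComplexField(rng.normal(size=(side, side)) + 0j, pitch)
        df = 1.0 / (side * pitch)
        bins = (5, -3)
        k = WaveVector(bins[0] * df, bins[1] * df, 2, "green")
        out = modulate_sample(f, k)
        spec_in = np.fft.fftshift(np.fft.fft2(f.values))
        spec_out = np.fft.fftshift(np.fft.fft2(out.values))
        rolled = np.roll(spec_in, shift=(bins[1], bins[0]), axis=(0, 1))
        assert np.abs(spec_out - rolled).max() / np.abs(spec_in).max() < 1e-8


class TestApplyCtf:
    def test_all_pass(self):
        ctf = CoherentTransferFunction(na=0.9, wavelength=0.5, grid_side=32, pixel_pitch_highres=1.0)
        rng = np.random.default_rng(2)
        spec = rng.normal(size=(32, 32)) + 0j
        np.testing.assert_array_equal(apply_ctf(spec, ctf), spec)

    def test_stopband_delta_zeroed(self):
        ctf = CoherentTransferFunction(na=0.1, wavelength=0.5, grid_side=64, pixel_pitch_highres=0.4)
        spec = np.zeros((64, 64), complex)
        spec[0, 0] = 1.0  # corner = far outside the pupil disk
        assert np.all(apply_ctf(spec, ctf) == 0)

    def test_passband_energy_fraction(self):
        ctf = CoherentTransferFunction(na=0.25, wavelength=0.5, grid_side=128, pixel_pitch_highres=0.4)
        flat = np.ones((128, 128), complex)
        frac = np.abs(apply_ctf(flat, ctf)).sum() / flat.size
        # count lattice points inside the disk independently
        df = 1.0 / (128 * 0.4)
        ax = (np.arange(128) - 64) * df
        kx, ky = np.meshgrid(ax, ax)
        expected = np.count_nonzero(kx**2 + ky**2 <= (0.25 / 0.5) ** 2) / 128**2
        assert frac == pytest.approx(expected)

    def test_grid_mismatch(self):
        ctf = CoherentTransferFunction(na=0.1, wavelength=0.5, grid_side=64, pixel_pitch_highres=0.4)
        with pytest.raises(ValueError):
            apply_ctf(np.zeros((32, 32)), ctf)


class TestCaptureIntensity:
    def test_uniform_plane_wave_unit_intensity(self):
        f = uniform_field(side=64)
        spec = np.fft.fftshift(np.fft.fft2(f.values))
        out = capture_intensity(spec, ratio=1)
        np.testing.assert_allclose(out, 1.0, atol=1e-10)

    def test_uniform_with_downsampling(self):
        f = uniform_field(side=64)
        spec = np.fft.fftshift(np.fft.fft2(f.values))
        out = capture_intensity(spec, ratio=4)
        assert out.shape == (16, 16)
        np.testing.assert_allclose(out, 1.0, atol=1e-10)

    def test_nonnegative_finite(self):
        rng = np.random.default_rng(3)
        spec = rng.normal(size=(64, 64)) + 1j * rng.normal(size=(64, 64))
        out = capture_intensity(spec, ratio=2)
        assert np.all(out >= 0) and np.all(np.isfinite(out))

    def test_bad_ratio(self):
        with pytest.raises(ValueError):
            capture_intensity(np.zeros((64, 64), complex), ratio=3)


class TestSimulateStack:
    def test_frame_count_13x13x3(self):
        array = LEDArray(rows=13, cols=13)
        f = uniform_field(side=64)
        samples = {ch: f for ch in ("red", "green", "blue")}
        ctfs = {
            ch: CoherentTransferFunction(na=0.1, wavelength=w, grid_side=64, pixel_pitch_highres=0.4)
            for ch, w in [("red", 0.632), ("green", 0.532), ("blue", 0.470)]
        }
        stack = simulate_stack(samples, array, ctfs, ratio=4)
        assert len(stack.frames) == 507

    def test_single_led_identity(self):
        rng = np.random.default_rng(4)
        values = rng.uniform(0.2, 1.0, size=(32, 32))
        f = ComplexField(values.astype(complex), 0.4)
        array = LEDArray(rows=1, cols=1, wavelengths={"green": 0.5})
        ctf = CoherentTransferFunction(na=0.9, wavelength=0.5, grid_side=32, pixel_pitch_highres=0.4)
        stack = simulate_stack({"green": f}, array, {"green": ctf}, ratio=1)
        assert len(stack.frames) == 1
        np.testing.assert_allclose(stack.frames[0].intensity, values**2, atol=1e-10)

    def test_seed_determinism(self, green_field, led_7x7, green_ctf):
        noise = NoiseSpec(gaussian_sigma=0.01, poisson_photons=1e4)
        s1 = simulate_stack({"green": green_field}, led_7x7, {"green": green_ctf}, 4, noise, seed=9)
        s2 = simulate_stack({"green": green_field}, led_7x7, {"green": green_ctf}, 4, noise, seed=9)
        for f1, f2 in zip(s1.frames, s2.frames):
            np.testing.assert_array_equal(f1.intensity, f2.intensity)

    def test_channel_major_ordering(self, rgb_stack):
        channels = [f.channel for f in rgb_stack.frames]
        assert channels == ["red"] * 9 + ["green"] * 9 + ["blue"] * 9

    def test_all_frames_nonnegative(self, green_stack):
        for f in green_stack.frames:
            assert np.all(f.intensity >= 0)

    def test_missing_channel_errors(self, green_field, led_7x7, green_ctf):
        with pytest.raises(KeyError):
            simulate_stack({"green": green_field}, led_7x7, {}, ratio=4)

    def test_brightfield_darkfield_dichotomy(self, green_stack):
        cutoff = 0.1 / 0.532
        bright = [f.intensity.mean() for f in green_stack.frames
                  if np.hypot(f.kx, f.ky) <= cutoff]
        dark = [f.intensity.mean() for f in green_stack.frames
                if np.hypot(f.kx, f.ky) > cutoff]
        assert bright and dark
        assert min(bright) > max(dark)


class TestShiftFilterEquivalence:
    def test_modulate_then_filter_equals_shift_then_filter(self, green_field, green_ctf, led_7x7):
        """Eq-4 route comparison: spectrum roll vs spatial modulation."""
        from fpmdetect.optics import shift_bins, simulate_frame

        k = compute_wave_vector(led_7x7, 1, 4, "green")
        # route 1: roll the precomputed spectrum
        spec = np.fft.fftshift(np.fft.fft2(green_field.values))
        i1 = simulate_frame(spec, k, green_ctf, ratio=4)
        # route 2: modulate in space with the bin-rounded k, transform, filter
        df = green_ctf.freq_step
        bx, by = shift_bins(k, df)
        k_snap = WaveVector(bx * df, by * df, k.led_index, "green")
        modulated = modulate_sample(green_field, k_snap)
        spec2 = np.fft.fftshift(np.fft.fft2(modulated.values))
        i2 = capture_intensity(apply_ctf(spec2, green_ctf), 4)
        assert np.abs(i1 - i2).max() / i1.max() < 1e-8


class TestLEDArrayValidation:
    def test_bad_distance(self):
        with pytest.raises(ValueError):
            LEDArray(distance_to_sample=0.0)

    def test_bad_wavelength(self):
        with pytest.raises(ValueError):
            LEDArray(wavelengths={"red": -0.6})

    def test_negative_intensity_rejected(self):
        from fpmdetect.optics import Frame

        frame = Frame(
            intensity=np.full((8, 8), -1.0), led_row=0, led_col=0,
            led_index=1, channel="green", wavelength=0.532, kx=0.0, ky=0.0,
        )
        with pytest.raises(ValueError):
            AcquisitionStack(
                frames=[frame], lowres_side=8, downsample_ratio=4,
                pixel_pitch_highres=0.4, na=0.1,
            )
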