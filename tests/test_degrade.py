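import numpy as np
import pytest
from hypothesis import given, strategies as st

from scenedegrade import degrade, spectra


def brute_force_filter(image, params):
    """Independent oracle: loop over every bin applying the scalar gain."""
    h, w = image.shape
    f = np.fft.fft2(image)
    out = np.zeros_like(f)
    for v in range(h):
        for u in range(w):
            fv = np.fft.fftfreq(h)[v]
            fu = np.fft.fftfreq(w)[u]
            radial = h * np.hypot(fu, fv)
            g = 1.0 if (v, u) == (0, 0) else degrade.filter_gain(radial, params)
            out[v, u] = f[v, u] * g
    return np.fft.ifft2(out).real


class TestFilterGain:
    @pytest.mark.parametrize("kind,f,expected", [
        ("lowpass", 1.0, 1.0),          # passband edge F0
        ("lowpass", 8.0, 0.0),          # full attenuation at F1
        ("lowpass", 2 ** 1.5, 0.75),    # 1.5 octaves past the edge
        ("lowpass", 0.5, 1.0),          # inside passband
        ("lowpass", 16.0, 0.0),         # beyond F1
        ("highpass", 64.0, 1.0),        # F0 for highpass F1=8
        ("highpass", 8.0, 0.0),         # F1
        ("highpass", 64.0 / 2 ** 1.5, 0.75),
        ("highpass", 0.0, 0.0),         # DC attenuated by definition
    ])
    def test_parabolic_falloff_values(self, kind, f, expected):
        params = degrade.FilterParams(kind, 8.0)
        assert np.isclose(degrade.filter_gain(f, params), expected)

    @given(st.sampled_from(["lowpass", "highpass"]),
           st.floats(0.1, 500.0), st.floats(0.0, 800.0))
    def test_gain_bounded_in_unit_interval(self, kind, f1, f):
        g = degrade.filter_gain(f, degrade.FilterParams(kind, f1))
        assert 0.0 <= g <= 1.0

    def test_three_octave_span_for_all_presets(self):
        for kind in ("lowpass", "highpass"):
            for grids in (degrade.HUMAN_LEVELS, degrade.CNN_LEVELS):
                for f1 in grids[kind]:
                    p = degrade.FilterParams(kind, f1)
                    assert abs(np.log2(p.F1 / p.F0)) == 3.0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            degrade.FilterParams("bandpass", 8.0)
        with pytest.raises(ValueError):
            degrade.FilterParams("lowpass", -1.0)


class TestBandFilter:
    @pytest.mark.parametrize("kind,f1", [("lowpass", 6.0), ("highpass", 40.0),
                                         ("lowpass", 2.5), ("highpass", 90.0)])
    def test_matches_brute_force_oracle(self, rng, kind, f1):
        img = rng.uniform(0, 255, (16, 16))
        params = degrade.FilterParams(kind, f1)
        np.testing.assert_allclose(degrade.apply_band_filter(img, params),
                                   brute_force_filter(img, params),
                                   rtol=1e-9, atol=1e-9)

    def test_allpass_lowpass_is_identity(self, random_image):
        h = random_image.shape[0]
        # F0 above the corner frequency: nothing is attenuated
        params = degrade.FilterParams("lowpass", 8 * h * np.sqrt(2))
        out = degrade.apply_band_filter(random_image, params)
        np.testing.assert_allclose(out, random_image, rtol=1e-9, atol=1e-8)

    def test_grating_above_f1_removed(self):
        h = w = 32
        img = 128 + 50 * np.cos(2 * np.pi * 12 * np.arange(w)[None, :] / w) \
            * np.ones((h, 1))  # 12 cpi horizontal grating
        out = degrade.apply_band_filter(img, degrade.FilterParams("lowpass", 8.0))
        amp = spectra.decompose(out).amplitude
        assert amp[0, 12] < 1e-8
        assert np.isclose(out.mean(), 128.0)  # DC passes

    def test_lowpass_energy_nonincreasing_in_stricter_f1(self, rng):
        img = rng.uniform(0, 255, (32, 32))
        energies = []
        for f1 in (64.0, 32.0, 16.0, 8.0, 4.0):
            out = degrade.apply_band_filter(img, degrade.FilterParams("lowpass", f1))
            energies.append(np.sum((out - out.mean()) ** 2))
        assert all(a >= b - 1e-9 for a, b in zip(energies, energies[1:]))

    def test_rgb_filtered_per_channel(self, rng):
        img = rng.uniform(0, 255, (16, 16, 3))
        params = degrade.FilterParams("lowpass", 6.0)
        out = degrade.apply_band_filter(img, params)
        assert out.shape == img.shape
        for c in range(3):
            np.testing.assert_allclose(
                out[:, :, c], degrade.apply_band_filter(img[:, :, c], params))


class TestPhaseScramble:
    @pytest.mark.parametrize("w", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_amplitude_spectrum_preserved(self, random_image, w):
        out = degrade.phase_scramble(random_image, w, seed=9)
        a_in = spectra.decompose(random_image).amplitude
        a_out = spectra.decompose(out).amplitude
        np.testing.assert_allclose(a_out, a_in, rtol=1e-6, atol=1e-6)

    def test_zero_weight_is_identity(self, random_image):
        out = degrade.phase_scramble(random_image, 0.0, seed=4)
        np.testing.assert_allclose(out, random_image, rtol=1e-9, atol=1e-8)

    def test_seed_reproducibility(self, random_image):
        a = degrade.phase_scramble(random_image, 0.6, seed=11)
        b = degrade.phase_scramble(random_image, 0.6, seed=11)
        c = degrade.phase_scramble(random_image, 0.6, seed=12)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_correlation_nonincreasing_in_weight(self, rng):
        img = rng.uniform(0, 255, (32, 32))
        weights = (0.0, 0.3, 0.6, 1.0)
        corrs = []
        for w in weights:
            cs = [np.corrcoef(img.ravel(),
                              degrade.phase_scramble(img, w, seed=s).ravel())[0, 1]
                  for s in range(8)]
            corrs.append(np.mean(cs))
        assert all(a >= b - 0.05 for a, b in zip(corrs, corrs[1:]))
        assert abs(corrs[-1]) < 0.2  # full scramble decorrelates

    def test_invalid_weight_rejected(self, random_image):
        with pytest.raises(ValueError):
            degrade.phase_scramble(random_image, 1.2, seed=0)

    def test_rgb_channels_share_noise_field(self, rng):
        gray = rng.uniform(0, 255, (16, 16))
        rgb = np.stack([gray, gray, gray], axis=-1)
        out = degrade.phase_scramble(rgb, 0.8, seed=3)
        np.testing.assert_allclose(out[:, :, 0], out[:, :, 1])
        np.testing.assert_allclose(out[:, :, 0], out[:, :, 2])


class TestWhiten:
    def test_constant_image_unchanged(self):
        img = np.full((16, 16), 99.0)
        np.testing.assert_allclose(degrade.whiten(img), img, atol=1e-9)

    def test_mean_preserved(self, random_image):
        assert np.isclose(degrade.whiten(random_image).mean(),
                          random_image.mean())

    def test_gain_shape(self):
        fn = 50.0
        assert degrade.whitening_gain(0.0, fn) == 0.0
        assert np.isclose(degrade.whitening_gain(fn, fn), 1.0)
        # rising through the natural-image passband
        f = np.linspace(1.0, 0.7 * fn, 30)
        g = degrade.whitening_gain(f, fn)
        assert np.all(np.diff(g) > 0)

    def test_white_noise_amplitude_follows_gain(self, rng):
        # expected amplitude of white noise is flat, so the whitened
        # radial-average amplitude must be proportional to W(f)
        h = w = 64
        amps = np.zeros((h, w))
        for s in range(20):
            img = np.random.default_rng(s).normal(size=(h, w))
            amps += spectra.decompose(degrade.whiten(img)).amplitude
        grid = spectra.frequency_grid(h, w)
        gain = degrade.whitening_gain(grid.radial_cpi, grid.nyquist_cpi)
        mask = grid.radial_cpi > 0
        ratio = amps[mask] / gain[mask]
        assert ratio.std() / ratio.mean() < 0.3


class TestRenormalization:
    def test_normalize_hits_targets(self):
        # an exactly uniform spread has max |z| = sqrt(3) < 127/72.11, so no
        # pixel clips after rescaling to the target SD
        img = np.linspace(40.0, 90.0, 24 * 36).reshape(24, 36)
        out = degrade.normalize_mean_sd(img)
        assert abs(out.mean() - 128.0) < 1e-6
        assert abs(out.std() - 72.11) < 1e-6

    def test_normalize_idempotent_when_no_clipping(self, rng):
        img = rng.uniform(100, 156, (20, 20))
        once = degrade.normalize_mean_sd(img, target_sd=20.0)
        twice = degrade.normalize_mean_sd(once, target_sd=20.0)
        np.testing.assert_allclose(once, twice, atol=1e-9)

    def test_normalize_clips_to_display_range(self, rng):
        img = rng.normal(128, 1.0, (32, 32))
        out = degrade.normalize_mean_sd(img)  # SD 72.11 forces clipping
        assert out.min() >= 0.0 and out.max() <= 255.0

    def test_stretch_spans_full_range(self, random_image):
        out = degrade.stretch_full_range(random_image)
        assert out.min() == 0.0 and out.max() == 255.0

    def test_stretch_two_pixel_example(self):
        out = degrade.stretch_full_range(np.array([[10.0, 20.0]]))
        np.testing.assert_allclose(out, [[0.0, 255.0]])

    def test_stretch_identity_on_spanning_input(self):
        img = np.linspace(0, 255, 64).reshape(8, 8)
        np.testing.assert_allclose(degrade.stretch_full_range(img), img)

    @pytest.mark.parametrize("op", [degrade.normalize_mean_sd,
                                    degrade.stretch_full_range])
    def test_constant_image_rejected(self, op):
        with pytest.raises(ValueError):
            op(np.full((8, 8), 5.0))


class TestStimulusSet:
    def test_design_enumeration_counts(self):
        manifest = degrade.build_stimulus_set(
            [f"img{i}" for i in range(12)],
            ["lowpass", "highpass", "phase_scramble"],
            degrade.HUMAN_LEVELS, seed=0)
        assert len(manifest) == 12 * 3 * 4

    def test_single_stimulus(self):
        manifest = degrade.build_stimulus_set(
            ["only"], ["lowpass"], {"lowpass": [9.19]}, seed=0)
        assert len(manifest) == 1

    def test_empty_image_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            degrade.build_stimulus_set([], ["lowpass"], degrade.HUMAN_LEVELS, 0)

    def test_missing_level_grid_rejected(self):
        with pytest.raises(ValueError):
            degrade.build_stimulus_set(["a"], ["whiten"], {}, 0)

    def test_rerun_determinism(self, rng, tmp_path):
        images = {f"im{i}": rng.uniform(0, 255, (24, 24)) for i in range(2)}
        kw = dict(kinds=["phase_scramble"], levels_per_kind={"phase_scramble": [0.6]},
                  seed=77)
        m1 = degrade.build_stimulus_set(images, out_dir=tmp_path / "a", **kw)
        m2 = degrade.build_stimulus_set(images, out_dir=tmp_path / "b", **kw)
        assert m1.drop(columns="path").equals(m2.drop(columns="path"))
        import imageio.v3 as iio
        for p1, p2 in zip(m1["path"], m2["path"]):
            assert np.array_equal(iio.imread(p1), iio.imread(p2))
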