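"""Evoked averaging, Morlet amplitudes, GFP and GMD against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hapticstim import efield as ef
from hapticstim import synthetic_eeg as se


def _epochs_from_array(data, fs=300.0, t0=0.0):
    n_t = data.shape[-1]
    return se.EpochSet(
        data=data, fs=fs, times=t0 + np.arange(n_t) / fs,
        trigger_type="start", participant_id="P0", group="Sham", phase="pre",
        montage=se.standard_montage(),
    )


def _map_from_array(data, fs=300.0):
    return ef.EvokedMap(
        data=data, fs=fs, times=np.arange(data.shape[1]) / fs, trigger_type="start"
    )


class TestEvoked:
    def test_single_trial_identity(self, rng):
        data = rng.standard_normal((1, 62, 100))
        assert np.array_equal(ef.evoked(_epochs_from_array(data)).data, data[0])

    def test_opposite_trials_cancel(self, rng):
        a = rng.standard_normal((1, 62, 50))
        data = np.concatenate([a, -a])
        assert np.allclose(ef.evoked(_epochs_from_array(data)).data, 0.0)

    def test_matches_naive_loop(self, rng):
        data = rng.standard_normal((50, 62, 40))
        out = ef.evoked(_epochs_from_array(data)).data
        acc = np.zeros((62, 40))
        for k in range(50):
            acc += data[k]
        assert np.allclose(out, acc / 50, atol=1e-12)


class TestPairedContrast:
    def test_self_contrast_is_zero(self, rng):
        a = _map_from_array(rng.standard_normal((62, 30)))
        assert np.all(ef.paired_contrast(a, a).data == 0.0)

    def test_zero_reference_is_identity(self, rng):
        a = _map_from_array(rng.standard_normal((62, 30)))
        b = _map_from_array(np.zeros((62, 30)))
        assert np.array_equal(ef.paired_contrast(a, b).data, a.data)

    def test_matches_elementwise_loop(self, rng):
        a = _map_from_array(rng.standard_normal((5, 8)))
        b = _map_from_array(rng.standard_normal((5, 8)))
        out = ef.paired_contrast(a, b).data
        for i in range(5):
            for j in range(8):
                assert out[i, j] == a.data[i, j] - b.data[i, j]

    def test_shape_mismatch_rejected(self, rng):
        a = _map_from_array(rng.standard_normal((5, 8)))
        b = _map_from_array(rng.standard_normal((5, 9)))
        with pytest.raises(ValueError):
            ef.paired_contrast(a, b)


class TestMorlet:
    def test_amplitude_linear_in_input(self):
        fs = 1200.0
        t = np.arange(int(1.4 * fs)) / fs
        ratios = []
        for A in (1.0, 2.0, 5.0):
            emap = _map_from_array(np.tile(A * np.sin(2 * np.pi * 10 * t), (3, 1)), fs=fs)
            out = ef.morlet_tfr(emap)
            i10 = list(out.freqs).index(10.0)
            ratios.append(out.data[i10][out.valid[i10]].mean() / A)
        assert max(ratios) / min(ratios) == pytest.approx(1.0, rel=1e-2)

    def test_zero_signal_zero_amplitude(self):
        emap = _map_from_array(np.zeros((4, 600)), fs=600.0)
        assert np.allclose(ef.morlet_tfr(emap).data, 0.0)

    def test_matches_direct_convolution_oracle(self):
        # Independent oracle: time-domain convolution, no FFT.
        fs = 600.0
        t = np.arange(int(1.0 * fs)) / fs
        sig = np.sin(2 * np.pi * 10 * t)
        emap = _map_from_array(np.tile(sig, (2, 1)), fs=fs)
        out = ef.morlet_tfr(emap, keep_channels=True)
        for i, f in enumerate(out.freqs):
            w = ef.morlet_wavelet(f, fs, 1.5)
            oracle = np.abs(np.convolve(sig, w, mode="same"))
            impl = out.data[0, i]
            m = out.valid[i]
            scale = np.max(oracle[m])
            assert np.allclose(impl[m] / scale, oracle[m] / scale, atol=1e-6)

    def test_well_separated_sinusoids_superpose(self):
        # Cross-terms between well-separated frequencies stay below 5%.
        fs = 600.0
        t = np.arange(int(2.0 * fs)) / fs
        s1 = np.sin(2 * np.pi * 10 * t)
        s2 = np.sin(2 * np.pi * 30 * t)
        freqs = (10.0, 30.0)
        n_cycles = 6.0
        a1 = ef.morlet_tfr(_map_from_array(s1[None, :].repeat(2, 0), fs), freqs, n_cycles)
        a2 = ef.morlet_tfr(_map_from_array(s2[None, :].repeat(2, 0), fs), freqs, n_cycles)
        both = ef.morlet_tfr(_map_from_array((s1 + s2)[None, :].repeat(2, 0), fs), freqs, n_cycles)
        m = both.valid.all(axis=0)
        expected = np.maximum(a1.data, a2.data)
        peak = expected[:, m].max()
        assert np.max(np.abs(both.data[:, m] - expected[:, m])) / peak < 0.05

    def test_induced_mode_sees_non_phase_locked_alpha(self, rng):
        fs = 600.0
        t = np.arange(int(1.0 * fs)) / fs
        trials = np.stack([
            np.tile(np.sin(2 * np.pi * 10 * t + phi), (62, 1))
            for phi in rng.uniform(0, 2 * np.pi, 40)
        ])
        ep = _epochs_from_array(trials, fs=fs)
        induced = ef.morlet_tfr(ep, mode="induced")
        evoked_mode = ef.morlet_tfr(ep, mode="evoked")
        i10 = list(induced.freqs).index(10.0)
        m = induced.valid[i10]
        assert induced.data[i10][m].mean() > 5 * evoked_mode.data[i10][m].mean()

    def test_window_too_short_rejected(self):
        emap = _map_from_array(np.zeros((3, 30)), fs=300.0)  # 0.1 s < one 8 Hz cycle
        with pytest.raises(ValueError):
            ef.morlet_tfr(emap)


class TestGFP:
    def test_uniform_map_zero(self):
        emap = _map_from_array(np.full((62, 20), 3.7))
        assert np.allclose(ef.gfp(emap).values, 0.0)

    def test_homogeneous_scaling(self, rng):
        data = rng.standard_normal((62, 20))
        g1 = ef.gfp(_map_from_array(data)).values
        g2 = ef.gfp(_map_from_array(-2.5 * data)).values
        assert np.allclose(g2, 2.5 * g1, atol=1e-12)

    def test_matches_naive_std_loop(self, rng):
        data = rng.standard_normal((62, 25))
        out = ef.gfp(_map_from_array(data)).values
        for j in range(25):
            col = data[:, j] - np.mean(data[:, j])
            oracle = np.sqrt(np.sum(col**2) / 62)  # population convention
            assert out[j] == pytest.approx(oracle, abs=1e-12)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            ef.gfp(_map_from_array(np.zeros((1, 10))))


class TestGMD:
    def test_proportional_maps_zero(self, rng):
        data = rng.standard_normal((62, 15))
        a, b = _map_from_array(data), _map_from_array(3.0 * data)
        assert np.allclose(ef.gmd(a, b).values, 0.0, atol=1e-12)

    def test_antipodal_maps_maximal(self, rng):
        data = rng.standard_normal((62, 15))
        out = ef.gmd(_map_from_array(data), _map_from_array(-data))
        assert np.allclose(out.values, 2.0, atol=1e-12)

    def test_symmetric(self, rng):
        a = _map_from_array(rng.standard_normal((62, 15)))
        b = _map_from_array(rng.standard_normal((62, 15)))
        assert np.allclose(ef.gmd(a, b).values, ef.gmd(b, a).values, atol=1e-12)

    @given(st.floats(min_value=0.1, max_value=50.0), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_positive_rescaling(self, k, seed):
        rng = np.random.default_rng(seed)
        a = _map_from_array(rng.standard_normal((10, 6)))
        b = _map_from_array(rng.standard_normal((10, 6)))
        b_scaled = _map_from_array(k * b.data)
        assert np.allclose(ef.gmd(a, b).values, ef.gmd(a, b_scaled).values, atol=1e-9)

    def test_matches_formula_loop(self, rng):
        da = rng.standard_normal((62, 8))
        db = rng.standard_normal((62, 8))
        out = ef.gmd(_map_from_array(da), _map_from_array(db)).values
        for j in range(8):
            u = da[:, j] - da[:, j].mean()
            v = db[:, j] - db[:, j].mean()
            u = u / np.sqrt(np.mean(u**2))
            v = v / np.sqrt(np.mean(v**2))
            oracle = np.sqrt(np.mean((u - v) ** 2))
            assert out[j] == pytest.approx(oracle, abs=1e-12)

    def test_zero_gfp_sample_flagged_nan(self, rng):
        da = rng.standard_normal((62, 5))
        db = rng.standard_normal((62, 5))
        da[:, 2] = 1.0  # uniform -> zero GFP after re-referencing
        out = ef.gmd(_map_from_array(da), _map_from_array(db)).values
        assert np.isnan(out[2]) and not np.isnan(out[[0, 1, 3, 4]]).any()

    def test_gfp_of_identical_contrast_zero(self, rng):
        a = _map_from_array(rng.standard_normal((62, 9)))
        contrast = ef.paired_contrast(a, a)
        assert np.allclose(ef.gfp(contrast).values, 0.0)
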