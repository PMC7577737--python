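"""Wave quantification: oracle equivalence, exact symmetries, surrogate
behaviour and per-frequency decomposition."""

import numpy as np
import pytest

from eegwaves.core_io import ElectrodeArray, Recording
from eegwaves.preprocessing import WindowSpec

from eegwaves.wave_quant import (BandDefinition, SurrogateSpec, WaveMap,
                                 peak_band_histogram, per_frequency_waves,
                                 quadrant_max, quantify_recording,
                                 quantify_window, spectrum_2d,
                                 surrogate_maxima, wave_db)

from conftest import make_plane_map


def brute_force_power(data: np.ndarray) -> np.ndarray:
    """Independent O(N^2) double-sum 2D power spectrum, fftshifted axes."""
    nx, nt = data.shape
    out = np.zeros((nx, nt))
    for k1 in range(nx):
        for k2 in range(nt):
            acc = 0.0 + 0.0j
            for x in range(nx):
                for t in range(nt):
                    acc += data[x, t] * np.exp(-2j * np.pi * (k1 * x / nx
                                                              + k2 * t / nt))
            out[k1, k2] = abs(acc) ** 2
    return np.fft.fftshift(out)


class TestSpectrum2D:
    def test_constant_map_is_dc_only(self):
        m = WaveMap(np.ones((5, 16)), 16.0)
        spec = spectrum_2d(m)
        i0 = np.flatnonzero(spec.spatial_freqs == 0)[0]
        j0 = np.flatnonzero(spec.temporal_freqs == 0)[0]
        total = spec.power.sum()
        assert spec.power[i0, j0] == pytest.approx(total, rel=1e-12)
        assert spec.power[i0, j0] == pytest.approx((5 * 16) ** 2, rel=1e-12)

    def test_plane_wave_two_symmetric_bins(self):
        # cos(2π·10·t − 2π·(1/5)·x): all power in two point-symmetric bins
        m = make_plane_map(temporal_hz=10.0, cpe=0.2)
        spec = spectrum_2d(m)
        flat = np.sort(spec.power.ravel())[::-1]
        assert flat[1] / flat[0] == pytest.approx(1.0, rel=1e-9)
        assert flat[2] / flat[0] < 1e-12
        i, j = np.unravel_index(np.argmax(spec.power), spec.power.shape)
        pairs = {(spec.spatial_freqs[i], spec.temporal_freqs[j]),
                 (-spec.spatial_freqs[i], -spec.temporal_freqs[j])}
        assert (-0.2, 10.0) in pairs  # forward wave: negative spatial freq

    def test_parseval_white_noise(self, rng):
        data = rng.standard_normal((5, 64))
        spec = spectrum_2d(WaveMap(data, 64.0))
        assert spec.power.sum() == pytest.approx(
            5 * 64 * np.sum(data ** 2), rel=1e-9)

    def test_point_symmetry(self, rng):
        # odd lengths so every (k, f) bin has a (-k, -f) partner
        spec = spectrum_2d(WaveMap(rng.standard_normal((5, 17)), 17.0))
        # real input: power(-k, -f) == power(k, f)
        np.testing.assert_allclose(spec.power, spec.power[::-1, ::-1],
                                   rtol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_oracle_equivalence_5x16(self, seed):
        data = np.random.default_rng(seed).standard_normal((5, 16))
        spec = spectrum_2d(WaveMap(data, 16.0))
        np.testing.assert_allclose(spec.power, brute_force_power(data),
                                   rtol=1e-9, atol=1e-9)


class TestQuadrantMax:
    def test_forward_wave_dominates_fw_quadrant(self):
        spec = spectrum_2d(make_plane_map(temporal_hz=10.0, cpe=0.2))
        fw, fw_hz, fw_cpe = quadrant_max(spec, "FW", (1, 45))
        bw, _, _ = quadrant_max(spec, "BW", (1, 45))
        assert 10 * np.log10(fw / bw) >= 20.0
        assert fw_hz == 10.0
        assert fw_cpe == -0.2

    def test_uniform_oscillation_symmetric(self, uniform_map):
        spec = spectrum_2d(uniform_map)
        fw, _, _ = quadrant_max(spec, "FW", (1, 45))
        bw, _, _ = quadrant_max(spec, "BW", (1, 45))
        assert fw == bw

    @pytest.mark.parametrize("seed", range(5))
    def test_flip_swaps_quadrants_bit_exact(self, seed):
        data = np.random.default_rng(seed).standard_normal((5, 32))
        spec = spectrum_2d(WaveMap(data, 32.0))
        fspec = spectrum_2d(WaveMap(data[::-1].copy(), 32.0))
        assert quadrant_max(fspec, "FW")[0] == quadrant_max(spec, "BW")[0]
        assert quadrant_max(fspec, "BW")[0] == quadrant_max(spec, "FW")[0]

    def test_oracle_quadrant_agreement(self, rng):
        data = rng.standard_normal((5, 16))
        spec = spectrum_2d(WaveMap(data, 16.0))
        bf = brute_force_power(data)
        sf = np.fft.fftshift(np.fft.fftfreq(5))
        tf = np.fft.fftshift(np.fft.fftfreq(16, 1 / 16.0))
        expected = bf[np.ix_(sf < 0, tf > 0)].max()
        assert quadrant_max(spec, "FW")[0] == pytest.approx(expected, rel=1e-9)

    def test_empty_band_rejected(self, forward_map):
        spec = spectrum_2d(forward_map)
        with pytest.raises(ValueError):
            quadrant_max(spec, "FW", (2000.0, 3000.0))

    def test_unknown_direction(self, forward_map):
        with pytest.raises(ValueError):
            quadrant_max(spectrum_2d(forward_map), "sideways")


class TestWaveDb:
    def test_identity_zero(self):
        assert wave_db(3.7, 3.7) == 0.0

    def test_factor_ten(self):
        assert wave_db(10.0, 1.0) == pytest.approx(10.0, abs=1e-12)

    def test_factor_two(self):
        assert wave_db(2.0, 1.0) == pytest.approx(3.0103, abs=1e-4)

    @pytest.mark.parametrize("w,wss", [(0.0, 1.0), (1.0, 0.0), (-1.0, 1.0)])
    def test_nonpositive_rejected(self, w, wss):
        with pytest.raises(ValueError):
            wave_db(w, wss)


class TestSurrogates:
    def test_uniform_map_permutation_invariant(self, uniform_map):
        spec = spectrum_2d(uniform_map)
        raw = quadrant_max(spec, "FW", (1, 45))[0]
        for seed in (0, 7, 123):
            wss = surrogate_maxima(uniform_map, "FW",
                                   SurrogateSpec(50, seed=seed))
            assert wss == raw

    def test_fixed_seed_deterministic(self, forward_map):
        a = surrogate_maxima(forward_map, "FW", SurrogateSpec(30, seed=5))
        b = surrogate_maxima(forward_map, "FW", SurrogateSpec(30, seed=5))
        assert a == b

    def test_exhaustive_is_limit_of_sampling(self, rng):
        """The 100-draw surrogate mean sits within 3 SE of the exhaustive
        mean over all 120 electrode orderings."""
        import itertools

        from eegwaves.wave_quant import _WindowEngine

        m = make_plane_map(noise=0.5, seed=4)
        exhaustive = surrogate_maxima(m, "FW", SurrogateSpec(exhaustive=True))
        # per-permutation maxima for the SE of a 100-draw mean
        eng = _WindowEngine(5, 1000, 1000.0)
        g = np.fft.fft(m.data, axis=-1)[:, eng.kt]
        per_perm = []
        for perm in itertools.permutations(range(5)):
            from eegwaves.wave_quant import _spatial_power

            p = _spatial_power(g[list(perm), :][None], eng.weights)[0]
            per_perm.append(p[eng.neg, :].max())
        se = np.std(per_perm) / np.sqrt(100)
        sampled = surrogate_maxima(m, "FW", SurrogateSpec(100, seed=11))
        assert abs(sampled - exhaustive) < 3 * se

    def test_exhaustive_repeatable_bit_identical(self, forward_map):
        spec = SurrogateSpec(exhaustive=True)
        assert (surrogate_maxima(forward_map, "FW", spec)
                == surrogate_maxima(forward_map, "FW", spec))

    def test_too_few_electrodes(self):
        with pytest.raises(ValueError):
            WaveMap(np.zeros((2, 16)), 16.0)


class TestQuantifyWindow:
    def test_forward_wave_with_noise(self):
        m = make_plane_map(noise=0.1, seed=1)  # SNR 10
        est = quantify_window(m, SurrogateSpec(100, seed=0))
        assert est.fw_db > 3.0
        assert est.bw_db < 1.0
        assert est.fw_peak_hz == 10.0

    def test_flip_swaps_db_exactly_exhaustive(self):
        m = make_plane_map(noise=0.3, seed=2)
        spec = SurrogateSpec(exhaustive=True)
        a = quantify_window(m, spec)
        b = quantify_window(m.flipped(), spec)
        assert a.fw_raw == b.bw_raw and a.bw_raw == b.fw_raw
        assert a.fw_db == b.bw_db and a.bw_db == b.fw_db

    @pytest.mark.parametrize("seed", [0, 3, 99])
    def test_uniform_map_exactly_zero(self, uniform_map, seed):
        est = quantify_window(uniform_map, SurrogateSpec(40, seed=seed))
        assert est.fw_db == 0.0
        assert est.bw_db == 0.0


class TestQuantifyRecording:
    def _recording(self, dur=60.0, fs=250.0, noise=None, seed=0):
        t = np.arange(int(dur * fs)) / fs
        x = np.arange(5)
        data = np.cos(2 * np.pi * 10 * t[None, :] - 2 * np.pi * 0.2 * x[:, None])
        if noise:
            data = data + noise * np.random.default_rng(seed).standard_normal(
                data.shape)
        return Recording(tuple(f"E{i}" for i in range(5)), fs, data)

    def test_window_count(self):
        rec = self._recording(dur=30.0)
        ests = quantify_recording(rec, ElectrodeArray(rec.labels),
                                  WindowSpec(1.0, 0.5), SurrogateSpec(20, seed=0))
        assert len(ests) == 59

    def test_stationary_halves_agree(self):
        rec = self._recording(dur=120.0, noise=0.5)
        ests = quantify_recording(rec, ElectrodeArray(rec.labels),
                                  WindowSpec(1.0, 0.5), SurrogateSpec(50, seed=0))
        fw = np.array([e.fw_db for e in ests])
        assert np.all(fw > 0)
        h1, h2 = fw[:len(fw) // 2], fw[len(fw) // 2:]
        se = np.sqrt(h1.var(ddof=1) / h1.size + h2.var(ddof=1) / h2.size)
        assert abs(h1.mean() - h2.mean()) < 2 * se

    def test_chunking_invariance(self):
        rec = self._recording(dur=10.0, noise=0.3)
        kw = dict(window=WindowSpec(1.0, 0.5), spec=SurrogateSpec(30, seed=3))
        a = quantify_recording(rec, ElectrodeArray(rec.labels), chunk=4, **kw)
        b = quantify_recording(rec, ElectrodeArray(rec.labels), chunk=64, **kw)
        for ea, eb in zip(a, b):
            assert ea == eb

    def test_lateral_null_control(self):
        """A posterior→anterior wave projected identically onto a left–right
        array carries no lateral propagation: dB within noise of zero."""
        fs, dur = 250.0, 60.0
        t = np.arange(int(dur * fs)) / fs
        rng = np.random.default_rng(8)
        common = np.cos(2 * np.pi * 10 * t)  # equal phase on all laterals
        data = np.tile(common, (5, 1)) + 0.5 * rng.standard_normal((5, t.size))
        rec = Recording(("T7", "C3", "Cz", "C4", "T8"), fs, data)
        ests = quantify_recording(rec, ElectrodeArray(rec.labels, "lateral"),
                                  WindowSpec(1.0, 0.5), SurrogateSpec(50, seed=1))
        for attr in ("fw_db", "bw_db"):
            vals = np.array([getattr(e, attr) for e in ests])
            se = vals.std(ddof=1) / np.sqrt(vals.size)
            assert abs(vals.mean()) < 3 * se

    def test_shuffle_preserves_temporal_power(self, rng):
        """Electrode shuffling conserves, per temporal frequency, the power
        summed over spatial frequencies (asserted per shuffle)."""
        from eegwaves.wave_quant import (_centered_spatial_weights,
                                         _spatial_power)

        data = rng.standard_normal((5, 32))
        g = np.fft.fft(data, axis=1)
        _, w = _centered_spatial_weights(5)
        base = _spatial_power(g[None], w)[0].sum(axis=0)
        for seed in range(5):
            perm = np.random.default_rng(seed).permutation(5)
            shuf = _spatial_power(g[perm][None], w)[0].sum(axis=0)
            np.testing.assert_allclose(shuf, base, rtol=1e-9)


class TestPerFrequency:
    def test_plane_wave_peak_frequency(self):
        m = make_plane_map(noise=0.2, seed=5)
        out = per_frequency_waves(m, SurrogateSpec(50, seed=0))
        best = out["freq_hz"][np.argmax(out["fw_db"])]
        assert best == 10.0

    def test_uniform_map_all_zero(self, uniform_map):
        out = per_frequency_waves(uniform_map, SurrogateSpec(20, seed=0))
        assert np.all(out["fw_db"] == 0.0)
        assert np.all(out["bw_db"] == 0.0)

    def test_max_decomposition(self, rng):
        m = WaveMap(rng.standard_normal((5, 100)), 100.0)
        out = per_frequency_waves(m, SurrogateSpec(20, seed=0))
        est_spec = spectrum_2d(m)
        qmax = quadrant_max(est_spec, "FW", (1, 45))[0]
        assert out["fw_raw"].max() == pytest.approx(qmax, rel=1e-9)
        assert out["fw_raw"].sum() >= qmax


class TestBandHistogram:
    def test_alpha_wave_counts(self):
        ests = [quantify_window(make_plane_map(noise=0.05, seed=s),
                                SurrogateSpec(10, seed=s)) for s in range(10)]
        counts = peak_band_histogram(ests, "FW")
        assert counts == {"delta": 0, "theta": 0, "alpha": 10, "beta": 0}

    def test_band_edges_upper_half_open(self):
        bands = BandDefinition()
        assert bands.classify(4.0) == "theta"
        assert bands.classify(13.0) == "beta"
        assert bands.classify(30.0) == "beta"  # last band closed above
        assert bands.classify(0.5) is None

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            peak_band_histogram([], "FW")

    def test_band_definition_validation(self):
        with pytest.raises(ValueError):
            BandDefinition((("a", 1.0, 5.0), ("b", 4.0, 8.0)))
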