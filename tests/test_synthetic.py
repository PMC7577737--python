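"""Synthetic generators: primitive signals, calibration, and study structure."""

import numpy as np
import pytest


from eegwaves.core_io import MIDLINE
from eegwaves.preprocessing import WindowSpec
from eegwaves.synthetic import (CalibrationError, StudySimConfig,
                                WaveComponent, _db_of_profile, gen_noise,
                                gen_plane_wave, gen_session,
                                gen_standing_wave, gen_study, solve_profile)
from eegwaves.wave_quant import (SurrogateSpec, WaveMap, quantify_recording,
                                 quantify_window)


class TestPlaneWave:
    def test_detected_as_forward(self):
        rec = gen_plane_wave(1000.0, 1.0, 5, WaveComponent(10.0, +0.2))
        est = quantify_window(WaveMap(rec.data, 1000.0),
                              SurrogateSpec(100, seed=0))
        assert est.fw_db > 0 > est.bw_db - 3

    def test_zero_cpe_is_uniform(self):
        rec = gen_plane_wave(500.0, 1.0, 5, WaveComponent(10.0, 0.0))
        est = quantify_window(WaveMap(rec.data, 500.0), SurrogateSpec(20, seed=1))
        assert est.fw_db == 0.0 and est.bw_db == 0.0

    def test_negated_cpe_equals_flip(self):
        n = 5
        cpe = 0.2
        fwd = gen_plane_wave(500.0, 1.0, n, WaveComponent(10.0, +cpe))
        # flipping electrodes shifts the spatial phase origin by (n-1) steps
        bwd = gen_plane_wave(500.0, 1.0, n,
                             WaveComponent(10.0, -cpe,
                                           phase0=-2 * np.pi * cpe * (n - 1)))
        np.testing.assert_allclose(bwd.data, fwd.data[::-1], atol=1e-9)

    def test_nyquist_rejected(self):
        with pytest.raises(ValueError):
            gen_plane_wave(100.0, 1.0, 5, WaveComponent(60.0, 0.2))
        with pytest.raises(ValueError):
            WaveComponent(10.0, 0.7)


class TestStandingWave:
    def test_equal_raw_quadrants(self):
        rec = gen_standing_wave(500.0, 1.0, 5, 10.0)
        est = quantify_window(WaveMap(rec.data, 500.0), SurrogateSpec(30, seed=0))
        assert est.fw_raw == pytest.approx(est.bw_raw, rel=1e-9)

    def test_both_directions_beat_null(self):
        rec = gen_standing_wave(500.0, 2.0, 5, 10.0)
        est = quantify_window(WaveMap(rec.data[:, :500], 500.0),
                              SurrogateSpec(exhaustive=True))
        assert est.fw_db > 0 and est.bw_db > 0
        assert est.fw_db == pytest.approx(est.bw_db, abs=0.5)

    def test_limit_is_plane_wave(self):
        fw = gen_plane_wave(500.0, 1.0, 5, WaveComponent(10.0, 0.2))
        st = gen_standing_wave(500.0, 1.0, 5, 10.0, spatial_cpe=0.2)
        bw = gen_plane_wave(500.0, 1.0, 5, WaveComponent(10.0, -0.2))
        np.testing.assert_allclose(st.data, fw.data + bw.data, atol=1e-12)


class TestNoise:
    @pytest.mark.parametrize("exponent,target,tol",
                             [(0.0, 0.0, 0.1), (1.0, -1.0, 0.15)])
    def test_spectral_slope(self, exponent, target, tol):
        rec = gen_noise(250.0, 60.0, 2, exponent=exponent, seed=3)
        from scipy.signal import welch

        f, psd = welch(rec.data[0], fs=250.0, nperseg=2048)
        keep = (f >= 1.0) & (f <= 45.0)
        slope = np.polyfit(np.log10(f[keep]), np.log10(psd[keep]), 1)[0]
        assert abs(slope - target) < tol

    def test_deterministic(self):
        a = gen_noise(100.0, 5.0, 3, 1.0, seed=9)
        b = gen_noise(100.0, 5.0, 3, 1.0, seed=9)
        np.testing.assert_array_equal(a.data, b.data)

    def test_rms_amplitude(self):
        rec = gen_noise(100.0, 10.0, 3, 1.0, amplitude=7.5, seed=0)
        np.testing.assert_allclose(rec.data.std(axis=1), 7.5, rtol=1e-9)

    def test_exponent_range(self):
        with pytest.raises(ValueError):
            gen_noise(100.0, 1.0, 2, exponent=5.0)


class TestCalibration:
    @pytest.mark.parametrize("targets", [(-0.20, 0.51), (0.19, 0.18),
                                         (0.9, -0.4)])
    def test_solver_hits_targets(self, targets):
        phases = np.random.default_rng(0).uniform(0, 2 * np.pi, 8)
        c = solve_profile(*targets, phases, mod_depth=0.3)
        grid = 0.3 * np.sin(2 * np.pi * np.arange(64) / 64)
        got = _db_of_profile(c, grid)
        assert got[0] == pytest.approx(targets[0], abs=0.02)
        assert got[1] == pytest.approx(targets[1], abs=0.02)

    def test_unreachable_raises(self):
        phases = np.random.default_rng(0).uniform(0, 2 * np.pi, 8)
        with pytest.raises(CalibrationError):
            solve_profile(30.0, 30.0, phases)


def _reduced_config(**kw):
    defaults = dict(n_subjects=3, pre_minutes=1, post_minutes=2,
                    block_minutes=2, n_channels=8, seed=0)
    defaults.update(kw)
    return StudySimConfig(**defaults)


class TestGenSession:
    def test_calibration_round_trip_noise_free(self):
        """Pipeline-recovered post-block means hit per-subject targets
        within ±0.05 dB when noise is disabled (parameter recovery)."""
        cfg = _reduced_config(midline_noise_uv=0.0, background_noise_uv=0.0)
        tgt = {"base": (-0.20, 0.51), "post": (0.19, 0.18)}
        rec = gen_session("dmt", tgt, cfg, seed=5)
        ests = quantify_recording(rec, MIDLINE, WindowSpec(),
                                  SurrogateSpec(100, seed=2))
        t = np.array([e.t_start for e in ests])
        post = (t >= 0) & (t < 120)
        fw = np.mean([e.fw_db for e, m in zip(ests, post) if m])
        bw = np.mean([e.bw_db for e, m in zip(ests, post) if m])
        assert fw == pytest.approx(0.19, abs=0.05)
        assert bw == pytest.approx(0.18, abs=0.05)

    def test_placebo_pre_post_stable(self):
        cfg = _reduced_config(pre_minutes=2)
        tgt = {"base": (-0.20, 0.51), "post": (-0.20, 0.51)}
        rec = gen_session("placebo", tgt, cfg, seed=3)
        ests = quantify_recording(rec, MIDLINE, WindowSpec(),
                                  SurrogateSpec(100, seed=4))
        t = np.array([e.t_start for e in ests])
        fw = np.array([e.fw_db for e in ests])
        pre, post = fw[t < 0], fw[t >= 0]
        se = np.sqrt(pre.var(ddof=1) / pre.size + post.var(ddof=1) / post.size)
        assert abs(pre.mean() - post.mean()) < 2 * se

    def test_drug_raises_forward_waves(self):
        cfg = _reduced_config(pre_minutes=2, post_minutes=3, block_minutes=3)
        tgt = {"base": (-0.20, 0.51), "post": (0.19, 0.18)}
        rec = gen_session("dmt", tgt, cfg, seed=1)
        ests = quantify_recording(rec, MIDLINE, WindowSpec(),
                                  SurrogateSpec(100, seed=0))
        t = np.array([e.t_start for e in ests])
        fw = np.array([e.fw_db for e in ests])
        assert fw[t >= 120].mean() > fw[t < 0].mean()

    def test_deterministic_bytes(self):
        cfg = _reduced_config()
        tgt = {"base": (-0.2, 0.5), "post": (0.2, 0.2)}
        a = gen_session("dmt", tgt, cfg, seed=7)
        b = gen_session("dmt", tgt, cfg, seed=7)
        np.testing.assert_array_equal(a.data, b.data)
        assert a.t0 == b.t0 == -60.0

    def test_unknown_condition(self):
        with pytest.raises(ValueError):
            gen_session("ketamine", {"base": (0, 0), "post": (0, 0)},
                        _reduced_config(), 0)


class TestGenStudy:
    def test_default_structure_is_paper_scale(self):
        # structure only: recordings stay lazy, nothing heavy is generated
        ds = gen_study(StudySimConfig(seed=0))
        assert len(ds.subjects) == 13
        assert set(c for _, c in ds.iter_sessions()) == {"placebo", "dmt"}
        minutes = ds.ratings.intensity.groupby("subject")["minute"].count()
        assert (minutes == 20).all()
        assert ds.ratings.vas.groupby("subject")["item"].count().eq(20).all()
        assert set(ds.doses_mg.values()) <= {7.0, 14.0, 18.0, 20.0}

    def test_ratings_bounded_and_effect_monotone(self):
        cfg = StudySimConfig(seed=1, rating_noise_sd=0.1)
        ds = gen_study(cfg)
        vals = ds.ratings.intensity["intensity"]
        assert vals.between(0, 10).all()
        # minute means should follow the onset/fade profile: rise then fall
        by_minute = ds.ratings.intensity.groupby("minute")["intensity"].mean()
        assert by_minute.loc[4] > by_minute.loc[1]
        assert by_minute.loc[4] > by_minute.loc[20]

    def test_study_deterministic(self):
        a = gen_study(_reduced_config(seed=5))
        b = gen_study(_reduced_config(seed=5))
        assert a.ratings.intensity.equals(b.ratings.intensity)
        ra = a.get_recording("S01", "dmt")
        rb = b.get_recording("S01", "dmt")
        np.testing.assert_array_equal(ra.data, rb.data)

    def test_effect_profile_shape(self):
        cfg = StudySimConfig()
        assert cfg.effect_profile(-1.0) == 0.0
        assert cfg.effect_profile(1.0) == 0.5
        assert cfg.effect_profile(3.0) == 1.0
        assert cfg.effect_profile(10.0) == pytest.approx(0.5)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            StudySimConfig(n_subjects=1)
        with pytest.raises(ValueError):
            StudySimConfig(block_minutes=30, post_minutes=20)
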