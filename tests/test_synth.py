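"""Generator contracts: determinism, ground-truth consistency, error paths."""

import numpy as np
import pytest

from lcpipe import photometry as ph
from lcpipe import ratio_imaging as ri
from lcpipe import synth


class TestYcGenerator:
    def test_null_effect_zero_noise_constant_ratio(self):
        rec, _ = synth.generate_yc_recording(
            [synth.SubstanceEffectSpec("acsf", "none")],
            n_rois=3,
            frame_interval=1.0,
            seed=0,
            noise_sd=0.0,
        )
        ratio = ri.compute_yc_ratio(rec)
        assert np.allclose(ratio, ratio[0], atol=1e-12)

    def test_determinism(self):
        effs = [synth.SubstanceEffectSpec("x", "decrease", 5.0)]
        a, _ = synth.generate_yc_recording(effs, 4, 1.0, seed=42)
        b, _ = synth.generate_yc_recording(effs, 4, 1.0, seed=42)
        assert np.array_equal(a.yfp, b.yfp) and np.array_equal(a.cfp, b.cfp)
        c, _ = synth.generate_yc_recording(effs, 4, 1.0, seed=43)
        assert not np.array_equal(a.yfp, c.yfp)

    def test_channels_anticorrelated_during_response(self):
        rec, truth = synth.generate_yc_recording(
            [synth.SubstanceEffectSpec("glu", "increase", 10.0)],
            n_rois=1,
            frame_interval=1.0,
            seed=1,
            noise_sd=0.02,
            bleach_tau=1e12,  # isolate the response component
        )
        peak = int(truth.kernels["glu"]["t_peak"])
        yfp, cfp = rec.yfp[:, 0], rec.cfp[:, 0]
        base_y, base_c = yfp[:200].mean(), cfp[:200].mean()
        assert yfp[peak - 30 : peak + 30].mean() > 1.02 * base_y
        assert cfp[peak - 30 : peak + 30].mean() < 0.98 * base_c

    def test_deep_dip_depth_and_latent_fwhm(self):
        """Depth-8 suppression: the noisy pipeline recovers the smoothed
        minimum within 1 Z; the latent (pre-noise) kernel has the requested
        analytic FWHM within 10%."""
        eff = synth.SubstanceEffectSpec(
            "pge2", "decrease", depth=8.0, onset_delay=10.0, duration_fwhm=600.0
        )
        rec, truth = synth.generate_yc_recording(
            [eff], 4, 1.0, session_layout=[300.0], seed=7, session_duration=1800.0
        )
        ratio = ri.compute_yc_ratio(rec)
        for j in range(rec.n_rois):
            zt = ri.correct_and_zscore(ratio[:, j], (0.0, 300.0), 1.0)
            res = ri.fwhm(zt, 300.0)
            assert not res.excluded
            assert res.z_min120 == pytest.approx(-8.0, abs=1.0)
        z_lat = truth.z_latent[:, 0]
        zl = ri.ZScoreTrace(
            z=z_lat, baseline_window=(0.0, 300.0), ratio_raw=z_lat, frame_interval=1.0
        )
        res_lat = ri.fwhm(zl, 300.0)
        assert res_lat.fwhm_seconds == pytest.approx(600.0, rel=0.10)
        assert abs(z_lat.min()) == pytest.approx(8.0, abs=1e-9)

    def test_latent_clean_before_onset(self):
        rec, truth = synth.generate_yc_recording(
            [synth.SubstanceEffectSpec("x", "decrease", 6.0)],
            2,
            1.0,
            session_layout=[300.0],
            seed=3,
            session_duration=1200.0,
        )
        assert np.allclose(truth.z_latent[:300], 0.0)

    def test_overlapping_applications_rejected(self):
        effs = [synth.SubstanceEffectSpec("a"), synth.SubstanceEffectSpec("b")]
        with pytest.raises(ValueError, match="overlap"):
            synth.generate_yc_recording(
                effs, 2, 1.0, session_layout=[300.0, 350.0], seed=0
            )

    def test_responder_fraction_respected(self):
        eff = synth.SubstanceEffectSpec("x", "increase", 6.0, responder_fraction=0.5)
        _, truth = synth.generate_yc_recording([eff], 400, 1.0, seed=5)
        frac = truth.responders["x"].mean()
        assert frac == pytest.approx(0.5, abs=0.08)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            synth.SubstanceEffectSpec("x", "sideways")
        with pytest.raises(ValueError):
            synth.SubstanceEffectSpec("x", "increase", depth=-1.0)
        with pytest.raises(ValueError):
            synth.SubstanceEffectSpec("x", "increase", 1.0, responder_fraction=1.5)


class TestTstGenerator:
    def test_no_bouts_all_immobile_truth(self):
        _, truth = synth.generate_tst_area_series(60.0, 30.0, seed=0)
        assert truth.immobile.all()

    def test_full_session_bout_no_immobility(self):
        _, truth = synth.generate_tst_area_series(
            60.0, 30.0, struggle_bouts=[(0.0, 60.0)], seed=0
        )
        assert not truth.immobile.any()

    def test_bout_interval_arithmetic(self):
        bouts = [(10.0, 60.0), (120.0, 180.0), (240.0, 330.0)]  # 200 s total
        _, truth = synth.generate_tst_area_series(
            360.0, 30.0, struggle_bouts=bouts, seed=1
        )
        struggle_frames = (~truth.immobile).sum()
        assert struggle_frames == pytest.approx(200.0 * 30.0, abs=3)

    def test_pendulum_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            synth.generate_tst_area_series(60.0, 30.0, pendulum_freq=15.0, seed=0)

    def test_determinism(self):
        a, _ = synth.generate_tst_area_series(60.0, 30.0, seed=9)
        b, _ = synth.generate_tst_area_series(60.0, 30.0, seed=9)
        assert np.array_equal(a.area, b.area)


class TestEegGenerator:
    def test_wake_emg_exceeds_nrem_emg(self):
        w = synth.generate_eeg_emg(["W"] * 20, sample_rate=250.0, seed=5)
        n = synth.generate_eeg_emg(["NR"] * 20, sample_rate=250.0, seed=5)
        rms = lambda x: np.sqrt((x**2).mean())
        assert rms(w[1]) > 2 * rms(n[1])

    def test_nrem_delta_dominates_theta(self):
        from lcpipe import sleep_staging as ss

        eeg, emg, ir, _ = synth.generate_eeg_emg(["NR"] * 20, sample_rate=250.0, seed=6)
        f = ss.epoch_features(eeg, emg, ir, 250.0)
        assert (f["delta_amp"] > f["delta_amp"] * f["theta_ratio"]).all()
        assert (f["theta_ratio"] < 1.0).all()

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            synth.generate_eeg_emg(["W", "Q"], seed=0)

    def test_determinism(self):
        seq = ["W", "NR", "R"] * 5
        a = synth.generate_eeg_emg(seq, seed=2)
        b = synth.generate_eeg_emg(seq, seed=2)
        for xa, xb in zip(a[:3], b[:3]):
            assert np.array_equal(xa, xb)

    def test_markov_sequence_properties(self):
        seq = synth.markov_state_sequence(5000, seed=1)
        assert set(seq) == {"W", "NR", "R"}
        assert seq == synth.markov_state_sequence(5000, seed=1)


class TestPhotometryGenerator:
    def test_zero_artifact_constant_latent_gives_constant_f470(self):
        latent = np.full(120, 3.0)
        raw, _ = synth.generate_photometry_raw(
            latent, np.zeros(120), seed=0, settle=False
        )
        f470, f405 = ph.deinterleave(raw)
        assert np.allclose(f470, f470[0]) and np.allclose(f405, f405[0])

    def test_zero_latent_corrects_to_zero(self, rng):
        art = rng.standard_normal(150)
        raw, _ = synth.generate_photometry_raw(np.zeros(150), art, seed=1)
        f_gc = ph.isosbestic_correct(*ph.deinterleave(raw))
        assert np.abs(f_gc).max() < 1e-9

    def test_operating_points_near_acquisition_voltages(self):
        raw, truth = synth.generate_photometry_raw(
            np.zeros(90), np.zeros(90), seed=0
        )
        assert truth.f470.mean() == pytest.approx(-1.0, abs=0.2)
        assert truth.f405.mean() == pytest.approx(-0.5, abs=0.2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            synth.generate_photometry_raw(np.zeros(10), np.zeros(11), seed=0)

    def test_stream_length_is_cycle_multiple(self):
        raw, _ = synth.generate_photometry_raw(np.zeros(33), np.zeros(33), seed=0)
        assert raw.voltage.size == 33 * 50

    def test_determinism(self):
        lat = np.linspace(0, 1, 60)
        a, _ = synth.generate_photometry_raw(lat, lat, seed=3, noise_sd=0.01)
        b, _ = synth.generate_photometry_raw(lat, lat, seed=3, noise_sd=0.01)
        assert np.array_equal(a.voltage, b.voltage)


class TestClusteredGenerator:
    def test_icc_zero_limit(self):
        from lcpipe import cluster_stats as cs

        est = []
        for r in range(30):
            v, c = synth.generate_clustered_values(20, 50, 0.0, seed=r)
            est.append(cs.icc_oneway(cs.ClusteredSample(v, c)).icc)
        assert abs(np.mean(est)) < 0.02

    def test_icc_one_identical_within_cluster(self):
        v, c = synth.generate_clustered_values(5, 10, 1.0, seed=0)
        for lbl in np.unique(c):
            vals = v[c == lbl]
            assert np.allclose(vals, vals[0])

    def test_invalid_icc_rejected(self):
        with pytest.raises(ValueError, match="icc_true"):
            synth.generate_clustered_values(5, 5, 1.2, seed=0)

    def test_determinism(self):
        a = synth.generate_clustered_values(5, 5, 0.3, seed=4)
        b = synth.generate_clustered_values(5, 5, 0.3, seed=4)
        assert np.array_equal(a[0], b[0])
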