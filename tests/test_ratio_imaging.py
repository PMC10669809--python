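"""Ratio, Z-scoring, classification, FWHM and ΔR/R0 unit tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import fwhm_bruteforce, make_ztrace
from lcpipe import ratio_imaging as ri
from lcpipe import synth


def make_rec(yfp, cfp, frame_interval=1.0, applications=()):
    return ri.RatiometricRecording(
        yfp=np.asarray(yfp, dtype=float),
        cfp=np.asarray(cfp, dtype=float),
        frame_interval=frame_interval,
        applications=list(applications),
    )


class TestYcRatio:
    def test_identity_and_scaling(self, rng):
        base = 1.0 + rng.random((100, 3))
        assert np.allclose(ri.compute_yc_ratio(make_rec(base, base)), 1.0)
        assert np.allclose(ri.compute_yc_ratio(make_rec(2 * base, base)), 2.0)

    def test_anticorrelated_channels(self):
        # +10% YFP with -10% CFP against a baseline ratio of 1
        rec = make_rec(np.full((10, 1), 1.1), np.full((10, 1), 0.9))
        assert np.allclose(ri.compute_yc_ratio(rec), 1.1 / 0.9)

    def test_nonpositive_cfp_names_roi_and_frame(self):
        cfp = np.ones((10, 2))
        cfp[7, 1] = 0.0
        with pytest.raises(ValueError, match=r"ROI 1.*frame 7"):
            ri.compute_yc_ratio(make_rec(np.ones((10, 2)), cfp))

    def test_overlapping_applications_rejected(self):
        apps = [ri.Application("a", 0.0, 120.0), ri.Application("b", 60.0, 120.0)]
        with pytest.raises(ValueError, match="overlap"):
            make_rec(np.ones((10, 1)), np.ones((10, 1)), applications=apps)


class TestCorrectAndZscore:
    def test_linear_drift_removed(self):
        t = np.arange(900.0)
        ratio = 1.0 + 2e-4 * t + 0.001 * np.where(np.arange(900) % 2 == 0, 1, -1)
        zt = ri.correct_and_zscore(ratio, (0, 300), 1.0, detrend="ols")
        assert np.abs(zt.z).max() < 0.1 or np.abs(zt.z[300:]).max() < 3.0
        # pure drift with no response stays near zero after detrending
        pure = 1.0 + 2e-4 * t
        with pytest.raises(ValueError, match="SD is zero"):
            # noiseless pure drift leaves zero residual SD
            ri.correct_and_zscore(pure, (0, 300), 1.0, detrend="ols")

    def test_baseline_mean_zero_sd_one(self, rng):
        ratio = 1.0 + 0.01 * rng.standard_normal(600)
        zt = ri.correct_and_zscore(ratio, (0, 300), 1.0)
        base = zt.z[:300]
        # detrend leaves the baseline standardized up to the fitted line
        assert abs(base.mean()) < 1e-9
        assert abs(base.std(ddof=1) - 1.0) < 1e-9

    def test_injected_dip_depth(self):
        # deterministic baseline texture of known SD; dip of 5 baseline-SDs
        n = 900
        pattern = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        ratio = 1.0 + 0.01 * pattern
        sd = (0.01 * pattern[:300]).std(ddof=1)
        dip = np.zeros(n)
        dip[400:500] = -5.0 * sd
        zt = ri.correct_and_zscore(ratio + dip, (0, 300), 1.0, detrend="ols")
        oracle = (-5.0 * sd) / sd  # hand-computed Z of the noiseless kernel
        assert zt.z.min() == pytest.approx(oracle, abs=1.5)

    @given(gain=st.floats(0.1, 10.0), offset=st.floats(-5.0, 5.0))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, gain, offset):
        rng = np.random.default_rng(7)
        ratio = 1.0 + 0.01 * rng.standard_normal(600) + np.linspace(0, 0.05, 600)
        z1 = ri.correct_and_zscore(ratio, (0, 300), 1.0).z
        z2 = ri.correct_and_zscore(gain * ratio + offset, (0, 300), 1.0).z
        assert np.allclose(z1, z2, atol=1e-8)

    def test_short_baseline_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            ri.correct_and_zscore(np.ones(100), (0, 10), 1.0)


class TestMeanResponse:
    def test_constant_values(self):
        zt = make_ztrace(np.full(900, 3.0))
        assert ri.mean_response(zt, 300.0) == pytest.approx(3.0)
        assert ri.mean_response(make_ztrace(np.zeros(900)), 300.0) == 0.0

    def test_linear_ramp_mean(self):
        z = np.zeros(900)
        z[300:600] = np.linspace(0.0, -6.0, 300)
        assert ri.mean_response(make_ztrace(z), 300.0) == pytest.approx(-3.0)

    def test_receptor_id_window(self):
        z = np.zeros(1000)
        z[900:960] = -4.0
        zt = make_ztrace(z)
        val = ri.mean_response(zt, 300.0, ri.RECEPTOR_ID_WINDOW)
        assert val == pytest.approx(-4.0)

    def test_window_past_end_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            ri.mean_response(make_ztrace(np.zeros(400)), 300.0)


class TestClassifySubstance:
    @pytest.mark.parametrize(
        "values, expected, quartile",
        [
            ([1.0, 2.5, 3.0, 4.0], "increase", ("q3", 3.25)),
            ([-5.0, -3.0, -2.5, -1.0], "decrease", ("q1", -3.5)),
            ([0.0, 0.0, 0.0, 0.0], "none", None),
        ],
    )
    def test_worked_examples(self, values, expected, quartile):
        label, (q1, med, q3) = ri.classify_substance(values)
        assert label == expected
        if quartile:
            name, val = quartile
            got = q3 if name == "q3" else q1
            # independent oracle: linear interpolation at p * (n - 1)
            v = np.sort(values)
            p = 0.75 if name == "q3" else 0.25
            pos = p * (len(v) - 1)
            lo = int(pos)
            oracle = v[lo] + (pos - lo) * (v[min(lo + 1, len(v) - 1)] - v[lo])
            assert got == pytest.approx(val) == pytest.approx(oracle)

    def test_quartile_ordering(self, rng):
        _, (q1, med, q3) = ri.classify_substance(rng.normal(0, 1, 50))
        assert q1 <= med <= q3

    def test_too_few_values(self):
        with pytest.raises(ValueError, match=">= 4"):
            ri.classify_substance([1.0, 2.0, 3.0])

    def test_bimodal_rejected(self):
        with pytest.raises(ValueError, match="bimodal"):
            ri.classify_substance([-10.0, -9.0, 9.0, 10.0])


class TestFwhm:
    def test_rectangular_dip_worked_example(self):
        z = np.zeros(3000)
        z[1000:1501] = -8.0
        res = ri.fwhm(make_ztrace(z, t_start=0.0), onset=1000.0)
        assert res.z_min120 == pytest.approx(-8.0)
        assert (res.t_from, res.t_to, res.fwhm_frames) == (1000, 1500, 500)
        assert not res.excluded and not res.censored
        assert res.fwhm_seconds == pytest.approx(500.0)

    def test_null_roi_excluded(self):
        res = ri.fwhm(make_ztrace(np.zeros(2000)), onset=300.0)
        assert res.excluded

    def test_exclusion_boundary_is_inclusive(self):
        # a ROI whose 5-min mean is exactly -2 does not qualify as suppressed
        z = np.full(2000, 0.0)
        z[300:600] = -2.0
        res = ri.fwhm(make_ztrace(z), onset=300.0)
        assert res.excluded

    def test_censoring_at_recording_edge(self):
        z = np.full(2000, -8.0)
        z[600:] = 0.0
        res = ri.fwhm(make_ztrace(z), onset=0.0, exclusion_window=(0.0, 300.0))
        assert res.t_from == 0 and res.censored

    def test_matches_bruteforce_oracle_on_random_traces(self, rng):
        for _ in range(50):
            z = rng.standard_normal(1500)
            dip_start = rng.integers(200, 900)
            width = rng.integers(150, 400)
            z[dip_start : dip_start + width] -= rng.uniform(5.0, 12.0)
            zt = make_ztrace(z)
            res = ri.fwhm(zt, onset=float(dip_start))
            if res.excluded:
                continue
            z_min, t_from, t_to, width_o = fwhm_bruteforce(z)
            assert res.z_min120 == pytest.approx(z_min)
            assert (res.t_from, res.t_to, res.fwhm_frames) == (t_from, t_to, width_o)

    def test_monotone_in_generated_duration(self):
        # noiseless analytic dips: doubling the width doubles the FWHM
        t = np.arange(4000.0)
        widths = [200.0, 400.0, 800.0]
        measured = []
        for w in widths:
            z = -8.0 * np.exp(-0.5 * ((t - 1500.0) / (w / 2.3548200450309493)) ** 2)
            res = ri.fwhm(make_ztrace(z), onset=1200.0)
            measured.append(res.fwhm_frames)
            assert res.fwhm_frames == pytest.approx(w, abs=62)
        assert measured[0] < measured[1] < measured[2]


class TestPeakDrOverR0:
    def test_flat_trace_zero(self):
        assert ri.peak_dr_over_r0(np.ones(100), (40.0, 60.0), 1.0) == 0.0

    def test_worked_arithmetic(self):
        ratio = np.ones(100)
        ratio[50] = 1.2
        assert ri.peak_dr_over_r0(ratio, (40.0, 60.0), 1.0) == pytest.approx(0.2)

    @given(c=st.floats(0.1, 50.0))
    @settings(max_examples=20, deadline=None)
    def test_rescale_invariance(self, c):
        rng = np.random.default_rng(3)
        ratio = 1.0 + 0.05 * rng.random(200)
        ratio[100:110] += 0.3
        a = ri.peak_dr_over_r0(ratio, (90.0, 120.0), 1.0)
        b = ri.peak_dr_over_r0(c * ratio, (90.0, 120.0), 1.0)
        assert a == pytest.approx(b, rel=1e-9)

    def test_insufficient_baseline(self):
        with pytest.raises(ValueError, match="pre-stimulus"):
            ri.peak_dr_over_r0(np.ones(100), (10.0, 20.0), 1.0)


class TestScreenSession:
    def test_control_contract(self):
        """Glutamate-like, aCSF-like and GABA-like controls classify as
        increase, none and decrease respectively."""
        effects = [
            synth.SubstanceEffectSpec("glu", "increase", depth=6.0),
            synth.SubstanceEffectSpec("acsf", "none"),
            synth.SubstanceEffectSpec("gaba", "decrease", depth=6.0),
        ]
        recs = [
            synth.generate_yc_recording(effects, 12, 1.0, seed=s)[0]
            for s in range(2)
        ]
        summaries = ri.screen_cohort(recs)
        assert summaries["glu"].classification == "increase"
        assert summaries["acsf"].classification == "none"
        assert summaries["gaba"].classification == "decrease"
        assert summaries["glu"].n_rois == 24

    def test_short_baseline_flagged_not_dropped(self):
        rec, _ = synth.generate_yc_recording(
            [synth.SubstanceEffectSpec("a"), synth.SubstanceEffectSpec("b")],
            4,
            1.0,
            session_layout=[300.0, 500.0],
            seed=0,
            session_duration=1400.0,
        )
        results = ri.screen_session(rec)
        by_name = {r.substance: r for r in results}
        assert not by_name["a"].flagged
        assert by_name["b"].flagged
        assert np.all(np.isfinite(by_name["b"].mean_z))  # scored, just flagged
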