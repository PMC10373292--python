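import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rotormap.mea import (
    analyze_electrograms,
    conduction_velocity,
    detect_spikes,
    fridericia,
    measure_fpd,
    paired_drug_delta,
)
from rotormap.synth import electrograms_from_events, plane_wave_spike_times


def plane_egs(v=40.0, n_beats=5, noise=0.0, fpd=190.0, seed=0, grid=(4, 4)):
    st_, pos = plane_wave_spike_times(grid, 1.0, v, n_beats=n_beats, period_ms=800.0)
    dur = st_.max() + 400.0
    return (
        electrograms_from_events(st_, pos, 1.0, dur, fpd_ms=fpd, noise_sd=noise, seed=seed),
        st_,
        pos,
    )


class TestDetectSpikes:
    def test_matches_ground_truth_delays(self):
        egs, st_, _ = plane_egs(noise=0.01)
        times0, _ = detect_spikes(egs.data[:, 0], 1.0)
        times_last, _ = detect_spikes(egs.data[:, -1], 1.0)
        assert len(times0) == len(times_last) == st_.shape[0]
        delays = times_last - times0
        true_delay = st_[0, -1] - st_[0, 0]
        assert np.all(np.abs(delays - true_delay) <= 1.0)  # within one sample

    def test_flat_trace_empty(self):
        t, a = detect_spikes(np.zeros(1000), 1.0)
        assert t.size == 0

    def test_amplitude_scales_with_gain(self):
        e1, *_ = plane_egs()
        st_, pos = plane_wave_spike_times((4, 4), 1.0, 40.0, n_beats=5, period_ms=800.0)
        e2 = electrograms_from_events(st_, pos, 1.0, st_.max() + 400, fpd_ms=190.0, spike_amplitude=2.0)
        _, a1 = detect_spikes(e1.data[:, 0], 1.0)
        _, a2 = detect_spikes(e2.data[:, 0], 1.0)
        assert np.allclose(a2, 2.0 * a1, rtol=1e-6)


class TestMeasureFpd:
    def test_twave_placement_recovered(self):
        egs, st_, _ = plane_egs(noise=0.0, fpd=190.0)
        t0 = st_[0, 0]
        fpd = measure_fpd(egs.data[:, 0], 1.0, t0, next_spike_time_ms=st_[1, 0])
        assert fpd == pytest.approx(190.0, abs=1.0)

    def test_polarity_agnostic(self):
        egs, st_, _ = plane_egs(fpd=190.0)
        inv = -egs.data[:, 0]
        fpd = measure_fpd(inv, 1.0, st_[0, 0], next_spike_time_ms=st_[1, 0])
        assert fpd == pytest.approx(190.0, abs=1.5)

    def test_no_twave_flagged_missing(self):
        rng = np.random.default_rng(0)
        trace = rng.normal(0, 0.01, 2000)
        assert np.isnan(measure_fpd(trace, 1.0, 100.0, next_spike_time_ms=900.0))


class TestFridericia:
    def test_exact_cubes(self):
        assert fridericia(300.0, 1000.0) == pytest.approx(300.0, rel=1e-12)
        assert fridericia(270.0, 729.0) == pytest.approx(300.0, rel=1e-12)
        assert fridericia(300.0, 8000.0) == pytest.approx(150.0, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            fridericia(-1.0, 1000.0)
        with pytest.raises(ValueError):
            fridericia(300.0, 0.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.floats(50.0, 600.0),
        st.floats(200.0, 4000.0),
        st.floats(0.1, 10.0),
    )
    def test_joint_scaling_invariance(self, fpd, rr, g):
        """FPDc is invariant when FPD and RR^(1/3) scale together."""
        a = fridericia(fpd, rr)
        b = fridericia(fpd * g, rr * g**3)
        assert b == pytest.approx(a, rel=1e-9)


class TestConductionVelocity:
    def test_noiseless_plane_wave(self):
        st_, pos = plane_wave_spike_times((4, 4), 1.0, 40.0)
        est = conduction_velocity(st_, pos, 1.0)
        assert est.velocity_cm_s == pytest.approx(40.0, abs=0.5)
        assert est.residual_rms_ms < 1e-9

    def test_rotation_invariance(self):
        rng = np.random.default_rng(1)
        ests = {}
        for ang in (0.0, 45.0):
            st_, pos = plane_wave_spike_times((4, 4), 1.0, 40.0, angle_deg=ang,
                                              n_beats=400, period_ms=700.0)
            noisy = st_ + rng.normal(0, 0.5, st_.shape)
            ests[ang] = conduction_velocity(noisy, pos, 1.0).velocity_cm_s
        assert abs(ests[45.0] / ests[0.0] - 1) < 0.01

    def test_simultaneous_activation_unresolvable(self):
        st_ = np.full((1, 16), 100.0)
        pos = [(r, c) for r in range(4) for c in range(4)]
        est = conduction_velocity(st_, pos, 1.0)
        assert est.flag == "unresolvable" and np.isinf(est.velocity_cm_s)

    def test_collinear_geometry_rejected(self):
        st_ = np.array([[0.0, 2.5, 5.0]])
        with pytest.raises(ValueError):
            conduction_velocity(st_, [(0, 0), (0, 1), (0, 2)], 1.0)

    def test_spike_times_unbiased_through_detection(self):
        """Spike-time estimation bias stays below half a sample across
        noisy synthetic electrograms at SNR >= 10."""
        errs = []
        for seed in range(25):
            egs, st_, _ = plane_egs(noise=0.1, seed=seed, n_beats=4)  # SNR ~ 20
            for e in range(egs.n_electrodes):
                t, _ = detect_spikes(egs.data[:, e], 1.0)
                if len(t) == st_.shape[0]:
                    errs.extend(t - st_[:, e])
        errs = np.asarray(errs)
        assert len(errs) > 500
        assert abs(errs.mean()) < 0.5


class TestAnalyzeElectrograms:
    def test_full_table_and_cv(self):
        egs, st_, _ = plane_egs(noise=0.01, seed=3)
        table, cv = analyze_electrograms(egs)
        assert table["beat"].nunique() == st_.shape[0]
        assert table["fpd_ms"].median() == pytest.approx(190.0, abs=2.0)
        assert table["beat_period_ms"].median() == pytest.approx(800.0, abs=2.0)
        # Fridericia at 0.8 s RR: 190 / 0.8^(1/3)
        assert table["fpdc_ms"].median() == pytest.approx(190.0 / 0.8 ** (1 / 3), abs=3.0)
        assert cv is not None
        assert cv.velocity_cm_s == pytest.approx(40.0, rel=0.05)


class TestPairedDrugDelta:
    def frame(self, scale=1.0):
        return pd.DataFrame(
            {
                "electrode": ["r0c0", "r0c1"],
                "beat_period_ms": [800.0 * scale, 820.0 * scale],
                "fpd_ms": [190.0 * scale, 200.0 * scale],
                "fpdc_ms": [204.0 * scale, 210.0 * scale],
                "spike_amplitude": [1.0 * scale, 1.1 * scale],
            }
        )

    def test_null_effect_is_unity(self):
        out = paired_drug_delta(self.frame(), self.frame(), self.frame(), self.frame())
        for m in ("beat_period_ms", "fpd_ms", "fpdc_ms", "spike_amplitude"):
            assert np.allclose(out[f"{m}_delta"], 1.0)

    def test_halved_beat_period(self):
        post = self.frame()
        post["beat_period_ms"] /= 2
        out = paired_drug_delta(self.frame(), post, self.frame(), self.frame())
        assert np.allclose(out["beat_period_ms_delta"], 0.5)

    def test_vehicle_drift_cancels(self):
        out = paired_drug_delta(self.frame(), self.frame(1.1), self.frame(), self.frame(1.1))
        for m in ("beat_period_ms", "fpd_ms", "fpdc_ms", "spike_amplitude"):
            assert np.allclose(out[f"{m}_delta"], 1.0)

    def test_unmatched_electrodes_listed(self):
        other = self.frame()
        other.loc[1, "electrode"] = "r9c9"
        with pytest.raises(ValueError, match="r9c9"):
            paired_drug_delta(self.frame(), other, self.frame(), self.frame())
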