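import numpy as np
import pandas as pd
import pytest

from rotormap.datatypes import FluorescenceMovie, PhaseMovie
from rotormap.oracles import brute_force_singularities, vortex_phase_field
from rotormap.phase import (
    detect_singularities,
    extract_wavefronts,
    instantaneous_phase,
    ring_offsets,
    rotor_report,
    track_singularities,
)
from tests.conftest import random_vortex_scene


def phase_movie(phase, mask=None, dt=5.0):
    phase = np.asarray(phase, dtype=float)
    mask = np.ones(phase.shape[1:], bool) if mask is None else mask
    return PhaseMovie(phase, dt, mask, np.zeros(phase.shape[0], bool))


class TestInstantaneousPhase:
    fs = 200.0

    def test_phase_slope_matches_frequency(self):
        t = np.arange(0, 10, 1 / self.fs)
        f0 = 2.0
        frames = np.sin(2 * np.pi * f0 * t)[:, None, None] * np.ones((1, 3, 3))
        pm = instantaneous_phase(FluorescenceMovie(frames, 5.0))
        phi = np.unwrap(pm.phase[:, 1, 1])
        mid = slice(200, 1800)
        slope = np.polyfit(t[mid], phi[mid], 1)[0]  # rad/s oracle by linear fit
        assert abs(slope - 2 * np.pi * f0) / (2 * np.pi * f0) < 0.01

    def test_quarter_period_shift_is_half_pi(self):
        t = np.arange(0, 10, 1 / self.fs)
        f0 = 2.0
        frames = np.zeros((t.size, 1, 2))
        frames[:, 0, 0] = np.sin(2 * np.pi * f0 * t)
        frames[:, 0, 1] = np.sin(2 * np.pi * f0 * (t - 1 / (4 * f0)))
        pm = instantaneous_phase(FluorescenceMovie(frames, 5.0))
        d = pm.phase[:, 0, 0] - pm.phase[:, 0, 1]
        d = np.angle(np.exp(1j * d))
        assert abs(np.median(d[200:-200]) - np.pi / 2) < 0.05

    def test_values_wrapped_and_dead_pixels_masked(self):
        frames = np.random.default_rng(0).normal(size=(100, 4, 4))
        frames[:, 0, 0] = 0.0
        pm = instantaneous_phase(FluorescenceMovie(frames, 5.0))
        live = pm.mask
        assert not live[0, 0]
        assert np.all(pm.phase[:, live] > -np.pi) and np.all(pm.phase[:, live] <= np.pi)


class TestDetectSingularities:
    def test_single_vortex_winding_and_position(self):
        phi = vortex_phase_field((64, 64), [(30.0, 30.0)], [1])
        out = detect_singularities(phi, subpixel=True)
        assert len(out) == 1
        ps = out[0]
        assert np.hypot(ps.row - 30, ps.col - 30) <= 1.0
        assert ps.chirality == 1
        assert abs(abs(ps.score_inner) - 2 * np.pi) < 0.1
        assert abs(abs(ps.score_outer) - 2 * np.pi) < 0.1

    def test_planar_ramp_no_detection(self):
        cols = np.arange(64)[None, :] * 0.2
        phi = np.angle(np.exp(1j * (cols + np.zeros((64, 64)))))
        assert detect_singularities(phi) == []

    def test_vortex_antivortex_pair(self):
        phi = vortex_phase_field((64, 64), [(32.0, 20.0), (32.0, 40.0)], [1, -1])
        out = detect_singularities(phi, subpixel=True)
        assert len(out) == 2
        assert sorted(p.chirality for p in out) == [-1, 1]
        assert sum(p.chirality for p in out) == 0  # topological charge balance

    def test_matches_brute_force_oracle_on_random_scenes(self):
        rng = np.random.default_rng(99)
        for _ in range(8):
            centers, chis = random_vortex_scene(rng)
            phi = vortex_phase_field((64, 64), centers, chis, offset=rng.uniform(-3, 3))
            oracle = brute_force_singularities(phi)
            det = detect_singularities(phi, subpixel=True)
            assert len(det) == len(oracle) == len(centers)
            for orow, ocol, ochi in oracle:
                dists = [np.hypot(p.row - orow, p.col - ocol) for p in det]
                j = int(np.argmin(dists))
                assert dists[j] <= 1.0 and det[j].chirality == ochi

    def test_mask_suppresses_detection(self):
        phi = vortex_phase_field((64, 64), [(30.0, 30.0)], [1])
        mask = np.ones((64, 64), bool)
        mask[28:33, 28:33] = False  # rings touch masked pixels -> skipped
        assert detect_singularities(phi, mask=mask) == []

    def test_ring_offsets_closed_and_ordered(self):
        for r in (2, 4):
            off = ring_offsets(r)
            ang = np.arctan2(off[:, 0], off[:, 1])
            assert np.all(np.diff(ang) > 0)
            assert np.allclose(np.hypot(off[:, 0], off[:, 1]), r, atol=0.5)


class TestTracking:
    def detections(self, rows):
        return pd.DataFrame(rows, columns=["frame", "row", "col", "chirality"]).assign(
            score_inner=2 * np.pi, score_outer=2 * np.pi
        )

    def test_stationary_track_lifetime(self):
        det = self.detections([(f, 10.0, 10.0, 1) for f in range(20)])
        tracks = track_singularities(det, 5.0)
        assert len(tracks) == 1
        assert tracks[0].lifetime_ms == 19 * 5.0
        assert tracks[0].mean_step_px == 0.0

    def test_large_jump_splits_track(self):
        det = self.detections(
            [(f, 10.0, 10.0, 1) for f in range(10)]
            + [(f, 10.0, 10.0 + 30.0, 1) for f in range(10, 20)]
        )
        tracks = track_singularities(det, 5.0, max_link_px=10.0)
        assert len(tracks) == 2

    def test_gap_bridging(self):
        det = self.detections([(f, 5.0, 5.0, -1) for f in (0, 1, 2, 5, 6)])
        tracks = track_singularities(det, 5.0, max_gap_frames=2)
        assert len(tracks) == 1 and tracks[0].lifetime_ms == 30.0

    def test_crossing_opposite_chirality_never_swap(self):
        rows = []
        for f in range(11):
            rows.append((f, 10.0, 10.0 + f, 1))      # moving right
            rows.append((f, 10.0, 20.0 - f, -1))     # moving left, crosses at f=5
        tracks = track_singularities(self.detections(rows), 5.0, max_link_px=5.0)
        assert len(tracks) == 2
        for tr in tracks:
            assert tr.points["chirality"].nunique() == 1
            assert len(tr.points) == 11


class TestWavefrontsAndReport:
    def test_empty_phase_movie_no_fronts(self):
        pm = phase_movie(np.full((10, 16, 16), np.nan), mask=np.zeros((16, 16), bool))
        assert extract_wavefronts(pm) == []

    def test_plane_wave_single_front_lifetime(self):
        # a single activation front sweeping the field at v px/frame
        # (wavelength exceeds the field) survives as one linked wavefront
        # for ~width/v frames (kinematic oracle)
        h = w = 48
        v = 2.0  # px / frame
        k = 2 * np.pi / 160.0  # wavelength > field width -> one front
        n = int(np.ceil(w / v)) + 4
        cols = np.arange(w)[None, :] * np.ones((h, 1))
        frames = [
            np.angle(np.exp(1j * (k * (cols - v * f) + np.pi / 2))) for f in range(n)
        ]
        pm = phase_movie(np.array(frames))
        fronts = extract_wavefronts(pm, phi_act=np.pi / 2, min_size=4)
        assert len(fronts) == 1
        expect = np.ceil(w / v)
        assert abs(fronts[0].lifetime_ms / pm.frame_interval_ms - expect) <= 2
        assert fronts[0].death_cause == "boundary"

    def test_report_mean_sd_arithmetic(self):
        det = pd.DataFrame(
            [(0, 1.0, 1.0, 1, 7.0, 7.0)],
            columns=["frame", "row", "col", "chirality", "score_inner", "score_outer"],
        )
        t1 = track_singularities(
            pd.DataFrame(
                [(f, 1.0, 1.0, 1) for f in range(201)],
                columns=["frame", "row", "col", "chirality"],
            ),
            5.0,
        )
        t2 = track_singularities(
            pd.DataFrame(
                [(f, 30.0, 30.0, -1) for f in range(401)],
                columns=["frame", "row", "col", "chirality"],
            ),
            5.0,
        )
        rep = rotor_report(t1 + t2, [], det)
        assert rep["track_count"] == 2
        assert rep["singularity_lifetime_ms_mean"] == pytest.approx(1500.0)
        assert rep["singularity_lifetime_ms_sd"] == pytest.approx(707.1, abs=0.05)
        assert rep["total_ps_detections"] == 1

    def test_no_detections_empty_report(self):
        rep = rotor_report([], [], pd.DataFrame(columns=["frame", "row", "col", "chirality"]))
        assert rep["track_count"] == 0
        assert rep["singularity_lifetime_ms_mean"] == 0.0


class TestSpiralEndToEnd:
    def test_front_attached_to_singularity(self, spiral_run):
        """On a stationary rotor, an activation wavefront pixel lies within
        r_outer+1 of the detected PS in >= 90% of frames with a detection."""
        pm, det = spiral_run["pm"], spiral_run["detections"]
        fronts = extract_wavefronts(pm, ps_detections=det)
        frame_pix: dict[int, list] = {}
        for fr in fronts:
            for f, comp in zip(fr.frames, fr.components):
                frame_pix.setdefault(f, []).append(comp)
        ok = tot = 0
        for f, grp in det.groupby("frame"):
            if f not in frame_pix:
                continue
            allpix = np.vstack(frame_pix[f])
            for _, r in grp.iterrows():
                tot += 1
                ok += np.min(np.hypot(allpix[:, 0] - r.row, allpix[:, 1] - r.col)) <= 5.0
        assert tot > 100
        assert ok / tot >= 0.9

    def test_single_chirality_matches_oracle(self, spiral_run):
        det = spiral_run["detections"]
        oracle_chi = spiral_run["truth"].tip_trajectory["chirality"].mode()[0]
        assert det["chirality"].mode()[0] == oracle_chi
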