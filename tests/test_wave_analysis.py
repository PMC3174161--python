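"""Tip / filament detectors and trajectory analysis on analytic fixtures."""

import numpy as np
import pytest

from borderzone.synthetic import make_synthetic_fields
from borderzone import wave_analysis as wa


class TestDetectTips:
    def test_linear_planes_exact(self):
        v, f, v_iso, f_iso = make_synthetic_fields(
            "linear-planes", nx=20, ny=20, x0=7.3, y0=11.6)
        tips = wa.detect_tips(v, f, v_iso, f_iso)
        assert len(tips) == 1
        assert tips[0].x == pytest.approx(7.3, abs=1e-12)
        assert tips[0].y == pytest.approx(11.6, abs=1e-12)

    def test_disjoint_isolines_empty(self):
        v = np.zeros((10, 10))
        f = np.ones((10, 10))
        assert wa.detect_tips(v, f, 5.0, 0.5) == []

    def test_spiral_tip_rotation_invariant(self):
        x0, y0 = 20.4, 21.7
        pos = []
        for phase in (0.0, 1.3, 2.7, 4.1):
            v, f, vi, fi = make_synthetic_fields(
                "spiral", nx=41, ny=41, x0=x0, y0=y0, phase=phase)
            tips = wa.detect_tips(v, f, vi, fi)
            assert len(tips) == 1
            pos.append((tips[0].x, tips[0].y))
        pos = np.asarray(pos)
        assert np.all(np.abs(pos[:, 0] - x0) < 0.1)
        assert np.all(np.abs(pos[:, 1] - y0) < 0.1)

    def test_mirror_flips_chirality(self):
        v, f, vi, fi = make_synthetic_fields("spiral", nx=41, ny=41,
                                             x0=20.2, y0=20.6)
        t1 = wa.detect_tips(v, f, vi, fi)
        t2 = wa.detect_tips(v[:, ::-1], f[:, ::-1], vi, fi)
        assert len(t1) == len(t2) == 1
        assert t1[0].chirality == -t2[0].chirality

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            wa.detect_tips(np.zeros((5, 5)), np.zeros((4, 5)), 0, 0)


class TestExtractFilaments:
    def test_extruded_spiral_straight(self):
        v, f, vi, fi = make_synthetic_fields(
            "extruded-spiral", nx=31, ny=31, nz=12, x0=15.2, y0=15.7)
        fils = wa.extract_filaments(v, f, vi, fi)
        assert len(fils) == 1
        fil = fils[0]
        # straight filament: length equals the box height within one cell
        assert fil.length == pytest.approx(11.0, abs=1.0)
        # projection onto (x, y) stays within one cell of the 2D tip
        assert np.all(np.abs(fil.points[:, 0] - 15.2) < 1.0)
        assert np.all(np.abs(fil.points[:, 1] - 15.7) < 1.0)

    def test_scroll_ring_length(self):
        r = 8.0
        v, f, vi, fi = make_synthetic_fields(
            "scroll-ring", nx=41, ny=41, nz=14, x0=20.0, y0=20.0,
            z0=6.5, ring_radius=r)
        fils = wa.extract_filaments(v, f, vi, fi)
        assert len(fils) == 1
        assert fils[0].closed
        assert fils[0].length == pytest.approx(2 * np.pi * r,
                                               rel=0.05)

    def test_quiescent_empty(self):
        v = np.full((10, 10, 5), -80.0)
        f = np.ones((10, 10, 5))
        assert wa.extract_filaments(v, f, -30.0, 0.5) == []


def _cycloid_track(v0=0.0 + 0.0j, radius=5.0, period=100.0,
                   t_end=1000.0, dt=2.0, jitter=0.0, seed=0):
    t = np.arange(0.0, t_end, dt)
    z = (20 + 20j) + v0 * t + radius * np.exp(2j * np.pi * t / period)
    if jitter:
        rng = np.random.default_rng(seed)
        z = z + jitter * (rng.standard_normal(len(t))
                          + 1j * rng.standard_normal(len(t)))
    return wa.TipTrajectory(t=t, x=z.real, y=z.imag, chirality=1)


class TestDriftVelocity:
    def test_closed_circle_zero_velocity(self):
        est = wa.drift_velocity(_cycloid_track())
        assert abs(est.velocity) < 1e-10
        assert est.period == pytest.approx(100.0, rel=0.02)

    def test_cycloid_recovers_translation(self):
        v0 = 0.004 - 0.002j
        est = wa.drift_velocity(_cycloid_track(v0=v0))
        assert abs(est.velocity - v0) < 0.01 * abs(v0) + 1e-6

    def test_jittered_cycloid_within_uncertainty(self):
        # Monte-Carlo calibration: the reported sigma should cover the
        # actual error in most of 20 jittered realizations
        v0 = 0.004 - 0.002j
        hits = 0
        for seed in range(20):
            tr = _cycloid_track(v0=v0, jitter=0.1, seed=seed)
            est = wa.drift_velocity(tr)
            if abs(est.velocity - v0) < 3 * est.uncertainty:
                hits += 1
        assert hits >= 18

    def test_too_short_rejected(self):
        tr = _cycloid_track(t_end=220.0)
        with pytest.raises(ValueError):
            wa.drift_velocity(tr, period=100.0)


class TestLinkTracks:
    def test_two_parallel_tracks(self):
        frames = []
        for k in range(50):
            t = float(k)
            tips = [wa.TipPoint(x=10 + 0.1 * k, y=10.0, chirality=1, t=t),
                    wa.TipPoint(x=30 - 0.1 * k, y=20.0, chirality=-1, t=t)]
            frames.append((t, tips))
        tracks = wa.link_tracks(frames)
        assert len(tracks) == 2
        assert {tr.chirality for tr in tracks} == {1, -1}
        assert all(len(tr.t) == 50 for tr in tracks)

    def test_gap_bridging(self):
        frames = []
        for k in range(40):
            tips = ([] if 18 <= k < 21 else
                    [wa.TipPoint(x=10 + 0.1 * k, y=5.0, chirality=1)])
            frames.append((float(k), tips))
        tracks = wa.link_tracks(frames)
        assert len(tracks) == 1
        assert len(tracks[0].t) == 37


class TestClassifyRegime:
    def test_quiescent(self):
        assert wa.classify_regime(np.zeros((5, 5), int),
                                  stimulated=False) == "quiescent"

    def test_focal_needs_spread(self):
        counts = np.zeros((5, 5), int)
        counts[2, 2] = 3
        counts[2, 3] = 2
        assert wa.classify_regime(counts, stimulated=False) == "focal"

    def test_stimulated_is_propagating_only(self):
        counts = np.ones((5, 5), int)
        assert wa.classify_regime(counts,
                                  stimulated=True) == "propagating-only"


class TestCountSpirals:
    def test_empty(self):
        assert wa.count_spirals([], t_after=100.0, period=50.0) == 0

    def test_persistent_vs_transient(self):
        long_tr = _cycloid_track(t_end=1000.0)
        short = wa.TipTrajectory(t=np.array([500.0, 510.0, 520.0]),
                                 x=np.zeros(3), y=np.zeros(3))
        n = wa.count_spirals([long_tr, short], t_after=400.0, period=100.0)
        assert n == 1
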