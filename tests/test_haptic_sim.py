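"""Force rendering, cycloidal guidance, exploration dynamics, kinematics."""

import numpy as np
import pytest

from hapticstim import haptic_sim as sim
from hapticstim import trial_design as td


class TestGratingForce:
    def test_quarter_period_reaches_amplitude(self):
        f = 164.0
        y = 1.0 / (4.0 * f)  # quarter spatial period
        assert sim.grating_force(y, f, C=3.0) == pytest.approx(3.0, abs=1e-12)

    def test_zero_at_origin(self):
        assert sim.grating_force(0.0, 120.0) == 0.0

    def test_dense_grid_maximum(self):
        f = 120.0
        y = np.linspace(0.0, 1.0 / f, 10_000)
        assert np.max(np.abs(sim.grating_force(y, f, C=3.0))) == pytest.approx(3.0, abs=1e-6)

    def test_amplitude_never_exceeds_C(self, rng):
        y = rng.uniform(-1.0, 1.0, 5000)
        f = rng.uniform(50.0, 300.0, 5000)
        assert np.all(np.abs(sim.grating_force(y, f, C=3.0)) <= 3.0 + 1e-12)


class TestTableForce:
    def test_printed_gains_at_floor(self):
        scene = sim.SceneParams()
        assert sim.table_force(0.0, 0.0, scene) == pytest.approx(1960 * 0.001)

    def test_zero_above_table(self):
        scene = sim.SceneParams()
        assert sim.table_force(0.002, -0.3, scene) == 0.0

    def test_hand_evaluated_penetration(self):
        scene = sim.SceneParams()
        z = scene.z_table - 1e-3
        expected = 1960 * 1e-3 + 28 * 0.01
        assert sim.table_force(z, -0.01, scene) == pytest.approx(expected)

    def test_continuous_at_surface_when_static(self):
        scene = sim.SceneParams()
        eps = 1e-12
        below = sim.table_force(scene.z_table - eps, 0.0, scene)
        above = sim.table_force(scene.z_table + eps, 0.0, scene)
        assert abs(below - above) < 1e-6


class TestCycloid:
    def test_boundary_conditions(self):
        for t, expected in ((0.0, (0.1, 0.0, 0.0)), (2.0, (0.3, 0.0, 0.0))):
            p, v, a = sim.cycloidal_reference(0.1, 0.3, 2.0, t)
            assert (p, v, a) == pytest.approx(expected, abs=1e-12)

    def test_midpoint_and_peak_velocity(self):
        y0, y1, T = 0.0, 0.18, 1.2
        p, v, _ = sim.cycloidal_reference(y0, y1, T, T / 2)
        assert p == pytest.approx((y0 + y1) / 2)
        assert v == pytest.approx(2 * (y1 - y0) / T)

    def test_velocity_matches_finite_difference(self):
        t = np.linspace(0.01, 1.19, 500)
        h = 1e-7
        _, v, a = sim.cycloidal_reference(0.0, 0.18, 1.2, t)
        p_hi, _, _ = sim.cycloidal_reference(0.0, 0.18, 1.2, t + h)
        p_lo, _, _ = sim.cycloidal_reference(0.0, 0.18, 1.2, t - h)
        num_v = (p_hi - p_lo) / (2 * h)
        assert np.allclose(v, num_v, rtol=1e-6, atol=1e-8)
        v_hi = sim.cycloidal_reference(0.0, 0.18, 1.2, t + h)[1]
        v_lo = sim.cycloidal_reference(0.0, 0.18, 1.2, t - h)[1]
        assert np.allclose(a, (v_hi - v_lo) / (2 * h), rtol=1e-5, atol=1e-6)

    def test_invalid_duration_rejected(self):
        with pytest.raises(ValueError):
            sim.cycloidal_reference(0.0, 0.1, 0.0, 0.0)


def _tiny_schedule(n_trials=2):
    trials = [
        td.TrialSpec(i, "pre", 0, ("St", "Co", "Co"), 1, 120.0, 164.0)
        for i in range(n_trials)
    ]
    return td.SessionSchedule(trials=trials)


class TestExploration:
    def test_guidance_tracks_reference(self):
        scene, guid = sim.SceneParams(), sim.GuidanceParams()
        traces = sim.simulate_exploration(_tiny_schedule(), scene, guid, seed=2)
        _, y_ref, _, _ = sim.reference_trajectory(scene, guid, 1000.0)
        for tr in traces:
            assert np.max(np.abs(y_ref - tr.y)) < 0.01

    def test_zero_gains_stationary(self):
        scene = sim.SceneParams()
        guid = sim.GuidanceParams(K_hg=0.0, B_hg=0.0)
        hand = sim.HandParams(noise_force=0.0, press_force=0.0)
        tr = sim.simulate_exploration(_tiny_schedule(1), scene, guid, seed=0,
                                      hand=hand)[0]
        assert np.max(np.abs(tr.y - tr.y[0])) == 0.0

    def test_total_force_decomposes(self):
        tr = sim.simulate_exploration(_tiny_schedule(1), seed=4)[0]
        assert np.array_equal(tr.F_total_y, tr.F_grating + tr.F_guidance)
        assert np.array_equal(tr.F_total_z, tr.F_table)
        # Contact gating of the scene forces.
        off = ~tr.in_contact
        assert np.all(tr.F_table[off] == 0.0)
        assert np.all(tr.F_guidance[off] == 0.0)
        assert np.all(tr.F_grating[tr.region < 0] == 0.0)

    @pytest.mark.parametrize("mass", [0.5, 1.0, 2.0])
    def test_stable_tracking_across_hand_masses(self, mass):
        scene, guid = sim.SceneParams(), sim.GuidanceParams()
        hand = sim.HandParams(mass=mass)
        tr = sim.simulate_exploration(_tiny_schedule(1), scene, guid, seed=6, hand=hand)[0]
        _, y_ref, _, _ = sim.reference_trajectory(scene, guid, 1000.0)
        assert np.max(np.abs(y_ref - tr.y)) < 0.05  # bounded, no runaway
        assert np.max(np.abs(tr.vy)) < 2.0


def _synthetic_trace(t, y, region, fs):
    vy = np.gradient(y, 1.0 / fs)
    zeros = np.zeros_like(t)
    return sim.ExplorationTrace(
        t=t, y=y, z=zeros, vy=vy, vz=zeros,
        F_grating=zeros, F_table=zeros, F_guidance=zeros,
        in_contact=np.ones_like(t, dtype=bool), region=region,
    )


class TestKinematicMetrics:
    def test_constant_speed_single_texture(self):
        fs = 1000.0
        t = np.arange(int(fs)) / fs
        y = 0.05 * t  # 0.05 m/s across a 0.05 m texture
        tr = _synthetic_trace(t, y, np.zeros(t.size, dtype=int), fs)
        m = sim.kinematic_metrics(tr)
        assert m["scanning_time"] == pytest.approx(1.0, rel=1e-2)
        assert m["path_length"] == pytest.approx(0.05, rel=1e-2)
        assert m["scanning_speed"] == pytest.approx(0.05, rel=1e-2)

    def test_below_speed_floor_is_missing(self):
        fs = 1000.0
        t = np.arange(500) / fs
        y = 0.001 * t  # 1 mm/s, below the 0.01 m/s floor
        tr = _synthetic_trace(t, y, np.zeros(t.size, dtype=int), fs)
        m = sim.kinematic_metrics(tr)
        assert all(np.isnan(v) for v in m.values())

    def test_piecewise_speeds_hand_computed(self):
        fs = 1000.0
        # 0.5 s at 0.04 m/s on texture 0, 0.5 s at 0.08 m/s on texture 1.
        t = np.arange(1000) / fs
        y = np.where(t < 0.5, 0.04 * t, 0.02 + 0.08 * (t - 0.5))
        region = np.where(t < 0.5, 0, 1)
        tr = _synthetic_trace(t, y, region, fs)
        m = sim.kinematic_metrics(tr)
        assert m["scanning_time"] == pytest.approx(0.5, rel=2e-2)
        assert m["path_length"] == pytest.approx((0.02 + 0.04) / 2, rel=2e-2)
        assert m["scanning_speed"] == pytest.approx((0.04 + 0.08) / 2, rel=2e-2)

    def test_invariant_to_resampling(self):
        tr = sim.simulate_exploration(_tiny_schedule(1), seed=9)[0]
        m1 = sim.kinematic_metrics(tr)
        t2 = np.arange(tr.t[0], tr.t[-1], 1.0 / (2 * tr.fs))

        def up(a):
            return np.interp(t2, tr.t, a)

        tr2 = sim.ExplorationTrace(
            t=t2, y=up(tr.y), z=up(tr.z), vy=up(tr.vy), vz=up(tr.vz),
            F_grating=up(tr.F_grating), F_table=up(tr.F_table),
            F_guidance=up(tr.F_guidance),
            in_contact=up(tr.in_contact.astype(float)) > 0.5,
            region=np.round(up(tr.region.astype(float))).astype(int),
        )
        m2 = sim.kinematic_metrics(tr2)
        for k in m1:
            assert m2[k] == pytest.approx(m1[k], rel=1e-2)
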