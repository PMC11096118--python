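"""Virtual-texture force rendering and guided-exploration simulation.

The haptic scene is planar (y: lateral, along the gratings; z: vertical).
Three force components act on the hand/end-effector:

* grating force  F_g = C * sin(2*pi*f*y)  while in contact inside a texture,
* virtual-table penalty  F_z = K_z*(z_tbl - z) - B_z*vz  while z < z_tbl,
* haptic-guidance PD force
  F_hg = a_R + B_hg*(v_R - vy) + K_hg*(y_R - y)  while in contact,

where (y_R, v_R, a_R) follow a cycloidal motion law sweeping each of the
three texture regions in turn.  The hand is a point mass with viscous
damping representing passive arm impedance; integration is fixed-step
semi-implicit Euler at the haptic control rate.  No forces act along x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import stream
from .errors import SimulationError


def _default_regions() -> tuple[tuple[float, float], ...]:
    # Three equal-width texture bands along the 0.20 m table with 0.01 m gaps.
    width = (0.20 - 2 * 0.01) / 3
    r = []
    y = 0.0
    for _ in range(3):
        r.append((y, y + width))
        y += width + 0.01
    return tuple(r)


@dataclass(frozen=True)
class SceneParams:
    """Haptic scene: grating constant, virtual table gains, texture layout."""

    C: float = 3.0  # grating force constant (N)
    K_z: float = 1960.0  # table stiffness (N/m)
    B_z: float = 28.0  # table damping (N*s/m)
    z_table: float = 0.001  # table height (m)
    table_size: tuple[float, float] = (0.20, 0.10)  # length x width (m)
    texture_regions: tuple[tuple[float, float], ...] = field(
        default_factory=_default_regions
    )

    def __post_init__(self) -> None:
        lo, hi = 0.0, self.table_size[0]
        spans = sorted(self.texture_regions)
        for (a, b) in spans:
            if not (lo - 1e-12 <= a < b <= hi + 1e-12):
                raise ValueError("texture region outside table footprint")
        for (_, b0), (a1, _) in zip(spans, spans[1:]):
            if a1 < b0:
                raise ValueError("texture regions overlap")

    def region_of(self, y: float | np.ndarray):
        """Texture index at lateral position y, or -1 outside all regions."""
        y = np.asarray(y)
        out = np.full(y.shape, -1, dtype=int)
        for i, (a, b) in enumerate(self.texture_regions):
            out = np.where((y >= a) & (y <= b), i, out)
        return out if out.ndim else int(out)


@dataclass(frozen=True)
class GuidanceParams:
    """PD haptic-guidance gains and sweep timing."""

    K_hg: float = 300.0  # guidance stiffness (N/m)
    B_hg: float = 60.0  # guidance damping (N*s/m)
    sweep_duration: float = 1.2  # seconds per texture pass


@dataclass(frozen=True)
class HandParams:
    """Point-mass hand/end-effector model with passive viscous damping."""

    mass: float = 1.0  # kg
    damping: float = 5.0  # N*s/m, passive arm impedance
    press_force: float = 3.0  # N, steady downward push keeping contact
    noise_force: float = 0.2  # N RMS, per-trial compliance noise


@dataclass
class ExplorationTrace:
    """Uniformly sampled kinematics of one trial's exploration."""

    t: np.ndarray  # s
    y: np.ndarray  # m
    z: np.ndarray  # m
    vy: np.ndarray  # m/s
    vz: np.ndarray  # m/s
    F_grating: np.ndarray  # N (lateral)
    F_table: np.ndarray  # N (vertical)
    F_guidance: np.ndarray  # N (lateral)
    in_contact: np.ndarray  # bool
    region: np.ndarray  # texture index, -1 when not on a texture or no contact

    @property
    def fs(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])

    @property
    def F_total_y(self) -> np.ndarray:
        return self.F_grating + self.F_guidance

    @property
    def F_total_z(self) -> np.ndarray:
        return self.F_table


def grating_force(y, f: float, C: float = 3.0):
    """Lateral grating force C*sin(2*pi*f*y); contact gating is the caller's."""
    return C * np.sin(2.0 * np.pi * f * np.asarray(y, dtype=float))


def table_force(z, vz, scene: SceneParams):
    """Vertical virtual-table penalty force; zero above the table surface."""
    z = np.asarray(z, dtype=float)
    vz = np.asarray(vz, dtype=float)
    force = scene.K_z * (scene.z_table - z) - scene.B_z * vz
    return np.where(z < scene.z_table, force, 0.0)


def cycloidal_reference(y0: float, y1: float, T: float, t):
    """Cycloidal motion law from y0 to y1 over duration T.

    Returns (position, velocity, acceleration) at time(s) ``t``; velocity
    and acceleration vanish at both endpoints, giving jerk-limited sweeps.
    """
    if T <= 0:
        raise ValueError("sweep duration must be positive")
    t = np.asarray(t, dtype=float)
    tau = t / T
    h = y1 - y0
    pos = y0 + h * (tau - np.sin(2 * np.pi * tau) / (2 * np.pi))
    vel = h / T * (1.0 - np.cos(2 * np.pi * tau))
    acc = h * 2 * np.pi / T**2 * np.sin(2 * np.pi * tau)
    return pos, vel, acc


def reference_trajectory(scene: SceneParams, guidance: GuidanceParams, fs: float):
    """The guidance reference (t, y_R, v_R, a_R) for one trial's sweeps."""
    return _sweep_plan(scene, guidance, fs)


def _sweep_plan(scene: SceneParams, guidance: GuidanceParams, fs: float):
    """Reference trajectory sweeping each texture left-to-right in turn,
    with cycloidal transitions across the inter-texture gaps."""
    segments = []  # (y0, y1, T)
    regions = sorted(scene.texture_regions)
    y_prev = regions[0][0]
    for i, (a, b) in enumerate(regions):
        if a != y_prev:
            segments.append((y_prev, a, 0.3))  # quick gap transition
        segments.append((a, b, guidance.sweep_duration))
        y_prev = b
    ts, ys, vs, acs = [], [], [], []
    t0 = 0.0
    for (a, b, T) in segments:
        n = max(int(round(T * fs)), 2)
        tt = np.arange(n) / fs
        p, v, ac = cycloidal_reference(a, b, T, tt)
        ts.append(t0 + tt)
        ys.append(p)
        vs.append(v)
        acs.append(ac)
        t0 += n / fs
    return np.concatenate(ts), np.concatenate(ys), np.concatenate(vs), np.concatenate(acs)


def simulate_exploration(
    schedule,
    scene: SceneParams = SceneParams(),
    guidance: GuidanceParams = GuidanceParams(),
    seed: int = 0,
    *,
    hand: HandParams = HandParams(),
    fs: float = 1000.0,
    phases=("pre", "intervention", "post"),
) -> list[ExplorationTrace]:
    """Simulate the guided exploration for every trial of a schedule.

    Returns one :class:`ExplorationTrace` per non-familiarization trial (in
    schedule order).  The seed drives small per-trial compliance noise of
    the simulated hand; everything else is deterministic.
    """
    trials = [t for t in schedule.trials if t.phase in phases]
    if not trials:
        return []
    freqs = np.array([t.frequencies() for t in trials])  # (m, 3)
    rng = stream(seed, "exploration")
    return _simulate_batch(freqs, scene, guidance, hand, fs, rng)


def _simulate_batch(freqs, scene, guidance, hand, fs, rng) -> list[ExplorationTrace]:
    """Integrate all m trials simultaneously (the time loop is the only
    sequential dependency; state updates vectorize across trials)."""
    t_ref, y_ref, v_ref, a_ref = _sweep_plan(scene, guidance, fs)
    m = freqs.shape[0]
    n = t_ref.size
    dt = 1.0 / fs
    y = np.empty((m, n))
    z = np.empty((m, n))
    vy = np.empty((m, n))
    vz = np.empty((m, n))
    Fg = np.empty((m, n))
    Ft = np.empty((m, n))
    Fh = np.empty((m, n))
    contact = np.empty((m, n), dtype=bool)
    region = np.empty((m, n), dtype=int)
    # Start resting on the table at the first reference point.
    yi = np.full(m, float(y_ref[0]))
    zi = np.full(m, scene.z_table - hand.press_force / scene.K_z)
    vyi = np.zeros(m)
    vzi = np.zeros(m)
    noise = hand.noise_force * rng.standard_normal((m, n))
    limit_lo = -0.05
    limit_hi = scene.table_size[0] + 0.05
    bounds = np.array(sorted(scene.texture_regions))  # (3, 2)
    starts, stops = bounds[:, 0], bounds[:, 1]
    trial_rows = np.arange(m)
    for i in range(n):
        in_contact = zi < scene.z_table
        idx = np.searchsorted(starts, yi, side="right") - 1
        reg = np.where(
            in_contact & (idx >= 0) & (yi <= stops[np.clip(idx, 0, 2)]), idx, -1
        )
        f_trial = freqs[trial_rows, np.clip(reg, 0, 2)]
        f_grating = np.where(
            reg >= 0, scene.C * np.sin(2 * np.pi * f_trial * yi), 0.0
        )
        f_table = np.where(
            in_contact, scene.K_z * (scene.z_table - zi) - scene.B_z * vzi, 0.0
        )
        f_guidance = np.where(
            in_contact,
            a_ref[i] + guidance.B_hg * (v_ref[i] - vyi) + guidance.K_hg * (y_ref[i] - yi),
            0.0,
        )
        y[:, i], z[:, i], vy[:, i], vz[:, i] = yi, zi, vyi, vzi
        Fg[:, i], Ft[:, i], Fh[:, i] = f_grating, f_table, f_guidance
        contact[:, i], region[:, i] = in_contact, reg
        # Semi-implicit Euler: velocities first, then positions.
        ay = (f_grating + f_guidance - hand.damping * vyi + noise[:, i]) / hand.mass
        az = (f_table - hand.press_force - hand.damping * vzi) / hand.mass
        vyi = vyi + ay * dt
        vzi = vzi + az * dt
        yi = yi + vyi * dt
        zi = zi + vzi * dt
        if np.any((yi < limit_lo) | (yi > limit_hi)):
            raise SimulationError(
                f"end-effector left the workspace at t={i * dt:.3f}s"
            )
    return [
        ExplorationTrace(
            t=t_ref, y=y[k], z=z[k], vy=vy[k], vz=vz[k],
            F_grating=Fg[k], F_table=Ft[k], F_guidance=Fh[k],
            in_contact=contact[k], region=region[k],
        )
        for k in range(m)
    ]


def kinematic_metrics(trace: ExplorationTrace, speed_floor: float = 0.01):
    """Scanning time, path length and scanning speed of one trial.

    A sample qualifies when the hand is in contact with a texture and moving
    laterally faster than ``speed_floor``.  Scanning time and path length
    are averaged over the three textures; scanning speed is the mean |vy|
    over all qualifying samples.  With no qualifying samples the metrics are
    missing (NaN), not zero.
    """
    qualifying = trace.in_contact & (trace.region >= 0) & (np.abs(trace.vy) > speed_floor)
    if not np.any(qualifying):
        return {"scanning_time": np.nan, "path_length": np.nan, "scanning_speed": np.nan}
    dt = 1.0 / trace.fs
    regions = np.unique(trace.region[qualifying])
    times, paths = [], []
    dy = np.abs(np.diff(trace.y, prepend=trace.y[0]))
    for r in regions:
        m = qualifying & (trace.region == r)
        times.append(np.sum(m) * dt)
        paths.append(np.sum(dy[m]))
    return {
        "scanning_time": float(np.mean(times)),
        "path_length": float(np.mean(paths)),
        "scanning_speed": float(np.mean(np.abs(trace.vy[qualifying]))),
    }
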