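"""Biphasic stimulation waveform, staircase thresholding, contact gating.

The stimulation train is rectangular charge-balanced biphasic: a cathodic
(negative) phase of 300 us, a 10 us interphase delay, then the balancing
anodic phase, repeated at a fixed 50 Hz rate.  The sensory threshold is
estimated by the three-sweep staircase used at the bench: coarse 0.5 mA
ascents until first perceived, 0.2 mA descents until no longer perceived,
then 0.1 mA fine ascents; the first fine-swept intensity perceived again is
the threshold.  During the intervention the stimulation runs at 95% of that
threshold (0 mA for the sham group) and only while the hand is in contact
with one of the textures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ProcedureError
from .haptic_sim import ExplorationTrace


@dataclass(frozen=True)
class StimProtocol:
    """Charge-balanced biphasic pulse-train parameters."""

    rate: float = 50.0  # Hz
    phase_width: float = 300e-6  # s
    interphase_delay: float = 10e-6  # s
    polarity: str = "cathode_first"
    intensity: float = 0.0  # mA

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ConfigurationError("intensity must be non-negative")
        if self.polarity != "cathode_first":
            raise ConfigurationError("only cathode-first pulses are supported")


@dataclass(frozen=True)
class StaircaseConfig:
    """Step sizes (mA) of the coarse-up / down / fine-up staircase."""

    up_coarse: float = 0.5
    down_step: float = 0.2
    up_fine: float = 0.1
    start: float = 0.0

    def __post_init__(self) -> None:
        if not (self.up_fine <= self.down_step <= self.up_coarse):
            raise ConfigurationError("steps must satisfy up_fine <= down_step <= up_coarse")


@dataclass(frozen=True)
class PerceiverModel:
    """Simulated participant report: perceives iff intensity >= threshold.

    With ``slope`` set, reports instead follow a logistic psychometric
    function P(perceive | I) = 1 / (1 + exp(-slope * (I - threshold))).
    """

    true_threshold: float = 2.8  # mA
    slope: float | None = None  # mA^-1; None = deterministic

    def __post_init__(self) -> None:
        if self.true_threshold <= 0:
            raise ConfigurationError("true_threshold must be positive")

    def perceives(self, intensity: float, rng: np.random.Generator | None = None) -> bool:
        if self.slope is None:
            return intensity >= self.true_threshold
        if rng is None:
            raise ValueError("stochastic perceiver needs an rng")
        p = 1.0 / (1.0 + np.exp(-self.slope * (intensity - self.true_threshold)))
        return bool(rng.random() < p)


def waveform(protocol: StimProtocol, duration: float, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Sample the stimulation current train.

    Returns (t, current) with current in mA: per pulse, -intensity for one
    phase width, zero for the interphase delay, +intensity for the second
    phase width; pulses repeat at ``protocol.rate``; zero elsewhere.
    """
    if duration <= 0:
        raise ConfigurationError("duration must be positive")
    if fs * protocol.interphase_delay < 1.0:
        raise ConfigurationError(
            f"fs={fs:g} Hz cannot resolve the {protocol.interphase_delay * 1e6:g} us interphase delay"
        )
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    current = np.zeros(n)
    n_phase = int(round(protocol.phase_width * fs))
    n_gap = int(round(protocol.interphase_delay * fs))
    period = 1.0 / protocol.rate
    k = 0
    while True:
        i0 = int(round(k * period * fs))
        if i0 >= n:
            break
        a, b = i0, min(i0 + n_phase, n)
        current[a:b] = -protocol.intensity
        a = i0 + n_phase + n_gap
        b = min(a + n_phase, n)
        if a < n:
            current[a:b] = protocol.intensity
        k += 1
    return t, current


def staircase_threshold(
    perceiver: PerceiverModel,
    config: StaircaseConfig = StaircaseConfig(),
    seed: int = 0,
    max_probes: int = 1000,
) -> float:
    """Run the three-sweep staircase against a perceiver model.

    Sweep 1 ascends from ``config.start`` in coarse steps until perceived.
    Sweep 2 starts one coarse step below that first-perceived intensity and
    descends in ``down_step`` decrements until no longer perceived (the
    starting intensity itself may already be imperceptible).  Sweep 3
    ascends in fine steps until perceived again; that intensity is returned.
    """
    rng = np.random.default_rng(seed)
    probes = 0

    def probe(level: float) -> bool:
        nonlocal probes
        probes += 1
        if probes > max_probes:
            raise ProcedureError("staircase did not converge within the probe budget")
        return perceiver.perceives(max(level, 0.0), rng)

    # Levels are rounded after every step so that accumulated float error
    # cannot miss a threshold lying exactly on the step grid.
    level = round(config.start, 9)
    while not probe(level):
        level = round(level + config.up_coarse, 9)
    level = round(level - config.up_coarse, 9)
    while level > 0 and probe(level):
        level = round(level - config.down_step, 9)
    level = max(level, 0.0)
    while not probe(level):
        level = round(level + config.up_fine, 9)
    return level


def intervention_intensity(threshold: float, group: str) -> float:
    """Subthreshold stimulation intensity: 95% of threshold, 0 for sham."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if group == "WH-Stim":
        return 0.95 * threshold
    if group == "Sham":
        return 0.0
    raise ValueError(f"unknown group {group!r}")


def gate_by_contact(
    trace: ExplorationTrace, protocol: StimProtocol | None = None
) -> list[tuple[float, float]]:
    """Intervals (s) during which stimulation is enabled.

    Stimulation runs only while the hand is in contact *and* inside one of
    the three textures; outside these intervals the output is 0 mA.
    """
    active = np.asarray(trace.in_contact) & (np.asarray(trace.region) >= 0)
    if not np.any(active):
        return []
    padded = np.concatenate(([False], active, [False])).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)  # exclusive sample index
    dt = 1.0 / trace.fs
    t0 = float(trace.t[0])
    return [(t0 + a * dt, t0 + b * dt) for a, b in zip(starts, stops)]
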