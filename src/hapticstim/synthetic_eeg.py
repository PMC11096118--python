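"""Synthetic multichannel EEG epochs with controlled alpha-band structure.

Each epoch is 1/f (pink) background noise — independent per channel, then
spatially smoothed across neighboring electrodes — plus an alpha oscillation
at a per-trial frequency drawn from 8-13 Hz with random phase.  The alpha
amplitude is ``alpha_base`` scaled by a multiplicative factor keyed by
(group, phase, trigger type) and weighted across the scalp by a fixed
centro-parietal Gaussian topography.  Epochs are average-referenced.

The default effect map encodes only the qualitative group-by-phase pattern
the analysis is meant to recover (stimulation group: alpha up during and
after the intervention; sham: up during, down after); the factors themselves
are synthetic design choices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._rng import stream
from .errors import ConfigurationError

TRIGGERS = ("start", "end")

# Extended 10-20 rows, front (positive y) to back: (labels, y)
_ROWS = [
    (["Fp1", "Fpz", "Fp2"], 0.90),
    (["AF7", "AF3", "AFz", "AF4", "AF8"], 0.72),
    (["F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8"], 0.50),
    (["FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8"], 0.25),
    (["T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8"], 0.00),
    (["TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8"], -0.25),
    (["P9", "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8", "P10"], -0.50),
    (["PO7", "PO3", "POz", "PO4", "PO8"], -0.72),
    (["O1", "Oz", "O2"], -0.90),
    (["Iz"], -1.00),
]

DEFAULT_BAD_CHANNELS = ("Fz", "Oz")


@dataclass(frozen=True)
class Montage:
    """Electrode labels with schematic 2-D scalp positions (unit head radius).

    64 nominal channels; the two bad channels (Fz, Oz by default) are
    dropped, leaving 62 usable channels.
    """

    names: tuple[str, ...]
    positions: np.ndarray  # (n, 2)
    excluded: tuple[str, ...] = DEFAULT_BAD_CHANNELS

    def __post_init__(self) -> None:
        if len(self.names) != self.positions.shape[0]:
            raise ConfigurationError("names/positions length mismatch")
        uniq = {tuple(p) for p in np.round(self.positions, 9)}
        if len(uniq) != len(self.names):
            raise ConfigurationError("electrode positions must be unique")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


def standard_montage(excluded: tuple[str, ...] = DEFAULT_BAD_CHANNELS) -> Montage:
    """The 64-channel extended 10-20 layout minus the excluded channels."""
    names, pos = [], []
    for labels, y in _ROWS:
        half_width = 0.92 * np.sqrt(max(1.0 - y * y, 0.08))
        n = len(labels)
        xs = np.linspace(-half_width, half_width, n) if n > 1 else np.array([0.0])
        for lab, x in zip(labels, xs):
            names.append(lab)
            pos.append((x, y))
    keep = [i for i, n in enumerate(names) if n not in excluded]
    return Montage(
        names=tuple(names[i] for i in keep),
        positions=np.array([pos[i] for i in keep]),
        excluded=tuple(excluded),
    )


def default_effect_map() -> dict[tuple[str, str, str], float]:
    """Multiplicative alpha-amplitude factors per (group, phase, trigger).

    Pre-intervention is the 1.0 reference everywhere.  The stimulation group
    gains alpha amplitude during (1.3x) and after (1.5x) the intervention;
    the sham group gains a little during (1.2x) and loses after (0.8x).
    """
    factors = {
        ("WH-Stim", "pre"): 1.0,
        ("WH-Stim", "intervention"): 1.3,
        ("WH-Stim", "post"): 1.5,
        ("Sham", "pre"): 1.0,
        ("Sham", "intervention"): 1.2,
        ("Sham", "post"): 0.8,
    }
    return {
        (g, p, trig): f for (g, p), f in factors.items() for trig in TRIGGERS
    }


def null_effect_map() -> dict[tuple[str, str, str], float]:
    """All factors 1.0 — no group-by-phase alpha modulation."""
    return {k: 1.0 for k in default_effect_map()}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic-EEG study generator."""

    n_per_group: int = 13
    fs: float = 1200.0
    window_start: tuple[float, float] = (0.0, 1.4)  # s, trial-start epochs
    window_end: tuple[float, float] = (-1.0, 0.4)  # s, trial-end epochs
    alpha_base: float = 5.0  # uV, alpha amplitude at the topography peak
    alpha_effects: dict = field(default_factory=default_effect_map)
    noise_exponent: float = 1.0  # 1/f^exponent power slope
    noise_scale: float = 5.0  # uV RMS of the background
    trials_per_phase: dict = field(
        default_factory=lambda: {"pre": 20, "intervention": 60, "post": 20}
    )
    seed: int = 0
    smoothing_width: float = 0.3  # spatial kernel width (head radii)
    topography_width: float = 0.35  # alpha topography width (head radii)

    def __post_init__(self) -> None:
        if self.fs <= 80.0:
            raise ConfigurationError("fs must exceed 80 Hz (2 x 40 Hz)")
        for name, (a, b) in (("window_start", self.window_start), ("window_end", self.window_end)):
            if b <= a:
                raise ConfigurationError(f"{name} must have positive length")
        if any(v <= 0 for v in self.alpha_effects.values()):
            raise ConfigurationError("alpha effect factors must be positive")

    def window(self, trigger_type: str) -> tuple[float, float]:
        return self.window_start if trigger_type == "start" else self.window_end


@dataclass
class EpochSet:
    """Trials x channels x time array for one participant/phase/trigger."""

    data: np.ndarray  # (n_trials, n_channels, n_times), uV
    fs: float
    times: np.ndarray  # s, relative to trigger
    trigger_type: str
    participant_id: str
    group: str
    phase: str
    montage: Montage

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def _alpha_topography(montage: Montage, width: float) -> np.ndarray:
    """Gaussian scalp weighting centered between Cz and Pz, peak 1."""
    cz = montage.positions[montage.index("Cz")]
    pz = montage.positions[montage.index("Pz")]
    center = 0.5 * (cz + pz)
    d2 = np.sum((montage.positions - center) ** 2, axis=1)
    return np.exp(-d2 / (2.0 * width**2))


def _smoothing_matrix(montage: Montage, width: float) -> np.ndarray:
    d2 = np.sum(
        (montage.positions[:, None, :] - montage.positions[None, :, :]) ** 2, axis=-1
    )
    w = np.exp(-d2 / (2.0 * width**2))
    return w / w.sum(axis=1, keepdims=True)


def _pink_noise(rng, shape, fs, exponent):
    """Gaussian noise with power spectral density ~ 1/f^exponent, unit RMS."""
    *lead, n_t = shape
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_t, 1.0 / fs)
    gain = np.zeros_like(f)
    gain[1:] = f[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spec * gain, n=n_t, axis=-1)
    return shaped / shaped.std()


def generate_participant_epochs(
    config: GeneratorConfig,
    participant_index: int,
    group: str,
    phase: str,
    trigger_type: str,
    montage: Montage | None = None,
) -> EpochSet:
    """Generate the epochs of one participant/phase/trigger cell."""
    montage = montage or standard_montage()
    rng = stream(config.seed, "eeg", group, participant_index, phase, trigger_type)
    t0, t1 = config.window(trigger_type)
    n_t = int(round((t1 - t0) * config.fs))
    times = t0 + np.arange(n_t) / config.fs
    n_trials = int(config.trials_per_phase[phase])
    n_ch = montage.n_channels
    try:
        factor = config.alpha_effects[(group, phase, trigger_type)]
    except KeyError as exc:
        raise ConfigurationError(
            f"alpha_effects has no entry for {(group, phase, trigger_type)}"
        ) from exc

    noise = config.noise_scale * _pink_noise(
        rng, (n_trials, n_ch, n_t), config.fs, config.noise_exponent
    )
    W = _smoothing_matrix(montage, config.smoothing_width)
    noise = np.einsum("ij,tjk->tik", W, noise)
    noise *= config.noise_scale / noise.std()

    topo = _alpha_topography(montage, config.topography_width)
    alpha_freq = rng.uniform(8.0, 13.0, size=n_trials)
    alpha_phase = rng.uniform(0.0, 2.0 * np.pi, size=n_trials)
    osc = np.sin(
        2.0 * np.pi * alpha_freq[:, None] * times[None, :] + alpha_phase[:, None]
    )
    data = noise + config.alpha_base * factor * topo[None, :, None] * osc[:, None, :]
    data -= data.mean(axis=1, keepdims=True)  # average reference
    return EpochSet(
        data=data,
        fs=config.fs,
        times=times,
        trigger_type=trigger_type,
        participant_id=f"{group[:2].upper()}{participant_index:02d}",
        group=group,
        phase=phase,
        montage=montage,
    )


def generate_epochs(config: GeneratorConfig) -> list[EpochSet]:
    """Generate every participant x phase x trigger cell of the study."""
    montage = standard_montage()
    phases = tuple(config.trials_per_phase)
    out = []
    for group in ("Sham", "WH-Stim"):
        for i in range(config.n_per_group):
            for phase in phases:
                for trig in TRIGGERS:
                    out.append(
                        generate_participant_epochs(config, i, group, phase, trig, montage)
                    )
    return out


def inject_artifacts(
    epochs: EpochSet, rng: np.random.Generator, line_freq: float = 50.0,
    line_amp: float = 2.0, blink_amp: float = 40.0, blink_rate: float = 0.1,
) -> EpochSet:
    """Optionally corrupt epochs with line noise and blink-like transients.

    Only exists to exercise I/O and robustness paths; the analysis pipeline
    assumes clean input (artifact removal on recorded data is out of scope).
    """
    data = epochs.data.copy()
    t = epochs.times
    data += line_amp * np.sin(2 * np.pi * line_freq * t)[None, None, :]
    frontal = np.exp(-np.sum(
        (epochs.montage.positions - np.array([0.0, 0.95])) ** 2, axis=1) / 0.08)
    for k in range(epochs.n_trials):
        if rng.random() < blink_rate:
            center = rng.uniform(t[0], t[-1])
            blink = np.exp(-0.5 * ((t - center) / 0.05) ** 2)
            data[k] += blink_amp * frontal[:, None] * blink[None, :]
    return replace(epochs, data=data)
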