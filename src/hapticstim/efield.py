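"""Evoked potentials, Morlet spectral amplitude, GFP and GMD.

Global field power (GFP) is the standard deviation of the voltages across
all electrodes at one time sample (population convention, so under average
reference it equals the spatial RMS) — a reference-free index of overall
response strength.  Global map dissimilarity (GMD) is the RMS difference
between two strength-normalized scalp maps: 0 for proportional maps, 2 for
antipodal ones; it indexes changes in the configuration of the underlying
generators irrespective of their strength.

The time-frequency representation uses complex Morlet wavelets
(w(t) = exp(i 2 pi f t) exp(-t^2 / 2 sigma_t^2) with sigma_t = n_cycles /
(2 pi f), unit-energy normalized, truncated at +-4 sigma_t).  Spectral
amplitude is sqrt(re^2 + im^2) of the convolution, in uV (up to the fixed
unit-energy scale).  Edge samples closer than half a wavelet to the window
boundary have incomplete support and are flagged invalid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import next_fast_len

from .synthetic_eeg import EpochSet, Montage

ALPHA_FREQS = tuple(float(f) for f in range(8, 14))  # 8..13 Hz in 1 Hz steps
ALPHA_BAND_PRESETS = {"computation": (8.0, 13.0), "narrow": (8.0, 12.0)}
DEFAULT_N_CYCLES = 1.5


@dataclass
class EvokedMap:
    """Trial-averaged (or contrast) channels x time map, average-referenced."""

    data: np.ndarray  # (n_channels, n_times), uV
    fs: float
    times: np.ndarray
    trigger_type: str
    montage: Montage | None = None
    metadata: dict = field(default_factory=dict)


@dataclass
class TFRAmplitude:
    """Spectral amplitude over frequency x time (channel-averaged default)."""

    data: np.ndarray  # (n_freqs, n_times) or (n_channels, n_freqs, n_times)
    freqs: np.ndarray
    fs: float
    times: np.ndarray
    n_cycles: float
    valid: np.ndarray  # bool, same trailing (n_freqs, n_times) shape
    metadata: dict = field(default_factory=dict)


@dataclass
class GFPSeries:
    values: np.ndarray  # uV, >= 0, one per time sample
    fs: float
    times: np.ndarray
    label: str = ""


@dataclass
class GMDSeries:
    values: np.ndarray  # in [0, 2]; NaN where undefined (zero-GFP sample)
    fs: float
    times: np.ndarray
    label: str = ""


def evoked(epochs: EpochSet) -> EvokedMap:
    """Arithmetic mean across trials."""
    if epochs.n_trials < 1:
        raise ValueError("need at least one trial")
    return EvokedMap(
        data=epochs.data.mean(axis=0),
        fs=epochs.fs,
        times=epochs.times,
        trigger_type=epochs.trigger_type,
        montage=epochs.montage,
        metadata={
            "participant_id": epochs.participant_id,
            "group": epochs.group,
            "label": epochs.phase,
        },
    )


def paired_contrast(a: EvokedMap, b: EvokedMap) -> EvokedMap:
    """Elementwise a - b (weights [1, -1]), e.g. intervention - pre."""
    if a.data.shape != b.data.shape:
        raise ValueError("evoked maps have mismatching shapes")
    if a.fs != b.fs:
        raise ValueError("evoked maps have mismatching sampling rates")
    label = f"{a.metadata.get('label', 'a')}-{b.metadata.get('label', 'b')}"
    meta = dict(a.metadata)
    meta["label"] = label
    return EvokedMap(
        data=a.data - b.data, fs=a.fs, times=a.times,
        trigger_type=a.trigger_type, montage=a.montage, metadata=meta,
    )


def morlet_wavelet(freq: float, fs: float, n_cycles: float = DEFAULT_N_CYCLES) -> np.ndarray:
    """Unit-energy complex Morlet wavelet, truncated at +-4 sigma_t."""
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(4.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2.0 * sigma_t**2))
    return w / np.sqrt(np.sum(np.abs(w) ** 2))


def morlet_tfr(
    signal: EvokedMap | EpochSet,
    freqs=ALPHA_FREQS,
    n_cycles: float = DEFAULT_N_CYCLES,
    *,
    mode: str | None = None,
    keep_channels: bool = False,
) -> TFRAmplitude:
    """Morlet spectral amplitude of an evoked map or an epoch set.

    For an :class:`EpochSet`, ``mode`` selects between ``"evoked"``
    (average first, then transform — phase-locked activity only) and
    ``"induced"`` (transform each trial, average the amplitudes — captures
    non-phase-locked oscillations).  An :class:`EvokedMap` is always
    transformed directly.  The channel-averaged map is returned unless
    ``keep_channels`` is set.
    """
    freqs = np.asarray(freqs, dtype=float)
    if isinstance(signal, EpochSet):
        mode = mode or "induced"
        if mode == "evoked":
            data = evoked(signal).data[None, ...]  # (1, ch, t)
        elif mode == "induced":
            data = signal.data
        else:
            raise ValueError(f"unknown TFR mode {mode!r}")
        fs, times = signal.fs, signal.times
    else:
        if mode not in (None, "evoked"):
            raise ValueError("an EvokedMap only supports evoked mode")
        data = signal.data[None, ...]
        fs, times = signal.fs, signal.times

    n_t = data.shape[-1]
    lowest = freqs.min()
    min_len = int(np.ceil(fs / lowest))  # one cycle at the lowest frequency
    if n_t < min_len:
        raise ValueError(
            f"window of {n_t} samples is shorter than one cycle at {lowest:g} Hz"
        )
    wavelets = [morlet_wavelet(f, fs, n_cycles) for f in freqs]
    nfft = next_fast_len(n_t + max(w.size for w in wavelets) - 1)
    spec = np.fft.fft(data, nfft, axis=-1)  # one forward transform, all freqs
    n_ch = data.shape[1]
    # Amplitudes are averaged over trials per frequency as they are made,
    # so the trials x channels x freqs x times array is never materialized.
    per_channel = np.empty((n_ch, freqs.size, n_t))
    valid = np.ones((freqs.size, n_t), dtype=bool)
    for i, w in enumerate(wavelets):
        half = (w.size - 1) // 2
        conv = np.fft.ifft(spec * np.fft.fft(w, nfft), axis=-1)
        per_channel[:, i, :] = np.abs(conv[..., half : half + n_t]).mean(axis=0)
        # Flag samples within half a wavelet of either boundary.
        edge = min(half, n_t)
        valid[i, :edge] = False
        if edge > 0:
            valid[i, n_t - edge:] = False
    out = per_channel if keep_channels else per_channel.mean(axis=0)
    meta = dict(getattr(signal, "metadata", {}) or {})
    meta.setdefault("mode", mode or "evoked")
    return TFRAmplitude(
        data=out, freqs=freqs, fs=fs, times=times,
        n_cycles=n_cycles, valid=valid, metadata=meta,
    )


def _average_reference(data: np.ndarray) -> np.ndarray:
    return data - data.mean(axis=0, keepdims=True)


def gfp(emap: EvokedMap) -> GFPSeries:
    """Global field power: per-sample std across channels (divide by N)."""
    if emap.data.shape[0] < 2:
        raise ValueError("GFP needs at least two channels")
    ref = _average_reference(emap.data)
    values = np.sqrt(np.mean(ref**2, axis=0))
    return GFPSeries(values=values, fs=emap.fs, times=emap.times,
                     label=str(emap.metadata.get("label", "")))


def gmd(a: EvokedMap, b: EvokedMap) -> GMDSeries:
    """Global map dissimilarity between two maps, per time sample.

    Both maps are re-average-referenced and divided by their GFP; the GMD
    is the RMS of the difference of the normalized maps.  Samples where
    either GFP is zero are undefined and returned as NaN.
    """
    if a.data.shape != b.data.shape:
        raise ValueError("evoked maps have mismatching shapes")
    ra = _average_reference(a.data)
    rb = _average_reference(b.data)
    ga = np.sqrt(np.mean(ra**2, axis=0))
    gb = np.sqrt(np.mean(rb**2, axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        diff = ra / ga[None, :] - rb / gb[None, :]
        values = np.sqrt(np.mean(diff**2, axis=0))
    values = np.where((ga == 0) | (gb == 0), np.nan, values)
    return GMDSeries(
        values=values, fs=a.fs, times=a.times,
        label=f"{a.metadata.get('label', 'a')} vs {b.metadata.get('label', 'b')}",
    )
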