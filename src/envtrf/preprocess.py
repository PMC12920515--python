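"""EEG conditioning: filtering, resampling, epoching, averaging, baseline
normalization, and the parietal alpha-power alertness control.

Conventions
-----------
Epochs cover a (-0.5, 2.5) s window around stimulus onset at 256 Hz: the
sample at t = 0 belongs to the epoch and windows are half-open
[t_min, t_max). Averaged responses are per-sentence means of repeated
presentations, band-passed 1-15 Hz, then z-scored against a baseline
mean/sd pooled across epochs AND channels so relative channel power is
preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .errors import DegenerateInputError, InvalidInputError, InvalidParameterError

__all__ = [
    "EpochSet",
    "AveragedResponse",
    "AlphaPowerResult",
    "bandpass_fir",
    "resample",
    "epoch",
    "average_repetitions",
    "baseline_normalize",
    "alpha_power",
    "load_continuous",
]


@dataclass
class EpochSet:
    """Per-subject, per-condition epoched EEG [epochs x channels x time]."""

    data: np.ndarray
    sample_rate: float
    epoch_window: tuple[float, float]
    channel_labels: list[str]
    condition: str = ""
    subject_id: str = ""
    item_labels: np.ndarray | None = None  # per-epoch sentence identity

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise InvalidInputError("epoch data must be [epochs x channels x time]")
        if self.data.shape[1] != len(self.channel_labels):
            raise InvalidInputError("channel_labels length mismatch")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise InvalidInputError("channel labels must be unique")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        t0, _ = self.epoch_window
        return t0 + np.arange(self.data.shape[2]) / self.sample_rate


@dataclass
class AveragedResponse(EpochSet):
    """Item-averaged responses [items x channels x time]; items are the
    distinct sentences, each the mean of its repetitions."""


@dataclass(frozen=True)
class AlphaPowerResult:
    """Alpha-band (8-12 Hz) PSD averaged over epochs and parietal sites."""

    power: float
    band: tuple[float, float]
    sites: tuple[str, ...]
    condition: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.power < 0:
            raise InvalidInputError("power must be nonnegative")


def _fir_taps(low: float, high: float, fs: float, transition: float, n_samples: int) -> np.ndarray:
    """Odd-length Hamming windowed-sinc band-pass, <= `transition` Hz wide
    at the low edge, capped so reflection padding stays feasible."""
    numtaps = int(np.ceil(3.3 * fs / transition))
    numtaps = min(numtaps, 2 * n_samples - 3)
    if numtaps % 2 == 0:
        numtaps += 1
    if numtaps < 3:
        raise InvalidInputError("signal too short to filter")
    return sps.firwin(numtaps, [low, high], pass_zero=False, window="hamming", fs=fs)


def _apply_zero_phase(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a linear-phase FIR with compensated delay (reflect padding)."""
    pad = (len(taps) - 1) // 2
    shape = data.shape
    flat = data.reshape(-1, shape[-1])
    padded = np.pad(flat, [(0, 0), (pad, pad)], mode="reflect")
    out = sps.fftconvolve(padded, taps[None, :], mode="valid", axes=-1)
    return out.reshape(shape)


def bandpass_fir(
    data: np.ndarray, low: float, high: float, fs: float, transition: float = 1.0
) -> np.ndarray:
    """Zero-phase linear-phase FIR band-pass along the last axis."""
    if not (0 < low < high):
        raise InvalidParameterError("need 0 < low < high")
    if high >= fs / 2:
        raise InvalidParameterError(f"high edge {high} Hz >= Nyquist {fs / 2} Hz")
    data = np.asarray(data, dtype=float)
    taps = _fir_taps(low, high, fs, transition, data.shape[-1])
    return _apply_zero_phase(data, taps)


def resample(data: np.ndarray, from_rate: float, to_rate: float) -> np.ndarray:
    """Polyphase anti-aliased resampling along the last axis."""
    if from_rate <= 0 or to_rate <= 0:
        raise InvalidParameterError("rates must be positive")
    if from_rate == to_rate:
        return np.asarray(data, dtype=float)
    frac = Fraction(to_rate / from_rate).limit_denominator(10000)
    return sps.resample_poly(np.asarray(data, dtype=float), frac.numerator, frac.denominator, axis=-1)


def epoch(
    data_continuous: np.ndarray,
    onsets: Sequence[int],
    fs: float,
    channel_labels: Sequence[str],
    window: tuple[float, float] = (-0.5, 2.5),
    condition: str = "",
    subject_id: str = "",
    item_labels: Sequence | None = None,
) -> EpochSet:
    """Cut a continuous [channels x time] array into onset-locked epochs.

    The sample at each onset index is t = 0; the epoch spans
    [onset + round(t_min*fs), onset + round(t_max*fs)) half-open.
    """
    data_continuous = np.atleast_2d(np.asarray(data_continuous, dtype=float))
    n_total = data_continuous.shape[1]
    i0 = int(round(window[0] * fs))
    i1 = int(round(window[1] * fs))
    n_t = i1 - i0
    bad = [int(o) for o in onsets if o + i0 < 0 or o + i1 > n_total]
    if bad:
        raise InvalidInputError(f"epoch window exceeds recording bounds at onsets {bad}")
    out = np.empty((len(onsets), data_continuous.shape[0], n_t))
    for k, o in enumerate(onsets):
        out[k] = data_continuous[:, o + i0 : o + i1]
    return EpochSet(
        out,
        fs,
        window,
        list(channel_labels),
        condition,
        subject_id,
        None if item_labels is None else np.asarray(item_labels),
    )


def average_repetitions(
    epochs: EpochSet,
    item_labels: Sequence | None = None,
    post_band: tuple[float, float] | None = (1.0, 15.0),
) -> AveragedResponse:
    """Average epochs per sentence, then band-pass the averages 1-15 Hz.

    ``post_band=None`` skips the post-average filter.
    """
    labels = epochs.item_labels if item_labels is None else np.asarray(item_labels)
    if labels is None or len(labels) != epochs.n_epochs:
        raise InvalidInputError("every epoch needs an item label")
    items = np.unique(labels)
    avg = np.stack([epochs.data[labels == it].mean(axis=0) for it in items])
    if post_band is not None:
        avg = bandpass_fir(avg, post_band[0], post_band[1], epochs.sample_rate)
    return AveragedResponse(
        avg,
        epochs.sample_rate,
        epochs.epoch_window,
        list(epochs.channel_labels),
        epochs.condition,
        epochs.subject_id,
        items,
    )


def baseline_normalize(resp: AveragedResponse) -> AveragedResponse:
    """Z-score against the pre-onset baseline pooled over items and channels.

    ONE scalar mean and ONE scalar sd are computed from every baseline
    sample of every item and channel, then applied to all samples — this
    preserves relative power differences across channels.
    """
    t = resp.times
    base = (t >= resp.epoch_window[0]) & (t < 0)
    if not np.any(base):
        raise InvalidInputError("epoch window has no baseline samples")
    samples = resp.data[:, :, base]
    mu = samples.mean()
    sd = samples.std()
    if sd == 0:
        raise DegenerateInputError("pooled baseline standard deviation is zero")
    return replace(resp, data=(resp.data - mu) / sd)


def alpha_power(
    epochs: EpochSet,
    sites: Sequence[str] = ("Pz", "POz"),
    band: tuple[float, float] = (8.0, 12.0),
) -> AlphaPowerResult:
    """Welch PSD (1 s Hann segments, 50% overlap) averaged within the
    alpha band, over epochs, and over the parietal sites."""
    missing = [s for s in sites if s not in epochs.channel_labels]
    if missing:
        raise InvalidInputError(f"site(s) not in channel labels: {missing}")
    idx = [epochs.channel_labels.index(s) for s in sites]
    fs = epochs.sample_rate
    nperseg = min(int(round(fs)), epochs.data.shape[2])
    f, psd = sps.welch(
        epochs.data[:, idx, :], fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2, axis=-1
    )
    in_band = (f >= band[0]) & (f <= band[1])
    power = float(psd[..., in_band].mean())
    return AlphaPowerResult(power, tuple(band), tuple(sites), epochs.condition, epochs.subject_id)


def load_continuous(path):
    """Read a continuous BDF/EDF recording via MNE.

    Returns ``(data [channels x time], fs, channel_labels)``; event
    extraction is left to the caller (recordings differ in how triggers
    are encoded).
    """
    import mne

    raw = mne.io.read_raw(path, preload=True, verbose="error")
    return raw.get_data(), float(raw.info["sfreq"]), list(raw.info["ch_names"])
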