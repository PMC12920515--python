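"""Auditory front-end: sub-band spectrogram and broadband envelope.

The TRF stimulus regressor is the slow amplitude modulation of speech,
computed as the unweighted mean of 128 logarithmically spaced sub-band
envelopes (~90-4,000 Hz) and resampled to the EEG rate. The front-end is
linear (band-pass, rectify, smooth) — a deliberate approximation of
cochlear models that include compressive nonlinearities, adequate here
because only the band-averaged temporal modulation is used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .errors import InvalidInputError
from .vocoder import AudioWaveform

__all__ = [
    "EnvelopeSignal",
    "AuditorySpectrogram",
    "auditory_spectrogram",
    "broadband_envelope",
    "speech_envelope",
]

N_BANDS = 128
F_LOW = 90.0
F_HIGH = 4000.0
SMOOTH_HZ = 30.0


@dataclass(frozen=True)
class EnvelopeSignal:
    """Nonnegative broadband temporal envelope at a fixed sample rate."""

    values: np.ndarray
    sample_rate: float
    source_id: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise InvalidInputError("envelope must be 1-D")
        if not np.all(np.isfinite(values)):
            raise InvalidInputError("envelope contains non-finite values")
        if np.any(values < 0):
            raise InvalidInputError("envelope must be nonnegative")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class AuditorySpectrogram:
    """Matrix of sub-band envelopes [bands x time] with band centers in Hz."""

    sub_band_envelopes: np.ndarray
    band_centers: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        env = np.asarray(self.sub_band_envelopes, dtype=float)
        centers = np.asarray(self.band_centers, dtype=float)
        if env.ndim != 2 or env.shape[0] != len(centers):
            raise InvalidInputError("spectrogram rows must match band centers")
        if np.any(np.diff(centers) <= 0):
            raise InvalidInputError("band centers must be strictly increasing")
        object.__setattr__(self, "sub_band_envelopes", env)
        object.__setattr__(self, "band_centers", centers)


def auditory_spectrogram(
    audio: AudioWaveform,
    n_bands: int = N_BANDS,
    f_low: float = F_LOW,
    f_high: float = F_HIGH,
    smooth_hz: float = SMOOTH_HZ,
) -> AuditorySpectrogram:
    """Sub-band envelope decomposition on log-spaced bands.

    Each row is the half-wave rectified, low-pass smoothed output of a
    zero-phase 4th-order Butterworth band-pass filter.
    """
    if audio.sample_rate < 2 * f_high:
        raise InvalidInputError(
            f"sample rate {audio.sample_rate} too low for {f_high} Hz upper edge"
        )
    n = len(audio.samples)
    if n < audio.sample_rate / smooth_hz:
        raise InvalidInputError("input shorter than one smoothing window")
    fs = audio.sample_rate
    edges = f_low * (f_high / f_low) ** (np.arange(n_bands + 1) / n_bands)
    centers = np.sqrt(edges[:-1] * edges[1:])
    lp = sps.butter(4, smooth_hz, btype="lowpass", fs=fs, output="sos")
    envs = np.empty((n_bands, n))
    for i in range(n_bands):
        sos = sps.butter(2, [edges[i], edges[i + 1]], btype="bandpass", fs=fs, output="sos")
        band = sps.sosfiltfilt(sos, audio.samples)
        envs[i] = np.maximum(sps.sosfiltfilt(lp, np.maximum(band, 0.0)), 0.0)
    return AuditorySpectrogram(envs, centers, float(fs))


def broadband_envelope(
    spec: AuditorySpectrogram, target_rate: float = 256.0, source_id: str = ""
) -> EnvelopeSignal:
    """Mean over sub-bands, anti-alias resampled to ``target_rate``.

    Resampling is polyphase with a Kaiser window; the result is clipped
    at 0 to preserve nonnegativity (ringing can undershoot slightly).
    """
    mean_env = spec.sub_band_envelopes.mean(axis=0)
    if target_rate != spec.sample_rate:
        frac = Fraction(target_rate / spec.sample_rate).limit_denominator(10000)
        mean_env = sps.resample_poly(mean_env, frac.numerator, frac.denominator)
    return EnvelopeSignal(np.maximum(mean_env, 0.0), float(target_rate), source_id)


def speech_envelope(
    audio: AudioWaveform, target_rate: float = 256.0, source_id: str = ""
) -> EnvelopeSignal:
    """Convenience: auditory_spectrogram -> broadband_envelope."""
    return broadband_envelope(auditory_spectrogram(audio), target_rate, source_id)
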