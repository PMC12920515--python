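"""N-channel noise vocoding.

Degrades speech the way a cochlear-implant acoustic simulation does: the
signal is split into a small number of logarithmically spaced analysis
bands, the temporal envelope of each band is extracted and used to
amplitude-modulate a Gaussian white-noise carrier confined to the same
band, and the modulated bands are summed. Within-band temporal envelopes
are preserved while spectral fine structure is destroyed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "AudioWaveform",
    "FilterBankSpec",
    "VocoderParams",
    "make_log_bank",
    "vocode",
    "band_envelopes",
    "read_wav",
    "write_wav",
]


@dataclass(frozen=True)
class AudioWaveform:
    """A mono sampled pressure signal.

    Parameters
    ----------
    samples : ndarray
        Real-valued pressure sequence (arbitrary units).
    sample_rate : int
        Sampling rate in Hz.
    """

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise InvalidInputError("audio must be mono (1-D)")
        if not np.all(np.isfinite(samples)):
            raise InvalidInputError("audio contains non-finite samples")
        if self.sample_rate <= 0:
            raise InvalidParameterError("sample_rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass(frozen=True)
class FilterBankSpec:
    """A contiguous band-pass filter bank defined by its band edges."""

    n_channels: int
    f_low: float
    f_high: float
    edges: np.ndarray
    spacing: str = "logarithmic"

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        if len(edges) != self.n_channels + 1:
            raise InvalidParameterError("need n_channels + 1 edges")
        if np.any(np.diff(edges) <= 0):
            raise InvalidParameterError("edges must be strictly increasing")
        object.__setattr__(self, "edges", edges)

    @property
    def bands(self) -> list[tuple[float, float]]:
        return list(zip(self.edges[:-1], self.edges[1:]))


@dataclass(frozen=True)
class VocoderParams:
    """Vocoder configuration: analysis bank, envelope cutoff, carrier, seed."""

    bank: FilterBankSpec
    env_lowpass_hz: float = 200.0
    carrier: str = "gaussian_white_noise"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.env_lowpass_hz <= 0:
            raise InvalidParameterError("env_lowpass_hz must be positive")
        if self.carrier != "gaussian_white_noise":
            raise InvalidParameterError(f"unknown carrier {self.carrier!r}")


def make_log_bank(n_channels: int, f_low: float, f_high: float) -> FilterBankSpec:
    """Geometrically spaced band edges from ``f_low`` to ``f_high``.

    Edge i is ``f_low * (f_high / f_low) ** (i / n_channels)``, so the
    ratio between consecutive edges is constant.
    """
    if n_channels < 1:
        raise InvalidParameterError("n_channels must be >= 1")
    if not (0 < f_low < f_high):
        raise InvalidParameterError("need 0 < f_low < f_high")
    edges = f_low * (f_high / f_low) ** (np.arange(n_channels + 1) / n_channels)
    return FilterBankSpec(n_channels, float(f_low), float(f_high), edges)


def _band_sos(low: float, high: float, fs: float) -> np.ndarray:
    # 4th-order Butterworth band-pass, applied forward-backward for zero
    # phase; contiguous bands overlap only in their transition skirts.
    return sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")


def _lowpass_sos(cutoff: float, fs: float) -> np.ndarray:
    return sps.butter(4, cutoff, btype="lowpass", fs=fs, output="sos")


def _check_rate(audio: AudioWaveform, f_high: float) -> None:
    if audio.sample_rate < 2 * f_high:
        raise InvalidParameterError(
            f"sample rate {audio.sample_rate} Hz too low for upper band edge "
            f"{f_high} Hz (need >= {2 * f_high} Hz)"
        )


def band_envelopes(
    audio: AudioWaveform, params: VocoderParams, smooth_hz: float | None = None
) -> np.ndarray:
    """Per-band temporal envelopes, shape (n_bands, n_samples).

    Analysis chain per band: zero-phase Butterworth band-pass, half-wave
    rectification, zero-phase low-pass at ``env_lowpass_hz``, clipped at
    0. ``smooth_hz`` overrides the low-pass cutoff, e.g. to compare
    envelopes at syllabic modulation rates where intrinsic carrier-noise
    fluctuations are averaged out.
    """
    _check_rate(audio, params.bank.f_high)
    fs = audio.sample_rate
    lp = _lowpass_sos(smooth_hz or params.env_lowpass_hz, fs)
    envs = np.empty((params.bank.n_channels, len(audio.samples)))
    for i, (lo, hi) in enumerate(params.bank.bands):
        band = sps.sosfiltfilt(_band_sos(lo, hi, fs), audio.samples)
        env = sps.sosfiltfilt(lp, np.maximum(band, 0.0))
        envs[i] = np.maximum(env, 0.0)
    return envs


def vocode(audio: AudioWaveform, params: VocoderParams) -> AudioWaveform:
    """Noise-vocode ``audio`` through the analysis bank in ``params``.

    Per band: band-pass the input, extract its envelope, modulate a
    band-limited Gaussian noise carrier with that envelope, band-pass
    the modulated product with the same filter to confine modulation
    sidebands, and re-normalize to the analysis band's RMS; bands are
    then summed. Identical ``rng_seed`` gives bit-identical output.
    """
    _check_rate(audio, params.bank.f_high)
    fs = audio.sample_rate
    rng = np.random.default_rng(params.rng_seed)
    lp = _lowpass_sos(params.env_lowpass_hz, fs)
    out = np.zeros_like(audio.samples)
    for lo, hi in params.bank.bands:
        sos = _band_sos(lo, hi, fs)
        band = sps.sosfiltfilt(sos, audio.samples)
        band_rms = np.sqrt(np.mean(band**2))
        white = rng.standard_normal(len(band))
        if band_rms == 0.0:
            continue  # silent band contributes nothing
        env = np.maximum(sps.sosfiltfilt(lp, np.maximum(band, 0.0)), 0.0)
        carrier = sps.sosfiltfilt(sos, white)
        mod = sps.sosfiltfilt(sos, carrier * env)
        mod_rms = np.sqrt(np.mean(mod**2))
        if mod_rms > 0.0:
            out += mod * (band_rms / mod_rms)
    return AudioWaveform(out, fs)


def read_wav(path) -> AudioWaveform:
    """Read a mono WAV file (PCM 16/24/32-bit or float) as float samples.

    Integer PCM is scaled to [-1, 1]; multichannel input is rejected.
    """
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise InvalidInputError(f"{path}: expected mono WAV, got {data.shape[1]} channels")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    return AudioWaveform(data, int(rate))


def write_wav(path, audio: AudioWaveform) -> None:
    """Write a waveform as float32 WAV."""
    wavfile.write(path, audio.sample_rate, audio.samples.astype(np.float32))
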