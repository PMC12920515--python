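"""Synthetic two-condition EEG studies with known ground-truth TRFs.

The generator implements exactly the forward model the TRF analysis
assumes: each epoch is the stimulus envelope convolved with a
condition-dependent kernel (negative ~90 ms, positive ~160 ms and
~390 ms Gaussian components with a fronto-central scalp topography),
plus spatially correlated 1/f noise. The "natural" condition carries
1.5x larger early components (N1/P2); the "vocoded" condition carries a
1.5x larger late component (P400), mirroring the qualitative contrast
between clean and degraded speech. Subject variability enters as shared
per-subject amplitude scaling (sd 20%) and latency jitter (sd 10 ms).

Two generation paths exist: ``simulate_dataset`` materializes every
epoch (items x repetitions), and ``simulate_averaged_study`` draws the
repetition-averaged responses directly with noise sd scaled by
1/sqrt(n_reps) — exact in distribution for Gaussian noise under the
linear averaging pipeline, and far cheaper for 50-subject studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import InvalidParameterError
from .frontend import EnvelopeSignal
from .preprocess import EpochSet
from .trf import LagSpec, lag_matrix

__all__ = [
    "KernelComponent",
    "KernelSpec",
    "SimConfig",
    "GroundTruth",
    "SimulatedStudy",
    "biosemi64_layout",
    "make_default_kernels",
    "synth_envelope",
    "pink_noise",
    "simulate_dataset",
    "simulate_averaged_study",
]

CONDITIONS = ("natural", "vocoded")


def biosemi64_layout() -> tuple[list[str], np.ndarray]:
    """Standard 64-channel cap labels and 3-D positions (meters)."""
    import mne

    montage = mne.channels.make_standard_montage("biosemi64")
    pos = montage.get_positions()["ch_pos"]
    labels = montage.ch_names
    return list(labels), np.array([pos[ch] for ch in labels])


@dataclass(frozen=True)
class KernelComponent:
    """One Gaussian-shaped TRF component."""

    name: str
    latency_ms: float
    width_ms: float  # Gaussian sd
    amplitude: float  # normalized units, > 0
    polarity: int  # +1 or -1
    topography: np.ndarray | None = None  # per-channel gain in [-1, 1]

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise InvalidParameterError("width_ms must be positive")
        if self.polarity not in (-1, 1):
            raise InvalidParameterError("polarity must be +1 or -1")


@dataclass(frozen=True)
class KernelSpec:
    """A condition's ground-truth kernel as a sum of components."""

    components: tuple[KernelComponent, ...]


def _frontocentral_topography(positions: np.ndarray, sigma: float = 0.045) -> np.ndarray:
    """Gaussian scalp gain peaking between FCz and Cz."""
    peak = np.array([0.0, 0.0185, 0.091])  # midpoint of FCz/Cz on the standard cap
    d = np.linalg.norm(positions - peak, axis=1)
    return np.exp(-(d**2) / (2 * sigma**2))


# component geometry: (latency ms, width ms, polarity)
_COMPONENT_SHAPE = {"N1": (90.0, 15.0, -1), "P2": (160.0, 25.0, 1), "P400": (390.0, 30.0, 1)}
# amplitudes per condition: natural has 1.5x N1/P2, vocoded has 1.5x P400
_AMPLITUDES = {
    "natural": {"N1": 1.5, "P2": 1.5, "P400": 1.0},
    "vocoded": {"N1": 1.0, "P2": 1.0, "P400": 1.5},
}


def make_default_kernels(positions: np.ndarray | None = None) -> dict[str, KernelSpec]:
    """Default natural/vocoded kernels with a fronto-central topography."""
    if positions is None:
        _, positions = biosemi64_layout()
    topo = _frontocentral_topography(positions)
    out = {}
    for cond in CONDITIONS:
        comps = tuple(
            KernelComponent(name, *_COMPONENT_SHAPE[name][:2],
                            amplitude=_AMPLITUDES[cond][name],
                            polarity=_COMPONENT_SHAPE[name][2], topography=topo)
            for name in ("N1", "P2", "P400")
        )
        out[cond] = KernelSpec(comps)
    return out


def make_identical_kernels(positions: np.ndarray | None = None) -> dict[str, KernelSpec]:
    """Both conditions share one kernel (across-condition mean amplitudes):
    the null generator for condition-contrast calibration checks."""
    base = make_default_kernels(positions)
    mean_amps = {
        nm: np.mean([_AMPLITUDES[c][nm] for c in CONDITIONS]) for nm in _COMPONENT_SHAPE
    }
    comps = tuple(
        KernelComponent(c.name, c.latency_ms, c.width_ms, mean_amps[c.name],
                        c.polarity, c.topography)
        for c in base[CONDITIONS[0]].components
    )
    return {cond: KernelSpec(comps) for cond in CONDITIONS}


def make_null_kernels(positions: np.ndarray | None = None) -> dict[str, KernelSpec]:
    """Zero-amplitude kernels: responses are pure noise, decoupled from
    the stimulus (the permutation-test null)."""
    base = make_default_kernels(positions)
    comps = tuple(
        KernelComponent(c.name, c.latency_ms, c.width_ms, 0.0, c.polarity, c.topography)
        for c in base[CONDITIONS[0]].components
    )
    return {cond: KernelSpec(comps) for cond in CONDITIONS}


def planted_windows():
    """Lag windows (latency +/- 2 sd) around the three planted components."""
    from .stats import ComponentWindow

    return [
        ComponentWindow(f"{nm}_TRF", lat - 2 * wd, lat + 2 * wd)
        for nm, (lat, wd, _pol) in _COMPONENT_SHAPE.items()
    ]


@dataclass
class SimConfig:
    """Study design parameters for the synthetic generator."""

    n_subjects: int = 50
    n_items: int = 10
    n_reps: int = 100
    fs: float = 256.0
    n_channels: int = 64
    snr_db: float = 0.0
    subject_amp_sd: float = 0.2
    latency_jitter_ms: float = 10.0
    pink_exponent: float = 1.0
    epoch_window: tuple[float, float] = (-0.5, 2.5)
    stim_duration_s: float = 2.5
    seed: int = 0
    kernels: dict[str, KernelSpec] | None = None  # default: make_default_kernels

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_items", "n_reps", "n_channels"):
            if getattr(self, name) < 1:
                raise InvalidParameterError(f"{name} must be >= 1")
        if self.fs <= 0:
            raise InvalidParameterError("fs must be positive")

    @property
    def lag_spec(self) -> LagSpec:
        return LagSpec(-100.0, 600.0, self.fs)

    @property
    def n_times(self) -> int:
        return int(round((self.epoch_window[1] - self.epoch_window[0]) * self.fs))

    @property
    def onset_index(self) -> int:
        return int(round(-self.epoch_window[0] * self.fs))


@dataclass
class GroundTruth:
    """Realized per-subject kernels stored with every generated dataset."""

    kernels: np.ndarray  # [n_subjects x n_conditions x n_channels x n_lags]
    lag_spec: LagSpec
    conditions: tuple[str, ...]
    channel_labels: list[str]

    def mean_kernel(self, condition: str) -> np.ndarray:
        return self.kernels[:, self.conditions.index(condition)].mean(axis=0)


@dataclass
class SimulatedStudy:
    """Item-averaged responses for all subjects and both conditions."""

    config: SimConfig
    envelopes: list[EnvelopeSignal]
    responses: np.ndarray  # [n_subjects x n_conditions x n_items x n_channels x n_times]
    conditions: tuple[str, ...]
    channel_labels: list[str]
    positions: np.ndarray
    ground_truth: GroundTruth

    @property
    def onset_index(self) -> int:
        return self.config.onset_index


def synth_envelope(duration_s: float = 2.5, fs: float = 256.0, seed: int = 0) -> EnvelopeSignal:
    """Speech-like nonnegative envelope with a ~4 Hz syllabic modulation.

    Narrow-band (2-6 Hz) Gaussian noise is half-wave rectified, smoothed
    below 10 Hz, ramped on/off over 50 ms, clipped at 0 and scaled to
    unit standard deviation.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    x = rng.standard_normal(n + int(fs))  # extra second to wash out filter edges
    sos_band = sps.butter(2, [2.0, 6.0], btype="bandpass", fs=fs, output="sos")
    syllabic = sps.sosfiltfilt(sos_band, x)
    env = np.maximum(syllabic, 0.0)
    sos_lp = sps.butter(4, 10.0, btype="lowpass", fs=fs, output="sos")
    env = np.maximum(sps.sosfiltfilt(sos_lp, env), 0.0)[int(fs) // 2 :][:n]
    ramp_n = max(int(round(0.05 * fs)), 1)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
    env[:ramp_n] *= ramp
    env[-ramp_n:] *= ramp[::-1]
    sd = env.std()
    if sd > 0:
        env = env / sd
    return EnvelopeSignal(env, fs, source_id=f"synth{seed}")


def pink_noise(rng: np.random.Generator, shape: tuple[int, ...], exponent: float = 1.0) -> np.ndarray:
    """1/f^exponent noise along the last axis, unit variance in expectation.

    Spectral shaping: complex Gaussian coefficients scaled by
    f^(-exponent/2) (DC zero), inverse-transformed. The exact ensemble
    variance of the resulting series is computed from the gains and
    divided out, so the output has unit expected variance per sample.
    """
    n = shape[-1]
    freqs = np.fft.rfftfreq(n)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (
        rng.standard_normal(shape[:-1] + (len(freqs),))
        + 1j * rng.standard_normal(shape[:-1] + (len(freqs),))
    ) * gain
    out = np.fft.irfft(spec, n=n, axis=-1)
    # Var(x[t]) from hermitian-paired coefficients (Nyquist bin is real)
    if n % 2 == 0:
        var = (gain[-1] ** 2 + 4.0 * (gain[1:-1] ** 2).sum()) / n**2
    else:
        var = 4.0 * (gain[1:] ** 2).sum() / n**2
    return out / np.sqrt(var)


def _smooth_mixing(rng: np.random.Generator, positions: np.ndarray, sigma: float = 0.04) -> np.ndarray:
    """Random channel-mixing matrix smoothed over scalp distance.

    Rows are unit-norm, so mixed unit-variance noise stays unit variance
    per channel while nearby channels become correlated.
    """
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    K = np.exp(-(d**2) / (2 * sigma**2))
    M = K @ rng.standard_normal((len(positions), len(positions)))
    return M / np.linalg.norm(M, axis=1, keepdims=True)


def _layout_for(cfg: SimConfig) -> tuple[list[str], np.ndarray]:
    labels, pos = biosemi64_layout()
    if cfg.n_channels == 64:
        return labels, pos
    if cfg.n_channels < 64:
        # evenly thinned subset of the standard cap
        idx = np.linspace(0, 63, cfg.n_channels).round().astype(int)
        return [labels[i] for i in idx], pos[idx]
    raise InvalidParameterError("n_channels > 64 is not supported")


def _realize_kernels(cfg: SimConfig, kernels: dict[str, KernelSpec],
                     positions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-subject kernels [n_subj x n_cond x n_ch x n_lags].

    Amplitude scaling and latency jitter are subject traits shared across
    conditions (drawn once per subject per component), so condition
    contrasts stay paired within subject.
    """
    lag_t = cfg.lag_spec.times_ms
    n_lags = cfg.lag_spec.n_lags
    out = np.zeros((cfg.n_subjects, len(CONDITIONS), cfg.n_channels, n_lags))
    comp_names = [c.name for c in kernels[CONDITIONS[0]].components]
    for s in range(cfg.n_subjects):
        amp_fac = {nm: max(1.0 + rng.normal(0.0, cfg.subject_amp_sd), 0.05) for nm in comp_names}
        lat_shift = {nm: rng.normal(0.0, cfg.latency_jitter_ms) for nm in comp_names}
        for ci, cond in enumerate(CONDITIONS):
            for comp in kernels[cond].components:
                topo = comp.topography
                if topo is None:
                    topo = _frontocentral_topography(positions)
                lat = comp.latency_ms + lat_shift[comp.name]
                shape = np.exp(-((lag_t - lat) ** 2) / (2 * comp.width_ms**2))
                amp = comp.polarity * comp.amplitude * amp_fac[comp.name]
                out[s, ci] += amp * np.outer(topo[: cfg.n_channels], shape)
    return out


def _study_core(cfg: SimConfig):
    """Shared setup: rngs, layout, envelopes, designs, realized kernels."""
    ss = np.random.SeedSequence(cfg.seed)
    rng_env, rng_kernel, rng_mix, rng_noise = [np.random.default_rng(s) for s in ss.spawn(4)]
    labels, positions = _layout_for(cfg)
    kernels = cfg.kernels or make_default_kernels(positions)
    envelopes = [
        synth_envelope(cfg.stim_duration_s, cfg.fs, seed=int(rng_env.integers(2**31)))
        for _ in range(cfg.n_items)
    ]
    # stimulus on the epoch time axis, zero before onset
    n_t = cfg.n_times
    lag_idx = cfg.lag_spec.lag_indices
    X = np.empty((cfg.n_items, n_t, len(lag_idx)))
    for i, env in enumerate(envelopes):
        s_full = np.zeros(n_t)
        stim = env.values[: n_t - cfg.onset_index]
        s_full[cfg.onset_index : cfg.onset_index + len(stim)] = stim
        X[i] = lag_matrix(s_full, lag_idx)
    realized = _realize_kernels(cfg, kernels, positions, rng_kernel)
    mixing = _smooth_mixing(rng_mix, positions)
    gt = GroundTruth(realized, cfg.lag_spec, CONDITIONS, labels)
    return labels, positions, envelopes, X, realized, mixing, gt, rng_noise


def _signals_for_subject(X2: np.ndarray, kernels_s: np.ndarray, n_items: int, n_t: int) -> np.ndarray:
    """Noise-free responses [n_cond x n_items x n_ch x n_t] for one subject."""
    n_cond, n_ch, n_lags = kernels_s.shape
    flat = X2 @ kernels_s.reshape(n_cond * n_ch, n_lags).T  # [(items*t) x (cond*ch)]
    return flat.reshape(n_items, n_t, n_cond, n_ch).transpose(2, 0, 3, 1)


def _noise_sd(signal: np.ndarray, onset_index: int, snr_db: float) -> float:
    """Noise sd giving the requested SNR over post-onset samples.

    A zero signal (null kernels) leaves the SNR undefined; unit-variance
    noise is used so the decoupled null still produces EEG-like data.
    """
    p_signal = float(np.mean(signal[..., onset_index:] ** 2))
    if p_signal == 0.0:
        return 1.0
    return float(np.sqrt(p_signal / 10.0 ** (snr_db / 10.0)))


def simulate_averaged_study(cfg: SimConfig, dtype=np.float32) -> SimulatedStudy:
    """Generate repetition-averaged responses for the whole study.

    Averaging n_reps epochs of signal + iid noise equals signal + noise
    with sd/sqrt(n_reps); that average is drawn directly. SNR refers to
    the single-epoch post-onset signal-to-noise power ratio. Responses
    are stored float32 by default (a 50-subject study is ~2 GB in
    float64); pass ``dtype=np.float64`` for precision-critical checks.
    """
    labels, positions, envelopes, X, realized, mixing, gt, rng_noise = _study_core(cfg)
    n_t = cfg.n_times
    X2 = X.reshape(-1, X.shape[-1])
    responses = np.empty(
        (cfg.n_subjects, len(CONDITIONS), cfg.n_items, cfg.n_channels, n_t), dtype=dtype
    )
    for s in range(cfg.n_subjects):
        sig = _signals_for_subject(X2, realized[s], cfg.n_items, n_t)
        sd = _noise_sd(sig, cfg.onset_index, cfg.snr_db) / np.sqrt(cfg.n_reps)
        noise = pink_noise(rng_noise, sig.shape, cfg.pink_exponent)
        noise = np.tensordot(mixing, noise, axes=([1], [2])).transpose(1, 2, 0, 3)
        responses[s] = sig + sd * noise
    return SimulatedStudy(cfg, envelopes, responses, CONDITIONS, labels, positions, gt)


def simulate_dataset(cfg: SimConfig):
    """Generate the full epoch-level dataset.

    Returns ``(epoch_sets, envelopes, ground_truth)`` where
    ``epoch_sets[subject][condition]`` is an :class:`EpochSet` of
    n_items * n_reps epochs with item labels. Identical seeds give
    bit-identical datasets. Intended for modest sizes; large studies
    should use :func:`simulate_averaged_study`.
    """
    labels, positions, envelopes, X, realized, mixing, gt, rng_noise = _study_core(cfg)
    n_t = cfg.n_times
    X2 = X.reshape(-1, X.shape[-1])
    epoch_sets: list[dict[str, EpochSet]] = []
    for s in range(cfg.n_subjects):
        sig = _signals_for_subject(X2, realized[s], cfg.n_items, n_t)
        sd = _noise_sd(sig, cfg.onset_index, cfg.snr_db)
        per_cond: dict[str, EpochSet] = {}
        for ci, cond in enumerate(CONDITIONS):
            data = np.repeat(sig[ci], cfg.n_reps, axis=0)  # [items*reps x ch x t]
            if sd > 0:
                noise = pink_noise(rng_noise, data.shape, cfg.pink_exponent)
                noise = np.tensordot(mixing, noise, axes=([1], [1])).transpose(1, 0, 2)
                data = data + sd * noise
            item_labels = np.repeat(np.arange(cfg.n_items), cfg.n_reps)
            per_cond[cond] = EpochSet(
                data, cfg.fs, cfg.epoch_window, list(labels), cond, f"S{s:03d}", item_labels
            )
        epoch_sets.append(per_cond)
    return epoch_sets, envelopes, gt
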