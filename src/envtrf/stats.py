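"""Component detection and statistics on estimated TRFs.

Global field power (GFP, the spatial standard deviation across
electrodes at each lag) summarizes overall response strength without a
reference. Conditions are compared lag-by-lag with two-tailed paired
t-tests, corrected by Benjamini-Hochberg FDR; maximal runs of
consecutive significant lags form component windows (N1/P2/P400-style),
which are then characterized by channel-averaged window amplitudes and
per-electrode dominance t-maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .errors import InvalidInputError, InvalidParameterError
from .trf import TRFModel

__all__ = [
    "GFPSeries",
    "PointwiseTestResult",
    "ComponentWindow",
    "WindowAmplitude",
    "gfp",
    "paired_t",
    "paired_t_series",
    "fdr_bh",
    "find_clusters",
    "label_clusters",
    "window_amplitude",
    "topographic_dominance",
    "gfp_vs_baseline",
    "compare_gfp",
]

# canonical component search ranges (ms), used only for labeling clusters
CANONICAL_RANGES = {"N1_TRF": (60.0, 130.0), "P2_TRF": (130.0, 250.0), "P400_TRF": (300.0, 500.0)}


@dataclass(frozen=True)
class GFPSeries:
    """Per-lag spatial standard deviation of a TRF."""

    values: np.ndarray
    times_ms: np.ndarray
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v < 0):
            raise InvalidInputError("GFP must be nonnegative")
        if len(v) != len(self.times_ms):
            raise InvalidInputError("GFP and lag axis lengths differ")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "times_ms", np.asarray(self.times_ms, dtype=float))


@dataclass(frozen=True)
class PointwiseTestResult:
    """Pointwise paired-t results with BH-FDR correction over one family."""

    t_values: np.ndarray
    p_raw: np.ndarray
    q_fdr: np.ndarray
    sig_mask: np.ndarray
    df: int
    axis_values: np.ndarray = field(default_factory=lambda: np.array([]))  # lag ms or channel idx
    alpha: float = 0.05


@dataclass(frozen=True)
class ComponentWindow:
    """A contiguous significant time window on the lag axis, in ms."""

    name: str
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if self.t_start >= self.t_end:
            raise InvalidParameterError("t_start must be < t_end")

    def overlaps(self, lo: float, hi: float) -> bool:
        return self.t_start <= hi and self.t_end >= lo


@dataclass(frozen=True)
class WindowAmplitude:
    """Summary amplitude of a TRF within a component window."""

    window: ComponentWindow
    value: float
    mode: str  # "mean" or "peak"
    subject_id: str = ""
    condition: str = ""


def gfp(model_or_weights) -> GFPSeries | np.ndarray:
    """Global field power: spatial sd across channels at each lag.

    Uses the population convention (divide by n_channels):
    GFP(tau) = sqrt(mean_ch (w(tau,ch) - mean_ch w(tau,.))^2).
    """
    if isinstance(model_or_weights, TRFModel):
        W = model_or_weights.weights
        if W.shape[0] < 2:
            raise InvalidInputError("GFP needs at least 2 channels")
        return GFPSeries(
            W.std(axis=0),
            model_or_weights.lag_spec.times_ms,
            model_or_weights.subject_id,
            model_or_weights.condition,
        )
    W = np.asarray(model_or_weights, dtype=float)
    if W.shape[-2] < 2:
        raise InvalidInputError("GFP needs at least 2 channels")
    return W.std(axis=-2)


def paired_t(x, y) -> tuple[float, float, int]:
    """Two-tailed paired t-test: t = mean(d) / (sd(d)/sqrt(n)), df = n-1.

    Degenerate cases: zero-variance, zero-mean differences give (0, 1);
    zero-variance, nonzero-mean differences give (+/-inf, 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("paired_t needs two equal-length 1-D arrays")
    n = len(x)
    if n < 2:
        raise InvalidInputError("paired_t needs n >= 2")
    t, p, _ = _t_from_d((x - y)[None, :].T)
    return float(t[0]), float(p[0]), n - 1


def _t_from_d(d: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorized paired t over columns of d [n_subjects x k]."""
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    t = np.empty(d.shape[1])
    zero_sd = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t[~zero_sd] = mean[~zero_sd] / (sd[~zero_sd] / np.sqrt(n))
    t[zero_sd & (mean == 0)] = 0.0
    t[zero_sd & (mean != 0)] = np.sign(mean[zero_sd & (mean != 0)]) * np.inf
    p = 2.0 * sstats.t.sf(np.abs(t), df=n - 1)
    p[np.isinf(t)] = 0.0
    p[t == 0] = np.where(zero_sd[t == 0], 1.0, p[t == 0])
    return t, p, n - 1


def paired_t_series(
    x: np.ndarray, y: np.ndarray, axis_values=None, alpha: float = 0.05
) -> PointwiseTestResult:
    """Pointwise paired t (x vs y, [n_subjects x k]) with BH-FDR over k."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 2:
        raise InvalidInputError("need matching [n_subjects x k] arrays")
    t, p, df = _t_from_d(x - y)
    q, mask = fdr_bh(p, alpha)
    axis = np.asarray(axis_values, dtype=float) if axis_values is not None else np.arange(x.shape[1], dtype=float)
    return PointwiseTestResult(t, p, q, mask, df, axis, alpha)


def fdr_bh(p_raw, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted q-values and significance mask.

    Monotonicity is enforced (q is nondecreasing in p); the mask is
    q < alpha.
    """
    p = np.asarray(p_raw, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, q < alpha


def find_clusters(sig_mask, times_ms, min_len: int = 1) -> list[ComponentWindow]:
    """Maximal runs of consecutive significant lags as component windows.

    Window endpoints are the first and last significant lag-sample times
    (no interpolation). Runs shorter than ``min_len`` lags are dropped.
    """
    mask = np.asarray(sig_mask, dtype=bool)
    times = np.asarray(times_ms, dtype=float)
    if len(mask) != len(times):
        raise InvalidInputError("mask and lag axis lengths differ")
    windows: list[ComponentWindow] = []
    edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.astype(int), [0]])))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start >= min_len:
            t0, t1 = times[start], times[stop - 1]
            if t0 == t1:  # single-lag run: widen to the sample spacing
                dt = np.median(np.diff(times)) if len(times) > 1 else 1.0
                t1 = t0 + dt / 2
                t0 = t0 - dt / 2
            windows.append(ComponentWindow(f"cluster_{len(windows)}", t0, t1))
    return windows


def label_clusters(windows: list[ComponentWindow]) -> list[ComponentWindow]:
    """Rename clusters that overlap canonical N1/P2/P400 latency ranges."""
    out = []
    for w in windows:
        name = w.name
        for cname, (lo, hi) in CANONICAL_RANGES.items():
            if w.overlaps(lo, hi):
                name = cname
                break
        out.append(ComponentWindow(name, w.t_start, w.t_end))
    return out


def _window_lag_mask(times_ms: np.ndarray, window: ComponentWindow) -> np.ndarray:
    mask = (times_ms >= window.t_start) & (times_ms <= window.t_end)
    if not np.any(mask):
        raise InvalidInputError(f"window {window.name} is empty after discretization")
    return mask


_PEAK_POLARITY = {"N1_TRF": -1}  # N1 is a negative deflection; default positive


def window_amplitude(
    model: TRFModel,
    window: ComponentWindow,
    channels: list[str] | None = None,
    mode: str = "mean",
    polarity: int | None = None,
) -> WindowAmplitude:
    """Channel-averaged TRF amplitude within a window (mean or signed peak).

    ``channels`` restricts to a sensor ROI (e.g. FCz/Cz/CPz); ``peak``
    takes the signed extremum of the given polarity (N1 windows default
    to the minimum, P2/P400 to the maximum).
    """
    if channels:
        missing = [c for c in channels if c not in model.channel_labels]
        if missing:
            raise InvalidInputError(f"channel(s) not found: {missing}")
        idx = [model.channel_labels.index(c) for c in channels]
        W = model.weights[idx]
    else:
        W = model.weights
    mask = _window_lag_mask(model.lag_spec.times_ms, window)
    trace = W.mean(axis=0)[mask]
    if mode == "mean":
        value = float(trace.mean())
    elif mode == "peak":
        pol = polarity if polarity is not None else _PEAK_POLARITY.get(window.name, 1)
        value = float(trace.min() if pol < 0 else trace.max())
    else:
        raise InvalidParameterError(f"unknown mode {mode!r}")
    return WindowAmplitude(window, value, mode, model.subject_id, model.condition)


def topographic_dominance(
    models_a: list[TRFModel],
    models_b: list[TRFModel],
    window: ComponentWindow,
    alpha: float = 0.05,
) -> PointwiseTestResult:
    """Per-electrode paired t-map of window-mean amplitudes, FDR over channels.

    Positive t: condition A (e.g. natural) larger; negative: condition B.
    """
    if len(models_a) != len(models_b) or not models_a:
        raise InvalidInputError("conditions must have the same paired subjects")
    mask = _window_lag_mask(models_a[0].lag_spec.times_ms, window)
    amp_a = np.stack([m.weights[:, mask].mean(axis=1) for m in models_a])
    amp_b = np.stack([m.weights[:, mask].mean(axis=1) for m in models_b])
    return paired_t_series(amp_a, amp_b, np.arange(amp_a.shape[1]), alpha)


def compare_gfp(
    gfp_a: np.ndarray, gfp_b: np.ndarray, times_ms, alpha: float = 0.05
) -> PointwiseTestResult:
    """Pointwise paired t of two conditions' GFP stacks [n_subjects x n_lags]."""
    return paired_t_series(np.asarray(gfp_a), np.asarray(gfp_b), times_ms, alpha)


def gfp_vs_baseline(
    gfp_stack: np.ndarray, times_ms, baseline: tuple[float, float] = (-100.0, 0.0),
    alpha: float = 0.05,
) -> PointwiseTestResult:
    """Pointwise paired t of per-subject GFP against its own baseline mean.

    The baseline is the mean GFP over ``baseline`` ms (default -100..0)
    per subject; FDR is applied across lags.
    """
    gfp_stack = np.asarray(gfp_stack, dtype=float)
    times = np.asarray(times_ms, dtype=float)
    base_mask = (times >= baseline[0]) & (times < baseline[1])
    if not np.any(base_mask):
        raise InvalidInputError("lag axis contains no baseline samples")
    base = gfp_stack[:, base_mask].mean(axis=1, keepdims=True)
    return paired_t_series(gfp_stack, np.broadcast_to(base, gfp_stack.shape), times, alpha)
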