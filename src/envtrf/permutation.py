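"""Stimulus-shuffling permutation null for TRF components.

Shuffled TRFs are fit with the identical pipeline as valid TRFs except
that envelopes are deranged relative to the EEG (no envelope keeps its
own response), giving the amplitude distribution expected under no
stimulus-response coupling. Valid vs shuffled window amplitudes are
compared with two-tailed paired t-tests, FDR-corrected over the
windows x conditions family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError, InvalidParameterError
from .stats import ComponentWindow, fdr_bh, gfp, paired_t
from .trf import LagSpec, batch_fit, loo_lambda_search

__all__ = ["ShuffleScheme", "PermutationResult", "shuffle_pairing", "run_permutation"]


@dataclass(frozen=True)
class ShuffleScheme:
    """A permutation of item indices; derangements have no fixed point."""

    mapping: np.ndarray
    rng_seed: int | None = None
    constraint: str = "derangement"

    def __post_init__(self) -> None:
        m = np.asarray(self.mapping)
        if sorted(m.tolist()) != list(range(len(m))):
            raise InvalidParameterError("mapping must be a permutation of 0..n-1")
        if self.constraint == "derangement" and np.any(m == np.arange(len(m))):
            raise InvalidParameterError("derangement must have no fixed points")
        object.__setattr__(self, "mapping", m)


def shuffle_pairing(n_items: int, seed=None, constraint: str = "derangement") -> ShuffleScheme:
    """Uniformly sampled derangement of item indices.

    Rejection sampling from uniform permutations conditioned on having
    no fixed point is uniform over derangements; the acceptance
    probability tends to 1/e, so this terminates quickly.
    """
    if n_items < 2:
        raise InvalidInputError("need at least 2 items to shuffle")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    while True:
        perm = rng.permutation(n_items)
        if constraint != "derangement" or not np.any(perm == np.arange(n_items)):
            break
    return ShuffleScheme(perm, None if isinstance(seed, np.random.Generator) else seed, constraint)


@dataclass
class PermutationResult:
    """Valid vs shuffled amplitudes and their paired comparisons."""

    windows: list[ComponentWindow]
    conditions: tuple[str, ...]
    valid_amp: np.ndarray  # [n_subjects x n_conditions x n_windows]
    shuffled_amp: np.ndarray
    stats: pd.DataFrame  # condition, window, t, p, q, significant
    valid_weights: np.ndarray  # [n_subjects x n_conditions x n_channels x n_lags]
    shuffled_weights: np.ndarray
    valid_metrics: pd.DataFrame | None = None  # per subject/condition LOO mse & r
    shuffled_metrics: pd.DataFrame | None = None


def _pairing_responses(responses: np.ndarray, mappings: np.ndarray) -> np.ndarray:
    """Reorder each subject's items so envelope j is paired with response
    mapping^-1(j) — equivalent to pairing envelope mapping(i) with
    response i, but expressible as one indexed copy."""
    n_subj, n_cond, n_items = responses.shape[:3]
    inv = np.argsort(mappings, axis=1)  # inverse permutations per subject
    idx = inv[:, None, :, None, None]
    return np.take_along_axis(responses, idx, axis=2)


def _window_peak_gfp(weights: np.ndarray, times_ms: np.ndarray,
                     windows: list[ComponentWindow]) -> np.ndarray:
    """Peak GFP within each window; weights [... x n_ch x n_lags]."""
    g = gfp(weights)
    out = np.empty(weights.shape[:-2] + (len(windows),))
    for wi, w in enumerate(windows):
        mask = (times_ms >= w.t_start) & (times_ms <= w.t_end)
        if not np.any(mask):
            raise InvalidInputError(f"window {w.name} has no lags")
        out[..., wi] = g[..., mask].max(axis=-1)
    return out


def _loo_metrics(envelopes, responses, lag_spec, lam, mappings, conditions,
                 normalize, onset_index) -> pd.DataFrame:
    rows = []
    for s in range(responses.shape[0]):
        env_order = [envelopes[j] for j in mappings[s]]
        for ci, cond in enumerate(conditions):
            res = loo_lambda_search(env_order, responses[s, ci].astype(float), lag_spec,
                                    grid=[lam], normalize=normalize, onset_index=onset_index)
            rows.append({"subject": s, "condition": cond,
                         "mse": res.cv_mse[0], "pearson_r": res.cv_r[0]})
    return pd.DataFrame(rows)


def run_permutation(
    envelopes,
    responses: np.ndarray,
    lag_spec: LagSpec,
    lambda_: float,
    windows: list[ComponentWindow],
    n_shuffles: int = 1,
    seed: int = 0,
    conditions: tuple[str, ...] = ("natural", "vocoded"),
    alpha: float = 0.05,
    normalize: bool = True,
    onset_index: int = 0,
    compute_metrics: bool = False,
    _schemes: np.ndarray | None = None,
) -> PermutationResult:
    """Fit valid and stimulus-shuffled TRFs and compare window amplitudes.

    ``responses`` is [n_subjects x n_conditions x n_items x n_channels x
    n_times]. Both arms run through the same fitting code; the only
    difference is the envelope-to-response pairing (``_schemes`` lets
    tests inject an explicit pairing, e.g. the identity). Shuffled
    weights are averaged over ``n_shuffles`` independent derangements.
    Amplitude = peak GFP within each window; comparisons are two-tailed
    paired t with BH-FDR over the windows x conditions family.
    """
    responses = np.asarray(responses)
    if responses.ndim != 5 or responses.shape[1] != len(conditions):
        raise InvalidInputError("responses must be [subj x cond x item x ch x time]")
    if n_shuffles < 1:
        raise InvalidParameterError("n_shuffles must be >= 1")
    n_subj, _, n_items = responses.shape[:3]
    rng = np.random.default_rng(seed)

    fit = lambda resp: batch_fit(envelopes, resp, lag_spec, lambda_,
                                 normalize=normalize, onset_index=onset_index)
    identity = np.tile(np.arange(n_items), (n_subj, 1))
    valid_W = fit(_pairing_responses(responses, identity))

    shuffled_W = np.zeros_like(valid_W)
    last_schemes = identity
    for _ in range(n_shuffles):
        if _schemes is not None:
            schemes = np.asarray(_schemes)
        else:
            schemes = np.stack([shuffle_pairing(n_items, rng).mapping for _ in range(n_subj)])
        last_schemes = schemes
        shuffled_W += fit(_pairing_responses(responses, schemes))
    shuffled_W /= n_shuffles

    times = lag_spec.times_ms
    valid_amp = _window_peak_gfp(valid_W, times, windows)
    shuffled_amp = _window_peak_gfp(shuffled_W, times, windows)

    rows = []
    for ci, cond in enumerate(conditions):
        for wi, w in enumerate(windows):
            t, p, df = paired_t(valid_amp[:, ci, wi], shuffled_amp[:, ci, wi])
            rows.append({"condition": cond, "window": w.name, "t": t, "p": p, "df": df})
    table = pd.DataFrame(rows)
    q, sig = fdr_bh(table["p"].to_numpy(), alpha)
    table["q"] = q
    table["significant"] = sig

    valid_metrics = shuffled_metrics = None
    if compute_metrics:
        valid_metrics = _loo_metrics(envelopes, responses, lag_spec, lambda_, identity,
                                     conditions, normalize, onset_index)
        shuffled_metrics = _loo_metrics(envelopes, responses, lag_spec, lambda_, last_schemes,
                                        conditions, normalize, onset_index)

    return PermutationResult(list(windows), tuple(conditions), valid_amp, shuffled_amp,
                             table, valid_W, shuffled_W, valid_metrics, shuffled_metrics)
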