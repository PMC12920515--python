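"""Forward (encoding) temporal response functions by ridge regression.

The TRF is the linear kernel w(tau, channel) mapping the stimulus
envelope s(t) to the EEG response r(t, channel) over lags -100..600 ms:

    r(t, ch) = sum_tau w(tau, ch) * s(t - tau) + intercept(ch)

Weights are estimated from the normal equations with a ridge penalty
scaled by the mean diagonal of X'X (so the regularization grid is
invariant to stimulus scale, the mTRF convention) and an unpenalized
intercept. The ridge parameter is selected by leave-one-out
cross-validation across sentence-level responses, scored by mean squared
error averaged over channels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as spl

from .errors import DegenerateInputError, InvalidInputError, InvalidParameterError
from .frontend import EnvelopeSignal
from .preprocess import AveragedResponse

__all__ = [
    "LagSpec",
    "TRFModel",
    "LambdaSearchResult",
    "PredictionMetrics",
    "lag_matrix",
    "fit_ridge",
    "fit_subject_trf",
    "batch_fit",
    "loo_lambda_search",
    "select_lambda_joint",
    "predict",
    "score",
    "grand_average",
]

DEFAULT_GRID = tuple(10.0**k for k in range(-6, 7))  # 1e-6 .. 1e6


@dataclass(frozen=True)
class LagSpec:
    """Lag window for the TRF, in ms, discretized on the EEG sample grid.

    Lag indices run from floor(t_min/1000*fs) to ceil(t_max/1000*fs)
    inclusive; for (-100, 600) ms at 256 Hz that is -26..154, 181 lags.
    """

    t_min_ms: float = -100.0
    t_max_ms: float = 600.0
    sample_rate: float = 256.0

    def __post_init__(self) -> None:
        if self.t_min_ms >= self.t_max_ms:
            raise InvalidParameterError("t_min_ms must be < t_max_ms")
        if self.sample_rate <= 0:
            raise InvalidParameterError("sample_rate must be positive")

    @property
    def lag_indices(self) -> np.ndarray:
        lo = math.floor(self.t_min_ms / 1000.0 * self.sample_rate)
        hi = math.ceil(self.t_max_ms / 1000.0 * self.sample_rate)
        return np.arange(lo, hi + 1)

    @property
    def times_ms(self) -> np.ndarray:
        return self.lag_indices * 1000.0 / self.sample_rate

    @property
    def n_lags(self) -> int:
        return len(self.lag_indices)


@dataclass
class TRFModel:
    """Estimated TRF kernel plus the fit's bookkeeping."""

    weights: np.ndarray  # [n_channels x n_lags], response units per envelope unit
    intercept: np.ndarray  # [n_channels]
    lag_spec: LagSpec
    lambda_: float
    channel_labels: list[str] = field(default_factory=list)
    condition: str = ""
    subject_id: str = ""
    normalized: bool = True  # whether envelope/response were z-scored per item

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise InvalidInputError("TRF weights must be finite")
        if self.weights.shape[1] != self.lag_spec.n_lags:
            raise InvalidInputError("weights do not match lag_spec")


@dataclass(frozen=True)
class LambdaSearchResult:
    """Cross-validation record of the ridge-parameter grid search."""

    grid: np.ndarray
    cv_mse: np.ndarray  # mean over folds and channels, per lambda
    cv_r: np.ndarray  # mean Pearson r over folds and channels, per lambda
    best_lambda: float


@dataclass(frozen=True)
class PredictionMetrics:
    """Channel-averaged and per-channel prediction accuracy."""

    mse: float
    pearson_r: float
    per_channel_mse: np.ndarray
    per_channel_r: np.ndarray


def lag_matrix(envelope, lag_spec_or_indices) -> np.ndarray:
    """Design matrix: column j holds the envelope delayed by lag j samples.

    X[t, j] = s[t - lag_j], zero outside the epoch, so the response at
    time t is modeled from the stimulus at t - tau.
    """
    if isinstance(envelope, EnvelopeSignal):
        s = envelope.values
    else:
        s = np.asarray(envelope, dtype=float)
    lags = (
        lag_spec_or_indices.lag_indices
        if isinstance(lag_spec_or_indices, LagSpec)
        else np.asarray(lag_spec_or_indices)
    )
    n = len(s)
    X = np.zeros((n, len(lags)))
    for j, lag in enumerate(lags):
        if lag >= 0:
            X[lag:, j] = s[: n - lag] if lag < n else 0.0
        else:
            X[: n + lag, j] = s[-lag:]
    return X


def _solve_normal(G: np.ndarray, C: np.ndarray, lam: float) -> np.ndarray:
    """Solve (G + lam*m*P) W = C with unpenalized first (intercept) row."""
    p = G.shape[0]
    diag = np.diag(G)[1:]
    m = diag.mean() if len(diag) else 1.0
    A = G.copy()
    A[np.arange(1, p), np.arange(1, p)] += lam * m
    try:
        return spl.solve(A, C, assume_a="sym")
    except np.linalg.LinAlgError as err:  # pragma: no cover - scipy raises LinAlgError
        raise DegenerateInputError(
            "normal equations singular; use lambda > 0 for rank-deficient designs"
        ) from err


def fit_ridge(X: np.ndarray, Y: np.ndarray, lambda_: float, lag_spec: LagSpec | None = None,
              **model_kwargs) -> TRFModel:
    """Ridge solution W = (X'X + lam*m*I)^-1 X'Y with unpenalized intercept.

    ``m`` is the mean diagonal of X'X (penalized block), making the
    lambda grid invariant to stimulus scale. ``Y`` is [n_times x
    n_channels]; the returned weights are [n_channels x n_lags].
    """
    if lambda_ < 0:
        raise InvalidParameterError("lambda_ must be >= 0")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise InvalidInputError("X and Y must be time-aligned")
    Xa = np.column_stack([np.ones(X.shape[0]), X])
    G = Xa.T @ Xa
    C = Xa.T @ Y
    if lambda_ == 0.0 and np.linalg.matrix_rank(G) < G.shape[0]:
        raise DegenerateInputError("design is rank-deficient at lambda = 0; use lambda > 0")
    W = _solve_normal(G, C, lambda_)
    spec = lag_spec or LagSpec(0, (X.shape[1] - 1) * 1000.0 / 256.0, 256.0)
    return TRFModel(W[1:].T, W[0], spec, float(lambda_), **model_kwargs)


def _as_item_arrays(envelopes, responses):
    """Coerce inputs to (list of 1-D envelope arrays, [items x ch x t] array)."""
    envs = [e.values if isinstance(e, EnvelopeSignal) else np.asarray(e, dtype=float)
            for e in envelopes]
    if isinstance(responses, AveragedResponse):
        resp = responses.data
    else:
        resp = np.asarray(responses, dtype=float)
    if resp.ndim != 3 or resp.shape[0] != len(envs):
        raise InvalidInputError("responses must be [n_items x n_channels x n_times]")
    return envs, resp


def _zscore_env(e: np.ndarray) -> np.ndarray:
    sd = e.std()
    if sd == 0:
        raise DegenerateInputError("constant envelope cannot be z-scored")
    return (e - e.mean()) / sd


def _zscore_resp(y: np.ndarray) -> np.ndarray:
    """Pooled (single-scalar) per-item z-score: preserves channel topography."""
    sd = y.std()
    if sd == 0:
        raise DegenerateInputError("constant response cannot be z-scored")
    return (y - y.mean()) / sd


def _item_designs(envs, lag_spec: LagSpec, n_times: int, normalize: bool):
    """Per-item augmented design matrices, padded/truncated to the epoch."""
    designs = []
    lags = lag_spec.lag_indices
    for e in envs:
        e = np.asarray(e, dtype=float)
        if normalize:
            e = _zscore_env(e)
        s = np.zeros(n_times)
        s[: min(len(e), n_times)] = e[:n_times]
        X = lag_matrix(s, lags)
        designs.append(np.column_stack([np.ones(n_times), X]))
    return designs


def fit_subject_trf(
    envelopes,
    responses,
    lag_spec: LagSpec,
    lambda_: float,
    normalize: bool = True,
    onset_index: int | None = None,
    **model_kwargs,
) -> TRFModel:
    """Fit one TRF from all sentence items of a subject/condition.

    Envelopes are aligned to the response epoch at ``onset_index``
    (defaults to the sample where the epoch window crosses t = 0). With
    ``normalize`` the envelope is z-scored per item and the response is
    z-scored per item with a single pooled scalar.
    """
    envs, resp = _as_item_arrays(envelopes, responses)
    n_items, n_ch, n_t = resp.shape
    if onset_index is None and isinstance(responses, AveragedResponse):
        onset_index = int(round(-responses.epoch_window[0] * responses.sample_rate))
    shift = onset_index or 0
    envs = [np.concatenate([np.zeros(shift), e]) for e in envs]
    designs = _item_designs(envs, lag_spec, n_t, normalize)
    G = sum(Xa.T @ Xa for Xa in designs)
    C = np.zeros((G.shape[0], n_ch))
    for Xa, y in zip(designs, resp):
        yz = _zscore_resp(y) if normalize else y
        C += Xa.T @ yz.T
    if lambda_ == 0.0 and np.linalg.matrix_rank(G) < G.shape[0]:
        raise DegenerateInputError("design is rank-deficient at lambda = 0; use lambda > 0")
    W = _solve_normal(G, C, lambda_)
    return TRFModel(W[1:].T, W[0], lag_spec, float(lambda_), normalized=normalize, **model_kwargs)


def batch_fit(
    envelopes,
    responses: np.ndarray,
    lag_spec: LagSpec,
    lambda_: float,
    normalize: bool = True,
    onset_index: int = 0,
    work_dtype=None,
) -> np.ndarray:
    """Fit many TRFs sharing the same stimulus set in one factorization.

    ``responses`` is [... x n_items x n_channels x n_times] (leading axes
    index subjects/conditions); returns weights [... x n_channels x
    n_lags]. Because the design depends only on the envelopes, the
    regularized normal matrix is factorized once and reused.
    ``work_dtype`` sets the precision of the cross-product accumulation
    (default float64; float32 halves memory traffic for large studies).
    """
    responses = np.asarray(responses, dtype=float)
    lead = responses.shape[:-3]
    n_items, n_ch, n_t = responses.shape[-3:]
    envs = [e.values if isinstance(e, EnvelopeSignal) else np.asarray(e, dtype=float)
            for e in envelopes]
    envs = [np.concatenate([np.zeros(onset_index), e]) for e in envs]
    designs = _item_designs(envs, lag_spec, n_t, normalize)
    Xa = np.stack(designs)  # [items x t x p]
    p = Xa.shape[-1]
    XaT = Xa.transpose(2, 0, 1).reshape(p, n_items * n_t)
    G = XaT @ XaT.T
    A = G.copy()
    A[np.arange(1, p), np.arange(1, p)] += lambda_ * np.diag(G)[1:].mean()
    cho = spl.cho_factor(A)
    work = np.dtype(work_dtype or np.float64)
    XaTw = XaT.astype(work) if work != XaT.dtype else XaT
    flat = responses.reshape(-1, n_items, n_ch, n_t)
    n_fits = flat.shape[0]
    W = np.empty((n_fits, n_ch, p))
    chunk = max(1, int(3e7 // (n_items * n_ch * n_t)))  # ~240 MB float64 per chunk
    for start in range(0, n_fits, chunk):
        block = np.asarray(flat[start : start + chunk], dtype=work)
        if normalize:
            sd = block.std(axis=(2, 3), keepdims=True)
            if np.any(sd == 0):
                raise DegenerateInputError("constant response cannot be z-scored")
            block = (block - block.mean(axis=(2, 3), keepdims=True)) / sd
        Y2 = block.transpose(0, 1, 3, 2).reshape(block.shape[0], n_items * n_t, n_ch)
        C = np.matmul(XaTw, Y2).astype(np.float64)  # [chunk x p x ch]
        Wc = spl.cho_solve(cho, C.transpose(1, 0, 2).reshape(p, -1))
        W[start : start + chunk] = (
            Wc.reshape(p, block.shape[0], n_ch).transpose(1, 2, 0)
        )
    return W[..., 1:].reshape(*lead, n_ch, lag_spec.n_lags)


def _pearson_cols(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Pearson r; constant columns yield NaN (undefined)."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    na = np.sqrt((a**2).sum(axis=0))
    nb = np.sqrt((b**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(axis=0) / (na * nb)
    r[(na == 0) | (nb == 0)] = np.nan
    return r


def loo_lambda_search(
    envelopes,
    responses,
    lag_spec: LagSpec,
    grid=DEFAULT_GRID,
    normalize: bool = True,
    onset_index: int | None = None,
) -> LambdaSearchResult:
    """Leave-one-out search for the ridge parameter across sentence items.

    For each lambda, each item in turn is held out: the TRF is fit on the
    remaining items and used to predict the held-out EEG from its
    envelope; MSE (averaged over channels and time) and Pearson r are
    averaged over folds. ``best_lambda`` minimizes the fold-averaged MSE.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise InvalidParameterError("grid must be non-empty")
    if np.any(grid < 0):
        raise InvalidParameterError("grid values must be >= 0")
    envs, resp = _as_item_arrays(envelopes, responses)
    n_items, n_ch, n_t = resp.shape
    if n_items < 2:
        raise InvalidInputError("leave-one-out needs at least 2 items")
    if onset_index is None and isinstance(responses, AveragedResponse):
        onset_index = int(round(-responses.epoch_window[0] * responses.sample_rate))
    shift = onset_index or 0
    envs = [np.concatenate([np.zeros(shift), e]) for e in envs]
    designs = _item_designs(envs, lag_spec, n_t, normalize)
    resp_z = np.stack([_zscore_resp(y) if normalize else y for y in resp])
    G_items = [Xa.T @ Xa for Xa in designs]
    C_items = [Xa.T @ y.T for Xa, y in zip(designs, resp_z)]
    G_all = sum(G_items)
    C_all = sum(C_items)
    cv_mse = np.zeros(len(grid))
    cv_r = np.zeros(len(grid))
    for gi, lam in enumerate(grid):
        fold_mse = np.zeros(n_items)
        fold_r = np.zeros(n_items)
        for f in range(n_items):
            W = _solve_normal(G_all - G_items[f], C_all - C_items[f], lam)
            pred = designs[f] @ W
            actual = resp_z[f].T
            fold_mse[f] = ((pred - actual) ** 2).mean()
            r = _pearson_cols(pred, actual)
            fold_r[f] = np.nanmean(r) if np.any(np.isfinite(r)) else np.nan
        cv_mse[gi] = fold_mse.mean()
        cv_r[gi] = np.nanmean(fold_r)
    best = float(grid[int(np.argmin(cv_mse))])
    return LambdaSearchResult(grid, cv_mse, cv_r, best)


def select_lambda_joint(*results: LambdaSearchResult) -> float:
    """One lambda minimizing the mean cross-validated MSE across searches
    (e.g. jointly across the two listening conditions)."""
    if not results:
        raise InvalidParameterError("need at least one search result")
    grid = results[0].grid
    for r in results[1:]:
        if not np.array_equal(r.grid, grid):
            raise InvalidInputError("lambda grids differ across results")
    mean_mse = np.mean([r.cv_mse for r in results], axis=0)
    return float(grid[int(np.argmin(mean_mse))])


def predict(model: TRFModel, envelope, n_times: int | None = None,
            onset_index: int = 0, normalize_env: bool | None = None) -> np.ndarray:
    """Predicted response [n_times x n_channels] for one envelope."""
    e = envelope.values if isinstance(envelope, EnvelopeSignal) else np.asarray(envelope, float)
    if normalize_env is None:
        normalize_env = model.normalized
    if normalize_env:
        e = _zscore_env(e)
    e = np.concatenate([np.zeros(onset_index), e])
    if n_times is not None:
        s = np.zeros(n_times)
        s[: min(len(e), n_times)] = e[:n_times]
        e = s
    X = lag_matrix(e, model.lag_spec)
    return X @ model.weights.T + model.intercept


def score(pred: np.ndarray, actual: np.ndarray) -> PredictionMetrics:
    """MSE and Pearson r per channel, then channel-averaged.

    Constant prediction or constant actual makes Pearson undefined; such
    channels are NaN and excluded from the channel average (flagged as
    missing, never coerced to 0).
    """
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape:
        raise InvalidInputError("prediction and actual shapes differ")
    err = ((pred - actual) ** 2).mean(axis=0)
    r = _pearson_cols(pred, actual)
    mean_r = float(np.nanmean(r)) if np.any(np.isfinite(r)) else float("nan")
    return PredictionMetrics(float(err.mean()), mean_r, err, r)


def grand_average(models: list[TRFModel]) -> TRFModel:
    """Element-wise mean of TRF weights across subjects."""
    if not models:
        raise InvalidInputError("no models to average")
    ref = models[0]
    for m in models[1:]:
        if m.lag_spec != ref.lag_spec or m.channel_labels != ref.channel_labels:
            raise InvalidInputError("models differ in lag spec or channels")
    W = np.mean([m.weights for m in models], axis=0)
    b = np.mean([m.intercept for m in models], axis=0)
    return TRFModel(W, b, ref.lag_spec, ref.lambda_, list(ref.channel_labels),
                    ref.condition, subject_id="grand_average", normalized=ref.normalized)
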