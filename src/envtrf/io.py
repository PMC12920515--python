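"""HDF5 containers for epochs, envelopes, and TRF models."""

from __future__ import annotations

import numpy as np
import h5py

from .frontend import EnvelopeSignal
from .preprocess import AveragedResponse, EpochSet
from .trf import LagSpec, TRFModel

__all__ = [
    "save_epochs",
    "load_epochs",
    "save_trf",
    "load_trf",
    "save_envelopes",
    "load_envelopes",
]

_STR = h5py.string_dtype()


def save_epochs(path, epochs: EpochSet) -> None:
    """Write an epoch container (/data, /fs, /window, /channels, ...)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip")
        f["fs"] = epochs.sample_rate
        f["window"] = np.asarray(epochs.epoch_window)
        f.create_dataset("channels", data=np.asarray(epochs.channel_labels, dtype=_STR))
        f["condition"] = epochs.condition
        f["subject"] = epochs.subject_id
        f["averaged"] = isinstance(epochs, AveragedResponse)
        if epochs.item_labels is not None:
            f.create_dataset("items", data=np.asarray(epochs.item_labels))


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        cls = AveragedResponse if bool(f["averaged"][()]) else EpochSet
        return cls(
            f["data"][()],
            float(f["fs"][()]),
            tuple(f["window"][()]),
            [c.decode() if isinstance(c, bytes) else str(c) for c in f["channels"][()]],
            f["condition"][()].decode(),
            f["subject"][()].decode(),
            f["items"][()] if "items" in f else None,
        )


def save_trf(path, model: TRFModel) -> None:
    """Write a TRF model (/weights, /lags_ms, /lambda, /fs, /channels)."""
    with h5py.File(path, "w") as f:
        f["weights"] = model.weights
        f["intercept"] = model.intercept
        f["lags_ms"] = np.asarray([model.lag_spec.t_min_ms, model.lag_spec.t_max_ms])
        f["fs"] = model.lag_spec.sample_rate
        f["lambda"] = model.lambda_
        f.create_dataset("channels", data=np.asarray(model.channel_labels, dtype=_STR))
        f["condition"] = model.condition
        f["subject"] = model.subject_id
        f["normalized"] = model.normalized


def load_trf(path) -> TRFModel:
    with h5py.File(path, "r") as f:
        spec = LagSpec(float(f["lags_ms"][0]), float(f["lags_ms"][1]), float(f["fs"][()]))
        return TRFModel(
            f["weights"][()],
            f["intercept"][()],
            spec,
            float(f["lambda"][()]),
            [c.decode() if isinstance(c, bytes) else str(c) for c in f["channels"][()]],
            f["condition"][()].decode(),
            f["subject"][()].decode(),
            bool(f["normalized"][()]),
        )


def save_envelopes(path, envelopes: list[EnvelopeSignal]) -> None:
    with h5py.File(path, "w") as f:
        for i, env in enumerate(envelopes):
            g = f.create_group(f"env{i:03d}")
            g["values"] = env.values
            g["fs"] = env.sample_rate
            g["source_id"] = env.source_id


def load_envelopes(path) -> list[EnvelopeSignal]:
    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            g = f[key]
            out.append(
                EnvelopeSignal(g["values"][()], float(g["fs"][()]), g["source_id"][()].decode())
            )
    return out
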