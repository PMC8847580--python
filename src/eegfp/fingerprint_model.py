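"""The convolutional identification model and its split into a
fingerprinting function plus a disposable identification head.

The network is a stack of same-padded conv blocks (ReLU + 2x2 max-pooling),
followed by flatten, dropout and a two-layer dense head (ReLU hidden,
softmax output).  After end-to-end training the head is cut off; the
flattened output of the last pooling stage is the fixed-length EEG
fingerprint.  Because that vector is shorter than the input tensor and the
network is non-injective (ReLU), the mapping is not invertible — the
fingerprint can be stored in place of raw EEG.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _nn
from .errors import ConfigurationError, TrainingError
from .preprocess import ModelInput, WindowParams, build_input_array
from .signal_io import EegRecording

__all__ = [
    "ClassifierConfig",
    "FingerprintVector",
    "TrainedModel",
    "FingerprintFunction",
    "build_classifier",
    "train_classifier",
    "split_fingerprint",
    "fingerprint_sample",
    "feature_length",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Architecture and training hyper-parameters.

    Defaults follow the reference configuration: RMSprop at learning rate
    1e-4, dropout 0.25, 30 epochs, batch 64, stride (1, 1); three conv
    blocks of 16/32/64 3x3 filters with 2x2 max-pooling, then a dense-128 +
    dense-n identification head (8 weight-bearing layers in total).
    """

    n_classes: int
    conv_blocks: tuple[tuple[int, tuple[int, int]], ...] = (
        (16, (3, 3)), (32, (3, 3)), (64, (3, 3)),
    )
    pool_size: tuple[int, int] = (2, 2)
    dense_hidden_size: int = 128
    dropout_rate: float = 0.25
    learning_rate: float = 1e-4
    epochs: int = 30
    batch_size: int = 64
    optimizer_name: str = "rmsprop"
    stride: tuple[int, int] = (1, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ConfigurationError("n_classes must be >= 2")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        if tuple(self.stride) != (1, 1):
            raise ConfigurationError("only stride (1, 1) is supported")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if not self.conv_blocks:
            raise ConfigurationError("at least one conv block is required")

    def to_dict(self) -> dict:
        return {
            "n_classes": self.n_classes,
            "conv_blocks": [[f, list(k)] for f, k in self.conv_blocks],
            "pool_size": list(self.pool_size),
            "dense_hidden_size": self.dense_hidden_size,
            "dropout_rate": self.dropout_rate,
            "learning_rate": self.learning_rate,
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "optimizer_name": self.optimizer_name,
            "stride": list(self.stride),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierConfig":
        d = dict(d)
        d["conv_blocks"] = tuple((int(f), tuple(k)) for f, k in d["conv_blocks"])
        d["pool_size"] = tuple(d["pool_size"])
        d["stride"] = tuple(d["stride"])
        return cls(**d)


@dataclass(frozen=True)
class FingerprintVector:
    """Fixed-length EEG fingerprint; the only thing the system stores.

    ``model_version`` binds the vector to the trained weights that produced
    it, so stale fingerprints are refused at verification time.
    """

    values: np.ndarray
    model_version: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=np.float64).ravel()
        )
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("fingerprint contains non-finite entries")

    def __len__(self) -> int:
        return self.values.size


def feature_length(config: ClassifierConfig,
                   input_shape: tuple[int, int, int]) -> int:
    """Fingerprint length m: propagate (eta, T) through the conv/pool stack.

    Same-padded stride-1 convolutions preserve the plane; each pooling floors
    both sides by the pool size; m = final height x width x last filter count.
    """
    h, w, _ = input_shape
    ph, pw = config.pool_size
    filters = 0
    for filters, kernel in config.conv_blocks:
        if kernel[0] > h or kernel[1] > w:
            raise ConfigurationError(
                f"kernel {kernel} larger than plane ({h}, {w})"
            )
        h //= ph
        w //= pw
        if h < 1 or w < 1:
            raise ConfigurationError("pooling collapsed the plane to nothing")
    return h * w * filters


class Classifier:
    """Untrained/trained CNN wrapper holding the layer stack and metadata."""

    def __init__(self, config: ClassifierConfig,
                 input_shape: tuple[int, int, int]):
        self.config = config
        self.input_shape = tuple(int(v) for v in input_shape)
        rng = np.random.default_rng((config.seed, 0xC0FFEE))
        layers: list[_nn.Layer] = []
        h, w, in_ch = self.input_shape
        for filters, kernel in config.conv_blocks:
            if kernel[0] > h or kernel[1] > w:
                raise ConfigurationError(
                    f"kernel {kernel} larger than plane ({h}, {w})"
                )
            layers.append(_nn.Conv2D(in_ch, filters, tuple(kernel), rng))
            layers.append(_nn.ReLU())
            layers.append(_nn.MaxPool2D(config.pool_size))
            in_ch = filters
            h //= config.pool_size[0]
            w //= config.pool_size[1]
            if h < 1 or w < 1:
                raise ConfigurationError("pooling collapsed the plane to nothing")
        layers.append(_nn.Flatten())
        self.fingerprint_boundary = len(layers)  # head starts here
        m = h * w * in_ch
        layers.append(_nn.Dropout(config.dropout_rate, rng))
        layers.append(_nn.Dense(m, config.dense_hidden_size, rng))
        layers.append(_nn.ReLU())
        layers.append(_nn.Dense(config.dense_hidden_size, config.n_classes, rng))
        self.net = _nn.Sequential(layers)
        self.feature_length = m
        self.trained = False
        self.history: list[dict] = []

    @property
    def n_weight_layers(self) -> int:
        """Weight-bearing layers (convs + dense)."""
        return sum(1 for layer in self.net.layers if layer.params)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = self._as_batch(x)
        return _nn.softmax(self.net.forward(x, training=False))

    def features(self, x: np.ndarray) -> np.ndarray:
        """Flattened output of the last fingerprinting layer, (N, m)."""
        x = self._as_batch(x)
        return self.net.forward(x, training=False,
                                upto=self.fingerprint_boundary)

    def head(self, features: np.ndarray) -> np.ndarray:
        """Identification head applied to precomputed features."""
        logits = self.net.forward_from(
            np.asarray(features, dtype=_nn.DTYPE), self.fingerprint_boundary
        )
        return _nn.softmax(logits)

    def _as_batch(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=_nn.DTYPE)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != self.input_shape:
            raise ConfigurationError(
                f"input shape {x.shape[1:]} != model shape {self.input_shape}"
            )
        return x

    @property
    def model_version(self) -> str:
        """Hash binding fingerprints to these exact weights and config."""
        digest = hashlib.sha256()
        digest.update(json.dumps(self.to_sidecar(), sort_keys=True).encode())
        for w in self.net.get_weights():
            digest.update(np.ascontiguousarray(w).tobytes())
        return digest.hexdigest()[:16]

    def to_sidecar(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "input_shape": list(self.input_shape),
            "feature_length": self.feature_length,
            "trained": self.trained,
        }


# spec-level aliases: a Classifier after train_classifier() is the TrainedModel
TrainedModel = Classifier


def build_classifier(config: ClassifierConfig,
                     input_shape: tuple[int, int, int]) -> Classifier:
    """Construct the untrained identification CNN for the given input shape."""
    return Classifier(config, input_shape)


def _stack_inputs(inputs) -> np.ndarray:
    if isinstance(inputs, np.ndarray):
        return inputs
    return np.stack([
        mi.data if isinstance(mi, ModelInput) else np.asarray(mi)
        for mi in inputs
    ])


def train_classifier(model: Classifier, inputs, labels,
                     config: ClassifierConfig | None = None) -> Classifier:
    """End-to-end training of the full model (fingerprinting + head).

    ``inputs`` is a list of :class:`ModelInput` (or an ``(N, eta, T, C)``
    array); ``labels`` are integer class ids in ``[0, n_classes)``.
    Reproducible: shuffling, dropout, and weight init all derive from
    ``config.seed``.  Records per-epoch loss/accuracy in ``model.history``.
    """
    config = config or model.config
    x = _stack_inputs(inputs).astype(_nn.DTYPE)
    y = np.asarray(labels, dtype=np.int64)
    if x.shape[0] != y.shape[0]:
        raise TrainingError(f"{x.shape[0]} inputs but {y.shape[0]} labels")
    if x.shape[1:] != model.input_shape:
        raise TrainingError(
            f"input shape {x.shape[1:]} != model shape {model.input_shape}"
        )
    if y.min(initial=0) < 0 or y.max(initial=0) >= config.n_classes:
        raise TrainingError(
            f"labels must lie in [0, {config.n_classes}), got range "
            f"[{y.min()}, {y.max()}]"
        )
    present = np.bincount(y, minlength=config.n_classes)
    if (present == 0).any():
        raise TrainingError(
            f"classes without samples: {np.flatnonzero(present == 0).tolist()}"
        )

    optimizer = _nn.make_optimizer(config.optimizer_name, config.learning_rate)
    shuffle_rng = np.random.default_rng((config.seed, 0x5A))
    n = x.shape[0]
    model.history = []
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        losses = []
        correct = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            loss, logits = model.net.train_step(x[idx], y[idx], optimizer)
            losses.append(loss * idx.size)
            correct += int((logits.argmax(axis=1) == y[idx]).sum())
        model.history.append({
            "epoch": epoch,
            "loss": float(np.sum(losses) / n),
            "accuracy": correct / n,
        })
    model.trained = True
    return model


class FingerprintFunction:
    """The one-way fingerprint function f: model input -> R^m.

    Wraps only the fingerprinting layers of a classifier; the identification
    head is not reachable through this object.
    """

    def __init__(self, classifier: Classifier):
        if not classifier.trained:
            import logging
            logging.getLogger(__name__).warning(
                "splitting an untrained model: fingerprints are valid vectors "
                "but useless for authentication"
            )
        self._classifier = classifier
        self.length = classifier.feature_length
        self.input_shape = classifier.input_shape
        self.model_version = classifier.model_version

    def __call__(self, x: np.ndarray) -> np.ndarray:
        """Fingerprint one input (m,) or a batch (N, m), float64."""
        single = np.asarray(x).ndim == 3
        feats = self._classifier.features(x).astype(np.float64)
        return feats[0] if single else feats


def split_fingerprint(model: Classifier) -> FingerprintFunction:
    """Cut off the identification head; return the fingerprint function f."""
    return FingerprintFunction(model)


def fingerprint_sample(
    f: FingerprintFunction,
    recording: EegRecording,
    channels,
    params: WindowParams,
    aggregation: str = "mean",
    orthogonalize_flag: bool = True,
) -> FingerprintVector:
    """Fingerprint a whole recording.

    Builds every augmented input (normalize -> orthogonalize -> window),
    applies ``f`` to each, and aggregates element-wise (default mean) into
    one stored vector.  ``aggregation="none"`` is used internally by
    score-level evaluation and returns the per-window matrix.
    """
    x, _ = build_input_array(
        recording, channels, params, orthogonalize_flag=orthogonalize_flag
    )
    feats = f(x)
    if aggregation == "none":
        return feats
    if aggregation == "mean":
        agg = feats.mean(axis=0)
    elif aggregation == "median":
        agg = np.median(feats, axis=0)
    else:
        raise ConfigurationError(f"unknown aggregation {aggregation!r}")
    return FingerprintVector(values=agg, model_version=f.model_version)


def save_model(path, model: Classifier) -> None:
    """Persist weights (NPZ) plus a JSON sidecar with config and version."""
    path = Path(path)
    weights = {f"w{i}": w for i, w in enumerate(model.net.get_weights())}
    np.savez(path.with_suffix(".npz"), **weights)
    sidecar = model.to_sidecar()
    sidecar["model_version"] = model.model_version
    sidecar["history"] = model.history
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path) -> Classifier:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    config = ClassifierConfig.from_dict(sidecar["config"])
    model = Classifier(config, tuple(sidecar["input_shape"]))
    with np.load(path.with_suffix(".npz")) as npz:
        model.net.set_weights([npz[f"w{i}"] for i in range(len(npz.files))])
    model.trained = bool(sidecar.get("trained", False))
    model.history = sidecar.get("history", [])
    if sidecar.get("model_version") and sidecar["model_version"] != model.model_version:
        raise ConfigurationError("model checkpoint corrupted: version mismatch")
    return model
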