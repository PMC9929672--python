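"""Three-dense-layer classifier: D -> D -> H -> C with ReLU, ReLU, softmax.

The first dense layer matches the input width (the receptor layer), the
variable-width intermediate layer is the bow-tie knot, and the output layer
is one softmax unit per response class.  Everything is plain NumPy with
explicit seeding, so full training is bitwise reproducible: same seeds, same
weights.  Training is mini-batch Adam on categorical cross-entropy.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field, replace

import numpy as np

from bowtienet.datagen import LabeledDataset, TRAIN, VALIDATION

__all__ = [
    "NetworkSpec", "TrainingConfig", "NetworkModel", "DivergenceError",
    "ModelFormatError", "init_network", "train", "transfer_train",
    "evaluate", "save_model", "load_model",
]


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


class ModelFormatError(ValueError):
    """Raised when a model file cannot be parsed."""


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of the classifier.

    ``first_layer_width`` always equals ``input_dim``: the receptor layer is
    one trainable unit per input.  ``intermediate_width`` (H) is the knot
    width swept in the experiments.
    """

    input_dim: int
    intermediate_width: int
    output_dim: int
    first_layer_trainable: bool = True

    def __post_init__(self) -> None:
        if self.input_dim < 1 or self.output_dim < 2:
            raise ValueError("need input_dim >= 1 and output_dim >= 2")
        if self.intermediate_width < 1:
            raise ValueError("intermediate_width must be >= 1")

    @property
    def first_layer_width(self) -> int:
        return self.input_dim

    @property
    def layer_shapes(self) -> list[tuple[int, int]]:
        D, H, C = self.input_dim, self.intermediate_width, self.output_dim
        return [(D, D), (D, H), (H, C)]


@dataclass(frozen=True)
class TrainingConfig:
    """Optimisation settings; defaults are the ecosystem's standard choices."""

    epochs: int = 600
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 128
    loss: str = "categorical_crossentropy"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.loss != "categorical_crossentropy":
            raise ValueError(f"unsupported loss {self.loss!r}")
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("learning_rate must be > 0 and batch_size >= 1")


@dataclass
class NetworkModel:
    """Weights, biases, spec, per-epoch history and the init seed."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    spec: NetworkSpec
    history: dict[str, list[float]] = field(
        default_factory=lambda: {"loss": [], "accuracy": []})
    rng_seed: int = 0

    def copy(self) -> "NetworkModel":
        return NetworkModel(
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
            spec=self.spec,
            history={k: list(v) for k, v in self.history.items()},
            rng_seed=self.rng_seed,
        )

    # -- forward pass -----------------------------------------------------
    def hidden_activations(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Post-ReLU outputs of the first (receptor) and intermediate layers."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        h1 = np.maximum(X @ self.weights[0] + self.biases[0], 0.0)
        h2 = np.maximum(h1 @ self.weights[1] + self.biases[1], 0.0)
        return h1, h2

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        _, h2 = self.hidden_activations(X)
        return _softmax(h2 @ self.weights[2] + self.biases[2])

    def predict(self, X: np.ndarray) -> np.ndarray:
        # np.argmax breaks ties toward the lowest class index
        return self.predict_proba(X).argmax(axis=1)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def init_network(spec: NetworkSpec, rng_seed: int = 0) -> NetworkModel:
    """Glorot-uniform weights, zero biases, fully determined by ``rng_seed``."""
    rng = np.random.default_rng(rng_seed)
    weights, biases = [], []
    for fan_in, fan_out in spec.layer_shapes:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return NetworkModel(weights=weights, biases=biases, spec=spec,
                        rng_seed=rng_seed)


def _check_dims(model: NetworkModel, ds: LabeledDataset) -> None:
    if ds.n_dims != model.spec.input_dim:
        raise ValueError(
            f"dataset has {ds.n_dims} inputs but network expects "
            f"{model.spec.input_dim}")
    if ds.y.max() >= model.spec.output_dim:
        raise ValueError(
            f"dataset label {int(ds.y.max())} exceeds network output_dim "
            f"{model.spec.output_dim}")


def train(model: NetworkModel, ds: LabeledDataset, cfg: TrainingConfig) -> NetworkModel:
    """Train a copy of ``model`` on the rows flagged ``train``.

    Returns a new model with per-epoch mean loss and accuracy appended to its
    history; the input model is not modified.  Deterministic given the init
    seed and ``cfg.rng_seed`` (which drives batch shuffling).
    """
    _check_dims(model, ds)
    out = model.copy()
    X, y = ds.partition(TRAIN)
    n = X.shape[0]
    if cfg.epochs == 0:
        return out
    if n < cfg.batch_size:
        raise ValueError(
            f"{n} training rows but batch_size={cfg.batch_size}; "
            "lower the batch size for small datasets")

    C = out.spec.output_dim
    Y = np.zeros((n, C))
    Y[np.arange(n), y] = 1.0

    params = out.weights + out.biases
    if cfg.optimizer == "adam":
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
    rng = np.random.default_rng(cfg.rng_seed)
    W, B = out.weights, out.biases

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses, correct, seen = 0.0, 0, 0
        for start in range(0, n - cfg.batch_size + 1, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            Xb, Yb, yb = X[idx], Y[idx], y[idx]
            bs = idx.size

            z1 = Xb @ W[0] + B[0]
            h1 = np.maximum(z1, 0.0)
            z2 = h1 @ W[1] + B[1]
            h2 = np.maximum(z2, 0.0)
            z3 = h2 @ W[2] + B[2]
            p = _softmax(z3)

            batch_loss = -np.log(np.clip(p[np.arange(bs), yb], 1e-12, None)).mean()
            losses += batch_loss * bs
            correct += int((p.argmax(axis=1) == yb).sum())
            seen += bs

            d3 = (p - Yb) / bs
            gW3 = h2.T @ d3
            gb3 = d3.sum(axis=0)
            d2 = (d3 @ W[2].T) * (z2 > 0)
            gW2 = h1.T @ d2
            gb2 = d2.sum(axis=0)
            d1 = (d2 @ W[1].T) * (z1 > 0)
            if out.spec.first_layer_trainable:
                gW1 = Xb.T @ d1
                gb1 = d1.sum(axis=0)
            else:
                gW1 = np.zeros_like(W[0])
                gb1 = np.zeros_like(B[0])
            grads = [gW1, gW2, gW3, gb1, gb2, gb3]

            if cfg.optimizer == "adam":
                step += 1
                lr_t = cfg.learning_rate * (
                    np.sqrt(1 - beta2 ** step) / (1 - beta1 ** step))
                for k, (prm, g) in enumerate(zip(params, grads)):
                    m[k] = beta1 * m[k] + (1 - beta1) * g
                    v[k] = beta2 * v[k] + (1 - beta2) * g * g
                    prm -= lr_t * m[k] / (np.sqrt(v[k]) + eps)
            else:  # plain SGD
                for prm, g in zip(params, grads):
                    prm -= cfg.learning_rate * g

        epoch_loss = losses / seen
        if not np.isfinite(epoch_loss):
            raise DivergenceError(
                f"training loss became non-finite at epoch {epoch + 1}")
        out.history["loss"].append(float(epoch_loss))
        out.history["accuracy"].append(correct / seen)
    return out


def transfer_train(pretrained: NetworkModel, full_ds: LabeledDataset,
                   cfg: TrainingConfig) -> NetworkModel:
    """Continue training a pre-evolved model on the full (unmasked) data.

    Histories concatenate, so the returned model carries the whole two-phase
    trajectory.  A spec/data mismatch raises before any computation.
    """
    _check_dims(pretrained, full_ds)
    return train(pretrained, full_ds, cfg)


def evaluate(model: NetworkModel, ds: LabeledDataset,
             which: str = VALIDATION) -> float:
    """Fraction of argmax-correct predictions over the selected partition."""
    _check_dims(model, ds)
    X, y = ds.partition(which)
    if X.shape[0] == 0:
        raise ValueError(f"partition {which!r} is empty")
    return float((model.predict(X) == y).mean())


# -- persistence: single .npz with weights + a JSON metadata entry ---------

def save_model(model: NetworkModel, path) -> None:
    """Write the model to a single ``.npz`` archive (weights bitwise exact)."""
    meta = {
        "spec": {
            "input_dim": model.spec.input_dim,
            "intermediate_width": model.spec.intermediate_width,
            "output_dim": model.spec.output_dim,
            "first_layer_trainable": model.spec.first_layer_trainable,
        },
        "history": model.history,
        "rng_seed": model.rng_seed,
    }
    arrays = {f"W{i}": w for i, w in enumerate(model.weights)}
    arrays.update({f"b{i}": b for i, b in enumerate(model.biases)})
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_model(path) -> NetworkModel:
    """Load a model written by :func:`save_model`; corrupt files raise
    :class:`ModelFormatError` rather than returning garbage."""
    try:
        with np.load(path, allow_pickle=False) as archive:
            meta = json.loads(bytes(archive["meta_json"]).decode("utf-8"))
            weights = [archive[f"W{i}"] for i in range(3)]
            biases = [archive[f"b{i}"] for i in range(3)]
    except (OSError, KeyError, ValueError, json.JSONDecodeError,
            zipfile.BadZipFile) as exc:
        raise ModelFormatError(f"cannot read model file {path}: {exc}") from exc
    spec = NetworkSpec(**meta["spec"])
    return NetworkModel(weights=weights, biases=biases, spec=spec,
                        history=meta["history"], rng_seed=meta["rng_seed"])
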