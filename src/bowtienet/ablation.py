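"""Prediction-time node masking and node/connection pruning.

Masking measures where task information is embedded: during inference only,
each node of a chosen layer's post-activation output is zeroed
independently with probability p — with NO rescaling of the survivors,
because the experiment models physical ablation of signaling elements, not
regularisation.  If input-layer and intermediate-layer masking degrade
accuracy by the same amount, the narrow intermediate layer embeds as much
task information as the wide input layer.

Pruning compares two sparsification analogies: node-centric (remove whole
intermediate units — pseudogenization) and connection-centric (zero the
smallest-magnitude weights — attenuated ligand-receptor binding).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from bowtienet.datagen import LabeledDataset, VALIDATION
from bowtienet.nnet import NetworkModel, _softmax, evaluate

__all__ = [
    "MaskingCurve", "PruningResult", "masked_accuracy", "masking_curve",
    "prune_nodes", "prune_connections", "pruning_equivalence",
]

LAYERS = ("input_layer", "intermediate_layer")


@dataclass
class MaskingCurve:
    """Mean accuracy per mask rate for one layer, over many stochastic passes."""

    layer: str
    mask_rates: list[float]
    mean_accuracy: list[float]
    baseline_accuracy: float
    n_predictions: int


@dataclass
class PruningResult:
    """Accuracy vs fraction of pooled hidden weights removed, one strategy."""

    strategy: str
    removed_fraction: list[float]
    accuracy: list[float]


def masked_accuracy(
    model: NetworkModel,
    ds: LabeledDataset,
    layer: str,
    p: float,
    n_predictions: int = 80_000,
    rng_seed: int = 0,
) -> float:
    """Fraction correct over ``n_predictions`` stochastic masked predictions.

    Prediction events cycle over the validation rows; each event draws an
    independent Bernoulli(p) mask over the chosen layer's post-activation
    nodes.  Surviving activations are NOT rescaled.  At p = 0 no node can be
    removed, so the plain validation accuracy is returned exactly.
    """
    if layer not in LAYERS:
        raise ValueError(f"layer must be one of {LAYERS}, got {layer!r}")
    if not 0 <= p <= 1:
        raise ValueError("mask rate p must lie in [0, 1]")
    if p == 0:
        return evaluate(model, ds, VALIDATION)

    Xv, yv = ds.partition(VALIDATION)
    n_val = Xv.shape[0]
    rng = np.random.default_rng(rng_seed)

    correct = 0
    done = 0
    chunk = 20_000                      # bound peak memory for large runs
    while done < n_predictions:
        k = min(chunk, n_predictions - done)
        idx = (np.arange(done, done + k)) % n_val
        X, y = Xv[idx], yv[idx]
        h1 = np.maximum(X @ model.weights[0] + model.biases[0], 0.0)
        if layer == "input_layer":
            h1 = h1 * (rng.random(h1.shape) >= p)
        h2 = np.maximum(h1 @ model.weights[1] + model.biases[1], 0.0)
        if layer == "intermediate_layer":
            h2 = h2 * (rng.random(h2.shape) >= p)
        probs = _softmax(h2 @ model.weights[2] + model.biases[2])
        correct += int((probs.argmax(axis=1) == y).sum())
        done += k
    return correct / n_predictions


def masking_curve(
    model: NetworkModel,
    ds: LabeledDataset,
    layer: str,
    mask_rates: list[float] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
    n_predictions: int = 80_000,
    rng_seed: int = 0,
) -> MaskingCurve:
    """Masked accuracy across a grid of rates, sharing one baseline."""
    baseline = evaluate(model, ds, VALIDATION)
    accs = [
        masked_accuracy(model, ds, layer, float(p), n_predictions,
                        rng_seed=rng_seed + i)
        for i, p in enumerate(mask_rates)
    ]
    return MaskingCurve(layer=layer, mask_rates=[float(p) for p in mask_rates],
                        mean_accuracy=accs, baseline_accuracy=baseline,
                        n_predictions=n_predictions)


def _node_scores(model: NetworkModel) -> np.ndarray:
    """Importance of each intermediate node: L1 norm of its outgoing weights."""
    return np.abs(model.weights[2]).sum(axis=1)


def prune_nodes(model: NetworkModel, keep_k: int) -> NetworkModel:
    """Silence all but the ``keep_k`` highest-importance intermediate nodes.

    A removed node's incoming weights, bias and outgoing weights are zeroed
    (no retraining), which is equivalent to deleting the unit.  Ties are
    broken by node index, making the operation idempotent.
    """
    H = model.spec.intermediate_width
    if not 1 <= keep_k <= H:
        raise ValueError(f"keep_k must lie in [1, {H}], got {keep_k}")
    out = model.copy()
    if keep_k == H:
        return out
    scores = _node_scores(model)
    order = np.lexsort((np.arange(H), scores))     # ascending score, then index
    drop = order[: H - keep_k]
    out.weights[1][:, drop] = 0.0
    out.biases[1][drop] = 0.0
    out.weights[2][drop, :] = 0.0
    return out


def prune_connections(model: NetworkModel, fraction: float) -> NetworkModel:
    """Zero the smallest-magnitude ``fraction`` of pooled hidden weights.

    Magnitudes are pooled globally over the two hidden weight matrices
    (receptor-to-intermediate and intermediate-to-output); biases are left
    untouched and there is no retraining.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    out = model.copy()
    if fraction == 0:
        return out
    pooled = np.concatenate([out.weights[1].ravel(), out.weights[2].ravel()])
    n_zero = int(np.floor(fraction * pooled.size))
    if n_zero == 0:
        return out
    order = np.argsort(np.abs(pooled), kind="stable")
    pooled[order[:n_zero]] = 0.0
    n2 = out.weights[1].size
    out.weights[1] = pooled[:n2].reshape(out.weights[1].shape)
    out.weights[2] = pooled[n2:].reshape(out.weights[2].shape)
    return out


def pruning_equivalence(
    model: NetworkModel,
    ds: LabeledDataset,
    node_grid: list[int] | None = None,
    connection_grid: list[float] | None = None,
) -> tuple[PruningResult, PruningResult]:
    """Accuracy curves for both strategies, indexed by the fraction of pooled
    hidden weights removed, so the two analogies are directly comparable.

    Removing one intermediate node removes its column of the
    receptor-to-intermediate matrix and its row of the intermediate-to-output
    matrix, i.e. a fraction 1/H of the pooled weights.  Both curves always
    include the unpruned point (fraction 0).
    """
    H = model.spec.intermediate_width
    if node_grid is None:
        node_grid = sorted({max(1, H - int(round(f * H)))
                            for f in (0.0, 0.25, 0.5, 0.75)}, reverse=True)
    if connection_grid is None:
        connection_grid = [0.0, 0.25, 0.5, 0.75]

    keep_ks = sorted({int(k) for k in node_grid} | {H}, reverse=True)
    node_fracs, node_accs = [], []
    for k in keep_ks:
        node_fracs.append((H - k) / H)
        node_accs.append(evaluate(prune_nodes(model, k), ds, VALIDATION))

    fracs = sorted({float(f) for f in connection_grid} | {0.0})
    conn_accs = [evaluate(prune_connections(model, f), ds, VALIDATION)
                 for f in fracs]

    return (
        PruningResult("node_centric", node_fracs, node_accs),
        PruningResult("connection_centric", fracs, conn_accs),
    )
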