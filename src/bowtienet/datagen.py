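"""Synthetic multi-class Gaussian data emulating cytokine-stimulation profiles.

Each response class is a binary prototype vector in D dimensions whose
elements are one of two levels (default 0.3 = signal absent, 0.7 = signal
present).  Samples are the prototype plus isotropic Gaussian noise with
covariance I/S, so the scalar ``S`` acts as a separability knob: larger S
means tighter, easier classes.  A nearest-prototype Bayes oracle gives the
information-theoretic accuracy ceiling for any classifier trained on the
same generative process.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PrototypeSet", "NoiseModel", "LabeledDataset",
    "make_prototypes", "sample_dataset", "apply_input_zeroing",
    "bayes_oracle_accuracy", "write_dataset", "read_dataset",
]

TRAIN = "train"
VALIDATION = "validation"

DEFAULT_LO = 0.3
DEFAULT_HI = 0.7


@dataclass(frozen=True)
class PrototypeSet:
    """C class-mean vectors in D dimensions, every element lo_value or hi_value."""

    prototypes: np.ndarray
    lo_value: float = DEFAULT_LO
    hi_value: float = DEFAULT_HI
    seed: int | None = None

    def __post_init__(self) -> None:
        protos = np.asarray(self.prototypes, dtype=float)
        object.__setattr__(self, "prototypes", protos)
        if protos.ndim != 2:
            raise ValueError("prototypes must be a C x D matrix")
        if self.n_classes < 2 or self.n_dims < 1:
            raise ValueError("need at least 2 classes and 1 dimension")
        if not self.lo_value < self.hi_value:
            raise ValueError("lo_value must be strictly below hi_value")
        levels = np.isclose(protos, self.lo_value) | np.isclose(protos, self.hi_value)
        if not levels.all():
            raise ValueError("every prototype element must equal lo_value or hi_value")

    @property
    def n_classes(self) -> int:
        return self.prototypes.shape[0]

    @property
    def n_dims(self) -> int:
        return self.prototypes.shape[1]


@dataclass(frozen=True)
class NoiseModel:
    """Isotropic Gaussian noise with covariance I/S (per-element sd 1/sqrt(S))."""

    S: float
    covariance_convention: str = "identity_over_S"

    def __post_init__(self) -> None:
        if self.S <= 0:
            raise ValueError(f"noise divisor S must be positive, got {self.S}")
        if self.covariance_convention not in ("identity_over_S", "scale_over_S"):
            raise ValueError(
                f"unknown covariance convention {self.covariance_convention!r}"
            )

    @property
    def sd(self) -> float:
        """Per-element standard deviation of the noise."""
        if self.covariance_convention == "identity_over_S":
            return 1.0 / np.sqrt(self.S)
        return 1.0 / self.S


@dataclass
class LabeledDataset:
    """Sample matrix with integer labels, a stratified train/validation split,
    and an optional record of zeroed ("not yet evolved") input columns."""

    X: np.ndarray
    y: np.ndarray
    split: np.ndarray
    n_per_class: int
    validation_fraction: float
    input_mask: tuple[int, ...] | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_dims(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.y.max()) + 1

    def rows(self, which: str) -> np.ndarray:
        if which not in (TRAIN, VALIDATION):
            raise ValueError(f"unknown partition {which!r}")
        return np.flatnonzero(self.split == which)

    def partition(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        idx = self.rows(which)
        return self.X[idx], self.y[idx]


def make_prototypes(
    n_classes: int,
    n_dims: int,
    rng_seed: int,
    lo_value: float = DEFAULT_LO,
    hi_value: float = DEFAULT_HI,
) -> PrototypeSet:
    """Draw C pairwise-distinct binary prototypes, each element lo/hi with p=1/2.

    Colliding rows are redrawn; with fewer than ``2**n_dims`` classes this
    terminates, otherwise an error is raised because distinct prototypes are
    impossible.
    """
    if n_classes < 2 or n_dims < 1:
        raise ValueError("need n_classes >= 2 and n_dims >= 1")
    if n_dims < 64 and n_classes > 2 ** n_dims:
        raise ValueError(
            f"cannot draw {n_classes} distinct prototypes in {n_dims} binary dimensions"
        )
    rng = np.random.default_rng(rng_seed)
    rows: list[tuple] = []
    seen: set[tuple] = set()
    while len(rows) < n_classes:
        candidate = tuple(rng.integers(0, 2, size=n_dims))
        if candidate not in seen:
            seen.add(candidate)
            rows.append(candidate)
    bits = np.array(rows, dtype=float)
    protos = np.where(bits == 1, hi_value, lo_value)
    return PrototypeSet(protos, lo_value=lo_value, hi_value=hi_value, seed=rng_seed)


def sample_dataset(
    protos: PrototypeSet,
    noise: NoiseModel,
    n_per_class: int = 1000,
    validation_fraction: float = 1.0 / 3.0,
    rng_seed: int = 0,
) -> LabeledDataset:
    """Sample ``n_per_class`` noisy points around each prototype and split.

    Row i with label c is ``prototype_c + eps`` with
    ``eps ~ N(0, I/S)``.  The train/validation split is stratified per class
    so balance is preserved within one row.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if not 0 < validation_fraction < 1:
        raise ValueError("validation_fraction must lie strictly in (0, 1)")
    rng = np.random.default_rng(rng_seed)
    C, D = protos.n_classes, protos.n_dims
    N = C * n_per_class
    X = np.repeat(protos.prototypes, n_per_class, axis=0)
    X = X + rng.normal(0.0, noise.sd, size=(N, D))
    y = np.repeat(np.arange(C), n_per_class)

    n_val = int(round(validation_fraction * n_per_class))
    split = np.full(N, TRAIN, dtype="<U10")
    for c in range(C):
        block = np.arange(c * n_per_class, (c + 1) * n_per_class)
        val_rows = rng.choice(block, size=n_val, replace=False)
        split[val_rows] = VALIDATION

    meta = {"S": noise.S, "C": C, "D": D, "n_per_class": n_per_class,
            "seed": rng_seed, "prototype_seed": protos.seed,
            "validation_fraction": validation_fraction}
    return LabeledDataset(X=X, y=y, split=split, n_per_class=n_per_class,
                          validation_fraction=validation_fraction, meta=meta)


def apply_input_zeroing(ds: LabeledDataset, masked_fraction: float) -> LabeledDataset:
    """Zero the trailing ``floor(masked_fraction * D)`` input columns.

    Models the "pre-evolved" state in which a fixed block of receptors has
    not yet evolved: those inputs carry no signal in either partition.  The
    original dataset is left untouched.
    """
    if not 0 <= masked_fraction <= 1:
        raise ValueError("masked_fraction must lie in [0, 1]")
    D = ds.n_dims
    n_masked = int(np.floor(masked_fraction * D))
    cols = tuple(range(D - n_masked, D))
    X = ds.X.copy()
    if cols:
        X[:, list(cols)] = 0.0
    return LabeledDataset(X=X, y=ds.y.copy(), split=ds.split.copy(),
                          n_per_class=ds.n_per_class,
                          validation_fraction=ds.validation_fraction,
                          input_mask=cols, meta=dict(ds.meta))


def bayes_oracle_accuracy(
    protos: PrototypeSet,
    noise: NoiseModel,
    n_mc: int = 100_000,
    rng_seed: int = 0,
) -> float:
    """Monte-Carlo accuracy of the minimum-distance-to-prototype classifier.

    With equal spherical class covariances and equal priors the Bayes rule is
    nearest-prototype, so this estimate upper-bounds (to sampling error) the
    validation accuracy of any classifier trained on the same process.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    rng = np.random.default_rng(rng_seed)
    C, D = protos.n_classes, protos.n_dims
    labels = np.arange(n_mc) % C
    X = protos.prototypes[labels] + rng.normal(0.0, noise.sd, size=(n_mc, D))
    # squared distances to every prototype, argmin ties to lowest class index
    d2 = ((X[:, None, :] - protos.prototypes[None, :, :]) ** 2).sum(axis=2)
    pred = d2.argmin(axis=1)
    return float((pred == labels).mean())


def write_dataset(ds: LabeledDataset, path: str | Path) -> Path:
    """Write the dataset as CSV ``class,x0..x{D-1},split`` plus a JSON sidecar."""
    path = Path(path)
    D = ds.n_dims
    frame = pd.DataFrame(ds.X, columns=[f"x{j}" for j in range(D)])
    frame.insert(0, "class", ds.y)
    frame["split"] = ds.split
    frame.to_csv(path, index=False, float_format="%.17g")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = dict(ds.meta)
    meta.update({
        "n_per_class": ds.n_per_class,
        "validation_fraction": ds.validation_fraction,
        "input_mask": list(ds.input_mask) if ds.input_mask is not None else None,
    })
    sidecar.write_text(json.dumps(meta, indent=2))
    return path


def read_dataset(path: str | Path) -> LabeledDataset:
    """Read a dataset written by :func:`write_dataset`."""
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    xcols = [c for c in frame.columns if c.startswith("x")]
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    mask = meta.pop("input_mask", None)
    return LabeledDataset(
        X=frame[xcols].to_numpy(dtype=float),
        y=frame["class"].to_numpy(dtype=int),
        split=frame["split"].to_numpy(dtype="<U10"),
        n_per_class=int(meta.pop("n_per_class", 0) or
                        np.bincount(frame["class"]).max()),
        validation_fraction=float(meta.pop("validation_fraction", 1.0 / 3.0)),
        input_mask=tuple(mask) if mask is not None else None,
        meta=meta,
    )
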