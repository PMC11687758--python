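"""Kernel-shape CNN window classifiers with speaker-disjoint cross-validation.

The classifier decides whether one 250 ms dual-channel MFCC stack is nasal
or oral.  Its two convolution blocks share a configurable kernel shape
``i x j`` drawn from the grid ``1 <= i, j <= 8`` excluding ``1 x 1``: a
kernel extending only along the coefficient axis (``j = 1``) is *spectral*,
only along the time axis (``i = 1``) *temporal*, and otherwise
*spectral-temporal*.  Each shape is tried both with the same kernel in both
layers and with a pointwise ``1 x 1`` first layer that mixes the nose and
mouth channels per cell, giving 126 configurations in total.

The architecture per block is convolution (16 filters, stride 1, same
padding, linear activation), batch normalization, leaky ReLU and 2x2
stride-1 same-padded max pooling; the head is a 128-unit linear dense layer
and a 2-way softmax.  Training uses Adam with Glorot-uniform
initialization; evaluation uses speaker-disjoint k-fold splits so that no
speaker contributes windows to both sides of a split.

Two surfaces are provided: the functional one (:func:`enumerate_kernel_grid`,
:func:`build_cnn`, :func:`crossvalidate`) and a model/results pair
(:class:`WindowClassifier` / :class:`WindowClassifierResults`) for
interactive use.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FeatureWindow
from . import nn

__all__ = [
    "KernelConfig",
    "TrainConfig",
    "TrainedModel",
    "enumerate_kernel_grid",
    "plan_grid_runs",
    "classify_kernel",
    "build_cnn",
    "train_model",
    "assign_folds",
    "crossvalidate",
    "windows_to_arrays",
    "WindowClassifier",
    "WindowClassifierResults",
]

LABEL_TO_INT = {"oral": 0, "nasal": 1}
INPUT_SHAPE = (2, 39, 26)


def classify_kernel(shape: tuple[int, int]) -> str:
    """Class of a kernel shape: spectral (j=1), temporal (i=1), or both axes."""
    i, j = shape
    if not (1 <= i <= 8 and 1 <= j <= 8):
        raise ValueError(f"kernel extent out of range: {shape}")
    if (i, j) == (1, 1):
        raise ValueError("1 x 1 is the pointwise first-layer option, not a shape class")
    if j == 1:
        return "spectral"
    if i == 1:
        return "temporal"
    return "spectral_temporal"


@dataclass(frozen=True)
class KernelConfig:
    """One point of the kernel grid.

    ``second_shape`` is the kernel of the second convolution block and, when
    ``pointwise_first`` is false, of the first block too; with
    ``pointwise_first`` the first block uses a 1 x 1 kernel.
    """

    pointwise_first: bool
    second_shape: tuple[int, int]

    def __post_init__(self) -> None:
        classify_kernel(self.second_shape)  # validates range and excludes 1x1

    @property
    def shape_class(self) -> str:
        return classify_kernel(self.second_shape)

    @property
    def first_shape(self) -> tuple[int, int]:
        return (1, 1) if self.pointwise_first else self.second_shape

    @property
    def config_id(self) -> str:
        i, j = self.second_shape
        return f"{'pw' if self.pointwise_first else 'same'}-{i}x{j}"


def enumerate_kernel_grid() -> list[KernelConfig]:
    """All 126 kernel configurations in deterministic order.

    63 same-kernel setups (every ``i x j`` with ``1 <= i, j <= 8`` except
    ``1 x 1``) followed by the same 63 shapes with a pointwise first layer;
    within each half ordered by ``i`` then ``j``.
    """
    grid = []
    for pointwise in (False, True):
        for i in range(1, 9):
            for j in range(1, 9):
                if (i, j) == (1, 1):
                    continue
                grid.append(KernelConfig(pointwise_first=pointwise, second_shape=(i, j)))
    return grid


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    The defaults are the full-scale settings (100 epochs, Adam at 1e-5);
    :meth:`reduced` gives the desk-scale variant used for tests and small
    synthetic cohorts.
    """

    n_filters: int = 16
    batch_size: int = 64
    epochs: int = 100
    learning_rate: float = 1e-5
    leaky_slope: float = 0.01
    dense_units: int = 128
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_filters, self.batch_size, self.epochs,
               self.dense_units, self.n_folds) <= 0:
            raise ValueError("all counts must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    @classmethod
    def reduced(cls, seed: int = 0, epochs: int = 20,
                learning_rate: float = 1e-3, n_folds: int = 5) -> "TrainConfig":
        """Desk-scale configuration: fewer epochs, a faster Adam step."""
        return cls(epochs=epochs, learning_rate=learning_rate,
                   n_folds=n_folds, seed=seed)


def plan_grid_runs(
    grid: Sequence[KernelConfig] | None = None, tc: TrainConfig | None = None
) -> list[tuple[str, int]]:
    """Enumerate every (config, fold) training run of a grid campaign.

    The full 126-configuration grid under 5-fold cross-validation plans
    630 runs.  No training happens here; the planner only fixes the run
    manifest order (grid order, then fold index).
    """
    grid = list(grid) if grid is not None else enumerate_kernel_grid()
    tc = tc or TrainConfig()
    return [(kc.config_id, fold) for kc in grid for fold in range(tc.n_folds)]


def build_cnn(kc: KernelConfig, tc: TrainConfig,
              input_shape: tuple[int, int, int] = INPUT_SHAPE) -> nn.Sequential:
    """Assemble the untrained two-block CNN for one kernel configuration.

    Weights are Glorot-uniform from ``tc.seed``; building twice with the
    same seed yields bit-identical parameters.
    """
    c, h, w = input_shape
    for kh, kw in (kc.first_shape, kc.second_shape):
        if kh > h or kw > w:
            raise ValueError(f"kernel {kh}x{kw} exceeds input extent {h}x{w}")
    rng = np.random.default_rng(tc.seed)
    k1, k2 = kc.first_shape, kc.second_shape
    return nn.Sequential([
        nn.Conv2D(c, tc.n_filters, *k1, rng),
        nn.BatchNorm2D(tc.n_filters),
        nn.LeakyReLU(tc.leaky_slope),
        nn.MaxPool2D(),
        nn.Conv2D(tc.n_filters, tc.n_filters, *k2, rng),
        nn.BatchNorm2D(tc.n_filters),
        nn.LeakyReLU(tc.leaky_slope),
        nn.MaxPool2D(),
        nn.Flatten(),
        nn.Dense(tc.n_filters * h * w, tc.dense_units, rng),
        nn.Dense(tc.dense_units, 2, rng),
    ])


@dataclass
class TrainedModel:
    """A trained fold model with its provenance and validation metrics."""

    kernel_config: KernelConfig
    fold_index: int
    net: nn.Sequential
    metadata: dict = field(default_factory=dict)

    def predict_posterior(self, stacks: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Two-class posteriors, rows summing to 1, for (n, 2, 39, 26) stacks."""
        stacks = np.asarray(stacks, dtype=np.float32)
        if stacks.ndim == 3:
            stacks = stacks[None]
        out = [
            nn.softmax(self.net.forward(stacks[i : i + batch_size], train=False))
            for i in range(0, len(stacks), batch_size)
        ]
        return np.concatenate(out, axis=0)

    def nasal_posterior(self, stacks: np.ndarray) -> np.ndarray:
        return self.predict_posterior(stacks)[:, 1]


def windows_to_arrays(
    windows: Sequence[FeatureWindow],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack labeled feature windows into (X, y, speakers) training arrays."""
    X = np.stack([w.stack for w in windows]).astype(np.float32)
    y = np.array([LABEL_TO_INT.get(w.label, -1) for w in windows], dtype=np.int64)
    speakers = np.array([w.speaker_id for w in windows])
    return X, y, speakers


def _accuracy_and_loss(model: nn.Sequential, X: np.ndarray, y: np.ndarray,
                       batch_size: int = 256) -> tuple[float, float]:
    losses, correct = [], 0
    for i in range(0, len(X), batch_size):
        logits = model.forward(X[i : i + batch_size], train=False)
        loss, _ = nn.cross_entropy_with_softmax(logits, y[i : i + batch_size])
        losses.append(loss * len(logits))
        correct += int((logits.argmax(axis=1) == y[i : i + batch_size]).sum())
    return correct / len(X), float(np.sum(losses) / len(X))


def train_model(
    X: np.ndarray,
    y: np.ndarray,
    kc: KernelConfig,
    tc: TrainConfig,
    fold_index: int = 0,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> TrainedModel:
    """Train one CNN on labeled stacks; final-epoch weights are kept.

    There is no early stopping or best-epoch selection.  The shuffling and
    initialization stream is derived from ``tc.seed`` and ``fold_index``.
    """
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=np.int64)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be 0 (oral) or 1 (nasal)")
    net = build_cnn(kc, replace(tc, seed=tc.seed + 1000 * fold_index),
                    input_shape=X.shape[1:])
    rng = np.random.default_rng((tc.seed, fold_index, 0xF17))
    opt = nn.Adam(net.params, lr=tc.learning_rate)
    final_loss = float("nan")
    for _epoch in range(tc.epochs):
        order = rng.permutation(len(X))
        epoch_losses = []
        for i in range(0, len(X), tc.batch_size):
            idx = order[i : i + tc.batch_size]
            logits = net.forward(X[idx], train=True)
            loss, dlogits = nn.cross_entropy_with_softmax(logits, y[idx])
            net.backward(dlogits)
            opt.step(net.grads)
            epoch_losses.append(loss * len(idx))
        final_loss = float(np.sum(epoch_losses) / len(X))
    meta = {
        "seed": tc.seed,
        "epochs_run": tc.epochs,
        "final_train_loss": final_loss,
        "n_train": int(len(X)),
    }
    if X_val is not None and y_val is not None and len(X_val):
        acc, vloss = _accuracy_and_loss(net, np.asarray(X_val, np.float32),
                                        np.asarray(y_val, np.int64))
        meta.update(val_accuracy=acc, val_loss=vloss, n_val=int(len(X_val)))
    return TrainedModel(kernel_config=kc, fold_index=fold_index, net=net, metadata=meta)


def assign_folds(speakers: np.ndarray, n_folds: int, seed: int) -> list[np.ndarray]:
    """Partition unique speakers into ``n_folds`` disjoint validation folds."""
    unique = np.unique(speakers)
    if len(unique) < n_folds:
        raise ValueError(
            f"need at least {n_folds} speakers for {n_folds}-fold "
            f"cross-validation, got {len(unique)}"
        )
    rng = np.random.default_rng((seed, 0xF01D))
    order = rng.permutation(unique)
    return [np.sort(part) for part in np.array_split(order, n_folds)]


def crossvalidate(
    windows: Sequence[FeatureWindow],
    kc: KernelConfig,
    tc: TrainConfig,
) -> list[TrainedModel]:
    """Speaker-disjoint k-fold cross-validation of one kernel configuration.

    Speakers are partitioned into ``tc.n_folds`` disjoint folds; each model
    trains on the windows of the other folds and is validated on its own
    fold, so no speaker appears on both sides of any split.  Each returned
    model carries its validation accuracy/loss and fold manifest in
    ``metadata``.
    """
    X, y, speakers = windows_to_arrays(windows)
    if np.any(y < 0):
        raise ValueError("all windows must be labeled oral or nasal")
    folds = assign_folds(speakers, tc.n_folds, tc.seed)
    models = []
    for fold_index, val_speakers in enumerate(folds):
        val_mask = np.isin(speakers, val_speakers)
        y_train = y[~val_mask]
        if len(np.unique(y_train)) < 2:
            raise ValueError(
                f"fold {fold_index}: training split contains a single class"
            )
        model = train_model(
            X[~val_mask], y_train, kc, tc, fold_index=fold_index,
            X_val=X[val_mask], y_val=y[val_mask],
        )
        model.metadata["val_speakers"] = [str(s) for s in val_speakers]
        model.metadata["train_speakers"] = sorted(
            str(s) for s in np.unique(speakers[~val_mask])
        )
        models.append(model)
    return models


class WindowClassifier:
    """Nasal/oral window classifier bound to a labeled dataset.

    Parameters
    ----------
    windows : sequence of FeatureWindow
        Labeled feature stacks with speaker identities.
    kernel : KernelConfig
        Kernel-shape configuration of the two convolution blocks.
    train_config : TrainConfig, optional
        Hyperparameters; defaults to the full-scale settings.
    """

    def __init__(self, windows: Sequence[FeatureWindow], kernel: KernelConfig,
                 train_config: TrainConfig | None = None) -> None:
        self.windows = list(windows)
        self.kernel = kernel
        self.train_config = train_config or TrainConfig()

    @classmethod
    def from_arrays(cls, stacks: np.ndarray, labels: Sequence[str],
                    speakers: Sequence[str], kernel: KernelConfig,
                    train_config: TrainConfig | None = None) -> "WindowClassifier":
        windows = [
            FeatureWindow(stack=s, start_ms=0.0, speaker_id=str(sp), label=str(lb))
            for s, lb, sp in zip(stacks, labels, speakers)
        ]
        return cls(windows, kernel, train_config)

    def fit(self) -> "WindowClassifierResults":
        """Run speaker-disjoint cross-validation and collect the fold models."""
        models = crossvalidate(self.windows, self.kernel, self.train_config)
        return WindowClassifierResults(self, models)


class WindowClassifierResults:
    """Fold models and validation diagnostics of a fitted window classifier."""

    def __init__(self, model: WindowClassifier, fold_models: list[TrainedModel]) -> None:
        self.model = model
        self.fold_models = fold_models

    @property
    def fold_metrics(self) -> pd.DataFrame:
        rows = [
            {
                "fold": m.fold_index,
                "val_accuracy": m.metadata.get("val_accuracy", np.nan),
                "val_loss": m.metadata.get("val_loss", np.nan),
                "final_train_loss": m.metadata.get("final_train_loss", np.nan),
                "n_train": m.metadata.get("n_train"),
                "n_val": m.metadata.get("n_val"),
            }
            for m in self.fold_models
        ]
        return pd.DataFrame(rows).set_index("fold")

    @property
    def mean_val_accuracy(self) -> float:
        return float(self.fold_metrics["val_accuracy"].mean())

    def predict_posterior(self, stacks: np.ndarray) -> np.ndarray:
        """Fold-ensemble two-class posterior (mean over fold models)."""
        return np.mean([m.predict_posterior(stacks) for m in self.fold_models], axis=0)

    def nasal_posterior(self, stacks: np.ndarray) -> np.ndarray:
        return self.predict_posterior(stacks)[:, 1]

    def summary(self) -> str:
        kc = self.model.kernel
        tc = self.model.train_config
        lines = [
            "Window classifier: nasal vs oral 250 ms MFCC stacks",
            "=" * 55,
            f"kernel config     : {kc.config_id} ({kc.shape_class})",
            f"first/second shape: {kc.first_shape} / {kc.second_shape}",
            f"filters/dense     : {tc.n_filters} / {tc.dense_units}",
            f"epochs/batch/lr   : {tc.epochs} / {tc.batch_size} / {tc.learning_rate:g}",
            f"folds (speaker-disjoint): {tc.n_folds}, seed {tc.seed}",
            f"n windows         : {len(self.model.windows)}",
            "-" * 55,
            self.fold_metrics.to_string(float_format=lambda v: f"{v:.4f}"),
            "-" * 55,
            f"mean validation accuracy: {self.mean_val_accuracy:.4f}",
        ]
        return "\n".join(lines)
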