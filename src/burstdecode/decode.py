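"""Training and cross-validation of the burst-tensor CNN decoders.

Four decoding problems share one architecture and differ only in input kind,
epochs and batch size:

* ``cnn1``  - memory state: 3-s encoding trials vs. random 3-s recall
  segments (100 epochs, batch 128);
* ``cnn2a`` - subsequent memory from broadband encoding-epoch iEEG
  (150 epochs, batch 128);
* ``cnn2b`` - subsequent memory from convolved high-gamma/beta burst
  tensors (150 epochs, batch 128);
* ``cnn3``  - good vs. poor recall sessions from whole 30-s recall-epoch
  burst tensors (100 epochs, batch 32; two folds, sessions being few).

`BurstCNNClassifier` is a scikit-learn compatible estimator, so model
selection utilities compose with it; `crossvalidate` pools test-fold
probabilities into one ROC per experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from . import nn
from .tensorize import LabeledDataset, TensorKind

__all__ = [
    "CNNConfig",
    "MODEL_CONFIGS",
    "BurstCNNClassifier",
    "crossvalidate",
    "train_test_distinct",
    "ablate_beta",
]


@dataclass(frozen=True)
class CNNConfig:
    """Training hyperparameters of one decoding model."""

    conv_units: tuple[int, ...] = (64, 128, 64)
    kernel_size: int = 3
    epochs: int = 150
    batch_size: int = 128
    learning_rate: float = 1e-3
    bn_momentum: float = 0.9
    folds: int = 5

    def scaled(self, epochs: int | None = None) -> "CNNConfig":
        """A copy with a reduced epoch count for small demonstration runs."""
        return replace(self, epochs=epochs if epochs is not None else self.epochs)


MODEL_CONFIGS: dict[str, CNNConfig] = {
    "cnn1": CNNConfig(epochs=100, batch_size=128, folds=5),
    "cnn2a": CNNConfig(epochs=150, batch_size=128, folds=5),
    "cnn2b": CNNConfig(epochs=150, batch_size=128, folds=5),
    "cnn3": CNNConfig(epochs=100, batch_size=32, folds=2),
}


class BurstCNNClassifier(ClassifierMixin, BaseEstimator):
    """Binary 1-D CNN classifier over (n_trials, n_rows, n_samples) tensors.

    Parameters mirror :class:`CNNConfig`.  ``random_state`` seeds both the
    weight initialization and the epoch shuffling, making ``fit`` fully
    deterministic.
    """

    def __init__(self, conv_units=(64, 128, 64), kernel_size=3, epochs=150,
                 batch_size=128, learning_rate=1e-3, bn_momentum=0.9,
                 random_state=0):
        self.conv_units = conv_units
        self.kernel_size = kernel_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.bn_momentum = bn_momentum
        self.random_state = random_state

    @classmethod
    def from_config(cls, config: CNNConfig, random_state: int = 0):
        return cls(conv_units=config.conv_units, kernel_size=config.kernel_size,
                   epochs=config.epochs, batch_size=config.batch_size,
                   learning_rate=config.learning_rate,
                   bn_momentum=config.bn_momentum, random_state=random_state)

    def _validate(self, X):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3:
            raise ValueError("X must have shape (n_trials, n_rows, n_samples)")
        return X

    def fit(self, X, y):
        X = self._validate(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("both classes must be present for training")
        y01 = (y == self.classes_[1]).astype(np.float64)
        self.net_ = nn.ConvNet(n_rows=X.shape[1], conv_units=tuple(self.conv_units),
                               kernel_size=self.kernel_size,
                               bn_momentum=self.bn_momentum,
                               seed=self.random_state)
        self.history_ = nn.train(self.net_, X, y01, epochs=self.epochs,
                                 batch_size=self.batch_size,
                                 lr=self.learning_rate, seed=self.random_state)
        self.n_rows_ = X.shape[1]
        self.n_samples_ = X.shape[2]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "net_")
        X = self._validate(X)
        if X.shape[1] != self.n_rows_:
            raise ValueError(f"expected {self.n_rows_} rows, got {X.shape[1]}")
        p1 = self.net_.predict_proba(X)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]


def _as_predictions(trial_ids, folds, labels, probs) -> pd.DataFrame:
    return pd.DataFrame({
        "trial_id": [str(t) for t in trial_ids],
        "fold": folds,
        "label": np.asarray(labels, dtype=int),
        "probability": np.asarray(probs, dtype=float),
    })


def crossvalidate(dataset: LabeledDataset, config: CNNConfig,
                  k: int | None = None, seed: int = 0) -> pd.DataFrame:
    """Stratified k-fold cross-validation, model retrained from scratch per
    fold; returns pooled per-trial test probabilities (one row per trial).

    Memory-state datasets carry list-index groups (random recall segments
    from one list can share samples); for those, folds hold out whole lists
    so no test trial shares content with a training trial.
    """
    if not dataset.is_trainable:
        raise ValueError("dataset must contain both classes")
    k = k if k is not None else config.folds
    X, y = dataset.tensors, dataset.labels
    if dataset.kind == TensorKind.STATE_SEGMENT and dataset.groups is not None:
        from sklearn.model_selection import StratifiedGroupKFold

        skf = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = skf.split(X, y, groups=dataset.groups)
    else:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = skf.split(X, y)
    base = BurstCNNClassifier.from_config(config, random_state=seed)
    rows = []
    for fold, (tr, te) in enumerate(splits):
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"fold {fold} lost a class despite stratification")
        model = clone(base)
        model.set_params(random_state=seed + fold)
        model.fit(X[tr], y[tr])
        probs = model.predict_proba(X[te])[:, 1]
        rows.append(_as_predictions([dataset.trial_ids[i] for i in te],
                                    np.full(len(te), fold), y[te], probs))
    return pd.concat(rows, ignore_index=True)


def train_test_distinct(train: LabeledDataset, test: LabeledDataset,
                        config: CNNConfig, seed: int = 0) -> pd.DataFrame:
    """Train once on ``train``, score every trial of ``test`` (the
    distinct-experiment validation used to gauge cross-validation optimism)."""
    if train.shape != test.shape:
        raise ValueError(f"tensor shapes differ: {train.shape} vs {test.shape}")
    model = BurstCNNClassifier.from_config(config, random_state=seed)
    model.fit(train.tensors, train.labels)
    probs = model.predict_proba(test.tensors)[:, 1]
    return _as_predictions(test.trial_ids, np.zeros(len(test), dtype=int),
                           test.labels, probs)


def ablate_beta(dataset: LabeledDataset) -> LabeledDataset:
    """Drop the beta rows of a burst tensor dataset, keeping only the
    high-gamma row of each contact (rows are contact-major, HG then beta)."""
    if dataset.kind == TensorKind.ENC_BROADBAND:
        raise ValueError("broadband tensors have no beta rows to ablate")
    if dataset.shape[0] % 2:
        raise ValueError("burst tensors must have an even number of rows")
    hg_rows = np.arange(0, dataset.shape[0], 2)
    return LabeledDataset(dataset.tensors[:, hg_rows, :].copy(), dataset.labels,
                          trial_ids=list(dataset.trial_ids), kind=dataset.kind,
                          fs_hz=dataset.fs_hz,
                          row_names=[dataset.row_names[i] for i in hg_rows]
                          if dataset.row_names else [],
                          provenance=list(dataset.provenance))
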