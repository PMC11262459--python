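"""Scikit-learn-style estimators over the adapter transformer.

:class:`ThermalClassifier` and :class:`MeltingTempRegressor` wrap the
encoder + training loops behind the standard ``fit`` / ``predict`` /
``get_params`` surface so they compose with sklearn pipelines and model
selection.  ``X`` is a sequence of amino-acid strings; ``y`` is 0/1 thermal
class (1 = thermophilic) for the classifier and Tm in °C for the regressor.

Both default to the desk-scale tiny encoder (2 layers, 2 heads, width 16)
with reduction-factor-2 adapters; the full-size preset exists for parameter
accounting, not for fitting.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .encoder import (
    CLASSIFIER,
    REGRESSOR,
    AdapterConfig,
    EncoderConfig,
    EncoderModel,
    HeadConfig,
)
from .seqio import (
    NON_THERMOPHILIC,
    THERMOPHILIC,
    UNLABELED,
    SequenceRecord,
    tokenize,
)
from .training import TrainPlan, TransferInit, train_classifier, train_regressor


def _as_records(X: Sequence[str], y=None, task: str = CLASSIFIER) -> list[SequenceRecord]:
    records = []
    for i, seq in enumerate(X):
        kwargs: dict = {}
        if y is not None:
            if task == CLASSIFIER:
                kwargs["thermal_class"] = THERMOPHILIC if y[i] == 1 else NON_THERMOPHILIC
            else:
                kwargs["melting_temp"] = float(y[i])
                kwargs["thermal_class"] = UNLABELED
        records.append(SequenceRecord(id=f"s{i:06d}", sequence=str(seq), **kwargs))
    return records


def _holdout(n: int, fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_val = max(1, int(round(fraction * n)))
    return order[n_val:], order[:n_val]


class _AdapterEstimator(BaseEstimator):
    """Shared plumbing for the two task estimators."""

    _task: str = CLASSIFIER

    def __init__(
        self,
        n_layers: int = 2,
        n_heads: int = 2,
        d_model: int = 16,
        d_ff: int = 32,
        reduction_factor: int = 2,
        max_epochs: int = 20,
        batch_size: int = 16,
        learning_rate: float = 5e-3,
        validation_fraction: float = 0.1,
        random_state: int = 0,
    ):
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.d_model = d_model
        self.d_ff = d_ff
        self.reduction_factor = reduction_factor
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def _build_model(self) -> EncoderModel:
        cfg = EncoderConfig(
            n_layers=self.n_layers, n_heads=self.n_heads,
            d_model=self.d_model, d_ff=self.d_ff,
        )
        return EncoderModel(
            cfg,
            adapters=AdapterConfig(reduction_factor=self.reduction_factor),
            head=HeadConfig(kind=self._task),
            seed=self.random_state,
        )

    def _plan(self) -> TrainPlan:
        return TrainPlan(
            max_epochs=self.max_epochs, batch_size=self.batch_size,
            lr=self.learning_rate, seeds=(self.random_state,),
        )

    def _split(self, records):
        tr_idx, val_idx = _holdout(
            len(records), self.validation_fraction, self.random_state
        )
        return [records[i] for i in tr_idx], [records[i] for i in val_idx]


class ThermalClassifier(_AdapterEstimator, ClassifierMixin):
    """Binary thermophilic / non-thermophilic sequence classifier.

    Fits adapter + head parameters of a frozen tiny transformer with
    cross-entropy, keeping the lowest-validation-loss epoch.  Mid-first-epoch
    adapter snapshots (25/50/75/100% of the epoch's steps, plus the fully
    trained adapters) are kept on ``snapshots_`` for transfer initialization
    of a :class:`MeltingTempRegressor`.
    """

    _task = CLASSIFIER

    def fit(self, X: Sequence[str], y: Sequence[int]) -> "ThermalClassifier":
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.classes_ = np.array([0, 1])
        records = _as_records(X, y, CLASSIFIER)
        train, val = self._split(records)
        self.model_ = self._build_model()
        result = train_classifier(
            train, val, self.model_, self._plan(), seed=self.random_state
        )
        self.history_ = result.history
        self.best_epoch_ = result.best_epoch
        self.snapshots_ = result.snapshots
        return self

    def predict_proba(self, X: Sequence[str]) -> np.ndarray:
        check_is_fitted(self, "model_")
        tokens = [tokenize(str(s)) for s in X]
        p1 = np.atleast_1d(self.model_.forward_classify(tokens))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X: Sequence[str]) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def gate(self):
        """A sequence → thermal-class callable for class-gated ensembles."""
        check_is_fitted(self, "model_")
        from .ensemble import classifier_gate

        return classifier_gate(self.model_)


class MeltingTempRegressor(_AdapterEstimator, RegressorMixin):
    """Melting-temperature (°C) regressor over the adapter transformer.

    MSE on z-normalized targets; predictions de-normalize with the stored
    training statistics.  ``transfer`` optionally initializes the adapters
    from a fitted :class:`ThermalClassifier`: a (classifier, fraction) pair
    where fraction is 0.25 / 0.5 / 0.75 / 1.0 (mid-first-epoch snapshot)
    or "full" (fully trained adapters).
    """

    _task = REGRESSOR

    def __init__(
        self,
        n_layers: int = 2,
        n_heads: int = 2,
        d_model: int = 16,
        d_ff: int = 32,
        reduction_factor: int = 2,
        max_epochs: int = 200,
        batch_size: int = 16,
        learning_rate: float = 5e-3,
        validation_fraction: float = 0.1,
        random_state: int = 0,
        transfer=None,
    ):
        super().__init__(
            n_layers=n_layers, n_heads=n_heads, d_model=d_model, d_ff=d_ff,
            reduction_factor=reduction_factor, max_epochs=max_epochs,
            batch_size=batch_size, learning_rate=learning_rate,
            validation_fraction=validation_fraction, random_state=random_state,
        )
        self.transfer = transfer

    def fit(self, X: Sequence[str], y: Sequence[float]) -> "MeltingTempRegressor":
        y = np.asarray(y, dtype=float)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        records = _as_records(X, y, REGRESSOR)
        train, val = self._split(records)
        self.model_ = self._build_model()
        init = None
        if self.transfer is not None:
            source, fraction = self.transfer
            snapshots = source.snapshots_ if hasattr(source, "snapshots_") else source
            init = TransferInit(snapshots=snapshots, fraction=fraction)
        result = train_regressor(
            train, val, self.model_, self._plan(), init=init, seed=self.random_state
        )
        self.history_ = result.history
        self.best_epoch_ = result.best_epoch
        return self

    def predict(self, X: Sequence[str]) -> np.ndarray:
        check_is_fitted(self, "model_")
        tokens = [tokenize(str(s)) for s in X]
        return np.atleast_1d(self.model_.forward_regress(tokens))
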