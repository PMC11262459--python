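"""Combining multiple melting-temperature regressors: oracle bound, greedy
subset selection, inverse-error weighting, robust (IQR / std) trimmed
averaging, and classifier-gated per-class sub-ensembles.

The class-gated strategy mirrors the published configuration: a thermal
classifier picks the class, and a per-class subset of regressors (five for
non-thermophilic, two for thermophilic in the original) produces the
combined prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import NON_THERMOPHILIC, THERMOPHILIC

MEAN = "mean"
IQR_TRIMMED_MEAN = "iqr_trimmed_mean"
STD_TRIMMED_MEAN = "std_trimmed_mean"
COMBINERS = (MEAN, IQR_TRIMMED_MEAN, STD_TRIMMED_MEAN)


@dataclass
class PredictionMatrix:
    """Per-model per-sample Tm predictions (°C), with optional truth."""

    predictions: np.ndarray          # (n_models, n_samples)
    model_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    truth: np.ndarray | None = None  # (n_samples,)

    def __post_init__(self) -> None:
        self.predictions = np.asarray(self.predictions, dtype=float)
        if self.predictions.ndim != 2:
            raise ValueError("predictions must be (models, samples)")
        M, N = self.predictions.shape
        if len(self.model_ids) != M or len(self.sample_ids) != N:
            raise ValueError("id lists must match the matrix shape")
        if len(set(self.model_ids)) != M or len(set(self.sample_ids)) != N:
            raise ValueError("ids must be unique")
        if not np.all(np.isfinite(self.predictions)):
            raise ValueError("predictions must be finite (no missing cells)")
        if self.truth is not None:
            self.truth = np.asarray(self.truth, dtype=float)
            if self.truth.shape != (N,):
                raise ValueError("truth must be one value per sample")

    def subset(self, member_ids: Sequence[str]) -> "PredictionMatrix":
        idx = [self.model_ids.index(m) for m in member_ids]
        return PredictionMatrix(
            self.predictions[idx], tuple(member_ids), self.sample_ids, self.truth
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.predictions, index=list(self.model_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, truth: Sequence[float] | None = None
    ) -> "PredictionMatrix":
        return cls(
            frame.to_numpy(dtype=float),
            tuple(map(str, frame.index)),
            tuple(map(str, frame.columns)),
            None if truth is None else np.asarray(truth, dtype=float),
        )


@dataclass(frozen=True)
class EnsembleSpec:
    """A fitted ensemble rule.

    ``strategy`` is one of oracle / greedy / weighted / class_gated.  For
    ``class_gated``, ``class_members`` maps each thermal class to its member
    subset.  ``combiner`` collapses member predictions per sample.
    """

    strategy: str
    member_ids: tuple[str, ...] = ()
    class_members: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    combiner: str = MEAN
    weights: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.combiner not in COMBINERS:
            raise ValueError(f"unknown combiner {self.combiner!r}")
        if self.strategy == "class_gated":
            missing = {THERMOPHILIC, NON_THERMOPHILIC} - set(self.class_members)
            if missing:
                raise ValueError(f"class_gated spec missing subsets for {missing}")
            if any(len(v) == 0 for v in self.class_members.values()):
                raise ValueError("class subsets must be non-empty")
        elif len(self.member_ids) == 0:
            raise ValueError("members must be non-empty")


def _mae(pred: np.ndarray, truth: np.ndarray) -> float:
    return float(np.abs(pred - truth).mean())


def oracle_bound(P: PredictionMatrix) -> tuple[np.ndarray, float, float]:
    """Per-sample best-member selection given the truth.

    Returns the per-sample oracle predictions, their MAE and R².  This is a
    lower bound on the error any member-selection ensemble can reach.
    """
    if P.truth is None:
        raise ValueError("oracle requires ground truth")
    err = np.abs(P.predictions - P.truth[None, :])
    best = err.argmin(axis=0)
    picked = P.predictions[best, np.arange(P.predictions.shape[1])]
    ss_res = float(((picked - P.truth) ** 2).sum())
    ss_tot = float(((P.truth - P.truth.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return picked, _mae(picked, P.truth), r2


def robust_combine(values: Sequence[float], combiner: str = MEAN) -> float:
    """Collapse one sample's member predictions into a single value.

    ``iqr_trimmed_mean`` drops values outside ``[Q1 - 1.5 IQR, Q3 + 1.5 IQR]``
    (quartiles by linear interpolation) before averaging;
    ``std_trimmed_mean`` drops values beyond mean ± 2 sd; ``mean`` is plain.
    If trimming removes everything, the plain mean is returned.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one value")
    if combiner == MEAN:
        return float(arr.mean())
    if combiner == IQR_TRIMMED_MEAN:
        q1, q3 = np.quantile(arr, [0.25, 0.75])
        iqr = q3 - q1
        keep = arr[(arr >= q1 - 1.5 * iqr) & (arr <= q3 + 1.5 * iqr)]
    elif combiner == STD_TRIMMED_MEAN:
        mu, sd = arr.mean(), arr.std()
        keep = arr[np.abs(arr - mu) <= 2.0 * sd]
    else:
        raise ValueError(f"unknown combiner {combiner!r}")
    return float(keep.mean()) if keep.size else float(arr.mean())


def combine_matrix(P: PredictionMatrix, combiner: str = MEAN) -> np.ndarray:
    """Apply the combiner column-wise over the member axis."""
    return np.array(
        [robust_combine(P.predictions[:, j], combiner) for j in range(P.predictions.shape[1])]
    )


def greedy_select(
    P_val: PredictionMatrix, combiner: str = MEAN
) -> tuple[str, ...]:
    """Greedy forward subset selection on the validation matrix.

    Starts empty and repeatedly adds the member whose inclusion minimizes
    the combined-prediction MAE, stopping when no addition improves it
    strictly; ties break by member id order.
    """
    if P_val.truth is None:
        raise ValueError("greedy selection requires ground truth")
    remaining = sorted(P_val.model_ids)
    chosen: list[str] = []
    best_mae = np.inf
    while remaining:
        candidates = []
        for m in remaining:
            trial = chosen + [m]
            mae = _mae(combine_matrix(P_val.subset(trial), combiner), P_val.truth)
            candidates.append((mae, m))
        mae, m = min(candidates)  # ties -> lexicographically first id
        if mae < best_mae:
            best_mae = mae
            chosen.append(m)
            remaining.remove(m)
        else:
            break
    return tuple(chosen)


def weighted_ensemble(P_val: PredictionMatrix) -> dict[str, float]:
    """Inverse-validation-MAE member weights, normalized to sum 1.

    A member with zero MAE takes all the weight (split if several are
    perfect).
    """
    if P_val.truth is None:
        raise ValueError("weighted ensemble requires ground truth")
    maes = np.abs(P_val.predictions - P_val.truth[None, :]).mean(axis=1)
    if np.any(maes == 0.0):
        perfect = maes == 0.0
        w = perfect / perfect.sum()
    else:
        inv = 1.0 / maes
        w = inv / inv.sum()
    return {m: float(wi) for m, wi in zip(P_val.model_ids, w)}


def weighted_predict(P: PredictionMatrix, weights: Mapping[str, float]) -> np.ndarray:
    w = np.array([weights[m] for m in P.model_ids])
    return (w[:, None] * P.predictions).sum(axis=0)


Predictor = Callable[[str], float]


def class_gated_predict(
    sequence: str,
    gate: Callable[[str], str],
    spec: EnsembleSpec,
    members: Mapping[str, Predictor],
) -> float:
    """Predict Tm for one sequence through the class gate.

    ``gate`` maps a sequence to a thermal class; the corresponding member
    subset's predictions are combined with ``spec.combiner``.
    """
    if spec.strategy != "class_gated":
        raise ValueError("spec is not class_gated")
    cls = gate(sequence)
    subset = spec.class_members.get(cls)
    if not subset:
        raise ValueError(f"no member subset for gated class {cls!r}")
    values = [members[m](sequence) for m in subset]
    return robust_combine(values, spec.combiner)


def classifier_gate(model) -> Callable[[str], str]:
    """Wrap a classifier model (probability of thermophilic) as a gate."""
    from .seqio import tokenize

    def gate(sequence: str) -> str:
        p = float(model.forward_classify(tokenize(sequence)))
        return THERMOPHILIC if p >= 0.5 else NON_THERMOPHILIC

    return gate
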