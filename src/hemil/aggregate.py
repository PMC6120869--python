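"""Bag-level aggregation and classification.

The multiset of calibrated region probabilities for a patient (pooled
over all of their cores) is summarized by its empirical quantile
function sampled at 16 equally spaced levels — a fixed-length, ordered,
permutation-invariant bag descriptor.  A second linear SVM with sigmoid
(Platt) calibration maps the 16-value signature to a patient-level
probability, and a task-specific cut point turns the probability into a
binary call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

from .instance_model import InstanceEnsemble, predict_instance_prob
from .synthetic_cohort import FeatureBag

N_QUANTILES = 16


class UnscorablePatientError(ValueError):
    """No regions survived tissue filtering; the patient cannot be scored."""


@dataclass(frozen=True)
class QuantileSignature:
    values: np.ndarray  # (16,) non-decreasing, in [0, 1]
    levels: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 1.0, N_QUANTILES)
    )

    def __post_init__(self) -> None:
        if self.values.shape != (N_QUANTILES,):
            raise ValueError(f"signature must have {N_QUANTILES} values")
        if np.any(np.diff(self.values) < -1e-12):
            raise ValueError("signature values must be non-decreasing")


def quantile_signature(
    probs: Sequence[float], midpoint_levels: bool = False
) -> QuantileSignature:
    """16-point sampling of the empirical inverse CDF of region probabilities.

    Levels are i/15 for i = 0..15 (both extremes included) with linear
    interpolation between order statistics, so the first value is the
    minimum and the last the maximum.  ``midpoint_levels`` switches to the
    (i + 0.5)/16 convention.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.size == 0:
        raise ValueError("cannot form a quantile signature from zero probabilities")
    if midpoint_levels:
        levels = (np.arange(N_QUANTILES) + 0.5) / N_QUANTILES
    else:
        levels = np.linspace(0.0, 1.0, N_QUANTILES)
    values = np.quantile(probs, levels, method="linear")
    return QuantileSignature(values=values, levels=levels)


# Task-specific probability cut points; a call is positive iff the
# probability STRICTLY exceeds the cut.
@dataclass(frozen=True)
class CutPoints:
    grade_high: float = 0.80
    er_positive: float = 0.50
    basal: float = 0.60
    ror_high: float = 0.20
    lobular: float = 0.10

    _BY_TASK = {
        "grade": "grade_high",
        "er": "er_positive",
        "basal": "basal",
        "ror": "ror_high",
        "histology": "lobular",
    }

    def for_task(self, task: str) -> float:
        try:
            return getattr(self, self._BY_TASK[task])
        except KeyError:
            raise ValueError(f"unknown task {task!r}") from None


def classify(prob: float, task: str, cuts: CutPoints | None = None) -> int:
    """1 (positive class of the task) iff prob > the task's cut point."""
    cuts = cuts or CutPoints()
    if not 0.0 <= prob <= 1.0:
        raise ValueError(f"probability outside [0, 1]: {prob}")
    return int(prob > cuts.for_task(task))


@dataclass
class PatientModel:
    coef: np.ndarray  # (16,)
    intercept: float
    sigmoid_a: float  # P(y=1|s) = 1 / (1 + exp(-(a s + b)))
    sigmoid_b: float

    def decision(self, signatures: np.ndarray) -> np.ndarray:
        return signatures @ self.coef + self.intercept

    def predict_proba(self, signatures: np.ndarray) -> np.ndarray:
        s = self.decision(np.atleast_2d(signatures))
        return 1.0 / (1.0 + np.exp(-(self.sigmoid_a * s + self.sigmoid_b)))


@dataclass
class TrainedPipeline:
    task: str
    ensemble: InstanceEnsemble
    patient_model: PatientModel
    cuts: CutPoints = field(default_factory=CutPoints)

    @property
    def cut_point(self) -> float:
        return self.cuts.for_task(self.task)


def fit_patient_model(
    signatures: Sequence[QuantileSignature],
    labels: Sequence[int],
    seed: int = 0,
    c: float = 1.0,
    n_folds: int = 5,
) -> PatientModel:
    """Linear SVM on 16-dim signatures with Platt calibration.

    The sigmoid is fit by logistic regression on decision values gathered
    from ``n_folds`` held-out folds of the training patients, then the
    final SVM is refit on all patients.  Deterministic per seed.
    """
    x = np.stack([s.values for s in signatures])
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("patient labels contain a single class")

    def _weights(n: int) -> np.ndarray:
        # fixed total weight: the fit depends on the empirical signature
        # distribution, not the sample count (duplicating data is a no-op)
        return np.full(n, 100.0 / n)

    svm = LinearSVC(C=c, dual=False, random_state=0)
    if counts.min() >= n_folds:
        rng = np.random.default_rng(seed)
        fold = np.empty(len(y), dtype=int)
        for cls in classes:
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            fold[idx] = np.arange(idx.size) % n_folds
        held_scores = np.empty(len(y))
        for k in range(n_folds):
            svm_k = LinearSVC(C=c, dual=False, random_state=0)
            svm_k.fit(x[fold != k], y[fold != k], sample_weight=_weights(int((fold != k).sum())))
            held_scores[fold == k] = x[fold == k] @ svm_k.coef_[0] + svm_k.intercept_[0]
    else:
        # too few patients for held-out calibration: calibrate in-sample
        svm.fit(x, y, sample_weight=_weights(len(y)))
        held_scores = svm.decision_function(x)

    svm.fit(x, y, sample_weight=_weights(len(y)))
    lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=1000)
    lr.fit(held_scores.reshape(-1, 1), y)
    return PatientModel(
        coef=svm.coef_[0].copy(),
        intercept=float(svm.intercept_[0]),
        sigmoid_a=float(lr.coef_[0, 0]),
        sigmoid_b=float(lr.intercept_[0]),
    )


def _bag_probability(pipeline: TrainedPipeline, bag: FeatureBag) -> float:
    if len(bag) == 0:
        raise UnscorablePatientError(
            f"no regions survived filtering for {bag.patient_id!r}"
        )
    probs = predict_instance_prob(pipeline.ensemble, bag)
    sig = quantile_signature(probs)
    return float(pipeline.patient_model.predict_proba(sig.values)[0])


def predict_patient(pipeline: TrainedPipeline, bag: FeatureBag) -> float:
    """Patient probability from the pooled regions of all their cores."""
    return _bag_probability(pipeline, bag)


def predict_core(pipeline: TrainedPipeline, bag: FeatureBag, core_id: int) -> float:
    """Probability for one core, using the patient-trained model on that
    core's own signature."""
    keep = bag.core_ids == core_id
    if not np.any(keep):
        raise UnscorablePatientError(
            f"core {core_id} of {bag.patient_id!r} has no scored regions"
        )
    sub = FeatureBag(
        patient_id=bag.patient_id,
        core_ids=bag.core_ids[keep],
        offsets=bag.offsets[keep],
        vectors=bag.vectors[keep],
    )
    return _bag_probability(pipeline, sub)


def mean_region_probability(pipeline: TrainedPipeline, bag: FeatureBag) -> float:
    """Alternative core/patient score: plain mean of region probabilities."""
    if len(bag) == 0:
        raise UnscorablePatientError(f"empty bag for {bag.patient_id!r}")
    return float(predict_instance_prob(pipeline.ensemble, bag).mean())


def select_cut_point(
    probs: Sequence[float], truths: Sequence[int], criterion: str = "youden"
) -> float:
    """Grid-search a probability threshold maximizing the criterion.

    Candidates are midpoints between adjacent distinct probabilities
    (plus the extremes 0 and 1).  ``youden`` maximizes sensitivity +
    specificity − 1; ``accuracy`` maximizes raw accuracy.  Ties resolve
    to the lowest candidate.
    """
    probs = np.asarray(probs, dtype=float)
    truths = np.asarray(truths, dtype=int)
    if np.unique(truths).size < 2:
        raise ValueError("cut-point selection needs both classes present")
    if criterion not in ("youden", "accuracy"):
        raise ValueError(f"unknown criterion {criterion!r}")

    uniq = np.unique(probs)
    candidates = np.concatenate(([0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]))
    n_pos = (truths == 1).sum()
    n_neg = (truths == 0).sum()
    best_cut, best_val = 0.0, -np.inf
    for cut in candidates:
        pred = probs > cut
        tp = int(np.sum(pred & (truths == 1)))
        tn = int(np.sum(~pred & (truths == 0)))
        if criterion == "youden":
            val = tp / n_pos + tn / n_neg - 1.0
        else:
            val = (tp + tn) / truths.size
        if val > best_val + 1e-12:
            best_cut, best_val = float(cut), val
    return best_cut
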