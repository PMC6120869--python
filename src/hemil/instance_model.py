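"""Calibrated instance-level classifier ensemble.

Regions inherit the (weak) patient label.  Training patients are split
into five folds; for each fold a linear SVM is fit on the other four and
an isotonic regression maps its decision values to probabilities on the
held-out fold, yielding five calibrated members whose averaged output is
the region's class probability.  The fold split is by patient, never by
region, so no patient's regions leak between fitting and calibration.
Optional grade-by-class sample weighting equalizes the total weight of
each (grade-bin, class) cell, reducing the leverage of tumor grade when
predicting molecular labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.isotonic import IsotonicRegression
from sklearn.svm import LinearSVC

from .synthetic_cohort import FeatureBag

C_GRID = (0.01, 0.1, 1.0)
N_MEMBERS = 5


def compute_sample_weights(
    cells: Sequence[tuple[str, int]], scheme: str = "uniform_class"
) -> np.ndarray:
    """Per-sample weights inversely proportional to cell size.

    ``cells`` pairs each sample's grade bin with its binary class.  Under
    ``grade_by_class`` the four (grade-bin, class) cells receive equal
    total weight; ``uniform_class`` collapses the grade bins so the two
    classes receive equal total weight.  Weights are scaled to mean 1.
    """
    if scheme not in ("uniform_class", "grade_by_class"):
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    keys = [
        (g, c) if scheme == "grade_by_class" else ("all", c) for g, c in cells
    ]
    counts: dict[tuple[str, int], int] = {}
    for k in keys:
        counts[k] = counts.get(k, 0) + 1
    for k, n in counts.items():
        if n == 0:
            raise ValueError(f"empty weighting cell {k}")
    k_norm = len(keys) / len(counts)  # makes the mean weight exactly 1
    return np.array([k_norm / counts[k] for k in keys])


@dataclass
class CalibratedMember:
    coef: np.ndarray  # (d,)
    intercept: float
    isotonic: IsotonicRegression

    def score(self, x: np.ndarray) -> np.ndarray:
        return x @ self.coef + self.intercept

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return np.clip(self.isotonic.predict(self.score(x)), 0.0, 1.0)


@dataclass
class InstanceEnsemble:
    members: list[CalibratedMember]
    task: str
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    c_value: float

    def __post_init__(self) -> None:
        if len(self.members) != N_MEMBERS:
            raise ValueError(f"ensemble must have exactly {N_MEMBERS} members")

    @property
    def dim(self) -> int:
        return self.feature_mean.shape[0]

    def standardize(self, x: np.ndarray) -> np.ndarray:
        return (x - self.feature_mean) / self.feature_scale


def _patient_folds(
    bags: Sequence[FeatureBag], labels: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Class-stratified partition of patient indices into n_folds groups."""
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[j % n_folds].append(int(i))
    return [np.sort(np.array(f)) for f in folds]


def fit_instance_ensemble(
    bags: Sequence[FeatureBag],
    patient_labels: Sequence[int],
    grade_bins: Sequence[str] | None = None,
    weighting: str = "uniform_class",
    seed: int = 0,
    task: str = "",
    c_grid: Sequence[float] = C_GRID,
) -> InstanceEnsemble:
    """Fit the five-member calibrated ensemble from weakly labeled bags.

    Every region of a bag carries its patient's label.  The SVM cost C is
    chosen once from ``c_grid`` by mean calibration-fold accuracy.
    """
    labels = np.asarray(patient_labels, dtype=int)
    if len(bags) != len(labels):
        raise ValueError("bags and patient_labels length mismatch")
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes among training patients")
    if counts.min() < N_MEMBERS:
        raise ValueError(
            f"need at least {N_MEMBERS} patients per class for patient-level "
            f"folds; smallest class has {counts.min()}"
        )
    if grade_bins is None:
        grade_bins = ["all"] * len(bags)

    # flatten regions, remembering each region's patient
    x = np.concatenate([b.vectors for b in bags])
    region_patient = np.concatenate(
        [np.full(len(b), i) for i, b in enumerate(bags)]
    )
    y = labels[region_patient]
    cells = [(grade_bins[i], int(labels[i])) for i in region_patient]
    w = compute_sample_weights(cells, scheme=weighting)

    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale = np.where(scale < 1e-12, 1.0, scale)
    xs = (x - mean) / scale

    rng = np.random.default_rng(seed)
    folds = _patient_folds(bags, labels, N_MEMBERS, rng)
    region_fold = np.empty(len(y), dtype=int)
    for k, fold_patients in enumerate(folds):
        region_fold[np.isin(region_patient, fold_patients)] = k

    for k in range(N_MEMBERS):
        if np.unique(y[region_fold == k]).size < 2:
            raise ValueError(
                f"calibration fold {k} contains a single class; re-seed or add data"
            )

    def _fit_members(c: float) -> tuple[list[CalibratedMember], float]:
        members, accs = [], []
        for k in range(N_MEMBERS):
            fit_idx = region_fold != k
            cal_idx = ~fit_idx
            svm = LinearSVC(C=c, dual=False, random_state=0)
            svm.fit(xs[fit_idx], y[fit_idx], sample_weight=w[fit_idx])
            scores_cal = xs[cal_idx] @ svm.coef_[0] + svm.intercept_[0]
            iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
            iso.fit(scores_cal, y[cal_idx], sample_weight=w[cal_idx])
            members.append(
                CalibratedMember(svm.coef_[0].copy(), float(svm.intercept_[0]), iso)
            )
            accs.append(np.average((scores_cal > 0) == y[cal_idx], weights=w[cal_idx]))
        return members, float(np.mean(accs))

    best_c, best_members, best_acc = None, None, -np.inf
    for c in c_grid:
        members, acc = _fit_members(c)
        if acc > best_acc + 1e-12:
            best_c, best_members, best_acc = c, members, acc
    return InstanceEnsemble(
        members=best_members,
        task=task,
        feature_mean=mean,
        feature_scale=scale,
        c_value=best_c,
    )


def predict_instance_prob(ensemble: InstanceEnsemble, bag: FeatureBag) -> np.ndarray:
    """Per-region probability: mean of the five calibrated member outputs."""
    if bag.dim != ensemble.dim:
        raise ValueError(
            f"bag dimension {bag.dim} does not match ensemble dimension {ensemble.dim}"
        )
    xs = ensemble.standardize(bag.vectors)
    probs = np.mean([m.predict_proba(xs) for m in ensemble.members], axis=0)
    return np.clip(probs, 0.0, 1.0)
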