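"""Synthetic TMA cohort generator.

Emulates the statistical structure of a population-based breast-cancer
tissue-microarray study: per-patient labels for five binary prediction
tasks (tumor grade, ER status, Basal-like intrinsic subtype, histologic
subtype, ROR risk class), 1-4 one-millimetre cores per patient, and
per-region feature bags with controllable class separation and
intra-tumor heterogeneity.  Optionally renders procedural H&E-like core
images (nucleus-like blobs on an eosin-pink disc over white glass) so
that the full image pipeline can be exercised without any real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

TASKS = ("grade", "er", "basal", "histology", "ror")

#: dichotomization threshold for the continuous risk-of-recurrence score
ROR_HIGH_CUTOFF = 64.7

# Positive-class frequencies taken from the reference cohort's published
# training-set counts (grade high 240/570, ER+ 405/569, Basal-like 92/374)
# and reference margins of the core-level tables (ROR high 188/648,
# lobular 82/820).
DEFAULT_MARGINALS: dict[str, float] = {
    "grade": 240 / 570,
    "er": 405 / 569,
    "basal": 92 / 374,
    "histology": 82 / 820,
    "ror": 188 / 648,
}

#: positive class name per task (the class coded 1 in binary labels)
POSITIVE_CLASS: dict[str, str] = {
    "grade": "high",
    "er": "positive",
    "basal": "Basal",
    "histology": "lobular",
    "ror": "high",
}

# Intrinsic subtype conditional on ER status: Basal-like tumors are
# predominantly ER-negative, Luminal tumors ER-positive.
SUBTYPE_GIVEN_ER: dict[str, dict[str, float]] = {
    "positive": {"LumA": 0.60, "LumB": 0.28, "HER2": 0.06, "Basal": 0.01, "Normal": 0.05},
    "negative": {"LumA": 0.04, "LumB": 0.03, "HER2": 0.10, "Basal": 0.80, "Normal": 0.03},
}


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    grade: Literal["low", "intermediate", "high"]
    er: Literal["negative", "positive"]
    subtype: Literal["LumA", "LumB", "HER2", "Basal", "Normal"]
    histology: Literal["ductal", "lobular"]
    ror_continuous: float
    ror_class: Literal["low_med", "high"]
    n_cores: int
    split: Literal["train", "test"]

    def __post_init__(self) -> None:
        if not 1 <= self.n_cores <= 4:
            raise ValueError(f"n_cores must be in [1, 4], got {self.n_cores}")
        expected = "high" if self.ror_continuous > ROR_HIGH_CUTOFF else "low_med"
        if self.ror_class != expected:
            raise ValueError(
                f"ror_class {self.ror_class!r} inconsistent with "
                f"ror_continuous={self.ror_continuous:.2f} at cutoff {ROR_HIGH_CUTOFF}"
            )

    def binary_label(self, task: str) -> int:
        """0/1 label for a task; 1 is the positive class of that task."""
        value = {
            "grade": self.grade,
            "er": self.er,
            "basal": self.subtype,
            "histology": self.histology,
            "ror": self.ror_class,
        }[task]
        return int(value == POSITIVE_CLASS[task])


@dataclass(frozen=True)
class CohortConfig:
    """Knobs of the generator.

    ``effect_size`` is the standardized mean separation between the two
    class-conditional feature distributions of a task; ``heterogeneity``
    is the fraction of regions drawn from the *opposite* class's
    distribution (intra-tumor heterogeneity); ``grade_effect_size`` adds
    a grade-aligned mean shift to every non-grade task's features so
    that grade confounding is present, as it is in real breast tumors.
    """

    n_patients: int = 300
    marginals: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MARGINALS))
    grade_er_association: float = 6.0
    heterogeneity: float = 0.1
    effect_size: float = 3.0
    grade_effect_size: float = 1.0
    feature_dim: int = 512
    regions_per_core: int = 10
    train_fraction: float = 2 / 3
    seed: int = 0

    def __post_init__(self) -> None:
        for task, f in self.marginals.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"marginal frequency for {task!r} outside [0, 1]: {f}")
        if not 0.0 <= self.heterogeneity <= 1.0:
            raise ValueError(f"heterogeneity outside [0, 1]: {self.heterogeneity}")
        if self.effect_size < 0 or self.grade_effect_size < 0:
            raise ValueError("effect sizes must be >= 0")
        if self.grade_er_association < 0:
            raise ValueError("grade_er_association must be an odds ratio >= 0")


@dataclass
class FeatureBag:
    """Pooled region feature vectors for one patient (possibly many cores).

    ``instance_labels`` records the generator's ground-truth class of each
    region (it differs from the patient label for heterogeneous regions);
    real pipelines never observe it, tests use it as an oracle.
    """

    patient_id: str
    core_ids: np.ndarray  # (n,) int
    offsets: np.ndarray  # (n, 2) region (row, col) offsets
    vectors: np.ndarray  # (n, d) float
    instance_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be 2-D (n_regions, d)")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("feature vectors contain non-finite values")

    def __len__(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


def _er_rates_given_grade(p_er: float, p_high: float, odds_ratio: float) -> tuple[float, float]:
    """Solve P(ER+|low-int) and P(ER+|high) matching the ER marginal and
    the configured odds ratio odds(ER+|low-int)/odds(ER+|high)."""
    if odds_ratio == 1.0 or p_high in (0.0, 1.0) or p_er in (0.0, 1.0):
        return p_er, p_er

    def _marginal_gap(p1: float) -> float:
        # p1 = P(ER+ | high); p0 follows from the odds ratio
        odds1 = p1 / (1 - p1)
        odds0 = odds1 * odds_ratio
        p0 = odds0 / (1 + odds0)
        return (1 - p_high) * p0 + p_high * p1 - p_er

    eps = 1e-9
    p1 = brentq(_marginal_gap, eps, 1 - eps)
    odds0 = (p1 / (1 - p1)) * odds_ratio
    return odds0 / (1 + odds0), p1


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Draw a reproducible synthetic patient cohort.

    Grade and ER are sampled jointly to honor ``grade_er_association``
    while matching both marginals; the intrinsic subtype is drawn
    conditional on ER; the train/test split is a per-patient random
    partition at ``train_fraction``.
    """
    m = config.marginals
    n = config.n_patients
    for task in TASKS:
        f = m.get(task, DEFAULT_MARGINALS[task])
        expected_minority = n * min(f, 1 - f)
        if expected_minority < 2:
            raise ValueError(
                f"n_patients={n} gives an expected minority-class count of "
                f"{expected_minority:.1f} for task {task!r}; need at least 2 "
                "patients per class — increase n_patients or rebalance marginals"
            )

    rng = np.random.default_rng(config.seed)
    p_high = m.get("grade", DEFAULT_MARGINALS["grade"])
    p_er = m.get("er", DEFAULT_MARGINALS["er"])
    p_er_low, p_er_high = _er_rates_given_grade(p_er, p_high, config.grade_er_association)

    grade_high = rng.random(n) < p_high
    # grade is ternary in the source data; split the non-high mass evenly low/intermediate
    low_or_int = rng.random(n) < 0.5
    er_pos = rng.random(n) < np.where(grade_high, p_er_high, p_er_low)

    subtype_names = list(SUBTYPE_GIVEN_ER["positive"])
    subtypes = np.empty(n, dtype=object)
    for er_value, mask in (("positive", er_pos), ("negative", ~er_pos)):
        probs = np.array([SUBTYPE_GIVEN_ER[er_value][s] for s in subtype_names])
        probs = probs / probs.sum()
        subtypes[mask] = rng.choice(subtype_names, size=int(mask.sum()), p=probs)

    lobular = rng.random(n) < m.get("histology", DEFAULT_MARGINALS["histology"])

    p_ror_high = m.get("ror", None)
    if p_ror_high is None:
        ror = rng.uniform(0.0, 100.0, size=n)
    else:
        # piecewise uniform: class frequency matches the marginal while the
        # 64.7 threshold invariant is preserved exactly
        high = rng.random(n) < p_ror_high
        ror = np.where(
            high,
            rng.uniform(ROR_HIGH_CUTOFF + 1e-9, 100.0, size=n),
            rng.uniform(0.0, ROR_HIGH_CUTOFF, size=n),
        )

    n_cores = rng.integers(1, 5, size=n)
    order = rng.permutation(n)
    n_train = int(round(config.train_fraction * n))
    split = np.empty(n, dtype=object)
    split[order[:n_train]] = "train"
    split[order[n_train:]] = "test"

    records = []
    for i in range(n):
        records.append(
            PatientRecord(
                patient_id=f"P{i:05d}",
                grade="high" if grade_high[i] else ("low" if low_or_int[i] else "intermediate"),
                er="positive" if er_pos[i] else "negative",
                subtype=str(subtypes[i]),
                histology="lobular" if lobular[i] else "ductal",
                ror_continuous=float(ror[i]),
                ror_class="high" if ror[i] > ROR_HIGH_CUTOFF else "low_med",
                n_cores=int(n_cores[i]),
                split=str(split[i]),
            )
        )
    return records


def task_directions(task: str, config: CohortConfig) -> tuple[np.ndarray, np.ndarray]:
    """Unit mean-shift directions (task direction, grade direction).

    Fixed functions of (task, feature_dim, seed) only, so every bag of a
    cohort shares them; tests use them as the generator's ground truth.
    """
    d = config.feature_dim
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7, TASKS.index(task)]))
    u = rng.standard_normal(d)
    u /= np.linalg.norm(u)
    g_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    g = g_rng.standard_normal(d)
    g /= np.linalg.norm(g)
    if task == "grade":
        return g, g
    # make the task axis exactly orthogonal to the grade axis so that
    # "alignment with the grade direction" is unambiguous in tests
    u = u - (u @ g) * g
    u /= np.linalg.norm(u)
    return u, g


def synthesize_feature_bag(
    record: PatientRecord, task: str, config: CohortConfig
) -> FeatureBag:
    """Draw one patient's per-region pooled feature vectors for a task.

    Each region's true class equals the patient's label with probability
    ``1 - heterogeneity`` and the opposite class otherwise.  Vectors are
    spherical unit-variance Gaussians whose means are separated by
    ``effect_size`` along the task direction, plus (for non-grade tasks)
    a ``grade_effect_size`` shift along the grade direction for
    high-grade patients.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    if config.regions_per_core == 0:
        raise ValueError(f"regions_per_core is 0: bag for {record.patient_id} would be empty")

    u_task, u_grade = task_directions(task, config)
    label = record.binary_label(task)
    n_regions = config.regions_per_core * record.n_cores
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, TASKS.index(task), int(record.patient_id[1:])])
    )
    flipped = rng.random(n_regions) < config.heterogeneity
    inst = np.where(flipped, 1 - label, label)

    vectors = rng.standard_normal((n_regions, config.feature_dim))
    # centre the two classes at ±effect_size/2 along the task axis
    vectors += np.outer(inst - 0.5, config.effect_size * u_task)
    if task != "grade" and record.grade == "high":
        vectors += config.grade_effect_size * u_grade

    core_ids = np.repeat(np.arange(record.n_cores), config.regions_per_core)
    offsets = np.stack(
        [np.tile(np.arange(config.regions_per_core), record.n_cores), core_ids], axis=1
    )
    return FeatureBag(
        patient_id=record.patient_id,
        core_ids=core_ids,
        offsets=offsets,
        vectors=vectors,
        instance_labels=inst.astype(int),
    )


# ---------------------------------------------------------------------------
# procedural core images


def _grade_texture_params(record: PatientRecord) -> dict[str, float]:
    # high-grade tumors: denser, larger, more pleomorphic nucleus-like blobs
    if record.grade == "high":
        return {"blob_density": 9e-4, "blob_radius": 5.5, "radius_sd": 1.8}
    return {"blob_density": 4e-4, "blob_radius": 4.0, "radius_sd": 0.8}


def synthesize_core_image(record: PatientRecord, side_px: int = 512, seed: int = 0) -> np.ndarray:
    """Render a procedural H&E-like TMA core as an (side, side, 3) uint8 array.

    A circular tissue disc (eosin-pink stroma with hematoxylin-blue
    nucleus-like blobs whose density and size depend on tumor grade)
    on a near-white glass background.  Deterministic per (record, seed).
    """
    if side_px < 256:
        raise ValueError(f"side_px must be >= 256, got {side_px}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, int(record.patient_id[1:])]))
    params = _grade_texture_params(record)

    yy, xx = np.mgrid[0:side_px, 0:side_px].astype(np.float64)
    c = (side_px - 1) / 2.0
    radius = 0.47 * side_px
    disc = (yy - c) ** 2 + (xx - c) ** 2 <= radius**2

    img = np.empty((side_px, side_px, 3), dtype=np.float64)
    img[...] = 247.0 + rng.normal(0.0, 2.0, size=(side_px, side_px, 1))  # glass

    # eosin-stained stroma with mild low-frequency variation
    stroma = np.array([233.0, 177.0, 200.0])
    wave = 6.0 * np.sin(2 * np.pi * yy / (side_px / 3.1)) * np.sin(2 * np.pi * xx / (side_px / 2.3))
    tissue = stroma[None, None, :] + wave[..., None] + rng.normal(0.0, 4.0, size=img.shape)
    img[disc] = tissue[disc]

    # hematoxylin nucleus-like blobs inside the disc
    n_blobs = rng.poisson(params["blob_density"] * np.pi * radius**2)
    hema = np.array([72.0, 48.0, 134.0])
    ang = rng.uniform(0.0, 2 * np.pi, size=n_blobs)
    rad = radius * np.sqrt(rng.uniform(0.0, 1.0, size=n_blobs))
    by = c + rad * np.sin(ang)
    bx = c + rad * np.cos(ang)
    br = np.clip(rng.normal(params["blob_radius"], params["radius_sd"], size=n_blobs), 1.5, None)
    for y0, x0, r0 in zip(by, bx, br):
        lo_y, hi_y = int(max(0, y0 - r0 - 1)), int(min(side_px, y0 + r0 + 2))
        lo_x, hi_x = int(max(0, x0 - r0 - 1)), int(min(side_px, x0 + r0 + 2))
        sub_y, sub_x = np.mgrid[lo_y:hi_y, lo_x:hi_x].astype(np.float64)
        blob = (sub_y - y0) ** 2 + (sub_x - x0) ** 2 <= r0**2
        img[lo_y:hi_y, lo_x:hi_x][blob] = hema + rng.normal(0.0, 6.0, size=3)

    # small clear "holes" (fat/lumen) so tissue fraction dips below the disc area
    n_holes = rng.poisson(2.5e-5 * np.pi * radius**2)
    for _ in range(n_holes):
        a = rng.uniform(0.0, 2 * np.pi)
        r = radius * np.sqrt(rng.uniform(0.0, 0.8))
        y0, x0 = c + r * np.sin(a), c + r * np.cos(a)
        r0 = rng.uniform(0.01, 0.03) * side_px
        lo_y, hi_y = int(max(0, y0 - r0 - 1)), int(min(side_px, y0 + r0 + 2))
        lo_x, hi_x = int(max(0, x0 - r0 - 1)), int(min(side_px, x0 + r0 + 2))
        sub_y, sub_x = np.mgrid[lo_y:hi_y, lo_x:hi_x].astype(np.float64)
        hole = (sub_y - y0) ** 2 + (sub_x - x0) ** 2 <= r0**2
        img[lo_y:hi_y, lo_x:hi_x][hole] = 246.0

    return np.clip(img, 0, 255).astype(np.uint8)


def core_disc_mask(side_px: int) -> np.ndarray:
    """Ground-truth tissue disc used by :func:`synthesize_core_image`."""
    yy, xx = np.mgrid[0:side_px, 0:side_px].astype(np.float64)
    c = (side_px - 1) / 2.0
    return (yy - c) ** 2 + (xx - c) ** 2 <= (0.47 * side_px) ** 2


# ---------------------------------------------------------------------------
# serialization


def cohort_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "split": [r.split for r in records],
            "grade": [r.grade for r in records],
            "er": [r.er for r in records],
            "subtype": [r.subtype for r in records],
            "histology": [r.histology for r in records],
            "ror_class": [r.ror_class for r in records],
            "ror_continuous": [r.ror_continuous for r in records],
            "n_cores": [r.n_cores for r in records],
        }
    )


def write_label_table(records: Sequence[PatientRecord], path) -> None:
    cohort_to_frame(records).to_csv(path, sep="\t", index=False)


def bag_to_frame(bag: FeatureBag) -> pd.DataFrame:
    d = bag.dim
    frame = pd.DataFrame(bag.vectors, columns=[f"f{i}" for i in range(d)])
    frame.insert(0, "region_col", bag.offsets[:, 1])
    frame.insert(0, "region_row", bag.offsets[:, 0])
    frame.insert(0, "core_id", bag.core_ids)
    frame.insert(0, "patient_id", bag.patient_id)
    return frame


def write_feature_bags(bags: Sequence[FeatureBag], path) -> None:
    pd.concat([bag_to_frame(b) for b in bags], ignore_index=True).to_csv(
        path, sep="\t", index=False
    )


def read_feature_bags(path) -> list[FeatureBag]:
    frame = pd.read_csv(path, sep="\t")
    feat_cols = [c for c in frame.columns if c.startswith("f") and c[1:].isdigit()]
    bags = []
    for pid, grp in frame.groupby("patient_id", sort=True):
        bags.append(
            FeatureBag(
                patient_id=str(pid),
                core_ids=grp["core_id"].to_numpy(),
                offsets=grp[["region_row", "region_col"]].to_numpy(),
                vectors=grp[feat_cols].to_numpy(dtype=float),
            )
        )
    return bags
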