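"""End-to-end orchestration: simulate -> preprocess -> featurize ->
fit -> predict -> evaluate -> render heat maps.

`run_pipeline` is a pure function of (config, seeds): it generates a
synthetic cohort, trains the two-stage classifier for each requested
task, scores the held-out test patients and cores, and writes TSV
predictions plus a metrics report.  `render_heatmap` paints region
probabilities over a core image (white = uncertain, saturated class
colors = confident).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic_cohort as sc
from .aggregate import (
    CutPoints,
    TrainedPipeline,
    classify,
    fit_patient_model,
    predict_core,
    predict_patient,
    quantile_signature,
)
from .evaluate import summarize
from .features import DOWNSAMPLE, ExtractorSpec, extract_feature_map, pool_region_features
from .instance_model import fit_instance_ensemble, predict_instance_prob
from .preprocess import extract_regions, normalize_stains, tissue_mask
from .synthetic_cohort import POSITIVE_CLASS, TASKS

log = logging.getLogger("hemil")

#: tasks trained with grade-by-class weighting to reduce grade leverage
GRADE_WEIGHTED_TASKS = ("er", "basal")


@dataclass
class RunConfig:
    tasks: tuple[str, ...] = TASKS
    cohort: sc.CohortConfig = field(default_factory=sc.CohortConfig)
    use_images: bool = False  # render cores and run the image path (slower)
    image_side_px: int = 512
    region_size_px: int = 128  # tile size for the image path
    train_stride_px: int = 128
    test_stride_px: int = 64
    min_tissue_fraction: float = 0.5
    extractor: ExtractorSpec = field(default_factory=lambda: ExtractorSpec(d=64))
    cuts: CutPoints = field(default_factory=CutPoints)
    seed: int = 0
    out_dir: Path | None = None


def _grade_bin(record: sc.PatientRecord) -> str:
    return "high" if record.grade == "high" else "low_int"


def _image_bag(
    record: sc.PatientRecord, config: RunConfig, stride_px: int
) -> sc.FeatureBag | None:
    """Featurize a patient's procedurally rendered cores."""
    parts = []
    for k in range(record.n_cores):
        img = sc.synthesize_core_image(
            record, side_px=config.image_side_px, seed=config.seed * 101 + k
        )
        norm = normalize_stains(img)
        mask = tissue_mask(norm)
        grid = extract_regions(
            img.shape[:2],
            mask,
            region_size_px=config.region_size_px,
            stride_px=stride_px,
            min_tissue_fraction=config.min_tissue_fraction,
        )
        if not grid.regions:
            log.warning("core %d of %s has no scorable regions", k, record.patient_id)
            continue
        fmap = extract_feature_map(norm, config.extractor)
        parts.append(
            pool_region_features(
                fmap, grid, patient_id=record.patient_id, core_id=k, downsample=DOWNSAMPLE
            )
        )
    if not parts:
        return None
    return sc.FeatureBag(
        patient_id=record.patient_id,
        core_ids=np.concatenate([p.core_ids for p in parts]),
        offsets=np.concatenate([p.offsets for p in parts]),
        vectors=np.concatenate([p.vectors for p in parts]),
    )


def fit_task(
    task: str,
    train_records: list[sc.PatientRecord],
    train_bags: list[sc.FeatureBag],
    config: RunConfig,
) -> TrainedPipeline:
    labels = [r.binary_label(task) for r in train_records]
    weighting = "grade_by_class" if task in GRADE_WEIGHTED_TASKS else "uniform_class"
    ensemble = fit_instance_ensemble(
        train_bags,
        labels,
        grade_bins=[_grade_bin(r) for r in train_records],
        weighting=weighting,
        seed=config.seed,
        task=task,
    )
    signatures = [
        quantile_signature(predict_instance_prob(ensemble, bag)) for bag in train_bags
    ]
    patient_model = fit_patient_model(signatures, labels, seed=config.seed)
    return TrainedPipeline(
        task=task, ensemble=ensemble, patient_model=patient_model, cuts=config.cuts
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage for every task; returns {task: {...}} artifacts.

    Per task: the trained pipeline, patient- and core-level prediction
    frames, and a metrics row (accuracy/sensitivity/specificity/kappa)
    against the generator's ground truth.  Deterministic per seeds.
    """
    records = sc.generate_cohort(config.cohort)
    train = [r for r in records if r.split == "train"]
    test = [r for r in records if r.split == "test"]
    log.info("cohort: %d train / %d test patients", len(train), len(test))

    out: dict = {"records": records, "tasks": {}}
    for task in config.tasks:
        if config.use_images:
            train_bags = [
                _image_bag(r, config, config.train_stride_px) for r in train
            ]
            test_bags = [_image_bag(r, config, config.test_stride_px) for r in test]
            train_pairs = [(r, b) for r, b in zip(train, train_bags) if b is not None]
            test_pairs = [(r, b) for r, b in zip(test, test_bags) if b is not None]
            dropped = len(test) - len(test_pairs)
            if dropped:
                log.info("task %s: %d unscorable test patients dropped", task, dropped)
        else:
            train_pairs = [
                (r, sc.synthesize_feature_bag(r, task, config.cohort)) for r in train
            ]
            test_pairs = [
                (r, sc.synthesize_feature_bag(r, task, config.cohort)) for r in test
            ]

        pipeline = fit_task(task, [r for r, _ in train_pairs], [b for _, b in train_pairs], config)

        rows, core_rows = [], []
        for r, bag in test_pairs:
            prob = predict_patient(pipeline, bag)
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "probability": prob,
                    "call": classify(prob, task, config.cuts),
                    "truth": r.binary_label(task),
                }
            )
            for core in np.unique(bag.core_ids):
                core_rows.append(
                    {
                        "patient_id": r.patient_id,
                        "core_id": int(core),
                        "probability": predict_core(pipeline, bag, int(core)),
                        "truth": r.binary_label(task),
                    }
                )
        patients = pd.DataFrame(rows)
        cores = pd.DataFrame(core_rows)
        counts = np.zeros((2, 2), dtype=int)
        for _, row in patients.iterrows():
            counts[int(row["call"]), int(row["truth"])] += 1
        metrics = summarize(counts, positive_class=POSITIVE_CLASS[task])
        metrics["task"] = task
        out["tasks"][task] = {
            "pipeline": pipeline,
            "patients": patients,
            "cores": cores,
            "metrics": metrics,
            "counts": counts,
        }
        log.info(
            "task %s: accuracy %s%% kappa %s (n=%d)",
            task,
            metrics["accuracy"],
            metrics["kappa"],
            metrics["n"],
        )

    if config.out_dir is not None:
        _write_artifacts(out, config)
    return out


def _write_artifacts(out: dict, config: RunConfig) -> None:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sc.write_label_table(out["records"], out_dir / "labels.tsv")
    metric_rows = []
    for task, art in out["tasks"].items():
        art["patients"].to_csv(out_dir / f"predictions_{task}_patients.tsv", sep="\t", index=False)
        art["cores"].to_csv(out_dir / f"predictions_{task}_cores.tsv", sep="\t", index=False)
        m = dict(art["metrics"])
        m["kappa_ci"] = "" if m["kappa_ci"] is None else f"{m['kappa_ci'][0]}-{m['kappa_ci'][1]}"
        m["seed"] = config.seed
        metric_rows.append(m)
    pd.DataFrame(metric_rows).to_csv(out_dir / "metrics.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# heat maps

POSITIVE_COLOR = np.array([255.0, 0.0, 0.0])  # saturated positive class (red)
NEGATIVE_COLOR = np.array([0.0, 0.0, 255.0])  # saturated negative class (blue)
WHITE = np.array([255.0, 255.0, 255.0])


def probability_tint(p: float) -> np.ndarray:
    """White at p = 0.5, saturating linearly toward the class colors."""
    if p >= 0.5:
        t = 2.0 * (p - 0.5)
        return (1 - t) * WHITE + t * POSITIVE_COLOR
    t = 2.0 * (0.5 - p)
    return (1 - t) * WHITE + t * NEGATIVE_COLOR


def render_heatmap(
    image: np.ndarray,
    offsets,
    probs,
    region_size_px: int,
    mask: np.ndarray | None = None,
    alpha: float = 1.0,
) -> np.ndarray:
    """Overlay region class probabilities on a core image.

    Overlapping regions contribute their average probability per pixel;
    pixels outside any region (or outside the tissue mask, if given) keep
    the original image.  ``alpha`` blends tint over image.
    """
    probs = np.asarray(probs, dtype=float)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    h, w = image.shape[:2]
    acc = np.zeros((h, w))
    cnt = np.zeros((h, w))
    s = region_size_px
    for (r, c), p in zip(offsets, probs):
        if r < 0 or c < 0 or r + s > h or c + s > w:
            raise ValueError(f"region ({r}, {c}) lies outside the image")
        acc[r : r + s, c : c + s] += p
        cnt[r : r + s, c : c + s] += 1

    covered = cnt > 0
    if mask is not None:
        covered &= np.asarray(mask, dtype=bool)
    avg = np.where(covered, acc / np.maximum(cnt, 1), 0.5)

    t = 2.0 * np.abs(avg - 0.5)
    color = np.where(avg[..., None] >= 0.5, POSITIVE_COLOR, NEGATIVE_COLOR)
    tint = (1 - t[..., None]) * WHITE + t[..., None] * color

    out = image.astype(np.float64).copy()
    out[covered] = (1 - alpha) * out[covered] + alpha * tint[covered]
    return np.clip(out, 0, 255).astype(np.uint8)
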