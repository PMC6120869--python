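"""Published concordance tables for the breast-cancer TMA study this
pipeline models.

Each entry is a 2×2 count matrix (rows = image-analysis or rater-1
prediction, columns = reference standard; index 1 = the positive/
sensitivity class) together with the statistics printed alongside it:
integer percentages and 2-decimal kappa.  The ``strict`` flag marks the
kappa confidence intervals that the asymptotic standard error reproduces
at printed precision; the remaining printed intervals come from an
unstated variance formula and are informational only.

These matrices are inputs: the statistics are always recomputed from the
counts through :mod:`hemil.evaluate`.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ReferenceTable:
    name: str
    counts: tuple[tuple[int, int], tuple[int, int]]
    positive_class: str
    accuracy: int
    sensitivity: int | None
    specificity: int | None
    kappa: float | None
    kappa_ci: tuple[float, float] | None = None
    ci_strict: bool = False  # asymptotic SE reproduces the printed CI
    percent_agreement: int | None = None


REFERENCE_TABLES: tuple[ReferenceTable, ...] = (
    # grade, patient level
    ReferenceTable(
        "grade_pathologists", ((113, 23), (4, 102)), "high",
        accuracy=89, sensitivity=82, specificity=97,
        kappa=0.78, kappa_ci=(0.70, 0.86), ci_strict=True, percent_agreement=89,
    ),
    ReferenceTable(
        "grade_image_analysis", ((118, 8), (45, 117)), "high",
        accuracy=82, sensitivity=94, specificity=72,
        kappa=0.64, kappa_ci=(0.55, 0.72), percent_agreement=82,
    ),
    # ER status, core level (995 cores)
    ReferenceTable(
        "er_unweighted_overall", ((260, 80), (83, 572)), "positive",
        accuracy=84, sensitivity=88, specificity=76,
        kappa=0.64, kappa_ci=(0.59, 0.69), ci_strict=True,
    ),
    ReferenceTable(
        "er_grade_weighted_overall", ((246, 104), (97, 548)), "positive",
        accuracy=80, sensitivity=84, specificity=72,
        kappa=0.55, kappa_ci=(0.50, 0.61), ci_strict=True,
    ),
    ReferenceTable(
        "er_unweighted_low_int", ((21, 24), (25, 467)), "positive",
        accuracy=91, sensitivity=95, specificity=46, kappa=0.41,
    ),
    ReferenceTable(
        "er_grade_weighted_low_int", ((28, 69), (18, 422)), "positive",
        accuracy=84, sensitivity=86, specificity=61, kappa=0.31,
    ),
    ReferenceTable(
        "er_unweighted_high", ((239, 46), (58, 104)), "positive",
        accuracy=77, sensitivity=69, specificity=80,
        kappa=0.49, kappa_ci=(0.40, 0.57), ci_strict=True,
    ),
    ReferenceTable(
        "er_grade_weighted_high", ((218, 35), (79, 125)), "positive",
        accuracy=75, sensitivity=78, specificity=73, kappa=0.48,
    ),
    # intrinsic subtype, core level (sensitivity class: non-Basal-like)
    ReferenceTable(
        "basal_overall", ((131, 101), (48, 368)), "non_basal",
        accuracy=77, sensitivity=78, specificity=73, kappa=0.47,
    ),
    ReferenceTable(
        "basal_low_int", ((11, 41), (4, 245)), "non_basal",
        accuracy=85, sensitivity=86, specificity=73, kappa=0.27,
    ),
    ReferenceTable(
        "basal_high", ((120, 60), (44, 123)), "non_basal",
        accuracy=70, sensitivity=67, specificity=73, kappa=0.40,
    ),
    # ROR-PT, core level (sensitivity class: high)
    ReferenceTable(
        "ror_overall", ((342, 40), (118, 148)), "high",
        accuracy=76, sensitivity=79, specificity=74, kappa=0.47,
    ),
    ReferenceTable(
        "ror_low_int", ((245, 16), (26, 14)), "high",
        accuracy=86, sensitivity=47, specificity=90, kappa=0.32,
    ),
    ReferenceTable(
        "ror_high_grade", ((97, 24), (92, 134)), "high",
        accuracy=67, sensitivity=85, specificity=51, kappa=0.35,
    ),
    # histologic subtype, core level (sensitivity class: lobular)
    ReferenceTable(
        "histology_overall", ((710, 24), (28, 58)), "lobular",
        accuracy=94, sensitivity=71, specificity=96, kappa=0.66,
    ),
    ReferenceTable(
        "histology_high_grade", ((442, 0), (5, 0)), "lobular",
        accuracy=99, sensitivity=None, specificity=99, kappa=None,
    ),
)
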