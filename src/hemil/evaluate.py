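"""Concordance statistics between predicted and reference labels.

Conventions match clinical concordance tables: the 2×2 count matrix has
predictions (rater 1) on rows and the reference standard (rater 2) on
columns, with index 1 the positive/sensitivity class.  Percentages are
reported rounded to integers and kappa to two decimals, the precision at
which such tables are printed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2_contingency

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class ConfusionSummary:
    counts: np.ndarray  # (2, 2) int; rows = prediction, cols = reference
    positive_class: str
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (2, 2):
            raise ValueError("counts must be 2x2")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def confusion(
    predicted: Sequence, reference: Sequence, positive_class: str
) -> ConfusionSummary:
    """Tabulate paired binary calls; pairs with missing reference are
    dropped and counted in ``n_dropped``."""
    if len(predicted) != len(reference):
        raise ValueError(
            f"length mismatch: {len(predicted)} predictions vs {len(reference)} references"
        )
    counts = np.zeros((2, 2), dtype=int)
    dropped = 0
    for p, r in zip(predicted, reference):
        if r is None or (isinstance(r, float) and math.isnan(r)):
            dropped += 1
            continue
        i = int(p == positive_class or p == 1 and not isinstance(p, str))
        j = int(r == positive_class or r == 1 and not isinstance(r, str))
        counts[i, j] += 1
    return ConfusionSummary(counts=counts, positive_class=positive_class, n_dropped=dropped)


def rates(counts: np.ndarray) -> dict[str, float | None]:
    """Accuracy, sensitivity, specificity as percentages (unrounded).

    Sensitivity is recall of the positive class (index 1 on both axes);
    a zero reference margin yields None (reported as N/A)."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n == 0:
        raise ValueError("empty table")
    acc = 100.0 * (counts[0, 0] + counts[1, 1]) / n
    pos_margin = counts[:, 1].sum()
    neg_margin = counts[:, 0].sum()
    sens = 100.0 * counts[1, 1] / pos_margin if pos_margin > 0 else None
    spec = 100.0 * counts[0, 0] / neg_margin if neg_margin > 0 else None
    return {"accuracy": acc, "sensitivity": sens, "specificity": spec}


def percent_agreement(counts: np.ndarray) -> float:
    """Raw percent agreement (identical to accuracy for a 2x2 table)."""
    return rates(counts)["accuracy"]


def cohens_kappa(
    counts: np.ndarray, se_method: str = "asymptotic"
) -> tuple[float, tuple[float, float]]:
    """Chance-corrected agreement with a 95% CI.

    kappa = (p_o - p_e) / (1 - p_e), expected agreement p_e from the
    product of row and column marginals.  The default standard error is
    the simple asymptotic form sqrt(p_o (1 - p_o) / (n (1 - p_e)^2));
    ``se_method='fleiss'`` uses the Fleiss–Cohen–Everitt variance.
    Degenerate margins (p_e = 1) yield (nan, (nan, nan)).
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n == 0:
        raise ValueError("empty table")
    p = counts / n
    po = np.trace(p)
    row, col = p.sum(axis=1), p.sum(axis=0)
    pe = float(row @ col)
    if abs(1.0 - pe) < 1e-12:
        return float("nan"), (float("nan"), float("nan"))
    kappa = (po - pe) / (1.0 - pe)

    if se_method == "asymptotic":
        se = math.sqrt(po * (1.0 - po) / (n * (1.0 - pe) ** 2))
    elif se_method == "fleiss":
        a = sum(
            p[i, i] * (1.0 - (row[i] + col[i]) * (1.0 - kappa)) ** 2
            for i in range(p.shape[0])
        )
        b = (1.0 - kappa) ** 2 * sum(
            p[i, j] * (col[i] + row[j]) ** 2
            for i in range(p.shape[0])
            for j in range(p.shape[1])
            if i != j
        )
        c = (kappa - pe * (1.0 - kappa)) ** 2
        se = math.sqrt(max(a + b - c, 0.0) / n) / (1.0 - pe)
    else:
        raise ValueError(f"unknown se_method {se_method!r}")
    return float(kappa), (float(kappa - Z95 * se), float(kappa + Z95 * se))


def chi_square_homogeneity(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square of independence on an r×2 count table
    (no continuity correction); df = r − 1."""
    table = np.asarray(table, dtype=float)
    if np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
        raise ValueError("table has a zero margin: expected counts undefined")
    stat, p, _, expected = chi2_contingency(table, correction=False)
    if np.any(expected <= 0):
        raise ValueError("zero expected cell count")
    return float(stat), float(p)


def odds_ratio(counts: np.ndarray) -> tuple[float, tuple[float, float], bool]:
    """OR = ad/bc with the Woolf logit 95% CI.

    Returns (OR, (low, high), corrected); zero cells trigger the Haldane
    +0.5 correction, flagged by ``corrected``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (2, 2):
        raise ValueError("odds ratio requires a 2x2 table")
    corrected = bool(np.any(counts == 0))
    c = counts + 0.5 if corrected else counts
    a, b = c[0, 0], c[0, 1]
    cc, d = c[1, 0], c[1, 1]
    or_ = (a * d) / (b * cc)
    se = math.sqrt(1 / a + 1 / b + 1 / cc + 1 / d)
    lo, hi = math.exp(math.log(or_) - Z95 * se), math.exp(math.log(or_) + Z95 * se)
    return float(or_), (float(lo), float(hi)), corrected


def summarize(counts: np.ndarray, positive_class: str = "positive") -> dict:
    """One table row: integer-rounded rates, 2-decimal kappa and CI."""
    r = rates(counts)
    kappa, ci = cohens_kappa(counts)
    out = {
        "n": int(np.asarray(counts).sum()),
        "positive_class": positive_class,
        "accuracy": None if r["accuracy"] is None else round(r["accuracy"]),
        "sensitivity": None if r["sensitivity"] is None else round(r["sensitivity"]),
        "specificity": None if r["specificity"] is None else round(r["specificity"]),
        "percent_agreement": round(percent_agreement(counts)),
        "kappa": None if math.isnan(kappa) else round(kappa, 2),
        "kappa_ci": None
        if math.isnan(kappa)
        else (round(ci[0], 2), round(ci[1], 2)),
    }
    return out
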