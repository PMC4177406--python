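"""Cohort comparison statistics and per-feature screening.

Group comparisons between benign and malignant patients: uncorrected Pearson
chi-square for the binary demographic/morphological variables, Welch's t
from summary statistics for age and diameter, and descriptive summaries.
Per-feature screening ranks each texture feature by Mann-Whitney AUC with a
Bonferroni significance threshold (0.05 / 672 = 7.4e-5 for the default
feature set).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from noduletex.smote import Dataset

__all__ = [
    "PATIENT_COLUMNS",
    "BINARY_VARIABLES",
    "ContingencyTable2x2",
    "chi_square_2x2",
    "fisher_exact_2x2",
    "welch_t",
    "describe",
    "bonferroni_threshold",
    "mann_whitney_auc",
    "feature_screen",
    "feature_family_eval",
    "cohort_tables",
]

# Patient table schema: 7 demographic + 12 morphological variables + label.
# Gender: 1 female / 0 male; other binaries: 1 yes / 0 no; age in years;
# diameter in cm.
DEMOGRAPHIC_VARIABLES = (
    "age", "gender", "smoking", "tuberculosis_history", "dust_history",
    "genetic_disease", "tumor_history",
)
MORPHOLOGICAL_VARIABLES = (
    "calcification", "cavitation", "uniform_density", "ground_glass",
    "lobulation", "lymphadenectasis", "spiculation", "vacuoles",
    "pleural_indentation", "pleural_fluid", "substantial_changes", "diameter",
)
PATIENT_COLUMNS = ("patient_id",) + DEMOGRAPHIC_VARIABLES \
    + MORPHOLOGICAL_VARIABLES + ("label",)
BINARY_VARIABLES = tuple(v for v in DEMOGRAPHIC_VARIABLES
                         + MORPHOLOGICAL_VARIABLES
                         if v not in ("age", "diameter"))
CONTINUOUS_VARIABLES = ("age", "diameter")


@dataclass
class ContingencyTable2x2:
    """2x2 counts, rows = class (benign, malignant), cols = variable level."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (2, 2):
            raise ValueError("expected a 2x2 table")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if self.counts.sum() == 0:
            raise ValueError("empty table")


def chi_square_2x2(t: ContingencyTable2x2) -> Tuple[float, float]:
    """Uncorrected Pearson chi-square (1 df) and its p value."""
    c = t.counts
    if (c.sum(axis=0) == 0).any() or (c.sum(axis=1) == 0).any():
        raise ValueError("zero marginal")
    stat, p, _, expected = sps.chi2_contingency(c, correction=False)
    if (expected <= 0).any():
        raise ValueError("zero expected count")
    return float(stat), float(p)


def fisher_exact_2x2(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p (fallback when expected counts are small)."""
    return float(sps.fisher_exact(t.counts)[1])


def welch_t(mean1: float, sd1: float, n1: int,
            mean2: float, sd2: float, n2: int) -> Tuple[float, float]:
    """|t| and p for the unequal-variance two-sample t from summaries."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                   equal_var=False)
    return float(abs(res.statistic)), float(res.pvalue)


def describe(values: Sequence[float]) -> Dict[str, float]:
    """Mean, sd (n-1), median, quartiles (linear interpolation), min, max."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "min": float(v.min()),
        "max": float(v.max()),
    }


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 672) -> float:
    """Per-test significance level alpha / n_tests."""
    return alpha / n_tests


def mann_whitney_auc(x_pos: np.ndarray, x_neg: np.ndarray) -> float:
    """AUC as the normalised Mann-Whitney U (ties counted one half)."""
    x_pos = np.asarray(x_pos, dtype=float)
    x_neg = np.asarray(x_neg, dtype=float)
    n1, n0 = len(x_pos), len(x_neg)
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required")
    allv = np.concatenate([x_pos, x_neg])
    ranks = sps.rankdata(allv)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def feature_screen(X: np.ndarray, y: np.ndarray,
                   alpha: float = 0.05,
                   feature_names: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-feature Mann-Whitney AUC, p and Bonferroni flag.

    Returns a frame with columns auc, p, significant, degenerate (constant
    columns get AUC 0.5, p 1 and a degenerate flag).
    """
    from noduletex.evaluate import auc_pvalue

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    pos = X[y == classes.max()]
    neg = X[y == classes.min()]
    threshold = bonferroni_threshold(alpha, X.shape[1])
    rows = []
    for jcol in range(X.shape[1]):
        col_p, col_n = pos[:, jcol], neg[:, jcol]
        if np.ptp(X[:, jcol]) == 0:
            rows.append((0.5, 1.0, False, True))
            continue
        auc = mann_whitney_auc(col_p, col_n)
        p = auc_pvalue(auc, len(col_p), len(col_n))
        rows.append((auc, p, p < threshold, False))
    names = list(feature_names) if feature_names is not None \
        else [f"f{j}" for j in range(X.shape[1])]
    return pd.DataFrame(rows, index=names,
                        columns=["auc", "p", "significant", "degenerate"])


def feature_family_eval(ds: Dataset, family: str, cfg=None, folds: int = 10,
                        seed: int = 0, grouping: str = "roi") -> dict:
    """Cross-validated metrics using only one feature family's 48 columns."""
    from noduletex.evaluate import KernelConfig, cross_validate
    from noduletex.features import FEATURE_NAMES

    if family not in FEATURE_NAMES:
        raise ValueError(f"unknown feature family {family!r}")
    # names are "L{level}_D{direction}_{feature}"; the feature itself may
    # contain underscores, so split off the level/direction prefix
    cols = [i for i, n in enumerate(ds.feature_names)
            if n.split("_", 2)[-1] == family]
    if not cols:
        raise ValueError(f"dataset has no columns for family {family!r}")
    sub = Dataset(X=ds.X[:, cols], y=ds.y, groups=ds.groups,
                  feature_names=[ds.feature_names[i] for i in cols])
    cfg = cfg or KernelConfig(seed=seed)
    return cross_validate(sub, cfg, folds=folds, grouping=grouping)


def cohort_tables(patients: pd.DataFrame) -> dict:
    """Group-comparison summary for every patient variable.

    Binary variables get class-conditional counts and the uncorrected
    chi-square (Fisher exact p replaces it when an expected count is < 5);
    age and diameter get descriptive summaries and Welch's t.
    """
    out: dict = {}
    benign = patients[patients["label"] == "benign"]
    malignant = patients[patients["label"] == "malignant"]
    for var in BINARY_VARIABLES:
        counts = np.array([
            [int((benign[var] == 1).sum()), int((benign[var] == 0).sum())],
            [int((malignant[var] == 1).sum()), int((malignant[var] == 0).sum())],
        ])
        entry: dict = {
            "benign_yes": int(counts[0, 0]), "benign_no": int(counts[0, 1]),
            "malignant_yes": int(counts[1, 0]), "malignant_no": int(counts[1, 1]),
        }
        table = ContingencyTable2x2(counts)
        try:
            expected = sps.chi2_contingency(counts, correction=False)[3]
            if (expected < 5).any():
                entry["p"] = fisher_exact_2x2(table)
                entry["test"] = "fisher"
            else:
                stat, p = chi_square_2x2(table)
                entry.update(statistic=stat, p=p, test="chi2")
        except ValueError:
            entry["test"] = "degenerate"
        out[var] = entry
    for var in CONTINUOUS_VARIABLES:
        db = describe(benign[var].to_numpy())
        dm = describe(malignant[var].to_numpy())
        stat, p = welch_t(db["mean"], db["sd"], len(benign),
                          dm["mean"], dm["sd"], len(malignant))
        out[var] = {"benign": db, "malignant": dm,
                    "statistic": stat, "p": p, "test": "welch_t"}
    return out
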