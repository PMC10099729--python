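"""Gene-level context: tissue specificity (tau), feature groups, and
rank-sum comparison of event entropy distributions between groups.

tau = sum_i (1 - x_i / max_j x_j) / (n - 1) over n tissues: 0 for perfectly
uniform expression, 1 for expression confined to a single tissue. Genes are
split into binary groups at the standard printed cutpoints (tau 0.3,
expression TPM 50, dN/dS 0.0993, PPI-degree median, housekeeping flag) and
the splicing entropies of events hosted by each group are compared with a
two-sided Wilcoxon rank-sum (Mann-Whitney U) test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneAnnotation",
    "GroupComparison",
    "tau",
    "group_genes",
    "compare_entropy_groups",
    "DEFAULT_CUTPOINTS",
]

DEFAULT_CUTPOINTS = {
    "tau": 0.3,  # High specificity: tau >= 0.3
    "expression": 50.0,  # High expression: TPM >= 50
    "dnds": 0.0993,  # fast-evolving: dN/dS > 0.0993
}


@dataclass
class GeneAnnotation:
    gene_id: str
    housekeeping: bool
    age_class: str  # "young" | "old"
    dnds: float
    ppi_degree: int
    expression: tuple[float, ...]  # per-tissue TPM

    def __post_init__(self) -> None:
        if self.dnds < 0 or self.ppi_degree < 0:
            raise ValueError(f"{self.gene_id}: negative dN/dS or PPI degree")


@dataclass
class GroupComparison:
    statistic: float  # Mann-Whitney U of group A
    pvalue: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int


def tau(expression: Sequence[float], n_tissues: int | None = None) -> float:
    """Tissue-specificity index in [0, 1]; nan for an all-zero vector."""
    x = np.asarray(expression, dtype=float)
    if n_tissues is not None and len(x) != n_tissues:
        raise ValueError(f"expected {n_tissues} tissues, got {len(x)}")
    if len(x) < 2:
        raise ValueError("tau requires at least two tissues")
    if np.any(x < 0):
        raise ValueError("expression must be non-negative")
    mx = x.max()
    if mx == 0:
        return math.nan
    return float((1.0 - x / mx).sum() / (len(x) - 1))


def group_genes(
    annotations: pd.DataFrame,
    feature: str,
    cutpoints: dict[str, float] | None = None,
) -> pd.Series:
    """Binary {'Low','High'} labels per gene for one feature.

    Features: 'tau' (specificity, High >= 0.3), 'expression' (High TPM >=
    50), 'dnds' (High = fast-evolving, > 0.0993), 'ppi_degree' (median
    split), 'housekeeping' (High = housekeeping), 'age' (High = old).
    Missing values are left unlabeled (NaN).
    """
    cp = dict(DEFAULT_CUTPOINTS)
    if cutpoints:
        cp.update(cutpoints)

    if feature == "housekeeping":
        vals = annotations["housekeeping"]
        lab = vals.map(lambda v: "High" if bool(v) else "Low", na_action="ignore")
    elif feature == "age":
        vals = annotations["age_class"]
        lab = vals.map(
            lambda v: "High" if v == "old" else "Low", na_action="ignore"
        )
    elif feature in ("tau", "expression", "dnds"):
        vals = pd.to_numeric(annotations[feature], errors="coerce")
        if feature == "dnds":
            lab = (vals > cp["dnds"]).where(vals.notna()).map(
                {True: "High", False: "Low"}, na_action="ignore"
            )
        else:
            lab = (vals >= cp[feature]).where(vals.notna()).map(
                {True: "High", False: "Low"}, na_action="ignore"
            )
    elif feature == "ppi_degree":
        vals = pd.to_numeric(annotations["ppi_degree"], errors="coerce")
        med = vals.median()
        lab = (vals >= med).where(vals.notna()).map(
            {True: "High", False: "Low"}, na_action="ignore"
        )
    else:
        raise KeyError(f"unknown feature {feature!r}")
    lab.name = feature
    return lab


def compare_entropy_groups(
    entropies_a: Sequence[float], entropies_b: Sequence[float]
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum comparison of two entropy samples.

    Mid-ranks handle ties. For small samples (combined n <= 12) the p-value
    is computed by exhaustive permutation of group assignments; larger
    samples use the tie-corrected normal approximation. A group smaller
    than two leaves the p-value undefined but still reports medians.
    """
    a = np.asarray(list(entropies_a), dtype=float)
    b = np.asarray(list(entropies_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    med_a, med_b = float(np.median(a)), float(np.median(b))
    if a.size < 2 or b.size < 2:
        u = float(stats.mannwhitneyu(a, b, alternative="two-sided").statistic)
        return GroupComparison(u, math.nan, med_a, med_b, a.size, b.size)
    if a.size + b.size <= 12:
        method: object = stats.PermutationMethod(n_resamples=1_000_000)
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        float(res.statistic), float(res.pvalue), med_a, med_b, a.size, b.size
    )
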