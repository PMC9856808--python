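"""Per-entity correlation panels, direction splitting of signatures, and
two-group expression tables.

Correlations are computed on the raw abundance scale by default (a log2p1
switch is provided); two-group comparisons default to Kruskal–Wallis, with
Mann–Whitney and Welch's t available. Benjamini–Hochberg adjustment is
applied jointly across all rows of a panel.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from tmesig.consensus import ConsensusSignature
from tmesig.dichotomize import DichotomyLabels
from tmesig.io import ExpressionMatrix, SampleAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationRow",
    "GroupStatRow",
    "pearson_r",
    "spearman_r",
    "entity_panel",
    "bh_adjust",
    "group_mean_test",
    "split_signature_by_direction",
]


@dataclass(frozen=True)
class CorrelationRow:
    entity: str
    gene: str
    r: float
    p: float
    q: float
    n: int
    flag: str = ""  # "" | "too_few_samples" | "zero_variance"


@dataclass(frozen=True)
class GroupStatRow:
    feature: str
    mean_high: float
    sd_high: float
    mean_low: float
    sd_low: float
    p: float
    flag: str = ""


def _check_pair(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-test p (n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_pair(x, y)
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def spearman_r(x, y) -> tuple[float, float]:
    """Pearson correlation of mid-ranks (average ranks on ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_pair(x, y)
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def entity_panel(
    expr: ExpressionMatrix,
    ann: SampleAnnotation,
    target: str,
    panel: list[str],
    method: str = "pearson",
    log2p1: bool = False,
) -> list[CorrelationRow]:
    """One correlation row per (entity, panel gene) against the target gene,
    BH-adjusted across the whole panel, sorted by entity then gene.

    Entities with fewer than 3 samples get a flagged row without a p-value.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    corr = pearson_r if method == "pearson" else spearman_r
    for g in [target, *panel]:
        expr.gene_index(g)  # raises KeyError if absent

    def prep(gene: str, samples: list[str]) -> np.ndarray:
        v = expr.gene_values(gene).loc[samples].to_numpy()
        return np.log2(v + 1.0) if log2p1 else v

    raw_rows: list[dict] = []
    for entity in sorted(ann.entity_names):
        samples = ann.samples_of(entity)
        tx = prep(target, samples)
        for gene in sorted(panel):
            row = {"entity": entity, "gene": gene, "n": len(samples)}
            if len(samples) < 3:
                row.update(r=math.nan, p=math.nan, flag="too_few_samples")
            else:
                gy = prep(gene, samples)
                if np.std(tx) == 0 or np.std(gy) == 0:
                    row.update(r=math.nan, p=math.nan, flag="zero_variance")
                else:
                    r, p = corr(tx, gy)
                    row.update(r=r, p=max(p, np.nextafter(0, 1)), flag="")
            raw_rows.append(row)

    testable = [i for i, row in enumerate(raw_rows) if not row["flag"]]
    qvals = bh_adjust([raw_rows[i]["p"] for i in testable]) if testable else []
    qmap = dict(zip(testable, qvals))
    return [
        CorrelationRow(
            entity=row["entity"], gene=row["gene"], r=row["r"], p=row["p"],
            q=float(qmap.get(i, math.nan)), n=row["n"], flag=row["flag"],
        )
        for i, row in enumerate(raw_rows)
    ]


_TESTS = {
    "mannwhitney": lambda a, b: stats.mannwhitneyu(a, b, alternative="two-sided").pvalue,
    "welch": lambda a, b: stats.ttest_ind(a, b, equal_var=False).pvalue,
    "kruskal": lambda a, b: stats.kruskal(a, b).pvalue,
}


def group_mean_test(
    feature_values: pd.Series,
    labels: DichotomyLabels,
    test: str = "kruskal",
    feature_name: str | None = None,
) -> GroupStatRow:
    """Raw-scale group means/sds of high vs. rest plus a two-sided p-value
    from the selected test.
    """
    if test not in _TESTS:
        raise ValueError(f"unknown test {test!r}; choose from {sorted(_TESTS)}")
    vals = feature_values.loc[list(labels.sample_ids)].to_numpy(dtype=float)
    mask = labels.as_binary().astype(bool)
    a, b = vals[mask], vals[~mask]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    flag = ""
    if len(a) < 2 or len(b) < 2:
        flag = "group_too_small"
    if np.all(vals == vals[0]):
        p = 1.0  # identical constant groups: no evidence either way
    else:
        try:
            p = float(_TESTS[test](a, b))
        except ValueError:  # e.g. kruskal on all-identical values
            p = 1.0
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return GroupStatRow(
        feature=feature_name or str(feature_values.name or "feature"),
        mean_high=float(a.mean()),
        sd_high=float(a.std(ddof=1)) if len(a) > 1 else math.nan,
        mean_low=float(b.mean()),
        sd_low=float(b.std(ddof=1)) if len(b) > 1 else math.nan,
        p=p,
        flag=flag,
    )


def split_signature_by_direction(
    signature: ConsensusSignature,
    expr: ExpressionMatrix,
    labels: DichotomyLabels,
    alpha: float = 0.05,
    test: str = "kruskal",
) -> tuple[list[str], list[str]]:
    """Partition signature genes into (up, down).

    A gene is "up" iff mean(high) > mean(rest) strictly AND the two-group
    test p-value is below ``alpha``; everything else is "down". The two
    lists always cover the signature exactly.
    """
    up: list[str] = []
    down: list[str] = []
    for gene in signature.gene_ids:
        row = group_mean_test(expr.gene_values(gene), labels, test=test)
        if row.mean_high > row.mean_low and row.p < alpha:
            up.append(gene)
        else:
            down.append(gene)
    return up, down
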