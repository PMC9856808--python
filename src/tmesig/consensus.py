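"""Consensus signature extraction by repeated random-forest importance
aggregation.

Many classifiers are trained on independent 50/50 train/evaluation splits to
discriminate target-high from rest samples; each model contributes its top-k
features by impurity importance, and genes are ranked by how often they occur
across the per-model top-k lists. A leave-target-out rerun (the target gene
removed from the feature space) quantifies how much of the signature depends
on the label-defining gene itself.

Features are raw, unscaled expression values. Per-model seeds are derived as
``seed + model_index`` so the whole procedure is reproducible and each model
has an independent stream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import train_test_split

from tmesig.dichotomize import DichotomyLabels, HIGH, REST
from tmesig.io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RFConfig",
    "ModelRun",
    "SignatureEntry",
    "ConsensusSignature",
    "CALIBRATION_RF",
    "train_single_model",
    "run_consensus",
    "rank_by_occurrence",
    "leave_target_out_overlap",
]


@dataclass(frozen=True)
class RFConfig:
    n_models: int = 100
    n_trees: int = 1000
    train_fraction: float = 0.5
    top_k: int = 200
    exclude_target: bool = False
    stratify: bool = True
    importance: str = "impurity"  # or "permutation"
    seed: int = 0

    def validate(self) -> None:
        if self.n_models < 1 or self.n_trees < 1 or self.top_k < 1:
            raise ValueError("n_models, n_trees and top_k must be positive")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.importance not in ("impurity", "permutation"):
            raise ValueError(f"unknown importance mode {self.importance!r}")


#: Desk-scale RF config paired with simulate.CALIBRATION_CONFIG: fewer,
#: smaller forests than the cohort-scale defaults (100 x 1000 trees) so the
#: full pipeline plus the leave-target-out rerun stays within minutes on one
#: CPU. Occurrence ranking is insensitive to the reduction at this scale.
CALIBRATION_RF = RFConfig(n_models=100, n_trees=100, top_k=200, seed=0)


@dataclass(frozen=True)
class ModelRun:
    model_index: int
    eval_sample_ids: tuple[str, ...]
    eval_predictions: tuple[str, ...]  # HIGH | REST per eval sample
    eval_accuracy: float
    topk_genes: tuple[tuple[str, float], ...]  # (gene_id, importance), importance desc


@dataclass(frozen=True)
class SignatureEntry:
    gene_id: str
    occurrence: int
    mean_importance: float


@dataclass(frozen=True)
class ConsensusSignature:
    entries: tuple[SignatureEntry, ...]
    accuracy_mean: float
    accuracy_sd: float
    accuracy_min: float
    accuracy_max: float
    config: RFConfig = field(repr=False)

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(e.gene_id for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def _feature_importances(
    clf: RandomForestClassifier,
    X_train: np.ndarray,
    y_train: np.ndarray,
    mode: str,
    seed: int,
) -> np.ndarray:
    if mode == "impurity":
        return clf.feature_importances_
    res = permutation_importance(
        clf, X_train, y_train, n_repeats=5, random_state=seed, n_jobs=1
    )
    return res.importances_mean


def train_single_model(
    expr: ExpressionMatrix,
    labels: DichotomyLabels,
    config: RFConfig,
    model_seed: int,
) -> ModelRun:
    """Fit one random forest on a train/evaluation split and report its
    evaluation accuracy and importance-ranked top-k gene list.

    With ``stratify=False`` a split missing a class in the training half is
    re-drawn (up to 100 attempts) with an incremented sub-seed.
    """
    config.validate()
    if tuple(labels.sample_ids) != tuple(expr.sample_ids):
        labels = DichotomyLabels(labels.labels.loc[list(expr.sample_ids)])
    y = labels.as_binary()
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 samples per class")
    X = expr.values.T  # samples x genes
    idx = np.arange(len(y))

    for attempt in range(100):
        train_idx, eval_idx = train_test_split(
            idx,
            train_size=config.train_fraction,
            random_state=model_seed + attempt,
            shuffle=True,
            stratify=y if config.stratify else None,
        )
        if len(np.unique(y[train_idx])) == 2:
            break
        logger.debug("model seed %d: one-class training half, re-drawing split", model_seed)
    else:
        raise ValueError("could not draw a training half containing both classes")

    clf = RandomForestClassifier(
        n_estimators=config.n_trees, random_state=model_seed, n_jobs=1
    )
    clf.fit(X[train_idx], y[train_idx])
    pred = clf.predict(X[eval_idx])
    acc = float((pred == y[eval_idx]).mean())

    imp = _feature_importances(clf, X[train_idx], y[train_idx], config.importance, model_seed)
    k = min(config.top_k, len(expr.gene_ids))
    # sort by importance desc, ties broken by gene id asc for determinism
    order = sorted(range(len(imp)), key=lambda i: (-imp[i], expr.gene_ids[i]))[:k]
    topk = tuple((expr.gene_ids[i], float(imp[i])) for i in order)

    return ModelRun(
        model_index=model_seed - config.seed,
        eval_sample_ids=tuple(expr.sample_ids[i] for i in eval_idx),
        eval_predictions=tuple(HIGH if p == 1 else REST for p in pred),
        eval_accuracy=acc,
        topk_genes=topk,
    )


def rank_by_occurrence(
    topk_lists: list[tuple[tuple[str, float], ...]],
    n_models: int,
    top_k: int,
) -> tuple[SignatureEntry, ...]:
    """Aggregate per-model top-k lists into occurrence-ranked entries.

    Genes are sorted by (occurrence desc, mean importance desc, gene id asc)
    and the ranking is truncated to ``top_k``.
    """
    if not topk_lists:
        raise ValueError("no top-k lists to aggregate")
    lengths = {len(lst) for lst in topk_lists}
    if len(lengths) != 1:
        raise ValueError(f"top-k lists have unequal lengths: {sorted(lengths)}")
    counts: dict[str, int] = {}
    imp_sums: dict[str, float] = {}
    for lst in topk_lists:
        for gene, imp in lst:
            counts[gene] = counts.get(gene, 0) + 1
            imp_sums[gene] = imp_sums.get(gene, 0.0) + imp
    entries = [
        SignatureEntry(g, c, imp_sums[g] / c) for g, c in counts.items()
    ]
    entries.sort(key=lambda e: (-e.occurrence, -e.mean_importance, e.gene_id))
    return tuple(entries[:top_k])


def run_consensus(
    expr: ExpressionMatrix,
    labels: DichotomyLabels,
    config: RFConfig,
    target_gene: str | None = None,
) -> tuple[ConsensusSignature, list[ModelRun]]:
    """Train ``n_models`` forests on independent splits and aggregate their
    top-k importance lists into a :class:`ConsensusSignature`.

    If ``config.exclude_target`` is set, ``target_gene`` must be given and
    its row is removed from the feature matrix before training.
    """
    config.validate()
    if config.exclude_target:
        if target_gene is None:
            raise ValueError("exclude_target requires target_gene")
        if target_gene in expr.gene_ids:
            expr = expr.drop_gene(target_gene)
    runs: list[ModelRun] = []
    for m in range(config.n_models):
        run = train_single_model(expr, labels, config, model_seed=config.seed + m)
        runs.append(run)
        logger.info(
            "model %d/%d: eval accuracy %.4f", m + 1, config.n_models, run.eval_accuracy
        )
    entries = rank_by_occurrence([r.topk_genes for r in runs], config.n_models, config.top_k)
    accs = np.array([r.eval_accuracy for r in runs])
    sig = ConsensusSignature(
        entries=entries,
        accuracy_mean=float(accs.mean()),
        accuracy_sd=float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
        accuracy_min=float(accs.min()),
        accuracy_max=float(accs.max()),
        config=config,
    )
    return sig, runs


def leave_target_out_overlap(
    expr: ExpressionMatrix,
    labels: DichotomyLabels,
    config: RFConfig,
    target_gene: str,
    original: ConsensusSignature,
) -> tuple[ConsensusSignature, float]:
    """Re-run the consensus without the target gene in the feature space and
    report the fraction of the original signature retained.
    """
    rerun_config = replace(config, exclude_target=True)
    rerun_sig, _ = run_consensus(expr, labels, rerun_config, target_gene=target_gene)
    overlap = len(set(original.gene_ids) & set(rerun_sig.gene_ids)) / config.top_k
    return rerun_sig, overlap
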