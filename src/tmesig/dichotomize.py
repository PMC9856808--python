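"""Target-high vs. rest dichotomization by per-entity expression z-score.

The default mirrors the conventional cbioportal mRNA query: z computed on
log2(x+1)-transformed values within each entity, against all samples of
that entity, with the sample (n−1) standard deviation, and an inclusive
threshold of 1.5. Every alternative is exposed in :class:`ZScoreConfig`.
Entities with zero spread (or a single sample) yield z = 0 — no
overexpression signal is definable there — and a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from tmesig.io import ExpressionMatrix, SampleAnnotation

logger = logging.getLogger(__name__)

__all__ = ["ZScoreConfig", "DichotomyLabels", "compute_entity_z", "select_high_expressers"]

HIGH = "high"
REST = "rest"


@dataclass(frozen=True)
class ZScoreConfig:
    threshold: float = 1.5
    transform: str = "log2p1"  # or "none"
    per_entity: bool = True
    sd_mode: str = "sample"  # or "population"

    def validate(self) -> None:
        if np.isnan(self.threshold):  # +/-inf allowed: select-none / select-all
            raise ValueError("threshold must not be NaN")
        if self.transform not in ("log2p1", "none"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.sd_mode not in ("sample", "population"):
            raise ValueError(f"unknown sd_mode {self.sd_mode!r}")


@dataclass(frozen=True)
class DichotomyLabels:
    """Per-sample high/rest assignment for a target gene."""

    labels: pd.Series  # sample_id -> HIGH | REST

    def __post_init__(self):
        bad = set(self.labels.unique()) - {HIGH, REST}
        if bad:
            raise ValueError(f"invalid label(s): {sorted(bad)}")

    @property
    def n_total(self) -> int:
        return int(len(self.labels))

    @property
    def n_high(self) -> int:
        return int((self.labels == HIGH).sum())

    @property
    def n_rest(self) -> int:
        return self.n_total - self.n_high

    @property
    def fraction_high(self) -> float:
        return self.n_high / self.n_total

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.labels.index)

    def as_binary(self) -> np.ndarray:
        """1 for high, 0 for rest, in sample order."""
        return (self.labels == HIGH).to_numpy(dtype=int)

    def is_high(self, sample_id: str) -> bool:
        return self.labels.loc[sample_id] == HIGH


def _transform(x: np.ndarray, transform: str) -> np.ndarray:
    if transform == "log2p1":
        return np.log2(x + 1.0)
    return x


def compute_entity_z(
    expr: ExpressionMatrix,
    ann: SampleAnnotation,
    gene: str,
    config: ZScoreConfig = ZScoreConfig(),
) -> pd.Series:
    """Per-sample z-score of one gene, standardized within each entity
    (or across the whole cohort when ``per_entity`` is false).
    """
    config.validate()
    x = expr.gene_values(gene)  # KeyError if absent
    missing = [s for s in expr.sample_ids if s not in set(ann.sample_ids)]
    if missing:
        raise ValueError(f"sample(s) without annotation: {', '.join(missing[:5])}")
    t = pd.Series(_transform(x.to_numpy(), config.transform), index=x.index)
    ddof = 1 if config.sd_mode == "sample" else 0
    z = pd.Series(0.0, index=t.index, name=f"z_{gene}")
    groups = (
        ann.entities.loc[t.index].groupby(ann.entities.loc[t.index]).groups
        if config.per_entity
        else {"__all__": t.index}
    )
    for entity, samples in groups.items():
        vals = t.loc[samples]
        if len(vals) < 2:
            logger.warning("entity %s has a single sample; z set to 0", entity)
            continue
        sd = float(vals.std(ddof=ddof))
        if sd == 0.0:
            logger.warning("gene %s constant within entity %s; z set to 0", gene, entity)
            continue
        z.loc[samples] = (vals - vals.mean()) / sd
    return z


def select_high_expressers(z: pd.Series, config: ZScoreConfig = ZScoreConfig()) -> DichotomyLabels:
    """Label a sample ``high`` iff its z-score meets the threshold
    (inclusive: z >= threshold).
    """
    config.validate()
    arr = z.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("z contains non-finite values")
    labels = pd.Series(np.where(arr >= config.threshold, HIGH, REST), index=z.index)
    labels.index.name = "sample_id"
    return DichotomyLabels(labels)
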