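"""Hypergeometric over-representation analysis of gene lists against GMT
collections, inside a user-defined universe (by default: all measured genes).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from tmesig.correlate import bh_adjust
from tmesig.io import GeneSetCollection

__all__ = ["EnrichmentRow", "hypergeom_pvalue", "ora_table"]


@dataclass(frozen=True)
class EnrichmentRow:
    set_name: str
    k: int  # overlap
    K: int  # set size in universe
    n: int  # query size in universe
    N: int  # universe size
    p: float
    q: float


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``k`` successes in a query of size ``n``, drawn without replacement from
    a universe of ``N`` genes of which ``K`` belong to the set.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"invalid hypergeometric bounds: k={k}, K={K}, n={n}, N={N}")
    # survival function at k-1 gives P(X >= k); scipy computes it stably
    return float(min(1.0, stats.hypergeom.sf(k - 1, N, K, n)))


def ora_table(
    query: list[str],
    sets: GeneSetCollection,
    universe: list[str],
    include_empty: bool = False,
) -> list[EnrichmentRow]:
    """One enrichment row per gene set, BH-adjusted across reported rows,
    sorted by ascending p (ties by set name).

    Query and sets are intersected with the universe first; sets with zero
    overlap are reported only when ``include_empty`` is set (their rows are
    excluded from the BH family either way).
    """
    uni = set(universe)
    if not uni:
        raise ValueError("universe is empty")
    q_genes = set(query) & uni
    if not q_genes:
        raise ValueError("query has no genes inside the universe")
    N, n = len(uni), len(q_genes)

    hits: list[tuple[str, int, int, float]] = []
    empties: list[tuple[str, int]] = []
    for name, (_desc, members) in sets:
        K = len(members & uni)
        k = len(members & q_genes)
        if k >= 1:
            hits.append((name, k, K, hypergeom_pvalue(k, K, n, N)))
        else:
            empties.append((name, K))

    qvals = bh_adjust([h[3] for h in hits]) if hits else []
    rows = [
        EnrichmentRow(set_name=name, k=k, K=K, n=n, N=N, p=p, q=float(qv))
        for (name, k, K, p), qv in zip(hits, qvals)
    ]
    rows.sort(key=lambda r: (r.p, r.set_name))
    if include_empty:
        rows.extend(
            EnrichmentRow(set_name=name, k=0, K=K, n=n, N=N, p=1.0, q=float("nan"))
            for name, K in sorted(empties)
        )
    return rows
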