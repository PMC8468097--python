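"""Pathway enrichment of treatment-specific entity sets.

Treatment-specific enzymes, environmental resources and expansion-produced
compounds are mapped to pathways and tested for over-representation with a
one-sided Fisher exact test (hypergeometric upper tail) against a universe
of same-class entities, followed by Benjamini-Hochberg FDR control over the
tested pathways.  A pathway enters the test set only when its universe size
K satisfies the user's min/max bounds, it is not explicitly excluded, and at
least one query entity maps to it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ContractError

__all__ = [
    "EnrichmentQuery",
    "EnrichmentRow",
    "fisher_pathway_enrichment",
    "bh_fdr",
    "pathway_table",
    "rows_to_frame",
]

ENTITY_CLASSES = ("enzyme", "resource", "compound")


@dataclass
class EnrichmentQuery:
    """A treatment-specific entity set and the universe it was drawn from."""

    entities: set[str]
    entity_class: str
    universe: set[str]
    scope_label: str = ""

    def __post_init__(self) -> None:
        if self.entity_class not in ENTITY_CLASSES:
            raise ContractError(
                f"entity_class must be one of {ENTITY_CLASSES}, got {self.entity_class!r}"
            )
        if not self.universe:
            raise ContractError("universe must be non-empty")
        stray = self.entities - self.universe
        if stray:
            raise ContractError(
                f"query entities outside universe: {sorted(stray)[:5]}"
            )


@dataclass
class EnrichmentRow:
    """One tested pathway: 2x2 table counts, Fisher p, BH q, enriched flag.

    k = |query ∩ pathway|, K = |pathway ∩ universe|, n = |query|,
    N = |universe|.
    """

    pathway: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    q_value: float
    enriched: bool


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    ps = list(p_values)
    if not ps:
        return []
    if any(not 0.0 <= p <= 1.0 for p in ps):
        raise ContractError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(ps, method="fdr_bh")
    return [float(x) for x in q]


def _upper_tail_p(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n): one-sided over-representation."""
    return float(hypergeom.sf(k - 1, N, K, n))


def fisher_pathway_enrichment(
    query: EnrichmentQuery,
    pathway_map: Mapping[str, Iterable[str]],
    min_size: int = 1,
    max_size: int = 10_000,
    excluded: Iterable[str] = (),
    alpha: float = 0.05,
) -> list[EnrichmentRow]:
    """Test each eligible pathway for over-representation in the query set.

    Returns rows sorted by (q, p, pathway name).  ``enriched`` is True when
    the BH-adjusted q-value is at or below ``alpha``.
    """
    if min_size < 1 or min_size > max_size:
        raise ContractError(f"need 1 <= min_size <= max_size, got ({min_size}, {max_size})")
    if not 0.0 < alpha <= 1.0:
        raise ContractError(f"alpha must lie in (0, 1], got {alpha}")
    excluded_set = set(excluded)

    # pathway -> members, restricted to the universe
    members: dict[str, set[str]] = {}
    for entity in query.universe:
        for pw in pathway_map.get(entity, ()):
            members.setdefault(pw, set()).add(entity)

    n = len(query.entities)
    N = len(query.universe)
    tested: list[tuple[str, int, int, float]] = []
    for pw in sorted(members):
        if pw in excluded_set:
            continue
        K = len(members[pw])
        if not min_size <= K <= max_size:
            continue
        k = len(members[pw] & query.entities)
        if k < 1:
            continue
        tested.append((pw, k, K, _upper_tail_p(k, K, n, N)))

    if not tested:
        return []
    qvals = bh_fdr([t[3] for t in tested])
    rows = [
        EnrichmentRow(
            pathway=pw, k=k, K=K, n=n, N=N,
            p_value=p, q_value=q, enriched=q <= alpha,
        )
        for (pw, k, K, p), q in zip(tested, qvals)
    ]
    rows.sort(key=lambda r: (r.q_value, r.p_value, r.pathway))
    return rows


def pathway_table(
    entities: Iterable[str],
    pathway_map: Mapping[str, Iterable[str]],
    entity_class: str,
    scope_label: str = "",
) -> pd.DataFrame:
    """One row per (entity, pathway) pair; unannotated entities get a single
    row with pathway = "unannotated"."""
    rows = []
    for entity in sorted(set(entities)):
        pathways = sorted(set(pathway_map.get(entity, ())))
        if pathways:
            for pw in pathways:
                rows.append((entity, pw))
        else:
            rows.append((entity, "unannotated"))
    frame = pd.DataFrame(rows, columns=["entity", "pathway"])
    frame["entity_class"] = entity_class
    frame["scope"] = scope_label
    return frame


def rows_to_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    """Enrichment rows as a DataFrame with the standard export columns."""
    return pd.DataFrame(
        [
            {
                "pathway": r.pathway,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "enriched": r.enriched,
            }
            for r in rows
        ],
        columns=["pathway", "k", "K", "n", "N", "p_value", "q_value", "enriched"],
    )
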