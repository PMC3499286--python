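"""Gene assignment from similarity hits, homolog-group rollups, and GO
classification with redundant counting.

A hit is positive only when its score is strictly greater than the
threshold (default 50).  GO counting is redundant by design: a query
contributes once to every term its gene maps to within a namespace, and
queries whose gene has no terms are omitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "GeneAssignment",
    "GO_NAMESPACES",
    "assign_genes",
    "count_unique_genes",
    "go_classify",
    "fold_others",
]

GO_NAMESPACES = ("molecular_function", "cellular_component", "biological_process")


@dataclass
class GeneAssignment:
    query_id: str
    species: str
    gene_id: str
    best_score: float
    homologene_id: str | None = None


def assign_genes(hits: pd.DataFrame, min_score: float = 50.0) -> list[GeneAssignment]:
    """Per (query, species), keep the highest-scoring hit with score
    strictly above ``min_score``; ties break by gene_id order.

    ``hits`` columns: query_id, species, gene_id, score.
    """
    out: dict[tuple[str, str], GeneAssignment] = {}
    for row in hits.itertuples(index=False):
        if row.score <= min_score:
            continue
        key = (row.query_id, row.species)
        cur = out.get(key)
        if cur is None or (row.score, _rev(row.gene_id)) > (cur.best_score, _rev(cur.gene_id)):
            out[key] = GeneAssignment(row.query_id, row.species, row.gene_id, float(row.score))
    return list(out.values())


class _rev(str):
    """Inverted ordering: used so score ties prefer the smaller gene_id."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


def count_unique_genes(
    assignments: list[GeneAssignment],
    homolog_map: dict[str, str],
) -> dict[str, int]:
    """Unique genes, genes lacking a homolog-group id, and unique groups
    (a group counts once however many genes map to it)."""
    genes = {a.gene_id for a in assignments}
    groups = {homolog_map[g] for g in genes if g in homolog_map}
    without = sum(1 for g in genes if g not in homolog_map)
    return {
        "n_unique_gene_ids": len(genes),
        "n_without_homologene": without,
        "n_unique_homologene": len(groups),
    }


def go_classify(
    assignments: list[GeneAssignment],
    go_map: pd.DataFrame,
) -> dict[str, dict[str, int]]:
    """Per-namespace term counts with redundant counting.

    ``go_map`` columns: gene_id, namespace, term_id (term_name optional).
    Each query adds +1 to every term its gene maps to in a namespace;
    queries with no term are omitted.  Unknown namespaces are an error.
    """
    bad = set(go_map["namespace"]) - set(GO_NAMESPACES)
    if bad:
        raise ValueError(f"unknown GO namespaces: {sorted(bad)}")
    gene_terms: dict[str, dict[str, set[str]]] = {}
    for row in go_map.itertuples(index=False):
        gene_terms.setdefault(row.gene_id, {}).setdefault(row.namespace, set()).add(row.term_id)
    counts: dict[str, dict[str, int]] = {ns: {} for ns in GO_NAMESPACES}
    for a in assignments:
        for ns, terms in gene_terms.get(a.gene_id, {}).items():
            for t in terms:
                counts[ns][t] = counts[ns].get(t, 0) + 1
    return counts


def fold_others(term_counts: dict[str, int], floor: int = 1000) -> dict[str, int]:
    """Aggregation view: terms counting below ``floor`` fold into 'Others'."""
    out: dict[str, int] = {}
    others = 0
    for term, n in sorted(term_counts.items()):
        if n < floor:
            others += n
        else:
            out[term] = n
    if others:
        out["Others"] = others
    return out
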