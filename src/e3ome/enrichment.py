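"""Phenotype-term enrichment for gene families.

For each family and each ontology term annotating at least ``min_genes`` of
the family's genes, a 2x2 table over a fixed protein-coding gene universe is
tested with a one-sided (enrichment) Fisher exact test. P-values are
adjusted with Benjamini-Hochberg separately within each family, and odds
ratios use the Haldane-Anscombe correction (0.5 added to every cell) so they
stay finite with zero cells.

The exact Fisher p is computed by log-factorial accumulation of the
hypergeometric upper tail, which is stable for the small intersection counts
typical of family-term tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln


class OntologyError(ValueError):
    """The ontology violates DAG requirements (e.g. contains a cycle)."""


@dataclass(frozen=True)
class OntologyTerm:
    id: str
    name: str = ""
    parents: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.id in self.parents:
            raise OntologyError(f"term {self.id} is its own parent")


@dataclass(frozen=True)
class ContingencyTable:
    """Counts a/b/c/d: family-with-term, family-without, non-family-with,
    non-family-without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def family_size(self) -> int:
        return self.a + self.b

    @property
    def term_size(self) -> int:
        return self.a + self.c

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EnrichmentResult:
    family: str
    term: str
    name: str
    table: ContingencyTable
    p: float
    p_adj: float
    odds_ratio: float


@dataclass
class AnnotationMap:
    """term -> gene-set mapping after ancestor propagation, over a universe."""

    term_genes: dict[str, frozenset[str]]
    universe: frozenset[str]

    @property
    def universe_size(self) -> int:
        return len(self.universe)


# --------------------------------------------------------------------------
# Ontology handling


def load_obo(path: str | Path) -> dict[str, OntologyTerm]:
    """Read terms (id, name, is_a parents) from an OBO file."""
    import obonet

    graph = obonet.read_obo(path)
    terms = {}
    for node, data in graph.nodes(data=True):
        parents = frozenset(
            v for _, v, k in graph.out_edges(node, keys=True) if k == "is_a"
        )
        terms[node] = OntologyTerm(node, data.get("name", ""), parents)
    return terms


def propagate_annotations(
    terms: Mapping[str, OntologyTerm],
    direct: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> AnnotationMap:
    """Propagate direct annotations to all ancestor terms (true-path rule).

    Each term's gene set becomes the union of its own direct annotations and
    those of all its descendants; genes outside the universe are dropped.
    """
    universe_set = frozenset(universe)
    g = nx.DiGraph()
    g.add_nodes_from(terms)
    for t in terms.values():
        for p in t.parents:
            g.add_edge(t.id, p)  # child -> parent
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise OntologyError(f"ontology contains a cycle: {cycle}")

    propagated: dict[str, set[str]] = {t: set() for t in terms}
    for term, genes in direct.items():
        if term in propagated:
            propagated[term].update(set(genes) & universe_set)
    # children before parents: reversed topological order of child->parent edges
    for node in nx.topological_sort(g):
        for parent in g.successors(node):
            propagated[parent].update(propagated[node])
    return AnnotationMap(
        {t: frozenset(gs) for t, gs in propagated.items()}, universe_set
    )


def load_annotations(path: str | Path, sep: str = "\t") -> dict[str, set[str]]:
    """Gene-term annotation TSV with columns ``gene`` and ``term``."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    if not {"gene", "term"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'gene' and 'term'")
    out: dict[str, set[str]] = {}
    for gene, term in zip(df["gene"], df["term"]):
        out.setdefault(term, set()).add(str(gene).strip().upper())
    return out


# --------------------------------------------------------------------------
# Statistics


def build_table(
    family_genes: Iterable[str],
    term_genes: Iterable[str],
    universe_size: int,
) -> ContingencyTable:
    """2x2 table from family and term gene sets over a universe of given size."""
    fam = set(family_genes)
    term = set(term_genes)
    a = len(fam & term)
    b = len(fam) - a
    c = len(term) - a
    d = universe_size - a - b - c
    if d < 0:
        raise ValueError(
            f"universe_size {universe_size} smaller than |family ∪ term| "
            f"{a + b + c}"
        )
    return ContingencyTable(a, b, c, d)


def fisher_one_sided(table: ContingencyTable) -> float:
    """Exact upper-tail (enrichment) Fisher p for a 2x2 table.

    Sums hypergeometric probabilities P(X = a') for a' >= a with the table's
    margins fixed, accumulating in log space via log-factorials.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    m = a + b        # family size
    k = a + c        # term size
    n = a + b + c + d
    a_max = min(m, k)

    def log_pmf(x: int) -> float:
        # log C(m, x) + log C(n - m, k - x) - log C(n, k)
        return (
            _log_comb(m, x)
            + _log_comb(n - m, k - x)
            - _log_comb(n, k)
        )

    logs = [log_pmf(x) for x in range(a, a_max + 1)]
    if not logs:
        return 1.0
    peak = max(logs)
    p = float(np.exp(peak) * sum(np.exp(l - peak) for l in logs))
    return min(p, 1.0)


def _log_comb(n: int, k: int) -> float:
    if k < 0 or k > n:
        return float("-inf")
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Sort ascending, compute p(i)*m/i, enforce monotonicity by a running
    minimum from the largest rank, cap at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out.tolist()


def haldane_anscombe_or(table: ContingencyTable) -> float:
    """Odds ratio with a 0.5 pseudocount in every cell; finite for zero cells."""
    return ((table.a + 0.5) * (table.d + 0.5)) / (
        (table.b + 0.5) * (table.c + 0.5)
    )


def enrich_family(
    family: str,
    family_genes: Iterable[str],
    annotations: AnnotationMap,
    min_genes: int = 3,
    term_names: Mapping[str, str] | None = None,
) -> list[EnrichmentResult]:
    """Enrichment results for one family over all sufficiently-annotated terms.

    Terms annotating fewer than ``min_genes`` family members are not tested.
    BH adjustment runs across exactly the tested terms of this family.
    """
    fam = set(family_genes)
    if not fam:
        raise ValueError("family gene set is empty")
    fam &= annotations.universe
    term_names = term_names or {}

    tested: list[tuple[str, ContingencyTable]] = []
    for term in sorted(annotations.term_genes):
        genes = annotations.term_genes[term]
        if len(fam & genes) >= min_genes:
            tested.append(
                (term, build_table(fam, genes, annotations.universe_size))
            )
    if not tested:
        return []
    pvals = [fisher_one_sided(t) for _, t in tested]
    padj = bh_adjust(pvals)
    return [
        EnrichmentResult(
            family=family,
            term=term,
            name=term_names.get(term, ""),
            table=tab,
            p=p,
            p_adj=pa,
            odds_ratio=haldane_anscombe_or(tab),
        )
        for (term, tab), p, pa in zip(tested, pvals, padj)
    ]


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Long-form enrichment table: family term name a b c d p p_adj odds_ratio."""
    return pd.DataFrame(
        [
            {
                "family": r.family,
                "term": r.term,
                "name": r.name,
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "p": r.p,
                "p_adj": r.p_adj,
                "odds_ratio": r.odds_ratio,
            }
            for r in results
        ]
    )
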