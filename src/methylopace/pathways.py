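"""Over-representation analysis and similarity-based term redundancy reduction.

Enrichment per source (GO / KEGG / Reactome) is the one-sided hypergeometric
tail with BH adjustment.  Redundancy among enriched terms is then reduced by
building a similarity network per source — Wang semantic similarity on the
GO DAG, Jaccard index on gene sets otherwise — keeping edges with similarity
strictly greater than a threshold (default 0.5), partitioning each network
into communities by deterministic greedy modularity maximization, and
keeping the smallest-adjusted-p term of each community as its
representative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .enrich import bh_adjust

__all__ = ["TermRecord", "OntologyGraph", "TermGraph", "ora_hypergeometric",
           "enrich_terms", "jaccard_similarity", "wang_similarity",
           "reduce_terms"]

#: Contribution weight of each edge relation in the Wang similarity.
RELATION_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


@dataclass
class TermRecord:
    """One enriched term with its gene set and (adjusted) p-values."""

    term: str
    source: str                     # 'GO', 'KEGG' or 'Reactome'
    genes: frozenset
    raw_p: float
    adj_p: float = float("nan")

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"term {self.term!r} has an empty gene set")


class OntologyGraph:
    """Directed acyclic child -> parent links with per-edge Wang weights."""

    def __init__(self, edges: Iterable[tuple]):
        g = nx.DiGraph()
        for child, parent, relation in edges:
            w = RELATION_WEIGHTS.get(relation)
            if w is None:
                raise ValueError(f"unknown relation {relation!r} "
                                 f"(expected {sorted(RELATION_WEIGHTS)})")
            g.add_edge(child, parent, weight=w)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology edges contain a cycle")
        self.graph = g

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "OntologyGraph":
        return cls(frame[["child", "parent", "relation"]].itertuples(
            index=False, name=None))

    def __contains__(self, term) -> bool:
        return term in self.graph


def ora_hypergeometric(query: Set[str], term_genes: Set[str],
                       universe: Set[str]) -> float:
    """One-sided hypergeometric over-representation p-value.

    p = P(X >= k) with population N = |universe|, K = |term| successes,
    n = |query| draws and k = |query & term| observed.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    query = set(query) & universe
    if not query:
        raise ValueError("empty query gene set (after universe restriction)")
    term_genes = set(term_genes) & universe
    N, K, n = len(universe), len(term_genes), len(query)
    k = len(query & term_genes)
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def enrich_terms(query: Set[str], gene_sets: Mapping[str, Set[str]],
                 universe: Set[str], source: str) -> List[TermRecord]:
    """Hypergeometric ORA of every term in one source, BH-adjusted."""
    records = []
    for term, genes in gene_sets.items():
        genes = set(genes) & set(universe)
        if not genes:
            continue
        p = ora_hypergeometric(query, genes, universe)
        records.append(TermRecord(term, source, frozenset(genes), p))
    adj = bh_adjust([r.raw_p for r in records])
    for r, a in zip(records, adj):
        r.adj_p = float(a)
    return records


def jaccard_similarity(a: Set, b: Set) -> float:
    """|A & B| / |A | B|; two empty sets give 0 (with a warning)."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        import warnings
        warnings.warn("Jaccard of two empty sets defined as 0", UserWarning,
                      stacklevel=2)
        return 0.0
    return len(a & b) / len(union)


def _svalues(term: str, graph: nx.DiGraph) -> Dict[str, float]:
    """Wang S-values of ``term`` and all its ancestors.

    S(term) = 1; for an ancestor t, S(t) is the maximum over incoming
    child edges (c -> t, c in the ancestor closure) of w_edge * S(c).
    """
    closure = {term} | nx.descendants(graph, term)  # ancestors via child->parent
    s = {term: 1.0}
    sub = graph.subgraph(closure)
    for t in nx.topological_sort(sub):
        if t == term:
            continue
        best = 0.0
        for c, _, data in sub.in_edges(t, data=True):
            if c in s:
                best = max(best, data["weight"] * s[c])
        s[t] = best
    return s


def wang_similarity(term_a: str, term_b: str,
                    ontology: OntologyGraph) -> float:
    """Wang semantic similarity of two ontology terms in [0, 1].

    sim = sum over shared ancestors t of (S_A(t) + S_B(t)) divided by
    (SV(A) + SV(B)) where SV(X) sums the S-values over X's closure.
    """
    g = ontology.graph
    for t in (term_a, term_b):
        if t not in g:
            raise KeyError(f"term {t!r} absent from the ontology")
    sa = _svalues(term_a, g)
    sb = _svalues(term_b, g)
    shared = set(sa) & set(sb)
    if not shared:
        return 0.0
    num = sum(sa[t] + sb[t] for t in shared)
    den = sum(sa.values()) + sum(sb.values())
    return float(num / den)


@dataclass
class TermGraph:
    """Similarity network of enriched terms with community representatives."""

    terms: List[TermRecord]
    edges: List[tuple]                       # (term_i, term_j, similarity)
    communities: Dict[str, int]              # term -> community id
    representatives: List[str]

    def to_frame(self) -> pd.DataFrame:
        reps = set(self.representatives)
        rows = [(r.term, r.source, r.raw_p, r.adj_p,
                 self.communities[r.term], r.term in reps)
                for r in self.terms]
        return pd.DataFrame(rows, columns=["term", "source", "raw_p", "adj_p",
                                           "community", "is_representative"])


def _communities(graph: nx.Graph) -> List[Set[str]]:
    """Deterministic greedy-modularity communities; isolates stand alone."""
    isolates = sorted(nx.isolates(graph))
    core = graph.subgraph(n for n in graph if n not in set(isolates))
    comms: List[Set[str]] = []
    if core.number_of_edges() > 0:
        comms = [set(c) for c in
                 nx.community.greedy_modularity_communities(core)]
    else:
        comms = [{n} for n in sorted(core.nodes)]
    comms += [{n} for n in isolates]
    # deterministic ordering by smallest member
    return sorted(comms, key=lambda c: min(c))


def reduce_terms(terms: Sequence[TermRecord], threshold: float = 0.5,
                 ontology: Optional[OntologyGraph] = None,
                 jaccard_fallback: bool = False) -> TermGraph:
    """Collapse redundant enriched terms to community representatives.

    Edges connect same-source term pairs with similarity strictly greater
    than ``threshold`` (Wang on the GO DAG when an ontology is supplied,
    Jaccard on gene sets otherwise).  Within each community the term with
    the smallest adjusted p is kept (ties broken by lexicographic term id);
    the union of representatives across sources is returned.
    """
    terms = sorted(terms, key=lambda r: r.term)
    ids = [r.term for r in terms]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate term ids")
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    by_source: Dict[str, List[TermRecord]] = {}
    for r in terms:
        by_source.setdefault(r.source, []).append(r)
    edges = []
    for source, recs in sorted(by_source.items()):
        use_wang = source == "GO" and not jaccard_fallback
        if use_wang and ontology is None:
            raise ValueError(
                "GO terms supplied without an ontology; pass ontology= or "
                "set jaccard_fallback=True")
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                a, b = recs[i], recs[j]
                if use_wang:
                    sim = wang_similarity(a.term, b.term, ontology)
                else:
                    sim = jaccard_similarity(a.genes, b.genes)
                if sim > threshold:
                    graph.add_edge(a.term, b.term, similarity=sim)
                    edges.append((a.term, b.term, sim))
    by_id = {r.term: r for r in terms}
    communities: Dict[str, int] = {}
    representatives = []
    for cid, comm in enumerate(_communities(graph)):
        for t in comm:
            communities[t] = cid
        rep = min(comm, key=lambda t: (by_id[t].adj_p, t))
        representatives.append(rep)
    return TermGraph(terms=list(terms), edges=edges, communities=communities,
                     representatives=sorted(representatives))
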