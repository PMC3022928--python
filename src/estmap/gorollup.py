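"""GO annotation summarization from protein-similarity HSP tables.

Translated-search HSPs are filtered on length, similarity and e-value;
passing hits transfer the GO terms of their matched proteins to the query
(union with a minimum-support rule); terms are propagated to their is_a
ancestors; and the counts are rolled up at a fixed ontology level, with
configured over-represented classes excluded from the normalization total.
The counting unit is the (query, level-term) pair, deduplicated per query,
so one query can appear under several level-2 terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet
import pandas as pd

from .io import HSP

NAMESPACES = ("molecular_function", "biological_process", "cellular_component")


@dataclass(frozen=True)
class GOAssignment:
    query_id: str
    go_terms: frozenset


@dataclass
class RollupTable:
    namespace: str
    rows: pd.DataFrame              # term, label, count, freq_pct
    excluded_rows: pd.DataFrame     # term, label, count
    unannotated_count: int


# --------------------------------------------------------------------------
# HSP filter and term assignment
# --------------------------------------------------------------------------

def filter_annotation_hsps(hsps: Sequence[HSP], min_len_bp: int = 80,
                           min_sim_pct: float = 80.0,
                           max_evalue: float = 1e-25) -> list[HSP]:
    """Keep HSPs strictly longer than ``min_len_bp``, with similarity
    strictly above ``min_sim_pct`` and e-value at most ``max_evalue``.

    Similarity is the BLAST positives percentage when present, falling
    back to identity.
    """
    kept = []
    for h in hsps:
        sim = h.similarity_pct if h.similarity_pct is not None else h.identity_pct
        if (h.aln_len > min_len_bp and sim > min_sim_pct
                and (h.evalue is None or h.evalue <= max_evalue)):
            kept.append(h)
    return kept


def assign_terms(filtered_hsps: Sequence[HSP],
                 protein2go: Mapping[str, Iterable[str]],
                 min_support: int = 1) -> list[GOAssignment]:
    """Per query, the union of GO terms of its passing hits.

    Each term must be supported by at least ``min_support`` hits; hit
    proteins absent from the mapping contribute nothing.
    """
    support: dict[str, dict[str, int]] = {}
    for h in filtered_hsps:
        terms = protein2go.get(h.target_id, ())
        per_q = support.setdefault(h.query_id, {})
        for t in set(terms):
            per_q[t] = per_q.get(t, 0) + 1
    return [GOAssignment(q, frozenset(t for t, n in terms.items()
                                      if n >= min_support))
            for q, terms in sorted(support.items())]


# --------------------------------------------------------------------------
# Ontology handling
# --------------------------------------------------------------------------

def load_ontology(path: str | Path) -> nx.MultiDiGraph:
    """Load an OBO ontology; obsolete terms are dropped by the reader."""
    graph = obonet.read_obo(str(path))
    if not nx.is_directed_acyclic_graph(isa_graph(graph)):
        raise ValueError("ontology is_a graph is cyclic")
    return graph


def isa_graph(graph: nx.MultiDiGraph) -> nx.DiGraph:
    """Child -> parent is_a projection of an OBO graph."""
    g = nx.DiGraph()
    g.add_nodes_from(graph.nodes(data=True))
    for u, v, key in graph.edges(keys=True):
        if key == "is_a":
            g.add_edge(u, v)
    return g


def term_levels(graph: nx.MultiDiGraph, namespace: str) -> dict[str, int]:
    """Ontology depth of each term in a namespace: the root is level 1 and
    a term's level is 1 + its shortest is_a path to the root."""
    isa = isa_graph(graph)
    nodes = [n for n, d in graph.nodes(data=True)
             if d.get("namespace") == namespace]
    roots = [n for n in nodes if isa.out_degree(n) == 0]
    if not roots:
        raise ValueError(f"no root found for namespace {namespace!r}")
    levels: dict[str, int] = {}
    for root in roots:
        dist = nx.shortest_path_length(isa.reverse(copy=False), root)
        for n, d in dist.items():
            lv = d + 1
            if n not in levels or lv < levels[n]:
                levels[n] = lv
    return levels


def ancestors_at_level(graph: nx.MultiDiGraph, term: str, level: int,
                       levels: Mapping[str, int]) -> set[str]:
    """All is_a ancestors of ``term`` (including itself) at a given level."""
    isa = isa_graph(graph)
    if term not in isa:
        return set()
    closure = {term} | nx.descendants(isa, term)
    return {t for t in closure if levels.get(t) == level}


# --------------------------------------------------------------------------
# Rollup
# --------------------------------------------------------------------------

def rollup(assignments: Sequence[GOAssignment], graph: nx.MultiDiGraph,
           level: int = 2,
           exclusions: Iterable[str] = (),
           n_queries_total: int | None = None) -> dict[str, RollupTable]:
    """Fixed-level GO rollup per namespace.

    Each query's terms are propagated to their is_a ancestors; the query is
    counted once per distinct level-``level`` ancestor.  Terms listed in
    ``exclusions`` (over-represented classes) are reported separately and
    omitted from the normalization total, so
    ``freq_pct = 100 * count / sum(non-excluded counts)``.
    ``n_queries_total``, when given, sets the base for the unannotated
    count (queries with no term in the namespace).
    """
    exclusions = set(exclusions)
    unknown = exclusions - set(graph.nodes)
    if unknown:
        import warnings
        warnings.warn(f"unknown exclusion ids: {sorted(unknown)}")
    isa = isa_graph(graph)
    levels_by_ns = {ns: term_levels(graph, ns) for ns in NAMESPACES
                    if any(d.get("namespace") == ns
                           for _, d in graph.nodes(data=True))}
    out: dict[str, RollupTable] = {}
    for ns, levels in levels_by_ns.items():
        counts: dict[str, int] = {}
        annotated = 0
        for a in assignments:
            ns_terms = [t for t in a.go_terms
                        if graph.nodes.get(t, {}).get("namespace") == ns]
            if not ns_terms:
                continue
            annotated += 1
            hit: set[str] = set()
            for t in ns_terms:
                closure = {t} | nx.descendants(isa, t)
                hit |= {x for x in closure if levels.get(x) == level}
            for t in hit:
                counts[t] = counts.get(t, 0) + 1
        excluded = {t: c for t, c in counts.items() if t in exclusions}
        included = {t: c for t, c in counts.items() if t not in exclusions}
        total = sum(included.values())
        rows = pd.DataFrame(
            [{"term": t, "label": graph.nodes[t].get("name", ""),
              "count": c,
              "freq_pct": 100.0 * c / total if total else 0.0}
             for t, c in sorted(included.items(),
                                key=lambda kv: (-kv[1], kv[0]))])
        excl = pd.DataFrame(
            [{"term": t, "label": graph.nodes[t].get("name", ""), "count": c}
             for t, c in sorted(excluded.items(),
                                key=lambda kv: (-kv[1], kv[0]))])
        base = n_queries_total if n_queries_total is not None else len(assignments)
        out[ns] = RollupTable(ns, rows, excl, base - annotated)
    return out


def read_protein2go(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (protein id, GO term id) -> mapping."""
    mapping: dict[str, set[str]] = {}
    df = pd.read_csv(path, sep="\t", header=None, names=["protein", "term"],
                     dtype=str, comment="#")
    for protein, term in df.itertuples(index=False):
        mapping.setdefault(protein, set()).add(term)
    return mapping
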