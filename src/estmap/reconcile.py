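"""Transcript-to-genome reconciliation.

Given HSP tables from a local aligner (BLAT-style), this module performs the
two-round HSP filtering, groups HSPs into collinear chains (the gapped,
multi-exon structure of a transcript on the genome), classifies every
alignment relationship into one of ten categories, measures coverage of
either sequence set, selects univocal 1-to-1 transcript/contig pairs for
downstream splice analysis, and builds the scaffold-join evidence graph.

Category glossary (one letter per relationship type):

=====  ================================================================
A      transcript with no retained HSP on any genome contig
B      genome contig with no retained HSP from any transcript
C / J  transcript overhang running off the left / right terminus of a
       genome contig (unassembled genomic sequence beyond the contig edge)
D      transcript-side gap with genomic continuity (putative gap in the
       transcript assembly)
E      genome-side gap with transcript continuity: a putative intron
F      co-linear unaligned sequence on both sides
G      contiguous/overlapping HSPs merging into one larger segment
H      genomic distance between HSPs of two different transcripts on the
       same contig: a putative intergenic interval
I      one transcript split across two genome contigs: evidence the
       contigs are adjacent (scaffold join)
=====  ================================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .io import HSP, Chain, interval_union_len

CATEGORIES = tuple("ABCDEFGHIJ")


@dataclass
class FilterParams:
    """Thresholds and tolerances for filtering, chaining and classification.

    Identity/length thresholds are strict inequalities: an HSP at exactly
    the threshold is rejected.
    """

    round1_min_identity_pct: float = 90.0
    round1_min_hsp_len: int = 50
    round2_drop_singletons: bool = True
    gap_tol: int = 10            # bp treated as "no gap" in the D/E/F trichotomy
    overlap_tol: int = 10        # max bp of overlap between chained HSPs
    end_tol: int = 20            # bp from a contig terminus counting as "edge"
    one2one_min_hsps: int = 2
    one2one_min_covered: int = 100
    one2one_min_identity: float = 90.0

    def __post_init__(self):
        if min(self.gap_tol, self.overlap_tol, self.end_tol) < 0:
            raise ValueError("tolerances must be >= 0")
        for v in (self.round1_min_identity_pct, self.one2one_min_identity):
            if not 0 <= v <= 100:
                raise ValueError("identity thresholds must be in [0, 100]")


@dataclass(frozen=True)
class ClassifiedFeature:
    """One classified alignment relationship (category A-J)."""

    category: str
    query_id: str | None
    target_id: str | None
    interval: tuple[int, int] | None = None
    derived_len: int = 0
    target_id2: str | None = None   # second contig, category I only

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.derived_len < 0:
            raise ValueError("derived_len must be >= 0")


@dataclass(frozen=True)
class CoverageReport:
    side: str
    covered_bp: int
    total_bp: int

    @property
    def pct(self) -> float:
        return 100.0 * self.covered_bp / self.total_bp if self.total_bp else 0.0


# --------------------------------------------------------------------------
# Filtering
# --------------------------------------------------------------------------

def filter_hsps(hsps: Sequence[HSP], params: FilterParams,
                singleton_ids: set[str] | None = None) -> list[HSP]:
    """Two-round HSP filter.

    Round 1 keeps HSPs with identity strictly above
    ``round1_min_identity_pct`` and length strictly above
    ``round1_min_hsp_len``.  Round 2 (when ``round2_drop_singletons``)
    removes HSPs whose query is a singleton read.  Input order is preserved.
    """
    kept = [h for h in hsps
            if h.identity_pct > params.round1_min_identity_pct
            and h.aln_len > params.round1_min_hsp_len]
    if params.round2_drop_singletons and singleton_ids:
        kept = [h for h in kept if h.query_id not in singleton_ids]
    return kept


# --------------------------------------------------------------------------
# Collinear chaining
# --------------------------------------------------------------------------

def _compatible(a: HSP, b: HSP, strand: str, overlap_tol: int) -> bool:
    """Can HSP ``b`` follow ``a`` in a collinear chain (query order)?"""
    if b.q_start < a.q_start or b.q_end <= a.q_end:
        return False
    if a.q_end - b.q_start > overlap_tol:
        return False
    if strand == "+":
        return (b.t_start >= a.t_start and b.t_end > a.t_end
                and a.t_end - b.t_start <= overlap_tol)
    return (b.t_start < a.t_start and b.t_end <= a.t_end
            and b.t_end - a.t_start <= overlap_tol)


def _best_chain(group: list[HSP], strand: str, overlap_tol: int) -> list[HSP]:
    """Maximum-query-coverage collinear chain by dynamic programming."""
    order = sorted(range(len(group)),
                   key=lambda i: (group[i].q_start, group[i].q_end,
                                  group[i].t_start))
    hs = [group[i] for i in order]
    n = len(hs)
    cov = [h.q_len for h in hs]     # best coverage of a chain ending at i
    prev = [-1] * n
    for j in range(n):
        for i in range(j):
            if not _compatible(hs[i], hs[j], strand, overlap_tol):
                continue
            gain = hs[j].q_end - max(hs[j].q_start, hs[i].q_end)
            if cov[i] + gain > cov[j]:
                cov[j] = cov[i] + gain
                prev[j] = i
    best = max(range(n), key=lambda i: (cov[i], -hs[i].q_start))
    path = []
    while best != -1:
        path.append(hs[best])
        best = prev[best]
    return path[::-1]


def chain_collinear(hsps: Sequence[HSP],
                    overlap_tol: int = 10) -> list[Chain]:
    """Partition HSPs into collinear chains.

    HSPs are grouped by (query, target, strand); within each group the
    maximum-coverage collinear subset (jointly monotone on query and target,
    overlaps bounded by ``overlap_tol``) forms one chain, and the procedure
    repeats on the leftovers until every HSP belongs to a chain.
    """
    groups: dict[tuple[str, str, str], list[HSP]] = {}
    for h in hsps:
        groups.setdefault((h.query_id, h.target_id, h.strand), []).append(h)
    chains: list[Chain] = []
    for (q, t, strand), group in sorted(groups.items()):
        remaining = list(group)
        while remaining:
            best = _best_chain(remaining, strand, overlap_tol)
            chains.append(Chain(q, t, strand, best))
            taken = set(map(id, best))
            remaining = [h for h in remaining if id(h) not in taken]
    return chains


def chain_score(hsps: Sequence[HSP], overlap_tol: int = 10) -> int:
    """Query coverage of the single best collinear chain in one group."""
    if not hsps:
        return 0
    strand = hsps[0].strand
    best = _best_chain(list(hsps), strand, overlap_tol)
    return interval_union_len([(h.q_start, h.q_end) for h in best])


# --------------------------------------------------------------------------
# Gap trichotomy within a chain
# --------------------------------------------------------------------------

def chain_gaps(chain: Chain) -> list[tuple[HSP, HSP, int, int]]:
    """(prev, next, query_gap, target_gap) for adjacent HSPs in a chain.

    The target gap is strand-aware: for minus-strand chains the later HSP in
    query order lies earlier on the target.
    """
    out = []
    for a, b in zip(chain.hsps, chain.hsps[1:]):
        qg = b.q_start - a.q_end
        tg = b.t_start - a.t_end if chain.strand == "+" else a.t_start - b.t_end
        out.append((a, b, qg, tg))
    return out


def gap_category(qg: int, tg: int, params: FilterParams) -> str:
    """Classify one inter-HSP relation as E, D, F or G."""
    if tg > params.gap_tol and qg <= params.gap_tol:
        return "E"
    if qg > params.gap_tol and tg <= params.gap_tol:
        return "D"
    if qg > params.gap_tol and tg > params.gap_tol:
        return "F"
    return "G"   # both gaps within tolerance (incl. bounded overlaps): merge


def intron_interval(a: HSP, b: HSP, strand: str) -> tuple[int, int]:
    """Genomic forward-strand interval between two chained HSPs."""
    if strand == "+":
        return a.t_end, b.t_start
    return b.t_end, a.t_start


# --------------------------------------------------------------------------
# Classification
# --------------------------------------------------------------------------

def classify(chains: Sequence[Chain],
             genome_lens: Mapping[str, int],
             transcript_lens: Mapping[str, int],
             params: FilterParams) -> tuple[list[ClassifiedFeature], pd.DataFrame]:
    """Classify chains into the ten alignment-relationship categories.

    Returns the feature list and a counts table (one row per category).
    A query whose chains span two or more genome contigs is classified as
    scaffold-join evidence (I) and is not additionally tested for terminal
    overhangs (C/J), so each planted scenario yields exactly one feature.
    """
    for ch in chains:
        if ch.target_id not in genome_lens:
            raise KeyError(f"unknown genome contig {ch.target_id!r}")
        if ch.query_id not in transcript_lens:
            raise KeyError(f"unknown transcript {ch.query_id!r}")

    features: list[ClassifiedFeature] = []
    queries_with_hits = {c.query_id for c in chains}
    targets_with_hits = {c.target_id for c in chains}

    for q in sorted(set(transcript_lens) - queries_with_hits):
        features.append(ClassifiedFeature("A", q, None,
                                          derived_len=transcript_lens[q]))
    for t in sorted(set(genome_lens) - targets_with_hits):
        features.append(ClassifiedFeature("B", None, t,
                                          derived_len=genome_lens[t]))

    by_query: dict[str, list[Chain]] = {}
    for ch in chains:
        by_query.setdefault(ch.query_id, []).append(ch)

    multi_target = set()
    for q, qchains in sorted(by_query.items()):
        targets = {c.target_id for c in qchains}
        if len(targets) < 2:
            continue
        spans = sorted(((c.q_span, c) for c in qchains),
                       key=lambda x: x[0])
        # adjacent chains (in query order) on different contigs with
        # disjoint query intervals support one join each
        emitted = False
        for (sa, ca), (sb, cb) in zip(spans, spans[1:]):
            if ca.target_id == cb.target_id:
                continue
            if sb[0] >= sa[1]:   # disjoint query intervals
                features.append(ClassifiedFeature(
                    "I", q, ca.target_id, interval=(sa[1], sb[0]),
                    derived_len=sb[0] - sa[1], target_id2=cb.target_id))
                emitted = True
        if emitted:
            multi_target.add(q)

    for ch in chains:
        tlen = genome_lens[ch.target_id]
        qlen = transcript_lens[ch.query_id]
        if ch.query_id not in multi_target:
            first, last = ch.hsps[0], ch.hsps[-1]
            left_unaligned = first.q_start
            right_unaligned = qlen - max(h.q_end for h in ch.hsps)
            if ch.strand == "+":
                at_left_edge = first.t_start <= params.end_tol
                at_right_edge = last.t_end >= tlen - params.end_tol
            else:
                at_left_edge = first.t_end >= tlen - params.end_tol
                at_right_edge = last.t_start <= params.end_tol
            if left_unaligned >= 1 and at_left_edge:
                features.append(ClassifiedFeature(
                    "C", ch.query_id, ch.target_id,
                    interval=(0, left_unaligned), derived_len=left_unaligned))
            if right_unaligned >= 1 and at_right_edge:
                features.append(ClassifiedFeature(
                    "J", ch.query_id, ch.target_id,
                    interval=(qlen - right_unaligned, qlen),
                    derived_len=right_unaligned))
        for a, b, qg, tg in chain_gaps(ch):
            cat = gap_category(qg, tg, params)
            if cat == "E":
                iv = intron_interval(a, b, ch.strand)
                features.append(ClassifiedFeature("E", ch.query_id,
                                                  ch.target_id, interval=iv,
                                                  derived_len=iv[1] - iv[0]))
            elif cat == "D":
                features.append(ClassifiedFeature("D", ch.query_id,
                                                  ch.target_id,
                                                  interval=(a.q_end, b.q_start),
                                                  derived_len=max(qg, 0)))
            elif cat == "F":
                iv = intron_interval(a, b, ch.strand)
                features.append(ClassifiedFeature("F", ch.query_id,
                                                  ch.target_id, interval=iv,
                                                  derived_len=iv[1] - iv[0]))
            else:
                merged = (min(a.q_start, b.q_start), max(a.q_end, b.q_end))
                features.append(ClassifiedFeature("G", ch.query_id,
                                                  ch.target_id,
                                                  interval=merged,
                                                  derived_len=merged[1] - merged[0]))

    # H: gaps between chains of *different* queries on the same target
    by_target: dict[str, list[Chain]] = {}
    for ch in chains:
        by_target.setdefault(ch.target_id, []).append(ch)
    for t, tchains in sorted(by_target.items()):
        spans = sorted((c.t_span + (c.query_id,) for c in tchains))
        for (s1, e1, q1), (s2, e2, q2) in zip(spans, spans[1:]):
            if q1 != q2 and s2 - e1 >= 1:
                features.append(ClassifiedFeature(
                    "H", f"{q1}|{q2}", t, interval=(e1, s2),
                    derived_len=s2 - e1))

    counts = pd.DataFrame({
        "category": CATEGORIES,
        "count": [sum(1 for f in features if f.category == c)
                  for c in CATEGORIES],
    })
    return features, counts


def features_table(features: Sequence[ClassifiedFeature]) -> pd.DataFrame:
    rows = []
    for f in features:
        rows.append({
            "category": f.category,
            "query_id": f.query_id or "",
            "target_id": f.target_id or "",
            "target_id2": f.target_id2 or "",
            "start": f.interval[0] if f.interval else "",
            "end": f.interval[1] if f.interval else "",
            "derived_len": f.derived_len,
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Coverage
# --------------------------------------------------------------------------

def coverage(hsps: Sequence[HSP], seq_lens: Mapping[str, int],
             side: str) -> CoverageReport:
    """Fraction of a sequence set covered by the union of HSP intervals.

    ``side`` is ``query_set`` or ``target_set``; the denominator is the
    total length of *all* sequences in ``seq_lens``, including those with
    no HSP at all.
    """
    if side not in ("query_set", "target_set"):
        raise ValueError("side must be 'query_set' or 'target_set'")
    per_seq: dict[str, list[tuple[int, int]]] = {}
    for h in hsps:
        sid = h.query_id if side == "query_set" else h.target_id
        iv = (h.q_start, h.q_end) if side == "query_set" else (h.t_start, h.t_end)
        if sid not in seq_lens:
            raise KeyError(f"HSP references unknown sequence {sid!r}")
        if iv[1] > seq_lens[sid]:
            raise ValueError(f"HSP interval exceeds length of {sid!r}")
        per_seq.setdefault(sid, []).append(iv)
    covered = sum(interval_union_len(ivs) for ivs in per_seq.values())
    total = sum(seq_lens.values())
    return CoverageReport(side, covered, total)


# --------------------------------------------------------------------------
# Univocal 1-to-1 selection
# --------------------------------------------------------------------------

def one_to_one_select(chains: Sequence[Chain],
                      params: FilterParams) -> list[tuple[str, str]]:
    """Select univocal transcript/genome-contig pairs.

    A chain qualifies when it has at least ``one2one_min_hsps`` HSPs,
    covers strictly more than ``one2one_min_covered`` bp of the transcript,
    and every member HSP has identity strictly above
    ``one2one_min_identity`` and length strictly above
    ``round1_min_hsp_len``.  A transcript is univocal when all its
    qualifying chains fall on a single genome contig.
    """
    qualifying: dict[str, set[str]] = {}
    for ch in chains:
        if len(ch) < params.one2one_min_hsps:
            continue
        if ch.covered_qbp <= params.one2one_min_covered:
            continue
        if any(h.identity_pct <= params.one2one_min_identity
               or h.aln_len <= params.round1_min_hsp_len for h in ch.hsps):
            continue
        qualifying.setdefault(ch.query_id, set()).add(ch.target_id)
    return sorted((q, next(iter(ts))) for q, ts in qualifying.items()
                  if len(ts) == 1)


# --------------------------------------------------------------------------
# Scaffold-join graph
# --------------------------------------------------------------------------

def join_graph(features_i: Sequence[ClassifiedFeature]) -> tuple[nx.Graph, dict]:
    """Build the genome-contig adjacency graph from category-I features.

    Nodes are genome contigs; an edge carries the set of transcripts
    supporting that join.  The report gives edge/support counts and the
    connected-component sizes.
    """
    g = nx.Graph()
    for f in features_i:
        if f.category != "I":
            raise ValueError("join_graph expects category-I features only")
        t1, t2 = f.target_id, f.target_id2
        if g.has_edge(t1, t2):
            g.edges[t1, t2]["support"].add(f.query_id)
        else:
            g.add_edge(t1, t2, support={f.query_id})
    report = {
        "n_edges": g.number_of_edges(),
        "n_supporting_queries": len({q for _, _, d in g.edges(data=True)
                                     for q in d["support"]}),
        "component_sizes": sorted((len(c) for c in nx.connected_components(g)),
                                  reverse=True),
    }
    return g, report


# --------------------------------------------------------------------------
# Known-gene coverage
# --------------------------------------------------------------------------

@dataclass
class KnownGeneCutoffs:
    max_evalue: float = 0.001
    min_identity_pct: float = 80.0   # strict >
    min_hsp_len: int = 50            # strict >


def known_gene_coverage(hsps: Sequence[HSP],
                        known_lens: Mapping[str, int],
                        cutoffs: KnownGeneCutoffs | None = None,
                        overlap_tol: int = 10) -> pd.DataFrame:
    """Per-known-gene coverage by transcript evidence.

    HSPs (transcript query vs known-gene target) are filtered by the
    cutoffs, co-linear HSPs are kept per (transcript, gene) pair via the
    best collinear chain, and per gene the report gives:

    - ``n_seqs``: distinct transcripts with a co-linear match,
    - ``coverage_pct``: union of co-linear HSP target intervals / gene length,
    - ``avg_cov_pct``: coverage_pct / n_seqs.

    Genes with no surviving HSP are reported with zeros.
    """
    cutoffs = cutoffs or KnownGeneCutoffs()
    kept = [h for h in hsps
            if (h.evalue is None or h.evalue <= cutoffs.max_evalue)
            and h.identity_pct > cutoffs.min_identity_pct
            and h.aln_len > cutoffs.min_hsp_len]
    chains = chain_collinear(kept, overlap_tol=overlap_tol)
    # keep only each (query, gene) pair's best chain as the co-linear set
    best: dict[tuple[str, str], Chain] = {}
    for ch in chains:
        key = (ch.query_id, ch.target_id)
        if key not in best or ch.covered_qbp > best[key].covered_qbp:
            best[key] = ch
    per_gene: dict[str, dict] = {g: {"ivs": [], "seqs": set()}
                                 for g in known_lens}
    for (q, g), ch in best.items():
        per_gene[g]["ivs"].extend((h.t_start, h.t_end) for h in ch.hsps)
        per_gene[g]["seqs"].add(q)
    rows = []
    for g in sorted(known_lens):
        info = per_gene[g]
        cov = 100.0 * interval_union_len(info["ivs"]) / known_lens[g]
        n = len(info["seqs"])
        rows.append({"gene": g, "n_seqs": n, "coverage_pct": cov,
                     "avg_cov_pct": cov / n if n else 0.0})
    return pd.DataFrame(rows)
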