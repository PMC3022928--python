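"""Intron inference and splice-site analysis on univocal transcript pairs.

Chains built from exact local matches place exon/intron boundaries only to
HSP-end resolution.  ``refine_boundaries`` re-anchors each putative intron
(the genome-side gaps of a chain) by a bounded joint shift that maximizes a
splice-motif score, after which donor/acceptor dinucleotides are clipped
(strand-corrected), introns are typed as U2 (GT-AG, with GC-AG flagged as a
noncanonical U2 variant) or U12 (AT-AC), and position weight matrices with
per-position information content are built over the clipped windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import Chain, revcomp
from .reconcile import FilterParams, chain_gaps, gap_category, intron_interval

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}

#: motif scores used by boundary refinement, in decreasing preference
_SPLICE_SCORES = {("GT", "AG"): 2, ("AT", "AC"): 2, ("GC", "AG"): 1}

MIN_INTRON_LEN = 4


@dataclass(frozen=True)
class Intron:
    """A genomic interval inferred between chained HSPs.

    ``donor``/``acceptor`` are the first/last two intronic bases after
    strand correction; ``cls`` is determined solely by that dinucleotide
    pair.  ``intron_index`` numbers introns within their source transcript
    (1-based, transcript 5'->3' order).
    """

    target_id: str
    t_start: int
    t_end: int
    strand: str
    donor: str
    acceptor: str
    cls: str
    source_query_id: str
    intron_index: int

    def __post_init__(self):
        if self.t_end - self.t_start < MIN_INTRON_LEN:
            raise ValueError("intron shorter than minimum length")

    @property
    def length(self) -> int:
        return self.t_end - self.t_start


def classify_intron(donor: str, acceptor: str) -> str:
    """Type an intron by its terminal dinucleotides.

    GT-AG -> U2 (major spliceosome); GC-AG -> U2 noncanonical variant;
    AT-AC -> U12 (minor spliceosome); anything else -> other.
    """
    pair = (donor.upper(), acceptor.upper())
    if pair == ("GT", "AG"):
        return "U2"
    if pair == ("GC", "AG"):
        return "U2-GCAG"
    if pair == ("AT", "AC"):
        return "U12"
    return "other"


def _corrected_dinucs(genome_seq: str, start: int, end: int,
                      strand: str) -> tuple[str, str]:
    """Donor/acceptor dinucleotides of [start, end) after strand correction."""
    if strand == "+":
        return genome_seq[start:start + 2].upper(), genome_seq[end - 2:end].upper()
    seg_start = revcomp(genome_seq[start:start + 2]).upper()
    seg_end = revcomp(genome_seq[end - 2:end]).upper()
    # on the minus strand the forward-strand end of the interval is the donor
    return seg_end, seg_start


def _splice_score(genome_seq: str, start: int, end: int, strand: str) -> int:
    donor, acceptor = _corrected_dinucs(genome_seq, start, end, strand)
    return _SPLICE_SCORES.get((donor, acceptor), 0)


def refine_boundaries(chain: Chain, genome_seq: str,
                      transcript_seq: str | None = None,
                      search_window: int = 12,
                      params: FilterParams | None = None) -> list[Intron]:
    """Infer introns from a chain's genome-side gaps, refining boundaries.

    For each within-chain gap classified as an intron (genome gap, query
    continuity), both boundaries are shifted jointly by
    delta in [-search_window, +search_window] (preserving intron length) to
    the position maximizing the splice-motif score (GT-AG = AT-AC = 2,
    GC-AG = 1, other = 0).  Ties are broken toward delta = 0, then the
    smallest ``|delta|`` (positive before negative).  Gaps shorter than 4 bp
    are discarded.
    """
    params = params or FilterParams()
    introns: list[Intron] = []
    index = 0
    for a, b, qg, tg in chain_gaps(chain):
        if gap_category(qg, tg, params) != "E":
            continue
        start, end = intron_interval(a, b, chain.strand)
        if end - start < MIN_INTRON_LEN:
            continue
        deltas = [0]
        for d in range(1, search_window + 1):
            deltas.extend((d, -d))
        best_delta, best_score = 0, -1
        for d in deltas:
            s, e = start + d, end + d
            if s < 0 or e > len(genome_seq):
                continue
            score = _splice_score(genome_seq, s, e, chain.strand)
            if score > best_score:
                best_delta, best_score = d, score
        start += best_delta
        end += best_delta
        donor, acceptor = _corrected_dinucs(genome_seq, start, end, chain.strand)
        index += 1
        introns.append(Intron(chain.target_id, start, end, chain.strand,
                              donor, acceptor, classify_intron(donor, acceptor),
                              chain.query_id, index))
    if chain.strand == "-":
        # query 5'->3' order runs right-to-left on the genome; renumber
        introns = [Intron(i.target_id, i.t_start, i.t_end, i.strand, i.donor,
                          i.acceptor, i.cls, i.source_query_id, k + 1)
                   for k, i in enumerate(introns)]
    return introns


# --------------------------------------------------------------------------
# Site extraction and PWMs
# --------------------------------------------------------------------------

def extract_sites(intron: Intron, genome_seq: str, exon_bp: int = 3,
                  intron_bp: int = 6) -> tuple[str, str, dict[str, str]]:
    """Clip strand-corrected donor and acceptor windows for an intron.

    The donor window is the last ``exon_bp`` exonic plus the first
    ``intron_bp`` intronic bases; the acceptor window is the last
    ``intron_bp`` intronic plus ``exon_bp`` exonic bases.  For minus-strand
    introns the genomic segment is reverse-complemented before clipping.
    Windows running past a contig end are padded with N.
    """
    if intron.strand == "+":
        seq = genome_seq
        s, e = intron.t_start, intron.t_end
    else:
        seq = revcomp(genome_seq)
        s = len(genome_seq) - intron.t_end
        e = len(genome_seq) - intron.t_start
    donor_win = _padded_slice(seq, s - exon_bp, s + intron_bp)
    acceptor_win = _padded_slice(seq, e - intron_bp, e + exon_bp)
    donor = seq[s:s + 2].upper()
    acceptor = seq[e - 2:e].upper()
    return donor, acceptor, {"donor": donor_win, "acceptor": acceptor_win}


def _padded_slice(seq: str, start: int, end: int) -> str:
    left = "N" * max(0, -start)
    right = "N" * max(0, end - len(seq))
    return (left + seq[max(start, 0):min(end, len(seq))] + right).upper()


@dataclass
class PWM:
    """Per-position nucleotide frequencies over aligned signal windows.

    ``freq`` is (positions x ACGT); ``ic`` is the per-position information
    content in bits under a uniform background:
    ``ic = 2 + sum_b p_b log2 p_b`` (0 log 0 = 0).  N bases are excluded
    from the column denominator.
    """

    n: int
    freq: np.ndarray
    ic: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.freq, columns=list(_BASES))
        df.insert(0, "position", np.arange(1, len(df) + 1))
        df["ic_bits"] = self.ic
        return df


def build_pwm(site_windows: Sequence[str],
              background: Sequence[float] | None = None) -> PWM:
    """Build a PWM (and per-position information content) from windows.

    All windows must have equal length.  With ``background`` given (ACGT
    frequencies), the information content is the relative entropy against
    that background instead of the uniform-background form.
    """
    if not site_windows:
        raise ValueError("at least one window required")
    width = len(site_windows[0])
    if any(len(w) != width for w in site_windows):
        raise ValueError("ragged windows")
    counts = np.zeros((width, 4))
    for w in site_windows:
        for pos, b in enumerate(w.upper()):
            if b in _BASE_IDX:
                counts[pos, _BASE_IDX[b]] += 1
    denom = counts.sum(axis=1, keepdims=True)
    freq = np.divide(counts, denom, out=np.zeros_like(counts),
                     where=denom > 0)
    ic = np.zeros(width)
    for pos in range(width):
        p = freq[pos]
        if p.sum() == 0:
            continue
        if background is None:
            ent = -sum(x * math.log2(x) for x in p if x > 0)
            ic[pos] = 2.0 - ent
        else:
            ic[pos] = sum(x * math.log2(x / bg)
                          for x, bg in zip(p, background) if x > 0)
    return PWM(n=len(site_windows), freq=freq, ic=ic)


# --------------------------------------------------------------------------
# Statistics and reports
# --------------------------------------------------------------------------

def intron_stats(introns: Sequence[Intron]) -> dict:
    """Introns-per-transcript histogram and intron-length summary."""
    per_query: dict[str, int] = {}
    for i in introns:
        per_query[i.source_query_id] = per_query.get(i.source_query_id, 0) + 1
    hist: dict[int, int] = {}
    for n in per_query.values():
        hist[n] = hist.get(n, 0) + 1
    lengths = np.array([i.length for i in introns]) if introns else np.array([])
    summary = {}
    if lengths.size:
        summary = {"min": int(lengths.min()),
                   "median": float(np.median(lengths)),
                   "max": int(lengths.max()),
                   "avg": float(lengths.mean())}
    return {"n_introns": len(introns),
            "introns_per_query": dict(sorted(hist.items())),
            "length_summary": summary}


def sites_table(introns: Sequence[Intron],
                genome: Mapping[str, str]) -> pd.DataFrame:
    """Splice-site report, one row per intron.

    ``ORI`` is -1 when the match was on the reverse strand of the genomic
    contig; ``SSSEQ`` shows three exonic bases, a dot, the first three
    intronic bases, three dots for the elided interior, the last three
    intronic bases, a dot, and three exonic bases, all strand-corrected.
    """
    rows = []
    for i in introns:
        _, _, wins = extract_sites(i, genome[i.target_id])
        donor_w, acceptor_w = wins["donor"], wins["acceptor"]
        ssseq = (f"{donor_w[:3]}.{donor_w[3:6]}...{acceptor_w[3:6]}."
                 f"{acceptor_w[6:9]}")
        rows.append({"GID": i.target_id, "CIG": i.source_query_id,
                     "INTNUM": i.intron_index,
                     "ORI": -1 if i.strand == "-" else 1,
                     "ILEN": i.length, "CLASS": i.cls,
                     "DONOR": i.donor, "ACCEPTOR": i.acceptor,
                     "SSSEQ": ssseq})
    return pd.DataFrame(rows)


def donor_acceptor_pwms(introns: Sequence[Intron],
                        genome: Mapping[str, str],
                        classes: Iterable[str] = ("U2",),
                        exon_bp: int = 3,
                        intron_bp: int = 6) -> tuple[PWM, PWM]:
    """Donor and acceptor PWMs over introns of the requested classes."""
    donors, acceptors = [], []
    wanted = set(classes)
    for i in introns:
        if i.cls not in wanted:
            continue
        _, _, wins = extract_sites(i, genome[i.target_id], exon_bp, intron_bp)
        donors.append(wins["donor"])
        acceptors.append(wins["acceptor"])
    if not donors:
        raise ValueError(f"no introns of class {sorted(wanted)}")
    return build_pwm(donors), build_pwm(acceptors)
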