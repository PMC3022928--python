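"""Seeded synthetic data with planted ground truth.

The generator emulates the structure of a 454-style transcriptome mapped
onto a fragmented, A/T-rich draft genome: background composition around a
target GC fraction (default 35%), multi-exon genes with mostly GT-AG and a
minority of AT-AC introns, and transcripts planted to realize each of the
ten alignment-relationship scenarios (novel transcript, contig-edge
extension, assembly gap, intron, intergenic spacing, scaffold join, ...).
Emitted HSPs are the exact exon-to-genome matches, so every pipeline stage
can be checked against the recorded truth without any aligner.

One genome contig is devoted to each planted scenario instance (two for a
scaffold join), with pads larger than the edge tolerance around interior
genes, so the classification of a clean run recovers the planted counts
exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import HSP, SequenceRecord, revcomp, write_fasta, write_hsp_table

_DEFAULT_SCENARIOS = {"A": 1, "B": 1, "C": 1, "D": 1, "E": 4,
                      "F": 1, "G": 1, "H": 1, "I": 1, "J": 1}

#: planted introns keep this neighbourhood free of competing canonical
#: splice motifs; it must cover the refinement search window plus the
#: largest boundary perturbation studied, so refinement stays unambiguous
MOTIF_FREE_WINDOW = 20

_HYDROPHILIC = "DEKRNQSTGH"
_HYDROPHOBIC = "LIVFAM"


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    A fixed seed yields byte-identical outputs.  Scenario counts are the
    number of planted instances per category; for category E each instance
    is one intron (grouped into transcripts of ``introns_per_transcript``
    introns each).
    """

    seed: int = 1
    gc_target: float = 0.35
    n_genome_contigs: int = 0          # extra background contigs (count as B)
    genome_contig_len: tuple[int, int] = (2000, 4000)
    exon_len: tuple[int, int] = (80, 240)
    intron_len: tuple[int, int] = (60, 400)
    introns_per_transcript: tuple[int, int] = (1, 1)
    u12_fraction: float = 0.05
    scenario_counts: dict = field(
        default_factory=lambda: dict(_DEFAULT_SCENARIOS))
    identity_jitter: float = 0.0
    minus_strand_fraction: float = 0.5
    tm_protein_count: int = 30
    sp_fraction: float = 0.3
    tm_disagreement: float = 0.0
    pad_len: tuple[int, int] = (150, 400)

    def __post_init__(self):
        if not 0 < self.gc_target < 1:
            raise ValueError("gc_target must be in (0, 1)")
        if not 0 <= self.u12_fraction <= 1:
            raise ValueError("u12_fraction must be in [0, 1]")
        if any(v < 0 for v in self.scenario_counts.values()):
            raise ValueError("scenario counts must be >= 0")
        unknown = set(self.scenario_counts) - set("ABCDEFGHIJ")
        if unknown:
            raise ValueError(f"unknown scenario categories: {sorted(unknown)}")
        if self.intron_len[0] < 2 * MOTIF_FREE_WINDOW + 4:
            raise ValueError("minimum intron length too short for "
                             "unambiguous boundary refinement")
        if self.intron_len[1] >= self.genome_contig_len[0]:
            raise ValueError("intron longer than the shortest genome contig")
        if not 0 <= self.identity_jitter < 0.5:
            raise ValueError("identity_jitter must be in [0, 0.5)")


@dataclass
class GroundTruth:
    """Planted facts the pipeline must recover."""

    categories: list[dict] = field(default_factory=list)
    introns: list[dict] = field(default_factory=list)
    joins: list[tuple[str, str, str]] = field(default_factory=list)
    tm: dict[str, dict] = field(default_factory=dict)

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in "ABCDEFGHIJ"}
        for rec in self.categories:
            counts[rec["category"]] += 1
        return counts


@dataclass
class SimResult:
    config: SimConfig
    genome: list[SequenceRecord]
    transcripts: list[SequenceRecord]
    hsps: list[HSP]
    proteins: list[SequenceRecord]
    truth: GroundTruth

    @property
    def genome_lens(self) -> dict[str, int]:
        return {r.id: len(r) for r in self.genome}

    @property
    def transcript_lens(self) -> dict[str, int]:
        return {r.id: len(r) for r in self.transcripts}

    @property
    def genome_seqs(self) -> dict[str, str]:
        return {r.id: r.seq for r in self.genome}

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, out / "genome.fa")
        write_fasta(self.transcripts, out / "transcripts.fa")
        write_fasta(self.proteins, out / "proteins.fa")
        write_hsp_table(self.hsps, out / "hsps.tsv", dialect="blast_tab")
        pd.DataFrame(self.truth.categories).to_csv(
            out / "truth_categories.tsv", sep="\t", index=False)
        pd.DataFrame(self.truth.introns).to_csv(
            out / "truth_introns.tsv", sep="\t", index=False)
        pd.DataFrame(self.truth.joins,
                     columns=["contig1", "contig2", "transcript"]).to_csv(
            out / "truth_joins.tsv", sep="\t", index=False)
        rows = [{"protein": pid, "n_tm": t["n_tm"],
                 "sp_end": t["sp"][1] if t["sp"] else 0}
                for pid, t in sorted(self.truth.tm.items())]
        pd.DataFrame(rows).to_csv(out / "truth_tm.tsv", sep="\t", index=False)


# --------------------------------------------------------------------------
# Sequence sampling
# --------------------------------------------------------------------------

def random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    """i.i.d. background with P(G) = P(C) = gc/2."""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def measured_gc(seqs) -> float:
    gc = total = 0
    for s in seqs:
        gc += sum(1 for b in s if b in "GCgc")
        total += len(s)
    return gc / total


# --------------------------------------------------------------------------
# Gene construction
# --------------------------------------------------------------------------

def _build_gene(rng: np.random.Generator, cfg: SimConfig,
                n_introns: int) -> tuple[str, list[tuple[int, int]], list[dict]]:
    """Forward-strand gene region: exons interleaved with spliceable introns.

    Returns (region sequence, exon intervals within region, intron records).
    Intron interiors and nearby exon bases are resampled until no competing
    canonical splice-motif pair exists within the refinement search window,
    so boundary refinement has a unique optimum.
    """
    for _ in range(200):
        exons = [random_dna(rng, int(rng.integers(*cfg.exon_len)), cfg.gc_target)
                 for _ in range(n_introns + 1)]
        intron_specs = []
        for _ in range(n_introns):
            if rng.random() < cfg.u12_fraction:
                cls, don, acc = "U12", "AT", "AC"
            else:
                cls, don, acc = "U2", "GT", "AG"
            ilen = int(rng.integers(*cfg.intron_len))
            interior = random_dna(rng, ilen - 4, cfg.gc_target)
            intron_specs.append((cls, don + interior + acc, don, acc))
        region_parts, exon_ivs, intron_recs = [], [], []
        pos = 0
        for k, ex in enumerate(exons):
            region_parts.append(ex)
            exon_ivs.append((pos, pos + len(ex)))
            pos += len(ex)
            if k < n_introns:
                cls, iseq, don, acc = intron_specs[k]
                intron_recs.append({"start": pos, "end": pos + len(iseq),
                                    "cls": cls, "donor": don, "acceptor": acc})
                region_parts.append(iseq)
                pos += len(iseq)
        region = "".join(region_parts)
        if all(_motif_unique(region, i["start"], i["end"])
               for i in intron_recs):
            return region, exon_ivs, intron_recs
    raise RuntimeError("could not build a motif-unique gene region")


def _motif_unique(region: str, start: int, end: int,
                  window: int = MOTIF_FREE_WINDOW) -> bool:
    """True if no competing canonical splice pair exists at a joint shift
    delta != 0 within the refinement window (checked on both strands)."""
    canonical = {("GT", "AG"), ("AT", "AC")}
    for d in range(-window, window + 1):
        if d == 0:
            continue
        s, e = start + d, end + d
        if s < 0 or e > len(region):
            continue
        fwd = (region[s:s + 2], region[e - 2:e])
        rev = (revcomp(region[e - 2:e]), revcomp(region[s:s + 2]))
        if fwd in canonical or rev in canonical:
            return False
    return True


# --------------------------------------------------------------------------
# Scenario planting
# --------------------------------------------------------------------------

def simulate(cfg: SimConfig) -> SimResult:
    """Generate a full synthetic dataset with ground truth."""
    rng = np.random.default_rng(cfg.seed)
    genome: list[SequenceRecord] = []
    transcripts: list[SequenceRecord] = []
    hsps: list[HSP] = []
    truth = GroundTruth()

    pad = lambda: random_dna(rng, int(rng.integers(*cfg.pad_len)), cfg.gc_target)

    counts = {c: cfg.scenario_counts.get(c, 0) for c in "ABCDEFGHIJ"}

    for k in range(counts["A"]):
        tid = f"tA{k + 1}"
        seq = random_dna(rng, int(rng.integers(200, 600)), cfg.gc_target)
        transcripts.append(SequenceRecord(tid, seq))
        truth.categories.append({"category": "A", "query_id": tid,
                                 "target_id": "", "derived_len": len(seq)})

    for k in range(counts["B"] + cfg.n_genome_contigs):
        gid = f"gB{k + 1}"
        seq = random_dna(rng, int(rng.integers(*cfg.genome_contig_len)),
                         cfg.gc_target)
        genome.append(SequenceRecord(gid, seq))
        truth.categories.append({"category": "B", "query_id": "",
                                 "target_id": gid, "derived_len": len(seq)})

    for k in range(counts["C"]):
        tid, gid = f"tC{k + 1}", f"gC{k + 1}"
        exon = random_dna(rng, int(rng.integers(120, 300)), cfg.gc_target)
        over = random_dna(rng, int(rng.integers(30, 120)), cfg.gc_target)
        genome.append(SequenceRecord(gid, exon + pad()))
        transcripts.append(SequenceRecord(tid, over + exon))
        hsps.append(HSP(tid, gid, len(over), len(over) + len(exon),
                        0, len(exon)))
        truth.categories.append({"category": "C", "query_id": tid,
                                 "target_id": gid, "derived_len": len(over)})

    for k in range(counts["J"]):
        tid, gid = f"tJ{k + 1}", f"gJ{k + 1}"
        exon = random_dna(rng, int(rng.integers(120, 300)), cfg.gc_target)
        over = random_dna(rng, int(rng.integers(30, 120)), cfg.gc_target)
        left = pad()
        genome.append(SequenceRecord(gid, left + exon))
        transcripts.append(SequenceRecord(tid, exon + over))
        hsps.append(HSP(tid, gid, 0, len(exon),
                        len(left), len(left) + len(exon)))
        truth.categories.append({"category": "J", "query_id": tid,
                                 "target_id": gid, "derived_len": len(over)})

    for k in range(counts["D"]):
        tid, gid = f"tD{k + 1}", f"gD{k + 1}"
        a = random_dna(rng, int(rng.integers(*cfg.exon_len)), cfg.gc_target)
        b = random_dna(rng, int(rng.integers(*cfg.exon_len)), cfg.gc_target)
        ins = random_dna(rng, int(rng.integers(25, 80)), cfg.gc_target)
        left = pad()
        genome.append(SequenceRecord(gid, left + a + b + pad()))
        transcripts.append(SequenceRecord(tid, a + ins + b))
        hsps.append(HSP(tid, gid, 0, len(a), len(left), len(left) + len(a)))
        hsps.append(HSP(tid, gid, len(a) + len(ins), len(a) + len(ins) + len(b),
                        len(left) + len(a), len(left) + len(a) + len(b)))
        truth.categories.append({"category": "D", "query_id": tid,
                                 "target_id": gid, "derived_len": len(ins)})

    for k in range(counts["F"]):
        tid, gid = f"tF{k + 1}", f"gF{k + 1}"
        a = random_dna(rng, int(rng.integers(*cfg.exon_len)), cfg.gc_target)
        b = random_dna(rng, int(rng.integers(*cfg.exon_len)), cfg.gc_target)
        ins = random_dna(rng, int(rng.integers(25, 80)), cfg.gc_target)
        spacer = random_dna(rng, int(rng.integers(25, 80)), cfg.gc_target)
        left = pad()
        genome.append(SequenceRecord(gid, left + a + spacer + b + pad()))
        transcripts.append(SequenceRecord(tid, a + ins + b))
        hsps.append(HSP(tid, gid, 0, len(a), len(left), len(left) + len(a)))
        hsps.append(HSP(tid, gid, len(a) + len(ins),
                        len(a) + len(ins) + len(b),
                        len(left) + len(a) + len(spacer),
                        len(left) + len(a) + len(spacer) + len(b)))
        truth.categories.append({"category": "F", "query_id": tid,
                                 "target_id": gid, "derived_len": len(spacer)})

    for k in range(counts["G"]):
        tid, gid = f"tG{k + 1}", f"gG{k + 1}"
        seg = random_dna(rng, int(rng.integers(200, 320)), cfg.gc_target)
        cut = int(rng.integers(80, len(seg) - 80))
        v = int(rng.integers(3, 9))    # overlap within tolerance
        left = pad()
        genome.append(SequenceRecord(gid, left + seg + pad()))
        transcripts.append(SequenceRecord(tid, seg))
        hsps.append(HSP(tid, gid, 0, cut, len(left), len(left) + cut))
        hsps.append(HSP(tid, gid, cut - v, len(seg),
                        len(left) + cut - v, len(left) + len(seg)))
        truth.categories.append({"category": "G", "query_id": tid,
                                 "target_id": gid, "derived_len": len(seg)})

    for k in range(counts["H"]):
        gid = f"gH{k + 1}"
        t1, t2 = f"tHa{k + 1}", f"tHb{k + 1}"
        a = random_dna(rng, int(rng.integers(150, 300)), cfg.gc_target)
        b = random_dna(rng, int(rng.integers(150, 300)), cfg.gc_target)
        gap = random_dna(rng, int(rng.integers(100, 800)), cfg.gc_target)
        left = pad()
        genome.append(SequenceRecord(gid, left + a + gap + b + pad()))
        transcripts.append(SequenceRecord(t1, a))
        transcripts.append(SequenceRecord(t2, b))
        hsps.append(HSP(t1, gid, 0, len(a), len(left), len(left) + len(a)))
        hsps.append(HSP(t2, gid, 0, len(b),
                        len(left) + len(a) + len(gap),
                        len(left) + len(a) + len(gap) + len(b)))
        truth.categories.append({"category": "H", "query_id": f"{t1}|{t2}",
                                 "target_id": gid, "derived_len": len(gap)})

    for k in range(counts["I"]):
        tid = f"tI{k + 1}"
        g1, g2 = f"gIa{k + 1}", f"gIb{k + 1}"
        e1 = random_dna(rng, int(rng.integers(120, 300)), cfg.gc_target)
        e2 = random_dna(rng, int(rng.integers(120, 300)), cfg.gc_target)
        left = pad()
        genome.append(SequenceRecord(g1, left + e1))   # exon at right edge
        genome.append(SequenceRecord(g2, e2 + pad()))  # exon at left edge
        transcripts.append(SequenceRecord(tid, e1 + e2))
        hsps.append(HSP(tid, g1, 0, len(e1), len(left), len(left) + len(e1)))
        hsps.append(HSP(tid, g2, len(e1), len(e1) + len(e2), 0, len(e2)))
        truth.categories.append({"category": "I", "query_id": tid,
                                 "target_id": g1, "derived_len": 0})
        truth.joins.append((g1, g2, tid))

    # E: planted introns, grouped into multi-exon transcripts
    remaining = counts["E"]
    gene_no = 0
    while remaining > 0:
        gene_no += 1
        n_int = int(rng.integers(cfg.introns_per_transcript[0],
                                 cfg.introns_per_transcript[1] + 1))
        n_int = min(n_int, remaining)
        remaining -= n_int
        tid, gid = f"tE{gene_no}", f"gE{gene_no}"
        region, exon_ivs, intron_recs = _build_gene(rng, cfg, n_int)
        left, right = pad(), pad()
        contig = left + region + right
        strand = "-" if rng.random() < cfg.minus_strand_fraction else "+"
        mrna = "".join(region[s:e] for s, e in exon_ivs)
        if strand == "-":
            contig = revcomp(contig)
            clen = len(contig)
            flip = lambda iv: (clen - (len(left) + iv[1]),
                               clen - (len(left) + iv[0]))
            exon_coords = [flip(iv) for iv in exon_ivs]
            intron_coords = [flip((i["start"], i["end"]))
                             for i in intron_recs]
        else:
            exon_coords = [(len(left) + s, len(left) + e)
                           for s, e in exon_ivs]
            intron_coords = [(len(left) + i["start"], len(left) + i["end"])
                             for i in intron_recs]
        genome.append(SequenceRecord(gid, contig))
        transcripts.append(SequenceRecord(tid, mrna))
        qpos = 0
        for (s, e), (ts, te) in zip(exon_ivs, exon_coords):
            hsps.append(HSP(tid, gid, qpos, qpos + (e - s), ts, te,
                            strand=strand))
            qpos += e - s
        for idx, (rec, (ts, te)) in enumerate(zip(intron_recs, intron_coords)):
            truth.introns.append({
                "target_id": gid, "t_start": ts, "t_end": te,
                "strand": strand, "cls": rec["cls"], "donor": rec["donor"],
                "acceptor": rec["acceptor"], "transcript": tid,
                "index": idx + 1})
            truth.categories.append({"category": "E", "query_id": tid,
                                     "target_id": gid,
                                     "derived_len": te - ts})

    if cfg.identity_jitter > 0:
        hsps = _apply_jitter(rng, hsps, transcripts, cfg.identity_jitter)

    proteins, tm_truth = _make_proteins(rng, cfg)
    truth.tm = tm_truth
    return SimResult(cfg, genome, transcripts, hsps, proteins, truth)


def _apply_jitter(rng, hsps, transcripts, jitter):
    """Plant mismatches in transcripts and discount HSP identities."""
    seqs = {t.id: list(t.seq) for t in transcripts}
    out = []
    for h in hsps:
        n_mut = int(jitter * h.q_len)
        if n_mut:
            pos = rng.choice(np.arange(h.q_start, h.q_end), size=n_mut,
                             replace=False)
            for p in pos:
                cur = seqs[h.query_id][p]
                seqs[h.query_id][p] = {"A": "C", "C": "A",
                                       "G": "T", "T": "G"}.get(cur, "A")
        out.append(replace(h, identity_pct=100.0 * (1 - n_mut / h.q_len)))
    for i, t in enumerate(transcripts):
        transcripts[i] = SequenceRecord(t.id, "".join(seqs[t.id]), t.set_label)
    return out


# --------------------------------------------------------------------------
# Proteins with planted TM segments / signal peptides
# --------------------------------------------------------------------------

def _aa(rng, alphabet, n):
    return "".join(rng.choice(list(alphabet), size=n))


def _make_proteins(rng: np.random.Generator,
                   cfg: SimConfig) -> tuple[list[SequenceRecord], dict]:
    proteins, truth = [], {}
    for k in range(cfg.tm_protein_count):
        pid = f"p{k + 1}"
        n_tm = k % 3              # deterministic mix of 0/1/2-TM proteins
        has_sp = rng.random() < cfg.sp_fraction
        parts = []
        sp = None
        if has_sp:
            sp_seq = _aa(rng, "MK", 2) + _aa(rng, _HYDROPHOBIC, 16) + \
                _aa(rng, "AS", 2)
            parts.append(sp_seq)
            sp = (0, len(sp_seq))
        parts.append(_aa(rng, _HYDROPHILIC, int(rng.integers(25, 40))))
        segments = []
        pos = sum(len(p) for p in parts)
        for _ in range(n_tm):
            tm = _aa(rng, _HYDROPHOBIC, 21)
            segments.append((pos, pos + 21))
            parts.append(tm)
            pos += 21
            linker = _aa(rng, _HYDROPHILIC, int(rng.integers(25, 40)))
            parts.append(linker)
            pos += len(linker)
        seq = "".join(parts)
        proteins.append(SequenceRecord(pid, seq))
        truth[pid] = {"n_tm": n_tm, "sp": sp, "segments": segments}
    return proteins, truth


def emit_tm_fixtures(result: SimResult, out_dir: str | Path,
                     disagreement: float | None = None,
                     disagree_predictor: str | None = None) -> dict[str, Path]:
    """Write three predictor-dialect files consistent with TM truth.

    A ``disagreement`` fraction of proteins get one predictor (random
    unless ``disagree_predictor`` is given) reporting a wrong TM count, so
    2-of-3 voting can be exercised; the remaining two predictors always
    agree with the truth.
    """
    cfg = result.config
    disagreement = cfg.tm_disagreement if disagreement is None else disagreement
    rng = np.random.default_rng(cfg.seed + 7919)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / f"{name}.txt" for name in ("phobius", "tmhmm", "sosui")}
    lines = {name: [] for name in paths}
    for rec in result.proteins:
        t = result.truth.tm[rec.id]
        n = t["n_tm"]
        counts = {"phobius": n, "tmhmm": n, "sosui": n}
        if disagreement > 0 and rng.random() < disagreement:
            victim = disagree_predictor or \
                rng.choice(["phobius", "tmhmm", "sosui"])
            counts[victim] = 0 if n >= 1 else 1
        sp = t["sp"]
        sp_field = f"Y:{sp[1]}" if sp else "0"
        lines["phobius"].append(
            f"{rec.id}\t{counts['phobius']}\t{sp_field}\t-")
        lines["tmhmm"].append(
            f"{rec.id}\tlen={len(rec.seq)}\tPredHel={counts['tmhmm']}\t"
            f"Topology=-")
        lines["sosui"].append(
            f"{rec.id}\t{counts['sosui']}\t"
            f"{'MEMBRANE' if counts['sosui'] else 'SOLUBLE'}")
    for name, path in paths.items():
        path.write_text("\n".join(lines[name]) + "\n")
    return paths


# --------------------------------------------------------------------------
# Perturbation helper for splice-refinement studies
# --------------------------------------------------------------------------

def perturb_intron_boundaries(result: SimResult, max_shift: int,
                              rng: np.random.Generator) -> tuple[list[HSP], dict]:
    """Jointly shift each planted intron's flanking HSP ends by a random
    nonzero delta in [-max_shift, max_shift], emulating an aligner placing
    the exon/intron boundary imprecisely.  Returns the perturbed HSP list
    and the applied shift per (transcript, intron index)."""
    by_query: dict[str, list[HSP]] = {}
    for h in result.hsps:
        by_query.setdefault(h.query_id, []).append(h)
    shifts: dict[tuple[str, int], int] = {}
    introns_by_query: dict[str, list[dict]] = {}
    for rec in result.truth.introns:
        introns_by_query.setdefault(rec["transcript"], []).append(rec)
    for tid, recs in introns_by_query.items():
        hs = sorted(by_query[tid], key=lambda h: h.q_start)
        recs = sorted(recs, key=lambda r: r["index"])
        for j, rec in enumerate(recs):
            delta = 0
            while delta == 0:
                delta = int(rng.integers(-max_shift, max_shift + 1))
            shifts[(tid, rec["index"])] = delta
            a, b = hs[j], hs[j + 1]
            if rec["strand"] == "+":
                hs[j] = replace(a, t_end=a.t_end + delta)
                hs[j + 1] = replace(b, t_start=b.t_start + delta)
            else:
                hs[j] = replace(a, t_start=a.t_start + delta)
                hs[j + 1] = replace(b, t_end=b.t_end + delta)
        by_query[tid] = hs
    perturbed = [h for q in sorted(by_query) for h in by_query[q]]
    return perturbed, shifts


# --------------------------------------------------------------------------
# Read-membership fixtures (assembly census)
# --------------------------------------------------------------------------

def simulate_membership(rng: np.random.Generator, n_reads: int = 500,
                        labels: Sequence[str] = ("a90", "a98", "a90e"),
                        split_fraction: float = 0.1) -> pd.DataFrame:
    """Random read-membership table over three assemblies.

    Reads land in a random non-empty subset of assemblies, as a contig
    member or singleton; a ``split_fraction`` of reads appear as two
    quality-clipped fragments with ``_1``/``_2`` suffixes (possibly with
    different placements, exercising the contig-precedence rule)."""
    rows = []
    for i in range(n_reads):
        rid = f"R{i + 1:05d}"
        present = [l for l in labels if rng.random() < 0.75]
        if not present:
            present = [labels[int(rng.integers(len(labels)))]]
        split = rng.random() < split_fraction
        frag_ids = [f"{rid}_1", f"{rid}_2"] if split else [rid]
        for a in present:
            for fid in frag_ids:
                placement = "contig" if rng.random() < 0.7 else "singleton"
                rows.append({"read_id": fid, "assembly": a,
                             "placement": placement})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Toy ontology / annotation fixtures (GO rollup)
# --------------------------------------------------------------------------

def random_ontology_obo(rng: np.random.Generator, n_terms: int = 12,
                        namespace: str = "molecular_function") -> str:
    """A small random is_a DAG in OBO format (term 0 is the root).

    Every non-root term gets 1-2 parents among the earlier terms, so the
    graph is acyclic by construction."""
    lines = ["format-version: 1.2", "ontology: toy", ""]
    for i in range(n_terms):
        tid = f"GO:{i:07d}"
        lines += ["[Term]", f"id: {tid}", f"name: term{i}",
                  f"namespace: {namespace}"]
        if i > 0:
            n_par = 1 if i == 1 else int(rng.integers(1, 3))
            parents = rng.choice(i, size=min(n_par, i), replace=False)
            for p in sorted(int(x) for x in parents):
                lines.append(f"is_a: GO:{p:07d} ! term{p}")
        lines.append("")
    return "\n".join(lines)


def random_annotation_fixture(rng: np.random.Generator, n_queries: int,
                              terms: Sequence[str],
                              n_proteins: int = 20
                              ) -> tuple[list[HSP], dict[str, set[str]]]:
    """Random protein-similarity HSPs plus a protein->GO mapping."""
    protein_ids = [f"np{j + 1}" for j in range(n_proteins)]
    protein2go = {p: {terms[int(i)] for i in
                      rng.choice(len(terms),
                                 size=int(rng.integers(1, 4)),
                                 replace=False)}
                  for p in protein_ids}
    hsps = []
    for i in range(n_queries):
        qid = f"q{i + 1}"
        for _ in range(int(rng.integers(1, 4))):
            p = protein_ids[int(rng.integers(n_proteins))]
            length = int(rng.integers(50, 200))
            sim = float(rng.uniform(60, 100))
            evalue = float(10.0 ** -rng.uniform(10, 60))
            hsps.append(HSP(qid, p, 0, length, 0, length,
                            identity_pct=min(sim, 100.0), aln_len=length,
                            evalue=evalue, similarity_pct=sim))
    return hsps, protein2go
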