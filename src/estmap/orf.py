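"""Six-frame translation, longest-ORF extraction and consensus
transmembrane-protein calling.

Transcripts are translated in all six frames, the longest stop-free
amino-acid segment becomes the protein database entry for that transcript,
and per-protein transmembrane (TM) segment counts from three topology
predictors are combined by 2-of-3 voting.  A built-in sliding-window
Kyte-Doolittle hydropathy predictor is provided so the whole path runs
without external binaries; parser adapters accept the short output formats
of the usual external tools as drop-in replacements.  Signal peptides mimic
TM segments and are masked (N-terminal truncation) before the second and
third predictors see the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import pandas as pd
from Bio.Seq import Seq

FRAMES = ("+1", "+2", "+3", "-1", "-2", "-3")

STOP = "*"

#: Kyte-Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


@dataclass(frozen=True)
class ORFRecord:
    parent_id: str
    frame: str
    aa_start: int
    aa_end: int
    aa_seq: str

    def __post_init__(self):
        if STOP in self.aa_seq:
            raise ValueError("ORF contains a stop symbol")


@dataclass(frozen=True)
class TMPrediction:
    predictor: str
    protein_id: str
    n_tm: int
    topology: str = ""
    sp_interval: tuple[int, int] | None = None

    def __post_init__(self):
        if self.n_tm < 0:
            raise ValueError("n_tm must be >= 0")


@dataclass(frozen=True)
class ConsensusRecord:
    protein_id: str
    votes: dict
    accepted: bool
    redundant_of: str | None = None


# --------------------------------------------------------------------------
# Translation and ORFs
# --------------------------------------------------------------------------

def six_frame_translate(nt_seq: str) -> dict[str, str]:
    """Translate a nucleotide sequence in all six reading frames.

    Standard genetic code; frames -1..-3 translate the reverse complement
    with offsets 0..2; a trailing partial codon is dropped; ambiguous
    codons give X and stops are rendered as ``*``.
    """
    if len(nt_seq) < 3:
        raise ValueError("sequence shorter than one codon")
    fwd = Seq(nt_seq.upper())
    rev = fwd.reverse_complement()
    out = {}
    for i, frame in enumerate(("+1", "+2", "+3")):
        sub = fwd[i:]
        out[frame] = str(sub[: len(sub) - len(sub) % 3].translate())
    for i, frame in enumerate(("-1", "-2", "-3")):
        sub = rev[i:]
        out[frame] = str(sub[: len(sub) - len(sub) % 3].translate())
    return out


def longest_orf(frames: Mapping[str, str], parent_id: str = "",
                min_orf_aa: int = 30,
                require_start: bool = False) -> ORFRecord | None:
    """Longest stop-free amino-acid segment across the six frames.

    With ``require_start`` the segment is additionally trimmed to begin at
    its first methionine.  Ties are broken by frame order +1, +2, +3, -1,
    -2, -3, then by the leftmost start.  Returns None when no segment
    reaches ``min_orf_aa``.
    """
    best: ORFRecord | None = None
    for frame in FRAMES:
        aa = frames.get(frame, "")
        pos = 0
        for segment in aa.split(STOP):
            if require_start:
                m = segment.find("M")
                seg, start = (segment[m:], pos + m) if m >= 0 else ("", pos)
            else:
                seg, start = segment, pos
            if len(seg) > (len(best.aa_seq) if best else -1):
                if seg:
                    best = ORFRecord(parent_id, frame, start,
                                     start + len(seg), seg)
            pos += len(segment) + 1
    if best is None or len(best.aa_seq) < min_orf_aa:
        return None
    return best


def translate_db(transcripts, min_orf_aa: int = 30,
                 require_start: bool = False) -> dict[str, str]:
    """Longest-ORF protein database from a transcript collection."""
    db = {}
    for rec in transcripts:
        if len(rec.seq) < 3:
            continue
        orf = longest_orf(six_frame_translate(rec.seq), rec.id,
                          min_orf_aa, require_start)
        if orf is not None:
            db[rec.id] = orf.aa_seq
    return db


# --------------------------------------------------------------------------
# Predictor output parsing
# --------------------------------------------------------------------------

def parse_predictions(path: str | Path, dialect: str) -> list[TMPrediction]:
    """Parse a topology-predictor summary file.

    Dialects (all whitespace/tab-separated, ``#`` comments skipped):

    ``phobius``
        ``id  n_tm  sp  topology`` where ``sp`` is ``0`` or ``Y``
        (optionally ``Y:<end>`` giving the signal-peptide end, 1-based).
    ``tmhmm``
        key=value summary lines; ``PredHel=N`` carries the TM count and
        ``Topology=...`` the topology string.
    ``sosui``
        ``id  n_tm  kind`` with kind MEMBRANE or SOLUBLE.
    """
    if dialect not in ("phobius", "tmhmm", "sosui"):
        raise ValueError(f"unknown dialect {dialect!r}")
    preds: list[TMPrediction] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                preds.append(_parse_pred_line(line, dialect))
            except Exception as exc:
                raise ValueError(f"{path}:{lineno}: malformed line ({exc})")
    return preds


def _parse_pred_line(line: str, dialect: str) -> TMPrediction:
    fields = line.split()
    if dialect == "phobius":
        pid, n_tm, sp = fields[0], int(fields[1]), fields[2]
        topo = fields[3] if len(fields) > 3 else ""
        sp_iv = None
        if sp.startswith("Y"):
            end = int(sp.split(":")[1]) if ":" in sp else 22
            sp_iv = (0, end)
        return TMPrediction("phobius", pid, n_tm, topo, sp_iv)
    if dialect == "tmhmm":
        pid = fields[0]
        kv = dict(f.split("=", 1) for f in fields[1:] if "=" in f)
        return TMPrediction("tmhmm", pid, int(kv["PredHel"]),
                            kv.get("Topology", ""))
    pid, n_tm = fields[0], int(fields[1])
    kind = fields[2] if len(fields) > 2 else ""
    return TMPrediction("sosui", pid, n_tm, kind)


# --------------------------------------------------------------------------
# Signal-peptide masking and built-in hydropathy predictor
# --------------------------------------------------------------------------

def mask_signal_peptide(aa_seq: str,
                        sp_interval: tuple[int, int] | None) -> str:
    """Remove an N-terminal signal peptide (prefix truncation)."""
    if sp_interval is None:
        return aa_seq
    start, end = sp_interval
    if start != 0:
        raise ValueError("signal peptides are N-terminal: interval must "
                         "start at 0")
    if end > len(aa_seq):
        raise ValueError("signal-peptide interval beyond sequence end")
    return aa_seq[end:]


def builtin_hydropathy_predict(aa_seq: str, protein_id: str = "",
                               window: int = 19,
                               threshold: float = 1.6,
                               min_separation: int = 5) -> TMPrediction:
    """Sliding-window Kyte-Doolittle TM-segment caller.

    Window means above ``threshold`` mark candidate membrane-spanning
    positions; maximal runs of above-threshold windows separated by at
    least ``min_separation`` residues each count as one TM segment.
    """
    if len(aa_seq) < window:
        return TMPrediction("builtin", protein_id, 0, topology="too_short")
    values = [KYTE_DOOLITTLE.get(a.upper(), 0.0) for a in aa_seq]
    acc = [0.0]
    for v in values:
        acc.append(acc[-1] + v)
    above = [(acc[i + window] - acc[i]) / window > threshold
             for i in range(len(values) - window + 1)]
    segments = 0
    last_end = None
    i = 0
    while i < len(above):
        if above[i]:
            run_start = i
            while i < len(above) and above[i]:
                i += 1
            if last_end is not None and run_start - last_end < min_separation:
                pass   # merged with the previous run
            else:
                segments += 1
            last_end = i
        else:
            i += 1
    return TMPrediction("builtin", protein_id, segments)


def run_builtin_panel(aa_db: Mapping[str, str],
                      phobius_sp: Mapping[str, tuple[int, int]] | None = None,
                      **kwargs) -> dict[str, dict[str, TMPrediction]]:
    """Emulate the three-predictor run with the built-in caller.

    The first pass also reports signal peptides (``phobius_sp`` supplies
    them when known); the second and third passes see the SP-masked
    sequence, mirroring the external-tool ordering.
    """
    phobius_sp = phobius_sp or {}
    out: dict[str, dict[str, TMPrediction]] = {}
    for pid, seq in aa_db.items():
        sp = phobius_sp.get(pid)
        first = builtin_hydropathy_predict(seq, pid, **kwargs)
        first = TMPrediction("phobius", pid, first.n_tm, first.topology, sp)
        masked = mask_signal_peptide(seq, sp)
        second = builtin_hydropathy_predict(masked, pid, **kwargs)
        out[pid] = {
            "phobius": first,
            "tmhmm": TMPrediction("tmhmm", pid, second.n_tm, second.topology),
            "sosui": TMPrediction("sosui", pid, second.n_tm, second.topology),
        }
    return out


# --------------------------------------------------------------------------
# Consensus and redundancy removal
# --------------------------------------------------------------------------

def consensus_and_dedupe(predictions: Mapping[str, Mapping[str, TMPrediction]],
                         aa_db: Mapping[str, str],
                         id_threshold: float = 95.0,
                         cov_threshold: float = 90.0,
                         min_votes: int = 2) -> list[ConsensusRecord]:
    """2-of-3 consensus TM calling followed by redundancy removal.

    A protein is accepted when at least ``min_votes`` predictors report one
    or more TM segments.  Among accepted proteins, a greedy keep-longest
    clustering marks a shorter sequence redundant when it aligns within a
    longer one at identity >= ``id_threshold`` over >= ``cov_threshold``
    percent of its own length (semi-global edit-distance alignment).
    Proteins with fewer than two predictions are excluded.
    """
    records: dict[str, ConsensusRecord] = {}
    for pid in sorted(predictions):
        preds = predictions[pid]
        if len(preds) < 2:
            continue
        votes = {name: p.n_tm for name, p in sorted(preds.items())}
        accepted = sum(1 for n in votes.values() if n >= 1) >= min_votes
        records[pid] = ConsensusRecord(pid, votes, accepted)

    accepted_ids = [pid for pid, r in records.items() if r.accepted
                    and pid in aa_db]
    accepted_ids.sort(key=lambda p: (-len(aa_db[p]), p))
    representatives: list[str] = []
    for pid in accepted_ids:
        seq = aa_db[pid]
        owner = None
        for rep in representatives:
            if _is_redundant(seq, aa_db[rep], id_threshold, cov_threshold):
                owner = rep
                break
        if owner is None:
            representatives.append(pid)
        else:
            r = records[pid]
            records[pid] = ConsensusRecord(pid, r.votes, True, owner)
    return [records[pid] for pid in sorted(records)]


def _is_redundant(short: str, long: str, id_threshold: float,
                  cov_threshold: float) -> bool:
    if len(short) > len(long):
        return False
    # infix alignment covers the whole shorter sequence (coverage 100%)
    if cov_threshold > 100.0:
        return False
    res = edlib.align(short, long, mode="HW", task="distance")
    dist = res["editDistance"]
    identity = 100.0 * (len(short) - dist) / len(short)
    return identity >= id_threshold


def consensus_table(records: Sequence[ConsensusRecord],
                    aa_db: Mapping[str, str]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "Sequence_ID": r.protein_id,
            "Length_aa": len(aa_db.get(r.protein_id, "")),
            **{f"{k}_TM": v for k, v in r.votes.items()},
            "accepted": int(r.accepted),
            "redundant_of": r.redundant_of or "",
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Annotation tallies
# --------------------------------------------------------------------------

def annotation_tally(accepted: Iterable[str],
                     annotation_table: Mapping[str, Iterable[str]],
                     top_k: int = 10) -> pd.DataFrame:
    """Top-k annotation frequency table over an accepted protein set.

    Counts each (protein, annotation) pair once; rows are sorted by
    descending count (ties alphabetically) and carry the cumulative
    fraction of all assignments.
    """
    counts: dict[str, int] = {}
    for pid in accepted:
        for ann in set(annotation_table.get(pid, ())):
            counts[ann] = counts.get(ann, 0) + 1
    if not counts:
        return pd.DataFrame(columns=["annotation", "count", "cum_fraction"])
    total = sum(counts.values())
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
    df = pd.DataFrame(rows, columns=["annotation", "count"])
    df["cum_fraction"] = df["count"].cumsum() / total
    return df
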