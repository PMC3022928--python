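"""Domain types, file-format readers/writers, and coordinate normalization.

All coordinates inside the package are 0-based half-open on the forward
strand of each sequence; conversion to/from 1-based or reversed conventions
happens only in this module, at the I/O boundary.  Strand is a property of
the query/target pair: target coordinates are always forward-strand, and
``strand == '-'`` means the query aligns to the reverse complement of the
target (PSL semantics).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or amino-acid sequence with an optional set label."""

    id: str
    seq: str
    set_label: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"SequenceRecord {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class HSP:
    """One local alignment segment between a query and a target sequence.

    Coordinates are 0-based half-open on the forward strand of each side.
    ``strand`` is the orientation of the query relative to the target.
    ``evalue`` and ``similarity_pct`` are populated only by dialects that
    report them (BLAST tabular); ``score`` carries the bit score (BLAST) or
    the match count (PSL).
    """

    query_id: str
    target_id: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    strand: str = "+"
    identity_pct: float = 100.0
    aln_len: int = 0
    score: float = 0.0
    evalue: float | None = None
    similarity_pct: float | None = None

    def __post_init__(self):
        if not (self.q_start < self.q_end):
            raise ValueError(f"HSP {self.query_id}/{self.target_id}: q_start >= q_end")
        if not (self.t_start < self.t_end):
            raise ValueError(f"HSP {self.query_id}/{self.target_id}: t_start >= t_end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if not (0.0 <= self.identity_pct <= 100.0):
            raise ValueError("identity_pct outside [0, 100]")
        if self.aln_len < 1:
            object.__setattr__(self, "aln_len", self.q_end - self.q_start)

    @property
    def q_len(self) -> int:
        return self.q_end - self.q_start

    @property
    def t_len(self) -> int:
        return self.t_end - self.t_start


@dataclass
class Chain:
    """An ordered, strand-consistent set of collinear HSPs for one
    (query, target) pair, sorted by query start."""

    query_id: str
    target_id: str
    strand: str
    hsps: list[HSP]
    covered_qbp: int = 0
    min_identity_pct: float = 100.0

    def __post_init__(self):
        for h in self.hsps:
            if (h.query_id, h.target_id, h.strand) != (
                self.query_id, self.target_id, self.strand
            ):
                raise ValueError("chain members must share query, target and strand")
        self.hsps = sorted(self.hsps, key=lambda h: (h.q_start, h.q_end))
        if not self.covered_qbp:
            self.covered_qbp = interval_union_len(
                [(h.q_start, h.q_end) for h in self.hsps]
            )
        if self.hsps:
            self.min_identity_pct = min(h.identity_pct for h in self.hsps)

    def __len__(self) -> int:
        return len(self.hsps)

    @property
    def q_span(self) -> tuple[int, int]:
        return self.hsps[0].q_start, max(h.q_end for h in self.hsps)

    @property
    def t_span(self) -> tuple[int, int]:
        return min(h.t_start for h in self.hsps), max(h.t_end for h in self.hsps)


def interval_union_len(intervals: Iterable[tuple[int, int]]) -> int:
    """Total length of the union of half-open intervals."""
    total = 0
    end = None
    for s, e in sorted(intervals):
        if end is None or s > end:
            total += e - s
            end = e
        elif e > end:
            total += e - end
            end = e
    return total


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------

def read_fasta(path: str | Path, set_label: str = "") -> list[SequenceRecord]:
    """Read a multi-record FASTA file, preserving order and case."""
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        if len(rec.seq) == 0:
            raise FormatError(f"{path}: record {rec.id!r} has empty sequence")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq), set_label))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


# --------------------------------------------------------------------------
# HSP tables
# --------------------------------------------------------------------------

_PSL_NCOLS = 21


def read_hsp_table(path: str | Path, dialect: str,
                   seq_lens: dict[str, int] | None = None) -> list[HSP]:
    """Read an HSP table, normalizing coordinates to the internal convention.

    Supported dialects:

    ``psl``
        21-column BLAT PSL (header auto-skipped).  Coordinates are already
        0-based half-open on the forward strands; identity is computed as
        matches / (matches + mismatches).
    ``blast_tab``
        BLAST ``-outfmt 6`` (12 columns, optionally a 13th with the
        positives/similarity percentage).  Coordinates are 1-based inclusive;
        a reversed coordinate pair signals the minus strand.

    If ``seq_lens`` is given, an HSP whose interval exceeds the stated
    sequence length raises :class:`FormatError`.
    """
    if dialect not in ("psl", "blast_tab"):
        raise ValueError(f"unknown dialect {dialect!r}")
    hsps: list[HSP] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if dialect == "psl" and _is_psl_header(line):
                continue
            try:
                if dialect == "psl":
                    h = _parse_psl_row(line)
                else:
                    h = _parse_blast_tab_row(line)
            except FormatError:
                raise
            except Exception as exc:
                raise FormatError(f"{path}:{lineno}: unparseable line ({exc})")
            if seq_lens is not None:
                _check_bounds(h, seq_lens, f"{path}:{lineno}")
            hsps.append(h)
    return hsps


def _is_psl_header(line: str) -> bool:
    fields = line.split("\t")
    if len(fields) != _PSL_NCOLS:
        return True
    try:
        int(fields[0])
    except ValueError:
        return True
    return False


def _parse_psl_row(line: str) -> HSP:
    f = line.split("\t")
    if len(f) != _PSL_NCOLS:
        raise ValueError(f"expected {_PSL_NCOLS} columns, got {len(f)}")
    matches, mismatches = int(f[0]), int(f[1])
    strand = f[8][0]
    q_name, q_start, q_end = f[9], int(f[11]), int(f[12])
    t_name, t_start, t_end = f[13], int(f[15]), int(f[16])
    if q_end - q_start <= 0 or t_end - t_start <= 0:
        raise FormatError(f"non-positive interval for {q_name}/{t_name}")
    denom = matches + mismatches
    identity = 100.0 * matches / denom if denom else 100.0
    return HSP(q_name, t_name, q_start, q_end, t_start, t_end, strand,
               identity_pct=identity, aln_len=q_end - q_start,
               score=float(matches))


def _parse_blast_tab_row(line: str) -> HSP:
    f = line.split("\t")
    if len(f) < 12:
        raise ValueError(f"expected >= 12 columns, got {len(f)}")
    q_name, t_name = f[0], f[1]
    pident, length = float(f[2]), int(f[3])
    qs, qe, ss, se = int(f[6]), int(f[7]), int(f[8]), int(f[9])
    evalue, bitscore = float(f[10]), float(f[11])
    q_rev, t_rev = qs > qe, ss > se
    if q_rev:
        qs, qe = qe, qs
    if t_rev:
        ss, se = se, ss
    strand = "-" if (q_rev != t_rev) else "+"
    similarity = float(f[12]) if len(f) > 12 else None
    if qe - qs < 0 or se - ss < 0:
        raise FormatError(f"negative interval for {q_name}/{t_name}")
    return HSP(q_name, t_name, qs - 1, qe, ss - 1, se, strand,
               identity_pct=pident, aln_len=length, score=bitscore,
               evalue=evalue, similarity_pct=similarity)


def _check_bounds(h: HSP, seq_lens: dict[str, int], where: str) -> None:
    qlen = seq_lens.get(h.query_id)
    tlen = seq_lens.get(h.target_id)
    if qlen is not None and h.q_end > qlen:
        raise FormatError(f"{where}: HSP exceeds query length for {h.query_id}")
    if tlen is not None and h.t_end > tlen:
        raise FormatError(f"{where}: HSP exceeds target length for {h.target_id}")


def write_hsp_table(hsps: Iterable[HSP], path: str | Path,
                    dialect: str = "blast_tab") -> None:
    """Serialize HSPs back to a table (inverse of :func:`read_hsp_table`)."""
    with open(path, "w") as fh:
        for h in hsps:
            if dialect == "blast_tab":
                qs, qe = h.q_start + 1, h.q_end
                ss, se = h.t_start + 1, h.t_end
                if h.strand == "-":
                    ss, se = se, ss
                cols = [h.query_id, h.target_id, f"{h.identity_pct:.2f}",
                        str(h.aln_len), "0", "0", str(qs), str(qe),
                        str(ss), str(se),
                        f"{h.evalue if h.evalue is not None else 0.0:.2e}",
                        f"{h.score:.1f}"]
                if h.similarity_pct is not None:
                    cols.append(f"{h.similarity_pct:.2f}")
            elif dialect == "psl":
                # minimal PSL: matches/mismatches reconstructed from identity
                n = h.aln_len
                matches = round(n * h.identity_pct / 100.0)
                cols = [str(matches), str(n - matches), "0", "0", "0", "0",
                        "0", "0", h.strand, h.query_id, "0",
                        str(h.q_start), str(h.q_end), h.target_id, "0",
                        str(h.t_start), str(h.t_end), "1",
                        f"{h.q_end - h.q_start},",
                        f"{h.q_start},", f"{h.t_start},"]
            else:
                raise ValueError(f"unknown dialect {dialect!r}")
            fh.write("\t".join(cols) + "\n")


def flip_hsp_target(h: HSP, target_len: int) -> HSP:
    """Remap an HSP onto the reverse-complemented target sequence."""
    return replace(h,
                   t_start=target_len - h.t_end,
                   t_end=target_len - h.t_start,
                   strand="-" if h.strand == "+" else "+")


# --------------------------------------------------------------------------
# GFF3
# --------------------------------------------------------------------------

def write_gff3_introns(introns: Sequence, path: str | Path) -> None:
    """Write inferred introns as GFF3 (1-based inclusive coordinates).

    Each record must expose ``target_id, t_start, t_end, strand, donor,
    acceptor, cls, source_query_id, intron_index`` (see
    :class:`estmap.splice.Intron`).  Donor/acceptor dinucleotides are already
    strand-corrected by the caller.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, intron in enumerate(introns):
            attrs = (f"ID=intron{i + 1};transcript={intron.source_query_id};"
                     f"intron_index={intron.intron_index};"
                     f"donor={intron.donor};acceptor={intron.acceptor};"
                     f"intron_class={intron.cls}")
            fh.write("\t".join([
                intron.target_id, "estmap", "intron",
                str(intron.t_start + 1), str(intron.t_end), ".",
                intron.strand, ".", attrs,
            ]) + "\n")
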