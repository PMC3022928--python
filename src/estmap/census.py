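"""Read-membership Venn across assemblies and per-set sequence statistics.

An assembly census answers two questions about competing assemblies of the
same read set: which raw reads ended up where (contig, singleton, absent)
in each assembly, and what the assembled sequence sets look like (GC
content, length distributions).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import SequenceRecord

_FRAGMENT_SUFFIX = re.compile(r"_\d+$")

#: valid placement states in a membership table
PLACEMENTS = ("contig", "singleton")


def canonical_read_id(raw_id: str) -> str:
    """Collapse a quality-clipping fragment id to its raw read id.

    Reads split into fragments carry a trailing ``_<integer>`` suffix; the
    suffix is removed once (rightmost only), so ``x_1_2`` -> ``x_1``.
    """
    if not raw_id:
        raise ValueError("empty read id")
    return _FRAGMENT_SUFFIX.sub("", raw_id, count=1)


def read_membership(path) -> pd.DataFrame:
    """Read a membership TSV with columns read_id, assembly, placement."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = {"read_id", "assembly", "placement"}
    if not expected.issubset(df.columns):
        raise ValueError(f"membership table must have columns {sorted(expected)}")
    bad = set(df["placement"]) - set(PLACEMENTS)
    if bad:
        raise ValueError(f"unknown placement states: {sorted(bad)}")
    return df


def collapse_membership(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse fragment rows to one state per (canonical read, assembly).

    A read counts as ``contig`` in an assembly if at least one of its
    fragments was assembled into a contig there; it is a ``singleton`` only
    if all of its fragments stayed singletons.
    """
    out = df.copy()
    out["read_id"] = out["read_id"].map(canonical_read_id)
    # contig takes precedence over singleton
    rank = out["placement"].map({"contig": 1, "singleton": 0})
    out = out.assign(_rank=rank)
    best = out.groupby(["read_id", "assembly"], sort=False)["_rank"].max()
    collapsed = best.map({1: "contig", 0: "singleton"}).reset_index()
    collapsed.columns = ["read_id", "assembly", "placement"]
    return collapsed


def venn3(membership: pd.DataFrame, assemblies: Sequence[str]) -> pd.DataFrame:
    """Three-way Venn of canonical read membership, split by placement.

    Returns one row per non-empty membership pattern (7 regions), with the
    total read count and a contig/singleton/mixed breakdown.  Within a
    region a read is counted as ``contig`` if it is in a contig in every
    member assembly of that region, ``singleton`` if a singleton in every
    one, and ``mixed`` otherwise.
    """
    if len(assemblies) != 3 or len(set(assemblies)) != 3:
        raise ValueError("exactly three distinct assembly labels required")
    df = collapse_membership(membership)
    df = df[df["assembly"].isin(assemblies)]
    state = df.pivot(index="read_id", columns="assembly", values="placement")
    rows = []
    for pattern in _region_patterns(assemblies):
        members = state
        for a in assemblies:
            if a in pattern:
                members = members[members[a].notna()] if a in members.columns \
                    else members.iloc[0:0]
            else:
                members = members[members[a].isna()] if a in members.columns \
                    else members
        n = len(members)
        placements = members[[a for a in assemblies if a in pattern
                              and a in members.columns]]
        all_ctg = int((placements == "contig").all(axis=1).sum()) if n else 0
        all_sgl = int((placements == "singleton").all(axis=1).sum()) if n else 0
        rows.append({
            "region": "&".join(pattern),
            "n_reads": n,
            "contig": all_ctg,
            "singleton": all_sgl,
            "mixed": n - all_ctg - all_sgl,
        })
    return pd.DataFrame(rows)


def _region_patterns(assemblies: Sequence[str]) -> list[tuple[str, ...]]:
    a, b, c = assemblies
    return [(a,), (b,), (c,), (a, b), (a, c), (b, c), (a, b, c)]


# --------------------------------------------------------------------------
# Sequence-set statistics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SetStats:
    """Per-assembly sequence statistics: counts, GC%, length summary."""

    n_seqs: int
    gc_pct: float
    len_min: int
    len_median: float
    len_max: int
    len_avg: float

    def __post_init__(self):
        assert self.len_min <= self.len_median <= self.len_max
        assert self.len_min <= self.len_avg <= self.len_max


_GC = frozenset("GCgc")
_UNAMBIG = frozenset("ACGTacgt")


def gc_percent(seqs: Iterable[str]) -> float:
    """GC% over unambiguous (ACGT) bases only; N and IUPAC codes are
    excluded from both numerator and denominator."""
    gc = total = 0
    for s in seqs:
        gc += sum(1 for b in s if b in _GC)
        total += sum(1 for b in s if b in _UNAMBIG)
    if total == 0:
        raise ValueError("no unambiguous bases")
    return 100.0 * gc / total


def set_stats(records: Sequence[SequenceRecord]) -> SetStats:
    """Summary statistics for a sequence set.

    The median for even n is the arithmetic mean of the two central
    values; the average is total bases / n exactly.
    """
    if not records:
        raise ValueError("set_stats requires at least one record")
    lengths = np.array([len(r) for r in records])
    return SetStats(
        n_seqs=len(records),
        gc_pct=gc_percent(r.seq for r in records),
        len_min=int(lengths.min()),
        len_median=float(np.median(lengths)),
        len_max=int(lengths.max()),
        len_avg=float(lengths.sum() / len(lengths)),
    )


def length_distribution(records: Sequence[SequenceRecord],
                        subsets: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Per-subset length summaries (n, quartiles, mean).

    ``subsets`` maps a subset name to the record ids it contains.  Unknown
    ids raise; quartiles use linear interpolation.
    """
    by_id = {r.id: len(r) for r in records}
    rows = []
    for name, ids in subsets.items():
        ids = list(ids)
        unknown = [i for i in ids if i not in by_id]
        if unknown:
            raise KeyError(f"subset {name!r} references unknown ids: {unknown[:3]}")
        lens = np.array([by_id[i] for i in ids], dtype=float)
        if lens.size == 0:
            raise ValueError(f"subset {name!r} is empty")
        q25, q50, q75 = np.percentile(lens, [25, 50, 75])
        rows.append({"subset": name, "n": lens.size,
                     "min": lens.min(), "q25": q25, "median": q50,
                     "q75": q75, "max": lens.max(), "mean": lens.mean()})
    return pd.DataFrame(rows)
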