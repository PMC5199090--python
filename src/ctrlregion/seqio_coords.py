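"""Sequence I/O, coordinate maps and haplotype collapsing.

This module provides the substrate every other analysis builds on: FASTA
reading/writing with a strict DNA alphabet, an alignment container,
alignment-column <-> reference-position coordinate maps (so intervals can be
expressed against a published reference genome), and collapsing of sequences
into haplotypes.

Conventions
-----------
* All coordinates are 1-based and ranges are inclusive, matching the style of
  segment tables in the mtDNA literature ("positions 001-386").
* The working alphabet is {A, C, G, T, -, N}.  Lower case and U are
  normalised on input; IUPAC ambiguity codes are collapsed to N, which is
  treated as missing data downstream.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "AlphabetError",
    "FastaParseError",
    "SeqRecord",
    "Alignment",
    "CoordinateMap",
    "HaplotypeSet",
    "read_fasta",
    "write_fasta",
    "build_coordinate_map",
    "collapse_haplotypes",
    "haplotype_report",
]

ALPHABET = frozenset("ACGT-N")
#: IUPAC ambiguity codes collapsed to N (missing) on input.
_AMBIGUITY = frozenset("RYSWKMBDHV")


class AlphabetError(ValueError):
    """A sequence contains a character outside the working alphabet."""


class FastaParseError(ValueError):
    """The input file is not well-formed FASTA."""


def _canonicalise(raw: str, record_id: str) -> str:
    """Upper-case, map U->T and ambiguity codes->N; reject anything else."""
    out = []
    for pos, ch in enumerate(raw.upper(), start=1):
        if ch == "U":
            ch = "T"
        elif ch in _AMBIGUITY or ch == "?":
            ch = "N"
        elif ch == ".":
            ch = "-"
        if ch not in ALPHABET:
            raise AlphabetError(
                f"record {record_id!r}: illegal character {ch!r} at position {pos}"
            )
        out.append(ch)
    return "".join(out)


@dataclass(frozen=True)
class SeqRecord:
    """A named DNA sequence over {A, C, G, T, -, N}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        object.__setattr__(self, "sequence", _canonicalise(self.sequence, self.id))

    def degapped(self) -> str:
        return self.sequence.replace("-", "")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Alignment:
    """An ordered set of equal-length records (a sequence matrix).

    ``records`` keeps input order; ``n_cols`` is the shared length.  Columns
    are addressed 1-based throughout.
    """

    records: list[SeqRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment must contain at least one record")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"records have unequal lengths: {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids: {dup}")

    @property
    def n_cols(self) -> int:
        return len(self.records[0])

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def record(self, record_id: str) -> SeqRecord:
        for r in self.records:
            if r.id == record_id:
                return r
        raise KeyError(f"no record with id {record_id!r}")

    def column(self, col: int) -> str:
        """The 1-based column ``col`` as a string, one character per record."""
        if not 1 <= col <= self.n_cols:
            raise IndexError(f"column {col} outside [1, {self.n_cols}]")
        return "".join(r.sequence[col - 1] for r in self.records)

    def subset(self, ids: Sequence[str]) -> "Alignment":
        """Row subset, keeping this alignment's record order."""
        wanted = set(ids)
        missing = wanted - set(self.ids)
        if missing:
            raise KeyError(f"ids not in alignment: {sorted(missing)}")
        return Alignment([r for r in self.records if r.id in wanted])

    def take_columns(self, cols: Sequence[int]) -> "Alignment":
        """Column subset (1-based, in the given order)."""
        for c in cols:
            if not 1 <= c <= self.n_cols:
                raise IndexError(f"column {c} outside [1, {self.n_cols}]")
        idx = [c - 1 for c in cols]
        return Alignment(
            [SeqRecord(r.id, "".join(r.sequence[i] for i in idx)) for r in self.records]
        )


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file into canonicalised records.

    Duplicate ids and non-FASTA content are rejected; illegal characters
    raise :class:`AlphabetError` naming the record and position.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path.name}: line {lineno}: expected '>' header, got {line.strip()[:30]!r}"
                )
            break
        else:
            raise FastaParseError(f"{path.name}: empty file")
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaParseError(f"{path.name}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(SeqRecord(rec.id, str(rec.seq)))
    if not records:
        raise FastaParseError(f"{path.name}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    """Write records as wrapped FASTA (deterministic byte output)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_alignment(path: str | Path) -> Alignment:
    """Read a FASTA file that is expected to be an alignment."""
    return Alignment(read_fasta(path))


@dataclass
class CoordinateMap:
    """Alignment-column (1-based) -> reference-position (1-based) map.

    Gap columns of the reference row are unmapped.  ``ref_start`` offsets the
    reference numbering, e.g. 15484 when columns should be reported against a
    complete mitochondrial genome whose control region starts there.
    """

    reference_id: str
    col_to_ref: dict[int, int]
    ref_start: int = 1
    _ref_to_col: dict[int, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        vals = list(self.col_to_ref.values())
        if vals != sorted(vals) or len(set(vals)) != len(vals):
            raise ValueError("mapped reference positions must be strictly increasing")
        self._ref_to_col = {v: k for k, v in self.col_to_ref.items()}

    def to_reference(self, col: int) -> int:
        try:
            return self.col_to_ref[col]
        except KeyError:
            raise KeyError(
                f"column {col} is a gap in reference {self.reference_id!r} (unmapped)"
            ) from None

    def to_column(self, ref_pos: int) -> int:
        try:
            return self._ref_to_col[ref_pos]
        except KeyError:
            raise KeyError(f"reference position {ref_pos} not mapped") from None

    def __len__(self) -> int:
        return len(self.col_to_ref)


def build_coordinate_map(
    aln: Alignment, reference_id: str, ref_start: int = 1
) -> CoordinateMap:
    """Map alignment columns onto ungapped positions of one reference row.

    Column ``c`` maps to ``ref_start - 1 +`` (number of non-gap reference
    characters in columns 1..c) whenever column ``c`` itself is non-gap in
    the reference.  An all-gap reference row yields an empty map with a
    warning.
    """
    ref = aln.record(reference_id)  # KeyError if absent
    mapping: dict[int, int] = {}
    count = 0
    for col, ch in enumerate(ref.sequence, start=1):
        if ch != "-":
            count += 1
            mapping[col] = ref_start - 1 + count
    if not mapping:
        warnings.warn(
            f"reference row {reference_id!r} is all gaps; coordinate map is empty",
            stacklevel=2,
        )
    return CoordinateMap(reference_id, mapping, ref_start)


@dataclass
class HaplotypeSet:
    """Sequences collapsed to unique strings over the analysed columns.

    ``haplotypes`` is ordered by first occurrence; ``assignment`` maps every
    input id to its haplotype index (0-based).
    """

    haplotypes: list[tuple[str, list[str]]]
    assignment: dict[str, int]

    @property
    def h(self) -> int:
        return len(self.haplotypes)

    def members(self, index: int) -> list[str]:
        return self.haplotypes[index][1]


def collapse_haplotypes(
    aln: Alignment,
    site_mask: Sequence[int] | None = None,
    gaps_as_state: bool = True,
) -> HaplotypeSet:
    """Collapse records into haplotypes on the analysed column set.

    Identity is exact string identity over ``site_mask`` (all columns when
    ``None``); haplotypes are numbered by first occurrence, so the result is
    deterministic and the count is invariant to record order.  With
    ``gaps_as_state`` (default) an indel difference separates haplotypes —
    appropriate for control regions where species differ by diagnostic
    deletions; with it off, every column carrying a gap in any record is
    dropped from the comparison, so indels can never separate haplotypes.

    N is intended as missing data: summaries that exclude N-bearing columns
    (complete deletion) pass the corresponding mask here so that an N can
    never create or mask a haplotype difference.
    """
    if site_mask is not None:
        cols = sorted(set(site_mask))
        if not cols:
            raise ValueError("site_mask must be non-empty")
        if cols[0] < 1 or cols[-1] > aln.n_cols:
            raise IndexError(
                f"site_mask outside [1, {aln.n_cols}]: {cols[0]}..{cols[-1]}"
            )
    else:
        cols = list(range(1, aln.n_cols + 1))
    idx = [c - 1 for c in cols]
    if not gaps_as_state:
        idx = [i for i in idx if all(r.sequence[i] != "-" for r in aln.records)]

    keyed: dict[str, int] = {}
    haplotypes: list[tuple[str, list[str]]] = []
    assignment: dict[str, int] = {}
    for rec in aln.records:
        key = "".join(rec.sequence[i] for i in idx)
        if key not in keyed:
            keyed[key] = len(haplotypes)
            haplotypes.append((key, []))
        hap_i = keyed[key]
        haplotypes[hap_i][1].append(rec.id)
        assignment[rec.id] = hap_i
    return HaplotypeSet(haplotypes, assignment)


def haplotype_report(hs: HaplotypeSet):
    """Tabular haplotype report (one row per haplotype).

    Columns: haplotype_index, n_members, member_ids (comma-joined),
    sequence_md5.  Returned as a pandas DataFrame; write with
    ``df.to_csv(path, sep="\\t", index=False)``.
    """
    import pandas as pd

    rows = []
    for i, (seq, members) in enumerate(hs.haplotypes):
        rows.append(
            {
                "haplotype_index": i,
                "n_members": len(members),
                "member_ids": ",".join(members),
                "sequence_md5": hashlib.md5(seq.encode()).hexdigest(),
            }
        )
    return pd.DataFrame(rows)


def to_biopython(aln: Alignment) -> list[_BioSeqRecord]:
    """Convert to Biopython records (for interop with external tools)."""
    return [_BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in aln.records]
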