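"""Sequence and alignment I/O plus alignment/ungapped coordinate bookkeeping.

All coordinates inside the toolkit are 0-based half-open.  Conversion to the
1-based inclusive convention used in human-readable reports happens only at
the reporting boundary; BED output stays 0-based half-open.

Gap dialects '-' and '.' are both accepted on input and normalised to '-'.
IUPAC ambiguity codes are retained verbatim (uppercased); downstream scoring
treats them as mismatching any specific base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

if TYPE_CHECKING:  # pragma: no cover
    from pestid.regions import VariableRegion

IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")
GAP = "-"
_GAP_CHARS = frozenset("-.")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input (empty file, duplicate ids, bad residues)."""


class AlignmentFormatError(ValueError):
    """Raised when an alignment file violates the equal-length contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single named nucleotide sequence, residues uppercased and validated."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaParseError("sequence record with empty id")
        bad = set(self.residues) - IUPAC_CODES - _GAP_CHARS
        if bad:
            raise FastaParseError(
                f"record '{self.id}': non-IUPAC characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "").replace(".", "")


@dataclass(frozen=True)
class CoordinateMap:
    """Bidirectional map between alignment columns and one species' ungapped positions.

    ``col_to_pos[c]`` is the 0-based ungapped position of column ``c``, or -1
    when the species has a gap there.  ``pos_to_col[p]`` is the alignment
    column holding ungapped position ``p``.  ``ungapped_before[c]`` counts
    non-gap columns strictly left of ``c`` (length ncols+1), which projects
    half-open column intervals onto half-open ungapped intervals.
    """

    species: str
    col_to_pos: np.ndarray
    pos_to_col: np.ndarray
    ungapped_before: np.ndarray

    @classmethod
    def from_aligned(cls, species: str, aligned: str) -> "CoordinateMap":
        arr = np.frombuffer(aligned.encode(), dtype="S1")
        is_base = arr != b"-"
        cum = np.concatenate(([0], np.cumsum(is_base)))
        col_to_pos = np.where(is_base, cum[:-1], -1).astype(np.int64)
        pos_to_col = np.flatnonzero(is_base).astype(np.int64)
        return cls(species, col_to_pos, pos_to_col, cum.astype(np.int64))

    def project_interval(self, col_start: int, col_end: int) -> tuple[int, int]:
        """Project a half-open column interval onto ungapped coordinates."""
        return int(self.ungapped_before[col_start]), int(self.ungapped_before[col_end])

    def columns_of(self, pos_start: int, pos_end: int) -> tuple[int, int]:
        """Smallest half-open column interval containing ungapped [pos_start, pos_end).

        The returned span may include columns that are gaps in this species
        (insertions in other species) strictly between the end positions.
        """
        if pos_start < 0 or pos_end > len(self.pos_to_col) or pos_start >= pos_end:
            raise IndexError(
                f"interval [{pos_start},{pos_end}) out of range for species "
                f"'{self.species}' of ungapped length {len(self.pos_to_col)}"
            )
        return int(self.pos_to_col[pos_start]), int(self.pos_to_col[pos_end - 1]) + 1


@dataclass
class Msa:
    """An in-memory multiple sequence alignment with per-species coordinate maps."""

    records: list[SequenceRecord]
    ncols: int
    _maps: dict[str, CoordinateMap] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise AlignmentFormatError("an alignment needs at least 2 sequences")
        for rec in self.records:
            if len(rec) != self.ncols:
                raise AlignmentFormatError(
                    f"record '{rec.id}' has length {len(rec)}, expected {self.ncols}"
                )
        if not self._maps:
            self._maps = {
                r.id: CoordinateMap.from_aligned(r.id, r.residues) for r in self.records
            }

    @property
    def species_ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def nrows(self) -> int:
        return len(self.records)

    def record(self, species: str) -> SequenceRecord:
        for r in self.records:
            if r.id == species:
                return r
        raise KeyError(f"species '{species}' not in alignment")

    def coordinate_map(self, species: str) -> CoordinateMap:
        try:
            return self._maps[species]
        except KeyError:
            raise KeyError(f"species '{species}' not in alignment") from None

    def ungapped(self, species: str) -> str:
        return self.record(species).ungapped

    def column(self, c: int) -> str:
        return "".join(r.residues[c] for r in self.records)


def _normalise(seq: str) -> str:
    return seq.upper().replace(".", "-")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into validated records.

    Raises :class:`FastaParseError` on an empty file, duplicate ids or
    non-IUPAC residues (the error names the offending record and, for bad
    residues, the 1-based file line).
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for bio in SeqIO.parse(str(path), "fasta"):
        residues = _normalise(str(bio.seq))
        if bio.id in seen:
            raise FastaParseError(f"{path}: duplicate sequence id '{bio.id}'")
        seen.add(bio.id)
        desc = bio.description[len(bio.id):].strip() if bio.description else ""
        try:
            records.append(SequenceRecord(id=bio.id, residues=residues, description=desc))
        except FastaParseError as exc:
            line = _locate_bad_line(path, bio.id)
            raise FastaParseError(f"{path}:{line}: {exc}") from None
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def _locate_bad_line(path: Path, rec_id: str) -> int:
    """Best-effort 1-based line number of the first bad residue in a record."""
    in_rec = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith(">"):
            in_rec = line[1:].split()[0] == rec_id if line[1:].strip() else False
            continue
        if in_rec:
            residues = _normalise(line.strip())
            if set(residues) - IUPAC_CODES - _GAP_CHARS:
                return lineno
    return 0


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_alignment(path: str | Path) -> Msa:
    """Read an aligned FASTA file (gaps '-' or '.') into an :class:`Msa`."""
    records = read_fasta(path)
    lengths = {len(r) for r in records}
    if len(lengths) > 1:
        detail = ", ".join(f"{r.id}:{len(r)}" for r in records)
        raise AlignmentFormatError(f"{path}: ragged alignment ({detail})")
    return Msa(records=records, ncols=lengths.pop())


def msa_from_strings(pairs: Sequence[tuple[str, str]]) -> Msa:
    """Build an Msa directly from (id, aligned-residues) pairs (test/synthetic helper)."""
    records = [SequenceRecord(id=i, residues=_normalise(s)) for i, s in pairs]
    if not records:
        raise AlignmentFormatError("empty alignment")
    return Msa(records=records, ncols=len(records[0]))


def write_regions_bed(
    regions: "Sequence[VariableRegion]", species: str, path: str | Path
) -> None:
    """Write variable regions projected onto one species as BED6 (0-based half-open)."""
    lines = []
    for region in regions:
        if species not in region.projections:
            raise KeyError(f"region {region.label} has no projection for '{species}'")
        start, end = region.projections[species]
        lines.append(f"{species}\t{start}\t{end}\t{region.label}\t0\t+")
    Path(path).write_text("".join(line + "\n" for line in lines))
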