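"""FASTA alignment input/output and the package's internal alignment container.

All downstream statistics operate on pre-aligned, equal-length, gapped
nucleotide sequences sharing one column coordinate system. Sequences are
stored uppercase with RNA ``U`` normalised to ``T``; gaps are preserved
verbatim and never realigned.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Alignment",
    "AlignmentError",
    "FastaParseError",
    "AlignmentShapeError",
    "read_alignment",
    "write_fasta",
]

#: Characters accepted in input sequences (after uppercasing and U->T):
#: the four bases, gap, and IUPAC ambiguity codes including N.
ALLOWED_CHARS = frozenset("ACGTNRYSWKMBDHV-")


class AlignmentError(ValueError):
    """Invalid alignment content (characters, ids, emptiness)."""


class FastaParseError(AlignmentError):
    """The input could not be parsed as multi-FASTA."""


class AlignmentShapeError(AlignmentError):
    """Sequences do not share a single column coordinate system."""


def _normalize(seq_id: str, raw: str) -> str:
    seq = str(raw).upper().replace("U", "T")
    bad = set(seq) - ALLOWED_CHARS
    if bad:
        raise AlignmentError(
            f"record {seq_id!r} contains unsupported characters: "
            f"{''.join(sorted(bad))!r} (allowed: ACGTU, gap '-', N and IUPAC codes)"
        )
    return seq


class Alignment:
    """An ordered, validated multiple sequence alignment.

    Parameters
    ----------
    records
        Iterable of ``(id, sequence)`` pairs. Sequences are uppercased and
        ``U`` is rewritten to ``T`` on construction.

    Raises
    ------
    AlignmentError
        Empty record list, duplicate ids, or disallowed characters.
    AlignmentShapeError
        Sequences of unequal length (names the offending record).
    """

    __slots__ = ("_records", "_index")

    def __init__(self, records: Iterable[tuple[str, str]]):
        pairs = [(str(i), _normalize(str(i), s)) for i, s in records]
        if not pairs:
            raise AlignmentError("alignment must contain at least one record")
        ref_id, ref_seq = pairs[0]
        if len(ref_seq) == 0:
            raise AlignmentError(f"record {ref_id!r} has an empty sequence")
        for rec_id, seq in pairs[1:]:
            if len(seq) != len(ref_seq):
                raise AlignmentShapeError(
                    f"record {rec_id!r} has length {len(seq)}, expected "
                    f"{len(ref_seq)} (from record {ref_id!r})"
                )
        index: dict[str, int] = {}
        for pos, (rec_id, _) in enumerate(pairs):
            if rec_id in index:
                raise AlignmentError(f"duplicate sequence id {rec_id!r}")
            index[rec_id] = pos
        self._records: tuple[tuple[str, str], ...] = tuple(pairs)
        self._index = index

    @property
    def records(self) -> tuple[tuple[str, str], ...]:
        return self._records

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(i for i, _ in self._records)

    @property
    def sequences(self) -> tuple[str, ...]:
        return tuple(s for _, s in self._records)

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self._records[0][1])

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self._records)

    def __getitem__(self, key: int | str) -> tuple[str, str]:
        if isinstance(key, str):
            return self._records[self._index[key]]
        return self._records[key]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return self._records == other._records

    def __hash__(self) -> int:
        return hash(self._records)

    def __repr__(self) -> str:
        return f"Alignment({len(self)} records x {self.length} columns)"


def read_alignment(path: str | Path) -> Alignment:
    """Read a multi-FASTA alignment from *path*.

    Record order is preserved; sequences are normalised (uppercase, U->T).
    Line wrapping in the FASTA body is irrelevant.
    """
    path = Path(path)
    with open(path) as handle:
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")]
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return Alignment(records)


def write_fasta(aln: Alignment, path: str | Path, wrap: int = 60) -> None:
    """Write *aln* as multi-FASTA to *path* (wrapped at *wrap* columns)."""
    records = [
        SeqRecord(Seq(seq), id=rec_id, description="") for rec_id, seq in aln
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=wrap)
        writer.write_file(records)
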