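"""Aligned-sequence container and FASTA I/O.

Sequences are stored upper-cased over IUPAC DNA symbols plus ``-`` for
alignment gaps.  Coordinates are 0-based half-open everywhere in the
library; converters to 1-based inclusive exist only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IUPAC_DNA = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


@dataclass(frozen=True)
class Alignment:
    """An immutable multiple sequence alignment.

    Parameters
    ----------
    ids
        Unique sequence labels, in display order.
    rows
        Equal-length strings over IUPAC DNA symbols plus ``-``.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "rows", tuple(r.upper() for r in self.rows))
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in number")
        if len(self.ids) < 2:
            raise ValueError("an alignment needs at least 2 sequences")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        allowed = set(IUPAC_DNA) | {"-", "?"}
        for sid, row in zip(self.ids, self.rows):
            bad = set(row) - allowed
            if bad:
                raise ValueError(f"{sid}: illegal symbols {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def __len__(self) -> int:
        return len(self.ids)

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"unknown sequence id: {seq_id}") from None

    def items(self) -> Iterable[tuple[str, str]]:
        return zip(self.ids, self.rows)

    def subset(self, ids: Sequence[str]) -> "Alignment":
        return Alignment(tuple(ids), tuple(self.row(i) for i in ids))

    def exclude_columns(self, ranges: Sequence[tuple[int, int]]) -> "Alignment":
        """Drop the 0-based half-open column ranges (ambiguous-region mask)."""
        drop = set()
        for start, end in ranges:
            if not (0 <= start <= end <= self.length):
                raise ValueError(f"mask range ({start}, {end}) out of bounds")
            drop.update(range(start, end))
        keep = [j for j in range(self.length) if j not in drop]
        return Alignment(self.ids, tuple("".join(r[j] for j in keep) for r in self.rows))

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Alignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls(tuple(r.id for r in records), tuple(str(r.seq) for r in records))

    def to_fasta(self, path: str | Path) -> None:
        records = [SeqRecord(Seq(row), id=sid, description="") for sid, row in self.items()]
        SeqIO.write(records, str(path), "fasta")
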