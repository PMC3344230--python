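"""Simple indel coding of alignment gaps into binary characters.

Gaps in an alignment are converted into presence/absence characters, one per
distinct gap extent, following the simple indel coding scheme: a sequence
scores 1 when it carries a gap run with *exactly* the character's extent, 0
when no gap of it overlaps the extent, and missing when an overlapping gap
run of a different extent makes the state undecidable.  Terminal gap runs
(touching the first or last column) usually reflect incomplete sequencing
rather than evolutionary indels, so by default they are never coded and
score missing wherever they overlap a character.

The same machinery locates a diagnostic deletion (for example the 15 bp
deletion that separates the two deep nuclear allele clades in the fern
complex this package models) via reciprocal-overlap matching.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

from reticulator.alignment import Alignment

#: sentinel for an undecidable (missing) indel state
MISSING = None

State = Literal[0, 1, None]


@dataclass(frozen=True)
class GapRun:
    """A maximal run of ``-`` in one sequence, 0-based half-open."""

    seq_id: str
    start: int
    end: int
    terminal: bool

    @property
    def extent(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class IndelCharacter:
    """One coded gap extent with a per-sequence 0/1/missing state vector."""

    start: int
    end: int
    states: dict[str, State]

    @property
    def extent(self) -> tuple[int, int]:
        return (self.start, self.end)


def find_gap_runs(aln: Alignment) -> list[GapRun]:
    """Report every maximal gap run of every sequence exactly once."""
    runs: list[GapRun] = []
    for sid, row in aln.items():
        j = 0
        n = len(row)
        while j < n:
            if row[j] == "-":
                start = j
                while j < n and row[j] == "-":
                    j += 1
                runs.append(GapRun(sid, start, j, terminal=(start == 0 or j == n)))
            else:
                j += 1
    return runs


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def simple_indel_coding(
    aln: Alignment,
    treat_terminal_gaps_as: Literal["missing", "coded"] = "missing",
) -> list[IndelCharacter]:
    """Code each distinct gap extent as one binary character.

    Characters are emitted in (start, end) lexicographic order.  With the
    default ``treat_terminal_gaps_as="missing"``, terminal runs contribute no
    characters and score missing for any character they overlap.
    """
    runs = find_gap_runs(aln)
    if treat_terminal_gaps_as == "coded":
        codable = runs
    else:
        codable = [r for r in runs if not r.terminal]
    extents = sorted({r.extent for r in codable})

    by_seq: dict[str, list[GapRun]] = {sid: [] for sid in aln.ids}
    for r in runs:
        by_seq[r.seq_id].append(r)

    characters: list[IndelCharacter] = []
    for extent in extents:
        states: dict[str, State] = {}
        for sid in aln.ids:
            state: State = 0
            for run in by_seq[sid]:
                if run.extent == extent and (
                    treat_terminal_gaps_as == "coded" or not run.terminal
                ):
                    state = 1
                    break
                if _overlaps(run.extent, extent):
                    state = MISSING
                    # keep scanning: an exact-extent run elsewhere cannot
                    # exist (runs are maximal and disjoint), so stop
                    break
            states[sid] = state
        characters.append(IndelCharacter(extent[0], extent[1], states))
    return characters


def detect_diagnostic_indel(
    seq_id: str,
    aln: Alignment,
    diagnostic: tuple[int, int],
    min_reciprocal_overlap: float = 0.8,
) -> Literal["carrier", "non_carrier", "ambiguous"]:
    """Classify one sequence against a known diagnostic gap window.

    ``carrier``: the sequence has a gap run whose reciprocal overlap with the
    window (overlap / max(run length, window length)) reaches the threshold.
    ``non_carrier``: no gap run overlaps the window.  ``ambiguous``: an
    overlapping run falls short of the threshold.
    """
    start, end = diagnostic
    if not (0 <= start < end <= aln.length):
        raise ValueError(f"diagnostic window ({start}, {end}) out of bounds")
    row = aln.row(seq_id)  # raises KeyError on unknown id
    del row
    overlapping = [
        r for r in find_gap_runs(aln) if r.seq_id == seq_id and _overlaps(r.extent, diagnostic)
    ]
    if not overlapping:
        return "non_carrier"
    window = end - start
    for run in overlapping:
        overlap = min(run.end, end) - max(run.start, start)
        if overlap / max(run.end - run.start, window) >= min_reciprocal_overlap:
            return "carrier"
    return "ambiguous"


def characters_to_tsv(characters: list[IndelCharacter], aln: Alignment, path: str | Path) -> None:
    """Write the coded matrix as TSV (columns: id then one per character)."""
    with open(path, "w") as fh:
        header = ["id"] + [f"indel_{c.start + 1}_{c.end}" for c in characters]
        fh.write("\t".join(header) + "\n")
        for sid in aln.ids:
            row = [sid] + [
                "?" if c.states[sid] is MISSING else str(c.states[sid]) for c in characters
            ]
            fh.write("\t".join(row) + "\n")


def characters_to_nexus(characters: list[IndelCharacter], aln: Alignment, path: str | Path) -> None:
    """Write a minimal NEXUS binary matrix (symbols 01, missing ?)."""
    with open(path, "w") as fh:
        fh.write("#NEXUS\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(aln)} NCHAR={len(characters)};\n")
        fh.write('  FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;\n')
        fh.write("  MATRIX\n")
        width = max((len(s) for s in aln.ids), default=1)
        for sid in aln.ids:
            states = "".join(
                "?" if c.states[sid] is MISSING else str(c.states[sid]) for c in characters
            )
            fh.write(f"    {sid:<{width}}  {states}\n")
        fh.write("  ;\nEND;\n")
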