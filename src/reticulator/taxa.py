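"""Shared domain types: dosage-ambiguous genotypes and taxon observations.

Presence/absence clone data cannot resolve allele dosage in polyploids: a
triploid seen to carry alleles X3 and Y may be X3X3Y or X3YY.  A
:class:`Genotype` therefore holds *all* candidate allele multisets of size
equal to the ploidy, under a star-notation label ("X3*Y") whenever more
than one candidate exists.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from pathlib import Path
from typing import Iterable

import pandas as pd


def _sorted_multiset(groups: Iterable[str]) -> tuple[str, ...]:
    return tuple(sorted(groups))


@dataclass(frozen=True)
class Genotype:
    """A set of candidate allele-group multisets sharing one star label."""

    candidates: frozenset[tuple[str, ...]]
    label: str

    def __post_init__(self) -> None:
        sizes = {len(c) for c in self.candidates}
        if len(sizes) != 1:
            raise ValueError("candidates of unequal ploidy")

    @property
    def ploidy(self) -> int:
        return len(next(iter(self.candidates)))

    @property
    def groups(self) -> frozenset[str]:
        """The allele groups observed (present in every candidate)."""
        return frozenset().union(*self.candidates)

    @property
    def ambiguous(self) -> bool:
        return len(self.candidates) > 1

    @classmethod
    def from_groups(cls, groups: Iterable[str], ploidy: int) -> "Genotype":
        """Build the genotype implied by observed groups at a given ploidy.

        Candidates are every multiset of size ``ploidy`` over the observed
        groups that contains each group at least once (there are
        C(ploidy-1, n_groups-1) of them).
        """
        gs = sorted(set(groups))
        if not gs:
            raise ValueError("no allele groups observed")
        if ploidy not in (2, 3, 4):
            raise ValueError(f"ploidy must be 2, 3 or 4, got {ploidy}")
        if len(gs) > ploidy:
            raise ValueError(
                f"{len(gs)} alleles cannot fit in a {ploidy}-copy genome"
            )
        extra = ploidy - len(gs)
        candidates = set()
        # distribute the extra copies over the observed groups
        for combo in combinations_with_repetition(gs, extra):
            candidates.add(_sorted_multiset(gs + list(combo)))
        if len(candidates) == 1:
            label = "".join(next(iter(candidates)))
        else:
            label = star_label(gs, ambiguous=True)
        return cls(frozenset(candidates), label)

    @classmethod
    def from_label(cls, label: str, ploidy: int) -> "Genotype":
        """Parse a star-notation label like ``X3*Y`` or ``X2X3Y``."""
        groups = parse_group_string(label.replace("*", ""))
        return cls.from_groups(groups, ploidy)


def combinations_with_repetition(items: list[str], k: int) -> Iterable[list[str]]:
    if k == 0:
        yield []
        return
    for i, item in enumerate(items):
        for rest in combinations_with_repetition(items[i:], k - 1):
            yield [item] + rest


def star_label(groups: Iterable[str], ambiguous: bool) -> str:
    gs = sorted(set(groups))
    if ambiguous and len(gs) > 1:
        return "".join(gs[:-1]) + "*" + gs[-1]
    if ambiguous:
        return gs[0] + "*"
    return "".join(gs)


def parse_group_string(text: str) -> list[str]:
    """Split a concatenated group string ("X2X3Y") into group names.

    Group names are an uppercase letter optionally followed by digits.
    """
    groups: list[str] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if not ch.isalpha():
            raise ValueError(f"cannot parse genotype label {text!r}")
        j = i + 1
        while j < len(text) and text[j].isdigit():
            j += 1
        groups.append(text[i:j])
        i = j
    return groups


def n_candidates(ploidy: int, n_groups: int) -> int:
    """Number of dosage candidates: compositions of ploidy over the groups."""
    return comb(ploidy - 1, n_groups - 1)


@dataclass
class TaxonObservation:
    """One observed individual/taxon with all evidence attached."""

    taxon_id: str
    ploidy: int
    genotype: Genotype
    haplotype: str | None = None
    reproduction: str = "apogamous"
    region: frozenset[str] = frozenset()
    phenology: str = "unknown"
    morph: str | None = None

    def __post_init__(self) -> None:
        self.region = frozenset(self.region)
        if self.genotype.ploidy != self.ploidy:
            raise ValueError(
                f"{self.taxon_id}: genotype candidates of size "
                f"{self.genotype.ploidy} but ploidy {self.ploidy}"
            )


def observations_to_frame(taxa: Iterable[TaxonObservation]) -> pd.DataFrame:
    rows = []
    for t in taxa:
        rows.append(
            {
                "taxon_id": t.taxon_id,
                "ploidy": t.ploidy,
                "genotype_label": t.genotype.label,
                "n_candidates": len(t.genotype.candidates),
                "haplotype": t.haplotype if t.haplotype is not None else "",
                "reproduction": t.reproduction,
                "region": ";".join(sorted(t.region)),
                "phenology": t.phenology,
                "morph": t.morph if t.morph is not None else "",
            }
        )
    return pd.DataFrame(rows)


def observations_from_tsv(path: str | Path) -> list[TaxonObservation]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    taxa = []
    for _, row in df.iterrows():
        ploidy = int(row["ploidy"])
        taxa.append(
            TaxonObservation(
                taxon_id=row["taxon_id"],
                ploidy=ploidy,
                genotype=Genotype.from_label(row["genotype_label"], ploidy),
                haplotype=row.get("haplotype") or None,
                reproduction=row.get("reproduction", "apogamous") or "apogamous",
                region=frozenset(r for r in row.get("region", "").split(";") if r),
                phenology=row.get("phenology", "unknown") or "unknown",
                morph=row.get("morph") or None,
            )
        )
    return taxa


def observations_to_tsv(taxa: Iterable[TaxonObservation], path: str | Path) -> None:
    observations_to_frame(taxa).to_csv(path, sep="\t", index=False)
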