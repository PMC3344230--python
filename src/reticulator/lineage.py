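"""Nuclear allele calling, genotype inference, and maternal-lineage mapping.

Cloned PCR products of a single-copy nuclear gene are collapsed into allele
calls (clusters of near-identical clones; singletons are flagged as putative
PCR/cloning artefacts and excluded from genotyping).  Each accepted allele
is placed into one of the declared allele lineage groups — first into a
major clade via a diagnostic indel, then into a subgroup by p-distance to
exemplar sequences.  Observed allele groups plus a ploidy call give a
dosage-ambiguous genotype.  Chloroplast haplotypes are clustered into deep
groups by distance, and the allele-to-haplotype correspondence (which allele
lineage was the maternal donor of which chloroplast group) is inferred by a
consistency pass followed by iterative elimination.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from reticulator.alignment import Alignment
from reticulator.indels import detect_diagnostic_indel
from reticulator.taxa import Genotype, TaxonObservation

GREEK = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta", "theta")


@dataclass(frozen=True)
class CloneSet:
    """Aligned clone sequences for one individual and one marker."""

    individual_id: str
    marker: Literal["nuclear", "chloroplast"]
    clones: tuple[tuple[str, str], ...]  # (clone_id, aligned sequence)

    def __post_init__(self) -> None:
        if not self.clones:
            raise ValueError(f"{self.individual_id}: empty clone set")
        lengths = {len(seq) for _, seq in self.clones}
        if len(lengths) != 1:
            raise ValueError(f"{self.individual_id}: clones of unequal aligned length")


@dataclass
class AlleleCall:
    allele_id: str
    sequence: str
    support: int
    clone_ids: tuple[str, ...]
    group: str = "unassigned"
    flagged_singleton: bool = False


def _gap_extents(seq: str) -> frozenset[tuple[int, int]]:
    extents = set()
    j = 0
    n = len(seq)
    while j < n:
        if seq[j] == "-":
            start = j
            while j < n and seq[j] == "-":
                j += 1
            extents.add((start, j))
        else:
            j += 1
    return frozenset(extents)


def substitution_distance(a: str, b: str) -> int | None:
    """Substitutions between two aligned sequences, or None when their gap
    extents differ (clones of different alleles, compared as coded indels)."""
    if _gap_extents(a) != _gap_extents(b):
        return None
    return sum(1 for x, y in zip(a, b) if x != y and x != "-" and y != "-")


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites over columns where both are ungapped."""
    compared = diff = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        compared += 1
        if x != y:
            diff += 1
    return diff / compared if compared else 0.0


def _majority_consensus(seqs: Sequence[str]) -> str:
    out = []
    for col in zip(*seqs):
        counts = Counter(col)
        top = max(counts.values())
        out.append(min(sym for sym, n in counts.items() if n == top))
    return "".join(out)


def collapse_clones(
    cs: CloneSet,
    max_error_mismatches: int = 2,
    min_support: int = 2,
) -> list[AlleleCall]:
    """Collapse clones into allele calls by single-linkage clustering.

    Clones within ``max_error_mismatches`` substitutions of one another
    (and with identical gap extents) are merged; each cluster yields a
    majority-rule consensus.  Clusters below ``min_support`` clones are
    flagged as singletons — putative PCR/cloning errors — and should be
    excluded from genotyping (they are still returned for audit).
    Clustering is invariant to clone input order.
    """
    clones = sorted(cs.clones)
    n = len(clones)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            d = substitution_distance(clones[i][1], clones[j][1])
            if d is not None and d <= max_error_mismatches:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)

    calls = []
    members_list = sorted(
        clusters.values(), key=lambda ms: (-len(ms), clones[ms[0]][0])
    )
    for k, members in enumerate(members_list, start=1):
        seqs = [clones[i][1] for i in members]
        consensus = _majority_consensus(seqs)
        calls.append(
            AlleleCall(
                allele_id=f"{cs.individual_id}:a{k}",
                sequence=consensus,
                support=len(members),
                clone_ids=tuple(clones[i][0] for i in members),
                flagged_singleton=len(members) < min_support,
            )
        )
    return calls


def assign_allele_group(
    allele: AlleleCall | str,
    references: Alignment,
    diagnostic: tuple[int, int],
    min_margin: float = 0.005,
    min_reciprocal_overlap: float = 0.8,
) -> str:
    """Assign an allele to a lineage group via the diagnostic indel + distance.

    ``references`` holds one exemplar per group (ids = group names), aligned
    to the same coordinates as the allele sequence.  The indel splits the
    groups into carrier/non-carrier major clades; within the matching major
    clade the nearest exemplar by p-distance wins, unless the runner-up is
    within ``min_margin`` (then ``"unassigned"``).
    """
    seq = allele.sequence if isinstance(allele, AlleleCall) else allele
    if len(seq) != references.length:
        raise ValueError("allele not aligned to the reference alignment")
    probe = Alignment(
        ("query",) + references.ids, (seq,) + references.rows
    )
    status = detect_diagnostic_indel("query", probe, diagnostic, min_reciprocal_overlap)
    if status == "ambiguous":
        return "unassigned"
    candidates = [
        g
        for g in references.ids
        if detect_diagnostic_indel(g, probe, diagnostic, min_reciprocal_overlap) == status
    ]
    if not candidates:
        return "unassigned"
    if len(candidates) == 1:
        return candidates[0]
    dists = sorted((p_distance(seq, references.row(g)), g) for g in candidates)
    if dists[1][0] - dists[0][0] < min_margin:
        return "unassigned"
    return dists[0][1]


def infer_genotype(groups: Iterable[str], ploidy: int) -> Genotype:
    """Dosage-ambiguous genotype from observed allele groups and ploidy.

    All multisets of size ``ploidy`` over the observed groups containing
    each group at least once; the star label marks dosage ambiguity
    (e.g. {X3, Y} at ploidy 3 -> "X3*Y": X3X3Y or X3YY).
    """
    return Genotype.from_groups(groups, ploidy)


@dataclass
class HaplotypeGrouping:
    """A partition of chloroplast sequences into deep haplotype groups."""

    labels: dict[str, str]  # sequence/individual id -> group label
    threshold: float
    merge_heights: tuple[float, ...]

    @property
    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sid, g in self.labels.items():
            out.setdefault(g, []).append(sid)
        return out

    @property
    def n_groups(self) -> int:
        return len(set(self.labels.values()))


def group_haplotypes(
    aln: Alignment,
    linkage_method: Literal["single", "average"] = "average",
) -> HaplotypeGrouping:
    """Cluster chloroplast haplotypes into deep groups.

    Hierarchical clustering on pairwise p-distance, cut at the midpoint of
    the largest gap in the sorted merge heights (with a leading zero, so a
    set of mutually divergent singletons still separates).  All-identical
    sequences give a single group.  Group labels (alpha, beta, ...) are
    assigned by decreasing group size, ties broken by the lexicographically
    smallest member id.
    """
    ids = aln.ids
    n = len(ids)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = p_distance(aln.rows[i], aln.rows[j])
    heights_src = linkage(squareform(dm), method=linkage_method)
    heights = sorted(float(h) for h in heights_src[:, 2])
    padded = [0.0] + heights
    gaps = [(padded[k + 1] - padded[k], k) for k in range(len(padded) - 1)]
    best_gap, best_k = max(gaps) if gaps else (0.0, 0)
    if best_gap <= 0:
        labels = {sid: GREEK[0] for sid in ids}
        return HaplotypeGrouping(labels, float("inf"), tuple(heights))
    threshold = (padded[best_k] + padded[best_k + 1]) / 2
    assignment = fcluster(heights_src, t=threshold, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for sid, c in zip(ids, assignment):
        clusters.setdefault(int(c), []).append(sid)
    ordered = sorted(clusters.values(), key=lambda ms: (-len(ms), min(ms)))
    labels = {}
    for k, members in enumerate(ordered):
        name = GREEK[k] if k < len(GREEK) else f"group{k + 1}"
        for sid in members:
            labels[sid] = name
    return HaplotypeGrouping(labels, threshold, tuple(heights))


@dataclass
class AlleleHaplotypeMap:
    """Allele-group -> haplotype-group maternal correspondence."""

    mapping: dict[str, str]
    conflicts: list[tuple[str, str, str, str]]  # (taxon, allele, expected, observed)
    ambiguous: dict[str, str]  # conflict-free but underdetermined candidates

    def get(self, allele: str) -> str | None:
        return self.mapping.get(allele)


def infer_allele_haplotype_map(
    taxa: Sequence[TaxonObservation],
    exempt: Iterable[str] = (),
) -> AlleleHaplotypeMap:
    """Infer which allele lineage donated which chloroplast group.

    Two phases, iterated to a fixpoint:

    1. direct: an allele maps to haplotype h when all its non-exempt
       carriers share h *and* in at least one carrier no co-allele is an
       equally consistent maternal candidate (uniqueness);
    2. elimination: carriers whose haplotype is already explained by a
       mapped co-allele are dropped from the evidence for the remaining
       alleles (e.g. X2 maps to alpha once the beta-carrying X2 taxa are
       explained by X4).

    Remaining all-consistent but never-unique alleles are reported as
    ambiguous candidates; inconsistent alleles produce conflict records.
    Nothing is ever guessed.
    """
    exempt_set = set(exempt)
    usable = [
        t for t in taxa if t.taxon_id not in exempt_set and t.haplotype is not None
    ]
    alleles = sorted({g for t in usable for g in t.genotype.groups})

    mapping: dict[str, str] = {}

    def active_carriers(a: str) -> list[TaxonObservation]:
        out = []
        for t in usable:
            if a not in t.genotype.groups:
                continue
            explained = any(
                mapping.get(b) == t.haplotype for b in t.genotype.groups if b != a
            )
            if not explained:
                out.append(t)
        return out

    def globally_consistent_with(b: str, h: str) -> bool:
        """Could b be the maternal donor of h?  Judged on b's full carrier
        set: an allele seen with several haplotypes cannot be the unique
        donor of any one of them."""
        haps = {t.haplotype for t in usable if b in t.genotype.groups}
        return haps == {h}

    changed = True
    while changed:
        changed = False
        for a in alleles:
            if a in mapping:
                continue
            carriers = active_carriers(a)
            if not carriers:
                continue
            haps = {t.haplotype for t in carriers}
            if len(haps) != 1:
                continue
            (h,) = haps
            unique_somewhere = False
            for t in carriers:
                others = [b for b in t.genotype.groups if b != a and b not in mapping]
                if not any(globally_consistent_with(b, h) for b in others):
                    unique_somewhere = True
                    break
            if unique_somewhere:
                mapping[a] = h
                changed = True
                break  # restart the sweep: elimination may unblock earlier alleles

    conflicts: list[tuple[str, str, str, str]] = []
    ambiguous: dict[str, str] = {}
    for a in alleles:
        if a in mapping:
            continue
        carriers = active_carriers(a)
        haps = sorted({t.haplotype for t in carriers})
        if len(haps) > 1:
            expected = haps[0]
            for t in carriers:
                if t.haplotype != expected:
                    conflicts.append((t.taxon_id, a, expected, t.haplotype))
        elif len(haps) == 1:
            ambiguous[a] = haps[0]
    return AlleleHaplotypeMap(mapping, conflicts, ambiguous)


def alleles_to_rows(individual: str, calls: Sequence[AlleleCall]) -> list[dict]:
    return [
        {
            "individual": individual,
            "allele": c.allele_id,
            "group": c.group,
            "support": c.support,
            "flagged_singleton": c.flagged_singleton,
        }
        for c in calls
    ]
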