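"""Diploids-first reconstruction of reticulate hybrid origins.

The strategy: posit one homozygous sexual diploid progenitor per nuclear
allele lineage; derive candidate sexual tetraploids by genome doubling and
genome addition; then explain every observed apogamous taxon by a single
cross, drawing mothers from sexual taxa (reduced gametes) and fathers from
sexual taxa or apogamous hybrids (unreduced gametes — apogamous plants are
functionally male only).  The maternal parent must carry the offspring's
chloroplast haplotype.  Among all feasible assignments the search keeps the
networks using the fewest presumed (unobserved) taxa, with the number of
events and a deterministic serialisation as tie-breaks; all co-optimal
networks are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from reticulator.lineage import AlleleHaplotypeMap
from reticulator.taxa import TaxonObservation


def _sorted_tuple(items: Iterable[str]) -> tuple[str, ...]:
    return tuple(sorted(items))


@dataclass(frozen=True)
class ParentTaxon:
    """A (possibly presumed) parent in the network."""

    genotype: tuple[str, ...]
    reproduction: Literal["sexual", "apogamous"]
    status: Literal["observed", "presumed"]
    haplotypes: frozenset[str] = frozenset()  # possible maternal haplotypes; empty = unknown
    provenance: tuple = ()  # ((mechanism, (source ParentTaxon, ...)), ...)
    taxon_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "genotype", _sorted_tuple(self.genotype))
        object.__setattr__(self, "haplotypes", frozenset(self.haplotypes))

    @property
    def ploidy(self) -> int:
        return len(self.genotype)

    @property
    def name(self) -> str:
        return "".join(self.genotype)

    @property
    def key(self) -> tuple:
        return (self.genotype, self.reproduction)


@dataclass(frozen=True)
class CrossEvent:
    """mother_gamete (+) father_gamete = one offspring genotype candidate."""

    mother: ParentTaxon
    mother_gamete: tuple[str, ...]
    father: ParentTaxon
    father_gamete: tuple[str, ...]
    offspring: str

    @property
    def offspring_genotype(self) -> tuple[str, ...]:
        return _sorted_tuple(self.mother_gamete + self.father_gamete)

    def describe(self) -> str:
        return (
            f"{self.offspring}: {self.mother.name} (gamete "
            f"{''.join(self.mother_gamete)}) x {self.father.name} "
            f"(gamete {''.join(self.father_gamete)})"
        )


@dataclass
class ReticulateNetwork:
    """One minimal scenario: crosses, derivations, presumed-node cost."""

    crosses: tuple[CrossEvent, ...]
    derivations: tuple[tuple[str, tuple[str, ...], str], ...]  # (mechanism, sources, result)
    progenitors: tuple[ParentTaxon, ...]
    nodes: tuple[ParentTaxon, ...]
    cost: int
    unexplained: tuple[str, ...] = ()
    co_optimal: list["ReticulateNetwork"] = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return len(self.crosses) + len(self.derivations)

    def serialization(self) -> tuple:
        return tuple(
            sorted(
                (c.offspring, c.mother.name, "".join(c.mother_gamete), c.father.name,
                 "".join(c.father_gamete))
                for c in self.crosses
            )
        ) + tuple(sorted(self.derivations))

    def maternal_ambiguity(self) -> dict[str, set[str]]:
        """Taxa whose maternal parent differs across co-optimal networks.

        A taxon listed here has a resolvable origin only up to scenario
        choice (e.g. a triploid whose haplotype conflicts with its allele
        content); callers should treat its maternal lineage as ambiguous
        rather than read it off the single best network.
        """
        mothers: dict[str, set[str]] = {}
        for net in [self] + list(self.co_optimal):
            for c in net.crosses:
                mothers.setdefault(c.offspring, set()).add(c.mother.name)
        return {tid: ms for tid, ms in mothers.items() if len(ms) > 1}

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {
                "child": c.offspring,
                "mother": c.mother.name,
                "father": c.father.name,
                "mother_gamete": "".join(c.mother_gamete),
                "father_gamete": "".join(c.father_gamete),
                "mechanism": "cross",
            }
            for c in self.crosses
        ] + [
            {
                "child": result,
                "mother": sources[0],
                "father": sources[-1],
                "mother_gamete": "",
                "father_gamete": "",
                "mechanism": mech,
            }
            for mech, sources, result in self.derivations
        ]
        return pd.DataFrame(
            rows,
            columns=["child", "mother", "father", "mother_gamete", "father_gamete", "mechanism"],
        )

    def to_graph(self):
        """Directed parent->child graph (networkx), for export/plotting."""
        import networkx as nx

        g = nx.MultiDiGraph()
        for node in self.nodes:
            g.add_node(node.name, status=node.status, reproduction=node.reproduction)
        for c in self.crosses:
            g.add_edge(c.mother.name, c.offspring, role="maternal",
                       gamete="".join(c.mother_gamete))
            g.add_edge(c.father.name, c.offspring, role="paternal",
                       gamete="".join(c.father_gamete))
        for mech, sources, result in self.derivations:
            for s in sources:
                g.add_edge(s, result, role=mech)
        return g


@dataclass
class NetworkConfig:
    """Search-time switches; defaults mirror the biological ground rules."""

    enforce_maternal_haplotype: bool = True
    unknown_mother: Literal["reject", "allow"] = "reject"
    allow_apogamous_mother: bool = False
    disomic_only: bool = False
    mechanisms: tuple[str, ...] = ("doubling", "genome_addition")
    # ploidy reduction is deliberately not an available mechanism
    max_co_optimal: int = 20
    max_nodes_explored: int = 200_000


# ---------------------------------------------------------------------
# progenitors and derived parents
# ---------------------------------------------------------------------


def hypothesize_progenitors(
    alleles: Iterable[str],
    amap: AlleleHaplotypeMap | Mapping[str, str] | None = None,
    observed: Sequence[TaxonObservation] = (),
) -> list[ParentTaxon]:
    """One homozygous sexual diploid per allele lineage (diploids-first).

    Haplotypes are attached from the allele->haplotype map where available;
    a progenitor is presumed unless an observed sexual taxon carries exactly
    its genotype.
    """
    get = amap.get if amap is not None else (lambda a: None)
    observed_keys = {}
    for t in observed:
        if t.reproduction == "sexual" and not t.genotype.ambiguous:
            observed_keys[next(iter(t.genotype.candidates))] = t
    out = []
    for a in sorted(set(alleles)):
        genotype = (a, a)
        match = observed_keys.get(genotype)
        h = get(a)
        out.append(
            ParentTaxon(
                genotype=genotype,
                reproduction="sexual",
                status="observed" if match else "presumed",
                haplotypes=frozenset({h}) if h else frozenset(),
                taxon_id=match.taxon_id if match else None,
            )
        )
    return out


def derive_sexual_tetraploids(
    diploids: Sequence[ParentTaxon],
    apogamous_diploids: Sequence[ParentTaxon] = (),
    mechanisms: Sequence[str] = ("doubling", "genome_addition"),
) -> list[ParentTaxon]:
    """Candidate sexual tetraploids by genome doubling / genome addition.

    Doubling of any diploid genotype g yields g+g (doubling an apogamous
    hybrid restores sexual reproduction); genome addition of two sexual
    diploids aa x bb yields aabb.  Duplicate genotypes are merged with
    multi-provenance; the possible maternal haplotypes of a derived
    tetraploid are those inherited through any of its provenances.
    """
    by_genotype: dict[tuple[str, ...], list[tuple[str, tuple[ParentTaxon, ...]]]] = {}
    haps: dict[tuple[str, ...], set[str]] = {}
    if "doubling" in mechanisms:
        for d in list(diploids) + list(apogamous_diploids):
            g = _sorted_tuple(d.genotype + d.genotype)
            by_genotype.setdefault(g, []).append(("doubling", (d,)))
            haps.setdefault(g, set()).update(d.haplotypes)
    if "genome_addition" in mechanisms:
        sexual = [d for d in diploids if d.reproduction == "sexual"]
        for d1, d2 in combinations(sexual, 2):
            g = _sorted_tuple(d1.genotype + d2.genotype)
            by_genotype.setdefault(g, []).append(("genome_addition", (d1, d2)))
            haps.setdefault(g, set()).update(d1.haplotypes | d2.haplotypes)
    out = []
    for g in sorted(by_genotype):
        out.append(
            ParentTaxon(
                genotype=g,
                reproduction="sexual",
                status="presumed",
                haplotypes=frozenset(haps[g]),
                provenance=tuple(by_genotype[g]),
            )
        )
    return out


# ---------------------------------------------------------------------
# crosses
# ---------------------------------------------------------------------


def reduced_gametes(
    genotype: tuple[str, ...], disomic_only: bool = False
) -> list[tuple[str, ...]]:
    """Distinct meiotic gametes of a sexual parent (half the genotype).

    Polysomic segregation by default: any size-p/2 sub-multiset.  With
    ``disomic_only``, a 2+2 tetraploid (aabb) produces only the ab gamete.
    """
    p = len(genotype)
    if p % 2 != 0:
        return []
    k = p // 2
    if disomic_only and p == 4:
        counts = sorted(set(genotype))
        if len(counts) == 2 and genotype.count(counts[0]) == 2:
            return [(counts[0], counts[1])]
    return sorted({_sorted_tuple(c) for c in combinations(genotype, k)})


def _mother_ok(
    mother: ParentTaxon,
    offspring: TaxonObservation,
    enforce: bool,
    unknown_mother: str,
) -> bool:
    if not enforce or offspring.haplotype is None:
        return True
    if not mother.haplotypes:
        return unknown_mother == "allow"
    return offspring.haplotype in mother.haplotypes


def enumerate_crosses(
    offspring: TaxonObservation,
    parent_pool: Sequence[ParentTaxon],
    enforce_maternal_haplotype: bool = True,
    unknown_mother: Literal["reject", "allow"] = "reject",
    allow_apogamous_mother: bool = False,
    disomic_only: bool = False,
) -> list[CrossEvent]:
    """All single-cross origins of one apogamous taxon from a parent pool.

    Gamete rules: a sexual parent of even ploidy p contributes any
    size-(p/2) sub-multiset of its genotype; an apogamous parent contributes
    its full genotype unreduced and may act only as father (unless
    ``allow_apogamous_mother``).  A cross qualifies when the two gametes sum
    to one of the offspring's genotype candidates and — if enforced and the
    offspring haplotype is known — the mother can carry that haplotype
    (mothers of unknown haplotype are rejected under the default policy).
    With enforcement off, role-swapped duplicates of sexual x sexual crosses
    collapse to a canonical orientation (lower ploidy, then lexicographic
    genotype, as mother).
    """
    if offspring.reproduction != "apogamous":
        raise ValueError(f"{offspring.taxon_id}: offspring must be apogamous")
    if not parent_pool:
        raise ValueError("empty parent pool")
    candidates = offspring.genotype.candidates
    pool = [p for p in parent_pool if p.taxon_id != offspring.taxon_id]

    seen: dict[tuple, CrossEvent] = {}
    for mother in pool:
        if mother.reproduction == "apogamous" and not allow_apogamous_mother:
            continue
        if not _mother_ok(mother, offspring, enforce_maternal_haplotype, unknown_mother):
            continue
        if mother.reproduction == "sexual":
            m_gametes = reduced_gametes(mother.genotype, disomic_only)
        else:
            m_gametes = [mother.genotype]
        for mg in m_gametes:
            for father in pool:
                if father.reproduction == "apogamous":
                    f_gametes = [father.genotype]
                else:
                    f_gametes = reduced_gametes(father.genotype, disomic_only)
                for fg in f_gametes:
                    if _sorted_tuple(mg + fg) not in candidates:
                        continue
                    key = (mother.key, mg, father.key, fg)
                    if not enforce_maternal_haplotype and (
                        mother.reproduction == "sexual"
                        and father.reproduction == "sexual"
                    ):
                        a = (mother.ploidy, mother.genotype, mg)
                        b = (father.ploidy, father.genotype, fg)
                        if b < a:
                            continue  # the mirrored orientation is canonical
                    if key not in seen:
                        seen[key] = CrossEvent(mother, mg, father, fg, offspring.taxon_id)
    return sorted(
        seen.values(),
        key=lambda c: (c.mother.name, "".join(c.mother_gamete), c.father.name,
                       "".join(c.father_gamete)),
    )


# ---------------------------------------------------------------------
# network search
# ---------------------------------------------------------------------


def build_parent_pool(
    observations: Sequence[TaxonObservation],
    amap: AlleleHaplotypeMap | Mapping[str, str] | None,
    config: NetworkConfig,
) -> list[ParentTaxon]:
    """Observed taxa + progenitors + presumed diploid hybrids + tetraploids.

    Entries are deduplicated by (genotype, reproduction), preferring
    observed over presumed.
    """
    alleles = sorted({g for t in observations for g in t.genotype.groups})
    progenitors = hypothesize_progenitors(alleles, amap, observations)

    pool: dict[tuple, ParentTaxon] = {}

    def add(p: ParentTaxon) -> None:
        cur = pool.get(p.key)
        if cur is None or (cur.status == "presumed" and p.status == "observed"):
            pool[p.key] = p

    for t in observations:
        for cand in sorted(t.genotype.candidates):
            add(
                ParentTaxon(
                    genotype=cand,
                    reproduction=t.reproduction,
                    status="observed",
                    haplotypes=frozenset({t.haplotype}) if t.haplotype else frozenset(),
                    taxon_id=t.taxon_id,
                )
            )
    for p in progenitors:
        add(p)
    # presumed apogamous diploid hybrids (depth-1 intermediates)
    apog_diploids = []
    for a, b in combinations(alleles, 2):
        cand = ParentTaxon(
            genotype=(a, b), reproduction="apogamous", status="presumed"
        )
        add(cand)
        apog_diploids.append(pool[cand.key])
    tetraploids = derive_sexual_tetraploids(
        progenitors, apog_diploids, config.mechanisms
    )
    for t4 in tetraploids:
        add(t4)
    return sorted(pool.values(), key=lambda p: (p.name, p.reproduction))


def _support_options(parent: ParentTaxon) -> list[tuple[int, frozenset]]:
    """Ways to make this parent available: (option id, presumed-node keys)."""
    if parent.status == "observed":
        return [(-1, frozenset())]
    if not parent.provenance:
        return [(-1, frozenset({parent.key}))]
    opts = []
    for k, (mech, sources) in enumerate(parent.provenance):
        need = {parent.key}
        need.update(s.key for s in sources if s.status == "presumed")
        opts.append((k, frozenset(need)))
    # dominated options (supersets) can never improve the union
    minimal = []
    for k, s in sorted(opts, key=lambda o: (len(o[1]), o[0])):
        if not any(prev[1] <= s for prev in minimal):
            minimal.append((k, s))
    return minimal


def infer_network(
    observations: Sequence[TaxonObservation],
    amap: AlleleHaplotypeMap | Mapping[str, str] | None = None,
    config: NetworkConfig | None = None,
) -> ReticulateNetwork:
    """Minimal-presumed-taxa reticulate network for the observed taxa.

    Branch-and-bound over one originating cross per observed apogamous
    taxon (and, for presumed tetraploid parents, over their provenance).
    Cost is the number of distinct presumed nodes used; ties break by fewer
    total events, then by a deterministic serialisation.  Taxa with no
    feasible cross are reported as unexplained, not an error.
    """
    config = config or NetworkConfig()
    observations = list(observations)
    pool = build_parent_pool(observations, amap, config)
    alleles = sorted({g for t in observations for g in t.genotype.groups})
    progenitors = tuple(hypothesize_progenitors(alleles, amap, observations))

    apogamous = [t for t in observations if t.reproduction == "apogamous"]
    cross_lists: dict[str, list[CrossEvent]] = {}
    unexplained = []
    for t in apogamous:
        crosses = enumerate_crosses(
            t,
            pool,
            enforce_maternal_haplotype=config.enforce_maternal_haplotype,
            unknown_mother=config.unknown_mother,
            allow_apogamous_mother=config.allow_apogamous_mother,
            disomic_only=config.disomic_only,
        )
        if crosses:
            cross_lists[t.taxon_id] = crosses
        else:
            unexplained.append(t.taxon_id)

    obs_hap = {t.taxon_id: t.haplotype for t in observations}
    order = sorted(cross_lists, key=lambda tid: (len(cross_lists[tid]), tid))
    # expand each cross into (cross, mother options, father options)
    expanded = {
        tid: [
            (c, _support_options(c.mother), _support_options(c.father))
            for c in cross_lists[tid]
        ]
        for tid in order
    }

    best_cost = [float("inf")]
    solutions: list[tuple[tuple[CrossEvent, ...], dict]] = []
    explored = [0]

    def dfs(i: int, used: frozenset, chosen: dict, picked: list) -> None:
        explored[0] += 1
        if explored[0] > config.max_nodes_explored:
            return
        if len(used) > best_cost[0]:
            return
        if i == len(order):
            cost = len(used)
            if cost < best_cost[0]:
                best_cost[0] = cost
                solutions.clear()
            if cost == best_cost[0] and len(solutions) < config.max_co_optimal * 4:
                solutions.append((tuple(picked), dict(chosen)))
            return
        tid = order[i]
        child_hap = obs_hap.get(tid)
        for cross, mopts, fopts in expanded[tid]:
            # a single (possibly presumed) taxon has one haplotype: once it
            # mothers an offspring of haplotype h, it cannot mother another
            # of haplotype h' in the same network
            hap_key = ("hap", cross.mother.key)
            if (
                config.enforce_maternal_haplotype
                and child_hap is not None
                and chosen.get(hap_key, child_hap) != child_hap
            ):
                continue
            for mo, mset in _consistent(mopts, cross.mother, chosen):
                for fo, fset in _consistent(fopts, cross.father, chosen):
                    new_used = used | mset | fset
                    if len(new_used) > best_cost[0]:
                        continue
                    updates = {}
                    if config.enforce_maternal_haplotype and child_hap is not None:
                        updates[hap_key] = child_hap
                    if cross.mother.status == "presumed" and cross.mother.provenance:
                        updates[cross.mother.key] = mo
                    if cross.father.status == "presumed" and cross.father.provenance:
                        updates[cross.father.key] = fo
                    new_chosen = {**chosen, **updates} if updates else chosen
                    picked.append(cross)
                    dfs(i + 1, new_used, new_chosen, picked)
                    picked.pop()

    def _consistent(opts, parent, chosen):
        if parent.status == "presumed" and parent.provenance and parent.key in chosen:
            fixed = chosen[parent.key]
            return [(k, s) for k, s in opts if k == fixed]
        return opts

    dfs(0, frozenset(), {}, [])

    if not solutions:
        return ReticulateNetwork(
            crosses=(),
            derivations=(),
            progenitors=progenitors,
            nodes=progenitors,
            cost=0,
            unexplained=tuple(sorted(set(unexplained) | set(cross_lists))),
        )

    networks = [
        _assemble(picked, chosen, progenitors, tuple(unexplained))
        for picked, chosen in solutions
    ]
    # dedupe and order deterministically: fewer events, then serialisation
    unique: dict[tuple, ReticulateNetwork] = {}
    for net in networks:
        unique.setdefault(net.serialization(), net)
    ordered = sorted(unique.values(), key=lambda n: (n.n_events, n.serialization()))
    ordered = ordered[: config.max_co_optimal]
    best = ordered[0]
    best.co_optimal = ordered[1:]
    return best


def _assemble(
    picked: tuple[CrossEvent, ...],
    chosen: dict,
    progenitors: tuple[ParentTaxon, ...],
    unexplained: tuple[str, ...],
) -> ReticulateNetwork:
    nodes: dict[tuple, ParentTaxon] = {}
    derivations = set()
    for cross in picked:
        for parent in (cross.mother, cross.father):
            nodes.setdefault(parent.key, parent)
            if parent.status == "presumed" and parent.provenance:
                k = chosen[parent.key]
                mech, sources = parent.provenance[k]
                derivations.add((mech, tuple(s.name for s in sources), parent.name))
                for s in sources:
                    nodes.setdefault(s.key, s)
    cost = sum(1 for p in nodes.values() if p.status == "presumed")
    return ReticulateNetwork(
        crosses=tuple(sorted(picked, key=lambda c: c.offspring)),
        derivations=tuple(sorted(derivations)),
        progenitors=progenitors,
        nodes=tuple(sorted(nodes.values(), key=lambda p: p.name)),
        cost=cost,
        unexplained=unexplained,
    )


# ---------------------------------------------------------------------
# regional structure
# ---------------------------------------------------------------------


@dataclass
class RegionalPartition:
    subnetworks: dict[str, pd.DataFrame]  # region -> induced edge list
    inventory: pd.DataFrame  # region x (kind, value, private)
    unplaced: tuple[str, ...]


def regional_partition(
    network: ReticulateNetwork,
    observations: Sequence[TaxonObservation],
) -> RegionalPartition:
    """Induced per-region subnetworks and shared/private inventories."""
    regions = sorted({r for t in observations for r in t.region})
    by_id = {t.taxon_id: t for t in observations}
    unplaced = tuple(sorted(t.taxon_id for t in observations if not t.region))

    edge_frame = network.edge_frame()
    subnetworks = {}
    for region in regions:
        members = {t.taxon_id for t in observations if region in t.region}
        subnetworks[region] = edge_frame[edge_frame["child"].isin(members)].reset_index(
            drop=True
        )

    presence: dict[tuple[str, str], set[str]] = {}
    for t in observations:
        for region in t.region:
            for g in sorted(t.genotype.groups):
                presence.setdefault(("allele", g), set()).add(region)
            if t.haplotype:
                presence.setdefault(("haplotype", t.haplotype), set()).add(region)
            presence.setdefault(("cytotype", f"{t.ploidy}x"), set()).add(region)
    rows = []
    for (kind, value), where in sorted(presence.items()):
        for region in sorted(where):
            rows.append(
                {
                    "region": region,
                    "kind": kind,
                    "value": value,
                    "private": len(where) == 1,
                }
            )
    inventory = pd.DataFrame(rows, columns=["region", "kind", "value", "private"])
    return RegionalPartition(subnetworks, inventory, unplaced)
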