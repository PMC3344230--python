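"""Synthetic hybrid-complex generator with known ground truth.

Emulates the statistical structure the analysis pipeline assumes: a handful
of nuclear allele lineages in two deep clades separated by a diagnostic
15-column deletion; a few divergent chloroplast haplotype groups tied to
allele lineages through maternal inheritance; hybrid individuals of ploidy
2-4 produced by crosses under the gamete rules of the reticulation module
(sexual parents give reduced gametes, apogamous parents full unreduced
genomes, fathers only); PCR-biased clone sampling with per-base errors;
two-peak flow-cytometry histograms at sample/standard ratios of 0.6 x
ploidy; and sporangium spore counts (apogamous plants: 32 with occasional
16/28).

Sequence evolution is independent per-site substitution at fixed expected
divergence (Jukes-Cantor-like), which is adequate at the few-percent
divergences being emulated.  Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from reticulator.alignment import Alignment
from reticulator.cytometry import FluorescenceHistogram
from reticulator.lineage import CloneSet
from reticulator.taxa import Genotype, TaxonObservation

BASES = "ACGT"


@dataclass(frozen=True)
class Event:
    """One generative event; refs name progenitors ("X2X2") or prior children."""

    kind: Literal["cross", "doubling"]
    mother: str
    father: str | None
    child: str
    region: str = "Taiwan"
    mother_gamete: tuple[str, ...] | None = None
    father_gamete: tuple[str, ...] | None = None


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic complex.

    Divergence defaults (0.5% within lineage, 3% between subgroups, 8%
    between the deep clades; 0.5%/4% for chloroplast) reproduce the
    well-separated clade structure the typing stage assumes; the histogram
    peak CV of 3% and the 20000-cell histograms match clean fresh-leaf
    cytometry runs.
    """

    seed: int = 0
    alleles: tuple[str, ...] = ("X1", "X2", "X3", "X4", "Y")
    deletion_clade: tuple[str, ...] = ("Y",)
    diagnostic_indel_length: int = 15
    nuclear_length: int = 600
    chloroplast_length: int = 500
    haplotype_groups: tuple[str, ...] = ("alpha", "beta", "gamma")
    allele_haplotype: dict = field(
        default_factory=lambda: {"X1": "alpha", "X2": "alpha", "X3": "gamma", "X4": "beta"}
    )
    d_within: float = 0.005
    d_between_group: float = 0.03
    d_between_clade: float = 0.08
    cp_d_within: float = 0.005
    cp_d_between: float = 0.04
    events: tuple[Event, ...] | None = None
    clones_per_individual: int = 6
    max_clones: int = 24
    pcr_bias: dict = field(default_factory=dict)  # allele -> weight (default 1.0)
    pcr_error_rate: float = 0.0005  # effective per-base error of a cloned PCR product
    standard_channel: float = 200.0
    n_channels: int = 1024
    peak_cv: float = 0.03
    histogram_cells: int = 20000
    spore_p32: float = 0.9
    n_sporangia: int = 5

    def __post_init__(self) -> None:
        if not (self.d_within < self.d_between_group < self.d_between_clade):
            raise ValueError("divergences must be ordered within < group < clade")
        if any(w <= 0 for w in self.pcr_bias.values()):
            raise ValueError("PCR bias weights must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory")

    @property
    def diagnostic_window(self) -> tuple[int, int]:
        start = self.nuclear_length // 3
        return (start, start + self.diagnostic_indel_length)


def default_events() -> tuple[Event, ...]:
    """A small complex in the spirit of the modelled fern group: four
    apogamous diploid hybrids, one genome doubling, a triploid and a
    tetraploid hybrid, spread over two regions."""
    return (
        Event("cross", "X2X2", "YY", "h1_X2Y", "Taiwan"),
        Event("cross", "X3X3", "YY", "h2_X3Y", "Taiwan"),
        Event("cross", "X1X1", "YY", "h3_X1Y", "Taiwan"),
        Event("cross", "X4X4", "YY", "h4_X4Y", "Hainan"),
        Event("doubling", "h4_X4Y", None, "t_X4X4YY", "Hainan"),
        Event("cross", "X2X2", "h2_X3Y", "h5_X2X3Y", "Taiwan"),
        Event(
            "cross", "t_X4X4YY", "h1_X2Y", "h6_X2X4YY", "Hainan",
            mother_gamete=("X4", "Y"),
        ),
    )


@dataclass
class IndividualTruth:
    genotype: tuple[str, ...]
    ploidy: int
    haplotype: str
    reproduction: str
    region: str
    label: str


@dataclass
class ResolvedEvent:
    kind: str
    mother: str
    father: str | None
    child: str
    mother_gamete: tuple[str, ...]
    father_gamete: tuple[str, ...]


@dataclass
class SimulationTruth:
    """Ground truth: progenitors, resolved events, per-individual latents."""

    progenitors: dict[str, tuple[str, ...]]
    events: tuple[ResolvedEvent, ...]
    individuals: dict[str, IndividualTruth]

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(json.dumps({"progenitors": {k: list(v) for k, v in self.progenitors.items()}}) + "\n")
            for ev in self.events:
                fh.write(json.dumps({"event": asdict(ev)}, default=list) + "\n")
            for name, ind in self.individuals.items():
                fh.write(json.dumps({"individual": name, **asdict(ind)}, default=list) + "\n")


@dataclass
class ObservationBundle:
    """Everything the pipeline consumes, in memory; `write` emits files."""

    nuclear_references: Alignment
    diagnostic_window: tuple[int, int]
    chloroplast: Alignment
    clone_sets: dict[str, CloneSet]
    histograms: dict[str, FluorescenceHistogram]
    spore_counts: dict[str, tuple[int, ...]]
    metadata: pd.DataFrame
    standard_channel: float

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.nuclear_references.to_fasta(directory / "nuclear_refs.fasta")
        self.chloroplast.to_fasta(directory / "chloroplast.fasta")
        for ind, cs in self.clone_sets.items():
            aln_rows = [seq for _, seq in cs.clones]
            ids = [cid for cid, _ in cs.clones]
            with open(directory / f"clones_{ind}.fasta", "w") as fh:
                for cid, seq in zip(ids, aln_rows):
                    fh.write(f">{ind}|{cid}\n{seq}\n")
        for ind, hist in self.histograms.items():
            hist.to_csv(directory / f"hist_{ind}.csv")
        sheet = self.metadata.copy()
        sheet["spores"] = [
            ",".join(map(str, self.spore_counts[i])) for i in sheet["individual"]
        ]
        sheet["histogram"] = [f"hist_{i}.csv" for i in sheet["individual"]]
        sheet["clones"] = [f"clones_{i}.fasta" for i in sheet["individual"]]
        sheet.to_csv(directory / "samples.tsv", sep="\t", index=False)
        manifest = {
            "diagnostic_window": list(self.diagnostic_window),
            "standard_channel": self.standard_channel,
        }
        (directory / "bundle.json").write_text(json.dumps(manifest, indent=2))


# ---------------------------------------------------------------------
# sequence machinery
# ---------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, length)


def _mutate(rng: np.random.Generator, seq: np.ndarray, d: float) -> np.ndarray:
    out = seq.copy()
    mask = rng.random(len(seq)) < d
    shifts = rng.integers(1, 4, int(mask.sum()))
    out[mask] = (out[mask] + shifts) % 4
    return out


def _to_string(seq: np.ndarray, gap: tuple[int, int] | None = None) -> str:
    chars = [BASES[i] for i in seq]
    if gap is not None:
        for j in range(*gap):
            chars[j] = "-"
    return "".join(chars)


def simulate_reference_sequences(
    config: SimulationConfig,
) -> tuple[Alignment, Alignment]:
    """Allele and haplotype exemplar alignments (deterministic per seed).

    Star phylogeny with two deep nuclear clades: exemplars diverge by
    ``d_between_clade`` across clades and ``d_between_group`` within; the
    deletion clade carries the diagnostic gap.  Chloroplast groups diverge
    by ``cp_d_between``.
    """
    rng = np.random.default_rng([config.seed, 1])
    root = _random_seq(rng, config.nuclear_length)
    # divergences are expected pairwise p-distances: the clade branch gets
    # what remains after the within-clade exemplar branches
    clade_branch = max(config.d_between_clade - config.d_between_group, 0.0) / 2
    clades = {"del": _mutate(rng, root, clade_branch),
              "ins": _mutate(rng, root, clade_branch)}
    window = config.diagnostic_window
    ids, rows = [], []
    for allele in config.alleles:
        clade = "del" if allele in config.deletion_clade else "ins"
        ex = _mutate(rng, clades[clade], config.d_between_group / 2)
        ids.append(allele)
        rows.append(_to_string(ex, gap=window if clade == "del" else None))
    nuclear = Alignment(tuple(ids), tuple(rows))

    cp_root = _random_seq(rng, config.chloroplast_length)
    cp_ids, cp_rows = [], []
    for group in config.haplotype_groups:
        ex = _mutate(rng, cp_root, config.cp_d_between / 2)
        cp_ids.append(group)
        cp_rows.append(_to_string(ex))
    chloroplast = Alignment(tuple(cp_ids), tuple(cp_rows))
    return nuclear, chloroplast


# ---------------------------------------------------------------------
# complex simulation
# ---------------------------------------------------------------------


def clone_group_probabilities(
    genotype: Sequence[str], pcr_bias: Mapping[str, float] | None = None
) -> dict[str, float]:
    """Per-draw probability of cloning each allele group.

    Proportional to dosage x PCR-bias weight: a triploid AAB with a 4:1
    bias against B samples B with probability 1 / (2*4 + 1) per clone.
    """
    bias = pcr_bias or {}
    groups = sorted(set(genotype))
    weights = {g: genotype.count(g) * bias.get(g, 1.0) for g in groups}
    total = sum(weights.values())
    return {g: w / total for g, w in weights.items()}


def simulate_histogram(
    ploidy: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    sample_id: str = "sample",
) -> FluorescenceHistogram:
    """Two-peak histogram: standard at the calibration channel, sample at
    ratio 0.6 x ploidy, both Gaussian with the configured CV, Poisson
    counting noise."""
    channels = np.arange(config.n_channels, dtype=float)
    expected = np.zeros(config.n_channels)
    for mean, cells in (
        (config.standard_channel, config.histogram_cells / 2),
        (0.6 * ploidy * config.standard_channel, config.histogram_cells / 2),
    ):
        sigma = config.peak_cv * mean
        pdf = np.exp(-0.5 * ((channels - mean) / sigma) ** 2) / (
            sigma * np.sqrt(2 * np.pi)
        )
        expected += cells * pdf
    counts = rng.poisson(expected)
    return FluorescenceHistogram(sample_id, tuple(channels), tuple(int(c) for c in counts))


def simulate_complex(
    config: SimulationConfig,
) -> tuple[ObservationBundle, SimulationTruth]:
    """Run the event list and emit the full observation bundle + truth.

    Cross children become observed apogamous individuals; doubling children
    stay latent (available as sexual parents of later events), mirroring a
    complex in which the sexual intermediates were never collected.
    """
    rng = np.random.default_rng([config.seed, 2])
    nuclear_refs, cp_refs = simulate_reference_sequences(config)
    events = config.events if config.events is not None else default_events()

    # one founding lineage sequence per allele (shared by all carriers)
    allele_seq: dict[str, str] = {}
    window = config.diagnostic_window
    for allele in config.alleles:
        base = np.array([BASES.index(c) if c != "-" else 0 for c in nuclear_refs.row(allele)])
        mutated = _mutate(rng, base, config.d_within)
        gap = window if allele in config.deletion_clade else None
        allele_seq[allele] = _to_string(mutated, gap=gap)

    cp_group_seq = {g: cp_refs.row(g) for g in config.haplotype_groups}

    progenitors = {a + a: (a, a) for a in config.alleles}

    # latent state per node: (genotype, haplotype, reproduction)
    nodes: dict[str, tuple[tuple[str, ...], str | None, str]] = {}
    for a in config.alleles:
        nodes[a + a] = ((a, a), config.allele_haplotype.get(a), "sexual")

    resolved: list[ResolvedEvent] = []
    individuals: dict[str, IndividualTruth] = {}
    regions: dict[str, str] = {}

    def draw_reduced(genotype: tuple[str, ...]) -> tuple[str, ...]:
        k = len(genotype) // 2
        idx = rng.choice(len(genotype), size=k, replace=False)
        return tuple(sorted(genotype[i] for i in idx))

    for ev in events:
        if ev.mother not in nodes:
            raise ValueError(f"event references unknown parent {ev.mother!r}")
        m_geno, m_hap, m_repro = nodes[ev.mother]
        if ev.kind == "doubling":
            child_geno = tuple(sorted(m_geno + m_geno))
            nodes[ev.child] = (child_geno, m_hap, "sexual")
            resolved.append(
                ResolvedEvent("doubling", ev.mother, None, ev.child, m_geno, m_geno)
            )
            continue
        if ev.father not in nodes:
            raise ValueError(f"event references unknown parent {ev.father!r}")
        if m_repro != "sexual":
            raise ValueError(f"{ev.child}: apogamous taxa cannot be mothers")
        if m_hap is None:
            raise ValueError(
                f"{ev.child}: mother {ev.mother} has no haplotype (unmapped allele)"
            )
        f_geno, _, f_repro = nodes[ev.father]
        mg = ev.mother_gamete or draw_reduced(m_geno)
        fg = (
            ev.father_gamete
            or (f_geno if f_repro == "apogamous" else draw_reduced(f_geno))
        )
        child_geno = tuple(sorted(mg + fg))
        nodes[ev.child] = (child_geno, m_hap, "apogamous")
        regions[ev.child] = ev.region
        resolved.append(ResolvedEvent("cross", ev.mother, ev.father, ev.child, tuple(mg), tuple(fg)))
        label = Genotype.from_groups(set(child_geno), len(child_geno)).label
        individuals[ev.child] = IndividualTruth(
            genotype=child_geno,
            ploidy=len(child_geno),
            haplotype=m_hap,
            reproduction="apogamous",
            region=ev.region,
            label=label,
        )

    # per-individual observable data
    clone_sets: dict[str, CloneSet] = {}
    histograms: dict[str, FluorescenceHistogram] = {}
    spores: dict[str, tuple[int, ...]] = {}
    cp_ids, cp_rows = [], []
    meta_rows = []
    for name, ind in individuals.items():
        # clone sampling: dosage x PCR-bias weighted
        prob_map = clone_group_probabilities(ind.genotype, config.pcr_bias)
        groups = sorted(prob_map)
        probs = np.array([prob_map[g] for g in groups])
        clones = []
        seen: dict[str, int] = {}
        # adaptive stopping rule: cloning effort grows with ploidy, and
        # sequencing continues (up to max_clones) until every captured
        # allele type has been seen more than once
        min_clones = config.clones_per_individual + 4 * (ind.ploidy - 2)
        while True:
            k = len(clones)
            if k >= config.max_clones:
                break
            if (
                k >= min_clones
                and len(seen) >= 2  # a hybrid is expected to show two types
                and all(v >= 2 for v in seen.values())
            ):
                break
            g = groups[int(rng.choice(len(groups), p=probs))]
            seen[g] = seen.get(g, 0) + 1
            seq = np.array([BASES.index(c) if c != "-" else -1 for c in allele_seq[g]])
            ungapped = seq >= 0
            errors = (rng.random(len(seq)) < config.pcr_error_rate) & ungapped
            shifts = rng.integers(1, 4, int(errors.sum()))
            seq[errors] = (seq[errors] + shifts) % 4
            text = "".join("-" if s < 0 else BASES[s] for s in seq)
            clones.append((f"c{len(clones) + 1}", text))
        clone_sets[name] = CloneSet(name, "nuclear", tuple(clones))

        cp_base = np.array([BASES.index(c) for c in cp_group_seq[ind.haplotype]])
        cp_ids.append(name)
        cp_rows.append(_to_string(_mutate(rng, cp_base, config.cp_d_within)))

        histograms[name] = simulate_histogram(ind.ploidy, config, rng, sample_id=name)

        counts = []
        for _ in range(config.n_sporangia):
            if ind.reproduction == "apogamous":
                if rng.random() < config.spore_p32:
                    counts.append(32)
                else:
                    counts.append(int(rng.choice([16, 28])))
            else:
                counts.append(64)
        spores[name] = tuple(counts)
        meta_rows.append(
            {
                "individual": name,
                "region": ind.region,
                "phenology": ["evergreen", "deciduous"][int(rng.integers(0, 2))],
            }
        )

    bundle = ObservationBundle(
        nuclear_references=nuclear_refs,
        diagnostic_window=window,
        chloroplast=Alignment(tuple(cp_ids), tuple(cp_rows)),
        clone_sets=clone_sets,
        histograms=histograms,
        spore_counts=spores,
        metadata=pd.DataFrame(meta_rows, columns=["individual", "region", "phenology"]),
        standard_channel=config.standard_channel,
    )
    truth = SimulationTruth(progenitors, tuple(resolved), individuals)
    return bundle, truth


def random_simulation_config(
    seed: int,
    n_alleles: int | None = None,
    n_hybrids: int | None = None,
) -> SimulationConfig:
    """A randomised study design: 3-5 allele lineages, 4-8 hybrid taxa.

    One lineage (``Y``) carries the diagnostic deletion and stays unmapped
    (as a paternal-only donor); the remaining lineages are spread over up
    to three chloroplast groups without injected conflicts.  Hybrids are
    diploid crosses between progenitors, triploids fathered by earlier
    apogamous diploids, and occasionally a tetraploid via genome doubling.
    """
    import random as _random

    rng = _random.Random(seed)
    n_alleles = n_alleles if n_alleles is not None else rng.randint(3, 5)
    n_hybrids = n_hybrids if n_hybrids is not None else rng.randint(4, 8)
    xs = [f"X{i + 1}" for i in range(n_alleles - 1)]
    alleles = tuple(xs) + ("Y",)
    groups = ("alpha", "beta", "gamma")[: min(3, len(xs))]
    amap = {a: groups[i % len(groups)] for i, a in enumerate(xs)}

    events: list[Event] = []
    diploids: list[str] = []
    used = set()
    for k in range(n_hybrids):
        region = rng.choice(["Taiwan", "Hainan"])
        roll = rng.random()
        if diploids and roll < 0.3:
            # triploid: sexual diploid mother x apogamous diploid father
            mother = rng.choice(xs)
            father = rng.choice(diploids)
            events.append(Event("cross", mother + mother, father, f"h{k}_3x", region))
        elif diploids and roll < 0.45:
            # tetraploid: doubled diploid hybrid mother x apogamous father
            source = rng.choice(diploids)
            t4 = f"t{k}_4x"
            events.append(Event("doubling", source, None, t4, region))
            father = rng.choice(diploids)
            events.append(Event("cross", t4, father, f"h{k}_4x", region))
        else:
            a = rng.choice(xs)
            b = rng.choice([x for x in alleles if x != a])
            child = f"h{k}_2x"
            events.append(Event("cross", a + a, b + b, child, region))
            diploids.append(child)
            used.update({a, b})
    return SimulationConfig(
        seed=rng.randrange(2**31),
        alleles=alleles,
        allele_haplotype=amap,
        haplotype_groups=("alpha", "beta", "gamma"),
        events=tuple(events),
    )


# ---------------------------------------------------------------------
# the transcribed reference complex
# ---------------------------------------------------------------------

#: taxa whose chloroplast group conflicts with their allele content and are
#: exempted from the maternal map (their parentage is left unresolved)
FIXTURE_EXEMPT = ("morph5-3x", "morph6-3x")


def reference_fixture() -> list[TaxonObservation]:
    """The reference 11-taxon complex (8 morphs across two islands).

    Morphs 1, 3, 4 and 7 are diploid; morphs 5 and 6 triploid; morph 2
    diploid and tetraploid; morph 8 diploid, triploid and tetraploid —
    11 (morph, cytotype) taxa in all, carrying five nuclear allele lineages
    (X1-X4, Y) and three chloroplast groups (alpha, beta, gamma).  Morph 6's
    chloroplast group is not directly recorded; alpha is the assignment
    consistent with X2 as its maternal element and is flagged as inferred.
    """

    def obs(tid, morph, ploidy, groups, hap, region, phen):
        return TaxonObservation(
            taxon_id=tid,
            ploidy=ploidy,
            genotype=Genotype.from_groups(groups, ploidy),
            haplotype=hap,
            reproduction="apogamous",
            region=frozenset(region),
            phenology=phen,
            morph=morph,
        )

    H, T = "Hainan", "Taiwan"
    return [
        obs("morph1-2x", "morph1", 2, {"X2", "Y"}, "alpha", {H, T}, "deciduous"),
        obs("morph2-2x", "morph2", 2, {"X4", "Y"}, "beta", {H}, "unknown"),
        obs("morph2-4x", "morph2", 4, {"X2", "X4", "Y"}, "beta", {H}, "evergreen"),
        obs("morph3-2x", "morph3", 2, {"X3", "Y"}, "gamma", {T}, "evergreen"),
        obs("morph4-2x", "morph4", 2, {"X3", "Y"}, "gamma", {H, T}, "evergreen"),
        obs("morph5-3x", "morph5", 3, {"X3", "Y"}, "alpha", {T}, "evergreen"),
        obs("morph6-3x", "morph6", 3, {"X2", "X3", "Y"}, "alpha", {T}, "evergreen"),
        obs("morph7-2x", "morph7", 2, {"X3", "Y"}, "gamma", {T}, "evergreen"),
        obs("morph8-2x", "morph8", 2, {"X1", "Y"}, "alpha", {H, T}, "deciduous"),
        obs("morph8-3x", "morph8", 3, {"X1", "Y"}, "alpha", {T}, "deciduous"),
        obs("morph8-4x", "morph8", 4, {"X2", "X4", "Y"}, "beta", {H}, "evergreen"),
    ]
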