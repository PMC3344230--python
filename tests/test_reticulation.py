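"""Diploids-first progenitors, gamete rules, cross enumeration and the
minimal-presumed-taxa network search."""

import random

import pytest

from helpers import brute_force_network_cost
from reticulator.lineage import infer_allele_haplotype_map
from reticulator.reticulation import (
    CrossEvent,
    NetworkConfig,
    ParentTaxon,
    build_parent_pool,
    derive_sexual_tetraploids,
    enumerate_crosses,
    hypothesize_progenitors,
    infer_network,
    reduced_gametes,
    regional_partition,
    _support_options,
)
from reticulator.simulate import FIXTURE_EXEMPT, reference_fixture
from reticulator.taxa import Genotype, TaxonObservation


def obs(tid, ploidy, groups, hap=None, region=(), repro="apogamous"):
    return TaxonObservation(
        tid, ploidy, Genotype.from_groups(groups, ploidy), haplotype=hap,
        reproduction=repro, region=frozenset(region),
    )


def sexual(genotype, hap=None, status="presumed"):
    return ParentTaxon(
        tuple(genotype), "sexual", status,
        haplotypes=frozenset({hap}) if hap else frozenset(),
    )


class TestProgenitors:
    def test_one_homozygous_diploid_per_allele(self):
        progs = hypothesize_progenitors(["X1", "X2", "X3", "X4", "Y"])
        assert [p.name for p in progs] == ["X1X1", "X2X2", "X3X3", "X4X4", "YY"]
        assert all(p.reproduction == "sexual" and p.status == "presumed" for p in progs)

    def test_single_allele_and_empty_set(self):
        assert [p.name for p in hypothesize_progenitors(["A"])] == ["AA"]
        assert hypothesize_progenitors([]) == []

    def test_observed_sexual_taxon_matches_presumed_progenitor(self):
        seen = obs("wild", 2, {"A"}, repro="sexual")
        progs = hypothesize_progenitors(["A", "B"], observed=[seen])
        by_name = {p.name: p for p in progs}
        assert by_name["AA"].status == "observed"
        assert by_name["BB"].status == "presumed"


class TestDerivedTetraploids:
    def test_doubling_of_hybrid_diploid(self):
        apog = ParentTaxon(("X2", "Y"), "apogamous", "presumed")
        tets = derive_sexual_tetraploids([], [apog], mechanisms=("doubling",))
        assert [t.name for t in tets] == ["X2X2YY"]
        assert tets[0].reproduction == "sexual"

    def test_genome_addition_of_two_progenitors(self):
        tets = derive_sexual_tetraploids(
            [sexual(("X4", "X4")), sexual(("Y", "Y"))],
            mechanisms=("genome_addition",),
        )
        assert [t.name for t in tets] == ["X4X4YY"]

    def test_doubling_homozygote_gives_autotetraploid(self):
        tets = derive_sexual_tetraploids([sexual(("X4", "X4"))], mechanisms=("doubling",))
        assert [t.name for t in tets] == ["X4X4X4X4"]

    def test_duplicate_genotypes_merge_with_multi_provenance(self):
        apog = ParentTaxon(("X2", "Y"), "apogamous", "presumed")
        tets = derive_sexual_tetraploids(
            [sexual(("X2", "X2")), sexual(("Y", "Y"))], [apog]
        )
        x2x2yy = [t for t in tets if t.name == "X2X2YY"]
        assert len(x2x2yy) == 1
        assert {mech for mech, _ in x2x2yy[0].provenance} == {
            "doubling", "genome_addition"
        }


class TestGametes:
    def test_diploid_and_tetraploid_reduced_gametes(self):
        assert reduced_gametes(("A", "B")) == [("A",), ("B",)]
        assert reduced_gametes(("A", "A", "B", "B")) == [
            ("A", "A"), ("A", "B"), ("B", "B"),
        ]

    def test_odd_ploidy_has_no_reduced_gametes(self):
        assert reduced_gametes(("A", "A", "B")) == []

    def test_disomic_tetraploid_restricts_to_heterogametes(self):
        assert reduced_gametes(("A", "A", "B", "B"), disomic_only=True) == [("A", "B")]


class TestEnumerateCrosses:
    def test_diploid_with_maternal_constraint_has_single_origin(self):
        amap = {"X1": "alpha", "X2": "alpha", "X3": "gamma", "X4": "beta"}
        progs = hypothesize_progenitors(["X1", "X2", "X3", "X4", "Y"], amap)
        target = obs("m1", 2, {"X2", "Y"}, hap="alpha")
        crosses = enumerate_crosses(target, progs, enforce_maternal_haplotype=True)
        assert len(crosses) == 1
        c = crosses[0]
        assert c.mother.name == "X2X2" and c.father.name == "YY"

    def test_triploid_worked_example_yields_exactly_three_crosses(self):
        pool = [
            sexual(("X2", "X2")),
            sexual(("X3", "X3")),
            sexual(("Y", "Y")),
            sexual(("X2", "X2", "Y", "Y")),
            sexual(("X3", "X3", "Y", "Y")),
            ParentTaxon(("X3", "Y"), "apogamous", "presumed"),
        ]
        target = obs("m6", 3, {"X2", "X3", "Y"})
        crosses = enumerate_crosses(target, pool, enforce_maternal_haplotype=False)
        got = {(c.mother.name, c.father.name) for c in crosses}
        assert got == {
            ("X2X2", "X3X3YY"),
            ("X3X3", "X2X2YY"),
            ("X2X2", "X3Y"),
        }

    def test_offspring_with_unmatched_allele_has_no_cross(self):
        pool = [sexual(("A", "A")), sexual(("B", "B"))]
        target = obs("x", 2, {"A", "C"})
        assert enumerate_crosses(target, pool, enforce_maternal_haplotype=False) == []

    def test_allele_conservation_and_ploidy_additivity(self):
        pool = build_parent_pool(reference_fixture(), None, NetworkConfig())
        for t in reference_fixture():
            for c in enumerate_crosses(t, pool, enforce_maternal_haplotype=False):
                combined = tuple(sorted(c.mother_gamete + c.father_gamete))
                assert combined in t.genotype.candidates
                assert len(c.mother_gamete) + len(c.father_gamete) == t.ploidy

    def test_apogamous_parents_are_fathers_only(self):
        apog = ParentTaxon(("A", "B"), "apogamous", "presumed")
        pool = [apog, sexual(("C", "C"), hap="h1")]
        target = obs("t", 3, {"A", "B", "C"}, hap="h1")
        crosses = enumerate_crosses(target, pool)
        assert crosses and all(c.father.name == "AB" for c in crosses)
        assert all(c.mother.name == "CC" for c in crosses)

    def test_unknown_haplotype_mothers_rejected_by_default(self):
        pool = [sexual(("A", "A")), sexual(("B", "B"))]  # no haplotypes known
        target = obs("t", 2, {"A", "B"}, hap="h1")
        assert enumerate_crosses(target, pool) == []
        relaxed = enumerate_crosses(target, pool, unknown_mother="allow")
        assert len(relaxed) == 2


class TestInferNetwork:
    def test_two_presumed_progenitors_for_one_hybrid(self):
        amap = {"A": "h1", "B": "h2"}
        net = infer_network([obs("hyb", 2, {"A", "B"}, hap="h1")], amap)
        assert net.cost == 2
        assert len(net.crosses) == 1
        assert net.crosses[0].mother.name == "AA"
        assert net.co_optimal == []

    def test_reference_complex_progenitor_hypothesis(self):
        taxa = reference_fixture()
        amap = infer_allele_haplotype_map(taxa, exempt=FIXTURE_EXEMPT)
        net = infer_network(taxa, amap)
        assert [p.name for p in net.progenitors] == [
            "X1X1", "X2X2", "X3X3", "X4X4", "YY",
        ]
        assert net.unexplained == ()
        # the triploid whose haplotype conflicts with its allele content has
        # no uniquely resolvable maternal parent
        assert "morph5-3x" in net.maternal_ambiguity()

    def test_maternal_haplotype_respected_in_every_cross(self):
        taxa = reference_fixture()
        amap = infer_allele_haplotype_map(taxa, exempt=FIXTURE_EXEMPT)
        net = infer_network(taxa, amap)
        by_id = {t.taxon_id: t for t in taxa}
        for network in [net] + net.co_optimal:
            for c in network.crosses:
                child_hap = by_id[c.offspring].haplotype
                if child_hap and c.mother.haplotypes:
                    assert child_hap in c.mother.haplotypes

    def test_search_cost_matches_brute_force_on_small_instances(self):
        rng = random.Random(6)
        for trial in range(20):
            alleles = ["A", "B", "C"][: rng.randint(2, 3)]
            amap = {a: f"h{i}" for i, a in enumerate(alleles)}
            observations = []
            for k in range(rng.randint(1, 4)):
                groups = set(rng.sample(alleles, rng.randint(1, min(2, len(alleles)))))
                ploidy = rng.choice([2, 3])
                if len(groups) > ploidy:
                    continue
                hap = amap[sorted(groups)[0]]
                observations.append(obs(f"t{k}", ploidy, groups, hap=hap))
            if not observations:
                continue
            config = NetworkConfig()
            net = infer_network(observations, amap, config)
            pool = build_parent_pool(observations, amap, config)
            cross_lists = {}
            feasible = True
            for t in observations:
                crosses = enumerate_crosses(t, pool)
                if crosses:
                    cross_lists[t.taxon_id] = crosses
            if not cross_lists:
                continue
            expected = brute_force_network_cost(cross_lists, _support_options)
            assert net.cost == expected, f"trial {trial}"

    def test_observing_a_sexual_progenitor_never_raises_cost(self):
        amap = {"A": "h1", "B": "h2"}
        hybrid = obs("hyb", 2, {"A", "B"}, hap="h1")
        base = infer_network([hybrid], amap)
        seen_aa = obs("wildAA", 2, {"A"}, hap="h1", repro="sexual")
        with_obs = infer_network([hybrid, seen_aa], amap)
        assert with_obs.cost <= base.cost
        assert with_obs.cost == 1  # only BB remains presumed

    def test_infeasible_taxon_reported_unexplained(self):
        # known offspring haplotype but no mother can ever carry it
        net = infer_network([obs("t", 2, {"A", "B"}, hap="h9")], {"A": "h1"})
        assert net.unexplained == ("t",)


class TestRegionalPartition:
    def test_reference_complex_private_inventory(self):
        taxa = reference_fixture()
        amap = infer_allele_haplotype_map(taxa, exempt=FIXTURE_EXEMPT)
        net = infer_network(taxa, amap)
        part = regional_partition(net, taxa)
        inv = part.inventory
        x4 = inv[(inv["kind"] == "allele") & (inv["value"] == "X4")]
        assert list(x4["region"]) == ["Hainan"]
        assert x4["private"].all()
        shared_y = inv[(inv["kind"] == "allele") & (inv["value"] == "Y")]
        assert set(shared_y["region"]) == {"Hainan", "Taiwan"}
        assert not shared_y["private"].any()

    def test_single_region_subnetwork_covers_all_crosses(self):
        taxa = [obs("a", 2, {"A", "B"}, hap="h1", region={"R"})]
        net = infer_network(taxa, {"A": "h1"})
        part = regional_partition(net, taxa)
        assert list(part.subnetworks) == ["R"]
        assert len(part.subnetworks["R"]) == len(net.edge_frame())

    def test_taxon_without_region_listed_unplaced(self):
        taxa = [obs("a", 2, {"A", "B"}, hap="h1", region=())]
        net = infer_network(taxa, {"A": "h1"})
        part = regional_partition(net, taxa)
        assert part.unplaced == ("a",)
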