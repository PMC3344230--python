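"""Clone collapsing, allele-group assignment, genotypes, haplotype groups
and the allele-to-haplotype maternal map."""

import random
from math import comb

import numpy as np
import pytest

from helpers import match_haplotype_labels
from reticulator.alignment import Alignment
from reticulator.lineage import (
    CloneSet,
    assign_allele_group,
    collapse_clones,
    group_haplotypes,
    infer_allele_haplotype_map,
    infer_genotype,
    p_distance,
    substitution_distance,
)
from reticulator.simulate import (
    FIXTURE_EXEMPT,
    SimulationConfig,
    reference_fixture,
    simulate_reference_sequences,
)
from reticulator.taxa import Genotype, TaxonObservation


BASE = "ACGTACGTACGTACGTACGT"


def mutate(seq, positions, to="T"):
    row = list(seq)
    for p in positions:
        row[p] = to if row[p] != to else "A"
    return "".join(row)


class TestCollapseClones:
    def test_clusters_with_error_tolerance(self):
        a = BASE
        a_err = mutate(BASE, [3])  # one PCR error away from a
        b = mutate(BASE, [0, 4, 8, 12, 16])  # a distinct allele
        cs = CloneSet(
            "ind1",
            "nuclear",
            tuple(
                (f"c{i}", s)
                for i, s in enumerate([a, a, a, b, b, a_err])
            ),
        )
        calls = collapse_clones(cs)
        accepted = [c for c in calls if not c.flagged_singleton]
        assert sorted(c.support for c in accepted) == [2, 4]
        assert max(accepted, key=lambda c: c.support).sequence == a

    def test_single_clone_is_flagged_singleton(self):
        calls = collapse_clones(CloneSet("i", "nuclear", (("c1", BASE),)))
        assert len(calls) == 1
        assert calls[0].flagged_singleton and calls[0].support == 1

    def test_identical_clones_collapse_to_one_call(self):
        cs = CloneSet("i", "nuclear", tuple((f"c{i}", BASE) for i in range(4)))
        calls = collapse_clones(cs)
        assert len(calls) == 1 and calls[0].support == 4

    def test_clone_order_does_not_matter(self):
        rng = random.Random(0)
        seqs = [BASE, BASE, mutate(BASE, [1]), mutate(BASE, [0, 4, 8, 12])]
        clones = [(f"c{i}", s) for i, s in enumerate(seqs)]
        ref = collapse_clones(CloneSet("i", "nuclear", tuple(clones)))
        for _ in range(5):
            rng.shuffle(clones)
            got = collapse_clones(CloneSet("i", "nuclear", tuple(clones)))
            assert [(c.sequence, c.support) for c in got] == [
                (c.sequence, c.support) for c in ref
            ]

    def test_different_gap_extents_never_merge(self):
        gapped = BASE[:5] + "---" + BASE[8:]
        d = substitution_distance(BASE, gapped)
        assert d is None
        calls = collapse_clones(
            CloneSet("i", "nuclear", (("c1", BASE), ("c2", gapped)))
        )
        assert len(calls) == 2


class TestAssignAlleleGroup:
    def test_deletion_carrier_goes_to_deletion_clade(self, reference_alignment):
        query = "TCGT----ACGTACGT"
        assert assign_allele_group(query, reference_alignment, (4, 8)) == "Y"

    def test_non_carrier_assigned_to_nearest_exemplar(self, reference_alignment):
        query = "ACGTACGTACGAACGA"  # 1 col from X2, 2 from X1
        assert (
            assign_allele_group(
                query, reference_alignment, (4, 8), min_margin=0.005
            )
            == "X2"
        )

    def test_equidistant_query_stays_unassigned(self, reference_alignment):
        # X1 and X2 differ at column 11; 'T' there matches neither
        query = "ACGTACGTACGCACGT"
        assert (
            assign_allele_group(query, reference_alignment, (4, 8)) == "unassigned"
        )

    def test_simulated_exemplars_assign_to_themselves(self):
        config = SimulationConfig(seed=5)
        nuclear, _ = simulate_reference_sequences(config)
        for allele in config.alleles:
            assert (
                assign_allele_group(
                    nuclear.row(allele), nuclear, config.diagnostic_window
                )
                == allele
            )


class TestInferGenotype:
    @pytest.mark.parametrize(
        "groups, ploidy, label, n_cand",
        [
            ({"X2", "Y"}, 2, "X2Y", 1),
            ({"X3", "Y"}, 3, "X3*Y", 2),
            ({"X2", "X3", "Y"}, 3, "X2X3Y", 1),
            ({"X2", "X4", "Y"}, 4, "X2X4*Y", 3),
        ],
    )
    def test_star_notation_and_candidates(self, groups, ploidy, label, n_cand):
        g = infer_genotype(groups, ploidy)
        assert g.label == label
        assert len(g.candidates) == n_cand
        assert all(len(c) == ploidy for c in g.candidates)
        assert all(set(c) == set(groups) for c in g.candidates)

    def test_triploid_dosage_candidates_are_the_two_printed_ones(self):
        g = infer_genotype({"X3", "Y"}, 3)
        assert g.candidates == frozenset(
            {("X3", "X3", "Y"), ("X3", "Y", "Y")}
        )

    def test_candidate_count_matches_composition_formula(self):
        for ploidy in (2, 3, 4):
            for k in range(1, ploidy + 1):
                groups = {f"G{i}" for i in range(k)}
                g = infer_genotype(groups, ploidy)
                assert len(g.candidates) == comb(ploidy - 1, k - 1)

    def test_more_groups_than_genome_copies_rejected(self):
        with pytest.raises(ValueError):
            infer_genotype({"A", "B", "C"}, 2)


class TestGroupHaplotypes:
    def test_three_simulated_clusters_recovered_exactly(self):
        rng = np.random.default_rng(31)
        bases = "ACGT"
        centers = []
        length = 400
        root = rng.integers(0, 4, length)
        for _ in range(3):
            c = root.copy()
            mask = rng.random(length) < 0.02
            c[mask] = (c[mask] + rng.integers(1, 4, mask.sum())) % 4
            centers.append(c)
        ids, rows, truth = [], [], {}
        for gi, center in enumerate(centers):
            for k in range(3):
                seq = center.copy()
                mask = rng.random(length) < 0.0025
                seq[mask] = (seq[mask] + rng.integers(1, 4, mask.sum())) % 4
                sid = f"g{gi}_s{k}"
                ids.append(sid)
                rows.append("".join(bases[i] for i in seq))
                truth[sid] = f"g{gi}"
        grouping = group_haplotypes(Alignment(tuple(ids), tuple(rows)))
        assert grouping.n_groups == 3
        mapping = match_haplotype_labels(grouping.labels, truth)
        assert all(mapping[grouping.labels[s]] == truth[s] for s in truth)

    def test_identical_sequences_form_one_group(self):
        grouping = group_haplotypes(Alignment(("a", "b"), ("ACGT", "ACGT")))
        assert grouping.n_groups == 1

    def test_reference_complex_has_three_haplotype_groups(self):
        taxa = reference_fixture()
        assert len({t.haplotype for t in taxa}) == 3


class TestAlleleHaplotypeMap:
    def test_reference_complex_map(self):
        taxa = reference_fixture()
        amap = infer_allele_haplotype_map(taxa, exempt=FIXTURE_EXEMPT)
        assert amap.mapping == {
            "X1": "alpha",
            "X2": "alpha",
            "X3": "gamma",
            "X4": "beta",
        }
        assert "Y" not in amap.mapping
        assert amap.conflicts == []

    def test_single_taxon_is_underdetermined_not_guessed(self):
        t = TaxonObservation(
            "t1", 2, Genotype.from_groups({"X1", "Y"}, 2), haplotype="alpha"
        )
        amap = infer_allele_haplotype_map([t])
        assert amap.mapping == {}
        assert amap.ambiguous == {"X1": "alpha", "Y": "alpha"}
        assert amap.conflicts == []

    def test_inconsistent_carriers_yield_conflict_records(self):
        t1 = TaxonObservation(
            "c1", 2, Genotype.from_groups({"X3", "Y"}, 2), haplotype="alpha"
        )
        t2 = TaxonObservation(
            "c2", 2, Genotype.from_groups({"X3", "Y"}, 2), haplotype="gamma"
        )
        amap = infer_allele_haplotype_map([t1, t2])
        assert "X3" not in amap.mapping
        assert any(allele == "X3" for _, allele, _, _ in amap.conflicts)


class TestDistances:
    def test_p_distance_ignores_gapped_columns(self):
        assert p_distance("AC-T", "ACGT") == 0.0
        assert p_distance("ACTT", "ACGT") == pytest.approx(0.25)
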