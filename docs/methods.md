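# Methods

This note records the models, rules and numerical choices behind each
stage, what the synthetic-data generator does and does not emulate, and the
design decisions taken where the procedure was genuinely open.

## Ploidy calling and reproduction typing

A propidium-iodide fluorescence histogram is smoothed with a centred
moving average (default window 5 bins) and local maxima with prominence
below 10% of the smoothed maximum are discarded; this removes G2 doublets
and debris shoulders while keeping both G1 peaks of a co-run sample.  The
lowest-channel qualifying peak is taken as the calibration standard — valid
because the 4X standard (20.08 pg) sits below every sample peak when
ratios are ≥ 1.2 — and the most intense remaining peak as the sample.  An
explicit standard peak can be supplied instead.

Genome size is `ratio × 20.08 pg` exactly (asserted to 1e-9 relative in
the tests).  Ploidy is the nearest of the reference ratios {1.2: 2X,
1.8: 3X, 2.4: 4X} if within tolerance 0.15 — the largest tolerance that
keeps the references non-overlapping (adjacent references are 0.6/2 = 0.3
apart).  Ratios outside every window are left *uncalled* rather than
forced.  Instrument gating and CV acceptance rules are not modelled; the
defaults above are this package's own.

Spore counts: a sporangium with 64 spores (± a configurable slack,
default 0) is sexual, ≤ 32 apogamous, 33–63 indeterminate — the gap region
is never observed in practice and is deliberately not resolved.  The
plant-level mode is the majority sporangium label; ties are indeterminate.

## Simple indel coding

Each distinct internal gap extent in the alignment becomes one binary
character: state 1 iff the sequence carries a maximal gap run with exactly
that extent, 0 iff no gap of the sequence overlaps it, missing otherwise
(an overlapping run of different extent makes the state undecidable).
Terminal gap runs usually reflect incomplete sequencing (primer-bounded
fragments), so by default they are never coded and score missing wherever
they overlap a character; a flag codes them like internal runs.
Coordinates are 0-based half-open throughout the library; 1-based
conversions exist only at I/O boundaries.  Ambiguously aligned regions are
excluded by an explicit column-range mask (`Alignment.exclude_columns`),
not by an automatic criterion.  Counts of coded characters are sensitive
to whether autapomorphic gaps are included; this implementation codes all
qualifying gaps.

Diagnostic-indel detection (used for the deep X/Y clade split) classifies
a sequence as carrier when some gap run reaches a reciprocal overlap of
0.8 with the diagnostic window (overlap divided by the longer of run and
window), non-carrier when no gap overlaps, ambiguous otherwise.

## Parsimony engine

Characters are unordered and equally weighted by default; missing data is
full-alphabet ambiguity at the leaves.  Fitch state sets are byte-packed
into Python big integers (one byte per character), so one post-order pass
costs a handful of word-parallel bit operations per internal node; the
per-byte zero test uses the borrow-free form `~(t | ((t | HI) − LO)) & HI`,
which is exact (the classical `(t − LO) & ~t & HI` form has false
positives above a zero byte and is not used).  Non-unit weights fall back
to a per-character pass.

Statistics follow the standard definitions: per character, the minimum
steps `m = (distinct singleton states) − 1` and the extra-steps bound
`g = (taxa with singleton states) − (largest single-state count)`;
`CI = Σm / L`, `RI = (Σm + Σg − L) / Σg`, clamped to [0, 1], with the
degenerate no-information case defined as RI = 1 when the length reaches
its minimum.  Ambiguous (multi-state) leaf symbols are treated as missing
in these counts and in the parsimony-informative filter (a character is
informative when at least two states each occur at least twice).

The exhaustive search enumerates unrooted binary topologies by stepwise
insertion with branch-and-bound pruning (a partial tree's length never
decreases as leaves are added) and returns *all* minimum-length trees; it
is restricted to 4–9 taxa and serves as the oracle for the heuristic.  The
heuristic uses random-addition starts (stepwise addition with seeded
random tie-breaking) followed by first-improvement hill climbing under SPR
(default) or NNI, then floods through equal-length neighbours to collect
all co-optimal topologies (MULTREES semantics, capped).  SPR replaces the
conventional TBR deliberately: at this scale TBR adds little, and SPR
keeps the search verifiable against the exhaustive oracle.

Bootstrap: characters resampled with replacement, each replicate searched
with reduced settings (3 addition sequences, NNI); a split counts as
recovered when it appears in the strict consensus of the replicate's best
trees.

ILD (partition homogeneity): `D = L(combined) − L(part1) − L(part2)`,
parsimony-informative characters only by default, permutation replicates
reassigning pooled characters into pseudo-partitions of the original
sizes.  The tail convention is pinned: `p = (1 + #{D_perm ≥ D_obs}) /
(n_reps + 1)`.  The partitions are put in a canonical internal order
first, making the p-value exactly invariant to swapping them.  The
combined length is computed once per test, so each replicate costs two
reduced searches.  Like any tie-prone permutation statistic the test is
conservative on small matrices; the calibration suite therefore simulates
nulls with a per-edge change probability of 0.45, where D has enough
resolution for the rejection rate to be measurable, and verifies it stays
within the nominal band.

## Allele calling, genotypes, haplotype groups, maternal map

Clones are clustered by single linkage at ≤ 2 substitutions, with the
constraint that clones of one allele share identical gap extents (indels
are compared as coded extents, never per column).  Each cluster yields a
per-column majority consensus; clusters with fewer than 2 clones are
flagged as putative PCR/cloning artefacts, excluded from genotyping but
kept for audit — the support threshold operationalises the cloning
protocol's "captured more than once" stopping rule.

Group assignment is two-stage: major clade by the diagnostic deletion,
then subgroup by minimum p-distance to exemplar sequences, with a margin
rule (runner-up within 0.5% p-distance → unassigned).  Distance to
exemplars was chosen over full tree placement because the subgroups are
deeply separated; placement is noted as future work.

A genotype is the *set* of allele multisets of size equal to the ploidy
that contain every observed group — dosage is unobservable from
presence/absence clone data, so candidates are exposed, never chosen.
There are C(p−1, k−1) candidates for k groups at ploidy p.  Labels use
star notation ("X3*Y") when more than one candidate exists; unique
candidates print the full multiset ("X2Y", "X2X2").

Chloroplast haplotypes are clustered hierarchically (average linkage on
p-distance) and cut at the midpoint of the largest gap in the sorted merge
heights (a leading zero is included so mutually divergent singletons still
separate).  All-identical inputs give one group.  A single diffuse cluster
with no deep structure can be over-split by this rule; the target use case
has well-separated groups (between/within divergence ratio ≥ 4, where the
simulated partition is recovered exactly).  Group labels are assigned by
decreasing size, ties by smallest member id.

The allele→haplotype maternal map runs a consistency pass and an
elimination pass to a fixpoint: an allele maps to haplotype h when all its
non-exempt carriers share h *and* in at least one carrier no co-allele is
a globally consistent alternative donor; carriers whose haplotype is
already explained by a mapped co-allele are then dropped from the evidence
for the remaining alleles, and the sweep restarts after every new mapping
(deterministic allele order).  Rival candidacy is judged on an allele's
*full* carrier set — an allele seen with several haplotypes can never be
the unique donor of one of them.  Alleles that stay consistent but never
unique are reported as ambiguous candidates; inconsistent carriers produce
conflict records.  Nothing is guessed.

## Diploids-first network reconstruction

Parent pool: observed taxa (one entry per genotype candidate), one
presumed homozygous sexual diploid per allele lineage (matched to an
observed sexual taxon when one exists), presumed apogamous diploid hybrids
for every allele pair (depth-1 intermediates), and sexual tetraploids
derived by genome doubling of any diploid (doubling an apogamous hybrid
restores sexuality) or genome addition of two sexual diploids, merged by
genotype with multi-provenance.  "Ploidy reduction" is deliberately not an
available mechanism.

Gamete rules: a sexual parent of even ploidy p contributes any size-p/2
sub-multiset (tetrasomic segregation by default; a flag restricts 2+2
tetraploids to disomic heterogametes); an apogamous parent contributes its
full genotype unreduced and acts only as father (a flag permits apogamous
mothers for exploratory use).  A cross is feasible when the gametes sum to
an offspring genotype candidate and, under the maternal constraint, the
mother can carry the offspring's chloroplast haplotype.  Mothers of
unknown haplotype are rejected when the offspring haplotype is known
(policy `unknown_mother="reject"`): allowing them would multiply
unfalsifiable scenarios.  With the constraint off, role-swapped duplicates
of sexual × sexual crosses collapse to a canonical orientation
(lower-ploidy parent as mother, then lexicographic).

The search assigns one originating cross per observed apogamous taxon by
exhaustive branch-and-bound, choosing a provenance for every presumed
tetraploid used (its chain of presumed sources is charged too) and
minimising the number of distinct presumed nodes; ties break by fewer
total events, then a deterministic serialisation.  A presumed node is
pinned to a single realised maternal haplotype within one network — it
cannot mother an α offspring in one cross and a β offspring in another.
All co-optimal networks are retained (capped, default 20), and taxa whose
maternal parent differs across co-optimal networks are reported by
`maternal_ambiguity()` — the correct reading for triploids whose
chloroplast group conflicts with their allele content, whose parentage the
pipeline surfaces as ambiguous rather than resolves.  A taxon with no
feasible cross at all is reported as unexplained, not an error.

## Synthetic-data generator

The generator emulates the statistical structure the pipeline assumes:
five nuclear allele lineages in two deep clades separated by a 15-column
diagnostic deletion; three chloroplast groups tied to the non-deletion
lineages through a configurable maternal map; hybrids of ploidy 2–4
produced by an event list executed under the same gamete rules the network
search assumes; dosage- and bias-weighted clone sampling with per-base PCR
errors; two-peak histograms at ratio 0.6 × ploidy with Gaussian peaks
(CV 3%) and Poisson counting noise; and apogamous spore counts (32 with
probability 0.9, else 16 or 28, five sporangia per plant).

Sequence evolution is independent per-site substitution at configured
expected pairwise divergences (0.5% within lineage, 3% between subgroups,
8% between clades; 0.5%/4% for chloroplast) — adequate at these levels,
but it omits rate heterogeneity, indel turnover beyond the diagnostic
deletion, and recombination (apogamy removes recombination from the real
system too).  PCR bias is a per-allele multiplicative sampling weight, a
deliberate simplification of a qualitative phenomenon.  Clone sampling
follows the adaptive laboratory protocol: at least 6 clones for a diploid,
4 more per extra genome copy, continuing (to at most 24) until at least
two allele types have each been captured more than once.  The effective
per-base clone error is 0.0005, a realistic figure for cloned products of
a non-proofreading polymerase and consistent with the 2-substitution
clone-clustering threshold at the simulated 600 bp fragment length.
Histograms use 1024 channels with the standard at channel 200 and 20000
cells split between the two peaks.

Everything is deterministic for a fixed seed (byte-identical bundles).
Passing tests on these simulations demonstrate the inference chain under
its own assumptions — clean peaks, well-separated lineages, conflict-free
maternal maps — not robustness to misalignment, contamination, aneuploidy
or chimeric clones, none of which the generator produces.

## Problem sizes in the test suite

The oracle suites run 500 Fitch-versus-enumeration cases at ≤ 6 leaves,
100 heuristic-versus-exhaustive searches at 8 taxa × 30 binary characters,
and 200 random alignments against a column-scan indel oracle.  ILD
calibration uses 200 null trials and 100 power trials at 199 permutations
each; end-to-end recovery uses 50 fixed-design and 100 randomised
complexes of 4–8 hybrids.  These sizes keep the full suite in the
single-digit minutes on one CPU while leaving each statistical band
well-resolved.

## Known limitations

- Subgroup assignment by exemplar distance assumes deep, well-separated
  subclades; closely spaced subgroups would need placement-based
  assignment.
- The largest-gap dendrogram cut can over-split a single diffuse cluster.
- The maternal map's elimination order favours alphabetically earlier
  alleles among simultaneously mappable ones; symmetric adversarial cases
  are resolved deterministically but reported, not proven unique.
- Derived tetraploids pool possible maternal haplotypes across
  provenances; the realised-haplotype pin is per network node, not coupled
  to the chosen provenance.
- The network search is exhaustive only at the intended scale (≤ ~15
  observed taxa, ≤ ~8 alleles, intermediate depth 1); a node-exploration
  cap guards against pathological inputs.
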