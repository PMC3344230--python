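# reticulator

Multi-evidence reconstruction of reticulate (net-like) origins in apogamous
fern species complexes.

Apogamous ferns reproduce asexually — sporophytes form without
fertilisation, each lineage propagating its genotype clonally — yet some
apogamous complexes show striking morphological diversity.  The standard
explanation is recurrent hybridisation and polyploidy: sexual diploid
progenitors crossed repeatedly, each hybrid then "froze" as an independent
apogamous lineage.  Testing that hypothesis takes four evidence streams per
plant, and this package implements the full inference chain:

1. **Ploidy** from flow cytometry: the sample G1 peak is compared with a
   co-run calibration standard (a 4X tobacco standard of 20.08 pg).  In the
   target complexes the sample/standard ratio r falls near `0.6 × ploidy`
   (1.2, 1.8, 2.4 for 2X/3X/4X), and genome size is `r × 20.08 pg`.
2. **Reproduction mode** from spore counts: sexual plants package 64 spores
   per sporangium, apogamous plants 32 or fewer.
3. **Biparental nuclear genotype** from cloned sequences of a single-copy
   gene (a PgiC-like marker): clones are collapsed into allele calls,
   assigned to allele lineage groups (a diagnostic 15 bp deletion separates
   the two deep clades; p-distance to exemplars resolves subgroups), and
   combined with ploidy into a dosage-ambiguous genotype — a triploid
   carrying alleles X3 and Y is written `X3*Y` because it may be X3X3Y or
   X3YY.
4. **Maternal lineage** from chloroplast haplotypes, clustered into deep
   groups (α, β, γ, ...) and tied to allele lineages through an
   allele→haplotype maternal map.

A compact maximum-parsimony engine (Fitch lengths; CI = Σmᵢ/L and
RI = (G−L)/(G−M) tree statistics; exhaustive and random-addition + SPR/NNI
searches; character bootstrap; the ILD partition-homogeneity permutation
test) supports the sequence analyses, with simple indel coding turning
alignment gaps into binary characters (exact gap extent → 1, no overlap →
0, conflicting overlap → missing).

The final stage is a **diploids-first network search**: posit one
homozygous sexual diploid per allele lineage (X1X1 … YY), derive candidate
sexual tetraploids by genome doubling and genome addition, and explain each
observed apogamous taxon by one cross — sexual mothers contribute reduced
gametes and must carry the offspring's chloroplast haplotype; apogamous
hybrids act only as fathers, contributing unreduced genomes.  A
branch-and-bound search returns every network that minimises the number of
presumed (unobserved) taxa.

A synthetic-data generator emits complete observation bundles (clone
FASTAs, histograms CSVs, spore counts, metadata) with known ground truth,
so every stage is testable end to end.

## Worked example

```python
from reticulator import (
    reference_fixture, infer_allele_haplotype_map, infer_network,
)
from reticulator.simulate import FIXTURE_EXEMPT

taxa = reference_fixture()                    # the transcribed 11-taxon complex
amap = infer_allele_haplotype_map(taxa, exempt=FIXTURE_EXEMPT)
print(amap.mapping)
net = infer_network(taxa, amap)
print(len(taxa), [p.name for p in net.progenitors], net.cost)
print(sorted(net.maternal_ambiguity()))
```

prints

```
{'X1': 'alpha', 'X3': 'gamma', 'X4': 'beta', 'X2': 'alpha'}
11 ['X1X1', 'X2X2', 'X3X3', 'X4X4', 'YY'] 7
['morph2-4x', 'morph5-3x', 'morph8-3x', 'morph8-4x']
```

— the 11 observed (morph, cytotype) taxa are explained from five
hypothesised homozygous diploid progenitors plus two presumed sexual
tetraploid intermediates (cost 7 presumed nodes in total); the maternal map
ties alleles X1/X2 to chloroplast group α, X3 to γ and X4 to β, leaving Y
unmapped; and the triploids whose haplotype conflicts with their allele
content are reported as maternally ambiguous across the co-optimal
networks rather than resolved.

A command-line interface wraps the stages:

```bash
reticulator simulate --outdir sim --seed 3     # synthetic bundle + truth
reticulator run -c sim --outdir out            # full pipeline, TSV tables
reticulator fixture --out fixture.tsv          # the 11-taxon table
reticulator mp-search --fasta aln.fasta        # parsimony search
reticulator ild --fasta1 a.fa --fasta2 b.fa    # partition-homogeneity test
```

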