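# File formats

All files are plain text; coordinates are 1-based inclusive in file
headers, 0-based half-open inside the library.

## Bundle directory (pipeline input; emitted by `reticulator simulate`)

- `samples.tsv` — tab-separated sample sheet: `individual`, `region`
  (semicolon-separated labels), `phenology`, `spores` (comma-separated
  per-sporangium counts), `histogram` (CSV filename), `clones` (FASTA
  filename).
- `hist_<individual>.csv` — flow-cytometry histogram, header
  `channel,count`, one row per fluorescence bin.
- `clones_<individual>.fasta` — aligned clone sequences, ids
  `individual|clone`.
- `nuclear_refs.fasta` — one aligned exemplar per allele lineage group
  (ids are the group names); deletion carriers show the diagnostic gap.
- `chloroplast.fasta` — one aligned chloroplast sequence per individual.
- `bundle.json` — manifest: `diagnostic_window` (0-based half-open
  columns), `standard_channel`.
- `truth.jsonl` — simulator ground truth (progenitors, resolved events,
  per-individual latent states), one JSON object per line.

## Pipeline outputs (`reticulator run --outdir`)

- `cytometry.tsv` — `sample_id, ratio, genome_size_pg, ploidy, mode`.
- `alleles.tsv` — `individual, allele, group, support, flagged_singleton`.
- `genotypes.tsv` — `individual, ploidy, label, n_candidates` (star
  notation marks dosage ambiguity).
- `haplotypes.tsv` — `individual, group`.
- `map.tsv` — `allele, haplotype, kind` (`mapped` or `ambiguous`).
- `network.tsv` — edge list: `child, mother, father, mother_gamete,
  father_gamete, mechanism` (`cross`, `doubling` or `genome_addition`).
- `inventory.tsv` — per-region allele/haplotype/cytotype inventory with a
  `private` flag.
- `taxa.tsv` — one row per individual with genotype, haplotype, region and
  a `status` of `typed`, `flagged` or `unexplained`.
- `report.txt` — stage summaries, warnings and provenance (seed + config
  hash).

## Other formats

- Trees: standard Newick text (unrooted; a rooted basal bifurcation is
  smoothed on input).
- Coded indel matrices: TSV (`0`/`1`/`?`, columns named
  `indel_<start>_<end>` in 1-based inclusive coordinates) and a minimal
  NEXUS standard-data block (`SYMBOLS="01" MISSING=?`).
- Alignments: FASTA with `-` for gaps; IUPAC ambiguity codes preserved.
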