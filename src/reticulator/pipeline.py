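"""End-to-end orchestration: cytometry -> typing -> grouping -> network.

The pipeline consumes a bundle directory (sample sheet, per-individual
histogram CSVs and clone FASTAs, a chloroplast FASTA, nuclear reference
exemplars and a small JSON manifest — exactly what the synthetic-data
generator emits) and produces TSV tables plus a plain-text report.  Every
stage records a summary; a failed individual is carried through with an
explicit status rather than aborting the run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd

from reticulator.alignment import Alignment
from reticulator.cytometry import (
    FluorescenceHistogram,
    UnresolvableHistogramError,
    call_sample,
    classify_reproduction,
)
from reticulator.lineage import (
    CloneSet,
    assign_allele_group,
    collapse_clones,
    group_haplotypes,
    infer_allele_haplotype_map,
    infer_genotype,
)
from reticulator.reticulation import (
    NetworkConfig,
    infer_network,
    regional_partition,
)
from reticulator.simulate import ObservationBundle
from reticulator.taxa import TaxonObservation, observations_to_frame


@dataclass
class PipelineConfig:
    """All thresholds of the pipeline in one auditable place."""

    input_dir: Path
    output_dir: Path | None = None
    seed: int = 0
    # cytometry
    smoothing_window: int = 5
    min_prominence_fraction: float = 0.10
    ploidy_tolerance: float = 0.15
    # clone typing
    max_error_mismatches: int = 2
    min_support: int = 2
    min_margin: float = 0.005
    min_reciprocal_overlap: float = 0.8
    # haplotype grouping
    linkage_method: str = "average"
    # maternal map / network
    exempt: tuple[str, ...] = ()
    network: NetworkConfig = field(default_factory=NetworkConfig)

    def digest(self) -> str:
        """Hash of the analysis settings (paths excluded)."""
        payload = {
            k: str(v)
            for k, v in self.__dict__.items()
            if k not in ("input_dir", "output_dir")
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class RunReport:
    stage_summaries: dict[str, dict]
    tables: dict[str, pd.DataFrame]
    warnings: list[str]
    provenance: dict

    def render(self) -> str:
        lines = ["pipeline report", "================"]
        for stage, summary in self.stage_summaries.items():
            lines.append(f"[{stage}] " + " ".join(f"{k}={v}" for k, v in summary.items()))
        for w in self.warnings:
            lines.append(f"WARNING: {w}")
        lines.append("provenance: " + json.dumps(self.provenance, sort_keys=True))
        return "\n".join(lines) + "\n"


def load_bundle(directory: str | Path) -> ObservationBundle:
    """Read a bundle directory back into memory (inverse of bundle.write)."""
    directory = Path(directory)
    sheet = pd.read_csv(directory / "samples.tsv", sep="\t", dtype=str)
    manifest = json.loads((directory / "bundle.json").read_text())
    clone_sets = {}
    histograms = {}
    spores = {}
    for _, row in sheet.iterrows():
        ind = row["individual"]
        clones = []
        aln = Alignment.from_fasta(directory / row["clones"])
        for cid, seq in aln.items():
            clones.append((cid.split("|", 1)[-1], seq))
        clone_sets[ind] = CloneSet(ind, "nuclear", tuple(clones))
        histograms[ind] = FluorescenceHistogram.from_csv(
            directory / row["histogram"], sample_id=ind
        )
        spores[ind] = tuple(int(x) for x in row["spores"].split(","))
    return ObservationBundle(
        nuclear_references=Alignment.from_fasta(directory / "nuclear_refs.fasta"),
        diagnostic_window=tuple(manifest["diagnostic_window"]),
        chloroplast=Alignment.from_fasta(directory / "chloroplast.fasta"),
        clone_sets=clone_sets,
        histograms=histograms,
        spore_counts=spores,
        metadata=sheet[["individual", "region", "phenology"]].copy(),
        standard_channel=float(manifest["standard_channel"]),
    )


def analyze_bundle(bundle: ObservationBundle, config: PipelineConfig) -> RunReport:
    """Run every stage on an in-memory bundle."""
    warnings: list[str] = []
    summaries: dict[str, dict] = {}
    tables: dict[str, pd.DataFrame] = {}

    meta = bundle.metadata.set_index("individual")
    individuals = list(bundle.clone_sets)

    # stage 1: cytometry + reproduction
    cyto_rows = []
    ploidies: dict[str, int | str] = {}
    modes: dict[str, str] = {}
    for ind in individuals:
        try:
            call = call_sample(
                bundle.histograms[ind],
                smoothing_window=config.smoothing_window,
                min_prominence_fraction=config.min_prominence_fraction,
                tolerance=config.ploidy_tolerance,
            )
            ploidies[ind] = call.ploidy
            ratio, genome = call.ratio, call.genome_size_pg
        except UnresolvableHistogramError as exc:
            warnings.append(str(exc))
            ploidies[ind] = "uncalled"
            ratio = genome = float("nan")
        repro = classify_reproduction(bundle.spore_counts[ind])
        modes[ind] = repro.mode
        cyto_rows.append(
            {
                "sample_id": ind,
                "ratio": round(ratio, 4),
                "genome_size_pg": round(genome, 3),
                "ploidy": ploidies[ind],
                "mode": repro.mode,
            }
        )
    tables["cytometry"] = pd.DataFrame(cyto_rows)
    summaries["cytometry"] = {
        "n": len(individuals),
        "uncalled": sum(1 for p in ploidies.values() if p == "uncalled"),
    }

    # stage 2: clone collapse + allele-group assignment
    allele_rows = []
    groups_by_ind: dict[str, set[str]] = {}
    for ind in individuals:
        calls = collapse_clones(
            bundle.clone_sets[ind],
            max_error_mismatches=config.max_error_mismatches,
            min_support=config.min_support,
        )
        accepted = set()
        for c in calls:
            if not c.flagged_singleton:
                c.group = assign_allele_group(
                    c,
                    bundle.nuclear_references,
                    bundle.diagnostic_window,
                    min_margin=config.min_margin,
                    min_reciprocal_overlap=config.min_reciprocal_overlap,
                )
                if c.group != "unassigned":
                    accepted.add(c.group)
            else:
                warnings.append(f"{ind}: singleton allele {c.allele_id} excluded")
            allele_rows.append(
                {
                    "individual": ind,
                    "allele": c.allele_id,
                    "group": c.group,
                    "support": c.support,
                    "flagged_singleton": c.flagged_singleton,
                }
            )
        groups_by_ind[ind] = accepted
    tables["alleles"] = pd.DataFrame(allele_rows)
    summaries["alleles"] = {
        "n_calls": len(allele_rows),
        "n_singletons": sum(r["flagged_singleton"] for r in allele_rows),
    }

    # stage 3: genotypes
    geno_rows = []
    observations: list[TaxonObservation] = []
    statuses: dict[str, str] = {}
    for ind in individuals:
        ploidy = ploidies[ind]
        groups = groups_by_ind[ind]
        if ploidy == "uncalled" or not groups or len(groups) > (ploidy if isinstance(ploidy, int) else 0):
            statuses[ind] = "flagged"
            warnings.append(f"{ind}: cannot type (ploidy={ploidy}, groups={sorted(groups)})")
            continue
        genotype = infer_genotype(groups, int(ploidy))
        statuses[ind] = "typed"
        geno_rows.append(
            {
                "individual": ind,
                "ploidy": ploidy,
                "label": genotype.label,
                "n_candidates": len(genotype.candidates),
            }
        )
        region = meta.loc[ind, "region"] if ind in meta.index else ""
        observations.append(
            TaxonObservation(
                taxon_id=ind,
                ploidy=int(ploidy),
                genotype=genotype,
                haplotype=None,
                reproduction="apogamous" if modes[ind] == "apogamous" else modes[ind],
                region=frozenset(r for r in str(region).split(";") if r),
                phenology=meta.loc[ind, "phenology"] if ind in meta.index else "unknown",
            )
        )
    tables["genotypes"] = pd.DataFrame(geno_rows)
    summaries["genotypes"] = {"typed": len(geno_rows), "flagged": sum(
        1 for s in statuses.values() if s == "flagged")}

    # stage 4: chloroplast haplotype groups
    grouping = group_haplotypes(bundle.chloroplast, linkage_method=config.linkage_method)
    for obs in observations:
        obs.haplotype = grouping.labels.get(obs.taxon_id)
    tables["haplotypes"] = pd.DataFrame(
        [{"individual": k, "group": v} for k, v in sorted(grouping.labels.items())]
    )
    summaries["haplotypes"] = {"n_groups": grouping.n_groups}

    # stage 5: allele -> haplotype maternal map
    amap = infer_allele_haplotype_map(observations, exempt=config.exempt)
    tables["map"] = pd.DataFrame(
        [{"allele": a, "haplotype": h, "kind": "mapped"} for a, h in sorted(amap.mapping.items())]
        + [{"allele": a, "haplotype": h, "kind": "ambiguous"} for a, h in sorted(amap.ambiguous.items())]
    )
    for taxon, allele, expected, observed in amap.conflicts:
        warnings.append(f"map conflict: {taxon} carries {allele} with {observed} (expected {expected})")
    summaries["map"] = {"mapped": len(amap.mapping), "conflicts": len(amap.conflicts)}

    # stage 6: reticulate network
    network = infer_network(observations, amap, config.network)
    tables["network"] = network.edge_frame()
    for tid in network.unexplained:
        statuses[tid] = "unexplained"
        warnings.append(f"{tid}: no feasible cross under the allowed parent sets")
    summaries["network"] = {
        "cost": network.cost,
        "co_optimal": len(network.co_optimal) + 1,
        "unexplained": len(network.unexplained),
    }

    # stage 7: regional partition
    partition = regional_partition(network, observations)
    tables["inventory"] = partition.inventory
    summaries["regions"] = {
        "n_regions": len(partition.subnetworks),
        "unplaced": len(partition.unplaced),
    }

    taxa_frame = observations_to_frame(observations)
    taxa_frame["status"] = [statuses[t] for t in taxa_frame["taxon_id"]]
    flagged = [
        {"taxon_id": ind, "ploidy": ploidies[ind], "genotype_label": "", "status": "flagged"}
        for ind, s in statuses.items()
        if s == "flagged"
    ]
    if flagged:
        taxa_frame = pd.concat([taxa_frame, pd.DataFrame(flagged)], ignore_index=True)
    tables["taxa"] = taxa_frame

    report = RunReport(
        stage_summaries=summaries,
        tables=tables,
        warnings=warnings,
        provenance={"seed": config.seed, "config": config.digest(), "version": "0.1.0"},
    )
    report.network = network  # type: ignore[attr-defined]
    report.observations = observations  # type: ignore[attr-defined]
    report.amap = amap  # type: ignore[attr-defined]
    return report


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Load a bundle directory, analyse it, and write the output tables."""
    report = analyze_bundle(load_bundle(config.input_dir), config)
    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in report.tables.items():
            table.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        (outdir / "report.txt").write_text(report.render())
    return report


def validate_inputs(config: PipelineConfig) -> list[str]:
    """Schema checks on the bundle directory; returns issues, raises nothing."""
    issues: list[str] = []
    directory = Path(config.input_dir)
    sheet_path = directory / "samples.tsv"
    if not sheet_path.exists():
        return [f"missing sample sheet: {sheet_path}"]
    sheet = pd.read_csv(sheet_path, sep="\t", dtype=str)
    if sheet.empty:
        issues.append("sample sheet is empty")
    required = {"individual", "region", "phenology", "spores", "histogram", "clones"}
    missing_cols = required - set(sheet.columns)
    if missing_cols:
        issues.append(f"sample sheet lacks columns: {sorted(missing_cols)}")
        return issues
    dupes = sheet["individual"][sheet["individual"].duplicated()].tolist()
    for d in dupes:
        issues.append(f"duplicate individual id: {d}")
    for row_no, row in sheet.iterrows():
        for col in ("histogram", "clones"):
            path = directory / str(row[col])
            if not path.exists():
                issues.append(f"row {row_no + 1}: missing file {path.name}")
        try:
            counts = [int(x) for x in str(row["spores"]).split(",")]
            if any(c < 0 for c in counts):
                issues.append(f"row {row_no + 1}: negative spore count")
        except ValueError:
            issues.append(f"row {row_no + 1}: unparseable spore counts {row['spores']!r}")
    for fname in ("bundle.json", "nuclear_refs.fasta", "chloroplast.fasta"):
        if not (directory / fname).exists():
            issues.append(f"missing file: {fname}")
    obs_path = directory / "observations.tsv"
    if obs_path.exists():
        obs = pd.read_csv(obs_path, sep="\t", dtype=str)
        for row_no, row in obs.iterrows():
            try:
                from reticulator.taxa import parse_group_string

                ploidy = int(row["ploidy"])
                groups = parse_group_string(row["genotype_label"].replace("*", ""))
                if len(groups) > ploidy:
                    issues.append(
                        f"observations row {row_no + 1}: genotype/ploidy mismatch"
                    )
            except (ValueError, KeyError) as exc:
                issues.append(f"observations row {row_no + 1}: {exc}")
    return issues
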