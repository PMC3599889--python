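"""End-to-end orchestration: reference building, per-library mapping,
quantification, differential expression, and stage-pattern reports.

``run_pipeline`` executes the stages in order, writes the tabular
reports of each stage under the configured output directory, and fails
fast with the offending stage named.  Identical configuration yields
byte-identical outputs (every random step is seeded from the run seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import io as tagio
from .diffexpr import call_de
from .mapping import filter_raw_tags, map_tags, mapping_summary, strand_breakdown
from .quantify import (
    ExpressionMatrix,
    copy_number_distribution,
    detect_genes,
    saturation_curve,
)
from .reference import build_reference_from_fasta, library_summary
from .stages import categorize_stages, compare_genotypes, transition_analysis

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is carried in the message."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class LibrarySpec:
    library_id: str
    path: str
    genotype: str | None = None
    stage: str | None = None
    format: str | None = None  # text | fastq | tsv (None: by extension)


@dataclass
class RunConfig:
    """Structured configuration of one pipeline run."""

    reference_fasta: str
    libraries: list[LibrarySpec]
    output_dir: str
    tag_tail_length: int = 17
    include_antisense: bool = True
    min_copies: int = 2
    drop_n: bool = True
    adapters: list[str] = field(default_factory=list)
    max_mismatch: int = 0
    detection_threshold: float = 1.0
    fdr_threshold: float = 0.001
    fc_threshold_log2: float = 1.0
    tpm_floor: float = 0.001
    saturation_steps: int = 10
    copy_number_bins: list[list[float]] | None = None
    de_pairs: list[list[str]] | None = None  # [[lib_a, lib_b], ...]
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        libs = [LibrarySpec(**entry) for entry in raw.pop("libraries")]
        return cls(libraries=libs, **raw)

    def default_de_pairs(self) -> list[list[str]]:
        """Pair libraries of the same stage across the two genotypes."""
        if self.de_pairs is not None:
            return self.de_pairs
        by_stage: dict[str, dict[str, str]] = {}
        for lib in self.libraries:
            if lib.stage and lib.genotype:
                by_stage.setdefault(lib.stage, {})[lib.genotype] = lib.library_id
        pairs = []
        for stage, members in by_stage.items():
            genos = sorted(members)
            if len(genos) == 2:
                wt = "WT" if "WT" in members else genos[0]
                other = next(g for g in genos if g != wt)
                pairs.append([members[wt], members[other]])
        return pairs


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
                raise PipelineError(name, exc) from exc

        return wrapped

    return deco


@_stage("reference_tags")
def _build_reference(config: RunConfig):
    ref = build_reference_from_fasta(
        config.reference_fasta,
        tag_tail_length=config.tag_tail_length,
        include_antisense=config.include_antisense,
    )
    logger.info(
        "reference: %d genes, %d distinct tags (%d unambiguous)",
        ref.n_genes,
        ref.total_reference_tags,
        ref.unambiguous_reference_tags,
    )
    return ref


@_stage("tag_processing")
def _process_library(config: RunConfig, ref, spec: LibrarySpec, outdir: Path):
    raw = tagio.read_tags(spec.path, fmt=spec.format)
    lib = filter_raw_tags(
        raw,
        library_id=spec.library_id,
        min_copies=config.min_copies,
        drop_n=config.drop_n,
        adapter_list=config.adapters,
        genotype=spec.genotype,
        stage=spec.stage,
    )
    result = map_tags(lib, ref, max_mismatch=config.max_mismatch)
    result.to_gene_tsv(outdir / f"{spec.library_id}.genes.tsv")
    result.to_unknown_tsv(outdir / f"{spec.library_id}.unknown.tsv")
    summary = mapping_summary(result, n_reference_genes=ref.n_genes)
    summary["Raw data"] = {"Total": lib.raw_total, "Distinct tags": lib.raw_distinct}
    summary["strand_breakdown"] = strand_breakdown(result)
    with open(outdir / f"{spec.library_id}.summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return lib, result, summary


@_stage("quantification")
def _quantify(config: RunConfig, libs, results, outdir: Path):
    matrix = ExpressionMatrix.from_mapping_results(results)
    matrix.to_tsv(outdir / "expression_matrix.tsv")
    flags, detected = detect_genes(matrix, config.detection_threshold)
    detected.to_csv(outdir / "detected_genes.tsv", sep="\t", header=["detected_genes"])
    for lib, res in zip(libs, results):
        if lib.clean_counts:
            dist = copy_number_distribution(lib.clean_counts)
            dist.to_csv(
                outdir / f"{lib.library_id}.copy_number.tsv", sep="\t", index=False
            )
            sat = saturation_curve(
                lib.clean_counts, res, n_steps=config.saturation_steps, seed=config.seed
            )
            sat.to_csv(outdir / f"{lib.library_id}.saturation.tsv", sep="\t", index=False)
    return matrix, flags, detected


@_stage("differential_expression")
def _differential(config: RunConfig, matrix, outdir: Path):
    summaries = []
    for lib_a, lib_b in config.default_de_pairs():
        table, summary = call_de(
            matrix,
            lib_a,
            lib_b,
            fdr_threshold=config.fdr_threshold,
            fc_threshold_log2=config.fc_threshold_log2,
            tpm_floor=config.tpm_floor,
            detection_threshold=config.detection_threshold,
        )
        table.to_csv(outdir / f"de_{lib_b}_vs_{lib_a}.tsv", sep="\t", float_format="%.6g")
        summaries.append(summary.as_dict())
    with open(outdir / "de_summaries.json", "w") as fh:
        json.dump(summaries, fh, indent=2)
        fh.write("\n")
    return summaries


@_stage("stage_dynamics")
def _stage_patterns(config: RunConfig, flags, outdir: Path):
    stage_order = []
    by_genotype: dict[str, dict[str, str]] = {}
    for lib in config.libraries:
        if lib.genotype and lib.stage:
            by_genotype.setdefault(lib.genotype, {})[lib.stage] = lib.library_id
            if lib.stage not in stage_order:
                stage_order.append(lib.stage)
    reports = {}
    for genotype, members in sorted(by_genotype.items()):
        if len(members) != 3:
            logger.info("genotype %s lacks a 3-stage grid; skipping patterns", genotype)
            continue
        det = flags[[members[s] for s in stage_order]].copy()
        det.columns = stage_order
        report = categorize_stages(det, genotype=genotype)
        reports[genotype] = report
        report.patterns.to_csv(outdir / f"stage_patterns_{genotype}.tsv", sep="\t")
        with open(outdir / f"stage_categories_{genotype}.json", "w") as fh:
            json.dump(
                {
                    "genotype": genotype,
                    "category_counts": report.category_counts,
                    "total_expressed": report.total_expressed,
                },
                fh,
                indent=2,
            )
            fh.write("\n")
        transition_analysis(report).to_csv(
            outdir / f"stage_transitions_{genotype}.tsv", sep="\t"
        )
    if len(reports) == 2:
        genos = sorted(reports)
        wt = "WT" if "WT" in reports else genos[0]
        other = next(g for g in genos if g != wt)
        compare_genotypes(reports[wt], reports[other]).to_csv(
            outdir / "genotype_comparison.tsv", sep="\t", float_format="%.4g"
        )
    return reports


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full pipeline and return the in-memory report bundle."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("run configuration: %s", config)

    ref = _build_reference(config)
    with open(outdir / "reference_summary.json", "w") as fh:
        json.dump(library_summary(ref, ref.n_genes), fh, indent=2)
        fh.write("\n")

    libs, results, summaries = [], [], []
    for spec in config.libraries:
        lib, result, summary = _process_library(config, ref, spec, outdir)
        libs.append(lib)
        results.append(result)
        summaries.append(summary)

    matrix, flags, detected = _quantify(config, libs, results, outdir)
    de_summaries = _differential(config, matrix, outdir)
    stage_reports = _stage_patterns(config, flags, outdir)

    bundle = {
        "reference": ref,
        "libraries": libs,
        "mapping_results": results,
        "mapping_summaries": summaries,
        "matrix": matrix,
        "detection": flags,
        "detected_counts": detected,
        "de_summaries": de_summaries,
        "stage_reports": stage_reports,
    }
    logger.info("pipeline complete: outputs in %s", outdir)
    return bundle
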