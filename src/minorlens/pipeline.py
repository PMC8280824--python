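"""End-to-end orchestration: introns -> classify -> quantify -> filter ->
differential -> subtype summary (optionally -> co-occurrence).

Every stage writes a self-describing TSV into the output directory and
the run finishes with a ``manifest.json`` recording the tool version,
a hash of the configuration, the seed, and per-stage row counts.
Rerunning with identical inputs and seed reproduces byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import pandas as pd

from . import __version__
from .annotation_io import (
    extract_introns,
    read_annotation,
    read_genome,
    write_intron_bed,
    write_intron_tsv,
)
from .coevolution import (
    profile_correlation,
    read_profile_matrix,
    select_cooccurring,
)
from .differential_ir import (
    cluster_retention,
    differential_table,
    summarize_by_subtype,
)
from .retention_quant import (
    compute_psi,
    count_intron_evidence,
    filter_introns,
    read_alignments,
)
from .u12_classifier import classify_catalog

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Inputs, thresholds and output location of one pipeline run."""

    genome: str
    gtf: str
    out_dir: str
    sam_paths: list[str] = field(default_factory=list)
    counts_path: str | None = None
    design: dict[str, str] = field(default_factory=dict)
    control: str = "control"
    treatment: str = "treatment"
    theta5: float = 0.07
    theta_bps: float = 0.14
    anchor: int = 8
    min_junction: int = 5
    alpha: float = 0.05
    dpsi: float = 0.1
    r_min: float = 0.5
    profile_matrix: str | None = None
    query_gene: str | None = None
    seed: int = 0


def _config_hash(config: RunConfig) -> str:
    # the hash covers inputs, thresholds and seed, not the output
    # location, so runs into different directories stay comparable
    payload = {k: v for k, v in asdict(config).items() if k != "out_dir"}
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; returns the manifest dictionary."""
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
    }

    def done(stage: str, rows: int) -> None:
        manifest["stages"][stage] = {"status": "complete", "rows": rows}
        logger.info("stage %s complete (%d rows)", stage, rows)

    out = lambda name: os.path.join(config.out_dir, name)

    # 1. intron catalog
    try:
        genome = read_genome(config.genome)
        transcripts = read_annotation(config.gtf)
        introns = extract_introns(transcripts, genome)
        write_intron_tsv(introns, out("introns.tsv"))
        write_intron_bed(introns, out("introns.bed"))
    except Exception as exc:
        raise PipelineError("introns", exc) from exc
    done("introns", len(introns))

    # 2. classification
    try:
        classification = classify_catalog(
            introns, theta5=config.theta5, theta_bps=config.theta_bps
        )
        classification.to_csv(out("classification.tsv"), sep="\t", index=False)
    except Exception as exc:
        raise PipelineError("classify", exc) from exc
    done("classify", len(classification))

    # 3. quantification
    try:
        if config.counts_path:
            counts = pd.read_csv(config.counts_path, sep="\t")
        else:
            def stream():
                for path in config.sam_paths:
                    yield from read_alignments(path)

            counts = count_intron_evidence(stream(), introns, anchor=config.anchor)
        counts.to_csv(out("counts.tsv"), sep="\t", index=False)
    except Exception as exc:
        raise PipelineError("quantify", exc) from exc
    done("quantify", len(counts))

    # 4. read-count filter (junction filter for the IR comparison)
    try:
        filtered = filter_introns(counts, min_junction=config.min_junction)
        filtered.to_csv(out("counts_filtered.tsv"), sep="\t", index=False)
    except Exception as exc:
        raise PipelineError("filter", exc) from exc
    done("filter", len(filtered))

    # 5. differential retention
    try:
        diff = differential_table(
            filtered, config.design, config.control, config.treatment,
            alpha=config.alpha, dpsi_cutoff=config.dpsi,
        )
        diff.to_csv(out("differential.tsv"), sep="\t", index=False)
        psi = compute_psi(filtered, config.design)
        psi.to_csv(out("psi.tsv"), sep="\t", index=False)
    except Exception as exc:
        raise PipelineError("differential", exc) from exc
    done("differential", len(diff))

    # 6. subtype summary + clustering of per-sample psi
    try:
        summary = summarize_by_subtype(diff, classification)
        with open(out("subtype_summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        per_sample = filtered.copy()
        with pd.option_context("mode.chained_assignment", None):
            denom = per_sample["B"] / 2.0 + per_sample["J"]
            per_sample["psi"] = (per_sample["B"] / 2.0) / denom.where(denom > 0)
        psi_matrix = per_sample.pivot_table(
            index="intron_key", columns="sample", values="psi"
        )
        _, leaf_order = cluster_retention(psi_matrix)
        pd.DataFrame({"intron_key": leaf_order}).to_csv(
            out("cluster_order.tsv"), sep="\t", index=False
        )
    except Exception as exc:
        raise PipelineError("summarize", exc) from exc
    done("summarize", len(summary["subtypes"]))

    # 7. optional co-occurrence screen
    if config.profile_matrix and config.query_gene:
        try:
            matrix = read_profile_matrix(config.profile_matrix)
            ranked = profile_correlation(config.query_gene, matrix)
            ranked.to_csv(out("cooccurrence.tsv"), sep="\t", index=False)
            selected = select_cooccurring(
                ranked, r_min=config.r_min, query_gene=config.query_gene
            )
            pd.DataFrame({"gene": sorted(selected)}).to_csv(
                out("cooccurring_genes.tsv"), sep="\t", index=False
            )
        except Exception as exc:
            raise PipelineError("coevolve", exc) from exc
        done("coevolve", len(ranked))

    manifest_path = out("manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
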