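"""End-to-end orchestration of the locus analysis stages.

Each stage is runnable standalone (the CLI exposes them one by one); this
module provides the shared per-species chain (annotate -> assemble -> lesion
scan -> status call) plus the full pipeline driver that writes a run manifest
and a machine-readable summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .annotate import (
    CodingSequence,
    GeneModel,
    assemble_cds,
    assign_hits_to_genes,
    find_exon_hits,
    rescue_missing_exons,
)
from .core import GenomicLocus, PipelineConfig, ReferenceGeneSet
from .status import GeneStatus, classify_gene_status, detect_lesions, write_status_table

log = logging.getLogger(__name__)


@dataclass
class GeneCall:
    """One homolog's annotation + classification in one species."""

    model: GeneModel
    cds: CodingSequence | None
    status: GeneStatus


def annotate_and_classify(
    locus: GenomicLocus,
    reference: ReferenceGeneSet,
    config: PipelineConfig | None = None,
    transcripts: Mapping[str, list[str]] | None = None,
) -> dict[str, GeneCall]:
    """Annotate one locus and classify every reference gene family.

    Returns a mapping from model id (reference gene id, or ``gene~copyN`` for
    extra copies) to the call. Reference genes with no recovered exons are
    reported as absent with completeness 0.
    """
    config = config or PipelineConfig()
    hits = find_exon_hits(locus, reference, config)
    models = assign_hits_to_genes(hits, reference, species=locus.species)
    rescue_missing_exons(models, locus, reference, config)
    calls: dict[str, GeneCall] = {}
    for model in models:
        base = model.gene_id.split("~")[0]
        ref_gene = reference[base]
        ref_cds = ref_gene.cds
        cds = assemble_cds(model, locus)
        lesions = detect_lesions(cds.seq, ref_cds, [len(e) for e in ref_gene.exons])
        cds.lesions = lesions
        aligned_fraction = min(1.0, len(cds.seq) / len(ref_cds))
        from .status import check_transcript_support

        tsupport = check_transcript_support(
            cds.seq, (transcripts or {}).get(base), config
        ) if transcripts is not None else "not_checked"
        status = classify_gene_status(
            completeness=model.completeness,
            aligned_fraction=aligned_fraction,
            lesions=lesions,
            transcript_support=tsupport,
            config=config,
        )
        calls[model.gene_id] = GeneCall(model=model, cds=cds, status=status)
    for gene in reference:
        if not any(k.split("~")[0] == gene.gene_id for k in calls):
            calls[gene.gene_id] = GeneCall(
                model=GeneModel(
                    gene_id=gene.gene_id,
                    species=locus.species,
                    exon_hits=[],
                    slot=gene.slot,
                    n_reference_exons=len(gene.exons),
                ),
                cds=None,
                status=GeneStatus(call="absent", completeness=0.0),
            )
    return calls


@dataclass
class RunManifest:
    config: dict
    rng_seed: int
    stages: list[str]
    input_digests: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.__dict__, indent=1, sort_keys=True))
        return path


def _digest(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    *,
    sim_preset: str = "primate",
    scale: float = 0.25,
    stages: tuple[str, ...] = ("simulate", "annotate", "status", "blocks", "events"),
) -> dict:
    """Run the simulated end-to-end analysis and write reports.

    Returns the summary dictionary (also written as ``summary.json``).
    Stages not listed are skipped; each stage reads only what earlier stages
    produced, so the pipeline can be resumed from files.
    """
    from . import blocks as blocks_mod
    from . import events as events_mod
    from .sim import emit_dataset, primate_like, reference_set_from_truth, rodent_like, simulate_dataset

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"preset": sim_preset, "seed": config.rng_seed}

    preset = primate_like if sim_preset == "primate" else rodent_like
    sim_config = preset(seed=config.rng_seed, scale=scale)
    loci, truth = simulate_dataset(sim_config)
    if "simulate" in stages:
        emit_dataset(loci, truth, outdir / "sim")
    ref_species = "Macaque" if sim_preset == "primate" else "Rat"
    reference = reference_set_from_truth(truth, ref_species)

    statuses: dict[str, dict[str, str]] = {}
    if "annotate" in stages or "status" in stages:
        for sp, locus in loci.items():
            calls = annotate_and_classify(locus, reference, config)
            statuses[sp] = {k: v.status.call for k, v in calls.items()}
        write_status_table(statuses, outdir / "gene_status.tsv")
        summary["status_matrix"] = statuses

    if "blocks" in stages:
        block_counts = {}
        for sp in sorted(loci):
            found = blocks_mod.find_similarity_blocks(loci[sp], config)
            block_counts[sp] = len(found)
        summary["block_counts"] = block_counts

    if "events" in stages and statuses:
        tree = sim_config.tree
        intact = {
            sp: {g: st in ("present", "partial_in_frame") for g, st in row.items()}
            for sp, row in statuses.items()
        }
        gene_ids = sorted({g.split("~")[0] for row in statuses.values() for g in row})
        losses = {}
        for gid in gene_ids:
            matrix = {
                sp: any(v for g, v in row.items() if g.split("~")[0] == gid)
                for sp, row in intact.items()
            }
            if not any(matrix.values()):
                continue
            rec = events_mod.dollo_reconstruct(matrix, tree, gid)
            losses[gid] = rec.loss_count
        summary["loss_counts"] = losses

    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    RunManifest(
        config=config.to_dict(),
        rng_seed=config.rng_seed,
        stages=list(stages),
        input_digests={"sim": _digest(truth.ancestral_seq)},
        outputs={"summary": str(outdir / "summary.json")},
    ).write(outdir / "manifest.json")
    return summary
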