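"""End-to-end per-sample pipeline: filter, validate, characterize, tile,
score binders, and compute the fusion fraction.

Every stage writes a machine-readable TSV and the run summary records the
funnel (kept/dropped counts with reasons) plus the full configuration, so a
run can be audited and reproduced from its output directory alone.
External MHC-I predictors are integrated by files only: the pipeline writes
a peptide FASTA for them and reads their binding table back; when no table
is supplied the deterministic mock predictor is used so fully synthetic runs
still exercise the binder-filtering stage.
"""

from __future__ import annotations

import json
import logging
import os
from typing import Optional

import pandas as pd

from . import epitopes as ep
from . import io as fio
from . import metrics as mt
from .concordance import validate_fusions
from .config import PipelineConfig
from .fusions import classify_fusion, filter_candidates
from .orf import characterize_fusion_protein
from .types import FrameClass, FusionClass, FusionNeoError

__all__ = ["run_pipeline"]

logger = logging.getLogger("fusionneo")


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except FusionNeoError as exc:
                raise FusionNeoError(f"[stage {name}] {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig, inputs: dict, outdir: str) -> dict:
    """Run the fusion-to-neoepitope flow for one sample.

    ``inputs`` keys: ``defuse`` (candidate TSV), ``contigs`` (FASTA),
    ``annotation_prefix``, ``sample_id``, ``mapped_paired_reads``; optional
    ``hla`` (allele table), ``binding`` (external predictor TSV),
    ``control_pairs`` (list of gene-name pairs seen in normal controls),
    ``control_ff`` (control fusion fraction for the high-FF call).
    Returns the run summary (also written to ``run_summary.json``).
    """
    os.makedirs(outdir, exist_ok=True)
    sample_id = inputs.get("sample_id", "sample")
    mapped = int(inputs["mapped_paired_reads"])
    if mapped < config.min_recommended_reads:
        logger.warning(
            "%s: %d mapped paired reads is below the recommended minimum of %d; "
            "assembly may miss prominent fusion transcripts",
            sample_id,
            mapped,
            config.min_recommended_reads,
        )

    candidates = _stage("read_defuse")(fio.read_defuse_table)(inputs["defuse"])
    contigs = _stage("read_contigs")(fio.read_fasta)(inputs["contigs"])
    annotation = _stage("read_annotation")(fio.read_annotation)(inputs["annotation_prefix"])

    # --- filter -----------------------------------------------------------
    control_pairs = [frozenset(p) for p in inputs.get("control_pairs", [])]
    report = _stage("filter")(filter_candidates)(
        candidates,
        probability_threshold=config.probability_threshold,
        control_pairs=control_pairs,
        excluded_families=config.excluded_families,
    )
    pd.DataFrame(
        [{"cluster_id": c.cluster_id, "status": "kept", "reason": ""} for c in report.kept]
        + [
            {"cluster_id": c.cluster_id, "status": "dropped", "reason": r.value}
            for c, r in report.dropped
        ]
    ).to_csv(os.path.join(outdir, "filter_report.tsv"), sep="\t", index=False)

    # --- classify ---------------------------------------------------------
    classes = {
        c.cluster_id: _stage("classify")(classify_fusion)(c, annotation) for c in report.kept
    }
    pd.DataFrame(
        [{"cluster_id": cid, "fusion_class": cls.value} for cid, cls in classes.items()]
    ).to_csv(os.path.join(outdir, "classes.tsv"), sep="\t", index=False)

    # --- validate against contigs ----------------------------------------
    validated, rejected = _stage("validate")(validate_fusions)(
        report.kept,
        contigs,
        concordance_threshold=config.concordance_threshold,
        inclusive=config.concordance_inclusive,
        max_arm=config.max_arm,
        scoring=config.scoring,
    )
    rows = []
    for status, pairs in (("validated", validated), ("rejected", rejected)):
        for cand, res in pairs:
            rows.append(
                {
                    "candidate_id": cand.cluster_id,
                    "status": status,
                    "best_contig_id": res.best_contig_id or "",
                    "concordance_percent": f"{res.concordance_percent:.4f}",
                    "junction_covered": res.junction_covered,
                    "matched_strand": res.matched_strand,
                }
            )
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "validated.tsv"), sep="\t", index=False)

    # --- characterize proteins & tile peptides ----------------------------
    reports = []
    windows = []
    for cand, res in validated:
        rep = _stage("characterize")(characterize_fusion_protein)(
            cand, res, contigs, annotation, k=config.inframe_kmer
        )
        reports.append(rep)
        if rep.frame_class != FrameClass.NO_ORF_AT_JUNCTION:
            windows.append(
                _stage("window")(ep.extract_window)(rep, rep.orf_protein, flank=config.flank_aa)
            )
    pd.DataFrame(
        [
            {
                "candidate_id": r.candidate_id,
                "frame_class": r.frame_class.value,
                "junction_aa_index": "" if r.junction_aa_index is None else r.junction_aa_index,
                "novel_tail": r.novel_tail,
                "novel_start_flag": r.novel_start_flag,
                "novel_end_flag": r.novel_end_flag,
                "transcript_direction": r.transcript_direction,
                "tail_censored": r.tail_censored,
                "orf_protein": r.orf_protein,
                "notes": r.notes,
            }
            for r in reports
        ]
    ).to_csv(os.path.join(outdir, "protein_reports.tsv"), sep="\t", index=False)

    peptides: list[tuple[str, str]] = []
    for window in windows:
        for i, pep in enumerate(
            _stage("tile")(ep.tile_peptides)(window, lengths=config.peptide_lengths)
        ):
            peptides.append((f"{window.candidate_id}_p{i:03d}", pep))
    fio.write_peptide_fasta(peptides, os.path.join(outdir, "peptides.fa"))

    # --- binding: external table or deterministic mock --------------------
    pep_to_candidate = {pid: pid.rsplit("_p", 1)[0] for pid, _ in peptides}
    if inputs.get("binding"):
        binding = _stage("read_binding")(fio.read_binding_table)(inputs["binding"])
    else:
        alleles: list[str] = []
        if inputs.get("hla"):
            per_sample = fio.read_hla_table(inputs["hla"])
            alleles = per_sample.get(sample_id, [])
        if not alleles:
            alleles = ["HLA-A*02:01", "HLA-B*07:02"]
        binding = ep.mock_binding_table(peptides, alleles)
        for rec in binding:
            rec.source_id = pep_to_candidate.get(rec.source_id, rec.source_id)
    strong = _stage("strong_binders")(ep.filter_strong_binders)(binding, threshold=config.strong_rank)
    pd.DataFrame(
        [
            {
                "peptide": e.peptide,
                "allele": e.hla_allele,
                "rank": f"{e.rank_percent:.6f}",
                "candidate_id": e.candidate_id or "",
            }
            for e in strong
        ]
    ).to_csv(os.path.join(outdir, "epitopes.tsv"), sep="\t", index=False)

    # --- fusion fraction --------------------------------------------------
    profile = _stage("fusion_fraction")(mt.fusion_fraction)(
        sample_id, validated, classes, mapped, mode=config.ff_mode
    )
    control_ff: Optional[float] = inputs.get("control_ff")
    if control_ff is not None:
        profile.high_ff = mt.high_ff(
            profile.fusion_fraction, float(control_ff), config.control_multiplier
        )

    summary = {
        "sample_id": sample_id,
        "config": config.to_dict(),
        "counts": {
            "input_candidates": len(candidates),
            "kept_after_filter": len(report.kept),
            "dropped": report.drop_counts,
            "validated": len(validated),
            "rejected": len(rejected),
            "classes": {
                cls.value: sum(1 for v in classes.values() if v == cls) for cls in FusionClass
            },
            "characterized": len(reports),
            "frame_classes": {
                fc.value: sum(1 for r in reports if r.frame_class == fc) for fc in FrameClass
            },
            "peptides": len(peptides),
            "binding_records": len(binding),
            "strong_binders": len(strong),
        },
        "fusion_fraction": profile.fusion_fraction,
        "mapped_paired_reads": mapped,
        "high_ff": profile.high_ff,
        "neoepitope_load": {str(k): v for k, v in ep.neoepitope_load(strong).items()},
    }
    with open(os.path.join(outdir, "run_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary
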