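"""Fusion classification and candidate-level filtering.

Fusion candidates fall into three classes: INTER (partners on different
chromosomes), INTRA (same chromosome, not neighbours), and TIC
(transcription-induced chimera: a read-through transcript of neighbouring
genes, which need not reflect any genomic rearrangement — the partners may
even be transcribed in opposite directions).

Candidate filtering applies three rules before any contig validation:
a caller-probability cut (strictly greater than 0.5 by default), subtraction
of gene pairs also seen in normal-control samples, and exclusion of gene
families whose incomplete annotation produces artifactual calls (the SRGAP2
family and its segmental duplicates by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .types import (
    DropReason,
    FusionCandidate,
    FusionClass,
    FusionNeoError,
    GeneAnnotation,
)

__all__ = [
    "classify_fusion",
    "filter_candidates",
    "FilterReport",
    "DEFAULT_EXCLUDED_FAMILIES",
    "DEFAULT_ADJACENCY_GAP",
]

#: Gene-name prefixes excluded by default (annotation artifacts).
DEFAULT_EXCLUDED_FAMILIES: tuple[str, ...] = ("SRGAP2",)

#: Maximum gap (bp) between gene bodies for the annotation-based
#: "neighbouring genes" fallback when the caller's own flags are absent.
DEFAULT_ADJACENCY_GAP = 1_000_000


@dataclass
class FilterReport:
    """Partition of the input into kept candidates and dropped candidates
    with a single reason each."""

    kept: list[FusionCandidate] = field(default_factory=list)
    dropped: list[tuple[FusionCandidate, DropReason]] = field(default_factory=list)

    @property
    def drop_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {r.value: 0 for r in DropReason}
        for _, reason in self.dropped:
            counts[reason.value] += 1
        return counts


def _genes_by_name_or_id(annotation: Mapping[str, GeneAnnotation], key: str) -> Optional[GeneAnnotation]:
    if key in annotation:
        return annotation[key]
    for g in annotation.values():
        if g.gene_name == key:
            return g
    return None


def _neighbouring(
    g1: GeneAnnotation,
    g2: GeneAnnotation,
    annotation: Mapping[str, GeneAnnotation],
    max_gap: int,
) -> bool:
    """Same chromosome, no annotated gene strictly between the two gene
    bodies, and gap between the bodies at most ``max_gap``.  Strand is
    irrelevant: read-through chimeras of convergent genes exist."""
    if g1.chrom != g2.chrom:
        return False
    left, right = (g1, g2) if g1.start <= g2.start else (g2, g1)
    gap_start, gap_end = left.end, right.start
    if gap_end - gap_start > max_gap:
        return False
    for other in annotation.values():
        if other.gene_id in (g1.gene_id, g2.gene_id) or other.chrom != g1.chrom:
            continue
        if other.start >= gap_start and other.end <= gap_end:
            return False
    return True


def classify_fusion(
    candidate: FusionCandidate,
    annotation: Optional[Mapping[str, GeneAnnotation]] = None,
    max_adjacency_gap: int = DEFAULT_ADJACENCY_GAP,
) -> FusionClass:
    """Classify a candidate as INTER, INTRA, or TIC.

    The fusion caller's own ``read_through``/``adjacent`` flags take
    precedence; when both are absent the annotation-based neighbouring-gene
    fallback is used.  Raises when neither flags nor annotated genes are
    available.
    """
    if candidate.read_through_flag or candidate.adjacent_flag:
        return FusionClass.TIC
    flags_known = (
        candidate.read_through_flag is not None and candidate.adjacent_flag is not None
    )
    if not flags_known:
        if annotation is None:
            raise FusionNeoError(
                f"{candidate.cluster_id}: no caller flags and no annotation; cannot classify"
            )
        g1 = _genes_by_name_or_id(annotation, candidate.gene1_id) or _genes_by_name_or_id(
            annotation, candidate.gene1_name
        )
        g2 = _genes_by_name_or_id(annotation, candidate.gene2_id) or _genes_by_name_or_id(
            annotation, candidate.gene2_name
        )
        if g1 is None or g2 is None:
            raise FusionNeoError(
                f"{candidate.cluster_id}: gene(s) absent from annotation and no caller flags"
            )
        if _neighbouring(g1, g2, annotation, max_adjacency_gap):
            return FusionClass.TIC
    if candidate.chrom1 != candidate.chrom2:
        return FusionClass.INTER
    # Same chromosome with explicit non-adjacent flags, or fallback said
    # not neighbouring.
    if flags_known:
        return FusionClass.INTRA
    return FusionClass.INTRA


def filter_candidates(
    candidates: Sequence[FusionCandidate],
    probability_threshold: float = 0.5,
    control_pairs: Optional[Iterable[frozenset]] = None,
    excluded_families: Sequence[str] = DEFAULT_EXCLUDED_FAMILIES,
) -> FilterReport:
    """Apply the candidate-level filters and report the funnel.

    Keeps candidates with probability strictly greater than
    ``probability_threshold``, whose unordered gene-name pair is not in
    ``control_pairs`` (fusions also seen in normal controls), and whose gene
    names do not start with any excluded family prefix.  A candidate failing
    several rules is reported once, with the first failing reason in the
    order LOW_PROBABILITY, IN_CONTROL, EXCLUDED_FAMILY.
    """
    if not (0.0 <= probability_threshold <= 1.0):
        raise FusionNeoError(f"probability threshold {probability_threshold} outside [0, 1]")
    controls = {frozenset(p) for p in control_pairs} if control_pairs else set()
    prefixes = tuple(excluded_families)
    report = FilterReport()
    for cand in candidates:
        if cand.probability <= probability_threshold:
            report.dropped.append((cand, DropReason.LOW_PROBABILITY))
        elif cand.gene_name_pair in controls:
            report.dropped.append((cand, DropReason.IN_CONTROL))
        elif prefixes and (
            cand.gene1_name.startswith(prefixes) or cand.gene2_name.startswith(prefixes)
        ):
            report.dropped.append((cand, DropReason.EXCLUDED_FAMILY))
        else:
            report.kept.append(cand)
    return report
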