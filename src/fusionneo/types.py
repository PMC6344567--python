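"""Domain types shared across the pipeline.

Conventions
-----------
All coordinates held in memory are 0-based, half-open.  External files keep
their native convention (deFuse breakpoint columns are 1-based; BED is
0-based half-open); the readers and writers in :mod:`fusionneo.io` convert at
the boundary.

The breakpoint marker inside a deFuse junction sequence is the single
character ``|``; the first base after the marker is the first base
contributed by the 3' partner gene.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "FusionCandidate",
    "AssembledTranscript",
    "GeneAnnotation",
    "CoverageTrack",
    "BindingRecord",
    "JunctionWindow",
    "ConcordanceResult",
    "OpenReadingFrame",
    "FrameClass",
    "FusionClass",
    "DropReason",
    "FilterReport",
    "FusionProteinReport",
    "PeptideWindow",
    "EpitopeCandidate",
    "SampleFusionProfile",
    "SurvivalRecord",
    "TicRatioResult",
    "FusionNeoError",
    "FormatError",
    "RecordError",
]

_NUC = set("ACGTN")
_AA = set("ACDEFGHIKLMNPQRSTVWY")


class FusionNeoError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(FusionNeoError):
    """A file-level problem: missing column, malformed structure."""


class RecordError(FusionNeoError):
    """A single record violates an invariant; carries the record id."""

    def __init__(self, record_id: str, message: str):
        self.record_id = record_id
        super().__init__(f"{record_id}: {message}")


class FusionClass(str, enum.Enum):
    """Fusion category.

    INTER: partner genes on different chromosomes.
    INTRA: same chromosome, not neighbouring.
    TIC:   transcription-induced chimera of neighbouring genes (read-through
           transcription rather than necessarily a genomic rearrangement).
    """

    INTER = "INTER"
    INTRA = "INTRA"
    TIC = "TIC"


class FrameClass(str, enum.Enum):
    IN_FRAME = "IN_FRAME"
    OUT_OF_FRAME = "OUT_OF_FRAME"
    NO_ORF_AT_JUNCTION = "NO_ORF_AT_JUNCTION"


class DropReason(str, enum.Enum):
    LOW_PROBABILITY = "LOW_PROBABILITY"
    IN_CONTROL = "IN_CONTROL"
    EXCLUDED_FAMILY = "EXCLUDED_FAMILY"


@dataclass
class FusionCandidate:
    """One deFuse-style fusion candidate.

    ``genomic_break_pos1/2`` are 0-based in memory (converted from the
    1-based file columns).  ``junction_sequence`` contains exactly one ``|``
    breakpoint marker.  ``adjacent_flag``/``read_through_flag`` are the
    fusion caller's own neighbouring-gene calls; ``None`` means the input
    did not provide them and classification must fall back on annotation.
    """

    cluster_id: str
    gene1_id: str
    gene2_id: str
    gene1_name: str
    gene2_name: str
    chrom1: str
    chrom2: str
    strand1: str
    strand2: str
    genomic_break_pos1: int
    genomic_break_pos2: int
    junction_sequence: str
    span_count: int
    split_count: int
    probability: float
    adjacent_flag: Optional[bool] = None
    read_through_flag: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.junction_sequence.count("|") != 1:
            raise RecordError(
                self.cluster_id,
                "junction sequence must contain exactly one '|' breakpoint marker",
            )
        left, right = self.junction_sequence.split("|")
        if not left or not right:
            raise RecordError(self.cluster_id, "both junction arms must be non-empty")
        if not (0.0 <= self.probability <= 1.0):
            raise RecordError(
                self.cluster_id, f"probability {self.probability} outside [0, 1]"
            )
        if self.span_count < 0 or self.split_count < 0:
            raise RecordError(self.cluster_id, "read counts must be non-negative")
        for s in (self.strand1, self.strand2):
            if s not in ("+", "-"):
                raise RecordError(self.cluster_id, f"bad strand {s!r}")

    @property
    def arms(self) -> tuple[str, str]:
        left, right = self.junction_sequence.split("|")
        return left, right

    @property
    def gene_name_pair(self) -> frozenset:
        return frozenset((self.gene1_name, self.gene2_name))


@dataclass
class AssembledTranscript:
    """A de novo assembled contig; orientation is arbitrary (unstranded)."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise RecordError(self.contig_id, "empty contig sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _NUC
        if bad:
            raise RecordError(self.contig_id, f"non-nucleotide characters {sorted(bad)}")


@dataclass
class GeneAnnotation:
    """Minimal gene model: body interval, exons, and optional CDS/protein."""

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_sequence: Optional[str] = None
    protein_sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise RecordError(self.gene_id, "gene start must precede end")
        prev_end = None
        for s, e in self.exons:
            if s >= e or s < self.start or e > self.end:
                raise RecordError(self.gene_id, f"exon ({s}, {e}) outside gene body")
            if prev_end is not None and s < prev_end:
                raise RecordError(self.gene_id, "exons must be sorted and non-overlapping")
            prev_end = e


@dataclass
class CoverageTrack:
    """Per-base read depths over a contiguous 0-based half-open interval."""

    chrom: str
    start: int
    depths: list[int]

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.depths):
            raise RecordError(f"{self.chrom}:{self.start}", "negative depth")

    @property
    def end(self) -> int:
        return self.start + len(self.depths)

    def slice(self, start: int, end: int) -> "CoverageTrack":
        """Sub-track over [start, end); must lie within the track."""
        if start < self.start or end > self.end or start >= end:
            raise FusionNeoError(
                f"slice [{start}, {end}) outside track [{self.start}, {self.end})"
            )
        return CoverageTrack(
            self.chrom, start, self.depths[start - self.start : end - self.start]
        )


@dataclass
class BindingRecord:
    """One peptide x HLA-allele row from an MHC-I binding predictor."""

    peptide: str
    hla_allele: str
    rank_percent: float
    source_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (8 <= len(self.peptide) <= 11):
            raise RecordError(self.peptide, "peptide length must be 8-11")
        if self.rank_percent < 0:
            raise RecordError(self.peptide, "rank percent must be non-negative")


@dataclass
class JunctionWindow:
    """The nucleotide window around a fusion breakpoint used for contig
    comparison.  ``breakpoint_offset`` is the index of the first 3'-arm base
    in the concatenated (marker-free) window."""

    left_arm: str
    right_arm: str

    @property
    def sequence(self) -> str:
        return self.left_arm + self.right_arm

    @property
    def breakpoint_offset(self) -> int:
        return len(self.left_arm)

    def __post_init__(self) -> None:
        if not self.left_arm or not self.right_arm:
            raise FusionNeoError("junction window arms must be non-empty")


@dataclass
class ConcordanceResult:
    """Best contig support for one candidate's junction window.

    ``concordance_percent`` is 100 x (identically aligned window bases) /
    (window length) for the best junction-covering local alignment; 0 when no
    alignment spans the breakpoint.  ``junction_pos_on_contig`` is the contig
    coordinate (in the matched orientation) aligned to the first 3'-arm base,
    and ``max_internal_gap`` the longest internal indel in the chosen
    alignment (used downstream to flag unusual splicing).
    """

    candidate_id: str
    best_contig_id: Optional[str]
    concordance_percent: float
    junction_covered: bool
    matched_strand: str = "+"
    aligned_span_on_window: Optional[tuple[int, int]] = None
    junction_pos_on_contig: Optional[int] = None
    max_internal_gap: int = 0


@dataclass
class OpenReadingFrame:
    """An ORF on a contig.  ``start``/``end`` are on the + strand of the
    contig; for ``strand == '-'`` the reading direction is end -> start on
    the reverse complement.  ``frame`` is start-of-reading mod 3 on the
    reading strand.  ``complete`` is False when no in-frame stop codon exists
    before the contig end (assembly truncation)."""

    contig_id: str
    start: int
    end: int
    strand: str
    frame: int
    protein: str
    complete: bool = True


@dataclass
class FusionProteinReport:
    """Characterization of the protein consequence of a validated fusion."""

    candidate_id: str
    frame_class: FrameClass
    junction_aa_index: Optional[int]
    novel_tail: str
    novel_start_flag: bool
    novel_end_flag: bool
    transcript_direction: str
    orf_protein: str = ""
    tail_censored: bool = False
    notes: str = ""


@dataclass
class PeptideWindow:
    """Amino-acid window handed to peptide tiling.

    ``junction_index`` is the 0-based index of the first residue encoded
    downstream of the fusion point (equals the number of upstream residues
    actually available)."""

    candidate_id: str
    sequence: str
    junction_index: int
    frame_class: FrameClass


@dataclass
class EpitopeCandidate:
    peptide: str
    candidate_id: Optional[str]
    hla_allele: str
    rank_percent: float
    strong: bool


@dataclass
class SampleFusionProfile:
    """Per-sample fusion burden.  ``fusion_fraction`` is validated INTER +
    INTRA span counts per 10 million mapped paired reads (TICs excluded)."""

    sample_id: str
    validated_fusions: list
    mapped_paired_reads: int
    fusion_fraction: float
    high_ff: Optional[bool] = None


@dataclass
class SurvivalRecord:
    sample_id: str
    time: float
    event: bool
    group: str

    def __post_init__(self) -> None:
        if self.time < 0:
            raise RecordError(self.sample_id, "survival time must be non-negative")


@dataclass
class TicRatioResult:
    """Read-through chimera abundance relative to total transcription.

    ``ratio`` = mean depth over the first 10 nt of the retained intron /
    mean depth over the last 10 nt of the shared exon."""

    exon_mean_depth: float
    intron_mean_depth: float
    ratio: float
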