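"""ORF finding, translation, and fusion-protein characterization.

Given a validated fusion and the contig supporting it, this module answers
the protein-level questions: does an open reading frame run across the
breakpoint, does the downstream partner stay in its native frame, and if
not, what novel peptide tail is translated before the first premature stop?
Out-of-frame tails are the neoantigen payload, so the junction-containing
ORF is never length-filtered.

Frame classification works on assembled contigs with unknown splice
structure, so instead of annotation-phase arithmetic it uses peptide k-mer
membership: the fusion is in-frame when the first ``k`` (default 8) amino
acids translated past the junction occur verbatim in the downstream
partner's reference protein.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

from Bio.Seq import Seq

from .concordance import reverse_complement
from .types import (
    AssembledTranscript,
    ConcordanceResult,
    FrameClass,
    FusionCandidate,
    FusionNeoError,
    FusionProteinReport,
    GeneAnnotation,
    OpenReadingFrame,
)

__all__ = ["translate", "find_orfs", "characterize_fusion_protein"]

_STOPS = {"TAA", "TAG", "TGA"}

#: Internal alignment gaps at least this long are flagged as unusual
#: splicing (e.g. intron retention on one side of the junction).
UNUSUAL_GAP_NT = 20


def translate(sequence: str, frame: int = 0, to_stop: bool = False) -> str:
    """Standard-genetic-code translation of ``sequence`` from ``frame``.

    Trailing partial codons are dropped.  Codons containing ``N`` translate
    to ``X`` (never to a stop).  With ``to_stop`` the result is truncated
    before the first stop; otherwise stops appear as ``*``.
    """
    if frame not in (0, 1, 2):
        raise FusionNeoError(f"frame must be 0, 1 or 2, not {frame}")
    sub = sequence.upper()[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        return ""
    protein = list(str(Seq(sub).translate()))
    for idx in range(len(protein)):
        if "N" in sub[3 * idx : 3 * idx + 3]:
            protein[idx] = "X"
    out = "".join(protein)
    if to_stop:
        out = out.split("*", 1)[0]
    return out


def find_orfs(transcript: AssembledTranscript, min_aa: int = 30) -> list[OpenReadingFrame]:
    """Enumerate ORFs on both strands and all three frames.

    Every ATG is paired with the first in-frame stop codon downstream; ATGs
    with no downstream stop yield incomplete ORFs running to the last full
    codon (``complete=False``).  Only ORFs whose protein is at least
    ``min_aa`` long are returned, sorted by protein length (descending) and
    then by coordinate.  Coordinates are on the contig's + strand.
    """
    seq = transcript.sequence
    length = len(seq)
    orfs: list[OpenReadingFrame] = []
    if length < 3:
        return orfs
    for strand in "+-":
        s = seq if strand == "+" else reverse_complement(seq)
        for frame in range(3):
            open_starts: list[int] = []
            last_full = frame + 3 * ((length - frame) // 3)
            for pos in range(frame, last_full, 3):
                codon = s[pos : pos + 3]
                if codon == "ATG":
                    open_starts.append(pos)
                elif codon in _STOPS:
                    for start in open_starts:
                        orfs.append(_make_orf(transcript.contig_id, s, start, pos + 3, strand, length, True))
                    open_starts = []
            for start in open_starts:  # ran off the contig end: censored
                if last_full > start:
                    orfs.append(_make_orf(transcript.contig_id, s, start, last_full, strand, length, False))
    orfs = [o for o in orfs if len(o.protein) >= min_aa]
    orfs.sort(key=lambda o: (-len(o.protein), o.start, o.end, o.strand))
    return orfs


def _make_orf(
    contig_id: str, reading_seq: str, start: int, end: int, strand: str, length: int, complete: bool
) -> OpenReadingFrame:
    coding = reading_seq[start : end - 3] if complete else reading_seq[start:end]
    protein = translate(coding)
    if strand == "+":
        plus_start, plus_end = start, end
    else:
        plus_start, plus_end = length - end, length - start
    return OpenReadingFrame(
        contig_id=contig_id,
        start=plus_start,
        end=plus_end,
        strand=strand,
        frame=start % 3,
        protein=protein,
        complete=complete,
    )


def _junction_aa_index(orf: OpenReadingFrame, pos: int) -> int:
    """Index (in the ORF's protein) of the amino acid whose codon contains
    the + strand contig position ``pos``."""
    if orf.strand == "+":
        return (pos - orf.start) // 3
    return (orf.end - 1 - pos) // 3


def characterize_fusion_protein(
    candidate: FusionCandidate,
    concordance_result: ConcordanceResult,
    contigs: Sequence[AssembledTranscript],
    annotation: Mapping[str, GeneAnnotation],
    k: int = 8,
) -> FusionProteinReport:
    """Characterize the protein consequence of a validated fusion.

    The breakpoint is located on the best supporting contig (in the matched
    orientation), the longest ORF containing it is selected, and the
    translation downstream of the junction decides the frame class: IN_FRAME
    when the first ``k`` downstream residues occur contiguously in the 3'
    partner's reference protein, OUT_OF_FRAME otherwise, with the novel tail
    running from the junction to the ORF's stop (censored when the ORF runs
    off the contig).  NO_ORF_AT_JUNCTION when no ORF contains the
    breakpoint.
    """
    if not concordance_result.junction_covered or concordance_result.best_contig_id is None:
        raise FusionNeoError(
            f"{candidate.cluster_id}: candidate has no junction-covering contig; validate first"
        )
    by_id = {c.contig_id: c for c in contigs}
    if concordance_result.best_contig_id not in by_id:
        raise FusionNeoError(f"contig {concordance_result.best_contig_id} not supplied")
    contig = by_id[concordance_result.best_contig_id]
    oriented = (
        contig.sequence
        if concordance_result.matched_strand == "+"
        else reverse_complement(contig.sequence)
    )
    jpos = concordance_result.junction_pos_on_contig
    if jpos is None:
        raise FusionNeoError(f"{candidate.cluster_id}: junction position not mapped on contig")

    gene2 = _lookup_gene(annotation, candidate.gene2_id, candidate.gene2_name)
    if gene2 is None or not gene2.protein_sequence:
        raise FusionNeoError(
            f"{candidate.cluster_id}: reference protein for 3' partner "
            f"{candidate.gene2_name} unavailable"
        )
    gene1 = _lookup_gene(annotation, candidate.gene1_id, candidate.gene1_name)

    notes = []
    if concordance_result.max_internal_gap >= UNUSUAL_GAP_NT:
        notes.append(
            f"unusual_splicing:internal_gap={concordance_result.max_internal_gap}nt"
        )

    oriented_transcript = AssembledTranscript(contig.contig_id, oriented)
    junction_orfs = [
        o for o in find_orfs(oriented_transcript, min_aa=1) if o.start <= jpos < o.end
    ]
    if not junction_orfs:
        return FusionProteinReport(
            candidate_id=candidate.cluster_id,
            frame_class=FrameClass.NO_ORF_AT_JUNCTION,
            junction_aa_index=None,
            novel_tail="",
            novel_start_flag=False,
            novel_end_flag=False,
            transcript_direction="+",
            notes=";".join(notes),
        )
    orf = junction_orfs[0]  # longest protein; find_orfs sorts
    jidx = _junction_aa_index(orf, jpos)
    downstream = orf.protein[jidx:]
    if not downstream:
        # breakpoint falls inside the stop codon itself
        return FusionProteinReport(
            candidate_id=candidate.cluster_id,
            frame_class=FrameClass.NO_ORF_AT_JUNCTION,
            junction_aa_index=None,
            novel_tail="",
            novel_start_flag=False,
            novel_end_flag=False,
            transcript_direction=orf.strand,
            notes=";".join(notes + ["junction_in_stop_codon"]),
        )

    probe = downstream[:k]
    in_frame = probe in gene2.protein_sequence
    novel_start = bool(
        gene1 is not None
        and gene1.protein_sequence
        and orf.protein[:k] not in gene1.protein_sequence
    )
    return FusionProteinReport(
        candidate_id=candidate.cluster_id,
        frame_class=FrameClass.IN_FRAME if in_frame else FrameClass.OUT_OF_FRAME,
        junction_aa_index=jidx,
        novel_tail="" if in_frame else downstream,
        novel_start_flag=novel_start,
        novel_end_flag=not in_frame,
        transcript_direction=orf.strand,
        orf_protein=orf.protein,
        tail_censored=(not in_frame) and not orf.complete,
        notes=";".join(notes),
    )


def _lookup_gene(
    annotation: Mapping[str, GeneAnnotation], gene_id: str, gene_name: str
) -> Optional[GeneAnnotation]:
    if gene_id in annotation:
        return annotation[gene_id]
    for g in annotation.values():
        if g.gene_name == gene_name:
            return g
    return None
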