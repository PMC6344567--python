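"""Junction-concordance scoring: fusion-caller windows versus de novo contigs.

A fusion call is considered assembly-supported when the nucleotide window
around its breakpoint (up to 250 nt per arm, so 200-500 nt in total for
typical caller output) aligns to a de novo assembled contig with the
alignment spanning the breakpoint itself, at a concordance of at least 25%
by default.  Concordance is the percentage of window bases identically
aligned in the best junction-covering local alignment; requiring the
alignment to cross the junction is what separates genuine chimeric contigs
from contigs that merely assemble one partner gene.

Assembled contigs are unstranded, so every contig is tested in both
orientations.  Ties between equally concordant contigs break
deterministically: lexicographically smaller contig id first, then the
forward orientation.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .align import LocalAlignment, Scoring, align_local
from .types import (
    AssembledTranscript,
    ConcordanceResult,
    FusionCandidate,
    FusionNeoError,
    JunctionWindow,
)

__all__ = [
    "make_junction_window",
    "compute_concordance",
    "validate_fusions",
    "reverse_complement",
]

_RC = str.maketrans("ACGTN", "TGCAN")

#: Shortest window that can be scored meaningfully.
MIN_WINDOW = 16


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def make_junction_window(candidate: FusionCandidate, max_arm: int = 250) -> JunctionWindow:
    """Build the breakpoint window from a candidate's junction sequence.

    Each arm is truncated to its innermost ``max_arm`` bases (those nearest
    the breakpoint), and the ``|`` marker is dropped; the breakpoint offset
    is the length of the retained left arm.
    """
    left, right = candidate.arms
    if not left or not right:
        raise FusionNeoError(f"{candidate.cluster_id}: empty junction arm")
    return JunctionWindow(left_arm=left[-max_arm:], right_arm=right[:max_arm])


def _covers_junction(aln: LocalAlignment, breakpoint_offset: int) -> bool:
    # The aligned window span must contain both breakpoint-flanking
    # positions (offset-1 and offset).
    return aln.q_start <= breakpoint_offset - 1 and aln.q_end >= breakpoint_offset + 1


def compute_concordance(
    window: JunctionWindow,
    contigs: Sequence[AssembledTranscript],
    scoring: Scoring = Scoring(),
    candidate_id: str = "",
) -> ConcordanceResult:
    """Score the window against every contig in both orientations and report
    the best junction-covering match.

    For each contig/orientation the single best local alignment is computed;
    orientations whose best alignment does not span the breakpoint
    contribute nothing.  When no junction-covering alignment exists at all,
    concordance is 0 and no contig is reported.
    """
    if not contigs:
        raise FusionNeoError("contig list is empty")
    wseq = window.sequence
    if len(wseq) < MIN_WINDOW:
        raise FusionNeoError(
            f"window of {len(wseq)} nt is below the scoreable minimum ({MIN_WINDOW})"
        )
    bo = window.breakpoint_offset
    best: Optional[tuple[float, str, str, LocalAlignment]] = None
    for contig in sorted(contigs, key=lambda c: c.contig_id):
        for strand in "+-":
            target = contig.sequence if strand == "+" else reverse_complement(contig.sequence)
            aln = align_local(wseq, target, scoring)
            if aln is None or not _covers_junction(aln, bo):
                continue
            pct = 100.0 * aln.identity / len(wseq)
            # Rank by concordance, then alignment score (a gap-free match
            # outranks a gapped one of equal identity), then id/orientation.
            if best is None or (pct, aln.score) > (best[0], best[3].score):
                best = (pct, contig.contig_id, strand, aln)
    if best is None:
        return ConcordanceResult(
            candidate_id=candidate_id,
            best_contig_id=None,
            concordance_percent=0.0,
            junction_covered=False,
        )
    pct, contig_id, strand, aln = best
    return ConcordanceResult(
        candidate_id=candidate_id,
        best_contig_id=contig_id,
        concordance_percent=pct,
        junction_covered=True,
        matched_strand=strand,
        aligned_span_on_window=(aln.q_start, aln.q_end),
        junction_pos_on_contig=aln.target_pos_at_or_after(bo),
        max_internal_gap=aln.max_internal_gap,
    )


def validate_fusions(
    candidates: Sequence[FusionCandidate],
    contigs: Sequence[AssembledTranscript],
    concordance_threshold: float = 25.0,
    inclusive: bool = True,
    max_arm: int = 250,
    scoring: Scoring = Scoring(),
) -> tuple[
    list[tuple[FusionCandidate, ConcordanceResult]],
    list[tuple[FusionCandidate, ConcordanceResult]],
]:
    """Split candidates into assembly-validated and rejected.

    A candidate validates when its best junction-covering concordance meets
    the threshold (inclusive comparison by default).  One contig may
    validate several candidates; multi-fusion contigs are legitimate.
    """
    validated, rejected = [], []
    for cand in candidates:
        window = make_junction_window(cand, max_arm=max_arm)
        result = compute_concordance(window, contigs, scoring, candidate_id=cand.cluster_id)
        passed = result.junction_covered and (
            result.concordance_percent >= concordance_threshold
            if inclusive
            else result.concordance_percent > concordance_threshold
        )
        (validated if passed else rejected).append((cand, result))
    return validated, rejected
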