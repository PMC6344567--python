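"""Junction windows, the local aligner, and concordance scoring."""

from __future__ import annotations

import numpy as np
import pytest
from Bio import Align

from fusionneo import align_local, compute_concordance, make_junction_window, validate_fusions
from fusionneo.concordance import reverse_complement
from fusionneo.types import AssembledTranscript, FusionNeoError, JunctionWindow

from oracles import oracle_concordance, oracle_local_align
from test_fusions import make_candidate

RNG = np.random.default_rng(20240901)


def random_seq(n: int) -> str:
    return "".join("ACGT"[i] for i in RNG.integers(0, 4, size=n))


# ---------------------------------------------------------------------------
# window construction


def test_window_truncates_arms_to_innermost_bases():
    cand = make_candidate(junction_sequence=random_seq(300) + "|" + random_seq(300))
    window = make_junction_window(cand)
    assert len(window.left_arm) == 250 and len(window.right_arm) == 250
    left, right = cand.arms
    assert window.left_arm == left[-250:] and window.right_arm == right[:250]


def test_window_below_cap_unchanged():
    cand = make_candidate(junction_sequence=random_seq(80) + "|" + random_seq(90))
    window = make_junction_window(cand)
    assert len(window.sequence) == 170 and window.breakpoint_offset == 80


def test_window_asymmetric_truncation():
    cand = make_candidate(junction_sequence=random_seq(600) + "|" + random_seq(100))
    window = make_junction_window(cand)
    assert len(window.left_arm) == 250 and len(window.right_arm) == 100


# ---------------------------------------------------------------------------
# aligner


def test_biopython_agrees_on_score():
    """Independent cross-check: the optimal local score matches
    Bio.Align.PairwiseAligner under the same scoring scheme."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -1
    for _ in range(40):
        q, t = random_seq(int(RNG.integers(20, 80))), random_seq(int(RNG.integers(40, 160)))
        ours = align_local(q, t)
        ref = aligner.score(q, t)
        assert (ours.score if ours else 0) == max(ref, 0)


def test_exact_substring_alignment_is_perfect():
    q = random_seq(60)
    t = random_seq(25) + q + random_seq(25)
    aln = align_local(q, t)
    assert aln.identity == 60 and aln.score == 60
    assert (aln.q_start, aln.q_end) == (0, 60)
    assert (aln.t_start, aln.t_end) == (25, 85)


def test_no_match_returns_none():
    assert align_local("AAAA", "CCCC") is None


# ---------------------------------------------------------------------------
# concordance


def _planted_contig(window_seq: str, mutations: int) -> str:
    seq = list(random_seq(40) + window_seq + random_seq(40))
    if mutations:
        positions = RNG.choice(np.arange(40, 40 + len(window_seq)), size=mutations, replace=False)
        for p in positions:
            seq[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[p]]
    return "".join(seq)


def test_verbatim_window_scores_100():
    window = JunctionWindow(random_seq(120), random_seq(120))
    contig = AssembledTranscript("c1", _planted_contig(window.sequence, 0))
    result = compute_concordance(window, [contig])
    assert result.concordance_percent == 100.0
    assert result.junction_covered and result.best_contig_id == "c1"
    assert result.junction_pos_on_contig == 40 + window.breakpoint_offset


def test_left_arm_only_contig_cannot_cover_junction():
    window = JunctionWindow(random_seq(100), random_seq(100))
    contig = AssembledTranscript("c1", window.left_arm)
    result = compute_concordance(window, [contig])
    assert result.concordance_percent == 0.0
    assert not result.junction_covered and result.best_contig_id is None


def test_strand_symmetry():
    """A contig and its reverse complement give the same concordance with
    the orientation flag flipped."""
    window = JunctionWindow(random_seq(80), random_seq(80))
    fwd = AssembledTranscript("c1", _planted_contig(window.sequence, 12))
    rev = AssembledTranscript("c1", reverse_complement(fwd.sequence))
    r_fwd = compute_concordance(window, [fwd])
    r_rev = compute_concordance(window, [rev])
    assert r_fwd.concordance_percent == r_rev.concordance_percent
    assert {r_fwd.matched_strand, r_rev.matched_strand} == {"+", "-"}


def test_mutation_monotonicity():
    """More mismatches in the supporting contig never increase concordance."""
    window = JunctionWindow(random_seq(100), random_seq(100))
    base = _planted_contig(window.sequence, 0)
    previous = 101.0
    for mutations in (0, 5, 15, 30, 60):
        contig = AssembledTranscript("c1", _planted_contig(window.sequence, mutations))
        pct = compute_concordance(window, [contig]).concordance_percent
        assert pct <= previous
        previous = pct
    assert compute_concordance(window, [AssembledTranscript("c1", base)]).concordance_percent == 100.0


def test_short_window_rejected():
    with pytest.raises(FusionNeoError):
        compute_concordance(JunctionWindow("ACGTACG", "ACGTACG"), [AssembledTranscript("c", "ACGT")])


def test_oracle_equivalence_planted_block():
    """A contig sharing a 150-nt identical block centred on the junction,
    rest random, scores exactly as the brute-force DP oracle says."""
    for _ in range(5):
        window = JunctionWindow(random_seq(60), random_seq(60))
        block = window.left_arm[-75:] + window.right_arm[:75]
        contig = AssembledTranscript("c1", random_seq(80) + block + random_seq(80))
        result = compute_concordance(window, [contig])
        pct, cid, strand = oracle_concordance(
            window.sequence, window.breakpoint_offset, [("c1", contig.sequence)]
        )
        assert result.concordance_percent == pct
        assert result.best_contig_id == cid and result.matched_strand == strand


def test_threshold_semantics_and_multi_fusion_contig():
    cand_a = make_candidate(cluster_id="A", junction_sequence=random_seq(90) + "|" + random_seq(90))
    cand_b = make_candidate(cluster_id="B", junction_sequence=random_seq(90) + "|" + random_seq(90))
    wa = make_junction_window(cand_a).sequence
    wb = make_junction_window(cand_b).sequence
    shared = AssembledTranscript("shared", wa + random_seq(30) + wb)
    validated, rejected = validate_fusions([cand_a, cand_b], [shared])
    # one contig carrying two junctions validates both candidates
    assert {c.cluster_id for c, _ in validated} == {"A", "B"}
    assert all(r.best_contig_id == "shared" for _, r in validated)
    assert rejected == []


def test_concordance_at_exactly_25_percent_is_kept():
    cand = make_candidate(junction_sequence=random_seq(50) + "|" + random_seq(50))
    window = make_junction_window(cand)
    # contig is exactly the central 25 window bases: identity 25/100
    contig = AssembledTranscript("c1", window.sequence[38:63])
    result = compute_concordance(window, [contig])
    assert result.concordance_percent == 25.0 and result.junction_covered
    validated, _ = validate_fusions([cand], [contig])
    assert len(validated) == 1
    validated, _ = validate_fusions([cand], [contig], inclusive=False)
    assert len(validated) == 0
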