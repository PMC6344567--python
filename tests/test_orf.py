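"""Translation, ORF enumeration, and fusion-protein characterization."""

from __future__ import annotations

import numpy as np
import pytest

from fusionneo import (
    characterize_fusion_protein,
    compute_concordance,
    find_orfs,
    make_junction_window,
    translate,
    validate_fusions,
)
from fusionneo.types import AssembledTranscript, FrameClass, FusionNeoError

from oracles import oracle_orfs, oracle_translate
from test_fusions import make_candidate

RNG = np.random.default_rng(77)


def random_seq(n: int) -> str:
    return "".join("ACGT"[i] for i in RNG.integers(0, 4, size=n))


# ---------------------------------------------------------------------------
# translate


def test_translate_basic():
    assert translate("ATGAAATAA", to_stop=True) == "MK"
    assert translate("ATGAAATAA") == "MK*"


def test_translate_frame_offset():
    seq = "NATGAAATAA"
    assert translate(seq, frame=1) == translate(seq[1:], frame=0)


def test_translate_n_codons_become_x():
    assert translate("ATGANATAA") == "MX*"
    # an N codon is never read as a stop
    assert translate("TANAAA", to_stop=True) == "XK"


@pytest.mark.parametrize("trial", range(5))
def test_translate_matches_codon_table_oracle(trial):
    seq = random_seq(300)
    for frame in (0, 1, 2):
        assert translate(seq, frame=frame) == oracle_translate(seq, frame=frame)
        assert translate(seq, frame=frame, to_stop=True) == oracle_translate(
            seq, frame=frame, to_stop=True
        )


# ---------------------------------------------------------------------------
# find_orfs


def test_single_orf():
    orfs = find_orfs(AssembledTranscript("c", "ATGAAATAA"), min_aa=1)
    plus = [o for o in orfs if o.strand == "+"]
    assert len(plus) == 1
    assert plus[0].protein == "MK" and plus[0].complete
    assert (plus[0].start, plus[0].end) == (0, 9)


def test_no_atg_no_orfs():
    # TTA/TTG/CTT... sequence without ATG on either strand
    assert find_orfs(AssembledTranscript("c", "CCCCCCCCCCCC"), min_aa=1) == []


def test_incomplete_orf_flagged():
    orfs = find_orfs(AssembledTranscript("c", "ATGAAAGGGCCC"), min_aa=1)
    plus = [o for o in orfs if o.strand == "+" and o.start == 0]
    assert plus and not plus[0].complete
    assert plus[0].protein == "MKGP"


@pytest.mark.parametrize("trial", range(6))
def test_find_orfs_matches_exhaustive_enumeration(trial):
    seq = random_seq(600)
    got = {
        (o.strand, o.start, o.end, o.protein, o.complete)
        for o in find_orfs(AssembledTranscript("c", seq), min_aa=5)
    }
    assert got == oracle_orfs(seq, min_aa=5)


def test_reported_orfs_retranslate_exactly():
    """Every ORF's protein is reproducible from its contig coordinates."""
    from fusionneo.concordance import reverse_complement

    seq = random_seq(600)
    for o in find_orfs(AssembledTranscript("c", seq), min_aa=5):
        sub = seq[o.start : o.end]
        reading = sub if o.strand == "+" else reverse_complement(sub)
        expected = translate(reading, to_stop=True) if o.complete else translate(reading)
        assert o.protein == expected


# ---------------------------------------------------------------------------
# characterization


def _validated(cand, contigs):
    window = make_junction_window(cand)
    return compute_concordance(window, contigs, candidate_id=cand.cluster_id)


def test_codon_boundary_join_is_in_frame(planted):
    annotation, candidates, contigs, manifest = planted
    truth = {f.candidate_id: f for f in manifest.fusions}
    in_frame = [
        c
        for c in candidates
        if truth[c.cluster_id].frame_class == "IN_FRAME"
        and truth[c.cluster_id].expected_validated
    ]
    assert in_frame
    for cand in in_frame:
        result = _validated(cand, contigs)
        report = characterize_fusion_protein(cand, result, contigs, annotation)
        assert report.frame_class == FrameClass.IN_FRAME
        assert report.novel_tail == "" and not report.novel_end_flag


def test_one_base_shift_gives_out_of_frame_with_oracle_tail(planted):
    """Deleting one base at the junction shifts the downstream partner; the
    novel tail equals brute-force translation of the shifted sequence up to
    the first stop."""
    annotation, candidates, contigs, manifest = planted
    truth = {f.candidate_id: f for f in manifest.fusions}
    oof = [
        c
        for c in candidates
        if truth[c.cluster_id].frame_class == "OUT_OF_FRAME"
        and truth[c.cluster_id].expected_validated
    ]
    assert oof
    for cand in oof:
        result = _validated(cand, contigs)
        report = characterize_fusion_protein(cand, result, contigs, annotation)
        assert report.frame_class == FrameClass.OUT_OF_FRAME
        assert report.novel_tail == truth[cand.cluster_id].novel_tail
        # tail is maximal, stop-free, and equals brute-force translation of
        # the contig downstream of the junction (junction is codon-aligned)
        assert "*" not in report.novel_tail
        oriented = _oriented_contig(result, contigs)
        oracle_tail = oracle_translate(
            oriented[result.junction_pos_on_contig :], frame=0, to_stop=True
        )
        assert report.novel_tail == oracle_tail


def _oriented_contig(result, contigs):
    from fusionneo.concordance import reverse_complement

    contig = next(c for c in contigs if c.contig_id == result.best_contig_id)
    return contig.sequence if result.matched_strand == "+" else reverse_complement(contig.sequence)


def test_planted_27aa_divergent_tail(toy_world):
    """A read-through fixture planted with a 27-residue divergent tail is
    recovered with exactly that tail length."""
    from fusionneo import PlanEntry, plant_fusions
    from fusionneo.types import FusionClass

    _, annotation = toy_world
    plan = [PlanEntry(FusionClass.TIC, FrameClass.OUT_OF_FRAME, "high", 6, tail_length=27)]
    candidates, contigs, manifest = plant_fusions(annotation, plan, seed=5)
    assert len(manifest.fusions[0].novel_tail) == 27
    cand = candidates[0]
    result = _validated(cand, contigs)
    report = characterize_fusion_protein(cand, result, contigs, annotation)
    assert report.frame_class == FrameClass.OUT_OF_FRAME
    assert len(report.novel_tail) == 27
    assert report.novel_tail == manifest.fusions[0].novel_tail


def test_missing_reference_protein_errors(planted):
    annotation, candidates, contigs, manifest = planted
    truth = {f.candidate_id: f for f in manifest.fusions}
    cand = next(c for c in candidates if truth[c.cluster_id].expected_validated)
    result = _validated(cand, contigs)
    pruned = {k: v for k, v in annotation.items() if k != cand.gene2_id}
    with pytest.raises(FusionNeoError, match="reference protein"):
        characterize_fusion_protein(cand, result, contigs, pruned)


def test_frame_recovery_on_many_random_fusions(toy_world):
    """Frame classification recovers 100% of planted frames across a larger
    randomized fixture panel (both classes, random contig orientations)."""
    from fusionneo import PlanEntry, plant_fusions
    from fusionneo.types import FusionClass

    _, annotation = toy_world
    hits = total = 0
    for seed in range(200, 210):
        plan = [
            PlanEntry(FusionClass.INTER, FrameClass.IN_FRAME, "high", 5),
            PlanEntry(FusionClass.INTER, FrameClass.OUT_OF_FRAME, "high", 5),
            PlanEntry(FusionClass.INTRA, FrameClass.IN_FRAME, "mid", 5),
            PlanEntry(FusionClass.TIC, FrameClass.OUT_OF_FRAME, "mid", 5),
            PlanEntry(FusionClass.INTER, FrameClass.OUT_OF_FRAME, "high", 5),
        ]
        candidates, contigs, manifest = plant_fusions(annotation, plan, seed)
        truth = {f.candidate_id: f for f in manifest.fusions}
        validated, _ = validate_fusions(candidates, contigs)
        for cand, result in validated:
            report = characterize_fusion_protein(cand, result, contigs, annotation)
            total += 1
            hits += report.frame_class.value == truth[cand.cluster_id].frame_class
    assert total >= 50 and hits == total
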