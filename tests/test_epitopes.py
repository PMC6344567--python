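"""Peptide windows, 8-11-mer tiling, mock ranks, strong-binder filtering."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from fusionneo import extract_window, filter_strong_binders, mock_rank_predictor, tile_peptides
from fusionneo.epitopes import mock_binding_table, neoepitope_load
from fusionneo.types import BindingRecord, FrameClass, FusionNeoError, FusionProteinReport, PeptideWindow

from oracles import oracle_tiles

RNG = np.random.default_rng(11)
AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(n: int) -> str:
    return "".join(AA[i] for i in RNG.integers(0, 20, size=n))


def make_report(frame_class, jidx, tail="", protein=None):
    return FusionProteinReport(
        candidate_id="F000",
        frame_class=frame_class,
        junction_aa_index=jidx,
        novel_tail=tail,
        novel_start_flag=False,
        novel_end_flag=frame_class == FrameClass.OUT_OF_FRAME,
        transcript_direction="+",
        orf_protein=protein or random_protein(60),
    )


# ---------------------------------------------------------------------------
# extract_window


def test_in_frame_window_is_11_plus_11():
    report = make_report(FrameClass.IN_FRAME, 30)
    window = extract_window(report, report.orf_protein)
    assert len(window.sequence) == 22 and window.junction_index == 11
    assert window.sequence == report.orf_protein[19:41]


def test_out_of_frame_window_is_11_plus_tail():
    tail = random_protein(30)
    report = make_report(FrameClass.OUT_OF_FRAME, 30, tail=tail)
    window = extract_window(report, report.orf_protein)
    assert len(window.sequence) == 41 and window.junction_index == 11
    assert window.sequence.endswith(tail)


def test_short_upstream_context_truncates():
    report = make_report(FrameClass.IN_FRAME, 5)
    window = extract_window(report, report.orf_protein)
    assert window.junction_index == 5 and len(window.sequence) == 16


def test_no_orf_report_rejected():
    report = make_report(FrameClass.NO_ORF_AT_JUNCTION, None)
    with pytest.raises(FusionNeoError):
        extract_window(report, "")


# ---------------------------------------------------------------------------
# tile_peptides


def test_in_frame_22mer_yields_34_junction_spanning_peptides():
    """Closed form: k-1 junction-spanning k-mers per length, 7+8+9+10 = 34."""
    window = PeptideWindow("F0", random_protein(22), 11, FrameClass.IN_FRAME)
    peptides = tile_peptides(window)
    assert len(peptides) == 34
    for k in (8, 9, 10, 11):
        assert sum(1 for p in peptides if len(p) == k) == k - 1
    assert peptides == oracle_tiles(window.sequence, 11, spanning=True)


def test_window_below_minimum_length_is_empty():
    window = PeptideWindow("F0", random_protein(7), 3, FrameClass.IN_FRAME)
    assert tile_peptides(window) == []


def test_out_of_frame_13mer_with_2_novel_residues():
    window = PeptideWindow("F0", random_protein(13), 11, FrameClass.OUT_OF_FRAME)
    peptides = tile_peptides(window)
    assert len(peptides) == 8
    assert peptides == oracle_tiles(window.sequence, 11, spanning=False)


@pytest.mark.parametrize("frame", [FrameClass.IN_FRAME, FrameClass.OUT_OF_FRAME])
@pytest.mark.parametrize("trial", range(4))
def test_tiling_matches_exhaustive_oracle(frame, trial):
    length = int(RNG.integers(8, 45))
    jidx = int(RNG.integers(0, length))
    window = PeptideWindow("F0", random_protein(length), jidx, frame)
    expected = oracle_tiles(window.sequence, jidx, spanning=frame == FrameClass.IN_FRAME)
    assert tile_peptides(window) == expected


def test_every_peptide_is_substring_overlapping_novel_content():
    window = PeptideWindow("F0", random_protein(30), 11, FrameClass.IN_FRAME)
    for pep in tile_peptides(window):
        start = window.sequence.find(pep)
        assert start >= 0
        assert start < 11 < start + len(pep)  # spans the junction


def test_naive_tiling_flag_restores_non_spanning_peptides():
    window = PeptideWindow("F0", random_protein(22), 11, FrameClass.IN_FRAME)
    naive = tile_peptides(window, require_spanning=False)
    spanning = tile_peptides(window)
    assert set(spanning) < set(naive)


# ---------------------------------------------------------------------------
# mock predictor


def test_mock_rank_is_deterministic_and_allele_sensitive():
    assert mock_rank_predictor("ACDEFGHI", "HLA-A*02:01") == mock_rank_predictor(
        "ACDEFGHI", "HLA-A*02:01"
    )
    ranks = {mock_rank_predictor("ACDEFGHI", a) for a in ("HLA-A*02:01", "HLA-B*07:02", "HLA-C*04:01")}
    assert len(ranks) == 3


def test_mock_rank_distribution_is_uniform():
    peptides = {random_protein(9) for _ in range(12000)}
    ranks = [mock_rank_predictor(p, "HLA-A*02:01") for p in sorted(peptides)][:10000]
    assert all(0 <= r < 100 for r in ranks)
    _, p_value = stats.kstest(np.array(ranks) / 100.0, "uniform")
    assert p_value > 0.01


# ---------------------------------------------------------------------------
# strong binders


def test_strong_binder_boundary_is_strict():
    records = [
        BindingRecord("ACDEFGHI", "HLA-A*02:01", 0.4, source_id="F0"),
        BindingRecord("ACDEFGHIK", "HLA-A*02:01", 0.5, source_id="F0"),
        BindingRecord("ACDEFGHIKL", "HLA-A*02:01", 0.4999, source_id="F1"),
    ]
    strong = filter_strong_binders(records)
    assert [e.peptide for e in strong] == ["ACDEFGHI", "ACDEFGHIKL"]
    assert all(e.strong for e in strong)
    assert neoepitope_load(strong) == {"F0": 1, "F1": 1}


def test_filter_matches_brute_force_on_mixed_list():
    records = [
        BindingRecord(random_protein(9), "HLA-A*02:01", float(r), source_id=f"F{i % 5}")
        for i, r in enumerate(RNG.uniform(0, 2, size=100))
    ]
    strong = filter_strong_binders(records)
    expected = [r.peptide for r in records if r.rank_percent < 0.5]
    assert [e.peptide for e in strong] == expected


def test_pipeline_composition_is_lossless(tmp_path):
    """window -> tiles -> peptide FASTA -> reread -> mock ranks -> filter is
    deterministic and loss-free."""
    from fusionneo import io as fio

    report = make_report(FrameClass.OUT_OF_FRAME, 30, tail=random_protein(20))
    window = extract_window(report, report.orf_protein)
    tiles = tile_peptides(window)
    pairs = [(f"F000_p{i:03d}", p) for i, p in enumerate(tiles)]
    path = tmp_path / "peptides.fa"
    fio.write_peptide_fasta(pairs, str(path))
    reread = fio.read_peptide_fasta(str(path))
    assert reread == pairs
    table = mock_binding_table(reread, ["HLA-A*02:01"])
    assert len(table) == len(tiles)
    again = mock_binding_table(reread, ["HLA-A*02:01"])
    assert [(r.peptide, r.rank_percent) for r in table] == [
        (r.peptide, r.rank_percent) for r in again
    ]
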