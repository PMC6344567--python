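"""Neoepitope construction: peptide windows, 8-11-mer tiling, binder filtering.

The peptide region screened for MHC-I binding depends on the frame class of
the fusion.  In-frame fusions contribute up to 11 residues on each side of
the fusion point (the junction itself is the only novel feature); an
out-of-frame fusion contributes up to 11 upstream residues plus the entire
novel tail, every residue of which is tumour-specific.  Candidate peptides
are all 8-11-mers overlapping novel content; for in-frame fusions a peptide
must actually span the junction, because peptides wholly on one side match
the wild-type proteins.

Binding prediction itself is external (NetMHC-class tools); this module
writes their input, reads their output, and filters strong binders (rank
strictly below 0.5% for a patient allele).  A deterministic hash-based mock
predictor stands in for the external tool in tests and fully synthetic runs.
"""

from __future__ import annotations

import hashlib
from collections import Counter
from typing import Iterable, Optional, Sequence

from .types import (
    BindingRecord,
    EpitopeCandidate,
    FrameClass,
    FusionNeoError,
    FusionProteinReport,
    PeptideWindow,
)

__all__ = [
    "extract_window",
    "tile_peptides",
    "mock_rank_predictor",
    "mock_binding_table",
    "filter_strong_binders",
    "neoepitope_load",
]

_AA_STANDARD = set("ACDEFGHIKLMNPQRSTVWY")

DEFAULT_LENGTHS = (8, 9, 10, 11)


def extract_window(
    report: FusionProteinReport, full_protein: str, flank: int = 11
) -> PeptideWindow:
    """Cut the peptide window for one characterized fusion.

    ``full_protein`` is the junction-spanning ORF's protein (as reported in
    ``report.orf_protein``).  The junction index of the returned window is
    the number of upstream residues actually available (less than ``flank``
    when the ORF starts close to the junction).
    """
    if report.frame_class == FrameClass.NO_ORF_AT_JUNCTION:
        raise FusionNeoError(f"{report.candidate_id}: no ORF at junction; no window to extract")
    jidx = report.junction_aa_index
    assert jidx is not None
    upstream = full_protein[max(0, jidx - flank) : jidx]
    if report.frame_class == FrameClass.IN_FRAME:
        sequence = upstream + full_protein[jidx : jidx + flank]
    else:
        sequence = upstream + report.novel_tail
    if not sequence:
        raise FusionNeoError(f"{report.candidate_id}: empty peptide window")
    return PeptideWindow(
        candidate_id=report.candidate_id,
        sequence=sequence,
        junction_index=len(upstream),
        frame_class=report.frame_class,
    )


def tile_peptides(
    window: PeptideWindow,
    lengths: Iterable[int] = DEFAULT_LENGTHS,
    require_spanning: bool = True,
) -> list[str]:
    """Enumerate candidate peptides from a window.

    All substrings with length in ``lengths`` that overlap novel content:
    for OUT_OF_FRAME windows any peptide containing at least one residue at
    or past the junction index; for IN_FRAME windows the peptide must span
    the junction (contain residues on both sides) unless the window has no
    upstream context or ``require_spanning`` is off.  Peptides containing
    non-standard residues (X from ambiguous codons) are skipped.  Duplicates
    keep their first occurrence; order is by start position, then length.
    """
    ks = sorted(set(lengths))
    seq, j = window.sequence, window.junction_index
    spanning_needed = (
        window.frame_class == FrameClass.IN_FRAME and require_spanning and j > 0
    )
    seen: set[str] = set()
    out: list[str] = []
    for start in range(len(seq)):
        for k in ks:
            end = start + k
            if end > len(seq):
                break
            if end <= j:  # entirely upstream: wild-type
                continue
            if spanning_needed and start >= j:
                continue
            pep = seq[start:end]
            if pep in seen or set(pep) - _AA_STANDARD:
                continue
            seen.add(pep)
            out.append(pep)
    return out


def mock_rank_predictor(peptide: str, hla_allele: str) -> float:
    """Deterministic stand-in for an MHC-I binding predictor.

    Maps (peptide, allele) to a pseudo-rank uniform on [0, 100) via SHA-256,
    identical across runs and platforms.  Useful for exercising the pipeline
    end to end without the external predictor; the ranks carry no biology.
    """
    digest = hashlib.sha256(f"{peptide}\t{hla_allele}".encode()).digest()
    return int.from_bytes(digest[:8], "big") / 2**64 * 100.0


def mock_binding_table(
    peptides: Sequence[tuple[str, str]], alleles: Sequence[str]
) -> list[BindingRecord]:
    """Run the mock predictor over ``(source_id, peptide)`` pairs x alleles."""
    return [
        BindingRecord(pep, allele, mock_rank_predictor(pep, allele), source_id=pid)
        for pid, pep in peptides
        for allele in alleles
    ]


def filter_strong_binders(
    records: Iterable[BindingRecord], threshold: float = 0.5
) -> list[EpitopeCandidate]:
    """Keep predicted strong binders: rank strictly below ``threshold`` %."""
    return [
        EpitopeCandidate(
            peptide=r.peptide,
            candidate_id=r.source_id,
            hla_allele=r.hla_allele,
            rank_percent=r.rank_percent,
            strong=True,
        )
        for r in records
        if r.rank_percent < threshold
    ]


def neoepitope_load(epitopes: Iterable[EpitopeCandidate]) -> dict[Optional[str], int]:
    """Strong-binder count per source fusion (the per-patient load figure)."""
    return dict(Counter(e.candidate_id for e in epitopes))
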