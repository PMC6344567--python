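"""Readers and writers for every external format the pipeline touches.

Formats
-------
* deFuse-style fusion candidate tables (TSV; breakpoint columns 1-based).
* FASTA for assembled contigs, CDS/protein companions, and peptide exports
  (via Bio.SeqIO).
* BED-like per-base coverage (``chrom  start  end  depth`` runs, 0-based
  half-open).
* Long-format MHC-binding tables (``peptide  allele  rank`` TSV, with an
  optional ``source_id`` column and a best-effort adapter for native
  NetMHC text output).
* GTF-like gene annotation (written here line-by-line, read back through
  gffutils) with CDS/protein companion FASTAs.
* Survival and HLA-allele tables (CSV/TSV).

Parsers never silently drop rows: with ``strict=True`` (default) the first
bad record raises; with ``strict=False`` they return ``(records, errors)``
so that ``len(rows) == len(records) + len(errors)``.
"""

from __future__ import annotations

import csv
import os
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    AssembledTranscript,
    BindingRecord,
    CoverageTrack,
    FormatError,
    FusionCandidate,
    FusionNeoError,
    GeneAnnotation,
    RecordError,
)

__all__ = [
    "DEFUSE_COLUMNS",
    "read_defuse_table",
    "write_defuse_table",
    "read_fasta",
    "write_fasta",
    "read_coverage_bed",
    "write_coverage_bed",
    "read_binding_table",
    "write_binding_table",
    "read_netmhc_output",
    "read_peptide_fasta",
    "write_peptide_fasta",
    "write_annotation",
    "read_annotation",
    "read_hla_table",
    "read_survival_table",
]

#: Required deFuse output columns (minimal sufficient set; extras ignored).
DEFUSE_COLUMNS = [
    "cluster_id",
    "splitr_sequence",
    "gene1",
    "gene2",
    "gene_name1",
    "gene_name2",
    "gene_chromosome1",
    "gene_chromosome2",
    "gene_strand1",
    "gene_strand2",
    "genomic_break_pos1",
    "genomic_break_pos2",
    "span_count",
    "splitr_count",
    "probability",
    "adjacent",
    "read_through",
]

_BOOL = {"Y": True, "N": False, "TRUE": True, "FALSE": False, "1": True, "0": False}


def _parse_bool(value: str, cluster_id: str, column: str) -> bool:
    try:
        return _BOOL[str(value).strip().upper()]
    except KeyError:
        raise RecordError(cluster_id, f"cannot parse boolean {column}={value!r}")


def read_defuse_table(path: str, strict: bool = True):
    """Read a deFuse-style TSV into :class:`FusionCandidate` records.

    Breakpoint coordinates are converted from the file's 1-based convention
    to the internal 0-based one.  Returns a list, or ``(list, errors)`` when
    ``strict=False``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in DEFUSE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"deFuse table {path} missing required column(s): {missing}")
    records: list[FusionCandidate] = []
    errors: list[RecordError] = []
    for row in df.itertuples(index=False):
        cid = str(getattr(row, "cluster_id"))
        try:
            records.append(
                FusionCandidate(
                    cluster_id=cid,
                    gene1_id=str(row.gene1),
                    gene2_id=str(row.gene2),
                    gene1_name=str(row.gene_name1),
                    gene2_name=str(row.gene_name2),
                    chrom1=str(row.gene_chromosome1),
                    chrom2=str(row.gene_chromosome2),
                    strand1=str(row.gene_strand1),
                    strand2=str(row.gene_strand2),
                    genomic_break_pos1=_parse_int(row.genomic_break_pos1, cid) - 1,
                    genomic_break_pos2=_parse_int(row.genomic_break_pos2, cid) - 1,
                    junction_sequence=str(row.splitr_sequence).upper(),
                    span_count=_parse_int(row.span_count, cid),
                    split_count=_parse_int(row.splitr_count, cid),
                    probability=_parse_float(row.probability, cid),
                    adjacent_flag=_parse_bool(row.adjacent, cid, "adjacent"),
                    read_through_flag=_parse_bool(row.read_through, cid, "read_through"),
                )
            )
        except RecordError as exc:
            if strict:
                raise
            errors.append(exc)
    if strict:
        return records
    return records, errors


def _parse_int(value, cluster_id: str) -> int:
    try:
        return int(str(value))
    except ValueError:
        raise RecordError(cluster_id, f"expected integer, got {value!r}")


def _parse_float(value, cluster_id: str) -> float:
    try:
        return float(str(value))
    except ValueError:
        raise RecordError(cluster_id, f"expected number, got {value!r}")


def write_defuse_table(candidates: Sequence[FusionCandidate], path: str) -> None:
    """Write candidates back out in the deFuse dialect (1-based breakpoints)."""
    rows = []
    for c in candidates:
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "splitr_sequence": c.junction_sequence,
                "gene1": c.gene1_id,
                "gene2": c.gene2_id,
                "gene_name1": c.gene1_name,
                "gene_name2": c.gene2_name,
                "gene_chromosome1": c.chrom1,
                "gene_chromosome2": c.chrom2,
                "gene_strand1": c.strand1,
                "gene_strand2": c.strand2,
                "genomic_break_pos1": c.genomic_break_pos1 + 1,
                "genomic_break_pos2": c.genomic_break_pos2 + 1,
                "span_count": c.span_count,
                "splitr_count": c.split_count,
                "probability": repr(c.probability),
                "adjacent": "Y" if c.adjacent_flag else "N",
                "read_through": "Y" if c.read_through_flag else "N",
            }
        )
    pd.DataFrame(rows, columns=DEFUSE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str) -> list[AssembledTranscript]:
    """Read a (contig) FASTA.  The id is the first whitespace-delimited token
    of the header; sequences are uppercased; duplicate ids are an error."""
    seen: set[str] = set()
    out: list[AssembledTranscript] = []
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        out.append(AssembledTranscript(rec.id, str(rec.seq)))
    return out


def write_fasta(transcripts: Iterable[AssembledTranscript], path: str) -> None:
    SeqIO.write(
        (SeqRecord(Seq(t.sequence), id=t.contig_id, description="") for t in transcripts),
        path,
        "fasta",
    )


_AA_STANDARD = set("ACDEFGHIKLMNPQRSTVWY")


def read_peptide_fasta(path: str) -> list[tuple[str, str]]:
    """Read a peptide FASTA back as ``(peptide_id, peptide)`` pairs."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]


def write_peptide_fasta(peptides: Sequence[tuple[str, str]], path: str) -> None:
    """Write ``(peptide_id, peptide)`` pairs as FASTA, preserving input order.

    This is the hand-off point to external MHC-I binding predictors, which
    accept 8-11-mer protein FASTA input.
    """
    records = []
    for pid, pep in peptides:
        if not (8 <= len(pep) <= 11):
            raise FusionNeoError(f"peptide {pid} length {len(pep)} outside 8-11")
        bad = set(pep) - _AA_STANDARD
        if bad:
            raise FusionNeoError(f"peptide {pid} contains non-standard residue(s) {sorted(bad)}")
        records.append(SeqRecord(Seq(pep), id=pid, description=""))
    SeqIO.write(records, path, "fasta")


# ---------------------------------------------------------------------------
# Coverage BED


def read_coverage_bed(path: str) -> list[CoverageTrack]:
    """Expand ``chrom start end depth`` runs into per-base tracks.

    Runs touching or overlapping with consistent depths are merged into one
    contiguous track; overlapping contradictory depths raise.
    """
    per_chrom: dict[str, dict[int, int]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: expected chrom/start/end/depth")
            chrom, start, end, depth = parts[0], int(parts[1]), int(parts[2]), int(parts[3])
            if start >= end or depth < 0:
                raise FormatError(f"{path}:{ln}: bad interval or depth")
            base_map = per_chrom.setdefault(chrom, {})
            for pos in range(start, end):
                if pos in base_map and base_map[pos] != depth:
                    raise FormatError(
                        f"{path}:{ln}: contradictory depth at {chrom}:{pos} "
                        f"({base_map[pos]} vs {depth})"
                    )
                base_map[pos] = depth
    tracks: list[CoverageTrack] = []
    for chrom in sorted(per_chrom):
        base_map = per_chrom[chrom]
        positions = sorted(base_map)
        run_start = positions[0]
        depths = [base_map[run_start]]
        for prev, pos in zip(positions, positions[1:]):
            if pos == prev + 1:
                depths.append(base_map[pos])
            else:
                tracks.append(CoverageTrack(chrom, run_start, depths))
                run_start, depths = pos, [base_map[pos]]
        tracks.append(CoverageTrack(chrom, run_start, depths))
    return tracks


def write_coverage_bed(tracks: Iterable[CoverageTrack], path: str) -> None:
    """Write tracks as maximal constant-depth runs."""
    with open(path, "w") as fh:
        for t in tracks:
            run_start, run_depth = t.start, t.depths[0]
            for offset, depth in enumerate(t.depths[1:], 1):
                if depth != run_depth:
                    fh.write(f"{t.chrom}\t{run_start}\t{t.start + offset}\t{run_depth}\n")
                    run_start, run_depth = t.start + offset, depth
            fh.write(f"{t.chrom}\t{run_start}\t{t.end}\t{run_depth}\n")


# ---------------------------------------------------------------------------
# Binding tables


def read_binding_table(path: str, strict: bool = True):
    """Read the long-format binding TSV: ``peptide  allele  rank`` plus an
    optional ``source_id`` column."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["peptide", "allele", "rank"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"binding table {path} missing column(s): {missing}")
    has_source = "source_id" in df.columns
    records: list[BindingRecord] = []
    errors: list[RecordError] = []
    for row in df.itertuples(index=False):
        try:
            records.append(
                BindingRecord(
                    peptide=str(row.peptide),
                    hla_allele=str(row.allele),
                    rank_percent=_parse_float(row.rank, str(row.peptide)),
                    source_id=str(row.source_id) if has_source else None,
                )
            )
        except RecordError as exc:
            if strict:
                raise
            errors.append(exc)
    if strict:
        return records
    return records, errors


def write_binding_table(records: Iterable[BindingRecord], path: str) -> None:
    rows = [
        {
            "peptide": r.peptide,
            "allele": r.hla_allele,
            "rank": repr(r.rank_percent),
            "source_id": r.source_id if r.source_id is not None else "",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["peptide", "allele", "rank", "source_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_netmhc_output(path: str) -> list[BindingRecord]:
    """Best-effort adapter for native NetMHC 4.0-style text output.

    Parses whitespace-delimited result lines (pos, HLA, peptide, ..., %Rank);
    layout is version-dependent, so the simplified long-format TSV is the
    preferred interchange.  Lines that do not look like result rows are
    skipped.
    """
    records: list[BindingRecord] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 4 or not parts[0].isdigit():
                continue
            allele = parts[1]
            peptide = next((p for p in parts[2:] if set(p) <= _AA_STANDARD and 8 <= len(p) <= 11), None)
            if peptide is None:
                continue
            rank = None
            for token in reversed(parts):
                try:
                    value = float(token)
                except ValueError:
                    continue
                if 0 <= value <= 100:
                    rank = value
                    break
            if rank is None:
                continue
            records.append(BindingRecord(peptide, allele, rank))
    return records


# ---------------------------------------------------------------------------
# Annotation (GTF + companion FASTAs)


def write_annotation(genes: Sequence[GeneAnnotation], prefix: str) -> None:
    """Write ``<prefix>.gtf`` plus ``<prefix>.cds.fa`` / ``<prefix>.protein.fa``
    companions for genes that carry sequences.  GTF is 1-based inclusive."""
    with open(prefix + ".gtf", "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}";'
            fh.write(
                f"{g.chrom}\tfusionneo\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\tfusionneo\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )
    cds = [SeqRecord(Seq(g.cds_sequence), id=g.gene_id, description="") for g in genes if g.cds_sequence]
    prot = [SeqRecord(Seq(g.protein_sequence), id=g.gene_id, description="") for g in genes if g.protein_sequence]
    SeqIO.write(cds, prefix + ".cds.fa", "fasta")
    SeqIO.write(prot, prefix + ".protein.fa", "fasta")


def read_annotation(prefix: str) -> dict[str, GeneAnnotation]:
    """Load annotation written by :func:`write_annotation` (or any GTF with
    gene/exon features and gene_id/gene_name attributes)."""
    import gffutils

    db = gffutils.create_db(
        prefix + ".gtf",
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    cds_path, prot_path = prefix + ".cds.fa", prefix + ".protein.fa"
    cds = {r.id: str(r.seq) for r in SeqIO.parse(cds_path, "fasta")} if os.path.exists(cds_path) else {}
    prot = {r.id: str(r.seq) for r in SeqIO.parse(prot_path, "fasta")} if os.path.exists(prot_path) else {}
    genes: dict[str, GeneAnnotation] = {}
    for feat in db.features_of_type("gene"):
        gid = feat.attributes["gene_id"][0]
        genes[gid] = GeneAnnotation(
            gene_id=gid,
            gene_name=feat.attributes.get("gene_name", [gid])[0],
            chrom=feat.seqid,
            strand=feat.strand,
            start=feat.start - 1,
            end=feat.end,
            exons=[],
            cds_sequence=cds.get(gid),
            protein_sequence=prot.get(gid),
        )
    for feat in db.features_of_type("exon"):
        gid = feat.attributes["gene_id"][0]
        if gid in genes:
            genes[gid].exons.append((feat.start - 1, feat.end))
    for g in genes.values():
        g.exons.sort()
    return genes


# ---------------------------------------------------------------------------
# Small tables


def read_hla_table(path: str) -> dict[str, list[str]]:
    """Read a per-patient HLA allele table (``sample_id  allele`` TSV/CSV,
    OptiType-style four-digit alleles, one row per allele)."""
    alleles: dict[str, list[str]] = {}
    with open(path, newline="") as fh:
        dialect = "\t" if "\t" in fh.readline() else ","
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=dialect)
        if reader.fieldnames is None or not {"sample_id", "allele"} <= set(reader.fieldnames):
            raise FormatError(f"HLA table {path} needs sample_id and allele columns")
        for row in reader:
            alleles.setdefault(row["sample_id"], []).append(row["allele"])
    return alleles


def read_survival_table(path: str) -> pd.DataFrame:
    """Read ``sample_id,time,event[,ff]`` survival data (CSV or TSV)."""
    sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in ("sample_id", "time", "event") if c not in df.columns]
    if missing:
        raise FormatError(f"survival table {path} missing column(s): {missing}")
    if (df["time"] < 0).any():
        raise FormatError(f"survival table {path} contains negative times")
    df["event"] = df["event"].astype(bool)
    return df
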