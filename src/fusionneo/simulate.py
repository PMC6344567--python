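"""Synthetic fixtures with planted ground truth for every pipeline stage.

Real inputs to this pipeline are cohort-scale RNA-seq runs pushed through a
fusion caller and a de novo assembler.  The generator here emulates their
outputs directly — candidate tables, contig FASTAs, annotation, coverage —
from a toy genome, planting known truths (fusion class, reading frame, novel
tail, concordance band, span counts, coverage proportions) that the pipeline
must recover.  Everything is a pure function of a single integer seed.

Concordance bands are realized by *synonymous* codon substitutions in the
emitted contig: nucleotide identity to the caller's junction window drops
while the encoded fusion protein — and therefore the planted frame class and
novel tail — stays exactly as constructed.  Contigs are emitted in a random
orientation, as an unstranded assembler would.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .concordance import reverse_complement
from .orf import find_orfs, translate
from .types import (
    AssembledTranscript,
    CoverageTrack,
    FrameClass,
    FusionCandidate,
    FusionClass,
    FusionNeoError,
    GeneAnnotation,
)

__all__ = [
    "PlanEntry",
    "PlantedFusion",
    "TruthManifest",
    "default_plan",
    "make_toy_annotation",
    "plant_fusions",
    "subsample_paired_records",
    "make_coverage_fixture",
    "BAND_CODON_MUTATION",
]

_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
_SENSE_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
)

#: Per-codon synonymous substitution fraction realizing each concordance band.
BAND_CODON_MUTATION = {"high": 0.0, "mid": 0.3, "low": 0.8}

#: Stop codons in all three frames; appended to every fusion transcript so
#: out-of-frame tails always terminate before the contig end.
_STOP_PAD = "TAAATAAATAAA"


def _synonym_table() -> dict[str, list[str]]:
    by_aa: dict[str, list[str]] = {}
    for codon in _SENSE_CODONS:
        by_aa.setdefault(translate(codon), []).append(codon)
    return {
        codon: [c for c in group if c != codon]
        for group in by_aa.values()
        for codon in group
        if len(group) > 1
    }

_SYNONYMS = _synonym_table()


@dataclass(frozen=True)
class PlanEntry:
    """What to plant for one fusion."""

    fusion_class: FusionClass
    frame_class: FrameClass
    band: Union[str, float] = "high"  # named band or per-codon mutation fraction
    span_count: int = 10
    drop_reason: Optional[str] = None  # plant a filter violation instead
    tail_length: Optional[int] = None  # exact novel-tail length (OUT_OF_FRAME only)


@dataclass
class PlantedFusion:
    candidate_id: str
    fusion_class: str
    frame_class: str
    novel_tail: str
    junction_aa_index: int
    band: Union[str, float]
    span_count: int
    drop_reason: Optional[str]
    expected_validated: bool
    contig_id: Optional[str]


@dataclass
class TruthManifest:
    """Planted truths: fully determines the expected pipeline output."""

    seed: int
    mapped_paired_reads: int
    fusions: list[PlantedFusion] = field(default_factory=list)
    control_pairs: list[list[str]] = field(default_factory=list)
    true_fusion_fraction: float = 0.0

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "TruthManifest":
        with open(path) as fh:
            data = json.load(fh)
        data["fusions"] = [PlantedFusion(**f) for f in data["fusions"]]
        return cls(**data)


def default_plan() -> list[PlanEntry]:
    """Six fusions covering all three classes and both frame classes, plus
    one junction-less contig and one planted filter violation."""
    return [
        PlanEntry(FusionClass.INTER, FrameClass.IN_FRAME, "high", span_count=10),
        PlanEntry(FusionClass.INTER, FrameClass.OUT_OF_FRAME, "mid", span_count=20),
        PlanEntry(FusionClass.INTRA, FrameClass.IN_FRAME, "high", span_count=30),
        PlanEntry(FusionClass.INTRA, FrameClass.OUT_OF_FRAME, "high", span_count=5),
        PlanEntry(FusionClass.TIC, FrameClass.OUT_OF_FRAME, "high", span_count=8),
        PlanEntry(FusionClass.TIC, FrameClass.IN_FRAME, "low", span_count=12),
        PlanEntry(FusionClass.INTER, FrameClass.OUT_OF_FRAME, "none", span_count=7),
        PlanEntry(
            FusionClass.INTRA,
            FrameClass.OUT_OF_FRAME,
            "high",
            span_count=9,
            drop_reason="LOW_PROBABILITY",
        ),
    ]


# ---------------------------------------------------------------------------
# Toy genome & annotation


def _random_cds(rng: np.random.Generator, n_interior: int) -> str:
    codons = rng.choice(len(_SENSE_CODONS), size=n_interior)
    stop = _STOPS[rng.integers(len(_STOPS))]
    return "ATG" + "".join(_SENSE_CODONS[i] for i in codons) + stop


def _random_seq(rng: np.random.Generator, length: int, forbid_atg: bool = False) -> str:
    while True:
        seq = "".join(_BASES[i] for i in rng.integers(0, 4, size=length))
        if not forbid_atg or "ATG" not in seq:
            return seq


def make_toy_annotation(
    seed: int, n_genes: int = 16
) -> tuple[dict[str, str], dict[str, GeneAnnotation]]:
    """Build a deterministic toy genome and gene set.

    Chromosome 1 carries a block of genes providing INTRA pairs (gene
    strictly between the partners) and adjacent pairs; chromosome 2 a
    dedicated block of adjacent pairs including one transcribed in opposite
    directions (the read-through exemplar); remaining genes sit alone on
    further chromosomes, providing INTER pairs with no shared genes.  The
    default of 16 genes is enough for a standard fusion plan to use pairwise
    gene-disjoint partners, which keeps every planted truth unambiguous.
    Returns (genome, annotation) with per-gene CDS and protein sequences.
    """
    if n_genes < 4:
        raise FusionNeoError("need at least 4 genes for a usable layout")
    rng = np.random.default_rng(seed)
    chrom_of: list[str] = []
    for idx in range(n_genes):
        if n_genes >= 10:
            if idx < 6:
                chrom_of.append("chr1")
            elif idx < 10:
                chrom_of.append("chr2")
            else:
                chrom_of.append(f"chr{idx}")
        elif idx < 3:
            chrom_of.append("chr1")
        elif idx < 5 and n_genes >= 5:
            chrom_of.append("chr2")
        else:
            chrom_of.append(f"chr{idx}")
    genome: dict[str, str] = {}
    annotation: dict[str, GeneAnnotation] = {}
    per_chrom: dict[str, list[int]] = {}
    for idx, chrom in enumerate(chrom_of):
        per_chrom.setdefault(chrom, []).append(idx)
    for chrom, gene_idxs in per_chrom.items():
        parts: list[str] = []
        cursor = 0
        for order, idx in enumerate(gene_idxs):
            gap = int(rng.integers(300, 600))
            parts.append(_random_seq(rng, gap))
            cursor += gap
            n_interior = int(rng.integers(60, 120))
            cds = _random_cds(rng, n_interior)
            # Opposite-direction adjacent pair: second gene on a shared
            # chromosome runs on the minus strand.
            strand = "-" if order == 1 and len(gene_idxs) > 1 else "+"
            gene_genomic = cds if strand == "+" else reverse_complement(cds)
            n_exons = int(rng.integers(2, 5))
            cuts = sorted(rng.choice(np.arange(1, len(gene_genomic)), size=n_exons - 1, replace=False))
            chunks = [gene_genomic[a:b] for a, b in zip([0] + list(cuts), list(cuts) + [len(gene_genomic)])]
            exons: list[tuple[int, int]] = []
            gene_start = cursor
            for chunk_no, chunk in enumerate(chunks):
                if chunk_no > 0:
                    intron = int(rng.integers(50, 150))
                    parts.append(_random_seq(rng, intron))
                    cursor += intron
                parts.append(chunk)
                exons.append((cursor, cursor + len(chunk)))
                cursor += len(chunk)
            gid = f"GENE{idx:03d}"
            annotation[gid] = GeneAnnotation(
                gene_id=gid,
                gene_name=f"TG{idx}",
                chrom=chrom,
                strand=strand,
                start=gene_start,
                end=cursor,
                exons=exons,
                cds_sequence=cds,
                protein_sequence=translate(cds, to_stop=True),
            )
        parts.append(_random_seq(rng, int(rng.integers(200, 400))))
        genome[chrom] = "".join(parts)
    return genome, annotation


# ---------------------------------------------------------------------------
# Fusion planting


def _pairs_by_class(annotation: dict[str, GeneAnnotation]) -> dict[FusionClass, list[tuple[str, str]]]:
    genes = list(annotation.values())
    inter, intra, tic = [], [], []
    for g1, g2 in itertools.combinations(genes, 2):
        if g1.chrom != g2.chrom:
            inter.append((g1.gene_id, g2.gene_id))
            continue
        left, right = (g1, g2) if g1.start <= g2.start else (g2, g1)
        between = any(
            o.chrom == g1.chrom
            and o.gene_id not in (g1.gene_id, g2.gene_id)
            and o.start >= left.end
            and o.end <= right.start
            for o in genes
        )
        (intra if between else tic).append((g1.gene_id, g2.gene_id))
    # Prefer INTER pairs whose genes sit alone on their chromosome, leaving
    # multi-gene chromosomes free for INTRA/TIC pairs.
    per_chrom = {}
    for g in genes:
        per_chrom[g.chrom] = per_chrom.get(g.chrom, 0) + 1
    chrom_of = {g.gene_id: g.chrom for g in genes}
    inter.sort(key=lambda p: (sum(per_chrom[chrom_of[g]] > 1 for g in p),))
    return {FusionClass.INTER: inter, FusionClass.INTRA: intra, FusionClass.TIC: tic}


def _assign_pairs(
    entries: Sequence[PlanEntry], pools: dict[FusionClass, list[tuple[str, str]]]
) -> list[tuple[str, str]]:
    """Pick a gene pair for every plan entry.

    Entries greedily take the first pair in their class pool whose genes are
    unused by every previously assigned entry: fusions sharing a partner
    gene can validate against each other's contigs, which would blur the
    planted truth.  When the pool offers no disjoint pair (small gene sets,
    long plans) the entry falls back to cycling the pool, preferring
    filter-dropped entries for the reuse since those never reach validation.
    """
    cycles = {cls: itertools.cycle(pairs) for cls, pairs in pools.items() if pairs}
    pair_for: list[Optional[tuple[str, str]]] = [None] * len(entries)
    used_genes: set[str] = set()
    # Entries that reach validation get first pick of disjoint pairs.
    order = sorted(range(len(entries)), key=lambda i: entries[i].drop_reason is not None)
    for idx in order:
        entry = entries[idx]
        if entry.fusion_class not in cycles:
            raise FusionNeoError(
                f"plan needs a {entry.fusion_class.value} pair but the annotation has none"
            )
        pool = pools[entry.fusion_class]
        pair = next(
            (p for p in pool if not (set(p) & used_genes)),
            next(cycles[entry.fusion_class]),
        )
        pair_for[idx] = pair
        used_genes.update(pair)
    return pair_for  # type: ignore[return-value]


def _mutate_synonymously(
    transcript: str,
    cds_start: int,
    n_codons: int,
    fraction: float,
    rng: np.random.Generator,
    protect: tuple[int, int] = (0, 0),
) -> str:
    """Swap a fraction of codons for synonyms inside the translated region;
    the encoded protein is unchanged.  Codons with index in the half-open
    ``protect`` range are left untouched: keeping the immediate junction
    neighbourhood exact ensures the planted breakpoint position stays
    well-defined under alignment, whatever the mutation load elsewhere."""
    if fraction <= 0:
        return transcript
    seq = list(transcript)
    mutable = [
        i
        for i in range(n_codons)
        if not (protect[0] <= i < protect[1])
        and transcript[cds_start + 3 * i : cds_start + 3 * i + 3] in _SYNONYMS
    ]
    n_pick = int(round(fraction * len(mutable)))
    if n_pick == 0:
        return transcript
    picks = rng.choice(len(mutable), size=n_pick, replace=False)
    for p in picks:
        i = mutable[int(p)]
        codon = transcript[cds_start + 3 * i : cds_start + 3 * i + 3]
        options = _SYNONYMS[codon]
        new = options[int(rng.integers(len(options)))]
        seq[cds_start + 3 * i : cds_start + 3 * i + 3] = new
    return "".join(seq)


def _build_fusion_transcript(
    g1: GeneAnnotation,
    g2: GeneAnnotation,
    frame_class: FrameClass,
    tail_length: Optional[int],
    rng: np.random.Generator,
) -> tuple[str, int, int, str, str]:
    """Join two CDSs at a breakpoint.

    Returns (transcript, junction_position, junction_aa_index, novel_tail,
    full_protein).  In-frame joins are at codon boundaries of both genes;
    out-of-frame joins delete one base at the junction, shifting the
    downstream partner by +1.
    """
    cds1, cds2 = g1.cds_sequence, g2.cds_sequence
    p2 = g2.protein_sequence
    assert cds1 and cds2 and p2
    n1 = len(cds1) // 3 - 1  # coding codons incl. start, excl. stop
    utr5 = _random_seq(rng, 12, forbid_atg=True)
    for _ in range(200):
        a = int(rng.integers(40, max(41, n1 - 2)))
        if frame_class == FrameClass.IN_FRAME:
            b = int(rng.integers(2, max(3, len(p2) - 9)))
            part2 = cds2[3 * b :]
        elif tail_length is not None:
            codons = rng.choice(len(_SENSE_CODONS), size=tail_length)
            part2 = "".join(_SENSE_CODONS[i] for i in codons) + _STOPS[rng.integers(3)]
        else:
            b = int(rng.integers(2, max(3, len(p2) - 9)))
            part2 = cds2[3 * b + 1 :]
        transcript = utr5 + cds1[: 3 * a] + part2 + _STOP_PAD
        junction = len(utr5) + 3 * a
        protein = translate(transcript[len(utr5) :], to_stop=True)
        downstream = protein[a:]
        if frame_class == FrameClass.IN_FRAME:
            if len(downstream) >= 8 and downstream[:8] in p2:
                return transcript, junction, a, "", protein
        else:
            if len(downstream) >= 8 and downstream[:8] not in p2 and "X" not in downstream:
                if tail_length is not None and len(downstream) != tail_length:
                    continue
                return transcript, junction, a, downstream, protein
    raise FusionNeoError(
        f"could not construct a {frame_class.value} fusion of {g1.gene_id} and {g2.gene_id}"
    )


def _planted_orf_is_selected(contig_seq: str, junction: int, utr_len: int = 12) -> bool:
    """Check the planted fusion ORF is what ORF selection will pick.

    Random sequence can coincidentally contain a competing ORF (shifted
    frame or antisense) that also spans the junction and out-lengths the
    planted one, which would make the planted truth ill-defined; such
    constructions are rejected and redrawn.
    """
    orfs = [
        o
        for o in find_orfs(AssembledTranscript("check", contig_seq), min_aa=1)
        if o.start <= junction < o.end
    ]
    return bool(orfs) and orfs[0].strand == "+" and orfs[0].start == utr_len


def plant_fusions(
    annotation: dict[str, GeneAnnotation],
    plan: Sequence[Union[PlanEntry, tuple]],
    seed: int,
    mapped_paired_reads: int = 60_000_000,
    n_decoy_contigs: int = 2,
) -> tuple[list[FusionCandidate], list[AssembledTranscript], TruthManifest]:
    """Plant the fusions described by ``plan`` and return caller-style
    candidates, assembler-style contigs, and the truth manifest."""
    rng = np.random.default_rng(seed)
    entries = [e if isinstance(e, PlanEntry) else PlanEntry(*e) for e in plan]
    pools = _pairs_by_class(annotation)
    pair_for = _assign_pairs(entries, pools)
    candidates: list[FusionCandidate] = []
    contigs: list[AssembledTranscript] = []
    manifest = TruthManifest(seed=seed, mapped_paired_reads=mapped_paired_reads)

    for idx, entry in enumerate(entries):
        gid1, gid2 = pair_for[idx]
        g1, g2 = annotation[gid1], annotation[gid2]
        fraction = 0.0
        if entry.band != "none":
            fraction = (
                BAND_CODON_MUTATION[entry.band]
                if isinstance(entry.band, str)
                else float(entry.band)
            )
        for _ in range(50):
            transcript, junction, jidx, tail, _ = _build_fusion_transcript(
                g1, g2, entry.frame_class, entry.tail_length, rng
            )
            n_codons = (len(transcript) - 12) // 3  # translated region after the 12-nt UTR
            mutated = _mutate_synonymously(
                transcript, 12, n_codons, fraction, rng, protect=(jidx - 5, jidx + 5)
            )
            if entry.band == "none" or _planted_orf_is_selected(mutated, junction):
                break
        else:
            raise FusionNeoError("could not realize an unambiguous planted fusion")
        cid = f"F{idx:03d}"
        arm_left = min(int(rng.integers(150, 301)), junction)
        arm_right = min(int(rng.integers(150, 301)), len(transcript) - junction)
        junction_seq = (
            transcript[junction - arm_left : junction] + "|" + transcript[junction : junction + arm_right]
        )
        is_tic = entry.fusion_class == FusionClass.TIC
        gene1_name = "SRGAP2C" if entry.drop_reason == "EXCLUDED_FAMILY" else g1.gene_name
        probability = (
            float(rng.uniform(0.05, 0.5))
            if entry.drop_reason == "LOW_PROBABILITY"
            else float(rng.uniform(0.6, 0.99))
        )
        candidates.append(
            FusionCandidate(
                cluster_id=cid,
                gene1_id=g1.gene_id,
                gene2_id=g2.gene_id,
                gene1_name=gene1_name,
                gene2_name=g2.gene_name,
                chrom1=g1.chrom,
                chrom2=g2.chrom,
                strand1=g1.strand,
                strand2=g2.strand,
                genomic_break_pos1=g1.end - 1,
                genomic_break_pos2=g2.start,
                junction_sequence=junction_seq,
                span_count=entry.span_count,
                split_count=int(rng.integers(2, 30)),
                probability=probability,
                adjacent_flag=is_tic,
                read_through_flag=bool(is_tic and rng.random() < 0.5),
            )
        )
        if entry.drop_reason == "IN_CONTROL":
            manifest.control_pairs.append(sorted([gene1_name, g2.gene_name]))

        contig_id = f"TRINITY_DN{idx}_c0_g1_i1"
        if entry.band == "none":
            contig_seq = transcript[:junction]  # one arm only: never spans the junction
        else:
            contig_seq = mutated
        if rng.random() < 0.5:
            contig_seq = reverse_complement(contig_seq)
        contigs.append(AssembledTranscript(contig_id, contig_seq))

        dropped = entry.drop_reason is not None
        manifest.fusions.append(
            PlantedFusion(
                candidate_id=cid,
                fusion_class=entry.fusion_class.value,
                frame_class=entry.frame_class.value,
                novel_tail=tail,
                junction_aa_index=jidx,
                band=entry.band,
                span_count=entry.span_count,
                drop_reason=entry.drop_reason,
                expected_validated=not dropped and entry.band != "none",
                contig_id=contig_id,
            )
        )

    for d in range(n_decoy_contigs):
        contigs.append(
            AssembledTranscript(f"TRINITY_DN9{d}_c0_g1_i1", _random_seq(rng, int(rng.integers(300, 500))))
        )

    span_total = sum(
        f.span_count
        for f in manifest.fusions
        if f.expected_validated and f.fusion_class != FusionClass.TIC.value
    )
    manifest.true_fusion_fraction = span_total / (mapped_paired_reads / 10_000_000)
    return candidates, contigs, manifest


# ---------------------------------------------------------------------------
# Paired-read subsampling & coverage fixtures


def _record_id(record) -> str:
    rid = record[0] if isinstance(record, (tuple, list)) else record.id
    for suffix in ("/1", "/2"):
        if rid.endswith(suffix):
            return rid[: -len(suffix)]
    return rid


def subsample_paired_records(reads1: Sequence, reads2: Sequence, n: int) -> tuple[list, list]:
    """Keep every n-th record pair (1st, n+1-th, ...), preserving mate
    pairing; the depth-titration scheme used to probe fusion-fraction
    stability.  Records are (id, seq, qual) tuples or SeqRecord-likes."""
    if n < 1:
        raise FusionNeoError("subsampling factor must be >= 1")
    if len(reads1) != len(reads2):
        raise FusionNeoError("mate streams differ in length; input is not properly paired")
    for r1, r2 in zip(reads1, reads2):
        if _record_id(r1) != _record_id(r2):
            raise FusionNeoError(f"mate ids disagree: {_record_id(r1)} vs {_record_id(r2)}")
    return list(reads1[::n]), list(reads2[::n])


def make_coverage_fixture(
    seed: int,
    chrom: str = "chr4",
    exon_end: int = 1000,
    chimera_proportion: float = 0.3,
    depth: int = 200,
) -> tuple[CoverageTrack, CoverageTrack, dict]:
    """Coverage over an exon/intron boundary with a planted chimera fraction.

    The last 10 exonic bases carry the full depth (all transcripts); each of
    the first 10 intronic bases carries Binomial(depth, p) reads (chimeric
    transcripts only), so the measured intron/exon ratio estimates p.
    """
    if not (0.0 <= chimera_proportion <= 1.0):
        raise FusionNeoError("chimera proportion must be in [0, 1]")
    if depth <= 0:
        raise FusionNeoError("depth must be positive")
    rng = np.random.default_rng(seed)
    exon = CoverageTrack(chrom, exon_end - 10, [depth] * 10)
    intron_depths = rng.binomial(depth, chimera_proportion, size=10).astype(int).tolist()
    intron = CoverageTrack(chrom, exon_end, intron_depths)
    manifest = {
        "seed": seed,
        "chimera_proportion": chimera_proportion,
        "depth": depth,
        "chrom": chrom,
        "exon_window": [exon_end - 10, exon_end],
        "intron_window": [exon_end, exon_end + 10],
    }
    return exon, intron, manifest
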