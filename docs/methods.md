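# Methods

This note records the models, numerical choices, and open design decisions
behind `fusionneo`, at the level of detail a maintainer or reviewer needs to
judge what the package computes and what its tests do and do not establish.

## Junction concordance

A fusion caller reports, per candidate, a junction sequence with a marked
breakpoint. We compare the breakpoint *window* — each arm truncated to its
innermost 250 bases, so 200–500 nt in total for typical caller output —
against every de novo assembled contig. Assemblies are unstranded, so each
contig is tested in both orientations.

**Alignment model.** Local alignment with integer scores: match +1,
mismatch −2, gap open −3, gap extend −1 (a gap of length L costs
3 + (L−1); `N` never matches). Mismatches cost twice a match and gaps
slightly more, so spurious junction-crossing alignments score poorly while
assembly SNPs and small indels are tolerated.

**Concordance definition.** The caller's own literature never pins down
"concordance" numerically, so the package defines it as

    concordance = 100 × (identically aligned window bases) / (window length)

for the single best local alignment per contig/orientation, *provided* the
aligned window span contains both breakpoint-flanking positions. A contig
whose best alignment stops at the breakpoint — i.e. one that assembles only
one partner gene — contributes nothing, whatever its identity. The best
junction-covering match over all contigs and orientations is reported; a
candidate validates at concordance ≥ 25% (inclusive by default; both the
threshold and the comparator are configurable because the operating point
is quoted both as "at least 25%" and as "> 25%" in practice).

**Determinism.** Co-optimal affine-gap alignments can differ in identity
count, which would make the percentage ill-defined. The aligner therefore
maximizes the pair (score, identity) lexicographically in a single dynamic
program — scores and identities are packed as `score·4096 + identity`, so
an ordinary integer maximum implements the rule — and resolves residual
ties with a fixed traceback preference (diagonal, then vertical gap, then
horizontal gap; first maximal cell in row-major order). Contigs at equal
concordance are ranked by alignment score (a gap-free match outranks a
gapped one of equal identity), then contig id, then forward orientation.
Equal inputs thus always give byte-identical output. The forward pass is
vectorized row-wise with numpy (the horizontal-gap state is a prefix-max
scan); the traceback is linear in the alignment length.

**Limits.** Windows are capped at 500 nt (identity must fit in the packed
low bits); windows under 16 nt are rejected as unscoreable. BLAST-style
uniqueness checking of the junction against the whole genome is out of
scope and left to external tools.

## Candidate filtering and classification

Filters run before any alignment, in a fixed order that assigns exactly one
drop reason per candidate (LOW_PROBABILITY, then IN_CONTROL, then
EXCLUDED_FAMILY), which keeps the kept/dropped partition auditable.
Probability must be *strictly* greater than 0.5. Control subtraction keys
on the unordered gene-*name* pair — a fusion seen in normal controls is
removed regardless of exact breakpoint, since recurrent artifacts rarely
reproduce coordinates. Family exclusion matches gene-name prefixes and
defaults to `("SRGAP2",)`, covering the SRGAP2 duplicate genes whose
incomplete annotation generates artifactual calls.

Classification: TIC when the caller's read-through/adjacent flags say so —
strand orientation does not veto a TIC, since read-through chimeras of
opposite-strand neighbours exist — else INTER across chromosomes, else
INTRA. When flags are absent entirely, an annotation fallback calls two
genes neighbours when they share a chromosome with no annotated gene
strictly between their bodies and a gap of at most 1 Mb.

## ORFs and protein consequence

`find_orfs` enumerates, over both strands and three frames, every ATG
paired with its first in-frame stop; ATGs with no downstream stop yield
incomplete ORFs (flagged, tail later reported as censored) — assembly
truncation is common enough that discarding them would lose real fusions.
Codons containing `N` translate to `X` and are never read as stops.

Characterization maps the breakpoint through the best alignment onto the
supporting contig (oriented to match the window) and selects the longest
ORF containing it, with *no* minimum length: short novel tails are exactly
the neoantigen payload. Frame class is decided by peptide k-mer membership
rather than annotation-phase arithmetic, because assembled contigs have
unknown splice structure: the fusion is IN_FRAME when the first k = 8
residues translated past the junction occur contiguously in the 3'
partner's reference protein. Eight residues make a chance hit in a
reference proteome negligible (20⁻⁸ per position) while tolerating short
tails. The novel tail of an OUT_OF_FRAME fusion is the translation from
the junction to the ORF's stop; it never contains a stop character and is
maximal by construction. A novel N-terminus is flagged when the ORF's
first 8 residues do not occur in the 5' partner's protein. Internal
alignment gaps of ≥ 20 nt produce an "unusual splicing" note (e.g. intron
retention at the junction); full splice-graph analysis is out of scope.
The reported transcript direction is the strand of the chosen ORF relative
to the window-matched contig orientation; on unspliced contigs this proxy
can in principle disagree with a splice-pattern-based call.

## Neoepitope construction

In-frame windows: up to 11 residues each side of the fusion point (only
the junction itself is novel). Out-of-frame windows: up to 11 upstream
residues plus the entire novel tail. Tiling enumerates all 8–11-mers that
overlap novel content; for in-frame fusions a peptide must actually span
the junction, because peptides wholly on either side are self peptides —
whether the original analyses removed such wild-type-matching peptides
before prediction is not recoverable, so a `require_spanning=False` flag
restores naive tiling. Closed form used as a test anchor: a 22-residue
in-frame window with full context yields k−1 junction-spanning k-mers,
7+8+9+10 = 34 in total. Duplicates keep their first occurrence
per-candidate (loads are counted per fusion); peptides containing `X` are
skipped since binding predictors reject them.

Binding prediction is external by design (file-based hand-off: peptide
FASTA out, `peptide/allele/rank` TSV back; a best-effort adapter parses
native NetMHC text output but the simplified TSV is the stable
interchange). Strong binders are rank *strictly* below 0.5% for a patient
allele. The built-in mock predictor hashes (peptide, allele) with SHA-256
to a rank uniform on [0, 100); it is deterministic across platforms and
carries no biology — it exists so the pipeline composes end to end in
tests and demos.

## Fusion fraction and survival

    FF = Σ span counts of validated INTER+INTRA fusions / (mapped paired reads / 10⁷)

TICs are excluded: read-through transcription need not reflect genomic
rearrangement. Summing span counts (rather than counting fusions) is the
default because span support is what scales with both expression and
clonality; the alternative reading is exposed as `ff_mode="fusion_count"`.
The normalization makes FF exactly invariant to proportional scaling of
spans and depth, and stable in expectation under binomial read subsampling
— the property that justifies comparing FF across samples sequenced at
different depths (recommended minimum 40 million paired reads; the
pipeline warns below it but continues).

High-FF calls use a strict doubling rule against matched-control FF.
Survival stratification splits at FF > 2.7 (a dataset-derived top-quartile
cutoff kept as a config default, not a constant; samples exactly at the
threshold go LOW). The Kaplan–Meier estimator and the two-sample log-rank
statistic are implemented directly from the product-limit and
observed-minus-expected formulas (hypergeometric variance, χ² with 1 df);
lifelines serves only as an independent cross-check in the test suite,
which agrees to 10⁻⁹ on the reference 12-record dataset.

The TIC read ratio is the arithmetic mean depth over the first 10 nt of
the retained intron (chimera-only reads) divided by the mean over the last
10 nt of the shared exon (chimera + native reads); it estimates the
chimera fraction of the downstream gene's transcription and is undefined
when the exon mean is zero.

## Synthetic fixtures

The generator emulates the *outputs* of the upstream tools, not reads: a
toy genome (default 16 genes: a six-gene chromosome providing INTRA pairs
with a gene between, a four-gene chromosome of adjacent pairs including an
opposite-strand pair, and singleton chromosomes for INTER pairs),
caller-style candidate tables, assembler-style contigs, GTF-like
annotation, and coverage tracks. Everything is a pure function of one
integer seed.

Fusion transcripts join two CDSs at codon boundaries (IN_FRAME) or with a
one-base deletion at the junction (OUT_OF_FRAME, +1 shift); a
stop-in-every-frame pad terminates every transcript so novel tails always
end before the contig does. Planted truths (class, frame, tail, junction
index, expected validation, fusion fraction) are recorded in a manifest at
construction time.

Three generator choices keep planted truths exactly recoverable rather
than merely likely:

* **Concordance bands are synonymous.** Contig degradation uses synonymous
  codon substitutions (bands high/mid/low = 0 / 0.3 / 0.8 of mutable
  codons), so nucleotide identity drops while the encoded fusion protein —
  hence frame class and tail — is untouched. Substitution-only noise also
  keeps the optimal alignment in register, except that a ±5-codon
  neighbourhood of the junction is left unmutated so local alignment
  desynchronization can never straddle the breakpoint.
* **Gene pairs are disjoint.** Planted fusions take pairwise gene-disjoint
  partners (fusions sharing a gene can validate against each other's
  contigs); entries planted *without* a junction-spanning contig get genes
  no other fusion uses.
* **Competing ORFs are rejected at build time.** Random sequence
  occasionally contains a coincidental ORF (shifted frame or antisense)
  that spans the junction and out-lengths the planted one; such
  constructions are redrawn so the planted ORF is provably the one
  selection picks.

What the fixtures do **not** emulate: sequencing error and coverage
fluctuation, alternative isoforms and real splice structure, assembly
fragmentation and chimeric misassembly, repeat-induced multi-mapping, and
paralogy between partner genes. Passing the planted-truth suite therefore
demonstrates the pipeline's logic is exact on well-posed inputs; it does
not bound error rates on real assemblies, where validation specificity
rests on the junction-coverage requirement and the 25% threshold.

Paired-record subsampling keeps every n-th mate pair (deterministic,
pairing-checked), mirroring the depth-titration scheme used to probe FF
stability. Coverage fixtures plant a chimera proportion p as
Binomial(depth, p) intron depths against constant exon depth, so the
measured ratio estimates p with standard error √(p(1−p)/(10·depth)).

## Numerical and interface choices

* Internal coordinates are 0-based half-open everywhere; files keep their
  native conventions (caller tables 1-based, BED 0-based) and convert at
  the I/O boundary.
* Parsers never silently drop rows: strict mode raises on the first bad
  record; collecting mode returns records plus errors such that rows =
  records + errors.
* The pipeline echoes its full configuration into every run summary, so an
  output directory alone reconstructs the parameterization; reruns are
  byte-identical.
* Stage errors abort with a stage-named message and non-zero exit; logs go
  to stderr only.
* Problem sizes in the test and acceptance runs — 8-fusion plans, 20
  seeded cohorts, 100–200 oracle instances, 600-nt ORF sequences — were
  chosen as the smallest sets that exercise every class/frame/band
  combination and give the brute-force oracles full coverage.

## Known limitations

* Concordance is a reconstruction: whether the original comparison used
  identity alignment or k-mer sharing is not recoverable, and the INTER/
  INTRA/TIC boundary cases follow main-text usage rather than a published
  formal definition.
* Frame classification can in principle misfire on partners sharing an
  8-residue stretch (close paralogs) and on heavily diverged references.
* The breakpoint-to-contig mapping takes the first aligned base at or past
  the junction; on assemblies with an indel exactly at the junction the
  reported junction residue can shift by one.
* Survival analysis is limited to two groups and the log-rank test; no
  Cox modelling, no multi-group comparisons.
* BAM-level coverage extraction is not built in; coverage arrives as
  BED-like per-base tracks computed externally.
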