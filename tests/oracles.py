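"""Independent brute-force oracles used to check the package's algorithms.

Everything here is deliberately naive and kept free of the package's own
implementation paths: a plain-Python tuple-based dynamic program for local
alignment, a literal codon table for translation, exhaustive six-frame
enumeration for ORFs, and exhaustive substring enumeration for peptide
tiling.
"""

from __future__ import annotations

from typing import NamedTuple, Optional

NEG = (-(10**9), 0)
ZERO = (0, 0)


class OracleAlignment(NamedTuple):
    score: int
    identity: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int


def oracle_local_align(
    q: str,
    t: str,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = -3,
    gap_extend: int = -1,
) -> Optional[OracleAlignment]:
    """Affine-gap local alignment maximizing (score, identity)
    lexicographically, with deterministic traceback (diagonal, then vertical
    gap, then horizontal gap; first maximal cell in row-major order).
    A gap of length L costs gap_open + (L-1) * gap_extend.  N never matches.
    """
    m, n = len(q), len(t)
    H = [[ZERO] * (n + 1) for _ in range(m + 1)]
    Ix = [[NEG] * (n + 1) for _ in range(m + 1)]
    Iy = [[NEG] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            is_match = qi == t[j - 1] and qi != "N"
            prev = max(ZERO, H[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            H[i][j] = (
                prev[0] + (match if is_match else mismatch),
                prev[1] + (1 if is_match else 0),
            )
            hx, ix = H[i - 1][j], Ix[i - 1][j]
            Ix[i][j] = max((hx[0] + gap_open, hx[1]), (ix[0] + gap_extend, ix[1]))
            hy, iy = H[i][j - 1], Iy[i][j - 1]
            Iy[i][j] = max((hy[0] + gap_open, hy[1]), (iy[0] + gap_extend, iy[1]))
    best, bi, bj = ZERO, 0, 0
    for i in range(m + 1):
        for j in range(n + 1):
            if H[i][j] > best:
                best, bi, bj = H[i][j], i, j
    if best[0] < 1:
        return None
    # traceback
    i, j, state = bi, bj, "H"
    q_start = q_end = t_start = t_end = None
    while True:
        if state == "H":
            is_match = q[i - 1] == t[j - 1] and q[i - 1] != "N"
            if q_end is None:
                q_end, t_end = i, j
            q_start, t_start = i - 1, j - 1
            need = (
                H[i][j][0] - (match if is_match else mismatch),
                H[i][j][1] - (1 if is_match else 0),
            )
            i, j = i - 1, j - 1
            if need == ZERO:
                break
            if H[i][j] == need:
                state = "H"
            elif Ix[i][j] == need:
                state = "Ix"
            elif Iy[i][j] == need:
                state = "Iy"
            else:
                raise AssertionError("oracle traceback failed")
        elif state == "Ix":
            val = Ix[i][j]
            if (H[i - 1][j][0] + gap_open, H[i - 1][j][1]) == val:
                state = "H"
            i -= 1
        else:
            val = Iy[i][j]
            if (H[i][j - 1][0] + gap_open, H[i][j - 1][1]) == val:
                state = "H"
            j -= 1
    return OracleAlignment(best[0], best[1], q_start, q_end, t_start, t_end)


def oracle_revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[b] for b in reversed(seq))


def oracle_concordance(
    window_seq: str, breakpoint_offset: int, contigs: list[tuple[str, str]]
) -> tuple[float, Optional[str], Optional[str]]:
    """Best junction-covering concordance over contigs and orientations.

    Mirrors the definition: per contig/orientation take the single best
    alignment, require the aligned window span to contain both
    breakpoint-flanking positions, rank by (percent, score), tie-break by
    contig id then forward orientation.  Returns (percent, contig_id,
    orientation).
    """
    bo = breakpoint_offset
    best = None  # (pct, score, contig_id, strand)
    for contig_id, seq in sorted(contigs):
        for strand, target in (("+", seq), ("-", oracle_revcomp(seq))):
            aln = oracle_local_align(window_seq, target)
            if aln is None:
                continue
            if not (aln.q_start <= bo - 1 and aln.q_end >= bo + 1):
                continue
            pct = 100.0 * aln.identity / len(window_seq)
            if best is None or (pct, aln.score) > (best[0], best[1]):
                best = (pct, aln.score, contig_id, strand)
    if best is None:
        return 0.0, None, None
    return best[0], best[2], best[3]


# ---------------------------------------------------------------------------
# Translation

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def oracle_translate(seq: str, frame: int = 0, to_stop: bool = False) -> str:
    sub = seq.upper()[frame:]
    out = []
    for i in range(0, len(sub) - len(sub) % 3, 3):
        codon = sub[i : i + 3]
        aa = "X" if "N" in codon else _CODON_TABLE[codon]
        if to_stop and aa == "*":
            return "".join(out)
        out.append(aa)
    return "".join(out)


# ---------------------------------------------------------------------------
# ORFs

_STOPS = {"TAA", "TAG", "TGA"}


def oracle_orfs(seq: str, min_aa: int) -> set[tuple[str, int, int, str, bool]]:
    """All (strand, plus_start, plus_end, protein, complete) ORFs: every ATG
    paired with the first in-frame stop, or the last full codon if none."""
    out = set()
    length = len(seq)
    for strand in "+-":
        s = seq if strand == "+" else oracle_revcomp(seq)
        for frame in range(3):
            positions = list(range(frame, length - 2, 3))
            for p_idx, pos in enumerate(positions):
                if s[pos : pos + 3] != "ATG":
                    continue
                end = None
                for stop_pos in positions[p_idx:]:
                    if s[stop_pos : stop_pos + 3] in _STOPS:
                        end = stop_pos + 3
                        break
                complete = end is not None
                if end is None:
                    end = frame + 3 * ((length - frame) // 3)
                coding_end = end - 3 if complete else end
                protein = oracle_translate(s[pos:coding_end])
                if len(protein) < min_aa:
                    continue
                if strand == "+":
                    out.add((strand, pos, end, protein, complete))
                else:
                    out.add((strand, length - end, length - pos, protein, complete))
    return out


# ---------------------------------------------------------------------------
# Peptide tiling


def oracle_tiles(
    seq: str, junction_index: int, spanning: bool, lengths=(8, 9, 10, 11)
) -> list[str]:
    """Exhaustive substring enumeration with the novel-content filter."""
    out, seen = [], set()
    for start in range(len(seq)):
        for k in sorted(lengths):
            end = start + k
            if end > len(seq):
                continue
            if end <= junction_index:
                continue
            if spanning and junction_index > 0 and start >= junction_index:
                continue
            pep = seq[start:end]
            if pep not in seen and not (set(pep) - set("ACDEFGHIKLMNPQRSTVWY")):
                seen.add(pep)
                out.append(pep)
    return out
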