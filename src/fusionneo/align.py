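"""Affine-gap local alignment with deterministic identity tie-breaking.

This is the computational core of the junction-concordance comparison: a
fusion caller's junction window is locally aligned against each assembled
contig and the fraction of identically aligned window bases becomes the
concordance score.  Percent identity of the best alignment must therefore be
a well-defined quantity, but co-optimal local alignments under an affine
scheme can differ in their number of matches.  The aligner below resolves
this by maximizing the pair (score, identity) lexicographically in a single
dynamic program: scores and identities are packed into one integer
(``score * SCALE + identity``), so an ordinary maximum implements the
lexicographic rule.  Traceback is deterministic (diagonal, then vertical
gap, then horizontal gap; first maximal cell in row-major order), making the
reported alignment a pure function of its inputs.

Gap costs follow the open/extend convention in which a gap of length L costs
``gap_open + (L - 1) * gap_extend``.  ``N`` never matches anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .types import FusionNeoError

__all__ = ["Scoring", "LocalAlignment", "align_local"]

#: Identity is packed into the low bits; window length must stay below this.
SCALE = 4096
_NEG = -(1 << 40)

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class Scoring:
    """Integer alignment scores.  Defaults favour contiguous identity runs
    around the breakpoint: mismatches cost twice a match and gaps slightly
    more, so spurious junction-crossing alignments score poorly."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -3
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if self.match <= 0 or min(self.mismatch, self.gap_open, self.gap_extend) >= 0:
            raise FusionNeoError("match must be positive and penalties negative")


@dataclass
class LocalAlignment:
    """One local alignment of a query (window) against a target (contig).

    ``pairs`` lists the aligned (query_pos, target_pos, is_match) triples in
    order; spans are 0-based half-open on each sequence.
    """

    score: int
    identity: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    pairs: list[tuple[int, int, bool]] = field(default_factory=list, repr=False)

    @property
    def max_internal_gap(self) -> int:
        worst = 0
        for (q0, t0, _), (q1, t1, _) in zip(self.pairs, self.pairs[1:]):
            worst = max(worst, (q1 - q0 - 1) + (t1 - t0 - 1))
        return worst

    def target_pos_at_or_after(self, query_pos: int) -> Optional[int]:
        """Target coordinate aligned to the first aligned query position at
        or beyond ``query_pos`` (None if the alignment ends before it)."""
        for q, t, _ in self.pairs:
            if q >= query_pos:
                return t
        return None


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_CODE.get(b, 4) for b in seq), dtype=np.int8, count=len(seq))


def align_local(query: str, target: str, scoring: Scoring = Scoring()) -> Optional[LocalAlignment]:
    """Best local alignment of ``query`` against ``target``.

    Returns None when no alignment with at least one match (positive score)
    exists.  The (score, identity) pair is maximized lexicographically and
    the traceback is deterministic, so equal inputs always give equal
    output.
    """
    m, n = len(query), len(target)
    if m == 0 or n == 0:
        return None
    if m >= SCALE:
        raise FusionNeoError(f"query longer than {SCALE - 1} not supported")

    q = _encode(query)
    t = _encode(target)
    match_enc = scoring.match * SCALE + 1
    mismatch_enc = scoring.mismatch * SCALE
    open_enc = scoring.gap_open * SCALE
    ext_enc = scoring.gap_extend * SCALE

    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    Ix = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    Iy = np.full((m + 1, n + 1), _NEG, dtype=np.int64)

    j_idx = np.arange(n, dtype=np.int64)
    for i in range(1, m + 1):
        sub = np.where((t == q[i - 1]) & (q[i - 1] != 4), match_enc, mismatch_enc)
        prev = np.maximum(
            np.maximum(H[i - 1, :-1], Ix[i - 1, :-1]),
            np.maximum(Iy[i - 1, :-1], 0),
        )
        H[i, 1:] = prev + sub
        Ix[i, 1:] = np.maximum(H[i - 1, 1:] + open_enc, Ix[i - 1, 1:] + ext_enc)
        # Horizontal-gap state via prefix-max: Iy[i,j] = ext*(j-1) +
        # max_{k<j} (H[i,k] + open - ext*k).
        g = H[i, :-1] + open_enc - ext_enc * j_idx
        Iy[i, 1:] = np.maximum.accumulate(g) + ext_enc * j_idx

    flat_best = int(np.argmax(H))
    bi, bj = divmod(flat_best, n + 1)
    best_val = int(H[bi, bj])
    if best_val < SCALE:  # no alignment scoring at least one match
        return None

    # Deterministic traceback.
    pairs: list[tuple[int, int, bool]] = []
    i, j, state = bi, bj, "H"
    while True:
        if state == "H":
            is_match = bool(t[j - 1] == q[i - 1] and q[i - 1] != 4)
            pairs.append((i - 1, j - 1, is_match))
            need = int(H[i, j]) - (match_enc if is_match else mismatch_enc)
            i, j = i - 1, j - 1
            if need == 0:
                break
            if H[i, j] == need:
                state = "H"
            elif Ix[i, j] == need:
                state = "Ix"
            elif Iy[i, j] == need:
                state = "Iy"
            else:  # pragma: no cover - DP consistency guard
                raise FusionNeoError("traceback failed: inconsistent DP matrices")
        elif state == "Ix":
            val = int(Ix[i, j])
            if H[i - 1, j] + open_enc == val:
                state = "H"
            i -= 1
        else:  # Iy
            val = int(Iy[i, j])
            if H[i, j - 1] + open_enc == val:
                state = "H"
            j -= 1
    pairs.reverse()

    identity = best_val % SCALE
    score = (best_val - identity) // SCALE
    return LocalAlignment(
        score=score,
        identity=identity,
        q_start=pairs[0][0],
        q_end=pairs[-1][0] + 1,
        t_start=pairs[0][1],
        t_end=pairs[-1][1] + 1,
        pairs=pairs,
    )
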