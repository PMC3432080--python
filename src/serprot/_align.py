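"""Affine-gap global alignment of protein sequences and profiles.

Implements Needleman-Wunsch/Gotoh dynamic programming with an affine gap
model in which a gap run of length L costs ``gap_open + (L - 1) * gap_extend``
(the first gap position pays the opening penalty).  End gaps are penalized,
i.e. the alignment is fully global.  Tie-breaking during traceback is
deterministic: diagonal is preferred over a vertical gap, which is preferred
over a horizontal gap.

The row recurrences are vectorized with numpy.  The horizontal-gap state is
computed with a running-maximum scan, which is exact because re-opening a
horizontal gap directly out of another horizontal gap is never optimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

_NEG_INF = -1e30


def blosum62_matrix() -> np.ndarray:
    """20x20 BLOSUM62 scores ordered by :data:`AMINO_ACIDS`."""
    blosum = substitution_matrices.load("BLOSUM62")
    m = np.empty((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            m[i, j] = blosum[a, b]
    return m


_BLOSUM62 = blosum62_matrix()


def encode_protein(seq: str) -> np.ndarray:
    """Map a protein string to indices into :data:`AMINO_ACIDS`.

    Raises ``ValueError`` on symbols outside the 20 standard residues.
    """
    try:
        return np.array([_AA_INDEX[c] for c in seq.upper()], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"unknown residue symbol {exc.args[0]!r}") from None


@dataclass(frozen=True)
class AlignmentMap:
    """Residue-level pairing of a query with a reference.

    ``pairs`` is an ordered list of ``(query_index, reference_index)`` tuples
    where exactly one member may be ``None`` (a gap).  Indices are 0-based and
    strictly increasing on each side.
    """

    pairs: list[tuple[int | None, int | None]]
    score: float

    def query_at_reference(self, ref_index: int) -> int | None:
        """Query index aligned to ``ref_index`` (None if a gap)."""
        for q, r in self.pairs:
            if r == ref_index:
                return q
        raise IndexError(f"reference index {ref_index} outside alignment")


def _dp_fill(sub: np.ndarray, gap_open: float, gap_extend: float):
    """Fill best/vertical/horizontal score matrices for an (m x n) score grid."""
    if gap_open < gap_extend:
        raise ValueError("gap_open must be >= gap_extend")
    m, n = sub.shape
    best = np.full((m + 1, n + 1), _NEG_INF)
    vert = np.full((m + 1, n + 1), _NEG_INF)
    horiz = np.full((m + 1, n + 1), _NEG_INF)
    best[0, 0] = 0.0
    if n:
        horiz[0, 1:] = -gap_open - gap_extend * np.arange(n)
        best[0, 1:] = horiz[0, 1:]
    ext_ramp = gap_extend * np.arange(n + 1)
    for i in range(1, m + 1):
        vert[i, :] = np.maximum(best[i - 1, :] - gap_open, vert[i - 1, :] - gap_extend)
        diag = np.full(n + 1, _NEG_INF)
        diag[1:] = best[i - 1, :-1] + sub[i - 1, :]
        # horizontal gaps open only from a diagonal/vertical (or column-0) state;
        # opening out of a horizontal gap is never optimal under this cost model
        anchor = np.maximum(diag, vert[i, :])
        anchor[0] = vert[i, 0]
        running = np.maximum.accumulate(anchor + ext_ramp)
        horiz[i, 1:] = running[:-1] - gap_open - gap_extend * np.arange(1, n + 1) + gap_extend
        best[i, :] = np.maximum(np.maximum(diag, vert[i, :]), horiz[i, :])
        best[i, 0] = vert[i, 0]
    return best, vert, horiz


def _traceback(sub, best, vert, horiz, gap_open, gap_extend):
    m, n = sub.shape
    pairs: list[tuple[int | None, int | None]] = []
    i, j = m, n

    def diag_val(i, j):
        return best[i - 1, j - 1] + sub[i - 1, j - 1] if i > 0 and j > 0 else _NEG_INF

    def anchor_val(i, j):
        # states a horizontal gap may open from: diagonal, vertical, or origin column
        if j == 0:
            return best[i, 0]
        return max(diag_val(i, j), vert[i, j] if i > 0 else _NEG_INF)

    state = "best"
    while i > 0 or j > 0:
        if state == "best":
            if i > 0 and j > 0 and best[i, j] == diag_val(i, j):
                state = "diag"
            elif i > 0 and best[i, j] == vert[i, j]:
                state = "vert"
            else:
                state = "horiz"
        elif state == "diag":
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
            state = "best"
        elif state == "vert":
            pairs.append((i - 1, None))
            closes = True if i == 1 else best[i - 1, j] - gap_open >= vert[i - 1, j] - gap_extend
            i -= 1
            state = "best" if closes else "vert"
        else:  # horiz
            pairs.append((None, j - 1))
            av = anchor_val(i, j - 1)
            if horiz[i, j] == av - gap_open:  # run opened at column j-1 (closure preferred on ties)
                j -= 1
                if j == 0:
                    state = "best"
                elif av == diag_val(i, j):
                    state = "diag"
                else:
                    state = "vert"
            else:
                j -= 1
                state = "horiz"
    pairs.reverse()
    return pairs


def global_align(
    query: str,
    reference: str,
    *,
    matrix: np.ndarray | None = None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> AlignmentMap:
    """Optimal global alignment of two protein sequences.

    Parameters follow the EMBOSS-style convention: BLOSUM62 scores with a
    penalty of ``gap_open`` for the first position of a gap run and
    ``gap_extend`` for each further position.
    """
    if not query or not reference:
        raise ValueError("sequences must be non-empty")
    mat = _BLOSUM62 if matrix is None else matrix
    qi = encode_protein(query)
    ri = encode_protein(reference)
    sub = mat[np.ix_(qi, ri)]
    best, vert, horiz = _dp_fill(sub, gap_open, gap_extend)
    pairs = _traceback(sub, best, vert, horiz, gap_open, gap_extend)
    return AlignmentMap(pairs=pairs, score=float(best[len(qi), len(ri)]))


def self_score(seq: str, *, matrix: np.ndarray | None = None) -> float:
    """Score of a sequence aligned gap-free to itself (normalization anchor)."""
    mat = _BLOSUM62 if matrix is None else matrix
    idx = encode_protein(seq)
    return float(mat[idx, idx].sum())


# ---------------------------------------------------------------------------
# profile-profile alignment (used by the progressive MSA)
# ---------------------------------------------------------------------------


def _profile_counts(rows: list[str]) -> np.ndarray:
    """Per-column residue frequency matrix (ncol x 20); gaps contribute zero."""
    ncol = len(rows[0])
    counts = np.zeros((ncol, 20))
    for row in rows:
        for j, c in enumerate(row):
            if c != "-":
                counts[j, _AA_INDEX[c]] += 1.0
    return counts / len(rows)


def align_profiles(
    rows_a: list[str],
    rows_b: list[str],
    *,
    matrix: np.ndarray | None = None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> tuple[list[str], list[str], float]:
    """Align two gapped blocks column-wise; returns re-gapped blocks + score.

    Column-pair score is the expected BLOSUM score over the two columns'
    residue frequencies (gap fractions score zero).
    """
    mat = _BLOSUM62 if matrix is None else matrix
    fa = _profile_counts(rows_a)
    fb = _profile_counts(rows_b)
    sub = fa @ mat @ fb.T
    best, vert, horiz = _dp_fill(sub, gap_open, gap_extend)
    pairs = _traceback(sub, best, vert, horiz, gap_open, gap_extend)
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    for qa, qb in pairs:
        for k, row in enumerate(rows_a):
            out_a[k].append(row[qa] if qa is not None else "-")
        for k, row in enumerate(rows_b):
            out_b[k].append(row[qb] if qb is not None else "-")
    score = float(best[len(fa), len(fb)])
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b], score
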