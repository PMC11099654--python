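"""Shared alignment machinery: substitution matrix, affine-gap dynamic
programming kernel, and profile-column scoring.

Every aligner in the toolkit (pairwise structural, progressive subset,
profile merge, loop re-packing) reduces to one primitive: global
Needleman-Wunsch/Gotoh alignment over a precomputed position-score
matrix ``S`` with affine gap penalties.  The kernel is JIT-compiled with
numba when available and falls back to pure Python otherwise.

Tie-breaking is fixed (diagonal, then gap-in-A, then gap-in-B) so every
alignment in the package is deterministic.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .records import ALPHABET, GAP, Msa

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    def _njit(*args, **kwargs):
        def wrap(f):
            return f
        if args and callable(args[0]):
            return args[0]
        return wrap

_AA_INDEX = {c: i for i, c in enumerate(ALPHABET)}
SS_STATES = "HEC"
_SS_INDEX = {c: i for i, c in enumerate(SS_STATES)}

# alignment edit operations emitted by the kernel's traceback
OP_MATCH = 0   # consume one position of A and one of B
OP_GAP_A = 1   # gap in A, consume one position of B
OP_GAP_B = 2   # gap in B, consume one position of A


def encode_sequence(residues: str) -> np.ndarray:
    """Map a residue string to integer indices over the 21-letter alphabet."""
    try:
        return np.array([_AA_INDEX[c] for c in residues], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"residue {exc} outside alphabet {ALPHABET!r}") from None


def encode_ss(states: str) -> np.ndarray:
    return np.array([_SS_INDEX[c] for c in states], dtype=np.int64)


@lru_cache(maxsize=None)
def blosum62(scale: float = 0.25) -> np.ndarray:
    """BLOSUM62 as a (21, 21) float matrix over ``ALPHABET``, times ``scale``."""
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")
    out = np.zeros((len(ALPHABET), len(ALPHABET)))
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            out[i, j] = m[a, b]
    return out * scale


def _affine_align_impl(S, gap_open, gap_ext):
    n, m = S.shape
    NEG = -1e17
    H = np.empty((n + 1, m + 1))
    E = np.empty((n + 1, m + 1))
    F = np.empty((n + 1, m + 1))
    H[0, 0] = 0.0
    E[0, 0] = NEG
    F[0, 0] = NEG
    for j in range(1, m + 1):
        E[0, j] = gap_open + (j - 1) * gap_ext
        H[0, j] = E[0, j]
        F[0, j] = NEG
    for i in range(1, n + 1):
        F[i, 0] = gap_open + (i - 1) * gap_ext
        H[i, 0] = F[i, 0]
        E[i, 0] = NEG
        for j in range(1, m + 1):
            e = H[i, j - 1] + gap_open
            e2 = E[i, j - 1] + gap_ext
            if e2 > e:
                e = e2
            f = H[i - 1, j] + gap_open
            f2 = F[i - 1, j] + gap_ext
            if f2 > f:
                f = f2
            h = H[i - 1, j - 1] + S[i - 1, j - 1]
            if e > h:
                h = e
            if f > h:
                h = f
            E[i, j] = e
            F[i, j] = f
            H[i, j] = h
    # traceback; ties resolved diagonal > gap-in-A > gap-in-B
    ops = np.empty(n + m, dtype=np.int8)
    k = 0
    i, j = n, m
    state = 0  # 0 in H, 1 in E (gap in A), 2 in F (gap in B)
    while i > 0 or j > 0:
        if state == 0:
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + S[i - 1, j - 1]:
                ops[k] = 0
                k += 1
                i -= 1
                j -= 1
            elif j > 0 and H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            from_h = E[i, j] == H[i, j - 1] + gap_open
            ops[k] = 1
            k += 1
            j -= 1
            if from_h:
                state = 0
        else:
            from_h = F[i, j] == H[i - 1, j] + gap_open
            ops[k] = 2
            k += 1
            i -= 1
            if from_h:
                state = 0
    return H[n, m], ops[:k][::-1].copy()


affine_align = _njit(cache=True)(_affine_align_impl)


def align_score_matrix(S: np.ndarray, gap_open: float, gap_ext: float):
    """Globally align two position sets given their score matrix.

    Returns ``(score, ops)`` where ``ops`` is the edit script over
    ``OP_MATCH``/``OP_GAP_A``/``OP_GAP_B``.  A gap of length L costs
    ``gap_open + (L - 1) * gap_ext``.
    """
    S = np.ascontiguousarray(S, dtype=np.float64)
    n, m = S.shape
    if n == 0:
        return 0.0, np.full(m, OP_GAP_A, dtype=np.int8)
    if m == 0:
        return 0.0, np.full(n, OP_GAP_B, dtype=np.int8)
    return affine_align(S, float(gap_open), float(gap_ext))


def ops_to_pairs(ops: np.ndarray) -> list[tuple[int, int]]:
    """Aligned (i, j) index pairs implied by an edit script."""
    pairs = []
    i = j = 0
    for op in ops:
        if op == OP_MATCH:
            pairs.append((i, j))
            i += 1
            j += 1
        elif op == OP_GAP_A:
            j += 1
        else:
            i += 1
    return pairs


def project_rows(rows_a: list[str], rows_b: list[str], ops: np.ndarray) -> tuple[list[str], list[str]]:
    """Expand two groups of gapped rows along an edit script.

    ``rows_a`` are columns indexed by the A coordinate of ``ops`` and
    ``rows_b`` by the B coordinate.  Wherever the script passes a gap op
    a full-height gap column is inserted into the corresponding group, so
    each group's internal column structure is preserved exactly.
    """
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    i = j = 0
    for op in ops:
        if op == OP_MATCH:
            for r, s in zip(out_a, rows_a):
                r.append(s[i])
            for r, s in zip(out_b, rows_b):
                r.append(s[j])
            i += 1
            j += 1
        elif op == OP_GAP_A:
            for r in out_a:
                r.append(GAP)
            for r, s in zip(out_b, rows_b):
                r.append(s[j])
            j += 1
        else:
            for r, s in zip(out_a, rows_a):
                r.append(s[i])
            for r in out_b:
                r.append(GAP)
            i += 1
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


# -- profile columns ----------------------------------------------------

def profile_counts(msa: Msa) -> tuple[np.ndarray, np.ndarray]:
    """Per-column residue counts.

    Returns ``(counts, nongap)``: counts is (width, 21) over ``ALPHABET``
    and nongap the per-column count of residue-bearing rows.
    """
    w = msa.width
    counts = np.zeros((w, len(ALPHABET)))
    for _, row in msa.rows:
        for j, c in enumerate(row):
            if c != GAP:
                counts[j, _AA_INDEX[c]] += 1.0
    nongap = counts.sum(axis=1)
    return counts, nongap


def ss_profile_counts(ss_rows: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-column secondary-structure state counts over gapped SS rows.

    Gap characters (rows without structure use all-gap SS rows) are
    ignored, mirroring :func:`profile_counts`.
    """
    if not ss_rows:
        return np.zeros((0, 3)), np.zeros(0)
    w = len(ss_rows[0])
    counts = np.zeros((w, 3))
    for row in ss_rows:
        for j, c in enumerate(row):
            if c in _SS_INDEX:
                counts[j, _SS_INDEX[c]] += 1.0
    return counts, counts.sum(axis=1)


def profile_score_matrix(
    counts_a: np.ndarray,
    nongap_a: np.ndarray,
    counts_b: np.ndarray,
    nongap_b: np.ndarray,
    substitution: np.ndarray,
) -> np.ndarray:
    """Mean substitution score over cross-profile non-gap residue pairs.

    Column pairs with no residue-residue contact score 0.
    """
    num = counts_a @ substitution @ counts_b.T
    den = np.outer(nongap_a, nongap_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return out
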