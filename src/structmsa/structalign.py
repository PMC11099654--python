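"""Structure-aware alignment of a subset of sequences.

The engine aligns pairs by iterating between (a) an affine-gap dynamic
program whose position scores combine substitution similarity, 3-state
secondary-structure agreement and, once a superposition exists, a
TM-score-like proximity term, and (b) a Kabsch superposition on the
currently aligned CA pairs.  Subsets larger than two are aligned
progressively along an average-linkage guide tree built from the
pairwise structural scores.

Unresolved positions contribute sequence and secondary-structure terms
only; the proximity term requires coordinates on both sides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import cdist

from .records import GAP, ChainStructure, Msa, SequenceRecord, SsString
from .scoring import (
    OP_GAP_A,
    OP_GAP_B,
    OP_MATCH,
    align_score_matrix,
    blosum62,
    encode_sequence,
    encode_ss,
    ops_to_pairs,
    profile_counts,
    profile_score_matrix,
    project_rows,
    ss_profile_counts,
)

logger = logging.getLogger(__name__)


@dataclass
class AlignParams:
    """Tunable scores of the structural aligner.

    ``w_seq`` scales BLOSUM62/4, ``w_ss`` the secondary-structure
    agreement bonus, ``w_d`` the superposition proximity term
    ``1 / (1 + (d/d0)^2)`` with ``d0`` in Å.
    """

    w_seq: float = 1.0
    w_ss: float = 2.0
    w_d: float = 4.0
    d0: float = 5.0
    gap_open: float = -8.0
    gap_ext: float = -0.5
    max_iterations: int = 10
    #: weight of the column-centroid proximity term in profile merges;
    #: higher than w_d because the centroid average has far lower noise
    #: than a single residue pair and must outvote per-row artefacts
    w_d_profile: float = 8.0


@dataclass
class SuperpositionResult:
    """Optimal rigid-body fit of one CA set onto another."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class PairwiseAlignment:
    id_a: str
    id_b: str
    pairs: list[tuple[int, int]]
    score: float
    rmsd: float
    ops: np.ndarray = field(repr=False, default=None)


class UnalignablePairError(ValueError):
    """No positively scoring residue pairing exists between two chains."""


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of paired CA sets (B onto A).

    Reflections are excluded, so the rotation is always proper.  At
    least three non-collinear pairs are required.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("paired (n, 3) coordinate arrays required")
    if A.shape[0] < 3:
        raise ValueError("superposition requires at least 3 paired positions")
    ca = A.mean(axis=0)
    cb = B.mean(axis=0)
    H = (B - cb).T @ (A - ca)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    moved = B @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - A) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def _pair_score_matrix(
    res_a: np.ndarray,
    res_b: np.ndarray,
    ss_a: np.ndarray,
    ss_b: np.ndarray,
    params: AlignParams,
    dist: Optional[np.ndarray] = None,
) -> np.ndarray:
    B = blosum62()
    S = params.w_seq * B[np.ix_(res_a, res_b)]
    S = S + params.w_ss * (ss_a[:, None] == ss_b[None, :])
    if dist is not None:
        prox = np.where(
            np.isfinite(dist), params.w_d / (1.0 + (dist / params.d0) ** 2), 0.0
        )
        S = S + prox
    return S


def pairwise_struct_align(
    rec_a: SequenceRecord,
    chain_a: ChainStructure,
    ss_a: SsString,
    rec_b: SequenceRecord,
    chain_b: ChainStructure,
    ss_b: SsString,
    params: AlignParams | None = None,
) -> PairwiseAlignment:
    """Iterative structure-aware pairwise alignment.

    Seeds with sequence + secondary-structure scores, then alternates
    superposition on the aligned CA pairs with realignment including the
    proximity term, until the aligned pair set is stable (at most
    ``params.max_iterations`` rounds).
    """
    params = params or AlignParams()
    res_a = encode_sequence(rec_a.residues)
    res_b = encode_sequence(rec_b.residues)
    s_a = encode_ss(ss_a.states)
    s_b = encode_ss(ss_b.states)
    ca_a = chain_a.ca_full()
    ca_b = chain_b.ca_full()

    S0 = _pair_score_matrix(res_a, res_b, s_a, s_b, params)
    if np.all(S0 <= 0):
        raise UnalignablePairError(f"unalignable pair {rec_a.id} / {rec_b.id}")

    def refine(pairs):
        """Alternate superposition and realignment until the pair set is stable."""
        score, ops = -np.inf, None
        rmsd = float("nan")
        for _ in range(params.max_iterations):
            resolved = [
                (i, j)
                for i, j in pairs
                if np.isfinite(ca_a[i]).all() and np.isfinite(ca_b[j]).all()
            ]
            if len(resolved) < 3:
                break
            sup = kabsch_superpose(
                ca_a[[i for i, _ in resolved]], ca_b[[j for _, j in resolved]]
            )
            rmsd = sup.rmsd
            moved_b = ca_b @ sup.rotation.T + sup.translation
            dist = cdist(ca_a, moved_b)  # NaN propagates for unresolved
            S = _pair_score_matrix(res_a, res_b, s_a, s_b, params, dist=dist)
            score, ops = align_score_matrix(S, params.gap_open, params.gap_ext)
            new_pairs = ops_to_pairs(ops)
            if new_pairs == pairs:
                break
            pairs = new_pairs
        return pairs, ops, score, rmsd

    # Multi-start: the sequence/SS seed plus gapless threadings at a
    # grid of offsets.  A single seed can lock the iteration into a
    # register-shifted local optimum (the wrong superposition keeps
    # endorsing the wrong alignment); refining from several rigid
    # threadings and keeping the best-scoring result avoids that trap.
    score0, ops0 = align_score_matrix(S0, params.gap_open, params.gap_ext)
    seed_pairs = ops_to_pairs(ops0)
    best = (seed_pairs, ops0, score0, float("nan"))
    candidates = [seed_pairs]
    la, lb = len(res_a), len(res_b)
    for off in range(-16, 17, 4):
        thread = [
            (i, i + off)
            for i in range(max(0, -off), min(la, lb - off))
            if np.isfinite(ca_a[i]).all() and np.isfinite(ca_b[i + off]).all()
        ]
        if len(thread) >= 20:
            candidates.append(thread)
    for cand in candidates:
        pairs, ops, score, rmsd = refine(cand)
        if ops is not None and score > best[2] + 1e-9:
            best = (pairs, ops, score, rmsd)
    pairs, ops, score, rmsd = best
    return PairwiseAlignment(
        id_a=rec_a.id, id_b=rec_b.id, pairs=pairs, score=float(score), rmsd=rmsd, ops=ops
    )


def pairwise_to_msa(rec_a: SequenceRecord, rec_b: SequenceRecord, aln: PairwiseAlignment) -> Msa:
    """Project a pairwise alignment to a 2-row gapped alignment."""
    rows_a, rows_b = project_rows([rec_a.residues], [rec_b.residues], aln.ops)
    return Msa([(rec_a.id, rows_a[0]), (rec_b.id, rows_b[0])])


@dataclass
class _Profile:
    """A growing sub-alignment with per-column structural centroids.

    ``coord_sum``/``coord_n`` accumulate, per column, the sum and count
    of resolved member CA coordinates expressed in the subset's common
    frame, so merges can keep using a superposition proximity term."""

    msa: Msa
    ss_rows: list[str]           # gapped SS rows parallel to msa rows
    coord_sum: np.ndarray        # (width, 3)
    coord_n: np.ndarray          # (width,)


def _expand_columns(values: np.ndarray, which: int, ops: np.ndarray) -> np.ndarray:
    """Spread per-column values along an edit script, zero at gap columns."""
    out_len = len(ops)
    out = np.zeros((out_len,) + values.shape[1:], dtype=values.dtype)
    src = 0
    consume = (OP_MATCH, OP_GAP_B) if which == 0 else (OP_MATCH, OP_GAP_A)
    for k, op in enumerate(ops):
        if op in consume:
            out[k] = values[src]
            src += 1
    return out


def _merge_profiles(p_a: _Profile, p_b: _Profile, params: AlignParams) -> _Profile:
    counts_a, nongap_a = profile_counts(p_a.msa)
    counts_b, nongap_b = profile_counts(p_b.msa)
    S = params.w_seq * profile_score_matrix(counts_a, nongap_a, counts_b, nongap_b, blosum62())
    ssc_a, ssn_a = ss_profile_counts(p_a.ss_rows)
    ssc_b, ssn_b = ss_profile_counts(p_b.ss_rows)
    num = ssc_a @ ssc_b.T
    den = np.outer(ssn_a, ssn_b)
    S = S + params.w_ss * np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    # structural proximity between column centroids in the common frame,
    # weighted by the fraction of resolved rows on each side
    n_a, n_b = p_a.msa.n_rows, p_b.msa.n_rows
    has_a = p_a.coord_n > 0
    has_b = p_b.coord_n > 0
    if has_a.any() and has_b.any():
        cent_a = np.where(has_a[:, None], p_a.coord_sum / np.maximum(p_a.coord_n, 1)[:, None], 0.0)
        cent_b = np.where(has_b[:, None], p_b.coord_sum / np.maximum(p_b.coord_n, 1)[:, None], 0.0)
        dist = cdist(cent_a, cent_b)
        prox = params.w_d_profile / (1.0 + (dist / params.d0) ** 2)
        weight = np.outer(p_a.coord_n / n_a, p_b.coord_n / n_b)
        S = S + prox * weight
    _, ops = align_score_matrix(S, params.gap_open, params.gap_ext)
    seq_rows_a = [row for _, row in p_a.msa.rows]
    seq_rows_b = [row for _, row in p_b.msa.rows]
    out_a, out_b = project_rows(seq_rows_a, seq_rows_b, ops)
    ss_a2, ss_b2 = project_rows(p_a.ss_rows, p_b.ss_rows, ops)
    ids = p_a.msa.ids + p_b.msa.ids
    coord_sum = _expand_columns(p_a.coord_sum, 0, ops) + _expand_columns(p_b.coord_sum, 1, ops)
    coord_n = _expand_columns(p_a.coord_n, 0, ops) + _expand_columns(p_b.coord_n, 1, ops)
    return _Profile(Msa(list(zip(ids, out_a + out_b))), ss_a2 + ss_b2, coord_sum, coord_n)


def _column_coords(row: str, ca_full: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column CA sums/counts for one gapped row."""
    w = len(row)
    csum = np.zeros((w, 3))
    cn = np.zeros(w)
    pos = 0
    for j, c in enumerate(row):
        if c != GAP:
            xyz = ca_full[pos]
            if np.isfinite(xyz).all():
                csum[j] = xyz
                cn[j] = 1.0
            pos += 1
    return csum, cn


def align_subset(
    members: Sequence[tuple[SequenceRecord, ChainStructure, SsString]],
    params: AlignParams | None = None,
) -> Msa:
    """Progressive structure-aware alignment of one subset.

    Pairwise structural alignments define an average-linkage guide
    tree; profiles are merged bottom-up with combined substitution and
    secondary-structure column scores.  Deterministic: input order does
    not affect the result beyond row order, which follows the guide
    tree over id-sorted members.
    """
    params = params or AlignParams()
    if not members:
        raise ValueError("empty subset")
    members = sorted(members, key=lambda m: m[0].id)
    if len(members) == 1:
        import warnings

        rec = members[0][0]
        warnings.warn(f"singleton subset {rec.id} returned as a 1-row alignment")
        return Msa([(rec.id, rec.residues)])
    if len(members) == 2:
        (ra, ca, sa), (rb, cb, sb) = members
        aln = pairwise_struct_align(ra, ca, sa, rb, cb, sb, params)
        return pairwise_to_msa(ra, rb, aln)

    n = len(members)
    sim = np.zeros((n, n))
    aln_cache: dict[tuple[int, int], PairwiseAlignment] = {}
    for i in range(n):
        for j in range(i + 1, n):
            (ra, ca, sa), (rb, cb, sb) = members[i], members[j]
            aln = pairwise_struct_align(ra, ca, sa, rb, cb, sb, params)
            aln_cache[(i, j)] = aln
            sim[i, j] = sim[j, i] = aln.score / max(
                1, min(len(ra.residues), len(rb.residues))
            )
    # similarities -> non-negative distances for average linkage
    dmax = sim.max()
    condensed = [dmax - sim[i, j] for i in range(n) for j in range(i + 1, n)]
    tree = to_tree(linkage(np.asarray(condensed), method="average"))

    # express every structure in the frame of the first member, so the
    # proximity term stays meaningful throughout the progressive merge
    frames: list[np.ndarray] = []
    ref_ca = members[0][1].ca_full()
    frames.append(ref_ca)
    for k in range(1, n):
        ca_k = members[k][1].ca_full()
        aln = aln_cache[(0, k)]
        resolved = [
            (i, j)
            for i, j in aln.pairs
            if np.isfinite(ref_ca[i]).all() and np.isfinite(ca_k[j]).all()
        ]
        if len(resolved) >= 3:
            sup = kabsch_superpose(
                ref_ca[[i for i, _ in resolved]], ca_k[[j for _, j in resolved]]
            )
            frames.append(ca_k @ sup.rotation.T + sup.translation)
        else:
            frames.append(ca_k)

    def leaf_profile(k: int) -> _Profile:
        rec, chain, ss = members[k]
        csum, cn = _column_coords(rec.residues, frames[k])
        return _Profile(Msa([(rec.id, rec.residues)]), [ss.states], csum, cn)

    def build(node) -> _Profile:
        if node.is_leaf():
            return leaf_profile(node.id)
        return _merge_profiles(build(node.left), build(node.right), params)

    profile = build(tree)
    return profile.msa.drop_all_gap_columns()


def subset_ss_rows(msa: Msa, ss_map: dict[str, SsString]) -> list[str]:
    """Gapped SS rows parallel to an alignment's rows.

    Rows without secondary structure get all-gap SS rows."""
    out = []
    for seq_id, row in msa.rows:
        ss = ss_map.get(seq_id)
        if ss is None:
            out.append(GAP * len(row))
            continue
        it = iter(ss.states)
        out.append("".join(next(it) if c != GAP else GAP for c in row))
    return out
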