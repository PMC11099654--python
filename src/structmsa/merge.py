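"""Shape-preserving combination of subset alignments.

Sub-alignments are merged by a profile-profile dynamic program whose
only permitted edit is the insertion of full-height gap columns: the
internal column structure of every input alignment survives the merge
exactly.  Formally, restricting the merged alignment to one input's
rows and deleting the columns that are all-gap in that restriction
reproduces the input bit-for-bit.  Orphan and structureless sequences
are then aligned individually to the growing alignment under the same
contract.

Column pairs are scored by the mean BLOSUM62/4 value over non-gap
residue pairs; when secondary structure and/or common-frame CA
coordinates are supplied for the rows, a state-agreement bonus and a
superposition proximity term are added with the same weights the
subset aligner uses -- at the low inter-subset identities this
pipeline targets, sequence information alone cannot hold the register
between sub-alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .records import GAP, Msa, SequenceRecord, SsString
from .scoring import (
    align_score_matrix,
    blosum62,
    profile_counts,
    profile_score_matrix,
    project_rows,
    ss_profile_counts,
)


@dataclass
class MergeParams:
    """Scoring of the shape-preserving merge.

    ``match_offset`` is subtracted from every column-pair score when
    secondary-structure or coordinate evidence is supplied: a pair of
    columns is then only aligned when its combined evidence clears this
    baseline, otherwise the merge prefers parallel gap columns --
    forcing dissimilar loop columns together would assert homology the
    data do not support, and the squeeze step later re-packs what is
    left staggered.  Pure sequence merges (no SS, no coordinates) use
    the raw log-odds scores with no offset.
    """

    gap_open: float = -4.0
    gap_ext: float = -0.5
    w_seq: float = 1.0
    w_ss: float = 2.0
    w_d: float = 8.0
    d0: float = 5.0
    match_offset: float = 3.0


@dataclass
class MergePlan:
    """What goes into the final alignment, and in which roles."""

    subset_msas: list[Msa]
    orphans: list[SequenceRecord] = field(default_factory=list)
    structureless: list[SequenceRecord] = field(default_factory=list)

    def all_ids(self) -> list[str]:
        ids = [i for m in self.subset_msas for i in m.ids]
        ids += [r.id for r in self.orphans] + [r.id for r in self.structureless]
        return ids

    def validate(self) -> None:
        ids = self.all_ids()
        if len(set(ids)) != len(ids):
            raise ValueError("merge plan assigns some sequence to more than one role")
        if not ids:
            raise ValueError("empty merge plan")


def _gapped_ss_rows(msa: Msa, ss_map: Mapping[str, SsString]) -> list[str]:
    rows = []
    for seq_id, row in msa.rows:
        ss = ss_map.get(seq_id)
        if ss is None:
            rows.append(GAP * len(row))
            continue
        it = iter(ss.states)
        rows.append("".join(next(it) if c != GAP else GAP for c in row))
    return rows


def _column_centroids(msa: Msa, frame_coords: Mapping[str, np.ndarray]):
    """Per-column CA centroid sums/counts over rows with frame coordinates."""
    w = msa.width
    csum = np.zeros((w, 3))
    cn = np.zeros(w)
    for seq_id, row in msa.rows:
        coords = frame_coords.get(seq_id)
        if coords is None:
            continue
        pos = 0
        for j, c in enumerate(row):
            if c != GAP:
                xyz = coords[pos]
                if np.isfinite(xyz).all():
                    csum[j] += xyz
                    cn[j] += 1.0
                pos += 1
    return csum, cn


def _merge_score_matrix(
    msa_a: Msa,
    msa_b: Msa,
    params: MergeParams,
    ss_map: Optional[Mapping[str, SsString]],
    frame_coords: Optional[Mapping[str, np.ndarray]],
) -> np.ndarray:
    counts_a, nongap_a = profile_counts(msa_a)
    counts_b, nongap_b = profile_counts(msa_b)
    S = params.w_seq * profile_score_matrix(counts_a, nongap_a, counts_b, nongap_b, blosum62())
    if ss_map:
        ssc_a, ssn_a = ss_profile_counts(_gapped_ss_rows(msa_a, ss_map))
        ssc_b, ssn_b = ss_profile_counts(_gapped_ss_rows(msa_b, ss_map))
        # only helix/helix and strand/strand agreement counts: coil is
        # the default state and coil-coil pairs carry no register signal
        num = ssc_a[:, :2] @ ssc_b[:, :2].T
        den = np.outer(ssn_a, ssn_b)
        S = S + params.w_ss * np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    if frame_coords:
        csum_a, cn_a = _column_centroids(msa_a, frame_coords)
        csum_b, cn_b = _column_centroids(msa_b, frame_coords)
        has_a, has_b = cn_a > 0, cn_b > 0
        if has_a.any() and has_b.any():
            cent_a = csum_a / np.maximum(cn_a, 1)[:, None]
            cent_b = csum_b / np.maximum(cn_b, 1)[:, None]
            dist = cdist(cent_a, cent_b)
            prox = params.w_d / (1.0 + (dist / params.d0) ** 2)
            weight = np.outer(
                np.where(has_a, cn_a / msa_a.n_rows, 0.0),
                np.where(has_b, cn_b / msa_b.n_rows, 0.0),
            )
            S = S + prox * weight
    if ss_map or frame_coords:
        S = S - params.match_offset
    return S


def merge_two(
    msa_a: Msa,
    msa_b: Msa,
    params: MergeParams | None = None,
    ss_map: Optional[Mapping[str, SsString]] = None,
    frame_coords: Optional[Mapping[str, np.ndarray]] = None,
) -> Msa:
    """Merge two alignments by inserting full-height gap columns only."""
    params = params or MergeParams()
    if msa_a.n_rows == 0:
        return Msa(msa_b.rows)
    if msa_b.n_rows == 0:
        return Msa(msa_a.rows)
    overlap = set(msa_a.ids) & set(msa_b.ids)
    if overlap:
        raise ValueError(f"cannot merge alignments sharing rows: {sorted(overlap)}")
    S = _merge_score_matrix(msa_a, msa_b, params, ss_map, frame_coords)
    _, ops = align_score_matrix(S, params.gap_open, params.gap_ext)
    rows_a = [row for _, row in msa_a.rows]
    rows_b = [row for _, row in msa_b.rows]
    out_a, out_b = project_rows(rows_a, rows_b, ops)
    return Msa(list(zip(msa_a.ids + msa_b.ids, out_a + out_b)))


def insert_sequence(
    msa: Msa,
    record: SequenceRecord,
    params: MergeParams | None = None,
    ss_map: Optional[Mapping[str, SsString]] = None,
    frame_coords: Optional[Mapping[str, np.ndarray]] = None,
) -> Msa:
    """Align one ungapped sequence to an alignment (sequence-to-profile)."""
    return merge_two(
        msa, Msa([(record.id, record.residues)]), params, ss_map, frame_coords
    )


def merge_all(
    plan: MergePlan,
    params: MergeParams | None = None,
    ss_map: Optional[Mapping[str, SsString]] = None,
    frame_coords: Optional[Mapping[str, np.ndarray]] = None,
) -> Msa:
    """Merge all subsets progressively, then insert the stragglers.

    Subsets are merged largest-first (ties by the id of their first
    row); orphans are inserted next, then structureless sequences, each
    individually and in id order.  All-gap columns are dropped from the
    result.
    """
    params = params or MergeParams()
    plan.validate()
    subsets = sorted(plan.subset_msas, key=lambda m: (-m.n_rows, m.ids[0] if m.ids else ""))
    if not subsets:
        raise ValueError("merge plan contains no subset alignments")
    current = subsets[0]
    for nxt in subsets[1:]:
        current = merge_two(current, nxt, params, ss_map, frame_coords)
    for rec in sorted(plan.orphans, key=lambda r: r.id):
        current = insert_sequence(current, rec, params, ss_map, frame_coords)
    for rec in sorted(plan.structureless, key=lambda r: r.id):
        current = insert_sequence(current, rec, params, ss_map, frame_coords)
    return current.drop_all_gap_columns()


def check_shape_preserved(merged: Msa, original: Msa) -> bool:
    """Does the merged alignment embed ``original`` unchanged?

    True iff restricting the merged rows to the original's ids and
    removing the columns that are all-gap in that restriction
    reproduces the original exactly (same row order as ``original``).
    """
    sub = merged.restrict(original.ids).reorder(original.ids)
    return sub.drop_all_gap_columns() == original.drop_all_gap_columns()


def common_frame_coords(
    members: Sequence[tuple[SequenceRecord, "object", SsString]],
) -> dict[str, np.ndarray]:
    """Superpose every structure onto the first member's frame.

    Members are (record, ChainStructure, SsString) triples; the
    returned map holds full-length CA coordinate arrays (NaN where
    unresolved) expressed in one shared frame, suitable for the
    structural term of :func:`merge_two`.
    """
    from .structalign import kabsch_superpose, pairwise_struct_align

    if not members:
        return {}
    members = sorted(members, key=lambda m: m[0].id)
    ref_rec, ref_chain, ref_ss = members[0]
    ref_ca = ref_chain.ca_full()
    frames = {ref_rec.id: ref_ca}
    for rec, chain, ss in members[1:]:
        ca = chain.ca_full()
        aln = pairwise_struct_align(ref_rec, ref_chain, ref_ss, rec, chain, ss)
        resolved = [
            (i, j)
            for i, j in aln.pairs
            if np.isfinite(ref_ca[i]).all() and np.isfinite(ca[j]).all()
        ]
        if len(resolved) >= 3:
            sup = kabsch_superpose(
                ref_ca[[i for i, _ in resolved]], ca[[j for _, j in resolved]]
            )
            frames[rec.id] = ca @ sup.rotation.T + sup.translation
        else:
            frames[rec.id] = ca
    return frames
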