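"""Gap reduction guided by conserved secondary structure ("squeeze").

Merging sub-alignments inflates gap counts in variable regions.  This
step finds alignment columns where a clear majority of the
structure-bearing rows share the same secondary-structure state (helix
or strand), freezes the maximal runs of such columns as conserved
blocks, and re-packs every loop region between blocks by re-aligning
the per-row residue segments with a sequence-only dynamic program.
Residues never cross block boundaries, conserved-block columns are
copied bit-for-bit, and the total number of gap characters never
increases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .records import GAP, Msa, SsString
from .scoring import (
    align_score_matrix,
    blosum62,
    profile_counts,
    profile_score_matrix,
    project_rows,
)
from .structalign import subset_ss_rows

DEFAULT_CATEGORIES = ("H", "E")


@dataclass
class SqueezeParams:
    categories: tuple[str, ...] = DEFAULT_CATEGORIES
    conservation_threshold: float = 0.8
    min_block: int = 2
    gap_open: float = -4.0
    gap_ext: float = -0.5


@dataclass
class ColumnAnnotation:
    """Per-column secondary-structure conservation of an alignment."""

    ss_fraction: dict[str, np.ndarray]   # category -> per-column fraction
    conserved: np.ndarray                # per-column flag
    block_id: np.ndarray                 # -1 outside blocks
    width: int

    @property
    def block_mask(self) -> np.ndarray:
        return self.block_id >= 0

    @property
    def loop_mask(self) -> np.ndarray:
        return ~self.block_mask

    def blocks(self) -> list[tuple[int, int]]:
        """Half-open column ranges of the conserved blocks, in order."""
        out = []
        ids = self.block_id
        i = 0
        while i < self.width:
            if ids[i] < 0:
                i += 1
                continue
            j = i
            while j < self.width and ids[j] == ids[i]:
                j += 1
            out.append((i, j))
            i = j
        return out


def annotate_columns(
    msa: Msa,
    ss_map: dict[str, SsString],
    params: SqueezeParams | None = None,
) -> ColumnAnnotation:
    """Flag columns whose structure-bearing rows agree on H or E.

    A column is conserved when, for some requested category, the
    fraction of structure-bearing non-gap rows in that state reaches
    the threshold and at least two such rows exist.  Blocks are maximal
    conserved runs of at least ``min_block`` columns.
    """
    params = params or SqueezeParams()
    if not set(params.categories) <= {"H", "E"}:
        raise ValueError("conserved categories must be a subset of {H, E}")
    if not 0.0 < params.conservation_threshold <= 1.0:
        raise ValueError("conservation threshold must be in (0, 1]")
    ss_rows = [r for r in subset_ss_rows(msa, ss_map) if set(r) != {GAP}]
    if not any(seq_id in ss_map for seq_id in msa.ids):
        raise ValueError("squeeze requires secondary structure for at least one row")
    w = msa.width
    counts = {c: np.zeros(w) for c in "HEC"}
    total = np.zeros(w)
    for row in ss_rows:
        for j, ch in enumerate(row):
            if ch != GAP:
                counts[ch][j] += 1
                total[j] += 1
    fractions = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for c in params.categories:
            fractions[c] = np.where(total > 0, counts[c] / np.maximum(total, 1), 0.0)
    conserved = np.zeros(w, dtype=bool)
    for c in params.categories:
        conserved |= (fractions[c] >= params.conservation_threshold) & (counts[c] >= 2)
    block_id = np.full(w, -1, dtype=int)
    next_id = 0
    i = 0
    while i < w:
        if not conserved[i]:
            i += 1
            continue
        j = i
        while j < w and conserved[j]:
            j += 1
        if j - i >= params.min_block:
            block_id[i:j] = next_id
            next_id += 1
        i = j
    return ColumnAnnotation(ss_fraction=fractions, conserved=conserved, block_id=block_id, width=w)


def _realign_segments(segments: list[str], params: SqueezeParams) -> list[str]:
    """Gap-minimising re-alignment of loop segments (order preserved).

    Segments are added progressively, longest first, to a growing
    profile using the sequence-only score; empty segments become all-gap
    rows.  Returns gapped rows in the original segment order.
    """
    n = len(segments)
    order = sorted(range(n), key=lambda k: (-len(segments[k]), k))
    rows: dict[int, str] = {}
    profile_ids: list[int] = []
    profile_rows: list[str] = []
    for k in order:
        seg = segments[k]
        if not seg:
            continue
        if not profile_rows:
            profile_ids, profile_rows = [k], [seg]
            continue
        msa_a = Msa([(str(i), r) for i, r in zip(profile_ids, profile_rows)])
        msa_b = Msa([(str(k), seg)])
        counts_a, nongap_a = profile_counts(msa_a)
        counts_b, nongap_b = profile_counts(msa_b)
        S = profile_score_matrix(counts_a, nongap_a, counts_b, nongap_b, blosum62())
        _, ops = align_score_matrix(S, params.gap_open, params.gap_ext)
        out_a, out_b = project_rows(profile_rows, [seg], ops)
        profile_rows = out_a + out_b
        profile_ids = profile_ids + [k]
    width = len(profile_rows[0]) if profile_rows else 0
    for i, k in enumerate(profile_ids):
        rows[k] = profile_rows[i]
    return [rows.get(k, GAP * width) for k in range(n)]


def squeeze_msa(msa: Msa, annotation: ColumnAnnotation, params: SqueezeParams | None = None) -> Msa:
    """Re-pack the loop regions between conserved blocks.

    Conserved-block columns are copied unchanged.  Each inter-block
    region is replaced by a re-alignment of its per-row residue
    segments, which cannot be wider than the original region (the
    original region is kept in the rare case re-alignment fails to
    shrink it).  Row order and row contents (ignoring gaps) are
    untouched.
    """
    params = params or SqueezeParams()
    if annotation.width != msa.width:
        raise ValueError("annotation does not match alignment width")
    arr = msa.to_char_array()
    ids = msa.ids
    pieces: list[np.ndarray] = []
    bounds = annotation.blocks()
    cursor = 0
    regions: list[tuple[int, int, bool]] = []  # (start, stop, is_block)
    for s, e in bounds:
        if cursor < s:
            regions.append((cursor, s, False))
        regions.append((s, e, True))
        cursor = e
    if cursor < msa.width:
        regions.append((cursor, msa.width, False))
    for s, e, is_block in regions:
        chunk = arr[:, s:e]
        if is_block or e - s == 0:
            pieces.append(chunk)
            continue
        segments = ["".join(row).replace(GAP, "") for row in chunk]
        realigned = _realign_segments(segments, params)
        new_w = len(realigned[0]) if realigned and realigned[0] is not None else 0
        if realigned and 0 < new_w < (e - s):
            packed = np.array([list(r) for r in realigned], dtype="<U1")
            pieces.append(packed)
        elif new_w == 0:
            continue  # region held no residues at all
        else:
            pieces.append(chunk)
    if not pieces:
        return Msa.from_char_array(ids, np.empty((len(ids), 0), dtype="<U1"))
    out = np.concatenate(pieces, axis=1)
    return Msa.from_char_array(ids, out)


def squeeze(
    msa: Msa,
    ss_map: dict[str, SsString],
    params: SqueezeParams | None = None,
) -> tuple[Msa, ColumnAnnotation]:
    """Annotate and squeeze in one call."""
    params = params or SqueezeParams()
    annotation = annotate_columns(msa, ss_map, params)
    return squeeze_msa(msa, annotation, params), annotation
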