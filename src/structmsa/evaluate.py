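"""Column Score and descriptive alignment statistics.

The Column Score (CS) of a query alignment against a reference is the
fraction of reference columns whose residue content is reproduced
exactly by some query column: a column scores 1 only when every shared
sequence contributes the very same residue (by sequence position), and
0 as soon as any row deviates.  CS = (number of matched columns) / m,
where m counts the evaluated reference columns.  Columns are compared
as sets of (row, residue-position) pairs, so repeated amino-acid types
cannot produce spurious matches, and the score is insensitive to
column order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .records import GAP, Msa


@dataclass
class GapStats:
    total_gaps: int
    gap_fraction: float
    width: int
    n_rows: int


@dataclass
class CsReport:
    overall_cs: float
    m: int
    regions: dict[str, float] = field(default_factory=dict)
    region_m: dict[str, int] = field(default_factory=dict)
    gap_stats: Optional[GapStats] = None

    def to_dict(self) -> dict:
        out = {
            "overall_cs": self.overall_cs,
            "m": self.m,
            "regions": {
                name: {"cs": cs, "m": self.region_m.get(name, 0)}
                for name, cs in self.regions.items()
            },
        }
        if self.gap_stats is not None:
            out["gap_stats"] = {
                "total_gaps": self.gap_stats.total_gaps,
                "gap_fraction": self.gap_stats.gap_fraction,
                "width": self.gap_stats.width,
                "n_rows": self.gap_stats.n_rows,
            }
        return out


def _column_keys(msa: Msa, row_ids: list[str]) -> list[frozenset]:
    """Per-column sets of (row, residue-position) pairs, gaps excluded."""
    keys: list[set] = [set() for _ in range(msa.width)]
    for rid in row_ids:
        row = msa.row(rid)
        pos = 0
        for j, c in enumerate(row):
            if c != GAP:
                keys[j].add((rid, pos))
                pos += 1
    return [frozenset(k) for k in keys]


def column_score(
    query: Msa,
    reference: Msa,
    region_masks: Optional[Mapping[str, np.ndarray]] = None,
    with_gap_stats: bool = True,
) -> CsReport:
    """Column Score of a query alignment against a reference.

    Both alignments must carry the shared sequences unchanged (row
    conservation); the comparison is restricted to the reference's ids,
    which must all be present in the query.  Reference columns that are
    all-gap over the shared rows are not evaluated.  ``region_masks``
    are boolean masks over reference columns; a per-region CS is
    reported for each.
    """
    shared = [rid for rid in reference.ids if rid in set(query.ids)]
    if not shared:
        raise ValueError("no shared sequence ids between query and reference")
    missing = set(reference.ids) - set(query.ids)
    if missing:
        raise ValueError(f"reference rows absent from query: {sorted(missing)}")
    for rid in shared:
        if query.degapped(rid) != reference.degapped(rid):
            raise ValueError(f"row {rid!r} differs between query and reference (degapped)")

    ref_keys = _column_keys(reference, shared)
    query_keys = set(_column_keys(query, shared))
    evaluated = [j for j, k in enumerate(ref_keys) if k]
    if not evaluated:
        raise ValueError("reference has no residue-bearing columns over shared rows")
    matched = np.zeros(reference.width, dtype=bool)
    for j in evaluated:
        matched[j] = ref_keys[j] in query_keys
    m = len(evaluated)
    overall = float(matched[evaluated].sum() / m)

    regions: dict[str, float] = {}
    region_m: dict[str, int] = {}
    if region_masks:
        eval_mask = np.zeros(reference.width, dtype=bool)
        eval_mask[evaluated] = True
        for name, mask in region_masks.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.size != reference.width:
                raise ValueError(f"region mask {name!r} does not match reference width")
            sel = mask & eval_mask
            if not sel.any():
                raise ValueError(f"region {name!r} selects no evaluated columns")
            region_m[name] = int(sel.sum())
            regions[name] = float(matched[sel].sum() / sel.sum())

    stats = gap_statistics(query) if with_gap_stats else None
    return CsReport(overall_cs=overall, m=m, regions=regions, region_m=region_m, gap_stats=stats)


def gap_statistics(msa: Msa, region_mask: Optional[np.ndarray] = None) -> GapStats:
    """Count gap characters, optionally restricted to a column mask."""
    arr = msa.to_char_array()
    if region_mask is not None:
        mask = np.asarray(region_mask, dtype=bool)
        if mask.size != msa.width:
            raise ValueError("region mask does not match alignment width")
        arr = arr[:, mask]
    cells = arr.size
    gaps = int((arr == GAP).sum())
    return GapStats(
        total_gaps=gaps,
        gap_fraction=gaps / cells if cells else 0.0,
        width=arr.shape[1] if arr.ndim == 2 else 0,
        n_rows=msa.n_rows,
    )
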