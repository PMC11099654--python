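"""Core domain objects: sequences, alignments, backbone structures.

These types are the common currency of the toolkit.  A
:class:`SequenceRecord` is an ungapped amino-acid sequence; an
:class:`Msa` is a rectangular gapped alignment over such records; a
:class:`ChainStructure` carries the CA trace of the matching protein
chain together with a per-position resolved mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

GAP = "-"

#: The 20 standard amino acids, alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Sequence alphabet: the 20 standard residues plus X for anything else.
ALPHABET = AMINO_ACIDS + "X"

#: Routing/labelling states a sequence moves through in the pipeline.
STATUS_UNMATCHED = "unmatched"
STATUS_MATCHED = "matched"
STATUS_ORPHAN = "orphan"
STATUS_STRUCTURELESS = "structureless"
STATUSES = (STATUS_UNMATCHED, STATUS_MATCHED, STATUS_ORPHAN, STATUS_STRUCTURELESS)


@dataclass
class SequenceRecord:
    """A named, ungapped amino-acid sequence.

    Parameters
    ----------
    id:
        Unique token (first whitespace-delimited word of the FASTA header).
    description:
        Remainder of the header line, free text.
    residues:
        Uppercase residue string over ``ALPHABET``; never contains gaps.
    uniprot_id:
        UniProt accession parsed from the header, if recognisable.
    status:
        Routing label; starts ``unmatched`` and is updated by the
        structure-matching and subsetting steps.
    """

    id: str
    residues: str
    description: str = ""
    uniprot_id: Optional[str] = None
    status: str = STATUS_UNMATCHED

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record requires a non-empty id")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        bad = set(self.residues) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid characters {sorted(bad)}"
            )
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")

    def __len__(self) -> int:
        return len(self.residues)


class Msa:
    """Rectangular gapped alignment: an ordered list of (id, gapped row).

    Invariants enforced on construction: all rows share one width, ids are
    unique, rows are non-empty.  Columns that consist entirely of gaps are
    permitted in memory but are dropped whenever an alignment is written
    out or returned by a public pipeline operation.
    """

    __slots__ = ("_ids", "_seqs")

    def __init__(self, rows: Iterable[tuple[str, str]]):
        rows = list(rows)
        self._ids = [r[0] for r in rows]
        self._seqs = [r[1] for r in rows]
        if len(set(self._ids)) != len(self._ids):
            seen, dups = set(), set()
            for i in self._ids:
                (dups if i in seen else seen).add(i)
            raise ValueError(f"duplicate row ids in alignment: {sorted(dups)}")
        widths = {len(s) for s in self._seqs}
        if len(widths) > 1:
            detail = ", ".join(
                f"{i}:{len(s)}" for i, s in zip(self._ids, self._seqs)
            )
            raise ValueError(f"ragged alignment rows ({detail})")

    # -- basic accessors -------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return list(self._ids)

    @property
    def rows(self) -> list[tuple[str, str]]:
        return list(zip(self._ids, self._seqs))

    @property
    def n_rows(self) -> int:
        return len(self._ids)

    @property
    def width(self) -> int:
        return len(self._seqs[0]) if self._seqs else 0

    def row(self, seq_id: str) -> str:
        try:
            return self._seqs[self._ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"no row {seq_id!r} in alignment") from None

    def degapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self._ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Msa):
            return NotImplemented
        return self._ids == other._ids and self._seqs == other._seqs

    def __repr__(self) -> str:
        return f"Msa({self.n_rows} rows x {self.width} columns)"

    # -- array view and column operations --------------------------------
    def to_char_array(self) -> np.ndarray:
        """Return the alignment as an (n_rows, width) array of 1-char strings."""
        if not self._seqs:
            return np.empty((0, 0), dtype="<U1")
        return np.array([list(s) for s in self._seqs], dtype="<U1")

    @classmethod
    def from_char_array(cls, ids: Sequence[str], arr: np.ndarray) -> "Msa":
        return cls([(i, "".join(row)) for i, row in zip(ids, arr)])

    def drop_all_gap_columns(self) -> "Msa":
        if self.n_rows == 0 or self.width == 0:
            return Msa(self.rows)
        arr = self.to_char_array()
        keep = (arr != GAP).any(axis=0)
        return Msa.from_char_array(self._ids, arr[:, keep])

    def restrict(self, ids: Sequence[str]) -> "Msa":
        """Sub-alignment of the named rows, in their current row order."""
        wanted = set(ids)
        missing = wanted - set(self._ids)
        if missing:
            raise KeyError(f"rows not in alignment: {sorted(missing)}")
        return Msa([(i, s) for i, s in zip(self._ids, self._seqs) if i in wanted])

    def reorder(self, ids: Sequence[str]) -> "Msa":
        return Msa([(i, self.row(i)) for i in ids])


@dataclass
class ChainStructure:
    """Backbone CA trace of one chain, mapped onto its sequence.

    ``resolved_mask`` has one flag per *sequence* position; ``ca_coords``
    holds one 3-vector (Å) per resolved position, in sequence order.
    Optional N/C coordinates, when present, parallel ``ca_coords``.
    """

    id: str
    ca_coords: np.ndarray
    resolved_mask: np.ndarray
    n_coords: Optional[np.ndarray] = None
    c_coords: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float).reshape(-1, 3)
        self.resolved_mask = np.asarray(self.resolved_mask, dtype=bool)
        if self.ca_coords.shape[0] != int(self.resolved_mask.sum()):
            raise ValueError(
                f"structure {self.id!r}: {self.ca_coords.shape[0]} CA coordinates "
                f"for {int(self.resolved_mask.sum())} resolved positions"
            )

    @property
    def sequence_length(self) -> int:
        return int(self.resolved_mask.size)

    @property
    def n_resolved(self) -> int:
        return int(self.resolved_mask.sum())

    @property
    def unresolved_fraction(self) -> float:
        if self.resolved_mask.size == 0:
            return 1.0
        return 1.0 - self.n_resolved / self.resolved_mask.size

    def ca_full(self) -> np.ndarray:
        """(L, 3) CA coordinates with NaN rows at unresolved positions."""
        full = np.full((self.sequence_length, 3), np.nan)
        full[self.resolved_mask] = self.ca_coords
        return full


@dataclass
class SsString:
    """Three-state secondary structure parallel to a sequence.

    States: H (helix), E (strand), C (coil / anything else, including
    unresolved positions)."""

    id: str
    states: str

    def __post_init__(self) -> None:
        bad = set(self.states) - set("HEC")
        if bad:
            raise ValueError(f"invalid secondary-structure states {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.states)


def degap(s: str) -> str:
    """Remove gap characters from a gapped row."""
    return s.replace(GAP, "")
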