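"""Reading and writing of external formats.

FASTA sequence files and FASTA alignments, PDB/mmCIF backbone
coordinates (read-only, via gemmi), three-state secondary-structure
FASTA files, and plain-text subset lists.  Everything is normalised on
the way in: residues are uppercased, gaps and characters outside the
21-letter alphabet are stripped from sequence files with a logged
warning, '.' gaps become '-' in alignments.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np
from Bio import SeqIO

from .records import ALPHABET, GAP, ChainStructure, Msa, SequenceRecord, SsString

logger = logging.getLogger(__name__)

# UniProt accession (the two live formats, 6 or 10 characters)
_UNIPROT_RE = re.compile(
    r"^(?:[OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2})$"
)

_STRUCTURE_SUFFIXES = (".pdb", ".ent", ".cif", ".mmcif")

_VALID = set(ALPHABET)
_GAPS = {"-", "."}


class FormatError(ValueError):
    """Raised when an external file violates its format contract."""


def extract_uniprot_id(header_id: str) -> Optional[str]:
    """Accession from a ``db|ACC|name`` style id or a bare accession."""
    parts = header_id.split("|")
    if len(parts) >= 2 and _UNIPROT_RE.match(parts[1]):
        return parts[1]
    if _UNIPROT_RE.match(header_id):
        return header_id
    return None


def _normalise_residues(seq_id: str, raw: str) -> str:
    up = raw.upper()
    kept = []
    dropped = set()
    for c in up:
        if c in _VALID:
            kept.append(c)
        else:
            dropped.add(c)
    if dropped or raw != up:
        logger.warning(
            "sequence %s: normalised (stripped %s, uppercased)",
            seq_id,
            sorted(dropped) if dropped else "nothing",
        )
    return "".join(kept)


def read_fasta(path) -> list[SequenceRecord]:
    """Read a multi-FASTA of protein sequences into records.

    Ids must be unique; residues are normalised to the 21-letter
    uppercase alphabet.  An empty file is an error.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = _normalise_residues(rec.id, str(rec.seq))
        if not residues:
            raise FormatError(f"sequence {rec.id!r} in {path} has no valid residues")
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=residues,
                description=desc,
                uniprot_id=extract_uniprot_id(rec.id),
            )
        )
    if not records:
        raise FormatError(f"no sequences in {path}")
    return records


def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n" + _wrap(rec.residues) + "\n")


def read_msa(path) -> Msa:
    """Read a FASTA alignment; rows must be rectangular.

    '.' gaps are normalised to '-'; residues are uppercased.
    """
    path = Path(path)
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        row = str(rec.seq).upper().replace(".", GAP)
        rows.append((rec.id, row))
    if not rows:
        raise FormatError(f"no alignment rows in {path}")
    widths = {len(s) for _, s in rows}
    if len(widths) > 1:
        detail = ", ".join(f"{i}:{len(s)}" for i, s in rows)
        raise FormatError(f"ragged alignment in {path} ({detail})")
    return Msa(rows)


def write_msa(msa: Msa, path, format: str = "fasta") -> None:
    """Write an alignment; all-gap columns are dropped on write."""
    if format != "fasta":
        raise ValueError(f"unsupported alignment format {format!r}")
    clean = msa.drop_all_gap_columns()
    with open(path, "w") as fh:
        for seq_id, row in clean.rows:
            fh.write(f">{seq_id}\n" + _wrap(row) + "\n")


# -- structures ---------------------------------------------------------

class StructureMismatchError(FormatError):
    """Chain-derived sequence does not match the expected sequence."""


def _chain_residue_letter(residue: gemmi.Residue) -> str:
    info = gemmi.find_tabulated_residue(residue.name)
    if info is None:
        return "X"
    one = info.one_letter_code.upper()
    return one if one in _VALID else "X"


def _pick_atom(residue: gemmi.Residue, name: str) -> Optional[gemmi.Atom]:
    best = None
    for atom in residue:
        if atom.name == name and (best is None or atom.occ > best.occ):
            best = atom
    return best


def read_structure(path, expected_sequence: str, chain_id: Optional[str] = None) -> ChainStructure:
    """Extract the CA trace of one chain and map it onto a sequence.

    The chain's one-letter sequence is derived from residue names and
    globally aligned to ``expected_sequence`` with identity scoring; the
    alignment defines which sequence positions are resolved.  Less than
    95% identity over resolved positions is a mismatch error.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise FormatError(f"{path}: no models")
    model = st[0]
    chain = None
    if chain_id is not None:
        chain = model.find_chain(chain_id)
        if chain is None:
            raise FormatError(f"{path}: no chain {chain_id!r}")
    else:
        for cand in model:
            if any(_pick_atom(res, "CA") is not None for res in cand):
                chain = cand
                break
    if chain is None:
        raise FormatError(f"{path}: no chain with CA atoms")

    letters, ca, n_at, c_at = [], [], [], []
    for res in chain:
        atom = _pick_atom(res, "CA")
        if atom is None:
            continue
        letters.append(_chain_residue_letter(res))
        ca.append([atom.pos.x, atom.pos.y, atom.pos.z])
        for store, nm in ((n_at, "N"), (c_at, "C")):
            a = _pick_atom(res, nm)
            store.append([a.pos.x, a.pos.y, a.pos.z] if a is not None else [np.nan] * 3)
    if not ca:
        raise FormatError(f"{path}: no CA atoms in chain {chain.name!r}")

    derived = "".join(letters)
    pairs = _identity_align(derived, expected_sequence)
    L = len(expected_sequence)
    mask = np.zeros(L, dtype=bool)
    order: list[int] = []
    matches = 0
    for i, j in pairs:  # i: derived index, j: expected index
        mask[j] = True
        order.append(i)
        if derived[i] == expected_sequence[j]:
            matches += 1
    if not order:
        raise StructureMismatchError(f"{path}: chain does not align to expected sequence")
    identity = matches / len(order)
    if identity < 0.95:
        raise StructureMismatchError(
            f"{path}: structure mismatch, {identity:.1%} identity over resolved positions"
        )
    ca_arr = np.asarray(ca)[order]
    n_arr = np.asarray(n_at)[order] if n_at else None
    c_arr = np.asarray(c_at)[order] if c_at else None
    return ChainStructure(
        id=expected_id_from_path(path),
        ca_coords=ca_arr,
        resolved_mask=mask,
        n_coords=n_arr,
        c_coords=c_arr,
    )


def _identity_align(a: str, b: str) -> list[tuple[int, int]]:
    """Global identity-scored alignment; returns aligned index pairs."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(a, b)[0]
    pairs: list[tuple[int, int]] = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    return pairs


def expected_id_from_path(path) -> str:
    return Path(path).stem


def index_structure_dir(directory) -> dict[str, Path]:
    """Map normalised sequence ids to structure files in a directory.

    Normalisation: file stem, case-folded.  PDB and mmCIF suffixes are
    recognised."""
    directory = Path(directory)
    index: dict[str, Path] = {}
    if not directory.is_dir():
        return index
    for p in sorted(directory.iterdir()):
        if p.suffix.lower() in _STRUCTURE_SUFFIXES:
            index[p.stem.casefold()] = p
    return index


# -- secondary-structure strings and subset lists -----------------------

def read_ss_fasta(path) -> dict[str, SsString]:
    """Read {H,E,C} strings from a FASTA-like .ss.fasta file."""
    out: dict[str, SsString] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = SsString(rec.id, str(rec.seq).upper())
    if not out:
        raise FormatError(f"no secondary-structure records in {path}")
    return out


def write_ss_fasta(ss_map: dict[str, SsString], path) -> None:
    with open(path, "w") as fh:
        for seq_id in ss_map:
            fh.write(f">{seq_id}\n" + _wrap(ss_map[seq_id].states) + "\n")


def write_subset_lists(subsets: Sequence[Sequence[str]], directory) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, subset in enumerate(subsets, start=1):
        p = directory / f"subset_{k:03d}.txt"
        p.write_text("".join(f"{sid}\n" for sid in subset))
        paths.append(p)
    return paths


def read_subset_list(path) -> list[str]:
    ids = [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
    if not ids:
        raise FormatError(f"empty subset list {path}")
    return ids
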