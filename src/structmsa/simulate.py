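"""Synthetic protein families with known alignment, structure and SS.

The generator emulates the kind of family the pipeline targets: a
conserved fold of alternating helix/strand blocks joined by variable
loops, at a tunable (and typically low) mean pairwise identity.  Blocks
never gain or lose residues, so every indel lives in a loop; all
sequences share ideal block backbone geometry while loop traces are
per-sequence random walks.  Because descent is simulated explicitly,
the true alignment, the true residue correspondences, the clade
structure and the per-residue secondary structure are all known
exactly, which is what lets every pipeline stage be scored against
ground truth without external reference data.

Substitutions use uniform replacement over the 19 alternative residues
(no rate matrix): adequate for controlling identity, not a
phylogenetic model.  The per-branch substitution probability is
calibrated by bisection so the realised mean pairwise identity hits
the requested target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .records import AMINO_ACIDS, GAP, ChainStructure, Msa, SequenceRecord, SsString

ArchElement = tuple  # ("H", length) | ("E", length) | ("loop", min_len, max_len)


def beta_alpha_beta_architecture(n_units: int = 3) -> tuple[ArchElement, ...]:
    """A compact beta-alpha repeat fold: (E loop H loop) x n + final E.

    Block lengths vary across units (as they do in real repeat
    proteins); exact translational self-similarity would make the
    register between repeat units ambiguous even at the structure
    level."""
    arch: list[ArchElement] = []
    for k in range(n_units):
        arch += [
            ("E", 6 + k % 3),
            ("loop", 2, 6),
            ("H", 9 + (2 * k) % 4),
            ("loop", 2, 6),
        ]
    arch.append(("E", 7))
    return tuple(arch)


@dataclass
class FamilySpec:
    """Parameters of one synthetic family.

    ``mean_identity`` is the target mean pairwise identity over all
    sequence pairs, measured on the true alignment; the generator
    calibrates the substitution probability to land within +/-0.05 of
    it.  When ``within_clade_identity`` and ``between_clade_identity``
    are both given they are calibrated instead (within first).
    """

    n_sequences: int = 8
    architecture: tuple[ArchElement, ...] = field(default_factory=beta_alpha_beta_architecture)
    mean_identity: float = 0.3
    n_clades: int = 1
    indel_rate: float = 0.05
    indel_extend: float = 0.4   # geometric continuation probability
    seed: int = 0
    within_clade_identity: Optional[float] = None
    between_clade_identity: Optional[float] = None
    tree: str = "balanced"      # or "star"

    def __post_init__(self) -> None:
        if self.n_sequences < 2:
            raise ValueError("a family needs at least 2 sequences")
        if not 0.15 <= self.mean_identity <= 1.0:
            raise ValueError("mean identity target must be in [0.15, 1.0]")
        if self.n_clades < 1 or self.n_clades > self.n_sequences:
            raise ValueError("invalid clade count")
        if self.tree not in ("balanced", "star"):
            raise ValueError("tree must be 'balanced' or 'star'")
        for el in self.architecture:
            if el[0] not in ("H", "E", "loop"):
                raise ValueError(f"unknown architecture element {el!r}")


@dataclass
class FamilyTruth:
    """Everything the generator knows about the family it emitted."""

    msa: Msa
    ss: dict[str, SsString]
    structures: dict[str, ChainStructure]
    clades: dict[str, int]
    column_regions: list[tuple[str, int]]    # per truth column: (kind, element index)
    block_column_mask: np.ndarray
    realized_mean_identity: float
    substitution_probability: float

    def loop_column_mask(self) -> np.ndarray:
        return ~self.block_column_mask

    def correspondence(self, id_a: str, id_b: str) -> list[tuple[int, int]]:
        """True homologous residue-position pairs between two sequences."""
        row_a = self.msa.row(id_a)
        row_b = self.msa.row(id_b)
        pairs = []
        ia = ib = 0
        for ca, cb in zip(row_a, row_b):
            if ca != GAP and cb != GAP:
                pairs.append((ia, ib))
            if ca != GAP:
                ia += 1
            if cb != GAP:
                ib += 1
        return pairs


# -- evolution over token-labelled sites --------------------------------

@dataclass
class _Site:
    token: int
    aa: int                  # index into AMINO_ACIDS
    region: tuple[str, int]  # (kind, architecture element index)


class _ColumnLedger:
    """Global homology-column bookkeeping during evolution.

    ``order`` is the master left-to-right ordering of all columns ever
    created; an insertion places its new columns immediately after the
    anchor column, which keeps every lineage's residue order consistent
    with the master order.
    """

    def __init__(self) -> None:
        self.order: list[int] = []
        self._next = 0

    def append_new(self) -> int:
        token = self._next
        self._next += 1
        self.order.append(token)
        return token

    def insert_after(self, anchor: int, count: int) -> list[int]:
        idx = self.order.index(anchor)
        tokens = list(range(self._next, self._next + count))
        self._next += count
        self.order[idx + 1 : idx + 1] = tokens
        return tokens


def _sample_ancestor(spec: FamilySpec, ledger: _ColumnLedger, anc_rng, indel_rng) -> list[_Site]:
    sites: list[_Site] = []
    for idx, el in enumerate(spec.architecture):
        kind = el[0]
        if kind == "loop":
            length = int(indel_rng.integers(el[1], el[2] + 1))
        else:
            length = el[1]
        for _ in range(length):
            sites.append(
                _Site(
                    token=ledger.append_new(),
                    aa=int(anc_rng.integers(20)),
                    region=(kind if kind != "loop" else "C", idx),
                )
            )
    return sites


def _mutate(sites: list[_Site], p_sub: float, spec: FamilySpec, subst_rng, indel_rng, ledger: _ColumnLedger) -> list[_Site]:
    """One branch of evolution: substitutions everywhere, indels in loops.

    Substitution draws are consumed for every site regardless of
    ``p_sub`` so the indel history (and hence all sequence lengths) is
    independent of the substitution probability -- the property the
    identity calibration relies on.
    """
    out: list[_Site] = []
    n = len(sites)
    u_sub = subst_rng.random(n)
    repl = subst_rng.integers(19, size=n)
    for k, site in enumerate(sites):
        aa = site.aa
        if u_sub[k] < p_sub:
            r = int(repl[k])
            aa = r if r < site.aa else r + 1  # uniform over the 19 others
        new_site = _Site(token=site.token, aa=aa, region=site.region)
        in_loop = site.region[0] == "C"
        deleted = False
        if in_loop:
            deleted = indel_rng.random() < spec.indel_rate
        if not deleted:
            out.append(new_site)
        if in_loop and indel_rng.random() < spec.indel_rate:
            length = int(indel_rng.geometric(1.0 - spec.indel_extend))
            tokens = ledger.insert_after(site.token, length)
            for token in tokens:
                out.append(_Site(token=token, aa=int(indel_rng.integers(20)), region=site.region))
    return out


def _clade_sizes(n: int, k: int) -> list[int]:
    base = n // k
    sizes = [base] * k
    for i in range(n - base * k):
        sizes[i] += 1
    return sizes


def _evolve_balanced(sites: list[_Site], n_leaves: int, p: float, spec: FamilySpec, rngs, ledger, leaves: list) -> None:
    if n_leaves == 1:
        leaves.append(sites)
        return
    left = (n_leaves + 1) // 2
    for part in (left, n_leaves - left):
        child = _mutate(sites, p, spec, *rngs, ledger)
        _evolve_balanced(child, part, p, spec, rngs, ledger, leaves)


def _evolve_star(sites: list[_Site], n_leaves: int, p: float, spec: FamilySpec, rngs, ledger, leaves: list) -> None:
    for _ in range(n_leaves):
        leaves.append(_mutate(sites, p, spec, *rngs, ledger))


def _generate_leaves(spec: FamilySpec, p_within: float, p_between: float):
    ss_root = np.random.SeedSequence(spec.seed)
    anc_ss, indel_ss, subst_ss, _ = ss_root.spawn(4)
    anc_rng = np.random.default_rng(anc_ss)
    indel_rng = np.random.default_rng(indel_ss)
    subst_rng = np.random.default_rng(subst_ss)
    ledger = _ColumnLedger()
    ancestor = _sample_ancestor(spec, ledger, anc_rng, indel_rng)
    leaves: list[list[_Site]] = []
    clade_of: list[int] = []
    evolve = _evolve_balanced if spec.tree == "balanced" else _evolve_star
    rngs = (subst_rng, indel_rng)
    for clade_idx, size in enumerate(_clade_sizes(spec.n_sequences, spec.n_clades)):
        clade_root = _mutate(ancestor, p_between, spec, *rngs, ledger) if spec.n_clades > 1 else ancestor
        before = len(leaves)
        evolve(clade_root, size, p_within, spec, rngs, ledger, leaves)
        clade_of += [clade_idx] * (len(leaves) - before)
    return leaves, clade_of, ledger


def _identity_stats(leaves: list[list[_Site]], clade_of: list[int], ledger=None):
    """Mean pairwise identity on the true alignment, overall and by clade relation."""
    tokens = sorted({s.token for leaf in leaves for s in leaf})
    col = {t: j for j, t in enumerate(tokens)}
    M = np.full((len(leaves), len(tokens)), -1, dtype=np.int16)
    lengths = np.array([len(leaf) for leaf in leaves])
    for i, leaf in enumerate(leaves):
        for s in leaf:
            M[i, col[s.token]] = s.aa
    n = len(leaves)
    within, between, overall = [], [], []
    for i in range(n):
        for j in range(i + 1, n):
            both = (M[i] >= 0) & (M[j] >= 0)
            ident = int(((M[i] == M[j]) & both).sum())
            frac = ident / min(lengths[i], lengths[j])
            overall.append(frac)
            (within if clade_of[i] == clade_of[j] else between).append(frac)
    mean = lambda xs: float(np.mean(xs)) if xs else float("nan")
    return mean(overall), mean(within), mean(between)


def _bisect(f, target: float, lo: float = 0.0, hi: float = 0.95, max_steps: int = 50) -> float:
    """Find p with |f(p) - target| small; f must be decreasing in p."""
    f_lo = f(lo)
    if f_lo <= target + 0.02:
        if f_lo >= target - 0.05:
            return lo
        raise ValueError(
            f"identity target {target} unreachable (ceiling {f_lo:.3f}; "
            "indels alone push identity below the target)"
        )
    if f(hi) > target + 0.05:
        raise ValueError(f"identity target {target} unreachable (floor {f(hi):.3f})")
    best_p, best_err = lo, abs(f(lo) - target)
    for _ in range(max_steps):
        mid = 0.5 * (lo + hi)
        val = f(mid)
        err = abs(val - target)
        if err < best_err:
            best_p, best_err = mid, err
        if err <= 0.02:
            return mid
        if val > target:
            lo = mid
        else:
            hi = mid
    if best_err > 0.05:
        raise ValueError(f"identity target {target} not reached (best {best_err:.3f} off)")
    return best_p


# -- geometry -----------------------------------------------------------

_HELIX_RISE = 1.5
_HELIX_TWIST = math.radians(100.0)
_HELIX_RADIUS = 2.3
_STRAND_STEP_X = 3.3
_STRAND_ZIGZAG = 0.9
_CA_STEP = 3.8
_BLOCK_SPACING = 12.0


def _helix_template(length: int, x0: float) -> np.ndarray:
    i = np.arange(length)
    return np.column_stack([
        x0 + _HELIX_RISE * i,
        _HELIX_RADIUS * np.cos(_HELIX_TWIST * i),
        _HELIX_RADIUS * np.sin(_HELIX_TWIST * i),
    ])


def _strand_template(length: int, x0: float) -> np.ndarray:
    i = np.arange(length)
    return np.column_stack([
        x0 + _STRAND_STEP_X * i,
        _STRAND_ZIGZAG * np.where(i % 2 == 0, 1.0, -1.0),
        np.zeros(length),
    ])


def _block_templates(architecture: Sequence[ArchElement]) -> dict[int, np.ndarray]:
    """Shared ideal coordinates per block element, laid out along x."""
    templates: dict[int, np.ndarray] = {}
    x = 0.0
    for idx, el in enumerate(architecture):
        if el[0] == "loop":
            x += _BLOCK_SPACING
            continue
        maker = _helix_template if el[0] == "H" else _strand_template
        templates[idx] = maker(el[1], x)
        x = templates[idx][-1, 0] + _BLOCK_SPACING
    return templates


def bridge_walk(start: np.ndarray, end: np.ndarray, n: int, rng, step: float = _CA_STEP) -> np.ndarray:
    """Random walk of n points from near ``start`` toward ``end``.

    Steps have fixed length; the direction blends a uniform random
    direction with a pull toward the target that strengthens as the
    remaining step budget tightens.  Used for loop traces.
    """
    pts = np.empty((n, 3))
    cur = np.asarray(start, dtype=float)
    for k in range(n):
        remaining = n - k + 1
        to_end = np.asarray(end, dtype=float) - cur
        dist = float(np.linalg.norm(to_end))
        rand = rng.standard_normal(3)
        rand /= max(np.linalg.norm(rand), 1e-12)
        if dist < 1e-9:
            direction = rand
        else:
            w = min(1.0, dist / (remaining * step))
            direction = (1.0 - w) * rand + w * to_end / dist
            direction /= max(np.linalg.norm(direction), 1e-12)
        cur = cur + step * direction
        pts[k] = cur
    return pts


def random_walk_chain(n: int, rng, step: float = _CA_STEP, min_separation: float = 3.0) -> np.ndarray:
    """Self-avoiding-ish random CA walk used as a coil fixture."""
    pts = np.zeros((n, 3))
    for k in range(1, n):
        for _ in range(10):
            d = rng.standard_normal(3)
            d /= max(np.linalg.norm(d), 1e-12)
            cand = pts[k - 1] + step * d
            if k < 2 or np.linalg.norm(pts[: k - 1] - cand, axis=1).min() >= min_separation:
                break
        pts[k] = cand
    return pts


def _leaf_structure(seq_id: str, sites: list[_Site], templates: dict[int, np.ndarray], arch: Sequence[ArchElement], rng) -> ChainStructure:
    coords = np.empty((len(sites), 3))
    block_pos: dict[int, int] = {}
    i = 0
    while i < len(sites):
        region = sites[i].region
        if region[0] != "C":
            k = block_pos.get(region[1], 0)
            coords[i] = templates[region[1]][k]
            block_pos[region[1]] = k + 1
            i += 1
            continue
        j = i
        while j < len(sites) and sites[j].region == region:
            j += 1
        el_idx = region[1]
        prev_blocks = [b for b in templates if b < el_idx]
        next_blocks = [b for b in templates if b > el_idx]
        start = templates[max(prev_blocks)][-1] if prev_blocks else (
            templates[min(next_blocks)][0] - np.array([_BLOCK_SPACING, 0.0, 0.0])
            if next_blocks else np.zeros(3)
        )
        end = templates[min(next_blocks)][0] if next_blocks else (
            start + np.array([_BLOCK_SPACING, 0.0, 0.0])
        )
        coords[i:j] = bridge_walk(start, end, j - i, rng)
        i = j
    return ChainStructure(
        id=seq_id,
        ca_coords=coords,
        resolved_mask=np.ones(len(sites), dtype=bool),
    )


# -- public entry points ------------------------------------------------

def generate_family(spec: FamilySpec) -> tuple[list[SequenceRecord], FamilyTruth]:
    """Simulate one family; deterministic per spec (including its seed)."""
    if spec.within_clade_identity is not None and spec.between_clade_identity is not None:
        p_within = _bisect(
            lambda p: _identity_stats(*_generate_leaves(spec, p, 0.0))[1],
            spec.within_clade_identity,
        )
        p_between = _bisect(
            lambda p: _identity_stats(*_generate_leaves(spec, p_within, p))[2],
            spec.between_clade_identity,
        )
    else:
        p_within = _bisect(
            lambda p: _identity_stats(*_generate_leaves(spec, p, p))[0],
            spec.mean_identity,
        )
        p_between = p_within

    leaves, clade_of, ledger = _generate_leaves(spec, p_within, p_between)
    realized = _identity_stats(leaves, clade_of)[0]

    pad = max(3, len(str(spec.n_sequences)))
    ids = [f"seq{i + 1:0{pad}d}" for i in range(len(leaves))]
    records = [
        SequenceRecord(id=sid, residues="".join(AMINO_ACIDS[s.aa] for s in leaf))
        for sid, leaf in zip(ids, leaves)
    ]

    present = {s.token for leaf in leaves for s in leaf}
    tokens = [t for t in ledger.order if t in present]
    col = {t: j for j, t in enumerate(tokens)}
    region_of: dict[int, tuple[str, int]] = {}
    rows = []
    for sid, leaf in zip(ids, leaves):
        chars = [GAP] * len(tokens)
        for s in leaf:
            chars[col[s.token]] = AMINO_ACIDS[s.aa]
            region_of[s.token] = s.region
        rows.append((sid, "".join(chars)))
    truth_msa = Msa(rows)
    column_regions = [region_of[t] for t in tokens]
    block_mask = np.array([r[0] != "C" for r in column_regions])

    ss_map = {
        sid: SsString(sid, "".join(s.region[0] for s in leaf))
        for sid, leaf in zip(ids, leaves)
    }

    templates = _block_templates(spec.architecture)
    coords_root = np.random.SeedSequence(spec.seed).spawn(4)[3]
    coord_rngs = coords_root.spawn(len(leaves))
    structures = {
        sid: _leaf_structure(sid, leaf, templates, spec.architecture, np.random.default_rng(crng))
        for sid, leaf, crng in zip(ids, leaves, coord_rngs)
    }

    truth = FamilyTruth(
        msa=truth_msa,
        ss=ss_map,
        structures=structures,
        clades=dict(zip(ids, clade_of)),
        column_regions=column_regions,
        block_column_mask=block_mask,
        realized_mean_identity=realized,
        substitution_probability=p_within,
    )
    return records, truth


def degrade_structure(chain: ChainStructure, unresolved_fraction: float, seed: int = 0) -> ChainStructure:
    """Remove coordinates for a contiguous stretch of positions."""
    if not 0.0 <= unresolved_fraction <= 1.0:
        raise ValueError("unresolved fraction must be in [0, 1]")
    L = chain.sequence_length
    n_unres = int(round(unresolved_fraction * L))
    mask = chain.resolved_mask.copy()
    if n_unres > 0:
        rng = np.random.default_rng(seed)
        start = int(rng.integers(0, L - n_unres + 1))
        mask[start : start + n_unres] = False
    full = chain.ca_full()
    keep = mask & chain.resolved_mask
    return ChainStructure(id=chain.id, ca_coords=full[keep], resolved_mask=keep)


def write_chain_pdb(residues: str, chain: ChainStructure, path) -> Path:
    """Write one CA-only chain as a PDB file (unresolved positions omitted)."""
    import gemmi
    from Bio.Data.IUPACData import protein_letters_1to3

    three = {a.upper(): protein_letters_1to3[a].upper() for a in protein_letters_1to3}
    st = gemmi.Structure()
    st.name = chain.id
    model = gemmi.Model("1")
    gchain = gemmi.Chain("A")
    full = chain.ca_full()
    for pos in range(chain.sequence_length):
        if not chain.resolved_mask[pos]:
            continue
        res = gemmi.Residue()
        res.name = three.get(residues[pos], "UNK")
        res.seqid = gemmi.SeqId(pos + 1, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*full[pos])
        atom.occ = 1.0
        res.add_atom(atom)
        gchain.add_residue(res)
    model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
    return Path(path)


def write_family_bundle(records: Sequence[SequenceRecord], truth: FamilyTruth, outdir) -> dict[str, Path]:
    """Write a complete fixture bundle consumable by the pipeline CLI."""
    from . import io as fio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    fio.write_fasta(records, outdir / "family.fasta")
    paths["fasta"] = outdir / "family.fasta"
    fio.write_msa(truth.msa, outdir / "truth.aln.fasta")
    paths["truth"] = outdir / "truth.aln.fasta"
    fio.write_ss_fasta(truth.ss, outdir / "family.ss.fasta")
    paths["ss"] = outdir / "family.ss.fasta"
    for rec in records:
        write_chain_pdb(rec.residues, truth.structures[rec.id], outdir / f"{rec.id}.pdb")
    with open(outdir / "clades.tsv", "w") as fh:
        fh.write("id\tclade\n")
        for rec in records:
            fh.write(f"{rec.id}\t{truth.clades[rec.id]}\n")
    paths["clades"] = outdir / "clades.tsv"
    return paths
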