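"""Three-state secondary structure: DSSP ingestion and CA-geometry assignment.

Two routes produce the per-sequence H/E/C strings the squeeze step
needs: parsing classic DSSP output (8 states collapsed to 3), or a
built-in geometric assignment in the spirit of P-SEA that needs nothing
beyond the CA trace.  The geometric route exists because predicted
models always provide CA atoms while DSSP output is rarely at hand.

Collapse rule: H, G, I -> H; E, B -> E; everything else (turns, bends,
polyproline, blanks) -> C.  Unresolved positions are always C.
"""

from __future__ import annotations

import numpy as np

from .records import ChainStructure, SsString

# DSSP 8-state to 3-state collapse
_COLLAPSE = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E"}

# CA-geometry windows (Å) for the ideal secondary structures
HELIX_D13 = (5.0, 6.0)     # CA(i)-CA(i+3), 5.5 +/- 0.5
HELIX_D14 = (5.8, 7.0)     # CA(i)-CA(i+4), 6.4 +/- 0.6
STRAND_D13 = (6.1, 7.3)    # CA(i)-CA(i+2), 6.7 +/- 0.6
STRAND_MIN_ANGLE = 120.0   # degrees at CA(i) between its two neighbours
STRAND_MAX_ANGLE = 155.0   # real strands zigzag; near-straight chains are coil
MIN_HELIX_RUN = 5
MIN_STRAND_RUN = 3


def collapse_dssp_code(code: str) -> str:
    """Collapse one 8-state DSSP code to H, E or C."""
    return _COLLAPSE.get(code.strip().upper() or "C", "C") if code.strip() else "C"


def parse_dssp(path, seq_id: str, sequence_length: int | None = None) -> SsString:
    """Read a classic DSSP file into a 3-state string.

    Positions are mapped via DSSP residue numbers (taken as 1-based
    sequence positions); positions without a record are coil.  When
    ``sequence_length`` is omitted the largest residue number defines
    the length.
    """
    from Bio.PDB.DSSP import make_dssp_dict

    try:
        dssp_dict, keys = make_dssp_dict(str(path))
    except Exception as exc:
        raise ValueError(f"malformed DSSP file {path}: {exc}") from exc
    by_position: dict[int, str] = {}
    for chain_id, res_id in keys:
        resnum = res_id[1]
        ss8 = dssp_dict[(chain_id, res_id)][1]
        by_position[resnum] = _COLLAPSE.get(ss8, "C")
    length = sequence_length if sequence_length is not None else (max(by_position) if by_position else 0)
    states = "".join(by_position.get(i + 1, "C") for i in range(length))
    return SsString(seq_id, states)


def _dist(ca: np.ndarray, i: int, j: int) -> float:
    return float(np.linalg.norm(ca[i] - ca[j]))


def _angle_deg(ca: np.ndarray, i: int) -> float:
    u = ca[i - 1] - ca[i]
    v = ca[i + 1] - ca[i]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    cosv = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosv)))


def assign_ss(chain: ChainStructure) -> SsString:
    """Assign H/E/C states from CA geometry alone.

    A position is helix-flagged when its CA(i)-CA(i+3) and CA(i)-CA(i+4)
    distances both fall in the canonical alpha-helix windows; runs of at
    least 5 flagged positions label the spanned residues (through i+4 of
    the last flag) H.  Strand flags need CA(i)-CA(i+2) in the extended
    window plus local backbone straightness, with runs of at least 3.
    Unresolved positions and everything else are coil.
    """
    L = chain.sequence_length
    ca = chain.ca_full()
    ok = np.isfinite(ca).all(axis=1)
    states = ["C"] * L
    if int(ok.sum()) < 5:
        return SsString(chain.id, "".join(states))

    helix_flag = np.zeros(L, dtype=bool)
    for i in range(L - 4):
        if not ok[i : i + 5].all():
            continue
        d13 = _dist(ca, i, i + 3)
        d14 = _dist(ca, i, i + 4)
        helix_flag[i] = HELIX_D13[0] <= d13 <= HELIX_D13[1] and HELIX_D14[0] <= d14 <= HELIX_D14[1]

    strand_flag = np.zeros(L, dtype=bool)
    for i in range(1, L - 2):
        if not (ok[i - 1] and ok[i] and ok[i + 1] and ok[i + 2]):
            continue
        d = _dist(ca, i, i + 2)
        strand_flag[i] = (
            STRAND_D13[0] <= d <= STRAND_D13[1]
            and STRAND_MIN_ANGLE <= _angle_deg(ca, i) <= STRAND_MAX_ANGLE
        )

    _label_runs(states, helix_flag, MIN_HELIX_RUN, 0, 4, "H")
    _label_runs(states, strand_flag, MIN_STRAND_RUN, 1, 2, "E")
    return SsString(chain.id, "".join(states))


def _label_runs(states: list[str], flags: np.ndarray, min_run: int, back: int, reach: int, label: str) -> None:
    """Label spans covered by qualifying runs of flags.

    A flag at i asserts ideal geometry over positions i-back..i+reach
    (strand flags test the backbone angle at i, which involves i-1), so
    a qualifying run labels the union of those windows.  Helix labels
    (set first) are not overwritten by strand labels.
    """
    L = len(states)
    i = 0
    while i < L:
        if not flags[i]:
            i += 1
            continue
        j = i
        while j < L and flags[j]:
            j += 1
        if j - i >= min_run:
            for k in range(max(i - back, 0), min(j - 1 + reach + 1, L)):
                if states[k] == "C":
                    states[k] = label
        i = j
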