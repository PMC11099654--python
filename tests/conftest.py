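"""Shared fixtures: synthetic families, MSA builders, DSSP file writer."""

from __future__ import annotations

import numpy as np
import pytest

from structmsa.records import Msa, SequenceRecord
from structmsa.secondary import assign_ss
from structmsa.simulate import FamilySpec, generate_family


@pytest.fixture(scope="session")
def small_family():
    """8 sequences, ~30% mean identity, one clade; the workhorse fixture."""
    spec = FamilySpec(n_sequences=8, mean_identity=0.3, n_clades=1, seed=11)
    records, truth = generate_family(spec)
    return records, truth


@pytest.fixture(scope="session")
def small_family_members(small_family):
    records, truth = small_family
    return [
        (r, truth.structures[r.id], assign_ss(truth.structures[r.id]))
        for r in records
    ]


@pytest.fixture(scope="session")
def clade_family():
    """Four well-separated clades for clustering recovery tests."""
    spec = FamilySpec(
        n_sequences=20,
        n_clades=4,
        mean_identity=0.4,
        within_clade_identity=0.85,
        between_clade_identity=0.25,
        seed=19,
    )
    return generate_family(spec)


def random_gapped_msa(rng, sequences: list[tuple[str, str]], max_width: int) -> Msa:
    """Insert random gaps into ungapped rows, one independent pattern per row."""
    width = max(len(s) for _, s in sequences)
    width = int(rng.integers(width, max(width + 1, max_width + 1)))
    rows = []
    for seq_id, seq in sequences:
        n_gaps = width - len(seq)
        positions = sorted(rng.choice(width, size=n_gaps, replace=False)) if n_gaps else []
        out, p = [], 0
        it = iter(seq)
        for j in range(width):
            if p < len(positions) and positions[p] == j:
                out.append("-")
                p += 1
            else:
                out.append(next(it))
        rows.append((seq_id, "".join(out)))
    msa = Msa(rows)
    return msa.drop_all_gap_columns()


def random_sequences(rng, n_rows: int, min_len: int = 3, max_len: int = 20):
    from structmsa.records import AMINO_ACIDS

    seqs = []
    for k in range(n_rows):
        L = int(rng.integers(min_len, max_len + 1))
        seqs.append(
            (f"r{k}", "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=L)))
        )
    return seqs


def write_dssp(path, rows: list[tuple[int, str, str]], chain: str = "A") -> None:
    """Write a minimal classic-format DSSP file.

    ``rows`` are (residue number, one-letter aa, 8-state SS code) tuples.
    """
    def fmt(idx, resseq, aa, ss):
        line = [" "] * 120
        def put(s, start):
            for k, ch in enumerate(s):
                line[start + k] = ch
        put(f"{idx:5d}", 0)
        put(f"{resseq:5d}", 5)
        put(chain, 11)
        put(aa, 13)
        put(ss if ss.strip() else " ", 16)
        put(f"{0:4d}", 34)
        put(f"{0:7d}", 38); put(f"{0.0:4.1f}", 46)
        put(f"{0:6d}", 50); put(f"{0.0:4.1f}", 57)
        put(f"{0:6d}", 61); put(f"{0.0:4.1f}", 68)
        put(f"{0:6d}", 72); put(f"{0.0:4.1f}", 79)
        put(f"{0.0:6.1f}", 103); put(f"{0.0:6.1f}", 109)
        return "".join(line)

    header = (
        "==== Secondary Structure Definition, synthetic test fixture ====\n"
        "REFERENCE  synthetic\nHEADER     synthetic\n"
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    "
        "N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA\n"
    )
    body = "\n".join(fmt(i + 1, resseq, aa, ss) for i, (resseq, aa, ss) in enumerate(rows))
    with open(path, "w") as fh:
        fh.write(header + body + "\n")
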