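"""Greedy identity-based clustering.

Used twice in the pipeline: once at a high identity cutoff to strip
redundant sequences, and once at a low cutoff (down to ~20%) to group
similar sequences into subsets for structure-aware alignment.  The
algorithm mirrors the classic representative-based greedy scheme:
sequences are visited longest-first and join the first cluster whose
representative they match at or above the threshold.  Identity uses the
shorter-sequence denominator, so a contained fragment scores 1.0
against its parent.

No k-mer prefilter is applied: all comparisons run the full global
alignment, trading speed for exactness and determinism at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .records import SequenceRecord


@dataclass
class Cluster:
    representative: str
    members: list[str]          # includes the representative
    collated: bool = False      # True for pooled small clusters

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClusterSet:
    """Partition of sequence ids into clusters with representatives."""

    clusters: list[Cluster]
    threshold: float

    @property
    def representatives(self) -> list[str]:
        return [c.representative for c in self.clusters]

    def all_ids(self) -> list[str]:
        return [m for c in self.clusters for m in c.members]

    def __len__(self) -> int:
        return len(self.clusters)


@lru_cache(maxsize=1)
def _identity_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_identity(a: str, b: str) -> float:
    """Fractional sequence identity between two residue strings.

    The sequences are globally aligned (BLOSUM62, affine gaps) and the
    number of identically aligned residue pairs is divided by the length
    of the shorter sequence.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    aln = _identity_aligner().align(a, b)[0]
    ident = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            if a[i] == b[j]:
                ident += 1
    return ident / min(len(a), len(b))


def greedy_cluster(records: Sequence[SequenceRecord], threshold: float) -> ClusterSet:
    """Representative-based greedy clustering at a fractional identity cutoff.

    Records are visited by decreasing length (ties by id) and join the
    first existing cluster whose representative matches at >= threshold,
    else found a new cluster.  Deterministic.
    """
    if not 0.2 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0.2, 1.0]")
    by_id = {r.id: r for r in records}
    if len(by_id) != len(records):
        raise ValueError("duplicate record ids")
    order = sorted(records, key=lambda r: (-len(r.residues), r.id))
    clusters: list[Cluster] = []
    for rec in order:
        for cluster in clusters:
            rep = by_id[cluster.representative]
            if pairwise_identity(rec.residues, rep.residues) >= threshold:
                cluster.members.append(rec.id)
                break
        else:
            clusters.append(Cluster(representative=rec.id, members=[rec.id]))
    return ClusterSet(clusters=clusters, threshold=threshold)


def reduce_redundancy(
    records: Sequence[SequenceRecord], threshold: float
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Keep one representative per cluster at the given identity cutoff.

    Returns the kept records (in input order) and a map from each
    dropped id to the representative it collapsed into.
    """
    cluster_set = greedy_cluster(records, threshold)
    keep = set(cluster_set.representatives)
    dropped: dict[str, str] = {}
    for cluster in cluster_set.clusters:
        for member in cluster.members:
            if member != cluster.representative:
                dropped[member] = cluster.representative
    kept = [r for r in records if r.id in keep]
    return kept, dropped


def make_subsets(
    cluster_set: ClusterSet,
    min_subset_size: int = 2,
    collate: bool = False,
) -> tuple[list[list[str]], list[str]]:
    """Turn clusters into alignment subsets, pooling or orphaning the rest.

    Clusters of at least ``min_subset_size`` members become subsets.
    Members of smaller clusters are either returned as orphans, or, with
    ``collate``, pooled largest-cluster-first into as few extra subsets
    as possible, each no larger than the median size of the regular
    subsets.
    """
    if min_subset_size < 2:
        raise ValueError("min_subset_size must be at least 2 (a subset must be alignable)")
    big = [c for c in cluster_set.clusters if c.size >= min_subset_size]
    small = [c for c in cluster_set.clusters if c.size < min_subset_size]
    big.sort(key=lambda c: (-c.size, c.representative))
    subsets = [list(c.members) for c in big]

    if not collate:
        orphans = sorted(m for c in small for m in c.members)
        return subsets, orphans

    if not small:
        return subsets, []
    small.sort(key=lambda c: (-c.size, c.representative))
    if subsets:
        sizes = sorted(len(s) for s in subsets)
        mid = len(sizes) // 2
        median = (
            sizes[mid]
            if len(sizes) % 2
            else (sizes[mid - 1] + sizes[mid]) / 2
        )
    else:
        median = 0
    # capacity must admit the largest small cluster and a viable subset
    capacity = int(max(median, max(c.size for c in small), min_subset_size))
    pooled: list[list[str]] = []
    for cluster in small:  # first-fit decreasing
        for pool in pooled:
            if len(pool) + cluster.size <= capacity:
                pool.extend(cluster.members)
                break
        else:
            pooled.append(list(cluster.members))
    # a trailing pool too small to align merges into its neighbour
    if pooled and len(pooled[-1]) < min_subset_size:
        leftover = pooled.pop()
        if pooled:
            pooled[-1].extend(leftover)
        elif subsets:
            subsets[-1].extend(leftover)
        else:
            return [], sorted(leftover)
    subsets.extend(pooled)
    return subsets, []
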