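"""Greedy identity clustering, subset creation and redundancy reduction."""

import itertools

import numpy as np
import pytest

from structmsa.cluster import (
    Cluster,
    ClusterSet,
    greedy_cluster,
    make_subsets,
    pairwise_identity,
    reduce_redundancy,
)
from structmsa.records import SequenceRecord
from structmsa.simulate import FamilySpec, generate_family


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ("PELICAN", "PELICAN", 1.0),
        ("PELICAN", "PELICANS", 1.0),  # shorter-sequence denominator
        ("AAAA", "CCCC", 0.0),
    ],
)
def test_pairwise_identity_examples(a, b, expected):
    assert pairwise_identity(a, b) == pytest.approx(expected)


def test_pairwise_identity_symmetric():
    a, b = "MKVLINGKTLKG", "MKVAINGATLKG"
    assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))


def _records(seqs):
    return [SequenceRecord(id=f"s{i}", residues=s) for i, s in enumerate(seqs)]


class TestGreedyCluster:
    def test_identical_sequences_one_cluster(self):
        recs = _records(["MKVLING"] * 3)
        cs = greedy_cluster(recs, 0.9)
        assert len(cs) == 1
        assert sorted(cs.clusters[0].members) == ["s0", "s1", "s2"]

    def test_dissimilar_sequences_two_singletons(self):
        recs = _records(["MKVLINGKTLK", "WYFHHEEDDRR"])
        assert pairwise_identity(recs[0].residues, recs[1].residues) < 0.9
        cs = greedy_cluster(recs, 0.9)
        assert len(cs) == 2

    def test_threshold_out_of_range(self):
        with pytest.raises(ValueError):
            greedy_cluster(_records(["MKV"]), 0.1)

    def test_planted_clades_recovered_at_separating_threshold(self, clade_family):
        """Brute-force identity oracle confirms the planted block structure,
        then greedy clustering at a separating threshold recovers it."""
        records, truth = clade_family
        ident = {}
        for a, b in itertools.combinations(records, 2):
            ident[(a.id, b.id)] = pairwise_identity(a.residues, b.residues)
        within = [
            v for (i, j), v in ident.items() if truth.clades[i] == truth.clades[j]
        ]
        between = [
            v for (i, j), v in ident.items() if truth.clades[i] != truth.clades[j]
        ]
        # the oracle must separate before the clustering claim means anything
        assert min(within) > 0.6
        assert max(between) < 0.5
        cs = greedy_cluster(records, 0.55)
        assert len(cs) == 4
        for cluster in cs.clusters:
            clades = {truth.clades[m] for m in cluster.members}
            assert len(clades) == 1

    def test_partition_property(self, clade_family):
        records, _ = clade_family
        for threshold in (0.3, 0.55, 0.9):
            cs = greedy_cluster(records, threshold)
            ids = cs.all_ids()
            assert sorted(ids) == sorted(r.id for r in records)

    def test_representative_identity_property(self, clade_family):
        records, _ = clade_family
        by_id = {r.id: r for r in records}
        cs = greedy_cluster(records, 0.55)
        for cluster in cs.clusters:
            rep = by_id[cluster.representative]
            for member in cluster.members:
                assert (
                    pairwise_identity(by_id[member].residues, rep.residues) >= 0.55
                )

    def test_threshold_monotonicity(self, clade_family):
        records, _ = clade_family
        counts = [
            len(greedy_cluster(records, t)) for t in (0.25, 0.4, 0.55, 0.7, 0.85, 1.0)
        ]
        assert counts == sorted(counts)


class TestMakeSubsets:
    def _cluster_set(self, sizes):
        clusters = []
        n = 0
        for k, size in enumerate(sizes):
            members = [f"c{k}m{i}" for i in range(size)]
            clusters.append(Cluster(representative=members[0], members=members))
            n += size
        return ClusterSet(clusters=clusters, threshold=0.3)

    def test_no_collation_yields_orphans(self):
        subsets, orphans = make_subsets(self._cluster_set([10, 6, 1, 1]), 2, collate=False)
        assert [len(s) for s in subsets] == [10, 6]
        assert len(orphans) == 2

    def test_collation_pools_singletons(self):
        subsets, orphans = make_subsets(self._cluster_set([10, 6, 1, 1]), 2, collate=True)
        assert [len(s) for s in subsets] == [10, 6, 2]
        assert orphans == []

    def test_all_singletons_no_collation(self):
        subsets, orphans = make_subsets(self._cluster_set([1, 1, 1]), 2, collate=False)
        assert subsets == []
        assert len(orphans) == 3

    def test_min_subset_size_validated(self):
        with pytest.raises(ValueError):
            make_subsets(self._cluster_set([3]), 1)

    def test_exhaustive_partition(self):
        cs = self._cluster_set([5, 3, 2, 1, 1, 1])
        for collate in (False, True):
            subsets, orphans = make_subsets(cs, 3, collate=collate)
            ids = [i for s in subsets for i in s] + list(orphans)
            assert sorted(ids) == sorted(cs.all_ids())


class TestReduceRedundancy:
    def test_duplicated_fasta_collapses(self):
        base = ["MKVLINGKTLKG", "WYFHHEEDDRRA", "GGSSAAPPLLTT"]
        recs = _records(base + base)
        kept, dropped = reduce_redundancy(recs, 0.9)
        assert len(kept) == 3
        assert len(dropped) == 3
        assert set(dropped.values()) <= {r.id for r in kept}

    def test_threshold_one_keeps_distinct(self):
        recs = _records(["MKVLING", "MKVLINA", "MKVLINC"])
        kept, dropped = reduce_redundancy(recs, 1.0)
        assert len(kept) == 3
        assert dropped == {}

    def test_planted_family_representatives(self, clade_family):
        records, truth = clade_family
        kept, dropped = reduce_redundancy(records, 0.55)
        assert len(kept) == 4
        assert {truth.clades[r.id] for r in kept} == {0, 1, 2, 3}
        assert set(dropped) | {r.id for r in kept} == {r.id for r in records}
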