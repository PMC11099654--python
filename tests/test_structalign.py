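"""Kabsch superposition and the structure-aware aligner."""

import numpy as np
import pytest

from structmsa.records import ChainStructure, Msa, SsString
from structmsa.secondary import assign_ss
from structmsa.simulate import FamilySpec, generate_family, random_walk_chain
from structmsa.structalign import (
    AlignParams,
    align_subset,
    kabsch_superpose,
    pairwise_struct_align,
    pairwise_to_msa,
)


def _random_rotation(rng):
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def quaternion_superpose_rmsd(A, B):
    """Independent oracle: optimal superposition RMSD via Horn's
    quaternion eigenvalue method."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    M = Bc.T @ Ac
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    ssd = (Ac**2).sum() + (Bc**2).sum() - 2.0 * lam
    return np.sqrt(max(ssd, 0.0) / len(A))


class TestKabsch:
    def test_identity_on_identical_sets(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((10, 3)) * 5
        sup = kabsch_superpose(A, A)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-12)

    def test_rigid_transform_recovered(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            A = rng.standard_normal((12, 3)) * 8
            R = _random_rotation(rng)
            t = rng.standard_normal(3) * 20
            B = (A - t) @ R  # A = B @ R.T + t-ish; any rigid scramble works
            sup = kabsch_superpose(A, B)
            assert sup.rmsd <= 1e-6
            moved = sup.apply(B)
            np.testing.assert_allclose(moved, A, atol=1e-6)

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            A = rng.standard_normal((8, 3))
            B = rng.standard_normal((8, 3))
            sup = kabsch_superpose(A, B)
            assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-8)
            np.testing.assert_allclose(
                sup.rotation @ sup.rotation.T, np.eye(3), atol=1e-8
            )

    def test_agrees_with_quaternion_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            A = rng.standard_normal((8, 3)) * 4
            B = rng.standard_normal((8, 3)) * 4
            sup = kabsch_superpose(A, B)
            assert abs(sup.rmsd - quaternion_superpose_rmsd(A, B)) < 1e-8

    def test_displaced_chain_rmsd_matches_direct_evaluation(self):
        rng = np.random.default_rng(4)
        A = rng.standard_normal((10, 3)) * 6
        B = A + rng.standard_normal((10, 3))
        sup = kabsch_superpose(A, B)
        direct = np.sqrt(np.mean(np.sum((sup.apply(B) - A) ** 2, axis=1)))
        assert sup.rmsd == pytest.approx(direct, abs=1e-12)
        assert sup.rmsd == pytest.approx(quaternion_superpose_rmsd(A, B), abs=1e-8)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


def _member(rec, truth):
    return rec, truth.structures[rec.id], assign_ss(truth.structures[rec.id])


class TestPairwise:
    def test_self_alignment_is_diagonal(self, small_family):
        records, truth = small_family
        rec = records[0]
        a = _member(rec, truth)
        rec_b = type(rec)(id="copy", residues=rec.residues)
        chain_b = ChainStructure(
            id="copy",
            ca_coords=truth.structures[rec.id].ca_coords.copy(),
            resolved_mask=truth.structures[rec.id].resolved_mask.copy(),
        )
        aln = pairwise_struct_align(*a, rec_b, chain_b, SsString("copy", a[2].states))
        assert aln.pairs == [(i, i) for i in range(len(rec.residues))]
        assert aln.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_fixture_pair_block_positions_recovered(self):
        """Same fold at ~30% identity with different loop lengths: at
        least 95% of the true block correspondences must be found."""
        records, truth = generate_family(
            FamilySpec(n_sequences=2, mean_identity=0.3, seed=21)
        )
        a = _member(records[0], truth)
        b = _member(records[1], truth)
        aln = pairwise_struct_align(*a, *b)
        ssa = truth.ss[records[0].id].states
        block_pairs = {
            (i, j)
            for i, j in truth.correspondence(records[0].id, records[1].id)
            if ssa[i] in "HE"
        }
        recovered = len(block_pairs & set(aln.pairs)) / len(block_pairs)
        assert recovered >= 0.95

    def test_no_crossing_invariant(self, small_family_members):
        a, b = small_family_members[0], small_family_members[3]
        aln = pairwise_struct_align(*a, *b)
        for (i1, j1), (i2, j2) in zip(aln.pairs, aln.pairs[1:]):
            assert i2 > i1 and j2 > j1

    def test_unrelated_random_structures_terminate(self):
        rng = np.random.default_rng(8)
        from structmsa.records import AMINO_ACIDS, SequenceRecord

        def rand_member(seq_id):
            n = 40
            seq = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, n))
            rec = SequenceRecord(id=seq_id, residues=seq)
            chain = ChainStructure(
                id=seq_id,
                ca_coords=random_walk_chain(n, rng),
                resolved_mask=np.ones(n, dtype=bool),
            )
            return rec, chain, assign_ss(chain)

        aln = pairwise_struct_align(*rand_member("r1"), *rand_member("r2"))
        assert aln.pairs  # converged and produced an alignment


class TestAlignSubset:
    def test_pair_subset_equals_pairwise_projection(self, small_family_members):
        a, b = small_family_members[0], small_family_members[1]
        msa = align_subset([a, b])
        aln = pairwise_struct_align(*a, *b)
        assert msa == pairwise_to_msa(a[0], b[0], aln)

    def test_row_conservation(self, small_family_members):
        msa = align_subset(small_family_members)
        for rec, _, _ in small_family_members:
            assert msa.degapped(rec.id) == rec.residues

    def test_input_order_invariance(self, small_family_members):
        msa1 = align_subset(small_family_members)
        msa2 = align_subset(small_family_members[::-1])
        assert dict(msa1.rows) == dict(msa2.rows)

    def test_rigid_transform_invariance(self, small_family_members):
        """Rotating one member's structure must not change the result."""
        rng = np.random.default_rng(5)
        R = _random_rotation(rng)
        t = rng.standard_normal(3) * 30
        members = list(small_family_members)
        rec, chain, ss = members[2]
        members[2] = (
            rec,
            ChainStructure(
                id=chain.id,
                ca_coords=chain.ca_coords @ R.T + t,
                resolved_mask=chain.resolved_mask,
            ),
            ss,
        )
        assert align_subset(members) == align_subset(list(small_family_members))

    def test_singleton_subset_warns(self, small_family_members):
        rec, chain, ss = small_family_members[0]
        with pytest.warns(UserWarning):
            msa = align_subset([(rec, chain, ss)])
        assert msa.rows == [(rec.id, rec.residues)]

    def test_conserved_columns_recovered_on_fixture_subset(self):
        """A 6-member subset at ~40% identity: nearly every conserved
        block column must gather the planted homologous residues."""
        from structmsa.evaluate import column_score

        records, truth = generate_family(
            FamilySpec(n_sequences=6, mean_identity=0.4, seed=3)
        )
        members = [_member(r, truth) for r in records]
        msa = align_subset(members)
        rep = column_score(
            msa, truth.msa, region_masks={"blocks": truth.block_column_mask}
        )
        assert rep.regions["blocks"] >= 5 / 6
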