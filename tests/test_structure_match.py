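"""Structure acquisition routing, best-effort resolution and the
unresolved-residue exclusion filter."""

from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from structmsa.records import (
    STATUS_MATCHED,
    STATUS_STRUCTURELESS,
    ChainStructure,
    SequenceRecord,
)
from structmsa.simulate import FamilySpec, degrade_structure, generate_family, write_chain_pdb
from structmsa.structure_match import (
    ESMF_MAX_LENGTH,
    ROUTE_AFDB,
    ROUTE_ESMF,
    ROUTE_NONE,
    ROUTE_USER_FILE,
    ProviderRequest,
    directory_provider,
    filter_unresolved,
    plan_structure_acquisition,
    resolve_structures,
)


def _rec(seq_id, length, uniprot=None):
    return SequenceRecord(id=seq_id, residues="A" * length, uniprot_id=uniprot)


class TestPlanning:
    def test_user_file_wins(self, tmp_path):
        rec = _rec("seqx", 50, uniprot="P12345")
        (plan,) = plan_structure_acquisition([rec], {"seqx": tmp_path / "seqx.pdb"})
        assert plan.route == ROUTE_USER_FILE

    def test_accession_routes_to_afdb(self):
        rec = SequenceRecord(
            id="sp|P0A6F5|CH60_ECOLI", residues="A" * 548, uniprot_id="P0A6F5"
        )
        (plan,) = plan_structure_acquisition([rec], {})
        assert plan.route == ROUTE_AFDB

    def test_short_chain_without_accession_goes_to_predictor(self):
        (plan,) = plan_structure_acquisition([_rec("s", 399)], {})
        assert plan.route == ROUTE_ESMF

    def test_long_chain_without_accession_is_unroutable(self):
        (plan,) = plan_structure_acquisition([_rec("s", 450)], {})
        assert plan.route == ROUTE_NONE

    def test_length_400_is_too_long_for_predictor(self):
        (plan,) = plan_structure_acquisition([_rec("s", ESMF_MAX_LENGTH)], {})
        assert plan.route == ROUTE_NONE

    def test_invalid_request_combinations_rejected(self):
        with pytest.raises(ValueError):
            ProviderRequest(seq_id="s", length=10, route=ROUTE_AFDB, uniprot_id=None)
        with pytest.raises(ValueError):
            ProviderRequest(seq_id="s", length=500, route=ROUTE_ESMF)

    @given(
        length=st.integers(min_value=1, max_value=800),
        has_acc=st.booleans(),
        has_file=st.booleans(),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_routing_invariants(self, length, has_acc, has_file):
        rec = SequenceRecord(
            id="s", residues="A" * length, uniprot_id="P12345" if has_acc else None
        )
        index = {"s": Path("s.pdb")} if has_file else {}
        (plan,) = plan_structure_acquisition([rec], index)
        if plan.route == ROUTE_AFDB:
            assert plan.uniprot_id
        if plan.route == ROUTE_ESMF:
            assert plan.length < ESMF_MAX_LENGTH
        if has_file:
            assert plan.route == ROUTE_USER_FILE


@pytest.fixture(scope="module")
def mini_family(tmp_path_factory):
    records, truth = generate_family(FamilySpec(n_sequences=4, mean_identity=0.5, seed=2))
    outdir = tmp_path_factory.mktemp("structures")
    for rec in records:
        write_chain_pdb(rec.residues, truth.structures[rec.id], outdir / f"{rec.id}.pdb")
    return records, truth, outdir


class TestResolve:
    def test_all_user_files_resolve(self, mini_family):
        records, truth, outdir = mini_family
        index = {p.stem.casefold(): p for p in outdir.glob("*.pdb")}
        requests = plan_structure_acquisition(records, index)
        matched, structureless = resolve_structures(
            requests, {r.id: r for r in records}, {ROUTE_USER_FILE: directory_provider}
        )
        assert structureless == []
        assert set(matched) == {r.id for r in records}
        assert all(r.status == STATUS_MATCHED for r in records)

    def test_provider_failure_demotes_one(self, mini_family):
        records, truth, outdir = mini_family
        records = [SequenceRecord(r.id, r.residues) for r in records]
        index = {p.stem.casefold(): p for p in outdir.glob("*.pdb")}
        requests = plan_structure_acquisition(records, index)
        bad_id = records[1].id

        def flaky(request, record):
            if request.seq_id == bad_id:
                raise OSError("simulated provider outage")
            return directory_provider(request, record)

        matched, structureless = resolve_structures(
            requests, {r.id: r for r in records}, {ROUTE_USER_FILE: flaky}
        )
        assert structureless == [bad_id]
        assert bad_id not in matched
        assert len(matched) == len(records) - 1

    def test_unroutable_becomes_structureless(self):
        rec = _rec("s", 500)
        requests = plan_structure_acquisition([rec], {})
        matched, structureless = resolve_structures(requests, {"s": rec}, {})
        assert matched == {}
        assert structureless == ["s"]
        assert rec.status == STATUS_STRUCTURELESS

    def test_exhaustive_partition(self, mini_family):
        records, truth, outdir = mini_family
        records = [SequenceRecord(r.id, r.residues) for r in records]
        index = {p.stem.casefold(): p for p in list(outdir.glob("*.pdb"))[:2]}
        requests = plan_structure_acquisition(records, index, enable_esmf=False)
        matched, structureless = resolve_structures(
            requests, {r.id: r for r in records}, {ROUTE_USER_FILE: directory_provider}
        )
        assert sorted(list(matched) + structureless) == sorted(r.id for r in records)


class TestFilterUnresolved:
    def _chain(self, frac):
        mask = np.ones(20, dtype=bool)
        mask[: int(round(frac * 20))] = False
        return ChainStructure(id="s", ca_coords=np.zeros((int(mask.sum()), 3)), resolved_mask=mask)

    def test_above_threshold_excluded(self):
        kept, excluded = filter_unresolved({"s": self._chain(0.3)}, 0.25)
        assert excluded == ["s"] and kept == {}

    def test_fully_resolved_kept(self):
        kept, excluded = filter_unresolved({"s": self._chain(0.0)}, 0.25)
        assert excluded == [] and set(kept) == {"s"}

    def test_threshold_one_keeps_everything(self):
        kept, excluded = filter_unresolved({"s": self._chain(1.0)}, 1.0)
        assert excluded == []

    def test_degraded_fixture_structure_excluded(self, mini_family):
        records, truth, _ = mini_family
        rec = records[0]
        degraded = degrade_structure(truth.structures[rec.id], 0.4, seed=1)
        kept, excluded = filter_unresolved({rec.id: degraded}, 0.25)
        assert excluded == [rec.id]
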