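"""End-to-end orchestration: clean → match → subset → align → merge →
squeeze, with per-stage manifests and resume.

Each stage reads its inputs from files, writes its outputs to files
under the run directory, and records a manifest (input content hashes,
parameters, output list).  A re-run skips a stage when its manifest
matches, so a run can be resumed from any checkpoint; changing an
input or a parameter invalidates the affected stage and everything
after it.  Subset alignments are independent jobs: with ``n_jobs > 1``
they run concurrently and the result is identical to a sequential run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import io as fio
from .cluster import greedy_cluster, make_subsets, reduce_redundancy
from .merge import MergeParams, MergePlan, common_frame_coords, merge_all
from .records import (
    STATUS_MATCHED,
    STATUS_ORPHAN,
    STATUS_STRUCTURELESS,
    ChainStructure,
    Msa,
    SequenceRecord,
    SsString,
)
from .secondary import assign_ss
from .squeeze import SqueezeParams, annotate_columns, squeeze_msa
from .structalign import AlignParams, align_subset
from .structure_match import (
    ROUTE_USER_FILE,
    directory_provider,
    filter_unresolved,
    plan_structure_acquisition,
    resolve_structures,
)

logger = logging.getLogger(__name__)

STAGES = ("clean", "match", "subset", "align", "merge", "squeeze")


class PipelineError(RuntimeError):
    """A stage failed; the stage name is preserved for resume."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


class MissingStageError(PipelineError):
    """An upstream stage has not produced its outputs yet."""


@dataclass
class PipelineConfig:
    """All pipeline tunables; round-trips losslessly through YAML."""

    input_fasta: str = ""
    structure_dir: Optional[str] = None
    ss_fasta: Optional[str] = None
    output_dir: str = "structmsa_out"
    redundancy_threshold: float = 0.9
    subset_threshold: float = 0.3
    min_subset_size: int = 2
    collate: bool = True
    squeeze: bool = True
    squeeze_categories: str = "H,E"
    squeeze_threshold: float = 0.8
    max_unresolved_fraction: float = 0.25
    enable_afdb: bool = False
    enable_esmf: bool = False
    n_jobs: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.2 <= self.redundancy_threshold <= 1.0:
            raise ValueError("redundancy_threshold outside [0.2, 1.0]")
        if not 0.2 <= self.subset_threshold <= 1.0:
            raise ValueError("subset_threshold outside [0.2, 1.0]")
        if self.min_subset_size < 2:
            raise ValueError("min_subset_size must be >= 2")
        if not 0.0 <= self.max_unresolved_fraction <= 1.0:
            raise ValueError("max_unresolved_fraction outside [0, 1]")
        if not 0.0 < self.squeeze_threshold <= 1.0:
            raise ValueError("squeeze_threshold outside (0, 1]")
        cats = set(self.categories)
        if self.squeeze and (not cats or not cats <= {"H", "E"}):
            raise ValueError("squeeze_categories must name H and/or E")

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(c.strip() for c in self.squeeze_categories.split(",") if c.strip())

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineResult:
    final_msa: Msa
    final_path: Path
    report_path: Path
    fates: dict[str, str]
    stages_run: list[str]
    stages_skipped: list[str]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class Pipeline:
    """Stage runner bound to one output directory."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.root = Path(config.output_dir)
        self.stage_dir = self.root / "stages"
        self.stages_run: list[str] = []
        self.stages_skipped: list[str] = []

    # -- manifest plumbing ----------------------------------------------
    def _manifest_path(self, stage: str) -> Path:
        return self.stage_dir / f"{stage}.manifest.json"

    def _stage_fresh(self, stage: str, inputs: list[Path], params: dict) -> bool:
        mpath = self._manifest_path(stage)
        if not mpath.exists():
            return False
        try:
            manifest = json.loads(mpath.read_text())
        except json.JSONDecodeError:
            return False
        want = {str(p): _sha256(p) for p in inputs if Path(p).exists()}
        if manifest.get("inputs") != want or manifest.get("params") != params:
            return False
        return all(Path(p).exists() for p in manifest.get("outputs", []))

    def _write_manifest(self, stage: str, inputs: list[Path], params: dict, outputs: list[Path]) -> None:
        self.stage_dir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "stage": stage,
            "inputs": {str(p): _sha256(p) for p in inputs},
            "params": params,
            "outputs": [str(p) for p in outputs],
            "status": "done",
        }
        self._manifest_path(stage).write_text(json.dumps(manifest, indent=1, sort_keys=True))

    def _run_stage(self, stage: str, inputs: list[Path], params: dict, fn) -> None:
        for p in inputs:
            if not Path(p).exists():
                raise MissingStageError(
                    stage, f"missing input {p}; run the prior stage first"
                )
        if self._stage_fresh(stage, inputs, params):
            logger.info("stage %s: up to date, skipping", stage)
            self.stages_skipped.append(stage)
            return
        logger.info("stage %s: running", stage)
        try:
            outputs = fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
        self._write_manifest(stage, inputs, params, outputs)
        self.stages_run.append(stage)

    # -- stage file layout ----------------------------------------------
    @property
    def cleaned_fasta(self) -> Path:
        return self.root / "clean" / "cleaned.fasta"

    @property
    def dropped_tsv(self) -> Path:
        return self.root / "clean" / "dropped.tsv"

    @property
    def match_dir(self) -> Path:
        return self.root / "match"

    @property
    def structures_json(self) -> Path:
        return self.match_dir / "structures.json"

    @property
    def ss_fasta_path(self) -> Path:
        return self.match_dir / "assigned.ss.fasta"

    @property
    def routes_tsv(self) -> Path:
        return self.match_dir / "routes.tsv"

    @property
    def subset_dir(self) -> Path:
        return self.root / "subset"

    @property
    def align_dir(self) -> Path:
        return self.root / "align"

    @property
    def merged_path(self) -> Path:
        return self.root / "merge" / "merged.aln.fasta"

    @property
    def final_path(self) -> Path:
        return self.root / "final.aln.fasta"

    @property
    def report_path(self) -> Path:
        return self.root / "report.tsv"

    # -- stages ----------------------------------------------------------
    def stage_clean(self) -> None:
        cfg = self.config
        params = {"redundancy_threshold": cfg.redundancy_threshold}

        def run():
            records = fio.read_fasta(cfg.input_fasta)
            kept, dropped = reduce_redundancy(records, cfg.redundancy_threshold)
            self.cleaned_fasta.parent.mkdir(parents=True, exist_ok=True)
            fio.write_fasta(kept, self.cleaned_fasta)
            with open(self.dropped_tsv, "w") as fh:
                fh.write("dropped_id\tcollapsed_into\n")
                for did in sorted(dropped):
                    fh.write(f"{did}\t{dropped[did]}\n")
            return [self.cleaned_fasta, self.dropped_tsv]

        self._run_stage("clean", [Path(cfg.input_fasta)], params, run)

    def stage_match(self) -> None:
        cfg = self.config
        params = {
            "structure_dir": cfg.structure_dir,
            "ss_fasta": cfg.ss_fasta,
            "max_unresolved_fraction": cfg.max_unresolved_fraction,
            "enable_afdb": cfg.enable_afdb,
            "enable_esmf": cfg.enable_esmf,
        }
        inputs = [self.cleaned_fasta]
        if cfg.ss_fasta:
            inputs.append(Path(cfg.ss_fasta))

        def run():
            records = fio.read_fasta(self.cleaned_fasta)
            by_id = {r.id: r for r in records}
            index = fio.index_structure_dir(cfg.structure_dir) if cfg.structure_dir else {}
            requests = plan_structure_acquisition(
                records, index, enable_afdb=cfg.enable_afdb, enable_esmf=cfg.enable_esmf
            )
            providers = {ROUTE_USER_FILE: directory_provider}
            if cfg.enable_afdb:
                from .structure_match import alphafold_db_provider

                providers["afdb"] = alphafold_db_provider
            if cfg.enable_esmf:
                from .structure_match import esmfold_provider

                providers["esmf"] = esmfold_provider
            matched, structureless = resolve_structures(requests, by_id, providers)
            kept, excluded = filter_unresolved(matched, cfg.max_unresolved_fraction)

            ss_map: dict[str, SsString] = {}
            if cfg.ss_fasta:
                ss_map.update(fio.read_ss_fasta(cfg.ss_fasta))
            for seq_id, chain in kept.items():
                if seq_id not in ss_map:
                    ss_map[seq_id] = assign_ss(chain)
            ss_map = {
                sid: ss
                for sid, ss in ss_map.items()
                if sid in by_id and len(ss) == len(by_id[sid].residues)
            }

            frames = common_frame_coords(
                [(by_id[sid], kept[sid], ss_map[sid]) for sid in sorted(kept)]
            )

            self.match_dir.mkdir(parents=True, exist_ok=True)
            payload = {}
            for sid in sorted(kept):
                chain = kept[sid]
                frame = frames[sid]
                payload[sid] = {
                    "resolved_mask": chain.resolved_mask.astype(int).tolist(),
                    "ca": np.round(chain.ca_coords, 4).tolist(),
                    "frame_ca": np.round(frame[chain.resolved_mask], 4).tolist(),
                }
            self.structures_json.write_text(json.dumps(payload, sort_keys=True))
            fio.write_ss_fasta(ss_map, self.ss_fasta_path)
            unres = {r.seq_id: r for r in requests}
            with open(self.routes_tsv, "w") as fh:
                fh.write("id\troute\toutcome\tunresolved_fraction\n")
                for rec in records:
                    route = unres[rec.id].route
                    if rec.id in kept:
                        outcome = "matched"
                        frac = f"{kept[rec.id].unresolved_fraction:.4f}"
                    elif rec.id in excluded:
                        outcome = "excluded-unresolved"
                        frac = f"{matched[rec.id].unresolved_fraction:.4f}"
                    else:
                        outcome = "structureless"
                        frac = ""
                    fh.write(f"{rec.id}\t{route}\t{outcome}\t{frac}\n")
            (self.match_dir / "structureless.txt").write_text(
                "".join(f"{sid}\n" for sid in sorted(structureless))
            )
            (self.match_dir / "excluded.txt").write_text(
                "".join(f"{sid}\n" for sid in sorted(excluded))
            )
            return [
                self.structures_json,
                self.ss_fasta_path,
                self.routes_tsv,
                self.match_dir / "structureless.txt",
                self.match_dir / "excluded.txt",
            ]

        self._run_stage("match", inputs, params, run)

    # -- loading helpers for downstream stages ---------------------------
    def _load_records(self) -> dict[str, SequenceRecord]:
        return {r.id: r for r in fio.read_fasta(self.cleaned_fasta)}

    def _load_structures(self) -> tuple[dict[str, ChainStructure], dict[str, np.ndarray]]:
        payload = json.loads(self.structures_json.read_text())
        chains: dict[str, ChainStructure] = {}
        frames: dict[str, np.ndarray] = {}
        for sid, entry in payload.items():
            mask = np.array(entry["resolved_mask"], dtype=bool)
            chains[sid] = ChainStructure(
                id=sid, ca_coords=np.array(entry["ca"]), resolved_mask=mask
            )
            frame = np.full((mask.size, 3), np.nan)
            frame[mask] = np.array(entry["frame_ca"])
            frames[sid] = frame
        return chains, frames

    def _load_ss(self) -> dict[str, SsString]:
        return fio.read_ss_fasta(self.ss_fasta_path)

    def _load_lists(self):
        subsets = [
            fio.read_subset_list(p)
            for p in sorted(self.subset_dir.glob("subset_*.txt"))
        ]
        orphans = [
            line.strip()
            for line in (self.subset_dir / "orphans.txt").read_text().splitlines()
            if line.strip()
        ]
        return subsets, orphans

    def stage_subset(self) -> None:
        cfg = self.config
        params = {
            "subset_threshold": cfg.subset_threshold,
            "min_subset_size": cfg.min_subset_size,
            "collate": cfg.collate,
        }

        def run():
            records = self._load_records()
            chains, _ = self._load_structures()
            matched = [records[sid] for sid in sorted(chains)]
            cluster_set = greedy_cluster(matched, cfg.subset_threshold)
            subsets, orphans = make_subsets(
                cluster_set, cfg.min_subset_size, collate=cfg.collate
            )
            self.subset_dir.mkdir(parents=True, exist_ok=True)
            for old in self.subset_dir.glob("subset_*.txt"):
                old.unlink()
            paths = fio.write_subset_lists(subsets, self.subset_dir)
            orphan_path = self.subset_dir / "orphans.txt"
            orphan_path.write_text("".join(f"{sid}\n" for sid in orphans))
            return list(paths) + [orphan_path]

        self._run_stage("subset", [self.cleaned_fasta, self.structures_json], params, run)

    def stage_align(self) -> None:
        cfg = self.config
        params = {"n_jobs": cfg.n_jobs}
        inputs = [self.structures_json, self.ss_fasta_path, self.subset_dir / "orphans.txt"]
        inputs += sorted(self.subset_dir.glob("subset_*.txt"))

        def run():
            records = self._load_records()
            chains, _ = self._load_structures()
            ss_map = self._load_ss()
            subsets, _ = self._load_lists()
            self.align_dir.mkdir(parents=True, exist_ok=True)

            def job(subset_ids):
                members = [(records[sid], chains[sid], ss_map[sid]) for sid in subset_ids]
                return align_subset(members, AlignParams())

            if cfg.n_jobs > 1:
                with ThreadPoolExecutor(max_workers=cfg.n_jobs) as pool:
                    msas = list(pool.map(job, subsets))
            else:
                msas = [job(s) for s in subsets]
            outputs = []
            for k, msa in enumerate(msas, start=1):
                path = self.align_dir / f"subset_{k:03d}.aln.fasta"
                fio.write_msa(msa, path)
                outputs.append(path)
            return outputs

        self._run_stage("align", inputs, params, run)

    def stage_merge(self) -> None:
        cfg = self.config
        params = {}
        subsets_present = sorted(self.subset_dir.glob("subset_*.txt"))
        inputs = [self.structures_json, self.ss_fasta_path, self.subset_dir / "orphans.txt"]
        inputs += [
            self.align_dir / f"subset_{k:03d}.aln.fasta"
            for k in range(1, len(subsets_present) + 1)
        ]

        def run():
            records = self._load_records()
            chains, frames = self._load_structures()
            ss_map = self._load_ss()
            _, orphans = self._load_lists()
            excluded = set((self.match_dir / "excluded.txt").read_text().split())
            structureless = sorted(set(records) - set(chains) - excluded)
            sub_msas = [
                fio.read_msa(p) for p in sorted(self.align_dir.glob("subset_*.aln.fasta"))
            ]
            plan = MergePlan(
                subset_msas=sub_msas,
                orphans=[records[sid] for sid in orphans],
                structureless=[records[sid] for sid in structureless],
            )
            for sid in orphans:
                records[sid].status = STATUS_ORPHAN
            merged = merge_all(plan, MergeParams(), ss_map=ss_map, frame_coords=frames)
            self.merged_path.parent.mkdir(parents=True, exist_ok=True)
            fio.write_msa(merged, self.merged_path)
            return [self.merged_path]

        self._run_stage("merge", inputs, params, run)

    def stage_squeeze(self) -> None:
        cfg = self.config
        params = {
            "squeeze": cfg.squeeze,
            "categories": list(cfg.categories),
            "threshold": cfg.squeeze_threshold,
        }

        def run():
            merged = fio.read_msa(self.merged_path)
            if not cfg.squeeze:
                shutil.copyfile(self.merged_path, self.final_path)
                return [self.final_path]
            ss_map = self._load_ss()
            sq_params = SqueezeParams(
                categories=cfg.categories,
                conservation_threshold=cfg.squeeze_threshold,
            )
            annotation = annotate_columns(merged, ss_map, sq_params)
            squeezed = squeeze_msa(merged, annotation, sq_params)
            fio.write_msa(squeezed, self.final_path)
            blocks_path = self.root / "squeeze" / "blocks.json"
            blocks_path.parent.mkdir(parents=True, exist_ok=True)
            blocks_path.write_text(
                json.dumps({"merged_width": merged.width, "blocks": annotation.blocks()})
            )
            return [self.final_path, blocks_path]

        self._run_stage("squeeze", [self.merged_path, self.ss_fasta_path], params, run)

    # -- reporting --------------------------------------------------------
    def write_report(self) -> dict[str, str]:
        """Per-sequence fate accounting over the original input."""
        original = fio.read_fasta(self.config.input_fasta)
        dropped = {}
        for line in self.dropped_tsv.read_text().splitlines()[1:]:
            did, into = line.split("\t")
            dropped[did] = into
        excluded = set((self.match_dir / "excluded.txt").read_text().split())
        structureless = set((self.match_dir / "structureless.txt").read_text().split())
        subsets, orphans = self._load_lists()
        fate: dict[str, str] = {}
        for k, subset in enumerate(subsets, start=1):
            for sid in subset:
                fate[sid] = f"subset_{k:03d}"
        for sid in orphans:
            fate[sid] = "orphan"
        for rec in original:
            if rec.id in dropped:
                fate[rec.id] = f"dropped-redundant:{dropped[rec.id]}"
            elif rec.id in excluded:
                fate[rec.id] = "excluded-unresolved"
            elif rec.id in structureless:
                fate[rec.id] = "structureless"
        with open(self.report_path, "w") as fh:
            fh.write("id\tfate\n")
            for rec in original:
                fh.write(f"{rec.id}\t{fate[rec.id]}\n")
        return fate


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run (or resume) the full pipeline and return the final alignment."""
    pipe = Pipeline(config)
    pipe.root.mkdir(parents=True, exist_ok=True)
    config.to_yaml(pipe.root / "config.yaml")
    pipe.stage_clean()
    pipe.stage_match()
    pipe.stage_subset()
    pipe.stage_align()
    pipe.stage_merge()
    pipe.stage_squeeze()
    fates = pipe.write_report()
    final = fio.read_msa(pipe.final_path)
    return PipelineResult(
        final_msa=final,
        final_path=pipe.final_path,
        report_path=pipe.report_path,
        fates=fates,
        stages_run=pipe.stages_run,
        stages_skipped=pipe.stages_skipped,
    )
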