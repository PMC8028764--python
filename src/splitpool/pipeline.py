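"""End-to-end orchestration: simulate -> curate -> demultiplex -> quantify
-> species QC -> saturation, as one reproducible run with a manifest.

One global seed deterministically derives per-stage seeds (stage-name
hashing), so any stage can be re-run in isolation and reproduce its
output.  Counts logged per stage are the same report objects serialised
into the manifest — there is no parallel bookkeeping.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as spio
from .demux import tag_reads
from .layout import ADAPTER_READ1, ADAPTER_READ2, BarcodeLayout, WhitelistSet
from .quant import assign_reads, build_index, build_matrix
from .readproc import FilterReport, filter_phase, trim_and_filter
from .saturation_transfer import saturation
from .simulate import (
    SimConfig,
    generate_reads,
    make_references,
    simulate_cells,
    write_run,
)
from .species_qc import apply_filters, barnyard, estimate_doublets

log = logging.getLogger("splitpool")


@dataclass
class RunConfig:
    """All pipeline parameters, serialisable to/from YAML.

    Numeric defaults are the analysis settings of the mixing experiment
    this pipeline models: 60/94 nt minimum mate lengths, quality cutoff
    10, Hamming-1 barcode correction, k=31 gene index, 100-gene matrix
    creation floor, 125-gene cell calling, 5000-UMI ceiling, 10% barnyard
    collision threshold and 10/25/50/75/100% saturation fractions.
    """

    outdir: str = "splitpool_run"
    seed: int = 0
    n_genes: int = 150
    transcript_length_range: tuple[int, int] = (200, 1500)
    sim: SimConfig = field(default_factory=SimConfig)
    min_len1: int = 60
    min_len2: int = 94
    qual_cutoff: int = 10
    adapter1: str = ADAPTER_READ1
    adapter2: str = ADAPTER_READ2
    phase_max_mismatch: int = 1
    max_hamming: int = 1
    index_k: int = 31
    creation_min_genes: int = 100
    calling_min_genes: int = 125
    max_umi: int = 5000
    theta: float = 0.10
    fractions: tuple[float, ...] = (0.10, 0.25, 0.50, 0.75, 1.00)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["transcript_length_range"] = list(self.transcript_length_range)
        d["fractions"] = list(self.fractions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = SimConfig(**d["sim"])
        if "transcript_length_range" in d:
            d["transcript_length_range"] = tuple(d["transcript_length_range"])
        if "fractions" in d:
            d["fractions"] = tuple(d["fractions"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def validate_config(config: RunConfig, whitelists: WhitelistSet | None = None) -> list[str]:
    """Every violation found, not just the first."""
    errors = list(config.sim.validate())
    if not 0 < config.theta < 0.5:
        errors.append("theta (barnyard collision threshold) must lie in (0, 0.5)")
    if config.min_len1 < 1 or config.min_len2 < 1:
        errors.append("minimum mate lengths must be positive")
    if config.index_k % 2 == 0 or not 15 <= config.index_k <= 63:
        errors.append("index_k must be odd and in [15, 63]")
    if config.creation_min_genes < 1:
        errors.append("creation_min_genes must be >= 1")
    if config.calling_min_genes < 1:
        errors.append("calling_min_genes must be >= 1")
    if config.max_umi < 1:
        errors.append("max_umi must be >= 1")
    for f in config.fractions:
        if not 0 < f <= 1:
            errors.append(f"saturation fraction {f} outside (0, 1]")
    for ad, name in ((config.adapter1, "adapter1"), (config.adapter2, "adapter2")):
        if not ad or not set(ad) <= set("ACGTN"):
            errors.append(f"{name} must be a non-empty uppercase nucleotide string")
    if whitelists is not None:
        for rnd, wl in zip(("round1", "round2", "round3"), whitelists.rounds):
            if len(set(wl)) != len(wl):
                errors.append(f"duplicate barcode sequence in whitelist {rnd}")
    return errors


def stage_seed(global_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    stages: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)

    def record_file(self, name: str, path: Path) -> None:
        self.files[name] = {"path": str(path), "sha256": _sha256(path)}

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "stages": self.stages, "files": self.files},
                      fh, indent=2, default=str)


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages in dependency order; abort on first failure.

    Returns the manifest (also written to ``<outdir>/manifest.json``).
    Upstream outputs are preserved when a later stage fails.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict())
    layout = BarcodeLayout.default()

    def run_stage(name, fn):
        log.info("stage=%s event=start", name)
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - stage name added for the operator
            manifest.stages[name] = {"status": "failed", "error": str(exc)}
            manifest.save(out / "manifest.json")
            raise StageFailure(name, exc) from exc
        log.info("stage=%s event=done", name)
        return result

    # --- simulate -----------------------------------------------------
    state: dict = {}

    def _simulate():
        sim_cfg = dataclasses.replace(config.sim, seed=stage_seed(config.seed, "simulate"))
        refs = make_references(
            config.n_genes, config.transcript_length_range,
            seed=stage_seed(config.seed, "references"),
        )
        wl = WhitelistSet.generate(seed=stage_seed(config.seed, "whitelists"))
        truth = simulate_cells(refs, sim_cfg, whitelists=wl)
        pairs, read_truth = generate_reads(truth, refs, layout, sim_cfg)
        written = write_run(out / "sim", truth, pairs, refs, layout, sim_cfg)
        for name, path in written.items():
            manifest.record_file(f"sim/{name}", path)
        state.update(refs=refs, wl=wl, truth=truth, pairs=pairs)
        return {"status": "complete", "n_units": truth.n_units, "n_reads": len(pairs)}

    manifest.stages["simulate"] = run_stage("simulate", _simulate)

    # --- readproc + demux (per sub-library) ---------------------------
    def _readproc_demux():
        wl = state["wl"]
        by_tag: dict[str, list] = {}
        for rec in state["pairs"]:
            by_tag.setdefault(rec[5], []).append(rec[:5])
        tagged_all = []
        reports = {}
        for tag in sorted(by_tag):
            report = FilterReport()
            kept, report = trim_and_filter(
                by_tag[tag], config.min_len1, config.min_len2,
                config.adapter1, config.adapter2, config.qual_cutoff, report=report,
            )
            kept, report = filter_phase(kept, layout, config.phase_max_mismatch, report=report)
            tagged, demux_report = tag_reads(kept, layout, wl, tag, config.max_hamming)
            tagged_all.extend(tagged)
            reports[tag] = {
                "filter": report.to_dict(),
                "demux": demux_report.to_dict(),
            }
        state["tagged"] = tagged_all
        return {"status": "complete", "per_sublib": reports, "n_tagged": len(tagged_all)}

    manifest.stages["readproc_demux"] = run_stage("readproc_demux", _readproc_demux)

    # --- quant --------------------------------------------------------
    def _quant():
        index = build_index(state["refs"], k=config.index_k)
        rows, n_multi, n_un = assign_reads(state["tagged"], index)
        matrices = build_matrix(rows, creation_min_genes=config.creation_min_genes)
        for sp, dem in matrices.items():
            dem.save_mtx(out / "matrices" / sp)
            for fname in ("matrix.mtx", "features.tsv", "barcodes.tsv"):
                manifest.record_file(f"matrices/{sp}/{fname}", out / "matrices" / sp / fname)
        state["assigned_rows"] = rows
        state["matrices"] = matrices
        return {
            "status": "complete",
            "n_assigned": len(rows),
            "n_multimap": n_multi,
            "n_unassigned": n_un,
            "per_species_barcodes": {sp: len(m.barcodes) for sp, m in matrices.items()},
        }

    manifest.stages["quant"] = run_stage("quant", _quant)

    # --- species QC ---------------------------------------------------
    def _qc():
        matrices = state["matrices"]
        sp_ids = sorted(matrices)
        if len(sp_ids) != 2:
            raise ValueError(f"species QC requires two species matrices, got {sp_ids}")
        records = barnyard(matrices[sp_ids[0]], matrices[sp_ids[1]], theta=config.theta)
        records.to_csv(out / "barnyard.tsv", sep="\t", index=False)
        manifest.record_file("barnyard.tsv", out / "barnyard.tsv")
        summary = {}
        retained = {}
        for sp in sp_ids:
            filtered, ledger = apply_filters(
                matrices[sp], records,
                min_genes=config.calling_min_genes,
                max_umi=config.max_umi, theta=config.theta,
            )
            retained[sp] = filtered
            summary[sp] = ledger.to_dict()
        est = estimate_doublets(records)
        state["records"] = records
        state["retained"] = retained
        return {
            "status": "complete",
            "ledgers": summary,
            "doublet_estimate": dataclasses.asdict(est),
        }

    manifest.stages["species_qc"] = run_stage("species_qc", _qc)

    # --- saturation ---------------------------------------------------
    def _saturation():
        rows = state["assigned_rows"]
        table = pd.DataFrame(rows, columns=["barcode", "umi", "gene", "species"])
        fixed = sorted(
            set().union(*(m.barcodes for m in state["retained"].values()))
        ) or sorted(set().union(*(m.barcodes for m in state["matrices"].values())))
        curve = saturation(
            table[["barcode", "gene", "umi"]], config.fractions,
            fixed_barcodes=fixed, seed=stage_seed(config.seed, "saturation"),
        )
        curve.table.to_csv(out / "saturation.tsv", sep="\t", index=False)
        manifest.record_file("saturation.tsv", out / "saturation.tsv")
        return {
            "status": "complete",
            "n_fixed_barcodes": len(fixed),
            "table": curve.table.to_dict(orient="records"),
        }

    manifest.stages["saturation"] = run_stage("saturation", _saturation)

    manifest.save(out / "manifest.json")
    return manifest
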