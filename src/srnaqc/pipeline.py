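"""End-to-end orchestration: simulate/load -> QC -> annotate -> quantify ->
saturate -> profile, with one consolidated QC summary table.

A run is described by a plain key-value config (usually YAML)::

    seed: 7
    outdir: out
    simulate:                      # either this ...
      reference: {n_mirna: 300, n_other_ncrna: 100, ...}
      libraries:
        blood_1: {tissue: blood, n_reads: 50000, abundance_skew: 0.9}
        brain_1: {tissue: brain, n_reads: 50000, abundance_skew: 0.12}
    fastq:                         # ... or this
      blood_1: {path: blood_1.fastq, tissue: blood}
    reference: ref.fasta           # required with `fastq`
    classmap: ref.classes.tsv
    qc: {min_len: 15, max_len: 40, min_mean_q: 30, adapter_seed_len: 10}
    align: {k: 10, max_mismatches: 1, containment: true}
    thresholds: [1, 10, 20]
    profile: {class: miRNA, threshold: 1, scope: all_replicates}

The single top-level seed fans out deterministically to per-library child
seeds, so identical config + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from .annotate import annotate_library, build_index, complete_report
from .io_formats import (
    CountMatrix,
    read_fastq,
    read_reference,
    write_counts,
    write_qc_report,
    write_qc_table,
)
from .qc_filter import QCParams, run_qc
from .quantify import build_count_matrix, normalize, size_factors
from .saturation import DEFAULT_DEPTH_FACTORS, DEFAULT_THRESHOLDS, saturation_curve
from .synthetic_data import LibraryConfig, RefConfig, simulate_to_dir
from .tissue_profile import profile_tissues


class ConfigError(ValueError):
    """Raised when a run configuration is invalid (nothing is written)."""


class StageError(RuntimeError):
    """Raised when a pipeline stage fails, naming the stage and input."""


def child_seed(seed: int, label: str) -> int:
    """Deterministic per-stage/per-library child seed below 2**31."""
    ss = np.random.SeedSequence([seed, zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int = 0
    outdir: Path = Path("srnaqc_out")
    simulate: dict | None = None
    fastq: dict[str, dict] = field(default_factory=dict)
    reference: Path | None = None
    classmap: Path | None = None
    qc: QCParams = field(default_factory=QCParams)
    align: dict = field(default_factory=lambda: {"k": 10, "max_mismatches": 1, "containment": True})
    thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS
    depth_factors: tuple[float, ...] = DEFAULT_DEPTH_FACTORS
    saturation_reps: int = 0
    profile: dict = field(
        default_factory=lambda: {
            "class": "miRNA",
            "threshold": 1,
            "scope": "all_replicates",
            "reference_tissue": None,
        }
    )

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        raw = dict(raw)
        cfg = cls()
        cfg.seed = int(raw.get("seed", 0))
        cfg.outdir = Path(raw.get("outdir", "srnaqc_out"))
        cfg.simulate = raw.get("simulate")
        cfg.fastq = dict(raw.get("fastq") or {})
        cfg.reference = Path(raw["reference"]) if raw.get("reference") else None
        cfg.classmap = Path(raw["classmap"]) if raw.get("classmap") else None
        if "qc" in raw:
            cfg.qc = QCParams(**raw["qc"])
        if "align" in raw:
            cfg.align.update(raw["align"])
        if "thresholds" in raw:
            cfg.thresholds = tuple(int(t) for t in raw["thresholds"])
        if "depth_factors" in raw:
            cfg.depth_factors = tuple(float(f) for f in raw["depth_factors"])
        cfg.saturation_reps = int(raw.get("saturation_reps", 0))
        if "profile" in raw:
            cfg.profile.update(raw["profile"])
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def validate(self) -> None:
        if bool(self.simulate) == bool(self.fastq):
            raise ConfigError("config needs exactly one of 'simulate' or 'fastq'")
        if self.fastq:
            if self.reference is None or self.classmap is None:
                raise ConfigError("'fastq' input requires 'reference' and 'classmap'")
            if not self.reference.exists():
                raise ConfigError(f"reference not found: {self.reference}")
            if not self.classmap.exists():
                raise ConfigError(f"classmap not found: {self.classmap}")
            for lib_id, spec in self.fastq.items():
                if "path" not in spec:
                    raise ConfigError(f"fastq entry {lib_id!r} missing 'path'")
                if not Path(spec["path"]).exists():
                    raise ConfigError(f"fastq not found: {spec['path']}")
        if self.simulate is not None and "libraries" not in self.simulate:
            raise ConfigError("'simulate' block needs a 'libraries' mapping")
        if any(t < 1 for t in self.thresholds):
            raise ConfigError("thresholds must be >= 1")


def run_pipeline(config: RunConfig, log=print) -> dict[str, Any]:
    """Execute the full pipeline; returns a summary dict of key outputs.

    Writes under ``config.outdir``: per-library QC reports (JSON + TSV), a
    consolidated QC table, raw and normalized count matrices, size factors,
    the miRNA saturation curve, the tissue profile (when >= 2 tissues) and a
    ``run_manifest.json`` recording version, config and seed.
    """
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)

    # --- stage: input (simulate or locate FASTQs) --------------------------
    stage = "simulate"
    try:
        if config.simulate is not None:
            sim_dir = outdir / "simulated"
            ref_cfg = RefConfig(
                **{
                    **(config.simulate.get("reference") or {}),
                    "seed": child_seed(config.seed, "reference"),
                }
            )
            lib_cfgs: dict[str, LibraryConfig] = {}
            tissues: dict[str, str] = {}
            for lib_id, spec in config.simulate["libraries"].items():
                spec = dict(spec)
                tissues[lib_id] = spec.pop("tissue", lib_id)
                spec["seed"] = child_seed(config.seed, f"library:{lib_id}")
                lib_cfgs[lib_id] = LibraryConfig(**spec)
            simulate_to_dir(ref_cfg, lib_cfgs, sim_dir)
            fastq_paths = {lib: sim_dir / f"{lib}.fastq" for lib in lib_cfgs}
            ref_fasta = sim_dir / "reference.fasta"
            ref_classmap = sim_dir / "reference.classes.tsv"
        else:
            fastq_paths = {
                lib: Path(spec["path"]) for lib, spec in config.fastq.items()
            }
            tissues = {
                lib: spec.get("tissue", lib) for lib, spec in config.fastq.items()
            }
            ref_fasta, ref_classmap = config.reference, config.classmap
    except (ConfigError,):
        raise
    except Exception as exc:
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: reference + index ------------------------------------------
    stage = "reference"
    try:
        ref = read_reference(ref_fasta, ref_classmap)
        index = build_index(
            ref,
            k=int(config.align.get("k", 10)),
            max_mismatches=int(config.align.get("max_mismatches", 1)),
            containment=bool(config.align.get("containment", True)),
        )
    except Exception as exc:
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: per-library QC + annotation --------------------------------
    reports = []
    per_library_counts: dict[str, dict[str, float]] = {}
    feature_classes: dict[str, str] = {}
    for lib_id, path in fastq_paths.items():
        stage = f"qc/annotate [{lib_id}]"
        try:
            survivors, report = run_qc(read_fastq(path), config.qc, library_id=lib_id)
            result = annotate_library(survivors, index)
            complete_report(report, result)
            reports.append(report)
            per_library_counts[lib_id] = result.all_counts()
            feature_classes.update(result.feature_classes)
            write_qc_report(report, outdir / "qc" / lib_id)
            log(
                f"[{lib_id}] raw={report.raw_reads} surviving={report.n_surviving} "
                f"unmapped={report.n_unmapped} unique={report.n_unique} "
                f"multi={report.n_multi} miRNA>=1={report.mirna_count_ge1}"
            )
        except Exception as exc:
            raise StageError(f"stage {stage!r} failed on {path}: {exc}") from exc
    write_qc_table(reports, outdir / "qc_table.tsv")

    # --- stage: count matrix + normalization -------------------------------
    stage = "quantify"
    try:
        import pandas as pd

        metadata = pd.DataFrame(
            {"tissue": {lib: tissues[lib] for lib in per_library_counts}}
        )
        matrix = build_count_matrix(per_library_counts, feature_classes, metadata)
        write_counts(matrix, outdir / "counts.tsv", decimals=4)
        factors = size_factors(matrix)
        factors.round(6).to_csv(outdir / "size_factors.tsv", sep="\t")
        normalized = normalize(matrix, factors)
        write_counts(normalized, outdir / "normalized_counts.tsv", decimals=4)
    except Exception as exc:
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: saturation (pooled miRNA counts) ---------------------------
    stage = "saturation"
    try:
        mirna = matrix.subset_class("miRNA")
        pooled = mirna.counts.sum(axis=1)
        total = int(round(pooled.sum()))
        depths = sorted({max(1, int(round(total * f))) for f in config.depth_factors})
        curve = saturation_curve(
            pooled,
            depths=depths,
            thresholds=config.thresholds,
            reps=config.saturation_reps,
            seed=child_seed(config.seed, "saturation"),
        )
        curve.write_tsv(outdir / "saturation.tsv")
    except Exception as exc:
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: tissue profile ---------------------------------------------
    stage = "profile"
    profile = None
    try:
        n_tissues = len(set(tissues.values()))
        if n_tissues >= 2:
            profile = profile_tissues(
                matrix,
                tissues,
                rna_class=str(config.profile.get("class", "miRNA")),
                threshold=float(config.profile.get("threshold", 1)),
                scope=str(config.profile.get("scope", "all_replicates")),
                reference_tissue=config.profile.get("reference_tissue"),
            )
            profile.write_dir(outdir / "profile")
    except Exception as exc:
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "srnaqc_version": __version__,
        "seed": config.seed,
        "libraries": sorted(fastq_paths),
        "tissues": dict(sorted(tissues.items())),
        "qc_params": {
            "adapter": config.qc.adapter,
            "adapter_seed_len": config.qc.adapter_seed_len,
            "min_len": config.qc.min_len,
            "max_len": config.qc.max_len,
            "min_mean_q": config.qc.min_mean_q,
        },
        "align": dict(config.align),
        "thresholds": list(config.thresholds),
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {
        "reports": reports,
        "matrix": matrix,
        "normalized": normalized,
        "size_factors": factors,
        "saturation": curve,
        "profile": profile,
    }
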