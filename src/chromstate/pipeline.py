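"""Workflow orchestration: single-condition state discovery and the
concatenated two-condition comparison, with config validation and run
manifests sufficient to reproduce a run exactly (seed, config hash,
per-output checksums)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genome_io import (
    BinnedGenome,
    read_binary_tracks,
    read_chrom_sizes,
    read_gff3,
    write_segmentation_bed,
)
from .hmm import FitConfig, fit_model, save_model, segment
from .model_evaluation import state_number_diagnostics
from .state_comparison import (
    build_confusion,
    classify_states,
    chromatin_type_fractions,
    comparison_stats,
    feature_overlap,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_discovery", "run_two_condition"]


@dataclass
class RunConfig:
    chrom_sizes: str
    tracks_dir: str
    out_dir: str
    tracks_dir2: str | None = None
    annotation_gff: str | None = None
    bin_size: int = 200
    K: int = 8
    K_range: list[int] | None = None
    seed: int = 0
    method: str = "posterior"
    major_threshold: float = 0.66
    minor_threshold: float = 0.20
    max_iter: int = 200
    tol: float = 1e-3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        missing = {"chrom_sizes", "tracks_dir", "out_dir"} - set(raw)
        if missing:
            raise ValueError(f"missing required config keys: {sorted(missing)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_manifest(out: Path, config: RunConfig, stage_outputs: dict[str, Path], extra: dict) -> None:
    manifest = {
        "chromstate_version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "outputs": {name: {"path": str(p), "sha256": _checksum(p)} for name, p in stage_outputs.items()},
        **extra,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def run_discovery(config: RunConfig) -> dict:
    """Learn a model on one condition, segment, and report state composition."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    genome = read_chrom_sizes(config.chrom_sizes, bin_size=config.bin_size)
    tracks = read_binary_tracks(config.tracks_dir, genome)

    diagnostics = None
    if config.K_range:
        models = []
        for K in sorted(set(config.K_range)):
            m, _ = fit_model(tracks, FitConfig(K=K, seed=config.seed,
                                               max_iter=config.max_iter, tol=config.tol))
            models.append(m)
        table, flagged = state_number_diagnostics(models)
        table.to_csv(out / "state_number_diagnostics.tsv", sep="\t", index=False)
        outputs["state_number_diagnostics"] = out / "state_number_diagnostics.tsv"
        diagnostics = {"flagged_K": flagged}

    model, report = fit_model(
        tracks, FitConfig(K=config.K, seed=config.seed, max_iter=config.max_iter, tol=config.tol)
    )
    save_model(model, out / "model.txt")
    outputs["model"] = out / "model.txt"

    seg = segment(model, tracks, method=config.method)
    write_segmentation_bed(seg, out / f"segmentation_{tracks.condition}.bed")
    outputs["segmentation"] = out / f"segmentation_{tracks.condition}.bed"

    counts = seg.state_counts()
    coverage = pd.DataFrame(
        {"state": seg.state_names, "bins": counts, "fraction": counts / counts.sum()}
    )
    coverage.to_csv(out / "coverage.tsv", sep="\t", index=False)
    outputs["coverage"] = out / "coverage.tsv"

    if config.annotation_gff:
        ann = read_gff3(config.annotation_gff)
        fo = feature_overlap(seg, ann, proportions=True)
        fo.to_csv(out / "feature_overlap.tsv", sep="\t")
        outputs["feature_overlap"] = out / "feature_overlap.tsv"

    extra = {
        "fit": {"iterations": report.n_iter, "converged": report.converged,
                "final_log_likelihood": report.log_likelihoods[-1]},
    }
    if diagnostics:
        extra["diagnostics"] = diagnostics
    _write_manifest(out, config, outputs, extra)
    return {"model": model, "segmentation": seg, "report": report, "coverage": coverage}


def run_two_condition(config: RunConfig) -> dict:
    """Concatenated two-condition model: shared parameters, per-condition
    segmentations, confusion-based JI/O/FC tables, and coverage fold-changes."""
    if not config.tracks_dir2:
        raise ValueError("two-condition run requires tracks_dir2")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    genome = read_chrom_sizes(config.chrom_sizes, bin_size=config.bin_size)
    tracks1 = read_binary_tracks(config.tracks_dir, genome)
    tracks2 = read_binary_tracks(config.tracks_dir2, genome)
    if not tracks1.genome.same_grid(tracks2.genome):
        raise ValueError("conditions are on different bin grids")

    model, report = fit_model(
        [tracks1, tracks2],
        FitConfig(K=config.K, seed=config.seed, max_iter=config.max_iter, tol=config.tol),
    )
    save_model(model, out / "model_concat.txt")
    outputs["model"] = out / "model_concat.txt"

    segs = {}
    for tr in (tracks1, tracks2):
        s = segment(model, tr, method=config.method)
        segs[tr.condition] = s
        p = out / f"segmentation_{tr.condition}.bed"
        write_segmentation_bed(s, p)
        outputs[f"segmentation_{tr.condition}"] = p

    seg1, seg2 = segs[tracks1.condition], segs[tracks2.condition]
    conf = build_confusion(seg1, seg2)
    stats = comparison_stats(conf)
    stats_df = stats.to_frame()
    stats_df.to_csv(out / "state_comparison.tsv", sep="\t")
    outputs["state_comparison"] = out / "state_comparison.tsv"

    c1, c2 = seg1.state_counts(), seg2.state_counts()
    coverage = pd.DataFrame(
        {
            "state": seg1.state_names,
            f"bins_{tracks1.condition}": c1,
            f"bins_{tracks2.condition}": c2,
        }
    )
    coverage.to_csv(out / "coverage_two_condition.tsv", sep="\t", index=False)
    outputs["coverage"] = out / "coverage_two_condition.tsv"

    _write_manifest(out, config, outputs, {
        "fit": {"iterations": report.n_iter, "converged": report.converged,
                "final_log_likelihood": report.log_likelihoods[-1]},
        "genome_wide_overlap": stats.genome_wide_overlap,
    })
    return {
        "model": model,
        "segmentations": segs,
        "confusion": conf,
        "stats": stats,
        "coverage": coverage,
        "report": report,
    }
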