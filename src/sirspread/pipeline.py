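"""Reproducible end-to-end pipeline: simulate -> aggregate -> smooth -> infer.

A single YAML/JSON config document drives everything; a run writes its
outputs plus a manifest (parameters, seed, file hashes, record counts) so a
re-run with the same config is byte-identical. Stage timings go to logging
only, never into the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .aggregate import aggregate_fraction, filter_coverage, merge_strand_track, smooth_track
from .annotation import RECRUITMENT_KINDS, toy_genome
from .inference import call_boundary, estimate_background
from .io_formats import (
    CoverageTrack,
    write_aggregate_bed,
    write_bed_annotation,
    write_bedgraph,
    write_perread_text,
)
from .models import EmissionModel, OccupancyModel, ReadSamplerConfig, occupancy_field, accessibility_field, sites_from_annotation
from .perread import binarize_calls
from .simulate import simulate_reads

log = logging.getLogger("sirspread")

ALL_STAGES = ("simulate", "aggregate", "infer")


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Fully serializable pipeline configuration."""

    seed: int = 0
    outdir: str = "sirspread_out"
    stages: tuple[str, ...] = ALL_STAGES
    # simulation
    coverage: float = 30.0
    mean_read_length: int = 8000
    adenine_density: float = 0.31
    nucleosome_repeat: int = 165
    peak_occupancy: float = 0.9
    decay_length: float = 2500.0
    boundary_attenuation: float = 0.0
    background_occupancy: float = 0.005
    methylation_rate: float = 0.8
    tpr: float = 0.9
    fpr: float = 0.01
    # processing
    threshold: float = 0.8
    min_coverage: int = 10
    enp_target: float = 100.0
    span: float | None = None
    merge_strands: bool = True
    # inference
    background_k: float = 2.0
    run_length: float = 300.0
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        for stage in self.stages:
            if stage not in ALL_STAGES:
                raise ConfigError(f"unknown stage {stage!r}")
        if not 0 < self.threshold < 1:
            raise ConfigError("threshold outside (0, 1)")
        if self.min_coverage < 1:
            raise ConfigError("min_coverage must be >= 1")
        if self.coverage <= 0:
            raise ConfigError("coverage must be > 0")

    @classmethod
    def from_dict(cls, d: dict, **overrides) -> "RunConfig":
        d = dict(d)
        d.update({k: v for k, v in overrides.items() if v is not None})
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        try:
            cfg = cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None
        cfg.overrides = {k: v for k, v in overrides.items() if v is not None}
        return cfg

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError("config must be a mapping")
        return cls.from_dict(d, **overrides)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _auto_direction(anchor, cluster_feats) -> int:
    """Point away from the local recruitment cluster's center of mass."""
    center = (anchor.start + anchor.end) / 2
    near = [
        f
        for f in cluster_feats
        if abs((f.start + f.end) / 2 - center) <= 5000
    ]
    if not near:
        return 1
    cm = float(np.mean([(f.start + f.end) / 2 for f in near]))
    return 1 if center >= cm else -1


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    counts: dict[str, int] = {}

    annotation = toy_genome(
        seed=config.seed,
        adenine_density=config.adenine_density,
        nrl=config.nucleosome_repeat,
    )
    model = OccupancyModel(
        recruitment_sites=sites_from_annotation(annotation, config.peak_occupancy),
        decay_length=config.decay_length,
        boundary_attenuation=config.boundary_attenuation,
        background_occupancy=config.background_occupancy,
        methylation_rate=config.methylation_rate,
    )
    emission = EmissionModel(p_true_positive=config.tpr, p_false_positive=config.fpr)
    sampler = ReadSamplerConfig(
        mean_read_length=config.mean_read_length,
        target_coverage=config.coverage,
        seed=config.seed,
    )

    calls = None
    stage = "simulate"
    try:
        if "simulate" in config.stages:
            t0 = time.perf_counter()
            calls = simulate_reads(annotation, model, emission, sampler)
            counts["perread_calls"] = len(calls)
            outputs["reads"] = write_perread_text(calls, outdir / "reads.perread.txt")
            outputs["annotation"] = write_bed_annotation(
                annotation.features, outdir / "annotation.bed"
            )
            for contig in annotation.contigs:
                occ = occupancy_field(model, annotation, contig)
                acc = accessibility_field(annotation, model, contig)
                outputs[f"truth_occupancy_{contig}"] = write_bedgraph(
                    CoverageTrack.from_per_base(contig, occ),
                    outdir / f"truth.occupancy.{contig}.bedgraph",
                )
                outputs[f"truth_accessibility_{contig}"] = write_bedgraph(
                    CoverageTrack.from_per_base(contig, acc),
                    outdir / f"truth.accessibility.{contig}.bedgraph",
                )
            log.info("simulate: %d calls in %.1fs", len(calls), time.perf_counter() - t0)

        tracks = {}
        stage = "aggregate"
        if "aggregate" in config.stages:
            if calls is None:
                raise RuntimeError("aggregate stage requires simulate stage")
            t0 = time.perf_counter()
            binary = binarize_calls(calls, config.threshold)
            for contig in annotation.contigs:
                raw = aggregate_fraction(binary, region=contig, merge_strands=False)
                outputs[f"aggregate_{contig}"] = write_aggregate_bed(
                    raw, outdir / f"aggregate.{contig}.bed"
                )
                track = merge_strand_track(raw) if config.merge_strands else raw
                track = filter_coverage(track, config.min_coverage)
                track = smooth_track(
                    track, effective_parameters=config.enp_target, span=config.span
                )
                tracks[contig] = track
                sm = track.df
                outputs[f"smoothed_{contig}"] = write_bedgraph(
                    CoverageTrack(
                        contig,
                        sm["position"].to_numpy(),
                        sm["position"].to_numpy() + 1,
                        sm["smoothed"].to_numpy(),
                    ),
                    outdir / f"smoothed.{contig}.bedgraph",
                )
                counts[f"track_positions_{contig}"] = len(track)
            log.info("aggregate: %d contigs in %.1fs", len(tracks), time.perf_counter() - t0)

        stage = "infer"
        if "infer" in config.stages:
            if not tracks:
                raise RuntimeError("infer stage requires aggregate stage")
            t0 = time.perf_counter()
            rows = []
            for contig, track in tracks.items():
                controls = [
                    (f.start, f.end)
                    for f in annotation.features_on(contig, "control_region")
                ]
                if not controls:
                    continue
                bg = estimate_background(track, regions=controls, k=config.background_k)
                anchors = [
                    f
                    for f in annotation.features_on(contig)
                    if f.kind in {"silencer", "x_element"}
                ]
                cluster = [f for f in annotation.features_on(contig) if f.kind in RECRUITMENT_KINDS]
                for anchor in anchors:
                    direction = _auto_direction(anchor, cluster)
                    bc = call_boundary(track, anchor, direction, bg, config.run_length)
                    rows.append(
                        {
                            "contig": contig,
                            "anchor": anchor.name or anchor.kind,
                            "anchor_start": anchor.start,
                            "anchor_end": anchor.end,
                            "direction": direction,
                            "boundary_position": bc.boundary_position,
                            "spread_extent": bc.spread_extent,
                            "background_level": round(bc.background_level, 6),
                            "status": bc.status,
                        }
                    )
            import pandas as pd

            bdf = pd.DataFrame(rows)
            path = outdir / "boundaries.tsv"
            bdf.to_csv(path, sep="\t", index=False)
            outputs["boundaries"] = path
            counts["boundary_calls"] = len(bdf)
            log.info("infer: %d boundary calls in %.1fs", len(bdf), time.perf_counter() - t0)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "record_counts": counts,
        "files": {name: {"path": p.name, "sha256": _sha256(p)} for name, p in sorted(outputs.items())},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
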