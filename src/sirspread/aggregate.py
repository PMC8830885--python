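"""Aggregate methylation tracks: percent of molecules methylated per adenine.

Per-position records carry integer coverage (emitted calls) and methylated
counts; percent (0-100) is the canonical display unit, matching the y-axes
of aggregate methylation plots. Tracks can be coverage-filtered, smoothed
with the coverage-weighted loess smoother, and median-normalized (ChIP).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calls import PerReadCallSet
from .io_formats import CoverageTrack
from .smoothing import loess_smooth


@dataclass
class AggregateTrack:
    """Per-position coverage and percent-methylated over one contig.

    ``df`` columns: position, strand, coverage, n_methylated, percent and,
    after :func:`smooth_track`, smoothed. Positions are sorted (by position,
    then strand).
    """

    contig: str
    df: pd.DataFrame
    mod_code: str = "Y"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        base = ["position", "strand", "coverage", "percent"]
        missing = [c for c in base if c not in self.df.columns]
        if missing:
            raise ValueError(f"aggregate track missing columns {missing}")
        if "n_methylated" not in self.df.columns:
            self.df = self.df.assign(
                n_methylated=np.rint(
                    self.df["percent"].fillna(0.0) * self.df["coverage"] / 100.0
                ).astype(np.int64)
            )
        self.df = self.df.sort_values(
            ["position", "strand"], kind="mergesort"
        ).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def positions(self) -> np.ndarray:
        return self.df["position"].to_numpy()

    @property
    def smoothed(self) -> np.ndarray:
        if "smoothed" not in self.df.columns:
            raise ValueError("track has no smoothed values; run smooth_track first")
        return self.df["smoothed"].to_numpy()

    def subset(self, start: int, end: int) -> "AggregateTrack":
        sub = self.df[(self.df["position"] >= start) & (self.df["position"] < end)]
        return AggregateTrack(self.contig, sub.reset_index(drop=True), self.mod_code, dict(self.meta))


def aggregate_fraction(
    calls: PerReadCallSet,
    region: tuple[str, int, int] | str | None = None,
    merge_strands: bool = False,
) -> AggregateTrack:
    """Percent of reads methylated at each (position, strand).

    coverage = number of emitted calls; percent = 100 * methylated/coverage.
    Positions with zero calls are simply absent. With ``merge_strands`` the
    counts of the two strands are summed per position (adenine positions on
    opposite strands are distinct, so this usually just unions the grids).
    """
    if not calls.is_binarized:
        raise ValueError("aggregate_fraction requires binarized calls")
    df = calls.df
    if region is None:
        contigs = df["contig"].unique()
        if len(contigs) != 1:
            raise ValueError("multi-contig call set: pass a region")
        contig = str(contigs[0])
    elif isinstance(region, str):
        contig = region
        df = df[df["contig"] == contig]
    else:
        contig, start, end = region
        df = df[
            (df["contig"] == contig)
            & (df["position"] >= start)
            & (df["position"] < end)
        ]
    keys = ["position"] if merge_strands else ["position", "strand"]
    grp = df.groupby(keys, sort=True)["methylated"]
    agg = grp.agg(coverage="size", n_methylated="sum").reset_index()
    if merge_strands:
        agg["strand"] = "."
    agg["coverage"] = agg["coverage"].astype(np.int64)
    agg["n_methylated"] = agg["n_methylated"].astype(np.int64)
    agg["percent"] = 100.0 * agg["n_methylated"] / agg["coverage"]
    agg = agg[["position", "strand", "coverage", "n_methylated", "percent"]]
    return AggregateTrack(
        contig,
        agg,
        meta={"threshold": calls.threshold, "merge_strands": merge_strands},
    )


def filter_coverage(track: AggregateTrack, min_coverage: int = 10) -> AggregateTrack:
    """Keep only positions with at least ``min_coverage`` calls (inclusive)."""
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    df = track.df[track.df["coverage"] >= min_coverage].reset_index(drop=True)
    meta = dict(track.meta, min_coverage=min_coverage)
    return AggregateTrack(track.contig, df, track.mod_code, meta)


def smooth_track(
    track: AggregateTrack,
    effective_parameters: float = 100.0,
    weight_by_coverage: bool = True,
    span: float | None = None,
) -> AggregateTrack:
    """Loess-smooth percent vs position, weighted by coverage.

    The span is calibrated so the smoother's effective number of parameters
    (hat-matrix trace) lands within +-2 of ``effective_parameters``, unless
    ``span`` is pinned directly. Smoothed values are evaluated at the
    retained positions only.
    """
    if len(track) < 3:
        raise ValueError("need >= 3 retained positions to smooth")
    x = track.df["position"].to_numpy()
    y = track.df["percent"].to_numpy()
    w = track.df["coverage"].to_numpy().astype(float) if weight_by_coverage else None
    fitted, span_used = loess_smooth(
        x, y, w, span=span, enp_target=None if span is not None else effective_parameters
    )
    df = track.df.assign(smoothed=fitted)
    meta = dict(
        track.meta,
        span=span_used,
        enp_target=None if span is not None else effective_parameters,
        weight_by_coverage=weight_by_coverage,
    )
    return AggregateTrack(track.contig, df, track.mod_code, meta)


def normalize_chip(
    coverage: CoverageTrack, exclusions: list[tuple[int, int]] | None = None
) -> CoverageTrack:
    """Divide ChIP depth by the median over non-excluded positions.

    Exclusions (rDNA, whole excluded chromosomes, subtelomeric ends) are
    half-open intervals on the track's contig. After normalization the
    median of the non-excluded positions is 1. Idempotent and
    scale-equivariant.
    """
    if np.any(coverage.values < 0):
        raise ValueError("negative depths")
    exclusions = list(exclusions or []) + list(coverage.excluded)
    dense = coverage.per_base()
    mask = np.ones(dense.size, dtype=bool)
    for s, e in exclusions:
        mask[max(s, 0) : min(e, dense.size)] = False
    if not mask.any():
        raise ValueError("all positions excluded")
    med = float(np.median(dense[mask]))
    if med == 0:
        raise ValueError("median depth over non-excluded positions is 0")
    return CoverageTrack(
        coverage.contig,
        coverage.starts.copy(),
        coverage.ends.copy(),
        coverage.values / med,
        excluded=list(coverage.excluded),
    )


def genotype_overlay(
    tracks: list[AggregateTrack],
    region: tuple[int, int] | None = None,
    labels: list[str] | None = None,
    column: str = "percent",
) -> pd.DataFrame:
    """Union-align several tracks over one contig for comparison plotting.

    One row per position in the union of the tracks' grids; one column per
    track; missing values are NaN (no interpolation). Strands are collapsed
    by position (use merged-strand tracks for a strand-agnostic overlay).
    """
    if not tracks:
        raise ValueError("no tracks")
    contig = tracks[0].contig
    if any(t.contig != contig for t in tracks):
        raise ValueError("tracks on different contigs")
    labels = labels or [t.meta.get("sample", f"track{i}") for i, t in enumerate(tracks)]
    cols = {}
    for lab, t in zip(labels, tracks):
        df = t.df
        if region is not None:
            df = df[(df["position"] >= region[0]) & (df["position"] < region[1])]
        cols[lab] = df.groupby("position")[column].mean()
    out = pd.DataFrame(cols)
    out.index.name = "position"
    return out.sort_index()


def merge_strand_track(track: AggregateTrack) -> AggregateTrack:
    """Sum coverages and methylated counts per position across strands."""
    grp = track.df.groupby("position", sort=True)[["coverage", "n_methylated"]].sum()
    df = grp.reset_index()
    df["strand"] = "."
    df["percent"] = 100.0 * df["n_methylated"] / df["coverage"]
    df = df[["position", "strand", "coverage", "n_methylated", "percent"]]
    return AggregateTrack(track.contig, df, track.mod_code, dict(track.meta, merge_strands=True))
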