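"""Readers and writers for every on-disk format the pipeline touches.

All coordinates are 0-based half-open. Dialects:

* **Per-read text** — the tab-separated per-read modified-base table
  (``read_id  chrm  strand  pos  mod_log_prob  can_log_prob  mod_base``),
  natural-log probabilities, one row per call.
* **Aggregate BED** — single-base methylation records, one per
  (position, strand): ``chrom  start  end  mod_code  coverage  strand
  percent``; ``end`` must equal ``start + 1``.
* **BED6** — feature annotations; the feature kind is recovered from the
  name by longest-prefix match (e.g. ``silencer_E_hml`` -> silencer).
* **bedGraph** — stepwise coverage/signal; overlapping intervals are an
  error; values expand per-base on demand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import FEATURE_KINDS, Feature, GenomeAnnotation
from .calls import COLUMNS, PerReadCallSet

PERREAD_HEADER = ["read_id", "chrm", "strand", "pos", "mod_log_prob", "can_log_prob", "mod_base"]

KNOWN_MOD_CODES = {"Y", "a", "m"}

#: log-probabilities serialize via repr: the shortest decimal string that
#: round-trips exactly (always >= 9 significant digits of information)
_LOGPROB_FMT = "{!r}"


def read_perread_text(path) -> PerReadCallSet:
    """Parse a per-read modified-base text file.

    Accepts a header line (column names containing ``read``/``chrm``) or
    headerless input in the documented column order; extra columns are
    ignored with a warning. Malformed rows raise with the 1-based line
    number.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        lines = fh.readlines()
    start = 0
    if lines:
        first = lines[0].rstrip("\n").split("\t")
        if first and (first[0].strip().lower() in {"read_id", "read id"}):
            start = 1
            if len(first) > len(PERREAD_HEADER):
                warnings.warn(
                    f"{path.name}: ignoring {len(first) - len(PERREAD_HEADER)} extra column(s)"
                )
    unknown_codes = set()
    for lineno, line in enumerate(lines[start:], start=start + 1):
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) < 7:
            raise ValueError(f"{path.name}:{lineno}: expected 7 columns, got {len(parts)}")
        try:
            pos = int(parts[3])
            mod_lp = float(parts[4])
            can_lp = float(parts[5])
        except ValueError as exc:
            raise ValueError(f"{path.name}:{lineno}: malformed row ({exc})") from None
        if mod_lp > 0 or can_lp > 0:
            raise ValueError(f"{path.name}:{lineno}: log probability > 0")
        if parts[6] not in KNOWN_MOD_CODES:
            unknown_codes.add(parts[6])
        rows.append((parts[0], parts[1], parts[2], pos, mod_lp, can_lp, parts[6]))
    if unknown_codes:
        warnings.warn(f"{path.name}: unknown mod code(s) {sorted(unknown_codes)}; rows kept")
    df = pd.DataFrame(rows, columns=COLUMNS)
    if df.empty:
        return PerReadCallSet.empty()
    df["position"] = df["position"].astype(np.int64)
    return PerReadCallSet(df)


def write_perread_text(calls: PerReadCallSet, path) -> Path:
    """Write the per-read dialect, sorted by (contig, position, read_id)."""
    path = Path(path)
    df = calls.sorted().df
    body = (
        df["read_id"].astype(str)
        + "\t"
        + df["contig"].astype(str)
        + "\t"
        + df["strand"].astype(str)
        + "\t"
        + df["position"].astype(str)
        + "\t"
        + df["mod_log_prob"].map(repr)
        + "\t"
        + df["can_log_prob"].map(repr)
        + "\t"
        + df["mod_code"].astype(str)
    )
    with open(path, "w") as fh:
        fh.write("\t".join(PERREAD_HEADER) + "\n")
        if len(body):
            fh.write("\n".join(body.tolist()) + "\n")
    return path


# ---------------------------------------------------------------------------
# aggregate methylation BED


def write_aggregate_bed(track, path) -> Path:
    """Write an AggregateTrack as single-base methylation BED records."""
    path = Path(path)
    df = track.df
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            pct = 0.0 if row.coverage == 0 else row.percent
            fh.write(
                f"{track.contig}\t{int(row.position)}\t{int(row.position) + 1}\t"
                f"{track.mod_code}\t{int(row.coverage)}\t{row.strand}\t"
                f"{pct!r}\n"
            )
    return path


def read_aggregate_bed(path):
    """Read single-base methylation BED records into an AggregateTrack.

    Records with ``end != start + 1`` raise; coverage-0 records read back
    with their percent flagged missing (NaN).
    """
    from .aggregate import AggregateTrack

    path = Path(path)
    recs = []
    contig = None
    mod_code = "Y"
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 7:
                raise ValueError(f"{path.name}:{lineno}: expected 7 columns")
            start, end = int(parts[1]), int(parts[2])
            if end != start + 1:
                raise ValueError(
                    f"{path.name}:{lineno}: single-base records required (end != start+1)"
                )
            if contig is None:
                contig = parts[0]
            elif parts[0] != contig:
                raise ValueError(f"{path.name}:{lineno}: multiple contigs in one track file")
            mod_code = parts[3]
            cov = int(parts[4])
            pct = float(parts[6]) if cov > 0 else np.nan
            recs.append((start, parts[5], cov, pct))
    df = pd.DataFrame(recs, columns=["position", "strand", "coverage", "percent"])
    if not df.empty:
        df["n_methylated"] = np.where(
            df["coverage"] > 0,
            np.rint(df["percent"].fillna(0.0) * df["coverage"] / 100.0),
            0,
        ).astype(np.int64)
    else:
        df["n_methylated"] = pd.Series(dtype=np.int64)
    df = df[["position", "strand", "coverage", "n_methylated", "percent"]]
    return AggregateTrack(contig=contig or "", df=df, mod_code=mod_code)


# ---------------------------------------------------------------------------
# BED6 annotations


def _kind_from_name(name: str) -> str | None:
    best = None
    for kind in FEATURE_KINDS:
        if name == kind or name.startswith(kind + "_") or name.startswith(kind):
            if best is None or len(kind) > len(best):
                best = kind
    # allow short aliases used in telomere annotations
    if best is None:
        for alias, kind in {"tg": "tg_repeat", "xelem": "x_element"}.items():
            if name.startswith(alias):
                return kind
    return best


def read_bed_annotation(path, contigs: dict[str, int] | None = None) -> list[Feature]:
    """Read BED6 features; kind is derived from the name prefix.

    Input need not be sorted; the result is sorted stably by
    (contig, start, end).
    """
    path = Path(path)
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path.name}:{lineno}: expected >= 4 BED columns")
            name = parts[3]
            kind = _kind_from_name(name)
            if kind is None:
                raise ValueError(f"{path.name}:{lineno}: cannot map name {name!r} to a feature kind")
            strand = parts[5] if len(parts) > 5 else "."
            feats.append(Feature(parts[0], int(parts[1]), int(parts[2]), strand, kind, name))
    feats.sort(key=lambda f: (f.contig, f.start, f.end, f.kind))
    if contigs is not None:
        for f in feats:
            if f.contig not in contigs or f.end > contigs[f.contig]:
                raise ValueError(f"feature {f.name} outside contig bounds")
    return feats


def write_bed_annotation(features: list[Feature], path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for f in sorted(features, key=lambda f: (f.contig, f.start, f.end, f.kind)):
            name = f.name or f.kind
            fh.write(f"{f.contig}\t{f.start}\t{f.end}\t{name}\t0\t{f.strand}\n")
    return path


# ---------------------------------------------------------------------------
# bedGraph


@dataclass
class CoverageTrack:
    """Stepwise per-base signal on one contig (ChIP coverage, truth fields).

    Stored as non-overlapping intervals; :meth:`per_base` expands on demand.
    """

    contig: str
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray
    excluded: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        order = np.argsort(self.starts, kind="mergesort")
        self.starts, self.ends, self.values = (
            self.starts[order],
            self.ends[order],
            self.values[order],
        )
        if np.any(self.ends <= self.starts):
            raise ValueError("empty or inverted bedGraph interval")
        if self.starts.size > 1 and np.any(self.starts[1:] < self.ends[:-1]):
            raise ValueError("overlapping bedGraph intervals")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite bedGraph values")

    @property
    def length(self) -> int:
        return int(self.ends[-1]) if self.ends.size else 0

    def per_base(self, length: int | None = None) -> np.ndarray:
        """Expand to a dense per-base vector (gaps are 0)."""
        n = length if length is not None else self.length
        out = np.zeros(n, dtype=float)
        for s, e, v in zip(self.starts, self.ends, self.values):
            out[s:min(e, n)] = v
        return out

    @classmethod
    def from_per_base(cls, contig: str, values: np.ndarray) -> "CoverageTrack":
        values = np.asarray(values, dtype=float)
        change = np.flatnonzero(np.diff(values) != 0) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [values.size]])
        return cls(contig, starts, ends, values[starts])


def read_bedgraph(path) -> CoverageTrack:
    path = Path(path)
    starts, ends, values = [], [], []
    contig = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path.name}:{lineno}: expected 4 bedGraph columns")
            if contig is None:
                contig = parts[0]
            elif parts[0] != contig:
                raise ValueError(f"{path.name}:{lineno}: multiple contigs in one track file")
            starts.append(int(parts[1]))
            ends.append(int(parts[2]))
            values.append(float(parts[3]))
    return CoverageTrack(contig or "", np.array(starts, dtype=np.int64), np.array(ends, dtype=np.int64), np.array(values))


def write_bedgraph(track: CoverageTrack, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for s, e, v in zip(track.starts, track.ends, track.values):
            fh.write(f"{track.contig}\t{int(s)}\t{int(e)}\t{float(v)!r}\n")
    return path
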