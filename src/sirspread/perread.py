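"""Binary per-read calls and windowed single-read methylation matrices.

A probability call becomes 'm6A' iff its modified-base probability strictly
exceeds the threshold (default 0.8). A methylation matrix holds one row per
read spanning a query window and one column per adenine position, ordered
for display by ascending mean methylation (least methylated molecule on
top), matching the aggregate-figure convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calls import PerReadCallSet


def binarize_calls(calls: PerReadCallSet, threshold: float = 0.8) -> PerReadCallSet:
    """Binarize probabilistic calls: methylated iff p > threshold (strict).

    Idempotent; the record count is unchanged.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold outside (0, 1)")
    df = calls.df.copy()
    df["methylated"] = np.exp(df["mod_log_prob"].to_numpy()) > threshold
    return PerReadCallSet(df, threshold=threshold, meta=dict(calls.meta))


@dataclass
class MethylationMatrix:
    """Reads x adenine-positions binary matrix for one query window.

    ``cells`` is float: 1.0 methylated, 0.0 unmethylated, NaN when the read
    emitted no call at that position (missing is distinct from unmethylated).
    ``row_order`` is the display permutation (set by :func:`order_reads`).
    """

    contig: str
    start: int
    end: int
    positions: np.ndarray
    read_ids: list[str]
    cells: np.ndarray
    row_order: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)

    def row_means(self) -> np.ndarray:
        """Mean methylation per read over emitted calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.cells, axis=1)

    def column_means(self) -> np.ndarray:
        """Per-position methylated fraction over emitted calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.cells, axis=0)

    def to_frame(self) -> pd.DataFrame:
        order = self.row_order if self.row_order is not None else np.arange(self.n_reads)
        return pd.DataFrame(
            self.cells[order],
            index=[self.read_ids[i] for i in order],
            columns=self.positions,
        )


def build_matrix(
    calls: PerReadCallSet,
    window: tuple[str, int, int],
    require_full_span: bool = True,
) -> MethylationMatrix:
    """Assemble the single-read matrix for ``window`` = (contig, start, end).

    With ``require_full_span`` (the default, as in the single-read figures)
    a read is retained only if its calls bracket the entire window, i.e. it
    has calls both at-or-before ``start`` and at-or-beyond ``end`` (the read
    footprint covers [start, end)). Columns are the adenine positions with at
    least one retained call.
    """
    if not calls.is_binarized:
        raise ValueError("build_matrix requires binarized calls")
    contig, start, end = window
    if not start < end:
        raise ValueError("empty window")
    df = calls.df[calls.df["contig"] == contig]
    if df.empty or not ((df["position"] >= start) & (df["position"] < end)).any():
        raise ValueError(f"window {contig}:{start}-{end} contains no adenine calls")

    # read footprints from their outermost calls on this contig
    spans = df.groupby("read_id")["position"].agg(["min", "max"])
    if require_full_span:
        keep = spans[(spans["min"] <= start) & (spans["max"] >= end - 1)].index
    else:
        keep = spans[(spans["min"] < end) & (spans["max"] >= start)].index
    sub = df[
        df["read_id"].isin(keep)
        & (df["position"] >= start)
        & (df["position"] < end)
    ]
    if sub.empty:
        warnings.warn(f"no reads span {contig}:{start}-{end}; empty matrix")
        return MethylationMatrix(
            contig, start, end, np.empty(0, np.int64), [], np.empty((0, 0))
        )
    positions = np.sort(sub["position"].unique())
    read_ids = sorted(sub["read_id"].unique())
    r_index = {r: i for i, r in enumerate(read_ids)}
    c_index = np.searchsorted(positions, sub["position"].to_numpy())
    cells = np.full((len(read_ids), positions.size), np.nan)
    rows = sub["read_id"].map(r_index).to_numpy()
    cells[rows, c_index] = sub["methylated"].to_numpy().astype(float)
    return MethylationMatrix(
        contig,
        start,
        end,
        positions,
        list(read_ids),
        cells,
        meta={"threshold": calls.threshold, "require_full_span": require_full_span},
    )


def order_reads(matrix: MethylationMatrix) -> MethylationMatrix:
    """Set the display order: ascending mean methylation, ties by read id.

    The least methylated molecule is drawn on top, the most methylated at
    the bottom. The sort is stable, so equal means fall back to the
    lexicographic read-id order of the matrix rows.
    """
    if matrix.n_reads == 0:
        raise ValueError("cannot order an empty matrix")
    means = matrix.row_means()
    order = np.argsort(means, kind="mergesort")  # rows already in read_id order
    matrix.row_order = order
    return matrix


def read_summary(matrix: MethylationMatrix) -> pd.DataFrame:
    """Per-read table: mean methylation, methylated count, emitted-call count."""
    emitted = (~np.isnan(matrix.cells)).sum(axis=1)
    n_meth = np.nansum(matrix.cells, axis=1).astype(np.int64)
    with np.errstate(invalid="ignore"):
        mean = np.where(emitted > 0, n_meth / np.maximum(emitted, 1), np.nan)
    return pd.DataFrame(
        {
            "read_id": matrix.read_ids,
            "mean_methylation": mean,
            "n_methylated": n_meth,
            "n_calls": emitted,
        }
    )


def plot_matrix(matrix: MethylationMatrix, ax=None, color="#6a3d9a"):
    """Raster plot of a single-read matrix: methylated colored, unmethylated
    gray, missing white. Returns the matplotlib Axes."""
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    if ax is None:
        _, ax = plt.subplots(figsize=(8, max(2, matrix.n_reads * 0.08)))
    order = matrix.row_order if matrix.row_order is not None else np.arange(matrix.n_reads)
    img = matrix.cells[order]
    cmap = ListedColormap(["#cccccc", color])
    cmap.set_bad("white")
    ax.imshow(
        np.ma.masked_invalid(img),
        aspect="auto",
        interpolation="nearest",
        cmap=cmap,
        vmin=0,
        vmax=1,
        extent=(matrix.start, matrix.end, matrix.n_reads, 0),
    )
    ax.set_xlabel(f"{matrix.contig} position (bp)")
    ax.set_ylabel("reads")
    return ax
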