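"""Quantitative readouts: background, boundaries, spread, periodicity, onset.

These operations turn aggregate/smoothed methylation tracks into the
biological quantities of interest: where the signal returns to background
(the spread boundary relative to a recruitment anchor), how a boundary and
signal level respond between two conditions, which positions differ
significantly, the nucleosome-repeat periodicity of the signal, the
linker/core methylation contrast, the establishment-onset time of each
position, and the exponential length scale of spreading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .aggregate import AggregateTrack
from .annotation import Feature, derive_rng
from .calls import PerReadCallSet


# ---------------------------------------------------------------------------
# background


@dataclass
class BackgroundEstimate:
    """Background methylation level: mean + k*SD of percent over control
    positions (a no-occupancy sample or control regions of the test sample)."""

    level: float
    mean: float
    sd: float
    n: int
    k: float

    def __float__(self) -> float:
        return self.level


def estimate_background(
    control_track: AggregateTrack,
    regions: list[tuple[int, int]] | None = None,
    k: float = 2.0,
    use_smoothed: bool = False,
) -> BackgroundEstimate:
    """Estimate the background level (percent) from control positions."""
    df = control_track.df
    if regions:
        mask = np.zeros(len(df), dtype=bool)
        pos = df["position"].to_numpy()
        for s, e in regions:
            mask |= (pos >= s) & (pos < e)
        df = df[mask]
    values = (df["smoothed"] if use_smoothed else df["percent"]).to_numpy(dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 20:
        raise ValueError(f"only {values.size} control positions (< 20)")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    return BackgroundEstimate(mean + k * sd, mean, sd, int(values.size), k)


# ---------------------------------------------------------------------------
# boundary calling


@dataclass
class BoundaryCall:
    """Inferred spread boundary relative to a recruitment anchor.

    ``direction`` is +1 (rightward / increasing coordinate) or -1. ``status``
    is ``bounded`` (signal returned to background inside the window),
    ``unbounded`` (still above background at the window edge; boundary is set
    to the edge) or ``at_anchor`` (never above background beyond the anchor).
    """

    contig: str
    anchor: Feature
    direction: int
    boundary_position: int
    spread_extent: float
    background_level: float
    status: str


def call_boundary(
    track: AggregateTrack,
    anchor: Feature,
    direction: int,
    background_level: float | BackgroundEstimate,
    run_length: float = 300.0,
) -> BoundaryCall:
    """First sustained return to background, walking away from the anchor.

    The boundary is the first position, moving from the anchor edge in
    ``direction``, at which the smoothed signal stays at or below
    ``background_level`` over at least ``run_length`` consecutive bp.
    """
    bg = float(background_level)
    if direction not in (1, -1):
        raise ValueError("direction must be +1 or -1")
    pos = track.positions
    sm = track.smoothed
    if pos.size == 0 or anchor.start >= pos.max() or anchor.end <= pos.min():
        raise ValueError("anchor outside the analyzed window")
    edge = anchor.end if direction == 1 else anchor.start - 1
    if direction == 1:
        sel = pos >= edge
        walk_pos, walk_sm = pos[sel], sm[sel]
        dist = (walk_pos - edge).astype(float)
    else:
        sel = pos <= edge
        walk_pos, walk_sm = pos[sel][::-1], sm[sel][::-1]
        dist = (edge - walk_pos).astype(float)
    if walk_pos.size == 0:
        raise ValueError("no track positions beyond the anchor edge")

    below = walk_sm <= bg
    i = 0
    n = below.size
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            span = dist[j] - dist[i]
            if span >= run_length or j == n - 1:
                boundary = int(walk_pos[i])
                if i == 0:
                    return BoundaryCall(
                        track.contig, anchor, direction, boundary, 0.0, bg, "at_anchor"
                    )
                return BoundaryCall(
                    track.contig, anchor, direction, boundary, float(dist[i]), bg, "bounded"
                )
            i = j + 1
        else:
            i += 1
    return BoundaryCall(
        track.contig,
        anchor,
        direction,
        int(walk_pos[-1]),
        float(dist[-1]),
        bg,
        "unbounded",
    )


# ---------------------------------------------------------------------------
# response classification


@dataclass
class ResponseCall:
    """Two-condition comparison at one anchor.

    category: ``extended`` (boundary moved out by more than the shift
    threshold with increased signal), ``increased_only`` (more signal, same
    boundary) or ``unchanged``. ``reversed`` flags the mirror case (track b
    retracted relative to a), i.e. "extended" with a negative shift.
    """

    anchor: Feature
    category: str
    boundary_shift: float
    level_ratio: float
    reversed: bool = False


def classify_response(
    track_a: AggregateTrack,
    track_b: AggregateTrack,
    anchor: Feature,
    background_level: float | BackgroundEstimate,
    direction: int = 1,
    shift_threshold: float = 500.0,
    ratio_threshold: float = 1.25,
    run_length: float = 300.0,
) -> ResponseCall:
    """Classify how condition b responds relative to condition a.

    boundary_shift = spread_extent(b) - spread_extent(a); level_ratio is the
    ratio of mean smoothed signal over the shared above-background domain
    (anchor interval plus the spread region both conditions cover).
    """
    bg = float(background_level)
    call_a = call_boundary(track_a, anchor, direction, bg, run_length)
    call_b = call_boundary(track_b, anchor, direction, bg, run_length)
    if call_a.status == "at_anchor" and call_b.status == "at_anchor":
        warnings.warn("both tracks at background beyond the anchor; unchanged")
        return ResponseCall(anchor, "unchanged", 0.0, 1.0)
    shift = call_b.spread_extent - call_a.spread_extent
    shared = min(call_a.spread_extent, call_b.spread_extent)
    if direction == 1:
        lo, hi = anchor.start, anchor.end + shared
    else:
        lo, hi = anchor.start - shared, anchor.end
    means = []
    for t in (track_a, track_b):
        sel = (t.positions >= lo) & (t.positions < hi)
        if not sel.any():
            raise ValueError("no track positions in the shared domain")
        means.append(float(t.smoothed[sel].mean()))
    ratio = means[1] / means[0] if means[0] > 0 else np.inf
    if shift > shift_threshold and ratio > ratio_threshold:
        category = "extended"
        rev = False
    elif shift < -shift_threshold and ratio < 1.0 / ratio_threshold:
        category = "extended"
        rev = True
    elif abs(shift) <= shift_threshold and ratio > ratio_threshold:
        category = "increased_only"
        rev = False
    else:
        category = "unchanged"
        rev = False
    return ResponseCall(anchor, category, float(shift), float(ratio), rev)


# ---------------------------------------------------------------------------
# differential methylation


def differential_positions(
    track_a: AggregateTrack,
    track_b: AggregateTrack,
    min_coverage: int = 10,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-position two-proportion exact test (Fisher) with BH correction.

    Positions failing the coverage floor in either sample are skipped. The
    exact test is used because per-position coverages can sit right at the
    10x floor, where normal approximations are unreliable.
    """
    keys = ["position", "strand"]
    a = track_a.df[keys + ["coverage", "n_methylated"]]
    b = track_b.df[keys + ["coverage", "n_methylated"]]
    merged = a.merge(b, on=keys, suffixes=("_a", "_b"))
    merged = merged[
        (merged["coverage_a"] >= min_coverage) & (merged["coverage_b"] >= min_coverage)
    ].reset_index(drop=True)
    if merged.empty:
        raise ValueError("no shared positions passing the coverage floor")
    pvals = np.empty(len(merged))
    for i, row in enumerate(merged.itertuples(index=False)):
        table = [
            [row.n_methylated_a, row.coverage_a - row.n_methylated_a],
            [row.n_methylated_b, row.coverage_b - row.n_methylated_b],
        ]
        pvals[i] = stats.fisher_exact(table, alternative="two-sided")[1]
    reject, qvals, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    out = merged.assign(
        percent_a=100.0 * merged["n_methylated_a"] / merged["coverage_a"],
        percent_b=100.0 * merged["n_methylated_b"] / merged["coverage_b"],
        p=pvals,
        q=qvals,
        significant=reject,
    )
    out["effect"] = out["percent_b"] - out["percent_a"]
    return out


# ---------------------------------------------------------------------------
# periodicity


@dataclass
class PeriodicityResult:
    """Nucleosome-repeat periodicity of the detrended methylation signal.

    ``repeat_length`` is None when no autocorrelation peak rises above the
    95% permutation band (``significant`` False).
    """

    repeat_length: float | None
    peak_strength: float
    significant: bool
    permutation_threshold: float


def _nearest_grid(pos: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Nearest-neighbor interpolation of irregular values onto a 1 bp grid."""
    grid = np.arange(pos[0], pos[-1] + 1)
    idx = np.searchsorted(pos, grid)
    idx = np.clip(idx, 1, pos.size - 1)
    left = pos[idx - 1]
    right = pos[idx]
    use_left = (grid - left) <= (right - grid)
    return np.where(use_left, values[idx - 1], values[idx])


def _acf(a: np.ndarray, max_lag: int) -> np.ndarray:
    a = a - a.mean()
    var = float(a @ a)
    if var == 0:
        return np.zeros(max_lag + 1)
    return np.array([(a[: a.size - k] @ a[k:]) / var for k in range(max_lag + 1)])


def estimate_periodicity(
    track: AggregateTrack,
    window: tuple[int, int] | None = None,
    max_lag: int = 400,
    min_lag: int = 50,
    n_permutations: int = 100,
    seed: int = 0,
) -> PeriodicityResult:
    """Repeat length from the autocorrelation of the detrended signal.

    The percent track is detrended by its smoothed values, interpolated to a
    1 bp grid (nearest neighbor; adenine spacing is irregular), and the
    repeat length is the lag of the first local maximum of the
    autocorrelation in [min_lag, max_lag]. Significance is assessed against
    a permutation null (residuals shuffled across positions) on the maximum
    autocorrelation over the same lag range.
    """
    df = track.df
    if window is not None:
        df = df[(df["position"] >= window[0]) & (df["position"] < window[1])]
    pos = df["position"].to_numpy()
    if pos.size < 10:
        raise ValueError("insufficient positions")
    if pos[-1] - pos[0] < 5 * max_lag:
        raise ValueError(f"window must span >= 5 * max_lag = {5 * max_lag} bp")
    resid = (df["percent"] - df["smoothed"]).to_numpy(dtype=float)

    acf = _acf(_nearest_grid(pos, resid), max_lag)
    lags = np.arange(min_lag, max_lag)
    local_max = [
        k for k in lags[1:] if acf[k] > acf[k - 1] and acf[k] >= acf[k + 1]
    ]
    rng = derive_rng(seed, "periodicity-permutation")
    null_peaks = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(resid)
        null_peaks[i] = _acf(_nearest_grid(pos, perm), max_lag)[min_lag:max_lag].max()
    threshold = float(np.quantile(null_peaks, 0.95))
    # the repeat length is the first local maximum that rises above the
    # permutation band; small-amplitude noise wiggles below the band are not
    # peaks
    for k in local_max:
        if acf[k] > threshold:
            return PeriodicityResult(float(k), float(acf[k]), True, threshold)
    return PeriodicityResult(None, float(acf[min_lag:max_lag].max()), False, threshold)


# ---------------------------------------------------------------------------
# linker enrichment


@dataclass
class LinkerEnrichment:
    """Linker/core methylation-rate ratio with a read-resampling CI."""

    ratio: float
    ci_low: float
    ci_high: float
    linker_rate: float
    core_rate: float
    n_linker: int
    n_core: int


def linker_enrichment(
    calls: PerReadCallSet,
    dyads: np.ndarray,
    core_halfwidth: int = 73,
    n_boot: int = 200,
    ci: float = 0.95,
    seed: int = 0,
) -> LinkerEnrichment:
    """Methylation-rate ratio between linker and nucleosome-core adenines.

    Calls within +-core_halfwidth of a dyad are core, others linker; rates
    are methylated / emitted calls per class; the CI is a percentile
    bootstrap resampling whole reads.
    """
    if not calls.is_binarized:
        raise ValueError("linker_enrichment requires binarized calls")
    dyads = np.sort(np.asarray(dyads, dtype=np.int64))
    if dyads.size == 0:
        raise ValueError("no dyads given")
    df = calls.df
    pos = df["position"].to_numpy()
    idx = np.clip(np.searchsorted(dyads, pos), 1, dyads.size - 1)
    nearest = np.minimum(np.abs(pos - dyads[idx - 1]), np.abs(dyads[idx] - pos))
    is_core = nearest <= core_halfwidth
    n_core = int(is_core.sum())
    n_linker = int((~is_core).sum())
    if n_core == 0:
        raise ValueError("zero core calls")
    if n_core < 100 or n_linker < 100:
        raise ValueError("need >= 100 calls in each class")
    meth = df["methylated"].to_numpy()
    if meth.sum() == 0:
        raise ValueError("no methylated calls anywhere; ratio undefined")
    core_rate = float(meth[is_core].mean())
    linker_rate = float(meth[~is_core].mean())
    if core_rate == 0:
        raise ValueError("zero methylation in the core class; ratio undefined")
    ratio = linker_rate / core_rate

    per_read = pd.DataFrame(
        {
            "m_core": np.where(is_core, meth, 0),
            "t_core": is_core.astype(int),
            "m_link": np.where(~is_core, meth, 0),
            "t_link": (~is_core).astype(int),
        },
        index=df["read_id"],
    ).groupby(level=0).sum()
    counts = per_read.to_numpy(dtype=float)
    rng = derive_rng(seed, "linker-bootstrap")
    n_reads = counts.shape[0]
    boots = np.empty(n_boot)
    for b in range(n_boot):
        take = rng.integers(0, n_reads, n_reads)
        mc, tc, ml, tl = counts[take].sum(axis=0)
        boots[b] = (ml / tl) / (mc / tc) if tc > 0 and tl > 0 and mc > 0 else np.nan
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.nanquantile(boots, [alpha, 1.0 - alpha])
    return LinkerEnrichment(ratio, float(lo), float(hi), linker_rate, core_rate, n_linker, n_core)


# ---------------------------------------------------------------------------
# establishment onset


def onset_times(
    timecourse: list[tuple[float, AggregateTrack]],
    background_level: float | BackgroundEstimate,
    min_consecutive: int = 2,
) -> pd.DataFrame:
    """Per-position establishment onset over a sampled time course.

    Onset is the earliest sampled time from which the position's percent
    methylation exceeds background for at least ``min_consecutive``
    consecutive sampled times; positions that never sustain an exceedance
    are censored. Raw (unsmoothed) percent values are used.
    """
    times = [t for t, _ in timecourse]
    if times != sorted(times):
        raise ValueError("time points must be sorted ascending")
    if len(times) < 3:
        raise ValueError("need >= 3 time points")
    bg = float(background_level)
    mats = []
    for t, track in timecourse:
        s = track.df.groupby("position")["percent"].mean()
        s.name = t
        mats.append(s)
    wide = pd.concat(mats, axis=1)
    wide = wide[wide.notna().sum(axis=1) >= 3]
    exceed = (wide > bg).fillna(False).to_numpy()
    onset = np.full(len(wide), np.nan)
    for j in range(exceed.shape[1] - min_consecutive + 1):
        run = exceed[:, j : j + min_consecutive].all(axis=1)
        onset = np.where(np.isnan(onset) & run, times[j], onset)
    return pd.DataFrame(
        {
            "position": wide.index.to_numpy(),
            "onset_time": onset,
            "censored": np.isnan(onset),
        }
    )


# ---------------------------------------------------------------------------
# spread length-scale fit


@dataclass
class SpreadFit:
    """Exponential spread fit percent(d) = bg + A exp(-d / lambda)."""

    amplitude: float
    decay_length: float | None
    residual: float
    censored: bool


def fit_spread_model(
    track: AggregateTrack,
    anchor: Feature,
    background_level: float | BackgroundEstimate,
    direction: int = 1,
    min_amplitude: float = 1.0,
) -> SpreadFit:
    """Least-squares exponential decay fit away from the anchor edge.

    Fits the smoothed percent values beyond the anchor edge; the background
    is held fixed at the supplied level. lambda is bounded to [10, 1e5] bp.
    A flat-at-background window (amplitude below ``min_amplitude`` percent)
    is reported censored.
    """
    bg = float(background_level)
    pos = track.positions
    sm = track.smoothed
    edge = anchor.end if direction == 1 else anchor.start - 1
    if direction == 1:
        sel = pos >= edge
        d = (pos[sel] - edge).astype(float)
    else:
        sel = pos <= edge
        d = (edge - pos[sel]).astype(float)
    y = sm[sel]
    above = y > bg
    if above.sum() < 10:
        return SpreadFit(float(max(y.max() - bg, 0.0)) if y.size else 0.0, None, 0.0, True)

    def model(dd, amp, lam):
        return bg + amp * np.exp(-dd / lam)

    a0 = max(float(y.max() - bg), 1e-3)
    try:
        popt, _ = optimize.curve_fit(
            model,
            d,
            y,
            p0=[a0, 500.0],
            bounds=([0.0, 10.0], [200.0, 1e5]),
            maxfev=5000,
        )
    except RuntimeError:
        return SpreadFit(a0, None, np.nan, True)
    amp, lam = float(popt[0]), float(popt[1])
    resid = float(np.sqrt(np.mean((model(d, *popt) - y) ** 2)))
    if amp < min_amplitude:
        return SpreadFit(amp, None, resid, True)
    return SpreadFit(amp, lam, resid, False)
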