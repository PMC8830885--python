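"""Coverage-weighted local-linear smoothing with tricube kernel.

This is a loess-style smoother for irregular genomic position grids. At each
evaluation point the k = ceil(span * n) nearest positions (a contiguous
window in the sorted grid) are fit by weighted linear least squares with
weights w_j * (1 - (d_j/h)^3)^3, where w_j are the observation weights
(coverage) and h is the window radius. The smoother's flexibility is pinned
by the effective number of parameters — the trace of the hat matrix — and
the span is calibrated to it by bisection.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-300


def _neighbor_windows(x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """For each point of sorted ``x``, the start of the contiguous k-window of
    nearest neighbors (two-pointer sweep). Returns (lo, h) with h the window
    radius max|x_j - x_i|."""
    n = x.size
    lo = np.empty(n, dtype=np.int64)
    s = 0
    for i in range(n):
        # advance the window while moving right shrinks the max distance
        while s + k < n and x[s + k] - x[i] < x[i] - x[s]:
            s += 1
        if s > i:
            s = i  # window must contain i
        if s + k <= i:
            s = i - k + 1
        lo[i] = s
    hi = lo + k - 1
    h = np.maximum(x - x[lo], x[hi] - x)
    return lo, h.astype(float)


def _local_linear(
    x: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    k: int,
    need_trace: bool = False,
) -> tuple[np.ndarray, float]:
    """Vectorized local-linear tricube fit evaluated at every point of x."""
    n = x.size
    k = min(max(k, 3), n)
    lo, h = _neighbor_windows(x, k)
    idx = lo[:, None] + np.arange(k)[None, :]
    dx = (x[idx] - x[:, None]).astype(float)
    h = np.maximum(h, 1e-9)
    u = np.abs(dx) / h[:, None]
    kern = np.clip(1.0 - u**3, 0.0, None) ** 3
    W = kern * w[idx]
    S0 = W.sum(axis=1)
    S1 = (W * dx).sum(axis=1)
    S2 = (W * dx * dx).sum(axis=1)
    D = S0 * S2 - S1 * S1
    # fall back to a local weighted mean where the linear system is
    # ill-posed (all kernel mass on one position)
    ok = D > 1e-10 * np.maximum(S0 * S2, 1e-30)
    lin = (W * (S2[:, None] - S1[:, None] * dx)) / np.where(ok, D, 1.0)[:, None]
    const = W / S0[:, None]
    coef = np.where(ok[:, None], lin, const)
    fitted = (coef * y[idx]).sum(axis=1)
    trace = 0.0
    if need_trace:
        self_col = np.argmax(idx == np.arange(n)[:, None], axis=1)
        trace = float(coef[np.arange(n), self_col].sum())
    return fitted, trace


def hat_trace(x: np.ndarray, w: np.ndarray, span: float, subgrid: int | None = 2000) -> float:
    """Effective number of parameters (trace of the hat matrix) at ``span``.

    On tracks longer than 5000 positions the per-point self-weights are
    evaluated on a uniformly thinned subgrid of evaluation points and scaled
    up; the local fits themselves still use the full grid.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    n = x.size
    k = min(max(int(np.ceil(span * n)), 3), n)
    lo, h = _neighbor_windows(x, k)
    if subgrid is not None and n > 5000:
        eval_idx = np.unique(np.linspace(0, n - 1, subgrid).astype(np.int64))
    else:
        eval_idx = np.arange(n)
    idx = lo[eval_idx, None] + np.arange(k)[None, :]
    dx = x[idx] - x[eval_idx, None]
    hh = np.maximum(h[eval_idx], 1e-9)
    u = np.abs(dx) / hh[:, None]
    kern = np.clip(1.0 - u**3, 0.0, None) ** 3
    W = kern * w[idx]
    S0 = W.sum(axis=1)
    S1 = (W * dx).sum(axis=1)
    S2 = (W * dx * dx).sum(axis=1)
    D = S0 * S2 - S1 * S1
    ok = D > 1e-10 * np.maximum(S0 * S2, 1e-30)
    self_col = np.argmax(idx == eval_idx[:, None], axis=1)
    rows = np.arange(eval_idx.size)
    w_self = W[rows, self_col]
    l_lin = (w_self * (S2 - S1 * dx[rows, self_col])) / np.where(ok, D, 1.0)
    l_ii = np.where(ok, l_lin, w_self / S0)
    return float(l_ii.mean() * n)


def calibrate_span(
    x: np.ndarray,
    w: np.ndarray,
    enp_target: float,
    tol: float = 2.0,
    max_iter: int = 50,
) -> float:
    """Bisection on span so the hat-matrix trace is within ``tol`` of target.

    The trace decreases monotonically in span (larger windows, stiffer fit).
    """
    n = len(x)
    if enp_target >= n:
        raise ValueError(
            f"effective_parameters ({enp_target}) must be < number of positions "
            f"({n}); pin the span instead"
        )
    lo_span, hi_span = 3.0 / n, 1.0
    t_lo = hat_trace(x, w, lo_span)
    if t_lo < enp_target:
        raise ValueError(
            f"cannot reach enp {enp_target} (max attainable ~{t_lo:.1f}); "
            "pin the span instead"
        )
    for _ in range(max_iter):
        mid = np.sqrt(lo_span * hi_span)
        t = hat_trace(x, w, mid)
        if abs(t - enp_target) <= tol:
            return float(mid)
        if t > enp_target:
            lo_span = mid
        else:
            hi_span = mid
    return float(np.sqrt(lo_span * hi_span))


def loess_smooth(
    x: np.ndarray,
    y: np.ndarray,
    w: np.ndarray | None = None,
    span: float | None = None,
    enp_target: float | None = 100.0,
) -> tuple[np.ndarray, float]:
    """Smooth y(x) with observation weights w; returns (fitted, span_used).

    Either pin ``span`` directly or give ``enp_target`` to calibrate it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if w is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(w, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 positions to smooth")
    if span is None:
        if enp_target is None:
            raise ValueError("give span or enp_target")
        span = calibrate_span(x, w, enp_target)
    k = int(np.ceil(span * x.size))
    fitted, _ = _local_linear(x, y, w, k)
    return fitted, float(span)
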