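"""Replicate-level recovery evaluations of the pipeline on simulated truth.

Each function runs the full pipeline (simulate -> binarize -> aggregate ->
filter -> smooth -> infer) over seeded replicates of one scenario and
summarizes how well the inference recovers the simulated ground truth:
boundary position, spread-versus-recruitment contrast, boundary fixity
under overexpression, spread decay length, establishment-onset ordering,
differential-test calibration, periodicity, and emission consistency.

The loess span is calibrated to the effective-parameter target on the first
replicate of a scenario and pinned for the remaining replicates (the grids
are draws from the same genome, so the calibrated span is a property of the
scenario, not of a replicate).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import scenarios as sc
from .aggregate import AggregateTrack
from .inference import (
    call_boundary,
    classify_response,
    differential_positions,
    estimate_background,
    estimate_periodicity,
    fit_spread_model,
    onset_times,
)
from .annotation import derive_rng
from .perread import binarize_calls
from .simulate import simulate_timecourse


def _rep_seed(seed: int, i: int) -> int:
    return int((seed * 100_003 + 7 * i + 1) % (2**31 - 1))


def emission_consistency(seed: int = 0, coverage: float = 30.0, fpr: float = 0.01) -> dict:
    """Genome-wide binarized fraction under zero occupancy vs the FPR."""
    s = sc.control_scenario(seed=seed, coverage=coverage, fpr=fpr)
    binary = binarize_calls(s.simulate())
    n = len(binary)
    frac = float(binary.df["methylated"].mean())
    se = float(np.sqrt(fpr * (1 - fpr) / n))
    return {
        "observed_fraction": frac,
        "expected_fraction": fpr,
        "n_calls": n,
        "binomial_se": se,
        "abs_error_in_se": abs(frac - fpr) / se,
    }


def boundary_recovery(
    n_reps: int = 100, seed: int = 0, tolerance_bp: float = 250.0
) -> dict:
    """Boundary-position recovery with a fully attenuating element at 5 kb."""
    span = None
    errors = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_reps):
            s = sc.boundary_scenario(seed=_rep_seed(seed, i))
            calls = s.simulate()
            track = sc.methylation_track(calls, span=span)
            span = track.meta["span"]
            bg = estimate_background(
                sc.methylation_track(calls, contig=sc.CTRL, smooth=False)
            )
            bc = call_boundary(track, s.anchors["anchor"], 1, bg)
            errors.append(bc.spread_extent - s.params["true_extent"])
    errors = np.array(errors)
    hits = np.abs(errors) <= tolerance_bp
    return {
        "n_reps": n_reps,
        "hit_rate": float(hits.mean()),
        "n_hits": int(hits.sum()),
        "mean_abs_error_bp": float(np.abs(errors).mean()),
        "max_abs_error_bp": float(np.abs(errors).max()),
    }


def contrast_recovery(n_reps: int = 100, seed: int = 0) -> dict:
    """Recruitment-without-spread contrast: spread-deficient < wild type at
    every anchor, with matched anchor-interval methylation."""
    span = None
    ordering_ok = []
    anchor_rel_diffs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_reps):
            wt, mut = sc.contrast_scenarios(seed=_rep_seed(seed, i))
            cw, cm = wt.simulate(), mut.simulate()
            tw = sc.methylation_track(cw, span=span)
            span = tw.meta["span"]
            tm = sc.methylation_track(cm, span=span)
            bgw = estimate_background(sc.methylation_track(cw, contig=sc.CTRL, smooth=False))
            bgm = estimate_background(sc.methylation_track(cm, contig=sc.CTRL, smooth=False))
            ok = True
            rep_diffs = []
            for name, direction in wt.params["directions"].items():
                bw = call_boundary(tw, wt.anchors[name], direction, bgw)
                bm = call_boundary(tm, mut.anchors[name], direction, bgm)
                if not bm.spread_extent < bw.spread_extent:
                    ok = False
                a = wt.anchors[name]
                mw = tw.df[(tw.df.position >= a.start) & (tw.df.position < a.end)]["percent"].mean()
                mm = tm.df[(tm.df.position >= a.start) & (tm.df.position < a.end)]["percent"].mean()
                rep_diffs.append(abs(mw - mm) / mw)
            ordering_ok.append(ok and max(rep_diffs) < 0.10)
            anchor_rel_diffs.extend(rep_diffs)
    return {
        "n_reps": n_reps,
        "success_rate": float(np.mean(ordering_ok)),
        "n_success": int(np.sum(ordering_ok)),
        "max_anchor_rel_diff": float(np.max(anchor_rel_diffs)),
        "mean_anchor_rel_diff": float(np.mean(anchor_rel_diffs)),
    }


def overexpression_fixity(n_reps: int = 100, seed: int = 0) -> dict:
    """Doubled peak occupancy against a fixed boundary element."""
    span = None
    results = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_reps):
            base, over = sc.overexpression_scenarios(seed=_rep_seed(seed, i))
            ca, cb = base.simulate(), over.simulate()
            ta = sc.methylation_track(ca, span=span)
            span = ta.meta["span"]
            tb = sc.methylation_track(cb, span=span)
            bg = estimate_background(sc.methylation_track(ca, contig=sc.CTRL, smooth=False))
            r = classify_response(ta, tb, base.anchors["anchor"], bg)
            results.append((r.category, abs(r.boundary_shift)))
    ok = [c == "increased_only" and s <= 500.0 for c, s in results]
    return {
        "n_reps": n_reps,
        "success_rate": float(np.mean(ok)),
        "n_success": int(np.sum(ok)),
        "max_abs_shift_bp": float(max(s for _, s in results)),
        "categories": {c: sum(1 for cc, _ in results if cc == c) for c in {c for c, _ in results}},
    }


def lambda_recovery(
    n_reps: int = 100, seed: int = 0, decay_length: float = 800.0, rel_tol: float = 0.15
) -> dict:
    """Spread decay-length recovery by exponential fitting."""
    span = None
    estimates = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_reps):
            s = sc.lambda_scenario(seed=_rep_seed(seed, i), decay_length=decay_length)
            calls = s.simulate()
            track = sc.methylation_track(calls, span=span)
            span = track.meta["span"]
            bg = estimate_background(
                sc.methylation_track(calls, contig=sc.CTRL, smooth=False), k=0
            )
            fit = fit_spread_model(track, s.anchors["anchor"], bg)
            estimates.append(np.nan if fit.decay_length is None else fit.decay_length)
    estimates = np.array(estimates)
    rel_err = np.abs(estimates - decay_length) / decay_length
    hits = rel_err <= rel_tol
    return {
        "n_reps": n_reps,
        "hit_rate": float(np.mean(hits)),
        "n_hits": int(np.sum(hits)),
        "median_lambda_hat": float(np.nanmedian(estimates)),
        "max_rel_error": float(np.nanmax(rel_err)),
    }


def onset_ordering(n_reps: int = 100, seed: int = 0) -> dict:
    """Establishment onset: recruitment sites before interior positions."""
    ok = []
    medians = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_reps):
            s = sc.timecourse_scenario(seed=_rep_seed(seed, i))
            course = simulate_timecourse(
                s.annotation, s.model, s.emission, s.sampler, s.params["times"]
            )
            tracks = [(t, sc.methylation_track(c, smooth=False)) for t, c in course]
            bg = estimate_background(
                sc.methylation_track(course[0][1], contig=sc.CTRL, smooth=False)
            )
            tab = onset_times(tracks, bg)
            pos = tab["position"].to_numpy()
            onset = np.where(tab["censored"], np.inf, tab["onset_time"])

            def _median(intervals):
                m = np.zeros(pos.size, bool)
                for a, b in intervals:
                    m |= (pos >= a) & (pos < b)
                return float(np.median(onset[m]))

            m_rec = _median(s.params["recruitment"])
            m_int = _median(s.params["interior"])
            medians.append((m_rec, m_int))
            ok.append(m_rec < m_int)
    return {
        "n_reps": n_reps,
        "success_rate": float(np.mean(ok)),
        "n_success": int(np.sum(ok)),
        "median_recruitment_onset_min": float(np.median([a for a, _ in medians])),
        "median_interior_onset_min": float(
            np.median([b for _, b in medians if np.isfinite(b)] or [np.inf])
        ),
    }


def differential_null_calibration(
    n_reps: int = 100, seed: int = 0, n_positions: int = 200, fdr: float = 0.05
) -> dict:
    """Type-I control: both samples drawn from one truth; BH at the given FDR."""
    rng = derive_rng(seed, "differential-null")
    truth = rng.uniform(0.05, 0.6, n_positions)
    fp_rates = []
    for _ in range(n_reps):
        cov_a = rng.poisson(30, n_positions) + 10
        cov_b = rng.poisson(30, n_positions) + 10
        tracks = []
        for cov in (cov_a, cov_b):
            nm = rng.binomial(cov, truth)
            tracks.append(
                AggregateTrack(
                    "c",
                    pd.DataFrame(
                        {
                            "position": np.arange(n_positions),
                            "strand": ".",
                            "coverage": cov,
                            "n_methylated": nm,
                            "percent": 100.0 * nm / cov,
                        }
                    ),
                )
            )
        out = differential_positions(tracks[0], tracks[1], fdr=fdr)
        fp_rates.append(out["significant"].mean())
    return {
        "n_reps": n_reps,
        "n_positions": n_positions,
        "mean_false_positive_proportion": float(np.mean(fp_rates)),
        "max_false_positive_proportion": float(np.max(fp_rates)),
        "nominal_fdr": fdr,
    }


def periodicity_recovery(seed: int = 0, coverage: float = 100.0, nrl: int = 165) -> dict:
    """Repeat-length recovery plus the white-noise (no dyad) control."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        s = sc.periodicity_scenario(seed=_rep_seed(seed, 0), coverage=coverage, nrl=nrl)
        track = sc.methylation_track(s.simulate())
        res = estimate_periodicity(track, window=(1000, 25_000), seed=seed)
        s0 = sc.periodicity_scenario(seed=_rep_seed(seed, 1), coverage=coverage, with_dyads=False)
        track0 = sc.methylation_track(s0.simulate())
        res0 = estimate_periodicity(track0, window=(1000, 25_000), seed=seed)
    return {
        "true_repeat_bp": nrl,
        "estimated_repeat_bp": res.repeat_length,
        "peak_strength": res.peak_strength,
        "significant": bool(res.significant),
        "control_significant": bool(res0.significant),
        "control_repeat_bp": res0.repeat_length,
    }
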