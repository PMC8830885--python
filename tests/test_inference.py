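import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sirspread as ss
from sirspread import scenarios as sc
from sirspread.aggregate import AggregateTrack
from sirspread.annotation import Feature
from sirspread.calls import PerReadCallSet
from sirspread.inference import (
    call_boundary,
    classify_response,
    differential_positions,
    estimate_background,
    estimate_periodicity,
    fit_spread_model,
    linker_enrichment,
    onset_times,
)
from sirspread.models import EmissionModel, OccupancyModel, ReadSamplerConfig
from sirspread.perread import binarize_calls
from sirspread.simulate import simulate_reads


def _smoothed_track(positions, smoothed, percent=None, coverage=30):
    df = pd.DataFrame(
        {
            "position": positions,
            "strand": ".",
            "coverage": coverage,
            "percent": smoothed if percent is None else percent,
            "smoothed": smoothed,
        }
    )
    return AggregateTrack("c", df)


ANCHOR = Feature("c", 900, 1000, ".", "silencer", "anchor")


class TestBackground:
    def test_constant_control(self):
        track = _smoothed_track(np.arange(30), np.full(30, 1.0))
        bg = estimate_background(track)
        assert bg.level == 1.0 and bg.sd == 0.0 and bg.n == 30

    def test_k_zero_is_mean(self, rng):
        vals = rng.random(50) * 4
        track = _smoothed_track(np.arange(50), vals)
        assert estimate_background(track, k=0).level == pytest.approx(vals.mean())

    def test_too_few_positions(self):
        track = _smoothed_track(np.arange(10), np.ones(10))
        with pytest.raises(ValueError, match="20"):
            estimate_background(track)

    def test_simulated_control_near_fpr(self):
        s = sc.control_scenario(seed=5, coverage=100, length=8000)
        track = sc.methylation_track(s.simulate(), contig=sc.SIM, smooth=False)
        bg = estimate_background(track, k=0)
        assert 0.5 <= bg.level <= 2.5


class TestCallBoundary:
    def test_all_background_is_at_anchor(self):
        track = _smoothed_track(np.arange(0, 5000, 2), np.full(2500, 1.0))
        bc = call_boundary(track, ANCHOR, 1, 2.0)
        assert bc.status == "at_anchor" and bc.spread_extent == 0.0

    def test_above_background_throughout_is_unbounded(self):
        track = _smoothed_track(np.arange(0, 5000, 2), np.full(2500, 50.0))
        bc = call_boundary(track, ANCHOR, 1, 2.0)
        assert bc.status == "unbounded"
        assert bc.boundary_position == 4998

    def test_step_track_boundary_located(self):
        pos = np.arange(0, 6000, 2)
        sm = np.where(pos < 3000, 40.0, 1.0)
        bc = call_boundary(_smoothed_track(pos, sm), ANCHOR, 1, 2.0)
        assert bc.status == "bounded"
        assert abs(bc.boundary_position - 3000) <= 2

    def test_short_dip_not_a_boundary(self):
        pos = np.arange(0, 6000, 2)
        sm = np.where(pos < 3000, 40.0, 1.0)
        sm[(pos >= 1500) & (pos < 1600)] = 0.5  # 100 bp dip < run length
        bc = call_boundary(_smoothed_track(pos, sm), ANCHOR, 1, 2.0, run_length=300)
        assert abs(bc.boundary_position - 3000) <= 2

    def test_leftward_direction(self):
        pos = np.arange(0, 6000, 2)
        anchor = Feature("c", 5000, 5100, ".", "silencer", "a")
        sm = np.where(pos > 2000, 40.0, 1.0)
        bc = call_boundary(_smoothed_track(pos, sm), anchor, -1, 2.0)
        assert bc.status == "bounded"
        assert abs(bc.spread_extent - (4999 - 2000)) <= 2

    def test_monotone_in_background(self, rng):
        pos = np.arange(0, 6000, 3)
        sm = 40 * np.exp(-pos / 1500) + rng.random(pos.size)
        track = _smoothed_track(pos, sm)
        anchor = Feature("c", 0, 10, ".", "silencer", "a")
        extents = [
            call_boundary(track, anchor, 1, bg).spread_extent for bg in (1.0, 2.0, 5.0, 10.0)
        ]
        assert all(e2 <= e1 for e1, e2 in zip(extents, extents[1:]))

    def test_anchor_outside_window(self):
        track = _smoothed_track(np.arange(100), np.ones(100))
        with pytest.raises(ValueError, match="anchor"):
            call_boundary(track, Feature("c", 5000, 5100, ".", "silencer", "a"), 1, 2.0)

    def test_recovers_simulated_boundary(self, sim_scenario, sim_calls):
        track = sc.methylation_track(sim_calls)
        bg = estimate_background(sc.methylation_track(sim_calls, contig=sc.CTRL, smooth=False))
        bc = call_boundary(track, sim_scenario.anchors["anchor"], 1, bg)
        assert bc.status == "bounded"
        assert abs(bc.spread_extent - sim_scenario.params["true_extent"]) <= 250


class TestClassifyResponse:
    def test_identical_tracks_unchanged(self):
        pos = np.arange(0, 6000, 2)
        sm = np.where(pos < 3000, 40.0, 1.0)
        t = _smoothed_track(pos, sm)
        r = classify_response(t, t, ANCHOR, 2.0)
        assert r.category == "unchanged"
        assert r.boundary_shift == 0.0 and r.level_ratio == pytest.approx(1.0)

    def test_increase_without_extension(self):
        pos = np.arange(0, 6000, 2)
        a = _smoothed_track(pos, np.where(pos < 3000, 20.0, 1.0))
        b = _smoothed_track(pos, np.where(pos < 3000, 40.0, 1.0))
        r = classify_response(a, b, ANCHOR, 2.0)
        assert r.category == "increased_only"
        assert abs(r.boundary_shift) <= 10 and r.level_ratio == pytest.approx(2.0, rel=0.01)

    def test_extension_with_increase(self):
        pos = np.arange(0, 8000, 2)
        a = _smoothed_track(pos, np.where(pos < 3000, 20.0, 1.0))
        b = _smoothed_track(pos, np.where(pos < 4800, 40.0, 1.0))
        r = classify_response(a, b, ANCHOR, 2.0)
        assert r.category == "extended" and r.boundary_shift == pytest.approx(1800, abs=10)

    def test_swap_symmetry_flags_reversal(self):
        pos = np.arange(0, 8000, 2)
        a = _smoothed_track(pos, np.where(pos < 3000, 20.0, 1.0))
        b = _smoothed_track(pos, np.where(pos < 4800, 40.0, 1.0))
        fwd = classify_response(a, b, ANCHOR, 2.0)
        rev = classify_response(b, a, ANCHOR, 2.0)
        assert fwd.category == "extended" and not fwd.reversed
        assert rev.category == "extended" and rev.reversed
        assert rev.boundary_shift == pytest.approx(-fwd.boundary_shift)

    def test_background_only_warns_unchanged(self):
        pos = np.arange(0, 4000, 2)
        t = _smoothed_track(pos, np.ones(pos.size))
        with pytest.warns(UserWarning):
            r = classify_response(t, t, ANCHOR, 2.0)
        assert r.category == "unchanged"


class TestDifferential:
    def test_identical_counts_nothing_significant(self):
        df = pd.DataFrame(
            {
                "position": np.arange(50),
                "strand": ".",
                "coverage": 30,
                "percent": 50.0,
            }
        )
        t = AggregateTrack("c", df)
        out = differential_positions(t, t)
        assert out["significant"].sum() == 0
        assert np.allclose(out["p"], 1.0)

    def test_strong_difference_detected(self):
        def mk(nm):
            return AggregateTrack(
                "c",
                pd.DataFrame(
                    {
                        "position": [1],
                        "strand": ".",
                        "coverage": [100],
                        "n_methylated": [nm],
                        "percent": [nm * 1.0],
                    }
                ),
            )

        out = differential_positions(mk(90), mk(10))
        assert out["p"].iloc[0] < 1e-10
        assert bool(out["significant"].iloc[0])
        # closed-form hypergeometric oracle for the one-sided tail, doubled
        tail = stats.hypergeom(200, 100, 100).cdf(10)
        assert out["p"].iloc[0] <= 2 * tail * 1.0001

    def test_coverage_floor_skips_positions(self):
        df = pd.DataFrame(
            {
                "position": [1, 2],
                "strand": ".",
                "coverage": [5, 30],
                "percent": [0.0, 50.0],
            }
        )
        t = AggregateTrack("c", df)
        out = differential_positions(t, t, min_coverage=10)
        assert out["position"].tolist() == [2]

    def test_no_shared_positions(self):
        t1 = AggregateTrack(
            "c", pd.DataFrame({"position": [1], "strand": ".", "coverage": [30], "percent": [10.0]})
        )
        t2 = AggregateTrack(
            "c", pd.DataFrame({"position": [2], "strand": ".", "coverage": [30], "percent": [10.0]})
        )
        with pytest.raises(ValueError, match="shared"):
            differential_positions(t1, t2)


class TestPeriodicity:
    def test_pure_cosine_recovered(self, rng):
        pos = np.sort(rng.choice(np.arange(8000), 4000, replace=False))
        signal = 10 * np.cos(2 * np.pi * pos / 165.0)
        track = _smoothed_track(pos, np.zeros(pos.size), percent=signal)
        res = estimate_periodicity(track, seed=1)
        assert res.significant
        assert abs(res.repeat_length - 165) <= 5

    def test_white_noise_flagged_none(self, rng):
        pos = np.sort(rng.choice(np.arange(8000), 4000, replace=False))
        track = _smoothed_track(pos, np.zeros(pos.size), percent=rng.normal(0, 5, pos.size))
        res = estimate_periodicity(track, seed=1)
        assert res.repeat_length is None and not res.significant

    def test_window_too_small(self):
        track = _smoothed_track(np.arange(0, 900, 2), np.zeros(450))
        with pytest.raises(ValueError, match="5"):
            estimate_periodicity(track)


class TestLinkerEnrichment:
    def _uniform_sim(self, core_acc, seed=0, coverage=150):
        site = Feature("c", 0, 5000, ".", "silencer", "s")
        from sirspread.annotation import make_annotation

        ann = make_annotation({"c": 5000}, [site], dyad_spacing={"c": 165}, seed=0)
        model = OccupancyModel(
            recruitment_sites=[(site, 0.9)],
            core_accessibility=core_acc,
            linker_accessibility=1.0 if core_acc < 1.0 else 1.0,
            background_occupancy=0.0,
        )
        calls = simulate_reads(
            ann, model, EmissionModel(), ReadSamplerConfig(target_coverage=coverage, seed=seed)
        )
        return binarize_calls(calls), ann.nucleosome_dyads["c"]

    def test_no_effect_ci_contains_one(self):
        calls, dyads = self._uniform_sim(core_acc=1.0, seed=3)
        res = linker_enrichment(calls, dyads)
        assert res.ci_low <= 1.0 <= res.ci_high

    def test_fivefold_effect_recovered(self):
        calls, dyads = self._uniform_sim(core_acc=0.2, seed=4, coverage=200)
        res = linker_enrichment(calls, dyads)
        assert 4.0 <= res.ratio <= 6.0

    def test_zero_methylation_errors(self):
        calls, dyads = self._uniform_sim(core_acc=1.0, seed=5)
        df = calls.df.copy()
        df["methylated"] = False
        with pytest.raises(ValueError, match="undefined|no methylated"):
            linker_enrichment(PerReadCallSet(df, threshold=0.8), dyads)


class TestOnset:
    def _course(self, series):
        """series: {pos: [percent at each time]} at times 0/15/45/90."""
        times = [0.0, 15.0, 45.0, 90.0]
        out = []
        for i, t in enumerate(times):
            df = pd.DataFrame(
                {
                    "position": list(series),
                    "strand": ".",
                    "coverage": 30,
                    "percent": [series[p][i] for p in series],
                }
            )
            out.append((t, AggregateTrack("c", df)))
        return out

    def test_always_exceeding_onsets_at_first_time(self):
        tab = onset_times(self._course({1: [10, 10, 10, 10]}), 2.0)
        assert tab["onset_time"].iloc[0] == 0.0

    def test_never_exceeding_censored(self):
        tab = onset_times(self._course({1: [1, 1, 1, 1]}), 2.0)
        assert bool(tab["censored"].iloc[0])

    def test_requires_sustained_exceedance(self):
        # one isolated blip does not count; onset at the sustained rise
        tab = onset_times(self._course({1: [1, 10, 1, 1], 2: [1, 1, 10, 10]}), 2.0)
        t = tab.set_index("position")
        assert bool(t.loc[1, "censored"])
        assert t.loc[2, "onset_time"] == 45.0

    def test_unsorted_times_rejected(self):
        course = self._course({1: [1, 1, 1, 1]})
        with pytest.raises(ValueError, match="sorted"):
            onset_times([course[1], course[0], course[2]], 2.0)

    def test_recruitment_before_interior_in_simulation(self):
        s = sc.timecourse_scenario(seed=8)
        from sirspread.simulate import simulate_timecourse

        course = simulate_timecourse(
            s.annotation, s.model, s.emission, s.sampler, sc.TIMECOURSE_TIMES
        )
        tracks = [(t, sc.methylation_track(c, smooth=False)) for t, c in course]
        bg = estimate_background(
            sc.methylation_track(course[0][1], contig=sc.CTRL, smooth=False)
        )
        tab = onset_times(tracks, bg)
        pos = tab["position"].to_numpy()
        onset = np.where(tab["censored"], np.inf, tab["onset_time"])

        def median_over(intervals):
            m = np.zeros(pos.size, bool)
            for a, b in intervals:
                m |= (pos >= a) & (pos < b)
            return np.median(onset[m])

        assert median_over(s.params["recruitment"]) < median_over(s.params["interior"])


class TestSpreadFit:
    def test_noiseless_exponential_recovered(self):
        pos = np.arange(0, 8000, 3)
        anchor = Feature("c", 0, 100, ".", "silencer", "a")
        d = np.clip(pos - 100, 0, None)
        sm = 2.0 + 60.0 * np.exp(-d / 800.0)
        fit = fit_spread_model(_smoothed_track(pos, sm), anchor, 2.0)
        assert not fit.censored
        assert fit.decay_length == pytest.approx(800.0, abs=1.0)
        assert fit.amplitude == pytest.approx(60.0, rel=0.01)

    def test_flat_track_censored(self):
        pos = np.arange(0, 8000, 3)
        anchor = Feature("c", 0, 100, ".", "silencer", "a")
        fit = fit_spread_model(_smoothed_track(pos, np.full(pos.size, 2.0)), anchor, 2.0)
        assert fit.censored and fit.decay_length is None

    def test_simulated_lambda_recovered(self):
        s = sc.lambda_scenario(seed=11)
        calls = s.simulate()
        track = sc.methylation_track(calls)
        bg = estimate_background(
            sc.methylation_track(calls, contig=sc.CTRL, smooth=False), k=0
        )
        fit = fit_spread_model(track, s.anchors["anchor"], bg)
        assert abs(fit.decay_length - 800.0) / 800.0 <= 0.15
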