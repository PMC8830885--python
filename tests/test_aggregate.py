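import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sirspread.aggregate import (
    AggregateTrack,
    aggregate_fraction,
    filter_coverage,
    genotype_overlay,
    merge_strand_track,
    normalize_chip,
    smooth_track,
)
from sirspread.calls import PerReadCallSet
from sirspread.io_formats import CoverageTrack
from sirspread.perread import binarize_calls
from sirspread.smoothing import calibrate_span, hat_trace, loess_smooth


def _track(positions, percents, coverages, strand="."):
    return AggregateTrack(
        "c",
        pd.DataFrame(
            {
                "position": positions,
                "strand": strand,
                "coverage": coverages,
                "percent": percents,
            }
        ),
    )


def _mini_calls(per_position):
    """per_position: {pos: (n_meth, n_total)} -> binarized call set."""
    recs = []
    for pos, (nm, nt) in per_position.items():
        for i in range(nt):
            recs.append((f"r{pos}_{i}", pos, 0.95 if i < nm else 0.05))
    return binarize_calls(
        PerReadCallSet.from_arrays(
            [r[0] for r in recs], "c", "+", [r[1] for r in recs], [r[2] for r in recs]
        )
    )


class TestAggregateFraction:
    def test_simple_fractions(self):
        track = aggregate_fraction(_mini_calls({10: (2, 5), 20: (0, 10)}))
        df = track.df.set_index("position")
        assert df.loc[10, "percent"] == 40.0 and df.loc[10, "coverage"] == 5
        assert df.loc[20, "percent"] == 0.0 and df.loc[20, "coverage"] == 10

    def test_matches_brute_force_recount(self, sim_calls):
        binary = binarize_calls(sim_calls)
        track = aggregate_fraction(binary, region="chrSim")
        sub = binary.df[binary.df["contig"] == "chrSim"]
        # independent recount with a dict loop
        counts = {}
        for pos, strand, meth in zip(sub["position"], sub["strand"], sub["methylated"]):
            cov, nm = counts.get((pos, strand), (0, 0))
            counts[(pos, strand)] = (cov + 1, nm + int(meth))
        assert len(track) == len(counts)
        df = track.df.set_index(["position", "strand"])
        for (pos, strand), (cov, nm) in list(counts.items())[::37]:
            row = df.loc[(pos, strand)]
            assert row["coverage"] == cov and row["n_methylated"] == nm
            assert row["percent"] == pytest.approx(100.0 * nm / cov)

    def test_merge_strands_sums_counts(self, sim_calls):
        binary = binarize_calls(sim_calls)
        separate = aggregate_fraction(binary, region="chrSim")
        merged = aggregate_fraction(binary, region="chrSim", merge_strands=True)
        assert merged.df["coverage"].sum() == separate.df["coverage"].sum()
        assert merged.df["position"].is_unique
        assert merge_strand_track(separate).df["coverage"].equals(merged.df["coverage"])


class TestFilterCoverage:
    def test_inclusive_threshold(self):
        track = _track([1, 2, 3], [10.0, 20.0, 30.0], [9, 10, 11])
        kept = filter_coverage(track, 10)
        assert kept.positions.tolist() == [2, 3]
        # values untouched
        assert kept.df["percent"].tolist() == [20.0, 30.0]

    def test_empty_track(self):
        track = _track([], [], [])
        assert len(filter_coverage(track, 10)) == 0

    def test_min_coverage_validated(self):
        with pytest.raises(ValueError):
            filter_coverage(_track([1], [1.0], [5]), 0)

    @given(m1=st.integers(1, 30), m2=st.integers(1, 30))
    def test_monotone_subset(self, m1, m2, rng):
        cov = rng.integers(1, 40, 50)
        track = _track(np.arange(50), rng.random(50) * 100, cov)
        lo, hi = sorted([m1, m2])
        keep_lo = set(filter_coverage(track, lo).positions)
        keep_hi = set(filter_coverage(track, hi).positions)
        assert keep_hi <= keep_lo


class TestSmoothing:
    def test_constant_reproduced(self):
        track = _track(np.arange(0, 500, 3), np.full(167, 37.0), np.full(167, 20))
        sm = smooth_track(track, effective_parameters=20)
        assert np.allclose(sm.smoothed, 37.0, atol=1e-9)

    def test_linear_ramp_reproduced(self):
        x = np.arange(0, 1000, 2)
        track = _track(x, 0.05 * x + 3.0, np.full(x.size, 10))
        sm = smooth_track(track, effective_parameters=20)
        assert np.allclose(sm.smoothed, 0.05 * x + 3.0, atol=1e-8)

    def test_matches_per_point_wls_oracle(self, rng):
        # independent oracle: per-point tricube-weighted lstsq fit
        n = 500
        x = np.sort(rng.choice(np.arange(5000), n, replace=False)).astype(float)
        y = rng.random(n) * 100
        w = rng.integers(10, 60, n).astype(float)
        span = 0.3
        fitted, _ = loess_smooth(x, y, w, span=span)
        k = int(np.ceil(span * n))
        for i in range(0, n, 23):
            d = np.abs(x - x[i])
            idx = np.argsort(d, kind="mergesort")[:k]
            h = d[idx].max()
            tric = np.clip(1 - (d[idx] / h) ** 3, 0, None) ** 3
            ww = tric * w[idx]
            X = np.column_stack([np.ones(k), x[idx] - x[i]])
            beta, *_ = np.linalg.lstsq(X * np.sqrt(ww)[:, None], y[idx] * np.sqrt(ww), rcond=None)
            assert fitted[i] == pytest.approx(beta[0], abs=1e-8)

    def test_enp_calibration_hits_target(self, rng):
        x = np.sort(rng.choice(np.arange(8000), 600, replace=False)).astype(float)
        w = rng.integers(10, 40, 600).astype(float)
        span = calibrate_span(x, w, 30.0)
        assert abs(hat_trace(x, w, span) - 30.0) <= 2.0

    def test_enp_exceeding_positions_errors(self):
        track = _track(np.arange(0, 50), np.random.default_rng(0).random(50), np.full(50, 10))
        with pytest.raises(ValueError, match="span"):
            smooth_track(track, effective_parameters=200)

    def test_coverage_weight_scale_invariance(self, rng):
        x = np.sort(rng.choice(np.arange(3000), 300, replace=False))
        y = rng.random(300) * 100
        cov = rng.integers(10, 50, 300)
        t1 = smooth_track(_track(x, y, cov), span=0.2)
        t2 = smooth_track(_track(x, y, cov * 2), span=0.2)
        assert np.allclose(t1.smoothed, t2.smoothed, atol=1e-9)

    def test_smoothed_within_local_range_interior(self, rng):
        x = np.sort(rng.choice(np.arange(6000), 400, replace=False))
        y = rng.random(400) * 100
        track = _track(x, y, np.full(400, 20))
        sm = smooth_track(track, span=0.1)
        k = int(np.ceil(0.1 * 400))
        viol = 0
        for i in range(k, 400 - k):
            lo, hi = y[i - k : i + k + 1].min(), y[i - k : i + k + 1].max()
            if not (lo - 1e-9 <= sm.smoothed[i] <= hi + 1e-9):
                viol += 1
        assert viol == 0

    def test_too_few_positions(self):
        with pytest.raises(ValueError, match="3"):
            smooth_track(_track([1, 2], [1.0, 2.0], [10, 10]))

    def test_cross_check_against_base_r_loess(self, tmp_path):
        """Independent cross-implementation check: base-R loess() at the
        same effective-parameter target and coverage weights agrees closely
        (the two smoothers pick their spans independently)."""
        import subprocess

        rng = np.random.default_rng(3)
        n = 400
        x = np.sort(rng.choice(np.arange(4000), n, replace=False)).astype(float)
        y = 30 + 20 * np.sin(x / 300) + rng.normal(0, 3, n)
        w = rng.integers(10, 50, n).astype(float)
        fitted, _ = loess_smooth(x, y, w, enp_target=20.0)

        fixture = tmp_path / "d.tsv"
        np.savetxt(fixture, np.column_stack([x, y, w]), delimiter="\t", header="x\ty\tw", comments="")
        script = tmp_path / "fit.R"
        script.write_text(
            f"d <- read.delim('{fixture}')\n"
            "fit <- loess(y ~ x, data=d, weights=d$w, degree=1, enp.target=20, surface='direct')\n"
            f"writeLines(sprintf('%.10f', predict(fit, d$x)), '{tmp_path / 'r.tsv'}')\n"
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        r_fit = np.loadtxt(tmp_path / "r.tsv")
        spread = fitted.max() - fitted.min()
        assert np.max(np.abs(fitted - r_fit)) < 0.05 * spread
        assert np.corrcoef(fitted, r_fit)[0, 1] > 0.999


class TestNormalizeChip:
    def test_divides_by_included_median(self):
        track = CoverageTrack("c", [0, 50], [50, 100], [4.0, 8.0])
        norm = normalize_chip(track)
        assert np.allclose(norm.values, [4 / 6, 8 / 6])
        dense = norm.per_base()
        assert np.median(dense) == pytest.approx(1.0)

    def test_exclusions_respected(self):
        track = CoverageTrack("c", [0, 50], [50, 100], [4.0, 100.0])
        norm = normalize_chip(track, exclusions=[(50, 100)])
        assert np.allclose(norm.values, [1.0, 25.0])

    def test_idempotent_and_scale_equivariant(self):
        track = CoverageTrack("c", [0, 30, 60], [30, 60, 90], [2.0, 4.0, 6.0])
        once = normalize_chip(track)
        twice = normalize_chip(once)
        assert np.allclose(once.values, twice.values)
        scaled = CoverageTrack("c", track.starts, track.ends, track.values * 7)
        assert np.allclose(normalize_chip(scaled).values, once.values)

    def test_zero_median_errors(self):
        track = CoverageTrack("c", [0], [100], [0.0])
        with pytest.raises(ValueError, match="median"):
            normalize_chip(track)


class TestGenotypeOverlay:
    def test_identical_tracks_identical_columns(self):
        t = _track([1, 5, 9], [10.0, 20.0, 30.0], [15, 15, 15])
        out = genotype_overlay([t, t], labels=["a", "b"])
        assert out["a"].equals(out["b"])

    def test_disjoint_tracks_block_missing_union(self):
        t1 = _track([1, 2, 3], [1.0, 2.0, 3.0], [10, 10, 10])
        t2 = _track([10, 11], [4.0, 5.0], [10, 10])
        out = genotype_overlay([t1, t2], labels=["a", "b"])
        assert len(out) == 5  # union size
        assert out.loc[10, "a"] != out.loc[10, "a"]  # NaN
        assert out.loc[1, "b"] != out.loc[1, "b"]

    def test_contig_mismatch(self):
        t1 = _track([1], [1.0], [10])
        t2 = AggregateTrack("other", t1.df.copy())
        with pytest.raises(ValueError, match="contig"):
            genotype_overlay([t1, t2])
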