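"""Genome scan: per-site statistics, windows, LOESS, interval calling."""

import numpy as np
import pandas as pd
import pytest

import pepperbsa as pb
from pepperbsa.bsascan import ScanConfig, sliding_windows, smooth_windows


def mkdepths(d1, d2):
    return pb.SampleDepths({"A": 30}, {"G": 30}, d1, d2)


class TestSnpIndex:
    def test_pure_bulk(self):
        d = mkdepths({"G": 30, "A": 0}, {})
        assert pb.snp_index(d, "G", "D1") == 1.0

    def test_fraction(self):
        d = mkdepths({}, {"G": 10, "A": 20})
        assert pb.snp_index(d, "G", "D2") == pytest.approx(1 / 3, abs=5e-5)

    def test_low_depth_masked_not_nan_propagating(self):
        d = mkdepths({}, {"G": 2, "A": 3})
        assert np.isnan(pb.snp_index(d, "G", "D2", min_depth=10))
        # masked input yields masked delta, not an exception
        assert np.isnan(pb.delta_index(0.5, float("nan")))


class TestDeltaIndex:
    @pytest.mark.parametrize("i1,i2,expected", [
        (1.0, 1 / 3, 2 / 3),   # dominant-locus configuration
        (0.5, 0.5, 0.0),
        (0.0, 1.0, 1.0),
    ])
    def test_values(self, i1, i2, expected):
        assert pb.delta_index(i1, i2) == pytest.approx(expected, abs=5e-5)

    def test_orientation_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            i1, i2 = rng.random(2)
            assert pb.delta_index(i1, i2) == pytest.approx(
                pb.delta_index(1 - i1, 1 - i2))


class TestEuclideanDistance:
    def test_identical_vectors(self):
        d = mkdepths({"A": 10, "G": 10}, {"A": 20, "G": 20})
        ed, ed2 = pb.euclidean_distance(d)
        assert ed == pytest.approx(0.0)

    def test_dominant_locus_frequencies(self):
        # D1 fixed for G, D2 at f_G = 1/3, f_A = 2/3
        d = mkdepths({"G": 30}, {"G": 10, "A": 20})
        ed, ed2 = pb.euclidean_distance(d)
        assert ed == pytest.approx(0.9428, abs=5e-5)
        assert ed2 == pytest.approx(0.8889, abs=5e-5)

    def test_opposite_fixation_is_maximal(self):
        d = mkdepths({"G": 30}, {"A": 25})
        ed, ed2 = pb.euclidean_distance(d)
        assert ed == pytest.approx(np.sqrt(2))
        assert ed2 == pytest.approx(2.0)

    def test_zero_depth_masked(self):
        ed, ed2 = pb.euclidean_distance(mkdepths({}, {"A": 10}))
        assert np.isnan(ed) and np.isnan(ed2)

    def test_bounds_on_fuzzed_depths(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            d1 = {a: int(c) for a, c in zip("ACGT", rng.integers(0, 30, 4))}
            d2 = {a: int(c) for a, c in zip("ACGT", rng.integers(0, 30, 4))}
            ed, ed2 = pb.euclidean_distance(mkdepths(d1, d2))
            if not np.isnan(ed):
                assert 0.0 <= ed <= np.sqrt(2) + 1e-12
                assert ed2 == pytest.approx(ed * ed)


class TestSlidingWindows:
    def test_mean_of_one_window(self):
        sites = pd.DataFrame({"chrom": "c", "pos": [100, 200, 300],
                              "delta": [0.2, 0.4, 0.6]})
        win = sliding_windows(sites, {"c": 400}, "delta",
                              window_bp=400, step_bp=400, min_markers=1)
        assert win["mean"].iloc[0] == pytest.approx(0.4)
        assert win["n_markers"].iloc[0] == 3

    def test_half_open_boundary(self):
        # a site at start + window_bp belongs to the next window only
        sites = pd.DataFrame({"chrom": "c", "pos": [101], "delta": [1.0]})
        win = sliding_windows(sites, {"c": 200}, "delta",
                              window_bp=100, step_bp=100, min_markers=0)
        first = win[win["start"] == 1].iloc[0]
        second = win[win["start"] == 101].iloc[0]
        assert first["n_markers"] == 0
        assert second["n_markers"] == 1

    def test_windows_match_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        pos = np.sort(rng.choice(np.arange(1, 10_001), 300, replace=False))
        val = rng.random(300)
        val[rng.random(300) < 0.1] = np.nan
        sites = pd.DataFrame({"chrom": "c", "pos": pos, "v": val})
        window_bp, step_bp = 1500, 400
        win = sliding_windows(sites, {"c": 10_000}, "v", window_bp, step_bp, 3)
        assert len(win) == len(range(1, 10_001, step_bp))
        for _, row in win.iterrows():
            inside = (pos >= row["start"]) & (pos < row["end"]) & ~np.isnan(val)
            assert row["n_markers"] == inside.sum()
            if inside.sum():
                assert row["mean"] == pytest.approx(val[inside].mean())
            else:
                assert np.isnan(row["mean"])
            assert row["eligible"] == (inside.sum() >= 3)

    def test_empty_chromosome_has_empty_windows(self):
        sites = pd.DataFrame({"chrom": [], "pos": [], "v": []})
        win = sliding_windows(sites, {}, "v")
        assert len(win) == 0


class TestLoess:
    def test_constant_reproduced(self):
        x = np.arange(50.0)
        out = pb.loess_smooth(x, np.full(50, 3.7), span=0.3)
        assert np.allclose(out, 3.7)

    def test_linear_ramp_exact_for_degree_one(self):
        x = np.arange(60.0)
        y = 0.5 * x + 2
        out = pb.loess_smooth(x, y, span=0.25, degree=1)
        assert np.allclose(out[5:-5], y[5:-5], atol=1e-6)

    def test_noise_reduction_on_step(self):
        rng = np.random.default_rng(4)
        x = np.arange(200.0)
        step = np.where(x < 100, 0.0, 1.0)
        noisy = step + rng.normal(0, 0.2, 200)
        sm = pb.loess_smooth(x, noisy, span=0.2)
        interior = np.r_[10:90, 110:190]
        assert (np.abs(sm - step)[interior].max()
                < np.abs(noisy - step)[interior].max())

    def test_agrees_with_statsmodels_on_smooth_data(self):
        from statsmodels.nonparametric.smoothers_lowess import lowess

        rng = np.random.default_rng(5)
        x = np.sort(rng.uniform(0, 10, 120))
        y = np.sin(x) + rng.normal(0, 0.05, 120)
        ours = pb.loess_smooth(x, y, span=0.3, degree=1, iterations=0)
        ref = lowess(y, x, frac=0.3, it=0, return_sorted=False)
        assert np.allclose(ours, ref, atol=0.05)

    def test_too_few_points_pass_through(self, caplog):
        x = np.arange(3.0)
        y = np.array([1.0, 5.0, 2.0])
        with caplog.at_level("WARNING"):
            out = pb.loess_smooth(x, y)
        assert np.allclose(out, y)


class TestCallIntervals:
    @staticmethod
    def windows_frame(values, start_step=100, width=300):
        starts = np.arange(1, len(values) * start_step + 1, start_step)
        return pd.DataFrame({
            "chrom": "c", "start": starts, "end": starts + width,
            "n_markers": 50, "mean": values, "eligible": True,
        })

    def test_single_peak(self):
        vals = np.zeros(100)
        vals[40] = 10.0
        ivs, thr = pb.call_intervals(self.windows_frame(vals), 0.99)
        assert len(ivs) == 1
        assert ivs[0].peak_value == 10.0

    def test_overlapping_significant_windows_merge(self):
        vals = np.zeros(100)
        vals[40] = vals[41] = 10.0  # windows overlap (width 300, step 100)
        ivs, _ = pb.call_intervals(self.windows_frame(vals), 0.99)
        assert len(ivs) == 1
        assert ivs[0].end - ivs[0].start == 400

    def test_two_peaks_match_brute_force(self):
        rng = np.random.default_rng(6)
        vals = rng.random(200) * 0.1
        vals[50:53] = [0.9, 1.0, 0.9]
        vals[150:152] = [0.85, 0.95]
        win = self.windows_frame(vals)
        ivs, thr = pb.call_intervals(win, 0.98)
        t = np.quantile(vals, 0.98)
        sig = win[win["mean"] >= t]
        assert len(ivs) == 2
        covered = set()
        for iv in ivs:
            for _, row in sig.iterrows():
                if iv.start <= row["start"] and row["end"] <= iv.end:
                    covered.add(row["start"])
        assert covered == set(sig["start"])

    def test_quantile_monotonicity(self):
        rng = np.random.default_rng(7)
        win = self.windows_frame(rng.random(300))
        prev_n, prev_len = None, None
        for q in (0.9, 0.95, 0.99, 0.995):
            ivs, _ = pb.call_intervals(win, q)
            n = len(ivs)
            total = sum(iv.end - iv.start for iv in ivs)
            if prev_n is not None:
                assert n <= prev_n or total <= prev_len
                assert total <= prev_len
            prev_n, prev_len = n, total

    def test_no_significant_windows_empty(self):
        win = self.windows_frame(np.zeros(50))
        win["eligible"] = False
        ivs, thr = pb.call_intervals(win)
        assert ivs == [] and thr == {}

    def test_threshold_override(self):
        vals = np.linspace(0, 1, 100)
        ivs, thr = pb.call_intervals(self.windows_frame(vals),
                                     threshold_override=2.0)
        assert ivs == []


class TestRunScan:
    def test_two_locus_recovery_seed_42(self, filtered_table):
        result = pb.run_scan(filtered_table)
        assert len(result.intervals_delta) == 2
        chroms = {iv.chrom for iv in result.intervals_delta}
        assert chroms == {"chr1", "chr10"}
        for chrom, pos in (("chr10", 16_450_000), ("chr1", 17_650_000)):
            assert any(iv.contains(chrom, pos)
                       for iv in result.intervals_delta)

    def test_ed2_concordant_with_delta(self, filtered_table):
        result = pb.run_scan(filtered_table)
        assert result.jaccard > 0.5

    def test_deterministic(self, filtered_table):
        a = pb.run_scan(filtered_table)
        b = pb.run_scan(filtered_table)
        pd.testing.assert_frame_equal(a.sites, b.sites)
        assert a.intervals_delta == b.intervals_delta

    def test_orientation_choice_leaves_delta_invariant(self, filtered_table):
        a = pb.run_scan(filtered_table, ScanConfig(orientation="yellow"))
        b = pb.run_scan(filtered_table, ScanConfig(orientation="green"))
        np.testing.assert_allclose(a.sites["delta"], b.sites["delta"])
        ok = ~a.sites["masked"]
        np.testing.assert_allclose(a.sites.loc[ok, "index_D1"],
                                   1 - b.sites.loc[ok, "index_D1"])
        assert [(iv.chrom, iv.start, iv.end) for iv in a.intervals_delta] == \
            [(iv.chrom, iv.start, iv.end) for iv in b.intervals_delta]
        for ia, ib in zip(a.intervals_delta, b.intervals_delta):
            assert ia.peak_value == pytest.approx(ib.peak_value)

    def test_site_tracks_within_bounds(self, filtered_table):
        sites = pb.run_scan(filtered_table).sites
        ok = sites.dropna(subset=["delta"])
        assert ok["index_D1"].between(0, 1).all()
        assert ok["index_D2"].between(0, 1).all()
        assert ok["delta"].between(0, 1).all()
        assert ok["ed"].between(0, np.sqrt(2) + 1e-12).all()

    def test_unfiltered_table_rejected(self, default_dataset):
        _, _, table = default_dataset
        with pytest.raises(ValueError, match="yellow-parent"):
            pb.run_scan(table)


class TestWriters:
    def test_bed_is_zero_based_half_open(self, filtered_table, tmp_path):
        from pepperbsa.bsascan import write_intervals_bed

        result = pb.run_scan(filtered_table)
        path = tmp_path / "iv.bed"
        write_intervals_bed(result.intervals_delta, path)
        lines = path.read_text().strip().split("\n")
        assert len(lines) == len(result.intervals_delta)
        for line, iv in zip(lines, result.intervals_delta):
            chrom, start, end, name, score = line.split("\t")
            assert int(start) == iv.start - 1
            assert int(end) == iv.end - 1
            assert name == "delta_index"
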