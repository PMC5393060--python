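import numpy as np
import pytest
from scipy.stats import chisquare, pearsonr, spearmanr

from macctools import macc as mc
from macctools.macc import (TitrationSeries, bin_frequencies, compute_occupancy,
                            coverage_track, fit_titration_slope, gc_correct,
                            pooled_occupancy, scale_metric, scale_track,
                            summarize_atac)
from macctools.tracks import BinnedTrack

from conftest import make_fragment_set, titration_series


def series_from_arrays(arrays, bin_size=200, chrom_len=None):
    arrays = [np.asarray(a, dtype=float) for a in arrays]
    n = len(arrays[0])
    chrom_len = chrom_len or n * bin_size
    tracks = [BinnedTrack(bin_size, {"chr1": a.copy()}, {"chr1": chrom_len})
              for a in arrays]
    return TitrationSeries(tracks=tracks)


class TestBinFrequencies:
    def test_midpoint_assignment(self):
        fs = make_fragment_set([("chr1", 100, 250)], chrom_lengths={"chr1": 1000})
        t = bin_frequencies(fs, 200, normalize=False)
        assert t.data["chr1"].tolist() == [1.0, 0.0, 0.0, 0.0, 0.0]

    def test_midpoint_boundary_goes_right(self):
        fs = make_fragment_set([("chr1", 190, 210)], chrom_lengths={"chr1": 1000})
        t = bin_frequencies(fs, 200, normalize=False)
        assert t.data["chr1"].tolist() == [0.0, 1.0, 0.0, 0.0, 0.0]

    def test_bad_bin_size(self):
        fs = make_fragment_set([("chr1", 0, 100)], chrom_lengths={"chr1": 1000})
        with pytest.raises(ValueError):
            bin_frequencies(fs, 0)

    def test_cpm_normalization(self):
        fs = make_fragment_set([("chr1", 0, 100)] * 4, chrom_lengths={"chr1": 200})
        t = bin_frequencies(fs, 200)
        assert t.data["chr1"][0] == pytest.approx(1e6)

    def test_uniform_fragments_poisson(self):
        rng = np.random.default_rng(0)
        starts = rng.integers(0, 1_000_000 - 150, 100_000)
        fs = make_fragment_set([("chr1", int(s), int(s) + 150) for s in starts],
                               chrom_lengths={"chr1": 1_000_000})
        t = bin_frequencies(fs, 200, normalize=False)
        counts = t.flatten(True).astype(int)
        lam = counts.mean()
        from scipy.stats import poisson
        hi = int(counts.max()) + 1
        obs = np.bincount(counts, minlength=hi + 1).astype(float)
        exp = poisson.pmf(np.arange(hi + 1), lam) * len(counts)
        exp[-1] = len(counts) - exp[:-1].sum()  # fold tail into last cell
        # merge cells with small expectation
        keep = exp >= 5
        obs_m = np.concatenate([obs[keep], [obs[~keep].sum()]])
        exp_m = np.concatenate([exp[keep], [exp[~keep].sum()]])
        stat, p = chisquare(obs_m, exp_m, ddof=1)
        assert p > 0.01


class TestTitrationSlope:
    def test_flat_series_zero(self):
        s = series_from_arrays([[3.0, 5.0]] * 4)
        np.testing.assert_allclose(fit_titration_slope(s).data["chr1"], 0.0)

    def test_decreasing_series(self):
        s = series_from_arrays([[4.0], [3.0], [2.0], [1.0]])
        assert fit_titration_slope(s).data["chr1"][0] == pytest.approx(-1.0)

    def test_increasing_series(self):
        s = series_from_arrays([[1.0], [2.0], [3.0], [4.0]])
        assert fit_titration_slope(s).data["chr1"][0] == pytest.approx(1.0)

    def test_closed_form_oracle_random(self):
        rng = np.random.default_rng(1)
        f = rng.normal(size=(4, 1000))
        s = series_from_arrays(list(f))
        got = fit_titration_slope(s).data["chr1"]
        oracle = (-3 * f[0] - f[1] + f[2] + 3 * f[3]) / 10.0
        np.testing.assert_allclose(got, oracle, atol=1e-10)

    def test_brute_force_lstsq_oracle(self):
        rng = np.random.default_rng(2)
        f = rng.normal(size=(4, 200))
        s = series_from_arrays(list(f))
        got = fit_titration_slope(s).data["chr1"]
        x = np.vstack([np.ones(4), np.arange(1, 5)]).T
        ref = np.array([np.linalg.lstsq(x, f[:, j], rcond=None)[0][1]
                        for j in range(f.shape[1])])
        np.testing.assert_allclose(got, ref, atol=1e-10)

    def test_missing_level_propagates_nan(self):
        f = [[1.0, 1.0], [2.0, np.nan], [3.0, 1.0], [4.0, 1.0]]
        out = fit_titration_slope(series_from_arrays(f)).data["chr1"]
        assert out[0] == pytest.approx(1.0)
        assert np.isnan(out[1])

    def test_wrong_track_count(self):
        with pytest.raises(ValueError):
            series_from_arrays([[1.0]])


class TestGcCorrect:
    def _tracks(self, slopes, gc, bin_size=200):
        n = len(slopes)
        cl = {"chr1": n * bin_size}
        return (BinnedTrack(bin_size, {"chr1": np.asarray(slopes, float)}, cl),
                BinnedTrack(bin_size, {"chr1": np.asarray(gc, float)}, cl))

    def test_pure_gc_trend_removed(self):
        rng = np.random.default_rng(3)
        gc = rng.uniform(0.3, 0.7, 5000)
        slopes = 0.5 * gc
        st, gt = self._tracks(slopes, gc)
        out = gc_correct(st, gt).flatten()
        inner = (gc > 0.34) & (gc < 0.66)  # smoother is biased at range edges
        assert np.nanmax(np.abs(out[inner])) < 1e-3

    def test_gc_independent_slopes_mean_centered(self):
        rng = np.random.default_rng(4)
        gc = rng.uniform(0.3, 0.7, 4000)
        slopes = rng.normal(0.2, 0.05, 4000)
        st, gt = self._tracks(slopes, gc)
        out = gc_correct(st, gt).flatten()
        assert abs(pearsonr(out, gc).statistic) < 0.05
        assert np.nanmean(out) == pytest.approx(0.0, abs=0.01)

    def test_constant_gc_mean_centering_only(self):
        slopes = np.arange(200, dtype=float)
        gc = np.full(200, 0.5)
        st, gt = self._tracks(slopes, gc)
        out = gc_correct(st, gt).flatten()
        np.testing.assert_allclose(out, -(slopes - slopes.mean()), atol=1e-9)

    def test_sign_flip_convention(self):
        rng = np.random.default_rng(5)
        gc = rng.uniform(0.3, 0.7, 500)
        slopes = rng.normal(size=500)
        st, gt = self._tracks(slopes, gc)
        flipped = gc_correct(st, gt, sign_flip=True).flatten()
        raw = gc_correct(st, gt, sign_flip=False).flatten()
        np.testing.assert_allclose(flipped, -raw)

    def test_few_bins_linear_fallback_warns(self):
        gc = np.linspace(0.3, 0.7, 50)
        slopes = 2.0 * gc + 0.1
        st, gt = self._tracks(slopes, gc)
        with pytest.warns(UserWarning, match="linear"):
            out = gc_correct(st, gt).flatten()
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_invalid_gc_rejected(self):
        st, gt = self._tracks([0.1, 0.2], [0.5, 1.5])
        with pytest.raises(ValueError):
            gc_correct(st, gt)


class TestOccupancy:
    def test_raw_mean(self):
        s = series_from_arrays([[4.0], [3.0], [2.0], [1.0]])
        occ = compute_occupancy(s, "raw")
        assert occ.values.data["chr1"][0] == pytest.approx(2.5)

    def test_chip_over_input_unity(self):
        s = series_from_arrays([[2.0, 4.0]] * 4)
        occ = compute_occupancy(s, "chip_over_input", input_series=s)
        np.testing.assert_allclose(occ.values.data["chr1"], 1.0)

    def test_input_subtracted(self):
        s = series_from_arrays([[2.0]] * 4)
        i = series_from_arrays([[1.0]] * 4)
        occ = compute_occupancy(s, "input_subtracted", input_series=i)
        assert occ.values.data["chr1"][0] == pytest.approx(1.0)

    def test_zero_input_nan(self):
        s = series_from_arrays([[2.0, 2.0]] * 4)
        i = series_from_arrays([[1.0, 0.0]] * 4)
        occ = compute_occupancy(s, "chip_over_input", input_series=i)
        assert occ.values.data["chr1"][0] == pytest.approx(2.0)
        assert np.isnan(occ.values.data["chr1"][1])

    def test_missing_input_rejected(self):
        s = series_from_arrays([[1.0]] * 4)
        with pytest.raises(ValueError):
            compute_occupancy(s, "chip_over_input")

    def test_permuting_levels_preserves_raw_occupancy_flips_slope(self):
        rng = np.random.default_rng(6)
        f = rng.uniform(1, 5, size=(4, 100))
        fwd = series_from_arrays(list(f))
        rev = series_from_arrays(list(f[::-1]))
        np.testing.assert_allclose(compute_occupancy(fwd).values.data["chr1"],
                                   compute_occupancy(rev).values.data["chr1"])
        np.testing.assert_allclose(fit_titration_slope(fwd).data["chr1"],
                                   -fit_titration_slope(rev).data["chr1"])


class TestCoverage:
    def test_single_fragment(self):
        fs = make_fragment_set([("chr1", 100, 250)], chrom_lengths={"chr1": 400})
        cov = coverage_track(fs, normalize=False)
        assert cov.data["chr1"][99] == 0
        assert cov.data["chr1"][100] == 1
        assert cov.data["chr1"][249] == 1
        assert cov.data["chr1"][250] == 0

    def test_duplicate_fragments_sum(self):
        fs = make_fragment_set([("chr1", 100, 250)] * 2, chrom_lengths={"chr1": 400})
        cov = coverage_track(fs, normalize=False)
        assert cov.data["chr1"][150] == 2

    def test_nested_fragments_sum(self):
        fs = make_fragment_set([("chr1", 100, 300), ("chr1", 150, 250)],
                               chrom_lengths={"chr1": 400})
        cov = coverage_track(fs, normalize=False)
        assert cov.data["chr1"][200] == 2
        assert cov.data["chr1"][120] == 1

    def test_empty_set_zero_track(self):
        fs = make_fragment_set([], chrom_lengths={"chr1": 400})
        fs.fragments = fs.fragments.astype({"start": np.int64, "end": np.int64})
        cov = coverage_track(fs, chrom_lengths={"chr1": 400}, normalize=False)
        assert cov.data["chr1"].sum() == 0

    def test_conservation_identity(self):
        rng = np.random.default_rng(7)
        rows = [("chr1", int(s), int(s) + int(l))
                for s, l in zip(rng.integers(0, 9000, 10_000),
                                rng.integers(50, 400, 10_000))]
        fs = make_fragment_set(rows, chrom_lengths={"chr1": 10_000})
        cov = coverage_track(fs)
        total_len = fs.lengths.sum()
        assert cov.data["chr1"].sum() == pytest.approx(
            total_len / fs.library_size * 1e6, rel=1e-9)

    def test_pooled_equals_depth_weighted_mean(self, flat_truth):
        from macctools.synthetic import simulate_titration_fragments
        import pandas as pd
        sets = [simulate_titration_fragments(flat_truth, 0, lev, 2000 * lev, seed=lev,
                                             contaminant_fraction=0.0)
                for lev in (1, 2, 3, 4)]
        pooled = sets[0].replace(pd.concat([s.fragments for s in sets],
                                           ignore_index=True))
        cov_pool = pooled_occupancy(pooled).values
        libs = np.array([s.library_size for s in sets], dtype=float)
        per_level = [coverage_track(s).data["chr1"] for s in sets]
        expected = sum(l * c for l, c in zip(libs, per_level)) / libs.sum()
        np.testing.assert_allclose(cov_pool.data["chr1"], expected, atol=1e-6)
        assert cov_pool is not None and pooled_occupancy(pooled).mode == "pooled"


class TestSummarizeAtac:
    def test_same_binning_as_frequencies(self):
        fs = make_fragment_set([("chr1", 100, 250), ("chr1", 190, 210)],
                               chrom_lengths={"chr1": 1000})
        a = summarize_atac(fs, 200)
        b = bin_frequencies(fs, 200)
        np.testing.assert_array_equal(a.data["chr1"], b.data["chr1"])


class TestScaleMetric:
    def test_oracle_1_to_100(self):
        v = np.arange(1, 101, dtype=float)
        out = scale_metric(v, 20)
        # groups of 5: medians 3 and 98
        assert out[v == 3][0] == pytest.approx(0.0)
        assert out[v == 98][0] == pytest.approx(1.0)

    def test_midpoint_value(self):
        v = np.append(np.arange(1, 101, dtype=float), 50.5)
        out = scale_metric(np.arange(1, 101, dtype=float), 20)
        scaled = (50.5 - 3.0) / 95.0
        assert scaled == pytest.approx(0.5)
        assert out[49] == pytest.approx((50.0 - 3.0) / 95.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(8)
        v = rng.normal(size=400)
        a = scale_metric(v)
        b = scale_metric(3.5 * v - 2.0)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_not_clipped(self):
        v = np.arange(1, 101, dtype=float)
        out = scale_metric(v, 20)
        assert out.min() < 0.0
        assert out.max() > 1.0

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            scale_metric(np.ones(100))

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            scale_metric(np.arange(5), n_groups=20)

    def test_nan_passthrough(self):
        v = np.append(np.arange(1, 101, dtype=float), np.nan)
        out = scale_metric(v, 20)
        assert np.isnan(out[-1])
        assert np.isfinite(out[:-1]).all()

    def test_scale_track_matches_scale_metric(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=300)
        t = BinnedTrack(200, {"chr1": vals.copy()}, {"chr1": 60_000})
        out = scale_track(t, 20)
        np.testing.assert_allclose(out.data["chr1"], scale_metric(vals, 20))


class TestMaccInvariants:
    def test_depth_scaling_invariance(self):
        # duplicating every fragment leaves CPM (hence MACC inputs) unchanged
        import pandas as pd
        rows = [("chr1", i * 37 % 800, i * 37 % 800 + 150) for i in range(200)]
        fs = make_fragment_set(rows, chrom_lengths={"chr1": 1000})
        doubled = fs.replace(pd.concat([fs.fragments] * 2, ignore_index=True))
        t1 = bin_frequencies(fs, 200)
        t2 = bin_frequencies(doubled, 200)
        np.testing.assert_allclose(t1.data["chr1"], t2.data["chr1"])

    def test_occupancy_recovery_on_simulation(self, flat_truth):
        series = titration_series(flat_truth, 0, 300_000, seed_base=700)
        occ = compute_occupancy(series).values.flatten(True)
        true_occ = flat_truth.occupancy_track(0).flatten(True)
        rho = spearmanr(true_occ, occ).statistic
        assert rho >= 0.8
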