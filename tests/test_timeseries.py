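"""Collection building: averaging, merging, SG smoothing, GPR gap-filling."""

import numpy as np
import pytest
from shapely.geometry import box

from phenolai.series import SampledSeries
from phenolai.synthetic import AcquisitionSchedule, render_scene, sample_series
from phenolai.timeseries import (SGConfig, build_collections, gpr_gapfill,
                                 merge_streams, parcel_average, savgol_smooth)


def series(times, values, pid="p", sensor=None):
    s = None if sensor is None else np.full(len(times), sensor, dtype=object)
    return SampledSeries(np.asarray(times, float), np.asarray(values, float),
                         sensor=s, parcel_id=pid)


class TestParcelAverage:
    def test_single_pixel_parcel_is_identity(self):
        s = series([0, 10, 20], [1.0, 2.0, 3.0])
        avg = parcel_average([s], parcel_id="p")
        assert np.array_equal(avg.values, s.values)

    def test_two_pixel_mean(self):
        a = series([0, 10], [1.0, 2.0])
        b = series([0, 10], [3.0, 4.0])
        avg = parcel_average([a, b])
        assert np.allclose(avg.values, [2.0, 3.0])

    def test_matches_mask_and_mean_loop_on_scene(self, calendar):
        from phenolai.synthetic import lai_truth_curve

        truth = lai_truth_curve("rice", 2016, calendar)
        poly = box(2, 3, 7, 8)
        sched = AcquisitionSchedule("S2", 15.0, jitter=0.0, end=365)
        stack, _ = render_scene({"p0": poly}, {"p0": truth}, sched, (10, 10),
                                seed=1, noise_sd=0.2, noise_mode="pixel")
        avg = parcel_average(stack, poly, parcel_id="p0")
        # explicit mask-and-mean loop oracle over pixel centres
        from shapely.geometry import Point

        expected = []
        for ti in range(stack.ntimes):
            vals = [stack.data[ti, r, c] for r in range(10) for c in range(10)
                    if poly.contains(Point(c + 0.5, r + 0.5))]
            expected.append(np.mean(vals))
        np.testing.assert_allclose(avg.values, expected, atol=1e-12)

    def test_no_intersection_raises_with_parcel_name(self, calendar):
        from phenolai.synthetic import lai_truth_curve

        truth = lai_truth_curve("rice", 2016, calendar)
        sched = AcquisitionSchedule("S2", 30.0, jitter=0.0, end=365)
        stack, _ = render_scene({"p0": box(0, 0, 3, 3)}, {"p0": truth},
                                sched, (8, 8), seed=0)
        with pytest.raises(ValueError, match="far_parcel"):
            parcel_average(stack, box(100, 100, 101, 101),
                           parcel_id="far_parcel")


class TestMerge:
    def test_disjoint_dates_concatenate(self):
        a = series(np.arange(0, 100, 10), np.ones(10), sensor="S2")
        b = series(np.arange(3, 70, 10), np.zeros(7), sensor="L8")
        m = merge_streams(a, b)
        assert len(m) == 17
        assert np.all(np.diff(m.times) > 0)

    def test_commutative(self):
        a = series([0, 10, 20], [1, 2, 3], sensor="S2")
        b = series([5, 10.2, 25], [4, 5, 6], sensor="L8")
        m1, m2 = merge_streams(a, b), merge_streams(b, a)
        np.testing.assert_allclose(m1.times, m2.times, atol=1e-12)
        np.testing.assert_allclose(m1.values, m2.values, atol=1e-12)

    def test_idempotent_on_output(self):
        a = series([0, 10, 20], [1, 2, 3], sensor="S2")
        b = series([0.2, 10, 21], [2, 3, 4], sensor="L8")
        m = merge_streams(a, b)
        mm = merge_streams(m, m)
        # merging the merged stream with itself only averages equal values
        np.testing.assert_allclose(mm.values, m.values, atol=1e-12)
        np.testing.assert_allclose(mm.times, m.times, atol=1e-12)

    def test_same_day_coincidence_averaged_and_tagged(self):
        a = series([0.0, 10.0], [1.0, 3.0], sensor="S2")
        b = series([10.1, 30.0], [5.0, 7.0], sensor="L8")
        m = merge_streams(a, b)
        assert len(m) == 3
        i = np.argmin(np.abs(m.times - 10.05))
        assert m.values[i] == pytest.approx(4.0)
        assert m.sensor[i] == "both"

    def test_different_parcels_rejected(self):
        with pytest.raises(ValueError, match="parcel"):
            merge_streams(series([0], [1], pid="a"), series([0], [1], pid="b"))

    def test_noiseless_merge_lies_on_truth(self, rice_truth):
        s2 = sample_series(rice_truth,
                           AcquisitionSchedule("S2", 5.0, jitter=0.0, end=365),
                           seed=1, parcel_id="p")
        l8 = sample_series(rice_truth,
                           AcquisitionSchedule("L8", 16.0, jitter=0.0, end=365),
                           seed=2, parcel_id="p")
        m = merge_streams(s2, l8)
        # single-sensor points are exact; coincidences average two exact values
        np.testing.assert_allclose(m.values, rice_truth(m.times), atol=1e-9)


class TestSavgol:
    def test_reproduces_quadratic_exactly(self):
        i = np.arange(15, dtype=float)
        v = 0.3 * i**2 - 2 * i + 1
        out = savgol_smooth(series(i, v))
        np.testing.assert_allclose(out.values, v, atol=1e-10)

    def test_constant_series_unchanged(self):
        out = savgol_smooth(series(np.arange(10.0), np.full(10, 2.5)))
        np.testing.assert_allclose(out.values, 2.5, atol=1e-12)

    def test_interior_matches_direct_least_squares(self, rng):
        v = rng.normal(size=15)
        out = savgol_smooth(series(np.arange(15.0), v))
        for i in range(3, 12):
            x = np.arange(-3, 4, dtype=float)
            c = np.polyfit(x, v[i - 3:i + 4], 2)
            assert out.values[i] == pytest.approx(np.polyval(c, 0.0), abs=1e-10)

    def test_interior_matches_scipy_filter(self, rng):
        from scipy.signal import savgol_filter

        v = rng.normal(size=20)
        out = savgol_smooth(series(np.arange(20.0), v))
        ref = savgol_filter(v, 7, 2)
        np.testing.assert_allclose(out.values[3:-3], ref[3:-3], atol=1e-10)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            savgol_smooth(series([0, 1], [1.0, 2.0]))

    def test_smoothing_reduces_noise_mse(self, rng):
        """MSE against a smooth truth does not increase after smoothing
        (noise sd 0.3, 20 seeded replicates)."""
        t = np.arange(0, 400, 10.0)
        truth = 2 + 2 * np.sin(t / 40)
        worse = 0
        for rep in range(20):
            noisy = truth + np.random.default_rng(rep).normal(0, 0.3, len(t))
            sm = savgol_smooth(series(t, noisy)).values
            if np.mean((sm - truth) ** 2) > np.mean((noisy - truth) ** 2):
                worse += 1
        assert worse == 0


class TestGapfill:
    def test_reconstructs_sinusoid_across_gap(self):
        t = np.arange(0, 400, 10.0)
        keep = (t < 180) | (t > 220)
        v = 2 + np.sin(2 * np.pi * t / 200)
        gf = gpr_gapfill(series(t[keep], v[keep]), grid_spacing=10.0, seed=0)
        in_gap = (gf.times >= 180) & (gf.times <= 220)
        truth = 2 + np.sin(2 * np.pi * gf.times[in_gap] / 200)
        assert np.max(np.abs(gf.values[in_gap] - truth)) < 0.05  # 5% of amp 1

    def test_interpolation_regime_recovers_observations(self):
        t = np.arange(0, 300, 10.0)
        v = 1 + 0.8 * np.sin(t / 30)
        gf = gpr_gapfill(series(t, v), grid_spacing=10.0, seed=0)
        np.testing.assert_allclose(gf.times, t, atol=1e-9)
        np.testing.assert_allclose(gf.values, v, atol=1e-3)

    def test_uncertainty_grows_inside_gap(self):
        t = np.arange(0, 400, 10.0)
        keep = (t < 150) | (t > 210)  # 60-day gap
        v = 2 + np.sin(2 * np.pi * t / 200)
        gf = gpr_gapfill(series(t[keep], v[keep]), grid_spacing=10.0, seed=0)
        in_gap = (gf.times > 150) & (gf.times < 210)
        obs_like = ~in_gap
        assert gf.sd[in_gap].max() > np.median(gf.sd[obs_like])

    def test_grid_is_regular_and_covers_range(self):
        t = np.sort(np.random.default_rng(3).uniform(0, 365, 40))
        v = np.sin(t / 50)
        gf = gpr_gapfill(series(t, v), grid_spacing=10.0, seed=0)
        assert gf.times[0] == pytest.approx(t[0])
        steps = np.diff(gf.times)
        np.testing.assert_allclose(steps, 10.0, atol=1e-9)
        assert gf.times[-1] <= t[-1] < gf.times[-1] + 10.0

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            gpr_gapfill(series([0, 1, 2, 3], np.ones(4)))


class TestCollections:
    def test_identical_inputs_make_sl30sg_equal_s30(self):
        t = np.arange(0, 200, 10.0)
        v = 1 + np.sin(t / 30)
        a = series(t, v, sensor="S2")
        b = series(t, v, sensor="L8")
        cols = build_collections(a, b, grid_spacing=10.0, seed=0)
        np.testing.assert_allclose(cols["SL30_SG"].values, cols["S30"].values,
                                   atol=1e-12)

    def test_four_collections_with_regular_gpr_grid(self, double_crop_truth):
        s2 = sample_series(double_crop_truth,
                           AcquisitionSchedule("S2", 5.0, gap_prob=0.2,
                                               end=1095),
                           noise_sd=0.2, seed=1, parcel_id="p")
        l8 = sample_series(double_crop_truth,
                           AcquisitionSchedule("L8", 16.0, gap_prob=0.2,
                                               end=1095),
                           noise_sd=0.2, seed=2, parcel_id="p")
        cols = build_collections(s2, l8, grid_spacing=10.0, seed=0)
        assert set(cols) == {"S30", "L30", "SL30_SG", "SL30_GPR"}
        np.testing.assert_allclose(np.diff(cols["SL30_GPR"].times), 10.0,
                                   atol=1e-9)
        assert cols["SL30_GPR"].sd is not None

    def test_all_collections_agree_on_clean_season_count(self, double_crop_truth):
        from phenolai.phenology import DetectionConfig, extract_seasons

        s2 = sample_series(double_crop_truth,
                           AcquisitionSchedule("S2", 5.0, end=1095),
                           seed=1, parcel_id="p")
        l8 = sample_series(double_crop_truth,
                           AcquisitionSchedule("L8", 16.0, end=1095),
                           seed=2, parcel_id="p")
        cols = build_collections(s2, l8, grid_spacing=10.0, seed=0)
        counts = {name: len(extract_seasons(c, DetectionConfig()))
                  for name, c in cols.items()}
        truth_n = len(double_crop_truth.seasons_in(0, 1095))
        assert all(n == truth_n for n in counts.values()), counts
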