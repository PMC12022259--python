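import numpy as np
import pytest
from scipy import stats

from perfsource.analysis import (
    ARRIVAL_GRID_DT,
    MixingTimeSeries,
    arrival_time,
    arrival_time_map,
    average_mixing_pairs,
    combine_multislice,
    delay_map,
    detect_vessel_voxels,
    normalize_energy,
    percent_change,
    t1_correct,
    territory_mask,
    ttest_maps,
    voxel_energy,
)
from perfsource.acquisition import DEFAULT_T1


class TestT1Correct:
    def test_zero_time_factor_one(self):
        s = MixingTimeSeries([0.0, 1.0], [2.0, 3.0])
        out = t1_correct(s)
        assert out.values[0] == 2.0

    def test_default_t1_is_1584_ms(self):
        assert DEFAULT_T1 == pytest.approx(1.584)
        s = MixingTimeSeries([DEFAULT_T1], [1.0])
        assert t1_correct(s).values[0] == pytest.approx(np.e)

    def test_decay_then_correct_recovers_original(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0.1, 3.0, 15))
        v = rng.uniform(0.0, 2.0, 15)
        decayed = v * np.exp(-t / DEFAULT_T1)
        out = t1_correct(MixingTimeSeries(t, decayed))
        np.testing.assert_allclose(out.values, v, rtol=1e-12)

    def test_nonpositive_t1_rejected(self):
        with pytest.raises(ValueError):
            t1_correct(MixingTimeSeries([1.0, 2.0], [1.0, 1.0]), t1=0.0)


class TestNormalizeEnergy:
    def test_uniform_map_normalizes_to_one_over_bins_times(self):
        vals = np.ones((2, 2, 2))
        out = normalize_energy(vals)
        np.testing.assert_allclose(out, 1.0 / 8.0)

    def test_hand_computed_2x2x2_oracle(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0.5, 2.0, size=(2, 2, 2))
        expected_energy = 0.0
        for i in range(2):
            for j in range(2):
                for k in range(2):
                    expected_energy += vals[i, j, k] ** 2
        out = normalize_energy(vals)
        np.testing.assert_allclose(out, vals / expected_energy, rtol=1e-12)
        assert voxel_energy(vals) == pytest.approx(expected_energy)

    def test_sumabs_mode_scale_invariant(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0.0, 1.0, size=(3, 4))
        a = normalize_energy(vals, mode="sumabs")
        b = normalize_energy(7.3 * vals, mode="sumabs")
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_zero_map_rejected(self):
        with pytest.raises(ValueError):
            normalize_energy(np.zeros((2, 2)))


class TestDetectVesselVoxels:
    def test_single_bright_voxel(self):
        img = np.zeros((5, 5))
        img[2, 3] = 1.0
        mask = detect_vessel_voxels(img)
        assert mask[2, 3]
        assert mask.sum() == 1

    def test_two_equal_peaks_both_returned(self):
        img = np.zeros((7, 7))
        img[1, 1] = img[5, 5] = 2.0
        mask = detect_vessel_voxels(img)
        assert mask[1, 1] and mask[5, 5]
        assert mask.sum() == 2

    def test_plateau_matches_brute_force_scan(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 4, size=(9, 9)).astype(float)  # many ties
        mask = detect_vessel_voxels(img, min_frac=0.2)
        # exhaustive neighbourhood scan oracle
        oracle = np.zeros_like(mask)
        for i in range(9):
            for j in range(9):
                neigh = img[max(0, i - 1) : i + 2, max(0, j - 1) : j + 2]
                oracle[i, j] = (img[i, j] >= neigh.max()) and (
                    img[i, j] >= 0.2 * img.max()
                )
        np.testing.assert_array_equal(mask, oracle)

    def test_fraction_threshold(self):
        img = np.zeros((5, 5))
        img[1, 1], img[3, 3] = 1.0, 0.1
        assert detect_vessel_voxels(img, min_frac=0.2).sum() == 1
        assert detect_vessel_voxels(img, min_frac=0.05).sum() == 2


class TestTerritoryMask:
    def test_single_mixing_time_suprathreshold_set(self):
        m = np.zeros((1, 4, 4))
        m[0, 1, 1], m[0, 2, 2] = 1.0, 0.05
        tm = territory_mask(m, threshold_frac=0.1)
        assert tm.mask[1, 1] and not tm.mask[2, 2]

    def test_union_monotone_in_appended_times(self):
        rng = np.random.default_rng(4)
        frames = rng.uniform(0, 1, size=(5, 6, 6))
        prev = np.zeros((6, 6), dtype=bool)
        for n in range(1, 6):
            cur = territory_mask(frames[:n]).mask
            assert np.all(prev <= cur)
            prev = cur

    def test_all_zero_frame_contributes_nothing(self):
        m = np.zeros((2, 3, 3))
        m[0, 1, 1] = 1.0
        tm = territory_mask(m)
        assert tm.mask.sum() == 1


class TestArrivalTime:
    def test_ramp_crossing_quantized_to_next_grid_point(self):
        # true 50% crossing of the 0->1 ramp is 0.500 s, which is not a
        # multiple of 15 ms; the first grid time at/above the crossing is
        # 0.510 s (34 * 15 ms)
        t = np.arange(0, 1.01, 0.1)
        s = MixingTimeSeries(t, t.copy())
        assert arrival_time(s) == pytest.approx(0.51, abs=1e-12)

    def test_delayed_ramp_shifts_arrival_by_300_ms(self):
        t = np.arange(0, 1.61, 0.1)
        ramp = np.clip(t - 0.3, 0.0, 1.0)
        base = arrival_time(MixingTimeSeries(t, np.clip(t, 0.0, 1.0)))
        delayed = arrival_time(MixingTimeSeries(t, ramp))
        assert delayed - base == pytest.approx(0.300, abs=1e-12)
        # dense-interpolation oracle: 1 ms grid crossing of the same series
        dense = t[0] + 0.001 * np.arange(int(1.6 / 0.001) + 1)
        interp = np.interp(dense, t, ramp)
        oracle = dense[np.argmax(interp >= 0.5 * interp.max())]
        assert abs(delayed - oracle) <= ARRIVAL_GRID_DT

    def test_constant_series_returns_t_min(self):
        s = MixingTimeSeries([0.2, 0.4, 0.6], [1.0, 1.0, 1.0])
        assert arrival_time(s) == pytest.approx(0.2)

    def test_all_zero_series_undefined(self):
        s = MixingTimeSeries([0.1, 0.2], [0.0, 0.0])
        assert np.isnan(arrival_time(s))

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            arrival_time(MixingTimeSeries([0.1], [1.0]))


class TestDelayMap:
    def test_identical_states_zero_delay(self):
        rng = np.random.default_rng(5)
        t = np.arange(1, 11) * 0.15
        maps = rng.uniform(0.2, 1.0, size=(10, 3, 3))
        dm = delay_map(t, maps, maps)
        np.testing.assert_allclose(dm.values[np.isfinite(dm.values)], 0.0)

    def test_below_floor_bins_masked(self):
        t = np.arange(1, 6) * 0.15
        maps = np.zeros((5, 2, 2))
        maps[:, 0, 0] = [0.1, 0.5, 1.0, 1.0, 1.0]
        maps[:, 1, 1] = 1e-4  # below 5% floor
        dm = delay_map(t, maps, maps)
        assert np.isfinite(dm.values[0, 0])
        assert np.isnan(dm.values[1, 1])
        assert np.isnan(dm.values[0, 1])

    def test_mismatched_grids_rejected(self):
        t = np.arange(1, 6) * 0.15
        with pytest.raises(ValueError):
            delay_map(t, np.zeros((5, 2, 2)), np.zeros((5, 3, 3)))


class TestPercentChange:
    def test_equal_maps_zero_percent(self):
        b = np.ones((3, 3))
        pc = percent_change(b, b)
        np.testing.assert_allclose(pc.values, 0.0)

    def test_doubling_gives_plus_100(self):
        b = np.full((2, 2), 0.5)
        pc = percent_change(b, 2 * b)
        np.testing.assert_allclose(pc.values, 100.0)

    def test_random_arrays_match_elementwise_loop_oracle(self):
        rng = np.random.default_rng(6)
        b = rng.uniform(0.5, 2.0, size=(4, 5))
        t = rng.uniform(0.5, 2.0, size=(4, 5))
        pc = percent_change(b, t, floor_frac=0.0)
        for i in range(4):
            for j in range(5):
                assert pc.values[i, j] == pytest.approx(
                    (t[i, j] - b[i, j]) / b[i, j] * 100.0
                )

    def test_floor_masking(self):
        b = np.array([[1.0, 1e-6]])
        t = np.array([[2.0, 1.0]])
        pc = percent_change(b, t, floor_frac=0.05)
        assert pc.values[0, 0] == pytest.approx(100.0)
        assert np.isnan(pc.values[0, 1])


class TestTtestMaps:
    def test_identical_series_t0_p1(self):
        x = np.tile(np.arange(5.0), (3, 1))
        res = ttest_maps(x, x)
        np.testing.assert_array_equal(res.t, 0.0)
        np.testing.assert_array_equal(res.p, 1.0)
        assert not res.significant.any()

    def test_hand_formula_on_five_point_series(self):
        b = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        t = b + np.array([0.5, 0.7, 0.4, 0.6, 0.55])
        res = ttest_maps(b[None, :], t[None, :])
        d = t - b
        tstat = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        p = 2 * stats.t.sf(abs(tstat), 4)
        assert res.t[0] == pytest.approx(tstat, rel=1e-12)
        assert res.p[0] == pytest.approx(p, rel=1e-12)
        # cross-check against scipy's paired test
        sp = stats.ttest_rel(t, b)
        assert res.t[0] == pytest.approx(sp.statistic, rel=1e-12)
        assert res.p[0] == pytest.approx(sp.pvalue, rel=1e-12)

    def test_zero_variance_offset_signed_infinity(self):
        b = np.zeros((2, 4))
        t = np.stack([np.full(4, 1.0), np.full(4, -1.0)])
        res = ttest_maps(b, t)
        assert res.t[0] == np.inf and res.t[1] == -np.inf
        np.testing.assert_array_equal(res.p, 0.0)
        assert res.significant.all()

    def test_default_alpha(self):
        res = ttest_maps(np.zeros((1, 3)), np.zeros((1, 3)))
        assert res.alpha == 0.05

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            ttest_maps(np.zeros((1, 2)), np.zeros((1, 2)))

    def test_independent_mode_matches_scipy(self):
        rng = np.random.default_rng(7)
        b = rng.normal(size=(3, 10))
        t = rng.normal(size=(3, 10))
        res = ttest_maps(b, t, paired=False)
        sp = stats.ttest_ind(t, b, axis=-1)
        np.testing.assert_allclose(res.t, sp.statistic, rtol=1e-12)
        np.testing.assert_allclose(res.p, sp.pvalue, rtol=1e-12)

    def test_bh_correction_is_more_conservative(self):
        rng = np.random.default_rng(8)
        b = rng.normal(size=(50, 10))
        t = rng.normal(size=(50, 10))
        raw = ttest_maps(b, t)
        bh = ttest_maps(b, t, correction="bh")
        assert bh.significant.sum() <= raw.significant.sum()


class TestAverageMixingPairs:
    def test_identical_pair_unchanged_at_mean_time(self):
        m = np.ones((2, 3, 3))
        t2, v2 = average_mixing_pairs(np.array([0.4, 0.5]), m)
        assert t2.tolist() == [pytest.approx(0.45)]
        np.testing.assert_array_equal(v2[0], m[0])

    def test_pairwise_mean_oracle(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=(4, 2, 2))
        t = np.array([0.1, 0.2, 0.3, 0.4])
        t2, v2 = average_mixing_pairs(t, vals)
        np.testing.assert_allclose(v2[0], (vals[0] + vals[1]) / 2)
        np.testing.assert_allclose(v2[1], (vals[2] + vals[3]) / 2)
        np.testing.assert_allclose(t2, [0.15, 0.35])

    def test_odd_leftover_passed_through(self):
        vals = np.arange(3.0)[:, None]
        t2, v2 = average_mixing_pairs(np.array([0.1, 0.2, 0.3]), vals)
        assert t2[-1] == pytest.approx(0.3)
        assert v2[-1, 0] == 2.0


class TestCombineMultislice:
    def test_single_slice_identity(self):
        vals = np.arange(12.0).reshape(1, 3, 4)
        gx, gz, out = combine_multislice(
            [(vals, (0.0, 0.0), np.arange(3.0), np.arange(4.0))], (1.0, 1.0)
        )
        np.testing.assert_array_equal(out, vals)

    def test_two_slices_manual_placement_oracle(self):
        a = np.ones((1, 2, 2))
        b = 2 * np.ones((1, 2, 2))
        ox = np.array([0.0, 6.0])
        oz = np.array([0.0, 6.0])
        gx, gz, out = combine_multislice(
            [(a, (0.0, 0.0), ox, oz), (b, (0.0, 18.0), ox, oz)], (6.0, 6.0)
        )
        # disjoint along z: bins 0,6 from a; 18,24 from b; 12 empty
        assert gz.tolist() == [0.0, 6.0, 12.0, 18.0, 24.0]
        manual = np.zeros((1, 2, 5))
        manual[0, :, 0:2] = 1.0
        manual[0, :, 3:5] = 2.0
        np.testing.assert_array_equal(out, manual)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            combine_multislice([], (1.0, 1.0))


class TestPurity:
    def test_operations_are_bit_deterministic(self):
        rng = np.random.default_rng(10)
        t = np.arange(1, 20) * 0.15
        maps = rng.uniform(0, 1, size=(19, 5, 5))
        for fn in (
            lambda: arrival_time_map(t, maps),
            lambda: territory_mask(maps).mask,
            lambda: percent_change(maps[0], maps[1]).values,
            lambda: ttest_maps(maps[:9].T, maps[10:].T).p,
        ):
            a, b = fn(), fn()
            np.testing.assert_array_equal(a, b)


class TestMixingTimeSeries:
    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            MixingTimeSeries([1.0, 2.0], [1.0])

    def test_nonincreasing_times_rejected(self):
        with pytest.raises(ValueError):
            MixingTimeSeries([1.0, 1.0], [1.0, 2.0])
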