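"""Outlier-filtered temperature extraction and session aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from canopytherm import (
    DriftModel,
    ProtocolConfig,
    SceneConfig,
    TemperatureReading,
    filter_extremes,
    generate_session,
    measure_session,
    repetition_reading,
    summarize_series,
    summarize_session,
)
from canopytherm.errors import EmptyROIError, InsufficientROIError, ShapeError


def brute_force_filter(values):
    """Independent arithmetic oracle for the mean + 3 sigma upper screen."""
    n = len(values)
    mu = sum(values) / n
    sigma = (sum((v - mu) ** 2 for v in values) / n) ** 0.5
    thr = mu + 3.0 * sigma
    return [v for v in values if v <= thr], thr


class TestFilterExtremes:
    def test_constant_values_all_retained(self):
        retained, thr = filter_extremes([25.0] * 9)
        assert list(retained) == [25.0] * 9
        assert thr == 25.0

    def test_borderline_value_retained(self):
        # mu = 22, population sigma = 4, threshold 34 -> 30 is kept
        retained, thr = filter_extremes([20, 20, 20, 20, 30])
        assert thr == pytest.approx(34.0)
        assert len(retained) == 5

    def test_hot_outlier_removed(self):
        values = [20.0] * 99 + [40.0]
        retained, thr = filter_extremes(values)
        assert thr == pytest.approx(20.2 + 3 * 1.98997487, abs=1e-6)
        assert len(retained) == 99
        assert 40.0 not in retained

    def test_cold_outliers_kept(self):
        retained, _ = filter_extremes([20.0] * 50 + [-5.0])
        assert -5.0 in retained

    def test_empty_rejected(self):
        with pytest.raises(EmptyROIError):
            filter_extremes([])

    @given(
        st.lists(st.floats(min_value=-20, max_value=60), min_size=1, max_size=60)
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_oracle(self, values):
        retained, thr = filter_extremes(values)
        exp_retained, exp_thr = brute_force_filter(values)
        assert thr == pytest.approx(exp_thr, abs=1e-9)
        np.testing.assert_allclose(retained, exp_retained)

    @given(
        st.lists(st.floats(min_value=-20, max_value=60), min_size=1, max_size=60)
    )
    @settings(max_examples=100, deadline=None)
    def test_subset_and_median_never_raised(self, values):
        retained, _ = filter_extremes(values)
        assert len(retained) <= len(values)
        assert np.median(retained) <= np.median(values) + 1e-12


class TestRepetitionReading:
    def test_constant_frame(self):
        frame = np.full((10, 10), 25.0)
        mask = np.ones((10, 10), dtype=bool)
        r = repetition_reading(frame, mask)
        assert r.mean_C == r.median_C == 25.0
        assert r.std_C == 0.0
        assert r.n_masked == r.n_retained == 100

    def test_garbage_in_garbage_out_with_background_mask(self):
        # a mask over hot soil reports soil, demonstrating why segmentation
        # accuracy matters upstream
        frame = np.full((10, 10), 40.0)
        frame[:5] = 25.0  # canopy half
        bg_mask = np.zeros((10, 10), dtype=bool)
        bg_mask[5:] = True
        assert repetition_reading(frame, bg_mask).median_C == 40.0

    def test_noiseless_scene_truth_mask_recovers_exactly(
        self, noiseless_scene_config
    ):
        from canopytherm import generate_scene

        pair = generate_scene(noiseless_scene_config, seed=2)
        r = repetition_reading(pair.thermal, pair.truth_mask_thermal)
        assert r.median_C == noiseless_scene_config.canopy_temp_C

    def test_sub_minimum_mask_rejected(self):
        frame = np.full((10, 10), 25.0)
        mask = np.zeros((10, 10), dtype=bool)
        mask[0, :5] = True
        with pytest.raises(InsufficientROIError):
            repetition_reading(frame, mask, min_canopy_cells=10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            repetition_reading(np.zeros((4, 4)), np.ones((5, 5), bool))

    def test_contamination_barely_moves_median(self, small_scene_config):
        from canopytherm import generate_scene

        cfg = SceneConfig(
            image_size_visible=(240, 320),
            grid_size_thermal=(60, 80),
            cover_fraction=0.35,
            canopy_spatial_sd_C=0.0,
            sensor_noise_sd_C=0.1,
        )
        rng = np.random.default_rng(0)
        for seed in range(5):
            pair = generate_scene(cfg, seed=seed)
            clean = repetition_reading(pair.thermal, pair.truth_mask_thermal)
            dirty = pair.thermal.data.copy()
            idx = np.flatnonzero(pair.truth_mask_thermal.ravel())
            hot = rng.choice(idx, size=max(1, idx.size // 20), replace=False)
            dirty.ravel()[hot] += 15.0
            contaminated = repetition_reading(dirty, pair.truth_mask_thermal)
            assert abs(contaminated.median_C - clean.median_C) < 0.05


def _reading(median):
    return TemperatureReading(
        mean_C=median, median_C=median, std_C=0.0,
        n_masked=10, n_retained=10, threshold_C=median,
    )


class TestSummaries:
    def test_series_summary_arithmetic(self):
        s = summarize_series([_reading(24.0), _reading(24.2), _reading(24.4)])
        assert s.mean_of_medians_C == pytest.approx(24.2)
        assert s.median_of_medians_C == pytest.approx(24.2)
        assert s.std_of_medians_C == pytest.approx(0.2)
        assert s.n_repetitions_used == 3

    def test_even_count_median_is_midpoint(self):
        s = summarize_series([_reading(24.0), _reading(25.0)])
        assert s.median_of_medians_C == pytest.approx(24.5)

    def test_single_reading_and_order_invariance(self):
        single = summarize_series([_reading(24.3)])
        assert single.median_of_medians_C == 24.3
        assert single.std_of_medians_C == 0.0
        a = summarize_series([_reading(m) for m in (24.0, 24.2, 24.4)])
        b = summarize_series([_reading(m) for m in (24.4, 24.0, 24.2)])
        assert a == b

    def test_session_mean_of_series_medians(self):
        series = [
            summarize_series([_reading(m)]) for m in (24.0, 25.0)
        ]
        res = summarize_session(series)
        assert res.t_canopy_C == pytest.approx(24.5)
        assert res.n_series == 2
        single = summarize_session(series[:1])
        assert single.t_canopy_C == 24.0
        assert single.std_C == 0.0

    def test_empty_inputs_rejected(self):
        with pytest.raises(EmptyROIError):
            summarize_series([])
        with pytest.raises(EmptyROIError):
            summarize_session([])


class TestParameterRecovery:
    def test_session_estimate_within_tolerance(self):
        cfg = SceneConfig(
            image_size_visible=(240, 320),
            grid_size_thermal=(60, 80),
            cover_fraction=0.35,
            canopy_temp_C=26.0,
            background_temp_C=38.0,
            sensor_noise_sd_C=0.1,
        )
        proto = ProtocolConfig(n_series=3, n_repetitions=25)
        for seed in range(3):
            session = generate_session(cfg, DriftModel(), proto, seed=seed)
            res = measure_session(session, session.truth_mask_thermal)
            assert abs(res.t_canopy_C - 26.0) <= 0.1
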