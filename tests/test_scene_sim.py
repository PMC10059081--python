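"""Synthetic scene, session and field-day generation."""

import numpy as np
import pandas as pd
import pytest

from canopytherm import (
    DriftModel,
    FieldDayConfig,
    ProtocolConfig,
    SceneConfig,
    generate_field_day,
    generate_scene,
    generate_session,
    register_mask,
    truth_registration,
)
from canopytherm.errors import ConfigurationError


class TestGenerateScene:
    def test_zero_cover_yields_background_only(self, small_scene_config):
        cfg = SceneConfig(
            image_size_visible=(120, 160),
            grid_size_thermal=(30, 40),
            cover_fraction=0.0,
        )
        pair = generate_scene(cfg, seed=1)
        assert not pair.truth_mask.any()
        assert not pair.truth_mask_thermal.any()
        # every thermal pixel is drawn from the soil/branch background
        assert pair.thermal.data.min() > cfg.canopy_temp_C + 3

    def test_full_cover_noiseless_is_constant_canopy_temp(self):
        cfg = SceneConfig(
            image_size_visible=(120, 160),
            grid_size_thermal=(30, 40),
            cover_fraction=1.0,
            canopy_temp_C=25.0,
            canopy_spatial_sd_C=0.0,
            sensor_noise_sd_C=0.0,
        )
        pair = generate_scene(cfg, seed=3)
        assert pair.truth_mask.all()
        np.testing.assert_array_equal(pair.thermal.data, 25.0)

    def test_realized_cover_and_canopy_mean(self):
        cfg = SceneConfig(cover_fraction=0.35)  # full 480x640 scene
        pair = generate_scene(cfg, seed=7)
        frac = pair.truth_mask.mean()
        assert 0.30 <= frac <= 0.40
        canopy_vals = pair.thermal.data[pair.truth_mask_thermal]
        total_sd = np.hypot(cfg.canopy_spatial_sd_C, cfg.sensor_noise_sd_C)
        tol = 3 * total_sd / np.sqrt(canopy_vals.size)
        assert abs(canopy_vals.mean() - cfg.canopy_temp_C) <= tol

    def test_deterministic_for_fixed_seed(self, small_scene_config):
        a = generate_scene(small_scene_config, seed=42)
        b = generate_scene(small_scene_config, seed=42)
        np.testing.assert_array_equal(a.visible, b.visible)
        np.testing.assert_array_equal(a.thermal.data, b.thermal.data)
        np.testing.assert_array_equal(a.truth_mask, b.truth_mask)

    def test_coverage_control_over_seeds(self):
        cfg_base = dict(image_size_visible=(120, 160), grid_size_thermal=(30, 40))
        for target in (0.1, 0.35, 0.6, 0.9):
            cfg = SceneConfig(cover_fraction=target, **cfg_base)
            fracs = [
                generate_scene(cfg, seed=s).truth_mask.mean() for s in range(20)
            ]
            assert abs(np.mean(fracs) - target) <= 0.02

    def test_noiseless_thermal_matches_registered_truth_mask(
        self, noiseless_scene_config
    ):
        pair = generate_scene(noiseless_scene_config, seed=9)
        model = truth_registration(noiseless_scene_config)
        registered = register_mask(pair.truth_mask, model)
        canopy_set = pair.thermal.data == noiseless_scene_config.canopy_temp_C
        np.testing.assert_array_equal(canopy_set, registered)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            SceneConfig(cover_fraction=1.5)
        with pytest.raises(ConfigurationError):
            SceneConfig(image_size_visible=(0, 10))
        with pytest.raises(ConfigurationError):
            SceneConfig(
                image_size_visible=(100, 100), grid_size_thermal=(200, 200)
            )
        with pytest.raises(ConfigurationError):
            SceneConfig(sensor_noise_sd_C=-1.0)


class TestGenerateSession:
    def test_no_drift_matches_single_scene_within_noise(self, small_scene_config):
        from canopytherm import measure_session

        proto = ProtocolConfig(n_series=3, n_repetitions=5)
        session = generate_session(
            small_scene_config, DriftModel(transient_bias_C=0.0), proto, seed=4
        )
        res = measure_session(session, session.truth_mask_thermal)
        assert abs(res.t_canopy_C - small_scene_config.canopy_temp_C) < 0.05

    def test_residual_bias_decays_exponentially(self, small_scene_config):
        # first post-transient repetition: b0 * exp(-30/10) ~= 0.0747 C
        drift = DriftModel(transient_bias_C=1.5, time_constant_s=10.0)
        proto = ProtocolConfig(n_series=1, n_repetitions=3, transient_s=30.0)
        cfg = SceneConfig(
            image_size_visible=(120, 160),
            grid_size_thermal=(30, 40),
            cover_fraction=0.35,
            canopy_spatial_sd_C=0.0,
            sensor_noise_sd_C=0.0,
        )
        session = generate_session(cfg, drift, proto, seed=5)
        rep0 = session.series[0].repetitions[0]
        assert rep0.thermal.time_since_ffc_s == pytest.approx(30.0)
        canopy = session.truth_mask_thermal
        bias = rep0.thermal.data[canopy].mean() - cfg.canopy_temp_C
        assert bias == pytest.approx(1.5 * np.exp(-3.0), abs=1e-9)

    def test_gusts_cool_canopy_cells_only(self, small_scene_config, short_protocol):
        gusty = generate_session(
            small_scene_config,
            DriftModel(gust_prob=1.0, gust_delta_C=2.0),
            short_protocol,
            seed=6,
        )
        calm = generate_session(
            small_scene_config,
            DriftModel(gust_prob=0.0, gust_delta_C=2.0),
            short_protocol,
            seed=6,
        )
        canopy = gusty.truth_mask_thermal
        for s_g, s_c in zip(gusty.series, calm.series):
            for r_g, r_c in zip(s_g.repetitions, s_c.repetitions):
                assert r_g.gust
                diff = r_c.thermal.data - r_g.thermal.data
                np.testing.assert_allclose(diff[canopy], 2.0)
                np.testing.assert_allclose(diff[~canopy], 0.0)

    def test_transient_flag_set_when_capturing_early(self, small_scene_config):
        proto = ProtocolConfig(
            n_series=1, n_repetitions=10, rep_time_s=5.0, transient_s=30.0,
            capture_during_transient=True,
        )
        session = generate_session(small_scene_config, DriftModel(), proto, seed=8)
        flags = [r.transient for r in session.series[0].repetitions]
        # captures at t = 0, 5, ..., 45 s: the first six are in the transient
        assert flags == [True] * 6 + [False] * 4


class TestGenerateFieldDay:
    def test_zero_noise_aligned_pairs_identical_at_equal_periods(self):
        from canopytherm import align_series

        cfg = FieldDayConfig(
            thermal_period_min=10,
            noise_sd_ts_C=0.0,
            noise_sd_tir_C=0.0,
            noise_sd_ta_C=0.0,
        )
        day = generate_field_day(cfg, seed=2)
        pairs = align_series(day.channels["T_S"], day.channels["T_IR"])
        np.testing.assert_allclose(
            pairs["slow_value"], pairs["fast_mean"], rtol=0, atol=1e-12
        )

    def test_sample_counts_on_inclusive_grid(self):
        day = generate_field_day(FieldDayConfig(), seed=1)
        # 07:00-15:00 at 15 min inclusive -> 33 thermal samples
        assert len(day.channels["T_S"]) == 33
        assert len(day.channels["T_IR"]) == 49

    def test_stressed_canopy_exceeds_air_after_peak_hour(self):
        cfg = FieldDayConfig(stress_offset_C=2.0)
        hours = np.array([cfg.air_peak_hour + 0.5, cfg.air_peak_hour + 2.0])
        assert (cfg.canopy_latent(hours) > cfg.air_temp_latent(hours)).all()
        # and sits below air temperature in the early morning
        assert cfg.canopy_latent(np.array([7.0])) < cfg.air_temp_latent(
            np.array([7.0])
        )

    def test_end_before_start_rejected(self):
        with pytest.raises(ConfigurationError):
            FieldDayConfig(
                start="2022-07-22T15:00:00+02:00", end="2022-07-22T07:00:00+02:00"
            )

    def test_shared_latent_curve_links_both_sensors(self):
        day = generate_field_day(FieldDayConfig(), seed=10)
        ts = day.channels["T_S"]
        assert day.truth is not None
        np.testing.assert_allclose(
            ts.to_numpy(), day.truth.to_numpy(), atol=1.0
        )
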