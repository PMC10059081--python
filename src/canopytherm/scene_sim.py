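"""Synthetic canopy scenes, measurement sessions and field days.

Everything the measurement pipeline consumes can be generated here with
known ground truth: downward-looking canopy scenes (20-50 % leaf cover over
soil and branches is the realistic regime), the thermal matrix seen by a
co-mounted low-resolution radiometric camera, full repetition/series
capture sessions including post-FFC transient drift and wind gusts, and
multi-rate field-day time series of canopy, reference-radiometer and
weather channels sharing one latent diurnal curve.

The scene model is deliberately simple - leaves are overlapping random
ellipses in green hues, placed until a target cover fraction is reached -
because it makes the ground-truth mask exact.  Within a session the scene
geometry is static (the cameras are rigidly mounted and a series lasts
under a minute); only sensor noise, calibration drift and gusts vary
between repetitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit
from skimage.draw import ellipse as draw_ellipse

from canopytherm.errors import ConfigurationError
from canopytherm.registration import RegistrationModel, register_mask
from canopytherm.types import ThermalFrame

__all__ = [
    "SceneConfig",
    "DriftModel",
    "ScenePair",
    "RepetitionCapture",
    "SeriesCapture",
    "Session",
    "FieldDayConfig",
    "generate_scene",
    "generate_session",
    "generate_field_day",
    "truth_registration",
]

_SOIL, _BRANCH, _CANOPY = 0, 1, 2


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, temperatures and noise of one synthetic scene.

    Attributes
    ----------
    image_size_visible
        ``(rows, cols)`` of the RGB frame, default (480, 640).
    grid_size_thermal
        ``(rows, cols)`` of the thermal matrix, default (120, 160); must not
        exceed the visible size on either axis.
    cover_fraction
        Target canopy area fraction in [0, 1].
    canopy_temp_C, background_temp_C, branch_temp_C
        True surface temperatures (C) of leaves, soil and branches.  The
        defaults (26 / 38 / 34) describe a transpiring midday canopy over
        sun-heated bare soil.
    canopy_spatial_sd_C
        Within-canopy temperature spread (C); a static leaf-to-leaf field.
    sensor_noise_sd_C
        Per-pixel additive read noise (C), redrawn every capture.
    emissivity, reflected_temp_C
        Radiometric metadata carried on generated frames; synthetic values
        are already surface temperatures.
    leaf_axis_frac
        Range of ellipse semi-axis lengths as a fraction of the smaller
        visible dimension.
    n_branches
        Number of dark branch strokes drawn across the background.
    """

    image_size_visible: tuple[int, int] = (480, 640)
    grid_size_thermal: tuple[int, int] = (120, 160)
    cover_fraction: float = 0.35
    canopy_temp_C: float = 26.0
    background_temp_C: float = 38.0
    branch_temp_C: float = 34.0
    canopy_spatial_sd_C: float = 0.3
    sensor_noise_sd_C: float = 0.1
    emissivity: float = 1.0
    reflected_temp_C: float = 22.0
    leaf_axis_frac: tuple[float, float] = (0.015, 0.05)
    n_branches: int = 4

    def __post_init__(self) -> None:
        hv, wv = self.image_size_visible
        ht, wt = self.grid_size_thermal
        if hv <= 0 or wv <= 0 or ht <= 0 or wt <= 0:
            raise ConfigurationError("image sizes must be positive")
        if ht > hv or wt > wv:
            raise ConfigurationError("thermal grid may not exceed visible grid")
        if not 0.0 <= self.cover_fraction <= 1.0:
            raise ConfigurationError("cover_fraction must lie in [0, 1]")
        if self.canopy_spatial_sd_C < 0 or self.sensor_noise_sd_C < 0:
            raise ConfigurationError("noise standard deviations must be >= 0")
        lo, hi = self.leaf_axis_frac
        if not 0 < lo <= hi:
            raise ConfigurationError("leaf_axis_frac must be positive and ordered")


@dataclass(frozen=True)
class DriftModel:
    """Post-FFC transient drift and wind-gust perturbations.

    After each flat-field correction the whole thermal frame carries an
    additive bias ``b0 * exp(-t / tau)`` where ``t`` is the time since the
    FFC; the defaults (b0 = 1.5 C, tau = 10 s) make the residual bias
    negligible (< 0.1 C) once the 30 s stabilisation wait has elapsed.
    Gusts model brief convective cooling: with probability ``gust_prob`` a
    repetition's canopy cells are lowered by ``gust_delta_C``.
    """

    transient_bias_C: float = 1.5
    time_constant_s: float = 10.0
    gust_prob: float = 0.0
    gust_delta_C: float = 2.0

    def __post_init__(self) -> None:
        if self.time_constant_s <= 0:
            raise ConfigurationError("time_constant_s must be positive")
        if not 0.0 <= self.gust_prob <= 1.0:
            raise ConfigurationError("gust_prob must lie in [0, 1]")

    def bias_C(self, t_since_ffc_s: float) -> float:
        """Residual frame bias (C) at a given time since the FFC."""
        return self.transient_bias_C * math.exp(
            -t_since_ffc_s / self.time_constant_s
        )


@dataclass
class ScenePair:
    """One visible frame + thermal matrix capture with ground truth."""

    visible: np.ndarray
    thermal: ThermalFrame
    truth_mask: np.ndarray
    truth_canopy_temp_C: float
    truth_mask_thermal: np.ndarray

    def __post_init__(self) -> None:
        if self.truth_mask.shape != self.visible.shape[:2]:
            raise ConfigurationError("truth mask must match visible dimensions")


@dataclass
class RepetitionCapture:
    """A single repetition within a series."""

    thermal: ThermalFrame
    transient: bool
    gust: bool


@dataclass
class SeriesCapture:
    """One FFC event followed by its repetitions."""

    ffc_time_s: float
    repetitions: list[RepetitionCapture]


@dataclass
class Session:
    """A protocol-structured capture: series of repetitions on one scene."""

    visible: np.ndarray
    truth_mask: np.ndarray
    truth_mask_thermal: np.ndarray
    truth_canopy_temp_C: float
    series: list[SeriesCapture]
    config: Optional[SceneConfig] = None
    drift: Optional[DriftModel] = None
    protocol: Optional["ProtocolConfig"] = None  # snapshot of the capture protocol


def truth_registration(config: SceneConfig) -> RegistrationModel:
    """Exact registration model of a synthetic scene (full-frame overlap)."""
    hv, wv = config.image_size_visible
    ht, wt = config.grid_size_thermal
    return RegistrationModel(
        visible_roi=(0.0, 0.0, float(hv), float(wv)),
        scale_rows=hv / ht,
        scale_cols=wv / wt,
        grid_size=(ht, wt),
    )


# ---------------------------------------------------------------------------
# scene rendering
# ---------------------------------------------------------------------------

def _render_labels(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Label image at visible resolution: 0 soil, 1 branch, 2 canopy."""
    H, W = config.image_size_visible
    labels = np.zeros((H, W), dtype=np.uint8)

    # branch strokes: thick random line segments over the soil
    for _ in range(config.n_branches):
        r0, c0 = rng.uniform(0, H), rng.uniform(0, W)
        ang = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(0.4, 1.0) * max(H, W)
        half_w = max(1, int(0.008 * min(H, W)))
        n_steps = max(2, int(length))
        rr = np.clip(np.linspace(r0, r0 + length * np.sin(ang), n_steps), 0, H - 1)
        cc = np.clip(np.linspace(c0, c0 + length * np.cos(ang), n_steps), 0, W - 1)
        ri, ci = rr.astype(int), cc.astype(int)
        for dr in range(-half_w, half_w + 1):
            for dc in range(-half_w, half_w + 1):
                labels[np.clip(ri + dr, 0, H - 1), np.clip(ci + dc, 0, W - 1)] = _BRANCH

    target = config.cover_fraction
    if target >= 1.0:
        labels[:] = _CANOPY
        return labels
    if target <= 0.0:
        return labels

    lo, hi = config.leaf_axis_frac
    base = min(H, W)
    total = H * W
    canopy = np.zeros((H, W), dtype=bool)
    n_true = 0
    max_ellipses = 100_000
    for _ in range(max_ellipses):
        if n_true / total >= target:
            break
        rc, cc_ = rng.uniform(0, H), rng.uniform(0, W)
        a = rng.uniform(lo, hi) * base
        b = a * rng.uniform(0.45, 0.9)
        rot = rng.uniform(0, np.pi)
        rr, cc2 = draw_ellipse(rc, cc_, a, b, shape=(H, W), rotation=rot)
        newly = ~canopy[rr, cc2]
        canopy[rr, cc2] = True
        n_true += int(newly.sum())
    labels[canopy] = _CANOPY
    return labels


def _downsample_labels(labels: np.ndarray, config: SceneConfig) -> np.ndarray:
    """Majority-vote label per thermal cell; canopy needs fraction >= 0.5.

    Uses the same pixel-to-cell assignment as ``register_mask`` under the
    scene's exact registration model, so the canopy cells here coincide
    exactly with the registered ground-truth mask.
    """
    H, W = labels.shape
    gr, gc = config.grid_size_thermal
    ri = (np.arange(H) * gr) // H
    ci = (np.arange(W) * gc) // W
    flat = (ri[:, None] * gc + ci[None, :]).ravel()
    tot = np.bincount(flat, minlength=gr * gc).astype(float)
    out = np.full(gr * gc, _SOIL, dtype=np.uint8)
    frac_canopy = np.bincount(
        flat, weights=(labels == _CANOPY).ravel(), minlength=gr * gc
    ) / tot
    frac_branch = np.bincount(
        flat, weights=(labels == _BRANCH).ravel(), minlength=gr * gc
    ) / tot
    frac_soil = np.bincount(
        flat, weights=(labels == _SOIL).ravel(), minlength=gr * gc
    ) / tot
    out[frac_branch > frac_soil] = _BRANCH
    out[frac_canopy >= 0.5] = _CANOPY
    return out.reshape(gr, gc)


def _render_visible(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """RGB render: soil browns, dark branches, green canopy, pixel jitter."""
    H, W = labels.shape
    img = np.empty((H, W, 3), dtype=float)
    img[labels == _SOIL] = (124.0, 92.0, 60.0)
    img[labels == _BRANCH] = (58.0, 44.0, 30.0)
    img[labels == _CANOPY] = (52.0, 138.0, 58.0)
    img += rng.normal(0.0, 9.0, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _base_temperature(labels_th: np.ndarray, config: SceneConfig) -> np.ndarray:
    temp = np.full(labels_th.shape, config.background_temp_C, dtype=float)
    temp[labels_th == _BRANCH] = config.branch_temp_C
    temp[labels_th == _CANOPY] = config.canopy_temp_C
    return temp


def _spatial_field(
    labels_th: np.ndarray, config: SceneConfig, rng: np.random.Generator
) -> np.ndarray:
    """Static within-canopy temperature spread (leaf-to-leaf variation)."""
    field_ = np.zeros(labels_th.shape, dtype=float)
    if config.canopy_spatial_sd_C > 0:
        canopy = labels_th == _CANOPY
        field_[canopy] = rng.normal(
            0.0, config.canopy_spatial_sd_C, size=int(canopy.sum())
        )
    return field_


def _thermal_capture(
    base: np.ndarray,
    config: SceneConfig,
    rng: np.random.Generator,
    *,
    bias_C: float = 0.0,
    gust_delta_C: float = 0.0,
    canopy_cells: Optional[np.ndarray] = None,
    time_since_ffc_s: float = 0.0,
    timestamp_s: float = 0.0,
) -> ThermalFrame:
    data = base + bias_C
    if config.sensor_noise_sd_C > 0:
        data = data + rng.normal(0.0, config.sensor_noise_sd_C, size=base.shape)
    else:
        data = data.copy()
    if gust_delta_C != 0.0 and canopy_cells is not None:
        data[canopy_cells] -= gust_delta_C
    return ThermalFrame(
        data=data,
        time_since_ffc_s=time_since_ffc_s,
        timestamp_s=timestamp_s,
        emissivity=config.emissivity,
        reflected_temp_C=config.reflected_temp_C,
    )


def generate_scene(config: SceneConfig, seed: int) -> ScenePair:
    """Generate one paired visible/thermal capture with exact ground truth.

    Deterministic for a fixed ``(config, seed)``.  The realised canopy
    fraction matches ``config.cover_fraction`` to within the area of a
    single leaf ellipse (well inside +/- 0.05 at default sizes).
    """
    rng = np.random.default_rng(seed)
    labels = _render_labels(config, rng)
    labels_th = _downsample_labels(labels, config)
    visible = _render_visible(labels, rng)
    base = _base_temperature(labels_th, config) + _spatial_field(
        labels_th, config, rng
    )
    thermal = _thermal_capture(base, config, rng)
    return ScenePair(
        visible=visible,
        thermal=thermal,
        truth_mask=labels == _CANOPY,
        truth_canopy_temp_C=config.canopy_temp_C,
        truth_mask_thermal=labels_th == _CANOPY,
    )


def generate_session(
    config: SceneConfig,
    drift: DriftModel,
    protocol: "ProtocolConfig",
    seed: int,
) -> Session:
    """Simulate a full measurement session on one static scene.

    Each series opens with an FFC; repetition ``k`` is captured at
    ``transient_s + k * rep_time_s`` seconds after it (or ``k * rep_time_s``
    when the protocol captures during the transient, in which case early
    repetitions carry the ``transient`` flag and a large residual bias).
    The whole frame of every repetition carries the additive drift bias
    ``b0 * exp(-t/tau)``; gust-affected repetitions have their canopy cells
    cooled by ``gust_delta_C``.
    """
    # local import: protocol module has no dependency back on scene_sim
    from canopytherm.protocol import ProtocolConfig  # noqa: F401

    rng = np.random.default_rng(seed)
    # independent streams so toggling gust_prob leaves other draws untouched
    scene_rng, noise_rng, gust_rng = rng.spawn(3)

    labels = _render_labels(config, scene_rng)
    labels_th = _downsample_labels(labels, config)
    visible = _render_visible(labels, scene_rng)
    canopy_cells = labels_th == _CANOPY
    base = _base_temperature(labels_th, config) + _spatial_field(
        labels_th, config, scene_rng
    )

    start_offset = 0.0 if protocol.capture_during_transient else protocol.transient_s
    series_span = protocol.transient_s + protocol.n_repetitions * protocol.rep_time_s

    series: list[SeriesCapture] = []
    for s in range(protocol.n_series):
        ffc_time = s * series_span
        reps: list[RepetitionCapture] = []
        for k in range(protocol.n_repetitions):
            t = start_offset + k * protocol.rep_time_s
            gust = bool(gust_rng.random() < drift.gust_prob)
            frame = _thermal_capture(
                base,
                config,
                noise_rng,
                bias_C=drift.bias_C(t),
                gust_delta_C=drift.gust_delta_C if gust else 0.0,
                canopy_cells=canopy_cells,
                time_since_ffc_s=t,
                timestamp_s=ffc_time + t,
            )
            reps.append(
                RepetitionCapture(
                    thermal=frame,
                    transient=t < protocol.transient_s,
                    gust=gust,
                )
            )
        series.append(SeriesCapture(ffc_time_s=ffc_time, repetitions=reps))

    return Session(
        visible=visible,
        truth_mask=labels == _CANOPY,
        truth_mask_thermal=canopy_cells,
        truth_canopy_temp_C=config.canopy_temp_C,
        series=series,
        config=config,
        drift=drift,
        protocol=protocol,
    )


# ---------------------------------------------------------------------------
# field days
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldDayConfig:
    """Multi-rate field-day time series shared by all sensors.

    The thermal sensor reads every ``thermal_period_min`` minutes while the
    reference radiometer and the weather station read every
    ``reference_period_min`` minutes (15 and 10 by default, so only two
    timestamps per hour coincide).  Canopy temperature follows a latent
    curve tied to the diurnal air-temperature cycle: a transpiring canopy
    sits ``morning_depression_C`` below air temperature in the morning and,
    as stomata close under water stress, rises to ``stress_offset_C`` above
    it after ``air_peak_hour`` - so the canopy and air curves cross around
    midday.  Both temperature sensors observe the *same* latent curve plus
    independent noise, making their true agreement known by construction.
    """

    start: str = "2022-07-22T07:00:00+02:00"
    end: str = "2022-07-22T15:00:00+02:00"
    thermal_period_min: int = 15
    reference_period_min: int = 10
    air_temp_min_C: float = 18.0
    air_temp_max_C: float = 36.0
    air_peak_hour: float = 14.0
    stress_offset_C: float = 2.0
    morning_depression_C: float = 1.5
    stress_width_h: float = 0.75
    wind_mean_mps: float = 1.5
    radiation_max_Wm2: float = 900.0
    noise_sd_ts_C: float = 0.15
    noise_sd_tir_C: float = 0.15
    noise_sd_ta_C: float = 0.15
    noise_sd_wind: float = 0.4
    noise_sd_rad: float = 25.0
    treatment: str = "CTL"

    def __post_init__(self) -> None:
        if self.thermal_period_min <= 0 or self.reference_period_min <= 0:
            raise ConfigurationError("sampling periods must be positive")
        if pd.Timestamp(self.end) <= pd.Timestamp(self.start):
            raise ConfigurationError("field day must end after it starts")
        for sd in (
            self.noise_sd_ts_C,
            self.noise_sd_tir_C,
            self.noise_sd_ta_C,
            self.noise_sd_wind,
            self.noise_sd_rad,
        ):
            if sd < 0:
                raise ConfigurationError("noise standard deviations must be >= 0")

    def air_temp_latent(self, hours: np.ndarray) -> np.ndarray:
        mean = 0.5 * (self.air_temp_min_C + self.air_temp_max_C)
        amp = 0.5 * (self.air_temp_max_C - self.air_temp_min_C)
        return mean + amp * np.cos(2 * np.pi * (hours - self.air_peak_hour) / 24.0)

    def canopy_latent(self, hours: np.ndarray) -> np.ndarray:
        dep, off = self.morning_depression_C, self.stress_offset_C
        excess = -dep + (off + dep) * expit(
            (hours - self.air_peak_hour) / self.stress_width_h
        )
        return self.air_temp_latent(hours) + excess


def _hours_of_day(index: pd.DatetimeIndex) -> np.ndarray:
    return (
        index.hour.to_numpy()
        + index.minute.to_numpy() / 60.0
        + index.second.to_numpy() / 3600.0
    )


def generate_field_day(config: FieldDayConfig, seed: int) -> "FieldDay":
    """Generate one field day of multi-rate sensor time series.

    Returns a :class:`canopytherm.comparison.FieldDay` whose ``truth``
    attribute holds the noise-free latent canopy curve at the thermal
    timestamps.
    """
    from canopytherm.comparison import FieldDay

    rng = np.random.default_rng(seed)
    t_th = pd.date_range(
        config.start, config.end, freq=f"{config.thermal_period_min}min"
    )
    t_ref = pd.date_range(
        config.start, config.end, freq=f"{config.reference_period_min}min"
    )
    h_th, h_ref = _hours_of_day(t_th), _hours_of_day(t_ref)

    latent_th = config.canopy_latent(h_th)
    latent_ref = config.canopy_latent(h_ref)

    ts = latent_th + rng.normal(0.0, config.noise_sd_ts_C, len(t_th))
    tir = latent_ref + rng.normal(0.0, config.noise_sd_tir_C, len(t_ref))
    ta = config.air_temp_latent(h_ref) + rng.normal(
        0.0, config.noise_sd_ta_C, len(t_ref)
    )
    wind = np.clip(
        config.wind_mean_mps
        + 0.6 * np.sin(2 * np.pi * (h_ref - 15.0) / 24.0)
        + rng.normal(0.0, config.noise_sd_wind, len(t_ref)),
        0.0,
        None,
    )
    rad = np.clip(
        config.radiation_max_Wm2
        * np.clip(np.sin(np.pi * (h_ref - 6.5) / 14.0), 0.0, None)
        + rng.normal(0.0, config.noise_sd_rad, len(t_ref)),
        0.0,
        None,
    )

    channels = {
        "T_S": pd.Series(ts, index=t_th, name="T_S"),
        "T_IR": pd.Series(tir, index=t_ref, name="T_IR"),
        "T_A": pd.Series(ta, index=t_ref, name="T_A"),
        "wind_mps": pd.Series(wind, index=t_ref, name="wind_mps"),
        "radiation_Wm2": pd.Series(rad, index=t_ref, name="radiation_Wm2"),
    }
    metadata = {
        "date": str(pd.Timestamp(config.start).date()),
        "treatment": config.treatment,
        "thermal_period_min": config.thermal_period_min,
        "reference_period_min": config.reference_period_min,
    }
    truth = pd.Series(latent_th, index=t_th, name="T_C_latent")
    return FieldDay(channels=channels, metadata=metadata, truth=truth)
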