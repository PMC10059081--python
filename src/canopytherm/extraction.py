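"""Robust canopy-temperature extraction from masked thermal matrices.

One repetition yields the temperatures of the thermal cells under the
registered leaf mask.  Extreme values - those above the mean plus three
standard deviations of the masked values - are filtered out in a single
upper-tail pass (hot soil or sky leaking through mask errors pulls the
distribution up, never down), and the median of the retained values is the
repetition's representative temperature.  Repetition medians are then
summarised per series (mean / median / std), and the session's final
canopy temperature T_S is the mean of the series medians, with their
standard deviation as the dispersion estimate.

Statistical conventions: the 3-sigma cut uses the population standard
deviation (divide by n) so the screen is a fixed function of the sample;
all *reported* dispersion statistics use the sample standard deviation
(divide by n-1), returning 0 for a single value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from canopytherm.errors import EmptyROIError, InsufficientROIError, ShapeError
from canopytherm.types import ThermalFrame

__all__ = [
    "TemperatureReading",
    "SeriesSummary",
    "SessionResult",
    "filter_extremes",
    "repetition_reading",
    "summarize_series",
    "summarize_session",
    "session_readings",
    "measure_session",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_CANOPY_CELLS = 10


@dataclass(frozen=True)
class TemperatureReading:
    """Per-repetition statistics of the masked, outlier-filtered cells."""

    mean_C: float
    median_C: float
    std_C: float
    n_masked: int
    n_retained: int
    threshold_C: float


@dataclass(frozen=True)
class SeriesSummary:
    """Statistics over the repetition medians of one series."""

    mean_of_medians_C: float
    median_of_medians_C: float
    std_of_medians_C: float
    n_repetitions_used: int


@dataclass(frozen=True)
class SessionResult:
    """Final session estimate: mean and std of the series medians."""

    t_canopy_C: float
    std_C: float
    n_series: int


def _sample_std(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1)) if values.size > 1 else 0.0


def filter_extremes(values: Sequence[float]) -> tuple[np.ndarray, float]:
    """Drop values above mean + 3 population-sigma; single pass, upper side.

    Returns ``(retained, threshold)``.  Cold outliers are kept - only the
    upper tail is screened, because contamination from a hotter background
    is the failure mode masking errors produce.

    Raises
    ------
    EmptyROIError
        If ``values`` is empty.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise EmptyROIError("cannot filter an empty set of temperatures")
    mu = float(np.mean(values))
    sigma = float(np.std(values))  # population sigma, ddof=0
    threshold = mu + 3.0 * sigma
    return values[values <= threshold], threshold


def repetition_reading(
    thermal: ThermalFrame | np.ndarray,
    mask: np.ndarray,
    min_canopy_cells: int = DEFAULT_MIN_CANOPY_CELLS,
) -> TemperatureReading:
    """Aggregate one thermal frame under a registered canopy mask.

    Gathers the masked temperatures, applies :func:`filter_extremes`, and
    reports mean / median / sample std of the retained values.  The median
    is the repetition's representative temperature.

    Raises
    ------
    InsufficientROIError
        If the mask holds fewer than ``min_canopy_cells`` true cells.
    """
    data = thermal.data if isinstance(thermal, ThermalFrame) else np.asarray(thermal)
    mask = np.asarray(mask).astype(bool)
    if data.shape != mask.shape:
        raise ShapeError(
            f"thermal shape {data.shape} does not match mask shape {mask.shape}"
        )
    n_masked = int(mask.sum())
    if n_masked < max(1, min_canopy_cells):
        raise InsufficientROIError(
            f"mask covers {n_masked} cells, fewer than the minimum {min_canopy_cells}"
        )
    retained, threshold = filter_extremes(data[mask])
    return TemperatureReading(
        mean_C=float(np.mean(retained)),
        median_C=float(np.median(retained)),
        std_C=_sample_std(retained),
        n_masked=n_masked,
        n_retained=int(retained.size),
        threshold_C=threshold,
    )


def summarize_series(readings: Sequence[TemperatureReading]) -> SeriesSummary:
    """Mean / median / sample std over the repetition medians of a series."""
    if len(readings) == 0:
        raise EmptyROIError("series has no usable repetitions")
    medians = np.asarray([r.median_C for r in readings], dtype=float)
    return SeriesSummary(
        mean_of_medians_C=float(np.mean(medians)),
        median_of_medians_C=float(np.median(medians)),
        std_of_medians_C=_sample_std(medians),
        n_repetitions_used=len(readings),
    )


def summarize_session(series: Sequence[SeriesSummary]) -> SessionResult:
    """Final canopy temperature: mean and std of the series medians."""
    if len(series) == 0:
        raise EmptyROIError("session has no usable series")
    medians = np.asarray([s.median_of_medians_C for s in series], dtype=float)
    return SessionResult(
        t_canopy_C=float(np.mean(medians)),
        std_C=_sample_std(medians),
        n_series=len(series),
    )


def session_readings(
    session,
    mask: np.ndarray,
    *,
    min_canopy_cells: int = DEFAULT_MIN_CANOPY_CELLS,
    include_transient: bool = False,
) -> list[list[TemperatureReading]]:
    """Per-series lists of repetition readings for a captured session.

    Repetitions flagged as captured during the post-FFC transient are
    excluded (the protocol waits for stabilisation before measuring) unless
    ``include_transient`` is set.  Repetitions whose mask is below the cell
    minimum are skipped with a logged warning.
    """
    out: list[list[TemperatureReading]] = []
    for s_idx, series in enumerate(session.series):
        readings: list[TemperatureReading] = []
        for r_idx, rep in enumerate(series.repetitions):
            if rep.transient and not include_transient:
                logger.info(
                    "series %d rep %d: transient (t=%.1fs), excluded",
                    s_idx,
                    r_idx,
                    rep.thermal.time_since_ffc_s,
                )
                continue
            try:
                reading = repetition_reading(
                    rep.thermal, mask, min_canopy_cells=min_canopy_cells
                )
            except InsufficientROIError as exc:
                logger.warning("series %d rep %d skipped: %s", s_idx, r_idx, exc)
                continue
            logger.info(
                "series %d rep %d: masked=%d retained=%d median=%.3fC",
                s_idx,
                r_idx,
                reading.n_masked,
                reading.n_retained,
                reading.median_C,
            )
            readings.append(reading)
        out.append(readings)
    return out


def measure_session(
    session,
    mask: np.ndarray,
    *,
    rep_indices: Optional[Sequence[int]] = None,
    n_series: Optional[int] = None,
    min_canopy_cells: int = DEFAULT_MIN_CANOPY_CELLS,
) -> SessionResult:
    """Full session estimate from a registered mask.

    ``rep_indices`` optionally subsamples the (post-transient) repetitions
    of every series before summarising - the hook used by the protocol
    optimization strategies.  ``n_series`` limits how many series are used.
    """
    per_series = session_readings(
        session, mask, min_canopy_cells=min_canopy_cells
    )
    if n_series is not None:
        per_series = per_series[:n_series]
    summaries = []
    for readings in per_series:
        if rep_indices is not None:
            readings = [readings[i] for i in rep_indices]
        if readings:
            summaries.append(summarize_series(readings))
    return summarize_session(summaries)
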