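"""Measurement protocol: timing model and repetition-subsampling strategies.

The standard reading is 3 series of 25 repetitions; every series opens with
a flat-field correction followed by a 30 s stabilisation wait, and each
repetition takes about 0.6 s to capture.  Because repetition medians within
a series are extremely stable, most repetitions are redundant, which
motivates three optimization strategies: keep the first / middle / last
repetition of each series, keep the first three of each series (the series
can then stop early, cutting the series time from 45 s to 32 s), or keep
the first three repetitions of a single series (one 32 s series in total).

``protocol_cost`` accounts for the retained-measurement count and wall
time of each variant; ``evaluate_protocols`` re-estimates session
temperatures under each strategy and scores their agreement against
reference readings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence, TypeVar

import numpy as np
import pandas as pd

from canopytherm.errors import ConfigurationError, ProtocolError, StatisticsError
from canopytherm import extraction

__all__ = [
    "ProtocolConfig",
    "CostBreakdown",
    "SELECTIONS",
    "selection_indices",
    "select_repetitions",
    "protocol_cost",
    "reduction_percentages",
    "standard_protocols",
    "measure_with_strategy",
    "evaluate_protocols",
]

T = TypeVar("T")

SELECTIONS = ("all", "first_mid_last_3", "first_3")
_SCOPES = ("all_series", "first_series_only")


@dataclass(frozen=True)
class ProtocolConfig:
    """Series/repetition structure and timing of one reading.

    ``selection`` names which repetitions of a series are retained for
    computation; ``series_scope`` whether all series or only the first are
    executed.  ``rep_time_s`` defaults to 0.6 s per capture, the value that
    makes a 25-repetition series last 45 s including the 30 s transient.
    ``capture_during_transient`` lets the simulator capture from the moment
    of the FFC (such repetitions are flagged and excluded from statistics);
    by default capture starts when the transient wait ends.
    """

    n_series: int = 3
    n_repetitions: int = 25
    transient_s: float = 30.0
    rep_time_s: float = 0.6
    selection: str = "all"
    series_scope: str = "all_series"
    session_period_min: int = 15
    capture_during_transient: bool = False

    def __post_init__(self) -> None:
        if self.n_series < 1 or self.n_repetitions < 1:
            raise ConfigurationError("need at least one series and one repetition")
        if self.transient_s < 0 or self.rep_time_s <= 0:
            raise ConfigurationError("invalid timing parameters")
        if self.selection not in SELECTIONS:
            raise ConfigurationError(f"unknown selection {self.selection!r}")
        if self.series_scope not in _SCOPES:
            raise ConfigurationError(f"unknown series_scope {self.series_scope!r}")
        if self.session_period_min <= 0:
            raise ConfigurationError("session_period_min must be positive")
        if self.selection != "all" and self.n_repetitions < 3:
            raise ProtocolError(
                f"selection {self.selection!r} needs >= 3 repetitions"
            )


@dataclass(frozen=True)
class CostBreakdown:
    """Retained-measurement count and timing of one protocol variant."""

    total_measurements: int
    series_time_s: int
    total_time_s: int
    n_series_executed: int
    reps_captured: int
    reps_retained: int


def selection_indices(n_repetitions: int, selection: str) -> tuple[int, ...]:
    """0-based repetition indices retained by a strategy.

    ``first_mid_last_3`` keeps indices ``0, (n-1)//2, n-1`` (for 25
    repetitions: 0, 12, 24 - the 13th repetition either way the middle is
    counted); ``first_3`` keeps ``0, 1, 2``; ``all`` keeps everything.
    """
    if selection == "all":
        return tuple(range(n_repetitions))
    if n_repetitions < 3:
        raise ProtocolError(
            f"selection {selection!r} needs >= 3 repetitions, got {n_repetitions}"
        )
    if selection == "first_mid_last_3":
        return (0, (n_repetitions - 1) // 2, n_repetitions - 1)
    if selection == "first_3":
        return (0, 1, 2)
    raise ConfigurationError(f"unknown selection {selection!r}")


def select_repetitions(series_readings: Sequence[T], selection: str) -> list[T]:
    """Subset a series' repetition readings per strategy, order preserved."""
    idx = selection_indices(len(series_readings), selection)
    return [series_readings[i] for i in idx]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def protocol_cost(config: ProtocolConfig) -> CostBreakdown:
    """Retained measurements and wall time of a protocol variant.

    A series executes the transient wait and captures up to the last
    repetition its strategy needs: ``first_3`` stops after 3 captures,
    while ``all`` and ``first_mid_last_3`` must run the full series (the
    last repetition is retained).  The series time is rounded to the
    nearest second *before* multiplying by the number of executed series,
    and "measurements" counts repetitions retained for computation, not
    frames captured.
    """
    if config.selection == "first_3":
        reps_captured = 3
    else:
        reps_captured = config.n_repetitions
    reps_retained = len(selection_indices(config.n_repetitions, config.selection))
    n_exec = 1 if config.series_scope == "first_series_only" else config.n_series
    series_time = _round_half_up(
        config.transient_s + reps_captured * config.rep_time_s
    )
    return CostBreakdown(
        total_measurements=reps_retained * n_exec,
        series_time_s=series_time,
        total_time_s=n_exec * series_time,
        n_series_executed=n_exec,
        reps_captured=reps_captured,
        reps_retained=reps_retained,
    )


def reduction_percentages(
    original: CostBreakdown, optimized: CostBreakdown
) -> tuple[float, float]:
    """Percent fewer measurements and percent less measurement time."""
    meas = 100.0 * (
        original.total_measurements - optimized.total_measurements
    ) / original.total_measurements
    time_ = 100.0 * (
        original.total_time_s - optimized.total_time_s
    ) / original.total_time_s
    return meas, time_


def standard_protocols(
    base: Optional[ProtocolConfig] = None,
) -> dict[str, ProtocolConfig]:
    """The original protocol and its three optimization variants."""
    base = base or ProtocolConfig()
    return {
        "original": replace(base, selection="all", series_scope="all_series"),
        "alternative_1": replace(
            base, selection="first_mid_last_3", series_scope="all_series"
        ),
        "alternative_2": replace(base, selection="first_3", series_scope="all_series"),
        "alternative_3": replace(
            base, selection="first_3", series_scope="first_series_only"
        ),
    }


def _strategy_config(strategy: str, base: ProtocolConfig) -> ProtocolConfig:
    named = standard_protocols(base)
    if strategy in named:
        return named[strategy]
    if strategy in SELECTIONS:
        return replace(base, selection=strategy, series_scope="all_series")
    raise ConfigurationError(f"unknown strategy {strategy!r}")


def measure_with_strategy(
    session,
    mask: np.ndarray,
    strategy: str,
    *,
    base: Optional[ProtocolConfig] = None,
    min_canopy_cells: int = extraction.DEFAULT_MIN_CANOPY_CELLS,
) -> extraction.SessionResult:
    """Session temperature after applying a subsampling strategy."""
    cfg = _strategy_config(strategy, base or ProtocolConfig())
    n_reps = len(session.series[0].repetitions)
    idx = selection_indices(n_reps, cfg.selection)
    n_series = 1 if cfg.series_scope == "first_series_only" else None
    return extraction.measure_session(
        session,
        mask,
        rep_indices=None if cfg.selection == "all" else idx,
        n_series=n_series,
        min_canopy_cells=min_canopy_cells,
    )


def evaluate_protocols(
    sessions: Sequence[tuple[object, float]],
    strategies: Sequence[str] = ("original", "alternative_1", "alternative_2", "alternative_3"),
    *,
    masks: Optional[Sequence[np.ndarray]] = None,
    base: Optional[ProtocolConfig] = None,
) -> pd.DataFrame:
    """Score each strategy's agreement against reference temperatures.

    Parameters
    ----------
    sessions
        Pairs ``(session, reference_temp_C)``; at least two are needed for
        the regression statistics.
    strategies
        Strategy names (``original`` ... ``alternative_3`` or bare
        selection names, which imply all-series scope).
    masks
        Registered canopy masks per session; defaults to each session's
        ground-truth thermal mask.

    Returns
    -------
    pandas.DataFrame
        One row per strategy with the cost columns and the agreement
        statistics (R-squared, delta mean / median / std / max) against the
        references.
    """
    from canopytherm import comparison

    if len(sessions) < 2:
        raise StatisticsError("need at least two sessions with references")
    base = base or ProtocolConfig()
    if masks is None:
        masks = [s.truth_mask_thermal for s, _ in sessions]

    # readings are computed once per session and re-subsampled per strategy
    all_readings = [
        extraction.session_readings(s, m) for (s, _), m in zip(sessions, masks)
    ]
    refs = np.asarray([ref for _, ref in sessions], dtype=float)

    rows = []
    for strategy in strategies:
        cfg = _strategy_config(strategy, base)
        temps = []
        for per_series in all_readings:
            use = per_series[:1] if cfg.series_scope == "first_series_only" else per_series
            summaries = [
                extraction.summarize_series(
                    select_repetitions(r, cfg.selection)
                )
                for r in use
                if r
            ]
            temps.append(extraction.summarize_session(summaries).t_canopy_C)
        temps = np.asarray(temps)
        slope, intercept, r2 = comparison.regress(refs, temps)
        deltas = comparison.delta_stats(temps, refs)
        cost = protocol_cost(cfg)
        rows.append(
            {
                "strategy": strategy,
                "n_series": cost.n_series_executed,
                "n_repetitions": cost.reps_retained,
                "total_measurements": cost.total_measurements,
                "series_time_s": cost.series_time_s,
                "total_time_s": cost.total_time_s,
                "r_squared": r2,
                "delta_mean_C": deltas["delta_mean_C"],
                "delta_median_C": deltas["delta_median_C"],
                "delta_std_C": deltas["delta_std_C"],
                "delta_max_C": deltas["delta_max_C"],
            }
        )
    return pd.DataFrame(rows, columns=list(rows[0].keys()))
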