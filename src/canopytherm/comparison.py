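"""Agreement analytics between the thermal sensor and a reference radiometer.

The thermal sensor reads every 15 min while the reference infrared
radiometer and the weather station read every 10 min, so most timestamps do
not coincide.  The faster channel is averaged within a centered window
around each slow timestamp to approximately match the slow sampling period;
the resulting pairs feed an ordinary least-squares regression (R-squared is
the squared Pearson correlation), delta-T summaries with
``delta = T_S - T_IR`` (positive when the thermal sensor overestimates the
canopy temperature), and covariate screens correlating delta against wind
speed, solar radiation and air temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from canopytherm.errors import StatisticsError, UndefinedFitError

__all__ = [
    "FieldDay",
    "AgreementResult",
    "align_series",
    "regress",
    "delta_stats",
    "covariate_r2",
    "compare_field_day",
    "covariate_screens",
]


@dataclass
class FieldDay:
    """One day of multi-rate sensor time series.

    ``channels`` maps channel names (``T_S``, ``T_IR``, ``T_A``,
    ``wind_mps``, ``radiation_Wm2``) to pandas Series indexed by timestamp
    (strictly increasing).  ``truth`` optionally carries the noise-free
    latent canopy curve when the day is synthetic.
    """

    channels: dict[str, pd.Series]
    metadata: dict
    truth: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        for name, series in self.channels.items():
            if len(series) and not series.index.is_monotonic_increasing:
                raise StatisticsError(f"channel {name!r} timestamps not increasing")


@dataclass(frozen=True)
class AgreementResult:
    """Regression and delta-T agreement between T_S and T_IR."""

    slope: float
    intercept_C: float
    r_squared: float
    delta_mean_C: float
    delta_median_C: float
    delta_std_C: float
    delta_max_C: float
    n_pairs: int

    def to_dict(self) -> dict:
        return asdict(self)


def _infer_period(index: pd.DatetimeIndex) -> pd.Timedelta:
    if len(index) < 2:
        raise StatisticsError("cannot infer sampling period from one sample")
    return pd.Timedelta(np.median(np.diff(index.asi8)), unit="ns")


def align_series(
    slow: pd.Series,
    fast: pd.Series,
    slow_period: Optional[pd.Timedelta] = None,
) -> pd.DataFrame:
    """Pair each slow sample with the mean of nearby fast samples.

    Every fast sample is assigned to its nearest slow timestamp (the
    earlier one on an exact tie) and contributes to at most one pair; fast
    samples farther than half the slow sampling period from every slow
    timestamp are dropped, and slow timestamps whose window holds no fast
    sample emit no pair.

    Returns
    -------
    pandas.DataFrame
        Columns ``timestamp``, ``slow_value``, ``fast_mean``, in slow-index
        order.
    """
    if len(slow) == 0 or len(fast) == 0:
        raise StatisticsError("align_series requires non-empty inputs")
    period = slow_period if slow_period is not None else _infer_period(slow.index)
    half = period / 2

    st = slow.index.asi8
    ft = fast.index.asi8
    pos = np.searchsorted(st, ft)
    left = np.clip(pos - 1, 0, len(st) - 1)
    right = np.clip(pos, 0, len(st) - 1)
    d_left = np.abs(ft - st[left])
    d_right = np.abs(ft - st[right])
    nearest = np.where(d_left <= d_right, left, right)  # earlier wins ties
    dist = np.minimum(d_left, d_right)
    keep = dist <= half.value

    sums = np.bincount(nearest[keep], weights=fast.to_numpy()[keep], minlength=len(st))
    counts = np.bincount(nearest[keep], minlength=len(st))
    has = counts > 0
    return pd.DataFrame(
        {
            "timestamp": slow.index[has],
            "slow_value": slow.to_numpy()[has],
            "fast_mean": sums[has] / counts[has],
        }
    )


def regress(x, y) -> tuple[float, float, float]:
    """Ordinary least squares of y on x; returns (slope, intercept, R^2).

    ``x`` is the reference channel (T_IR), ``y`` the channel under test
    (T_S); R-squared is the squared Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size != x.size:
        raise StatisticsError("regression needs >= 2 paired values")
    if np.ptp(x) == 0:
        raise UndefinedFitError("regression undefined for constant x")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def delta_stats(t_s, t_ir) -> dict[str, float]:
    """Summaries of delta = T_S - T_IR: mean, median, sample std, max |delta|."""
    t_s = np.asarray(t_s, dtype=float)
    t_ir = np.asarray(t_ir, dtype=float)
    if t_s.size == 0 or t_s.size != t_ir.size:
        raise StatisticsError("delta_stats needs >= 1 matched pair")
    d = t_s - t_ir
    return {
        "delta_mean_C": float(np.mean(d)),
        "delta_median_C": float(np.median(d)),
        "delta_std_C": float(np.std(d, ddof=1)) if d.size > 1 else 0.0,
        "delta_max_C": float(np.max(np.abs(d))),
    }


def covariate_r2(deltas, covariate) -> float:
    """Squared Pearson correlation of delta-T against a covariate."""
    deltas = np.asarray(deltas, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if deltas.size < 3 or deltas.size != covariate.size:
        raise StatisticsError("covariate screen needs >= 3 matched values")
    if np.ptp(covariate) == 0:
        raise UndefinedFitError("covariate screen undefined for constant covariate")
    if np.ptp(deltas) == 0:
        return 0.0
    r, _ = stats.pearsonr(deltas, covariate)
    return float(r**2)


def _paired(day: FieldDay) -> pd.DataFrame:
    slow = day.channels["T_S"]
    fast = day.channels["T_IR"]
    period = pd.Timedelta(minutes=day.metadata.get("thermal_period_min", 15))
    return align_series(slow, fast, slow_period=period)


def compare_field_day(day: FieldDay) -> AgreementResult:
    """Align T_IR onto the T_S sampling grid and score their agreement."""
    pairs = _paired(day)
    if len(pairs) < 2:
        raise StatisticsError("fewer than two aligned T_S/T_IR pairs")
    slope, intercept, r2 = regress(pairs["fast_mean"], pairs["slow_value"])
    d = delta_stats(pairs["slow_value"], pairs["fast_mean"])
    return AgreementResult(
        slope=slope,
        intercept_C=intercept,
        r_squared=r2,
        n_pairs=len(pairs),
        **d,
    )


def covariate_screens(day: FieldDay) -> dict[str, float]:
    """R-squared of delta-T against wind, radiation and air temperature."""
    pairs = _paired(day).set_index("timestamp")
    deltas = pairs["slow_value"] - pairs["fast_mean"]
    period = pd.Timedelta(minutes=day.metadata.get("thermal_period_min", 15))
    out: dict[str, float] = {}
    for name in ("wind_mps", "radiation_Wm2", "T_A"):
        if name not in day.channels:
            continue
        cov = align_series(
            day.channels["T_S"], day.channels[name], slow_period=period
        ).set_index("timestamp")["fast_mean"]
        joined = pd.concat([deltas.rename("delta"), cov.rename("cov")], axis=1).dropna()
        out[name] = covariate_r2(joined["delta"], joined["cov"])
    return out
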