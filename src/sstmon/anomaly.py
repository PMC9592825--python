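"""Outlier detection on the 16 quality indicators.

Two interchangeable methods classify each indicator of a new run against
its history:

* ``quantile`` — static acceptance intervals from historical quantiles,
  available once at least 60 runs are stored. Assumes a stationary
  instrument.
* ``isolation_forest`` — the default: a univariate isolation forest per
  indicator, refitted over history + the new run on every arrival, so the
  whole stored history is re-evaluated and the method adapts to slow
  drift. Requires only 20 runs.

Both methods apply a direction-aware correction: values that are extreme on
the *beneficial* side of an indicator (very high signal-to-noise, very low
mass error, ...) are never flagged. The run score is the number of
non-outlier indicators; more than 4 outliers marks the run bad.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import IsolationForest

from .errors import SchemaError
from .indicators import DIRECTIONS, HIGHER_BETTER, INDICATOR_NAMES, LOWER_BETTER

OK = "ok"
OUTLIER = "outlier"
INSUFFICIENT = "insufficient_history"

QUANTILE = "quantile"
ISOLATION_FOREST = "isolation_forest"

#: a run is bad when strictly more than this many indicators are outliers
MAX_OUTLIERS_FOR_GOOD = 4


@dataclass(frozen=True)
class AnomalyConfig:
    method: str = ISOLATION_FOREST
    min_history_quantile: int = 60
    min_history_iforest: int = 20
    q_low: float = 0.05
    q_high: float = 0.95
    n_estimators: int = 100
    max_samples: int = 256
    contamination: float = 0.05
    seed: int = 0
    #: small-history compensation: flag at most ceil(n/10) historical runs
    max_flag_fraction: float = 0.1


@dataclass
class OutlierVerdict:
    """Per-indicator flags plus the derived run score and quality."""

    flags: dict[str, str]
    method: str
    score: int
    quality: str

    def n_outliers(self) -> int:
        return sum(1 for f in self.flags.values() if f == OUTLIER)

    def to_series(self) -> pd.Series:
        return pd.Series(self.flags, name="flag")


def _directions(columns) -> dict[str, str]:
    missing = [c for c in columns if c not in DIRECTIONS]
    if missing:
        raise SchemaError(f"indicators without registered direction: {missing}")
    return {c: DIRECTIONS[c] for c in columns}


def quantile_intervals(
    history: pd.DataFrame, cfg: AnomalyConfig | None = None
) -> dict[str, tuple[float, float]] | None:
    """Per-indicator acceptance intervals from historical quantiles.

    One-sided per direction: ``lower_better`` indicators get no lower
    bound, ``higher_better`` no upper bound. Returns None when the history
    is shorter than the configured minimum (insufficient-history signal,
    not an error).
    """
    cfg = cfg or AnomalyConfig()
    if len(history) < cfg.min_history_quantile:
        return None
    dirs = _directions(history.columns)
    intervals: dict[str, tuple[float, float]] = {}
    for name in history.columns:
        col = history[name].to_numpy(dtype=float)
        lo = float(np.quantile(col, cfg.q_low))
        hi = float(np.quantile(col, cfg.q_high))
        if dirs[name] == LOWER_BETTER:
            intervals[name] = (-math.inf, hi)
        else:
            intervals[name] = (lo, math.inf)
    return intervals


def quantile_flags(
    history: pd.DataFrame,
    new_run: pd.Series,
    cfg: AnomalyConfig | None = None,
) -> dict[str, str]:
    """Flag each indicator of a new run against quantile intervals."""
    cfg = cfg or AnomalyConfig()
    intervals = quantile_intervals(history, cfg)
    if intervals is None:
        return {name: INSUFFICIENT for name in history.columns}
    flags = {}
    for name, (lo, hi) in intervals.items():
        v = float(new_run[name])
        flags[name] = OUTLIER if (v < lo or v > hi) else OK
    return flags


def _iforest_univariate(
    values: np.ndarray, cfg: AnomalyConfig, direction: str
) -> np.ndarray:
    """Outlier mask over all points of one indicator series (history + new)."""
    n = values.size
    sd = values.std(ddof=1) if n > 1 else 0.0
    if not sd > np.finfo(float).eps:
        # degenerate history: nothing can be called an outlier
        return np.zeros(n, dtype=bool)
    forest = IsolationForest(
        n_estimators=cfg.n_estimators,
        max_samples=min(cfg.max_samples, n),
        contamination=cfg.contamination,
        random_state=cfg.seed,
    )
    x = values.reshape(-1, 1)
    pred = forest.fit_predict(x)
    scores = forest.score_samples(x)  # lower = more anomalous
    flagged = pred == -1
    # small-history compensation: cap the number of flags at ceil(n/10),
    # keeping the most anomalous points
    cap = max(1, math.ceil(n * cfg.max_flag_fraction))
    if flagged.sum() > cap:
        keep = np.argsort(scores)[:cap]
        capped = np.zeros(n, dtype=bool)
        capped[keep[flagged[keep]]] = True
        flagged = capped
    # direction-aware correction: extremes on the beneficial side are fine
    med = float(np.median(values))
    if direction == HIGHER_BETTER:
        flagged &= values < med
    else:
        flagged &= values > med
    return flagged


def iforest_flags(
    history: pd.DataFrame,
    new_run: pd.Series,
    cfg: AnomalyConfig | None = None,
) -> dict[str, str]:
    """Isolation-forest flags for the new run's indicators.

    Each indicator is scored univariately over history + new run; the
    direction correction rescinds flags on the beneficial side.
    """
    cfg = cfg or AnomalyConfig()
    if len(history) < cfg.min_history_iforest:
        return {name: INSUFFICIENT for name in history.columns}
    dirs = _directions(history.columns)
    flags = {}
    for name in history.columns:
        series = np.append(
            history[name].to_numpy(dtype=float), float(new_run[name])
        )
        mask = _iforest_univariate(series, cfg, dirs[name])
        flags[name] = OUTLIER if mask[-1] else OK
    return flags


def reevaluate_history(
    history: pd.DataFrame, cfg: AnomalyConfig | None = None
) -> pd.DataFrame:
    """Re-score every stored run (isolation-forest mode).

    Returns a boolean (runs x indicators) outlier matrix; all-False when
    the history is below the method's minimum length.
    """
    cfg = cfg or AnomalyConfig()
    out = pd.DataFrame(False, index=history.index, columns=history.columns)
    if len(history) < cfg.min_history_iforest:
        return out
    dirs = _directions(history.columns)
    for name in history.columns:
        series = history[name].to_numpy(dtype=float)
        out[name] = _iforest_univariate(series, cfg, dirs[name])
    return out


def classify_run(
    history: pd.DataFrame,
    new_run: pd.Series,
    cfg: AnomalyConfig | None = None,
) -> "OutlierVerdict":
    """Flag a new run by the configured method and score it."""
    cfg = cfg or AnomalyConfig()
    if cfg.method == QUANTILE:
        flags = quantile_flags(history, new_run, cfg)
    elif cfg.method == ISOLATION_FOREST:
        flags = iforest_flags(history, new_run, cfg)
    else:
        raise SchemaError(f"unknown anomaly method {cfg.method!r}")
    return score_run(flags, method=cfg.method)


def score_run(flags: dict[str, str], method: str = ISOLATION_FOREST) -> OutlierVerdict:
    """Derive the run score and quality verdict from 16 indicator flags.

    The score counts non-outlier indicators; strictly more than 4 outliers
    makes the run bad; any insufficient-history flag leaves it unscored.
    """
    if len(flags) != len(INDICATOR_NAMES):
        raise SchemaError(
            f"expected {len(INDICATOR_NAMES)} indicator flags, got {len(flags)}"
        )
    bad_values = set(flags.values()) - {OK, OUTLIER, INSUFFICIENT}
    if bad_values:
        raise SchemaError(f"unknown flag values: {sorted(bad_values)}")
    n_out = sum(1 for f in flags.values() if f == OUTLIER)
    n_ok = sum(1 for f in flags.values() if f == OK)
    if any(f == INSUFFICIENT for f in flags.values()):
        quality = "unscored"
    elif n_out > MAX_OUTLIERS_FOR_GOOD:
        quality = "bad"
    else:
        quality = "good"
    return OutlierVerdict(
        flags=dict(flags), method=method, score=n_ok, quality=quality
    )
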