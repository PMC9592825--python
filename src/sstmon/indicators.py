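"""Condense a feature vector into the 16 monitored quality indicators.

Each indicator reports one analytically meaningful aspect of instrument
state — resolving power, mass accuracy, isotopic fidelity, adduct
formation, in-source fragmentation, signal level, dirt and detector noise —
and carries a direction: whether larger values are good news
(``higher_better``) or bad news (``lower_better``). Directions drive the
one-sided outlier logic: a suspiciously *good* value is never flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, SchemaError
from .features import FeatureVector, SchemaConfig, _make_windows
from .registry import (
    ADDUCT,
    ExpectedPeak,
    ISOTOPOLOGUE,
    MONOISOTOPIC,
    compounds,
    default_registry,
    qc_peaks,
)

HIGHER_BETTER = "higher_better"
LOWER_BETTER = "lower_better"

#: indicator -> direction; the one-sided outlier semantics per indicator.
DIRECTIONS: dict[str, str] = {
    "resolution_200": HIGHER_BETTER,
    "resolution_700": HIGHER_BETTER,
    "average_accuracy": LOWER_BETTER,
    "chemical_dirt": LOWER_BETTER,
    "instrument_noise": LOWER_BETTER,
    "isotopic_presence": HIGHER_BETTER,
    "isotopic_accuracy": HIGHER_BETTER,
    "adduct_presence": LOWER_BETTER,
    "fragmentation_305": LOWER_BETTER,
    "fragmentation_hi": LOWER_BETTER,
    "baseline_25_150": LOWER_BETTER,
    "baseline_50_650": LOWER_BETTER,
    "signal": HIGHER_BETTER,
    "transmission": HIGHER_BETTER,
    "s2b": HIGHER_BETTER,
    "s2n": HIGHER_BETTER,
}

INDICATOR_NAMES = tuple(DIRECTIONS)


@dataclass(frozen=True)
class IndicatorConfig:
    """Anchors and formula parameters for the default 16-indicator roster."""

    registry: tuple[ExpectedPeak, ...] = field(
        default_factory=lambda: tuple(default_registry())
    )
    schema: SchemaConfig = field(default_factory=SchemaConfig)
    resolution_anchors: tuple[float, float] = (200.0, 700.0)
    primary_fragment: str = "fluconazole_frag"
    secondary_fragment: str = "digoxin_frag"
    baseline_anchors: tuple[tuple[int, float], ...] = ((25, 150.0), (50, 650.0))
    transmission_split_mz: float = 450.0
    ratio_cap: float = 1.0e9


@dataclass
class QualityIndicators:
    """The 16 monitored values with their direction semantics."""

    values: dict[str, float]
    directions: dict[str, str] = field(default_factory=lambda: dict(DIRECTIONS))

    def __post_init__(self) -> None:
        if len(self.values) != 16:
            raise SchemaError(
                f"expected exactly 16 indicators, got {len(self.values)}"
            )
        for name in self.values:
            if name not in self.directions:
                raise SchemaError(f"indicator {name!r} has no registered direction")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __len__(self) -> int:
        return len(self.values)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, name="value")


def _nearest_monoisotopic(registry, target_mz: float) -> ExpectedPeak:
    monos = [p for p in registry if p.kind == MONOISOTOPIC]
    return min(monos, key=lambda p: abs(p.theoretical_mz - target_mz))


def _window_id(windows, mz: float) -> str:
    for low, high in windows:
        if low <= mz < high:
            return f"w{int(low)}_{int(high)}"
    raise SchemaError(f"no QC window contains m/z {mz}")


def _ratio(num: float, den: float, cap: float) -> float:
    if den <= 0:
        return cap if num > 0 else 0.0
    return min(num / den, cap)


def compute_indicators(
    fv: FeatureVector, cfg: IndicatorConfig | None = None
) -> QualityIndicators:
    """Compute the 16 quality indicators from a full feature vector."""
    cfg = cfg or IndicatorConfig()
    registry = list(cfg.registry)
    qps = qc_peaks(registry)
    comp_ids = compounds(registry)

    def feat(name: str) -> float:
        return fv[name]

    out: dict[str, float] = {}

    # resolving power at the two mass anchors: m/z divided by FWHM of the
    # monoisotopic peak nearest each anchor
    for anchor, key in zip(cfg.resolution_anchors, ("resolution_200", "resolution_700")):
        p = _nearest_monoisotopic(registry, anchor)
        fwhm = feat(f"qc_peak:{p.peak_id}:width_50:mean")
        out[key] = p.theoretical_mz / fwhm if fwhm > 0 else 0.0

    # mass accuracy: mean |ppm| over QC peaks that were actually found
    ppms = []
    for p in qps:
        if feat(f"qc_peak:{p.peak_id}:intensity:mean") > 0:
            ppms.append(abs(feat(f"qc_peak:{p.peak_id}:ppm_error:mean")))
    out["average_accuracy"] = float(np.mean(ppms)) if ppms else float("nan")

    # dirt and noise: total intensity of the background and flow-stop scans
    bg_windows = _make_windows(*cfg.schema.bg_windows)
    out["chemical_dirt"] = sum(
        feat(f"background_window:w{int(a)}_{int(b)}:intensity_sum:single")
        for a, b in bg_windows
    )
    noise_windows = _make_windows(*cfg.schema.noise_windows)
    out["instrument_noise"] = sum(
        feat(f"noise_window:w{int(a)}_{int(b)}:intensity_sum:single")
        for a, b in noise_windows
    )

    isotopologues = [p for p in qps if p.kind == ISOTOPOLOGUE]
    found = [
        p for p in isotopologues
        if feat(f"qc_peak:{p.peak_id}:intensity:mean") > 0
    ]
    out["isotopic_presence"] = (
        len(found) / len(isotopologues) if isotopologues else 0.0
    )
    devs = [
        feat(f"qc_peak:{c}:isotope_pattern_deviation:mean") for c in comp_ids
    ]
    out["isotopic_accuracy"] = 1.0 - float(np.mean(devs)) if devs else float("nan")

    adducts = [p for p in qps if p.kind == ADDUCT]
    out["adduct_presence"] = (
        float(np.mean([
            feat(f"qc_peak:{p.peak_id}:relative_height:mean") for p in adducts
        ]))
        if adducts else 0.0
    )
    out["fragmentation_305"] = feat(
        f"qc_peak:{cfg.primary_fragment}:relative_height:mean"
    )
    out["fragmentation_hi"] = feat(
        f"qc_peak:{cfg.secondary_fragment}:relative_height:mean"
    )

    # baseline_p_m: p-th percentile of non-expected signal in the 50-amu QC
    # window containing m/z m
    qc_windows = _make_windows(*cfg.schema.qc_windows)
    for (pct, anchor), key in zip(
        cfg.baseline_anchors, ("baseline_25_150", "baseline_50_650")
    ):
        wid = _window_id(qc_windows, anchor)
        out[key] = feat(f"qc_window:{wid}:p{pct}:mean")

    monos = [p for p in qps if p.kind == MONOISOTOPIC]
    heights = {
        p.peak_id: feat(f"qc_peak:{p.peak_id}:intensity:mean") for p in monos
    }
    out["signal"] = float(sum(heights.values()))
    hi = [heights[p.peak_id] for p in monos if p.theoretical_mz >= cfg.transmission_split_mz]
    lo = [heights[p.peak_id] for p in monos if p.theoretical_mz < cfg.transmission_split_mz]
    out["transmission"] = _ratio(
        float(np.mean(hi)) if hi else 0.0,
        float(np.mean(lo)) if lo else 0.0,
        cfg.ratio_cap,
    )
    out["s2b"] = _ratio(out["signal"], out["chemical_dirt"], cfg.ratio_cap)
    out["s2n"] = _ratio(out["signal"], out["instrument_noise"], cfg.ratio_cap)

    return QualityIndicators(values={k: out[k] for k in INDICATOR_NAMES})


def intra_day_cv(
    feature_matrix: pd.DataFrame,
) -> tuple[pd.Series, float, list[str]]:
    """Per-feature coefficient of variation over repeated same-day runs.

    Returns (per-feature CV, median CV over defined features, names of
    features excluded because their mean is zero). CV uses the sample
    standard deviation.
    """
    if not isinstance(feature_matrix, pd.DataFrame):
        feature_matrix = pd.DataFrame(np.asarray(feature_matrix))
    if len(feature_matrix) < 2:
        raise InsufficientDataError("intra-day CV needs at least 2 runs")
    means = feature_matrix.mean(axis=0)
    sds = feature_matrix.std(axis=0, ddof=1)
    defined = means.abs() > 0
    excluded = [str(c) for c in means.index[~defined]]
    cv = sds[defined] / means[defined].abs()
    return cv, float(cv.median()), excluded
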