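"""Feature extraction: one acquisition -> the named 2,850-entry vector.

Five scans are analysed per acquisition. The QC-bolus scan is located
dynamically as the scan with the highest total ion current and the analysis
is extended to the two following scans, so every QC-derived quantity gets a
mean and a standard deviation. One early scan characterizes the chemical
background via the two lock masses and coarse mass windows; one late
flow-stop scan characterizes detector noise.

Default schema totals (peaks x quantities x statistics):

=====================  =====================================  =====
provenance             composition                            count
=====================  =====================================  =====
qc_peak                37 peaks x 23 quantities x {mean,sd}
                       + 9 isotope-pattern scores x {mean,sd}  1720
qc_window              15 windows x 24 quantities x {mean,sd}   720
background_lockmass    2 lock masses x 70 quantities            140
background_window      9 windows x 20 quantities                180
noise_window           5 windows x 18 quantities                 90
=====================  =====================================  =====
grand total                                                    2850
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import RangeError, SchemaError, SelectionError
from .io import Acquisition, ProfileSpectrum, total_ion_chronogram
from .registry import (
    ExpectedPeak,
    ISOTOPOLOGUE,
    LOCK_MASS,
    MONOISOTOPIC,
    by_id,
    compounds,
    lock_mass_peaks,
    qc_peaks,
)

QC_QUANTITIES = (
    "intensity", "absolute_mass_error", "ppm_error",
    "width_10", "width_25", "width_50", "width_75",
    "left_tail_area", "right_tail_area", "tail_ratio",
    "symmetry", "gaussian_gof", "n_subsequent_peaks",
    "sub_ratio_1", "sub_ratio_2", "sub_ratio_3", "sub_ratio_4", "sub_ratio_5",
    "relative_height", "abundance_deviation", "centroid_apex_offset",
    "local_baseline", "local_snr",
)

PROVENANCES = (
    "qc_peak", "qc_window", "background_lockmass", "background_window",
    "noise_window",
)


@dataclass(frozen=True)
class ScanConfig:
    """Which scans are analysed."""

    background_scan_index: int = 18
    noise_offset_from_end: int = 3
    noise_scan_index: int | None = None


@dataclass(frozen=True)
class ScanSelection:
    qc_scan_indices: tuple[int, int, int]
    background_scan_index: int
    noise_scan_index: int


@dataclass(frozen=True)
class FitConfig:
    """Expected-peak fitting parameters.

    ``search_tol`` (Th) bounds the apex search around the theoretical m/z;
    the detection threshold is the local baseline median plus
    ``detection_k`` MADs. Subsequent peaks ("ringing") are local maxima up
    to ``subsequent_span`` Th to the right of the apex with height at least
    ``subsequent_min_ratio`` of the apex.
    """

    search_tol: float = 0.05
    height_fractions: tuple[float, ...] = (0.10, 0.25, 0.50, 0.75)
    baseline_halfwidth: float = 0.5
    baseline_exclude: float = 0.12
    detection_k: float = 3.0
    max_subsequent: int = 5
    subsequent_span: float = 1.0
    subsequent_min_ratio: float = 0.01
    snr_cap: float = 1.0e6


@dataclass
class PeakFit:
    """Result of fitting one expected peak in one profile spectrum.

    Missing peaks (``found=False``) carry sentinel values: zero intensity,
    widths and areas, worst-case mass error (the search tolerance), zero
    goodness-of-fit.
    """

    peak: ExpectedPeak
    found: bool
    centroid_mz: float
    apex_mz: float
    apex_height: float
    absolute_mass_error: float
    ppm_error: float
    widths: dict[float, float]
    left_tail_area: float
    right_tail_area: float
    tail_ratio: float
    symmetry: float
    gaussian_gof: float
    n_subsequent_peaks: int
    subsequent_intensity_ratios: tuple[float, ...]
    relative_height: float
    abundance_deviation: float
    centroid_apex_offset: float
    local_baseline: float
    local_snr: float

    def quantities(self, names: tuple[str, ...] = QC_QUANTITIES) -> np.ndarray:
        vals = []
        for q in names:
            if q == "intensity":
                vals.append(self.apex_height)
            elif q.startswith("width_"):
                frac = float(q.split("_")[1]) / 100.0
                vals.append(self.widths.get(round(frac, 4), 0.0))
            elif q.startswith("sub_ratio_") or q.startswith("ringing_"):
                k = int(q.rsplit("_", 1)[1]) - 1
                r = self.subsequent_intensity_ratios
                vals.append(r[k] if k < len(r) else 0.0)
            else:
                vals.append(float(getattr(self, q)))
        return np.asarray(vals, dtype=np.float64)


def select_scans(acq: Acquisition, cfg: ScanConfig | None = None) -> ScanSelection:
    """Pick the QC triple (TIC apex + two following), background and noise scans."""
    cfg = cfg or ScanConfig()
    tic = total_ion_chronogram(acq)[:, 1]
    n = len(acq)
    if n < cfg.background_scan_index + 3:
        raise SelectionError(
            f"acquisition has {n} scans, need at least "
            f"{cfg.background_scan_index + 3}"
        )
    if np.allclose(tic, tic[0]):
        raise SelectionError("flat chronogram: QC bolus apex is ambiguous")
    apex = int(np.argmax(tic))
    if apex >= n - 2:
        raise SelectionError(
            f"TIC apex at scan {apex} leaves no room for the two following scans"
        )
    if cfg.background_scan_index >= apex:
        raise SelectionError(
            f"background scan {cfg.background_scan_index} does not precede "
            f"the QC apex at scan {apex}"
        )
    noise = (
        cfg.noise_scan_index
        if cfg.noise_scan_index is not None
        else n - cfg.noise_offset_from_end
    )
    if not apex + 2 < noise < n:
        raise SelectionError(f"noise scan {noise} invalid for {n} scans")
    return ScanSelection(
        qc_scan_indices=(apex, apex + 1, apex + 2),
        background_scan_index=cfg.background_scan_index,
        noise_scan_index=noise,
    )


def _interp_crossing(x0: float, y0: float, x1: float, y1: float, level: float) -> float:
    if y1 == y0:
        return x1
    return x0 + (level - y0) * (x1 - x0) / (y1 - y0)


def _area(x: np.ndarray, y: np.ndarray, a: float, b: float) -> float:
    """Trapezoid area of the trace between abscissae a and b (linear ends)."""
    if b <= a:
        return 0.0
    ia = np.searchsorted(x, a)
    ib = np.searchsorted(x, b)
    xs = [a] + list(x[ia:ib]) + [b]
    ys = [np.interp(a, x, y)] + list(y[ia:ib]) + [np.interp(b, x, y)]
    return float(np.trapezoid(ys, xs))


def _gauss(x, h, mu, sigma):
    return h * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _sentinel_fit(peak: ExpectedPeak, cfg: FitConfig, local_baseline: float) -> PeakFit:
    tol = cfg.search_tol
    theo_abund = (
        1.0 if peak.kind in (MONOISOTOPIC, LOCK_MASS)
        else peak.theoretical_relative_abundance
    )
    return PeakFit(
        peak=peak, found=False, centroid_mz=peak.theoretical_mz,
        apex_mz=peak.theoretical_mz, apex_height=0.0,
        absolute_mass_error=tol, ppm_error=tol / peak.theoretical_mz * 1e6,
        widths={round(f, 4): 0.0 for f in cfg.height_fractions},
        left_tail_area=0.0, right_tail_area=0.0, tail_ratio=0.0,
        symmetry=1.0, gaussian_gof=0.0, n_subsequent_peaks=0,
        subsequent_intensity_ratios=(0.0,) * cfg.max_subsequent,
        relative_height=0.0, abundance_deviation=-theo_abund,
        centroid_apex_offset=0.0, local_baseline=local_baseline, local_snr=0.0,
    )


def fit_expected_peak(
    spectrum: ProfileSpectrum,
    peak: ExpectedPeak,
    cfg: FitConfig | None = None,
    parent_fit: PeakFit | None = None,
) -> PeakFit:
    """Characterize one expected peak in a profile spectrum.

    The apex is the highest point within ``theoretical_mz +- search_tol``,
    refined by a parabola through its two neighbours; the centroid is the
    intensity-weighted mean of the contiguous points above half height;
    widths come from linear interpolation at the configured height
    fractions. ``parent_fit`` supplies the monoisotopic reference for
    relative-height and abundance-deviation quantities.
    """
    cfg = cfg or FitConfig()
    x, y = spectrum.mz, spectrum.intensity
    theo = peak.theoretical_mz
    if theo + cfg.search_tol < x[0] or theo - cfg.search_tol > x[-1]:
        raise RangeError(
            f"search window for {peak.peak_id} ({theo} Th) lies outside the "
            f"spectrum range [{x[0]:.2f}, {x[-1]:.2f}]"
        )

    b_lo = np.searchsorted(x, theo - cfg.baseline_halfwidth)
    b_hi = np.searchsorted(x, theo + cfg.baseline_halfwidth)
    xb, yb = x[b_lo:b_hi], y[b_lo:b_hi]
    mask = np.abs(xb - theo) > cfg.baseline_exclude
    local = yb[mask]
    base_med = float(np.median(local)) if local.size else 0.0
    base_mad = float(np.median(np.abs(local - base_med))) if local.size else 0.0

    w_lo = np.searchsorted(x, theo - cfg.search_tol)
    w_hi = np.searchsorted(x, theo + cfg.search_tol)
    if w_hi <= w_lo:
        return _sentinel_fit(peak, cfg, base_med)
    i_apex = w_lo + int(np.argmax(y[w_lo:w_hi]))
    apex_raw = float(y[i_apex])
    threshold = base_med + cfg.detection_k * base_mad
    if apex_raw <= threshold or apex_raw <= 0.0:
        return _sentinel_fit(peak, cfg, base_med)

    # apex refinement on the uniform local grid: a parabola through the log
    # of the top three points is exact for a Gaussian whatever the grid
    # phase; fall back to a plain parabola when logs are unusable
    apex_mz, apex_h = float(x[i_apex]), apex_raw
    if 0 < i_apex < x.size - 1:
        y0, y1, y2 = y[i_apex - 1], y[i_apex], y[i_apex + 1]
        step = 0.5 * (x[i_apex + 1] - x[i_apex - 1])
        if y0 > 0 and y2 > 0:
            l0, l1, l2 = np.log([y0, y1, y2])
            denom = l0 - 2 * l1 + l2
            if denom < 0:
                delta = 0.5 * (l0 - l2) / denom
                if abs(delta) <= 1.0:
                    apex_mz = float(x[i_apex] + delta * step)
                    apex_h = float(np.exp(l1 - 0.25 * (l0 - l2) * delta))
        else:
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                delta = 0.5 * (y0 - y2) / denom
                if abs(delta) <= 1.0:
                    apex_mz = float(x[i_apex] + delta * step)
                    apex_h = float(y1 - 0.25 * (y0 - y2) * delta)

    # crossings at each height fraction, walking outward from the apex
    def crossing(frac: float) -> tuple[float, float]:
        level = frac * apex_h
        i = i_apex
        limit_l = np.searchsorted(x, apex_mz - cfg.baseline_halfwidth)
        while i > limit_l and y[i - 1] >= level:
            i -= 1
        left = (
            _interp_crossing(x[i - 1], y[i - 1], x[i], y[i], level)
            if i > limit_l else float(x[i])
        )
        j = i_apex
        limit_r = min(np.searchsorted(x, apex_mz + cfg.baseline_halfwidth), x.size - 1)
        while j < limit_r and y[j + 1] >= level:
            j += 1
        right = (
            _interp_crossing(x[j], y[j], x[j + 1], y[j + 1], level)
            if j < limit_r else float(x[j])
        )
        return left, right

    widths: dict[float, float] = {}
    cross: dict[float, tuple[float, float]] = {}
    for frac in sorted(cfg.height_fractions):
        l, r = crossing(frac)
        cross[round(frac, 4)] = (l, r)
        widths[round(frac, 4)] = r - l

    half_l, half_r = crossing(0.50) if 0.50 not in cross else cross[0.50]
    i_half_lo = np.searchsorted(x, half_l)
    i_half_hi = np.searchsorted(x, half_r, side="right")
    xs, ys = x[i_half_lo:i_half_hi], y[i_half_lo:i_half_hi]
    centroid = float(np.sum(xs * ys) / np.sum(ys)) if ys.sum() > 0 else apex_mz

    l10, r10 = cross.get(round(min(cfg.height_fractions), 4), (half_l, half_r))
    l50, r50 = cross.get(0.50, (half_l, half_r))
    left_tail = _area(x, y, l10, l50)
    right_tail = _area(x, y, r50, r10)
    total_area = _area(x, y, l10, r10)
    tail_ratio = (left_tail + right_tail) / total_area if total_area > 0 else 0.0
    left_half = _area(x, y, l10, apex_mz)
    right_half = _area(x, y, apex_mz, r10)
    symmetry = right_half / left_half if left_half > 0 else 1.0

    g_lo = np.searchsorted(x, l10)
    g_hi = np.searchsorted(x, r10, side="right")
    gx, gy = x[g_lo:g_hi], y[g_lo:g_hi]
    gof = 0.0
    if gx.size >= 4:
        sigma0 = max(widths.get(0.50, 0.0) / 2.3548, 1e-6)
        try:
            popt, _ = curve_fit(
                _gauss, gx, gy, p0=(apex_h, apex_mz, sigma0), maxfev=200
            )
            resid = gy - _gauss(gx, *popt)
            ss_tot = float(np.sum((gy - gy.mean()) ** 2))
            gof = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
        except RuntimeError:
            gof = 0.0
    gof = float(np.clip(gof, 0.0, 1.0))

    s_lo = np.searchsorted(x, r10)
    s_hi = np.searchsorted(x, apex_mz + cfg.subsequent_span, side="right")
    ratios: list[float] = []
    n_sub = 0
    if s_hi - s_lo >= 3:
        seg = y[s_lo:s_hi]
        floor = max(threshold, cfg.subsequent_min_ratio * apex_h)
        is_max = (seg[1:-1] > seg[:-2]) & (seg[1:-1] >= seg[2:]) & (seg[1:-1] > floor)
        for k in np.flatnonzero(is_max) + 1:
            n_sub += 1
            ratios.append(float(seg[k]) / apex_h)
    ratios = ratios[: cfg.max_subsequent]
    ratios += [0.0] * (cfg.max_subsequent - len(ratios))

    theo_abund = (
        1.0 if peak.kind in (MONOISOTOPIC, LOCK_MASS)
        else peak.theoretical_relative_abundance
    )
    if peak.kind in (MONOISOTOPIC, LOCK_MASS):
        rel = 1.0
    elif parent_fit is not None and parent_fit.apex_height > 0:
        rel = apex_h / parent_fit.apex_height
    else:
        rel = 0.0

    noise = 1.4826 * base_mad
    if noise > 0:
        snr = min((apex_h - base_med) / noise, cfg.snr_cap)
    else:
        snr = cfg.snr_cap if apex_h > base_med else 0.0

    err = centroid - theo
    return PeakFit(
        peak=peak, found=True, centroid_mz=centroid, apex_mz=apex_mz,
        apex_height=apex_h, absolute_mass_error=err,
        ppm_error=err / theo * 1e6, widths=widths,
        left_tail_area=left_tail, right_tail_area=right_tail,
        tail_ratio=tail_ratio, symmetry=symmetry, gaussian_gof=gof,
        n_subsequent_peaks=n_sub,
        subsequent_intensity_ratios=tuple(ratios),
        relative_height=rel, abundance_deviation=rel - theo_abund,
        centroid_apex_offset=centroid - apex_mz,
        local_baseline=base_med, local_snr=snr,
    )


@dataclass(frozen=True)
class WindowConfig:
    percentiles: tuple[float, ...]
    top_n: int = 10
    top_percentiles: tuple[float, ...] = ()
    exclusion_halfwidth: float = 0.1

    @property
    def n_quantities(self) -> int:
        return 2 + len(self.percentiles) + self.top_n + len(self.top_percentiles)

    def quantity_names(self) -> list[str]:
        names = ["peak_count", "intensity_sum"]
        names += [f"p{_fmt_pct(p)}" for p in self.percentiles]
        names += [f"top_{k}" for k in range(1, self.top_n + 1)]
        names += [f"top_p{_fmt_pct(p)}" for p in self.top_percentiles]
        return names


def _fmt_pct(p: float) -> str:
    return str(int(p)) if float(p).is_integer() else str(p).replace(".", "_")


def window_features(
    spectrum: ProfileSpectrum,
    windows: list[tuple[float, float]],
    exclusions: list[ExpectedPeak],
    cfg: WindowConfig,
) -> list[np.ndarray]:
    """Summarize each mass window: peak count, intensity sum, percentiles of
    the trace with expected-ion exclusion zones removed, the ten tallest
    local maxima and their percentile summary."""
    if not windows:
        raise SchemaError("empty window list")
    x, y = spectrum.mz, spectrum.intensity
    excl_mz = np.array([p.theoretical_mz for p in exclusions])
    out = []
    for low, high in windows:
        lo = np.searchsorted(x, low)
        hi = np.searchsorted(x, high)
        xs, ys = x[lo:hi], y[lo:hi]
        row = np.zeros(cfg.n_quantities)
        if xs.size >= 3:
            med = float(np.median(ys))
            mad = float(np.median(np.abs(ys - med)))
            threshold = med + 3.0 * 1.4826 * mad
            inner = (ys[1:-1] > ys[:-2]) & (ys[1:-1] >= ys[2:]) & (ys[1:-1] > threshold)
            peak_idx = np.flatnonzero(inner) + 1
            heights = np.sort(ys[peak_idx])[::-1]
            if excl_mz.size:
                keep = np.ones(xs.size, dtype=bool)
                for mz in excl_mz[(excl_mz >= low - 1) & (excl_mz < high + 1)]:
                    keep &= np.abs(xs - mz) > cfg.exclusion_halfwidth
                kept = ys[keep]
            else:
                kept = ys
            pcts = (
                np.percentile(kept, cfg.percentiles) if kept.size
                else np.zeros(len(cfg.percentiles))
            )
            top = np.zeros(cfg.top_n)
            top[: min(cfg.top_n, heights.size)] = heights[: cfg.top_n]
            row[0] = float(peak_idx.size)
            row[1] = float(ys.sum())
            row[2 : 2 + len(cfg.percentiles)] = pcts
            row[2 + len(cfg.percentiles) : 2 + len(cfg.percentiles) + cfg.top_n] = top
            if cfg.top_percentiles:
                row[2 + len(cfg.percentiles) + cfg.top_n :] = np.percentile(
                    top, cfg.top_percentiles
                )
        out.append(row)
    return out


def _make_windows(low: float, high: float, width: float) -> list[tuple[float, float]]:
    edges = np.arange(low, high + width / 2, width)
    return [(float(a), float(b)) for a, b in zip(edges[:-1], edges[1:])]


LOCK_EXTRA_FRACTIONS = (0.05, 0.15, 0.20, 0.30, 0.40, 0.60, 0.65, 0.80, 0.90)
LOCK_NEIGHBORHOOD_PERCENTILES = (5, 10, 15, 20, 25, 30, 40, 50, 60, 70, 80, 90, 95, 99)


@dataclass(frozen=True)
class SchemaConfig:
    """The full feature schema; defaults reproduce the 2,850-entry vector."""

    scan: ScanConfig = field(default_factory=ScanConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    qc_windows: tuple[float, float, float] = (100.0, 850.0, 50.0)
    qc_window_cfg: WindowConfig = field(
        default_factory=lambda: WindowConfig(
            percentiles=(5, 25, 50, 75, 90, 95),
            top_percentiles=(5, 25, 50, 75, 90, 95),
        )
    )
    bg_windows: tuple[float, float, float] = (100.0, 1000.0, 100.0)
    bg_window_cfg: WindowConfig = field(
        default_factory=lambda: WindowConfig(
            percentiles=(25, 50, 75, 95), top_percentiles=(25, 50, 75, 95)
        )
    )
    noise_windows: tuple[float, float, float] = (0.0, 1000.0, 200.0)
    noise_window_cfg: WindowConfig = field(
        default_factory=lambda: WindowConfig(
            percentiles=(25, 50, 75, 95), top_percentiles=(50, 90)
        )
    )
    expected_qc_peaks: int = 37
    expected_lock_masses: int = 2
    lock_extra_fractions: tuple[float, ...] = LOCK_EXTRA_FRACTIONS
    lock_ringing_slots: int = 10
    lock_neighborhood_percentiles: tuple[float, ...] = LOCK_NEIGHBORHOOD_PERCENTILES
    lock_neighborhood_span: tuple[float, float] = (0.2, 3.0)

    def lock_fit_config(self) -> FitConfig:
        fracs = tuple(sorted(set(self.fit.height_fractions) | set(self.lock_extra_fractions)))
        return FitConfig(
            search_tol=self.fit.search_tol, height_fractions=fracs,
            baseline_halfwidth=self.fit.baseline_halfwidth,
            baseline_exclude=self.fit.baseline_exclude,
            detection_k=self.fit.detection_k,
            max_subsequent=self.lock_ringing_slots,
            subsequent_span=self.fit.subsequent_span,
            subsequent_min_ratio=self.fit.subsequent_min_ratio,
            snr_cap=self.fit.snr_cap,
        )


LOCK_QUANTITIES = (
    QC_QUANTITIES
    + tuple(f"width_{int(f * 100)}" for f in LOCK_EXTRA_FRACTIONS)
    + tuple(f"ringing_{k}" for k in range(1, 11))
    + tuple(f"bg_left_p{_fmt_pct(p)}" for p in LOCK_NEIGHBORHOOD_PERCENTILES)
    + tuple(f"bg_right_p{_fmt_pct(p)}" for p in LOCK_NEIGHBORHOOD_PERCENTILES)
)


class FeatureVector:
    """Ordered, named feature vector with per-feature provenance and stat tag."""

    def __init__(
        self,
        names: list[str],
        values: np.ndarray,
        provenance: list[str],
        stat: list[str],
    ) -> None:
        if not (len(names) == len(values) == len(provenance) == len(stat)):
            raise SchemaError("feature metadata arrays differ in length")
        if len(set(names)) != len(names):
            raise SchemaError("feature names are not unique")
        self.names = list(names)
        self.values = np.asarray(values, dtype=np.float64)
        self.provenance = list(provenance)
        self.stat = list(stat)
        self._index = {n: i for i, n in enumerate(names)}

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> float:
        try:
            return float(self.values[self._index[name]])
        except KeyError:
            raise SchemaError(f"feature {name!r} not in vector") from None

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def subtotals(self) -> dict[str, int]:
        out: dict[str, int] = {p: 0 for p in PROVENANCES}
        for p in self.provenance:
            out[p] += 1
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "name": self.names, "value": self.values,
                "provenance": self.provenance, "stat": self.stat,
            }
        )

    def to_series(self):
        import pandas as pd

        return pd.Series(self.values, index=self.names)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FeatureVector)
            and self.names == other.names
            and np.array_equal(self.values, other.values)
        )


def _sd(mat: np.ndarray) -> np.ndarray:
    """Sample SD along axis 0, exactly 0 where the values are constant."""
    sd = mat.std(axis=0, ddof=1)
    return np.where(np.ptp(mat, axis=0) == 0, 0.0, sd)


def _fit_scan(
    spectrum: ProfileSpectrum, peaks: list[ExpectedPeak], cfg: FitConfig
) -> dict[str, PeakFit]:
    """Fit all expected peaks in one scan, parents before children."""
    fits: dict[str, PeakFit] = {}
    parents = [p for p in peaks if p.kind in (MONOISOTOPIC, LOCK_MASS)]
    children = [p for p in peaks if p.kind not in (MONOISOTOPIC, LOCK_MASS)]
    for p in parents:
        fits[p.peak_id] = fit_expected_peak(spectrum, p, cfg)
    for p in children:
        fits[p.peak_id] = fit_expected_peak(
            spectrum, p, cfg, parent_fit=fits.get(p.parent_id)
        )
    return fits


def extract_features(
    acq: Acquisition,
    registry: list[ExpectedPeak] | None = None,
    cfg: SchemaConfig | None = None,
) -> FeatureVector:
    """Extract the full, deterministically ordered feature vector."""
    from .registry import default_registry

    registry = registry if registry is not None else default_registry()
    cfg = cfg or SchemaConfig()
    index = by_id(registry)
    qps = sorted(qc_peaks(registry), key=lambda p: p.theoretical_mz)
    locks = sorted(lock_mass_peaks(registry), key=lambda p: p.theoretical_mz)
    if len(qps) != cfg.expected_qc_peaks or len(locks) != cfg.expected_lock_masses:
        raise SchemaError(
            f"registry has {len(qps)} QC peaks and {len(locks)} lock masses; "
            f"schema expects {cfg.expected_qc_peaks} and {cfg.expected_lock_masses}"
        )
    comp_ids = compounds(registry)

    sel = select_scans(acq, cfg.scan)
    qc_scans = [acq[i] for i in sel.qc_scan_indices]
    bg_scan = acq[sel.background_scan_index]
    noise_scan = acq[sel.noise_scan_index]

    names: list[str] = []
    values: list[float] = []
    prov: list[str] = []
    stat: list[str] = []

    def emit(name: str, value: float, p: str, s: str) -> None:
        names.append(name)
        values.append(float(value))
        prov.append(p)
        stat.append(s)

    # --- QC peak features: 37 x 23 x {mean, sd} + 9 compound scores x 2 ---
    per_scan = [_fit_scan(s, qps, cfg.fit) for s in qc_scans]
    for p in qps:
        mat = np.stack([fits[p.peak_id].quantities() for fits in per_scan])
        means, sds = mat.mean(axis=0), _sd(mat)
        for q, m, s in zip(QC_QUANTITIES, means, sds):
            emit(f"qc_peak:{p.peak_id}:{q}:mean", m, "qc_peak", "mean")
            emit(f"qc_peak:{p.peak_id}:{q}:sd", s, "qc_peak", "sd")
    for comp in comp_ids:
        isos = [
            p.peak_id for p in qps
            if p.kind == ISOTOPOLOGUE and p.parent_id == comp
        ]
        scores = []
        for fits in per_scan:
            devs = [abs(fits[i].abundance_deviation) for i in isos]
            scores.append(float(np.mean(devs)) if devs else 0.0)
        scores = np.asarray(scores)
        emit(
            f"qc_peak:{comp}:isotope_pattern_deviation:mean",
            scores.mean(), "qc_peak", "mean",
        )
        emit(
            f"qc_peak:{comp}:isotope_pattern_deviation:sd",
            scores.std(ddof=1), "qc_peak", "sd",
        )

    # --- QC windows: 15 x 24 x {mean, sd} ---
    windows = _make_windows(*cfg.qc_windows)
    wq = cfg.qc_window_cfg.quantity_names()
    per_scan_w = np.stack(
        [
            np.stack(window_features(s, windows, qps + locks, cfg.qc_window_cfg))
            for s in qc_scans
        ]
    )  # (3, n_windows, n_quantities)
    w_mean = per_scan_w.mean(axis=0)
    w_sd = _sd(per_scan_w)
    for wi, (low, high) in enumerate(windows):
        wid = f"w{int(low)}_{int(high)}"
        for qi, q in enumerate(wq):
            emit(f"qc_window:{wid}:{q}:mean", w_mean[wi, qi], "qc_window", "mean")
            emit(f"qc_window:{wid}:{q}:sd", w_sd[wi, qi], "qc_window", "sd")

    # --- background scan: 2 lock masses x 70 + 9 windows x 20 ---
    lock_cfg = cfg.lock_fit_config()
    lock_fits = _fit_scan(bg_scan, locks, lock_cfg)
    for p in locks:
        f = lock_fits[p.peak_id]
        base = f.quantities(QC_QUANTITIES)
        extra_w = [
            f.widths.get(round(fr, 4), 0.0) for fr in cfg.lock_extra_fractions
        ]
        ring = list(f.subsequent_intensity_ratios[: cfg.lock_ringing_slots])
        ring += [0.0] * (cfg.lock_ringing_slots - len(ring))
        near, far = cfg.lock_neighborhood_span
        x, y = bg_scan.mz, bg_scan.intensity
        mu = p.theoretical_mz
        sides = []
        for lo_mz, hi_mz in ((mu - far, mu - near), (mu + near, mu + far)):
            lo_i, hi_i = np.searchsorted(x, [lo_mz, hi_mz])
            seg = y[lo_i:hi_i]
            sides.append(
                np.percentile(seg, cfg.lock_neighborhood_percentiles)
                if seg.size
                else np.zeros(len(cfg.lock_neighborhood_percentiles))
            )
        all_vals = np.concatenate([base, extra_w, ring, sides[0], sides[1]])
        for q, v in zip(LOCK_QUANTITIES, all_vals):
            emit(
                f"background_lockmass:{p.peak_id}:{q}:single",
                v, "background_lockmass", "single",
            )

    bg_windows = _make_windows(*cfg.bg_windows)
    bgq = cfg.bg_window_cfg.quantity_names()
    rows = window_features(bg_scan, bg_windows, locks, cfg.bg_window_cfg)
    for (low, high), row in zip(bg_windows, rows):
        wid = f"w{int(low)}_{int(high)}"
        for q, v in zip(bgq, row):
            emit(
                f"background_window:{wid}:{q}:single", v,
                "background_window", "single",
            )

    # --- noise scan: 5 windows x 18 ---
    n_windows = _make_windows(*cfg.noise_windows)
    nq = cfg.noise_window_cfg.quantity_names()
    rows = window_features(noise_scan, n_windows, [], cfg.noise_window_cfg)
    for (low, high), row in zip(n_windows, rows):
        wid = f"w{int(low)}_{int(high)}"
        for q, v in zip(nq, row):
            emit(f"noise_window:{wid}:{q}:single", v, "noise_window", "single")

    return FeatureVector(names, np.asarray(values), prov, stat)
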