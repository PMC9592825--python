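"""Synthetic acquisitions and run histories with known ground truth.

Every downstream stage (feature extraction, indicators, anomaly/trend
detection, association analysis) is testable against data generated here,
without instrument access. Two generators are provided:

``simulate_acquisition``
    One flow-injection QC acquisition: a chronogram with three regimes
    (chemical background with lock masses, the QC bolus arriving ~25 s
    after the start and clearing within ~80 s, then flow-stop scans with
    detector noise only), Gaussian profile peaks with FWHM = m/z / R, a
    piecewise-constant chemical baseline, Gaussian detector noise and
    optional detector "ringing" echoes after each peak.

``simulate_history``
    A longitudinal series of runs: 16 quality-indicator values per run with
    configurable means/noise, planted anomalies (shifts in SD units),
    planted linear drifts over calendar windows, plus instrument settings
    (~50 tunables, ~10 readbacks) with planted linear settings->indicator
    causal links.

All randomness flows from a single integer seed; identical truth + seed
gives byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import Acquisition, ProfileSpectrum
from .registry import (
    ExpectedPeak,
    LOCK_MASS,
    MONOISOTOPIC,
    by_id,
    default_registry,
)

_GAUSS_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # FWHM = 2.3548 sigma


@dataclass(frozen=True)
class ChronogramConfig:
    """Scan-regime layout of the 2-minute flow-injection method.

    The defaults place 120 scans at ~1 Hz: chemical background in scans
    0-29, the QC bolus apex at scan 40 (about 25 s of injection delay plus
    transfer time), the bolus cleared by scan 80, and flow-stop
    (detector-only) scans from scan 95 on.
    """

    n_scans: int = 120
    background_end: int = 30
    bolus_start: int = 30
    apex_scan: int = 40
    cleared_scan: int = 80
    flowstop_start: int = 95
    scan_hz: float = 1.0

    def __post_init__(self) -> None:
        ok = (
            0 < self.background_end
            <= self.bolus_start
            < self.apex_scan
            < self.cleared_scan
            <= self.flowstop_start
            < self.n_scans
        )
        if not ok:
            raise ConfigurationError(
                "chronogram regimes must satisfy background < bolus apex "
                "< cleared <= flow stop < n_scans"
            )

    @classmethod
    def scaled(cls, n_scans: int) -> "ChronogramConfig":
        """Proportionally rescale the default 120-scan layout."""
        if n_scans < 12:
            raise ConfigurationError(
                f"{n_scans} scans cannot host background, bolus and "
                "flow-stop regimes"
            )
        f = n_scans / 120.0
        return cls(
            n_scans=n_scans,
            background_end=max(2, round(30 * f)),
            bolus_start=max(2, round(30 * f)),
            apex_scan=max(3, round(40 * f)),
            cleared_scan=max(5, round(80 * f)),
            flowstop_start=max(6, round(95 * f)),
        )

    @classmethod
    def compact(cls) -> "ChronogramConfig":
        """A 60-scan layout that keeps the default background scan (18) valid."""
        return cls(
            n_scans=60, background_end=22, bolus_start=22, apex_scan=28,
            cleared_scan=44, flowstop_start=50,
        )

    def bolus_amplitude(self, scan: int) -> float:
        """Relative QC-mix abundance in the source at a given scan."""
        if scan < self.bolus_start or scan >= self.flowstop_start:
            return 0.0
        if scan <= self.apex_scan:
            rise_sd = max((self.apex_scan - self.bolus_start) / 3.0, 0.5)
            return float(np.exp(-0.5 * ((scan - self.apex_scan) / rise_sd) ** 2))
        tau = max((self.cleared_scan - self.apex_scan) / 4.5, 0.5)
        return float(np.exp(-(scan - self.apex_scan) / tau))


# default piecewise-constant chemical baseline: counts per 100-Th region
_BASELINE_EDGES = (100.0, 200.0, 300.0, 400.0, 500.0, 600.0, 700.0, 800.0, 900.0, 1000.0)
_BASELINE_LEVELS = (60.0, 50.0, 40.0, 35.0, 30.0, 25.0, 20.0, 15.0, 12.0)

# chemically plausible background contaminant ions (TFA, fatty acids, ...)
_DEFAULT_CONTAMINANTS = (
    (112.9856, 4.0e4),
    (255.2330, 2.5e4),
    (283.2643, 1.8e4),
    (311.1686, 8.0e3),
    (421.0073, 5.0e3),
)

_DEFAULT_HEIGHTS = {
    "taurine_M": 4.0e5, "hippurate_M": 8.0e5, "citrate_M": 1.2e6,
    "estradiol_M": 6.0e5, "fluconazole_M": 1.5e6, "raffinose_M": 9.0e5,
    "atp_M": 5.0e5, "maltotetraose_M": 7.0e5, "digoxin_M": 3.0e5,
    "HOT": 2.0e5, "HEX": 1.5e5,
}


@dataclass
class SpectrumTruth:
    """Ground truth behind one synthetic acquisition.

    ``mz_true``/``height``/``resolution``/``relative_abundance`` are keyed by
    registry ``peak_id``; heights refer to the bolus apex scan (lock masses
    keep their height on every non-flow-stop scan). The m/z grid emulates a
    TOF digitizer: fine sampling (``points_per_fwhm`` points per FWHM,
    default 10) around every expected position, coarse sampling elsewhere.
    """

    mz_true: dict[str, float]
    height: dict[str, float]
    resolution: dict[str, float]
    relative_abundance: dict[str, float]
    baseline_edges: tuple[float, ...] = _BASELINE_EDGES
    baseline_levels: tuple[float, ...] = _BASELINE_LEVELS
    contaminants: tuple[tuple[float, float], ...] = _DEFAULT_CONTAMINANTS
    noise_scale: float = 5.0
    detector_noise_scale: float = 2.0
    ppm_offset: float = 0.0
    ringing_spacing: float = 0.3
    ringing_ratios: tuple[float, ...] = (0.02, 0.008)
    tail_fraction: float = 0.0
    tail_scale: float = 0.02
    points_per_fwhm: int = 10
    coarse_spacing: float = 0.1
    fine_left: float = 0.4
    fine_right: float = 1.25
    mz_range: tuple[float, float] = (100.0, 1000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for pid, h in self.height.items():
            if h <= 0:
                raise ConfigurationError(f"height of {pid} must be > 0")
        for pid, r in self.resolution.items():
            if r <= 0:
                raise ConfigurationError(f"resolution of {pid} must be > 0")
        for pid, a in self.relative_abundance.items():
            if not 0.0 <= a <= 1.0:
                raise ConfigurationError(
                    f"relative abundance of {pid} must be in [0, 1]"
                )

    @classmethod
    def default(
        cls,
        registry: list[ExpectedPeak] | None = None,
        resolution: float = 30000.0,
        ppm_offset: float = 0.0,
        noise_scale: float = 5.0,
        seed: int = 0,
        heights: dict[str, float] | None = None,
        abundance_overrides: dict[str, float] | None = None,
        **kwargs,
    ) -> "SpectrumTruth":
        """Build a truth whose abundances follow the registry's theory."""
        registry = registry if registry is not None else default_registry()
        index = by_id(registry)
        heights = dict(_DEFAULT_HEIGHTS) if heights is None else dict(heights)
        abundance = {}
        mz_true, height, res = {}, {}, {}
        for p in registry:
            mz_true[p.peak_id] = p.theoretical_mz * (1.0 + ppm_offset * 1e-6)
            res[p.peak_id] = resolution
            if p.kind in (MONOISOTOPIC, LOCK_MASS):
                height[p.peak_id] = heights.get(p.peak_id, 5.0e5)
            else:
                a = p.theoretical_relative_abundance
                if abundance_overrides and p.peak_id in abundance_overrides:
                    a = abundance_overrides[p.peak_id]
                abundance[p.peak_id] = a
                height[p.peak_id] = a * heights.get(p.parent_id, 5.0e5)
        return cls(
            mz_true=mz_true, height=height, resolution=res,
            relative_abundance=abundance, ppm_offset=ppm_offset,
            noise_scale=noise_scale, seed=seed, **kwargs,
        )

    def fwhm(self, peak_id: str) -> float:
        return self.mz_true[peak_id] / self.resolution[peak_id]


def _build_grid(truth: SpectrumTruth) -> np.ndarray:
    """TOF-like m/z grid: locally uniform fine sampling around every
    expected/contaminant position, coarse sampling elsewhere.

    Overlapping fine regions are merged into a single uniform segment (the
    smallest member spacing), so the grid is strictly uniform across every
    peak cluster — apex interpolation relies on that.
    """
    lo, hi = truth.mz_range
    centres = [(truth.mz_true[pid], truth.fwhm(pid)) for pid in truth.mz_true]
    centres += [(mz, mz / 30000.0) for mz, _h in truth.contaminants]
    spans = sorted(
        (mu - truth.fine_left, mu + truth.fine_right, fwhm / truth.points_per_fwhm, mu)
        for mu, fwhm in centres
    )
    merged: list[list] = []  # [a, b, [(mu, step), ...]]
    for a, b, step, mu in spans:
        if merged and a <= merged[-1][1] + truth.coarse_spacing:
            merged[-1][1] = max(merged[-1][1], b)
            merged[-1][2].append((mu, step))
        else:
            merged.append([a, b, [(mu, step)]])
    segments = []
    for a, b, members in merged:
        # each member peak owns the region closest to it (Voronoi split at
        # midpoints) and samples it on its own uniform grid anchored at the
        # peak centre: every expected peak sits exactly on a locally
        # uniform, symmetric grid, so apexes and centroids are unbiased
        members = sorted(members)
        mids = [
            0.5 * (members[i][0] + members[i + 1][0])
            for i in range(len(members) - 1)
        ]
        edges = [max(a, lo)] + mids + [min(b, hi)]
        for (mu, step), r_lo, r_hi in zip(members, edges[:-1], edges[1:]):
            k_lo = int(np.ceil((r_lo - mu) / step))
            k_hi = int(np.floor((r_hi - mu) / step))
            if k_hi >= k_lo:
                segments.append(mu + np.arange(k_lo, k_hi + 1) * step)
    coarse = np.arange(lo, hi + truth.coarse_spacing / 2, truth.coarse_spacing)
    keep = np.ones(coarse.size, dtype=bool)
    for a, b, *_rest in merged:
        keep &= ~(
            (coarse >= a - truth.coarse_spacing / 2)
            & (coarse <= b + truth.coarse_spacing / 2)
        )
    grid = np.unique(np.concatenate([coarse[keep]] + segments))
    return grid


def _add_peak(
    out: np.ndarray, grid: np.ndarray, mu: float, h: float, sigma: float,
    truth: SpectrumTruth, with_ringing: bool = True,
) -> None:
    lo = np.searchsorted(grid, mu - 6 * sigma)
    hi = np.searchsorted(grid, mu + 6 * sigma)
    x = grid[lo:hi]
    if x.size:
        out[lo:hi] += h * np.exp(-0.5 * ((x - mu) / sigma) ** 2)
    if truth.tail_fraction > 0:
        t_lo = np.searchsorted(grid, mu)
        t_hi = np.searchsorted(grid, mu + 8 * truth.tail_scale)
        x = grid[t_lo:t_hi]
        if x.size:
            out[t_lo:t_hi] += h * truth.tail_fraction * np.exp(-(x - mu) / truth.tail_scale)
    if with_ringing:
        for k, ratio in enumerate(truth.ringing_ratios, start=1):
            echo_mu = mu + k * truth.ringing_spacing
            e_lo = np.searchsorted(grid, echo_mu - 6 * sigma)
            e_hi = np.searchsorted(grid, echo_mu + 6 * sigma)
            x = grid[e_lo:e_hi]
            if x.size:
                out[e_lo:e_hi] += h * ratio * np.exp(-0.5 * ((x - echo_mu) / sigma) ** 2)


def simulate_acquisition(
    truth: SpectrumTruth | None = None,
    registry: list[ExpectedPeak] | None = None,
    n_scans: int | None = None,
    chron: ChronogramConfig | None = None,
    run_id: str = "synthetic",
    acquired_at: datetime | None = None,
) -> tuple[Acquisition, SpectrumTruth]:
    """Generate one synthetic QC acquisition and return it with its truth.

    Background scans contain the chemical baseline, contaminant ions and
    the two lock masses; bolus scans add all QC-mix peaks scaled by the
    chronogram amplitude (strictly maximal at the apex scan); flow-stop
    scans contain detector noise only.
    """
    registry = registry if registry is not None else default_registry()
    truth = truth if truth is not None else SpectrumTruth.default(registry)
    if chron is None:
        chron = ChronogramConfig() if n_scans is None else ChronogramConfig.scaled(n_scans)
    elif n_scans is not None and n_scans != chron.n_scans:
        raise ConfigurationError("n_scans conflicts with the chronogram config")
    lo, hi = truth.mz_range
    for p in registry:
        if not lo <= p.theoretical_mz <= hi:
            raise ConfigurationError(
                f"registry peak {p.peak_id} at {p.theoretical_mz} Th is "
                f"outside the acquisition mass range ({lo}, {hi})"
            )

    rng = np.random.default_rng(truth.seed)
    grid = _build_grid(truth)
    # piecewise-constant baseline: flat within each region so that peak
    # centroids sit on a locally level background
    region = np.searchsorted(np.asarray(truth.baseline_edges)[1:-1], grid, side="right")
    baseline = np.asarray(truth.baseline_levels)[region]

    qc_ids = [p.peak_id for p in registry if p.kind != LOCK_MASS]
    lock_ids = [p.peak_id for p in registry if p.kind == LOCK_MASS]

    steady = baseline.copy()
    for mz, h in truth.contaminants:
        if lo <= mz <= hi:
            _add_peak(steady, grid, mz, h, (mz / 30000.0) / _GAUSS_FWHM, truth)
    for pid in lock_ids:
        sigma = truth.fwhm(pid) / _GAUSS_FWHM
        _add_peak(steady, grid, truth.mz_true[pid], truth.height[pid], sigma, truth)

    qc_profile = np.zeros_like(grid)
    for pid in qc_ids:
        sigma = truth.fwhm(pid) / _GAUSS_FWHM
        _add_peak(qc_profile, grid, truth.mz_true[pid], truth.height[pid], sigma, truth)

    spectra = []
    for s in range(chron.n_scans):
        if s >= chron.flowstop_start:
            inten = np.abs(rng.normal(0.0, truth.detector_noise_scale, grid.size)) \
                if truth.detector_noise_scale > 0 else np.zeros(grid.size)
        else:
            inten = steady + chron.bolus_amplitude(s) * qc_profile
            if truth.noise_scale > 0:
                inten = inten + rng.normal(0.0, truth.noise_scale, grid.size)
            inten = np.clip(inten, 0.0, None)
        spectra.append(
            ProfileSpectrum(
                scan_index=s, mz=grid, intensity=inten,
                is_profile=True, scan_time=s / chron.scan_hz,
            )
        )
    acq = Acquisition(
        spectra=spectra, run_id=run_id,
        acquired_at=acquired_at, mz_range=truth.mz_range,
    )
    return acq, truth


def write_truth_sidecar(truth: SpectrumTruth, path: str | Path) -> Path:
    """Serialize ground truth as JSON next to the emitted mzML."""
    path = Path(path)
    payload = dataclasses.asdict(truth)
    path.write_text(json.dumps(payload, indent=2, default=list))
    return path


# ---------------------------------------------------------------------------
# longitudinal histories
# ---------------------------------------------------------------------------

DEFAULT_INDICATOR_MEANS = {
    "resolution_200": 32000.0, "resolution_700": 28000.0,
    "average_accuracy": 1.2, "chemical_dirt": 2.0e6,
    "instrument_noise": 4.0e4, "isotopic_presence": 0.97,
    "isotopic_accuracy": 0.96, "adduct_presence": 0.05,
    "fragmentation_305": 0.10, "fragmentation_hi": 0.07,
    "baseline_25_150": 150.0, "baseline_50_650": 60.0,
    "signal": 9.0e6, "transmission": 0.8, "s2b": 4.5, "s2n": 225.0,
}

DEFAULT_TUNABLES = {
    "Acc_Focus": (4600.0, 90.0), "Amp_Offset": (120.0, 4.0),
    "Bot_Slit": (78.0, 2.5), "Top_Slit": (82.0, 2.5),
    "Cell_Entr": (-38.0, 1.5), "Cell_Exit": (-30.0, 1.5),
    "InstrumentFW": (8.0, 0.5), "Lens_1": (-42.0, 1.2),
    "Lens_2": (-14.5, 0.8), "Lens_1_RF_Ph": (15.0, 0.9),
    "Lens_2_RF_Ph": (22.0, 0.9), "MCP": (830.0, 18.0),
    "Mirror_Front": (8250.0, 40.0), "Mirror_Mid": (7300.0, 35.0),
    "Mirror_Back": (6420.0, 30.0), "Oct_1_RF_Vpp_1": (620.0, 14.0),
    "Oct_1_RF_Ph": (12.0, 0.6), "Oct_1_DC": (-6.0, 0.4),
    "Oct_2_DC": (-8.0, 0.4), "Puller_Offset": (6.5, 0.4),
    "Pusher_V": (920.0, 9.0), "Slicer": (118.0, 3.0),
    "Fragmentor": (365.0, 8.0), "Skimmer_1": (65.0, 2.0),
    "Quad_AMU_Gain": (1.002, 0.003), "Quad_AMU_Offset": (0.15, 0.02),
    "Cap_Voltage": (3500.0, 60.0), "Nozzle_Voltage": (2000.0, 45.0),
    "Drying_Gas_Temp": (200.0, 3.0), "Drying_Gas_Flow": (14.0, 0.3),
    "Sheath_Gas_Temp": (350.0, 4.0), "Sheath_Gas_Flow": (11.0, 0.3),
    "Nebulizer_Pressure": (35.0, 0.8), "Ion_Focus": (370.0, 9.0),
    "Hexapole_RF": (750.0, 15.0), "Hexapole_DC": (-4.0, 0.3),
    "Collision_Energy": (0.0, 0.1), "Cell_RF": (150.0, 4.0),
    "Detector_Gain": (1.15, 0.03), "Amp_Gain": (3.2, 0.08),
    "Pulser_Freq": (9800.0, 25.0), "Ms1_Heater": (110.0, 2.0),
    "Vaux_1": (24.0, 0.5), "Vaux_2": (-18.0, 0.5),
    "Deflector_V": (64.0, 1.5), "Ion_Guide_DC": (-2.4, 0.2),
    "Ion_Guide_RF": (480.0, 10.0), "Entrance_Lens": (-26.0, 0.9),
    "Exit_Lens": (-31.0, 0.9), "Ref_Mass_Flow": (0.35, 0.02),
}

DEFAULT_READBACKS = {
    "TOF_Vac": (2.4e-7, 1.2e-8), "Quad_Vac": (4.8e-5, 2.5e-6),
    "Rough_Vac": (2.1, 0.07), "Turbo1_Speed": (100.0, 0.4),
    "Turbo2_Speed": (99.6, 0.4), "MCP_Current": (21.0, 0.8),
    "Ion_Current": (0.85, 0.05), "Source_Temp_Read": (199.4, 1.1),
    "Noise_Floor": (3.2, 0.2), "Line_Voltage": (230.1, 1.3),
}


@dataclass
class HistoryTruth:
    """Ground truth behind a simulated longitudinal run history.

    ``anomalies`` are (run index, indicator, shift in SD units); ``trends``
    are (indicator, (start day, end day), slope per day); ``causal_edges``
    are (setting, indicator, coefficient) where the coefficient is the
    effect, in indicator SD units, of a one-SD change of the setting.
    """

    indicator_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INDICATOR_MEANS)
    )
    indicator_sds: dict[str, float] | None = None
    tunables: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TUNABLES)
    )
    readbacks: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_READBACKS)
    )
    anomalies: list[tuple[int, str, float]] = field(default_factory=list)
    trends: list[tuple[str, tuple[float, float], float]] = field(default_factory=list)
    causal_edges: list[tuple[str, str, float]] = field(default_factory=list)
    noise_cv: float = 0.04
    start: datetime = field(
        default_factory=lambda: datetime(2021, 1, 4, 9, 0, tzinfo=timezone.utc)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.indicator_sds is None:
            self.indicator_sds = {
                k: abs(v) * self.noise_cv for k, v in self.indicator_means.items()
            }
        for s, i, c in self.causal_edges:
            if not np.isfinite(c):
                raise ConfigurationError(f"edge {s}->{i} has non-finite coefficient")
        seen = set()
        for idx, ind, _shift in self.anomalies:
            if (idx, ind) in seen:
                raise ConfigurationError(
                    f"conflicting anomaly plants on run {idx}, indicator {ind}"
                )
            seen.add((idx, ind))


@dataclass
class SimulatedHistory:
    """A simulated run series: indicators, settings and ground-truth labels."""

    timestamps: pd.DatetimeIndex
    run_ids: list[str]
    indicators: pd.DataFrame
    settings: pd.DataFrame
    setting_categories: dict[str, str]
    anomaly_labels: pd.DataFrame
    truth: HistoryTruth

    def __len__(self) -> int:
        return len(self.run_ids)


def simulate_history(
    truth: HistoryTruth | None = None,
    n_runs: int = 100,
    cadence_days: float = 1.0,
) -> tuple[SimulatedHistory, HistoryTruth]:
    """Generate a longitudinal QC history with planted structure."""
    truth = truth if truth is not None else HistoryTruth()
    if n_runs < 1:
        raise ConfigurationError("n_runs must be >= 1")
    for idx, ind, _shift in truth.anomalies:
        if not 0 <= idx < n_runs:
            raise ConfigurationError(f"anomaly index {idx} outside history")
        if ind not in truth.indicator_means:
            raise ConfigurationError(f"anomaly on unknown indicator {ind}")

    rng = np.random.default_rng(truth.seed)
    days = np.arange(n_runs) * cadence_days
    timestamps = pd.DatetimeIndex(
        [truth.start + timedelta(days=float(d)) for d in days]
    )
    run_ids = [f"run{idx:04d}" for idx in range(n_runs)]

    all_settings = {**truth.tunables, **truth.readbacks}
    categories = {name: "tunable" for name in truth.tunables}
    categories.update({name: "readback" for name in truth.readbacks})
    z_settings = pd.DataFrame(
        rng.standard_normal((n_runs, len(all_settings))),
        columns=list(all_settings), index=run_ids,
    )
    settings = pd.DataFrame(
        {
            name: mean + sd * z_settings[name].to_numpy()
            for name, (mean, sd) in all_settings.items()
        },
        index=run_ids,
    )

    names = list(truth.indicator_means)
    values = np.empty((n_runs, len(names)))
    for j, name in enumerate(names):
        mean = truth.indicator_means[name]
        sd = truth.indicator_sds[name]
        v = mean + sd * rng.standard_normal(n_runs)
        for setting, ind, coef in truth.causal_edges:
            if ind == name:
                v = v + coef * sd * z_settings[setting].to_numpy()
        for ind, (d0, d1), slope in truth.trends:
            if ind == name:
                mask = (days >= d0) & (days <= d1)
                v[mask] = v[mask] + slope * (days[mask] - d0)
        values[:, j] = v

    labels = pd.DataFrame(False, index=run_ids, columns=names)
    for idx, ind, shift in truth.anomalies:
        j = names.index(ind)
        values[idx, j] += shift * truth.indicator_sds[ind]
        labels.iloc[idx, j] = True

    indicators = pd.DataFrame(values, index=run_ids, columns=names)
    history = SimulatedHistory(
        timestamps=timestamps, run_ids=run_ids, indicators=indicators,
        settings=settings, setting_categories=categories,
        anomaly_labels=labels, truth=truth,
    )
    return history, truth
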