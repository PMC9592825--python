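"""End-to-end orchestration of one QC run.

``process_qc_run`` is the unit of work triggered by the appearance of a QC
acquisition file: read the acquisition, extract the 2,850 features,
condense them into the 16 indicators, optionally attach the run's
instrument-settings file, classify each indicator against the stored
history, persist everything and emit a report. A settings-file parse
failure degrades to a warning and never blocks feature extraction.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .anomaly import AnomalyConfig, OutlierVerdict, classify_run
from .errors import SSTError
from .features import SchemaConfig, extract_features
from .indicators import IndicatorConfig, compute_indicators
from .io import read_acquisition
from .store import QCStore, RunRecord, ingest_settings


@dataclass(frozen=True)
class PipelineConfig:
    schema: SchemaConfig = field(default_factory=SchemaConfig)
    indicators: IndicatorConfig = field(default_factory=IndicatorConfig)
    anomaly: AnomalyConfig = field(default_factory=AnomalyConfig)


@dataclass
class PipelineReport:
    """What one processed run produced."""

    run_id: str
    quality: str
    score: int | None
    verdict: OutlierVerdict | None
    indicator_table: pd.DataFrame
    artifacts: list[str]
    warnings: list[str]

    def summary(self) -> str:
        lines = [
            f"run        : {self.run_id}",
            f"quality    : {self.quality}"
            + (f" (score {self.score}/16)" if self.score is not None else ""),
            "",
            self.indicator_table.to_string(index=False),
        ]
        for w in self.warnings:
            lines.append(f"warning    : {w}")
        return "\n".join(lines)


def process_qc_run(
    path: str | Path,
    store: QCStore,
    cfg: PipelineConfig | None = None,
    seed: int = 0,
    settings_path: str | Path | None = None,
    overwrite: bool = False,
) -> PipelineReport:
    """Process one acquisition file end to end and persist the run."""
    cfg = cfg or PipelineConfig()
    warn: list[str] = []
    try:
        acq = read_acquisition(path, require_profile=True)
    except SSTError as exc:
        raise type(exc)(f"[read] {exc}") from exc

    try:
        fv = extract_features(acq, list(cfg.indicators.registry), cfg.schema)
    except SSTError as exc:
        raise type(exc)(f"[features] {exc}") from exc
    try:
        qi = compute_indicators(fv, cfg.indicators)
    except SSTError as exc:
        raise type(exc)(f"[indicators] {exc}") from exc

    settings = None
    if settings_path is not None:
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                settings = ingest_settings(settings_path)
            warn += [f"[settings] {w.message}" for w in caught]
        except SSTError as exc:
            warn.append(f"[settings] skipped: {exc}")

    acquired_at = acq.acquired_at or datetime.now(timezone.utc)

    history = store.load_history(indicators_only=True)
    anomaly_cfg = dataclasses.replace(cfg.anomaly, seed=seed)
    verdict = classify_run(history, qi.to_series(), anomaly_cfg) if len(history) else None
    if verdict is None:
        quality, score = "unscored", None
        warn.append("[anomaly] empty history: run left unscored")
    elif verdict.quality == "unscored":
        quality, score = "unscored", None
    else:
        quality, score = verdict.quality, verdict.score

    record = RunRecord(
        run_id=acq.run_id, acquired_at=acquired_at, indicators=qi,
        features=fv, settings=settings, quality=quality, score=score,
    )
    try:
        store.save_run(record, overwrite=overwrite)
    except SSTError as exc:
        raise type(exc)(f"[store] {exc}") from exc

    table = pd.DataFrame(
        {
            "indicator": list(qi.values),
            "value": list(qi.values.values()),
            "direction": [qi.directions[k] for k in qi.values],
            "flag": [
                verdict.flags.get(k, "insufficient_history") if verdict else
                "insufficient_history"
                for k in qi.values
            ],
        }
    )
    return PipelineReport(
        run_id=acq.run_id, quality=quality, score=score, verdict=verdict,
        indicator_table=table, artifacts=[str(path)], warnings=warn,
    )
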