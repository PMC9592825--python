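"""Persistence of QC runs and instrument settings; feature-redundancy summary.

A single-file SQLite database holds one row per run plus long-form tables
for features, indicators and settings, so schema evolution never requires
table migrations. The store is the access point for all downstream
analyses: histories are always served ordered by acquisition timestamp
(ties broken by run_id).
"""

from __future__ import annotations

import sqlite3
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConflictError, FormatError, InsufficientDataError, StoreError
from .features import FeatureVector
from .indicators import DIRECTIONS, QualityIndicators
from .simulate import DEFAULT_READBACKS, DEFAULT_TUNABLES

TUNABLE = "tunable"
READBACK = "readback"

#: default dialect: known setting names -> category
DEFAULT_SETTINGS_CATEGORIES: dict[str, str] = {
    **{name: TUNABLE for name in DEFAULT_TUNABLES},
    **{name: READBACK for name in DEFAULT_READBACKS},
}


@dataclass
class InstrumentSettings:
    """Numeric instrument settings from one run's settings/tune report."""

    values: dict[str, float]
    categories: dict[str, str]
    source: str = ""

    def __post_init__(self) -> None:
        for name in self.values:
            if name not in self.categories:
                raise ValueError(f"setting {name!r} has no registered category")

    def tunables(self) -> dict[str, float]:
        return {k: v for k, v in self.values.items() if self.categories[k] == TUNABLE}

    def readbacks(self) -> dict[str, float]:
        return {k: v for k, v in self.values.items() if self.categories[k] == READBACK}

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class RunRecord:
    """One persisted QC run: features, indicators, settings and verdict."""

    run_id: str
    acquired_at: datetime
    indicators: QualityIndicators
    features: FeatureVector | None = None
    settings: InstrumentSettings | None = None
    quality: str = "unscored"
    score: int | None = None

    def __post_init__(self) -> None:
        if self.quality not in ("good", "bad", "unscored"):
            raise ValueError(f"invalid quality {self.quality!r}")
        if self.score is not None and not 0 <= self.score <= 16:
            raise ValueError("score must be in [0, 16]")


def ingest_settings(
    path: str | Path, dialect: dict[str, str] | None = None
) -> InstrumentSettings:
    """Parse a settings file (CSV: name,value[,category]) into settings.

    Categories come from the file's optional third column, else from the
    ``dialect`` registry; unknown names default to ``readback`` with a
    warning. Non-numeric values are skipped with a warning.
    """
    path = Path(path)
    dialect = DEFAULT_SETTINGS_CATEGORIES if dialect is None else dialect
    values: dict[str, float] = {}
    categories: dict[str, str] = {}
    try:
        raw = pd.read_csv(path, header=None, comment="#", skip_blank_lines=True)
    except Exception as exc:
        raise FormatError(f"cannot parse settings file {path}: {exc}") from exc
    if raw.shape[1] < 2:
        raise FormatError(f"settings file {path} has no value column")
    # tolerate an optional header row
    first = str(raw.iloc[0, 0]).strip().lower()
    if first in ("name", "setting", "parameter"):
        raw = raw.iloc[1:]
    for _, row in raw.iterrows():
        name = str(row.iloc[0]).strip()
        try:
            value = float(row.iloc[1])
        except (TypeError, ValueError):
            warnings.warn(f"skipping non-numeric setting {name!r}", stacklevel=2)
            continue
        if not name:
            continue
        if raw.shape[1] >= 3 and isinstance(row.iloc[2], str) and row.iloc[2].strip():
            cat = row.iloc[2].strip()
        elif name in dialect:
            cat = dialect[name]
        else:
            warnings.warn(
                f"unknown setting {name!r}: assuming category 'readback'",
                stacklevel=2,
            )
            cat = READBACK
        values[name] = value
        categories[name] = cat
    if not values:
        raise FormatError(f"no parseable settings entries in {path}")
    return InstrumentSettings(values=values, categories=categories, source=str(path))


_SCHEMA = """
CREATE TABLE IF NOT EXISTS runs (
    run_id TEXT PRIMARY KEY,
    acquired_at TEXT NOT NULL,
    quality TEXT NOT NULL,
    score INTEGER
);
CREATE TABLE IF NOT EXISTS features (
    run_id TEXT NOT NULL,
    position INTEGER NOT NULL,
    name TEXT NOT NULL,
    value REAL,
    provenance TEXT,
    stat TEXT,
    PRIMARY KEY (run_id, position)
);
CREATE TABLE IF NOT EXISTS indicators (
    run_id TEXT NOT NULL,
    name TEXT NOT NULL,
    value REAL,
    PRIMARY KEY (run_id, name)
);
CREATE TABLE IF NOT EXISTS settings (
    run_id TEXT NOT NULL,
    name TEXT NOT NULL,
    value REAL,
    category TEXT,
    PRIMARY KEY (run_id, name)
);
"""


class QCStore:
    """Single-file relational store for QC runs."""

    def __init__(self, path: str | Path = ":memory:") -> None:
        self.path = str(path)
        self._conn = sqlite3.connect(self.path)
        self._conn.executescript(_SCHEMA)
        self._conn.commit()

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "QCStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- write ------------------------------------------------------------

    def save_run(self, record: RunRecord, overwrite: bool = False) -> str:
        cur = self._conn.cursor()
        exists = cur.execute(
            "SELECT 1 FROM runs WHERE run_id = ?", (record.run_id,)
        ).fetchone()
        if exists and not overwrite:
            raise ConflictError(f"run {record.run_id!r} already stored")
        if exists:
            for table in ("runs", "features", "indicators", "settings"):
                cur.execute(f"DELETE FROM {table} WHERE run_id = ?", (record.run_id,))
        ts = record.acquired_at
        if ts.tzinfo is None:
            ts = ts.replace(tzinfo=timezone.utc)
        cur.execute(
            "INSERT INTO runs VALUES (?, ?, ?, ?)",
            (
                record.run_id,
                ts.astimezone(timezone.utc).isoformat(),
                record.quality,
                record.score,
            ),
        )
        cur.executemany(
            "INSERT INTO indicators VALUES (?, ?, ?)",
            [(record.run_id, k, float(v)) for k, v in record.indicators.values.items()],
        )
        if record.features is not None:
            fv = record.features
            cur.executemany(
                "INSERT INTO features VALUES (?, ?, ?, ?, ?, ?)",
                [
                    (record.run_id, i, n, float(v), p, s)
                    for i, (n, v, p, s) in enumerate(
                        zip(fv.names, fv.values, fv.provenance, fv.stat)
                    )
                ],
            )
        if record.settings is not None:
            cur.executemany(
                "INSERT INTO settings VALUES (?, ?, ?, ?)",
                [
                    (record.run_id, k, float(v), record.settings.categories[k])
                    for k, v in record.settings.values.items()
                ],
            )
        self._conn.commit()
        return record.run_id

    # -- read -------------------------------------------------------------

    def _ordered_run_rows(self, up_to: datetime | None):
        q = "SELECT run_id, acquired_at, quality, score FROM runs"
        args: tuple = ()
        if up_to is not None:
            if up_to.tzinfo is None:
                up_to = up_to.replace(tzinfo=timezone.utc)
            q += " WHERE acquired_at <= ?"
            args = (up_to.astimezone(timezone.utc).isoformat(),)
        q += " ORDER BY acquired_at, run_id"
        return self._conn.execute(q, args).fetchall()

    def load_run(self, run_id: str) -> RunRecord:
        row = self._conn.execute(
            "SELECT run_id, acquired_at, quality, score FROM runs WHERE run_id = ?",
            (run_id,),
        ).fetchone()
        if row is None:
            raise StoreError(f"run {run_id!r} not in store")
        ind = dict(
            self._conn.execute(
                "SELECT name, value FROM indicators WHERE run_id = ?", (run_id,)
            ).fetchall()
        )
        frows = self._conn.execute(
            "SELECT position, name, value, provenance, stat FROM features "
            "WHERE run_id = ? ORDER BY position",
            (run_id,),
        ).fetchall()
        features = None
        if frows:
            features = FeatureVector(
                names=[r[1] for r in frows],
                values=np.array([r[2] for r in frows]),
                provenance=[r[3] for r in frows],
                stat=[r[4] for r in frows],
            )
        srows = self._conn.execute(
            "SELECT name, value, category FROM settings WHERE run_id = ?", (run_id,)
        ).fetchall()
        settings = None
        if srows:
            settings = InstrumentSettings(
                values={r[0]: r[1] for r in srows},
                categories={r[0]: r[2] for r in srows},
            )
        return RunRecord(
            run_id=row[0],
            acquired_at=datetime.fromisoformat(row[1]),
            indicators=QualityIndicators(
                values={k: ind[k] for k in DIRECTIONS if k in ind}
            ),
            features=features,
            settings=settings,
            quality=row[2],
            score=row[3],
        )

    def load_history(
        self, up_to: datetime | None = None, indicators_only: bool = False
    ):
        """Ordered run history; with ``indicators_only`` a (runs x 16) frame."""
        rows = self._ordered_run_rows(up_to)
        if indicators_only:
            data = {}
            for run_id, *_rest in rows:
                ind = dict(
                    self._conn.execute(
                        "SELECT name, value FROM indicators WHERE run_id = ?",
                        (run_id,),
                    ).fetchall()
                )
                data[run_id] = ind
            frame = pd.DataFrame.from_dict(data, orient="index")
            if frame.empty:
                return pd.DataFrame(columns=list(DIRECTIONS))
            return frame.reindex(
                index=[r[0] for r in rows], columns=list(DIRECTIONS)
            )
        return [self.load_run(r[0]) for r in rows]

    def timestamps(self, up_to: datetime | None = None) -> pd.Series:
        rows = self._ordered_run_rows(up_to)
        return pd.Series(
            pd.to_datetime([r[1] for r in rows]),
            index=[r[0] for r in rows],
            name="acquired_at",
        )

    def settings_frame(self, up_to: datetime | None = None) -> pd.DataFrame:
        """(runs x settings) wide frame for runs that carry settings."""
        rows = self._ordered_run_rows(up_to)
        data = {}
        for run_id, *_ in rows:
            srows = self._conn.execute(
                "SELECT name, value FROM settings WHERE run_id = ?", (run_id,)
            ).fetchall()
            if srows:
                data[run_id] = dict(srows)
        return pd.DataFrame.from_dict(data, orient="index")

    def setting_categories(self) -> dict[str, str]:
        rows = self._conn.execute(
            "SELECT DISTINCT name, category FROM settings"
        ).fetchall()
        return {r[0]: r[1] for r in rows}

    def feature_matrix(self, up_to: datetime | None = None) -> pd.DataFrame:
        rows = self._ordered_run_rows(up_to)
        data = {}
        for run_id, *_ in rows:
            frows = self._conn.execute(
                "SELECT name, value FROM features WHERE run_id = ? ORDER BY position",
                (run_id,),
            ).fetchall()
            if frows:
                data[run_id] = dict(frows)
        return pd.DataFrame.from_dict(data, orient="index")

    def update_verdict(self, run_id: str, quality: str, score: int | None) -> None:
        self._conn.execute(
            "UPDATE runs SET quality = ?, score = ? WHERE run_id = ?",
            (quality, score, run_id),
        )
        self._conn.commit()

    def __len__(self) -> int:
        return self._conn.execute("SELECT COUNT(*) FROM runs").fetchone()[0]


def feature_correlation_summary(
    feature_matrix: pd.DataFrame, strong_threshold: float = 0.9
) -> tuple[float, float, pd.DataFrame, list[str]]:
    """Pairwise Pearson correlation summary over all feature pairs.

    Returns (fraction of pairs with |r| < 0.5, fraction with |r| > 0.9, a
    table of the strongly correlated pairs, names of constant features
    excluded because their correlation is undefined).
    """
    if len(feature_matrix) < 3:
        raise InsufficientDataError("correlation summary needs >= 3 runs")
    sds = feature_matrix.std(axis=0, ddof=1)
    constant = [str(c) for c in sds.index[~(sds > 0)]]
    mat = feature_matrix.loc[:, sds > 0]
    p = mat.shape[1]
    if p < 2:
        raise InsufficientDataError("fewer than 2 non-constant features")
    corr = np.corrcoef(mat.to_numpy(), rowvar=False)
    iu = np.triu_indices(p, k=1)
    r = corr[iu]
    frac_low = float(np.mean(np.abs(r) < 0.5))
    frac_strong = float(np.mean(np.abs(r) > strong_threshold))
    strong_mask = np.abs(r) > strong_threshold
    pairs = pd.DataFrame(
        {
            "feature_a": mat.columns.to_numpy()[iu[0][strong_mask]],
            "feature_b": mat.columns.to_numpy()[iu[1][strong_mask]],
            "pearson_r": r[strong_mask],
        }
    ).sort_values("pearson_r", key=np.abs, ascending=False, ignore_index=True)
    return frac_low, frac_strong, pairs, constant
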