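"""Experiment log container and CSV round-tripping.

A log is one time-ordered table mixing two row kinds:

* *sample* rows (``event == ""``): one per acquisition tick, with raw
  signal, calibrated transmittance and boxcar-filtered transmittance;
* *event* rows (``event`` in ``refresh_start``, ``refresh_cycle``,
  ``refresh_stop``, ``abort``): controller actions, carrying pinch time
  and delivered/removed volumes where applicable.

Logs are written as plain UTF-8 CSV ('.' decimal, header row) with a
JSON metadata sidecar (``<path>.meta.json``) holding the config
snapshot, seed and software version, so any stats environment can
consume them and every number is reconcilable: transmittance can be
recomputed from the raw column and the calibration in the metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import LogFormatError

__all__ = ["ExperimentLog", "LOG_COLUMNS", "write_log", "read_log"]

LOG_COLUMNS = [
    "time_s",
    "channel",
    "raw",
    "transmittance_pct",
    "filtered_pct",
    "phase",
    "event",
    "pinch_time_s",
    "volume_added_mL",
    "volume_removed_mL",
    "cumulative_medium_mL",
]

_STR_COLUMNS = ("phase", "event")


@dataclass
class ExperimentLog:
    """Time-ordered experiment record plus run metadata."""

    rows: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in LOG_COLUMNS if c not in self.rows.columns]
        if missing:
            raise LogFormatError(f"log is missing columns: {missing}")
        self.rows = self.rows[LOG_COLUMNS].reset_index(drop=True)

    @classmethod
    def from_records(cls, records: list[dict], metadata: dict | None = None) -> "ExperimentLog":
        df = pd.DataFrame(records, columns=LOG_COLUMNS)
        for col in _STR_COLUMNS:
            df[col] = df[col].fillna("").astype(str)
        return cls(df, metadata or {})

    @property
    def samples(self) -> pd.DataFrame:
        """Acquisition rows only."""
        return self.rows[self.rows["event"] == ""]

    @property
    def events(self) -> pd.DataFrame:
        """Controller event rows only."""
        return self.rows[self.rows["event"] != ""]

    @property
    def refresh_cycles(self) -> pd.DataFrame:
        return self.rows[self.rows["event"] == "refresh_cycle"]

    @property
    def aborted(self) -> bool:
        return bool(self.metadata.get("aborted"))

    def __len__(self) -> int:
        return len(self.rows)


def write_log(log: ExperimentLog, path: str | Path) -> Path:
    """Write the log CSV and its JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    log.rows.to_csv(path, index=False)
    sidecar = path.with_name(path.name + ".meta.json")
    sidecar.write_text(json.dumps(log.metadata, indent=2, sort_keys=True))
    return path


def read_log(path: str | Path) -> ExperimentLog:
    """Read a log written by :func:`write_log` (field-for-field round trip)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, keep_default_na=True)
    except pd.errors.ParserError as exc:  # pandas reports the offending line
        raise LogFormatError(f"malformed log {path}: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise LogFormatError(f"empty log file {path}") from exc
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise LogFormatError(f"log {path} is missing columns: {missing}")
    for col in _STR_COLUMNS:
        df[col] = df[col].fillna("").astype(str)
    sidecar = path.with_name(path.name + ".meta.json")
    metadata = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return ExperimentLog(df, metadata)
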