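"""Listening-session logs, adherence aggregation and provenance records.

All CSV schemas are UTF-8 with a header row; units are embedded in column
names (minutes_listened, course_months) and dates are ISO-8601.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass
from importlib.metadata import PackageNotFoundError, version

import pandas as pd

__all__ = [
    "SessionLog",
    "aggregate_listening",
    "read_session_logs_csv",
    "provenance",
    "ADHERENCE_THRESHOLD_HOURS",
]

#: Recommended daily listening dose (hours/day); below this a subject is
#: flagged nonadherent.
ADHERENCE_THRESHOLD_HOURS = 2.0


@dataclass(frozen=True)
class SessionLog:
    """One day of recorded sound exposure for one subject."""

    subject_id: str
    date: _dt.date
    minutes_listened: float
    source: str = "self_report"

    def __post_init__(self) -> None:
        if self.minutes_listened < 0:
            raise ValueError(
                f"minutes_listened must be >= 0, got {self.minutes_listened}"
            )
        if self.source not in ("app", "self_report"):
            raise ValueError(f"unknown log source {self.source!r}")
        if isinstance(self.date, str):
            object.__setattr__(self, "date", _dt.date.fromisoformat(self.date))


def aggregate_listening(
    logs: list[SessionLog],
    adherence_threshold_hours: float = ADHERENCE_THRESHOLD_HOURS,
) -> pd.DataFrame:
    """Mean daily listening hours per subject over each subject's logged span.

    The span is the number of calendar days from first to last log entry
    (inclusive), so unlogged days inside the span count as zero listening.
    Subjects averaging below the threshold are flagged nonadherent.
    """
    if not logs:
        raise ValueError("aggregate_listening needs at least one log entry")
    df = pd.DataFrame(
        {"subject_id": l.subject_id, "date": l.date,
         "minutes": l.minutes_listened}
        for l in logs
    )
    rows = []
    for sid, sub in df.groupby("subject_id"):
        span_days = (sub["date"].max() - sub["date"].min()).days + 1
        hours_per_day = sub["minutes"].sum() / 60.0 / span_days
        rows.append({
            "subject_id": sid,
            "n_days_logged": int(sub["date"].nunique()),
            "span_days": int(span_days),
            "mean_hours_per_day": round(float(hours_per_day), 3),
            "adherent": bool(hours_per_day >= adherence_threshold_hours),
        })
    return pd.DataFrame(rows).sort_values("subject_id").reset_index(drop=True)


def read_session_logs_csv(path) -> list[SessionLog]:
    """Read logs from CSV: subject_id, date (ISO-8601), minutes_listened[, source]."""
    df = pd.read_csv(path)
    required = {"subject_id", "date", "minutes_listened"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"session log CSV lacks columns: {sorted(missing)}")
    logs = []
    for _, r in df.iterrows():
        logs.append(SessionLog(
            subject_id=str(r["subject_id"]),
            date=_dt.date.fromisoformat(str(r["date"])),
            minutes_listened=float(r["minutes_listened"]),
            source=str(r.get("source", "self_report")) if "source" in df.columns
            else "self_report",
        ))
    return logs


def provenance(seed: int | None = None, config: dict | None = None) -> dict:
    """Machine-readable provenance block attached to every CLI output."""
    try:
        ver = version("dfcrs")
    except PackageNotFoundError:
        ver = "unknown"
    cfg_json = json.dumps(config or {}, sort_keys=True, default=str)
    return {
        "package": "dfcrs",
        "version": ver,
        "seed": seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
    }
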