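"""Session event logs and task-performance metrics.

The cognitive-motor task logs every interaction as a timestamped event.
From one session's event stream this module computes the outcome measures
used to compare the experimental conditions:

* **Cell Completion Time (CCT)** - the interval from the first confirmed
  selection of a target empty cell to the first correct entry that locks it.
  If a different cell was selected and then abandoned, timing is bound to
  the final target cell only (the selection episode that actually ends in
  the locking entry).
* **Total completion time** - from the "Start" countdown cue (first event if
  no countdown is present) to the completion event; censored (``None``)
  when the session never completed.
* **Error count** - number of incorrect entry events; repeated identical
  wrong entries each count.
* **Response-time variability** - the standard deviation of the CCT values.

Canonical on-disk formats are plain text: JSON-lines for event logs and CSV
for per-session metric tables; an Excel mirror is provided for convenience.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "EVENT_TYPES",
    "SessionEvent",
    "MetricsRecord",
    "MalformedLogError",
    "SchemaError",
    "compute_cct",
    "compute_metrics",
    "write_session_log",
    "read_session_log",
    "metrics_frame",
    "write_metrics_csv",
    "read_metrics_csv",
    "export_metrics_excel",
]

#: within-subject experimental conditions
CONDITIONS = ("no_tremor", "tremor_unfiltered", "tremor_filtered")

EVENT_TYPES = ("select", "entry", "voice", "countdown", "complete")

METRICS_COLUMNS = [
    "subject",
    "condition",
    "total_time_s",
    "cct_mean_s",
    "cct_sd_s",
    "n_errors",
    "n_completed",
]


class MalformedLogError(ValueError):
    """Raised when an event stream violates the logging contract."""


class SchemaError(ValueError):
    """Raised when a metrics table is missing required columns."""


@dataclass
class SessionEvent:
    """One logged interaction.

    ``t`` is in seconds from session start; ``cell`` is a 0-based
    (row, col) pair for select/entry events; ``value`` is the entered digit
    (entry), the recognised word (voice) or the cue text (countdown);
    ``correct`` flags entry correctness.
    """

    t: float
    type: str
    cell: tuple[int, int] | None = None
    value: object = None
    correct: bool | None = None

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type!r}")
        if self.cell is not None:
            self.cell = (int(self.cell[0]), int(self.cell[1]))

    def to_json(self) -> str:
        d = {"t": self.t, "type": self.type}
        if self.cell is not None:
            d["cell"] = list(self.cell)
        if self.value is not None:
            d["value"] = self.value
        if self.correct is not None:
            d["correct"] = self.correct
        return json.dumps(d)

    @classmethod
    def from_dict(cls, d: dict) -> "SessionEvent":
        cell = tuple(d["cell"]) if d.get("cell") is not None else None
        return cls(
            t=float(d["t"]),
            type=d["type"],
            cell=cell,
            value=d.get("value"),
            correct=d.get("correct"),
        )


@dataclass
class MetricsRecord:
    """Per-session outcome summary for one subject x condition cell."""

    subject: str
    condition: str
    total_time_s: float | None
    cct_mean_s: float | None
    cct_sd_s: float | None
    n_errors: int
    n_completed: int
    cct_values: list[float] = field(default_factory=list, repr=False)


def _check_order(events: list[SessionEvent]) -> None:
    last = -math.inf
    for ev in events:
        if ev.t < last:
            raise MalformedLogError(
                f"event timestamps decrease at t={ev.t} (previous {last})"
            )
        last = ev.t


def compute_cct(events: list[SessionEvent]) -> dict[tuple[int, int], float]:
    """Cell Completion Time per locked cell, honouring the final-target rule.

    A selection episode for a cell starts at the first ``select`` of that
    cell after any other cell was (re)selected, and ends when the cell
    receives its first correct entry.  Selecting a different cell abandons
    the previous episode.  Wrong entries on the current cell do not end the
    episode.
    """
    _check_order(events)
    ccts: dict[tuple[int, int], float] = {}
    current: tuple[int, int] | None = None
    episode_start = 0.0
    for ev in events:
        if ev.type == "select":
            if ev.cell is None:
                raise MalformedLogError(f"select event at t={ev.t} has no cell")
            if ev.cell != current:
                current = ev.cell
                episode_start = ev.t
        elif ev.type == "entry" and ev.correct:
            if ev.cell is None:
                raise MalformedLogError(f"entry event at t={ev.t} has no cell")
            if ev.cell != current:
                raise MalformedLogError(
                    f"correct entry for cell {ev.cell} at t={ev.t} without a "
                    "preceding selection of that cell"
                )
            if ev.cell not in ccts:  # first lock only
                ccts[ev.cell] = ev.t - episode_start
            current = None
    return ccts


def compute_metrics(
    events: list[SessionEvent], condition: str, subject: str = "s01"
) -> MetricsRecord:
    """Summarise one session's event stream into a :class:`MetricsRecord`.

    The session clock starts at the "Start" countdown cue when a countdown
    is present, else at the first event.  A missing completion event leaves
    ``total_time_s`` censored (``None``); all other metrics are still
    computed.
    """
    if not events:
        return MetricsRecord(subject, condition, None, None, None, 0, 0)
    _check_order(events)
    ccts = list(compute_cct(events).values())
    n_errors = sum(
        1 for ev in events if ev.type == "entry" and ev.correct is False
    )
    start_t = events[0].t
    for ev in events:
        if ev.type == "countdown" and str(ev.value).lower() == "start":
            start_t = ev.t
            break
    total: float | None = None
    for ev in events:
        if ev.type == "complete":
            total = ev.t - start_t
            break
    mean = float(np.mean(ccts)) if ccts else None
    sd = float(np.std(ccts, ddof=1)) if len(ccts) >= 2 else None
    return MetricsRecord(
        subject=subject,
        condition=condition,
        total_time_s=total,
        cct_mean_s=mean,
        cct_sd_s=sd,
        n_errors=n_errors,
        n_completed=len(ccts),
        cct_values=ccts,
    )


# -- session-log persistence (JSON-lines) --------------------------------

def write_session_log(
    record: MetricsRecord, events: list[SessionEvent], path
) -> None:
    """One header line with the metrics record, then one event per line."""
    meta = asdict(record)
    meta.pop("cct_values", None)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(json.dumps({"record": meta}) + "\n")
        for ev in events:
            fh.write(ev.to_json() + "\n")


def read_session_log(path) -> tuple[MetricsRecord, list[SessionEvent]]:
    """Inverse of :func:`write_session_log`; recomputes CCT values."""
    events: list[SessionEvent] = []
    record: MetricsRecord | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                d = json.loads(line)
            except json.JSONDecodeError as exc:
                raise MalformedLogError(f"{path}: line {lineno}: {exc}") from exc
            if "record" in d:
                if lineno != 1:
                    raise MalformedLogError(
                        f"{path}: line {lineno}: record header not on line 1"
                    )
                try:
                    record = MetricsRecord(**d["record"])
                except TypeError as exc:
                    raise MalformedLogError(
                        f"{path}: line {lineno}: bad record header: {exc}"
                    ) from exc
            else:
                try:
                    events.append(SessionEvent.from_dict(d))
                except (KeyError, ValueError) as exc:
                    raise MalformedLogError(
                        f"{path}: line {lineno}: {exc}"
                    ) from exc
    if record is None:
        raise MalformedLogError(f"{path}: missing record header line")
    record.cct_values = list(compute_cct(events).values())
    return record, events


# -- metrics tables -------------------------------------------------------

def metrics_frame(records: list[MetricsRecord]) -> pd.DataFrame:
    """Tabular export, one row per session."""
    rows = []
    for r in records:
        rows.append(
            {
                "subject": r.subject,
                "condition": r.condition,
                "total_time_s": r.total_time_s,
                "cct_mean_s": r.cct_mean_s,
                "cct_sd_s": r.cct_sd_s,
                "n_errors": r.n_errors,
                "n_completed": r.n_completed,
            }
        )
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)


def write_metrics_csv(records: list[MetricsRecord], path) -> None:
    metrics_frame(records).to_csv(path, index=False)


def read_metrics_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in METRICS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df


def export_metrics_excel(records: list[MetricsRecord], path) -> None:
    """Spreadsheet mirror of the metrics CSV (one row per session)."""
    metrics_frame(records).to_excel(path, index=False)
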