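"""Event-record CSV format, run configuration and provenance helpers.

The event CSV is a flat pharmacometric record: one row per dose or
observation, grouped contiguously by subject id.  Times are hours from
each subject's first dose, concentrations mg/L, volumes L throughout.
Below-LOQ observations are written as "<{loq}" tokens (e.g. "<0.5").

Columns: id, event (dose|observation), time, dose, duration, value,
output (serum|csf), then any covariate columns (one value per subject,
repeated on each of their rows).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import pandas as pd

from .estimate import DEFAULT_LOQ, Observation, SubjectRecord
from .model import DoseEvent

__all__ = ["EventFormatError", "RunConfig", "read_events", "write_events"]

_CORE_COLUMNS = ["id", "event", "time", "dose", "duration", "value", "output"]


class EventFormatError(ValueError):
    """A malformed event-record row, reported with its line number."""


@dataclass(frozen=True)
class RunConfig:
    """Validated run settings, hashable for output provenance."""

    box: dict = field(default_factory=dict)
    error_model: dict = field(
        default_factory=lambda: {
            "serum": {"c0": 0.25, "c1": 0.05},
            "csf": {"c0": 0.1, "c1": 0.05},
            "lambda": 0.2,
        }
    )
    loq: dict = field(default_factory=lambda: dict(DEFAULT_LOQ))
    blq_policy: str = "loq_half"
    fit: dict = field(
        default_factory=lambda: {"n_initial": 2048, "tol": 1e-4, "seed": 0}
    )
    pta_targets: tuple = (1.0, 2.0, 4.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.blq_policy not in {"loq_half", "censored"}:
            raise ValueError(f"unknown blq_policy {self.blq_policy!r}")
        if any(l <= 0 for l in self.loq.values()):
            raise ValueError("LOQs must be > 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=list)

    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def _parse_value(token, loq_map, output, line_no):
    """A concentration cell: a float, or a '<x' BLQ token."""
    token = str(token).strip()
    if token.startswith("<"):
        try:
            loq = float(token[1:])
        except ValueError as exc:
            raise EventFormatError(
                f"line {line_no}: bad BLQ token {token!r} in column 'value'"
            ) from exc
        return 0.0, True, loq
    try:
        value = float(token)
    except ValueError as exc:
        raise EventFormatError(
            f"line {line_no}: bad concentration {token!r} in column 'value'"
        ) from exc
    return value, False, loq_map.get(output, DEFAULT_LOQ.get(output))


def read_events(path, loq: dict | None = None) -> list[SubjectRecord]:
    """Parse an event-record CSV into validated SubjectRecords.

    Raises EventFormatError naming the offending line and column.
    Observations before a subject's first dose are retained (the model
    predicts zero there); a warning is attached to the record instead of
    dropping data.
    """
    loq_map = dict(DEFAULT_LOQ if loq is None else loq)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _CORE_COLUMNS if c not in df.columns]
    if missing:
        raise EventFormatError(f"missing required columns: {missing}")
    covariate_cols = [c for c in df.columns if c not in _CORE_COLUMNS]

    subjects: list[SubjectRecord] = []
    seen: set[str] = set()
    current: SubjectRecord | None = None
    for pos, row in enumerate(df.itertuples(index=False)):
        line_no = pos + 2  # header is line 1
        sid = str(row.id)
        if current is None or sid != current.id:
            if sid in seen:
                raise EventFormatError(
                    f"line {line_no}: subject id {sid!r} rows are not contiguous"
                )
            seen.add(sid)
            covariates = {}
            for c in covariate_cols:
                raw = str(getattr(row, c)).strip()
                if raw == "":
                    continue
                try:
                    covariates[c] = float(raw)
                except ValueError:
                    covariates[c] = raw
            current = SubjectRecord(id=sid, doses=[], observations=[], covariates=covariates)
            subjects.append(current)
        try:
            time = float(row.time)
        except ValueError as exc:
            raise EventFormatError(
                f"line {line_no}: bad time {row.time!r} in column 'time'"
            ) from exc
        if time < 0:
            raise EventFormatError(f"line {line_no}: negative time {time} in column 'time'")
        kind = str(row.event).strip().lower()
        if kind == "dose":
            try:
                amount = float(row.dose)
                duration = float(row.duration)
            except ValueError as exc:
                raise EventFormatError(
                    f"line {line_no}: bad dose/duration ({row.dose!r}, {row.duration!r})"
                ) from exc
            if duration <= 0:
                raise EventFormatError(
                    f"line {line_no}: infusion duration must be > 0 in column 'duration'"
                )
            current.doses.append(DoseEvent(start_time=time, amount=amount, duration=duration))
        elif kind == "observation":
            output = str(row.output).strip().lower()
            if output not in {"serum", "csf"}:
                raise EventFormatError(
                    f"line {line_no}: unknown output {row.output!r} in column 'output'"
                )
            value, blq, obs_loq = _parse_value(row.value, loq_map, output, line_no)
            current.observations.append(
                Observation(time=time, value=value, output=output, blq=blq, loq=obs_loq)
            )
        else:
            raise EventFormatError(
                f"line {line_no}: unknown event type {row.event!r} in column 'event'"
            )
    for s in subjects:
        first_dose = min((d.start_time for d in s.doses), default=0.0)
        early = [o for o in s.observations if o.time < first_dose]
        if early:
            s.covariates["_warning_pre_dose_observations"] = len(early)
    return subjects


def _fmt(x: float) -> str:
    # repr of a Python float is the shortest round-trip representation,
    # so written files reload without loss
    return repr(float(x))


def write_events(subjects, path) -> None:
    """Write SubjectRecords back to the canonical event CSV."""
    covariate_cols: list[str] = []
    for s in subjects:
        for c in s.covariates:
            if not c.startswith("_") and c not in covariate_cols:
                covariate_cols.append(c)
    rows = []
    for s in subjects:
        cov = {
            c: (s.covariates[c] if not isinstance(s.covariates.get(c), float)
                else _fmt(s.covariates[c]))
            for c in covariate_cols
            if c in s.covariates
        }
        events = [("dose", d.start_time, d) for d in s.doses] + [
            ("observation", o.time, o) for o in s.observations
        ]
        events.sort(key=lambda e: (e[1], 0 if e[0] == "dose" else 1))
        for kind, time, ev in events:
            row = {c: "" for c in _CORE_COLUMNS + covariate_cols}
            row.update({"id": s.id, "event": kind, "time": _fmt(time)})
            if kind == "dose":
                row["dose"] = _fmt(ev.amount)
                row["duration"] = _fmt(ev.duration)
            else:
                row["value"] = f"<{_fmt(ev.loq)}" if ev.blq else _fmt(ev.value)
                row["output"] = ev.output
            row.update(cov)
            rows.append(row)
    pd.DataFrame(rows, columns=_CORE_COLUMNS + covariate_cols).to_csv(path, index=False)
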