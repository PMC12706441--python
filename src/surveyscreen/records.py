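"""Record and dataset schema for web-survey response exports.

A :class:`RespondentRecord` is one survey submission: answers to declared
questions, optional personal identifiers (email, name, phone, postcode, IP),
platform anti-bot signals (CAPTCHA score, honeypot field) and timestamps.
Datasets round-trip through CSV (one column per question, ``q:`` / ``ft:``
prefixes) or JSON-lines; the schema declaring question ids and value domains
is a small YAML document.

Identifiers that a study chose not to collect are represented as ``None``,
never as empty strings; the honeypot field is the one exception — it is a
real form field whose *empty* string is the human answer.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Iterable, Mapping, Optional

import pandas as pd
import yaml

from .errors import LoadError, SchemaError

ARCHETYPES = ("genuine", "duplicator", "misrepresenter", "bot")
FRAUD_ARCHETYPES = ("duplicator", "misrepresenter", "bot")

IDENTIFIER_FIELDS = ("email", "name", "phone", "postcode", "ip")

_FIXED_COLUMNS = [
    "record_id",
    "started_at",
    "submitted_at",
    "duration_s",
    "email",
    "name",
    "phone",
    "postcode",
    "ip",
    "remuneration_requested",
    "captcha_score",
    "honeypot_value",
    "screening_attempts",
    "registry_verified",
    "truth_archetype",
]


def _parse_ts(value: str | datetime | None) -> Optional[datetime]:
    if value is None or value == "":
        return None
    if isinstance(value, datetime):
        return value if value.tzinfo else value.replace(tzinfo=timezone.utc)
    dt = datetime.fromisoformat(str(value))
    return dt if dt.tzinfo else dt.replace(tzinfo=timezone.utc)


def _fmt_ts(value: Optional[datetime]) -> str:
    if value is None:
        return ""
    return value.astimezone(timezone.utc).isoformat()


def _fmt_number(value: Optional[float]) -> str:
    if value is None:
        return ""
    if float(value).is_integer():
        return str(int(value))
    return repr(float(value))


def _parse_bool(value: Any) -> Optional[bool]:
    if value is None or value == "":
        return None
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValueError(f"not a boolean: {value!r}")


@dataclass
class QuestionSpec:
    """Declared domain of one survey question."""

    qid: str
    kind: str  # "categorical" | "numeric" | "text"
    values: Optional[list[str]] = None
    minimum: Optional[float] = None
    maximum: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "numeric", "text"):
            raise SchemaError(f"question {self.qid!r}: unknown kind {self.kind!r}")
        if self.kind == "categorical" and not self.values:
            raise SchemaError(f"question {self.qid!r}: categorical without values")

    def coerce(self, raw: Any) -> Any:
        """Coerce a raw (string) cell to the declared value type."""
        if raw is None or raw == "":
            return None
        if self.kind == "numeric":
            x = float(raw)
            return int(x) if x == int(x) else x
        return str(raw)

    def check(self, value: Any) -> Optional[str]:
        """Return a violation description or None when the value is in-domain."""
        if value is None:
            return None
        if self.kind == "categorical":
            if str(value) not in self.values:  # type: ignore[operator]
                return f"value {value!r} not in declared domain"
        elif self.kind == "numeric":
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                return f"value {value!r} is not numeric"
            if self.minimum is not None and value < self.minimum:
                return f"value {value!r} below minimum {self.minimum}"
            if self.maximum is not None and value > self.maximum:
                return f"value {value!r} above maximum {self.maximum}"
        return None


@dataclass
class SurveySchema:
    """Declared question ids, value domains and free-text question ids."""

    questions: dict[str, QuestionSpec] = field(default_factory=dict)
    free_text: list[str] = field(default_factory=list)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "SurveySchema":
        questions: dict[str, QuestionSpec] = {}
        for qid, spec in (data.get("questions") or {}).items():
            questions[qid] = QuestionSpec(
                qid=qid,
                kind=spec.get("kind", "text"),
                values=[str(v) for v in spec["values"]] if spec.get("values") else None,
                minimum=spec.get("min"),
                maximum=spec.get("max"),
            )
        return cls(questions=questions, free_text=list(data.get("free_text") or []))

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {"questions": {}, "free_text": list(self.free_text)}
        for qid, q in self.questions.items():
            spec: dict[str, Any] = {"kind": q.kind}
            if q.values is not None:
                spec["values"] = list(q.values)
            if q.minimum is not None:
                spec["min"] = q.minimum
            if q.maximum is not None:
                spec["max"] = q.maximum
            out["questions"][qid] = spec
        return out

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SurveySchema":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class RespondentRecord:
    """One survey response with identifiers, signals and answers."""

    record_id: str
    started_at: Optional[datetime] = None
    submitted_at: Optional[datetime] = None
    duration_s: Optional[float] = None
    email: Optional[str] = None
    name: Optional[str] = None
    phone: Optional[str] = None
    postcode: Optional[str] = None
    ip: Optional[str] = None
    answers: dict[str, Any] = field(default_factory=dict)
    free_texts: dict[str, str] = field(default_factory=dict)
    remuneration_requested: Optional[bool] = None
    captcha_score: Optional[float] = None
    honeypot_value: str = ""
    screening_attempts: int = 1
    registry_verified: Optional[bool] = None
    truth_archetype: Optional[str] = None

    def __post_init__(self) -> None:
        # Duration is recomputed from timestamps when both are present; the
        # stored value is only authoritative when a timestamp is missing.
        if self.started_at is not None and self.submitted_at is not None:
            self.duration_s = (self.submitted_at - self.started_at).total_seconds()

    def identifier(self, fieldname: str) -> Optional[str]:
        if fieldname not in IDENTIFIER_FIELDS:
            raise KeyError(f"{fieldname!r} is not an identifier field")
        return getattr(self, fieldname)


@dataclass
class Violation:
    """One schema/invariant violation on a record; data, not an exception."""

    record_id: str
    field: str
    rule: str
    message: str


@dataclass
class RejectedRow:
    """A raw input row that could not be parsed into a record."""

    line_no: int
    reason: str
    raw: str


@dataclass
class SurveyDataset:
    """An ordered collection of records plus the declared schema."""

    records: list[RespondentRecord] = field(default_factory=list)
    schema: SurveySchema = field(default_factory=SurveySchema)
    fraud_onset_date: Optional[datetime] = None
    rejects: list[RejectedRow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_id(self) -> dict[str, RespondentRecord]:
        return {r.record_id: r for r in self.records}

    def ids(self) -> list[str]:
        return [r.record_id for r in self.records]


# ---------------------------------------------------------------------------
# validation


def validate_record(record: RespondentRecord, schema: SurveySchema) -> list[Violation]:
    """Check one record against the dataset invariants and declared domains.

    Violations are returned as data; an empty list means the record is valid.
    """
    out: list[Violation] = []
    rid = record.record_id

    if not rid:
        out.append(Violation(rid, "record_id", "required", "record_id is empty"))

    if record.duration_s is not None and record.duration_s < 0:
        out.append(
            Violation(rid, "duration_s", "non_negative",
                      f"duration_s = {record.duration_s} is negative")
        )
    if (
        record.started_at is not None
        and record.submitted_at is not None
        and record.submitted_at < record.started_at
    ):
        out.append(
            Violation(rid, "submitted_at", "ordered_timestamps",
                      "submitted_at precedes started_at")
        )
    if record.captcha_score is not None and not (0.0 <= record.captcha_score <= 1.0):
        out.append(
            Violation(rid, "captcha_score", "unit_interval",
                      f"captcha_score = {record.captcha_score} outside [0, 1]")
        )
    if record.screening_attempts < 0:
        out.append(
            Violation(rid, "screening_attempts", "non_negative",
                      f"screening_attempts = {record.screening_attempts}")
        )

    for qid, value in record.answers.items():
        if qid not in schema.questions:
            out.append(
                Violation(rid, qid, "undeclared_question",
                          f"answer for undeclared question {qid!r}")
            )
            continue
        problem = schema.questions[qid].check(value)
        if problem:
            out.append(Violation(rid, qid, "domain", problem))

    for qid in record.free_texts:
        if schema.free_text and qid not in schema.free_text:
            out.append(
                Violation(rid, qid, "undeclared_free_text",
                          f"free text for undeclared question {qid!r}")
            )

    if record.truth_archetype is not None and record.truth_archetype not in ARCHETYPES:
        out.append(
            Violation(rid, "truth_archetype", "domain",
                      f"unknown archetype {record.truth_archetype!r}")
        )
    return out


# ---------------------------------------------------------------------------
# record <-> flat row


def _record_to_row(record: RespondentRecord, schema: SurveySchema) -> dict[str, Any]:
    row: dict[str, Any] = {
        "record_id": record.record_id,
        "started_at": _fmt_ts(record.started_at),
        "submitted_at": _fmt_ts(record.submitted_at),
        "duration_s": _fmt_number(record.duration_s),
        "email": record.email or "",
        "name": record.name or "",
        "phone": record.phone or "",
        "postcode": record.postcode or "",
        "ip": record.ip or "",
        "remuneration_requested": ""
        if record.remuneration_requested is None
        else str(record.remuneration_requested).lower(),
        "captcha_score": "" if record.captcha_score is None else repr(record.captcha_score),
        "honeypot_value": record.honeypot_value,
        "screening_attempts": str(record.screening_attempts),
        "registry_verified": ""
        if record.registry_verified is None
        else str(record.registry_verified).lower(),
        "truth_archetype": record.truth_archetype or "",
    }
    for qid in schema.questions:
        v = record.answers.get(qid)
        row[f"q:{qid}"] = "" if v is None else str(v)
    for qid in schema.free_text:
        row[f"ft:{qid}"] = record.free_texts.get(qid, "")
    return row


def _row_to_record(row: Mapping[str, Any], schema: SurveySchema) -> RespondentRecord:
    rid = str(row.get("record_id", "")).strip()
    if not rid:
        raise ValueError("empty record_id")

    def _get(col: str) -> Any:
        v = row.get(col)
        if v is None:
            return ""
        if isinstance(v, float) and math.isnan(v):
            return ""
        return v

    answers: dict[str, Any] = {}
    for qid, qspec in schema.questions.items():
        raw = _get(f"q:{qid}")
        value = qspec.coerce(raw)
        if value is not None:
            answers[qid] = value
    free_texts: dict[str, str] = {}
    for qid in schema.free_text:
        raw = str(_get(f"ft:{qid}"))
        if raw:
            free_texts[qid] = raw

    duration_raw = _get("duration_s")
    captcha_raw = _get("captcha_score")
    attempts_raw = _get("screening_attempts")
    return RespondentRecord(
        record_id=rid,
        started_at=_parse_ts(_get("started_at") or None),
        submitted_at=_parse_ts(_get("submitted_at") or None),
        duration_s=float(duration_raw) if duration_raw != "" else None,
        email=str(_get("email")) or None,
        name=str(_get("name")) or None,
        phone=str(_get("phone")) or None,
        postcode=str(_get("postcode")) or None,
        ip=str(_get("ip")) or None,
        answers=answers,
        free_texts=free_texts,
        remuneration_requested=_parse_bool(_get("remuneration_requested") or None),
        captcha_score=float(captcha_raw) if captcha_raw != "" else None,
        honeypot_value=str(_get("honeypot_value")),
        screening_attempts=int(float(attempts_raw)) if attempts_raw != "" else 1,
        registry_verified=_parse_bool(_get("registry_verified") or None),
        truth_archetype=str(_get("truth_archetype")) or None,
    )


# ---------------------------------------------------------------------------
# dataset IO


def write_responses(dataset: SurveyDataset, path: str | Path) -> None:
    """Write a dataset as CSV (``.csv``) or JSON-lines (``.jsonl``)."""
    path = Path(path)
    if path.suffix == ".jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for rec in dataset.records:
                obj = {
                    "record_id": rec.record_id,
                    "started_at": _fmt_ts(rec.started_at) or None,
                    "submitted_at": _fmt_ts(rec.submitted_at) or None,
                    "duration_s": rec.duration_s,
                    "email": rec.email,
                    "name": rec.name,
                    "phone": rec.phone,
                    "postcode": rec.postcode,
                    "ip": rec.ip,
                    "answers": rec.answers,
                    "free_texts": rec.free_texts,
                    "remuneration_requested": rec.remuneration_requested,
                    "captcha_score": rec.captcha_score,
                    "honeypot_value": rec.honeypot_value,
                    "screening_attempts": rec.screening_attempts,
                    "registry_verified": rec.registry_verified,
                    "truth_archetype": rec.truth_archetype,
                }
                fh.write(json.dumps(obj, sort_keys=True) + "\n")
        return

    columns = list(_FIXED_COLUMNS)
    columns += [f"q:{qid}" for qid in dataset.schema.questions]
    columns += [f"ft:{qid}" for qid in dataset.schema.free_text]
    rows = [_record_to_row(rec, dataset.schema) for rec in dataset.records]
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, index=False, lineterminator="\n")


def load_responses(path: str | Path, schema: SurveySchema) -> SurveyDataset:
    """Load a CSV or JSON-lines response export against a declared schema.

    Unparseable rows are collected into ``dataset.rejects`` (never silently
    dropped). A missing ``record_id`` column raises :class:`SchemaError`;
    duplicated record ids raise :class:`LoadError` naming the ids.
    """
    path = Path(path)
    records: list[RespondentRecord] = []
    rejects: list[RejectedRow] = []

    if path.suffix == ".jsonl":
        with open(path, "r", encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    obj = json.loads(line)
                    if "record_id" not in obj:
                        raise SchemaError(f"{path}: row {i} has no record_id field")
                    records.append(_json_to_record(obj, schema))
                except SchemaError:
                    raise
                except Exception as exc:  # noqa: BLE001 - reject row, keep loading
                    rejects.append(RejectedRow(i, str(exc), line[:200]))
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        if "record_id" not in df.columns:
            raise SchemaError(f"{path}: no record_id column in header")
        for i, row in enumerate(df.to_dict(orient="records"), start=2):
            try:
                records.append(_row_to_record(row, schema))
            except Exception as exc:  # noqa: BLE001
                rejects.append(RejectedRow(i, str(exc), str(row)[:200]))

    seen: dict[str, int] = {}
    for rec in records:
        seen[rec.record_id] = seen.get(rec.record_id, 0) + 1
    dupes = sorted(rid for rid, n in seen.items() if n > 1)
    if dupes:
        raise LoadError(f"{path}: duplicate record_id values: {', '.join(dupes)}")

    return SurveyDataset(records=records, schema=schema, rejects=rejects)


def _json_to_record(obj: Mapping[str, Any], schema: SurveySchema) -> RespondentRecord:
    answers = {}
    for qid, v in (obj.get("answers") or {}).items():
        if v is not None:
            answers[qid] = schema.questions[qid].coerce(v) if qid in schema.questions else v
    return RespondentRecord(
        record_id=str(obj["record_id"]),
        started_at=_parse_ts(obj.get("started_at")),
        submitted_at=_parse_ts(obj.get("submitted_at")),
        duration_s=obj.get("duration_s"),
        email=obj.get("email"),
        name=obj.get("name"),
        phone=obj.get("phone"),
        postcode=obj.get("postcode"),
        ip=obj.get("ip"),
        answers=answers,
        free_texts={k: v for k, v in (obj.get("free_texts") or {}).items() if v},
        remuneration_requested=obj.get("remuneration_requested"),
        captcha_score=obj.get("captcha_score"),
        honeypot_value=obj.get("honeypot_value") or "",
        screening_attempts=int(obj.get("screening_attempts", 1)),
        registry_verified=obj.get("registry_verified"),
        truth_archetype=obj.get("truth_archetype"),
    )


# ---------------------------------------------------------------------------
# decisions IO


def write_decisions(dataset: SurveyDataset, decisions: Iterable, path: str | Path) -> None:
    """Write per-record score decisions as CSV, one row per scored record.

    Raises :class:`LoadError` when a decision references an unknown record id
    or a dataset record has no decision.
    """
    path = Path(path)
    known = set(dataset.ids())
    decisions = list(decisions)
    rows = []
    seen = set()
    for d in decisions:
        if d.record_id not in known:
            raise LoadError(f"decision for unknown record_id {d.record_id!r}")
        seen.add(d.record_id)
        rows.append(
            {
                "record_id": d.record_id,
                "total_score": d.total_score,
                "bucket": d.bucket,
                "final": d.final or "",
                "review_reason": d.review_reason or "",
                "fired_criteria": ";".join(
                    f"{name}:{points:+g}" for name, points in d.breakdown
                ),
            }
        )
    missing = sorted(known - seen)
    if missing:
        raise LoadError(f"no decision for record(s): {', '.join(missing)}")
    df = pd.DataFrame(
        rows,
        columns=["record_id", "total_score", "bucket", "final", "review_reason",
                 "fired_criteria"],
    )
    df.to_csv(path, index=False, lineterminator="\n")


def read_decisions(path: str | Path) -> pd.DataFrame:
    """Re-load a decisions table written by :func:`write_decisions`."""
    return pd.read_csv(path, dtype={"record_id": str, "bucket": str, "final": str},
                       keep_default_na=False)
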