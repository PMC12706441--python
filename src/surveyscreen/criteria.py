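"""Fraud-criterion evaluators and the signed fraud-point registry.

Each criterion is a pure predicate over one record (plus dataset context for
duplicate/batch/free-text-duplication checks). A fired *suspicious* criterion
contributes positive points; a fired *protective* criterion contributes
negative points; criteria never short-circuit one another — no single
criterion includes or excludes a respondent on its own.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Any, Callable, Mapping, Optional, Sequence

import pandas as pd

from .errors import ConfigError
from .records import IDENTIFIER_FIELDS, RespondentRecord, SurveyDataset, SurveySchema
from .words import dictionary_ratio

# ---------------------------------------------------------------------------
# registry types


@dataclass
class CriterionSpec:
    """One criterion: direction, signed point weight, evaluator id, params."""

    name: str
    direction: str  # "protective" | "suspicious"
    points: float
    evaluator: str
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.direction not in ("protective", "suspicious"):
            raise ConfigError(f"criterion {self.name!r}: bad direction {self.direction!r}")
        if self.points == 0:
            raise ConfigError(f"criterion {self.name!r}: points must be non-zero")
        if self.direction == "protective" and self.points > 0:
            raise ConfigError(f"criterion {self.name!r}: protective points must be negative")
        if self.direction == "suspicious" and self.points < 0:
            raise ConfigError(f"criterion {self.name!r}: suspicious points must be positive")
        if self.evaluator not in EVALUATORS:
            raise ConfigError(f"criterion {self.name!r}: unknown evaluator {self.evaluator!r}")


@dataclass
class CriterionResult:
    record_id: str
    criterion: str
    fired: bool
    points_awarded: float


@dataclass
class ConsistencyRule:
    """AND-conjunction of answer clauses whose joint truth is nonsensical."""

    name: str
    clauses: list[tuple[str, str, Any]]  # (field, operator, value)

    _OPS: dict[str, Callable[[Any, Any], bool]] = field(
        default_factory=lambda: {}, repr=False, compare=False
    )

    def check_fields(self, schema: SurveySchema) -> None:
        for fieldname, _, _ in self.clauses:
            if fieldname not in schema.questions:
                raise ConfigError(
                    f"consistency rule {self.name!r} references unknown field {fieldname!r}"
                )

    def fires(self, record: RespondentRecord) -> bool:
        return all(
            _apply_op(op, record.answers.get(fieldname), value)
            for fieldname, op, value in self.clauses
        )


def _apply_op(op: str, lhs: Any, rhs: Any) -> bool:
    if lhs is None:
        return False
    if op == "eq":
        return lhs == rhs
    if op == "ne":
        return lhs != rhs
    if op == "in":
        return lhs in rhs
    if op == "not_in":
        return lhs not in rhs
    if op == "lt":
        return lhs < rhs
    if op == "gt":
        return lhs > rhs
    if op == "le":
        return lhs <= rhs
    if op == "ge":
        return lhs >= rhs
    raise ConfigError(f"unknown consistency operator {op!r}")


def consistency_violations(
    record: RespondentRecord, rules: Sequence[ConsistencyRule]
) -> list[str]:
    """Names of the rules whose clause conjunction holds on this record."""
    return [rule.name for rule in rules if rule.fires(record)]


# ---------------------------------------------------------------------------
# duplicate detection


@dataclass
class DuplicateGroup:
    """Records sharing a normalized identifier; first-by-start is retained."""

    key_values: list[str]
    record_ids: list[str]  # ordered by started_at; [0] is retained

    @property
    def retained(self) -> str:
        return self.record_ids[0]

    @property
    def extras(self) -> list[str]:
        return self.record_ids[1:]


def _normalize_key(value: Optional[str]) -> Optional[str]:
    if value is None:
        return None
    v = value.strip().lower()
    return v or None


def find_duplicates(dataset: SurveyDataset, keys: Sequence[str]) -> list[DuplicateGroup]:
    """Group records sharing any normalized identifier value.

    Groups are connected components: two records belong together when they
    share at least one key value (possibly on different keys chaining through
    a third record). Within a group, records are ordered by ``started_at``
    (ties broken by record id) and the earliest is the one to retain.
    """
    if not keys:
        raise ConfigError("find_duplicates: keys must be non-empty")
    for key in keys:
        if key not in IDENTIFIER_FIELDS:
            raise ConfigError(f"find_duplicates: {key!r} is not an identifier field")

    parent: dict[str, str] = {r.record_id: r.record_id for r in dataset.records}

    def _find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def _union(a: str, b: str) -> None:
        ra, rb = _find(a), _find(b)
        if ra != rb:
            parent[rb] = ra

    value_owner: dict[tuple[str, str], str] = {}
    for rec in dataset.records:
        for key in keys:
            val = _normalize_key(rec.identifier(key))
            if val is None:
                continue
            slot = (key, val)
            if slot in value_owner:
                _union(value_owner[slot], rec.record_id)
            else:
                value_owner[slot] = rec.record_id

    members: dict[str, list[RespondentRecord]] = {}
    for rec in dataset.records:
        members.setdefault(_find(rec.record_id), []).append(rec)

    groups: list[DuplicateGroup] = []
    far_future = datetime.max.replace(tzinfo=timezone.utc)
    order = {r.record_id: i for i, r in enumerate(dataset.records)}
    for root in sorted(members, key=lambda r: order[r]):
        recs = members[root]
        if len(recs) < 2:
            continue
        recs = sorted(recs, key=lambda r: (r.started_at or far_future, r.record_id))
        key_values = sorted(
            {
                v
                for r in recs
                for k in keys
                if (v := _normalize_key(r.identifier(k))) is not None
            }
        )
        groups.append(DuplicateGroup(key_values=key_values,
                                     record_ids=[r.record_id for r in recs]))
    return groups


# ---------------------------------------------------------------------------
# per-record evaluators


def email_pattern_flag(
    email: Optional[str], name: Optional[str], params: Optional[Mapping[str, Any]] = None
) -> bool:
    """Flag emails that are mostly digits or bear no relation to the name.

    Fires when the local part's digit fraction exceeds ``digit_frac``
    (default 0.5), or when it shares no case-insensitive substring of length
    >= 3 with the name's tokens/initials *and* alternates between digit runs
    and letter runs at least ``alt_runs`` (default 3) times. A syntactically
    malformed address fires outright.
    """
    params = dict(params or {})
    digit_frac = params.get("digit_frac", 0.5)
    alt_runs = params.get("alt_runs", 3)
    if email is None:
        return False
    local, sep, domain = email.partition("@")
    if not sep or not local or not domain or "@" in domain:
        return True
    local_l = local.lower()
    alnum = [ch for ch in local_l if ch.isalnum()]
    if not alnum:
        return True
    digits = sum(ch.isdigit() for ch in alnum)
    if digits / len(alnum) > digit_frac:
        return True

    tokens = re.findall(r"[a-z]+", (name or "").lower())
    candidates = [t for t in tokens if len(t) >= 3]
    initials = "".join(t[0] for t in tokens)
    if len(initials) >= 3:
        candidates.append(initials)
    overlap = any(
        tok[i : i + 3] in local_l
        for tok in candidates
        for i in range(len(tok) - 2)
    )
    if overlap:
        return False

    runs = 0
    prev: Optional[bool] = None
    for ch in alnum:
        is_digit = ch.isdigit()
        if prev is not None and is_digit != prev:
            runs += 1
        prev = is_digit
    return runs >= alt_runs


def completion_time_flag(duration_s: Optional[float], threshold_s: float) -> bool:
    """True iff the survey was completed in strictly less than the threshold."""
    if duration_s is None:
        return False
    return duration_s < threshold_s


def batch_flag(
    dataset: SurveyDataset,
    window_s: float,
    min_count: int,
    shared_key: Optional[str] = None,
) -> set[str]:
    """Records belonging to a run of >= min_count submissions with every
    consecutive gap <= window_s (optionally restricted to records sharing an
    identifier value)."""
    if min_count < 2:
        raise ConfigError("batch_flag: min_count must be >= 2")
    if shared_key is not None and shared_key not in IDENTIFIER_FIELDS:
        raise ConfigError(f"batch_flag: {shared_key!r} is not an identifier field")

    groups: dict[Optional[str], list[RespondentRecord]] = {}
    for rec in dataset.records:
        if rec.submitted_at is None:
            continue
        if shared_key is None:
            groups.setdefault(None, []).append(rec)
        else:
            val = _normalize_key(rec.identifier(shared_key))
            if val is None:
                continue
            groups.setdefault(val, []).append(rec)

    flagged: set[str] = set()
    for recs in groups.values():
        recs = sorted(recs, key=lambda r: (r.submitted_at, r.record_id))
        run: list[RespondentRecord] = []
        for rec in recs:
            if (
                run
                and (rec.submitted_at - run[-1].submitted_at).total_seconds() > window_s
            ):
                if len(run) >= min_count:
                    flagged.update(r.record_id for r in run)
                run = []
            run.append(rec)
        if len(run) >= min_count:
            flagged.update(r.record_id for r in run)
    return flagged


def freetext_protective(
    record: RespondentRecord,
    params: Optional[Mapping[str, Any]] = None,
    text_counts: Optional[Mapping[tuple[str, str], int]] = None,
) -> bool:
    """Sensical free-text answers as a protective signal.

    A field qualifies when it has >= ``min_tokens`` tokens, a dictionary-word
    ratio >= ``dict_ratio``, and its text is not duplicated verbatim in
    another record's same field; the criterion fires when >= ``min_fields``
    fields qualify. ``text_counts`` maps (question id, normalized text) to
    its number of occurrences across the dataset.
    """
    params = dict(params or {})
    min_fields = params.get("min_fields", 1)
    min_tokens = params.get("min_tokens", 5)
    dict_ratio = params.get("dict_ratio", 0.6)

    qualifying = 0
    for qid, text in record.free_texts.items():
        tokens = re.findall(r"[a-zA-Z']+", text)
        if len(tokens) < min_tokens:
            continue
        if dictionary_ratio(tokens) < dict_ratio:
            continue
        if text_counts is not None and text_counts.get((qid, text.strip()), 0) > 1:
            continue
        qualifying += 1
    return qualifying >= min_fields


def bot_flags(
    record: RespondentRecord, captcha_threshold: float = 0.5
) -> dict[str, bool]:
    """Honeypot and CAPTCHA signals: non-empty honeypot, sub-threshold score."""
    return {
        "honeypot_fired": bool(record.honeypot_value),
        "captcha_fired": record.captcha_score is not None
        and record.captcha_score < captcha_threshold,
    }


def remuneration_flag(record: RespondentRecord) -> str:
    """Not asking for remuneration is protective; asking is merely neutral."""
    return "protective" if record.remuneration_requested is False else "neutral"


def onset_flag(
    record: RespondentRecord, fraud_onset_date: Optional[datetime]
) -> Optional[str]:
    """Submission strictly before the fraud-onset date is protective, on/after
    it suspicious; with no onset set the criterion is inert (None)."""
    if fraud_onset_date is None or record.submitted_at is None:
        return None
    if record.submitted_at < fraud_onset_date:
        return "protective"
    return "suspicious"


def screening_attempts_flag(record: RespondentRecord) -> bool:
    """More than one screening attempt."""
    return record.screening_attempts > 1


# ---------------------------------------------------------------------------
# evaluator registry and matrix evaluation


@dataclass
class EvalContext:
    """Dataset-level context computed once and broadcast to evaluators."""

    dataset: SurveyDataset
    duplicate_members: set[str] = field(default_factory=set)
    duplicate_extras: set[str] = field(default_factory=set)
    batch_flagged: dict[str, set[str]] = field(default_factory=dict)
    text_counts: dict[tuple[str, str], int] = field(default_factory=dict)


def build_context(dataset: SurveyDataset, registry: Sequence[CriterionSpec]) -> EvalContext:
    ctx = EvalContext(dataset=dataset)
    for spec in registry:
        if spec.evaluator == "duplicate":
            keys = spec.params.get("keys", ["email"])
            groups = find_duplicates(dataset, keys)
            for g in groups:
                ctx.duplicate_members.update(g.record_ids)
                ctx.duplicate_extras.update(g.extras)
        elif spec.evaluator == "batch":
            ctx.batch_flagged[spec.name] = batch_flag(
                dataset,
                window_s=spec.params.get("window_s", 300),
                min_count=spec.params.get("min_count", 3),
                shared_key=spec.params.get("shared_key"),
            )
    counts: dict[tuple[str, str], int] = {}
    for rec in dataset.records:
        for qid, text in rec.free_texts.items():
            slot = (qid, text.strip())
            counts[slot] = counts.get(slot, 0) + 1
    ctx.text_counts = counts
    return ctx


def _ev_duplicate(rec: RespondentRecord, ctx: EvalContext, p: Mapping[str, Any]) -> bool:
    scope = p.get("scope", "any")
    if scope == "extras":
        return rec.record_id in ctx.duplicate_extras
    return rec.record_id in ctx.duplicate_members


def _ev_email_pattern(rec, ctx, p) -> bool:
    if rec.email is None:
        return False
    return email_pattern_flag(rec.email, rec.name, p)


def _ev_completion_time(rec, ctx, p) -> bool:
    return completion_time_flag(rec.duration_s, p.get("threshold_s", 300))


def _ev_batch(rec, ctx, p, *, _name=None) -> bool:
    raise ConfigError("batch evaluator is resolved via context")  # pragma: no cover


def _ev_consistency(rec, ctx, p) -> bool:
    rules = p.get("rules", [])
    return bool(consistency_violations(rec, rules))


def _ev_freetext(rec, ctx, p) -> bool:
    return freetext_protective(rec, p, ctx.text_counts)


def _ev_honeypot(rec, ctx, p) -> bool:
    return bool(rec.honeypot_value)


def _ev_captcha(rec, ctx, p) -> bool:
    return bot_flags(rec, p.get("threshold", 0.5))["captcha_fired"]


def _ev_no_remuneration(rec, ctx, p) -> bool:
    return remuneration_flag(rec) == "protective"


def _ev_onset(rec, ctx, p) -> bool:
    side = p.get("side", "after")
    outcome = onset_flag(rec, ctx.dataset.fraud_onset_date)
    if outcome is None:
        return False
    return outcome == ("protective" if side == "before" else "suspicious")


def _ev_screening_attempts(rec, ctx, p) -> bool:
    return screening_attempts_flag(rec)


def _ev_registry_unverified(rec, ctx, p) -> bool:
    return rec.registry_verified is False


def _ev_answer_equals(rec, ctx, p) -> bool:
    return rec.answers.get(p["field"]) == p["value"]


def _ev_missing_answer(rec, ctx, p) -> bool:
    v = rec.answers.get(p["field"])
    return v is None or v == ""


def _ev_straightline(rec, ctx, p) -> bool:
    fields = p.get("fields", [])
    values = [rec.answers.get(f) for f in fields]
    if len(values) < 2 or any(v is None for v in values):
        return False
    return len(set(values)) == 1


EVALUATORS: dict[str, Callable[[RespondentRecord, EvalContext, Mapping[str, Any]], bool]] = {
    "duplicate": _ev_duplicate,
    "email_pattern": _ev_email_pattern,
    "completion_time": _ev_completion_time,
    "batch": _ev_batch,
    "consistency": _ev_consistency,
    "freetext_protective": _ev_freetext,
    "honeypot": _ev_honeypot,
    "captcha": _ev_captcha,
    "no_remuneration": _ev_no_remuneration,
    "onset": _ev_onset,
    "screening_attempts": _ev_screening_attempts,
    "registry_unverified": _ev_registry_unverified,
    "answer_equals": _ev_answer_equals,
    "missing_answer": _ev_missing_answer,
    "straightline": _ev_straightline,
}


@dataclass
class EvaluationMatrix:
    """record x criterion fired/points matrices plus the registry evaluated."""

    fired: pd.DataFrame  # bool, index record_id, columns criterion names
    specs: list[CriterionSpec]

    def points(self) -> pd.DataFrame:
        pts = self.fired.astype(float).copy()
        for spec in self.specs:
            pts[spec.name] *= spec.points
        return pts

    def totals(self) -> pd.Series:
        return self.points().sum(axis=1)

    def results(self) -> list[CriterionResult]:
        out = []
        for spec in self.specs:
            col = self.fired[spec.name]
            for rid, fired in col.items():
                out.append(
                    CriterionResult(
                        record_id=rid,
                        criterion=spec.name,
                        fired=bool(fired),
                        points_awarded=spec.points if fired else 0.0,
                    )
                )
        return out

    def breakdown(self, record_id: str) -> list[tuple[str, float]]:
        row = self.fired.loc[record_id]
        return [(s.name, s.points) for s in self.specs if bool(row[s.name])]


def evaluate_all(
    dataset: SurveyDataset,
    registry: Sequence[CriterionSpec],
    context: Optional[EvalContext] = None,
) -> EvaluationMatrix:
    """Evaluate every criterion on every record.

    Dataset-context evaluators (duplicates, batches, free-text duplication)
    are computed once and broadcast. A precomputed ``context`` may be passed
    so that dataset-level signals reflect the data as collected even when
    scoring runs on a cleaned subset (a record whose duplicates were already
    removed still belonged to a duplicate group). Unknown evaluator ids raise
    ConfigError at CriterionSpec construction, before evaluation starts.
    """
    if not registry:
        raise ConfigError("evaluate_all: registry must be non-empty")
    names = [s.name for s in registry]
    if len(set(names)) != len(names):
        raise ConfigError("evaluate_all: duplicate criterion names in registry")

    ctx = context if context is not None else build_context(dataset, registry)
    data: dict[str, list[bool]] = {}
    ids = dataset.ids()
    for spec in registry:
        if spec.evaluator == "batch":
            flagged = ctx.batch_flagged[spec.name]
            data[spec.name] = [rid in flagged for rid in ids]
        else:
            fn = EVALUATORS[spec.evaluator]
            data[spec.name] = [fn(rec, ctx, spec.params) for rec in dataset.records]
    fired = pd.DataFrame(data, index=pd.Index(ids, name="record_id"))
    return EvaluationMatrix(fired=fired, specs=list(registry))


# ---------------------------------------------------------------------------
# YAML registry loading


def load_registry(path_or_data: Any, schema: Optional[SurveySchema] = None) -> list[CriterionSpec]:
    """Load a criteria registry from YAML (path) or an already-parsed list."""
    import yaml

    if isinstance(path_or_data, (str,)) or hasattr(path_or_data, "read_text"):
        with open(path_or_data, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    else:
        data = path_or_data
    specs = []
    for item in data:
        params = dict(item.get("params", {}))
        if "rules" in params:
            params["rules"] = [
                ConsistencyRule(
                    name=r["name"],
                    clauses=[(c["field"], c["op"], c["value"]) for c in r["clauses"]],
                )
                for r in params["rules"]
            ]
            if schema is not None:
                for rule in params["rules"]:
                    rule.check_fields(schema)
        specs.append(
            CriterionSpec(
                name=item["name"],
                direction=item["direction"],
                points=item["points"],
                evaluator=item["evaluator"],
                params=params,
            )
        )
    return specs
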