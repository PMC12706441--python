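"""Score aggregation, three-way triage and the categorical risk profile.

A respondent's fraud points are summed; scores at or below the low cut are
included, at or above the high cut excluded, and the midrange is marked for
review. Review resolution automates the manual pass: protective free text
with no nonsensical combinations rescues a record, a fired consistency rule
or duplicate flag condemns it, and anything else falls to a configurable
(conservative, exclude-by-default) outcome.

The categorical profile formalizes a triage over six boolean suspicious-
activity signals — multiple screening attempts, missing personal health
number, screening inconsistency, straight-lined scale answers, conspicuous
remuneration interest, and low program engagement — of which three
(attempts, remuneration interest, inconsistency) carry high weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .calibration import Thresholds
from .criteria import EvaluationMatrix
from .errors import ConfigError
from .records import RespondentRecord, SurveyDataset

INCLUDE = "INCLUDE"
EXCLUDE = "EXCLUDE"
REVIEW = "REVIEW"

RISK_SIGNALS = (
    "multiple_attempts",
    "no_phn",
    "screening_inconsistency",
    "straightline",
    "gift_card_interest",
    "low_engagement",
)
HIGH_WEIGHT_SIGNALS = frozenset(
    {"multiple_attempts", "gift_card_interest", "screening_inconsistency"}
)


@dataclass
class ScoreDecision:
    record_id: str
    total_score: float
    breakdown: list[tuple[str, float]] = field(default_factory=list)
    bucket: str = REVIEW
    final: Optional[str] = None
    review_reason: Optional[str] = None


@dataclass
class ReviewParams:
    default_review_outcome: str = EXCLUDE


@dataclass
class RiskCategory:
    record_id: str
    category: str  # "low" | "medium" | "high"
    fired_criteria: list[str] = field(default_factory=list)


def total_score(points_row: Mapping[str, float] | pd.Series | Sequence[float]) -> float:
    """Arithmetic sum of a record's awarded points."""
    if isinstance(points_row, pd.Series):
        return float(points_row.sum())
    if isinstance(points_row, Mapping):
        return float(sum(points_row.values()))
    return float(sum(points_row))


def bucket(score: float, thresholds: Thresholds) -> str:
    """Three-way triage; both cut points are inside their bands."""
    if score >= thresholds.high_cut:
        return EXCLUDE
    if score <= thresholds.low_cut:
        return INCLUDE
    return REVIEW


def decide(matrix: EvaluationMatrix, thresholds: Thresholds) -> list[ScoreDecision]:
    """Build one ScoreDecision per record, with REVIEW left unresolved."""
    totals = matrix.totals()
    out = []
    for rid in matrix.fired.index:
        score = float(totals[rid])
        b = bucket(score, thresholds)
        out.append(
            ScoreDecision(
                record_id=rid,
                total_score=score,
                breakdown=matrix.breakdown(rid),
                bucket=b,
                final=b if b != REVIEW else None,
            )
        )
    return out


def resolve_review(
    record: RespondentRecord,
    decision: ScoreDecision,
    *,
    freetext_ok: bool,
    violations: Sequence[str],
    duplicate_flagged: bool = False,
    params: Optional[ReviewParams] = None,
) -> ScoreDecision:
    """Resolve a REVIEW decision by the automated manual-review rules."""
    if decision.bucket != REVIEW:
        raise ConfigError(
            f"resolve_review called on {decision.bucket} decision {decision.record_id}"
        )
    params = params or ReviewParams()
    if violations or duplicate_flagged:
        decision.final = EXCLUDE
        decision.review_reason = (
            f"consistency violation: {', '.join(violations)}"
            if violations
            else "duplicate identifier"
        )
    elif freetext_ok:
        decision.final = INCLUDE
        decision.review_reason = "protective free text, no violations"
    else:
        decision.final = params.default_review_outcome
        decision.review_reason = "no deciding signal; default outcome"
    return decision


def bucket_counts(decisions: Iterable[ScoreDecision]) -> dict[str, int]:
    counts = {INCLUDE: 0, EXCLUDE: 0, REVIEW: 0}
    for d in decisions:
        counts[d.bucket] += 1
    return counts


def categorize_risk(
    record_id: str,
    signals: Mapping[str, bool],
    high_weight: frozenset[str] = HIGH_WEIGHT_SIGNALS,
) -> RiskCategory:
    """Low/medium/high fraud likelihood from the six boolean signals.

    High: at least one high-weight signal together with any other signal, or
    two or more high-weight signals. Medium: two or more signals without
    meeting high. Low: otherwise.
    """
    unknown = set(signals) - set(RISK_SIGNALS)
    if unknown:
        raise ConfigError(f"categorize_risk: unknown signals {sorted(unknown)}")
    fired = [s for s in RISK_SIGNALS if signals.get(s, False)]
    n_total = len(fired)
    n_high = sum(1 for s in fired if s in high_weight)
    if n_high >= 2 or (n_high >= 1 and n_total >= 2):
        category = "high"
    elif n_total >= 2:
        category = "medium"
    else:
        category = "low"
    return RiskCategory(record_id=record_id, category=category, fired_criteria=fired)


def risk_signals_from_record(
    record: RespondentRecord, violations: Sequence[str]
) -> dict[str, bool]:
    """Derive the six categorical-profile signals from one record."""
    scale = [record.answers.get(f"scale_{i}") for i in range(1, 6)]
    straight = all(v is not None for v in scale) and len(set(scale)) == 1
    return {
        "multiple_attempts": record.screening_attempts > 1,
        "no_phn": record.answers.get("phn_provided") == "no",
        "screening_inconsistency": bool(violations),
        "straightline": straight,
        "gift_card_interest": record.answers.get("gift_card_interest") == "high",
        "low_engagement": record.answers.get("engagement") == "low",
    }


def sensitivity_split(
    dataset: SurveyDataset, categories: Mapping[str, RiskCategory]
) -> tuple[list[str], list[str]]:
    """Primary analysis set (low only) and the with-medium sensitivity set
    (low + medium); high-likelihood records are excluded from both."""
    missing = [rid for rid in dataset.ids() if rid not in categories]
    if missing:
        raise ConfigError(f"sensitivity_split: no category for {missing[:5]}")
    low = [rid for rid in dataset.ids() if categories[rid].category == "low"]
    low_medium = [
        rid for rid in dataset.ids() if categories[rid].category in ("low", "medium")
    ]
    return low, low_medium
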