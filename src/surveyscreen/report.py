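"""Dataset accounting and pipeline validation metrics.

Accounting follows the two-step convention of survey data cleaning: non-fraud
removals (duplicates, incomplete mandatory fields, ineligibility) come off
the started count first, and fraud-score removals come off the remaining
*scored* denominator. All percentages are recomputed from the counts with
half-up rounding — nothing is stored that can drift from its numerator and
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional

from .errors import ConfigError
from .records import FRAUD_ARCHETYPES


def proportion_report(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100 * numerator / denominator, rounded half-up to `decimals` places."""
    if denominator <= 0:
        raise ConfigError("proportion_report: denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ConfigError(
            f"proportion_report: numerator {numerator} outside [0, {denominator}]"
        )
    q = Decimal(1).scaleb(-decimals)
    value = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
        q, rounding=ROUND_HALF_UP
    )
    return float(value)


@dataclass
class DatasetAccounting:
    """Stage-by-stage counts: started -> cleaned -> scored -> included."""

    n_started: int
    n_cleaning_removed: int
    n_scored: int
    n_fraud_removed: int
    n_included: int
    pct_fraud_of_scored: float
    pct_included_of_started: float


def account(
    n_started: int, n_cleaning_removed: int, n_fraud_removed: int
) -> DatasetAccounting:
    """Derive the full accounting from the three primitive counts."""
    if min(n_started, n_cleaning_removed, n_fraud_removed) < 0:
        raise ConfigError("account: counts must be non-negative")
    n_scored = n_started - n_cleaning_removed
    if n_scored < 0:
        raise ConfigError("account: cleaning removals exceed started count")
    n_included = n_scored - n_fraud_removed
    if n_included < 0:
        raise ConfigError("account: fraud removals exceed scored count")
    return DatasetAccounting(
        n_started=n_started,
        n_cleaning_removed=n_cleaning_removed,
        n_scored=n_scored,
        n_fraud_removed=n_fraud_removed,
        n_included=n_included,
        pct_fraud_of_scored=proportion_report(n_fraud_removed, n_scored)
        if n_scored
        else 0.0,
        pct_included_of_started=proportion_report(n_included, n_started)
        if n_started
        else 0.0,
    )


@dataclass
class PipelineMetrics:
    """End-to-end confusion of final decisions against truth archetypes."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: Optional[float]
    specificity: Optional[float]


def pipeline_metrics(
    decisions: Iterable, truth: Mapping[str, str]
) -> PipelineMetrics:
    """EXCLUDE vs fraudulent-archetype as the positive class.

    ``truth`` maps record_id to archetype; every decided record must be
    labeled.
    """
    tp = fp = tn = fn = 0
    for d in decisions:
        if d.record_id not in truth or truth[d.record_id] is None:
            raise ConfigError(f"pipeline_metrics: no truth label for {d.record_id}")
        is_fraud = truth[d.record_id] in FRAUD_ARCHETYPES
        excluded = d.final == "EXCLUDE"
        if is_fraud:
            tp += excluded
            fn += not excluded
        else:
            fp += excluded
            tn += not excluded
    sens = tp / (tp + fn) if (tp + fn) else None
    spec = tn / (tn + fp) if (tn + fp) else None
    return PipelineMetrics(tp, fp, tn, fn, sens, spec)
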