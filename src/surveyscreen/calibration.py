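"""Control-based calibration of fraud criteria and score cut-point selection.

The piloting procedure: respondents with known or institutional email domains
are designated *negative* controls (assumed genuine), those with highly
suspicious pattern-based emails *positive* controls (assumed fraudulent).
Each criterion's sensitivity and specificity are measured on the controls,
and two score cut points are chosen so that the include band keeps almost no
positive control and the exclude band catches almost no negative control;
everything between lands in a manual-review band.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .criteria import EvaluationMatrix
from .errors import CalibrationError
from .records import FRAUD_ARCHETYPES, SurveyDataset

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass
class ControlLabels:
    """record_id -> positive / negative; everything else is unlabeled."""

    labels: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def positives(self) -> set[str]:
        return {rid for rid, lab in self.labels.items() if lab == POSITIVE}

    @property
    def negatives(self) -> set[str]:
        return {rid for rid, lab in self.labels.items() if lab == NEGATIVE}

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class PerformanceRow:
    """Confusion counts and ratios of one criterion over the controls."""

    criterion: str
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: Optional[float]
    specificity: Optional[float]


@dataclass
class Thresholds:
    """Score cut points: include at or below low_cut, exclude at or above
    high_cut, review in between."""

    low_cut: float
    high_cut: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.low_cut > self.high_cut:
            raise CalibrationError(
                f"low_cut {self.low_cut} exceeds high_cut {self.high_cut}"
            )


@dataclass
class CalibrationTargets:
    """Performance floor for the cut points.

    The exclude cut may misclassify at most ``1 - min_specificity`` of the
    negative controls; the include cut at most ``1 - min_sensitivity`` of the
    positive controls. Defaults (0.99 / 0.90) sit at the level the strongest
    individual criteria reach in practice — specificities of 99-100% with
    sensitivities in the low 90s.
    """

    min_specificity: float = 0.99
    min_sensitivity: float = 0.90


def designate_controls(
    dataset: SurveyDataset,
    negative_email_domains: Sequence[str],
    positive_email_patterns: Sequence[str],
) -> ControlLabels:
    """Label controls from email rules.

    Negative where the email domain is in the trusted list (subdomains
    included); positive where the local part matches a suspicious pattern;
    a record matching both is left unlabeled with a warning.
    """
    if not negative_email_domains or not positive_email_patterns:
        raise CalibrationError(
            "designate_controls: both negative domains and positive patterns "
            "are required (calibration impossible without controls)"
        )
    trusted = [d.strip().lower() for d in negative_email_domains]
    patterns = [re.compile(p) for p in positive_email_patterns]

    out = ControlLabels()
    for rec in dataset.records:
        if not rec.email or "@" not in rec.email:
            continue
        local, _, domain = rec.email.lower().partition("@")
        is_negative = any(domain == d or domain.endswith("." + d) for d in trusted)
        is_positive = any(p.search(local) for p in patterns)
        if is_negative and is_positive:
            msg = (
                f"{rec.record_id}: email matches both a trusted domain and a "
                "suspicious pattern; left unlabeled"
            )
            out.warnings.append(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        if is_negative:
            out.labels[rec.record_id] = NEGATIVE
        elif is_positive:
            out.labels[rec.record_id] = POSITIVE
    return out


def truth_controls(dataset: SurveyDataset) -> ControlLabels:
    """Treat synthetic truth archetypes as controls (testing convenience)."""
    out = ControlLabels()
    for rec in dataset.records:
        if rec.truth_archetype is None:
            continue
        out.labels[rec.record_id] = (
            POSITIVE if rec.truth_archetype in FRAUD_ARCHETYPES else NEGATIVE
        )
    return out


def criterion_performance(
    fired: Mapping[str, bool] | pd.Series,
    direction: str,
    labels: ControlLabels,
    criterion: str = "",
) -> PerformanceRow:
    """2x2 confusion counts of one criterion over labeled records only.

    A suspicious criterion predicts fraud when it fires; a protective
    criterion's polarity is inverted (not firing predicts fraud). Undefined
    ratios are reported as None, never 0.
    """
    pos, neg = labels.positives, labels.negatives
    if not pos or not neg:
        missing = "positive" if not pos else "negative"
        raise CalibrationError(f"criterion_performance: no {missing} controls")

    if isinstance(fired, pd.Series):
        fired = fired.to_dict()
    tp = fp = tn = fn = 0
    for rid, lab in labels.labels.items():
        if rid not in fired:
            continue
        pred_fraud = bool(fired[rid]) if direction == "suspicious" else not bool(fired[rid])
        if lab == POSITIVE:
            tp += pred_fraud
            fn += not pred_fraud
        else:
            fp += pred_fraud
            tn += not pred_fraud
    sens = tp / (tp + fn) if (tp + fn) else None
    spec = tn / (tn + fp) if (tn + fp) else None
    return PerformanceRow(criterion, tp, fp, tn, fn, sens, spec)


def calibration_table(
    matrix: EvaluationMatrix, labels: ControlLabels
) -> pd.DataFrame:
    """Per-criterion performance table mirroring a pilot calibration report."""
    rows = []
    for spec in matrix.specs:
        row = criterion_performance(
            matrix.fired[spec.name], spec.direction, labels, criterion=spec.name
        )
        rows.append(
            {
                "criterion": row.criterion,
                "direction": spec.direction,
                "points": spec.points,
                "TP": row.tp,
                "FP": row.fp,
                "TN": row.tn,
                "FN": row.fn,
                "sensitivity": row.sensitivity,
                "specificity": row.specificity,
            }
        )
    return pd.DataFrame(rows)


def write_calibration_report(table: pd.DataFrame, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "# control-based calibration report; control designation and "
            "targets are study assumptions, not measured ground truth\n"
        )
        table.to_csv(fh, index=False, lineterminator="\n")


def select_thresholds(
    total_scores: Mapping[str, float] | pd.Series,
    labels: ControlLabels,
    targets: Optional[CalibrationTargets] = None,
) -> Thresholds:
    """Pick the low/high score cut points from control score distributions.

    high_cut: the smallest candidate score such that the fraction of negative
    controls scoring >= it stays within 1 - min_specificity. low_cut: the
    largest candidate such that the fraction of positive controls scoring
    <= it stays within 1 - min_sensitivity. When no observed score satisfies
    either constraint (e.g. all controls share one score), or the cuts cross,
    both collapse to the midpoint with a degeneracy warning.
    """
    targets = targets or CalibrationTargets()
    if isinstance(total_scores, pd.Series):
        total_scores = total_scores.to_dict()
    pos = np.array(sorted(total_scores[r] for r in labels.positives if r in total_scores))
    neg = np.array(sorted(total_scores[r] for r in labels.negatives if r in total_scores))
    if len(pos) == 0 or len(neg) == 0:
        raise CalibrationError("select_thresholds: need scored controls of both classes")

    observed = np.unique(np.concatenate([pos, neg]))
    spec_slack = 1.0 - targets.min_specificity
    sens_slack = 1.0 - targets.min_sensitivity

    high_cut = None
    for c in observed:  # ascending: smallest satisfying candidate wins
        if np.mean(neg >= c) <= spec_slack:
            high_cut = float(c)
            break
    high_sentinel = high_cut is None
    if high_sentinel:
        high_cut = float(observed[-1]) + 1.0

    low_cut = None
    for c in observed[::-1]:  # descending: largest satisfying candidate wins
        if np.mean(pos <= c) <= sens_slack:
            low_cut = float(c)
            break
    low_sentinel = low_cut is None
    if low_sentinel:
        low_cut = float(observed[0]) - 1.0

    if low_sentinel and high_sentinel:
        # no observed score satisfies either constraint (e.g. all controls
        # share one score): collapse to the middle of the observed range
        mid = float((observed[0] + observed[-1]) / 2.0)
        warnings.warn(
            "select_thresholds: no usable control separation; collapsing both "
            f"cuts to {mid}",
            stacklevel=2,
        )
        return Thresholds(low_cut=mid, high_cut=mid, degenerate=True)
    if low_cut > high_cut:
        mid = (low_cut + high_cut) / 2.0
        warnings.warn(
            f"select_thresholds: cuts crossed (low {low_cut} > high {high_cut});"
            f" collapsing both to {mid}",
            stacklevel=2,
        )
        return Thresholds(low_cut=mid, high_cut=mid, degenerate=True)

    return Thresholds(low_cut=low_cut, high_cut=high_cut)
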