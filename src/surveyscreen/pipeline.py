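"""End-to-end orchestration: load/generate -> clean -> score -> calibrate ->
classify -> report.

Every removal is logged exactly once with a machine-readable reason code
(``duplicate_entry``, ``invalid:<field>`` or ``fraud_score``), so that
included + fraud-excluded + cleaning-removed always reconstructs the started
count. Given a config (and its seed) the decisions table is byte-identical
across reruns; only the log's wall-clock timestamps differ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml

from .calibration import (
    CalibrationTargets,
    ControlLabels,
    Thresholds,
    calibration_table,
    designate_controls,
    select_thresholds,
    truth_controls,
    write_calibration_report,
)
from .classify import (
    EXCLUDE,
    REVIEW,
    ReviewParams,
    ScoreDecision,
    bucket_counts,
    decide,
    resolve_review,
)
from .cohort import CohortConfig, case1_like_config, generate_cohort
from .criteria import (
    build_context,
    consistency_violations,
    evaluate_all,
    find_duplicates,
    load_registry,
)
from .errors import PipelineError, SurveyScreenError
from .presets import NEGATIVE_EMAIL_DOMAINS, POSITIVE_EMAIL_PATTERNS, registry
from .records import (
    SurveyDataset,
    SurveySchema,
    load_responses,
    write_decisions,
    write_responses,
)
from .report import DatasetAccounting, PipelineMetrics, account, pipeline_metrics


@dataclass
class PipelineConfig:
    """Declarative description of one screening run."""

    # input: either a cohort to generate or a file to load
    cohort: Optional[CohortConfig] = None
    input_path: Optional[str] = None
    schema_path: Optional[str] = None

    registry_name: str = "case1"
    registry_path: Optional[str] = None

    dedup_keys: list[str] = field(default_factory=lambda: ["email", "phone"])
    drop_invalid: bool = True

    controls: str = "email"  # "email" | "truth"
    negative_email_domains: list[str] = field(
        default_factory=lambda: list(NEGATIVE_EMAIL_DOMAINS)
    )
    positive_email_patterns: list[str] = field(
        default_factory=lambda: list(POSITIVE_EMAIL_PATTERNS)
    )
    targets: CalibrationTargets = field(default_factory=CalibrationTargets)
    #: bypass control-based calibration with explicit cut points
    fixed_thresholds: Optional[Thresholds] = None
    review: ReviewParams = field(default_factory=ReviewParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        cfg = cls()
        cohort = data.get("cohort")
        if cohort:
            if cohort.get("preset") == "case1_like":
                cfg.cohort = case1_like_config(
                    n_records=int(cohort.get("n", 2000)), seed=int(cohort.get("seed", 0))
                )
            else:
                cfg.cohort = CohortConfig(
                    n_records=int(cohort.get("n", 1000)), seed=int(cohort.get("seed", 0))
                )
        data_block = data.get("data")
        if data_block:
            cfg.input_path = data_block.get("path")
            cfg.schema_path = data_block.get("schema")
        reg = data.get("registry", "case1")
        if isinstance(reg, str) and reg.endswith((".yaml", ".yml")):
            cfg.registry_path = reg
        else:
            cfg.registry_name = reg
        cleaning = data.get("cleaning") or {}
        cfg.dedup_keys = list(cleaning.get("dedup_keys", cfg.dedup_keys))
        cfg.drop_invalid = bool(cleaning.get("drop_invalid", True))
        calib = data.get("calibration") or {}
        cfg.controls = calib.get("controls", "email")
        targets = calib.get("targets") or {}
        cfg.targets = CalibrationTargets(
            min_specificity=float(targets.get("min_specificity", 0.99)),
            min_sensitivity=float(targets.get("min_sensitivity", 0.90)),
        )
        fixed = calib.get("thresholds")
        if fixed:
            cfg.fixed_thresholds = Thresholds(
                low_cut=float(fixed["low"]), high_cut=float(fixed["high"])
            )
        review = data.get("review") or {}
        cfg.review = ReviewParams(
            default_review_outcome=review.get("default_outcome", EXCLUDE)
        )
        return cfg


@dataclass
class RunResult:
    dataset: SurveyDataset
    scored: SurveyDataset
    decisions: list[ScoreDecision]
    thresholds: Thresholds
    controls: ControlLabels
    accounting: DatasetAccounting
    metrics: Optional[PipelineMetrics]
    removal_log: list[tuple[str, str, str]]  # (stage, record_id, reason)
    bucket_counts: dict[str, int]


def _log_line(fh, stage: str, message: str) -> None:
    ts = datetime.now(timezone.utc).isoformat(timespec="seconds")
    fh.write(f"{ts}\t{stage}\t{message}\n")


def run_pipeline(
    config: PipelineConfig, out_dir: Optional[str | Path] = None
) -> RunResult:
    """Run the whole screening pipeline and (optionally) write all artifacts.

    Any stage failure raises :class:`PipelineError` naming the stage, and
    partially written outputs are removed.
    """
    out = Path(out_dir) if out_dir is not None else None
    written: list[Path] = []
    try:
        result = _run(config, out, written)
    except SurveyScreenError:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return result


def _run(config: PipelineConfig, out: Optional[Path], written: list[Path]) -> RunResult:
    log_lines: list[str] = []
    removal_log: list[tuple[str, str, str]] = []

    # --- stage: input
    try:
        if config.cohort is not None:
            dataset = generate_cohort(config.cohort)
        elif config.input_path:
            if not config.schema_path:
                raise PipelineError("input: schema_path required with input_path")
            schema = SurveySchema.from_yaml(config.schema_path)
            dataset = load_responses(config.input_path, schema)
        else:
            raise PipelineError("input: neither cohort nor input_path configured")
    except SurveyScreenError as exc:
        raise PipelineError(f"input: {exc}") from exc
    n_started = len(dataset)

    # --- stage: cleaning
    try:
        removed_ids: set[str] = set()
        if config.dedup_keys:
            for group in find_duplicates(dataset, config.dedup_keys):
                for rid in group.extras:
                    if rid not in removed_ids:
                        removed_ids.add(rid)
                        removal_log.append(("cleaning", rid, "duplicate_entry"))
        if config.drop_invalid:
            for rec in dataset.records:
                if rec.record_id in removed_ids:
                    continue
                violations = [
                    v
                    for v in _validate(rec, dataset.schema)
                    if v.rule != "undeclared_free_text"
                ]
                if violations:
                    removed_ids.add(rec.record_id)
                    removal_log.append(
                        ("cleaning", rec.record_id, f"invalid:{violations[0].field}")
                    )
        kept = [r for r in dataset.records if r.record_id not in removed_ids]
        scored_ds = SurveyDataset(
            records=kept, schema=dataset.schema, fraud_onset_date=dataset.fraud_onset_date
        )
    except SurveyScreenError as exc:
        raise PipelineError(f"cleaning: {exc}") from exc
    n_cleaning_removed = n_started - len(scored_ds)

    # --- stage: scoring
    try:
        if config.registry_path:
            specs = load_registry(config.registry_path, scored_ds.schema)
        else:
            specs = registry(config.registry_name)
        # dataset-level context (duplicate groups, batches, repeated free
        # text) reflects the data as collected, not the cleaned subset
        ctx = build_context(dataset, specs)
        matrix = evaluate_all(scored_ds, specs, context=ctx)
        totals = matrix.totals()
    except SurveyScreenError as exc:
        raise PipelineError(f"scoring: {exc}") from exc

    # --- stage: calibration
    try:
        if config.controls == "truth":
            controls = truth_controls(scored_ds)
        else:
            controls = designate_controls(
                scored_ds, config.negative_email_domains, config.positive_email_patterns
            )
        if config.fixed_thresholds is not None:
            thresholds = config.fixed_thresholds
            calib = (
                calibration_table(matrix, controls)
                if controls.positives and controls.negatives
                else None
            )
        else:
            calib = calibration_table(matrix, controls)
            thresholds = select_thresholds(totals, controls, config.targets)
    except SurveyScreenError as exc:
        raise PipelineError(f"calibration: {exc}") from exc

    # --- stage: classification
    try:
        decisions = decide(matrix, thresholds)
        rules = []
        for spec in specs:
            if spec.evaluator == "consistency":
                rules = spec.params.get("rules", [])
                break
        by_id = scored_ds.by_id()
        for d in decisions:
            if d.bucket != REVIEW:
                continue
            rec = by_id[d.record_id]
            violations = consistency_violations(rec, rules)
            from .criteria import freetext_protective

            resolve_review(
                rec,
                d,
                freetext_ok=freetext_protective(rec, {}, ctx.text_counts),
                violations=violations,
                duplicate_flagged=rec.record_id in ctx.duplicate_members,
                params=config.review,
            )
        for d in decisions:
            if d.final == EXCLUDE:
                removal_log.append(("classification", d.record_id, "fraud_score"))
    except SurveyScreenError as exc:
        raise PipelineError(f"classification: {exc}") from exc

    # --- stage: reporting
    n_fraud_removed = sum(1 for d in decisions if d.final == EXCLUDE)
    accounting = account(n_started, n_cleaning_removed, n_fraud_removed)
    truth = {
        r.record_id: r.truth_archetype
        for r in scored_ds.records
        if r.truth_archetype is not None
    }
    metrics = pipeline_metrics(decisions, truth) if len(truth) == len(scored_ds) else None
    counts = bucket_counts(decisions)

    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        dec_path = out / "decisions.csv"
        write_decisions(scored_ds, decisions, dec_path)
        written.append(dec_path)

        if calib is not None:
            calib_path = out / "calibration.csv"
            write_calibration_report(calib, calib_path)
            written.append(calib_path)

        acc_path = out / "accounting.json"
        acc_path.write_text(json.dumps(accounting.__dict__, indent=2) + "\n")
        written.append(acc_path)

        review_ds = SurveyDataset(
            records=[by_id[d.record_id] for d in decisions if d.bucket == REVIEW],
            schema=scored_ds.schema,
            fraud_onset_date=scored_ds.fraud_onset_date,
        )
        review_path = out / "review_records.csv"
        write_responses(review_ds, review_path)
        written.append(review_path)

        log_path = out / "run.log"
        with open(log_path, "w", encoding="utf-8") as fh:
            _log_line(fh, "input", f"n_started={n_started}")
            for stage, rid, reason in removal_log:
                _log_line(fh, stage, f"removed\t{rid}\t{reason}")
            _log_line(
                fh,
                "thresholds",
                f"low_cut={thresholds.low_cut} high_cut={thresholds.high_cut}"
                f" degenerate={thresholds.degenerate}",
            )
            _log_line(
                fh,
                "report",
                f"buckets include={counts['INCLUDE']} exclude={counts['EXCLUDE']}"
                f" review={counts['REVIEW']}",
            )
        written.append(log_path)

    return RunResult(
        dataset=dataset,
        scored=scored_ds,
        decisions=decisions,
        thresholds=thresholds,
        controls=controls,
        accounting=accounting,
        metrics=metrics,
        removal_log=removal_log,
        bucket_counts=counts,
    )


def _validate(rec, schema):
    from .records import validate_record

    return validate_record(rec, schema)
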