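"""Shared fixtures: tiny hand-built datasets and a module-scoped cohort run."""

from __future__ import annotations

import warnings
from datetime import datetime, timedelta, timezone

import pytest

from surveyscreen.cohort import case1_like_config, generate_cohort
from surveyscreen.pipeline import PipelineConfig, run_pipeline
from surveyscreen.records import (
    QuestionSpec,
    RespondentRecord,
    SurveyDataset,
    SurveySchema,
)

UTC = timezone.utc
T0 = datetime(2020, 9, 1, 12, 0, tzinfo=UTC)


@pytest.fixture
def tiny_schema() -> SurveySchema:
    return SurveySchema(
        questions={
            "specialty": QuestionSpec(
                "specialty", "categorical",
                values=["family_medicine", "ob_gyn", "mfm_subspecialist",
                        "nurse_practitioner"],
            ),
            "college": QuestionSpec(
                "college", "categorical",
                values=["cfpc", "rcpsc", "nursing_college", "none"],
            ),
            "years_practice": QuestionSpec("years_practice", "numeric",
                                           minimum=0, maximum=60),
        },
        free_text=["comments"],
    )


def make_record(rid: str, *, minutes: float = 0.0, duration: float = 1200.0,
                **kwargs) -> RespondentRecord:
    """A valid baseline record submitted `minutes` after the fixture epoch."""
    submitted = T0 + timedelta(minutes=minutes)
    defaults = dict(
        record_id=rid,
        started_at=submitted - timedelta(seconds=duration),
        submitted_at=submitted,
        email=f"{rid}@example.org",
        name="Jane Smith",
        answers={"specialty": "family_medicine", "college": "cfpc",
                 "years_practice": 10},
        free_texts={"comments": "i also provide care at a second clinic"},
        remuneration_requested=True,
        captcha_score=0.9,
    )
    defaults.update(kwargs)
    return RespondentRecord(**defaults)


@pytest.fixture
def tiny_dataset(tiny_schema) -> SurveyDataset:
    records = [make_record(f"r{i}", minutes=10 * i) for i in range(3)]
    return SurveyDataset(records=records, schema=tiny_schema)


@pytest.fixture(scope="session")
def cohort_1500():
    """A mid-sized labelled cohort shared by signal-rate and evaluator tests."""
    return generate_cohort(case1_like_config(n_records=1500, seed=11))


@pytest.fixture(scope="session")
def case1_like_run():
    """One end-to-end pipeline run on the flagship preset (n=2000, fixed seed)."""
    config = PipelineConfig(cohort=case1_like_config(n_records=2000, seed=1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(config)
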