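"""Labelled synthetic respondent cohorts for exercising the screening pipeline.

Four respondent archetypes are emulated, mirroring the taxonomy of web-survey
fraud: *genuine* respondents; *duplicators* (eligible people re-submitting
under shared identifiers for extra remuneration); *misrepresenters* (humans
faking eligibility, betrayed by internally inconsistent answers); and *bots*
(short completion times, honeypot hits, low CAPTCHA scores, pattern emails,
burst submissions concentrated after a fraud-onset date).

The generator is a pure function of its configuration: identical configs give
byte-identical serialized datasets. Every behavioural probability is held in
:class:`CohortConfig`, so label-conditional signal rates in the output are
binomially distributed around the configured values.

The synthetic survey instrument is a small clinician questionnaire (specialty,
professional college, practice questions, five Likert items, two open-ended
fields) chosen so that "nonsensical combination" rules — e.g. a maternal-fetal
medicine subspecialist registered with a family-physician college — have
natural footing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Optional

import numpy as np

from .errors import ConfigError
from .records import (
    ARCHETYPES,
    IDENTIFIER_FIELDS,
    QuestionSpec,
    RespondentRecord,
    SurveyDataset,
    SurveySchema,
)
from .words import WORDS

_WORDLIST = sorted(WORDS)

_FIRST_NAMES = [
    "alice", "amira", "ben", "carmen", "chen", "claire", "daniel", "deepa",
    "elena", "fatima", "george", "hannah", "ivan", "jane", "jorge", "karen",
    "liam", "mei", "nadia", "omar", "priya", "quinn", "rosa", "sam",
    "tara", "victor", "wei", "yusuf",
]
_LAST_NAMES = [
    "anderson", "baker", "chow", "davis", "evans", "fischer", "garcia",
    "hassan", "ivanova", "jones", "khan", "lee", "martin", "nguyen",
    "osman", "patel", "quon", "rossi", "singh", "taylor", "umar",
    "vasquez", "wong", "young",
]
_INSTITUTIONAL_DOMAINS = [
    "ubc.ca", "monash.edu", "utoronto.ca", "unimelb.edu.au",
    "healthnetwork.ca", "stmaryshospital.org.au",
]
_GENERIC_DOMAINS = ["gmail.com", "outlook.com", "yahoo.com", "mail.com", "hotmail.com"]

# answer combinations a regulatory/medical context cannot produce
CONSISTENT_COLLEGE = {
    "family_medicine": "cfpc",
    "ob_gyn": "rcpsc",
    "mfm_subspecialist": "rcpsc",
    "nurse_practitioner": "nursing_college",
}
NONSENSE_PAIRS = [
    ("mfm_subspecialist", "cfpc"),
    ("nurse_practitioner", "rcpsc"),
]

_CANNED_PHRASES = [
    "very good survey thank you very much",
    "i like this survey it is good",
    "good survey good questions good study",
]

_SCALE_QIDS = ["scale_1", "scale_2", "scale_3", "scale_4", "scale_5"]


def default_schema() -> SurveySchema:
    """The synthetic clinician-survey instrument."""
    questions = {
        "specialty": QuestionSpec(
            "specialty", "categorical",
            values=["family_medicine", "ob_gyn", "mfm_subspecialist", "nurse_practitioner"],
        ),
        "college": QuestionSpec(
            "college", "categorical",
            values=["cfpc", "rcpsc", "nursing_college", "none"],
        ),
        "provides_procedural": QuestionSpec(
            "provides_procedural", "categorical", values=["yes", "no"]
        ),
        "years_practice": QuestionSpec("years_practice", "numeric", minimum=0, maximum=60),
        "gift_card_interest": QuestionSpec(
            "gift_card_interest", "categorical", values=["low", "high"]
        ),
        "engagement": QuestionSpec("engagement", "categorical", values=["normal", "low"]),
        "phn_provided": QuestionSpec("phn_provided", "categorical", values=["yes", "no"]),
    }
    for qid in _SCALE_QIDS:
        questions[qid] = QuestionSpec(qid, "numeric", minimum=1, maximum=5)
    return SurveySchema(questions=questions, free_text=["other_services", "comments"])


def _per_archetype(genuine, duplicator, misrepresenter, bot) -> dict[str, float]:
    return {
        "genuine": genuine,
        "duplicator": duplicator,
        "misrepresenter": misrepresenter,
        "bot": bot,
    }


@dataclass
class BatchConfig:
    """Bot burst-submission waves: n_waves runs of wave_size submissions whose
    consecutive gaps stay within window_s, sharing one email account."""

    n_waves: int = 2
    wave_size: int = 12
    window_s: float = 300.0


@dataclass
class CohortConfig:
    """All study conditions for one synthetic cohort.

    Defaults describe a Case-1-like survey: a roughly five-month recruitment
    window with fraud onset slightly past its midpoint, 55% genuine
    respondents, and strongly separable fraud signals (bots nearly always trip
    the honeypot, genuine respondents write concordant name-derived emails).
    """

    n_records: int = 1000
    prevalence: dict[str, float] = field(
        default_factory=lambda: _per_archetype(0.55, 0.08, 0.12, 0.25)
    )
    seed: int = 0

    window_start: datetime = datetime(2020, 7, 15, tzinfo=timezone.utc)
    window_days: float = 150.0
    fraud_onset_fraction: float = 0.55

    batch: BatchConfig = field(default_factory=BatchConfig)

    genuine_duration: tuple[float, float] = (900.0, 0.5)  # lognormal median_s, sigma
    bot_duration: tuple[float, float] = (30.0, 300.0)  # uniform bounds, seconds

    email_present_prob: dict[str, float] = field(
        default_factory=lambda: _per_archetype(0.9, 1.0, 1.0, 1.0)
    )
    email_concordance_prob: dict[str, float] = field(
        default_factory=lambda: _per_archetype(1.0, 1.0, 0.1, 0.0)
    )
    institutional_domain_prob: dict[str, float] = field(
        default_factory=lambda: _per_archetype(0.35, 0.0, 0.0, 0.0)
    )
    freetext_plausibility_prob: dict[str, float] = field(
        default_factory=lambda: _per_archetype(0.97, 0.9, 0.1, 0.02)
    )
    honeypot_prob: dict[str, float] = field(
        default_factory=lambda: _per_archetype(0.0, 0.0, 0.0, 0.95)
    )
    inconsistency_prob: dict[str, float] = field(
        default_factory=lambda: _per_archetype(0.01, 0.01, 0.9, 0.6)
    )
    remuneration_request_prob: dict[str, float] = field(
        default_factory=lambda: _per_archetype(0.6, 1.0, 0.98, 0.98)
    )
    captcha_beta: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "genuine": (9.0, 1.0),
            "duplicator": (9.0, 1.0),
            "misrepresenter": (8.0, 2.0),
            "bot": (1.0, 6.0),
        }
    )
    captcha_missing_prob: float = 0.05
    registry_verified_prob: dict[str, float] = field(
        default_factory=lambda: _per_archetype(0.8, 0.8, 0.02, 0.0)
    )
    multi_attempt_prob: dict[str, float] = field(
        default_factory=lambda: _per_archetype(0.03, 0.1, 0.6, 0.6)
    )
    gift_card_interest_prob: dict[str, float] = field(
        default_factory=lambda: _per_archetype(0.1, 0.5, 0.8, 0.8)
    )
    after_onset_prob: dict[str, float] = field(
        default_factory=lambda: _per_archetype(0.45, 0.5, 0.85, 0.95)
    )
    duplicate_multiplicity: dict[int, float] = field(
        default_factory=lambda: {2: 0.6, 3: 0.3, 4: 0.1}
    )
    straightline_prob: dict[str, float] = field(
        default_factory=lambda: _per_archetype(0.01, 0.01, 0.2, 0.8)
    )

    def validate(self) -> None:
        if self.n_records <= 0:
            raise ConfigError("n_records must be positive")
        total = sum(self.prevalence.values())
        if any(v < 0 for v in self.prevalence.values()):
            raise ConfigError("prevalence fractions must be non-negative")
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"prevalence must sum to 1 (got {total})")
        for name in self.prevalence:
            if name not in ARCHETYPES:
                raise ConfigError(f"unknown archetype {name!r}")
        if self.batch.wave_size < 2:
            raise ConfigError("batch wave_size must be >= 2")
        if not 0.0 <= self.fraud_onset_fraction <= 1.0:
            raise ConfigError("fraud_onset_fraction must be in [0, 1]")
        prob_maps = [
            self.email_present_prob, self.email_concordance_prob,
            self.institutional_domain_prob, self.freetext_plausibility_prob,
            self.honeypot_prob, self.inconsistency_prob,
            self.remuneration_request_prob, self.registry_verified_prob,
            self.multi_attempt_prob, self.gift_card_interest_prob,
            self.after_onset_prob, self.straightline_prob,
        ]
        for m in prob_maps:
            for v in m.values():
                if not 0.0 <= v <= 1.0:
                    raise ConfigError(f"probability {v} outside [0, 1]")


def case1_like_config(n_records: int = 2000, seed: int = 0) -> CohortConfig:
    """The default preset: 55% genuine / 45% fraudulent, separable signals."""
    return CohortConfig(n_records=n_records, seed=seed)


# ---------------------------------------------------------------------------
# generation helpers


def _person(rng: np.random.Generator) -> tuple[str, str]:
    first = _FIRST_NAMES[rng.integers(len(_FIRST_NAMES))]
    last = _LAST_NAMES[rng.integers(len(_LAST_NAMES))]
    return first, last


def _concordant_email(rng, first: str, last: str, institutional: bool) -> str:
    domain = (
        _INSTITUTIONAL_DOMAINS[rng.integers(len(_INSTITUTIONAL_DOMAINS))]
        if institutional
        else _GENERIC_DOMAINS[rng.integers(len(_GENERIC_DOMAINS))]
    )
    style = rng.integers(4)
    if style == 0:
        local = f"{first}.{last}"
    elif style == 1:
        local = f"{first[0]}{last}"
    elif style == 2:
        local = f"{first}{last[0]}"
    else:
        local = f"{first}.{last}{rng.integers(10, 100)}"
    return f"{local}@{domain}"


def _pattern_email(rng) -> str:
    """Suspicious local part: pure digits, or letter/digit alternation."""
    domain = _GENERIC_DOMAINS[rng.integers(len(_GENERIC_DOMAINS))]
    if rng.random() < 0.5:
        local = "".join(str(rng.integers(10)) for _ in range(rng.integers(8, 12)))
    else:
        k = int(rng.integers(4, 7))
        letters = "abcdefghijklmnopqrstuvwxyz"
        local = "".join(letters[rng.integers(26)] + str(rng.integers(10)) for _ in range(k))
    return f"{local}@{domain}"


def _plausible_text(rng) -> str:
    k = int(rng.integers(6, 15))
    return " ".join(_WORDLIST[rng.integers(len(_WORDLIST))] for _ in range(k))


def _junk_text(rng) -> str:
    kind = rng.random()
    if kind < 0.35:
        return ["ok", "none", "good", "n/a"][rng.integers(4)]
    if kind < 0.75:
        consonants = "bcdfghjklmnpqrstvwxz"
        toks = []
        for _ in range(int(rng.integers(3, 8))):
            t = "".join(consonants[rng.integers(20)] for _ in range(int(rng.integers(3, 7))))
            if rng.random() < 0.5:
                t += str(rng.integers(100))
            toks.append(t)
        return " ".join(toks)
    return _CANNED_PHRASES[rng.integers(len(_CANNED_PHRASES))]


def _answers(rng, archetype: str, config: CohortConfig) -> dict:
    inconsistent = rng.random() < config.inconsistency_prob[archetype]
    if inconsistent:
        specialty, college = NONSENSE_PAIRS[rng.integers(len(NONSENSE_PAIRS))]
    else:
        specialty = list(CONSISTENT_COLLEGE)[rng.integers(len(CONSISTENT_COLLEGE))]
        college = CONSISTENT_COLLEGE[specialty]
    answers = {
        "specialty": specialty,
        "college": college,
        "provides_procedural": "yes" if rng.random() < 0.4 else "no",
        "years_practice": int(rng.integers(1, 41)),
        "gift_card_interest": "high"
        if rng.random() < config.gift_card_interest_prob[archetype]
        else "low",
        "engagement": "low"
        if archetype != "genuine" and rng.random() < 0.7
        else ("low" if rng.random() < 0.1 else "normal"),
        "phn_provided": "yes"
        if rng.random() < (0.95 if archetype in ("genuine", "duplicator") else 0.3)
        else "no",
    }
    if rng.random() < config.straightline_prob[archetype]:
        v = int(rng.integers(1, 6))
        for qid in _SCALE_QIDS:
            answers[qid] = v
    else:
        for qid in _SCALE_QIDS:
            answers[qid] = int(rng.integers(1, 6))
    return answers


def _free_texts(rng, archetype: str, config: CohortConfig) -> tuple[dict[str, str], bool]:
    plausible = rng.random() < config.freetext_plausibility_prob[archetype]
    out: dict[str, str] = {}
    if plausible:
        out["comments"] = _plausible_text(rng)
        if rng.random() < 0.5:
            out["other_services"] = _plausible_text(rng)
    else:
        out["comments"] = _junk_text(rng)
        if rng.random() < 0.5:
            out["other_services"] = _junk_text(rng)
    return out, plausible


def _duration(rng, archetype: str, config: CohortConfig) -> float:
    if archetype == "bot":
        lo, hi = config.bot_duration
        return float(np.round(rng.uniform(lo, hi), 1))
    median, sigma = config.genuine_duration
    return float(np.round(rng.lognormal(math.log(median), sigma), 1))


def _submit_time(rng, archetype: str, config: CohortConfig,
                 start: datetime, onset: datetime, end: datetime) -> datetime:
    after = rng.random() < config.after_onset_prob[archetype]
    lo, hi = (onset, end) if after else (start, onset)
    span = max((hi - lo).total_seconds(), 1.0)
    return lo + timedelta(seconds=float(rng.uniform(0, span)))


def _unique(value: str, used: Optional[set[str]]) -> str:
    """Disambiguate an email local part so distinct persons never collide."""
    if used is None:
        return value
    candidate = value
    n = 2
    while candidate in used:
        local, _, domain = value.partition("@")
        candidate = f"{local}{n}@{domain}" if domain else f"{value}{n}"
        n += 1
    used.add(candidate)
    return candidate


def _base_record(rng, archetype: str, config: CohortConfig,
                 submitted: datetime,
                 used_emails: Optional[set[str]] = None,
                 used_phones: Optional[set[str]] = None) -> RespondentRecord:
    first, last = _person(rng)
    has_email = rng.random() < config.email_present_prob[archetype]
    concordant = rng.random() < config.email_concordance_prob[archetype]
    institutional = rng.random() < config.institutional_domain_prob[archetype]
    if not has_email:
        email = None
    elif concordant:
        email = _unique(_concordant_email(rng, first, last, institutional), used_emails)
    else:
        email = _unique(_pattern_email(rng), used_emails)

    free_texts, plausible = _free_texts(rng, archetype, config)
    answers = _answers(rng, archetype, config)
    duration = _duration(rng, archetype, config)

    a, b = config.captcha_beta[archetype]
    captcha = None if rng.random() < config.captcha_missing_prob else float(
        np.round(rng.beta(a, b), 3)
    )
    honeypot = ""
    if rng.random() < config.honeypot_prob[archetype]:
        honeypot = "".join("abcdefghijklmnopqrstuvwxyz"[rng.integers(26)] for _ in range(4))

    attempts = 1
    if rng.random() < config.multi_attempt_prob[archetype]:
        attempts += int(rng.integers(1, 4))

    registry: Optional[bool] = None
    if rng.random() < 0.85:
        registry = bool(rng.random() < config.registry_verified_prob[archetype])

    rec = RespondentRecord(
        record_id="tmp",
        started_at=submitted - timedelta(seconds=duration),
        submitted_at=submitted,
        email=email,
        name=f"{first.capitalize()} {last.capitalize()}",
        phone=_unique(f"04{rng.integers(10**7, 10**8)}", used_phones),
        postcode=f"{rng.integers(1000, 10000)}",
        ip=f"10.{rng.integers(256)}.{rng.integers(256)}.{rng.integers(256)}",
        answers=answers,
        free_texts=free_texts,
        remuneration_requested=bool(
            rng.random() < config.remuneration_request_prob[archetype]
        ),
        captcha_score=captcha,
        honeypot_value=honeypot,
        screening_attempts=attempts,
        registry_verified=registry,
        truth_archetype=archetype,
    )
    # stash the latent free-text label for generator-vs-evaluator validation
    rec.latent_freetext_plausible = plausible  # type: ignore[attr-defined]
    return rec


# ---------------------------------------------------------------------------
# public API


def generate_cohort(config: CohortConfig, schema: Optional[SurveySchema] = None) -> SurveyDataset:
    """Generate a labelled cohort; a pure function of the configuration."""
    config.validate()
    schema = schema or default_schema()

    seeds = np.random.SeedSequence(config.seed).spawn(5)
    rngs = {a: np.random.default_rng(s) for a, s in zip(ARCHETYPES, seeds[:4])}
    rng_assembly = np.random.default_rng(seeds[4])

    start = config.window_start
    end = start + timedelta(days=config.window_days)
    onset = start + timedelta(days=config.window_days * config.fraud_onset_fraction)

    probs = [config.prevalence.get(a, 0.0) for a in ARCHETYPES]
    counts = dict(zip(ARCHETYPES, rng_assembly.multinomial(config.n_records, probs)))

    records: list[RespondentRecord] = []
    used_emails: set[str] = set()
    used_phones: set[str] = set()

    # genuine and misrepresenting humans: independent submissions
    for archetype in ("genuine", "misrepresenter"):
        rng = rngs[archetype]
        for _ in range(counts[archetype]):
            submitted = _submit_time(rng, archetype, config, start, onset, end)
            records.append(
                _base_record(rng, archetype, config, submitted, used_emails, used_phones)
            )

    # duplicators: groups resubmitting under shared identifiers with the
    # same answers and free text (duplicate entries present as identical
    # responses, not as fresh interviews)
    rng = rngs["duplicator"]
    remaining = counts["duplicator"]
    mults = sorted(config.duplicate_multiplicity)
    mult_probs = [config.duplicate_multiplicity[m] for m in mults]
    while remaining > 0:
        m = int(rng.choice(mults, p=np.asarray(mult_probs) / sum(mult_probs)))
        m = min(m, remaining) if remaining >= 2 else remaining
        base_submit = _submit_time(rng, "duplicator", config, start, onset, end)
        base = _base_record(rng, "duplicator", config, base_submit,
                            used_emails, used_phones)
        group = [base]
        for _ in range(m - 1):
            gap_s = float(rng.uniform(3600, 72 * 3600))
            submitted = min(base_submit + timedelta(seconds=gap_s), end)
            sib = _base_record(rng, "duplicator", config, submitted)
            sib.email = base.email
            sib.phone = base.phone
            sib.name = base.name
            sib.answers = dict(base.answers)
            sib.free_texts = dict(base.free_texts)
            group.append(sib)
        if len(group) >= 2:
            # verbatim-copied text is no longer evidence of an independently
            # authored response, for the original as much as for the copies
            for member in group:
                member.latent_freetext_plausible = False  # type: ignore[attr-defined]
        records.extend(group)
        remaining -= m

    # bots: a portion arrives in same-email waves, the rest independently
    rng = rngs["bot"]
    n_bots = counts["bot"]
    n_waved = min(n_bots, config.batch.n_waves * config.batch.wave_size)
    wave_sizes = []
    left = n_waved
    for _ in range(config.batch.n_waves):
        take = min(config.batch.wave_size, left)
        if take >= 2:
            wave_sizes.append(take)
        left -= take
        if left <= 0:
            break
    placed = 0
    for wsize in wave_sizes:
        shared_email = _pattern_email(rng)
        shared_ip = f"10.{rng.integers(256)}.{rng.integers(256)}.{rng.integers(256)}"
        margin = timedelta(seconds=config.batch.window_s * wsize + 3600)
        span = max((end - margin - onset).total_seconds(), 1.0)
        t = onset + timedelta(seconds=float(rng.uniform(0, span)))
        for _ in range(wsize):
            rec = _base_record(rng, "bot", config, t, used_phones=used_phones)
            rec.email = shared_email
            rec.ip = shared_ip
            records.append(rec)
            placed += 1
            t = t + timedelta(seconds=float(rng.uniform(5, config.batch.window_s * 0.9)))
    for _ in range(n_bots - placed):
        submitted = _submit_time(rng, "bot", config, start, onset, end)
        records.append(
            _base_record(rng, "bot", config, submitted, used_emails, used_phones)
        )

    records.sort(key=lambda r: (r.submitted_at, r.truth_archetype, r.name, r.phone))
    for i, rec in enumerate(records, start=1):
        rec.record_id = f"r{i:05d}"

    return SurveyDataset(records=records, schema=schema, fraud_onset_date=onset)


def inject_fraud_wave(
    dataset: SurveyDataset,
    start: datetime,
    size: int,
    window_s: float = 300.0,
    shared_key: str = "email",
    seed: int = 0,
) -> SurveyDataset:
    """Append a burst of bot submissions sharing one identifier value.

    Consecutive submissions are spaced at most ``window_s`` seconds apart;
    the record count grows by exactly ``size``.
    """
    if size < 2:
        raise ConfigError("inject_fraud_wave: size must be >= 2")
    if shared_key not in IDENTIFIER_FIELDS:
        raise ConfigError(f"inject_fraud_wave: {shared_key!r} is not an identifier field")

    rng = np.random.default_rng(seed)
    config = CohortConfig(seed=seed)
    if shared_key == "email":
        shared_value = _pattern_email(rng)
    elif shared_key == "ip":
        shared_value = f"10.{rng.integers(256)}.{rng.integers(256)}.{rng.integers(256)}"
    else:
        shared_value = f"04{rng.integers(10**7, 10**8)}"

    new_records = list(dataset.records)
    t = start
    existing = set(dataset.ids())
    for i in range(size):
        rec = _base_record(rng, "bot", config, t)
        setattr(rec, shared_key, shared_value)
        rid = f"wave{i + 1:04d}"
        while rid in existing:
            rid = "x" + rid
        rec.record_id = rid
        existing.add(rid)
        new_records.append(rec)
        t = t + timedelta(seconds=float(rng.uniform(1, window_s)))

    return SurveyDataset(
        records=new_records,
        schema=dataset.schema,
        fraud_onset_date=dataset.fraud_onset_date,
        rejects=list(dataset.rejects),
    )
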