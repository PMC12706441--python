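"""Built-in criteria registries and control-designation rules.

Four presets encode the screening profile each case-study design calls for:

``case1``
    The point-scoring algorithm of an anonymized clinician survey: protective
    points for sensical free text, for not requesting remuneration and for
    pre-onset submission; suspicious points for nonsensical answer
    combinations, pattern emails, failed CAPTCHA, honeypot hits, very short
    completions and identifier-sharing duplicate entries. Point magnitudes
    follow the stronger-signal-more-points principle; exact published weights
    for such algorithms are study-specific, so these are this package's own
    defaults and every weight is configurable.

``case2``
    A verification-centred profile: name/email discordance, 5-minute minimum
    completion time, honeypot + CAPTCHA, same-account batch submission, and
    an external-registry verification flag.

``case3``
    Identifier-rich dedup profile: duplicates on email/phone/name/IP with
    retain-first, an 800 s completion-time floor, and the platform's
    ReCAPTCHA score.

``case4``
    The six suspicious-activity signals feeding the low/medium/high
    categorical risk profile.
"""

from __future__ import annotations

from .cohort import NONSENSE_PAIRS, _SCALE_QIDS
from .criteria import ConsistencyRule, CriterionSpec
from .errors import ConfigError

#: trusted domains for negative-control designation
NEGATIVE_EMAIL_DOMAINS = [
    "ubc.ca", "monash.edu", "utoronto.ca", "unimelb.edu.au",
    "healthnetwork.ca", "stmaryshospital.org.au",
]

#: local-part regexes for positive-control designation: mostly-digits locals
#: and strict letter/digit alternation
POSITIVE_EMAIL_PATTERNS = [
    r"^\d{6,}$",
    r"^(?:[a-z]\d){3,}[a-z]?$",
]


def default_consistency_rules() -> list[ConsistencyRule]:
    """Nonsensical specialty/college combinations of the synthetic instrument."""
    return [
        ConsistencyRule(
            name=f"{spec}_{college}",
            clauses=[("specialty", "eq", spec), ("college", "eq", college)],
        )
        for spec, college in NONSENSE_PAIRS
    ]


def registry(name: str) -> list[CriterionSpec]:
    """Return a built-in criteria registry by preset name."""
    rules = default_consistency_rules()
    if name == "case1":
        return [
            CriterionSpec("free_text_protective", "protective", -3, "freetext_protective"),
            CriterionSpec("no_remuneration_request", "protective", -1, "no_remuneration"),
            CriterionSpec("submitted_before_onset", "protective", -1, "onset",
                          {"side": "before"}),
            CriterionSpec("submitted_after_onset", "suspicious", +1, "onset",
                          {"side": "after"}),
            CriterionSpec("nonsensical_combination", "suspicious", +3, "consistency",
                          {"rules": rules}),
            CriterionSpec("email_pattern", "suspicious", +2, "email_pattern"),
            CriterionSpec("captcha_low", "suspicious", +2, "captcha", {"threshold": 0.5}),
            CriterionSpec("honeypot", "suspicious", +3, "honeypot"),
            CriterionSpec("short_completion", "suspicious", +2, "completion_time",
                          {"threshold_s": 300}),
            CriterionSpec("duplicate_entry", "suspicious", +6, "duplicate",
                          {"keys": ["email", "phone"], "scope": "any"}),
        ]
    if name == "case2":
        return [
            CriterionSpec("email_pattern", "suspicious", +2, "email_pattern"),
            CriterionSpec("short_completion", "suspicious", +2, "completion_time",
                          {"threshold_s": 300}),
            CriterionSpec("batch_same_account", "suspicious", +3, "batch",
                          {"window_s": 1800, "min_count": 3, "shared_key": "email"}),
            CriterionSpec("honeypot", "suspicious", +3, "honeypot"),
            CriterionSpec("captcha_low", "suspicious", +2, "captcha", {"threshold": 0.5}),
            CriterionSpec("registry_unverified", "suspicious", +2, "registry_unverified"),
            CriterionSpec("duplicate_entry", "suspicious", +3, "duplicate",
                          {"keys": ["email"], "scope": "any"}),
        ]
    if name == "case3":
        return [
            CriterionSpec("duplicate_entry", "suspicious", +3, "duplicate",
                          {"keys": ["email", "phone", "name", "ip"], "scope": "extras"}),
            CriterionSpec("short_completion", "suspicious", +3, "completion_time",
                          {"threshold_s": 800}),
            CriterionSpec("recaptcha_low", "suspicious", +2, "captcha", {"threshold": 0.5}),
        ]
    if name == "case4":
        return [
            CriterionSpec("multiple_attempts", "suspicious", +2, "screening_attempts"),
            CriterionSpec("no_phn", "suspicious", +1, "answer_equals",
                          {"field": "phn_provided", "value": "no"}),
            CriterionSpec("screening_inconsistency", "suspicious", +2, "consistency",
                          {"rules": rules}),
            CriterionSpec("straightline", "suspicious", +1, "straightline",
                          {"fields": list(_SCALE_QIDS)}),
            CriterionSpec("gift_card_interest", "suspicious", +2, "answer_equals",
                          {"field": "gift_card_interest", "value": "high"}),
            CriterionSpec("low_engagement", "suspicious", +1, "answer_equals",
                          {"field": "engagement", "value": "low"}),
        ]
    raise ConfigError(f"unknown registry preset {name!r}")
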