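"""Criterion evaluators against independent brute-force oracles."""

from __future__ import annotations

import itertools
import random
import re
from datetime import datetime, timezone

import pytest

from surveyscreen.cohort import case1_like_config, generate_cohort
from surveyscreen.criteria import (
    ConsistencyRule,
    CriterionSpec,
    batch_flag,
    bot_flags,
    build_context,
    completion_time_flag,
    consistency_violations,
    email_pattern_flag,
    evaluate_all,
    find_duplicates,
    freetext_protective,
    onset_flag,
    remuneration_flag,
    screening_attempts_flag,
)
from surveyscreen.errors import ConfigError
from surveyscreen.records import SurveyDataset

from conftest import make_record

UTC = timezone.utc


# ---------------------------------------------------------------------------
# duplicates


class TestFindDuplicates:
    def test_shared_email_groups_two_and_retains_earlier(self, tiny_schema):
        ds = SurveyDataset(
            records=[
                make_record("a", minutes=0, email="a@x.org"),
                make_record("b", minutes=10, email="A@X.ORG "),  # normalized match
                make_record("c", minutes=20, email="c@x.org"),
            ],
            schema=tiny_schema,
        )
        groups = find_duplicates(ds, ["email"])
        assert len(groups) == 1
        assert groups[0].record_ids == ["a", "b"]
        assert groups[0].retained == "a"

    def test_all_distinct_identifiers_give_zero_groups(self, tiny_dataset):
        assert find_duplicates(tiny_dataset, ["email", "phone"]) == []

    def test_non_identifier_key_rejected(self, tiny_dataset):
        with pytest.raises(ConfigError, match="identifier"):
            find_duplicates(tiny_dataset, ["answers"])

    def test_matches_pairwise_oracle_on_random_data(self, tiny_schema):
        """The union of flagged duplicates equals an O(n^2) pairwise sweep."""
        rng = random.Random(13)
        records = []
        for i in range(150):
            records.append(
                make_record(
                    f"r{i:03d}",
                    minutes=rng.uniform(0, 5000),
                    email=f"u{rng.randint(1, 60)}@x.org" if rng.random() < 0.9 else None,
                    phone=f"04{rng.randint(100, 160)}" if rng.random() < 0.8 else None,
                )
            )
        ds = SurveyDataset(records=records, schema=tiny_schema)
        keys = ["email", "phone"]
        groups = find_duplicates(ds, keys)

        # oracle: a record is a duplicate-group member iff some other record
        # shares a normalized identifier value on any key
        def norm(v):
            return v.strip().lower() if v else None

        members = set()
        for a, b in itertools.combinations(records, 2):
            if any(
                norm(a.identifier(k)) is not None
                and norm(a.identifier(k)) == norm(b.identifier(k))
                for k in keys
            ):
                members.update({a.record_id, b.record_id})
        flagged = {rid for g in groups for rid in g.record_ids}
        assert flagged == members
        # exactly one retained record per group, the earliest started
        for g in groups:
            recs = [r for r in records if r.record_id in g.record_ids]
            earliest = min(recs, key=lambda r: (r.started_at, r.record_id))
            assert g.retained == earliest.record_id


# ---------------------------------------------------------------------------
# email pattern


def _email_oracle(email, name, digit_frac=0.5, alt_runs=3):
    """Literal restatement of the rule, independent of the implementation."""
    if email is None:
        return False
    m = re.fullmatch(r"([^@]+)@([^@]+)", email)
    if not m:
        return True
    local = "".join(ch for ch in m.group(1).lower() if ch.isalnum())
    if not local:
        return True
    if sum(c.isdigit() for c in local) / len(local) > digit_frac:
        return True
    toks = re.findall(r"[a-z]+", (name or "").lower())
    subs = {t[i : i + 3] for t in toks if len(t) >= 3 for i in range(len(t) - 2)}
    ini = "".join(t[0] for t in toks)
    if len(ini) >= 3:
        subs |= {ini[i : i + 3] for i in range(len(ini) - 2)}
    if any(s in m.group(1).lower() for s in subs):
        return False
    transitions = sum(
        1 for a, b in zip(local, local[1:]) if a.isdigit() != b.isdigit()
    )
    return transitions >= alt_runs


class TestEmailPattern:
    @pytest.mark.parametrize(
        "email,name,expected",
        [
            ("jane.smith@hospital.ca", "Jane Smith", False),
            ("9823471265@mail.com", "Any Name", True),
            ("q1w2e3r4@mail.com", "Jane Smith", True),
            ("jsmith@clinic.org", "Jane Smith", False),
            ("not-an-email", "Jane Smith", True),
            (None, "Jane Smith", False),
        ],
    )
    def test_stated_examples(self, email, name, expected):
        assert email_pattern_flag(email, name) is expected

    def test_matches_rule_oracle_on_random_pairs(self):
        rng = random.Random(29)
        firsts = ["jane", "omar", "mei", "carlos", "priya"]
        lasts = ["smith", "khan", "wong", "garcia", "patel"]
        alphabet = "abcdefghijklmnopqrstuvwxyz0123456789."
        for _ in range(500):
            name = f"{rng.choice(firsts).title()} {rng.choice(lasts).title()}"
            style = rng.random()
            if style < 0.3:
                local = rng.choice(firsts) + "." + rng.choice(lasts)
            elif style < 0.5:
                local = "".join(rng.choice("0123456789") for _ in range(rng.randint(4, 12)))
            elif style < 0.7:
                local = "".join(
                    rng.choice("abcdef") + rng.choice("0123456789")
                    for _ in range(rng.randint(2, 6))
                )
            else:
                local = "".join(rng.choice(alphabet) for _ in range(rng.randint(1, 14)))
            email = f"{local}@mail.com"
            assert email_pattern_flag(email, name) == _email_oracle(email, name), (
                email,
                name,
            )


# ---------------------------------------------------------------------------
# completion time / bot flags / simple flags


class TestSimpleFlags:
    @pytest.mark.parametrize(
        "duration,threshold,expected",
        [(799, 800, True), (800, 800, False), (299, 300, True), (300, 300, False)],
    )
    def test_completion_time_is_strict(self, duration, threshold, expected):
        assert completion_time_flag(duration, threshold) is expected

    def test_bot_flags(self):
        clean = make_record("a", honeypot_value="", captcha_score=0.9)
        assert bot_flags(clean) == {"honeypot_fired": False, "captcha_fired": False}
        hp = make_record("b", honeypot_value="abc", captcha_score=0.9)
        assert bot_flags(hp)["honeypot_fired"] is True
        low = make_record("c", captcha_score=0.49)
        assert bot_flags(low, 0.5)["captcha_fired"] is True
        boundary = make_record("d", captcha_score=0.5)
        assert bot_flags(boundary, 0.5)["captcha_fired"] is False

    def test_remuneration_direction(self):
        assert remuneration_flag(make_record("a", remuneration_requested=False)) == "protective"
        assert remuneration_flag(make_record("b", remuneration_requested=True)) == "neutral"
        # a cohort where everyone requests remuneration earns no protective
        # points from this criterion
        recs = [make_record(f"r{i}", remuneration_requested=True) for i in range(20)]
        assert sum(remuneration_flag(r) == "protective" for r in recs) == 0

    def test_onset_direction_and_boundary(self):
        onset = datetime(2020, 10, 6, tzinfo=UTC)
        before = make_record("a", submitted_at=datetime(2020, 9, 1, tzinfo=UTC),
                             started_at=None)
        assert onset_flag(before, onset) == "protective"
        at = make_record("b", submitted_at=onset, started_at=None)
        assert onset_flag(at, onset) == "suspicious"
        assert onset_flag(before, None) is None

    @pytest.mark.parametrize("attempts,expected", [(0, False), (1, False), (2, True)])
    def test_screening_attempts(self, attempts, expected):
        rec = make_record("a", screening_attempts=attempts)
        assert screening_attempts_flag(rec) is expected


# ---------------------------------------------------------------------------
# batches


class TestBatchFlag:
    def test_five_close_records_all_flagged(self, tiny_schema):
        ds = SurveyDataset(
            records=[make_record(f"r{i}", minutes=i) for i in range(5)],
            schema=tiny_schema,
        )
        assert batch_flag(ds, window_s=120, min_count=3) == {f"r{i}" for i in range(5)}

    def test_wide_gaps_give_empty_set(self, tiny_schema):
        ds = SurveyDataset(
            records=[make_record(f"r{i}", minutes=60 * i) for i in range(5)],
            schema=tiny_schema,
        )
        assert batch_flag(ds, window_s=120, min_count=2) == set()

    def test_matches_exhaustive_run_enumeration(self, tiny_schema):
        """Flagged set equals brute-force enumeration of qualifying runs on
        randomized timestamps (n <= 200)."""
        rng = random.Random(31)
        for trial in range(5):
            n = rng.randint(20, 200)
            records = [
                make_record(f"r{i:03d}", minutes=rng.uniform(0, n / 2))
                for i in range(n)
            ]
            ds = SurveyDataset(records=records, schema=tiny_schema)
            window_s, min_count = 90.0, rng.randint(2, 4)
            got = batch_flag(ds, window_s, min_count)

            ordered = sorted(records, key=lambda r: (r.submitted_at, r.record_id))
            expect = set()
            for i in range(len(ordered)):
                for j in range(i + min_count - 1, len(ordered)):
                    gaps_ok = all(
                        (ordered[k + 1].submitted_at - ordered[k].submitted_at)
                        .total_seconds() <= window_s
                        for k in range(i, j)
                    )
                    if gaps_ok:
                        expect.update(r.record_id for r in ordered[i : j + 1])
                    else:
                        break
            assert got == expect


# ---------------------------------------------------------------------------
# consistency rules


MFM_RULE = ConsistencyRule(
    name="mfm_cfpc",
    clauses=[("specialty", "eq", "mfm_subspecialist"), ("college", "eq", "cfpc")],
)


class TestConsistency:
    def test_subspecialist_with_family_college_is_nonsensical(self):
        rec = make_record("a", answers={"specialty": "mfm_subspecialist",
                                        "college": "cfpc", "years_practice": 10})
        assert consistency_violations(rec, [MFM_RULE]) == ["mfm_cfpc"]

    def test_empty_rule_list(self):
        assert consistency_violations(make_record("a"), []) == []

    def test_matches_predicate_oracle_on_random_records(self):
        rng = random.Random(17)
        specialties = ["family_medicine", "ob_gyn", "mfm_subspecialist",
                       "nurse_practitioner"]
        colleges = ["cfpc", "rcpsc", "nursing_college", "none"]
        rules = [
            MFM_RULE,
            ConsistencyRule("np_rcpsc", [("specialty", "eq", "nurse_practitioner"),
                                         ("college", "eq", "rcpsc")]),
            ConsistencyRule("young_veteran", [("years_practice", "gt", 35),
                                              ("specialty", "eq", "nurse_practitioner")]),
        ]
        for _ in range(300):
            answers = {
                "specialty": rng.choice(specialties),
                "college": rng.choice(colleges),
                "years_practice": rng.randint(0, 45),
            }
            rec = make_record("a", answers=answers)
            fired = consistency_violations(rec, rules)
            expect = []
            if answers["specialty"] == "mfm_subspecialist" and answers["college"] == "cfpc":
                expect.append("mfm_cfpc")
            if answers["specialty"] == "nurse_practitioner" and answers["college"] == "rcpsc":
                expect.append("np_rcpsc")
            if answers["years_practice"] > 35 and answers["specialty"] == "nurse_practitioner":
                expect.append("young_veteran")
            assert fired == expect


# ---------------------------------------------------------------------------
# free text


class TestFreetextProtective:
    def test_sensical_explanation_is_protective(self):
        rec = make_record(
            "a",
            free_texts={"comments": "I also provide procedural abortion at a second clinic"},
        )
        assert freetext_protective(rec) is True

    def test_empty_free_texts_not_protective(self):
        rec = make_record("a", free_texts={})
        assert freetext_protective(rec) is False

    def test_garbage_tokens_not_protective(self):
        rec = make_record("a", free_texts={"comments": "xk7 qwzt 99a bbfg zzt"})
        assert freetext_protective(rec) is False

    def test_verbatim_cross_record_duplication_disqualifies(self):
        text = "i provide care at a rural clinic most days"
        counts = {("comments", text): 2}
        rec = make_record("a", free_texts={"comments": text})
        assert freetext_protective(rec, text_counts=counts) is False
        assert freetext_protective(rec, text_counts={("comments", text): 1}) is True

    def test_agreement_with_generator_latent_label(self, cohort_1500):
        """On seeded cohorts, the evaluator recovers the generator's latent
        plausibility label in >= 95% of records."""
        counts: dict = {}
        for rec in cohort_1500.records:
            for qid, text in rec.free_texts.items():
                counts[(qid, text.strip())] = counts.get((qid, text.strip()), 0) + 1
        agree = sum(
            freetext_protective(rec, text_counts=counts) == rec.latent_freetext_plausible
            for rec in cohort_1500.records
        )
        assert agree / len(cohort_1500) >= 0.95


# ---------------------------------------------------------------------------
# matrix evaluation


def _registry():
    return [
        CriterionSpec("honeypot", "suspicious", +3, "honeypot"),
        CriterionSpec("short", "suspicious", +2, "completion_time", {"threshold_s": 300}),
        CriterionSpec("no_remun", "protective", -1, "no_remuneration"),
    ]


class TestEvaluateAll:
    def test_matrix_shape_is_records_by_criteria(self, tiny_dataset):
        matrix = evaluate_all(tiny_dataset, _registry())
        assert matrix.fired.shape == (3, 3)
        assert len(matrix.results()) == 9

    def test_single_record_single_criterion(self, tiny_schema):
        ds = SurveyDataset(records=[make_record("a")], schema=tiny_schema)
        matrix = evaluate_all(ds, [_registry()[0]])
        assert matrix.fired.shape == (1, 1)

    def test_totals_equal_independent_summation(self, cohort_1500):
        registry = _registry()
        matrix = evaluate_all(cohort_1500, registry)
        totals = matrix.totals()
        ctx = build_context(cohort_1500, registry)
        for rec in cohort_1500.records[:200]:
            expect = 0.0
            if rec.honeypot_value:
                expect += 3
            if rec.duration_s is not None and rec.duration_s < 300:
                expect += 2
            if rec.remuneration_requested is False:
                expect -= 1
            assert totals[rec.record_id] == expect

    def test_monotonicity_of_added_criteria(self, cohort_1500):
        """Adding a suspicious criterion never lowers any total; adding a
        protective one never raises any."""
        base = _registry()[:1]
        matrix0 = evaluate_all(cohort_1500, base)
        with_susp = evaluate_all(cohort_1500, base + [_registry()[1]])
        with_prot = evaluate_all(cohort_1500, base + [_registry()[2]])
        assert (with_susp.totals() >= matrix0.totals()).all()
        assert (with_prot.totals() <= matrix0.totals()).all()

    def test_repeated_evaluation_is_identical(self, tiny_dataset):
        a = evaluate_all(tiny_dataset, _registry()).fired
        b = evaluate_all(tiny_dataset, _registry()).fired
        assert a.equals(b)

    def test_separable_honeypot_is_perfect(self):
        """With bots always tripping the honeypot and humans never, the
        honeypot criterion alone is a perfect classifier."""
        config = case1_like_config(400, seed=6)
        config.honeypot_prob["bot"] = 1.0
        ds = generate_cohort(config)
        matrix = evaluate_all(ds, [_registry()[0]])
        for rec in ds.records:
            fired = bool(matrix.fired.loc[rec.record_id, "honeypot"])
            if rec.truth_archetype == "bot":
                assert fired
            elif rec.truth_archetype == "genuine":
                assert not fired

    def test_sign_convention_enforced(self):
        with pytest.raises(ConfigError, match="protective"):
            CriterionSpec("bad", "protective", +2, "honeypot")
        with pytest.raises(ConfigError, match="unknown evaluator"):
            CriterionSpec("bad", "suspicious", +2, "nope")
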