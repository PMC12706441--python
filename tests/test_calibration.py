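"""Control designation, per-criterion 2x2 performance, cut-point selection."""

from __future__ import annotations

import random

import numpy as np
import pytest

from surveyscreen.calibration import (
    CalibrationTargets,
    ControlLabels,
    criterion_performance,
    designate_controls,
    select_thresholds,
    truth_controls,
)
from surveyscreen.errors import CalibrationError
from surveyscreen.records import SurveyDataset

from conftest import make_record

TRUSTED = ["ubc.ca", "monash.edu"]
PATTERNS = [r"^\d{6,}$", r"^(?:[a-z]\d){3,}[a-z]?$"]


class TestDesignateControls:
    def _dataset(self, tiny_schema, emails):
        records = [
            make_record(f"r{i}", minutes=i, email=e) for i, e in enumerate(emails)
        ]
        return SurveyDataset(records=records, schema=tiny_schema)

    def test_trusted_domain_is_negative(self, tiny_schema):
        ds = self._dataset(tiny_schema, ["a@ubc.ca"])
        labels = designate_controls(ds, TRUSTED, PATTERNS)
        assert labels.labels == {"r0": "negative"}

    def test_pattern_local_part_is_positive(self, tiny_schema):
        ds = self._dataset(tiny_schema, ["q1w2e3r4@mail.com", "88123456@mail.com"])
        labels = designate_controls(ds, TRUSTED, PATTERNS)
        assert labels.positives == {"r0", "r1"}

    def test_conflict_is_unlabeled_with_warning(self, tiny_schema):
        ds = self._dataset(tiny_schema, ["123456789@ubc.ca"])
        with pytest.warns(UserWarning, match="both"):
            labels = designate_controls(ds, TRUSTED, PATTERNS)
        assert labels.labels == {}
        assert labels.warnings

    def test_plain_generic_email_stays_unlabeled(self, tiny_schema):
        ds = self._dataset(tiny_schema, ["jane.smith@gmail.com"])
        labels = designate_controls(ds, TRUSTED, PATTERNS)
        assert labels.labels == {}

    def test_empty_rules_are_an_error(self, tiny_schema):
        ds = self._dataset(tiny_schema, ["a@ubc.ca"])
        with pytest.raises(CalibrationError):
            designate_controls(ds, [], PATTERNS)
        with pytest.raises(CalibrationError):
            designate_controls(ds, TRUSTED, [])


def _labels(pos, neg):
    labels = ControlLabels()
    labels.labels.update({r: "positive" for r in pos})
    labels.labels.update({r: "negative" for r in neg})
    return labels


class TestCriterionPerformance:
    def test_perfect_criterion(self):
        labels = _labels([f"p{i}" for i in range(10)], [f"n{i}" for i in range(10)])
        fired = {f"p{i}": True for i in range(10)} | {f"n{i}": False for i in range(10)}
        row = criterion_performance(fired, "suspicious", labels)
        assert (row.tp, row.fp, row.tn, row.fn) == (10, 0, 10, 0)
        assert row.sensitivity == 1.0 and row.specificity == 1.0

    def test_51_of_55_positives_gives_92_7_percent_sensitivity(self):
        labels = _labels([f"p{i}" for i in range(55)], ["n0"])
        fired = {f"p{i}": i < 51 for i in range(55)} | {"n0": False}
        row = criterion_performance(fired, "suspicious", labels)
        assert (row.tp, row.fn) == (51, 4)
        assert row.sensitivity == pytest.approx(0.927, abs=5e-4)

    def test_protective_criterion_polarity_is_inverted(self):
        # a protective criterion firing on a negative control is a true negative
        labels = _labels(["p0"], ["n0"])
        row = criterion_performance({"p0": False, "n0": True}, "protective", labels)
        assert (row.tp, row.tn, row.fp, row.fn) == (1, 1, 0, 0)

    def test_missing_control_class_errors_naming_it(self):
        with pytest.raises(CalibrationError, match="negative"):
            criterion_performance({"p0": True}, "suspicious", _labels(["p0"], []))
        with pytest.raises(CalibrationError, match="positive"):
            criterion_performance({"n0": True}, "suspicious", _labels([], ["n0"]))

    def test_matches_brute_force_tabulation_on_random_instances(self):
        rng = random.Random(41)
        for _ in range(200):
            n = rng.randint(2, 40)
            ids = [f"r{i}" for i in range(n)]
            lab = {r: rng.choice(["positive", "negative"]) for r in ids}
            if len(set(lab.values())) < 2:
                continue
            fired = {r: rng.random() < 0.5 for r in ids}
            direction = rng.choice(["suspicious", "protective"])
            labels = ControlLabels(labels=lab)
            row = criterion_performance(fired, direction, labels)
            tp = fp = tn = fn = 0
            for r in ids:
                pred = fired[r] if direction == "suspicious" else not fired[r]
                if lab[r] == "positive":
                    tp, fn = tp + pred, fn + (not pred)
                else:
                    fp, tn = fp + pred, tn + (not pred)
            assert (row.tp, row.fp, row.tn, row.fn) == (tp, fp, tn, fn)

    def test_order_invariance(self):
        labels = _labels(["p0", "p1"], ["n0", "n1"])
        fired = {"p0": True, "p1": False, "n0": False, "n1": True}
        a = criterion_performance(fired, "suspicious", labels)
        reordered = ControlLabels(
            labels=dict(reversed(list(labels.labels.items())))
        )
        b = criterion_performance(fired, "suspicious", reordered)
        assert (a.tp, a.fp, a.tn, a.fn) == (b.tp, b.fp, b.tn, b.fn)


class TestSelectThresholds:
    def test_separable_controls_classify_perfectly(self):
        labels = _labels([f"p{i}" for i in range(20)], [f"n{i}" for i in range(20)])
        scores = {f"p{i}": 5.0 for i in range(20)} | {f"n{i}": -5.0 for i in range(20)}
        thr = select_thresholds(scores, labels, CalibrationTargets(0.95, 0.95))
        assert thr.low_cut < thr.high_cut
        assert all(scores[p] >= thr.high_cut for p in labels.positives)
        assert all(scores[n] <= thr.low_cut for n in labels.negatives)

    def test_single_shared_score_is_degenerate(self):
        labels = _labels(["p0", "p1"], ["n0", "n1"])
        scores = {r: 2.0 for r in labels.labels}
        with pytest.warns(UserWarning):
            thr = select_thresholds(scores, labels)
        assert thr.degenerate
        assert thr.low_cut == thr.high_cut == 2.0

    def test_constraints_verified_by_exhaustive_scan(self):
        """Non-degenerate cuts must be exactly the optimum an exhaustive scan
        over candidate cut values finds."""
        rng = np.random.default_rng(23)
        checked = 0
        for _ in range(200):
            n_pos, n_neg = int(rng.integers(3, 40)), int(rng.integers(3, 40))
            pos = rng.integers(-2, 12, n_pos).astype(float)
            neg = rng.integers(-10, 4, n_neg).astype(float)
            labels = _labels(
                [f"p{i}" for i in range(n_pos)], [f"n{i}" for i in range(n_neg)]
            )
            scores = {f"p{i}": pos[i] for i in range(n_pos)}
            scores |= {f"n{i}": neg[i] for i in range(n_neg)}
            targets = CalibrationTargets(
                min_specificity=float(rng.uniform(0.6, 1.0)),
                min_sensitivity=float(rng.uniform(0.6, 1.0)),
            )
            import warnings as w

            with w.catch_warnings():
                w.simplefilter("ignore")
                thr = select_thresholds(scores, labels, targets)
            if thr.degenerate:
                continue
            checked += 1
            candidates = np.unique(np.concatenate([pos, neg]))
            ok_high = [
                c for c in candidates
                if np.mean(neg >= c) <= 1 - targets.min_specificity
            ]
            ok_low = [
                c for c in candidates
                if np.mean(pos <= c) <= 1 - targets.min_sensitivity
            ]
            assert thr.high_cut == (min(ok_high) if ok_high else candidates[-1] + 1)
            assert thr.low_cut == (max(ok_low) if ok_low else candidates[0] - 1)
            # and the stated fraction constraints hold
            assert np.mean(neg >= thr.high_cut) <= 1 - targets.min_specificity
            assert np.mean(pos <= thr.low_cut) <= 1 - targets.min_sensitivity
        assert checked > 100

    def test_raising_min_specificity_never_lowers_high_cut(self):
        rng = np.random.default_rng(5)
        pos = rng.integers(0, 10, 30).astype(float)
        neg = rng.integers(-8, 5, 30).astype(float)
        labels = _labels([f"p{i}" for i in range(30)], [f"n{i}" for i in range(30)])
        scores = {f"p{i}": pos[i] for i in range(30)}
        scores |= {f"n{i}": neg[i] for i in range(30)}
        import warnings as w

        cuts = []
        for spec_target in (0.7, 0.8, 0.9, 0.95, 0.99):
            with w.catch_warnings():
                w.simplefilter("ignore")
                thr = select_thresholds(
                    scores, labels, CalibrationTargets(spec_target, 0.5)
                )
            cuts.append(thr.high_cut)
        assert cuts == sorted(cuts)

    def test_no_controls_is_an_error(self):
        with pytest.raises(CalibrationError):
            select_thresholds({}, ControlLabels())


class TestTruthControls:
    def test_label_source_equivalence(self, cohort_1500):
        """Treating truth archetypes as controls reproduces the direct
        fraud/genuine partition of the cohort."""
        labels = truth_controls(cohort_1500)
        for rec in cohort_1500.records:
            expected = "negative" if rec.truth_archetype == "genuine" else "positive"
            assert labels.labels[rec.record_id] == expected
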