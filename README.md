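# surveyscreen

Fraud screening for web-based survey datasets.

Anonymous web surveys that recruit through a generic link and offer
remuneration attract fraudulent responses — bots, people misrepresenting
their eligibility, and eligible respondents duplicating submissions for
extra incentives. Research teams routinely have to remove 15–45% of
collected responses before analysis. `surveyscreen` packages the screening
methodology such teams use into a reusable, testable pipeline for
biostatisticians and survey methodologists:

* a **criteria engine** that evaluates protective and suspicious signals on
  each response — sensical free text, nonsensical answer combinations
  (e.g. a maternal-fetal medicine subspecialist registered with a
  family-physician college), pattern-based email addresses, honeypot and
  CAPTCHA signals, sub-threshold completion times, batch submissions from a
  shared account, duplicate identifiers, multiple screening attempts — and
  awards signed *fraud points* (negative = protective, positive =
  suspicious, larger magnitude = stronger assumed predictive value);
* **control-based calibration**: respondents with institutional email
  domains are designated negative controls, those with highly suspicious
  pattern emails positive controls; per-criterion sensitivity
  Se = TP/(TP+FN) and specificity Sp = TN/(TN+FP) are tabulated on the
  controls, and two score cut points are selected so that the include band
  retains at most 1−Se_min of positive-control mass and the exclude band
  admits at most 1−Sp_min of negative-control mass;
* **three-way triage** of total scores into INCLUDE / REVIEW / EXCLUDE with
  automated review resolution (protective free text rescues, a fired
  consistency rule or duplicate flag condemns), plus a categorical
  low/medium/high risk profile over six suspicious-activity signals with a
  with/without-medium sensitivity split;
* **dataset accounting** with the two-step convention
  `started − cleaning_removed = scored` and
  `scored − fraud_removed = included`, all percentages recomputed half-up
  from counts;
* a **synthetic respondent generator** producing labelled cohorts of four
  archetypes (genuine, duplicator, misrepresenter, bot) with configurable
  prevalence, fraud-onset date, batch waves, identifier realism and
  free-text plausibility, so every stage is testable without any real
  survey data.

## Worked example

Run the whole pipeline on the flagship synthetic preset (2000 respondents,
55% genuine / 45% fraudulent, separable signals, fixed seed):

```sh
cat > run.yaml <<EOF
cohort: {preset: case1_like, n: 2000, seed: 1}
registry: case1
EOF
surveyscreen run --config run.yaml --out-dir out
```

prints

```json
{
  "n_started": 2000,
  "n_cleaning_removed": 125,
  "n_scored": 1875,
  "n_fraud_removed": 787,
  "n_included": 1088,
  "buckets": {"INCLUDE": 1088, "EXCLUDE": 787, "REVIEW": 0},
  "low_cut": 2.0,
  "high_cut": 2.0,
  "sensitivity": 0.9874371859296482,
  "specificity": 0.9990732159406858
}
```

Reading this: of 2000 started responses, 125 were removed during cleaning
(duplicate identifiers, invalid fields); the remaining 1875 were scored
against the `case1` criteria registry; calibration on email-rule controls
selected the score cut points (here both collapsed to +2, leaving an empty
review band); 787 responses at or above the exclude cut were removed as
fraudulent, leaving 1088 for analysis. Because the cohort is synthetic, the
final decisions can be compared with the hidden truth labels: 98.7% of
fraudulent records were excluded (sensitivity) while 99.9% of genuine
records were retained (specificity). `out/` contains the decisions table,
the per-criterion calibration report, the accounting summary, the records
that would go to manual review, and a log naming every removed record with
its reason code.

The accounting arithmetic is available standalone — for a survey with 1050
respondents, 135 cleaning removals and 415 fraud-score removals:

```sh
surveyscreen report --started 1050 --cleaning-removed 135 --fraud-removed 415
```

```json
{
  "n_started": 1050,
  "n_cleaning_removed": 135,
  "n_scored": 915,
  "n_fraud_removed": 415,
  "n_included": 500,
  "pct_fraud_of_scored": 45.4,
  "pct_included_of_started": 47.6
}
```

The same operations are importable (`surveyscreen.account`,
`surveyscreen.evaluate_all`, `surveyscreen.select_thresholds`,
`surveyscreen.run_pipeline`, ...); see `docs/methods.md` for the model and
parameter choices.

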