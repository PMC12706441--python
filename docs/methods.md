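# Methods

This note documents the screening model implemented by `surveyscreen`, the
parameters that matter, what the synthetic cohort generator does and does
not emulate, and the numerical conventions adopted where the underlying
methodology leaves choices open.

## The screening model

Fraud screening is organised as three stages, by analogy with disease
prevention: *primary* prevention is design-time deterrence (CAPTCHA,
honeypot fields, eligibility screens — these appear here as record fields
the platform provides); *secondary* prevention is in-flight monitoring that
establishes a **fraud-onset date**; *tertiary* prevention — the part this
package automates — is the post-hoc identification and removal of
fraudulent records.

Tertiary screening is a weighted additive score. Each criterion *c* is a
pure predicate over a record (and, for duplicate/batch/free-text-repetition
checks, over the dataset as collected) with a signed weight
*w_c*: negative for protective criteria, positive for suspicious ones,
larger magnitude for stronger assumed predictive value. A respondent's
total score is `S = Σ_c w_c · 1[c fires]`. No single criterion includes or
excludes a respondent; only the combination does.

Records with `S ≤ low_cut` are included, `S ≥ high_cut` excluded, and the
midrange sent to review. Review resolution automates the manual pass:
protective free text with no consistency violations rescues a record;
a fired consistency rule or a duplicate-identifier flag condemns it;
anything else falls to a configurable default, which is **exclude** —
conservative toward data integrity, accepting that some valid respondents
may be dropped.

### Criteria and their parameters

| criterion | direction | default params | notes |
|---|---|---|---|
| free-text plausibility | protective | ≥1 field, ≥5 tokens, dictionary ratio ≥0.6, not duplicated verbatim across records | proxy for "sensical free text"; see below |
| no remuneration request | protective | — | not asking for payment is protective; asking is neutral, not suspicious |
| submitted before onset | protective | — | requires a fraud-onset date |
| submitted on/after onset | suspicious | — | the onset instant itself counts as on/after |
| nonsensical answer combination | suspicious | declarative AND-clause rules | e.g. subspecialist + wrong college |
| email pattern | suspicious | digit fraction >0.5, or no ≥3-char overlap with name tokens/initials together with ≥3 digit/letter run alternations | malformed addresses fire outright |
| CAPTCHA score low | suspicious | threshold 0.5, strict `<` | score absent ⇒ inert |
| honeypot non-empty | suspicious | — | any non-empty value |
| short completion | suspicious | threshold 300 s (case1/2 profiles) or 800 s (case3 profile), strict `<` | thresholds mirror the 5-minute and ~13-minute floors that discriminate well between human and bot completions |
| duplicate identifier | suspicious | keys email+phone; fires for every member of a sharing group | see below |
| batch submission | suspicious | run of ≥3 submissions, consecutive gaps ≤ window, same email account | sliding over time-sorted records |
| multiple screening attempts | suspicious | fires at >1 | categorical profile |

Weights in the built-in registries range from −3 (free text) to +6
(duplicate identifiers). The exact published weights of the study this
scheme descends from are not public; the defaults here follow the
stronger-signal-more-points principle — honeypot and consistency failures
at +3, identifier sharing at +6 (identifier-rich studies treat it as
grounds for outright removal), contextual signals (onset timing) at ±1 —
and every weight is configurable in YAML.

**Duplicate groups** are connected components under shared normalized
(lowercased, trimmed) identifier values across the configured keys; within
a group the earliest-started record is the one to retain. Cleaning removes
the extras; the *retained* member still carries the duplicate criterion's
points, because sharing a remuneration identifier across several
submissions is itself evidence of incentive-driven duplication. For the
same reason, dataset-level context (duplicate groups, batches, repeated
free text) is computed on the dataset *as collected*, then broadcast to the
scored subset — cleaning must not erase the signal it acted on.

**Free-text plausibility** operationalizes a human judgment ("sensical
free-text responses") that cannot be replicated mechanically: a field
qualifies when it has enough tokens, a sufficient fraction of
dictionary words (a compact built-in vocabulary of function words plus
clinical-survey vocabulary), and is not a verbatim copy of another record's
answer in the same field. The thresholds are validated against the
generator's latent plausibility label (agreement ≥95% is asserted in the
tests), not against real prose.

### Calibration

Controls are designated from email rules alone, as in a pilot: negative
controls (assumed genuine) where the domain is on a trusted institutional
list; positive controls (assumed fraudulent) where the local part matches a
suspicious pattern (all-digits locals, strict letter/digit alternation).
A record matching both rules is left unlabeled with a warning. Per-criterion
confusion counts are tabulated over controls only, with protective criteria
scored at inverted polarity (not firing predicts fraud); undefined ratios
are reported as absent, never as zero.

Cut points: `high_cut` is the smallest observed score with
`frac(negatives ≥ cut) ≤ 1 − min_specificity`; `low_cut` the largest with
`frac(positives ≤ cut) ≤ 1 − min_sensitivity`. Defaults
`min_specificity = 0.99`, `min_sensitivity = 0.90` reflect what strong
individual criteria achieve (specificity 99–100%, sensitivity in the low
90s). Two degenerate cases are handled explicitly: if no observed score
satisfies either constraint (all controls share one score) both cuts
collapse to the midpoint of the observed range; if the cuts cross —
possible when both constraints are individually easy — they collapse to
their mutual midpoint. Both emit a warning and empty the review band.
Ties at a candidate value resolve toward the stricter (higher-specificity)
side by construction, since the smallest satisfying candidate is taken.

### Categorical risk profile

Where a study prefers a categorical judgment to a numeric score, six
boolean signals (multiple screening attempts, missing personal health
number, screening inconsistency, straight-lined scale answers, conspicuous
remuneration interest, low program engagement) map to low/medium/high fraud
likelihood. Three signals — attempts, remuneration interest, inconsistency
— carry high weight: *high* requires a high-weight signal plus any other
signal (or two high-weight signals); *medium* is any two signals short of
high; *low* otherwise. This is a stated formalization of a qualitative team
judgment; the high-weight set is configurable. The sensitivity split
returns the low-only and low+medium analysis sets, with high-likelihood
records excluded from both.

### Accounting

Counts follow the two-step convention: `scored = started −
cleaning_removed` (duplicates, invalid fields, ineligibility — logged with
reason codes) and `included = scored − fraud_removed`. Percentages are
always recomputed from the counts with half-up rounding to one decimal
(`Decimal`-based, so 6.25% → 6.3%); nothing stored can drift from its
numerator and denominator. Note that half-up rounding of a removal fraction
like 415/915 yields 45.4%, whereas truncation would print 45.3% — the
package standardizes on half-up and treats the count identities as the
invariants that matter.

## The synthetic cohort generator

The generator emulates the joint structure of the fraud phenomena the
screening criteria target, per archetype:

* **genuine** respondents: lognormal completion times (median 900 s,
  σ = 0.5 — a substantial professional questionnaire), name-concordant
  emails (35% on institutional domains, so negative controls exist), high
  CAPTCHA scores (Beta(9,1)), plausible free text with probability 0.97,
  empty honeypot, submissions uniform over a ~5-month window;
* **duplicators**: eligible-looking records in groups of 2–4 sharing email
  and phone, resubmitting the *same* answers and free text hours-to-days
  apart (duplicate entries present as identical responses, so their copied
  free text is no longer evidence of independent authorship — the latent
  plausibility label is false for every member of a copy group, original
  included);
* **misrepresenters**: human-like timing but internally inconsistent answer
  combinations with probability 0.9, discordant or pattern emails, junk
  free text;
* **bots**: uniform(30 s, 300 s) completions, honeypot hits with
  probability 0.95, low CAPTCHA scores (Beta(1,6)), pattern emails,
  concentrated after the fraud-onset date (placed at 55% of the window,
  matching a fraud wave detected part-way through recruitment), partly
  arriving in same-account waves minutes apart.

The flagship preset (`case1_like`) uses 55% genuine / 45% fraudulent
prevalence, matching the removal fraction at the upper end of what such
studies report. Generation is a pure function of the configuration: a
single seed spawns per-archetype substreams deterministically, records are
sorted by submission time, and identical configurations serialize
byte-identically. Emails and phones are unique across distinct persons
(collisions disambiguated with numeric suffixes) so that duplicate groups
exist only by construction.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: realistic clinical free text (plausibility is a
latent coin plus dictionary-word surface text, so the free-text evaluator's
real-world error rate is unknowable from these tests); adversaries that
mimic genuine signal distributions (the preset is deliberately separable;
recovery metrics measure pipeline correctness, not detection power against
capable fraud); recruitment-funnel dynamics beyond a screening-attempts
count; IP geolocation structure; and item-level answer dependence beyond
the declared consistency pairs.

## Numerical and interface conventions

* Timestamps are ISO-8601 UTC; duration is recomputed from timestamps when
  both are present, with the stored value used otherwise.
* Missing identifiers are `None`/empty-cell, never empty strings; the
  honeypot field is the exception (its empty string is the human answer).
* All threshold comparisons that encode "faster/lower than the floor" are
  strict (`<`); band edges are closed (include at `low_cut`, exclude at
  `high_cut`, with exclusion taking precedence when the cuts coincide).
* Submissions at exactly the onset instant count as on/after (suspicious).
* The problem sizes used by the test suite and the acceptance script —
  cohorts of 200–2000 records, oracle fixtures of ≤200 records, 300–1000
  randomized calibration instances — were chosen as the smallest sizes at
  which the binomial tolerances (3 SDs) and recovery thresholds are
  meaningful and stable across seeds.

## Known limitations

* Registry point weights and calibration targets are package defaults, not
  published constants; studies adapting the pipeline should re-pilot them
  on their own controls.
* Email-rule control designation assumes emails were collected; fully
  anonymous studies must supply controls some other way (the pipeline
  accepts truth-label controls for synthetic validation, or fixed cut
  points).
* External registry verification (e.g. professional-registration lookups)
  is consumed as a given boolean flag; no lookup is performed.
* The review stage automates a judgment that was originally human and
  consensus-based; the automated rules are deliberately simple and
  conservative.
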