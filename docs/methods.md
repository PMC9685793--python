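# Methods

`rxregimen` operationalizes a question that secondary data sources cannot
answer directly: when a second anti-seizure medication (ASM) appears in a
patient's dispensing history, was the first drug *replaced* (a switch) or
*supplemented* (an add-on)? Prescription registers record redemptions, not
intentions, so the package reconstructs exposure from refill behavior and
classifies the footprint the regimen change leaves in the overlap between
the two drugs' exposure intervals.

## Study population

The cohort is an incident new-user design. A person enters when they redeem
their first-ever ASM (ATC group N03A, plus clonazepam N05BA09, which is
classed as a benzodiazepine but used as an ASM) on or after the admission
date of their first epilepsy contact (ICD-8 345 / ICD-10 G40\*). That
redemption date is the *index date*; any ASM redemption before it excludes
the person (wash-out). Default eligibility: age ≥ 65 years at index, index
date inside the 1996–2018 calendar window. Follow-up runs 730 days from the
index date, censored at death, emigration, or the administrative study end.
Exclusions are logged with reason codes (no-diagnosis, no-ASM, prior-ASM,
age, window) so attrition is auditable. Where a register distinguishes
admission from outpatient visit dates, the admission date is used uniformly
as the diagnosis anchor.

## Supply duration

Nordic-style prescription registers lack a days-supplied field, so supply
duration is estimated from the data. For each drug, the *refill gaps* —
day differences between consecutive redemptions by the same person — are
pooled; gaps above the 0.8 ECDF quantile are treated as treatment
interruptions and trimmed; the remainder is clustered with k-means
(k ∈ 1..5, chosen by mean silhouette width, ties toward smaller k, k = 1
when fewer than 3 distinct gap values remain). Each cluster's median is a
candidate supply duration. A prescription receives the cluster median
closest to its person's own median gap for that drug; persons with a single
redemption get the smallest cluster (the conservative choice), and drugs
with fewer than 10 usable gaps fall back to a 30-day default (a typical
one-month supply). Every constant is a config knob (`see.*`).

Two caveats are worth stating. First, on data with many exactly-tied gap
values the silhouette criterion may split ties into finer clusters than a
human would draw; assignments are essentially unaffected because the
nearest-cluster rule collapses neighboring medians. Second, whether the
original estimator assigned duration per prescription or per person-drug
stint is not recoverable from published descriptions; the nearest-cluster
rule here is one defensible reading, isolated behind the module interface.

## Events, overlaps, N, J and stage

All intervals are half-open day ranges `[start, end)`. Per person and drug,
supply intervals (redemption date + estimated duration) that overlap or
abut merge into maximal *medication events*, clipped to the follow-up
window; a `grace_gap_days` knob (default 0) lets short gaps merge too.
Every maximal intersection between events of two different drugs is a
*co-exposure episode*. Two distinct overlap windows of the same drug pair
are two episodes.

For an episode starting on day `t` of follow-up:

* `N` = overlap days / potential co-exposure days, where the potential runs
  from `t` to the person's last day in ASM treatment or the end of the
  730-day window, whichever comes first. By default "last day in treatment"
  considers *any* ASM event of the person (`denominator_scope: any_asm`);
  `pair_only` restricts it to the episode's own pair.
* `J` = `t` (days from the index date).
* Stage: *early* if `J` ≤ 182.5 (first quartile of the 730-day window),
  *late* if `J` ≥ 548 (first whole day past the third quartile, 547.5),
  *middle* otherwise.

Non-overlapping stop/start transitions are deliberately out of scope: they
are indistinguishable from a stop of one treatment and an unrelated start
of another. Different strengths or brands of one ATC code are one drug.

## Classification

**Approach 1 (thresholds).** add-on iff N ≥ 0.35; switch iff N ≤ 0.10;
otherwise unknown. The middle band is left unknown because only the two
extremes carry a clear signature. The known failure mode is the
*short-term add-on*: a drug added briefly on top of ongoing therapy
produces a small N and is mislabeled as a switch.

**Approach 2 (pharmacological rules).** A configurable rule table forces
labels for drugs that notoriously appear as brief add-ons. Defaults:
clonazepam (short-course first-line drug for myoclonic seizures) and
phenytoin (status-epilepticus co-drug unsuited to long-term combination)
force *add-on*. A rule matches either member of the pair; episodes matching
no rule keep their approach-1 label.

**Approach 3 (supervised).** Six models — linear regression thresholded at
0.5 (logistic available as a config alternative), Gaussian naive Bayes,
SVM, a single-hidden-layer neural network (width 16), CART, random forest —
trained on nine features per episode: J; days from first co-exposure to the
end of follow-up; the episode's temporal rank within the person; follow-up
length; index year; the durations of the two overlapping events (the
event-duration feature realized as two numbers); first diagnosis code
(one-hot); days from hospital discharge to the first redemption; and
hospitalization length. Features are standardized for the SVM and the
neural network only. Because reference labels carry three classes but
performance is reported per label, classification runs as two one-vs-rest
binary tasks (switch, add-on); episodes of the unknown class serve as
negatives in both.

Cross-validation uses 8 combination-aware folds: drug pairs with ≥ 8
episodes are dealt round-robin into every fold, smaller pairs spread across
a global round-robin counter. Each fold is scored by training on the other
seven; the per-model summary is the median of the 8 fold accuracies. A
separate stratified 75/25 split provides a held-out accuracy per model.
The best model per task (highest median fold accuracy, ties broken by
median fold sensitivity) supplies the deployed labels, combined across the
two tasks by out-of-fold prediction (neither positive ⇒ unknown; both ⇒
the larger score). All stochastic components (fold shuffling, model
initialization) consume one config seed. The neural network runs a fixed
1000-iteration budget without early stopping: at the episode counts this
tool typically sees, an early-stopping validation split is too small to be
informative and systematically under-trains the model.

Direction (which drug came first) and stage are computed upstream from the
event intervals and are never altered by any approach.

## Evaluation

Each task is scored one-vs-rest: confusion matrix, overall accuracy with a
Wilson 95% interval, sensitivity, specificity. When fold accuracies exist,
the report adds their median and the 2.5–97.5 percentile band — the
published description of the accuracy interval does not pin down a method,
so both a binomial interval and a fold-distribution band are emitted. AUC
is the normalized Mann–Whitney statistic (ties one half), verified in tests
against an O(n²) pair-counting oracle. Descriptive per-stage ×
per-label counts carry an optional small-cell suppression flag that masks
nonzero cells below 6, mirroring the disclosure rule applied to registry
outputs.

## Synthetic registry

Real register data are access-restricted and carry no regimen-change ground
truth, so the generator plants it. Each person receives a hospitalization
(admission in 1996–mid-2015 so the full follow-up fits in the calendar
window; stay lognormal, median 5 days; ICD G40 subcodes at realistic
frequencies), a first ASM 0–36 days later (lognormal, median 8 days), an
age drawn from 65.5–95 years, and one of four trajectories:

* **monotherapy** (p = 0.40) — one drug refilled through follow-up;
* **switch** (p = 0.12) — drug A until a change day, drug B starting with
  a 4–8 day taper overlap and continuing; N ≤ 0.10 by construction;
* **add-on** (p = 0.43) — sustained (both drugs continue; N = 1) or, for
  30% of add-ons, a short-term rule-drug add-on (clonazepam or phenytoin
  redeemed once or twice, then stopped) whose small N reproduces the
  threshold approach's failure mode;
* **unknown** (p = 0.05) — both drugs stop mid-window with the overlap
  fraction planted inside the ambiguous band (target N in 0.17–0.28).

Monotherapy is deliberately down-weighted relative to registry reality
(where multi-therapy within two years is rare) so desk-scale cohorts remain
informative; the episode-type mix among non-monotherapy persons follows the
roughly 72/20/8 add-on/switch/unknown split seen in elderly epilepsy
registry populations. Change days are drawn early/middle/late with
probabilities 0.82/0.12/0.06, matching the strong early-stage predominance
of regimen changes in the first two treatment years; planted unknowns are
restricted to early/middle because both drugs must stop inside the window.

Refill behavior uses per-person-per-drug phenotypes: 70% refill exactly at
supply exhaustion (gap = supply), 15% six days early, 15% eight days early,
with supplies of 30 days (most drugs) or 90 days (carbamazepine,
phenobarbital). Within a phenotype the gap is constant. This makes the
planted overlaps exactly recoverable and the gap clusters exactly
identifiable, which is what the end-to-end tests need; it does **not**
emulate the irregular refill timing, dose titration, stockpiling or
hospitalization gaps of real claims data. Passing tests therefore
demonstrate correctness of the algorithmic pipeline under clean refill
behavior, not field performance on noisy registries. A configurable
fraction of extra ineligible persons (under-age, or with a pre-diagnosis
redemption) exercises the exclusion machinery; optional exponential
death/emigration hazards (default 0) exercise censoring, and planted
episodes destroyed by censoring are flagged rather than dropped silently.

All randomness derives from one seed; each person's stream is seeded with
`(seed, person index)`, so a person's trajectory is reproducible
independently of cohort size and identical seeds yield byte-identical
tables.

## Problem sizes

The shipped tests run cohorts of 40–1000 synthetic persons and feature sets
of 120–240 episodes; the acceptance script uses 1000 eligible persons
(~600 episodes). These sizes were chosen as the smallest at which the
planted-recovery and learning-sanity properties are stable across seeds.

## Known limitations

* One planted co-exposure episode per synthetic person (real patients show
  up to nine); the `sequence_index` feature is therefore nearly constant on
  synthetic data.
* Constant within-person refill gaps make duration recovery exact; the
  estimator's behavior under realistic gap noise is exercised only in unit
  tests with perturbed fixtures.
* The generator never plants late-stage unknowns.
* Approach-3 scores from different model families (probabilities vs margin
  distances) are compared only within a task, never across models.
* Accuracy values measured on the synthetic registry characterize the
  pipeline under the generator's assumptions and are not estimates of
  performance on any real registry.
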