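# rxregimen

Identify treatment **switches** and **add-ons** in prescription-redemption
records.

Administrative prescription registers record *that* a drug was redeemed,
never *why*. When a second anti-seizure medication (ASM) appears in an
epilepsy patient's dispensing history, a drug-utilization researcher needs
to know whether the first drug was replaced (a switch) or supplemented (an
add-on) — and registers do not say. `rxregimen` reconstructs drug exposure
from refill behavior and classifies the regimen change from the footprint
it leaves in the overlap of the two drugs' exposure intervals. It is
written for pharmacoepidemiologists working with registry-style flat
tables (prescriptions, hospital diagnoses, demographics).

## Method

For an incident new-user cohort (first ASM on/after first epilepsy
diagnosis, no prior ASM, followed 730 days from the index date):

1. **Supply duration.** Registers lack a days-supplied field, so per-drug
   refill gaps are clustered (ECDF-trimmed k-means, k by silhouette); the
   cluster medians are the candidate supply durations.
2. **Medication events.** Per person and drug, supply intervals
   `[redemption, redemption + duration)` that overlap or abut merge into
   maximal exposure events.
3. **Co-exposure episodes.** Every overlap between events of two different
   drugs yields an episode with
   * `N` — overlap days / potential co-exposure days (first overlap day to
     the last day in ASM treatment or the window end, whichever first),
   * `J` — days from the index date to the first overlap day,
   * a **stage** by window quartile: early (`J` ≤ 182.5), middle, late
     (`J` ≥ 548).
4. **Classification**, three ways:
   * *Approach 1*: add-on iff `N` ≥ 0.35, switch iff `N` ≤ 0.10, else
     unknown;
   * *Approach 2*: pharmacological overrides — clonazepam or phenytoin in
     the pair forces add-on (both are characteristically brief co-drugs
     that approach 1 mistakes for switches);
   * *Approach 3*: six supervised models (linear regression, naive Bayes,
     SVM, neural network, CART, random forest) on nine episode features,
     8-fold combination-aware cross-validation, evaluated as one-vs-rest
     switch and add-on tasks.

An evaluation layer scores any approach against reference labels
(confusion matrix, accuracy with Wilson 95% CI, sensitivity/specificity,
Mann–Whitney AUC), and a synthetic-registry generator plants
switch/add-on/unknown trajectories with known ground truth so the whole
pipeline is testable without access to real registry data. See
`docs/methods.md` for the full model description and its limitations.

## Worked example

```bash
rxregimen simulate --out sim/ --n-persons 300 --seed 7
rxregimen all --in sim/ --out results/
```

prints (seed 7):

```
{
  "cohort_size": 300,
  "exclusions": { "no_diagnosis": 0, "no_asm": 0, "prior_asm": 8, "age": 7, "window": 0 },
  "n_events": 470,
  "n_episodes": 170
}
```

300 eligible synthetic persons (15 planted ineligibles were excluded: 8
with a pre-index ASM redemption, 7 under age 65) produced 470 medication
events and 170 co-exposure episodes. `results/evaluation.txt` then shows,
per approach and task, the confusion matrix against the planted truth:

```
[approach1] task: switch
  confusion: tp=36 fp=25 fn=0 tn=109
  accuracy:  0.853 (95% CI 0.792-0.898)
  sensitivity: 1.000  specificity: 0.813
[approach2] task: switch
  confusion: tp=36 fp=0 fn=0 tn=134
  accuracy:  1.000 (95% CI 0.978-1.000)
  sensitivity: 1.000  specificity: 1.000
```

Approach 1 mislabels short-term clonazepam/phenytoin add-ons as switches
(25 false positives); the rule overrides of approach 2 repair exactly
those, which is the behavior the method was designed to capture.
`results/episodes_labeled.csv` carries every episode with its `N`, `J`,
stage and the labels under all three approaches;
`results/model_reports.json` holds per-model fold accuracies for
approach 3. The same steps are available as library calls
(`rxregimen.run_pipeline`) and as separate subcommands (`simulate`,
`cohort`, `events`, `episodes`, `classify`, `evaluate`).

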