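# collabcare

Mining multidisciplinary collaboration patterns — and their relationship to
glycemic control — from primary-care encounter logs of patients with type 2
diabetes mellitus (T2DM).

In team-based chronic care, a patient's cardiovascular periodic appointments
(CVPAs) are attended by a triad of disciplines: physician (P), nurse (N) and
dietitian (D). How these disciplines hand patients to one another is rarely
protocolized, yet it may matter for outcomes. `collabcare` turns two flat
event tables — CVPA encounters and HbA1c test results — into an explicit,
testable answer: which collaboration configurations exist in the data, and
do patients under some configurations evolve differently from the cohort as
a whole? It is written for health-services researchers and process-mining
practitioners working with electronic clinical record (ECR) extracts.

## The method

1. **Selection funnel.** Patients need ≥ 2 HbA1c results; no comorbidity or
   diabetes complication (DCSI and CIC counts both 0); adherence to the
   band-dependent test schedule (≤ 12/6/3 months after a compensated /
   moderate / high result, + 4 months tolerance); and a normalized study
   window of 18 ± 8 months anchored at the first test.
2. **Discipline log and collaborative network.** Per patient, the
   time-ordered sequence c_h of attending disciplines; per patient group,
   the directed graph over {P, N, D} whose arc (a → b) counts consecutive
   attendances, self-loops included. Three indices summarize it:
   participation(d) = CVPAs by d / all CVPAs; self-referral(d) =
   arcs d→d / arcs d→·; referral(d→e) = arcs d→e / arcs d→· (all in %).
3. **Trace clustering.** Complete-linkage agglomerative clustering on the
   normalized Levenshtein distance between discipline sequences, cut at
   15% dissimilarity; clusters smaller than ⌈3% · n⌉ are pooled as outliers.
4. **Pattern classification.** Each cluster's indices go through a decision
   tree yielding one of seven patterns: *self-contained*, *tacit leader*,
   *shared*, *participatory*, *equitably centered*, *hierarchically
   centered*, *self-referred leader* (plus explicit *unclassified*).
5. **Outcome segments.** Each HbA1c series is classified as *compensated*
   (all < 7%, or one excursion into [7, 9]% with mean < 7%), *improved*
   (negative OLS slope, final < 7%), *highly decompensated* (reaches 9%)
   or *moderately decompensated* (the rest) — in that order.
6. **Statistics.** Pattern × segment contingency table; each subgroup
   proportion is compared against the total population with a
   two-proportion z-test (continuity-corrected; Fisher's exact test when an
   expected cell is below 5), α = 0.05, no multiplicity adjustment by
   default.

A seeded synthetic-cohort generator plants collaboration patterns (Markov
chains or sharply separated sequence templates), HbA1c trajectory classes
and adherence violations, so the whole pipeline is testable end to end
against known ground truth.

## Worked example

Simulate a 120-patient cohort with sharply separated planted patterns and
run the full pipeline:

```bash
collabcare simulate --n-patients 120 --seed 7 --separated --out demo_data
collabcare report \
  --encounters demo_data/encounters.csv \
  --measurements demo_data/measurements.csv \
  --patients demo_data/patients.csv \
  --out demo_out
```

which prints:

```
# Collaboration-pattern analysis

## Selection funnel
- total: 120
- min_tests: 120
- no_comorbidity: 120
- adherent: 120
- windowed: 120

## Clusters
- C01: 19 patients — equitably centered
- C02: 19 patients — hierarchically centered
- C03: 19 patients — tacit leader
- C04: 18 patients — participatory
- C05: 17 patients — shared
- C06: 14 patients — self-contained
- C07: 11 patients — self-referred leader
- outliers: 3 patients — outlier group

## Outcome segments
- compensated: 21 (17.5%)
- improved: 36 (30.0%)
- moderately decompensated: 36 (30.0%)
- highly decompensated: 27 (22.5%)

## Significant comparisons (subgroup vs population)
- hierarchically centered × improved: 63.2% vs 30.0% (p=0.01033, two-proportion z with continuity correction)
```

Reading it: no patient was removed by the funnel (the generator planted no
violations), the seven planted patterns were recovered as seven labeled
clusters, and three patients landed in the outlier pool — they carried the
rarer nurse-only variant of the self-contained pattern, and a group of 3 is
below the minimum cluster size ⌈0.03 · 120⌉ = 4. Patterns and outcomes are
planted independently here, so the one flagged comparison is the kind of
false positive unadjusted multiple testing produces — exactly what the
contingency stage is there to quantify. `demo_out/` also receives the
funnel JSON, per-cluster GraphML/DOT networks, assignment and comparison
CSVs, and a bit-for-bit reproducible `report.json`.

## Documentation

`docs/methods.md` describes the model, its assumptions, every tunable
parameter with its default and rationale, what the synthetic generator
does and does not emulate, and known limitations.
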