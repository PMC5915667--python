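# Methods

## Setting and data model

The pipeline analyzes chronic-care delivery for type 2 diabetes in
primary-care centers where a triad of disciplines — physician (P), nurse
(N), dietitian (D) — attends scheduled cardiovascular periodic
appointments (CVPAs). Two event streams drive everything:

* **Encounters**: `(patient_id, date, discipline)`, optionally with the
  prescribed next appointment. Only CVPA-type rows are used.
* **HbA1c results**: `(patient_id, date, value%)`. HbA1c reflects average
  glycemia over roughly the preceding 120 days; < 7% is the treatment
  goal ("compensated"), [7, 9]% moderate decompensation (both ends
  inclusive), > 9% high decompensation.

A patient table supplies precomputed comorbidity/complication counts
(DCSI, CIC) used solely as exclusion flags. Time is converted to months
as days / 30.44 everywhere; clinical rules are stated in months while
ECR dates have daily resolution.

## Selection funnel

Filters run in a fixed order, each on the survivors of the previous one:

1. **≥ 2 HbA1c results** (distinct records after deduplication).
2. **No comorbidity**: DCSI = 0 and CIC = 0. Missing flags are an error,
   not an implicit exclusion.
3. **Test adherence**: every consecutive inter-test gap must not exceed
   the schedule implied by the *earlier* result's band — 12 months after
   a compensated result, 6 after a moderate one, 3 after a high one —
   plus a 4-month tolerance (centers' own estimate of system-side delay).
   The boundary is inclusive (a 10.0-month gap after an 8.0% result
   passes). Patients with one test cannot demonstrate adherence and are
   excluded with a logged reason.
4. **Study window**: t0 is the first test; the end point is the test
   whose offset from t0 is closest to 18 months within [10, 26]. A tie
   between two equidistant candidates resolves to the earlier one — the
   conservative, shorter follow-up. No candidate in range → rejected.

Measurements and encounters after the selected end point are dropped;
both streams are windowed identically, the only self-consistent choice
when the window is defined on the HbA1c stream.

## Collaborative networks and indices

The discipline log maps each eligible patient to the time-ordered
sequence of disciplines attending their in-window CVPAs. Same-day events
are ordered P < N < D (a documented, configurable tie-break; the data
carry no intra-day times) and duplicate (date, discipline) pairs
collapse. Arcs of the collaborative network count consecutive attended
visits — *observed* handovers, not the prescribed next appointment,
which may go unfulfilled (the prescribed field, when present, feeds only
descriptive adherence reporting). A patient's last visit emits no arc,
giving the conservation identity `Σ arcs = Σ CVPAs − n_patients`, which
the tests verify against a brute-force pair-enumeration oracle.

Indices are percentages at full precision internally and rounded only
for reporting. A discipline with no outgoing arc has *undefined*
self-referral and referral indices, represented as `None` — never 0,
which would wrongly assert "no self-referrals".

## Trace clustering

Patients are grouped by normalized Levenshtein distance between their
discipline sequences (edit distance / longer length; computed with
edlib, cross-checked against a dynamic-programming oracle in the tests).
The distance is a pluggable argument so alternative trace
dissimilarities can be swapped in without touching the clustering.

Agglomerative clustering uses **complete linkage** by default, so the
configured 15% threshold is a hard within-cluster guarantee: no two
members of a cluster differ by more than 15%. (Whether the original
tool's "similarity" is a pairwise or centroid criterion is not
determinable; the complete-linkage reading is the one that matches the
stated guarantee, and average linkage is available by config.) The cut
uses cophenetic distance ≤ threshold; thresholds live in (0, 1] — the
upper bound is inclusive because normalized distances reach exactly 1.

Clusters smaller than ⌈outlier_fraction · n⌉ (default 3%; ⌈0.03·231⌉ = 7
matches the reference cohort's stated 7-patient minimum) are pooled into
a single outlier group: excluded from pattern classification, retained
for outcome statistics. Note that after this pooling, raising the
threshold can *increase* the number of non-outlier clusters (two
undersized groups may merge into one admissible one), so monotonicity in
the threshold holds for the raw dendrogram cut, not the pooled result.

## Pattern classification

The seven patterns are an explicit decision tree over a cluster's
indices, with every cut-off in a `PatternThresholds` config (defaults in
parentheses), evaluated most-specific-first:

* 1 discipline present → **self-contained**.
* 2 disciplines: leader participation ≥ 65% *and* the other discipline
  refers ≥ 70% of its CVPAs to the leader → **tacit leader**; else both
  participations in 40–60% *and* both cross-referrals ≥ 60% → **shared**;
  else unclassified.
* 3 disciplines: physician participation ≥ 70% *and* physician
  self-referral ≥ 65% *and* the smallest participation ≤ 5% →
  **self-referred leader**; else max participation ≤ 45% →
  **participatory**; else, if the physician leads, the nurse–dietitian
  interaction share (N→D plus D→N arcs over all N- and D-outgoing arcs)
  decides **equitably centered** (≥ 10%) vs **hierarchically centered**;
  else unclassified.

The participatory ceiling is 45% rather than the 40% maximum observed in
the reference clusters: it leaves margin for sampling noise without
overlapping the 51–54% physician-centered profiles. The 10%
nurse–dietitian floor operationalizes "almost no interaction between
nurse and dietitian"; it is a judgment call and is deliberately surfaced
in the config. `unclassified` is a reported outcome, excluded from
pattern-level statistics, never an exception.

## Outcome segmentation

Rules run in order on the in-window series: **compensated** (all < 7%,
or exactly one value in [7, 9]% with no value above 9% and mean < 7%),
**improved** (OLS slope strictly < 0 and final value < 7%, regardless of
the starting level), **highly decompensated** (some value ≥ 9%), else
**moderately decompensated**. OLS over (months, value) is the standard
trend estimate for ≥ 2 unevenly spaced points; a zero slope is not
improvement. The two band descriptions are contradictory at exactly
9.0% ("did not reach or exceed 9%" vs "over 9%"); treating 9.0 as high
keeps the partition exhaustive and is applied consistently (a single 9.0
excursion with mean < 7 is still compensated because that rule is
checked first). Percentages are reported to one decimal, counts
rounded half-up.

## Statistics

The pattern × segment table includes the outlier row; integer row
percentages, one-decimal totals. Each (pattern, segment) subgroup
proportion is compared against the **total** population — which contains
the subgroup, reproducing the original overlapping design; comparing
against the complement is a config option. The default test is the
two-proportion z-test with continuity correction (the classical
`prop.test` behaviour), switching to Fisher's exact test when any
expected cell of the 2×2 table is below 5 (strictly below: an expected
cell of exactly 5.0 stays with the z-test). Sidedness is configurable:
the documented one-sided variant (direction of the observed difference,
continuity-corrected, no Fisher fallback) is the configuration under
which the reference cohort's three headline contrasts land on their
published values (p = 0.004, 0.035, 0.045). No multiplicity adjustment
is applied by default, matching the original analysis; Holm adjustment
is available. The reference table's moderately-decompensated column
total is taken as 43 (43/231 = 18.6%), the count consistent with the
published percentage.

## Synthetic cohorts

The generator emulates the ECR extract with planted ground truth per
patient: collaboration pattern, outcome segment, adherence-violator
flag — pattern and segment planted independently unless a config couples
them.

* **Sequences.** Either first-order Markov chains over {P, N, D}
  (row-stochastic matrices validated to 1e-9) or deterministic per-pattern
  templates cycled to the visit count. Chains are the realistic default;
  templates exist because recovery experiments need within-pattern edit
  distances below the 15% cut, and a first-order chain realizing, say, a
  50% leader self-referral has per-step entropy that pushes same-pattern
  sequences far beyond 15% at realistic lengths — clusters would shatter
  below the minimum size regardless of implementation. The shipped
  archetype templates were verified to sit > 0.15 apart across patterns
  and ≤ 0.15 within (the self-referred-leader pair of variants pools the
  rare nurse contact needed for its "≤ 5% participation" signature;
  self-contained keeps physician-only and nurse-only variants that form
  two clusters sharing one label).
* **Trajectories.** `HbA1c(t) = baseline + slope·t + N(0, sd)`,
  truncated to [4, 20]%: the simplest generative model realizing all four
  segments, since only the outcome categories, not a data-generating
  process, are documented. Defaults: compensated 6.2%/flat, improved
  9.5% falling 0.2%/month, moderate 8.0%/flat, high 9.8%/flat, noise sd
  0.2%.
* **Schedules.** Visits every 114 days ± 20 (≈ 4.8 CVPAs per 18 months,
  the reference cohort's mean) over a 20-month horizon. Test gaps follow
  the band-driven 12/6/3-month protocol scaled by a factor drawn in
  [0.7, 0.95] — below 1, so non-violators are adherent by construction;
  planted violators get their first gap pushed beyond schedule +
  tolerance, so they survive the ≥ 2-test filter and are removed exactly
  at the adherence stage. A fixed-gap mode (used by `separated_config`)
  decouples the test schedule from the planted segment so every patient
  gets the same study window and hence the same sequence length.
* **Mixes.** Defaults mirror the reference cohort's pattern row totals
  (41/61/24/35/21/14/17 of 213) and segment totals (114/37/43/37 of 231);
  `separated_config` uses uniform mixes.
* **Determinism.** One seeded numpy generator; per patient the draw order
  is pattern, segment, violator flag, comorbidity flag, demographics,
  visit schedule, then test schedule/values. Equal configs produce
  byte-identical cohorts.

What the generator does **not** emulate: medication and treatment
changes, center-level heterogeneity, missed-then-rescheduled
appointments, informative missingness, coupling between collaboration
and outcome, or seasonal effects. Passing recovery tests therefore shows
the pipeline recovers *planted* structure under its own assumptions —
not that real cohorts are this separable; real trace clusterings will
put far more weight on the outlier pool.

## Numerical choices and problem sizes

* Months = days / 30.44; band edges < 7 / [7, 9] / > 9 applied
  consistently across adherence scheduling and segmentation.
* Reporting rounds half-up (integer row percentages, one-decimal
  totals); all statistics run at full precision.
* Clustering and the whole analysis are deterministic: patients sorted
  lexicographically, clusters labeled by decreasing size then smallest
  member id; rerunning a pipeline on the same inputs reproduces the
  report hash bit-for-bit.
* Recovery experiments run at 500 patients (pattern/ARI) and 400
  patients (segments, noise sd 0.2%); the adherence-rate convergence
  check at 1000 patients; the Fisher oracle sweep covers every 2×2 table
  with total ≤ 40. These sizes give stable estimates while keeping the
  suite fast on a single CPU.

## Known limitations

* The trace dissimilarity used by the original proprietary discovery
  tool is not public; normalized Levenshtein is the closest defined
  stand-in, and real clusterings may differ near the threshold.
* The equitably/hierarchically centered split rests on a qualitative
  description; the 10% interaction floor is a default, not an estimate.
* DCSI/CIC are consumed as precomputed flags; no derivation from
  diagnosis codes.
* Appointment-level adherence (prescribed vs actual visit dates) is
  reported descriptively at most; only test-interval adherence filters
  patients.
* Exact published p-values depend on an undocumented test variant; the
  one-sided continuity-corrected configuration reproduces them, but the
  package default remains the two-sided test with Fisher fallback.
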