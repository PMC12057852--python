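# Methods

## Problem and data model

The pipeline analyses a complete-case cohort of knee-replacement
patients, one row per participant: sex, age, artificial joint type
(unilateral/bilateral), five-repetition sit-to-stand time, BMI,
Charlson Comorbidity Index (CCI), CES-D depression score, the three
WOMAC subscales (pain 0–20, stiffness 0–8, physical function 0–68,
higher = worse), and SF-12 PCS and MCS (norm-based around 50,
higher = better) preoperatively and at 1 and 2 years after surgery.
Scores arrive already scaled — scoring questionnaires from items is out
of scope. Missing or out-of-range cells are rejected with the row and
column named, never imputed or clamped: the analysed cohort is defined
as complete cases.

## Dichotomization

Every variable maps to a pair of mutually exclusive items so that
either state can serve as a rule condition (e.g. *non*-depressive
symptoms as an antecedent):

| variable | method | high state |
|---|---|---|
| age | fixed cut-off | ≥ 60 y |
| BMI | fixed cut-off | ≥ 30 kg/m² |
| CES-D | fixed cut-off | ≥ 16 |
| CCI | fixed cut-off | ≥ 1 comorbidity |
| SF-12 PCS/MCS (×6) | fixed cut-off | ≥ 50 |
| sit-to-stand, WOMAC ×3 | median split | > sample median |
| sex, joint type | categorical | one item per level |

Fixed cut-offs are inclusive on the high side, following the "16 or
higher" / "≥ 60 years" conventions. The median split is computed on
the full analysis sample; values strictly greater than the median go
high, ties at the median fall low. This tie rule is the one choice
consistent with every published group size in the reference cohort
(stiffness 18 high / 26 low with the low group's maximum equal to the
median 2.0; tie-free variables split exactly 22/22 at N = 44). A
single-valued vector admits no split and raises rather than returning
an arbitrary partition.

## Rule mining

Antecedents are conjunctions of 1 or 2 items from distinct variables,
excluding the consequent's own variable; no temporal restriction is
imposed (postoperative items may be conditions, matching the reference
analysis, and a config option can restrict to preoperative variables
for sensitivity analyses). With the applicable group A and consequent
B, support = a/N, confidence = a/(a+b), lift = confidence / ((a+c)/N).
Extraction gates default to confidence ≥ 0.80 and lift ≥ 1.1; there is
deliberately **no** support floor (the reference tables contain a rule
at support 6/44, implying none was applied), though `min_support` is
exposed. Cohort sizes are tens of participants with ~30 items, so
rules are enumerated exhaustively; Apriori-style pruning would buy
nothing.

Internally all metric comparisons and the output ordering use exact
rational arithmetic (`fractions.Fraction`), so a confidence of exactly
0.80 passes the ≥ 0.80 gate regardless of binary-float representation,
and ties are broken deterministically: lift desc, confidence desc,
support desc, then lexicographic antecedent labels. Four consequents
are mined by default — low PCS and low MCS at 1 and 2 years — and an
empty rule table is a valid, reported outcome. Combined rules are
flagged "strengthened" when both confidence and lift strictly exceed
those of every extracted single constituent; the attainable ceiling
N/(a+c) is reported alongside, since a full-confidence rule always sits
exactly on it.

## Contingency-table testing

Each extracted rule's applicable/non-applicable × outcome table is
tested two-sided at α = 0.05. The test is chosen by Cochran's rule:
Fisher's exact test when any expected count (row × column margin / N)
is below 5, otherwise χ² *without* Yates continuity correction (a flag
enables it). Fisher's two-sided p sums hypergeometric probabilities of
tables no more probable than the observed one; the suite cross-checks
this against direct hypergeometric summation. No multiplicity
adjustment is applied by default, matching exploratory practice at this
scale; Benjamini–Hochberg adjusted p-values can be reported alongside
the raw ones (they never change the significance flag). At N = 44 the
small expected counts make Fisher the usual choice, and it is
conservative: under simulated independence the empirical rejection rate
at α = 0.05 stays near 2–3%.

## Synthetic cohorts and planted rules

Generation is state-first with a single root `numpy` Generator seed:

1. each variable's binary state (or categorical level) is drawn from
   its marginal prevalence;
2. planted rules then set outcome states: participants matching all
   antecedent states receive the outcome state with the planted
   conditional probability, others with the baseline (two rules may
   share an outcome only with the same state and baseline; a planted
   antecedent may not itself be a planted outcome);
3. the continuous score is sampled from the state-conditional
   component — a truncated normal confined to that state's side of the
   cut-off (integer-rounded for CES-D and CCI).

Because values never cross their state's cut-off, a rule planted on
fixed-cutoff variables survives dichotomization *exactly*; for
median-split variables the components sit on either side of the
reference median with prevalence 0.5, so recovery is exact up to the
binomial wobble of the realized sample median. Default prevalences are
calibrated to the published 44-patient cohort (26/44 aged ≥ 60, 10/44
comorbid, 4/44 depressive, 32/44 with low 2-year PCS, …); one
dependency is planted by default — P(low 2-year PCS | comorbidity) = 1
against a 22/34 baseline — mirroring the cohort's strongest signal.
The published 2-year-MCS group sizes (32 and 17) exceed N = 44; the
default uses their ratio 32/49 and does not reproduce the
inconsistency. Component shapes are cosmetic: only the binarized
structure feeds the miner, which is why the generator's fidelity to
real OAI score distributions (skew, floor effects, longitudinal
correlation) is not claimed — passing tests demonstrate correctness of
the pipeline's logic, not clinical validity of any mined rule.

`recover_planted_rules` re-estimates each planted rule through the full
pipeline at a larger n (2,000 by default in the drivers) and reports
estimated vs planted confidence and lift with binomial / delta-method
standard errors; the planted lift is conditional / P(B) with
P(B) = p_A·conditional + (1−p_A)·baseline under independent antecedent
marginals.

## Numerical and reporting choices

- Printed percentages and lift round half-up to 2 decimals from exact
  fractions (a lift of exactly 1.1875 prints 1.19); p-values print to
  4 significant figures with a `<0.001` form available.
- Rule TSVs carry the raw a, b, c, d counts so every printed metric is
  recomputable from its own row.
- Runs are deterministic: identical inputs give byte-identical outputs,
  and the manifest digests the variable config and thresholds so any
  change is visible.
- Problem sizes in tests and drivers: null-table simulations use 2,000
  replicates; recovery uses n = 2,000; oracle equivalence checks 200
  random matrices up to 50 × 10 — ample for the binomial tolerances
  asserted (±0.03 confidence, ±0.05 lift).

## Known limitations

- Two-condition antecedents only, by design; no weighted or fuzzy
  rules, and no exact unconditional tests (Barnard/Boschloo).
- The generator does not model dropout, missingness, measurement error
  or longitudinal correlation between the SF-12 time points beyond what
  planted rules induce.
- With ~380 candidate antecedents per consequent and no multiplicity
  adjustment by default, spurious gate-passing rules are expected in
  null data at N = 44; the screen is exploratory and the per-rule tests
  are reported as such.
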