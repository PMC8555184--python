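# Methods

## Units and definitions

The analysis unit is the *encounter* — one prescription presented at one
pharmacy outlet.  Each encounter carries one or more medicines; each
medicine carries six event flags (generic-name prescribing, antibiotic,
injection, EML membership, dispensed, labelled).  Encounter-level
indicators (antibiotic %, injection %) count an encounter once however
many flagged medicines it holds; medicine-level indicators (generic %,
EML %, dispensed %) use all prescribed medicines as denominator; the
labelling indicator divides labelled by **dispensed** medicines.  The
average-medicines indicator counts *different* medicines per encounter:
duplicate entries of the same generic entity within one encounter are
deduplicated for that count only (a raw-count mode exists via
`dedupe=False`); all other indicators count medicine rows as written.

## Intake filter

Survey write-ups state that incomplete prescriptions are excluded but
rarely enumerate the rules.  We fix an explicit ordered checklist so the
filter is reproducible: (1) no medicines; (2) an empty medicine name;
(3) missing district or category; (4) a missing dispensed flag; (5)
labelled without dispensed; (6) more than 12 medicines (the plausible
range cap).  Validation never raises — it classifies, and the exclusion
log records `(encounter_id, first failing rule)`.  An encounter whose
only defect is an unresolvable medicine *name* (brand with no map entry)
is retained with a warning: nothing in the record is missing, only our
reference data.

## Medicine classification

Names are canonicalized (lowercase, collapsed whitespace, trailing
dose/strength tokens stripped by a documented pattern: bare numbers,
number+unit, unit-bearing ratios such as `125mg/5ml`, bare units;
unitless ratios like insulin's `30/70` are treated as part of the name).
Generic-name prescribing is exact membership of the canonical name in
the INN reference set — deterministic and testable; no fuzzy matching.
Brand names resolve through a brand→generic map; EML and antibiotic
status are resolved on the generic entity; the injection flag comes from
an injectables list or a parenteral form-token list.  The reference
lists shipped with the generator are synthetic toy lists standing in for
the national documents.

## Synthetic survey generator

The generator is a model of the survey *design*, not of any particular
dataset.  Its defaults are the design and marginal rates of a 2015
island-wide Sri Lankan retail-pharmacy survey:

| parameter | default | meaning |
|---|---|---|
| districts | 25-district fixture | approximate relative populations; per-district category availability |
| min_area_population | 100 000 | WHO/HAI minimum per survey area; smaller districts merge with a declared neighbour |
| double_set_population | 1 000 000 | areas above this get two sample sets |
| encounters_per_outlet | 30 | consecutive prescriptions per outlet |
| count_mean / count_sd | 3.1 / 1.9 | medicines per encounter, truncated to [1, 12] |
| p_encounter_antibiotic | 0.238 | encounter-level antibiotic probability |
| p_encounter_injection | 0.012 | encounter-level injection probability |
| p_generic / p_eml / p_dispensed | 0.355 / 0.688 / 0.924 | per-medicine Bernoulli rates |
| p_labelled_given_dispensed | 0.985 | labelling conditional on dispensing |
| p_incomplete | 0.03 | fraction of encounters corrupted |

Under the default fixture the allocation rules give 24 survey areas
(one merged pair), 80 outlets and 2400 planned encounters.  The district
populations are approximations of relative census sizes; the category
availability pattern is likewise an emulation chosen so that the
one-outlet-per-available-category-per-set rule lands on the design total
of 80 outlets (real surveys sometimes double a category within an area
instead, which this rule cannot express).

**Medicine counts.**  A shifted negative binomial on `count - 1` is
moment-matched to the target mean/SD, evaluated on 1..12 and
renormalized (an under-dispersed target falls back to a shifted
Poisson).  Truncation pulls the implied mean/SD slightly off the
nominal targets (3.09/1.87 at the defaults); the truth record stores the
implied values so parameter-recovery checks compare against the exact
truth.  A hard error is raised when the mean lies outside the truncation
range.

**Flag structure.**  Antibiotic and injection events are drawn at
encounter level — matching the indicator definitions — and pushed down
onto exactly one randomly chosen medicine, avoiding double-counting
ambiguity.  Names are drawn from a weighted table *without replacement*
within an encounter, so the different-medicines count equals the drawn
count; real prescriptions can repeat an entity across dosage forms, a
feature the generator deliberately omits.  Per-medicine flags are
independent Bernoulli draws, so the generator has no confounding between
e.g. generic prescribing and EML membership, and re-classifying a
generated file by name will not reproduce its Bernoulli EML flags — the
flag columns are authoritative for generated data.

**Corruption.**  Exactly `round(p_incomplete × n)` encounters, chosen
uniformly without replacement, each receive one uniformly chosen
violation from the five-rule checklist.  The exact count (rather than
i.i.d. Bernoulli corruption) makes the 2400 → 2328 (97.0%) filter
deterministic at the default configuration.

**Per-category overrides.**  `category_overrides` lets a category carry
its own rates/count moments (e.g. state-owned: mean 3.6, antibiotic
15%), which is how surveys with real between-category contrasts are
emulated for power checks.

Identical seed and configuration give byte-identical output; all
randomness flows from one `numpy.random.default_rng(seed)`.

What passing tests on generated data do **not** show: robustness to
handwriting/free-text noise, within-outlet correlation of prescribing
habits (encounters are exchangeable within an outlet here), seasonal
structure, or realistic name–flag dependence.

## Index computation

Components are directional capped ratios (see README).  Two numeric
conventions:

* `printed` (default): the observed indicator is taken at one decimal
  place, the ratio computed in decimal arithmetic, capped at 1, and
  rounded half-to-even to two decimals; composites sum the *rounded*
  components and are reported at two decimals.  This is the unique
  simple convention that reproduces published index tables exactly
  (e.g. 23.4/23.8 → 0.98; 0.355 → 0.36; 0.985 → 0.98; 0.695 → 0.70).
* `raw`: full floating precision throughout, for new analyses where no
  printed table is being matched.

Capping is explicit: an observed value at least as good as the optimal
point scores exactly 1.00 (the published safe-injection indices print
1.00 although the uncapped ratio would exceed 15).  An observed value of
0 under a lower-is-better direction scores 1.00 (better than optimal),
not a division error.  Undefined indicators (zero denominators)
propagate as explicit missing values; a group missing a component gets
`None` composites rather than a fabricated number.  Note that under the
printed convention a component can also *round* to 1.00 from just below
(e.g. 23.5 observed vs 23.4 optimal → 0.9957 → 1.00), and extreme ratios
can round to 0.00; the strict `(0, 1]` bound and the cap-iff-optimal
equivalence hold exactly in raw mode.

Optimal points default to the WHO range midpoints (1.7, 23.4, 18.75)
and 100 for the unbounded-optimum indicators, and are configurable; a
point outside its reference range is rejected.

## Statistical comparisons

Proportions are compared with Pearson chi-square on k×2 event/non-event
tables, df = k−1, no continuity correction by default (a Yates 2×2
variant is available); expected cells below 1 attach a warning rather
than failing.  Means (medicines per encounter) use a pooled-variance
two-sided Student t for two groups and one-way ANOVA for three or more.
Degenerate inputs follow documented conventions: identical data →
statistic 0, p 1; zero within-group variance with distinct means →
p 0.  Pairwise annotation marks each significant pair with a shared
letter (groups sharing a letter in a row differ at α = 0.05); the
pairwise family matches the omnibus family, and no multiple-testing
correction is applied by default (a Bonferroni option exists), matching
how such surveys report unadjusted p-values.  Whether the original
analyses used pooled or Welch t-tests, or which post-hoc scheme, is not
stated in survey reports; ours are documented choices, not claims about
the originals.

Encounters are treated as independent.  Real surveys cluster encounters
within outlets and districts; ignoring the design effect makes p-values
anti-conservative on clustered data.  This mirrors the analysis style of
the surveys being reproduced and is a known limitation, not an
endorsement.

## Problem sizes in the test suite

The parameter-recovery and power checks run at the full design size
(80 outlets × 30 encounters); the type-I calibration uses 200 null
replicates of a 9-outlet / 270-encounter survey with equal rates across
categories, a size at which both tests' expected counts are comfortably
in the chi-square/F asymptotic regime; the power check uses 100
full-size replicates at the published per-category rates.  Tolerances:
three standard errors for parameter recovery (per-indicator, against the
truth record's implied moments), [3%, 7%] empirical rejection at
α = 0.05 for calibration, ≥95% of replicates recovering both category
contrasts with p < 0.001 for power.

## Known limitations

* Exact-membership name classification: misspellings become
  "unresolvable" rather than fuzzy-matched (an edit-distance option was
  considered and deliberately left out of the default path for
  determinism).
* The polypharmacy threshold is exposed (`threshold`, default ≥4, with a
  strict `>` mode) because the field uses both conventions.
* Aggregate mode trusts its input table; it cannot detect
  numerator/denominator inconsistencies the way raw mode's conservation
  checks can.
* District-level results on synthetic data share one global rate
  structure (unless overridden) and should not be read as emulating real
  geographic heterogeneity.
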