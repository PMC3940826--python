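# Methods

`glycodiary` re-implements, as a reusable library, the analytical pipeline
of a matched case-control dietary survey in type 2 diabetes: 4-day
semi-weighed food diaries are expanded against a per-100 g composition
table, every food receives a glycaemic index (GI) through a fixed imputation
hierarchy, participant-level dietary GI/glycaemic load (GL), nutrient and
percent-of-energy profiles are computed, reported energy intake is screened
for plausibility, foods are aggregated into 38 mutually exclusive groups,
and the two arms are compared with matched-pair tests. Because the original
survey and clinic data are not publicly deposited, the package ships a
synthetic cohort generator that reproduces the *structure* of such data;
every downstream stage is exercised and tested against it.

## GI assignment hierarchy

Each food in the composition table receives exactly one GI via, in order:

1. **Low-carbohydrate zero.** Foods with ≤ 5 g available carbohydrate per
   100 g get GI 0. This is a property of the food, not of reference-table
   coverage, so it is evaluated first; the rule is per-100 g and is applied
   as such even to foods eaten in large portions.
2. **Reference-table match.** All matching reference rows are collected
   (exact food-code match, or glob patterns in the reference table). If any
   matching row comes from a UK study, the mean of the UK rows only is used
   (UK values being most representative of foods eaten in Ireland); the
   interpretation that UK presence restricts the averaging set, rather than
   merely breaking ties, is a documented choice. Otherwise the mean of all
   matches is used (a single match is recorded as `direct`).
3. **Composite dishes.** A dish with a recipe resolves through its
   carbohydrate-contributing components: if one component supplies more
   than the dominance threshold (default 0.5) of the dish's carbohydrate,
   its GI is used; otherwise the unweighted mean GI of the components.
4. **Analogue imputation.** The GI of a closely equivalent food, resolved
   through the reference table.
5. **Default 50.** Anything still unresolved is assigned GI 50.

Reference GIs above 100 are accepted (glucose-scale values can exceed 100);
no cap is applied.

## Dietary GI and GL

For one participant-day,

- dietary GI = Σ_f GI_f · c_f / Σ_f c_f, where c_f = grams eaten ×
  carbohydrate per 100 g / 100. A day whose total carbohydrate is zero has
  no defined GI and is excluded from the participant mean (an error only
  when every day is undefined).
- dietary GL = Σ_f (GI_f / 100) · c_f. The /100 scaling is the standard GL
  convention and the only one that yields daily loads of the magnitude
  (~100–150) reported for adult diets; `GIConfig(gl_per_100=False)` gives
  the literal un-scaled sum for comparison.

The participant's dietary GI is the carbohydrate-weighted mean over defined
days — algebraically identical to pooling all items of the recording
period — and dietary GL is the mean of the per-day loads. Because GL is a
sum of per-item terms, regrouping those terms by food group reproduces the
participant total exactly; the food-group GL decomposition relies on this
identity and it is asserted to 1e-9 relative tolerance in the tests.

## Energy screen

BMR is predicted from the Henry (2005) weight-only equations (MJ/day =
a·weight + b by sex and age band, bands [18,30), [30,60), [60,70), [70,∞)),
converted at 239.006 kcal/MJ. The weight-only rather than weight+height
form is used because the protocol being reproduced cites only the Henry
equation without height. Energy intake (EI) is the mean of daily energy
totals over recorded days, taken from the composition table's energy field
rather than recomputed from macronutrients (mirroring survey practice; the
generator writes factor-consistent energies so the two coincide on
synthetic data). The Goldberg screen flags EI/BMR below 1.1. The boundary
is convention: the screen's default flags strictly `< 1.1`, while the
sensitivity-exclusion subset removes `≤ 1.1`; both comparators are config
(`goldberg.comparator`, `goldberg.exclusion_comparator`) because source
descriptions of this cutoff mix the two forms. No PAL-adjusted Goldberg
bounds are computed — the protocol uses the fixed 1.1 cutoff only.

## Nutrients, %E and recommendations

Diary expansion is exact linear aggregation (amount × per-100 g / 100).
Percent of energy uses the UK metabolisable-energy factors (protein 4.0,
fat 9.0, available carbohydrate as monosaccharide 3.75, alcohol 7.0
kcal/g); on factor-consistent composition data protein+fat+carbohydrate+
alcohol %E sums to exactly 100, a conservation law the tests assert at
1e-6. Recommendation targets: upper bounds are strict (`<35` %E fat,
`<10` SFA, `<10` PUFA, `<2300` mg sodium), lower bounds inclusive (fibre
24 g, calcium 800 mg, vitamin D 10 µg, B12 1.4 µg, folate 300 µg, vitamin
C 60 mg), bands inclusive on both ends (protein 10–20, MUFA 10–20,
carbohydrate 45–60 %E), iron sex-specific (≥10 mg men, ≥9 mg women — the
lower bound of the printed women's range). "Non-milk sugars" is a
composition-table column, not derived.

## Food groups

The 38-group scheme partitions the catalogue (mutually exclusive,
exhaustive); nutritional supplements are kept as their own group so their
micronutrient contribution is isolable. A "consumer" of a group is anyone
with positive intake on any recorded day. Quantiles are type-7 (linear
interpolation); because printed IQR-like spreads in survey tables sometimes
span the full observed range, table3 emits both the 25th–75th percentile
and the min–max alongside. Consumers-only statistics are computed within
arm; paired tests always use total-population values (zeros included).

## Statistical protocol

Continuous variables are routed by a Kolmogorov–Smirnov test of the pooled
(both-arm) values against a normal with estimated mean and SD; p > 0.05
routes to the paired t-test, otherwise the Wilcoxon signed-rank test.
Food-group intakes and contribution percentages always take the
signed-rank route. Note the KS test with estimated parameters is
anticonservative as a normality test (the Lilliefors correction is not
applied), which mimics common statistical-package practice; routing
affects efficiency, not validity, on paired data. Per-arm routing is
available via `StatsConfig(ks_scope="per_arm")`.

The signed-rank test drops zero differences, mid-ranks ties, and uses the
exact null distribution for ≤ 25 non-zero differences (a polynomial
convolution over doubled ranks, identical to enumerating all 2^n sign
assignments; p = 2·min tail, capped at 1) and a tie-corrected normal
approximation above. Pearson's χ² is computed without continuity
correction, with a warning when an expected count falls below 5. p ≤ 0.05
(inclusive) is flagged significant; p-values are unadjusted, with a
Benjamini–Hochberg column emitted for reference but never used for the
primary flags. Missing values are handled by pairwise deletion per
variable.

The sensitivity re-run drops the *whole pair* whenever either member falls
at or below the exclusion cutoff — matched tests need complete pairs — and
reports per-variable (p_full, p_subset, flag_changed).

## Synthetic cohort generator

What it emulates: matched pairs (same sex and social class, age within
±2 y, BMI within ±1.5 kg/m²; matching is generated jointly rather than
solved post hoc, since matching against a pre-existing survey is not
reproducible); 4-day diaries with ≥1 weekend day; a ~120-food catalogue
spanning all 38 groups whose reference-GI coverage exercises every
hierarchy branch; zero-inflated log-normal intakes (participant-level
consumer gate per group, day-level eating gate, log-normal daily amount —
chosen because survey tables show many non-consumers per group); and a
configurable under-reported fraction (default 0.37) whose members'
amounts are deflated by a per-person factor in [0.6, 0.95].

Group-level consumer fractions and typical daily grams follow the
magnitudes of published Irish adult survey tables; a single global portion
scale sets mean reported energy near 2 300 kcal/day, giving EI/BMR ratios
centred a little above 1.1 so that both naturally low reporters and
injected under-reporters appear, as in real cohorts. Arm effects are
multiplicative shifts applied to both the consumer-gate odds and the
amount scale (surveys show arms differing in both % consumers and
consumed amounts); supplements are the one exception — their shift acts on
the gate only, since taking fewer supplements does not shrink the dose of
those who take them. **The arm-effects map is the generator's only arm
asymmetry**: with it empty, arms are exchangeable by construction, which
is what makes the type-I calibration test meaningful.

What it does not emulate: nutrient–covariate correlations (diet is
independent of age, sex and BMI; real intakes are not), brand-level foods,
seasonal or day-of-week structure, correlated food choices within a
participant beyond the consumer gates, and selective (food-specific)
under-reporting. Passing tests therefore certify the pipeline's
arithmetic, calibration and power under the assumed intake model — not
that the generator's medians match any real population.

## Problem sizes and numerical choices

- Type-I calibration: 500 null cohorts of 50 pairs; the battery is the 22
  nutrient variables plus the 38 food-group intakes per replicate (dietary
  GI/GL, deterministic functions of the same diary, are exercised by the
  conservation and invariance suites instead); the pooled rejection
  fraction at α = 0.05 must lie in [0.03, 0.07].
- Effect-direction recovery: 100 cohorts of 124 pairs with the default arm
  effects; the sign of each configured shift is measured on the arm
  difference in *mean* group intake (g/day), not the median, because
  zero-inflated groups can have median 0 in both arms, leaving the median
  difference sign undefined.
- Conservation: 1 000 synthetic participants; decomposition identities at
  1e-6 (shares) and 1e-9 relative (GL regrouping).
- Oracle equivalence: 200 random signed-rank instances (n ≤ 12) against
  full 2^n enumeration; 1 000 participant-days of nutrient expansion
  against per-item re-summation.
- Output tables are CSV with 12-significant-digit floats, deterministic
  column order and sorted rows; identical inputs give byte-identical
  outputs.
- Degenerate inputs: all-zero differences → p = 1 with a degenerate flag;
  zero-variance t-route falls back to the degenerate result inside the
  battery but raises when called directly; zero-carbohydrate days are
  excluded from dietary GI (error only if all days are); groups with no
  consumers emit missing consumers-only statistics.

## Known limitations

- The exact signed-rank null is O(n²·max-rank) per variable and switches
  to the normal approximation above 25 non-zero differences; near the
  switch the approximation (no continuity correction) can differ from the
  exact tail by ~0.002–0.005.
- The KS routing's anticonservatism means borderline-normal variables
  route to the signed-rank test more often than a Lilliefors-corrected
  test would; both destinations are valid paired tests.
- Compliance percentages are computed on reported (possibly
  under-reported) intake, as in the reproduced protocol; the Goldberg flag
  is carried through but only the sensitivity re-run consumes it.
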