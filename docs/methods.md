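# Methods

## Cohort model

One row per individual: `age` (integer years ≥ 0), `sex` (M/F),
`simd_decile` (1–10, 1 = most deprived), `ethnicity`
(white/nonwhite/NA), `urban_rural`, `mainland_island`, `score`
(probability, open interval (0, 1)), `outcome` (0/1: emergency
admission or death within one year), `event_kind`
(none/admission/death_without_admission) and `icd10_code` (present iff
`outcome = 1`; for deaths without a prior admission, the primary cause
of death). Scores are held as probabilities throughout; the deployed
1–99 integer convention is treated purely as a display scale, because
the analysis conditions on thresholds such as Ŷ < 0.1. Missing
categoricals use the sentinel `NA` on disk and in memory, so file
round-trips are exact. Validation raises distinct named errors (missing
column, score out of (0, 1), invalid category, event inconsistency),
each naming the offending row and field.

Six built-in comparisons contrast the extremes of each grouping
variable; rows matching neither side — including rows with a missing
value for that variable — are excluded from that comparison only. Age
uses ≥ 65 vs ≤ 25 (both inclusive); deprivation builds quintiles from
decile pairs {1,2} vs {9,10}. Each comparison is evaluated
independently on the full table.

## Synthetic cohort generator

The generator's role is *structural realism plus known ground truth*:
it emulates the statistical features the audit must cope with, not any
deployed model's risk surface.

**Demographics.** Sex is Bernoulli(0.454). Age is a three-component
truncated-normal mixture on [0, 110] — child (μ 5.87, σ 7.5, w 0.20),
adult (45, 13, 0.6317), elderly (78, 7.5, 0.1683) — whose components
were solved analytically so the mixture has mean 43.3 and SD 23.8.
SIMD decile weights put 21.5% in the top two and 18.7% in the bottom
two deciles. Ethnicity is missing with probability logistic in age
(slope 0.5 per age SD; the intercept is calibrated by root-finding on
each drawn cohort so the overall missing fraction is 11.4%), making
missingness non-random with older missing rows; the white:nonwhite
split among non-missing rows is 0.668:0.218. Urban residence
probability varies by decile (0.965 at decile 1 down to ~0.74
mid-range, 0.919 at decile 10; implied overall fraction 0.833) and
optionally by age *band* (`urban_age_slope`, default 0; band-level
rather than exact-age dependence so that age-mediated residence
effects live exactly on the strata grid the audit standardises over —
a confounder acting below strata resolution cannot, by construction,
be removed by strata standardisation). Island residence is
concentrated among rural rows (P(island|rural) = 0.083 vs 0.0058
urban, overall 1.86%).

**Risk and score.** True risk is logistic:
logit p = −3.2 + 1.5·z_age + 0.10·male + 0.35·d + optional direct
group effects + N(0, 0.8²) individual noise, with z_age the
standardised age and d = (5.5 − decile)/4.5 the deprivation score
(+1 most, −1 least deprived). p is clipped into [0.01, 0.99]; the
defaults give an overall event rate near 0.10 with a strong age
gradient (mean risk ≈ 0.30 over 65 vs ≈ 0.013 under 25). Outcomes are
Bernoulli(p). The reported score equals p exactly unless a per-group
calibration distortion is configured (logit Ŷ = a·logit p + b on the
named group, clipped back into (0.01, 0.99)); `inject_group_miscalibration`
applies a pure log-odds shift post hoc, leaving outcomes and all other
groups' scores untouched.

**Events.** Given an event, death-without-admission occurs with
probability 0.6·sigmoid((age − 80)/8) — deaths against expectation are
concentrated in the elderly, exercising the cause-of-death rule. Each
event's ICD-10 code is `letter + "00"`, the letter drawn from a
mixture over chapter letters specific to the (age band, sex,
deprivation band) cell. Defaults inflate external-cause letters
(S, T, V, X, Y) ×2.5 in young males (×1.6 young females), circulatory/
respiratory/neoplastic letters in the elderly, and give adult females
an obstetric component — so external causes are planted among low-risk
young males, the structure the decomposition is expected to recover.

**What it does not emulate:** longitudinal hospital-activity and
prescribing histories (the feature space of real scores), regional
correlation, household structure, secular trends, and any real risk
model's functional form. Passing tests demonstrate the audit machinery
is correct under known ground truth, not that any particular deployed
score is fair.

All draws flow from one seeded `numpy` generator; identical config and
seed give byte-identical cohorts.

## Metrics

**Score CDF / parity.** P(Ŷ < c | G) with strict inequality (the
decision rule's negative leg), on the default grid c = 0.01…0.99;
pointwise 95% Wilson intervals (statsmodels).

**Counterfactual CDF.** Σ_s w_g(s)·CDF_{g′,s}(c) over age-band × sex ×
SIMD-decile strata, where w_g is the target group's empirical strata
distribution restricted to strata the source group occupies and
renormalised (the dropped mass is reported per curve and logged).
Default age bands are 5-year bands 0–4 … 90+. Intervals by stratified
bootstrap (resampling individuals within source strata via multinomial
bin counts; 1000 replicates; percentile). For comparisons defined *on*
a strata component (age, sex, deprivation) the runner drops that
component from the grid — the two groups share no stratum otherwise.

**AUROC.** Midrank implementation of (concordant + ½ ties)/(n₁n₀) —
ties get half credit because real scores have 1–99 display granularity
— with the placement-value (DeLong) variance
S₁₀/n₁ + S₀₁/n₀; the estimator name is carried in the result metadata.

**Calibration.** Mean score vs observed event rate per bin with Wilson
bands; 20 equal-width bins by default, equal-occupancy (quantile) bins
by flag; bins under `min_count` (default 50) are omitted and logged.
Quantile binning is preferred for formal identity checks because
equal-width tail bins near the count floor carry sampling noise of the
same order as any deviation of interest.

**FOR / FDR.** FOR(c) = events/rows among Ŷ < c; FDR(c) =
non-events/rows among Ŷ ≥ c (positive prediction is Ŷ ≥ c throughout).
Cutoffs whose conditioning set is empty yield NaN — undefined is never
silently zero. Standardised versions replace the group rate with
Σ_s w_ref(s)·rate_s(c); the reference distribution is the pooled pair
by default (making the two groups' adjusted curves commensurable), the
comparator group or the group itself by option. Strata with an empty
conditioning set at a cutoff are dropped and the weights renormalised,
with the dropped reference mass reported per cutoff; intervals by
within-stratum bootstrap as above. Drop-and-renormalise was chosen
over model-based imputation: no assumptions, transparent diagnostics.

**False-negative decomposition.** Events are typed by the uppercased
first letter of the ICD-10 code through a fully configurable letter →
category map (defaults: external = S,T,V,X,Y; abnormality-NEC = R;
remaining chapters by letter family; empty/invalid codes go to
`unknown` with a warning). Admissions and deaths-without-admission are
decomposed separately. A is the category's share of all the group's
events of that kind; B its share among events with Ŷ < 0.1 (strict).
The B − A interval bootstraps the *events* jointly over
(category × below-threshold) cells, so each replicate's low-score set
remains a subset of its event set. Within each panel Σ A = Σ B = 1 and
Σ(B − A) = 0 exactly.

## Orchestration and determinism

`run_audit` derives one RNG per (comparison, metric) stage from the
root seed via `SeedSequence((seed, comparison_index, metric_index))`,
so stages are independently reproducible and insertion order is
irrelevant. Stage failures (e.g. an empty or single-class subgroup) are
caught per (comparison, metric), recorded in the manifest with the
stage name, and do not stop other stages. The manifest echoes the
config, software version, seed, and every warning any stage emitted.
Figures are SVG with the date field stripped, so bundles are
byte-identical under re-run.

## Validation methodology

The test suite validates every estimator against independent
brute-force loops on small cohorts (hypothesis-generated, to machine
precision), and the pipeline's statistical behaviour on 100k-row
cohorts: marginal and mixture recovery within 3 binomial SEs;
calibration identity under zero distortion (max deviation < 0.02 over
equal-occupancy bins of ≈ 5000); signed detection of an injected +1
log-odds group shift with the other group bit-identical; removal of a
purely age-mediated urban/rural FOR difference by standardisation;
agreement of the counterfactual CDF with the target group's raw CDF
when score ⊥ group given the strata; the binormal AUROC closed form
Φ(1/√2); decomposition conservation and planted-effect recovery; and
byte-identical bundles under a fixed seed.

Two coverage-style checks (mediation removal, counterfactual null)
judge a standardised *difference* against a pointwise 95% band. The
band used is the pooled-variance stratified two-sample proportion
z-band rather than a combination of the curves' own percentile
bootstrap bands: percentile bands collapse to zero width beyond the
smaller group's score support and understate variance in strata where
the smaller group has only a handful of members, so they are a
miscalibrated yardstick for tail cutoffs even when the estimates are
exactly right. The z-band is non-degenerate wherever any shared
stratum conditions and was verified by Monte Carlo across generator
seeds to give ~95% pointwise coverage.

Problem sizes: property tests use ≤ 20-row cohorts; statistical tests
use n = 10⁵ with 500–1000 bootstrap replicates, enough for the
marginal-recovery and coverage statements above while keeping the full
suite around a minute.

## Known limitations

* The counterfactual reweights over age/sex/SIMD strata only; matching
  on richer history (hospital activity, prescriptions) is out of scope
  without that feature space, so "counterfactual" here means
  "covariate-composition-adjusted".
* 5-year age bands leave residual within-band confounding when a
  mediator acts on exact age (of order 0.005 on FOR for a strong
  gradient); bands are configurable where that matters.
* Letter-level ICD-10 categories split some chapters imperfectly
  (e.g. the D range spans blood and neoplasms); the map is a
  configurable text file, not a claim about any particular chapter
  table.
* Percentile bootstrap intervals degenerate at cutoffs beyond a
  group's score support; undefined estimates and dropped-mass columns
  make this visible rather than hiding it.
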