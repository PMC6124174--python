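# Methods

`caphos` evaluates the serum calcium-to-phosphorous ratio (Ca/P) as a
diagnostic index for primary hyperparathyroidism (PHPT). PHPT raises serum
calcium (Ca) and lowers phosphorous (P), and the two analytes are inversely
related even within the disease, so their ratio concentrates the diagnostic
signal of both into a single number that needs no hormone assay. The package
implements two complementary evaluation designs — a case-control study with
chart-verified diagnoses, and a distributional mining cascade over an
anonymous laboratory database — plus the statistics and synthetic data needed
to exercise them end to end.

## Biochemical layer

All computation is in SI units: Ca and P in mmol/L, intact PTH in ng/L,
creatinine in µmol/L, albumin in g/L, 25-OH vitamin D in nmol/L. Conventional
units (mg/dL) appear only at explicit conversion boundaries, which removes the
usual double-conversion failure mode. The conversion factors are the molar
masses over ten: 4.008 (Ca) and 3.097 (P) mg/dL per mmol/L, 88.4 µmol/L per
mg/dL for creatinine. A Ca/P cutoff therefore rescales between systems by
4.008/3.097 ≈ 1.294: the SI cutoff 2.71 is 3.5 in conventional units at one
decimal.

Albumin-corrected calcium is the standard linear adjustment
`Ca + 0.02·(40 − albumin[g/L])`. When albumin was not measured the correction
is explicitly unavailable (an exception, not a sentinel value) and callers
fall back to total Ca; corrected indices are evaluated only on the
albumin-available subset.

Renal function is the MDRD estimate
`GFR = 186·creat[mg/dL]^−1.154·age^−0.203·(1.210 if black)·(0.742 if female)`.
Creatinine is stored in µmol/L and divided by 88.4 inside the formula, because
the 186 coefficient is defined for mg/dL (the conventional adult reference
interval 0.5–1.4 mg/dL is exactly the stored 44.2–123.8 µmol/L). The formula
accepts any positive age: the database cascade computes GFR before its age
filter, so under-18 rows legitimately pass through it.

## Positivity conventions

Cutoff types carry different boundary conventions, and the package keeps them
explicit rather than forcing one global rule:

* ROC-derived ratio cutoffs are inclusive (`score ≥ cutoff`), so a published
  cutoff classifies itself positive; ties are measure-zero for continuous
  ratios.
* Reference-limit indices are strict: hypercalcemia is Ca *above* 2.65
  mmol/L, PTH excess is *above* 88 ng/L, hypophosphatemia is P *below* 2.5
  mg/dL (0.807 mmol/L). This matters structurally: normocalcemic PHPT is
  defined as Ca ≤ 2.65, so with a strict boundary the serum-Ca index has
  exactly zero sensitivity in that subgroup — an identity the test suite
  asserts, not an empirical accident.
* The combined rule is positive when Ca/P ≥ 2.71 **or** Ca > 2.65; its
  positive set is a superset of the Ca index's, so its sensitivity dominates
  serum Ca's on every cohort.

The PTH index deserves a caveat the package reproduces deliberately: controls
are *defined* to have PTH in range, so PTH's apparent specificity of 100% in
the case-control design is circular, not informative.

## ROC, AUC and the Youden cutoff

Candidate thresholds are the distinct observed scores plus one sentinel above
the maximum — the exact finite-data "best pair" search, not a fixed grid. The
AUC is the Mann–Whitney concordance probability (rank form, half credit for
ties). The operating cutoff maximises Youden's J = sensitivity + specificity −
1; ties break toward the lowest threshold, favouring sensitivity, which is the
natural choice for a screening index. J is maximised in integer arithmetic
(`tp·n0 + tn·n1`) so exact ties are never decided by floating-point noise —
the test suite checks exact agreement with an exhaustive rational-arithmetic
sweep.

The AUC standard error is the Hanley–McNeil approximation with
Q1 = A/(2−A), Q2 = 2A²/(1+A), and the 95% CI is the normal approximation
clipped to [0, 1]; a seeded stratified percentile bootstrap (2000 resamples by
default) is available as an alternative. Monte-Carlo coverage of the 95% CI on
two-normal cohorts sits in the low-to-mid 90s in the test suite, as expected
for the approximation.

Metric percentages keep their raw values; printed tables are integers under an
ambiguous convention (some published cells truncate, some round), so both
half-away rounding and truncation are exposed and assertions against published
integers use convention-invariant cells only.

## Case-control pipeline

Eligibility excludes age < 18 or > 90, MDRD GFR ≤ 30, and any coded chart
exclusion (cancer, malabsorption, lithium, thiazides, bisphosphonates, active
vitamin-D metabolites, severe obesity, active bone disease, ...), in that
fixed order; a record failing several criteria is counted once under the
first. Every stage logs (in, excluded, reason, out) into a flow report whose
conservation is validated structurally.

Ground-truth PHPT status is an input column — chart diagnosis in the original
design, generator truth here; the pipeline never infers truth from
biochemistry. PHPT records split on total Ca at 2.65 mmol/L into
hypercalcemic and normocalcemic subtypes (a configuration switch allows the
split on corrected Ca instead, the ambiguity being genuinely open);
non-PHPT records qualify as controls only with both Ca and PTH in range.

## Database mining cascade

Raw extract rows are refined in the fixed order completeness (all of Ca, P,
PTH, creatinine present) → renal (GFR > 30) → age (18–90). Analyte
distributions are then assessed on the refined set: an analyte whose sample
skewness exceeds 1 in absolute value is log-transformed before centile
computation (PTH, log-normal-like in practice, always triggers; a Shapiro–Wilk
trigger is available via config for sites that prefer a test statistic).
Bounds are empirical 5th/95th centiles with linear interpolation,
back-transformed to the measurement scale.

Labeling is two-stage with a fixed precedence: rows with PTH *or* Ca below
the 5th centile are excluded first as possible hypoparathyroidism (even if the
other analyte is high); of the remainder, rows with *both* PTH and Ca above
the 95th centile are PHPT-like, everything else control. Centile bounds are
computed *before* the hypoparathyroid exclusion, mirroring the original
workflow in which the exclusion consumes the bounds; `bounds_on:
pre_exclusion` records the choice in config. One row is one measurement
occasion; no subject-level de-duplication is attempted (the extract is
anonymous).

Evaluation reports Ca/P at the fixed case-control cutoff 2.71 *and* the
database's own Youden cutoff, mirroring the two published operating points
(2.71 evaluated, 2.64 derived).

## Synthetic data

The generators define the study conditions; they are not tuning knobs.

**Cohort.** 97 PHPT (62 hypercalcemic, 35 normocalcemic) vs 96 controls.
Only medians and min–max ranges are known per group, so distribution families
are a modelling choice: truncated skew-normal for Ca and P, truncated
log-normal for PTH, 25-OH-D and creatinine, truncated normal for albumin.
Each marginal's location is solved by root-finding so a stated quantile of the
truncated distribution matches the published median exactly; scales and shapes
are frozen in the versioned in-module calibration table. Two structural
wrinkles:

* The PHPT group's overall Ca median (2.75) must emerge from a mixture in
  which 35/97 members are ≤ 2.65 by definition; the hypercalcemic marginal is
  therefore calibrated at its (48.5−35)/62 ≈ 0.218 quantile so the mixture
  median lands on 2.75. Normocalcemic Ca is high-normal on [2.35, 2.65]
  (median 2.55) with PTH kept above 88, matching the clinical definition.
* The published control ranges slightly straddle the reference limits the
  control definition requires (Ca minimum 2.07 vs limit 2.12; PTH minimum 14
  vs limit 15). Control marginals are truncated to the intersection so
  generated controls actually satisfy the definition; the labeling code still
  enforces it on arbitrary input.

Ca and P are coupled through a Gaussian copula on ranks (ρ = −0.4 in the
cohort, −0.3 in the database), reflecting their approximately inverse
physiological relationship; the coupling is what gives the ratio its edge over
either analyte alone. Albumin is present with probability 0.75 (cases) / 0.70
(controls), mirroring the reported availability. A single global seed spawns
per-group substreams, so output is byte-identical across runs and adding a
group does not perturb the others.

Across 50 seeds the across-seed median of each group's Ca, P and PTH medians
falls within 1% of the calibration targets (the suite's tolerance is 5%).
The generated separation (Ca/P AUC ≈ 0.96 median across seeds) is at the
upper end of what the published operating point implies — truncated ranges
admit no outlier overlap — which the AUC sanity check therefore evaluates on
the across-seed median rather than any single noisy draw at n = 193.

**Database.** A six-component mixture at n = 20,000 by default: healthy
(73.1%), PHPT-like (2.9%, matching the published prevalence of PHPT-labeled
records), hypoparathyroid-like (8%), renal failure (10%), incomplete panel
(5%), out-of-age (1%). Renal rows invert the MDRD formula at GFR = 30 for
each row's age and sex and draw creatinine strictly above that bound, so the
renal filter catches all of them by construction. Healthy Ca and P are normal
with 90% intervals matching the reported refined-set intervals (2.1–2.5 and
0.8–1.4 mmol/L); healthy PTH is log-normal with median 37 ng/L and log-sd
0.45, giving 5th/95th centiles near the reported 17.5/78 ng/L and a raw-scale
skewness well above the transform trigger. The renal fraction is far smaller
than a real consecutive-sampling laboratory's (where renal exclusions can
approach half the complete panels): the cascade's logic, not its attrition
profile, is what the simulation is for.

What the generators do *not* emulate: assay noise and between-platform bias,
within-subject repeat measurements, seasonal vitamin-D structure, age trends
in any analyte, and the real database's case-mix drift. Passing tests
therefore show that the pipeline implements its definitions correctly under
realistic marginal structure — not that the published accuracy transfers to
any particular laboratory population.

## Numerical and degenerate-input choices

* Marginal calibration roots are found with Brent's method; truncation uses
  `scipy.stats.truncnorm` for (log-)normal families (numerically stable far
  tails) and cdf-inversion with a locally expanded bracket for skew-normals.
* Metrics with zero denominators are explicitly undefined (`None`), never 0.
* ROC construction rejects single-class input and constant scores; the
  distribution assessment rejects constant columns (skewness undefined) and
  fewer than 50 rows.
* Problem sizes in the test suite — 20-seed cohort replications at n = 193,
  one 20,000-row database, 10⁵ points for the binormal closed-form check —
  were chosen as the smallest sizes at which the Monte-Carlo tolerances are
  comfortably non-binding.

## Known limitations

* The exact published cutoffs (2.71, 2.64) and table cells that depend on the
  original patient data are not reproducible from a generator calibrated only
  to medians and ranges; the suite checks bracketing intervals obtained from
  repeat-simulation spread instead.
* The Hanley–McNeil interval is approximate near AUC = 1 (it collapses to a
  point at exactly 1); the bootstrap alternative is preferable there.
* Familial hypocalciuric hypercalcemia, imaging concordance, and clinical
  management are out of scope: the package evaluates biochemical indices only.
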