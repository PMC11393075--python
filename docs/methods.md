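# Methods

This note records the statistical model and conventions the package
implements, the choices made where convention was genuinely open, and
what the synthetic-data tests do and do not establish about real data.

## Data model and parsing

A spontaneous report is one DEMO row plus joined DRUG/REAC/HIST rows.
Child rows with a case id absent from DEMO are collected into an orphan
report rather than failing the load: real spontaneous-report extracts
are dirty, and the analysis proceeds on the joinable subset while the
load summary keeps the evidence.

Ages arrive as integers, decade bands (`"70s"`), qualitative tokens
(`"pediatric"`, `"adult"`, `"elderly"`) or blanks; weights as numbers or
10-kg bands (`"40s_kg"`). Bands map to their **lower bound** (70s → 70,
40s_kg → 40). This is deterministic, and it makes the analysis
dichotomies (age ≥ 70, weight < 50 kg) exact band-membership checks —
the conventional way banded registry data is dichotomised. Qualitative
age tokens are kept distinct from missing values because the exclusion
cascade treats them as a separate rule.

Partial dates keep year / year-month / full resolution. For onset
arithmetic, year-month dates impute **day 1 at both endpoints**; the
induced error in a difference is at most ±30 days and symmetric.
Year-only dates are unresolvable and excluded from latency analysis.

## Exclusion cascade

Six rules run in a fixed order: (1) age < 20; (2) missing sex, age or
weight; (3) qualitative (non-numeric) age; (4) no suspected-role drug;
(5) intravenous administration of an active vitamin D3 analog;
(6) duplicate analog use, read as ≥ 2 distinct analogs among the
suspected drugs — so every exposed case maps to exactly one analog.
Final membership is order-independent (a case violating any rule is
removed); the per-rule attribution is order-dependent, which is why the
order is part of the report and the report always reconciles
(initial − Σ removed = final).

Adverse events are read from REAC, comorbidities from HIST — the only
reading consistent with HIST being medical history. Co-medication
flags (NSAIDs, RASIs, loop diuretics, thiazide-type diuretics,
magnesium oxide) count a drug entry of **any** role other than the
target analog itself: co-administration is what matters, not the
reporter's causality attribution. Aspirin is deliberately absent from
the NSAID class (it appears in reports as an antiplatelet agent), and
the loader enforces that.

## Disproportionality

ROR = ad/bc on the case-level 2×2 with the full-dataset comparator;
CI = exp(ln ROR ± z·√(1/a+1/b+1/c+1/d)); signal ⇔ lower bound > 1.
This Wald/Woolf form is used because it reproduces the published
univariate CIs exactly from the published marginal counts (the
package's embedded validation fixture). Tables containing a zero cell
get 0.5 added to **all four** cells (Haldane–Anscombe) before the ratio
— the standard disproportionality convention — and the result is
flagged `correction_applied`. The p-value attached to a signal is the
two-sided **uncorrected** Pearson chi-square on the raw table; the
uncorrected convention is pinned by the fixture's sex comparison
(269/40 vs 628/134 → P = 0.062; the Yates-corrected statistic does not
reproduce it). Each case counts once per drug regardless of how many
matching drug entries it lists.

## Time to onset

days = resolved(onset) − resolved(start) + 1, so a same-day start and
onset is day 1. Retained observations satisfy 1 ≤ days ≤ 730;
nonpositive values (onset before start — data errors) and values beyond
the 730-day cap are excluded with reason codes, never clamped. When a
case has several qualifying events the **earliest** computable onset is
used (latency to first event). Summaries use linear-interpolation
quantiles and a 4-week-bin histogram over 0–104 weeks; both are
configurable since quantile conventions differ across software.

## Logistic risk model

Forced-entry (no selection) logistic regression of the AKI indicator on
12 binary covariates among exposed cases, maximised by Newton–Raphson /
IRLS with step-halving (the log-likelihood never decreases), converged
when the largest score component < 1e-8 or the relative log-likelihood
change < 1e-10, max 50 iterations. Wald standard errors come from the
inverse observed information; ORs and CIs are exp-transformed. These
are conventional tolerances; all are module constants. A coefficient
exceeding |β| > 15 triggers a separation warning and an unconverged
partial result; a singular information matrix raises an error naming
the collinear columns (via SVD of the design). For a single binary
predictor the fit provably collapses to the 2×2 cross-product ratio and
its Wald interval, and the test suite enforces that equivalence against
the contingency-table route on random tables.

**Calibration.** Hosmer–Lemeshow statistic
Σ (O_g − E_g)² / (n_g·p̄_g·(1 − p̄_g)) on groups of fitted risk,
p-value from χ²(groups − 2). With all-binary covariates the fitted
probabilities take at most 2¹² values and often far fewer; when the
distinct risk patterns number below the requested 10 groups, the test
groups **by pattern** with df = patterns − 2 (the decile rule is
ill-defined under heavy ties), and the output records which grouping
was used. The χ² reference is known to be approximate when patterns
are few and heavily tied; the null-uniformity property test therefore
uses designs with many near-distinct patterns.

**Discrimination.** AUC by the Mann–Whitney concordance form (ties
count ½), equivalent to all-pairs enumeration; CI by DeLong's
placement-value variance, the de facto standard when no method is
stated. The AUC is invariant under strictly monotone score transforms.

## Synthetic data generator

The generator emulates the study conditions: three-analog exposure at
the published scale (621/408/42 exposed per 298,891 reports; scalable
for small runs), twelve independent covariates at the published
other-event-column prevalences, an AKI outcome drawn from a logistic
model whose per-covariate odds ratios default to the published
multivariate estimates, a background AKI reporting rate of 3.5% among
non-exposed reports (which puts the design pooled ROR at ≈ 11.2), and
log-normal onset latencies with median 15.4 weeks and log-sd 1.25 (the
log-sd is fitted to the published IQR 6.5–35.1 around that median; no
distribution is stated for the source data, and the right-skewed shape
is consistent with log-normal). The intercept is solved exactly — the
linear predictor's 2¹²-atom distribution is convolved and bisected — so
the marginal event rate among exposed cases hits its target (0.2885)
in expectation. Dates degrade to missing or year-month at configurable
rates (defaults ~8–10%, a plausible registry level; the source states
none). Planted exclusion-rule violations are appended beyond
`n_cases` with recorded ids so the cascade can be audited case by case.

Because covariates are sampled **independently** (only margins are
published), the generator reproduces marginal prevalences and
conditional odds ratios but not real-world covariate correlation, and
it encodes no reporting biases (stimulated reporting, notoriety
effects). Passing tests therefore establish that the machinery is
correct under the stated generating process — not that real JADER
extracts satisfy those assumptions. The 730-day cap trims ~6% of the
onset distribution's right tail, so the *observable* median in
generated data sits near 14 weeks even though the generating median is
15.4; the recovery tests account for this.

## Validation fixture and problem sizes

The published marginal counts (309 AKI vs 762 other-event cases and
their per-covariate splits) are embedded as a reference fixture; the
univariate odds-ratio and chi-square conventions are pinned by
reproducing the published values from them exactly. The multivariate
estimates cannot be rebuilt from margins alone (they need the joint
individual-level data), so the multivariate path is validated by
parameter recovery instead: at 5,000 exposed synthetic cases every
fitted log-OR falls within 3 standard errors of its generating value,
and across 40 seeds at n = 1,200 the 95% CI covers the generating
hypertension log-OR at the nominal rate. ROR interval coverage is
checked at 93–97% over 1,000 simulated tables. Simulation sizes in the
test suite (e.g. 250 replicates for the Hosmer–Lemeshow null, 40 seeds
for CI coverage) are the package's own choices, sized to keep the suite
fast while leaving the checks well-powered.

## Known limitations

* Bundled PT lists are small synthetic stubs, not MedDRA; real analyses
  must supply licensed SMQ-derived lists via the dictionary loaders.
* Exact-match PT lookup means misspelled or non-PT event text never
  matches (by design — no substring heuristics).
* The Hosmer–Lemeshow χ² reference degrades under heavily tied risk
  patterns; the pattern-grouping fallback is reported but the p-value
  should be read cautiously when patterns are very few.
* Wald intervals (everywhere) are first-order; with very sparse cells
  profile-likelihood or exact methods would differ.
* The exclusion cascade applies rules 1–4 to the whole database and
  5–6 wherever analog entries occur; attribution counts depend on the
  documented order.
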