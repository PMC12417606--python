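# Methods

## Setting and model

`prevlink` estimates ASD prevalence among school-age children (6–18 years)
from an administrative school registry in which ASD status is visible only
through access to a special-education-needs (SEN) programme, and corrects
that estimate using clinical records available for a single health service.
The design has four statistical components, each in its own module.

### Direct standardization and gamma limits (`prevalence`)

All prevalences are age-band × sex standardized:
`p = Σ wᵢ (xᵢ/nᵢ) / Σ wᵢ` with standard weights `wᵢ` (persons). Crude
intervals are exact Poisson limits from chi-square quantiles
(`χ²(α/2, 2x)/2n`, `χ²(1−α/2, 2x+2)/2n`). For the standardized rate we use
the Fay–Feuer gamma construction: with per-capita weights
`w'ᵢ = (wᵢ/Σw)/nᵢ`, rate `y = Σ w'ᵢ xᵢ` and variance `v = Σ w'ᵢ² xᵢ`, the
limits are chi-square quantiles on the scaled-count transform, with the
largest per-capita weight entering the upper limit. This is the canonical
interval for directly standardized rates with small counts; it collapses
to the exact Poisson interval when a single stratum carries its own
population as weight (tested), and approaches normal-approximation limits
for large counts (tested at ≥10,000 cases).

The standardization reference shipped with the package
(`standard_population_synthetic.csv`) is a synthetic stand-in: band × sex
products of the registry's own published marginals. The census projection
actually used for the national analysis is not redistributable; with the
synthetic reference, standardized and crude estimates on generator output
are close by construction. Band-level (not single-year) weights are used
throughout.

Prevalences are carried as proportions internally and rendered as percent
only at the report boundary, 2 d.p., ties to even.

### Fellegi–Sunter linkage (`linkage`)

Clinical patients are matched to ASD-flagged students on date of birth,
sex, commune of residence and a socioeconomic proxy (school-fee band).
Blocking is exact on sex + full date of birth (a `year_month` relaxation
exists but is off by default, matching the observed candidate behaviour of
exact blocking). Comparators:

- dates: 1 on equality, 0.8 on a day/month transposition, 0 otherwise;
- commune: exact, with the best similarity over all communes recorded for
  a patient (patients deduplicated to one candidate per id first);
- fee band: `1 − |rank difference|/5` over the six ranked bands; `Missing`
  and absent values score 0 (counted in the log).

Composite weight: `Σ_f s_f·log₂(m_f/u_f) + (1−s_f)·log₂((1−m_f)/(1−u_f))`
— fractional similarities interpolate linearly between the agreement and
disagreement weights (Winkler-style). Default m/u values are conventional
rather than estimated (EM estimation is out of scope): dob 0.95/0.001,
sex 0.98/0.5, commune 0.9/(1/#communes), fee band 0.8/0.2. With 21
communes, full agreement scores ≈17.1 bits.

Assignment is greedy by descending weight with a 12-bit acceptance
threshold, one-to-one on both sides, ties broken lexicographically by
(student_id, patient_id) so results are invariant to row order. Pairs
scoring 8–12 bits are exported as a grey zone for human review (the
clerical-review step of a production linkage is inherently manual; the
threshold replaces it here). The 12-bit default sits between a
full-agreement true pair that lost its commune (≈9.6 bits) and a blocked
non-match that happens to share a commune (≈15 bits); those two
configurations overlap in principle and are exactly what the grey zone is
for.

Cohen's κ `(p_o − p_e)/(1 − p_e)` is provided for diagnostic-validation
agreement tables.

### Adjusted prevalence delta and unmet need (`bayes`, `pipeline`)

In the clinical service, corrected cases = SEN-accessing (flagged) students
plus clinical patients with no registry match. The delta is the difference
in percentage points between the corrected and school-only standardized
prevalences (applied additively — the published per-service arithmetic is
additive, e.g. 0.43 → 1.28). Its carried CI width is the maximum of the
two source interval widths. Unmet need = corrected cases minus
SEN accessors.

### Bayesian projection (`bayes`)

For each service *s*:

    p_s ~ Uniform(lower_s, upper_s)        lower = school prevalence,
                                           upper = lower + delta
    b_s ~ Normal(0, σ²),  σ ~ Half-Normal(1)
    y_s ~ Binomial(n_s, logit⁻¹(logit p_s + b_s))

`y_s` is the adjusted expected school case count (`lower_s · n_s` by
default; raw counts can be passed instead via `ServicePrior.y`, and
`y=None` gives prior-only sampling). The exact likelihood/random-effect
structure behind the published projection is not fully documented anywhere
public; this structure is the simplest one consistent with every published
statement (bounded uniform priors, adjusted case counts, a random effect on
health service), and it is confined to `ServicePrior`/`run_mcmc` so
alternatives can be slotted in.

The sampler is Metropolis-within-Gibbs, fully vectorized over chains and
services: a random-walk update of `p_s` on the logit of its rescaled
position inside the prior box (support containment is therefore
structural, not clipped), a random-walk update of `b_s`, a joint "ridge"
move that shifts `p_s` and compensates `b_s` to keep the likelihood
invariant (the likelihood pins `logit p_s + b_s`, so single-site moves
alone mix poorly along that ridge), and a log-scale update of σ. Step
sizes auto-tune during burn-in toward a 20–50% acceptance rate. Defaults:
2000 burn-in + 2000 kept iterations, no thinning, 4 chains, split R-hat
per service via arviz with a 1.1 convergence flag. The sampler is checked
against a Riemann grid integration of the (p, b) posterior at fixed σ
(agreement within 0.02 percentage points in posterior mean) and against
prior-only and degenerate-prior limits.

Reported credible bands around the per-service projections follow the
published construction: centred on school prevalence + delta with width
`max(school CI width, delta CI width)`, truncated to [0, 100]. Posterior
summaries (mean, histogram mode, central 95% interval) are reported
alongside.

### Access determinants (`determinants`)

Adjusted prevalence ratios for SEN access use Poisson regression with log
link on the binary ASD flag and the robust sandwich variance
`H⁻¹(Σ gᵢgᵢᵀ)H⁻¹` (statsmodels GLM, HC0), with reference levels girls /
6–8 years / non-immigrant / no native group / free fees / urban, and a
two-sided p < 0.001 significance flag (multiplicity-conservative; p-values
are never used for selection). The companion two-level mixed-effects
logistic sensitivity model is intentionally out of scope
(`MIXED_MODEL_NOTE`): it requires the confidential full registry.

## Synthetic data generator (`simulate`)

The generator emulates the study conditions and carries full ground truth:

- 29 services with the published child populations; per-service true
  prevalence = published school prevalence + 0.85 points; per-service
  school detection probability = school/true, so registry flag prevalence
  reproduces the published school prevalence (for the clinical service:
  true 1.22%, detection 0.37/1.22).
- male:female risk ratio 6 and a declining band gradient
  (1.25, 1.09, 0.88, 0.78), both renormalized to preserve marginal
  prevalence; demographic marginals (sex, band, fee band, ethnicity,
  rurality) from the published registry table; immigrant share 3% (not
  published; plausible for the 2021 enrolment).
- EHR rows only for the clinical service. Clinical capture defaults to
  1.0 for truly autistic children: the published corrected case count
  equals essentially all true cases in the clinical service (488 + 1132 ≈
  1.22% of 132,242), i.e. the 8-year clinical window was treated as
  exhaustive. Tests vary this.
- field corruption, independently per field: dob day/month swap when valid
  else ±1 day (rate 0.02), commune mis-recorded (0.02), fee band
  off-by-one (0.05); 2% of patients carry a duplicate row under a second
  commune; 2% of students have a missing address, imputed from their
  school's commune.
- date of birth uniform within the age band relative to the reference date
  (2021-06-30), so bands and dobs are always consistent.

What it does **not** emulate: school-level clustering beyond a school-id
label, the 28 distinct SEN categories (binary ASD only), false-positive
clinical diagnoses (diagnostic validity was near-perfect in the source
setting), regionally varying capture, and any correlation between field
errors. Passing tests therefore show the pipeline recovers truth under
independent administrative noise, not that it would survive systematically
biased records.

Identical config + seed gives byte-identical CSVs; the pipeline cascades
one global seed into per-stage seeds via `SeedSequence` spawns.

## Problem sizes in tests and the acceptance script

Module and acceptance tests use a single clinical-style service of
20,000–200,000 children (200,000 for the prevalence-ratio recovery, the
study's own order of magnitude for one service), 20 seeds for the
stochastic properties, and the full 2000+2000×4 MCMC configuration. The
acceptance script runs the complete pipeline at one quarter of the
registry population (≈764,000 children), where the delta is measured with
a standard error of about 0.07 points, plus a ten-seed linkage accuracy
experiment at n = 30,000.

## Known limitations

- The gamma upper limit caps at 100%; degenerate standard populations
  (single stratum) are allowed and collapse to exact Poisson limits.
- m/u weights are declared configuration, not estimated from data; linkage
  quality claims hold under the generator's error model.
- The projection assumes the school/clinical gap is uniform across
  services — the central design assumption of the source analysis; the
  random effect absorbs service-level likelihood misfit but cannot rescue
  a regionally varying delta.
- The published 64.57% unmet-need share derives from age–sex-adjusted
  posited counts (40,113) that cannot be recomputed without the census
  weights; recomputing the share from the published counts gives 64.575…%,
  which rounds to 64.58 rather than the printed 64.57.
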