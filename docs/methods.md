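# Methods

## The problem being simulated

When a second-line drug is compared with a first-line drug whose
indication shares symptoms with the outcome under study, patients whose
outcome is initially misdiagnosed as the indication are over-represented
among second-line users: refractory "indication" symptoms are exactly
what drives both switching and, eventually, the corrected diagnosis.
Even with no causal effect, the second-line drug then appears to raise
the outcome hazard — reverse-causation (protopathic) bias.

`protosim` quantifies this mechanism for the motivating case: topical
tacrolimus (second-line) vs topical corticosteroids (TCS, first-line)
for atopic dermatitis (AD), with cutaneous T-cell lymphoma (CTCL) as the
outcome. CTCL can masquerade as AD for years before it is correctly
diagnosed. The simulation builds the null in by construction — no
treatment influences any hazard — so any hazard ratio away from 1 is
pure design-induced bias.

## The multistate model

Every patient is simulated from birth through the states *healthy* →
*AD-treated* (TCS or tacrolimus compartments; TCS→tacrolimus switching
allowed, never the reverse) → *CTCL diagnosed* (absorbing), with death
as censoring. Per patient the following latent quantities are drawn
(all inverse-CDF transforms of uniforms; units are years of age unless
noted):

| Quantity | Law | Default parameters |
|---|---|---|
| AD onset `T_AD` | case with prob. 0.105; cases: mixture of Exp(mean 3.2 y) (w.p. 0.63) and Uniform(18, 100) | see "AD onset calibration" |
| CTCL onset `T_CTCL` | Exponential, constant rate λ_CTCL | 6 × 10⁻⁶ / person-year |
| Censoring `T_CENS` | `(1 − U²)·100` on [0, 100] | mean 200/3 ≈ 66.7 y |
| Correct initial CTCL diagnosis `Q` | Bernoulli(p1) | setting-specific |
| TCS first-line `S` | Bernoulli(p2) | setting-specific |
| Switch, true AD `P` | Bernoulli(p3) | setting-specific |
| Switch, misdiagnosed CTCL `R` | Bernoulli(p4) | setting-specific |
| TCS non-response duration `S1` | 40%: `1 − U²` (< 1 y); 60%: 1 + Exp(rate 3) (≥ 1 y) | `p_short_switch = 0.40` |
| Re-evaluation delay `S2` | max of n = 2 Weibull(scale λ, shape 0.9) draws | λ = 3.5 y (main setting): median 4.40 y |

Diagnosis resolution: if `T_AD < T_CTCL` the patient is diagnosed with
AD at `T_AD`. If CTCL comes first, the patient is misdiagnosed with AD
at `T_CTCL` with probability 1 − p1 (then the CTCL diagnosis arrives
only at `T_AD,OBS + S2`), or correctly diagnosed at once with
probability p1 (then AD treatment, if any, starts at the true `T_AD`).
Treatment starts at the AD diagnosis: TCS with probability p2, else
first-line tacrolimus; TCS starters switch to tacrolimus after `S1` with
probability p3 (true AD) or p4 (misdiagnosed CTCL). Events that never
happen are held at a sentinel age (1e9) or, for treatment times per the
model's bookkeeping, at the censoring age.

## AD onset calibration

The AD age-at-onset distribution is specified through population
anchors rather than a closed-form rate: cumulative risk 6–7% by age 18
and 10–11% by age 100, with a median onset among cases of about 5
years. The default sampler is a calibrated mixture solved in closed
form to hit these anchors: eventual-case probability 0.105; cases draw
from {0.63: Exponential(mean 3.2 y), 0.37: Uniform(18, 100)}, giving
P(onset ≤ 18) = 0.105·0.63·(1 − e^(−18/3.2)) = 0.0659, P(onset ≤ 100) =
0.105 and P(onset ≤ 5 | case) = 0.498. The sampler is pluggable via
`ADOnsetCalibration`; the historical exponential-rate constant
λ_AD = 1.28 × 10⁻⁶ is kept on `ScenarioParameters` for a literal
substitute but is unused by the default.

The short/long switch split is taken as 40% of switchers under one year
(`p_short_switch = 0.40`, configurable), matching the descriptive
account of the switching process.

## Cohort design emulation

Each replicate samples a fresh base population of 4,000,000 patients
and extracts the AD cohort: a patient enters at
`max(r0, age at AD diagnosis)` with `r0 ~ Uniform(0, 100)` drawn
independently of all latent times, and exits at
`min(r0 + 12, T_CENS, T_CTCL,OBS)`; inclusion requires strictly
positive at-risk time. A CTCL diagnosis at the exit age is an event
(ties break in favour of the event; a diagnosis exactly at entry is
excluded — zero at-risk time). Under the main setting this yields
cohorts of roughly 2 × 10⁵ patients and ~130 events per replicate.

The analysis timescale is time since treatment initiation, so entry
after treatment start produces left truncation. Exposure is ever-use:
person-time is first-line (TCS) until the first tacrolimus use and
second-line thereafter, encoded as (start, stop] counting-process rows
with at most one split per patient.

## Estimators

**Cox model.** One binary time-dependent covariate (ever-use of
tacrolimus). With a binary covariate the Breslow partial likelihood
depends on the data only through per-event-time risk-set counts
(n₀, n₁) and event splits (d₀, d₁); these are computed once by sorted
search (`start < t ≤ stop`), after which the scalar Newton iteration
runs to absolute score tolerance 1e-10 (max 50 steps), with the
standard error from the observed information. Breslow tie handling is
adopted because event times are continuous (ties have probability
zero), so the choice is immaterial while keeping the likelihood simple
enough to cross-check by brute force. Monotone likelihoods (all events
on one arm) are reported as non-converged fits, counted and excluded
from summaries rather than raised. Significance is the two-sided Wald
test at α = 0.05.

**Incidence rates.** Per exposure group, events / person-years scaled
to 1,000 person-years — the closed-form MLE of a Poisson model with a
log person-time offset (asserted as an identity against a GLM in the
tests).

**Summaries.** Across replicates: median, 95% reference interval
(2.5th–97.5th percentile, linear interpolation between order
statistics), min–max, percent significant among usable replicates, and
the count of excluded (non-converged/degenerate) replicates.

## Reproducibility

Replicate `r` of a run keyed by `master_seed` uses the independent
stream `SeedSequence(master_seed, spawn_key=(r,))`, split once more into
the population seed and the inclusion-age seed. Within a replicate each
variable consumes one vectorised block of draws in a fixed, documented
order. Results are therefore bit-identical across runs, batch sizes and
parallel scheduling.

## Problem sizes used in the test suite

The headline settings (A1, B1, B3) are checked at 100 replicates of
full-size 4-million-patient populations; medians are compared at three
bootstrap standard errors of the replicate median, percentages at three
binomial standard errors, counts at three binomial standard deviations.
The bias-ordering and null-recovery properties use a desk-scale
configuration — 250,000 patients with the CTCL onset rate raised
tenfold (6 × 10⁻⁵) — chosen so each replicate keeps a realistic event
yield while the outcome stays rare; because the bias mechanism depends
on the *composition* of person-time rather than the absolute event
rate, median hazard ratios at this scale track the full-size values
closely (verified against the full-scale batches).

## What the generator does and does not emulate

It emulates: rare-outcome onset misdiagnosed as a common indication,
first/second-line treatment dynamics with symptom-driven switching,
registry-style random administrative windows, left truncation, and
ever-use exposure classification. It does not emulate: confounding (no
covariates influence both treatment and outcome), any causal treatment
effect on any hazard, age-varying CTCL incidence, competing cancers,
country-level heterogeneity, or lag-time (event-lagging) analyses.
Passing tests therefore demonstrate the magnitude of reverse-causation
bias under the stated mechanism — not that real-world estimates are
free of other biases.

## Numerical choices and degenerate inputs

- "Never" sentinel 1e9 years, strictly above any attainable follow-up
  age; serialised as missing in tabular dumps.
- Exact ties `T_AD = T_CTCL` (probability zero) resolve to the AD-first
  branch; CTCL diagnosis at the window boundary counts as an event.
- Uniform draws from the generator are nudged off exact 0 (probability
  2⁻⁵³) so inverse-CDF transforms stay finite.
- `log1p` is avoided on hot paths (no SIMD in this numpy build);
  `log(1 − u)` is used instead, and the max-of-two-Weibull delay is
  computed by taking the max in u-space (the transform is monotone).
- Coefficients beyond |log HR| > 15 are treated as saturation
  (separation), flagged non-converged.

## Known limitations

- The one-covariate Cox fit is exact for this design but does not
  generalise to multiple covariates or stratification.
- The AD-onset mixture matches the stated anchors, not any specific
  national incidence curve; absolute cohort sizes are therefore
  approximate (order 10⁵), though the bias mechanism is insensitive to
  this.
- Reference intervals at 100 replicates are noticeably wider than at
  1,000; only medians and percentages are asserted at desk scale.
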