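# Methods

## Model and estimands

Consider a population in which each person is followed over age, subject to
right censoring and possibly delayed entry (left truncation), and in which
death is classified into K mutually exclusive causes. For a conditioning
age *a* and a restriction age τ, the quantities estimated are

* the conditional survivor function `S(t | a)` for `t ∈ [a, τ]`,
* the cause-specific cumulative incidence functions `F_k(t | a)` with
  `S + Σ_k F_k ≡ 1`,
* the τ-restricted remaining life expectancy `LE(a) = ∫_a^τ S(t|a) dt`,
* the Life Years Lost `LYL(a) = (τ − a) − LE(a) = Σ_k ∫_a^τ F_k(t|a) dt`,
* onset-weighted averages `Σ_i n_i LYL(i) / Σ_i n_i` over integer onset
  ages *i*, and
* excess LYL: the diseased value minus a reference population's value at
  the same age(s).

Restricting to τ is essential: with censored observations the survivor
curve need not reach zero, so the unrestricted mean lifetime is
ill-determined. When censoring is administrative at a fixed age (95 in the
default synthetic population, 90 in aggregated examples), τ must be capped
there and the result reads as "life lost before τ".

Interpretation is descriptive, not causal: LYL summarizes observed
mortality differences; it does not correspond to an intervention.

## Estimators

**Product limit with delayed entry.** The risk set at event age *t*
contains every person with `max(entry, a) < t ≤ exit`. Persons entering
follow-up after the landmark *a* join at their entry age; this maximizes
information use and is the standard delayed-entry convention. All events at
one age are processed jointly against the risk set just before that age;
censorings tied with deaths remain in the risk set for those deaths.

**Aalen–Johansen CIFs.** `F_k` accumulates `S(t−) d_k / n` over event ages.
The survivor curve is reported as `1 − Σ_k F_k` (mathematically identical
to the product limit; the `S(t−)` factors come from the product-limit
recursion), so the additivity identity holds exactly at every jump rather
than only up to accumulated round-off.

**Integration.** Curves are right-continuous step functions; ages are
continuous with no internal rounding; restricted areas are exact sums of
`value × segment width`. After the last observed event the curve is flat to
τ, the usual Kaplan–Meier extension.

**Life tables.** A reference given per integer age as survivor proportions
and/or mortality rates is treated as piecewise exponential within years:
`survivor(x+1) = survivor(x)·exp(−rate_x)`. Either column suffices; when
both are present they must be mutually consistent to 1e-6 (otherwise an
error — no silent preference), and survivor proportions are then used. Year
areas use the closed form `S(x)·(1 − e^{−r})/r` with the limit `S(x)·w` at
`r = 0`; fractional conditioning ages interpolate through the within-year
exponential.

**Aggregated mode.** When the diseased group is only available as
age-specific rates plus new-case counts, both sides are piecewise
exponential and the per-age excess is averaged with the new-case weights.
The landmark construction is implicit in the diseased table (its rates are
read as conditional-on-onset mortality from each age onward). No bootstrap
is offered here — there is no individual resampling unit — so aggregated
reports are point estimates only.

**Bootstrap.** Percentile intervals from resampling individuals with
replacement (the simplest defensible non-parametric choice; BCa was
deliberately not implemented). Quantiles use numpy's default linear
interpolation. One master seed spawns independent per-iteration
`SeedSequence` streams, so runs are bit-reproducible and extending `niter`
keeps earlier replicates. Replicates whose resample leaves an empty risk
set are redrawn, with a capped retry count. For range estimates the onset
weights are held fixed across replicates: they describe the distribution
being averaged over, not a sampled quantity.

## Key parameters

| parameter | meaning | default |
|---|---|---|
| `tau` | restriction age (years); cap at the administrative censoring age | 95 (individual), 90 (aggregated examples) |
| `condition_age` / range | landmark age(s), years; range mode uses integer ages | — |
| `niter` | bootstrap iterations | 1000 (CLI); diagnostics can confirm sufficiency |
| `level` | CI level | 0.95 |
| `censor_label` | reserved status string | `"alive"` |

Weight binning for onset ages is by floor (an onset at 45.9 counts at age
45), consistent with treating possible onset ages as integers; ages with
zero weight stay in the table but contribute nothing. Ages whose risk set
is empty yield flagged missing rows, never interpolation, and an error if
weighted.

## Synthetic data

`simulate_population` emulates a register cohort followed from birth:
constant onset hazard 0.012/y; pre-onset cause-specific hazards
natural 0.0235, unnatural 0.0015; post-onset 0.037 and 0.004;
administrative censoring at 95. Competing causes use independent
exponential latent times, an exact construction when cause-specific
hazards depend only on attained age (piecewise-constant per-year hazard
arrays are also supported, sampled by inverting the cumulative hazard).
Under the defaults ~31% of persons develop the disease and ~7% of deaths
are unnatural — the counts a moderately severe chronic-disease register
would show. What this generator does **not** emulate: age-varying hazard
shapes of real mortality (infant mortality, old-age acceleration), an
onset-age distribution peaking in mid-life (the constant onset hazard
front-loads onsets), duration-since-onset effects, and dependent
censoring. Passing tests therefore demonstrate estimator correctness
under the stated sampling model, not robustness to those real-data
features.

`constant_hazard_cohort` plus `closed_form_lyl` form the analytic oracle:
with total hazard Λ over a horizon Δ = τ − a, `LE = (1 − e^{−ΛΔ})/Λ` and
cause k takes share λ_k/Λ of the loss.

## Numerical choices and degenerate inputs

* Zero-length follow-up intervals are rejected at construction.
* A landmark past the last exit is an error naming the age ("no
  individuals at risk"); a cohort with no events yields a flat curve and
  zero loss, which is valid.
* Additivity holds exactly by construction; survivor values are clipped at
  0 against ulp-level negatives.
* A reference supplied without replicates is treated as estimated without
  uncertainty (reasonable for whole-population registers and national
  life tables); when both sides carry replicates they are paired by
  iteration index and must share `niter`.
* Life-table comparisons are total-only (standard life tables carry no
  causes); the diseased side's cause decomposition is still reported.

## Validation sizes

The statistical checks run at sizes chosen to keep Monte-Carlo error well
below the asserted tolerances: exhaustive hand-recursion agreement on all
3^n status patterns for n ≤ 6; closed-form recovery at n = 100,000 within
0.3 years; bootstrap coverage over 200 cohorts of n = 2,000 with
niter = 200 within 0.95 ± 0.04; aggregated-versus-individual consistency at
n = 100,000 within 0.2 years.

## Known limitations

No covariate adjustment, smoothing, parametric fits, or interval
censoring; no estimation of the onset distribution from illness–death
transition intensities (observed onset counts are used as weights);
independent censoring is assumed throughout, as in standard time-to-event
analysis. Negative excess values are meaningful (a cause can show negative
excess when competing causes preclude it) and are reported as-is.
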