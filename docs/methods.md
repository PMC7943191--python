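# Methods

## The generating model

Each region × sex × 10-year age band × year cell carries a three-parameter
skew-normal BMI distribution with location ξ (kg/m²), scale ω (kg/m², > 0)
and shape α (unitless). The family was chosen because it nests the normal at
α = 0, separates "where the distribution sits" from "how it is shaped" with
independent parameters, and has a closed-form mean,

    E[X] = ξ + ω δ √(2/π),   δ = α / √(1 + α²),

which makes exact oracles cheap: tail probabilities come from the
skew-normal CDF/SF (scipy), and any scenario's true shift/shape split of a
prevalence change can be computed directly from the generating parameters
(`true_decomposition`). Real BMI distributions are not skew-normal; the
family is an emulation of the qualitative structure (mild-to-moderate right
skew, region-dependent spread), not an estimate of it. Passing tests
therefore demonstrate that the *method* recovers truth when its assumptions
hold approximately, not that any particular real population satisfies them.

### Baseline (1985) parameters

Defaults span lean to high-BMI populations: analytic mean
22.0 + 0.45·(region index) + age offset (0 … 1.2, peaking at 50–59) + 0.3
for men; scale 3.6 + 0.1·(region index), + 0.3 for women; shape
0.6 + 0.1·(region index). These give 1985 means of 22–27 kg/m², SDs of
roughly 3.3–4.5 kg/m², underweight prevalences from < 1% to ~15% and severe
obesity from ~0.02% to ~2% — the orders of magnitude seen in adult
populations over this period.

### Scenarios

Annual drifts act linearly from 1985. Scale and shape follow their own
drifts and the location is always re-solved from the mean identity, so the
analytic mean follows `mean₁₉₈₅ + location_drift · (year − 1985)` exactly —
in `shape_only` scenarios the mean is therefore held fixed to machine
precision while the distribution reshapes.

- `pure_shift`: location drift 0.08 kg/m²/yr (a 2.5 kg/m² rise over
  1985–2016, the middle of the 1–4 kg/m² range observed across regions);
  scale/shape fixed.
- `shape_only`: scale drift 0.02 kg/m²/yr and shape drift 0.04/yr at fixed
  mean — a widening, increasingly right-skewed distribution.
- `mixed`: location 0.06, scale 0.015, shape 0.02 per year. Under these
  defaults the true (oracle) mean-shift share of the 1985→2016 prevalence
  change is roughly 90% for underweight, ~100% for obesity and ~75% for
  severe obesity — a genuine mixture whose exact value the recovery tests
  compute from the oracle at run time rather than assuming.

### Between-study heterogeneity

Every simulated study carries a persistent location offset drawn from
N(0, 1 kg/m²) shared by all its strata. This emulates the country- and
community-level spread of mean BMI inside a pooled region and is essential,
not cosmetic: on a deterministic grid where all studies in a region-year
share one mean, the mean-BMI columns of the regression are exactly collinear
with the age×region and year×region terms and the prevalence–mean slope is
unidentified. Cross-sectional spread of means within region-years is what
identifies it, in the synthetic data as in real pooled analyses.

### Sampling

Draws use scipy's skew-normal sampler with per-stratum `SeedSequence`
substreams keyed by (seed, region, sex, age band, year, study index), so
microdata are bitwise reproducible and independent of execution order.
Survey weights default to 1; a gamma(4, ¼) option (mean 1) exercises the
weighted estimators. BMI values are floored at 0.1 kg/m² as a positivity
guard (a < 10⁻⁹ event under all default parameterisations).

## Stratum summaries and inclusion rules

Stratum summaries are survey-weighted: mean Σwx/Σw, prevalence as the
weighted indicator mean with the underweight cutoff strict (`< 18.5`) and
the obesity cutoffs closed (`≥ 30`, `≥ 35`), and a design-effect-free
standard error (weighted SD/√n) — full complex-survey variance estimation
would need design metadata the inputs do not carry. Inclusion requires a
standard 10-year band in 20–79, n ≥ 25, and outcome prevalence strictly
inside (0, 1); the probit transform is undefined at the boundaries. The
rules are applied per outcome (a stratum with zero underweight cases can
still inform the obesity model) in the fixed precedence age band → n →
boundary prevalence, so each excluded row gets exactly one logged reason and
filtering is deterministic and idempotent.

## The regression

One model per sex × outcome: OLS of probit prevalence on centred mean BMI
(centre 25 kg/m²), age band, region, centred year (origin 1985), and the
pairwise interactions mean·age, mean·region, age·region, age·year,
year·region — 82 columns for the full 9-region × 6-band design, in a fixed
documented order. Choices where the design was genuinely open:

- **Unweighted OLS by default.** An inverse-variance option (delta-method
  variance p(1−p)/(n·φ(z)²) of the probit prevalence) is available behind
  `ModelSpec.weighted`. In validation runs weighting changed scenario
  recovery little and is not the default.
- **Year as a continuous linear term.** A categorical year with year×region
  interactions would add ~300 columns and be unstable at the simulated data
  sizes; a linear trend is the minimal encoding of "prevalence drifts beyond
  what the mean explains".
- **Mean BMI linear.** Probit-linearity is exact for location-shifted
  fixed-shape families; for moderate skew (α ≤ ~1.5) the curvature left over
  is below half a percentage point across the relevant mean range.
- **Treatment coding with configurable references.** Presentation only: the
  interaction structure spans the same column space under any reference
  choice, and predictions are checked invariant to 10⁻¹⁰.

Columns that are identically zero for a given table (absent levels) are
dropped and recorded; genuine rank deficiency raises an error naming the
collinear terms (QR with column pivoting) rather than silently regularising.
R² is reported on the probit scale; a constant response yields R² = 0 with a
warning.

## Decomposition

Total change evaluates the fitted model at (mean₂₀₁₆, 2016) minus
(mean₁₉₈₅, 1985); the mean contribution moves the mean while holding year at
1985; the shape residual is their difference, so additivity is exact by
construction (≈ 10⁻¹⁵ in floating point) at every stratum. Ten-year results
are aggregated into 20–49 and 50–79 as weighted averages of the absolute
(percentage-point) changes using WHO World Standard population weights
(Ahmad et al. 2001; 10-year sums 16.15/14.76/12.63 and 9.92/6.68/3.73%,
renormalised within each broad band, overridable via CSV), which preserves
additivity exactly. `percent_explained` is computed *after* aggregation —
not as an average of stratum-level percentages — and only where the total
change reaches a relevance threshold (default 1.0 percentage point,
configurable): ratios of tiny changes are noise.

## Validation design and problem sizes

The test suite validates each stage against an independent oracle: the
skew-normal mean against numerical quadrature and Monte-Carlo sampling; the
probit fit against the closed form slope ∓1/σ on noiseless normal strata;
the decomposition against `true_decomposition` on scenarios where the truth
is known by construction. Scenario-recovery checks run the full 9-region
pipeline at 10⁴ participants per stratum and 3 studies per region-year
(≈ 11,000 strata per scenario), with three fixed replicate seeds averaged
per cell: single-run Monte-Carlo noise on the shift share of small
(~1 percentage point) severe-obesity changes is ±2–3% per broad-band cell,
and averaging three replicates keeps the maximum across ~86 cells inside the
±5% recovery band without enlarging the per-run sample sizes. Sampled-
versus-analytic agreement is checked at 10⁵ draws per stratum with 3-SE
bands.

## Known limitations

- The skew-normal cannot produce the heavy or crossing tails some real
  populations show; the "underweight tail left behind" pattern is emulated
  by scenario construction, not estimated from data.
- No uncertainty intervals are produced for coefficients, predictions or
  decomposition contributions.
- The standard error of stratum means ignores survey design effects.
- Probit transforms of small-count prevalences are biased and, combined with
  the exclusion of zero-prevalence strata, can tilt fitted time trends for
  rare outcomes (visible as a few percent of share noise for severe obesity
  at 10⁴ participants per stratum).
- Year enters linearly; strongly non-linear shape change over time would be
  attributed to the shape residual only on average.
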