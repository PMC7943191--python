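# bmishift

Tools for asking how much of a change in the prevalence of underweight
(BMI < 18.5 kg/m²), obesity (BMI ≥ 30 kg/m²) and severe obesity
(BMI ≥ 35 kg/m²) is explained by a shift of the whole population BMI
distribution, versus a change in the distribution's *shape* (its spread,
skewness or tails). The question matters to epidemiologists and nutrition
policy analysts: a uniform shift and a "left-behind" underweight tail call
for different interventions, but both move prevalence.

## The model

For each sex and outcome, stratum-level prevalence is probit-transformed and
regressed on population mean BMI:

```
Φ⁻¹(pᵢ) = β₀ + β₁·(mᵢ − 25) + age + region + year
         + mean·age + mean·region + age·region + age·year + year·region
```

where `pᵢ` is the weighted prevalence and `mᵢ` the weighted mean BMI of a
study × sex × 10-year age-band stratum (ages 20–79, nine world regions,
years 1985–2019). The probit scale is the natural one: if the BMI
distribution translates with fixed shape, `Φ⁻¹(p)` is *linear* in the mean
(exactly so for a normal population, with slope ∓1/σ for the lower/upper
tail). Strata with fewer than 25 participants, non-standard age bands, or
prevalence exactly 0 or 1 are excluded (logged, per outcome).

The fitted model then supports a counterfactual decomposition of the
1985→2016 prevalence change in every region × sex × age band:

- **total change** = P(mean₂₀₁₆, year 2016) − P(mean₁₉₈₅, year 1985)
- **mean contribution** = P(mean₂₀₁₆, year 1985) − P(mean₁₉₈₅, year 1985)
- **shape residual** = total − mean contribution (exactly additive)

Age-band results are aggregated into 20–49 and 50–79 using WHO World
Standard population weights, and a share "percent explained by the mean
shift" is reported wherever the total change reaches 1 percentage point.

Because the real pooled anthropometry database is not openly redistributable,
the package ships a first-class synthetic generator: skew-normal BMI
populations (location ξ, scale ω, shape α) per region × sex × age × year,
with scenarios that translate the distribution (`pure_shift`), reshape it at
exactly fixed mean (`shape_only`), or both (`mixed`). Every scenario exposes
closed-form oracles (means, tail probabilities, true shift/shape split), so
the whole pipeline is verifiable end to end.

## Worked example

```python
import bmishift as b

summaries, trajectories = b.make_fixtures(seed=0)   # mixed scenario, 540 strata
women = summaries[summaries.sex == "female"]
included, excluded = b.apply_inclusion_filters(women, "underweight")
coef = b.fit_model(included, b.ModelSpec(outcome="underweight", sex="female"))
print(coef.r_squared, coef.n_obs)                   # 0.995 267

profile = b.regional_prevalence_profile(coef, 25.0, "50-59", 2016)
print((100 * profile).round(1))
```

The profile is the predicted underweight prevalence (%) for women aged
50–59 in 2016 if every region sat at a mean BMI of 25 kg/m²:

```
Central and Eastern Europe                         2.4
Central Asia, the Middle East, and North Africa    2.5
East and Southeast Asia                            2.3
High-income Asia Pacific                           2.1
High-income Western                                1.7
Latin America and the Caribbean                    2.0
Oceania                                            2.0
South Asia                                         1.8
Sub-Saharan Africa                                 3.4
```

so regional spread at a common mean is 1.7 percentage points here, and
`b.unit_bmi_relative_change(coef, 25.0, "50-59", "Sub-Saharan Africa", 2016)`
reports −60.7: one extra unit of mean BMI predicts a 61% relative drop in
underweight prevalence in that region. Fitting all six models and calling
`b.run_decomposition` yields rows like (women, obesity, ages 20–49):

```
region                total_change_pp  mean_contribution_pp  shape_residual_pp  percent_explained
Oceania                         10.39                  9.96               0.44              95.80
South Asia                      11.59                 11.65              -0.05             100.46
Sub-Saharan Africa              12.69                 13.59              -0.90             107.06
```

i.e. in this mixed scenario nearly all of the simulated obesity rise is
carried by the mean shift, with a small shape contribution either way.

The same pipeline runs from a shell:

```
bmishift run-all --scenario pure_shift --seed 0 --out results/
bmishift fit --input strata.csv --outcome obesity --sex female --output coef.csv
```

and accepts user-supplied stratum-summary and mean-trajectory CSVs in the
documented schemas in place of a scenario.

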