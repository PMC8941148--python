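# aapflux

Quantifying the photoheterotrophic metabolism of aerobic anoxygenic
phototrophic (AAP) bacteria in lake surface waters, and what ignoring it
does to whole-lake carbon budgets.

AAP bacteria harvest light with bacteriochlorophyll-*a* reaction centers
(absorption ~870 nm) and use the photochemical ATP to relieve
respiration and boost substrate assimilation. Because community
respiration is conventionally measured in the dark, it is overestimated
whenever AAP bacteria are abundant. The experimental remedy is a paired
incubation: bottles in the dark versus bottles behind an infrared (IR)
filter passing only >740 nm light — usable by AAP reaction centers but
invisible to oxygenic phototrophs — so the dark−IR rate difference
isolates AAP photoheterotrophy.

`aapflux` implements the complete measurement-to-budget chain for such a
campaign, for aquatic microbial ecologists and biogeochemists:

- **winkler** — Winkler titration chemistry (1 mol O₂ ≡ 4 mol S₂O₃²⁻,
  KIO₃ standardisation, reagent-displacement correction) to dissolved O₂,
  respiration and net primary production (NPP) rates.
- **carbonate** — total alkalinity by Gran titration
  (F(Vₐ) = (V₀+Vₐ)·10^(−pH), x-intercept = equivalence volume) and DIC
  from temperature/pH/alkalinity via freshwater carbonic-acid constants.
- **radiotracer** — ³H/¹⁴C monomer assimilation (glucose, pyruvate,
  leucine, thymidine) from scintillation DPM with killed-control
  subtraction, and fractionated H¹⁴CO₃⁻ incorporation scaled by the DIC
  pool.
- **mixedlm** — the light effect per analyte from a random-intercept
  linear mixed model fitted by maximum likelihood,

  y_ij = β₀ + β₁·IR_ij + b_j + ε_ij,  b_j ~ N(0, σ_d²), ε_ij ~ N(0, σ²),

  with the sampling date *j* as the random intercept; significance by
  likelihood-ratio ANOVA, and the effect summarised as
  100·|β₁|/μ_dark with a 95% CI.
- **budget** — photoperiod-weighted daily rates
  (resp_IR,daily = resp_IR·L + resp_dark·(24−L)), trapezoidal
  integration over the >10 °C season (180 d), and upscaling to g CO₂
  for the lake's 0.5 m surface layer at a respiratory quotient of 1.
- **community** — rare-ASV filtering (> 3 counts in ≥ 20 % of samples),
  a negative-binomial variance-stabilising transform, Bray–Curtis
  dissimilarities, and distance-based linear models (DistLM: pseudo-F on
  the Gower-centred matrix with permutation tests and forward selection)
  plus dbRDA ordination.
- **simulate** — a synthetic-study generator with known ground truth
  (multiplicative IR effects, date random intercepts, titration and
  Poisson counting noise, covariate-structured Dirichlet-multinomial
  count tables) so every stage is testable without field data.

## Worked example

Simulate a two-season campaign (16 monthly dates, triplicate bottles per
treatment, a −15.2 % IR effect on respiration and +18.1/+9.5/+5.9 % on
glucose/pyruvate/leucine), derive all rates, and fit the light effects:

```python
from aapflux.simulate import SimConfig, simulate_activity
from aapflux import pipeline

study = simulate_activity(SimConfig(seed=1))
rates = pipeline.rates_from_study(study)
effects = pipeline.light_effect_summaries(
    rates[rates.treatment.isin(["dark", "IR"])]
)
print(effects.round(4).to_string(index=False))
```

```
     analyte  percent_difference  ci_low  ci_high      direction  p_value
 respiration             16.0915 13.3663  18.8167 higher in dark   0.0000
CO2_fixation              2.2397 -0.3793   4.8587   higher in IR   0.0966
     glucose             17.4624 14.9160  20.0088   higher in IR   0.0000
    pyruvate              9.9751  7.5193  12.4308   higher in IR   0.0000
     leucine              5.4539  2.9488   7.9591   higher in IR   0.0001
   thymidine              0.2406 -2.4949   2.9760   higher in IR   0.8632
```

Each row is the mixed-model percent difference between dark and IR
rates with its 95 % CI and likelihood-ratio p value: this seed recovers
the generating effects (respiration ~15 % higher in the dark; glucose,
pyruvate and leucine assimilation enhanced in IR light; thymidine and
bicarbonate incorporation unaffected). Upscaling the same study:

```python
sb = pipeline.seasonal_budget(rates, study.station_table)
print(sb.summary().to_string(index=False))
print(f"dark - IR difference: {sb.difference_dark_minus_ir:.3e} g CO2/season")
```

```
               quantity   dark_g_co2     ir_g_co2
                    NPP 2.426523e+07 2.426523e+07
            respiration 3.445769e+07 3.140825e+07
excess CO2 (resp - NPP) 1.019246e+07 7.143026e+06
dark - IR difference: 3.049e+06 g CO2/season
```

The dark-based budget overstates the lake's seasonal CO₂ release by the
dark−IR respiration difference; NPP is identical in both scenarios and
cancels.

The same stages are available from a shell via the `aapflux` CLI
(`simulate`, `winkler`, `carbonate`, `tracer`, `lmm`, `budget`,
`distlm`, `run`), exchanging plain CSV tables with provenance headers.

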