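# neighwalk

Multilevel-spatial analysis of recreational walking and the residential
neighborhood environment.

Epidemiologic cohorts that geocode participants into census-tract
neighborhoods routinely find that walking behavior varies between
neighborhoods, and that part of that variation is *spatially
structured*: adjacent tracts resemble each other. `neighwalk` packages
the full analysis chain for this setting — for biostatisticians and
social-epidemiology researchers who want to fit convolution
(Besag–York–Mollié) regressions to individual outcome data, decompose
the between-neighborhood variance into spatially structured and
unstructured parts, derive ecometric neighborhood scores from resident
surveys, and quantify overall environmental disparities with a
bootstrapped risk score. Because cohort data of this kind are rarely
public, the package ships a synthetic-cohort generator that reproduces
the statistical structure of such studies, so every stage is testable
end to end.

## The model

For individual *i* living in neighborhood *j(i)*, with covariates
*x<sub>i</sub>* (sociodemographics, 8-day weather-window summaries, and
quartile-categorized environmental exposures):

- binary outcome (any recreational walking):
  logit P(y<sub>i</sub> = 1) = **x**<sub>i</sub>′β + u<sub>j(i)</sub> + v<sub>j(i)</sub>
- ordinal outcome (neighborhood walking time, 5 categories with category
  1 = zero minutes): cumulative logit
  P(y<sub>i</sub> ≤ k) = σ(κ<sub>k</sub> − **x**<sub>i</sub>′β − u<sub>j(i)</sub> − v<sub>j(i)</sub>)

with two neighborhood random effects in the same linear predictor:
an exchangeable intercept u<sub>j</sub> ~ N(0, σ<sub>u</sub>²) and an
intrinsic conditional-autoregressive (ICAR) effect **v** with
conditional SD τ<sub>v</sub> on the binary contiguity graph, identified
by Σ<sub>j</sub> v<sub>j</sub> = 0. Estimation is by adaptive
Metropolis-within-Gibbs MCMC.

A random-effect SD σ on the log-odds scale is reported as an
**interquartile odds ratio** IqOR = exp(2kσ) with k = φ(z₀.₇₅)/0.25 ≈
1.27110 — the odds contrast between residents of top-quartile and
bottom-quartile neighborhoods. Per MCMC iteration the unstructured SD
is the σ<sub>u</sub> draw and the structured SD is the empirical
across-neighborhood SD of **v**; squared log-IqORs add, giving the
total IqOR and the percentage of between-neighborhood variance that is
spatially structured.

## Worked example

```python
from neighwalk import BYMLogistic, GeneratorConfig, MCMCConfig, generate_cohort

cfg = GeneratorConfig(lattice_rows=10, lattice_cols=10, n_per_neighborhood=30,
                      vary_n=False, missing_rate=0.0, seed=11)
cohort, graph = generate_cohort(cfg)

model = BYMLogistic.from_cohort(
    cohort, "walk_any",
    ["age_class", "sex_male", "nbhd_education", "air_traffic"],
    graph=graph,
)
res = model.fit(MCMCConfig(n_iter=4000, n_burnin=1500, thin=2, seed=5))
print(res.odds_ratios().round(2))
print(res.decompose())
```

prints

```
                     OR  OR_2.5%  OR_97.5%
age_class[2]       0.95     0.81      1.16
age_class[3]       0.97     0.76      1.17
sex_male[1]        1.32     1.14      1.55
nbhd_education[2]  0.92     0.66      1.35
nbhd_education[3]  1.27     0.88      1.96
nbhd_education[4]  1.47     0.94      2.23
air_traffic[1]     0.57     0.41      0.76
IqOR unstructured 1.80 (1.09, 2.73) | IqOR structured 2.12 (1.39, 2.94) |
IqOR total 2.63 (2.03, 3.52) | structured 61% (12%, 99%)
```

The OR rows are posterior-median odds ratios with 95% credible
intervals: men walk more (true generating OR 1.38), high neighborhood
education is supportive and air-traffic exposure deterrent (truths 1.47
and 0.75; the wide intervals reflect that exposures vary only at the
neighborhood level). The last line decomposes residual
between-neighborhood variation: a total IqOR of 2.63 means residents of
the most walking-favorable quartile of neighborhoods have 2.6 times the
odds of the least favorable quartile, and ~61% of that variance is
spatially structured.

The five-step modeling workflow (age/sex model → individual+weather
selection → one-by-one environmental pretests → combined final model →
weather-interaction tests, plus the bootstrapped risk-score disparity
analysis, a Markdown/CSV report and GeoJSON choropleths of the
posterior spatial effects) runs via

```python
from neighwalk.pipeline import fixture_config, run_pipeline
report = run_pipeline(fixture_config(output_dir="demo_run", seed=314))
```

or from the shell: `neighwalk run --seed 314 --out demo_run`.

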