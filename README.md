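# yeastclim

Climate-envelope modelling of wild yeast distribution from oak-tree surveys.

Wild *Saccharomyces paradoxus* — and, far more elusively, wild
*S. cerevisiae* — live on the bark of oak trees. Where in the world should
one look for them? `yeastclim` implements a complete analysis pipeline that
answers this from presence/absence survey data:

1. **Survey model.** For each oak tree, the number of bark samples yielding
   *S. paradoxus* out of the samples taken is modelled as a weighted binomial
   GLM with logit link,

   logit p<sub>i</sub> = β₀ + β₁·girth<sub>i</sub> + β₂·Tmax<sub>i</sub> +
   β₃·south<sub>i</sub> + β₄·girth<sub>i</sub>·south<sub>i</sub> +
   β₅·Tmax<sub>i</sub>·south<sub>i</sub>,

   where girth (m) proxies tree age, Tmax (°C) is the mean daily maximum
   temperature of the hottest month at the tree's location, and *south*
   distinguishes hot southern from cool northern European sites. The fit is
   by IRLS; an initial model with all interactions is simplified backwards by
   chi-square likelihood-ratio tests on the deviance, respecting marginality,
   and a three-level oak-type factor can be collapsed to two levels by
   contrast testing. Cook's distances flag influential trees.
2. **Temperature envelope.** The fitted temperature response defines an
   *optimum* Tmax interval (peak predicted isolation frequency, 22–28 °C)
   inside a wider *occurrence* interval (18–31 °C) for *S. paradoxus*.
   Because woodland *S. cerevisiae* grow optimally about 7 °C hotter in the
   laboratory, shifting the envelope by +7 °C predicts the *S. cerevisiae*
   range (occurrence 25–38 °C), with sympatry expected in the 25–31 °C
   overlap.
3. **Worldwide validation.** Strain records from published genotyping
   studies are classified against a Tmax raster (WorldClim-style grids,
   values stored as tenths of °C): each strain gets the value of its single
   containing pixel, an in/out-of-range flag, and — when out of range — the
   great-circle distance to the nearest in-range cell. Summaries are
   stratified by genotype class, because human-associated (wine/brewery)
   strains form dispersal-maintained sink populations that do not test a
   climate envelope. Fisher's exact test compares isolation rates between
   surveys; the Wilcoxon rank-sum test compares distance distributions
   between genotype classes.

A synthetic-data module generates surveys, rasters and strain tables with
exactly this structure, so the entire pipeline is testable offline.

## Worked example

```sh
yeastclim run --seed 1 --out demo
cat demo/validation_report.txt
```

prints (abridged):

```
final model: n_sp_positive/n_samples ~ girth_m + tmax_c + region + ... + girth_m:region + tmax_c:region
residual deviance 77.2 on 96 df (null 152.0)
deviance explained: 49.2%

S. paradoxus: optimum (22.0, 28.0) degC, occurrence (18.0, 31.0) degC
S. cerevisiae: optimum (29.0, 35.0) degC, occurrence (25.0, 38.0) degC

  genotype_class  n_total  n_in  n_out  fraction_in  median_distance_km
human-associated       20    10      9     0.526316                 0.0
            wild       40    40      0     1.000000                 0.0
```

Reading this: a 126-tree survey was simulated, the full four-variable
interaction model was pruned by stepwise deviance testing down to girth,
temperature, region and the two generating interactions (one spurious
other-yeast interaction survived at α = 0.05 in this seed), explaining about
half the tree-to-tree deviance in isolation frequency. The *S. paradoxus*
envelope shifted by +7 °C gives the 25–38 °C *S. cerevisiae* occurrence
range; classifying a simulated strain table against that range on a
simulated raster, every wild-genotype strain falls in range while half the
human-associated strains sit out of range, up to thousands of km away.

The same stages are available as a library:

```python
from yeastclim import BinomialGLM, ModelSpec, stepwise_simplify, simulate_survey, SurveyParams

survey = simulate_survey(SurveyParams(seed=1))
start = ModelSpec.from_formula(
    "n_sp_positive/n_samples ~ girth_m * tmax_c * region * other_yeast_freq")
final_spec, deletion_log = stepwise_simplify(start, survey, alpha=0.05)
model = BinomialGLM(spec=final_spec).fit(survey.dropna(subset=["girth_m"]))
print(model.result_.summary())
```

`BinomialGLM` follows the scikit-learn estimator protocol (`fit`,
`predict`, `get_params`), so it clones and composes with sklearn tooling.

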