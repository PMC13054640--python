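# ecostab

Resistance and resilience of grassland aboveground biomass to extreme dry
and wet climate events, and how plant community properties — species
richness, evenness, and the abundance of the long-term dominant species —
together with nutrient addition shape them.

`ecostab` is a reusable pipeline for long-term, multi-site grassland
datasets (plot × year biomass and species composition, plus monthly site
climate). It was built for quantitative community ecologists who want to
run this analysis end to end on their own data or stress-test it on
synthetic data with known ground truth.

## What it computes

**Climate events.** The Standardized Precipitation-Evapotranspiration
Index (SPEI) at timescale *k* is the *k*-month sum of precipitation minus
potential evapotranspiration, fitted per calendar month with a
three-parameter log-logistic distribution (unbiased probability-weighted
moments) and mapped to a standard-normal deviate. August SPEI-9 classifies
site-years: extreme wet at SPEI ≥ 1.28, extreme dry at SPEI ≤ −1.28
(1-in-10-year tails), normal strictly inside (−0.67, 0.67). The
biomass-relevant timescale is chosen by AICc over mixed models of
ln(biomass + 1) against each candidate SPEI.

**Stability statistics.** With Ȳₙ a plot's mean biomass over normal years,
Yₑ its event-year biomass and Yₑ₊₁ the next year's:

    resistance   Ω = Ȳₙ / |Yₑ − Ȳₙ|
    resilience   Δ = |Yₑ − Ȳₙ| / |Yₑ₊₁ − Ȳₙ|      (dropped after consecutive extremes)
    LRR          ln(Yₑ / Ȳₙ)                        (biomass and each community property)

**Community properties.** Richness (species with positive abundance), Evar
evenness (1 − (2/π)·arctan of the population variance of log abundances),
and dominance: the relative abundance, each year, of the species that
topped the plot's ranking in the most years.

**Inference.** Standardized-coefficient linear mixed models of ln Ω and
ln Δ on prior-year community properties, event type and nutrient treatment
(random intercepts for plot-in-experiment-in-site, crossed with year), with
a likelihood-ratio ladder over interaction terms; LRR cell models with
Tukey-adjusted pairwise contrasts; VIF screening; leave-one-out
sensitivity. A multigroup piecewise path model tests whether nutrients act
on stability directly or through the community properties, with global fit
from d-separation claims combined as Fisher's C.

**Synthetic data.** A seeded generator emits multi-site climate,
composition and biomass whose event-year excursions follow known linear
models in the community properties, so every stage of the pipeline can be
validated against exact generating coefficients.

## Worked example

```python
from ecostab import synth, validation

bundle = synth.generate_all(synth.GeneratorConfig(seed=1))
fits = validation.fit_headline_models(bundle)
fit = fits[("resistance", "extreme_dry")]
print(fit.tidy().round(3).to_string(index=False))
```

```
     term   beta    se   stat     p
Intercept  1.660 0.075 22.153 0.000
 richness  0.127 0.020  6.190 0.000
dominance -0.027 0.026 -1.059 0.289
 evenness  0.048 0.025  1.885 0.059
treatment -0.200 0.044 -4.576 0.000
```

Each `beta` is a standardized coefficient of the dry-event resistance
model: here a one-SD increase in prior-year richness raises ln Ω by about
0.13 (more resistant), nutrient addition lowers it, and dominance and
evenness do essentially nothing — matching the effects the generator was
seeded with (0.12, −0.19, −0.01, 0.03).

The same run from the shell:

```bash
ecostab synth all --seed 1 --out demo/
ecostab pipeline validate --config demo/run.yaml
ecostab pipeline run --config demo/run.yaml
```

## Layout

```
src/ecostab/
  spei.py        SPEI computation, log-logistic PWM fits, timescale selection
  community.py   cleaning, richness, Evar, long-term dominance
  stability.py   event catalog, Ω / Δ / LRR tables
  lmm.py         mixed models, AICc, marginal R², VIF, ladder, Tukey, LOO
  sem.py         path diagrams, d-separation, Fisher's C, effects
  synth.py       ground-truth synthetic data generator
  validation.py  replicate studies against generator truth
  pipeline.py    end-to-end orchestration with run manifest
  cli.py         `ecostab` command-line interface
```

See `docs/methods.md` for the statistical details and design choices.
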