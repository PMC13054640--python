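# Methods

## Scope and data model

`ecostab` analyses how grassland aboveground biomass withstands and
recovers from extreme dry and wet years, and how species richness, Evar
evenness, long-term dominance and nutrient addition shape those responses.
Inputs are tidy long tables: monthly site climate (`site, year, month,
precip, pet`; PET is an input, never estimated here), plot biomass
(`site, experiment, plot, year, treatment, biomass`, litter excluded
upstream), and species composition (`..., species, abundance` as percent
cover or biomass). Upstream dataset curation (minimum run lengths,
exclusion of grazed/irrigated/weeded plots, taxonomic name harmonization)
is documented input preparation, not computed here.

## SPEI

The climatic water balance D_k is the rolling k-month sum of precipitation
minus PET; months without a complete window are missing, never zero. Per
site, calendar month and scale, a three-parameter log-logistic distribution
F(x) = [1 + (α/(x−γ))^β]⁻¹ is fitted by unbiased probability-weighted
moments (ascending-sorted sample; the F-weighted unbiased estimators b₀,
b₁, b₂ are converted to the (1−F)-weighted moments the closed forms use:
w₀ = b₀, w₁ = b₀−b₁, w₂ = b₀−2b₁+b₂). β ≤ 1 (undefined distribution
moments) triggers an interquartile-range fallback and a flag. SPEI is the
standard-normal deviate of F(D), computed with the classic rational
approximation to the inverse normal (constants 2.515517 / 0.802853 /
0.010328 over 1.432788 / 0.189269 / 0.001308; |error| < 5×10⁻⁴, asserted
against the exact quantile at 0.005). Probabilities are clamped to
[10⁻⁶, 1−10⁻⁶] before the transform. The calibration window defaults to
the full supplied series and is configurable; when recomputing SPEI from
station data instead of using a gridded product's calibration, both
choices are supported and the default is documented here as
"calibrate on what you have".

Timescale selection fits, per candidate scale k ∈ {3, 6, 9, 12},
ln(biomass+1) ~ SPEI (+ SPEI² optionally) on control plots with random
intercepts for plot nested in site, by ML so AICc is comparable across
fixed structures, **restricted to site-years where every candidate has a
defined SPEI** (otherwise likelihoods are not comparable). The lowest-AICc
scale wins; a runner-up within ΔAICc ≤ 2 sets an indecision flag.

## Event classification and stability statistics

August SPEI-9 per site-year is classified: extreme wet at SPEI ≥ 1.28,
extreme dry at SPEI ≤ −1.28 (the standard-normal 1-in-10-year tails),
normal strictly inside (−0.67, 0.67) (the central 50%), "other" for the
remainder; |SPEI| exactly 0.67 is "other", exactly 1.28 is extreme.

With Ȳₙ the plot mean over its normal years (time-invariant, all normal
years in the record), Ω = Ȳₙ/|Yₑ−Ȳₙ| and Δ = |Yₑ−Ȳₙ|/|Yₑ₊₁−Ȳₙ|. The
absolute-value convention keeps both positive so their natural logarithms
exist; Δ > 1 means movement back toward Ȳₙ. Resilience is missing when the
following year is itself extreme (no clean recovery year) or unobserved.
Deviations below 10⁻⁹ of the baseline count as zero (they are below the
float precision of the baseline mean): such rows are flagged undefined and
excluded, never imputed. LRRs are ln(Yₑ/Ȳₙ) for biomass, richness,
dominance and evenness, with the same normal-year baseline set for all
metrics. Model rows carry community properties from the year before the
event, whatever that year's own classification; exclusion counts are
reported for missing prior years.

## Community properties

Cleaning removes non-plant records (case-insensitive match against a
configurable label list: litter, miscellaneous litter, fungi, bare ground,
rock, moss-unknown) and zero-abundance rows, then renormalizes relative
abundance within plot-year. Richness counts species with positive
abundance. Evar = 1 − (2/π)·arctan(Var_S[ln x]) uses natural logs and the
divide-by-S population variance over the S present species; it is exactly
scale-invariant, 1 iff all species are equal, and a single-species
community returns 1 by convention (zero log-variance). The long-term
dominant is the species topping relative abundance in the most years of
the plot's whole record (a year's ties credit every tied species; record
ties break by higher mean relative abundance, then species name); its
relative abundance each year — 0 when absent, and even in years another
species ranks higher — is the dominance value.

## Mixed models

All stability models are Gaussian linear mixed models with random
intercepts for plot nested in experiment nested in site, crossed with
year, implemented as variance components over a single spanning group.
Aliased factors (identical partitions of the rows, e.g. one experiment per
site) are deduplicated, factors with one level dropped, both flagged. Two
optimizers (L-BFGS and BFGS) are run and the better likelihood kept; for
ML fits the likelihood is additionally checked against the nested
zero-variance (OLS) model and the fit falls back to it when an optimizer
stalls below that bound. Fixed-effect covariance uses the GLS formula
(X′V̂⁻¹X)⁻¹ via the Woodbury identity, conditional on the estimated
variance components — always defined, including on variance boundaries.
Term tests are Wald (normal); coefficients and SEs are the reproduction
contract, degrees-of-freedom approximations are not. REML for reported
fits, ML for likelihood comparisons. AICc = −2lnL + 2k + 2k(k+1)/(n−k−1)
with k counting fixed effects, variance components and the residual.
Marginal/conditional R² follow the variance-partition definition:
var(Xβ̂) over itself plus summed intercept variances plus residual.

Continuous predictors are z-scored within each fitted model's data
(so per-event-type models are standardized on that event type's predictor
scale); binary treatment indicators stay 0/1. The interaction ladder drops
each listed interaction in turn by ML likelihood-ratio test at α = 0.05
(χ² on the parameter-count difference), in a configurable order. LRR
models use a cell-means parametrization over event type × treatment;
pairwise contrasts take q = √2·|t| against the studentized-range
distribution with k cells and residual df, a familywise-adjusted analogue
of the usual all-pairs procedure. Leave-one-out sensitivity refits per
omitted site or event year and reports coefficient spread.

## Path model

The default diagram: nutrients → each community property; community
properties, nutrients and event strength (|SPEI-9|) → resistance and
resilience; correlated errors among the three community properties **and
between resistance and resilience**. With that error structure the
d-separation basis set contains exactly three claims — event strength
against each community property given nutrients — hence 6 df for the
global test; declaring the resistance–resilience residual association free
is our reading of a 6-df grouped test, since a basis set that also tested
that pair would have 8. Claims condition on the parents of the downstream
node only; pairs of two exogenous variables are never claims. Each claim
is tested as the Wald p of the omitted variable in the corresponding local
model; Fisher's C = −2Σln pᵢ against χ² with 2k df (p-values floored at
10⁻¹²; an empty basis set means a saturated diagram and an undefined p).
Multigroup fits share the diagram: component models are estimated
separately per event type (variables centered and scaled per group, binary
indicators included, so edges are standardized), while claims are tested
once on the pooled data with the group indicator added to each
conditioning set. Because d-separation tests reject trivially small misfit
at large n, fits on more than 2000 rows carry an explicit oversensitivity
warning. Fisher's combination also assumes independent claim p-values;
when the tested variables share correlated errors (as the community
properties do here) the claims are mildly dependent and the global test
runs a little hot — a type-I rate nearer 0.07 than 0.05 in calibration
runs, a property shared with the piecewise approach generally. Indirect effects are products of edge coefficients summed over
directed paths; total = direct + indirect.

## Synthetic data generator

The generator emulates the study design: 3 sites × 2 experiments × 30
paired control/nutrient plots × 40 years by default (~7200 plot-years).
Monthly precipitation is gamma with a seasonal mean cycle and a per-site
wetness multiplier; PET is a seasonal sinusoid with small noise. Because
SPEI standardizes per calendar month, ~10% of Augusts per tail exceed
±1.28 by construction. Communities draw subordinate species from a site
pool each year (presence probability lower under nutrients: −1.2 species
in expectation), with one persistent dominant per plot whose Dirichlet
weight (mean 6, ×1.12 under nutrients) sets dominance, and per-plot
subordinate-concentration heterogeneity driving evenness variation.
Occasional litter/fungi rows exercise cleaning.

Baseline ln biomass carries site/experiment/plot intercepts (SD 0.15 /
0.10 / 0.20), a crossed year effect (SD 0.05), a linear response of 0.15
per unit August SPEI-9 (a marginal R² around 0.2, typical of
biomass–drought relationships in mesic grasslands), and residual SD 0.10.
In extreme years the generator draws ln Ω and (when the next year is
non-extreme) ln Δ from linear models in the z-scored prior-year community
properties, the 0/1 nutrient indicator and their interactions, plus a
shared site-by-event-year intercept (SD 0.15), a plot intercept (SD 0.10)
and residuals (SD 0.50 / 0.60), then solves Yₑ = Ȳₙ(1 ∓ e^(−lnΩ)) and
Yₑ₊₁ = Ȳₙ ∓ |Yₑ−Ȳₙ|·e^(−lnΔ) (dry events deviate down, wet up; dry
recovery values are clamped positive). Event-year deviations therefore act
multiplicatively on the ln scale, matching the ln-scale analysis models.
The default generating coefficients are the standardized effect sizes the
stability literature reports for mesic grasslands — e.g. richness → dry
resistance 0.12, dominance → wet resistance 0.06, evenness → resilience
0.36 in unfertilized plots, evenness × nutrients −0.42, dominance ×
nutrients −0.25 for wet resilience, nutrient main effects near −0.2 —
with every term of the per-event-type models given explicitly in
`GeneratorConfig`. One RNG stream per stage derives from the master seed,
so stages regenerate independently and identical seeds give bitwise
identical output.

Two design details matter for identifiability. First, predictor z-scales
are computed over exactly the rows each model will be fitted on (all event
rows for resistance; rows with a usable following year for resilience), so
generating and fitted scales coincide. Second, recovery years are often
classified "normal" and therefore enter the plot's normal-year mean; the
generator iterates the event/recovery construction to the fixed point at
which the baseline anchoring the draws equals the normal-year mean an
analyst computes from the emitted data. Without that step the contaminated
baseline attenuates recovery-related coefficients by tens of percent —
a caution that applies equally to real data, where Ȳₙ inevitably includes
post-event years.

What the generator does **not** emulate: spatial autocorrelation,
phenology, species turnover driven by the events themselves (community
LRRs are null by construction), mechanistic growth, observation error in
cover estimates, and any dependence between event strength and community
state beyond the optional omitted-edge switch used for power studies.
Passing tests therefore demonstrate that the pipeline recovers the
statistical structure it assumes, not that real grasslands satisfy that
structure. One further note on internal consistency: because a single
equation links Yₑ to both ln Ω and the biomass LRR (LRR_dry =
ln(1 − e^(−lnΩ))), the generator cannot set the nutrient effect on ln Ω
and the dry-event nutrient LRR independently; the defaults pin the
resistance/resilience coefficient surface, and the implied LRR cell means
(dry control ≈ −0.21, dry nutrient more negative) follow from the link.

## Validation studies and problem sizes

Replicate studies run at a reduced size chosen for desk-scale runtime:
3 sites × 2 experiments × 12 plots × 45 years per replicate. With 20
seeded replicates: each headline generating effect lies within ±2 SE of
its estimate in ≥ 90% of replicates; with all effects zeroed, the pooled
per-term Wald rejection rate at α = 0.05 stays ≤ 0.10; the 9-month driver
timescale is selected in ≥ 80% of replicates. Fisher's C, on 200 draws of
n = 180 from the default diagram (no grouping variance, so local models
reduce to ordinary regressions), rejects at 0.05 ± 0.03. These rates are
recomputed by `scripts/acceptance.py` and asserted in the test suite.

## Known limitations

- Satterthwaite/Kenward-Roger degrees of freedom are not implemented;
  p-values are Wald-normal and slightly anticonservative in small cells.
- The SEM engine estimates recursive path diagrams with correlated errors
  only; no latent variables and no covariance-based estimation.
- `run_pipeline` skips the interaction ladder by default (configurable)
  to keep full runs fast; selection behavior is validated directly in the
  inference tests.
- Resilience is a one-year recovery ratio; multi-year trajectories and
  compound-event metrics are out of scope.
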