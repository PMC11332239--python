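# Methods

This note documents the models, the numerical choices, and the limits of
what the synthetic-data tests demonstrate.

## Colour quantification

**Grid.** CIELAB is split into a regular 3-D grid: 12 bins on each
chromatic axis (a: green–red, b: blue–yellow) and 4 on lightness
(L ∈ [0, 100]), 576 cells in total.  Chromatic ranges default to
[−110, 110], which covers the entire sRGB gamut; pixels outside the ranges
are clamped to edge bins and counted, with a logged warning.  Bins are
half-open [lo, hi) except the closed last bin on each axis, so axis maxima
(L = 100, a = b = 110) are representable.  sRGB→Lab conversion goes
through XYZ under D65 (scikit-image); the white point maps to
L = 100, a ≈ b ≈ 0.

**Categories.**  Every cell maps to exactly one of ten named categories by
rules on the cell centroid's lightness L, chroma C = √(a² + b²) and hue
h = atan2(b, a):

* C < 15 → black (L < 25), white (L ≥ 75) or grey.  The cutoff of 15 Lab
  units must exceed the centroid chroma (~13) of the four central
  chromatic cells of the default grid, otherwise no cell would be
  achromatic at all.
* chromatic cells by hue sector: red (h ≥ 330° or < 25°), warm
  (25–70°: rufous if C ≥ 45 else brown), yellow hues (70–110°: yellow if
  L ≥ 50, else brown), green (110–180°), blue (180–280°), purple
  (280–330°).

The light/dark tone of a splittable colour (blue, brown, green, grey,
purple, red, rufous) is decided by the lightness half: the lower two of
four L bins are dark, the upper two light.  Black, white and yellow are
defined by lightness to begin with, so a tone split is not meaningful for
them and none is emitted.  The map is exported as a plain CSV of
(L_bin, a_bin, b_bin, category, tone) rows and can be edited and reloaded;
the rule constants are one defensible reading of "adjacent cells combined
into categories", not a claim of uniqueness.

**Diversity and elaboration.**  Colour diversity is the count of occupied
cells (any cell with proportion > 0 counts by default; a minimum-proportion
filter exists to suppress anti-aliasing speckle in real scans).  Colour
elaboration is the proportion-weighted mean Euclidean ΔE\*ab distance from
each occupied cell's *centroid* to the global average colour, itself the
unweighted mean over images of each image's proportion-weighted mean Lab
colour.  Working from cell centroids rather than raw pixels mirrors the
locus-based definitions; an unweighted (per-locus) elaboration mode is
provided for sensitivity analysis.  Euclidean ΔE\*ab is used because CIELAB
is approximately perceptually uniform; CIEDE2000 was considered and left
out of scope as the simple metric is the natural reading of a "distance in
Lab space".

## Synthetic data

The generator exists to give every downstream stage a recovery test with
known truth; its defaults encode the study conditions the pipeline is
meant for.

* **Taxonomy:** orders/families/genera/species counts fixed or sampled
  from inclusive ranges; a configurable fraction of species is
  dichromatic (male + female records), the rest monomorphic ("undefined").
  Labels are globally unique so taxonomic nesting is implicit in the
  coding.
* **Images:** each category in the requested mix is painted with
  representative sRGB colours taken at Lab cell centroids and verified by a
  Lab → 8-bit sRGB → Lab round trip into the same category (and tone), so
  gamut clipping can never silently move pixels between categories.  Pixel
  counts realise the mix by largest-remainder rounding (exact to one
  pixel).  Layouts: `stripe` (contiguous runs) and `blob` (patches grown
  around random seed pixels).  A 1-pixel transparent border provides a
  non-trivial mask.  Real photographic variation (lighting, pose,
  anti-aliasing) is deliberately not emulated: the images are exact colour
  fixtures, so colour-pipeline tests prove binning/accounting correctness,
  not robustness to photographic noise.
* **Attractiveness:** drawn from exactly the model the fitting code
  assumes — logit(μ) = Xβ + taxonomic random intercepts,
  y ~ Beta(μφ, (1−μ)φ).  Draw order (one normal vector per taxonomic
  level with sorted labels, then one beta vector) is fixed and documented
  so an independent script can replay the draws.  Defaults: σ(order) = 0.3,
  σ(family) = σ(genus) = 0.2, σ(species) = 0.1 on the logit scale, and
  φ = 30, i.e. clear but not dominant taxonomic signal and a realistic
  spread of consensus scores; coefficient defaults put moderate positive
  weight on elaboration, blue, red and crest and negative weight on body
  mass and black, matching the direction and rough size of effects such a
  study reports.
* **Ratings:** the latent mean rating of a species × sex is 1 + 9 ·
  response.  Photo counts are truncated-Poisson on [1, 15] with mean 5
  (the realistic photo-pool size per species); photo quality 1–5 is skewed
  high because rating pools prioritise good photographs.  A rating adds a
  quality effect proportional to (quality − 5), a rater-language offset, a
  Gaussian photo effect and Gaussian noise, then rounds and clips to 1–10.
  This affine-plus-noise mechanism is a stand-in: the true psychology of
  crowd raters is unknown, so consensus-recovery tests demonstrate that
  the estimator inverts *this* generative process, which shares the
  confounders (photo quality, language, photo pseudo-replication) the
  estimator is built to remove.
* Random streams are split per sub-generator (`SeedSequence.spawn`), so
  e.g. changing the number of photos never perturbs the taxonomy.

## Consensus model

A Gaussian linear mixed model on the raw 1–10 ratings: fixed effects are
photo quality (categorical, reference 5), rater language (categorical,
reference = majority language) and sex (reference "undefined"); random
intercepts for photo, species, genus, family and order.  The Gaussian
likelihood is the minimal faithful choice for an integer rating scale
treated as continuous — the upstream crowd-rating methodology is not
restated here, and ordinal likelihoods are out of scope.  The consensus
score of a species × sex is the prediction at reference conditions
(best-quality photo, majority language): intercept + sex effect + the
species', genus', family's and order's BLUPs.  Predictions are shifted by
−1 to the 0–9 scale and divided by 10.  Exact-boundary values are squeezed
by (y(n−1) + 0.5)/n; interior values are left untouched so that a raw
score of 4.5 is exactly 0.45.  The reported SE is the within-group
standard error of the raw ratings, a descriptive quantity rather than the
model-based prediction variance.  When the ratings have no variance at all
the model is degenerate; the fit short-circuits to the common value and
warns, rather than producing a singular solve.

## Beta mixed models

**Model.**  y ~ Beta(μφ, (1−μ)φ) with logit(μ) = Xβ + Σ_k Z_k b_k and
b_k ~ N(0, σ_k² I) for k ∈ {Order, Family, Genus, Species ID}.  The logit
link is the beta-regression default; φ is constant (no dispersion
sub-model).  The factors are independent random-intercept terms; nesting
is carried by the globally unique labels.

**Estimation.**  Laplace-approximate maximum likelihood with β profiled
into the inner problem: for fixed θ = (log σ², log φ), penalized Fisher
scoring finds the joint mode of (β, b) — the Fisher weight for the beta
family, φ²(ψ′(μφ) + ψ′((1−μ)φ))·μ²(1−μ)², is strictly positive, so the
inner system A′WA + D⁻¹ is always SPD and is solved sparsely (LU).  The
Laplace marginal log-likelihood
ℓ(θ) = ℓ_pen(û) − ½[logdet(Z′WZ + D⁻¹) + logdet D]
is maximized over θ by L-BFGS-B with finite-difference gradients (step
1e-5, then a polishing restart at 1e-6; the step must sit above the inner
solver's noise floor).  Profiling β keeps the outer dimension at 5
regardless of the number of fixed effects — the same device lme4 uses for
its fast GLMM deviance — and the reduction oracle (variances pinned at
zero vs an independent plain beta-regression ML fit) agrees to < 1e-4 in
every coefficient.  log σ² is bounded below at −12; a component reaching
the bound is reported as pinned at zero with a singular-fit warning.
Starting values: σ² = 0.1 per factor and method-of-moments φ.  For the
Gaussian family the same machinery is exact (the inner problem is
quadratic), which is how the consensus model is fitted.

**Inference.**  Wald 95% CIs and normal p-values from the (β, b) block of
the joint information at the optimum, i.e. conditional on θ̂ — the
variance-parameter and precision uncertainty is not propagated, the usual
Laplace-GLMM approximation.  p-values are reported but effect sizes and
CIs are the intended reading.  Randomized quantile residuals (beta CDF →
normal quantile; exact, no randomization needed for a continuous response)
feed a KS test against N(0,1), a residual-vs-fitted correlation, and
per-order residual summaries.

**Battery.**  `main` (the headline model), `extended` (+ trophic level,
IUCN, range size, |latitude|, migration), `males`/`females`/`undefined`
(one sex each, dropping the sex term and the Species ID factor, which is
redundant with one row per species), `dark`/`light` (blue/red/green
replaced by one tone; black/white/yellow have no tones by construction),
`loci` (the six colour proportions replaced by colour diversity;
elaboration retained, since "colour variables" reads as the proportions),
`dull` (the six colours replaced by purple, brown, grey, rufous).
Reference classes: sex "undefined", trophic "omnivore", IUCN
"Non-threatened", migration "non-migratory".

## Trait preparation

Allometric ornament residuals come from OLS of log(length) on log(mass) —
the standard allometric form, consistent with the log treatment of body
mass; a linear-scale option exists because the choice is not forced.
Non-positive lengths/masses are excluded from the fit, logged, and
returned as NaN.  Reclassification maps are total on documented raw
vocabularies and fail loudly on unknown labels.  Scaling stores per-column
means/SDs (post-log) for exact inversion; a zero-variance column is a
named error at the library level, while the pipeline skips constant
columns (e.g. a colour tone absent from a small panel) with a warning.
The collinearity screen reports every pairwise Pearson r and flags
|r| > 0.6 by default; nothing is dropped implicitly — colour diversity is
on the pipeline's explicit drop list because it co-varies with several
colour proportions, and its effect is tested in the separate `loci` model
instead.

## Problem sizes and determinism

Test and acceptance problem sizes are chosen as the smallest panels that
exercise the full structure: ~1800 species × sex rows across 10 orders /
30 families / 150 genera for parameter recovery (20 replicates; every true
fixed effect inside its 95% CI in ≥ 90% of them), 120 species × 50 ratings
for consensus recovery (rank correlation > 0.95), 100 random 24 × 24
images for the bit-exact colour oracle, and a ~50-species toy scenario for
the end-to-end smoke run, whose manifest checksums are identical across
same-seed reruns.  All randomness flows from explicit seeds through
`numpy.random.default_rng`.

## Known limitations

* The image generator emits flat colour patches; nothing here validates
  segmentation or mask extraction from real illustrations.
* The category map is a rule-based reconstruction; analyses sensitive to
  the exact category boundaries should re-run with an edited map CSV.
* Wald CIs conditional on θ̂ can undercover slightly when a variance
  component is estimated from few levels (e.g. 10 orders).
* The consensus SE is descriptive; downstream models use only the point
  estimates (no measurement-error propagation).
* Taxonomic random intercepts approximate phylogeny as a 4-level
  hierarchy; proper phylogenetic covariance is out of scope.
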