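# Methods

This note documents the statistical model behind `coopcare`, the choices
made where the design was genuinely open, and what the synthetic-data
experiments do and do not demonstrate.

## Data model

One row per species: helper effort (%), mean helper–brood kinship r,
helper sex ratio (% male), mean size of helped groups (breeders +
helpers, ≥ 2), % of nests with helpers, an ordinal data-quality score
(1 weak – 3 strong), an extra-pair-paternity (EPP) rate where known, and
a conservative-exclusion flag with a free-text reason.

Helper effort is derived from provisioning rates measured in helped
groups: `effort% = 100 · helper_rate / (s·male_rate + (1−s)·female_rate)`
with *s* the proportion of male helpers. When only sex-specific helper
rates are available they are pooled with the same weights *s* and 1 − *s*
(mirroring the parental benchmark; the symmetric choice is this package's
convention, since pooling by sample size is equally defensible but the
sample sizes are usually not reported). Any within-study corrections to
standard brood size, group size or nestling age are treated as properties
of the input rates and are not recomputed. Mean kinship is the mixture
mean Σ p_c r_c over pedigree classes. The response is the natural log of
effort; natural (not base-10) logs are the only scale on which typical
intercepts back-transform to plausible effort percentages.

Filtering: the full analysis drops species whose *known* EPP exceeds 20%
(parents must be a valid r ≈ 0.5 benchmark); species with unknown EPP are
retained but logged. The conservative re-analysis additionally drops
species carrying per-record flags (juvenile helpers, multi-nest
provisioning, paternity-linked helping, single-group data) and species
with EPP in 10–20%. Exclusions are flag-driven, not re-derived from
biology, and every drop is logged as a JSON line.

## Phylogenetic covariance

Trees are read from multi-Newick files (dendropy underneath; polytomies
accepted; tip matching is exact after space/underscore normalization).
The Brownian covariance has C[i,j] equal to the shared root-to-MRCA path
length; trees are normalized to unit height so C has unit diagonal for
ultrametric trees and σ² is interpretable across ensembles.
Non-ultrametric inputs are normalized by the mean root-to-tip depth with
a warning. Pagel's λ multiplies the off-diagonal of C.

## Regression with quality variance components

    y = Xβ + ε,   Cov(ε) = V = σ² ( C_λ + Σ_k γ_k D_k ),  γ_k ≥ 0, λ ∈ [0,1]

D_k is the diagonal indicator of quality class k. The γ_k are variance
*ratios* to the phylogenetic scale σ², so they are reported directly on
the "scaled to phylogeny" convention. An additive structure on the
correlation scale was chosen over multiplicative weights because it
nests both the plain-PGLS (γ = 0) and the heteroscedastic-OLS (λ = 0)
corners exactly and keeps each γ_k interpretable as "extra noise variance
of class k in units of the phylogenetic variance".

β and σ² have closed-form profiles; the profiled criterion is maximized
over (λ, γ) by multi-start bounded optimization (deterministic starts at
corners/centre of the box, L-BFGS-B on a log1p scale for γ so that steps
in γ ~ 100 and λ ∈ [0,1] are commensurate, then a derivative-free Powell
polish from the best point; the likelihood can be ridge-shaped near the
λ = 1 boundary). All linear algebra goes through triangular
factorizations; a single 1e−8·mean(diag) jitter retry is attempted, with
a logged warning, if a factorization fails.

**Identifiability.** With a free γ for every quality class, λ is
confounded with the overall scale: V(λ, γ, σ²) is *identical* to
V(1, (1+γ)/λ − 1, σ²λ) for any 0 < λ ≤ 1. The likelihood is exactly flat
along this ridge, so fits are reported as the canonical λ = 1
representative ("variance components scaled to phylogeny, λ set to
unity"); a λ estimate of exactly 0 (no off-diagonal signal) is a
genuinely distinct point and is reported as such. In the λ-only model
(γ fixed at 0, used for the bivariate sex-ratio checks) λ is identified
and estimated freely. Consequently the "λ = 1.00 ± 0.00" pattern is the
expected output of this model class whenever phylogenetic signal is
present, with the λ SE reported as 0 and a boundary flag.

**Criterion and inference.** REML is the default criterion because at
n ≈ 36 the ML variance components are biased low enough to visibly
distort coefficient inference; ML remains available and is always used
for the likelihood-ratio R² (REML likelihoods are not comparable across
different fixed effects, so R² internally refits both models by ML).
Coefficient SEs are the GLS SEs at the fitted V using the RSS/(n−p)
scale, inflated by a Kenward–Roger-type adjustment that propagates the
REML sampling covariance of the free variance-structure directions
(off-diagonal scale and the per-class diagonal components; components
pinned at a bound are treated as fixed). t-tests use df = n − p.
Variance-parameter SEs come from a central-difference Hessian of the
profiled criterion; parameters at an active bound get SE 0 plus a
boundary flag. Under the study design (below) this combination gives
95%-interval coverage of ≈ 0.93–0.96 and type-I error ≈ 0.04–0.06,
whereas naive ML plug-in SEs give ≈ 0.85 coverage and ≈ 15% type-I
error — the adjustment is not optional at this sample size.

R² is the likelihood-ratio statistic 1 − exp((2/n)(ℓ₀ − ℓ₁)) against the
intercept-only model with the covariance structure re-estimated; it
equals the classical R² in the OLS corner.

**Ensembles.** The model is refitted on every tree of the ensemble;
the reported table uses across-tree arithmetic means (median available)
of β, SE, t, λ, γ, with across-tree SDs retained. p-values are averaged
across trees like the other quantities — a documented convention, since
no aggregation of per-tree p-values is canonical. Per-tree fits are kept;
single-tree failures are logged and skipped.

## Wilcoxon signed-rank test

The one-tailed one-sample test of "female care share > 0.5" drops exact
ties with 0.5, midranks tied absolute deviations, and computes
P(W⁺ ≥ observed) under the exact 2ⁿ sign-flip null for n ≤ 25 (via
subset-sum counting, equivalent to full enumeration), switching to the
normal approximation with tie and continuity corrections above. With
midranks the tied pair {0.4, 0.6} gives p = 0.75, matching
`scipy.stats.wilcoxon(method="exact")`.

## Synthetic data

The generator emulates the study conditions the package targets: 36
species on a unit-height Yule (pure-birth) tree, a 1,000-tree ensemble by
default, predictors drawn without phylogenetic signal (kinship uniform on
[0, 0.5], its biological range for helpers; sex ratio uniform on [0, 100]%;
group size 2 + Exponential(2.5); % nests helped uniform on [5, 100]),
quality classes multinomial (1/3, 1/3, 1/3), and a response
y = Xβ + ε with Cov(ε) = σ²(C_λ + Σ γ_k D_k) drawn through the exact
triangular factor of the generating covariance on the first tree.
Defaults: β = (3.32, 1.98, −0.015, 0, 0) on raw predictor scales, λ = 1,
γ = (22.33, 0.11, 0.18), σ² = 0.05 — the γ are ratios, so σ² itself is a
free choice; 0.05 makes the weak-quality class a log-scale noise SD near
1, i.e. weak studies are dominated by noise while strong studies are
dominated by phylogeny, the regime the variance components exist for.
Effort is exp(y), so the log transform never fails on synthetic data.
All randomness flows from one integer seed; identical configs write
byte-identical files.

What the generator does *not* emulate: correlated ensemble trees (the
n_trees − 1 extra trees are independent Yule draws, unlike posterior
tree samples, which share most structure — so across-tree spread of
estimates is pessimistic here and λ may collapse to 0 on non-generating
trees), phylogenetic signal in predictors (available via an option, off
by default since GLS validity does not require it), measurement of
provisioning from visit streams, or missing-data patterns. Passing the
calibration experiments therefore validates the estimator under its own
assumptions; it does not certify literature-collated data.

## Problem sizes in the validation experiments

The calibration experiments use 200 replicates (coverage, boundary λ)
and 500 replicates (type-I error) at n = 36 with single-tree fits and
3 optimization starts; oracle comparisons use 10–14 species instances
and a dense (λ, γ) grid; the end-to-end demonstration uses 36 species
and 5 trees. These sizes keep a full validation run in the low minutes
on one CPU while leaving Monte-Carlo error well inside the asserted
bands.

## Known limitations

- The quality variance components are weakly identified at n ≈ 36
  (a dozen species per class); their Hessian SEs can be enormous on
  trees that fit the data poorly. The coefficient inference is protected
  by the small-sample adjustment, not the γ SEs.
- Aggregating p-values across trees by the mean is a convention;
  examine the per-tree spread for boundary cases.
- The exact Wilcoxon null conditions on the observed (mid)ranks; with
  heavy ties other defensible conventions (e.g. averaging over tie-break
  orderings) give slightly different p-values.
- df = n − p ignores the estimated variance-parameter count; the
  calibration experiments show this is adequate at the study design but
  it has not been checked for much smaller n.
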