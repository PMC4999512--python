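# coopcare

Phylogenetic comparative analysis of helper effort in cooperatively
breeding birds.

In many cooperatively breeding bird species, non-breeding "helpers"
provision the brood of a breeding pair. How hard helpers work varies
enormously across species. Inclusive-fitness theory (Hamilton's rule)
predicts that, all else equal, helpers should invest more the more
closely related they are to the brood they feed. Testing that prediction
across species requires (i) a helper-effort measure comparable across
species, (ii) a mean helper–brood kinship estimate per species, and
(iii) a regression that respects shared ancestry and very uneven data
quality across source studies. `coopcare` implements that full pipeline
for comparative datasets of the kind assembled from the cooperative
breeding literature, together with a synthetic-data generator so every
stage can be validated end to end.

## The model

Helper effort is a helper's provisioning rate as a percentage of a
sex-ratio-weighted parental benchmark measured in the same helped groups:
with a fraction *s* of helpers male,

    benchmark = s · (male breeder rate) + (1 − s) · (female breeder rate)
    effort%   = 100 · (helper rate) / benchmark

so a helper feeding at the breeders' rate scores 100% (values above 100%
are legitimate). Mean kinship to brood is a proportion-weighted mixture
over pedigree classes, r = Σ p_c r_c (full siblings 0.5, half siblings
0.25, unrelated 0, ...).

The statistical core is generalized least squares for y = log(effort%) on
z-scored predictors (kinship, helper sex ratio, group size, % nests with
helpers) with residual covariance

    V = σ² ( C_λ + Σ_k γ_k D_k )

where C is the Brownian-motion covariance of a unit-height phylogeny,
C_λ is C with its off-diagonal scaled by Pagel's λ, D_k is the diagonal
indicator of ordinal data-quality class k ∈ {1, 2, 3} (1 weak … 3
strong), and γ_k ≥ 0 is the extra residual variance of class k expressed
relative to the phylogenetic scale σ² ("scaled to phylogeny"). β and σ²
are profiled in closed form; (λ, γ) are estimated by bounded REML (ML
optional) with multiple starts. Coefficient standard errors carry a
Kenward–Roger-type small-sample adjustment and t-tests use n − p degrees
of freedom. The model is re-fitted across an ensemble of equiprobable
trees and estimates averaged across trees. One-sample, one-tailed exact
Wilcoxon signed-rank tests (full 2ⁿ enumeration for n ≤ 25) check
whether females contribute more than half of total care.

## Worked example

```python
import coopcare as cc

# a synthetic comparative dataset at the default study conditions:
# 36 species, effect structure (intercept 3.32, kinship slope 1.98,
# sex-ratio slope -0.015 per % male), lambda = 1, quality variance
# ratios (22.33, 0.11, 0.18)
ds = cc.simulate_dataset(cc.SyntheticConfig(n_species=36, n_trees=5, seed=42))

report = cc.run_full_analysis(ds.records, ds.trees,
                              cc.AnalysisConfig(n_starts=3))
print(report.table_tsv())
```

which prints (standardized coefficients, mean across the 5 trees):

```
term	coefficient	se	t	p
intercept	-0.0234	0.0742	-0.4826	0.632
kinship_r	0.3635	0.0607	6.1064	2.652e-06
sexratio_pct_male	-0.4104	0.0459	-9.4701	2.352e-09
group_size	-0.0105	0.0517	-0.1782	0.8039
pct_nests_helped	0.0151	0.0508	0.2360	0.6125

variance_component	estimate	se
lambda	0.4000	0.0000
data_quality_1	108.9492	16316.9492
data_quality_2	2.2681	473.1804
data_quality_3	1.5685	353.6673

r2	0.7518
```

Read it as: after standardization, helper effort rises significantly with
kinship and falls with the proportion of male helpers, while group size
and % nests helped have no detectable effect; the weak-data class
(quality 1) contributes by far the most residual variance. The variance
components are on the scaled-to-phylogeny convention, so each per-tree
fit reports λ = 1 when phylogenetic signal is present; the across-tree
mean of 0.40 here reflects that only the generating tree of this
synthetic ensemble carries the signal (the other four are independent
topologies). `report.to_json()` contains the per-tree fits, the
conservative re-fit, the bivariate sex-ratio checks and the exclusion
log.

The command-line interface mirrors this: `coopcare simulate`,
`coopcare fit`, `coopcare wilcoxon` (see `--help` on each).

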