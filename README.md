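# compadapt

Quantitative analysis of **compensatory adaptation in gene-deletion
founders**: how much of the outcome of experimental evolution — both the
*rate* of adaptation and its *genetic basis* — is predictable from the
founder's genotype, its initial fitness, and the functional module its
deleted gene belongs to.

The package is aimed at experimental-evolution and systems-biology groups
running hierarchically designed evolve-and-resequence experiments: replicate
populations evolved from each of a panel of deletion founders, with founders
nested inside functional modules defined by a genome-scale genetic
interaction map.

## What it computes

**Competitive fitness.** Per-generation selection coefficients from
two-timepoint competition assays, `s = (1/t) ln(r_f/r_i)` (% per
generation), replicate aggregation, and robust median summaries of
revertant-clone triplicates.

**Epistasis and entrenchment.** For a population with founder fitness `x`,
evolved fitness `y_e` and median revertant fitness `y_r`, the evolved
mutations' effect is `y_e − x` in the deletion background and `y_r` in the
wild-type background; their difference

&nbsp;&nbsp;&nbsp;&nbsp;ε = (y_e − x) − y_r

measures epistasis between the evolved mutations and the founding deletion.
A deletion is *entrenched* when reverting it was initially beneficial
(−x > 0) but no longer is after compensatory evolution (y_r − y_e < 0).

**Hierarchical variance components.** Maximum-likelihood fitting of the
nested random-effects model

&nbsp;&nbsp;&nbsp;&nbsp;y_ijkl = α + β·x_ij + m_i + g_ij + p_ijk + τ_ijkl,
&nbsp;&nbsp;&nbsp;&nbsp;m_i ~ N(0, σ_m²), g_ij ~ N(0, σ_g²), p_ijk ~ N(0, σ_p²), τ_ijkl ~ N(0, σ_τ²)

for replicate measurement *l* of population *k* from founder gene *j* in
module *i* (response: fitness gain, or ε).  The exact Gaussian marginal
likelihood is evaluated blockwise in O(n); nested models are compared by
likelihood-ratio tests (with an optional boundary correction for variance
components), and the between-population variance is partitioned into
initial-fitness, module, gene, evolutionary-stochasticity and
measurement-error fractions.

**Interaction-profile clustering.** Pearson correlations of
genetic-interaction profiles (self-columns excluded), Ward ("D2"
convention) module assignment on `1 − |ρ|`, and threshold-graph
"interaction clusters" (connected components at ρ > 0.2).

**Parallelism by mutual information.** For multi-hit targets (genes or
interaction clusters mutated in ≥ 2 populations), the plug-in MI (bits)
between founder label (module, or gene conditioned on module) and the
per-population mutation indicators, reported in excess of a permutation
null that shuffles the pooled mutation labels while preserving each
population's mutation count.

**Synthetic data.** Generators for founder panels, hierarchical fitness
gains, revertant triplicates (with planted ε and transformation-artifact
outliers), founder-dependent mutation tables, and modular interaction maps
— all deterministic under a seed, with ground truth returned, defaulting to
the reference design (37 founders / 16 modules + 2 controls / 20
populations / 3 replicates).

## Worked example

```python
import compadapt as ca

panel = ca.reference_panel()                       # 37 founders, 18 groups
cfg = ca.SimConfig(seed=7)                         # reference design
gains = ca.simulate_fitness_gains(panel, config=cfg)   # 2220 measurements

fits = ca.fit_standard_models(gains, panel)
full = fits["b+m+g+p"]
lrt = ca.likelihood_ratio_test(full, fits["b+g+p"])
dec = ca.variance_fractions(full, gains, panel)

table, _ = ca.simulate_mutation_table(panel, ca.SimConfig(seed=7, mi_effect_strength=2.0))
res = ca.excess_mi(table, level="gene", by="module",
                   excluded_founders=("ade2", "hxk2"),
                   n_permutations=1000, seed=7)
```

Output (printed by the snippet above with small formatting):

```
alpha=1.58 beta=-0.41 sigma_m=1.50 sigma_g=1.64 sigma_p=1.46 sigma_tau=0.81
loglik full=-3623.2 vs no-module=-3626.6
LRT module effect: stat=6.8, df=1, p=0.009
{'fitness': 54.0, 'module': 13.4, 'gene': 16.0, 'population': 12.7, 'error': 3.9}
founder identity: 83.4%
excess MI (founder module vs multi-hit genes): 0.65 bits, CI=(0.59, 0.70), p=0.000999
```

Reading this: the fitted slope β ≈ −0.41 is *declining adaptability* —
every 1 %/gen of initial fitness deficit buys ≈ 0.4 %/gen of extra gain;
the module variance component is significantly nonzero (LRT p = 0.009), so
founders in the same module adapt more similarly than initial fitness alone
explains; founder identity (fitness + module + gene) accounts for ~83 % of
between-population variance in this realization; and knowing the founder's
module provides ~0.65 bits of information about which multi-hit genes its
descendants mutate (permutation p < 0.001).

A command-line interface mirrors the library
(`compadapt simulate | fitness | epistasis | fit-hier | cluster | mi |
pipeline`); `compadapt simulate --out-dir d && compadapt pipeline
--in-dir d --out-dir out` runs the whole preset analysis on a synthetic
input set.

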