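# Methods

This note documents the statistical models implemented in `compadapt`, the
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Setting

The package analyses a hierarchically designed evolve-and-resequence
experiment: a panel of haploid yeast founders, each carrying a single gene
deletion, with the deleted genes nested inside functional modules (groups of
genes with correlated genetic-interaction profiles).  Many replicate
populations are evolved from each founder; their competitive fitness is
measured in replicate; in a subset of evolved clones the founding deletion
is reverted and the revertants' fitnesses measured; and evolved clones are
sequenced for coding mutations.  The reference design bundled with the
package is 37 founders in 16 functional modules plus two controls, 20
populations per founder, 3 fitness replicates (2,220 measurements).

## Competitive fitness

Fitness is the per-generation Malthusian selection coefficient from a
two-timepoint competition against a fluorescent reference,
`s = (1/t) ln(r_f / r_i)` with `r` the reference/test cell-count ratio and
`t` the generations between readings (default 20).  Written this way the
quantity is the fitness of the *reference*; a fitter test strain makes it
negative.  Because the panel convention reports the fitness of the test
strain, `competitive_fitness` negates it by default
(`orientation="test"`); the literal orientation is available as
`orientation="reference"`.  Natural log is the only choice consistent with
"% per generation" magnitudes; the public interface multiplies by 100.
Whether the reference marker's own fitness cost is subtracted from reported
fitnesses is not resolvable from the assay definition; it is treated as
absorbed into the reference baseline.

Revertant clones come in independent triplicates; transformation
occasionally introduces a de-novo mutation into one clone, visible as
exactly one clone deviating from the other two.  The per-population summary
is therefore the median, which is robust to that failure mode;
`median_revertant` additionally flags triplets whose sd exceeds 0.5 %/gen
with the one-deviant pattern.

## Epistasis and entrenchment

With all fitnesses relative to the wild-type ancestor (0 by construction),
for a population with founder fitness `x`, evolved fitness `y_e` and median
revertant fitness `y_r`:

* effect of the evolved mutations in the deletion background: `y_e − x`;
* effect in the wild-type background: `y_r`;
* epistasis `ε = (y_e − x) − y_r` (exact identity, asserted in tests).

The wild-type baseline is 0 by construction of the relative assay; the
neutral-control founder (`ho`, initial fitness −0.0) serves as an empirical
check of that convention rather than a subtracted term.  A population is
*entrenched* when reverting the deletion would have been beneficial in the
ancestor (`−x > 0`) but is deleterious after compensatory evolution
(`y_r − y_e < 0`).  Founders with fewer than two successfully reverted
populations are excluded before model fitting
(`retained_populations`): a single reverted population cannot separate the
founder-gene effect from population-level stochasticity.

## Hierarchical variance-component model

Each replicate measurement `l` of population `k` from founder gene `j` in
module `i` is modelled as

    y_ijkl = α + β x_ij + m_i + g_ij + p_ijk + τ_ijkl,

with independent zero-mean normal random effects of standard deviation σ_m
(module), σ_g (gene), σ_p (population = evolutionary stochasticity) and σ_τ
(measurement error), and `x_ij` the founder's initial fitness.  The same
machinery fits either the 500-generation fitness gain or per-population ε
as the response (for ε, the three revertant clones enter as the
replicate-measurement level `l`).

**Fitting is by maximum likelihood, not REML.**  The analysis requires
likelihood-ratio tests of nested models including a fixed-effect comparison
(dropping β), which REML likelihoods cannot support, and absolute
log-likelihoods (with the normal constant `−n/2 ln 2π`) are reported so
nested fits are directly comparable.

**Exact likelihood, O(n) per evaluation.**  The marginal covariance is
block-diagonal by module.  Within a block, replicates are collapsed to
per-population sufficient statistics — the within-population contrasts are
iid N(0, σ_τ²) and the population means carry the rest — which is exact,
not an approximation.  The remaining population-level covariance
`diag(σ_p² + σ_τ²/L_k) + σ_g²[same gene] + σ_m²` is inverted with two
nested rank-one Woodbury identities.  The test suite asserts equality with
(a) a dense multivariate-normal evaluation and (b) a tensorized
Gauss–Hermite integration over the random effects, to 1e−6 and better.
Unbalanced designs (lost populations, missing replicates) are handled
exactly by the same formulas.

**Optimization.**  L-BFGS-B over (α, β, σ's) with box constraints σ ≥ 0,
from three moment-based starts including one at the σ_m = σ_g = 0 boundary.
Direct bounded optimization (rather than a log-σ transform) was chosen
because boundary estimates of exactly zero are legitimate, stable outcomes
— the gene component of the ε model pins to 0.00 in practice — and a log
transform cannot represent them.  σ_τ has a lower bound of 1e−6 whenever
replicates exist (σ_τ = 0 with replicates makes the covariance singular;
`marginal_loglik` raises a degeneracy error there).  Non-convergence is
flagged on the fit, not raised.

**Variance partitioning.**  From the full-model fit, the fixed-effect share
is the population-weighted empirical variance of `β x_ij` (each population
counted once, ddof = 0); the random shares are σ_m², σ_g², σ_p², σ_τ²;
fractions are each component over the total.  "Founder identity" is the sum
of the fitness, module and gene fractions.

**Tests.**  `likelihood_ratio_test` uses `2Δℓ` against χ² with df = number
of added parameters.  Because a variance component under the null sits on
the boundary of its parameter space, the plain χ²₁ reference is
conservative for single-variance comparisons; the 50:50 mixture
`(χ²₀ + χ²₁)/2` correction is available (`boundary_corrected=True`) and its
type-I error is verified by simulation.  Plain χ² is the default.

**Uncertainty.**  `bootstrap_se` is a parametric bootstrap: simulate from
the fitted parameters on the observed design and refit.  A nonparametric
cluster bootstrap would resample the top-level units — only 16–18 modules —
which is too few; simulation happens directly at the level of sufficient
statistics (population means and within-population sums of squares), which
is distributionally exact and fast.  Founder initial fitnesses enter as
point estimates; their measurement error is not propagated (the panel
stores standard errors should a user wish to do so by simulation).

## Interaction-profile clustering

Genes are compared by the Pearson correlation ρ of their
genetic-interaction profiles, computed over partner positions scored in
both profiles and *excluding the pair's own two columns* (self-interaction
positions and the mutual score would trivially inflate similarity).  Pairs
sharing fewer than `min_shared` (default 3) positions are masked.

* **Module assignment**: agglomerative clustering under Ward's
  minimum-variance criterion on the distance `1 − |ρ|`, in the
  squared-dissimilarity ("ward.D2") convention — input dissimilarities are
  squared inside the Lance–Williams update and heights reported on the
  original scale.  This is what `scipy.cluster.hierarchy.linkage(method=
  "ward")` computes for a precomputed distance matrix, so results are
  reproducible bit-for-bit against R's `hclust(..., method="ward.D2")`.
* **Interaction clusters**: connected components of the graph joining pairs
  with ρ above a threshold (default 0.2).  The edge rule uses *signed* ρ:
  anti-correlated profiles suggest opposite rather than shared function
  (`use_abs=True` switches to |ρ|; the choice between components and, say,
  complete linkage at the threshold is a genuine open question — components
  were chosen as the most literal reading of "connect ... into groups").
  Hand assignments for pathways poorly represented in the interaction map
  are supported via `overrides`.

## Mutual-information parallelism statistics

Targets are multi-hit genes (or interaction clusters): those mutated in at
least two distinct populations after removing excluded founders (by
default the two founders whose compensation is mechanistically obvious and
would dominate).  Duplicate hits within a population collapse to a binary
indicator `m_g`.  The statistic is the sum over targets of the plug-in MI
(base 2) between the founder label W (module or gene) and `m_g`; the
conditional version weights module strata by population frequency and
measures what the founder gene adds beyond its module.  Probabilities are
observed frequencies with 0·log 0 = 0.

Plug-in MI is biased upward, so the reported effect is the excess over a
permutation null: pool every mutation's label across analyzed populations,
redistribute them uniformly (sampling without replacement), keeping each
population's mutation count fixed; recompute the statistic against the
*same* target set.  Fixing targets from the observed table keeps the
statistic's meaning constant across permutations.  The same global
(unstratified) redistribution serves marginal and conditional statistics.
Reported: excess = M − mean(null); 95% CI `[M − q0.975(null),
M − q0.025(null)]`; p = (1 + #{null ≥ M})/(1 + n_permutations), so with the
default 1,000 permutations the smallest reportable value is p < 0.001.
Bias-corrected MI estimators (Miller–Madow, jackknife) are deliberately out
of scope: the plug-in-minus-null design is the contract.

**A caveat worth knowing.**  The excess can be systematically *negative*
under alternatives where every founder concentrates its mutations on one
or two private targets and populations per founder are few: permutation
spreads the pooled labels over many more targets per module stratum than
the observed table occupies, so the null acquires more plug-in bias than
the observed statistic gains signal.  This is a property of the statistic,
not an implementation artifact; the null-calibration test (excess centered
at 0, p super-uniform under independence) is unaffected.  Conditional
gene-level analyses should be interpreted with the per-founder sample size
in mind.

## Synthetic-data generator

The generator produces every input with known ground truth, deterministic
under (config, seed):

* **Founder panel** — module sizes default to the reference design
  (16 functional modules of 1–5 genes plus two single-gene controls, 37
  genes); initial fitnesses drawn N(−8, 7.5²) %/gen, matching the reference
  panel's spread (−24 to +4).  The panel's measurement SE is a parameter
  (default 0.5 %/gen) because the distribution of founder-fitness
  measurement error is not otherwise specified.
* **Fitness gains** — drawn *exactly* from the hierarchical model, with the
  published full-model estimates (α=2.01, β=−0.39, σ_m=2.47, σ_g=1.78,
  σ_p=1.45, σ_τ=0.81) as default generating values; module draws are shared
  by all genes of the module and gene draws by all populations of the
  founder, matching the nesting the likelihood assumes.  No forward
  population-genetic simulation is attempted: gains are draws from the
  statistical model, not evolved, so the generator validates inference, not
  evolutionary dynamics.
* **Revertants** — triplicates at configurable clone noise; with
  probability `outlier_rate` exactly one clone is offset (the
  transformation-artifact pattern); planted ε per module/gene/population is
  recorded as ground truth.
* **Mutation tables** — per-population counts from a configurable
  distribution (default Poisson with mean 1.53, matching 153 coding
  mutations over 100 clones); gene identities from a founder-conditional
  categorical over a target universe (default 24 genes), with the founder's
  module-preferred and gene-preferred targets' log-odds tilted by
  `mi_effect_strength` (0 = exact independence).  Ground-truth hit
  probabilities are returned alongside.
* **Interaction maps** — profiles are `sqrt(ρ)·(module factor) +
  sqrt(1−ρ)·noise` over a universe of panel plus background genes, giving
  expected within-module profile correlation ρ and ≈0 across modules.

What the generator does *not* emulate: selection dynamics and clonal
interference, linkage between mutations, non-normal fitness measurement
error, missing-at-random structure in real interaction maps, and
reversion failure (populations that cannot be transformed).  Passing tests
therefore demonstrate correctness of the estimators under the model's own
assumptions, not robustness to their violation.

## Problem sizes used in the checked analyses

The bundled validation runs use the reference design (2,220 measurements)
for model fitting — a full four-model fit takes well under a second — with
20 simulation replicates and 40 bootstrap refits for the
parameter-recovery study, and 1,000 simulations × 200 permutations for the
null-calibration study.  These sizes give Monte-Carlo error comfortably
below the asserted tolerances.

## Known limitations

* ML variance components are biased downward in small designs (no REML
  option by design); the bootstrap quantifies but does not remove this.
* The ε model treats the founder fitness `x` as known.
* Interaction-cluster membership is sensitive to the 0.2 threshold near
  ties; the monotone-refinement property (raising the threshold never
  merges) is the only guarantee.
* The permutation null conditions on per-population mutation counts only;
  mutational target-size differences between genes are not modelled.
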