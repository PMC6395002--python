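"""Synthetic data with the statistical structure the analyses assume.

Every generator is deterministic given (config, seed) and mirrors one input
of the analysis pipeline:

* a founder panel of gene-deletion strains nested in modules, with a wide
  range of initial fitness effects;
* replicate fitness gains drawn exactly from the nested hierarchical model
  (fixed initial-fitness effect plus module/gene/population random effects
  plus measurement noise);
* triplicate revertant-clone fitnesses with occasional single-clone
  outliers (the signature of a transformation-induced mutation), with the
  planted epistasis recorded as ground truth;
* mutation tables whose gene-hit probabilities depend on the founder module
  and gene with tunable strength (known ground-truth association); and
* gene-by-gene interaction-score matrices with controlled within-module
  profile correlation.

The default configuration reproduces the reference study design: 18 label
groups (16 functional modules plus two single-gene controls) containing 37
founder genes, 20 populations per founder, 3 replicate fitness measurements,
and generating parameters equal to the published full-model estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .hiervar import HierParams
from .mi import MutationTable

__all__ = [
    "SimConfig",
    "simulate_founder_panel",
    "simulate_fitness_gains",
    "simulate_revertant_data",
    "simulate_mutation_table",
    "simulate_interaction_map",
    "DEFAULT_GENES_PER_MODULE",
]

#: Module sizes of the reference design: 16 functional modules of 1-5 genes
#: plus two single-gene controls (37 genes total).
DEFAULT_GENES_PER_MODULE = (2, 3, 3, 5, 2, 3, 3, 2, 2, 3, 2, 1, 1, 1, 1, 1, 1, 1)

#: Published full-model estimates, used as default generating values.
_DEFAULT_HIER = HierParams(alpha=2.01, beta=-0.39, sigma_m=2.47,
                           sigma_g=1.78, sigma_p=1.45, sigma_tau=0.81)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic-data generators.

    ``founder_fitness_distribution`` is (location, scale) of a normal in
    percent per generation; the default (-8, 7.5) matches the spread of
    deletion fitness effects in the reference panel (roughly -24 to +4).
    ``mutations_per_population`` is ``("poisson", mean)`` or ``("fixed", k)``
    or a callable ``(rng, n) -> int array``; the default Poisson mean 1.53
    matches the observed 153 coding mutations across 100 sequenced clones.
    ``mi_effect_strength`` >= 0 scales the log-odds tilt of the
    founder-conditional mutation-target distribution (0 = independence).
    """

    n_modules: int = len(DEFAULT_GENES_PER_MODULE)
    genes_per_module: int | Sequence[int] = DEFAULT_GENES_PER_MODULE
    n_populations_per_founder: int = 20
    n_replicate_measurements: int = 3
    founder_fitness_distribution: tuple[float, float] = (-8.0, 7.5)
    founder_se: float = 0.5
    hier_params: HierParams = field(default_factory=lambda: _DEFAULT_HIER)
    mi_effect_strength: float = 0.0
    mutations_per_population: tuple | Callable = ("poisson", 1.53)
    n_target_genes: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = self.module_sizes
        if self.n_modules < 1 or any(s < 1 for s in sizes):
            raise ValueError("all counts must be >= 1")
        if len(sizes) != self.n_modules:
            raise ValueError("genes_per_module length must equal n_modules")
        if self.n_populations_per_founder < 1 or self.n_replicate_measurements < 1:
            raise ValueError("all counts must be >= 1")
        if self.founder_fitness_distribution[1] < 0 or self.founder_se < 0:
            raise ValueError("scale parameters must be >= 0")
        if self.mi_effect_strength < 0:
            raise ValueError("mi_effect_strength must be >= 0")
        if self.n_target_genes < 1:
            raise ValueError("mutation-target gene universe must be non-empty")

    @property
    def module_sizes(self) -> tuple[int, ...]:
        if isinstance(self.genes_per_module, int):
            return (self.genes_per_module,) * self.n_modules
        return tuple(self.genes_per_module)


def _rng(config_seed: int, stream: int,
         seed: int | np.random.Generator | None = None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    base = config_seed if seed is None else seed
    return np.random.default_rng([int(base), stream])


def simulate_founder_panel(config: SimConfig,
                           seed: int | None = None) -> pd.DataFrame:
    """Founder panel: one gene per row, nested in modules.

    Columns ``module``, ``gene``, ``initial_fitness`` (drawn from the
    configured normal, %/gen) and ``se`` (the configured measurement standard
    error of the initial fitness, so error bars on founder fitness are
    reproducible downstream).
    """
    rng = _rng(config.seed, 1, seed)
    loc, scale = config.founder_fitness_distribution
    rows = []
    for i, size in enumerate(config.module_sizes, start=1):
        for j in range(1, size + 1):
            rows.append((f"M{i:02d}", f"M{i:02d}g{j}"))
    x = rng.normal(loc, scale, size=len(rows))
    return pd.DataFrame(
        {
            "module": [m for m, _ in rows],
            "gene": [g for _, g in rows],
            "initial_fitness": x,
            "se": config.founder_se,
        }
    )


def simulate_fitness_gains(
    panel: pd.DataFrame,
    params: HierParams | None = None,
    config: SimConfig = SimConfig(),
    seed: int | None = None,
) -> pd.DataFrame:
    """Replicate fitness gains drawn exactly from the hierarchical model.

    One module effect per module, one gene effect per gene, one population
    effect per population, one error term per measurement; the expected gain
    of founder (i, j) is ``alpha + beta * x_ij``.  Returns one row per
    measurement with columns ``module``, ``gene``, ``population``,
    ``replicate``, ``value``.
    """
    if len(panel) == 0:
        raise ValueError("panel must be non-empty")
    p = params if params is not None else config.hier_params
    rng = _rng(config.seed, 2, seed)
    npop = config.n_populations_per_founder
    nrep = config.n_replicate_measurements

    modules = panel["module"].drop_duplicates().tolist()
    m_eff = dict(zip(modules, rng.normal(0.0, p.sigma_m, len(modules))))
    rows = []
    for _, founder in panel.iterrows():
        g_eff = rng.normal(0.0, p.sigma_g)
        mu = p.alpha + p.beta * founder["initial_fitness"] + \
            m_eff[founder["module"]] + g_eff
        pop_eff = rng.normal(0.0, p.sigma_p, npop)
        tau = rng.normal(0.0, p.sigma_tau, (npop, nrep))
        for k in range(npop):
            for l in range(nrep):
                rows.append(
                    (founder["module"], founder["gene"], k + 1, l + 1,
                     mu + pop_eff[k] + tau[k, l])
                )
    return pd.DataFrame(
        rows, columns=["module", "gene", "population", "replicate", "value"]
    )


def simulate_revertant_data(
    evolved: pd.DataFrame,
    panel: pd.DataFrame,
    epsilon_spec: float | Mapping[str, float] | Callable = 0.0,
    outlier_rate: float = 0.07,
    clone_sd: float = 0.2,
    outlier_offset: float = 5.0,
    config: SimConfig = SimConfig(),
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Triplicate revertant-clone fitnesses with planted epistasis.

    ``evolved`` needs columns ``population``, ``gene`` (founder gene) and
    ``evolved_fitness`` (%/gen relative to wild type).  The planted epsilon
    per population comes from ``epsilon_spec``: a scalar, a mapping from
    founder module (or gene) to epsilon, or a callable of the evolved row.
    The true revertant fitness is ``(evolved - x) - epsilon``; each clone
    adds N(0, clone_sd) noise and, with probability ``outlier_rate``, exactly
    one of the three clones is shifted by ``outlier_offset`` (the
    transformation-artifact pattern).

    Returns ``(clones, truth)``: clones long-form (``population``, ``clone``,
    ``fitness``), truth per population (``population``, ``epsilon_true``,
    ``revertant_true``, ``outlier_planted``).
    """
    if not 0.0 <= outlier_rate <= 1.0:
        raise ValueError("outlier rate must be in [0, 1]")
    if clone_sd < 0:
        raise ValueError("clone_sd must be >= 0")
    rng = _rng(config.seed, 3, seed)
    pan = panel.set_index("gene")

    def eps_for(row: pd.Series) -> float:
        if callable(epsilon_spec):
            return float(epsilon_spec(row))
        if isinstance(epsilon_spec, Mapping):
            gene = row["gene"]
            module = pan.loc[gene, "module"]
            if gene in epsilon_spec:
                return float(epsilon_spec[gene])
            return float(epsilon_spec.get(module, 0.0))
        return float(epsilon_spec)

    clone_rows, truth_rows = [], []
    for _, row in evolved.iterrows():
        x = float(pan.loc[row["gene"], "initial_fitness"])
        eps = eps_for(row)
        true_rev = (float(row["evolved_fitness"]) - x) - eps
        clones = true_rev + rng.normal(0.0, clone_sd, 3)
        planted = bool(rng.random() < outlier_rate)
        if planted:
            clones[rng.integers(3)] += outlier_offset
        for c, f in enumerate(clones, start=1):
            clone_rows.append((row["population"], c, f))
        truth_rows.append((row["population"], eps, true_rev, planted))
    clones_df = pd.DataFrame(clone_rows,
                             columns=["population", "clone", "fitness"])
    truth_df = pd.DataFrame(
        truth_rows,
        columns=["population", "epsilon_true", "revertant_true",
                 "outlier_planted"],
    )
    return clones_df, truth_df


def _mutation_counts(config: SimConfig, rng: np.random.Generator,
                     n: int) -> np.ndarray:
    spec = config.mutations_per_population
    if callable(spec):
        return np.asarray(spec(rng, n), dtype=int)
    kind, value = spec
    if kind == "poisson":
        return rng.poisson(value, n)
    if kind == "fixed":
        return np.full(n, int(value), dtype=int)
    raise ValueError(f"unknown mutation-count distribution {kind!r}")


def simulate_mutation_table(
    panel: pd.DataFrame,
    config: SimConfig = SimConfig(),
    n_populations_per_founder: int | None = None,
    seed: int | None = None,
) -> tuple[MutationTable, pd.DataFrame]:
    """Mutation table with founder-dependent target-gene probabilities.

    Each population draws its mutation count from the configured
    distribution, then draws gene identities from a founder-conditional
    categorical distribution over a universe of ``n_target_genes`` genes
    (named ``T01``...).  The log-odds of a founder's module-preferred and
    gene-preferred target genes (assigned round-robin) are tilted by
    ``mi_effect_strength``; strength 0 gives the uniform marginal, i.e.
    founder-independent mutations.  Target genes carry interaction-cluster
    labels grouping consecutive triples, so cluster-level analyses run on
    the output.

    Returns ``(table, truth)`` where ``truth`` holds the generating hit
    probability of every (founder gene, target gene) pair.
    """
    if config.n_target_genes < 1:
        raise ValueError("mutation-target gene universe must be non-empty")
    rng = _rng(config.seed, 4, seed)
    npop = (config.n_populations_per_founder
            if n_populations_per_founder is None else n_populations_per_founder)
    targets = [f"T{t:02d}" for t in range(1, config.n_target_genes + 1)]
    cluster_of = {t: f"C{(i // 3) + 1:02d}" for i, t in enumerate(targets)}

    modules = panel["module"].drop_duplicates().tolist()
    mod_pref = {m: i % len(targets) for i, m in enumerate(modules)}
    gene_pref = {g: (j + 7) % len(targets)
                 for j, g in enumerate(panel["gene"])}

    pop_rows, mut_rows, truth_rows = [], [], []
    s = config.mi_effect_strength
    pid = 0
    for _, founder in panel.iterrows():
        logw = np.zeros(len(targets))
        logw[mod_pref[founder["module"]]] += s
        logw[gene_pref[founder["gene"]]] += s
        probs = np.exp(logw - logw.max())
        probs /= probs.sum()
        for t, pr in zip(targets, probs):
            truth_rows.append((founder["gene"], t, pr))
        counts = _mutation_counts(config, rng, npop)
        for k in range(npop):
            pid += 1
            pop_rows.append((pid, founder["gene"], founder["module"]))
            for gene_idx in rng.choice(len(targets), size=counts[k], p=probs):
                t = targets[gene_idx]
                mut_rows.append((pid, t, cluster_of[t]))
    table = MutationTable(
        populations=pd.DataFrame(
            pop_rows, columns=["population", "founder_gene", "founder_module"]
        ),
        mutations=pd.DataFrame(
            mut_rows, columns=["population", "gene", "cluster"]
        ),
    )
    truth = pd.DataFrame(
        truth_rows, columns=["founder_gene", "target_gene", "hit_probability"]
    )
    return table, truth


def simulate_interaction_map(
    modules: Mapping[str, str] | pd.Series,
    within_module_rho: float | Mapping[str, float] = 0.5,
    noise_sd: float = 0.0,
    n_background: int = 120,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Gene-by-gene interaction-score matrix with modular profile structure.

    ``modules`` maps each panel gene to its module.  Each module has a latent
    profile; a member gene's profile is ``sqrt(rho) * latent +
    sqrt(1 - rho) * idiosyncratic`` over a universe consisting of the panel
    genes plus ``n_background`` unstructured genes, so same-module genes have
    expected profile correlation ``rho`` and cross-module genes ~0.
    ``noise_sd`` adds independent measurement noise to every score.  Returns
    a square DataFrame (rows = profiles) over the full universe.
    """
    mod = pd.Series(modules)
    rho_of = (within_module_rho if isinstance(within_module_rho, Mapping)
              else {m: within_module_rho for m in mod.unique()})
    for m, r in rho_of.items():
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"within_module_rho for {m} must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng([int(seed), 5])
    genes = list(mod.index) + [f"bg{i:03d}" for i in range(n_background)]
    p = len(genes)
    latent = {m: rng.normal(size=p) for m in mod.unique()}
    profiles = np.empty((p, p))
    for i, g in enumerate(genes):
        if g in mod.index:
            r = rho_of[mod[g]]
            profiles[i] = math.sqrt(r) * latent[mod[g]] + \
                math.sqrt(1.0 - r) * rng.normal(size=p)
        else:
            profiles[i] = rng.normal(size=p)
    if noise_sd > 0:
        profiles = profiles + rng.normal(0.0, noise_sd, (p, p))
    return pd.DataFrame(profiles, index=genes, columns=genes)
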