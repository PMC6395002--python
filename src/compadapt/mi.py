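"""Parallelism between founder genotype and evolved mutations, in bits.

For each multi-hit target (a gene, or an interaction cluster of genes,
mutated independently in at least two populations) define the per-population
binary indicator ``m_g``.  The association between the founder label ``W``
(module or gene) and the mutation targets is the sum over targets of the
plug-in mutual information

    M(W, g) = sum_g sum_W p(W) sum_{m in {0,1}} p(m|W) log2 p(m|W)/p(m),

with probabilities estimated as observed frequencies and 0·log 0 = 0.  The
conditional version M(W, g | Z) weights each stratum of a coarser founder
property Z (here, the module containing the founder gene) by its population
frequency, measuring what the specific founder gene adds beyond its module.

Plug-in MI is biased upward in finite samples, so the reported effect is the
*excess* over a permutation null that redistributes the pooled mutation
labels uniformly across populations while keeping each population's mutation
count fixed; target sets are determined once from the observed table and
held fixed across permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MutationTable",
    "TargetSet",
    "MIResult",
    "multi_hit_targets",
    "mutual_information",
    "conditional_mutual_information",
    "permutation_null",
    "excess_mi_report",
    "excess_mi",
    "parallelism_report",
]


@dataclass(frozen=True)
class MutationTable:
    """Per-population founder annotations and mutated-gene multisets.

    ``populations``: one row per population, columns ``population``,
    ``founder_gene``, ``founder_module``.  ``mutations``: one row per called
    mutation, columns ``population``, ``gene`` and optionally ``cluster``
    (interaction-cluster label of the mutated gene).  Populations with no
    mutations simply have no rows in ``mutations``.
    """

    populations: pd.DataFrame
    mutations: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"population", "founder_gene", "founder_module"}
        if not need <= set(self.populations.columns):
            raise ValueError(f"populations table needs columns {sorted(need)}")
        if self.populations["population"].duplicated().any():
            raise ValueError("duplicate population ids")
        if not {"population", "gene"} <= set(self.mutations.columns):
            raise ValueError("mutations table needs columns population, gene")
        orphan = set(self.mutations["population"]) - set(
            self.populations["population"]
        )
        if orphan:
            raise ValueError(f"mutations reference unknown populations: {orphan}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MutationTable":
        """Build from a long table with one row per (population, mutation).

        Rows with a null ``mutated_gene`` record a population with no
        mutations.
        """
        pops = (
            df[["population", "founder_gene", "founder_module"]]
            .drop_duplicates("population")
            .reset_index(drop=True)
        )
        muts = df[df["mutated_gene"].notna()].rename(
            columns={"mutated_gene": "gene"}
        )
        cols = ["population", "gene"] + (
            ["cluster"] if "cluster" in muts.columns else []
        )
        return cls(pops, muts[cols].reset_index(drop=True))

    @property
    def n_populations(self) -> int:
        return len(self.populations)


@dataclass(frozen=True)
class TargetSet:
    """Fixed multi-hit targets plus everything needed to permute the table."""

    level: str
    names: tuple[str, ...]
    pop_ids: tuple
    founder_gene: np.ndarray  # integer codes per analyzed population
    founder_module: np.ndarray
    gene_levels: tuple[str, ...]
    module_levels: tuple[str, ...]
    indicators: np.ndarray  # (n_pops, n_targets) bool
    mut_pop: np.ndarray = field(repr=False)  # (n_mutations,) population index
    mut_target: np.ndarray = field(repr=False)  # (n_mutations,) target col or -1

    @property
    def n_targets(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class MIResult:
    statistic: float
    conditioning: str | None
    null_mean: float
    excess: float
    ci: tuple[float, float]
    p_value: float
    n_permutations: int
    seed: int | None


def multi_hit_targets(
    table: MutationTable,
    level: str = "gene",
    min_populations: int = 2,
    excluded_founders: Sequence[str] = (),
) -> TargetSet:
    """Targets mutated in >= ``min_populations`` distinct populations.

    Populations descended from ``excluded_founders`` are removed first (the
    entrenched ade2/hxk2 founders have overwhelming, mechanistically obvious
    target enrichment and would dominate the statistic).  Duplicate hits of
    one target within a population collapse to a single indicator.
    """
    if level not in ("gene", "cluster"):
        raise ValueError("level must be 'gene' or 'cluster'")
    pops = table.populations
    if excluded_founders:
        pops = pops[~pops["founder_gene"].isin(set(excluded_founders))]
    pops = pops.reset_index(drop=True)
    pop_index = {p: i for i, p in enumerate(pops["population"])}

    muts = table.mutations[table.mutations["population"].isin(pop_index)]
    if level == "cluster":
        if "cluster" not in muts.columns:
            raise ValueError("mutation table has no cluster labels")
        labels = muts["cluster"].astype(str)
    else:
        labels = muts["gene"].astype(str)

    hit_pops = (
        pd.DataFrame({"label": labels, "population": muts["population"]})
        .groupby("label")["population"]
        .nunique()
    )
    names = tuple(sorted(hit_pops[hit_pops >= min_populations].index))
    col = {t: j for j, t in enumerate(names)}

    n = len(pops)
    ind = np.zeros((n, len(names)), dtype=bool)
    mut_pop = np.array([pop_index[p] for p in muts["population"]], dtype=np.intp)
    mut_target = np.array([col.get(l, -1) for l in labels], dtype=np.intp)
    valid = mut_target >= 0
    ind[mut_pop[valid], mut_target[valid]] = True

    g_codes, g_levels = pd.factorize(pops["founder_gene"], sort=True)
    m_codes, m_levels = pd.factorize(pops["founder_module"], sort=True)
    return TargetSet(
        level=level,
        names=names,
        pop_ids=tuple(pops["population"]),
        founder_gene=g_codes.astype(np.intp),
        founder_module=m_codes.astype(np.intp),
        gene_levels=tuple(map(str, g_levels)),
        module_levels=tuple(map(str, m_levels)),
        indicators=ind,
        mut_pop=mut_pop,
        mut_target=mut_target,
    )


def _plugin_mi(w: np.ndarray, n_w: int, ind: np.ndarray) -> float:
    """Sum over targets of plug-in MI between labels ``w`` and indicators."""
    n, _ = ind.shape
    if n == 0:
        return 0.0
    counts_w = np.bincount(w, minlength=n_w).astype(float)
    c1 = np.zeros((n_w, ind.shape[1]))
    np.add.at(c1, w, ind.astype(float))
    c0 = counts_w[:, None] - c1
    tot1 = ind.sum(axis=0).astype(float)
    tot0 = n - tot1
    total = 0.0
    for c, tot in ((c1, tot1), (c0, tot0)):
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = (c * n) / (counts_w[:, None] * tot[None, :])
            term = np.where(c > 0, c * np.log2(np.where(c > 0, ratio, 1.0)), 0.0)
        total += float(term.sum())
    return total / n


def mutual_information(targets: TargetSet, by: str = "module") -> float:
    """M(W, g) in bits, summed over the fixed target set.

    ``by`` chooses the founder label W: ``"module"`` or ``"gene"``.
    """
    w, n_w = _founder_codes(targets, by)
    return _plugin_mi(w, n_w, targets.indicators)


def conditional_mutual_information(
    targets: TargetSet, by: str = "gene", given: str = "module"
) -> float:
    """M(W, g | Z) in bits: founder label W beyond the coarser property Z.

    Requires Z to coarsen W (each founder gene lies in one module); computed
    as the population-frequency-weighted average of the within-stratum MI.
    """
    w, n_w = _founder_codes(targets, by)
    z, n_z = _founder_codes(targets, given)
    n = len(w)
    total = 0.0
    for zi in range(n_z):
        sel = z == zi
        n_sel = int(sel.sum())
        if n_sel == 0:
            continue
        w_sub, levels = pd.factorize(w[sel])
        total += (n_sel / n) * _plugin_mi(
            w_sub.astype(np.intp), len(levels), targets.indicators[sel]
        )
    return total


def _founder_codes(targets: TargetSet, which: str) -> tuple[np.ndarray, int]:
    if which == "module":
        return targets.founder_module, len(targets.module_levels)
    if which == "gene":
        return targets.founder_gene, len(targets.gene_levels)
    raise ValueError("founder label must be 'module' or 'gene'")


def _statistic(targets: TargetSet, by: str, conditioned_on: str | None) -> float:
    if conditioned_on is None:
        return mutual_information(targets, by=by)
    return conditional_mutual_information(targets, by=by, given=conditioned_on)


def permutation_null(
    targets: TargetSet,
    by: str = "module",
    conditioned_on: str | None = None,
    n_permutations: int = 1000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Null distribution of the MI statistic under label shuffling.

    Each permutation pools every mutation's target label across the analyzed
    populations and redistributes them uniformly at random (a permutation of
    the pooled list, i.e. sampling without replacement), preserving both the
    per-population mutation counts and the pooled label multiset; indicators
    are recomputed against the SAME fixed target set.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(seed)
    n, t = targets.indicators.shape
    out = np.empty(n_permutations)
    mut_pop = targets.mut_pop
    mut_target = targets.mut_target
    base_counts = np.bincount(mut_pop, minlength=n)
    for i in range(n_permutations):
        perm = rng.permutation(mut_target)
        # invariants of the scheme: per-population counts and pooled labels
        assert np.array_equal(np.bincount(mut_pop, minlength=n), base_counts)
        assert np.array_equal(np.sort(perm), np.sort(mut_target))
        ind = np.zeros((n, t), dtype=bool)
        valid = perm >= 0
        ind[mut_pop[valid], perm[valid]] = True
        shuffled = TargetSet(
            level=targets.level, names=targets.names, pop_ids=targets.pop_ids,
            founder_gene=targets.founder_gene,
            founder_module=targets.founder_module,
            gene_levels=targets.gene_levels,
            module_levels=targets.module_levels,
            indicators=ind, mut_pop=mut_pop, mut_target=perm,
        )
        out[i] = _statistic(shuffled, by, conditioned_on)
    return out


def excess_mi_report(
    observed: float,
    null: np.ndarray,
    conditioning: str | None = None,
    seed: int | None = None,
) -> MIResult:
    """Summarise an observed statistic against its permutation null.

    excess = M - mean(null); the 95% CI is ``[M - q0.975(null),
    M - q0.025(null)]``; the p-value is ``(1 + #{null >= M}) / (1 + n)``.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    lo = float(observed - np.quantile(null, 0.975))
    hi = float(observed - np.quantile(null, 0.025))
    p = (1.0 + float(np.sum(null >= observed))) / (1.0 + null.size)
    return MIResult(
        statistic=float(observed),
        conditioning=conditioning,
        null_mean=float(null.mean()),
        excess=float(observed - null.mean()),
        ci=(lo, hi),
        p_value=p,
        n_permutations=int(null.size),
        seed=seed,
    )


def excess_mi(
    table: MutationTable,
    level: str = "gene",
    by: str = "module",
    conditioned_on: str | None = None,
    min_populations: int = 2,
    excluded_founders: Sequence[str] = (),
    n_permutations: int = 1000,
    seed: int = 0,
) -> MIResult:
    """End-to-end excess-MI analysis for one cell of the parallelism report."""
    targets = multi_hit_targets(table, level, min_populations, excluded_founders)
    obs = _statistic(targets, by, conditioned_on)
    null = permutation_null(targets, by, conditioned_on, n_permutations, seed)
    return excess_mi_report(obs, null, conditioning=conditioned_on, seed=seed)


def parallelism_report(
    table: MutationTable,
    excluded_founders: Sequence[str] = ("ade2", "hxk2"),
    n_permutations: int = 1000,
    seed: int = 0,
    levels: Sequence[str] = ("gene", "cluster"),
) -> pd.DataFrame:
    """The four-cell founder-vs-mutation parallelism table.

    Rows: founder module (marginal MI) and founder gene conditioned on
    module; columns crossed with mutation level (multi-hit genes and, when
    cluster labels are present, multi-hit interaction clusters).
    """
    rows = []
    for level in levels:
        if level == "cluster" and "cluster" not in table.mutations.columns:
            continue
        for by, cond in (("module", None), ("gene", "module")):
            res = excess_mi(
                table, level=level, by=by, conditioned_on=cond,
                excluded_founders=excluded_founders,
                n_permutations=n_permutations, seed=seed,
            )
            rows.append(
                {
                    "founder_property": by,
                    "conditioned_on": cond or "",
                    "mutation_level": level,
                    "excess_bits": res.excess,
                    "ci_low": res.ci[0],
                    "ci_high": res.ci[1],
                    "p_value": res.p_value,
                    "observed_bits": res.statistic,
                    "null_mean_bits": res.null_mean,
                    "n_permutations": res.n_permutations,
                }
            )
    return pd.DataFrame(rows)
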