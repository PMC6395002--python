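"""Epistasis between founder deletions and evolved mutations; entrenchment.

All fitnesses are relative to the wild-type ancestor, in percent per
generation, with the wild type at 0 by construction of the competition assay.
For one evolved population we have three numbers:

* ``founder_fitness`` (x) — fitness of the founding deletion strain;
* ``evolved_fitness``   — fitness of the population after evolution;
* ``revertant_fitness`` — median fitness of three clones in which the
  founding deletion was reverted to the wild-type allele.

The evolved mutations' effect in the deletion background is
``evolved - founder``; their effect in the wild-type background is the
revertant fitness itself (the revertant carries the evolved mutations on an
otherwise wild-type genome).  The difference between the two effects,
epsilon, measures epistasis between the evolved mutations and the founding
deletion: positive epsilon means the mutations are more beneficial in the
background in which they arose.

Entrenchment: a deletion is entrenched when reverting it would have been
beneficial in the ancestor (x < 0, so the reversion effect -x > 0) but is no
longer beneficial after compensatory evolution
(``revertant - evolved < 0``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

__all__ = [
    "EpistasisRecord",
    "ReversionOutcome",
    "compute_epsilon",
    "classify_reversion",
    "epistasis_table",
    "retained_populations",
]


@dataclass(frozen=True)
class EpistasisRecord:
    population: int | str
    founder_gene: str
    effect_in_deletion_bg: float
    effect_in_wt_bg: float
    epsilon: float


@dataclass(frozen=True)
class ReversionOutcome:
    population: int | str
    reversion_effect_wt: float
    reversion_effect_evolved: float
    entrenched: bool


def compute_epsilon(
    founder_fitness: float,
    evolved_fitness: float,
    revertant_median_fitness: float,
    population: int | str = 0,
    founder_gene: str = "",
) -> EpistasisRecord:
    """Epistasis between evolved mutations and the founding deletion.

    epsilon = (evolved - founder) - revertant, exactly; all in %/gen.
    """
    for v in (founder_fitness, evolved_fitness, revertant_median_fitness):
        if not math.isfinite(v):
            raise ValueError("all three fitnesses must be finite")
    in_del = evolved_fitness - founder_fitness
    in_wt = revertant_median_fitness
    return EpistasisRecord(population, founder_gene, in_del, in_wt, in_del - in_wt)


def classify_reversion(
    founder_fitness: float,
    evolved_fitness: float,
    revertant_median_fitness: float,
    population: int | str = 0,
) -> ReversionOutcome:
    """Classify the reversion of a founding deletion as entrenched or not."""
    for v in (founder_fitness, evolved_fitness, revertant_median_fitness):
        if not math.isfinite(v):
            raise ValueError("all three fitnesses must be finite")
    rev_wt = -founder_fitness
    rev_evolved = revertant_median_fitness - evolved_fitness
    return ReversionOutcome(population, rev_wt, rev_evolved,
                            entrenched=(rev_wt > 0) and (rev_evolved < 0))


def epistasis_table(
    merged: pd.DataFrame,
    drop_missing: bool = True,
    exclude_founders: Iterable[str] = (),
) -> pd.DataFrame:
    """Vectorised epsilon/entrenchment table for many populations.

    ``merged`` needs columns ``population``, ``founder_gene``,
    ``founder_fitness``, ``evolved_fitness``, ``revertant_fitness`` (the
    per-population median revertant fitness; NaN when no revertant was
    obtained).  Rows with a missing revertant are dropped (with ``drop_missing``)
    rather than raising — populations that could not be reverted carry no
    epistasis information.  ``exclude_founders`` removes descendants of the
    named founder genes (e.g. the entrenched ade2/hxk2/tps1 founders for the
    "without entrenched" variance decomposition).
    """
    df = merged.copy()
    if exclude_founders:
        df = df[~df["founder_gene"].isin(set(exclude_founders))]
    if drop_missing:
        df = df[df["revertant_fitness"].notna()]
    out = df[["population", "founder_gene"]].copy()
    out["effect_in_deletion_bg"] = df["evolved_fitness"] - df["founder_fitness"]
    out["effect_in_wt_bg"] = df["revertant_fitness"]
    out["epsilon"] = out["effect_in_deletion_bg"] - out["effect_in_wt_bg"]
    out["reversion_effect_wt"] = -df["founder_fitness"]
    out["reversion_effect_evolved"] = df["revertant_fitness"] - df["evolved_fitness"]
    out["entrenched"] = (out["reversion_effect_wt"] > 0) & (
        out["reversion_effect_evolved"] < 0
    )
    return out.reset_index(drop=True)


def retained_populations(
    revertant_counts: pd.DataFrame, min_reverted: int = 2
) -> pd.DataFrame:
    """Filter founders by reversion success before model fitting.

    ``revertant_counts``: columns ``founder_gene`` and ``population`` (one row
    per successfully reverted population).  Founders with fewer than
    ``min_reverted`` reverted populations are excluded entirely — a founder
    represented by a single reverted population cannot separate its gene
    effect from population-level stochasticity.
    """
    counts = revertant_counts.groupby("founder_gene")["population"].nunique()
    keep = counts[counts >= min_reverted].index
    return revertant_counts[revertant_counts["founder_gene"].isin(keep)].reset_index(
        drop=True
    )
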