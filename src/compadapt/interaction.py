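"""Functional-module assignment from genetic-interaction profiles.

A genome-scale genetic interaction map gives every gene a profile: its vector
of epistasis scores against many partner genes.  Genes with correlated
profiles tend to act in the same pathway or complex, so profile correlation
is a functional similarity metric.  Two groupings are provided:

* :func:`ward_cluster` — agglomerative hierarchical clustering under Ward's
  minimum-variance criterion on the distance ``1 - |rho|`` (Pearson), using
  the squared-dissimilarity ("ward.D2") convention: input dissimilarities are
  squared inside the Lance-Williams update and merge heights are reported on
  the original scale.  This is the variant scipy implements for a
  precomputed distance matrix, and results are reproducible bit-for-bit.
* :func:`interaction_clusters` — connected components of the graph linking
  gene pairs whose profile correlation exceeds a threshold (default 0.2),
  used to group evolved-mutation target genes into "interaction clusters".
  The edge rule uses signed ``rho > threshold`` by default (anti-correlated
  profiles suggest opposite, not shared, function); set ``use_abs`` to
  threshold ``|rho|`` instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "ProfileCorrelation",
    "ClusterAssignment",
    "profile_correlations",
    "ward_cluster",
    "interaction_clusters",
    "within_module_mean_correlation",
    "linkage_to_newick",
]


@dataclass(frozen=True)
class ProfileCorrelation:
    """Pairwise Pearson correlations of genetic-interaction profiles.

    ``rho`` is symmetric with unit diagonal; entries are NaN where two
    profiles shared fewer than ``min_shared`` scored positions.
    """

    genes: tuple[str, ...]
    rho: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.genes, columns=self.genes)


@dataclass(frozen=True)
class ClusterAssignment:
    labels: dict[str, int]
    linkage: np.ndarray | None = field(default=None, compare=False)

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, name="cluster")


def profile_correlations(
    matrix: pd.DataFrame, min_shared: int = 3
) -> ProfileCorrelation:
    """Pairwise profile correlations from a gene-by-gene score matrix.

    ``matrix``: rows are gene profiles, columns the partner genes (row order
    equals column order); NaN marks missing scores.  For each pair the
    correlation is computed over partner positions scored in both profiles,
    excluding the pair's own columns (self-interaction positions and the
    mutual score would trivially inflate similarity).  Pairs sharing fewer
    than ``min_shared`` positions are masked as NaN.
    """
    if list(matrix.index) != list(matrix.columns):
        raise ValueError("row order must equal column order")
    genes = tuple(matrix.index)
    vals = matrix.to_numpy(dtype=float)
    n = len(genes)
    rho = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            keep = np.ones(n, dtype=bool)
            keep[[a, b]] = False
            pa, pb = vals[a, keep], vals[b, keep]
            ok = np.isfinite(pa) & np.isfinite(pb)
            if ok.sum() < min_shared:
                rho[a, b] = rho[b, a] = np.nan
                continue
            xa, xb = pa[ok] - pa[ok].mean(), pb[ok] - pb[ok].mean()
            denom = np.sqrt((xa @ xa) * (xb @ xb))
            r = float(xa @ xb / denom) if denom > 0 else np.nan
            rho[a, b] = rho[b, a] = r
    return ProfileCorrelation(genes, rho)


def ward_cluster(
    corr: ProfileCorrelation,
    k: int | None = None,
    height: float | None = None,
) -> ClusterAssignment:
    """Ward (D2 convention) hierarchical clustering on the distance 1 - |rho|.

    Cut the tree at ``k`` clusters or at a merge ``height``; exactly one of
    the two must be given.  Labels are renumbered by first appearance in the
    input gene order so they are invariant to internal tie-breaking.
    """
    n = len(corr.genes)
    if (k is None) == (height is None):
        raise ValueError("give exactly one of k or height")
    if k is not None and not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}]")
    d = 1.0 - np.abs(corr.rho)
    if np.isnan(d).any():
        raise ValueError("correlation matrix has masked entries; "
                         "ward_cluster needs a complete distance matrix")
    np.fill_diagonal(d, 0.0)
    Z = hierarchy.linkage(squareform(d, checks=False), method="ward")
    if k is not None:
        raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    else:
        raw = hierarchy.fcluster(Z, t=height, criterion="distance")
    labels: dict[str, int] = {}
    remap: dict[int, int] = {}
    for gene, lab in zip(corr.genes, raw):
        remap.setdefault(int(lab), len(remap) + 1)
        labels[gene] = remap[int(lab)]
    return ClusterAssignment(labels, linkage=Z)


def interaction_clusters(
    corr: ProfileCorrelation,
    threshold: float = 0.2,
    use_abs: bool = False,
    overrides: dict[str, int] | None = None,
) -> ClusterAssignment:
    """Threshold-graph interaction clusters (connected components).

    Genes whose profile correlation exceeds ``threshold`` are connected;
    clusters are the connected components (singletons allowed).  ``overrides``
    maps genes to hand-assigned cluster ids for pathways poorly represented
    in the interaction map; overridden genes are removed from the graph
    first.
    """
    overrides = overrides or {}
    g = nx.Graph()
    free = [gene for gene in corr.genes if gene not in overrides]
    g.add_nodes_from(free)
    idx = {gene: i for i, gene in enumerate(corr.genes)}
    for a in free:
        for b in free:
            if a >= b:
                continue
            r = corr.rho[idx[a], idx[b]]
            if np.isnan(r):
                continue
            score = abs(r) if use_abs else r
            if score > threshold:
                g.add_edge(a, b)
    labels: dict[str, int] = {}
    next_label = (max(overrides.values()) if overrides else 0) + 1
    components = sorted(nx.connected_components(g),
                        key=lambda c: min(idx[x] for x in c))
    for comp in components:
        for gene in comp:
            labels[gene] = next_label
        next_label += 1
    labels.update(overrides)
    return ClusterAssignment({gene: labels[gene] for gene in corr.genes})


def linkage_to_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    """Render a hierarchical merge tree as a Newick string (branch lengths
    are differences in merge height)."""
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.get_left(), node.dist)
        right = walk(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def within_module_mean_correlation(
    corr: ProfileCorrelation, modules: dict[str, str] | pd.Series
) -> pd.Series:
    """Mean pairwise profile correlation within each module.

    Modules with a single gene have no within-module pair and are reported
    as NaN.
    """
    mod = pd.Series(modules)
    idx = {gene: i for i, gene in enumerate(corr.genes)}
    out: dict[str, float] = {}
    for m, genes in mod.groupby(mod).groups.items():
        members = [g for g in genes if g in idx]
        if len(members) < 2:
            out[str(m)] = float("nan")
            continue
        vals = [
            corr.rho[idx[a], idx[b]]
            for i, a in enumerate(members)
            for b in members[i + 1:]
        ]
        out[str(m)] = float(np.nanmean(vals))
    return pd.Series(out, name="mean_rho")
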