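"""Independent oracles used by the test suite.

These deliberately avoid the code paths of the package: the likelihood
oracles integrate the random effects out numerically (tensorized
Gauss-Hermite quadrature) or build the dense joint covariance explicitly;
the MI oracles are literal loop transcriptions of the plug-in formulas.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import multivariate_normal, norm


def gh_marginal_loglik(params, data: pd.DataFrame, panel: pd.DataFrame,
                       spec, value_col: str = "value",
                       n_nodes: int = 90) -> float:
    """Marginal log-likelihood by nested Gauss-Hermite integration over the
    module, gene and population random effects (slow; tiny instances only)."""
    t, w = np.polynomial.hermite_e.hermegauss(n_nodes)  # weight e^{-x^2/2}
    logw = np.log(w) - 0.5 * math.log(2 * math.pi)

    def nodes(sigma):
        if sigma == 0:
            return np.array([0.0]), np.array([0.0])
        return sigma * t, logw

    sm = params.sigma_m if spec.include_module else 0.0
    sg = params.sigma_g if spec.include_gene else 0.0
    pan = panel.set_index("gene")
    total = 0.0
    for module, mgrp in data.groupby(data["gene"].map(pan["module"])):
        m_nodes, m_logw = nodes(sm)
        log_per_gene = np.zeros((len(m_nodes), 0))
        acc_m = np.zeros(len(m_nodes))
        for gene, ggrp in mgrp.groupby("gene"):
            mu = params.alpha
            if spec.include_beta:
                mu += params.beta * float(pan.loc[gene, "initial_fitness"])
            g_nodes, g_logw = nodes(sg)
            acc_g = np.zeros((len(m_nodes), len(g_nodes)))
            for _, pgrp in ggrp.groupby("population"):
                p_nodes, p_logw = nodes(params.sigma_p)
                y = pgrp[value_col].to_numpy()
                # (m, g, p) grid of sum_l log phi(y_l - mu - m - g - p)
                shift = (m_nodes[:, None, None] + g_nodes[None, :, None]
                         + p_nodes[None, None, :])
                ll = norm.logpdf(
                    y[None, None, None, :] - mu - shift[..., None],
                    scale=params.sigma_tau,
                ).sum(axis=-1)
                acc_g += logsumexp(ll + p_logw[None, None, :], axis=-1)
            acc_m += logsumexp(acc_g + g_logw[None, :], axis=-1)
        total += float(logsumexp(acc_m + m_logw))
    return total


def dense_marginal_loglik(params, data: pd.DataFrame, panel: pd.DataFrame,
                          spec, value_col: str = "value") -> float:
    """Marginal log-likelihood via the explicit dense joint covariance."""
    pan = panel.set_index("gene")
    df = data.reset_index(drop=True)
    n = len(df)
    mod = df["gene"].map(pan["module"]).to_numpy()
    gene = df["gene"].to_numpy()
    pop = df["population"].to_numpy()
    x = df["gene"].map(pan["initial_fitness"]).to_numpy(dtype=float)
    mu = np.full(n, params.alpha, dtype=float)
    if spec.include_beta:
        mu = mu + params.beta * x
    sm2 = params.sigma_m**2 if spec.include_module else 0.0
    sg2 = params.sigma_g**2 if spec.include_gene else 0.0
    C = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            c = 0.0
            if mod[a] == mod[b]:
                c += sm2
                if gene[a] == gene[b]:
                    c += sg2
                    if pop[a] == pop[b]:
                        c += params.sigma_p**2
                        if a == b:
                            c += params.sigma_tau**2
            C[a, b] = c
    return float(multivariate_normal(mean=mu, cov=C).logpdf(
        df[value_col].to_numpy()))


def brute_force_mi(founders: list, hits: dict) -> float:
    """Literal evaluation of M(W,g) = sum_g sum_W p(W) sum_m p(m|W)
    log2[p(m|W)/p(m)] with plug-in frequencies and 0 log 0 = 0."""
    n = len(founders)
    levels = sorted(set(founders))
    total = 0.0
    for target, ind in hits.items():
        assert len(ind) == n
        for W in levels:
            in_W = [i for i in range(n) if founders[i] == W]
            pW = len(in_W) / n
            for m in (0, 1):
                p_m_W = sum(1 for i in in_W if ind[i] == m) / len(in_W)
                p_m = sum(1 for i in range(n) if ind[i] == m) / n
                if p_m_W > 0:
                    total += pW * p_m_W * math.log2(p_m_W / p_m)
    return total


def brute_force_conditional_mi(founders: list, strata: list,
                               hits: dict) -> float:
    """Literal evaluation of M(W,g|Z) = sum_g sum_Z p(Z) sum_W p(W|Z)
    sum_m p(m|W,Z) log2[p(m|W,Z)/p(m|Z)]."""
    n = len(founders)
    total = 0.0
    for target, ind in hits.items():
        for Z in sorted(set(strata)):
            in_Z = [i for i in range(n) if strata[i] == Z]
            pZ = len(in_Z) / n
            for W in sorted({founders[i] for i in in_Z}):
                in_WZ = [i for i in in_Z if founders[i] == W]
                pW_Z = len(in_WZ) / len(in_Z)
                for m in (0, 1):
                    p_m_WZ = sum(1 for i in in_WZ if ind[i] == m) / len(in_WZ)
                    p_m_Z = sum(1 for i in in_Z if ind[i] == m) / len(in_Z)
                    if p_m_WZ > 0:
                        total += pZ * pW_Z * p_m_WZ * math.log2(p_m_WZ / p_m_Z)
    return total
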