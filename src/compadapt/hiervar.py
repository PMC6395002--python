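"""Nested hierarchical random-effects models of fitness gain and epistasis.

Model
-----
Each replicate measurement ``l`` of evolved population ``k``, descended from
founder gene ``j`` in functional module ``i``, is

    y_ijkl = alpha + beta * x_ij + m_i + g_ij + p_ijk + tau_ijkl

with ``x_ij`` the founder's initial fitness and independent zero-mean normal
random effects: ``m_i ~ N(0, sigma_m^2)`` (module), ``g_ij ~ N(0, sigma_g^2)``
(gene), ``p_ijk ~ N(0, sigma_p^2)`` (population, i.e. evolutionary
stochasticity) and ``tau_ijkl ~ N(0, sigma_tau^2)`` (measurement error).
Fitting is by maximum likelihood (not REML): the exact Gaussian marginal
log-likelihood after integrating out the random effects, including the
normal constant, so log-likelihoods of nested models are directly comparable
and usable in likelihood-ratio tests (including tests of the fixed effect
beta, which REML would not allow).

Computation
-----------
The marginal covariance is block-diagonal by module, so the likelihood is
computed blockwise.  Within a block, replicates are first collapsed to
per-population sufficient statistics (an exact step: the within-population
contrasts are iid N(0, sigma_tau^2)); the remaining population-level
covariance ``diag(v_k) + sigma_g^2 * [same gene] + sigma_m^2`` is handled by
two nested rank-one Woodbury identities, giving an O(n) likelihood
evaluation.  Equality with a dense multivariate-normal evaluation and with a
Gauss-Hermite integration oracle is asserted in the test suite.

Variances are optimized directly under a ``sigma >= 0`` box constraint, so
boundary estimates of exactly zero (which occur in practice for the gene
component of the epistasis model) are representable without transform
tricks; a multistart at the module/gene boundary guards against local
optima.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "HierParams",
    "ModelSpec",
    "HierModelFit",
    "VarianceDecomposition",
    "LRTResult",
    "NumericalDegeneracyError",
    "marginal_loglik",
    "fit_ml",
    "variance_fractions",
    "likelihood_ratio_test",
    "bootstrap_se",
    "STANDARD_SPECS",
]

_LOG2PI = math.log(2.0 * math.pi)


class NumericalDegeneracyError(ValueError):
    """Raised when the marginal covariance is singular (all variances zero)."""


@dataclass(frozen=True)
class HierParams:
    """Parameters of the hierarchical model, in percent per generation.

    ``beta`` is dimensionless (slope on founder initial fitness); excluded
    terms are conventionally held at 0.
    """

    alpha: float
    beta: float = 0.0
    sigma_m: float = 0.0
    sigma_g: float = 0.0
    sigma_p: float = 0.0
    sigma_tau: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sigma_m", "sigma_g", "sigma_p", "sigma_tau"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ModelSpec:
    """Which terms of the full model are included.

    The population random effect is always present (it is the replication
    level of the design).  One spec is nested in another iff its included
    terms are a subset of the other's.
    """

    include_beta: bool = True
    include_module: bool = True
    include_gene: bool = True
    include_population: bool = True
    response: str = "fitness_gain"

    def __post_init__(self) -> None:
        if not self.include_population:
            raise ValueError("the population random effect is always included")

    @property
    def terms(self) -> frozenset[str]:
        t = {"alpha", "population", "error"}
        if self.include_beta:
            t.add("beta")
        if self.include_module:
            t.add("module")
        if self.include_gene:
            t.add("gene")
        return frozenset(t)

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return self.response == other.response and self.terms <= other.terms

    @property
    def n_params(self) -> int:
        return len(self.terms)

    @property
    def label(self) -> str:
        bits = ["alpha"]
        if self.include_beta:
            bits.append("beta*x")
        if self.include_module:
            bits.append("m_i")
        if self.include_gene:
            bits.append("g_ij")
        bits.append("p_ijk")
        return " + ".join(bits)


#: The four nested specs fitted throughout: population-only baseline with a
#: gene effect, plus module, plus initial-fitness slope, plus both.
STANDARD_SPECS = {
    "g+p": ModelSpec(include_beta=False, include_module=False),
    "m+g+p": ModelSpec(include_beta=False, include_module=True),
    "b+g+p": ModelSpec(include_beta=True, include_module=False),
    "b+m+g+p": ModelSpec(include_beta=True, include_module=True),
}


@dataclass(frozen=True)
class HierModelFit:
    spec: ModelSpec
    params: HierParams
    loglik: float
    n_measurements: int
    converged: bool
    diagnostics: dict = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class VarianceDecomposition:
    """Fractions of between-population variance attributed to each component."""

    fraction_fitness: float
    fraction_module: float
    fraction_gene: float
    fraction_population: float
    fraction_error: float

    def as_dict(self) -> dict[str, float]:
        return {
            "fitness": self.fraction_fitness,
            "module": self.fraction_module,
            "gene": self.fraction_gene,
            "population": self.fraction_population,
            "error": self.fraction_error,
        }

    @property
    def fraction_founder_identity(self) -> float:
        """Fitness + module + gene: everything attributable to the founder."""
        return self.fraction_fitness + self.fraction_module + self.fraction_gene


@dataclass(frozen=True)
class LRTResult:
    stat: float
    df: int
    p_value: float
    boundary_corrected: bool


# ---------------------------------------------------------------------------
# sufficient statistics


class _SuffStats:
    """Per-population sufficient statistics, sorted so genes are contiguous
    within modules.  Collapsing replicates is exact for the nested model."""

    __slots__ = (
        "L", "ybar", "rss", "x", "gene_of_pop", "module_of_gene",
        "n_pops", "n_genes", "n_modules", "n_measurements", "pop_ids",
        "gene_names", "module_names",
    )

    def __init__(self, data: pd.DataFrame, panel: pd.DataFrame, value_col: str):
        required = {"gene", "population", value_col}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"data is missing columns: {sorted(missing)}")
        pan = panel.set_index("gene")
        unknown = set(data["gene"]) - set(pan.index)
        if unknown:
            raise ValueError(f"genes absent from panel: {sorted(unknown)}")
        df = data.copy()
        df["_module"] = df["gene"].map(pan["module"])
        df["_x"] = df["gene"].map(pan["initial_fitness"]).astype(float)
        grp = df.groupby(["_module", "gene", "population"], sort=True)
        agg = grp[value_col].agg(["count", "mean"])
        # within-population residual sum of squares
        means = grp[value_col].transform("mean")
        df["_sq"] = (df[value_col] - means) ** 2
        rss = df.groupby(["_module", "gene", "population"], sort=True)["_sq"].sum()
        self.L = agg["count"].to_numpy(dtype=float)
        self.ybar = agg["mean"].to_numpy(dtype=float)
        self.rss = rss.to_numpy(dtype=float)
        self.x = grp["_x"].first().to_numpy(dtype=float)
        idx = agg.index
        self.pop_ids = list(idx)
        gene_keys = pd.MultiIndex.from_arrays(
            [idx.get_level_values(0), idx.get_level_values(1)]
        )
        gene_codes, gene_uniques = pd.factorize(gene_keys, sort=True)
        self.gene_of_pop = gene_codes.astype(np.intp)
        mod_codes, mod_uniques = pd.factorize(
            gene_uniques.get_level_values(0), sort=True
        )
        self.module_of_gene = mod_codes.astype(np.intp)
        self.n_pops = len(self.L)
        self.n_genes = len(gene_uniques)
        self.n_modules = len(mod_uniques)
        self.n_measurements = int(self.L.sum())
        self.gene_names = list(gene_uniques.get_level_values(1))
        self.module_names = list(mod_uniques)


def _loglik_stats(s: _SuffStats, p: HierParams, spec: ModelSpec) -> float:
    """Exact marginal log-likelihood from sufficient statistics (nats)."""
    st2 = p.sigma_tau**2
    sp2 = p.sigma_p**2
    sg2 = p.sigma_g**2 if spec.include_gene else 0.0
    sm2 = p.sigma_m**2 if spec.include_module else 0.0

    has_reps = bool(np.any(s.L > 1))
    if st2 == 0.0:
        if has_reps:
            raise NumericalDegeneracyError(
                "sigma_tau = 0 with replicate measurements: singular covariance"
            )
        if sp2 == 0.0 and sg2 == 0.0 and sm2 == 0.0:
            raise NumericalDegeneracyError("all variance components are zero")

    mu = p.alpha + (p.beta * s.x if spec.include_beta else 0.0)
    r = s.ybar - mu
    v = sp2 + st2 / s.L
    if np.any(v <= 0):
        raise NumericalDegeneracyError("population-level variance is zero")
    w = 1.0 / v

    # replicate level: contrasts are iid N(0, sigma_tau^2); the 0.5*log L term
    # is the Jacobian of the mean/contrast transform
    rep = 0.0
    if has_reps:
        nres = s.L - 1.0
        rep = float(np.sum(-0.5 * nres * (_LOG2PI + math.log(st2))
                           - s.rss / (2.0 * st2)))
    rep -= 0.5 * float(np.sum(np.log(s.L)))

    # gene level (rank-one update per gene over its populations)
    S1 = np.bincount(s.gene_of_pop, weights=w, minlength=s.n_genes)
    Sr = np.bincount(s.gene_of_pop, weights=w * r, minlength=s.n_genes)
    Srr = np.bincount(s.gene_of_pop, weights=w * r * r, minlength=s.n_genes)
    Slogv = np.bincount(s.gene_of_pop, weights=np.log(v), minlength=s.n_genes)
    den_g = 1.0 + sg2 * S1
    a1 = S1 / den_g
    ar = Sr / den_g
    arr = Srr - sg2 * Sr * Sr / den_g
    logdet_g = Slogv + np.log(den_g)

    # module level (rank-one update over all populations in the module)
    B1 = np.bincount(s.module_of_gene, weights=a1, minlength=s.n_modules)
    Br = np.bincount(s.module_of_gene, weights=ar, minlength=s.n_modules)
    Brr = np.bincount(s.module_of_gene, weights=arr, minlength=s.n_modules)
    logdet = np.bincount(s.module_of_gene, weights=logdet_g, minlength=s.n_modules)
    den_m = 1.0 + sm2 * B1
    logdet = logdet + np.log(den_m)
    quad = Brr - sm2 * Br * Br / den_m

    npop_m = np.bincount(
        s.module_of_gene[s.gene_of_pop], minlength=s.n_modules
    ).astype(float)
    mvn = float(np.sum(-0.5 * (npop_m * _LOG2PI + logdet + quad)))
    return rep + mvn


def marginal_loglik(
    params: HierParams,
    data: pd.DataFrame,
    panel: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    value_col: str = "value",
) -> float:
    """Exact Gaussian marginal log-likelihood (nats) of the nested model.

    ``data`` holds one row per replicate measurement with columns ``gene``,
    ``population`` and ``value_col``; ``panel`` maps genes to modules and
    initial fitnesses (columns ``gene``, ``module``, ``initial_fitness``).
    Measurements are jointly normal with mean ``alpha + beta*x`` and
    covariance ``sigma_m^2 [same module] + sigma_g^2 [same gene] +
    sigma_p^2 [same population] + sigma_tau^2 [same measurement]``.
    """
    return _loglik_stats(_SuffStats(data, panel, value_col), params, spec)


# ---------------------------------------------------------------------------
# fitting


def _pack(p: HierParams, spec: ModelSpec) -> np.ndarray:
    vals = [p.alpha]
    if spec.include_beta:
        vals.append(p.beta)
    if spec.include_module:
        vals.append(p.sigma_m)
    if spec.include_gene:
        vals.append(p.sigma_g)
    vals += [p.sigma_p, p.sigma_tau]
    return np.array(vals, dtype=float)


def _unpack(theta: np.ndarray, spec: ModelSpec) -> HierParams:
    it = iter(theta)
    alpha = next(it)
    beta = next(it) if spec.include_beta else 0.0
    sm = next(it) if spec.include_module else 0.0
    sg = next(it) if spec.include_gene else 0.0
    sp = next(it)
    st = next(it)
    return HierParams(alpha, beta, max(sm, 0.0), max(sg, 0.0),
                      max(sp, 0.0), max(st, 0.0))


def _moment_starts(s: _SuffStats, spec: ModelSpec) -> list[HierParams]:
    """Data-driven starting points: moment split of the total variance."""
    y = s.ybar
    alpha = float(np.mean(y))
    beta = 0.0
    resid = y - alpha
    if spec.include_beta:
        xc = s.x - s.x.mean()
        denom = float(xc @ xc)
        if denom > 0:
            beta = float(xc @ resid) / denom
        alpha = float(np.mean(y - beta * s.x))
        resid = y - alpha - beta * s.x
    tot = max(float(np.var(resid)), 1e-4)
    st = math.sqrt(max(float(np.sum(s.rss)) /
                       max(float(np.sum(s.L - 1.0)), 1.0), 1e-6))
    k = 1 + int(spec.include_module) + int(spec.include_gene)
    share = math.sqrt(tot / k)
    starts = []
    for sm_f, sg_f, sp_f in ((1, 1, 1), (0, 0, 1.5), (2, 0.5, 0.5)):
        starts.append(
            HierParams(
                alpha,
                beta,
                sm_f * share if spec.include_module else 0.0,
                sg_f * share if spec.include_gene else 0.0,
                sp_f * share,
                st,
            )
        )
    return starts


def fit_ml(
    data: pd.DataFrame,
    panel: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    starts: Sequence[HierParams] | None = None,
    value_col: str = "value",
    gtol: float = 1e-8,
) -> HierModelFit:
    """Maximum-likelihood fit of a nested hierarchical model.

    Maximizes :func:`marginal_loglik` over the intercept, the initial-fitness
    slope (if included) and the included standard deviations, the latter
    constrained to be nonnegative (boundary estimates of exactly 0 are
    legitimate outcomes).  Multiple starting points are tried and the best
    optimum kept; non-convergence is flagged on the result, not raised.
    """
    s = _SuffStats(data, panel, value_col)
    if spec.include_module and s.n_modules < 2:
        raise ValueError("need >= 2 modules to estimate a module effect")
    if spec.include_gene and s.n_genes < 2:
        raise ValueError("need >= 2 genes to estimate a gene effect")

    has_reps = bool(np.any(s.L > 1))
    start_list = list(starts) if starts is not None else _moment_starts(s, spec)

    lo_tau = 1e-6 if has_reps else 0.0
    bounds = [(None, None)]
    if spec.include_beta:
        bounds.append((None, None))
    if spec.include_module:
        bounds.append((0.0, None))
    if spec.include_gene:
        bounds.append((0.0, None))
    bounds += [(0.0, None), (lo_tau, None)]

    def nll(theta: np.ndarray) -> float:
        try:
            return -_loglik_stats(s, _unpack(theta, spec), spec)
        except NumericalDegeneracyError:
            return np.inf

    best = None
    n_success = 0
    for p0 in start_list:
        theta0 = _pack(p0, spec)
        theta0[-1] = max(theta0[-1], lo_tau)
        res = optimize.minimize(
            nll, theta0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 2000, "ftol": 1e-12, "gtol": gtol},
        )
        n_success += int(res.success)
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    params = _unpack(best.x, spec)
    return HierModelFit(
        spec=spec,
        params=params,
        loglik=-float(best.fun),
        n_measurements=s.n_measurements,
        converged=bool(best.success),
        diagnostics={
            "n_starts": len(start_list),
            "n_converged_starts": n_success,
            "message": str(best.message),
            "n_populations": s.n_pops,
            "n_genes": s.n_genes,
            "n_modules": s.n_modules,
        },
    )


def fit_standard_models(
    data: pd.DataFrame,
    panel: pd.DataFrame,
    value_col: str = "value",
    response: str = "fitness_gain",
) -> dict[str, HierModelFit]:
    """Fit the four standard nested models; keys as in :data:`STANDARD_SPECS`."""
    return {
        key: fit_ml(data, panel, replace(sp, response=response), value_col=value_col)
        for key, sp in STANDARD_SPECS.items()
    }


# ---------------------------------------------------------------------------
# variance partitioning and tests


def variance_fractions(
    fit: HierModelFit,
    data: pd.DataFrame,
    panel: pd.DataFrame,
    value_col: str = "value",
) -> VarianceDecomposition:
    """Partition between-population variance among the model components.

    The fixed-effect share is the population-weighted empirical variance of
    ``beta * x_ij`` (each population counted once); the random shares are the
    fitted variances.  Requires the full model spec.
    """
    spec = fit.spec
    if not (spec.include_beta and spec.include_module and spec.include_gene):
        raise ValueError("variance_fractions requires the full model spec")
    s = _SuffStats(data, panel, value_col)
    p = fit.params
    v_fit = p.beta**2 * float(np.var(s.x))  # ddof=0, one entry per population
    comps = np.array([v_fit, p.sigma_m**2, p.sigma_g**2,
                      p.sigma_p**2, p.sigma_tau**2])
    fr = comps / comps.sum()
    return VarianceDecomposition(*map(float, fr))


def likelihood_ratio_test(
    fit_full: HierModelFit,
    fit_nested: HierModelFit,
    boundary_corrected: bool = False,
) -> LRTResult:
    """Likelihood-ratio test of a nested model against a richer one.

    ``stat = 2 (l_full - l_nested)`` referred to chi-square with df equal to
    the number of added parameters.  With ``boundary_corrected`` and a single
    added variance component, the 50:50 mixture ``(chi2_0 + chi2_1)/2`` is
    used instead, acknowledging that the null value sits on the boundary of
    the parameter space (halves the p-value for positive statistics).
    """
    if not fit_nested.spec.is_nested_in(fit_full.spec):
        raise ValueError("second fit's spec must be nested in the first's")
    if fit_nested.spec.terms == fit_full.spec.terms:
        df = 0
    else:
        df = len(fit_full.spec.terms - fit_nested.spec.terms)
    stat = 2.0 * (fit_full.loglik - fit_nested.loglik)
    stat = max(stat, 0.0)  # optimizer tolerance can leave a tiny negative
    if df == 0:
        return LRTResult(stat, 0, 1.0, False)
    added_variance = "module" in fit_full.spec.terms - fit_nested.spec.terms or \
        "gene" in fit_full.spec.terms - fit_nested.spec.terms
    if boundary_corrected and df == 1 and added_variance:
        p = 0.5 * float(stats.chi2.sf(stat, 1)) if stat > 0 else 1.0
        return LRTResult(stat, 1, p, True)
    return LRTResult(stat, df, float(stats.chi2.sf(stat, df)), False)


def bootstrap_se(
    fit: HierModelFit,
    data: pd.DataFrame,
    panel: pd.DataFrame,
    n_boot: int = 50,
    seed: int | np.random.Generator = 0,
    value_col: str = "value",
) -> pd.DataFrame:
    """Parametric-bootstrap standard errors for a fitted model.

    Simulates ``n_boot`` datasets from the fitted parameters on the observed
    design (same module/gene/population structure, replicate counts and x
    values), refits each, and returns per-parameter bootstrap means and
    standard deviations.  Simulation happens at the level of sufficient
    statistics (population means and within-population sums of squares),
    which is distributionally exact for this model.
    """
    rng = np.random.default_rng(seed)
    s = _SuffStats(data, panel, value_col)
    spec, p = fit.spec, fit.params
    mu = p.alpha + (p.beta * s.x if spec.include_beta else 0.0)
    names = ["alpha"]
    if spec.include_beta:
        names.append("beta")
    if spec.include_module:
        names.append("sigma_m")
    if spec.include_gene:
        names.append("sigma_g")
    names += ["sigma_p", "sigma_tau"]

    draws = np.empty((n_boot, len(names)))
    nres = (s.L - 1.0).astype(float)
    module_of_pop = s.module_of_gene[s.gene_of_pop]
    for b in range(n_boot):
        m = rng.normal(0.0, p.sigma_m if spec.include_module else 0.0, s.n_modules)
        g = rng.normal(0.0, p.sigma_g if spec.include_gene else 0.0, s.n_genes)
        pop = rng.normal(0.0, p.sigma_p, s.n_pops)
        taubar = rng.normal(0.0, p.sigma_tau / np.sqrt(s.L))
        ybar = mu + m[module_of_pop] + g[s.gene_of_pop] + pop + taubar
        rss = p.sigma_tau**2 * rng.chisquare(np.maximum(nres, 1e-12)) * (nres > 0)
        sim = _SuffStats.__new__(_SuffStats)
        for attr in ("L", "x", "gene_of_pop", "module_of_gene", "n_pops",
                     "n_genes", "n_modules", "n_measurements", "pop_ids",
                     "gene_names", "module_names"):
            setattr(sim, attr, getattr(s, attr))
        sim.ybar = ybar
        sim.rss = rss

        def nll(theta: np.ndarray) -> float:
            try:
                return -_loglik_stats(sim, _unpack(theta, spec), spec)
            except NumericalDegeneracyError:
                return np.inf

        lo_tau = 1e-6 if np.any(s.L > 1) else 0.0
        bounds = [(None, None)] + [(None, None)] * int(spec.include_beta)
        bounds += [(0.0, None)] * (int(spec.include_module) + int(spec.include_gene))
        bounds += [(0.0, None), (lo_tau, None)]
        res = optimize.minimize(
            nll, _pack(p, spec), method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 2000, "ftol": 1e-12},
        )
        draws[b] = res.x
    return pd.DataFrame(
        {"estimate": _pack(p, spec), "boot_mean": draws.mean(axis=0),
         "boot_se": draws.std(axis=0, ddof=1)},
        index=names,
    )
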