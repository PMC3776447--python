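"""Null-distribution machinery: permutation, scaled chi-square, normal mixture, FDR.

The permutation null permutes the phenotype labels and recomputes the
statistic; working covariances are re-estimated inside every permutation
(the working covariance is the error covariance conditional on x, so it
changes with the permuted pairing). The scaled chi-square (Satterthwaite)
p-value matches the first two permutation moments of Q to kappa*chisq_nu;
the normal-mixture refinement fits a two-component Gaussian mixture to the
probit-transformed per-permutation scaled-chi-square p-values to sharpen
small p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import chi2, norm

import pandas as pd

from . import covariance as _cov
from . import statistic as _stat
from ._types import (
    CovarianceMatrix,
    ExpressionMatrix,
    GeneSetCollection,
    Phenotype,
    TegsResult,
    WorkingCovarianceSpec,
)

logger = logging.getLogger("tegs")

__all__ = [
    "PermutationDraws",
    "NormalMixtureFit",
    "permutation_test",
    "satterthwaite_pvalue",
    "normal_mixture_pvalue",
    "fit_normal_mixture",
    "qvalues",
    "test_gene_sets",
]

DEFAULT_MIN_B = 100


@dataclass
class PermutationDraws:
    """The permutation null sample of the statistic."""

    Q_values: np.ndarray
    B: int
    seed: int | None = None
    satt_p_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.Q_values = np.asarray(self.Q_values, dtype=float).ravel()
        if self.Q_values.size != self.B:
            raise ValueError("Q_values length does not match B")
        if np.any(self.Q_values < 0):
            raise ValueError("permuted statistics must be nonnegative")


@dataclass
class NormalMixtureFit:
    """Two-component normal mixture fitted to probit-scale null p-values."""

    pi: np.ndarray  # length 2, sums to 1
    mu: np.ndarray  # length 2
    var: np.ndarray  # length 2
    loglik: float
    converged: bool

    def cdf(self, z: float | np.ndarray) -> np.ndarray:
        sd = np.sqrt(self.var)
        return self.pi[0] * norm.cdf((z - self.mu[0]) / sd[0]) + self.pi[1] * norm.cdf(
            (z - self.mu[1]) / sd[1]
        )


# ---------------------------------------------------------------------------
# Permutation engine

def _permuted_x(x: np.ndarray, B: int, rng: np.random.Generator) -> np.ndarray:
    """B random permutations of x, as a (B, n) array."""
    keys = rng.random((B, x.size))
    order = np.argsort(keys, axis=1)
    return x[order]


def _batched_null_Q(
    Yc: np.ndarray,
    Xp: np.ndarray,
    spec: WorkingCovarianceSpec,
    n_samples: int,
) -> np.ndarray:
    """Q for every permuted phenotype row of Xp, re-estimating V per row."""
    Xc = Xp - Xp.mean(axis=1, keepdims=True)
    s_all = Xc @ Yc  # (B, p) score vectors
    if spec.kind == "indpt":
        return np.einsum("bp,bp->b", s_all, s_all)
    if spec.kind == "supplied":
        factor = cho_factor(spec.supplied_matrix.matrix, lower=True)
        U = cho_solve(factor, s_all.T)
        return np.einsum("pb,pb->b", U, U)
    Sr = _cov._batched_residual_ridge(Yc, Xc, spec.ridge_percentile)
    if spec.kind == "unstr":
        Vb = Sr
    elif spec.kind == "cpsym":
        Vb = _cov._batched_cpsym(Sr)
    elif spec.kind == "f2":
        Vb = _cov._batched_factor(Sr, n_factors=spec.n_factors)
    elif spec.kind == "f-adpt":
        Vb = _cov._batched_factor(
            Sr,
            variance_fraction=spec.variance_fraction,
            max_factors=min(Yc.shape[1], n_samples - 1),
        )
    else:
        raise ValueError(f"unknown working covariance kind {spec.kind!r}")
    u = np.linalg.solve(Vb, s_all[:, :, None])[:, :, 0]
    return np.einsum("bp,bp->b", u, u)


def permutation_draws(
    expr: ExpressionMatrix,
    pheno: Phenotype,
    spec: WorkingCovarianceSpec,
    B: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw B permuted statistics Q^(b), re-estimating V in each permutation."""
    Yc = expr.values - expr.values.mean(axis=0, keepdims=True)
    Xp = _permuted_x(pheno.x, B, rng)
    max_retries = max(1, B // 100)  # a >1% failure rate is a run error
    for attempt in range(max_retries + 1):
        try:
            return _batched_null_Q(Yc, Xp, spec, expr.n_samples)
        except np.linalg.LinAlgError:
            # isolate failing rows and redraw them
            ok_rows = []
            bad = 0
            for b in range(B):
                try:
                    q = _batched_null_Q(Yc, Xp[b : b + 1], spec, expr.n_samples)
                    ok_rows.append(q[0])
                except np.linalg.LinAlgError:
                    bad += 1
                    Xp[b] = _permuted_x(pheno.x, 1, rng)[0]
                    ok_rows.append(np.nan)
            logger.warning("permutation_draws: %d covariance failures, retrying", bad)
            if bad > max_retries:
                raise RuntimeError(
                    f"covariance estimation failed in {bad}/{B} permutations"
                ) from None
    raise RuntimeError("covariance estimation kept failing across retries")


def permutation_test(
    expr: ExpressionMatrix,
    pheno: Phenotype,
    spec: WorkingCovarianceSpec,
    B: int = 1000,
    seed: int | None = None,
    methods: tuple[str, ...] = ("perm", "satt", "mix"),
    min_B: int = DEFAULT_MIN_B,
    set_name: str = "",
    keep_draws: bool = True,
) -> tuple[TegsResult, PermutationDraws]:
    """Full single-set test: observed Q, permutation null, and p-values.

    p_perm uses the (1 + #{Q^(b) >= Q_obs}) / (B + 1) convention, which is
    valid (never anti-conservative, never exactly zero) and counts ties
    conservatively.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if B < min_B:
        raise ValueError(f"B={B} is below the reporting floor {min_B}")
    rng = np.random.default_rng(seed)
    design = _stat.center_under_null(expr, pheno)
    V_obs = _cov.build_working_covariance(expr, pheno, spec)
    Q_obs = _stat.tegs_statistic(design, V_obs)
    Q_b = permutation_draws(expr, pheno, spec, B, rng)
    draws = PermutationDraws(Q_values=Q_b, B=B, seed=seed)

    p_perm = p_satt = p_mix = kappa = nu = None
    if "perm" in methods:
        p_perm = float((1 + np.sum(Q_b >= Q_obs)) / (B + 1))
    if "satt" in methods or "mix" in methods:
        kappa, nu, p_satt = satterthwaite_pvalue(Q_obs, draws)
    if "mix" in methods:
        draws.satt_p_values = chi2.sf(Q_b / kappa, nu)
        _, p_mix = normal_mixture_pvalue(p_satt, draws)
    result = TegsResult(
        set_name=set_name,
        Q_observed=Q_obs,
        p_perm=p_perm,
        p_satt=p_satt if "satt" in methods else None,
        p_mix=p_mix,
        kappa=kappa,
        nu=nu,
        B=B,
        seed=seed,
        covariance_kind=spec.label,
        n_genes=expr.n_genes,
        perm_Q=Q_b if keep_draws else None,
    )
    return result, draws


# ---------------------------------------------------------------------------
# Scaled chi-square (Satterthwaite)

def satterthwaite_pvalue(Q_obs: float, draws: PermutationDraws) -> tuple[float, float, float]:
    """Match permutation moments of Q to kappa * chisq_nu and return its tail.

    kappa = Var(Q) / (2 E(Q)), nu = 2 E(Q)^2 / Var(Q), with E and Var the
    sample mean and unbiased variance of the permuted statistics.
    """
    E = float(draws.Q_values.mean())
    Var = float(draws.Q_values.var(ddof=1))
    if Var <= 0:
        raise ValueError("permutation sample has zero variance; use the permutation p-value")
    kappa = Var / (2.0 * E)
    nu = 2.0 * E * E / Var
    p = float(chi2.sf(Q_obs / kappa, nu))
    return kappa, nu, max(p, np.finfo(float).tiny)


# ---------------------------------------------------------------------------
# Normal mixture refinement

def _em_1d(
    z: np.ndarray,
    pi1: float,
    mu: np.ndarray,
    var: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-8,
    var_floor: float = 1e-6,
) -> tuple[NormalMixtureFit, np.ndarray]:
    """EM for a univariate two-component Gaussian mixture; loglik is monotone."""
    pi = np.array([pi1, 1.0 - pi1])
    mu = mu.astype(float).copy()
    var = np.maximum(var.astype(float), var_floor)
    loglik_trace = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        # E step
        logdens = np.stack(
            [norm.logpdf(z, mu[a], np.sqrt(var[a])) + np.log(max(pi[a], 1e-300)) for a in (0, 1)]
        )
        m = logdens.max(axis=0)
        lse = m + np.log(np.exp(logdens - m).sum(axis=0))
        loglik = float(lse.sum())
        loglik_trace.append(loglik)
        resp = np.exp(logdens - lse)
        # M step
        w = resp.sum(axis=1)
        w = np.maximum(w, 1e-12)
        pi = w / z.size
        mu = (resp @ z) / w
        var = np.array([resp[a] @ (z - mu[a]) ** 2 for a in (0, 1)]) / w
        var = np.maximum(var, var_floor)
        # tolerance scales with the loglik magnitude so convergence is
        # recognized on near-degenerate (single-component) fits
        if np.isfinite(prev) and loglik - prev < tol * max(1.0, abs(loglik)):
            converged = True
            break
        prev = loglik
    fit = NormalMixtureFit(pi=pi, mu=mu, var=var, loglik=loglik_trace[-1], converged=converged)
    return fit, np.asarray(loglik_trace)


def fit_normal_mixture(
    z: np.ndarray,
    seed: int | None = None,
    n_restarts: int = 10,
) -> NormalMixtureFit:
    """Maximum-likelihood two-component normal mixture on probit values z.

    Initialization splits z at its median (component moments from each
    half), followed by seeded random restarts; the best-loglik converged fit
    wins. If no restart converges the fit degenerates to a single normal.
    """
    z = np.asarray(z, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    med = np.median(z)
    lo, hi = z[z <= med], z[z > med]
    if hi.size == 0:  # all values tied at the median
        lo, hi = z, z
    inits = [(0.5, np.array([lo.mean(), hi.mean()]), np.array([max(lo.var(), 1e-4), max(hi.var(), 1e-4)]))]
    for _ in range(n_restarts):
        centers = rng.choice(z, size=2, replace=False) if z.size >= 2 else np.array([z[0], z[0]])
        pi1 = rng.uniform(0.2, 0.8)
        inits.append((pi1, np.sort(centers), np.array([z.var(), z.var()])))
    best: NormalMixtureFit | None = None
    for pi1, mu0, var0 in inits:
        fit, _ = _em_1d(z, pi1, mu0, var0)
        if fit.converged and (best is None or fit.loglik > best.loglik):
            best = fit
    if best is None:
        logger.warning("normal mixture EM did not converge; falling back to a single normal")
        best = NormalMixtureFit(
            pi=np.array([1.0, 0.0]),
            mu=np.array([z.mean(), z.mean()]),
            var=np.array([max(z.var(), 1e-6)] * 2),
            loglik=float(norm.logpdf(z, z.mean(), max(z.std(), 1e-3)).sum()),
            converged=False,
        )
    return best


def normal_mixture_pvalue(
    p_obs_satt: float,
    draws: PermutationDraws,
    seed: int | None = None,
) -> tuple[NormalMixtureFit, float]:
    """Refined p-value from a normal mixture fitted to probit null p-values.

    The per-permutation scaled-chi-square p-values are probit-transformed
    (clipped away from 0/1), a two-component normal mixture is fitted by EM,
    and the reported p-value is the mixture's lower-tail probability at the
    probit of the observed scaled-chi-square p-value (small p-values map to
    very negative probits).
    """
    if draws.satt_p_values is None:
        raise ValueError("draws.satt_p_values is required for the mixture refinement")
    B = draws.B
    eps = 1.0 / (10.0 * B)
    z = norm.ppf(np.clip(draws.satt_p_values, eps, 1.0 - eps))
    fit = fit_normal_mixture(z, seed=seed if seed is not None else draws.seed)
    z_obs = norm.ppf(float(np.clip(p_obs_satt, eps, 1.0 - eps)))
    p = float(fit.cdf(z_obs))
    return fit, min(max(p, np.finfo(float).tiny), 1.0)


# ---------------------------------------------------------------------------
# FDR across gene sets

def qvalues(p: np.ndarray, method: str = "storey", lambda_: float = 0.5) -> np.ndarray:
    """Storey q-values (pi0 estimated at a fixed lambda) or Benjamini-Hochberg.

    BH equals the Storey procedure with pi0 forced to 1. Monotonicity is
    enforced by a cumulative minimum from the largest p-value down.
    """
    p = np.asarray(p, dtype=float).ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if method == "storey":
        pi0 = np.mean(p > lambda_) / (1.0 - lambda_)
        pi0 = min(max(pi0, 1.0 / m), 1.0)
    elif method == "bh":
        pi0 = 1.0
    else:
        raise ValueError(f"unknown q-value method {method!r}")
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


# ---------------------------------------------------------------------------
# Collection-level driver

def test_gene_sets(
    expr: ExpressionMatrix,
    pheno: Phenotype,
    sets: GeneSetCollection,
    spec: WorkingCovarianceSpec,
    B: int = 1000,
    seed: int | None = None,
    methods: tuple[str, ...] = ("perm", "satt", "mix"),
    q_method: str = "storey",
) -> pd.DataFrame:
    """Run the test on every gene set in a collection and attach q-values.

    Each set gets a child RNG stream derived from ``seed`` and the set
    name, so results for a given set do not depend on which other sets (or
    which out-of-set genes) are present.
    """
    import zlib

    rows = []
    for name, genes in sets:
        sub = expr.subset_genes(genes)
        ss = np.random.SeedSequence([0 if seed is None else seed, zlib.crc32(name.encode())])
        child_seed = int(ss.generate_state(1)[0] % (2**31))
        result, _ = permutation_test(
            sub, pheno, spec, B=B, seed=child_seed, methods=methods,
            set_name=name, keep_draws=False,
        )
        rows.append(
            {
                "set": name,
                "p_genes": sub.n_genes,
                "Q": result.Q_observed,
                "p_perm": result.p_perm,
                "p_satt": result.p_satt,
                "p_mix": result.p_mix,
                "kappa": result.kappa,
                "nu": result.nu,
            }
        )
    df = pd.DataFrame(rows)
    for col in ("p_perm", "p_satt", "p_mix"):
        if df[col].notna().all():
            df["q_value"] = qvalues(df[col].to_numpy(), method=q_method)
            break
    return df
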