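"""Synthetic-data generation and size/power experiment runners.

Data follow the multivariate linear model Y_i = x_i * beta + eps_i with
eps_i ~ N(0, Sigma) and a binary group phenotype. The covariance menu
(compound symmetry, AR1, two-factor, stabilized-unstructured fixture)
and the sparse +/- effect layouts mirror the standard benchmark designs
for self-contained gene-set tests; the multi-set scenarios embed 20 sets
(ten of 10 genes, ten of 40) with 104 signal genes, optional cross-set
correlation, and optionally 4500 extra null genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import covariance as _cov
from . import inference as _inf
from ._types import (
    CovarianceMatrix,
    EffectVector,
    ExpressionMatrix,
    GeneSetCollection,
    Phenotype,
    WorkingCovarianceSpec,
)

__all__ = [
    "make_cov_cs",
    "make_cov_ar1",
    "make_cov_twofactor",
    "make_cov_unstructured_fixture",
    "make_beta",
    "simulate_gene_set",
    "SimulationScenario",
    "run_size_power_experiment",
    "MultiSetScenario",
    "default_beta_table",
    "simulate_multiset",
]


# ---------------------------------------------------------------------------
# Covariance constructors

def make_cov_cs(p: int, rho: float) -> CovarianceMatrix:
    """Compound symmetry: unit diagonal, constant off-diagonal rho."""
    if not (-1.0 / (p - 1) < rho < 1.0):
        raise ValueError(f"rho={rho} outside the positive-definite range for p={p}")
    out = np.full((p, p), rho)
    np.fill_diagonal(out, 1.0)
    return CovarianceMatrix(out, kind=f"cs({rho})")


def make_cov_ar1(p: int, r: float) -> CovarianceMatrix:
    """First-order autoregressive: entry (j, k) = r^|j-k|, unit diagonal."""
    if not (-1.0 < r < 1.0):
        raise ValueError("AR1 decay must satisfy |r| < 1")
    idx = np.arange(p)
    out = r ** np.abs(idx[:, None] - idx[None, :])
    return CovarianceMatrix(out, kind=f"ar1({r})")


def make_cov_twofactor(p: int, factor_share: float = 0.5, seed: int | None = None) -> CovarianceMatrix:
    """Two-factor covariance P1 P1' + P2 P2' + diag(u) with unit diagonal.

    Factor entries are i.i.d. standard normal; the rank-2 part is rescaled
    so it contributes ``factor_share`` of the unit diagonal on average, and
    the idiosyncratic diagonal u fills each diagonal entry to exactly 1,
    floored at 0.05 (shrinking the factor part if a gene's variance would
    otherwise be fully factor-explained).
    """
    if not (0.0 < factor_share < 1.0):
        raise ValueError("factor_share must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    P = rng.standard_normal((p, 2))
    R = P @ P.T
    R *= factor_share / np.diag(R).mean()
    dmax = np.diag(R).max()
    if dmax > 0.95:
        R *= 0.95 / dmax
    u = 1.0 - np.diag(R)
    out = R + np.diag(u)
    return CovarianceMatrix(out, kind="f2-true")


def make_cov_unstructured_fixture(p: int, seed: int | None = None, n_pseudo: int = 34) -> CovarianceMatrix:
    """Synthetic stand-in for a stabilized real-data sample covariance.

    Draws ``n_pseudo`` pseudo-samples from a heterogeneous-variance
    three-factor model, takes their sample covariance, and adds the 5th
    percentile of its diagonal to the diagonal (the same stabilization used
    for working-covariance estimation). This reproduces the construction of
    an unstructured "truth" taken from pilot data without requiring any
    external dataset.
    """
    if p < 2:
        raise ValueError("need p >= 2")
    rng = np.random.default_rng(seed)
    L = rng.standard_normal((p, 3)) * 0.6
    idio_sd = rng.uniform(0.5, 1.5, size=p)
    F = rng.standard_normal((n_pseudo, 3))
    E = rng.standard_normal((n_pseudo, p)) * idio_sd
    X = F @ L.T + E
    Xc = X - X.mean(axis=0, keepdims=True)
    S = Xc.T @ Xc / (n_pseudo - 1)
    ridge = float(np.percentile(np.diag(S), 5.0))
    return CovarianceMatrix(S + ridge * np.eye(p), kind="uns-fixture")


# ---------------------------------------------------------------------------
# Effects and data

def make_beta(p: int, count_neg: int, count_pos: int, magnitude: float) -> EffectVector:
    """Sparse +/- effect layout: count_neg entries at -magnitude, then
    count_pos at +magnitude, remaining genes null. Positions are fixed
    (leading entries) — the test is equivariant to gene order, so placement
    is immaterial."""
    if count_neg < 0 or count_pos < 0 or count_neg + count_pos > p:
        raise ValueError("count_neg + count_pos must not exceed p")
    beta = np.zeros(p)
    beta[:count_neg] = -magnitude
    beta[count_neg : count_neg + count_pos] = magnitude
    return EffectVector(beta)


def simulate_gene_set(
    n: int,
    n1: int,
    beta: EffectVector,
    Sigma: CovarianceMatrix,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, Phenotype]:
    """One dataset from the model: x is n1 zeros then n - n1 ones,
    Y_i = x_i * beta + eps_i with eps_i ~ N(0, Sigma)."""
    if Sigma.p != beta.p:
        raise ValueError("Sigma dimension does not match beta")
    if rng is None:
        rng = np.random.default_rng(seed)
    p = Sigma.p
    L = np.linalg.cholesky(Sigma.matrix)
    eps = rng.standard_normal((n, p)) @ L.T
    x = np.concatenate([np.zeros(n1), np.ones(n - n1)])
    Y = x[:, None] * beta.beta[None, :] + eps
    expr = ExpressionMatrix(
        Y, [f"G{j + 1:04d}" for j in range(p)], [f"S{i + 1:04d}" for i in range(n)]
    )
    return expr, Phenotype(x, kind="binary")


# ---------------------------------------------------------------------------
# Single-gene-set size/power experiments

@dataclass
class SimulationScenario:
    """One simulation cell: design sizes, truth, effects, replication plan."""

    n: int
    n1: int
    p: int
    true_cov: CovarianceMatrix
    beta: EffectVector
    replicates: int = 2000
    B: int = 500
    alpha: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.true_cov.p != self.p or self.beta.p != self.p:
            raise ValueError("true_cov and beta must have dimension p")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.B < 100:
            raise ValueError("B must be >= 100")
        if not (0 < self.n1 < self.n):
            raise ValueError("n1 must be strictly between 0 and n")

    @property
    def effect_index(self) -> float:
        """Sum of |beta_j| over the average gene variance of the truth."""
        return float(np.abs(self.beta.beta).sum() / np.diag(self.true_cov.matrix).mean())


def _shared_ridge_batches(Yc, Xc_obs, Xc_perm, specs, n):
    """Batched ridge covariances shared across working-covariance variants."""
    out_obs, out_perm, eig_perm, eig_obs = {}, {}, {}, {}
    for spec in specs:
        if spec.kind in ("unstr", "cpsym", "f2", "f-adpt"):
            key = spec.ridge_percentile
            if key not in out_perm:
                out_obs[key] = _cov._batched_residual_ridge(Yc, Xc_obs, key)
                out_perm[key] = _cov._batched_residual_ridge(Yc, Xc_perm, key)
            if spec.kind in ("f2", "f-adpt") and key not in eig_perm:
                eig_obs[key] = np.linalg.eigh(out_obs[key])
                eig_perm[key] = np.linalg.eigh(out_perm[key])
    return out_obs, out_perm, eig_obs, eig_perm


def _variant_Q(Yc, s, Sr, eig, spec, n, p):
    """Q values for one variant given precomputed score vectors and ridges."""
    if spec.kind == "indpt":
        return np.einsum("bp,bp->b", s, s)
    if spec.kind == "supplied":
        u = np.linalg.solve(spec.supplied_matrix.matrix, s.T).T
        return np.einsum("bp,bp->b", u, u)
    Srk = Sr[spec.ridge_percentile]
    if spec.kind == "unstr":
        Vb = Srk
    elif spec.kind == "cpsym":
        Vb = _cov._batched_cpsym(Srk)
    elif spec.kind == "f2":
        Vb = _cov._batched_factor(Srk, n_factors=spec.n_factors, eig=eig[spec.ridge_percentile])
    elif spec.kind == "f-adpt":
        Vb = _cov._batched_factor(
            Srk,
            variance_fraction=spec.variance_fraction,
            max_factors=min(p, n - 1),
            eig=eig[spec.ridge_percentile],
        )
    else:
        raise ValueError(spec.kind)
    u = np.linalg.solve(Vb, s[:, :, None])[:, :, 0]
    return np.einsum("bp,bp->b", u, u)


def run_size_power_experiment(
    scenario: SimulationScenario,
    work_covs: list[WorkingCovarianceSpec],
    methods: tuple[str, ...] = ("perm", "satt"),
    return_pvalues: bool = False,
):
    """Monte Carlo size/power of the test for several working covariances.

    For each replicate the same simulated dataset and the same permutations
    are shared by every variant (paired comparisons); V is re-estimated
    inside each permutation for estimated structures. Returns a tidy table
    of rejection proportions at ``scenario.alpha`` with binomial standard
    errors, plus (optionally) the full p-value arrays.

    Methods: "perm" (permutation p-value), "satt" (scaled chi-square with
    permutation-estimated moments), and "theory" (scaled chi-square with
    the moments computed analytically from the known truth — the test whose
    power the analytic power formula approximates; only available for
    fixed working covariances, i.e. 'indpt' and 'supplied').
    """
    from scipy.stats import chi2 as _chi2

    from .power import PowerProblem, theoretical_null_moments

    sc = scenario
    labels = [spec.label for spec in work_covs]
    if len(set(labels)) != len(labels):
        raise ValueError("working covariance variants must have distinct labels")
    theory_kn: dict[str, tuple[float, float]] = {}
    if "theory" in methods:
        x_ph = Phenotype(np.concatenate([np.zeros(sc.n1), np.ones(sc.n - sc.n1)]))
        for spec, lab in zip(work_covs, labels):
            if spec.kind == "supplied":
                Vfix = spec.supplied_matrix
            elif spec.kind == "indpt":
                Vfix = CovarianceMatrix(np.eye(sc.p), kind="indpt")
            else:
                raise ValueError("'theory' p-values need a fixed working covariance")
            E0, Var0 = theoretical_null_moments(
                PowerProblem(x_ph, Vfix, sc.true_cov, EffectVector(np.zeros(sc.p)), sc.alpha)
            )
            theory_kn[lab] = (Var0 / (2 * E0), 2 * E0 * E0 / Var0)
    pvals = {lab: {m: np.empty(sc.replicates) for m in methods} for lab in labels}
    streams = np.random.SeedSequence(sc.seed).spawn(sc.replicates)
    x = np.concatenate([np.zeros(sc.n1), np.ones(sc.n - sc.n1)])
    for r, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        expr, pheno = simulate_gene_set(sc.n, sc.n1, sc.beta, sc.true_cov, rng=rng)
        Yc = expr.values - expr.values.mean(axis=0, keepdims=True)
        xc = x - x.mean()
        need_perms = "perm" in methods or "satt" in methods
        if need_perms:
            Xp = _inf._permuted_x(x, sc.B, rng)
            Xc_perm = Xp - Xp.mean(axis=1, keepdims=True)
            s_perm_all = Xc_perm @ Yc  # (B, p)
        else:
            Xc_perm = np.empty((0, sc.n))
        s_obs_all = xc[None, :] @ Yc  # (1, p)
        Sr_obs, Sr_perm, eig_obs, eig_perm = _shared_ridge_batches(
            Yc, xc[None, :], Xc_perm, work_covs, sc.n
        )
        for spec, lab in zip(work_covs, labels):
            Q_obs = float(_variant_Q(Yc, s_obs_all, Sr_obs, eig_obs, spec, sc.n, sc.p)[0])
            if need_perms:
                Q_b = _variant_Q(Yc, s_perm_all, Sr_perm, eig_perm, spec, sc.n, sc.p)
            if "perm" in methods:
                pvals[lab]["perm"][r] = (1 + np.sum(Q_b >= Q_obs)) / (sc.B + 1)
            if "satt" in methods:
                draws = _inf.PermutationDraws(Q_values=Q_b, B=sc.B)
                _, _, p_satt = _inf.satterthwaite_pvalue(Q_obs, draws)
                pvals[lab]["satt"][r] = p_satt
            if "theory" in methods:
                kap, nu = theory_kn[lab]
                pvals[lab]["theory"][r] = _chi2.sf(Q_obs / kap, nu)
    rows = []
    for lab in labels:
        for m in methods:
            rej = int(np.sum(pvals[lab][m] < sc.alpha))
            rate = rej / sc.replicates
            rows.append(
                {
                    "variant": lab,
                    "method": m,
                    "replicates": sc.replicates,
                    "n_reject": rej,
                    "rejection_rate": rate,
                    "mc_se": float(np.sqrt(rate * (1 - rate) / sc.replicates)),
                    "effect_index": sc.effect_index,
                }
            )
    table = pd.DataFrame(rows)
    if return_pvalues:
        return table, pvals
    return table


# ---------------------------------------------------------------------------
# Multiple gene sets

#: per-set (count_neg, count_pos, magnitude); sets 1-10 have p=10, 11-20 p=40
_DEFAULT_BETAS_P10 = [
    (1, 3, 0.5),
    (2, 6, 0.5),
    (1, 3, 1.0),
    (2, 6, 1.0),
] + [(0, 0, 0.0)] * 6
_DEFAULT_BETAS_P40 = [
    (2, 8, 0.5),
    (5, 25, 0.5),
    (2, 8, 1.0),
    (5, 25, 1.0),
] + [(0, 0, 0.0)] * 6

#: 0-based set indices sharing a covariance block in settings 2-3
_CORRELATED_BLOCKS = [(0, 1, 2), (3, 4, 5), (6, 7, 8), (10, 11, 12), (13, 14, 15), (16, 17, 18)]


def default_beta_table() -> list[tuple[int, int, float]]:
    """The default per-set effect layouts (104 signal genes in total)."""
    return list(_DEFAULT_BETAS_P10) + list(_DEFAULT_BETAS_P40)


@dataclass
class MultiSetScenario:
    """A 20-gene-set benchmark: ten sets of 10 genes and ten of 40.

    setting 1: sets mutually independent; 2: six 3-set blocks share a
    two-factor covariance; 3: as 2 plus 4500 extra null genes outside every
    set.
    """

    setting: int = 1
    n: int = 20
    n1: int = 10
    set_sizes: list[int] = field(default_factory=lambda: [10] * 10 + [40] * 10)
    beta_table: list[tuple[int, int, float]] = field(default_factory=default_beta_table)
    extra_null_genes: int | None = None
    factor_share: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.setting not in (1, 2, 3):
            raise ValueError("setting must be 1, 2 or 3")
        if len(self.beta_table) != len(self.set_sizes):
            raise ValueError("beta_table must have one entry per gene set")
        if self.extra_null_genes is None:
            self.extra_null_genes = 4500 if self.setting == 3 else 0

    @property
    def correlated_blocks(self) -> list[tuple[int, ...]]:
        return [] if self.setting == 1 else list(_CORRELATED_BLOCKS)

    @property
    def total_genes(self) -> int:
        return sum(self.set_sizes) + self.extra_null_genes

    @property
    def n_signal_genes(self) -> int:
        return sum(neg + pos for neg, pos, _ in self.beta_table)


def _multiset_covariance_blocks(scenario: MultiSetScenario, ss: np.random.SeedSequence):
    """List of (set_indices, CovarianceMatrix) blocks covering all 20 sets.

    Cross-set structures are seeded synthetic two-factor covariances of the
    appropriate joint dimension (stand-ins for pilot-data-estimated blocks).
    """
    sizes = scenario.set_sizes
    grouped: list[tuple[tuple[int, ...], int]] = []
    used: set[int] = set()
    for block in scenario.correlated_blocks:
        grouped.append((block, sum(sizes[i] for i in block)))
        used.update(block)
    for i in range(len(sizes)):
        if i not in used:
            grouped.append(((i,), sizes[i]))
    grouped.sort(key=lambda t: t[0][0])
    children = ss.spawn(len(grouped))
    blocks = []
    for (idxs, dim), child in zip(grouped, children):
        seed = int(child.generate_state(1)[0] % (2**31))
        blocks.append((idxs, make_cov_twofactor(dim, scenario.factor_share, seed=seed)))
    return blocks


def simulate_multiset(
    scenario: MultiSetScenario,
) -> tuple[ExpressionMatrix, Phenotype, GeneSetCollection]:
    """One dataset for a multi-set benchmark setting.

    The core (in-set) genes are generated from a stream independent of the
    extra-null-gene stream, so settings 2 and 3 with the same seed produce
    bit-identical data for every gene that belongs to a set.
    """
    sc = scenario
    root = np.random.SeedSequence(sc.seed)
    cov_ss, core_ss, extra_ss = root.spawn(3)
    blocks = _multiset_covariance_blocks(sc, cov_ss)
    sizes = sc.set_sizes
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    p_core = int(offsets[-1])
    n = sc.n
    core_rng = np.random.default_rng(core_ss)
    Y = np.empty((n, p_core))
    x = np.concatenate([np.zeros(sc.n1), np.ones(n - sc.n1)])
    beta = np.zeros(p_core)
    for i, (neg, pos, mag) in enumerate(sc.beta_table):
        beta[offsets[i] : offsets[i + 1]] = make_beta(sizes[i], neg, pos, mag).beta
    for idxs, cov in blocks:
        cols = np.concatenate([np.arange(offsets[i], offsets[i + 1]) for i in idxs])
        L = np.linalg.cholesky(cov.matrix)
        Y[:, cols] = core_rng.standard_normal((n, cols.size)) @ L.T
    Y += x[:, None] * beta[None, :]
    gene_ids = [f"G{j + 1:05d}" for j in range(p_core)]
    if sc.extra_null_genes:
        extra_rng = np.random.default_rng(extra_ss)
        Y = np.hstack([Y, extra_rng.standard_normal((n, sc.extra_null_genes))])
        gene_ids += [f"N{j + 1:05d}" for j in range(sc.extra_null_genes)]
    expr = ExpressionMatrix(Y, gene_ids, [f"S{i + 1:04d}" for i in range(n)])
    sets = {
        f"set{i + 1:02d}": gene_ids[offsets[i] : offsets[i + 1]] for i in range(len(sizes))
    }
    return expr, Phenotype(x, kind="binary"), GeneSetCollection(sets)
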