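"""The gene-set variance-component score statistic and its special cases.

The multivariate linear model is Y_ij = alpha_j + x_i beta_j + eps_ij with
eps_i ~ N(0, Sigma). Treating the beta_j as random with common variance tau
turns the p-dimensional null beta = 0 into the 1-dimensional variance
component null tau = 0, whose score statistic with a working covariance V is
a quadratic form in the data. Block algebra reduces the stacked np-vector
expression to

    Q = || V^-1 s ||^2,   s = sum_i (x_i - xbar)(Y_i - Ybar),

which is what this module computes: no np x np matrix is ever built, and V
is handled through a Cholesky solve rather than an explicit inverse.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from ._types import (
    CenteredDesign,
    CovarianceMatrix,
    ExpressionMatrix,
    Phenotype,
    QuadraticNullSpec,
)

__all__ = [
    "center_under_null",
    "tegs_statistic",
    "tegs_two_group",
    "global_test_statistic",
    "null_mixture_weights",
    "adjust_for_covariates",
]


def center_under_null(expr: ExpressionMatrix, pheno: Phenotype) -> CenteredDesign:
    """Center responses by their per-gene grand means and x by its mean.

    Under the null, the GLS estimate of the per-gene intercepts collapses to
    the plain sample mean for any error covariance, so the null centering is
    covariance-free. For a binary phenotype the two group means are recorded
    for the closed-form two-group statistic.
    """
    Y = expr.values
    Yc = Y - Y.mean(axis=0, keepdims=True)
    xc = pheno.x - pheno.x.mean()
    group_means = None
    group_sizes = None
    if pheno.kind == "binary":
        g0 = pheno.x == 0
        group_means = (Y[g0].mean(axis=0), Y[~g0].mean(axis=0))
        group_sizes = (int(g0.sum()), int((~g0).sum()))
    return CenteredDesign(Yc, xc, group_means=group_means, group_sizes=group_sizes)


def tegs_statistic(design: CenteredDesign, V: CovarianceMatrix) -> float:
    """Q = s' V^-1 V^-1 s with s the p-dimensional score vector."""
    if V.p != design.p:
        raise ValueError("working covariance dimension does not match gene count")
    s = design.score_vector()
    factor = cho_factor(V.matrix, lower=True)
    u = cho_solve(factor, s)
    return float(u @ u)


def tegs_two_group(design: CenteredDesign, V: CovarianceMatrix) -> float:
    """Closed form for a binary phenotype: (n1 n2 / n)^2 * d' V^-2 d.

    d is the difference of the two group mean vectors. Identical to
    ``tegs_statistic``; provided as the two-group reduction.
    """
    if design.group_means is None:
        raise ValueError("two-group statistic requires a binary phenotype")
    m0, m1 = design.group_means
    n1, n2 = design.group_sizes
    n = n1 + n2
    d = m0 - m1
    factor = cho_factor(V.matrix, lower=True)
    u = cho_solve(factor, d)
    return float((n1 * n2 / n) ** 2 * (u @ u))


def global_test_statistic(design: CenteredDesign) -> float:
    """The working-independence statistic Q_ind = s's (the global test)."""
    s = design.score_vector()
    return float(s @ s)


def null_mixture_weights(
    design: CenteredDesign,
    V: CovarianceMatrix,
    Sigma: CovarianceMatrix,
) -> QuadraticNullSpec:
    """Weights of the mixture-of-chi-squares null law of Q.

    Under the null, s ~ N(0, c*Sigma) with c = sum_i (x_i - xbar)^2, so
    Q = s'V^-2 s is a weighted sum of 1-df chi-squares with weights equal to
    the eigenvalues of c * V^-1 Sigma V^-1 (which reduces to c * Sigma^-1
    when V = Sigma). The weight sum equals E_H0(Q) by the trace identity.
    """
    if V.p != design.p or Sigma.p != design.p:
        raise ValueError("covariance dimensions do not match the design")
    c = design.x_sumsq
    Vinv_Sigma_Vinv = np.linalg.solve(V.matrix, np.linalg.solve(V.matrix, Sigma.matrix).T)
    M = c * 0.5 * (Vinv_Sigma_Vinv + Vinv_Sigma_Vinv.T)
    weights = np.linalg.eigvalsh(M)
    return QuadraticNullSpec(weights)


def adjust_for_covariates(
    expr: ExpressionMatrix,
    covariates: np.ndarray,
    ridge_penalty: float = 0.0,
) -> ExpressionMatrix:
    """Residualize expression on nuisance covariates by per-gene ridge regression.

    The intercept is unpenalized; covariate coefficients carry the ridge
    penalty (needed when p is large relative to n). With ridge_penalty = 0
    this is ordinary least-squares residualization. The returned matrix is
    meant to replace raw expression before testing x.
    """
    if ridge_penalty < 0:
        raise ValueError("ridge penalty must be nonnegative")
    Z = np.atleast_2d(np.asarray(covariates, dtype=float))
    if Z.shape[0] != expr.n_samples:
        Z = Z.T
    if Z.shape[0] != expr.n_samples:
        raise ValueError("covariate matrix does not match the number of samples")
    n, k = Z.shape
    W = np.column_stack([np.ones(n), Z])
    P = np.diag([0.0] + [ridge_penalty] * k)
    WtW = W.T @ W + P
    if ridge_penalty == 0 and np.linalg.matrix_rank(W) < k + 1:
        raise ValueError("covariate design is rank deficient; use a ridge penalty")
    coef = np.linalg.solve(WtW, W.T @ expr.values)
    residuals = expr.values - W @ coef
    return ExpressionMatrix(residuals, expr.gene_ids, expr.sample_ids)
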