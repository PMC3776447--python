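"""Working-covariance estimation for the gene-set score test.

All estimated structures derive from one object: the ridge-stabilized
unstructured residual covariance, i.e. the sample covariance of per-gene
OLS residuals with the 5th percentile of the sample variances added to the
diagonal. Compound symmetry averages its diagonal and off-diagonal; the
factor covariances keep its leading eigencomponents and restore the exact
diagonal.

The ``_batched_*`` helpers evaluate the same estimators simultaneously for
many permuted phenotype vectors; they rely on the closed form

    S_b = (Yc' Yc - c * g_b g_b') / (n - 1),   g_b = Yc' xt_b / c,

where ``Yc`` is the column-centered expression matrix, ``xt_b`` the
centered permuted phenotype and ``c = xt'xt`` (constant across
permutations). This is exactly the residual covariance of per-gene
regressions on (1, x) and holds for binary and numeric phenotypes alike.
"""

from __future__ import annotations

import numpy as np

from ._types import (
    CovarianceMatrix,
    ExpressionMatrix,
    Phenotype,
    ResidualMatrix,
    WorkingCovarianceSpec,
)

__all__ = [
    "compute_residuals",
    "estimate_unstructured_ridge",
    "estimate_compound_symmetry",
    "estimate_factor_covariance",
    "build_working_covariance",
]

_D_FLOOR_REL = 1e-8


def compute_residuals(expr: ExpressionMatrix, pheno: Phenotype) -> ResidualMatrix:
    """Per-gene OLS residuals of expression on (1, x).

    For a binary phenotype this equals centering each gene by its group
    means.
    """
    x = pheno.x
    if np.var(x) <= 0:
        raise ValueError("phenotype is constant: degenerate design")
    xc = x - x.mean()
    c = float(xc @ xc)
    Yc = expr.values - expr.values.mean(axis=0, keepdims=True)
    slopes = Yc.T @ xc / c  # length p
    residuals = Yc - np.outer(xc, slopes)
    return ResidualMatrix(residuals, dof_used=2)


def estimate_unstructured_ridge(res: ResidualMatrix, ridge_percentile: float = 5.0) -> CovarianceMatrix:
    """Ridge-stabilized unstructured covariance: S + c*I.

    S is the sample covariance of the residual columns (divisor n-1); the
    ridge constant c is the ``ridge_percentile``-th percentile of the
    sample variances (linear interpolation between order statistics).
    """
    if res.n < 3:
        raise ValueError("need at least 3 samples to estimate a residual covariance")
    R = res.residuals
    S = R.T @ R / (res.n - 1)
    variances = np.diag(S)
    if np.all(variances == 0):
        raise ValueError("all residuals are zero: no variability to estimate")
    ridge = float(np.percentile(variances, ridge_percentile))
    return CovarianceMatrix(S + ridge * np.eye(res.p), kind="unstr")


def estimate_compound_symmetry(ridge_cov: CovarianceMatrix) -> CovarianceMatrix:
    """Exchangeable covariance: common variance and common pairwise covariance.

    The pairwise covariance is the mean of the off-diagonal entries of the
    ridge estimator; the common variance is the mean of its diagonal, making
    the output exactly exchangeable.
    """
    p = ridge_cov.p
    if p < 2:
        raise ValueError("compound symmetry needs at least 2 genes")
    M = ridge_cov.matrix
    diag_mean = float(np.trace(M)) / p
    off_mean = float(M.sum() - np.trace(M)) / (p * (p - 1))
    out = np.full((p, p), off_mean)
    np.fill_diagonal(out, diag_mean)
    # exchangeable eigenvalues: diag_mean + (p-1)*off, diag_mean - off
    if diag_mean + (p - 1) * off_mean <= 0 or diag_mean - off_mean <= 0:
        raise ValueError("compound symmetry estimate is not positive definite")
    return CovarianceMatrix(out, kind="cpsym")


def _factor_from_eigh(
    eigvals: np.ndarray,
    eigvecs: np.ndarray,
    diag: np.ndarray,
    k: int,
) -> np.ndarray:
    lam = eigvals[::-1][:k]
    U = eigvecs[:, ::-1][:, :k]
    lowrank = (U * lam) @ U.T
    d = diag - np.diag(lowrank)
    floor = _D_FLOOR_REL * diag.mean()
    d = np.maximum(d, floor)
    out = lowrank + np.diag(d)
    return out


def estimate_factor_covariance(
    ridge_cov: CovarianceMatrix,
    spec: WorkingCovarianceSpec,
    max_factors: int | None = None,
) -> CovarianceMatrix:
    """Factor-analytic covariance from the ridge estimator's eigenstructure.

    Keeps the top-k eigencomponents (k = ``spec.n_factors`` for 'f2'; for
    'f-adpt' the smallest k whose cumulative eigenvalue fraction reaches
    ``spec.variance_fraction``) and adds a diagonal that restores the ridge
    estimator's diagonal exactly, floored away from zero.
    """
    p = ridge_cov.p
    eigvals, eigvecs = np.linalg.eigh(ridge_cov.matrix)
    if spec.kind == "f-adpt":
        lam_desc = eigvals[::-1]
        frac = np.cumsum(lam_desc) / lam_desc.sum()
        k = int(np.searchsorted(frac, spec.variance_fraction - 1e-12) + 1)
        if max_factors is not None:
            k = min(k, max_factors)
        k = min(k, p)
    else:
        k = spec.n_factors
    if k > p:
        raise ValueError(f"number of factors {k} exceeds matrix dimension {p}")
    out = _factor_from_eigh(eigvals, eigvecs, np.diag(ridge_cov.matrix).copy(), k)
    return CovarianceMatrix(out, kind=spec.kind)


def build_working_covariance(
    expr: ExpressionMatrix,
    pheno: Phenotype,
    spec: WorkingCovarianceSpec,
) -> CovarianceMatrix:
    """Dispatch over the working-covariance menu.

    indpt -> identity; unstr -> ridge estimator; cpsym / f2 / f-adpt ->
    transforms of the ridge estimator; supplied -> validated passthrough.
    """
    p = expr.n_genes
    if spec.kind == "indpt":
        return CovarianceMatrix(np.eye(p), kind="indpt")
    if spec.kind == "supplied":
        if spec.supplied_matrix.p != p:
            raise ValueError("supplied covariance dimension does not match the gene count")
        return spec.supplied_matrix
    res = compute_residuals(expr, pheno)
    ridge = estimate_unstructured_ridge(res, spec.ridge_percentile)
    if spec.kind == "unstr":
        return ridge
    if spec.kind == "cpsym":
        return estimate_compound_symmetry(ridge)
    if spec.kind in ("f2", "f-adpt"):
        return estimate_factor_covariance(ridge, spec, max_factors=min(p, expr.n_samples - 1))
    raise ValueError(f"unknown working covariance kind {spec.kind!r}")


# ---------------------------------------------------------------------------
# Batched estimation across permutations (private)

def _batched_residual_ridge(
    Yc: np.ndarray,
    Xc: np.ndarray,
    ridge_percentile: float = 5.0,
) -> np.ndarray:
    """Ridge-stabilized residual covariances for B centered phenotype vectors.

    Yc: (n, p) column-centered expression; Xc: (B, n) centered phenotype
    permutations (all with identical sum of squares). Returns (B, p, p).
    """
    n = Yc.shape[0]
    c = float(Xc[0] @ Xc[0])
    G = Yc.T @ Yc
    g = Xc @ Yc / c  # (B, p) per-gene slopes
    S = (G[None, :, :] - c * np.einsum("bi,bj->bij", g, g)) / (n - 1)
    d = np.diagonal(S, axis1=1, axis2=2)
    ridge = np.percentile(d, ridge_percentile, axis=1)
    idx = np.arange(Yc.shape[1])
    S[:, idx, idx] += ridge[:, None]
    return S


def _batched_cpsym(Sr: np.ndarray) -> np.ndarray:
    """Compound-symmetry transforms of a batch of ridge covariances."""
    B, p, _ = Sr.shape
    tr = np.trace(Sr, axis1=1, axis2=2)
    diag_mean = tr / p
    off_mean = (Sr.sum(axis=(1, 2)) - tr) / (p * (p - 1))
    out = np.broadcast_to(off_mean[:, None, None], (B, p, p)).copy()
    idx = np.arange(p)
    out[:, idx, idx] = diag_mean[:, None]
    return out


def _batched_factor(
    Sr: np.ndarray,
    n_factors: int | None = None,
    variance_fraction: float | None = None,
    max_factors: int | None = None,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Factor-analytic transforms of a batch of ridge covariances.

    Exactly one of n_factors (fixed k) or variance_fraction (adaptive k,
    optionally capped at max_factors) must be given. A precomputed batched
    eigendecomposition may be passed to share work between f2 and f-adpt.
    """
    B, p, _ = Sr.shape
    if eig is None:
        eigvals, eigvecs = np.linalg.eigh(Sr)
    else:
        eigvals, eigvecs = eig
    lam = eigvals[:, ::-1]  # descending
    U = eigvecs[:, :, ::-1]
    if n_factors is not None:
        keep = np.zeros((B, p), dtype=bool)
        keep[:, :n_factors] = True
    else:
        frac = np.cumsum(lam, axis=1) / lam.sum(axis=1, keepdims=True)
        kvec = (frac < variance_fraction - 1e-12).sum(axis=1) + 1
        if max_factors is not None:
            kvec = np.minimum(kvec, max_factors)
        kvec = np.minimum(kvec, p)
        keep = np.arange(p)[None, :] < kvec[:, None]
    lam_kept = np.where(keep, lam, 0.0)
    lowrank = np.einsum("bpk,bk,bqk->bpq", U, lam_kept, U)
    diag = np.diagonal(Sr, axis1=1, axis2=2)
    d = diag - np.diagonal(lowrank, axis1=1, axis2=2)
    floor = _D_FLOOR_REL * diag.mean(axis=1)
    d = np.maximum(d, floor[:, None])
    idx = np.arange(p)
    out = lowrank.copy()
    out[:, idx, idx] += d
    return out
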