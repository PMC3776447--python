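"""Shared fixtures and independent oracles.

The stacked-matrix helpers evaluate the score statistic and its theoretical
moments literally in the np-dimensional formulation (building J, X, H and
the block-diagonal covariance explicitly); they are deliberately naive and
serve as brute-force oracles for the p-dimensional production code.
"""

from __future__ import annotations

import numpy as np
import pytest

from tegs import CovarianceMatrix, ExpressionMatrix, Phenotype


# ---------------------------------------------------------------------------
# Brute-force stacked-matrix oracles

def stacked_pieces(x: np.ndarray, p: int, V: np.ndarray):
    n = x.size
    J = np.tile(np.eye(p), (n, 1))
    X = np.vstack([xi * np.eye(p) for xi in x])
    H = J @ J.T / n
    Vn_inv = np.kron(np.eye(n), np.linalg.inv(V))
    return J, X, H, Vn_inv


def stacked_Q(Y: np.ndarray, x: np.ndarray, V: np.ndarray) -> float:
    """Literal np x np evaluation of the score statistic."""
    n, p = Y.shape
    _, X, H, Vn_inv = stacked_pieces(x, p, V)
    Yv = Y.reshape(-1)
    M = (np.eye(n * p) - H) @ Vn_inv @ X @ X.T @ Vn_inv @ (np.eye(n * p) - H)
    return float(Yv @ M @ Yv)


def stacked_null_moments(x: np.ndarray, V: np.ndarray, Sigma: np.ndarray) -> tuple[float, float]:
    """Literal trace formulas for E_H0(Q) and Var_H0(Q)."""
    n = x.size
    p = V.shape[0]
    _, X, H, Vn_inv = stacked_pieces(x, p, V)
    Sn = np.kron(np.eye(n), Sigma)
    B = (np.eye(n * p) - H) @ Vn_inv @ X @ X.T @ Vn_inv @ (np.eye(n * p) - H)
    E = float(np.trace(B @ Sn))
    Var = float(2.0 * np.trace(B @ Sn @ B @ Sn))
    return E, Var


def stacked_alternative_mean(
    x: np.ndarray, V: np.ndarray, Sigma: np.ndarray, beta: np.ndarray
) -> float:
    """Literal E_HA(Q): null trace plus the quadratic form in beta."""
    n = x.size
    p = V.shape[0]
    _, X, H, Vn_inv = stacked_pieces(x, p, V)
    E0, _ = stacked_null_moments(x, V, Sigma)
    A = X.T @ (np.eye(n * p) - H) @ Vn_inv @ X
    return E0 + float(beta @ A @ A.T @ beta)


# ---------------------------------------------------------------------------
# Random-instance builders

def random_pd(p: int, rng: np.random.Generator) -> np.ndarray:
    A = rng.standard_normal((p, p))
    return A @ A.T + p * np.eye(p)


def random_instance(n: int, p: int, rng: np.random.Generator, binary: bool = False):
    Y = rng.standard_normal((n, p))
    if binary:
        n1 = n // 2
        x = np.concatenate([np.zeros(n1), np.ones(n - n1)])
        pheno = Phenotype(x, kind="binary")
    else:
        x = rng.standard_normal(n)
        pheno = Phenotype(x, kind="numeric")
    expr = ExpressionMatrix(Y, [f"g{j}" for j in range(p)], [f"s{i}" for i in range(n)])
    return expr, pheno


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_binary_instance(rng):
    return random_instance(8, 5, rng, binary=True)


@pytest.fixture
def random_cov(rng):
    def make(p: int) -> CovarianceMatrix:
        return CovarianceMatrix(random_pd(p, rng))

    return make
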