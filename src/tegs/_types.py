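"""Core domain types for gene-set testing.

The central objects are an expression matrix (samples x genes), a phenotype
(the single independent variable x, binary or numeric), gene-set
collections, covariance matrices (true or working), and result containers
for the variance-component score test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("tegs")

__all__ = [
    "ExpressionMatrix",
    "Phenotype",
    "GeneSetCollection",
    "CovarianceMatrix",
    "CenteredDesign",
    "TegsResult",
    "EffectVector",
    "WorkingCovarianceSpec",
    "ResidualMatrix",
    "QuadraticNullSpec",
]

_SYM_RTOL = 1e-10


class FormatError(ValueError):
    """Raised for malformed input files."""


@dataclass
class ExpressionMatrix:
    """An n-samples x p-genes matrix of continuous expression values.

    Samples are rows, matching the multivariate-regression framing in which
    each subject contributes a p-vector of outcomes.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n, p = self.values.shape
        if n < 4:
            raise ValueError(f"need at least 4 samples, got {n}")
        if p < 1:
            raise ValueError("need at least one gene")
        if len(self.gene_ids) != p:
            raise ValueError("gene_ids length does not match number of columns")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match number of rows")
        if len(set(self.gene_ids)) != p:
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains missing or non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        """Return the sub-matrix for ``gene_ids`` in the given order."""
        index = {g: j for j, g in enumerate(self.gene_ids)}
        cols = [index[g] for g in gene_ids]
        return ExpressionMatrix(self.values[:, cols], list(gene_ids), self.sample_ids)


@dataclass
class Phenotype:
    """The independent variable x, one value per sample."""

    x: np.ndarray
    kind: str = "binary"  # "binary" or "numeric"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).ravel()
        if self.kind not in ("binary", "numeric"):
            raise ValueError(f"unknown phenotype kind {self.kind!r}")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("phenotype contains non-finite values")
        if self.kind == "binary":
            if not np.all(np.isin(self.x, (0.0, 1.0))):
                raise ValueError("binary phenotype must be coded 0/1")
            n1 = int(np.sum(self.x == 0))
            n2 = int(np.sum(self.x == 1))
            if n1 < 2 or n2 < 2:
                raise ValueError(f"each group needs >= 2 samples (got {n1} and {n2})")
        if np.var(self.x) <= 0:
            raise ValueError("phenotype has zero variance")

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def group_sizes(self) -> tuple[int, int]:
        if self.kind != "binary":
            raise ValueError("group sizes are defined only for binary phenotypes")
        return int(np.sum(self.x == 0)), int(np.sum(self.x == 1))


@dataclass
class GeneSetCollection:
    """An ordered mapping of set name -> member gene ids."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} contains duplicate gene ids")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


@dataclass
class CovarianceMatrix:
    """A p x p symmetric positive-definite covariance (true Sigma or working V)."""

    matrix: np.ndarray
    kind: str = "supplied"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("covariance must be a square matrix")
        scale = max(np.abs(self.matrix).max(), 1.0)
        if np.abs(self.matrix - self.matrix.T).max() > _SYM_RTOL * scale:
            raise ValueError("covariance matrix is not symmetric")
        # enforce exact symmetry so downstream Cholesky factorizations are clean
        self.matrix = 0.5 * (self.matrix + self.matrix.T)
        try:
            np.linalg.cholesky(self.matrix)
        except np.linalg.LinAlgError:
            raise ValueError("covariance matrix is not positive definite") from None

    @property
    def p(self) -> int:
        return self.matrix.shape[0]


@dataclass
class CenteredDesign:
    """Null-centered data: per-gene grand-mean-centered responses and centered x.

    Under the null the GLS intercept estimate is the plain sample mean for
    any error covariance, so centering never depends on the working V.
    """

    centered_responses: np.ndarray  # n x p, Y_i - Ybar
    centered_x: np.ndarray  # length n, x_i - xbar
    group_means: tuple[np.ndarray, np.ndarray] | None = None  # (Ybar_g0, Ybar_g1)
    group_sizes: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.centered_responses = np.asarray(self.centered_responses, dtype=float)
        self.centered_x = np.asarray(self.centered_x, dtype=float).ravel()
        if np.abs(self.centered_responses.sum(axis=0)).max() > 1e-8:
            raise ValueError("centered responses have non-zero column sums")
        if abs(self.centered_x.sum()) > 1e-8:
            raise ValueError("centered x does not sum to zero")

    @property
    def n(self) -> int:
        return self.centered_responses.shape[0]

    @property
    def p(self) -> int:
        return self.centered_responses.shape[1]

    @property
    def x_sumsq(self) -> float:
        """c = sum_i (x_i - xbar)^2, the scale constant of the score vector."""
        return float(self.centered_x @ self.centered_x)

    def score_vector(self) -> np.ndarray:
        """s = sum_i (x_i - xbar)(Y_i - Ybar), the p-dimensional score."""
        return self.centered_responses.T @ self.centered_x


@dataclass
class TegsResult:
    """Result of one gene-set test."""

    set_name: str
    Q_observed: float
    p_perm: float | None = None
    p_satt: float | None = None
    p_mix: float | None = None
    kappa: float | None = None
    nu: float | None = None
    B: int = 0
    seed: int | None = None
    covariance_kind: str = ""
    n_genes: int = 0
    perm_Q: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.Q_observed < 0:
            raise ValueError("Q must be nonnegative")
        for name in ("p_perm", "p_satt", "p_mix"):
            p = getattr(self, name)
            if p is not None and not (0.0 < p <= 1.0):
                raise ValueError(f"{name}={p} outside (0, 1]")
        if self.kappa is not None and self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.nu is not None and self.nu <= 0:
            raise ValueError("nu must be positive")


@dataclass
class EffectVector:
    """Per-gene effects beta with the variance-component magnitude tau.

    tau = 0 encodes the null configuration (all beta_j = 0).
    """

    beta: np.ndarray
    tau: float = 0.0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        if self.tau < 0:
            raise ValueError("tau must be nonnegative")
        is_null = not np.any(self.beta != 0)
        if is_null and self.tau != 0:
            raise ValueError("tau > 0 requires a nonzero beta configuration")
        if not is_null and self.tau == 0:
            # convenience: infer tau as the empirical variance of beta
            self.tau = float(np.var(self.beta))

    @property
    def p(self) -> int:
        return self.beta.size


WORKING_KINDS = ("indpt", "unstr", "cpsym", "f2", "f-adpt", "supplied")


@dataclass
class WorkingCovarianceSpec:
    """Which working covariance structure to estimate, and how.

    kind:
        indpt    working independence (identity V; the global test)
        unstr    ridge-stabilized unstructured sample covariance
        cpsym    compound symmetry derived from the ridge estimator
        f2       two-factor covariance from the ridge estimator
        f-adpt   adaptive number of factors explaining >= variance_fraction
        supplied a user-provided (e.g. true) covariance, held fixed
    """

    kind: str = "unstr"
    ridge_percentile: float = 5.0
    variance_fraction: float = 0.80
    n_factors: int = 2
    supplied_matrix: CovarianceMatrix | None = None

    def __post_init__(self) -> None:
        if self.kind not in WORKING_KINDS:
            raise ValueError(f"unknown working covariance kind {self.kind!r}")
        if not (0.0 < self.ridge_percentile < 100.0):
            raise ValueError("ridge_percentile must be in (0, 100)")
        if not (0.0 < self.variance_fraction <= 1.0):
            raise ValueError("variance_fraction must be in (0, 1]")
        if self.n_factors < 1:
            raise ValueError("n_factors must be a positive integer")
        if self.kind == "supplied" and self.supplied_matrix is None:
            raise ValueError("kind='supplied' requires supplied_matrix")

    @property
    def label(self) -> str:
        return self.kind if self.kind != "supplied" else f"supplied[{self.supplied_matrix.kind}]"


@dataclass
class ResidualMatrix:
    """Per-gene OLS residuals of expression on (1, x)."""

    residuals: np.ndarray  # n x p
    dof_used: int = 2

    def __post_init__(self) -> None:
        self.residuals = np.asarray(self.residuals, dtype=float)
        if np.abs(self.residuals.sum(axis=0)).max() > 1e-8:
            raise ValueError("residual columns must sum to zero")

    @property
    def n(self) -> int:
        return self.residuals.shape[0]

    @property
    def p(self) -> int:
        return self.residuals.shape[1]


@dataclass
class QuadraticNullSpec:
    """Null law of Q as a nonnegative mixture of 1-df chi-squares.

    Q ~ sum_j lambda_j * chisq_1 with weights equal to the eigenvalues of
    c * V^-1 Sigma V^-1; the weight sum equals E_H0(Q).
    """

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if np.any(self.weights < -1e-10):
            raise ValueError("mixture weights must be nonnegative")
        self.weights = np.clip(self.weights, 0.0, None)

    @property
    def null_mean(self) -> float:
        return float(self.weights.sum())

    @property
    def null_var(self) -> float:
        return float(2.0 * np.sum(self.weights**2))
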