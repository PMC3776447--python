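"""Estimate the working-covariance menu from residuals and inspect it.

All estimated structures derive from the ridge-stabilized unstructured
residual covariance: compound symmetry averages it, the factor covariances
keep its leading eigencomponents.
"""

import numpy as np

from tegs import WorkingCovarianceSpec, build_working_covariance
from tegs.covariance import compute_residuals, estimate_unstructured_ridge
from tegs.simulate import make_beta, make_cov_cs, simulate_gene_set

Sigma = make_cov_cs(8, rho=0.5)  # truth: exchangeable, correlation 0.5
expr, pheno = simulate_gene_set(n=30, n1=15, beta=make_beta(8, 0, 0, 0), Sigma=Sigma, seed=3)

res = compute_residuals(expr, pheno)
ridge = estimate_unstructured_ridge(res, ridge_percentile=5.0)
print(f"ridge constant added to the diagonal: {ridge.matrix[0,0] - np.cov(res.residuals.T)[0,0]:.4f}")

for kind in ("indpt", "unstr", "cpsym", "f2", "f-adpt"):
    V = build_working_covariance(expr, pheno, WorkingCovarianceSpec(kind=kind))
    off = V.matrix[~np.eye(8, dtype=bool)]
    print(
        f"{kind:<8} mean diag {np.diag(V.matrix).mean():6.3f}   "
        f"mean off-diag {off.mean():6.3f}   min eigenvalue {np.linalg.eigvalsh(V.matrix).min():6.3f}"
    )

print(
    "\nWith an exchangeable truth (pairwise covariance 0.5), 'cpsym' recovers"
    "\na constant off-diagonal near 0.5, while 'indpt' discards it entirely."
    "\nEvery estimate is positive definite (min eigenvalue > 0)."
)
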