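"""Test one gene set for a phenotype effect under several working covariances.

Simulates a 20-sample, 10-gene set whose genes share a two-factor
correlation structure, injects a sparse effect (2 genes down, 4 up by 0.4),
and runs the variance-component score test with each working covariance.
"""

from tegs import WorkingCovarianceSpec, permutation_test
from tegs.simulate import make_beta, make_cov_twofactor, simulate_gene_set

Sigma = make_cov_twofactor(10, factor_share=0.5, seed=7)
expr, pheno = simulate_gene_set(n=20, n1=10, beta=make_beta(10, 2, 4, 0.4), Sigma=Sigma, seed=1)

specs = [WorkingCovarianceSpec(kind="supplied", supplied_matrix=Sigma)] + [
    WorkingCovarianceSpec(kind=k) for k in ("indpt", "unstr", "cpsym", "f2", "f-adpt")
]

print(f"{'working V':<18}{'Q':>10}{'p_perm':>10}{'p_satt':>10}{'p_mix':>10}")
for spec in specs:
    res, _ = permutation_test(expr, pheno, spec, B=1000, seed=42)
    print(
        f"{spec.label:<18}{res.Q_observed:>10.3f}{res.p_perm:>10.4f}"
        f"{res.p_satt:>10.4f}{res.p_mix:>10.4f}"
    )

print(
    "\nEach row is the same data tested with a different assumed covariance"
    "\namong the genes: small p-values flag a set-level phenotype effect."
    "\n'indpt' ignores the correlation (the global test); 'supplied' uses the"
    "\ngenerating covariance and is the best-case reference."
)
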