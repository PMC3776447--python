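"""Monte Carlo size and power across working covariances (scaled down).

Reproduces the structure of the single-gene-set benchmark: null replicates
confirm the 5% size; alternative replicates rank the working covariances,
with the true covariance best and working independence (the global test)
worst. Replicate counts are reduced so the script runs in ~20 s.
"""

from tegs import WorkingCovarianceSpec
from tegs.simulate import SimulationScenario, make_beta, make_cov_cs, run_size_power_experiment

Sigma = make_cov_cs(10, rho=0.5)
specs = [
    WorkingCovarianceSpec(kind="supplied", supplied_matrix=Sigma),
    WorkingCovarianceSpec(kind="cpsym"),
    WorkingCovarianceSpec(kind="indpt"),
]

for label, beta in [("NULL (beta = 0)", make_beta(10, 0, 0, 0)),
                    ("ALTERNATIVE (2 down / 4 up, 0.4)", make_beta(10, 2, 4, 0.4))]:
    sc = SimulationScenario(
        n=20, n1=10, p=10, true_cov=Sigma, beta=beta, replicates=300, B=300, seed=5
    )
    table = run_size_power_experiment(sc, specs)
    print(f"\n{label}  (effect index {sc.effect_index:.2f}):")
    print(table[table.method == "perm"][["variant", "rejection_rate", "mc_se"]].to_string(index=False))

print(
    "\nUnder the null every variant rejects ~5% of the time; under the"
    "\nalternative the true covariance leads, the estimated exchangeable"
    "\ncovariance follows, and ignoring correlation costs the most power."
)
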