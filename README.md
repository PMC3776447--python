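# tegs — variance component score tests for gene sets

`tegs` tests whether a *gene set* (a pathway, network module, cytoband, or
any predefined group of genes) is associated with a phenotype or exposure,
using a variance-component score test that explicitly models the
correlation among the genes in the set. It is aimed at transcriptomics
analyses — bulk or single-cell expression matrices with a binary or numeric
sample-level variable — where single-gene tests are underpowered and
rank-based enrichment ignores within-set correlation.

## The model and the statistic

For subject *i* (of *n*) and gene *j* (of *p* genes in the set):

    Y_ij = α_j + x_i β_j + ε_ij,    ε_i ~ N(0, Σ)

where `x` is the phenotype and Σ is the unknown true covariance of the
genes. Testing the set means testing H₀: β = 0, a p-dimensional hypothesis.
Treating the β_j as random draws from a common distribution with mean 0 and
variance τ converts this to the 1-dimensional variance-component null
H₀: τ = 0, whose score statistic under a *working covariance* V is

    Q = ‖ V⁻¹ s ‖²,   s = Σᵢ (xᵢ − x̄)(Yᵢ − Ȳ)

(the p-dimensional reduction of the stacked quadratic form; no np×np matrix
is ever formed). With V = I this is exactly the global test; with V closer
to Σ the test gains power. The package estimates V from residuals on a menu
of structures — working independence (`indpt`), ridge-stabilized
unstructured (`unstr`), compound symmetry (`cpsym`), two-factor (`f2`), and
adaptive-factor (`f-adpt`) — or accepts a supplied matrix.

p-values come from three null approximations:

- **permutation**: relabel `x`, re-estimate V inside every permutation,
  p = (1 + #{Q⁽ᵇ⁾ ≥ Q}) / (B + 1);
- **scaled chi-square** (Satterthwaite): match the permutation mean and
  variance of Q to κ·χ²_ν and take the upper tail;
- **normal mixture**: fit a two-component Gaussian mixture to the probits
  of the per-permutation scaled-chi-square p-values for sharper small
  p-values.

Across many sets, Storey q-values (or Benjamini–Hochberg) control the FDR.
An analytic power module computes design-stage power from the theoretical
null moments E₀(Q) = c·tr(V⁻²Σ), Var₀(Q) = 2c²·tr((V⁻²Σ)²) and a scaled
noncentral chi-square, with c = Σᵢ(xᵢ − x̄)².

## Worked example

```python
from tegs import WorkingCovarianceSpec, permutation_test
from tegs.simulate import make_beta, make_cov_twofactor, simulate_gene_set

Sigma = make_cov_twofactor(10, factor_share=0.5, seed=7)
expr, pheno = simulate_gene_set(n=20, n1=10, beta=make_beta(10, 2, 4, 0.4),
                                Sigma=Sigma, seed=1)
res, _ = permutation_test(expr, pheno, WorkingCovarianceSpec(kind="f2"),
                          B=1000, seed=42)
print(res.Q_observed, res.p_perm, res.p_satt)
```

Running `python examples/01_test_a_gene_set.py` (this dataset under all six
working covariances) prints:

```
working V                  Q    p_perm    p_satt     p_mix
supplied[f2-true]     67.380    0.2148    0.2071    0.2175
indpt                 47.807    0.4286    0.4441    0.4218
unstr                 66.568    0.1159    0.1436    0.1258
cpsym                 21.859    0.4745    0.4826    0.4616
f2                    69.439    0.1638    0.1785    0.1688
f-adpt               172.071    0.1568    0.1702    0.1526
```

Q is the observed score statistic (its scale depends on V, so only the
p-values are comparable across rows); each p-value asks how surprising the
observed set-level association is under relabeling of the phenotype. Note
the correlation-aware rows (`f2`, `f-adpt`, `unstr`) give smaller p-values
than the correlation-blind `indpt` (global test) on the same data — the
point of modeling V.

The other scripts in `examples/` cover the covariance menu, analytic power
sweeps, Monte Carlo size/power tables, and the GCT/CLS/GMT file pipeline.

## Command line

```bash
tegs run --expr study.gct --pheno study.cls --sets study.gmt \
         --cov f-adpt --perms 2000 --seed 1 --method all --out results.tsv
tegs simulate --preset cs --n 20 --p 40 --rho 0.5 --beta neg:5,pos:25,mag:0.5 \
              --reps 1000 --perms 500 --seed 1 --out sim_out/
tegs power --n 20 --n1 10 --p 10 --cov-true cs --rho 0.5 \
           --beta-spec neg:2,pos:4,mag:0.4
```

Input formats: GCT v1.2 expression (genes as rows on disk), CLS phenotype
(two-class categorical or `#numeric`), GMT gene sets, plus plain-TSV
fallbacks. Sets with fewer than four genes present in the matrix are
excluded by default (`--min-set-size`).

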