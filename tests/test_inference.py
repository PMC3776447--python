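"""Tests for permutation, scaled chi-square, normal mixture, and q-values."""

import numpy as np
import pytest
from itertools import combinations
from scipy.stats import chi2, norm

import tegs
from tegs import (
    CovarianceMatrix,
    ExpressionMatrix,
    Phenotype,
    WorkingCovarianceSpec,
    permutation_test,
    qvalues,
    satterthwaite_pvalue,
)
from tegs.inference import (
    NormalMixtureFit,
    PermutationDraws,
    _em_1d,
    fit_normal_mixture,
    normal_mixture_pvalue,
)
from tegs.inference import test_gene_sets as run_gene_set_tests  # noqa: avoid pytest collection
from tegs.statistic import center_under_null, tegs_statistic

from conftest import random_instance


# ---------------------------------------------------------------------------
# Permutation p-values

def test_permutation_exact_enumeration_oracle():
    """n=4 balanced binary: large-B p_perm converges to the exact p over all
    C(4,2)=6 label assignments."""
    rng = np.random.default_rng(7)
    Y = rng.standard_normal((4, 3))
    expr = ExpressionMatrix(Y, ["a", "b", "c"], [f"s{i}" for i in range(4)])
    pheno = Phenotype(np.array([0.0, 0.0, 1.0, 1.0]))
    V = CovarianceMatrix(np.eye(3))
    q_obs = tegs_statistic(center_under_null(expr, pheno), V)
    # exhaustive null: every way to place the two '1' labels
    exact_qs = []
    for ones in combinations(range(4), 2):
        x = np.zeros(4)
        x[list(ones)] = 1.0
        d = center_under_null(expr, Phenotype(x))
        exact_qs.append(tegs_statistic(d, V))
    p_exact = np.mean([q >= q_obs - 1e-12 for q in exact_qs])
    res, _ = permutation_test(
        expr, pheno, WorkingCovarianceSpec(kind="indpt"), B=6000, seed=1, methods=("perm",)
    )
    # (1 + r) / (B + 1) converges to the exhaustive proportion
    assert res.p_perm == pytest.approx(p_exact, abs=0.02)


def test_permutation_pvalue_convention_never_zero(rng):
    # numeric phenotype: a random permutation matching the observed x has
    # probability 1/n!, so with an overwhelming effect only the observed
    # statistic contributes and p_perm attains its floor 1/(B+1)
    expr, pheno = random_instance(10, 3, rng, binary=False)
    expr = ExpressionMatrix(
        expr.values + 50.0 * pheno.x[:, None], expr.gene_ids, expr.sample_ids
    )
    res, draws = permutation_test(
        expr, pheno, WorkingCovarianceSpec(kind="indpt"), B=200, seed=2, methods=("perm",)
    )
    assert res.p_perm == pytest.approx(1.0 / 201.0)
    assert draws.B == 200


def test_permutation_bit_reproducible(rng):
    expr, pheno = random_instance(12, 4, rng, binary=True)
    spec = WorkingCovarianceSpec(kind="unstr")
    r1, d1 = permutation_test(expr, pheno, spec, B=120, seed=9)
    r2, d2 = permutation_test(expr, pheno, spec, B=120, seed=9)
    assert np.array_equal(d1.Q_values, d2.Q_values)
    assert (r1.p_perm, r1.p_satt, r1.p_mix) == (r2.p_perm, r2.p_satt, r2.p_mix)


def test_permutation_floor_enforced(rng):
    expr, pheno = random_instance(8, 3, rng, binary=True)
    with pytest.raises(ValueError, match="floor"):
        permutation_test(expr, pheno, WorkingCovarianceSpec(kind="indpt"), B=50, seed=0)


def test_null_pvalues_roughly_uniform(rng):
    """Mean of p_perm over null replicates is near 1/2 (super-uniformity sanity)."""
    from tegs.simulate import SimulationScenario, make_beta, make_cov_cs, run_size_power_experiment

    sc = SimulationScenario(
        n=16, n1=8, p=5, true_cov=make_cov_cs(5, 0.3), beta=make_beta(5, 0, 0, 0),
        replicates=200, B=150, seed=4,
    )
    _, pv = run_size_power_experiment(
        sc, [WorkingCovarianceSpec(kind="indpt")], return_pvalues=True
    )
    pp = pv["indpt"]["perm"]
    assert abs(pp.mean() - 0.5) < 3 * (1 / np.sqrt(12 * 200)) + 1 / 151


# ---------------------------------------------------------------------------
# Satterthwaite

def test_satterthwaite_plugin_formulas():
    # values with sample mean 10 and unbiased variance 40
    draws = PermutationDraws(Q_values=np.array([2.0, 6.0, 10.0, 14.0, 18.0]), B=5)
    kappa, nu, p = satterthwaite_pvalue(20.0, draws)
    assert kappa == pytest.approx(2.0)
    assert nu == pytest.approx(5.0)
    assert p == pytest.approx(chi2.sf(10.0, 5.0))
    assert p == pytest.approx(0.0752, abs=2e-4)


def test_satterthwaite_moment_match():
    rng = np.random.default_rng(3)
    qs = rng.chisquare(4, size=400) * 1.7
    draws = PermutationDraws(Q_values=qs, B=400)
    kappa, nu, _ = satterthwaite_pvalue(5.0, draws)
    # the fitted kappa*chisq_nu law reproduces the sample moments exactly
    assert kappa * nu == pytest.approx(qs.mean())
    assert 2 * kappa**2 * nu == pytest.approx(qs.var(ddof=1))


def test_satterthwaite_zero_variance_error():
    draws = PermutationDraws(Q_values=np.ones(10), B=10)
    with pytest.raises(ValueError):
        satterthwaite_pvalue(2.0, draws)


# ---------------------------------------------------------------------------
# Normal mixture refinement

def test_mixture_uniform_null_recovers_satt_p():
    """If the per-permutation p-values are uniform, the probits are standard
    normal and the mixture p-value approximately equals the input p."""
    rng = np.random.default_rng(12)
    B = 2000
    draws = PermutationDraws(Q_values=rng.chisquare(3, B), B=B, seed=5)
    draws.satt_p_values = rng.uniform(size=B)
    for p_obs in (0.5, 0.1, 0.01):
        fit, p_mix = normal_mixture_pvalue(p_obs, draws)
        assert p_mix == pytest.approx(p_obs, rel=0.35)
    # fitted mixture is close to N(0, 1) overall: check first two moments
    m = fit.pi @ fit.mu
    v = fit.pi @ (fit.var + fit.mu**2) - m**2
    assert abs(m) < 0.12
    assert abs(v - 1.0) < 0.2


def test_mixture_symmetric_midpoint():
    rng = np.random.default_rng(8)
    B = 1000
    draws = PermutationDraws(Q_values=rng.chisquare(3, B), B=B, seed=6)
    draws.satt_p_values = rng.uniform(size=B)
    _, p_mix = normal_mixture_pvalue(0.5, draws)
    assert p_mix == pytest.approx(0.5, abs=0.1)


def test_em_loglik_monotone():
    rng = np.random.default_rng(21)
    z = np.concatenate([rng.normal(-1.5, 0.7, 300), rng.normal(0.8, 1.1, 500)])
    _, trace = _em_1d(z, 0.4, np.array([-1.0, 1.0]), np.array([1.0, 1.0]))
    assert np.all(np.diff(trace) >= -1e-9)


def test_em_matches_sklearn_loglik():
    """Independent EM (sklearn GaussianMixture) reaches the same likelihood."""
    from sklearn.mixture import GaussianMixture

    rng = np.random.default_rng(13)
    z = np.concatenate([rng.normal(-2.0, 0.6, 400), rng.normal(0.5, 1.0, 600)])
    fit = fit_normal_mixture(z, seed=2)
    gm = GaussianMixture(n_components=2, n_init=5, random_state=0, tol=1e-8, reg_covar=1e-6)
    gm.fit(z[:, None])
    ll_sklearn = gm.score(z[:, None]) * z.size
    assert fit.loglik == pytest.approx(ll_sklearn, abs=0.5)
    # matched components (sorted by mean)
    mu_mine = np.sort(fit.mu)
    mu_skl = np.sort(gm.means_.ravel())
    assert np.allclose(mu_mine, mu_skl, atol=0.1)


def test_mixture_pvalue_tracks_tail_example():
    """A spiked two-component null gives a mixture p consistent with the
    fitted cdf at the observed probit."""
    rng = np.random.default_rng(14)
    B = 1500
    z = np.concatenate([rng.normal(-1.0, 0.5, B // 3), rng.normal(0.5, 1.0, B - B // 3)])
    p_b = norm.cdf(z)
    draws = PermutationDraws(Q_values=np.ones(B) + rng.uniform(size=B), B=B, seed=3)
    draws.satt_p_values = p_b
    fit, p_mix = normal_mixture_pvalue(0.002, draws)
    z_obs = norm.ppf(np.clip(0.002, 1 / (10 * B), 1 - 1 / (10 * B)))
    assert p_mix == pytest.approx(float(fit.cdf(z_obs)), rel=1e-12)


# ---------------------------------------------------------------------------
# q-values

def test_qvalues_all_ones():
    assert np.array_equal(qvalues(np.ones(5)), np.ones(5))


def test_qvalues_monotone_in_sorted_order(rng):
    p = rng.uniform(size=40)
    q = qvalues(p)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)


def test_qvalues_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    p = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.212, 0.216])
    q = qvalues(p, method="bh")
    _, q_ref, _, _ = multipletests(p, method="fdr_bh")
    assert np.allclose(q, q_ref, atol=1e-12)


def test_qvalues_storey_scales_bh():
    rng = np.random.default_rng(5)
    p = rng.uniform(size=60)
    pi0 = min(1.0, np.mean(p > 0.5) / 0.5)
    assert np.allclose(qvalues(p, method="storey"), np.clip(pi0 * qvalues(p, method="bh"), 0, 1))


def test_qvalues_empty():
    assert qvalues(np.array([])).size == 0


# ---------------------------------------------------------------------------
# Collection driver

def test_gene_sets_results_independent_of_other_sets(rng):
    from tegs.simulate import make_cov_cs, make_beta, simulate_gene_set

    Sigma = make_cov_cs(12, 0.4)
    expr, pheno = simulate_gene_set(14, 7, make_beta(12, 2, 2, 0.7), Sigma, seed=30)
    sets_all = tegs.GeneSetCollection(
        {"A": expr.gene_ids[:5], "B": expr.gene_ids[5:10], "C": expr.gene_ids[2:9]}
    )
    sets_sub = tegs.GeneSetCollection({"B": expr.gene_ids[5:10]})
    spec = WorkingCovarianceSpec(kind="f2")
    df_all = run_gene_set_tests(expr, pheno, sets_all, spec, B=120, seed=17, methods=("perm",))
    df_sub = run_gene_set_tests(expr, pheno, sets_sub, spec, B=120, seed=17, methods=("perm",))
    p_all = df_all.set_index("set").loc["B", "p_perm"]
    p_sub = df_sub.set_index("set").loc["B", "p_perm"]
    assert p_all == p_sub


def test_gene_sets_attaches_qvalues(rng):
    from tegs.simulate import make_cov_cs, make_beta, simulate_gene_set

    Sigma = make_cov_cs(10, 0.3)
    expr, pheno = simulate_gene_set(12, 6, make_beta(10, 0, 0, 0), Sigma, seed=31)
    sets = tegs.GeneSetCollection({f"S{k}": expr.gene_ids[k : k + 4] for k in range(5)})
    df = run_gene_set_tests(expr, pheno, sets, WorkingCovarianceSpec(kind="indpt"), B=120, seed=3, methods=("perm",))
    assert "q_value" in df.columns
    assert df["q_value"].between(0, 1).all()
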