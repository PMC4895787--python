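"""Maximum-likelihood fitting, LRT p-values, and the two scoring paths."""

import numpy as np
import pytest
from scipy import stats

from coalmap import (
    coalmap_score,
    eigenstrat_score,
    eigenstrat_scores,
    fit_ml,
    full_alignment_pcs,
    lrt_pvalue,
    score_alignment,
    simulate_trait_realization,
)


def test_perfect_fit_handled_by_rss_floor(rng):
    x = rng.normal(size=30)
    fit = fit_ml(2.0 * x, None, x)
    assert fit.rss_floored
    assert abs(fit.beta_hat - 2.0) < 1e-6
    assert np.isfinite(fit.loglik)


def test_three_point_toy_matches_normal_equations():
    y = np.array([1.0, 2.0, 3.0])
    x = np.array([0.0, 1.0, 1.0])
    fit = fit_ml(y, None, x)
    # hand-solved OLS: intercept 1, slope 1.5, RSS = 0.5
    assert abs(fit.coef[0] - 1.0) < 1e-10
    assert abs(fit.beta_hat - 1.5) < 1e-10
    n, rss = 3, 0.5
    assert abs(fit.loglik - (-n / 2 * (np.log(2 * np.pi * rss / n) + 1))) < 1e-10
    assert abs(fit.tau_hat - n / rss) < 1e-8


def test_null_column_leaves_loglik_unchanged(rng):
    y = rng.normal(size=40)
    W = rng.normal(size=(40, 3))
    base = fit_ml(y, W)
    padded = fit_ml(y, np.column_stack([W, np.zeros(40)]))
    assert abs(base.loglik - padded.loglik) < 1e-10
    assert padded.dropped  # the all-zero column was detected


def test_ml_equals_ols_on_random_designs(rng):
    """Property: the ML fit solves the normal equations (200 draws)."""
    for _ in range(200):
        n = int(rng.integers(12, 40))
        p = int(rng.integers(1, 5))
        W = rng.normal(size=(n, p))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        fit = fit_ml(y, W, x)
        D = np.column_stack([np.ones(n), W, x])
        ref = np.linalg.solve(D.T @ D, D.T @ y)
        np.testing.assert_allclose(fit.coef, ref, atol=1e-8)


def test_lrt_boundary_and_quantile():
    y = np.arange(10.0)
    f = fit_ml(y, None)
    assert lrt_pvalue(f, f) == 1.0
    # chi-square 1 df: Lambda = 3.841459 -> p = 0.05
    assert abs(stats.chi2.sf(3.841459, 1) - 0.05) < 1e-6


def test_lrt_rejects_non_nested():
    y = np.arange(12.0)
    W = np.column_stack([y**2, np.sin(y), np.cos(y)])
    big = fit_ml(y, W)
    small = fit_ml(y, W[:, :1])
    with pytest.raises(ValueError):
        lrt_pvalue(small, big)


def test_null_pvalues_are_uniform(rng):
    """Under a true null the SNP LRT p-value is Uniform(0,1)."""
    n = 300  # the chi-square reference is asymptotic; use study-scale n
    W = rng.normal(size=(n, 3))
    pvals = np.empty(2000)
    for i in range(2000):
        y = rng.normal(size=n)
        x = rng.integers(0, 2, size=n).astype(float)
        null = fit_ml(y, W)
        alt = fit_ml(y, W, x)
        pvals[i] = lrt_pvalue(alt, null)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_minp_is_min_of_nested_pvalues(small_alignment, small_partitions, small_builder, rng):
    tr = simulate_trait_realization(small_alignment, "single", pi=1.0, rng=rng)
    j = int(tr.delta[0])
    ell = small_partitions.partition_of_site(j)
    res = coalmap_score(tr.y, small_alignment.genotypes[:, j],
                        small_builder.bundle(ell), site=j)
    assert res.p_value == min(res.p_global, res.p_glocal)
    assert res.selected_model in ("global", "glocal")


def test_scan_matches_per_snp_scoring(small_alignment, small_partitions, small_builder, rng):
    """The vectorized alignment scan reproduces the per-SNP fits."""
    aln, parts = small_alignment, small_partitions
    tr = simulate_trait_realization(aln, "two", pi=0.9, rng=rng)
    table = score_alignment(aln, parts, tr.y, builder=small_builder)
    check = rng.choice(aln.n_sites, size=25, replace=False)
    for j in check:
        ell = parts.partition_of_site(int(j))
        ref = coalmap_score(tr.y, aln.genotypes[:, j],
                            small_builder.bundle(ell), site=int(j))
        row = table.iloc[int(j)]
        assert abs(row.p_global - ref.p_global) < 1e-8
        assert abs(row.p_glocal - ref.p_glocal) < 1e-8
        assert row.selected_model == ref.selected_model
        assert abs(row.beta_hat - ref.beta_hat) < 1e-8


def test_forward_rule_tests_snp_in_adopted_design(small_alignment, small_partitions, small_builder, rng):
    aln, parts = small_alignment, small_partitions
    tr = simulate_trait_realization(aln, "single", pi=0.9, rng=rng)
    table = score_alignment(aln, parts, tr.y, rule="forward", builder=small_builder)
    picked = table.groupby("partition_id")["selected_model"].nunique()
    assert (picked == 1).all()  # adoption is a per-partition decision
    glocal_rows = table[table.selected_model == "glocal"]
    if len(glocal_rows):
        assert np.allclose(glocal_rows.p_value, glocal_rows.p_glocal)


def test_causal_snps_score_better_than_background(small_alignment, small_partitions, rng):
    tr = simulate_trait_realization(small_alignment, "single", pi=1.0, rng=rng)
    table = score_alignment(small_alignment, small_partitions, tr.y)
    causal = table.p_value.to_numpy()[tr.delta]
    noncausal = np.delete(table.p_value.to_numpy(), tr.delta)
    assert np.median(causal) <= np.median(noncausal)


def test_eigenstrat_confounded_snp_has_p_one(rng):
    n = 50
    pcs = rng.normal(size=(n, 3))
    x = pcs @ np.array([1.0, -2.0, 0.5])  # SNP entirely in PC span
    y = rng.normal(size=n)
    assert eigenstrat_score(y, x, pcs) > 0.999


def test_eigenstrat_zero_pcs_is_plain_correlation():
    y = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
    x = np.array([0.0, 1.0, 1.0, 0.0, 1.0])
    r = np.corrcoef(x, y)[0, 1]
    expected = float(stats.chi2.sf((5 - 1) * r * r, 1))
    assert abs(eigenstrat_score(y, x, None) - expected) < 1e-10


def test_eigenstrat_type_one_error_calibrated(small_alignment, rng):
    """With structure captured by the PCs and no causal SNPs, the baseline
    rejects at roughly the nominal rate."""
    aln = small_alignment
    rejections = []
    for _ in range(30):
        y = rng.normal(size=aln.n_samples)
        p = eigenstrat_scores(aln, y, n_pcs=10)
        rejections.append((p < 0.05).mean())
    rate = float(np.mean(rejections))
    assert abs(rate - 0.05) < 0.02


def test_permuted_phenotype_kills_enrichment(small_alignment, small_partitions, rng):
    from coalmap import roc_and_auroc

    tr = simulate_trait_realization(small_alignment, "single", pi=1.0, rng=rng)
    y_perm = rng.permutation(tr.y)
    table = score_alignment(small_alignment, small_partitions, y_perm)
    labels = np.zeros(small_alignment.n_sites, dtype=bool)
    labels[tr.delta] = True
    auroc = roc_and_auroc(table.p_value.to_numpy(), labels).auroc
    assert abs(auroc - 0.5) < 0.2


def test_local_only_ablation_design(small_alignment, small_partitions, small_builder, rng):
    from coalmap.assoc import _added_column_pvalues

    tr = simulate_trait_realization(small_alignment, "single", pi=0.9, rng=rng)
    table = score_alignment(small_alignment, small_partitions, tr.y,
                            design="local-only", builder=small_builder)
    assert (table.selected_model == "local").all()
    j = 3
    ell = small_partitions.partition_of_site(j)
    bundle = small_builder.bundle(ell)
    idx = small_partitions.site_indices(ell)
    p_ref, _ = _added_column_pvalues(
        tr.y, bundle.W_local, small_alignment.genotypes[:, idx].astype(float)
    )
    assert abs(table.p_value.iloc[j] - p_ref[np.flatnonzero(idx == j)[0]]) < 1e-12


def test_lambda_gc_deflates_inflated_statistics(small_alignment, rng):
    # a structured phenotype (population means) inflates the baseline;
    # genomic control pushes p-values back toward uniform
    pops = np.asarray(small_alignment.populations)
    y = (pops == "H").astype(float) + 0.01 * rng.normal(size=pops.size)
    p_raw = eigenstrat_scores(small_alignment, y, n_pcs=2)
    p_gc = eigenstrat_scores(small_alignment, y, n_pcs=2, lambda_gc=True)
    assert np.all(p_gc >= p_raw - 1e-12)
    assert np.median(p_gc) > np.median(p_raw)


def test_drop_test_snp_from_local_pca(small_alignment, small_partitions, small_builder, rng):
    """Leaving the test SNP out of its local PCA changes only p_glocal,
    and only when the SNP loads on the local PCs."""
    tr = simulate_trait_realization(small_alignment, "single", pi=0.9, rng=rng)
    full = score_alignment(small_alignment, small_partitions, tr.y,
                           builder=small_builder)
    loo = score_alignment(small_alignment, small_partitions, tr.y,
                          builder=small_builder, drop_test_snp_from_local=True)
    np.testing.assert_allclose(loo.p_global, full.p_global, atol=1e-9)
    assert not np.allclose(loo.p_glocal, full.p_glocal)
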