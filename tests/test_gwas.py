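"""Kinship, PCA, REML null model, marker scan, and the multi-locus scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pleionet as pn
from pleionet.datatypes import MISSING, SimConfig
from pleionet.gwas import _reml_loglik

from conftest import make_geno


# ----------------------------------------------------------------- kinship

def test_kinship_identical_samples_share_diagonal():
    dos = np.array([[0, 1, 2, 1], [0, 1, 2, 1], [2, 0, 1, 0]])
    K = pn.compute_kinship(make_geno(dos))
    assert K[0, 1] == pytest.approx(K[0, 0])
    assert K[0, 1] == pytest.approx(K[1, 1])
    np.testing.assert_allclose(K, K.T)


def test_kinship_matches_vanraden_hand_computation():
    dos = np.array([
        [0, 1, 2],
        [1, 1, 0],
        [2, 0, 1],
        [1, 2, 1],
    ], dtype=float)
    K = pn.compute_kinship(make_geno(dos))
    p = dos.mean(axis=0) / 2
    W = dos - 2 * p
    expected = W @ W.T / (2 * np.sum(p * (1 - p)))
    np.testing.assert_allclose(K, expected, atol=1e-12)


def test_kinship_ignores_monomorphic_markers():
    dos = np.array([[0, 1], [1, 2], [2, 0]])
    with_mono = np.column_stack([dos, [2, 2, 2]])
    K1 = pn.compute_kinship(make_geno(dos))
    K2 = pn.compute_kinship(make_geno(with_mono))
    np.testing.assert_allclose(K1, K2, atol=1e-12)


def test_kinship_no_polymorphic_markers_is_error():
    with pytest.raises(ValueError, match="polymorphic"):
        pn.compute_kinship(make_geno(np.full((3, 2), 2)))


# --------------------------------------------------------------------- PCA

def test_pcs_rank_one_matrix():
    base = np.array([0.0, 1, 2, 1, 0])
    dos = np.round(np.outer(base, np.ones(4))).astype(int)
    scores, eigvals = pn.compute_pcs(make_geno(dos), q=2)
    assert eigvals[0] > 0
    assert eigvals[1] == pytest.approx(0.0, abs=1e-10)


def test_pcs_scores_orthogonal(sim_panel):
    scores, _ = pn.compute_pcs(sim_panel, q=5)
    gram = scores.T @ scores
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() < 1e-6 * np.abs(np.diag(gram)).max()


def test_pcs_eigenvalues_match_dense_eigendecomposition():
    rng = np.random.default_rng(8)
    dos = rng.integers(0, 3, size=(6, 5))
    scores, eigvals = pn.compute_pcs(make_geno(dos), q=4)
    d = dos - dos.mean(axis=0)
    cov = d @ d.T / (6 - 1)
    dense = np.sort(np.linalg.eigvalsh(cov))[::-1]
    np.testing.assert_allclose(eigvals, dense[:4], atol=1e-10)


def test_pcs_q_too_large_is_error(sim_panel):
    with pytest.raises(ValueError, match="n_samples"):
        pn.compute_pcs(sim_panel, q=sim_panel.n_samples)


# ------------------------------------------------------------- null model

def test_reml_delta_beats_grid(sim_panel):
    rng = np.random.default_rng(9)
    K = pn.compute_kinship(sim_panel)
    y = rng.normal(size=sim_panel.n_samples)
    fit = pn.fit_null_model(y, K)
    s, u = np.linalg.eigh(K)
    s = np.clip(s, 0, None)
    yr, xr = u.T @ y, u.T @ np.ones((len(y), 1))
    best = _reml_loglik(np.log(fit.delta), s, yr, xr)
    for g in np.linspace(np.log(1e-4), np.log(1e4), 50):
        assert best >= _reml_loglik(g, s, yr, xr) - 1e-6


def test_null_trait_pseudo_heritability_near_zero():
    hits = 0
    for seed in range(10):
        geno = pn.simulate_genotypes(SimConfig(n_samples=150, n_markers=300, seed=seed))
        K = pn.compute_kinship(geno)
        y = np.random.default_rng(seed + 500).normal(size=150)
        if pn.fit_null_model(y, K).pseudo_heritability <= 0.2:
            hits += 1
    assert hits >= 8


def test_pseudo_heritability_recovery():
    ests = []
    for seed in range(10):
        geno = pn.simulate_genotypes(SimConfig(n_samples=400, n_markers=400, seed=seed + 20))
        K = pn.compute_kinship(geno)
        rng = np.random.default_rng(seed + 900)
        s, u = np.linalg.eigh(K)
        g = u @ (np.sqrt(np.clip(s, 0, None)) * rng.normal(size=400))
        g = g / g.std()
        y = np.sqrt(0.8) * g + np.sqrt(0.2) * rng.normal(size=400)
        ests.append(pn.fit_null_model(y, K).pseudo_heritability)
    assert abs(np.mean(ests) - 0.8) < 0.15


def test_singular_covariates_is_error(sim_panel):
    K = pn.compute_kinship(sim_panel)
    y = np.random.default_rng(0).normal(size=sim_panel.n_samples)
    X = np.ones((sim_panel.n_samples, 2))  # duplicated intercept
    with pytest.raises(ValueError, match="rank"):
        pn.fit_null_model(y, K, X)


# -------------------------------------------------------------------- scan

def test_identity_kinship_scan_equals_ols():
    rng = np.random.default_rng(10)
    geno = pn.simulate_genotypes(SimConfig(n_samples=120, n_markers=150, seed=31))
    y = rng.normal(size=120) + 0.5 * geno.dosage[:, 3]
    K = np.eye(120)
    fit = pn.fit_null_model(y, K)
    res = pn.scan_markers(geno, y, fit)
    for j in [0, 3, 50, geno.n_markers - 1]:
        x = geno.dosage[:, j].astype(float)
        X = np.column_stack([np.ones(120), x])
        beta, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sigma2 = resid @ resid / (120 - 2)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        t = beta[1] / se
        p = 2 * stats.t.sf(abs(t), 120 - 2)
        assert res["p"].iloc[j] == pytest.approx(p, abs=1e-8)
        assert res["beta"].iloc[j] == pytest.approx(beta[1], abs=1e-8)


def test_zero_variance_marker_reported_missing():
    dos = np.array([[0, 1, 1], [1, 1, 0], [2, 1, 2], [1, 1, 1]])
    geno = make_geno(dos)
    y = np.array([0.2, 1.1, 1.7, 0.6])
    fit = pn.fit_null_model(y, np.eye(4))
    res = pn.scan_markers(geno, y, fit)
    assert np.isnan(res["p"].iloc[1])
    assert np.isfinite(res["p"].iloc[0])


def test_duplicated_marker_columns_identical_results(sim_panel):
    rng = np.random.default_rng(11)
    dup = np.column_stack([sim_panel.dosage[:, :20], sim_panel.dosage[:, 5]])
    geno = make_geno(dup, samples=list(sim_panel.samples))
    y = rng.normal(size=geno.n_samples)
    fit = pn.fit_null_model(y, pn.compute_kinship(sim_panel))
    res = pn.scan_markers(geno, y, fit)
    for col in ("beta", "se", "p"):
        assert res[col].iloc[5] == pytest.approx(res[col].iloc[20], abs=1e-12)


def test_scan_permutation_invariance(sim_panel):
    rng = np.random.default_rng(12)
    n = sim_panel.n_samples
    y = rng.normal(size=n) + sim_panel.dosage[:, 10]
    K = pn.compute_kinship(sim_panel)
    pcs, _ = pn.compute_pcs(sim_panel, 3)
    X = np.column_stack([np.ones(n), pcs])
    fit = pn.fit_null_model(y, K, X)
    res = pn.scan_markers(sim_panel, y, fit)

    perm = rng.permutation(n)
    from pleionet.datatypes import GenotypeMatrix
    geno_p = GenotypeMatrix(dosage=sim_panel.dosage[perm],
                            markers=sim_panel.markers.copy(),
                            samples=[sim_panel.samples[i] for i in perm])
    fit_p = pn.fit_null_model(y[perm], K[np.ix_(perm, perm)], X[perm])
    res_p = pn.scan_markers(geno_p, y[perm], fit_p)
    np.testing.assert_allclose(res["p"].to_numpy(), res_p["p"].to_numpy(),
                               rtol=0, atol=1e-10)


# -------------------------------------------------------------------- mlmm

def test_mlmm_zero_steps_equals_single_locus(sim_panel):
    rng = np.random.default_rng(13)
    y = rng.normal(size=sim_panel.n_samples)
    K = pn.compute_kinship(sim_panel)
    single = pn.scan_markers(sim_panel, y, pn.fit_null_model(y, K))
    multi = pn.mlmm_scan(sim_panel, y, K, max_steps=0, maf_min=0.0)
    np.testing.assert_allclose(single["p"].to_numpy(), multi["p"].to_numpy(),
                               rtol=0, atol=1e-12)
    assert multi.attrs["cofactors"] == []


def test_mlmm_recovers_planted_qtl_as_first_cofactor():
    hits = 0
    for seed in range(10):
        geno = pn.simulate_genotypes(SimConfig(
            n_samples=400, n_markers=600,
            chrom_lengths=(("Chr1", 20_000_000), ("Chr2", 20_000_000)),
            seed=seed + 40))
        maf = geno.maf()
        qtl = int(np.flatnonzero(maf >= 0.2)[10])
        rng = np.random.default_rng(seed + 700)
        x = geno.dosage[:, qtl].astype(float)
        g = x / x.std() * np.sqrt(0.30)
        y = g + np.sqrt(0.70) * rng.normal(size=400)
        K = pn.compute_kinship(geno)
        res = pn.mlmm_scan(geno, y, K, max_steps=3)
        cof = res.attrs["cofactors"]
        if not cof:
            continue
        first = geno.marker_index(cof[0])
        same_chrom = geno.markers["chrom"].iloc[first] == geno.markers["chrom"].iloc[qtl]
        close = abs(geno.markers["pos"].iloc[first] - geno.markers["pos"].iloc[qtl]) <= 50_000
        in_ld = pn.ld_r2(geno, first, qtl) >= 0.5
        if first == qtl or (same_chrom and close and in_ld):
            hits += 1
    assert hits >= 9


def test_mlmm_null_selects_empty_model():
    empty = 0
    for seed in range(10):
        geno = pn.simulate_genotypes(SimConfig(n_samples=200, n_markers=500, seed=seed + 60))
        y = np.random.default_rng(seed + 800).normal(size=200)
        K = pn.compute_kinship(geno)
        res = pn.mlmm_scan(geno, y, K, max_steps=3)
        if res.attrs["cofactors"] == []:
            empty += 1
    assert empty >= 8


def test_mlmm_negative_steps_is_error(sim_panel):
    y = np.zeros(sim_panel.n_samples)
    with pytest.raises(ValueError, match="max_steps"):
        pn.mlmm_scan(sim_panel, y, np.eye(sim_panel.n_samples), max_steps=-1)
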