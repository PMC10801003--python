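"""Kinship- and PC-corrected association scans with a multi-locus extension.

The mixed model is y = X b + g + e with g ~ N(0, sigma2_g K) and
e ~ N(0, sigma2_e I). The kinship K is eigendecomposed once
(K = U S U'); in the rotated frame the model is a weighted regression
with per-observation variances sigma2_g (S_i + delta), delta =
sigma2_e / sigma2_g, and the restricted likelihood is a 1-D function of
delta optimized numerically (EMMA-style REML).

The per-marker scan is population-parameters-previously-determined (P3D):
delta is held at the null-model estimate, and each marker is tested by
weighted least squares with the residual scale re-estimated per marker.
This makes the identity-kinship limit coincide exactly with the ordinary
least-squares t-test.

The multi-locus scan (mlmm_scan) is forward selection: at each step the
most significant marker joins the fixed covariates, delta is refit, and
the scan is repeated; the step minimizing the extended BIC is returned.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import MISSING, GenotypeMatrix, MixedModelFit

logger = logging.getLogger(__name__)

ASSOC_COLUMNS = ["chrom", "pos", "id", "beta", "se", "p", "minus_log10_p", "n", "maf", "model_tag"]


def _imputed_dosage(geno: GenotypeMatrix) -> np.ndarray:
    """Float dosage with per-marker mean imputation of missing calls."""
    d = geno.dosage.astype(float)
    miss = geno.dosage == MISSING
    if miss.any():
        col_mean = np.where(
            miss.all(axis=0), 0.0,
            np.nanmean(np.where(miss, np.nan, d), axis=0),
        )
        d = np.where(miss, col_mean[None, :], d)
    return d


def compute_kinship(geno: GenotypeMatrix) -> np.ndarray:
    """VanRaden genomic relationship matrix.

    Centered dosages W = D - 2p scaled by 2 * sum p(1-p); missing dosages
    mean-imputed per marker; monomorphic markers skipped.
    """
    if geno.n_samples < 2:
        raise ValueError("kinship needs >= 2 samples")
    d = _imputed_dosage(geno)
    p = d.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("kinship needs >= 1 polymorphic marker")
    w = d[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    return (w @ w.T) / denom


def compute_pcs(geno: GenotypeMatrix, q: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Top-q principal component scores of the centered dosage matrix.

    Returns (scores, eigenvalues); scores has shape (n_samples, q), columns
    ordered by decreasing eigenvalue, sign fixed so each component's
    largest-magnitude loading is positive.
    """
    if q >= geno.n_samples:
        raise ValueError(f"q={q} must be < n_samples={geno.n_samples}")
    d = _imputed_dosage(geno)
    d = d - d.mean(axis=0)
    u, s, vt = np.linalg.svd(d, full_matrices=False)
    eigvals = s**2 / (geno.n_samples - 1)
    scores = u[:, :q] * s[:q]
    for k in range(q):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            scores[:, k] *= -1.0
    return scores, eigvals[:q]


def _reml_loglik(log_delta: float, s: np.ndarray, yr: np.ndarray, xr: np.ndarray) -> float:
    """Restricted log-likelihood at delta = exp(log_delta) in the rotated frame."""
    delta = np.exp(log_delta)
    n, p = xr.shape
    w = 1.0 / (s + delta)
    xtwx = (xr * w[:, None]).T @ xr
    xtwy = (xr * w[:, None]).T @ yr
    beta = np.linalg.solve(xtwx, xtwy)
    resid = yr - xr @ beta
    rss = float(np.sum(w * resid**2))
    sigma2 = rss / (n - p)
    _, ld_xtwx = np.linalg.slogdet(xtwx)
    _, ld_xtx = np.linalg.slogdet(xr.T @ xr)
    return -0.5 * (
        (n - p) * (np.log(2 * np.pi * sigma2) + 1)
        + float(np.sum(np.log(s + delta)))
        + ld_xtwx
        - ld_xtx
    )


def fit_null_model(y: np.ndarray, K: np.ndarray, X: np.ndarray | None = None) -> MixedModelFit:
    """REML fit of the variance components by 1-D optimization over delta.

    ``X`` defaults to an intercept; pass intercept + PCs for the standard
    scan. The kinship is eigendecomposed once and cached in the fit.
    """
    y = np.asarray(y, float)
    n = len(y)
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix X is rank deficient")

    s, u = np.linalg.eigh(K)
    s = np.clip(s, 0.0, None)
    yr = u.T @ y
    xr = u.T @ X

    grid = np.linspace(np.log(1e-5), np.log(1e5), 60)
    lls = np.array([_reml_loglik(g, s, yr, xr) for g in grid])
    if not np.all(np.isfinite(lls)):
        raise ValueError("non-finite restricted likelihood; check covariates for singularity")
    k = int(np.argmax(lls))
    lo, hi = grid[max(0, k - 1)], grid[min(len(grid) - 1, k + 1)]
    res = optimize.minimize_scalar(
        lambda g: -_reml_loglik(g, s, yr, xr), bounds=(lo, hi), method="bounded"
    )
    log_delta = float(res.x) if -res.fun >= lls[k] else float(grid[k])
    delta = float(np.exp(log_delta))

    w = 1.0 / (s + delta)
    xtwx = (xr * w[:, None]).T @ xr
    beta = np.linalg.solve(xtwx, (xr * w[:, None]).T @ yr)
    rss = float(np.sum(w * (yr - xr @ beta) ** 2))
    sigma2_g = rss / (n - X.shape[1])
    return MixedModelFit(
        sigma2_g=sigma2_g,
        sigma2_e=delta * sigma2_g,
        delta=delta,
        eigenvalues=s,
        rotation=u,
        X=X,
        y=y,
        reml_loglik=float(_reml_loglik(log_delta, s, yr, xr)),
    )


def scan_markers(
    geno: GenotypeMatrix,
    y: np.ndarray,
    fit: MixedModelFit,
    cofactors: list[int] | None = None,
    model_tag: str = "single-locus",
) -> pd.DataFrame:
    """GLS test of each marker added to the covariates under the null fit.

    Cofactor markers enter the fixed design and are excluded from their
    own test (missing p). Markers collinear with the covariates or with
    zero variance get missing results, never p = 1.
    """
    cofactors = list(cofactors or [])
    d = _imputed_dosage(geno)
    u, s, delta = fit.rotation, fit.eigenvalues, fit.delta
    sw = 1.0 / np.sqrt(s + delta)

    Xfull = fit.X if not cofactors else np.column_stack([fit.X, d[:, cofactors]])
    xw = (u.T @ Xfull) * sw[:, None]
    yw = (u.T @ np.asarray(y, float)) * sw
    gw = (u.T @ d) * sw[:, None]

    q, _ = np.linalg.qr(xw)
    ry = yw - q @ (q.T @ yw)
    rg = gw - q @ (q.T @ gw)

    n, p = xw.shape
    df = n - p - 1
    gtg = np.einsum("ij,ij->j", rg, rg)
    gty = rg.T @ ry
    yty = float(ry @ ry)

    with np.errstate(divide="ignore", invalid="ignore"):
        beta = gty / gtg
        rss = yty - beta * gty
        sigma2 = rss / df
        se = np.sqrt(sigma2 / gtg)
        tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)

    # invalidate degenerate tests: zero variance or collinear with covariates
    scale = float(np.max(gtg)) if gtg.size else 1.0
    bad = ~np.isfinite(tstat) | (gtg <= 1e-10 * max(scale, 1.0))
    bad[cofactors] = True
    raw_var = geno.dosage.astype(float).var(axis=0)
    bad |= raw_var == 0
    for arr in (beta, se):
        arr[bad] = np.nan
    pvals[bad] = np.nan

    out = geno.markers[["chrom", "pos", "id"]].copy()
    out["beta"] = beta
    out["se"] = se
    out["p"] = pvals
    with np.errstate(divide="ignore"):
        out["minus_log10_p"] = -np.log10(pvals)
    out["n"] = n
    out["maf"] = geno.maf()
    out["model_tag"] = model_tag
    return out


def mlmm_scan(
    geno: GenotypeMatrix,
    y: np.ndarray,
    K: np.ndarray,
    X: np.ndarray | None = None,
    max_steps: int = 10,
    maf_min: float = 0.05,
) -> pd.DataFrame:
    """Multi-locus forward-selection scan with extended-BIC model choice.

    At each step the most significant marker becomes a fixed cofactor,
    delta is refit, and the scan repeats; stops at ``max_steps`` or when
    the pseudo-heritability drops to <= 0.01. The returned scan is the one
    from the step minimizing the extended BIC
    ``n log(sigma2_hat) + k (log n + 2 log m)``; its cofactor ids are in
    ``.attrs['cofactors']``.
    """
    if max_steps < 0:
        raise ValueError("max_steps must be >= 0")
    keep = geno.maf() >= maf_min
    if maf_min > 0 and not keep.all():
        geno = geno.subset_markers(np.flatnonzero(keep))
    y = np.asarray(y, float)
    n = geno.n_samples
    m = geno.n_markers
    d = _imputed_dosage(geno)

    cofactors: list[int] = []
    steps: list[tuple[float, pd.DataFrame, list[int]]] = []
    for k in range(max_steps + 1):
        Xstep = np.ones((n, 1)) if X is None else np.asarray(X, float)
        if cofactors:
            Xstep = np.column_stack([Xstep, d[:, cofactors]])
        fit = fit_null_model(y, K, Xstep)
        # scan uses the base covariates; cofactors already folded into Xstep
        scan_fit = MixedModelFit(
            sigma2_g=fit.sigma2_g, sigma2_e=fit.sigma2_e, delta=fit.delta,
            eigenvalues=fit.eigenvalues, rotation=fit.rotation,
            X=Xstep, y=y, reml_loglik=fit.reml_loglik,
        )
        tag = "single-locus" if k == 0 else f"step-{k}"
        res = scan_markers(geno, y, scan_fit, cofactors=cofactors, model_tag=tag)

        # extended BIC of the cofactor model itself (marker not included)
        sw = 1.0 / np.sqrt(fit.eigenvalues + fit.delta)
        xw = (fit.rotation.T @ Xstep) * sw[:, None]
        yw = (fit.rotation.T @ y) * sw
        beta, rss_arr, *_ = np.linalg.lstsq(xw, yw, rcond=None)
        rss = float(rss_arr[0]) if len(rss_arr) else float(np.sum((yw - xw @ beta) ** 2))
        ebic = n * np.log(rss / n) + len(cofactors) * (np.log(n) + 2.0 * np.log(max(m, 2)))
        steps.append((ebic, res, list(cofactors)))

        if k == max_steps or fit.pseudo_heritability <= 0.01:
            break
        pcand = res["p"].to_numpy()
        if not np.isfinite(pcand).any():
            break
        cofactors.append(int(np.nanargmin(pcand)))

    best = min(range(len(steps)), key=lambda i: steps[i][0])
    _, res, cof = steps[best]
    res.attrs["cofactors"] = [geno.markers["id"].iloc[c] for c in cof]
    res.attrs["n_steps_evaluated"] = len(steps)
    return res


def association_scan(
    geno: GenotypeMatrix,
    y: np.ndarray,
    n_pcs: int = 10,
    maf_min: float = 0.05,
    K: np.ndarray | None = None,
    multi_locus: bool = True,
    max_steps: int = 10,
    loco: bool = False,
) -> pd.DataFrame:
    """Convenience wrapper: kinship + PCs + (multi-locus) mixed-model scan.

    ``loco=True`` uses a leave-one-chromosome-out kinship for the
    single-locus scan: markers on the tested chromosome are excluded from
    the relationship matrix, avoiding proximal contamination (the tested
    locus absorbing itself through the polygenic term). Ignored for the
    multi-locus scan, which manages its cofactors explicitly.
    """
    keep = geno.maf() >= maf_min
    geno_f = geno.subset_markers(np.flatnonzero(keep)) if not keep.all() else geno
    X = np.ones((geno_f.n_samples, 1))
    if n_pcs > 0:
        pcs, _ = compute_pcs(geno_f, q=n_pcs)
        X = np.column_stack([X, pcs])
    if multi_locus:
        if K is None:
            K = compute_kinship(geno_f)
        return mlmm_scan(geno_f, y, K, X, max_steps=max_steps, maf_min=0.0)
    if loco and geno_f.markers["chrom"].nunique() > 1:
        parts = []
        chroms = geno_f.markers["chrom"].to_numpy()
        for chrom in dict.fromkeys(chroms):
            on = chroms == chrom
            K_off = compute_kinship(geno_f.subset_markers(np.flatnonzero(~on)))
            fit = fit_null_model(y, K_off, X)
            sub = geno_f.subset_markers(np.flatnonzero(on))
            parts.append(scan_markers(sub, y, fit))
        out = pd.concat(parts, ignore_index=True)
        out["model_tag"] = "single-locus-loco"
        return out
    if K is None:
        K = compute_kinship(geno_f)
    fit = fit_null_model(y, K, X)
    return scan_markers(geno_f, y, fit)


__all__ = [
    "ASSOC_COLUMNS",
    "compute_kinship",
    "compute_pcs",
    "fit_null_model",
    "scan_markers",
    "mlmm_scan",
    "association_scan",
]
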