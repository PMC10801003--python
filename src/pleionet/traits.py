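"""Derived traits, BLUEs, broad-sense heritability and trait summaries.

Phenotypes arrive as a long table (sample, env, rep, trait, value) from
multi-environment replicated trials. Per-trait processing:

* compound traits: pod range PR = (PH - LPH) / PH and internode length
  IL = PH / NN, computed per observation;
* BLUE: genotype best linear unbiased estimate across environments from a
  mixed model with genotype fixed (cell-mean coding) and environment
  random, solved by the Henderson mixed-model equations; a single
  environment collapses to per-sample means;
* broad-sense heritability on an entry-mean basis from a two-way ANOVA
  variance partition (genotype, environment, GxE, residual) by the
  expected-mean-squares method of moments, negative components truncated
  at zero:

      H2 = s2_G / (s2_G + s2_GxE / E + s2_res / (E R)).

The EMS formulas are exact for balanced designs and adequate for the
near-balanced trials they are meant for; no REML iteration is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import validate_phenotypes

logger = logging.getLogger(__name__)


@dataclass
class TraitSummary:
    """Per-trait BLUEs, variance components and derived statistics."""

    trait: str
    blue: pd.Series  # indexed by sample
    H2: float
    cv_percent: float  # CV% over BLUEs
    cv_percent_raw: float  # CV% over raw observations
    variance_components: tuple[float, float, float, float]  # G, E, GxE, residual


def derive_traits(pheno: pd.DataFrame) -> pd.DataFrame:
    """Add pod range and internode length records derived per observation.

    PR = (PH - LPH) / PH and IL = PH / NN for every (sample, env, rep)
    where the parent traits are present. Records where PH or NN is zero
    yield a missing value and a logged warning. Existing records are
    returned untouched, with the derived records appended.
    """
    validate_phenotypes(pheno)
    wide = pheno.pivot_table(
        index=["sample", "env", "rep"], columns="trait", values="value", aggfunc="first"
    )
    out = [pheno]
    for name, formula, needed, denom_col in (
        ("PR", lambda w: (w["PH"] - w["LPH"]) / w["PH"], ("PH", "LPH"), "PH"),
        ("IL", lambda w: w["PH"] / w["NN"], ("PH", "NN"), "NN"),
    ):
        if name in wide.columns or not all(c in wide.columns for c in needed):
            continue
        present = wide[list(needed)].notna().all(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = formula(wide)
        vals = vals.mask(~np.isfinite(vals))
        n_bad = int((present & (wide[denom_col] == 0)).sum())
        if n_bad:
            logger.warning("derive_traits: %d records with zero %s marked missing for %s",
                           n_bad, denom_col, name)
        rec = vals[present].reset_index()
        rec.columns = ["sample", "env", "rep", "value"]
        rec["trait"] = name
        out.append(rec[["sample", "env", "rep", "trait", "value"]])
    return pd.concat(out, ignore_index=True)


def _trait_table(pheno: pd.DataFrame, trait: str) -> pd.DataFrame:
    sub = pheno.loc[(pheno["trait"] == trait) & pheno["value"].notna()]
    if sub.empty:
        raise ValueError(f"no observations for trait {trait!r}")
    return sub


def compute_blue(pheno: pd.DataFrame, trait: str) -> pd.Series:
    """Genotype BLUEs for one trait across environments.

    Fits value = mu + genotype_i + env_j + residual with genotype fixed
    and environment random, returning the genotype estimate per sample.
    Variance components for the environment shrinkage come from the same
    ANOVA partition as :func:`estimate_h2`. With a single environment the
    model collapses to per-sample means. Samples without observations are
    dropped with a warning, never imputed.
    """
    sub = _trait_table(pheno, trait)
    all_samples = pheno.loc[pheno["trait"] == trait, "sample"].unique()
    dropped = set(all_samples) - set(sub["sample"])
    if dropped:
        logger.warning("compute_blue(%s): dropping %d samples with no observations",
                       trait, len(dropped))

    samples = pd.Index(sorted(sub["sample"].unique()))
    envs = pd.Index(sorted(sub["env"].unique()))
    y = sub["value"].to_numpy(float)
    gi = samples.get_indexer(sub["sample"])
    ej = envs.get_indexer(sub["env"])

    if len(envs) == 1:
        means = sub.groupby("sample")["value"].mean()
        return means.reindex(samples).rename(trait)

    comps = _variance_components(sub)
    # lam -> 0 leaves genotype and environment effects confounded; a tiny
    # floor keeps the system nonsingular without noticeable shrinkage
    lam = comps["res"] / comps["env"] if comps["env"] > 0 else 1e8
    lam = max(lam, 1e-8)

    G, E = len(samples), len(envs)
    n_obs = len(y)
    # Henderson equations with X = genotype indicators, Z = env indicators
    XtX = np.bincount(gi, minlength=G).astype(float)
    ZtZ = np.bincount(ej, minlength=E).astype(float)
    XtZ = np.zeros((G, E))
    np.add.at(XtZ, (gi, ej), 1.0)
    Xty = np.bincount(gi, weights=y, minlength=G)
    Zty = np.bincount(ej, weights=y, minlength=E)

    A = np.zeros((G + E, G + E))
    A[:G, :G] = np.diag(XtX)
    A[:G, G:] = XtZ
    A[G:, :G] = XtZ.T
    A[G:, G:] = np.diag(ZtZ + lam)
    rhs = np.concatenate([Xty, Zty])
    sol = np.linalg.solve(A, rhs)
    return pd.Series(sol[:G], index=samples, name=trait)


def _variance_components(sub: pd.DataFrame) -> dict[str, float]:
    """EMS method-of-moments variance partition on (near-)balanced data.

    Returns genotype, environment, GxE and residual components (negatives
    truncated at 0) plus the design sizes used.
    """
    cell = sub.groupby(["sample", "env"])["value"]
    cell_mean = cell.mean().unstack()  # G x E, NaN for empty cells
    cell_n = cell.size().unstack().fillna(0)
    G = cell_mean.shape[0]
    E = cell_mean.shape[1]
    R = float(cell_n.to_numpy()[cell_n.to_numpy() > 0].mean())

    if G < 2:
        raise ValueError("variance partition needs >= 2 genotypes")

    gm = np.nanmean(cell_mean.to_numpy())
    row = np.nanmean(cell_mean.to_numpy(), axis=1)
    col = np.nanmean(cell_mean.to_numpy(), axis=0)

    ms_g = E * R * np.nansum((row - gm) ** 2) / (G - 1) if G > 1 else 0.0
    ms_e = G * R * np.nansum((col - gm) ** 2) / (E - 1) if E > 1 else 0.0
    inter = cell_mean.to_numpy() - row[:, None] - col[None, :] + gm
    df_int = (G - 1) * (E - 1)
    ms_gxe = R * np.nansum(inter**2) / df_int if df_int > 0 else 0.0

    # within-cell residual
    resid_ss = float(((sub["value"] - cell.transform("mean")) ** 2).sum())
    df_res = int((cell_n.to_numpy() - 1).clip(min=0).sum())
    ms_res = resid_ss / df_res if df_res > 0 else np.nan

    if E == 1:
        s_res = ms_res if df_res > 0 else 0.0
        s_g = max(0.0, (ms_g - s_res) / R)
        return {"g": s_g, "env": 0.0, "gxe": 0.0, "res": s_res, "E": E, "R": R}
    if df_res == 0:
        # single replicate: interaction mean square is the error term
        s_res = ms_gxe
        s_g = max(0.0, (ms_g - s_res) / (E * R))
        s_env = max(0.0, (ms_e - s_res) / (G * R))
        return {"g": s_g, "env": s_env, "gxe": 0.0, "res": s_res, "E": E, "R": R}

    s_res = ms_res
    s_gxe = max(0.0, (ms_gxe - ms_res) / R)
    s_g = max(0.0, (ms_g - ms_gxe) / (E * R))
    s_env = max(0.0, (ms_e - ms_gxe) / (G * R))
    return {"g": s_g, "env": s_env, "gxe": s_gxe, "res": s_res, "E": E, "R": R}


def estimate_h2(pheno: pd.DataFrame, trait: str) -> TraitSummary:
    """Entry-mean broad-sense heritability and trait summary for one trait.

    Requires >= 2 environments and >= 2 replicates for the full variance
    partition; degrades to reduced formulas otherwise (see
    :func:`_variance_components`).
    """
    sub = _trait_table(pheno, trait)
    if sub["sample"].nunique() < 2:
        raise ValueError(f"trait {trait!r}: heritability needs >= 2 genotypes")
    comps = _variance_components(sub)
    E, R = comps["E"], comps["R"]
    denom = comps["g"] + comps["gxe"] / E + comps["res"] / (E * R)
    h2 = comps["g"] / denom if denom > 0 else 0.0

    blue = compute_blue(pheno, trait)
    cv_blue = 100.0 * blue.std(ddof=1) / abs(blue.mean()) if blue.mean() != 0 else np.nan
    raw = sub["value"]
    cv_raw = 100.0 * raw.std(ddof=1) / abs(raw.mean()) if raw.mean() != 0 else np.nan
    return TraitSummary(
        trait=trait,
        blue=blue,
        H2=float(np.clip(h2, 0.0, 1.0)),
        cv_percent=float(cv_blue),
        cv_percent_raw=float(cv_raw),
        variance_components=(comps["g"], comps["env"], comps["gxe"], comps["res"]),
    )


def blue_matrix(pheno: pd.DataFrame, traits: list[str] | None = None) -> pd.DataFrame:
    """Sample-by-trait matrix of BLUEs."""
    traits = traits or sorted(pheno["trait"].unique())
    return pd.DataFrame({t: compute_blue(pheno, t) for t in traits})


def trait_correlations(blues: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between traits on pairwise-complete samples.

    Zero-variance traits yield missing correlations.
    """
    return blues.corr(method="pearson", min_periods=3)


def era_trend(blues: pd.Series, release_years: pd.Series) -> tuple[float, float, float]:
    """OLS of BLUE on release year; returns (slope, R2, two-sided p)."""
    joined = pd.concat([blues.rename("y"), release_years.rename("year")], axis=1).dropna()
    if len(joined) < 3:
        raise ValueError("era trend needs >= 3 samples with release years")
    if joined["year"].nunique() < 2:
        raise ValueError("all release years identical: degenerate regression design")
    if joined["y"].nunique() == 1:
        return 0.0, 0.0, 1.0
    res = stats.linregress(joined["year"], joined["y"])
    return float(res.slope), float(res.rvalue**2), float(res.pvalue)


__all__ = [
    "TraitSummary",
    "derive_traits",
    "compute_blue",
    "estimate_h2",
    "blue_matrix",
    "trait_correlations",
    "era_trend",
]
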