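"""Greedy p-value/LD clumping of association signals into QTL regions.

Follows plink --clump semantics: markers are visited in ascending p-value
order; each unassigned marker with p <= p1 seeds a clump (index SNP) and
absorbs unassigned markers within the distance window that pass the
member threshold p2 and are in LD (r2 >= r2_min) with the index. Clumps
whose interval holds fewer than ``singleton_min_snps`` markers below
``singleton_p`` are dropped as singletons; survivors are promoted to QTL
regions spanning their member positions.

LD here is the squared Pearson correlation of allele dosages (composite
LD). For the near-fully homozygous inbred panels this pipeline targets it
coincides with the haplotype r2 a phased estimator would report.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import MISSING, Clump, ClumpParams, GenotypeMatrix, QTLRegion

logger = logging.getLogger(__name__)


def ld_r2(geno: GenotypeMatrix, i: int, j: int) -> float:
    """Squared Pearson correlation of dosages at markers i and j.

    Computed over samples non-missing at both markers; returns NaN when
    either marker is monomorphic in the shared samples.
    """
    gi = geno.dosage[:, i]
    gj = geno.dosage[:, j]
    ok = (gi != MISSING) & (gj != MISSING)
    a, b = gi[ok].astype(float), gj[ok].astype(float)
    if len(a) < 2 or a.var() == 0 or b.var() == 0:
        return float("nan")
    # elementwise products commute, so this is exactly symmetric in (i, j)
    da, db = a - a.mean(), b - b.mean()
    cov = float(np.sum(da * db))
    denom = float(np.sum(da * da)) * float(np.sum(db * db))
    return cov * cov / denom


def pairwise_r2(geno: GenotypeMatrix, idx1: np.ndarray, idx2: np.ndarray) -> np.ndarray:
    """r2 matrix between two marker index sets (NaN for monomorphic pairs)."""
    idx1 = np.asarray(idx1, int)
    idx2 = np.asarray(idx2, int)
    if (geno.dosage[:, np.concatenate([idx1, idx2])] == MISSING).any():
        out = np.empty((len(idx1), len(idx2)))
        for a, i in enumerate(idx1):
            for b, j in enumerate(idx2):
                out[a, b] = ld_r2(geno, int(i), int(j))
        return out
    d1 = geno.dosage[:, idx1].astype(float)
    d2 = geno.dosage[:, idx2].astype(float)
    d1 = d1 - d1.mean(axis=0)
    d2 = d2 - d2.mean(axis=0)
    s1 = np.sqrt((d1**2).sum(axis=0))
    s2 = np.sqrt((d2**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (d1.T @ d2) / np.outer(s1, s2)
    r2 = r**2
    r2[s1 == 0, :] = np.nan
    r2[:, s2 == 0] = np.nan
    return r2


def clump(
    assoc: pd.DataFrame,
    geno: GenotypeMatrix,
    params: ClumpParams = ClumpParams(),
) -> list[Clump]:
    """Greedy clumping of one trait's association results.

    Returns raw clumps (marker indices into ``geno``); an empty list when
    no marker passes p1. Ties in p are broken by genomic order for
    determinism.
    """
    id_to_idx = {mid: k for k, mid in enumerate(geno.markers["id"])}
    rows = assoc.loc[assoc["p"].notna() & assoc["id"].isin(id_to_idx)]
    gidx = rows["id"].map(id_to_idx).to_numpy(int)
    pvals = rows["p"].to_numpy(float)
    chrom = geno.markers["chrom"].to_numpy()
    pos = geno.markers["pos"].to_numpy()

    order = np.lexsort((pos[gidx], chrom[gidx].astype(str), pvals))
    window = params.window_kb * 1000.0
    assigned: set[int] = set()
    trait = str(assoc.attrs.get("trait", ""))
    p_of = dict(zip(gidx.tolist(), pvals.tolist()))

    clumps: list[Clump] = []
    for k in order:
        idx = int(gidx[k])
        if pvals[k] > params.p1:
            break
        if idx in assigned:
            continue
        members = [idx]
        assigned.add(idx)
        near = (
            (chrom[gidx] == chrom[idx])
            & (np.abs(pos[gidx] - pos[idx]) <= window)
            & (pvals <= params.p2)
        )
        for cand in gidx[near]:
            cand = int(cand)
            if cand in assigned:
                continue
            r2 = ld_r2(geno, idx, cand)
            if np.isfinite(r2) and r2 >= params.r2_min:
                members.append(cand)
                assigned.add(cand)
        members.sort(key=lambda mi: (pos[mi]))
        clumps.append(Clump(index_marker=idx, members=members, trait=trait))
    # deterministic report order: by index-marker p
    clumps.sort(key=lambda c: p_of[c.index_marker])
    return clumps


def apply_singleton_filter(
    clumps: list[Clump],
    assoc: pd.DataFrame,
    geno: GenotypeMatrix,
    params: ClumpParams = ClumpParams(),
    trait: str | None = None,
    environment: str | None = None,
) -> list[QTLRegion]:
    """Drop singleton clumps and promote survivors to QTL regions.

    A clump is a singleton when its interval (span of member positions)
    contains fewer than ``singleton_min_snps`` tested markers with
    p < ``singleton_p``. Survivors become 1-based inclusive QTL regions.
    """
    id_to_idx = {mid: k for k, mid in enumerate(geno.markers["id"])}
    rows = assoc.loc[assoc["p"].notna() & assoc["id"].isin(id_to_idx)]
    a_idx = rows["id"].map(id_to_idx).to_numpy(int)
    a_p = rows["p"].to_numpy(float)
    pos = geno.markers["pos"].to_numpy()
    chrom = geno.markers["chrom"].to_numpy()
    p_by_idx = dict(zip(a_idx.tolist(), a_p.tolist()))

    regions: list[QTLRegion] = []
    n_dropped = 0
    for c in clumps:
        mpos = pos[c.members]
        start, end = int(mpos.min()), int(mpos.max())
        ch = chrom[c.index_marker]
        in_interval = (chrom[a_idx] == ch) & (pos[a_idx] >= start) & (pos[a_idx] <= end)
        n_support = int(np.sum(in_interval & (a_p < params.singleton_p)))
        if n_support < params.singleton_min_snps:
            n_dropped += 1
            continue
        member_p = [p_by_idx[m] for m in c.members]
        tr = trait if trait is not None else c.trait
        regions.append(QTLRegion(
            id=f"q{tr}_{len(regions) + 1}",
            trait=tr,
            chrom=str(ch),
            start=start,
            end=end,
            index_marker=str(geno.markers["id"].iloc[c.index_marker]),
            member_markers=[str(geno.markers["id"].iloc[m]) for m in c.members],
            min_p=float(min(member_p)),
            environments=(environment,) if environment else (),
        ))
    if n_dropped:
        logger.info("singleton filter dropped %d of %d clumps", n_dropped, len(clumps))
    return regions


def merge_environment_regions(regions: list[QTLRegion]) -> list[QTLRegion]:
    """Merge same-trait regions from different datasets by interval overlap.

    Regions of one trait detected in several environments (or in the BLUE
    dataset) that share >= 1 bp are collapsed into one region spanning
    their union, recording the list of environments observed.
    """
    out: list[QTLRegion] = []
    by_trait: dict[str, list[QTLRegion]] = {}
    for r in regions:
        by_trait.setdefault(r.trait, []).append(r)
    for trait, regs in by_trait.items():
        regs = sorted(regs, key=lambda r: (r.chrom, r.start, r.end))
        merged: list[QTLRegion] = []
        for r in regs:
            if merged and merged[-1].chrom == r.chrom and r.start <= merged[-1].end:
                last = merged[-1]
                envs = tuple(dict.fromkeys(last.environments + r.environments))
                keep_best = last if last.min_p <= r.min_p else r
                merged[-1] = QTLRegion(
                    id=last.id,
                    trait=trait,
                    chrom=last.chrom,
                    start=last.start,
                    end=max(last.end, r.end),
                    index_marker=keep_best.index_marker,
                    member_markers=list(dict.fromkeys(last.member_markers + r.member_markers)),
                    min_p=min(last.min_p, r.min_p),
                    environments=envs,
                )
            else:
                merged.append(r)
        for k, r in enumerate(merged, 1):
            r.id = f"q{trait}_{k}"
        out.extend(merged)
    return out


def colocalize(
    qtls: list[QTLRegion],
    catalog: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Overlap QTL regions with a known-QTL catalog (1-based inclusive).

    ``catalog`` needs columns chrom, start, end, name. Returns a per-QTL
    report (one row per QTL with the overlapping catalog names) and
    summary counts of co-located vs novel regions. Catalog entries on
    chromosomes absent from the QTL set are skipped with a warning.
    """
    known_chroms = {q.chrom for q in qtls}
    unknown = set(catalog["chrom"].astype(str)) - known_chroms
    if unknown:
        logger.warning("colocalize: skipping catalog entries on unknown chromosomes %s",
                       sorted(unknown))
    cat = catalog.loc[catalog["chrom"].astype(str).isin(known_chroms)]

    rows = []
    for q in qtls:
        hits = cat.loc[
            (cat["chrom"].astype(str) == q.chrom)
            & (cat["start"] <= q.end)
            & (cat["end"] >= q.start),
            "name",
        ].tolist()
        rows.append({
            "qtl": q.id, "trait": q.trait, "chrom": q.chrom,
            "start": q.start, "end": q.end,
            "known_loci": ",".join(hits), "co_located": bool(hits),
        })
    report = pd.DataFrame(rows)
    n_co = int(report["co_located"].sum()) if len(report) else 0
    summary = {"co_located": n_co, "novel": len(qtls) - n_co, "total": len(qtls)}
    return report, summary


__all__ = [
    "ld_r2",
    "pairwise_r2",
    "clump",
    "apply_singleton_filter",
    "merge_environment_regions",
    "colocalize",
]
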