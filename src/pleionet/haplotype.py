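"""Gene-region haplotype calling and haplotype-phenotype association.

Candidate genes inside QTL or hub intervals are screened by grouping the
panel into haplotypes — samples sharing an identical dosage combination
over all variants in the gene body plus its 2-kb upstream promoter
region — and testing the phenotype (BLUEs by default) across groups:
a two-sided rank-sum test for two groups, a one-way ANOVA F-test for
three or more. Rare haplotypes (group size below ``min_count``, default
10) are excluded from testing. No multiple-testing correction is applied
by default; a Benjamini-Hochberg option is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneModel, GenotypeMatrix, HaplotypeGrouping

logger = logging.getLogger(__name__)


def gene_region(gene: GeneModel, upstream_bp: int = 2000,
                chrom_length: int | None = None) -> tuple[str, int, int]:
    """Gene span extended by ``upstream_bp`` on the promoter side.

    [start - upstream, end] for + strand, [start, end + upstream] for -
    strand, clipped to [1, chrom_length].
    """
    if gene.strand == "+":
        start, end = gene.start - upstream_bp, gene.end
    else:
        start, end = gene.start, gene.end + upstream_bp
    start = max(1, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return gene.chrom, start, end


def call_haplotypes(
    geno: GenotypeMatrix,
    region: tuple[str, int, int],
    min_count: int = 10,
) -> HaplotypeGrouping:
    """Group samples by their exact dosage combination over region variants.

    Labels are H1, H2, ... in descending group size (ties broken by first
    occurrence). Groups smaller than ``min_count`` are excluded from
    testing but still labelled. A region without variants yields a single
    untestable group.
    """
    chrom, start, end = region
    idx = geno.markers_in_interval(chrom, start, end)
    variant_ids = [str(v) for v in geno.markers["id"].iloc[idx]]
    if len(idx) == 0:
        labels = {s: "H1" for s in geno.samples}
        return HaplotypeGrouping(region=region, variant_ids=[], labels=labels,
                                 group_sizes={"H1": geno.n_samples},
                                 excluded_rare=0, testable=False)

    keys = ["/".join(map(str, row)) for row in geno.dosage[:, idx]]
    counts: dict[str, int] = {}
    first_seen: dict[str, int] = {}
    for i, k in enumerate(keys):
        counts[k] = counts.get(k, 0) + 1
        first_seen.setdefault(k, i)
    ranked = sorted(counts, key=lambda k: (-counts[k], first_seen[k]))
    name_of = {k: f"H{r + 1}" for r, k in enumerate(ranked)}
    labels = {s: name_of[k] for s, k in zip(geno.samples, keys)}
    group_sizes = {name_of[k]: counts[k] for k in ranked}
    retained = [h for h, n in group_sizes.items() if n >= min_count]
    excluded = sum(n for h, n in group_sizes.items() if n < min_count)
    return HaplotypeGrouping(
        region=region, variant_ids=variant_ids, labels=labels,
        group_sizes=group_sizes, excluded_rare=excluded,
        testable=len(retained) >= 2,
    )


@dataclass
class HaplotypeTest:
    p: float
    test: str  # "ranksum" or "anova"
    group_means: dict[str, float]
    group_n: dict[str, int]


def test_haplotype_trait(
    grouping: HaplotypeGrouping,
    blue: pd.Series,
    min_count: int = 10,
) -> HaplotypeTest | None:
    """Test phenotype differences between retained haplotype groups.

    Two groups: two-sided Wilcoxon rank-sum; three or more: one-way ANOVA
    F-test. Returns None when fewer than two groups with >= 2 phenotyped
    samples remain (untestable, never p = 1).
    """
    values: dict[str, np.ndarray] = {}
    for h, n in grouping.group_sizes.items():
        if n < min_count:
            continue
        members = [s for s, lab in grouping.labels.items() if lab == h]
        v = blue.reindex(members).dropna().to_numpy(float)
        if len(v) >= 2:
            values[h] = v
    if len(values) < 2:
        return None
    groups = [values[h] for h in sorted(values)]
    if len(groups) == 2:
        stat = stats.ranksums(groups[0], groups[1])
        test = "ranksum"
    else:
        stat = stats.f_oneway(*groups)
        test = "anova"
    return HaplotypeTest(
        p=float(stat.pvalue),
        test=test,
        group_means={h: float(np.mean(values[h])) for h in sorted(values)},
        group_n={h: len(values[h]) for h in sorted(values)},
    )


def genes_in_regions(genes: list[GeneModel], regions: list[tuple[str, int, int]]) -> list[GeneModel]:
    """Genes whose span overlaps any of the given 1-based inclusive intervals."""
    out = []
    for g in genes:
        for chrom, start, end in regions:
            if g.chrom == chrom and g.start <= end and g.end >= start:
                out.append(g)
                break
    return out


def candidate_gene_screen(
    regions: dict[str, list[tuple[str, int, int]]],
    genes: list[GeneModel],
    geno: GenotypeMatrix,
    blues: pd.DataFrame,
    alpha: float = 0.05,
    upstream_bp: int = 2000,
    min_count: int = 10,
    bh_correct: bool = False,
) -> tuple[pd.DataFrame, dict[str, set[str]], set[str]]:
    """Haplotype-test every gene in each trait's regions; intersect hits.

    ``regions`` maps trait -> list of (chrom, start, end); ``blues`` is
    the sample-by-trait BLUE matrix. Returns (per-test results table,
    per-trait significant gene sets, intersection across traits).
    ``bh_correct=True`` applies Benjamini-Hochberg within each trait
    before thresholding at ``alpha``.
    """
    rows = []
    sig: dict[str, set[str]] = {}
    for trait, intervals in regions.items():
        blue = blues[trait]
        trait_rows = []
        for gene in genes_in_regions(genes, intervals):
            grouping = call_haplotypes(geno, gene_region(gene, upstream_bp), min_count)
            result = test_haplotype_trait(grouping, blue, min_count)
            trait_rows.append({
                "gene": gene.gene_id, "trait": trait,
                "n_groups": len([n for n in grouping.group_sizes.values() if n >= min_count]),
                "n_variants": len(grouping.variant_ids),
                "p": result.p if result else np.nan,
                "test": result.test if result else "untestable",
            })
        tdf = pd.DataFrame(trait_rows,
                           columns=["gene", "trait", "n_groups", "n_variants", "p", "test"])
        pv = tdf["p"].to_numpy(float)
        if bh_correct and np.isfinite(pv).any():
            ok = np.isfinite(pv)
            adj = np.full_like(pv, np.nan)
            adj[ok] = stats.false_discovery_control(pv[ok], method="bh")
            tdf["p_adj"] = adj
            tdf["significant"] = tdf["p_adj"] < alpha
        else:
            tdf["significant"] = tdf["p"] < alpha
        sig[trait] = set(tdf.loc[tdf["significant"].fillna(False), "gene"])
        rows.append(tdf)
    results = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["gene", "trait", "n_groups", "n_variants", "p", "test", "significant"])
    traits = list(regions)
    intersection = set.intersection(*(sig[t] for t in traits)) if traits else set()
    return results, sig, intersection


__all__ = [
    "gene_region",
    "call_haplotypes",
    "HaplotypeTest",
    "test_haplotype_trait",
    "genes_in_regions",
    "candidate_gene_screen",
]
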