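"""End-to-end pipeline driver: simulate -> traits -> gwas -> clump -> network -> haplotype.

``PipelineConfig`` gathers every stage parameter; the defaults mirror the
standard analysis conventions this pipeline implements (clump p1=1e-5,
p2=1e-3, 455-kb window, Inter-LD threshold 0.4, 10 PCs, 2-kb upstream
promoter, genome-wide significance at -log10 p = 5). The resolved
configuration is serialized into the output directory, and every stage
table carries the config hash, so a run is reproducible from its outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import clumping as clump_mod
from . import gwas as gwas_mod
from . import haplotype as hap_mod
from . import io as io_mod
from . import network as net_mod
from . import simulate as sim_mod
from . import traits as traits_mod
from .datatypes import ClumpParams, GenotypeMatrix, SimConfig

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters of the pipeline driver."""

    # inputs (None -> simulate)
    vcf: str | None = None
    dosage_tsv: str | None = None
    marker_map: str | None = None
    phenotypes: str | None = None
    catalog: str | None = None
    gff3: str | None = None

    # simulation
    seed: int = 1
    n_samples: int = 300
    n_markers: int = 3000
    n_chromosomes: int = 3
    chrom_length_bp: int = 50_000_000
    n_env: int = 2
    n_rep: int = 3

    # gwas
    n_pcs: int = 10
    maf_min: float = 0.05
    multi_locus: bool = False
    max_steps: int = 10
    sig_log10p: float = 5.0

    # clump
    clump_p1: float = 1e-5
    clump_p2: float = 1e-3
    clump_kb: float = 455.0
    clump_r2: float = 0.5
    singleton_p: float = 2.5e-4
    singleton_min_snps: int = 5

    # network
    inter_ld_min: float = 0.4

    # haplotype
    upstream_bp: int = 2000
    hap_min_count: int = 10
    hap_alpha: float = 0.05

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def clump_params(self) -> ClumpParams:
        return ClumpParams(
            p1=self.clump_p1, p2=self.clump_p2, window_kb=self.clump_kb,
            r2_min=self.clump_r2, singleton_p=self.singleton_p,
            singleton_min_snps=self.singleton_min_snps,
        )


def _load_genotypes(config: PipelineConfig) -> GenotypeMatrix:
    if config.vcf:
        return io_mod.read_vcf(config.vcf)
    if config.dosage_tsv:
        if not config.marker_map:
            raise ValueError("dosage_tsv input requires marker_map")
        return io_mod.read_dosage_tsv(config.dosage_tsv, config.marker_map)
    sim = SimConfig(
        n_samples=config.n_samples,
        n_markers=config.n_markers,
        chrom_lengths=tuple(
            (f"Chr{i + 1}", config.chrom_length_bp) for i in range(config.n_chromosomes)
        ),
        seed=config.seed,
    )
    return sim_mod.simulate_genotypes(sim)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage, writing stage tables into ``outdir``.

    Returns a summary dict with the stage bookkeeping counts. A stage
    failure halts the run with the stage name and cause.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    (outdir / "config.json").write_text(json.dumps(config.to_dict(), indent=2) + "\n")
    summary: dict = {"config_hash": chash}

    def _stage(name, fn):
        try:
            logger.info("stage %s: starting", name)
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    # -- genotypes / phenotypes ------------------------------------------
    geno = _stage("genotypes", lambda: _load_genotypes(config))
    summary["n_samples"], summary["n_markers"] = geno.n_samples, geno.n_markers

    def _phenotypes():
        if config.phenotypes:
            return io_mod.read_phenotypes(config.phenotypes), None
        # plant two pleiotropic hubs mirroring the plant-height and seed
        # trait clusters, on different chromosomes where possible
        maf = geno.maf()
        pos = geno.markers["pos"].to_numpy()
        chroms = list(dict.fromkeys(geno.markers["chrom"]))
        hub_markers: dict[int, tuple[str, ...]] = {}
        for chrom, traits in zip(chroms, (("PH", "NN", "IL"), ("HSW", "SW", "SL"))):
            on = (geno.markers["chrom"] == chrom).to_numpy() & (maf >= 0.2)
            cand = np.flatnonzero(on)
            if cand.size:
                mid = pos[on].mean()
                hub_markers[int(cand[np.argmin(np.abs(pos[cand] - mid))])] = traits
        arch = sim_mod.random_architecture(
            geno, seed=config.seed + 1, hub_markers=hub_markers,
            n_env=config.n_env, n_rep=config.n_rep
        )
        pheno, truth = sim_mod.simulate_phenotypes(geno, arch, seed=config.seed + 2)
        io_mod.write_table(truth, outdir / "truth_qtls.tsv", "simulate", chash)
        return pheno, truth

    pheno, _ = _stage("phenotypes", _phenotypes)
    io_mod.write_dosage_tsv(geno, outdir / "genotypes")

    # -- traits -----------------------------------------------------------
    def _traits():
        full = traits_mod.derive_traits(pheno)
        io_mod.write_phenotypes(full, outdir / "phenotypes.tsv",
                                [f"stage: traits", f"config: {chash}"])
        trait_names = sorted(full["trait"].unique())
        summaries = {t: traits_mod.estimate_h2(full, t) for t in trait_names}
        blues = pd.DataFrame({t: s.blue for t, s in summaries.items()})
        io_mod.write_table(
            pd.DataFrame([{
                "trait": t, "H2": s.H2, "cv_percent_blue": s.cv_percent,
                "cv_percent_raw": s.cv_percent_raw,
                "var_G": s.variance_components[0], "var_E": s.variance_components[1],
                "var_GxE": s.variance_components[2], "var_res": s.variance_components[3],
            } for t, s in summaries.items()]),
            outdir / "trait_summary.tsv", "traits", chash)
        blues.rename_axis("sample").to_csv(outdir / "blues.tsv", sep="\t")
        corr = traits_mod.trait_correlations(blues)
        corr.to_csv(outdir / "trait_correlations.tsv", sep="\t")
        return blues

    blues = _stage("traits", _traits)

    # -- gwas + clump -----------------------------------------------------
    def _gwas_clump():
        params = config.clump_params()
        K = gwas_mod.compute_kinship(geno)
        all_regions = []
        n_sig_total = 0
        for trait in blues.columns:
            y = blues[trait].reindex(geno.samples).to_numpy(float)
            assoc = gwas_mod.association_scan(
                geno, y, n_pcs=config.n_pcs, maf_min=config.maf_min, K=K,
                multi_locus=config.multi_locus, max_steps=config.max_steps,
            )
            assoc.attrs["trait"] = trait
            io_mod.write_table(assoc, outdir / f"assoc_{trait}.tsv", "gwas", chash)
            n_sig_total += int((assoc["minus_log10_p"] >= config.sig_log10p).sum())
            raw = clump_mod.clump(assoc, geno, params)
            regions = clump_mod.apply_singleton_filter(
                raw, assoc, geno, params, trait=trait, environment="BLUE")
            logger.info("trait %s: %d clumps, %d regions after singleton filter",
                        trait, len(raw), len(regions))
            all_regions.extend(regions)
        all_regions = clump_mod.merge_environment_regions(all_regions)
        io_mod.write_table(io_mod.qtl_table(all_regions), outdir / "qtl_regions.tsv",
                           "clump", chash)
        summary["n_significant_markers"] = n_sig_total
        summary["n_qtl_regions"] = len(all_regions)
        return all_regions

    regions = _stage("gwas+clump", _gwas_clump)

    # -- co-localization --------------------------------------------------
    if config.catalog:
        def _coloc():
            catalog = io_mod.read_catalog(config.catalog)
            report, counts = clump_mod.colocalize(regions, catalog)
            io_mod.write_table(report, outdir / "colocalization.tsv", "colocalize", chash)
            return counts
        summary["colocalization"] = _stage("colocalize", _coloc)

    # -- network ----------------------------------------------------------
    def _network():
        nodes = net_mod.merge_overlapping_qtls(regions)
        net = net_mod.build_network(nodes, geno, threshold=config.inter_ld_min)
        net_mod.export_network(net, outdir)
        counts = net_mod.classify_counts(net)
        logger.info("network: %s", counts)
        return nodes, net, counts

    nodes, net, counts = _stage("network", _network)
    summary["node_classes"] = counts

    # -- haplotype screen -------------------------------------------------
    if config.gff3:
        def _haplotype():
            genes = io_mod.read_gff3_genes(config.gff3)
            hubs = [n for n in nodes if len(n.traits) >= 3]
            regions_by_trait: dict[str, list[tuple[str, int, int]]] = {}
            for h in hubs:
                for t in h.traits:
                    regions_by_trait.setdefault(t, []).append((h.chrom, h.start, h.end))
            if not regions_by_trait:
                return {"tested": 0, "candidates": 0}
            results, sig, inter = hap_mod.candidate_gene_screen(
                regions_by_trait, genes, geno, blues,
                alpha=config.hap_alpha, upstream_bp=config.upstream_bp,
                min_count=config.hap_min_count,
            )
            io_mod.write_table(results, outdir / "haplotype_tests.tsv", "haplotype", chash)
            return {"tested": len(results), "candidates": len(inter)}
        summary["haplotype"] = _stage("haplotype", _haplotype)

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=str) + "\n")
    return summary


__all__ = ["PipelineConfig", "run_pipeline"]
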