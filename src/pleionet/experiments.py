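"""Validation experiments: calibration and planted-signal recovery.

These functions re-run the whole pipeline on freshly simulated panels with
known ground truth. They back the package's own acceptance checks and are
useful templates for sizing real studies. Problem sizes are chosen to be
informative on a single CPU in minutes: panels of 300-400 samples and a
few thousand markers over two chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import clumping as cl
from . import network as nw
from .datatypes import ClumpParams, QTLAssignment, SimConfig, TraitArchitecture
from .gwas import association_scan
from .simulate import random_architecture, simulate_genotypes, simulate_phenotypes
from .traits import compute_blue, estimate_h2


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n child seeds (< 2^31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


@dataclass
class HubRecoveryResult:
    recovered: bool
    hub_pos: int
    n_regions: int
    min_p: dict[str, float]


def hub_recovery_trial(seed: int, n_samples: int = 400, qtl_h2: float = 0.2,
                       n_traits: int = 3) -> HubRecoveryResult:
    """One end-to-end trial: plant a pleiotropic QTL, ask for a hub node.

    A single marker near the centre of chromosome 1 (MAF >= 0.2) drives
    ``n_traits`` traits at per-trait heritability ``qtl_h2``; the full
    pipeline (BLUE -> LOCO mixed-model scan -> clump -> singleton filter ->
    merge) must produce a hub node whose interval contains the planted
    position.
    """
    s_geno, s_eff, s_pheno = _spawn_seeds(seed, 3)
    geno = simulate_genotypes(SimConfig(
        n_samples=n_samples, n_markers=2400,
        chrom_lengths=(("Chr1", 30_000_000), ("Chr2", 30_000_000)),
        seed=s_geno))
    maf = geno.maf()
    on_chr1 = (geno.markers["chrom"] == "Chr1").to_numpy()
    cand = np.flatnonzero(on_chr1 & (maf >= 0.2))
    pos = geno.markers["pos"].to_numpy()
    hub = int(cand[np.argmin(np.abs(pos[cand] - 15_000_000))])
    hub_pos = int(pos[hub])

    rng = np.random.default_rng(s_eff)
    traits = tuple(f"T{i + 1}" for i in range(n_traits))
    arch = TraitArchitecture(
        trait_names=traits,
        qtl_assignments=[QTLAssignment(hub, {t: float(rng.choice([-1.0, 1.0]))
                                             for t in traits})],
        h2_target={t: qtl_h2 for t in traits},
        gxe_fraction={t: 0.3 for t in traits},
        n_env=2, n_rep=2)
    pheno, _ = simulate_phenotypes(geno, arch, seed=s_pheno)

    params = ClumpParams()
    regions = []
    min_p = {}
    for t in traits:
        y = compute_blue(pheno, t).reindex(geno.samples).to_numpy(float)
        assoc = association_scan(geno, y, multi_locus=False, loco=True)
        assoc.attrs["trait"] = t
        min_p[t] = float(np.nanmin(assoc["p"].to_numpy()))
        raw = cl.clump(assoc, geno, params)
        regions.extend(cl.apply_singleton_filter(raw, assoc, geno, params, trait=t))
    nodes = nw.merge_overlapping_qtls(regions)
    hit = any(len(n.traits) >= n_traits and n.start <= hub_pos <= n.end for n in nodes)
    return HubRecoveryResult(recovered=hit, hub_pos=hub_pos,
                             n_regions=len(regions), min_p=min_p)


def hub_recovery_rate(seed: int, n_seeds: int = 20) -> float:
    """Fraction of trials recovering the planted hub node."""
    seeds = _spawn_seeds(seed, n_seeds)
    return float(np.mean([hub_recovery_trial(s).recovered for s in seeds]))


def null_scan_calibration(seed: int, n_seeds: int = 10, n_samples: int = 300,
                          n_markers: int = 2000) -> float:
    """Mean fraction of markers with p < 0.05 on heritability-zero traits."""
    fracs = []
    for s in _spawn_seeds(seed, n_seeds):
        s_geno, s_pheno = _spawn_seeds(s, 2)
        geno = simulate_genotypes(SimConfig(
            n_samples=n_samples, n_markers=n_markers,
            chrom_lengths=(("Chr1", 40_000_000), ("Chr2", 40_000_000)),
            seed=s_geno))
        arch = TraitArchitecture(trait_names=("NULL",), qtl_assignments=[],
                                 h2_target={"NULL": 0.0}, gxe_fraction={"NULL": 0.0},
                                 n_env=2, n_rep=2)
        pheno, _ = simulate_phenotypes(geno, arch, seed=s_pheno)
        y = compute_blue(pheno, "NULL").reindex(geno.samples).to_numpy(float)
        p = association_scan(geno, y, multi_locus=False)["p"].to_numpy()
        fracs.append(float(np.mean(p[np.isfinite(p)] < 0.05)))
    return float(np.mean(fracs))


def h2_recovery(seed: int, n_seeds: int = 10, h2_target: float = 0.8,
                n_samples: int = 300, n_env: int = 2, n_rep: int = 3) -> float:
    """Mean entry-mean H2 estimate on panels simulated at ``h2_target``."""
    out = []
    for s in _spawn_seeds(seed, n_seeds):
        s_geno, s_arch, s_pheno = _spawn_seeds(s, 3)
        geno = simulate_genotypes(SimConfig(
            n_samples=n_samples, n_markers=500,
            chrom_lengths=(("Chr1", 40_000_000),), seed=s_geno))
        arch = random_architecture(geno, seed=s_arch, trait_names=("T",),
                                   n_private_qtls=5, h2_target={"T": h2_target},
                                   gxe_fraction={"T": 0.3}, n_env=n_env, n_rep=n_rep)
        pheno, _ = simulate_phenotypes(geno, arch, seed=s_pheno)
        out.append(estimate_h2(pheno, "T").H2)
    return float(np.mean(out))


def haplotype_null_rejection(seed: int, n_reps: int = 1000, n: int = 200,
                             alpha: float = 0.05) -> float:
    """Rejection rate of the two-group haplotype test under the null.

    Two haplotype groups of n/2 samples each, phenotypes drawn from one
    normal distribution: the two-sided rank-sum test should reject at
    about the nominal rate.
    """
    from .datatypes import HaplotypeGrouping
    from .haplotype import test_haplotype_trait

    rng = np.random.default_rng(seed)
    samples = [f"S{i}" for i in range(n)]
    labels = {s: ("H1" if i < n // 2 else "H2") for i, s in enumerate(samples)}
    grouping = HaplotypeGrouping(
        region=("Chr1", 1, 1000), variant_ids=["v1"], labels=labels,
        group_sizes={"H1": n // 2, "H2": n - n // 2}, excluded_rare=0, testable=True)
    hits = 0
    for _ in range(n_reps):
        blue = pd.Series(rng.normal(size=n), index=samples)
        res = test_haplotype_trait(grouping, blue)
        if res is not None and res.p < alpha:
            hits += 1
    return hits / n_reps


__all__ = [
    "HubRecoveryResult",
    "hub_recovery_trial",
    "hub_recovery_rate",
    "null_scan_calibration",
    "h2_recovery",
    "haplotype_null_rejection",
]
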