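"""Synthetic genotype panels and multi-trait, multi-environment phenotypes.

The genotype model is a founder-copying mosaic: every sample haplotype is a
piecewise copy of one of ``n_founders`` founder haplotypes, switching
founders between adjacent markers with probability ``1 - exp(-s * d)`` for
gap ``d`` bp and switch rate ``s``. This produces linkage disequilibrium
that decays with physical distance — r2 roughly halves where
``exp(-2 s d) = 1/2`` — which is all the downstream pipeline consumes; no
demography is modelled. A ``selfing`` parameter copies the first haplotype
onto the second for most samples, mimicking highly homozygous inbred
accessions.

Phenotypes are built from planted QTLs: per trait, the genetic value is the
dosage-weighted sum of planted effects; environment main effects, G-by-E
draws and plot residuals are added with variances scaled so the expected
entry-mean heritability over ``n_env`` environments and ``n_rep`` replicates
equals ``h2_target``.

All randomness flows from one integer seed through
``numpy.random.SeedSequence`` spawning, so each stage is independently
reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    DEFAULT_TRAITS,
    GenotypeMatrix,
    QTLAssignment,
    SimConfig,
    TraitArchitecture,
)

# Default per-trait entry-mean heritabilities: seed traits high, branch
# angles low, plant-height traits intermediate-to-high, spanning ~0.27-0.9.
DEFAULT_H2 = {
    "PH": 0.90, "NN": 0.90, "PR": 0.60, "IL": 0.70, "LPH": 0.60, "BN": 0.50,
    "1-BA": 0.32, "2-BA": 0.27, "3-BA": 0.32,
    "HSW": 0.85, "SW": 0.85, "SL": 0.80,
}

DEFAULT_GXE = {t: (0.1 if t in ("HSW", "SW", "SL") else 0.3) for t in DEFAULT_TRAITS}


def _founder_haplotypes(
    n_founders: int,
    positions: np.ndarray,
    switch_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Founder alleles with along-chromosome persistence.

    Per-marker alt frequency is Uniform(0.1, 0.9); each founder copies its
    previous allele with probability exp(-switch_rate * gap), else draws
    fresh. This gives the founders internal haplotype blocks, so samples
    copying the same founder segment are in high LD at short range.
    """
    n_markers = len(positions)
    freq = rng.uniform(0.1, 0.9, size=n_markers)
    hap = np.empty((n_founders, n_markers), dtype=np.int8)
    hap[:, 0] = rng.random(n_founders) < freq[0]
    persist = np.exp(-switch_rate * np.diff(positions).astype(float))
    for j in range(1, n_markers):
        copy = rng.random(n_founders) < persist[j - 1]
        fresh = rng.random(n_founders) < freq[j]
        hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
    return hap


def _mosaic_paths(
    n_paths: int,
    positions: np.ndarray,
    n_founders: int,
    switch_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Founder-index paths along one chromosome, Markov in distance."""
    gaps = np.diff(positions).astype(float)
    p_switch = 1.0 - np.exp(-switch_rate * gaps)
    paths = np.empty((n_paths, len(positions)), dtype=np.int32)
    paths[:, 0] = rng.integers(0, n_founders, size=n_paths)
    for j, p in enumerate(p_switch, start=1):
        switch = rng.random(n_paths) < p
        paths[:, j] = np.where(switch, rng.integers(0, n_founders, size=n_paths), paths[:, j - 1])
    return paths


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Simulate a diploid inbred-like panel with distance-decaying LD.

    Returns dosages in {0, 1, 2}; markers with MAF < ``config.maf_min``
    are removed. Deterministic given ``config.seed``.
    """
    root = np.random.SeedSequence(config.seed)
    rng_pos, rng_founder, rng_mosaic, rng_self = (
        np.random.default_rng(s) for s in root.spawn(4)
    )

    total_len = sum(length for _, length in config.chrom_lengths)
    chrom_markers = [
        max(1, round(config.n_markers * length / total_len))
        for _, length in config.chrom_lengths
    ]

    # selfed samples copy haplotype 1 onto haplotype 2 on every chromosome
    selfed = rng_self.random(config.n_samples) < config.selfing

    dosage_parts: list[np.ndarray] = []
    marker_parts: list[pd.DataFrame] = []
    for (chrom, length), n_mark in zip(config.chrom_lengths, chrom_markers):
        positions = np.sort(rng_pos.choice(length, size=min(n_mark, length), replace=False)) + 1
        block_rate = (config.founder_block_rate if config.founder_block_rate is not None
                      else config.switch_rate)
        founders = _founder_haplotypes(config.n_founders, positions,
                                       block_rate, rng_founder)
        paths1 = _mosaic_paths(config.n_samples, positions, config.n_founders,
                               config.switch_rate, rng_mosaic)
        paths2 = _mosaic_paths(config.n_samples, positions, config.n_founders,
                               config.switch_rate, rng_mosaic)
        paths2[selfed] = paths1[selfed]
        hap1 = founders[paths1, np.arange(len(positions))]
        hap2 = founders[paths2, np.arange(len(positions))]
        dosage_parts.append((hap1 + hap2).astype(np.int8))
        marker_parts.append(pd.DataFrame({
            "chrom": chrom,
            "pos": positions.astype(np.int64),
            "id": [f"{chrom}_{p}" for p in positions],
            "ref": "A",
            "alt": "T",
        }))

    dosage = np.concatenate(dosage_parts, axis=1)
    markers = pd.concat(marker_parts, ignore_index=True)
    samples = [f"S{i:04d}" for i in range(config.n_samples)]
    geno = GenotypeMatrix(dosage=dosage, markers=markers, samples=samples)

    keep = geno.maf() >= config.maf_min
    if not keep.any():
        raise ValueError(
            f"all {geno.n_markers} simulated markers fall below maf_min={config.maf_min}"
        )
    return geno.subset_markers(np.flatnonzero(keep))


def random_architecture(
    geno: GenotypeMatrix,
    seed: int,
    trait_names: tuple[str, ...] = DEFAULT_TRAITS,
    n_private_qtls: int = 5,
    hub_markers: dict[int, tuple[str, ...]] | None = None,
    hub_effect_scale: float = 2.0,
    h2_target: dict[str, float] | None = None,
    gxe_fraction: dict[str, float] | None = None,
    n_env: int = 6,
    n_rep: int = 3,
) -> TraitArchitecture:
    """Draw a trait architecture: private QTLs per trait plus optional hubs.

    ``hub_markers`` maps a marker index to the traits it affects (a hub
    planting assigns >= 3 traits to one marker). Private effects are drawn
    Normal(0, 1) before variance scaling in :func:`simulate_phenotypes`;
    hub effects are scaled by ``hub_effect_scale``, reflecting that known
    pleiotropic loci in crop panels are typically major-effect.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    assignments: list[QTLAssignment] = []
    taken: set[int] = set(hub_markers or {})
    for trait in trait_names:
        free = np.setdiff1d(np.arange(geno.n_markers), sorted(taken))
        chosen = rng.choice(free, size=min(n_private_qtls, free.size), replace=False)
        taken.update(int(c) for c in chosen)
        for m in chosen:
            assignments.append(QTLAssignment(int(m), {trait: float(rng.normal())}))
    for m, traits in (hub_markers or {}).items():
        if m >= geno.n_markers:
            raise ValueError(f"hub marker index {m} outside genotype matrix")
        assignments.append(
            QTLAssignment(int(m), {t: float(hub_effect_scale * rng.normal())
                                   for t in traits})
        )
    return TraitArchitecture(
        trait_names=trait_names,
        qtl_assignments=assignments,
        h2_target=dict(h2_target or {t: DEFAULT_H2.get(t, 0.5) for t in trait_names}),
        gxe_fraction=dict(gxe_fraction or {t: DEFAULT_GXE.get(t, 0.3) for t in trait_names}),
        n_env=n_env,
        n_rep=n_rep,
    )


def simulate_phenotypes(
    geno: GenotypeMatrix,
    arch: TraitArchitecture,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the long phenotype table and return it with the truth table.

    Each observation is ``sum(marker effects) + env effect + GxE draw +
    residual``; G-by-E and residual variances are scaled so the expected
    entry-mean heritability equals ``h2_target`` for each trait:

        H2 = V_G / (V_G + V_GxE / E + V_res / (E R)).

    Returns ``(phenotypes, truth)`` where truth lists the planted QTLs
    (trait, marker id/chrom/pos, raw effect).
    """
    for a in arch.qtl_assignments:
        if not (0 <= a.marker < geno.n_markers):
            raise ValueError(f"planted marker index {a.marker} outside genotype matrix")
    for trait in arch.trait_names:
        if arch.h2(trait) == 1.0 and arch.gxe(trait) > 0:
            raise ValueError(
                f"trait {trait!r}: h2_target=1 with gxe_fraction>0 is inconsistent "
                "(no non-genetic variance available for GxE)"
            )

    root = np.random.SeedSequence(seed)
    rng_env, rng_gxe, rng_res = (np.random.default_rng(s) for s in root.spawn(3))

    n, E, R = geno.n_samples, arch.n_env, arch.n_rep
    envs = [f"E{j + 1}" for j in range(E)]

    # genetic values per trait
    gvalues = {t: np.zeros(n) for t in arch.trait_names}
    truth_rows = []
    for a in arch.qtl_assignments:
        dos = geno.dosage[:, a.marker].astype(float)
        for trait, eff in a.effects.items():
            gvalues[trait] += eff * dos
            mk = geno.markers.iloc[a.marker]
            truth_rows.append({
                "trait": trait, "marker_index": a.marker, "marker_id": mk["id"],
                "chrom": mk["chrom"], "pos": int(mk["pos"]), "effect": eff,
            })
    truth = pd.DataFrame(
        truth_rows, columns=["trait", "marker_index", "marker_id", "chrom", "pos", "effect"]
    )

    frames = []
    for trait in arch.trait_names:
        g = gvalues[trait]
        v_g = float(np.var(g))
        h2, gxe = arch.h2(trait), arch.gxe(trait)
        if h2 == 0.0 or v_g == 0.0:
            g = np.zeros(n)
            v_noise_entry = 1.0  # unit phenotypic variance under the null
        else:
            v_noise_entry = v_g * (1.0 - h2) / h2
        v_gxe = E * gxe * v_noise_entry
        v_res = E * R * (1.0 - gxe) * v_noise_entry
        v_env = 0.5 * v_g if v_g > 0 else 1.0

        env_eff = rng_env.normal(0.0, np.sqrt(v_env), size=E)
        gxe_eff = rng_gxe.normal(0.0, np.sqrt(v_gxe), size=(n, E)) if v_gxe > 0 else np.zeros((n, E))
        res = rng_res.normal(0.0, np.sqrt(v_res), size=(n, E, R)) if v_res > 0 else np.zeros((n, E, R))

        values = g[:, None, None] + env_eff[None, :, None] + gxe_eff[:, :, None] + res
        idx = pd.MultiIndex.from_product(
            [geno.samples, envs, range(1, R + 1)], names=["sample", "env", "rep"]
        )
        frames.append(pd.DataFrame({
            "sample": idx.get_level_values("sample"),
            "env": idx.get_level_values("env"),
            "rep": idx.get_level_values("rep"),
            "trait": trait,
            "value": values.reshape(-1),
        }))

    pheno = pd.concat(frames, ignore_index=True)
    return pheno, truth


__all__ = [
    "DEFAULT_H2",
    "DEFAULT_GXE",
    "simulate_genotypes",
    "simulate_phenotypes",
    "random_architecture",
]
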