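"""Core in-memory containers shared across the pipeline.

Coordinates are 1-based inclusive everywhere inside the package; the only
conversions happen at the BED boundary (see :mod:`pleionet.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1  # missing-dosage code in integer dosage matrices

#: Default trait panel: nine architecture traits and three seed traits.
DEFAULT_TRAITS = (
    "PH", "NN", "PR", "IL", "LPH", "BN",
    "1-BA", "2-BA", "3-BA", "HSW", "SW", "SL",
)

PHENO_COLUMNS = ("sample", "env", "rep", "trait", "value")


@dataclass
class GenotypeMatrix:
    """Samples x markers allele-dosage matrix with a marker map.

    Attributes
    ----------
    dosage : ndarray of shape (n_samples, n_markers)
        Alt-allele dosages in {0, 1, 2}; missing coded as ``MISSING``.
    markers : DataFrame with columns chrom, pos, id, ref, alt
        One row per marker, positions 1-based and strictly increasing
        within each chromosome.
    samples : list of sample ids (unique).
    """

    dosage: np.ndarray
    markers: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage)
        if self.dosage.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids must be unique")
        for _, sub in self.markers.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("marker positions must be strictly increasing per chromosome")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per marker, ignoring missing dosages."""
        d = np.ma.masked_equal(self.dosage, MISSING)
        p = d.mean(axis=0).filled(np.nan) / 2.0
        return np.minimum(p, 1.0 - p)

    def subset_markers(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            dosage=self.dosage[:, idx],
            markers=self.markers.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
        )

    def marker_index(self, marker_id: str) -> int:
        hits = np.flatnonzero((self.markers["id"] == marker_id).to_numpy())
        if hits.size == 0:
            raise KeyError(f"unknown marker id {marker_id!r}")
        return int(hits[0])

    def markers_in_interval(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of markers with start <= pos <= end on chrom."""
        m = self.markers
        mask = (m["chrom"] == chrom) & (m["pos"] >= start) & (m["pos"] <= end)
        return np.flatnonzero(mask.to_numpy())


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the founder-mosaic genotype simulator."""

    n_samples: int = 400
    n_markers: int = 3000
    chrom_lengths: tuple[tuple[str, int], ...] = (
        ("Chr1", 50_000_000),
        ("Chr2", 50_000_000),
        ("Chr3", 50_000_000),
    )
    n_founders: int = 24
    # per-bp mosaic switch probability; with founder_block_rate defaulting
    # to the same value, sample-level r2 decays roughly as exp(-4 s d), so
    # the default puts the half-maximum near 455 kb
    switch_rate: float = float(np.log(2) / (4 * 455_000))
    # per-bp allele-block decay rate of the founder haplotypes themselves
    # (None -> switch_rate)
    founder_block_rate: float | None = None
    maf_min: float = 0.05
    selfing: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ValueError("n_founders must be >= 2")
        if not self.switch_rate > 0:
            raise ValueError("switch_rate must be > 0")
        if not (0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must lie in [0, 0.5)")
        if any(length <= 0 for _, length in self.chrom_lengths):
            raise ValueError("all chromosome lengths must be > 0")
        if not (0 <= self.selfing <= 1):
            raise ValueError("selfing must lie in [0, 1]")


@dataclass(frozen=True)
class QTLAssignment:
    """One planted QTL: a marker index and its per-trait effects."""

    marker: int
    effects: dict[str, float]  # trait name -> raw effect size

    @property
    def traits(self) -> frozenset[str]:
        return frozenset(self.effects)


@dataclass
class TraitArchitecture:
    """Genetic architecture of the simulated trait panel.

    ``h2_target`` is entry-mean broad-sense heritability; ``gxe_fraction``
    is the share of the non-genetic entry-mean variance contributed by
    genotype-by-environment interaction.
    """

    trait_names: tuple[str, ...] = DEFAULT_TRAITS
    qtl_assignments: list[QTLAssignment] = field(default_factory=list)
    h2_target: dict[str, float] = field(default_factory=dict)
    gxe_fraction: dict[str, float] = field(default_factory=dict)
    n_env: int = 6
    n_rep: int = 3

    def __post_init__(self) -> None:
        for t, h2 in self.h2_target.items():
            if not (0 <= h2 <= 1):
                raise ValueError(f"h2_target[{t!r}]={h2} outside [0, 1]")
        for t, f in self.gxe_fraction.items():
            if not (0 <= f <= 1):
                raise ValueError(f"gxe_fraction[{t!r}]={f} outside [0, 1]")

    def h2(self, trait: str) -> float:
        return self.h2_target.get(trait, 0.5)

    def gxe(self, trait: str) -> float:
        return self.gxe_fraction.get(trait, 0.3)


@dataclass
class MixedModelFit:
    """Null-model REML fit on the spectral decomposition of the kinship."""

    sigma2_g: float
    sigma2_e: float
    delta: float  # sigma2_e / sigma2_g
    eigenvalues: np.ndarray
    rotation: np.ndarray  # U such that K = U diag(eigenvalues) U'
    X: np.ndarray  # covariates (intercept + PCs), original scale
    y: np.ndarray
    reml_loglik: float

    @property
    def pseudo_heritability(self) -> float:
        tot = self.sigma2_g + self.sigma2_e
        return self.sigma2_g / tot if tot > 0 else 0.0


@dataclass(frozen=True)
class ClumpParams:
    """Greedy p-value/LD clumping thresholds (plink --clump semantics)."""

    p1: float = 1e-5
    p2: float = 1e-3
    window_kb: float = 455.0
    r2_min: float = 0.5
    singleton_p: float = 2.5e-4
    singleton_min_snps: int = 5

    def __post_init__(self) -> None:
        if self.p1 > self.p2:
            raise ValueError("p1 must be <= p2")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be > 0")
        if not (0 <= self.r2_min <= 1):
            raise ValueError("r2_min must lie in [0, 1]")


@dataclass
class Clump:
    """A raw clump before promotion to a QTL region."""

    index_marker: int  # marker index of the index SNP
    members: list[int]  # marker indices incl. the index SNP
    trait: str


@dataclass
class QTLRegion:
    """A clump promoted to a genomic interval (1-based inclusive)."""

    id: str
    trait: str
    chrom: str
    start: int
    end: int
    index_marker: str
    member_markers: list[str]
    min_p: float
    environments: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"QTL {self.id}: start {self.start} > end {self.end}")

    def overlaps(self, other: "QTLRegion") -> bool:
        return self.chrom == other.chrom and self.start <= other.end and other.start <= self.end


@dataclass
class InterLDResult:
    """Inter-LD statistic between two QTL intervals."""

    qtl1: str
    qtl2: str
    ave_ld: float
    pmax_ld1: float
    pmax_ld2: float
    inter_ld: float


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")


@dataclass
class HaplotypeGrouping:
    """Per-sample haplotype labels over a gene region."""

    region: tuple[str, int, int]  # chrom, start, end
    variant_ids: list[str]
    labels: dict[str, str]  # sample -> haplotype label (H1 largest group)
    group_sizes: dict[str, int]
    excluded_rare: int
    testable: bool


def validate_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    """Check the long phenotype table schema and key uniqueness."""
    missing_cols = set(PHENO_COLUMNS) - set(pheno.columns)
    if missing_cols:
        raise ValueError(f"phenotype table missing columns {sorted(missing_cols)}")
    keys = pheno[["sample", "env", "rep", "trait"]]
    if keys.duplicated().any():
        raise ValueError("duplicate (sample, env, rep, trait) keys in phenotype table")
    return pheno


__all__ = [
    "MISSING",
    "DEFAULT_TRAITS",
    "PHENO_COLUMNS",
    "GenotypeMatrix",
    "SimConfig",
    "QTLAssignment",
    "TraitArchitecture",
    "MixedModelFit",
    "ClumpParams",
    "Clump",
    "QTLRegion",
    "InterLDResult",
    "GeneModel",
    "HaplotypeGrouping",
    "validate_phenotypes",
    "replace",
]
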