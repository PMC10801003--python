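# Methods

This note documents the models, estimators and design choices behind
`pleionet`, in the order the pipeline runs them.

## Synthetic panels

**Genotypes.** Each sample haplotype is a mosaic of `n_founders` founder
haplotypes: walking along a chromosome, the copied founder switches
between adjacent markers with probability `1 − exp(−s·d)` for gap `d` bp
and switch rate `s` (`SimConfig.switch_rate`). The founder haplotypes
themselves carry allele blocks that decay at `founder_block_rate`
(default: the same `s`), because mosaics of internally uncorrelated
founders cannot exceed a baseline LD of about `1/n_founders` at any
distance. With both rates equal, sample-level r² decays approximately as
`exp(−4·s·d)`; the default `s = ln 2 / (4 · 455 000) ≈ 3.8×10⁻⁷` per bp
puts the r² half-maximum near 455 kb, the decay scale typical of inbred
soybean panels (measured on simulated panels: mean r² 0.98 below 20 kb,
0.49 at 455 kb, 0.006 at 5 Mb). A `selfing` probability (default 0.95)
copies haplotype one onto haplotype two, giving the mostly homozygous
genotypes of selfing crops. Markers with MAF below `maf_min` (default
0.05) are removed; positions are uniform draws, strictly increasing per
chromosome. Defaults: `n_founders = 24`, three 50-Mb chromosomes.

What this emulates — and what it does not: the generator reproduces
distance-decaying LD, relatedness structure (founder sharing) and
homozygosity, which are the only genotype features the downstream
methods consume. It has no demography, selection, geographic gradients
or missing data, so passing tests say nothing about imputation accuracy
or confounding structures beyond founder admixture.

**Phenotypes.** An observation for sample *i*, environment *j*,
replicate *k* is

    y_ijk = Σ_q a_q · g_iq + E_j + (GE)_ij + ε_ijk

with planted QTL effects `a_q` (private effects Normal(0,1); hub effects
scaled by `hub_effect_scale = 2`, since known pleiotropic loci in crop
panels are major-effect), environment main effects
`E_j ~ N(0, 0.5·V_G)`, and independent G×E and residual draws. Given a
target entry-mean heritability `h²` over `E` environments and `R`
replicates, the non-genetic entry-mean variance is
`V_ne = V_G (1 − h²)/h²`, split as `V_GxE = E · f · V_ne` and
`V_res = E·R · (1 − f) · V_ne` where `f` is `gxe_fraction`. `h² = 1`
with `f > 0` is rejected as inconsistent. Default per-trait targets span
0.27–0.9 (seed traits high, branch angles low), mirroring the range
reported for such panels. Each trait receives 5 private QTLs by default;
both the count and the effect distribution are package choices exposed
in the architecture config. All randomness derives from one integer seed
through `SeedSequence` spawning, so stages re-run reproducibly.

## Trait processing

Pod range and internode length are computed per observation
(`PR = (PH − LPH)/PH`, `IL = PH/NN`); zero denominators give missing
values with a logged warning.

**BLUEs** come from `y = μ + genotype_i + env_j + ε` with genotype fixed
(cell-mean coding) and environment random, solved by the Henderson
mixed-model equations with shrinkage `λ = σ²_res/σ²_env` from the ANOVA
variance partition (a 10⁻⁸ floor keeps the system nonsingular when the
residual component vanishes). No G×E term enters the BLUE fit — with
few environments it is not separable from the residual and is absorbed
there. A single environment collapses to per-sample means; samples
without observations are dropped, never imputed.

**Variance components** use the expected-mean-squares method of moments
on cell means (exact for balanced data, adequate near balance; no REML
iteration), negatives truncated at zero. With one replicate, the
interaction mean square is the error term; with one environment, a
one-way partition is used. Entry-mean heritability is
`H² = σ²_G / (σ²_G + σ²_GxE/E + σ²_res/(E·R))`. CV% is reported both on
BLUEs and on raw observations, labelled separately, since either
convention appears in the literature.

Trait correlations are Pearson on pairwise-complete BLUEs (≥ 3 shared
samples); era trends are OLS of BLUE on release year (slope, R²,
two-sided p), with a constant response returning slope 0, R² 0.

## Mixed-model association

Kinship is the VanRaden genomic relationship matrix on mean-imputed,
centered dosages scaled by `2Σp(1−p)`; population structure covariates
are the top 10 PCs of the centered dosage matrix. The null model
`y = Xb + g + e`, `g ~ N(0, σ²_g K)`, is fit by REML: K is
eigendecomposed once, and the restricted likelihood is a 1-D function of
`δ = σ²_e/σ²_g` maximized by a 60-point log-grid plus bounded refinement
(the returned δ is verified in tests to beat a 50-point grid).

The scan holds δ at the null estimate (the P3D approximation) and tests
each marker by weighted least squares in the rotated frame, with the
residual scale re-estimated per marker and a t-test on `n − p − 1`
degrees of freedom. This choice makes the identity-kinship limit
coincide *exactly* with the OLS t-test, which is the package's oracle
for the scan. Markers collinear with the covariates, monomorphic, or
serving as cofactors are reported missing, never `p = 1`. An optional
leave-one-chromosome-out (LOCO) kinship excludes the tested chromosome
from K, avoiding proximal contamination — the tested locus absorbing
itself through the polygenic term; the recovery experiments use it, as
single-QTL traits at h² = 0.2 otherwise lose a unit of −log₁₀p and
intermittently miss the clumping threshold.

The multi-locus scan is forward selection: add the most significant
marker as a fixed cofactor, refit δ, rescan; stop at `max_steps`
(default 10) or pseudo-heritability ≤ 0.01; return the step minimizing
the extended BIC `n·log(σ̂²) + k(log n + 2 log m)`. The step rule, the
stopping rule and the model-choice criterion are this package's
concrete reading of multi-locus mixed-model scanning; all three are
configurable. A MAF filter (default 0.05) runs before testing. The
−log₁₀(p) ≥ 5 significance convention is applied downstream of the
scan, never inside it.

## Clumping and QTL regions

Greedy clumping with plink `--clump` semantics: visit markers by
ascending p; each unassigned marker with `p ≤ p1` (default 1e-5) seeds a
clump and absorbs unassigned markers within ±455 kb having `p ≤ p2`
(1e-3) and `r² ≥ 0.5` to the index. `r²` is the squared Pearson
correlation of dosages (composite LD) — on near-fully homozygous panels
this coincides with the phased haplotype r²; the `r² ≥ 0.5` default is
the plink default, stated explicitly because the convention command line
omits it. Ties in p break by genomic order for determinism. A clump
whose member-position span contains fewer than 5 tested SNPs at
`p < 2.5×10⁻⁴` is dropped as a singleton; the threshold is read as a
p-value bound (the only reading on which the rule discards anything).
Survivors become 1-based inclusive QTL regions spanning their member
positions. Same-trait regions from different environments/datasets are
merged by interval overlap, recording the environment list.
Co-localization against a catalog (BED, converted to 1-based inclusive
on read, or TSV) requires ≥ 1 shared bp on the same chromosome; abutting
intervals do not overlap.

## The association network

For two same-chromosome intervals, `aveLD` is the mean r² over all
cross pairs drawn from **all genotyped markers** inside each interval
(not only clump members), and `PmaxLD(Q)` is the maximum pairwise r²
within Q, defined as 1 for a single-marker interval. Then
`Inter-LD = ½(aveLD/PmaxLD₁ + aveLD/PmaxLD₂)`. Missing pairwise r²
values are excluded from the mean; a pair with no polymorphic cross pair
is skipped with a warning. The statistic can exceed 1 when cross-LD
beats both within-interval maxima; no cap is applied, a warning is
logged. The pair is evaluated in a canonical order so symmetry holds to
the last bit.

QTL regions are merged into nodes transitively (same chromosome, ≥ 1
shared bp); merging precedes Inter-LD computation, and edges are then
computed between merged spans at threshold 0.4. Node classes partition
the QTL nodes exhaustively: hub (≥ 3 directly associated traits),
two-trait, linked-1-trait (one trait, ≥ 1 Inter-LD edge), independent.
Inter-LD edges never add traits to a node — hub status counts only
direct trait associations. Exports: node/edge TSVs whose round-trip read
reproduces the graph exactly, plus GraphML and SIF for Cytoscape.

## Haplotype screening

A gene region is the gene span extended 2 kb on the promoter side
(upstream of the 5′ end, strand-aware), clipped at chromosome bounds.
Samples sharing an identical dosage vector over the region's variants
form one haplotype group, labelled H1, H2, ... by descending size;
groups below `min_count` (default 10 — a rare-haplotype rule is
unavoidable even though no standard value exists) are excluded from
testing. Two groups are compared by a two-sided Wilcoxon rank-sum test,
three or more by one-way ANOVA — a deterministic dispatch. Fewer than
two testable groups yields "untestable", never p = 1. The screen tests
every gene overlapping each trait's regions against that trait's BLUEs
at α = 0.05 with no multiplicity correction by default (matching the
convention of reporting raw per-gene significance; Benjamini–Hochberg
is available behind a flag) and returns per-trait significant sets plus
their intersection. Expression-based filtering of candidates is left to
a user-supplied keep-list.

## Validation experiments and problem sizes

The `experiments` module re-runs the pipeline end to end on panels with
known truth:

* **Hub recovery** — one marker (MAF ≥ 0.2, mid-chromosome) drives three
  traits at per-trait h² = 0.2; n = 400 samples, 2400 markers over two
  30-Mb chromosomes (≈ 25-kb spacing — sparser maps starve the 5-SNP
  singleton rule; real panels are far denser still), 2 environments × 2
  replicates, LOCO scan. Success = a ≥ 3-trait node containing the
  planted position. Expected ≥ 90% over 20 seeds.
* **Null calibration** — h² = 0 traits, 300 samples × 2000 markers; the
  fraction of markers at p < 0.05 averaged over 10 seeds should sit in
  [0.03, 0.07]. The haplotype rank-sum test is checked the same way over
  1000 null replicates of two 100-sample groups.
* **H² recovery** — five QTLs at h² = 0.8, 300 genotypes, 2 × 3 design;
  the EMS estimate should land within ±0.1 of target over 10 seeds.

## Numerical conventions

All genomic coordinates are 1-based inclusive internally; BED input is
converted on read (`start+1`, `end`) and back on write. Dosages are
{0, 1, 2} with −1 for missing; kinship/PCA mean-impute missing dosages,
LD uses pairwise-complete samples. Variance components are truncated at
zero; H² is clipped to [0, 1]. PCA signs are fixed by making each
component's largest-magnitude loading positive. Every output table
carries a header naming its stage and the configuration hash, and
re-running a pipeline with the same config and seed reproduces every
TSV byte for byte.

## Known limitations

The BLUE model's fixed/random allocation is a documented choice, not a
universal convention; REML variance components would differ slightly on
unbalanced data. The multi-locus scan's selection rules are one of
several defensible variants. Composite-LD r² diverges from phased r² in
outbred material. The simulator's LD is stationary along chromosomes —
no recombination hotspots — so clump spans are more regular than in
real data. Cross-chromosome Inter-LD edges are deliberately not
computed.
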