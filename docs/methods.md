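# Methods

## The association model

Each SNP is tested under a Gaussian linear model
`y = W_j α + x_j β + ε`, `ε ~ MVN_n(0, τ⁻¹ I_n)`, where `W_j` always
contains an intercept plus principal-component covariates.  Because the
error covariance is a scalar multiple of the identity (no random genetic
effect), the maximum-likelihood estimates coincide with ordinary least
squares, with `τ̂ = n / RSS` and
`loglik = −(n/2)(log(2π·RSS/n) + 1)`; the implementation therefore uses
the closed form rather than an iterative optimizer.  The per-SNP score
is a likelihood-ratio test of the SNP effect,
`Λ = 2(ll_alt − ll_null) = n·log(RSS₀/RSS₁)`, referred to χ² with one
degree of freedom.

Two nested covariate sets compete for each SNP:

* **global** — top `n_global_pcs` (default 5) PC scores computed on the
  alignment *excluding* the local partition containing the SNP, so that
  a causal partition cannot launder its own signal into the correction;
* **glocal** — the global set plus up to `n_local_pcs` (default 5) PC
  scores of the local partition itself (rank-deficient partitions
  contribute rank-many columns rather than erroring: short partitions
  are common near tract edges).

Under the default **min-P** rule both LRTs are run and the smaller
p-value is reported, so the method's positive set at any threshold
contains each nested model's positive set (this dominance is asserted
on every simulated replicate).  The alternative **forward** rule adopts
the local block only when the no-SNP covariate LRT (df = number of local
columns) is significant at P < 0.05, then tests the SNP in the adopted
design; it is more conservative and is not the default.

The min-P score is treated as a *ranking* statistic.  The minimum of two
positively correlated χ²₁ p-values is stochastically smaller than
uniform; measured on pure-noise traits its empirical type-I error at the
0.05 threshold is roughly 0.09–0.10.  No recalibration is applied —
evaluation is by ROC on the ranking, where any monotone miscalibration
is irrelevant — but users who need calibrated per-SNP p-values should
use `p_global`/`p_glocal` individually or calibrate empirically.

Genotypes enter PCA after EIGENSTRAT-style standardization: per site
subtract the allele frequency `p̂` and divide by `sqrt(p̂(1−p̂))`,
haploid 0/1 dosage, monomorphic sites dropped.  PC scores are unit-norm
left singular vectors with a deterministic sign convention
(largest-magnitude entry positive).  Because the normalization is
per-column, the leave-one-partition-out global PCA is computed exactly
from a single Gram-matrix downdate `MMᵀ − M_ℓ M_ℓᵀ` followed by an
`n×n` eigendecomposition; this is algebraically identical to an SVD of
the excluded-sites matrix (verified in tests) and makes a whole-genome
scan cost a few matrix products per partition.

The **EIGENSTRAT-style baseline** residualizes phenotype and genotype on
an intercept plus the top 10 PCs of the *full* alignment and refers
`(n − K − 1) r²` of the residual correlation to χ²₁.  No genomic-control
rescaling is applied (a deliberate design choice; per-replicate λ
rescaling would break the comparability of p-values pooled across
replicates).

## The simulator and what it emulates

`simulate_alignment` draws, per locus, an independent genealogy under a
three-population coalescent: populations A, B, H coalesce in isolation
(rate C(k,2) each, exact exponential waiting times) until the
hybridization time `t2 = 2.0`, where each surviving H lineage joins
ancestral B with probability γ (else ancestral A); two populations
persist until the divergence time `t1 = 3.0`, then merge until the MRCA.
All population sizes are equal; admixture is a point event.  Mutations
are infinite-sites: Poisson(θ/2 × total branch length) per locus, placed
uniformly on branches, each defining one biallelic column.  Loci are
unlinked (free recombination) and internally completely linked.  One
root seed spawns per-locus substreams, so loci are independent and every
dataset is bit-reproducible.

Defaults define the study conditions: `t1=3.0`, `t2=2.0`,
γ ∈ {0.5, 0.25, 0.1, 0.01}, 10 loci × 250 bp.  Interpretively, `t1=3.0`
corresponds to ~1.5 My divergence at 2 generations/year with
N_e = 2.5×10⁵.  Two parameters the study design leaves open were fixed
once as package defaults: **n = 100 haploid samples per population**
(300 total; large enough for stable PCA and MAF estimation at desk
scale) and **θ = 25 per locus** (each locus then yields ample SNPs in
the causal MAF window).  Note that with this deep-structure demography
the expected segregating sites per locus (~440 for n=300) greatly
exceeds the panmictic Watterson value θ·Σ1/i; the Watterson calibration
test therefore uses a single-deme sample, where the formula applies.

Traits are additive: `y_i = π·Σ_{j∈Δ} Q_ij/|Δ| + (1−π)·e_i` with
`e_i ~ N(0, 0.01)` (variance 0.01, i.e. s.d. 0.1 — standard
N(mean, variance) notation).  Δ holds 20 causal SNPs with MAF (folded
at 0.5, computed over all samples jointly) in [0.1, 0.3], drawn from
one, two, or all loci (loci uniform at random; a locus draw lacking
enough eligible SNPs is redrawn up to 20 times).  **π defaults to 0.9**
(only a π=1 genotype-only sensitivity setting is otherwise specified);
with this parameterization the environmental term is small, so the
simulated traits are strongly genetic and power differences between
methods are driven by structure correction, not noise.

What the simulator does *not* emulate: positive selection (no selective
sweeps — the neutral backward simulation with complete intra-locus
linkage stands in for sweep-like local LD), intra-locus recombination,
recurrent/back mutation, diploidy, genotyping error, and more than two
parental populations.  Passing tests therefore demonstrate behavior
under idealized tract structure, not performance on empirical genomes.

## Four-Gamete-Test partitioning

Breakpoints are inferred by a greedy left-to-right scan growing maximal
blocks: a new site closes the block if it is incompatible (all four
gametes 00/01/10/11 present) with *any* block member.  Greedy maximal
blocks minimize the number of partitions, so inferred partitions never
outnumber the true loci.  Placement, however, can overshoot a true
boundary: the leading sites of a new locus (typically low-frequency
variants; singletons are compatible with every column) may be
compatible with the entire preceding block, and since pairwise
compatibility of binary characters implies joint tree-compatibility,
*no* compatibility-based method can resolve such sites — the data are
genuinely ambiguous.  Empirically this affects roughly one boundary per
ten at study scale and the overshoot is a handful of sites.  Tests
assert the achievable guarantees: every breakpoint is witnessed by an
incompatible spanning pair, blocks are internally compatible, and any
overshoot passes only through sites compatible with the whole preceding
block.  Partitions are stored 0-based half-open internally and written
1-based inclusive.

## Evaluation

Per condition, p-values of all replicates are pooled into a single ROC
per method (causal SNPs are positives), built on −p with tie-aware
steps so the trapezoidal AUROC equals the tie-corrected Mann–Whitney
statistic; TPR at FPR 0.05 is the largest TPR whose FPR does not exceed
0.05 (step-function evaluation, no interpolation).  Correlated AUROCs
are compared with the DeLong placement-value estimator (two-sided normal
p; a non-positive variance of the difference yields p = 1 with a
degenerate-variance flag).  Benjamini–Hochberg runs across the
conditions of one study table (one family per table, setwise α = 0.05).
Per-replicate AUROCs are also reported for dispersion.  Pooling raw
p-values across replicates assumes cross-replicate comparability of the
score scale — one reason no per-replicate genomic control is applied.

## Numerical choices and degenerate inputs

* Collinear design columns are dropped by pivoted-QR rank detection at
  tolerance 1e-10 (relative to the largest R diagonal); a SNP collinear
  with its covariates gets df = 0 and p = 1.
* Perfect fits floor the RSS at `1e-12·n·Var(y)` to keep log-likelihoods
  finite; such fits are flagged.
* The vectorized whole-alignment scan uses the exact add-one-regressor
  identity `RSS₁ = RSS₀ − (r_yᵀr_x)²/‖r_x‖²` on residuals against an
  orthonormal null-design basis; tests verify it matches the per-SNP
  fits to 1e-8.
* A locus simulating zero segregating sites is redrawn (genealogy and
  mutations) up to 100 times; a replicate failing trait construction
  (insufficient eligible SNPs) is retried with a fresh derived seed up
  to 5 times, then counted as skipped.
* k = 1 alignments yield one single-site partition; a single-partition
  dataset has no global covariates and is rejected.
* Per-replicate seeds are CRC32 hashes of (root seed, condition label,
  replicate, attempt), kept below 2³¹; replicate artifacts record them.

## Problem sizes used in the shipped checks

The validation suite runs the full 12-condition grid at 20 replicates
with the default study conditions (300 samples, ~4–5k SNPs per
replicate; about five minutes single-threaded).  Calibration properties
that are size-independent (admixture fraction, pairwise diversity,
breakpoint placement, null type-I error) run on reduced simulations
(2–150 samples, 5–8 loci) chosen so each check completes in seconds
while retaining its statistical meaning; Monte-Carlo error for null
type-I is taken at replicate level because p-values within a replicate
share one phenotype draw and complete within-locus linkage.

## Known limitations

* Min-P p-values are anticonservative as calibrated tests (above).
* Fixed-effects correction only: no kinship/variance-component model.
* The greedy FGT scan's boundary ambiguity (above) slightly blurs
  partition edges; association uses the inferred partitions, as the
  validation design intends.
* Haploid biallelic data only; no missing data, no VCF/PLINK ingestion.
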