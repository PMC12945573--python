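# Methods

This note records the models, numerical choices, and known limitations
behind panelkit's implementations, in the order a pipeline would use
them.

## Synthetic haplotype model

The generator is a **founder-copying model**, not a coalescent
simulator. Each planted block has a pool of founder haplotypes (default
8); every sampled haplotype copies one founder per block (uniform,
independent across blocks) and flips each allele independently at the
block's mutation rate (default 0.02). This choice trades realism for
recoverable truth: within-block LD strength is controlled directly by
the founder-pool size and mutation rate, and cross-block LD is zero in
expectation — exactly the structure the block-detection and varLD
validations need to recover. Per-variant MAF is forced into a window
(default [0.05, 0.5]) by redrawing the founder column and its flips, at
most 1,000 rounds before an explicit per-variant failure.

What the generator does **not** emulate: recombination gradients and
hotspots inside blocks (LD is distance-independent within a block),
demographic history, genotyping error, and indels. Passing recovery
tests therefore demonstrate correctness of the algorithms under clean
block structure, not their power on real genomes.

### Population divergence

`derive_populations` models drift at two coupled levels, both scaled by
the target F_ST:

1. **Haplotype composition.** Per population and block, haplotypes are
   a bootstrap of the ancestral rows under symmetric Dirichlet weights
   with total concentration (1−F)/F. This is the haplotype-frequency
   analog of the Balding–Nichols model: the induced variance of any
   haplotype-group frequency is F·q(1−q), so within-block haplotype
   composition — and with it the LD structure — drifts apart as F
   grows, while the founder patterns themselves are preserved.
2. **Allele frequency.** Per variant and population, the ancestral
   frequency p is perturbed by a Balding–Nichols draw
   Beta(p(1−F)/F, (1−p)(1−F)/F), and the realized column count is
   pinned to that draw by the minimal number of allele flips. Flips
   follow a fixed per-population priority ordering of haplotypes, so
   they accumulate on the same rows and act as additional
   population-specific haplotypes rather than white noise.

Pinning realized frequencies to the Beta draws is what makes F_ST
recovery sharp (±0.005 at 1,000 individuals × 2,000 SNPs with a
Hudson-type estimator): a naive redraw of founder columns per
population would add founder-pool sampling variance of order
1/n_founders that the estimator does not correct, biasing F̂_ST upward
by an order of magnitude more than the drift signal at small pools.
The two-level construction is also what gives varLD its monotone
response: frequency perturbation alone alters allele frequencies
without differentiating LD.

### Admixture, array masking, dosage noise, phenotypes

- `simulate_admixed` copies each block of each admixed haplotype from
  source A with probability α, else source B, and records the realized
  per-individual fraction. Ancestry is block-granular; there is no
  recombination within blocks.
- `mask_to_array` samples exactly round(fraction·m) "typed" variants
  without replacement.
- `corrupt_to_dosages` adds Gaussian noise with **constant absolute
  standard deviation** `error_scale·√0.5` (the genotype sd of a
  MAF-50% variant), clamped to [0, 2]. Relative to a variant's own
  genotype variance 2p(1−p), the noise grows as MAF falls, so the
  per-variant expected r² = 2p(1−p)/(2p(1−p)+σ²) is monotone
  increasing in MAF — the qualitative accuracy-vs-MAF profile of real
  imputation. A noise sd proportional to √(2p(1−p)) was considered and
  rejected: it cancels the signal variance exactly and produces a flat,
  MAF-independent accuracy profile.
- `simulate_phenotype` builds the phenotype on the unit-variance scale:
  y = √h²·g* + covariate effects + residual, with g* the standardized
  weighted dosage sum and sex/age effects parameterized as variance
  shares (default 0.05 each), so sample Var(g)/Var(y) targets h² by
  construction. Genotype PCs are computed from the panel's
  standardized dosages by SVD.

All generators derive their random stream from (user seed, operation
name) via CRC-32 keying, so adding one stochastic operation to a
pipeline never perturbs another's stream, and every output is a pure
function of inputs and seed.

## QC

Genotype masking (DP < 10 or GQ < 20 → missing; absent fields pass)
precedes variant filtering; call rate is computed on post-masking
calls. Variant rules run in a fixed order — call rate ≤ 0.80,
monomorphic, mean depth > 500, region mask — and each excluded variant
is attributed to the first rule it fails, so the report's counts
reconcile exactly with the input count. Relatedness pruning at kinship
≥ 2^−3.5 iteratively removes the member of the related graph with the
most partners (ties: the sample later in input order); the literature
this follows does not fix a pruning algorithm, and other defensible
rules (e.g. maximal independent set) can retain different sample sets.

## LD statistics

Two-locus haplotype LD uses the closed-form frequency definitions; the
D = 0 case is defined as r = 0, D′ = 0, sign 0. Dosage correlations use
pairwise-complete deletion; matrix routines mean-impute missing entries
for vectorization (identical when data are complete, which QC'ed
windows are). Signs follow the stored alt-allele dosage and are
therefore reference-allele dependent — irrelevant for r², |r| and D′.

The shrinkage covariance estimator multiplies off-diagonal sample
covariances by exp(−ρ_ab/2n) with ρ_ab = 4·N_e·(cM_b−cM_a)/100, zeroes
factors below 1e-8, and applies the mutation adjustment
(1−θ)²·S + (θ/2)(1−θ/2)·I with θ = (1/h)/(2n + 1/h),
h = Σ_{i<n} 1/i, n the panel haplotype count. N_e defaults to 11,418.
All three constants are exposed as arguments.

## Broad-scale blocks

Per (overlapping) chunk the shrunk covariance is computed and reduced
to a per-gap profile: the **mean** absolute off-diagonal entry on the
antidiagonal through each inter-SNP gap. The mean, rather than the raw
sum, removes the antidiagonal-length ramp (short antidiagonals near
chromosome ends), which would otherwise swamp the low-LD troughs the
minima search targets. The profile is smoothed by a centered moving
average of width 11, doubled while the count of suppressed local minima
exceeds the breakpoint budget ceil(m/target)−1, capped at a quarter of
the target block size so adjacent troughs cannot fuse. Minima selection
is deepest-first with non-maximum suppression at the smoothing scale;
each selected trough is then refined to the minimum of the
lightly-smoothed profile within one smoothing width. Candidates from
chunk overlaps within one suppression radius are reconciled by keeping
the smaller smoothed value. With fewer variants than the target, the
chromosome is one block. On planted panels (3 × 200 SNPs, 500
individuals) recovered boundaries sit within ±3 SNPs of truth across
20 seeds.

## Fine-scale blocks

The |dosage r| ≥ 0.5 adjacency graph (pairs evaluated within a
1,000-SNP window) is clustered by greedy CLQ: seed at the
highest-degree vertex, grow a maximal clique by repeatedly adding the
highest-degree common neighbor, remove the clique, repeat. Clusters
expand to their covering index interval; transitively overlapping
intervals merge; uncovered SNPs become singleton blocks. Exhaustive
maximum-clique clustering is kept as an independent oracle in the test
suite (≤ 12-SNP toys); on LD-structured inputs the greedy and exact
partitions coincide.

## varLD

Window scores use raw (unstandardized) L1 eigenvalue distances with
descending pairing; a genome-wide standardization (mean 0, sd 1) is
available behind `VarLDTrack.standardized()` for compatibility with the
original convention. Windows are defined in SNP-count space (50 SNPs,
step 1); the trailing partial window is skipped. Region calling pools
scores across all comparisons, thresholds at the (1−pct) quantile with
a strict inequality (a constant track yields no calls), and merges
overlapping qualifying windows.

## LD lookup panel

Pairs are restricted to the same chromosome within 1 Mb; the reporting
floor r² ≥ 0.2 is inclusive; monomorphic variants are skipped and
counted; no minor-allele-count floor is applied, so singleton pairs
appear — which is why panel size drives rare-variant coverage (the
detection floor of an n-sample panel is 1/2n, ≈ 0.1% at n = 489). The
builder is a generator: memory is constant in the number of pairs.
Cross-panel comparison is keyed by (chrom, pos1, pos2); strand-flip
reconciliation is deliberately not attempted.

## Imputation metrics

Aggregated r² stacks the truth and dosage entries of all variants in a
MAF bin (lower-exclusive, upper-inclusive, on the designated reference
MAF) into two vectors and squares their Pearson correlation; this is
*not* the mean of per-variant r², and the tests pin the distinction.
NRD classifies mismatches of rounded best-guess genotypes (ties round
half up) by the *true* class; concordant homozygous-reference calls
enter neither numerator nor denominator, so the rate is undefined (not
0) for all-reference data. Estimated Rsq is Var(dosage)/(2p̂(1−p̂))
with p̂ from the dosages; the carry-forward filter keeps Rsq ≥ 0.3,
inclusive. The bundled nearest-haplotype imputer is demonstration
plumbing: per individual it selects the donor pair minimizing typed
dosage mismatch among minimal-incompatibility candidates; it performs
no recombination-aware modeling.

## PRS evaluation

Scoring matches weight entries to panel variants by (chrom, pos),
flips dosages when the effect allele is the panel reference, drops
strand-ambiguous entries, and mean-imputes missing dosages. Phenotype
standardization is per sex stratum with the population (divide-by-n)
variance convention. Incremental R² is the gain in unadjusted R² when
the PRS joins intercept + age + 20 PCs, computed via a single QR
decomposition with the PRS as the last column (the reduced model's fit
is the projection onto the leading columns, so ΔR² = z_last²/TSS); an
exactly collinear PRS contributes 0 rather than an error, while
collinear covariates raise. The bootstrap resamples whole rows
(pairs bootstrap), 1,000 replicates, percentile 95% CI; rank-deficient
replicates are redrawn up to 10× the replicate budget. At a planted
0.20 variance share (n = 2,000) the point estimate is unbiased within
±0.02 and CI coverage is ≈ 95%.

## f4 and admixture proportions

f4(A,B;C,D) is the mean over complete-frequency variants of
(p_A−p_B)(p_C−p_D). The admixture proportion is the standard f4 ratio
α̂ = f4(O, X; D1, D2)/f4(O, S1; D1, D2). The quadruple configuration is
caller-supplied; the synthetic default used throughout the tests is:

- sources A and B derived from the ancestral panel at the target F_ST;
- the A sample split in half — S1 (the source proxy, and the only A
  haplotypes the admixed individuals draw from) and D1 (the first
  differentiator, fully held out);
- an independent outgroup O and a second independent lineage E (the
  other differentiator), each with its own drift from the ancestral
  panel.

Holding D1 out of the admixture is essential: if the admixed
individuals copy haplotypes that also define a differentiator, the
shared sampling noise inflates α̂ by a few percent (measured ≈ +0.023
when admixing from all of A), a classic f4-ratio pitfall. With the
held-out configuration, recovery is within ±0.03 of planted
α ∈ {0, 0.3, 0.7, 1} at 20,000 SNPs × 200 individuals. Per-individual
estimates use dosage/2 as a pseudo-frequency vector. Out-of-[0,1]
estimates are flagged, never clamped; a denominator below 1e-6 is an
error (uninformative references). Sub-population assignment applies the
published %ANI cutoffs (low ≤ 0.540 ≤ high < 0.824) to on-cline units;
estimates at or above the upper bound stay in the high group with a
warning flag, since the published range is data-driven. Cline
membership is an input label; the bundled 2-means-on-PCs labeler is
plumbing for demos only.

## Pipeline and problem sizes

The demo pipeline (`panelkit run`) chains all stages on a 150-individual,
3 × 80-SNP synthetic cohort and completes in a few seconds; reruns
under the same config and seed are byte-identical, and the manifest
records every parameter, seed, and output hash. The validation battery
uses the sizes its guarantees are stated at: 500 × 600 for block
recovery, 1,000 × 2,000 for F_ST, 200 × 20,000 for ancestry fractions,
2,000 individuals × 100 replicates × 1,000 bootstrap resamples for PRS
coverage — sizes at which the Monte-Carlo error of each recovery
target is several times smaller than its stated tolerance.

## Known limitations

- The founder-copying model has no within-block recombination, so
  broad-scale blocks are sharper than on real data; boundary-recovery
  tolerances would loosen under gradual LD decay.
- The greedy CLQ clustering is heuristic; the exact-oracle agreement is
  demonstrated on small LD-structured graphs, not adversarial ones.
- The naive imputer cannot resolve haplotypes that are identical at
  typed sites but differ at masked sites (information-theoretic, not
  algorithmic).
- varLD scores are reported raw; comparisons across window sizes or
  SNP densities require the standardized variant.
- Sign conventions of signed outputs (r, D, f4) depend on allele
  encoding and the configured group slots respectively.
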