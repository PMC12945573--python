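# panelkit

Tools for characterizing linkage disequilibrium (LD) in a sequencing
cohort and evaluating its use as a population reference panel —
for statistical geneticists building or assessing LD lookup panels,
imputation panels, and polygenic-score (PRS) transferability in
underrepresented populations.

The package implements, as a tested library with a CLI, the analysis
battery such a project needs:

- **LD statistics** on phased haplotypes and genotype dosages:
  r = D / √(p₁(1−p₁)p₂(1−p₂)), r², D′ = |D| / D_max, and the sign of D,
  with the Wen–Stephens distance-shrinkage covariance estimator
  (off-diagonal damping exp(−ρ/2n), ρ = 4·N_e·d_cM/100) used for block
  detection.
- **LD blocks at two scales**: a broad-scale partition that locates
  low-LD troughs via antidiagonal profiles of the shrunk covariance
  matrix (LDetect-style), and a fine-scale partition by clique
  clustering of the |r| ≥ 0.5 graph with interval-graph merging
  (Big-LD-style).
- **varLD** comparison of regional LD between two populations: per
  sliding 50-SNP window, the score is Σᵢ |λ_A(i) − λ_B(i)| over the
  descending-sorted eigenvalues of each population's signed-r² matrix,
  plus top-percentile region calling.
- **LD lookup panels**: all variant pairs within 1 Mb with r² ≥ 0.2
  (no minimum minor-allele count), panel summaries and cross-panel r²
  concordance.
- **Imputation accuracy**: aggregated r² (squared correlation of
  *stacked* dosage and truth vectors per MAF bin — not the mean of
  per-variant r²), nonreference discordance
  NRD = (e_rr+e_ra+e_aa)/(e_rr+e_ra+e_aa+m_ra+m_aa), and the
  Rsq ≥ 0.3 quality filter.
- **PRS evaluation**: effect-allele scoring with allele reconciliation,
  within-sex phenotype standardization, incremental R² from nested OLS
  models (age + 20 genotype PCs ± PRS), and a 1,000-resample pairs
  bootstrap for 95% CIs.
- **Population structure**: f4 statistics
  f4(A,B;C,D) = mean[(p_A−p_B)(p_C−p_D)], f4-ratio admixture
  proportions (e.g. %ANI, the Ancestral North Indian fraction),
  sub-population assignment at the published 0.540 / 0.824 cutoffs,
  and median-centroid genetic distances in PC space.
- **Cohort QC**: DP < 10 / GQ < 20 genotype masking, call-rate ≤ 80%,
  monomorphic, mean-depth > 500 and region-mask variant filters with
  exact exclusion accounting, and greedy relatedness pruning at
  kinship 2^−3.5 ≈ 0.088.
- **A synthetic-data generator** producing phased haplotype panels with
  planted LD blocks, Balding–Nichols-diverged populations at a target
  F_ST, admixed individuals with known ancestry fractions, array
  masks, imputation-like dosages, and heritable phenotypes — with full
  ground truth, so every method above is validated by recovery tests.

## Worked example

Plant three 200-SNP LD blocks in 500 diploid individuals, recover the
block boundaries, then derive two populations at F_ST = 0.10 and score
their LD difference:

```python
from panelkit import SimConfig, BlockSpec, simulate_block_haplotypes, derive_populations
from panelkit.blocks import ldetect_partition, block_ld_summary
from panelkit.containers import RecombinationMap
from panelkit.varld import varld_scores, summarize_track

cfg = SimConfig(n_individuals=500,
                blocks=tuple(BlockSpec(n_snps=200, n_founders=8, mutation_rate=0.02)
                             for _ in range(3)),
                seed=11)
panel, truth = simulate_block_haplotypes(cfg)

geno = panel.to_genotypes()
pos = geno.variants["pos"].to_numpy().astype(float)
rec_map = RecombinationMap(pos, (pos - pos[0]) / 1e6)   # 1 cM/Mb
part = ldetect_partition(geno, rec_map, target_avg_snps=200, maf_min=0.0)
print("recovered breakpoints:", part.breakpoints())

s = block_ld_summary(part, geno, seed=0)
print(f"within-block mean r2 = {s['within_block_mean_r2']:.4f}, "
      f"between-block mean r2 = {s['between_block_mean_r2']:.4f}")

popA, popB = derive_populations(panel, fst=0.10, seed=12)
track = varld_scores(popA.to_genotypes(), popB.to_genotypes())
print(summarize_track(track))
```

Output:

```
recovered breakpoints: [200 400]
within-block mean r2 = 0.1139, between-block mean r2 = 0.0021
varLD summary: {'n_windows': 551, 'mean': 4.82, 'q1': 3.43, 'median': 4.18, 'q3': 5.37, 'max': 12.14}
```

The partition recovers the planted boundaries (variants 200 and 400)
exactly; LD within blocks is ~50× stronger than across neighboring
blocks; and the 551 sliding 50-SNP windows quantify how much the two
derived populations' LD structure has drifted apart (a self-comparison
scores 0 in every window).

The same steps are available from a shell:

```bash
panelkit run --out-dir demo --seed 7          # full synthetic pipeline
panelkit blocks --method broad --vcf in.vcf --map map.txt --out blocks.bed
panelkit varld --vcf-a A.vcf --vcf-b B.vcf --out track.tsv
panelkit ld-panel --vcf in.vcf --out panel/
panelkit prs-eval --vcf in.vcf --weights w.tsv --pheno ph.tsv --out prs.json
```

`panelkit run` executes simulate → qc → blocks → varld → ld-panel →
impute-eval → prs-eval → ancestry end to end and writes a manifest with
parameter and output hashes; reruns under the same seed are
byte-identical.

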