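"""Synthetic haplotype panels with planted, recoverable structure.

The generator uses a founder-copying model rather than a coalescent
simulator: each planted block has a small pool of founder haplotypes,
every sampled haplotype copies one founder per block (independent
founder choice across blocks) with independent per-allele mutation
flips. This gives direct, tunable control of within-block LD and
exactly zero expected cross-block LD — the truth that the block
detection and varLD tests recover. Downstream generators derive
diverged populations (Balding–Nichols frequency perturbation), admixed
individuals with known ancestry fractions, array-masked genotypes,
imputation-like dosages with MAF-dependent noise, and heritable
phenotypes with sex/age covariate effects.

Every generator is a pure function of its inputs and a seed; random
streams are derived per operation (see :mod:`panelkit._rng`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import derived_rng
from .containers import GenotypeMatrix, HaplotypePanel, make_variant_table

MAX_REJECTION_ROUNDS = 1000


@dataclass(frozen=True)
class BlockSpec:
    """One planted LD block: SNP count, founder-pool size, mutation rate."""

    n_snps: int
    n_founders: int = 8
    mutation_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ValueError("n_founders must be >= 2")
        if not 0.0 <= self.mutation_rate < 1.0:
            raise ValueError("mutation_rate must be in [0, 1)")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the founder-copying haplotype simulator."""

    n_individuals: int
    blocks: tuple[BlockSpec, ...]
    maf_min: float = 0.05
    maf_max: float = 0.5
    chrom_label: str = "1"
    bp_spacing: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("need at least one individual")
        if not self.blocks:
            raise ValueError("need at least one block")
        if not 0.0 <= self.maf_min <= self.maf_max <= 0.5:
            raise ValueError("need 0 <= maf_min <= maf_max <= 0.5")
        if self.bp_spacing < 1:
            raise ValueError("bp_spacing must be >= 1")


@dataclass
class TruthSet:
    """Planted simulation parameters used as recovery targets in tests."""

    block_boundaries: np.ndarray | None = None
    fst: float | None = None
    ancestry_fraction: np.ndarray | None = None
    effect_weights: pd.DataFrame | None = None
    h2: float | None = None
    masked_sites: np.ndarray | None = None
    typed_sites: np.ndarray | None = None
    dosage_error_scale: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.block_boundaries is not None:
            bb = np.asarray(self.block_boundaries, dtype=int)
            if bb.size and np.any(np.diff(bb) <= 0):
                raise ValueError("block boundaries must be strictly increasing")
            self.block_boundaries = bb
        if self.h2 is not None and not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must be in [0, 1]")


class MAFRangeError(RuntimeError):
    """Raised when rejection resampling cannot reach the MAF window."""


def simulate_block_haplotypes(config: SimConfig) -> tuple[HaplotypePanel, TruthSet]:
    """Generate a phased panel with planted LD blocks and known truth.

    Per block, each of the ``2n`` haplotypes copies one founder
    haplotype (uniform choice) and flips each allele independently at
    the block's mutation rate. Per-variant realized MAF is forced into
    ``[maf_min, maf_max]`` by redrawing the founder column (and its
    flips) up to ``MAX_REJECTION_ROUNDS`` times.
    """
    rng = derived_rng(config.seed, "simulate_block_haplotypes")
    n_hap = 2 * config.n_individuals
    columns: list[np.ndarray] = []
    boundaries = []
    offset = 0
    for block in config.blocks:
        boundaries.append(offset)
        assign = rng.integers(0, block.n_founders, size=n_hap)
        block_cols = _draw_block(rng, assign, block, config, offset)
        columns.append(block_cols)
        offset += block.n_snps
    haplotypes = np.concatenate(columns, axis=1)
    variants = make_variant_table(
        offset, chrom=config.chrom_label, spacing=config.bp_spacing
    )
    panel = HaplotypePanel(
        haplotypes,
        variants,
        [f"S{i}" for i in range(config.n_individuals)],
        block_boundaries=np.asarray(boundaries, dtype=int),
    )
    truth = TruthSet(block_boundaries=np.asarray(boundaries, dtype=int))
    return panel, truth


def _draw_block(
    rng: np.random.Generator,
    assign: np.ndarray,
    block: BlockSpec,
    config: SimConfig,
    offset: int,
) -> np.ndarray:
    n_hap = assign.size
    m = block.n_snps
    cols = np.empty((n_hap, m), dtype=np.uint8)
    todo = np.arange(m)
    for _ in range(MAX_REJECTION_ROUNDS):
        k = todo.size
        q = rng.uniform(config.maf_min, config.maf_max, size=k)
        founders = (rng.random((block.n_founders, k)) < q).astype(np.uint8)
        drawn = founders[assign, :]
        if block.mutation_rate > 0:
            flips = rng.random((n_hap, k)) < block.mutation_rate
            drawn = drawn ^ flips
        cols[:, todo] = drawn
        freq = cols[:, todo].mean(axis=0)
        maf = np.minimum(freq, 1.0 - freq)
        bad = (maf < config.maf_min) | (maf > config.maf_max)
        if not bad.any():
            return cols
        todo = todo[bad]
    raise MAFRangeError(
        f"MAF window [{config.maf_min}, {config.maf_max}] unattainable for "
        f"variant index {offset + int(todo[0])} after {MAX_REJECTION_ROUNDS} rounds"
    )


def derive_populations(
    panel: HaplotypePanel, fst: float, seed: int
) -> tuple[HaplotypePanel, HaplotypePanel]:
    """Split a panel into two populations diverged at a target FST.

    Drift acts at two levels, both scaled by ``F``:

    * haplotype composition — each population's haplotypes are a
      per-block bootstrap of the ancestral rows under Dirichlet weights
      with concentration ``(1-F)/F`` (the haplotype-frequency analog of
      the Balding–Nichols model), so within-block haplotype frequencies
      — and therefore the LD structure — drift apart as ``F`` grows
      while the founder patterns themselves are preserved;
    * allele frequency — per variant, the ancestral alt frequency ``p``
      is perturbed per population by a Balding–Nichols draw
      ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` and the realized column count is
      pinned to that draw by the minimal number of flips, applied to a
      fixed per-population priority ordering of haplotypes so the flips
      themselves form population-specific haplotypes rather than
      white noise.

    ``fst = 0`` returns statistically exchangeable panels (plain
    bootstrap, no perturbation).
    """
    if not 0.0 <= fst < 1.0:
        raise ValueError("fst must be in [0, 1)")
    rng = derived_rng(seed, "derive_populations")
    p = panel.allele_frequencies().astype(float)
    n_hap = panel.haplotypes.shape[0]
    m = panel.n_variants
    bounds = (
        panel.block_boundaries
        if panel.block_boundaries is not None
        else np.array([0])
    )
    edges = np.append(np.asarray(bounds, dtype=int), m)
    out = []
    for label in ("A", "B"):
        hap = np.empty_like(panel.haplotypes)
        for b in range(len(edges) - 1):
            lo, hi = edges[b], edges[b + 1]
            if fst > 0:
                # symmetric Dirichlet with total concentration (1-F)/F:
                # induced haplotype-frequency variance matches BN drift
                w = rng.dirichlet(np.full(n_hap, (1.0 - fst) / (fst * n_hap)))
                idx = rng.choice(n_hap, size=n_hap, p=w)
            else:
                idx = rng.integers(0, n_hap, size=n_hap)
            hap[:, lo:hi] = panel.haplotypes[idx, lo:hi]
        if fst > 0:
            pc = np.clip(p, 1e-12, 1 - 1e-12)
            p_new = rng.beta(pc * (1 - fst) / fst, (1 - pc) * (1 - fst) / fst)
        else:
            p_new = p
        _retune_frequencies(rng, hap, p_new, priority=rng.permutation(n_hap))
        out.append(
            HaplotypePanel(
                hap,
                panel.variants.copy(),
                [f"{label}{i}" for i in range(panel.n_individuals)],
                block_boundaries=panel.block_boundaries,
            )
        )
    return out[0], out[1]


def _retune_frequencies(
    rng: np.random.Generator,
    hap: np.ndarray,
    p_target: np.ndarray,
    priority: np.ndarray | None = None,
) -> None:
    """Flip entries so column counts match the targets (in place).

    With a ``priority`` ordering, flips at different variants land on
    the same (highest-priority) haplotypes, so frequency drift carries
    haplotype-level drift: the perturbed rows become population-
    specific haplotypes and the population's LD structure diverges with
    the amount of drift, not just its allele frequencies. Without a
    priority, flip positions are drawn uniformly per column.
    """
    n_hap = hap.shape[0]
    target = np.rint(p_target * n_hap).astype(int)
    current = hap.sum(axis=0).astype(int)
    delta = target - current
    rank = None if priority is None else np.empty(n_hap, dtype=int)
    if rank is not None:
        rank[priority] = np.arange(n_hap)
    for j in np.flatnonzero(delta):
        d = int(delta[j])
        pool = np.flatnonzero(hap[:, j] == (0 if d > 0 else 1))
        k = min(abs(d), pool.size)
        if rank is None:
            flip = rng.choice(pool, size=k, replace=False)
        else:
            flip = pool[np.argsort(rank[pool])][:k]
        hap[flip, j] = 1 if d > 0 else 0


def simulate_admixed(
    panelA: HaplotypePanel,
    panelB: HaplotypePanel,
    alpha: float,
    n_individuals: int,
    seed: int,
    block_boundaries: np.ndarray | None = None,
) -> tuple[HaplotypePanel, TruthSet]:
    """Admix two source panels block-wise at ancestry proportion ``alpha``.

    Each admixed haplotype copies every block from a random ``panelA``
    haplotype with probability ``alpha``, else from ``panelB``. The
    realized per-individual A-ancestry fraction (share of copied
    segments) is recorded in the returned :class:`TruthSet`.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    keyA = panelA.variants[["chrom", "pos", "ref", "alt"]]
    keyB = panelB.variants[["chrom", "pos", "ref", "alt"]]
    if not keyA.equals(keyB):
        raise ValueError("panels must share an identical variant list")
    if block_boundaries is None:
        block_boundaries = (
            panelA.block_boundaries
            if panelA.block_boundaries is not None
            else np.array([0])
        )
    bounds = np.asarray(block_boundaries, dtype=int)
    m = panelA.n_variants
    edges = np.append(bounds, m)
    rng = derived_rng(seed, "simulate_admixed")
    n_hap = 2 * n_individuals
    n_blocks = len(bounds)
    from_a = rng.random((n_hap, n_blocks)) < alpha
    rowsA = rng.integers(0, panelA.haplotypes.shape[0], size=(n_hap, n_blocks))
    rowsB = rng.integers(0, panelB.haplotypes.shape[0], size=(n_hap, n_blocks))
    hap = np.empty((n_hap, m), dtype=np.uint8)
    for b in range(n_blocks):
        lo, hi = edges[b], edges[b + 1]
        src = np.where(
            from_a[:, [b]],
            panelA.haplotypes[rowsA[:, b], lo:hi],
            panelB.haplotypes[rowsB[:, b], lo:hi],
        )
        hap[:, lo:hi] = src
    frac = from_a.reshape(n_individuals, 2 * n_blocks).mean(axis=1)
    panel = HaplotypePanel(
        hap,
        panelA.variants.copy(),
        [f"ADM{i}" for i in range(n_individuals)],
        block_boundaries=bounds,
    )
    truth = TruthSet(block_boundaries=bounds, ancestry_fraction=frac)
    return panel, truth


def mask_to_array(
    panel: HaplotypePanel, array_fraction: float, seed: int
) -> tuple[GenotypeMatrix, TruthSet]:
    """Retain a random "typed" variant subset, as on a genotyping array.

    Exactly ``round(array_fraction * m)`` variants are sampled without
    replacement; the complement is recorded as masked sites.
    """
    if not 0.0 < array_fraction < 1.0:
        raise ValueError("array_fraction must be in (0, 1)")
    rng = derived_rng(seed, "mask_to_array")
    m = panel.n_variants
    n_typed = int(round(array_fraction * m))
    typed = np.sort(rng.choice(m, size=n_typed, replace=False))
    masked = np.setdiff1d(np.arange(m), typed)
    geno = panel.to_genotypes()
    typed_geno = GenotypeMatrix(
        geno.dosages[:, typed],
        geno.variants.iloc[typed].reset_index(drop=True),
        list(geno.samples),
    )
    truth = TruthSet(masked_sites=masked, typed_sites=typed)
    return typed_geno, truth


def corrupt_to_dosages(truth: GenotypeMatrix, error_scale: float, seed: int):
    """Perturb genotypes into imputation-like dosages.

    ``dosage = clamp(g + N(0, error_scale * sqrt(2 * 0.25)), 0, 2)``:
    the noise standard deviation is constant in dosage units
    (``error_scale`` expressed as a fraction of a MAF-50% variant's
    genotype sd), so rarer variants — whose genotype variance
    ``2 p (1-p)`` is smaller — receive proportionally noisier dosages.
    This reproduces the characteristic decay of imputation accuracy at
    low MAF without modeling an imputation HMM: the per-variant
    expected r² is ``2p(1-p) / (2p(1-p) + noise variance)``, monotone
    increasing in MAF. Per-variant estimated Rsq
    (``Var(dosage) / (2 p_hat (1 - p_hat))``) is stored alongside.
    """
    from .imputation import ImputationEvalSet, estimated_rsq

    if error_scale < 0:
        raise ValueError("error_scale must be >= 0")
    rng = derived_rng(seed, "corrupt_to_dosages")
    g = truth.dosages
    p = truth.allele_frequencies()
    sd = error_scale * np.sqrt(0.5)  # genotype sd of a MAF-50% variant
    noise = rng.normal(0.0, sd, size=g.shape) if error_scale > 0 else np.zeros(g.shape)
    dosages = np.clip(np.where(np.isnan(g), 2.0 * p[None, :], g) + noise, 0.0, 2.0)
    return ImputationEvalSet(
        truth=truth,
        dosages=dosages,
        est_rsq=estimated_rsq(dosages),
        maf_reference=np.minimum(p, 1.0 - p),
        dosage_error_scale=error_scale,
    )


def simulate_phenotype(
    panel: HaplotypePanel,
    weights: pd.DataFrame,
    h2: float,
    seed: int,
    sex_var_share: float = 0.05,
    age_var_share: float = 0.05,
    n_pcs: int = 20,
) -> tuple[pd.DataFrame, TruthSet]:
    """Simulate a heritable quantitative phenotype with covariates.

    The genetic value ``g`` is the weighted effect-allele dosage sum
    (see :func:`panelkit.prs.score_prs`); the phenotype is built on the
    unit-variance scale as ``sqrt(h2) g* + covariate effects + noise``
    with sex and age effects sized by variance share, so the sample
    ``Var(g)/Var(y)`` targets ``h2`` by construction. Genotype PCs are
    computed from the panel's standardized dosages.

    Returns the phenotype/covariate table (columns ``sample,
    phenotype, sex, age, PC1..PCk``) and a :class:`TruthSet` recording
    weights, ``h2``, and the genetic values.
    """
    from .prs import score_prs

    if not 0.0 <= h2 <= 1.0:
        raise ValueError("h2 must be in [0, 1]")
    resid_share = 1.0 - h2 - sex_var_share - age_var_share
    if resid_share < 0:
        raise ValueError("h2 + covariate variance shares exceed 1")
    rng = derived_rng(seed, "simulate_phenotype")
    geno = panel.to_genotypes()
    n = geno.n_samples
    g = score_prs(geno, weights)
    if h2 > 0:
        if np.std(g) == 0:
            raise ValueError("genetic value has zero variance but h2 > 0")
        g_std = (g - g.mean()) / g.std()
    else:
        g_std = np.zeros(n)
    sex = rng.integers(1, 3, size=n)
    age = rng.uniform(60.0, 90.0, size=n)
    sex_c = (sex - sex.mean()) / max(sex.std(), 1e-12)
    age_c = (age - age.mean()) / age.std()
    noise = rng.normal(size=n)
    y = (
        np.sqrt(h2) * g_std
        + np.sqrt(sex_var_share) * sex_c
        + np.sqrt(age_var_share) * age_c
        + np.sqrt(resid_share) * (noise - noise.mean()) / noise.std()
    )
    pcs = _genotype_pcs(geno.dosages, n_pcs)
    table = pd.DataFrame({"sample": geno.samples, "phenotype": y, "sex": sex, "age": age})
    for k in range(pcs.shape[1]):
        table[f"PC{k + 1}"] = pcs[:, k]
    truth = TruthSet(
        effect_weights=weights.copy(),
        h2=h2,
        extras={"genetic_value": np.sqrt(h2) * g_std, "raw_genetic_value": g},
    )
    return table, truth


def _genotype_pcs(dosages: np.ndarray, n_pcs: int) -> np.ndarray:
    """Top principal-component scores of the standardized dosage matrix."""
    X = dosages - np.nanmean(dosages, axis=0)
    X = np.nan_to_num(X)
    sd = X.std(axis=0)
    keep = sd > 0
    X = X[:, keep] / sd[keep]
    k = min(n_pcs, min(X.shape) - 1)
    if k < 1:
        return np.zeros((dosages.shape[0], n_pcs))
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = u[:, :k] * s[:k]
    out = np.zeros((dosages.shape[0], n_pcs))
    out[:, :k] = scores
    return out
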