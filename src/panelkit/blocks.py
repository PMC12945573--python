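"""Chromosome partitioning into LD blocks at two scales.

Broad scale: a shrinkage-covariance / antidiagonal-trough procedure.
The chromosome is split into overlapping chunks; per chunk a
distance-shrunk covariance matrix is computed, the absolute off-diagonal
entries are summed along antidiagonals (one value per inter-SNP gap),
the profile is smoothed with a centered moving average whose width is
doubled until few enough local minima remain, and the deepest minima
become block breakpoints.

Fine scale: clique-based clustering (CLQ) of the |r| >= threshold
adjacency graph, expansion of each clique to its covering index
interval, and merging of mutually overlapping intervals (interval-graph
connected components). SNPs in no cluster become singleton blocks.

Both methods return an ordered, non-overlapping, covering partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, RecombinationMap, is_strand_ambiguous
from .ld import genotype_maf, interpolate_cM, shrinkage_covariance

SMOOTH_INITIAL_WIDTH = 11
CHUNK_SNPS = 5000
CHUNK_OVERLAP_SNPS = 500
PAIR_WINDOW_SNPS = 1000


@dataclass(frozen=True)
class LDBlock:
    chrom: str
    start_index: int
    end_index: int  # inclusive
    start_pos: int
    end_pos: int

    def __post_init__(self) -> None:
        if self.end_index < self.start_index:
            raise ValueError("block end before start")

    @property
    def n_snps(self) -> int:
        return self.end_index - self.start_index + 1


@dataclass
class BlockPartition:
    """Ordered, non-overlapping, covering blocks on one chromosome."""

    blocks: list[LDBlock]
    method: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        prev_end = -1
        for b in self.blocks:
            if b.start_index != prev_end + 1:
                raise ValueError("blocks must be contiguous in index space")
            prev_end = b.end_index

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def breakpoints(self) -> np.ndarray:
        """Start indices of blocks after the first."""
        return np.array([b.start_index for b in self.blocks[1:]], dtype=int)

    def block_of(self) -> np.ndarray:
        """Block label per variant index."""
        labels = np.empty(self.blocks[-1].end_index + 1, dtype=int)
        for k, b in enumerate(self.blocks):
            labels[b.start_index : b.end_index + 1] = k
        return labels

    def to_bed(self) -> pd.DataFrame:
        """0-based half-open BED intervals."""
        return pd.DataFrame(
            {
                "chrom": [b.chrom for b in self.blocks],
                "start": [b.start_pos - 1 for b in self.blocks],
                "end": [b.end_pos for b in self.blocks],
            }
        )


def _blocks_from_breakpoints(
    variants: pd.DataFrame, breakpoints, method: str, parameters: dict
) -> BlockPartition:
    m = len(variants)
    starts = [0] + sorted(int(b) for b in breakpoints) + [m]
    chrom = str(variants["chrom"].iloc[0])
    pos = variants["pos"].to_numpy()
    blocks = [
        LDBlock(chrom, s, e - 1, int(pos[s]), int(pos[e - 1]))
        for s, e in zip(starts[:-1], starts[1:])
        if e > s
    ]
    return BlockPartition(blocks, method, parameters)


def antidiagonal_profile(cov: np.ndarray) -> np.ndarray:
    """Mean |off-diagonal entry| on the antidiagonal through each gap.

    Entry ``t`` (gap between SNPs ``t`` and ``t+1``) aggregates
    ``|C[i, j]|`` over ``i < j`` with ``i + j = 2t + 1`` — the
    antidiagonal that straddles the gap. The aggregate is the mean, not
    the raw sum: antidiagonal length varies with position (short near
    the chromosome ends), and a raw sum would ramp with length and
    swamp the low-LD troughs the minima search is after. Low values
    mark low-LD gaps regardless of sign convention.
    """
    m = cov.shape[0]
    a = np.abs(cov)
    prof = np.zeros(m - 1)
    for t in range(m - 1):
        k = 2 * t + 1
        i = np.arange(max(0, k - m + 1), k // 2 + 1)
        j = k - i
        prof[t] = a[i, j].mean()
    return prof


def moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with edge truncation."""
    if width <= 1 or x.size == 0:
        return x.astype(float)
    half = width // 2
    csum = np.cumsum(np.concatenate(([0.0], x)))
    out = np.empty_like(x, dtype=float)
    for i in range(x.size):
        lo = max(0, i - half)
        hi = min(x.size, i + half + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def local_minima(x: np.ndarray) -> np.ndarray:
    """Indices of strict local minima (plateaus collapse to their start)."""
    mins = []
    i = 1
    n = x.size
    while i < n - 1:
        if x[i] < x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j < n - 1 and x[j + 1] > x[i]:
                mins.append(i)
            i = j + 1
        else:
            i += 1
    return np.asarray(mins, dtype=int)


def _chunk_breakpoints(
    genotypes: GenotypeMatrix,
    cM: np.ndarray,
    lo: int,
    hi: int,
    n_break: int,
    ne: float,
    max_width: int = 10**9,
) -> list[tuple[int, float]]:
    """Breakpoints (global start index, smoothed depth) within one chunk."""
    sub = GenotypeMatrix(
        genotypes.dosages[:, lo:hi],
        genotypes.variants.iloc[lo:hi].reset_index(drop=True),
        list(genotypes.samples),
    )
    cov = shrinkage_covariance(sub, cM[lo:hi], ne=ne)
    prof = antidiagonal_profile(cov)
    if prof.size == 0 or n_break <= 0:
        return []
    def suppressed_minima(smoothed: np.ndarray, width: int) -> list[int]:
        # deepest-first with non-maximum suppression: noise jitter can
        # split one trough into adjacent minima, which must not count
        # (or be selected) as separate candidate breakpoints
        mins = local_minima(smoothed)
        sep = max(width, SMOOTH_INITIAL_WIDTH)
        kept: list[int] = []
        for t in mins[np.argsort(smoothed[mins])]:
            if all(abs(int(t) - u) > sep for u in kept):
                kept.append(int(t))
        return kept

    width = SMOOTH_INITIAL_WIDTH
    smoothed = moving_average(prof, width)
    candidates = suppressed_minima(smoothed, width)
    while len(candidates) > n_break and 2 * width <= max_width:
        width *= 2
        wider = moving_average(prof, width)
        wider_cands = suppressed_minima(wider, width)
        if not wider_cands:
            break  # over-smoothed to a monotone/unimodal profile; keep previous
        smoothed, candidates = wider, wider_cands
    if not candidates:
        return []
    # refine each selected trough on the lightly smoothed profile: wide
    # smoothing locates the trough robustly but jitters its position
    fine = moving_average(prof, SMOOTH_INITIAL_WIDTH)
    refined = []
    for t in candidates[:n_break]:
        a, b = max(0, t - width), min(prof.size, t + width + 1)
        refined.append(a + int(np.argmin(fine[a:b])))
    # gap t separates SNP t from t+1: breakpoint = global start index t+1
    return [(lo + t + 1, float(smoothed[t])) for t in sorted(refined)]


def ldetect_partition(
    genotypes: GenotypeMatrix,
    rec_map: RecombinationMap,
    target_avg_snps: int = 7000,
    maf_min: float = 0.01,
    chunk_snps: int = CHUNK_SNPS,
    chunk_overlap_snps: int = CHUNK_OVERLAP_SNPS,
    ne: float = 11418.0,
) -> BlockPartition:
    """Broad-scale partition via shrinkage covariance antidiagonal troughs.

    Expects MAF-filtered input (``maf_min`` is verified, not applied).
    The number of breakpoints is ``ceil(m / target_avg_snps) - 1``; with
    fewer variants than the target the whole chromosome is one block.
    """
    maf = genotype_maf(genotypes)
    if np.any(maf < maf_min):
        raise ValueError(
            f"{int((maf < maf_min).sum())} variants below maf_min={maf_min}; "
            "filter before partitioning"
        )
    m = genotypes.n_variants
    params = {
        "target_avg_snps": target_avg_snps,
        "maf_min": maf_min,
        "chunk_snps": chunk_snps,
        "chunk_overlap_snps": chunk_overlap_snps,
        "ne": ne,
    }
    n_break = int(np.ceil(m / target_avg_snps)) - 1
    if n_break <= 0:
        return _blocks_from_breakpoints(genotypes.variants, [], "broad", params)
    cM = interpolate_cM(rec_map, genotypes.variants["pos"].to_numpy())
    # overlapping chunks; breakpoints allocated proportionally to chunk size
    starts = list(range(0, max(m - chunk_overlap_snps, 1), chunk_snps - chunk_overlap_snps))
    candidates: list[tuple[int, float]] = []
    for lo in starts:
        hi = min(lo + chunk_snps, m)
        frac = (hi - lo) / m
        k = max(1, int(round(n_break * frac))) if len(starts) > 1 else n_break
        # smoothing wider than ~1/4 of a target block would fuse the
        # troughs of adjacent breakpoints into one
        max_width = max(SMOOTH_INITIAL_WIDTH, target_avg_snps // 4)
        candidates.extend(_chunk_breakpoints(genotypes, cM, lo, hi, k, ne, max_width))
        if hi >= m:
            break
    # reconcile near-duplicate candidates from chunk overlap: prefer the
    # smaller smoothed value (separation at the smoothing scale, so
    # distinct breakpoints are never fused)
    candidates.sort(key=lambda c: (c[0], c[1]))
    merged: list[tuple[int, float]] = []
    for idx, depth in candidates:
        if merged and abs(idx - merged[-1][0]) <= max_width:
            if depth < merged[-1][1]:
                merged[-1] = (idx, depth)
        else:
            merged.append((idx, depth))
    merged.sort(key=lambda c: c[1])
    chosen = sorted(idx for idx, _ in merged[:n_break])
    return _blocks_from_breakpoints(genotypes.variants, chosen, "broad", params)


# ---------------------------------------------------------------------------
# fine-scale (clique-based) partitioning


def _abs_r_adjacency(
    genotypes: GenotypeMatrix, r_threshold: float, pair_window_snps: int
) -> dict[int, set[int]]:
    m = genotypes.n_variants
    X = genotypes.dosages
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), col_mean[None, :], X)
    sd = X.std(axis=0)
    Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    adj: dict[int, set[int]] = {i: set() for i in range(m)}
    step = max(pair_window_snps, 1)
    for lo in range(0, m, step):
        hi = min(lo + 2 * step, m)
        r = (Z[:, lo:hi].T @ Z[:, lo:hi]) / Z.shape[0]
        ii, jj = np.nonzero(np.abs(r) >= r_threshold)
        for a, b in zip(ii, jj):
            i, j = lo + int(a), lo + int(b)
            if i < j and j - i <= pair_window_snps and sd[i] > 0 and sd[j] > 0:
                adj[i].add(j)
                adj[j].add(i)
    return adj


def clq_clusters(adj: dict[int, set[int]]) -> list[list[int]]:
    """Greedy CLQ: grow a maximal clique from the highest-degree vertex,
    remove its members, repeat until no edges remain."""
    neighbours = {v: set(nb) for v, nb in adj.items()}
    clusters: list[list[int]] = []
    while True:
        active = [v for v, nb in neighbours.items() if nb]
        if not active:
            break
        seed = max(active, key=lambda v: (len(neighbours[v]), -v))
        clique = [seed]
        cands = set(neighbours[seed])
        while cands:
            v = max(cands, key=lambda u: (len(neighbours[u]), -u))
            clique.append(v)
            cands &= neighbours[v]
        clusters.append(sorted(clique))
        for v in clique:
            for u in neighbours[v]:
                neighbours[u].discard(v)
            neighbours[v] = set()
    return clusters


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Connected components of the interval-overlap graph, as intervals."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [ivs[0]]
    for lo, hi in ivs[1:]:
        if lo <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], hi))
        else:
            out.append((lo, hi))
    return out


def bigld_partition(
    genotypes: GenotypeMatrix,
    r_threshold: float = 0.5,
    maf_min: float = 0.01,
    pair_window_snps: int = PAIR_WINDOW_SNPS,
) -> BlockPartition:
    """Fine-scale partition by clique clustering of the |r| graph."""
    maf = genotype_maf(genotypes)
    if np.any(maf < maf_min):
        raise ValueError(
            f"{int((maf < maf_min).sum())} variants below maf_min={maf_min}; "
            "filter before partitioning"
        )
    adj = _abs_r_adjacency(genotypes, r_threshold, pair_window_snps)
    clusters = clq_clusters(adj)
    intervals = [(c[0], c[-1]) for c in clusters]
    merged = merge_intervals(intervals)
    breakpoints: list[int] = []
    m = genotypes.n_variants
    cursor = 0
    for lo, hi in merged:
        # singleton blocks for uncovered SNPs before this interval
        for s in range(cursor, lo):
            breakpoints.append(s)
        breakpoints.append(lo)
        cursor = hi + 1
    for s in range(cursor, m):
        breakpoints.append(s)
    breakpoints = sorted(set(breakpoints) - {0})
    params = {
        "r_threshold": r_threshold,
        "maf_min": maf_min,
        "pair_window_snps": pair_window_snps,
    }
    return _blocks_from_breakpoints(genotypes.variants, breakpoints, "fine", params)


def block_ld_summary(
    partition: BlockPartition,
    genotypes: GenotypeMatrix,
    max_pairs_per_block: int = 50000,
    seed: int = 0,
) -> dict:
    """Mean r² within blocks and across adjacent block pairs.

    Pair sets larger than ``max_pairs_per_block`` are subsampled with
    the recorded seed. Empty pair sets (e.g., all single-variant
    blocks) are reported as None, not 0.
    """
    rng = np.random.default_rng(seed)
    X = genotypes.dosages
    sd = X.std(axis=0)
    Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    def mean_r2(pairs: np.ndarray) -> float | None:
        if pairs.size == 0:
            return None
        if pairs.shape[0] > max_pairs_per_block:
            pick = rng.choice(pairs.shape[0], max_pairs_per_block, replace=False)
            pairs = pairs[pick]
        r = (Z[:, pairs[:, 0]] * Z[:, pairs[:, 1]]).mean(axis=0)
        return float((r * r).mean())

    within_pairs = []
    for b in partition.blocks:
        idx = np.arange(b.start_index, b.end_index + 1)
        if idx.size >= 2:
            ii, jj = np.triu_indices(idx.size, k=1)
            within_pairs.append(np.column_stack([idx[ii], idx[jj]]))
    between_pairs = []
    for a, b in zip(partition.blocks[:-1], partition.blocks[1:]):
        ia = np.arange(a.start_index, a.end_index + 1)
        ib = np.arange(b.start_index, b.end_index + 1)
        grid = np.array(np.meshgrid(ia, ib)).reshape(2, -1).T
        between_pairs.append(grid)
    within = mean_r2(np.concatenate(within_pairs) if within_pairs else np.empty((0, 2), int))
    between = mean_r2(np.concatenate(between_pairs) if between_pairs else np.empty((0, 2), int))
    return {"within_block_mean_r2": within, "between_block_mean_r2": between, "seed": seed}


def export_block_correlations(
    partition: BlockPartition,
    genotypes: GenotypeMatrix,
    snp_subset: set[str] | list[str],
    maf_min: float = 0.01,
    log=None,
) -> dict[int, pd.DataFrame]:
    """Per-block SNP-SNP Pearson correlation matrices on a SNP subset.

    Restricts each block to the given SNP ids (e.g., a HapMap3-style
    list), then drops SNPs with MAF < 1% or strand-ambiguous alleles.
    Blocks with fewer than 2 surviving SNPs are skipped with a log
    line.
    """
    subset = set(snp_subset)
    if not subset:
        raise ValueError("empty SNP subset")
    ids = genotypes.variants["id"].to_numpy()
    maf = genotype_maf(genotypes)
    ambiguous = np.array(
        [
            is_strand_ambiguous(r, a)
            for r, a in zip(genotypes.variants["ref"], genotypes.variants["alt"])
        ]
    )
    eligible = np.array([s in subset for s in ids]) & (maf >= maf_min) & ~ambiguous
    out: dict[int, pd.DataFrame] = {}
    emit = log or (lambda msg: None)
    for k, b in enumerate(partition.blocks):
        idx = np.arange(b.start_index, b.end_index + 1)
        idx = idx[eligible[idx]]
        if idx.size < 2:
            emit(f"block {k} skipped: {idx.size} eligible SNPs")
            continue
        X = genotypes.dosages[:, idx]
        if np.isnan(X).any():
            X = np.where(np.isnan(X), np.nanmean(X, axis=0)[None, :], X)
        corr = np.corrcoef(X, rowvar=False)
        out[k] = pd.DataFrame(corr, index=ids[idx], columns=ids[idx])
    return out
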