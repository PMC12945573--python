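"""Core linkage-disequilibrium statistics.

Pairwise LD on phased haplotypes (r, r², D′, sign of D), Pearson
correlation of diploid dosages with pairwise-complete deletion, signed-r²
matrices, genetic-map interpolation, and the distance-shrinkage
covariance estimator used by broad-scale block detection.

Sign conventions follow the stored alt-allele dosage; they are
reference-allele dependent, which is irrelevant to r² and |r|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, HaplotypePanel, RecombinationMap

#: default effective population size for the shrinkage estimator
DEFAULT_NE = 11418.0
#: shrink factors below this are zeroed outright
DEFAULT_ZERO_CUTOFF = 1e-8


@dataclass(frozen=True)
class LDStats:
    """Two-locus LD summary: signed r, r², normalized D′, sign of D."""

    r: float
    r2: float
    dprime: float
    sign: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.r <= 1.0 + 1e-9:
            raise ValueError("r out of [-1, 1]")
        if not -1e-9 <= self.dprime <= 1.0 + 1e-9:
            raise ValueError("D' out of [0, 1]")


def minor_allele_frequency(data, variant_index: int) -> float:
    """MAF = min(p, 1-p) over non-missing calls at one variant."""
    if isinstance(data, HaplotypePanel):
        col = data.haplotypes[:, variant_index].astype(float)
        p = col.mean()
    elif isinstance(data, GenotypeMatrix):
        col = data.dosages[:, variant_index]
        ok = ~np.isnan(col)
        if not ok.any():
            raise ValueError(f"variant {variant_index} has no non-missing calls")
        p = col[ok].mean() / 2.0
    else:
        col = np.asarray(data, dtype=float)[:, variant_index]
        ok = ~np.isnan(col)
        if not ok.any():
            raise ValueError(f"variant {variant_index} has no non-missing calls")
        p = col[ok].mean() / (2.0 if np.nanmax(col) > 1 else 1.0)
    return float(min(p, 1.0 - p))


def haplotype_maf(panel: HaplotypePanel) -> np.ndarray:
    p = panel.allele_frequencies()
    return np.minimum(p, 1.0 - p)


def genotype_maf(genotypes: GenotypeMatrix) -> np.ndarray:
    p = genotypes.allele_frequencies()
    return np.minimum(p, 1.0 - p)


def haplotype_ld(panel: HaplotypePanel, i: int, j: int) -> LDStats:
    """LD between two variants from phased haplotype frequencies.

    With alt frequencies ``p_i, p_j`` and joint alt-alt haplotype
    frequency ``p_ij``: ``D = p_ij - p_i p_j``,
    ``r = D / sqrt(p_i(1-p_i) p_j(1-p_j))``, and ``D' = |D| / D_max``
    where ``D_max = min(p_i p_j, (1-p_i)(1-p_j))`` for ``D < 0`` and
    ``min(p_i(1-p_j), (1-p_i)p_j)`` otherwise.
    """
    a = panel.haplotypes[:, i].astype(float)
    b = panel.haplotypes[:, j].astype(float)
    p_i, p_j = a.mean(), b.mean()
    if p_i in (0.0, 1.0) or p_j in (0.0, 1.0):
        raise ValueError("monomorphic variant: correlation undefined")
    p_ij = (a * b).mean()
    d = p_ij - p_i * p_j
    r = d / np.sqrt(p_i * (1 - p_i) * p_j * (1 - p_j))
    if d == 0:
        return LDStats(0.0, 0.0, 0.0, 0)
    if d < 0:
        dmax = min(p_i * p_j, (1 - p_i) * (1 - p_j))
    else:
        dmax = min(p_i * (1 - p_j), (1 - p_i) * p_j)
    return LDStats(float(r), float(r * r), float(abs(d) / dmax), int(np.sign(d)))


def dosage_r(genotypes: GenotypeMatrix, i: int, j: int) -> float:
    """Pearson correlation of two dosage columns, pairwise-complete."""
    a = genotypes.dosages[:, i]
    b = genotypes.dosages[:, j]
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 pairwise-complete samples")
    a, b = a[ok], b[ok]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("constant dosage column: correlation undefined")
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def signed_r2_matrix(genotypes: GenotypeMatrix, window=None) -> np.ndarray:
    """Matrix of sign(r)·r² over a variant index range; unit diagonal.

    Missing dosages are mean-imputed for the vectorized product (the
    per-pair contract is pairwise-complete deletion; with no missing
    data the two coincide, and callers pass QC'ed windows).
    """
    idx = np.arange(genotypes.n_variants) if window is None else np.asarray(window)
    X = genotypes.dosages[:, idx]
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), col_mean[None, :], X)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = idx[np.flatnonzero(sd == 0)]
        raise ValueError(f"constant dosage column(s) at variant index {bad.tolist()}")
    Z = (X - X.mean(axis=0)) / sd
    r = (Z.T @ Z) / Z.shape[0]
    np.clip(r, -1.0, 1.0, out=r)
    m = np.sign(r) * r * r
    np.fill_diagonal(m, 1.0)
    return m


def interpolate_cM(rec_map: RecombinationMap, positions) -> np.ndarray:
    """Piecewise-linear cumulative cM at base-pair positions (clamped ends)."""
    pos = np.asarray(positions, dtype=float)
    return np.interp(pos, rec_map.positions, rec_map.cumulative_cM)


def read_recombination_map(path) -> RecombinationMap:
    """Read a HapMap-style 4-column genetic map (header tolerated).

    Columns: chrom, position(bp), rate(cM/Mb), cumulative cM.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    # drop a header line if the position column is not numeric
    if not df.iloc[0, 1].replace(".", "", 1).lstrip("-").isdigit():
        df = df.iloc[1:]
    pos = df.iloc[:, 1].astype(float).to_numpy()
    cm = df.iloc[:, 3].astype(float).to_numpy()
    order = np.argsort(pos)
    return RecombinationMap(pos[order], cm[order])


def wen_stephens_theta(n_haplotypes: int) -> float:
    """Mutation adjustment θ from the panel haplotype count (harmonic form)."""
    h = np.sum(1.0 / np.arange(1, n_haplotypes))
    return float((1.0 / h) / (2.0 * n_haplotypes + 1.0 / h))


def shrinkage_covariance(
    genotypes: GenotypeMatrix,
    cM: np.ndarray,
    ne: float = DEFAULT_NE,
    n_haplotypes: int | None = None,
    zero_cutoff: float = DEFAULT_ZERO_CUTOFF,
) -> np.ndarray:
    """Distance-shrunk covariance of dosages with mutation adjustment.

    Off-diagonal sample covariances are damped by
    ``exp(-rho_ab / (2 n_hap))`` with ``rho_ab = 4 Ne (cM_b - cM_a)/100``
    and zeroed below ``zero_cutoff``; the damped matrix is then blended
    as ``(1-θ)² S + θ/2 (1-θ/2) I`` with θ from
    :func:`wen_stephens_theta`. Distant pairs therefore decouple, which
    is what makes antidiagonal sums dip at block boundaries.
    """
    cM = np.asarray(cM, dtype=float)
    if cM.shape[0] != genotypes.n_variants:
        raise ValueError("cM vector not aligned to variant columns")
    if n_haplotypes is None:
        n_haplotypes = 2 * genotypes.n_samples
    X = genotypes.dosages
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), col_mean[None, :], X)
    S = np.cov(X, rowvar=False)
    S = np.atleast_2d(S)
    rho = 4.0 * ne * np.abs(cM[None, :] - cM[:, None]) / 100.0
    shrink = np.exp(-rho / (2.0 * n_haplotypes))
    shrink[shrink < zero_cutoff] = 0.0
    np.fill_diagonal(shrink, 1.0)
    theta = wen_stephens_theta(n_haplotypes)
    out = (1.0 - theta) ** 2 * (S * shrink)
    out[np.diag_indices_from(out)] += theta / 2.0 * (1.0 - theta / 2.0)
    return out
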