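"""Core in-memory containers shared across the toolkit.

The substrate for all LD computation is a phased haplotype panel: a
``2n x m`` binary matrix (``n`` diploid individuals, ``m`` variants,
columns sorted by position) plus variant and sample metadata. Diploid
dosages live in a :class:`GenotypeMatrix` (``n x m`` over {0, 1, 2} with
NaN for missing calls). Variant metadata is a :class:`pandas.DataFrame`
with columns ``chrom, pos, id, ref, alt`` (1-based positions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]

#: alleles that are their own reverse complement; unsafe to match across strands
AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def _check_variants(variants: pd.DataFrame, n_cols: int) -> pd.DataFrame:
    if list(variants.columns[:5]) != VARIANT_COLUMNS:
        missing = [c for c in VARIANT_COLUMNS if c not in variants.columns]
        if missing:
            raise ValueError(f"variant table missing columns {missing}")
        variants = variants[VARIANT_COLUMNS + [c for c in variants.columns if c not in VARIANT_COLUMNS]]
    if len(variants) != n_cols:
        raise ValueError(f"variant table has {len(variants)} rows for {n_cols} matrix columns")
    pos = variants["pos"].to_numpy()
    for chrom in variants["chrom"].unique():
        p = pos[variants["chrom"].to_numpy() == chrom]
        if np.any(np.diff(p) <= 0):
            raise ValueError(f"positions not strictly increasing on {chrom}")
    return variants.reset_index(drop=True)


def is_strand_ambiguous(ref: str, alt: str) -> bool:
    """True for A/T and C/G SNPs, whose strand cannot be resolved."""
    return (str(ref).upper(), str(alt).upper()) in AMBIGUOUS_PAIRS


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes with variant and sample metadata.

    Haplotype rows ``2i`` and ``2i + 1`` belong to individual ``i``.
    """

    haplotypes: np.ndarray
    variants: pd.DataFrame
    samples: list[str]
    phased: bool = True
    #: variant indices where planted LD blocks start (simulation provenance)
    block_boundaries: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        if self.haplotypes.size and not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype entries must be 0/1")
        if self.haplotypes.shape[0] != 2 * len(self.samples):
            raise ValueError("haplotype row count must be 2 x sample count")
        self.variants = _check_variants(self.variants, self.haplotypes.shape[1])
        if self.block_boundaries is not None:
            self.block_boundaries = np.asarray(self.block_boundaries, dtype=int)

    @property
    def n_individuals(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Alt-allele frequency per variant."""
        return self.haplotypes.mean(axis=0)

    def to_genotypes(self) -> "GenotypeMatrix":
        """Collapse phased haplotypes into diploid dosages."""
        dos = self.haplotypes[0::2].astype(float) + self.haplotypes[1::2]
        return GenotypeMatrix(dos, self.variants.copy(), list(self.samples))


@dataclass
class GenotypeMatrix:
    """Diploid dosages over {0, 1, 2}; NaN marks a missing call."""

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix")
        if self.dosages.shape[0] != len(self.samples):
            raise ValueError("dosage row count must equal sample count")
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if self.dosages.size and not ok.all():
            raise ValueError("genotype dosages must be 0/1/2 or missing")
        self.variants = _check_variants(self.variants, self.dosages.shape[1])

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Alt-allele frequency per variant over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0


@dataclass
class RecombinationMap:
    """Cumulative genetic map: base-pair knots with non-decreasing cM."""

    positions: np.ndarray
    cumulative_cM: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.cumulative_cM = np.asarray(self.cumulative_cM, dtype=float)
        if self.positions.size == 0:
            raise ValueError("empty recombination map")
        if self.positions.shape != self.cumulative_cM.shape:
            raise ValueError("map positions and cM arrays differ in length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("map positions must be strictly increasing")
        if np.any(np.diff(self.cumulative_cM) < 0):
            raise ValueError("cumulative cM must be non-decreasing")


def make_variant_table(
    n: int,
    chrom: str = "1",
    start: int = 1,
    spacing: int = 1000,
    ref: str = "A",
    alt: str = "G",
) -> pd.DataFrame:
    """Uniformly spaced variant metadata, 1-based positions."""
    pos = start + spacing * np.arange(n, dtype=np.int64)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "id": [f"{chrom}:{p}" for p in pos],
            "ref": ref,
            "alt": alt,
        }
    )
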