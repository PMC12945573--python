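"""LD lookup panels: pairwise statistics within a distance window.

A lookup panel reports, for every same-chromosome variant pair within
1 Mb, the haplotype r², D′ and the sign of D — but only for pairs with
r² at or above a reporting floor (default 0.2, inclusive). No minimum
minor-allele count is applied: singletons may appear, which is what
gives a large panel its rare-variant coverage advantage. The builder is
a generator (constant memory in the number of emitted pairs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .containers import HaplotypePanel
from .ld import haplotype_ld, haplotype_maf

MAX_DIST_BP = 1_000_000
R2_MIN = 0.2


@dataclass(frozen=True)
class LDPairRecord:
    chrom: str
    pos1: int
    id1: str
    pos2: int
    id2: str
    r2: float
    dprime: float
    sign: int

    def __post_init__(self) -> None:
        if self.pos2 <= self.pos1:
            raise ValueError("pairs must be ordered pos1 < pos2")


@dataclass
class PanelSummary:
    variant_counts_by_maf_bin: dict
    variants_with_partner_at_r2: dict
    pair_counts_by_r2: dict
    n_pairs: int
    n_variants_in_pairs: int

    def to_dict(self) -> dict:
        return {
            "variant_counts_by_maf_bin": {str(k): v for k, v in self.variant_counts_by_maf_bin.items()},
            "variants_with_partner_at_r2": {str(k): v for k, v in self.variants_with_partner_at_r2.items()},
            "pair_counts_by_r2": {str(k): v for k, v in self.pair_counts_by_r2.items()},
            "n_pairs": self.n_pairs,
            "n_variants_in_pairs": self.n_variants_in_pairs,
        }


def minimum_detectable_maf(n_samples: int) -> float:
    """Frequency of a single allele copy among ``2 n`` chromosomes.

    The detection floor of a sequencing panel: a variant must appear on
    at least one haplotype, so the smallest observable MAF is
    ``1 / (2 n)`` (about 0.1% for a 489-sample panel).
    """
    if n_samples < 1:
        raise ValueError("need at least one sample")
    return 1.0 / (2.0 * n_samples)


def build_lookup_panel(
    panel: HaplotypePanel,
    max_dist: int = MAX_DIST_BP,
    r2_min: float = R2_MIN,
    log=None,
) -> Iterator[LDPairRecord]:
    """Yield LD records for same-chromosome pairs within ``max_dist``.

    Monomorphic variants are skipped silently (no defined correlation)
    and counted via the optional ``log`` callable. Records come out
    ordered by (pos1, pos2).
    """
    freq = panel.allele_frequencies()
    poly = (freq > 0) & (freq < 1)
    n_mono = int((~poly).sum())
    variants = panel.variants
    pos = variants["pos"].to_numpy()
    chroms = variants["chrom"].to_numpy()
    ids = variants["id"].to_numpy()
    m = panel.n_variants
    for i in range(m):
        if not poly[i]:
            continue
        for j in range(i + 1, m):
            if chroms[j] != chroms[i] or pos[j] - pos[i] > max_dist:
                break
            if not poly[j]:
                continue
            stats = haplotype_ld(panel, i, j)
            if stats.r2 >= r2_min:
                yield LDPairRecord(
                    str(chroms[i]),
                    int(pos[i]),
                    str(ids[i]),
                    int(pos[j]),
                    str(ids[j]),
                    stats.r2,
                    stats.dprime,
                    stats.sign,
                )
    if log is not None:
        log(f"skipped {n_mono} monomorphic variants")


DEFAULT_R2_CUTOFFS = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)
DEFAULT_MAF_BINS = ((0.0, 0.001), (0.001, 0.01), (0.01, 0.05), (0.05, 0.5))


def summarize_panel(
    pairs: Iterable[LDPairRecord],
    panel: HaplotypePanel,
    maf_bins=DEFAULT_MAF_BINS,
    r2_cutoffs=DEFAULT_R2_CUTOFFS,
) -> PanelSummary:
    """Tagging summary: variants with >= 1 partner and pair counts per cutoff.

    MAF bins are lower-exclusive / upper-inclusive, except the first
    bin which is closed below so singletons are binned.
    """
    partners_at: dict[float, set[str]] = {c: set() for c in r2_cutoffs}
    pair_counts: dict[float, int] = {c: 0 for c in r2_cutoffs}
    tagged: set[str] = set()
    n_pairs = 0
    for rec in pairs:
        n_pairs += 1
        tagged.update((rec.id1, rec.id2))
        for c in r2_cutoffs:
            if rec.r2 >= c:
                pair_counts[c] += 1
                partners_at[c].update((rec.id1, rec.id2))
    maf = haplotype_maf(panel)
    ids = panel.variants["id"].to_numpy()
    tag_mask = np.array([s in tagged for s in ids])
    maf_counts = {}
    for lo, hi in maf_bins:
        in_bin = (maf > lo) & (maf <= hi) if lo > 0 else (maf >= 0) & (maf <= hi)
        maf_counts[(lo, hi)] = int((in_bin & tag_mask).sum())
    return PanelSummary(
        variant_counts_by_maf_bin=maf_counts,
        variants_with_partner_at_r2={c: len(v) for c, v in partners_at.items()},
        pair_counts_by_r2=pair_counts,
        n_pairs=n_pairs,
        n_variants_in_pairs=len(tagged),
    )


def compare_panels(
    pairsA: Iterable[LDPairRecord], pairsB: Iterable[LDPairRecord]
) -> dict:
    """Pearson correlation of r² on the shared pair-key set, plus exclusives.

    Keys are (chrom, pos1, pos2); allele identity travels with the
    variant ids. An empty intersection yields an undefined (None)
    correlation.
    """
    a = {(r.chrom, r.pos1, r.pos2): r.r2 for r in pairsA}
    b = {(r.chrom, r.pos1, r.pos2): r.r2 for r in pairsB}
    shared = sorted(set(a) & set(b))
    result = {
        "n_shared": len(shared),
        "n_only_a": len(set(a) - set(b)),
        "n_only_b": len(set(b) - set(a)),
        "r2_correlation": None,
    }
    if len(shared) >= 2:
        xa = np.array([a[k] for k in shared])
        xb = np.array([b[k] for k in shared])
        if xa.std() > 0 and xb.std() > 0:
            result["r2_correlation"] = float(np.corrcoef(xa, xb)[0, 1])
    return result


def write_pairs_tsv(pairs: Iterable[LDPairRecord], path) -> int:
    """Write pair records as a TSV stream; returns the row count."""
    n = 0
    with open(path, "w") as fh:
        fh.write("CHROM\tPOS1\tID1\tPOS2\tID2\tR2\tDPRIME\tSIGN\n")
        for r in pairs:
            sign = "+" if r.sign > 0 else "-" if r.sign < 0 else "0"
            fh.write(
                f"{r.chrom}\t{r.pos1}\t{r.id1}\t{r.pos2}\t{r.id2}"
                f"\t{r.r2:.6g}\t{r.dprime:.6g}\t{sign}\n"
            )
            n += 1
    return n


def read_pairs_tsv(path) -> list[LDPairRecord]:
    df = pd.read_csv(path, sep="\t")
    sign_map = {"+": 1, "-": -1, "0": 0}
    return [
        LDPairRecord(
            str(r.CHROM), int(r.POS1), str(r.ID1), int(r.POS2), str(r.ID2),
            float(r.R2), float(r.DPRIME), sign_map[str(r.SIGN)],
        )
        for r in df.itertuples(index=False)
    ]
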