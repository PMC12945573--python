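"""Regional LD comparison between two populations (varLD).

Per sliding window of 50 SNPs (advancing one SNP at a time along the
forward strand), each population's signed-r² matrix is eigendecomposed
and the score is the L1 distance between the two descending-sorted
eigenvalue spectra. Identical LD structure scores 0; the score grows
with LD differentiation. Raw (unstandardized) scores are the primary
output; genome-wide standardization is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, is_strand_ambiguous
from .ld import genotype_maf, signed_r2_matrix

WINDOW_SNPS = 50


@dataclass
class VarLDTrack:
    """Per-window scores; windows advance by one SNP."""

    windows: pd.DataFrame  # chrom, start_pos, end_pos, first_snp_index, score
    window_snps: int = WINDOW_SNPS
    comparison_label: str = ""

    def __post_init__(self) -> None:
        if len(self.windows) and (self.windows["score"] < -1e-9).any():
            raise ValueError("varLD scores must be nonnegative")

    @property
    def scores(self) -> np.ndarray:
        return self.windows["score"].to_numpy()

    def standardized(self) -> "VarLDTrack":
        """Scores centered and scaled to mean 0, sd 1 (original convention)."""
        w = self.windows.copy()
        s = w["score"]
        w["score_std"] = (s - s.mean()) / s.std(ddof=0)
        return VarLDTrack(w, self.window_snps, self.comparison_label)


@dataclass(frozen=True)
class RegionCall:
    chrom: str
    start_pos: int
    end_pos: int
    peak_score: float
    percentile_threshold: float

    def __post_init__(self) -> None:
        if self.peak_score < self.percentile_threshold:
            raise ValueError("peak below threshold")


def common_snp_set(
    popA: GenotypeMatrix, popB: GenotypeMatrix, maf_min: float = 0.01
) -> np.ndarray:
    """Indices (into popA) of SNPs usable for cross-population comparison.

    Keeps variants present in both panels (matched by chrom/pos) with
    MAF >= maf_min in both and alleles that are not strand ambiguous;
    mismatched alleles at a shared position are an error.
    """
    kb = {
        (c, p): (k, r, a)
        for k, (c, p, r, a) in enumerate(
            popB.variants[["chrom", "pos", "ref", "alt"]].itertuples(index=False)
        )
    }
    mafA = genotype_maf(popA)
    mafB = genotype_maf(popB)
    keep = []
    for i, (c, p, r, a) in enumerate(
        popA.variants[["chrom", "pos", "ref", "alt"]].itertuples(index=False)
    ):
        hit = kb.get((c, p))
        if hit is None:
            continue
        j, rb, ab = hit
        if (r, a) != (rb, ab):
            raise ValueError(f"allele mismatch at {c}:{p} ({r}/{a} vs {rb}/{ab})")
        if is_strand_ambiguous(r, a):
            continue
        if mafA[i] >= maf_min and mafB[j] >= maf_min:
            keep.append(i)
    return np.asarray(keep, dtype=int)


def varld_scores(
    popA: GenotypeMatrix,
    popB: GenotypeMatrix,
    window_snps: int = WINDOW_SNPS,
    comparison_label: str = "",
) -> VarLDTrack:
    """Sliding-window eigenvalue L1 scores; trailing partial window skipped.

    Inputs are expected to be restricted to a common SNP set (same
    variant grid in both populations).
    """
    if popA.n_variants != popB.n_variants:
        raise ValueError("populations must share the variant grid")
    m = popA.n_variants
    rows = []
    if m >= window_snps:
        rA = signed_r2_matrix(popA)
        rB = signed_r2_matrix(popB)
        pos = popA.variants["pos"].to_numpy()
        chrom = str(popA.variants["chrom"].iloc[0])
        for s in range(m - window_snps + 1):
            sl = slice(s, s + window_snps)
            evA = np.sort(np.linalg.eigvalsh(rA[sl, sl]))[::-1]
            evB = np.sort(np.linalg.eigvalsh(rB[sl, sl]))[::-1]
            score = float(np.abs(evA - evB).sum())
            rows.append((chrom, int(pos[s]), int(pos[s + window_snps - 1]), s, score))
    else:
        import warnings

        warnings.warn(
            f"only {m} shared SNPs for a {window_snps}-SNP window; empty track",
            stacklevel=2,
        )
    windows = pd.DataFrame(
        rows, columns=["chrom", "start_pos", "end_pos", "first_snp_index", "score"]
    )
    return VarLDTrack(windows, window_snps, comparison_label)


def summarize_track(track: VarLDTrack) -> dict:
    """Mean, quartiles, and max of the window scores."""
    s = track.scores
    if s.size == 0:
        raise ValueError("empty varLD track")
    q1, q2, q3 = np.percentile(s, [25, 50, 75])
    return {
        "n_windows": int(s.size),
        "mean": float(s.mean()),
        "q1": float(q1),
        "median": float(q2),
        "q3": float(q3),
        "max": float(s.max()),
    }


def top_regions(tracks: list[VarLDTrack], pct: float = 0.01) -> list[RegionCall]:
    """Regions above the pooled top-``pct`` score threshold, merged per track.

    The threshold is the ``(1 - pct)`` quantile of all window scores
    pooled across tracks; windows strictly above it are merged into
    maximal overlapping regions.
    """
    if not 0.0 < pct < 1.0:
        raise ValueError("pct must be in (0, 1)")
    pooled = np.concatenate([t.scores for t in tracks if t.scores.size])
    if pooled.size == 0:
        return []
    threshold = float(np.quantile(pooled, 1.0 - pct))
    calls: list[RegionCall] = []
    for track in tracks:
        w = track.windows
        hot = w[w["score"] > threshold]
        current = None
        for row in hot.itertuples(index=False):
            if (
                current is not None
                and row.chrom == current["chrom"]
                and row.start_pos <= current["end_pos"]
            ):
                current["end_pos"] = max(current["end_pos"], row.end_pos)
                current["peak"] = max(current["peak"], row.score)
            else:
                if current is not None:
                    calls.append(
                        RegionCall(
                            current["chrom"],
                            current["start_pos"],
                            current["end_pos"],
                            current["peak"],
                            threshold,
                        )
                    )
                current = {
                    "chrom": row.chrom,
                    "start_pos": row.start_pos,
                    "end_pos": row.end_pos,
                    "peak": row.score,
                }
        if current is not None:
            calls.append(
                RegionCall(
                    current["chrom"],
                    current["start_pos"],
                    current["end_pos"],
                    current["peak"],
                    threshold,
                )
            )
    return calls
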