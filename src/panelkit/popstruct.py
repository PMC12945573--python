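"""f4 statistics, admixture proportions, and sub-population assignment.

The f4 statistic for groups (A, B; C, D) is the mean over variants of
(p_A - p_B)(p_C - p_D): it measures correlated allele-frequency drift
and vanishes when A and B are symmetric with respect to the (C, D)
contrast. A ratio of two f4 statistics estimates the mixing proportion
of an admixed group between two source populations — the construction
used to place individuals on an ancestry cline (e.g., the Ancestral
North Indian fraction, %ANI) and bin them into sub-populations at
published cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, HaplotypePanel

LOW_HIGH_CUT = 0.540
HIGH_UPPER = 0.824
DENOM_FLOOR = 1e-6


@dataclass
class FreqTable:
    """Per-variant alt-allele frequencies per labeled group."""

    freqs: pd.DataFrame  # columns = group labels, rows = variants
    sizes: dict[str, int]

    def __post_init__(self) -> None:
        vals = self.freqs.to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("frequencies must lie in [0, 1]")

    @classmethod
    def from_panels(cls, panels: dict[str, HaplotypePanel | GenotypeMatrix]) -> "FreqTable":
        cols = {}
        sizes = {}
        for label, panel in panels.items():
            cols[label] = panel.allele_frequencies()
            sizes[label] = (
                panel.n_individuals if isinstance(panel, HaplotypePanel) else panel.n_samples
            )
        return cls(pd.DataFrame(cols), sizes)

    def add_individuals(self, genotypes: GenotypeMatrix) -> "FreqTable":
        """Append per-individual pseudo-frequency columns (dosage / 2)."""
        freqs = self.freqs.copy()
        for i, s in enumerate(genotypes.samples):
            freqs[s] = genotypes.dosages[i, :] / 2.0
        sizes = dict(self.sizes, **{s: 1 for s in genotypes.samples})
        return FreqTable(freqs, sizes)


@dataclass
class AncestryResult:
    unit_id: str
    ani_fraction: float

    @property
    def out_of_range(self) -> bool:
        return not 0.0 <= self.ani_fraction <= 1.0


@dataclass(frozen=True)
class SubpopAssignment:
    unit_id: str
    label: str  # high_ANI | low_ANI | out_of_cline
    boundary_warning: bool = False


def f4(freqs: FreqTable, a: str, b: str, c: str, d: str) -> float:
    """Mean over usable variants of (p_a - p_b)(p_c - p_d).

    Variants with any missing frequency among the four groups are
    dropped; zero usable variants is an error.
    """
    sub = freqs.freqs[[a, b, c, d]].to_numpy(dtype=float)
    ok = ~np.isnan(sub).any(axis=1)
    if not ok.any():
        raise ValueError("no variants with complete frequencies for f4")
    pa, pb, pc, pd_ = sub[ok].T
    return float(np.mean((pa - pb) * (pc - pd_)))


def ancestry_fraction(
    freqs: FreqTable,
    test_unit: str,
    outgroup: str,
    source1_proxy: str,
    differentiator_pair: tuple[str, str],
    denom_floor: float = DENOM_FLOOR,
) -> AncestryResult:
    """f4-ratio admixture proportion of ``test_unit`` toward source 1.

    alpha = f4(outgroup, test; D1, D2) / f4(outgroup, source1; D1, D2).
    The differentiator pair must separate the two source lineages while
    remaining symmetric to the second source, so the ratio identifies
    the source-1 fraction. Out-of-[0, 1] estimates are retained and
    flagged, never clamped. Per-individual estimates use a diploid
    genome's dosages/2 as its frequency vector.
    """
    d1, d2 = differentiator_pair
    denom = f4(freqs, outgroup, source1_proxy, d1, d2)
    if abs(denom) < denom_floor:
        raise ValueError(
            f"uninformative references: |f4 denominator| = {abs(denom):.3g} < {denom_floor}"
        )
    num = f4(freqs, outgroup, test_unit, d1, d2)
    return AncestryResult(test_unit, num / denom)


def assign_subpopulation(
    ancestry: list[AncestryResult],
    on_cline: dict[str, bool],
    low_high_cut: float = LOW_HIGH_CUT,
    high_upper: float = HIGH_UPPER,
) -> list[SubpopAssignment]:
    """Three-way sub-population labels from %ANI and cline membership.

    Off-cline units are labeled out_of_cline regardless of the
    estimate; on-cline units are high_ANI for
    ``low_high_cut <= alpha < high_upper`` and low_ANI for
    ``alpha <= low_high_cut``. Estimates at or above the upper bound
    (the published range is data-driven) stay high_ANI with a warning
    flag.
    """
    out = []
    for res in ancestry:
        if res.unit_id not in on_cline:
            raise ValueError(f"missing cline flag for {res.unit_id}")
        if not on_cline[res.unit_id]:
            out.append(SubpopAssignment(res.unit_id, "out_of_cline"))
        elif res.ani_fraction >= high_upper:
            out.append(SubpopAssignment(res.unit_id, "high_ANI", boundary_warning=True))
        elif res.ani_fraction >= low_high_cut:
            out.append(SubpopAssignment(res.unit_id, "high_ANI"))
        else:
            out.append(SubpopAssignment(res.unit_id, "low_ANI"))
    return out


def centroid_distance(
    pc_coords: pd.DataFrame, labels: list[SubpopAssignment]
) -> pd.DataFrame:
    """Euclidean distances between per-group median centroids in PC space.

    ``pc_coords`` is indexed by unit id with PC columns.
    """
    by_label: dict[str, list[str]] = {}
    for a in labels:
        by_label.setdefault(a.label, []).append(a.unit_id)
    centroids = {}
    for label, units in by_label.items():
        sub = pc_coords.loc[units]
        if len(sub) == 0:
            raise ValueError(f"empty group {label}")
        centroids[label] = sub.median(axis=0).to_numpy(dtype=float)
    names = sorted(centroids)
    dist = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            d = float(np.linalg.norm(centroids[a] - centroids[b]))
            dist.loc[a, b] = dist.loc[b, a] = d
    return dist


def kmeans_cline_labels(pc_coords: pd.DataFrame, seed: int = 0) -> dict[str, bool]:
    """Convenience 2-means clustering on PCs into on/off-cline (plumbing).

    The larger cluster is called on-cline. Real analyses should supply
    curated cline membership; this exists so demo pipelines can run
    end-to-end.
    """
    rng = np.random.default_rng(seed)
    X = pc_coords.to_numpy(dtype=float)
    centers = X[rng.choice(len(X), size=2, replace=False)]
    for _ in range(50):
        d = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        lab = d.argmin(axis=1)
        new = np.array([X[lab == k].mean(axis=0) if (lab == k).any() else centers[k] for k in range(2)])
        if np.allclose(new, centers):
            break
        centers = new
    major = int(np.bincount(lab, minlength=2).argmax())
    return {unit: bool(lab[i] == major) for i, unit in enumerate(pc_coords.index)}
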