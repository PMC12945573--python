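"""Genotype- and variant-level quality control.

The rules mirror a deep-WGS cohort QC protocol: genotype calls are
masked (set missing) at low depth or quality, then variants are dropped
by call rate, monomorphism, extreme mean depth, or membership in an
excluded-region mask — evaluated in that order, each variant attributed
to the first rule it fails so exclusion counts reconcile exactly.
Relatedness pruning removes one member of each pair above a kinship
cutoff (default 2^-3.5 ≈ 0.088).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DP_MIN = 10
GQ_MIN = 20
CALL_RATE_MAX_EXCL = 0.80
MEAN_DEPTH_MAX = 500.0
KINSHIP_THRESHOLD = 2.0 ** -3.5

RULES = ("call_rate", "monomorphic", "mean_depth", "region_mask")


@dataclass(eq=False)
class SiteRecord:
    """One bi-allelic variant with per-sample calls and quality scores.

    ``genotypes`` holds dosages in {0, 1, 2} with NaN for missing;
    ``dp``/``gq`` may be None when the source VCF lacks those fields.
    """

    chrom: str
    pos: int
    id: str
    ref: str
    alt: str
    genotypes: np.ndarray
    dp: np.ndarray | None = None
    gq: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        self.genotypes = np.asarray(self.genotypes, dtype=float)


@dataclass
class QCReport:
    """Per-rule exclusion tallies; counts reconcile by construction."""

    n_input: int = 0
    n_genotypes_masked: int = 0
    excluded_by_rule: dict = field(
        default_factory=lambda: {rule: 0 for rule in RULES}
    )
    n_retained: int = 0

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_genotypes_masked": self.n_genotypes_masked,
            "excluded_by_rule": dict(self.excluded_by_rule),
            "n_retained": self.n_retained,
        }


def mask_low_quality_genotypes(
    record: SiteRecord, dp_min: int = DP_MIN, gq_min: int = GQ_MIN
) -> SiteRecord:
    """Set calls missing where DP < dp_min or GQ < gq_min (strict).

    Absent DP/GQ fields are treated as passing: the rule applies only
    where scores exist.
    """
    geno = record.genotypes.copy()
    masked = np.zeros(geno.shape, dtype=bool)
    if record.dp is not None:
        masked |= np.asarray(record.dp, dtype=float) < dp_min
    if record.gq is not None:
        masked |= np.asarray(record.gq, dtype=float) < gq_min
    geno[masked] = np.nan
    out = replace(record, genotypes=geno)
    out.n_masked = int((masked & ~np.isnan(record.genotypes)).sum())  # type: ignore[attr-defined]
    return out


class RegionMask:
    """1-based inclusive intervals per chromosome (BED converts on read)."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        self._by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            self._by_chrom.setdefault(str(chrom), []).append((int(start), int(end)))
        for ivs in self._by_chrom.values():
            ivs.sort()

    @classmethod
    def from_bed(cls, path) -> "RegionMask":
        """Read BED (0-based half-open) into 1-based inclusive intervals."""
        out = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end = line.split()[:3]
                out.append((chrom, int(start) + 1, int(end)))
        return cls(out)

    def contains(self, chrom: str, pos: int) -> bool:
        for start, end in self._by_chrom.get(str(chrom), ()):
            if start <= pos <= end:
                return True
        return False


def filter_variants(
    records: Iterable[SiteRecord],
    call_rate_max_excl: float = CALL_RATE_MAX_EXCL,
    mean_depth_max: float = MEAN_DEPTH_MAX,
    region_mask: RegionMask | None = None,
) -> tuple[list[SiteRecord], QCReport]:
    """Variant-level QC in the protocol's stated order.

    Drops a variant if its post-masking call rate is <= the threshold,
    OR all non-missing genotypes are identical (monomorphic), OR mean
    DP over non-missing calls exceeds the depth cap, OR its position
    falls in the region mask. Attribution goes to the first failing
    rule; output order equals input order.
    """
    report = QCReport()
    kept: list[SiteRecord] = []
    mask = region_mask or RegionMask()
    for rec in records:
        report.n_input += 1
        report.n_genotypes_masked += getattr(rec, "n_masked", 0)
        geno = rec.genotypes
        ok = ~np.isnan(geno)
        call_rate = ok.mean() if geno.size else 0.0
        if call_rate <= call_rate_max_excl:
            report.excluded_by_rule["call_rate"] += 1
            continue
        vals = geno[ok]
        if np.all(vals == vals[0]):
            report.excluded_by_rule["monomorphic"] += 1
            continue
        if rec.dp is not None:
            depth = np.asarray(rec.dp, dtype=float)[ok]
            if depth.size and depth.mean() > mean_depth_max:
                report.excluded_by_rule["mean_depth"] += 1
                continue
        if mask.contains(rec.chrom, rec.pos):
            report.excluded_by_rule["region_mask"] += 1
            continue
        kept.append(rec)
        report.n_retained += 1
    return kept, report


def select_unrelated(
    sample_ids: Sequence[str],
    kinship: pd.DataFrame,
    threshold: float = KINSHIP_THRESHOLD,
) -> list[str]:
    """Greedy relatedness pruning at a kinship cutoff.

    ``kinship`` is a long table with columns ``id1, id2, kinship``.
    While any pair at or above the threshold remains, the member with
    more related partners is removed (ties: the sample later in input
    order). Retained ids are returned in input order.
    """
    order = {s: k for k, s in enumerate(sample_ids)}
    known = set(sample_ids)
    neighbours: dict[str, set[str]] = {s: set() for s in sample_ids}
    missing = sorted(
        {x for x in pd.concat([kinship["id1"], kinship["id2"]]) if x not in known}
    )
    if missing:
        raise ValueError(f"kinship table names unknown samples: {missing}")
    for a, b, k in kinship[["id1", "id2", "kinship"]].itertuples(index=False):
        if a != b and float(k) >= threshold:
            neighbours[a].add(b)
            neighbours[b].add(a)
    removed: set[str] = set()
    while True:
        active = [s for s in sample_ids if s not in removed and neighbours[s]]
        if not active:
            break
        worst = max(active, key=lambda s: (len(neighbours[s]), order[s]))
        removed.add(worst)
        for other in neighbours[worst]:
            neighbours[other].discard(worst)
        neighbours[worst] = set()
    return [s for s in sample_ids if s not in removed]
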