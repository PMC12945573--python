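"""Genotype-imputation accuracy metrics.

Aggregated r² stacks all imputed dosages and true genotypes of the
variants in an MAF bin into two long vectors and takes their squared
Pearson correlation — deliberately not the mean of per-variant r²
values, which weights rare variants differently. Nonreference
discordance (NRD) counts genotype mismatches classified by the true
genotype class and excludes concordant homozygous-reference calls from
both numerator and denominator:

    NRD = (e_rr + e_ra + e_aa) / (e_rr + e_ra + e_aa + m_ra + m_aa)

A per-variant estimated quality score Rsq = Var(dosage) / (2 p (1-p))
supports the standard Rsq >= 0.3 carry-forward filter, and a nearest
reference-haplotype imputer is provided as plumbing for end-to-end
demonstrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, HaplotypePanel

RSQ_MIN = 0.3

#: MAF bin edges in the style of imputation-accuracy reports:
#: lower-exclusive, upper-inclusive, in frequency units
DEFAULT_MAF_BINS = (
    (0.0, 0.0002),
    (0.0002, 0.0005),
    (0.0005, 0.001),
    (0.001, 0.002),
    (0.002, 0.005),
    (0.005, 0.01),
    (0.01, 0.02),
    (0.02, 0.05),
    (0.05, 0.5),
)


@dataclass
class ImputationEvalSet:
    """Paired truth genotypes and imputed dosages with per-variant quality."""

    truth: GenotypeMatrix
    dosages: np.ndarray
    est_rsq: np.ndarray | None = None
    maf_reference: np.ndarray | None = None
    dosage_error_scale: float | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != self.truth.dosages.shape:
            raise ValueError("dosage and truth shapes differ")
        if self.dosages.size and (
            np.nanmin(self.dosages) < -1e-9 or np.nanmax(self.dosages) > 2 + 1e-9
        ):
            raise ValueError("dosages must lie in [0, 2]")
        if self.est_rsq is None:
            self.est_rsq = estimated_rsq(self.dosages)
        if self.maf_reference is None:
            p = self.truth.allele_frequencies()
            self.maf_reference = np.minimum(p, 1.0 - p)

    @property
    def n_variants(self) -> int:
        return self.truth.n_variants

    def subset_variants(self, idx: np.ndarray) -> "ImputationEvalSet":
        sub_truth = GenotypeMatrix(
            self.truth.dosages[:, idx],
            self.truth.variants.iloc[idx].reset_index(drop=True),
            list(self.truth.samples),
        )
        return ImputationEvalSet(
            sub_truth,
            self.dosages[:, idx],
            self.est_rsq[idx],
            self.maf_reference[idx],
            self.dosage_error_scale,
        )

    def subset_samples(self, rows: np.ndarray) -> "ImputationEvalSet":
        sub_truth = GenotypeMatrix(
            self.truth.dosages[rows],
            self.truth.variants.copy(),
            [self.truth.samples[i] for i in np.atleast_1d(rows)],
        )
        return ImputationEvalSet(
            sub_truth,
            self.dosages[rows],
            self.est_rsq,
            self.maf_reference,
            self.dosage_error_scale,
        )


@dataclass(frozen=True)
class NRDResult:
    e_rr: int
    e_ra: int
    e_aa: int
    m_ra: int
    m_aa: int

    @property
    def rate(self) -> float | None:
        num = self.e_rr + self.e_ra + self.e_aa
        den = num + self.m_ra + self.m_aa
        return None if den == 0 else num / den


def estimated_rsq(dosages: np.ndarray) -> np.ndarray:
    """Imputation quality: dosage variance over binomial variance 2p(1-p)."""
    d = np.asarray(dosages, dtype=float)
    p = np.nanmean(d, axis=0) / 2.0
    denom = 2.0 * p * (1.0 - p)
    var = np.nanvar(d, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsq = np.where(denom > 0, var / denom, 0.0)
    return rsq


def aggregate_r2(
    evalset: ImputationEvalSet, bins=DEFAULT_MAF_BINS
) -> pd.DataFrame:
    """Per-MAF-bin stacked-vector squared correlation.

    Bins are lower-exclusive / upper-inclusive on the reference MAF.
    Entries with missing truth are dropped; bins with constant stacked
    vectors report an undefined (NaN) r².
    """
    maf = evalset.maf_reference
    rows = []
    for lo, hi in bins:
        idx = np.flatnonzero((maf > lo) & (maf <= hi))
        r2 = np.nan
        if idx.size:
            t = evalset.truth.dosages[:, idx].ravel()
            d = evalset.dosages[:, idx].ravel()
            ok = ~np.isnan(t)
            t, d = t[ok], d[ok]
            if t.size >= 2 and t.std() > 0 and d.std() > 0:
                r2 = float(np.corrcoef(t, d)[0, 1] ** 2)
        rows.append({"maf_lo": lo, "maf_hi": hi, "n_variants": int(idx.size), "aggregated_r2": r2})
    return pd.DataFrame(rows)


def best_guess_genotypes(dosages: np.ndarray) -> np.ndarray:
    """Round dosages to the nearest of {0, 1, 2}; ties round half up."""
    return np.clip(np.floor(np.asarray(dosages, dtype=float) + 0.5), 0, 2)


def nrd(evalset: ImputationEvalSet) -> NRDResult:
    """Nonreference discordance from best-guess genotypes.

    Mismatches are classified by the TRUE genotype (hom-ref, het,
    hom-alt); matches count only for het and hom-alt truth, so
    concordant hom-ref calls never enter the formula.
    """
    truth = evalset.truth.dosages
    call = best_guess_genotypes(evalset.dosages)
    ok = ~np.isnan(truth)
    t = truth[ok]
    c = call[ok]
    mismatch = t != c
    return NRDResult(
        e_rr=int((mismatch & (t == 0)).sum()),
        e_ra=int((mismatch & (t == 1)).sum()),
        e_aa=int((mismatch & (t == 2)).sum()),
        m_ra=int((~mismatch & (t == 1)).sum()),
        m_aa=int((~mismatch & (t == 2)).sum()),
    )


def filter_by_rsq(evalset: ImputationEvalSet, rsq_min: float = RSQ_MIN) -> ImputationEvalSet:
    """Keep variants with estimated Rsq >= rsq_min (inclusive)."""
    keep = np.flatnonzero(evalset.est_rsq >= rsq_min)
    return evalset.subset_variants(keep)


def stratified_accuracy(
    evalset: ImputationEvalSet,
    groups: dict[str, str],
    bins=DEFAULT_MAF_BINS,
) -> pd.DataFrame:
    """aggregate_r2 and NRD within each sample group.

    ``groups`` maps sample id -> group label; every sample must be
    labeled. Groups with < 2 samples get undefined entries and a flag.
    """
    missing = [s for s in evalset.truth.samples if s not in groups]
    if missing:
        raise ValueError(f"unlabeled samples: {missing}")
    out = []
    labels = sorted(set(groups.values()))
    for label in labels:
        rows = np.array([i for i, s in enumerate(evalset.truth.samples) if groups[s] == label])
        flagged = rows.size < 2
        sub = evalset.subset_samples(rows) if not flagged else None
        if flagged:
            for lo, hi in bins:
                out.append(
                    {"group": label, "maf_lo": lo, "maf_hi": hi, "n_variants": 0,
                     "aggregated_r2": np.nan, "nrd": np.nan, "too_few_samples": True}
                )
            continue
        agg = aggregate_r2(sub, bins)
        group_nrd = nrd(sub).rate
        for rec in agg.itertuples(index=False):
            out.append(
                {"group": label, "maf_lo": rec.maf_lo, "maf_hi": rec.maf_hi,
                 "n_variants": rec.n_variants, "aggregated_r2": rec.aggregated_r2,
                 "nrd": np.nan if group_nrd is None else group_nrd,
                 "too_few_samples": False}
            )
    return pd.DataFrame(out)


def naive_hap_imputer(
    typed: GenotypeMatrix,
    reference: HaplotypePanel,
    masked_sites: np.ndarray,
    truth: GenotypeMatrix | None = None,
) -> ImputationEvalSet:
    """Nearest reference-haplotype imputation (demo plumbing).

    Per target individual, candidate first donors are the reference
    haplotypes with the fewest genotype incompatibilities on typed
    sites (an allele of 1 where the genotype is 0, or 0 where it is 2);
    the chosen donor pair minimizes the total typed-dosage mismatch
    ``sum |h1 + h2 - g|`` over candidates x all reference haplotypes
    (ties: lowest indices). Both donors contribute their alleles at
    masked sites; dosages are donor sums. A target individual whose
    haplotypes are in the reference is reconstructed exactly.

    Truth genotypes for the masked sites may be supplied for
    evaluation; otherwise the imputed dosages are paired with
    themselves.
    """
    if reference.n_variants == 0 or reference.n_individuals == 0:
        raise ValueError("empty reference panel")
    ref_pos = {
        (c, p): k
        for k, (c, p) in enumerate(reference.variants[["chrom", "pos"]].itertuples(index=False))
    }
    typed_idx = []
    for c, p in typed.variants[["chrom", "pos"]].itertuples(index=False):
        if (c, p) not in ref_pos:
            raise ValueError(f"typed site {c}:{p} absent from reference")
        typed_idx.append(ref_pos[(c, p)])
    typed_idx = np.asarray(typed_idx, dtype=int)
    masked_sites = np.asarray(masked_sites, dtype=int)
    R_typed = reference.haplotypes[:, typed_idx].astype(np.int16)
    R_masked = reference.haplotypes[:, masked_sites]
    n = typed.n_samples
    g = np.nan_to_num(typed.dosages)
    dosages = np.empty((n, masked_sites.size), dtype=float)
    max_candidates = 64
    for k in range(n):
        gk = g[k]
        incompat = ((gk == 0) & (R_typed == 1)).sum(axis=1) + (
            (gk == 2) & (R_typed == 0)
        ).sum(axis=1)
        cands = np.flatnonzero(incompat == incompat.min())[:max_candidates]
        # pair cost: |h1 + h2 - g| summed over typed sites
        cost = np.abs(
            R_typed[cands][:, None, :] + R_typed[None, :, :] - gk[None, None, :]
        ).sum(axis=2)
        i, j = np.unravel_index(int(np.argmin(cost)), cost.shape)
        first, second = int(cands[i]), int(j)
        dosages[k] = R_masked[first].astype(float) + R_masked[second]
    masked_variants = reference.variants.iloc[masked_sites].reset_index(drop=True)
    if truth is None:
        truth = GenotypeMatrix(dosages.copy(), masked_variants, list(typed.samples))
    return ImputationEvalSet(truth, dosages)
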