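"""Polygenic score construction and transferability evaluation.

A PRS is the weighted sum of effect-allele dosages. Predictive
performance is incremental R²: the gain in the (unadjusted) coefficient
of determination when the PRS joins a covariate-only linear model of
the phenotype (age + 20 genotype PCs), with the phenotype centered and
standardized to unit variance within each sex beforehand. Uncertainty
comes from a pairs bootstrap: individuals (whole rows) resampled with
replacement, the 2.5th/97.5th percentiles of 1,000 replicate
incremental-R² values forming the 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import derived_rng
from .containers import GenotypeMatrix, HaplotypePanel, is_strand_ambiguous

N_BOOT = 1000
WEIGHT_COLUMNS = ["chrom", "pos", "effect_allele", "other_allele", "weight"]


@dataclass(frozen=True)
class IncR2Result:
    estimate: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low > ci_high")


def read_weights_tsv(path) -> pd.DataFrame:
    """Weights TSV with header CHROM POS EA OA WEIGHT."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    renames = {"ea": "effect_allele", "oa": "other_allele"}
    df = df.rename(columns=renames)
    missing = [c for c in WEIGHT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"weights table missing columns {missing}")
    return df[WEIGHT_COLUMNS]


def score_prs(genotypes, weights: pd.DataFrame, log=None) -> np.ndarray:
    """Per-sample weighted effect-allele dosage sum.

    Variants are matched by (chrom, pos). When the effect allele is the
    panel's ref allele the dosage is flipped to ``2 - d``; entries with
    alleles that do not match either orientation, or that are strand
    ambiguous, are dropped with a logged count. Missing dosages are
    mean-imputed per variant.
    """
    if isinstance(genotypes, HaplotypePanel):
        genotypes = genotypes.to_genotypes()
    panel_key = {
        (str(c), int(p)): (k, str(r).upper(), str(a).upper())
        for k, (c, p, r, a) in enumerate(
            genotypes.variants[["chrom", "pos", "ref", "alt"]].itertuples(index=False)
        )
    }
    D = genotypes.dosages
    if np.isnan(D).any():
        D = np.where(np.isnan(D), np.nanmean(D, axis=0)[None, :], D)
    scores = np.zeros(genotypes.n_samples)
    n_matched = n_dropped = 0
    for c, p, ea, oa, w in weights[WEIGHT_COLUMNS].itertuples(index=False):
        hit = panel_key.get((str(c), int(p)))
        if hit is None:
            n_dropped += 1
            continue
        k, ref, alt = hit
        ea, oa = str(ea).upper(), str(oa).upper()
        if is_strand_ambiguous(ea, oa):
            n_dropped += 1
            continue
        if (ea, oa) == (alt, ref):
            dos = D[:, k]
        elif (ea, oa) == (ref, alt):
            dos = 2.0 - D[:, k]
        else:
            n_dropped += 1
            continue
        scores += float(w) * dos
        n_matched += 1
    if n_matched == 0:
        raise ValueError("no weight entries matched the panel")
    if log is not None:
        log(f"matched {n_matched} weight entries, dropped {n_dropped}")
    return scores


def standardize_within_sex(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Center and scale the phenotype to mean 0, variance 1 per sex stratum.

    Uses the population variance convention (divide by n). Other
    columns are unchanged.
    """
    out = phenotypes.copy()
    for sex, idx in out.groupby("sex").groups.items():
        y = out.loc[idx, "phenotype"].to_numpy(dtype=float)
        sd = y.std()  # ddof=0
        if y.size < 2 or sd == 0:
            raise ValueError(f"sex stratum {sex!r} has zero phenotype variance")
        out.loc[idx, "phenotype"] = (y - y.mean()) / sd
    return out


def _design(phenotypes: pd.DataFrame, prs: np.ndarray):
    """Response and full design [1, age, PCs..., PRS]; complete cases only."""
    pc_cols = [c for c in phenotypes.columns if c.startswith("PC")]
    cols = ["phenotype", "age"] + pc_cols
    sub = phenotypes[cols].astype(float).copy()
    sub["prs"] = np.asarray(prs, dtype=float)
    sub = sub.dropna()
    y = sub["phenotype"].to_numpy()
    X = np.column_stack(
        [np.ones(len(sub)), sub[["age"] + pc_cols].to_numpy(), sub["prs"].to_numpy()]
    )
    return y, X


def _delta_r2(y: np.ndarray, X: np.ndarray) -> float:
    """Incremental R² of the last design column via nested QR projection.

    With the added column last, the reduced model's fit is the
    projection onto the leading columns of Q, so one decomposition
    yields both R² values.
    """
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = 1e-10 * max(diag.max(), 1.0)
    if np.any(diag[:-1] < tol):
        bad = np.flatnonzero(diag[:-1] < tol)
        raise np.linalg.LinAlgError(f"rank-deficient design; collinear columns {bad.tolist()}")
    if diag[-1] < tol:
        # added column lies in the covariate span (e.g. a constant PRS):
        # it cannot improve the fit
        return 0.0
    z = Q.T @ y
    yc = y - y.mean()
    tss = float(yc @ yc)
    if tss == 0:
        raise ValueError("constant response")
    return float(z[-1] ** 2 / tss)


def incremental_r2(phenotypes: pd.DataFrame, prs: np.ndarray) -> float:
    """ΔR² = R²(y ~ age + PCs + PRS) - R²(y ~ age + PCs), plain OLS."""
    y, X = _design(phenotypes, prs)
    if len(y) < X.shape[1] + 2:
        raise ValueError("too few complete cases for the model")
    return _delta_r2(y, X)


def bootstrap_ci(
    phenotypes: pd.DataFrame,
    prs: np.ndarray,
    n_boot: int = N_BOOT,
    seed: int = 0,
) -> IncR2Result:
    """Pairs-bootstrap percentile CI for incremental R².

    Rows (phenotype + covariates + PRS) are resampled jointly with
    replacement; rank-deficient replicates are redrawn (at most
    ``10 * n_boot`` attempts).
    """
    y, X = _design(phenotypes, prs)
    estimate = _delta_r2(y, X)
    rng = derived_rng(seed, "bootstrap_ci")
    n = len(y)
    reps = np.empty(n_boot)
    done = attempts = 0
    while done < n_boot:
        if attempts >= 10 * n_boot:
            raise RuntimeError("too many rank-deficient bootstrap replicates")
        attempts += 1
        idx = rng.integers(0, n, size=n)
        try:
            reps[done] = _delta_r2(y[idx], X[idx])
        except (np.linalg.LinAlgError, ValueError):
            continue
        done += 1
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return IncR2Result(estimate, float(lo), float(hi), n_boot, seed)
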