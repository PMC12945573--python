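"""End-to-end demonstration pipeline over synthetic data.

Runs simulate -> qc -> blocks -> varld -> ld-panel -> impute-eval ->
prs-eval -> ancestry on generated panels with known truth, writing
plain-text outputs plus a JSON manifest (parameters, seed, output
hashes). Re-running with the same config and seed reproduces
byte-identical numeric outputs; any stage failure aborts with a
stage-named error.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._rng import derived_rng
from .blocks import block_ld_summary, ldetect_partition
from .containers import RecombinationMap
from .imputation import aggregate_r2, nrd
from .io import write_bed, write_vcf
from .lookup import build_lookup_panel, summarize_panel, write_pairs_tsv
from .popstruct import FreqTable, ancestry_fraction
from .prs import bootstrap_ci, score_prs, standardize_within_sex
from .qc import SiteRecord, filter_variants
from .simulate import (
    BlockSpec,
    SimConfig,
    corrupt_to_dosages,
    derive_populations,
    mask_to_array,
    simulate_admixed,
    simulate_block_haplotypes,
    simulate_phenotype,
)
from .varld import summarize_track, varld_scores


@dataclass
class PipelineConfig:
    seed: int = 7
    out_dir: str = "panelkit_demo"
    n_individuals: int = 150
    block_snps: tuple[int, ...] = (80, 80, 80)
    n_founders: int = 8
    mutation_rate: float = 0.02
    fst: float = 0.05
    alpha: float = 0.7
    array_fraction: float = 0.5
    dosage_error_scale: float = 0.3
    h2: float = 0.3
    n_weighted_snps: int = 60
    n_boot: int = 200
    target_avg_snps: int = 80
    window_snps: int = 50
    stages: tuple[str, ...] = (
        "simulate", "qc", "blocks", "varld", "ld-panel",
        "impute-eval", "prs-eval", "ancestry",
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "stages": {},
    }
    state: dict = {}
    for stage in config.stages:
        runner = _STAGES.get(stage)
        if runner is None:
            raise ValueError(f"unknown stage {stage!r}")
        try:
            outputs = runner(config, out, state)
        except Exception as exc:  # annotate with the failing stage
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "outputs": {name: _sha256(Path(p)) for name, p in outputs.items()},
            "paths": {name: str(p) for name, p in outputs.items()},
        }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _stage_simulate(cfg: PipelineConfig, out: Path, state: dict) -> dict:
    sim = SimConfig(
        n_individuals=cfg.n_individuals,
        blocks=tuple(BlockSpec(n, cfg.n_founders, cfg.mutation_rate) for n in cfg.block_snps),
        seed=cfg.seed,
    )
    panel, truth = simulate_block_haplotypes(sim)
    popA, popB = derive_populations(panel, cfg.fst, cfg.seed)
    admixed, adm_truth = simulate_admixed(popA, popB, cfg.alpha, cfg.n_individuals, cfg.seed)
    state.update(panel=panel, truth=truth, popA=popA, popB=popB,
                 admixed=admixed, adm_truth=adm_truth)
    paths = {}
    for name, pnl in [("ancestral", panel), ("popA", popA), ("popB", popB), ("admixed", admixed)]:
        p = out / f"{name}.vcf"
        write_vcf(p, pnl)
        paths[name] = p
    tp = out / "truth.json"
    tp.write_text(json.dumps({
        "block_boundaries": truth.block_boundaries.tolist(),
        "fst": cfg.fst,
        "alpha_mean": float(adm_truth.ancestry_fraction.mean()),
    }, indent=2))
    paths["truth"] = tp
    return paths


def _stage_qc(cfg: PipelineConfig, out: Path, state: dict) -> dict:
    geno = state["popA"].to_genotypes()
    records = [
        SiteRecord(
            chrom=str(r.chrom), pos=int(r.pos), id=str(r.id), ref=str(r.ref),
            alt=str(r.alt), genotypes=geno.dosages[:, i],
        )
        for i, r in enumerate(geno.variants.itertuples(index=False))
    ]
    kept, report = filter_variants(records)
    state["qc_records"] = kept
    keep_idx = [i for i, r in enumerate(records) if r in kept]
    state["qc_keep_idx"] = np.asarray(keep_idx, dtype=int)
    p = out / "qc_report.json"
    p.write_text(json.dumps(report.to_dict(), indent=2))
    return {"qc_report": p}


def _linear_map(positions: np.ndarray, cm_per_mb: float = 1.0) -> RecombinationMap:
    pos = np.asarray(positions, dtype=float)
    return RecombinationMap(pos, (pos - pos[0]) * cm_per_mb / 1e6)


def _stage_blocks(cfg: PipelineConfig, out: Path, state: dict) -> dict:
    geno = state["popA"].to_genotypes()
    rec_map = _linear_map(geno.variants["pos"].to_numpy())
    part = ldetect_partition(geno, rec_map, target_avg_snps=cfg.target_avg_snps, maf_min=0.0)
    state["partition"] = part
    bed = out / "blocks.bed"
    write_bed(bed, part.to_bed())
    summary = block_ld_summary(part, geno, seed=cfg.seed)
    sp = out / "blocks_summary.json"
    sp.write_text(json.dumps(summary, indent=2))
    return {"blocks_bed": bed, "blocks_summary": sp}


def _stage_varld(cfg: PipelineConfig, out: Path, state: dict) -> dict:
    track = varld_scores(
        state["popA"].to_genotypes(), state["popB"].to_genotypes(),
        window_snps=cfg.window_snps, comparison_label="popA_vs_popB",
    )
    state["varld_track"] = track
    p = out / "varld_track.tsv"
    track.windows.to_csv(p, sep="\t", index=False, float_format="%.6g")
    sp = out / "varld_summary.json"
    sp.write_text(json.dumps(summarize_track(track), indent=2))
    return {"varld_track": p, "varld_summary": sp}


def _stage_ld_panel(cfg: PipelineConfig, out: Path, state: dict) -> dict:
    panel = state["popA"]
    pairs_path = out / "ld_pairs.tsv"
    write_pairs_tsv(build_lookup_panel(panel), pairs_path)
    summary = summarize_panel(build_lookup_panel(panel), panel)
    sp = out / "ld_panel_summary.json"
    sp.write_text(json.dumps(summary.to_dict(), indent=2))
    return {"ld_pairs": pairs_path, "ld_panel_summary": sp}


def _stage_impute_eval(cfg: PipelineConfig, out: Path, state: dict) -> dict:
    typed, mask_truth = mask_to_array(state["popB"], cfg.array_fraction, cfg.seed)
    full = state["popB"].to_genotypes()
    evalset = corrupt_to_dosages(full, cfg.dosage_error_scale, cfg.seed)
    agg = aggregate_r2(evalset)
    res = nrd(evalset)
    p = out / "imputation_eval.tsv"
    agg.to_csv(p, sep="\t", index=False, float_format="%.6g")
    jp = out / "imputation_eval.json"
    jp.write_text(json.dumps({
        "nrd": res.rate,
        "counts": {"e_rr": res.e_rr, "e_ra": res.e_ra, "e_aa": res.e_aa,
                   "m_ra": res.m_ra, "m_aa": res.m_aa},
        "n_typed": int(typed.n_variants),
        "n_masked": int(mask_truth.masked_sites.size),
    }, indent=2))
    return {"imputation_eval": p, "imputation_json": jp}


def _stage_prs_eval(cfg: PipelineConfig, out: Path, state: dict) -> dict:
    panel = state["popA"]
    rng = derived_rng(cfg.seed, "pipeline_weights")
    m = panel.n_variants
    pick = np.sort(rng.choice(m, size=min(cfg.n_weighted_snps, m), replace=False))
    v = panel.variants.iloc[pick]
    weights = pd.DataFrame({
        "chrom": v["chrom"].to_numpy(), "pos": v["pos"].to_numpy(),
        "effect_allele": v["alt"].to_numpy(), "other_allele": v["ref"].to_numpy(),
        "weight": rng.normal(size=len(pick)),
    })
    pheno, _ = simulate_phenotype(panel, weights, cfg.h2, cfg.seed)
    prs = score_prs(panel, weights)
    pheno_std = standardize_within_sex(pheno)
    result = bootstrap_ci(pheno_std, prs, n_boot=cfg.n_boot, seed=cfg.seed)
    p = out / "prs_eval.json"
    p.write_text(json.dumps({
        "incremental_r2": result.estimate,
        "ci_low": result.ci_low, "ci_high": result.ci_high,
        "n_boot": result.n_boot, "seed": result.seed,
    }, indent=2))
    return {"prs_eval": p}


def _stage_ancestry(cfg: PipelineConfig, out: Path, state: dict) -> dict:
    panel, popA, popB = state["panel"], state["popA"], state["popB"]
    # independent outgroup and extra differentiator lineages
    outg, extra = derive_populations(panel, max(cfg.fst, 0.01), cfg.seed + 1)
    nA = popA.n_individuals
    halfA1 = _panel_half(popA, slice(0, nA // 2))
    halfA2 = _panel_half(popA, slice(nA // 2, nA))
    freqs = FreqTable.from_panels({
        "outgroup": outg, "extra": extra, "source1": halfA1,
        "d1": halfA2, "source2": popB, "admixed": state["admixed"],
    })
    res = ancestry_fraction(freqs, "admixed", "outgroup", "source1", ("d1", "extra"))
    p = out / "ancestry.json"
    p.write_text(json.dumps({
        "alpha_estimate": res.ani_fraction,
        "alpha_truth": float(state["adm_truth"].ancestry_fraction.mean()),
        "flagged_out_of_range": res.out_of_range,
    }, indent=2))
    return {"ancestry": p}


def _panel_half(panel, sl: slice):
    from .containers import HaplotypePanel

    rows = np.arange(2 * sl.start if sl.start else 0, 2 * sl.stop)
    return HaplotypePanel(
        panel.haplotypes[rows],
        panel.variants.copy(),
        panel.samples[sl],
        block_boundaries=panel.block_boundaries,
    )


_STAGES = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "blocks": _stage_blocks,
    "varld": _stage_varld,
    "ld-panel": _stage_ld_panel,
    "impute-eval": _stage_impute_eval,
    "prs-eval": _stage_prs_eval,
    "ancestry": _stage_ancestry,
}
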