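"""Imputation accuracy metrics: stacked-vector r², NRD arithmetic, Rsq filter."""

import numpy as np
import pandas as pd
import pytest

from panelkit.containers import GenotypeMatrix, make_variant_table
from panelkit.imputation import (
    DEFAULT_MAF_BINS,
    ImputationEvalSet,
    aggregate_r2,
    best_guess_genotypes,
    filter_by_rsq,
    naive_hap_imputer,
    nrd,
    stratified_accuracy,
)
from panelkit.simulate import (
    BlockSpec,
    SimConfig,
    corrupt_to_dosages,
    mask_to_array,
    simulate_block_haplotypes,
)
from .conftest import genotypes_from_array


def evalset_from(truth, dosages, maf=None):
    truth = np.asarray(truth, dtype=float)
    gm = GenotypeMatrix(
        truth, make_variant_table(truth.shape[1]), [f"s{i}" for i in range(truth.shape[0])]
    )
    es = ImputationEvalSet(gm, np.asarray(dosages, dtype=float))
    if maf is not None:
        es.maf_reference = np.asarray(maf, dtype=float)
    return es


class TestAggregateR2:
    def test_perfect_dosages_give_one(self, small_panel):
        panel, _ = small_panel
        geno = panel.to_genotypes()
        es = corrupt_to_dosages(geno, 0.0, seed=1)
        table = aggregate_r2(es)
        populated = table.dropna(subset=["aggregated_r2"])
        assert len(populated) > 0
        assert np.allclose(populated["aggregated_r2"], 1.0)

    def test_single_variant_equals_plain_pearson(self):
        truth = np.array([[0.0], [1.0], [2.0], [0.0]])
        dos = np.array([[0.1], [0.9], [1.8], [0.2]])
        es = evalset_from(truth, dos, maf=[0.3])
        table = aggregate_r2(es, bins=[(0.0, 0.5)])
        want = np.corrcoef(truth.ravel(), dos.ravel())[0, 1] ** 2
        assert table["aggregated_r2"].iloc[0] == pytest.approx(want)

    def test_stacking_differs_from_mean_of_per_variant_r2(self):
        # two variants whose stacked correlation is NOT the mean of the
        # per-variant correlations (different scales + offsets)
        truth = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 1.0], [0.0, 2.0]])
        dos = np.array([[0.0, 1.9], [1.0, 1.7], [2.0, 0.1], [0.0, 0.2]])
        es = evalset_from(truth, dos, maf=[0.3, 0.3])
        stacked = aggregate_r2(es, bins=[(0.0, 0.5)])["aggregated_r2"].iloc[0]
        per_var = np.mean(
            [np.corrcoef(truth[:, j], dos[:, j])[0, 1] ** 2 for j in range(2)]
        )
        assert stacked == pytest.approx(
            np.corrcoef(truth.ravel(), dos.ravel())[0, 1] ** 2
        )
        assert abs(stacked - per_var) > 0.05

    def test_missing_truth_dropped(self):
        truth = np.array([[0.0], [np.nan], [2.0], [1.0]])
        dos = np.array([[0.0], [1.0], [2.0], [1.0]])
        es = evalset_from(truth, dos, maf=[0.4])
        assert aggregate_r2(es, bins=[(0.0, 0.5)])["aggregated_r2"].iloc[0] == pytest.approx(1.0)

    def test_empty_bin_undefined(self):
        es = evalset_from([[0.0], [1.0]], [[0.0], [1.0]], maf=[0.4])
        table = aggregate_r2(es, bins=[(0.0, 0.01)])
        assert table["n_variants"].iloc[0] == 0
        assert np.isnan(table["aggregated_r2"].iloc[0])

    def test_monotone_degradation_with_noise(self, small_panel):
        panel, _ = small_panel
        geno = panel.to_genotypes()
        r2s = []
        for scale in (0.0, 0.3, 0.6, 1.0):
            es = corrupt_to_dosages(geno, scale, seed=2)
            t = aggregate_r2(es, bins=[(0.0, 0.5)])
            r2s.append(t["aggregated_r2"].iloc[0])
        assert all(a >= b for a, b in zip(r2s[:-1], r2s[1:]))

    def test_accuracy_rises_with_maf_under_scaled_noise(self):
        cfg = SimConfig(400, (BlockSpec(300, 8, 0.02),), maf_min=0.005, seed=3)
        panel, _ = simulate_block_haplotypes(cfg)
        es = corrupt_to_dosages(panel.to_genotypes(), 0.6, seed=4)
        bins = [(0.0, 0.02), (0.02, 0.1), (0.1, 0.5)]
        t = aggregate_r2(es, bins=bins).dropna(subset=["aggregated_r2"])
        vals = t["aggregated_r2"].tolist()
        assert vals == sorted(vals)


class TestNRD:
    def test_rounding_rule(self):
        assert best_guess_genotypes(np.array([0.4, 0.5, 1.49, 1.5, 2.0])).tolist() == [
            0.0, 1.0, 1.0, 2.0, 2.0,
        ]

    def test_perfect_calls_zero_rate(self):
        es = evalset_from([[0.0], [1.0], [2.0]], [[0.1], [1.1], [1.8]])
        assert nrd(es).rate == 0.0

    def test_all_homref_denominator_zero(self):
        es = evalset_from([[0.0], [0.0]], [[0.1], [0.2]])
        assert nrd(es).rate is None

    def test_hand_counted_toy(self):
        # truth (one column of 10): classes chosen to give
        # e_rr=1, e_ra=1, e_aa=0, m_ra=3, m_aa=5 -> rate 2/10
        truth = [[0.0], [0.0], [1.0], [1.0], [1.0], [1.0], [2.0], [2.0], [2.0], [2.0]]
        calls = [[0.0], [1.0], [0.0], [1.0], [1.0], [1.0], [2.0], [2.0], [2.0], [2.0]]
        truth = np.array(truth + [[2.0]])
        calls = np.array(calls + [[2.0]])
        res = nrd(evalset_from(truth, calls))
        assert (res.e_rr, res.e_ra, res.e_aa, res.m_ra, res.m_aa) == (1, 1, 0, 3, 5)
        assert res.rate == pytest.approx(0.2)

    def test_invariant_under_homref_matches(self):
        truth = np.array([[1.0], [2.0], [0.0]])
        calls = np.array([[1.0], [1.0], [0.0]])
        base = nrd(evalset_from(truth, calls)).rate
        padded = nrd(
            evalset_from(np.vstack([truth, np.zeros((5, 1))]), np.vstack([calls, np.zeros((5, 1))]))
        ).rate
        assert base == padded

    def test_missing_truth_excluded(self):
        truth = np.array([[1.0], [np.nan]])
        calls = np.array([[0.0], [0.0]])
        res = nrd(evalset_from(truth, calls))
        assert res.e_ra == 1 and res.e_rr == 0


class TestRsqFilter:
    def test_boundary_inclusive(self):
        rng = np.random.default_rng(0)
        truth = rng.integers(0, 3, size=(50, 3)).astype(float)
        es = evalset_from(truth, truth)
        es.est_rsq = np.array([0.29, 0.30, 1.0])
        kept = filter_by_rsq(es, 0.3)
        assert kept.n_variants == 2

    def test_constant_dosage_removed(self):
        truth = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        dos = truth.copy()
        dos[:, 1] = 1.0
        es = evalset_from(truth, dos)
        assert filter_by_rsq(es).n_variants == 1

    def test_identity_when_all_pass(self, small_panel):
        panel, _ = small_panel
        es = corrupt_to_dosages(panel.to_genotypes(), 0.0, seed=5)
        assert filter_by_rsq(es).n_variants == es.n_variants


class TestStratified:
    def test_single_group_reproduces_unstratified(self, small_panel):
        panel, _ = small_panel
        es = corrupt_to_dosages(panel.to_genotypes(), 0.4, seed=6)
        groups = {s: "all" for s in es.truth.samples}
        strat = stratified_accuracy(es, groups)
        flat = aggregate_r2(es)
        merged = strat.merge(flat, on=["maf_lo", "maf_hi"], suffixes=("_g", "_f"))
        both = merged.dropna(subset=["aggregated_r2_g", "aggregated_r2_f"])
        assert np.allclose(both["aggregated_r2_g"], both["aggregated_r2_f"])

    def test_noisier_group_scores_lower(self, small_panel):
        panel, _ = small_panel
        geno = panel.to_genotypes()
        clean = corrupt_to_dosages(geno, 0.1, seed=7)
        noisy = corrupt_to_dosages(geno, 0.8, seed=7)
        n = geno.n_samples
        combined = ImputationEvalSet(
            GenotypeMatrix(
                np.vstack([geno.dosages, geno.dosages]),
                geno.variants.copy(),
                [f"c{i}" for i in range(n)] + [f"n{i}" for i in range(n)],
            ),
            np.vstack([clean.dosages, noisy.dosages]),
        )
        groups = {f"c{i}": "clean" for i in range(n)}
        groups.update({f"n{i}": "noisy" for i in range(n)})
        t = stratified_accuracy(combined, groups, bins=[(0.0, 0.5)])
        clean_r2 = t.loc[t["group"] == "clean", "aggregated_r2"].iloc[0]
        noisy_r2 = t.loc[t["group"] == "noisy", "aggregated_r2"].iloc[0]
        assert clean_r2 > noisy_r2

    def test_unlabeled_sample_raises(self, small_panel):
        panel, _ = small_panel
        es = corrupt_to_dosages(panel.to_genotypes(), 0.2, seed=8)
        with pytest.raises(ValueError, match="unlabeled"):
            stratified_accuracy(es, {})


class TestNaiveImputer:
    def test_target_in_reference_is_perfect(self):
        # mutation-free founder copies: typed sites determine masked
        # content uniquely, so an in-reference target must reconstruct
        # exactly
        cfg = SimConfig(
            120, (BlockSpec(40, 6, 0.0), BlockSpec(40, 6, 0.0)), seed=3
        )
        panel, _ = simulate_block_haplotypes(cfg)
        typed, truth = mask_to_array(panel, 0.5, seed=9)
        masked = truth.masked_sites
        full = panel.to_genotypes()
        held_out = GenotypeMatrix(
            full.dosages[:, masked],
            full.variants.iloc[masked].reset_index(drop=True),
            full.samples,
        )
        es = naive_hap_imputer(typed, panel, masked, truth=held_out)
        assert nrd(es).rate == 0.0

    def test_single_reference_haplotype(self, small_panel):
        panel, _ = small_panel
        one = panel.haplotypes[:1]
        ref = type(panel)(
            np.vstack([one, one]), panel.variants.copy(), [panel.samples[0]]
        )
        typed, truth = mask_to_array(panel, 0.5, seed=10)
        es = naive_hap_imputer(typed, ref, truth.masked_sites)
        want = 2.0 * one[0, truth.masked_sites]
        assert np.allclose(es.dosages, want[None, :])

    def test_accuracy_improves_with_reference_size(self):
        cfg = SimConfig(330, (BlockSpec(60, 10, 0.02),), seed=12)
        panel, _ = simulate_block_haplotypes(cfg)
        target_rows = np.arange(0, 60)
        target = type(panel)(
            panel.haplotypes[target_rows], panel.variants.copy(), panel.samples[:30]
        )
        typed, truth = mask_to_array(target, 0.5, seed=13)
        full = target.to_genotypes()
        held_out = GenotypeMatrix(
            full.dosages[:, truth.masked_sites],
            full.variants.iloc[truth.masked_sites].reset_index(drop=True),
            full.samples,
        )
        accs = []
        for n_ref in (25, 300):
            rows = np.arange(60, 60 + 2 * n_ref)
            ref = type(panel)(
                panel.haplotypes[rows], panel.variants.copy(),
                panel.samples[30 : 30 + n_ref],
            )
            es = naive_hap_imputer(typed, ref, truth.masked_sites, truth=held_out)
            accs.append(aggregate_r2(es, bins=[(0.0, 0.5)])["aggregated_r2"].iloc[0])
        assert accs[1] >= accs[0]

    def test_empty_reference_raises(self, small_panel):
        panel, _ = small_panel
        typed, truth = mask_to_array(panel, 0.5, seed=14)
        empty = type(panel)(
            np.empty((0, panel.n_variants), dtype=np.uint8), panel.variants.copy(), []
        )
        with pytest.raises(ValueError, match="empty reference"):
            naive_hap_imputer(typed, empty, truth.masked_sites)
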