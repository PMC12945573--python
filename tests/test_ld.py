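"""LD statistics against independent oracles and hand-computed values."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panelkit.containers import RecombinationMap
from panelkit.ld import (
    dosage_r,
    haplotype_ld,
    interpolate_cM,
    minor_allele_frequency,
    read_recombination_map,
    shrinkage_covariance,
    signed_r2_matrix,
    wen_stephens_theta,
)
from .conftest import genotypes_from_array, panel_from_haplotypes


def two_locus_oracle(col_a, col_b):
    """Brute-force r² and D′ by enumerating the four haplotype classes."""
    col_a, col_b = np.asarray(col_a), np.asarray(col_b)
    n = len(col_a)
    n_ab = ((col_a == 1) & (col_b == 1)).sum() / n
    p1, p2 = col_a.mean(), col_b.mean()
    d = n_ab - p1 * p2
    r2 = d * d / (p1 * (1 - p1) * p2 * (1 - p2))
    if d == 0:
        return 0.0, 0.0
    dmax = min(p1 * p2, (1 - p1) * (1 - p2)) if d < 0 else min(p1 * (1 - p2), (1 - p1) * p2)
    return r2, abs(d) / dmax


class TestMAF:
    @pytest.mark.parametrize(
        "column,expected",
        [([1, 1, 0, 0], 0.5), ([1, 0, 0, 0, 0, 0, 0, 0], 0.125)],
    )
    def test_haplotype_maf(self, column, expected):
        panel = panel_from_haplotypes(np.array([column, column]).T)
        assert minor_allele_frequency(panel, 0) == expected

    def test_genotype_maf_skips_missing(self):
        geno = genotypes_from_array(np.array([[2.0], [1.0], [0.0], [np.nan]]))
        # p = 3/6 over the three non-missing diploid calls
        assert minor_allele_frequency(geno, 0) == 0.5

    def test_all_missing_raises(self):
        geno = genotypes_from_array(np.array([[np.nan], [np.nan]]))
        with pytest.raises(ValueError):
            minor_allele_frequency(geno, 0)


class TestHaplotypeLD:
    def test_identical_columns(self):
        col = [1, 1, 0, 0, 1, 0]
        panel = panel_from_haplotypes(np.array([col, col]).T)
        stats = haplotype_ld(panel, 0, 1)
        assert stats.r2 == pytest.approx(1.0)
        assert stats.dprime == pytest.approx(1.0)
        assert stats.sign == 1

    def test_independent_columns(self):
        panel = panel_from_haplotypes(np.array([[1, 1, 0, 0], [1, 0, 1, 0]]).T)
        stats = haplotype_ld(panel, 0, 1)
        assert stats.r2 == 0.0 and stats.dprime == 0.0 and stats.sign == 0

    def test_hand_computed_counts(self):
        # haplotype classes AB=3, Ab=1, aB=1, ab=3
        a = [1] * 4 + [0] * 4
        b = [1, 1, 1, 0, 1, 0, 0, 0]
        panel = panel_from_haplotypes(np.array([a, b]).T)
        stats = haplotype_ld(panel, 0, 1)
        assert stats.r2 == pytest.approx(0.25)
        assert stats.dprime == pytest.approx(0.5)
        assert stats.sign == 1

    def test_monomorphic_raises(self):
        panel = panel_from_haplotypes(np.array([[1, 1, 1, 1], [1, 0, 1, 0]]).T)
        with pytest.raises(ValueError):
            haplotype_ld(panel, 0, 1)

    def test_enumeration_oracle_all_tiny_panels(self):
        """r²/D′ match four-class enumeration on every 6-haplotype 2-SNP panel."""
        checked = 0
        for a in itertools.product([0, 1], repeat=6):
            if len(set(a)) < 2:
                continue
            for b in itertools.product([0, 1], repeat=6):
                if len(set(b)) < 2:
                    continue
                panel = panel_from_haplotypes(np.array([a, b]).T)
                stats = haplotype_ld(panel, 0, 1)
                r2, dp = two_locus_oracle(a, b)
                assert stats.r2 == pytest.approx(r2, abs=1e-12)
                assert stats.dprime == pytest.approx(dp, abs=1e-12)
                assert 0.0 <= stats.dprime <= 1.0 + 1e-12
                checked += 1
        assert checked == 62 * 62

    def test_dprime_one_when_a_class_is_absent(self):
        # no 'Ab' haplotype: D' must be exactly 1
        a = [1, 1, 0, 0, 0, 0]
        b = [1, 1, 1, 0, 0, 0]
        panel = panel_from_haplotypes(np.array([a, b]).T)
        assert haplotype_ld(panel, 0, 1).dprime == pytest.approx(1.0)


class TestDosageR:
    def test_self_correlation(self):
        g = genotypes_from_array(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]))
        assert dosage_r(g, 0, 1) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        g = genotypes_from_array(np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]]))
        assert dosage_r(g, 0, 1) == pytest.approx(-1.0)

    def test_hand_pearson(self):
        g = genotypes_from_array(np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 2.0], [2.0, 2.0]]))
        assert dosage_r(g, 0, 1) == pytest.approx(3 / np.sqrt(11))

    def test_pairwise_complete_deletion(self):
        g = genotypes_from_array(
            np.array([[0.0, 0.0], [1.0, np.nan], [2.0, 2.0], [1.0, 1.0]])
        )
        # row 1 dropped: remaining columns are identical
        assert dosage_r(g, 0, 1) == pytest.approx(1.0)

    def test_constant_column_raises(self):
        g = genotypes_from_array(np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0]]))
        with pytest.raises(ValueError):
            dosage_r(g, 0, 1)


class TestSignedR2Matrix:
    def test_duplicated_snp(self):
        g = genotypes_from_array(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]))
        assert np.allclose(signed_r2_matrix(g), np.ones((2, 2)))

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(5)
        g = genotypes_from_array(rng.integers(0, 3, size=(80, 10)).astype(float))
        mat = signed_r2_matrix(g)
        for i in range(10):
            for j in range(i + 1, 10):
                r = dosage_r(g, i, j)
                assert mat[i, j] == pytest.approx(np.sign(r) * r * r, abs=1e-12)
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 1.0)

    def test_trace_conservation(self):
        rng = np.random.default_rng(6)
        g = genotypes_from_array(rng.integers(0, 3, size=(60, 12)).astype(float))
        ev = np.linalg.eigvalsh(signed_r2_matrix(g))
        assert ev.sum() == pytest.approx(12.0)


class TestRecombinationMap:
    def test_knot_and_midpoint_and_clamp(self):
        m = RecombinationMap([100, 200, 300], [0.0, 1.0, 2.0])
        assert interpolate_cM(m, [200]) == pytest.approx(1.0)
        assert interpolate_cM(m, [250]) == pytest.approx(1.5)
        assert interpolate_cM(m, [999]) == pytest.approx(2.0)
        assert interpolate_cM(m, [1]) == pytest.approx(0.0)

    def test_reader_tolerates_header(self, tmp_path):
        p = tmp_path / "map.txt"
        p.write_text(
            "chr position rate cM\n1 100 1.0 0.0\n1 200 1.0 0.1\n1 300 1.0 0.2\n"
        )
        m = read_recombination_map(p)
        assert m.positions.tolist() == [100.0, 200.0, 300.0]
        assert interpolate_cM(m, [150]) == pytest.approx(0.05)

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            RecombinationMap([], [])


def shrinkage_oracle(X, cM, ne, nh, cutoff):
    """Step-by-step recomputation of the shrinkage estimator, coded
    independently of the production path."""
    S = np.cov(X, rowvar=False)
    m = X.shape[1]
    h = sum(1.0 / i for i in range(1, nh))
    theta = (1.0 / h) / (2.0 * nh + 1.0 / h)
    out = np.empty((m, m))
    for a in range(m):
        for b in range(m):
            rho = 4.0 * ne * abs(cM[b] - cM[a]) / 100.0
            f = np.exp(-rho / (2.0 * nh))
            if f < cutoff:
                f = 0.0
            if a == b:
                f = 1.0
            out[a, b] = (1 - theta) ** 2 * S[a, b] * f
            if a == b:
                out[a, b] += theta / 2.0 * (1 - theta / 2.0)
    return out


class TestShrinkageCovariance:
    def test_zero_distance_off_diagonal(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 3, size=(50, 2)).astype(float)
        g = genotypes_from_array(X)
        cov = shrinkage_covariance(g, np.array([0.7, 0.7]))
        theta = wen_stephens_theta(100)
        S = np.cov(X, rowvar=False)
        assert cov[0, 1] == pytest.approx((1 - theta) ** 2 * S[0, 1])

    def test_distant_pair_exactly_zero(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 3, size=(50, 2)).astype(float)
        g = genotypes_from_array(X)
        # 4*Ne*dcM/100 / (2*nh) > -ln(1e-8) requires dcM > ~40 cM at n=50
        cov = shrinkage_covariance(g, np.array([0.0, 500.0]))
        assert cov[0, 1] == 0.0

    def test_formula_oracle_on_toy(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 3, size=(40, 5)).astype(float)
        g = genotypes_from_array(X)
        cM = np.array([0.0, 0.5, 1.0, 1.5, 2.0])
        got = shrinkage_covariance(g, cM)
        want = shrinkage_oracle(X, cM, 11418.0, 80, 1e-8)
        assert np.allclose(got, want)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_positive_semidefinite(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 3, size=(30, 6)).astype(float)
        if np.any(X.std(axis=0) == 0):
            X[0] = (X[0] + 1) % 3
        g = genotypes_from_array(X)
        cM = np.sort(rng.uniform(0, 2, size=6))
        cov = shrinkage_covariance(g, cM)
        assert np.linalg.eigvalsh(cov).min() >= -1e-8

    def test_misaligned_cm_raises(self):
        g = genotypes_from_array(np.array([[0.0, 1.0], [1.0, 2.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            shrinkage_covariance(g, np.array([0.0, 1.0, 2.0]))
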