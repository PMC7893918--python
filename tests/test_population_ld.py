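"""Two-locus EM haplotype frequencies and the r^2 LD matrix."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famtag.population_ld import (
    HaplotypeFrequencies,
    _em_from_counts,
    _pair_counts,
    em_haplotype_freqs,
    ld_matrix_genotypes,
    ld_matrix_haploid,
    pair_log_likelihood,
    r2_from_freqs,
)
from famtag.types import GenotypeMatrix


def table_to_columns(counts):
    """Expand a {(g_k, g_l): n} dict into two genotype columns."""
    gk, gl = [], []
    for (a, b), n in counts.items():
        gk += [a] * n
        gl += [b] * n
    return np.array(gk), np.array(gl)


def grid_search_freqs(counts_3x3, step=1e-3):
    """Likelihood oracle: the two allele frequencies are fixed by counting,
    so the ML problem is one-dimensional in f_AA; scan it exhaustively."""
    n = counts_3x3
    tot = n.sum()
    f_k = (2 * n[2].sum() + n[1].sum()) / (2 * tot)
    f_l = (2 * n[:, 2].sum() + n[:, 1].sum()) / (2 * tot)
    lo = max(0.0, f_k + f_l - 1.0)
    hi = min(f_k, f_l)
    best, best_ll = None, -np.inf
    for f_AA in np.arange(lo, hi + step / 2, step):
        f_AB = f_k - f_AA
        f_BA = f_l - f_AA
        f_BB = 1 - f_AA - f_AB - f_BA
        if min(f_AB, f_BA, f_BB) < -1e-12:
            continue
        f = HaplotypeFrequencies(max(f_AA, 0), max(f_AB, 0), max(f_BA, 0), max(f_BB, 0))
        ll = pair_log_likelihood(n, f)
        if ll > best_ll:
            best, best_ll = f, ll
    return best


class TestR2FromFreqs:
    @pytest.mark.parametrize(
        "freqs, expected",
        [
            ((0.5, 0.0, 0.0, 0.5), 1.0),  # perfect LD
            ((0.25, 0.25, 0.25, 0.25), 0.0),  # equilibrium
            ((0.4, 0.1, 0.2, 0.3), 1 / 6),  # D=0.10, f_k=0.5, f_l=0.6
        ],
    )
    def test_worked_values(self, freqs, expected):
        assert r2_from_freqs(HaplotypeFrequencies(*freqs)) == pytest.approx(expected)

    def test_boundary_frequency_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            r2_from_freqs(HaplotypeFrequencies(0.5, 0.5, 0.0, 0.0))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        w=st.tuples(*([st.floats(0.01, 1.0)] * 4)).map(
            lambda v: tuple(x / sum(v) for x in v)
        )
    )
    def test_r2_in_unit_interval(self, w):
        """For any interior haplotype-frequency vector, r^2 is a valid
        squared correlation in [0, 1]."""
        f = HaplotypeFrequencies(*w)
        r2 = r2_from_freqs(f)
        assert 0.0 <= r2 <= 1.0

    def test_label_swap_invariance(self, rng):
        for _ in range(20):
            f = rng.dirichlet(np.ones(4))
            base = HaplotypeFrequencies(*f)
            swapped_k = HaplotypeFrequencies(f[2], f[3], f[0], f[1])
            swapped_l = HaplotypeFrequencies(f[1], f[0], f[3], f[2])
            try:
                r2 = r2_from_freqs(base)
            except ValueError:
                continue
            assert r2_from_freqs(swapped_k) == pytest.approx(r2)
            assert r2_from_freqs(swapped_l) == pytest.approx(r2)


class TestEM:
    def test_unambiguous_double_homozygotes(self):
        gk, gl = table_to_columns({(0, 0): 50, (2, 2): 50})
        f = em_haplotype_freqs(gk, gl)
        assert f.f_AA == pytest.approx(0.5)
        assert f.f_BB == pytest.approx(0.5)
        assert f.f_AB == pytest.approx(0.0)

    def test_no_double_het_equals_direct_counting(self):
        gk, gl = table_to_columns({(2, 2): 10, (2, 1): 5, (1, 0): 5, (0, 0): 10})
        f = em_haplotype_freqs(gk, gl)
        total = 60.0
        assert f.f_AA == pytest.approx(25 / total)
        assert f.f_AB == pytest.approx(10 / total)
        assert f.f_BB == pytest.approx(25 / total)

    def test_em_matches_grid_search_oracle(self):
        counts = {(2, 2): 40, (2, 0): 10, (0, 2): 10, (0, 0): 30, (1, 1): 10}
        gk, gl = table_to_columns(counts)
        f_em = em_haplotype_freqs(gk, gl)
        f_grid = grid_search_freqs(_pair_counts(gk, gl))
        for name in ("f_AA", "f_AB", "f_BA", "f_BB"):
            assert getattr(f_em, name) == pytest.approx(getattr(f_grid, name), abs=2e-3)

    def test_em_matches_oracle_on_random_tables(self, rng):
        for _ in range(10):
            n = _pair_counts(rng.integers(0, 3, 200), rng.integers(0, 3, 200))
            f_em = _em_from_counts(n)
            f_grid = grid_search_freqs(n)
            for name in ("f_AA", "f_AB", "f_BA", "f_BB"):
                assert getattr(f_em, name) == pytest.approx(getattr(f_grid, name), abs=2e-3)

    def test_log_likelihood_nondecreasing(self, rng):
        gk = rng.integers(0, 3, 300)
        gl = rng.integers(0, 3, 300)
        _, history = em_haplotype_freqs(gk, gl, return_history=True)
        n = _pair_counts(gk, gl)
        lls = [pair_log_likelihood(n, HaplotypeFrequencies(*f)) for f in history]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_monomorphic_locus_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            em_haplotype_freqs(np.zeros(50, int), np.ones(50, int))

    def test_missing_excluded_pairwise(self):
        gk = np.array([2, 2, 0, 0, -1, 2])
        gl = np.array([2, 2, 0, 0, 2, -1])
        f = em_haplotype_freqs(gk, gl)
        assert f.f_AA == pytest.approx(0.5)


class TestLdMatrixGenotypes:
    def test_duplicated_column_gives_r2_one(self, rng):
        col = rng.integers(0, 3, 200)
        G = GenotypeMatrix(np.column_stack([col, col]), ["A"] * 200, ["a", "b"])
        R = ld_matrix_genotypes(G)
        assert R.values[0, 1] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self, rng):
        n = 10_000
        vals = rng.binomial(2, 0.5, size=(n, 6))
        G = GenotypeMatrix(vals, ["A"] * n, [f"m{j}" for j in range(6)])
        R = ld_matrix_genotypes(G)
        off = R.values[np.triu_indices(6, 1)]
        assert np.nanmean(off) < 0.01

    def test_matrix_agrees_with_scalar_em(self, rng):
        vals = rng.integers(0, 3, size=(150, 5))
        vals[rng.random((150, 5)) < 0.1] = -1
        G = GenotypeMatrix(vals, ["A"] * 150, [f"m{j}" for j in range(5)])
        R = ld_matrix_genotypes(G)
        for k in range(5):
            for l in range(k + 1, 5):
                try:
                    expected = r2_from_freqs(em_haplotype_freqs(vals[:, k], vals[:, l]))
                except ValueError:
                    expected = np.nan
                np.testing.assert_allclose(R.values[k, l], expected, atol=1e-6)

    def test_monomorphic_cells_missing(self, rng):
        vals = rng.integers(0, 3, size=(50, 3))
        vals[:, 1] = 2
        G = GenotypeMatrix(vals, ["A"] * 50, ["a", "b", "c"])
        R = ld_matrix_genotypes(G)
        assert np.isnan(R.values[0, 1]) and np.isnan(R.values[1, 1])
        assert R.values[0, 0] == 1.0

    def test_em_r2_recovers_true_haplotype_r2(self, rng):
        """On data simulated from known gamete frequencies, the genotype EM
        converges to the phased-haplotype r^2 as n grows."""
        f = np.array([0.45, 0.15, 0.05, 0.35])
        true_r2 = r2_from_freqs(HaplotypeFrequencies(*f))
        n = 10_000
        gametes = rng.choice(4, size=(n, 2), p=f)
        a = np.isin(gametes, (0, 1)).sum(axis=1)  # A at locus k on haplotypes 0,1
        b = np.isin(gametes, (0, 2)).sum(axis=1)
        est = r2_from_freqs(em_haplotype_freqs(a, b))
        assert est == pytest.approx(true_r2, abs=0.02)


class TestLdMatrixHaploid:
    def test_identical_and_complementary_columns(self):
        x = np.array([0, 0, 1, 1, 0, 1])
        H = np.column_stack([x, x, 1 - x])
        R = ld_matrix_haploid(H)
        assert R.values[0, 1] == pytest.approx(1.0)
        assert R.values[0, 2] == pytest.approx(1.0)

    def test_orthogonal_columns(self):
        H = np.column_stack([[0, 0, 1, 1], [0, 1, 0, 1]])
        R = ld_matrix_haploid(H)
        assert R.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_equals_squared_spearman(self, rng):
        from scipy.stats import spearmanr

        H = rng.integers(0, 2, size=(60, 4))
        R = ld_matrix_haploid(H)
        rho = spearmanr(H).statistic
        np.testing.assert_allclose(R.values, rho**2, atol=1e-10)

    def test_constant_column_missing(self):
        H = np.column_stack([[0, 1, 0, 1], [1, 1, 1, 1]])
        R = ld_matrix_haploid(H)
        assert np.isnan(R.values[0, 1]) and np.isnan(R.values[1, 1])
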