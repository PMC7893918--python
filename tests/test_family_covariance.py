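"""Theoretical sib-family covariance: map function, gametic covariance,
family combination and correlation scaling."""

import numpy as np
import pytest

from famtag.family_covariance import (
    build_family_covariance,
    gamete_covariance,
    haldane_theta,
    theta_matrix,
    to_correlation,
)
from famtag.types import (
    CovarianceMatrix,
    GeneticMap,
    MaternalLD,
    Parent,
    ParentalHaplotypes,
    ValidationError,
)


def mc_gamete_cov(h1, h2, positions_cm, n_meioses, rng):
    """Monte-Carlo oracle: explicit Poisson crossover process (continuous
    crossover positions, parity count per locus), independent of the
    per-interval implementation."""
    h1 = np.asarray(h1)
    h2 = np.asarray(h2)
    L = positions_cm[-1] - positions_cm[0]
    gametes = np.empty((n_meioses, h1.size))
    for i in range(n_meioses):
        k = rng.poisson(L / 100.0)
        cuts = np.sort(rng.uniform(positions_cm[0], positions_cm[-1], size=k))
        parity = (np.searchsorted(cuts, positions_cm) + rng.integers(2)) % 2
        gametes[i] = np.where(parity == 0, h1, h2)
    return np.cov(gametes, rowvar=False, ddof=0)


class TestHaldane:
    def test_values_and_limits(self):
        assert haldane_theta(0.0) == 0.0
        assert haldane_theta(50.0) == pytest.approx(0.5 * (1 - np.exp(-1)))
        assert haldane_theta(1e7) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            haldane_theta(-1.0)

    def test_theta_matrix_monotone_in_distance(self, small_map):
        th = theta_matrix(small_map)
        assert th[0, 1] < th[0, 2] < th[0, 4]
        np.testing.assert_array_equal(np.diag(th), 0)

    def test_different_chromosomes_unlinked(self):
        gmap = GeneticMap(["a", "b"], ["1", "2"], np.array([0.0, 0.0]))
        assert theta_matrix(gmap)[0, 1] == 0.5


class TestGameteCovariance:
    def test_coupling_complete_linkage(self):
        C = gamete_covariance([1, 1], [0, 0], np.zeros((2, 2)))
        np.testing.assert_allclose(C, [[0.25, 0.25], [0.25, 0.25]])

    def test_repulsion_quarter_theta(self):
        theta = np.array([[0.0, 0.25], [0.25, 0.0]])
        C = gamete_covariance([1, 0], [0, 1], theta)
        assert C[0, 1] == pytest.approx(-(1 - 0.5) / 4)

    def test_homozygous_locus_row_zero(self):
        theta = np.full((3, 3), 0.1)
        np.fill_diagonal(theta, 0)
        C = gamete_covariance([1, 1, 0], [1, 0, 1], theta)
        np.testing.assert_allclose(C[0], 0, atol=1e-15)
        assert C[1, 1] == pytest.approx(0.25)

    def test_magnitude_decays_with_theta(self):
        covs = []
        for t in (0.0, 0.1, 0.25, 0.4, 0.5):
            theta = np.array([[0.0, t], [t, 0.0]])
            covs.append(abs(gamete_covariance([1, 1], [0, 0], theta)[0, 1]))
        assert all(a >= b for a, b in zip(covs, covs[1:]))

    def test_matches_monte_carlo_meiosis(self, rng):
        positions = np.array([0.0, 12.0, 30.0, 55.0])
        theta = haldane_theta(np.abs(positions[:, None] - positions[None, :]))
        np.fill_diagonal(theta, 0)
        for _ in range(5):
            h1 = rng.integers(0, 2, 4)
            h2 = rng.integers(0, 2, 4)
            C = gamete_covariance(h1, h2, theta)
            n = 20_000
            C_mc = mc_gamete_cov(h1, h2, positions, n, rng)
            se = np.sqrt((np.outer(np.diag(C), np.diag(C)) + C**2) / n) + 1e-12
            assert np.all(np.abs(C - C_mc) < 4 * se + 1e-9)


class TestBuildFamilyCovariance:
    def test_homozygous_sire_leaves_maternal_part(self, small_map):
        hap = np.vstack([np.ones(5, int), np.ones(5, int)])
        sires = ParentalHaplotypes([Parent("F1", "sire", hap)], {"F1": 10})
        p = np.full(5, 0.5)
        D = np.full((5, 5), 0.25)
        cov = build_family_covariance("half_sib", sires, small_map, MaternalLD(D, p))
        np.testing.assert_allclose(cov.C, 0.25)

    def test_full_sib_coupling_parents_perfect_correlation(self):
        gmap = GeneticMap(["a", "b"], ["1", "1"], np.array([0.0, 0.0]))
        hap = np.array([[1, 1], [0, 0]])
        parents = ParentalHaplotypes(
            [Parent("F1", "sire", hap), Parent("F1", "dam", hap)], {"F1": 5}
        )
        cov = build_family_covariance("full_sib", parents, gmap)
        np.testing.assert_allclose(cov.C, 0.5)
        R = to_correlation(cov)
        np.testing.assert_allclose(R.values, 1.0)

    def test_family_size_weighted_sum(self, small_map, rng):
        """Two half-sib families sizes 30/70 equal the weighted sum of the
        single-family matrices plus the shared maternal part."""
        h_a = rng.integers(0, 2, (2, 5))
        h_b = rng.integers(0, 2, (2, 5))
        p = rng.uniform(0.2, 0.8, 5)
        D = np.diag(p * (1 - p))
        mat = MaternalLD(D, p)
        both = ParentalHaplotypes(
            [Parent("A", "sire", h_a), Parent("B", "sire", h_b)],
            {"A": 30, "B": 70},
        )
        C = build_family_covariance("half_sib", both, small_map, mat).C
        only_a = ParentalHaplotypes([Parent("A", "sire", h_a)], {"A": 1})
        only_b = ParentalHaplotypes([Parent("B", "sire", h_b)], {"B": 1})
        P_a = build_family_covariance("half_sib", only_a, small_map, mat, parts="paternal").C
        P_b = build_family_covariance("half_sib", only_b, small_map, mat, parts="paternal").C
        np.testing.assert_allclose(C, 0.3 * P_a + 0.7 * P_b + D, atol=1e-12)

    def test_full_sib_identical_parents_doubles_single_part(self, small_map, rng):
        hap = rng.integers(0, 2, (2, 5))
        fs = ParentalHaplotypes(
            [Parent("F", "sire", hap), Parent("F", "dam", hap)], {"F": 3}
        )
        C = build_family_covariance("full_sib", fs, small_map).C
        single = build_family_covariance(
            "full_sib", fs, small_map, parts="paternal"
        ).C
        np.testing.assert_allclose(C, 2 * single, atol=1e-12)

    def test_half_sib_requires_maternal_ld(self, small_map, het_sire):
        with pytest.raises(ValidationError, match="maternal"):
            build_family_covariance("half_sib", het_sire, small_map, None)

    def test_missing_parent_allele_drops_marker(self, small_map, flat_maternal):
        hap = np.array([[1, -1, 1, 0, 1], [0, -1, 0, 1, 0]])
        sires = ParentalHaplotypes([Parent("F", "sire", hap)], {"F": 4})
        cov = build_family_covariance("half_sib", sires, small_map, flat_maternal)
        assert 1 not in cov.kept_index
        assert cov.C.shape == (4, 4)

    def test_per_family_component_positive_semidefinite(self, small_map, rng):
        for _ in range(5):
            hap = rng.integers(0, 2, (2, 5))
            sires = ParentalHaplotypes([Parent("F", "sire", hap)], {"F": 2})
            C = build_family_covariance(
                "half_sib", sires, small_map,
                MaternalLD(np.diag(np.full(5, 0.25)), np.full(5, 0.5)),
            ).C
            assert np.linalg.eigvalsh(C).min() > -1e-8


class TestToCorrelation:
    def test_identity_covariance(self):
        cov = CovarianceMatrix(C=0.25 * np.eye(3), kept_index=np.arange(3), design="half_sib")
        R = to_correlation(cov)
        np.testing.assert_allclose(R.values, np.eye(3))
        np.testing.assert_array_equal(R.kept_index, [0, 1, 2])

    def test_sire_homozygous_loci_discarded(self, rng):
        """Cattle-style: of 300 loci, 61 have zero diagonal (all sires
        homozygous, no maternal variance there) -> 239 retained."""
        p = 300
        dead = rng.choice(p, size=61, replace=False)
        diag = np.full(p, 0.3)
        diag[dead] = 0.0
        C = np.outer(np.sqrt(diag), np.sqrt(diag)) * 0.5
        np.fill_diagonal(C, diag)
        R = to_correlation(CovarianceMatrix(C=C, kept_index=np.arange(p), design="half_sib"))
        assert R.values.shape == (239, 239)
        assert not np.isin(dead, R.kept_index).any()

    def test_scaling_invariance(self, rng):
        A = rng.normal(size=(6, 6))
        C = A @ A.T + 1e-3 * np.eye(6)
        base = CovarianceMatrix(C=C, kept_index=np.arange(6), design="half_sib")
        scaled = CovarianceMatrix(C=7.3 * C, kept_index=np.arange(6), design="half_sib")
        np.testing.assert_allclose(
            to_correlation(base).values, to_correlation(scaled).values, atol=1e-12
        )

    def test_all_dead_raises(self):
        cov = CovarianceMatrix(C=np.zeros((3, 3)), kept_index=np.arange(3), design="half_sib")
        with pytest.raises(ValidationError, match="no segregating"):
            to_correlation(cov)
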