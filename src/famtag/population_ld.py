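"""Population linkage disequilibrium (r^2) between marker pairs.

For unphased diploid genotypes the two-locus haplotype frequencies are
estimated by maximum likelihood: every genotype combination except the
double heterozygote contributes unambiguous gamete counts, and the double
heterozygotes are split between the coupling (A-A/B-B) and repulsion
(A-B/B-A) resolutions by an EM iteration.  For haploid data (double
haploids, gametes) haplotypes are observed and r^2 reduces to the squared
(Spearman = Pearson, for binary columns) correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import MISSING, DependenceMatrix, GenotypeMatrix


@dataclass
class HaplotypeFrequencies:
    """Frequencies of the four two-locus gamete classes."""

    f_AA: float
    f_AB: float
    f_BA: float
    f_BB: float

    def __post_init__(self) -> None:
        f = np.array([self.f_AA, self.f_AB, self.f_BA, self.f_BB])
        if np.any(f < -1e-12) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must be a probability vector")

    @property
    def f_k(self) -> float:
        return self.f_AA + self.f_AB

    @property
    def f_l(self) -> float:
        return self.f_AA + self.f_BA


def _pair_counts(g_k: np.ndarray, g_l: np.ndarray) -> np.ndarray:
    """3x3 table of genotype-pair counts over pairwise-complete individuals."""
    ok = (g_k != MISSING) & (g_l != MISSING)
    counts = np.zeros((3, 3))
    np.add.at(counts, (g_k[ok], g_l[ok]), 1)
    return counts


def _em_from_counts(
    n: np.ndarray, tol: float = 1e-8, max_iter: int = 1000, return_history: bool = False
):
    """EM on a 3x3 genotype-pair count table; codes are counts of allele A."""
    c_AA = 2 * n[2, 2] + n[2, 1] + n[1, 2]
    c_AB = 2 * n[2, 0] + n[2, 1] + n[1, 0]
    c_BA = 2 * n[0, 2] + n[1, 2] + n[0, 1]
    c_BB = 2 * n[0, 0] + n[1, 0] + n[0, 1]
    n_dh = n[1, 1]
    total = c_AA + c_AB + c_BA + c_BB + 2 * n_dh
    if total == 0:
        raise ValueError("r2 undefined: no pairwise-complete genotypes")
    f_k = (c_AA + c_AB + n_dh) / total
    f_l = (c_AA + c_BA + n_dh) / total
    if f_k in (0.0, 1.0) or f_l in (0.0, 1.0):
        raise ValueError("r2 undefined: monomorphic locus")

    # start at linkage equilibrium
    f = np.array([f_k * f_l, f_k * (1 - f_l), (1 - f_k) * f_l, (1 - f_k) * (1 - f_l)])
    history = [f.copy()]
    for _ in range(max_iter):
        denom = f[0] * f[3] + f[1] * f[2]
        r = f[0] * f[3] / denom if denom > 0 else 0.5
        new = (
            np.array([c_AA, c_AB, c_BA, c_BB])
            + n_dh * np.array([r, 1 - r, 1 - r, r])
        ) / total
        delta = np.max(np.abs(new - f))
        f = new
        if return_history:
            history.append(f.copy())
        if delta < tol:
            break
    freqs = HaplotypeFrequencies(*f)
    return (freqs, history) if return_history else freqs


def em_haplotype_freqs(
    g_k: np.ndarray,
    g_l: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
    return_history: bool = False,
):
    """Maximum-likelihood two-locus haplotype frequencies from two genotype
    columns (codes 0/1/2; missing entries excluded pairwise-complete)."""
    g_k = np.asarray(g_k)
    g_l = np.asarray(g_l)
    if g_k.shape != g_l.shape:
        raise ValueError("genotype columns must have equal length")
    return _em_from_counts(
        _pair_counts(g_k, g_l), tol=tol, max_iter=max_iter, return_history=return_history
    )


def pair_log_likelihood(n: np.ndarray, f: HaplotypeFrequencies) -> float:
    """Multinomial log-likelihood of a 3x3 genotype-pair table under random
    union of gametes with the given haplotype frequencies."""
    fs = np.array([f.f_AA, f.f_AB, f.f_BA, f.f_BB])
    # genotype-pair probabilities from gamete-pair products
    hap_code = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])  # allele at (k,l)
    P = np.zeros((3, 3))
    for a in range(4):
        for b in range(4):
            gk = hap_code[a, 0] + hap_code[b, 0]
            gl = hap_code[a, 1] + hap_code[b, 1]
            P[gk, gl] += fs[a] * fs[b]
    with np.errstate(divide="ignore"):
        ll = np.where(n > 0, n * np.log(np.maximum(P, 1e-300)), 0.0)
    return float(ll.sum())


def r2_from_freqs(f: HaplotypeFrequencies) -> float:
    """Squared gametic correlation r^2 = (f_AA f_BB - f_AB f_BA)^2 /
    (f_k (1-f_k) f_l (1-f_l))."""
    f_k, f_l = f.f_k, f.f_l
    if not (0 < f_k < 1 and 0 < f_l < 1):
        raise ValueError("r2 undefined at boundary allele frequency")
    d = f.f_AA * f.f_BB - f.f_AB * f.f_BA
    r2 = d * d / (f_k * (1 - f_k) * f_l * (1 - f_l))
    if r2 > 1 + 1e-12:
        raise ValueError(f"r2 = {r2} exceeds 1 beyond tolerance")
    return float(min(max(r2, 0.0), 1.0))


def ld_matrix_genotypes(
    G: GenotypeMatrix, tol: float = 1e-8, max_iter: int = 1000
) -> DependenceMatrix:
    """Pairwise r^2 matrix from unphased progeny genotypes.

    Runs the two-locus EM for all pairs simultaneously on vectorized
    genotype-pair count tables.  Cells involving a monomorphic SNP are NaN;
    the diagonal is 1 for polymorphic SNPs.
    """
    vals = G.values
    p = vals.shape[1]
    ind = [(vals == code).astype(np.float64) for code in (0, 1, 2)]
    n = np.empty((3, 3, p, p))
    for a in range(3):
        for b in range(3):
            n[a, b] = ind[a].T @ ind[b]

    c_AA = 2 * n[2, 2] + n[2, 1] + n[1, 2]
    c_AB = 2 * n[2, 0] + n[2, 1] + n[1, 0]
    c_BA = 2 * n[0, 2] + n[1, 2] + n[0, 1]
    c_BB = 2 * n[0, 0] + n[1, 0] + n[0, 1]
    n_dh = n[1, 1]
    total = c_AA + c_AB + c_BA + c_BB + 2 * n_dh

    with np.errstate(invalid="ignore", divide="ignore"):
        f_k = (c_AA + c_AB + n_dh) / total
        f_l = (c_AA + c_BA + n_dh) / total
    valid = (total > 0) & (f_k > 0) & (f_k < 1) & (f_l > 0) & (f_l < 1)

    fAA = np.where(valid, f_k * f_l, np.nan)
    fAB = np.where(valid, f_k * (1 - f_l), np.nan)
    fBA = np.where(valid, (1 - f_k) * f_l, np.nan)
    fBB = np.where(valid, (1 - f_k) * (1 - f_l), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        for _ in range(max_iter):
            denom = fAA * fBB + fAB * fBA
            r = np.where(denom > 0, fAA * fBB / np.where(denom > 0, denom, 1.0), 0.5)
            nAA = (c_AA + n_dh * r) / total
            nAB = (c_AB + n_dh * (1 - r)) / total
            nBA = (c_BA + n_dh * (1 - r)) / total
            nBB = (c_BB + n_dh * r) / total
            delta = np.nanmax(
                np.abs(np.stack([nAA - fAA, nAB - fAB, nBA - fBA, nBB - fBB]))
            )
            fAA, fAB, fBA, fBB = nAA, nAB, nBA, nBB
            if not np.isfinite(delta) or delta < tol:
                break
        d = fAA * fBB - fAB * fBA
        r2 = d * d / (f_k * (1 - f_k) * f_l * (1 - f_l))
    r2 = np.clip(r2, 0.0, 1.0)
    r2[~valid] = np.nan
    poly = np.diag(valid)
    r2[np.diag_indices(p)] = np.where(poly, 1.0, np.nan)
    r2 = 0.5 * (r2 + r2.T)
    return DependenceMatrix(values=r2, kept_index=np.arange(p), source="population_ld")


def ld_matrix_haploid(H: np.ndarray) -> DependenceMatrix:
    """Squared rank correlation between haploid 0/1 columns.

    For binary data the Spearman and Pearson correlations coincide, so this
    is computed as the squared Pearson correlation; constant columns give
    NaN cells.
    """
    H = np.asarray(H, dtype=float)
    if not np.isin(H, (0, 1)).all():
        raise ValueError("haploid matrix must contain only 0/1")
    p = H.shape[1]
    sd = H.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(H, rowvar=False)
    R = np.atleast_2d(R)
    r2 = R * R
    const = sd == 0
    r2[const, :] = np.nan
    r2[:, const] = np.nan
    idx = np.diag_indices(p)
    r2[idx] = np.where(const, np.nan, 1.0)
    return DependenceMatrix(values=r2, kept_index=np.arange(p), source="population_ld")
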