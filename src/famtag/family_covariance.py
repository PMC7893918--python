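"""Theoretical covariance between biallelic markers for half- and full-sib
family designs.

The covariance of the allele counts transmitted by a phased parent follows
from meiosis without interference: between loci k and l with recombination
fraction theta the transmitted gamete keeps the parental phase with
probability (1 - theta) and recombines with probability theta.  The
paternal (observed sire) and maternal (observed dam, or population LD of
the dam pool) contributions add up to the family covariance; several
families combine as a progeny-share weighted average.
"""

from __future__ import annotations

import numpy as np

from .types import (
    MISSING,
    CovarianceMatrix,
    DependenceMatrix,
    GeneticMap,
    MaternalLD,
    ParentalHaplotypes,
    ValidationError,
)

#: diagonal entries below this are treated as non-segregating and dropped
ZERO_VARIANCE_FLOOR = 1e-12


def haldane_theta(d: float | np.ndarray) -> float | np.ndarray:
    """Recombination fraction from genetic distance ``d`` in cM under the
    Haldane (no-interference) map function: theta = (1 - exp(-2d/100)) / 2."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("genetic distance must be non-negative")
    theta = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(theta) if theta.ndim == 0 else theta


def theta_matrix(gmap: GeneticMap) -> np.ndarray:
    """Pairwise recombination fractions implied by a genetic map.

    Markers on different chromosomes segregate independently
    (theta = 0.5)."""
    pos = gmap.position_cm
    theta = haldane_theta(np.abs(pos[:, None] - pos[None, :]))
    chrom = np.asarray(gmap.chromosome)
    theta[chrom[:, None] != chrom[None, :]] = 0.5
    np.fill_diagonal(theta, 0.0)
    return theta


def gamete_covariance(h1: np.ndarray, h2: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Covariance matrix of the allele counts of one transmitted gamete from
    a parent with phased haplotypes ``h1``/``h2`` (0/1 vectors).

    The transmitted allele at locus k is h1_k or h2_k with equal
    probability; jointly over loci k, l the parental pairing is kept with
    probability (1 - theta_kl) and swapped with probability theta_kl.
    Consequences: the diagonal is 1/4 at heterozygous loci and 0 at
    homozygous loci; off-diagonals are +(1-2 theta)/4 in coupling phase,
    -(1-2 theta)/4 in repulsion, and 0 if either locus is homozygous.
    """
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    if h1.shape != h2.shape or h1.ndim != 1:
        raise ValidationError("haplotypes must be equal-length vectors")
    if theta.shape != (h1.size, h1.size):
        raise ValidationError("theta matrix must match haplotype length")
    mean = 0.5 * (h1 + h2)
    same = np.outer(h1, h1) + np.outer(h2, h2)
    cross = np.outer(h1, h2) + np.outer(h2, h1)
    second = 0.5 * (1.0 - theta) * same + 0.5 * theta * cross
    cov = second - np.outer(mean, mean)
    # theta_kk = 0 makes the diagonal exact; symmetrize against float noise
    return 0.5 * (cov + cov.T)


def build_family_covariance(
    design: str,
    parents: ParentalHaplotypes,
    gmap: GeneticMap,
    maternal: MaternalLD | None = None,
    parts: str = "both",
) -> CovarianceMatrix:
    """Combine parental contributions into the family covariance matrix.

    half_sib: per family, the sire's gametic covariance plus the maternal
    population's gametic LD matrix D (whose diagonal is p(1-p)).
    full_sib: sire plus dam gametic covariances of the family.
    ``parts`` can mask either component, e.g. ``"maternal"`` for designs
    where only maternal meioses are informative (double-haploid progeny of
    heterozygous mothers).

    Families are combined as C = sum_i w_i C_i with w_i the family's share
    of progeny.  Markers for which a required parental allele is missing
    (and that receive no maternal-LD variance either) are dropped and
    recorded in ``kept_index``.
    """
    if design not in ("half_sib", "full_sib"):
        raise ValueError(f"unknown design {design!r}")
    if parts not in ("paternal", "maternal", "both"):
        raise ValueError(f"unknown parts {parts!r}")
    if design == "half_sib" and parts != "paternal" and maternal is None:
        raise ValidationError("half_sib design requires maternal LD information")
    p = parents.n_markers
    if p != gmap.n_markers:
        raise ValidationError("map and haplotypes disagree on marker count")
    if maternal is not None and maternal.p_freq.size != p:
        raise ValidationError("maternal LD dimension mismatch")
    families = parents.families
    if not families:
        raise ValidationError("at least one family required")

    theta = theta_matrix(gmap)
    sizes = np.array([parents.family_size[f] for f in families], dtype=float)
    weights = sizes / sizes.sum()

    usable = np.ones(p, dtype=bool)
    per_family: list[np.ndarray] = []
    for fam in families:
        C_i = np.zeros((p, p))
        roles = ["sire"] if design == "half_sib" else ["sire", "dam"]
        for role in roles:
            if parts == "maternal" and role == "sire":
                continue
            if parts == "paternal" and role == "dam":
                continue
            ps = parents.by_family(fam, role)
            if design == "full_sib" and not ps:
                raise ValidationError(f"family {fam!r}: missing {role} haplotypes")
            if not ps:
                continue
            hap = ps[0].haplotypes
            missing = (hap == MISSING).any(axis=0)
            usable &= ~missing
            h1 = np.where(missing, 0, hap[0])
            h2 = np.where(missing, 0, hap[1])
            C_i += gamete_covariance(h1, h2, theta)
        per_family.append(C_i)
    C = sum(w * C_i for w, C_i in zip(weights, per_family))

    if design == "half_sib" and parts != "paternal":
        D = maternal.D.copy()
        d_diag = maternal.p_freq * (1 - maternal.p_freq)
        if np.all(np.abs(np.diag(D)) <= ZERO_VARIANCE_FLOOR):
            np.fill_diagonal(D, d_diag)  # D supplied without its diagonal
        C = C + D

    keep = np.flatnonzero(usable)
    C = C[np.ix_(keep, keep)]
    return CovarianceMatrix(C=C, kept_index=keep, design=design, parts=parts)


def to_correlation(cov: CovarianceMatrix) -> DependenceMatrix:
    """Scale a family covariance to the correlation matrix R, dropping
    markers whose total variance is (numerically) zero — e.g. loci at which
    every sire is homozygous and no maternal variance remains."""
    diag = np.diag(cov.C)
    keep = diag > ZERO_VARIANCE_FLOOR
    if not keep.any():
        raise ValidationError("no segregating markers: all diagonal entries are zero")
    idx = np.flatnonzero(keep)
    sub = cov.C[np.ix_(idx, idx)]
    scale = 1.0 / np.sqrt(np.diag(sub))
    R = sub * np.outer(scale, scale)
    if np.any(np.abs(R) > 1 + 1e-10):
        raise ValidationError("correlation entry outside [-1, 1]")
    R = np.clip(R, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return DependenceMatrix(
        values=R, kept_index=cov.kept_index[idx], source="family"
    )
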