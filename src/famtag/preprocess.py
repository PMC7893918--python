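"""Data-preparation rules applied before dependence matrices are built:
call-rate and MAF filters, major-allele recoding, double-haploid
heterozygote masking, frequency-based imputation and within-family
standardization."""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .types import MISSING, GenotypeMatrix, Parent, ParentalHaplotypes

log = logging.getLogger(__name__)


@dataclass
class FilterReport:
    removed_individuals: list[int]
    removed_markers: list[int]


def _subset(G: GenotypeMatrix, rows: np.ndarray, cols: np.ndarray) -> GenotypeMatrix:
    return GenotypeMatrix(
        values=G.values[np.ix_(rows, cols)],
        family_label=[G.family_label[i] for i in np.flatnonzero(rows)],
        marker_ids=[G.marker_ids[j] for j in np.flatnonzero(cols)],
        individual_ids=(
            [G.individual_ids[i] for i in np.flatnonzero(rows)]
            if G.individual_ids is not None
            else None
        ),
    )


def filter_call_rate(
    G: GenotypeMatrix, ind_min: float = 0.9, snp_min: float = 0.9
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop individuals whose non-missing fraction is below ``ind_min``,
    then SNPs below ``snp_min`` (individual-first order)."""
    if not (0 <= ind_min <= 1 and 0 <= snp_min <= 1):
        raise ValueError("call-rate thresholds must lie in [0,1]")
    obs = G.values != MISSING
    keep_ind = obs.mean(axis=1) >= ind_min
    if not keep_ind.any():
        raise ValueError("empty after filtering: no individual meets the call rate")
    keep_snp = obs[keep_ind].mean(axis=0) >= snp_min
    report = FilterReport(
        removed_individuals=list(np.flatnonzero(~keep_ind)),
        removed_markers=list(np.flatnonzero(~keep_snp)),
    )
    return _subset(G, keep_ind, keep_snp), report


def minor_allele_frequency(G: GenotypeMatrix, haploid: bool = False) -> np.ndarray:
    """Per-SNP minor allele frequency over non-missing entries."""
    vals = G.values
    obs = vals != MISSING
    ploidy = 1 if haploid else 2
    with np.errstate(invalid="ignore"):
        freq = np.where(
            obs.sum(axis=0) > 0,
            np.where(obs, vals, 0).sum(axis=0) / (ploidy * obs.sum(axis=0)),
            np.nan,
        )
    return np.fmin(freq, 1 - freq)


def filter_maf(
    G: GenotypeMatrix, maf_min: float = 0.05, haploid: bool = False
) -> tuple[GenotypeMatrix, FilterReport]:
    """Discard SNPs with minor allele frequency strictly below ``maf_min``."""
    maf = minor_allele_frequency(G, haploid=haploid)
    keep = ~(maf < maf_min)  # NaN (all-missing) columns are kept
    if not keep.any():
        log.warning("MAF filter removed every SNP")
    report = FilterReport(removed_individuals=[], removed_markers=list(np.flatnonzero(~keep)))
    return _subset(G, np.ones(G.n_individuals, bool), keep), report


def _flip_mask_from_reference(ref_values: np.ndarray, ploidy: int) -> np.ndarray:
    obs = ref_values != MISSING
    counts = np.where(obs, ref_values, 0).sum(axis=0)
    totals = ploidy * obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.where(totals > 0, counts / np.maximum(totals, 1), np.nan)
    # ties at exactly 0.5 are never flipped (stable coding)
    return freq < 0.5


def recode_major_allele(
    data: GenotypeMatrix | ParentalHaplotypes,
    reference_values: np.ndarray | None = None,
    reference_ploidy: int | None = None,
) -> tuple[GenotypeMatrix | ParentalHaplotypes, np.ndarray]:
    """Recode allele counts so the counted allele is the major allele of the
    reference population.

    ``reference_values`` is the allele-count matrix of the reference sample
    (defaults to ``data`` itself); at SNPs where the counted allele has
    reference frequency < 0.5 every code x becomes ``ploidy - x``.  Returns
    the recoded object and the boolean flip mask.
    """
    if isinstance(data, GenotypeMatrix):
        own = data.values
        ploidy = 2
    else:
        own = np.vstack([p.haplotypes for p in data.parents])
        ploidy = 1
    if reference_values is None:
        reference_values = own
        reference_ploidy = ploidy
    flip = _flip_mask_from_reference(
        np.asarray(reference_values), reference_ploidy or ploidy
    )

    def apply(values: np.ndarray, pl: int) -> np.ndarray:
        out = values.copy()
        cols = np.flatnonzero(flip)
        sub = out[:, cols]
        sub[sub != MISSING] = pl - sub[sub != MISSING]
        out[:, cols] = sub
        return out

    if isinstance(data, GenotypeMatrix):
        return replace(data, values=apply(data.values, 2)), flip
    new_parents = [
        Parent(family=p.family, role=p.role, haplotypes=apply(p.haplotypes, 1))
        for p in data.parents
    ]
    return ParentalHaplotypes(parents=new_parents, family_size=dict(data.family_size)), flip


def het_to_missing(G: GenotypeMatrix) -> GenotypeMatrix:
    """Mask heterozygous calls: in double-haploid progeny a heterozygote is a
    genotyping artefact, so every code 1 becomes missing."""
    values = G.values.copy()
    n = int((values == 1).sum())
    values[values == 1] = MISSING
    if n:
        log.info("het_to_missing: masked %d heterozygous calls", n)
    return replace(G, values=values)


def impute_sample_homozygotes(G: GenotypeMatrix, seed: int | np.random.Generator = 0) -> GenotypeMatrix:
    """Fill missing entries by sampling homozygous codes 0/2 with
    probabilities proportional to their observed counts per SNP.

    Draws stream from one seeded generator in marker-major order, so results
    are reproducible given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = G.values.copy()
    n0 = (values == 0).sum(axis=0)
    n2 = (values == 2).sum(axis=0)
    for j in range(values.shape[1]):
        miss = values[:, j] == MISSING
        if not miss.any():
            continue
        if n0[j] + n2[j] == 0:
            raise ValueError(
                f"SNP {G.marker_ids[j]!r}: no observed homozygote to impute from"
            )
        p2 = n2[j] / (n0[j] + n2[j])
        values[miss, j] = 2 * (rng.random(miss.sum()) < p2)
    return replace(G, values=values)


def standardize_within_family(
    M: np.ndarray, families: list[str] | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Center each column within family, then scale each column to unit
    empirical variance (denominator n-1).

    Columns whose post-centering variance is zero are left at 0 and flagged;
    returns ``(standardized matrix, zero_variance mask)``.
    """
    X = np.asarray(M, dtype=float).copy()
    families = np.asarray(families)
    for fam in np.unique(families):
        rows = families == fam
        X[rows] -= X[rows].mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    degenerate = sd <= 1e-12
    if degenerate.any():
        log.info("standardize_within_family: %d zero-variance columns", degenerate.sum())
    X[:, ~degenerate] /= sd[~degenerate]
    X[:, degenerate] = 0.0
    return X, degenerate
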