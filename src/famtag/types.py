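"""Core domain containers shared across the toolkit.

All marker-indexed objects are kept in genetic-map order; marker indices are
0-based in memory and 1-based in files written by :mod:`famtag.io`.
The missing-value sentinel for integer allele/genotype codes is ``MISSING``
(= -1); text files use the literal ``NA`` (``.`` in VCF).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: integer sentinel for a missing genotype/allele code
MISSING: int = -1


class ValidationError(ValueError):
    """Raised when an input object violates a structural invariant."""


@dataclass
class GeneticMap:
    """Ordered marker positions on one or more chromosomes.

    Positions are in centimorgan (cM) and must be non-decreasing within a
    chromosome; they are the basis for recombination fractions via the
    Haldane map function.
    """

    marker_id: list[str]
    chromosome: list[str]
    position_cm: np.ndarray
    position_bp: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.position_cm = np.asarray(self.position_cm, dtype=float)
        if len(self.marker_id) != len(self.chromosome) or len(self.marker_id) != self.position_cm.size:
            raise ValidationError("map fields must have equal length")
        if np.any(self.position_cm < 0):
            raise ValidationError("negative cM position in genetic map")
        for chrom in dict.fromkeys(self.chromosome):
            pos = self.position_cm[[c == chrom for c in self.chromosome]]
            if np.any(np.diff(pos) < 0):
                raise ValidationError(
                    f"cM positions not non-decreasing on chromosome {chrom!r}"
                )

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_markers


@dataclass
class GenotypeMatrix:
    """n individuals x p markers of diploid codes {0,1,2} (count of the
    counted allele), with ``MISSING`` for no-calls, plus a family label per
    individual."""

    values: np.ndarray
    family_label: list[str]
    marker_ids: list[str]
    individual_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValidationError("genotype values must be 2-D")
        bad = ~np.isin(self.values, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"genotype code {self.values[i, j]} outside {{0,1,2,NA}} at "
                f"individual {i}, marker {j}"
            )
        if len(self.family_label) != self.values.shape[0]:
            raise ValidationError("one family label per individual required")
        if any(not str(f) for f in self.family_label):
            raise ValidationError("family labels must be non-empty")
        if len(self.marker_ids) != self.values.shape[1]:
            raise ValidationError("one marker id per column required")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]


@dataclass
class Parent:
    """One phased parent of a family: two allele vectors over the map."""

    family: str
    role: str  # "sire" or "dam"
    haplotypes: np.ndarray  # (2, p) with entries in {0, 1, MISSING}

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes)
        if self.haplotypes.shape[0] != 2:
            raise ValidationError("a parent carries exactly two haplotypes")
        if self.role not in ("sire", "dam"):
            raise ValidationError(f"unknown parent role {self.role!r}")
        if not np.isin(self.haplotypes, (0, 1, MISSING)).all():
            raise ValidationError("haplotype alleles must be 0/1/NA")


@dataclass
class ParentalHaplotypes:
    """Phased parents grouped by family, with progeny counts per family."""

    parents: list[Parent]
    family_size: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {p.haplotypes.shape[1] for p in self.parents}
        if len(lengths) > 1:
            raise ValidationError("all parental haplotypes must have equal length")
        for fam, n in self.family_size.items():
            if n < 1:
                raise ValidationError(f"family {fam!r} has non-positive size {n}")
        # default: unit size for any family without an explicit count
        for p in self.parents:
            self.family_size.setdefault(p.family, 1)

    @property
    def n_markers(self) -> int:
        return self.parents[0].haplotypes.shape[1] if self.parents else 0

    @property
    def families(self) -> list[str]:
        return list(dict.fromkeys(p.family for p in self.parents))

    def by_family(self, family: str, role: str | None = None) -> list[Parent]:
        return [
            p
            for p in self.parents
            if p.family == family and (role is None or p.role == role)
        ]


@dataclass
class MaternalLD:
    """Gametic covariance matrix D and allele frequencies of the unobserved
    parent population (typically the dams of half-sib families)."""

    D: np.ndarray
    p_freq: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        self.p_freq = np.asarray(self.p_freq, dtype=float)
        p = self.p_freq.size
        if self.D.shape != (p, p):
            raise ValidationError("D must be p x p, aligned with p_freq")
        if not np.allclose(self.D, self.D.T, atol=1e-8):
            raise ValidationError("maternal LD matrix must be symmetric")
        if np.any(self.p_freq < 0) or np.any(self.p_freq > 1):
            raise ValidationError("allele frequencies outside [0,1]")
        bound = np.sqrt(
            np.outer(self.p_freq * (1 - self.p_freq), self.p_freq * (1 - self.p_freq))
        )
        if np.any(np.abs(self.D) > bound + 1e-8):
            raise ValidationError("maternal LD entry exceeds its frequency bound")


@dataclass
class CovarianceMatrix:
    """Theoretical between-marker covariance for a family design."""

    C: np.ndarray
    kept_index: np.ndarray
    design: str  # "half_sib" | "full_sib"
    parts: str = "both"  # "paternal" | "maternal" | "both"

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        self.kept_index = np.asarray(self.kept_index, dtype=int)
        if not np.allclose(self.C, self.C.T, atol=1e-8):
            raise ValidationError("covariance matrix must be symmetric")


@dataclass
class DependenceMatrix:
    """Symmetric matrix of scaled dependence between markers: either the
    family correlation R (entries in [-1,1]) or population LD r^2 (in [0,1]).
    NaN marks pairs whose dependence is not estimable."""

    values: np.ndarray
    kept_index: np.ndarray
    source: str  # "family" | "population_ld"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.kept_index = np.asarray(self.kept_index, dtype=int)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValidationError("dependence matrix must be square")
        if self.kept_index.size != self.values.shape[0]:
            raise ValidationError("kept_index must align with the matrix")

    @property
    def n_markers(self) -> int:
        return self.values.shape[0]


@dataclass
class Grouping:
    """Ordered partition of marker indices into groups with one
    representative (tagSNP) each; groups are stored in build order."""

    groups: list[list[int]]
    representatives: list[int]
    threshold: float
    source: str = "family"

    def __post_init__(self) -> None:
        if len(self.groups) != len(self.representatives):
            raise ValidationError("one representative per group required")
        seen: set[int] = set()
        for g, rep in zip(self.groups, self.representatives):
            if rep not in g:
                raise ValidationError("representative must belong to its group")
            if seen & set(g):
                raise ValidationError("groups must be pairwise disjoint")
            seen.update(g)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def marker_indices(self) -> np.ndarray:
        return np.sort(np.concatenate([np.asarray(g, int) for g in self.groups]))

    def labels(self, markers: Sequence[int] | None = None) -> np.ndarray:
        """Group label (build order, 0-based) per marker index."""
        lut = {k: b for b, g in enumerate(self.groups) for k in g}
        idx = self.marker_indices if markers is None else np.asarray(markers, int)
        return np.array([lut[k] for k in idx], dtype=int)
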