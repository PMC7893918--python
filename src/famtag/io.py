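"""Readers and writers for the plain-text formats the toolkit exchanges.

Supported inputs: PLINK ``.map`` / TSV genetic maps, phased VCF or TSV
parental haplotypes, TSV genotype matrices with family labels, TSV
maternal-LD matrices with allele frequencies.  Outputs: TSV groupings,
square matrices with a marker-id header, phenotype tables.

Conventions: marker indices are 1-based in files and 0-based in memory;
``NA`` is the missing sentinel in TSV; everything is re-sorted to map order
when combined with a :class:`~famtag.types.GeneticMap`.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    MISSING,
    GeneticMap,
    GenotypeMatrix,
    Grouping,
    MaternalLD,
    Parent,
    ParentalHaplotypes,
    ValidationError,
)

log = logging.getLogger(__name__)


class ParseError(ValueError):
    """Raised when a file cannot be parsed; carries the offending line."""


# ---------------------------------------------------------------------------
# genetic map


def read_genetic_map(
    path: str | Path,
    dialect: str = "plink_map",
    mbp_to_cm_fallback: bool = True,
) -> GeneticMap:
    """Read a genetic map.

    ``plink_map`` expects four whitespace-separated columns per line:
    chromosome, marker id, position in cM, position in bp.  ``tsv`` expects
    a header with columns ``marker_id``, ``chromosome``, ``position_cm`` and
    optionally ``position_bp``.

    If every cM entry is zero and physical positions are present,
    ``mbp_to_cm_fallback`` fills the genetic positions assuming a 1:1
    relationship between Mbp and cM.
    """
    path = Path(path)
    if dialect == "plink_map":
        chroms, ids, cms, bps = [], [], [], []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                parts = line.split()
                if len(parts) != 4:
                    raise ParseError(
                        f"{path}:{lineno}: expected 4 columns, got {len(parts)}"
                    )
                try:
                    chroms.append(parts[0])
                    ids.append(parts[1])
                    cms.append(float(parts[2]))
                    bps.append(int(parts[3]))
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from exc
        cm = np.array(cms, dtype=float)
        bp = np.array(bps, dtype=int)
    elif dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
        required = {"marker_id", "chromosome", "position_cm"}
        if not required.issubset(df.columns):
            raise ParseError(f"{path}: missing columns {required - set(df.columns)}")
        chroms = df["chromosome"].astype(str).tolist()
        ids = df["marker_id"].astype(str).tolist()
        cm = df["position_cm"].to_numpy(dtype=float)
        bp = (
            df["position_bp"].to_numpy(dtype=int)
            if "position_bp" in df.columns
            else None
        )
    else:
        raise ValueError(f"unknown map dialect {dialect!r}")

    if mbp_to_cm_fallback and bp is not None and np.all(cm == 0) and np.any(bp > 0):
        log.info("cM column is all-zero; applying 1:1 Mbp->cM fallback")
        cm = bp / 1e6
    return GeneticMap(marker_id=ids, chromosome=chroms, position_cm=cm, position_bp=bp)


# ---------------------------------------------------------------------------
# parental haplotypes


def read_phased_haplotypes(
    path: str | Path,
    dialect: str = "vcf",
    samples: list[str] | None = None,
    roles: dict[str, str] | None = None,
    families: dict[str, str] | None = None,
    family_size: dict[str, int] | None = None,
) -> ParentalHaplotypes:
    """Read phased parental haplotypes from a VCF or an allele-matrix TSV.

    VCF genotypes must be phased (``|`` separator) and biallelic; alleles
    stay on the REF/ALT scale (major-allele recoding is a preprocessing
    step).  The TSV dialect is a whitespace/tab-separated allele matrix with
    two consecutive rows per parent and no header.

    ``roles``/``families`` map a parent name to its role ("sire"/"dam") and
    family label; unnamed parents default to one sire per single-parent
    family ``F1, F2, ...``.
    """
    path = Path(path)
    if dialect == "vcf":
        parents = _haplotypes_from_vcf(path, samples)
    elif dialect == "tsv":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                try:
                    rows.append(
                        [MISSING if tok == "NA" else int(tok) for tok in line.split()]
                    )
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if not rows:
            raise ParseError(f"{path}: no haplotype rows")
        if len(rows) % 2:
            raise ParseError(f"{path}: odd number of haplotype rows")
        if len({len(r) for r in rows}) > 1:
            raise ParseError(f"{path}: ragged haplotype rows")
        mat = np.array(rows, dtype=np.int64)
        names = [f"P{i + 1}" for i in range(len(rows) // 2)]
        parents = {n: mat[2 * i : 2 * i + 2] for i, n in enumerate(names)}
    else:
        raise ValueError(f"unknown haplotype dialect {dialect!r}")

    out = []
    for i, (name, hap) in enumerate(parents.items()):
        fam = (families or {}).get(name, f"F{i + 1}")
        role = (roles or {}).get(name, "sire")
        out.append(Parent(family=fam, role=role, haplotypes=hap))
    return ParentalHaplotypes(parents=out, family_size=dict(family_size or {}))


def _haplotypes_from_vcf(path: Path, samples: list[str] | None) -> dict[str, np.ndarray]:
    from cyvcf2 import VCF

    vcf = VCF(str(path), samples=samples, gts012=False)
    names = list(vcf.samples)
    cols: list[np.ndarray] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ValidationError(
                f"non-biallelic site {variant.CHROM}:{variant.POS} ({variant.ID})"
            )
        col = np.empty((len(names), 2), dtype=np.int64)
        for i, gt in enumerate(variant.genotypes):
            a0, a1, phased = gt[0], gt[1], gt[-1]
            if a0 >= 0 and a1 >= 0 and not phased:
                raise ValidationError(
                    f"unphased genotype for sample {names[i]} at "
                    f"{variant.CHROM}:{variant.POS}"
                )
            col[i, 0] = a0 if a0 >= 0 else MISSING
            col[i, 1] = a1 if a1 >= 0 else MISSING
        cols.append(col)
    if not cols:
        raise ParseError(f"{path}: no variant records")
    stacked = np.stack(cols, axis=2)  # (samples, 2, p)
    return {n: stacked[i] for i, n in enumerate(names)}


# ---------------------------------------------------------------------------
# genotype matrix


def read_genotype_matrix(path: str | Path) -> GenotypeMatrix:
    """Read a TSV genotype table: header of marker ids after the first two
    columns (individual id, family label); entries 0/1/2 or ``NA``."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 3:
        raise ParseError(f"{path}: expected id, family and >=1 marker column")
    if df.shape[0] == 0:
        raise ParseError(f"{path}: no individuals")
    marker_ids = list(df.columns[2:])
    raw = df.iloc[:, 2:].to_numpy()
    values = np.empty(raw.shape, dtype=np.int64)
    for (i, j), tok in np.ndenumerate(raw):
        if pd.isna(tok) or tok == "NA":
            values[i, j] = MISSING
        else:
            try:
                values[i, j] = int(tok)
            except ValueError as exc:
                raise ParseError(f"{path}: row {i + 2}, column {j + 3}: {exc}") from exc
    n_missing = int((values == MISSING).sum())
    if n_missing:
        log.info("%s: %d missing genotype entries", path, n_missing)
    return GenotypeMatrix(
        values=values,
        family_label=df.iloc[:, 1].astype(str).tolist(),
        marker_ids=marker_ids,
        individual_ids=df.iloc[:, 0].astype(str).tolist(),
    )


def write_genotype_matrix(path: str | Path, G: GenotypeMatrix) -> None:
    vals = G.values.astype(object)
    vals[G.values == MISSING] = "NA"
    ids = G.individual_ids or [f"I{i + 1}" for i in range(G.n_individuals)]
    df = pd.DataFrame(vals, columns=G.marker_ids)
    df.insert(0, "family", G.family_label)
    df.insert(0, "individual_id", ids)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# grouping


def write_grouping(path: str | Path, grouping: Grouping, marker_ids: list[str] | None = None) -> None:
    """Write a grouping as TSV with columns group_index (1-based, build
    order), marker_id and is_representative; round-trips via
    :func:`read_grouping`."""
    rows = []
    for b, (group, rep) in enumerate(zip(grouping.groups, grouping.representatives), 1):
        for k in group:
            mid = marker_ids[k] if marker_ids is not None else f"M{k + 1}"
            rows.append((b, mid, k + 1, int(k == rep)))
    df = pd.DataFrame(rows, columns=["group_index", "marker_id", "marker_index", "is_representative"])
    with open(path, "w") as fh:
        fh.write(f"# threshold={grouping.threshold}\tsource={grouping.source}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_grouping(path: str | Path) -> Grouping:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        meta = dict(
            tok.split("=", 1) for tok in header.lstrip("#").split() if "=" in tok
        )
        df = pd.read_csv(fh, sep="\t")
    groups: dict[int, list[int]] = {}
    reps: dict[int, int] = {}
    for _, row in df.iterrows():
        k = int(row["marker_index"]) - 1
        b = int(row["group_index"])
        groups.setdefault(b, []).append(k)
        if int(row["is_representative"]):
            reps[b] = k
    order = sorted(groups)
    return Grouping(
        groups=[groups[b] for b in order],
        representatives=[reps[b] for b in order],
        threshold=float(meta.get("threshold", "nan")),
        source=meta.get("source", "family"),
    )


# ---------------------------------------------------------------------------
# square matrices / maternal LD / phenotypes


def write_matrix(path: str | Path, M: np.ndarray, marker_ids: list[str]) -> None:
    """Write a square marker-by-marker matrix as TSV with an id header;
    NaN cells become ``NA``."""
    pd.DataFrame(np.asarray(M, float), index=marker_ids, columns=marker_ids).to_csv(
        path, sep="\t", na_rep="NA", index_label="marker_id"
    )


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def read_maternal_ld(d_path: str | Path, freq_path: str | Path) -> MaternalLD:
    """Read a maternal gametic-covariance matrix (TSV with marker-id header)
    and the matching allele-frequency table (columns marker_id, freq)."""
    D, ids = read_matrix(d_path)
    freq = pd.read_csv(freq_path, sep="\t")
    if not {"marker_id", "freq"}.issubset(freq.columns):
        raise ParseError(f"{freq_path}: expected columns marker_id, freq")
    freq = freq.set_index("marker_id").loc[ids, "freq"].to_numpy(dtype=float)
    ld = MaternalLD(D=D, p_freq=freq)
    return ld


def write_phenotypes(path: str | Path, y: np.ndarray, individual_ids: list[str], family: list[str]) -> None:
    pd.DataFrame(
        {"individual_id": individual_ids, "family": family, "phenotype": np.asarray(y, float)}
    ).to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "phenotype" not in df.columns:
        raise ParseError(f"{path}: expected a 'phenotype' column")
    return df
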