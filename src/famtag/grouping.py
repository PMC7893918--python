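"""Greedy binning of markers from a scaled dependence matrix and selection
of one representative (tagSNP) per group.

Groups are built successively, the largest first.  At iteration b, every
unbinned marker k collects the set C_k of unbinned markers l with
|R_kl| > t (k itself included, since |R_kk| = 1); a marker c with maximal
#C_k seeds group b = C_c.  Within the group, the candidate set T holds the
members associated above t with *every* group member, and the
ceil(#T/2)-th candidate (ascending marker index) becomes the tagSNP.  The
binned markers are removed and the iteration repeats until no marker is
left, giving O(p^2) total work.
"""

from __future__ import annotations

import numpy as np

from .types import DependenceMatrix, GeneticMap, Grouping


def _adjacency(R: np.ndarray, t: float) -> np.ndarray:
    """|R_kl| > t with NaN (unestimable) pairs never associated; the
    diagonal is forced True (|R_kk| = 1 > t)."""
    with np.errstate(invalid="ignore"):
        A = np.abs(R) > t
    A &= ~np.isnan(R)
    np.fill_diagonal(A, True)
    return A


def build_groups(R: DependenceMatrix | np.ndarray, t: float = 0.8) -> Grouping:
    """Partition markers into groups of mutual dependence above threshold
    ``t`` (strict inequality) and pick a tagSNP per group.

    Ties in the largest-set choice are broken by the smallest marker
    index, so identical inputs always give identical groupings.
    """
    if not (0 <= t < 1):
        raise ValueError("threshold t must lie in [0, 1)")
    if isinstance(R, DependenceMatrix):
        mat, source = R.values, R.source
    else:
        mat, source = np.asarray(R, dtype=float), "family"
    p = mat.shape[0]
    A = _adjacency(mat, t)

    unbinned = np.ones(p, dtype=bool)
    groups: list[list[int]] = []
    reps: list[int] = []
    while unbinned.any():
        counts = (A & unbinned).sum(axis=1)
        counts[~unbinned] = -1
        c = int(np.argmax(counts))  # argmax takes the smallest index on ties
        members = np.flatnonzero(A[c] & unbinned)
        groups.append(members.tolist())
        reps.append(select_representative(members, A))
        unbinned[members] = False
    return Grouping(groups=groups, representatives=reps, threshold=t, source=source)


def select_representative(group: np.ndarray, A_or_R: np.ndarray, t: float | None = None) -> int:
    """TagSNP of a group built by the greedy step: among members associated
    with every other member, return the ceil(#T/2)-th in ascending index
    order.

    ``A_or_R`` is either the boolean association matrix or the dependence
    matrix itself (then ``t`` must be given).
    """
    group = np.sort(np.asarray(group, dtype=int))
    A = A_or_R if A_or_R.dtype == bool else _adjacency(np.asarray(A_or_R, float), t)
    sub = A[np.ix_(group, group)]
    candidates = group[sub.all(axis=1)]
    if candidates.size == 0:
        raise AssertionError("empty candidate set: greedy invariant violated")
    return int(candidates[int(np.ceil(candidates.size / 2)) - 1])


def grouping_summary(
    grouping: Grouping, gmap: GeneticMap, kept_index: np.ndarray | None = None
) -> dict:
    """Headline numbers of a grouping: group count, count of groups with at
    least three members, median distance (cM) between consecutive tagSNPs,
    and the tagSNP list.

    ``kept_index`` maps matrix-local marker indices to map positions when
    the dependence matrix was built on a subset of the map.
    """
    reps = np.asarray(grouping.representatives, dtype=int)
    if kept_index is not None:
        reps_map = np.asarray(kept_index, int)[reps]
    else:
        reps_map = reps
    pos = np.sort(gmap.position_cm[reps_map])
    gaps = np.diff(pos)
    return {
        "n_groups": grouping.n_groups,
        "n_groups_ge3": sum(len(g) >= 3 for g in grouping.groups),
        "median_tag_distance_cm": float(np.median(gaps)) if gaps.size else float("nan"),
        "tag_snps": reps_map.tolist(),
    }
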