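"""Cluster-quality evaluation of marker groupings.

The Calinski-Harabasz (CH) index scores a partition of markers by the
ratio of between- to within-cluster dispersion, each divided by its
degrees of freedom; markers are represented as points by their
within-family standardized genotype vectors, so a higher CH means the
grouping separates genuinely dependent markers from independent ones.
"""

from __future__ import annotations

import logging

import numpy as np

from .preprocess import standardize_within_family
from .types import GenotypeMatrix, Grouping

log = logging.getLogger(__name__)


def ch_index(points: np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz index of ``q`` points (rows) under integer cluster
    ``labels``:

        CH = [B / (K - 1)] / [W / (q - K)]

    with B the size-weighted squared distances of cluster centroids to the
    grand centroid and W the summed squared distances of points to their
    cluster centroid.  A zero within-dispersion yields +inf with a warning.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    q = points.shape[0]
    if labels.shape[0] != q:
        raise ValueError("one label per point required")
    uniq = np.unique(labels)
    K = uniq.size
    if K < 2:
        raise ValueError("CH undefined for fewer than two clusters")
    if q <= K:
        raise ValueError("CH requires more points than clusters")
    grand = points.mean(axis=0)
    B = 0.0
    W = 0.0
    for lab in uniq:
        cluster = points[labels == lab]
        centroid = cluster.mean(axis=0)
        B += cluster.shape[0] * float(np.sum((centroid - grand) ** 2))
        W += float(np.sum((cluster - centroid) ** 2))
    if W == 0.0:
        log.warning("ch_index: zero within-cluster dispersion; returning +inf")
        return float("inf")
    return (B / (K - 1)) / (W / (q - K))


def grouping_quality(G: GenotypeMatrix, grouping: Grouping) -> float:
    """CH index of a marker grouping on the within-family standardized
    genotype matrix.

    Each marker becomes one point (its standardized genotype vector over
    individuals); markers that lose all variance in standardization are
    excluded with a warning.  Higher is better; the comparison between
    methods is up to the caller.
    """
    markers = grouping.marker_indices
    X, degenerate = standardize_within_family(
        G.values[:, markers].astype(float), G.family_label
    )
    keep = ~degenerate
    if degenerate.any():
        log.warning(
            "grouping_quality: %d markers dropped (zero within-family variance)",
            int(degenerate.sum()),
        )
    labels = grouping.labels(markers)
    return ch_index(X.T[keep], labels[keep])


def plot_dependence_matrix(values: np.ndarray, path: str, title: str = "") -> None:
    """Basic heatmap of a dependence matrix; NaN cells render white."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(values, cmap="RdBu_r", vmin=-1, vmax=1, interpolation="nearest")
    ax.set_title(title)
    ax.set_xlabel("marker index")
    ax.set_ylabel("marker index")
    fig.colorbar(im, ax=ax)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
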