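"""Average-linkage hierarchical clustering on correlation distance.

Distance between two items (genes or samples) is 1 - r, with r the
centred Pearson correlation over their pairwise-complete positions, so
distances live in [0, 2].  Agglomeration is UPGMA with ties in the
minimum merge distance broken deterministically toward the pair whose
clusters contain the lexicographically smallest leaf labels, making the
result invariant to input row/column order.

The two-group sample cut used for patient stratification is the split
at the root of the sample dendrogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import Dendrogram, ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

_TIE_TOL = 1e-12


@dataclass
class ClusteringConfig:
    metric: str = "centered_correlation"
    linkage: str = "average"
    min_pairwise_overlap: int = 3

    def __post_init__(self) -> None:
        if self.metric not in ("centered_correlation", "uncentered_correlation"):
            raise ValidationError("unknown metric")
        if self.linkage != "average":
            raise ValidationError("only average linkage is supported")


def correlation_distance(
    matrix: ExpressionMatrix,
    axis: str = "samples",
    config: ClusteringConfig | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Pairwise 1 - r distance matrix over genes or samples.

    Pairs sharing fewer than ``min_pairwise_overlap`` non-missing
    positions get the maximum observed distance plus a small epsilon,
    with a warning.
    """
    config = config or ClusteringConfig()
    if axis == "samples":
        data = matrix.values.T
        labels = matrix.sample_ids
    elif axis == "genes":
        data = matrix.values
        labels = matrix.probe_ids
    else:
        raise ValidationError("axis must be 'samples' or 'genes'")

    n = data.shape[0]
    counts = (~np.isnan(data)).sum(axis=1)
    bad = [labels[i] for i in range(n) if counts[i] < 2]
    if bad:
        raise ValidationError(f"items with < 2 non-missing values: {bad}")

    dist = np.zeros((n, n))
    low_overlap: list[tuple[int, int]] = []
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(data[i]) & ~np.isnan(data[j])
            if both.sum() < config.min_pairwise_overlap:
                low_overlap.append((i, j))
                dist[i, j] = dist[j, i] = np.nan
                continue
            x, y = data[i, both], data[j, both]
            if config.metric == "centered_correlation":
                x = x - x.mean()
                y = y - y.mean()
            denom = np.sqrt((x * x).sum() * (y * y).sum())
            r = 0.0 if denom == 0 else float((x * y).sum() / denom)
            dist[i, j] = dist[j, i] = 1.0 - np.clip(r, -1.0, 1.0)
    if low_overlap:
        finite = dist[~np.isnan(dist)]
        fill = (finite.max() if finite.size else 2.0) + 1e-6
        for i, j in low_overlap:
            dist[i, j] = dist[j, i] = fill
        logger.warning(
            "%d item pairs below the overlap threshold; distance set to %g",
            len(low_overlap), fill,
        )
    return dist, labels


def average_linkage(
    distances: np.ndarray, labels: list[str]
) -> Dendrogram:
    """UPGMA agglomeration with lexicographic tie-breaking."""
    distances = np.asarray(distances, dtype=float)
    n = distances.shape[0]
    if distances.ndim != 2 or distances.shape[0] != distances.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(distances, distances.T, atol=1e-9, equal_nan=True):
        raise ValidationError("distance matrix must be symmetric")
    if len(labels) != n:
        raise ValidationError("labels must match distance matrix size")
    if n < 2:
        return Dendrogram(labels=list(labels))

    # active clusters: id -> (size, smallest leaf label)
    d = distances.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    active = list(range(n))            # positions into the working matrix
    node_of = list(range(n))           # node ids (leaves 0..n-1, merges n..)
    sizes = [1] * n
    min_label = [str(lab) for lab in labels]
    merges: list[tuple[int, int, float, int]] = []

    work = d.copy()
    for _ in range(n - 1):
        k = len(active)
        sub = work[np.ix_(active, active)]
        mval = np.min(sub)
        # candidate pairs within tolerance of the minimum
        cand = np.argwhere(sub <= mval + _TIE_TOL)
        best = None
        for a, b in cand:
            if a >= b:
                continue
            ia, ib = active[a], active[b]
            key = tuple(sorted((min_label[ia], min_label[ib])))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        ia, ib = active[a], active[b]
        na, nb = sizes[ia], sizes[ib]
        left, right = node_of[ia], node_of[ib]
        if min_label[ib] < min_label[ia]:
            left, right = right, left
        merges.append((left, right, float(work[ia, ib]), na + nb))

        # average-linkage update into slot ia
        for ic in active:
            if ic in (ia, ib):
                continue
            work[ia, ic] = work[ic, ia] = (
                na * work[ia, ic] + nb * work[ib, ic]
            ) / (na + nb)
        sizes[ia] = na + nb
        min_label[ia] = min(min_label[ia], min_label[ib])
        node_of[ia] = n + len(merges) - 1
        active.remove(ib)
        work[ib, :] = np.inf
        work[:, ib] = np.inf
    return Dendrogram(labels=[str(lab) for lab in labels], merges=merges)


def cluster_axis(
    matrix: ExpressionMatrix,
    axis: str = "samples",
    config: ClusteringConfig | None = None,
) -> Dendrogram:
    dist, labels = correlation_distance(matrix, axis=axis, config=config)
    return average_linkage(dist, labels)


def cut_two_groups(sample_dendrogram: Dendrogram) -> tuple[list[str], list[str]]:
    """Partition items into the two subtrees of the root."""
    if sample_dendrogram.n_leaves < 2:
        raise ValidationError("two-group cut requires at least 2 items")
    left, right = sample_dendrogram.root_children_leafsets()
    labels = sample_dendrogram.labels
    return [labels[i] for i in left], [labels[i] for i in right]
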