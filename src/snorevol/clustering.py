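"""Agglomerative clustering of clip features and semantic labeling.

Clips are merged bottom-up (average linkage by default) on the precomputed
Euclidean distance matrix, the dendrogram is cut into three clusters, and
the clusters are named snoring / normal / uncertain by their mean clip RMS
(loudest -> snoring, quietest -> uncertain).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from snorevol.preprocess import Clip

SEMANTIC_LABELS = ("snoring", "normal", "uncertain")


@dataclass
class Dendrogram:
    """Merge sequence in scipy linkage format plus leaf count."""

    merges: np.ndarray  # (n-1, 4): node_a, node_b, height, new_size
    n_leaves: int
    linkage: str


@dataclass
class ClusterAssignment:
    cluster_id: np.ndarray  # per clip, in {0..k-1}
    semantic: dict[int, str]  # cluster id -> label

    def labels(self) -> list[str]:
        return [self.semantic[int(c)] for c in self.cluster_id]


def _validate_distance_matrix(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=np.float64)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(d < 0):
        raise ValueError("distance matrix must be nonnegative")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    return d


def ahc_linkage(d: np.ndarray, linkage: str = "average") -> Dendrogram:
    """Agglomerative merge sequence on a precomputed distance matrix.

    ``ward`` operates on the distances as given (valid for Euclidean
    matrices); other linkages use the matrix directly.
    """
    d = _validate_distance_matrix(d)
    condensed = squareform(d, checks=False)
    merges = hierarchy.linkage(condensed, method=linkage)
    return Dendrogram(merges=merges, n_leaves=d.shape[0], linkage=linkage)


def cut_tree(t: Dendrogram, k: int) -> np.ndarray:
    """Partition into k clusters by undoing the last k-1 merges.

    Cluster ids are relabeled to 0..k-1 in order of first appearance so the
    output is deterministic.
    """
    if not 1 <= k <= t.n_leaves:
        raise ValueError(f"k must be in [1, {t.n_leaves}], got {k}")
    raw = hierarchy.cut_tree(t.merges, n_clusters=k).ravel()
    ids = np.empty_like(raw)
    mapping: dict[int, int] = {}
    for i, c in enumerate(raw):
        if c not in mapping:
            mapping[c] = len(mapping)
        ids[i] = mapping[c]
    return ids


def assign_semantics(ids: np.ndarray, clips: list[Clip]) -> ClusterAssignment:
    """Name 3 clusters by mean clip RMS.

    Quietest cluster -> uncertain; of the remaining two the louder ->
    snoring, the other -> normal.  Ties break by cluster id (lower id gets
    the louder label).
    """
    ids = np.asarray(ids)
    uniq = np.unique(ids)
    if len(uniq) != 3:
        raise ValueError(f"semantic assignment requires exactly 3 clusters, got {len(uniq)}")
    if len(ids) != len(clips):
        raise ValueError("ids and clips length mismatch")
    rms = np.array([c.rms() for c in clips])
    mean_rms = {int(c): float(rms[ids == c].mean()) for c in uniq}
    # sort loud -> quiet; ties broken by ascending cluster id
    order = sorted(mean_rms, key=lambda c: (-mean_rms[c], c))
    semantic = {order[0]: "snoring", order[1]: "normal", order[2]: "uncertain"}
    return ClusterAssignment(cluster_id=ids, semantic=semantic)


def merges_to_table(t: Dendrogram) -> list[dict]:
    """Dendrogram merge list as plain records for CSV export."""
    return [
        {
            "step": i,
            "node_a": int(row[0]),
            "node_b": int(row[1]),
            "height": float(row[2]),
            "new_size": int(row[3]),
        }
        for i, row in enumerate(t.merges)
    ]
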