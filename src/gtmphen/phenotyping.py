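"""Macro-cluster phenotypes: Ward's minimum-variance agglomerative clustering
of the GTM reference vectors (Euclidean metric), with labels mapped back to
latent nodes and thence to subjects.

Merge heights follow the Euclidean-equivalent Ward convention (the
``sqrt(2 * increase-in-ESS)`` family), so dendrograms are directly comparable
with other standard implementations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from . import gtm

__all__ = ["Dendrogram", "PhenotypeAssignment", "ward_linkage", "cut",
           "suggest_k", "derive_phenotypes"]


@dataclass
class Dendrogram:
    """Agglomerative merge history over K leaves.

    ``linkage`` is the standard (K-1) x 4 matrix: each row merges two
    clusters (indices < K are leaves; index K+i is the cluster formed at
    step i) at a given height, producing a cluster of the recorded size.
    """

    linkage: np.ndarray
    n_leaves: int

    def __post_init__(self) -> None:
        Z = np.asarray(self.linkage, dtype=float)
        if Z.shape != (self.n_leaves - 1, 4):
            raise ValueError("linkage must have shape (K-1, 4)")
        heights = Z[:, 2]
        if np.any(np.diff(heights) < -1e-10):
            raise ValueError("merge heights must be non-decreasing")
        if int(Z[-1, 3]) != self.n_leaves:
            raise ValueError("merge sizes must conserve the leaf count")
        self.linkage = Z

    @property
    def merges(self) -> list[tuple[int, int, float, int]]:
        return [(int(a), int(b), float(h), int(s)) for a, b, h, s in self.linkage]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.linkage,
                     columns=["cluster_a", "cluster_b", "height", "new_size"]
                     ).to_csv(path, index=False)

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        height = {i: 0.0 for i in range(self.n_leaves)}
        label = {i: str(i) for i in range(self.n_leaves)}
        for step, (a, b, h, _s) in enumerate(self.merges):
            node = self.n_leaves + step
            la = f"{label[a]}:{h - height[a]:.6g}"
            lb = f"{label[b]}:{h - height[b]:.6g}"
            label[node] = f"({la},{lb})"
            height[node] = h
        return label[2 * self.n_leaves - 2] + ";"


@dataclass
class PhenotypeAssignment:
    k: int
    node_labels: np.ndarray        # length K, phenotype ids 1..k
    subject_labels: np.ndarray     # length N, phenotype ids 1..k
    dendrogram: Dendrogram
    empty_phenotypes: list[int]    # phenotypes with no assigned subjects

    def to_csv(self, path: str | Path, subject_ids=None, micro_labels=None) -> None:
        n = len(self.subject_labels)
        df = pd.DataFrame({
            "subject_id": subject_ids if subject_ids is not None else np.arange(n),
            "micro_node": micro_labels if micro_labels is not None else -1,
            "phenotype": self.subject_labels,
        })
        df.to_csv(path, index=False)


def ward_linkage(vectors: np.ndarray) -> Dendrogram:
    """Ward's minimum-variance dendrogram of the rows of ``vectors``.

    Each merge is the pair of clusters whose union least increases the total
    within-cluster sum of squares; distances are Euclidean.
    """
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2 or vectors.shape[0] < 2:
        raise ValueError("need a K x D matrix with K >= 2")
    if not np.isfinite(vectors).all():
        raise ValueError("vectors must be finite")
    Z = hierarchy.linkage(vectors, method="ward")
    return Dendrogram(linkage=Z, n_leaves=vectors.shape[0])


def cut(dendrogram: Dendrogram, k: int) -> np.ndarray:
    """Labels obtained by undoing the last ``k - 1`` merges.

    Returns contiguous ids 1..k, numbered by each cluster's first leaf index.
    """
    K = dendrogram.n_leaves
    if not 1 <= k <= K:
        raise ValueError(f"k must be in [1, {K}], got {k}")
    raw = hierarchy.cut_tree(dendrogram.linkage, n_clusters=k).ravel()
    relabel: dict[int, int] = {}
    out = np.empty(K, dtype=int)
    for leaf in range(K):
        out[leaf] = relabel.setdefault(raw[leaf], len(relabel) + 1)
    return out


def suggest_k(dendrogram: Dendrogram, k_range: tuple[int, int]) -> int:
    """Advisory number of phenotypes: the cut with the largest relative gap
    between successive merge heights.  Falls back to the range minimum when
    heights are uniform.  Never applied silently."""
    K = dendrogram.n_leaves
    kmin, kmax = k_range
    if not (2 <= kmin <= kmax <= K - 1):
        raise ValueError(f"k_range must satisfy 2 <= min <= max <= {K - 1}")
    heights = dendrogram.linkage[:, 2]
    best_k, best_gap = kmin, -np.inf
    for k in range(kmin, kmax + 1):
        kept = heights[K - 1 - k]          # last merge still applied
        undone = heights[K - k]            # first merge undone by this cut
        gap = (undone - kept) / kept if kept > 0 else (np.inf if undone > 0 else 0.0)
        if gap > best_gap + 1e-12:
            best_gap, best_k = gap, k
    return best_k


def derive_phenotypes(model: gtm.GTMModel, data: np.ndarray, k: int) -> PhenotypeAssignment:
    """Full macro-clustering: Ward on the reference vectors, cut at ``k``,
    then propagate node labels to subjects via their argmax micro-cluster.

    A phenotype may end up with zero subjects (its nodes attract no argmax);
    such phenotypes are reported, not an error.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    Y = gtm.reference_vectors(model)
    dend = ward_linkage(Y)
    node_labels = cut(dend, k)
    micro = gtm.assign_micro(model, data)
    subject_labels = node_labels[micro]
    empty = sorted(set(range(1, k + 1)) - set(subject_labels.tolist()))
    return PhenotypeAssignment(k=k, node_labels=node_labels,
                               subject_labels=subject_labels,
                               dendrogram=dend, empty_phenotypes=empty)
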