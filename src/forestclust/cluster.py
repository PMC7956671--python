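"""Hierarchical consensus clustering with Ward linkage on the forest distance.

The averaged forest dissimilarity is clustered agglomeratively (Ward
linkage, applied to the raw dissimilarities).  Robust cluster numbers and
labels come from consensus resampling: random item subsets are clustered
and cut at each candidate k, co-assignment proportions form a consensus
matrix per k, and k is chosen by the largest relative increase in the area
under the consensus CDF (the delta-area rule).  Final labels are obtained
by Ward on 1 - consensus at the chosen k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .distance import DissimilarityMatrix


class Dendrogram:
    """An agglomerative merge sequence over n leaves.

    Wraps a scipy linkage matrix plus leaf identifiers.  ``merge_step(i, j)``
    is the 1-based step at which leaves i and j first co-cluster; cutting
    the tree into k clusters keeps them together iff merge_step <= n - k.
    """

    def __init__(self, Z: np.ndarray, leaf_ids: list[str]):
        self.Z = np.asarray(Z, dtype=float)
        self.leaf_ids = list(leaf_ids)
        self.n = len(self.leaf_ids)
        if self.Z.shape[0] != self.n - 1:
            raise ValueError("linkage must contain exactly n-1 merges")
        heights = self.Z[:, 2]
        #: Ward on a metric input gives monotone heights; violations are
        #: recorded (e.g. consensus distances), never silently reordered.
        self.monotone = bool(np.all(np.diff(heights) >= -1e-9))

    def cut(self, k: int) -> np.ndarray:
        """Labels 1..k from removing the k-1 highest merges, ids by leaf order."""
        return self.cut_many([k])[int(k)]

    def cut_many(self, ks) -> dict[int, np.ndarray]:
        """Labels for several cluster counts in one replay of the merge sequence."""
        want = {int(k) for k in ks}
        for k in want:
            if not (1 <= k <= self.n):
                raise ValueError(f"k={k} out of range [1, {self.n}]")
        n = self.n
        assign = np.arange(n, dtype=np.int64)
        members: list[np.ndarray] = [np.array([i]) for i in range(n)]
        raw: dict[int, np.ndarray] = {}
        if n in want:
            raw[n] = assign.copy()
        for m, (a, b, _, _) in enumerate(self.Z):
            merged = np.concatenate([members[int(a)], members[int(b)]])
            members.append(merged)
            assign[merged] = n + m
            count = n - m - 1
            if count in want:
                raw[count] = assign.copy()
        order = hierarchy.leaves_list(self.Z) if n > 1 else np.array([0])
        out = {}
        for k, labels in raw.items():
            relabel: dict[int, int] = {}
            for leaf in order:
                relabel.setdefault(int(labels[leaf]), len(relabel) + 1)
            out[k] = np.array([relabel[int(c)] for c in labels], dtype=np.int64)
        return out

    def merge_steps(self) -> np.ndarray:
        """n x n matrix of 1-based first-merge steps (0 on the diagonal)."""
        n = self.n
        steps = np.zeros((n, n), dtype=np.int64)
        members: list[np.ndarray] = [np.array([i]) for i in range(n)]
        for m, (a, b, _, _) in enumerate(self.Z, start=1):
            left = members[int(a)]
            right = members[int(b)]
            steps[np.ix_(left, right)] = m
            steps[np.ix_(right, left)] = m
            members.append(np.concatenate([left, right]))
        return steps

    def group(self, i: int, j: int, k: int) -> int:
        """1 iff leaves i and j share a cluster when the tree is cut into k."""
        return int(self.merge_steps()[i, j] <= self.n - k)

    def to_newick(self) -> str:
        """Newick text with branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.Z)

        def rec(node, parent_dist: float) -> str:
            length = max(parent_dist - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.leaf_ids[node.id]}:{length:.6g}"
            return f"({rec(node.left, node.dist)},{rec(node.right, node.dist)}):{length:.6g}"

        return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def _as_square(D) -> tuple[np.ndarray, list[str]]:
    if isinstance(D, DissimilarityMatrix):
        return np.asarray(D.D, dtype=float), list(D.sample_ids)
    D = np.asarray(D, dtype=float)
    return D, [f"S{i + 1:04d}" for i in range(len(D))]


def ward_cluster(D) -> Dendrogram:
    """Ward-linkage agglomeration of a square dissimilarity matrix."""
    M, ids = _as_square(D)
    if len(M) < 2:
        raise ValueError("clustering requires at least 2 samples")
    M = (M + M.T) / 2.0
    np.fill_diagonal(M, 0.0)
    Z = hierarchy.linkage(squareform(M, checks=False), method="ward")
    return Dendrogram(Z, ids)


def cut_tree(dend: Dendrogram, k: int) -> np.ndarray:
    return dend.cut(k)


@dataclass
class ClusteringResult:
    """Consensus clustering output: dendrogram, consensus matrix, k, labels."""

    dendrogram: Dendrogram
    consensus_matrix: np.ndarray
    chosen_k: int
    labels: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    consensus_area: dict[int, float] = field(default_factory=dict)
    delta_area: dict[int, float] = field(default_factory=dict)


def _consensus_area(M: np.ndarray) -> float:
    """Area under the empirical CDF of the off-diagonal consensus entries.

    For values in [0, 1] the area under the CDF equals 1 - mean(values).
    """
    iu = np.triu_indices(len(M), k=1)
    return float(1.0 - np.mean(M[iu]))


def consensus_cluster(
    D,
    k_range=range(2, 11),
    n_resamples: int = 250,
    item_fraction: float = 0.8,
    rng: np.random.Generator | int | None = None,
    force_k: int | None = None,
) -> ClusteringResult:
    """Consensus Ward clustering of a dissimilarity matrix.

    Each resample Ward-clusters a random item subset of size
    round(item_fraction x n) and cuts it at every k in ``k_range``; the
    consensus matrix at k is the per-pair co-assignment count divided by
    the co-sampling count.  ``chosen_k`` maximises the delta-area criterion
    (relative increase of the area under the consensus CDF); final labels
    come from Ward on 1 - consensus at the chosen k.
    """
    M, ids = _as_square(D)
    n = len(M)
    ks = [int(k) for k in k_range]
    if any(k < 2 or k > n - 1 for k in ks):
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    if not (0.0 < item_fraction <= 1.0):
        raise ValueError("item_fraction must be in (0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    m = max(2, int(round(item_fraction * n)))
    co_sample = np.zeros((n, n))
    co_cluster = {k: np.zeros((n, n)) for k in ks}
    for _ in range(n_resamples):
        sub = rng.choice(n, size=m, replace=False)
        sub.sort()
        dend = ward_cluster(M[np.ix_(sub, sub)])
        co_sample[np.ix_(sub, sub)] += 1.0
        cuts = dend.cut_many([k for k in ks if k < m])
        for k, lab in cuts.items():
            same = lab[:, None] == lab[None, :]
            co_cluster[k][np.ix_(sub, sub)] += same
    off = ~np.eye(n, dtype=bool)
    if (co_sample[off] == 0).any():
        raise ValueError(
            "some sample pair was never co-sampled; increase n_resamples "
            "or item_fraction so every pair is covered"
        )
    consensus = {}
    for k in ks:
        with np.errstate(invalid="ignore"):
            Mk = np.where(co_sample > 0, co_cluster[k] / np.maximum(co_sample, 1), 0.0)
        np.fill_diagonal(Mk, 1.0)
        consensus[k] = (Mk + Mk.T) / 2.0
    areas = {k: _consensus_area(consensus[k]) for k in ks}
    deltas: dict[int, float] = {}
    for i, k in enumerate(ks):
        if i == 0:
            deltas[k] = areas[k]
        else:
            prev = areas[ks[i - 1]]
            deltas[k] = (areas[k] - prev) / prev if prev > 0 else 0.0
    if force_k is not None:
        chosen = int(force_k)
        if chosen not in consensus:
            if not (2 <= chosen <= n - 1):
                raise ValueError(f"forced k={chosen} out of range")
            # compute the consensus matrix for the forced k as well
            raise ValueError(f"forced k={chosen} not in k_range {ks}")
    else:
        best = max(deltas.values())
        chosen = min(k for k, v in deltas.items() if v >= best - 1e-12)
    Mk = consensus[chosen]
    final_D = 1.0 - Mk
    np.fill_diagonal(final_D, 0.0)
    dend = ward_cluster(DissimilarityMatrix(final_D, ids))
    labels = dend.cut(chosen)
    return ClusteringResult(dend, Mk, chosen, labels, ids, areas, deltas)
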