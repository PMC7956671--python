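"""Cluster-evaluation metrics: ARI, purity, feature purity, Baker's Gamma, CHI.

External agreement between two partitions is measured by the Adjusted Rand
Index and cluster purity; agreement between two dendrograms by Baker's
Gamma (rank correlation of the cluster counts at which leaf pairs first
merge).  Internal consistency is measured by the Calinski-Harabasz index
for numeric features and by feature purity for categorical ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score, calinski_harabasz_score

from .cluster import Dendrogram
from .table import MixedTable


@dataclass
class MetricReport:
    """Optional fields are populated only when their inputs were supplied."""

    ari: float | None = None
    cluster_purity: float | None = None
    feature_purity: float | None = None
    bakers_gamma: float | None = None
    chi: float | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (name, v)
            for name, v in (
                ("ARI", self.ari),
                ("cluster_purity", self.cluster_purity),
                ("feature_purity", self.feature_purity),
                ("bakers_gamma", self.bakers_gamma),
                ("CHI", self.chi),
            )
            if v is not None
        ]
        return pd.DataFrame(rows, columns=["metric", "value"])


def _check_lengths(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a)
    b = np.asarray(b)
    if len(a) != len(b):
        raise ValueError(f"label vectors differ in length ({len(a)} vs {len(b)})")
    return a, b


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected pair-counting agreement between two partitions."""
    a, b = _check_lengths(labels_a, labels_b)
    if len(a) < 2:
        raise ValueError("ARI requires at least 2 samples")
    return float(adjusted_rand_score(a, b))


def cluster_purity(labels_pred, labels_true) -> float:
    """(1/n) sum over predicted clusters of the modal true-class count."""
    pred, true = _check_lengths(labels_pred, labels_true)
    total = 0
    for c in np.unique(pred):
        _, counts = np.unique(true[pred == c], return_counts=True)
        total += counts.max()
    return float(total / len(pred))


def feature_purity(table: MixedTable, labels) -> float:
    """Homogeneity of clusters in the categorical features.

    For each categorical feature, the modal-level fraction per cluster is
    averaged over clusters weighted by cluster size; the result is the
    unweighted mean over categorical features.  Numeric features are the
    province of the Calinski-Harabasz index and are excluded.
    """
    labels = np.asarray(labels)
    if len(labels) != table.n:
        raise ValueError("labels length does not match table")
    cat = [f for f in table.schema if f.is_categorical]
    if not cat:
        raise ValueError("feature purity requires at least one categorical feature")
    per_feature = []
    for f in cat:
        col = table.values[f.name].to_numpy()
        ok = np.array([v is not None for v in col])
        weighted = 0.0
        n_ok = ok.sum()
        if n_ok == 0:
            continue
        for c in np.unique(labels):
            members = (labels == c) & ok
            if not members.any():
                continue
            _, counts = np.unique(col[members], return_counts=True)
            weighted += counts.max() / members.sum() * (members.sum() / n_ok)
        per_feature.append(weighted)
    return float(np.mean(per_feature))


def _gamma_from_steps(sa: np.ndarray, sb: np.ndarray) -> float:
    """Goodman-Kruskal gamma between two integer sequences via a contingency table.

    Exact concordant/discordant counts from 2-D suffix sums; ties (in
    either sequence) are excluded per the gamma convention.
    """
    ka = int(sa.max())
    kb = int(sb.max())
    T = np.zeros((ka, kb), dtype=np.int64)
    np.add.at(T, (sa - 1, sb - 1), 1)
    # F[i, j] = count of observations with a-index < i and b-index < j
    F = np.zeros((ka + 1, kb + 1), dtype=np.int64)
    F[1:, 1:] = np.cumsum(np.cumsum(T, axis=0), axis=1)
    total = F[ka, kb]
    i, j = np.nonzero(T)
    # strictly greater in both coordinates
    n_greater = total - F[i + 1, kb] - F[ka, j + 1] + F[i + 1, j + 1]
    # strictly greater in a, strictly smaller in b
    n_discord = F[ka, j] - F[i + 1, j]
    concordant = int(np.sum(T[i, j] * n_greater))
    discordant = int(np.sum(T[i, j] * n_discord))
    if concordant + discordant == 0:
        return 0.0
    return float((concordant - discordant) / (concordant + discordant))


def bakers_gamma(dend_a: Dendrogram, dend_b: Dendrogram) -> float:
    """Similarity of two dendrograms over the same leaves.

    For every leaf pair, the lowest number of clusters k at which the pair
    first co-clusters is recorded in each dendrogram (equivalently the
    first-merge step); Baker's Gamma is the Goodman-Kruskal rank
    correlation between the two pairwise sequences.  It depends only on
    merge order, so it is invariant to monotone height transformations.
    """
    if set(dend_a.leaf_ids) != set(dend_b.leaf_ids):
        raise ValueError("dendrograms must share the same leaf set")
    order_b = [dend_b.leaf_ids.index(s) for s in dend_a.leaf_ids]
    sa = dend_a.merge_steps()
    sb = dend_b.merge_steps()[np.ix_(order_b, order_b)]
    iu = np.triu_indices(dend_a.n, k=1)
    return _gamma_from_steps(sa[iu], sb[iu])


def calinski_harabasz(numeric_features, labels) -> float:
    """Between- vs within-cluster scatter ratio, scaled by (n-k)/(k-1).

    Degenerate within-cluster scatter (all points identical within every
    cluster) is reported as +inf rather than raising.
    """
    X = np.atleast_2d(np.asarray(numeric_features, dtype=float))
    if X.shape[0] == 1 and len(np.asarray(labels)) != 1:
        X = X.T
    labels = np.asarray(labels)
    n = len(labels)
    k = len(np.unique(labels))
    if k < 2 or k >= n:
        raise ValueError(f"CHI undefined for k={k} with n={n}")
    within = 0.0
    for c in np.unique(labels):
        block = X[labels == c]
        within += float(((block - block.mean(axis=0)) ** 2).sum())
    if within <= 0.0:
        return float("inf")
    return float(calinski_harabasz_score(X, labels))


def evaluate(
    labels_pred=None,
    labels_true=None,
    table: MixedTable | None = None,
    dend_a: Dendrogram | None = None,
    dend_b: Dendrogram | None = None,
) -> MetricReport:
    """Populate every metric whose inputs are available."""
    report = MetricReport()
    if labels_pred is not None and labels_true is not None:
        report.ari = adjusted_rand_index(labels_pred, labels_true)
        report.cluster_purity = cluster_purity(labels_pred, labels_true)
    if table is not None and labels_pred is not None:
        if any(f.is_categorical for f in table.schema):
            report.feature_purity = feature_purity(table, labels_pred)
        numeric = [f.name for f in table.schema if not f.is_categorical]
        if numeric:
            Xn = table.values[numeric].to_numpy(dtype=float)
            labels = np.asarray(labels_pred)
            k = len(np.unique(labels))
            if 2 <= k < len(labels) and not np.isnan(Xn).any():
                report.chi = calinski_harabasz(Xn, labels)
    if dend_a is not None and dend_b is not None:
        report.bakers_gamma = bakers_gamma(dend_a, dend_b)
    return report
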