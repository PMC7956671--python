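"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (enumeration, double loops, direct
formula transcription) and shares no code with the package internals.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


# -- partition metrics ---------------------------------------------------------


def ari_brute(a, b) -> float:
    """Pair-counting ARI over all C(n,2) pairs."""
    a = list(a)
    b = list(b)
    n = len(a)
    n11 = n00 = n10 = n01 = 0
    for i in range(n):
        for j in range(i + 1, n):
            sa = a[i] == a[j]
            sb = b[i] == b[j]
            n11 += sa and sb
            n00 += (not sa) and (not sb)
            n10 += sa and (not sb)
            n01 += (not sa) and sb
    total = comb(n, 2)
    index = n11
    sum_a = sum(comb(c, 2) for c in np.unique(a, return_counts=True)[1])
    sum_b = sum(comb(c, 2) for c in np.unique(b, return_counts=True)[1])
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 0.0
    return (index - expected) / (max_index - expected)


def purity_brute(pred, true) -> float:
    pred = list(pred)
    true = list(true)
    total = 0
    for c in set(pred):
        members = [t for p, t in zip(pred, true) if p == c]
        total += max(members.count(v) for v in set(members))
    return total / len(pred)


def feature_purity_brute(columns: list[list], labels) -> float:
    """columns: list of categorical columns (values hashable, None = missing)."""
    labels = list(labels)
    feats = []
    for col in columns:
        acc = 0.0
        n_ok = sum(v is not None for v in col)
        for c in set(labels):
            members = [v for v, l in zip(col, labels) if l == c and v is not None]
            if not members:
                continue
            modal = max(members.count(v) for v in set(members))
            acc += (modal / len(members)) * (len(members) / n_ok)
        feats.append(acc)
    return float(np.mean(feats))


def gamma_brute(x, y) -> float:
    """Goodman-Kruskal gamma by enumerating all pairs of observations."""
    x = list(x)
    y = list(y)
    conc = disc = 0
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx * dy > 0:
                conc += 1
            elif dx * dy < 0:
                disc += 1
    if conc + disc == 0:
        return 0.0
    return (conc - disc) / (conc + disc)


def chi_brute(X, labels) -> float:
    """Calinski-Harabasz from explicit between/within scatter matrices."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] == 1 and len(labels) != 1:
        X = X.T
    labels = np.asarray(labels)
    n = len(labels)
    ks = np.unique(labels)
    k = len(ks)
    grand = X.mean(axis=0)
    B = 0.0
    W = 0.0
    for c in ks:
        block = X[labels == c]
        mu = block.mean(axis=0)
        B += len(block) * float(((mu - grand) ** 2).sum())
        W += float(((block - mu) ** 2).sum())
    if W == 0:
        return float("inf")
    return (B / (k - 1)) / (W / (n - k))


# -- merge-step matrices and dendrogram comparison -----------------------------


def merge_steps_brute(Z: np.ndarray) -> np.ndarray:
    """First-merge step per leaf pair by replaying the linkage naively."""
    n = Z.shape[0] + 1
    clusters = {i: {i} for i in range(n)}
    steps = np.zeros((n, n), int)
    for m, (a, b, *_ ) in enumerate(Z, start=1):
        left = clusters.pop(int(a))
        right = clusters.pop(int(b))
        for i in left:
            for j in right:
                steps[i, j] = steps[j, i] = m
        clusters[n + m - 1] = left | right
    return steps


# -- split enumeration ---------------------------------------------------------


def _gini(counts) -> float:
    tot = sum(counts)
    return 1.0 - sum((c / tot) ** 2 for c in counts)


def _split_gain(y_left, y_right) -> float:
    y = list(y_left) + list(y_right)
    parent = _gini([y.count(0), y.count(1)])
    n = len(y)
    wl = len(y_left) / n * _gini([list(y_left).count(0), list(y_left).count(1)])
    wr = len(y_right) / n * _gini([list(y_right).count(0), list(y_right).count(1)])
    return parent - wl - wr


def best_split_brute(x, y, nominal: bool):
    """Exhaustive best Gini split: all thresholds or ALL level bipartitions.

    Returns (gain, rule) or None; rule ('thr', t) / ('set', frozenset).
    """
    x = list(x)
    y = list(y)
    best = None
    if not nominal:
        for t in sorted(set(x))[:-1]:
            left = [yi for xi, yi in zip(x, y) if xi <= t]
            right = [yi for xi, yi in zip(x, y) if xi > t]
            if not left or not right:
                continue
            gain = _split_gain(left, right)
            if best is None or gain > best[0] + 1e-12:
                best = (gain, ("thr", t))
    else:
        levels = sorted(set(x))
        for r in range(1, len(levels)):
            for subset in itertools.combinations(levels, r):
                s = set(subset)
                left = [yi for xi, yi in zip(x, y) if xi in s]
                right = [yi for xi, yi in zip(x, y) if xi not in s]
                gain = _split_gain(left, right)
                if best is None or gain > best[0] + 1e-12:
                    best = (gain, ("set", frozenset(s)))
    if best is None or best[0] <= 1e-12:
        return None
    return best


# -- forest recounts -----------------------------------------------------------


def proximity_brute(forest, X) -> np.ndarray:
    """O(T * N^2) triple loop over (tree, i, j)."""
    N = len(X)
    S = np.zeros((N, N))
    for tree in forest.trees:
        term = [_route_one(tree.root, X[i]) for i in range(N)]
        for i in range(N):
            for j in range(N):
                if term[i] == term[j]:
                    S[i, j] += 1
    return S / len(forest.trees)


def _route_one(node, row):
    while node.terminal_id is None:
        x = row[node.feature]
        if node.threshold is not None:
            node = node.left if x <= node.threshold else node.right
        else:
            node = node.left if x in set(node.left_levels.tolist()) else node.right
    return node.terminal_id


def votes_brute(forest, X) -> np.ndarray:
    """Per-row per-class vote recount: route each row down each tree, take the
    terminal's majority class from its recounted class_counts."""
    votes = np.zeros((len(X), 2), int)
    for tree in forest.trees:
        for i in range(len(X)):
            tid = _route_one(tree.root, X[i])
            counts = _terminal_counts(tree.root, tid)
            votes[i, int(np.argmax(counts))] += 1
    return votes


def _terminal_counts(node, tid):
    if node.terminal_id is not None:
        return node.class_counts if node.terminal_id == tid else None
    left = _terminal_counts(node.left, tid)
    if left is not None:
        return left
    return _terminal_counts(node.right, tid)


# -- Ward agglomeration --------------------------------------------------------


def ward_brute(D: np.ndarray):
    """Naive Ward (Lance-Williams) agglomeration.

    Returns a list of (members_left, members_right, height) with frozenset
    members, choosing at each step the minimal-distance pair (ties to the
    lexicographically smallest index pair).
    """
    n = len(D)
    dist = {}
    active = {i: frozenset([i]) for i in range(n)}
    size = {i: 1 for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(D[i, j])
    merges = []
    next_id = n
    while len(active) > 1:
        (a, b), d = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        merges.append((active[a], active[b], d))
        na, nb = size[a], size[b]
        new = next_id
        next_id += 1
        for k in list(active):
            if k in (a, b):
                continue
            nk = size[k]
            dka = dist[tuple(sorted((k, a)))]
            dkb = dist[tuple(sorted((k, b)))]
            dab = d
            val = np.sqrt(
                ((na + nk) * dka**2 + (nb + nk) * dkb**2 - nk * dab**2) / (na + nb + nk)
            )
            dist[tuple(sorted((k, new)))] = float(val)
        for key in [key for key in dist if a in key or b in key]:
            del dist[key]
        active[new] = active[a] | active[b]
        size[new] = na + nb
        del active[a], active[b], size[a], size[b]
    return merges


def linkage_to_merges(Z: np.ndarray):
    """Convert a scipy linkage matrix to the ward_brute merge representation."""
    n = Z.shape[0] + 1
    members = {i: frozenset([i]) for i in range(n)}
    merges = []
    for m, (a, b, h, _) in enumerate(Z):
        la = members[int(a)]
        lb = members[int(b)]
        merges.append((la, lb, float(h)))
        members[n + m] = la | lb
    return merges


def cut_brute(Z: np.ndarray, k: int) -> list[frozenset]:
    """Partition from keeping the first n-k merges (connected components)."""
    n = Z.shape[0] + 1
    members = {i: frozenset([i]) for i in range(n)}
    current = {i: frozenset([i]) for i in range(n)}
    for m, (a, b, *_rest) in enumerate(Z[: n - k]):
        la = members[int(a)]
        lb = members[int(b)]
        members[n + m] = la | lb
        current = {key: v for key, v in current.items() if v != la and v != lb}
        current[n + m] = la | lb
    return sorted(current.values(), key=lambda s: min(s))
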