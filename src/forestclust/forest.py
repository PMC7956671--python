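"""Classification trees and forests with three split regimes.

The engine grows binary classification trees that separate real from
synthetic rows (see :mod:`forestclust.distance`).  Three split regimes are
supported:

``RF``
    Classic Gini impurity reduction.
``RRF``
    Regularized Gini: the gain of a feature the current tree has not yet
    split on is multiplied by a penalty ``rrf_lambda`` in (0, 1], favouring
    compact per-tree feature sets and reducing overfitting.
``uncondCIF`` / ``condCIF``
    Conditional-inference splitting: at each node a Monte-Carlo permutation
    test of independence between each candidate feature and the class label
    is performed; the node splits on the feature with the smallest
    Bonferroni-adjusted p-value, or stops when none is significant at
    ``cif_alpha``.  Because the test is calibrated per feature, features of
    high cardinality are no longer favoured.  The two CIF backends grow
    identical trees and differ only in the variable-importance scheme
    applied afterwards (unconditional vs conditional permutation).

Subsampling is always WITHOUT replacement, by default 0.632 x N per tree,
which removes the category-size bias of bootstrap resampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

BACKENDS = ("RF", "RRF", "uncondCIF", "condCIF")
_EPS = 1e-12


class ParameterError(ValueError):
    """An invalid forest parameter (mtry > p, n_trees < 1, lambda outside (0,1], ...)."""


@dataclass
class ForestParams:
    """Tuning parameters of a forest.

    mtry defaults to ceil(sqrt(p)) at fit time when left as None.
    """

    backend: str = "condCIF"
    n_trees: int = 100
    mtry: int | None = None
    subsample_fraction: float = 0.632
    rrf_lambda: float = 0.8
    cif_alpha: float = 0.05
    cif_early_stop: bool = False
    cif_permutations: int = 199
    max_depth: int | None = None
    min_node_size: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.backend not in BACKENDS:
            raise ParameterError(f"backend {self.backend!r} not in {BACKENDS}")
        if self.n_trees < 1:
            raise ParameterError("n_trees must be >= 1")
        if not (0.0 < self.subsample_fraction <= 1.0):
            raise ParameterError("subsample_fraction must be in (0, 1]")
        if not (0.0 < self.rrf_lambda <= 1.0):
            raise ParameterError("rrf_lambda must be in (0, 1]")
        if not (0.0 < self.cif_alpha < 1.0):
            raise ParameterError("cif_alpha must be in (0, 1)")
        if self.cif_permutations < 1:
            raise ParameterError("cif_permutations must be >= 1")
        if self.min_node_size < 1:
            raise ParameterError("min_node_size must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ParameterError("mtry must be >= 1")


class TreeNode:
    """One node of a split tree.

    Exactly one of (split rule, terminal_id) is set.  Ordered features split
    by ``x <= threshold``; nominal features by membership of the level code
    in ``left_levels`` (codes never seen in the node route right).
    """

    __slots__ = (
        "feature",
        "threshold",
        "left_levels",
        "left",
        "right",
        "terminal_id",
        "class_counts",
    )

    def __init__(self, class_counts: np.ndarray) -> None:
        self.feature: int | None = None
        self.threshold: float | None = None
        self.left_levels: np.ndarray | None = None
        self.left: "TreeNode | None" = None
        self.right: "TreeNode | None" = None
        self.terminal_id: int | None = None
        self.class_counts = class_counts

    @property
    def is_terminal(self) -> bool:
        return self.terminal_id is not None


class Tree:
    """A grown tree: root node plus routing/prediction helpers."""

    def __init__(
        self,
        root: TreeNode,
        n_terminals: int,
        terminal_class: np.ndarray,
        used_features: frozenset[int],
        thresholds: dict[int, list[float]],
    ) -> None:
        self.root = root
        self.n_terminals = n_terminals
        self.terminal_class = terminal_class
        self.used_features = used_features
        self.thresholds = thresholds  # per ordered feature: thresholds used in this tree

    def route(self, X: np.ndarray) -> np.ndarray:
        """Terminal id for every row (the partition property: exactly one leaf)."""
        term = np.empty(len(X), dtype=np.int64)
        stack = [(self.root, np.arange(len(X)))]
        while stack:
            node, idx = stack.pop()
            if node.is_terminal:
                term[idx] = node.terminal_id
                continue
            x = X[idx, node.feature]
            if node.threshold is not None:
                go_left = x <= node.threshold
            else:
                go_left = np.isin(x, node.left_levels)
            stack.append((node.left, idx[go_left]))
            stack.append((node.right, idx[~go_left]))
        return term

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.terminal_class[self.route(X)]


# -- impurity and split search -------------------------------------------------


def gini_impurity(class_counts: Sequence[float]) -> float:
    """Gini impurity 1 - sum f_c^2 of a node's class counts."""
    counts = np.asarray(class_counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty node: Gini impurity undefined")
    f = counts / total
    return float(1.0 - np.sum(f * f))


def _scan_prefix_splits(n1_cum: np.ndarray, n: int, n1: int, valid: np.ndarray):
    """Best prefix split of a sorted sequence under Gini; returns (pos, gain) or None.

    n1_cum[i] = class-1 count among the first i+1 items; valid[i] marks
    positions after which a split is allowed (boundary between distinct
    values).  Gain is impurity decrease relative to the parent node.
    """
    if not valid.any():
        return None
    m = len(n1_cum)  # = n - 1 prefix positions
    nL = np.arange(1, m + 1, dtype=float)
    nR = n - nL
    n1L = n1_cum.astype(float)
    n1R = n1 - n1L
    pL = n1L / nL
    pR = n1R / nR
    weighted = (nL / n) * 2.0 * pL * (1.0 - pL) + (nR / n) * 2.0 * pR * (1.0 - pR)
    weighted = np.where(valid, weighted, np.inf)
    pos = int(np.argmin(weighted))
    parent = gini_impurity([n1, n - n1])
    gain = parent - float(weighted[pos])
    return pos, gain


def _best_split_feature(x: np.ndarray, y: np.ndarray, nominal: bool):
    """Best Gini split of one feature; returns (gain, rule) or None.

    rule is ('thr', threshold) for ordered features and ('set', level_codes)
    for nominal ones.  For nominal features the levels are ordered by their
    class-1 fraction and scanned as prefixes, which is exact for a binary
    class label under Gini.
    """
    n = len(y)
    n1 = int(y.sum())
    if n1 == 0 or n1 == n:
        return None
    if not nominal:
        order = np.argsort(x, kind="stable")
        xs = x[order]
        boundary = xs[:-1] < xs[1:]
        res = _scan_prefix_splits(np.cumsum(y[order])[:-1], n, n1, boundary)
        if res is None:
            return None
        pos, gain = res
        if gain <= _EPS:
            return None
        return gain, ("thr", float((xs[pos] + xs[pos + 1]) / 2.0))
    levels, inverse = np.unique(x, return_inverse=True)
    if len(levels) < 2:
        return None
    nl = np.bincount(inverse).astype(float)
    n1l = np.bincount(inverse, weights=y.astype(float))
    frac = n1l / nl
    order = np.lexsort((levels, frac))  # by class fraction, ties by level code
    # weighted impurity over level prefixes, with item (not level) counts
    cum_n = np.cumsum(nl[order])[:-1]
    cum_n1 = np.cumsum(n1l[order])[:-1]
    pL = cum_n1 / cum_n
    nR = n - cum_n
    pR = (n1 - cum_n1) / nR
    weighted = (cum_n / n) * 2.0 * pL * (1.0 - pL) + (nR / n) * 2.0 * pR * (1.0 - pR)
    pos = int(np.argmin(weighted))
    parent = gini_impurity([n1, n - n1])
    gain = parent - float(weighted[pos])
    if gain <= _EPS:
        return None
    return gain, ("set", levels[order[: pos + 1]].copy())


def _batched_ordered_gains(Xc: np.ndarray, y: np.ndarray, n1: int):
    """Per-column best Gini split over a block of ordered features.

    Returns (gains, positions, sorted_values); gain is -inf for columns
    with no admissible split.  Vectorised across columns: one argsort and
    one cumulative sum for the whole candidate block.
    """
    n, m = Xc.shape
    order = np.argsort(Xc, axis=0, kind="stable")
    xs = np.take_along_axis(Xc, order, axis=0)
    ys = y[order].astype(np.float64)
    n1L = np.cumsum(ys, axis=0)[:-1]
    nL = np.arange(1, n, dtype=np.float64)[:, None]
    nR = n - nL
    n1R = n1 - n1L
    # nL*2p(1-p) + nR*2q(1-q) = 2*(n1L - n1L^2/nL + n1R - n1R^2/nR)
    weighted = (2.0 / n) * (n1L - n1L * n1L / nL + n1R - n1R * n1R / nR)
    weighted[xs[:-1] >= xs[1:]] = np.inf  # splits only between distinct values
    pos = np.argmin(weighted, axis=0)
    cols = np.arange(m)
    parent = gini_impurity([n1, n - n1])
    gains = parent - weighted[pos, cols]
    gains[~np.isfinite(gains)] = -np.inf
    return gains, pos, xs


def best_split_gini(X: np.ndarray, y: np.ndarray, candidates: Sequence[int], nominal_mask: np.ndarray):
    """Best (feature, rule, gain) over candidate features; None if no split improves.

    Ties in gain are broken toward the lowest feature index (candidates are
    scanned in ascending order with a strict improvement test).
    """
    best = None
    for j in sorted(candidates):
        res = _best_split_feature(X[:, j], y, bool(nominal_mask[j]))
        if res is None:
            continue
        gain, rule = res
        if best is None or gain > best[2] + _EPS:
            best = (j, rule, gain)
    return best


def regularized_gain(raw_gain: float, feature: int, used_set: set[int], rrf_lambda: float) -> float:
    """RRF-adjusted gain: unpenalized if the tree already split on the feature."""
    if raw_gain < 0:
        raise ValueError("raw_gain must be >= 0")
    if not (0.0 < rrf_lambda <= 1.0):
        raise ParameterError("rrf_lambda must be in (0, 1]")
    return raw_gain if feature in used_set else rrf_lambda * raw_gain


# -- conditional-inference permutation tests -----------------------------------


def _perm_label_matrix(y: np.ndarray, n_permutations: int, rng: np.random.Generator) -> np.ndarray:
    """n_permutations independent uniform permutations of the binary label.

    Exploits binary labels: a permutation is determined by which positions
    receive the n1 ones, so each row marks the n1 smallest of n random keys.
    """
    uniq = np.unique(y)
    if len(uniq) == 2 and uniq[0] == 0 and uniq[1] == 1:
        n1 = int(y.sum())
        R = rng.random((n_permutations, len(y)))
        thr = np.partition(R, n1 - 1, axis=1)[:, n1 - 1][:, None]
        return (R <= thr).astype(np.float64)
    tiled = np.tile(y.astype(np.float64), (n_permutations, 1))
    return rng.permuted(tiled, axis=1)


def _ordered_stats(x: np.ndarray, y_float: np.ndarray, P: np.ndarray):
    """|centered class-1 group sum| for observed and permuted labels."""
    xc = x - x.mean()
    return abs(float(y_float @ xc)), np.abs(P @ xc)


def _nominal_stats(x: np.ndarray, y_float: np.ndarray, P: np.ndarray):
    """Pearson chi-square of the level x label table, observed and permuted."""
    levels, inverse = np.unique(x, return_inverse=True)
    L = len(levels)
    D = np.zeros((len(x), L))
    D[np.arange(len(x)), inverse] = 1.0
    nl = D.sum(axis=0)
    n = float(len(x))
    n1 = float(y_float.sum())
    e1 = n1 * nl / n
    e0 = (n - n1) * nl / n
    c_obs = y_float @ D
    with np.errstate(divide="ignore", invalid="ignore"):
        obs = np.nansum((c_obs - e1) ** 2 / e1 + ((nl - c_obs) - e0) ** 2 / e0)
        C = P @ D
        perm = np.nansum((C - e1) ** 2 / e1 + ((nl - C) - e0) ** 2 / e0, axis=1)
    return float(obs), perm


def cif_feature_test(
    x: np.ndarray,
    y: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
    nominal: bool = False,
) -> float:
    """Monte-Carlo permutation p-value for independence of a feature and the label.

    Test statistic: |centered group sum| (standardized linear association)
    for ordered features; Pearson chi-square on the level x label table for
    nominal features.  p = (1 + #{perm >= obs}) / (1 + B); a constant
    feature returns 1 by convention.
    """
    if len(np.unique(y)) < 2:
        raise ValueError("labels must take at least 2 values in the node")
    if len(np.unique(x)) < 2:
        return 1.0
    y_float = y.astype(np.float64)
    P = _perm_label_matrix(y, n_permutations, rng)
    obs, perm = (_nominal_stats if nominal else _ordered_stats)(x, y_float, P)
    return float((1 + int(np.sum(perm >= obs - 1e-12))) / (1 + n_permutations))


def _cif_node_pvalues(
    X: np.ndarray,
    y: np.ndarray,
    candidates: Sequence[int],
    nominal_mask: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """p-values for all candidates, sharing one permutation set per node.

    All candidate statistics are evaluated through a single (B x n) @ (n x K)
    product: ordered candidates contribute one centered column, nominal
    candidates a block of level indicators.

    Returns (p_conservative, p_mid).  The conservative value
    (1 + #{perm >= obs}) / (1 + B) is a valid test and drives the stopping
    decision; the mid-p variant counts only half of the tie atom
    (#{perm > obs} + (#{perm == obs} + 1) / 2) / (1 + B) and is used to RANK
    candidates, because the full tie mass would systematically handicap
    features with discrete statistics (few levels) against continuous ones
    -- re-introducing a cardinality bias through the back door.
    """
    n = len(y)
    y_float = y.astype(np.float64)
    cols: list[np.ndarray] = []
    meta: list[tuple] = []  # ('const',) | ('ord', col) | ('nom', start, L, nl)
    width = 0
    for j in candidates:
        x = X[:, j]
        if x.min() == x.max():
            meta.append(("const",))
            continue
        if nominal_mask[j]:
            levels, inverse = np.unique(x, return_inverse=True)
            L = len(levels)
            D = np.zeros((n, L))
            D[np.arange(n), inverse] = 1.0
            cols.append(D)
            meta.append(("nom", width, L, D.sum(axis=0)))
            width += L
        else:
            cols.append((x - x.mean())[:, None])
            meta.append(("ord", width))
            width += 1
    pvals = np.ones(len(candidates))
    pmid = np.ones(len(candidates))
    if width == 0:
        return pvals, pmid
    M = np.hstack(cols)
    P = _perm_label_matrix(y, n_permutations, rng)
    obs_row = y_float @ M
    perm_rows = P @ M
    n1 = float(y_float.sum())
    for i, m in enumerate(meta):
        if m[0] == "const":
            continue
        if m[0] == "ord":
            c = m[1]
            obs = abs(obs_row[c])
            perm = np.abs(perm_rows[:, c])
        else:
            _, start, L, nl = m
            e1 = n1 * nl / n
            e0 = (n - n1) * nl / n
            c_obs = obs_row[start : start + L]
            C = perm_rows[:, start : start + L]
            with np.errstate(divide="ignore", invalid="ignore"):
                obs = np.nansum((c_obs - e1) ** 2 / e1 + ((nl - c_obs) - e0) ** 2 / e0)
                perm = np.nansum((C - e1) ** 2 / e1 + ((nl - C) - e0) ** 2 / e0, axis=1)
        n_ge = int(np.sum(perm >= obs - 1e-12))
        n_gt = int(np.sum(perm > obs + 1e-12))
        pvals[i] = (1 + n_ge) / (1 + n_permutations)
        pmid[i] = (n_gt + (n_ge - n_gt + 1) / 2.0) / (1 + n_permutations)
    return pvals, pmid


def cif_select_and_split(
    X: np.ndarray,
    y: np.ndarray,
    candidates: Sequence[int],
    nominal_mask: np.ndarray,
    cif_alpha: float,
    n_permutations: int,
    rng: np.random.Generator,
    early_stop: bool = True,
):
    """CIF node decision: (feature, rule) to split on, or None to stop.

    Candidate p-values are Bonferroni-adjusted over the number of
    candidates; with ``early_stop`` growth stops when the smallest
    adjusted p-value exceeds ``cif_alpha``.  Inside a forest the stop is
    disabled by default (the convention of conditional-inference forests,
    where single-tree significance stopping would leave most trees
    degenerate) and the node simply splits on the smallest-p candidate.
    Ties break toward the lowest feature index.
    """
    candidates = sorted(candidates)
    pvals, pmid = _cif_node_pvalues(X, y, candidates, nominal_mask, n_permutations, rng)
    # stopping uses the conservative Bonferroni-adjusted minimum; candidate
    # RANKING uses the mid-p values (common factor, see _cif_node_pvalues)
    if early_stop and min(1.0, pvals.min() * len(candidates)) > cif_alpha:
        return None
    if pvals.min() >= 1.0:
        return None  # no candidate shows any association (e.g. all constant)
    best = int(np.argmin(pmid))  # first occurrence = lowest feature index
    res = best_split_gini(X, y, [candidates[best]], nominal_mask)
    if res is None:
        return None
    j, rule, _ = res
    return j, rule


# -- tree growing --------------------------------------------------------------


def _grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    nominal_mask: np.ndarray,
    params: ForestParams,
    mtry: int,
    rng: np.random.Generator,
) -> Tree:
    p = X.shape[1]
    used: set[int] = set()
    thresholds: dict[int, list[float]] = {}
    terminal_counts: list[np.ndarray] = []

    def make_terminal(node: TreeNode) -> None:
        node.terminal_id = len(terminal_counts)
        terminal_counts.append(node.class_counts)

    root = TreeNode(np.bincount(y, minlength=2))
    stack = [(root, np.arange(len(y)), 0)]
    while stack:
        node, idx, depth = stack.pop()
        yn = y[idx]
        n1 = int(yn.sum())
        pure = n1 == 0 or n1 == len(idx)
        too_small = len(idx) < max(2, params.min_node_size)
        too_deep = params.max_depth is not None and depth >= params.max_depth
        if pure or too_small or too_deep:
            make_terminal(node)
            continue
        cand = rng.choice(p, size=mtry, replace=False)
        cand.sort()
        Xn = X[idx]
        split = None
        if params.backend in ("uncondCIF", "condCIF"):
            sel = cif_select_and_split(
                Xn,
                yn,
                cand,
                nominal_mask,
                params.cif_alpha,
                params.cif_permutations,
                rng,
                early_stop=params.cif_early_stop,
            )
            if sel is not None:
                split = (*sel, 0.0)
        else:  # RF / RRF: Gini gain, batched over the ordered candidates
            ord_cand = [int(j) for j in cand if not nominal_mask[j]]
            results: dict[int, tuple[float, tuple]] = {}
            if ord_cand:
                gains, pos, xs = _batched_ordered_gains(Xn[:, ord_cand], yn, n1)
                for i, j in enumerate(ord_cand):
                    if gains[i] > _EPS:
                        thr = float((xs[pos[i], i] + xs[pos[i] + 1, i]) / 2.0)
                        results[j] = (float(gains[i]), ("thr", thr))
            for j in cand:
                if nominal_mask[j]:
                    res = _best_split_feature(Xn[:, j], yn, True)
                    if res is not None:
                        results[int(j)] = res
            best = None  # (adjusted gain, feature, rule, raw gain)
            for j in cand:
                j = int(j)
                if j not in results:
                    continue
                gain, rule = results[j]
                adj = (
                    regularized_gain(gain, j, used, params.rrf_lambda)
                    if params.backend == "RRF"
                    else gain
                )
                if best is None or adj > best[0] + _EPS:
                    best = (adj, j, rule, gain)
            if best is not None:
                split = (best[1], best[2], best[3])
        if split is None:
            make_terminal(node)
            continue
        j, rule, _gain = split
        node.feature = int(j)
        used.add(int(j))
        if rule[0] == "thr":
            node.threshold = rule[1]
            thresholds.setdefault(int(j), []).append(rule[1])
            go_left = Xn[:, j] <= node.threshold
        else:
            node.left_levels = np.asarray(rule[1], dtype=float)
            go_left = np.isin(Xn[:, j], node.left_levels)
        left_idx = idx[go_left]
        right_idx = idx[~go_left]
        if len(left_idx) == 0 or len(right_idx) == 0:  # defensive; rules come from data
            make_terminal(node)
            continue
        node.left = TreeNode(np.bincount(y[left_idx], minlength=2))
        node.right = TreeNode(np.bincount(y[right_idx], minlength=2))
        # push right first so the left child is processed first (stable ids)
        stack.append((node.right, right_idx, depth + 1))
        stack.append((node.left, left_idx, depth + 1))

    term_class = np.array([int(np.argmax(c)) for c in terminal_counts], dtype=np.int64)
    return Tree(root, len(terminal_counts), term_class, frozenset(used), thresholds)


# -- forests -------------------------------------------------------------------


@dataclass
class ForestModel:
    """A fitted ensemble: trees, their in-bag index sets, and the data schema tag."""

    params: ForestParams
    trees: list[Tree]
    inbag: list[np.ndarray]
    n_samples: int
    n_features: int
    nominal_mask: np.ndarray
    mtry: int = 0

    def oob_mask(self) -> np.ndarray:
        """Boolean (n_trees, n_samples): True where a row is out-of-bag."""
        mask = np.ones((len(self.trees), self.n_samples), dtype=bool)
        for t, ib in enumerate(self.inbag):
            mask[t, ib] = False
        return mask


def _tree_rng(seed: int | None, tree_index: int) -> np.random.Generator:
    entropy = 0 if seed is None else int(seed)
    return np.random.default_rng(np.random.SeedSequence(entropy=entropy, spawn_key=(tree_index,)))


def fit_forest_matrix(
    X: np.ndarray, y: np.ndarray, nominal_mask: np.ndarray, params: ForestParams
) -> ForestModel:
    """Fit a forest on an encoded matrix with binary labels.

    Each tree sees an independent no-replacement subsample of size
    round(subsample_fraction x N); at each node mtry features are drawn
    uniformly without replacement.  Deterministic given ``params.seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    if np.isnan(X).any():
        raise ValueError("forest requires complete cases; use MixedTable.drop_incomplete()")
    n, p = X.shape
    if len(np.unique(y)) != 2 or not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1 with both classes present")
    mtry = params.mtry if params.mtry is not None else int(np.ceil(np.sqrt(p)))
    if mtry > p:
        raise ParameterError(f"mtry={mtry} exceeds number of features p={p}")
    n_inbag = int(round(params.subsample_fraction * n))
    n_inbag = max(2, n_inbag)
    trees: list[Tree] = []
    inbags: list[np.ndarray] = []
    for t in range(params.n_trees):
        rng = _tree_rng(params.seed, t)
        ib = rng.choice(n, size=n_inbag, replace=False)
        ib.sort()
        yb = y[ib]
        if yb.min() == yb.max():  # degenerate subsample: single-leaf tree
            root = TreeNode(np.bincount(yb, minlength=2))
            root.terminal_id = 0
            tree = Tree(root, 1, np.array([int(np.argmax(root.class_counts))]), frozenset(), {})
        else:
            tree = _grow_tree(X[ib], yb, nominal_mask, params, mtry, rng)
        trees.append(tree)
        inbags.append(ib)
    return ForestModel(params, trees, inbags, n, p, np.asarray(nominal_mask, bool), mtry)


def fit_forest(table, params: ForestParams) -> ForestModel:
    """Fit a forest on a MixedTable whose ``labels`` carry the binary class."""
    if table.labels is None:
        raise ValueError("fit_forest requires a MixedTable with binary labels attached")
    X, nominal_mask = table.to_matrix()
    classes = np.unique(np.asarray(table.labels))
    if len(classes) != 2:
        raise ValueError("fit_forest requires exactly 2 classes")
    y = (np.asarray(table.labels) == classes[1]).astype(np.int64)
    return fit_forest_matrix(X, y, nominal_mask, params)


def predict_votes(forest: ForestModel, X: np.ndarray) -> np.ndarray:
    """(n_rows, 2) per-class vote counts across trees."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != forest.n_features:
        raise ValueError("feature count does not match the fitted forest")
    votes = np.zeros((len(X), 2), dtype=np.int64)
    for tree in forest.trees:
        pred = tree.predict(X)
        votes[np.arange(len(X)), pred] += 1
    return votes


def predict(forest: ForestModel, X: np.ndarray) -> np.ndarray:
    """Aggregate majority-vote class per row (ties to the lowest class index)."""
    return np.argmax(predict_votes(forest, X), axis=1)


def oob_error(forest: ForestModel, X: np.ndarray, y: np.ndarray) -> float:
    """Out-of-bag misclassification rate.

    Each row is predicted only by trees whose subsample excluded it; rows
    that are never out-of-bag are excluded from the denominator.  With
    subsample_fraction = 1 no row is ever out-of-bag and the error is
    undefined (raises).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    oob = forest.oob_mask()
    if not oob.any():
        raise ValueError("no out-of-bag rows (subsample_fraction = 1): OOB error undefined")
    votes = np.zeros((len(X), 2), dtype=np.int64)
    for t, tree in enumerate(forest.trees):
        rows = np.flatnonzero(oob[t])
        if len(rows) == 0:
            continue
        pred = tree.predict(X[rows])
        votes[rows, pred] += 1
    covered = votes.sum(axis=1) > 0
    if not covered.any():
        raise ValueError("no row is out-of-bag for any tree")
    pred = np.argmax(votes[covered], axis=1)
    return float(np.mean(pred != y[covered]))
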