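"""Synthetic-marginal augmentation, forest proximity and permutation VIMs.

The unsupervised trick: append to the n real rows n synthetic rows drawn
column-by-column from the empirical marginal distributions of the real
data.  Cross-column dependence is destroyed in the synthetic block, so a
forest trained to dichotomise real vs synthetic rows learns exactly the
dependence structure of the real data.  Routing all rows down every tree
yields a proximity s_ij (fraction of trees in which i and j share a
terminal node), hence a dissimilarity d_ij = 1 - s_ij; restricted to the
real rows this is the forest distance used for clustering.

Because one augmentation is a Monte-Carlo draw, dissimilarities and
variable importances are averaged over ``n_forests`` independent
augmentation + forest repetitions.

Variable importance (VIM) of feature j is the mean drop in out-of-bag
real-vs-synthetic accuracy when column j is permuted: unconditionally, or
conditionally within strata of each other feature in turn (which breaks
only the feature-label association while preserving the correlation
structure, the appropriate scheme for correlated predictors).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forest import ForestModel, ForestParams, fit_forest_matrix, oob_error
from .table import MixedTable


@dataclass
class AugmentedData:
    """Real table stacked over its synthetic-marginal copy, with origin labels."""

    table: MixedTable
    origin: np.ndarray  # 0 = real, 1 = synthetic, length 2n
    real_index_map: np.ndarray  # positions of the n real rows

    @property
    def n_real(self) -> int:
        return len(self.real_index_map)


@dataclass
class ProximityMatrix:
    S: np.ndarray
    n_trees: int


@dataclass
class DissimilarityMatrix:
    """Forest distance over REAL rows only; d_ij = 1 - s_ij."""

    D: np.ndarray
    sample_ids: list[str]
    n_forests: int = 1

    def validate(self) -> None:
        D = self.D
        assert np.allclose(D, D.T), "dissimilarity must be symmetric"
        assert np.allclose(np.diag(D), 0.0), "self-dissimilarity must be 0"
        assert D.min() >= -1e-12 and D.max() <= 1 + 1e-12, "entries must lie in [0,1]"


@dataclass
class VimReport:
    """Per-feature importance, raw (unscaled) and scaled to [0, 1]."""

    features: list[str]
    raw: np.ndarray
    scaled: np.ndarray | None = None
    mode: str = "unconditional"
    n_forests: int = 1

    def to_frame(self) -> pd.DataFrame:
        d = {"feature": self.features, "raw": self.raw}
        if self.scaled is not None:
            d["scaled"] = self.scaled
        return pd.DataFrame(d)


# -- synthetic augmentation ----------------------------------------------------


def _augment_matrix(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Synthetic block: each column resampled i.i.d. with replacement."""
    n, p = X.shape
    syn = np.empty_like(X)
    for j in range(p):
        syn[:, j] = X[rng.integers(0, n, size=n), j]
    return syn


def make_synthetic(table: MixedTable, rng: np.random.Generator) -> AugmentedData:
    """Stack the real table over a synthetic-marginal copy of itself.

    Column j of the synthetic block is an i.i.d. with-replacement sample
    from the real column j, so every marginal is preserved while all
    cross-column dependence is destroyed.
    """
    if table.missing_mask.any():
        raise ValueError(
            "synthetic augmentation requires complete cases; "
            "apply MixedTable.drop_incomplete() first"
        )
    n = table.n
    syn_rows = {}
    for f in table.schema:
        col = table.values[f.name].to_numpy()
        syn_rows[f.name] = col[rng.integers(0, n, size=n)]
    syn_df = pd.DataFrame(syn_rows)
    stacked = pd.concat([table.values, syn_df], ignore_index=True)
    samples = list(table.samples) + [f"synthetic_{i + 1:04d}" for i in range(n)]
    aug = MixedTable(stacked, table.schema, samples=samples)
    origin = np.concatenate([np.zeros(n, dtype=np.int64), np.ones(n, dtype=np.int64)])
    return AugmentedData(aug, origin, np.arange(n))


# -- proximity -----------------------------------------------------------------


def compute_proximity(forest: ForestModel, X: np.ndarray) -> ProximityMatrix:
    """Co-terminal fraction over trees for all rows (real and synthetic).

    Every row is routed down every tree (in-bag and out-of-bag alike); a
    shared terminal node increments s_ij by 1, and the matrix is finally
    divided by the number of trees.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != forest.n_features:
        raise ValueError("feature count does not match the fitted forest")
    N = len(X)
    S = np.zeros((N, N), dtype=np.float64)
    for tree in forest.trees:
        term = tree.route(X)
        S += term[:, None] == term[None, :]
    S /= len(forest.trees)
    return ProximityMatrix(S, len(forest.trees))


def to_dissimilarity(
    prox: ProximityMatrix, real_index_map: np.ndarray, sample_ids: list[str] | None = None
) -> DissimilarityMatrix:
    """d = 1 - s restricted to the real x real block, zero diagonal."""
    idx = np.asarray(real_index_map)
    D = 1.0 - prox.S[np.ix_(idx, idx)]
    np.fill_diagonal(D, 0.0)
    if sample_ids is None:
        sample_ids = [f"S{i + 1:04d}" for i in range(len(idx))]
    return DissimilarityMatrix(D, list(sample_ids), n_forests=1)


# -- variable importance -------------------------------------------------------


def _tree_oob_accuracy(tree, X_oob: np.ndarray, y_oob: np.ndarray) -> float:
    return float(np.mean(tree.predict(X_oob) == y_oob))


def vim_unconditional(
    forest: ForestModel, X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Mean per-tree drop in OOB accuracy when each column is permuted.

    A feature used in zero splits of the forest has importance exactly 0:
    permuting it cannot change any routing.
    """
    X = np.asarray(X, dtype=float)
    p = forest.n_features
    oob = forest.oob_mask()
    imp = np.zeros(p)
    for t, tree in enumerate(forest.trees):
        rows = np.flatnonzero(oob[t])
        if len(rows) == 0:
            continue
        X_oob = X[rows]
        y_oob = y[rows]
        base = _tree_oob_accuracy(tree, X_oob, y_oob)
        for j in range(p):
            if j not in tree.used_features:
                continue  # permutation cannot change routing: drop is exactly 0
            perm = rng.permutation(len(rows))
            Xp = X_oob.copy()
            Xp[:, j] = X_oob[perm, j]
            imp[j] += base - _tree_oob_accuracy(tree, Xp, y_oob)
    return imp / len(forest.trees)


def _conditioning_strata(
    forest: ForestModel, tree, X_all: np.ndarray, x_cond: np.ndarray, k: int
) -> np.ndarray:
    """Stratum id per row for conditioning feature k.

    Categorical conditioners stratify by level; numeric conditioners by the
    split thresholds this tree used for k, falling back to quartile bins of
    the full augmented column when the tree never split on k.
    """
    if forest.nominal_mask[k]:
        _, strata = np.unique(x_cond, return_inverse=True)
        return strata
    thr = sorted(tree.thresholds.get(k, []))
    if not thr:
        thr = list(np.unique(np.quantile(X_all[:, k], [0.25, 0.5, 0.75])))
    return np.digitize(x_cond, thr)


def vim_conditional(
    forest: ForestModel, X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Conditional permutation importance.

    For feature j, column j is permuted within the strata induced by each
    other feature k in turn (size-1 strata are left untouched); the OOB
    accuracy drops are averaged over conditioners, then over trees.
    """
    X = np.asarray(X, dtype=float)
    p = forest.n_features
    oob = forest.oob_mask()
    imp = np.zeros(p)
    for t, tree in enumerate(forest.trees):
        rows = np.flatnonzero(oob[t])
        if len(rows) == 0:
            continue
        X_oob = X[rows]
        y_oob = y[rows]
        base = _tree_oob_accuracy(tree, X_oob, y_oob)
        for j in range(p):
            if j not in tree.used_features:
                continue
            drops = []
            for k in range(p):
                if k == j:
                    continue
                strata = _conditioning_strata(forest, tree, X, X_oob[:, k], k)
                Xp = X_oob.copy()
                for s in np.unique(strata):
                    members = np.flatnonzero(strata == s)
                    if len(members) < 2:
                        continue
                    Xp[members, j] = X_oob[members[rng.permutation(len(members))], j]
                drops.append(base - _tree_oob_accuracy(tree, Xp, y_oob))
            if drops:
                imp[j] += float(np.mean(drops))
    return imp / len(forest.trees)


def scale_vims(report: VimReport) -> VimReport:
    """Populate the scaled field: raw clipped at 0, divided by the maximum."""
    raw = np.asarray(report.raw, dtype=float)
    clipped = np.clip(raw, 0.0, None)
    m = clipped.max() if len(clipped) else 0.0
    scaled = clipped / m if m > 0 else np.zeros_like(clipped)
    return VimReport(report.features, raw, scaled, report.mode, report.n_forests)


# -- the averaged pipeline -----------------------------------------------------


@dataclass
class ForestDistanceResult:
    dissimilarity: DissimilarityMatrix
    vims: VimReport
    oob_errors: list[float]

    @property
    def mean_oob_error(self) -> float:
        return float(np.mean(self.oob_errors))


def forest_distance(
    table: MixedTable,
    params: ForestParams,
    n_forests: int = 20,
    seed: int | None = None,
    vim_mode: str | None = None,
) -> ForestDistanceResult:
    """Monte-Carlo averaged forest distance and VIMs.

    Each repetition draws a fresh synthetic augmentation, fits a fresh
    forest, and computes the dissimilarity over real rows plus the
    (unconditional or conditional) VIMs; element-wise means over the
    ``n_forests`` repetitions are returned.  Deterministic given ``seed``.

    vim_mode: 'unconditional', 'conditional', None (skip VIMs, raw = 0),
    or 'auto' (conditional for the condCIF backend, else unconditional).
    """
    if n_forests < 1:
        raise ValueError("n_forests must be >= 1")
    if vim_mode == "auto":
        vim_mode = "conditional" if params.backend == "condCIF" else "unconditional"
    if vim_mode not in (None, "unconditional", "conditional"):
        raise ValueError(f"unknown vim_mode {vim_mode!r}")
    n = table.n
    p = table.p
    D_sum = np.zeros((n, n))
    vim_sum = np.zeros(p)
    oob_errors = []
    for f_idx in range(n_forests):
        child = np.random.SeedSequence(
            entropy=0 if seed is None else int(seed), spawn_key=(f_idx,)
        )
        ss_syn, ss_fit, ss_vim = child.spawn(3)
        aug = make_synthetic(table, np.random.default_rng(ss_syn))
        Xa, nominal_mask = aug.table.to_matrix()
        fit_seed = int(ss_fit.generate_state(1)[0]) & 0x7FFFFFFF
        fparams = ForestParams(**{**params.__dict__, "seed": fit_seed})
        forest = fit_forest_matrix(Xa, aug.origin, nominal_mask, params=fparams)
        prox = compute_proximity(forest, Xa)
        D_sum += to_dissimilarity(prox, aug.real_index_map, table.samples).D
        try:
            oob_errors.append(oob_error(forest, Xa, aug.origin))
        except ValueError:
            pass
        if vim_mode is not None:
            vim_fn = vim_unconditional if vim_mode == "unconditional" else vim_conditional
            vim_sum += vim_fn(forest, Xa, aug.origin, np.random.default_rng(ss_vim))
    D = DissimilarityMatrix(D_sum / n_forests, list(table.samples), n_forests=n_forests)
    vims = VimReport(
        table.feature_names,
        vim_sum / n_forests,
        mode=vim_mode or "unconditional",
        n_forests=n_forests,
    )
    return ForestDistanceResult(D, scale_vims(vims), oob_errors)


# -- artifact I/O (consumed by the CLI) ---------------------------------------


def write_dissimilarity(D: DissimilarityMatrix, path: str) -> str:
    pd.DataFrame(D.D, index=D.sample_ids, columns=D.sample_ids).to_csv(path)
    return path


def read_dissimilarity(path: str) -> DissimilarityMatrix:
    df = pd.read_csv(path, index_col=0)
    return DissimilarityMatrix(df.to_numpy(dtype=float), [str(s) for s in df.index])


def write_vims(report: VimReport, path: str) -> str:
    report.to_frame().to_csv(path, sep="\t", index=False)
    return path
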