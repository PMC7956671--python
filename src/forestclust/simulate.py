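"""Simulation designs and experiment runners for the clustering benches.

Two designs probe the two classic failure modes of Gini-based forests:

Cardinality design
    Two latent classes; every informative feature is a latent standard
    Gaussian shifted by ``effect_size`` between the classes and then
    discretised at equal-probability bins into its declared cardinality
    (binary through 32-level nominal; continuous features keep the latent
    value).  High-cardinality noise features let Gini splitting exhibit
    its preference for many-valued features; a calibrated permutation test
    does not.  With effect_size = 0 the design is a global null.

Correlation design
    Twelve standard Gaussian predictors, the first four pairwise
    correlated at rho; a latent response y = X beta + eps with
    beta = (5, 5, 2, 0, -5, -5, -2, 0, ...) is median-dichotomised into
    the class label.  X4 carries no coefficient but is correlated with
    X1..X3; X5..X7 carry large coefficients but are uncorrelated -- the
    configuration under which unconditional permutation importance
    misattributes relevance.

Both generators are pure functions of their spec (same spec, same table).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import consensus_cluster
from .distance import forest_distance, scale_vims
from .forest import ForestParams
from .metrics import adjusted_rand_index, cluster_purity
from .table import FeatureSchema, MixedTable

#: default feature kinds of the cardinality design: binary through
#: 32-level nominal plus two continuous features (8 predictors, matching
#: the mtry grid {1, 3, 8})
DEFAULT_CARDINALITY_FEATURES: tuple[tuple[str, int | None], ...] = (
    ("binary", 2),
    ("binary", 2),
    ("nominal", 4),
    ("nominal", 8),
    ("nominal", 16),
    ("nominal", 32),
    ("continuous", None),
    ("continuous", None),
)


@dataclass
class CardinalitySimSpec:
    n: int = 200
    features: tuple[tuple[str, int | None], ...] = DEFAULT_CARDINALITY_FEATURES
    informative: tuple[int, ...] | None = None  # None = all features informative
    effect_size: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for kind, levels in self.features:
            if kind in ("binary", "nominal", "ordinal") and (levels is None or levels < 2):
                raise ValueError("categorical features need n_levels >= 2")


@dataclass
class CorrelationSimSpec:
    n: int = 200
    p: int = 12
    correlated_block: tuple[int, ...] = (0, 1, 2, 3)
    rho: float = 0.9
    beta: tuple[float, ...] = (5, 5, 2, 0, -5, -5, -2, 0, 0, 0, 0, 0)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.beta) != self.p:
            raise ValueError("beta must have length p")
        if any(j < 0 or j >= self.p for j in self.correlated_block):
            raise ValueError("correlated_block indices must lie in [0, p)")


def simulate_cardinality(spec: CardinalitySimSpec) -> MixedTable:
    """Mixed-cardinality two-class table; labels attached for evaluation only.

    Feature j for a sample of class c is drawn from
    N((c - 1/2) * effect_size_j, 1) and, if categorical with L levels,
    discretised at the standard-normal L-quantiles (noise features are
    therefore exactly uniform over their levels).
    """
    rng = np.random.default_rng(spec.seed)
    p = len(spec.features)
    informative = set(range(p) if spec.informative is None else spec.informative)
    classes = rng.integers(0, 2, size=spec.n)
    schema = []
    cols = {}
    for j, (kind, n_levels) in enumerate(spec.features):
        name = f"X{j + 1}"
        shift = spec.effect_size if j in informative else 0.0
        z = rng.normal(0.0, 1.0, size=spec.n) + (classes - 0.5) * shift
        if kind == "continuous":
            schema.append(FeatureSchema(name, "continuous"))
            cols[name] = z
        else:
            levels = tuple(f"L{i + 1:02d}" for i in range(n_levels))
            cuts = stats.norm.ppf(np.arange(1, n_levels) / n_levels)
            codes = np.digitize(z, cuts)
            schema.append(FeatureSchema(name, kind, levels))
            cols[name] = [levels[c] for c in codes]
    return MixedTable(pd.DataFrame(cols), schema, labels=classes)


def simulate_correlation(spec: CorrelationSimSpec) -> MixedTable:
    """Correlated-Gaussian two-class table via a median-dichotomised response."""
    rng = np.random.default_rng(spec.seed)
    cov = np.eye(spec.p)
    block = list(spec.correlated_block)
    for a in block:
        for b in block:
            if a != b:
                cov[a, b] = spec.rho
    # positive-definiteness check (equicorrelation is PD for rho > -1/(m-1))
    if np.linalg.eigvalsh(cov).min() <= 0:
        raise ValueError("requested correlation structure is not positive definite")
    X = rng.multivariate_normal(np.zeros(spec.p), cov, size=spec.n, method="cholesky")
    y_latent = X @ np.asarray(spec.beta) + rng.normal(0.0, spec.noise_sd, size=spec.n)
    labels = (y_latent >= np.median(y_latent)).astype(np.int64)
    schema = [FeatureSchema(f"X{j + 1}", "continuous") for j in range(spec.p)]
    df = pd.DataFrame({f"X{j + 1}": X[:, j] for j in range(spec.p)})
    return MixedTable(df, schema, labels=labels)


def simulate_planted_clusters(
    n: int = 100,
    n_continuous: int = 4,
    n_binary: int = 4,
    shift: float = 3.0,
    flip: float = 0.1,
    seed: int = 0,
) -> MixedTable:
    """Two planted mixed-type clusters: shifted continuous block + flipped binary block.

    A positive control: the default shift (3 SD) and bit-flip rate (0.1)
    make the two groups essentially Bayes-separable, so failure to recover
    them indicates a pipeline defect rather than intrinsic ambiguity.
    """
    rng = np.random.default_rng(seed)
    classes = (np.arange(n) % 2).astype(np.int64)
    rng.shuffle(classes)
    cols = {}
    schema = []
    for j in range(n_continuous):
        name = f"C{j + 1}"
        schema.append(FeatureSchema(name, "continuous"))
        cols[name] = rng.normal(classes * shift, 1.0)
    for j in range(n_binary):
        name = f"B{j + 1}"
        schema.append(FeatureSchema(name, "binary", ("0", "1")))
        bits = np.where(rng.random(n) < flip, 1 - classes, classes)
        cols[name] = [str(b) for b in bits]
    return MixedTable(pd.DataFrame(cols), schema, labels=classes)


# -- experiment runners --------------------------------------------------------


def _rep_seed(master: int, rep: int) -> int:
    return int(np.random.SeedSequence(entropy=int(master), spawn_key=(rep,)).generate_state(1)[0]) & 0x7FFFFFFF


def run_pipeline(
    table: MixedTable,
    params: ForestParams,
    n_forests: int = 20,
    seed: int | None = None,
    vim_mode: str | None = "auto",
    k_range=range(2, 11),
    n_resamples: int = 250,
    item_fraction: float = 0.8,
    force_k: int | None = None,
):
    """Full pipeline: averaged forest distance then consensus Ward clustering.

    Returns (ForestDistanceResult, ClusteringResult).
    """
    dist = forest_distance(table, params, n_forests=n_forests, seed=seed, vim_mode=vim_mode)
    cl_seed = None if seed is None else (int(seed) + 0x5F3759) & 0x7FFFFFFF
    clustering = consensus_cluster(
        dist.dissimilarity,
        k_range=k_range,
        n_resamples=n_resamples,
        item_fraction=item_fraction,
        rng=cl_seed,
        force_k=force_k,
    )
    return dist, clustering


def _run_experiment(
    make_table,
    params_grid: list[ForestParams],
    n_reps: int,
    master_seed: int,
    n_forests: int,
    vim_mode: str | None,
    n_resamples: int,
    k_range,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = []
    vim_rows = []
    for rep in range(n_reps):
        seed = _rep_seed(master_seed, rep)
        table = make_table(seed)
        truth = table.labels
        for params in params_grid:
            dist, clustering = run_pipeline(
                table,
                params,
                n_forests=n_forests,
                seed=seed,
                vim_mode=vim_mode,
                n_resamples=n_resamples,
                k_range=k_range,
            )
            rows.append(
                {
                    "rep": rep,
                    "backend": params.backend,
                    "mtry": params.mtry,
                    "chosen_k": clustering.chosen_k,
                    "ari": adjusted_rand_index(clustering.labels, truth),
                    "cluster_purity": cluster_purity(clustering.labels, truth),
                    "oob_error": dist.mean_oob_error,
                }
            )
            scaled = scale_vims(dist.vims)
            for name, raw, sc in zip(scaled.features, scaled.raw, scaled.scaled):
                vim_rows.append(
                    {
                        "rep": rep,
                        "backend": params.backend,
                        "mtry": params.mtry,
                        "feature": name,
                        "vim_raw": raw,
                        "vim_scaled": sc,
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(vim_rows)


def run_cardinality_experiment(
    spec: CardinalitySimSpec,
    params_grid: list[ForestParams],
    n_reps: int = 25,
    n_forests: int = 20,
    vim_mode: str | None = "auto",
    n_resamples: int = 250,
    k_range=range(2, 11),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per (backend, mtry, rep): ARI, purity, OOB error and scaled VIMs."""

    def make(seed: int) -> MixedTable:
        return simulate_cardinality(replace(spec, seed=seed))

    return _run_experiment(
        make, params_grid, n_reps, spec.seed, n_forests, vim_mode, n_resamples, k_range
    )


def run_correlation_experiment(
    spec: CorrelationSimSpec,
    params_grid: list[ForestParams],
    n_reps: int = 25,
    n_forests: int = 20,
    vim_mode: str | None = "auto",
    n_resamples: int = 250,
    k_range=range(2, 11),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    def make(seed: int) -> MixedTable:
        return simulate_correlation(replace(spec, seed=seed))

    return _run_experiment(
        make, params_grid, n_reps, spec.seed, n_forests, vim_mode, n_resamples, k_range
    )
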