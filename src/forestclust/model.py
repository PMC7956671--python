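"""Model/Results objects tying the pipeline together.

``ForestClusterModel`` is constructed from a :class:`~forestclust.table.MixedTable`
(or a DataFrame plus schema) together with the forest and consensus
parameters; ``fit()`` runs synthetic augmentation, forest training,
Monte-Carlo distance averaging, permutation variable importance and
consensus Ward clustering, and returns a :class:`ForestClusterResults`
carrying the estimates, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.iolib.table import SimpleTable

from . import __version__
from .cluster import ClusteringResult, consensus_cluster
from .distance import (
    DissimilarityMatrix,
    VimReport,
    forest_distance,
    write_dissimilarity,
    write_vims,
)
from .forest import ForestParams
from .metrics import MetricReport, evaluate
from .table import FeatureSchema, MixedTable


class ForestClusterModel:
    """Permutation-based unsupervised forest clustering of a mixed-type table.

    Parameters
    ----------
    table : MixedTable
        Complete-case mixed-type data (rows = samples).
    backend : {'RF', 'RRF', 'uncondCIF', 'condCIF'}
    n_forests : int
        Number of augmentation+forest repetitions averaged into the
        dissimilarity and the VIMs (controls Monte-Carlo variation).
    vim_mode : {'auto', 'unconditional', 'conditional', None}
        'auto' pairs the condCIF backend with conditional permutation
        importance and every other backend with the unconditional scheme.
    k_range, n_resamples, item_fraction, k
        Consensus-clustering controls; ``k`` forces the cluster number
        instead of the consensus-CDF delta-area rule.
    Remaining keyword arguments are forwarded to :class:`ForestParams`.
    """

    def __init__(
        self,
        table: MixedTable,
        backend: str = "condCIF",
        n_forests: int = 20,
        vim_mode: str | None = "auto",
        k_range=range(2, 11),
        n_resamples: int = 250,
        item_fraction: float = 0.8,
        k: int | None = None,
        **forest_kwargs,
    ) -> None:
        if table.missing_mask.any():
            raise ValueError(
                "the forest engine requires complete cases; "
                "call MixedTable.drop_incomplete() first"
            )
        self.table = table
        self.params = ForestParams(backend=backend, **forest_kwargs)
        self.n_forests = int(n_forests)
        self.vim_mode = vim_mode
        self.k_range = list(k_range)
        self.n_resamples = int(n_resamples)
        self.item_fraction = float(item_fraction)
        self.force_k = k

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        schema: Sequence[FeatureSchema],
        labels: Sequence | None = None,
        **kwargs,
    ) -> "ForestClusterModel":
        return cls(MixedTable(df, schema, labels=labels), **kwargs)

    def fit(self, seed: int | None = None) -> "ForestClusterResults":
        dist = forest_distance(
            self.table,
            self.params,
            n_forests=self.n_forests,
            seed=seed,
            vim_mode=self.vim_mode,
        )
        cl_seed = None if seed is None else (int(seed) + 0x5F3759) & 0x7FFFFFFF
        clustering = consensus_cluster(
            dist.dissimilarity,
            k_range=self.k_range,
            n_resamples=self.n_resamples,
            item_fraction=self.item_fraction,
            rng=cl_seed,
            force_k=self.force_k,
        )
        return ForestClusterResults(self, dist.dissimilarity, dist.vims, clustering,
                                    dist.oob_errors, seed)


class ForestClusterResults:
    """Fitted clustering: distance, importances, labels and diagnostics."""

    def __init__(
        self,
        model: ForestClusterModel,
        dissimilarity: DissimilarityMatrix,
        vims: VimReport,
        clustering: ClusteringResult,
        oob_errors: list[float],
        seed: int | None,
    ) -> None:
        self.model = model
        self.dissimilarity = dissimilarity
        self.vims = vims
        self.clustering = clustering
        self.oob_errors = oob_errors
        self.seed = seed

    # -- convenience views -----------------------------------------------------

    @property
    def labels_(self) -> np.ndarray:
        return self.clustering.labels

    @property
    def chosen_k(self) -> int:
        return self.clustering.chosen_k

    @property
    def dendrogram(self):
        return self.clustering.dendrogram

    @property
    def mean_oob_error(self) -> float:
        return float(np.mean(self.oob_errors))

    def vim_frame(self) -> pd.DataFrame:
        return self.vims.to_frame().sort_values("raw", ascending=False).reset_index(drop=True)

    def evaluate(self, labels_true) -> MetricReport:
        """External + internal metrics against supplied ground-truth labels."""
        return evaluate(self.labels_, labels_true, table=self.model.table)

    # -- presentation ----------------------------------------------------------

    def summary(self) -> str:
        m = self.model
        sizes = pd.Series(self.labels_).value_counts().sort_index()
        info = [
            ("Backend:", m.params.backend),
            ("No. samples:", str(m.table.n)),
            ("No. features:", str(m.table.p)),
            ("Trees / forest:", str(m.params.n_trees)),
            ("Forests averaged:", str(self.dissimilarity.n_forests)),
            ("Subsample (no repl.):", f"{m.params.subsample_fraction:g}"),
            ("VIM mode:", self.vims.mode),
            ("Mean OOB error:", f"{self.mean_oob_error:.3f}"),
            ("Chosen k:", str(self.chosen_k)),
            ("Cluster sizes:", ", ".join(f"{c}:{n}" for c, n in sizes.items())),
        ]
        half = (len(info) + 1) // 2
        left, right = info[:half], info[half:]
        right += [("", "")] * (len(left) - len(right))
        rows = [l + r for l, r in zip(left, right)]
        head = SimpleTable(rows, title="Permutation Forest Clustering Results")
        top = self.vim_frame().head(10)
        vim_rows = [
            [name, f"{raw: .5f}", f"{sc:.3f}"]
            for name, raw, sc in zip(top["feature"], top["raw"], top.get("scaled", top["raw"]))
        ]
        vtab = SimpleTable(
            vim_rows,
            headers=["feature", "VIM (raw)", "VIM (scaled)"],
            title="Top variable importances",
        )
        return str(head) + "\n" + str(vtab)

    def plot_consensus(self, ax=None):
        """Heatmap of the consensus matrix, samples in dendrogram leaf order."""
        import matplotlib.pyplot as plt
        from scipy.cluster import hierarchy

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        order = hierarchy.leaves_list(self.dendrogram.Z)
        M = self.clustering.consensus_matrix[np.ix_(order, order)]
        im = ax.imshow(M, cmap="viridis", vmin=0, vmax=1)
        ax.set_title(f"Consensus matrix (k={self.chosen_k})")
        ax.figure.colorbar(im, ax=ax, shrink=0.8)
        return ax

    # -- artifact set ----------------------------------------------------------

    def save(self, outdir: str) -> dict:
        """Write the artifact set; returns the run manifest."""
        import os

        os.makedirs(outdir, exist_ok=True)
        write_dissimilarity(self.dissimilarity, os.path.join(outdir, "dissimilarity.csv"))
        write_vims(self.vims, os.path.join(outdir, "vims.tsv"))
        pd.DataFrame(
            {"sample": self.dissimilarity.sample_ids, "cluster": self.labels_}
        ).to_csv(os.path.join(outdir, "labels.csv"), index=False)
        with open(os.path.join(outdir, "dendrogram.nwk"), "w") as fh:
            fh.write(self.dendrogram.to_newick() + "\n")
        pd.DataFrame(
            self.clustering.consensus_matrix,
            index=self.dissimilarity.sample_ids,
            columns=self.dissimilarity.sample_ids,
        ).to_csv(os.path.join(outdir, "consensus.csv"))
        m = self.model
        manifest = {
            "package": "forestclust",
            "version": __version__,
            "numpy": np.__version__,
            "seed": self.seed,
            "params": {**m.params.__dict__},
            "n_forests": self.dissimilarity.n_forests,
            "vim_mode": self.vims.mode,
            "k_range": m.k_range,
            "n_resamples": m.n_resamples,
            "item_fraction": m.item_fraction,
            "forced_k": m.force_k,
            "chosen_k": int(self.chosen_k),
        }
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
        return manifest
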