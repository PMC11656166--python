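"""Model/Results facade over the subtyping pipeline.

``SubtypeModel`` bundles one modality's analysis-ready feature matrix with a
run configuration; ``fit()`` executes hyperparameter tuning, random-forest
dissimilarity, classical MDS, average-linkage clustering and index-based k
selection, returning a ``SubtypeResults`` object that carries the labels,
the validation-index table, the embedding and diagnostic summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import RoiAtlas, RoiMatrix, RunConfig, SubjectMeta, auto_mtry_grid
from .forest import (ClusterSolution, DissimilarityMatrix, Embedding, RfParams,
                     StabilityReport, average_linkage, classical_mds, cut_tree,
                     rf_dissimilarity, stability_assessment, tune_rf)
from .preprocessing import (apply_icv_adjustment, fit_icv_model,
                            normalize_global_mean)
from .validation import IndexTable, k_selection_report


class SubtypeModel:
    """Unsupervised subtyping model for one modality's feature matrix.

    Parameters
    ----------
    values : RoiMatrix
        Analysis-state features (global-normalized uptake or icv-adjusted
        volumes); raw matrices are rejected.
    config : RunConfig
        Pipeline settings (tree count, grids, MDS dimensions, k range, seed).
    """

    def __init__(self, values: RoiMatrix, config: RunConfig | None = None):
        if values.state == "raw":
            raise ValueError("SubtypeModel expects preprocessed features; "
                             "use from_cohort or run preprocessing first")
        self.values = values
        self.config = config if config is not None else RunConfig()

    @classmethod
    def from_cohort(cls, modality: str, fdg: RoiMatrix, mri: RoiMatrix,
                    meta: SubjectMeta, atlas: RoiAtlas, ad_ids: list[str],
                    cn_ids: list[str], config: RunConfig | None = None) -> "SubtypeModel":
        """Build the analysis matrix for one modality from raw cohort tables.

        Uptake is global-mean normalized; volumes are head-size adjusted with
        a control-fitted model.  Only the patient sample enters clustering.
        """
        if modality == "FDG":
            feats = normalize_global_mean(fdg, atlas).subset(ad_ids)
        elif modality == "MRI":
            icv_model = fit_icv_model(mri.subset(cn_ids), meta)
            feats = apply_icv_adjustment(mri, meta, icv_model).subset(ad_ids)
        else:
            raise ValueError(f"unknown modality {modality!r}")
        return cls(feats, config)

    def fit(self) -> "SubtypeResults":
        cfg = self.config
        X = self.values.values
        mtry_grid = cfg.mtry_grid or auto_mtry_grid(X.shape[1])
        if cfg.tune_hyperparameters:
            params = tune_rf(X, mtry_grid, cfg.nodesize_grid, cfg.n_trees, cfg.seed)
        else:
            params = RfParams(cfg.n_trees, mtry_grid[0], cfg.nodesize_grid[0], cfg.seed)
        diss = rf_dissimilarity(X, params, oob_only=cfg.proximity_oob_only,
                                sqrt_transform=cfg.sqrt_dissimilarity)
        embedding = classical_mds(diss, cfg.mds_dims)
        solution = average_linkage(embedding)
        k_lo, k_hi = cfg.k_range
        k_hi = min(k_hi, len(X) - 1)
        index_table = k_selection_report(embedding, solution, (k_lo, k_hi))
        k = cfg.manual_k if cfg.manual_k is not None else index_table.recommended_k
        labels = pd.Series(cut_tree(solution, k), index=self.values.subjects,
                           name=f"{self.values.modality.lower()}_subtype")
        solution.chosen_k = k
        stability = None
        if cfg.run_stability:
            stability = stability_assessment(X, params, cfg.n_stability_runs,
                                             k=k, mds_dims=cfg.mds_dims)
        return SubtypeResults(model=self, params=params, dissimilarity=diss,
                              embedding=embedding, solution=solution,
                              index_table=index_table, k=k, labels=labels,
                              stability=stability)


@dataclass
class SubtypeResults:
    """Fitted subtyping solution for one modality."""

    model: SubtypeModel
    params: RfParams
    dissimilarity: DissimilarityMatrix
    embedding: Embedding
    solution: ClusterSolution
    index_table: IndexTable
    k: int
    labels: pd.Series
    stability: StabilityReport | None = None

    @property
    def cluster_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def labels_for(self, k: int) -> pd.Series:
        return pd.Series(cut_tree(self.solution, k), index=self.labels.index,
                         name=self.labels.name)

    def summary(self) -> str:
        lines = [
            f"Subtype clustering summary ({self.model.values.modality}, "
            f"state={self.model.values.state})",
            "=" * 64,
            f"subjects: {len(self.labels)}   regions: {len(self.model.values.regions)}",
            f"forest: {self.params.n_trees} trees, mtry={self.params.mtry}, "
            f"nodesize={self.params.nodesize}, seed={self.params.seed}",
            f"embedding: {self.embedding.d} dimensions "
            f"(top eigenvalues: "
            f"{np.array2string(self.embedding.eigenvalues[:4], precision=3)})",
            f"chosen k: {self.k}   index votes: {self.index_table.votes}",
            "cluster sizes: " + ", ".join(
                f"{lab}: {n}" for lab, n in self.cluster_sizes.items()),
            "",
            "validation indices by k:",
            self.index_table.table.round(3).to_string(),
        ]
        if self.stability is not None:
            lines.append("")
            lines.append(f"stability over {self.stability.n_runs} re-runs: "
                         f"{self.stability.summary()}")
        return "\n".join(lines)

    # -- plotting ------------------------------------------------------------

    def plot_scree(self, ax=None):
        """Eigenvalue scree plot of the MDS spectrum."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ev = self.embedding.eigenvalues
        ax.plot(np.arange(1, len(ev) + 1), ev, marker="o", ms=3)
        ax.axvline(self.embedding.d, ls="--", color="grey")
        ax.set_xlabel("dimension")
        ax.set_ylabel("eigenvalue")
        ax.set_title("classical MDS eigenvalues")
        return ax

    def plot_dendrogram(self, ax=None):
        """Average-linkage dendrogram of the embedded subjects."""
        import matplotlib.pyplot as plt
        from scipy.cluster import hierarchy
        if ax is None:
            _, ax = plt.subplots()
        hierarchy.dendrogram(self.solution.linkage, ax=ax, no_labels=True,
                             color_threshold=None)
        ax.set_ylabel("Euclidean distance between clusters")
        return ax
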