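"""Model/Results interface over the full coexpression analysis.

:class:`CoexpressionTimeCourse` is built from the two platform expression
matrices (plus an optional functional annotation); :meth:`~CoexpressionTimeCourse.fit`
runs normalization, combined k-means clustering (with randomized-reference
selection of k or a pinned k), centroid reclustering, replication scoring,
inclusion filtering and — when an annotation is present — FEI enrichment,
returning a :class:`CoexpressionResults` carrying every intermediate table
and a text ``summary()``.

Example
-------
>>> from xplatclust import SimConfig, simulate_dataset, CoexpressionTimeCourse
>>> arr, cnt, ann, truth = simulate_dataset(SimConfig(n_clusters=4,
...     genes_per_cluster=30, seed=1))
>>> res = CoexpressionTimeCourse(arr, cnt, annotation=ann).fit(k=4, seed=1)
>>> res.clusters.k
4
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import enrichment as _enrichment
from . import normalize as _normalize
from . import replication as _replication
from .io import AnnotationTable, ExpressionMatrix, read_annotation_tsv, read_expression_tsv

__all__ = ["CoexpressionTimeCourse", "CoexpressionResults"]


def _substream(seed: int, name: str) -> int:
    """Deterministic per-stage child seed below 2**31."""
    h = 0
    for ch in name:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return int(np.random.default_rng([seed % (2**31), h]).integers(2**31))


class CoexpressionTimeCourse:
    """Dual-platform time-course coexpression model.

    Parameters
    ----------
    array, counts
        The intensity-valued and count-valued :class:`ExpressionMatrix`
        over (mostly) the same gene universe.
    annotation
        Optional gene -> functional class table for enrichment.
    pseudocount_counts, pseudocount_array
        Added to normalized values before log-ratioing (defaults 1.0 / 0.0).
    size_factors
        Optional precomputed per-sample factors for the count platform
        (e.g. from an external normalization); estimated by median-of-ratios
        when omitted.  Note the estimator assumes a mostly non-differential
        transcriptome.
    """

    def __init__(
        self,
        array: ExpressionMatrix,
        counts: ExpressionMatrix,
        annotation: AnnotationTable | None = None,
        pseudocount_counts: float = 1.0,
        pseudocount_array: float = 0.0,
        size_factors: _normalize.SizeFactors | None = None,
    ) -> None:
        if array.platform != "array" or counts.platform != "counts":
            raise ValueError("expected an 'array' matrix and a 'counts' matrix")
        self.array = array
        self.counts = counts
        self.annotation = annotation
        self.pseudocount_counts = pseudocount_counts
        self.pseudocount_array = pseudocount_array
        self._size_factors = size_factors

    @classmethod
    def from_tsv(
        cls,
        array_path,
        counts_path,
        annotation_path=None,
        **kwargs,
    ) -> "CoexpressionTimeCourse":
        annotation = read_annotation_tsv(annotation_path) if annotation_path else None
        return cls(
            read_expression_tsv(array_path, "array"),
            read_expression_tsv(counts_path, "counts"),
            annotation=annotation,
            **kwargs,
        )

    def fit(
        self,
        k: int | str = "select",
        k_grid: tuple[int, ...] = _cluster.DEFAULT_K_GRID,
        n_init: int = 25,
        n_randomizations: int = 10,
        seed: int = 0,
        pcc_space: str = "raw",
        fc_threshold: float = 1.0,
        pcc_threshold: float = 0.5,
        frac_threshold: float = 0.5,
        class_universe: str = "clustered",
    ) -> "CoexpressionResults":
        """Run the full analysis.

        ``k="select"`` applies the randomized-reference rule over ``k_grid``
        (the first-crossing reading: smallest grid k at which the real
        within-cluster variance drops below the randomized reference's); an
        integer k pins the cluster count, mirroring an externally fixed
        choice such as k=50.
        """
        sf = self._size_factors or _normalize.size_factors(self.counts)
        fc_array = _normalize.log2_fold_change(self.array, self.pseudocount_array)
        fc_counts = _normalize.log2_fold_change(
            self.counts, self.pseudocount_counts, size_factors=sf
        )
        combined = _normalize.combine_platforms(fc_array, fc_counts)

        k_trace = None
        if k == "select":
            k_trace = _cluster.select_k(
                combined.values,
                k_grid=k_grid,
                n_randomizations=n_randomizations,
                seed=_substream(seed, "select_k"),
            )
            chosen_k = k_trace.chosen_k
        elif isinstance(k, int):
            chosen_k = k
        else:
            raise ValueError("k must be 'select' or an integer")

        clusters = _cluster.kmeans_cluster(
            combined.values, chosen_k, seed=_substream(seed, "kmeans"), n_init=n_init
        )
        clusters.linkage, clusters.leaf_order = _cluster.recluster_centroids(
            clusters.centroids
        )

        gene_pccs = _replication.gene_pcc_table(
            self.array,
            self.counts,
            size_factors=sf,
            space=pcc_space,
            fc_array=fc_array,
            fc_counts=fc_counts,
        )
        cluster_stats = _replication.evaluate_clusters(
            clusters,
            gene_pccs,
            array_width=combined.array_width,
            fc_threshold=fc_threshold,
            pcc_threshold=pcc_threshold,
            frac_threshold=frac_threshold,
        )

        enrichment = None
        if self.annotation is not None:
            enrichment = _enrichment.fei_table(
                clusters.assignment, self.annotation, class_universe=class_universe
            )

        return CoexpressionResults(
            model=self,
            size_factors=sf,
            fold_change_array=fc_array,
            fold_change_counts=fc_counts,
            combined=combined,
            k_trace=k_trace,
            clusters=clusters,
            gene_pcc=gene_pccs,
            cluster_stats=cluster_stats,
            enrichment=enrichment,
            seed=seed,
        )


@dataclass
class CoexpressionResults:
    """Fitted quantities of one coexpression analysis run."""

    model: CoexpressionTimeCourse
    size_factors: _normalize.SizeFactors
    fold_change_array: _normalize.FoldChangeProfile
    fold_change_counts: _normalize.FoldChangeProfile
    combined: _normalize.CombinedProfiles
    k_trace: _cluster.KSelectionTrace | None
    clusters: _cluster.ClusterModel
    gene_pcc: pd.DataFrame
    cluster_stats: pd.DataFrame
    enrichment: _enrichment.EnrichmentTable | None
    seed: int = 0

    @property
    def assignment(self) -> pd.Series:
        return self.clusters.assignment

    @property
    def n_replicated(self) -> int:
        return int(self.cluster_stats["replicated"].sum())

    @property
    def n_included(self) -> int:
        return int(self.cluster_stats["included"].sum())

    def heatmap_table(self) -> pd.DataFrame:
        """Centroid log2FC profiles in dendrogram leaf order with per-cluster
        statistics appended (n_genes, centroid_pcc, within-cluster variance,
        included flag) — the numbers behind the cluster heatmap display."""
        order = self.clusters.leaf_order or list(self.clusters.centroids.index)
        table = self.clusters.centroids.loc[order].copy()
        pcv = _cluster.per_cluster_variance(
            self.combined.values, self.clusters.assignment, self.clusters.centroids
        )
        stats = self.cluster_stats.loc[order]
        table["n_genes"] = stats["n_genes"]
        table["centroid_pcc"] = stats["centroid_pcc"]
        table["within_cluster_variance"] = pcv.loc[order]
        table["included"] = stats["included"]
        return table

    def subcluster(
        self,
        cluster_id: int,
        n_subclusters: int | None = None,
        cut_height: float | None = None,
    ) -> pd.Series:
        """Hierarchically split one cluster's member profiles (labels
        ``{cluster_id}.1``, ``{cluster_id}.2``, ...)."""
        members = self.clusters.members(cluster_id)
        return _cluster.subcluster(
            self.combined.values.loc[members],
            n_subclusters=n_subclusters,
            cut_height=cut_height,
            parent_label=cluster_id,
        )

    def summary(self) -> str:
        """Plain-text overview of the fitted analysis."""
        lines = [
            "Cross-platform coexpression time-course fit",
            "=" * 45,
            f"genes clustered            {len(self.assignment)}",
            f"combined profile width     {self.combined.values.shape[1]} "
            f"(array {self.combined.array_width} + counts {self.combined.counts_width})",
            f"k (clusters)               {self.clusters.k}"
            + (
                ""
                if self.k_trace is None
                else f"  [selected from grid {self.k_trace.k_grid[0]}..{self.k_trace.k_grid[-1]}"
                + (", fell through]" if self.k_trace.fell_through else "]")
            ),
            f"within-cluster variance    {self.clusters.within_cluster_variance:.4f}",
            f"replicated clusters        {self.n_replicated} / {self.clusters.k}"
            f"  (centroid PCC > 0.5)",
            f"included clusters          {self.n_included} / {self.clusters.k}",
            f"median gene PCC            {self.gene_pcc['pcc'].median():.3f}",
        ]
        if self.enrichment is not None:
            top = self.enrichment.fei.stack().idxmax()
            lines.append(
                f"max FEI                    {self.enrichment.fei.stack().max():.2f} "
                f"(cluster {top[0]}, class {top[1]})"
            )
        return "\n".join(lines)
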