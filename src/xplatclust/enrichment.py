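"""Functional Enrichment Index (FEI) over clusters and functional classes.

Clusters and functional classes hold different numbers of genes, so raw
overlap counts are not comparable across cells.  The FEI normalizes the
overlap by both totals:

    FEI = (G_clusterclass / (G_cluster * G_class)) * 1000

where G_clusterclass is the number of genes in both the cluster and the
class, G_cluster the total number of genes in the cluster (annotated or
not), and G_class the total number of genes carrying the class.  By default
G_class is tabulated over the clustered gene universe; ``class_universe=
"all-genes"`` switches the denominator to every annotated gene.

Under independence of clusters and classes, E[G_clusterclass] is
approximately G_cluster * G_class / N, so FEI cells concentrate around
1000 / N for N clustered genes; values well above that mark disproportionate
membership.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .io import AnnotationTable
from .simulate import KOG_CLASSES

__all__ = ["EnrichmentTable", "fei", "fei_table"]


@dataclass
class EnrichmentTable:
    """FEI values plus the underlying counts.

    ``fei``: cluster x class FEI matrix; ``counts``: cluster x class
    G_clusterclass; ``g_cluster``: genes per cluster; ``g_class``: genes per
    class over the chosen universe; ``n_unclustered_annotated``: annotated
    genes ignored because they were not clustered.
    """

    fei: pd.DataFrame
    counts: pd.DataFrame
    g_cluster: pd.Series
    g_class: pd.Series
    n_unclustered_annotated: int = 0


def fei(g_clusterclass: int, g_cluster: int, g_class: int) -> float:
    """Functional enrichment index of one (cluster, class) cell."""
    if g_cluster < 1 or g_class < 1:
        raise ValueError("g_cluster and g_class must be >= 1")
    if not 0 <= g_clusterclass <= min(g_cluster, g_class):
        raise ValueError(
            f"g_clusterclass={g_clusterclass} must lie in [0, min(g_cluster, g_class)]"
        )
    return (g_clusterclass / (g_cluster * g_class)) * 1000.0


def fei_table(
    assignment: pd.Series,
    annotation: AnnotationTable,
    class_vocabulary: tuple[str, ...] | None = None,
    class_universe: str = "clustered",
) -> EnrichmentTable:
    """Tabulate class membership per cluster and compute FEI cellwise.

    ``assignment`` maps gene id -> cluster id.  G_cluster counts all genes in
    the cluster, annotated or not.  A gene with several classes increments
    G_clusterclass for each.  Classes in the vocabulary but absent from the
    data appear as all-zero columns (FEI 0).  Annotated genes that were not
    clustered are counted and ignored with a warning.
    """
    if assignment.empty:
        raise ValueError("assignment must be nonempty")
    if class_universe not in ("clustered", "all-genes"):
        raise ValueError("class_universe must be 'clustered' or 'all-genes'")
    if class_vocabulary is None:
        # default: the KOG single-letter codes, extended by any extra
        # observed labels so no annotation is silently dropped
        observed = set(annotation.all_classes)
        class_vocabulary = tuple(list(KOG_CLASSES) + sorted(observed - set(KOG_CLASSES)))
    classes = list(class_vocabulary)

    clustered = set(assignment.index)
    unclustered = [g for g in annotation.mapping if g not in clustered]
    if unclustered:
        warnings.warn(
            f"{len(unclustered)} annotated gene(s) are not in any cluster; ignored"
        )

    cluster_ids = sorted(assignment.unique())
    class_set = set(classes)
    pair_clusters: list = []
    pair_classes: list[str] = []
    for gene, cid in assignment.items():
        for cls in annotation.classes_of(gene):
            if cls in class_set:
                pair_clusters.append(cid)
                pair_classes.append(cls)
    counts = (
        pd.crosstab(pd.Index(pair_clusters), pd.Index(pair_classes))
        .reindex(index=cluster_ids, columns=classes, fill_value=0)
        if pair_clusters
        else pd.DataFrame(0, index=cluster_ids, columns=classes)
    )
    counts.index.name = "cluster"

    g_cluster = assignment.value_counts().sort_index().rename("g_cluster")
    if class_universe == "clustered":
        g_class = counts.sum(axis=0).rename("g_class")
    else:
        g_class = pd.Series(0, index=pd.Index(classes), name="g_class")
        for gene, gcls in annotation.mapping.items():
            for cls in gcls:
                if cls in g_class.index:
                    g_class[cls] += 1

    fei_values = counts.astype(float).copy()
    for cls in classes:
        denom = g_class[cls]
        if denom == 0:
            fei_values[cls] = 0.0  # class absent: zero overlap everywhere
        else:
            fei_values[cls] = counts[cls] / (g_cluster * denom) * 1000.0
    return EnrichmentTable(
        fei=fei_values,
        counts=counts,
        g_cluster=g_cluster,
        g_class=g_class,
        n_unclustered_annotated=len(unclustered),
    )
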