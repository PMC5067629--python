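"""Cross-platform replication scoring and cluster inclusion filtering.

A gene's response replicates when its time course on the intensity platform
correlates with its time course on the count platform (Pearson correlation,
PCC).  Per the study convention, the gene-level PCC is computed on the raw
time-matched values — intensities against size-factor-normalized counts,
replicates averaged per time point — not on log2 fold-changes (a
``space="log2fc"`` alternative is provided).  Pearson correlation is
invariant to positive affine transforms, so the platforms' different scales
do not matter.

At the cluster level, the centroid of the combined profile is split into its
array half and counts half and the two halves are correlated position-wise.
Clusters pass the inclusion filter when their centroid shows strong
differential expression (max |log2FC| above a threshold) and — for
replicated clusters only — a majority of member genes themselves replicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import ClusterModel
from .io import ExpressionMatrix
from .normalize import SizeFactors

__all__ = [
    "GeneReplication",
    "gene_pcc",
    "gene_pcc_table",
    "centroid_pcc",
    "evaluate_clusters",
]


@dataclass
class GeneReplication:
    """Per-gene cross-platform Pearson correlation; ``pcc`` is NaN when either
    series is constant (no replication evidence)."""

    gene_id: str
    pcc: float
    n_points: int

    @property
    def defined(self) -> bool:
        return not np.isnan(self.pcc)


def gene_pcc(array_series: np.ndarray, count_series: np.ndarray) -> float:
    """Pearson correlation of two time-aligned series; NaN if either is
    constant.  Series must have equal length >= 3."""
    x = np.asarray(array_series, dtype=float)
    y = np.asarray(count_series, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"series length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or x.size < 3:
        raise ValueError("series must be 1-D with length >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0.0:
        return float("nan")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def _time_averaged(matrix: ExpressionMatrix, size_factors: SizeFactors | None) -> pd.DataFrame:
    vals = matrix.values
    if matrix.platform == "counts":
        if size_factors is None:
            raise ValueError("counts platform requires size_factors")
        vals = vals / size_factors.factors
    return vals.T.groupby(matrix.sample_meta["time"]).mean().T


def gene_pcc_table(
    array: ExpressionMatrix,
    counts: ExpressionMatrix,
    size_factors: SizeFactors | None = None,
    space: str = "raw",
    fc_array=None,
    fc_counts=None,
) -> pd.DataFrame:
    """Per-gene cross-platform PCC over time-matched, replicate-averaged values.

    ``space="raw"`` (default) correlates intensities against normalized
    counts; ``space="log2fc"`` correlates the fold-change profiles supplied
    via ``fc_array``/``fc_counts``.  Returns a DataFrame indexed by gene with
    columns ``pcc`` and ``n_points``; genes present in only one platform are
    omitted.
    """
    if space == "raw":
        a = _time_averaged(array, None)
        c = _time_averaged(counts, size_factors)
    elif space == "log2fc":
        if fc_array is None or fc_counts is None:
            raise ValueError("space='log2fc' requires fc_array and fc_counts")
        a, c = fc_array.values, fc_counts.values
    else:
        raise ValueError(f"unknown pcc space {space!r}")
    shared_genes = a.index.intersection(c.index)
    shared_times = [t for t in a.columns if t in set(c.columns)]
    if len(shared_times) < 3:
        raise ValueError("need >= 3 shared time points for per-gene PCC")
    A = a.loc[shared_genes, shared_times].to_numpy(dtype=float)
    C = c.loc[shared_genes, shared_times].to_numpy(dtype=float)
    Ac = A - A.mean(axis=1, keepdims=True)
    Cc = C - C.mean(axis=1, keepdims=True)
    denom = np.sqrt((Ac**2).sum(axis=1) * (Cc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        pcc = np.where(denom > 0, (Ac * Cc).sum(axis=1) / denom, np.nan)
    pcc = np.clip(pcc, -1.0, 1.0)
    return pd.DataFrame(
        {"pcc": pcc, "n_points": len(shared_times)},
        index=pd.Index(shared_genes, name="gene_id"),
    )


def centroid_pcc(centroid: np.ndarray, array_width: int) -> float:
    """Pearson correlation between the array half and counts half of a
    combined centroid vector (matched position-wise by time point).  NaN if
    either half is constant."""
    v = np.asarray(centroid, dtype=float)
    if not 3 <= array_width <= v.size - 3:
        raise ValueError("both halves must have length >= 3")
    return gene_pcc(v[:array_width], v[array_width:])


def evaluate_clusters(
    model: ClusterModel,
    gene_pccs: pd.DataFrame,
    array_width: int,
    fc_threshold: float = 1.0,
    pcc_threshold: float = 0.5,
    frac_threshold: float = 0.5,
) -> pd.DataFrame:
    """Apply the cluster inclusion criteria.

    A cluster is *replicated* when its centroid PCC exceeds
    ``pcc_threshold``.  It is *included* for downstream analysis when its
    centroid shows strong differential expression (max |log2FC| >
    ``fc_threshold``) and, for replicated clusters only, more than
    ``frac_threshold`` of its genes have PCC > ``pcc_threshold`` (genes with
    undefined PCC count as unreplicated).  Unreplicated clusters are exempt
    from the gene-fraction criterion.

    Returns one row per cluster id (sorted): n_genes, centroid_pcc,
    max_abs_centroid_fc, frac_genes_replicated, replicated, included.
    """
    rows = []
    pcc_by_gene = gene_pccs["pcc"]
    for cid in model.centroids.index:
        members = model.members(cid)
        centroid = model.centroids.loc[cid].to_numpy(dtype=float)
        cpcc = centroid_pcc(centroid, array_width)
        max_fc = float(np.abs(centroid).max())
        member_pcc = pcc_by_gene.reindex(members)
        frac = float((member_pcc > pcc_threshold).sum() / len(members)) if members else 0.0
        replicated = bool(not np.isnan(cpcc) and cpcc > pcc_threshold)
        included = bool(
            max_fc > fc_threshold and (not replicated or frac > frac_threshold)
        )
        rows.append(
            {
                "cluster": cid,
                "n_genes": len(members),
                "centroid_pcc": cpcc,
                "max_abs_centroid_fc": max_fc,
                "frac_genes_replicated": frac,
                "replicated": replicated,
                "included": included,
            }
        )
    return pd.DataFrame(rows).set_index("cluster").sort_index()
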