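"""Fold-change profiling relative to the 0 h baseline.

Counts are first brought onto a common scale with median-of-ratios size
factors (the estimator behind DESeq2-style normalized counts), replicate
samples at the same time point are averaged on the normalized linear scale,
and each gene's profile is expressed as log2((x_t + pc) / (x_0 + pc)) against
the 0 h baseline.  The two platform profiles are finally joined into the
combined gene x (2T-2) clustering space, dropping the identically-zero
baseline columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = [
    "SizeFactors",
    "FoldChangeProfile",
    "CombinedProfiles",
    "size_factors",
    "log2_fold_change",
    "combine_platforms",
]

# Column tags of the combined clustering space: MA = microarray, RS = RNA-Seq.
PLATFORM_TAGS = {"array": "MA", "counts": "RS"}


@dataclass
class SizeFactors:
    """Per-count-sample scaling factors, rescaled to geometric mean 1."""

    factors: pd.Series

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("size factors must be positive")
        gm = np.exp(np.log(self.factors).mean())
        if not np.isclose(gm, 1.0, rtol=1e-8):
            raise ValueError(f"size factors must have geometric mean 1 (got {gm})")

    def __getitem__(self, sample: str) -> float:
        return float(self.factors[sample])


@dataclass
class FoldChangeProfile:
    """Gene x timepoint log2 fold-changes relative to the 0 h baseline.

    ``values`` columns are the numeric hours (strictly increasing, starting
    with the baseline, whose column is identically 0).  ``dropped_genes``
    lists genes removed because their fold-change was non-finite.
    """

    values: pd.DataFrame
    platform: str
    dropped_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = list(self.values.columns)
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if times and times[0] != 0:
            raise ValueError("first timepoint must be the 0 h baseline")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("fold-change values must be finite")
        if len(times) and not (self.values.iloc[:, 0] == 0).all():
            raise ValueError("baseline column must be identically 0")

    @property
    def timepoints(self) -> list[float]:
        return [float(t) for t in self.values.columns]


@dataclass
class CombinedProfiles:
    """Inner join of the two platform profiles over their shared genes.

    ``values`` has the array platform's non-baseline columns (MA4..MA24 for
    the 6-point course) followed by the counts platform's (RS4..RS24);
    ``array_width`` is the number of array columns.  ``unmatched`` maps each
    platform to the genes present only there.
    """

    values: pd.DataFrame
    array_width: int
    unmatched: dict[str, list[str]]

    @property
    def counts_width(self) -> int:
        return self.values.shape[1] - self.array_width


def size_factors(counts: ExpressionMatrix) -> SizeFactors:
    """Median-of-ratios size factors.

    Reference genes are those with strictly positive counts in every sample;
    each sample's factor is the median over reference genes of
    count / (gene-wise geometric mean), rescaled so the factors have
    geometric mean 1.
    """
    vals = counts.values.to_numpy(dtype=float)
    positive = (vals > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has strictly positive counts in every sample; add a "
            "pseudocount or filter samples before estimating size factors"
        )
    ref = vals[positive]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = ref / np.exp(log_geomean)[:, None]
    f = np.median(ratios, axis=0)
    f = f / np.exp(np.log(f).mean())
    return SizeFactors(factors=pd.Series(f, index=counts.values.columns))


def log2_fold_change(
    matrix: ExpressionMatrix,
    pseudocount: float | None = None,
    size_factors: SizeFactors | None = None,
) -> FoldChangeProfile:
    """Per-gene log2 fold-change profiles relative to the 0 h baseline.

    Counts are divided by their size factor first (mandatory for the counts
    platform); replicates at the same time point are averaged on the
    normalized linear scale before ratioing.  The default pseudocount is 1.0
    for counts (guards zero counts) and 0.0 for intensities.

    Genes whose fold-change is non-finite at some time point are dropped from
    the profile and listed in ``dropped_genes``.  A zero baseline (after the
    pseudocount) for any gene is an error: raise the pseudocount or filter.
    """
    if pseudocount is None:
        pseudocount = 1.0 if matrix.platform == "counts" else 0.0
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if matrix.platform == "counts" and size_factors is None:
        raise ValueError("counts platform requires size_factors")

    vals = matrix.values.copy()
    if size_factors is not None:
        vals = vals / size_factors.factors
    meta = matrix.sample_meta
    by_time = vals.T.groupby(meta["time"]).mean().T  # genes x times, averaged replicates
    times = sorted(by_time.columns)
    by_time = by_time[times]

    base = by_time[times[0]] + pseudocount
    zero_base = base[base == 0]
    if len(zero_base):
        raise ValueError(
            "zero baseline (after pseudocount) for gene(s): "
            + ", ".join(map(str, zero_base.index[:10]))
            + ("..." if len(zero_base) > 10 else "")
        )
    fc = np.log2((by_time + pseudocount).div(base, axis=0))
    fc[times[0]] = 0.0  # exact zero at baseline

    finite = np.isfinite(fc.to_numpy()).all(axis=1)
    dropped = list(fc.index[~finite])
    fc = fc.loc[finite]
    return FoldChangeProfile(values=fc, platform=matrix.platform, dropped_genes=dropped)


def combine_platforms(
    fc_array: FoldChangeProfile, fc_counts: FoldChangeProfile
) -> CombinedProfiles:
    """Concatenate the non-baseline columns of the two platform profiles.

    Genes are inner-joined; those present in only one platform are reported
    in ``unmatched``, not silently dropped.  Baseline columns carry no
    information (identically 0) and are excluded from the clustering space.
    """
    shared = fc_array.values.index.intersection(fc_counts.values.index)
    if len(shared) == 0:
        raise ValueError("no genes shared between the two platforms")
    unmatched = {
        fc_array.platform: list(fc_array.values.index.difference(shared)),
        fc_counts.platform: list(fc_counts.values.index.difference(shared)),
    }

    def tagged(fc: FoldChangeProfile) -> pd.DataFrame:
        tag = PLATFORM_TAGS.get(fc.platform, fc.platform)
        block = fc.values.loc[shared, fc.values.columns[1:]]
        block.columns = [f"{tag}{t:g}" for t in block.columns]
        return block

    left, right = tagged(fc_array), tagged(fc_counts)
    return CombinedProfiles(
        values=pd.concat([left, right], axis=1),
        array_width=left.shape[1],
        unmatched=unmatched,
    )
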