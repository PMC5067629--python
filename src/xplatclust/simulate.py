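"""Paired-platform time-course simulator with known ground truth.

The generator emulates the data structure of a dual-platform (microarray +
RNA-Seq) transcriptome time course of silicon-starved *Thalassiosira
pseudonana*: genes fall into latent coexpression clusters, each cluster
following a shared archetype of log2 fold-change over the time course.
"Replicating" genes present the same latent profile on both platforms;
non-replicating genes draw an independent archetype for the second platform
(which may, with probability 1/K, coincide with the true one — realized
replication is therefore >= the nominal fraction).

Intensities are lognormal around the latent profile; counts are negative
binomial with per-sample library-size factors.  The negative binomial is
parameterized by mean mu and dispersion d with variance mu + d * mu**2 (the
RNA-Seq convention; "dispersion" is overloaded in other parameterizations).
Functional classes are assigned one per gene, uniformly, except for genes of
designated (cluster, class) pairs which receive the planted class with
probability proportional to ``enrichment_factor``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import AnnotationTable, ExpressionMatrix, write_annotation_tsv, write_expression_tsv

__all__ = [
    "KOG_CLASSES",
    "SimConfig",
    "GroundTruth",
    "generate_archetypes",
    "simulate_dataset",
    "write_dataset",
]

# Single-letter KOG functional class codes (metabolism / cellular-process
# classes used for the enrichment display): E amino acid, G carbohydrate,
# I lipid, H coenzyme, C energy, Q secondary metabolites, P inorganic ion,
# Z cytoskeleton, Y nuclear structure, D cell cycle, F nucleotide,
# B chromatin, L replication/repair, A RNA processing, J translation.
KOG_CLASSES: tuple[str, ...] = tuple("EGIHCQPZYDFBLAJ")

# Paper-style sampling grid: hours of silicon starvation.
DEFAULT_HOURS = (0.0, 4.0, 8.0, 12.0, 18.0, 24.0)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated dual-platform experiment.

    Attributes
    ----------
    n_clusters, genes_per_cluster
        K latent clusters, each with the same number of member genes.
    n_timepoints
        T samples per platform (default 6: hours 0, 4, 8, 12, 18, 24).
    amplitude_range
        (min, max) peak |log2FC| of the cluster archetypes.
    profile_noise_sd
        Per-gene log2FC deviation from the cluster archetype.
    replication_fraction
        Fraction of genes whose latent profile is shared across platforms.
    array_noise_sd
        SD of additive noise on log2 intensities.
    nb_dispersion
        Negative-binomial dispersion d (variance mu + d*mu^2); 0 means
        Poisson counts.
    baseline_mean_log10
        (lo, hi) range of per-gene baseline abundance on the log10 scale.
    size_factors
        Per-count-sample library-size factors (length T); None means all 1.
    n_enriched_classes / enrichment_factor / n_classes
        Plant ``n_enriched_classes`` (cluster i, class i) pairs whose genes
        receive class i with odds ``enrichment_factor`` : 1 over each other
        class; remaining genes draw uniformly from ``n_classes`` classes.
    deterministic_counts
        Replace the count sampling with rounding of the expected value
        (noise-free limit used for exactness checks).
    """

    n_clusters: int
    genes_per_cluster: int
    n_timepoints: int = 6
    amplitude_range: tuple[float, float] = (1.0, 3.0)
    profile_noise_sd: float = 0.2
    replication_fraction: float = 1.0
    array_noise_sd: float = 0.1
    nb_dispersion: float = 0.05
    baseline_mean_log10: tuple[float, float] = (1.5, 3.5)
    size_factors: tuple[float, ...] | None = None
    n_enriched_classes: int = 0
    enrichment_factor: float = 4.0
    n_classes: int = 15
    deterministic_counts: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_clusters < 1 or self.genes_per_cluster < 1:
            raise ValueError("n_clusters and genes_per_cluster must be >= 1")
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if not 0.0 <= self.replication_fraction <= 1.0:
            raise ValueError("replication_fraction must lie in [0, 1]")
        if self.profile_noise_sd < 0 or self.array_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.amplitude_range[0] <= 0 or self.amplitude_range[1] < self.amplitude_range[0]:
            raise ValueError("amplitude_range must be 0 < min <= max")
        if self.size_factors is not None:
            if len(self.size_factors) == 0:
                raise ValueError("size_factors must not be empty")
            if len(self.size_factors) != self.n_timepoints:
                raise ValueError(
                    "size_factors must have one entry per count sample "
                    f"({self.n_timepoints}), got {len(self.size_factors)}"
                )
            if any(f <= 0 for f in self.size_factors):
                raise ValueError("size_factors must be positive")
        if self.n_enriched_classes < 0 or self.n_enriched_classes > min(
            self.n_clusters, self.n_classes
        ):
            raise ValueError("n_enriched_classes must be in [0, min(K, n_classes)]")
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")

    @property
    def hours(self) -> tuple[float, ...]:
        if self.n_timepoints == len(DEFAULT_HOURS):
            return DEFAULT_HOURS
        return tuple(4.0 * i for i in range(self.n_timepoints))


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset.

    ``table`` is indexed by gene id with columns ``true_cluster`` (1..K),
    ``replicating`` (bool), ``counts_cluster`` (archetype index used on the
    counts platform; equals ``true_cluster`` for replicating genes) and
    ``true_class``.  ``archetypes`` is the K x T archetype profile matrix
    (rows indexed 1..K; each row is 0 at the baseline column).
    ``enriched_pairs`` lists the planted (cluster, class) pairs.
    """

    table: pd.DataFrame
    archetypes: pd.DataFrame
    enriched_pairs: list[tuple[int, str]]

    @property
    def assignment(self) -> pd.Series:
        return self.table["true_cluster"]


def _class_labels(n_classes: int) -> list[str]:
    labels = list(KOG_CLASSES[:n_classes])
    labels += [f"X{i}" for i in range(1, n_classes - len(labels) + 1)]
    return labels


def _smooth(row: np.ndarray) -> np.ndarray:
    """Three-point moving average with reflected ends; keeps the length."""
    padded = np.concatenate([row[:1], row, row[-1:]])
    return (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0


def generate_archetypes(
    K: int,
    T: int,
    amplitude_range: tuple[float, float],
    seed: int | np.random.Generator,
    min_separation: float = 2.0,
    max_tries: int = 10_000,
) -> np.ndarray:
    """Generate K pairwise-distinct archetype log2FC profiles of length T.

    Each archetype is a smoothed cumulative Gaussian random walk pinned to 0
    at the baseline index and rescaled so its peak |log2FC| is uniform in
    ``amplitude_range``.  Candidates closer than ``min_separation`` (Euclidean)
    to an accepted archetype are rejected and resampled, guaranteeing
    separable cluster shapes.  Deterministic given the seed.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if T < 2:
        raise ValueError("T must be >= 2")
    lo, hi = amplitude_range
    if lo <= 0 or hi < lo:
        raise ValueError("amplitude_range must be 0 < min <= max")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    rows: list[np.ndarray] = []
    tries = 0
    while len(rows) < K:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {K} archetypes at min separation {min_separation}; "
                "reduce K or min_separation"
            )
        walk = np.cumsum(rng.normal(size=T))
        if T > 3:
            walk = _smooth(walk)
        walk = walk - walk[0]
        peak = np.abs(walk).max()
        if peak == 0.0:
            continue
        target = rng.uniform(lo, hi)
        row = walk * (target / peak)
        if any(np.linalg.norm(row - prev) <= min_separation for prev in rows):
            continue
        rows.append(row)
    return np.vstack(rows)


def _sample_counts(
    rng: np.random.Generator,
    mu: np.ndarray,
    dispersion: float,
    deterministic: bool,
) -> np.ndarray:
    """Draw counts with mean ``mu``: NB(mu, d), Poisson at d=0, or round(mu)."""
    if deterministic:
        return np.rint(mu).astype(np.int64)
    if dispersion == 0.0:
        return rng.poisson(mu).astype(np.int64)
    n_param = 1.0 / dispersion
    p = n_param / (n_param + mu)
    return rng.negative_binomial(n_param, p).astype(np.int64)


def simulate_dataset(
    config: SimConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, AnnotationTable, GroundTruth]:
    """Simulate one paired-platform dataset.

    Returns (array_matrix, count_matrix, annotation, truth).  Bit-identical
    output for identical config (the seed is part of the config).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    K, gpc, T = config.n_clusters, config.genes_per_cluster, config.n_timepoints
    n = K * gpc
    hours = config.hours
    log2_10 = np.log2(10.0)

    archetypes = generate_archetypes(K, T, config.amplitude_range, rng)

    gene_ids = [f"g{i:05d}" for i in range(n)]
    true_cluster = np.repeat(np.arange(1, K + 1), gpc)
    replicating = rng.random(n) < config.replication_fraction

    def gene_noise() -> np.ndarray:
        eps = rng.normal(0.0, config.profile_noise_sd, size=(n, T))
        eps[:, 0] = 0.0  # profiles are fold-changes from baseline
        return eps

    profiles_array = archetypes[true_cluster - 1] + gene_noise()
    counts_cluster = np.where(
        replicating, true_cluster, rng.integers(1, K + 1, size=n)
    )
    fresh = archetypes[counts_cluster - 1] + gene_noise()
    profiles_counts = np.where(replicating[:, None], profiles_array, fresh)

    baseline_log10 = rng.uniform(*config.baseline_mean_log10, size=n)
    baseline = 10.0 ** baseline_log10

    array_log2 = (
        baseline_log10[:, None] * log2_10
        + profiles_array
        + rng.normal(0.0, config.array_noise_sd, size=(n, T))
    )
    array_values = 2.0 ** array_log2

    sf = np.asarray(config.size_factors if config.size_factors is not None else [1.0] * T)
    mu = sf[None, :] * baseline[:, None] * 2.0 ** profiles_counts
    count_values = _sample_counts(rng, mu, config.nb_dispersion, config.deterministic_counts)

    columns = [f"t{h:g}_r1" for h in hours]
    array_em = ExpressionMatrix(
        values=pd.DataFrame(array_values, index=gene_ids, columns=columns),
        platform="array",
    )
    counts_em = ExpressionMatrix(
        values=pd.DataFrame(count_values.astype(float), index=gene_ids, columns=columns),
        platform="counts",
    )

    labels = _class_labels(config.n_classes)
    enriched_pairs = [(c, labels[c - 1]) for c in range(1, config.n_enriched_classes + 1)]
    planted_class = {c: cls for c, cls in enriched_pairs}
    classes = np.empty(n, dtype=object)
    uniform_p = np.full(config.n_classes, 1.0 / config.n_classes)
    for cluster in range(1, K + 1):
        members = np.where(true_cluster == cluster)[0]
        if cluster in planted_class:
            w = np.ones(config.n_classes)
            w[labels.index(planted_class[cluster])] = config.enrichment_factor
            p = w / w.sum()
        else:
            p = uniform_p
        classes[members] = rng.choice(labels, size=members.size, p=p)

    annotation = AnnotationTable(
        mapping={g: {c} for g, c in zip(gene_ids, classes)},
        vocabulary=tuple(labels),
    )
    truth = GroundTruth(
        table=pd.DataFrame(
            {
                "true_cluster": true_cluster,
                "replicating": replicating,
                "counts_cluster": counts_cluster,
                "true_class": classes,
            },
            index=pd.Index(gene_ids, name="gene_id"),
        ),
        archetypes=pd.DataFrame(
            archetypes, index=pd.RangeIndex(1, K + 1, name="cluster"), columns=list(hours)
        ),
        enriched_pairs=enriched_pairs,
    )
    return array_em, counts_em, annotation, truth


def write_dataset(
    outdir,
    array_em: ExpressionMatrix,
    counts_em: ExpressionMatrix,
    annotation: AnnotationTable,
    truth: GroundTruth,
    config: SimConfig | None = None,
) -> dict[str, Path]:
    """Write a simulated dataset (expression TSVs, annotation, truth, config echo)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "array": outdir / "array.tsv",
        "counts": outdir / "counts.tsv",
        "annotation": outdir / "annotation.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_expression_tsv(array_em, paths["array"])
    write_expression_tsv(counts_em, paths["counts"])
    write_annotation_tsv(annotation, paths["annotation"])
    truth.table.to_csv(paths["truth"], sep="\t")
    if config is not None:
        paths["config"] = outdir / "sim_config.json"
        with open(paths["config"], "w") as fh:
            json.dump(dataclasses.asdict(config), fh, indent=2, default=list)
            fh.write("\n")
    return paths
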