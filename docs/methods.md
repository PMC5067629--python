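# Methods

## Setting

Two expression matrices over (mostly) the same gene universe describe one
perturbation time course: an intensity platform ("array": strictly positive
reals, lognormal-like noise) and a count platform ("counts": nonnegative
integers with per-sample library sizes). Samples are labelled
`t{hours}_r{rep}`; the 0 h baseline must be present on both platforms. The
analysis asks (i) which genes co-move over the course, (ii) whether each
coexpression cluster's shape replicates across the two platforms, and
(iii) which functional classes concentrate where.

## Normalization and fold-change profiles

Size factors for the count platform are estimated by median-of-ratios: with
reference genes R = {g : counts strictly positive in every sample},

    s_j = median_{g in R} ( c_gj / (prod_t c_gt)^(1/T) ),

rescaled so the factors have geometric mean 1 (making values comparable
across runs). The estimator assumes the bulk of genes is non-differential;
when every gene carries a strong temporal profile the median absorbs the
median profile per time point and the factors are biased. Precomputed
factors (e.g. from an external normalization) can be supplied to the model
instead of being estimated.

Per-gene profiles are log2((x_t + pc)/(x_0 + pc)) on normalized values,
with replicate samples averaged on the normalized *linear* scale before
ratioing (one value per time point per platform, matching a 2×(T−1)-column
clustering space for two platforms). The pseudocount pc defaults to 1.0
for counts (guards zero counts) and 0.0 for intensities (assumed strictly
positive). The baseline column is forced to exact 0; genes with non-finite
fold-change anywhere are dropped from the profile and reported, and a zero
baseline after the pseudocount is an error rather than a silent ±inf.

The combined clustering space inner-joins the two platforms' genes and
concatenates their non-baseline columns (the baseline columns are
identically zero and would only shrink all distances); unmatched genes are
reported, never silently dropped.

## Clustering and the choice of k

k-means uses Lloyd iterations with Euclidean distance, best of `n_init`
(default 25) seeded random initializations (scikit-learn's implementation;
its empty-cluster repair relocates centroids to the highest-inertia
points). Final centroids are recomputed as exact member means, and the
within-cluster variance statistic is the mean over clusters of the mean
squared member-to-centroid distance — 0 iff every member sits on its
centroid, and invariant to duplicating the gene set.

The randomized reference for selecting k permutes each column of the
profile matrix independently across genes. This destroys gene-level
temporal structure (what k-means exploits) while preserving every
column's marginal exactly; a global value shuffle would also destroy the
per-time-point scale. For each grid k (default 5,10,…,50,60,…,100) the
real and randomized (mean over R) variances are recorded; the chosen k is
the smallest grid value where

    actual < (1 − margin) × randomized,   margin = 0.10.

The margin exists because for data *without* coexpression structure the
real matrix and its column permutations are exchangeable: their variances
differ only by k-means sampling fluctuation (measured at ±5% on 200×10
i.i.d. Gaussian input), so a bare `<` comparison would fire by coin flip.
Ten percent sits well above that fluctuation and far below the variance
deficit of genuinely clustered data (ratios ≈ 0.2 under the study
conditions). If no grid k qualifies, the rule falls through to max(k) with
a warning flag. A `fixed:K` rule bypasses selection to mirror an
externally pinned cluster count (e.g. 50).

Centroids are ordered for display by average-linkage (UPGMA, Euclidean)
hierarchical clustering; scipy's linkage is deterministic with distance
ties broken by the lower observation index. Subclustering cuts an
average-linkage tree over one cluster's members at a requested count or
height, yielding nested labels (`15.1`, `15.2`, …).

## Replication scoring and inclusion

Gene-level replication is the Pearson correlation between the two
platforms' time-matched series — by default the *raw* normalized values
(intensities vs size-factor-normalized counts, replicates averaged), with
a `log2fc` alternative. Pearson is invariant to positive affine maps, so
platform scale is irrelevant; a constant series yields an undefined (NaN)
PCC, which counts as "not replicated" (a flat gene carries no replication
evidence). All available shared time points are used (≥ 3 required).

Cluster-level replication correlates the array half of the centroid with
its counts half, position-matched by time. Inclusion applies three
thresholds (defaults 0.5 PCC, 1.0 |log2FC|, 0.5 gene fraction):

    replicated := centroid_pcc > 0.5
    included   := max|centroid log2FC| > 1
                  AND (NOT replicated OR frac(gene PCC > 0.5) > 0.5)

i.e. the gene-fraction criterion binds replicated clusters only. The
|log2FC| condition is evaluated on the centroid maximum (cluster-level
summary), not per member gene.

## Functional Enrichment Index

FEI = (G_clusterclass / (G_cluster × G_class)) × 1000. G_cluster counts
*all* genes in the cluster, annotated or not; G_class is tabulated over
the clustered gene universe by default (`all-genes` switches to every
annotated gene); a multi-class gene increments G_clusterclass once per
class, unweighted. Under independence E[G_clusterclass] =
G_cluster·G_class/N, so null FEI cells concentrate at 1000/N — the package
verifies this calibration empirically. No significance test is attached to
FEI; it is a descriptive index.

## Promoter motif scan

Motifs are IUPAC strings over ACGTRYSWKMBDHVN. A sequence `N` (unknown
base) is matched only by pattern `N`; pattern `N` matches anything.
Scanning is regex-based with a lookahead so overlapping occurrences are
all reported; a position-by-position checker serves as the test oracle.

Offset convention (declared, since an anchor base is otherwise ambiguous):
regions are written 5'→3' ending at the base immediately adjacent to the
ORF start; a hit's `upstream_offset` is the 1-based distance from that
adjacent base to the motif's **3'-most** base — the rightmost matched base
on the + strand, the leftmost on the − strand (a − strand motif reads
right-to-left). Consequently reverse-complementing a region maps offsets
as offset' = L − offset + 1 and swaps strands. Strand − scanning matches
the reverse-complemented pattern against the displayed sequence and is off
by default (cis-elements are typically strand-specific).

## Synthetic data generator

The generator emulates the dual-platform experiment: K archetype log2FC
profiles (smoothed cumulative Gaussian random walks pinned to 0 at
baseline, peak |log2FC| uniform in `amplitude_range`, rejection-resampled
to a minimum pairwise Euclidean separation of 2.0 — chosen so that at the
default per-gene noise the cluster clouds, whose radius is ≈ 0.63 in the
10-D combined space, stay well separated from neighbouring archetypes);
per-gene Gaussian deviations from the archetype (`profile_noise_sd`);
a replicating fraction of genes sharing one latent profile across
platforms, the rest drawing an independent archetype for the counts
platform (which coincides with the true one with probability 1/K, so
realized replication ≥ nominal); lognormal intensities
(2^(log2 baseline + profile + N(0, array_noise_sd))); negative-binomial
counts with mean s_j · baseline · 2^profile and variance μ + d·μ²
(mean/dispersion parameterization; d = 0 gives Poisson, and a
deterministic mode rounds the mean for exactness checks); and one
functional class per gene, uniform except in planted (cluster, class)
pairs where the planted class has odds `enrichment_factor` : 1.

Defaults encode the study conditions: T = 6 time points at hours
0/4/8/12/18/24; amplitude range (1, 3) in log2 units (strong responses,
consistent with an inclusion threshold of |log2FC| > 1); profile noise sd
0.2; array noise sd 0.1 on log2 intensities; NB dispersion 0.05 (typical
for replicated bulk RNA-Seq); baselines 10^1.5–10^3.5; unit size factors.
Identical config (seed included) reproduces bit-identical output.

What the generator does *not* emulate — probe-level microarray artifacts,
batch effects, read-level sequencing, correlated gene-gene noise within
clusters beyond the shared archetype, unannotated genes, multi-class
annotations (available behind the annotation API but not generated) — 
bounds what passing tests show: recovery results demonstrate correctness
of the pipeline's statistics under the stated generative model, not
robustness to real-platform systematics.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: 400–2000 genes,
K = 4–10 clusters, 3–10 randomizations and 5–25 k-means starts, which keeps
the full suite in seconds while leaving every statistic's behaviour
(crossing vs fall-through, ARI, calibration) unambiguous. All randomness
descends from a single root seed through named substreams, so stages are
individually reproducible. Ties in hierarchical merges follow scipy's
deterministic lower-index rule; subcluster labels are renumbered in order
of first appearance; k-means determinism is per (seed, n_init), with
best-of-n monotone in n for a fixed seed stream.

## Known limitations

- Median-of-ratios factors are biased when most genes are differential
  (see above); supply external factors in that regime.
- The k-selection margin is a fixed 10%: datasets whose structure reduces
  within-cluster variance by less than that will fall through rather than
  pick a k.
- Exact replication of any specific historical clustering tool's
  assignments is not attempted; the variance statistic and randomization
  scheme here are declared, not inferred from such tools.
- FEI has no attached inferential test; compare values against the 1000/N
  null scale.
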