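"""End-to-end orchestration: simulate/load -> normalize -> cluster ->
replicate -> enrich (-> scan motifs), with a manifest of emitted files.

A run is driven by a single :class:`RunConfig` (YAML/JSON on disk).  Exactly
one of an input-path block or a simulation block must be present; the seed is
mandatory and every source of randomness derives from it through named
substreams, so reruns with the same config are checksum-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .cluster import linkage_to_newick
from .io import read_annotation_tsv, read_expression_tsv, read_fasta, write_expression_tsv
from .model import CoexpressionTimeCourse
from .motifs import presence_table, read_motifs_tsv, scan_promoters
from .simulate import SimConfig, simulate_dataset, write_dataset

__all__ = ["RunConfig", "RunManifest", "run_all", "load_run_config"]

logger = logging.getLogger("xplatclust")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    outdir: str
    seed: int
    # either input paths ...
    array_path: str | None = None
    counts_path: str | None = None
    annotation_path: str | None = None
    # ... or a simulation block
    sim: SimConfig | None = None
    # analysis parameters
    pseudocount: float = 1.0
    k_rule: str = "first-crossing"  # or "fixed:K"
    k_grid: tuple[int, ...] | None = None
    n_init: int = 25
    n_randomizations: int = 10
    pcc_threshold: float = 0.5
    fc_threshold: float = 1.0
    frac_threshold: float = 0.5
    pcc_space: str = "raw"
    class_universe: str = "clustered"
    # optional motif scan
    promoters_path: str | None = None
    motifs_path: str | None = None
    both_strands: bool = False

    def validate(self) -> None:
        has_paths = self.array_path is not None or self.counts_path is not None
        if has_paths and self.sim is not None:
            raise ValueError("config error: give input paths OR a 'sim' block, not both")
        if not has_paths and self.sim is None:
            raise ValueError("config error: one of input paths or a 'sim' block is required")
        if has_paths and (self.array_path is None or self.counts_path is None):
            raise ValueError("config error: both array_path and counts_path are required")
        if not isinstance(self.seed, int):
            raise ValueError("config error: field 'seed' must be an integer")
        for name in ("pcc_threshold", "frac_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"config error: field {name!r} must lie in [0, 1]")
        if self.fc_threshold < 0:
            raise ValueError("config error: field 'fc_threshold' must be >= 0")
        if not (
            self.k_rule == "first-crossing"
            or (self.k_rule.startswith("fixed:") and self.k_rule[6:].isdigit())
        ):
            raise ValueError("config error: k_rule must be 'first-crossing' or 'fixed:K'")
        if (self.promoters_path is None) != (self.motifs_path is None):
            raise ValueError(
                "config error: promoters_path and motifs_path must be given together"
            )


@dataclass
class RunManifest:
    """Record of a completed (or aborted) run."""

    config: dict
    version: str
    files: dict[str, dict] = field(default_factory=dict)  # name -> {path, sha256}
    wall_times: dict[str, float] = field(default_factory=dict)
    warnings: dict[str, int] = field(default_factory=dict)
    completed_stages: list[str] = field(default_factory=list)

    def record(self, name: str, path: Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.files[name] = {"path": str(path), "sha256": digest}

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)
            fh.write("\n")


def load_run_config(path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    if "seed" not in raw:
        raise ValueError("config error: required field 'seed' is missing")
    if "outdir" not in raw:
        raise ValueError("config error: required field 'outdir' is missing")
    sim = raw.pop("sim", None)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"config error: unknown field(s) {sorted(unknown)}")
    if "k_grid" in raw and raw["k_grid"] is not None:
        raw["k_grid"] = tuple(int(k) for k in raw["k_grid"])
    cfg = RunConfig(**raw)
    if sim is not None:
        sim_fields = {f.name for f in dataclasses.fields(SimConfig)}
        unknown = set(sim) - sim_fields
        if unknown:
            raise ValueError(f"config error: unknown sim field(s) {sorted(unknown)}")
        for tup in ("amplitude_range", "baseline_mean_log10", "size_factors"):
            if tup in sim and sim[tup] is not None:
                sim[tup] = tuple(sim[tup])
        sim.setdefault("seed", cfg.seed)
        cfg.sim = SimConfig(**sim)
    cfg.validate()
    return cfg


def run_all(config: RunConfig) -> RunManifest:
    """Execute every configured stage in order, emitting TSV/JSON/Newick
    outputs and a manifest with per-file checksums.

    Identical config (same seed) reproduces byte-identical outputs.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cfg_dict = dataclasses.asdict(config)
    manifest = RunManifest(config=cfg_dict, version=__version__)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    def stage(name):
        logger.info("stage %s: start", name)
        return time.perf_counter()

    def done(name, t0):
        manifest.wall_times[name] = time.perf_counter() - t0
        manifest.completed_stages.append(name)
        logger.info("stage %s: done (%.2fs)", name, manifest.wall_times[name])

    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")

            # ---- inputs ----------------------------------------------------
            t0 = stage("inputs")
            annotation = None
            if config.sim is not None:
                array_em, counts_em, annotation, truth = simulate_dataset(config.sim)
                paths = write_dataset(
                    outdir, array_em, counts_em, annotation, truth, config.sim
                )
                for name, p in paths.items():
                    manifest.record(f"sim_{name}", p)
            else:
                array_em = read_expression_tsv(config.array_path, "array")
                counts_em = read_expression_tsv(config.counts_path, "counts")
                if config.annotation_path:
                    annotation = read_annotation_tsv(config.annotation_path)
            done("inputs", t0)

            # ---- fit (normalize + cluster + replicate + enrich) ------------
            t0 = stage("fit")
            model = CoexpressionTimeCourse(
                array_em, counts_em, annotation=annotation,
                pseudocount_counts=config.pseudocount,
            )
            if config.k_rule.startswith("fixed:"):
                k: int | str = int(config.k_rule.split(":", 1)[1])
            else:
                k = "select"
            fit_kwargs = dict(
                k=k,
                n_init=config.n_init,
                n_randomizations=config.n_randomizations,
                seed=config.seed,
                pcc_space=config.pcc_space,
                fc_threshold=config.fc_threshold,
                pcc_threshold=config.pcc_threshold,
                frac_threshold=config.frac_threshold,
                class_universe=config.class_universe,
            )
            if config.k_grid is not None:
                fit_kwargs["k_grid"] = config.k_grid
            results = model.fit(**fit_kwargs)
            done("fit", t0)

            # ---- outputs ---------------------------------------------------
            t0 = stage("outputs")
            sf_path = outdir / "size_factors.tsv"
            results.size_factors.factors.rename("size_factor").to_csv(sf_path, sep="\t")
            manifest.record("size_factors", sf_path)

            for tag, fc in (
                ("fold_change_array", results.fold_change_array),
                ("fold_change_counts", results.fold_change_counts),
            ):
                p = outdir / f"{tag}.tsv"
                out = fc.values.copy()
                out.columns = [f"t{c:g}" for c in out.columns]
                out.index.name = "gene_id"
                out.to_csv(p, sep="\t", float_format="%.6g")
                manifest.record(tag, p)

            p = outdir / "assignment.tsv"
            results.assignment.rename("cluster").to_csv(p, sep="\t")
            manifest.record("assignment", p)

            p = outdir / "centroids.tsv"
            results.clusters.centroids.to_csv(p, sep="\t", float_format="%.6g")
            manifest.record("centroids", p)

            if results.k_trace is not None:
                p = outdir / "k_selection.tsv"
                results.k_trace.as_frame().to_csv(p, sep="\t", index=False, float_format="%.6g")
                manifest.record("k_selection", p)

            if results.clusters.linkage is not None and results.clusters.leaf_order:
                p = outdir / "centroid_dendrogram.nwk"
                leaf_ids = list(results.clusters.centroids.index)
                p.write_text(
                    linkage_to_newick(results.clusters.linkage, leaf_ids) + "\n"
                )
                manifest.record("centroid_dendrogram", p)

            p = outdir / "gene_pcc.tsv"
            results.gene_pcc.to_csv(p, sep="\t", float_format="%.6g")
            manifest.record("gene_pcc", p)

            p = outdir / "cluster_stats.tsv"
            results.cluster_stats.to_csv(p, sep="\t", float_format="%.6g")
            manifest.record("cluster_stats", p)

            p = outdir / "heatmap_table.tsv"
            results.heatmap_table().to_csv(p, sep="\t", float_format="%.6g")
            manifest.record("heatmap_table", p)

            if results.enrichment is not None:
                p = outdir / "fei.tsv"
                results.enrichment.fei.to_csv(p, sep="\t", float_format="%.6g")
                manifest.record("fei", p)
                p = outdir / "enrichment_counts.tsv"
                results.enrichment.counts.to_csv(p, sep="\t")
                manifest.record("enrichment_counts", p)
            done("outputs", t0)

            # ---- optional motif scan --------------------------------------
            if config.promoters_path and config.motifs_path:
                t0 = stage("scan_motifs")
                regions = read_fasta(config.promoters_path)
                motif_defs = read_motifs_tsv(config.motifs_path)
                hits = scan_promoters(regions, motif_defs, both_strands=config.both_strands)
                import pandas as pd

                p = outdir / "motif_hits.tsv"
                pd.DataFrame([dataclasses.asdict(h) for h in hits]).to_csv(
                    p, sep="\t", index=False
                )
                manifest.record("motif_hits", p)
                p = outdir / "motif_presence.tsv"
                presence_table(hits, regions, motif_defs).to_csv(p, sep="\t", float_format="%g")
                manifest.record("motif_presence", p)
                done("scan_motifs", t0)

            for w in caught:
                key = str(w.message)[:80]
                manifest.warnings[key] = manifest.warnings.get(key, 0) + 1
    finally:
        manifest_path = outdir / "manifest.json"
        manifest.write(manifest_path)
        logger.removeHandler(handler)
        handler.close()
    return manifest
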