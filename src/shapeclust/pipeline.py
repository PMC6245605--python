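"""End-to-end orchestration: read -> align -> descriptors -> fuse -> cluster.

The pipeline reads a directory of PDB models (lexicographic id order), builds
one descriptor-space distance matrix per requested descriptor (plus the
TM-score baseline on request), min-max normalizes and fuses them, clusters the
final matrix (fixed k or silhouette-based selection over a k range), and —
given ground-truth labels — reports the Rand index on the labelled subset.
All randomness is funnelled through named seeds; a run is reproducible
bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering as cl
from . import distances as dist
from .descriptors3d import DescriptorConfig
from .evaluation import LabeledPartition, adjusted_rand, evaluate_on_subset
from .pdb_io import read_pdb_dir

__all__ = ["PipelineConfig", "PipelineResult", "run"]

VALID_DESCRIPTORS = ("fpfh", "sc3d", "rsd", "vfh", "tm")


@dataclass
class PipelineConfig:
    input_dir: str
    output_dir: str
    labels_path: str | None = None
    selection: str = "all_heavy"  # or "calpha"
    descriptors: tuple[str, ...] = ("fpfh", "sc3d", "rsd", "vfh")
    fusion: str = "equal"  # "equal" | "silhouette" | "none"
    method: str = "kmedoids"  # "kmedoids" | "agglomerative" | "dbscan"
    k: int | None = None  # fixed cluster count; None -> select over k_range
    k_range: tuple[int, int] = (3, 25)
    alignment_mode: str = "pairwise"  # or "reference"
    seed: int = 42
    restarts: int = 10
    dbscan_eps: float | None = None
    dbscan_min_pts: int = 4
    descriptor_config: DescriptorConfig = field(default_factory=DescriptorConfig)

    def validate(self) -> None:
        if not self.descriptors:
            raise ValueError("config.descriptors: at least one descriptor required")
        for d in self.descriptors:
            if d not in VALID_DESCRIPTORS:
                raise ValueError(f"config.descriptors: unknown descriptor {d!r}")
        if self.fusion not in ("equal", "silhouette", "none"):
            raise ValueError(f"config.fusion: unknown scheme {self.fusion!r}")
        if self.method not in ("kmedoids", "agglomerative", "dbscan"):
            raise ValueError(f"config.method: unknown method {self.method!r}")
        if self.selection not in ("all_heavy", "calpha"):
            raise ValueError(f"config.selection: unknown selection {self.selection!r}")
        if self.alignment_mode not in ("pairwise", "reference"):
            raise ValueError(
                f"config.alignment_mode: unknown mode {self.alignment_mode!r}"
            )
        lo, hi = self.k_range
        if lo < 2 or hi < lo:
            raise ValueError("config.k_range: need 2 <= low <= high")
        self.descriptor_config.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        desc_cfg = data.pop("descriptor_config", None)
        cfg = cls(**data)
        if desc_cfg:
            cfg.descriptor_config = DescriptorConfig(**desc_cfg)
        if isinstance(cfg.descriptors, list):
            cfg.descriptors = tuple(cfg.descriptors)
        if isinstance(cfg.k_range, list):
            cfg.k_range = tuple(cfg.k_range)
        cfg.validate()
        return cfg


@dataclass
class PipelineResult:
    report: dict
    clustering: cl.Clustering
    matrices: dict[str, dist.DistanceMatrix]
    profile: cl.SilhouetteProfile | None


def _build_matrices(models, config: PipelineConfig) -> dict[str, dist.DistanceMatrix]:
    matrices: dict[str, dist.DistanceMatrix] = {}
    shared_pairwise = None
    need_pairwise = config.alignment_mode == "pairwise" or "tm" in config.descriptors
    if need_pairwise:
        shared_pairwise = dist.compute_pairwise_alignments(models)
    shared_reference = None
    if config.alignment_mode == "reference":
        shared_reference = dist.compute_reference_alignments(models)
    for d in config.descriptors:
        if d == "tm":
            matrices[d] = dist.tm_distance_matrix(models,
                                                  alignments=shared_pairwise)
        else:
            aln = (shared_pairwise if config.alignment_mode == "pairwise"
                   else shared_reference)
            matrices[d] = dist.pairwise_distance_matrix(
                models, d, config.descriptor_config,
                selection=config.selection, mode=config.alignment_mode,
                alignments=aln)
    return matrices


def _final_matrix(matrices, config: PipelineConfig, report: dict):
    named = list(matrices.items())
    if config.fusion == "none" or len(named) == 1:
        report["fusion"] = {"scheme": "none"}
        return named[0][1]
    normalized = [dist.normalize_matrix(m) for _, m in named]
    if config.fusion == "equal":
        weights = dist.FusionWeights(weights=[1.0] * len(normalized),
                                     scheme="equal")
    else:
        lo, hi = config.k_range
        weights = dist.silhouette_weights(normalized, range(lo, hi + 1),
                                          seed=config.seed,
                                          restarts=config.restarts)
    report["fusion"] = {
        "scheme": config.fusion,
        "weights": {name: w for (name, _), w in zip(named, weights.weights)},
    }
    return dist.fuse(normalized, weights)


def _cluster(final, config: PipelineConfig, report: dict):
    profile = None
    if config.method == "dbscan":
        clustering = cl.dbscan(final, eps=config.dbscan_eps,
                               min_pts=config.dbscan_min_pts)
        if clustering.n_clusters > 1:
            profile = cl.silhouette(final, clustering)
        report["clustering"] = {"method": "dbscan",
                                "params": clustering.params,
                                "n_clusters": clustering.n_clusters}
    elif config.k is not None:
        if config.method == "kmedoids":
            clustering = cl.k_medoids(final, config.k, seed=config.seed,
                                      restarts=config.restarts)
        else:
            clustering = cl.agglomerative(final, config.k)
        if clustering.n_clusters > 1:
            profile = cl.silhouette(final, clustering)
        report["clustering"] = {"method": config.method, "k": config.k,
                                "n_clusters": clustering.n_clusters}
    else:
        lo, hi = config.k_range
        k_star, clustering, profile = cl.select_k(
            final, method=config.method, k_range=range(lo, hi + 1),
            seed=config.seed, restarts=config.restarts)
        report["clustering"] = {"method": config.method, "k_star": k_star,
                                "k_range": [lo, hi],
                                "n_clusters": clustering.n_clusters}
    if profile is not None:
        report["clustering"]["average_silhouette"] = profile.average
    return clustering, profile


def run(config: PipelineConfig) -> PipelineResult:
    """Execute the full workflow and write report files to the output dir."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    models = read_pdb_dir(config.input_dir)
    models.sort(key=lambda m: m.model_id)
    if len(models) < 3:
        raise ValueError("pipeline needs at least 3 input models")

    report: dict = {
        "seed": config.seed,
        "n_models": len(models),
        "selection": config.selection,
        "alignment_mode": config.alignment_mode,
        "descriptors": list(config.descriptors),
    }
    matrices = _build_matrices(models, config)
    for name, m in matrices.items():
        m.to_tsv(out / f"distance_{name}.tsv")
    final = _final_matrix(matrices, config, report)
    final.to_tsv(out / "distance_final.tsv")

    clustering, profile = _cluster(final, config, report)
    pd.DataFrame({"model_id": clustering.ids,
                  "cluster": clustering.labels}).to_csv(
        out / "assignments.tsv", sep="\t", index=False)
    if profile is not None and profile.per_k:
        pd.DataFrame(sorted(profile.per_k.items()),
                     columns=["k", "average_silhouette"]).to_csv(
            out / "silhouette_per_k.tsv", sep="\t", index=False)

    if config.labels_path:
        truth = LabeledPartition.from_tsv(config.labels_path)
        report["rand_index"] = evaluate_on_subset(clustering, truth)
        truth_common = truth.restricted_to(set(clustering.ids))
        cluster_part = LabeledPartition.from_clustering(clustering).restricted_to(
            set(truth.ids))
        report["adjusted_rand_index"] = adjusted_rand(cluster_part, truth_common)

    with open(out / "report.json", "w") as handle:
        json.dump(report, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return PipelineResult(report=report, clustering=clustering,
                          matrices=matrices, profile=profile)
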