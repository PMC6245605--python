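"""Descriptor-space distance matrices, the TM-score baseline, and fusion.

Two proteins are compared in descriptor space by the root-mean-square
Euclidean deviation between corresponding per-point feature vectors,

    RMSD(F_i, F_j) = sqrt( (1/L) sum_k || f_ik - f_jk ||^2 ),

where the point correspondence k <-> k is given by shared alignment anchors
(the C-alpha atoms of structurally aligned residue pairs). For a global
descriptor (L = 1) this reduces to the Euclidean distance.

Per-descriptor matrices are min-max normalized (by their largest off-diagonal
entry) and fused as a weighted sum D = sum_m w_m D_m, with weights either all
equal or taken from each descriptor's best average silhouette width over a
range of cluster counts.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import euclidean_distances

from . import clustering as _clustering
from .descriptors3d import (DescriptorConfig, DescriptorSet, default_viewpoint,
                            estimate_normals, extract)
from .pdb_io import ProteinModel, to_point_cloud
from .superpose import SuperpositionResult, tm_align

__all__ = [
    "DistanceMatrix",
    "FusionWeights",
    "descriptor_rmsd",
    "pairwise_distance_matrix",
    "tm_distance_matrix",
    "normalize_matrix",
    "fuse",
    "silhouette_weights",
    "compute_pairwise_alignments",
    "compute_reference_alignments",
]


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # (n, n), symmetric, zero diagonal
    provenance: str = ""  # descriptor type, "tm", or "combined"
    normalized: bool = False

    @property
    def n(self) -> int:
        return len(self.ids)

    def validate(self) -> None:
        v = self.values
        if v.shape != (self.n, self.n):
            raise ValueError("matrix shape does not match the id list")
        if not np.all(np.isfinite(v)):
            raise ValueError("matrix has non-finite entries")
        if np.any(v < 0):
            raise ValueError("matrix has negative entries")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-9):
            raise ValueError("matrix diagonal is not zero")

    def off_diagonal(self) -> np.ndarray:
        mask = ~np.eye(self.n, dtype=bool)
        return self.values[mask]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", float_format="%.10g"
        )

    @classmethod
    def from_tsv(cls, path: str | Path, provenance: str = "") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        m = cls(ids=[str(c) for c in df.columns], values=df.to_numpy(dtype=float),
                provenance=provenance)
        m.validate()
        return m


@dataclass
class FusionWeights:
    weights: list[float]
    scheme: str = "equal"  # "equal" or "silhouette"

    def validate(self) -> None:
        if any(w < 0 for w in self.weights):
            raise ValueError("fusion weights must be nonnegative")
        if not any(w > 0 for w in self.weights):
            raise ValueError("at least one fusion weight must be positive")


def descriptor_rmsd(f_i: DescriptorSet, f_j: DescriptorSet) -> float:
    """RMS Euclidean deviation between corresponding feature vectors."""
    if f_i.descriptor_type != f_j.descriptor_type:
        raise ValueError(
            f"descriptor types differ: {f_i.descriptor_type} vs {f_j.descriptor_type}"
        )
    if f_i.vectors.shape != f_j.vectors.shape:
        raise ValueError(
            f"descriptor shapes differ: {f_i.vectors.shape} vs {f_j.vectors.shape}"
        )
    diff = f_i.vectors - f_j.vectors
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def _usable_models(models: list[ProteinModel]) -> list[ProteinModel]:
    """Drop models that cannot be aligned (fewer than 5 C-alpha residues)."""
    usable = []
    for m in models:
        n_ca = sum(1 for _, res in m.iter_residues()
                   if any(a.name == "CA" for a in res.atoms))
        if n_ca >= 5:
            usable.append(m)
        else:
            warnings.warn(f"model {m.model_id!r} excluded: only {n_ca} C-alpha atoms")
    return usable


def compute_pairwise_alignments(
    models: list[ProteinModel],
) -> dict[tuple[int, int], SuperpositionResult]:
    """tm_align for every unordered pair, keyed by (i, j) with i < j."""
    out = {}
    for i, j in itertools.combinations(range(len(models)), 2):
        out[(i, j)] = tm_align(models[i], models[j])
    return out


def compute_reference_alignments(
    models: list[ProteinModel],
) -> list[SuperpositionResult | None]:
    """tm_align of every model onto models[0]; entry 0 is None (identity)."""
    return [None] + [tm_align(models[0], m) for m in models[1:]]


def _residue_keys(model: ProteinModel) -> list[tuple[str, int]]:
    keys = []
    for chain_id, res in model.iter_residues():
        if any(a.name == "CA" for a in res.atoms):
            keys.append((chain_id, res.number))
    return keys


def _pair_descriptor_distance(model_a, model_b, sup, descriptor_type,
                              config, selection) -> float:
    """Descriptor distance of one aligned pair at shared alignment anchors."""
    moved_b = model_b.transformed(sup.rotation, sup.translation)
    cloud_a = to_point_cloud(model_a, selection)
    cloud_b = to_point_cloud(moved_b, selection)
    viewpoint = default_viewpoint(cloud_a.points)
    cloud_a = estimate_normals(cloud_a, config.neighbor_k, viewpoint)
    cloud_b = estimate_normals(cloud_b, config.neighbor_k, viewpoint)
    keys_a = _residue_keys(model_a)
    keys_b = _residue_keys(model_b)
    if descriptor_type == "vfh":
        anchors_a = anchors_b = None
    else:
        anchors_a = np.array([cloud_a.anchor_index[keys_a[ia]]
                              for ia, _ in sup.alignment.pairs])
        anchors_b = np.array([cloud_b.anchor_index[keys_b[ib]]
                              for _, ib in sup.alignment.pairs])
    cfg = config
    if descriptor_type == "vfh" and cfg.viewpoint is None:
        from dataclasses import replace
        cfg = replace(cfg, viewpoint=viewpoint)  # shared across the pair
    da = extract(cloud_a, descriptor_type, cfg, anchors_a, model_a.model_id)
    db = extract(cloud_b, descriptor_type, cfg, anchors_b, model_b.model_id)
    return descriptor_rmsd(da, db)


def pairwise_distance_matrix(models: list[ProteinModel], descriptor_type: str,
                             config: DescriptorConfig | None = None,
                             selection: str = "all_heavy",
                             mode: str = "pairwise",
                             alignments=None) -> DistanceMatrix:
    """Descriptor-space distance matrix over a set of models.

    ``mode="pairwise"`` (default) aligns every pair and extracts descriptors
    on the aligned pose at the pair's shared anchors. ``mode="reference"``
    aligns all models to the first one and extracts descriptors once per
    model at a common anchor set (the reference residues aligned in every
    model) — a faster approximation for large sets.
    """
    config = config or DescriptorConfig()
    config.validate()
    models = _usable_models(models)
    if len(models) < 2:
        raise ValueError("need at least 2 alignable models")
    ids = [m.model_id for m in models]
    n = len(models)
    values = np.zeros((n, n))

    if mode == "pairwise":
        if alignments is None:
            alignments = compute_pairwise_alignments(models)
        for (i, j), sup in alignments.items():
            d = _pair_descriptor_distance(models[i], models[j], sup,
                                          descriptor_type, config, selection)
            values[i, j] = values[j, i] = d
    elif mode == "reference":
        values = _reference_mode_matrix(models, descriptor_type, config,
                                        selection, alignments)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    m = DistanceMatrix(ids=ids, values=values, provenance=descriptor_type)
    m.validate()
    return m


def _reference_mode_matrix(models, descriptor_type, config, selection,
                           alignments=None) -> np.ndarray:
    if alignments is None:
        alignments = compute_reference_alignments(models)
    ref = models[0]
    ref_keys = _residue_keys(ref)
    n_ref = len(ref_keys)
    # residue map per model: reference residue index -> model residue index
    maps = [{i: i for i in range(n_ref)}]
    common = set(range(n_ref))
    for sup in alignments[1:]:
        m = {ia: ib for ia, ib in sup.alignment.pairs}
        maps.append(m)
        common &= set(m)
    if len(common) < 1 and descriptor_type != "vfh":
        raise ValueError("no reference residues aligned across all models")
    common_sorted = sorted(common)
    viewpoint = default_viewpoint(to_point_cloud(ref, selection).points)

    stacks = []
    for model, sup, rmap in zip(models, alignments, maps):
        moved = model if sup is None else model.transformed(sup.rotation,
                                                            sup.translation)
        cloud = to_point_cloud(moved, selection)
        cloud = estimate_normals(cloud, config.neighbor_k, viewpoint)
        keys = _residue_keys(model)
        if descriptor_type == "vfh":
            anchors = None
            cfg = config
            if cfg.viewpoint is None:
                from dataclasses import replace
                cfg = replace(cfg, viewpoint=viewpoint)
        else:
            anchors = np.array([cloud.anchor_index[keys[rmap[r]]]
                                for r in common_sorted])
            cfg = config
        ds = extract(cloud, descriptor_type, cfg, anchors, model.model_id)
        stacks.append(ds.vectors.reshape(-1))
    X = np.vstack(stacks)
    L = 1 if descriptor_type == "vfh" else len(common_sorted)
    values = euclidean_distances(X) / np.sqrt(L)
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 0.0)
    return np.maximum(values, 0.0)


def tm_distance_matrix(models: list[ProteinModel],
                       alignments=None) -> DistanceMatrix:
    """Baseline matrix: 1 - mean of the two TM-score directions per pair."""
    models = _usable_models(models)
    if len(models) < 2:
        raise ValueError("need at least 2 alignable models")
    if alignments is None:
        alignments = compute_pairwise_alignments(models)
    n = len(models)
    values = np.zeros((n, n))
    for (i, j), sup in alignments.items():
        d = 1.0 - 0.5 * (sup.tm_score_ab + sup.tm_score_ba)
        values[i, j] = values[j, i] = max(d, 0.0)
    m = DistanceMatrix(ids=[m_.model_id for m_ in models], values=values,
                       provenance="tm")
    m.validate()
    return m


def normalize_matrix(matrix: DistanceMatrix) -> DistanceMatrix:
    """Divide by the largest off-diagonal entry (min-max normalization)."""
    matrix.validate()
    max_off = matrix.off_diagonal().max() if matrix.n > 1 else 0.0
    if max_off <= 0:
        raise ValueError("cannot normalize an all-zero distance matrix")
    out = DistanceMatrix(ids=list(matrix.ids), values=matrix.values / max_off,
                         provenance=matrix.provenance, normalized=True)
    out.validate()
    return out


def fuse(matrices: list[DistanceMatrix], weights: FusionWeights,
         require_normalized: bool = True) -> DistanceMatrix:
    """Weighted sum of distance matrices over a shared id ordering."""
    if len(matrices) != len(weights.weights):
        raise ValueError("one weight per matrix required")
    weights.validate()
    ids = matrices[0].ids
    for m in matrices:
        if m.ids != ids:
            raise ValueError("matrices have mismatched id orderings")
        if require_normalized and not m.normalized:
            raise ValueError(
                f"matrix {m.provenance!r} is not normalized; normalize first "
                "or pass require_normalized=False for the raw weighted sum"
            )
    values = sum(w * m.values for w, m in zip(weights.weights, matrices))
    out = DistanceMatrix(ids=list(ids), values=values, provenance="combined",
                         normalized=False)
    out.validate()
    return out


def silhouette_weights(matrices: list[DistanceMatrix],
                       k_range=range(3, 26), seed: int = 42,
                       restarts: int = 10) -> FusionWeights:
    """Per-matrix weight = best average silhouette width over the k range.

    Clustering is k-medoids; negative maxima are clamped to 0. If every
    weight clamps to 0 the scheme falls back to equal weights.
    """
    ws = []
    for m in matrices:
        if m.n < 3:
            raise ValueError("silhouette weights need at least 3 objects")
        best = -np.inf
        for k in k_range:
            if not 2 <= k <= m.n - 1:
                continue
            c = _clustering.k_medoids(m, k, seed=seed, restarts=restarts)
            prof = _clustering.silhouette(m, c)
            best = max(best, prof.average)
        ws.append(max(best, 0.0) if np.isfinite(best) else 0.0)
    if not any(w > 0 for w in ws):
        warnings.warn("all silhouette weights clamp to 0; falling back to equal")
        ws = [1.0] * len(matrices)
    fw = FusionWeights(weights=ws, scheme="silhouette")
    fw.validate()
    return fw
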