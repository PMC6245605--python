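"""Point-cloud shape descriptors over protein atom clouds.

Four descriptors from the 3D-object-recognition literature are computed on a
protein's atom point cloud (after pairwise structural alignment, so that the
orientation-sensitive ones are comparable between proteins):

* FPFH — per-point histograms of the three Darboux-frame angles between the
  query point/normal and its k nearest neighbors, neighbor-smoothed with
  inverse-distance weights: FPFH(p) = SPFH(p) + (1/k) sum_i SPFH(p_i)/d_i.
* 3DSC — per-point histogram over a spherical support region, binned uniformly
  in azimuth and elevation and logarithmically in radius; each in-support
  point contributes 1 / (rho_i * V(bin)^(1/3)) where rho_i is the local point
  density (count within a sphere of radius delta) and V the bin volume.
* RSD — per point, the (minimum, maximum) radius of spheres through the point
  and each neighbor consistent with their normals, via the chord relation
  d = r sqrt(2 - 2 cos(alpha)); near-parallel normals use the first-order
  Taylor inversion r = d / alpha, clamped at a plane radius.
* VFH — one global vector per cloud: an SPFH anchored at the centroid
  (treating every point as a neighbor) concatenated with a histogram of angles
  between the point normals and the viewpoint-to-centroid direction.

All computations are deterministic for a fixed input order and configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .pdb_io import PointCloud

__all__ = [
    "DescriptorConfig",
    "DescriptorSet",
    "estimate_normals",
    "pair_features",
    "spfh",
    "fpfh",
    "shape_context_3d",
    "rsd",
    "vfh",
    "extract",
    "default_viewpoint",
    "sc_point_weight",
]

DESCRIPTOR_TYPES = ("fpfh", "sc3d", "rsd", "vfh")


@dataclass
class DescriptorConfig:
    """Tunable parameters for normal estimation and the four descriptors.

    Defaults follow the conventions of the reference point-cloud descriptor
    implementations; distances are in Angstrom.
    """

    neighbor_k: int = 10  # normals & FPFH neighborhood size
    support_radius: float = 8.0  # 3DSC / RSD support sphere
    sc_bins: tuple[int, int, int] = (12, 11, 15)  # azimuth J, elevation K, radial R
    sc_min_radius_fraction: float = 0.1
    sc_density_radius: float = 2.0  # delta of the 3DSC density term
    rsd_plane_radius: float = 20.0  # clamp for flat neighborhoods
    fpfh_bins_per_feature: int = 11  # 3 features x 11 bins = 33 dimensions
    rsd_taylor_angle: float = 0.1  # rad; below this use r = d / alpha
    viewpoint: np.ndarray | None = None  # None -> default_viewpoint(cloud)

    @classmethod
    def for_calpha(cls) -> "DescriptorConfig":
        """Parameters suited to sparse C-alpha-only clouds.

        With one point per residue (3.8 A spacing) the default 10-point
        neighborhood only spans the chain tube, where surface normals are
        ill-defined; ~30 neighbors reach spatially adjacent secondary-
        structure elements. The shape-context bins are coarsened so each
        bin keeps an O(1) expected point count instead of an almost always
        empty one, and the support sphere is widened to cover cross-strand
        contacts.
        """
        return cls(neighbor_k=30, support_radius=12.0, sc_bins=(6, 5, 5))

    def validate(self) -> None:
        if self.neighbor_k < 1 or self.fpfh_bins_per_feature < 1:
            raise ValueError("counts must be >= 1")
        if min(self.sc_bins) < 1:
            raise ValueError("3DSC bin counts must be >= 1")
        if self.support_radius <= 0 or self.sc_density_radius <= 0 \
                or self.rsd_plane_radius <= 0:
            raise ValueError("radii must be positive")
        if not 0 < self.sc_min_radius_fraction < 1:
            raise ValueError("sc_min_radius_fraction must be in (0, 1)")


@dataclass
class DescriptorSet:
    """L feature vectors of dimension D for one model under one descriptor."""

    model_id: str
    descriptor_type: str
    vectors: np.ndarray  # (L, D)
    anchor_points: np.ndarray | None = None  # indices of the L query points

    @property
    def l(self) -> int:
        return self.vectors.shape[0]

    @property
    def d(self) -> int:
        return self.vectors.shape[1]

    def validate(self) -> None:
        if self.descriptor_type not in DESCRIPTOR_TYPES:
            raise ValueError(f"unknown descriptor type {self.descriptor_type!r}")
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be a 2D (L x D) array")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("descriptor vectors have non-finite entries")
        if self.descriptor_type in ("fpfh", "sc3d", "vfh") and np.any(self.vectors < 0):
            raise ValueError("histogram descriptors must be nonnegative")
        if self.descriptor_type == "vfh" and self.l != 1:
            raise ValueError("VFH is a single global vector (L = 1)")


def default_viewpoint(points: np.ndarray) -> np.ndarray:
    """A fixed point outside the cloud: centroid + 3 bounding radii.

    The offset direction is the cloud's own principal axis (sign fixed by the
    third moment along it), so the viewpoint co-rotates with the cloud and
    descriptor extraction is invariant to a common rigid motion of the input.
    """
    points = np.asarray(points, dtype=float)
    centroid = points.mean(axis=0)
    centered = points - centroid
    radius = float(np.max(np.linalg.norm(centered, axis=1)))
    direction = np.array([0.0, 0.0, 1.0])
    if len(points) >= 3:
        cov = centered.T @ centered
        eigvals, eigvecs = np.linalg.eigh(cov)
        scale = max(eigvals[-1], 1e-12)
        for axis_idx in (2, 1, 0):  # try axes by decreasing variance
            axis = eigvecs[:, axis_idx]
            skew = float(np.sum((centered @ axis) ** 3))
            if abs(skew) > 1e-9 * scale ** 1.5:
                direction = axis if skew > 0 else -axis
                break
        else:
            # fully symmetric cloud: lexicographic sign of the major axis
            axis = eigvecs[:, 2]
            for comp in axis:
                if abs(comp) > 1e-9:
                    direction = axis if comp > 0 else -axis
                    break
    return centroid + 3.0 * max(radius, 1.0) * direction


def estimate_normals(cloud: PointCloud, neighbor_k: int = 10,
                     viewpoint: np.ndarray | None = None) -> PointCloud:
    """Per-point unit normals from the neighborhood covariance.

    The normal is the eigenvector of the k-neighborhood covariance with the
    smallest eigenvalue, sign-flipped to face the viewpoint.
    """
    points = cloud.points
    n = len(points)
    if n < neighbor_k + 1:
        raise ValueError(
            f"need at least neighbor_k+1={neighbor_k + 1} points, got {n}"
        )
    if viewpoint is None:
        viewpoint = default_viewpoint(points)
    tree = cKDTree(points)
    _, idx = tree.query(points, k=neighbor_k + 1)
    normals = np.empty((n, 3))
    for i in range(n):
        nbrs = points[idx[i]]
        centered = nbrs - nbrs.mean(axis=0)
        cov = centered.T @ centered
        if np.allclose(cov, 0.0, atol=1e-12):
            warnings.warn(f"degenerate neighborhood at point {i}; normal set to +z")
            normals[i] = (0.0, 0.0, 1.0)
            continue
        eigvals, eigvecs = np.linalg.eigh(cov)
        normal = eigvecs[:, 0]
        facing = np.dot(normal, viewpoint - points[i])
        if abs(facing) > 1e-9:
            if facing < 0:
                normal = -normal
        else:
            # Viewpoint direction is ambiguous; orient by a deterministic
            # lexicographic sign rule so jittered inputs agree.
            for comp in normal:
                if abs(comp) > 1e-9:
                    if comp < 0:
                        normal = -normal
                    break
        normals[i] = normal / np.linalg.norm(normal)
    return PointCloud(points=points.copy(), normals=normals,
                      anchor_index=dict(cloud.anchor_index))


def pair_features(p1: np.ndarray, n1: np.ndarray,
                  p2: np.ndarray, n2: np.ndarray) -> tuple[float, float, float]:
    """The three Darboux-frame angle features (alpha, phi, theta) of a pair.

    Frame: u = n1, v = u x (p2-p1)/d (normalized), w = u x v; then
    alpha = v . n2, phi = u . (p2-p1)/d, theta = atan2(w . n2, u . n2).
    Invariant to common rigid motion of the pair.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    diff = p2 - p1
    dist = np.linalg.norm(diff)
    if dist < 1e-12:
        raise ValueError("coincident points have no pair features")
    du = diff / dist
    u = np.asarray(n1, dtype=float)
    v = np.cross(u, du)
    v_norm = np.linalg.norm(v)
    if v_norm < 1e-12:
        # u parallel to the connecting line; any perpendicular works — pick
        # a deterministic one.
        ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        v = np.cross(u, ref)
        v /= np.linalg.norm(v)
    else:
        v /= v_norm
    w = np.cross(u, v)
    n2 = np.asarray(n2, dtype=float)
    alpha = float(np.dot(v, n2))
    phi = float(np.dot(u, du))
    theta = float(np.arctan2(np.dot(w, n2), np.dot(u, n2)))
    return alpha, phi, theta


def _require_normals(cloud: PointCloud) -> None:
    if cloud.normals is None:
        raise ValueError("point cloud has no normals; run estimate_normals first")


def _snapped_bins(scaled: np.ndarray, bins: int, circular: bool) -> np.ndarray:
    """Floor to bin indices after snapping to 1e-9 of a bin width.

    Snapping makes values that sit exactly on a bin edge (up to numerical
    jitter) resolve to the same bin for bit-jittered copies of a cloud;
    circular features additionally wrap the +/-pi seam onto one bin.
    """
    idx = np.floor(np.round(scaled, 9)).astype(int)
    if circular:
        return idx % bins
    return np.clip(idx, 0, bins - 1)


def _feature_histogram(features: np.ndarray, bins: int) -> np.ndarray:
    """Concatenated (alpha, phi, theta) histograms, each block summing to 100."""
    out = np.zeros(3 * bins)
    ranges = ((-1.0, 1.0), (-1.0, 1.0), (-np.pi, np.pi))
    for f in range(3):
        lo, hi = ranges[f]
        vals = features[:, f]
        idx = _snapped_bins((vals - lo) / (hi - lo) * bins, bins,
                            circular=(f == 2))
        block = np.bincount(idx, minlength=bins).astype(float)
        total = block.sum()
        if total > 0:
            block *= 100.0 / total
        out[f * bins: (f + 1) * bins] = block
    return out


def _knn_indices(tree: cKDTree, points: np.ndarray, i: int, k: int):
    """The k nearest neighbors of point i (self excluded).

    Distance ties are broken by point index (distances snapped to 1e-9 A so
    exactly tied neighbors of jittered copies of a cloud resolve identically).
    """
    n = len(points)
    kk = min(k + 8, n)  # headroom so ties straddling the cutoff are visible
    dists, idx = tree.query(points[i], k=kk)
    dists, idx = np.atleast_1d(dists), np.atleast_1d(idx)
    mask = idx != i
    dists, idx = dists[mask], idx[mask]
    order = np.lexsort((idx, np.round(dists / 1e-9)))
    return idx[order][:k], dists[order][:k]


def spfh(cloud: PointCloud, query_index: int, neighbor_k: int = 10,
         bins_per_feature: int = 11, tree: cKDTree | None = None) -> np.ndarray:
    """Simplified point feature histogram of one query point (3*bins vector)."""
    _require_normals(cloud)
    points, normals = cloud.points, cloud.normals
    if tree is None:
        tree = cKDTree(points)
    idx, _ = _knn_indices(tree, points, query_index, neighbor_k)
    if len(idx) < neighbor_k:
        warnings.warn(
            f"only {len(idx)} neighbors available for k={neighbor_k}; using all"
        )
    feats = np.array([
        pair_features(points[query_index], normals[query_index],
                      points[j], normals[j])
        for j in idx
    ])
    return _feature_histogram(feats, bins_per_feature)


def fpfh(cloud: PointCloud, neighbor_k: int = 10, bins_per_feature: int = 11,
         anchors: np.ndarray | None = None, model_id: str = "") -> DescriptorSet:
    """Fast point feature histograms at the anchor points (all points by default)."""
    _require_normals(cloud)
    points = cloud.points
    n = len(points)
    tree = cKDTree(points)
    spfh_all = np.array([
        spfh(cloud, i, neighbor_k, bins_per_feature, tree=tree) for i in range(n)
    ])
    if anchors is None:
        anchors = np.arange(n)
    anchors = np.asarray(anchors, dtype=int)
    vectors = np.empty((len(anchors), 3 * bins_per_feature))
    for row, a in enumerate(anchors):
        idx, dists = _knn_indices(tree, points, int(a), neighbor_k)
        k = len(idx)
        weights = 1.0 / np.maximum(dists, 1e-12)
        vectors[row] = spfh_all[a] + (weights @ spfh_all[idx]) / k
    ds = DescriptorSet(model_id, "fpfh", vectors, anchors)
    ds.validate()
    return ds


def sc_point_weight(rho: float, bin_volume: float) -> float:
    """3DSC contribution of one in-support point: 1 / (rho * V^(1/3))."""
    return 1.0 / (rho * np.cbrt(bin_volume))


def _local_frame(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic orthonormal frame with z along the normal."""
    z = normal / np.linalg.norm(normal)
    ref = np.array([1.0, 0.0, 0.0]) if abs(z[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    x = ref - np.dot(ref, z) * z
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return x, y, z


def shape_context_3d(cloud: PointCloud, config: DescriptorConfig | None = None,
                     anchors: np.ndarray | None = None,
                     model_id: str = "") -> DescriptorSet:
    """3D shape context histograms at the anchor points.

    The support sphere around each anchor is oriented by its surface normal
    and divided into J azimuth x K elevation x R log-radial bins; each
    in-support point contributes 1/(rho * V^(1/3)).
    """
    config = config or DescriptorConfig()
    config.validate()
    _require_normals(cloud)
    points, normals = cloud.points, cloud.normals
    n = len(points)
    J, K, R = config.sc_bins
    r_max = config.support_radius
    r_min = config.sc_min_radius_fraction * r_max
    radial_edges = np.exp(np.linspace(np.log(r_min), np.log(r_max), R + 1))
    elev_edges = np.linspace(0.0, np.pi, K + 1)
    # Bin volumes: wedge of (2 pi / J) azimuth x elevation band x radial shell.
    shell = (radial_edges[1:] ** 3 - radial_edges[:-1] ** 3) / 3.0
    band = np.cos(elev_edges[:-1]) - np.cos(elev_edges[1:])
    volumes = (2.0 * np.pi / J) * band[:, None] * shell[None, :]  # (K, R)

    tree = cKDTree(points)
    density = np.array([len(tree.query_ball_point(p, config.sc_density_radius))
                        for p in points], dtype=float)  # includes the point itself

    if anchors is None:
        anchors = np.arange(n)
    anchors = np.asarray(anchors, dtype=int)
    vectors = np.zeros((len(anchors), J * K * R))
    for row, a in enumerate(anchors):
        nbrs = [j for j in tree.query_ball_point(points[a], r_max) if j != a]
        if not nbrs:
            warnings.warn(f"empty 3DSC support at anchor {a}")
            continue
        x_ax, y_ax, z_ax = _local_frame(normals[a])
        rel = points[nbrs] - points[a]
        xs = rel @ x_ax
        ys = rel @ y_ax
        zs = rel @ z_ax
        r = np.linalg.norm(rel, axis=1)
        azim = np.arctan2(ys, xs)  # (-pi, pi], circular
        j_bin = _snapped_bins((azim + np.pi) / (2 * np.pi) * J, J, circular=True)
        elev = np.arccos(np.clip(zs / np.maximum(r, 1e-12), -1.0, 1.0))
        k_bin = _snapped_bins(elev / np.pi * K, K, circular=False)
        # Points closer than the minimum radius are counted in the innermost shell.
        r_bin = np.clip(np.searchsorted(radial_edges, r, side="right") - 1, 0, R - 1)
        for t, j in enumerate(nbrs):
            flat = (j_bin[t] * K + k_bin[t]) * R + r_bin[t]
            vectors[row, flat] += sc_point_weight(density[j],
                                                  volumes[k_bin[t], r_bin[t]])
    ds = DescriptorSet(model_id, "sc3d", vectors, anchors)
    ds.validate()
    return ds


def rsd(cloud: PointCloud, config: DescriptorConfig | None = None,
        anchors: np.ndarray | None = None, model_id: str = "") -> DescriptorSet:
    """Radius-based surface descriptor: (r_min, r_max) of fitted spheres."""
    config = config or DescriptorConfig()
    config.validate()
    _require_normals(cloud)
    points, normals = cloud.points, cloud.normals
    n = len(points)
    tree = cKDTree(points)
    if anchors is None:
        anchors = np.arange(n)
    anchors = np.asarray(anchors, dtype=int)
    r_plane = config.rsd_plane_radius
    vectors = np.empty((len(anchors), 2))
    for row, a in enumerate(anchors):
        nbrs = [j for j in tree.query_ball_point(points[a], config.support_radius)
                if j != a]
        if not nbrs:
            warnings.warn(f"no RSD neighbors at anchor {a}; plane radius assumed")
            vectors[row] = (r_plane, r_plane)
            continue
        d = np.linalg.norm(points[nbrs] - points[a], axis=1)
        cos_a = np.clip(normals[nbrs] @ normals[a], -1.0, 1.0)
        alpha = np.arccos(cos_a)
        radii = np.empty(len(nbrs))
        small = alpha < config.rsd_taylor_angle
        # First-order Taylor of the chord relation for near-parallel normals.
        with np.errstate(divide="ignore"):
            radii[small] = np.where(alpha[small] > 1e-9,
                                    d[small] / np.maximum(alpha[small], 1e-9),
                                    np.inf)
        radii[~small] = d[~small] / np.sqrt(2.0 - 2.0 * cos_a[~small])
        radii = np.minimum(radii, r_plane)
        vectors[row] = (radii.min(), radii.max())
    ds = DescriptorSet(model_id, "rsd", vectors, anchors)
    ds.validate()
    return ds


def vfh(cloud: PointCloud, viewpoint: np.ndarray | None = None,
        bins_per_feature: int = 11, model_id: str = "") -> DescriptorSet:
    """Viewpoint feature histogram: one global vector for the whole cloud.

    Concatenation of (a) the SPFH of the centroid treating every point as a
    neighbor (centroid normal = renormalized mean of the point normals) and
    (b) the histogram of cosines between the viewpoint->centroid direction
    and each point normal.
    """
    _require_normals(cloud)
    points, normals = cloud.points, cloud.normals
    if len(points) < 2:
        raise ValueError("VFH needs at least 2 points")
    centroid = points.mean(axis=0)
    if viewpoint is None:
        viewpoint = default_viewpoint(points)
    viewpoint = np.asarray(viewpoint, dtype=float)
    if np.linalg.norm(viewpoint - centroid) < 1e-9:
        raise ValueError("viewpoint coincides with the centroid")
    mean_normal = normals.mean(axis=0)
    nn = np.linalg.norm(mean_normal)
    centroid_normal = mean_normal / nn if nn > 1e-12 else np.array([0.0, 0.0, 1.0])
    feats = []
    for p, nrm in zip(points, normals):
        if np.linalg.norm(p - centroid) < 1e-12:
            continue
        feats.append(pair_features(centroid, centroid_normal, p, nrm))
    shape_part = _feature_histogram(np.array(feats), bins_per_feature)
    view_dir = centroid - viewpoint
    view_dir /= np.linalg.norm(view_dir)
    cosines = normals @ view_dir
    idx = _snapped_bins((cosines + 1.0) / 2.0 * bins_per_feature,
                        bins_per_feature, circular=False)
    view_part = np.bincount(idx, minlength=bins_per_feature).astype(float)
    view_part *= 100.0 / view_part.sum()
    ds = DescriptorSet(model_id, "vfh",
                       np.concatenate([shape_part, view_part])[None, :],
                       anchor_points=None)
    ds.validate()
    return ds


def extract(cloud: PointCloud, descriptor_type: str,
            config: DescriptorConfig | None = None,
            anchors: np.ndarray | None = None,
            model_id: str = "") -> DescriptorSet:
    """Dispatch to one of the four descriptors (normals must be present)."""
    config = config or DescriptorConfig()
    if descriptor_type == "fpfh":
        return fpfh(cloud, config.neighbor_k, config.fpfh_bins_per_feature,
                    anchors, model_id)
    if descriptor_type == "sc3d":
        return shape_context_3d(cloud, config, anchors, model_id)
    if descriptor_type == "rsd":
        return rsd(cloud, config, anchors, model_id)
    if descriptor_type == "vfh":
        return vfh(cloud, config.viewpoint, config.fpfh_bins_per_feature, model_id)
    raise ValueError(f"unknown descriptor type {descriptor_type!r}")
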