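"""Surface features on the dense target cloud.

PCA normal estimation, exact kd-tree nearest-neighbour search with a
deterministic tie rule, distance-gated correspondence search, and spherical
ROI cropping.

Normal sign is left unoriented: every registration objective uses the
point-to-plane residual through ``|n . r|`` or its square, which is even in
the sign of ``n``.  ``orient_outward`` is a diagnostic/visualisation helper.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .errors import ParameterError
from .geometry import PointCloud, RigidTransform


@dataclass(frozen=True)
class NeighborhoodPCA:
    """Local plane fit of one k-neighbourhood (eigendecomposition of the
    neighbourhood covariance; eigenvalues ascending, v1 is the normal)."""

    centroid: np.ndarray       # mm
    covariance: np.ndarray     # 3x3, mm^2
    eigenvalues: np.ndarray    # ascending, mm^2
    eigenvectors: np.ndarray   # columns v1, v2, v3 (unit)

    @property
    def normal(self) -> np.ndarray:
        return self.eigenvectors[:, 0]


def neighborhood_pca(points) -> NeighborhoodPCA:
    """PCA of one explicit neighbourhood ``(k, 3)``; the covariance uses the
    1/k divisor with the centroid taken over the k points themselves."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise ParameterError("neighbourhood must be (k>=3, 3)")
    c = pts.mean(axis=0)
    X = pts - c
    C = X.T @ X / pts.shape[0]
    w, v = np.linalg.eigh(C)
    return NeighborhoodPCA(centroid=c, covariance=C, eigenvalues=w, eigenvectors=v)


def estimate_normals(cloud: PointCloud, k_neighbors: int = 30) -> PointCloud:
    """Attach PCA normals to every point of ``cloud``.

    Each point's normal is the unit eigenvector belonging to the smallest
    eigenvalue of the covariance of its k nearest neighbours (the query point
    counts as one of the k), i.e. the least-squares local plane normal.
    """
    if k_neighbors < 3:
        raise ParameterError(f"k_neighbors must be >= 3, got {k_neighbors}")
    n = len(cloud)
    if n < k_neighbors:
        raise ParameterError(f"cloud has {n} points, fewer than k_neighbors={k_neighbors}")
    tree = cKDTree(cloud.points)
    _, idx = tree.query(cloud.points, k=k_neighbors)
    nb = cloud.points[idx]                       # (n, k, 3)
    ctr = nb.mean(axis=1, keepdims=True)
    X = nb - ctr
    cov = np.einsum("nki,nkj->nij", X, X) / k_neighbors
    _, vecs = np.linalg.eigh(cov)                # ascending eigenvalues
    normals = vecs[:, :, 0]
    normals = normals / np.linalg.norm(normals, axis=1, keepdims=True)
    return PointCloud(cloud.points, normals)


def orient_outward(cloud: PointCloud, center: Optional[np.ndarray] = None) -> PointCloud:
    """Flip normals to point away from ``center`` (default: cloud centroid).
    Purely cosmetic; the registration objectives are sign-invariant."""
    if not cloud.has_normals:
        raise ValueError("cloud has no normals to orient")
    c = cloud.centroid() if center is None else np.asarray(center, dtype=float)
    out = cloud.points - c
    sign = np.where(np.einsum("ij,ij->i", cloud.normals, out) < 0, -1.0, 1.0)
    return PointCloud(cloud.points, cloud.normals * sign[:, None])


class SpatialIndex:
    """Exact nearest-neighbour index over a target cloud (kd-tree).

    Ties in nearest distance are broken toward the lowest target index so
    results are independent of target point ordering up to that rule.
    """

    def __init__(self, cloud: PointCloud):
        if len(cloud) == 0:
            raise ValueError("cannot index an empty cloud")
        self.cloud = cloud
        self._tree = cKDTree(cloud.points)

    def nearest(self, points) -> tuple[np.ndarray, np.ndarray]:
        """Exact nearest neighbour of each query: ``(distances, indices)``."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d, i = self._tree.query(pts)
        # enforce the lowest-index tie rule (exact distance equality only)
        for q in range(pts.shape[0]):
            cands = self._tree.query_ball_point(pts[q], d[q] * (1 + 1e-12) + 1e-300)
            if len(cands) > 1:
                dd = np.linalg.norm(self.cloud.points[cands] - pts[q], axis=1)
                exact = [c for c, dc in zip(cands, dd) if dc == d[q]]
                if exact:
                    i[q] = min(exact)
        return d, i


def build_spatial_index(cloud: PointCloud) -> SpatialIndex:
    return SpatialIndex(cloud)


@dataclass(frozen=True)
class CorrespondenceSet:
    """Gated source/target/normal triples feeding one linearized solve.

    ``source_points`` are stored in the pose they had when matched; use
    :meth:`transformed` to express them in an updated pose without changing
    the matches.
    """

    source_points: np.ndarray    # (N, 3) mm, current pose
    target_points: np.ndarray    # (N, 3) mm
    target_normals: np.ndarray   # (N, 3) unit
    distances: np.ndarray        # (N,) mm
    kept: np.ndarray             # (N,) bool, d <= d_max
    source_indices: np.ndarray   # (N,) into the original source cloud
    target_indices: np.ndarray   # (N,) into the target cloud

    def __post_init__(self):
        n = self.source_points.shape[0]
        for name in ("target_points", "target_normals", "distances", "kept",
                     "source_indices", "target_indices"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} length mismatch")

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())

    def kept_arrays(self):
        """(x, y, n) restricted to kept pairs."""
        m = self.kept
        return self.source_points[m], self.target_points[m], self.target_normals[m]

    def kept_subset(self) -> "CorrespondenceSet":
        m = self.kept
        return CorrespondenceSet(
            self.source_points[m], self.target_points[m], self.target_normals[m],
            self.distances[m], np.ones(int(m.sum()), dtype=bool),
            self.source_indices[m], self.target_indices[m],
        )

    def transformed(self, t: RigidTransform) -> "CorrespondenceSet":
        """Move the source side through ``t``; matches/gating unchanged."""
        return CorrespondenceSet(
            t.apply(self.source_points), self.target_points, self.target_normals,
            self.distances, self.kept, self.source_indices, self.target_indices,
        )


def find_correspondences(source: PointCloud, index: SpatialIndex,
                         d_max: float) -> CorrespondenceSet:
    """One nearest-target candidate per source point, gated at ``d_max`` (mm)."""
    if not index.cloud.has_normals:
        raise ValueError(
            "target cloud carries no normals; run estimate_normals on it first"
        )
    d, i = index.nearest(source.points)
    return CorrespondenceSet(
        source_points=np.array(source.points),
        target_points=index.cloud.points[i],
        target_normals=index.cloud.normals[i],
        distances=d,
        kept=d <= d_max,
        source_indices=np.arange(len(source)),
        target_indices=i,
    )


def crop_roi(target: PointCloud, center, radius: float) -> PointCloud:
    """Subset of ``target`` within ``radius`` (mm) of ``center``; normals carried."""
    if radius <= 0:
        raise ParameterError(f"radius must be > 0, got {radius}")
    c = np.asarray(center, dtype=float)
    mask = np.linalg.norm(target.points - c, axis=1) <= radius
    if not mask.any():
        warnings.warn("ROI crop produced an empty cloud", stacklevel=2)
    normals = target.normals[mask] if target.has_normals else None
    return PointCloud(target.points[mask], normals)


def default_roi(target: PointCloud, source: PointCloud,
                coarse: RigidTransform, radius_factor: float = 1.5) -> PointCloud:
    """Default ROI rule: sphere at the coarse-transformed source centroid with
    radius ``radius_factor`` x the source bounding-sphere radius."""
    center = coarse.apply(source.centroid())
    return crop_roi(target, center, radius_factor * source.bounding_radius())
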