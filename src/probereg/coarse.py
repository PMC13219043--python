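"""Paired-landmark rigid alignment (the three-point coarse registration).

Given N >= 3 paired landmarks, the least-squares rotation comes from the SVD
of the cross-covariance H = sum (p_src - c_src)(p_tgt - c_tgt)^T with the
standard reflection guard R = V diag(1, 1, det(V U^T)) U^T, and the
translation is T = -R c_src + c_tgt.  Solves source (patient/tracker frame)
-> target (CT frame).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, InsufficientLandmarksError
from .geometry import RigidTransform

#: Relative singular-value threshold below which landmarks count as collinear.
COLLINEARITY_RTOL = 1e-9


@dataclass(frozen=True)
class CoarseSolution:
    """Result of the landmark alignment plus condition diagnostics."""

    transform: RigidTransform
    H: np.ndarray                 # 3x3 cross-covariance (mm^2)
    centroid_source: np.ndarray   # mm
    centroid_target: np.ndarray   # mm
    rms_residual: float           # mm
    singular_values: np.ndarray   # of H, descending (mm^2)
    collinear: bool

    @property
    def smallest_singular_value(self) -> float:
        return float(self.singular_values[-1])


def _paired_arrays(source, target):
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.ndim != 2 or src.shape[1] != 3 or src.shape != tgt.shape:
        raise ValueError("source and target must be congruent (N, 3) arrays")
    return src, tgt


def kabsch_align(source, target) -> CoarseSolution:
    """Best-fit rigid transform mapping paired ``source`` points onto ``target``.

    Raises
    ------
    InsufficientLandmarksError
        if fewer than 3 pairs are given.
    DegenerateGeometryError
        if the landmarks are collinear/coincident (the rotation is then not
        unique).  Note any 3 points are coplanar, so the test is on the
        *middle* singular value of H; the smallest one vanishes for every
        minimal 3-point problem and is reported as a diagnostic only.
    """
    src, tgt = _paired_arrays(source, target)
    n = src.shape[0]
    if n < 3:
        raise InsufficientLandmarksError(f"need >= 3 landmark pairs, got {n}")

    c_src = src.mean(axis=0)
    c_tgt = tgt.mean(axis=0)
    H = (src - c_src).T @ (tgt - c_tgt)
    # H above is sum_i (p_src - c)(p_tgt - c)^T; SVD convention H = U S V^T.
    U, S, Vt = np.linalg.svd(H)
    V = Vt.T
    if S[1] <= COLLINEARITY_RTOL * max(S[0], np.finfo(float).tiny):
        raise DegenerateGeometryError(
            "landmarks are collinear or coincident: middle singular value of H is "
            f"{S[1]:.3e} (largest {S[0]:.3e})"
        )
    d = np.linalg.det(V @ U.T)
    R = V @ np.diag([1.0, 1.0, d]) @ U.T
    T = -R @ c_src + c_tgt
    transform = RigidTransform(R, T)
    rms = landmark_fre(src, tgt, transform)
    return CoarseSolution(
        transform=transform,
        H=H,
        centroid_source=c_src,
        centroid_target=c_tgt,
        rms_residual=rms,
        singular_values=S,
        collinear=False,
    )


def landmark_fre(source, target, transform: RigidTransform) -> float:
    """Root-mean-square landmark residual ``||R p_src + T - p_tgt||`` (mm)."""
    src, tgt = _paired_arrays(source, target)
    d = transform.apply(src) - tgt
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))
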