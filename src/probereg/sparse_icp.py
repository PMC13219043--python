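"""Fine registration: sparse point-to-plane ICP solved with ADMM.

The objective is the Lp sparsity-inducing point-to-plane loss

    E(R, T) = sum_i | n_i . (R x_i + T - y_i) |^p ,   0 < p < 1,

over distance-gated nearest-neighbour correspondences (x_i, y_i, n_i).
Residuals of outlier correspondences (probe slips, cartilage stand-off)
contribute almost nothing to the Lp loss, so they are effectively
down-weighted without an explicit rejection heuristic.

The non-convex problem is split with an auxiliary per-pair residual
z_i = n_i.(R x_i + T - y_i) and solved by ADMM with fixed penalty mu:

  (a) proximal step  z_i <- argmin_z |z|^p + (mu/2)(z - e~_i)^2,
      e~_i = n_i.(R x_i + T - y_i) + lambda_i / mu   (hard thresholding);
  (b) pose step: damped least squares on the small-angle linearization
      r_i = n_i.(x_i - y_i) + n_i.dt + n_i.(omega x x_i) - z_i,
      i.e. rows A_i = [(x_i x n_i)^T, n_i^T], b_i = z_i - n_i.(x_i - y_i),
      followed by the left-composed update R <- exp([omega]x) R;
  (c) dual ascent  lambda_i <- lambda_i + mu (n_i.(R x_i + T - y_i) - z_i).

The ADMM cycles alternate with correspondence search until the pose
increment or the change in the sparse objective falls below tolerance.
Point-to-point and plain point-to-plane baselines share the same outer
loop, gating and stopping rules, for clean ablation comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .coarse import kabsch_align
from .errors import DegenerateGeometryError, LostRegistrationError, ParameterError
from .geometry import (PointCloud, RigidTransform, RotationIncrement,
                       apply_transform, compose, exp_so3, rotation_angle)
from .surface import (CorrespondenceSet, SpatialIndex, build_spatial_index,
                      find_correspondences)

# ---------------------------------------------------------------------------
# parameters and state
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SparseICPParams:
    """Tunable parameters of the fine registration.

    Defaults follow the method's published operating point: p = 0.5,
    mu = 1.0 (fixed during optimisation), d_max = 5.0 mm, k_max = 100,
    pose tolerances 0.01 mm / 0.01 deg, objective tolerance 1e-6, and
    k_neighbors = 30 for PCA normal estimation.
    """

    p: float = 0.5               # sparsity exponent, 0 < p < 1
    mu: float = 1.0              # ADMM penalty
    d_max: float = 5.0           # correspondence gate (mm)
    k_max: int = 100             # outer iteration cap
    trans_tol: float = 0.01      # mm
    rot_tol: float = 0.01        # degrees
    obj_tol: float = 1e-6        # |E(k) - E(k-1)| stop
    inner_iters: int = 5         # ADMM cycles per correspondence update
    lm_damping: float = 1e-9     # Tikhonov damping on A^T A
    step_cap: float = 0.1        # max ||omega|| per update (rad)
    k_neighbors: int = 30        # PCA normal neighbourhood size

    def __post_init__(self):
        if not 0.0 < self.p < 1.0:
            raise ParameterError(f"p must satisfy 0 < p < 1, got {self.p}")
        if self.mu <= 0:
            raise ParameterError(f"mu must be > 0, got {self.mu}")
        for name in ("d_max", "trans_tol", "rot_tol", "obj_tol", "step_cap"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.k_max < 1 or self.inner_iters < 1:
            raise ParameterError("k_max and inner_iters must be >= 1")
        if self.lm_damping < 0:
            raise ParameterError("lm_damping must be >= 0")
        if self.k_neighbors < 3:
            raise ParameterError("k_neighbors must be >= 3")


@dataclass
class ADMMState:
    """Per-pair auxiliary residuals and duals of the sparse inner loop."""

    z: np.ndarray          # auxiliary residuals (mm)
    lam: np.ndarray        # Lagrange multipliers (mm)
    mu: float
    p: float
    e_tilde: np.ndarray = field(default=None)  # shifted residuals n.r + lam/mu
    delta: np.ndarray = field(default=None)    # constraint residuals n.r - z

    @classmethod
    def zeros(cls, n: int, params: SparseICPParams) -> "ADMMState":
        return cls(z=np.zeros(n), lam=np.zeros(n), mu=params.mu, p=params.p,
                   e_tilde=np.zeros(n), delta=np.zeros(n))


@dataclass(frozen=True)
class LinearizedSystem:
    """Stacked small-angle point-to-plane system ``A xi ~ b``, xi = [omega, dt]."""

    A: np.ndarray   # (N, 6)
    b: np.ndarray   # (N,)


@dataclass
class IterationTrace:
    """Per-outer-iteration record of one fine-registration run."""

    objective: list = field(default_factory=list)       # E(k)
    n_kept: list = field(default_factory=list)
    dt_norm: list = field(default_factory=list)         # mm
    dtheta_deg: list = field(default_factory=list)
    inner_iterations: list = field(default_factory=list)
    termination_reason: str = "max_iters"

    @property
    def n_iterations(self) -> int:
        return len(self.objective)

    def to_dict(self) -> dict:
        return {
            "objective": [float(v) for v in self.objective],
            "n_kept": [int(v) for v in self.n_kept],
            "dt_norm_mm": [float(v) for v in self.dt_norm],
            "dtheta_deg": [float(v) for v in self.dtheta_deg],
            "inner_iterations": [int(v) for v in self.inner_iterations],
            "termination_reason": self.termination_reason,
        }


# ---------------------------------------------------------------------------
# proximal operator of the Lp penalty
# ---------------------------------------------------------------------------

def prox_lp(e_tilde, mu: float, p: float):
    """Global minimiser of ``f(z) = |z|^p + (mu/2)(z - e_tilde)^2``.

    Hard-thresholding operator: z = 0 whenever |e_tilde| falls below the
    threshold at which the non-zero stationary branch stops existing or
    stops winning; above it, z has the sign of e_tilde and |z| < |e_tilde|.
    Exact ties at the threshold resolve to z = 0 (the sparser solution).
    Accepts scalars or arrays (elementwise).
    """
    if not (0.0 < p < 1.0):
        raise ParameterError(f"p must satisfy 0 < p < 1, got {p}")
    if mu <= 0:
        raise ParameterError(f"mu must be > 0, got {mu}")
    e = np.asarray(e_tilde, dtype=float)
    scalar = e.ndim == 0
    e = np.atleast_1d(e)
    a = np.abs(e)
    z = np.zeros_like(a)

    # smallest |e| for which the stationary equation t + (p/mu) t^(p-1) = |e|
    # has a real root: the minimum of the left side over t > 0
    t_knee = (p * (1.0 - p) / mu) ** (1.0 / (2.0 - p))
    e_exist = t_knee + (p / mu) * t_knee ** (p - 1.0)
    cand = a > e_exist
    if np.any(cand):
        ac = a[cand]
        # threshold-iteration: fixed point t <- |e| - (p/mu) t^(p-1), started at
        # |e|; converges to the larger (locally minimal) stationary branch
        t = ac.copy()
        for _ in range(200):
            t_new = ac - (p / mu) * t ** (p - 1.0)
            if np.all(np.abs(t_new - t) < 1e-14 * np.maximum(1.0, ac)):
                t = t_new
                break
            t = t_new
        # keep the non-zero branch only where it strictly beats z = 0
        f_t = t ** p + 0.5 * mu * (t - ac) ** 2
        f_0 = 0.5 * mu * ac ** 2
        win = f_t < f_0
        zc = np.where(win, t, 0.0)
        z[cand] = np.sign(e[cand]) * zc
    return float(z[0]) if scalar else z


# ---------------------------------------------------------------------------
# objective, linearization, pose solve
# ---------------------------------------------------------------------------

def _plane_residuals(corrs: CorrespondenceSet, transform: RigidTransform) -> np.ndarray:
    """Point-to-plane residuals n_i.(R x_i + T - y_i) over kept pairs."""
    x, y, n = corrs.kept_arrays()
    return np.einsum("ij,ij->i", n, transform.apply(x) - y)


def objective_value(corrs: CorrespondenceSet, transform: RigidTransform,
                    p: float) -> float:
    """Sparse objective E = sum_kept |n_i.(R x_i + T - y_i)|^p."""
    if corrs.n_kept == 0:
        raise LostRegistrationError("no kept correspondences to evaluate")
    r = _plane_residuals(corrs, transform)
    return float(np.sum(np.abs(r) ** p))


def build_linear_system(corrs: CorrespondenceSet, z) -> LinearizedSystem:
    """Stack the small-angle rows over kept pairs, with x_i in the current pose:
    ``A_i = [(x_i x n_i)^T, n_i^T]``, ``b_i = z_i - n_i.(x_i - y_i)``."""
    x, y, n = corrs.kept_arrays()
    if x.shape[0] == 0:
        raise LostRegistrationError("no kept correspondences to linearize")
    z = np.asarray(z, dtype=float)
    if z.shape != (x.shape[0],):
        raise ValueError("z must be congruent with the kept-pair count")
    A = np.hstack([np.cross(x, n), n])
    b = z - np.einsum("ij,ij->i", n, x - y)
    return LinearizedSystem(A=A, b=b)


def solve_increment(system: LinearizedSystem, lm_damping: float = 1e-9,
                    step_cap: float = 0.1) -> RotationIncrement:
    """Damped normal-equations solve ``(A^T A + damping I) xi = A^T b``.

    The rotation step is kept within ``step_cap`` rad (the small-angle trust
    region) Levenberg-Marquardt style: if the solution overshoots the cap the
    damping is escalated on the diagonal scale of A^T A, which suppresses
    excursions along weakly constrained pose modes without corrupting the
    well-constrained ones.  A final rescale enforces the cap exactly.
    """
    A, b = system.A, system.b
    AtA = A.T @ A
    Atb = A.T @ b
    if np.linalg.cond(AtA + lm_damping * np.eye(6)) > 1e12:
        raise DegenerateGeometryError(
            "normal equations are rank-deficient beyond damping rescue "
            "(correspondence geometry does not constrain all 6 DOF)"
        )
    scale = np.diag(np.maximum(np.diag(AtA), 1e-12))
    lam = max(lm_damping, 1e-12)
    xi = np.linalg.solve(AtA + lam * scale, Atb)
    for _ in range(40):
        if np.linalg.norm(xi[:3]) <= step_cap:
            break
        lam *= 10.0
        xi = np.linalg.solve(AtA + lam * scale, Atb)
    w = np.linalg.norm(xi[:3])
    if w > step_cap:
        xi = xi * (step_cap / w)
    return RotationIncrement(omega=xi[:3], dt=xi[3:])


# ---------------------------------------------------------------------------
# inner ADMM loop
# ---------------------------------------------------------------------------

def admm_inner_loop(corrs: CorrespondenceSet, state: ADMMState,
                    pose: RigidTransform, params: SparseICPParams
                    ) -> tuple[RigidTransform, ADMMState]:
    """Run ``inner_iters`` ADMM cycles with fixed correspondences.

    ``pose`` is the incremental transform applied on top of the pose at which
    ``corrs`` was matched (identity on entry from the outer loop).
    """
    kept = corrs.kept_subset()
    z, lam = state.z.copy(), state.lam.copy()
    mu, p = params.mu, params.p
    for _ in range(params.inner_iters):
        cur = kept.transformed(pose)
        r = _plane_residuals(cur, RigidTransform.identity())
        e_tilde = r + lam / mu
        z = prox_lp(e_tilde, mu, p)
        system = build_linear_system(cur, z)
        inc = solve_increment(system, params.lm_damping, params.step_cap)
        pose = compose(inc.as_transform(), pose)
        cur = kept.transformed(pose)
        r = _plane_residuals(cur, RigidTransform.identity())
        delta = r - z
        lam = lam + mu * delta
    new_state = ADMMState(z=z, lam=lam, mu=mu, p=p,
                          e_tilde=r + lam / mu, delta=delta)
    return pose, new_state


# ---------------------------------------------------------------------------
# outer loops
# ---------------------------------------------------------------------------

def _require_target_normals(target: PointCloud):
    if not target.has_normals:
        raise ValueError("target cloud must carry normals (run estimate_normals)")


def _check_lost(corrs: CorrespondenceSet, params: SparseICPParams):
    if corrs.n_kept == 0:
        raise LostRegistrationError(
            f"all correspondences exceed d_max={params.d_max} mm; increase d_max "
            "or provide a better initial transform"
        )


def _support_key(corrs: CorrespondenceSet):
    m = corrs.kept
    return (corrs.source_indices[m].tobytes(), corrs.target_indices[m].tobytes())


def sparse_icp_register(source: PointCloud, target: PointCloud,
                        init: RigidTransform, params: SparseICPParams = SparseICPParams(),
                        ) -> tuple[RigidTransform, IterationTrace]:
    """Full sparse point-to-plane registration.

    Parameters
    ----------
    source : sparse probe cloud in the patient/tracker frame.
    target : dense CT-surface cloud with normals.
    init : starting pose (typically the coarse landmark solution).

    Returns the **total** transform source-frame -> target-frame (the fine
    correction composed onto ``init``) and the full iteration trace.
    """
    _require_target_normals(target)
    index = build_spatial_index(target)
    pose = init
    trace = IterationTrace()
    prev_E: Optional[float] = None
    prev_support = None

    for _ in range(params.k_max):
        src_cur = apply_transform(pose, source)
        corrs = find_correspondences(src_cur, index, params.d_max)
        _check_lost(corrs, params)
        # fresh auxiliaries/duals per correspondence set: the ADMM splitting is
        # only meaningful for a fixed set of constraints z_i = n_i.r_i, and
        # carrying duals across re-matching destabilises the alternation
        state = ADMMState.zeros(corrs.n_kept, params)
        inc, state = admm_inner_loop(corrs, state, RigidTransform.identity(), params)
        pose = compose(inc, pose)

        E = objective_value(corrs, inc, params.p)
        dt = float(np.linalg.norm(inc.T))
        dtheta = np.degrees(rotation_angle(inc.R))
        trace.objective.append(E)
        trace.n_kept.append(corrs.n_kept)
        trace.dt_norm.append(dt)
        trace.dtheta_deg.append(dtheta)
        trace.inner_iterations.append(params.inner_iters)

        if dt < params.trans_tol and dtheta < params.rot_tol:
            trace.termination_reason = "pose_tol"
            break
        support = _support_key(corrs)
        if (prev_E is not None and support == prev_support
                and abs(E - prev_E) < params.obj_tol):
            trace.termination_reason = "obj_tol"
            break
        prev_E, prev_support = E, support
    else:
        trace.termination_reason = "max_iters"
    return pose, trace


def icp_point_to_plane(source: PointCloud, target: PointCloud,
                       init: RigidTransform, params: SparseICPParams = SparseICPParams(),
                       ) -> tuple[RigidTransform, IterationTrace]:
    """Plain point-to-plane ICP (quadratic loss; the sparse z/lambda machinery
    disabled, i.e. z = 0 identically): one damped least-squares step per
    correspondence update, the standard formulation.  Shares gating and
    stopping rules with :func:`sparse_icp_register`; trace objective is
    sum (n.r)^2."""
    _require_target_normals(target)
    index = build_spatial_index(target)
    pose = init
    trace = IterationTrace()
    prev_E: Optional[float] = None
    prev_support = None
    for _ in range(params.k_max):
        src_cur = apply_transform(pose, source)
        corrs = find_correspondences(src_cur, index, params.d_max)
        _check_lost(corrs, params)
        kept = corrs.kept_subset()
        system = build_linear_system(kept, np.zeros(kept.n_kept))
        step = solve_increment(system, params.lm_damping, params.step_cap)
        inc_pose = step.as_transform()
        pose = compose(inc_pose, pose)
        r = _plane_residuals(kept, inc_pose)
        E = float(np.sum(r * r))
        dt = float(np.linalg.norm(inc_pose.T))
        dtheta = np.degrees(rotation_angle(inc_pose.R))
        trace.objective.append(E)
        trace.n_kept.append(corrs.n_kept)
        trace.dt_norm.append(dt)
        trace.dtheta_deg.append(dtheta)
        trace.inner_iterations.append(1)
        if dt < params.trans_tol and dtheta < params.rot_tol:
            trace.termination_reason = "pose_tol"
            break
        support = _support_key(corrs)
        if (prev_E is not None and support == prev_support
                and abs(E - prev_E) < params.obj_tol):
            trace.termination_reason = "obj_tol"
            break
        prev_E, prev_support = E, support
    else:
        trace.termination_reason = "max_iters"
    return pose, trace


def icp_point_to_point(source: PointCloud, target: PointCloud,
                       init: RigidTransform, params: SparseICPParams = SparseICPParams(),
                       ) -> tuple[RigidTransform, IterationTrace]:
    """Classic point-to-point ICP: same gated nearest-neighbour matching, the
    per-iteration pose update is the closed-form SVD alignment of the matched
    pairs.  Trace objective is the mean squared point-to-point distance."""
    _require_target_normals(target)   # protocol parity: same preprocessed target
    index = build_spatial_index(target)
    pose = init
    trace = IterationTrace()
    prev_E: Optional[float] = None
    prev_support = None
    for _ in range(params.k_max):
        src_cur = apply_transform(pose, source)
        corrs = find_correspondences(src_cur, index, params.d_max)
        _check_lost(corrs, params)
        x, y, _ = corrs.kept_arrays()
        sol = kabsch_align(x, y)
        inc = sol.transform
        pose = compose(inc, pose)
        d = inc.apply(x) - y
        E = float(np.mean(np.sum(d * d, axis=1)))
        dt = float(np.linalg.norm(inc.T))
        dtheta = np.degrees(rotation_angle(inc.R))
        trace.objective.append(E)
        trace.n_kept.append(corrs.n_kept)
        trace.dt_norm.append(dt)
        trace.dtheta_deg.append(dtheta)
        trace.inner_iterations.append(1)
        if dt < params.trans_tol and dtheta < params.rot_tol:
            trace.termination_reason = "pose_tol"
            break
        support = _support_key(corrs)
        if (prev_E is not None and support == prev_support
                and abs(E - prev_E) < params.obj_tol):
            trace.termination_reason = "obj_tol"
            break
        prev_E, prev_support = E, support
    else:
        trace.termination_reason = "max_iters"
    return pose, trace


#: Registry of fine-registration methods sharing one call signature.
FINE_METHODS: dict[str, Callable] = {
    "sparse_p2pl": sparse_icp_register,
    "p2pl": icp_point_to_plane,
    "p2pt": icp_point_to_point,
}
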