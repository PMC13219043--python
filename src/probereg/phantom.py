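"""Synthetic bone-phantom generator.

Emulates the physical validation setup: a bone-like surface (acetabulum-like
cup or femur-like ball+shaft), a dense CT-frame surface point cloud, fixture
fiducials off the bone surface, a known ground-truth rigid transform between
the patient (tracker) frame and the CT frame, sparse noisy probe samples
restricted to a surgically accessible region, cartilage-like one-sided
outliers, and noisy coarse-registration landmarks.

Shape note: an ideal hemispherical shell or sphere+cylinder is a surface of
revolution, so rotation about its symmetry axis would be unidentifiable and
no surface-based registration could pin it down.  Real bone is not a surface
of revolution; the generated shapes therefore carry anatomically motivated
symmetry-breaking features — the cup gets a sinusoidally varying rim height,
three oblique flat facets on its outer wall and a low-order radial relief
("bone texture"); the femur head gets an oblique resection-plane cut, a
fovea-like flat pit off the cut axis, and the same relief.  Planar features
have zero surface-curvature bias under point-to-plane matching against a
sampled cloud; the relief gives the smooth sphere-like regions tangential
stiffness so the pose cannot slide along them for free.

All randomness flows from the single config seed through a fixed
``numpy.random.SeedSequence.spawn`` order (ground truth, dense sampling,
probe strata, probe noise, outliers, landmarks, fiducials), so two runs with
equal configs are bit-identical and changing e.g. ``n_probe`` does not change
the ground-truth transform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import trimesh
from scipy.spatial.transform import Rotation
from trimesh.proximity import closest_point_naive

from .errors import ParameterError
from .geometry import PointCloud, RigidTransform, compose, exp_so3, invert

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))

# Cup feature defaults.  The rim-height wave amplitude stays below half the
# 5 mm correspondence gate so rim points are never gated out under azimuth
# error (long-range alignment signal); the flat facets sit clear of the rim
# band so their boundary creases stay away from probe-accessible regions.
CUP_RIM_WAVE_DEG = 5.0
CUP_FACET_DEPTH = 3.0
CUP_FACET_POLAR_DEG = 118.0

# Bone-like surface texture on the cup's outer wall: a fixed low-order radial
# undulation (amplitude mm, azimuthal/polar harmonic orders).  Real bone is
# not a smooth sphere; without tangential relief a sphere-dominated patch
# leaves point-to-plane registration free to slide, and correspondence
# outliers then drag the pose at no inlier cost.  Wavelengths (~12-15 mm)
# stay an order of magnitude above the k=30 PCA neighbourhood so normal
# estimation is unaffected; local curvature radius stays above ~10 mm.
CUP_TEXTURE_AMP = 0.5
_CUP_TEXTURE_WAVES = ((8, 5, 0.9, 0.4), (5, 7, 2.7, 1.8), (11, 4, 4.2, 3.1))


def _cup_texture(theta, phi, amplitude: float) -> np.ndarray:
    """Radial relief field (mm) for outer-wall vertices at (theta, phi)."""
    f = np.zeros_like(theta + phi)
    for m, l, a0, b0 in _CUP_TEXTURE_WAVES:
        f = f + np.sin(m * phi + a0) * np.sin(l * theta + b0)
    return amplitude * f / len(_CUP_TEXTURE_WAVES)

SHAPES = ("cup", "ball_shaft")


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for one synthetic phantom trial.

    Defaults: ~30 probe points, 4 fixture fiducials, 0.2 mm isotropic probe
    noise, no outliers unless asked, 2.0 mm landmark noise, ground-truth pose
    drawn from +/-30 deg per axis and +/-50 mm per axis, and a 60 deg
    accessible patch.
    """

    shape: str = "cup"
    dense_n: int = 50_000
    n_probe: int = 30
    n_fiducials: int = 4
    probe_noise_sigma: float = 0.2          # mm
    outlier_fraction: float = 0.0           # in [0, 1)
    outlier_offset_range: tuple = (2.0, 5.0)   # mm
    landmark_noise_sigma: float = 2.0       # mm
    gt_rotation_range: tuple = (-30.0, 30.0)   # degrees, per axis
    gt_translation_range: tuple = (-50.0, 50.0)  # mm, per axis
    roi_cap_angle: float = 60.0             # degrees
    seed: int = 0
    size_params: Optional[dict] = None      # overrides for make_bone_mesh

    def __post_init__(self):
        if self.shape not in SHAPES:
            raise ParameterError(f"shape must be one of {SHAPES}, got {self.shape!r}")
        if self.dense_n < 1:
            raise ParameterError("dense_n must be >= 1")
        if self.n_probe < 3:
            raise ParameterError("n_probe must be >= 3")
        if self.n_fiducials < 3:
            raise ParameterError("n_fiducials must be >= 3")
        if self.probe_noise_sigma < 0 or self.landmark_noise_sigma < 0:
            raise ParameterError("noise sigmas must be >= 0")
        if not 0.0 <= self.outlier_fraction < 1.0:
            raise ParameterError("outlier_fraction must lie in [0, 1)")
        lo, hi = self.outlier_offset_range
        if not (0 <= lo <= hi):
            raise ParameterError("outlier_offset_range must be a valid mm interval")
        for rng_ in (self.gt_rotation_range, self.gt_translation_range):
            if not (np.isfinite(rng_).all() and rng_[0] <= rng_[1]):
                raise ParameterError("ground-truth ranges must be finite intervals")
        if self.roi_cap_angle < 1.0:
            raise ParameterError(
                "roi_cap_angle too small to hold distinct probe strata; "
                "use a larger accessible patch"
            )


@dataclass(frozen=True)
class SyntheticPhantom:
    """One generated trial: geometry, ground truth and simulated measurements."""

    config: PhantomConfig
    mesh: trimesh.Trimesh                 # CT frame
    target_cloud: PointCloud              # CT frame, mm (no normals attached)
    gt_transform: RigidTransform          # patient -> CT
    fiducials_ct: np.ndarray              # (m, 3) mm, noise-free reference
    fiducials_patient: np.ndarray         # (m, 3) mm, = gt^-1(fiducials_ct)
    probe_points: np.ndarray              # (n_probe, 3) patient frame, noisy
    truth_feet: np.ndarray                # (n_probe, 3) CT frame, exact surface feet
    truth_faces: np.ndarray               # (n_probe,) mesh face of each foot
    landmark_names: tuple
    landmarks_patient: np.ndarray         # (>=3, 3), noisy
    landmarks_ct: np.ndarray              # (>=3, 3), exact
    outlier_indices: np.ndarray           # displaced probe points
    outlier_offsets: np.ndarray           # mm, along the outward normal

    @property
    def probe_cloud(self) -> PointCloud:
        return PointCloud(self.probe_points)


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

def _sph_dir(theta, phi):
    """Unit direction(s) at polar angle theta (from +z) and azimuth phi."""
    st = np.sin(theta)
    return np.stack([st * np.cos(phi), st * np.sin(phi),
                     np.cos(theta) * np.ones_like(phi * theta)], axis=-1)


def _grid_mesh(start_pole, rows, end_pole):
    """Watertight mesh from a (K, n_phi, 3) ring grid walked pole-to-pole.

    Winding convention: quads follow (row, phi) orientation so that walking
    the grid along the surface from start to end pole with phi increasing CCW
    yields solid-outward normals for every shape built here.
    """
    K, n_phi, _ = rows.shape
    verts = np.vstack([np.asarray(start_pole)[None, :],
                       rows.reshape(-1, 3),
                       np.asarray(end_pole)[None, :]])
    vid = lambda i, j: 1 + i * n_phi + (j % n_phi)  # noqa: E731
    faces = []
    for j in range(n_phi):
        faces.append([0, vid(0, j), vid(0, j + 1)])          # start fan
    for i in range(K - 1):
        for j in range(n_phi):
            a, b = vid(i, j), vid(i + 1, j)
            c, d = vid(i + 1, j + 1), vid(i, j + 1)
            faces.append([a, b, c])
            faces.append([a, c, d])
    last = len(verts) - 1
    for j in range(n_phi):
        faces.append([vid(K - 1, j), last, vid(K - 1, j + 1)])  # end fan
    return verts, np.asarray(faces, dtype=int)


def _rim_polar(phi, rim_wave: float) -> np.ndarray:
    """Cup rim polar angle (radians from +z) as a function of azimuth: the rim
    rises from the equator by up to ``rim_wave`` on one side."""
    return np.pi / 2.0 - rim_wave * 0.5 * (1.0 + np.sin(phi))


def _clamp_to_planes(verts: np.ndarray, plane_dirs, offset: float) -> np.ndarray:
    """Project vertices beyond each plane ``v.u > offset`` back onto it,
    creating flat facets while preserving watertightness."""
    v = verts.copy()
    for u in plane_dirs:
        s = v @ u - offset
        mask = s > 0
        v[mask] -= s[mask, None] * u[None, :]
    return v


def _make_cup(outer_radius: float = 27.0, thickness: float = 6.0,
              rim_wave_deg: float = CUP_RIM_WAVE_DEG, facet_depth: float = CUP_FACET_DEPTH,
              facet_polar_deg: float = CUP_FACET_POLAR_DEG, n_facets: int = 3,
              texture_amp: float = CUP_TEXTURE_AMP,
              n_phi: int = 128, n_inner: int = 20, n_outer: int = 30,
              ) -> trimesh.Trimesh:
    """Acetabulum-like shell.  The 6 mm wall leaves the rim strip wide enough
    that a k=30 PCA neighbourhood fits inside it away from both edges; the
    outer wall carries the bone-like radial texture (``texture_amp=0`` gives
    an exactly spherical outer wall)."""
    if outer_radius <= 0 or thickness <= 0 or thickness >= outer_radius:
        raise ParameterError("cup requires 0 < thickness < outer_radius")
    r_out, r_in = outer_radius, outer_radius - thickness
    rim_wave = math.radians(rim_wave_deg)
    phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
    th_rim = _rim_polar(phi, rim_wave)

    rows = []
    # inner surface: from near the inner pole up to the rim (theta decreasing)
    for i in range(1, n_inner + 1):
        th = np.pi - (np.pi - th_rim) * i / n_inner
        rows.append(r_in * _sph_dir(th, phi))
    # rim strip: radius ramp from inner to outer at the rim polar angle
    for s in (0.25, 0.5, 0.75, 1.0):
        rows.append((r_in + (r_out - r_in) * s) * _sph_dir(th_rim, phi))
    # outer surface: from the rim down to near the outer pole, with the
    # texture tapered in below the rim and out again toward the pole
    for i in range(1, n_outer):
        th = th_rim + (np.pi - th_rim) * i / n_outer
        taper = (np.clip((th - th_rim) / math.radians(8.0), 0.0, 1.0)
                 * np.clip((math.radians(155.0) - th) / math.radians(10.0), 0.0, 1.0))
        r = r_out + taper * _cup_texture(th, phi, texture_amp)
        rows.append(r[..., None] * _sph_dir(th, phi))
    rows = np.stack(rows, axis=0)
    verts, faces = _grid_mesh([0.0, 0.0, -r_in], rows, [0.0, 0.0, -r_out])

    if n_facets > 0 and facet_depth > 0:
        fp = math.radians(facet_polar_deg)
        dirs = [_sph_dir(fp, 2.0 * np.pi * m / n_facets + math.radians(30.0))
                for m in range(n_facets)]
        # planes never reach the inner surface: offset > r_in
        offset = r_out - facet_depth
        if offset <= r_in:
            raise ParameterError("facet_depth would cut through the shell")
        verts = _clamp_to_planes(verts, [np.asarray(d).ravel() for d in dirs], offset)
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


#: Fovea-like flat pit on the femoral head (off the resection-cut axis): the
#: real head carries the fovea capitis, and without an off-axis feature the
#: probed region (sphere cap + circular cut disc) would be rotationally
#: symmetric about the cut normal, leaving one pose DOF unidentifiable.
BALL_FOVEA_DEPTH = 1.5
BALL_FOVEA_POLAR_DEG = 28.0
BALL_FOVEA_AZIM_DEG = 200.0
BALL_CUT_POLAR_DEG = 70.0


def _ball_cut_planes(size: dict):
    """(direction, offset) of the resection cut and fovea planes."""
    a = size.get("head_radius", 23.0)
    planes = []
    cut_depth = size.get("cut_depth", 4.0)
    if cut_depth > 0:
        u = np.asarray(_sph_dir(math.radians(
            size.get("cut_polar_deg", BALL_CUT_POLAR_DEG)), 0.0)).ravel()
        planes.append((u, a - cut_depth))
    fovea_depth = size.get("fovea_depth", BALL_FOVEA_DEPTH)
    if fovea_depth > 0:
        u = np.asarray(_sph_dir(math.radians(BALL_FOVEA_POLAR_DEG),
                                math.radians(BALL_FOVEA_AZIM_DEG))).ravel()
        planes.append((u, a - fovea_depth))
    return planes


def _make_ball_shaft(head_radius: float = 23.0, shaft_radius: float = 14.0,
                     shaft_length: float = 80.0, cut_depth: float = 4.0,
                     cut_polar_deg: float = BALL_CUT_POLAR_DEG,
                     fovea_depth: float = BALL_FOVEA_DEPTH,
                     texture_amp: float = CUP_TEXTURE_AMP, n_phi: int = 112,
                     ) -> trimesh.Trimesh:
    if min(head_radius, shaft_radius, shaft_length) <= 0:
        raise ParameterError("ball_shaft dimensions must be positive")
    if shaft_radius >= head_radius:
        raise ParameterError("shaft_radius must be smaller than head_radius")
    a, rs = head_radius, shaft_radius
    z_junction = -math.sqrt(a * a - rs * rs)
    z_end = -(a + shaft_length)   # total axial extent = shaft_length + 2a
    theta_j = math.acos(z_junction / a)

    phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
    rows = []
    for th in np.linspace(0.0, theta_j, 32)[1:]:
        # bone-like relief on the head, tapered off at the pole and junction
        taper = (min(max(th / math.radians(8.0), 0.0), 1.0)
                 * min(max((theta_j - math.radians(8.0) - th) / math.radians(8.0),
                           0.0), 1.0))
        r = a + taper * _cup_texture(np.full(n_phi, th), phi, texture_amp)
        rows.append(r[..., None] * _sph_dir(th, phi))
    for z in np.linspace(z_junction, z_end, 16)[1:]:
        rows.append(np.stack([rs * np.cos(phi), rs * np.sin(phi),
                              np.full(n_phi, z)], axis=-1))
    for r in np.linspace(rs, 0.0, 7)[1:-1]:
        rows.append(np.stack([r * np.cos(phi), r * np.sin(phi),
                              np.full(n_phi, z_end)], axis=-1))
    rows = np.stack(rows, axis=0)
    verts, faces = _grid_mesh([0.0, 0.0, a], rows, [0.0, 0.0, z_end])

    size = {"head_radius": a, "cut_depth": cut_depth, "cut_polar_deg": cut_polar_deg,
            "fovea_depth": fovea_depth}
    for u, offset in _ball_cut_planes(size):
        verts = _clamp_to_planes(verts, [u], offset)
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


def make_bone_mesh(shape: str, **size_params) -> trimesh.Trimesh:
    """Build a watertight bone-like triangle mesh with outward face winding.

    ``shape='cup'``: acetabulum-like hemispherical shell (outer radius 27 mm,
    wall 6 mm) with a wavy rim, three oblique outer-wall facets and bone-like
    radial relief.  ``shape='ball_shaft'``: femur-like head (radius 23 mm) +
    shaft (radius 14 mm, 80 mm exposed) with an oblique resection-plane cut
    and a fovea-like pit on the head.
    """
    if shape == "cup":
        mesh = _make_cup(**size_params)
    elif shape == "ball_shaft":
        mesh = _make_ball_shaft(**size_params)
    else:
        raise ParameterError(f"shape must be one of {SHAPES}, got {shape!r}")
    if mesh.volume < 0:
        mesh.invert()
    return mesh


# ---------------------------------------------------------------------------
# surface sampling
# ---------------------------------------------------------------------------

def sample_surface(mesh: trimesh.Trimesh, n: int, seed) -> PointCloud:
    """Area-weighted uniform surface samples; deterministic given ``seed``
    (accepts an int or a numpy Generator)."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    if len(mesh.faces) == 0 or mesh.area <= 0:
        raise ValueError("mesh has no sampleable surface")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    areas = mesh.area_faces
    face_idx = rng.choice(len(areas), size=n, p=areas / areas.sum())
    tri = mesh.triangles[face_idx]
    r1 = np.sqrt(rng.random(n))
    r2 = rng.random(n)
    pts = ((1.0 - r1)[:, None] * tri[:, 0]
           + (r1 * (1.0 - r2))[:, None] * tri[:, 1]
           + (r1 * r2)[:, None] * tri[:, 2])
    return PointCloud(pts)


def _project_to_surface(mesh: trimesh.Trimesh, points: np.ndarray):
    """Exact closest points on the mesh (brute force over triangles)."""
    feet, _, faces = closest_point_naive(mesh, np.atleast_2d(points))
    return np.asarray(feet), np.asarray(faces)


# ---------------------------------------------------------------------------
# probe / landmark / fiducial placement
# ---------------------------------------------------------------------------

def _cup_facet_dirs(n_facets: int = 3, facet_polar_deg: float = CUP_FACET_POLAR_DEG):
    return [np.asarray(_sph_dir(math.radians(facet_polar_deg),
                                2.0 * np.pi * m / n_facets + math.radians(30.0))).ravel()
            for m in range(n_facets)]


def _cup_probe_targets(cfg: PhantomConfig, size: dict, n: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Stratified targets on the accessible patch around the cup opening: one
    azimuth stratum per point on the outer-wall band below the rim, with
    strata whose azimuth crosses an outer-wall facet sometimes (p=0.6)
    touching the facet interior instead.

    Targets keep a margin away from surface creases (rim edge, facet
    boundaries): a probe tip cannot sit stably on an edge, and the local
    tangent plane is undefined there.
    """
    r_out = size.get("outer_radius", 27.0)
    r_in = r_out - size.get("thickness", 6.0)
    rim_wave = math.radians(size.get("rim_wave_deg", CUP_RIM_WAVE_DEG))
    facet_depth = size.get("facet_depth", CUP_FACET_DEPTH)
    n_facets = size.get("n_facets", 3)
    facet_polar = size.get("facet_polar_deg", CUP_FACET_POLAR_DEG)
    cap = math.radians(cfg.roi_cap_angle)
    edge_margin = math.radians(6.0)   # stay clear of the rim crease (wall side)
    rim_margin = 2.2                  # mm inside the rim strip edges

    j = np.arange(n)
    phi = 2.0 * np.pi * (j + rng.random(n)) / n
    th_rim = _rim_polar(phi, rim_wave)
    # ~40% of strata touch the rim-strip interior (normals ~ along the polar
    # direction), the rest the outer-wall band (radial normals); together with
    # the facet interiors they constrain all six pose DOF
    on_rim = rng.random(n) < 0.4
    rim_lo, rim_hi = r_in + rim_margin, r_out - rim_margin
    radius = np.where(on_rim, rim_lo + (rim_hi - rim_lo) * rng.random(n), r_out)
    theta = np.where(
        on_rim, th_rim,
        np.minimum(th_rim + edge_margin + (cap - edge_margin) * rng.random(n),
                   np.pi - 0.05))
    targets = radius[:, None] * _sph_dir(theta, phi)

    if n_facets > 0 and facet_depth > 0:
        offset = r_out - facet_depth
        chord = math.sqrt(max(r_out ** 2 - offset ** 2, 0.0))
        rho_max = max(chord - 2.5, 0.0)   # facet interior, 2.5 mm off the boundary
        if rho_max > 0:
            for u in _cup_facet_dirs(n_facets, facet_polar):
                phi_f = math.atan2(u[1], u[0])
                half_width = math.asin(min(chord / (r_out * math.sin(
                    math.radians(facet_polar))), 1.0))
                dphi = np.abs((phi - phi_f + np.pi) % (2.0 * np.pi) - np.pi)
                hit = (dphi < half_width) & (rng.random(n) < 0.6) & ~on_rim
                if not hit.any():
                    continue
                e1 = np.cross(u, [0.0, 0.0, 1.0])
                e1 /= np.linalg.norm(e1)
                e2 = np.cross(u, e1)
                rho = rho_max * np.sqrt(rng.random(int(hit.sum())))
                ang = 2.0 * np.pi * rng.random(int(hit.sum()))
                targets[hit] = (offset * u[None, :]
                                + rho[:, None] * (np.cos(ang)[:, None] * e1
                                                  + np.sin(ang)[:, None] * e2))
    return targets


def _ball_probe_targets(cfg: PhantomConfig, size: dict, n: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Quasi-equal-area (Fibonacci) strata on the head cap around +z, covering
    the resection cut; jittered within strata and randomly spun per phantom.

    Targets keep a ~2.5 mm margin away from the cut boundary crease: strata
    landing well beyond the cut plane move to the flat cut interior, strata
    landing in the crease zone fold back onto the spherical part.
    """
    a = size.get("head_radius", 23.0)
    cap = math.radians(cfg.roi_cap_angle)
    zmin = math.cos(cap)
    i = np.arange(n)
    z = 1.0 - (i + rng.random(n)) * (1.0 - zmin) / n
    phi = _GOLDEN_ANGLE * i + 2.0 * np.pi * rng.random()
    st = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    targets = a * np.stack([st * np.cos(phi), st * np.sin(phi), z], axis=-1)

    margin = 2.5
    for u, offset in _ball_cut_planes(size):
        chord = math.sqrt(max(a * a - offset * offset, 0.0))
        s = targets @ u
        proj = targets - np.maximum(s - offset, 0.0)[:, None] * u[None, :]
        rho = np.linalg.norm(proj - offset * u, axis=1)
        on_flat = (s > offset) & (rho <= max(chord - margin, 0.0))
        crease = (s > offset - margin) & ~on_flat
        targets[on_flat] = proj[on_flat]
        if crease.any():
            folded = targets[crease] - ((s[crease] - (offset - margin)) / a)[:, None] * u
            folded *= a / np.linalg.norm(folded, axis=1, keepdims=True)
            targets[crease] = folded
    return targets


def _cup_landmark_targets(size: dict, rng: np.random.Generator) -> np.ndarray:
    r_out = size.get("outer_radius", 27.0)
    rim_wave = math.radians(size.get("rim_wave_deg", CUP_RIM_WAVE_DEG))
    phi = np.radians([90.0, 210.0, 330.0]) + rng.uniform(-0.2, 0.2, 3)
    theta = _rim_polar(phi, rim_wave) + math.radians(15.0)
    return r_out * _sph_dir(theta, phi)


def _ball_landmark_targets(size: dict, rng: np.random.Generator) -> np.ndarray:
    """Two head points plus one shaft point: ~60 mm spread conditions the
    three-point alignment far better than a small triangle on the head."""
    a = size.get("head_radius", 23.0)
    rs = size.get("shaft_radius", 14.0)
    phi = np.radians([90.0, 270.0, 0.0]) + rng.uniform(-0.2, 0.2, 3)
    head = a * _sph_dir(np.radians(40.0) + rng.uniform(-0.05, 0.05, 2), phi[:2])
    z_shaft = -(a + 0.35 * size.get("shaft_length", 80.0))
    shaft = np.array([[rs * math.cos(phi[2]), rs * math.sin(phi[2]), z_shaft]])
    return np.vstack([head, shaft])


def _fiducial_positions(mesh: trimesh.Trimesh, n: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Fixture-ball stand-ins: 20-60 mm off the bone surface at spread
    (Fibonacci) directions around the shape."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = _GOLDEN_ANGLE * i
    st = np.sqrt(1.0 - z * z)
    dirs = np.stack([st * np.cos(phi), st * np.sin(phi), z], axis=-1)
    center = mesh.vertices.mean(axis=0)
    support = np.max((mesh.vertices - center) @ dirs.T, axis=0)  # per direction
    offsets = rng.uniform(20.0, 60.0, n)
    return center + dirs * (support + offsets)[:, None]


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

def perturb_transform(gt: RigidTransform, rot_deg: float, trans_mm: float,
                      seed) -> RigidTransform:
    """Compose ``gt`` with a random rotation of exactly ``rot_deg`` about a
    uniformly random axis and a translation of exactly ``trans_mm`` in a
    uniformly random direction (controlled imperfect-initialisation helper)."""
    if rot_deg < 0 or trans_mm < 0:
        raise ParameterError("perturbation magnitudes must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    tdir = rng.normal(size=3)
    tdir /= np.linalg.norm(tdir)
    delta = RigidTransform(exp_so3(axis * math.radians(rot_deg)), tdir * trans_mm)
    return compose(delta, gt)


def make_phantom(config: PhantomConfig) -> SyntheticPhantom:
    """Generate one synthetic trial from its config (fully seed-determined)."""
    size = dict(config.size_params or {})
    mesh = make_bone_mesh(config.shape, **size)

    ss = np.random.SeedSequence(config.seed)
    rng_gt, rng_dense, rng_probe, rng_noise, rng_out, rng_lm, rng_fid = (
        np.random.default_rng(s) for s in ss.spawn(7))

    # ground-truth patient -> CT transform
    lo_r, hi_r = config.gt_rotation_range
    lo_t, hi_t = config.gt_translation_range
    angles = np.radians(rng_gt.uniform(lo_r, hi_r, 3))
    R = Rotation.from_euler("xyz", angles).as_matrix()
    gt = RigidTransform(R, rng_gt.uniform(lo_t, hi_t, 3))
    gt_inv = invert(gt)

    target_cloud = sample_surface(mesh, config.dense_n, rng_dense)

    # probe feet: stratified targets on the accessible patch, projected onto
    # the actual mesh so noise-free probe points sit exactly on the surface
    if config.shape == "cup":
        targets = _cup_probe_targets(config, size, config.n_probe, rng_probe)
        lm_targets = _cup_landmark_targets(size, rng_lm)
    else:
        targets = _ball_probe_targets(config, size, config.n_probe, rng_probe)
        lm_targets = _ball_landmark_targets(size, rng_lm)
    feet, foot_faces = _project_to_surface(mesh, targets)

    probe = gt_inv.apply(feet)
    if config.probe_noise_sigma > 0:
        probe = probe + rng_noise.normal(0.0, config.probe_noise_sigma, probe.shape)

    n_out = math.ceil(config.outlier_fraction * config.n_probe)
    if n_out > 0:
        out_idx = np.sort(rng_out.choice(config.n_probe, size=n_out, replace=False))
        lo, hi = config.outlier_offset_range
        offsets = rng_out.uniform(lo, hi, n_out)
        normals_ct = mesh.face_normals[foot_faces[out_idx]]   # outward
        probe[out_idx] += gt_inv.apply_directions(normals_ct) * offsets[:, None]
    else:
        out_idx = np.zeros(0, dtype=int)
        offsets = np.zeros(0)

    lm_ct, _ = _project_to_surface(mesh, lm_targets)
    lm_patient = gt_inv.apply(lm_ct)
    if config.landmark_noise_sigma > 0:
        lm_patient = lm_patient + rng_lm.normal(
            0.0, config.landmark_noise_sigma, lm_patient.shape)

    fid_ct = _fiducial_positions(mesh, config.n_fiducials, rng_fid)
    fid_patient = gt_inv.apply(fid_ct)   # noise-free evaluation reference

    return SyntheticPhantom(
        config=config,
        mesh=mesh,
        target_cloud=target_cloud,
        gt_transform=gt,
        fiducials_ct=fid_ct,
        fiducials_patient=fid_patient,
        probe_points=probe,
        truth_feet=feet,
        truth_faces=foot_faces,
        landmark_names=tuple(f"L{i+1}" for i in range(len(lm_ct))),
        landmarks_patient=lm_patient,
        landmarks_ct=lm_ct,
        outlier_indices=out_idx,
        outlier_offsets=offsets,
    )
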