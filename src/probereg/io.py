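"""Readers/writers for meshes, point clouds, landmark tables, transforms and
run configuration, plus structured run logging.

Coordinate files are assumed to be in millimetres; a config flag
(``units="m"``) converts metres to mm on read (x1000) — never guessed from
magnitudes.  CSV dialect: comma separator, ``.`` decimal, optional header
auto-detected by a non-numeric first row.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import NamedTuple, Optional

import numpy as np
import trimesh
import yaml

from .errors import ConfigError, FormatError, PairingError
from .geometry import PointCloud, RigidTransform
from .phantom import PhantomConfig
from .sparse_icp import SparseICPParams

_MESH_EXTS = {".stl", ".ply", ".obj"}

logger = logging.getLogger("probereg")


class LoadedMesh(NamedTuple):
    mesh: trimesh.Trimesh
    degenerate_faces: np.ndarray  # indices of zero-area faces


def read_mesh(path) -> LoadedMesh:
    """Load an STL/PLY/OBJ triangle mesh (vertices in mm).

    STL stores duplicated vertices per facet; they are welded on load.
    Zero-area faces are not removed, only flagged in the diagnostics.
    A vertex-only PLY yields a mesh with zero faces.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"mesh file not found: {path}")
    if path.suffix.lower() not in _MESH_EXTS:
        raise FormatError(f"unsupported mesh extension {path.suffix!r} (want STL/PLY/OBJ)")
    if path.stat().st_size == 0:
        raise FormatError(f"mesh file is empty: {path}")
    try:
        loaded = trimesh.load(str(path), process=False)
    except Exception as exc:  # noqa: BLE001 - re-raise as format error
        raise FormatError(f"could not parse {path}: {exc}") from exc
    if isinstance(loaded, trimesh.points.PointCloud):
        mesh = trimesh.Trimesh(vertices=np.asarray(loaded.vertices),
                               faces=np.zeros((0, 3), dtype=int), process=False)
    elif isinstance(loaded, trimesh.Trimesh):
        mesh = loaded
    else:
        raise FormatError(f"{path} did not contain a single triangle mesh")
    if not np.all(np.isfinite(mesh.vertices)):
        raise FormatError(f"{path}: non-finite vertex coordinates")
    if len(mesh.faces) and mesh.faces.max() >= len(mesh.vertices):
        raise FormatError(f"{path}: face indexes a missing vertex")
    if len(mesh.faces):
        # weld exact duplicates (STL facet soup) without altering geometry
        mesh.merge_vertices()
        degenerate = np.flatnonzero(mesh.area_faces <= 0.0)
    else:
        degenerate = np.zeros(0, dtype=int)
    return LoadedMesh(mesh=mesh, degenerate_faces=degenerate)


# ---------------------------------------------------------------------------
# point clouds
# ---------------------------------------------------------------------------

def _looks_numeric(tokens) -> bool:
    try:
        [float(t) for t in tokens]
        return True
    except ValueError:
        return False


def read_point_cloud(path, units: str = "mm") -> PointCloud:
    """Read XYZ/CSV (3 or 6 columns: xyz [+ normal]) or ASCII PLY point files.

    Six-column files carry normals; off-unit normals are re-normalised, with
    a warning when they deviate from unit length by more than 1e-3.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"point file not found: {path}")
    scale = {"mm": 1.0, "m": 1000.0}.get(units)
    if scale is None:
        raise ConfigError(f"unknown units {units!r} (use 'mm' or 'm')")
    if path.suffix.lower() == ".ply":
        loaded = trimesh.load(str(path), process=False)
        pts = np.asarray(loaded.vertices, dtype=float) * scale
        return PointCloud(pts)
    rows = []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = [t for t in line.replace(",", " ").split() if t]
            if lineno == 1 and not _looks_numeric(tokens):
                continue  # header row
            if not _looks_numeric(tokens):
                raise FormatError(f"{path}:{lineno}: non-numeric field in {line!r}")
            if len(tokens) not in (3, 6):
                raise FormatError(
                    f"{path}:{lineno}: expected 3 or 6 columns, got {len(tokens)}")
            if ncols is None:
                ncols = len(tokens)
            elif len(tokens) != ncols:
                raise FormatError(f"{path}:{lineno}: ragged row ({len(tokens)} cols, "
                                  f"expected {ncols})")
            rows.append([float(t) for t in tokens])
    if not rows:
        raise FormatError(f"{path}: no points found")
    data = np.asarray(rows, dtype=float)
    pts = data[:, :3] * scale
    normals = None
    if data.shape[1] == 6:
        normals = data[:, 3:]
        lens = np.linalg.norm(normals, axis=1)
        if np.any(lens <= 0):
            raise FormatError(f"{path}: zero-length normal encountered")
        if np.any(np.abs(lens - 1.0) > 1e-3):
            warnings.warn(f"{path}: normals off unit length by more than 1e-3; "
                          "re-normalised", stacklevel=2)
        normals = normals / lens[:, None]
    return PointCloud(pts, normals)


def write_point_cloud(cloud: PointCloud, path) -> None:
    """Write a cloud as CSV (xyz or xyz+normal); round-trips within 1e-6 mm."""
    path = Path(path)
    if cloud.has_normals:
        data = np.hstack([cloud.points, cloud.normals])
        header = "x,y,z,nx,ny,nz"
    else:
        data = cloud.points
        header = "x,y,z"
    np.savetxt(path, data, delimiter=",", header=header, comments="", fmt="%.10g")


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LandmarkPairs:
    """Paired coarse-registration landmarks, name-sorted."""

    names: tuple
    source: np.ndarray  # (N, 3) patient/tracker frame
    target: np.ndarray  # (N, 3) CT frame

    def __len__(self) -> int:
        return len(self.names)


def read_landmarks(path) -> LandmarkPairs:
    """Read a landmark CSV with columns ``name, frame, x, y, z`` where frame
    is ``source`` or ``target`` and every name appears once in each frame."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"landmark file not found: {path}")
    per_frame: dict[str, dict[str, np.ndarray]] = {"source": {}, "target": {}}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            tokens = [t.strip() for t in line.split(",")]
            if lineno == 1 and tokens[:2] == ["name", "frame"]:
                continue
            if len(tokens) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns, got {len(tokens)}")
            name, frame = tokens[0], tokens[1].lower()
            if frame not in per_frame:
                raise FormatError(f"{path}:{lineno}: frame must be source|target, "
                                  f"got {frame!r}")
            if not _looks_numeric(tokens[2:]):
                raise FormatError(f"{path}:{lineno}: non-numeric coordinate")
            if name in per_frame[frame]:
                raise FormatError(f"{path}:{lineno}: duplicate landmark {name!r} "
                                  f"in frame {frame}")
            per_frame[frame][name] = np.array([float(t) for t in tokens[2:]])
    missing_tgt = sorted(set(per_frame["source"]) - set(per_frame["target"]))
    missing_src = sorted(set(per_frame["target"]) - set(per_frame["source"]))
    if missing_tgt or missing_src:
        parts = []
        if missing_tgt:
            parts.append(f"missing in target frame: {', '.join(missing_tgt)}")
        if missing_src:
            parts.append(f"missing in source frame: {', '.join(missing_src)}")
        raise PairingError("unpaired landmarks — " + "; ".join(parts))
    names = tuple(sorted(per_frame["source"]))
    if len(names) < 3:
        raise PairingError(f"need >= 3 complete landmark pairs, got {len(names)}")
    src = np.array([per_frame["source"][n] for n in names])
    tgt = np.array([per_frame["target"][n] for n in names])
    return LandmarkPairs(names=names, source=src, target=tgt)


def write_landmarks(pairs: LandmarkPairs, path) -> None:
    with open(path, "w") as fh:
        fh.write("name,frame,x,y,z\n")
        for name, p in zip(pairs.names, pairs.source):
            fh.write(f"{name},source,{p[0]:.10g},{p[1]:.10g},{p[2]:.10g}\n")
        for name, p in zip(pairs.names, pairs.target):
            fh.write(f"{name},target,{p[0]:.10g},{p[1]:.10g},{p[2]:.10g}\n")


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def write_transform(transform: RigidTransform, path) -> None:
    """TXT: plain 4x4 row-major homogeneous matrix; JSON: rotation/translation."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(transform.to_dict(), indent=2) + "\n")
    else:
        np.savetxt(path, transform.as_matrix(), fmt="%.17g")


def read_transform(path) -> RigidTransform:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"transform file not found: {path}")
    try:
        if path.suffix.lower() == ".json":
            return RigidTransform.from_dict(json.loads(path.read_text()))
        return RigidTransform.from_matrix(np.loadtxt(path))
    except (ValueError, KeyError) as exc:
        raise FormatError(f"could not parse transform {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_LOG_LEVELS = ("DEBUG", "INFO", "WARNING", "ERROR")


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved run configuration: algorithm + phantom parameters, seed,
    output directory and log level.  Unknown keys are rejected by name."""

    params: SparseICPParams = field(default_factory=SparseICPParams)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    seed: int = 0
    output_dir: str = "."
    log_level: str = "INFO"
    units: str = "mm"

    def __post_init__(self):
        if self.log_level not in _LOG_LEVELS:
            raise ConfigError(f"log_level must be one of {_LOG_LEVELS}, "
                              f"got {self.log_level!r}")
        if self.units not in ("mm", "m"):
            raise ConfigError(f"units must be 'mm' or 'm', got {self.units!r}")

    def to_dict(self) -> dict:
        return {
            "params": asdict(self.params),
            "phantom": asdict(self.phantom),
            "seed": self.seed,
            "output_dir": str(self.output_dir),
            "log_level": self.log_level,
            "units": self.units,
        }


def _build_section(cls, data: dict, section: str):
    valid = {f.name for f in fields(cls)}
    unknown = sorted(set(data) - valid)
    if unknown:
        raise ConfigError(f"unknown key(s) in {section!r} section: {', '.join(unknown)}")
    try:
        return cls(**data)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid {section} configuration: {exc}") from exc


def config_from_dict(data: Optional[dict]) -> RunConfig:
    data = dict(data or {})
    params = _build_section(SparseICPParams, data.pop("params", {}), "params")
    phantom = _build_section(PhantomConfig, data.pop("phantom", {}), "phantom")
    top = {"params": params, "phantom": phantom}
    allowed = {"seed", "output_dir", "log_level", "units"}
    unknown = sorted(set(data) - allowed)
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {', '.join(unknown)}")
    top.update(data)
    return RunConfig(**top)


def load_config(path) -> RunConfig:
    """Load a JSON or YAML run configuration; unspecified fields take the
    documented defaults (p=0.5, mu=1.0, d_max=5.0 mm, k_max=100,
    k_neighbors=30, n_probe=30).  The resolved config is echoed to the log."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        data = yaml.safe_load(text) if text.strip() else {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    cfg = config_from_dict(data)
    logger.info("resolved config: %s", json.dumps(cfg.to_dict(), sort_keys=True))
    return cfg


# ---------------------------------------------------------------------------
# structured logging
# ---------------------------------------------------------------------------

class RunLogger:
    """Writes human-readable text plus a machine-readable JSON-lines stream.

    Every registration run should log its resolved config, per-iteration
    objective values, correspondence counts and final metrics.
    """

    def __init__(self, jsonl_path=None, level: str = "INFO"):
        self._fh = open(jsonl_path, "a") if jsonl_path else None
        logger.setLevel(getattr(logging, level))

    def event(self, kind: str, **payload) -> None:
        record = {"event": kind, **payload}
        logger.info("%s: %s", kind, json.dumps(payload, sort_keys=True, default=str))
        if self._fh is not None:
            self._fh.write(json.dumps(record, sort_keys=True, default=str) + "\n")
            self._fh.flush()

    def trace(self, trace) -> None:
        self.event("trace", **trace.to_dict())

    def close(self) -> None:
        if self._fh is not None:
            self._fh.close()
            self._fh = None

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
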