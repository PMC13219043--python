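"""Accuracy metrics and the repeated-trial evaluation protocol.

Metrics (all mm):

* TRE  = (1/m) sum_j ||true_j - est_j|| over the m fixture fiducials — the
  navigation-relevant localisation error at points not used by the solver;
* RMSE = sqrt(mean of squared per-pair distances);
* STD  = population standard deviation (1/n divisor) of the per-pair errors;
* MaxErr = largest per-pair distance.

The trial protocol mirrors a fair algorithm comparison: per repeat, one
phantom is generated, one coarse landmark solution is computed, and every
fine method runs on the *identical* probe points, target cloud and initial
pose (an input checksum is recorded and asserted equal across methods).
Surface metrics are reported against nearest-target-point residuals by
default; residuals against the known true surface feet are exported as well.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .coarse import kabsch_align
from .errors import ParameterError
from .geometry import PointCloud, RigidTransform, apply_transform
from .phantom import PhantomConfig, SyntheticPhantom, make_phantom
from .sparse_icp import FINE_METHODS, SparseICPParams
from .surface import build_spatial_index, estimate_normals

logger = logging.getLogger("probereg")

#: Method names accepted by the trial protocol (coarse_only = no refinement).
METHOD_NAMES = ("coarse_only",) + tuple(FINE_METHODS)

METRIC_NAMES = ("tre", "rmse", "std", "max_err")


@dataclass(frozen=True)
class MetricsReport:
    """One registration's error metrics (mm)."""

    tre: float
    rmse: float
    std: float
    max_err: float
    m_fiducials: int
    n_pairs: int

    def to_dict(self) -> dict:
        return asdict(self)


def compute_tre(fiducials_true, fiducials_est) -> float:
    """Mean Euclidean distance between true and registered fiducial centres."""
    t = np.asarray(fiducials_true, dtype=float)
    e = np.asarray(fiducials_est, dtype=float)
    if t.ndim != 2 or t.shape[1] != 3 or t.shape != e.shape:
        raise ValueError("fiducial arrays must be congruent (m, 3)")
    if t.shape[0] == 0:
        raise ParameterError("need at least one fiducial")
    return float(np.mean(np.linalg.norm(t - e, axis=1)))


def compute_surface_metrics(errors) -> tuple[float, float, float]:
    """(rmse, std, max_err) of per-pair distances; STD uses the population
    (1/n) divisor."""
    e = np.asarray(errors, dtype=float)
    if e.ndim != 1 or e.shape[0] == 0:
        raise ParameterError("need a non-empty 1-D array of distances")
    if np.any(e < 0):
        raise ValueError("distances must be >= 0")
    rmse = float(np.sqrt(np.mean(e * e)))
    std = float(np.sqrt(np.mean((e - e.mean()) ** 2)))
    return rmse, std, float(e.max())


def evaluate_registration(phantom: SyntheticPhantom, total_transform: RigidTransform,
                          pairing: str = "nearest") -> MetricsReport:
    """Score one registration against the phantom's ground truth.

    TRE compares the patient-side fiducials mapped by ``total_transform``
    with their noise-free CT positions.  Surface metrics use the registered
    probe points' residuals, paired either to the nearest dense-cloud point
    (``pairing='nearest'``, the default — mirrors intraoperative probe-tip
    verification) or to the known true surface feet (``pairing='true'``).
    """
    fid_est = total_transform.apply(phantom.fiducials_patient)
    tre = compute_tre(phantom.fiducials_ct, fid_est)
    probe_est = total_transform.apply(phantom.probe_points)
    if pairing == "nearest":
        index = build_spatial_index(
            PointCloud(phantom.target_cloud.points))
        d, _ = index.nearest(probe_est)
        errors = d
    elif pairing == "true":
        errors = np.linalg.norm(probe_est - phantom.truth_feet, axis=1)
    else:
        raise ValueError("pairing must be 'nearest' or 'true'")
    rmse, std, max_err = compute_surface_metrics(errors)
    return MetricsReport(tre=tre, rmse=rmse, std=std, max_err=max_err,
                         m_fiducials=phantom.fiducials_ct.shape[0],
                         n_pairs=errors.shape[0])


# ---------------------------------------------------------------------------
# repeated-trial protocol
# ---------------------------------------------------------------------------

@dataclass
class TrialSummary:
    """Per-method statistics over repeats plus the raw per-repeat records."""

    methods: tuple
    n_repeats: int
    seeds: tuple
    reference_method: str
    config: PhantomConfig
    records: list = field(default_factory=list)   # one dict per repeat
    failures: dict = field(default_factory=dict)  # method -> list of seeds

    def metric_values(self, method: str, metric: str = "tre",
                      pairing: str = "nearest") -> np.ndarray:
        key = "metrics" if pairing == "nearest" else "metrics_true"
        return np.array([rec[key][method][metric] for rec in self.records
                         if method in rec[key]])

    def mean_sd(self, method: str, metric: str = "tre") -> tuple[float, float]:
        v = self.metric_values(method, metric)
        return float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0

    def paired_differences(self, method: str, metric: str = "tre") -> np.ndarray:
        """Per-repeat metric difference (method - reference), pairwise over
        repeats where both methods succeeded."""
        diffs = []
        for rec in self.records:
            m = rec["metrics"]
            if method in m and self.reference_method in m:
                diffs.append(m[method][metric] - m[self.reference_method][metric])
        return np.asarray(diffs)

    def to_dict(self) -> dict:
        cfg = asdict(self.config)
        cfg["size_params"] = cfg["size_params"] or {}
        return {
            "methods": list(self.methods),
            "n_repeats": self.n_repeats,
            "seeds": list(self.seeds),
            "reference_method": self.reference_method,
            "config": cfg,
            "summary": {
                method: {metric: dict(zip(("mean", "sd"), self.mean_sd(method, metric)))
                         for metric in METRIC_NAMES}
                for method in self.methods
            },
            "paired_differences_tre": {
                method: [float(v) for v in self.paired_differences(method)]
                for method in self.methods if method != self.reference_method
            },
            "records": self.records,
            "failures": {k: list(v) for k, v in self.failures.items()},
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def format_table(self, pairing: str = "nearest") -> str:
        """Plain-text methods x metrics table of mean +/- SD values (mm)."""
        header = f"{'method':<14}" + "".join(f"{m.upper():>16}" for m in METRIC_NAMES)
        lines = [header, "-" * len(header)]
        for method in self.methods:
            cells = []
            for metric in METRIC_NAMES:
                v = self.metric_values(method, metric, pairing)
                cells.append(f"{v.mean():7.3f} ± {v.std(ddof=1) if v.size > 1 else 0.0:5.3f}")
            lines.append(f"{method:<14}" + "".join(f"{c:>16}" for c in cells))
        return "\n".join(lines)


def _input_checksum(phantom: SyntheticPhantom, init: RigidTransform) -> str:
    h = hashlib.sha256()
    h.update(phantom.probe_points.tobytes())
    h.update(phantom.target_cloud.points.tobytes())
    h.update(init.R.tobytes())
    h.update(init.T.tobytes())
    return h.hexdigest()


def run_trials(config: PhantomConfig, methods: Sequence[str],
               n_repeats: int = 30, base_seed: int = 0,
               params: SparseICPParams = SparseICPParams(),
               reference_method: Optional[str] = None) -> TrialSummary:
    """Repeat the full pipeline ``n_repeats`` times under the identical-inputs
    protocol.

    Per repeat (seed = ``base_seed`` + repeat index): one phantom is built,
    its target cloud gets PCA normals once, one coarse landmark solution is
    fitted, and every requested method runs on references to the same arrays
    with the same initial pose.  Method failures are recorded per repeat and
    excluded pairwise, never silently.
    """
    methods = tuple(methods)
    if not methods:
        raise ParameterError("need at least one method")
    for m in methods:
        if m not in METHOD_NAMES:
            raise ParameterError(f"unknown method {m!r}; choose from {METHOD_NAMES}")
    if n_repeats < 1:
        raise ParameterError("n_repeats must be >= 1")
    ref = reference_method or methods[0]
    if ref not in methods:
        raise ParameterError(f"reference method {ref!r} not among methods")

    seeds = tuple(base_seed + r for r in range(n_repeats))
    summary = TrialSummary(methods=methods, n_repeats=n_repeats, seeds=seeds,
                           reference_method=ref, config=config)
    for seed in seeds:
        phantom = make_phantom(replace(config, seed=seed))
        target_n = estimate_normals(phantom.target_cloud, params.k_neighbors)
        coarse = kabsch_align(phantom.landmarks_patient, phantom.landmarks_ct)
        init = coarse.transform
        checksum = _input_checksum(phantom, init)
        rec = {"seed": seed, "input_checksum": checksum, "coarse_fre_mm":
               coarse.rms_residual, "metrics": {}, "metrics_true": {},
               "termination": {}, "iterations": {}}
        source = phantom.probe_cloud
        for method in methods:
            try:
                if method == "coarse_only":
                    total = init
                else:
                    total, trace = FINE_METHODS[method](source, target_n, init, params)
                    rec["termination"][method] = trace.termination_reason
                    rec["iterations"][method] = trace.n_iterations
                rec["metrics"][method] = evaluate_registration(
                    phantom, total, pairing="nearest").to_dict()
                rec["metrics_true"][method] = evaluate_registration(
                    phantom, total, pairing="true").to_dict()
            except Exception as exc:  # noqa: BLE001 - recorded, never silent
                summary.failures.setdefault(method, []).append(seed)
                logger.warning("seed %d: method %s failed: %s", seed, method, exc)
        summary.records.append(rec)
    for method, seeds_failed in summary.failures.items():
        logger.warning("method %s failed on %d/%d repeats (excluded pairwise)",
                       method, len(seeds_failed), n_repeats)
    return summary


#: The four ablation configurations, worst-expected to best-expected.
ABLATION_METHODS = ("coarse_only", "p2pt", "p2pl", "sparse_p2pl")


def run_ablation(config: PhantomConfig, n_repeats: int = 30, base_seed: int = 0,
                 params: SparseICPParams = SparseICPParams()) -> TrialSummary:
    """Evaluate the four registration configurations — coarse only, coarse +
    point-to-point ICP, coarse + plain point-to-plane, coarse + sparse
    point-to-plane (full method) — under the identical-inputs protocol."""
    return run_trials(config, ABLATION_METHODS, n_repeats=n_repeats,
                      base_seed=base_seed, params=params,
                      reference_method="sparse_p2pl")


def run_sample_sweep(config: PhantomConfig, counts: Sequence[int],
                     n_repeats: int = 30, base_seed: int = 0,
                     params: SparseICPParams = SparseICPParams(),
                     method: str = "sparse_p2pl") -> dict[int, TrialSummary]:
    """Repeat the full pipeline at each probe-point count (the accuracy vs.
    sampling-effort trade-off sweep).  Returns {count: TrialSummary}."""
    out = {}
    for count in counts:
        if count < 3:
            raise ParameterError("counts must be >= 3 (minimum rigid constraint)")
        out[int(count)] = run_trials(replace(config, n_probe=int(count)),
                                     [method], n_repeats=n_repeats,
                                     base_seed=base_seed, params=params)
    return out
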