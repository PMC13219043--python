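# Methods

## Model and procedure

`probereg` estimates the rigid transform `p_CT = R p_P + T` (SE(3), all
coordinates in millimetres, radians internally) between a patient/tracker
frame and a CT frame, from two kinds of measurements:

* ≥3 paired anatomical landmarks (both frames) for the coarse stage;
* a sparse cloud of probe-tip surface points (~30, patient frame) and a dense
  CT-surface point cloud (tens of thousands of points) for the fine stage.

**Coarse stage.** Classic closed-form landmark alignment: SVD of the
cross-covariance of centred pairs, with the determinant guard
`R = V diag(1,1,det(VUᵀ)) Uᵀ` so noisy or coplanar landmark sets can never
return a reflection, and `T = −R c_src + c_tgt`.  Collinearity is detected on
the *middle* singular value of the covariance (any minimal 3-point set is
coplanar, so the smallest singular value is uninformative and is reported as
a diagnostic only).

**Fine stage.** Sparse point-to-plane ICP.  Per outer iteration:

1. nearest-neighbour correspondences from a kd-tree over the target cloud,
   gated at `d_max` (euclidean), ties broken toward the lowest target index;
2. an ADMM inner loop (auxiliaries `z`, duals `λ` reset at each re-matching,
   `inner_iters` cycles): proximal step `z ← argmin |z|^p + (μ/2)(z−ẽ)²`
   solved by threshold iteration (fixed point of the stationarity equation,
   with an explicit comparison against `z = 0`; ties resolve to 0), then a
   damped Gauss–Newton pose step on the small-angle linearisation, then dual
   ascent `λ ← λ + μ(n·r − z)`;
3. stopping on pose increment (‖Δt‖ < 0.01 mm AND Δθ < 0.01°), objective
   change (|E(k)−E(k−1)| < 1e-6, only when the kept correspondence support is
   identical — the Lp objective is not comparable across different supports),
   or the iteration cap `k_max = 100`.

The pose update left-composes the increment: `R ← exp([ω]×)R`,
`T ← exp([ω]×)T + Δt`.  This is the update consistent with the linearised
residual model the normal equations solve (the ω-then-translate form); a
per-step `T ← T + Δt` variant differs only at second order and both agree at
convergence.

**Baselines** (for the ablation): point-to-point ICP (same gating, closed-form
SVD update per re-matching, monotone mean-squared error on clean data) and
plain point-to-plane ICP (quadratic loss, one damped least-squares step per
re-matching — the standard formulation).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `p` | 0.5 | sparsity exponent, 0<p<1; smaller = more aggressive outlier down-weighting |
| `mu` | 1.0 | ADMM penalty, fixed during optimisation |
| `d_max` | 5.0 mm | correspondence gate |
| `k_max` | 100 | outer iteration cap |
| `trans_tol`, `rot_tol` | 0.01 mm, 0.01° | pose-increment stop |
| `obj_tol` | 1e-6 | objective-change stop |
| `inner_iters` | 5 | ADMM cycles per correspondence update |
| `lm_damping` | 1e-9 | base Tikhonov damping of the pose solve |
| `step_cap` | 0.1 rad | trust region of the small-angle step |
| `k_neighbors` | 30 | PCA normal neighbourhood (query point included) |

With `p = 0.5, μ = 1` the proximal dead zone is ≈ ±1.19 mm: residuals below
it behave exactly like plain point-to-plane (z = 0), larger ones are treated
as outliers.  Consequently the sparse variant *equals* plain point-to-plane
on clean data and departs from it exactly where contamination lives.

## Numerical safeguards

* The pose solve is Levenberg–Marquardt style: when the raw normal-equation
  solution exceeds the rotation trust region, damping is escalated on
  `diag(AᵀA)` until it fits.  Rescaling the raw step instead is not safe: a
  weakly constrained pose mode (e.g. rotation about a locally symmetric
  surface patch) can blow up the raw solution, and rescaling then destroys
  the well-constrained components — observed as persistent cap-saturated
  steps and orbiting.
* Rank deficiency beyond damping rescue (all normals parallel, etc.) raises a
  degenerate-geometry error rather than returning an arbitrary pose.
* ADMM auxiliaries and duals are reset at every correspondence update.  The
  splitting is defined for a fixed constraint set `zᵢ = nᵢ·rᵢ`; carrying
  duals across re-matching (tried during development) produces limit cycles.
* Normals are estimated once on the target (it never moves), left unoriented:
  every objective term is even in the normal sign.
* SO(3) validity is enforced at 1e-9 (Frobenius) on every constructed
  transform; re-orthonormalisation exists only as an explicit utility.

## The synthetic phantom

`phantom.make_phantom` emulates a physical accuracy study: a bone-like mesh
in the CT frame, a dense surface cloud sampled from it (area-weighted,
default 50 000 points), a ground-truth rigid transform drawn from ±30° / ±50
mm per axis, four fixture fiducials placed 20–60 mm off the surface at spread
directions (the evaluation reference — never seen by the solver), ~30 probe
points on a restricted accessible patch with 0.2 mm isotropic noise, a
configurable fraction of cartilage-like outliers (displaced 2–5 mm outward
along the surface normal, one-sided), and three coarse landmarks with 2 mm
noise on the patient side.  All randomness flows from one seed through a
fixed `SeedSequence.spawn` order, so runs are bit-reproducible and changing
`n_probe` does not change the ground truth.

Shape design matters more than it may appear:

* An ideal hemispherical shell or sphere+cylinder is a surface of revolution;
  rotation about its axis would be unidentifiable from surface points.  Real
  bone is not.  The cup therefore carries a sinusoidally varying rim height
  (amplitude kept below half the 5 mm gate so rim points are never gated out
  under azimuth error — a long-range alignment funnel), three oblique flat
  facets on the outer wall, and a fixed low-order radial relief (±0.5 mm,
  12–15 mm wavelengths).  The femoral head carries an oblique resection-plane
  cut and a fovea-like flat pit off the cut axis; without the pit the probed
  region (sphere cap + circular disc) stays symmetric about the cut normal.
* The relief also gives smooth sphere-like regions tangential stiffness.  On
  a featureless patch, point-to-plane residuals are blind to tangential
  motion, and within-gate outliers then drag the pose at no inlier cost.
* Probe targets keep ≥2–2.5 mm margins from mesh creases (rim edges, facet
  boundaries): a k = 30 PCA neighbourhood (radius ≈1.4 mm at the default
  density) straddling a crease yields meaningless tangent planes, and a probe
  tip cannot sit stably on an edge anyway.

What the phantom does **not** model: real anatomical shape variation, CT
segmentation artefacts, tracker-specific (non-isotropic, temporally drifting)
noise, soft-tissue interference beyond the one-sided outlier model, or probe
calibration error.  Passing tests demonstrate the algorithmic properties of
the pipeline under the stated synthetic conditions, not clinical accuracy.

## Evaluation protocol

`evaluation.run_trials` repeats the full pipeline (phantom → coarse from the
noisy landmarks → each fine method on *identical* inputs, checksum-logged)
and reports, per method, mean ± SD of TRE (mean fiducial error), RMSE, STD
(population divisor, per the printed formula) and MaxErr over the probe
points, plus per-repeat paired differences against a reference method.
Surface metrics pair registered probe points either to the nearest
dense-cloud point (default; mirrors intraoperative probe-tip verification —
note its floor is the cloud spacing) or to the known true surface feet
(`pairing="true"`).  `run_ablation` runs the four configurations of the
method decomposition; `run_sample_sweep` varies the probe count.

At the study conditions (0.2 mm noise, 20% outliers, 30 paired repeats,
default geometry) the suite measures mean TREs of roughly: coarse-only ≈ 5.0
mm, +point-to-point ≈ 3.4 mm, +sparse point-to-plane ≈ 1.5 mm, with the
10-point sweep ≈ 10 mm vs ≈ 1.6 mm at 30 points.  These are recomputed (not
asserted as constants) by `scripts/acceptance.py`.

## Known limitations

* **Convergence basin.** With the fixed 5 mm gate, no feature a ~27 mm bone
  model can carry survives a 10 mm initialisation error: gated point-to-plane
  descent then provably walks into wrong minima (energy decreases
  monotonically while the pose error grows — verified by monotone
  trust-region descent reaching the same minima).  From initialisations of a
  realistic three-point coarse stage (≤~8° / ≤~3 mm) the full method
  converged on every seed tested; from a 10° / 10 mm kick roughly a third of
  seeds land in wrong minima.  The registration is a *refinement* method and
  inherits ICP's local character.
* **Accuracy floor of a sampled target.** PCA normals at k = 30 on a
  50 000-point cloud carry ≈0.4° tilt noise, and nearest-sample tangent
  planes carry curvature bias d²/2R; together they bound noise-free
  end-to-end TRE at roughly 1e-3–1e-2 mm even from a perfect initialisation.
  Idealised "exact recovery to 1e-3 mm" claims assume a continuous,
  exactly-normal target and are not attainable against a discrete sampled
  one at this density.
* **Plain point-to-plane under heavy one-sided outliers.** When *every*
  outlier lies inside the gate (offsets 2–5 mm vs a 5 mm gate), the quadratic
  point-to-plane landscape is globally corrupted: started *at* the ground
  truth it descends to poses several mm away, because within-gate outliers
  buy large error reductions along rotation modes that plane residuals price
  weakly.  The closed-form point-to-point update is immune (every point
  constrains every rotation DOF), so under these synthetic conditions plain
  point-to-plane scores *worse* than point-to-point, while the sparse variant
  — which freezes exactly those outliers — scores best.  With milder
  contamination (offsets small relative to the gate, or partially gated) the
  conventional ordering point-to-plane < point-to-point reappears.
* The femur-like model is registered from its head/resection patch only;
  fiducials distributed along the 126 mm shaft amplify any residual rotation
  error by lever arm, so its TREs run higher than the acetabular model's.
  The acetabular model is the primary benchmark.
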