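# Methods

`facefem` predicts where the facial soft tissue ends up after a Le Fort I
maxillary advancement — not as one deterministic surface, but as a
per-landmark *prediction envelope* (minimum, maximum, histogram and
cumulative density) that reflects uncertainty in tissue properties and in
the surgical execution of the plan.  This note records the model, the
synthetic study design, the numerical choices, and what the shipped tests
do and do not establish.

## Forward model

The forward problem is quasi-static, small-strain linear (visco)elasticity
on linear tetrahedra, with four regions:

| region           | constitutive law            | defaults / ranges            |
|------------------|-----------------------------|------------------------------|
| skull base       | linear elastic              | E ∈ [5000, 15000] MPa, ν ∈ [0.2, 0.4] |
| mobile maxilla   | linear elastic (same E, ν)  | translated anteriorly by x_adv |
| nasal cartilage  | linear elastic              | E ∈ [0.5, 5] MPa, ν ∈ [0.26, 0.38] |
| facial soft tissue | linear viscoelastic       | E ∈ [0.1, 1] MPa, ν ∈ [0.45, 0.499] |

Soft tissue is treated as nearly incompressible with *deviatoric-only*
relaxation (no volumetric relaxation).  The normalised shear relaxation is
a two-term Prony series

    G(t)/G0 = 1 − s·Σᵢ gᵢ (1 − e^(−t/τᵢ)),   g = (0.325, 0.3), τ = (1, 6) s,

i.e. 62.5 % long-time relaxation at unit scale.  The dimensionless scale
factor `s = G_scale` sweeps [0.488, 1.512], covering 30.5 %–94.5 % total
relaxation.  Boundary conditions: the soft tissue is fixed on its
posterior, superior and inferior faces, the skull base posteriorly and
superiorly; the prescribed advancement `(0, x_adv, 0)` is applied to every
surface node of the mobile segment.  The reported "postoperative"
prediction is the anterior (y) displacement component at each landmark at
the end of the hold, with the preoperative state as the zero baseline.

### Numerical treatment

* **Anti-locking.**  Plain linear tetrahedra lock near ν = 0.5.  The
  volumetric strain of the soft tissue is replaced by its volume-weighted
  average over element patches (B-bar): on the structured phantom meshes
  the patches are the parent hexahedral cells — each contributes six
  tetrahedra — which reproduces the classic mean-dilatation treatment;
  for meshes without patch provenance the averaging falls back to nodal
  patches (node-based uniform strain).  The deviatoric operator is
  untouched, the treatment is variationally consistent (the same averaged
  operator appears on both sides of the stiffness), and the matrix stays
  sparse enough for repeated direct factorisation.
* **Time integration.**  The hereditary integral is advanced with the
  standard internal-variable exponential recurrence, exact for strain
  varying linearly within a step.  The load protocol (nowhere fully
  constrained by the application, hence a package choice) is a linear ramp
  of the prescribed translation over 1 s followed by a hold to
  t_end = 10·max(τ) = 60 s, where G(t) is within 10⁻⁴ of G∞.  The default
  grid uses 4 ramp + 12 uniform hold steps; steps sharing a Δt share one
  LU factorisation.  Against a dense 40-step log-spaced reference the
  default grid reproduces landmark displacements to ~3·10⁻⁵ relative.
* **Verification.**  The test suite checks: homogeneous uniaxial
  extension against the closed form (< 0.5 %); the end-of-hold
  viscoelastic field against a separate elastic solve at
  G∞ = G0(1 − s·Σg) (< 1 %); the instantaneous (short-ramp) response
  against the unrelaxed elastic solve (< 1 %); invariance of the
  displacement field under a joint rescaling of all Young's moduli
  (prescribed-displacement loading); monotonicity in x_adv; and a mesh
  refinement study (halving the 5 mm target edge changes each landmark by
  < 5 %).

## The phantom and what it stands for

Real applications segment patient CBCT into anatomy.  Here a rectangular
layered block preserves the mechanical structure the pipeline needs while
staying dependency-free and fast: an 80 × 30 × 80 mm domain (x lateral,
y anterior, z superior), a 10 mm posterior bone plate spanning z ∈
[25, 80] mm, split by a 5 mm osteotomy gap (z ∈ [40, 45] mm, spanning
whole cell layers at both test resolutions so refinement does not change
the carved geometry) into a mobile segment (below) and fixed skull base
(above); a 20 mm soft-tissue slab in front of the bone and filling the
region below it (where the mandible would be); and a 20 × 10 × 15 mm
cartilage block embedded in the soft tissue, bridging the osteotomy level
up to the nose landmark (as the septal/alar cartilage does).  Landmarks
sit on the skin surface: N (0, 30, 50) over the cartilage, UL (0, 30, 30)
in front of the mobile segment, LL (0, 30, 15) below it, RC/LC
(±20, 30, 55) in front of the fixed skull base.  Meshing is a structured
6-tets-per-hex subdivision, mirrored about x = 0 so the mesh is exactly
midline-symmetric, with half-size cells below the bone plate (the region
of small, steep displacements near the clamped bottom edge); the default
5 mm target edge gives ≈2600 nodes and ≈12000 tetrahedra.

This geometry reproduces the qualitative sensitivity pattern of the
application: the advancement dominates every landmark; stiffer cartilage
shields the nose (negative E_cart effect on N); softer, more relaxed
tissue transmits less (negative G_scale effect); the cheeks, lying in
front of fixed bone, respond weakly and are systematically
under-predicted.  It does **not** emulate curved anatomy, distinct
skin/SMAS/fat layers, sliding contacts, bone plates, swelling, or
mandibular autorotation — so passing tests demonstrate that the
*pipeline* behaves as intended on a mechanically analogous system, not
that its numbers transfer to patient anatomy.

## Synthetic subjects and ground truth

Each of the eight cohort records (packaged as a plain CSV fixture with
ages, imaging intervals and planned advancements; the planned advancement
column has mean 4.6 mm) becomes a phantom replicate with hidden true
inputs: material truth = population reference (geometric mean of the range
for the order-of-magnitude E parameters, midpoint for ν and G_scale) plus
truncated-normal jitter with sd 5 % of each range; achieved advancement =
plan + truncated-normal execution error (sd 0.75 mm, clipped at the ±2 mm
uncertainty the planning literature reports).  Observed landmark
displacements are the forward solve at the true inputs plus N(0, 0.1 mm)
measurement noise per landmark, standing in for postoperative CBCT
segmentation/registration error.  Subjects P2, P3, P5, P7, P8 train the
optimisation; P1, P4, P6 are held out for validation, mirroring the
application's split.  All draws are governed by explicit per-stage seeds.

## Pipeline

1. **Screening** (subject P1, 100-run maximin Latin hypercube over all
   eight inputs): Spearman rank correlation of every input against every
   landmark, 95 % CIs by Fisher z with the rank-correlation variance
   1.06/(n−3).  Inputs significant (p < 0.05) against ≥ 1 landmark enter
   later stages as ranges; the rest are frozen at their range midpoint.
   No multiplicity correction is applied (by design), so with 40 pairwise
   tests a truly inert input still has a ≈ 23 % chance of riding in; the
   bone parameters are nevertheless excluded from material optimisation
   by construction.  At the default seed the screen selects E_cart,
   E_soft, G_scale and x_adv; ν_soft's effect on this geometry
   (|r| ≈ 0.13 at n = 100) falls short of the threshold, so the pipeline
   carries three material distributions rather than four — the
   correlation analysis, not a fixed list, decides.
2. **DOE I** (every subject): maximin Latin hypercube (100 restarts) over
   the selected inputs, sized by the central-composite rule
   2^(k−1) + 2k + 1 for k ≥ 5 (27 runs at k = 5; 2^k + 2k + 1 below
   five), one forward solve per row, per-landmark min/max ranges.
   Results are cached on disk keyed by an input hash.
3. **Optimisation** (training subjects): per-landmark response surfaces
   over the selected inputs — full quadratic polynomial vs anisotropic-RBF
   Gaussian process, winner by leave-one-out RMSE (the polynomial's LOO is
   the exact hat-matrix form; the GP's fixes hyperparameters at the
   full-data optimum).  A goal-driven NSGA-II then minimises
   |surrogate − observed| for N, UL, RC, LC (the lower lip is excluded
   because mandibular surgery is not modelled), with x_adv fixed at the
   subject's planned value; this one objective form both matches reachable
   targets and pushes to the admissible bound otherwise.  Settings follow
   the reference configuration: 1000 solutions/iteration (500 in the desk
   preset), ≤ 10 iterations, early stop at < 2 % change of every
   objective's best with ≥ 70 % of the population non-dominated.  The
   "best 100" are the top of the rank-sorted final population by
   equally-weighted, range-normalised objective sum (rank-2 tops up when
   the first front is smaller than 100).
4. **Distribution fit**: candidates pooled row-wise across the five
   training subjects (5 × 100 rows) and a three-parameter Weibull fitted
   per material column by maximum likelihood with the location profiled
   on a refined grid below the sample minimum.  The location shift is
   essential for parameters living far from zero (e.g. a Poisson ratio on
   [0.45, 0.499]); x_adv is *not* fitted — execution uncertainty stays
   uniform at plan ± 2 mm.
5. **DOE II** (validation subjects): materials drawn from the fitted
   Weibulls by stratified inverse-CDF sampling (a Latin hypercube pushed
   through the bound-truncated CDF; ν_soft capped at 0.4999), advancement
   uniform over plan ± 2 mm, one solve per row (default: the DOE I size),
   then envelopes, Freedman–Diaconis histograms and empirical CDFs per
   landmark.
6. **Validation**: truth containment per landmark, distance-to-range when
   outside, and the refinement check DOE II width ≤ DOE I width.

## Problem sizes and runtime

Default study conditions: 5 mm mesh (≈7900 DOF), 16 time steps per solve,
100 screening runs, 27 (or 25) DOE runs per subject and iteration,
NSGA-II population 500.  A full fit-plus-prediction runs in minutes on a
single core; the forward solves dominate, so they are cached and the
solver pre-assembles region-wise unit stiffness blocks that are only
rescaled per realisation.

## Design choices on genuinely open points

* "Optimal space-filling" sampling is realised as maximin-LHS with
  restarts; the commercial "genetic aggregation" response surface is
  replaced by the documented LOO-selected polynomial/GP family.
* Spearman (not Pearson) correlation is used for screening; the screening
  statistic and the CI method are stated above because the application
  leaves both ambiguous.
* The reported displacement is the signed anterior component, not a
  magnitude; baseline is the preoperative state.
* The prediction time protocol, DOE II sample count, and "best 100"
  ranking are package conventions, documented rather than inferred.
* The desk preset (default) halves the genetic-algorithm population to
  500; the `paper` preset restores 1000.

## Known limitations

* The phantom is a block, not a face; absolute millimetre values are
  geometry-specific and only the behavioural pattern is meaningful.
* Linear kinematics and homogeneous soft tissue; no contact, no plates,
  no swelling, no mandible (hence LL is reported but never optimised).
* Envelope containment is a behavioural check, not a calibrated coverage
  statement: the envelope is a min/max over a finite design, and its
  coverage depends on the truth-generator settings documented above.
* Screening selection is seed-dependent near the significance threshold;
  downstream stages follow whatever the screen selects.
* Range refinement (DOE II width ≤ DOE I width) holds with a thin margin.
  The landmarks are dominated by the advancement, whose ±2 mm execution
  uncertainty is identical in both design iterations, so the refinement
  comes entirely from the material share of the variance; on this phantom
  the material leverage (0.1–0.4 mm across a full literature range) is
  comparable to the 0.1 mm observation noise, the optimisation therefore
  cannot pin the materials tightly, and the fitted distributions stay
  broad.  Min/max widths of 27-run designs fluctuate by roughly ±10 %, so
  individual subject/landmark refinement checks can land on either side
  of equality even though the per-landmark average width does shrink.
  The test suite asserts the strict per-subject form and reports the
  outcome as-is.
* Kolmogorov–Smirnov statistics of the pooled Weibull fits typically
  exceed the single-sample 5 % critical value — the pooled data mix five
  subjects with different optimisation targets — and are reported as
  warnings, not failures.
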