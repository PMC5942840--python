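# facefem

Probabilistic finite-element prediction of facial soft-tissue position
after Le Fort I maxillary advancement.

## The problem

Orthognathic surgery repositions the maxilla; planning software predicts
the resulting facial appearance by simulating how the soft tissue follows
the bone.  Deterministic predictions hide two real uncertainties: the
patient's soft-tissue material properties (known only as literature
ranges) and the surgeon's execution of the plan (the achieved advancement
differs from the planned one by as much as ±2 mm).  `facefem` propagates
both through a viscoelastic finite-element model and reports, for each
facial landmark — nose tip (N), upper lip (UL), lower lip (LL), right and
left cheek (RC, LC) — a *prediction envelope*: minimum, maximum,
histogram and cumulative density of the predicted anterior displacement,
rather than a single number.  It is aimed at computational-biomechanics
researchers studying uncertainty quantification for surgical simulation.

## The model

Forward problem: quasi-static small-strain FEM on a layered midface
phantom (fixed skull base, mobile maxillary segment split off by an
osteotomy gap, nasal cartilage inclusion, near-incompressible soft-tissue
layer), with the advancement prescribed on the mobile segment.  The soft
tissue relaxes in shear by a two-term Prony series

    G(t)/G0 = 1 − s·Σᵢ gᵢ(1 − e^(−t/τᵢ)),  g = (0.325, 0.3), τ = (1, 6) s,

(62.5 % total relaxation at s = 1; the scale factor s sweeps
0.488–1.512, i.e. 30.5–94.5 %), with no volumetric relaxation and a
B-bar (node-averaged volumetric strain) treatment against locking at
ν → 0.5.

Around the solver, a two-iteration uncertainty-quantification pipeline:

1. **screen** — Spearman rank correlation of all 8 uncertain inputs
   (E, ν for bone/cartilage/soft tissue; relaxation scale; advancement)
   against the 5 landmarks; non-significant inputs are frozen at their
   range midpoint;
2. **DOE I** — maximin Latin-hypercube design over the selected inputs
   (27 runs for 5 variables), one FEM solve per row → per-landmark
   prediction ranges;
3. **optimise** — per training subject, leave-one-out-selected response
   surfaces (quadratic polynomial vs Gaussian process) and a goal-driven
   NSGA-II minimising |prediction − observed| at N, UL, RC, LC → best
   candidate material vectors;
4. **fit** — candidates pooled over the five training subjects, one
   location-shifted Weibull distribution per material parameter;
5. **DOE II** — designs for the held-out subjects drawn from those
   distributions (advancement stays uniform within plan ± 2 mm) →
   prediction envelopes, validated for truth containment and range
   refinement.

Patient imaging is out of scope: a synthetic-truth generator plays the
role of the postoperative CBCT measurement, with hidden per-subject
material truths and execution errors.  See `docs/methods.md` for the full
model description and design choices.

## Worked example

```python
from facefem import shear_relaxation, scale_for_relaxation
from facefem.model import MaxillaryAdvancementUQ
from facefem.pipeline import desk_config

# Prony arithmetic: long-time relaxation at unit and minimum scale
print(100 * (1 - shear_relaxation(1e6, scale=1.0)))    # 62.5
print(100 * (1 - shear_relaxation(1e6, scale=0.488)))  # 30.5
print(scale_for_relaxation(30.5))                      # 0.488

# Full pipeline on the packaged eight-subject cohort (a few minutes)
res = MaxillaryAdvancementUQ(config=desk_config(seed=0)).fit()
res.predict()          # DOE II on the validation subjects P1, P4, P6
print(res.summary())
```

The summary (abridged; full text in the API) prints the screened inputs,
the fitted Weibull material distributions and the per-subject envelopes:

```
screened inputs (n=100 runs, alpha=0.05):
  selected: E_cart, E_soft, nu_soft, G_scale, x_adv
  frozen:   E_bone=10000, nu_bone=0.3, nu_cart=0.32
...
fitted Weibull material distributions:
            shape   scale  location    n      ks    mean
parameter
E_cart     2.3840  3.3799    0.0500  500  0.1333  3.0459
E_soft     0.9726  0.3893    0.0999  500  0.1044  0.4940
nu_soft    0.7307  0.0156    0.4500  500  0.1013  0.4690
G_scale    2.1707  0.6201    0.3856  500  0.0841  0.9347
...
subject P1 prediction envelopes (mm):
landmark   min   max  truth  contains_truth  refined
       N 0.557 1.361  1.084            True     True
      UL 2.004 4.533  3.388            True     True
      LL 0.599 1.489  0.965            True    False
      RC 0.418 0.985  0.674            True     True
      LC 0.418 0.985  0.897            True     True
```

Read it as: the screen keeps five of the eight uncertain inputs
(advancement dominates every landmark, |r| ≥ 0.82; bone stiffness drops
out), and the optimisation on the training subjects turns the uniform
literature ranges into four fitted Weibull material distributions.  The
probabilistic second design for held-out subject P1 then brackets the
true (synthetic) postoperative displacement at every landmark — in
particular at the nose and upper lip, the clinically decisive points —
and the envelopes of the optimised landmarks are narrower than the
DOE I literature-range predictions (`refined`; LL is never optimised
because the mandible is not modelled).  Landmark displacements are
anterior components in mm with the preoperative position as 0.

The same pipeline runs from the shell, stage by stage (each stage talks
to the next only through files in the run directory):

```bash
facefem run-all --outdir run --seed 1          # or: phantom, screen, doe1,
facefem report  --outdir run                   # optimize, fitdist, doe2,
                                               # validate, report
```

`report` writes range-bar charts, material histograms with the fitted
Weibull curves, per-landmark probability histograms and CDFs, a midline
profile band, min/max displacement fields (VTU) and `summary.json`.

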