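# Methods

## Model and procedure

`toothmove` treats every tooth and every mandible as a rigid body.  The
quantity of interest per tooth is the **prediction difference**: the
six-parameter rigid displacement required to carry the achieved
(post-treatment) crown onto its predicted (planned) position, expressed
in the tooth's own anatomical axes.  The pipeline has four stages:

1. **Case superimposition.**  The T2 (post-treatment) record is mapped
   into the T1 frame where the predicted dentition lives.  A Kabsch
   least-squares fit on three corresponded stable landmarks — pogonion
   and the left/right mental foramina — initialises a point-to-point ICP
   between the mandible surfaces.  The landmarks are anatomically stable
   over treatment, which is what justifies using the mandibular body as
   the common reference.
2. **Crown preparation.**  Crowns are cropped to the occlusal third of
   their extent along the occlusogingival axis: the occlusal surface is
   the most reliably segmented part of a crown, and restricting the fit
   to it avoids gingival-margin segmentation noise.  The anatomical frame
   (+X buccal, +Y mesial, +Z occlusal, right-handed) comes from per-tooth
   orientation hints carried in the manifest; the package never infers
   anatomy from shape, which would be unvalidatable.
3. **Per-tooth fit.**  Both crowns are expressed in the predicted crown's
   local frame, whose origin is the predicted crown's bounding-box
   centre.  Fixing the origin there matters: a rigid transform about an
   arbitrary origin mixes rotation into translation, so the translation
   components would otherwise depend on where the tooth sits in world
   space.  The achieved crown is ICP-fitted onto the predicted one and
   the resulting transform decomposed into (Φ, Θ, Ψ, X, Y, Z).
4. **Statistics.**  One-sample t tests per tooth-type × measure cell with
   Bonferroni correction, adjusted simultaneous CIs, ICC(A,1) and
   Bland–Altman agreement.

## Conventions that had to be fixed

* **Euler sequence.**  "Tait–Bryan" names six possible orderings.  The
  package fixes intrinsic Z(Φ) → Y(Θ) → X(Ψ), i.e. R = Rz·Ry·Rx, used
  identically in composition and decomposition and recorded in every
  serialized output.  For the small rotations typical of aligner
  discrepancies the orderings agree to first order, so the choice does
  not affect clinical interpretation; for large rotations results are
  convention-dependent, which the output metadata makes explicit.
* **Gimbal lock.**  At |Θ| = 90° only Φ∓Ψ is determined.  The
  decomposition then sets Φ := 0, lets Ψ absorb the free angle, issues a
  warning and flags the result, rather than failing — clinical torque
  never approaches 90°.
* **Sign rule.**  The reported transform carries achieved → predicted, so
  an achieved pose displaced +d along one axis yields a prediction
  difference of −d on that axis.  For *composite* displacements the
  expected difference is the six-measure decomposition of the inverse
  transform (Euler angles negate component-wise only for single-axis
  motions); the test suite checks both forms.
* **Axis polarity.**  +Y is mesial, so an achieved tooth sitting distal
  of its prediction yields a positive mesiodistal prediction difference.
  Polarity is a package convention, recorded in outputs.

## Registration numerics

* **Kabsch**: SVD-based with the determinant correction that excludes
  reflections.  Degenerate (near-collinear) sources are rejected when the
  second/first singular-value ratio of the centred source drops below
  1e-6 — with three landmarks the rotation about the line would be free.
* **ICP variant**: point-to-point, correspondences to the nearest point
  on the fixed *triangulated surface* (not the nearest vertex), which
  removes discretisation bias.  The nearest-surface query is exact: a
  KD-tree over triangle centroids prunes candidates using the distance to
  the nearest fixed vertex (an upper bound on the surface distance) plus
  the largest triangle circumradius, then the true closest point is
  evaluated on every candidate triangle.  Defaults: max 200 iterations,
  stop when the RMS improves by < 1e-6 mm — far below the 0.05 mm
  acceptance gate.  The RMS trace is non-increasing by construction
  (each Kabsch step cannot worsen the current correspondences, and
  re-association can only shorten distances).
* **RMS definition**: root-mean-square of closest-point distances over
  the sampled moving vertices; recorded in output metadata since other
  definitions (landmark residuals, all-vertex) exist.  The 0.05
  acceptance gate is read in mm and is inclusive.
* **Fit-target margin**: in case measurement the moving (achieved) crown
  is cropped to its occlusal third, but the fixed fit target is the
  predicted crown cropped 2 mm *deeper*.  Cropping both at the same
  plane would leave moving points near the cut without true counterparts
  whenever the achieved pose is displaced occlusogingivally; those points
  snap to the cut rim and bias the fit (observed as ~1–2° torque/tip
  error in noiseless simulations).  Extending the fixed surface is
  neutral — extra fixed surface never attracts a point whose true
  counterpart exists — and restores noiseless recovery to < 0.001° /
  0.0001 mm.  The local frame and translation origin still come from the
  occlusal-third crop of the predicted crown.
* **Per-tooth initialisation**: identity in the predicted-local frame
  (after case superimposition the crowns are already close); a coarse
  0.5 mm / 5° grid search triggers only if the identity-initialised fit
  stalls above 10× the RMS gate.

## Statistics choices

* **Family size m = 24** (4 tooth types × 6 measures) by default — the
  most conservative defensible family for "all simultaneous comparisons";
  configurable to per-measure (m = 4) or per-type (m = 6).
* **Adjusted CIs** use t_{1−(α/m)/2, n−1}, making CI and test exactly
  dual: the interval excludes 0 iff min(1, m·p) < α.  This duality is
  asserted on every sample in the test suite.
* **ICC form**: ICC(A,1) — two-way, absolute agreement, single measure —
  computed from the ANOVA mean squares; appropriate because the same
  quantities are re-measured, so rater bias must count against
  agreement.  Cross-checked against an independent implementation
  (pingouin) in the tests.
* **Independence assumption**: teeth within a patient are treated as
  independent observations.  This ignores within-patient clustering and
  is a known limitation of the study design; mixed-effects modelling is
  deliberately out of scope.
* Degenerate samples: sd = 0 with mean = 0 gives t = 0, p = 1, CI [0,0];
  sd = 0 with mean ≠ 0 gives p = 0 with a warning.

## Synthetic data: what it emulates and what it does not

The generator exists because no deposited data of this kind is public.
Per case it emits: a T1 mandible slab carrying a chin prominence, two
mental-foramen pits, an asymmetric top ridge, and the three landmark
coordinates; a T2 mandible equal to T1 under a random rigid case
transform (rotations ≤ 10°, translations ≤ 10 mm); 14 predicted crowns
on an elliptical arch (FDI 31–37, 41–47); and achieved crowns displaced
from the predicted ones by per-tooth transforms drawn from
N(μ_type, σ_type), injected about the frame of the cropped predicted
crown in the prediction-difference sign convention, so the measurement
stage should recover exactly the drawn vector.

* **Crown asymmetry is the load-bearing fixture property.**  ICP on a
  rotationally symmetric shape is ill-posed.  Crowns are rounded boxes
  with tooth-type-specific cusp bumps (1 ridge / 1 / 2 / 4 cusps for
  incisor / canine / premolar / molar) of unequal heights plus a lateral
  skew; the suite verifies that a self-fit under a 180° pre-rotation
  leaves RMS > 0.1 mm for every type, rather than assuming asymmetry.
* **Default study conditions**: 5 patients × 14 mandibular teeth (70
  teeth: 20 incisors, 10 canines, 20 premolars, 20 molars); displacement
  spreads σ = 1.5° / 0.25 mm with zero means — sub-clinical spreads of
  the size aligner-prediction discrepancies typically show; surface noise
  0.02 mm (scanner-scale), applied along vertex normals.  The noise model
  is isotropic Gaussian — a stand-in, since real segmentation error is
  spatially correlated.
* **What passing tests show**: that the measurement machinery recovers
  known rigid displacements through the full pipeline, that the case
  transform is fully removed by superimposition, and that the statistics
  are calibrated.  They do not show robustness to anatomy-specific
  segmentation artefacts, partial crown coverage, or non-rigid tooth
  deformation — real-data properties the generator does not emulate.

## Problem sizes

Crowns are subdivided boxes (~770 faces; ~240 vertices after cropping);
mandibles ~3 000 faces with a 2 000-vertex seeded ICP subsample.  These
sizes keep a full five-patient cohort — generation, registration,
measurement and statistics — under a minute on one core while leaving
ICP residuals orders of magnitude below the acceptance gate; the
statistical calibration runs use 1 000 table-level replicates.

## Known limitations

* Occlusal-third cropping is measured along the hinted occlusal axis;
  anatomical long-axis estimation is out of scope.
* The Euler ordering is a convention, not a recovered fact; comparisons
  with other software must match conventions before comparing angles.
* STL carries no units; the package declares millimetres and requires
  consistent per-case coordinates as an input contract.
* Binary STL stores float32 coordinates, so round-trips are exact only
  for float32-representable values (~1e-6 relative precision — far below
  any clinical signal).
* No deformable registration: a crown whose shape changed (restoration,
  wear, segmentation differences) violates the rigidity assumption and
  will surface as elevated fit RMS rather than being corrected.
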