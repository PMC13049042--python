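# Methods

## Coordinate frame and conventions

Right-handed frame with X = medial–lateral, Y = anterior–posterior,
Z = superior–inferior, so the anatomical plane names map literally onto
coordinate planes: transverse = X-Y, coronal = X-Z, sagittal = Y-Z.  All
lengths are millimetres; angles are reported in degrees and computed in
radians.  The sagittal midplane used for mirroring is x = 0.

## Measurement model

The affected proximal femur and the mirrored healthy contralateral are placed
in one frame by rigid registration; the head region is excluded from the
registration so the quantity being measured (the fracture displacement)
cannot bias the alignment — operationally, the fit locks onto trochanter and
shaft morphology.  The head center E is the center of a least-squares sphere
fitted to head-labeled surface vertices; the fovea C is an annotated
landmark.  Indicators: d1 = |C1−C2|, d2 = |E1−E2|, α the angle between the
fovea→center lines, and the three projection angles obtained by orthogonally
projecting both lines onto a coordinate plane and taking the angle between
the projections (the natural reading of plane-wise angle decomposition; no
other decomposition is attempted).

Numerical choices:

* dot products are clamped to [−1, 1] before `arccos` (safety at 0°/180°);
* α is invariant to the common direction convention because both vectors run
  fovea → center and the result lies in [0, 180];
* a projection shorter than 1e-8 of its vector's norm makes the projected
  angle undefined; it is returned as flagged-missing (NaN), never as 0 — a
  silent zero would bias agreement statistics.  Downstream, Bland–Altman and
  pairwise CCC drop such values pairwise, ANOVA-based ICC and the overall
  CCC drop subjects listwise (the balanced design requires complete rows);
  deletion counts are recorded in the outputs.

### Sphere fit

Algebraic (linear least-squares) initialization followed by a
Levenberg–Marquardt refinement of the geometric objective Σ(|p−c|−r)², with
parameter-step tolerance 1e-10 mm and an iteration cap.  Coplanar input makes
the algebraic system rank-deficient and raises a named error.  On noiseless
sphere samples the fit is exact to better than 1e-9 mm.

### Registration

Trimmed point-to-point ICP on vertex clouds: centroid + principal-axes
initialization (all four proper sign assignments scored by nearest-neighbour
distance), Kabsch updates on the best 80 % of correspondences, relative
mean-square-change stopping tolerance 1e-12, cap 100 iterations.  The manual,
visually-guided alignment this replaces has no published convergence
criterion; trimmed ICP is the closest auditable analogue.  On noiseless
phantoms the known transform is recovered to ~1e-13, comfortably inside the
1e-6 contract asserted in tests.

## The phantom

Minimal geometry that exercises every stage: a UV-sphere head (radius 24 mm)
carrying the fovea landmark on its posteroinferior medial surface, cylinders
for neck and proximal shaft, a greater-trochanter ellipsoid giving the
registration an asymmetric feature, and a posteromedial lesser-trochanter
bump that breaks anterior–posterior symmetry so the principal-axes
initialization is unambiguous.  Each primitive is a closed, outward-oriented
component; meshing is deterministic (the RNG seed never affects vertices).
Left and right are exact reflections across x = 0 — the symmetry assumption
of contralateral referencing holds by construction, to 1e-9.

A fracture is a rigid displacement of the head-labeled vertices (rotation
about a pivot at the head center, then translation); ground-truth indicator
values follow in closed form from the transform.

### Between-subject displacement distribution

Translation direction uniform on the sphere; magnitude log-normal; rotation
axis uniform; angle folded-normal.  Scale parameters default to a typical
fracture cohort: translation 13.48 ± 7.41 mm and rotation 26.94 ± 12.12°
preoperatively, 5.51 ± 1.92 mm and 12.84 ± 5.57° postoperatively.  These
calibrate the *generating* translation magnitude and rotation angle; derived
indicators (α, projections) inherit their distributions through the geometry
and are not separately tuned.

### Observer error model

Each observer carries four SDs, applied at the stage where the error
physically enters: isotropic jitter on both fovea annotations (default
1.0 mm), a small random rigid perturbation of the registered reference
(rotation SD 1.0° about a uniform axis through the reference head center,
translation SD 0.5 mm per component), and isotropic jitter on both fitted
head centers (0.5 mm).  Defaults are plausible magnitudes for a manual CT
workflow, fixed once; all-zero SDs reproduce ground truth exactly, and every
agreement statistic then attains its perfect value (tested).

Two simulation routes share the same drawn displacements per seed: the
*landmark* route applies observer noise directly to the true landmark
geometry (fast; used for statistic-level studies), and the *mesh* route runs
the full surface pipeline per subject/observer, composing the observer's
registration perturbation onto the ICP result (the automatic fit is
deterministic, so manual-alignment variability must be injected).  At zero
noise the two routes agree to mesh tolerance (tested).

What the generator does **not** emulate: segmentation/thresholding error,
true femoral anatomy (aspherical heads, neck anteversion variation),
bilateral asymmetry of real patients, or observer bias that is systematic
rather than random.  A green test therefore establishes correctness of the
geometry and statistics pipeline under the stated error model, not clinical
accuracy on real CT data.

## Agreement statistics

* Balanced two-way ANOVA; method-of-moments components σ²ₑ = MSE,
  σ²ᵣ = (MSO − MSE)/n, σ²ₛ = (MSS − MSE)/k.  Negative estimates are reported
  unaltered with a flag, never truncated silently.
* ICC(A,k) = (MSS − MSE)/(MSS + (MSO − MSE)/n), algebraically identical to
  the variance-ratio definition at the estimated components; ICC(A,1) the
  single-measure analogue.  95 % CIs use the F-based absolute-agreement
  method with a Satterthwaite denominator df (McGraw–Wong family; the CI
  method is a package choice, recorded in output metadata).  The p-value is
  the subject-effect F test of H0: ICC = 0.
* CCC/OCCC use population (1/n) moments, matching the overall-CCC formula's
  definition; the overall CCC equals the denominator-weighted average of the
  pairwise CCCs and hence always lies within their span (tested to 1e-12).
* SEM = σ√(1 − ICC(A,k)) with σ the pooled sample SD over all n·k values of
  the indicator.  Published SEMs of this design are not reconstructible from
  summary tables under any simple σ choice, so the choice here is documented
  rather than reverse-engineered, and tagged in the result.
* Bland–Altman uses the sample (n−1) SD and the literal 1.96 multiplier;
  differences are first-argument-minus-second, recorded in the result.
* Paired t-tests compare observer-averaged pre vs post values; no
  multiple-testing correction is applied across the six indicators (none is
  customary for this design), which the report notes.

## Reproducibility

All randomness flows through explicit integer seeds via
`numpy.random.default_rng` seed sequences; identical configs give
byte-identical report CSVs (tested).  Observers share no state: permuting
their processing order permutes matrix columns and changes no number.

## Known limitations

* The sagittal projection θ_yz is intrinsically ill-conditioned here: the
  fovea→center line points mostly medially, so its Y-Z projection is short
  and observer noise is amplified in the projected angle.  Postoperatively
  (smaller rotations) this inflates the sagittal Bland–Altman LoA width by
  roughly 10 % even though no other indicator worsens — the corresponding
  acceptance assertion is deliberately left failing for θ_yz with this
  analysis, and the effect is the synthetic counterpart of sagittal error
  inflation in manual workflows.
* Registration is point-to-point ICP on vertices, adequate for phantoms with
  exact correspondences; real scan pairs would warrant point-to-plane ICP
  and outlier-robust losses.
* The phantom's head is perfectly spherical, so sphere-fit residuals carry
  no model error; real femoral heads are mildly aspherical and the fitted
  center absorbs that asymmetry.
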