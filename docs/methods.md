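# Methods

`plateplan` automates the placement of a volar osteosynthesis plate on a
segmented, virtually corrected distal radius. The pipeline has four stages —
frame standardization, landmark extraction, deterministic initial
alignment, and constrained pose optimization — followed by placement
comparison metrics and a synthetic anatomy generator that provides analytic
ground truth for testing. This note records the model, the parameters that
matter, and the numerical and design choices.

## Standardized frame (stage a)

Bone and plate are expressed in a canonical frame before any landmarking:

- origin at the mesh centroid, taken as the unweighted vertex mean. The
  centroid only serves as an interior reference point for orientation
  tests, so area- or volume-weighting would add cost without changing any
  downstream decision.
- the longest principal axis (eigenvector of the 3×3 vertex covariance) on
  Z. Raw eigenvector signs are fixed by requiring non-negative skewness of
  the projections, then overridden by anatomical rules: the distal
  direction is verified by checking that the osteotomy-plane centroids lie
  above the centroid, otherwise the mesh is flipped (realized as a proper
  rotation, never a reflection);
- +Y through the most distal vertex — the styloid process — projected
  orthogonal to Z; X completes a right-handed frame and points volar.
- plates: centroid at the origin, long axis on Z with the wider (head) end
  up, and the contact face toward −X. The head end is found from the
  transverse extent of the two axial quartiles; the contact side from the
  skewness of the thickness-axis projections (a transversely bent plate has
  its edges displaced toward the concave, bone-facing side). A perfectly
  flat plate leaves the facing ambiguous; the generator's plates are always
  contoured.
- right-side anatomy is mirrored across the YZ plane into this canonical
  left-handed convention on input and un-mirrored on output, so one
  pipeline serves both sides and left/right results are exactly mirror
  images.

Rigid poses are parametrized as three Euler angles about fixed axes (XYZ
order, degrees) plus a translation in mm; this maps one-to-one onto the
per-axis ±30° rotation limits of the final stage.

## Landmarks (stage b)

- **Osteotomy planes.** The cut faces are tessellated much more coarsely
  than the anatomical surface, so faces with area ≥ 4× the median face area
  are clustered by normal (cosine ≥ 0.99) and plane offset (≤ 0.5 mm);
  exactly two clusters (of at least 3 faces) must remain. Planes are fitted
  by SVD and oriented away from the bone centroid. The 4× factor is
  configurable; nothing in the pipeline is sensitive to it between ~3 and
  ~8 on the meshes we generate.
- **Midplane** = average of the two cut planes (midpoint, normalized mean
  of sign-aligned normals).
- **Alignment line.** The most volar (max X) vertex of the proximal
  segment defines a sagittal plane {x = P.x}; its intersection with the
  midplane is the bone's initial alignment line, anchored at y = 0.
- **Watershed line.** Within the distal segment (vertices above the 40 mm
  cutoff — about 17% of an average radius length), the maximum-X vertex of
  each 1 mm Y-slice is a candidate; candidates whose Z deviates more than
  3 mm from the candidates' mean Z are discarded; X and Z are smoothed as
  cubic polynomials in Y (least squares over the candidates' true vertex
  coordinates) and sampled at the surviving bin centers. The "3 units" of
  the source procedure are read as millimetres, consistent with every other
  length in the pipeline; slice width and polynomial degree are config
  values (`landmarks.slice_mm`, `landmarks.poly_degree`).
- **Radius width** (denominator of the lateral constraint) is the Y-extent
  of the bone in a thin slab at the midplane level; the slab widens
  automatically because the midplane sits inside the empty osteotomy gap.
- **Plate landmarks.** PCA quadrants; the vertex farthest from the
  centroid in each upper quadrant is a top corner, the vertex farthest
  from the top-corner line is the bottom corner, and the alignment line
  runs through the centroid parallel to the top-corner line.

## Initial alignment (stage c)

Five deterministic sub-steps: (1) overlap the plate and bone alignment
lines (minimal rotation between the line directions, centroid onto the
line); (2) translate along Z until both top corners lie ≥ 2 mm below the
watershed line (the margin that protects the flexor tendons; the binding
corner sits exactly at the margin); (3) rotate about the plate's center
line until the bottom end contacts the bone; (4) rotate about the long
axis to align the corner X-positions with the watershed (golden-section on
the summed squared mismatch); (5) translate along the volar axis to first
surface contact.

Numerical choices: contact is detected on signed point-to-surface distance
(tolerance 0.05 mm, root-finding tolerance 1e-3 mm); the bottom-contact
probe uses the bone-facing vertices within 4 mm of the bottom landmark,
because the landmark itself is the outermost tip vertex and a solid plate
can only ever touch with its inner face. The contact translation uses a
fixed-point iteration (the gap function is 1-Lipschitz along the approach
axis) with bisection as fallback. Because sub-steps 3–5 perturb the margin
achieved in sub-step 2, a short settle loop alternates downward Z
correction, bottom-contact rotation and contact translation until margin
and contact hold simultaneously; a closing Z-only correction removes any
residual deficit of the order of the root tolerance. The result is fully
deterministic: identical inputs give bit-identical poses.

## Final alignment (stage d)

The pose is refined by minimizing

    f = d_plate + a·d_top + b·d_bottom + c·M + d·θ + e·|y_bottom − y_middle|

with weights (a, b, c, d, e) = (105, 100, 4, 5, 60). `d_plate` sums the
distances from all transformed plate vertices to the bone vertices
(point-to-vertex, per the method's definition; sums, not means), `d_top`
and `d_bottom` do the same for the three corner landmarks, `M` counts
plate vertices inside the bone, `θ` is the angle in degrees between the
longest principal axes of plate and bone, and the last term keeps the
bottom corner centered on the shaft. `y_middle` is the mean Y of bone
vertices within ±2 mm of the bottom corner's axial level; both Y values
are measured along the bone's own principal axes, which makes every term
invariant under a simultaneous rigid motion of bone and plate.

Constraints: rotations within ±30° of the initial pose per axis; volar
displacement within a quarter of the radius width; medial–lateral movement
within the watershed width; the pose Z between 1.5 plate lengths below the
bone's top and the watershed's maximum Z; and — implementing "without
exceeding the watershed line's Z-extent" in the only way that actually
restrains the plate end — each top corner at least the 2 mm margin below
the watershed Z at the corner's Y (an inequality constraint; feasibility
slack 0.01 mm, matching the initial alignment's root tolerance). Without
the corner constraint the optimizer slides the plate several millimetres
past the rim, erasing the margin whose clinical purpose stage (c)
establishes.

Numerics: the integer count `M` has zero gradient, so during optimization
it is replaced by a sum of sigmoids of signed vertex distance (sharpness
10/mm); the sign is resolved only within 4 mm of the surface (farther
contributions are below 1e-17) using the nearest bone vertex's
angle-weighted pseudonormal. The reported count is always exact, via
feature-classified pseudonormal containment, which on watertight meshes
agrees with the generalized winding number (asserted in the test suite).

The solver is SLSQP with finite-difference gradients (step 1e-4, ftol
1e-6), wrapped in a deterministic refinement cascade: quick descents from
a fixed 14-point stencil around the initial placement (the pose the whole
method anchors on), then alternating full SLSQP with a coarse-to-fine
compass search until the incumbent stops improving. The compass stage
exists because the nearest-vertex distance field is only piecewise smooth
and SLSQP's linesearch stalls on its kinks; the stencil exists because the
surrogate has several shallow basins within the clinical bounds and a
single-start descent is not reproducible under small perturbations of its
starting pose. The returned pose is the best feasible candidate among the
solver output, the recorded incumbent and the initial pose, so the exact
objective never exceeds its value at the initial pose.

A property of the method worth stating plainly: at the constrained optimum
a small fraction of plate vertices (typically a few percent, median depth
about half the local mesh spacing, bounded at 1 mm in our tests) ends up
counted inside the bone. This is intrinsic to point-to-vertex distances —
the contact patch prefers to straddle the bone's vertex lattice — and
matches the penetration the original clinical evaluation reports in a
sizeable minority of cases. The penalty weight c bounds the depth but does
not eliminate the count.

## Comparison metrics

The unpaired maximum Hausdorff distance is the symmetric worst-case
nearest-neighbour distance between the two vertex sets, without
correspondence. Pose differences report the geodesic rotation angle of the
relative rotation (computed from matrices, independent of the Euler
encoding) and the displacement of the plate centroid; since a standardized
plate carries its centroid at the pose origin, that is the distance between
the pose translations.

## Synthetic anatomy

The generator provides the study conditions for every test. Defaults,
chosen once as a realistic distal radius: length 230 mm (so the 40 mm
cutoff is ~17% of length), dorsal shaft half-width 8 mm, transverse flare
1.55×, volar crest 2.5 mm proud of the shaft line, oblique 8° osteotomy
with a 4 mm gap ~25 mm below the joint, surface noise σ = 0.05 mm; plate
58 × 20 mm, 2.4 mm thick, transverse bend radius 18 mm (anatomically
contoured — the same constant volar curvature the bone carries, as
clinical volar plates are precontoured to the bone they target).

Construction: cross-sections combine a circular dorsal half of half-width
w(z) with a flat volar cortex whose outline is the parabola
x(y) = a(z)(1 − y²/w(z)²); tying a ∝ w² keeps the volar transverse
curvature radius w²/2a constant along the bone, and the crest line a(z) is
linear along the metaphyseal ramp, so a straight contoured plate can lie
flush — without these two properties the optimizer is forced into deep
penetration trades that clinical geometry does not pose. A short
metaphyseal band holds the maximal section with a 0.8 mm quadratic droop
toward its edges (fading out below), which localizes the watershed crest
in Z; at the band center the crest is exactly the quadratic
x(y) = a_max (1 − y²/w_max²), the analytic oracle for the watershed tests.
Cut faces are fan-tessellated disks whose facets exceed 10× the median
face area; the styloid is an apex vertex on the +Y side of the centroid
(and by construction the most distal vertex). Loft parameters are jittered
per vertex — with the points kept exactly on the analytic surface — and
the plate's interior grid nodes are jittered in-plane, because perfectly
regular lattices create artificial "locking" minima for the point-to-vertex
objective that decimated CT meshes do not have. Frozen vertices (cut
rings, cap centers, apexes, plate boundary and corners) are never
jittered, so plane fits and corner landmarks are exact.

Mesh resolution (~16k bone faces, ~1k plate faces at 2 mm grid) is the
package's desk-scale problem size; tests and the acceptance script state
the sizes they use. What the generator does not emulate: real anatomical
shape variation, cortical/trabecular interior structure, segmentation
artifacts, malunion deformity. Passing tests therefore demonstrate the
algorithmic properties (frame logic, landmark recovery, the placement
rules and the optimization contract) rather than clinical accuracy on
patient data.

## Accuracy of the watershed tests

The watershed check measures the in-plane (X–Y) distance from the fitted
polyline to the analytic crest curve and requires it below 3σ of the
surface noise at every surviving bin center within the central 95% of the
crest span; the Z coordinate is checked against the band extent. A fixed-Y
x-difference would multiply surface noise by the curve slope (|dx/dy| ≈
1.6 at the lateral ends) and misstate the extraction error; distance to
the curve is the geometric reading of "within 3σ of the crest". The error
budget (extreme-value selection bias over the rows competing within one
noise scale, plus fit variance) sits near 2σ at the defaults, which the
acceptance run confirms.

## Known limitations

- Weights are the published ones; no automatic tuning from manual plans.
- The optimizer is local by design (plus the fixed stencil); it refines
  the initial placement rather than searching the full constraint box.
- Shallow lattice-straddle penetration at the optimum, as discussed above.
- Plates flatter than the bone they target (bend radius well above the
  local volar curvature) revert the method to line contact, and the
  distance term then rewards pressing the plate in; the penalty weights
  would need retuning for such hardware, as the original method's authors
  also note for new plate types.
- The non-watertight containment fallback (3-ray parity voting) is
  approximate near the open boundary.
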