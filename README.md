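# plateplan

Automatic osteosynthesis-plate placement planning on 3D bone meshes,
developed for volar plating of distal radius osteotomies.

Corrective osteotomy of a malunited distal radius is routinely planned on
CT-derived 3D models: the surgeon defines the cut, realigns the distal
fragment, and positions the fixation plate — the step that patient-specific
guide design depends on and that costs an expert the most time. `plateplan`
automates the plate positioning. Given a segmented bone STL (with the two
osteotomy cut faces tessellated coarsely, as decimation leaves them), a
plate STL and a side flag, it:

1. **standardizes the frames** — principal-axis alignment with the distal
   direction verified against the osteotomy planes, +Y through the radial
   styloid, +X volar; right-side anatomy is mirrored through one canonical
   left-handed pipeline;
2. **extracts landmarks** — the osteotomy planes (from their oversized
   triangles), the midplane, the volar alignment line, and the watershed
   line (per-slice most-volar points, filtered to a 3 mm Z-band and
   smoothed by polynomial regression);
3. **computes a deterministic initial pose** — alignment lines overlapped,
   the plate's top corners kept ≥ 2 mm below the watershed line (bony
   support without tendon irritation), rotated and translated to surface
   contact;
4. **refines the pose** by SLSQP under clinical constraints (±30° per
   axis, lateral movement within a quarter of the radius width,
   medial–lateral within the watershed width, vertical within 1.5 plate
   lengths of the bone top and below the watershed rim), minimizing

   ```
   f(pose) = d_plate + a·d_top + b·d_bottom + c·M_penalty
             + d·θ_penalty + e·|y_bottom − y_middle|
   ```

   with weights (a, b, c, d, e) = (105, 100, 4, 5, 60): the summed
   plate-to-bone vertex distances, the three key corner distances, the
   count of penetrating plate vertices, the axis-alignment angle and the
   shaft-centering of the bottom corner.

It also ships the placement-comparison measures (unpaired maximum
Hausdorff distance, total 3D rotation and translation between placements)
and a synthetic anatomy generator — a radius-like bone with an analytic
watershed crest, oblique cut faces and a styloid apex, plus a contoured
T-plate — so every stage is testable against closed-form ground truth
without clinical data. See `docs/methods.md` for the full model
description and design choices.

## Worked example

```
$ plateplan synth --out fixtures --seed 0
wrote bone.stl, plate.stl, ground_truth.json to fixtures

$ plateplan place --bone fixtures/bone.stl --plate fixtures/plate.stl \
      --side left --out planned
placed: objective 1510.4 -> 848.0, penetration 12, watershed margin 2.00 mm, converged=True
```

The objective drops from 1510.4 at the deterministic initial pose to 848.0
after constrained refinement — the plate is pulled flush against the volar
surface while the top corners stay exactly 2.00 mm below the watershed
line; 12 of the 463 plate vertices end up marginally (< 1 mm) inside the
bone surface, the shallow lattice-straddle residue the methods note
discusses.
`planned/` contains the standardized bone, the placed plate and a JSON
report with the objective terms and both poses.

Comparing the final placement against the initial one quantifies the
adjustment the optimizer made:

```
$ plateplan compare --a planned/plate_initial.stl --b planned/plate_placed.stl
hausdorff 3.802 mm
```

(Every stage is also importable: `plateplan.run_place`,
`plateplan.optimize_pose`, `plateplan.hausdorff_max`, … operate on in-memory
meshes.)

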