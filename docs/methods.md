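# Methods

## The measurement model

The clinically tracked quantity is the maximal diameter of the aorta in the
plane perpendicular to the vessel — equivalently, the plane through a
centerline point with *minimal cross-sectional area*, since any oblique
plane cuts an elongated, larger section. `aortatrace` discretizes that
definition as a stepwise walk over a binary segmentation:

1. **Initialization.** The centers of mass of the largest in-plane
   component of the two most inferior axial slices (each with at least
   `min_area_mm2` of foreground) seed the position and direction. This
   assumes the descending aorta runs nearly vertically at the diaphragm,
   which holds for thoracic acquisitions cropped there; the assumption is
   documented, not validated.
2. **Propagation.** Each step extrapolates `step_mm` along the direction of
   the two previous centerline points.
3. **Wobble.** Plane normals within a spherical cap of `wobble_max_deg`
   around the travel direction are searched for the minimal *connected*
   cross-sectional area: a coarse grid over two tilt angles (about the base
   frame's in-plane axes, `wobble_coarse_deg` apart), then a local
   refinement at `wobble_fine_deg`. Ties break toward the smallest tilt
   from the travel direction, then lexicographically, so the search is
   fully deterministic.
4. **Connectivity restriction.** The in-plane region is grown 4-connected
   from the current position (seed snapped to the nearest foreground pixel
   within 5 pixels), discarding other crossings of the arch through the
   same plane — essential superiorly, where one plane may cut the aorta two
   or three times.
5. **Re-centering and measurement.** The new centerline point is the
   region's center of mass; the recorded measurements are the region's
   pixel-count area and its maximum and minimum Feret diameters over
   boundary-pixel centers (convex hull + rotating calipers).

No smoothing or spline fitting is applied to the centerline: the diameter
profile, not the curve's exact shape, is the deliverable.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `step_mm` | min voxel edge | walk step; sub-voxel steps add no information |
| `wobble_max_deg` | 30° | half-angle of the orientation search cap |
| `wobble_coarse_deg` / `wobble_fine_deg` | 3° / 0.5° | two-stage grid resolution |
| `min_area_mm2` | 10 mm² | termination floor, below any plausible aortic lumen; stops the walk from chasing thin segmentation spurs |
| `stall_window` | 5 | consecutive direction reversals before declaring a stall |
| `pitch_mm` | min spacing / 2 | measurement-plane pixel pitch; sub-voxel pitch keeps discretization error below the 0.1 mm clinical reporting precision |
| `wobble_pitch_mm` | min spacing | coarser pitch used inside the orientation search |
| `half_fov_floor_mm` | 20 mm | measurement plane half-extent floor; grows to 3× the current radius estimate |
| `lookahead_mm` | 20 mm | ray probe distinguishing enclosed cavitations from true exits |
| `max_steps` | 2000 | hard stop (clinical aortas need 300–400 steps) |

## Numerical choices

**Soft search objective.** Counting thresholded pixels gives an area that
is piecewise constant in the tilt angles — at 1 mm resolution the plateaus
span many degrees, so an argmin over counted areas cannot localize the
perpendicular plane. The search instead minimizes the *soft* connected
area: the sum of the trilinearly interpolated mask values over the
connected component and its one-pixel rim. This is a strictly better
estimator of the same integral and varies smoothly with orientation. The
*recorded* area remains pixel count × pitch², so reported areas have an
exact, simple definition.

**Connectivity at the half-voxel level.** An oblique plane grazing the
inner wall of a bend can leave a sub-pixel neck in the true section; at the
0.5 threshold the rasterized section falls apart and the truncated piece
would masquerade as an area minimum (a numerical check against the
continuum geometry shows the true connected area is monotone in tilt
there). Connectivity is therefore decided on the 0.25 level set — within
half a voxel of the lumen — while measurement stays at 0.5. Genuinely
separate crossings of the vessel, separated by real background, remain
separate.

**Open ends.** The minimal-area objective is degenerate within about half
a radius of a flat open end: a tilted plane wins by clipping the cap. Two
consequences: the walk starts one radius-scaled advance
(`0.6·sqrt(A0/π)`) beyond the seed slices, and the end of the walk is
detected by a direction reversal occurring while the recent areas are
stable, the direction is coherent with recent travel, and a forward ray
leaves the mask for good. Trailing steps whose recorded plane tilts more
than 15° from the local travel direction (the cap-clipping signature) are
trimmed so their obliquely elongated diameters cannot pose as the profile
peak. A profile therefore excludes roughly one radius of vessel at each
open end — the same region where the phantoms' analytic truth is declared
invalid.

**Status taxonomy.** `completed` — the walk left the mask through an end
after a substantive, coherent traverse. `lost_lumen` — no foreground near
the plane seed anywhere in the search cap while foreground reappears along
the forward ray: an enclosed, unsegmented cavitation. `stalled` — repeated
direction reversals or a turn-back (the walk ends far closer to its start
than its farthest excursion). `branch_exit_suspected` — either the area
profile collapses by more than 60% within 10 steps and never recovers to
80% of its pre-drop rolling-median baseline (`detect_branch_exit`, the
walk climbed into a side vessel), or a stall/turn-back happens amid area
spikes exceeding 1.6× the profile median — the signature of measurement
planes slicing longitudinally into a head/neck vessel. The flag is
advisory: no corrective action is taken.

## What the phantoms emulate — and what they do not

The generator rasterizes implicit solids at voxel centers (strictly inside;
optional seeded Gaussian jitter of the wall surface emulates rough manual
segmentation; flat end caps stand for the crop of the imaging volume and
stay exact). Shapes: straight, tilted and elliptical tubes; a half-torus
arch; a candy cane (vertical descending limb + half-torus arch + shorter
ascending limb — the topology of a real arch, with the limbs overrunning
the junction plane slightly so the union rasterizes without a seam); the
candy cane with a supra-aortic branch; and a tube with an interior
spherical cavitation. Each phantom carries its analytic centerline,
area-vs-arc-length and diameter-vs-arc-length functions, valid at least two
radii from the open ends.

Passing on these phantoms demonstrates geometric correctness of the plane
search, the connectivity guard, the Feret measurements and the failure
taxonomy on ideal and defective tubular anatomy. It does not demonstrate
performance on real segmentations, which add wall roughness beyond the
jitter model, multiple adjacent branch ostia, intensity-dependent
segmentation gaps, and anatomical taper and ectasia.

**The branch failure scenario.** The default branch phantom places a
half-caliber branch 60° along the arch, 30° from the local travel
direction, pointing out of the arch plane — a left-subclavian-like
take-off. Systematic exploration (about 35 geometries and jitter settings)
shows that this tracker never *follows* a smooth side branch of up to
0.6× trunk radius: while the seed stays in the trunk, a clean trunk plane
with smaller connected area is always reachable within the search cap, and
the centroid pull toward the branch is bounded by the branch's share of
the merged section. What the branch does cause — deterministically — is an
entangled rattle at the fork: alternating clean and longitudinally sliced
sections, loss of forward progress, and a turn-back. That walk is
classified `branch_exit_suspected` via the spike signature described
above. A genuine climb into a side vessel (which rougher real anatomy can
produce) is flagged by the area-collapse rule of `detect_branch_exit`.

## Agreement statistics

`icc_two_way_single` computes ICC(2,1) — two-way random effects, absolute
agreement, single measurement — from the two-way ANOVA mean squares, with
the F-based 95% interval and the F test of the subject effect. Absolute
agreement (not consistency) is the clinically meaningful variant when the
automated measurement is to be interchangeable with the manual one. Missing
values are dropped pairwise per site, matching reference tables whose N
varies by site. Note the finite-sample estimate can fall below −1 for
strongly discordant pairs (the population quantity cannot); values are
reported unclamped so they remain exactly reproducible against the ANOVA
decomposition. The profile peak excludes steps flagged by the spike filter
(diameter > 1.5× a centered 15-step rolling median) — spikes are kept in
the profile output as orientation cues, as in clinical review practice.
The 50% spike threshold is a package choice; spikes are described only
qualitatively in the clinical workflow this mirrors.

## Problem sizes

Default analyses use tubes of radius 8–15 mm and length 80–120 mm, a
candy-cane arch of trunk radius 12 mm and arch radius 35 mm (about 205 mm
of centerline), 1 mm isotropic voxels, 0.5 mm measurement pitch and 1 mm
steps — the caliber, curvature and resolution regime of thoracic cardiac
MR. Each phantom tracks in well under a minute on one CPU; the full
verification suite and the acceptance script each complete in a few
minutes.

## Known limitations

- The first and last ~one radius of vessel are not profiled (open-end
  degeneracy, above); step counts are correspondingly below tube length /
  step size by about one diameter.
- Diameters carry a positive bias of up to ~2·pitch on circular sections
  (boundary pixels at the interpolated 0.5 surface), within the stated
  recovery tolerances.
- The wobble cap of ±30° assumes the vessel bends by less than 30° per
  re-centering scale; tighter kinks than a normal or dilated arch would
  defeat the search.
- On a steeply expanding lumen (cone half-angle ≳ 20°) the minimal-area
  plane is genuinely oblique and local diameters are overestimated; gentle
  fusiform dilation is handled correctly.
- `branch_exit_suspected` via the spike signature is a heuristic
  classification of fork entanglement; it cannot distinguish which vessel
  ultimately captured the walk.
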