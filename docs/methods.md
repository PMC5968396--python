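# Methods

## Model overview

`corovasc` builds an organ-scale model of the human coronary arterial
circulation in three stages and then measures the spatial heterogeneity of
the blood flow (BF) it delivers.

1. **Topology.** Two binary arterial trees are generated stochastically per
   heart — the right coronary artery (RCA) and the left anterior descending
   artery (LAD), the latter carrying the left circumflex (LCX) as an
   order-10 sub-tree attached at a junction in the proximal third of the
   LAD trunk.  Vessels are classified by Strahler number (SN); the model
   spans SN 6 (smallest resolved arterioles) to SN 11 (main coronaries).
   Elements (chains of same-order segments sharing one radius) are drawn
   from per-order statistics: segment count 1 + Poisson(spe − 1) where spe
   is the segments-per-element ratio, segment lengths from a zero-truncated
   normal, radius equal to the order mean.  Each internal junction of an
   element spawns one lower-order side branch drawn from the element
   connectivity matrix row (the row minus the two terminating order-(m−1)
   daughters, clipped at zero and renormalized); each element of order
   m > 6 ends in two order-(m−1) daughters.  Trunk lengths are enforced by
   rejection: RCA in [120, 192] mm, LAD and LCX in [100, 160] mm.
2. **Geometry.** Trunks are laid along parametric epicardial paths (RCA
   wrapping the right AV groove, LAD descending anteriorly base-to-apex and
   wrapping the apex, LCX leaving its LAD attachment around the left
   lateral wall).  Every other node is placed root-outward by the
   space-filling rule: branching angles from the law-of-cosines
   construction on vectors of magnitude Q/r²; a self-avoidance vector
   summing decaying unit pulls away from already-placed distal nodes of
   segments at least as large as the smaller daughter (weight
   (L_s/d)^ξ / (1 + (L_s/d)^ξ), ξ = 2); a boundary-avoidance vector
   summing inward wall normals weighted by exp(−d/2L); their unit-weighted
   combination (c_s = c_b = 0.5) defines the branching plane, and the
   daughter directions are rotations of it by ±θ about the plane normal.
   Daughters landing outside tissue are stepped back along the
   violated-wall direction (step L/20, direction refreshed every 10 steps,
   budget 200 steps); irreparably placed sub-trees are pruned and flows
   re-solved.
3. **Hemodynamics.** Segment resistance is Poiseuille, R = 8μL/(πr⁴), with
   μ = 3.6 × 10⁻³ Pa·s.  With every terminal held at 20 mmHg and the inlet
   at 100 mmHg (control), the tree reduces exactly: downstream equivalent
   resistances leaf-to-root (series along chains, parallel at
   bifurcations), then flows split top-down by downstream conductance.
   The splitting form is algebraically identical to propagating ΔP = RQ
   but conserves flow to machine precision even where distal pressures
   approach the terminal pressure within rounding.

An ensemble of instances (540 by default, matching the study scale; the
analyses below state the sizes actually used) is voxelized: each
instance's terminal outflows are summed into the 1 mm³ voxels containing
the terminal coordinates, and the ensemble mean is the BF map.

## Heterogeneity measures

* **Relative flow**: d_j = (a_j/m_j)/(A/M) with per-voxel flow a_j, voxel
  mass m_j (1 at native resolution, the tissue-voxel count of a block
  after coarsening), total flow A and total mass M.  The mass-weighted
  mean of d_j is 1 by construction.
* **Relative dispersion (RD)**: mass-weighted standard deviation of the
  d_j themselves; the binned density is used only for display and
  modality counting, removing bin-width sensitivity.
* **Fractal dimension (FD)**: from RD at the native resolution and at the
  paired low resolution (adjacent voxel pairs along one axis, nominal
  mass ratio 2 — the literal two-mass reading of the scaling relation
  RD(m₂) = RD(m₁)(m₂/m₁)^(1−D); a 2×2×2 mode is available),
  D = 1 − log(RD_low/RD_high)/log(mass ratio).
* **Convergence**: FD is computed on cumulative sub-ensembles and fitted
  with FD(n) = A + B·exp(−n/τ); A is the reported asymptote.
* **Transmural profiles**: each tissue voxel's distance to its own
  ventricle's endocardial surface (exact nearest point on the ellipsoid)
  assigns it to a 1 mm layer; layer 1 (1–2 mm) is the sub-endocardium.
* **Modality**: local maxima of the 5-bin moving-average-smoothed density
  with prominence ≥ 5% of the maximum; a plateau counts once and any
  non-empty density counts at least one mode.

Relative-flow quantities are invariant under uniform scaling of the map,
hence under any inlet-pressure change at fixed structure; this is exact in
the resistive network and verified to 1e−9 in the tests.

## Anatomy

Idealized truncated-ellipsoid ventricles: LV wall between concentric
ellipsoids with semi-axes (27, 27, 53)/(36, 36, 62) → defaults
(25.5, 25.5, 49.5) endo and (34, 34, 58) epi mm; RV free wall the crescent
between an offset pair (42, 37, 47)/(48, 42, 52) mm centred at
(−14, 0, −2), clipped to the outside of the LV epicardium; both truncated
by the basal plane z = 10 mm.  The RV offset is chosen so the RV pair's
left-side closure stays inside the LV epicardium — otherwise a spurious
free-wall sliver appears beyond the left epicardial surface.  Tissue
membership is boundary-inclusive.  The default mask holds ≈ 1.4 × 10⁵
voxels of 1 mm³, an adult-scale biventricular myocardium.

## The morphometry fixture and what it can and cannot reproduce

The exact cast-morphometry tables and anatomy dimensions this model class
is built from are not published with the source study; the packaged
fixture is a literature-scale stand-in, fully replaceable through the YAML
interface.  Two printed quantities anchor it: the SN 11 diameter (3.2 mm)
fixes the human diameter scaling, and the control mean voxel BF
(~3.7 mm³/s) fixes the joint conductance of the lower orders — with no
arteriolar/capillary orders below SN 6 in the network, the SN 6–9 radii
are effective parameters absorbing the missing downstream resistance, and
the model's absolute flows are accordingly far above physiological
perfusion, as is inherent to this truncation.

One consequence is worth stating plainly: the printed anchors are not
jointly attainable.  A mean of ~3.7 mm³/s over ~1.4 × 10⁵ voxels implies
~5 × 10⁵ mm³/s of total flow; if ~15% of that crossed the mid-LAD trunk
(the published effect of severe mid-LAD stenosis), the Poiseuille drop
along a 1.6 mm-radius, ≥100 mm trunk would exceed the entire 80 mmHg
driving pressure.  The fixture therefore keeps the mean-BF anchor; under
it the mid-trunk carries only a few percent of total flow, most of which
returns through proximal side branches when the segment is stenosed, so
the severe-stenosis experiments reproduce the direction but not the
magnitude of the published perfusion loss, and the map's fractal dimension
barely responds to the stenosis.

A second structural limitation is sampling density.  With ~2.7 × 10³
SN 6 terminals per heart and ensembles of 200–540 instances, a voxel
receives ~2–4 deposits on average, so the ensemble-mean map carries
substantial shot noise: the control relative dispersion is dominated by
it, the relative-flow density has its mode at zero, and the measured FD
decays with ensemble size toward a structural asymptote near 1.  The
published maps were evidently built from trees with several-fold more
terminals; at that density a distinct low-flow mode can separate from the
main peak under severe stenosis, which this fixture's maps cannot show.
Conclusions from passing tests therefore transfer to real data only for
the structural and conservation properties, the pressure-scaling
invariances, and the qualitative ensemble statistics — not for absolute
modality structure of the PDFs.

## Numerical choices

* Units: SI internally (Pa, m³/s); mm, mmHg, mm³/s at every interface
  (1 mmHg = 133.322 Pa).
* Nearest point on an ellipsoid by 80-step bisection of the standard
  one-parameter projection (exact to ~1e−6 mm; on-axis interior points
  perturbed by 1e−9 mm to select a unique projection).
* The branching-angle formula uses the corrected law-of-cosines index
  convention (straight continuation ⇒ zero angle); the as-printed variant
  (which yields 90° in that limit) is available behind
  `AvoidanceParams(strict_printed_angles=True)`.
* Self-avoidance contributors are the distal nodes of placed segments, per
  the figure-level description of the rule (the prose says "upstream";
  distal is the more specific reading and is the default).
* Junctions of equal depth are placed as one vectorized batch;
  within-batch siblings do not see each other in the self-avoidance sum.
  Their interaction is dominated by the ±θ split at the shared junction;
  batching makes the per-instance cost ~1.5 s instead of minutes.
* Single-daughter nodes (mid-element chain nodes of SN 6 elements, and
  junctions left behind by pruning) continue along the unit sum of the
  parent direction and the combined avoidance vector.
* Pruning may leave leaves of order > 6; the terminal pressure boundary is
  applied at every leaf and voxel deposits are taken at every leaf.
* Coarsening truncates trailing partial blocks; block mass is the
  constituent tissue-voxel count, and relative-flow moments are
  mass-weighted throughout.
* Degenerate fallbacks: both avoidance vectors zero ⇒ the parent
  direction; branching plane undefined (parallel vectors) ⇒ a fixed
  reference axis orthogonalized against the direction.

## Problem sizes used

The packaged analyses use ensembles of 200 instances in the test suite
and 300 in the acceptance script, with FD convergence evaluated on
cumulative sub-ensembles up to the full size.  These sizes sit on the
flat part of the convergence curve fit and keep a full run in the
minutes range on one CPU; the 540-instance study-scale default remains
`EnsembleSpec.n_instances`.

## Known limitations

Steady-state flow only (no pulsatility, autoregulation, or
haematocrit-dependent viscosity); uniform radius within an element (no
diameter asymmetry); SN 9–11 vessels are not constrained to the
epicardial surface beyond their trunk paths; position assignment is the
deterministic space-filling rule, not an energy optimization; the NRRD
voxel format is not read (NIfTI only).
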