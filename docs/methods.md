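# Methods

## Coordinate conventions and scene model

A scene lives in a fixed nanometer frame: the presynaptic membrane is the
plane `z = 0` with the cytoplasm at `z > 0`; the long axis of the AZM band
runs along `+y`; the transverse axis is `x`. "Distance to the presynaptic
membrane" is therefore exactly a z coordinate, and a vesicle's shortest
membrane distance is `max(center_z − z_semi_axis, 0)`.

The membrane is modeled flat. Real active zones sit on a ridge where the
membrane curves into the synaptic cleft, but every statistic computed here
is defined relative to the flat portion, so ridge curvature would change
no output while complicating every distance definition.

Vesicles are spheres; after artificial z-compression they become oblate
spheroids storing a separate z semi-axis (the x–y radius is untouched).
Filaments are classed polylines with a diameter attribute (steps carry
separate horizontal and vertical diameters, masts a strand count).
Connection sites are never stored independently: they are derived,
bijectively, from vesicle-bound filament endpoints, which makes the
"one site per binding" conservation law structural rather than checked.

Surface-binding and membrane-contact tolerances are 0.5 nm, well below
the 2–3 nm resolution of the reconstructions the geometry emulates.

## The synthetic generator

The generator emulates the measured organization of a straight stretch of
a frog neuromuscular-junction active zone:

* **Core scaffold.** Beam segments (length 75.1 ± 13.1 nm) laid end to end
  along the midline at half-diameter height; steps (28.4 ± 7.6 nm long)
  at center-to-center intervals of 48.8 ± 14.9 nm on top of the beams; one
  mast (31.5 ± 4.5 nm) rising vertically from each step. The last step and
  beam may extend past the nominal band end: censoring boundary draws
  would bias the realized spacing and length distributions low.
* **Docked vesicles.** Diameter uniform on [50, 60] nm (only the range is
  reported for the source data). One vesicle per row per inter-step gap,
  centered at the gap midpoint, touching the membrane (center z = radius),
  rows mirrored in x at the band half-width plus the vesicle radius. Each
  step is thus centered between a tetrad of four docked vesicles and each
  vesicle is flanked by two steps/masts.
* **Connections.** Per docked vesicle: ribs (count round-normal 3.9 ± 0.6)
  from the beam, two-ish spars (2.2 ± 0.5) alternating between the two
  flanking steps, booms from the two flanking masts, pins (integer 3–5,
  mean 4.1) from the membrane on the away-facing hemisphere, and ~10
  unorganized non-AZM filaments. Connection-site depths follow the layered
  structure: rib sites at z = 7.7 ± 3.3 nm, spar sites at the vesicle's
  realized rib centroid + 10.3 ± 4.4 nm, boom sites at rib centroid +
  24.2 ± 6.6 nm (clipped to the sphere with a metadata warning when a draw
  exceeds the vesicle top). Site azimuths are spread evenly (with jitter)
  over the AZM-facing hemisphere — rib and pin sites together therefore
  ring the fusion domain.
* **Topmasts.** 1–2 per mast, connecting the mast deep end to undocked
  vesicles placed 45–75 nm from the membrane near the midline. These deep
  vesicles sit beyond the farthest connectivity bin by construction.

### Filament path construction

Three measured quantities are exact by construction for every rib, spar
and boom: the arc length equals the drawn class length; the
horizontal-plane direction makes the drawn approach angle with the
perpendicular to the band axis (sign of the along-band component random);
and the vesicle endpoint sits at the drawn site depth. The non-vesicle
endpoint then lands near its parent structure: its height targets the
parent height (beam top, step plane, or for booms a drawn origin height of
39.0 ± 7.7 nm on the mast), clamped to ±0.95 of the filament length when
a draw cannot span the gap. This ordering means the angle-measurement
protocol (a projection) recovers the configured angle distribution with no
projection-bias correction, and length/depth statistics recover their
configured means; the boom origin height is the one quantity treated as a
soft target (no measurement operator reads it back).

Pins are nearly vertical: length drawn (8.6 ± 3.5 nm), tilt uniform on
[0°, 25°], membrane anchor placed so the pin length is exact.

### Draw distributions

Continuous quantities use normals truncated to their physical range
(lengths/depths at 0, angles to [0°, 90°]) with the location parameter
solved so the **truncated mean equals the configured mean** and the scale
kept at the configured SD. Plain truncation would inflate realized means
whenever the mean is within ~2 SD of a bound (≈ +0.6° for rib angles),
which would show up as a systematic bias at large pooled n. The realized
SD of a truncated draw is slightly below the configured SD; means, not
SDs, are the recovery targets. Integer counts are normal draws rounded
and clipped to their stated range (rounding is mean-preserving to well
under 0.01 for the SDs used here).

Boom counts are parameterized per mast (10.6 ± 1.8 shared over a tetrad)
but realized per vesicle: each docked vesicle's count is the rounded sum
of its two flanking masts' per-tetrad-member rates (drawn total / 4),
then split between the masts. This keeps the per-vesicle mean at
2 × 10.6/4 = 5.3 independent of band ends (end masts have two-vesicle
tetrads), and makes the degenerate (all-SDs-zero) configuration emit
exactly round(5.3) = 5 booms per vesicle. The source reports booms per
vesicle as 5.0 ± 2.0 — the ~0.3 discrepancy between its per-mast and
per-vesicle statistics is internal to the source data and is left as is.

### Activated scenes

A configured fraction (default 0.5) of docked vesicles is vacated. One
vacated position (by default) becomes a fused, Ω-shaped former docked
vesicle retaining its full main-body complement but no pins. Every other
vacated position receives an undocked replacement vesicle at a membrane
distance drawn uniformly within a distance bin, cycling the three bins
round-robin so all bins fill evenly (the source's per-bin sample sizes
are not reported). Wiring follows the bin rules: booms always
(4.8–5.6 ± ~1 per bin), spars and ribs gated by bin (far bin: 0.3 spars,
no ribs; middle: 1.7 spars, 1.3 ribs; near: 1.9 spars, 3.6 ribs), site
depths offset from the vesicle's lowest point by the same class depth
structure as docked vesicles.

Pins attach only to vesicles within 15 nm of the membrane. A pin's length
is the vesicle distance plus a nonnegative moment-matched offset whose
mean makes the marginal pin length 16.5 ± 6.5 nm over the pin-bearing
distance range — this realizes "pin length grows with vesicle distance"
while keeping the geometry feasible (a pin can never be shorter than the
gap it spans); drawing length and distance independently would force
rejections and bias the mean.

## Measurement operators

* **Length**: polyline arc length (invariant under rigid motion).
* **Step spacing**: Euclidean distances between consecutive step
  centroids ordered along the band axis.
* **Angle of approach**: project the filament's long-axis direction
  (non-vesicle endpoint → vesicle endpoint) onto the horizontal plane;
  report the unsigned angle to the perpendicular of the band axis, range
  [0°, 90°]; vertical filaments raise an undefined-angle error.
* **Connection counts**: per vesicle per class, with the main-body total
  = ribs + spars + booms.
* **Compression**: the estimate is the mean vesicle z/x–y diameter ratio;
  the stretch correction multiplies all z coordinates (and z semi-axes)
  by a factor — the standard 1.2 applied to a 0.805 compression leaves a
  residual ratio of 0.966, and the exact inverse restores coordinates to
  machine precision.
* All summary SDs are sample SDs (n − 1).

## Unit-sphere alignment

Each vesicle's sites map to unit vectors (site − center, normalized),
normalizing vesicle-diameter variability. Rough alignment rotates each
vesicle's mean site direction onto a common axis by the minimal-angle
rotation (identity fallback, with a warning, for a degenerate zero mean).
Fine alignment maximizes the **rib connection overlap**

    O = Σ_pairs exp(−d² / 2σ²),

summed over unordered pairs of rib sites from different vesicles, `d` the
great-circle distance and σ the bandwidth (default 0.3 rad, configurable).
The original overlap functional is not recoverable from the source (it is
printed only as an image), so this Gaussian kernel is a declared
substitute chosen for its required invariances — smooth, symmetric under
vesicle relabeling, invariant under a common rotation — not a
reconstruction; any kernel with those properties could be swapped in.

The optimizer is per-vesicle coordinate ascent: for each vesicle in id
order, scan a coarse Euler-angle grid (default 10°, candidates pre-sorted
by rotation magnitude so ties break toward the smaller rotation), refine
the best grid point with Nelder–Mead, and accept only improvements — so
the objective trace is monotone non-decreasing and the procedure is
deterministic. On two-vesicle instances it reaches the 5°-grid exhaustive
optimum and recovers planted relative rotations to well under 5°.

Class-centroid depth statistics do not depend on the alignment: depth is
the physical z of a site, averaged per class per vesicle, and offsets are
normalized per vesicle to its rib centroid. The between-class "distance"
is read as this membrane-depth difference (matching the per-vesicle
rib-normalization step); a 3-D centroid-to-centroid reading would be a
different statistic and is not implemented. Class separation uses one-way
ANOVA on per-site depths; if all group means coincide, F is reported as 0
(p = 1) rather than the indeterminate 0/0.

## Distance-binned connectivity

Bins are closed intervals keeping the reported gaps — [4, 16], [17, 24],
[29, 42] nm — and vesicles falling between bins (e.g. at 26 nm) are
reported as "unbinned", never silently dropped or reassigned: inventing
ownership of the gaps would fabricate data. Profile comparisons use
Welch's t-test (the safe default under unequal n and variance).

Two comparisons need care:

* **Near bin vs docked.** The equivalence of the near-bin profile to the
  docked profile is a *power-limited* claim at the original sample sizes
  (~6 near-bin vesicles against 20 docked). The configured near-bin means
  (ribs 3.6 vs 3.9, spars 1.9 vs 2.2) differ slightly by construction, so
  a test on hundreds of pooled vesicles would (correctly) detect the
  difference. The equivalence tests therefore compare at the study scale,
  where all four classes are non-significant, and that is how the claim
  should be read: same complement, not identical rates.
* **Pins.** The pin-count statistic (3.8 ± 0.5) applies to vesicles
  within the 15 nm pin reach; near-bin vesicles at 15–16 nm are
  structurally pinless, so pin comparisons are restricted to pin-bearing
  vesicles.

## Serialization and determinism

Scenes serialize to versioned JSON with sorted keys and 6-decimal float
formatting (sub-tolerance for every invariant), so identical scenes are
byte-identical and the full generate → measure → align → profile pipeline
is reproducible from (config, seed). One master seed spawns per-stage
child generators; unknown JSON fields, version mismatches, dangling
references and stored-vs-derived connection-site mismatches are distinct
error types. Scene validation returns violations as data (never raises)
and is idempotent.

## Problem sizes and runtime

Default analyses pool 30 resting scenes (≈500 docked vesicles, ≈260 step
gaps, ≈2000 ribs) and 12 activated scenes (≥20 undocked vesicles per
distance bin) — a few seconds of generation — which puts every pooled
standard error comfortably inside the recovery tolerances. Alignment
tests use a 300 nm band (8 vesicles, ~200 sites) with a 15° grid, and the
exhaustive oracle runs on two-vesicle instances at 5°.

## Limitations

* The generator reproduces first and second moments and the layered
  topology, not real tomographic noise: no segmentation error, missing
  wedge anisotropy, stain variability, or curved/branched filaments
  (straight 2-point paths except the multi-segment beams). Passing
  recovery tests shows the measurement operators are unbiased on clean
  geometry, not that they are robust to reconstruction artifacts.
* Step horizontal/vertical diameters are stored attributes; no operator
  estimates them from geometry (the originals were measured with a
  thickness tool on surface models not reproduced here). Peg
  macromolecules and the mast-strand fine structure are out of scope.
* Bands are straight; the occasional angular changes of real bands (and
  the larger steps found there) are not generated.
* Vesicle-vesicle overlap is not forbidden: at ~49 nm spacing and
  50–60 nm diameters, neighboring vesicles may interpenetrate slightly,
  as a flat-membrane simplification.
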