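# Methods

## Problem and model

Pretreatment patient-specific QA for step-and-shoot IMRT is usually
measured with the gantry parked at 0°, although treatment delivers the
beams at their planned gantry angles. Gravity displaces MLC leaves as the
gantry rotates, so the narrow over/underdose lines at MLC leaf-abutment
positions differ between 0° and the treatment angle. `gacdose` implements
a correction chain that measures this angular dependence with an EPID,
turns it into per-angle lookup tables, and folds it into a 3D dose
prediction built from 0° QA measurements:

1. **Non-gap test.** Ten abutting 2 cm × 20 cm MLC strips (1 MU each, no
   leaf gap) are delivered onto the EPID and summed into a composite
   image. At each of the 9 × 19 = 171 abutment nodes the ratio
   R = A/B × 100 is formed, where A is the mean pixel value in a
   10 mm × 5 mm ROI on the abutment and B the mean of the two flanking
   open-field strip-center ROIs. R > 100 flags an overdose line, R < 100
   an underdose line. B-normalisation removes output and profile
   variations, so R is scale-invariant.
2. **Calibration.** Film-derived relative dose ratios are regressed on
   the EPID pixel ratios (OLS). Only the slope s (dose-ratio change per
   pixel-ratio unit, nominally 0.0203) is used downstream: corrections
   are formed as differences against the 0° reference, so the intercept
   cancels by construction.
3. **GAC table.** For every measured angle θ, δ(θ, leaf, x) =
   s · (R(θ) − R(0)) is a fractional dose delta on the abutment lattice.
   Queries interpolate linearly between abutment nodes of the same leaf
   (constant extrapolation beyond the outermost nodes) and linearly on
   the circle between the two adjacent measured angles; leaf rows are
   never interpolated across, because leaves are mechanically
   independent. The table is purely empirical — no model of the
   underlying leaf sag is attempted.
4. **Prediction.** Per beam, a fractional 2D error map e(u, v) is built
   from the planned coronal plane (1-mm grid, 10 cm depth) and the
   sparse diode-array measurement. Abutments are detected on the
   TPS-exported segmented intensity map (adjacent 1-mm samples differing
   by ≥ 1% of the beam maximum; runs within 1 mm merged at their
   |difference|-weighted centroid) and matched to plan segments within
   1.5 mm. The GAC delta, weighted by the matched segment's MU fraction,
   is added to e over a 2-mm band at the abutment within its leaf row.
   Each voxel of the per-beam planned 3D grid is divergently projected
   onto the beam's-eye-view isocenter plane (IEC 61217 rotation, point
   source at SAD 100 cm) and scaled by 1 + e(u, v); the predicted total
   is the voxelwise sum over beams.
5. **Evaluation.** Gamma index (global normalisation to the reference
   maximum; search lattice step DTA/10 within radius 3·DTA), signed dose
   difference in % of the reference maximum, distance-to-agreement with
   a saturation cap, DVH indices (ICRU-83 reading of Dx as the dose
   received by at least x% of the volume, linearly interpolated), and a
   two-tailed paired Student's t-test for cohort comparisons.

## Key conventions and numerical choices

- **Frames and units.** Millimetres and Gray everywhere. One right-handed
  patient frame (IEC 61217 fixed: x lateral = leaf travel at gantry 0,
  y longitudinal = leaf width, z vertical toward the gantry-0 source) is
  used for dose grids, structures and projection; structure polygon
  stacks are sliced along y. Grids are voxel/pixel-center addressed.
- **Composite = per-pixel sum**, assuming a linear detector response
  (each strip carries the same MU). Frame-averaged exposures are treated
  as one image per strip.
- **ROI geometry.** The abutment ROI is 10 mm along leaf travel × 5 mm
  along leaf width at isocenter scale, centered on (abutment x, leaf
  center); both orientations are configurable. Field sizes and abutment
  coordinates are reported at isocenter scale (detector coordinates
  divided by SID/SAD = 1.5).
- **FWHM field size.** The profile is averaged over the central 5 mm of
  the leaf's width; the 50% reference level is the mean over the central
  half of the *nominal* field (robust against abutment lines, unlike a
  global maximum); edges are located by linear sub-pixel interpolation
  scanning from outside inward. Per-side error is |measured edge| −
  nominal half-size, positive when the opening is larger than nominal.
- **Difference, not quotient.** The per-angle correction is the slope
  times the *difference* of ratio-percent values. This is the only
  reading consistent with a slope quoted per pixel-ratio unit; a
  quotient of ratios would not have units of ratio change.
- **Error-map interpolation.** The fractional error is formed at each
  diode sample (against the planned dose interpolated to the diode
  position) and the *ratio* is interpolated onto the 1-mm grid.
  Interpolating raw diode doses instead would manufacture spurious
  errors wherever the dose varies nonlinearly between 7-mm samples
  (penumbra), and would break the exact closure property (perfect
  measurement ⇒ prediction ≡ plan) that anchors the test suite.
- **Additive GAC combination.** The GAC delta adds to the measured
  fractional error at abutment bands; at the few-percent magnitudes
  involved an additive and a multiplicative composition differ only at
  second order. The injection is restricted to in-field (masked) points.
- **MU weighting and tie-break.** An abutment formed by a segment
  delivering a fraction f of the beam MU perturbs the beam dose by f
  times the full-exposure delta. Where two adjacent segments share a
  boundary leaf end, the abutment is attributed to the lowest-index
  matching segment (deterministic). Detected steps with no matching
  segment end within 1.5 mm carry no MU weight and are skipped by the
  injection.
- **Back-projection.** Divergent (point-source) projection with a
  multiplicative 1 + e model per beam; the error map's depth dependence
  is ignored (single measurement plane at 10 cm depth, the QA geometry).
  Outside the map or off-mask, e = 0.
- **Gamma.** Global normalisation to the reference maximum; γ = 1 counts
  as a pass (boundary tolerance 1e-9); points below the low-dose
  threshold (default 10%) are excluded from the rate. The default search
  lattice (step DTA/10, radius 3·DTA) is validated against a brute-force
  exhaustive search in the test suite; for 3D grids a coarser
  `search_step` can be passed explicitly. Gamma is asymmetric; the
  reference supplies grid and normalisation.
- **DTA.** Agreement at an offset means the evaluated dose matches the
  reference point's dose within 0.1% of the reference maximum or the
  residual changes sign (an equal-dose crossing); the map saturates at
  the search radius in flat disagreeing regions.
- **DVH.** Dx via `numpy` linear-interpolation quantiles of the masked
  voxel doses (equivalent to reading the linearly interpolated
  cumulative DVH); VxGy as the percentage of masked voxels at or above
  x Gy. Structures are rasterized by voxel-center-in-polygon with the
  even-odd rule (contours on one slice combine by exclusive-or);
  partial-volume weighting is deliberately not used, for testability.
- **RT Dose quantisation.** Doses are stored as 32-bit unsigned integers
  with the scaling chosen to fill the range; round-trip error is at most
  one scaling quantum.
- **Text dose planes.** Two header lines (`# origin_mm:`, `# spacing_mm:`)
  followed by the row-major matrix. The dialect is a repository
  convention; TPS text exports vary and should be converted to it.

## Synthetic data: what it emulates, what it does not

The generators (`gacdose.synthetic`) reproduce the *study conditions*:
a 1024 × 1024 EPID at 0.40 mm/px and SID 150 cm; ten 2 cm × 20 cm strips
with error-function penumbra (σ = 2 mm at isocenter scale, typical of a
flat panel in air); the ten-angle QA set {0, 45, 90, 105, 135, 180, 225,
255, 270, 315}°; a five-beam step-and-shoot plan at {45, 105, 180, 255,
315}° with three segments per beam (MU fractions 0.40/0.35/0.25,
aperture boundaries −50/−15/+22/+50 mm), 78 Gy in 39 fractions
prescribed; diode measurements on a 7-mm lattice; and ellipsoidal
PTV/CTV/rectum/bladder structures.

Angular ratio perturbations default to a gravity-like pattern — zero at
the reference, near-zero at 90°/270°, and all-positive changes at 180°
with mean 3.43 ratio units and scatter 1.58 units, i.e. ≈ 7 ± 3% in dose
through the 2.03%-per-unit slope — matching the magnitudes the method is
designed to correct.

EPID noise is multiplicative Gaussian gain noise drawn per exposure on
10 mm × 10 mm cells aligned with the ROI lattice (default σ = 0.55%).
The cell structure models low-frequency output/response fluctuation and
is chosen so the replicate CoV of the A/B ratio equals σ analytically
(per-pixel white noise would average to ~0.02% over the ~700-pixel ROIs
and could not reproduce a realistic replicate CoV in the 0.2–1.6% range
that the default straddles).

The toy forward model (fluence × exponential depth factor, τ = 300 mm)
is *not* a dose engine: no scatter, heterogeneity, MLC transmission or
tongue-and-groove. It guarantees exactly the relationships the pipeline
consumes — per-beam planes consistent with per-beam 3D grids, abutments
consistent with segment maps and plan leaf ends, injected error fields
recoverable by construction, per-beam grids summing exactly to the
total. Passing tests therefore demonstrate the correctness of the
analysis chain, not the physical fidelity of any dose calculation;
results on real TPS/EPID data inherit whatever physics those systems
provide.

Problem sizes used by the test suite are the package's own choice for
routine runs: most image-analysis tests use a 256-px panel at 1.6 mm/px
(identical isocenter coverage to the full panel), while the null
field-size case and the acceptance script run the full 1024-px geometry.
The 3D fixture uses a 61³ grid at 2 mm over ±6 cm.

## Known limitations

- Angular interpolation between measured QA angles is linear on the
  circle; for treatment angles far from measured nodes, measuring at the
  actual angles is preferable to interpolation.
- The GAC injection band width (2 mm default) is a configurable choice;
  the physical abutment line width is machine-dependent.
- A single global calibration line is fitted; per-leaf calibration is
  out of scope.
- The 2D error map is applied depth-independently along each ray.
- Structure rasterization is voxel-center based; very thin structures on
  coarse grids will show quantisation in VxGy.
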