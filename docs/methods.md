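# Methods

## Scope and data flow

The package covers the automatable half of periodic linac QA: constructing
the test deliveries as control-point sequences, and analyzing the portal
images those deliveries produce.  A third component — the synthetic EPID
renderer — closes the loop offline: every analyzer can be exercised against
images whose ground truth is known exactly, and injected delivery errors
(leaf offsets, jaw gaps/overlaps, phantom shifts and SSD changes, band
intensity perturbations) propagate through rendering so the analyzers'
sensitivity can be measured.

All three components share one geometry: IEC 61217 collimator coordinates,
`x` crossplane (MLC travel) and `y` inplane, all positions in millimetres in
the isocenter plane.  Detector pixels map to the isocenter plane as
`(index − cax_pixel) × pixel_spacing × SAD/SID`.  Images are rendered
directly in isocenter-plane millimetres on the detector grid, which avoids
double magnification bookkeeping; only the light-rad phantom, which sits at
a variable SSD, is projected (pattern scaled by `SAD/SSD`).

## Plan construction

Plans are ordered beams of control points (cumulative meterset weight,
gantry/collimator/couch angles, X/Y jaws, two MLC banks with
`bank A ≤ bank B` per pair).  The default MLC model is the Millennium-120
layout: 60 leaf pairs spanning ±200 mm inplane, 10 × 10 mm + 40 × 5 mm +
10 × 10 mm.  Builder-recorded expectations (nominal picket centers, junction
line positions, band ROI rectangles, BB layout) live in plan metadata and
round-trip through DICOM in a private tag block, because the analyzers must
compare against *nominal* geometry even when the delivered control points
carry injected errors.

Decisions taken where the design was open:

* **Picket fence.** Slit width defaults to 2 mm; the expected "position" of a
  picket is the slit center, per leaf pair the mean of the two bank positions
  at that picket's dwell control point.  The delivery is modeled as dwell
  segments: two control points per picket at equal machine state, with the
  full meterset accrued while parked and instantaneous moves between stops.
* **Junction test.** Defaults to four abutting quadrants so that both the
  x- and y-jaw junctions exist in one composite image; a two-field single-
  axis mode is available.  A signed junction error of `e` mm recedes (gap,
  `e > 0`) or advances (overlap) each abutting edge by `e/2`.
* **Light-rad phantom.** The phantom's BB layout is only partially
  constrained by its description; this package assumes eight BBs, two per
  field side on the side's perpendicular bisector — inner at 5 mm inside the
  radiation edge, outer at 25 mm — numbered 1–8 clockwise in beam's-eye view
  starting at the patient-right side, inner ring first.
* **VMAT T2/T3.** The vendor band geometry and meterset schedule are not
  public; the defaults are configurable stand-ins: 7 (T2) or 4 (T3)
  contiguous 24 mm bands delivered as a step-wise band sweep, with ROIs over
  the central 2/3 of each band and 80% of the inplane aperture.
* **Resampling.** Control-point resampling interpolates all axes linearly;
  the spacing metric is gantry degrees for rotating beams (shortest-path
  rotation between neighbours) and meterset weight otherwise.  Original
  control points are kept exactly, so resampling is idempotent once the
  bound is met.  Arcs are assumed to be finely sampled to begin with (no
  single control-point pair spanning more than 180°).
* A dosimetric-leaf-gap sweeping-field builder is included (configurable gap
  widths) but no DLG analyzer; the plan exists so the delivery can be
  scheduled, the analysis method is out of scope.

## Image formation model (synthetic EPID)

The renderer is deliberately the *simplest model containing the features
each detector needs*:

* Field edges are error functions with width `penumbra_sigma_mm`
  (default 1.5 mm, roughly a 6X beam's EPID penumbra); the 50% level falls
  exactly at the jaw/leaf position.  Abutting edges therefore sum exactly to
  the open plateau — the property the junction test rests on.
* DMLC deliveries are integrated control point by control point, weighting
  each segment's aperture (midpoint of neighbouring states) by its meterset.
* Ball bearings are circular attenuation disks (default 4 mm diameter, 25%
  attenuation) blurred by the same penumbra sigma; the phantom plane is
  projected by `SAD/SSD` and translated by the phantom shift, while the
  radiation edges stay put.
* Band images multiply each band by its perturbation factor; an optional
  radial "bowing" factor models off-axis beam shape and applies identically
  to the open-field companion, so the corrected reading cancels it.
* Noise is additive Gaussian, relative to the open-field plateau
  (σ = 0.01 of the plateau in the noise studies), with an explicit seed;
  every renderer is deterministic given (plan, config, error, seed).
* Default grid: 512 × 512 at 0.5 mm, SID = SAD = 1000 mm.

Not modeled: scatter, EPID glare/ghosting and dose-response nonlinearity,
MLC tongue-and-groove, rounded leaf ends, gantry-angle-dependent sag.
Passing tests on these images therefore demonstrate the *analyzers'*
correctness (geometry, statistics, error recovery), not robustness to every
clinical image artifact; the tolerances in use (0.3, 1.5%, 1 mm, 2 mm) are
large against the omitted effects.

## Analyzer conventions

* **Field edge** = 50% of the background-subtracted plateau, found by linear
  interpolation on mean profiles taken over the central half of the field's
  bounding box.  Background is the mean of the four image-corner patches;
  the plateau is a high percentile of in-field pixels (robust to small
  fields and to in-field BBs).
* **Junction sampling.** The statistic's three inputs are named but their
  sampling regions are not standardized; here `I_junc` is the extremum
  within ±3 mm of the nominal match line (minimum for gaps, maximum for
  overlaps — whichever lies farther from the plateau), `I_rad` the profile
  mean at least 10 mm from both the junction and the field edges, and
  `I_BG` the corner background.  Each junction axis is sampled on two bands
  (5–20 mm either side of center) so the orthogonal junction cannot
  contaminate the profile, giving four junction values on a quadrant
  delivery; the worst value decides pass/fail at ±0.3.
* **BB detection.** Grey-scale closing (window ≈ 6 expected radii) removes
  BB-sized dark spots but preserves the field's edge roll-off, so
  `closed − image` isolates the attenuation dips.  Dips above 8% of the
  field contrast are segmented; regions are filtered by size (equivalent
  radius within ±50% of expected) and circularity (5th/95th percentile
  ratio of centroid-to-boundary distances, threshold 0.85).  Because the
  penumbra distorts a dip's outline, the circularity score is only trusted
  for regions more than two BB diameters from an edge; regions whose
  centroid is within 3 mm of a 50% edge are discarded entirely — such BBs
  are reported *undetected*, never mislocated, mirroring the behaviour of
  automated detection near field edges.  Centroids are weighted by relative
  attenuation (`dip/closed`) so a dose gradient across the BB does not bias
  them.
* **Picket fence.** Per leaf pair, the crossplane profile is averaged over
  the central 60% of the pair's inplane band; each stripe is the parabolic
  sub-pixel maximum within ± half the picket spacing of its expected
  center and must rise above half the image-wide stripe plateau, otherwise
  the leaf is flagged undetected and leaves the percent-passing denominator
  (with the flag preserved in the result).  Deviation is signed
  `expected − measured`: a +2 mm delivered offset reads as −2 mm.
* **VMAT bands.** `corrected_b = mean(test ROI_b) / mean(open ROI_b)`;
  `percent_diff_b = 100 × (corrected_b / mean(corrected) − 1)`;
  `Diff_ABS = mean |percent_diff_b|`; pass iff every band is within ±1.5%.
  The signed percent differences average to zero by construction, and the
  statistic is invariant under separate global scalings of the two images.
* **Gamma.** Global normalization to the reference maximum; for each
  reference pixel the gamma quadratic is minimized over displacements on a
  sub-pixel grid (default step `dta/4`) within a disk of radius `3 × dta`,
  sampling the evaluated image bilinearly; pixels below the low-dose cutoff
  (default 10%) are excluded from the pass rate.  Criteria default to
  3%/3 mm but are configurable — tolerance choice is left to the
  institution.  The discretized search makes the computed map an upper
  bound on the continuous-displacement gamma, tight at the step size; the
  test suite pins it against an independent exhaustive search.
* **Winston–Lutz.** Field center = midpoint of the 50% edges; BB center from
  the BB detector; result is the offset vector and magnitude.
* **Sensitivity bookkeeping.** A *failing* delivery is the positive class:
  sensitivity = caught failures / true failures.  The batch sweep injects
  jaw errors of 0/±2/±4 mm and phantom SSDs of 95–105 cm, with ground truth
  from closed-form oracles (the erf edge-sum for junctions, the SAD/SSD
  projection for the phantom), and tabulates 2 × 2 contingency tables.  In
  the noiseless limit every out-of-tolerance case is detected.

## Numerical notes and problem sizes

Tolerance defaults live in one mapping (`DEFAULT_TOLERANCES`) and can be
overridden per evaluation without code changes; re-evaluating a stored
report recomputes pass flags from the stored measurements.  Degenerate
inputs (uniform images, `I_rad ≤ I_BG`, empty ROIs, no BB) raise typed
errors rather than returning numbers.  DICOM output uses deterministic,
seed-derived UIDs so emitted files are byte-reproducible; RT-Image pixel
data is stored as 16-bit scaled integers (round-trip error ≤ 1.5 × 10⁻⁵ of
the maximum), while the plain-grid sidecar format is lossless.

The test suite and the acceptance script run everything at the default
512 × 512 / 0.5 mm grid except the gamma-oracle comparisons, which use
32 × 32 grids so the exhaustive reference search stays cheap; these sizes
were chosen as the smallest at which sub-pixel behaviour (0.1–0.2 mm
assertions) is meaningfully exercised.
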