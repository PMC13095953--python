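# Methods

## The measurement model

A two-zone micropillar chip traps 15 µm immunoassay beads one per site
and is imaged as a paired bright-field / fluorescence micrograph.  The
readout of interest is each bead's mean fluorescence grayscale inside
its circular boundary; beads are segregated by the zone rectangle
containing their centre, each zone's value `V` is the mean of its
per-bead means, and the assay result is the Relative Fluorescence Ratio
`RFR = V_MDF / V_MPF × 100%`, the test zone normalised to the on-chip
positive reference.  Because both zones share one chip, one imaging
pass and one reagent batch, multiplicative systematic factors
(illumination, exposure, labelling efficiency) appear in both `V`
values and cancel in the ratio; the package's scale-equivariance test
asserts exactly this.  The ratio is computed as `100 × (V_MDF /
V_MPF)` so a zone ratioed against itself returns exactly 100%.

A run is *self-validated*: a reference zone with no measurable beads or
a non-positive mean voids the run with an `invalid-run` error rather
than reporting a ratio, since without the positive control no statement
about the test sample is defensible.

## Chip geometry and the simulator

The simulator idealises the trap region as a rectangular lattice with
pitch = pillar diameter + inter-pillar spacing = 50 + 14 = 64 µm, one
trap per lattice cell centre and one pillar per cell corner; the real
oblique-flow arrangement is only qualitative in its source description,
and only the monodispersed positions matter downstream.  The default
layout is 4 × 5 traps per zone (40 sites total), sized so a default
scene carries ~40 beads — large enough to exercise zone statistics,
small enough to render in well under a second.

**Bead loading.**  Trapping is modelled on the chip's self-regulated
sequential mechanism: an occupied trap's raised longitudinal resistance
diverts later beads laterally onward.  Each injected bead walks the
empty sites in serpentine flow order and lodges in the current one with
probability `p_trap` (default 0.8); occupied sites are always skipped;
a bead that passes every remaining site counts as escaped.  The
invariant `placed + escaped = injected` holds for every parameter set.
Optional doublets (`doublet_prob`, default 0) let an arriving bead pile
onto an occupied site, breaking monodispersion deliberately.

**Optics and noise.**  Images are 16-bit (8-bit supported) at
0.5 µm/px, so a bead spans 30 px.  Bright-field renders beads and
pillars as dark disks (contrasts −9000 and −15000 on a 30000
background) — the typical appearance of polystyrene beads and PDMS
pillars; the pillars act as distractors for the detector.  Fluorescence
is background (default 0) plus a per-bead disk of its true mean
intensity, drawn lognormally about the zone mean with CV 0.1
(positive-valued biological heterogeneity; no distribution is
prescribed by the assay description).  Both channels are blurred by a
Gaussian PSF (σ = 1 px default), optionally shot-noised (Poisson on the
photon-borne part only), offset by the constant camera black level
(1800 grayscale units, the microscope's black-balance setting, modelled
as purely additive since its semantics are not further specified),
read-noised (Gaussian, σ = 30 default) and clipped to the bit depth
after rounding.  With blur and noise off, in-mask pixels equal
`background + black_level + true_mean` exactly, which anchors the
migration tests.

Not emulated: diffraction rings, vignetting, autofluorescence, focus
drift, bead clumps at chamber edges, or real trap geometry.  Passing
tests therefore demonstrate the *pipeline's* correctness and its
statistical behaviour under controlled noise, not detector robustness
to real-instrument artefacts.

## Reference detector

Real deployments use a trained object detector; this package fixes a
deterministic classical reference behind the same pluggable contract.
The beads' strictly uniform geometry under constant illumination makes
a matched filter appropriate: the image is correlated (zero-normalised
cross-correlation, `skimage.feature.match_template`) with a disk
template of the expected radius, sign-adjusted for dark beads.  Local
maxima above `match_threshold` (default 0.6) become candidates with the
correlation as confidence.  Each candidate's radius is then estimated
as the peak of the absolute radial derivative of its angle-averaged
intensity profile (sampled to 2× the expected radius, 48 angles,
bilinear interpolation); candidates deviating more than
`radius_tolerance` (default 30%) are rejected.  This removes pillar
responses without consulting the chip layout — pillar interiors are
flat (no gradient peak) and pillar edges average to a near-constant
profile.  Survivors pass greedy non-maximum suppression at IoU 0.5 with
a deterministic tie-break (confidence, then smaller y, then x).  Boxes
are squares of side `2 × radius + 2 px` centred on the peak; the margin
absorbs sub-pixel offsets.

The correlation confidence of this detector and a neural detector's
confidence are not calibrated against each other; no mapping is
attempted.

## Evaluation conventions

Matching is greedy in descending confidence; each detection takes the
highest-IoU unmatched truth at or above the cutoff (default 0.5, the
community convention).  Detection has no true negatives, so accuracy is
defined as `TP / (TP + FP + FN)`; precision, recall and F1 are
standard.  Dataset splitting shuffles with a seeded generator and
allocates sizes by largest-remainder rounding, so 10 items at 7:2:1
give exactly (7, 2, 1) and the subsets always partition the input.

## Quantification choices

* **Mask shape**: default is the inscribed circle (readout "within the
  circular region"); a `full_box` rule is also provided since boundary
  boxes are an equally defensible reading of the boundary-transfer
  description.  Membership is centre-in-circle, which is exactly
  reproducible by a per-pixel loop — the oracle-equivalence tests
  demand bit-identical means.
* **Black-level handling**: subtraction is off by default (ratios are
  formed on raw grayscale as far as the assay description states); the
  pipeline accepts a numeric offset or `"auto"` (black level +
  fluorescence background, available in simulation).  The consequence
  is documented by the scale-equivariance property: the RFR equals the
  true intensity ratio only when the additive offset is removed.
* **Zone membership** is half-open (min edge in, max edge out) in both
  µm and pixel frames, so the zones tile without double counting;
  beads in neither zone are labelled `unassigned`, logged, and excluded
  from summaries.
* Zone SD uses the sample convention (n−1) and is absent for a single
  bead.
* Both zones may come from one micrograph pair (zone rectangles decide
  membership) or each zone from its own pair (membership assigned
  directly); the config selects the mode.

## Calibration and QC

The dilution-series fit is ordinary least squares of signal on
concentration (log-concentration optional), `R² = 1 − SS_res/SS_tot`.
The LOD follows the blank + kσ convention with k = 3 by default — the
concentration at which the fitted line reaches
`blank_mean + k × blank_sd`, floored at zero; k is configurable because
the underlying rule ("signal-to-noise ratio with a blank control") does
not pin down 3σ vs 3.3σ.  Retention efficiency is
`100 × retained/total`, with replicate aggregation reporting the mean ±
sample SD of per-replicate percentages.

## Problem sizes and numerical tolerances

Simulated studies in the test suite use the default 40-site layout
(1536 × 640 px scenes): 20 scenes for detector scoring, 20 seeds for
RFR recovery (statistical assertions use three standard errors of the
Monte-Carlo mean), 200 simulated series of 5 concentrations × 50
replicates with 10 blanks for LOD recovery (median within 20% of the
analytic 3σ/slope), 1000 random parameter sets for loading
conservation, and 500 random instances for the NMS/matching oracles.
Noiseless linear fits are asserted to R² = 1 within 1e-12; migrated
means are asserted exactly equal to the brute-force loop.  All
randomness flows from explicit seeds (NumPy `SeedSequence` spawning),
and a pipeline run with a fixed config and seed reproduces its output
files byte-for-byte.

## Known limitations

The detector's perfect scores hold on clean synthetic scenes;
occlusion, debris and focus variation are out of the simulator's scope.
Sub-pixel localisation is not attempted (centres are correlation-peak
pixels + 0.5).  The simulator's lattice is a stand-in for the real
oblique trap arrangement, and saturated pixels are only flagged, not
corrected.
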