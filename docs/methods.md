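# Methods

## Pipeline model and assumptions

The pipeline treats an echocardiographic *exam* (one study UID) as a bag
of *recordings* and makes all decisions per exam in three phases:
curation (classification + gates), measurement (timing, segmentation QC,
biplane volumetry), and analysis (agreement + feasibility accounting).
Learned components are deliberately outside the package: modality/view
classifiers, the event-timing detector and the segmentation models enter
only through backend contracts. The shipped backends are an *oracle*
(reads the synthetic ground-truth annotations) and seeded *noisy*/
*disabled*/*biased* variants for stress testing; a trained model can be
registered without touching pipeline code. Consequently everything the
package itself asserts is about the deterministic logic around the
models: taxonomies, gates, geometry, arithmetic and accounting.

## Tunable parameters

| parameter | default | units | role |
|---|---|---|---|
| `confidence_threshold` | 0.85 | – | view-classification gate, inclusive (≥) |
| `dice_threshold` | 0.8 | – | dual-segmentation agreement gate, inclusive |
| `timing_cutoff_frames` | 5 | frames | max network-vs-regression deviation before falling back to the ECG regression (strictly greater switches) |
| `n_discs` | 20 | – | disc count of the biplane Simpson summation (guideline convention) |
| `bsa_formula` | mosteller | – | √(W·H)/60; DuBois available as alternative |

The ES-offset regression constants are fixed: 498 ms − 1.60 ms/bpm
(male), 522 ms − 1.77 ms/bpm (female). A non-positive offset (heart
rates beyond the formula's validity) is an error, never clamped.

## Geometry core

*Long axis*: principal eigenvector of the mask pixel covariance;
endpoints are the extreme pixel projections onto that line, extended by
half a pixel for the pixel footprint. The base end is the endpoint whose
neighbourhood (nearest 10% of the axis) has the larger perpendicular
width; exact ties (symmetric phantoms) break toward the larger row
coordinate. Masks that are empty, smaller than 50 px or disconnected
raise an invalid-segmentation signal that becomes a funnel exclusion.

*Disc diameters*: the apex→base axis is split into `n_discs` equal
slabs; at each slab center the mask is sampled along the perpendicular
by bilinear interpolation at quarter-pixel steps, and the diameter is
the extent between the first and last samples ≥ 0.5. The 0.5-crossing
of the interpolated binary mask sits at the pixel-grid boundary on
average, so no additional footprint correction is applied to diameters
(adding one was measurably biased against the ellipsoid closed form).

*Biplane volume*: V = (π/4)·(L/n)·Σ aᵢbᵢ with L the longer of the two
view lengths. A length discrepancy above 20% between views sets a
foreshortening-suspicion flag on the result but never rejects it. On
rasterized prolate-ellipsoid sections at 0.5 mm/px and 20 discs the
relative error against (π/6)·L·D1·D2 is ≈0.3%, decreasing with finer
spacing (the test suite asserts < 2% and monotone decrease).

*Averaging*: every gated-in A4C clip is paired with every gated-in A2C
clip; cycle j pairs with cycle j; measurements (EDV, ESV, EF each) are
averaged over cycles within a pairing, then over pairings.
`n_clips_averaged` counts contributing pairings. A Dice failure at
either measured frame (ED or ES) drops that pairing; the exam is
excluded only when no pairing survives, with reason precedence
timing → invalid segmentation → low Dice, mirroring the stage order.

## Timing conventions

Milliseconds convert to frames by round-half-up on ms·rate/1000. The
5-frame reconciliation rule uses the maximum of the ED and ES deviations
(the per-event vs joint question is unspecified in the underlying
regression literature; max is the conservative reading and is
configurable). The ED anchor for the ECG path is the cycle-start
annotation carried in the manifest (or the DICOM R-wave reference when
ingesting real files); the package performs no QRS detection, so a
recording without heart rate or anchor is excluded with an explicit
reason, never silently defaulted.

## Curation conventions

Exclusion reasons partition the cohort with precedence: TEE-only /
no-B-mode, then missing view (A4C before A2C), then low view confidence,
then the measurement-phase reasons. A slot whose views were *present
but all gated out* reports `low_view_confidence`; a slot with no such
views at all reports `missing_*`. The gate applies before the
LV-focused/standard preference: a low-confidence focused view never
shadows a high-confidence standard one (the alternative ordering was
considered and rejected because it would let an untrusted
classification suppress a trusted one). Image-quality classes are the
arithmetic mean of regional scores rounded half-up to an integer in
[0, 5] — half-up because "rounded" alone is ambiguous and half-up is
deterministic and conventional.

## Synthetic phantom

The LV is a *full* prolate ellipsoid (semi-axes a, b, b; default
long/short diameter ratio 1.8), not a truncated realistic shape: the
payoff is the exact closed-form biplane-Simpson limit, which turns the
geometry core into an analytically checkable unit. Volume interpolates
by cosine between EDV (at each cycle-start frame) and ESV (at the frame
placed by the same sex-specific regression the fallback uses), scaling
all semi-axes by (V/EDV)^{1/3}; both orthogonal views therefore share
the long axis exactly at every frame. The LA is an analogous rounder
ellipsoid (ratio 1.3) with exact end-systolic volume. Masks are
rasterized (pixel-center inclusion) at the ED/ES frames of every cycle
— the only frames measurement reads — at 0.5 mm/px by default.

A generated exam holds LV-focused and standard A4C/A2C recordings (LA
masks on the standard views) plus one PW-Doppler clip that modality
classification must filter out. Corruptions: dropped views, per-view
confidence overrides, secondary-mask degradation (iterated
erosion/dilation until the Dice against the primary reaches the target
1 − d, achieved value recorded in the ground truth), disabled or
frame-shifted timing output, and injected regional-quality scores. Each
corruption's forced exclusion reason is recorded so funnel accounting
can be verified exactly. Cohort defaults sample EDV 90–180 mL, EF
30–65%, LA volume 30–90 mL, HR 55–95 bpm, frame rate 40–60 Hz, and
sex-independent uniform height/weight — ranges a mixed clinical echo
population plausibly spans. All randomness flows from one integer seed
through a single `numpy` generator; no global state.

What the phantom does **not** emulate: B-mode speckle or any pixel
texture (classification backends are oracles, not image models),
truncation of the LV at the mitral plane, foreshortened or off-axis
acquisition, anisotropic pixel spacing, real dual-network disagreement
structure, and arrhythmic cycle-length variability. Passing tests
therefore certify the deterministic pipeline logic and the geometry
under ideal segmentations — not the accuracy of any trained model on
clinical images; the base-detection heuristic in particular is untested
against real mitral-plane anatomy.

## Problem sizes

Tests and the synthetic validation study run cohorts of up to 100 exams
at 0.5 mm/px with one cycle per recording — enough for the binomial and
Monte-Carlo checks (n = 5000 for the Bland–Altman error-recovery test)
while keeping the whole suite around ten seconds. Larger cohorts scale
linearly; the pipeline streams one exam at a time.

## Known limitations

- Disc diameters are full perpendicular extents (max-chord), matching
  caliper semantics; for non-convex real masks an area-equivalent width
  would differ.
- The common-L choice (longer view) and the averaging order are
  conventions; both are isolated behind single functions.
- DICOM ingestion reads public tags only; vendor-private raw data and
  ICD-10 record linkage are out of scope.
- The Bland–Altman LOA multiplier is fixed at 1.96 by definition but
  exposed for sensitivity analyses.
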