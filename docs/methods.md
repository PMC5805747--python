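# Methods

## Imaging model

The forward model is an *effective monochromatic* description of a
three-grating fringe-scanning interferometer. Each detector pixel sees a
stepping curve over the scan phases `φ_k`,

    I_k = I0 · T · (1 + v0 · D · cos(φ_k + φ_pixel)),

with `T = exp(-attenuation line integral)` and
`D = exp(-scatter line integral)` taken directly from the phantom maps,
`v0` the sample-free fringe visibility, and `φ_pixel` the flat-field fringe
phase. The fringe phase varies along image rows only (period 16 px), i.e.
the fringes are horizontal lines orthogonal to the scan direction — which is
why coherent perturbations (cardiac motion, tile gaps) appear as horizontal
streaks after retrieval. Spectral physics (the 70 kVp tungsten spectrum,
beam hardening), wave-optical propagation, detector MTF, and the distinction
between a Talbot self-image and the direct G1 shadow geometry are not
modelled: every quantity this package reproduces is an ROI statistic of
retrieved images, which only depends on the (T, D, noise) triple delivered
to retrieval. The 30–40 s slot-scanning acquisition of the real prototype is
likewise collapsed into a static phase-stepping model; `n_steps = 8` equally
spaced samples per fringe period is an assumption (any value ≥ 3
determines the three unknowns).

Photon noise is Poisson per frame with expectation as above
(`photons_per_step = 2500` in the frozen calibration). The reference scan is
noiseless by default, representing a well-averaged flat field; a noisy
reference mode exists but is off in the calibration.

Retrieval fits `a0 + a1·cos(φ_k + φ)` per pixel by linear least squares
(`[1, cos φ_k, sin φ_k]` design; identical to the discrete-Fourier estimate
for equally spaced phases), then forms `T = a0_s/a0_r` and
`D = (a1_s/a0_s)/(a1_r/a0_r)`. `a1` is non-negative by convention, the
phase absorbing the sign; phases of pixels with modulation below numerical
noise are reported as 0. `D` is clipped to [0, 1.5] before analysis — photon
noise can push the visibility ratio above 1 in non-scattering regions, and
the clip keeps ROI statistics finite without touching calibrated regions
(noiseless `D ≤ 1` is unaffected). Pixels with vanishing reference mean or
modulation (tile gaps, dead regions) are masked to NaN and excluded.

## Phantom

The phantom is a stylized 2-D posterior-anterior projection (row 0 =
dorsal; 0-based pixels; areas count mask pixels × pixel size²), sufficient
because the downstream analysis is entirely ROI-based: an elliptical body,
two lung ellipses separated by a heart/mediastinum ellipse, nine curved rib
bands (attenuation only), a diaphragm edge with a 0.8 cm attenuation ramp
into the abdomen, and one retro-diaphragmatic lung ellipse per side whose
pixel count realizes the per-animal target area. The native grid is the
scanner's 32 × 35 cm field of view at 360 µm effective pixels (889 × 972);
`half` (720 µm) and `smoke` (1440 µm) scales exist for fast tests, with
texture correlation lengths rescaled so object-plane structure is
scale-invariant.

Anatomical noise — the dominant, spatially correlated part of the measured
ROI standard deviations — is modelled with two unit-variance Gaussian random
fields fixed per animal:

- a short-range granularity field (correlation length 6 px at full scale)
  multiplying the lung scatter lognormally (`exp(g·field − g²/2)`),
  emulating unresolved alveolar structure of high spatial frequency;
- a long-range additive field (12 px) on the attenuation map over the whole
  body, emulating overlying soft-tissue structure in transmission.

Pneumothorax induction is exact in the truth bookkeeping. *Lateral*: a gas
band is carved off the lateral lung edge, `scatter = 0` and attenuation
reduced by the lung-minus-gas contrast there; the band width is a linear
stand-in, 1.2 cm at 500 ml (only monotonicity in the instilled volume is
used anywhere). *Dorsal*: air rising to the uppermost (dorsal) pleural space
compresses the retro-diaphragmatic lung; the dorsal-most
`round(f·n)` pixels of the region are relabelled as pleural gas, so the
truth area shrinks by the collapse fraction exactly (up to one pixel).
Because the animals lie in abdominal position, *every* pneumothorax carries
a dorsal collapse (drawn N(0.205, 0.03), clipped to [0.03, 0.5]); the
lateral band is added for the six laterally visible animals. This matches
the study design in which all eight animals enter the before/after area
comparison while only the six lateral ones enter the CNR analysis.

Default cohort distributions (per animal, redrawn per cohort seed):
AP diameter N(20.2, 2.3) cm (scales all tissue line integrals), body mass
N(25.8, 5.9) kg (cosmetic), lateral air volume U(200, 500) ml, dorsal-only
air U(50, 150) ml, baseline retro-diaphragmatic area N(62.8, 7.8) cm² on the
affected and N(57.6, 10.3) cm² on the control side. Composition: 3 ex vivo
(all lateral), 5 in vivo (3 lateral, 2 dorsal-only).

## Calibration `paper2018`

The study this pipeline models deposited no image data, so the phantom's
free parameters were fixed by forward simulation: starting from values
obtained by inverting the CNR equation against the four published CNR means
(3.65/1.13/2.45/1.14 for filtered dark-field / unfiltered transmission /
unfiltered dark-field / filtered transmission) and the Gaussian filter's
white-noise factor, full-resolution cohorts were simulated and the
parameters adjusted until the grand-mean ROI statistics of the *retrieved*
images matched; the result is frozen in `calibration.py` and not scale- or
seed-specific. The load-bearing values: lung scatter line integral 0.357
(lung `D ≈ 0.70` vs gas `D ≈ 1`, contrast ≈ 0.30), granularity amplitude
0.385, lung/gas attenuation 0.80/0.732 (transmission contrast ≈ 0.03 in T),
transmission texture sd 0.060 at 12 px, `v0 = 0.25`, 2500 photons/step.
With these, dark-field noise splits into comparable anatomical (~0.08) and
photon (~0.06) parts — filtering helps a lot — while transmission noise is
anatomical-noise-dominated, so filtering barely improves its CNR; both
behaviours mirror the published discussion. `v0` and the fluence are free
parameters of the calibration (the prototype's visibility is not public);
only their combination is constrained by the CNR targets.

The cardiac motion artifact (relative amplitude 0.004, applied to in-vivo
scans along the heart-edge rows with a 40 px column falloff) is deliberately
weak: the study found no significant ex-vivo/in-vivo CNR difference, and the
pipeline reproduces that as a property (p > 0.05 in ≥ 90% of cohorts).

## Analysis choices

- **ROIs**: the published analysis used manual ROIs of unstated size.
  Default placement here is automatic from phantom truth masks: a ~2 × 2 cm
  lung square medially adjacent to the gas band and the eroded gas band
  restricted to the same rows, both excluding rib and heart pixels and
  eroded by 0.11 cm (3 px at full scale) from every boundary. Manual JSON
  ROIs (label + pixel runs) are accepted. Identical ROIs are applied to the
  transmission and dark-field image of one exposure.
- **Quantitative filtering**: only the FWHM 3.25 px Gaussian
  (σ = FWHM/2.3548, truncated at 4σ, reflect edges), applied to dark-field
  before CNR; the filtered-transmission variant is computed for comparison.
  3.25 px × 360 µm is 1.17 mm; the pixel-unit value is taken as normative.
  The display pipeline (tile-gap low-pass, then one 3 × 3 binomial pass —
  the published "successive" application count is unstated, default 1)
  flags its output, and every quantitative operation rejects flagged
  images.
- **Segmentation**: inflated retro-diaphragmatic lung is `D` below 0.7 × the
  free-gas/soft-tissue plateau median (pixels with D ≥ 0.8 in the analysis
  band; fallback: upper half) after Gaussian filtering, restricted to the
  per-side band below the diaphragm, morphologically closed (2 iterations,
  8-connected), hole-filled, largest component. The factor 0.7 is part of
  the frozen calibration (the published outlining was manual). The
  threshold crossing on the blurred boundary biases the mask slightly
  inward (~1 px), a ≤ 5% area deficit at smoke scale and ~1% at full scale;
  percent *changes* are nearly unaffected because the bias cancels between
  states.
- **Statistics**: percent change is the mean of per-animal percent changes,
  not the percent change of the means — the published control-side value
  (−0.3%) is only consistent with the per-animal convention. The power
  routine is parameter-driven (`μ_d`, `σ_d`, `n`, `α`); the published worked
  example uses n = 6.

## Problem sizes and determinism

The acceptance computations use 20 independently seeded full-resolution
cohorts (120 lateral animals for the CNR grand means; 160 animals × 2
states for the area statistics), chosen so the cohort-mean Monte-Carlo
error (~0.05 on the dark-field CNR) is well below the comparison
tolerances. Every random draw flows from explicit integer seeds through
`numpy` `SeedSequence`; identical seeds give bit-identical phantoms, scans
and result tables.

## Limitations

Passing tests show that the *analysis chain* (retrieval, filtering, ROI
statistics, segmentation, paired statistics) behaves correctly on images
whose contrast and noise structure match the published summary statistics —
not that the phantom is anatomically realistic. No 3-D anatomy, organ
motion, airway trees, realistic bone texture, spectral effects, scatter-to-
sensitivity conversion from the grating geometry, or reader performance are
modelled; pneumothorax volume is not estimated from projected area. The
lateral gap-width-vs-volume map and the independence of dorsal collapse
fraction from instilled volume are stand-ins where the study reports no
quantitative relation.
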