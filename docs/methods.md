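# Methods

## Scan geometry and conventions

`ScanGeometry` ties the three data axes to physical units: A-line index ↦
angle (θ = 2πi/a_lines_per_bscan, counter-clockwise from the +x axis),
B-scan index ↦ pullback position (pullback_length / n_bscans per frame),
depth-sample index ↦ physical depth (axial_pixel_pitch / refractive_index
µm per sample). Depth index 0 is on the probe/sheath side and increases
into tissue; all coordinates are 0-based with half-open ranges.

One B-scan per probe revolution is assumed, so the frame rate equals the
rotation rate (2400 rpm → 40 fps). Recorded counts (A-lines per B-scan,
number of B-scans) are stored exactly as supplied by the acquisition
rather than derived from the rates: acquisition software routinely reports
counts that are not commensurate with the nominal clock rates, and the
analysis needs the counts that actually shaped the arrays. The default
tissue group index is 1.38 (typical soft tissue) and is configurable,
since depth calibration is instrument-specific.

## Synthetic phantom

The generator renders a four-layer cylindrical wall (lumen → serosa:
colonic mucosa, muscularis mucosa, submucosa, muscularis propria) inside a
transparent sheath drawn as two thin bright rings. Within layer L starting
at interface depth z₀ the noiseless profile is

    I(z) = R_L · T_L · exp(−2 μ_L (z − z₀)),

with R_L the layer's surface reflectivity, μ_L its attenuation
coefficient, and T_L the accumulated two-way transmission of the layers
above; each interface additionally carries a single-sample specular spike
(×2 by default). Speckle is fully developed: unit-mean multiplicative
exponential intensity noise applied to the signal, after which a constant
noise floor is added. Interfaces are quantized to integer depth samples so
ground-truth masks, boundaries and thicknesses agree with the rendered
voxels exactly — the counting identity `mask.sum() == Σ (bottom − top)`
holds by construction.

Default parameters (all configurable) and what they emulate:

| parameter | default | role |
| --- | --- | --- |
| layer thicknesses | 200/30/50/100 µm | literature-plausible murine wall; baselines are explicitly arbitrary since all checks compare to generated truth |
| layer μ_A | 3.0/1.0/2.0/1.5 mm⁻¹ | scattering-dominated attenuation at 1310 nm |
| sheath radii | 0.20/0.25 mm | scaled-down probe; wall rests on the outer surface |
| detachment | 1 gap, 25°, ≤150 µm | angular spans where wall–sheath contact is lost |
| motion jitter | 10 µm radial, 0.5° angular SD per frame | tissue/probe motion between revolutions |
| surface waviness | 15 µm, 2 cycles/rev | smooth non-circular lumen shape |
| crypt modulation | amplitude 0.3, period 12° | angular reflectivity texture of the mucosa, recoverable in en-face views |
| biological CV | 5% | per-mouse-per-day multiplicative variation of thickness and attenuation |
| noise floor | 10⁻³ | detector background relative to unit reflectivity |

The scaled-down default geometry used throughout testing is 40 B-scans ×
360 A-lines × 256 depth samples at 5 µm (in-air) pitch; simulations shrink
it further (down to 4 × 90 for purely statistical runs) because the
quantities being checked do not depend on raster density.

The colitis effect is phenomenological: per-day multipliers on layer
thickness and attenuation for the challenged group (defaults ×1.5 and
×0.7 at day 9, identity at days 0 and 24). The mechanism behind the
in-vivo attenuation drop (immune-cell infiltration changing refractive
index contrast) is not modelled — only its direction and magnitude.

Biological variation is drawn **independently per mouse-day**, not once
per mouse. A persistent mouse effect would be invisible to the group × day
interaction contrast while still inflating the residual, making the
interaction F-test conservative; with independent draws the test is
exactly calibrated, which is the regime the type-I-error check verifies.
Random streams are split per (group, mouse, day) with `numpy`
`SeedSequence` spawn keys, so enlarging a study never perturbs existing
draws.

What the phantom does **not** model, and hence what passing tests do not
show about real data: coherent interference and the point-spread function
(interfaces are ideal steps plus spikes), non-uniform rotational
distortion, blood vessels and peristalsis, depth-dependent focus/roll-off,
and any systematic miscalibration of the depth axis. Segmentation accuracy
on the phantom is therefore an upper bound for real B-scans.

## Segmentation

Per B-scan (dB scale): Canny edges → border-connected hole filling →
morphological closing (disk) → sheath-band deletion → largest connected
component → per-A-line band [top, bottom). Choices that were genuinely
open:

* **Edge detection in dB.** Speckle is multiplicative, so log-compression
  makes gradient statistics stationary across the wall. Canny thresholds
  (0.1/0.3) are relative to the maximum gradient magnitude of the
  σ = 2 px smoothed image.
* **Closing, not opening.** "Dilation and erosion" is implemented as
  closing (se_radius = 3): speckle makes the wall interior edge-dense, and
  closing consolidates it into one solid component.
* **Sheath removal by known geometry.** The sheath's radial position is
  known, so rows within [inner − 3, outer + 2 + 3] px are deleted before
  component selection (auto-detecting the two bright rings would also be
  possible but is not the default). Ties in component size break toward
  the component nearer the lumen.
* **Top-boundary recovery under the sheath.** Deleting the sheath band
  hides wall surfaces at or just beyond the sheath. Each A-line therefore
  walks upward from its first component row through a brightness mask
  (Otsu threshold of the dB image, laterally dilated 9 × 3 so neighbouring
  A-lines vouch for contiguity across sparse speckle, while genuine
  multi-row detachment gaps still block the walk). A walk that reaches the
  ring is classified as contact and snapped to the sheath outer surface;
  otherwise the stop row, refined on the A-line's own column, is the top.
  Detachments smaller than ~3 samples are fundamentally hidden behind the
  ring and are reported at the sheath radius.
* **Gap handling.** A-lines with no component foreground are linearly
  interpolated across angular gaps ≤ 15° (circularly), larger gaps stay
  missing (sentinel −1) and are excluded from quantification.

Flattening shifts each A-line up by its top boundary and stores the
shifts, so it is exactly invertible for retained rows.

## Quantification

Thickness is (bottom − top) × pitch / n per A-line, summarized as the
median within 10 equal pullback bins (bins or layers with under 25% valid
A-lines are reported missing, not imputed). The attenuation fit averages
A-scans in linear intensity within a bin (averaging before the log removes
the −0.577·8.686 dB speckle bias of per-A-line log fits), skips 3 samples
below each interface (specular guard), and regresses ln I on physical
depth; μ_A = −slope/2. On noiseless data this is exact to machine
precision because the generator's decay is exactly log-linear; a
Levenberg–Marquardt exponential fit is available behind a flag and agrees
on clean data. Thin layers are the known hard case: with the default
pitch, the 30 µm muscularis mucosa leaves a 5-sample window whose slope
estimate is noisy at any realistic averaging depth — per-layer recovery
checks therefore use windows of adequate depth, and real studies should
pool such layers (e.g. mucosa including epithelium) exactly as
practitioners do.

## Statistics

Two-way ANOVA of response ~ group * day with Type II sums of squares
(statsmodels). The default analysis unit is the mouse-day mean: the 10
pullback locations are repeated measurements of one colon, and treating
them as replicates would inflate the effective sample size; the
location-level mode exists and is labelled. Significance annotation
follows the *** (p ≤ 0.001) convention. Operating characteristics at the
default study conditions (n = 3/group, days 0/9/24, 5% biological CV):
type-I error of the interaction is nominal (checked against the binomial
95% band over 200 null simulations) and power for the day-9 effect
(×1.5 / ×0.7) exceeds 95% at p < 0.01. These simulations run the
generator without voxel rendering: the test's operating characteristics
depend on the study-level random structure, not on speckle, and the
rendered path is validated separately (Dice, thickness ratio). With a
real effect and 3 + 3 mice, the label-permutation distribution has only
C(6,3) = 20 support points, so the permutation check is exhaustive: the
true labeling must maximize the interaction F (its complement ties).

## Numerical and degenerate-input policy

Intensities are clipped to a floor before logs; fit windows shorter than
4 samples are rejected; empty segmentation results are flagged, never
raised; crop depths beyond the recorded range clip with a warning; all
physical quantities carry their units in field names (µm, mm, s). Volumes
interchange as multi-page float32 TIFF with a YAML geometry sidecar;
masks as uint8 TIFF; boundaries and quantification tables as CSV. The
pipeline writes a manifest (seed, config, version, timings) and is
bit-reproducible for a fixed seed; resuming from volumes on disk is
reproducible to float32 precision.

## Known limitations

* No automatic intra-wall (per-layer) boundary segmentation: layer windows
  come from ground truth (synthetic data) or user-supplied offsets.
* No NURD correction or frame-to-frame registration; flattening absorbs
  rigid radial motion only.
* μ_s and μ_a are never separated; only their sum is estimated.
* Absolute attenuation values depend on the depth calibration
  (pitch, refractive index); cross-study comparisons should use the
  day-0-normalized percent change.
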