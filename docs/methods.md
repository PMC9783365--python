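# Methods

## The reconstruction

Shifted position-diffuse reflectance imaging (SP-DRI) reveals absorbing
structures (capillary-scale threads, vessels) beneath the surface of a
turbid medium. Two diffuse-reflectance frames are acquired with the same
scene but the illumination source displaced laterally by a known amount —
here, by switching between LEDs mounted at fixed positions along two edges
of the imaging field. The processing chain is:

1. **Shift.** The frame of the second source is translated by the integer
   pixel difference between the two source positions, so the illumination
   cones of the two frames coincide. The subsurface structure content is
   thereby displaced between the two operands.
2. **Divide.** The first frame is divided pixelwise by the translated
   second frame. Because both operands now carry (to first order) the same
   illumination profile, the steep cone cancels and the ratio sits at a
   flat baseline of 1. The structure appears twice: as a dip below 1 where
   it darkens the numerator, and as a peak above 1 at its displaced copy
   in the denominator.
3. **Smooth.** A 2-D Gaussian filter (sigma 5 px) is applied to the ratio
   map, restricted to the valid region.
4. **Profile.** Cross-sections along the shift axis are post-filtered with
   a Savitzky–Golay filter (polynomial order 5, window 151 px) and the
   *deflection* — the largest departure from the profile's median
   baseline — is reported with its position, amplitude and polarity.

Key geometric constraint: the source shift must exceed the width of the
structure's image, otherwise the dip–peak doublet partially cancels under
the smoothing filters. The instrument geometry respects this (shifts of
153 px along x and 389 px along y against a ~151 px filter window and
structure images a few tens of px wide), and the synthetic test geometry
preserves those shift magnitudes even on reduced frames.

### Assumptions

- The two frames differ only in the illumination position ("otherwise
  identical parameters"): no motion, no exposure drift between frames.
- Integer-pixel shifts; source positions are rounded. Sub-pixel
  interpolation would alter the noise structure and is not used.
- One shift axis at a time (x or y). Joint two-axis alignment is a known
  possible refinement and is out of scope.
- Division order is fixed: the frame of the lower-numbered LED is the
  numerator, so the sign of a deflection is interpretable.

### Numerical choices

- Pixels translated out of the frame are masked invalid, not zero-filled.
- Zero-denominator pixels are invalidated rather than epsilon-padded: real
  16-bit data contain true zeros far from the cone.
- An optional illumination floor (`min_counts`) removes pixels where
  either operand is below a threshold. The ratio of two near-noise pixels
  is meaningless, and far from the source both operands approach the noise
  floor; the demonstration pipeline uses 5 sensor-noise sigmas. The
  default is 0 (plain `b > 0` rule).
- Smoothing uses a renormalized masked filter, `conv(ratio·mask) /
  conv(mask)`, so invalid pixels never leak into the valid region and a
  constant map is exactly preserved; `sigma = 0` is the identity.
- Savitzky–Golay filtering treats masked (NaN) samples by filtering each
  contiguous finite run separately, shrinking the window (keeping it odd)
  on runs shorter than 151 px. Missing values are propagated, never
  interpolated.
- Deflection detection uses the profile median as baseline (robust to a
  single deflection; the quantitative definition of "deflection amplitude"
  is this package's own, chosen because the source material treats it
  qualitatively). The extremum search excludes a border — the shift
  magnitude plus the filter half-window — around the profile ends *and
  around every masked run*, because division and filter edge artifacts
  concentrate at mask edges.
- Reciprocity (swapping numerator and denominator inverts the map) holds
  pixelwise on a shared alignment; it is exact up to IEEE division
  round-off (observed < 1e-14).

## Calibration

**LED localization.** The cross-section through a raw frame at the edge
row/column containing the sources is fitted with a four-parameter Gaussian
`a·exp(−(u−μ)²/2σ²) + c` by least squares; μ is reported as the LED
position. The physical cone decays exponentially, not Gaussian, but the
symmetric Gaussian is an adequate *position* estimator; the fit quality is
reported as R² = 1 − SSres/SStot on the raw profile, and values above
0.96 with center errors below 5 px are reached on synthetic cones with up
to 1% sensor noise. The offset term c is included although the underlying
model has none: real cross-sections ride on a background pedestal.
Initialization: μ at the argmax, σ at a quarter of the profile length,
a at max − min, c at min. A caveat: with the source close to one end of
the profile (short-side LEDs), the asymmetric domain biases the fitted
center by a few px toward the long tail.

**Exposure.** The exposure time is scaled so that the brightest region of
the frame lands at 95% of the 16-bit ceiling, assuming counts strictly
linear in exposure time. "Brightest region" is operationalized as the
99.9th-percentile pixel, which resists isolated hot pixels. A reference
whose robust peak is already clipped cannot be scaled meaningfully; the
exposure is halved (with a warning) until the predicted peak is unclipped.
No dark-frame subtraction or nonlinearity correction is applied.

**Depth window.** Only structures within 150–300 μm depth (inclusive) are
analyzed; the filter is a plain inclusive-bounds predicate.

## Optics closed forms

- Magnification: an infinity-corrected objective of nominal magnification
  M (designed for a reference tube focal length, 200 mm by Mitutoyo
  convention — an argument, not a constant) used with tube focal length f
  gives `M·f/f_ref`; the instrument's 5×/150 mm combination gives 3.75.
- USAF-1951: element resolution is `2^(group + (element−1)/6)` line pairs
  per mm; line width is `500/resolution` μm. Group 7 element 6 → 2.19 μm.
- Depth from focus: `d = t·(n2 − √(n2²−NA²)) / (n1 − √(n1²−NA²))`,
  implemented exactly as printed in the formula's source lineage. Note a
  documented oddity: its small-NA limit is `d → t/n2`, whereas the
  classical paraxial apparent-depth correction for focusing through a
  medium gives `d = n2·t`; the ratio may be inverted relative to the
  classical references. The printed form is kept deliberately rather than
  "corrected"; NA = 0 is rejected as a domain error (0/0).

## The synthetic phantom generator

The generator produces frame pairs with known ground truth so that every
stage is testable without instrument data. It emulates:

- **Illumination:** a single-exponential radial decay
  `I(r) = I₀·exp(−r/L)` centered at the LED's edge position. Defaults:
  peak I₀ = 60000 counts (≈ 92% of 16-bit saturation, matching the
  near-saturation exposure policy), decay length L = 500 px. The
  exponential character matches the observed cones; a full
  photon-transport solution is deliberately out of scope, because the
  reconstruction cancels the cone by division whatever its precise shape.
- **The thread:** an ordered polyline rasterized at width
  `diameter/pixel_pitch` px. Pixel pitch defaults to 3.45 μm / 3.75 ≈
  0.92 μm/px (camera pixel over system magnification). Local attenuation
  follows a Beer–Lambert-inspired saturating law
  `A = 1 − exp(−g·D·exp(−z/ζ))` with contrast gain g = 0.05 /μm and depth
  scale ζ = 300 μm; A rises with diameter D and falls with depth z, the
  two behaviours the reconstruction must reproduce, and stays in (0, 1).
  Depth additionally blurs the thread image (scattering) with a Gaussian
  of sigma `0.1 px/μm × z` — about 20 px at 200 μm depth, a diffuse-shadow
  spread that keeps the structure image narrower than the source shifts.
  The numeric values of g, ζ and the blur rate are modelling choices
  (only the monotonicities are externally constrained) and are
  configurable.
- **Sensor noise:** seeded Gaussian read noise, default sigma 0.5% of the
  peak (keeping localization fits above R² = 0.96 while exercising
  robustness), or Poisson shot noise; bit-for-bit reproducible given the
  seed.

What it does *not* emulate: radiative transfer and multiple-scattering
speckle, the phantom's bulk optical properties, polarization, curved
surfaces, frame-to-frame registration error, sensor nonlinearity and
fixed-pattern noise. Passing tests therefore demonstrate the algorithmic
correctness and the qualitative signal behaviour, not quantitative
radiometric fidelity on real tissue.

## Demonstration pipeline

`run_demo` mirrors a full measurement session for both thread diameters
(10 and 20 μm) and both shift axes (LED pairs #1→#2 and #4→#5): simulate
the pair, calibrate (exposure check and LED localization on the first
frame), reconstruct, profile, and report. The thread is a single hairpin
loop placed in the lit region of the active pair — as in practice, where
the operator verifies the structure is in the field of view before
measuring — with its legs perpendicular to the shift axis and spaced
2·|shift| apart so numerator and denominator images of the legs never
coincide. On frames smaller than the full 4096×3000 sensor, LED pairs
that do not fit are recentered with their shift preserved (scaling
positions proportionally would shrink the shift below the filter window
and self-cancel the doublet).

The raw-versus-reconstruction contrast comparison quantifies why the
ratio map is the better place to look for structure. The raw cross-section
is divided by its own Savitzky–Golay trend — in raw data the illumination
profile is unknown, so it must be estimated from the data, and the
estimate unavoidably absorbs part of the structure signal — then both
profiles' deflection amplitudes are taken relative to their baselines.
The ratio-map deflection also benefits from the denominator-side peak,
whose amplitude `A/(1−A)` exceeds the plain dip `A`. In every synthetic
case the reconstruction's relative deflection exceeds the raw one by a
factor of several.

## Problem sizes

Acceptance-level simulations of the calibration chain run on the full
4096×3000 frame. The property suite runs the demonstration cases at full
scale once and uses reduced frames (2600×2200 and smaller) elsewhere,
chosen so that the full-scale shift magnitudes, the 151 px filter window
and the detection borders all fit with margin; the asserted properties are
size-independent. The amplitude-monotonicity grid is 3 diameters
(10/15/20 μm) × 3 depths (150/225/300 μm) with noise disabled.

## Known limitations

- Integer-pixel alignment only; sub-pixel source spacing is rounded.
- The short-side (y) geometry places the sources close to the frame edge;
  Gaussian localization there carries a few px of asymmetric-domain bias,
  and the out-of-overlap band (up to 389 px) plus detection border
  consumes a substantial part of the frame height.
- The deflection detector reports the single largest departure; multiple
  structures in one profile are not separated.
- Exposure calibration trusts strict linearity of counts in exposure
  time and a single reference frame.
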