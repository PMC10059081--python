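# Methods

This note documents the models, conventions and design choices behind
`canopytherm`, and what the synthetic benchmarks do and do not show.

## Measurement pipeline

**Extraction statistic.** A repetition's temperature is the median of the
masked thermal cells after a single upper-tail screen at μ + 3σ.  Two
conventions are fixed deliberately:

* the screen uses the **population** standard deviation (divide by n), so
  the filter is an unambiguous function of the sample; all *reported*
  dispersion statistics use the sample standard deviation (divide by n−1,
  returning 0 for a single value);
* the screen runs **once** and only on the upper side.  Masking errors leak
  hotter background (soil, branches) into the ROI, never colder material,
  so cold values are kept and the filter is not iterated to convergence.

Consequences tested as invariants: the retained set is a subset of the
input, and the median can only stay or fall.  With 5 % of masked cells
contaminated at +15 °C the screen removes the contamination outright
(threshold ≈ μ + 10 °C) and the median moves by < 0.05 °C.

Repetitions captured inside the post-FFC transient window are excluded
from all statistics; repetitions whose registered mask covers fewer than
`min_canopy_cells` (default 10) thermal cells are skipped with a logged
warning rather than failing the session.

**Registration.** The cameras are rigidly co-mounted, so the model is an
axis-aligned crop + per-axis scale (no rotation, shear or lens model).
Coordinates are 0-based, row-major, top-left origin; rectangles are
half-open.  Calibration point pairs give the visible pixel at the top-left
corner of a thermal cell's footprint; per-axis ordinary least squares
recovers scale and offset, and the RMS residual is reported in cell units.
A thermal cell becomes canopy when the canopy fraction of its contributing
visible pixels is ≥ `min_fraction` (default 0.5; ties count as canopy).
The cell index of a pixel is computed as ⌊(r − row0)/scale⌋; this is exact
whenever the pixels-per-cell ratio is an integer (the 4× default), which
is also the regime in which the synthetic ground-truth mask and the
registered mask coincide exactly.

**Segmentation.** The default backend is ExG = 2g − r − b on
channel-sum-normalised pixels (range [−1, 2]; all-green = 2, gray = 0),
thresholded by Otsu, with connected components under `min_region_px`
(default 8) removed to suppress speckle.  Normalisation makes the index
invariant to uniform brightness scaling.  Otsu on a constant index image
is degenerate, so the configured fixed threshold is used as a fallback.
The *learned* backend replaces a semantic-segmentation network stage with
a gradient-boosted per-pixel classifier over (r, g, b chromaticities, ExG,
intensity), trained on synthetic scenes; it exists to exercise the
pluggable-backend interface and is optional — the pipeline runs end to end
on the color index alone.  No morphology or hole filling is applied to
either backend's mask by default.

**Protocol cost model.** A series executes the 30 s transient and captures
up to the last repetition its strategy retains: `first_3` stops after
3 × 0.6 s = 1.8 s of captures (31.8 s, rounded to 32 s), while `all` and
`first_mid_last_3` must run the full 25 (45 s).  The per-repetition capture
time of 0.6 s is inferred from that timing identity (45 = 30 + 25 × 0.6)
and is configurable.  Two accounting rules matter and are fixed by the
published timing table they reproduce: the series time is rounded to the
nearest second **before** multiplying by the executed series count (3 × 32
= 96 s, not round(3 × 31.8) = 95 s), and "measurements" counts repetitions
retained for computation, not frames captured (the first/middle/last
strategy captures 75 frames but reports 9).  The middle index of n
repetitions is ⌊(n−1)/2⌋; for n = 25 the 0- and 1-based conventions pick
the same (13th) repetition.

**Alignment.** With a 15-min thermal period and 10-min reference period
only two timestamps per hour coincide, so each faster sample is assigned
to its nearest thermal timestamp (earlier wins exact ties) and averaged
within ± half the thermal period; windows without samples emit no pair and
each fast sample contributes at most once.  The window is centered because
the averaging is only required to "approximately" match the slow rate; the
exact rule is fixed here for determinism.  Note that window-averaging a
*curved* latent signal introduces an O(curvature × window²) bias (~5 mK at
the default rates), so the exact zero-noise identity (slope 1, intercept
0, R² 1 to 1e−9) is asserted with equal sampling periods, where alignment
is pointwise.

ΔT is defined as T_S − T_IR, so a thermal sensor that overestimates the
canopy yields positive ΔT; the reported maximum is max|ΔT|.  R² is the
squared Pearson correlation, for the regression and for the covariate
screens alike.

## Synthetic data

The scene generator emulates the statistical structure the pipeline
assumes, not plant morphology.  Leaves are overlapping random ellipses in
green hues placed until the target cover fraction is reached (realised
cover overshoots by at most one ellipse, ≲ 0.3 % of the frame at default
sizes); the background is soil brown crossed by dark branch strokes.  The
thermal matrix assigns each cell its majority class temperature — defaults
26 °C canopy / 38 °C soil / 34 °C branches, a transpiring midday canopy
over sun-heated bare soil — plus a *static* within-canopy spread
(0.3 °C, leaf-to-leaf geometry) and per-capture sensor noise (0.1 °C).
Within a session the scene geometry is fixed: the cameras are rigidly
mounted and a series lasts under a minute, so only noise, drift and gusts
vary between repetitions.

Drift is additive and uniform across the frame, b₀·exp(−t/τ) since the
FFC, with defaults b₀ = 1.5 °C, τ = 10 s chosen so that the residual bias
at the first post-transient capture is 1.5·e⁻³ ≈ 0.075 °C — consistent
with a protocol that waits 30 s precisely because the reading has then
stabilised.  These are artifact defaults, not measured camera constants.
Gusts subtract a fixed delta from canopy cells of randomly selected
repetitions; gust flags are drawn from a dedicated RNG stream so that
toggling the gust probability leaves every other draw unchanged
(paired-seed differencing is a test oracle).

Field days share one latent canopy curve between the thermal and reference
channels: air temperature is a 24-h cosine (min 18, max 36 °C, peak 14:00
by default) and the canopy sits 1.5 °C below it in the morning, crossing
near the peak hour and rising to the configured stress offset above it —
the diurnal signature of a water-stressed canopy.  Both temperature
sensors see this curve plus independent 0.15 °C noise, so their true
agreement is known; wind and radiation are independent diurnal shapes with
noise, so the ΔT covariate screens have a true R² of ~0.

**What passing does not show.** The synthetic scenes have near-separable
leaf/soil color distributions, no shadows, specular highlights, mixed
pixels, sky background or registration error beyond the model class, and
the field-day noise is white.  Results on this benchmark bound the
pipeline's arithmetic and protocol logic, not the field performance of any
camera or of the segmentation backends on real imagery — which is why the
agreement benchmark is a structural analogue (R² ≥ 0.95 at these noise
levels) rather than a reproduction of field statistics.

## Problem sizes and numerics

The bundled benchmarks use 20 sessions of 3 × 25 repetitions at the full
480×640 / 120×160 resolution (≈ 6700 canopy cells at 35 % cover, far above
the ≥ 500 the recovery analysis assumes), 8 field days of 33 thermal
samples each, 20 segmentation scenes across the realistic 20–50 % cover
range, and 1000 random vectors (n ≤ 200) for the filter oracle; unit tests
run on 120×160 scenes.  Temperatures are float64 throughout; centikelvin
TIFF decoding is value/100 − 273.15 with values below −80 °C rejected as
non-physical; CSV reports format temperatures at 3 decimals while JSON
keeps full precision so round trips are exact.  All generators are
`numpy.random.default_rng` streams spawned from a single seed;
identical (config, seed) gives bit-identical output.

## Known limitations

* No radiometric physics: emissivity and reflected temperature are carried
  as metadata only, and synthetic thermal values are already in °C.
* Registration ignores rotation and lens distortion; field-of-view overlap
  must be rectangular.
* The learned backend is a color classifier; it cannot use texture or
  context and is not a substitute for evaluating a segmentation network on
  real imagery.
* The cost model accounts for capture time only, not energy, storage or
  transmission, which the subsampling strategies also reduce.
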