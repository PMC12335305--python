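# Methods

This note documents the models, algorithms and design choices behind
`mupadkit`, and what the synthetic-data tests do and do not demonstrate
about real captured images.

## Colour models

All statistics are computed in floating point on the readout's scales:
R/G/B/grayscale on 0–255, hue on 0–360°, saturation and value on 0–100 %.
Conversions use the standard hexcone model. Grayscale uses the ITU-R BT.601
luma weights (0.299, 0.587, 0.114) — the default of the desktop tool
typically used for manual zone measurement — so that manual-vs-automatic
comparisons are not confounded by a weighting mismatch. Two conventions
keep downstream statistics well defined:

- achromatic pixels carry hue 0, never NaN, so zone averages never propagate
  missing values;
- hue is always averaged circularly (atan2 of mean sine/cosine). The
  arithmetic mean of, say, {350°, 10°} is 180° — the opposite colour — while
  the circular mean is 0°, which is why it is the only sanctioned hue
  average in the package.

Libraries that use a 0–179 hue dialect must be converted at the I/O
boundary; nothing inside the package uses that scale.

## Zone segmentation

Coloured reaction products on white filter paper separate most strongly in
the saturation channel, so segmentation thresholds S (rescaled to 8 bits)
with Otsu's criterion, using a smallest-maximiser tie-break and defining
foreground as strictly above the level. Nearly achromatic images
(max S < 5 %) fall back to inverted grayscale.

One global Otsu level is not sufficient when the four zones carry different
analyte levels: the between-class criterion can then place the threshold
*between* faint and strong zones rather than between paper and zones. The
package therefore applies Otsu hierarchically — while fewer than the
expected number of zones survive filtering, Otsu is re-run on the lower
intensity class, admitting progressively fainter zones. On
equal-saturation layouts this reduces to a single Otsu application.

Surviving connected components are filtered by area
(≥ 0.25 × median component area) and isoperimetric circularity
(4πA/P² ≥ 0.6; zones are printed circles, flow channels and smears are
elongated). If more components than zones survive, the largest by area are
kept, or the ones nearest an optional expected-layout hint. Zone IDs are
assigned in reading order (top-to-bottom, left-to-right by centroid, with a
row tolerance of half the median zone diameter). Before measurement every
mask is eroded by 10 % of its equivalent radius: paper substrates
concentrate pigment at the zone rim (coffee-ring effect), and the rendered
synthetic zones have anti-aliased rims, so the same margin excludes both.
Fewer surviving zones than expected raise a segmentation error carrying the
count found — the pipeline never guesses.

## Calibration

The static response is fitted by ordinary least squares,
`y = intercept + b·c`. Metrics:

- sensitivity |b| (channel units per mM);
- `S = sqrt(SSres / (n − 2))`, the residual standard deviation;
- `LOD = 3.3·S/|b|`, `LOQ = 10·S/|b|` (the ICH σ/slope convention), so
  LOQ/LOD = 10/3.3 for every curve;
- R², the coefficient of determination.

At least three points with two distinct concentrations are required (two
exactly collinear points would leave zero residual degrees of freedom); a
numerically zero slope raises an error rather than returning an infinite
LOD.

Hue-channel series are unwrapped around their circular mean before
regression — a hue response crossing 360→0 would otherwise corrupt the fit —
and the same offset is applied to readings at prediction time.

Inverse prediction uses `c = (y − intercept)/b` with the first-order
inverse-regression standard error
`se = S/|b| · sqrt(1 + 1/n + (c − c̄)²/Sxx)`. Out-of-range estimates are
flagged (`below_range`/`above_range`) but returned as-is: a device can
legitimately read above its linear span, and clipping would hide that.

Channel routing encodes the multiplex selectivity findings: dopamine is
quantified on saturation (FeCl₃+phenanthroline or DNP), NADH on hue
(FeCl₃+phenanthroline or resazurin); dopamine+resazurin and NADH+DNP do not
react and are flagged non-selective, with the raw hue still reported.

Accuracy is summarised as MAPE, `(100/n)·Σ|aᵢ − pᵢ|/aᵢ`, undefined when any
true value is zero.

## Kinetics

Colour development is modelled as a single exponential approach to a
plateau, `I(t) = I∞ + (I₀ − I∞)·e^(−t/τ)`, with no sign restriction on
I₀ − I∞ (hue may fall while saturation rises). Fitting is nonlinear least
squares (trust-region reflective) with relative tolerance 1e−8,
initialised from the data: I₀ from the first sample, I∞ from the mean of
the last 10 % of samples, τ from the 63 %-of-range crossing time by linear
interpolation; τ is bounded in (0, 100·t_max]. An optimiser failure returns
an unconverged result with diagnostics, never a silent default.

Traces whose range falls below 3× a noise estimate are rejected as flat.
The noise estimate uses second differences (`σ̂² = E[Δ²I²]/6`), which is
insensitive to the smooth exponential trend. Note the gate's limits: the
range of *many* i.i.d. noise samples can exceed 3σ, so a long pure-noise
trace may pass the gate and instead reveal itself through a near-zero R².

`time_to_fraction(f) = −τ·ln(1−f)` converts τ into a time-to-develop
readout (f = 1 − e⁻¹ returns τ). `acceleration_ratio(τ_ref, τ_cat)` is the
fold-speedup of the catalysed reaction; applied to the bundled measured τ
table it reproduces the ≥17-fold (dopamine) and ≥2.4-fold (NADH) G/Pt
acceleration across catalyst levels.

## Synthetic device generator

The generator defines the study conditions for all tests:

- geometry: four non-overlapping circular zones (radius 30 px on a 240×320
  canvas, a 2×2 layout) on white paper, anti-aliased rims via coverage
  blending;
- static response: the target HSV channel follows
  `intercept + slope·min(c, range_max)` — defaults are the
  dopamine/saturation response of the best catalysed device, slope
  4.26 %/mM over 0.01–10 mM — with the other channels at fixed base values,
  converted to device RGB for rendering;
- noise: additive i.i.d. Gaussian in RGB, clipped to [0, 255] after
  rounding. This deliberate simplification keeps CLT-based test bounds
  exact; real sensor noise is neither Gaussian nor pixel-independent;
- illumination: a multiplicative radial cosine falloff (on all RGB
  channels, which scales V while leaving H and S invariant), default
  strength 0 — the physical detection chamber achieves uniform
  illumination, and the default encodes that;
- kinetic traces and calibration series from the same closed forms the
  fitters assume, with seeded Gaussian noise (hue series wrap mod 360
  rather than clip).

Identical spec + seed give byte-identical images; changing the seed changes
only the noise realisation, never the ground truth.

Because the generator and the fitted models share their functional forms,
passing tests demonstrate *parameter recovery under the stated noise
model* — correctness of the algorithms — not robustness to the ways real
captures differ: paper texture, uneven reagent spreading, perspective,
white-balance drift and illumination structure are all outside the noise
model. The noise-contraction test fixture additionally uses a dark,
saturated zone colour (V = 40, S = 90) whose saturation responds with ≈ unit
gain to RGB perturbations, since the σ/√area scaling it checks presumes
that gain; for brighter, less saturated colours the same scaling holds with
a colour-dependent gain factor < 1.

## Numerical choices and degenerate inputs

- Otsu ties broken to the smallest maximising level; constant histograms
  raise a degenerate-input error.
- Channel statistics stay floating point end to end; rounding happens only
  at CSV export (4 decimals) and 8-bit rendering.
- A mask erosion that would empty a zone falls back to the uneroded mask.
- Quantisation budget for the full loop: rounding planted RGB to 8 bits
  perturbs a zone's mean saturation by at most ~100/V_max·0.5 ≈ 0.4 %,
  i.e. ≲ 0.5 channel units ≙ 0.12 mM at sensitivity 4.26 — the tolerance
  used by the loop-identity tests.
- All randomness flows through `numpy.random.default_rng` from explicit
  seeds; replicate studies derive per-replicate seeds from a base seed.

## Problem sizes

The replicate studies use 100 seeded calibration fits (16 concentrations
each), 200 noisy kinetic traces (61 samples), 20 noisy four-zone images and
10⁵ random RGB triples for the oracle-equivalence check — sizes chosen so
the whole suite and the acceptance script run in seconds while the
stochastic assertions retain comfortable margins.

## Known limitations

- The segmentation route is data-driven; a fixed-geometry (printed-design)
  route exists only for the synthetic "manual" comparison, not for real
  images with an unknown pose.
- No colour management: the package assumes capture-time white balance, as
  in an enclosed, LED-lit detection chamber.
- Single-exponential kinetics only; mechanistic rate laws and
  multi-exponential development are out of scope.
- Unweighted OLS calibration only; no 4PL or variance weighting.
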