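# Methods

## The photogeometric model

For a Lambertian surface under a collimated source, luminance in
observer-centric spherical coordinates is

    L = max(0, r · i · [cos φs cos φi + sin φs sin φi cos(θs − θi)])

with surface tilt θs, slant φs, light azimuth θi, elevation φi, albedo
r and source strength i — i.e. the clipped dot product of the unit
surface normal and unit light vector. For fixed illumination this is a
cosine of tilt,

    L = max(0, A cos φs + B sin φs cos(θs − C)),

whose offset A·cos φs vanishes and amplitude B·sin φs saturates as
slant approaches 90°. At a self-occluding rim, where slant ≈ 90° and
tilt equals the orientation of the rim's image contour, luminance
therefore reduces to a pure cosine of contour orientation,
L = max(0, B cos(θrim − C)), with phase C equal to the illumination
azimuth. A *level cut* — the contour made by slicing a relief surface
with a fronto-parallel plane — approximates the same relationship:
contour orientation equals surface tilt (up to the convex/concave
180° ambiguity), and for smooth terrain the slant terms vary slowly
along the cut, so intensity adjacent to the contour still covaries with
contour orientation.

The *covariation statistic* quantifies this in an image: contour
orientations are converted into angular separations from a candidate
illumination azimuth, separation is Pearson-correlated with adjacent
intensity (sign-flipped so shading-like falloff scores +1), and the
maximum over 16 candidate azimuths (0°–337.5° in 22.5° steps) is the
score ρ. The sweep guards against incidental correlations consistent
with some other light direction; its argmax breaks ties toward the
smallest azimuth so results are deterministic. A linear falloff is used
in place of the cosine when *constructing* ribbon stimuli because over
the quarter range of separations [0°, 90°] the two functions correlate
at r = 0.979 (0.993 over the full half-turn); the package computes this
constant on a dense grid rather than hard-coding it.

## Coordinate and angle conventions

Rasters are stored row-major, origin top-left, rows running down the
screen. All angle-valued quantities use the display convention: 0° =
rightward, 90° = up on screen, counter-clockwise positive, achieved by
an explicit sign flip of the row axis. Heights are proximal relief
(larger = nearer the viewer); the surface normal of h is ∝ (−hx, −hy, 1)
in display coordinates, so the image-projected normal — the tilt
direction — points downhill. At a convex level cut the into-mask
contour normal coincides with this tilt, which is what makes the
ground-truth-tilt oracle usable for validating the contour-orientation
estimator.

One deliberate exception: gauge-figure probe settings record tilt as
the *uphill* image direction. The profile integrator uses the standard
along-line gradient g = tan(slant)·cos(tilt − line direction), and with
the uphill convention the integrated profile reads directly as relief
(a 45°-slant probe with tilt along the line contributes slope +1), so a
synthetic observer's settings on a known ridge round-trip to the ridge
itself rather than to its negation.

## Synthetic terrain

Terrains are seeded Gaussian white noise, low-pass filtered in the
frequency domain with a hard isotropic cutoff (default 8 cycles/image),
zero-meaned and scaled to a target RMS relief. This replaces the
procedural-modeling route of deforming and subdividing a mesh: the
perceptual machinery downstream only needs a smooth, isotropic,
band-limited relief, and the spectral construction gives exact control
of that band. A hard cutoff concentrates 100% of spectral energy below
the band limit; the mild ringing it can introduce is far below the
relief amplitude and does not affect contour statistics. The
flat-valley variant used for defocus scenes clips the field at a height
quantile (default the median) and Gaussian-smooths the clip skirts
(σ = 3 px default), emulating smooth bumps rising from a plane.

Level-cut depths are read off the exact empirical height distribution
(sorted heights, ties toward the smaller depth), so the achieved
visible fraction is within 1/size² of the request for continuous
fields. Convex masks hide everything behind the plane (h < d); bistable
masks are their exact complements.

What the generator does *not* emulate: perspective, cast shadows,
interreflections, specular components, sensor noise, and the particular
spatial statistics of any procedural-texture implementation. Passing
tests therefore show that the measurement machinery is correct on
smooth band-limited reliefs, not that it is robust to photographs.

## Rendering and defocus

Rendering is orthographic: per-pixel normals from central differences,
shaded with the clipped Lambertian law. Default illumination is the
top-lit condition (azimuth 90°, elevation 45°, strength 5) with albedo
0.3. The default normalization divides by r·i so a fronto-parallel
facet maps to cos(elevation) ≈ 0.71 and nothing clips; max-to-1 and
unnormalized modes are available, the applied scale is recorded, and
clipping to [0, 1] plus any quantization is always last.

Defocus is a thin-lens layered blur: per-pixel blur scale
σ(z) = g·|z − z_focus|/N for f-number N, with the depth map split into
≥ 8 equal bins (12 by default), each layer Gaussian-blurred with its
bin-center σ and alpha-composited far to near with normalized coverage.
The bin containing the focal plane is snapped onto it so in-focus
layers pass through exactly. The calibration constant g (default
18.7 px per length-unit of defocus at N = 1) is chosen so the strong
condition (f/1.4, far plane 0.6 length units from focus, the default
camera-at-20/plane-at-19.9/peaks-at-19.3 geometry) gives σ ≈ 8 px on a
1024² image; only the ordinal structure (none < f/2.8 < f/1.4, with σ
exactly doubling when N halves) carries scientific weight, since a
physical pixel scale would require lens internals that are not part of
the model.

## Contour measurement

Contour pixels are the non-mask pixels with a masked 8-neighbour —
i.e. they live on the shading side, so an intensity sample one pixel
further into the gradients can never read the occluder gray. (For a
disc occluder this ring is the Chebyshev perimeter, ≈ 8R pixels rather
than 2πR; the extraction is validated against a brute-force per-pixel
neighbour check.) The undirected tangent at each contour pixel is the
leading principal axis of contour-pixel coordinates in a centered 9×9
window; fewer than 3 contour pixels in the window flags the pixel
invalid. The tangent is resolved into a 360° into-mask normal by
probing 2 px along both candidates (tangent ± 90°): the candidate whose
probe lands in the mask wins, both-or-neither is flagged invalid. A
2-px probe is used because a 1-px probe fails on single-pixel mask
necks. Ribbon stimuli are measured with inset 0 (the ribbon is centered
on the contour); masked terrain renders with inset 1.

On 50%-visibility level cuts of default terrains the estimator attains
a circular MAE of ≈ 4° against the −∇h tilt oracle with > 95% of pixels
valid.

## Ribbon stimuli

Ribbon paths are convex level-cut contours of fresh seeded terrains at
50% visibility. Noiseless luminance is L = 0.8 − 0.6·Δ(θ, 90°)/180°
(Δ = angular separation): 0.8 at 90°, 0.5 — the background gray — at
exactly vertical segments, 0.2 at 270°. Covariation is degraded by
mixing with noise whose radially averaged Fourier amplitude matches the
average spectrum of a deterministic bank of 16 rendered terrains
(computed at first use and cached; random conjugate-symmetric phase
makes each texture real-valued and seeded). Noise samples are affinely
rescaled to the ribbon gamut [0.2, 0.8] along the path before mixing so
a pure-noise ribbon occupies the same range as a noiseless one. Width-2
ribbons paint each path pixel and its neighbour one step along the
into-mask normal. The 13 stock mixing proportions (0, 0.15, 0.30,
0.35–0.70 in steps of 0.05, 0.85, 1.0) spread the measured score
roughly uniformly over [0, 1].

## Analysis layer and synthetic observer

Paired-comparison data live in a wins matrix; tallies are percent
chosen per appearance (mean exactly 50% for complete balanced designs).
Trials are binned by measured ρ into [0.9, 1.0], [0.8, 0.9), …,
[0.4, 0.5) plus a bottom bin for everything below 0.4; empty bins are
missing, not zero. The selection slope is OLS of percent-chosen on
noise percentage. Latent scores use a Bradley–Terry fit (logistic link,
MM iteration to 1e−8, geometric-mean identification); it refuses
disconnected designs and stimuli with all-one-sided records, whose MLE
is infinite. The probit (Thurstone) link would serve equally; logistic
was chosen for its closed-form two-item check (a 75/25 split is a score
difference of log 3).

Gauge-figure settings are integrated by averaging repeats at the
gradient stage — integration is linear, so this equals averaging
profiles but tolerates missing repeats — then cumulative trapezoid
integration from zero. Profiles are normalized multiplicatively to the
grand mean height (profiles are anchored at zero, so additive shifts
would not equalize them); zero-mean profiles are rejected rather than
silently shifted.

The synthetic observer is a latent-score chooser: score = α·ρ +
β·convex_fraction − γ·blur_level (defaults α = 2, β = 1, γ = 0.75 —
fixtures chosen to separate the masking conditions, not estimates of
human parameters), choices Bernoulli with logistic link, decision
noise τ and optional lapse rate. Gauge settings are ground-truth
attitudes perturbed by Gaussian angular noise of dispersion κ degrees
(slant clipped to [0, 89.9°] to keep gradients bounded); κ = 0 returns
the exact truth.

## Numerical choices and problem sizes

- All randomness flows through `numpy.random.default_rng(seed)`; every
  generator output is a pure function of (arguments, seed).
- Azimuth-sweep ties break to the smallest azimuth; quantile ties to
  the smaller cut depth; PCA tangents use the symmetric eigensolver.
- The cosine fit linearizes I ≈ A + u·cos θ + v·sin θ and reports the
  Pearson r between fitted and observed values with a two-sided t
  p-value (n − 2 df). The p-value ignores spatial autocorrelation
  along the contour and is descriptive only. Degenerate designs
  (constant intensity, rank-deficient regressors) raise errors.
- Test and validation runs use 128²–256² grids, 160² ribbon stimuli,
  100-seed Monte-Carlo loops, 500 trials/pair for score recovery and
  200 trials/level for slope recovery; these sizes already leave the
  checked tolerances an order of magnitude of headroom, and all
  statistics scale in the expected √n manner if larger runs are wanted.

## Known limitations

- Orientation estimation is pixel-level; no sub-pixel contour
  localization or polygonal tracing.
- The defocus model is layered 2D compositing, not light transport;
  occlusion-boundary bleeding is approximated by normalized coverage.
- The covariation p-values are anti-conservative on real contours
  (neighbouring pixels are correlated).
- The synthetic observer is a validation harness for the analysis
  code; its coefficients carry no psychophysical content.
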