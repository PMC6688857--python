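# photogeo

Stimulus synthesis and measurement tools for studying how bounding
contours shape the perception of shading, 3D shape and optical focus.

When a smooth Lambertian surface is lit by a collimated source, the
intensity of the shading adjacent to its bounding contour covaries with
the orientation of that contour: along a self-occluding rim,
L = max(0, B·cos(θ − C)), a cosine of contour orientation θ whose phase
C is the illumination azimuth. The same relationship approximately
holds along *level cuts* — contours made by slicing a relief surface
with a fronto-parallel plane. This orientation–intensity covariation is
a candidate cue the visual system uses to decide that a blurry-looking
gradient is actually focused surface shading. `photogeo` builds the
stimuli that manipulate this cue and the machinery that measures it:

- **terrain** — seeded band-limited random relief; level-cut masks at
  chosen visibility fractions, convex/bistable polarity, 180° rotation;
- **shading** — orthographic Lambertian rendering, gray-mask
  compositing at the gradient mean, thin-lens depth-of-field blur;
- **contours** — gradient-side contour extraction, 9×9 principal-axis
  orientation estimation, into-mask 360° disambiguation, adjacent
  intensity sampling;
- **covariation** — the statistic ρ: sign-adjusted Pearson correlation
  of angular separation vs. intensity, maximized over 16 candidate
  illumination azimuths, plus a direct cosine fit;
- **ribbons** — two-pixel-wide shaded ribbons on a gray background with
  the covariation parametrically degraded by spectrum-matched noise;
- **psychophysics** — paired-comparison tallies, correlation binning,
  selection-slope regression, Bradley–Terry latent scores,
  gauge-figure relief-profile reconstruction;
- **observer** — a synthetic observer (latent focus scores, logistic
  choices, noisy gauge probes) so the whole analysis layer is testable
  without human data.

See `docs/methods.md` for the model, conventions and numerical choices.

## Worked example

Generate a ribbon stimulus at 45% noise and re-measure its covariation:

```python
from photogeo import ribbons

img, spec, mask = ribbons.make_ribbon_stimulus(seed=7, noise_proportion=0.45, size=256)
res = ribbons.measure_ribbon(img, mask)
print(f"n={res.n_pixels}  rho={res.score:.3f}  azimuth={res.best_azimuth:g}  "
      f"cosine-fit r={res.cosine_fit_r:.3f}")
```

prints

```
n=4199  rho=0.903  azimuth=90  cosine-fit r=0.892
```

4199 contour pixels were measured; the maximum sign-adjusted
correlation between angular separation and ribbon intensity over the
16 candidate azimuths is ρ = 0.903, attained at the top-lit 90°
azimuth (as designed — noise weakens but does not relocate the
covariation), and a direct cosine fit of intensity against orientation
agrees (r = 0.892). The same ribbon with `noise_proportion=0.0`
measures ρ = 0.9998 at 90°: the noiseless construction is near-perfect
by design, and ρ falls monotonically toward chance as the noise
proportion rises to 1.

The same operations are scriptable from a shell:

```sh
photogeo terrain --seed 1 --size 512 --out h.tif
photogeo levelcut --heights h.tif --fraction 0.5 --polarity convex --out m.png
photogeo render --heights h.tif --mask m.png --out stimulus.png
photogeo ribbons --seed 7 --noise 0.45 --out ribbon.png
```

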