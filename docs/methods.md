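# Methods

`camopt` estimates the *visibility function* of a coloured target in a
natural scene — the mapping from target colour to expected detection
time — and searches it for the colours that are hardest and easiest to
see, for a normal trichromatic observer and for a simulated red–green
dichromat (protanope). Because the original human reaction-time data
are not public, the package ships a synthetic observer whose ground
truth is known exactly; every downstream stage (regression, gamut
search, inference) is exercised and validated against that ground
truth.

## Dichromat simulation

Protanopia is simulated with the Viénot–Brettel–Mollon construction:
8-bit sRGB channels are linearised, transformed to an LMS-like cone
space by

```
L = 17.8824 R + 43.5161 G + 4.11935 B
M = 3.45565 R + 27.1554 G + 3.86714 B
S = 0.0299566 R + 0.184309 G + 1.46709 B
```

the missing long-wavelength signal is replaced by
`L' = 2.02344 M − 2.52581 S` (the plane through white and the blue
primary, both of which the projection leaves fixed), and the result is
transformed back, clamped and re-quantised. The default transfer
function is a pure power law with exponent 2.2 and the default
re-quantisation rounds half away from zero; both are configuration
(`transfer="gamma22" | "srgb" | "vienot"`, `rounding="half-away" |
"half-even"`), because the projected gamut's unique-colour count is a
sensitive joint fingerprint of exactly these conventions. Under the
default conventions the full 2^24-colour cube projects onto 73,953
unique 8-bit colours; the `vienot` transfer (which applies the
reference implementation's affine gamma pre-step on decode) gives
64,760. Published counts from other implementations differ at the
hundreds level for exactly this reason, so `enumerate_dichromat_gamut`
always records the achieved count and the conventions in its metadata
rather than presuming one canonical number.

Quantisation also means the projection is idempotent only to within
one 8-bit step: re-applying it moves about 11% of gamut members by ±1
in a single channel. The achromatic axis is exactly fixed.

## Stimuli

A stimulus is three layers: procedural background, shaded sphere
target, foreground occluders. Backgrounds are multi-octave value
noise mapped through an environment palette (dark greens/khakis for
forest; beiges for desert — palettes are config data). The target is
a 128 px diameter sphere whose widest opaque row spans exactly its
diameter; shading is Lambertian from a single upper-left light with an
ambient floor of 0.2, peaking at 1.0 at the highlight, applied
multiplicatively to the base colour. Occluders are an independent
thresholded noise field (mean cover 37.5%); compositing paints the
sphere over the background and then re-paints occluder pixels on top.
The occlusion fraction is the occluded share of the sphere's full disc
area in pixels, and placements are rejection-sampled from the
permissible-centre mask until the realised fraction lands in the
requested range ([25%, 50%] by default). Real photographs can be
substituted for the procedural layers wherever a `StimulusScene` is
accepted; the procedural generator trades their spatial statistics
(true 1/f structure, shadows, perspective) for determinism and
self-containment, so passing tests demonstrate correctness of the
pipeline, not ecological validity of any particular colour.

## Synthetic observer

Log reaction time for participant *p*, colour *c*, occlusion *o* in
environment *e*:

```
mu = mu0 + beta*o + delta_p − alpha * d/(d+k),   RT = exp(mu + sigma*z)
```

where `d` is the Euclidean distance in linear RGB between the
observer's representation of `c` and the nearest background centroid.
The representation is the colour itself for trichromats and its protan
projection for dichromats — so colours that project identically are
*exactly* equally detectable (the metamer contract). Noise is
lognormal because geometric-mean detection time is the summary of
interest, and `z ~ N(0,1)` trials exceeding the 10 s deadline are
recorded as failures without an RT (and excluded from regression
training; the trial table keeps them).

Defaults (units): `mu0 = log 2800` log-ms (baseline ≈2.8 s for a
perfectly matching colour at zero occlusion), `beta = 0.8` log-RT per
unit occlusion (≈22% slower across the experimental occlusion range),
`alpha = 1.5` (the most salient colours are found ≈3–4× faster than
the best-camouflaged one), `k = 0.25` (half-saturation contrast),
`sigma = 0.30` (trial-to-trial CV ≈31%, typical for visual search),
participant s.d. 0.1 log-units. Forest centroid rgb(70, 80, 40) (dark
khaki green); desert has two centroids, rgb(150, 125, 95) and
rgb(200, 175, 140) (dark and light beige), so the desert visibility
function is deliberately bimodal. These values were fixed once as
plausible magnitudes for a search task with a 10 s deadline and are
config, not code.

## Regression model

Per condition, reaction times are regressed on (colour/255, occlusion,
participant one-hot) with a residual MLP implemented in numpy: linear
projection to width 64, then N pre-activation residual blocks (two
64×64 fully connected layers with a skip each), then a linear head.
The target is log RT, standardised internally (which makes training
exactly equivariant to the RT unit). Training: Adam (lr 1e-3), batch
64, MSE, a random 90/10 train/validation split, early stopping with
patience 20 within at most 500 epochs, best weights restored;
everything float64 and single-threaded so runs are bit-reproducible
from the seeds. The block count is selected from {2, 4, 6} by paired
validation loss (ties to the smallest); which candidate wins on
synthetic data depends on the ground truth's complexity and is not
asserted.

Uncertainty comes from a bootstrap ensemble: each member trains on a
with-replacement resample of the condition's trials (resampling at
trial level over the pooled 5,000-trial table). A member's prediction
for a colour is the geometric mean over participants (exp of the
uniformly weighted mean of its per-participant log-RT outputs); the
ensemble point estimate is the mean of member predictions and the
standard error their s.d. divided by sqrt(n_members). Participant
marginalisation uses uniform weights; the choice is exposed as a
weight vector.

## Gamut search and summaries

Ensembles are evaluated at 37.5% occlusion (the design's mean) over
the full gamut or a lattice. The hardest/easiest colours are the
argmax/argmin of the point estimate, with ties broken by lower
standard error and then lexicographic colour order. The polar summary
maps each colour to (hue angle, RT deficit from the hardest colour);
achromatic colours, whose hue is undefined, are flagged and assigned
to a designated spoke. Full-scale evaluation (16.7M colours × 100
members) is supported but the analysis scripts run a 33-per-axis
lattice with 10 members — extremes on nested lattices of a smooth
function agree to within a grid step, which the tests check, and the
scale is recorded in every manifest so scaled runs are always
labelled.

## Inference

Two-sample permutation tests on the difference of means, 100,000
resamples, two-sided p with add-one smoothing `(1+k)/(n+1)`. The
sampling unit for between-condition contrasts is the per-bootstrap-
member mean predicted RT; within-condition (hardest vs easiest)
contrasts permute member-level predictions at the two extreme
colours. The resampler draws the smaller group's labels from the
sorted pool, making the two-sided p exactly invariant under swapping
the samples at a fixed seed. Families of contrasts are adjusted with
Benjamini–Hochberg FDR (statsmodels). The luminance-confound check
computes each image's mean Rec. 709 luminance on linearised channels,
differences it from the mid-grey interstimulus reference, and applies
a pooled two-sample t-test (df = n1+n2−2; 32+32 images gives df 62).

## Simulated validation

From each fitted visibility function, 25 colours per category —
easiest, intermediate (midpoint of the extreme RTs), hardest — are
drawn uniformly among colours within ±25 ms of the category target
(uniform sampling is this package's choice where the selection rule
was otherwise open). Fresh simulated participants then search only
those colours, and the report checks that the categories' geometric-
mean RTs preserve the predicted ordering.

## Numerical choices and limitations

* All randomness flows from named integer seeds through
  `numpy.random.SeedSequence`; dataset generation is a pure function
  of (config, ground truth, seed).
* The trichromat gamut is stored as packed 24-bit codes, never as
  Python objects; the dichromat enumeration is vectorised per red
  level and runs in a few seconds.
* Degenerate inputs fail loudly: occlusion ranges outside [0,1],
  unplaceable scenes (`PlacementInfeasibleError`), validation
  categories with fewer than 25 eligible colours, non-finite training
  loss, probability weights that do not sum to 1.
* The synthetic observer is smooth and low-dimensional by design; it
  cannot certify how the regression behaves on human data with
  sequential effects, learning, or non-lognormal tails.
* The protan projection darkens red-heavy colours, so with the default
  (reddish-beige) desert palette the luminance-confound t-test *does*
  find a rendering difference; whether the confound is absent depends
  on the background imagery, which is exactly why the check is part of
  the analysis rather than assumed away.
* BH adjustment is monotone and dominates the raw p-values but is not
  idempotent (a property sometimes wrongly assumed); tests assert the
  true properties.
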