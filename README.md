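# camopt — optimal colours for camouflage and conspicuity

What colour makes an object hardest — or easiest — to find in a given
natural environment, and how does the answer change when the observer
is red–green colour-blind? `camopt` answers this by estimating the
**visibility function** `V(c)`: the geometric-mean detection time of a
partially occluded target of colour `c` embedded in a scene. Because
an exhaustive search of the 24-bit RGB cube (2^24 colours) cannot be
run as an experiment, the pipeline measures reaction times on a few
thousand sampled colours, fits a smooth interpolator, and then reads
the optimum off the fitted function:

1. **Stimulus synthesis** — three-layer search scenes (background,
   shaded 128 px sphere target, foreground occluders), with occlusion
   rejection-sampled into [25%, 50%]. Dichromatic (protanope) viewing
   is simulated with the Viénot–Brettel–Mollon LMS projection.
2. **Trial data** — a synthetic observer emits reaction times
   `RT = exp(mu0 + beta*occ + delta_p − alpha·sat(contrast) + sigma*z)`
   per trial (lognormal noise, 10 s deadline censoring), 500 trials ×
   10 participants per environment × chromacy condition. Human trial
   tables in the same CSV schema can be substituted directly.
3. **Regression** — per condition, a residual MLP (block count chosen
   from {2, 4, 6} by validation loss) maps (colour, occlusion,
   participant) to log RT; a bootstrap ensemble (100 members at full
   scale, 10 at desk scale) provides the point estimate
   `V(c) = mean_m exp(mean_p log RT_m(c, p))` and its standard error.
4. **Gamut search** — the ensemble is evaluated over the whole gamut
   (or a lattice) at the mean occlusion 37.5%; argmax/argmin give the
   hardest/easiest colours, summarised in polar (hue, ΔRT) maps.
5. **Inference** — two-sample permutation tests (100,000 resamples) on
   per-member mean RTs, Benjamini–Hochberg FDR across each family.

The scientific model and every default are documented in
[docs/methods.md](docs/methods.md).

## Worked example

```python
from camopt import (SimulationConfig, ObserverGroundTruth, generate_dataset,
                    train_ensemble, predict_gamut, find_extremes, subgrid_gamut)

gt = ObserverGroundTruth(sigma=0.1)          # known ground truth
cfg = SimulationConfig(environments=("forest",), chromacies=("trichromat",))
trials = generate_dataset(cfg, gt, seed=11)  # 5,000 trials
ens = train_ensemble(trials, n_boot=10, base_seed=5, n_blocks=4,
                     condition=("forest", "trichromat"))
pred = predict_gamut(ens, subgrid_gamut(points=17), occlusion=0.375)
ext = find_extremes(pred)
print(ext.hardest, round(ext.hardest_rt), ext.easiest, round(ext.easiest_rt))
```

prints

```
ColourTriplet(r=64, g=80, b=32) 2932 ColourTriplet(r=255, g=255, b=255) 967
```

i.e. the fitted function says a dark khaki green (10 RGB units from
the generator's true optimum rgb(70, 80, 40)) takes ~2.9 s to find in
the forest, while white pops out in under a second.

The full analysis lives in `analysis/` as numbered drivers
(`01_simulate_trials.py` … `05_validation.py`): simulate all four
conditions, fit and search each visibility function, draw the polar
maps, check the luminance confound between renderings, and run the
simulated validation experiment. Each writes compact tables under
`results/`. At desk scale (10-member ensembles, 33-per-axis lattice)
the fitted extremes land on the generator's optima — e.g. forest
trichromat hardest rgb(40, 72, 40) at 2976 ms vs easiest rgb(0, 0, 255)
at 969 ms — and the dichromat conditions are uniformly slower
(mean +240–250 ms, all FDR-adjusted permutation p < 0.0001).

There is also a small CLI: `camo scene render`, `camo simulate`,
`camo colour simulate-protan`, `camo colour gamut`, `camo run-all`.

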