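# edge-salience

Tools for studying the **spectral edge effect** in auditory scene analysis:
the finding that in a scene of several simultaneous melodies occupying
separated frequency bands, listeners detect the melodies at the lowest and
highest bands of the scene better than those in between — a *relative*
frequency bias, independent of absolute frequency region.

The package covers the whole experimental cycle for a yes/no
melody-in-mixture detection task:

- **Stimuli** — random eight-tone pure-tone melodies, 2 s long, confined to
  frequency bands spaced evenly on the ERB-number scale
  (E(f) = 21.4·log₁₀(0.00437·f + 1)), each band anchoring a half-octave
  log-uniform melody range at its center. Tones get 10-ms raised-cosine
  ramps, and all melodies are aligned in A-weighted level so no band
  carries a loudness cue.
- **Designs** — counterbalanced trial lists for a six-band experiment
  (Target–Mixture and Mixture–Target presentation orders, random
  nontarget-band muting for constant mixture density) and a split-range
  experiment (two four-band ranges at density three, where muting can
  promote an interior band to a *relative edge*).
- **Simulated cohorts** — equal-variance Gaussian signal-detection
  observers with per-cell sensitivities d′ by (order × edge position),
  Gaussian between-participant variability, and optional
  musical-sophistication covariates; plus a matched-filter observer that
  detects templates directly in the rendered audio.
- **Analysis** — hit/false-alarm rates → d′ = z(H) − z(F) with log-linear
  correction → per-participant edge-minus-middle contrasts Δd′ →
  percentile bootstrap CIs over participants → mixed-effects models with
  random participant intercepts, a binomial GLM for within-band
  relative-edge hit rates, and the adjacent-vs-non-adjacent muting
  contrast.

## Worked example

Simulate a 25-participant cohort on the six-band design and run the full
analysis chain:

```python
from edge_salience import RunConfig, run_pipeline

cfg = RunConfig(experiment=1, n_participants=25, master_seed=42)
summary = run_pipeline(cfg, "demo_run")
```

or, equivalently, from the shell:

```sh
edge-salience run --experiment 1 --participants 25 --seed 42 --out demo_run
edge-salience report --summary demo_run/summary.json
```

which prints:

```
experiment 1: 25 participants
order effect: TM d'=3.00 MT d'=1.75 diff=1.25 CI [1.08, 1.43]
edge effect: edge d'=2.57 mid d'=1.85 delta=0.72 CI [0.60, 0.83]
  LME Intercept: beta=+1.544 p=5.02e-45
  LME order_tm: beta=+1.132 p=3.92e-53
  LME edge: beta=+0.875 p=3.47e-22
  LME order_tm:edge: beta=-0.787 p=7.13e-10
  LME band: beta=-0.020 p=0.254
  LME msi_training: beta=-0.050 p=0.583
  LME msi_perception: beta=-0.044 p=0.625
```

Reading the output: cohort sensitivity is far higher when the target cue
precedes the mixture (d′ = 3.00 vs 1.75 — with the cue first, attention can
be directed at the target band), and edge-band melodies beat interior
melodies by Δd′ = 0.72 with a bootstrap 95% CI excluding zero. In the
mixed model, the positive `order_tm` and `edge` coefficients recover both
effects; the negative `order_tm:edge` interaction says the edge advantage
is larger in the harder Mixture–Target order, while the numeric frequency
band and the sophistication covariates (simulated here with zero slope) do
nothing. This is the qualitative pattern the simulated cohort is
programmed with.

The stimulus side works standalone too:

```python
from edge_salience import default_layout, draw_melody, synthesize_melody
import numpy as np

layout = default_layout()             # centers 65 ... 2080 Hz
layout.band_range(5)                  # (1299.91, 1838.35): half-octave range
melody = draw_melody(layout, 5, np.random.default_rng(0))
wave = synthesize_melody(melody)      # 2 s at 44.1 kHz, ramped tones
```

`edge-salience generate --experiment 1 --seed 0 --audio --out stim/`
renders every trial's cue and mixture as WAV with a trial manifest.

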