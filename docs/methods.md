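# Methods

## Task and stimulus model

The package models a yes/no auditory pattern-matching task: a 2-s cue
melody and a 2-s mixture of melodies in separated frequency bands, in
either order (Target–Mixture or Mixture–Target), with a 1-s pause between
them; the listener reports whether the cue melody occurred in the mixture.
On present trials the melody embedded in the mixture is identical to the
cue in both frequencies and timing; on absent trials the cued band is
silent in the mixture and the cue melody is freshly drawn and withheld.

**Band layout.** Bands are placed by linear interpolation on the
ERB-number scale, E(f) = 21.4·log₁₀(0.00437·f + 1), between 65 and
2080 Hz, using the Glasberg–Moore (1990) constants; six bands give centers
that round to 65, 215, 441, 783, 1300, 2080 Hz. A band's melody range runs
from its center to half an octave above it (ratio √2); the layout
validator requires the gap between one band's upper bound and the next
band's center to be at least one ERB, ERB(f) = 24.7·(0.00437·f + 1),
evaluated at the gap's lower edge. This keeps concurrent melodies outside
each other's auditory filters, so detection is limited by informational
rather than energetic masking. Centers are kept at full floating
precision; integers appear only on display.

**Melodies.** Eight contiguous tones partition [0, 2] s. Boundaries come
from seven draws uniform on (0, 2), sorted; the whole draw is rejected if
any resulting duration is ≤ 50 ms (acceptance probability ≈ 0.21, matching
the closed form (1 − 8·0.05/2)⁷ and measured by simulation; a rejection is
always a full redraw, which preserves the conditional-uniform
distribution). Frequencies are uniform on log₂
frequency over the band's half-octave range, with no interval or scale
constraints. Tones are sinusoids gated by 10-ms raised-cosine onset and
offset ramps. The ramps are placed *inside* each tone's interval, so tones
stay contiguous and the 2-s duration is exact; whether the original
procedure extended tones instead is not determinable from the stimulus
description, and the embedded reading preserves the timepoint partition
exactly.

**Leveling.** Loudness cues are removed by aligning every melody to a
common A-weighted level. The IEC 61672 analytic A-magnitude curve is
applied in the frequency domain to the whole 2-s waveform (inter-tone
silence included in the RMS window), and each melody is scaled to the
target level — by default 40 dB SPL(A) under a configurable full-scale
calibration of 0 dBFS = 100 dB SPL. Alignment is per-melody, not per-band.
In a headless pipeline the absolute SPL figure is only a shared reference;
what matters is that the 65-Hz band receives ≈ 26 dB more digital gain
than a 1-kHz band of equal digital RMS, exactly compensating the A-curve.

## Experiment designs

**Six-band design (experiment 1).** One Target–Mixture block of 120
trials (20 per band condition) followed by one Mixture–Target block of 240
(40 per condition); presence is counterbalanced exactly within every
(block, band) condition, and trial order is a seeded uniform shuffle. In
design version 2, one random nontarget band is muted on present trials so
the mixture always contains five melodies regardless of target presence
(preventing a density-counting strategy); version 1 applies no muting.
Muting draws use an RNG stream separate from the shuffle so both versions
share identical trial bookkeeping under one seed. On absent trials the
target band is silent and all other bands play.

**Split-range design (experiment 2).** The six bands are split into a low
range (bands 1–4) and a high range (bands 3–6); each (order × range) block
is built as above (20/40 per condition, totalling 160 Target–Mixture and
320 Mixture–Target trials) and the range order is a configuration switch
for cross-participant counterbalancing. Density is fixed at three: present
trials play the target plus two of its three in-range nontargets (one
muted at random), absent trials play all three nontargets.

**Edge bookkeeping.** Every trial is classified from its design alone:
*absolute edge* if the target band is the extreme band of its block's
range; *relative edge* if muting left no active band below (or above) an
interior target, making it the extreme band of the actual scene; *center*
if active bands flank it on both sides. Interior-band absent trials in the
split-range design are always center by construction.

## Simulated cohort

The generative observer is equal-variance Gaussian SDT. Trial evidence is
N(d, 1) when the target is present and N(0, 1) when absent, with
d = d_cell + participant offset (+ covariate term), and the response is
"yes" above a criterion placed at d/2 + c (c = 0 is unbiased, making hits
and false alarms symmetric so that z(H) − z(F) estimates d). Programmed
cell sensitivities are keyed by (order, edge position):

- six-band defaults: TM edge 2.95, TM mid 2.55, MT edge 2.12, MT mid 1.31;
- split-range defaults: edges TM 2.93/2.93 and MT 2.42/2.36 by range, mid
  cells 0.56 d′ lower within each (order, range) — the cohort-level
  edge-minus-mid contrast applied to the edge cells, since the mid cells
  are not independently constrained by the reported summary statistics.

Relative-edge trials fall back to the "mid" value unless a finer key is
programmed, mirroring how a band-based analysis treats them. Participant
offsets are Gaussian on the d′ scale with SD 0.5 — a deliberate free
parameter: cohort-level summaries pin down cell means but not individual
spread, and 0.5 puts ~95% of simulated participants within ±1 d′ of the
cell mean, matching the qualitative spread of individual-difference plots
in this literature. Optional musical-sophistication covariates (training
and perception scores drawn at realistic means/SDs) add a linear slope to
sensitivity.

The matched-filter observer is a bottom-up diagnostic only: it correlates
the cue's magnitude spectrogram with the band-restricted mixture
spectrogram and answers "yes" above a threshold. It verifies that rendered
present/absent stimuli are acoustically separable (d′ ≫ 0) and has no
order or edge effects by construction.

## Statistical chain

- **d′**: z(hit rate) − z(false-alarm rate). Default extreme-rate handling
  is the log-linear correction (add 0.5 to each count, 1 to each total),
  with the 1/(2N) clamp available; uncorrected rates are available for
  large-sample checks. Cohort means are means of participant means.
- **Edge effect**: per participant, mean d′ over the edge bands of each
  range minus mean d′ over interior bands, positive = edge advantage; in
  the split-range design, interior-band present trials that muting
  promoted to relative edges are excluded from the middle cells.
- **Bootstrap**: percentile intervals from B = 10 000 resamples drawn over
  participants (the independent sampling units) with replacement, seeded.
- **Mixed model**: participant-cell d′ regressed on order (binary, 1 =
  Target–Mixture), edge (binary), their interaction, numeric band, a range
  indicator when the design has one, and standardized sophistication
  scores, with random participant intercepts (statsmodels MixedLM, REML).
  A trial-level binomial variant is intentionally not the default: the
  d′-cell response matches how the sensitivity results are summarized.
- **Relative-edge hit rates**: present interior-band trials only, binomial
  (logit) GLM of hit on relative-edge class, order, and band — hit rates
  are bounded, so a linear model on rates would be misspecified. The link
  function is an assumption; logit is the convention.
- **Adjacent-muting contrast**: present-trial hits per (participant,
  order, adjacency of the muted band) paired with that participant-order's
  false alarms to form d′ cells, then a random-intercept model with the
  adjacency × order interaction.

## Numerical and scale choices

- All randomness flows from one master seed through named SeedSequence
  streams (design shuffle, muting, observer, bootstrap), so every artifact
  is reproducible and re-running a configuration rewrites identical files.
- Timepoint rejection sampling is capped at 10⁶ attempts (never
  approached at the 50-ms floor: ~5 attempts per melody on average).
- The A-weighted level contract is 0.01 dB after alignment; the A-curve
  itself is evaluated analytically, so no filter-design tolerance enters.
- The recovery study in the test suite uses 100 replicate cohorts of 25
  participants at the full 360-trial design, with B = 2 000 bootstrap
  resamples per interval; the coverage study uses 500 cohorts of 40
  participants. These sizes make Monte-Carlo error small relative to the
  asserted margins while keeping the suite quick.

## Limitations

- The simulated cohort emulates the *effect structure* of a human cohort
  (order and edge effects, individual variability, covariate slopes), not
  its mechanisms: no memory decay in the Mixture–Target order, no
  attention dynamics, no frequency-specific biases beyond the programmed
  cells. Passing recovery tests shows the analysis chain is consistent,
  not that humans behave like the generative model.
- Sample d′ is a biased estimator in small cells: with the log-linear
  correction and 10–20 present trials per cell, high sensitivities
  (d′ ≈ 3) are underestimated by ≈ 0.1–0.3 as participants saturate at
  perfect hit rates. This is a property of the estimator, not a bug; it
  is visible in the recovery study as a downward shift of the highest
  programmed cell, and any comparison of programmed and recovered values
  at realistic trial counts must expect it.
- Regression coefficients (β, t, p, F) from a real cohort depend on that
  sample and are not reproduction targets; the pipeline targets the
  directional and interval structure instead.
- Audio rendering assumes pure tones in silence: no headphone
  equalization, hardware calibration, or loudness (sone) modeling.
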