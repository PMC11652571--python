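"""Trial lists and stimulus rendering for the two melody-detection experiments.

Both experiments use a yes/no template-matching task: a 2-s cue melody and
a 2-s multi-band mixture separated by a 1-s pause, with the cue either
before the mixture (Target-Mixture order) or after it (Mixture-Target).
The task is to report whether the cue melody is present in the mixture.

Experiment 1 uses all six bands.  Its Target-Mixture block has 20 trials
per frequency condition (120 total) and its Mixture-Target block 40 per
condition (240 total).  In version 2 of the design one random nontarget
band is muted whenever the target is present, so mixture density is five
melodies regardless of target presence; version 1 applies no muting
(density six when present, five when absent).

Experiment 2 splits the bands into a low range (bands 1-4) and a high
range (bands 3-6), with separate blocks per (order, range) and mixture
density fixed at three bands in every trial.  Muting the outermost active
band can promote an interior band to a "relative edge"; trial records
carry that classification for the within-band edge analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .erb_bands import BandLayout
from .stimulus_synthesis import (
    DEFAULT_CALIBRATION_DB,
    DEFAULT_RATE_HZ,
    DEFAULT_TARGET_DBA_SPL,
    Melody,
    Waveform,
    align_levels,
    draw_melody,
    mix,
    synthesize_melody,
)

TARGET_MIXTURE = "TM"
MIXTURE_TARGET = "MT"
ORDERS = (TARGET_MIXTURE, MIXTURE_TARGET)

ABSOLUTE_EDGE = "absolute-edge"
RELATIVE_EDGE = "relative-edge"
CENTER = "center"

EXP2_RANGES = {"low": (1, 2, 3, 4), "high": (3, 4, 5, 6)}


@dataclass(frozen=True)
class TrialSpec:
    """Design-time description of one trial; fully determines its stimuli."""

    experiment: int
    block: int
    trial: int
    order: str
    target_band: int
    target_present: bool
    active_bands: tuple[int, ...]
    muted_band: int | None = None
    range_block: str | None = None  # exp 2 only: "low" or "high"
    seed: tuple[int, ...] = ()

    def __post_init__(self):
        if self.target_present and self.target_band not in self.active_bands:
            raise ValueError("present target must be among the active bands")
        if not self.target_present and self.target_band in self.active_bands:
            raise ValueError("absent target band must be silent")
        if self.muted_band == self.target_band:
            raise ValueError("muted band must be a nontarget band")

    @property
    def band_pool(self) -> tuple[int, ...]:
        """All bands eligible in this trial's block."""
        if self.experiment == 2:
            return EXP2_RANGES[self.range_block]
        return (1, 2, 3, 4, 5, 6)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(list(self.seed)))


@dataclass
class BlockSpec:
    order: str
    trials: list[TrialSpec]
    range_block: str | None = None

    def __len__(self):
        return len(self.trials)


def classify_edge(spec: TrialSpec, layout: BandLayout | None = None) -> str:
    """Position of the target band within its trial's spectral scene.

    ``absolute-edge``: the target band is the lowest or highest band of the
    block's range.  ``relative-edge``: an interior band left without any
    active band below (or above) it by muting, i.e. the extreme band of the
    actual mixture.  ``center``: active bands exist both below and above
    the target band.  Classification depends only on the design (target
    band and active bands), never on responses; on target-absent trials
    the cued band is classified the same way against the active bands.
    """
    pool = spec.band_pool
    if spec.target_band in (min(pool), max(pool)):
        return ABSOLUTE_EDGE
    others = [b for b in spec.active_bands if b != spec.target_band]
    below = any(b < spec.target_band for b in others)
    above = any(b > spec.target_band for b in others)
    if below and above:
        return CENTER
    return RELATIVE_EDGE


def _counterbalanced_presence(n: int) -> list[bool]:
    if n % 2:
        raise ValueError(
            f"per-condition trial count {n} must be even so present and "
            "absent trials counterbalance exactly")
    return [True] * (n // 2) + [False] * (n // 2)


def _exp1_bands(target: int, present: bool, version: int,
                rng: np.random.Generator) -> tuple[tuple[int, ...], int | None]:
    all_bands = (1, 2, 3, 4, 5, 6)
    nontargets = [b for b in all_bands if b != target]
    if not present:
        return tuple(nontargets), None
    if version == 1:
        return all_bands, None
    muted = int(rng.choice(nontargets))
    return tuple(b for b in all_bands if b != muted), muted


def build_experiment1(layout: BandLayout, n_tm_per_cond: int = 20,
                      n_mt_per_cond: int = 40, version: int = 2,
                      rng: np.random.Generator | None = None,
                      master_seed: int = 0) -> list[BlockSpec]:
    """Build the two Experiment-1 blocks (Target-Mixture first).

    Defaults give 120 Target-Mixture and 240 Mixture-Target trials, with
    presence exactly counterbalanced within each of the six frequency
    conditions.  Trial order is a seeded uniform shuffle within block.
    """
    if version not in (1, 2):
        raise ValueError("version must be 1 or 2")
    if rng is None:
        rng = np.random.default_rng(master_seed)
    blocks = []
    for block_idx, (order, n_per) in enumerate(
            [(TARGET_MIXTURE, n_tm_per_cond), (MIXTURE_TARGET, n_mt_per_cond)]):
        cells = [(band, present)
                 for band in range(1, 7)
                 for present in _counterbalanced_presence(n_per)]
        rng.shuffle(cells)
        # muting draws use their own stream so both design versions share
        # identical trial bookkeeping under one seed
        mute_rng = np.random.default_rng(
            np.random.SeedSequence([master_seed, 101, block_idx]))
        trials = []
        for t, (band, present) in enumerate(cells):
            active, muted = _exp1_bands(band, present, version, mute_rng)
            trials.append(TrialSpec(
                experiment=1, block=block_idx, trial=t, order=order,
                target_band=band, target_present=present,
                active_bands=active, muted_band=muted,
                seed=(master_seed, block_idx, t)))
        blocks.append(BlockSpec(order=order, trials=trials))
    return blocks


def _exp2_bands(target: int, present: bool, pool: tuple[int, ...],
                rng: np.random.Generator) -> tuple[tuple[int, ...], int | None]:
    nontargets = [b for b in pool if b != target]
    if not present:
        # density 3 without the target: all three nontarget bands play
        return tuple(nontargets), None
    muted = int(rng.choice(nontargets))
    return tuple(sorted([target] + [b for b in nontargets if b != muted])), muted


def build_experiment2(layout: BandLayout, n_tm_per_cond: int = 20,
                      n_mt_per_cond: int = 40, start_range: str = "low",
                      rng: np.random.Generator | None = None,
                      master_seed: int = 0) -> list[BlockSpec]:
    """Build the four Experiment-2 blocks.

    Two Target-Mixture blocks come first (one per frequency range, order
    set by ``start_range`` for cross-participant counterbalancing), then
    two Mixture-Target blocks in the same range order.  Defaults give 160
    Target-Mixture and 320 Mixture-Target trials.  Mixture density is
    three bands in every trial: present trials play the target plus two
    random nontargets of its 4-band range, absent trials play all three
    nontargets.
    """
    if start_range not in EXP2_RANGES:
        raise ValueError("start_range must be 'low' or 'high'")
    if rng is None:
        rng = np.random.default_rng(master_seed)
    range_order = ([start_range, "high" if start_range == "low" else "low"])
    blocks = []
    block_idx = 0
    for order, n_per in [(TARGET_MIXTURE, n_tm_per_cond),
                         (MIXTURE_TARGET, n_mt_per_cond)]:
        for rng_name in range_order:
            pool = EXP2_RANGES[rng_name]
            cells = [(band, present)
                     for band in pool
                     for present in _counterbalanced_presence(n_per)]
            rng.shuffle(cells)
            mute_rng = np.random.default_rng(
                np.random.SeedSequence([master_seed, 101, block_idx]))
            trials = []
            for t, (band, present) in enumerate(cells):
                active, muted = _exp2_bands(band, present, pool, mute_rng)
                trials.append(TrialSpec(
                    experiment=2, block=block_idx, trial=t, order=order,
                    target_band=band, target_present=present,
                    active_bands=active, muted_band=muted,
                    range_block=rng_name,
                    seed=(master_seed, block_idx, t)))
            blocks.append(BlockSpec(order=order, trials=trials,
                                    range_block=rng_name))
            block_idx += 1
    return blocks


def render_trial(spec: TrialSpec, layout: BandLayout,
                 rate_hz: int = DEFAULT_RATE_HZ,
                 target_dba: float = DEFAULT_TARGET_DBA_SPL,
                 calibration_db: float = DEFAULT_CALIBRATION_DB,
                 ) -> tuple[Waveform, Waveform, dict]:
    """Render one trial to (cue, mixture, manifest-entry) from its seed.

    Fresh melodies are drawn for the cued band and every active band.  On
    target-present trials the cue melody itself is embedded in the mixture
    (frequencies and timing identical); on absent trials the cue is drawn
    for the target band but withheld, leaving that band silent.  All
    melodies are aligned in A-weighted level before mixing.
    """
    rng = spec.rng()
    melodies: dict[int, Melody] = {
        spec.target_band: draw_melody(layout, spec.target_band, rng, spec.seed)}
    for b in spec.active_bands:
        if b != spec.target_band:
            melodies[b] = draw_melody(layout, b, rng, spec.seed)
    waves = {b: synthesize_melody(m, rate_hz) for b, m in melodies.items()}
    bands = sorted(waves)
    aligned = dict(zip(bands, align_levels([waves[b] for b in bands],
                                           target_dba, calibration_db)))
    cue = aligned[spec.target_band]
    mixture = mix([aligned[b] for b in spec.active_bands])
    entry = manifest_entry(spec)
    return cue, mixture, entry


def manifest_entry(spec: TrialSpec) -> dict:
    return {
        "experiment": spec.experiment,
        "block": spec.block,
        "trial": spec.trial,
        "order": spec.order,
        "target_band": spec.target_band,
        "present": int(spec.target_present),
        "muted_band": -1 if spec.muted_band is None else spec.muted_band,
        "active_bands": ",".join(map(str, spec.active_bands)),
        "range_block": spec.range_block or "",
        "edge_class": classify_edge(spec),
        "seed": ":".join(map(str, spec.seed)),
    }


def manifest(blocks: list[BlockSpec]):
    """Flatten blocks to a tidy per-trial table."""
    import pandas as pd

    return pd.DataFrame([manifest_entry(s) for b in blocks for s in b.trials])


def all_trials(blocks: list[BlockSpec]) -> list[TrialSpec]:
    return [s for b in blocks for s in b.trials]
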