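"""Constrained random eight-tone melodies and their audio rendering.

Each melody lasts exactly 2 s and consists of eight contiguous pure tones.
Tone frequencies are drawn uniformly on a log2 scale within the owning
band's half-octave range; tone boundaries come from seven uniform draws on
(0, 2) s, rejected wholesale whenever any resulting tone would last 50 ms
or less.  Tones are synthesized with 10 ms raised-cosine onset and offset
ramps embedded inside each tone's interval, and whole melodies are aligned
in A-weighted level so that no band carries a loudness cue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .erb_bands import BandLayout

DEFAULT_RATE_HZ = 44100
MELODY_DURATION_S = 2.0
N_TONES = 8
MIN_TONE_S = 0.050
RAMP_S = 0.010
#: Full-scale digital level mapped to this SPL by default (dB).  The
#: absolute figure only matters as a common reference in a headless
#: pipeline; it is configurable wherever levels are set.
DEFAULT_CALIBRATION_DB = 100.0
DEFAULT_TARGET_DBA_SPL = 40.0


class ClippingError(ValueError):
    """Raised when a requested gain or mix would exceed digital full scale."""


@dataclass(frozen=True)
class ToneEvent:
    freq_hz: float
    onset_s: float
    offset_s: float

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass(frozen=True)
class Melody:
    """Eight contiguous tones confined to one frequency band."""

    band_index: int
    tones: tuple[ToneEvent, ...]
    seed: object = None

    def __post_init__(self):
        if len(self.tones) != N_TONES:
            raise ValueError(f"melody must have {N_TONES} tones")

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([t.freq_hz for t in self.tones])


@dataclass
class Waveform:
    """Mono audio in digital full-scale units ([-1, 1])."""

    samples: np.ndarray
    rate_hz: int = DEFAULT_RATE_HZ

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate_hz

    @property
    def peak(self) -> float:
        return float(np.max(np.abs(self.samples))) if len(self.samples) else 0.0


def draw_melody_frequencies(layout: BandLayout, k: int, n_tones: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Draw tone frequencies uniform on a log2 scale over band ``k``'s range."""
    if n_tones < 1:
        raise ValueError("need at least one tone")
    low, high = layout.band_range(k)
    return 2.0 ** rng.uniform(np.log2(low), np.log2(high), size=n_tones)


def draw_timepoints(rng: np.random.Generator, max_attempts: int = 10 ** 6
                    ) -> list[tuple[float, float]]:
    """Draw the eight tone intervals partitioning [0, 2] s.

    Seven interior boundaries are drawn uniformly on (0, 2) and sorted; the
    whole draw is rejected and redrawn if any of the eight resulting
    durations is <= 50 ms.  Returns (onset, offset) pairs; consecutive
    tones share their boundary so durations always sum to exactly 2 s.
    """
    for _ in range(max_attempts):
        pts = np.sort(rng.uniform(0.0, MELODY_DURATION_S, size=N_TONES - 1))
        bounds = np.concatenate(([0.0], pts, [MELODY_DURATION_S]))
        if np.all(np.diff(bounds) > MIN_TONE_S):
            return list(zip(bounds[:-1], bounds[1:]))
    raise RuntimeError("timepoint rejection sampling exceeded attempt cap")


def draw_melody(layout: BandLayout, k: int, rng: np.random.Generator,
                seed=None) -> Melody:
    """Draw one complete melody for band ``k``."""
    freqs = draw_melody_frequencies(layout, k, N_TONES, rng)
    times = draw_timepoints(rng)
    tones = tuple(ToneEvent(f, on, off) for f, (on, off) in zip(freqs, times))
    return Melody(band_index=k, tones=tones, seed=seed)


def synthesize_melody(melody: Melody, rate_hz: int = DEFAULT_RATE_HZ,
                      amplitude: float = 0.1) -> Waveform:
    """Render a melody to audio with 10 ms raised-cosine ramps.

    Each tone is a sinusoid at its nominal frequency, gated by an onset
    ramp over its first 10 ms and an offset ramp over its last 10 ms; both
    ramps lie inside the tone's interval, so consecutive tones neither
    overlap nor leave gaps.
    """
    n = int(round(MELODY_DURATION_S * rate_hz))
    out = np.zeros(n)
    t = np.arange(n) / rate_hz
    for tone in melody.tones:
        if tone.duration_s <= 2 * RAMP_S:
            raise ValueError(
                f"tone duration {tone.duration_s * 1e3:.1f} ms too short for "
                f"{2 * RAMP_S * 1e3:.0f} ms of ramps")
        i0 = int(round(tone.onset_s * rate_hz))
        i1 = int(round(tone.offset_s * rate_hz))
        seg_t = t[i0:i1] - tone.onset_s
        seg = amplitude * np.sin(2 * np.pi * tone.freq_hz * seg_t)
        n_ramp = int(round(RAMP_S * rate_hz))
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        seg[:n_ramp] *= ramp
        seg[-n_ramp:] *= ramp[::-1]
        out[i0:i1] = seg
    return Waveform(out, rate_hz)


def a_weighting_db(f) -> np.ndarray:
    """A-weighting magnitude in dB at frequency ``f`` (IEC 61672 curve).

    Evaluates the analytic pole-zero magnitude response, normalized to
    0 dB at 1 kHz.
    """
    f = np.asarray(f, dtype=float)
    f2 = f ** 2
    num = (12194.0 ** 2) * f2 ** 2
    den = ((f2 + 20.6 ** 2)
           * np.sqrt((f2 + 107.7 ** 2) * (f2 + 737.9 ** 2))
           * (f2 + 12194.0 ** 2))
    with np.errstate(divide="ignore"):
        ra = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        db = 20.0 * np.log10(np.where(ra > 0, ra, np.finfo(float).tiny))
    return db + 2.000  # normalization: A(1000 Hz) = 0 dB

def a_weight_level(w: Waveform, calibration_db: float = DEFAULT_CALIBRATION_DB
                   ) -> float:
    """A-weighted RMS level of a waveform in dB SPL(A).

    The A-weighting magnitude curve is applied in the frequency domain to
    the whole waveform (silence included in the RMS window); the full-scale
    digital RMS is mapped to SPL through ``calibration_db`` (dB SPL of a
    full-scale, 0 dBFS RMS signal).  Pass ``calibration_db=0`` for a level
    re digital full scale.
    """
    x = w.samples
    if not np.any(x):
        raise ValueError("level of an all-zero waveform is undefined")
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(len(x), d=1.0 / w.rate_hz)
    gain = 10.0 ** (a_weighting_db(freqs) / 20.0)
    gain[0] = 0.0  # DC carries no A-weighted energy
    # Parseval: mean square of the weighted signal from the rfft bins.
    mag2 = np.abs(spec * gain) ** 2
    if len(x) % 2 == 0:
        mag2[1:-1] *= 2.0
    else:
        mag2[1:] *= 2.0
    mean_square = np.sum(mag2) / len(x) ** 2
    return 10.0 * np.log10(mean_square) + calibration_db


def align_levels(waveforms: list[Waveform],
                 target_dba: float = DEFAULT_TARGET_DBA_SPL,
                 calibration_db: float = DEFAULT_CALIBRATION_DB
                 ) -> list[Waveform]:
    """Scale each waveform so its A-weighted level equals ``target_dba``.

    Shapes are unchanged up to a scalar gain.  Raises ``ClippingError``
    when the required gain would push any sample beyond full scale.
    """
    out = []
    for w in waveforms:
        level = a_weight_level(w, calibration_db)
        g = 10.0 ** ((target_dba - level) / 20.0)
        if w.peak * g > 1.0:
            raise ClippingError(
                f"gain {20 * np.log10(g):.1f} dB would clip "
                f"(peak {w.peak * g:.3f} > 1); lower the target level or "
                f"raise the calibration constant")
        out.append(Waveform(w.samples * g, w.rate_hz))
    return out


def mix(waveforms: list[Waveform]) -> Waveform:
    """Sample-wise sum of equal-length, equal-rate waveforms."""
    if not waveforms:
        raise ValueError("nothing to mix")
    rate = waveforms[0].rate_hz
    n = len(waveforms[0].samples)
    if any(w.rate_hz != rate or len(w.samples) != n for w in waveforms):
        raise ValueError("waveforms must share length and sampling rate")
    total = np.sum([w.samples for w in waveforms], axis=0)
    peak = np.max(np.abs(total))
    if peak > 1.0:
        raise ClippingError(f"mix clips at peak {peak:.3f}")
    return Waveform(total, rate)
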