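"""ERB-number scale conversions and the six-band melody layout.

Frequency bands for the melody-detection task are spaced evenly on the
ERB-number scale (Glasberg & Moore, 1990), which tracks the bandwidths of
human auditory filters and therefore spaces bands perceptually rather than
linearly or logarithmically.  Each band anchors a half-octave melody range
at its center frequency: a band centered at ``f_c`` hosts melodies whose
tone frequencies lie in ``[f_c, f_c * 2**0.5]``.  Adjacent bands are laid
out so that the top of one band's melody range and the next band's center
are separated by at least one ERB, which keeps simultaneous melodies out of
each other's auditory filters and so limits energetic masking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Glasberg & Moore (1990) ERB constants for young normal-hearing listeners.
_ERB_SCALE = 21.4
_ERB_K = 0.00437
_ERB_MIN_BW = 24.7

#: Ratio between the upper and lower bound of each band's melody range.
HALF_OCTAVE_RATIO = 2.0 ** 0.5


class LayoutError(ValueError):
    """Raised when a band layout violates the inter-band separation rule."""


def erb_number(f):
    """Convert frequency in Hz to ERB-number (Cam) units.

    ``E(f) = 21.4 * log10(0.00437 * f + 1)``.  Strictly increasing in ``f``
    and zero in the limit ``f -> 0``.

    Parameters
    ----------
    f : float or array_like
        Frequency in Hz, must be positive.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    out = _ERB_SCALE * np.log10(_ERB_K * f + 1.0)
    return out.item() if out.ndim == 0 else out


def erb_number_inverse(e):
    """Convert ERB-number units back to frequency in Hz."""
    e = np.asarray(e, dtype=float)
    out = (10.0 ** (e / _ERB_SCALE) - 1.0) / _ERB_K
    return out.item() if out.ndim == 0 else out


def erb_bandwidth(f):
    """Equivalent rectangular bandwidth in Hz of the auditory filter at ``f``.

    ``ERB(f) = 24.7 * (0.00437 * f + 1)``; approaches 24.7 Hz at low
    frequency and grows linearly with ``f``.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    out = _ERB_MIN_BW * (_ERB_K * f + 1.0)
    return out.item() if out.ndim == 0 else out


@dataclass(frozen=True)
class BandLayout:
    """Ordered ERB-spaced frequency bands, each with a half-octave melody range.

    Band indices are 1-based throughout (band 1 is the lowest), matching how
    the experiments refer to "Frequency Band 1" etc.
    """

    centers_hz: tuple[float, ...]
    half_octave_ratio: float = HALF_OCTAVE_RATIO
    _validate: bool = field(default=True, repr=False)

    def __post_init__(self):
        centers = tuple(float(c) for c in self.centers_hz)
        object.__setattr__(self, "centers_hz", centers)
        if len(centers) < 2:
            raise ValueError("layout needs at least two bands")
        if any(c <= 0 for c in centers):
            raise ValueError("band centers must be positive")
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValueError("band centers must be strictly increasing")
        if self._validate:
            self.validate_separation()

    @property
    def n_bands(self) -> int:
        return len(self.centers_hz)

    def band_range(self, k: int) -> tuple[float, float]:
        """Melody frequency range (low, high) in Hz of band ``k`` (1-based).

        The center frequency is the lower bound; the upper bound sits half
        an octave above it.
        """
        if not 1 <= k <= self.n_bands:
            raise IndexError(f"band index {k} out of range 1..{self.n_bands}")
        low = self.centers_hz[k - 1]
        return low, low * self.half_octave_ratio

    def validate_separation(self) -> None:
        """Check every adjacent gap is at least one ERB wide.

        The gap runs from band k's upper melody bound to band k+1's center;
        one ERB is evaluated at the gap's lower edge.
        """
        for k in range(1, self.n_bands):
            _, upper = self.band_range(k)
            nxt = self.centers_hz[k]
            gap = nxt - upper
            if gap < erb_bandwidth(upper):
                raise LayoutError(
                    f"bands {k} and {k + 1}: gap {gap:.1f} Hz between the upper "
                    f"melody bound {upper:.1f} Hz and the next center {nxt:.1f} Hz "
                    f"is narrower than one ERB ({erb_bandwidth(upper):.1f} Hz)"
                )

    def rounded_centers(self) -> tuple[int, ...]:
        """Centers rounded to the nearest integer Hz, for display."""
        return tuple(int(round(c)) for c in self.centers_hz)

    def to_dict(self) -> dict:
        return {
            "centers_hz": list(self.centers_hz),
            "half_octave_ratio": self.half_octave_ratio,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BandLayout":
        if "centers_hz" in d:
            return cls(
                tuple(d["centers_hz"]),
                half_octave_ratio=d.get("half_octave_ratio", HALF_OCTAVE_RATIO),
            )
        return build_layout(d["f_low"], d["f_high"], d["n_bands"])


def build_layout(f_low: float, f_high: float, n_bands: int = 6) -> BandLayout:
    """Place ``n_bands`` centers equally spaced on the ERB-number scale.

    Centers interpolate linearly in ERB-number units between ``E(f_low)``
    and ``E(f_high)`` and are inverted back to Hz at full precision.  For
    the task's configuration (65 Hz to 2080 Hz, six bands) the centers
    round to 65, 215, 441, 783, 1300 and 2080 Hz.

    Raises
    ------
    LayoutError
        If any band's upper melody bound comes within one ERB of the next
        band's center.
    """
    if not 0 < f_low < f_high:
        raise ValueError("need 0 < f_low < f_high")
    if n_bands < 2:
        raise ValueError("need at least two bands")
    e = np.linspace(erb_number(f_low), erb_number(f_high), n_bands)
    centers = erb_number_inverse(e)
    return BandLayout(tuple(centers))


def default_layout() -> BandLayout:
    """The six-band layout used by both experiments (65–2080 Hz)."""
    return build_layout(65.0, 2080.0, 6)
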