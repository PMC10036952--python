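"""Disambiguation schedules and random disambiguation sequences.

A kinetic-depth-effect (KDE) sphere is ambiguous about its rotation
direction.  It can be disambiguated by making the dots on the "front"
surface larger than the dots on the "back" surface.  An experiment divides
the disambiguated portion of each prime presentation into short segments of
constant disambiguation strength; the strength of each segment is drawn
independently and uniformly from the 21-level grid
``{-1.0, -0.9, ..., 0.9, 1.0}``.

Three schedule variants are supported:

``onset_only``
    10 segments x 30 ms covering the first 300 ms of an 800 ms presentation.
``full``
    10 segments x 30 ms covering an entire 300 ms presentation.
``onset_offset``
    20 segments x 30 ms: 10 at the start and 10 covering the final 300 ms of
    a 1000 ms presentation (segments 11-20 start at 700 ms).

Strengths are stored internally as *integer tenths* so that the 0.1-step
grid is exact; the float view is derived on demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DisambiguationSchedule",
    "DisambiguationSequence",
    "DotSizePair",
    "GRID_TENTHS",
    "generate_sequence",
    "strength_to_dot_sizes",
    "segment_onset_times",
]

#: The 21 admissible strengths, in integer tenths: -10, -9, ..., 10.
GRID_TENTHS: np.ndarray = np.arange(-10, 11, dtype=np.int64)

#: Mean dot size in degrees of visual angle; front + back always sum to 2x this.
_MEAN_DOT_DVA = 0.2

_VARIANTS = ("onset_only", "full", "onset_offset")


@dataclass(frozen=True)
class DisambiguationSchedule:
    """Timing layout of the disambiguated segments for one experiment variant."""

    variant: str
    n_segments: int
    segment_ms: int
    presentation_ms: int
    segment_onsets_ms: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown schedule variant {self.variant!r}")
        if len(self.segment_onsets_ms) != self.n_segments:
            raise ValueError("number of onsets must equal n_segments")
        if any(
            onset + self.segment_ms > self.presentation_ms
            for onset in self.segment_onsets_ms
        ):
            raise ValueError("a segment extends past the presentation interval")
        if list(self.segment_onsets_ms) != sorted(set(self.segment_onsets_ms)):
            raise ValueError("onsets must be strictly increasing")

    @classmethod
    def from_variant(
        cls,
        variant: str,
        *,
        n_segments: int | None = None,
        segment_ms: int | None = None,
    ) -> "DisambiguationSchedule":
        """Build a standard schedule, optionally overriding the segment layout.

        Overrides exist for scaled-down tests; the defaults are the three
        experimental designs.  For ``onset_offset`` an override keeps the
        two-window structure (half the segments at onset, half before offset).
        """
        seg_ms = 30 if segment_ms is None else int(segment_ms)
        if variant == "onset_only":
            n = 10 if n_segments is None else int(n_segments)
            onsets = tuple(seg_ms * i for i in range(n))
            pres = max(800, onsets[-1] + seg_ms)
            return cls(variant, n, seg_ms, pres, onsets)
        if variant == "full":
            n = 10 if n_segments is None else int(n_segments)
            onsets = tuple(seg_ms * i for i in range(n))
            return cls(variant, n, seg_ms, onsets[-1] + seg_ms, onsets)
        if variant == "onset_offset":
            n = 20 if n_segments is None else int(n_segments)
            if n % 2:
                raise ValueError("onset_offset needs an even segment count")
            half = n // 2
            window = half * seg_ms
            pres = max(1000, 2 * window + 100)
            onsets = tuple(seg_ms * i for i in range(half)) + tuple(
                pres - window + seg_ms * i for i in range(half)
            )
            return cls(variant, n, seg_ms, pres, onsets)
        raise ValueError(f"unknown schedule variant {variant!r}")


@dataclass(frozen=True)
class DisambiguationSequence:
    """A per-segment strength sequence, held on the exact integer-tenths grid."""

    tenths: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.tenths, dtype=np.int64)
        if arr.ndim != 1:
            raise ValueError("sequence must be one-dimensional")
        if np.any(np.abs(arr) > 10):
            raise ValueError("strengths must lie in [-1, 1] (|tenths| <= 10)")
        object.__setattr__(self, "tenths", arr)

    def __len__(self) -> int:
        return int(self.tenths.size)

    @property
    def values(self) -> np.ndarray:
        """Strengths as floats in [-1, 1]."""
        return self.tenths / 10.0

    @classmethod
    def from_values(cls, values: np.ndarray) -> "DisambiguationSequence":
        """Encode float strengths, rejecting anything off the 0.1 grid."""
        values = np.asarray(values, dtype=float)
        tenths = np.round(values * 10.0)
        if not np.allclose(tenths, values * 10.0, atol=1e-9):
            raise ValueError("strengths must be exact multiples of 0.1")
        return cls(tenths.astype(np.int64))


@dataclass(frozen=True)
class DotSizePair:
    """Front/back dot sizes (dva) realising one disambiguation magnitude."""

    front_dva: float
    back_dva: float


def generate_sequence(
    schedule: DisambiguationSchedule, rng: np.random.Generator
) -> DisambiguationSequence:
    """Draw one random sequence: i.i.d. uniform over the 21-level grid."""
    tenths = rng.integers(-10, 11, size=schedule.n_segments, dtype=np.int64)
    return DisambiguationSequence(tenths)


def strength_to_dot_sizes(strength_magnitude: float) -> DotSizePair:
    """Map an unsigned strength to front/back dot sizes.

    The map is linear between the two anchor points: magnitude 0 gives a
    fully ambiguous display (all dots 0.2 dva) and magnitude 1 gives the
    maximal contrast (0.4 vs 0.0 dva).
    """
    m = float(strength_magnitude)
    if not 0.0 <= m <= 1.0:
        raise ValueError(f"strength magnitude {m} outside [0, 1]")
    return DotSizePair(_MEAN_DOT_DVA * (1.0 + m), _MEAN_DOT_DVA * (1.0 - m))


def segment_onset_times(schedule: DisambiguationSchedule) -> list[int]:
    """Onset time (ms after stimulus onset) of every disambiguation segment."""
    return list(schedule.segment_onsets_ms)
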