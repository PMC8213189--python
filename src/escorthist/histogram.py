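"""Intensity histograms of 8-bit image channels.

Every container in this module lives on the fixed 8-bit intensity axis
g = 0..255 (0 is black, 255 is white).  A channel of an image is summarised
by its tally of intensities (:class:`ChannelCounts`), normalised to a
:class:`ProbabilityHistogram`, and accumulated into a
:class:`CumulativeDistribution` F_g = sum_{h<g} p_h (note the *strict*
inequality: F_0 = 0 and the mass at 255 is not included in F_255).

Stochastic dominance of one cumulative curve over another gives the
"darker than" ordering used to compare treatment arms: a histogram whose
mass sits at lower intensities has the larger CDF everywhere and is the
darker one.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

N_BINS = 256

__all__ = [
    "N_BINS",
    "Channel",
    "ChannelCounts",
    "ProbabilityHistogram",
    "CumulativeDistribution",
    "Dominance",
    "count_intensities",
    "to_probability",
    "cumulative",
    "summarize",
    "darker_than",
]


class Channel(str, enum.Enum):
    """One of the four monochromatic views of an RGB image."""

    GRAY = "gray"
    RED = "red"
    GREEN = "green"
    BLUE = "blue"


class Dominance(str, enum.Enum):
    """Verdict of the darkness comparison of two cumulative distributions."""

    FIRST_DARKER = "first_darker"
    SECOND_DARKER = "second_darker"
    INCOMPARABLE = "incomparable"


@dataclass(frozen=True)
class ChannelCounts:
    """Tally of pixel intensities of one channel of one image.

    Attributes
    ----------
    counts : ndarray of shape (256,), non-negative integers
        ``counts[g]`` is the number of pixels with intensity ``g``.
    channel : Channel
        Which monochromatic view the tally describes.
    source_id : str
        Opaque identifier of the originating image.
    """

    counts: np.ndarray
    channel: Channel
    source_id: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (N_BINS,):
            raise ValueError(f"counts must have shape (256,), got {counts.shape}")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ProbabilityHistogram:
    """Normalised intensity distribution p_g on g = 0..255.

    ``support`` is exactly the set of bins with strictly positive mass;
    downstream operations (logit transform, escort families, entropies)
    are restricted to it.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape != (N_BINS,):
            raise ValueError(f"probs must have shape (256,), got {probs.shape}")
        if np.any(probs < 0):
            raise ValueError("probabilities must be non-negative")
        total = probs.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1 (got {total!r})")
        object.__setattr__(self, "probs", probs)

    @property
    def support(self) -> np.ndarray:
        """Intensities g with p_g > 0, in increasing order."""
        return np.flatnonzero(self.probs > 0)


@dataclass(frozen=True)
class CumulativeDistribution:
    """F_g = sum_{h<g} p_h; monotone non-decreasing, each value in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (N_BINS,):
            raise ValueError(f"values must have shape (256,), got {values.shape}")
        if np.any(np.diff(values) < -1e-12):
            raise ValueError("cumulative distribution must be non-decreasing")
        if values[0] < -1e-12 or values[-1] > 1 + 1e-9:
            raise ValueError("cumulative values must lie in [0, 1]")
        object.__setattr__(self, "values", values)


def count_intensities(
    grid: np.ndarray, channel: Channel = Channel.GRAY, source_id: str = ""
) -> ChannelCounts:
    """Tally the intensities of a 2-D grid of 8-bit values."""
    grid = np.asarray(grid)
    if grid.size == 0:
        raise ValueError("cannot count intensities of an empty grid")
    if grid.min() < 0 or grid.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    counts = np.bincount(grid.ravel().astype(np.int64), minlength=N_BINS)
    return ChannelCounts(counts=counts, channel=channel, source_id=source_id)


def to_probability(counts: ChannelCounts) -> ProbabilityHistogram:
    """Normalise a tally to relative frequencies p_g = counts_g / n_pixels."""
    n = counts.n_pixels
    if n <= 0:
        raise ValueError("cannot normalise a tally with zero pixels")
    return ProbabilityHistogram(probs=counts.counts / n)


def cumulative(hist: ProbabilityHistogram) -> CumulativeDistribution:
    """Strict cumulative distribution F_g = sum_{h<g} p_h (so F_0 = 0)."""
    csum = np.cumsum(hist.probs)
    values = np.concatenate([[0.0], csum[:-1]])
    return CumulativeDistribution(values=values)


def summarize(hist: ProbabilityHistogram) -> dict:
    """Mean intensity and median of a histogram.

    The median is the smallest g at which the (inclusive) cumulative mass
    reaches 1/2 — the bin where the cumulative curve crosses the half line.
    """
    g = np.arange(N_BINS)
    mean = float(np.dot(g, hist.probs))
    inclusive = np.cumsum(hist.probs)
    median = int(np.argmax(inclusive >= 0.5))
    return {"mean": mean, "median": median}


def darker_than(
    first: CumulativeDistribution, second: CumulativeDistribution
) -> Dominance:
    """Darkness ordering of two cumulative distributions.

    The first is darker iff F_g >= G_g everywhere with strict inequality
    somewhere (its mass is concentrated at lower intensities).  Crossing
    curves — and identical ones, which dominate nowhere strictly — are
    incomparable.
    """
    f, g = first.values, second.values
    if np.all(f >= g) and np.any(f > g):
        return Dominance.FIRST_DARKER
    if np.all(g >= f) and np.any(g > f):
        return Dominance.SECOND_DARKER
    return Dominance.INCOMPARABLE
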