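"""Reading images and extracting monochromatic channels.

Input rasters are 8-bit RGB (or 8-bit grayscale, which is promoted to RGB
by triplication).  The gray view is a luma-weighted combination of the
three components; the default weights (0.2125, 0.7154, 0.0721) follow the
scikit-image ``rgb2gray`` convention, with ITU-R BT.601 weights
(0.299, 0.587, 0.114) available through the ``weights`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

from .histogram import (
    Channel,
    ChannelCounts,
    CumulativeDistribution,
    ProbabilityHistogram,
    count_intensities,
    to_probability,
)

#: scikit-image rgb2gray luma weights (ITU-R BT.709 primaries).
DEFAULT_GRAY_WEIGHTS = (0.2125, 0.7154, 0.0721)
#: ITU-R BT.601 luma weights.
BT601_GRAY_WEIGHTS = (0.299, 0.587, 0.114)

__all__ = [
    "DEFAULT_GRAY_WEIGHTS",
    "BT601_GRAY_WEIGHTS",
    "ImageArray",
    "ImageDecodeError",
    "read_image",
    "extract_channel",
    "image_channel_counts",
    "write_histogram_tsv",
    "write_cumulative_tsv",
]


class ImageDecodeError(RuntimeError):
    """Raised when a file cannot be decoded as an 8-bit RGB raster."""


@dataclass(frozen=True)
class ImageArray:
    """Decoded 8-bit RGB raster: height x width x 3 integer intensities."""

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be (H, W, 3), got {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have at least one pixel")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def read_image(path: str | Path) -> ImageArray:
    """Decode a JPEG/PNG file into an :class:`ImageArray`.

    Grayscale-on-disk files are promoted to RGB by component triplication.
    Anything that is not 8 bits per component is rejected rather than
    rescaled, since bin identity on the 0..255 axis matters downstream.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            if im.mode not in ("RGB", "L"):
                # palette / RGBA / 16-bit etc.: accept only exact 8-bit forms
                if im.mode in ("P", "RGBA", "LA"):
                    im = im.convert("RGB")
                else:
                    raise ImageDecodeError(
                        f"{path}: unsupported mode {im.mode!r}; "
                        "only 8-bit RGB or grayscale rasters are accepted"
                    )
            arr = np.asarray(im)
    except (UnidentifiedImageError, OSError) as exc:
        raise ImageDecodeError(f"cannot decode image file {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return ImageArray(pixels=arr, source_id=path.name)


def extract_channel(
    img: ImageArray,
    channel: Channel,
    weights: tuple[float, float, float] = DEFAULT_GRAY_WEIGHTS,
) -> np.ndarray:
    """One monochromatic 2-D view of an RGB image.

    Red/green/blue return the component verbatim.  Gray returns the
    weighted luma, rounded half-to-even and clipped to [0, 255]; on
    achromatic pixels (r = g = b) this is the identity for any weights
    summing to 1.
    """
    channel = Channel(channel)
    px = img.pixels
    if channel is Channel.RED:
        return px[:, :, 0].copy()
    if channel is Channel.GREEN:
        return px[:, :, 1].copy()
    if channel is Channel.BLUE:
        return px[:, :, 2].copy()
    w = np.asarray(weights, dtype=float)
    luma = px.astype(float) @ w
    return np.clip(np.rint(luma), 0, 255).astype(np.uint8)


def image_channel_counts(
    img: ImageArray,
    channel: Channel,
    weights: tuple[float, float, float] = DEFAULT_GRAY_WEIGHTS,
) -> ChannelCounts:
    """Extract a channel and tally its intensities in one step."""
    grid = extract_channel(img, channel, weights=weights)
    return count_intensities(grid, channel=Channel(channel), source_id=img.source_id)


def write_histogram_tsv(
    path: str | Path, counts: ChannelCounts, hist: ProbabilityHistogram | None = None
) -> None:
    """Write a per-image histogram as TSV with columns g, count, prob."""
    if hist is None:
        hist = to_probability(counts)
    with open(path, "w") as fh:
        fh.write("g\tcount\tprob\n")
        for g in range(len(counts.counts)):
            fh.write(f"{g}\t{counts.counts[g]}\t{hist.probs[g]:.17g}\n")


def write_cumulative_tsv(path: str | Path, cdf: CumulativeDistribution) -> None:
    """Write a cumulative curve as TSV with columns g, F_g."""
    with open(path, "w") as fh:
        fh.write("g\tF\n")
        for g, v in enumerate(cdf.values):
            fh.write(f"{g}\t{v:.17g}\n")
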