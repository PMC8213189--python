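"""Synthetic stained-histology image studies with known ground truth.

The generator realises exactly the statistical structure the fixed-shift
analysis assumes, so that estimation can be validated against a known
truth:

* a single reference gray-intensity histogram shared by an arm;
* an image-specific random shift b_i ~ Normal(0, shift_sigma^2) applied to
  the log-odds of every bin against the reference bin g = 0 (so each image
  samples a tilted version of the reference);
* i.i.d. pixel sampling from the tilted histogram (the pixel noise);
* for the treated arm only, disc-shaped "cluster" regions whose
  intensities are offset, moving mass into otherwise sparsely populated
  bins and raising histogram entropy — the histogram-level proxy for
  chondrocyte cluster formation;
* a deterministic RGB tint per staining type (haematoxylin-eosin 'H',
  Safranin O 'S', Masson's trichrome 'M') so that channel dependence is
  testable.  The tints make no claim of histological realism.

All randomness derives from one master seed through a counter-based
``SeedSequence`` spawn scheme keyed by (arm, image index), so generating
more images never perturbs earlier ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .histogram import N_BINS, ProbabilityHistogram
from .io import ImageArray

__all__ = [
    "ClusterParams",
    "SyntheticStudySpec",
    "SyntheticStudy",
    "STAIN_TINTS",
    "default_reference_histogram",
    "shifted_histogram",
    "sample_image",
    "add_clusters",
    "tint_to_rgb",
    "generate_study",
    "write_study",
]

#: Per-staining RGB scalings of the gray field.  Chosen only so the four
#: channel views differ in a staining-dependent way.
STAIN_TINTS: dict[str, tuple[float, float, float]] = {
    "H": (0.85, 0.55, 0.80),  # magenta-purple dominant
    "S": (0.95, 0.60, 0.35),  # red-orange dominant
    "M": (0.50, 0.70, 0.90),  # blue-green dominant
}

#: Group sizes of the study being emulated: 8 image pairs for S-staining,
#: 7 for H and M.
DEFAULT_N_IMAGES: dict[str, int] = {"H": 7, "S": 8, "M": 7}


@dataclass(frozen=True)
class ClusterParams:
    """Disc-shaped intensity-offset regions added to treated-arm images."""

    n_clusters: int = 3
    radius_px: float = 6.0
    intensity_offset: int = 60

    def __post_init__(self) -> None:
        if self.n_clusters < 0:
            raise ValueError("n_clusters must be >= 0")
        if self.radius_px <= 0:
            raise ValueError("radius_px must be positive")


def default_reference_histogram() -> ProbabilityHistogram:
    """Reference gray histogram of the control arm.

    A point mass of 0.15 at g = 0 (the dark reference bin, so that the
    logit shift is a genuine perturbation) plus a two-component Gaussian
    mixture with a dark tissue mode at 95 and a light background mode at
    165, truncated to the band 40..190.  The support is deliberately
    bounded: a stained section occupies a limited dynamic range, and the
    empty upper bins are exactly where a cluster intensity offset moves
    mass, raising histogram entropy by opening new support.
    """
    g = np.arange(N_BINS, dtype=float)
    dark = np.exp(-0.5 * ((g - 95.0) / 25.0) ** 2)
    light = np.exp(-0.5 * ((g - 165.0) / 20.0) ** 2)
    band = (g >= 40) & (g <= 190)
    body = (0.45 * dark / dark.sum() + 0.55 * light / light.sum()) * band
    body = 0.85 * body / body.sum()
    body[0] = 0.15
    return ProbabilityHistogram(probs=body / body.sum())


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Full parameterisation of a two-arm synthetic image study."""

    staining_tag: str = "H"
    n_images_per_arm: int | None = None
    image_height: int = 1024
    image_width: int = 1360
    reference_histogram: ProbabilityHistogram | None = None
    shift_sigma: float = 0.5
    cluster_params: ClusterParams = field(default_factory=ClusterParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.staining_tag not in STAIN_TINTS:
            raise ValueError(f"staining_tag must be one of {sorted(STAIN_TINTS)}")
        if self.shift_sigma < 0:
            raise ValueError("shift_sigma must be >= 0")
        if self.image_height < 1 or self.image_width < 1:
            raise ValueError("image dimensions must be positive")
        if self.n_images_per_arm is None:
            object.__setattr__(
                self, "n_images_per_arm", DEFAULT_N_IMAGES[self.staining_tag]
            )
        if self.n_images_per_arm < 1:
            raise ValueError("n_images_per_arm must be >= 1")
        if self.reference_histogram is None:
            object.__setattr__(
                self, "reference_histogram", default_reference_histogram()
            )


@dataclass(frozen=True)
class SyntheticStudy:
    """Generated two-arm study plus the ground truth that produced it."""

    spec: SyntheticStudySpec
    treated: list[ImageArray]
    control: list[ImageArray]
    truth: dict


def shifted_histogram(ref: ProbabilityHistogram, b: float) -> ProbabilityHistogram:
    """Apply the logit shift rho_g -> rho_g + b and renormalise.

    Mass moves between the reference bin 0 and the rest:
    p'_0 = p_0 / (p_0 + e^b (1 - p_0)), p'_g = e^b p_g / (p_0 + e^b (1 - p_0)).
    """
    p = ref.probs
    if p[0] <= 0:
        raise ValueError("reference bin g=0 must have positive probability")
    z = p[0] + np.exp(b) * (1.0 - p[0])
    probs = np.exp(b) * p / z
    probs[0] = p[0] / z
    return ProbabilityHistogram(probs=probs / probs.sum())


def sample_image(
    hist: ProbabilityHistogram,
    height: int,
    width: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw an (height x width) grid of i.i.d. pixels from a histogram."""
    if height < 1 or width < 1:
        raise ValueError("image dimensions must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cdf = np.cumsum(hist.probs)
    cdf[-1] = 1.0
    u = rng.random(height * width)
    return np.searchsorted(cdf, u, side="right").astype(np.uint8).reshape(height, width)


def add_clusters(
    grid: np.ndarray,
    params: ClusterParams,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Offset the intensities inside disc-shaped regions at random centres.

    Returns the modified grid and the boolean mask of altered pixels.
    Discs may overlap; offsets are applied once per pixel and clipped to
    [0, 255].
    """
    grid = np.asarray(grid)
    h, w = grid.shape
    if params.n_clusters > 0 and (2 * params.radius_px >= min(h, w)):
        raise ValueError(
            f"cluster radius {params.radius_px} does not fit a {h}x{w} image"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = np.zeros((h, w), dtype=bool)
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    for _ in range(params.n_clusters):
        cr = rng.uniform(params.radius_px, h - params.radius_px)
        cc = rng.uniform(params.radius_px, w - params.radius_px)
        mask |= (rows - cr) ** 2 + (cols - cc) ** 2 <= params.radius_px**2
    out = grid.astype(np.int64)
    out[mask] = np.clip(out[mask] + params.intensity_offset, 0, 255)
    return out.astype(np.uint8), mask


def tint_to_rgb(gray: np.ndarray, staining_tag: str) -> np.ndarray:
    """Stack the gray field into RGB with staining-dependent channel scalings."""
    scales = STAIN_TINTS[staining_tag]
    channels = [
        np.clip(np.rint(s * gray.astype(float)), 0, 255).astype(np.uint8)
        for s in scales
    ]
    return np.stack(channels, axis=-1)


def _channel_reference(ref: ProbabilityHistogram, scale: float) -> list[float]:
    """Pushforward of the gray reference under v -> round(scale * v)."""
    probs = np.zeros(N_BINS)
    targets = np.clip(np.rint(scale * np.arange(N_BINS)), 0, 255).astype(int)
    np.add.at(probs, targets, ref.probs)
    return probs.tolist()


def generate_study(spec: SyntheticStudySpec) -> SyntheticStudy:
    """Generate both arms of a synthetic study, byte-deterministic in seed.

    Per image: draw b_i ~ Normal(0, shift_sigma^2) from the image's own
    random stream, tilt the reference histogram, sample the gray field,
    add clusters (treated arm only), and tint to RGB.
    """
    ref = spec.reference_histogram
    arms: dict[str, list[ImageArray]] = {"treated": [], "control": []}
    shifts: dict[str, list[float]] = {"treated": [], "control": []}
    masks: list[np.ndarray] = []
    for arm_idx, arm in enumerate(("treated", "control")):
        for img_idx in range(spec.n_images_per_arm):
            ss = np.random.SeedSequence(spec.seed, spawn_key=(arm_idx, img_idx))
            rng = np.random.default_rng(ss)
            b = float(rng.normal(0.0, spec.shift_sigma))
            gray = sample_image(
                shifted_histogram(ref, b), spec.image_height, spec.image_width, rng
            )
            if arm == "treated":
                gray, mask = add_clusters(gray, spec.cluster_params, rng)
                masks.append(mask)
            rgb = tint_to_rgb(gray, spec.staining_tag)
            arms[arm].append(
                ImageArray(pixels=rgb, source_id=f"{arm}_{img_idx:03d}.png")
            )
            shifts[arm].append(b)
    scales = STAIN_TINTS[spec.staining_tag]
    truth = {
        "staining_tag": spec.staining_tag,
        "reference_gray": ref.probs.tolist(),
        "reference_channels": {
            "red": _channel_reference(ref, scales[0]),
            "green": _channel_reference(ref, scales[1]),
            "blue": _channel_reference(ref, scales[2]),
        },
        "shifts": shifts,
        "cluster_masks": masks,
    }
    return SyntheticStudy(
        spec=spec, treated=arms["treated"], control=arms["control"], truth=truth
    )


def _rle_encode(mask: np.ndarray) -> list[list[int]]:
    """Row-major run-length encoding of a boolean mask: [start, length] runs."""
    flat = np.asarray(mask).ravel()
    if flat.size == 0:
        return []
    changes = np.flatnonzero(np.diff(flat.astype(np.int8))) + 1
    starts = np.concatenate([[0], changes])
    lengths = np.diff(np.concatenate([starts, [flat.size]]))
    return [
        [int(s), int(l)] for s, l, v in zip(starts, lengths, flat[starts]) if v
    ]


def write_study(study: SyntheticStudy, outdir: str | Path) -> Path:
    """Write PNGs under treated/ and control/ plus a truth.json manifest."""
    outdir = Path(outdir)
    for arm in ("treated", "control"):
        arm_dir = outdir / arm
        arm_dir.mkdir(parents=True, exist_ok=True)
        for img in getattr(study, arm):
            Image.fromarray(img.pixels, mode="RGB").save(arm_dir / img.source_id)
    manifest = dict(study.truth)
    manifest["cluster_masks"] = [_rle_encode(m) for m in study.truth["cluster_masks"]]
    manifest["spec"] = {
        "staining_tag": study.spec.staining_tag,
        "n_images_per_arm": study.spec.n_images_per_arm,
        "image_height": study.spec.image_height,
        "image_width": study.spec.image_width,
        "shift_sigma": study.spec.shift_sigma,
        "cluster_params": {
            "n_clusters": study.spec.cluster_params.n_clusters,
            "radius_px": study.spec.cluster_params.radius_px,
            "intensity_offset": study.spec.cluster_params.intensity_offset,
        },
        "seed": study.spec.seed,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(manifest, fh)
    return outdir
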