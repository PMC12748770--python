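"""Synthetic colorimetric flow-cell images ("phantoms").

Emulates what a smartphone camera sees when imaging the optically clear
chamber of a microfluidic flow cell holding a reacted chromogenic sample:
a centred rectangular chamber filled with a concentration-dependent colour,
a dark enclosure background, radially vignetted LED illumination, a
device-specific colour transform, and additive sensor noise.

The colour model is per-channel Beer-Lambert transmission with a saturating
effective concentration:

    c_eff   = s * (1 - exp(-c / s))          (s = saturation_conc)
    rgb(c)  = blank_rgb * 10 ** (-absorptivity * c_eff)

which is linear in ``c`` at low concentration (intensity change proportional
to analyte) and flattens as the chromophore saturates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, List, Sequence

import numpy as np
from skimage.transform import rotate as _sk_rotate

from .assays import AssayDefinition, DeviceProfile, IlluminationField

__all__ = [
    "PhantomImage",
    "concentration_to_rgb",
    "apply_device_transform",
    "render_phantom",
    "augment",
    "generate_dataset",
    "derive_seed",
]

DEFAULT_SIZE = 128
# Chamber occupies the central 80% of each axis (64% of pixels, > 50%).
CHAMBER_MARGIN_FRACTION = 0.10
BACKGROUND_RGB = (0.12, 0.12, 0.14)

# Augmentation bounds: flips, small rotations, mild photometric jitter.
ROTATION_MAX_DEG = 10.0
BRIGHTNESS_MAX = 0.05
CONTRAST_MAX = 0.05


@dataclass(frozen=True)
class PhantomImage:
    """A rendered flow-cell image with its ground-truth label.

    ``pixels`` is an (H, W, 3) float array in [0, 1] (128x128 by default;
    smaller sizes are used for reduced-scale runs). ``seed`` is the
    per-image RNG seed that makes the render reproducible.
    """

    pixels: np.ndarray
    concentration: float
    assay: str
    device: str
    seed: int
    augmented: bool = False

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) array")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("pixel values must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


def concentration_to_rgb(assay: AssayDefinition, c: float) -> np.ndarray:
    """Chamber colour for analyte concentration ``c`` (assay units).

    Returns the blank reagent colour attenuated per channel by
    ``10 ** (-absorptivity * c_eff)`` with the saturating effective
    concentration defined in the module docstring. Monotonically
    non-increasing in ``c`` in every channel.
    """
    if c < 0:
        raise ValueError(f"concentration must be >= 0, got {c}")
    s = assay.saturation_conc
    c_eff = s * (1.0 - np.exp(-c / s))
    blank = np.asarray(assay.blank_rgb, dtype=np.float64)
    absorptivity = np.asarray(assay.absorptivity, dtype=np.float64)
    return blank * 10.0 ** (-absorptivity * c_eff)


def apply_device_transform(pixels: np.ndarray, device: DeviceProfile) -> np.ndarray:
    """Apply a device's colour rendition: ``clip((g*x + o)**gamma, 0, 1)``.

    The reference profile (unit gain, gamma 1, zero offset) is the identity.
    Noise is *not* applied here; it is added at render time.
    """
    px = np.asarray(pixels, dtype=np.float64)
    gain = np.asarray(device.channel_gain, dtype=np.float64)
    offset = np.asarray(device.white_offset, dtype=np.float64)
    out = np.clip(px * gain + offset, 0.0, None) ** device.gamma
    return np.clip(out, 0.0, 1.0)


def _illumination_grid(size: int, illum: IlluminationField) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    cx = (size - 1) / 2.0
    r2 = ((yy - cx) ** 2 + (xx - cx) ** 2) / (2.0 * cx**2 + 1e-12)
    return illum.center_intensity * (1.0 - illum.vignette_strength * r2)


def render_phantom(
    assay: AssayDefinition,
    c: float,
    device: DeviceProfile,
    illum: IlluminationField | None = None,
    seed: int = 0,
    *,
    size: int = DEFAULT_SIZE,
    allow_out_of_range: bool = False,
) -> PhantomImage:
    """Render one flow-cell capture. Deterministic for a fixed seed.

    ``c`` must lie in the assay's detection range unless
    ``allow_out_of_range`` is set (needed e.g. for the 0-concentration blank
    standard used in recalibration).
    """
    if c < 0:
        raise ValueError(f"concentration must be >= 0, got {c}")
    if not assay.in_range(c) and not allow_out_of_range:
        low, high = assay.detection_range
        raise ValueError(
            f"concentration {c} outside detection range [{low}, {high}] of "
            f"{assay.name}; pass allow_out_of_range=True to override"
        )
    if illum is None:
        illum = IlluminationField()

    img = np.empty((size, size, 3), dtype=np.float64)
    img[:] = BACKGROUND_RGB
    m = int(round(CHAMBER_MARGIN_FRACTION * size))
    img[m : size - m, m : size - m, :] = concentration_to_rgb(assay, c)

    img *= _illumination_grid(size, illum)[:, :, None]
    img = apply_device_transform(img, device)
    if device.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, device.noise_sigma, img.shape)
    img = np.clip(img, 0.0, 1.0)
    return PhantomImage(
        pixels=img,
        concentration=float(c),
        assay=assay.name,
        device=device.name,
        seed=int(seed),
    )


def chamber_slice(size: int) -> tuple[slice, slice]:
    """Row/column slices of the chamber region for a given image size."""
    m = int(round(CHAMBER_MARGIN_FRACTION * size))
    return slice(m, size - m), slice(m, size - m)


def draw_augmentation_plan(seed: int) -> dict:
    """Seeded draw of the augmentation applied by :func:`augment`.

    Exposed separately so the transform applied for a given seed can be
    inspected (and tested) without re-implementing the RNG protocol. Each of
    the five candidate transforms is included with probability 1/2; if none
    is selected the brightness shift is forced so the output differs from
    the input. All magnitude draws happen unconditionally to keep the
    stream layout fixed.
    """
    rng = np.random.default_rng(seed)
    flags = rng.random(5) < 0.5
    angle = rng.uniform(-ROTATION_MAX_DEG, ROTATION_MAX_DEG)
    brightness = rng.uniform(-BRIGHTNESS_MAX, BRIGHTNESS_MAX)
    contrast = rng.uniform(1.0 - CONTRAST_MAX, 1.0 + CONTRAST_MAX)
    if not flags.any():
        flags[3] = True
    return {
        "hflip": bool(flags[0]),
        "vflip": bool(flags[1]),
        "rotate": bool(flags[2]),
        "brightness": bool(flags[3]),
        "contrast": bool(flags[4]),
        "angle": float(angle),
        "brightness_shift": float(brightness),
        "contrast_scale": float(contrast),
    }


def augment(image: PhantomImage, seed: int) -> PhantomImage:
    """Label-preserving augmentation of an original phantom.

    Applies a seeded random subset of {horizontal flip, vertical flip,
    rotation within +/-10 degrees, brightness shift within +/-5%, contrast
    scale within +/-5%}; the concentration label is unchanged and the output
    is flagged ``augmented=True``.
    """
    if image.augmented:
        raise ValueError("augment expects an original (non-augmented) image")
    plan = draw_augmentation_plan(seed)
    px = image.pixels
    if plan["hflip"]:
        px = px[:, ::-1, :]
    if plan["vflip"]:
        px = px[::-1, :, :]
    if plan["rotate"]:
        px = _sk_rotate(px, plan["angle"], mode="edge", preserve_range=True)
    if plan["brightness"]:
        px = px + plan["brightness_shift"]
    if plan["contrast"]:
        mean = px.mean()
        px = mean + plan["contrast_scale"] * (px - mean)
    px = np.clip(px, 0.0, 1.0)
    return replace(image, pixels=px, seed=int(seed), augmented=True)


def derive_seed(master_seed: int, *indices: int) -> int:
    """Stable per-image seed from a master seed and index path (< 2**31)."""
    ss = np.random.SeedSequence([int(master_seed), *map(int, indices)])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_dataset(
    assay: AssayDefinition,
    originals_per_level: int,
    augmented_per_original: int,
    device: DeviceProfile,
    master_seed: int,
    *,
    size: int = DEFAULT_SIZE,
    illum: IlluminationField | None = None,
    illumination_jitter: float = 0.02,
) -> List[PhantomImage]:
    """Render a labelled dilution-series dataset.

    Yields ``len(levels) * originals_per_level`` originals plus
    ``len(levels) * originals_per_level * augmented_per_original`` augmented
    copies. Per-image seeds are derived deterministically from
    ``master_seed`` so the whole collection is reproducible. Each original
    is captured under slightly jittered illumination (centre intensity drawn
    uniformly from ``[1 - illumination_jitter, 1]``, scaled by the base
    field), emulating session-to-session LED drift.
    """
    if originals_per_level < 1:
        raise ValueError("originals_per_level must be >= 1")
    if augmented_per_original < 0:
        raise ValueError("augmented_per_original must be >= 0")
    base = illum if illum is not None else IlluminationField()

    images: List[PhantomImage] = []
    for li, c in enumerate(assay.levels):
        for rep in range(originals_per_level):
            seed = derive_seed(master_seed, li, rep)
            jitter_rng = np.random.default_rng(derive_seed(master_seed, li, rep, 7))
            ci = base.center_intensity * (
                1.0 - jitter_rng.uniform(0.0, illumination_jitter)
            )
            field = IlluminationField(ci, base.vignette_strength)
            original = render_phantom(
                assay, c, device, field, seed=seed, size=size
            )
            images.append(original)
            for k in range(augmented_per_original):
                aug_seed = derive_seed(master_seed, li, rep, k + 1)
                images.append(augment(original, aug_seed))
    return images


def stack_pixels(images: Sequence[PhantomImage]) -> np.ndarray:
    """(N, H, W, 3) float array of a collection's pixels."""
    return np.stack([im.pixels for im in images])


def labels_of(images: Sequence[PhantomImage]) -> np.ndarray:
    """(N,) float array of concentration labels."""
    return np.array([im.concentration for im in images], dtype=np.float64)
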