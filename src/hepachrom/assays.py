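"""Assay and capture-device definitions.

An :class:`AssayDefinition` describes one chromogenic liver-function assay:
its calibration levels, validated detection range, and the parameters of the
per-channel Beer-Lambert colour model used by the phantom renderer. The four
built-in assays cover the standard liver panel: direct and total bilirubin
(diazo/azobilirubin reaction, pinkish chromophore, mg/dL) and the two
transaminases ALT and AST (2,4-DNPH hydrazone, brownish-red chromophore, U/L).

A :class:`DeviceProfile` models how a particular smartphone camera renders
the same scene: per-channel gain, a gamma exponent, a white-level offset and
additive sensor noise. The ``reference`` profile is the identity transform
and represents the device the regression model is trained on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

__all__ = [
    "AssayDefinition",
    "DeviceProfile",
    "IlluminationField",
    "REFERENCE_DEVICE",
    "BUILTIN_ASSAYS",
    "BUILTIN_DEVICES",
    "get_assay",
    "get_device",
]

RGB = Tuple[float, float, float]


@dataclass(frozen=True)
class AssayDefinition:
    """One colorimetric assay and its colour-response parameters.

    Parameters
    ----------
    name:
        Assay identifier (``direct-bilirubin``, ``total-bilirubin``,
        ``ALT`` or ``AST`` for the built-ins).
    units:
        Concentration units, ``"mg/dL"`` or ``"U/L"``.
    levels:
        The ordered calibration concentrations (six levels for the
        built-in assays), strictly increasing and inside ``detection_range``.
    detection_range:
        Closed validated interval ``(low, high)`` in assay units.
    blank_rgb:
        Reagent colour at zero analyte, RGB in [0, 1].
    absorptivity:
        Effective per-unit-concentration absorbance per channel (>= 0).
        Channels with larger absorptivity darken faster with concentration.
    saturation_conc:
        Concentration scale at which the colour change saturates; the
        effective concentration driving absorbance is
        ``saturation_conc * (1 - exp(-c / saturation_conc))``.
    """

    name: str
    units: str
    levels: Tuple[float, ...]
    detection_range: Tuple[float, float]
    blank_rgb: RGB
    absorptivity: RGB
    saturation_conc: float

    def __post_init__(self) -> None:
        low, high = self.detection_range
        if not low < high:
            raise ValueError("detection_range must satisfy low < high")
        lv = tuple(float(x) for x in self.levels)
        if any(b <= a for a, b in zip(lv, lv[1:])):
            raise ValueError("levels must be strictly increasing")
        if lv and (lv[0] < low or lv[-1] > high):
            raise ValueError("levels must lie within detection_range")
        if any(not 0.0 <= v <= 1.0 for v in self.blank_rgb):
            raise ValueError("blank_rgb components must be in [0, 1]")
        if any(v < 0.0 for v in self.absorptivity):
            raise ValueError("absorptivity components must be >= 0")
        if self.saturation_conc <= 0:
            raise ValueError("saturation_conc must be positive")

    def in_range(self, c: float) -> bool:
        low, high = self.detection_range
        return low <= c <= high


@dataclass(frozen=True)
class DeviceProfile:
    """Colour rendition of one capture device.

    The pixel transform is ``clip((gain * x + offset) ** gamma, 0, 1)``
    applied channel-wise, followed by additive Gaussian sensor noise with
    standard deviation ``noise_sigma`` (on the [0, 1] pixel scale).
    """

    name: str
    channel_gain: RGB = (1.0, 1.0, 1.0)
    gamma: float = 1.0
    white_offset: RGB = (0.0, 0.0, 0.0)
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.channel_gain):
            raise ValueError("channel_gain components must be > 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def is_reference(self) -> bool:
        return (
            self.channel_gain == (1.0, 1.0, 1.0)
            and self.gamma == 1.0
            and self.white_offset == (0.0, 0.0, 0.0)
        )


@dataclass(frozen=True)
class IlluminationField:
    """Radially symmetric LED illumination with optional vignetting.

    Relative intensity at radius fraction ``r`` (0 at centre, 1 at the
    image corner) is ``center_intensity * (1 - vignette_strength * r**2)``,
    which stays in (0, 1] for the allowed parameter ranges.
    """

    center_intensity: float = 1.0
    vignette_strength: float = 0.12

    def __post_init__(self) -> None:
        if not 0.0 < self.center_intensity <= 1.0:
            raise ValueError("center_intensity must be in (0, 1]")
        if not 0.0 <= self.vignette_strength < 1.0:
            raise ValueError("vignette_strength must be in [0, 1)")


# Built-in liver panel. Colour directions follow the assay chemistry:
# azobilirubin (pinkish) absorbs green strongest, then blue; the DNPH
# hydrazone (brownish red) absorbs blue/green. Absorptivities are scaled so
# the six calibration levels are well separated in chamber mean colour.
BUILTIN_ASSAYS = {
    "direct-bilirubin": AssayDefinition(
        name="direct-bilirubin",
        units="mg/dL",
        levels=(0.1, 1.0, 5.0, 10.0, 15.0, 20.0),
        detection_range=(0.1, 20.0),
        blank_rgb=(0.94, 0.95, 0.93),
        absorptivity=(0.006, 0.030, 0.018),
        saturation_conc=40.0,
    ),
    "total-bilirubin": AssayDefinition(
        name="total-bilirubin",
        units="mg/dL",
        levels=(0.1, 1.0, 5.0, 10.0, 15.0, 20.0),
        detection_range=(0.1, 20.0),
        blank_rgb=(0.95, 0.94, 0.92),
        absorptivity=(0.007, 0.028, 0.020),
        saturation_conc=40.0,
    ),
    "ALT": AssayDefinition(
        name="ALT",
        units="U/L",
        levels=(10.0, 50.0, 100.0, 150.0, 200.0, 300.0),
        detection_range=(10.0, 300.0),
        blank_rgb=(0.96, 0.93, 0.88),
        absorptivity=(0.0006, 0.0019, 0.0025),
        saturation_conc=600.0,
    ),
    "AST": AssayDefinition(
        name="AST",
        units="U/L",
        levels=(10.0, 50.0, 100.0, 150.0, 200.0, 300.0),
        detection_range=(10.0, 300.0),
        blank_rgb=(0.95, 0.92, 0.89),
        absorptivity=(0.0007, 0.0021, 0.0024),
        saturation_conc=600.0,
    ),
}

REFERENCE_DEVICE = DeviceProfile(name="reference", noise_sigma=0.008)

# Two plausible alternate handsets. Captures happen inside a light-isolated
# enclosure with fixed manual ISO/shutter/white-balance, so residual
# inter-device differences are percent-level responsivity (gain), tone-curve
# (gamma) and black-level (offset) shifts, not gross white-balance swings.
# The two-point recalibration presumes such mild distortions: it corrects
# the resulting near-affine shift of the prediction scale.
BUILTIN_DEVICES = {
    "reference": REFERENCE_DEVICE,
    "alt-a": DeviceProfile(
        name="alt-a",
        channel_gain=(1.02, 0.99, 1.01),
        gamma=1.02,
        white_offset=(0.006, -0.004, 0.004),
        noise_sigma=0.010,
    ),
    "alt-b": DeviceProfile(
        name="alt-b",
        channel_gain=(0.985, 1.015, 0.995),
        gamma=0.985,
        white_offset=(-0.005, 0.006, -0.003),
        noise_sigma=0.012,
    ),
}


def get_assay(name: str) -> AssayDefinition:
    try:
        return BUILTIN_ASSAYS[name]
    except KeyError:
        raise KeyError(
            f"unknown assay {name!r}; built-ins: {sorted(BUILTIN_ASSAYS)}"
        ) from None


def get_device(name: str) -> DeviceProfile:
    try:
        return BUILTIN_DEVICES[name]
    except KeyError:
        raise KeyError(
            f"unknown device {name!r}; built-ins: {sorted(BUILTIN_DEVICES)}"
        ) from None
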