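"""Two-point cross-device recalibration.

A regressor trained on one handset drifts when its inputs come from a
different camera (gain, gamma and offset differences shift the rendered
colours and hence the raw predictions). Instead of retraining, the device is
recalibrated in prediction space from two reference solutions: a blank
(0 concentration) and a known mid-range standard (10 mg/dL for the bilirubin
assays; 150 U/L by default for the enzyme assays). The correction is the
unique affine map sending the blank prediction to 0 and the mid-range
prediction to its known value:

    slope     = mid_true / (mid_pred - blank_pred)
    intercept = -slope * blank_pred

For any affine distortion of the prediction scale this recovers the
undistorted prediction exactly; corrected values are clipped at 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .assays import AssayDefinition, DeviceProfile, IlluminationField
from .phantom import derive_seed, render_phantom

__all__ = [
    "ReferenceReadings",
    "RecalibrationMap",
    "fit_two_point",
    "apply_map",
    "cross_device_deviation",
    "measure_reference_readings",
    "default_mid_standard",
    "save_map",
    "load_map",
]


@dataclass(frozen=True)
class ReferenceReadings:
    """Model predictions on a device's two reference standards."""

    blank_pred: float
    mid_pred: float
    mid_true: float

    def __post_init__(self) -> None:
        if self.mid_true <= 0:
            raise ValueError("mid_true must be positive")


@dataclass(frozen=True)
class RecalibrationMap:
    """Affine correction from raw device predictions to reference scale."""

    slope: float
    intercept: float
    device: str = ""


def fit_two_point(readings: ReferenceReadings) -> RecalibrationMap:
    """Fit the affine map anchored at the blank and mid-range standards."""
    span = readings.mid_pred - readings.blank_pred
    if span <= 0:
        raise ValueError(
            "ill-posed references: mid-range prediction must exceed blank "
            f"prediction (blank={readings.blank_pred}, mid={readings.mid_pred})"
        )
    slope = readings.mid_true / span
    return RecalibrationMap(slope=slope, intercept=-slope * readings.blank_pred)


def apply_map(cal: RecalibrationMap, raw) -> np.ndarray | float:
    """Corrected concentration(s): ``slope * raw + intercept``, clipped at 0."""
    out = np.clip(cal.slope * np.asarray(raw, dtype=np.float64) + cal.intercept, 0.0, None)
    return float(out) if out.ndim == 0 else out


def cross_device_deviation(
    reference_values: Sequence[float], device_values: Sequence[float]
) -> float:
    """Mean absolute percentage deviation of device readings from reference."""
    ref = np.asarray(reference_values, dtype=np.float64)
    dev = np.asarray(device_values, dtype=np.float64)
    if ref.shape != dev.shape:
        raise ValueError("sequences must have equal length")
    if np.any(ref == 0):
        raise ValueError("percentage deviation undefined for zero reference value")
    return float(np.mean(100.0 * np.abs(dev - ref) / np.abs(ref)))


def default_mid_standard(assay: AssayDefinition) -> float:
    """Mid-range standard concentration: 10 mg/dL, or 150 U/L for enzymes."""
    return 10.0 if assay.units == "mg/dL" else 150.0


def measure_reference_readings(
    regressor,
    assay: AssayDefinition,
    device: DeviceProfile,
    seed: int,
    mid_true: float | None = None,
    n_replicates: int = 5,
    illum: IlluminationField | None = None,
) -> ReferenceReadings:
    """Capture and average replicate predictions of the two standards.

    Renders ``n_replicates`` images of the blank (0 concentration, outside
    the validated range, hence rendered with the out-of-range override) and
    of the mid-range standard on the given device, and averages the
    regressor's predictions.
    """
    if mid_true is None:
        mid_true = default_mid_standard(assay)
    size = regressor.config.input_size

    def _mean_pred(conc: float, tag: int) -> float:
        preds = []
        for r in range(n_replicates):
            img = render_phantom(
                assay,
                conc,
                device,
                illum,
                seed=derive_seed(seed, tag, r),
                size=size,
                allow_out_of_range=True,
            )
            preds.append(float(regressor.predict(img.pixels)))
        return float(np.mean(preds))

    return ReferenceReadings(
        blank_pred=_mean_pred(0.0, 0),
        mid_pred=_mean_pred(mid_true, 1),
        mid_true=float(mid_true),
    )


def save_map(cal: RecalibrationMap, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {"device": cal.device, "slope": cal.slope, "intercept": cal.intercept},
            indent=2,
        )
    )


def load_map(path: str | Path) -> RecalibrationMap:
    d = json.loads(Path(path).read_text())
    return RecalibrationMap(
        slope=float(d["slope"]), intercept=float(d["intercept"]), device=d.get("device", "")
    )
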