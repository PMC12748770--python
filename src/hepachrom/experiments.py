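"""Experiment orchestration: the four validation studies as library calls.

Each function is reproducible from its arguments plus a seed, mutates
nothing, and returns plain DataFrames/dataclasses the CLI writes to disk:

* :func:`run_training` — dataset generation, stratified split, CNN training
  and held-out regression metrics;
* :func:`run_crossdevice` — cross-device deviation before/after two-point
  recalibration;
* :func:`run_repeatability` — %CV of replicate simulated measurements under
  within-day / between-day / between-user noise contexts;
* :func:`load_agreement_pairs` / the metrics module — method agreement on
  paired commercial-vs-developed readings (a bundled example panel of
  paired readings ships with the package).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .adapt import (
    apply_map,
    default_mid_standard,
    fit_two_point,
    measure_reference_readings,
)
from .assays import (
    AssayDefinition,
    DeviceProfile,
    IlluminationField,
    REFERENCE_DEVICE,
    get_assay,
    get_device,
)
from .cnn import ModelConfig, TrainConfig, TrainedRegressor, predict, train
from .dataset import SplitSpec, stratified_split
from .metrics import (
    PairedMeasurements,
    RegressionMetrics,
    ReplicateSeries,
    cv_percent,
    regression_metrics,
)
from .phantom import (
    PhantomImage,
    derive_seed,
    generate_dataset,
    labels_of,
    render_phantom,
    stack_pixels,
)

__all__ = [
    "TrainingResult",
    "run_training",
    "run_crossdevice",
    "run_repeatability",
    "REPEATABILITY_CONTEXTS",
    "load_agreement_pairs",
]


@dataclass
class TrainingResult:
    regressor: TrainedRegressor
    test_set: List[PhantomImage]
    test_metrics: RegressionMetrics


def run_training(
    assay: AssayDefinition | str,
    seed: int,
    *,
    originals_per_level: int = 50,
    augmented_per_original: int = 2,
    image_size: int = 48,
    device: DeviceProfile = REFERENCE_DEVICE,
    train_fraction: float = 0.8,
    max_epochs: int = 40,
    batch_size: int = 32,
) -> TrainingResult:
    """Generate a dilution-series dataset, split, train and evaluate.

    Defaults give a reduced-scale run: 6 levels x 50 originals x (1 + 2
    augmented) = 900 images at 48x48, up to 40 epochs — sized for a
    single-CPU session. The full-scale configuration is 250 originals per
    level at 128x128.
    """
    if isinstance(assay, str):
        assay = get_assay(assay)
    images = generate_dataset(
        assay,
        originals_per_level,
        augmented_per_original,
        device,
        master_seed=seed,
        size=image_size,
    )
    train_set, test_set = stratified_split(
        images, SplitSpec(train_fraction=train_fraction, seed=derive_seed(seed, 101))
    )
    cfg = TrainConfig(
        max_epochs=max_epochs, batch_size=batch_size, seed=derive_seed(seed, 202)
    )
    regressor = train(train_set, cfg, ModelConfig(input_size=image_size))
    preds = predict(regressor, stack_pixels(test_set))
    mets = regression_metrics(labels_of(test_set), preds)
    return TrainingResult(regressor=regressor, test_set=test_set, test_metrics=mets)


def _mean_prediction(
    regressor: TrainedRegressor,
    assay: AssayDefinition,
    c: float,
    device: DeviceProfile,
    illum: IlluminationField | None,
    seed: int,
    n_replicates: int,
) -> float:
    preds = []
    for r in range(n_replicates):
        img = render_phantom(
            assay,
            c,
            device,
            illum,
            seed=derive_seed(seed, r),
            size=regressor.config.input_size,
            allow_out_of_range=True,
        )
        preds.append(float(regressor.predict(img.pixels)))
    return float(np.mean(preds))


def run_crossdevice(
    regressor: TrainedRegressor,
    devices: Sequence[DeviceProfile | str],
    concentrations: Sequence[float],
    seed: int,
    *,
    n_replicates: int = 6,
    mid_true: float | None = None,
) -> pd.DataFrame:
    """Evaluate alternate devices before/after two-point recalibration.

    For each device: predict the two reference standards, fit the affine
    recalibration, then measure each test concentration (averaging
    ``n_replicates`` fresh captures) raw and recalibrated. Returns one row
    per (device, concentration) with absolute percentage deviations from the
    expected concentration.
    """
    assay = get_assay(regressor.assay)
    if mid_true is None:
        mid_true = default_mid_standard(assay)
    rows = []
    for di, dev in enumerate(devices):
        device = get_device(dev) if isinstance(dev, str) else dev
        readings = measure_reference_readings(
            regressor, assay, device, seed=derive_seed(seed, di, 900), mid_true=mid_true
        )
        cal = fit_two_point(readings)
        for ci, c in enumerate(concentrations):
            raw = _mean_prediction(
                regressor, assay, c, device, None, derive_seed(seed, di, ci), n_replicates
            )
            recal = float(apply_map(cal, raw))
            rows.append(
                {
                    "device": device.name,
                    "concentration": c,
                    "raw_pred": raw,
                    "recal_pred": recal,
                    "pre_deviation_pct": 100.0 * abs(raw - c) / c,
                    "post_deviation_pct": 100.0 * abs(recal - c) / c,
                }
            )
    return pd.DataFrame(rows)


# Context -> (illumination jitter SD, common-mode gain jitter SD).
# Within-day replicates share lighting and handset, so only sensor noise
# varies; across days the LED warm-up state drifts slightly; across users
# handling/positioning perturbs the lighting and the overall optical path.
# All jitters are common-mode (the handset and its manual settings are the
# same; a user cannot alter per-channel sensor gains) and small because
# captures happen inside a light-isolated enclosure.
REPEATABILITY_CONTEXTS: Dict[str, Tuple[float, float]] = {
    "same-day": (0.0, 0.0),
    "different-day": (0.005, 0.0),
    "different-user": (0.010, 0.003),
}


def run_repeatability(
    regressor: TrainedRegressor,
    concentrations: Sequence[float],
    seed: int,
    *,
    n_replicates: int = 10,
    contexts: Dict[str, Tuple[float, float]] | None = None,
    device: DeviceProfile = REFERENCE_DEVICE,
) -> pd.DataFrame:
    """%CV of replicate simulated measurements per (context, concentration).

    Each replicate is a fresh capture: new sensor-noise draw, and per the
    context, jittered illumination intensity and/or device channel gain.
    """
    assay = get_assay(regressor.assay)
    if contexts is None:
        contexts = REPEATABILITY_CONTEXTS
    rows = []
    for ctx_i, (ctx, (illum_sd, gain_sd)) in enumerate(contexts.items()):
        for ci, c in enumerate(concentrations):
            preds = []
            for r in range(n_replicates):
                rng = np.random.default_rng(derive_seed(seed, ctx_i, ci, r))
                ci_base = IlluminationField().center_intensity
                intensity = min(1.0, max(1e-3, ci_base * (1.0 + rng.normal(0.0, illum_sd))))
                field = IlluminationField(intensity, IlluminationField().vignette_strength)
                common = 1.0 + rng.normal(0.0, gain_sd)
                gains = tuple(float(g * common) for g in device.channel_gain)
                dev = DeviceProfile(
                    name=device.name,
                    channel_gain=gains,
                    gamma=device.gamma,
                    white_offset=device.white_offset,
                    noise_sigma=device.noise_sigma,
                )
                img = render_phantom(
                    assay,
                    c,
                    dev,
                    field,
                    seed=derive_seed(seed, ctx_i, ci, r, 1),
                    size=regressor.config.input_size,
                )
                preds.append(float(regressor.predict(img.pixels)))
            series = ReplicateSeries(values=tuple(preds), context=ctx)
            rows.append(
                {
                    "assay": assay.name,
                    "context": ctx,
                    "concentration": c,
                    "mean_pred": float(np.mean(preds)),
                    "cv_percent": cv_percent(series),
                }
            )
    return pd.DataFrame(rows)


def load_agreement_pairs(path=None) -> Dict[str, PairedMeasurements]:
    """Paired (commercial, developed) readings per analyte.

    Without a path, loads the bundled example liver-panel comparison
    (five serum samples per analyte spanning the physiological and
    pathological ranges).
    """
    if path is None:
        src = resources.files("hepachrom.data") / "liver_panel_agreement.csv"
        with resources.as_file(src) as p:
            table = pd.read_csv(p)
    else:
        table = pd.read_csv(path)
    if table.empty:
        raise ValueError("agreement table is empty")
    out: Dict[str, PairedMeasurements] = {}
    for analyte, grp in table.groupby("analyte", sort=False):
        out[str(analyte)] = PairedMeasurements(
            x=tuple(grp["commercial"].astype(float)),
            y=tuple(grp["developed"].astype(float)),
        )
    return out
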