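"""Disk round-trip for phantom collections: 8-bit PNGs + CSV sidecar.

Images are stored as 8-bit RGB PNGs and converted back to floats in [0, 1]
on load (matching smartphone capture followed by CNN input normalisation).
The sidecar CSV carries one row per image: path, assay, concentration,
units, device, augmented flag and seed. A small YAML manifest records how
the collection was generated.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .assays import get_assay
from .phantom import PhantomImage

__all__ = ["save_collection", "load_collection", "SIDECAR_NAME", "MANIFEST_NAME"]

SIDECAR_NAME = "labels.csv"
MANIFEST_NAME = "manifest.yaml"


def _to_uint8(pixels: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(pixels * 255.0), 0, 255).astype(np.uint8)


def save_collection(
    images: Sequence[PhantomImage],
    out_dir: str | Path,
    manifest: dict | None = None,
) -> Path:
    """Write PNGs, the CSV sidecar and a manifest; returns the sidecar path."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, im in enumerate(images):
        rel = f"images/{i:06d}.png"
        Image.fromarray(_to_uint8(im.pixels), mode="RGB").save(out / rel)
        rows.append(
            {
                "image_path": rel,
                "assay": im.assay,
                "concentration": im.concentration,
                "units": get_assay(im.assay).units,
                "device": im.device,
                "augmented": im.augmented,
                "seed": im.seed,
            }
        )
    sidecar = out / SIDECAR_NAME
    pd.DataFrame(rows).to_csv(sidecar, index=False)
    if manifest is not None:
        with open(out / MANIFEST_NAME, "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
    return sidecar


def load_collection(dataset_dir: str | Path) -> Tuple[List[PhantomImage], pd.DataFrame]:
    """Load a saved collection; returns (images, sidecar table)."""
    root = Path(dataset_dir)
    sidecar = root / SIDECAR_NAME
    if not sidecar.exists():
        raise FileNotFoundError(f"no {SIDECAR_NAME} under {root}")
    table = pd.read_csv(sidecar)
    images: List[PhantomImage] = []
    for row in table.itertuples(index=False):
        px = np.asarray(Image.open(root / row.image_path).convert("RGB"))
        images.append(
            PhantomImage(
                pixels=px.astype(np.float64) / 255.0,
                concentration=float(row.concentration),
                assay=str(row.assay),
                device=str(row.device),
                seed=int(row.seed),
                augmented=bool(row.augmented),
            )
        )
    return images, table
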