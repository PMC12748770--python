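"""Dataset assembly: clinical categories, stratified splits, summaries.

Concentrations are binned into five clinically named categories
(Very Low, Low, Normal, High, Very High) with left-closed/right-open bins,
and collections are split into train/test partitions stratified either by
calibration level or by category.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .phantom import PhantomImage

__all__ = [
    "CATEGORY_NAMES",
    "CategoryScheme",
    "SplitSpec",
    "BUILTIN_SCHEMES",
    "get_scheme",
    "assign_category",
    "stratified_split",
    "summarize",
    "collection_frame",
]

CATEGORY_NAMES = ("Very Low", "Low", "Normal", "High", "Very High")


@dataclass(frozen=True)
class CategoryScheme:
    """Five-bin clinical categorisation of one assay's concentrations.

    ``edges`` are the four strictly increasing cut-points; bin ``i`` is
    ``[edges[i-1], edges[i])`` with the first bin starting at 0 and the last
    unbounded above.
    """

    assay: str
    edges: Tuple[float, float, float, float]
    names: Tuple[str, ...] = CATEGORY_NAMES

    def __post_init__(self) -> None:
        if len(self.names) != 5:
            raise ValueError("a category scheme needs exactly 5 names")
        if len(self.edges) != 4:
            raise ValueError("a category scheme needs exactly 4 edges")
        e = self.edges
        if any(b <= a for a, b in zip(e, e[1:])):
            raise ValueError("edges must be strictly increasing")

    def midpoints(self) -> np.ndarray:
        """Finite representative centre of each bin (used as ROC anchors).

        The open-ended top bin is assigned its lower edge plus half the
        width of the bin below it.
        """
        e = self.edges
        mids = [e[0] / 2.0]
        mids += [(a + b) / 2.0 for a, b in zip(e, e[1:])]
        mids.append(e[3] + (e[3] - e[2]) / 2.0)
        return np.array(mids)


# Default edges chosen so each assay's six calibration levels spread over
# all five named bins; fully configurable.
BUILTIN_SCHEMES: Dict[str, CategoryScheme] = {
    "direct-bilirubin": CategoryScheme("direct-bilirubin", (0.5, 3.0, 7.5, 12.5)),
    "total-bilirubin": CategoryScheme("total-bilirubin", (0.5, 3.0, 7.5, 12.5)),
    "ALT": CategoryScheme("ALT", (30.0, 75.0, 125.0, 250.0)),
    "AST": CategoryScheme("AST", (30.0, 75.0, 125.0, 250.0)),
}


def get_scheme(assay: str) -> CategoryScheme:
    try:
        return BUILTIN_SCHEMES[assay]
    except KeyError:
        raise KeyError(f"no built-in category scheme for assay {assay!r}") from None


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split specification (default 80:20, level-stratified)."""

    train_fraction: float = 0.8
    seed: int = 0
    stratify_by: str = "level"  # "level" or "category"

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.stratify_by not in ("level", "category"):
            raise ValueError("stratify_by must be 'level' or 'category'")


def assign_category(c: float, scheme: CategoryScheme) -> str:
    """Category name of concentration ``c`` (bins left-closed, right-open)."""
    if c < 0:
        raise ValueError(f"concentration must be >= 0, got {c}")
    idx = int(np.searchsorted(scheme.edges, c, side="right"))
    return scheme.names[idx]


def _strata(
    images: Sequence[PhantomImage], spec: SplitSpec, scheme: CategoryScheme | None
) -> Dict[object, List[int]]:
    strata: Dict[object, List[int]] = {}
    for i, im in enumerate(images):
        if spec.stratify_by == "level":
            key: object = im.concentration
        else:
            if scheme is None:
                raise ValueError("category stratification requires a scheme")
            key = assign_category(im.concentration, scheme)
        strata.setdefault(key, []).append(i)
    return strata


def stratified_split(
    images: Sequence[PhantomImage],
    spec: SplitSpec,
    scheme: CategoryScheme | None = None,
) -> Tuple[List[PhantomImage], List[PhantomImage]]:
    """Deterministic stratified partition into (train, test).

    Each stratum contributes ``round(train_fraction * n)`` members to the
    train split; both partitions must be non-empty in every stratum, else a
    ``ValueError`` naming the offending stratum is raised. Train and test
    are disjoint and their union is the input.
    """
    strata = _strata(images, spec, scheme)
    rng = np.random.default_rng(spec.seed)
    train_idx: List[int] = []
    test_idx: List[int] = []
    for key in sorted(strata, key=str):
        members = np.array(strata[key])
        if len(members) < 2:
            raise ValueError(f"stratum {key!r} has fewer than 2 members")
        n_train = int(round(spec.train_fraction * len(members)))
        if n_train == 0 or n_train == len(members):
            raise ValueError(
                f"stratum {key!r}: train_fraction {spec.train_fraction} leaves "
                "an empty partition"
            )
        perm = rng.permutation(len(members))
        train_idx.extend(members[perm[:n_train]].tolist())
        test_idx.extend(members[perm[n_train:]].tolist())
    train_idx.sort()
    test_idx.sort()
    return [images[i] for i in train_idx], [images[i] for i in test_idx]


def collection_frame(images: Sequence[PhantomImage]) -> pd.DataFrame:
    """Metadata table of a collection (one row per image)."""
    return pd.DataFrame(
        {
            "assay": [im.assay for im in images],
            "concentration": [im.concentration for im in images],
            "device": [im.device for im in images],
            "augmented": [im.augmented for im in images],
            "seed": [im.seed for im in images],
        }
    )


def summarize(images: Sequence[PhantomImage]) -> pd.DataFrame:
    """Counts per (assay, concentration level, augmented flag).

    Mirrors a dilution-series dataset summary: per level, how many original
    and augmented images; counts sum to the collection size.
    """
    if len(images) == 0:
        return pd.DataFrame(
            columns=["assay", "concentration", "augmented", "count"]
        )
    frame = collection_frame(images)
    out = (
        frame.groupby(["assay", "concentration", "augmented"], sort=True)
        .size()
        .reset_index(name="count")
    )
    return out
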