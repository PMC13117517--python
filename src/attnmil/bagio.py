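"""Readers and writers for per-slide feature bags and label tables.

A *bag* is one slide's set of patch-level feature vectors together with the
level-0 pixel coordinates of each patch. Bags are stored one HDF5 container
per slide (bags are consumed one at a time during training, so a monolithic
store buys nothing), with datasets ``features`` (N x D float32) and
``coords`` (N x 2 int64) and attributes ``slide_id`` and ``patch_size``.

Coordinates are level-0, 0-based top-left corners of half-open patch
footprints ``[x, x + patch_size) x [y, y + patch_size)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "FeatureBag",
    "LabelTable",
    "BagValidationError",
    "BagFormatError",
    "write_bag",
    "read_bag",
    "load_label_table",
]


class BagValidationError(ValueError):
    """A bag or label table violates its invariants."""


class BagFormatError(ValueError):
    """An on-disk container is missing required content."""


@dataclass
class FeatureBag:
    """One slide's instance feature matrix plus patch coordinates.

    Attributes
    ----------
    slide_id : str
        Unique slide identifier.
    features : ndarray, shape (N, D)
        Real-valued instance descriptors, one row per patch.
    coords : ndarray, shape (N, 2)
        Level-0 top-left corner of each patch, ``(x, y)`` order.
    patch_size : int
        Side length in level-0 pixels of the square patch footprint.
    label : int or None
        Class index in ``[0, C)`` if known.
    """

    slide_id: str
    features: np.ndarray
    coords: np.ndarray
    patch_size: int = 256
    label: int | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float32)
        self.coords = np.asarray(self.coords, dtype=np.int64)
        self.validate()

    @property
    def n_instances(self) -> int:
        return self.features.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.features.shape[1]

    def validate(self) -> None:
        if self.features.ndim != 2 or self.features.shape[0] < 1:
            raise BagValidationError(
                f"features must be a non-empty N x D matrix, got shape {self.features.shape}"
            )
        if not np.isfinite(self.features).all():
            raise BagValidationError(f"bag {self.slide_id!r}: features contain NaN/Inf")
        if self.coords.shape != (self.features.shape[0], 2):
            raise BagValidationError(
                f"coords shape {self.coords.shape} does not match N={self.features.shape[0]}"
            )
        if (self.coords < 0).any():
            raise BagValidationError(f"bag {self.slide_id!r}: negative coordinates")
        if len(np.unique(self.coords, axis=0)) != len(self.coords):
            raise BagValidationError(f"bag {self.slide_id!r}: duplicate patch coordinates")
        if self.patch_size <= 0:
            raise BagValidationError("patch_size must be positive")


@dataclass
class LabelTable:
    """Mapping slide_id -> dense class index, with ordered class names."""

    labels: dict[str, int]
    class_names: list[str] = field(default_factory=list)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def __getitem__(self, slide_id: str) -> int:
        return self.labels[slide_id]

    def validate(self) -> None:
        c = self.n_classes
        idx = set(self.labels.values())
        if not idx.issubset(range(c)):
            raise BagValidationError("class indices must be dense in [0, C)")


def write_bag(bag: FeatureBag, path: str | Path) -> Path:
    """Write a validated bag to one HDF5 container; inverse of :func:`read_bag`."""
    bag.validate()
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=bag.features.astype(np.float32))
        f.create_dataset("coords", data=bag.coords.astype(np.int64))
        f.attrs["slide_id"] = bag.slide_id
        f.attrs["patch_size"] = bag.patch_size
        if bag.label is not None:
            f.attrs["label"] = int(bag.label)
    return path


def read_bag(path: str | Path) -> FeatureBag:
    """Load a bag written by :func:`write_bag`, failing loud on malformed files."""
    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except OSError as e:
        raise OSError(f"cannot read bag container {path}: {e}") from e
    with f:
        for key in ("features", "coords"):
            if key not in f:
                raise BagFormatError(f"{path}: missing required dataset {key!r}")
        features = f["features"][()]
        coords = f["coords"][()]
        slide_id = f.attrs.get("slide_id", path.stem)
        patch_size = int(f.attrs.get("patch_size", 256))
        label = int(f.attrs["label"]) if "label" in f.attrs else None
    return FeatureBag(
        slide_id=str(slide_id), features=features, coords=coords,
        patch_size=patch_size, label=label,
    )


def load_label_table(csv_path: str | Path) -> LabelTable:
    """Load a slide_id,label CSV.

    Class names are sorted lexicographically and indices assigned in that
    order, so the mapping depends only on the set of labels present.
    """
    df = pd.read_csv(csv_path, dtype=str)
    if not {"slide_id", "label"}.issubset(df.columns):
        raise BagFormatError(f"{csv_path}: expected header slide_id,label")
    if len(df) == 0:
        raise BagValidationError(f"{csv_path}: empty label table")
    if df["slide_id"].duplicated().any():
        dupes = df.loc[df["slide_id"].duplicated(), "slide_id"].tolist()
        raise BagValidationError(f"{csv_path}: duplicate slide_id(s): {dupes}")
    class_names = sorted(df["label"].unique())
    index = {name: i for i, name in enumerate(class_names)}
    labels = {row.slide_id: index[row.label] for row in df.itertuples()}
    table = LabelTable(labels=labels, class_names=class_names)
    table.validate()
    return table
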