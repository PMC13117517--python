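"""Synthetic feature-bag datasets and synthetic slide images with known truth.

Two generators back the test surface of the whole package:

* :func:`generate_bag_dataset` emulates the weakly supervised structure of
  slide classification: each bag carries a single label but only a small,
  known fraction of its instances (the "signal" instances, drawn near a
  class prototype) actually encode it; the rest are isotropic noise. The
  per-instance ground-truth flags let attention quality be measured
  directly, which no real slide dataset allows.
* :func:`generate_tissue_image` draws saturated tissue blobs, background
  colored holes and sub-threshold artifact speckles on a near-white canvas,
  with exact rasterized masks, exercising the segmentation pipeline
  end to end.

Both are pure functions of (config, seed): identical inputs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .bagio import FeatureBag, LabelTable, write_bag

__all__ = [
    "BagSimConfig",
    "ImageSimConfig",
    "ConfigError",
    "HISTOTYPES",
    "generate_bag_dataset",
    "generate_tissue_image",
    "toy_feature_extractor",
    "save_dataset",
]

#: The five main ovarian carcinoma histotypes; used as default class names.
HISTOTYPES = ["HGSC", "EC", "CCC", "MC", "LGSC"]


class ConfigError(ValueError):
    """A simulation config violates its invariants."""


@dataclass
class BagSimConfig:
    """Parameters of the synthetic bag generator.

    Defaults are the desk-scale study conditions: 5 classes (mirroring the
    five histotypes), 20 bags per class, 100-300 instances per bag of
    dimension 64, 5% signal prevalence, noise sd 0.5, prototype separation 5.
    """

    n_classes: int = 5
    bags_per_class: int = 20
    instances_per_bag: tuple[int, int] = (100, 300)
    feature_dim: int = 64
    signal_prevalence: float = 0.05
    prototype_separation: float = 5.0
    noise_sd: float = 0.5
    seed: int = 0
    patch_size: int = 256
    class_names: list[str] | None = None

    def __post_init__(self) -> None:
        n_min, n_max = self.instances_per_bag
        if self.n_classes < 2:
            raise ConfigError("need at least 2 classes")
        if self.bags_per_class < 1 or self.feature_dim < 1:
            raise ConfigError("bags_per_class and feature_dim must be positive")
        if n_min < 1 or n_min > n_max:
            raise ConfigError(f"invalid instance range [{n_min}, {n_max}]")
        if not 0.0 < self.signal_prevalence <= 1.0:
            raise ConfigError("signal_prevalence must lie in (0, 1]")
        if self.noise_sd < 0 or self.prototype_separation < 0:
            raise ConfigError("noise_sd and prototype_separation must be nonnegative")
        if self.class_names is not None and len(self.class_names) != self.n_classes:
            raise ConfigError("class_names length must equal n_classes")


def _make_prototypes(c: int, dim: int, separation: float, rng: np.random.Generator) -> np.ndarray:
    """C near-orthogonal unit vectors scaled so pairwise distances ~ separation.

    Random Gaussian directions orthonormalized by QR when dim >= C, else
    plain normalized Gaussians (high-dim near-orthogonality is lost but the
    pairwise scale is still controlled by `separation`).
    """
    g = rng.standard_normal((dim, max(c, 1)))
    if dim >= c:
        q, _ = np.linalg.qr(g)
        basis = q[:, :c].T
    else:
        basis = g[:, :c].T
        basis /= np.linalg.norm(basis, axis=1, keepdims=True)
    # orthonormal prototypes at radius s have pairwise distance s*sqrt(2)
    return basis * (separation / np.sqrt(2.0))


def generate_bag_dataset(
    config: BagSimConfig,
) -> tuple[list[FeatureBag], LabelTable, dict[str, np.ndarray]]:
    """Generate labeled bags whose signal is carried by a known instance subset.

    Each bag of class ``c`` contains ``ceil(prevalence * N)`` signal
    instances drawn from Normal(prototype_c, sd^2 I) at positions chosen
    uniformly at random within the bag, and noise instances drawn from
    Normal(0, sd^2 I).

    Returns
    -------
    bags : list of FeatureBag
        With ``label`` set to the class index of the lexicographically
        sorted class names (matching :func:`attnmil.bagio.load_label_table`).
    labels : LabelTable
    signal_flags : dict slide_id -> bool ndarray of length N
        True where the instance was drawn from the class prototype.
    """
    rng = np.random.default_rng(config.seed)
    c, dim = config.n_classes, config.feature_dim
    names = config.class_names or (
        HISTOTYPES[:c] if c <= len(HISTOTYPES) else [f"class{i:02d}" for i in range(c)]
    )
    class_names = sorted(names)
    prototypes = _make_prototypes(c, dim, config.prototype_separation, rng)

    n_min, n_max = config.instances_per_bag
    bags: list[FeatureBag] = []
    labels: dict[str, int] = {}
    flags: dict[str, np.ndarray] = {}
    for cls in range(c):
        for b in range(config.bags_per_class):
            slide_id = f"{class_names[cls]}_{b:03d}"
            n = int(rng.integers(n_min, n_max + 1))
            n_signal = int(np.ceil(config.signal_prevalence * n))
            signal_pos = rng.choice(n, size=n_signal, replace=False)
            x = rng.standard_normal((n, dim)) * config.noise_sd
            x[signal_pos] += prototypes[cls]
            flag = np.zeros(n, dtype=bool)
            flag[signal_pos] = True
            coords = _grid_coords(n, config.patch_size)
            bags.append(FeatureBag(slide_id=slide_id, features=x, coords=coords,
                                   patch_size=config.patch_size, label=cls))
            labels[slide_id] = cls
            flags[slide_id] = flag
    return bags, LabelTable(labels=labels, class_names=class_names), flags


def _grid_coords(n: int, patch_size: int) -> np.ndarray:
    """First n cells of a square row-major patch grid (unique, grid-aligned)."""
    side = int(np.ceil(np.sqrt(n)))
    idx = np.arange(n)
    return np.stack([(idx % side) * patch_size, (idx // side) * patch_size], axis=1)


# ---------------------------------------------------------------------------
# synthetic slide images


@dataclass
class ImageSimConfig:
    """A scene of saturated tissue blobs, holes and small artifact speckles.

    ``blobs`` are (center(x, y), radius, saturation in [0, 255]); ``holes``
    are (center, radius) and must have their center inside some blob;
    ``artifacts`` are (center, radius) speckles rendered at full saturation
    but intended to fall below any sensible area threshold.
    """

    canvas_size: tuple[int, int] = (512, 512)  # (H, W)
    blobs: list[tuple[tuple[float, float], float, float]] = field(default_factory=list)
    holes: list[tuple[tuple[float, float], float]] = field(default_factory=list)
    artifacts: list[tuple[tuple[float, float], float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.canvas_size
        if h < 1 or w < 1:
            raise ConfigError("canvas must be nonempty")
        for (cx, cy), r, *_ in [*self.blobs, *self.holes, *self.artifacts]:
            if not (0 <= cx - r and cx + r < w and 0 <= cy - r and cy + r < h):
                raise ConfigError(f"shape at ({cx}, {cy}) r={r} exceeds canvas {w}x{h}")
        for (cx, cy), _ in self.holes:
            inside = any((cx - bx) ** 2 + (cy - by) ** 2 <= br ** 2
                         for (bx, by), br, _ in self.blobs)
            if not inside:
                raise ConfigError(f"hole center ({cx}, {cy}) lies outside every blob")


_BACKGROUND_RGB = np.array([243, 243, 243], dtype=np.uint8)


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    h, w = shape
    yy, xx = np.ogrid[:h, :w]
    cx, cy = center
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2


def _saturated_rgb(saturation: float) -> np.ndarray:
    """RGB of a magenta-ish hue at the given HSV saturation (0-255 scale)."""
    s = saturation / 255.0
    v = 0.85
    # hue 300 deg: R = V, G = V(1-S), B = V
    return np.array([v * 255, v * (1 - s) * 255, v * 255], dtype=np.uint8)


def generate_tissue_image(
    config: ImageSimConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render the scene and return (RGB uint8 image, tissue mask, hole mask).

    The tissue mask is the union of blob disks minus hole disks; artifact
    speckles are saturated in the image but excluded from the tissue mask
    (they are what the segmenter's area filter must reject).
    """
    h, w = config.canvas_size
    img = np.tile(_BACKGROUND_RGB, (h, w, 1)).copy()
    tissue = np.zeros((h, w), dtype=bool)
    hole_mask = np.zeros((h, w), dtype=bool)

    for center, radius, sat in config.blobs:
        d = _disk_mask((h, w), center, radius)
        img[d] = _saturated_rgb(sat)
        tissue |= d
    for center, radius in config.holes:
        d = _disk_mask((h, w), center, radius)
        img[d] = _BACKGROUND_RGB
        hole_mask |= d & tissue
    tissue &= ~hole_mask
    for center, radius in config.artifacts:
        d = _disk_mask((h, w), center, radius)
        img[d] = _saturated_rgb(255.0)
    return img, tissue, hole_mask


# ---------------------------------------------------------------------------
# toy feature extractor


def toy_feature_extractor(
    patches: list[np.ndarray] | np.ndarray,
    dim: int,
    seed: int = 0,
    projection: np.ndarray | None = None,
) -> np.ndarray:
    """Deterministic fixed random projection of flattened pixels to `dim` dims.

    A test stand-in for a pretrained patch encoder: it preserves nothing
    semantic, only determinism and shape. ``projection`` may be supplied
    explicitly ((dim, n_pixels)); otherwise a Gaussian projection scaled by
    1/sqrt(n_pixels) is drawn once from ``seed``.
    """
    patches = list(patches)
    if len(patches) == 0:
        return np.zeros((0, dim), dtype=np.float64)
    shapes = {p.shape for p in patches}
    if len(shapes) != 1:
        raise ValueError(f"tiles must share shape, got {shapes}")
    flat = np.stack([np.asarray(p, dtype=np.float64).ravel() for p in patches])
    n_pix = flat.shape[1]
    if projection is None:
        rng = np.random.default_rng(seed)
        projection = rng.standard_normal((dim, n_pix)) / np.sqrt(n_pix)
    elif projection.shape != (dim, n_pix):
        raise ValueError(f"projection shape {projection.shape} != ({dim}, {n_pix})")
    return flat @ projection.T


def save_dataset(
    bags: list[FeatureBag],
    labels: LabelTable,
    flags: dict[str, np.ndarray],
    out_dir: str | Path,
) -> Path:
    """Write bags (plus signal flags) and labels.csv under `out_dir`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for bag in bags:
        path = write_bag(bag, out_dir / f"{bag.slide_id}.h5")
        if bag.slide_id in flags:
            with h5py.File(path, "a") as f:
                f.create_dataset("signal_flags", data=flags[bag.slide_id].astype(np.uint8))
    lines = ["slide_id,label"]
    lines += [f"{sid},{labels.class_names[c]}" for sid, c in sorted(labels.labels.items())]
    (out_dir / "labels.csv").write_text("\n".join(lines) + "\n")
    return out_dir
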