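"""Attention heatmaps: per-patch weights rendered as rasters and overlays.

Scores are min-max normalized per slide, each patch footprint is painted
with its normalized score at the rendering downsample, and the raster can
be colormapped and alpha-blended onto a slide thumbnail. Pixels outside
every patch footprint keep a background sentinel (-1) and pass the
thumbnail through unchanged in overlays.

For the multi-branch model the convention is to render the predicted
class's branch weights; single-branch models render their (only) weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps

__all__ = ["HeatmapSpec", "BACKGROUND", "attention_to_raster", "overlay"]

logger = logging.getLogger(__name__)

BACKGROUND = -1.0  # sentinel for pixels outside every patch footprint


@dataclass
class HeatmapSpec:
    """What to paint: per-patch scores at level-0 coords, and how."""

    scores: np.ndarray            # (M,)
    coords: np.ndarray            # (M, 2) level-0 top-left corners
    patch_size: int = 256
    canvas_downsample: float = 1.0
    colormap: str = "viridis"
    alpha: float = 0.5

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float).ravel()
        self.coords = np.asarray(self.coords)
        if len(self.scores) != len(self.coords):
            raise ValueError("scores and coords must have equal length")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


def attention_to_raster(spec: HeatmapSpec, canvas_extent: tuple[int, int]) -> np.ndarray:
    """Paint normalized scores into a (H, W) float raster at the given scale.

    ``canvas_extent`` is the level-0 (width, height); the raster has shape
    (H/ds, W/ds). Min-max normalization is per slide; if all scores are
    equal every patch is painted 1.0 (degenerate normalization, warned).
    """
    w0, h0 = canvas_extent
    ds = spec.canvas_downsample
    h, w = int(np.ceil(h0 / ds)), int(np.ceil(w0 / ds))
    raster = np.full((h, w), BACKGROUND, dtype=float)
    lo, hi = spec.scores.min(initial=np.inf), spec.scores.max(initial=-np.inf)
    if len(spec.scores) == 0:
        return raster
    if hi - lo <= 0:
        logger.warning("all attention scores equal; painting 1.0 everywhere")
        norm = np.ones_like(spec.scores)
    else:
        norm = (spec.scores - lo) / (hi - lo)
    for (x, y), v in zip(spec.coords, norm):
        x0, y0 = int(np.floor(x / ds)), int(np.floor(y / ds))
        x1 = int(np.floor((x + spec.patch_size) / ds))
        y1 = int(np.floor((y + spec.patch_size) / ds))
        raster[y0:min(y1, h), x0:min(x1, w)] = v
    return raster


def overlay(raster: np.ndarray, thumbnail: np.ndarray,
            colormap: str = "viridis", alpha: float = 0.5) -> np.ndarray:
    """Alpha-blend the colormapped raster over an RGB thumbnail.

    Background-sentinel pixels pass the thumbnail through untouched;
    painted pixels become ``(1 - alpha) * thumb + alpha * color``.
    """
    thumbnail = np.asarray(thumbnail)
    if raster.shape != thumbnail.shape[:2]:
        raise ValueError(
            f"raster extent {raster.shape} != thumbnail {thumbnail.shape[:2]}"
        )
    cmap = colormaps[colormap]
    painted = raster != BACKGROUND
    colors = cmap(np.clip(raster, 0.0, 1.0))[:, :, :3] * 255.0
    out = thumbnail[:, :, :3].astype(float)
    out[painted] = (1.0 - alpha) * out[painted] + alpha * colors[painted]
    return np.clip(np.round(out), 0, 255).astype(np.uint8)
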