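"""Tissue segmentation and patch tessellation on a synthetic slide.

Renders a scene with two tissue blobs, a hole and two sub-threshold
artifact speckles, runs the HSV-saturation segmentation pipeline, and
tessellates the mask into non-overlapping patches. The artifacts must be
rejected by the area filter and the hole excluded from the patch grid.
"""

import numpy as np

from attnmil import synthdata, tissueseg

scene = synthdata.ImageSimConfig(
    canvas_size=(400, 400),
    blobs=[((130, 130), 80, 220), ((290, 280), 60, 200)],
    holes=[((130, 130), 25)],
    artifacts=[((360, 50), 2), ((40, 360), 2)],
)
img, truth, _ = synthdata.generate_tissue_image(scene)

mask = tissueseg.segment_tissue(img, tissueseg.SegParams(athresh=100, hole_athresh=16))
print(f"{len(mask.contours)} tissue contours, {len(mask.holes)} holes "
      "(2 blobs kept, artifacts filtered, hole retained)")

recovered = tissueseg.rasterize_mask(mask, truth.shape)
iou = (recovered & truth).sum() / (recovered | truth).sum()
print(f"IoU against ground truth: {iou:.3f}")

grid = tissueseg.tessellate(mask, patch_size=32, image_extent=(400, 400))
print(f"{len(grid.coords)} patches of 32x32 px with centers in tissue")
centers = grid.coords + 16
inside_hole = ((centers - [130, 130]) ** 2).sum(axis=1) <= 25 ** 2
print(f"patches with centers inside the hole: {int(inside_hole.sum())} (expected 0)")
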