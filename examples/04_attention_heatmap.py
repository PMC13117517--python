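"""Render a trained model's attention as a spatial heatmap.

Trains a quick model, takes one bag's attention weights, paints each
patch's footprint with its min-max-normalized weight, and overlays the
colormapped raster on a synthetic thumbnail. The brightest footprint
marks the patch the model weighted most for its prediction.
"""

import numpy as np

from attnmil import heatmap, synthdata, trainer
from attnmil.milnet import ModelConfig

cfg = synthdata.BagSimConfig(n_classes=3, bags_per_class=6,
                             instances_per_bag=(25, 36), feature_dim=16,
                             signal_prevalence=0.2, seed=2)
bags, labels, flags = synthdata.generate_bag_dataset(cfg)
bag_map = {b.slide_id: b for b in bags}
tcfg = trainer.TrainConfig(n_runs=1, seed=0, max_epochs=20, patience=20,
                           model=ModelConfig(arch="sab"))
plan = trainer.make_splits(sorted(bag_map), labels, tcfg)[0]
trained = trainer.train_model(bag_map, labels, plan, tcfg)

bag = bag_map[plan.test_ids[0]]
pred = trained.model.forward(bag)
print(f"slide {bag.slide_id}: predicted class {pred.predicted_class} "
      f"(p = {pred.probs[pred.predicted_class]:.2f}), true class {bag.label}")

extent = (int(bag.coords[:, 0].max()) + bag.patch_size,
          int(bag.coords[:, 1].max()) + bag.patch_size)
spec = heatmap.HeatmapSpec(scores=pred.attention.weights, coords=bag.coords,
                           patch_size=bag.patch_size, canvas_downsample=64.0)
raster = heatmap.attention_to_raster(spec, extent)
print(f"raster {raster.shape}, painted pixels: {(raster != heatmap.BACKGROUND).sum()}")

thumb = np.full((*raster.shape, 3), 240, dtype=np.uint8)
blended = heatmap.overlay(raster, thumb, colormap="viridis", alpha=0.6)
print(f"overlay shape {blended.shape}; max-attention patch index "
      f"{int(np.argmax(pred.attention.weights))} is signal: "
      f"{bool(flags[bag.slide_id][np.argmax(pred.attention.weights)])}")
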