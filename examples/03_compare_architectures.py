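"""Non-parametric comparison of MIL architectures.

Trains SAB and the stochastic-attention variant SA-2 over four shared
random splits, then runs the paired Wilcoxon signed-rank test on the
per-run balanced accuracies, and shows the Nemenyi critical difference
for the study-scale comparison shape (6 models over 10 runs).
"""

from attnmil import compare, synthdata, trainer
from attnmil.milnet import ModelConfig

cfg = synthdata.BagSimConfig(n_classes=3, bags_per_class=8,
                             instances_per_bag=(40, 80), feature_dim=32,
                             signal_prevalence=0.2, seed=1)
bags, labels, _ = synthdata.generate_bag_dataset(cfg)

archs = {"SAB": ModelConfig(arch="sab"), "SA-2": ModelConfig(arch="sa", k=2)}
results = trainer.run_experiment(
    bags, labels, archs, trainer.TrainConfig(n_runs=4, seed=0, max_epochs=15,
                                             patience=15))

wide = results[results.metric == "balanced_accuracy"].pivot(
    index="run_id", columns="model", values="value")
print("per-run balanced accuracy:")
print(wide.round(3).to_string())

stat, p = compare.wilcoxon_signed_rank(wide["SA-2"].to_numpy(), wide["SAB"].to_numpy())
print(f"\nWilcoxon signed-rank SA-2 vs SAB: W = {stat:.1f}, p = {p:.3f}")
print("(small p would mean one model consistently outranks the other; "
      "4 paired runs can at best reach p = 0.125)")

cd = compare.nemenyi_cd(6, 10, alpha=0.05)
print(f"\nNemenyi critical difference for 6 models x 10 runs: {cd:.2f}")
print("(two models differ significantly when their average ranks "
      f"differ by at least {cd:.2f})")
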