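"""Training protocol: repeated random sub-sampling, weighted sampling,
Adam at 2e-4, early stopping on validation loss.

The protocol mirrors weakly supervised slide classification practice:

* 10 independent random 75 / 12.5 / 12.5 train/val/test partitions of the
  slide ids (not stratified; class imbalance is handled by the sampler);
* each training epoch is ``len(train)`` single-bag steps drawn with
  replacement, with per-slide probability inversely proportional to its
  class count, so every class contributes equally in expectation;
* bag-level cross-entropy, Adam with learning rate 2e-4, at most 50
  epochs, early stopping with patience 10 on the validation loss, and the
  best-epoch parameters restored.

Everything is deterministic given (seed, config).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bagio import FeatureBag, LabelTable
from .milnet import MILModel, ModelConfig
from . import metrics as _metrics

__all__ = [
    "SplitPlan",
    "TrainConfig",
    "TrainedModel",
    "make_splits",
    "class_weighted_sampler",
    "train_model",
    "evaluate_model",
    "run_experiment",
    "AdamState",
]

logger = logging.getLogger(__name__)


@dataclass
class SplitPlan:
    """One run's disjoint train/val/test slide-id partition."""

    run_id: int
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]

    def validate(self, cohort: set[str]) -> None:
        parts = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        if parts[0] | parts[1] | parts[2] != cohort:
            raise ValueError("split does not cover the cohort")
        if parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2]:
            raise ValueError("split partitions overlap")


@dataclass
class TrainConfig:
    """Optimization protocol; defaults are the study conditions."""

    learning_rate: float = 2e-4
    max_epochs: int = 50
    patience: int = 10
    batch_size: int = 1
    n_runs: int = 10
    seed: int = 0
    model: ModelConfig = field(default_factory=ModelConfig)
    stratify: bool = False

    def __post_init__(self) -> None:
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if self.batch_size != 1:
            raise ValueError("the attention pipeline trains one bag at a time")


@dataclass
class TrainedModel:
    model: MILModel
    history: pd.DataFrame  # columns: epoch, train_loss, val_loss, val_balanced_accuracy
    best_epoch: int
    stopped_early: bool


def make_splits(
    slide_ids: list[str],
    labels: LabelTable,
    config: TrainConfig,
) -> list[SplitPlan]:
    """n_runs independent random 75/12.5/12.5 partitions.

    12.5% fractions are rounded with banker's rounding; the shuffled list
    is consumed val first, then test, then train, which fixes the partition
    for a given (seed, run_id). With ``stratify`` the same rule is applied
    within each class.
    """
    n = len(slide_ids)
    if n < 8:
        raise ValueError("need at least 8 slides for a 75/12.5/12.5 split")
    if labels.n_classes < 2:
        raise ValueError("need at least 2 classes")
    plans = []
    for run_id in range(config.n_runs):
        rng = np.random.default_rng([config.seed, run_id])
        if config.stratify:
            val: list[str] = []
            test: list[str] = []
            train: list[str] = []
            by_class: dict[int, list[str]] = {}
            for sid in slide_ids:
                by_class.setdefault(labels[sid], []).append(sid)
            for cls in sorted(by_class):
                ids = list(by_class[cls])
                rng.shuffle(ids)
                nv = round(0.125 * len(ids))
                val += ids[:nv]
                test += ids[nv: 2 * nv]
                train += ids[2 * nv:]
        else:
            ids = list(slide_ids)
            rng.shuffle(ids)
            nv = round(0.125 * n)
            nt = round(0.125 * n)
            val, test, train = ids[:nv], ids[nv: nv + nt], ids[nv + nt:]
        plan = SplitPlan(run_id=run_id, train_ids=train, val_ids=val, test_ids=test)
        plan.validate(set(slide_ids))
        for name, part in (("val", val), ("test", test)):
            present = {labels[s] for s in part}
            if len(present) < labels.n_classes:
                logger.warning("run %d: %s set is missing %d class(es)",
                               run_id, name, labels.n_classes - len(present))
        plans.append(plan)
    return plans


def class_weighted_sampler(train_labels: list[int]) -> np.ndarray:
    """Per-slide sampling probability proportional to 1/count(class).

    Expected draws per class are equal, countering class imbalance.
    """
    if len(train_labels) == 0:
        raise ValueError("empty training set")
    y = np.asarray(train_labels)
    counts = np.bincount(y)
    if (counts > 0).sum() == 1:
        logger.warning("single-class training set; weighted sampling is uniform")
    p = 1.0 / counts[y]
    return p / p.sum()


class AdamState:
    """Plain Adam with the conventional beta/epsilon defaults."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 2e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _eval_loss_and_preds(model: MILModel, bags: dict[str, FeatureBag],
                         ids: list[str], labels: LabelTable):
    losses, y_true, y_pred, probs = [], [], [], []
    for sid in ids:
        pred = model.forward(bags[sid], mode="eval")
        y = labels[sid]
        losses.append(-np.log(max(pred.probs[y], 1e-300)))
        y_true.append(y)
        y_pred.append(pred.predicted_class)
        probs.append(pred.probs)
    return float(np.mean(losses)), np.array(y_true), np.array(y_pred), np.array(probs)


def train_model(
    bags: dict[str, FeatureBag] | list[FeatureBag],
    labels: LabelTable,
    split: SplitPlan,
    config: TrainConfig,
) -> TrainedModel:
    """Train one architecture on one split with early stopping.

    The validation loss is computed after every epoch; training stops when
    it has failed to improve for ``patience`` consecutive epochs or at
    ``max_epochs``, and the parameters of the best epoch are restored.
    Test ids are never touched here.
    """
    if isinstance(bags, list):
        bags = {b.slide_id: b for b in bags}
    cfg = replace(config.model, in_dim=next(iter(bags.values())).feature_dim,
                  n_classes=labels.n_classes)
    rng = np.random.default_rng([config.seed, split.run_id, 7])
    model = MILModel(cfg, seed=int(rng.integers(2 ** 31)))
    adam = AdamState(model.params, lr=config.learning_rate)

    train_ids = list(split.train_ids)
    probs = class_weighted_sampler([labels[s] for s in train_ids])

    best_loss = np.inf
    best_epoch = -1
    best_params: dict[str, np.ndarray] = {}
    bad_epochs = 0
    rows = []
    stopped_early = False
    for epoch in range(config.max_epochs):
        epoch_losses = []
        draws = rng.choice(len(train_ids), size=len(train_ids), replace=True, p=probs)
        for j in draws:
            sid = train_ids[j]
            loss, grads, _ = model.loss_and_gradients(
                bags[sid], labels[sid], mode="train", rng=rng
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, bag {sid!r}"
                )
            adam.step(model.params, grads)
            epoch_losses.append(loss)
        val_loss, y_true, y_pred, _ = _eval_loss_and_preds(model, bags, split.val_ids, labels)
        val_bacc = _metrics.balanced_accuracy(y_true, y_pred)
        rows.append({"epoch": epoch, "train_loss": float(np.mean(epoch_losses)),
                     "val_loss": val_loss, "val_balanced_accuracy": val_bacc})
        if val_loss < best_loss:
            best_loss = val_loss
            best_epoch = epoch
            best_params = {k: v.copy() for k, v in model.params.items()}
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                stopped_early = True
                break
    model.params = best_params
    return TrainedModel(model=model, history=pd.DataFrame(rows),
                        best_epoch=best_epoch, stopped_early=stopped_early)


def evaluate_model(
    model: MILModel,
    bags: dict[str, FeatureBag],
    ids: list[str],
    labels: LabelTable,
) -> dict[str, float]:
    """Point estimates of the six study metrics on the given slide ids."""
    _, y_true, y_pred, probs = _eval_loss_and_preds(model, bags, ids, labels)
    return _metrics.metric_suite(y_true, y_pred, probs)


def run_experiment(
    bags: dict[str, FeatureBag] | list[FeatureBag],
    labels: LabelTable,
    architectures: dict[str, ModelConfig],
    config: TrainConfig,
) -> pd.DataFrame:
    """Train every architecture on every split; tidy results table.

    Returns a DataFrame with columns run_id, model, metric, value — the
    input format of the comparison module. Splits are shared across
    architectures so per-run metrics are paired.
    """
    if isinstance(bags, list):
        bags = {b.slide_id: b for b in bags}
    slide_ids = sorted(bags)
    plans = make_splits(slide_ids, labels, config)
    rows = []
    for plan in plans:
        for name, model_cfg in architectures.items():
            run_cfg = replace(config, model=model_cfg)
            trained = train_model(bags, labels, plan, run_cfg)
            scores = evaluate_model(trained.model, bags, plan.test_ids, labels)
            for metric, value in scores.items():
                rows.append({"run_id": plan.run_id, "model": name,
                             "metric": metric, "value": value})
            logger.info("run %d %s: %s", plan.run_id, name,
                        {k: round(v, 3) for k, v in scores.items()})
    return pd.DataFrame(rows)
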