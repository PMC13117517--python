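"""Gated-attention MIL heads: SAB, MAB, DIP and SA-k.

All four architectures share a fully connected + ReLU transform of the raw
instance features (with dropout in training mode) and differ in how the
bag representation is pooled:

* **SAB** — single gated-attention branch: per instance,
  ``a_i = w^T (tanh(V h_i) * sigmoid(U h_i))``, softmax over instances,
  ``M = sum_i alpha_i h_i``, linear classifier on M.
* **MAB** — one gated-attention branch and one scalar-output classifier per
  class; the final probabilities are a softmax over the C per-branch logits.
* **DIP** — a two-layer perceptron scores each raw instance feature; only
  the top-K instances are retained and fed to SAB. The hard top-K gives the
  scorer no gradient from the bag loss.
* **SA-k** — SAB in which, during training only, the weighted average is
  taken over a subset of k instances sampled without replacement with
  probability proportional to the attention weights, and the sampled
  weights are renormalized. A dropout-like regularizer against attention
  concentration. Evaluation is exactly SAB.

Everything is plain NumPy (float64) with hand-derived analytic gradients;
finite-difference checks live in the test suite. A batch is one bag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .bagio import FeatureBag

__all__ = [
    "ModelConfig",
    "AttentionResult",
    "Prediction",
    "MILModel",
    "transform_features",
    "gated_attention_scores",
    "attention_weights",
    "aggregate",
    "dip_select",
    "stochastic_sample",
    "sab_forward",
    "mab_forward",
    "dip_forward",
    "sa_forward",
    "init_params",
    "save_checkpoint",
    "load_checkpoint",
    "ARCHITECTURES",
]

ARCHITECTURES = ("sab", "mab", "dip", "sa")


@dataclass
class ModelConfig:
    """Architecture and hyperparameters of one MIL model.

    ``hidden_dim`` (L) and ``attn_dim`` are desk-scale defaults; ``k`` is
    the stochastic-attention sample count (4, 16 or 32 in the study
    conditions), ``top_k`` the DIP retained-instance count.
    """

    arch: str = "sab"
    in_dim: int = 64
    n_classes: int = 5
    hidden_dim: int = 128
    attn_dim: int = 64
    dropout: float = 0.25
    k: int = 4
    top_k: int = 64
    replacement: bool = False
    score_transformed: bool = False
    scorer_hidden: int = 64
    clustering_weight: float = 0.0
    clustering_top: int = 8

    def __post_init__(self) -> None:
        if self.arch not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.arch!r}; choose from {ARCHITECTURES}")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.k < 1 or self.top_k < 1:
            raise ValueError("k and top_k must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


@dataclass
class AttentionResult:
    """Raw attention scores, normalized weights and the bag representation.

    For SAB/SA/DIP the arrays are (N,) and the representation is (L,);
    for MAB they are (N, C) and (C, L). Each weight column sums to 1.
    """

    raw_scores: np.ndarray
    weights: np.ndarray
    representation: np.ndarray
    kept_indices: np.ndarray | None = None  # DIP pruning / SA sampling


@dataclass
class Prediction:
    """Class probabilities with the maximum-probability decision rule."""

    probs: np.ndarray
    predicted_class: int
    attention: AttentionResult

    def __post_init__(self) -> None:
        # np.argmax already breaks ties by lowest index
        assert self.predicted_class == int(np.argmax(self.probs))


# ---------------------------------------------------------------------------
# parameter initialization


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape: tuple) -> np.ndarray:
    scale = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.standard_normal(shape) * scale


def init_params(config: ModelConfig, seed: int = 0) -> dict[str, np.ndarray]:
    """Draw an initial parameter set for the given architecture."""
    rng = np.random.default_rng(seed)
    d, l, a, c = config.in_dim, config.hidden_dim, config.attn_dim, config.n_classes
    p: dict[str, np.ndarray] = {
        "W1": _glorot(rng, d, l, (d, l)),
        "b1": np.zeros(l),
    }
    if config.arch == "mab":
        p["V"] = _glorot(rng, l, a, (c, a, l))
        p["bv"] = np.zeros((c, a))
        p["U"] = _glorot(rng, l, a, (c, a, l))
        p["bu"] = np.zeros((c, a))
        p["w"] = _glorot(rng, a, 1, (c, a))
        p["bw"] = np.zeros(c)
        p["Wc"] = _glorot(rng, l, 1, (c, l))
        p["bc"] = np.zeros(c)
    else:
        p["V"] = _glorot(rng, l, a, (a, l))
        p["bv"] = np.zeros(a)
        p["U"] = _glorot(rng, l, a, (a, l))
        p["bu"] = np.zeros(a)
        p["w"] = _glorot(rng, a, 1, (a,))
        p["bw"] = np.zeros(())
        p["Wc"] = _glorot(rng, l, c, (l, c))
        p["bc"] = np.zeros(c)
    if config.arch == "dip":
        s_in = l if config.score_transformed else d
        s = config.scorer_hidden
        p["Ws1"] = _glorot(rng, s_in, s, (s_in, s))
        p["bs1"] = np.zeros(s)
        p["Ws2"] = _glorot(rng, s, 1, (s,))
        p["bs2"] = np.zeros(())
    if config.clustering_weight > 0:
        p["Wi"] = _glorot(rng, l, c, (l, c))
        p["bi"] = np.zeros(c)
    return p


# ---------------------------------------------------------------------------
# elementary operations (forward)


def transform_features(
    X: np.ndarray,
    W1: np.ndarray,
    b1: np.ndarray,
    dropout: float = 0.0,
    train: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Shared FC + ReLU transform, H = relu(X W1 + b1), dropout when training.

    Returns (H, cache) where cache holds what the backward pass needs.
    Inverted dropout (mask scaled by 1/(1-p)) keeps eval and train scales equal.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != W1.shape[0]:
        raise ValueError(f"X shape {X.shape} incompatible with W1 {W1.shape}")
    if not np.isfinite(X).all():
        raise ValueError("input features contain NaN/Inf")
    Z = X @ W1 + b1
    relu_mask = Z > 0
    H = Z * relu_mask
    if train and dropout > 0:
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        drop_mask = (rng.random(H.shape) >= dropout) / (1.0 - dropout)
        H = H * drop_mask
    else:
        drop_mask = None
    return H, {"X": X, "relu_mask": relu_mask, "drop_mask": drop_mask}


def gated_attention_scores(
    H: np.ndarray,
    V: np.ndarray,
    bv: np.ndarray,
    U: np.ndarray,
    bu: np.ndarray,
    w: np.ndarray,
    bw: np.ndarray,
) -> tuple[np.ndarray, dict]:
    """Gated attention: a_i = w^T (tanh(V h_i + bv) * sigmoid(U h_i + bu)) + bw.

    Single branch when V is (A, L) -> scores (N,); per-class branches when
    V is (C, A, L) -> scores (N, C).
    """
    if V.ndim == 2:
        T = np.tanh(H @ V.T + bv)                       # (N, A)
        G = _sigmoid(H @ U.T + bu)
        E = T * G
        a = E @ w + bw
    else:
        T = np.tanh(np.einsum("nl,cal->nca", H, V) + bv)  # (N, C, A)
        G = _sigmoid(np.einsum("nl,cal->nca", H, U) + bu)
        E = T * G
        a = np.einsum("nca,ca->nc", E, w) + bw
    return a, {"T": T, "G": G, "E": E}


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def attention_weights(raw_scores: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the instance axis (axis 0), per column."""
    a = np.asarray(raw_scores, dtype=np.float64)
    a = a - a.max(axis=0, keepdims=True)
    e = np.exp(a)
    return e / e.sum(axis=0, keepdims=True)


def aggregate(H: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted sum of instance rows: (L,) for a weight vector, (C, L) for columns."""
    if weights.ndim == 1:
        return weights @ H
    return np.einsum("nc,nl->cl", weights, H)


def _softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max())
    return e / e.sum()


def dip_select(
    features: np.ndarray,
    Ws1: np.ndarray,
    bs1: np.ndarray,
    Ws2: np.ndarray,
    bs2: np.ndarray,
    top_k: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Score instances with the two-layer perceptron and keep the K best.

    Returns (kept indices in original order, all scores). Ties are broken by
    lower original index; K >= N keeps everything.
    """
    features = np.asarray(features, dtype=np.float64)
    if features.shape[0] < 1:
        raise ValueError("cannot prune an empty bag")
    scores = np.maximum(features @ Ws1 + bs1, 0.0) @ Ws2 + bs2
    order = np.argsort(-scores, kind="stable")[: min(top_k, len(scores))]
    return np.sort(order), scores


def stochastic_sample(
    weights: np.ndarray,
    k: int,
    rng: np.random.Generator,
    replacement: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample k instance indices with probability proportional to their weights.

    Without replacement (the default) the draw is sequential-proportional,
    realized as Gumbel-top-k for O(N log N) determinism under a seeded rng;
    if k >= N every index is returned and the weights are unchanged. The
    returned weights are the sampled weights renormalized to sum 1.
    """
    alpha = np.asarray(weights, dtype=np.float64)
    n = alpha.shape[0]
    if not replacement:
        if k >= n:
            return np.arange(n), alpha  # full bag: weights pass through exactly
        else:
            gumbel = -np.log(-np.log(rng.random(n)))
            keys = np.log(alpha) + gumbel
            idx = np.sort(np.argsort(-keys, kind="stable")[:k])
    else:
        idx = np.sort(rng.choice(n, size=k, replace=True, p=alpha / alpha.sum()))
    sub = alpha[idx]
    return idx, sub / sub.sum()


# ---------------------------------------------------------------------------
# full forward passes


def _as_matrix(bag) -> np.ndarray:
    if isinstance(bag, FeatureBag):
        return np.asarray(bag.features, dtype=np.float64)
    return np.asarray(bag, dtype=np.float64)


def sab_forward(
    bag,
    params: dict[str, np.ndarray],
    config: ModelConfig,
    mode: str = "eval",
    rng: np.random.Generator | None = None,
) -> Prediction:
    """Single-attention-branch forward pass on one bag."""
    pred, _ = _sab_core(_as_matrix(bag), params, config, mode, rng, sample_k=None)
    return pred


def sa_forward(
    bag,
    params: dict[str, np.ndarray],
    config: ModelConfig,
    mode: str = "eval",
    rng: np.random.Generator | None = None,
) -> Prediction:
    """Stochastic-attention forward: samples k instances in training mode,
    reverts to the deterministic SAB computation in evaluation mode."""
    sample_k = config.k if mode == "train" else None
    pred, _ = _sab_core(_as_matrix(bag), params, config, mode, rng, sample_k=sample_k)
    return pred


def dip_forward(
    bag,
    params: dict[str, np.ndarray],
    config: ModelConfig,
    mode: str = "eval",
    rng: np.random.Generator | None = None,
) -> Prediction:
    """Dynamic instance pruning: top-K prefilter, then SAB on the kept subset."""
    X = _as_matrix(bag)
    if config.score_transformed:
        scorer_in, _ = transform_features(X, params["W1"], params["b1"])
    else:
        scorer_in = X
    idx, scores = dip_select(
        scorer_in, params["Ws1"], params["bs1"], params["Ws2"], params["bs2"], config.top_k
    )
    pred, _ = _sab_core(X[idx], params, config, mode, rng, sample_k=None)
    pred.attention.kept_indices = idx
    return pred


def mab_forward(
    bag,
    params: dict[str, np.ndarray],
    config: ModelConfig,
    mode: str = "eval",
    rng: np.random.Generator | None = None,
) -> Prediction:
    """Multi-branch forward: one attention branch and one scalar classifier
    per class, softmax over the C logits."""
    X = _as_matrix(bag)
    if params["V"].ndim != 3 or params["V"].shape[0] != config.n_classes:
        raise ValueError(
            f"MAB needs {config.n_classes} attention branches, got V shape {params['V'].shape}"
        )
    H, _ = transform_features(
        X, params["W1"], params["b1"], config.dropout, mode == "train", rng
    )
    a, _ = gated_attention_scores(
        H, params["V"], params["bv"], params["U"], params["bu"], params["w"], params["bw"]
    )
    alpha = attention_weights(a)                      # (N, C)
    M = aggregate(H, alpha)                           # (C, L)
    logits = np.einsum("cl,cl->c", M, params["Wc"]) + params["bc"]
    probs = _softmax(logits)
    att = AttentionResult(raw_scores=a, weights=alpha, representation=M)
    return Prediction(probs=probs, predicted_class=int(np.argmax(probs)), attention=att)


def _sab_core(
    X: np.ndarray,
    params: dict[str, np.ndarray],
    config: ModelConfig,
    mode: str,
    rng: np.random.Generator | None,
    sample_k: int | None,
) -> tuple[Prediction, dict]:
    """Shared SAB/SA computation; caches every intermediate for backward."""
    train = mode == "train"
    H, tcache = transform_features(
        X, params["W1"], params["b1"], config.dropout, train, rng
    )
    a, acache = gated_attention_scores(
        H, params["V"], params["bv"], params["U"], params["bu"], params["w"], params["bw"]
    )
    alpha = attention_weights(a)
    if sample_k is not None:
        if rng is None:
            raise ValueError("stochastic attention in training mode needs an rng")
        idx, beta = stochastic_sample(alpha, sample_k, rng, config.replacement)
        M = beta @ H[idx]
    else:
        idx, beta = None, None
        M = aggregate(H, alpha)
    logits = M @ params["Wc"] + params["bc"]
    probs = _softmax(logits)
    att = AttentionResult(raw_scores=a, weights=alpha, representation=M,
                          kept_indices=idx)
    pred = Prediction(probs=probs, predicted_class=int(np.argmax(probs)), attention=att)
    cache = {"H": H, "alpha": alpha, "M": M, "probs": probs, "idx": idx, "beta": beta,
             **tcache, **acache}
    return pred, cache


# ---------------------------------------------------------------------------
# losses and analytic gradients


def _cross_entropy(probs: np.ndarray, y: int) -> float:
    return float(-np.log(max(probs[y], 1e-300)))


def _backward_transform(dH: np.ndarray, cache: dict, params: dict,
                        grads: dict) -> None:
    if cache["drop_mask"] is not None:
        dH = dH * cache["drop_mask"]
    dZ = dH * cache["relu_mask"]
    grads["W1"] += cache["X"].T @ dZ
    grads["b1"] += dZ.sum(axis=0)


def _backward_attention_single(da: np.ndarray, cache: dict, params: dict,
                               grads: dict) -> np.ndarray:
    """Gradient of single-branch scores a wrt H and attention params; returns dH."""
    T, G, E, H = cache["T"], cache["G"], cache["E"], cache["H"]
    dE = np.outer(da, params["w"])
    grads["w"] += E.T @ da
    grads["bw"] += da.sum()
    dpre_t = dE * G * (1.0 - T ** 2)
    dpre_g = dE * T * G * (1.0 - G)
    grads["V"] += dpre_t.T @ H
    grads["bv"] += dpre_t.sum(axis=0)
    grads["U"] += dpre_g.T @ H
    grads["bu"] += dpre_g.sum(axis=0)
    return dpre_t @ params["V"] + dpre_g @ params["U"]


def _zero_grads(params: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {k: np.zeros_like(v) for k, v in params.items()}


def _sab_loss_grads(X, y, params, config, mode, rng, sample_k):
    pred, c = _sab_core(X, params, config, mode, rng, sample_k)
    loss = _cross_entropy(pred.probs, y)
    grads = _zero_grads(params)

    dlogits = c["probs"].copy()
    dlogits[y] -= 1.0
    grads["Wc"] += np.outer(c["M"], dlogits)
    grads["bc"] += dlogits
    dM = params["Wc"] @ dlogits                      # (L,)

    H, alpha = c["H"], c["alpha"]
    dH = np.zeros_like(H)
    dalpha = np.zeros_like(alpha)
    if c["idx"] is None:
        dalpha[:] = H @ dM
        dH += np.outer(alpha, dM)
    else:
        idx, beta = c["idx"], c["beta"]
        dbeta = H[idx] @ dM
        dH[idx] += np.outer(beta, dM)
        s = alpha[idx].sum()
        dalpha[idx] = (dbeta - dbeta @ beta) / s
    da = alpha * (dalpha - alpha @ dalpha)           # softmax backward
    dH += _backward_attention_single(da, c, params, grads)

    if config.clustering_weight > 0 and mode == "train":
        loss += _clustering_term(H, alpha, y, params, config, grads, dH)

    _backward_transform(dH, c, params, grads)
    return loss, grads, pred


def _clustering_term(H, alpha, y, params, config, grads, dH) -> float:
    """Optional instance-level clustering loss: the top-attention instances
    are pseudo-labeled with the bag class and pushed through a shared
    instance classifier. Encourages class separation at the instance level;
    off by default because the bag loss alone matches the training protocol."""
    b = min(config.clustering_top, H.shape[0])
    top = np.argsort(-alpha, kind="stable")[:b]
    logits = H[top] @ params["Wi"] + params["bi"]
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    loss = -np.log(np.maximum(p[:, y], 1e-300)).mean()
    dlog = p.copy()
    dlog[:, y] -= 1.0
    dlog *= config.clustering_weight / b
    grads["Wi"] += H[top].T @ dlog
    grads["bi"] += dlog.sum(axis=0)
    dH[top] += dlog @ params["Wi"].T
    return config.clustering_weight * loss


def _mab_loss_grads(X, y, params, config, mode, rng):
    train = mode == "train"
    H, tcache = transform_features(X, params["W1"], params["b1"],
                                   config.dropout, train, rng)
    a, acache = gated_attention_scores(
        H, params["V"], params["bv"], params["U"], params["bu"], params["w"], params["bw"]
    )
    alpha = attention_weights(a)                     # (N, C)
    M = aggregate(H, alpha)                          # (C, L)
    logits = np.einsum("cl,cl->c", M, params["Wc"]) + params["bc"]
    probs = _softmax(logits)
    loss = _cross_entropy(probs, y)
    grads = _zero_grads(params)

    dlogits = probs.copy()
    dlogits[y] -= 1.0
    grads["Wc"] += dlogits[:, None] * M
    grads["bc"] += dlogits
    dM = dlogits[:, None] * params["Wc"]             # (C, L)

    dalpha = np.einsum("cl,nl->nc", dM, H)
    dH = np.einsum("nc,cl->nl", alpha, dM)
    da = alpha * (dalpha - np.einsum("nc,nc->c", alpha, dalpha))

    T, G, E = acache["T"], acache["G"], acache["E"]
    dE = da[:, :, None] * params["w"][None, :, :]
    grads["w"] += np.einsum("nca,nc->ca", E, da)
    grads["bw"] += da.sum(axis=0)
    dpre_t = dE * G * (1.0 - T ** 2)
    dpre_g = dE * T * G * (1.0 - G)
    grads["V"] += np.einsum("nca,nl->cal", dpre_t, H)
    grads["bv"] += dpre_t.sum(axis=0)
    grads["U"] += np.einsum("nca,nl->cal", dpre_g, H)
    grads["bu"] += dpre_g.sum(axis=0)
    dH += np.einsum("nca,cal->nl", dpre_t, params["V"])
    dH += np.einsum("nca,cal->nl", dpre_g, params["U"])

    _backward_transform(dH, {**tcache}, params, grads)
    att = AttentionResult(raw_scores=a, weights=alpha, representation=M)
    pred = Prediction(probs=probs, predicted_class=int(np.argmax(probs)), attention=att)
    return loss, grads, pred


# ---------------------------------------------------------------------------
# the model facade


class MILModel:
    """One MIL architecture with its parameters; batch = one bag.

    >>> model = MILModel(ModelConfig(arch="sab", in_dim=64, n_classes=5), seed=0)
    >>> pred = model.forward(bag)             # doctest: +SKIP
    """

    def __init__(self, config: ModelConfig, seed: int = 0,
                 params: dict[str, np.ndarray] | None = None):
        self.config = config
        self.params = params if params is not None else init_params(config, seed)

    def forward(self, bag, mode: str = "eval",
                rng: np.random.Generator | None = None) -> Prediction:
        fn = {"sab": sab_forward, "mab": mab_forward,
              "dip": dip_forward, "sa": sa_forward}[self.config.arch]
        return fn(bag, self.params, self.config, mode=mode, rng=rng)

    def loss_and_gradients(
        self, bag, y: int, mode: str = "train",
        rng: np.random.Generator | None = None,
    ) -> tuple[float, dict[str, np.ndarray], Prediction]:
        """Bag-level cross-entropy and analytic gradients for every parameter."""
        X = _as_matrix(bag)
        cfg = self.config
        if cfg.arch == "mab":
            return _mab_loss_grads(X, y, self.params, cfg, mode, rng)
        if cfg.arch == "dip":
            if cfg.score_transformed:
                scorer_in, _ = transform_features(X, self.params["W1"], self.params["b1"])
            else:
                scorer_in = X
            idx, _ = dip_select(scorer_in, self.params["Ws1"], self.params["bs1"],
                                self.params["Ws2"], self.params["bs2"], cfg.top_k)
            loss, grads, pred = _sab_loss_grads(X[idx], y, self.params, cfg, mode, rng, None)
            pred.attention.kept_indices = idx
            return loss, grads, pred
        sample_k = cfg.k if (cfg.arch == "sa" and mode == "train") else None
        return _sab_loss_grads(X, y, self.params, cfg, mode, rng, sample_k)


# ---------------------------------------------------------------------------
# checkpoints: npz parameter archive + JSON sidecar


def save_checkpoint(model: MILModel, path: str | Path) -> Path:
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.params)
    meta = {k: v for k, v in vars(model.config).items()}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")
    return path.with_suffix(".npz")


def load_checkpoint(path: str | Path) -> MILModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    known = set(ModelConfig.__dataclass_fields__)
    config = ModelConfig(**{k: v for k, v in meta.items() if k in known})
    with np.load(path.with_suffix(".npz")) as f:
        params = {k: f[k] for k in f.files}
    return MILModel(config, params=params)
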