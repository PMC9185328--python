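"""Fitness evaluation: decode a solution, train a classifier, score it.

The scalar being minimized is ``1 - accuracy`` on the evaluation set.  The
loss function itself is one of the searched hyperparameters, so raw loss
values are not comparable across solutions; accuracy is.

The built-in trainable model, ``toy_cnn``, is a compact CPU-trainable
convolutional network implemented directly on numpy: mean-pool to 32 x 32,
one 3 x 3 convolution (8 filters, ReLU), global average pooling, a 16-unit
ReLU dense layer, dropout, and a K-way softmax head.  It supports the full
menu of searched hyperparameters — six losses, eleven optimizers, dropout,
and the fine-tuning "learn ratio" (the trailing percentage of backbone layers
left trainable, the rest frozen).  Heavier ImageNet-pretrained backbones
(DenseNet201 ... Xception) can be attached through the backbone-builder
registry by a deep-learning backend plugin; they are deliberately not part of
this package's core.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .metrics import ConfusionCounts, full_report
from .preprocessing import DatasetBundle, build_augmenter, scale
from .search_space import (
    HyperparameterConfig,
    SearchSpace,
    build_default_space,
    map_solution,
)

__all__ = [
    "BackboneSpec",
    "TrainConfig",
    "FitnessResult",
    "build_classifier",
    "evaluate_fitness",
    "register_backbone",
    "PRETRAINED_BACKBONES",
]

PRETRAINED_BACKBONES = (
    "DenseNet201",
    "MobileNet",
    "MobileNetV2",
    "MobileNetV3Small",
    "MobileNetV3Large",
    "VGG16",
    "VGG19",
    "Xception",
)

_BACKBONE_BUILDERS: dict[str, Callable] = {}


def register_backbone(name: str):
    """Register a backbone builder ``fn(config, K, train_cfg) -> model``."""

    def deco(fn):
        _BACKBONE_BUILDERS[name] = fn
        return fn

    return deco


@dataclass(frozen=True)
class BackboneSpec:
    """Which network body to train and how it is initialized."""

    name: str = "toy_cnn"
    pretrained_weights: str = "none"  # "imagenet" or "none"

    def __post_init__(self) -> None:
        if self.name == "toy_cnn" and self.pretrained_weights != "none":
            raise ValueError("toy_cnn has no pretrained weights")
        if self.name != "toy_cnn" and self.name not in PRETRAINED_BACKBONES:
            raise ValueError(f"unknown backbone {self.name!r}")


@dataclass
class TrainConfig:
    """Training-run settings independent of the searched hyperparameters."""

    epochs: int = 5
    input_size: tuple[int, int, int] = (128, 128, 3)
    seed: int = 0
    eval_on: str = "full"  # "full", "test" or "validation"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.eval_on not in ("full", "test", "validation", "train"):
            raise ValueError(f"unknown eval_on {self.eval_on!r}")


@dataclass
class FitnessResult:
    """Everything recorded for one evaluated solution."""

    fitness: float
    metric_report: dict[str, float]
    config: HyperparameterConfig
    confusion: ConfusionCounts | None


# ---------------------------------------------------------------------------
# losses: value and gradient with respect to the softmax output p
# ---------------------------------------------------------------------------

_EPS = 1e-9


def _loss_and_grad(name: str, y: np.ndarray, p: np.ndarray):
    """Mean loss over the batch and dL/dp (batch-mean included in the grad)."""
    B, K = y.shape
    pc = np.clip(p, _EPS, 1.0)
    if name in ("Categorical Crossentropy", "KLDivergence"):
        val = float(-(y * np.log(pc)).sum(axis=1).mean())
        if name == "KLDivergence":
            val += float(np.where(y > 0, y * np.log(np.clip(y, _EPS, 1)), 0.0).sum(axis=1).mean())
        grad = -(y / pc) / B
    elif name == "Poisson":
        val = float((p - y * np.log(pc)).mean())
        grad = (1.0 - y / pc) / (B * K)
    elif name == "Hinge":
        yt = 2.0 * y - 1.0
        margin = 1.0 - yt * p
        val = float(np.maximum(0.0, margin).mean())
        grad = np.where(margin > 0, -yt, 0.0) / (B * K)
    elif name == "Squared Hinge":
        yt = 2.0 * y - 1.0
        margin = np.maximum(0.0, 1.0 - yt * p)
        val = float((margin ** 2).mean())
        grad = -2.0 * yt * margin / (B * K)
    elif name == "Categorical Hinge":
        pos = (y * p).sum(axis=1)
        masked = np.where(y == 1, -np.inf, p)
        neg_idx = masked.argmax(axis=1)
        neg = masked[np.arange(B), neg_idx]
        active = (1.0 - pos + neg) > 0
        val = float(np.maximum(0.0, 1.0 - pos + neg).mean())
        grad = np.zeros_like(p)
        grad -= y * active[:, None]
        grad[np.arange(B), neg_idx] += active
        grad /= B
    else:
        raise ValueError(f"unknown loss {name!r}")
    return val, grad


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _grad_through_softmax(p: np.ndarray, dLdp: np.ndarray) -> np.ndarray:
    return p * (dLdp - (dLdp * p).sum(axis=1, keepdims=True))


# ---------------------------------------------------------------------------
# optimizers (per-tensor state; defaults follow common framework settings)
# ---------------------------------------------------------------------------


class Optimizer:
    """Stateful first-order update rules for a list of parameter arrays."""

    #: default step sizes tuned for small networks on desk-scale data;
    #: AdaDelta's effective step is already normalized, so it runs at 1.0
    DEFAULT_LR = {"SGD": 0.05, "SGD Nesterov": 0.05, "AdaDelta": 1.0}

    def __init__(self, name: str, lr: float | None = None):
        self.name = name
        base_lr = self.DEFAULT_LR.get(name, 0.01)
        self.lr = base_lr if lr is None else lr
        self.t = 0
        self.state: dict[int, dict[str, np.ndarray]] = {}
        if name not in _OPTIMIZER_RULES:
            raise ValueError(f"unknown optimizer {name!r}")

    def _slot(self, i: int, key: str, like: np.ndarray, fill: float = 0.0) -> np.ndarray:
        slots = self.state.setdefault(i, {})
        if key not in slots:
            slots[key] = np.full_like(like, fill)
        return slots[key]

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        rule = _OPTIMIZER_RULES[self.name]
        for i, (w, g) in enumerate(zip(params, grads)):
            if g is None:
                continue
            rule(self, i, w, g)


def _sgd(o: Optimizer, i, w, g):
    w -= o.lr * g


def _sgd_nesterov(o: Optimizer, i, w, g, momentum=0.9):
    v = o._slot(i, "v", w)
    v *= momentum
    v -= o.lr * g
    w += momentum * v - o.lr * g


def _rmsprop(o: Optimizer, i, w, g, rho=0.9, eps=1e-7):
    s = o._slot(i, "s", w)
    s *= rho
    s += (1 - rho) * g * g
    w -= o.lr * g / (np.sqrt(s) + eps)


def _rmsprop_centered(o: Optimizer, i, w, g, rho=0.9, eps=1e-7):
    s = o._slot(i, "s", w)
    m = o._slot(i, "m", w)
    s *= rho
    s += (1 - rho) * g * g
    m *= rho
    m += (1 - rho) * g
    w -= o.lr * g / (np.sqrt(s - m * m + eps))


def _adagrad(o: Optimizer, i, w, g, eps=1e-7):
    a = o._slot(i, "a", w, fill=0.1)
    a += g * g
    w -= o.lr * g / (np.sqrt(a) + eps)


def _adadelta(o: Optimizer, i, w, g, rho=0.95, eps=1e-7):
    a = o._slot(i, "a", w)
    d = o._slot(i, "d", w)
    a *= rho
    a += (1 - rho) * g * g
    update = np.sqrt(d + eps) / np.sqrt(a + eps) * g
    d *= rho
    d += (1 - rho) * update * update
    w -= o.lr * update


def _adam_core(o: Optimizer, i, w, g, b1=0.9, b2=0.999, eps=1e-7,
               amsgrad=False, nesterov=False):
    m = o._slot(i, "m", w)
    v = o._slot(i, "v", w)
    m *= b1
    m += (1 - b1) * g
    v *= b2
    v += (1 - b2) * g * g
    mhat = m / (1 - b1 ** o.t)
    vhat = v / (1 - b2 ** o.t)
    if amsgrad:
        vmax = o._slot(i, "vmax", w)
        np.maximum(vmax, vhat, out=vmax)
        vhat = vmax
    if nesterov:
        mhat = b1 * mhat + (1 - b1) * g / (1 - b1 ** o.t)
    w -= o.lr * mhat / (np.sqrt(vhat) + eps)


def _adamax(o: Optimizer, i, w, g, b1=0.9, b2=0.999, eps=1e-7):
    m = o._slot(i, "m", w)
    u = o._slot(i, "u", w)
    m *= b1
    m += (1 - b1) * g
    np.maximum(b2 * u, np.abs(g), out=u)
    w -= o.lr / (1 - b1 ** o.t) * m / (u + eps)


def _ftrl(o: Optimizer, i, w, g, lr_power=-0.5, l1=0.0, l2=0.0):
    n = o._slot(i, "n", w, fill=0.1)
    z = o._slot(i, "z", w)
    n_new = n + g * g
    sigma = (n_new ** -lr_power - n ** -lr_power) / o.lr
    z += g - sigma * w
    n[:] = n_new
    quad = n ** -lr_power / o.lr + 2 * l2
    w[:] = np.where(
        np.abs(z) > l1, -(z - np.sign(z) * l1) / quad, 0.0
    )


_OPTIMIZER_RULES = {
    "SGD": _sgd,
    "SGD Nesterov": _sgd_nesterov,
    "RMSProp": _rmsprop,
    "RMSProp Centered": _rmsprop_centered,
    "AdaGrad": _adagrad,
    "AdaDelta": _adadelta,
    "AdaMax": _adamax,
    "Ftrl": _ftrl,
    "Adam": lambda o, i, w, g: _adam_core(o, i, w, g),
    "Adam AMSGrad": lambda o, i, w, g: _adam_core(o, i, w, g, amsgrad=True),
    "NAdam": lambda o, i, w, g: _adam_core(o, i, w, g, nesterov=True),
}


# ---------------------------------------------------------------------------
# the toy convolutional network
# ---------------------------------------------------------------------------


class ToyCNN:
    """Mean-pool -> conv 3x3 (8 filters, ReLU) -> GAP -> dense 16 -> softmax K.

    The convolution and the 16-unit dense layer form the "backbone"; the
    softmax head is always trainable.  ``tl_learn_ratio`` percent of the
    backbone layers, counted from the output end and rounded (never below
    one trainable layer overall), stay trainable; the rest are frozen.
    """

    POOLED = 32
    FILTERS = 8
    HIDDEN = 16
    BN_MOMENTUM = 0.9

    def __init__(self, K: int, config: HyperparameterConfig, seed: int = 0,
                 in_channels: int = 3):
        if K < 2:
            raise ValueError("K must be >= 2")
        self.K = K
        self.config = config
        rng = np.random.default_rng(seed)
        c = in_channels
        k = 3
        fan_conv = k * k * c
        self.W1 = rng.normal(0.0, np.sqrt(2.0 / fan_conv), (fan_conv, self.FILTERS))
        self.b1 = np.zeros(self.FILTERS)
        self.W2 = rng.normal(0.0, np.sqrt(2.0 / self.FILTERS), (self.FILTERS, self.HIDDEN))
        self.b2 = np.zeros(self.HIDDEN)
        self.W3 = rng.normal(0.0, np.sqrt(2.0 / self.HIDDEN), (self.HIDDEN, K))
        self.b3 = np.zeros(K)
        self.run_mu = np.zeros(self.FILTERS)
        self.run_var = np.ones(self.FILTERS)
        self._bn_ready = False
        self.rng = rng
        self.optimizer = Optimizer(config.optimizer_name)
        # backbone layers, input to output: conv (W1), dense (W2); at least
        # one stays trainable even at the smallest learn ratio
        n_backbone = 2
        n_trainable = min(n_backbone, max(1, round(config.tl_learn_ratio / 100 * n_backbone)))
        self.train_conv = n_trainable >= 2
        self.train_dense = n_trainable >= 1

    # -- plumbing -----------------------------------------------------------

    def _pool(self, X: np.ndarray) -> np.ndarray:
        B, H, W, C = X.shape
        fh, fw = max(1, H // self.POOLED), max(1, W // self.POOLED)
        Hp, Wp = H // fh, W // fw
        X = X[:, : Hp * fh, : Wp * fw]
        return X.reshape(B, Hp, fh, Wp, fw, C).mean(axis=(2, 4))

    def _im2col(self, P: np.ndarray) -> np.ndarray:
        B, H, W, C = P.shape
        k = 3
        Ho, Wo = H - k + 1, W - k + 1
        s = P.strides
        windows = np.lib.stride_tricks.as_strided(
            P, (B, Ho, Wo, k, k, C), (s[0], s[1], s[2], s[1], s[2], s[3])
        )
        return windows.reshape(B, Ho, Wo, k * k * C), (Ho, Wo)

    def _forward(self, X: np.ndarray, train: bool = False):
        cache: dict[str, np.ndarray] = {}
        P = self._pool(X)
        cols, (Ho, Wo) = self._im2col(P)
        conv = cols @ self.W1 + self.b1
        relu1 = np.maximum(conv, 0.0)
        raw = relu1.mean(axis=(1, 2))  # global average pool
        # batch standardization of the pooled features (no learned affine):
        # the across-image variation of GAP responses is orders of magnitude
        # smaller than their per-filter baselines, so each feature is centered
        # and rescaled across the batch; inference uses running statistics
        if train:
            mu = raw.mean(axis=0)
            var = raw.var(axis=0)
            if not self._bn_ready:
                # seed the running statistics from the first batch: the raw
                # GAP variances are orders of magnitude below 1, so a (0, 1)
                # start would squash evaluation-time features for many steps
                self.run_mu[:] = mu
                self.run_var[:] = var
                self._bn_ready = True
            else:
                self.run_mu += (1.0 - self.BN_MOMENTUM) * (mu - self.run_mu)
                self.run_var += (1.0 - self.BN_MOMENTUM) * (var - self.run_var)
        else:
            mu, var = self.run_mu, self.run_var
        sigma = np.sqrt(var + 1e-8)
        feats = (raw - mu) / sigma
        h = np.maximum(feats @ self.W2 + self.b2, 0.0)
        if train and self.config.dropout > 0.0:
            mask = (self.rng.random(h.shape) >= self.config.dropout) / (
                1.0 - self.config.dropout
            )
        else:
            mask = np.ones_like(h)
        hd = h * mask
        logits = hd @ self.W3 + self.b3
        probs = _softmax(logits)
        cache.update(
            cols=cols, relu1=relu1, feats=feats, sigma=sigma, h=h, mask=mask,
            hd=hd, probs=probs, hw=np.array([Ho, Wo]),
        )
        return probs, cache

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(X, dtype=float), train=False)[0]

    def train_batch(self, X: np.ndarray, y_onehot: np.ndarray) -> float:
        probs, c = self._forward(np.asarray(X, dtype=float), train=True)
        val, dLdp = _loss_and_grad(self.config.loss_name, y_onehot, probs)
        if not np.isfinite(val):
            return val
        dlogits = _grad_through_softmax(probs, dLdp)
        gW3 = c["hd"].T @ dlogits
        gb3 = dlogits.sum(axis=0)
        dh = (dlogits @ self.W3.T) * c["mask"] * (c["h"] > 0)
        gW2 = gb2 = None
        dfeats = dh @ self.W2.T
        if self.train_dense:
            gW2 = c["feats"].T @ dh
            gb2 = dh.sum(axis=0)
        gW1 = gb1 = None
        if self.train_conv:
            Ho, Wo = c["hw"]
            # back through the batch standardization, then the pooling
            fhat = c["feats"]
            draw = (
                dfeats
                - dfeats.mean(axis=0)
                - fhat * (dfeats * fhat).mean(axis=0)
            ) / c["sigma"]
            drelu = (
                draw[:, None, None, :] / (Ho * Wo) * (c["relu1"] > 0)
            )
            gW1 = np.tensordot(c["cols"], drelu, axes=([0, 1, 2], [0, 1, 2]))
            gb1 = drelu.sum(axis=(0, 1, 2))
        params = [self.W3, self.b3]
        grads = [gW3, gb3]
        if self.train_dense:
            params += [self.W2, self.b2]
            grads += [gW2, gb2]
        if self.train_conv:
            params += [self.W1, self.b1]
            grads += [gW1, gb1]
        self.optimizer.step(params, grads)
        return val

    @property
    def trainable_layers(self) -> int:
        """Backbone layers left trainable (the softmax head is always on)."""
        return int(self.train_conv) + int(self.train_dense)


def build_classifier(
    backbone: BackboneSpec | str,
    config: HyperparameterConfig,
    K: int,
    train_cfg: TrainConfig | None = None,
):
    """Instantiate a trainable classifier for ``K`` classes.

    ``toy_cnn`` is built in; any registered backbone builder is dispatched
    to, and unregistered pretrained names raise with a pointer to the
    registry.
    """
    if isinstance(backbone, str):
        backbone = BackboneSpec(name=backbone)
    if K < 2:
        raise ValueError("K must be >= 2")
    train_cfg = train_cfg or TrainConfig()
    if backbone.name == "toy_cnn":
        return ToyCNN(K, config, seed=train_cfg.seed,
                      in_channels=train_cfg.input_size[2])
    if backbone.name in _BACKBONE_BUILDERS:
        return _BACKBONE_BUILDERS[backbone.name](config, K, train_cfg)
    raise NotImplementedError(
        f"backbone {backbone.name!r} has no registered builder; "
        "register one with troposearch.fitness.register_backbone"
    )


# ---------------------------------------------------------------------------
# fitness evaluation
# ---------------------------------------------------------------------------


def _stack_scaled(images: list[np.ndarray], technique: str) -> np.ndarray:
    out = []
    for img in images:
        try:
            out.append(scale(img, technique))
        except ValueError:  # degenerate image (constant); pass through unscaled
            out.append(np.asarray(img, dtype=float))
    return np.stack(out)


def evaluate_fitness(
    solution,
    bundle: DatasetBundle,
    backbone: BackboneSpec | str = "toy_cnn",
    train_cfg: TrainConfig | None = None,
    space: SearchSpace | None = None,
) -> FitnessResult:
    """Decode, train for the configured epochs, and score one solution.

    Training uses the split's train images, scaled with the decoded technique
    and streamed through the class-balancing augmenter; fitness is
    ``1 - accuracy`` on the evaluation set (the full dataset by default, or
    the held-out test split with ``eval_on="test"``).  Training divergence
    (non-finite loss) returns an ``inf`` fitness sentinel.
    """
    train_cfg = train_cfg or TrainConfig()
    space = space or build_default_space()
    config = map_solution(solution, space)
    rng = np.random.default_rng(train_cfg.seed)

    train_part = bundle.split_part("train") if bundle.split is not None else bundle
    model = build_classifier(backbone, config, bundle.n_classes, train_cfg)
    augmenter = build_augmenter(config, seed=train_cfg.seed)

    K = bundle.n_classes
    eye = np.eye(K)
    diverged = False
    for _ in range(train_cfg.epochs):
        images, labels = augmenter.balanced_epoch(train_part.images, train_part.labels)
        Xs = _stack_scaled(images, config.scaling_technique)
        order = rng.permutation(len(labels))
        for start in range(0, len(order), config.batch_size):
            sel = order[start : start + config.batch_size]
            loss = model.train_batch(Xs[sel], eye[labels[sel]])
            if not np.isfinite(loss):
                diverged = True
                break
        if diverged:
            break

    if diverged:
        return FitnessResult(
            fitness=float("inf"), metric_report={}, config=config, confusion=None
        )

    if train_cfg.eval_on == "full" or bundle.split is None:
        eval_part = bundle
    else:
        eval_part = bundle.split_part(train_cfg.eval_on)
    Xe = _stack_scaled(eval_part.images, config.scaling_technique)
    probs = model.predict_proba(Xe)
    report, confusion = full_report(eval_part.labels, probs, K)
    accuracy = float((probs.argmax(axis=1) == eval_part.labels).mean())
    report["Loss"] = _loss_and_grad(
        config.loss_name, eye[eval_part.labels], np.clip(probs, _EPS, 1.0)
    )[0]
    return FitnessResult(
        fitness=1.0 - accuracy, metric_report=report, config=config,
        confusion=confusion,
    )
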