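"""The two U-net architectures, their losses, and member training.

Two variants are built from one parameterization:

* ``multi_unet`` — the ensemble member: five encoder levels of two zero-padded
  3x3 convolutions with leaky-ReLU, 2x2 max pooling between levels, channel
  dropout at the deepest level, a decoder of 2x nearest-neighbor upsampling +
  skip concatenation + two convolutions, and a final 1-filter convolution with
  a sigmoid that assigns each pixel a lesion probability.  Filter counts follow
  2^(base + layer); trained with RMSprop on the negative soft Dice loss,
  LeCun-uniform initialization.
* ``original_unet`` — the classic comparator: identical topology but unpadded
  ('valid') convolutions, so skip tensors must be center-cropped before
  concatenation and the output grid is smaller than the input; two-channel
  softmax output trained with categorical cross-entropy and momentum SGD,
  Xavier-normal initialization.

Everything runs on the pure-NumPy engine in :mod:`busseg.nn`; a desk-scale
profile (64x64 input, base 2, depth 4) makes CPU training of a full ensemble
feasible in minutes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .nn import Conv2D, LeakyReLU, MaxPool2, Upsample2, ChannelDropout, make_optimizer

__all__ = [
    "NetworkConfig",
    "ProbabilityMap",
    "UNet",
    "build_network",
    "soft_dice_loss",
    "train_member",
    "predict",
    "UNetSegmenter",
]


@dataclass(frozen=True)
class NetworkConfig:
    """All architecture and training hyperparameters of one U-net.

    Defaults are the full-scale ensemble-member settings (208x208 input, base
    exponent 5 so encoder level L has 2^(5+L) filters, dropout 0.6, RMSprop at
    5e-6 on negative Dice).  Use :meth:`original_unet` for the comparator and
    :meth:`scale_profile` for the CPU-sized test profile.
    """

    variant: str = "multi_unet"  # "multi_unet" | "original_unet"
    depth: int = 5
    filter_exponent_base: int = 5
    input_size: int = 208
    conv_size: int = 3
    conv_stride: int = 1
    padding_mode: str = "zero"  # "zero" | "none"
    pool_size: int = 2
    dropout_rate: float = 0.6
    upsample_size: int = 2
    crop_per_edge_by_layer: tuple[int, ...] | None = None
    optimizer: str = "rmsprop"  # "rmsprop" | "sgd"
    learning_rate: float = 5e-6
    sgd_momentum: float = 0.99
    loss: str = "negative_dice"  # "negative_dice" | "categorical_crossentropy"
    init: str = "lecun_uniform"  # "lecun_uniform" | "xavier_normal"
    leaky_slope: float = 0.01
    dice_smooth: float = 1.0
    epochs: int = 50
    batch_size: int = 8
    patience: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in ("multi_unet", "original_unet"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "multi_unet":
            if self.crop_per_edge_by_layer is not None:
                raise ValueError("crop_per_edge_by_layer applies only to original_unet")
            step = 2 ** (self.depth - 1)
            if self.input_size % step != 0:
                raise ValueError(
                    f"input_size {self.input_size} not divisible by {step} "
                    f"({self.depth - 1} poolings)"
                )
        if self.leaky_slope <= 0:
            raise ValueError("leaky_slope must be > 0")
        if self.dice_smooth <= 0:
            raise ValueError("dice_smooth must be > 0")

    def filters(self, level: int) -> int:
        """Filter count of encoder level ``level`` (1-based): 2^(base+level)."""
        return 2 ** (self.filter_exponent_base + level)

    @classmethod
    def multi_unet(cls, **overrides) -> "NetworkConfig":
        return cls(**overrides)

    @classmethod
    def original_unet(cls, **overrides) -> "NetworkConfig":
        defaults = dict(
            variant="original_unet",
            input_size=572,
            padding_mode="none",
            dropout_rate=0.5,
            crop_per_edge_by_layer=(88, 40, 16, 4),
            optimizer="sgd",
            learning_rate=0.01,  # unstated; momentum 0.99 is prescribed
            loss="categorical_crossentropy",
            init="xavier_normal",
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def scale_profile(cls, variant: str = "multi_unet", **overrides) -> "NetworkConfig":
        """Desk-scale profile for CPU training: 64x64 input, base 2, depth 4.

        The learning rate is 5e-4 — half the common RMSprop framework
        default: the full-scale 5e-6 rate is tied to long training on a
        large clinical set and does not move a phantom-scale model in this
        epoch budget, while the 1e-3 default makes soft-Dice training
        collapse into the all-background minimum for a noticeable fraction
        of initializations.  The epoch budget (12, patience 4) reflects that
        phantom training converges within ~5 epochs at this rate and keeps a
        ten-member ensemble trainable on one CPU in minutes.
        """
        if variant == "multi_unet":
            defaults = dict(
                input_size=64, depth=4, filter_exponent_base=2,
                learning_rate=5e-4, epochs=12, patience=4, batch_size=8,
            )
        elif variant == "original_unet":
            # 108 is the smallest unpadded-friendly input near the profile;
            # every conv/pool grid propagates to an integer (output 20x20)
            defaults = dict(
                variant="original_unet", input_size=108, depth=4,
                filter_exponent_base=2, padding_mode="none",
                dropout_rate=0.5, crop_per_edge_by_layer=None,
                optimizer="sgd", learning_rate=0.01,
                loss="categorical_crossentropy", init="xavier_normal",
                epochs=12, patience=4, batch_size=8,
            )
        else:
            raise ValueError(f"unknown variant {variant!r}")
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class ProbabilityMap:
    """Per-pixel lesion probability from one network."""

    pixels: np.ndarray
    model_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("probability map must be 2-D")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")


def _propagate_shapes(config: NetworkConfig) -> dict:
    """Static shape propagation; raises on the first non-integral grid."""
    pad = config.padding_mode == "zero"
    loss_conv = 0 if pad else 2 * (config.conv_size // 2)
    s = config.input_size
    enc = []
    for level in range(1, config.depth + 1):
        s_in = s
        s = s - 2 * loss_conv  # two convolutions
        if s < 1:
            raise ValueError(f"encoder level {level}: grid collapsed to {s}")
        enc.append({"level": level, "in": s_in, "out": s,
                    "filters": config.filters(level)})
        if level < config.depth:
            if s % 2 != 0:
                raise ValueError(
                    f"encoder level {level}: grid {s}x{s} not divisible by 2 "
                    "for max pooling"
                )
            s //= 2
    dec = []
    crops = []
    for level in range(config.depth - 1, 0, -1):
        s *= 2  # upsample
        skip = enc[level - 1]["out"]
        crop = (skip - s) // 2
        if skip - 2 * crop != s or crop < 0:
            raise ValueError(
                f"decoder level {level}: skip grid {skip} cannot be cropped to {s}"
            )
        crops.append(crop)
        s_in = s
        s = s - 2 * loss_conv
        dec.append({"level": level, "in": s_in, "out": s, "crop": crop,
                    "filters": config.filters(level)})
    if pad and any(c != 0 for c in crops):
        raise AssertionError("zero padding must align skips exactly")
    crops_by_layer = tuple(reversed(crops))  # indexed by encoder layer 1..depth-1
    if config.crop_per_edge_by_layer is not None:
        if tuple(config.crop_per_edge_by_layer) != crops_by_layer:
            raise ValueError(
                f"configured crops {config.crop_per_edge_by_layer} disagree with "
                f"shape propagation {crops_by_layer}"
            )
    return {
        "encoder": enc,
        "decoder": dec,
        "bottleneck": enc[-1]["out"],
        "output_size": s,
        "crops_by_layer": crops_by_layer,
    }


class UNet:
    """A built U-net: layers, forward/backward, weight (de)serialization."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator | None = None):
        self.config = config
        self.shapes = _propagate_shapes(config)
        rng = rng or np.random.default_rng(config.rng_seed)
        pad = "same" if config.padding_mode == "zero" else "valid"
        k = config.conv_size
        D = config.depth
        mk = lambda cin, cout, name: Conv2D(
            cin, cout, k=k, padding=pad, init=config.init, rng=rng, name=name
        )
        act = lambda: LeakyReLU(config.leaky_slope)

        self.enc = []
        cin = 1
        for level in range(1, D + 1):
            f = config.filters(level)
            self.enc.append(
                {
                    "conv1": mk(cin, f, f"enc{level}a"), "act1": act(),
                    "conv2": mk(f, f, f"enc{level}b"), "act2": act(),
                    "pool": MaxPool2(name=f"pool{level}") if level < D else None,
                }
            )
            cin = f
        self.dropout = ChannelDropout(config.dropout_rate, rng=rng)

        self.dec = []
        for level in range(D - 1, 0, -1):
            f = config.filters(level)
            f_up = config.filters(level + 1)
            self.dec.append(
                {
                    "level": level,
                    "up": Upsample2(),
                    "conv1": mk(f + f_up, f, f"dec{level}a"), "act1": act(),
                    "conv2": mk(f, f, f"dec{level}b"), "act2": act(),
                }
            )
        out_ch = 1 if config.loss == "negative_dice" else 2
        self.out_channels = out_ch
        self.final = Conv2D(config.filters(1), out_ch, k=1, padding="valid",
                            init=config.init, rng=rng, name="final")

    # -- plumbing ---------------------------------------------------------

    def params(self):
        out = []
        for blk in self.enc:
            out += blk["conv1"].params() + blk["conv2"].params()
        for blk in self.dec:
            out += blk["conv1"].params() + blk["conv2"].params()
        out += self.final.params()
        return out

    def get_weights(self) -> list[np.ndarray]:
        return [w.copy() for w, _ in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        own = self.params()
        if len(own) != len(weights):
            raise ValueError("weight list length mismatch")
        for (w, _), new in zip(own, weights):
            w[...] = new

    # -- forward / backward ----------------------------------------------

    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """(N, H, W) standardized images -> (N, h, w, out_channels) logits."""
        x = np.ascontiguousarray(x, dtype=np.float32)[..., None]
        if x.shape[1] != self.config.input_size or x.shape[2] != self.config.input_size:
            raise ValueError(
                f"input grid {x.shape[1:3]} does not match configured "
                f"input_size {self.config.input_size}"
            )
        skips = []
        D = self.config.depth
        for level, blk in enumerate(self.enc, start=1):
            x = blk["act1"].forward(blk["conv1"].forward(x, training), training)
            x = blk["act2"].forward(blk["conv2"].forward(x, training), training)
            if level < D:
                skips.append(x)
                x = blk["pool"].forward(x, training)
        x = self.dropout.forward(x, training)
        self._crop_records = []
        for blk in self.dec:
            x = blk["up"].forward(x, training)
            s = skips[blk["level"] - 1]
            crop = (s.shape[1] - x.shape[1]) // 2
            if crop:
                s_c = s[:, crop:-crop, crop:-crop, :]
            else:
                s_c = s
            self._crop_records.append((crop, s.shape))
            x = np.concatenate([s_c, x], axis=-1)
            x = blk["act1"].forward(blk["conv1"].forward(x, training), training)
            x = blk["act2"].forward(blk["conv2"].forward(x, training), training)
        return self.final.forward(x, training)

    def backward(self, dz: np.ndarray) -> None:
        """Backpropagate loss gradient w.r.t. logits; fills layer .gW/.gb."""
        D = self.config.depth
        d = self.final.backward(dz)
        dskips: dict[int, np.ndarray] = {}
        for blk, (crop, s_shape) in zip(reversed(self.dec), reversed(self._crop_records)):
            d = blk["conv1"].backward(blk["act1"].backward(
                blk["conv2"].backward(blk["act2"].backward(d))))
            f_skip = s_shape[-1]
            ds_c, d = d[..., :f_skip], d[..., f_skip:]
            if crop:
                ds = np.zeros(s_shape, dtype=np.float32)
                ds[:, crop:-crop, crop:-crop, :] = ds_c
            else:
                ds = ds_c
            dskips[blk["level"]] = ds
            d = blk["up"].backward(d)
        d = self.dropout.backward(d)
        for level in range(D, 0, -1):
            blk = self.enc[level - 1]
            if level < D:
                d = blk["pool"].backward(d) + dskips[level]
            d = blk["conv1"].backward(blk["act1"].backward(
                blk["conv2"].backward(blk["act2"].backward(d))))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """(N, H, W) -> (N, h, w) per-pixel lesion probability (inference mode)."""
        z = self.forward_logits(x, training=False)
        if self.out_channels == 1:
            return _sigmoid(z[..., 0])
        p = _softmax(z)
        return p[..., 1]

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        path = Path(path)
        cfg = asdict(self.config)
        if cfg["crop_per_edge_by_layer"] is not None:
            cfg["crop_per_edge_by_layer"] = list(cfg["crop_per_edge_by_layer"])
        arrays = {f"w{i}": w for i, (w, _) in enumerate(self.params())}
        np.savez(path, __config__=json.dumps(cfg), **arrays)

    @classmethod
    def load(cls, path) -> "UNet":
        with np.load(path, allow_pickle=False) as data:
            cfg = json.loads(str(data["__config__"]))
            if cfg.get("crop_per_edge_by_layer") is not None:
                cfg["crop_per_edge_by_layer"] = tuple(cfg["crop_per_edge_by_layer"])
            model = cls(NetworkConfig(**cfg))
            model.set_weights([data[f"w{i}"] for i in range(len(model.params()))])
        return model


def build_network(config: NetworkConfig, rng: np.random.Generator | None = None) -> UNet:
    """Build (and shape-validate) a network from its configuration."""
    return UNet(config, rng=rng)


# -- losses ---------------------------------------------------------------


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def soft_dice_loss(prediction, truth, smooth: float = 1.0) -> float:
    """Negative soft Dice: -(2*sum(p*g) + smooth) / (sum(p) + sum(g) + smooth).

    Always <= 0; approaches -1 for perfect overlap as smooth -> 0.  The
    smoothing term keeps the loss finite (and the gradient informative) on
    empty masks.
    """
    p = np.asarray(getattr(prediction, "pixels", prediction), dtype=np.float64)
    g = np.asarray(getattr(truth, "pixels", truth), dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    if smooth <= 0:
        raise ValueError("smooth must be > 0")
    num = 2.0 * float((p * g).sum()) + smooth
    den = float(p.sum()) + float(g.sum()) + smooth
    return -num / den


def _neg_dice_loss_and_grad(p: np.ndarray, g: np.ndarray, smooth: float):
    """Batched negative soft Dice (mean over samples) and dL/dp."""
    n = p.shape[0]
    axes = tuple(range(1, p.ndim))
    num = 2.0 * (p * g).sum(axis=axes) + smooth
    den = p.sum(axes) + g.sum(axes) + smooth
    loss = float(np.mean(-num / den))
    sh = (n,) + (1,) * (p.ndim - 1)
    dp = -(2.0 * g * den.reshape(sh) - num.reshape(sh)) / (den.reshape(sh) ** 2) / n
    return loss, dp


def _cce_loss_and_grad(z: np.ndarray, g: np.ndarray):
    """Softmax + categorical cross-entropy on logits z (N,h,w,2), g binary."""
    p = _softmax(z)
    n_pix = g.size
    y1 = g.astype(np.float64)
    eps = 1e-12
    loss = float(-(y1 * np.log(p[..., 1] + eps)
                   + (1 - y1) * np.log(p[..., 0] + eps)).sum() / n_pix)
    y = np.stack([1 - y1, y1], axis=-1)
    dz = (p - y) / n_pix
    return loss, dz.astype(np.float32)


# -- training -------------------------------------------------------------


def _check_disjoint(train_ids, val_ids) -> None:
    overlap = set(train_ids) & set(val_ids)
    if overlap:
        raise ValueError(
            f"training and validation sets share patients: {sorted(overlap)[:5]}"
        )


def _center_crop(m: np.ndarray, size: int) -> np.ndarray:
    c = (m.shape[-1] - size) // 2
    return m[..., c : c + size, c : c + size] if c else m


def _val_dice(model: UNet, xv: np.ndarray, yv: np.ndarray, batch: int = 8) -> float:
    out = model.shapes["output_size"]
    scores = []
    for i in range(0, len(xv), batch):
        probs = model.predict_proba(xv[i : i + batch])
        preds = probs >= 0.5
        truths = _center_crop(yv[i : i + batch], out).astype(bool)
        for p, t in zip(preds, truths):
            denom = p.sum() + t.sum()
            scores.append(1.0 if denom == 0 else 2.0 * (p & t).sum() / denom)
    return float(np.mean(scores))


def train_member(
    model: UNet,
    train_set: list[tuple[np.ndarray, np.ndarray, str]],
    validation_set: list[tuple[np.ndarray, np.ndarray, str]],
    config: NetworkConfig | None = None,
    rng_seed: int = 0,
    augment_config=None,
) -> dict:
    """Train one U-net member; returns its history, leaves best weights set.

    ``train_set``/``validation_set`` are lists of (standardized image, binary
    mask, patient_id) triples on the network's input grid; they must be
    disjoint by patient.  Optimizes the configured loss, records validation
    Dice each epoch, stops early after ``patience`` epochs without
    improvement, and restores the best-validation weight snapshot.
    ``augment_config`` (a :class:`busseg.preprocess.PreprocessConfig`) turns
    on the two ultrasound-safe augmentations during training.
    """
    from . import preprocess as _pp

    config = config or model.config
    if not train_set:
        raise ValueError("empty training set")
    if not validation_set:
        raise ValueError("empty validation set")
    _check_disjoint([t[2] for t in train_set], [t[2] for t in validation_set])

    rng = np.random.default_rng(rng_seed)
    model.dropout.rng = rng  # dropout draws come from the training stream
    opt = make_optimizer(config.optimizer, config.learning_rate, config.sgd_momentum)
    out_size = model.shapes["output_size"]

    xs = np.stack([np.asarray(t[0], dtype=np.float32) for t in train_set])
    ys = np.stack([np.asarray(t[1], dtype=np.float32) for t in train_set])
    xv = np.stack([np.asarray(t[0], dtype=np.float32) for t in validation_set])
    yv = np.stack([np.asarray(t[1], dtype=np.float32) for t in validation_set])

    history = {"epoch": [], "train_loss": [], "val_dice": [], "restarts": []}
    best = (-np.inf, model.get_weights())
    stale = 0
    restarts = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(xs))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            if augment_config is not None:
                pairs = [
                    _pp.augment(xs[i], ys[i], augment_config, rng) for i in idx
                ]
                xb = np.stack([p[0] for p in pairs]).astype(np.float32)
                yb = np.stack([p[1] for p in pairs]).astype(np.float32)
            else:
                xb, yb = xs[idx], ys[idx]
            yb = _center_crop(yb, out_size)
            z = model.forward_logits(xb, training=True)
            if config.loss == "negative_dice":
                p = _sigmoid(z[..., 0])
                loss, dp = _neg_dice_loss_and_grad(p, yb.astype(np.float64),
                                                   config.dice_smooth)
                dz = (dp * p * (1.0 - p)).astype(np.float32)[..., None]
            else:
                loss, dz = _cce_loss_and_grad(z.astype(np.float64), yb)
            model.backward(dz)
            opt.step(model.params())
            losses.append(loss)
        vd = _val_dice(model, xv, yv, batch=config.batch_size)
        history["epoch"].append(epoch)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_dice"].append(vd)
        if epoch >= 1 and max(best[0], vd) <= 0.0 and restarts < 2:
            # soft-Dice training has fallen into the degenerate all-background
            # minimum (saturated sigmoid, no recoverable gradient): reseed
            restarts += 1
            history["restarts"].append(epoch)
            reinit_seed = (rng_seed + 7919 * restarts) % (2**31 - 1)
            fresh = UNet(model.config, rng=np.random.default_rng(reinit_seed))
            model.set_weights(fresh.get_weights())
            opt = make_optimizer(config.optimizer, config.learning_rate,
                                 config.sgd_momentum)
            best = (-np.inf, model.get_weights())
            stale = 0
            continue
        if vd > best[0]:
            best = (vd, model.get_weights())
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    model.set_weights(best[1])
    history["best_val_dice"] = best[0]
    return history


def predict(model: UNet, image: np.ndarray, model_id: str = "") -> ProbabilityMap:
    """Inference on one standardized image; dropout disabled, deterministic."""
    arr = np.asarray(image, dtype=np.float32)
    if arr.ndim != 2:
        raise ValueError("predict expects a single 2-D image")
    probs = model.predict_proba(arr[None])[0]
    return ProbabilityMap(probs, model_id=model_id)


# -- estimator surface ----------------------------------------------------


class UNetSegmenter(BaseEstimator):
    """Scikit-learn-style wrapper around one U-net.

    Parameters mirror :class:`NetworkConfig`; ``config`` may supply a complete
    configuration directly (it wins over the keyword defaults).  ``fit`` takes
    ``X`` of shape (n, H, W) — standardized images on the configured input
    grid — and binary masks ``y`` of the same shape.
    """

    def __init__(self, config: NetworkConfig | None = None, augment: bool = True,
                 random_state: int = 0):
        self.config = config
        self.augment = augment
        self.random_state = random_state

    def _resolved_config(self) -> NetworkConfig:
        return self.config if self.config is not None else NetworkConfig()

    def fit(self, X, y, patient_ids=None, validation=None):
        """Train on (X, y); ``validation`` is an optional (Xv, yv, ids) triple.

        Without an explicit validation set the last ~10% of patients (by
        sorted id) is held out, mirroring a 9:1 split.
        """
        from .preprocess import PreprocessConfig

        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if patient_ids is None:
            patient_ids = [f"im{i}" for i in range(len(X))]
        cfg = replace(self._resolved_config(), rng_seed=self.random_state)
        if validation is None:
            pats = sorted(set(patient_ids))
            n_val = max(1, len(pats) // 10)
            val_pats = set(pats[-n_val:])
            tr = [i for i, p in enumerate(patient_ids) if p not in val_pats]
            va = [i for i, p in enumerate(patient_ids) if p in val_pats]
            if not tr:
                raise ValueError("not enough patients to hold out validation")
            validation = (X[va], y[va], [patient_ids[i] for i in va])
            X, y = X[tr], y[tr]
            patient_ids = [patient_ids[i] for i in tr]
        self.model_ = UNet(cfg, rng=np.random.default_rng(self.random_state))
        train_set = list(zip(X, y, patient_ids))
        val_set = list(zip(*validation))
        # augment() only reads flip/zoom parameters; target_size is unused here
        aug = PreprocessConfig() if self.augment else None
        self.history_ = train_member(
            self.model_, train_set, val_set, cfg,
            rng_seed=self.random_state, augment_config=aug,
        )
        self.config_ = cfg
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        out = []
        for i in range(0, len(X), 8):
            out.append(self.model_.predict_proba(X[i : i + 8]))
        return np.concatenate(out, axis=0)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(np.uint8)

    def score(self, X, y) -> float:
        """Mean Dice of thresholded predictions against binary masks."""
        from .metrics import dice as _dice

        preds = self.predict(X)
        out = self.model_.shapes["output_size"]
        ys = _center_crop(np.asarray(y), out)
        return float(np.mean([_dice(p, t) for p, t in zip(preds, ys)]))
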