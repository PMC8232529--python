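"""3D U-Net segmentation model with soft Dice loss.

Architecture: four encoder levels and three decoder levels; every level is
two (3x3x3 conv -> group norm -> ReLU) stages; 2x2x2 max pooling between
encoder levels; 3x3x3 stride-2 transposed convolutions and skip feature-map
concatenation on the decoder path; a 1x1x1 convolution and two-class
softmax head ({background, organ}).  Feature counts double per level from
``base_features``.

The soft Dice loss on foreground probabilities p against a binary target t is

    L = 1 - (2 Σ p·t + ε) / (Σ p + Σ t + ε),   ε = 1e-5,

the ε term guarding the empty-target 0/0 case.  Optimization is Adam,
batch size 1 (whole volumes).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .imgio import SegmentationMask, Volume, derive_seed

DICE_EPS = 1e-5


@dataclass(frozen=True)
class UNetSpec:
    """Topology of the segmentation network."""

    encoder_levels: int = 4
    decoder_levels: int = 3
    base_features: int = 8
    norm_groups: int = 8
    in_channels: int = 1
    n_classes: int = 2

    def __post_init__(self):
        if self.decoder_levels != self.encoder_levels - 1:
            raise ValueError(
                f"decoder_levels must be encoder_levels-1, got "
                f"{self.decoder_levels} vs {self.encoder_levels}"
            )
        if self.base_features < 1 or self.encoder_levels < 2:
            raise ValueError("base_features >= 1 and encoder_levels >= 2 required")

    @property
    def divisor(self) -> int:
        """Input extents must be divisible by this (or are padded to be)."""
        return 2 ** (self.encoder_levels - 1)


class _ConvBlock:
    """Two (conv -> group norm -> ReLU) stages."""

    def __init__(self, c_in, c_out, groups, rng, dtype):
        self.layers = []
        for cin in (c_in, c_out):
            self.layers += [
                nn.Conv3d(cin, c_out, 3, rng=rng, dtype=dtype),
                nn.GroupNorm(c_out, groups, dtype=dtype),
                nn.ReLU(),
            ]

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self):
        out = []
        for i, layer in enumerate(self.layers):
            out += [(f"{i}.{n}", p, g) for n, p, g in layer.params()]
        return out


class UNet3D:
    """The network; see module docstring.  Arrays are (C, D, H, W), batch-free."""

    def __init__(self, spec: UNetSpec, seed: int = 0, dtype=np.float32):
        self.spec = spec
        self.seed = int(seed)
        self.dtype = np.dtype(dtype)
        feats = [spec.base_features * 2**i for i in range(spec.encoder_levels)]
        self.enc = []
        self.pools = []
        k = 0

        def _rng():
            nonlocal k
            k += 1
            return np.random.default_rng(derive_seed(self.seed, "layer", k))

        c_prev = spec.in_channels
        for f in feats:
            self.enc.append(_ConvBlock(c_prev, f, spec.norm_groups, _rng(), self.dtype))
            c_prev = f
        self.pools = [nn.MaxPool3d() for _ in range(spec.encoder_levels - 1)]
        self.ups = []
        self.dec = []
        for j in range(spec.decoder_levels):
            c_skip = feats[-(j + 2)]
            c_deep = feats[-(j + 1)] if j == 0 else feats[-(j + 1)]
            self.ups.append(nn.Deconv3d(c_deep, c_skip, rng=_rng(), dtype=self.dtype))
            self.dec.append(
                _ConvBlock(2 * c_skip, c_skip, spec.norm_groups, _rng(), self.dtype)
            )
        self.head = nn.Conv3d(feats[0], spec.n_classes, kernel=1, rng=_rng(), dtype=self.dtype)

    # -- parameter plumbing -------------------------------------------------
    def params(self):
        out = []
        for i, blk in enumerate(self.enc):
            out += [(f"enc{i}.{n}", p, g) for n, p, g in blk.params()]
        for j, (up, blk) in enumerate(zip(self.ups, self.dec)):
            out += [(f"up{j}.{n}", p, g) for n, p, g in up.params()]
            out += [(f"dec{j}.{n}", p, g) for n, p, g in blk.params()]
        out += [(f"head.{n}", p, g) for n, p, g in self.head.params()]
        return out

    @property
    def n_params(self) -> int:
        return sum(p.size for _, p, _ in self.params())

    def get_weights(self) -> dict:
        return {name: p.copy() for name, p, _ in self.params()}

    def set_weights(self, weights: dict) -> None:
        own = {name: p for name, p, _ in self.params()}
        if set(own) != set(weights):
            missing = set(own) ^ set(weights)
            raise ValueError(f"weight name mismatch (spec mismatch?): {sorted(missing)[:4]}")
        for name, p in own.items():
            src = np.asarray(weights[name], dtype=p.dtype)
            if src.shape != p.shape:
                raise ValueError(f"shape mismatch for '{name}': {src.shape} vs {p.shape}")
            p[...] = src

    # -- forward / backward -------------------------------------------------
    def _pad_input(self, x):
        d = self.spec.divisor
        pads = [(0, 0)]
        for n in x.shape[1:]:
            extra = (-n) % d
            pads.append((0, extra))
        self._crop = tuple(slice(0, n) for n in x.shape[1:])
        return np.pad(x, pads) if any(p[1] for p in pads) else x

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Input (in_channels, D, H, W) -> logits (n_classes, D, H, W)."""
        if x.ndim != 4 or x.shape[0] != self.spec.in_channels:
            raise ValueError(f"expected ({self.spec.in_channels}, D, H, W), got {x.shape}")
        x = self._pad_input(np.asarray(x, dtype=self.dtype))
        self._padded_shape = x.shape
        skips = []
        for i, blk in enumerate(self.enc):
            x = blk.forward(x)
            if i < len(self.pools):
                skips.append(x)
                x = self.pools[i].forward(x)
        self._splits = []
        for up, blk in zip(self.ups, self.dec):
            x = up.forward(x)
            skip = skips.pop()
            self._splits.append(skip.shape[0])
            x = np.concatenate([skip, x], axis=0)
            x = blk.forward(x)
        z = self.head.forward(x)
        c = self._crop
        return z[:, c[0], c[1], c[2]]

    def backward(self, dz: np.ndarray) -> None:
        full = np.zeros((self.spec.n_classes,) + self._padded_shape[1:], dtype=self.dtype)
        c = self._crop
        full[:, c[0], c[1], c[2]] = dz
        g = self.head.backward(full)
        skip_grads = []
        # walk decoder in reverse
        for j in range(len(self.dec) - 1, -1, -1):
            g = self.dec[j].backward(g)
            nskip = self._splits[j]
            skip_grads.append(g[:nskip])
            g = self.ups[j].backward(g[nskip:])
        # walk encoder in reverse; the last-appended skip grad belongs to the
        # deepest encoder level
        for i in range(len(self.enc) - 1, -1, -1):
            if i < len(self.pools):
                g = self.pools[i].backward(g)
                g = g + skip_grads.pop()
            g = self.enc[i].backward(g)

    def zero_grad(self):
        for _, _, g in self.params():
            g[...] = 0.0

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Softmax class probabilities, shape (n_classes, D, H, W)."""
        z = self.forward(x)
        return softmax_channels(z)


def softmax_channels(z: np.ndarray) -> np.ndarray:
    zs = z - z.max(axis=0, keepdims=True)
    e = np.exp(zs)
    return e / e.sum(axis=0, keepdims=True)


def build_model(spec: UNetSpec, seed: int = 0, dtype=np.float32) -> UNet3D:
    """Construct a trainable U-Net; weight init is deterministic given seed."""
    return UNet3D(spec, seed=seed, dtype=dtype)


def soft_dice_loss(pred_prob: np.ndarray, target_mask: np.ndarray) -> float:
    """Soft Dice loss on foreground probabilities vs a binary target."""
    p = np.asarray(pred_prob, dtype=np.float64)
    t = np.asarray(target_mask, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs target {t.shape}")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("pred probabilities must lie in [0, 1]")
    inter = (p * t).sum()
    denom = p.sum() + t.sum()
    return float(1.0 - (2.0 * inter + DICE_EPS) / (denom + DICE_EPS))


def soft_dice_loss_grad(logits: np.ndarray, target: np.ndarray):
    """Loss and its gradient w.r.t. the two-class logits.

    Returns (loss, dlogits).  The gradient goes through the softmax:
    with p1 the foreground probability, dL/dz1 = p1(1-p1) dL/dp1 and
    dL/dz0 = -dL/dz1.
    """
    p = softmax_channels(logits)
    p1 = p[1]
    t = np.asarray(target, dtype=logits.dtype)
    inter = float((p1 * t).sum())
    denom = float(p1.sum() + t.sum())
    loss = 1.0 - (2.0 * inter + DICE_EPS) / (denom + DICE_EPS)
    dldp1 = -(2.0 * t * (denom + DICE_EPS) - (2.0 * inter + DICE_EPS)) / (
        denom + DICE_EPS
    ) ** 2
    dz1 = p1 * (1.0 - p1) * dldp1
    dz = np.stack([-dz1, dz1]).astype(logits.dtype)
    return float(loss), dz


def predict(model: UNet3D, volume: Volume) -> SegmentationMask:
    """Foreground probability map for a preprocessed volume (deterministic)."""
    x = volume.data[None].astype(model.dtype)
    prob = model.predict_proba(x)[1]
    return SegmentationMask(
        np.clip(prob, 0.0, 1.0).astype(np.float32), volume.spacing_mm, volume.axis_convention
    )


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def make_checkpoint(model: UNet3D, history=None, meta=None) -> dict:
    return {
        "spec": asdict(model.spec),
        "seed": model.seed,
        "weights": model.get_weights(),
        "history": list(history or []),
        "meta": dict(meta or {}),
    }


def model_from_checkpoint(ckpt: dict, dtype=np.float32) -> UNet3D:
    spec = UNetSpec(**ckpt["spec"])
    model = UNet3D(spec, seed=int(ckpt.get("seed", 0)), dtype=dtype)
    model.set_weights(ckpt["weights"])
    return model


def save_checkpoint(ckpt: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = json.dumps(
        {"spec": ckpt["spec"], "seed": ckpt["seed"], "history": ckpt["history"],
         "meta": ckpt["meta"]}
    )
    arrays = {f"w_{k}": v for k, v in ckpt["weights"].items()}
    np.savez_compressed(path, header=np.array(header), **arrays)


def load_checkpoint(path) -> dict:
    with np.load(Path(path), allow_pickle=False) as z:
        header = json.loads(str(z["header"]))
        weights = {k[2:]: z[k] for k in z.files if k.startswith("w_")}
    return {**header, "weights": weights}


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class UNetSegmenter(BaseEstimator):
    """Scikit-learn-style wrapper around the U-Net training loop.

    Parameters
    ----------
    base_features : feature maps at the first encoder level (doubled per level).
    learning_rate : Adam step size.  The study-scale default is 1e-5; the
        desk-scale presets use 1e-3 because tiny grids make 1e-5 impractically
        slow to converge.
    epochs : full passes over the training set; each epoch draws one
        (augmented) sample per case.
    augment : an ``augment.AugmentConfig`` or None to disable augmentation
        (fully deterministic training).
    init_weights : a checkpoint dict used as warm start (the "template").
    seed : master seed for weight init and augmentation streams.

    Fitted attributes: ``model_`` (the network), ``history_`` (per-epoch mean
    training loss), ``spec_``.
    """

    def __init__(
        self,
        base_features: int = 8,
        encoder_levels: int = 4,
        norm_groups: int = 8,
        learning_rate: float = 1e-3,
        epochs: int = 100,
        augment=None,
        init_weights=None,
        seed: int = 0,
        dtype: str = "float32",
    ):
        self.base_features = base_features
        self.encoder_levels = encoder_levels
        self.norm_groups = norm_groups
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.augment = augment
        self.init_weights = init_weights
        self.seed = seed
        self.dtype = dtype

    def _make_spec(self) -> UNetSpec:
        return UNetSpec(
            encoder_levels=self.encoder_levels,
            decoder_levels=self.encoder_levels - 1,
            base_features=self.base_features,
            norm_groups=self.norm_groups,
        )

    def _build(self) -> UNet3D:
        if self.init_weights is not None:
            spec = UNetSpec(**self.init_weights["spec"])
            if spec != self._make_spec():
                raise ValueError(
                    f"checkpoint spec {spec} does not match estimator spec {self._make_spec()}"
                )
            return model_from_checkpoint(self.init_weights, dtype=self.dtype)
        return UNet3D(self._make_spec(), seed=derive_seed(self.seed, "init"), dtype=self.dtype)

    def fit(self, X, y=None):
        """Train on ``X``: a sequence of (case_id, Volume, SegmentationMask).

        Each epoch optimizes on one augmented sample per case (or the raw
        sample when augmentation is off).
        """
        from .augment import epoch_stream  # local import to avoid a cycle

        cases = list(X)
        if not cases:
            raise ValueError("empty training set")
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        self.model_ = self._build()
        self.spec_ = self.model_.spec
        opt = nn.Adam(self.model_.params(), lr=self.learning_rate)
        history = []
        for epoch in range(int(self.epochs)):
            losses = []
            for case_id, vol, mask in epoch_stream(
                cases, self.augment, epoch, derive_seed(self.seed, "aug")
            ):
                x = vol.data[None].astype(self.model_.dtype)
                z = self.model_.forward(x)
                loss, dz = soft_dice_loss_grad(z, mask.data)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged: non-finite loss at epoch {epoch}, case {case_id}"
                    )
                opt.zero_grad()
                self.model_.backward(dz)
                opt.step()
                losses.append(loss)
            history.append(float(np.mean(losses)))
        self.history_ = history
        return self

    def predict(self, volume: Volume) -> SegmentationMask:
        """Soft foreground-probability mask for one preprocessed volume."""
        self._check_fitted()
        return predict(self.model_, volume)

    def evaluate_loss(self, X) -> float:
        """Mean soft Dice loss over cases with the current weights (no updates)."""
        self._check_fitted()
        losses = []
        for case_id, vol, mask in X:
            z = self.model_.forward(vol.data[None].astype(self.model_.dtype))
            loss, _ = soft_dice_loss_grad(z, mask.data)
            losses.append(loss)
        return float(np.mean(losses))

    def checkpoint(self, meta=None) -> dict:
        self._check_fitted()
        return make_checkpoint(self.model_, history=getattr(self, "history_", []), meta=meta)

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            # warm starts are usable for prediction without fitting
            if self.init_weights is not None:
                self.model_ = self._build()
                self.spec_ = self.model_.spec
                self.history_ = list(self.init_weights.get("history", []))
            else:
                raise RuntimeError("estimator is not fitted and has no init_weights")
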