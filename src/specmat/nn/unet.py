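"""The two-stage decomposition networks.

``FeatureNetwork`` is a U-Net classifier over 64x64 4-channel patches whose
encoder follows the fixed channel plan

    16x(64x64) -> 32x(32x32) -> 64x(16x16) -> 128x(8x8) -> 256x(4x4)

and whose decoder returns to 16 channels at 64x64; a 1x1 convolution and
softmax yield 4-class per-voxel probabilities.  ``ConcentrationNetwork`` is a
second U-Net that consumes the classifier's 16 penultimate feature channels
(the classifier stays frozen) and outputs iodine/gadolinium/calcium
concentrations (softplus, mg/mL) plus a tissue probability (sigmoid).
"""

from __future__ import annotations

import numpy as np

from .layers import (
    Adam,
    BatchNorm2D,
    Conv2D,
    ConvTranspose2x2,
    MaxPool2,
    ReLU,
    cross_entropy,
    softmax,
    weights_hash,
)

__all__ = ["FeatureNetwork", "ConcentrationNetwork", "ENCODER_CHANNELS"]

ENCODER_CHANNELS = (16, 32, 64, 128, 256)


class _ConvBlock:
    def __init__(self, cin, cout, rng):
        self.conv = Conv2D(cin, cout, 3, rng)
        self.bn = BatchNorm2D(cout)
        self.act = ReLU()

    def forward(self, x, train):
        return self.act.forward(self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, dy):
        return self.conv.backward(self.bn.backward(self.act.backward(dy)))

    def params(self):
        return self.conv.params() + self.bn.params()


class _UNetCore:
    """Shared encoder/decoder trunk; subclasses add the output head."""

    def __init__(self, in_channels: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        ch = ENCODER_CHANNELS
        self.enc = [_ConvBlock(in_channels, ch[0], rng)]
        for a, b in zip(ch[:-1], ch[1:]):
            self.enc.append(_ConvBlock(a, b, rng))
        self.pools = [MaxPool2() for _ in range(len(ch) - 1)]
        self.ups = [
            ConvTranspose2x2(b, a, rng) for a, b in zip(ch[:-1], ch[1:])
        ][::-1]
        self.dec = [
            _ConvBlock(2 * a, a, rng) for a in ch[:-1]
        ][::-1]
        self.seed = seed
        self._skip_cache = None

    # -- plumbing ---------------------------------------------------------
    def params(self):
        out = []
        for blk in self.enc:
            out += blk.params()
        for up in self.ups:
            out += up.params()
        for blk in self.dec:
            out += blk.params()
        return out

    def weights_hash(self) -> str:
        return weights_hash(self.params())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.value.copy() for i, p in enumerate(self.params())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.value[...] = state[f"p{i}"]

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    # -- trunk ------------------------------------------------------------
    def trunk_forward(self, x: np.ndarray, train: bool):
        """Returns the 16-channel penultimate features and encoder shapes."""
        skips = []
        h = x
        shapes = []
        for i, blk in enumerate(self.enc):
            h = blk.forward(h, train)
            shapes.append(h.shape[1:])
            if i < len(self.pools):
                skips.append(h)
                h = self.pools[i].forward(h, train)
        for up, dec, skip in zip(self.ups, self.dec, skips[::-1]):
            h = up.forward(h, train)
            h = dec.forward(np.concatenate([skip, h], axis=1), train)
        self._encoder_shapes = shapes
        if train:
            self._n_skip = [s.shape[1] for s in skips]
        return h

    def trunk_backward(self, dh: np.ndarray) -> np.ndarray:
        dskips = []
        for up, dec, n_skip in zip(
            self.ups[::-1], self.dec[::-1], self._n_skip
        ):
            d = dec.backward(dh)
            dskips.append(d[:, :n_skip])
            dh = up.backward(d[:, n_skip:])
        dx = dh
        for i in range(len(self.enc) - 1, -1, -1):
            if i < len(self.pools):
                dx = self.pools[i].backward(dx)
                dx = dx + dskips[i]  # dskips[i] pairs with skips[i]
            dx = self.enc[i].backward(dx)
        return dx

    def encoder_shapes(self, patch: int = 64, in_channels: int | None = None):
        """Channel/spatial plan observed on a real forward pass."""
        cin = in_channels or self.enc[0].conv.w.value.shape[1]
        x = np.zeros((1, cin, patch, patch), dtype=np.float32)
        self.trunk_forward(x, train=False)
        return [tuple(s) for s in self._encoder_shapes]


class FeatureNetwork(_UNetCore):
    """4-class per-voxel classifier; exposes its 16 penultimate channels."""

    n_classes = 4

    def __init__(self, in_channels: int = 4, seed: int = 0):
        super().__init__(in_channels, seed)
        rng = np.random.default_rng(seed + 1)
        self.head = Conv2D(ENCODER_CHANNELS[0], self.n_classes, 1, rng)

    def params(self):
        return super().params() + self.head.params()

    def forward(self, x: np.ndarray, train: bool = False):
        """Returns (class probabilities, 16-channel penultimate features)."""
        feats = self.trunk_forward(x.astype(np.float32), train)
        logits = self.head.forward(feats, train)
        return softmax(logits), feats

    def train_step(self, x: np.ndarray, targets: np.ndarray, opt: Adam) -> float:
        probs, _ = self.forward(x, train=True)
        loss, dlogits = cross_entropy(probs, targets)
        opt.zero_grad()
        self.trunk_backward(self.head.backward(dlogits))
        opt.step()
        return loss

    def loss(self, x: np.ndarray, targets: np.ndarray) -> float:
        probs, _ = self.forward(x, train=False)
        return cross_entropy(probs, targets)[0]


def _softplus(x):
    return np.logaddexp(0.0, x)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


class ConcentrationNetwork(_UNetCore):
    """Regressor from 16 feature channels to I/Gd/Ca (mg/mL) + tissue prob.

    Output scaling: concentration channels are softplus activations times
    fixed per-material scales so one unit of network output spans the
    physical concentration ranges (calcium runs to hundreds of mg/mL).
    """

    #: mg/mL per softplus unit for (iodine, gadolinium, calcium)
    OUTPUT_SCALES = np.array([2.0, 2.0, 80.0], dtype=np.float32)

    def __init__(self, in_channels: int = 16, seed: int = 100):
        super().__init__(in_channels, seed)
        rng = np.random.default_rng(seed + 1)
        self.head = Conv2D(ENCODER_CHANNELS[0], 4, 1, rng)

    def params(self):
        return super().params() + self.head.params()

    def forward(self, feats: np.ndarray, train: bool = False):
        h = self.trunk_forward(feats.astype(np.float32), train)
        raw = self.head.forward(h, train)
        out = np.empty_like(raw)
        out[:, :3] = _softplus(raw[:, :3]) * self.OUTPUT_SCALES[None, :, None, None]
        out[:, 3] = _sigmoid(raw[:, 3])
        if train:
            self._raw = raw
        return out

    def _loss_grad(self, out, raw, conc_targets, tissue_targets, mask):
        """Masked MSE on concentrations (scaled units) + BCE on tissue."""
        scales = self.OUTPUT_SCALES[None, :, None, None]
        diff = (out[:, :3] - conc_targets) / scales  # normalized residuals
        m = mask[:, None].astype(np.float32)
        nm = max(m.sum() * 3, 1.0)
        mse = float((m * diff**2).sum() / nm)
        dout = np.zeros_like(raw)
        # d mse / d raw = 2 diff / nm * d(out/scale)/draw ; softplus' = sigmoid
        dout[:, :3] = 2.0 * m * diff / nm * _sigmoid(raw[:, :3])
        p = out[:, 3]
        t = tissue_targets.astype(np.float32)
        nv = p.size
        eps = 1e-7
        bce = float(-(t * np.log(p + eps) + (1 - t) * np.log(1 - p + eps)).sum() / nv)
        dout[:, 3] = (p - t) / nv  # sigmoid+BCE shortcut
        return mse + bce, dout

    def train_step(self, feats, conc_targets, tissue_targets, mask, opt: Adam) -> float:
        out = self.forward(feats, train=True)
        loss, draw = self._loss_grad(out, self._raw, conc_targets, tissue_targets, mask)
        opt.zero_grad()
        self.trunk_backward(self.head.backward(draw))
        opt.step()
        return loss

    def loss(self, feats, conc_targets, tissue_targets, mask) -> float:
        out = self.forward(feats, train=False)
        scales = self.OUTPUT_SCALES[None, :, None, None]
        diff = (out[:, :3] - conc_targets) / scales
        m = mask[:, None].astype(np.float32)
        nm = max(m.sum() * 3, 1.0)
        mse = float((m * diff**2).sum() / nm)
        p = out[:, 3]
        t = tissue_targets.astype(np.float32)
        eps = 1e-7
        bce = float(
            -(t * np.log(p + eps) + (1 - t) * np.log(1 - p + eps)).sum() / p.size
        )
        return mse + bce
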