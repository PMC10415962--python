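"""Network architectures for the two pipeline stages.

``UNet2d`` is a compact encoder-decoder with skip connections for single-slice
muscle segmentation; ``DenseNetRegressor`` is a densely-connected convolutional
regressor that maps one axial slice to its signed physical offset (mm) from the
mid-C3 level. Both are sized for CPU training on modest phantom sets; the
``base_filters`` / ``growth_rate`` knobs scale them up toward full-size variants.

Normalization is per-sample instance normalization, so training and inference
apply the identical transform and single-image prediction is deterministic.
Checkpoints are plain ``.npz`` files carrying every parameter and the
architecture hyperparameters; a reloaded model reproduces predictions bit for
bit.
"""

from __future__ import annotations

import json

import numpy as np

from .layers import (
    F32,
    Adam,
    Conv2d,
    Dense,
    GlobalAvgPool,
    InstanceNorm2d,
    MaxPool2,
    Param,
    ReLU,
    Upsample2,
    sigmoid,
)


class _ConvBNRelu:
    def __init__(self, cin, cout, k, rng):
        self.conv = Conv2d(cin, cout, k, rng)
        self.bn = InstanceNorm2d(cout)
        self.relu = ReLU()

    @property
    def layers(self):
        return [self.conv, self.bn, self.relu]

    def params(self):
        return self.conv.params() + self.bn.params()

    def forward(self, x, training):
        return self.relu.forward(self.bn.forward(self.conv.forward(x, training), training), training)

    def backward(self, gy):
        return self.conv.backward(self.bn.backward(self.relu.backward(gy)))


class _Model:
    """Shared parameter bookkeeping and checkpoint I/O."""

    kind = "model"

    def _blocks(self) -> list:  # pragma: no cover - overridden
        raise NotImplementedError

    def params(self) -> list[Param]:
        out = []
        for b in self._blocks():
            out.extend(b.params())
        return out

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.v for i, p in enumerate(self.params())}

    def load_state_arrays(self, arrs) -> None:
        for i, p in enumerate(self.params()):
            p.v[...] = arrs[f"p{i}"]

    def save(self, path) -> None:
        meta = json.dumps({"kind": self.kind, "hp": self.hyperparams})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **self.state_arrays())

    @classmethod
    def load(cls, path):
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta["kind"] != cls.kind:
                raise ValueError(f"checkpoint is a {meta['kind']!r} model, expected {cls.kind!r}")
            model = cls(rng=np.random.default_rng(0), **meta["hp"])
            model.load_state_arrays(data)
        return model


class UNet2d(_Model):
    """Two-level U-Net with additive skip connections and a 1x1 output head.

    Input (N, 1, H, W) with H, W divisible by 4; output is the muscle logit map.
    """

    kind = "unet2d"

    def __init__(self, base_filters: int = 16, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        f = base_filters
        self.hyperparams = {"base_filters": base_filters}
        self.e1 = _ConvBNRelu(1, f, 3, rng)
        self.e1b = _ConvBNRelu(f, f, 3, rng)
        self.pool1 = MaxPool2()
        self.e2 = _ConvBNRelu(f, 2 * f, 3, rng)
        self.pool2 = MaxPool2()
        self.bott = _ConvBNRelu(2 * f, 4 * f, 3, rng)
        self.up1 = Upsample2()
        self.proj1 = Conv2d(4 * f, 2 * f, 1, rng)
        self.d2 = _ConvBNRelu(2 * f, 2 * f, 3, rng)
        self.up2 = Upsample2()
        self.proj2 = Conv2d(2 * f, f, 1, rng)
        self.d1 = _ConvBNRelu(f, f, 3, rng)
        self.head = Conv2d(f, 1, 1, rng)

    def _blocks(self):
        return [self.e1, self.e1b, self.e2, self.bott, self.proj1, self.d2,
                self.proj2, self.d1, self.head]

    def forward(self, x, training=False):
        x = np.ascontiguousarray(x, dtype=F32)
        s1 = self.e1b.forward(self.e1.forward(x, training), training)
        x2 = self.pool1.forward(s1, training)
        s2 = self.e2.forward(x2, training)
        x3 = self.pool2.forward(s2, training)
        xb = self.bott.forward(x3, training)
        u1 = self.proj1.forward(self.up1.forward(xb, training), training) + s2
        xd2 = self.d2.forward(u1, training)
        u2 = self.proj2.forward(self.up2.forward(xd2, training), training) + s1
        xd1 = self.d1.forward(u2, training)
        return self.head.forward(xd1, training)

    def backward(self, gy):
        g = self.head.backward(gy)
        g = self.d1.backward(g)
        gs1 = g.copy()                      # additive skip to e1b
        g = self.up2.backward(self.proj2.backward(g))
        g = self.d2.backward(g)
        gs2 = g.copy()                      # additive skip to e2
        g = self.up1.backward(self.proj1.backward(g))
        g = self.bott.backward(g)
        g = self.pool2.backward(g)
        g = self.e2.backward(g + gs2)
        g = self.pool1.backward(g)
        g = self.e1b.backward(g + gs1)
        return self.e1.backward(g)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Per-pixel muscle probability for (N, H, W) or (H, W) input."""
        single = images.ndim == 2
        x = images[None] if single else images
        logits = self.forward(x[:, None], training=False)[:, 0]
        p = sigmoid(logits)
        return p[0] if single else p


class _DenseBlock:
    """Densely connected block: each layer sees the concat of all previous maps."""

    def __init__(self, cin, growth, n_layers, rng):
        self.convs = []
        c = cin
        for _ in range(n_layers):
            self.convs.append(_ConvBNRelu(c, growth, 3, rng))
            c += growth
        self.cout = c

    @property
    def layers(self):
        return [l for cv in self.convs for l in cv.layers]

    def params(self):
        out = []
        for cv in self.convs:
            out.extend(cv.params())
        return out

    def forward(self, x, training):
        feats = [x]
        for cv in self.convs:
            cat = feats[0] if len(feats) == 1 else np.concatenate(feats, axis=1)
            feats.append(cv.forward(cat, training))
        self._widths = [f.shape[1] for f in feats]
        return np.concatenate(feats, axis=1)

    def backward(self, gy):
        widths = self._widths
        bounds = np.cumsum(widths)
        grads = [gy[:, (0 if i == 0 else bounds[i - 1]):bounds[i]].copy()
                 for i in range(len(widths))]
        for i in range(len(self.convs) - 1, -1, -1):
            gcat = self.convs[i].backward(grads[i + 1])
            cb = np.cumsum(widths[:i + 1])
            for j in range(i + 1):
                grads[j] += gcat[:, (0 if j == 0 else cb[j - 1]):cb[j]]
        return grads[0]


class DenseNetRegressor(_Model):
    """Dense-block CNN regressing one axial slice to a signed mm offset.

    Stem (conv-pool) then three dense blocks with transition layers, global
    average pooling, and a two-layer head producing a single scalar.
    """

    kind = "densenet_regressor"

    def __init__(self, growth_rate: int = 8, stem_filters: int = 8,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        g = growth_rate
        self.hyperparams = {"growth_rate": growth_rate, "stem_filters": stem_filters}
        self.stem = _ConvBNRelu(1, stem_filters, 3, rng)
        self.pool0 = MaxPool2()
        self.block1 = _DenseBlock(stem_filters, g, 3, rng)
        self.trans1 = Conv2d(self.block1.cout, self.block1.cout // 2, 1, rng)
        self.pool1 = MaxPool2()
        self.block2 = _DenseBlock(self.block1.cout // 2, g, 3, rng)
        self.trans2 = Conv2d(self.block2.cout, self.block2.cout // 2, 1, rng)
        self.pool2 = MaxPool2()
        self.block3 = _DenseBlock(self.block2.cout // 2, g, 2, rng)
        self.gap = GlobalAvgPool()
        self.fc1 = Dense(self.block3.cout, 32, rng)
        self.relu_fc = ReLU()
        self.fc2 = Dense(32, 1, rng)

    def _blocks(self):
        return [self.stem, self.block1, self.trans1, self.block2, self.trans2,
                self.block3, self.fc1, self.fc2]

    def forward(self, x, training=False):
        x = np.ascontiguousarray(x, dtype=F32)
        h = self.pool0.forward(self.stem.forward(x, training), training)
        h = self.block1.forward(h, training)
        h = self.pool1.forward(self.trans1.forward(h, training), training)
        h = self.block2.forward(h, training)
        h = self.pool2.forward(self.trans2.forward(h, training), training)
        h = self.block3.forward(h, training)
        h = self.gap.forward(h, training)
        h = self.relu_fc.forward(self.fc1.forward(h, training), training)
        return self.fc2.forward(h, training)

    def backward(self, gy):
        g = self.fc2.backward(gy)
        g = self.fc1.backward(self.relu_fc.backward(g))
        g = self.gap.backward(g)
        g = self.block3.backward(g)
        g = self.trans2.backward(self.pool2.backward(g))
        g = self.block2.backward(g)
        g = self.trans1.backward(self.pool1.backward(g))
        g = self.block1.backward(g)
        g = self.pool0.backward(g)
        return self.stem.backward(g)

    def predict_offsets(self, slices: np.ndarray, scale: float) -> np.ndarray:
        """Offsets in mm for a stack of (N, H, W) slices; ``scale`` undoes target scaling."""
        out = self.forward(slices[:, None], training=False)[:, 0]
        return out.astype(float) * scale


__all__ = ["UNet2d", "DenseNetRegressor", "Adam", "sigmoid"]
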