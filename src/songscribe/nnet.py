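"""Minimal convolutional network on numpy: forward, backprop, SGD.

Layers operate on (channels, rows, frames) tensors, single example at a time
(an "example" here is a whole spectrogram excerpt: the network is fully
convolutional, so one pass scores every window the excerpt contains).
Convolutions are valid, stride 1, implemented as im2col + matrix products so
the heavy lifting runs in BLAS. Max-pools are 2x2, stride 2, truncating odd
trailing rows/columns.

Dense (per-frame) outputs despite the three stride-2 pools are obtained by
shift-and-stitch evaluated efficiently: computation is shared up to each pool,
where the two temporal phases are evaluated separately and the results
interleaved, so a dense pass costs roughly one stride-1 pass per layer rather
than eight full passes.
"""

from __future__ import annotations

import numpy as np

from .architecture import ArchitectureSpec, LayerSpec

__all__ = ["Network", "initialize_parameters"]

DEFAULT_DTYPE = np.float32


def _conv2d(x: np.ndarray, w4: np.ndarray) -> np.ndarray:
    """Valid correlation of (C, H, W) input with (Co, C, hf, wf) filters.

    Implemented as hf*wf shifted matrix products so the inner loops run in
    BLAS without an im2col transpose copy.
    """
    co, c, hf, wf = w4.shape
    _, h, wd = x.shape
    oh, ow = h - hf + 1, wd - wf + 1
    acc = np.zeros((co, oh * ow), dtype=x.dtype)
    for i in range(hf):
        for j in range(wf):
            patch = x[:, i : i + oh, j : j + ow].reshape(c, oh * ow)
            acc += w4[:, :, i, j] @ patch
    return acc.reshape(co, oh, ow)


class ConvLayer:
    """Valid convolution, optional rectified-linear activation."""

    def __init__(self, spec: LayerSpec, in_channels: int, rng: np.random.Generator,
                 dtype=DEFAULT_DTYPE):
        self.spec = spec
        self.in_channels = in_channels
        fan_in = in_channels * spec.filter_height * spec.filter_width
        sigma = np.sqrt(2.0 / fan_in)
        self.W = rng.normal(0.0, sigma, size=(spec.channels, fan_in)).astype(dtype)
        self.b = np.zeros(spec.channels, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    @property
    def out_channels(self) -> int:
        return self.spec.channels

    def _w4(self) -> np.ndarray:
        hf, wf = self.spec.filter_height, self.spec.filter_width
        return self.W.reshape(self.out_channels, self.in_channels, hf, wf)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        hf, wf = self.spec.filter_height, self.spec.filter_width
        if hf == 1 and wf == 1:
            c, h, w = x.shape
            y = (self.W @ x.reshape(c, h * w) + self.b[:, None]).reshape(
                self.out_channels, h, w
            )
        elif self.in_channels * hf * wf <= 256:
            # small fan-in: one im2col + GEMM beats the shifted accumulation
            win = np.lib.stride_tricks.sliding_window_view(x, (hf, wf), axis=(1, 2))
            c, oh, ow = win.shape[:3]
            cols = win.transpose(0, 3, 4, 1, 2).reshape(c * hf * wf, oh * ow)
            y = (self.W @ cols + self.b[:, None]).reshape(self.out_channels, oh, ow)
        else:
            y = _conv2d(x, self._w4())
            y += self.b[:, None, None]
        relu = self.spec.activation == "relu"
        if relu:
            np.maximum(y, 0.0, out=y)
        if train:
            self._cache = (x, y if relu else None)
        return y

    def backward(self, dy: np.ndarray, need_dx: bool = True) -> np.ndarray | None:
        x, y_relu = self._cache
        if y_relu is not None:
            dy = dy * (y_relu > 0)
        co, oh, ow = dy.shape
        dyf = dy.reshape(co, oh * ow)
        self.db += dyf.sum(axis=1)
        hf, wf = self.spec.filter_height, self.spec.filter_width
        c = self.in_channels
        dx = None
        if hf == 1 and wf == 1:
            self.dW += dyf @ x.reshape(c, oh * ow).T
            if need_dx:
                dx = (self.W.T @ dyf).reshape(x.shape)
        else:
            dw4 = self.dW.reshape(co, c, hf, wf)
            for i in range(hf):
                for j in range(wf):
                    patch = x[:, i : i + oh, j : j + ow].reshape(c, oh * ow)
                    dw4[:, :, i, j] += dyf @ patch.T
            if need_dx:
                # transposed convolution by scatter-add of shifted products
                w4 = self._w4()
                dx = np.zeros(x.shape, dtype=dy.dtype)
                for i in range(hf):
                    for j in range(wf):
                        contrib = (w4[:, :, i, j].T @ dyf).reshape(c, oh, ow)
                        dx[:, i : i + oh, j : j + ow] += contrib
        self._cache = None
        return dx

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class MaxPoolLayer:
    """2x2 max-pool with stride 2; odd trailing rows/columns are dropped."""

    def __init__(self, spec: LayerSpec):
        self.spec = spec
        self._cache = None

    @staticmethod
    def pool(x: np.ndarray, phase: int = 0) -> np.ndarray:
        """Pool with a temporal phase offset (used for dense evaluation)."""
        x = x[:, :, phase:]
        c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        x = x[:, : 2 * h2, : 2 * w2]
        a = np.maximum(x[:, 0::2, :], x[:, 1::2, :])
        return np.maximum(a[:, :, 0::2], a[:, :, 1::2])

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = self.pool(x, 0)
        if train:
            self._cache = (x, y)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        # Gradient flows to every element equal to the block maximum. Exact
        # positive ties (vanishing for continuous inputs) share the gradient;
        # tied zeros are killed by the upstream rectifier mask anyway.
        x, y = self._cache
        c, h, w = x.shape
        h2, w2 = dy.shape[1], dy.shape[2]
        up_y = np.repeat(np.repeat(y, 2, axis=1), 2, axis=2)
        up_dy = np.repeat(np.repeat(dy, 2, axis=1), 2, axis=2)
        dx = np.zeros((c, h, w), dtype=dy.dtype)
        crop = x[:, : 2 * h2, : 2 * w2]
        dx[:, : 2 * h2, : 2 * w2] = (crop == up_y) * up_dy
        self._cache = None
        return dx

    def params(self):
        return []

    def grads(self):
        return []


class Network:
    """The fully-convolutional classifier for one architecture spec.

    The final softmax is applied over channels; :meth:`loss_and_grad`
    accumulates cross-entropy gradients for labeled output positions.
    """

    def __init__(self, arch: ArchitectureSpec, seed: int, dtype=DEFAULT_DTYPE):
        self.arch = arch
        self.seed = seed
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self.layers = []
        in_ch = 1
        for spec in arch.layers:
            if spec.kind == "maxpool":
                self.layers.append(MaxPoolLayer(spec))
            else:
                layer = ConvLayer(spec, in_ch, rng, dtype=dtype)
                in_ch = spec.channels
                self.layers.append(layer)

    # -- parameter plumbing -------------------------------------------------

    def parameters(self):
        return [p for layer in self.layers for p in layer.params()]

    def gradients(self):
        return [g for layer in self.layers for g in layer.grads()]

    def get_state(self):
        return [p.copy() for p in self.parameters()]

    def set_state(self, state):
        for p, s in zip(self.parameters(), state):
            p[...] = s

    def zero_grad(self):
        for g in self.gradients():
            g[...] = 0.0

    def sgd_step(self, lr: float, scale: float = 1.0):
        for p, g in zip(self.parameters(), self.gradients()):
            p -= lr * scale * g

    # -- strided forward / training ----------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Strided logits (n_outputs, H_out, W_out); H_out is 1 for full-height input."""
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 2:
            x = x[None]
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    @staticmethod
    def softmax(logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=0, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=0, keepdims=True)

    def loss_and_grad(self, x: np.ndarray, labels: np.ndarray) -> tuple[float, int]:
        """Cross-entropy over labeled output positions; accumulates gradients.

        ``labels`` has one entry per temporal output position; entries < 0 are
        not trainable and excluded from the loss. Returns (summed loss, count).
        """
        logits = self.forward(x, train=True)
        k, oh, ow = logits.shape
        assert oh == 1, "input height must collapse to one output row"
        probs = self.softmax(logits[:, 0, :])
        labels = np.asarray(labels)
        assert labels.shape[0] == ow
        mask = labels >= 0
        count = int(mask.sum())
        dlogits = np.zeros_like(probs)
        loss = 0.0
        if count:
            cols = np.flatnonzero(mask)
            lab = labels[cols]
            p = probs[lab, cols]
            loss = float(-np.log(np.maximum(p, 1e-300)).sum())
            dlogits[:, cols] = probs[:, cols]
            dlogits[lab, cols] -= 1.0
        dy = dlogits.reshape(k, 1, ow)
        for li in range(len(self.layers) - 1, -1, -1):
            if li == 0 and isinstance(self.layers[li], ConvLayer):
                self.layers[li].backward(dy, need_dx=False)
            else:
                dy = self.layers[li].backward(dy)
        return loss, count

    def predict_strided(self, x: np.ndarray) -> np.ndarray:
        """Softmax scores at stride-``temporal_stride`` output positions."""
        logits = self.forward(x, train=False)
        return self.softmax(logits[:, 0, :])

    # -- dense (per-frame) evaluation ---------------------------------------

    def predict_dense(self, x: np.ndarray) -> np.ndarray:
        """Softmax scores for every temporal position (shift-and-stitch)."""
        logits = self._dense(0, x)
        return self.softmax(logits[:, 0, :])

    def _dense(self, li: int, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 2:
            x = x[None]
        while li < len(self.layers):
            layer = self.layers[li]
            if isinstance(layer, MaxPoolLayer):
                y0 = MaxPoolLayer.pool(x, 0)
                y1 = MaxPoolLayer.pool(x, 1)
                z0 = self._dense(li + 1, y0)
                z1 = self._dense(li + 1, y1)
                k, h, w0 = z0.shape
                w1 = z1.shape[2]
                out = np.empty((k, h, w0 + w1), dtype=z0.dtype)
                out[:, :, 0::2] = z0
                out[:, :, 1::2] = z1
                return out
            x = layer.forward(x, train=False)
            li += 1
        return x


def initialize_parameters(arch: ArchitectureSpec, seed: int,
                          dtype=DEFAULT_DTYPE) -> Network:
    """He-initialized network: weights ~ N(0, sqrt(2/fan_in)), biases zero."""
    return Network(arch, seed, dtype=dtype)
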