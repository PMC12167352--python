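"""A CPU numpy implementation of the UNet used for input-artery segmentation.

The network follows the classic encoder-decoder layout: a contracting path
of levels, each with two 3x3 stride-1 convolutions (instance normalization +
ReLU after every convolution) and 2x2 max-pooling between levels, with
channels doubling from ``base_channels`` up to ``max_channels`` (64 to 512
by default, i.e. four resolution levels and eight encoder convolutions); and
an expanding path that mirrors it with 2x nearest-neighbor upsampling,
concatenation skip connections and two 3x3 convolutions per level.  A final
1x1 convolution with a sigmoid produces per-pixel probabilities in [0, 1].

Forward and backward passes are written directly against numpy (im2col
matmuls for the convolutions), processing one image at a time; instance
normalization makes single-sample training well-posed.  This is intended for
desk-scale experiments on small images; it is a faithful, if slow, CPU
realization of the architecture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_EPS = 1e-5


@dataclass
class UNetConfig:
    """Architecture hyperparameters.

    ``base_channels``/``max_channels`` define the channel progression
    (doubling per level): the defaults 64/512 give the four-level,
    eight-convolution encoder; small desk-scale runs shrink both.
    """

    in_channels: int = 1
    base_channels: int = 64
    max_channels: int = 512
    binarize_threshold: float = 0.5

    @property
    def level_channels(self) -> list[int]:
        chans = [self.base_channels]
        while chans[-1] < self.max_channels:
            chans.append(min(chans[-1] * 2, self.max_channels))
        return chans

    @property
    def n_levels(self) -> int:
        return len(self.level_channels)


class _Layer:
    """Minimal layer protocol: forward, backward, trainable params."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv3x3(_Layer):
    """3x3 stride-1 same-padding convolution via im2col matmul."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.cin, self.cout = cin, cout
        std = np.sqrt(2.0 / (9 * cin))  # He init for ReLU stacks
        self.W = rng.normal(0.0, std, size=(cin * 9, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
        # (c, h, w, 3, 3) -> (h*w, c*9)
        cols = win.transpose(1, 2, 0, 3, 4).reshape(h * w, c * 9)
        self._cols, self._hw = cols, (h, w)
        y = cols @ self.W + self.b
        return np.ascontiguousarray(y.reshape(h, w, self.cout).transpose(2, 0, 1))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        h, w = self._hw
        dyf = dy.transpose(1, 2, 0).reshape(h * w, self.cout)
        self.grads[0][...] = self._cols.T @ dyf
        self.grads[1][...] = dyf.sum(axis=0)
        dcols = (dyf @ self.W.T).reshape(h, w, self.cin, 3, 3)
        dxp = np.zeros((self.cin, h + 2, w + 2), dtype=np.float32)
        for di in range(3):
            for dj in range(3):
                dxp[:, di : di + h, dj : dj + w] += dcols[:, :, :, di, dj].transpose(2, 0, 1)
        return dxp[:, 1 : 1 + h, 1 : 1 + w]


class Conv1x1(_Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.cin, self.cout = cin, cout
        std = np.sqrt(2.0 / cin)
        self.W = rng.normal(0.0, std, size=(cin, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = np.tensordot(self.W.T, x, axes=1) + self.b[:, None, None]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = np.tensordot(self._x, dy, axes=((1, 2), (1, 2)))
        self.grads[1][...] = dy.sum(axis=(1, 2))
        return np.tensordot(self.W, dy, axes=(1, 0))


class InstanceNorm(_Layer):
    """Per-channel normalization over the spatial axes, with affine scale/shift."""

    def __init__(self, c: int) -> None:
        super().__init__()
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(1, 2), keepdims=True)
        var = x.var(axis=(1, 2), keepdims=True)
        self._inv_std = 1.0 / np.sqrt(var + _EPS)
        self._xhat = (x - mu) * self._inv_std
        return self.gamma[:, None, None] * self._xhat + self.beta[:, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat = self._xhat
        self.grads[0][...] = (dy * xhat).sum(axis=(1, 2))
        self.grads[1][...] = dy.sum(axis=(1, 2))
        dxhat = dy * self.gamma[:, None, None]
        m1 = dxhat.mean(axis=(1, 2), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(1, 2), keepdims=True)
        return self._inv_std * (dxhat - m1 - xhat * m2)


class ReLU(_Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class MaxPool2(_Layer):
    """2x2 max-pooling; input spatial dims must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        blocks = x.reshape(c, h // 2, 2, w // 2, 2)
        y = blocks.max(axis=(2, 4))
        self._mask = blocks == y[:, :, None, :, None]
        self._shape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        up = self._mask * dy[:, :, None, :, None]
        # ties split the gradient; negligible for continuous activations
        counts = self._mask.sum(axis=(2, 4), keepdims=True)
        return (up / counts).reshape(self._shape)


class Upsample2(_Layer):
    """2x nearest-neighbor upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, h, w = dy.shape
        return dy.reshape(c, h // 2, 2, w // 2, 2).sum(axis=(2, 4))


def _conv_block(cin: int, cout: int, rng: np.random.Generator) -> list[_Layer]:
    return [
        Conv3x3(cin, cout, rng), InstanceNorm(cout), ReLU(),
        Conv3x3(cout, cout, rng), InstanceNorm(cout), ReLU(),
    ]


class UNet:
    """Encoder-decoder segmentation network producing per-pixel logits.

    ``forward`` returns logits; apply a sigmoid (``predict_proba``) for
    probabilities.  ``backward`` accepts the gradient of a scalar loss with
    respect to the logits and accumulates parameter gradients.
    """

    def __init__(self, config: UNetConfig | None = None, seed: int = 0) -> None:
        self.config = config or UNetConfig()
        rng = np.random.default_rng(seed)
        chans = self.config.level_channels
        self.enc_blocks: list[list[_Layer]] = []
        cin = self.config.in_channels
        for c in chans:
            self.enc_blocks.append(_conv_block(cin, c, rng))
            cin = c
        self.pools = [MaxPool2() for _ in chans[:-1]]
        self.ups = [Upsample2() for _ in chans[:-1]]
        self.dec_blocks: list[list[_Layer]] = []
        for skip_c, deep_c in zip(chans[-2::-1], chans[:0:-1]):
            self.dec_blocks.append(_conv_block(deep_c + skip_c, skip_c, rng))
        self.head = Conv1x1(chans[0], 1, rng)

    # -- plumbing ---------------------------------------------------------
    @property
    def layers(self) -> list[_Layer]:
        out: list[_Layer] = []
        for block in self.enc_blocks + self.dec_blocks:
            out.extend(block)
        out.extend(self.pools)
        out.extend(self.ups)
        out.append(self.head)
        return out

    @property
    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p for i, p in enumerate(self.parameters)}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters):
            p[...] = state[f"p{i}"]

    # -- computation ------------------------------------------------------
    def forward(self, image: np.ndarray) -> np.ndarray:
        """Logits for a single ``(H, W)`` or ``(C, H, W)`` image.

        Spatial dims must be divisible by ``2**(n_levels - 1)``; use
        :func:`pad_to_depth` / cropping for arbitrary sizes.
        """
        x = np.asarray(image, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        skips = []
        for i, block in enumerate(self.enc_blocks):
            for layer in block:
                x = layer.forward(x)
            if i < len(self.enc_blocks) - 1:
                skips.append(x)
                x = self.pools[i].forward(x)
        self._skip_channels = []
        for j, block in enumerate(self.dec_blocks):
            x = self.ups[j].forward(x)
            skip = skips[-1 - j]
            self._skip_channels.append((skip.shape[0], x.shape[0]))
            x = np.concatenate([skip, x], axis=0)
            for layer in block:
                x = layer.forward(x)
        return self.head.forward(x)[0]

    def backward(self, dlogits: np.ndarray) -> None:
        dx = self.head.backward(np.asarray(dlogits, dtype=np.float32)[None])
        dskips = []
        for j in range(len(self.dec_blocks) - 1, -1, -1):
            for layer in reversed(self.dec_blocks[j]):
                dx = layer.backward(dx)
            skip_c, _ = self._skip_channels[j]
            # decoder block j consumed encoder skip i = n_levels-2-j, so the
            # descending-j append order is ascending in i
            dskips.append(dx[:skip_c])
            dx = self.ups[j].backward(dx[skip_c:])
        for i in range(len(self.enc_blocks) - 1, -1, -1):
            if i < len(self.enc_blocks) - 1:
                dx = self.pools[i].backward(dx)
                dx = dx + dskips[i]
            for layer in reversed(self.enc_blocks[i]):
                dx = layer.backward(dx)

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        """Per-pixel probabilities for an image of arbitrary size.

        Pads reflectively to the pooling depth and crops the output back, so
        the result always matches the input dimensions.
        """
        x = np.asarray(image, dtype=np.float32)
        h, w = x.shape[-2:]
        d = 2 ** (self.config.n_levels - 1)
        ph, pw = (-h) % d, (-w) % d
        if ph or pw:
            pad = [(0, ph), (0, pw)] if x.ndim == 2 else [(0, 0), (0, ph), (0, pw)]
            x = np.pad(x, pad, mode="reflect")
        logits = self.forward(x)
        return _sigmoid(logits[:h, :w])


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def predict_mask(model: UNet, minip: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Binary input-artery mask from a MinIP image.

    Probabilities are binarized at ``threshold`` (default: the config's 0.5);
    the mask has exactly the input's spatial dimensions.
    """
    thr = model.config.binarize_threshold if threshold is None else threshold
    proba = model.predict_proba(minip)
    return (proba >= thr).astype(np.uint8)
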