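"""A compact convolutional network for B-factor regression, in numpy.

The architecture follows the multiscale-image pipeline: a (8, 10, 3)
persistence-image tensor passes through two 2x2 valid convolutions with
ReLU, a dropout of 0.5, a channelwise dense layer, and is flattened;
the flattened image code is concatenated with the auxiliary (local and
global) features and fed through dense layers of 218, 100 and 10 units
(ReLU) with dropouts of 0.5 and 0.25 between them, ending in a single
linear output neuron.  Training minimises mean squared error with Adam
at learning rate 0.001.

The network is written directly in numpy (forward and backward passes,
inverted dropout, Adam updates) and is deliberately small: it trains in
seconds on the synthetic fixtures used here, and its gradients are
verified against finite differences in the test suite.  All randomness
(initialisation, dropout masks, batch shuffling) flows from one integer
seed, so training is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

IMAGE_SHAPE = (8, 10, 3)


@dataclass(frozen=True)
class CNNConfig:
    learning_rate: float = 0.001
    epochs: int = 1000
    batch_size: int = 1000
    conv_filters: tuple = (8, 16)
    image_dense: int = 8
    head: tuple = (218, 100, 10)
    dropouts: tuple = (0.5, 0.5, 0.25)  # post-conv, post-218, post-100


def _relu(x):
    return np.maximum(x, 0.0)


class _Adam:
    def __init__(self, params, lr):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps)


def _conv2x2_forward(x, w, b):
    """Valid 2x2 convolution: x (n, H, W, Cin) -> (n, H-1, W-1, Cout)."""
    n, H, W, _ = x.shape
    out = np.broadcast_to(b, (n, H - 1, W - 1, b.size)).copy()
    for di in (0, 1):
        for dj in (0, 1):
            out += np.tensordot(x[:, di:di + H - 1, dj:dj + W - 1, :],
                                w[di, dj], axes=([3], [0]))
    return out


def _conv2x2_backward(x, w, dout):
    n, H, W, cin = x.shape
    dw = np.zeros_like(w)
    db = dout.sum(axis=(0, 1, 2))
    dx = np.zeros_like(x)
    for di in (0, 1):
        for dj in (0, 1):
            window = x[:, di:di + H - 1, dj:dj + W - 1, :]
            dw[di, dj] = np.tensordot(window, dout, axes=([0, 1, 2],
                                                          [0, 1, 2]))
            dx[:, di:di + H - 1, dj:dj + W - 1, :] += np.tensordot(
                dout, w[di, dj], axes=([3], [1]))
    return dx, dw, db


class CNNRegressor:
    """Image + auxiliary-feature regressor with one linear output."""

    def __init__(self, n_aux: int, config: CNNConfig | None = None,
                 seed: int = 0):
        self.config = config or CNNConfig()
        self.n_aux = int(n_aux)
        rng = np.random.default_rng(seed)
        f1, f2 = self.config.conv_filters
        dimg = self.config.image_dense
        h1, h2, h3 = self.config.head
        rows, cols, chans = IMAGE_SHAPE
        flat = (rows - 2) * (cols - 2) * dimg

        def init(*shape):
            fan_in = int(np.prod(shape[:-1])) or 1
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.params = {
            "wc1": init(2, 2, chans, f1), "bc1": np.zeros(f1),
            "wc2": init(2, 2, f1, f2), "bc2": np.zeros(f2),
            "wd": init(f2, dimg), "bd": np.zeros(dimg),
            "w1": init(flat + self.n_aux, h1), "b1": np.zeros(h1),
            "w2": init(h1, h2), "b2": np.zeros(h2),
            "w3": init(h2, h3), "b3": np.zeros(h3),
            "wout": init(h3, 1), "bout": np.zeros(1),
        }
        self._rng = rng

    # -- forward / backward -------------------------------------------------

    def _forward(self, images, aux, train_rng=None):
        p, cfg = self.params, self.config
        cache = {}
        a1 = _relu(_conv2x2_forward(images, p["wc1"], p["bc1"]))
        a2 = _relu(_conv2x2_forward(a1, p["wc2"], p["bc2"]))
        drop = a2
        if train_rng is not None and cfg.dropouts[0] > 0:
            keep = 1 - cfg.dropouts[0]
            mask = (train_rng.random(a2.shape) < keep) / keep
            drop = a2 * mask
            cache["mask0"] = mask
        d = _relu(drop @ p["wd"] + p["bd"])       # channelwise dense
        flat = d.reshape(len(images), -1)
        z = np.concatenate([flat, aux], axis=1)
        h1 = _relu(z @ p["w1"] + p["b1"])
        h1d = h1
        if train_rng is not None and cfg.dropouts[1] > 0:
            keep = 1 - cfg.dropouts[1]
            mask = (train_rng.random(h1.shape) < keep) / keep
            h1d = h1 * mask
            cache["mask1"] = mask
        h2 = _relu(h1d @ p["w2"] + p["b2"])
        h2d = h2
        if train_rng is not None and cfg.dropouts[2] > 0:
            keep = 1 - cfg.dropouts[2]
            mask = (train_rng.random(h2.shape) < keep) / keep
            h2d = h2 * mask
            cache["mask2"] = mask
        h3 = _relu(h2d @ p["w3"] + p["b3"])
        out = (h3 @ p["wout"] + p["bout"]).ravel()
        cache.update(images=images, aux=aux, a1=a1, a2=a2, drop=drop, d=d,
                     flat=flat, z=z, h1=h1, h1d=h1d, h2=h2, h2d=h2d, h3=h3)
        return out, cache

    def _backward(self, cache, dout):
        p = self.params
        g = {}
        n = len(dout)
        dh3 = dout[:, None] @ p["wout"].T
        g["wout"] = cache["h3"].T @ dout[:, None]
        g["bout"] = dout.sum(keepdims=True)
        dh3 *= cache["h3"] > 0
        dh2d = dh3 @ p["w3"].T
        g["w3"] = cache["h2d"].T @ dh3
        g["b3"] = dh3.sum(axis=0)
        if "mask2" in cache:
            dh2d *= cache["mask2"]
        dh2 = dh2d * (cache["h2"] > 0)
        dh1d = dh2 @ p["w2"].T
        g["w2"] = cache["h1d"].T @ dh2
        g["b2"] = dh2.sum(axis=0)
        if "mask1" in cache:
            dh1d *= cache["mask1"]
        dh1 = dh1d * (cache["h1"] > 0)
        dz = dh1 @ p["w1"].T
        g["w1"] = cache["z"].T @ dh1
        g["b1"] = dh1.sum(axis=0)
        dflat = dz[:, :cache["flat"].shape[1]]
        dd = dflat.reshape(cache["d"].shape) * (cache["d"] > 0)
        g["wd"] = np.tensordot(cache["drop"], dd, axes=([0, 1, 2], [0, 1, 2]))
        g["bd"] = dd.sum(axis=(0, 1, 2))
        ddrop = np.tensordot(dd, p["wd"], axes=([3], [1]))
        if "mask0" in cache:
            ddrop *= cache["mask0"]
        da2 = ddrop * (cache["a2"] > 0)
        da1, g["wc2"], g["bc2"] = _conv2x2_backward(cache["a1"], p["wc2"],
                                                    da2)
        da1 *= cache["a1"] > 0
        _, g["wc1"], g["bc1"] = _conv2x2_backward(cache["images"], p["wc1"],
                                                  da1)
        return g

    # -- public API ---------------------------------------------------------

    def fit(self, images, aux, targets, verbose: bool = False):
        """Train with Adam on mini-batch MSE; returns per-epoch losses."""
        images = self._check_images(images)
        aux = np.asarray(aux, dtype=float)
        y = np.asarray(targets, dtype=float)
        cfg = self.config
        opt = _Adam(self.params, cfg.learning_rate)
        n = len(y)
        losses = []
        for epoch in range(cfg.epochs):
            order = self._rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                out, cache = self._forward(images[idx], aux[idx],
                                           train_rng=self._rng)
                err = out - y[idx]
                epoch_loss += float((err ** 2).sum())
                dout = 2.0 * err / len(idx)
                grads = self._backward(cache, dout)
                opt.step(self.params, grads)
            losses.append(epoch_loss / n)
            if verbose and (epoch % 50 == 0 or epoch == cfg.epochs - 1):
                print(f"epoch {epoch}: mse {losses[-1]:.4f}")
        return losses

    def predict(self, images, aux) -> np.ndarray:
        images = self._check_images(images)
        out, _ = self._forward(images, np.asarray(aux, dtype=float))
        return out

    @staticmethod
    def _check_images(images) -> np.ndarray:
        arr = np.asarray(images, dtype=float)
        if arr.ndim != 4 or arr.shape[1:] != IMAGE_SHAPE:
            raise ValueError(
                f"images must be (n, {IMAGE_SHAPE[0]}, {IMAGE_SHAPE[1]}, "
                f"{IMAGE_SHAPE[2]}), got {arr.shape}")
        return arr


def train_cnn(images, aux, targets, config: CNNConfig | None = None,
              seed: int = 0, verbose: bool = False) -> CNNRegressor:
    """Train the image + auxiliary-feature network; images should already
    be standardised (see :func:`aspholib.modeling.standardize_images`)."""
    model = CNNRegressor(n_aux=np.asarray(aux).shape[1], config=config,
                         seed=seed)
    model.fit(images, aux, targets, verbose=verbose)
    return model
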