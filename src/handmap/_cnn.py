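"""Minimal numpy convolutional network used by the map classifier.

One convolution layer (valid padding), batch normalization per filter,
ReLU, inverted dropout, a fully connected layer and softmax, trained
with cross-entropy and stochastic gradient descent with momentum.  Sized
for 2 x 5 x 20 inputs and tens-of-maps training sets, where a framework
dependency would be overkill; everything is plain dense linear algebra.
"""

from __future__ import annotations

import numpy as np

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


def _glorot_uniform(rng: np.random.Generator, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N, P, C*k*k) patches for a valid k x k convolution."""
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    # win: (N, C, H-k+1, W-k+1, k, k) -> (N, P, C*k*k)
    n, c, ho, wo, _, _ = win.shape
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * k * k)


class SmallConvNet:
    """Conv(k x k, F filters) -> BN -> ReLU -> Dropout -> FC -> softmax."""

    def __init__(
        self,
        input_shape: tuple[int, int, int],
        n_classes: int,
        kernel_size: int = 3,
        n_filters: int = 13,
        dropout: float = 0.5,
        rng: np.random.Generator | None = None,
    ):
        c, h, w = input_shape
        k = kernel_size
        if h < k or w < k:
            raise ValueError(f"input {input_shape} smaller than kernel {k}")
        self.input_shape = (c, h, w)
        self.k = k
        self.n_filters = n_filters
        self.n_classes = n_classes
        self.dropout = dropout
        self.out_hw = (h - k + 1, w - k + 1)
        n_patches = self.out_hw[0] * self.out_hw[1]
        self.flat_dim = n_patches * n_filters

        rng = rng or np.random.default_rng()
        fan_in = c * k * k
        self.W_conv = _glorot_uniform(
            rng, (fan_in, n_filters), fan_in, n_filters * k * k
        )
        self.b_conv = np.zeros(n_filters)
        self.gamma = np.ones(n_filters)
        self.beta = np.zeros(n_filters)
        self.run_mean = np.zeros(n_filters)
        self.run_var = np.ones(n_filters)
        self.W_fc = _glorot_uniform(
            rng, (self.flat_dim, n_classes), self.flat_dim, n_classes
        )
        self.b_fc = np.zeros(n_classes)
        self._params = ["W_conv", "b_conv", "gamma", "beta", "W_fc", "b_fc"]
        self._vel = {p: np.zeros_like(getattr(self, p)) for p in self._params}

    # ---- forward -----------------------------------------------------

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None):
        """Returns class probabilities and (in train mode) a cache for backprop."""
        n = x.shape[0]
        cols = _im2col(x, self.k)  # (N, P, CK)
        conv = cols @ self.W_conv + self.b_conv  # (N, P, F)

        if train:
            mu = conv.mean(axis=(0, 1))
            var = conv.var(axis=(0, 1))
            self.run_mean = _BN_MOMENTUM * self.run_mean + (1 - _BN_MOMENTUM) * mu
            self.run_var = _BN_MOMENTUM * self.run_var + (1 - _BN_MOMENTUM) * var
        else:
            mu, var = self.run_mean, self.run_var
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (conv - mu) * inv_std
        bn = self.gamma * xhat + self.beta

        relu = np.maximum(bn, 0.0)

        if train and self.dropout > 0:
            mask = (rng.random(relu.shape) >= self.dropout) / (1.0 - self.dropout)
            dropped = relu * mask
        else:
            mask = None
            dropped = relu

        flat = dropped.reshape(n, self.flat_dim)
        logits = flat @ self.W_fc + self.b_fc
        logits -= logits.max(axis=1, keepdims=True)
        expz = np.exp(logits)
        probs = expz / expz.sum(axis=1, keepdims=True)

        cache = None
        if train:
            cache = (cols, xhat, inv_std, relu, mask, flat, probs)
        return probs, cache

    # ---- backward + SGDM update --------------------------------------

    def train_step(
        self,
        x: np.ndarray,
        y_onehot: np.ndarray,
        lr: float,
        momentum: float,
        rng: np.random.Generator,
    ) -> float:
        probs, cache = self.forward(x, train=True, rng=rng)
        cols, xhat, inv_std, relu, mask, flat, _ = cache
        n = x.shape[0]
        loss = float(-np.sum(y_onehot * np.log(probs + 1e-12)) / n)

        dlogits = (probs - y_onehot) / n  # (N, K)
        grads = {
            "W_fc": flat.T @ dlogits,
            "b_fc": dlogits.sum(axis=0),
        }
        dflat = dlogits @ self.W_fc.T
        ddrop = dflat.reshape(relu.shape)
        if mask is not None:
            ddrop = ddrop * mask
        drelu = ddrop * (relu > 0)

        # batch-norm backward (per filter, statistics over N*P values)
        m = relu.shape[0] * relu.shape[1]
        grads["gamma"] = (drelu * xhat).sum(axis=(0, 1))
        grads["beta"] = drelu.sum(axis=(0, 1))
        dxhat = drelu * self.gamma
        dconv = (
            inv_std
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=(0, 1))
                - xhat * (dxhat * xhat).sum(axis=(0, 1))
            )
        )

        grads["W_conv"] = np.tensordot(cols, dconv, axes=([0, 1], [0, 1]))
        grads["b_conv"] = dconv.sum(axis=(0, 1))

        for p in self._params:
            v = self._vel[p]
            v *= momentum
            v -= lr * grads[p]
            getattr(self, p).__iadd__(v)
        return loss

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        probs, _ = self.forward(x, train=False, rng=None)
        return probs
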