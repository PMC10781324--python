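"""Minimal differentiable layers for 1-D signal translation networks.

All layers follow a batch-first convention: sequence tensors are
(batch, length, channels).  Each layer stores its parameters and, after a
backward pass, the matching gradients, so a first-order optimizer can walk
the layer list.  Frozen layers keep accumulating gradients (gradients must
still flow through them) but are skipped by the optimizer.
"""

from __future__ import annotations

import numpy as np


def _act(name: str):
    if name == "relu":
        return lambda z: np.maximum(z, 0.0)
    if name == "sigmoid":
        return lambda z: 1.0 / (1.0 + np.exp(-z))
    if name == "tanh":
        return np.tanh
    if name == "linear":
        return lambda z: z
    raise ValueError(f"unknown activation {name!r}")


def _act_grad(name: str, out: np.ndarray) -> np.ndarray:
    # derivative expressed through the activation output
    if name == "relu":
        return (out > 0).astype(out.dtype)
    if name == "sigmoid":
        return out * (1.0 - out)
    if name == "tanh":
        return 1.0 - out**2
    if name == "linear":
        return np.ones_like(out)
    raise ValueError(name)


class Layer:
    """Base class; parameterless layers leave ``params`` empty."""

    kind = "layer"

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.frozen = False

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def out_shape(self, in_shape: tuple) -> tuple:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def describe(self) -> str:
        return self.kind


def _uniform_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Flatten(Layer):
    kind = "flatten"

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)

    def out_shape(self, in_shape: tuple) -> tuple:
        return (int(np.prod(in_shape)),)


class Reshape(Layer):
    kind = "reshape"

    def __init__(self, length: int, channels: int) -> None:
        super().__init__()
        self.length = length
        self.channels = channels

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.reshape(x.shape[0], self.length, self.channels)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(dout.shape[0], -1)

    def out_shape(self, in_shape: tuple) -> tuple:
        return (self.length, self.channels)


class Dense(Layer):
    kind = "dense"

    def __init__(self, n_in: int, n_out: int, activation: str, rng: np.random.Generator) -> None:
        super().__init__()
        self.n_in, self.n_out, self.activation = n_in, n_out, activation
        self.params["W"] = _uniform_init(rng, (n_in, n_out), n_in)
        self.params["b"] = _uniform_init(rng, (n_out,), n_in)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._out = _act(self.activation)(x @ self.params["W"] + self.params["b"])
        return self._out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dz = dout * _act_grad(self.activation, self._out)
        self.grads["W"] = self._x.T @ dz
        self.grads["b"] = dz.sum(axis=0)
        return dz @ self.params["W"].T

    def out_shape(self, in_shape: tuple) -> tuple:
        return (self.n_out,)

    def describe(self) -> str:
        return f"dense({self.n_out}, {self.activation})"


def _im2col(xp: np.ndarray, k: int) -> np.ndarray:
    """(B, Lp, C) padded input -> (B, L, k*C) sliding columns."""
    cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
    # cols: (B, L, C, k) -> (B, L, k, C)
    cols = cols.transpose(0, 1, 3, 2)
    b, l = cols.shape[:2]
    return np.ascontiguousarray(cols).reshape(b, l, -1)


def _col2im(dcols: np.ndarray, k: int, c: int, lp: int) -> np.ndarray:
    b, l = dcols.shape[:2]
    dcols = dcols.reshape(b, l, k, c)
    dxp = np.zeros((b, lp, c))
    for i in range(k):
        dxp[:, i : i + l] += dcols[:, :, i]
    return dxp


class Conv1D(Layer):
    """Length-preserving 1-D convolution (symmetric zero padding, odd k)."""

    kind = "conv1d"

    def __init__(self, c_in: int, c_out: int, kernel: int, activation: str, rng: np.random.Generator) -> None:
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for symmetric padding")
        self.c_in, self.c_out, self.kernel, self.activation = c_in, c_out, kernel, activation
        fan_in = c_in * kernel
        self.params["W"] = _uniform_init(rng, (fan_in, c_out), fan_in)
        self.params["b"] = _uniform_init(rng, (c_out,), fan_in)

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.kernel // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        self._cols = _im2col(xp, self.kernel)
        self._lp = xp.shape[1]
        z = self._cols @ self.params["W"] + self.params["b"]
        self._out = _act(self.activation)(z)
        return self._out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dz = dout * _act_grad(self.activation, self._out)
        b, l, _ = dz.shape
        flat_cols = self._cols.reshape(b * l, -1)
        flat_dz = dz.reshape(b * l, -1)
        self.grads["W"] = flat_cols.T @ flat_dz
        self.grads["b"] = flat_dz.sum(axis=0)
        dcols = dz @ self.params["W"].T
        p = self.kernel // 2
        dxp = _col2im(dcols, self.kernel, self.c_in, self._lp)
        return dxp[:, p : p + l]

    def out_shape(self, in_shape: tuple) -> tuple:
        return (in_shape[0], self.c_out)

    def describe(self) -> str:
        return f"conv1d({self.c_out}, k{self.kernel}, {self.activation})"


class MaxPool1D(Layer):
    kind = "maxpool1d"

    def __init__(self, pool: int = 2) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, l, c = x.shape
        if l % self.pool:
            raise ValueError(f"length {l} not divisible by pool {self.pool}")
        xr = x.reshape(b, l // self.pool, self.pool, c)
        self._idx = xr.argmax(axis=2)
        self._in_shape = x.shape
        return xr.max(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, lo, c = dout.shape
        dxr = np.zeros((b, lo, self.pool, c))
        np.put_along_axis(dxr, self._idx[:, :, None, :], dout[:, :, None, :], axis=2)
        return dxr.reshape(self._in_shape)

    def out_shape(self, in_shape: tuple) -> tuple:
        return (in_shape[0] // self.pool, in_shape[1])

    def describe(self) -> str:
        return f"maxpool1d({self.pool})"


class ConvTranspose1D(Layer):
    """Learnable upsampling: zero-stuff the input by ``stride`` then apply a
    length-preserving convolution, so output length = input length * stride."""

    kind = "convtranspose1d"

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int, activation: str, rng: np.random.Generator) -> None:
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.c_in, self.c_out, self.kernel, self.stride = c_in, c_out, kernel, stride
        self.activation = activation
        fan_in = c_in * kernel
        self.params["W"] = _uniform_init(rng, (fan_in, c_out), fan_in)
        self.params["b"] = _uniform_init(rng, (c_out,), fan_in)

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, l, c = x.shape
        xd = np.zeros((b, l * self.stride, c))
        xd[:, :: self.stride] = x
        p = self.kernel // 2
        xp = np.pad(xd, ((0, 0), (p, p), (0, 0)))
        self._cols = _im2col(xp, self.kernel)
        self._lp = xp.shape[1]
        z = self._cols @ self.params["W"] + self.params["b"]
        self._out = _act(self.activation)(z)
        return self._out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dz = dout * _act_grad(self.activation, self._out)
        b, lo, _ = dz.shape
        flat_cols = self._cols.reshape(b * lo, -1)
        flat_dz = dz.reshape(b * lo, -1)
        self.grads["W"] = flat_cols.T @ flat_dz
        self.grads["b"] = flat_dz.sum(axis=0)
        dcols = dz @ self.params["W"].T
        p = self.kernel // 2
        dxd = _col2im(dcols, self.kernel, self.c_in, self._lp)[:, p : p + lo]
        return dxd[:, :: self.stride]

    def out_shape(self, in_shape: tuple) -> tuple:
        return (in_shape[0] * self.stride, self.c_out)

    def describe(self) -> str:
        return f"convtranspose1d({self.c_out}, k{self.kernel}, s{self.stride}, {self.activation})"


class LSTM(Layer):
    """Full-sequence LSTM (returns the hidden state at every step).

    Gate order in the fused weight matrices is (input, forget, cell, output);
    parameter count is 4 * ((n_in + units) * units + units).
    """

    kind = "lstm"

    def __init__(self, n_in: int, units: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.n_in, self.units = n_in, units
        fan_in = n_in + units
        self.params["Wx"] = _uniform_init(rng, (n_in, 4 * units), fan_in)
        self.params["Wh"] = _uniform_init(rng, (units, 4 * units), fan_in)
        self.params["b"] = _uniform_init(rng, (4 * units,), fan_in)

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, t, _ = x.shape
        u = self.units
        self._x = x
        self._i = np.empty((b, t, u))
        self._f = np.empty((b, t, u))
        self._g = np.empty((b, t, u))
        self._o = np.empty((b, t, u))
        self._c = np.empty((b, t, u))
        self._tc = np.empty((b, t, u))
        self._h = np.empty((b, t, u))
        h = np.zeros((b, u))
        c = np.zeros((b, u))
        Wx, Wh, bias = self.params["Wx"], self.params["Wh"], self.params["b"]
        xz = x @ Wx  # precompute input projections for all steps
        for s in range(t):
            z = xz[:, s] + h @ Wh + bias
            i = 1.0 / (1.0 + np.exp(-z[:, :u]))
            f = 1.0 / (1.0 + np.exp(-z[:, u : 2 * u]))
            g = np.tanh(z[:, 2 * u : 3 * u])
            o = 1.0 / (1.0 + np.exp(-z[:, 3 * u :]))
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            self._i[:, s], self._f[:, s], self._g[:, s] = i, f, g
            self._o[:, s], self._c[:, s], self._tc[:, s] = o, c, tc
            self._h[:, s] = h
        return self._h

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, t, _ = dout.shape
        u = self.units
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros_like(self.params["b"])
        dx = np.empty_like(self._x)
        dh_next = np.zeros((b, u))
        dc_next = np.zeros((b, u))
        for s in range(t - 1, -1, -1):
            i, f, g = self._i[:, s], self._f[:, s], self._g[:, s]
            o, c, tc = self._o[:, s], self._c[:, s], self._tc[:, s]
            c_prev = self._c[:, s - 1] if s > 0 else np.zeros((b, u))
            h_prev = self._h[:, s - 1] if s > 0 else np.zeros((b, u))
            dh = dout[:, s] + dh_next
            dc = dh * o * (1.0 - tc**2) + dc_next
            do = dh * tc
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dWx += self._x[:, s].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, s] = dz @ Wx.T
            dh_next = dz @ Wh.T
            dc_next = dc * f
        self.grads["Wx"], self.grads["Wh"], self.grads["b"] = dWx, dWh, db
        return dx

    def out_shape(self, in_shape: tuple) -> tuple:
        return (in_shape[0], self.units)

    def describe(self) -> str:
        return f"lstm({self.units}, tanh)"
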