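"""Trainable layers built on the :mod:`subcdr.autodiff` engine.

Layers follow the usual conventions: Glorot-uniform weight
initialization from an explicit :class:`numpy.random.Generator`,
``parameters()`` returning the flat list of trainable tensors, and
``__call__`` taking/returning :class:`~subcdr.autodiff.Tensor`.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat

__all__ = [
    "Module", "Linear", "MLP", "GRU", "Conv1d", "batch_norm", "dropout",
]


def glorot(rng: np.random.Generator, shape) -> Tensor:
    fan_in, fan_out = shape[-1], shape[-2] if len(shape) > 1 else shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Module:
    def parameters(self):
        params = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def state_arrays(self):
        return [p.data for p in self.parameters()]


class Linear(Module):
    def __init__(self, in_width: int, out_width: int, rng: np.random.Generator):
        self.W = glorot(rng, (out_width, in_width))
        self.b = Tensor(np.zeros(out_width), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W.T + self.b


class MLP(Module):
    """Stack of affine layers with leaky-ReLU between and optional dropout."""

    def __init__(self, widths, rng, dropout_p: float = 0.0):
        self.layers = [Linear(a, b, rng) for a, b in zip(widths[:-1], widths[1:])]
        self.dropout_p = dropout_p

    def __call__(self, x: Tensor, rng=None, train: bool = False) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.leaky_relu()
                if train and self.dropout_p > 0:
                    x = dropout(x, self.dropout_p, rng)
        return x


class GRUCell(Module):
    """One gated recurrent layer.

    Gates follow the update-gate-keeps-previous convention:
    ``r = sig(Wr d + Ur h)``, ``b = sig(Wb d + Ub h)``,
    ``o = tanh(Wh d + Ud (r*h))``, ``h' = b*h + (1-b)*o``.
    """

    def __init__(self, in_width: int, hidden: int, rng):
        self.Wr = glorot(rng, (hidden, in_width))
        self.Wb = glorot(rng, (hidden, in_width))
        self.Wh = glorot(rng, (hidden, in_width))
        self.Ur = glorot(rng, (hidden, hidden))
        self.Ub = glorot(rng, (hidden, hidden))
        self.Ud = glorot(rng, (hidden, hidden))
        self.hidden = hidden

    def step(self, d: Tensor, h: Tensor) -> Tensor:
        r = (d @ self.Wr.T + h @ self.Ur.T).sigmoid()
        b = (d @ self.Wb.T + h @ self.Ub.T).sigmoid()
        o = (d @ self.Wh.T + (r * h) @ self.Ud.T).tanh()
        return b * h + (1.0 - b) * o


class GRU(Module):
    """Multi-layer unidirectional GRU over a padded sequence batch.

    Input ``x`` has shape (batch, t, in_width); returns the full state
    sequence (batch, t, hidden) of the last layer. The initial state of
    every layer is the zero vector.
    """

    def __init__(self, in_width: int, hidden: int, num_layers: int, rng):
        self.cells = [
            GRUCell(in_width if i == 0 else hidden, hidden, rng)
            for i in range(num_layers)
        ]
        self.hidden = hidden

    def __call__(self, x: Tensor) -> Tensor:
        batch, t = x.shape[0], x.shape[1]
        seq = [x[:, i, :] for i in range(t)]
        for cell in self.cells:
            h = Tensor(np.zeros((batch, cell.hidden)))
            out = []
            for d in seq:
                h = cell.step(d, h)
                out.append(h)
            seq = out
        from .autodiff import stack

        return stack(seq, axis=1)


class Conv1d(Module):
    """1-D convolution with 'same' zero padding, stride 1.

    Input (batch, channels_in, length) -> (batch, channels_out, length).
    ``depthwise=True`` (requires c_in == c_out) convolves each channel
    independently — used on the cell side so that row i of the encoded
    matrix remains attributable to gene subset i rather than a mixture
    of all subsets. Implemented as a sum of shifted slice products,
    which the autodiff engine differentiates exactly.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng,
                 depthwise: bool = False):
        if depthwise and c_in != c_out:
            raise ValueError("depthwise convolution needs c_in == c_out")
        self.depthwise = depthwise
        if depthwise:
            limit = np.sqrt(6.0 / (2 * kernel))
            self.W = Tensor(rng.uniform(-limit, limit, size=(c_out, kernel)),
                            requires_grad=True)
        else:
            limit = np.sqrt(6.0 / (c_in * kernel + c_out * kernel))
            self.W = Tensor(rng.uniform(-limit, limit,
                                        size=(c_out, c_in, kernel)),
                            requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.kernel = kernel

    def __call__(self, x: Tensor) -> Tensor:
        batch, c_in, length = x.shape
        k = self.kernel
        left = (k - 1) // 2
        right = k - 1 - left
        pad_l = Tensor(np.zeros((batch, c_in, left)))
        pad_r = Tensor(np.zeros((batch, c_in, right)))
        xp = concat([pad_l, x, pad_r], axis=2)
        out = None
        for j in range(k):
            xs = xp[:, :, j:j + length]            # (B, Cin, L)
            if self.depthwise:
                term = xs * self.W[:, j].reshape(1, -1, 1)
            else:
                wj = self.W[:, :, j]               # (Cout, Cin)
                term = (xs.swapaxes(1, 2) @ wj.T).swapaxes(1, 2)
            out = term if out is None else out + term
        return out + self.b.reshape(1, -1, 1)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize each column of a (rows, features) tensor to zero mean, unit var."""
    mu = x.mean(axis=0, keepdims=True)
    var = ((x - mu) ** 2.0).mean(axis=0, keepdims=True)
    return (x - mu) * ((var + eps) ** -0.5) * gamma + beta


def dropout(x: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    mask = (rng.random(x.shape) >= p).astype(np.float64) / (1.0 - p)
    return x * Tensor(mask)
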