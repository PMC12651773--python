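"""A small fully-connected network core with explicit backpropagation.

The networks used throughout this package are tiny (at most a 12-dimensional
input, a few hundred rows, hidden widths of 128 or less), so they are written
directly on numpy: dense layers with ReLU hidden activations, optional
inverted dropout after selected hidden layers, mean-squared-error loss and an
Adam optimizer.  Everything is driven by explicit ``numpy.random.Generator``
instances, which makes initialization, batch order and dropout masks exactly
reproducible from a seed — a property the reproducibility contracts of the
training code depend on.

Weight initialization follows the uniform fan-in scheme
``U(-1/sqrt(fan_in), +1/sqrt(fan_in))`` for both weights and biases.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ShapeError


class MLP:
    """Multi-layer perceptron: ReLU hidden layers, linear output.

    Parameters
    ----------
    dims
        Layer widths including input and output, e.g. ``(11, 128, 64, 32, 1)``.
    rng
        Generator used for weight initialization.
    dropout
        Mapping from hidden-layer index (0-based, counting hidden layers only)
        to dropout probability, applied after that layer's activation.
    """

    def __init__(self, dims, rng: np.random.Generator, dropout: dict[int, float] | None = None):
        if len(dims) < 2:
            raise ShapeError("an MLP needs at least an input and an output layer")
        self.dims = tuple(int(d) for d in dims)
        self.dropout = dict(dropout or {})
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(self.dims[:-1], self.dims[1:]):
            k = 1.0 / np.sqrt(fan_in)
            self.W.append(rng.uniform(-k, k, size=(fan_in, fan_out)))
            self.b.append(rng.uniform(-k, k, size=fan_out))
        self.gW = [np.zeros_like(w) for w in self.W]
        self.gb = [np.zeros_like(bb) for bb in self.b]
        self._cache = None

    # -- bookkeeping --------------------------------------------------------

    @property
    def n_layers(self) -> int:
        return len(self.W)

    @property
    def n_params(self) -> int:
        return sum(w.size for w in self.W) + sum(bb.size for bb in self.b)

    def params(self) -> list[np.ndarray]:
        return self.W + self.b

    def grads(self) -> list[np.ndarray]:
        return self.gW + self.gb

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_state(self, state) -> None:
        for p, s in zip(self.params(), state):
            p[...] = np.asarray(s, float).reshape(p.shape)

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Forward pass; with ``train=True`` dropout is active and a cache is kept."""
        x = np.atleast_2d(np.asarray(x, float))
        if x.shape[1] != self.dims[0]:
            raise ShapeError(f"input has {x.shape[1]} columns, model expects {self.dims[0]}")
        if train and self.dropout and rng is None:
            raise ValueError("training forward pass with dropout needs an rng")
        acts = [x]          # post-activation (and post-dropout) outputs per layer
        pre = []            # pre-activation values of hidden layers
        masks: dict[int, np.ndarray] = {}
        h = x
        last = self.n_layers - 1
        for i, (w, bb) in enumerate(zip(self.W, self.b)):
            z = h @ w + bb
            if i == last:
                h = z
            else:
                pre.append(z)
                h = np.maximum(z, 0.0)
                p = self.dropout.get(i)
                if p and train:
                    mask = (rng.random(h.shape) >= p) / (1.0 - p)
                    h = h * mask
                    masks[i] = mask
            acts.append(h)
        self._cache = (acts, pre, masks) if train else None
        return h

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        """Backpropagate ``dL/d_output``; fills gradients, returns ``dL/d_input``."""
        if self._cache is None:
            raise RuntimeError("backward requires a prior forward(train=True)")
        acts, pre, masks = self._cache
        g = np.asarray(grad_out, float)
        last = self.n_layers - 1
        for i in range(last, -1, -1):
            if i != last:
                mask = masks.get(i)
                if mask is not None:
                    g = g * mask
                g = g * (pre[i] > 0)
            self.gW[i][...] = acts[i].T @ g
            self.gb[i][...] = g.sum(axis=0)
            g = g @ self.W[i].T
        return g


class Adam:
    """Adam optimizer over a fixed list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1.0 - self.b1) * g
            v[...] = self.b2 * v + (1.0 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean-squared error over all elements and its gradient w.r.t. ``pred``."""
    pred = np.asarray(pred, float)
    target = np.asarray(target, float)
    if pred.shape != target.shape:
        raise ShapeError(f"prediction shape {pred.shape} != target shape {target.shape}")
    diff = pred - target
    loss = float(np.mean(diff * diff))
    grad = 2.0 * diff / diff.size
    return loss, grad
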