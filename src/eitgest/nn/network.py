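"""Network containers, loss, and the Adam optimizer."""

from __future__ import annotations

import numpy as np

from .layers import Concat, Layer


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(p[np.arange(n), y] + eps).mean()
    grad = p
    grad[np.arange(n), y] -= 1.0
    return float(loss), grad / n


def accuracy(logits: np.ndarray, y: np.ndarray) -> float:
    return float((logits.argmax(axis=-1) == y).mean())


class Network:
    def forward(self, x, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad) -> None:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:  # pragma: no cover
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(v.size for v, _ in self.params())

    def predict_logits(self, x, batch_size: int = 512) -> np.ndarray:
        """Evaluation-mode forward pass in batches."""
        n = x[0].shape[0] if isinstance(x, tuple) else x.shape[0]
        outs = []
        for lo in range(0, n, batch_size):
            hi = lo + batch_size
            xb = tuple(a[lo:hi] for a in x) if isinstance(x, tuple) else x[lo:hi]
            outs.append(self.forward(xb, train=False))
        return np.concatenate(outs, axis=0)


class Sequential(Network):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


class DualNetwork(Network):
    """Two input branches, feature concatenation, shared head.

    The branches are structurally identical but separately parameterized (no
    weight sharing). Early fusion is expressed with empty branches and the
    concatenation feeding the head directly.
    """

    def __init__(self, branch_a: Sequential, branch_b: Sequential, head: Sequential):
        self.branch_a = branch_a
        self.branch_b = branch_b
        self.head = head
        self.concat = Concat()

    def forward(self, x, train):
        a, b = x
        fa = self.branch_a.forward(a, train)
        fb = self.branch_b.forward(b, train)
        return self.head.forward(self.concat.forward((fa, fb), train), train)

    def backward(self, grad):
        grad = self.head.backward(grad)
        ga, gb = self.concat.backward(grad)
        return self.branch_a.backward(ga), self.branch_b.backward(gb)

    def params(self):
        return self.branch_a.params() + self.branch_b.params() + self.head.params()


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(v) for v, _ in params]
        self.v = [np.zeros_like(v) for v, _ in params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for (val, grad), m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * grad
            v *= b2
            v += (1 - b2) * grad * grad
            val -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
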