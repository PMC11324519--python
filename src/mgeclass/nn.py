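"""Minimal NumPy neural-network primitives with manual backpropagation.

Everything the package's small networks need lives here: dense and strided
1-D convolution layers, an attention pooling layer over feature-map patches,
focal and supervised-contrastive losses, and Adam with optional gradient
centralization (weight-matrix gradients are re-centered to zero row mean
before the moment updates). All layers cache their forward inputs, so a
forward call must precede the matching backward call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Param:
    name: str
    value: np.ndarray
    grad: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.value = np.asarray(self.value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=axis, keepdims=True))


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient with respect to the logits."""
    n = logits.shape[0]
    logp = log_softmax(logits)
    loss = -logp[np.arange(n), labels].mean()
    grad = softmax(logits)
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n


def focal_loss(
    logits: np.ndarray, labels: np.ndarray, gamma: float = 2.0
) -> tuple[float, np.ndarray]:
    """Focal loss −(1−p_t)^γ log p_t, mean over the batch, plus gradient.

    At γ=0 this reduces exactly to cross-entropy.
    """
    n = logits.shape[0]
    p = softmax(logits)
    pt = p[np.arange(n), labels]
    logpt = log_softmax(logits)[np.arange(n), labels]
    one_minus = 1.0 - pt
    loss = float(np.mean(one_minus**gamma * -logpt))
    # dL/dp_t, then through the softmax Jacobian
    if gamma == 0:
        dpt = -1.0 / pt
    else:
        dpt = gamma * one_minus ** (gamma - 1) * logpt - one_minus**gamma / pt
    grad = np.zeros_like(p)
    onehot = np.zeros_like(p)
    onehot[np.arange(n), labels] = 1.0
    grad = dpt[:, None] * pt[:, None] * (onehot - p)
    return loss, grad / n


def l2_normalize(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norm = np.linalg.norm(z, axis=-1, keepdims=True)
    norm = np.maximum(norm, 1e-12)
    return z / norm, norm


def l2_normalize_backward(dy: np.ndarray, y: np.ndarray, norm: np.ndarray) -> np.ndarray:
    return (dy - y * np.sum(y * dy, axis=-1, keepdims=True)) / norm


def supcon_loss(
    z: np.ndarray, labels: np.ndarray, temperature: float = 0.1
) -> tuple[float, np.ndarray]:
    """Supervised contrastive loss over L2-normalized embeddings.

    Each sample is an anchor; its positives are the other samples sharing
    its label. Anchors with no positive are skipped. Returns the mean loss
    and the gradient with respect to the (already normalized) embeddings.
    """
    n = z.shape[0]
    labels = np.asarray(labels)
    sim = z @ z.T / temperature
    np.fill_diagonal(sim, -np.inf)
    logits = sim - sim.max(axis=1, keepdims=True)
    exps = np.exp(logits)
    alpha = exps / exps.sum(axis=1, keepdims=True)  # softmax over a != i

    pos = (labels[:, None] == labels[None, :]) & ~np.eye(n, dtype=bool)
    n_pos = pos.sum(axis=1)
    anchors = n_pos > 0
    if not anchors.any():
        return 0.0, np.zeros_like(z)
    logprob = logits - np.log(exps.sum(axis=1, keepdims=True))
    per_anchor = -np.where(pos, logprob, 0.0).sum(axis=1)[anchors] / n_pos[anchors]
    loss = float(per_anchor.mean())

    g = np.zeros_like(sim)
    g[anchors] = alpha[anchors] - pos[anchors] / n_pos[anchors, None]
    g /= anchors.sum()
    dz = (g + g.T) @ z / temperature
    return loss, dz


def centralize_gradient(g: np.ndarray) -> np.ndarray:
    """Gradient centralization: zero the mean across each leading slice.

    For a matrix this subtracts each row's mean; vectors and scalars pass
    through unchanged.
    """
    if g.ndim < 2:
        return g
    return g - g.mean(axis=tuple(range(1, g.ndim)), keepdims=True)


class Adam:
    """Adam with optional gradient centralization on multi-axis params."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        centralize: bool = True,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.centralize = centralize
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if self.centralize:
                g = centralize_gradient(g)
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / (1 - self.b1**self.t)
            vhat = self._v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Dense:
    """Fully connected layer y = x W + b."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, name: str = "dense"):
        scale = np.sqrt(2.0 / n_in)
        self.W = Param(f"{name}.W", rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param(f"{name}.b", np.zeros(n_out))
        self._x: np.ndarray | None = None

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        self.W.grad += x.reshape(-1, x.shape[-1]).T @ dy.reshape(-1, dy.shape[-1])
        self.b.grad += dy.reshape(-1, dy.shape[-1]).sum(axis=0)
        return dy @ self.W.value.T


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Conv1D:
    """1-D convolution, valid padding, configurable stride, over (B, L, C)."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        stride: int,
        rng: np.random.Generator,
        name: str = "conv",
    ):
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.W = Param(f"{name}.W", rng.normal(0.0, scale, size=(c_in, kernel, c_out)))
        self.b = Param(f"{name}.b", np.zeros(c_out))
        self.kernel = kernel
        self.stride = stride
        self._windows: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def out_length(self, L: int) -> int:
        return (L - self.kernel) // self.stride + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        # windows: (B, T, C_in, kernel)
        w = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=1)
        w = w[:, :: self.stride]
        T = self.out_length(x.shape[1])
        w = w[:, :T]
        self._windows = w
        self._in_shape = x.shape
        return np.einsum("btck,cko->bto", w, self.W.value, optimize=True) + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        w = self._windows
        self.W.grad += np.einsum("btck,bto->cko", w, dy, optimize=True)
        self.b.grad += dy.sum(axis=(0, 1))
        dx = np.zeros(self._in_shape)
        T = dy.shape[1]
        for j in range(self.kernel):
            # positions j, j+stride, ..., j+stride*(T-1)
            dx[:, j : j + self.stride * T : self.stride] += np.einsum(
                "bto,cko->btc", dy, self.W.value[:, j : j + 1], optimize=True
            ).reshape(dy.shape[0], T, -1)
        return dx


class PatchAttentionPool:
    """Attention over non-local feature-map patches, pooling to one vector.

    Patches are fixed slices of the feature map: patch p gathers positions
    (p, p+P, p+2P, ...) so that each patch spans the whole map and encodes
    non-local structure. Each patch's gathered features are scored by a
    learned attention head and the softmax-weighted sum of learned patch
    values forms the sequence embedding.
    """

    def __init__(
        self,
        n_positions: int,
        n_channels: int,
        n_patches: int,
        patch_size: int,
        dim: int,
        rng: np.random.Generator,
        name: str = "pool",
    ):
        self.patch_idx = np.stack(
            [
                (p + np.arange(patch_size) * n_patches) % n_positions
                for p in range(n_patches)
            ]
        )  # (P, m)
        d_in = patch_size * n_channels
        self.att = Dense(d_in, 1, rng, name=f"{name}.att")
        self.val = Dense(d_in, dim, rng, name=f"{name}.val")
        self._cache: tuple | None = None

    @property
    def params(self) -> list[Param]:
        return self.att.params + self.val.params

    def forward(self, fmap: np.ndarray) -> np.ndarray:
        B = fmap.shape[0]
        P, m = self.patch_idx.shape
        V = fmap[:, self.patch_idx, :].reshape(B, P, -1)  # (B, P, m*C)
        u = self.att.forward(V)[..., 0]  # (B, P)
        a = softmax(u, axis=1)
        vals = self.val.forward(V)  # (B, P, D)
        e = np.einsum("bp,bpd->bd", a, vals)
        self._cache = (fmap.shape, V, a, vals)
        return e

    def backward(self, de: np.ndarray) -> np.ndarray:
        fshape, V, a, vals = self._cache
        B, P, _ = V.shape
        dvals = a[..., None] * de[:, None, :]
        da = np.einsum("bpd,bd->bp", vals, de)
        du = a * (da - np.sum(a * da, axis=1, keepdims=True))
        dV = self.val.backward(dvals)
        dV += self.att.backward(du[..., None])
        dfmap = np.zeros(fshape)
        m = self.patch_idx.shape[1]
        dV = dV.reshape(B, P, m, -1)
        np.add.at(dfmap, (slice(None), self.patch_idx), dV)
        return dfmap


class MLP:
    """Dense/ReLU stack; the last layer is linear."""

    def __init__(
        self, sizes: list[int], rng: np.random.Generator, name: str = "mlp"
    ):
        self.layers: list = []
        for i in range(len(sizes) - 1):
            self.layers.append(Dense(sizes[i], sizes[i + 1], rng, name=f"{name}.{i}"))
            if i < len(sizes) - 2:
                self.layers.append(ReLU())

    @property
    def params(self) -> list[Param]:
        out = []
        for layer in self.layers:
            if isinstance(layer, Dense):
                out.extend(layer.params)
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def params_to_state(params: list[Param]) -> dict:
    return {p.name: p.value.tolist() for p in params}


def state_to_params(params: list[Param], state: dict) -> None:
    for p in params:
        value = np.asarray(state[p.name], dtype=np.float64)
        if value.shape != p.value.shape:
            raise ValueError(f"shape mismatch for {p.name}")
        p.value = value
        p.grad = np.zeros_like(value)
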