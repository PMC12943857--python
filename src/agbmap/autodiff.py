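"""Compact reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the tabular CNN-Transformer regressor: dense
linear algebra, ReLU, softmax, layer normalization, zero-padding/slicing
(for the convolution), elementwise maximum (for max pooling), dropout and
axis means. Every operation broadcasts like numpy; gradients of broadcast
operands are summed back onto the original shape.

Parameters carry ``requires_grad=True``; activations inherit the flag from
their parents. ``Tensor.backward()`` runs a topological sweep.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "DTYPE"]

#: working precision of the engine; float32 keeps the optimizer update and
#: gradient traffic (the cost drivers for many small parameter tensors)
#: memory-light while staying deterministic
DTYPE = np.float32

try:  # fused single-pass Adam update; numpy fallback below if unavailable
    from numba import njit

    @njit(cache=True)
    def _adam_kernel(flat, grad, m, v, b1, b2, alpha, eps2):  # pragma: no cover
        one = DTYPE(1.0)
        for i in range(flat.size):
            g = grad[i]
            m[i] = b1 * m[i] + (one - b1) * g
            v[i] = b2 * v[i] + (one - b2) * g * g
            flat[i] -= alpha * m[i] / (np.sqrt(v[i]) + eps2)

except ImportError:  # pragma: no cover
    _adam_kernel = None


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that were broadcast to reach its shape."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (gs, ss) in enumerate(zip(grad.shape, shape)):
        if ss == 1 and gs != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "_pin_grad")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None
        self._pin_grad = False

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        # The incoming array is borrowed, never mutated: the first
        # accumulation stores it as-is, later ones allocate a fresh sum.
        # Pinned gradients (optimizer-owned buffers) accumulate in place.
        if self._pin_grad:
            self.grad += g
        elif self.grad is None:
            self.grad = g
        else:
            self.grad = self.grad + g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- primitives ---------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        out._backward = back
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def back(g):
            if self.requires_grad:
                self._accum(-g)

        out._backward = back
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = back
        return out

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape))

        out._backward = back
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], parents=(self,))

        def back(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[key] = g
                self._accum(full)

        out._backward = back
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def back(g):
            if self.requires_grad:
                self._accum(g.reshape(self.shape))

        out._backward = back
        return out

    def moveaxis(self, src, dst):
        out = Tensor(np.moveaxis(self.data, src, dst), parents=(self,))

        def back(g):
            if self.requires_grad:
                self._accum(np.moveaxis(g, dst, src))

        out._backward = back
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))

        def back(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = back
        return out

    def maximum(self, other):
        """Elementwise max; ties route the gradient to ``self``."""
        other = self._lift(other)
        take_self = self.data >= other.data
        out = Tensor(np.where(take_self, self.data, other.data), parents=(self, other))

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * take_self, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * ~take_self, other.shape))

        out._backward = back
        return out

    def pad_axis(self, axis: int, before: int, after: int):
        """Zero-pad along one axis."""
        widths = [(0, 0)] * self.data.ndim
        widths[axis] = (before, after)
        out = Tensor(np.pad(self.data, widths), parents=(self,))
        sl = [slice(None)] * self.data.ndim
        sl[axis] = slice(before, before + self.data.shape[axis])
        sl = tuple(sl)

        def back(g):
            if self.requires_grad:
                self._accum(g[sl])

        out._backward = back
        return out

    def mean(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.mean(axis=axis, keepdims=keepdims), parents=(self,))
        n = self.data.size / out.data.size

        def back(g):
            if self.requires_grad:
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.shape) / n)

        out._backward = back
        return out

    def softmax(self):
        """Softmax over the last axis."""
        z = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=-1, keepdims=True)
        out = Tensor(s, parents=(self,))

        def back(g):
            if self.requires_grad:
                dot = (g * s).sum(axis=-1, keepdims=True)
                self._accum(s * (g - dot))

        out._backward = back
        return out

    def layernorm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Layer normalization over the last axis with affine parameters."""
        mu = self.data.mean(axis=-1, keepdims=True)
        xc = self.data - mu
        var = (xc**2).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        out = Tensor(xhat * gamma.data + beta.data, parents=(self, gamma, beta))
        d = self.data.shape[-1]

        def back(g):
            if gamma.requires_grad:
                gamma._accum(_unbroadcast(g * xhat, gamma.shape))
            if beta.requires_grad:
                beta._accum(_unbroadcast(g, beta.shape))
            if self.requires_grad:
                gx = g * gamma.data
                t1 = gx.sum(axis=-1, keepdims=True)
                t2 = (gx * xhat).sum(axis=-1, keepdims=True)
                self._accum(inv * (gx - t1 / d - xhat * t2 / d))

        out._backward = back
        return out

    def linear(self, w: "Tensor", b: "Tensor"):
        """Fused affine map x @ W + b (one graph node).

        When W is stacked per replica as (F, 1, d_in, d_out) and x is
        (F, B, T, d_in), the product runs as one batched GEMM per replica
        (merging B and T) instead of F*B tiny GEMMs, and the weight gradient
        contracts the batch axes directly without a broadcast intermediate.
        """
        fast = (
            self.data.ndim == 4
            and w.data.ndim == 4
            and w.data.shape[:2] == (self.data.shape[0], 1)
        )
        if fast:
            f, bb, t, di = self.data.shape
            do = w.data.shape[-1]
            x2 = self.data.reshape(f, bb * t, di)
            y = (x2 @ w.data[:, 0]).reshape(f, bb, t, do) + b.data
        else:
            y = self.data @ w.data + b.data
        out = Tensor(y, parents=(self, w, b))

        def back(g):
            if fast:
                f, bb, t, do = g.shape
                g2 = g.reshape(f, bb * t, do)
                if self.requires_grad:
                    self._accum((g2 @ np.swapaxes(w.data[:, 0], -1, -2)).reshape(self.shape))
                if w.requires_grad:
                    w._accum((np.swapaxes(x2, -1, -2) @ g2)[:, None])
                if b.requires_grad:
                    b._accum(_unbroadcast(g, b.shape))
                return
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(w.data, -1, -2), self.shape))
            if w.requires_grad:
                w._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, w.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        out._backward = back
        return out

    def mha_core(self, k: "Tensor", v: "Tensor", n_heads: int):
        """Fused multi-head scaled dot-product attention (self = queries).

        Inputs are (..., T, d); heads are split internally, the attention
        weights softmax(QK^T/sqrt(d_k)) applied to V, and the heads merged
        back to (..., T, d). Equivalent to composing reshape/moveaxis,
        matmul, scaling and softmax, in a single graph node.
        """
        q = self
        *lead, t, d = q.shape
        dk = d // n_heads
        scale = 1.0 / np.sqrt(dk)

        def split(a):
            return np.moveaxis(a.reshape(*lead, t, n_heads, dk), -2, -3)

        def merge(a):
            return np.moveaxis(a, -3, -2).reshape(*lead, t, d)

        qh, kh, vh = split(q.data), split(k.data), split(v.data)
        # token counts here are tiny, so the score/apply contractions run as
        # broadcast multiply-sums (one vectorized pass over all replicas,
        # batch rows and heads) rather than stacks of 2x2 GEMMs
        scores = (qh[..., :, None, :] * kh[..., None, :, :]).sum(-1) * scale
        scores -= scores.max(axis=-1, keepdims=True)
        e = np.exp(scores)
        s = e / e.sum(axis=-1, keepdims=True)
        out = Tensor(merge((s[..., None] * vh[..., None, :, :]).sum(-2)), parents=(q, k, v))

        def back(g):
            gh = split(g)
            if v.requires_grad:
                v._accum(merge((s[..., None] * gh[..., :, None, :]).sum(-3)))
            if q.requires_grad or k.requires_grad:
                ds = (gh[..., :, None, :] * vh[..., None, :, :]).sum(-1)
                dscore = s * (ds - (ds * s).sum(axis=-1, keepdims=True)) * scale
                if q.requires_grad:
                    q._accum(merge((dscore[..., None] * kh[..., None, :, :]).sum(-2)))
                if k.requires_grad:
                    k._accum(merge((dscore[..., :, None] * qh[..., :, None, :]).sum(-3)))

        out._backward = back
        return out

    def dropout(self, rate: float, rng: np.random.Generator, training: bool):
        """Inverted dropout; identity when not training or rate == 0."""
        if not training or rate <= 0:
            return self
        mask = (rng.random(self.shape, dtype=np.float32) >= rate).astype(DTYPE) / DTYPE(1.0 - rate)
        out = Tensor(self.data * mask, parents=(self,))

        def back(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = back
        return out


class Adam:
    """Adam with the standard defaults (beta1 0.9, beta2 0.999, eps 1e-8).

    Parameter data and gradients are repacked into single flat buffers so the
    update is a handful of whole-vector operations regardless of how many
    parameter tensors the model has; each tensor's ``data``/``grad`` become
    views into those buffers.
    """

    def __init__(self, params: list[Tensor], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        total = sum(p.data.size for p in params)
        self.flat = np.empty(total, dtype=DTYPE)
        self.flat_grad = np.zeros(total, dtype=DTYPE)
        pos = 0
        for p in params:
            n = p.data.size
            self.flat[pos : pos + n] = p.data.ravel()
            p.data = self.flat[pos : pos + n].reshape(p.data.shape)
            p.grad = self.flat_grad[pos : pos + n].reshape(p.data.shape)
            p._pin_grad = True
            pos += n
        self.m = np.zeros(total, dtype=DTYPE)
        self.v = np.zeros(total, dtype=DTYPE)
        self._tmp = np.empty(total, dtype=DTYPE)
        self._decay_mask = None

    def set_decay_mask(self, flags: list[bool]) -> None:
        """Mark which parameter tensors receive weight decay (one flag per
        tensor, in constructor order); biases and normalization parameters
        are conventionally excluded."""
        mask = np.zeros_like(self.flat)
        pos = 0
        for p, flag in zip(self.params, flags):
            n = p.data.size
            if flag:
                mask[pos : pos + n] = 1.0
            pos += n
        self._decay_mask = mask

    def apply_weight_decay(self, wd: float) -> None:
        """Add an L2 penalty gradient wd * theta (masked if configured)."""
        if self._decay_mask is None:
            self.flat_grad += wd * self.flat
        else:
            self.flat_grad += wd * self.flat * self._decay_mask

    def zero_grad(self) -> None:
        self.flat_grad.fill(0.0)

    def step(self) -> None:
        """Bias-corrected update, algebraically folded into the step size:

        flat -= [lr sqrt(1-b2^t)/(1-b1^t)] * m / (sqrt(v) + eps sqrt(1-b2^t))

        Runs as a single fused pass over the flat buffers when numba is
        available, otherwise as a short sequence of whole-vector numpy ops.
        """
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr2 = float(np.sqrt(1.0 - b2**self.t))
        alpha = float(self.lr * corr2 / (1.0 - b1**self.t))
        eps2 = float(self.eps * corr2)
        if _adam_kernel is not None:
            _adam_kernel(self.flat, self.flat_grad, self.m, self.v,
                         DTYPE(b1), DTYPE(b2), DTYPE(alpha), DTYPE(eps2))
            return
        g = self.flat_grad
        tmp = self._tmp
        self.m *= b1
        np.multiply(g, 1.0 - b1, out=tmp)
        self.m += tmp
        self.v *= b2
        np.multiply(g, g, out=tmp)
        tmp *= 1.0 - b2
        self.v += tmp
        np.sqrt(self.v, out=tmp)
        tmp += eps2
        np.divide(self.m, tmp, out=tmp)
        tmp *= alpha
        self.flat -= tmp
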