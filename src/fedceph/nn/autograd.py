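"""A compact reverse-mode automatic-differentiation engine on numpy arrays.

Implements exactly the primitives the package's convolutional classifiers
need: broadcast arithmetic, matmul, 2-D convolution (im2col), batch
normalization, max/avg/adaptive-average pooling, ReLU/sigmoid, concatenation,
reductions and a softmax cross-entropy loss.  Everything runs in float64 on
CPU; graphs are built per forward call and freed after ``backward``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "Parameter"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _result(data, parents, backward_fn) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward_fn
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64)
        else:
            self.grad += grad

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------

    @staticmethod
    def _as_tensor(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other) -> "Tensor":
        other = Tensor._as_tensor(other)

        def backward(grad):
            self._accum(_unbroadcast(grad, self.data.shape))
            other._accum(_unbroadcast(grad, other.data.shape))

        return Tensor._result(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(grad):
            self._accum(-grad)

        return Tensor._result(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._as_tensor(other))

    def __mul__(self, other) -> "Tensor":
        other = Tensor._as_tensor(other)

        def backward(grad):
            self._accum(_unbroadcast(grad * other.data, self.data.shape))
            other._accum(_unbroadcast(grad * self.data, other.data.shape))

        return Tensor._result(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        other = Tensor._as_tensor(other)
        a, b = self.data, other.data
        if a.ndim != 2 or b.ndim != 2:
            raise ValueError("matmul supports 2-D operands only")

        def backward(grad):
            self._accum(grad @ b.T)
            other._accum(a.T @ grad)

        return Tensor._result(a @ b, (self, other), backward)

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(grad):
            self._accum(grad.reshape(old))

        return Tensor._result(self.data.reshape(shape), (self,), backward)

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int = 1) -> "Tensor":
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def backward(grad):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                idx = [slice(None)] * grad.ndim
                idx[axis] = slice(lo, hi)
                t._accum(grad[tuple(idx)])

        data = np.concatenate([t.data for t in tensors], axis=axis)
        return Tensor._result(data, tuple(tensors), backward)

    # -- activations ----------------------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(grad):
            self._accum(grad * mask)

        return Tensor._result(self.data * mask, (self,), backward)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(grad):
            self._accum(grad * out_data * (1.0 - out_data))

        return Tensor._result(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------

    def mean(self, axis, keepdims: bool = False) -> "Tensor":
        axis = (axis,) if isinstance(axis, int) else tuple(axis)
        count = int(np.prod([self.data.shape[a] for a in axis]))
        shape_kept = list(self.data.shape)
        for a in axis:
            shape_kept[a] = 1

        def backward(grad):
            g = grad if keepdims else grad.reshape(shape_kept)
            self._accum(np.broadcast_to(g, self.data.shape) / count)

        return Tensor._result(
            self.data.mean(axis=axis, keepdims=keepdims), (self,), backward
        )

    def amax(self, axis, keepdims: bool = False) -> "Tensor":
        axis = (axis,) if isinstance(axis, int) else tuple(axis)
        out_data = self.data.max(axis=axis, keepdims=True)
        # ties split gradient equally, matching a subgradient choice
        mask = (self.data == out_data).astype(np.float64)
        mask /= mask.sum(axis=axis, keepdims=True)
        shape_kept = out_data.shape

        def backward(grad):
            g = grad if keepdims else grad.reshape(shape_kept)
            self._accum(mask * g)

        return Tensor._result(
            out_data if keepdims else out_data.reshape(
                [s for i, s in enumerate(self.data.shape) if i not in axis]
            ),
            (self,),
            backward,
        )

    # -- neural-network primitives -------------------------------------------

    def linear(self, weight: "Tensor", bias: "Tensor | None" = None) -> "Tensor":
        """``x @ weight.T + bias`` with x of shape (N, in), weight (out, in)."""
        x, w = self, weight

        def backward(grad):
            x._accum(grad @ w.data)
            w._accum(grad.T @ x.data)
            if bias is not None:
                bias._accum(grad.sum(axis=0))

        data = x.data @ w.data.T
        if bias is not None:
            data = data + bias.data
            parents = (x, w, bias)
        else:
            parents = (x, w)
        return Tensor._result(data, parents, backward)

    def conv2d(
        self,
        weight: "Tensor",
        bias: "Tensor | None" = None,
        stride: int = 1,
        padding: int = 0,
    ) -> "Tensor":
        """2-D cross-correlation. x: (N,C,H,W), weight: (O,C,kh,kw)."""
        x, w = self, weight
        N, C, H, W = x.data.shape
        O, Cw, kh, kw = w.data.shape
        if Cw != C:
            raise ValueError(f"conv2d channel mismatch: input {C}, kernel {Cw}")
        s, p = stride, padding
        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
        Hp, Wp = xp.shape[2], xp.shape[3]
        Ho = (Hp - kh) // s + 1
        Wo = (Wp - kw) // s + 1
        win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
        # (N, C, Ho, Wo, kh, kw) -> (N, Ho*Wo, C*kh*kw)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            N, Ho * Wo, C * kh * kw
        )
        wmat = w.data.reshape(O, C * kh * kw)
        out = cols @ wmat.T  # (N, L, O)
        if bias is not None:
            out = out + bias.data
        out = out.transpose(0, 2, 1).reshape(N, O, Ho, Wo)

        def backward(grad):
            gout = np.ascontiguousarray(
                grad.reshape(N, O, Ho * Wo).transpose(0, 2, 1)
            )  # (N, L, O)
            L = Ho * Wo
            if w.requires_grad:
                gw = gout.reshape(N * L, O).T @ cols.reshape(N * L, -1)
                w._accum(gw.reshape(O, C, kh, kw))
            if bias is not None and bias.requires_grad:
                bias._accum(gout.sum(axis=(0, 1)))
            if x.requires_grad:
                gcols = gout @ wmat  # (N, L, C*kh*kw)
                gcols = gcols.reshape(N, Ho, Wo, C, kh, kw)
                gxp = np.zeros((N, C, Hp, Wp))
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += (
                            gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                        )
                x._accum(gxp[:, :, p : p + H, p : p + W] if p else gxp)

        parents = (x, w) if bias is None else (x, w, bias)
        return Tensor._result(out, parents, backward)

    def max_pool2d(self, kernel: int, stride: int, padding: int = 0) -> "Tensor":
        x = self
        N, C, H, W = x.data.shape
        k, s, p = kernel, stride, padding
        if p:
            xp = np.pad(
                x.data, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf
            )
        else:
            xp = x.data
        Hp, Wp = xp.shape[2], xp.shape[3]
        Ho = (Hp - k) // s + 1
        Wo = (Wp - k) // s + 1
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        flat = win.reshape(N, C, Ho, Wo, k * k)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

        def backward(grad):
            gxp = np.zeros((N, C, Hp, Wp))
            for t in range(k * k):
                i, j = divmod(t, k)
                mask = (idx == t).astype(np.float64)
                gxp[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += mask * grad
            x._accum(gxp[:, :, p : p + H, p : p + W] if p else gxp)

        return Tensor._result(out, (x,), backward)

    def avg_pool2d(self, kernel: int, stride: int) -> "Tensor":
        x = self
        N, C, H, W = x.data.shape
        k, s = kernel, stride
        Ho = (H - k) // s + 1
        Wo = (W - k) // s + 1
        win = sliding_window_view(x.data, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        out = win.mean(axis=(-2, -1))

        def backward(grad):
            gx = np.zeros((N, C, H, W))
            g = grad / (k * k)
            for i in range(k):
                for j in range(k):
                    gx[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += g
            x._accum(gx)

        return Tensor._result(out, (x,), backward)

    def adaptive_avg_pool2d(self, out_h: int, out_w: int) -> "Tensor":
        """Adaptive average pooling with floor/ceil half-open bin boundaries.

        Bin ``b`` of ``out_h`` spans rows ``floor(b*H/out_h)`` to
        ``ceil((b+1)*H/out_h)`` (half-open); likewise for columns.  When the
        input is smaller than the grid, bins overlap/repeat rows.
        """
        x = self
        N, C, H, W = x.data.shape
        rb = [(int(np.floor(b * H / out_h)), int(np.ceil((b + 1) * H / out_h)))
              for b in range(out_h)]
        cb = [(int(np.floor(b * W / out_w)), int(np.ceil((b + 1) * W / out_w)))
              for b in range(out_w)]
        out = np.empty((N, C, out_h, out_w))
        for bi, (r0, r1) in enumerate(rb):
            for bj, (c0, c1) in enumerate(cb):
                out[:, :, bi, bj] = x.data[:, :, r0:r1, c0:c1].mean(axis=(2, 3))

        def backward(grad):
            gx = np.zeros((N, C, H, W))
            for bi, (r0, r1) in enumerate(rb):
                for bj, (c0, c1) in enumerate(cb):
                    gx[:, :, r0:r1, c0:c1] += grad[:, :, bi, bj][:, :, None, None] / (
                        (r1 - r0) * (c1 - c0)
                    )
            x._accum(gx)

        return Tensor._result(out, (x,), backward)

    def batch_norm2d(
        self,
        gamma: "Tensor",
        beta: "Tensor",
        running_mean: np.ndarray,
        running_var: np.ndarray,
        training: bool,
        momentum: float = 0.1,
        eps: float = 1e-5,
    ) -> "Tensor":
        """Per-channel batch normalization on (N,C,H,W).

        In training mode normalizes with (biased) batch statistics and
        updates the running buffers in place; in eval mode uses the buffers.
        """
        x = self
        N, C, H, W = x.data.shape
        if training:
            mean = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            running_mean *= 1.0 - momentum
            running_mean += momentum * mean
            running_var *= 1.0 - momentum
            running_var += momentum * var
        else:
            mean, var = running_mean, running_var
        invstd = 1.0 / np.sqrt(var + eps)
        xhat = (x.data - mean[None, :, None, None]) * invstd[None, :, None, None]
        out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
        m = N * H * W

        def backward(grad):
            if gamma.requires_grad:
                gamma._accum((grad * xhat).sum(axis=(0, 2, 3)))
            if beta.requires_grad:
                beta._accum(grad.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gxhat = grad * gamma.data[None, :, None, None]
                if training:
                    s1 = gxhat.sum(axis=(0, 2, 3), keepdims=True)
                    s2 = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                    gx = (invstd[None, :, None, None] / m) * (
                        m * gxhat - s1 - xhat * s2
                    )
                else:
                    gx = gxhat * invstd[None, :, None, None]
                x._accum(gx)

        return Tensor._result(out, (x, gamma, beta), backward)

    def cross_entropy(self, targets: np.ndarray) -> "Tensor":
        """Mean softmax cross-entropy of (N,K) logits against int targets."""
        x = self
        logits = x.data
        n = logits.shape[0]
        targets = np.asarray(targets, dtype=np.intp)
        shifted = logits - logits.max(axis=1, keepdims=True)
        logsumexp = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
        logp = shifted - logsumexp
        loss = -logp[np.arange(n), targets].mean()

        def backward(grad):
            softmax = np.exp(logp)
            softmax[np.arange(n), targets] -= 1.0
            x._accum(grad * softmax / n)

        return Tensor._result(loss, (x,), backward)

    # -- backprop -------------------------------------------------------------

    def backward(self) -> None:
        """Reverse-mode sweep from this (scalar or any-shape) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # free graph references
        for node in topo:
            if node is not self:
                node._backward = None
                node._parents = ()


class Parameter(Tensor):
    """A trainable tensor (persisted across forward passes)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
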