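"""A compact reverse-mode automatic-differentiation engine on numpy.

Implements exactly the operations the contact-pattern detector needs:
2-D convolution (im2col), ReLU, nearest-neighbour x2 upsampling for the
top-down pyramid pathway, dense layers, bilinear ROI pooling, and the
fused classification / box-regression / mask losses.  Tensors hold
float64 data; gradients accumulate on ``backward()`` over a topological
sort of the tape.  Everything is single-image (no batch axis on
feature maps): maps are small and CPU-bound, so simplicity wins.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """A node in the autodiff tape: value, gradient, backward closure."""

    __slots__ = ("data", "grad", "_prev", "_backward")

    def __init__(self, data, prev: tuple = ()):  # noqa: ANN001
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._prev = prev
        self._backward = None

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def backward(self) -> None:
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
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    # -- convenience arithmetic ------------------------------------------
    def __add__(self, other: "Tensor") -> "Tensor":
        return add(self, other)

    def __mul__(self, scalar: float) -> "Tensor":
        return scale(self, float(scalar))

    __rmul__ = __mul__


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def parameter(rng: np.random.Generator, shape: tuple, fan_in: int) -> Tensor:
    """He-normal initialised trainable tensor."""
    return Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape))


def zeros(shape: tuple) -> Tensor:
    return Tensor(np.zeros(shape))


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, prev=(a, b))

    def _bw() -> None:
        _accum(a, _unbroadcast(out.grad, a.data.shape))
        _accum(b, _unbroadcast(out.grad, b.data.shape))

    out._backward = _bw
    return out


def scale(a: Tensor, s: float) -> Tensor:
    out = Tensor(a.data * s, prev=(a,))

    def _bw() -> None:
        _accum(a, out.grad * s)

    out._backward = _bw
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(a.data * mask, prev=(a,))

    def _bw() -> None:
        _accum(a, out.grad * mask)

    out._backward = _bw
    return out


def reshape(a: Tensor, shape: tuple) -> Tensor:
    out = Tensor(a.data.reshape(shape), prev=(a,))

    def _bw() -> None:
        _accum(a, out.grad.reshape(a.data.shape))

    out._backward = _bw
    return out


def transpose(a: Tensor, axes: tuple) -> Tensor:
    out = Tensor(a.data.transpose(axes), prev=(a,))
    inv = np.argsort(axes)

    def _bw() -> None:
        _accum(a, out.grad.transpose(inv))

    out._backward = _bw
    return out


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw() -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * out.grad.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, out.grad[tuple(sl)])

    out._backward = _bw
    return out


def gather_rows(a: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx, dtype=int)
    out = Tensor(a.data[idx], prev=(a,))

    def _bw() -> None:
        g = np.zeros_like(a.data)
        np.add.at(g, idx, out.grad)
        _accum(a, g)

    out._backward = _bw
    return out


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """x (N, F) @ w (F, O) + b (O,)."""
    out = Tensor(x.data @ w.data + b.data, prev=(x, w, b))

    def _bw() -> None:
        _accum(x, out.grad @ w.data.T)
        _accum(w, x.data.T @ out.grad)
        _accum(b, out.grad.sum(axis=0))

    out._backward = _bw
    return out


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    win = win[:, ::stride, ::stride]  # (C, OH, OW, KH, KW)
    c, oh, ow = win.shape[:3]
    return win.transpose(1, 2, 0, 3, 4).reshape(oh * ow, c * kh * kw), oh, ow


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """x (C, H, W) -> (OC, OH, OW) with kernel w (OC, C, KH, KW)."""
    oc, c, kh, kw = w.data.shape
    xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad))) if pad else x.data
    cols, oh, ow = _im2col(xp, kh, kw, stride)
    wmat = w.data.reshape(oc, -1)
    out_mat = cols @ wmat.T + b.data
    out = Tensor(out_mat.T.reshape(oc, oh, ow), prev=(x, w, b))
    hp, wp = xp.shape[1], xp.shape[2]

    def _bw() -> None:
        gmat = out.grad.reshape(oc, oh * ow).T  # (OH*OW, OC)
        _accum(w, (gmat.T @ cols).reshape(w.data.shape))
        _accum(b, gmat.sum(axis=0))
        dcols = gmat @ wmat  # (OH*OW, C*KH*KW)
        c_idx = np.arange(c)[None, None, :, None, None]
        r_idx = (np.arange(oh) * stride)[:, None, None, None, None] + \
            np.arange(kh)[None, None, None, :, None]
        q_idx = (np.arange(ow) * stride)[None, :, None, None, None] + \
            np.arange(kw)[None, None, None, None, :]
        idx = np.broadcast_to(
            c_idx * (hp * wp) + r_idx * wp + q_idx, (oh, ow, c, kh, kw)
        ).reshape(oh * ow, -1)
        gxp = np.bincount(
            idx.ravel(), weights=dcols.ravel(), minlength=c * hp * wp
        ).reshape(c, hp, wp)
        _accum(x, gxp[:, pad:hp - pad, pad:wp - pad] if pad else gxp)

    out._backward = _bw
    return out


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour doubling of the two spatial axes of (C, H, W)."""
    out = Tensor(x.data.repeat(2, axis=1).repeat(2, axis=2), prev=(x,))
    c, h, w = x.data.shape

    def _bw() -> None:
        _accum(x, out.grad.reshape(c, h, 2, w, 2).sum(axis=(2, 4)))

    out._backward = _bw
    return out


def roi_align(x: Tensor, boxes: np.ndarray, out_size: int) -> Tensor:
    """Bilinear ROI pooling: x (C, H, W), boxes (R, 4) as (y0, x0, y1, x1)
    in the feature map's continuous coordinate frame -> (R, C, S, S).

    One sample point per output bin, at the bin centre; feature values
    live at cell centres (index + 0.5); out-of-bounds samples clamp to
    the border (never wrap).
    """
    boxes = np.asarray(boxes, dtype=float)
    c, h, w = x.data.shape
    r = boxes.shape[0]
    s = out_size
    if r == 0:
        return Tensor(np.zeros((0, c, s, s)))
    y0, x0, y1, x1 = boxes.T
    ys = y0[:, None] + (np.arange(s)[None, :] + 0.5) * ((y1 - y0) / s)[:, None]
    xs = x0[:, None] + (np.arange(s)[None, :] + 0.5) * ((x1 - x0) / s)[:, None]
    yy = np.clip(ys - 0.5, 0.0, h - 1.0)
    xx = np.clip(xs - 0.5, 0.0, w - 1.0)
    yi0 = np.floor(yy).astype(int)
    xi0 = np.floor(xx).astype(int)
    yi1 = np.minimum(yi0 + 1, h - 1)
    xi1 = np.minimum(xi0 + 1, w - 1)
    wy = yy - yi0  # (R, S)
    wx = xx - xi0

    Y0 = yi0[:, :, None]
    Y1 = yi1[:, :, None]
    X0 = xi0[:, None, :]
    X1 = xi1[:, None, :]
    WY = wy[:, :, None]
    WX = wx[:, None, :]
    w00 = (1 - WY) * (1 - WX)
    w01 = (1 - WY) * WX
    w10 = WY * (1 - WX)
    w11 = WY * WX

    def gather(Yi, Xi):  # -> (C, R, S, S)
        return x.data[:, np.broadcast_to(Yi, (r, s, s)), np.broadcast_to(Xi, (r, s, s))]

    v00 = gather(Y0, X0)
    v01 = gather(Y0, X1)
    v10 = gather(Y1, X0)
    v11 = gather(Y1, X1)
    vals = (
        w00[None] * v00 + w01[None] * v01 + w10[None] * v10 + w11[None] * v11
    )  # (C, R, S, S)
    out = Tensor(vals.transpose(1, 0, 2, 3), prev=(x,))

    corners = (
        (Y0, X0, w00), (Y0, X1, w01), (Y1, X0, w10), (Y1, X1, w11),
    )

    def _bw() -> None:
        g = out.grad.transpose(1, 0, 2, 3)  # (C, R, S, S)
        gflat = np.zeros(c * h * w)
        ch_off = (np.arange(c) * (h * w))[:, None]
        for Yi, Xi, wt in corners:
            idx = np.broadcast_to(Yi * w + Xi, (r, s, s)).ravel()
            contrib = (wt[None] * g).reshape(c, -1)
            full_idx = (ch_off + idx[None, :]).ravel()
            gflat += np.bincount(
                full_idx, weights=contrib.ravel(), minlength=c * h * w
            )
        _accum(x, gflat.reshape(c, h, w))

    out._backward = _bw
    return out


def sum_all(a: Tensor) -> Tensor:
    out = Tensor(a.data.sum(), prev=(a,))

    def _bw() -> None:
        _accum(a, np.full_like(a.data, out.grad))

    out._backward = _bw
    return out


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of (N, K) logits against integer labels."""
    labels = np.asarray(labels, dtype=int)
    n = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    ll = -np.log(np.clip(probs[np.arange(n), labels], 1e-12, None))
    out = Tensor(ll.mean(), prev=(logits,))

    def _bw() -> None:
        g = probs.copy()
        g[np.arange(n), labels] -= 1.0
        _accum(logits, out.grad * g / n)

    out._backward = _bw
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy of logits (any shape) against {0,1} targets."""
    targets = np.asarray(targets, dtype=float)
    z = logits.data
    loss = np.maximum(z, 0) - z * targets + np.log1p(np.exp(-np.abs(z)))
    n = max(z.size, 1)
    out = Tensor(loss.sum() / n, prev=(logits,))

    def _bw() -> None:
        _accum(logits, out.grad * (sigmoid(z) - targets) / n)

    out._backward = _bw
    return out


def smooth_l1(pred: Tensor, targets: np.ndarray) -> Tensor:
    """Mean smooth-L1 (Huber, delta=1) over all elements."""
    targets = np.asarray(targets, dtype=float)
    d = pred.data - targets
    ad = np.abs(d)
    loss = np.where(ad < 1.0, 0.5 * d * d, ad - 0.5)
    n = max(d.size, 1)
    out = Tensor(loss.sum() / n, prev=(pred,))

    def _bw() -> None:
        _accum(pred, out.grad * np.clip(d, -1.0, 1.0) / n)

    out._backward = _bw
    return out


class Adam:
    """Adam optimiser over a list of parameter Tensors."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
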