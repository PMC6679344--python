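"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The prediction model (convolutional branch, bidirectional LSTM branch,
path-level attention, softmax heads) is small enough to train on a CPU,
but its recurrence is non-standard, so the forward pass is written
against this tape rather than against a deep-learning framework.

Only the primitives the model needs are provided: elementwise arithmetic
with broadcasting, matrix multiplication, activations, concatenation,
gather, valid 2-D convolution, width-wise average pooling, log-softmax,
and segment (ragged-batch) softmax / summation used by the attention
layer. Gradients accumulate into ``Tensor.grad`` after ``backward()``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "take_rows", "conv2d", "avg_pool_w",
           "log_softmax", "segment_softmax", "segment_sum",
           "default_dtype", "set_default_dtype"]

# float64 keeps finite-difference gradient checks tight; training at scale
# may switch to float32 for speed (see set_default_dtype)
DTYPE = np.float64


def default_dtype():
    return DTYPE


def set_default_dtype(dtype):
    """Set the dtype new tensors are created with; returns the old one."""
    global DTYPE
    old = DTYPE
    DTYPE = np.dtype(dtype).type
    return old


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node on the autodiff tape wrapping a float ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # -- factory for op results -------------------------------------------
    @staticmethod
    def _op(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g):
        g = _unbroadcast(np.asarray(g, dtype=self.data.dtype), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(g)
            if b.requires_grad:
                b._accum(g)
        return Tensor._op(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(-g)
        return Tensor._op(-self.data, (self,), bwd)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(g * b.data)
            if b.requires_grad:
                b._accum(g * a.data)
        return Tensor._op(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(g @ b.data.T if b.data.ndim == 2 else np.outer(g, b.data))
            if b.requires_grad:
                b._accum(a.data.T @ g if a.data.ndim == 2 else np.outer(a.data, g))
        return Tensor._op(self.data @ other.data, (self, other), bwd)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        orig = self.data.shape
        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(g.reshape(orig))
        return Tensor._op(self.data.reshape(*shape), (self,), bwd)

    def __getitem__(self, idx):
        def bwd(g, a=self, idx=idx):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accum(full)
        return Tensor._op(self.data[idx], (self,), bwd)

    def sum(self, axis=None, keepdims=False):
        def bwd(g, a=self, axis=axis, keepdims=keepdims):
            if not a.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.data.shape))
        return Tensor._op(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- activations -------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        def bwd(g, a=self, mask=mask):
            if a.requires_grad:
                a._accum(g * mask)
        return Tensor._op(self.data * mask, (self,), bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        def bwd(g, a=self, y=out_data):
            if a.requires_grad:
                a._accum(g * y * (1.0 - y))
        return Tensor._op(out_data, (self,), bwd)

    def tanh(self):
        out_data = np.tanh(self.data)
        def bwd(g, a=self, y=out_data):
            if a.requires_grad:
                a._accum(g * (1.0 - y * y))
        return Tensor._op(out_data, (self,), bwd)

    def exp(self):
        out_data = np.exp(self.data)
        def bwd(g, a=self, y=out_data):
            if a.requires_grad:
                a._accum(g * y)
        return Tensor._op(out_data, (self,), bwd)

    def log(self):
        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data)
        return Tensor._op(np.log(self.data), (self,), bwd)

    # -- backward pass -----------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order via iterative DFS
        topo, seen, stack = [], set(), [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


# -- free functions ---------------------------------------------------------

def concat(tensors, axis=0):
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    def bwd(g, ts=tensors, offs=offsets, axis=axis):
        for t, lo, hi in zip(ts, offs[:-1], offs[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])
    return Tensor._op(np.concatenate([t.data for t in tensors], axis=axis),
                      tensors, bwd)


def take_rows(x: Tensor, idx):
    """Gather rows of a 2-D tensor; backward scatter-adds."""
    idx = np.asarray(idx)
    def bwd(g, a=x, idx=idx):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)
    return Tensor._op(x.data[idx], (x,), bwd)


def _im2col(x: np.ndarray, kh: int, kw: int):
    """x: (B, C, H, W) -> (B, H-kh+1, W-kw+1, C*kh*kw) via stride tricks."""
    B, C, H, W = x.shape
    oh, ow = H - kh + 1, W - kw + 1
    s0, s1, s2, s3 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x, shape=(B, oh, ow, C, kh, kw), strides=(s0, s2, s3, s1, s2, s3))
    return cols.reshape(B, oh, ow, C * kh * kw)


def conv2d(x: Tensor, w: Tensor, b: Tensor):
    """Valid cross-correlation. x: (B, Cin, H, W); w: (Cout, Cin, kh, kw);
    b: (Cout,). Returns (B, Cout, H-kh+1, W-kw+1). No stride, no padding."""
    B, Cin, H, W = x.data.shape
    Cout, Cin2, kh, kw = w.data.shape
    if Cin != Cin2:
        raise ValueError(f"channel mismatch: input {Cin} vs kernel {Cin2}")
    if kh > H or kw > W:
        raise ValueError(
            f"kernel ({kh},{kw}) larger than input ({H},{W})")
    cols = _im2col(x.data, kh, kw)              # (B, oh, ow, Cin*kh*kw)
    wmat = w.data.reshape(Cout, -1)             # (Cout, Cin*kh*kw)
    out = cols @ wmat.T + b.data                # (B, oh, ow, Cout)
    out = np.moveaxis(out, -1, 1)               # (B, Cout, oh, ow)

    def bwd(g, x=x, w=w, b=b, cols=cols, wmat=wmat, kh=kh, kw=kw):
        g_ = np.moveaxis(g, 1, -1)              # (B, oh, ow, Cout)
        if b.requires_grad:
            b._accum(g_.sum(axis=(0, 1, 2)))
        if w.requires_grad:
            gw = np.tensordot(g_, cols, axes=([0, 1, 2], [0, 1, 2]))
            w._accum(gw.reshape(w.data.shape))
        if x.requires_grad:
            gcols = g_ @ wmat                   # (B, oh, ow, Cin*kh*kw)
            B, oh, ow, _ = gcols.shape
            Cin, H, W = x.data.shape[1:]
            gx = np.zeros_like(x.data)
            gcols = gcols.reshape(B, oh, ow, Cin, kh, kw)
            for di in range(kh):
                for dj in range(kw):
                    gx[:, :, di:di + oh, dj:dj + ow] += gcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
            x._accum(gx)
    return Tensor._op(out, (x, w, b), bwd)


def avg_pool_w(x: Tensor, pool: int):
    """Non-overlapping mean pooling along the width (last) axis only; a
    trailing remainder narrower than `pool` is truncated."""
    if pool == 1:
        return x
    W = x.data.shape[-1]
    ow = W // pool
    lead = x.data.shape[:-1]
    blocks = x.data[..., :ow * pool].reshape(*lead, ow, pool)
    out = blocks.mean(axis=-1)

    def bwd(g, x=x, pool=pool, ow=ow, W=W):
        if not x.requires_grad:
            return
        gx = np.zeros_like(x.data)
        gx[..., :ow * pool] = np.repeat(g, pool, axis=-1) / pool
        x._accum(gx)
    return Tensor._op(out, (x,), bwd)


def log_softmax(x: Tensor, axis=-1):
    m = x.data.max(axis=axis, keepdims=True)
    z = x.data - m
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out = z - lse
    sm = np.exp(out)

    def bwd(g, x=x, sm=sm, axis=axis):
        if x.requires_grad:
            x._accum(g - sm * g.sum(axis=axis, keepdims=True))
    return Tensor._op(out, (x,), bwd)


def segment_softmax(x: Tensor, seg: np.ndarray):
    """Softmax within contiguous-id segments of a 1-D tensor.

    `seg` assigns each entry to a segment; entries of a segment need not be
    contiguous. Used for attention over ragged path sets in a batch."""
    seg = np.asarray(seg)
    nseg = int(seg.max()) + 1 if seg.size else 0
    m = np.full(nseg, -np.inf, dtype=x.data.dtype)
    np.maximum.at(m, seg, x.data)
    e = np.exp(x.data - m[seg])
    denom = np.zeros(nseg, dtype=x.data.dtype)
    np.add.at(denom, seg, e)
    out = e / denom[seg]

    def bwd(g, x=x, out=out, seg=seg, nseg=nseg):
        if not x.requires_grad:
            return
        dot = np.zeros(nseg, dtype=x.data.dtype)
        np.add.at(dot, seg, g * out)
        x._accum(out * (g - dot[seg]))
    return Tensor._op(out, (x,), bwd)


def segment_sum(x: Tensor, seg: np.ndarray, n_segments: int):
    """Sum rows of a 2-D tensor into `n_segments` buckets by segment id."""
    seg = np.asarray(seg)
    out = np.zeros((n_segments, x.data.shape[1]), dtype=x.data.dtype)
    np.add.at(out, seg, x.data)

    def bwd(g, x=x, seg=seg):
        if x.requires_grad:
            x._accum(g[seg])
    return Tensor._op(out, (x,), bwd)
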