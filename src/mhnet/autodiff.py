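"""Minimal reverse-mode automatic differentiation on numpy arrays.

The registration model needs gradients through 3D convolutions, trilinear
resampling (the spatial-transformer warp), windowed statistics (local NCC)
and elementwise arithmetic.  This module provides a small tape-based
``Tensor`` with exactly those operations: each op records its parents and a
vector-Jacobian product, and :meth:`Tensor.backward` walks the tape in
reverse topological order.

Only what the package uses is implemented; broadcasting is supported for
elementwise ops via gradient un-broadcasting.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "leaky_relu",
    "conv3d",
    "upsample3",
    "grid_pull",
    "box_sum",
]


class Tensor:
    """A numpy array plus an optional gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad=False, _parents=(), _vjp=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _parents
        )
        self._parents = _parents
        self._vjp = _vjp

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self):
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autodiff ------------------------------------------------------------
    def backward(self, grad=None):
        """Accumulate gradients of ``self`` w.r.t. every reachable leaf."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad and not t._parents:
                t.grad = g if t.grad is None else t.grad + g
            if t._vjp is None:
                continue
            for p, pg in zip(t._parents, t._vjp(g)):
                if pg is None or not p.requires_grad:
                    continue
                acc = grads.get(id(p))
                grads[id(p)] = pg if acc is None else acc + pg

    def zero_grad(self):
        self.grad = None

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = self._coerce(other)
        return Tensor(
            self.data + other.data,
            _parents=(self, other),
            _vjp=lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, _parents=(self,), _vjp=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def _coerce(self, other):
        """Wrap ``other`` as a Tensor; scalars adopt this tensor's dtype so
        python floats never promote a float32 graph to float64."""
        if isinstance(other, Tensor):
            return other
        arr = np.asarray(other)
        if arr.ndim == 0:
            arr = arr.astype(self.dtype)
        return Tensor(arr)

    def __mul__(self, other):
        other = self._coerce(other)
        return Tensor(
            self.data * other.data,
            _parents=(self, other),
            _vjp=lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        return Tensor(
            self.data / other.data,
            _parents=(self, other),
            _vjp=lambda g: (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            ),
        )

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        return Tensor(
            self.data**exponent,
            _parents=(self,),
            _vjp=lambda g: (g * exponent * self.data ** (exponent - 1),),
        )

    def sqrt(self):
        out = np.sqrt(self.data)
        return Tensor(out, _parents=(self,), _vjp=lambda g: (g * 0.5 / out,))

    # -- reductions / indexing -----------------------------------------------
    def sum(self):
        return Tensor(
            np.sum(self.data, keepdims=False),
            _parents=(self,),
            _vjp=lambda g: (np.broadcast_to(g, self.shape).copy(),),
        )

    def mean(self):
        n = self.data.size
        return Tensor(
            np.mean(self.data),
            _parents=(self,),
            _vjp=lambda g: (np.broadcast_to(g / n, self.shape).copy(),),
        )

    def reshape(self, *shape):
        return Tensor(
            self.data.reshape(*shape),
            _parents=(self,),
            _vjp=lambda g: (g.reshape(self.shape),),
        )

    def __getitem__(self, key):
        def vjp(g):
            full = np.zeros(self.shape, dtype=g.dtype)
            np.add.at(full, key, g)
            return (full,)

        return Tensor(self.data[key], _parents=(self,), _vjp=vjp)


def as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == tuple(shape):
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


# ---------------------------------------------------------------------------
# structural ops
# ---------------------------------------------------------------------------

def concat(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        _parents=tuple(tensors),
        _vjp=vjp,
    )


def leaky_relu(x, slope=0.2):
    x = as_tensor(x)
    mask = x.data >= 0
    scale = np.where(mask, 1.0, slope).astype(x.dtype)
    return Tensor(x.data * scale, _parents=(x,), _vjp=lambda g: (g * scale,))


# ---------------------------------------------------------------------------
# 3D convolution
# ---------------------------------------------------------------------------

def _kernel_slices(k, stride, out_shape):
    """The strided input slice aligned with each kernel offset (i, j, l)."""
    ox, oy, oz = out_shape
    for i in range(k):
        si = slice(i, i + stride * (ox - 1) + 1, stride)
        for j in range(k):
            sj = slice(j, j + stride * (oy - 1) + 1, stride)
            for l in range(k):
                sl = slice(l, l + stride * (oz - 1) + 1, stride)
                yield (i, j, l), (slice(None), si, sj, sl)


def conv3d(x, weight, bias=None, stride=1, pad=None):
    """3D cross-correlation of a (C_in, X, Y, Z) tensor.

    ``weight`` has shape (C_out, C_in, k, k, k); ``pad`` defaults to the
    'same' padding (k - 1) // 2 so stride-1 convs preserve spatial shape.
    Implemented as one small GEMM per kernel offset, which keeps peak
    memory at one channel-slice copy instead of a full im2col buffer.
    """
    x = as_tensor(x)
    weight = as_tensor(weight)
    c_out, c_in, k = weight.shape[0], weight.shape[1], weight.shape[2]
    if x.shape[0] != c_in:
        raise ValueError(
            f"conv3d channel mismatch: input has {x.shape[0]}, weight expects {c_in}"
        )
    if pad is None:
        pad = (k - 1) // 2
    xp = (
        np.pad(x.data, ((0, 0), (pad, pad), (pad, pad), (pad, pad)))
        if pad
        else x.data
    )
    out_shape = tuple((s - k) // stride + 1 for s in xp.shape[1:])
    wd = weight.data
    dtype = np.result_type(x.dtype, wd.dtype)
    yf = np.zeros((c_out, int(np.prod(out_shape))), dtype=dtype)
    for (i, j, l), sl in _kernel_slices(k, stride, out_shape):
        yf += wd[:, :, i, j, l] @ xp[sl].reshape(c_in, -1)
    y = yf.reshape(c_out, *out_shape)
    parents = [x, weight]
    if bias is not None:
        bias = as_tensor(bias)
        y = y + bias.data.reshape(-1, 1, 1, 1)
        parents.append(bias)

    def vjp(g):
        gf = np.ascontiguousarray(g.reshape(c_out, -1))
        gw = np.empty_like(wd)
        gxp = np.zeros_like(xp) if x.requires_grad else None
        for (i, j, l), sl in _kernel_slices(k, stride, out_shape):
            xs = xp[sl].reshape(c_in, -1)
            gw[:, :, i, j, l] = gf @ xs.T
            if gxp is not None:
                gxp[sl] += (wd[:, :, i, j, l].T @ gf).reshape(c_in, *out_shape)
        gx = None
        if gxp is not None:
            gx = gxp[:, pad:-pad, pad:-pad, pad:-pad] if pad else gxp
        grads = [gx, gw]
        if bias is not None:
            grads.append(g.sum(axis=(1, 2, 3)))
        return tuple(grads)

    return Tensor(y, _parents=tuple(parents), _vjp=vjp)


# ---------------------------------------------------------------------------
# trilinear upsampling (separable, half-pixel centres, clamped)
# ---------------------------------------------------------------------------

def _axis_lerp(n_in, factor):
    out = np.arange(n_in * factor)
    c = np.clip((out + 0.5) / factor - 0.5, 0.0, n_in - 1.0)
    i0 = np.minimum(np.floor(c).astype(np.intp), max(n_in - 2, 0))
    t = c - i0
    i1 = np.minimum(i0 + 1, n_in - 1)
    return i0, i1, t


def upsample3(x, factor):
    """Trilinear upsampling of a (C, X, Y, Z) tensor by an integer factor."""
    x = as_tensor(x)
    plans = [_axis_lerp(n, factor) for n in x.shape[1:]]

    def fwd(a):
        for axis, (i0, i1, t) in enumerate(plans, start=1):
            sh = [1] * a.ndim
            sh[axis] = -1
            tt = t.reshape(sh).astype(a.dtype)
            a = np.take(a, i0, axis=axis) * (1 - tt) + np.take(a, i1, axis=axis) * tt
        return a

    def adj(g):
        for axis, (i0, i1, t) in enumerate(plans, start=1):
            sh = [1] * g.ndim
            sh[axis] = -1
            tt = t.reshape(sh).astype(g.dtype)
            n_in = x.shape[axis]
            out_sh = list(g.shape)
            out_sh[axis] = n_in
            acc = np.zeros(out_sh, dtype=g.dtype)
            gm = np.moveaxis(acc, axis, 0)
            np.add.at(gm, i0, np.moveaxis(g * (1 - tt), axis, 0))
            np.add.at(gm, i1, np.moveaxis(g * tt, axis, 0))
            g = acc
        return (g,)

    return Tensor(fwd(x.data), _parents=(x,), _vjp=adj)


# ---------------------------------------------------------------------------
# spatial-transformer sampling
# ---------------------------------------------------------------------------

def _corner_terms(img, u, mode):
    """Shared forward bookkeeping for grid_pull and its gradients."""
    C = img.shape[0]
    X, Y, Z = img.shape[1:]
    grid = np.meshgrid(
        np.arange(X, dtype=u.dtype),
        np.arange(Y, dtype=u.dtype),
        np.arange(Z, dtype=u.dtype),
        indexing="ij",
    )
    p = [grid[d] + u[d] for d in range(3)]
    dims = (X, Y, Z)
    if mode == "clamp":
        inside = [(p[d] > 0) & (p[d] < dims[d] - 1) for d in range(3)]
        q = [np.clip(p[d], 0.0, dims[d] - 1.0) for d in range(3)]
        i0 = [np.minimum(np.floor(q[d]).astype(np.intp), max(dims[d] - 2, 0)) for d in range(3)]
        t = [q[d] - i0[d] for d in range(3)]
        i1 = [i0[d] + 1 for d in range(3)]
        valid0 = valid1 = [np.ones_like(t[0], dtype=bool)] * 3
    elif mode == "zeros":
        inside = [np.ones_like(p[0], dtype=bool)] * 3
        i0f = [np.floor(p[d]) for d in range(3)]
        i0 = [i.astype(np.intp) for i in i0f]
        t = [p[d] - i0f[d] for d in range(3)]
        i1 = [i0[d] + 1 for d in range(3)]
        valid0 = [(i0[d] >= 0) & (i0[d] < dims[d]) for d in range(3)]
        valid1 = [(i1[d] >= 0) & (i1[d] < dims[d]) for d in range(3)]
        i0 = [np.clip(i0[d], 0, dims[d] - 1) for d in range(3)]
        i1 = [np.clip(i1[d], 0, dims[d] - 1) for d in range(3)]
    else:
        raise ValueError(f"unknown boundary mode {mode!r}")
    return i0, i1, t, valid0, valid1, inside


def grid_pull(img, u, mode="clamp"):
    """Sample ``img`` (C, X, Y, Z) at the displaced grid ``i + u(i)``.

    Trilinear interpolation over the 8 integer neighbours with weights
    prod_d (1 - |j_d - i'_d|); out-of-domain samples are clamped to the
    border or treated as zero depending on ``mode``.  Differentiable w.r.t.
    both the image and the displacement field.
    """
    img = as_tensor(img)
    u = as_tensor(u)
    if img.shape[1:] != u.shape[1:] or u.shape[0] != 3:
        raise ValueError(
            f"displacement shape {u.shape} incompatible with image shape {img.shape}"
        )
    i0, i1, t, valid0, valid1, inside = _corner_terms(img.data, u.data, mode)
    C = img.shape[0]
    out = np.zeros_like(img.data)
    gu_needed = u.requires_grad
    gu_terms = np.zeros((3, C, *img.shape[1:]), dtype=img.data.dtype) if gu_needed else None
    weights = []  # (idx triple, weight) per corner, kept for the vjp
    for cx in (0, 1):
        wx = (1 - t[0]) if cx == 0 else t[0]
        ix = i0[0] if cx == 0 else i1[0]
        vx = valid0[0] if cx == 0 else valid1[0]
        sx = -1.0 if cx == 0 else 1.0
        for cy in (0, 1):
            wy = (1 - t[1]) if cy == 0 else t[1]
            iy = i0[1] if cy == 0 else i1[1]
            vy = valid0[1] if cy == 0 else valid1[1]
            sy = -1.0 if cy == 0 else 1.0
            for cz in (0, 1):
                wz = (1 - t[2]) if cz == 0 else t[2]
                iz = i0[2] if cz == 0 else i1[2]
                vz = valid0[2] if cz == 0 else valid1[2]
                sz = -1.0 if cz == 0 else 1.0
                v = vx & vy & vz
                w = wx * wy * wz * v
                vals = img.data[:, ix, iy, iz]
                out += vals * w
                weights.append(((ix, iy, iz), w))
                if gu_needed:
                    gu_terms[0] += vals * (sx * wy * wz * v)
                    gu_terms[1] += vals * (wx * sy * wz * v)
                    gu_terms[2] += vals * (wx * wy * sz * v)

    def vjp(g):
        gimg = None
        if img.requires_grad:
            gimg = np.zeros_like(img.data)
            for (ix, iy, iz), w in weights:
                np.add.at(gimg, (slice(None), ix, iy, iz), g * w)
        gu = None
        if gu_needed:
            gu = np.empty_like(u.data)
            for d in range(3):
                gu[d] = (g * gu_terms[d]).sum(axis=0) * inside[d]
        return (gimg, gu)

    return Tensor(out, _parents=(img, u), _vjp=vjp)


# ---------------------------------------------------------------------------
# windowed sums (for local NCC)
# ---------------------------------------------------------------------------

def _box_sum_nd(a, w):
    """Moving-window sum of edge ``w`` (odd) along every axis, zero-padded."""
    r = w // 2
    for axis in range(a.ndim):
        n = a.shape[axis]
        pad = [(0, 0)] * a.ndim
        pad[axis] = (r + 1, r)
        cs = np.cumsum(np.pad(a, pad), axis=axis)
        hi = _take_range(cs, axis, r + 1 + np.arange(n) + r)
        lo = _take_range(cs, axis, r + 1 + np.arange(n) - r - 1)
        a = hi - lo
    return a


def _take_range(a, axis, idx):
    idx = np.clip(idx, 0, a.shape[axis] - 1)
    return np.take(a, idx, axis=axis)


def box_sum(x, window):
    """Differentiable moving-window sum (cube of edge ``window``, zero pad).

    Self-adjoint because the window is symmetric, so the vjp is another
    box sum of the incoming gradient.
    """
    if window % 2 != 1 or window < 1:
        raise ValueError("window must be an odd positive integer")
    x = as_tensor(x)
    return Tensor(
        _box_sum_nd(x.data, window),
        _parents=(x,),
        _vjp=lambda g: (_box_sum_nd(g, window),),
    )
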