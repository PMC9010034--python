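"""Minimal reverse-mode automatic differentiation over numpy arrays.

The fusion network is small (a handful of 3x3 convolutions, pooling, and
elementwise gates), so a tape-based engine with exactly the primitives the
architecture needs keeps the whole model transparent and dependency-free.
All primitives operate in float64; gradients are accumulated by a reverse
topological sweep from a scalar root.

Feature maps are (channels, height, width) arrays; convolution weights
follow the (out_channels, in_channels, kh, kw) layout.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "conv_transpose2d",
    "adaptive_avg_pool2d",
    "global_max_pool",
    "bilinear_upsample",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the closure needed to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
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

    def item(self) -> float:
        return float(self.data)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- autograd driver ------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar root")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic ----------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._coerce(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor._make(out_data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def relu(self):
        mask = self.data > 0.0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        return Tensor._make(s, (self,), backward)

    def abs(self):
        sign = np.sign(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * sign)

        return Tensor._make(np.abs(self.data), (self,), backward)

    def sqrt(self):
        root = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * 0.5 / root)

        return Tensor._make(root, (self,), backward)

    # -- reductions & reshapes ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        orig = self.shape
        out_data = self.data.reshape(*shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return Tensor._make(out_data, (self,), backward)

    def __getitem__(self, key):
        out_data = self.data[key]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accum(full)

        return Tensor._make(out_data, (self,), backward)

    def pad2d(self, pad_top: int, pad_bottom: int, pad_left: int, pad_right: int):
        """Zero-pad the trailing two (spatial) axes."""
        widths = [(0, 0)] * (self.ndim - 2) + [
            (pad_top, pad_bottom),
            (pad_left, pad_right),
        ]
        out_data = np.pad(self.data, widths)
        h, w = self.shape[-2], self.shape[-1]

        def backward(g):
            if self.requires_grad:
                sl = (Ellipsis, slice(pad_top, pad_top + h), slice(pad_left, pad_left + w))
                self._accum(g[sl])

        return Tensor._make(out_data, (self,), backward)

    def flip2d(self):
        """Reverse both spatial axes (used to express transposed convolution)."""
        out_data = self.data[..., ::-1, ::-1].copy()

        def backward(g):
            if self.requires_grad:
                self._accum(g[..., ::-1, ::-1])

        return Tensor._make(out_data, (self,), backward)

    def swap01(self):
        """Swap the first two axes (in/out channel transpose for conv weights)."""
        out_data = np.swapaxes(self.data, 0, 1).copy()

        def backward(g):
            if self.requires_grad:
                self._accum(np.swapaxes(g, 0, 1))

        return Tensor._make(out_data, (self,), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(int(lo), int(hi))
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


# ---------------------------------------------------------------------------
# Convolution primitives (stride 1; SAME/VALID padding) via im2col
# ---------------------------------------------------------------------------


def _im2col(padded: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(C, Hp, Wp) -> (H*W, C*kh*kw) patch matrix for stride-1 windows."""
    c = padded.shape[0]
    windows = np.lib.stride_tricks.sliding_window_view(padded, (kh, kw), axis=(1, 2))
    # windows: (C, H, W, kh, kw) -> (H, W, C, kh, kw)
    windows = windows.transpose(1, 2, 0, 3, 4)
    h, w = windows.shape[:2]
    return windows.reshape(h * w, c * kh * kw), h, w


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, padding: str = "same") -> Tensor:
    """2-D cross-correlation, stride 1.

    x: (Cin, H, W); weight: (Cout, Cin, kh, kw); bias: (Cout,) or None.
    padding 'same' keeps the spatial size (odd kernels); 'valid' shrinks it.
    """
    x = Tensor._coerce(x)
    weight = Tensor._coerce(weight)
    cout, cin, kh, kw = weight.shape
    if x.shape[0] != cin:
        raise ValueError(f"conv2d: input has {x.shape[0]} channels, weight expects {cin}")
    if padding == "same":
        pt, pl = (kh - 1) // 2, (kw - 1) // 2
        pb, pr = kh - 1 - pt, kw - 1 - pl
    elif padding == "valid":
        pt = pb = pl = pr = 0
    else:
        raise ValueError(f"unknown padding {padding!r}")

    padded = np.pad(x.data, ((0, 0), (pt, pb), (pl, pr)))
    cols, oh, ow = _im2col(padded, kh, kw)
    wmat = weight.data.reshape(cout, cin * kh * kw)
    out = cols @ wmat.T  # (oh*ow, cout)
    if bias is not None:
        out = out + bias.data
    out_data = out.T.reshape(cout, oh, ow)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gmat = g.reshape(cout, oh * ow).T  # (oh*ow, cout)
        if weight.requires_grad:
            weight._accum((gmat.T @ cols).reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(gmat.sum(axis=0))
        if x.requires_grad:
            dcols = gmat @ wmat  # (oh*ow, cin*kh*kw)
            dcols = dcols.reshape(oh, ow, cin, kh, kw)
            dpad = np.zeros_like(padded)
            for i in range(kh):
                for j in range(kw):
                    dpad[:, i : i + oh, j : j + ow] += dcols[:, :, :, i, j].transpose(2, 0, 1)
            h, w = x.shape[1], x.shape[2]
            self_slice = dpad[:, pt : pt + h, pl : pl + w]
            x._accum(self_slice)

    return Tensor._make(out_data, parents, backward)


def conv_transpose2d(
    x: Tensor, weight: Tensor, bias: Tensor | None = None, stride: int = 1
) -> Tensor:
    """Transposed convolution ("deconvolution"), odd kernels.

    x: (Cin, H, W); weight: (Cin, Cout, kh, kw). Output spatial size is
    stride * H (the SAME-style transposed geometry: padding k//2, output
    padding stride-1). Expressed through autograd primitives: zero-dilate,
    pad, then correlate with the spatially flipped, channel-swapped kernel.
    """
    x = Tensor._coerce(x)
    weight = Tensor._coerce(weight)
    cin, cout, kh, kw = weight.shape
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("conv_transpose2d supports odd kernels only")
    if x.shape[0] != cin:
        raise ValueError(f"conv_transpose2d: input has {x.shape[0]} channels, weight expects {cin}")
    h, w = x.shape[1], x.shape[2]
    s = int(stride)
    if s < 1:
        raise ValueError("stride must be >= 1")

    if s > 1:
        dil_data = np.zeros((cin, (h - 1) * s + 1, (w - 1) * s + 1))
        dil_data[:, ::s, ::s] = x.data

        def dil_backward(g, _x=x, _s=s):
            if _x.requires_grad:
                _x._accum(g[:, ::_s, ::_s])

        dilated = Tensor._make(dil_data, (x,), dil_backward)
    else:
        dilated = x

    p = kh // 2
    # pad so that a VALID correlation with the flipped kernel yields stride*H
    extra = s - 1  # output padding, applied at the bottom/right
    padded = dilated.pad2d(kh - 1 - p, kh - 1 - p + extra, kw - 1 - p, kw - 1 - p + extra)
    kernel = weight.flip2d().swap01()  # (Cout, Cin, kh, kw)
    out = conv2d(padded, kernel, bias=None, padding="valid")
    if bias is not None:
        out = out + bias.reshape(cout, 1, 1)
    return out


# ---------------------------------------------------------------------------
# Pooling and resampling primitives
# ---------------------------------------------------------------------------


def _pool_windows(size: int, grid: int):
    starts = [(i * size) // grid for i in range(grid)]
    ends = [-(-((i + 1) * size) // grid) for i in range(grid)]
    return starts, ends


def adaptive_avg_pool2d(x: Tensor, grid: int) -> Tensor:
    """Average-pool (C, H, W) onto a (C, grid, grid) output.

    Window i spans rows [floor(i*H/g), ceil((i+1)*H/g)); for H divisible by
    g these are the uniform non-overlapping blocks of the pyramid pooling.
    """
    x = Tensor._coerce(x)
    c, h, w = x.shape
    if grid < 1 or grid > h or grid > w:
        raise ValueError(f"pooling grid {grid} incompatible with spatial size {h}x{w}")
    rs, re = _pool_windows(h, grid)
    cs, ce = _pool_windows(w, grid)
    out_data = np.empty((c, grid, grid))
    for i in range(grid):
        for j in range(grid):
            out_data[:, i, j] = x.data[:, rs[i] : re[i], cs[j] : ce[j]].mean(axis=(1, 2))

    def backward(g):
        if not x.requires_grad:
            return
        dx = np.zeros_like(x.data)
        for i in range(grid):
            for j in range(grid):
                n = (re[i] - rs[i]) * (ce[j] - cs[j])
                dx[:, rs[i] : re[i], cs[j] : ce[j]] += g[:, i, j][:, None, None] / n
        x._accum(dx)

    return Tensor._make(out_data, (x,), backward)


def global_max_pool(x: Tensor) -> Tensor:
    """Per-channel spatial maximum: (C, H, W) -> (C,)."""
    x = Tensor._coerce(x)
    c = x.shape[0]
    flat = x.data.reshape(c, -1)
    idx = flat.argmax(axis=1)
    out_data = flat[np.arange(c), idx]

    def backward(g):
        if x.requires_grad:
            dflat = np.zeros_like(flat)
            dflat[np.arange(c), idx] = g
            x._accum(dflat.reshape(x.shape))

    return Tensor._make(out_data, (x,), backward)


def _bilinear_coeffs(n_in: int, n_out: int):
    """Pixel-center source coordinates with edge clamping."""
    scale = n_in / n_out
    src = (np.arange(n_out) + 0.5) * scale - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    return lo, hi, frac


def bilinear_upsample(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resample of (C, H, W) to (C, out_h, out_w), pixel-center aligned."""
    x = Tensor._coerce(x)
    c, h, w = x.shape
    y0, y1, fy = _bilinear_coeffs(h, out_h)
    x0, x1, fx = _bilinear_coeffs(w, out_w)
    wy0, wy1 = (1.0 - fy)[:, None], fy[:, None]
    wx0, wx1 = (1.0 - fx)[None, :], fx[None, :]
    out_data = (
        x.data[:, y0[:, None], x0[None, :]] * (wy0 * wx0)
        + x.data[:, y0[:, None], x1[None, :]] * (wy0 * wx1)
        + x.data[:, y1[:, None], x0[None, :]] * (wy1 * wx0)
        + x.data[:, y1[:, None], x1[None, :]] * (wy1 * wx1)
    )

    def backward(g):
        if not x.requires_grad:
            return
        dx = np.zeros_like(x.data)
        for rows, cols, wgt in (
            (y0, x0, wy0 * wx0),
            (y0, x1, wy0 * wx1),
            (y1, x0, wy1 * wx0),
            (y1, x1, wy1 * wx1),
        ):
            np.add.at(
                dx,
                (slice(None), rows[:, None], cols[None, :]),
                g * wgt,
            )
        x._accum(dx)

    return Tensor._make(out_data, (x,), backward)
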