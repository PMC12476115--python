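"""Minimal reverse-mode automatic differentiation on numpy arrays.

The dense-prediction model is small (embedding dims of 16-96, a single
transformer block, three depth-wise transposed convolutions), so a compact
tape-based engine over numpy is sufficient to train it on CPU. ``Tensor``
wraps an ndarray and records a closure per operation; ``Tensor.backward``
runs the tape in reverse topological order.

Only the primitives the model actually needs are implemented: broadcasted
arithmetic, batched matmul, reductions, shape ops, ``log cosh``, randomized
leaky ReLU, dropout, and a depth-wise 3D transposed convolution evaluated
via cached real FFTs (scipy.fft) or a direct tap loop, whichever is
cheaper for the operand sizes.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat"]


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
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autograd -------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accum(self, grad):
        if not self.requires_grad:
            return
        grad = _unbroadcast(grad, self.data.shape).astype(self.data.dtype, copy=False)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic -----------------------------------------------------------
    # scalars take a fast path as plain Python floats so they do not
    # promote float32 model tensors to float64
    def __add__(self, other):
        if isinstance(other, (int, float)) or np.isscalar(other):
            c = float(other)
            return Tensor._make(self.data + c, (self,),
                                lambda g: self._accum(g))
        other = Tensor.as_tensor(other)
        return Tensor._make(
            self.data + other.data,
            (self, other),
            lambda g: (self._accum(g), other._accum(g)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: self._accum(-g))

    def __sub__(self, other):
        if isinstance(other, (int, float)) or np.isscalar(other):
            return self + (-float(other))
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        if isinstance(other, (int, float)) or np.isscalar(other):
            return (-self) + float(other)
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)) or np.isscalar(other):
            c = float(other)
            return Tensor._make(self.data * c, (self,),
                                lambda g: self._accum(g * c))
        other = Tensor.as_tensor(other)
        return Tensor._make(
            self.data * other.data,
            (self, other),
            lambda g: (self._accum(g * other.data), other._accum(g * self.data)),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)) or np.isscalar(other):
            return self * (1.0 / float(other))
        other = Tensor.as_tensor(other)
        return Tensor._make(
            self.data / other.data,
            (self, other),
            lambda g: (
                self._accum(g / other.data),
                other._accum(-g * self.data / other.data**2),
            ),
        )

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, p: float):
        return Tensor._make(
            self.data**p,
            (self,),
            lambda g: self._accum(g * p * self.data ** (p - 1)),
        )

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = np.matmul(self.data, other.data)

        def backward(g):
            self._accum(np.matmul(g, np.swapaxes(other.data, -1, -2)))
            other._accum(np.matmul(np.swapaxes(self.data, -1, -2), g))

        return Tensor._make(out_data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g: self._accum(g * out_data))

    def log(self):
        return Tensor._make(
            np.log(self.data), (self,), lambda g: self._accum(g / self.data)
        )

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor._make(
            out_data, (self,), lambda g: self._accum(g * 0.5 / out_data)
        )

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._make(
            out_data, (self,), lambda g: self._accum(g * (1.0 - out_data**2))
        )

    def logcosh(self):
        # |x| + log1p(exp(-2|x|)) - log 2 is the overflow-safe log cosh
        a = np.abs(self.data)
        out_data = a + np.log1p(np.exp(-2.0 * a)) - float(np.log(2.0))
        return Tensor._make(
            out_data, (self,), lambda g: self._accum(g * np.tanh(self.data))
        )

    def clamp_min(self, lo: float):
        mask = self.data >= lo
        return Tensor._make(
            np.maximum(self.data, lo), (self,), lambda g: self._accum(g * mask)
        )

    def rrelu(self, lower: float, upper: float, rng: np.random.Generator | None):
        """Randomized leaky ReLU: negative slope ~U(lower, upper) per element
        while training, the mean slope in evaluation mode (rng=None)."""
        if rng is None:
            slope = np.full_like(self.data, (lower + upper) / 2.0)
        else:
            slope = rng.uniform(lower, upper, size=self.data.shape).astype(
                self.data.dtype
            )
        factor = np.where(self.data >= 0, 1.0, slope).astype(self.data.dtype)
        return Tensor._make(
            self.data * factor, (self,), lambda g: self._accum(g * factor)
        )

    def dropout(self, p: float, rng: np.random.Generator | None):
        """Inverted dropout; identity when rng is None (eval) or p == 0."""
        if rng is None or p <= 0.0:
            return self
        keep = (rng.random(self.data.shape) >= p) / (1.0 - p)
        keep = keep.astype(self.data.dtype)
        return Tensor._make(
            self.data * keep, (self,), lambda g: self._accum(g * keep)
        )

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(
                    g, axis if isinstance(axis, tuple) else (axis,)
                )
            self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor._make(
            self.data.reshape(shape),
            (self,),
            lambda g: self._accum(g.reshape(old)),
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(axes),
            (self,),
            lambda g: self._accum(g.transpose(inv)),
        )

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accum(full)

        return Tensor._make(self.data[idx], (self,), backward)

    def pad(self, pad_width):
        """Zero-pad; pad_width as for np.pad."""
        slices = tuple(
            slice(lo, lo + n) for (lo, _), n in zip(pad_width, self.data.shape)
        )
        return Tensor._make(
            np.pad(self.data, pad_width),
            (self,),
            lambda g: self._accum(g[slices]),
        )

    # -- composites -----------------------------------------------------------
    def softmax(self, axis=-1):
        shifted = self + Tensor(-self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    # -- depth-wise transposed 3D convolution ---------------------------------
    def dwconvt3d(self, weight: "Tensor", stride: int = 1, dilation: int = 1,
                  crop=None):
        """Depth-wise (groups == channels) transposed 3D convolution.

        self: (T, C, D, H, W) batched feature maps, weight: (C, k, k, k).
        Output spatial size per axis is (D-1)*stride + (k-1)*dilation + 1,
        then ``crop`` = ((lo, hi), ...) removes (or, if negative, zero-pads)
        each border. Equivalent to torch's ConvTranspose3d with
        groups=channels and padding implemented via the crop.
        """
        return _DwConvT3d.apply(self, weight, stride, dilation, crop)


class _DwConvT3d:
    """Forward/backward for the depth-wise transposed conv primitive.

    The forward pass, the gradient wrt the input, and the gradient wrt the
    weight are all correlations/convolutions of the zero-stuffed input,
    the dilated kernel, and the (uncropped) output gradient with one
    another, so one shared FFT of each operand serves all three — the
    weight gradient is even summed over the batch in the frequency domain.
    Tiny problems fall back to a direct tap loop.
    """

    DIRECT_TAP_LIMIT = 2_000_000  # taps * voxels below which the loop wins

    @staticmethod
    def apply(x: Tensor, w: Tensor, stride: int, dilation: int, crop):
        T, C, D, H, W = x.data.shape
        Cw, k0, k1, k2 = w.data.shape
        if Cw != C:
            raise ValueError("weight channels must match input channels")
        xs = _DwConvT3d._stuff(x.data, stride)
        wd = _DwConvT3d._dilate(w.data, dilation)
        taps = int(np.prod(wd.shape[-3:]))
        use_direct = (
            taps * xs[0, 0].size * T * C <= _DwConvT3d.DIRECT_TAP_LIMIT
        )
        full_shape = tuple(
            a + b - 1 for a, b in zip(xs.shape[-3:], wd.shape[-3:])
        )
        if use_direct:
            full = _DwConvT3d._direct_full(xs, wd)
            fft_cache = None
        else:
            full, fft_cache = _DwConvT3d._fft_full(xs, wd, full_shape)
        out = _DwConvT3d._crop(full, crop)

        def backward(g):
            gf = _DwConvT3d._uncrop(g, (T, C) + full_shape, crop)
            if use_direct:
                if x.requires_grad:
                    gxs = _DwConvT3d._direct_valid(gf, wd[None])
                    x._accum(
                        gxs[..., ::stride, ::stride, ::stride]
                        if stride > 1 else gxs
                    )
                if w.requires_grad:
                    gw_full = _DwConvT3d._direct_valid(gf, xs).sum(axis=0)
                    if dilation > 1:
                        gw_full = gw_full[:, ::dilation, ::dilation,
                                          ::dilation]
                    w._accum(gw_full)
                return
            from scipy.fft import irfftn, rfftn
            fsize, Xf, Wf = fft_cache
            Gf = rfftn(gf, s=fsize, axes=(2, 3, 4))
            if x.requires_grad:
                gxs = irfftn(Gf * np.conj(Wf[None]), s=fsize, axes=(2, 3, 4))
                gxs = gxs[..., :xs.shape[2], :xs.shape[3], :xs.shape[4]]
                gxs = gxs.astype(x.data.dtype)
                x._accum(
                    gxs[..., ::stride, ::stride, ::stride]
                    if stride > 1 else gxs
                )
            if w.requires_grad:
                gw_full = irfftn((Gf * np.conj(Xf)).sum(axis=0),
                                 s=fsize, axes=(1, 2, 3))
                gw_full = gw_full[
                    :, :wd.shape[1], :wd.shape[2], :wd.shape[3]
                ].astype(w.data.dtype)
                if dilation > 1:
                    gw_full = gw_full[:, ::dilation, ::dilation, ::dilation]
                w._accum(gw_full)

        return Tensor._make(out, (x, w), backward)

    @staticmethod
    def _fft_full(xs, wd, full_shape):
        """Full convolution via cached real FFTs of both operands."""
        from scipy.fft import irfftn, next_fast_len, rfftn
        fsize = tuple(next_fast_len(n) for n in full_shape)
        Xf = rfftn(xs, s=fsize, axes=(2, 3, 4))
        Wf = rfftn(wd, s=fsize, axes=(1, 2, 3))
        full = irfftn(Xf * Wf[None], s=fsize, axes=(2, 3, 4))
        full = full[..., :full_shape[0], :full_shape[1], :full_shape[2]]
        return full.astype(xs.dtype), (fsize, Xf, Wf)

    # helpers ---------------------------------------------------------------
    @staticmethod
    def _stuff(x, stride):
        if stride == 1:
            return x
        T, C, D, H, W = x.shape
        out = np.zeros(
            (T, C, (D - 1) * stride + 1, (H - 1) * stride + 1,
             (W - 1) * stride + 1),
            dtype=x.dtype,
        )
        out[..., ::stride, ::stride, ::stride] = x
        return out

    @staticmethod
    def _dilate(w, dilation):
        if dilation == 1:
            return w
        C, k0, k1, k2 = w.shape
        out = np.zeros(
            (C, (k0 - 1) * dilation + 1, (k1 - 1) * dilation + 1,
             (k2 - 1) * dilation + 1),
            dtype=w.dtype,
        )
        out[:, ::dilation, ::dilation, ::dilation] = w
        return out

    @staticmethod
    def _direct_full(xs, wd):
        T, C, D, H, W = xs.shape
        k0, k1, k2 = wd.shape[-3:]
        out = np.zeros((T, C, D + k0 - 1, H + k1 - 1, W + k2 - 1), xs.dtype)
        for a in range(k0):
            for b in range(k1):
                for c in range(k2):
                    coef = wd[:, a, b, c]
                    if not np.any(coef):
                        continue
                    out[:, :, a:a + D, b:b + H, c:c + W] += (
                        xs * coef[None, :, None, None, None]
                    )
        return out

    @staticmethod
    def _direct_valid(big, small):
        """Valid correlation: out[j] = sum_m big[j+m] * small[m]."""
        kd, kh, kw = small.shape[-3:]
        od = big.shape[2] - kd + 1
        oh = big.shape[3] - kh + 1
        ow = big.shape[4] - kw + 1
        bshape = np.broadcast_shapes(big.shape[:2], small.shape[:2])
        out = np.zeros(bshape + (od, oh, ow), dtype=big.dtype)
        for a in range(kd):
            for b in range(kh):
                for c in range(kw):
                    coef = small[..., a, b, c]
                    if not np.any(coef):
                        continue
                    out += big[..., a:a + od, b:b + oh, c:c + ow] \
                        * coef[..., None, None, None]
        return out

    @staticmethod
    def _crop(full, crop):
        if crop is None:
            return full
        out = full
        for ax, (lo, hi) in zip((2, 3, 4), crop):
            n = out.shape[ax]
            if lo > 0 or hi > 0:
                sl = [slice(None)] * out.ndim
                sl[ax] = slice(max(lo, 0), n - max(hi, 0))
                out = out[tuple(sl)]
            if lo < 0 or hi < 0:
                pw = [(0, 0)] * out.ndim
                pw[ax] = (max(-lo, 0), max(-hi, 0))
                out = np.pad(out, pw)
        return out

    @staticmethod
    def _uncrop(g, full_shape, crop):
        if crop is None:
            return np.ascontiguousarray(g)
        out = g
        for ax, (lo, hi) in zip((2, 3, 4), crop):
            if lo < 0 or hi < 0:
                sl = [slice(None)] * out.ndim
                sl[ax] = slice(max(-lo, 0),
                               out.shape[ax] - max(-hi, 0))
                out = out[tuple(sl)]
        padded = np.zeros(full_shape, dtype=g.dtype)
        sl = [slice(None)] * len(full_shape)
        for ax, (lo, hi) in zip((2, 3, 4), crop):
            sl[ax] = slice(max(lo, 0), full_shape[ax] - max(hi, 0))
        padded[tuple(sl)] = out
        return padded


def concat(tensors, axis=0):
    tensors = [Tensor.as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor._make(data, tensors, backward)
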