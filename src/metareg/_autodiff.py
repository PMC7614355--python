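"""Minimal reverse-mode automatic differentiation over numpy arrays.

Only the operations needed by the registration network and its
weakly-supervised loss are provided: 3D convolution, 2x average pooling,
2x linear upsampling, channel concatenation, leaky ReLU, trilinear
backward warping, zero-padded Gaussian smoothing, soft Dice and bending
energy.  Tensors are channel-first ``(C, D, H, W)`` or plain ``(D, H, W)``
grids; scalars are 0-d arrays.

The engine is deliberately small: each op stores a closure that scatters
the upstream gradient into its parents, and ``backward`` walks the graph
in reverse topological order.  All linear ops implement exact adjoints
(verified by dot-product tests), so gradients are exact up to float64
rounding.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np
from scipy import ndimage

#: float64 by default (exactness in tests and metrics); meta-training may
#: switch to float32 for speed via :func:`set_default_dtype`.
DTYPE = np.float64


def set_default_dtype(dtype) -> None:
    global DTYPE
    DTYPE = np.dtype(dtype).type


class Tensor:
    """Node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        value: np.ndarray,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.value.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=DTYPE, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.value.ndim != 0:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones((), dtype=DTYPE)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic ------------------------------------------
    def __add__(self, other: "Tensor | float") -> "Tensor":
        if not isinstance(other, Tensor):
            other = Tensor(np.asarray(other, dtype=DTYPE))
        out = Tensor(self.value + other.value, parents=(self, other))

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.value.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.value.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other: "Tensor | float") -> "Tensor":
        if not isinstance(other, Tensor):
            other = Tensor(np.asarray(other, dtype=DTYPE))
        out = Tensor(self.value * other.value, parents=(self, other))

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.value, self.value.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.value, other.value.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * (-1.0)

    def __sub__(self, other: "Tensor | float") -> "Tensor":
        return self + (-other if isinstance(other, Tensor) else -float(other))

    def __rsub__(self, other: float) -> "Tensor":
        return (-self) + float(other)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    g = np.asarray(g)
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def constant(x: np.ndarray) -> Tensor:
    return Tensor(np.asarray(x, dtype=DTYPE))


def parameter(x: np.ndarray) -> Tensor:
    return Tensor(np.asarray(x, dtype=DTYPE), requires_grad=True)


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    mask = x.value >= 0
    out = Tensor(np.where(mask, x.value, slope * x.value), parents=(x,))

    def bw(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accum(np.where(mask, g, slope * g))

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# 3D convolution (stride 1, zero "same" padding, odd kernels)
# ---------------------------------------------------------------------------

def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Channel-first 3D correlation: x (Ci,D,H,W), w (Co,Ci,k,k,k), b (Co,).

    Implemented as im2col + one matmul; the patch matrix is cached for
    the weight gradient, and the input gradient is a col2im fold.
    """
    ci, d, h, wd = x.value.shape
    co, ci2, kd, kh, kw = w.value.shape
    if ci != ci2:
        raise ValueError(f"channel mismatch: input {ci}, kernel {ci2}")
    pd, ph, pw = kd // 2, kh // 2, kw // 2
    pshape = (ci, d + 2 * pd, h + 2 * ph, wd + 2 * pw)
    xp = np.zeros(pshape, dtype=DTYPE)
    xp[:, pd:pd + d, ph:ph + h, pw:pw + wd] = x.value
    n = d * h * wd
    cols = np.empty((ci, kd * kh * kw, n), dtype=DTYPE)
    t = 0
    for i in range(kd):
        for j in range(kh):
            for k in range(kw):
                cols[:, t, :] = xp[:, i:i + d, j:j + h, k:k + wd].reshape(ci, n)
                t += 1
    cols = cols.reshape(ci * kd * kh * kw, n)
    w2 = w.value.reshape(co, ci * kd * kh * kw)
    y = (w2 @ cols).reshape(co, d, h, wd)
    if b is not None:
        y += b.value[:, None, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, parents=parents)

    def bw(g: np.ndarray) -> None:
        g2 = g.reshape(co, -1)
        if x.requires_grad:
            dcols = (w2.T @ g2).reshape(ci, kd, kh, kw, d, h, wd)
            gxp = np.zeros(pshape, dtype=DTYPE)
            for i in range(kd):
                for j in range(kh):
                    for k in range(kw):
                        gxp[:, i:i + d, j:j + h, k:k + wd] += dcols[:, i, j, k]
            x._accum(gxp[:, pd:pd + d, ph:ph + h, pw:pw + wd])
        if w.requires_grad:
            w._accum((g2 @ cols.T).reshape(w.value.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(1, 2, 3)))

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# resolution changes
# ---------------------------------------------------------------------------

def avg_pool2(x: Tensor) -> Tensor:
    """Mean over non-overlapping 2x2x2 blocks; spatial dims must be even."""
    c, d, h, w = x.value.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError(f"odd spatial shape {(d, h, w)} cannot be pooled by 2")
    v = x.value.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
    out = Tensor(v.mean(axis=(2, 4, 6)), parents=(x,))

    def bw(g: np.ndarray) -> None:
        if x.requires_grad:
            gg = np.broadcast_to(
                g[:, :, None, :, None, :, None] / 8.0,
                (c, d // 2, 2, h // 2, 2, w // 2, 2),
            )
            x._accum(gg.reshape(c, d, h, w))

    out._backward = bw
    return out


def _up1(v: np.ndarray, axis: int) -> np.ndarray:
    """Linear 2x upsampling along one axis: out[2i]=v[i], out[2i+1]=mid."""
    v = np.moveaxis(v, axis, 0)
    n = v.shape[0]
    out = np.empty((2 * n,) + v.shape[1:], dtype=v.dtype)
    out[0::2] = v
    out[1:-1:2] = 0.5 * (v[:-1] + v[1:])
    out[-1] = v[-1]
    return np.moveaxis(out, 0, axis)


def _up1_adj(g: np.ndarray, axis: int) -> np.ndarray:
    """Exact adjoint of :func:`_up1`."""
    g = np.moveaxis(g, axis, 0)
    n = g.shape[0] // 2
    out = np.array(g[0::2], copy=True)
    mid = g[1:-1:2]
    out[:-1] += 0.5 * mid
    out[1:] += 0.5 * mid
    out[-1] += g[-1]
    return np.moveaxis(out, 0, axis)


def upsample2(x: Tensor) -> Tensor:
    """Trilinear 2x upsampling of a (C,D,H,W) tensor (separable per axis)."""
    v = x.value
    for ax in (1, 2, 3):
        v = _up1(v, ax)
    out = Tensor(v, parents=(x,))

    def bw(g: np.ndarray) -> None:
        if x.requires_grad:
            for ax in (3, 2, 1):
                g = _up1_adj(g, ax)
            x._accum(g)

    out._backward = bw
    return out


def concat_channels(tensors: Iterable[Tensor]) -> Tensor:
    ts = list(tensors)
    sizes = [t.value.shape[0] for t in ts]
    out = Tensor(np.concatenate([t.value for t in ts], axis=0), parents=tuple(ts))

    def bw(g: np.ndarray) -> None:
        ofs = 0
        for t, c in zip(ts, sizes):
            if t.requires_grad:
                t._accum(g[ofs:ofs + c])
            ofs += c

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# trilinear backward warping (gradient w.r.t. the displacement field only)
# ---------------------------------------------------------------------------

def _corner_gather(vol: np.ndarray, coords: np.ndarray):
    """Pre-compute floor corners and clipped indices for trilinear sampling."""
    nd, nh, nw = vol.shape
    c = np.clip(coords, [[0.0]], np.array([nd - 1, nh - 1, nw - 1])[:, None])
    f = np.floor(c)
    # keep the base corner a valid cell origin so f+1 stays in range
    f = np.minimum(f, np.array([nd - 2, nh - 2, nw - 2])[:, None].clip(min=0))
    t = c - f
    i0 = f.astype(np.intp)
    return c, i0, t


def warp3(vol: np.ndarray, ddf: Tensor) -> Tensor:
    """Backward-warp ``vol`` (D,H,W) by displacement ``ddf`` (3,D,H,W), voxels.

    ``out(x) = vol(x + u(x))`` with trilinear interpolation and
    clamp-to-edge sampling.  The gradient flows into ``u`` only (the
    volume is data).  At clamped locations the coordinate gradient is
    zero, matching the flat extension of the volume.
    """
    vol = np.asarray(vol, dtype=DTYPE)
    nd, nh, nw = vol.shape
    if ddf.value.shape != (3, nd, nh, nw):
        raise ValueError(
            f"displacement grid {ddf.value.shape[1:]} does not match "
            f"volume grid {(nd, nh, nw)}")
    base = np.stack(np.meshgrid(
        np.arange(nd), np.arange(nh), np.arange(nw), indexing="ij"))
    coords = (base + ddf.value).reshape(3, -1)
    # clamping is per-axis: a clamped axis has zero coordinate gradient
    # while the other axes keep theirs
    inside = (coords >= 0) & (coords <= np.array([nd - 1, nh - 1, nw - 1])[:, None])
    c, i0, t = _corner_gather(vol, coords)
    td, th, tw = t
    i, j, k = i0
    out_flat = np.zeros(coords.shape[1], dtype=DTYPE)
    grads = np.zeros((3, coords.shape[1]), dtype=DTYPE)
    for dz in (0, 1):
        wz = td if dz else 1.0 - td
        dwz = 1.0 if dz else -1.0
        for dy in (0, 1):
            wy = th if dy else 1.0 - th
            dwy = 1.0 if dy else -1.0
            for dx in (0, 1):
                wx = tw if dx else 1.0 - tw
                dwx = 1.0 if dx else -1.0
                v = vol[i + dz, j + dy, k + dx]
                out_flat += wz * wy * wx * v
                grads[0] += dwz * wy * wx * v
                grads[1] += wz * dwy * wx * v
                grads[2] += wz * wy * dwx * v
    grads *= inside  # clamped samples are constant in u
    out = Tensor(out_flat.reshape(nd, nh, nw), parents=(ddf,))

    def bw(g: np.ndarray) -> None:
        if ddf.requires_grad:
            ddf._accum((grads * g.reshape(1, -1)).reshape(3, nd, nh, nw))

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# Gaussian smoothing (zero-padded, hence exactly self-adjoint)
# ---------------------------------------------------------------------------

def gaussian_kernel1d(sigma_vox: float, truncate: float = 3.0) -> np.ndarray:
    """Normalized 1D Gaussian taps truncated at ``truncate`` sigmas."""
    if sigma_vox <= 0:
        return np.ones(1)
    r = max(1, int(truncate * sigma_vox + 0.5))
    x = np.arange(-r, r + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma_vox) ** 2)
    return k / k.sum()


def _blur_nd(v: np.ndarray, sigma_vox: float) -> np.ndarray:
    if sigma_vox <= 0:
        return v
    k = gaussian_kernel1d(sigma_vox)
    for ax in range(v.ndim):
        v = ndimage.correlate1d(v, k, axis=ax, mode="constant", cval=0.0)
    return v


def gaussian_blur(x: Tensor, sigma_vox: float) -> Tensor:
    """Separable Gaussian with zero boundary; symmetric => self-adjoint."""
    out = Tensor(_blur_nd(x.value, sigma_vox), parents=(x,))

    def bw(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accum(_blur_nd(g, sigma_vox))

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# loss primitives
# ---------------------------------------------------------------------------

def soft_dice_t(a: Tensor, b: Tensor, eps: float = 1e-7) -> Tensor:
    """Soft probabilistic Dice 2<a,b>/(|a|^2+|b|^2+eps) as a scalar node."""
    if a.value.shape != b.value.shape:
        raise ValueError(f"label grids differ: {a.value.shape} vs {b.value.shape}")
    s_ab = float(np.sum(a.value * b.value))
    s_aa = float(np.sum(a.value * a.value))
    s_bb = float(np.sum(b.value * b.value))
    denom = s_aa + s_bb + eps
    val = 2.0 * s_ab / denom
    out = Tensor(np.asarray(val), parents=(a, b))

    def bw(g: np.ndarray) -> None:
        gs = float(g)
        if a.requires_grad:
            a._accum(gs * (2.0 * b.value * denom - 2.0 * s_ab * 2.0 * a.value) / denom ** 2)
        if b.requires_grad:
            b._accum(gs * (2.0 * a.value * denom - 2.0 * s_ab * 2.0 * b.value) / denom ** 2)

    out._backward = bw
    return out


def _second_diffs(u: np.ndarray):
    """Interior second differences of one displacement component (D,H,W)."""
    # pure terms
    dxx = u[2:, 1:-1, 1:-1] - 2 * u[1:-1, 1:-1, 1:-1] + u[:-2, 1:-1, 1:-1]
    dyy = u[1:-1, 2:, 1:-1] - 2 * u[1:-1, 1:-1, 1:-1] + u[1:-1, :-2, 1:-1]
    dzz = u[1:-1, 1:-1, 2:] - 2 * u[1:-1, 1:-1, 1:-1] + u[1:-1, 1:-1, :-2]
    # mixed (central) terms
    dxy = 0.25 * (u[2:, 2:, 1:-1] - u[2:, :-2, 1:-1] - u[:-2, 2:, 1:-1] + u[:-2, :-2, 1:-1])
    dxz = 0.25 * (u[2:, 1:-1, 2:] - u[2:, 1:-1, :-2] - u[:-2, 1:-1, 2:] + u[:-2, 1:-1, :-2])
    dyz = 0.25 * (u[1:-1, 2:, 2:] - u[1:-1, 2:, :-2] - u[1:-1, :-2, 2:] + u[1:-1, :-2, :-2])
    return dxx, dyy, dzz, dxy, dxz, dyz


def _second_diffs_adj(grads, shape):
    """Adjoint of :func:`_second_diffs` scattering into a (D,H,W) array."""
    gxx, gyy, gzz, gxy, gxz, gyz = grads
    out = np.zeros(shape)
    out[2:, 1:-1, 1:-1] += gxx
    out[1:-1, 1:-1, 1:-1] += -2 * gxx
    out[:-2, 1:-1, 1:-1] += gxx
    out[1:-1, 2:, 1:-1] += gyy
    out[1:-1, 1:-1, 1:-1] += -2 * gyy
    out[1:-1, :-2, 1:-1] += gyy
    out[1:-1, 1:-1, 2:] += gzz
    out[1:-1, 1:-1, 1:-1] += -2 * gzz
    out[1:-1, 1:-1, :-2] += gzz
    out[2:, 2:, 1:-1] += 0.25 * gxy
    out[2:, :-2, 1:-1] += -0.25 * gxy
    out[:-2, 2:, 1:-1] += -0.25 * gxy
    out[:-2, :-2, 1:-1] += 0.25 * gxy
    out[2:, 1:-1, 2:] += 0.25 * gxz
    out[2:, 1:-1, :-2] += -0.25 * gxz
    out[:-2, 1:-1, 2:] += -0.25 * gxz
    out[:-2, 1:-1, :-2] += 0.25 * gxz
    out[1:-1, 2:, 2:] += 0.25 * gyz
    out[1:-1, 2:, :-2] += -0.25 * gyz
    out[1:-1, :-2, 2:] += -0.25 * gyz
    out[1:-1, :-2, :-2] += 0.25 * gyz
    return out


def bending_energy_t(ddf: Tensor) -> Tensor:
    """Mean over interior voxels of the squared second derivatives of u.

    Per component: dxx^2 + dyy^2 + dzz^2 + 2(dxy^2 + dxz^2 + dyz^2),
    central differences in voxel units; zero for any affine field.
    """
    if any(n < 3 for n in ddf.value.shape[1:]):
        raise ValueError(f"grid {ddf.value.shape[1:]} too small for second differences")
    n_int = float(np.prod([n - 2 for n in ddf.value.shape[1:]]))
    total = 0.0
    cache = []
    for c in range(3):
        diffs = _second_diffs(ddf.value[c])
        cache.append(diffs)
        dxx, dyy, dzz, dxy, dxz, dyz = diffs
        total += np.sum(dxx**2 + dyy**2 + dzz**2 + 2 * (dxy**2 + dxz**2 + dyz**2))
    out = Tensor(np.asarray(total / n_int), parents=(ddf,))

    def bw(g: np.ndarray) -> None:
        if not ddf.requires_grad:
            return
        gs = float(g) / n_int
        gfull = np.zeros_like(ddf.value)
        for c in range(3):
            dxx, dyy, dzz, dxy, dxz, dyz = cache[c]
            gfull[c] = _second_diffs_adj(
                (2 * gs * dxx, 2 * gs * dyy, 2 * gs * dzz,
                 4 * gs * dxy, 4 * gs * dxz, 4 * gs * dyz),
                ddf.value.shape[1:])
        ddf._accum(gfull)

    out._backward = bw
    return out
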