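"""Minimal trainable neural-network layers on numpy arrays.

Every layer implements an explicit ``forward``/``backward`` pair; gradients
are accumulated into per-parameter ``grads`` buffers so an optimizer can walk
``named_parameters()``. The working dtype defaults to float32; tests promote
models to float64 for finite-difference gradient checks via ``Module.astype``.

Only the operations the two-channel classifier needs are provided: 3D
convolution (3x3x3, stride 1, "same" padding), 2x2x2 max pooling, dense
layers, layer normalization, multi-head self-attention, dropout, and the
token/positional embedding used by the genetic channel.
"""

from __future__ import annotations

import numpy as np

DEFAULT_DTYPE = np.float32


class Module:
    """Base class: parameter registry plus child-module composition."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.children: dict[str, "Module"] = {}

    def add_param(self, name: str, value: np.ndarray) -> np.ndarray:
        self.params[name] = value
        self.grads[name] = np.zeros_like(value)
        return value

    def add_child(self, name: str, module: "Module") -> "Module":
        self.children[name] = module
        return module

    def named_parameters(self, prefix: str = ""):
        for name, value in self.params.items():
            yield prefix + name, value, self.grads[name]
        for cname, child in self.children.items():
            yield from child.named_parameters(prefix + cname + ".")

    def zero_grad(self) -> None:
        for g in self.grads.values():
            g[...] = 0.0
        for child in self.children.values():
            child.zero_grad()

    def astype(self, dtype) -> "Module":
        for name in self.params:
            self.params[name] = self.params[name].astype(dtype)
            self.grads[name] = self.grads[name].astype(dtype)
        for child in self.children.values():
            child.astype(dtype)
        return self

    def n_parameters(self) -> int:
        return sum(int(v.size) for _, v, _ in self.named_parameters())

    # subclasses implement forward(x, train=False, rng=None) and backward(dy)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 scale: str = "relu", dtype=DEFAULT_DTYPE) -> None:
        super().__init__()
        std = np.sqrt((2.0 if scale == "relu" else 1.0) / n_in)
        self.add_param("W", (rng.standard_normal((n_in, n_out)) * std).astype(dtype))
        self.add_param("b", np.zeros(n_out, dtype=dtype))

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        x = self._x
        xf = x.reshape(-1, x.shape[-1])
        dyf = dy.reshape(-1, dy.shape[-1])
        self.grads["W"] += xf.T @ dyf
        self.grads["b"] += dyf.sum(axis=0)
        return dy @ self.params["W"].T


class ReLU(Module):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout(Module):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float) -> None:
        super().__init__()
        self.p = float(p)

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in train mode requires an rng")
        keep = 1.0 - self.p
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


# offsets of the 27 taps of a 3x3x3 kernel, fixed ordering
_OFFSETS = [(i, j, k) for i in range(3) for j in range(3) for k in range(3)]


class Conv3d(Module):
    """3x3x3 convolution, stride 1, zero padding 1 (spatial extent preserved)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 dtype=DEFAULT_DTYPE, input_grad: bool = True) -> None:
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.input_grad = input_grad  # False for the first layer: dx unused
        fan_in = c_in * 27
        self.add_param("W", (rng.standard_normal((fan_in, c_out))
                             * np.sqrt(2.0 / fan_in)).astype(dtype))
        self.add_param("b", np.zeros(c_out, dtype=dtype))

    def _im2col(self, xp, d, h, w):
        # (B, C, 27, D, H, W) without fancy indexing; 27 cheap slices
        slabs = [xp[:, :, i:i + d, j:j + h, k:k + w] for i, j, k in _OFFSETS]
        return np.stack(slabs, axis=2)

    def forward(self, x, train=False, rng=None):
        b, c, d, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        xp = np.zeros((b, c, d + 2, h + 2, w + 2), dtype=x.dtype)
        xp[:, :, 1:-1, 1:-1, 1:-1] = x
        cols = self._im2col(xp, d, h, w)              # (B, C, 27, D, H, W)
        cols = cols.reshape(b, c * 27, d * h * w)
        self._cols = cols
        self._shape = (b, c, d, h, w)
        wm = np.ascontiguousarray(self.params["W"].T)  # (c_out, C*27)
        y = np.matmul(wm, cols)                        # batched gemm (B, c_out, V)
        y += self.params["b"][None, :, None]
        return y.reshape(b, self.c_out, d, h, w)

    def backward(self, dy):
        b, c, d, h, w = self._shape
        dyf = np.ascontiguousarray(dy.reshape(b, self.c_out, d * h * w))
        # dW via (B, C*27, V) @ (B, V, c_out): first operand is contiguous
        dw = np.matmul(self._cols, dyf.swapaxes(1, 2)).sum(axis=0)
        self.grads["W"] += dw
        self.grads["b"] += dyf.sum(axis=(0, 2))
        self._cols = None
        if not self.input_grad:
            return None
        wt = np.ascontiguousarray(self.params["W"])    # (C*27, c_out)
        dcols = np.matmul(wt, dyf)                     # (B, C*27, V)
        dcols = dcols.reshape(b, c, 27, d, h, w)
        dxp = np.zeros((b, c, d + 2, h + 2, w + 2), dtype=dy.dtype)
        for n, (i, j, k) in enumerate(_OFFSETS):
            dxp[:, :, i:i + d, j:j + h, k:k + w] += dcols[:, :, n]
        return dxp[:, :, 1:-1, 1:-1, 1:-1]


class MaxPool3d(Module):
    """Non-overlapping 2x2x2 max pooling (stride 2)."""

    def forward(self, x, train=False, rng=None):
        b, c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError("spatial dims must be even for 2x2x2 pooling")
        xr = (x.reshape(b, c, d // 2, 2, h // 2, 2, w // 2, 2)
               .transpose(0, 1, 2, 4, 6, 3, 5, 7)
               .reshape(b, c, d // 2, h // 2, w // 2, 8))
        self._argmax = xr.argmax(axis=-1)
        self._shape = (b, c, d, h, w)
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        b, c, d, h, w = self._shape
        dz = np.zeros((b, c, d // 2, h // 2, w // 2, 8), dtype=dy.dtype)
        np.put_along_axis(dz, self._argmax[..., None], dy[..., None], axis=-1)
        return (dz.reshape(b, c, d // 2, h // 2, w // 2, 2, 2, 2)
                  .transpose(0, 1, 2, 5, 3, 6, 4, 7)
                  .reshape(b, c, d, h, w))


class LayerNorm(Module):
    def __init__(self, dim: int, dtype=DEFAULT_DTYPE, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps = eps
        self.add_param("g", np.ones(dim, dtype=dtype))
        self.add_param("b", np.zeros(dim, dtype=dtype))

    def forward(self, x, train=False, rng=None):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self.params["g"] * self._xhat + self.params["b"]

    def backward(self, dy):
        xhat, inv = self._xhat, self._inv
        self.grads["g"] += (dy * xhat).reshape(-1, xhat.shape[-1]).sum(axis=0)
        self.grads["b"] += dy.reshape(-1, dy.shape[-1]).sum(axis=0)
        dxhat = dy * self.params["g"]
        n = xhat.shape[-1]
        return (inv / n) * (n * dxhat
                            - dxhat.sum(axis=-1, keepdims=True)
                            - xhat * (dxhat * xhat).sum(axis=-1, keepdims=True))


def softmax(z, axis=-1):
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention with ``n_heads`` parallel heads."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 dtype=DEFAULT_DTYPE) -> None:
        super().__init__()
        if dim % n_heads:
            raise ValueError("model dim must be divisible by n_heads")
        self.dim, self.n_heads, self.d_head = dim, n_heads, dim // n_heads
        self.add_child("qkv", Linear(dim, 3 * dim, rng, scale="linear", dtype=dtype))
        self.add_child("proj", Linear(dim, dim, rng, scale="linear", dtype=dtype))

    def _split(self, z, b, L):
        return z.reshape(b, L, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def forward(self, x, train=False, rng=None):
        b, L, _ = x.shape
        qkv = self.children["qkv"].forward(x)
        q, k, v = (self._split(z, b, L) for z in np.split(qkv, 3, axis=-1))
        scale = float(1.0 / np.sqrt(self.d_head))  # python float: no f64 promotion
        att = softmax((q @ k.transpose(0, 1, 3, 2)) * scale)   # (B, H, L, L)
        out = att @ v                                          # (B, H, L, dh)
        self._cache = (q, k, v, att, scale, b, L)
        return self.children["proj"].forward(
            out.transpose(0, 2, 1, 3).reshape(b, L, self.dim))

    def backward(self, dy):
        q, k, v, att, scale, b, L = self._cache
        dout = self.children["proj"].backward(dy)
        dout = self._split(dout, b, L)
        datt = dout @ v.transpose(0, 1, 3, 2)
        dv = att.transpose(0, 1, 3, 2) @ dout
        ds = att * (datt - (datt * att).sum(axis=-1, keepdims=True))
        dq = (ds @ k) * scale
        dk = (ds.transpose(0, 1, 3, 2) @ q) * scale
        merge = lambda z: z.transpose(0, 2, 1, 3).reshape(b, L, self.dim)
        dqkv = np.concatenate([merge(dq), merge(dk), merge(dv)], axis=-1)
        self._cache = None
        return self.children["qkv"].backward(dqkv)


class EncoderLayer(Module):
    """Pre-norm Transformer encoder layer.

    x <- x + drop(attn(ln1(x))); x <- x + drop(ffn(ln2(x)))
    with a two-layer position-wise feed-forward network of the given width.
    """

    def __init__(self, dim: int, n_heads: int, ffn_dim: int, p_drop: float,
                 rng: np.random.Generator, dtype=DEFAULT_DTYPE) -> None:
        super().__init__()
        self.add_child("ln1", LayerNorm(dim, dtype=dtype))
        self.add_child("attn", MultiHeadSelfAttention(dim, n_heads, rng, dtype=dtype))
        self.add_child("drop1", Dropout(p_drop))
        self.add_child("ln2", LayerNorm(dim, dtype=dtype))
        self.add_child("ffn1", Linear(dim, ffn_dim, rng, scale="relu", dtype=dtype))
        self.add_child("relu", ReLU())
        self.add_child("ffn2", Linear(ffn_dim, dim, rng, scale="linear", dtype=dtype))
        self.add_child("drop2", Dropout(p_drop))

    def forward(self, x, train=False, rng=None):
        c = self.children
        x = x + c["drop1"].forward(
            c["attn"].forward(c["ln1"].forward(x), train, rng), train, rng)
        h = c["ffn2"].forward(c["relu"].forward(
            c["ffn1"].forward(c["ln2"].forward(x)), train, rng))
        return x + c["drop2"].forward(h, train, rng)

    def backward(self, dy):
        c = self.children
        dh = c["drop2"].backward(dy)
        dx2 = c["ln2"].backward(c["ffn1"].backward(
            c["relu"].backward(c["ffn2"].backward(dh))))
        dy = dy + dx2
        da = c["drop1"].backward(dy)
        dx1 = c["ln1"].backward(c["attn"].backward(da))
        return dy + dx1


class TokenEmbedding(Module):
    """Dosage-token + learned positional embedding for the genetic channel.

    Regular SNP positions index a {0,1,2} vocabulary; the single flagged APOE
    position indexes a separate {0,1,2} vocabulary so the allele count of the
    APOE e4 haplotype gets its own representation.
    """

    def __init__(self, seq_len: int, dim: int, rng: np.random.Generator,
                 dtype=DEFAULT_DTYPE) -> None:
        super().__init__()
        self.seq_len = seq_len
        self.add_param("tok", (rng.standard_normal((3, dim)) * 0.02).astype(dtype))
        self.add_param("apoe", (rng.standard_normal((3, dim)) * 0.02).astype(dtype))
        self.add_param("pos", (rng.standard_normal((seq_len, dim)) * 0.02).astype(dtype))

    def forward(self, tokens, apoe_position=None, train=False, rng=None):
        tokens = np.asarray(tokens)
        if tokens.ndim != 2 or tokens.shape[1] != self.seq_len:
            raise ValueError(
                f"expected token batch of shape (B, {self.seq_len}), got {tokens.shape}")
        if not np.isin(tokens, (0, 1, 2)).all():
            raise ValueError("dosage tokens must be in {0, 1, 2}")
        emb = self.params["tok"][tokens]
        if apoe_position is not None:
            emb[:, apoe_position, :] = self.params["apoe"][tokens[:, apoe_position]]
        self._tokens, self._apoe_position = tokens, apoe_position
        return emb + self.params["pos"]

    def backward(self, dy):
        tokens, apos = self._tokens, self._apoe_position
        self.grads["pos"] += dy.sum(axis=0)
        if apos is not None:
            np.add.at(self.grads["apoe"], tokens[:, apos], dy[:, apos, :])
            keep = np.ones(self.seq_len, dtype=bool)
            keep[apos] = False
            np.add.at(self.grads["tok"], tokens[:, keep], dy[:, keep, :])
        else:
            np.add.at(self.grads["tok"], tokens, dy)
        return None  # tokens are discrete inputs


class Flatten(Module):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class MeanPoolSeq(Module):
    """Mean over the sequence (second) axis of a (B, L, D) tensor."""

    def forward(self, x, train=False, rng=None):
        self._L = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy):
        return np.repeat(dy[:, None, :], self._L, axis=1) / self._L


class Sequential(Module):
    def __init__(self, *layers: Module) -> None:
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(self.layers):
            self.add_child(str(i), layer)

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def softmax_cross_entropy(scores: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy from raw scores; returns (loss, dscores).

    Computed stably via log-sum-exp; dscores is the gradient of the mean loss.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape[0] == 0:
        raise ValueError("empty batch")
    n = scores.shape[0]
    z = scores - scores.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    loss = -logp[np.arange(n), labels].mean()
    p = np.exp(logp)
    p[np.arange(n), labels] -= 1.0
    return float(loss), p / n
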