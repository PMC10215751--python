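"""Global attention operator: a channel gate followed by a spatial gate.

The operator takes a feature map ``F1`` of shape ``(C, H, W)`` and produces

    F2 = M_C(F1) * F1        (elementwise)
    F3 = M_S(F2) * F2        (elementwise)

``M_C`` is a channel gate: the channel vector at every spatial location is
passed through a shared two-layer perceptron (C -> C/r -> C, ReLU in
between, r the reduction ratio) and squashed with a logistic sigmoid, so the
full 3-D arrangement of the map is retained rather than pooled away.
``M_S`` is a spatial gate: two same-padded convolutions (C -> C/r -> C, ReLU
in between, no pooling anywhere) followed by a sigmoid.  Both gates lie
strictly in (0, 1), so the operator only ever attenuates: |F3| <= |F2| <= |F1|
entrywise.

This module is the pure feed-forward computation with weights supplied
explicitly or drawn reproducibly from a seed; training and integration into a
particular detector are out of scope (in the detection network the operator
is inserted on the head side, in front of each detection scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["GamParams", "channel_gate", "spatial_gate", "gam_forward"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable logistic
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class GamParams:
    """Weights of the two gate sub-networks for channel count ``C``.

    Shapes: ``w1 (C/r, C)``, ``b1 (C/r,)``, ``w2 (C, C/r)``, ``b2 (C,)`` for
    the perceptron; ``k1 (C/r, C, k, k)``, ``k2 (C, C/r, k, k)`` for the two
    convolutions (k odd, same padding).
    """

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    k1: np.ndarray
    k2: np.ndarray
    r: int
    kernel_size: int

    def __post_init__(self) -> None:
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        c = self.w1.shape[1]
        if c % self.r != 0:
            raise ValueError(f"channels {c} not divisible by reduction ratio {self.r}")
        cr = c // self.r
        expected = {
            "w1": (cr, c),
            "b1": (cr,),
            "w2": (c, cr),
            "b2": (c,),
            "k1": (cr, c, self.kernel_size, self.kernel_size),
            "k2": (c, cr, self.kernel_size, self.kernel_size),
        }
        for name, shape in expected.items():
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")

    @property
    def channels(self) -> int:
        return self.w1.shape[1]

    @classmethod
    def random(
        cls, channels: int, r: int = 4, kernel_size: int = 7, seed: int = 0
    ) -> "GamParams":
        """Uniform init in +-1/sqrt(fan_in), reproducible under ``seed``."""
        if channels % r != 0:
            raise ValueError(f"channels {channels} not divisible by reduction ratio {r}")
        rng = np.random.default_rng(seed)
        cr = channels // r

        def u(shape, fan_in):
            bound = 1.0 / np.sqrt(fan_in)
            return rng.uniform(-bound, bound, size=shape)

        k2 = kernel_size * kernel_size
        return cls(
            w1=u((cr, channels), channels),
            b1=u((cr,), channels),
            w2=u((channels, cr), cr),
            b2=u((channels,), cr),
            k1=u((cr, channels, kernel_size, kernel_size), channels * k2),
            k2=u((channels, cr, kernel_size, kernel_size), cr * k2),
            r=r,
            kernel_size=kernel_size,
        )

    @classmethod
    def zeros(cls, channels: int, r: int = 4, kernel_size: int = 7) -> "GamParams":
        """All-zero weights: both gates are exactly 0.5 everywhere."""
        if channels % r != 0:
            raise ValueError(f"channels {channels} not divisible by reduction ratio {r}")
        cr = channels // r
        k = kernel_size
        return cls(
            w1=np.zeros((cr, channels)),
            b1=np.zeros(cr),
            w2=np.zeros((channels, cr)),
            b2=np.zeros(channels),
            k1=np.zeros((cr, channels, k, k)),
            k2=np.zeros((channels, cr, k, k)),
            r=r,
            kernel_size=k,
        )

    def save(self, path) -> None:
        np.savez(
            path,
            w1=self.w1,
            b1=self.b1,
            w2=self.w2,
            b2=self.b2,
            k1=self.k1,
            k2=self.k2,
            r=np.asarray(self.r),
            k=np.asarray(self.kernel_size),
        )

    @classmethod
    def load(cls, path) -> "GamParams":
        with np.load(path) as z:
            return cls(
                w1=z["w1"],
                b1=z["b1"],
                w2=z["w2"],
                b2=z["b2"],
                k1=z["k1"],
                k2=z["k2"],
                r=int(z["r"]),
                kernel_size=int(z["k"]),
            )


def _check_input(f: np.ndarray, p: GamParams) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if f.ndim != 3:
        raise ValueError(f"feature map must be 3-D (C, H, W), got shape {f.shape}")
    if f.shape[0] != p.channels:
        raise ValueError(
            f"feature map has {f.shape[0]} channels, params expect {p.channels}"
        )
    if not np.all(np.isfinite(f)):
        raise ValueError("feature map must be finite")
    return f


def channel_gate(f: np.ndarray, p: GamParams) -> np.ndarray:
    """Channel gate M_C: shared per-location MLP over the channel axis.

    The map is permuted so each spatial location exposes its channel vector,
    the two-layer perceptron is applied, the result is permuted back and
    squashed; output shape equals input shape, entries strictly in (0, 1).
    """
    f = _check_input(f, p)
    x = np.transpose(f, (1, 2, 0))  # (H, W, C)
    hidden = np.maximum(x @ p.w1.T + p.b1, 0.0)
    logits = hidden @ p.w2.T + p.b2
    return _sigmoid(np.transpose(logits, (2, 0, 1)))


def _conv_same(f: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """Same-padded 2-D cross-correlation: (Cin,H,W) x (Cout,Cin,k,k) -> (Cout,H,W)."""
    cout, cin = kernels.shape[:2]
    out = np.zeros((cout, f.shape[1], f.shape[2]))
    for o in range(cout):
        for c in range(cin):
            out[o] += ndimage.correlate(f[c], kernels[o, c], mode="constant", cval=0.0)
    return out


def spatial_gate(f: np.ndarray, p: GamParams) -> np.ndarray:
    """Spatial gate M_S: two same-padded convolutions, ReLU between, sigmoid.

    No pooling anywhere in this path, so the full spatial resolution is kept.
    """
    f = _check_input(f, p)
    hidden = np.maximum(_conv_same(f, p.k1), 0.0)
    return _sigmoid(_conv_same(hidden, p.k2))


def gam_forward(f1: np.ndarray, p: GamParams) -> np.ndarray:
    """Full operator: F2 = M_C(F1)*F1, then F3 = M_S(F2)*F2."""
    f1 = _check_input(f1, p)
    f2 = channel_gate(f1, p) * f1
    return spatial_gate(f2, p) * f2
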