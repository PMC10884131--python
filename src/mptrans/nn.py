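"""Minimal NumPy conv-net primitives with explicit backpropagation.

Layers are stateless in their activations: ``forward`` returns
``(output, cache)`` and ``backward(grad_output, cache)`` returns the input
gradient while accumulating parameter gradients, so the same module can
appear several times in one computation graph (as the generators do inside
the cycle objective).  Shapes follow the (batch, channels, height, width)
convention.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Module:
    """Base class: parameter/gradient registry."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def add_param(self, name: str, value: np.ndarray) -> None:
        self.params[name] = value
        self.grads[name] = np.zeros_like(value)

    def zero_grad(self) -> None:
        for g in self.grads.values():
            g[...] = 0.0

    def modules(self) -> list["Module"]:
        return [self]

    def n_parameters(self) -> int:
        return sum(p.size for m in self.modules() for p in m.params.values())


class Conv2d(Module):
    """2-D convolution (cross-correlation) with zero padding."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        stride: int = 1,
        pad: int = 0,
        rng: np.random.Generator | None = None,
        init_scale: float | None = None,
    ) -> None:
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.stride, self.pad = kernel, stride, pad
        rng = rng or np.random.default_rng(0)
        if init_scale is None:
            init_scale = float(np.sqrt(2.0 / (c_in * kernel * kernel)))
        w = rng.standard_normal((c_out, c_in, kernel, kernel)) * init_scale
        self.add_param("W", w)
        self.add_param("b", np.zeros(c_out))

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, dict]:
        b, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {c}")
        k, s, p = self.kernel, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # win: (B, Cin, Ho, Wo, k, k)
        ho, wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b, ho * wo, c * k * k)
        wm = self.params["W"].reshape(self.c_out, -1)
        out = cols @ wm.T + self.params["b"]
        out = out.transpose(0, 2, 1).reshape(b, self.c_out, ho, wo)
        cache = {"cols": cols, "x_shape": x.shape, "ho": ho, "wo": wo}
        return out, cache

    def backward(self, gy: np.ndarray, cache: dict) -> np.ndarray:
        b, _, ho, wo = gy.shape
        k, s, p = self.kernel, self.stride, self.pad
        cols = cache["cols"]
        g = gy.reshape(b, self.c_out, ho * wo).transpose(0, 2, 1)  # (B, HoWo, Cout)
        wm = self.params["W"].reshape(self.c_out, -1)
        self.grads["W"] += (
            g.reshape(-1, self.c_out).T @ cols.reshape(-1, cols.shape[-1])
        ).reshape(self.params["W"].shape)
        self.grads["b"] += g.sum(axis=(0, 1))
        gcols = (g @ wm).reshape(b, ho, wo, self.c_in, k, k).transpose(0, 3, 1, 2, 4, 5)
        _, _, h, w = cache["x_shape"]
        gxp = np.zeros((b, self.c_in, h + 2 * p, w + 2 * p))
        for ki in range(k):
            for kj in range(k):
                gxp[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s] += gcols[..., ki, kj]
        return gxp[:, :, p : p + h, p : p + w] if p else gxp


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2) -> None:
        super().__init__()
        self.slope = slope

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, dict]:
        neg = x < 0
        out = np.where(neg, self.slope * x, x)
        return out, {"neg": neg}

    def backward(self, gy: np.ndarray, cache: dict) -> np.ndarray:
        return np.where(cache["neg"], self.slope * gy, gy)


class Upsample2x(Module):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, dict]:
        return x.repeat(2, axis=2).repeat(2, axis=3), {}

    def backward(self, gy: np.ndarray, cache: dict) -> np.ndarray:
        b, c, h, w = gy.shape
        return gy.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Sequential(Module):
    def __init__(self, *layers: Module) -> None:
        super().__init__()
        self.layers = list(layers)

    def modules(self) -> list[Module]:
        out: list[Module] = []
        for layer in self.layers:
            out.extend(layer.modules())
        return out

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, list]:
        caches = []
        for layer in self.layers:
            x, c = layer.forward(x)
            caches.append(c)
        return x, caches

    def backward(self, gy: np.ndarray, caches: list) -> np.ndarray:
        for layer, c in zip(reversed(self.layers), reversed(caches)):
            gy = layer.backward(gy, c)
        return gy

    def zero_grad(self) -> None:
        for m in self.modules():
            m.zero_grad()


class SGDMomentum:
    """Classical momentum SGD over a set of modules."""

    def __init__(self, modules: list[Module], lr: float, momentum: float = 0.9) -> None:
        self.modules = [m for m in modules if m.params]
        self.lr = lr
        self.momentum = momentum
        self.velocity = [
            {k: np.zeros_like(v) for k, v in m.params.items()} for m in self.modules
        ]

    def step(self) -> None:
        for m, vel in zip(self.modules, self.velocity):
            for k in m.params:
                vel[k] = self.momentum * vel[k] - self.lr * m.grads[k]
                m.params[k] += vel[k]


class Adam:
    """Adam with the usual bias correction (beta1 acts as the momentum)."""

    def __init__(
        self,
        modules: list[Module],
        lr: float,
        momentum: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.modules = [m for m in modules if m.params]
        self.lr, self.b1, self.b2, self.eps = lr, momentum, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in m.params.items()} for m in self.modules]
        self.v = [{k: np.zeros_like(v) for k, v in m.params.items()} for m in self.modules]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for mod, m1, v2 in zip(self.modules, self.m, self.v):
            for k in mod.params:
                g = mod.grads[k]
                m1[k] = self.b1 * m1[k] + (1 - self.b1) * g
                v2[k] = self.b2 * v2[k] + (1 - self.b2) * g * g
                mod.params[k] -= self.lr * (m1[k] / bc1) / (np.sqrt(v2[k] / bc2) + self.eps)


def make_optimizer(kind: str, modules: list[Module], lr: float, momentum: float):
    if kind == "momentum":
        return SGDMomentum(modules, lr=lr, momentum=momentum)
    if kind == "adam":
        return Adam(modules, lr=lr, momentum=momentum)
    raise ValueError(f"unknown optimizer {kind!r}")


class ResUNetGenerator(Module):
    """Small 3-level U-Net with additive skips and a residual output.

    The final convolution is zero-initialized, so an untrained generator
    is exactly the identity map -- training only has to learn the
    correction.
    """

    def __init__(self, width: int, rng: np.random.Generator) -> None:
        super().__init__()
        w = width
        act = 0.1
        self.c1 = Conv2d(1, w, 3, 1, 1, rng)
        self.a1 = LeakyReLU(act)
        self.d1 = Conv2d(w, 2 * w, 3, 2, 1, rng)
        self.a2 = LeakyReLU(act)
        self.c2 = Conv2d(2 * w, 2 * w, 3, 1, 1, rng)
        self.a3 = LeakyReLU(act)
        self.d2 = Conv2d(2 * w, 4 * w, 3, 2, 1, rng)
        self.a4 = LeakyReLU(act)
        self.bott = Conv2d(4 * w, 4 * w, 3, 1, 1, rng)
        self.a5 = LeakyReLU(act)
        self.up1 = Upsample2x()
        self.u1 = Conv2d(4 * w, 2 * w, 3, 1, 1, rng)
        self.a6 = LeakyReLU(act)
        self.up2 = Upsample2x()
        self.u2 = Conv2d(2 * w, w, 3, 1, 1, rng)
        self.a7 = LeakyReLU(act)
        self.out = Conv2d(w, 1, 3, 1, 1, rng, init_scale=0.0)
        self._order = [
            self.c1, self.a1, self.d1, self.a2, self.c2, self.a3, self.d2,
            self.a4, self.bott, self.a5, self.up1, self.u1, self.a6,
            self.up2, self.u2, self.a7, self.out,
        ]

    def modules(self) -> list[Module]:
        return self._order

    def zero_grad(self) -> None:
        for m in self._order:
            m.zero_grad()

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, dict]:
        if x.shape[2] % 4 or x.shape[3] % 4:
            raise ValueError("input size must be divisible by 4")
        cc: dict = {}
        h, cc["c1"] = self.c1.forward(x)
        s1, cc["a1"] = self.a1.forward(h)
        h, cc["d1"] = self.d1.forward(s1)
        h, cc["a2"] = self.a2.forward(h)
        h, cc["c2"] = self.c2.forward(h)
        s2, cc["a3"] = self.a3.forward(h)
        h, cc["d2"] = self.d2.forward(s2)
        h, cc["a4"] = self.a4.forward(h)
        h, cc["bott"] = self.bott.forward(h)
        h, cc["a5"] = self.a5.forward(h)
        h, cc["up1"] = self.up1.forward(h)
        h, cc["u1"] = self.u1.forward(h)
        h, cc["a6"] = self.a6.forward(h)
        h = h + s2  # additive skip
        h, cc["up2"] = self.up2.forward(h)
        h, cc["u2"] = self.u2.forward(h)
        h, cc["a7"] = self.a7.forward(h)
        h = h + s1
        r, cc["out"] = self.out.forward(h)
        return x + r, cc

    def backward(self, gy: np.ndarray, cc: dict) -> np.ndarray:
        gh = self.out.backward(gy, cc["out"])
        gs1 = gh.copy()
        gh = self.a7.backward(gh, cc["a7"])
        gh = self.u2.backward(gh, cc["u2"])
        gh = self.up2.backward(gh, cc["up2"])
        gs2 = gh.copy()
        gh = self.a6.backward(gh, cc["a6"])
        gh = self.u1.backward(gh, cc["u1"])
        gh = self.up1.backward(gh, cc["up1"])
        gh = self.a5.backward(gh, cc["a5"])
        gh = self.bott.backward(gh, cc["bott"])
        gh = self.a4.backward(gh, cc["a4"])
        gh = self.d2.backward(gh, cc["d2"])
        gh = gh + gs2
        gh = self.a3.backward(gh, cc["a3"])
        gh = self.c2.backward(gh, cc["c2"])
        gh = self.a2.backward(gh, cc["a2"])
        gh = self.d1.backward(gh, cc["d1"])
        gh = gh + gs1
        gh = self.a1.backward(gh, cc["a1"])
        gx = self.c1.backward(gh, cc["c1"])
        return gx + gy  # residual path


class PatchDiscriminator(Sequential):
    """Stride-2 conv stack producing a patch map of realness scores."""

    def __init__(self, width: int, rng: np.random.Generator) -> None:
        w = width
        super().__init__(
            Conv2d(1, w, 4, 2, 1, rng),
            LeakyReLU(0.2),
            Conv2d(w, 2 * w, 4, 2, 1, rng),
            LeakyReLU(0.2),
            Conv2d(2 * w, 4 * w, 4, 2, 1, rng),
            LeakyReLU(0.2),
            Conv2d(4 * w, 1, 3, 1, 1, rng),
        )
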