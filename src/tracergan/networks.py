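"""Modified U-Net generator and encoder-half discriminator.

The generator is a U-Net in which max-pooling is replaced by strided
convolutions and the contracting path uses leaky ReLU; the expanding path
uses nearest-neighbour up-convolutions with skip connections from the
matching encoder levels and ReLU activations, finishing in a sigmoid so the
output stays in the unit intensity range of the preprocessed PET slices.

The discriminator reuses only the contracting (encoder) half of the same
topology and emits a real-valued patch score map consumed by a
least-squares (MSE) adversarial objective.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._nn import (Adam, Conv2d, Identity, InstanceNorm, Layer, LeakyReLU,
                  NearestUp2, Parameter, ReLU, Sigmoid)

__all__ = [
    "GeneratorConfig", "DiscriminatorConfig", "Generator", "Discriminator",
    "build_generator", "build_discriminator", "parameter_count",
    "save_checkpoint", "load_checkpoint", "InvalidConfigError",
]


class InvalidConfigError(ValueError):
    """Network configuration incompatible with the input geometry."""


@dataclass(frozen=True)
class GeneratorConfig:
    levels: int = 4
    base_filters: int = 32
    leaky_slope: float = 0.2
    output_activation: str = "sigmoid"  # or "clamp"
    instance_norm: bool = True
    input_shape: tuple[int, int, int] = (64, 64, 1)

    def validate(self) -> None:
        h, w, c = self.input_shape
        if self.levels < 2:
            raise InvalidConfigError("levels must be >= 2")
        if self.base_filters < 1:
            raise InvalidConfigError("base_filters must be >= 1")
        if h % (2 ** self.levels) or w % (2 ** self.levels):
            raise InvalidConfigError(
                f"input shape {h}x{w} not divisible by 2^levels={2**self.levels}")


@dataclass(frozen=True)
class DiscriminatorConfig:
    levels: int = 4
    base_filters: int = 32
    leaky_slope: float = 0.2
    head: str = "patch_map"  # or "scalar"
    instance_norm: bool = True
    input_shape: tuple[int, int, int] = (64, 64, 1)

    def validate(self) -> None:
        h, w, c = self.input_shape
        if self.levels < 2:
            raise InvalidConfigError("levels must be >= 2")
        if self.base_filters < 1:
            raise InvalidConfigError("base_filters must be >= 1")
        if h % (2 ** self.levels) or w % (2 ** self.levels):
            raise InvalidConfigError(
                f"input shape {h}x{w} not divisible by 2^levels={2**self.levels}")


class _EncBlock(Layer):
    """Strided conv + (instance norm) + leaky ReLU: one contracting level."""

    def __init__(self, c_in, c_out, slope, norm, rng):
        self.conv = Conv2d(c_in, c_out, kernel=4, stride=2, pad=1, rng=rng)
        self.norm = InstanceNorm(c_out) if norm else Identity()
        self.act = LeakyReLU(slope)

    def parameters(self):
        return self.conv.parameters() + self.norm.parameters()

    def forward(self, x):
        h, c1 = self.conv.forward(x)
        h, c2 = self.norm.forward(h)
        y, c3 = self.act.forward(h)
        return y, (c1, c2, c3)

    def backward(self, gy, cache):
        c1, c2, c3 = cache
        g = self.act.backward(gy, c3)
        g = self.norm.backward(g, c2)
        return self.conv.backward(g, c1)


class _DecBlock(Layer):
    """Up-convolution level: 2x upsample, concat skip, conv, norm, ReLU."""

    def __init__(self, c_in, c_skip, c_out, norm, rng):
        self.up = NearestUp2()
        self.conv = Conv2d(c_in + c_skip, c_out, kernel=3, stride=1, pad=1, rng=rng)
        self.norm = InstanceNorm(c_out) if norm else Identity()
        self.act = ReLU()
        self.c_in = c_in

    def parameters(self):
        return self.conv.parameters() + self.norm.parameters()

    def forward(self, x, skip):
        u, c0 = self.up.forward(x)
        h = np.concatenate([u, skip], axis=1)
        h, c1 = self.conv.forward(h)
        h, c2 = self.norm.forward(h)
        y, c3 = self.act.forward(h)
        return y, (c0, c1, c2, c3)

    def backward(self, gy, cache):
        c0, c1, c2, c3 = cache
        g = self.act.backward(gy, c3)
        g = self.norm.backward(g, c2)
        g = self.conv.backward(g, c1)
        gu, gskip = g[:, :self.c_in], g[:, self.c_in:]
        gx = self.up.backward(gu, c0)
        return gx, gskip


class Generator:
    """U-Net translator mapping unit-range slices between tracer domains.

    ``role`` records the translation direction ("A->B" forward from amyloid
    to FDG, "B->A" backward); the architecture is identical for both.
    """

    def __init__(self, config: GeneratorConfig, seed: int, role: str = "A->B"):
        config.validate()
        self.config = config
        self.seed = int(seed)
        self.role = role
        rng = np.random.default_rng(seed)
        L, F = config.levels, config.base_filters
        c_in = config.input_shape[2]
        norm = config.instance_norm
        self.enc: list[_EncBlock] = []
        chans = [c_in] + [F * 2 ** l for l in range(L)]
        for l in range(L):
            self.enc.append(_EncBlock(chans[l], chans[l + 1],
                                      config.leaky_slope, norm, rng))
        # decoder mirrors the encoder; the last level concatenates the raw
        # input as its skip so a full-resolution shortcut exists
        self.dec: list[_DecBlock] = []
        for i in range(L):
            cin = chans[L - i]
            cskip = chans[L - 1 - i] if i < L - 1 else c_in
            cout = chans[L - 1 - i] if i < L - 1 else F
            self.dec.append(_DecBlock(cin, cskip, cout, norm, rng))
        self.head = Conv2d(F, c_in, kernel=1, stride=1, pad=0, rng=rng)
        self.out_act = Sigmoid() if config.output_activation == "sigmoid" else None

    def parameters(self) -> list[Parameter]:
        ps: list[Parameter] = []
        for blk in self.enc + self.dec:
            ps.extend(blk.parameters())
        ps.extend(self.head.parameters())
        return ps

    def forward(self, x: np.ndarray):
        """Run a (N,1,H,W) batch; returns (output, tape) for backprop."""
        skips, caches_e = [], []
        h = x
        for blk in self.enc:
            h, c = blk.forward(h)
            skips.append(h)
            caches_e.append(c)
        caches_d = []
        L = self.config.levels
        for i, blk in enumerate(self.dec):
            skip = skips[L - 2 - i] if i < L - 1 else x
            h, c = blk.forward(h, skip)
            caches_d.append(c)
        h, c_head = self.head.forward(h)
        if self.out_act is not None:
            y, c_out = self.out_act.forward(h)
        else:
            y, c_out = np.clip(h, 0.0, 1.0), (h > 0) & (h < 1)
        return y, (caches_e, caches_d, c_head, c_out)

    def backward(self, gy: np.ndarray, tape) -> np.ndarray:
        caches_e, caches_d, c_head, c_out = tape
        L = self.config.levels
        if self.out_act is not None:
            g = self.out_act.backward(gy, c_out)
        else:
            g = gy * c_out
        g = self.head.backward(g, c_head)
        g_skips = [None] * L
        g_x = None
        for i in reversed(range(L)):
            g, gskip = self.dec[i].backward(g, caches_d[i])
            if i < L - 1:
                g_skips[L - 2 - i] = gskip
            else:
                g_x = gskip
        # gradient flowing into the deepest encoder output
        cur = g
        for l in reversed(range(L)):
            if g_skips[l] is not None:
                cur = cur + g_skips[l]
            cur = self.enc[l].backward(cur, caches_e[l])
        return cur + g_x

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]


class Discriminator:
    """Encoder-half network scoring realism of translated slices."""

    def __init__(self, config: DiscriminatorConfig, seed: int):
        config.validate()
        self.config = config
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        L, F = config.levels, config.base_filters
        c_in = config.input_shape[2]
        self.enc: list[_EncBlock] = []
        chans = [c_in] + [F * 2 ** l for l in range(L)]
        for l in range(L):
            # no normalisation on the first level, following GAN practice
            norm = config.instance_norm and l > 0
            self.enc.append(_EncBlock(chans[l], chans[l + 1],
                                      config.leaky_slope, norm, rng))
        self.head = Conv2d(chans[-1], 1, kernel=1, stride=1, pad=0, rng=rng)

    def parameters(self) -> list[Parameter]:
        ps: list[Parameter] = []
        for blk in self.enc:
            ps.extend(blk.parameters())
        ps.extend(self.head.parameters())
        return ps

    def forward(self, x: np.ndarray):
        caches = []
        h = x
        for blk in self.enc:
            h, c = blk.forward(h)
            caches.append(c)
        s, c_head = self.head.forward(h)
        if self.config.head == "scalar":
            score = s.mean(axis=(1, 2, 3), keepdims=True)
            return score, (caches, c_head, s.shape)
        return s, (caches, c_head, None)

    def backward(self, gy: np.ndarray, tape) -> np.ndarray:
        caches, c_head, sshape = tape
        if self.config.head == "scalar":
            n, c, h, w = sshape
            gy = np.broadcast_to(gy / (c * h * w), sshape)
        g = self.head.backward(gy, c_head)
        for blk, c in zip(reversed(self.enc), reversed(caches)):
            g = blk.backward(g, c)
        return g

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]


def build_generator(config: GeneratorConfig | None = None, seed: int = 0,
                    role: str = "A->B") -> Generator:
    """Construct a generator with deterministic, seed-controlled weights."""
    return Generator(config or GeneratorConfig(), seed, role)


def build_discriminator(config: DiscriminatorConfig | None = None,
                        seed: int = 0) -> Discriminator:
    return Discriminator(config or DiscriminatorConfig(), seed)


def parameter_count(net: Generator | Discriminator) -> int:
    return sum(p.size for p in net.parameters())


def save_checkpoint(net: Generator | Discriminator, path: str | Path) -> None:
    """Save parameters as .npz with a JSON sidecar recording config + seed."""
    path = Path(path)
    arrays = {f"p{i}": p.value for i, p in enumerate(net.parameters())}
    np.savez(path, **arrays)
    sidecar = {
        "kind": type(net).__name__,
        "config": asdict(net.config),
        "seed": net.seed,
    }
    if isinstance(net, Generator):
        sidecar["role"] = net.role
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> Generator | Discriminator:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg = meta["config"]
    cfg["input_shape"] = tuple(cfg["input_shape"])
    if meta["kind"] == "Generator":
        net: Generator | Discriminator = Generator(
            GeneratorConfig(**cfg), meta["seed"], meta.get("role", "A->B"))
    else:
        net = Discriminator(DiscriminatorConfig(**cfg), meta["seed"])
    npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    data = np.load(npz_path)
    for i, p in enumerate(net.parameters()):
        p.value[...] = data[f"p{i}"]
    return net
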