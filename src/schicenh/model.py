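"""Dual-branch enhancement network and discriminator.

The generator runs two branches over a w x w context tile and its k x k
central crop.  Each branch is: conv stem -> squeeze-and-excitation gate ->
rank-one extraction (an (n x 1) kernel collapsing one spatial axis into
per-channel vectors, refined by two kernel-3 1-D convolutions) ->
outer-product reconstruction (exactly symmetric per channel) with an
additive skip from the stem.  Branch outputs are aligned to k x k,
concatenated, fused by 1x1 convolutions, symmetrized as (X + X^T)/2 and
passed through a softplus clamped at ``output_clamp`` so values stay in
[0, output_clamp].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

from . import nn

__all__ = [
    "GeneratorConfig",
    "DiscriminatorConfig",
    "RankOneBundle",
    "SEBlock",
    "RankOneHead",
    "Generator",
    "Discriminator",
    "rank_one_extract",
    "rank_one_reconstruct",
    "se_recalibrate",
    "generator_forward",
    "discriminator_forward",
    "Checkpoint",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class GeneratorConfig:
    window: int = 40
    central: int = 28
    stem_channels: tuple = (16, 32)
    se_reduction: int = 4
    n_rank_one_channels: int = 32
    branch_channels: int = 16
    fusion_channels: int = 16
    activation: str = "softplus_clamped"
    output_clamp: float = 1.2

    def __post_init__(self):
        self.stem_channels = tuple(int(c) for c in self.stem_channels)
        if self.window <= self.central or self.central <= 0:
            raise ValueError("need 0 < central < window")
        if (self.window - self.central) % 2 != 0:
            raise ValueError("window - central must be even")
        if any(c <= 0 for c in self.stem_channels) or self.se_reduction < 1:
            raise ValueError("channel counts and se_reduction must be positive")
        if self.stem_channels[-1] % self.se_reduction != 0:
            raise ValueError(
                f"se_reduction {self.se_reduction} must divide stem channels {self.stem_channels[-1]}"
            )
        if self.n_rank_one_channels < 1:
            raise ValueError("need at least one rank-one channel")


@dataclass
class DiscriminatorConfig:
    channels: tuple = (8, 16)
    patch_output: bool = False

    def __post_init__(self):
        self.channels = tuple(int(c) for c in self.channels)
        if any(c <= 0 for c in self.channels):
            raise ValueError("discriminator channels must be positive")


@dataclass
class RankOneBundle:
    """Per-channel length-n vectors with nonnegative channel weights."""

    vectors: np.ndarray  # (C, n)
    channel_weights: np.ndarray  # (C,)

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        self.channel_weights = np.asarray(self.channel_weights, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[0] < 1:
            raise ValueError("vectors must be (C, n) with C >= 1")
        if self.channel_weights.shape != (self.vectors.shape[0],):
            raise ValueError("one channel weight per vector required")
        if np.any(self.channel_weights < 0):
            raise ValueError("channel weights must be nonnegative")


class SEBlock(nn.Module):
    """Squeeze-and-excitation channel gate (pool -> C/r -> C -> sigmoid)."""

    def __init__(self, rng, channels: int, reduction: int):
        if channels % reduction != 0:
            raise ValueError(f"reduction {reduction} must divide channels {channels}")
        self.fc1 = nn.Dense(rng, channels, channels // reduction)
        self.fc2 = nn.Dense(rng, channels // reduction, channels)

    def gates(self, x: nn.Tensor) -> nn.Tensor:
        pooled = nn.global_avg_pool(x)
        return nn.sigmoid(self.fc2(nn.relu(self.fc1(pooled))))

    def __call__(self, x: nn.Tensor, bypass: bool = False) -> nn.Tensor:
        if bypass:  # exact identity; sigmoid saturation is unreachable otherwise
            return x
        return nn.scale_channels(x, self.gates(x))


class RankOneHead(nn.Module):
    """(n x 1) collapsing convolution plus two kernel-3 1-D refinements."""

    def __init__(self, rng, n: int, channels: int):
        self.n = n
        self.collapse_w = nn.he_init(rng, (channels, channels, n), channels * n)
        self.collapse_b = nn.Tensor(np.zeros(channels), requires_grad=True)
        self.refine1 = nn.Conv1d(rng, channels, channels, 3, pad=1)
        self.refine2 = nn.Conv1d(rng, channels, channels, 3, pad=1)
        self.raw_weights = nn.Tensor(np.zeros(channels), requires_grad=True)

    def vectors(self, x: nn.Tensor) -> nn.Tensor:
        if x.data.shape[2] != self.n or x.data.shape[3] != self.n:
            raise ValueError(
                f"spatial size {x.data.shape[2:]} does not match rank-one kernel n={self.n}"
            )
        v = nn.collapse_conv(x, self.collapse_w, self.collapse_b)
        v = nn.leaky_relu(v)
        v = nn.leaky_relu(self.refine1(v))
        v = self.refine2(v)
        return v  # (B, C, n)

    def weights(self) -> nn.Tensor:
        return nn.softplus(self.raw_weights)

    def reconstruct(self, v: nn.Tensor) -> nn.Tensor:
        maps = nn.outer_self(v)  # (B, C, n, n), each channel exactly symmetric
        return nn.mul(maps, _expand(self.weights()))

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        return self.reconstruct(self.vectors(x))


def _expand(w: nn.Tensor) -> nn.Tensor:
    """(C,) -> (1, C, 1, 1) view usable in broadcasting multiplications."""
    data = w.data.reshape(1, -1, 1, 1)

    def vjp(g):
        return g.sum(axis=(0, 2, 3))

    return nn.Tensor(data, vjps=[(w, vjp)])


class Branch(nn.Module):
    """One generator branch operating at a fixed spatial size ``n``."""

    def __init__(self, rng, n: int, cfg: GeneratorConfig):
        c1, c2 = cfg.stem_channels
        self.stem1 = nn.Conv2d(rng, 1, c1, 3, pad=1)
        self.stem2 = nn.Conv2d(rng, c1, c2, 3, pad=1)
        self.se = SEBlock(rng, c2, cfg.se_reduction)
        self.head = RankOneHead(rng, n, c2)
        self.proj = nn.Conv2d(rng, c2, cfg.branch_channels, 1)

    def __call__(self, x: nn.Tensor, se_bypass: bool = False) -> nn.Tensor:
        f = nn.leaky_relu(self.stem1(x))
        f = nn.leaky_relu(self.stem2(f))
        f = self.se(f, bypass=se_bypass)
        y = nn.add(self.head(f), f)  # additive skip from the stem stack
        return nn.leaky_relu(self.proj(y))


class Generator(nn.Module):
    """Dual-branch generator mapping (w x w, k x k) tiles to a k x k tile."""

    def __init__(self, cfg: GeneratorConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.branch_outer = Branch(rng, cfg.window, cfg)
        self.branch_central = Branch(rng, cfg.central, cfg)
        fused_in = 2 * cfg.branch_channels
        self.fuse1 = nn.Conv2d(rng, fused_in, cfg.fusion_channels, 1)
        # negative output bias starts predictions near zero (sparse targets)
        self.fuse2 = nn.Conv2d(rng, cfg.fusion_channels, 1, 1, bias_init=-3.0)

    def __call__(self, outer: nn.Tensor, central: nn.Tensor,
                 se_bypass: bool = False) -> nn.Tensor:
        cfg = self.cfg
        # symmetrize inputs so generator(M^T) == generator(M) exactly
        outer = nn.mul(nn.add(outer, nn.transpose_last2(outer)), 0.5)
        central = nn.mul(nn.add(central, nn.transpose_last2(central)), 0.5)
        yo = self.branch_outer(outer, se_bypass=se_bypass)
        p = (cfg.window - cfg.central) // 2
        yo = nn.crop2d(yo, p, p + cfg.central, p, p + cfg.central)
        yc = self.branch_central(central, se_bypass=se_bypass)
        z = nn.concat([yo, yc], axis=1)
        z = nn.leaky_relu(self.fuse1(z))
        z = self.fuse2(z)
        z = nn.mul(nn.add(z, nn.transpose_last2(z)), 0.5)
        return nn.clamp_max(nn.softplus(z), cfg.output_clamp)


class Discriminator(nn.Module):
    """Strided convolution stack scoring k x k tiles for realness."""

    def __init__(self, cfg: DiscriminatorConfig, rng: np.random.Generator):
        self.cfg = cfg
        chans = (1,) + cfg.channels
        self.convs = [
            nn.Conv2d(rng, chans[i], chans[i + 1], 3, stride=2, pad=1)
            for i in range(len(cfg.channels))
        ]
        if cfg.patch_output:
            self.out_conv = nn.Conv2d(rng, cfg.channels[-1], 1, 1)
        else:
            self.out_dense = nn.Dense(rng, cfg.channels[-1], 1)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        for conv in self.convs:
            x = nn.leaky_relu(conv(x))
        if self.cfg.patch_output:
            return self.out_conv(x)
        return self.out_dense(nn.global_avg_pool(x))  # (B, 1)


# ---------------------------------------------------------------------------
# spec-level functional wrappers (channels-last, single sample, no grad)
# ---------------------------------------------------------------------------

def _to_bchw(x: np.ndarray) -> np.ndarray:
    """(n, n, C) or (n, n) channels-last -> (1, C, n, n)."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:
        x = x[:, :, None]
    if x.ndim != 3 or x.shape[0] != x.shape[1]:
        raise ValueError(f"expected (n, n, C) input, got shape {x.shape}")
    return np.transpose(x, (2, 0, 1))[None]


def rank_one_extract(x: np.ndarray, head: RankOneHead) -> RankOneBundle:
    """Collapse an (n, n, C) feature stack into per-channel vectors."""
    t = nn.Tensor(_to_bchw(x))
    v = head.vectors(t)
    return RankOneBundle(vectors=v.data[0], channel_weights=head.weights().data)


def rank_one_reconstruct(bundle: RankOneBundle) -> np.ndarray:
    """Weighted outer products -> (n, n, C); each channel is exactly symmetric."""
    v = bundle.vectors
    maps = bundle.channel_weights[:, None, None] * (v[:, :, None] * v[:, None, :])
    return np.transpose(maps, (1, 2, 0))


def se_recalibrate(x: np.ndarray, se: SEBlock, bypass: bool = False) -> np.ndarray:
    """Gate an (n, n, C) stack channel-wise through the SE perceptron."""
    t = nn.Tensor(_to_bchw(x))
    out = se(t, bypass=bypass)
    return np.transpose(out.data[0], (1, 2, 0))


def generator_forward(outer: np.ndarray, central: np.ndarray,
                      gen: Generator, se_bypass: bool = False) -> np.ndarray:
    """Run the generator on one tile pair; returns the enhanced k x k tile."""
    outer = np.asarray(outer, dtype=np.float64)
    central = np.asarray(central, dtype=np.float64)
    if not (np.all(np.isfinite(outer)) and np.all(np.isfinite(central))):
        raise ValueError("non-finite values in generator input")
    w, k = gen.cfg.window, gen.cfg.central
    if outer.shape != (w, w) or central.shape != (k, k):
        raise ValueError(
            f"expected tiles ({w},{w}) and ({k},{k}), got {outer.shape} and {central.shape}"
        )
    out = gen(nn.Tensor(outer[None, None]), nn.Tensor(central[None, None]),
              se_bypass=se_bypass)
    return out.data[0, 0]


def discriminator_forward(tile: np.ndarray, disc: Discriminator):
    """Score one k x k tile; scalar unless the config asks for a patch grid."""
    tile = np.asarray(tile, dtype=np.float64)
    if tile.ndim != 2 or tile.shape[0] != tile.shape[1]:
        raise ValueError(f"expected a square tile, got shape {tile.shape}")
    out = disc(nn.Tensor(tile[None, None]))
    if disc.cfg.patch_output:
        return out.data[0, 0]
    return float(out.data[0, 0])


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

@dataclass
class Checkpoint:
    generator: Generator
    discriminator: Discriminator
    gcfg: GeneratorConfig
    dcfg: DiscriminatorConfig
    cap: float
    seed: int


def save_checkpoint(path, ckpt: Checkpoint) -> None:
    meta = {
        "gcfg": asdict(ckpt.gcfg),
        "dcfg": asdict(ckpt.dcfg),
        "cap": ckpt.cap,
        "seed": ckpt.seed,
        "format": 1,
    }
    arrays = {f"g::{k}": v for k, v in ckpt.generator.state().items()}
    arrays.update({f"d::{k}": v for k, v in ckpt.discriminator.state().items()})
    arrays["__meta__"] = np.frombuffer(json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> Checkpoint:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        g_state = {k[3:]: data[k] for k in data.files if k.startswith("g::")}
        d_state = {k[3:]: data[k] for k in data.files if k.startswith("d::")}
    gcfg = GeneratorConfig(**{k: tuple(v) if isinstance(v, list) else v
                              for k, v in meta["gcfg"].items()})
    dcfg = DiscriminatorConfig(**{k: tuple(v) if isinstance(v, list) else v
                                  for k, v in meta["dcfg"].items()})
    rng = np.random.default_rng(0)  # weights overwritten below
    gen = Generator(gcfg, rng)
    gen.load_state(g_state)
    disc = Discriminator(dcfg, rng)
    disc.load_state(d_state)
    return Checkpoint(generator=gen, discriminator=disc, gcfg=gcfg, dcfg=dcfg,
                      cap=float(meta["cap"]), seed=int(meta["seed"]))
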