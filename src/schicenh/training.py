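"""Pair construction, adversarial training loop and whole-matrix enhancement.

Supervision pairs come from binomial downsampling: the network sees tiles
of the thinned matrix and regresses the matching tiles of the original.
The loss is lambda_rec * L1 + lambda_adv * least-squares GAN, with one
discriminator step per generator step.  Validation splits are by whole
cells so overlapping tile context never leaks across the split.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .matio import (
    ContactMatrix,
    default_cap,
    denormalize,
    extract_submatrices,
    merge_submatrices,
    normalize,
)
from .model import (
    Checkpoint,
    Discriminator,
    DiscriminatorConfig,
    Generator,
    GeneratorConfig,
)
from .synthetic import downsample

__all__ = ["TrainConfig", "TrainHistory", "TilePairs", "make_pairs", "train_gan", "enhance"]


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 16
    lr_g: float = 1e-4
    lr_d: float = 1e-4
    lambda_rec: float = 10.0
    lambda_adv: float = 1.0
    downsample_ratio: float = 9.0
    seed: int = 0
    validation_fraction: float = 0.1

    def __post_init__(self):
        if self.lambda_rec <= 0:
            raise ValueError("lambda_rec must be positive")
        if self.lambda_adv < 0:
            raise ValueError("lambda_adv must be nonnegative")
        if not (0 <= self.validation_fraction < 1):
            raise ValueError("validation_fraction must be in [0, 1)")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")


@dataclass
class TrainHistory:
    g_loss: list = field(default_factory=list)
    d_loss: list = field(default_factory=list)
    val_mae: list = field(default_factory=list)

    def as_rows(self):
        return list(zip(range(1, len(self.g_loss) + 1), self.g_loss, self.d_loss, self.val_mae))


@dataclass
class TilePairs:
    """Aligned (context, central input, target) tiles across a cohort."""

    outer: np.ndarray  # (N, w, w) normalized downsampled context
    central: np.ndarray  # (N, k, k) normalized downsampled central crop
    target: np.ndarray  # (N, k, k) normalized original central block
    cell_index: np.ndarray  # (N,)
    cap: float
    window: int
    central_size: int


def make_pairs(cells: list[ContactMatrix], ratio: float, seed: int,
               window: int = 40, central: int = 28,
               cap: float | None = None) -> TilePairs:
    """Downsample each cell and tile both versions into training pairs."""
    if not cells:
        raise ValueError("empty cell list")
    if ratio < 1:
        raise ValueError("downsampling ratio must be >= 1")
    if cap is None:
        cap = default_cap(cells)
    ds_seeds = np.random.SeedSequence(seed).generate_state(len(cells))
    outer, central_in, target, cell_index = [], [], [], []
    p = (window - central) // 2
    for ci, cell in enumerate(cells):
        ds = downsample(cell, ratio, seed=int(ds_seeds[ci]))
        norm_ds = normalize(ds, cap)
        norm_orig = normalize(cell, cap)
        batch = extract_submatrices(norm_ds, window, central, cap=cap)
        for tile, anchor in zip(batch.outer_tiles, batch.anchors):
            outer.append(tile)
            central_in.append(tile[p : p + central, p : p + central])
            blk = np.zeros((central, central))
            ext = min(central, cell.n_bins - anchor)
            blk[:ext, :ext] = norm_orig.counts[anchor : anchor + ext, anchor : anchor + ext]
            target.append(blk)
            cell_index.append(ci)
    return TilePairs(
        outer=np.stack(outer),
        central=np.stack(central_in),
        target=np.stack(target),
        cell_index=np.asarray(cell_index),
        cap=float(cap),
        window=window,
        central_size=central,
    )


def _check_finite(value: float, what: str, epoch: int, batch: int):
    if not np.isfinite(value):
        raise RuntimeError(
            f"non-finite {what} loss ({value}) at epoch {epoch}, batch {batch}"
        )


def train_gan(pairs: TilePairs, gcfg: GeneratorConfig, dcfg: DiscriminatorConfig,
              tcfg: TrainConfig, log=None) -> tuple[Checkpoint, TrainHistory]:
    """Alternating LSGAN updates; ``lambda_adv=0`` reduces to L1 regression."""
    if pairs.outer.shape[0] < 1:
        raise ValueError("need at least one training pair")
    if gcfg.window != pairs.window or gcfg.central != pairs.central_size:
        raise ValueError("generator config tile sizes do not match the pairs")
    rng = np.random.default_rng(tcfg.seed)
    gen = Generator(gcfg, rng)
    disc = Discriminator(dcfg, rng)

    cells = np.unique(pairs.cell_index)
    shuffled = cells[rng.permutation(len(cells))]
    n_val = int(round(tcfg.validation_fraction * len(cells)))
    val_cells = set(shuffled[:n_val].tolist())
    val_mask = np.isin(pairs.cell_index, sorted(val_cells))
    train_idx = np.flatnonzero(~val_mask)
    val_idx = np.flatnonzero(val_mask)
    if train_idx.size == 0:
        raise ValueError("validation split left no training tiles")

    opt_g = nn.Adam(gen.parameters(), lr=tcfg.lr_g)
    opt_d = nn.Adam(disc.parameters(), lr=tcfg.lr_d)
    history = TrainHistory()

    for epoch in range(tcfg.epochs):
        order = train_idx[rng.permutation(train_idx.size)]
        g_losses, d_losses = [], []
        for bi, start in enumerate(range(0, order.size, tcfg.batch_size)):
            idx = order[start : start + tcfg.batch_size]
            outer = nn.Tensor(pairs.outer[idx][:, None])
            central = nn.Tensor(pairs.central[idx][:, None])
            target = nn.Tensor(pairs.target[idx][:, None])

            if tcfg.lambda_adv > 0:
                fake_detached = nn.Tensor(gen(outer, central).data)
                d_real = disc(target)
                d_fake = disc(fake_detached)
                d_loss = nn.add(
                    nn.mse_loss(d_real, np.ones_like(d_real.data)),
                    nn.mse_loss(d_fake, np.zeros_like(d_fake.data)),
                )
                _check_finite(float(d_loss.data), "discriminator", epoch, bi)
                opt_d.zero_grad()
                d_loss.backward()
                opt_d.step()
                d_losses.append(float(d_loss.data))
            else:
                d_losses.append(0.0)

            fake = gen(outer, central)
            g_loss = nn.mul(nn.l1_loss(fake, target), tcfg.lambda_rec)
            if tcfg.lambda_adv > 0:
                d_out = disc(fake)
                adv = nn.mse_loss(d_out, np.ones_like(d_out.data))
                g_loss = nn.add(g_loss, nn.mul(adv, tcfg.lambda_adv))
            _check_finite(float(g_loss.data), "generator", epoch, bi)
            opt_g.zero_grad()
            opt_d.zero_grad()
            g_loss.backward()
            opt_g.step()
            g_losses.append(float(g_loss.data))

        history.g_loss.append(float(np.mean(g_losses)))
        history.d_loss.append(float(np.mean(d_losses)))
        history.val_mae.append(_batched_mae(gen, pairs, val_idx if val_idx.size else train_idx))
        if log is not None:
            log(epoch + 1, history.g_loss[-1], history.d_loss[-1], history.val_mae[-1])

    ckpt = Checkpoint(generator=gen, discriminator=disc, gcfg=gcfg, dcfg=dcfg,
                      cap=pairs.cap, seed=tcfg.seed)
    return ckpt, history


def _batched_mae(gen: Generator, pairs: TilePairs, idx: np.ndarray,
                 chunk: int = 64) -> float:
    errs, n = 0.0, 0
    for start in range(0, idx.size, chunk):
        sl = idx[start : start + chunk]
        out = gen(nn.Tensor(pairs.outer[sl][:, None]), nn.Tensor(pairs.central[sl][:, None]))
        errs += float(np.abs(out.data[:, 0] - pairs.target[sl]).sum())
        n += pairs.target[sl].size
    return errs / max(n, 1)


def enhance(ckpt: Checkpoint, m: ContactMatrix, chunk: int = 16) -> ContactMatrix:
    """Normalize, tile, run the generator and merge back to a full matrix.

    Entries outside the enhanced diagonal band are copied from the input;
    the output is symmetric and nonnegative.
    """
    w, k = ckpt.gcfg.window, ckpt.gcfg.central
    if m.n_bins < k:
        raise ValueError(f"matrix has {m.n_bins} bins, need at least central={k}")
    norm = normalize(m, ckpt.cap)
    batch = extract_submatrices(norm, w, k, cap=ckpt.cap)
    p = (w - k) // 2
    outer = np.stack(batch.outer_tiles)[:, None]
    central = outer[:, :, p : p + k, p : p + k]
    outs = []
    for start in range(0, outer.shape[0], chunk):
        res = ckpt.generator(nn.Tensor(outer[start : start + chunk]),
                             nn.Tensor(central[start : start + chunk]))
        outs.append(res.data[:, 0])
    enhanced_norm = np.concatenate(outs, axis=0)
    denorm_tiles = [np.clip(np.expm1(t * ckpt.cap), 0.0, None) for t in enhanced_norm]
    raw_batch = extract_submatrices(m, w, k, cap=ckpt.cap)
    out = merge_submatrices(raw_batch, denorm_tiles)
    return replace(out, cell_id=m.cell_id)
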