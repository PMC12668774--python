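"""Contact-matrix container, sparse triplet I/O, normalization and tiling.

Conventions follow cooler-style single-chromosome matrices: 0-based bins,
half-open intervals, and an upper-triangle ``bin_i<TAB>bin_j<TAB>count``
text format (gzip-transparent).  Lines starting with ``#`` are comments.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ContactMatrix",
    "SubmatrixBatch",
    "read_triplets",
    "write_triplets",
    "normalize",
    "denormalize",
    "default_cap",
    "extract_submatrices",
    "merge_submatrices",
]


@dataclass
class ContactMatrix:
    """One cell x one chromosome symmetric contact matrix."""

    cell_id: str
    chrom: str
    resolution_bp: int
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError(f"counts must be square, got shape {self.counts.shape}")
        if self.n_bins < 2:
            raise ValueError("contact matrix needs at least 2 bins")
        if self.resolution_bp <= 0:
            raise ValueError("resolution_bp must be positive")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if not np.array_equal(self.counts, self.counts.T):
            raise ValueError("counts must be symmetric")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def copy(self) -> "ContactMatrix":
        return replace(self, counts=self.counts.copy())


@dataclass
class SubmatrixBatch:
    """Diagonal-band tiles of one matrix at two nested window sizes.

    ``outer_tiles[t]`` is the w x w context window whose central
    ``central_size`` x ``central_size`` block covers diagonal bins
    ``[anchors[t], anchors[t] + central_size)``.  ``valid_extents[t]`` is
    the number of non-padded central rows/cols of tile ``t``.
    """

    outer_tiles: list[np.ndarray]
    central_size: int
    anchors: list[int]
    source_n_bins: int
    normalization_cap: float
    valid_extents: list[int] = field(default_factory=list)
    source: ContactMatrix | None = None

    @property
    def window(self) -> int:
        return self.outer_tiles[0].shape[0]

    @property
    def pad(self) -> int:
        return (self.window - self.central_size) // 2

    def central_tiles(self) -> list[np.ndarray]:
        p, k = self.pad, self.central_size
        return [t[p : p + k, p : p + k] for t in self.outer_tiles]


# ---------------------------------------------------------------------------
# triplet text I/O
# ---------------------------------------------------------------------------

def _open_text(path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_triplets(path, n_bins: int, resolution_bp: int, cell_id: str = "",
                  chrom: str = "chr0") -> ContactMatrix:
    """Read an upper-triangle triplet file into a symmetric matrix.

    Duplicate (i, j) pairs are summed; missing pairs are zero.
    """
    counts = np.zeros((n_bins, n_bins))
    with _open_text(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            i, j = int(parts[0]), int(parts[1])
            c = float(parts[2])
            if i < 0 or j < 0 or i >= n_bins or j >= n_bins:
                raise ValueError(
                    f"{path}:{lineno}: bin index ({i}, {j}) out of range for n_bins={n_bins}"
                )
            if c < 0:
                raise ValueError(f"{path}:{lineno}: negative count {c}")
            counts[i, j] += c
            if i != j:
                counts[j, i] += c
    if np.all(counts == np.floor(counts)):
        counts = counts.astype(np.int64)
    return ContactMatrix(cell_id=cell_id or str(path), chrom=chrom,
                         resolution_bp=resolution_bp, counts=counts)


def write_triplets(m: ContactMatrix, path, header_lines: list[str] | None = None) -> None:
    """Write the nonzero upper triangle (i <= j) as triplet text."""
    iu, ju = np.triu_indices(m.n_bins)
    vals = m.counts[iu, ju]
    nz = vals != 0
    integral = np.all(m.counts == np.floor(m.counts))
    with _open_text(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write(f"# bin_i\tbin_j\tcount\tresolution_bp={m.resolution_bp}\tn_bins={m.n_bins}\n")
        for i, j, v in zip(iu[nz], ju[nz], vals[nz]):
            if integral:
                fh.write(f"{i}\t{j}\t{int(v)}\n")
            else:
                fh.write(f"{i}\t{j}\t{v:.17g}\n")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def default_cap(cells, percentile: float = 99.9) -> float:
    """log1p of the given percentile of nonzero counts across a cohort."""
    pool = []
    for m in cells:
        nz = m.counts[m.counts > 0]
        if nz.size:
            pool.append(nz)
    if not pool:
        return 1.0
    cap = float(np.log1p(np.percentile(np.concatenate(pool), percentile)))
    return max(cap, 1e-6)


def normalize(m: ContactMatrix, cap: float) -> ContactMatrix:
    """x -> min(log1p(x), cap) / cap, mapping counts into [0, 1]."""
    if cap <= 0:
        raise ValueError("cap must be positive")
    vals = np.minimum(np.log1p(m.counts.astype(np.float64)), cap) / cap
    return replace(m, counts=vals)


def denormalize(m: ContactMatrix, cap: float) -> ContactMatrix:
    """y -> expm1(y * cap), clipped at 0."""
    if cap <= 0:
        raise ValueError("cap must be positive")
    vals = np.clip(np.expm1(m.counts.astype(np.float64) * cap), 0.0, None)
    return replace(m, counts=vals)


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------

def extract_submatrices(m: ContactMatrix, window: int, central: int,
                        cap: float = 1.0) -> SubmatrixBatch:
    """Tile the diagonal into w x w context windows with k x k central targets.

    Anchors step by ``central`` along the diagonal; windows reaching past
    either matrix edge are zero-padded, with the valid central extent
    recorded per tile.
    """
    w, k = window, central
    if not (0 < k < w):
        raise ValueError(f"need 0 < central < window, got window={w} central={k}")
    if (w - k) % 2 != 0:
        raise ValueError(f"window - central must be even, got {w - k}")
    n = m.n_bins
    p = (w - k) // 2
    anchors = list(range(0, n, k)) or [0]
    tiles, extents = [], []
    for a in anchors:
        tile = np.zeros((w, w), dtype=np.float64)
        lo, hi = a - p, a - p + w
        src_lo, src_hi = max(lo, 0), min(hi, n)
        dst_lo, dst_hi = src_lo - lo, src_hi - lo
        tile[dst_lo:dst_hi, dst_lo:dst_hi] = m.counts[src_lo:src_hi, src_lo:src_hi]
        tiles.append(tile)
        extents.append(min(k, n - a))
    return SubmatrixBatch(
        outer_tiles=tiles,
        central_size=k,
        anchors=anchors,
        source_n_bins=n,
        normalization_cap=cap,
        valid_extents=extents,
        source=m,
    )


def merge_submatrices(batch: SubmatrixBatch, enhanced_tiles) -> ContactMatrix:
    """Re-assemble enhanced central blocks into a full matrix.

    Only the central k x k block of each enhanced tile (which is disjoint
    across tiles) is written at its anchor; everything outside the
    assembled diagonal blocks is copied from the source matrix.  The
    result is symmetrized as (M + M^T) / 2.
    """
    if batch.source is None:
        raise ValueError("batch has no source matrix to merge into")
    enhanced_tiles = list(enhanced_tiles)
    if len(enhanced_tiles) != len(batch.anchors):
        raise ValueError(
            f"tile count mismatch: {len(enhanced_tiles)} tiles for {len(batch.anchors)} anchors"
        )
    k, w, p = batch.central_size, batch.window, batch.pad
    out = batch.source.counts.astype(np.float64).copy()
    for tile, a, ext in zip(enhanced_tiles, batch.anchors, batch.valid_extents):
        tile = np.asarray(tile, dtype=np.float64)
        if tile.shape == (w, w):
            block = tile[p : p + k, p : p + k]
        elif tile.shape == (k, k):
            block = tile
        else:
            raise ValueError(f"enhanced tile has shape {tile.shape}, expected ({w},{w}) or ({k},{k})")
        out[a : a + ext, a : a + ext] = block[:ext, :ext]
    out = 0.5 * (out + out.T)
    return replace(batch.source, counts=out)
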