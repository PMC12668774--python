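"""Downstream chromatin-structure callers used to score enhancement.

A/B compartments come from the leading eigenvector of the row-wise
correlation of the observed/expected matrix (the classical method; the
orientation is fixed against a reference profile, typically pseudo-bulk).
TAD-like boundaries are prominence-filtered minima of a diamond
insulation track restricted to a near-diagonal band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .matio import ContactMatrix

__all__ = [
    "CompartmentProfile",
    "InsulationTrack",
    "BoundarySet",
    "observed_expected",
    "compartment_profile",
    "insulation_score",
    "call_boundaries",
]


@dataclass
class CompartmentProfile:
    labels: np.ndarray  # +1 (A), -1 (B), 0 (undetermined) per bin
    scores: np.ndarray  # oriented leading-eigenvector entries

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.labels.shape != self.scores.shape:
            raise ValueError("labels and scores must have equal length")


@dataclass
class InsulationTrack:
    scores: np.ndarray  # NaN where undefined (within window_bins of each end)
    window_bins: int


@dataclass
class BoundarySet:
    boundary_bins: np.ndarray

    def __post_init__(self):
        self.boundary_bins = np.unique(np.asarray(self.boundary_bins, dtype=np.int64))


def observed_expected(m: ContactMatrix) -> np.ndarray:
    """Divide each entry by its diagonal-stratum mean (zero-mean strata -> 0)."""
    counts = m.counts.astype(np.float64)
    n = m.n_bins
    out = np.zeros_like(counts)
    for d in range(n):
        mu = np.diagonal(counts, offset=d).mean()
        if mu == 0:
            continue
        idx = np.arange(n - d)
        out[idx, idx + d] = counts[idx, idx + d] / mu
        out[idx + d, idx] = out[idx, idx + d]
    return out


def compartment_profile(m: ContactMatrix, orientation_ref=None,
                        pseudocount: float = 1e-2) -> CompartmentProfile:
    """Leading eigenvector of the O/E correlation matrix, sign-oriented.

    Bins whose rows are all-zero (or constant after O/E) get label 0.
    When ``orientation_ref`` is provided the global sign is flipped to
    maximize label agreement with it; otherwise the convention is a
    nonnegative eigenvector sum.
    """
    if m.n_bins < 4:
        raise ValueError("need at least 4 bins for compartment calling")
    oe = observed_expected(m) + pseudocount
    informative = m.counts.sum(axis=1) > 0
    row_std = oe.std(axis=1)
    degenerate = (~informative) | (row_std == 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} degenerate bins labeled 0 in compartment call",
            stacklevel=2,
        )
    keep = np.flatnonzero(~degenerate)
    n = m.n_bins
    scores = np.zeros(n)
    labels = np.zeros(n, dtype=np.int64)
    if keep.size >= 2:
        corr = np.corrcoef(oe[np.ix_(keep, keep)])
        corr = np.nan_to_num(corr, nan=0.0)
        evals, evecs = np.linalg.eigh(corr)
        v = evecs[:, np.argmax(evals)]
        scores[keep] = v
        labels[keep] = np.sign(v).astype(np.int64)
        if orientation_ref is not None:
            ref = np.asarray(orientation_ref, dtype=np.float64)
            if ref.shape != (n,):
                raise ValueError("orientation_ref must have length n_bins")
            agree = float(np.sum(np.sign(ref[keep]) * labels[keep]))
            flip = agree < 0
        else:
            flip = scores.sum() < 0
        if flip:
            scores = -scores
            labels = -labels
    return CompartmentProfile(labels=labels, scores=scores)


def insulation_score(m: ContactMatrix, window_bins: int = 10,
                     band_bins: int = 20) -> InsulationTrack:
    """Diamond insulation: log2(local diamond mean / chromosome-wide mean).

    The diamond at bin i is counts[i-W:i, i+1:i+1+W], restricted to
    entries within ``band_bins`` of the diagonal.  Bins within W of
    either end are undefined (NaN).
    """
    W, B = window_bins, band_bins
    n = m.n_bins
    if not (1 <= W <= B <= n):
        raise ValueError(f"need 1 <= window ({W}) <= band ({B}) <= n_bins ({n})")
    if W > n / 2:
        raise ValueError(f"window {W} too large for {n} bins")
    counts = m.counts.astype(np.float64)
    rows = np.arange(1, W + 1)
    dist_mask = (rows[:, None] + rows[None, :]) <= B  # distance of (i-a, i+b) is a+b
    diamonds = np.full(n, np.nan)
    for i in range(W, n - W):
        block = counts[i - W : i, i + 1 : i + 1 + W][::-1]  # row a-1 is bin i-a
        vals = block[dist_mask]
        diamonds[i] = vals.mean() if vals.size else np.nan
    finite = diamonds[np.isfinite(diamonds)]
    global_mean = finite.mean() if finite.size else np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.log2(diamonds / global_mean)
    return InsulationTrack(scores=scores, window_bins=W)


def call_boundaries(track: InsulationTrack, delta_threshold: float = 0.1) -> BoundarySet:
    """Local insulation minima with prominence >= ``delta_threshold``."""
    if delta_threshold < 0:
        raise ValueError("delta_threshold must be nonnegative")
    scores = np.asarray(track.scores, dtype=np.float64)
    finite = np.isfinite(scores)
    boundaries = []
    # process each contiguous defined segment separately; -inf dips (zero
    # diamonds) are clamped to a finite floor so prominence stays defined
    i = 0
    n = scores.size
    while i < n:
        if not finite[i] and not np.isneginf(scores[i]):
            i += 1
            continue
        j = i
        while j < n and (finite[j] or np.isneginf(scores[j])):
            j += 1
        seg = scores[i:j].copy()
        if seg.size >= 3:
            seg_finite = seg[np.isfinite(seg)]
            floor = (seg_finite.min() if seg_finite.size else 0.0) - 10.0
            seg[np.isneginf(seg)] = floor
            peaks, _ = find_peaks(-seg, prominence=delta_threshold if delta_threshold > 0 else None)
            boundaries.extend((i + p) for p in peaks)
        i = j
    return BoundarySet(boundary_bins=np.asarray(boundaries, dtype=np.int64))
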