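"""Bin voxels on an Nbin x Nbin grid over joint (MR1, MR2) intensity space.

Each cell accumulates the count and mean CT number of the training voxels
whose normalized intensities fall in it; empty cells are imputed from the
nearest filled cell (Euclidean distance in bin-index units) before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "TrainingSample",
    "BinGrid",
    "bin_index",
    "build_bin_grid",
    "fill_empty_bins",
]


@dataclass(frozen=True)
class TrainingSample:
    """One voxel of training data: normalized intensities, CT number, region code."""

    s1: float
    s2: float
    ct: float
    region: int = 0


@dataclass
class BinGrid:
    """Accumulator over joint intensity space.

    ``counts`` and ``filled`` always describe the raw data (imputation does
    not touch them); ``mean_ct`` / ``weights`` are NaN / 0 on empty bins until
    :func:`fill_empty_bins` runs.
    """

    nbin: int
    axis_max: tuple[float, float]
    counts: np.ndarray
    mean_ct: np.ndarray
    filled: np.ndarray
    weights: np.ndarray
    imputed: bool = False

    @property
    def bin_width(self) -> tuple[float, float]:
        return (self.axis_max[0] / self.nbin, self.axis_max[1] / self.nbin)

    def centers(self, axis: int) -> np.ndarray:
        """Bin-center intensities along one axis."""
        w = self.axis_max[axis] / self.nbin
        return (np.arange(self.nbin) + 0.5) * w

    def to_frame(self) -> pd.DataFrame:
        i, j = np.meshgrid(np.arange(self.nbin), np.arange(self.nbin), indexing="ij")
        return pd.DataFrame(
            {
                "i": i.ravel(),
                "j": j.ravel(),
                "count": self.counts.ravel(),
                "mean_ct": self.mean_ct.ravel(),
                "filled": self.filled.ravel(),
                "weight": self.weights.ravel(),
            }
        )

    def save_table(self, path) -> None:
        self.to_frame().to_csv(Path(path), index=False)


def bin_index(
    value: float | np.ndarray, axis_max: float, nbin: int
) -> int | np.ndarray:
    """Map an intensity to its bin along one axis.

    Bins are half-open ``[i*w, (i+1)*w)`` with width ``w = axis_max / nbin``,
    except the last bin which is closed above; values beyond ``axis_max``
    clamp into the last bin (the model is untrained beyond the observed
    range).
    """
    if axis_max <= 0:
        raise ValueError(f"axis_max must be positive, got {axis_max}")
    if nbin < 1:
        raise ValueError(f"nbin must be >= 1, got {nbin}")
    arr = np.asarray(value, dtype=np.float64)
    if np.any(arr < 0):
        raise ValueError("negative intensity value")
    idx = np.floor(arr * nbin / axis_max).astype(np.int64)
    idx = np.clip(idx, 0, nbin - 1)
    if np.isscalar(value) or arr.ndim == 0:
        return int(idx)
    return idx


def build_bin_grid(
    samples: Iterable[TrainingSample] | None = None,
    nbin: int = 200,
    axis_max: tuple[float, float] | None = None,
    *,
    s1: np.ndarray | None = None,
    s2: np.ndarray | None = None,
    ct: np.ndarray | None = None,
) -> BinGrid:
    """Accumulate samples into counts and per-bin arithmetic-mean CT.

    Accepts either an iterable of :class:`TrainingSample` or the three
    parallel arrays ``s1``, ``s2``, ``ct``.  ``axis_max`` defaults to the
    per-axis sample maximum.
    """
    if samples is not None:
        samples = list(samples)
        s1 = np.array([s.s1 for s in samples], dtype=np.float64)
        s2 = np.array([s.s2 for s in samples], dtype=np.float64)
        ct = np.array([s.ct for s in samples], dtype=np.float64)
    if s1 is None or s2 is None or ct is None:
        raise ValueError("provide samples or all of s1, s2, ct")
    s1 = np.asarray(s1, dtype=np.float64).ravel()
    s2 = np.asarray(s2, dtype=np.float64).ravel()
    ct = np.asarray(ct, dtype=np.float64).ravel()
    if s1.size == 0:
        raise ValueError("empty sample list")
    if not (s1.size == s2.size == ct.size):
        raise ValueError("s1, s2, ct must have equal length")
    if not np.all(np.isfinite(ct)):
        raise ValueError("non-finite CT values in training samples")

    if axis_max is None:
        axis_max = (float(np.max(s1)) or 1.0, float(np.max(s2)) or 1.0)
    axis_max = (float(axis_max[0]), float(axis_max[1]))

    i = bin_index(s1, axis_max[0], nbin)
    j = bin_index(s2, axis_max[1], nbin)
    flat = np.asarray(i) * nbin + np.asarray(j)
    counts = np.bincount(flat, minlength=nbin * nbin).reshape(nbin, nbin)
    sums = np.bincount(flat, weights=ct, minlength=nbin * nbin).reshape(nbin, nbin)
    filled = counts > 0
    mean_ct = np.full((nbin, nbin), np.nan)
    mean_ct[filled] = sums[filled] / counts[filled]
    weights = counts.astype(np.float64)
    return BinGrid(
        nbin=nbin,
        axis_max=axis_max,
        counts=counts,
        mean_ct=mean_ct,
        filled=filled,
        weights=weights,
    )


def fill_empty_bins(grid: BinGrid, empty_weight_fraction: float = 0.1) -> BinGrid:
    """Impute each empty bin from its nearest filled bin(s).

    The empty bin at index ``(ie, je)`` receives the mean CT of the filled bin
    minimizing ``d = sqrt((i - ie)^2 + (j - je)^2)``.  When several filled
    bins tie at the minimal distance, the assigned value is the average over
    the tied set, and the imputed weight is ``empty_weight_fraction`` times
    the (average) weight of the tied set.  Filled bins are unchanged; the
    operation is idempotent.
    """
    if not np.any(grid.filled):
        raise ValueError("cannot impute: all bins are empty")
    mean_ct = grid.mean_ct.copy()
    weights = grid.weights.copy()
    empty_idx = np.argwhere(~grid.filled)
    if empty_idx.size:
        filled_idx = np.argwhere(grid.filled)
        tree = cKDTree(filled_idx)
        dmin, _ = tree.query(empty_idx)
        # distances are sqrt of integers; find all filled bins at exactly the
        # minimal squared distance so ties are averaged
        d2min = np.rint(dmin * dmin).astype(np.int64)
        neighbors = tree.query_ball_point(empty_idx, dmin + 1e-6)
        fvals = grid.mean_ct[grid.filled]
        fweights = grid.weights[grid.filled]
        for (ie, je), d2, cand in zip(empty_idx, d2min, neighbors):
            cand = np.asarray(cand)
            dd = filled_idx[cand] - np.array([ie, je])
            tied = cand[np.einsum("ij,ij->i", dd, dd) == d2]
            mean_ct[ie, je] = float(np.mean(fvals[tied]))
            weights[ie, je] = empty_weight_fraction * float(np.mean(fweights[tied]))
    return replace(grid, mean_ct=mean_ct, weights=weights, imputed=True)
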