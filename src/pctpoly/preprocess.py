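"""Cohort intensity normalization, body masking, and mm-margin region labels."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .volumes import BONY, MIXED, OUTSIDE, SOFT, ImageVolume, RegionLabelMap

__all__ = [
    "NormalizationModel",
    "MaskParams",
    "fit_normalization",
    "normalization_factor",
    "apply_normalization",
    "make_body_mask",
    "build_region_labels",
    "mark_air",
]

AIR_HU = -1000.0


@dataclass
class NormalizationModel:
    """Multiplicative per-patient intensity correction for one MR sequence.

    ``factor = cohort_mean / patient_mean``; after multiplying a patient's
    volume by its factor, every patient's body-voxel mean equals
    ``cohort_mean``.
    """

    cohort_mean: float
    patient_factors: dict[str, float] = field(default_factory=dict)

    def factor(self, patient_id: str) -> float:
        return self.patient_factors[patient_id]


@dataclass
class MaskParams:
    """Parameters for body masking and region-margin construction (mm)."""

    body_threshold: float = 0.0
    closing_radius_mm: float = 2.0
    bone_inner_margin_mm: float = 1.0
    soft_exclusion_margin_mm: float = 2.5

    def __post_init__(self) -> None:
        if self.closing_radius_mm < 0:
            raise ValueError("closing_radius_mm must be >= 0")
        if self.bone_inner_margin_mm < 0 or self.soft_exclusion_margin_mm < 0:
            raise ValueError("margins must be >= 0")


def patient_body_mean(vol: ImageVolume, body_mask: np.ndarray) -> float:
    if body_mask.shape != vol.shape:
        raise ValueError("body mask shape does not match volume")
    if not np.any(body_mask):
        raise ValueError("empty body mask")
    return float(np.mean(vol.data[body_mask]))


def fit_normalization(
    patient_volumes: Iterable[tuple[str, ImageVolume, np.ndarray]],
) -> NormalizationModel:
    """Fit the cohort normalization from ``(patient_id, volume, body_mask)`` triples.

    The cohort mean is the unweighted mean of per-patient body-voxel means, so
    patients with larger bodies do not dominate.  Each patient's factor is
    ``cohort_mean / patient_mean``.
    """
    ids: list[str] = []
    means: list[float] = []
    for pid, vol, mask in patient_volumes:
        if not np.any(mask):
            raise ValueError(f"patient {pid}: empty body mask")
        m = patient_body_mean(vol, mask)
        if m <= 0:
            raise ValueError(f"patient {pid}: nonpositive body-mean intensity {m}")
        ids.append(pid)
        means.append(m)
    if not ids:
        raise ValueError("need at least one patient to fit normalization")
    cohort_mean = float(np.mean(means))
    factors = {pid: cohort_mean / m for pid, m in zip(ids, means)}
    return NormalizationModel(cohort_mean=cohort_mean, patient_factors=factors)


def normalization_factor(cohort_mean: float, patient_mean: float) -> float:
    """Correction factor for a patient outside the fitting cohort (e.g. LOOCV target)."""
    if patient_mean <= 0:
        raise ValueError(f"nonpositive patient mean {patient_mean}")
    return cohort_mean / patient_mean


def apply_normalization(vol: ImageVolume, factor: float) -> ImageVolume:
    if factor <= 0:
        raise ValueError(f"normalization factor must be positive, got {factor}")
    return vol.with_data(vol.data * factor)


def _footprint(radius_mm: float, spacing: Sequence[float]) -> np.ndarray | None:
    """Ellipsoidal structuring element for a mm radius on an anisotropic grid.

    The mm radius is converted per-axis to a voxel radius rounded to nearest
    integer (minimum 0); a radius of 0 on every axis means identity (None).
    """
    r = [max(0, int(round(radius_mm / s))) for s in spacing]
    if all(ri == 0 for ri in r):
        return None
    grids = np.meshgrid(*[np.arange(-ri, ri + 1) for ri in r], indexing="ij")
    dist2 = np.zeros(grids[0].shape)
    for g, ri in zip(grids, r):
        dist2 += (g / max(ri, 1)) ** 2
    return dist2 <= 1.0 + 1e-9


def make_body_mask(vol: ImageVolume, params: MaskParams) -> np.ndarray:
    """Binary body mask: threshold, close, fill holes, keep the largest component."""
    data = vol.data
    if not np.all(np.isfinite(data)):
        raise ValueError("volume contains non-finite values")
    mask = data > params.body_threshold
    if not np.any(mask):
        raise ValueError(f"no voxel above threshold {params.body_threshold}")
    fp = _footprint(params.closing_radius_mm, vol.spacing)
    if fp is not None:
        mask = ndimage.binary_closing(mask, structure=fp)
    mask = ndimage.binary_fill_holes(mask)
    labeled, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n + 1))
        mask = labeled == (1 + int(np.argmax(sizes)))
    return mask.astype(bool)


def build_region_labels(
    bone_mask: np.ndarray,
    body_mask: np.ndarray,
    spacing: Sequence[float],
    params: MaskParams,
) -> RegionLabelMap:
    """Partition the body into BONY / SOFT / MIXED around a bone mask.

    BONY is the bone mask eroded inward by ``bone_inner_margin_mm``; SOFT is
    the body minus the bone mask dilated by ``soft_exclusion_margin_mm``; the
    remaining body shell between the two margins is MIXED.
    """
    bone_mask = np.asarray(bone_mask, dtype=bool)
    body_mask = np.asarray(body_mask, dtype=bool)
    if bone_mask.shape != body_mask.shape:
        raise ValueError("bone and body masks must have the same shape")
    if np.any(bone_mask & ~body_mask):
        raise ValueError("bone mask extends outside the body mask")

    fp_in = _footprint(params.bone_inner_margin_mm, spacing)
    bony = ndimage.binary_erosion(bone_mask, structure=fp_in) if fp_in is not None else bone_mask
    fp_out = _footprint(params.soft_exclusion_margin_mm, spacing)
    dilated = ndimage.binary_dilation(bone_mask, structure=fp_out) if fp_out is not None else bone_mask
    soft = body_mask & ~dilated
    mixed = body_mask & ~bony & ~soft

    labels = np.full(body_mask.shape, OUTSIDE, dtype=np.int16)
    labels[mixed] = MIXED
    labels[soft] = SOFT
    labels[bony & body_mask] = BONY
    return RegionLabelMap(labels=labels)


def mark_air(pct: ImageVolume, body_mask: np.ndarray) -> ImageVolume:
    """Set all voxels outside the body to exactly -1000 HU."""
    if np.asarray(body_mask).shape != pct.shape:
        raise ValueError(
            f"mask shape {np.asarray(body_mask).shape} does not match volume shape {pct.shape}"
        )
    data = pct.data.copy()
    data[~np.asarray(body_mask, dtype=bool)] = AIR_HU
    return pct.with_data(data)
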