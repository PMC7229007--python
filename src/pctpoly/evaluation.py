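"""HU-error metrics, the error-budget decomposition, and the dose comparator.

Conventions: MAE is the mean absolute voxel difference, sigma the RMS
difference over the same voxels (so sigma >= MAE always).  The fit error is
the count-weighted deviation of the model from the per-bin mean CT; the
spread error is the within-bin deviation of individual voxels from their bin
mean; with per-bin predictions the two add exactly in quadrature to the
total RMS error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .binning import BinGrid, bin_index
from .model import InterpolationModel, PolynomialModel
from .volumes import BODY_REGIONS, REGION_NAMES, ImageVolume, RegionLabelMap

__all__ = [
    "mae",
    "rms_diff",
    "fit_errors",
    "spread_errors",
    "decomposition_check",
    "weighted_region_table",
    "ScopeMetrics",
    "EvaluationReport",
    "evaluate_patient",
    "DoseReport",
    "dose_passing_rate",
]


def _masked_diff(pct: ImageVolume, rct: ImageVolume, mask: np.ndarray) -> np.ndarray:
    if pct.shape != rct.shape:
        raise ValueError(f"volume shapes differ: {pct.shape} vs {rct.shape}")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != pct.shape:
        raise ValueError("mask shape does not match volumes")
    if not np.any(mask):
        raise ValueError("empty evaluation mask")
    return pct.data[mask] - rct.data[mask]


def mae(pct: ImageVolume, rct: ImageVolume, mask: np.ndarray) -> float:
    """Mean absolute HU difference over masked voxels."""
    return float(np.mean(np.abs(_masked_diff(pct, rct, mask))))


def rms_diff(pct: ImageVolume, rct: ImageVolume, mask: np.ndarray) -> float:
    """Root-mean-square HU difference over masked voxels."""
    return float(np.sqrt(np.mean(_masked_diff(pct, rct, mask) ** 2)))


def fit_errors(
    grid: BinGrid, model: PolynomialModel | InterpolationModel
) -> tuple[float, float]:
    """Goodness of fit of the model to the per-bin mean CT.

    Count-weighted mean absolute and RMS deviation between the bin means and
    the model evaluated at the bin centers, over filled bins; the normalizer
    is the total voxel count.
    """
    total = int(grid.counts.sum())
    if total == 0:
        raise ValueError("zero total count in bin grid")
    sel = grid.filled
    c1, c2 = np.meshgrid(grid.centers(0), grid.centers(1), indexing="ij")
    pred = model.evaluate(c1[sel], c2[sel])
    dev = grid.mean_ct[sel] - pred
    n = grid.counts[sel].astype(np.float64)
    mae_fit = float(np.sum(np.abs(dev) * n) / total)
    sigma_fit = float(np.sqrt(np.sum(dev**2 * n) / total))
    return mae_fit, sigma_fit


def spread_errors(
    grid: BinGrid, s1: np.ndarray, s2: np.ndarray, rct: np.ndarray
) -> tuple[float, float]:
    """Within-bin CT spread: deviation of each voxel's CT from its bin mean.

    Voxels are assigned to bins with the grid's own axis maxima; the
    normalizer is the total voxel count pooled over all bins.
    """
    s1 = np.asarray(s1, dtype=np.float64).ravel()
    s2 = np.asarray(s2, dtype=np.float64).ravel()
    rct = np.asarray(rct, dtype=np.float64).ravel()
    if s1.size == 0:
        raise ValueError("no voxels")
    i = bin_index(s1, grid.axis_max[0], grid.nbin)
    j = bin_index(s2, grid.axis_max[1], grid.nbin)
    dev = rct - grid.mean_ct[np.asarray(i), np.asarray(j)]
    return float(np.mean(np.abs(dev))), float(np.sqrt(np.mean(dev**2)))


def decomposition_check(sigma_pct: float, sigma_rct: float, sigma_fit: float) -> float:
    """Relative discrepancy of the quadrature error budget.

    Returns ``|sigma_pct^2 - (sigma_rct^2 + sigma_fit^2)| / sigma_pct^2``.
    With per-bin predictions the cross term vanishes by the bin-mean
    property, so the discrepancy is zero up to rounding; with per-voxel
    predictions it is small on smooth data.
    """
    if sigma_pct < 0 or sigma_rct < 0 or sigma_fit < 0:
        raise ValueError("sigma inputs must be nonnegative")
    if sigma_pct == 0:
        if sigma_rct == 0 and sigma_fit == 0:
            return 0.0
        raise ValueError("sigma_pct is zero with nonzero components")
    return float(abs(sigma_pct**2 - (sigma_rct**2 + sigma_fit**2)) / sigma_pct**2)


def weighted_region_table(
    raw_mae_by_region: Mapping[str, float], counts_by_region: Mapping[str, int]
) -> pd.DataFrame:
    """Weighted-MAE accounting: region MAE scaled by its voxel fraction.

    The weighted values sum to the overall MAE when the regions partition the
    evaluated voxels.
    """
    regions = list(raw_mae_by_region)
    if set(regions) != set(counts_by_region):
        raise ValueError("raw MAE and counts must cover the same regions")
    total = float(sum(counts_by_region.values()))
    if total <= 0:
        raise ValueError("zero total voxel count")
    rows = []
    for r in regions:
        frac = counts_by_region[r] / total
        rows.append(
            {
                "region": r,
                "voxel_count": int(counts_by_region[r]),
                "voxel_fraction": frac,
                "raw_mae": float(raw_mae_by_region[r]),
                "weighted_mae": float(raw_mae_by_region[r]) * frac,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["overall_mae"] = float(df["weighted_mae"].sum())
    return df


@dataclass
class ScopeMetrics:
    """Error metrics for one evaluation scope (overall or one region)."""

    voxel_count: int
    mae: float
    sigma: float
    voxel_fraction: float | None = None
    weighted_mae: float | None = None
    mae_fit: float | None = None
    sigma_fit: float | None = None
    mae_rct: float | None = None
    sigma_rct: float | None = None


@dataclass
class EvaluationReport:
    """Per-scope metrics for one evaluated patient (or pooled set)."""

    scopes: dict[str, ScopeMetrics] = field(default_factory=dict)

    @property
    def overall(self) -> ScopeMetrics:
        return self.scopes["OVERALL"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, m in self.scopes.items():
            row = {"scope": name}
            row.update({k: v for k, v in vars(m).items()})
            rows.append(row)
        return pd.DataFrame(rows)

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def evaluate_patient(
    pct: ImageVolume,
    rct: ImageVolume,
    labels: RegionLabelMap,
    include_excluded: bool = False,
) -> EvaluationReport:
    """Overall and per-region MAE/sigma between a pseudo-CT and its reference.

    Air voxels never count; excluded-overlay voxels are omitted unless
    *include_excluded* is set.  Per-region weighted MAE uses the region's
    voxel fraction, so the weighted values sum to the overall MAE.
    """
    body = labels.body_mask
    if not include_excluded:
        body = body & ~labels.excluded
    report = EvaluationReport()
    n_total = int(body.sum())
    report.scopes["OVERALL"] = ScopeMetrics(
        voxel_count=n_total,
        mae=mae(pct, rct, body),
        sigma=rms_diff(pct, rct, body),
    )
    for code in BODY_REGIONS:
        sel = body & (labels.labels == code)
        n = int(sel.sum())
        if n == 0:
            continue
        raw = mae(pct, rct, sel)
        report.scopes[REGION_NAMES[code]] = ScopeMetrics(
            voxel_count=n,
            mae=raw,
            sigma=rms_diff(pct, rct, sel),
            voxel_fraction=n / n_total,
            weighted_mae=raw * n / n_total,
        )
    return report


@dataclass
class DoseReport:
    """Point-to-point dose comparison summary."""

    passing_rate: float
    tolerance_pct: float
    reference_dose: float | None
    voxel_count: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.passing_rate <= 100.0:
            raise ValueError("passing rate must be within [0, 100]")


def dose_passing_rate(
    dose_p: ImageVolume,
    dose_r: ImageVolume,
    mask: np.ndarray,
    tolerance_pct: float = 2.0,
    reference: float | None = None,
    normalization: str = "reference",
) -> DoseReport:
    """Percent of masked voxels whose dose difference is within tolerance.

    A voxel passes when ``|Dp - Dr| <= tolerance`` with the tolerance taken as
    a percentage of a global *reference* dose (default mode, e.g. the
    prescription) or of the local reference-plan dose
    (``normalization="local"``).  The comparison is inclusive at the boundary
    and purely point-to-point (no spatial search).
    """
    mask = np.asarray(mask, dtype=bool)
    if dose_p.shape != dose_r.shape or mask.shape != dose_p.shape:
        raise ValueError("dose grids and mask must share one grid")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty dose evaluation mask")
    diff = np.abs(dose_p.data[mask] - dose_r.data[mask])
    if normalization == "reference":
        if reference is None or reference <= 0:
            raise ValueError("reference dose must be positive")
        passing = diff <= (tolerance_pct / 100.0) * reference
    elif normalization == "local":
        local = np.abs(dose_r.data[mask])
        if np.any(local <= 0):
            raise ValueError("local normalization requires positive reference-plan dose")
        passing = diff <= (tolerance_pct / 100.0) * local
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return DoseReport(
        passing_rate=100.0 * float(np.count_nonzero(passing)) / n,
        tolerance_pct=tolerance_pct,
        reference_dose=reference,
        voxel_count=n,
    )
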