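"""Reproducible multi-patient phantom cohorts for end-to-end pipeline testing.

Each phantom is a nested-ellipsoid body with a bone shell and a transition
shell, dual-channel MR intensities built from smoothed random fields with
region-dependent mean/scale, and a CT volume generated from a known, noisy
per-region intensity->HU map.  Patients share the geometry family and the
ground-truth map but differ in their random fields and global scanner gain,
so cohort normalization is genuinely exercised.

All randomness flows from one explicit seed through a per-patient substream;
no global generator state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .volumes import (
    BONY,
    MIXED,
    OUTSIDE,
    SOFT,
    ImageVolume,
    Modality,
    RegionLabelMap,
)

__all__ = [
    "RegionIntensitySpec",
    "PhantomSpec",
    "PatientData",
    "generate_phantom",
    "generate_cohort",
    "region_volume_fractions",
    "ground_truth_ct",
]

#: Internal scale used to express ground-truth polynomial coefficients on
#: O(1) variables regardless of the raw channel units.
GT_SCALE = (1500.0, 40000.0)


@dataclass(frozen=True)
class RegionIntensitySpec:
    """Mean/scale of the two MR channels for one region (arbitrary units)."""

    mr1_mean: float
    mr1_scale: float
    mr2_mean: float
    mr2_scale: float


def _default_intensities() -> dict[int, RegionIntensitySpec]:
    return {
        SOFT: RegionIntensitySpec(700.0, 260.0, 20000.0, 7000.0),
        BONY: RegionIntensitySpec(350.0, 180.0, 9000.0, 5000.0),
        MIXED: RegionIntensitySpec(550.0, 220.0, 14000.0, 6000.0),
    }


def _default_ground_truth() -> dict[int, dict[tuple[int, int], float]]:
    # Low-degree maps with both channels informative in every region, so the
    # dual-channel model has a real advantage over either single channel.
    return {
        SOFT: {(0, 0): 40.0, (1, 0): -120.0, (0, 1): 160.0, (1, 1): -60.0},
        BONY: {(0, 0): 900.0, (1, 0): 450.0, (0, 1): -600.0, (2, 0): 250.0},
        MIXED: {(0, 0): 300.0, (1, 0): 280.0, (0, 1): -420.0, (0, 2): 180.0},
    }


@dataclass
class PhantomSpec:
    """Everything needed to generate a deterministic phantom cohort."""

    shape: tuple[int, int, int] = (64, 64, 32)
    spacing: tuple[float, float, float] = (2.0, 2.0, 3.0)
    #: Body ellipsoid semi-axes as fractions of each half-dimension.
    body_semiaxes_frac: tuple[float, float, float] = (0.92, 0.88, 0.9)
    #: Bone shell in normalized ellipsoid-radius units [inner, outer].
    bone_band: tuple[float, float] = (0.55, 0.75)
    #: Thickness of the mixed transition shell on each side of the bone band.
    mixed_margin: float = 0.06
    intensities: dict[int, RegionIntensitySpec] = field(default_factory=_default_intensities)
    #: Spatial correlation length of the random intensity fields, in mm.
    smoothness_mm: float = 5.0
    #: Per-region ground-truth map: {(i1, i2): coeff} on GT_SCALE-scaled inputs.
    ground_truth: dict[int, dict[tuple[int, int], float]] = field(
        default_factory=_default_ground_truth
    )
    #: Replace the BONY polynomial map with a steep sigmoidal map (a
    #: non-polynomial target, to exercise approximation error).
    bone_sigmoid: bool = False
    ct_noise_sd: float = 0.0
    excluded_fraction: float = 0.0
    #: HU offset applied to excluded voxels' CT (modality-mismatch outlier).
    excluded_outlier_hu: float = 700.0
    #: Log-sd of per-patient, per-channel multiplicative gain factors; set to
    #: 0 for gain-free cohorts.  Explicit gains override the random draw.
    gain_log_sd: float = 0.2
    patient_gains: Sequence[tuple[float, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")
        if not 0 <= self.excluded_fraction < 1:
            raise ValueError("excluded_fraction must be in [0, 1)")
        lo, hi = self.bone_band
        if not (0 < lo < hi) or hi + self.mixed_margin >= 1.0:
            raise ValueError(
                "impossible geometry: bone band plus mixed margin must nest inside the body"
            )


@dataclass
class PatientData:
    """One phantom patient: co-registered MR1/MR2/CT volumes plus labels."""

    patient_id: str
    mr1: ImageVolume
    mr2: ImageVolume
    ct: ImageVolume
    labels: RegionLabelMap
    gains: tuple[float, float] = (1.0, 1.0)


def _normalized_radius(spec: PhantomSpec) -> np.ndarray:
    """rho(x): 0 at the body center, 1 on the body ellipsoid surface."""
    axes = [np.arange(n) - (n - 1) / 2.0 for n in spec.shape]
    grids = np.meshgrid(*axes, indexing="ij")
    rho2 = np.zeros(spec.shape)
    for g, n, f in zip(grids, spec.shape, spec.body_semiaxes_frac):
        semi = f * (n - 1) / 2.0
        rho2 += (g / semi) ** 2
    return np.sqrt(rho2)


def make_labels(spec: PhantomSpec) -> RegionLabelMap:
    """Region labels from the nested-ellipsoid geometry (no excluded overlay)."""
    rho = _normalized_radius(spec)
    lo, hi = spec.bone_band
    m = spec.mixed_margin
    labels = np.full(spec.shape, OUTSIDE, dtype=np.int16)
    body = rho < 1.0
    labels[body] = SOFT
    mixed = body & (rho >= lo - m) & (rho <= hi + m)
    labels[mixed] = MIXED
    bone = body & (rho >= lo) & (rho <= hi)
    labels[bone] = BONY
    return RegionLabelMap(labels=labels)


def region_volume_fractions(spec: PhantomSpec) -> dict[int, float]:
    """Analytic voxel fractions of each region within the body ellipsoid.

    For nested similar ellipsoids the volume inside normalized radius r is
    proportional to r**3, so band fractions are differences of cubes.
    """
    lo, hi = spec.bone_band
    m = spec.mixed_margin
    bony = hi**3 - lo**3
    mixed = (lo**3 - (lo - m) ** 3) + (min(hi + m, 1.0) ** 3 - hi**3)
    return {BONY: bony, MIXED: mixed, SOFT: 1.0 - bony - mixed}


def _smooth_field(rng: np.random.Generator, spec: PhantomSpec) -> np.ndarray:
    """Zero-mean, unit-sd random field with spatial scale ``smoothness_mm``."""
    noise = rng.standard_normal(spec.shape)
    sigma = [max(spec.smoothness_mm / s, 1e-6) for s in spec.spacing]
    f = ndimage.gaussian_filter(noise, sigma=sigma, mode="nearest")
    sd = f.std()
    if sd == 0:
        return f
    return (f - f.mean()) / sd


def _nominal_body_means(spec: PhantomSpec, labels: RegionLabelMap) -> tuple[float, float]:
    """Label-count-weighted nominal channel means (identical for all patients)."""
    n1 = n2 = total = 0.0
    for code, inten in spec.intensities.items():
        n = float(np.count_nonzero(labels.labels == code))
        n1 += n * inten.mr1_mean
        n2 += n * inten.mr2_mean
        total += n
    return n1 / total, n2 / total


def ground_truth_ct(
    spec: PhantomSpec, s1_true: np.ndarray, s2_true: np.ndarray, labels: RegionLabelMap
) -> np.ndarray:
    """Noise-free CT from the per-region ground-truth map; -1000 outside."""
    u = np.asarray(s1_true) / GT_SCALE[0]
    v = np.asarray(s2_true) / GT_SCALE[1]
    ct = np.full(labels.shape, -1000.0)
    for code, coeffs in spec.ground_truth.items():
        sel = labels.labels == code
        if not np.any(sel):
            continue
        if code == BONY and spec.bone_sigmoid:
            ct[sel] = 250.0 + 1100.0 / (1.0 + np.exp(8.0 * (u[sel] - 0.25))) - 500.0 * v[sel]
            continue
        val = np.zeros(int(sel.sum()))
        for (i1, i2), c in coeffs.items():
            val += c * u[sel] ** i1 * v[sel] ** i2
        ct[sel] = val
    return ct


def generate_phantom(spec: PhantomSpec, patient_index: int) -> PatientData:
    """Deterministic phantom for one patient index under one seed."""
    rng = np.random.default_rng([spec.seed, patient_index])
    labels = make_labels(spec)
    body = labels.body_mask

    if spec.patient_gains is not None:
        g1, g2 = spec.patient_gains[patient_index]
    elif spec.gain_log_sd > 0:
        g1, g2 = np.exp(rng.normal(0.0, spec.gain_log_sd, size=2))
    else:
        g1, g2 = 1.0, 1.0
    if g1 <= 0 or g2 <= 0:
        raise ValueError("patient gains must be positive")

    field1 = _smooth_field(rng, spec)
    field2 = _smooth_field(rng, spec)
    s1_true = np.zeros(spec.shape)
    s2_true = np.zeros(spec.shape)
    for code, inten in spec.intensities.items():
        sel = labels.labels == code
        s1_true[sel] = inten.mr1_mean + inten.mr1_scale * field1[sel]
        s2_true[sel] = inten.mr2_mean + inten.mr2_scale * field2[sel]
    np.clip(s1_true, 0.0, None, out=s1_true)
    np.clip(s2_true, 0.0, None, out=s2_true)
    s1_true[~body] = 0.0
    s2_true[~body] = 0.0
    # Pin each patient's gain-free body mean to a spec-determined constant:
    # cohort normalization then puts every patient on one exact common scale,
    # so the ground-truth map is a single learnable function of the
    # normalized intensities (the structure the method assumes).
    m1_target, m2_target = _nominal_body_means(spec, labels)
    s1_true *= m1_target / float(s1_true[body].mean())
    s2_true *= m2_target / float(s2_true[body].mean())

    ct = ground_truth_ct(spec, s1_true, s2_true, labels)
    if spec.ct_noise_sd > 0:
        noise = rng.normal(0.0, spec.ct_noise_sd, size=spec.shape)
        ct[body] += noise[body]
    excluded = np.zeros(spec.shape, dtype=bool)
    if spec.excluded_fraction > 0:
        excluded = body & (rng.random(spec.shape) < spec.excluded_fraction)
        ct[excluded] += spec.excluded_outlier_hu
    np.clip(ct, -1000.0, 2000.0, out=ct)

    def vol(data: np.ndarray, modality: Modality) -> ImageVolume:
        return ImageVolume(data=data, spacing=spec.spacing, modality=modality)

    return PatientData(
        patient_id=f"phantom{patient_index:02d}",
        mr1=vol(s1_true * g1, Modality.MR1),
        mr2=vol(s2_true * g2, Modality.MR2),
        ct=vol(ct, Modality.CT),
        labels=RegionLabelMap(labels=labels.labels.copy(), excluded=excluded),
        gains=(float(g1), float(g2)),
    )


def generate_cohort(spec: PhantomSpec, n_patients: int) -> list[PatientData]:
    """Cohort sharing geometry and ground truth, varying fields and gains."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    return [generate_phantom(spec, k) for k in range(n_patients)]
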