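"""Per-region intensity->HU models: weighted bivariate polynomial or bilinear lookup.

The polynomial is a total-degree-<=n expansion whose inputs are rescaled to
[0, 1] per axis before monomial construction (raw intensities in the tens of
thousands raised to the 30th power would overflow), fitted to the imputed
bin-grid means by weighted least squares via SVD with a relative
singular-value cutoff, which makes the degree-30 default deterministic and
reproducible despite severe ill-conditioning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .binning import BinGrid, bin_index, build_bin_grid, fill_empty_bins
from .volumes import (
    BODY_REGIONS,
    REGION_NAMES,
    ImageVolume,
    Modality,
    RegionLabelMap,
)

__all__ = [
    "HU_CLAMP",
    "monomial_exponents",
    "PolynomialModel",
    "InterpolationModel",
    "RegionModelSet",
    "fit_polynomial",
    "evaluate_model",
    "train_region_models",
    "predict_pct",
    "predict_pct_per_bin",
]

#: Predicted CT numbers are restricted to this HU range.
HU_CLAMP = (-1000.0, 2000.0)

#: Region key used when segmentation is disabled and one model covers the body.
WHOLE_BODY = "BODY"


def monomial_exponents(degree: int) -> list[tuple[int, int]]:
    """Exponent pairs (i1, i2) with i1 + i2 <= degree, (i1, i2) lexicographic."""
    if degree < 0:
        raise ValueError("degree must be >= 0")
    return [(i1, i2) for i1 in range(degree + 1) for i2 in range(degree + 1 - i1)]


def _design_matrix(u: np.ndarray, v: np.ndarray, degree: int) -> np.ndarray:
    """Monomial columns u**i1 * v**i2 for all exponent pairs, in storage order.

    Powers are built by cumulative multiplication, ascending in each exponent.
    """
    u = np.asarray(u, dtype=np.float64).ravel()
    v = np.asarray(v, dtype=np.float64).ravel()
    upow = np.ones((degree + 1, u.size))
    vpow = np.ones((degree + 1, v.size))
    for k in range(1, degree + 1):
        upow[k] = upow[k - 1] * u
        vpow[k] = vpow[k - 1] * v
    cols = [upow[i1] * vpow[i2] for i1, i2 in monomial_exponents(degree)]
    return np.stack(cols, axis=1)


@dataclass
class PolynomialModel:
    """Total-degree-<=n bivariate polynomial with input scaling and output clamp."""

    degree: int
    coeffs: np.ndarray
    input_scale: tuple[float, float]
    clamp: tuple[float, float] = HU_CLAMP

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=np.float64).ravel()
        n_expected = (self.degree + 1) * (self.degree + 2) // 2
        if self.coeffs.size != n_expected:
            raise ValueError(
                f"degree {self.degree} needs {n_expected} coefficients, got {self.coeffs.size}"
            )
        if self.input_scale[0] <= 0 or self.input_scale[1] <= 0:
            raise ValueError("input_scale components must be positive")

    def evaluate(self, s1: np.ndarray, s2: np.ndarray) -> np.ndarray:
        """Predicted HU at raw (unscaled) intensities, clamped to the HU range.

        Inputs beyond the trained range clamp to it; monomial contributions
        are accumulated in ascending-total-degree order.
        """
        s1 = np.asarray(s1, dtype=np.float64)
        s2 = np.asarray(s2, dtype=np.float64)
        shape = np.broadcast_shapes(s1.shape, s2.shape)
        u = np.clip(np.broadcast_to(s1, shape), 0.0, self.input_scale[0]) / self.input_scale[0]
        v = np.clip(np.broadcast_to(s2, shape), 0.0, self.input_scale[1]) / self.input_scale[1]
        A = _design_matrix(u, v, self.degree)
        exps = monomial_exponents(self.degree)
        order = np.argsort([i1 + i2 for i1, i2 in exps], kind="stable")
        out = np.zeros(A.shape[0])
        for k in order:
            out += A[:, k] * self.coeffs[k]
        return np.clip(out.reshape(shape), *self.clamp)


@dataclass
class InterpolationModel:
    """Bilinear interpolation of bin means over the bin-center lattice.

    Queries outside the lattice hull clamp to it (constant extrapolation);
    output is clamped to the HU range like the polynomial.
    """

    grid: BinGrid
    clamp: tuple[float, float] = HU_CLAMP
    _interp: RegularGridInterpolator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.grid.imputed or not np.all(np.isfinite(self.grid.mean_ct)):
            raise ValueError("interpolation requires a fully imputed bin grid")
        self._interp = RegularGridInterpolator(
            (self.grid.centers(0), self.grid.centers(1)),
            self.grid.mean_ct,
            method="linear",
            bounds_error=False,
        )

    @property
    def input_scale(self) -> tuple[float, float]:
        return self.grid.axis_max

    def evaluate(self, s1: np.ndarray, s2: np.ndarray) -> np.ndarray:
        s1 = np.asarray(s1, dtype=np.float64)
        s2 = np.asarray(s2, dtype=np.float64)
        shape = np.broadcast_shapes(s1.shape, s2.shape)
        c1, c2 = self.grid.centers(0), self.grid.centers(1)
        q1 = np.clip(np.broadcast_to(s1, shape).ravel(), c1[0], c1[-1])
        q2 = np.clip(np.broadcast_to(s2, shape).ravel(), c2[0], c2[-1])
        out = self._interp(np.column_stack([q1, q2]))
        return np.clip(out.reshape(shape), *self.clamp)


def fit_polynomial(grid: BinGrid, degree: int, rcond: float = 1e-10) -> PolynomialModel:
    """Weighted least-squares polynomial fit to the imputed bin means.

    Minimizes ``sum_ij w_ij * (mean_ct_ij - p(center_ij))**2`` over bin
    centers with inputs scaled to [0, 1]; solved by SVD with relative
    singular-value cutoff *rcond*.
    """
    if not np.all(np.isfinite(grid.mean_ct)):
        raise ValueError("bin grid has non-finite means; run fill_empty_bins first")
    w = grid.weights.ravel()
    if not np.any(w > 0):
        raise ValueError("degenerate fit: all weights are zero")
    u = (np.arange(grid.nbin) + 0.5) / grid.nbin
    uu, vv = np.meshgrid(u, u, indexing="ij")
    A = _design_matrix(uu.ravel(), vv.ravel(), degree)
    sw = np.sqrt(w)
    coeffs, *_ = np.linalg.lstsq(A * sw[:, None], grid.mean_ct.ravel() * sw, rcond=rcond)
    return PolynomialModel(degree=degree, coeffs=coeffs, input_scale=grid.axis_max)


def evaluate_model(
    model: PolynomialModel | InterpolationModel, s1: np.ndarray, s2: np.ndarray
) -> np.ndarray:
    """Predicted HU for raw intensities (dispatches on the model type)."""
    return model.evaluate(s1, s2)


@dataclass
class RegionModelSet:
    """One fitted model per region, plus the shared intensity-axis metadata."""

    models: dict[str, PolynomialModel | InterpolationModel]
    axis_max: tuple[float, float]
    nbin: int
    model_type: str = "polynomial"
    metadata: dict = field(default_factory=dict)
    #: Imputed training bin grids per region; kept in memory for the error
    #: budget (fit/spread deviations) but not persisted for polynomial models.
    grids: dict[str, BinGrid] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("model set must contain at least one region model")

    def region_model(self, region_name: str) -> PolynomialModel | InterpolationModel:
        if WHOLE_BODY in self.models:
            return self.models[WHOLE_BODY]
        if region_name not in self.models:
            raise KeyError(f"no model for region {region_name}")
        return self.models[region_name]

    # -- persistence: plain structured text (JSON), diffable ---------------
    def save(self, path) -> None:
        doc: dict = {
            "format": "pctpoly-models",
            "version": 1,
            "model_type": self.model_type,
            "nbin": self.nbin,
            "axis_max": list(self.axis_max),
            "metadata": self.metadata,
            "regions": {},
        }
        for name, m in self.models.items():
            if isinstance(m, PolynomialModel):
                doc["regions"][name] = {
                    "type": "polynomial",
                    "degree": m.degree,
                    "input_scale": list(m.input_scale),
                    "clamp": list(m.clamp),
                    "coeffs": [
                        [i1, i2, float(c)]
                        for (i1, i2), c in zip(monomial_exponents(m.degree), m.coeffs)
                    ],
                }
            else:
                g = m.grid
                doc["regions"][name] = {
                    "type": "interpolation",
                    "nbin": g.nbin,
                    "axis_max": list(g.axis_max),
                    "clamp": list(m.clamp),
                    "mean_ct": g.mean_ct.ravel().tolist(),
                    "counts": g.counts.ravel().tolist(),
                    "weights": g.weights.ravel().tolist(),
                }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path) -> "RegionModelSet":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"model file not found: {path}")
        doc = json.loads(path.read_text())
        if doc.get("format") != "pctpoly-models":
            raise ValueError(f"{path} is not a model file")
        models: dict[str, PolynomialModel | InterpolationModel] = {}
        for name, spec in doc["regions"].items():
            if spec["type"] == "polynomial":
                coeffs = np.array([c for _, _, c in spec["coeffs"]])
                models[name] = PolynomialModel(
                    degree=spec["degree"],
                    coeffs=coeffs,
                    input_scale=tuple(spec["input_scale"]),
                    clamp=tuple(spec["clamp"]),
                )
            else:
                nbin = spec["nbin"]
                mean_ct = np.array(spec["mean_ct"]).reshape(nbin, nbin)
                counts = np.array(spec["counts"], dtype=np.int64).reshape(nbin, nbin)
                weights = np.array(spec["weights"]).reshape(nbin, nbin)
                grid = BinGrid(
                    nbin=nbin,
                    axis_max=tuple(spec["axis_max"]),
                    counts=counts,
                    mean_ct=mean_ct,
                    filled=counts > 0,
                    weights=weights,
                    imputed=True,
                )
                models[name] = InterpolationModel(grid=grid, clamp=tuple(spec["clamp"]))
        return cls(
            models=models,
            axis_max=tuple(doc["axis_max"]),
            nbin=doc["nbin"],
            model_type=doc["model_type"],
            metadata=doc.get("metadata", {}),
        )


def _patient_tuple(p) -> tuple[ImageVolume, ImageVolume, ImageVolume, RegionLabelMap]:
    if isinstance(p, tuple):
        return p
    return (p.mr1, p.mr2, p.ct, p.labels)


def pooled_training_samples(
    patients: Iterable,
    include_excluded: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pool (s1, s2, ct, region_code) arrays over all patients' body voxels.

    Voxels flagged excluded are dropped unless *include_excluded* is set.
    """
    s1_parts, s2_parts, ct_parts, reg_parts = [], [], [], []
    for p in patients:
        mr1, mr2, ct, labels = _patient_tuple(p)
        mask = labels.body_mask
        if not include_excluded:
            mask = mask & ~labels.excluded
        s1_parts.append(mr1.data[mask])
        s2_parts.append(mr2.data[mask])
        ct_parts.append(ct.data[mask])
        reg_parts.append(labels.labels[mask])
    if not s1_parts:
        raise ValueError("no training patients")
    return (
        np.concatenate(s1_parts),
        np.concatenate(s2_parts),
        np.concatenate(ct_parts),
        np.concatenate(reg_parts),
    )


def train_region_models(
    patients: Sequence,
    nbin: int = 200,
    degree: int = 30,
    model_type: str = "polynomial",
    axis_max: tuple[float, float] | None = None,
    segmentation: bool = True,
    include_excluded: bool = False,
    empty_weight_fraction: float = 0.1,
) -> RegionModelSet:
    """Train one model per region from pooled cohort voxels.

    Each region's non-excluded body voxels across all patients are binned,
    empty bins imputed, and the configured model fitted.  ``axis_max``
    defaults to the per-axis maximum over the pooled training voxels.
    """
    if model_type not in ("polynomial", "interpolation"):
        raise ValueError(f"unknown model type {model_type!r}")
    s1, s2, ct, regions = pooled_training_samples(patients, include_excluded)
    if s1.size == 0:
        raise ValueError("no body voxels available for training")
    if axis_max is None:
        axis_max = (float(np.max(s1)) or 1.0, float(np.max(s2)) or 1.0)

    if segmentation:
        groups = {REGION_NAMES[c]: regions == c for c in BODY_REGIONS}
    else:
        groups = {WHOLE_BODY: np.ones(s1.shape, dtype=bool)}

    models: dict[str, PolynomialModel | InterpolationModel] = {}
    grids: dict[str, BinGrid] = {}
    for name, sel in groups.items():
        if not np.any(sel):
            if segmentation:
                continue  # region absent from this cohort's labels
            raise ValueError(f"region {name}: zero training voxels")
        grid = build_bin_grid(s1=s1[sel], s2=s2[sel], ct=ct[sel], nbin=nbin, axis_max=axis_max)
        grid = fill_empty_bins(grid, empty_weight_fraction)
        grids[name] = grid
        if model_type == "polynomial":
            models[name] = fit_polynomial(grid, degree)
        else:
            models[name] = InterpolationModel(grid=grid)
    if not models:
        raise ValueError("no region had any training voxels")
    return RegionModelSet(
        models=models,
        axis_max=axis_max,
        nbin=nbin,
        model_type=model_type,
        metadata={"degree": degree, "segmentation": segmentation},
        grids=grids,
    )


def predict_pct(
    models: RegionModelSet,
    mr1: ImageVolume,
    mr2: ImageVolume,
    labels: RegionLabelMap,
) -> ImageVolume:
    """Synthesize a pseudo-CT volume: each body voxel through its region's model.

    Outside-body voxels are set to exactly -1000 HU.  The excluded overlay is
    ignored here: it matters for training and evaluation, not prediction.
    """
    if mr1.shape != mr2.shape or mr1.shape != labels.shape:
        raise ValueError("MR volumes and labels must share one grid")
    out = np.full(mr1.shape, -1000.0)
    for code in labels.present_regions():
        name = REGION_NAMES[code]
        model = models.region_model(name)
        sel = labels.labels == code
        out[sel] = model.evaluate(mr1.data[sel], mr2.data[sel])
    return mr1.with_data(out, modality=Modality.PCT)


def predict_pct_per_bin(
    models: RegionModelSet,
    mr1: ImageVolume,
    mr2: ImageVolume,
    labels: RegionLabelMap,
) -> ImageVolume:
    """Pseudo-CT where every voxel receives the model value at its bin center.

    This is the piecewise-constant variant used to study the error budget:
    with per-bin predictions the fit error and the within-bin CT spread add
    exactly in quadrature.
    """
    if mr1.shape != mr2.shape or mr1.shape != labels.shape:
        raise ValueError("MR volumes and labels must share one grid")
    out = np.full(mr1.shape, -1000.0)
    nbin = models.nbin
    for code in labels.present_regions():
        name = REGION_NAMES[code]
        model = models.region_model(name)
        sel = labels.labels == code
        i = bin_index(mr1.data[sel], models.axis_max[0], nbin)
        j = bin_index(mr2.data[sel], models.axis_max[1], nbin)
        c1 = (np.asarray(i) + 0.5) * models.axis_max[0] / nbin
        c2 = (np.asarray(j) + 0.5) * models.axis_max[1] / nbin
        out[sel] = model.evaluate(c1, c2)
    return mr1.with_data(out, modality=Modality.PCT)
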