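"""Orchestration: train / predict / evaluate / leave-one-out runs.

Functions here operate on in-memory :class:`~pctpoly.synthetic.PatientData`
lists; the CLI wraps them with file I/O and a YAML config.  Every run is
deterministic given the config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .evaluation import (
    EvaluationReport,
    evaluate_patient,
    fit_errors,
    spread_errors,
)
from .model import (
    RegionModelSet,
    WHOLE_BODY,
    predict_pct,
    train_region_models,
)
from .preprocess import (
    apply_normalization,
    fit_normalization,
    normalization_factor,
    patient_body_mean,
)
from .synthetic import PatientData
from .volumes import REGION_NAMES, ImageVolume, RegionLabelMap

__all__ = [
    "RunConfig",
    "normalize_cohort",
    "run_train",
    "run_predict",
    "run_loocv",
    "LoocvResult",
]

log = logging.getLogger("pctpoly")

SEQUENCE_CHOICES = ("both", "MR1", "MR2")


@dataclass
class RunConfig:
    """Fully-resolved run parameters (mirrors the YAML config and CLI flags)."""

    patients: list[dict] = field(default_factory=list)
    nbin: int = 200
    degree: int = 30
    model_type: str = "polynomial"
    axis_max: tuple[float, float] | None = None
    segmentation: bool = True
    use_excluded: bool = False  # include excluded voxels in training/evaluation
    sequences: str = "both"
    empty_weight_fraction: float = 0.1
    dose_tolerance_pct: float = 2.0
    dose_reference_gy: float | None = None
    output_dir: str = "."
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nbin < 1:
            raise ValueError("nbin must be >= 1")
        if self.degree < 0:
            raise ValueError("degree must be >= 0")
        if self.sequences not in SEQUENCE_CHOICES:
            raise ValueError(f"sequences must be one of {SEQUENCE_CHOICES}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if doc.get("axis_max") is not None:
            doc["axis_max"] = tuple(doc["axis_max"])
        return cls(**doc)

    def to_yaml(self, path) -> None:
        doc = dataclasses.asdict(self)
        if doc["axis_max"] is not None:
            doc["axis_max"] = list(doc["axis_max"])
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _mask_channel(p: PatientData, sequences: str) -> PatientData:
    """Zero out the disabled MR channel so it collapses into a single bin."""
    if sequences == "both":
        return p
    if sequences == "MR1":
        return replace(p, mr2=p.mr2.with_data(np.zeros(p.mr2.shape)))
    return replace(p, mr1=p.mr1.with_data(np.zeros(p.mr1.shape)))


def normalize_cohort(
    train: Sequence[PatientData],
    targets: Sequence[PatientData] = (),
    sequences: str = "both",
) -> tuple[list[PatientData], list[PatientData], dict[str, float]]:
    """Cohort-normalize each enabled MR channel over the training patients.

    Training factors come from :func:`fit_normalization`; target patients
    (outside the fitting cohort, e.g. the held-out LOOCV patient) get
    ``cohort_mean / own_mean``.  Returns normalized copies plus the per-channel
    cohort means.
    """
    channels = {"both": ("mr1", "mr2"), "MR1": ("mr1",), "MR2": ("mr2",)}[sequences]
    train_out = [_mask_channel(p, sequences) for p in train]
    target_out = [_mask_channel(p, sequences) for p in targets]
    cohort_means: dict[str, float] = {}
    for ch in channels:
        model = fit_normalization(
            (p.patient_id, getattr(p, ch), p.labels.body_mask) for p in train_out
        )
        cohort_means[ch.upper()] = model.cohort_mean
        train_out = [
            replace(p, **{ch: apply_normalization(getattr(p, ch), model.factor(p.patient_id))})
            for p in train_out
        ]
        target_out = [
            replace(
                p,
                **{
                    ch: apply_normalization(
                        getattr(p, ch),
                        normalization_factor(
                            model.cohort_mean,
                            patient_body_mean(getattr(p, ch), p.labels.body_mask),
                        ),
                    )
                },
            )
            for p in target_out
        ]
    return train_out, target_out, cohort_means


def run_train(patients: Sequence[PatientData], config: RunConfig) -> RegionModelSet:
    """Normalization -> binning -> imputation -> per-region fit."""
    if len(patients) < 1:
        raise ValueError("training stage: need at least one patient")
    t0 = time.perf_counter()
    train, _, cohort_means = normalize_cohort(patients, sequences=config.sequences)
    log.info("normalization: %d patients, cohort means %s", len(train), cohort_means)
    models = train_region_models(
        train,
        nbin=config.nbin,
        degree=config.degree,
        model_type=config.model_type,
        axis_max=config.axis_max,
        segmentation=config.segmentation,
        include_excluded=config.use_excluded,
        empty_weight_fraction=config.empty_weight_fraction,
    )
    models.metadata.update(
        {
            "cohort_means": cohort_means,
            "sequences": config.sequences,
            "config_digest": config.digest(),
            "seed": config.seed,
        }
    )
    log.info("training: fitted %s model(s) in %.2fs", sorted(models.models), time.perf_counter() - t0)
    return models


def run_predict(models: RegionModelSet, patient: PatientData) -> ImageVolume:
    """Normalize the target against the stored cohort means and synthesize pCT."""
    target = _norm_target(models, patient)
    return predict_pct(models, target.mr1, target.mr2, target.labels)


def _attach_error_budget(
    report: EvaluationReport,
    models: RegionModelSet,
    target: PatientData,
    include_excluded: bool,
) -> None:
    """Fill per-region fit/spread metrics from the training grids."""
    for name, grid in models.grids.items():
        if name == WHOLE_BODY:
            scope = report.scopes.get("OVERALL")
            sel = target.labels.body_mask
        else:
            scope = report.scopes.get(name)
            code = {v: k for k, v in REGION_NAMES.items()}[name]
            sel = target.labels.labels == code
        if scope is None:
            continue
        if not include_excluded:
            sel = sel & ~target.labels.excluded
        if not np.any(sel):
            continue
        scope.mae_fit, scope.sigma_fit = fit_errors(grid, models.models[name])
        scope.mae_rct, scope.sigma_rct = spread_errors(
            grid, target.mr1.data[sel], target.mr2.data[sel], target.ct.data[sel]
        )


@dataclass
class LoocvResult:
    """Per-cycle evaluation reports plus a mean +/- sd summary."""

    cycles: list[tuple[str, EvaluationReport]]

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for pid, report in self.cycles:
            df = report.to_frame()
            df.insert(0, "cycle", pid)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> pd.DataFrame:
        """Mean and sample standard deviation of each metric across cycles."""
        df = self.to_frame()
        metrics = [c for c in df.columns if c not in ("cycle", "scope")]
        grouped = df.groupby("scope")[metrics]
        mean = grouped.mean()
        sd = grouped.std(ddof=1)
        out = pd.concat({"mean": mean, "sd": sd}, axis=1)
        out.columns = [f"{m}_{stat}" for stat, m in out.columns]
        return out.reset_index()


def run_loocv(
    patients: Sequence[PatientData],
    config: RunConfig,
    error_budget: bool = True,
) -> LoocvResult:
    """Hold each patient out once: train on the rest, predict and evaluate it.

    The held-out patient's excluded overlay is omitted from evaluation (unless
    ``config.use_excluded``); its normalization factor is computed against the
    training cohort's mean, exactly as a clinical target patient would be.
    """
    if len(patients) < 2:
        raise ValueError("LOOCV needs at least 2 patients")
    cycles: list[tuple[str, EvaluationReport]] = []
    for held in range(len(patients)):
        t0 = time.perf_counter()
        train = [p for i, p in enumerate(patients) if i != held]
        target = patients[held]
        models = run_train(train, config)
        norm_target = _norm_target(models, target)
        pct = predict_pct(models, norm_target.mr1, norm_target.mr2, norm_target.labels)
        report = evaluate_patient(
            pct, norm_target.ct, norm_target.labels, include_excluded=config.use_excluded
        )
        if error_budget:
            _attach_error_budget(report, models, norm_target, config.use_excluded)
        cycles.append((target.patient_id, report))
        log.info(
            "cycle %s: overall MAE %.2f HU (%.2fs)",
            target.patient_id,
            report.overall.mae,
            time.perf_counter() - t0,
        )
    return LoocvResult(cycles=cycles)


def _norm_target(models: RegionModelSet, patient: PatientData) -> PatientData:
    """Target patient normalized against the model's stored cohort means."""
    sequences = models.metadata.get("sequences", "both")
    target = _mask_channel(patient, sequences)
    for ch, mean in models.metadata.get("cohort_means", {}).items():
        attr = ch.lower()
        factor = normalization_factor(
            mean, patient_body_mean(getattr(target, attr), target.labels.body_mask)
        )
        target = replace(target, **{attr: apply_normalization(getattr(target, attr), factor)})
    return target
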