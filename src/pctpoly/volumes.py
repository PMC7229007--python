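"""Core volumetric types and NIfTI I/O.

All processing happens in voxel-index space: only the voxel spacing from the
header is used, the rest of the world affine is carried along on write but
never interpreted.  Inputs are assumed pre-registered onto one common grid.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

__all__ = [
    "Modality",
    "ImageVolume",
    "RegionLabelMap",
    "OUTSIDE",
    "BONY",
    "SOFT",
    "MIXED",
    "REGION_NAMES",
    "REGION_CODES",
    "DEFAULT_CODE_TABLE",
    "read_volume",
    "write_volume",
    "read_labelmap",
    "write_labelmap",
]


class Modality(str, Enum):
    """What the scalar in a volume means."""

    MR1 = "MR1"
    MR2 = "MR2"
    CT = "CT"
    PCT = "PCT"
    DOSE = "DOSE"


# Region label codes.  0 is reserved for air / outside-body so that an
# all-zero file is a valid "nothing segmented" map.
OUTSIDE = 0
BONY = 1
SOFT = 2
MIXED = 3

REGION_NAMES: dict[int, str] = {OUTSIDE: "OUTSIDE", BONY: "BONY", SOFT: "SOFT", MIXED: "MIXED"}
REGION_CODES: dict[str, int] = {v: k for k, v in REGION_NAMES.items()}
#: Body regions in canonical order (excludes OUTSIDE).
BODY_REGIONS = (BONY, SOFT, MIXED)

DEFAULT_CODE_TABLE: dict[int, str] = dict(REGION_NAMES)


@dataclass
class ImageVolume:
    """A 3D scalar grid with voxel spacing in mm.

    Parameters
    ----------
    data:
        3D array of scalars (MRI intensity in arbitrary units, CT number in
        HU, or dose in Gy).
    spacing:
        Voxel edge lengths in mm, one per axis, all positive.
    modality:
        One of :class:`Modality` (or its string value).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    modality: Modality = Modality.CT
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D data")
        if min(self.data.shape) < 1:
            raise ValueError(f"all dimensions must be >= 1, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        self.modality = Modality(self.modality)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray, modality: Modality | str | None = None) -> "ImageVolume":
        """New volume on the same grid with replaced voxel values."""
        return ImageVolume(
            data=np.asarray(data, dtype=np.float64),
            spacing=self.spacing,
            modality=Modality(modality) if modality is not None else self.modality,
            affine=self.affine,
        )

    def same_grid(self, other: "ImageVolume") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


@dataclass
class RegionLabelMap:
    """Per-voxel categorical region labels plus an independent excluded overlay.

    ``labels`` partitions the grid into OUTSIDE plus the body regions
    {BONY, SOFT, MIXED}; ``excluded`` is a boolean overlay that may cover
    voxels of any region (it marks anatomy mismatched between modalities,
    to be dropped from training and evaluation but not from prediction).
    """

    labels: np.ndarray
    excluded: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected 3D label map, got {self.labels.ndim}D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.all(self.labels == np.round(self.labels)):
                raise ValueError("label map must be integer-valued")
            self.labels = self.labels.astype(np.int16)
        unknown = set(np.unique(self.labels)) - set(REGION_NAMES)
        if unknown:
            raise ValueError(f"unknown region codes in label map: {sorted(unknown)}")
        if self.excluded is None:
            self.excluded = np.zeros(self.labels.shape, dtype=bool)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if self.excluded.shape != self.labels.shape:
            raise ValueError(
                f"excluded overlay shape {self.excluded.shape} does not match "
                f"labels shape {self.labels.shape}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def body_mask(self) -> np.ndarray:
        return self.labels != OUTSIDE

    def region_mask(self, code: int) -> np.ndarray:
        return self.labels == code

    def present_regions(self) -> list[int]:
        """Body region codes that have at least one voxel."""
        return [c for c in BODY_REGIONS if np.any(self.labels == c)]


def _load_nifti(path: str | os.PathLike) -> nib.spatialimages.SpatialImage:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"file not found: {path}")
    return nib.load(str(path))


def read_volume(path: str | os.PathLike, modality: Modality | str = Modality.CT) -> ImageVolume:
    """Read a 3D scalar NIfTI image.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    ValueError
        If the image is not 3D.
    TypeError
        If the voxel datatype is not a real scalar type.
    """
    img = _load_nifti(path)
    if len(img.shape) != 3:
        raise ValueError(f"expected 3D volume, got {len(img.shape)}D image in {path}")
    dtype = img.get_data_dtype()
    if dtype.kind not in "fiu":
        raise TypeError(f"expected scalar voxel data, got dtype {dtype} in {path}")
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(data=data, spacing=spacing, modality=modality, affine=np.array(img.affine))


def write_volume(vol: ImageVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-2 (float64 voxels and spacing: lossless round-trip)."""
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"directory does not exist: {path.parent}")
    affine = vol.affine if vol.affine is not None else np.diag([*vol.spacing, 1.0])
    img = nib.Nifti2Image(vol.data.astype(np.float64), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_labelmap(
    path: str | os.PathLike,
    code_table: Mapping[int, str] | None = None,
    excluded_path: str | os.PathLike | None = None,
) -> RegionLabelMap:
    """Read an integer-coded region map, translating file codes via *code_table*.

    Every integer present in the file must appear in *code_table* and map to a
    canonical region name (OUTSIDE/BONY/SOFT/MIXED).  The excluded overlay is
    read from *excluded_path* when given, else all-false.
    """
    table = dict(DEFAULT_CODE_TABLE if code_table is None else code_table)
    img = _load_nifti(path)
    if len(img.shape) != 3:
        raise ValueError(f"expected 3D label map, got {len(img.shape)}D image in {path}")
    raw = np.asarray(img.dataobj)
    if not np.all(raw == np.round(raw)):
        raise ValueError(f"label map {path} is not integer-valued")
    raw = raw.astype(np.int64)
    codes = np.unique(raw)
    labels = np.zeros(raw.shape, dtype=np.int16)
    for code in codes:
        if int(code) not in table:
            raise ValueError(f"unknown label code {int(code)} in {path}: not in code table")
        name = table[int(code)]
        if name not in REGION_CODES:
            raise ValueError(f"code table maps {int(code)} to unknown region {name!r}")
        labels[raw == code] = REGION_CODES[name]
    excluded = None
    if excluded_path is not None:
        ex_img = _load_nifti(excluded_path)
        excluded = np.asarray(ex_img.dataobj) > 0
    return RegionLabelMap(labels=labels, excluded=excluded)


def write_labelmap(
    lm: RegionLabelMap,
    path: str | os.PathLike,
    excluded_path: str | os.PathLike | None = None,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> None:
    """Write labels (and optionally the excluded overlay) as integer NIfTI-2."""
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"directory does not exist: {path.parent}")
    affine = np.diag([*spacing, 1.0])
    img = nib.Nifti2Image(lm.labels.astype(np.int16), affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))
    if excluded_path is not None:
        ex = nib.Nifti2Image(lm.excluded.astype(np.int16), affine)
        ex.header.set_zooms(spacing)
        nib.save(ex, str(excluded_path))
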