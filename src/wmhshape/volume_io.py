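"""Reading and writing image volumes and tabular lesion/subject data.

Volumes travel as :class:`VolumeGrid`: a 3D array plus per-axis voxel
spacing in mm and a 4x4 grid-to-world affine. Voxel indices are 0-based and
world coordinates are voxel-center positions under the affine. Binary masks
are stored as unsigned 8-bit; feature tables hold 64-bit floats.

Lesion tables are plain CSV with a fixed, documented header
(:data:`LESION_TABLE_COLUMNS`); missing optional values (e.g. the lobe of a
non-punctuate lesion) are written as empty fields, never as zero.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "SubjectMeta",
    "FormatError",
    "GridMismatchError",
    "read_volume",
    "write_volume",
    "read_mask",
    "check_same_grid",
    "write_lesion_table",
    "read_lesion_table",
    "write_subject_table",
    "read_subject_table",
    "LESION_TABLE_COLUMNS",
    "SUBJECT_TABLE_COLUMNS",
]


class FormatError(ValueError):
    """Raised for malformed image or table inputs."""


class GridMismatchError(ValueError):
    """Raised when volumes of one subject disagree in shape/spacing/affine."""


@dataclass
class VolumeGrid:
    """A 3D scalar or binary image with grid metadata.

    Parameters
    ----------
    data:
        3D array. Binary volumes contain only {0, 1}.
    spacing:
        Per-axis voxel size ``(sx, sy, sz)`` in mm, strictly positive.
    affine:
        4x4 grid-to-world transform mapping 0-based voxel indices to mm
        world coordinates (voxel centers). Defaults to ``diag(spacing)``.
    is_binary:
        Marks the volume as a mask.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None
    is_binary: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"expected a 3D volume, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        if self.is_binary:
            vals = np.unique(self.data)
            if not np.all(np.isin(vals, (0, 1))):
                raise FormatError("binary volume contains values other than 0/1")
            self.data = self.data.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in ml (mm^3 / 1000)."""
        return math.prod(self.spacing) / 1000.0


@dataclass
class SubjectMeta:
    """Demographics and normalization data for one subject.

    ``icv`` is the intracranial volume in ml; optional covariates (gray and
    white matter volume as %ICV, diabetes duration in years) are ``None``
    when absent.
    """

    subject_id: str
    group: str  # "patient" | "control"
    age: float
    sex: str  # "M" | "F"
    icv: float
    gm_volume: float | None = None
    wm_volume: float | None = None
    diabetes_duration: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise ValueError(f"group must be patient/control, got {self.group!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be M/F, got {self.sex!r}")
        if not self.icv > 0:
            raise ValueError("icv must be positive")
        if not self.age > 0:
            raise ValueError("age must be positive")


def _grid_from_nifti(img: nib.Nifti1Image) -> VolumeGrid:
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"expected a 3D image, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise FormatError(f"invalid voxel spacing in header: {zooms}")
    return VolumeGrid(data=data, spacing=tuple(float(z) for z in zooms), affine=np.asarray(img.affine))


def read_volume(path: str | Path) -> VolumeGrid:
    """Read a 3D NIfTI volume, extracting spacing from the header.

    4D inputs with a singleton last dimension are squeezed. Non-3D data or
    missing spacing raise :class:`FormatError`.
    """
    img = nib.load(str(path))
    return _grid_from_nifti(img)


def write_volume(grid: VolumeGrid, path: str | Path) -> None:
    """Write a :class:`VolumeGrid` as NIfTI-1, preserving spacing/affine."""
    data = grid.data.astype(np.uint8) if grid.is_binary else np.asarray(grid.data)
    img = nib.Nifti1Image(data, grid.affine)
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path, threshold: float = 0.5) -> VolumeGrid:
    """Read a volume and binarize it at ``threshold`` (values >= threshold -> 1)."""
    grid = read_volume(path)
    data = (np.asarray(grid.data, dtype=float) >= threshold).astype(np.uint8)
    return VolumeGrid(data=data, spacing=grid.spacing, affine=grid.affine, is_binary=True)


def check_same_grid(a: VolumeGrid, b: VolumeGrid, tol: float = 1e-4) -> None:
    """Raise :class:`GridMismatchError` unless two volumes share shape, spacing and affine."""
    if a.shape != b.shape:
        raise GridMismatchError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing, b.spacing, atol=tol):
        raise GridMismatchError(f"spacing mismatch: {a.spacing} vs {b.spacing}")
    if not np.allclose(a.affine, b.affine, atol=tol):
        raise GridMismatchError("affine mismatch")


# Fixed lesion-table header. The first block mirrors the documented
# interchange contract; the remaining columns complete the per-lesion
# feature record so that read(write(x)) is the identity.
LESION_TABLE_COLUMNS = [
    "subject_id",
    "lesion_id",
    "n_voxels",
    "volume_ml",
    "surface_area_icv",
    "eccentricity",
    "compactness1",
    "compactness2",
    "compactness3",
    "fractal_dimension",
    "shape_index",
    "curvedness",
    "lesion_class",
    "lobe",
    "min_ventricle_distance_mm",
    "max_diameter_mm",
    "surface_area_mm2",
    "bbox_dim_x_mm",
    "bbox_dim_y_mm",
    "bbox_dim_z_mm",
    "override_applied",
]

SUBJECT_TABLE_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "sex",
    "icv",
    "gm_volume",
    "wm_volume",
    "diabetes_duration",
]


def _fmt(value: float | None) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    return repr(float(value))


def _parse_float(text: str) -> float | None:
    return None if text == "" else float(text)


def write_lesion_table(records: Sequence, path: str | Path) -> None:
    """Write lesion records to CSV with the fixed header.

    All records must share one ``subject_id``. Optional fields (lobe of a
    non-punctuate lesion, flagged-undefined features) are written empty.
    """
    subject_ids = {r.subject_id for r in records}
    if len(subject_ids) > 1:
        raise ValueError(f"records span multiple subjects: {sorted(subject_ids)}")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(LESION_TABLE_COLUMNS)
        for r in records:
            f = r.features
            writer.writerow(
                [
                    r.subject_id,
                    r.lesion_id,
                    r.n_voxels,
                    _fmt(f.volume_ml),
                    _fmt(f.surface_area_icv),
                    _fmt(f.eccentricity),
                    _fmt(f.compactness1),
                    _fmt(f.compactness2),
                    _fmt(f.compactness3),
                    _fmt(f.fractal_dimension),
                    _fmt(f.shape_index),
                    _fmt(f.curvedness),
                    r.lesion_class,
                    r.lobe if r.lobe is not None else "",
                    _fmt(r.min_ventricle_distance_mm),
                    _fmt(f.max_diameter_mm),
                    _fmt(f.surface_area_mm2),
                    _fmt(f.bbox_dims_mm[0]),
                    _fmt(f.bbox_dims_mm[1]),
                    _fmt(f.bbox_dims_mm[2]),
                    int(r.override_applied),
                ]
            )


def read_lesion_table(path: str | Path) -> list:
    """Read a lesion CSV back into :class:`~wmhshape.location_features.LesionRecord` objects."""
    from .location_features import LesionRecord
    from .shape_features import ShapeFeatureSet

    records: list = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError("empty lesion table")
        if header != LESION_TABLE_COLUMNS:
            raise FormatError(f"unexpected lesion table header: {header}")
        for row in reader:
            vals = dict(zip(header, row))

            def num(key: str) -> float:
                v = _parse_float(vals[key])
                return math.nan if v is None else v

            features = ShapeFeatureSet(
                volume_ml=num("volume_ml"),
                surface_area_mm2=num("surface_area_mm2"),
                surface_area_icv=num("surface_area_icv"),
                eccentricity=num("eccentricity"),
                compactness1=num("compactness1"),
                compactness2=num("compactness2"),
                compactness3=num("compactness3"),
                fractal_dimension=num("fractal_dimension"),
                shape_index=num("shape_index"),
                curvedness=num("curvedness"),
                max_diameter_mm=num("max_diameter_mm"),
                bbox_dims_mm=(num("bbox_dim_x_mm"), num("bbox_dim_y_mm"), num("bbox_dim_z_mm")),
            )
            records.append(
                LesionRecord(
                    subject_id=vals["subject_id"],
                    lesion_id=int(vals["lesion_id"]),
                    n_voxels=int(vals["n_voxels"]),
                    features=features,
                    lesion_class=vals["lesion_class"],
                    lobe=vals["lobe"] or None,
                    min_ventricle_distance_mm=num("min_ventricle_distance_mm"),
                    override_applied=bool(int(vals["override_applied"])),
                )
            )
    return records


def write_subject_table(metas: Iterable[SubjectMeta], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SUBJECT_TABLE_COLUMNS)
        for m in metas:
            writer.writerow(
                [
                    m.subject_id,
                    m.group,
                    _fmt(m.age),
                    m.sex,
                    _fmt(m.icv),
                    _fmt(m.gm_volume),
                    _fmt(m.wm_volume),
                    _fmt(m.diabetes_duration),
                ]
            )


def read_subject_table(path: str | Path) -> list[SubjectMeta]:
    metas = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError("empty subject table")
        if header != SUBJECT_TABLE_COLUMNS:
            raise FormatError(f"unexpected subject table header: {header}")
        for row in reader:
            vals = dict(zip(header, row))
            metas.append(
                SubjectMeta(
                    subject_id=vals["subject_id"],
                    group=vals["group"],
                    age=float(vals["age"]),
                    sex=vals["sex"],
                    icv=float(vals["icv"]),
                    gm_volume=_parse_float(vals["gm_volume"]),
                    wm_volume=_parse_float(vals["wm_volume"]),
                    diabetes_duration=_parse_float(vals["diabetes_duration"]),
                )
            )
    return metas
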