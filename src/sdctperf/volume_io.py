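"""Volumetric and tabular I/O for per-case spectral-CT data.

Each analysis case consists of co-registered 3-D volumes on one voxel grid:
an iodine-density image (IDI, mg iodine/mL), a virtual-non-contrast image
(VNC, Hounsfield units), a lung mask and two vascular reference-ROI masks
(main pulmonary artery and left atrium). Volumes are exchanged as NIfTI-1
files; cohort and feature tables as UTF-8 CSV.

Grid consistency is enforced, never repaired: volumes that do not share a
shape and affine are rejected as mis-registered.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Volume kinds. ``idi`` carries mg iodine/mL, ``vnc`` carries HU, ``mask``
#: carries {0, 1} labels stored as uint8.
VOLUME_KINDS = ("idi", "vnc", "mask")

#: Required columns of a cohort table (one row per case).
COHORT_COLUMNS = (
    "case_id",
    "subgroup_label",
    "idi_path",
    "vnc_path",
    "lung_mask_path",
    "mpa_mask_path",
    "la_mask_path",
)

#: Columns of the per-case feature table, in output order.
FEATURE_COLUMNS = (
    "case_id",
    "id_mpa",
    "id_la",
    "v_perfnorm_pct",
    "v_perfdef_pct",
    "v_ves_pct",
    "meanid_norm",
    "meanid_def",
    "skew_norm",
    "skew_def",
    "kurt_norm",
    "kurt_def",
    "emphysema_pct",
    "delta_index",
    "pred_stage1",
    "pred_subgroup",
    "true_label",
)

SUBGROUP_LABELS = ("control", "g1", "g2_ipc", "g2_cpc", "g3", "g4")


class GridMismatchError(ValueError):
    """Volumes of one case do not share a voxel grid (shape + affine)."""


@dataclass
class VoxelVolume:
    """A 3-D scalar grid with voxel spacing and a voxel-to-world affine.

    Parameters
    ----------
    values
        3-D array. mg iodine/mL for ``kind='idi'``, HU for ``'vnc'``,
        {0, 1} for ``'mask'``.
    spacing
        Per-axis voxel size in mm, all components > 0.
    affine
        4x4 voxel-to-world transform (NIfTI convention).
    kind
        One of :data:`VOLUME_KINDS`, or ``None`` if unspecified.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    kind: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(
                f"expected 3-D volume, got {self.values.ndim}-D array"
            )
        if min(self.values.shape) < 1:
            raise ValueError("every axis must have length >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if self.kind is not None and self.kind not in VOLUME_KINDS:
            raise ValueError(f"unknown volume kind {self.kind!r}")
        if self.kind == "mask":
            vals = np.unique(self.values)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(
                    "mask must be binary; found values "
                    f"{vals[~np.isin(vals, (0, 1))][:5].tolist()}"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (spacing is in mm)."""
        return float(np.prod(self.spacing)) / 1000.0


@dataclass
class LoadedCase:
    """One cohort case with all five volumes loaded and grid-validated."""

    case_id: str
    idi: VoxelVolume
    vnc: VoxelVolume
    lung_mask: VoxelVolume
    mpa_mask: VoxelVolume
    la_mask: VoxelVolume
    true_label: str | None = None


def read_volume(path: str | os.PathLike, kind: str | None = None) -> VoxelVolume:
    """Read a NIfTI volume.

    ``kind`` given by the caller wins; otherwise it is inferred from the
    ``descrip`` header field written by :func:`write_volume` (``kind=...``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3-D volume, got {data.ndim}-D image in {path}")
    if kind is None:
        descrip = bytes(img.header["descrip"]).split(b"\x00")[0].decode(errors="ignore")
        if descrip.startswith("kind="):
            candidate = descrip[5:].strip()
            if candidate in VOLUME_KINDS:
                kind = candidate
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VoxelVolume(values=data, spacing=spacing, affine=np.asarray(img.affine), kind=kind)


def write_volume(vol: VoxelVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1.

    Masks are stored as uint8, images as float32, so a write/read round trip
    is bit-identical for those payloads. Overwrites are allowed and logged.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    if path.exists():
        logger.info("overwriting existing volume %s", path)
    dtype = np.uint8 if vol.kind == "mask" else np.float32
    img = nib.Nifti1Image(np.ascontiguousarray(vol.values, dtype=dtype), vol.affine)
    img.header.set_zooms(vol.spacing)
    if vol.kind is not None:
        img.header["descrip"] = f"kind={vol.kind}".encode()
    nib.save(img, str(path))


def validate_case_grids(volumes: Sequence[VoxelVolume], atol: float = 1e-4) -> None:
    """Check that all volumes of a case share one grid.

    Raises :class:`GridMismatchError` on a shape or affine mismatch — the
    signature of mis-registered inputs. Symmetric in argument order.
    """
    if len(volumes) < 2:
        raise ValueError("need at least 2 volumes to validate a grid")
    ref = volumes[0]
    for i, vol in enumerate(volumes[1:], start=1):
        if vol.shape != ref.shape:
            raise GridMismatchError(
                f"shape mismatch: volume 0 has {ref.shape}, volume {i} has {vol.shape}"
            )
        if not np.allclose(vol.affine, ref.affine, atol=atol, rtol=0):
            raise GridMismatchError(
                f"affine mismatch between volume 0 and volume {i} (atol={atol}); "
                "inputs appear mis-registered"
            )


def read_cohort_table(path: str | os.PathLike, check_paths: bool = True) -> pd.DataFrame:
    """Read and validate a cohort CSV (columns :data:`COHORT_COLUMNS`).

    Relative file paths are resolved against the CSV's directory.
    """
    path = Path(path)
    table = pd.read_csv(path, dtype={"case_id": str})
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing required column(s): {', '.join(missing)}")
    dupes = table["case_id"][table["case_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate case_id in cohort table: {dupes}")
    base = path.parent
    for col in COHORT_COLUMNS:
        if not col.endswith("_path"):
            continue
        resolved = [str(p) if Path(p).is_absolute() else str(base / p) for p in table[col]]
        table[col] = resolved
        if check_paths:
            for p in resolved:
                if not Path(p).exists():
                    raise FileNotFoundError(f"cohort table references missing file: {p}")
    return table


def load_case(row: pd.Series | dict) -> LoadedCase:
    """Load all five volumes of one cohort-table row and validate the grid."""
    idi = read_volume(row["idi_path"], kind="idi")
    vnc = read_volume(row["vnc_path"], kind="vnc")
    lung = read_volume(row["lung_mask_path"], kind="mask")
    mpa = read_volume(row["mpa_mask_path"], kind="mask")
    la = read_volume(row["la_mask_path"], kind="mask")
    validate_case_grids([idi, vnc, lung, mpa, la])
    label = row.get("subgroup_label")
    return LoadedCase(
        case_id=str(row["case_id"]), idi=idi, vnc=vnc, lung_mask=lung,
        mpa_mask=mpa, la_mask=la, true_label=None if label is None else str(label),
    )


def _as_row(record) -> dict:
    if isinstance(record, dict):
        return dict(record)
    from dataclasses import asdict, is_dataclass

    if is_dataclass(record):
        return asdict(record)
    raise TypeError(f"cannot convert {type(record).__name__} to a feature row")


def write_feature_table(records: Iterable, path: str | os.PathLike) -> pd.DataFrame:
    """Write per-case feature records as CSV with columns :data:`FEATURE_COLUMNS`.

    Numeric fields round-trip at full precision (Python repr formatting).
    Returns the frame that was written.
    """
    rows = [_as_row(r) for r in records]
    frame = pd.DataFrame(rows)
    missing = [c for c in FEATURE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"feature records missing field(s): {', '.join(missing)}")
    frame = frame[list(FEATURE_COLUMNS)]
    frame.to_csv(path, index=False)
    return frame


def read_feature_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a feature CSV written by :func:`write_feature_table`."""
    table = pd.read_csv(path, dtype={"case_id": str})
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing required column(s): {', '.join(missing)}")
    dupes = table["case_id"][table["case_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate case_id in feature table: {dupes}")
    return table
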