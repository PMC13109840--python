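"""Readers and writers for the neuroimaging and tabular formats the pipeline touches.

Conventions used throughout the package:

* world coordinates are RAS millimeters;
* voxel indices are 0-based and a voxel's world position is the affine image of
  its integer index (voxel-center convention).

These conventions matter: the >50 % contact-in-region rule downstream counts
voxels whose *centers* fall inside the contact cylinder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumeImage",
    "ContactTable",
    "read_volume",
    "write_volume",
    "read_vertex_map",
    "write_vertex_map",
    "read_contacts",
    "write_contacts",
    "read_surface_geometry",
    "write_surface_geometry",
    "read_parcellation_table",
    "write_parcellation_table",
]

CONTACT_DIAMETER_MM = 0.8
CONTACT_LENGTH_MM = 2.0

_REQUIRED_CONTACT_COLUMNS = (
    "contact_id",
    "electrode",
    "x",
    "y",
    "z",
    "axis_x",
    "axis_y",
    "axis_z",
    "soz_flag",
)


@dataclass
class VolumeImage:
    """A 3-D scalar grid with a voxel-to-world affine (RAS mm).

    ``data`` may carry PET activity, anatomical intensity, or integer labels;
    ``affine`` maps 0-based voxel indices to world mm at voxel centers.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3-D, got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError("volume grid must have extent >= 1 along each axis")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Per-axis voxel edge lengths in mm (column norms of the linear part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def is_label_volume(self) -> bool:
        return np.issubdtype(self.data.dtype, np.integer) or self.data.dtype == bool

    def with_data(self, data: np.ndarray) -> "VolumeImage":
        return VolumeImage(data=data, affine=self.affine.copy())


@dataclass
class ContactTable:
    """SEEG contact table: one row per cylindrical contact in world mm.

    Columns: contact_id, electrode, x, y, z, axis_x, axis_y, axis_z, soz_flag.
    All contacts share the fixed cylinder geometry (0.8 mm diameter, 2 mm
    length). Axis vectors are unit-norm.
    """

    df: pd.DataFrame
    diameter_mm: float = CONTACT_DIAMETER_MM
    length_mm: float = CONTACT_LENGTH_MM

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED_CONTACT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"contact table missing columns: {missing}")
        if self.df["contact_id"].duplicated().any():
            dups = self.df["contact_id"][self.df["contact_id"].duplicated()].tolist()
            raise ValueError(f"duplicate contact ids: {dups}")
        if self.diameter_mm <= 0 or self.length_mm <= 0:
            raise ValueError("contact diameter and length must be positive")
        axes = self.df[["axis_x", "axis_y", "axis_z"]].to_numpy(dtype=float)
        norms = np.linalg.norm(axes, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero-length contact axis vector")
        if np.any(np.abs(norms - 1.0) > 1e-3):
            warnings.warn(
                "non-unit contact axis vectors renormalized", stacklevel=2
            )
        self.df = self.df.copy()
        self.df[["axis_x", "axis_y", "axis_z"]] = axes / norms[:, None]
        self.df["soz_flag"] = self.df["soz_flag"].astype(bool)
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def centers(self) -> np.ndarray:
        return self.df[["x", "y", "z"]].to_numpy(dtype=float)

    @property
    def axes(self) -> np.ndarray:
        return self.df[["axis_x", "axis_y", "axis_z"]].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# volumes


def read_volume(path: str | Path) -> VolumeImage:
    """Read a NIfTI-1 (.nii/.nii.gz) or MGH (.mgh/.mgz) volume."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return VolumeImage(data=data, affine=np.asarray(img.affine))


def write_volume(volume: VolumeImage, path: str | Path) -> Path:
    """Write a volume as NIfTI-1. Data dtype is preserved."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = volume.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, volume.affine)
    img.header.set_data_dtype(data.dtype)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# vertex maps


def read_vertex_map(path: str | Path, n_vertices: int | None = None) -> np.ndarray:
    """Read a per-vertex scalar map.

    ``.csv`` files must carry ``vertex_id,value`` columns (rows in any order);
    any other extension is read as FreeSurfer curv format. If ``n_vertices``
    is given, a length mismatch is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"vertex map not found: {path}")
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        if not {"vertex_id", "value"}.issubset(df.columns):
            raise ValueError("vertex map CSV requires columns vertex_id,value")
        df = df.sort_values("vertex_id")
        ids = df["vertex_id"].to_numpy()
        if not np.array_equal(ids, np.arange(len(ids))):
            raise ValueError("vertex_id column must cover 0..n-1 exactly once")
        values = df["value"].to_numpy(dtype=np.float32)
    else:
        values = np.asarray(nib.freesurfer.read_morph_data(str(path)), dtype=np.float32)
    if n_vertices is not None and len(values) != n_vertices:
        raise ValueError(
            f"vertex map length {len(values)} does not match surface "
            f"vertex count {n_vertices}"
        )
    return values


def write_vertex_map(values: np.ndarray, path: str | Path) -> Path:
    """Write a per-vertex map as CSV (``.csv``) or FreeSurfer curv (otherwise)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    values = np.asarray(values, dtype=np.float32)
    if values.ndim != 1:
        raise ValueError("vertex map must be 1-D")
    if path.suffix.lower() == ".csv":
        pd.DataFrame(
            {"vertex_id": np.arange(len(values)), "value": values}
        ).to_csv(path, index=False)
    else:
        nib.freesurfer.write_morph_data(str(path), values)
    return path


# ---------------------------------------------------------------------------
# surfaces (geometry only; see surface.SurfaceModel for the full container)


def read_surface_geometry(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read FreeSurfer binary surface geometry -> (vertices mm, faces)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"surface file not found: {path}")
    vertices, faces = nib.freesurfer.read_geometry(str(path))
    return np.asarray(vertices, dtype=float), np.asarray(faces, dtype=int)


def write_surface_geometry(
    vertices: np.ndarray, faces: np.ndarray, path: str | Path
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.freesurfer.write_geometry(str(path), np.asarray(vertices), np.asarray(faces))
    return path


# ---------------------------------------------------------------------------
# parcellation label tables


def write_parcellation_table(
    labels: np.ndarray, region_table: pd.DataFrame, path: str | Path
) -> Path:
    """Write a per-vertex label table (vertex_id,region_id,region,hemisphere)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lut = region_table.set_index("region_id")
    names = lut["name"].reindex(labels).fillna("unknown").to_numpy()
    hemis = lut["hemisphere"].reindex(labels).fillna("unknown").to_numpy()
    pd.DataFrame(
        {
            "vertex_id": np.arange(len(labels)),
            "region_id": labels,
            "region": names,
            "hemisphere": hemis,
        }
    ).to_csv(path, index=False)
    return path


def read_parcellation_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"parcellation table not found: {path}")
    df = pd.read_csv(path)
    required = {"vertex_id", "region_id", "region", "hemisphere"}
    if not required.issubset(df.columns):
        raise ValueError(f"parcellation table requires columns {sorted(required)}")
    return df.sort_values("vertex_id").reset_index(drop=True)


# ---------------------------------------------------------------------------
# contacts


def read_contacts(path: str | Path) -> ContactTable:
    """Read a contact CSV; validates columns, uniqueness, and axis norms."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"contact table not found: {path}")
    df = pd.read_csv(path)
    return ContactTable(df=df)


def write_contacts(table: ContactTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.df.to_csv(path, index=False)
    return path
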