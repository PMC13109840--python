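"""SEEG contact localization in a labeled volume.

Each cylindrical contact (0.8 mm diameter, 2 mm length) is rasterized into
the label volume: the footprint is the set of voxels whose centers fall
inside the cylinder. A contact resides in gray matter only if strictly more
than 50 % of its footprint falls within a single cortical region; the
denominator is the full footprint, all labels (white matter and background
included). On grids too coarse for the cylinder to capture several voxel
centers, candidate voxels are subdivided 4x per axis and fractional occupancy
is used, which keeps the rule meaningful at clinical voxel sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ContactTable, VolumeImage
from .surface import Parcellation

__all__ = [
    "ContactFootprint",
    "ContactAssignment",
    "voxelize_contact",
    "assign_contact_region",
    "filter_gray_matter_contacts",
]

MIN_DIRECT_VOXELS = 8
SUPERSAMPLE = 4


@dataclass
class ContactFootprint:
    """Voxels overlapped by one contact, with fractional occupancy weights."""

    indices: np.ndarray  # (n, 3) voxel indices
    weights: np.ndarray  # (n,) occupancy in (0, 1]
    supersampled: bool

    @property
    def total(self) -> float:
        return float(self.weights.sum())


@dataclass
class ContactAssignment:
    """Region decision for one contact under the strict >50 % rule."""

    contact_id: str
    region_id: int | None
    region: tuple[str, str] | None
    majority_fraction: float
    verified: bool
    voxel_counts: dict = field(default_factory=dict)


def _cylinder_test(points: np.ndarray, center: np.ndarray, axis: np.ndarray,
                   radius: float, half_length: float) -> np.ndarray:
    d = points - center
    axial = d @ axis
    radial_sq = np.einsum("ij,ij->i", d, d) - axial**2
    return (np.abs(axial) <= half_length) & (radial_sq <= radius**2 + 1e-12)


def voxelize_contact(
    center,
    axis,
    label_volume: VolumeImage,
    diameter_mm: float = 0.8,
    length_mm: float = 2.0,
) -> ContactFootprint:
    """Rasterize a cylindrical contact into a volume grid.

    Returns the voxels whose centers lie inside the cylinder (radius
    ``diameter_mm/2``, half-length ``length_mm/2`` about the center along the
    axis). If fewer than 8 voxel centers are captured — coarse grids — each
    candidate voxel is subdivided 4x per axis and fractional occupancy weights
    are returned instead.
    """
    center = np.asarray(center, dtype=float)
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("contact axis must be non-zero")
    axis = axis / norm
    radius = diameter_mm / 2.0
    half_length = length_mm / 2.0

    shape = np.asarray(label_volume.shape)
    cvox = label_volume.world_to_voxel(center)[0]
    if np.any(cvox < -0.5) or np.any(cvox > shape - 0.5):
        raise ValueError(f"contact center {center} lies outside the volume grid")

    # candidate box: world AABB of the cylinder mapped through the inverse affine
    reach = half_length * np.abs(axis) + radius
    corners = center + np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
    ) * (reach + 1e-9)
    corner_vox = label_volume.world_to_voxel(corners)
    lo = np.maximum(np.floor(corner_vox.min(axis=0)).astype(int), 0)
    hi = np.minimum(np.ceil(corner_vox.max(axis=0)).astype(int), shape - 1)
    grids = np.meshgrid(*[np.arange(lo[i], hi[i] + 1) for i in range(3)], indexing="ij")
    candidates = np.column_stack([g.ravel() for g in grids])
    if len(candidates) == 0:
        raise ValueError("contact footprint is empty")

    centers_world = label_volume.voxel_to_world(candidates)
    inside = _cylinder_test(centers_world, center, axis, radius, half_length)
    if inside.sum() >= MIN_DIRECT_VOXELS:
        idx = candidates[inside]
        return ContactFootprint(
            indices=idx, weights=np.ones(len(idx)), supersampled=False
        )

    # supersampling fallback: fractional occupancy per candidate voxel
    s = SUPERSAMPLE
    offsets_unit = (np.arange(s) + 0.5) / s - 0.5
    og = np.meshgrid(offsets_unit, offsets_unit, offsets_unit, indexing="ij")
    sub_offsets_vox = np.column_stack([g.ravel() for g in og])
    sub_offsets_world = sub_offsets_vox @ label_volume.affine[:3, :3].T
    occupancy = np.zeros(len(candidates))
    for k, sub in enumerate(sub_offsets_world):
        occupancy += _cylinder_test(
            centers_world + sub, center, axis, radius, half_length
        )
    occupancy /= len(sub_offsets_world)
    hit = occupancy > 0
    if not hit.any():
        raise ValueError("contact footprint is empty even after supersampling")
    return ContactFootprint(
        indices=candidates[hit], weights=occupancy[hit], supersampled=True
    )


def assign_contact_region(
    footprint: ContactFootprint,
    label_volume: VolumeImage,
    parcellation: Parcellation,
    contact_id: str = "",
) -> ContactAssignment:
    """Apply the strict >50 % single-region rule to a contact footprint.

    The footprint's (possibly fractional) voxel weights are summed per label;
    the contact is verified gray matter iff one cortical region holds strictly
    more than half of the total footprint. Exact 50/50 ties fail. The
    denominator includes every label (white matter, background).
    """
    if len(footprint.indices) == 0:
        raise ValueError("empty footprint")
    labels = label_volume.data[tuple(footprint.indices.T)].astype(int)
    counts: dict[int, float] = {}
    for lab, w in zip(labels, footprint.weights):
        counts[int(lab)] = counts.get(int(lab), 0.0) + float(w)
    total = footprint.total
    gray_ids = set(int(i) for i in parcellation.region_ids)
    gray_counts = {l: c for l, c in counts.items() if l in gray_ids}
    if gray_counts:
        best = max(sorted(gray_counts), key=lambda l: gray_counts[l])
        fraction = gray_counts[best] / total
    else:
        best, fraction = None, 0.0
    verified = best is not None and fraction > 0.5
    return ContactAssignment(
        contact_id=contact_id,
        region_id=best if verified else None,
        region=parcellation.key_of(best) if verified else None,
        majority_fraction=fraction,
        verified=verified,
        voxel_counts=counts,
    )


def filter_gray_matter_contacts(
    contact_table: ContactTable,
    label_volume: VolumeImage,
    parcellation: Parcellation,
) -> tuple[ContactTable, pd.DataFrame]:
    """Keep only contacts verified by the >50 % rule; report every contact.

    Returns the verified subset of the table plus a report with one row per
    input contact (contact_id, region, hemisphere, majority_fraction,
    verified).
    """
    rows = []
    verified_mask = []
    for _, row in contact_table.df.iterrows():
        footprint = voxelize_contact(
            row[["x", "y", "z"]].to_numpy(dtype=float),
            row[["axis_x", "axis_y", "axis_z"]].to_numpy(dtype=float),
            label_volume,
            diameter_mm=contact_table.diameter_mm,
            length_mm=contact_table.length_mm,
        )
        a = assign_contact_region(
            footprint, label_volume, parcellation, contact_id=str(row["contact_id"])
        )
        hemi, name = a.region if a.region else ("", "")
        rows.append(
            {
                "contact_id": a.contact_id,
                "region_id": a.region_id if a.region_id is not None else 0,
                "region": name,
                "hemisphere": hemi,
                "majority_fraction": a.majority_fraction,
                "verified": a.verified,
            }
        )
        verified_mask.append(a.verified)
    report = pd.DataFrame(
        rows,
        columns=[
            "contact_id",
            "region_id",
            "region",
            "hemisphere",
            "majority_fraction",
            "verified",
        ],
    )
    kept = contact_table.df[np.asarray(verified_mask, dtype=bool)].reset_index(drop=True) \
        if len(contact_table.df) else contact_table.df.copy()
    verified_table = ContactTable(
        df=kept,
        diameter_mm=contact_table.diameter_mm,
        length_mm=contact_table.length_mm,
    ) if len(kept) else ContactTable(
        df=pd.DataFrame(columns=contact_table.df.columns),
        diameter_mm=contact_table.diameter_mm,
        length_mm=contact_table.length_mm,
    )
    return verified_table, report
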