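"""Synthetic data generators for every input the analysis consumes.

The generators emulate the statistical structure the pipeline assumes — a
healthy-control cohort of vertex metabolic maps with per-vertex Gaussian
variation, patients with planted regional hypometabolism of stated effect
size (in multiples of the control standard deviation), a phantom head volume
pair with a known affine misalignment and a cerebellum reference compartment,
and SEEG contact tables with ground-truth region and seizure-onset labels —
so that every downstream stage is testable without clinical data.

Everything is fully deterministic under ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh
from scipy import ndimage
from scipy.sparse import csgraph, csr_matrix
from scipy.spatial import cKDTree

from .io_formats import CONTACT_LENGTH_MM, ContactTable, VolumeImage
from .preproc import FWHM_TO_SIGMA, AffineTransform
from .surface import Parcellation, SurfaceModel, SurfacePair

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SceneBundle",
    "make_toy_surface",
    "make_parcellation",
    "make_parcellation_pair",
    "make_surface_pair",
    "regional_means",
    "control_baseline",
    "simulate_control_cohort",
    "simulate_patient",
    "simulate_volume_scene",
    "simulate_contacts",
]

# independent random streams per generator, all derived from config.seed
_TAG_THICKNESS = 11
_TAG_PARCEL = 12
_TAG_BASELINE = 13
_TAG_CONTROLS = 14
_TAG_PATIENT = 15
_TAG_SCENE = 16
_TAG_CONTACTS = 17

WHITE_LABEL = 1001
CEREBELLUM_LABEL = 1002

CONTACT_SPACING_MM = 1.5  # edge-to-edge gap between adjacent contacts
CONTACT_PITCH_MM = CONTACT_LENGTH_MM + CONTACT_SPACING_MM  # center-to-center

# phantom head geometry (world mm; grid is centered on the origin); the
# hemisphere spheres overlap slightly at the midline and a brainstem cylinder
# joins them to the cerebellum so the brain is one connected component
HEMI_RADIUS_MM = 22.0
HEMI_CENTERS = {"left": (-21.0, 6.0, 6.0), "right": (21.0, 6.0, 6.0)}
RIBBON_THICKNESS_MM = 3.0
CEREBELLUM_CENTER = (0.0, -24.0, -16.0)
CEREBELLUM_RADIUS_MM = 9.0
STEM_TOP = (0.0, 6.0, 2.0)
STEM_RADIUS_MM = 5.0
SKULL_GAP_MM = 4.0
SKULL_THICKNESS_MM = 3.0

ANAT_WHITE = 120.0  # T1-like contrast: white matter brighter than gray
ANAT_GRAY = 100.0
ANAT_CEREBELLUM = 110.0
ANAT_SKULL = 20.0
WHITE_UPTAKE = 2.5


def _rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(tag,)))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort and phantom.

    ``n_controls`` defaults to the 23-subject healthy-control template cohort;
    ``control_noise_sd`` is the vertex noise standard deviation as a fraction
    of the local baseline metabolic level; ``lesion_effect`` is the planted
    hypometabolic shift in multiples of the control SD (negative for
    hypometabolism). The seed fully determines all outputs.
    """

    n_controls: int = 23
    n_patients: int = 30
    control_noise_sd: float = 0.05
    lesion_effect: float = -3.0
    lesion_regions: list[tuple[str, str]] | None = None
    mesh_subdivisions: int = 3
    n_regions_per_hemisphere: int = 12
    seed: int = 0
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 1.5
    psf_fwhm_mm: float = 5.0
    reference_uptake: float = 4.0

    def __post_init__(self) -> None:
        if self.n_controls < 2:
            raise ValueError("n_controls must be >= 2")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.control_noise_sd < 0:
            raise ValueError("control_noise_sd must be >= 0")
        if self.mesh_subdivisions < 1:
            raise ValueError("mesh_subdivisions must be >= 1")
        if self.n_regions_per_hemisphere < 1:
            raise ValueError("n_regions_per_hemisphere must be >= 1")


@dataclass
class GroundTruth:
    """Planted truth labels for recovery tests."""

    soz_regions: set = field(default_factory=set)  # {(hemisphere, region name)}
    soz_region_ids: set = field(default_factory=set)
    contact_region_assignments: dict = field(default_factory=dict)
    true_affine: AffineTransform | None = None


@dataclass
class SceneBundle:
    """Phantom volume scene: anatomical/PET pair plus all ground truth."""

    anatomical: VolumeImage
    pet: VolumeImage
    labels: VolumeImage
    cerebellum_mask: VolumeImage
    true_activity: VolumeImage
    brain_mask_truth: VolumeImage
    surfaces: SurfacePair
    parcellation: Parcellation
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# surfaces and parcellations


def _neighbor_smooth(surface: SurfaceModel, values: np.ndarray, iterations: int) -> np.ndarray:
    out = np.asarray(values, dtype=float).copy()
    a = surface.adjacency
    degree = np.asarray(a.sum(axis=1)).ravel()
    for _ in range(iterations):
        out = (out + a @ out) / (1.0 + degree)
    return out


def make_toy_surface(
    mesh_subdivisions: int = 3,
    seed: int = 0,
    hemisphere: str = "left",
    radii: tuple[float, float, float] = (60.0, 80.0, 55.0),
    center: tuple[float, float, float] = (0.0, 0.0, 0.0),
    uniform_thickness: float | None = None,
) -> SurfaceModel:
    """Subdivided icosahedron deformed to an ellipsoid, with analytic normals.

    Vertex count is 10 * 4**n + 2. Thickness is a smooth random field within
    [1.5, 4.5] mm unless ``uniform_thickness`` fixes it.
    """
    if mesh_subdivisions < 1:
        raise ValueError("mesh_subdivisions must be >= 1")
    ico = trimesh.creation.icosphere(subdivisions=mesh_subdivisions, radius=1.0)
    unit = np.asarray(ico.vertices, dtype=float)
    faces = np.asarray(ico.faces, dtype=int)
    radii_arr = np.asarray(radii, dtype=float)
    center_arr = np.asarray(center, dtype=float)
    vertices = unit * radii_arr + center_arr
    # outward normal of the ellipsoid implicit surface sum((x-c)_i^2 / r_i^2) = 1
    normals = unit / radii_arr
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    n = len(vertices)
    if uniform_thickness is not None:
        thickness = np.full(n, float(uniform_thickness))
    else:
        rng = _rng(seed, _TAG_THICKNESS)
        raw = rng.uniform(0.0, 1.0, size=n)
        probe = SurfaceModel(
            vertices=vertices,
            faces=faces,
            normals=normals,
            thickness=np.ones(n),
            hemisphere=hemisphere,
        )
        smooth = _neighbor_smooth(probe, raw, 10)
        lo, hi = smooth.min(), smooth.max()
        span = hi - lo if hi > lo else 1.0
        thickness = 2.0 + 2.0 * (smooth - lo) / span  # in [2.0, 4.0]
    return SurfaceModel(
        vertices=vertices,
        faces=faces,
        normals=normals,
        thickness=thickness,
        hemisphere=hemisphere,
    )


def make_surface_pair(
    mesh_subdivisions: int = 3,
    seed: int = 0,
    radii: tuple[float, float, float] = (HEMI_RADIUS_MM,) * 3,
    uniform_thickness: float | None = RIBBON_THICKNESS_MM,
) -> SurfacePair:
    """Left/right hemisphere pair placed at the phantom head positions."""
    left = make_toy_surface(
        mesh_subdivisions, seed, "left", radii, HEMI_CENTERS["left"], uniform_thickness
    )
    right = make_toy_surface(
        mesh_subdivisions, seed + 1, "right", radii, HEMI_CENTERS["right"], uniform_thickness
    )
    return SurfacePair(left=left, right=right)


def _lobe_quotas(n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n regions to the five lobes."""
    weights = {"frontal": 28, "parietal": 11, "temporal": 14, "occipital": 13, "insular": 8}
    total = sum(weights.values())
    exact = {k: n * w / total for k, w in weights.items()}
    quotas = {k: int(v) for k, v in exact.items()}
    if n >= 5:
        for k in quotas:
            quotas[k] = max(1, quotas[k])
    while sum(quotas.values()) < n:
        k = max(exact, key=lambda k: exact[k] - quotas[k])
        quotas[k] += 1
    while sum(quotas.values()) > n:
        k = max(quotas, key=lambda k: quotas[k] - exact[k])
        if quotas[k] > 1:
            quotas[k] -= 1
        else:
            k2 = max(quotas, key=lambda q: quotas[q])
            quotas[k2] -= 1
    return quotas


def _assign_lobes(centroids: np.ndarray, n: int) -> list[str]:
    """Geometric lobe assignment: anterior regions frontal, posterior occipital,
    the middle band split superior/inferior into parietal/temporal/insular."""
    quotas = _lobe_quotas(n)
    lobes = [""] * n
    by_y = np.argsort(-centroids[:, 1], kind="stable")
    frontal = by_y[: quotas["frontal"]]
    occipital = by_y[n - quotas["occipital"]:] if quotas["occipital"] else np.array([], int)
    middle = by_y[quotas["frontal"]: n - quotas["occipital"]]
    mid_by_z = middle[np.argsort(-centroids[middle, 2], kind="stable")]
    parietal = mid_by_z[: quotas["parietal"]]
    temporal = mid_by_z[len(mid_by_z) - quotas["temporal"]:] if quotas["temporal"] else np.array([], int)
    insular = mid_by_z[quotas["parietal"]: len(mid_by_z) - quotas["temporal"]]
    for idx, lobe in (
        (frontal, "frontal"),
        (parietal, "parietal"),
        (temporal, "temporal"),
        (occipital, "occipital"),
        (insular, "insular"),
    ):
        for i in idx:
            lobes[int(i)] = lobe
    return lobes


def make_parcellation(
    surface: SurfaceModel,
    n_regions: int,
    seed: int = 0,
    region_id_offset: int = 0,
) -> Parcellation:
    """Partition a surface into edge-connected patches by geodesic Voronoi
    growth from random seed vertices, with a region-to-lobe map attached."""
    n = surface.n_vertices
    if not 1 <= n_regions <= n:
        raise ValueError("n_regions must be in [1, vertex count]")
    rng = _rng(seed, _TAG_PARCEL)
    seed_vertices = rng.choice(n, size=n_regions, replace=False)
    e = surface.edges
    w = np.linalg.norm(surface.vertices[e[:, 0]] - surface.vertices[e[:, 1]], axis=1)
    graph = csr_matrix(
        (np.concatenate([w, w]), (np.concatenate([e[:, 0], e[:, 1]]),
                                  np.concatenate([e[:, 1], e[:, 0]]))),
        shape=(n, n),
    )
    dist = csgraph.dijkstra(graph, indices=seed_vertices)
    if not np.all(np.isfinite(dist.min(axis=0))):
        raise RuntimeError("region growing could not cover all vertices (mesh disconnected)")
    nearest = np.argmin(dist, axis=0)
    labels = region_id_offset + 1 + nearest
    centroids = np.stack(
        [surface.vertices[nearest == k].mean(axis=0) for k in range(n_regions)]
    )
    lobes = _assign_lobes(centroids - surface.vertices.mean(axis=0), n_regions)
    table = pd.DataFrame(
        {
            "region_id": region_id_offset + 1 + np.arange(n_regions),
            "hemisphere": surface.hemisphere,
            "name": [f"region_{k + 1:02d}" for k in range(n_regions)],
            "lobe": lobes,
        }
    )
    return Parcellation(labels=labels, region_table=table)


def make_parcellation_pair(
    pair: SurfacePair, n_regions_per_hemisphere: int, seed: int = 0
) -> Parcellation:
    """Parcellate both hemispheres with distinct region ids (left first)."""
    left = make_parcellation(pair.left, n_regions_per_hemisphere, seed, region_id_offset=0)
    right = make_parcellation(
        pair.right, n_regions_per_hemisphere, seed + 1,
        region_id_offset=n_regions_per_hemisphere,
    )
    return Parcellation(
        labels=np.concatenate([left.labels, right.labels]),
        region_table=pd.concat(
            [left.region_table, right.region_table], ignore_index=True
        ),
    )


# ---------------------------------------------------------------------------
# vertex metabolic maps


def regional_means(parcellation: Parcellation, config: SimulationConfig) -> dict[int, float]:
    """Per-region baseline uptake levels (shared by vertex and volume sims)."""
    rng = _rng(config.seed, _TAG_BASELINE)
    ids = parcellation.region_table["region_id"].to_numpy()
    means = rng.uniform(5.0, 7.0, size=len(ids))
    return {int(i): float(m) for i, m in zip(ids, means)}


def control_baseline(
    surfaces: SurfaceModel | SurfacePair,
    parcellation: Parcellation,
    config: SimulationConfig,
) -> np.ndarray:
    """Smooth regional baseline metabolic profile, one value per vertex."""
    means = regional_means(parcellation, config)
    overall = float(np.mean(list(means.values())))
    baseline = np.array([means.get(int(l), overall) for l in parcellation.labels])
    if isinstance(surfaces, SurfacePair):
        lh, rh = surfaces.split(baseline)
        baseline = surfaces.concat(
            _neighbor_smooth(surfaces.left, lh, 5),
            _neighbor_smooth(surfaces.right, rh, 5),
        )
    else:
        baseline = _neighbor_smooth(surfaces, baseline, 5)
    return baseline


def simulate_control_cohort(
    surfaces: SurfaceModel | SurfacePair,
    parcellation: Parcellation,
    config: SimulationConfig,
    n_controls: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[np.ndarray]:
    """Control vertex maps: baseline plus vertex-independent Gaussian noise
    with SD equal to ``control_noise_sd`` times the local baseline."""
    n = config.n_controls if n_controls is None else n_controls
    if n < 2:
        raise ValueError("need at least 2 controls")
    if rng is None:
        rng = _rng(config.seed, _TAG_CONTROLS)
    baseline = control_baseline(surfaces, parcellation, config)
    sd = config.control_noise_sd * baseline
    maps = []
    for _ in range(n):
        values = baseline + sd * rng.standard_normal(len(baseline))
        maps.append(np.maximum(values, 1e-9))
    return maps


def _resolve_region_ids(parcellation: Parcellation, regions) -> set[int]:
    ids = set()
    known = set(int(i) for i in parcellation.region_ids)
    for r in regions:
        rid = parcellation.id_of(*r) if isinstance(r, tuple) else int(r)
        if rid not in known:
            raise KeyError(f"unknown region label: {r}")
        ids.add(rid)
    return ids


def simulate_patient(
    surfaces: SurfaceModel | SurfacePair,
    parcellation: Parcellation,
    soz_regions,
    lesion_effect: float,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Patient vertex map: a control draw with ``lesion_effect`` control-SD
    units added inside the planted regions (negative = hypometabolism)."""
    if rng is None:
        rng = _rng(config.seed, _TAG_PATIENT)
    ids = _resolve_region_ids(parcellation, soz_regions)
    baseline = control_baseline(surfaces, parcellation, config)
    sd = config.control_noise_sd * baseline
    values = baseline + sd * rng.standard_normal(len(baseline))
    lesion = np.isin(parcellation.labels, list(ids))
    values = values + lesion * lesion_effect * sd
    truth = GroundTruth(
        soz_regions={parcellation.key_of(i) for i in ids},
        soz_region_ids=ids,
    )
    return np.maximum(values, 1e-9), truth


# ---------------------------------------------------------------------------
# phantom volume scene


def simulate_volume_scene(
    config: SimulationConfig,
    pair: SurfacePair | None = None,
    parcellation: Parcellation | None = None,
    true_affine: AffineTransform | None = None,
    lesion_region_ids: set[int] | None = None,
    lesion_effect: float = 0.0,
) -> SceneBundle:
    """Phantom head: spherical hemisphere shells with a labeled gray-matter
    ribbon, a white-matter core, a cerebellum of uniform reference uptake and
    a skull shell. The PET volume is the true activity convolved with a
    Gaussian PSF and misaligned from the anatomical grid by a known affine
    (``true_affine`` is the transform that re-aligns PET to the anatomy)."""
    if pair is None:
        pair = make_surface_pair(config.mesh_subdivisions, config.seed)
    if parcellation is None:
        parcellation = make_parcellation_pair(
            pair, config.n_regions_per_hemisphere, config.seed
        )
    if true_affine is None:
        true_affine = AffineTransform.identity()
    if abs(np.linalg.det(true_affine.matrix)) < 1e-12:
        raise ValueError("true_affine must be invertible")

    shape = tuple(config.grid_shape)
    vox = float(config.voxel_size_mm)
    affine = np.diag([vox, vox, vox, 1.0])
    affine[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * vox

    axes = [affine[i, 3] + vox * np.arange(shape[i]) for i in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")

    def radial(center):
        return np.sqrt(
            (gx - center[0]) ** 2 + (gy - center[1]) ** 2 + (gz - center[2]) ** 2
        )

    r_left = radial(HEMI_CENTERS["left"])
    r_right = radial(HEMI_CENTERS["right"])
    r_cereb = radial(CEREBELLUM_CENTER)

    # brainstem: distance to the segment STEM_TOP -> CEREBELLUM_CENTER
    a = np.asarray(STEM_TOP)
    b = np.asarray(CEREBELLUM_CENTER)
    ab = b - a
    px, py, pz = gx - a[0], gy - a[1], gz - a[2]
    t = np.clip((px * ab[0] + py * ab[1] + pz * ab[2]) / (ab @ ab), 0.0, 1.0)
    r_stem = np.sqrt(
        (px - t * ab[0]) ** 2 + (py - t * ab[1]) ** 2 + (pz - t * ab[2]) ** 2
    )

    inner = HEMI_RADIUS_MM - RIBBON_THICKNESS_MM
    gray = ((r_left <= HEMI_RADIUS_MM) & (r_left > inner)) | (
        (r_right <= HEMI_RADIUS_MM) & (r_right > inner)
    )
    white = (r_left <= inner) | (r_right <= inner) | (r_stem <= STEM_RADIUS_MM)
    gray &= ~white
    cereb = r_cereb <= CEREBELLUM_RADIUS_MM
    white &= ~cereb
    brain = gray | white | cereb

    dist_out = np.minimum.reduce(
        [
            np.minimum(r_left, r_right) - HEMI_RADIUS_MM,
            r_cereb - CEREBELLUM_RADIUS_MM,
            r_stem - STEM_RADIUS_MM,
        ]
    )
    skull = (dist_out > SKULL_GAP_MM) & (
        dist_out <= SKULL_GAP_MM + SKULL_THICKNESS_MM
    )

    # gray-matter labels: nearest surface vertex decides the region
    labels = np.zeros(shape, dtype=np.int32)
    labels[white] = WHITE_LABEL
    labels[cereb] = CEREBELLUM_LABEL
    gray_idx = np.argwhere(gray)
    if len(gray_idx):
        pts = gray_idx * vox + affine[:3, 3]
        all_vertices = np.vstack([pair.left.vertices, pair.right.vertices])
        _, nearest = cKDTree(all_vertices).query(pts)
        labels[tuple(gray_idx.T)] = parcellation.labels[nearest]

    rng = _rng(config.seed, _TAG_SCENE)
    anatomical = np.zeros(shape)
    anatomical[white] = ANAT_WHITE
    anatomical[gray] = ANAT_GRAY
    anatomical[cereb] = ANAT_CEREBELLUM
    anatomical[skull] = ANAT_SKULL
    anatomical += rng.normal(0.0, 1.0, size=shape)

    means = regional_means(parcellation, config)
    activity = np.zeros(shape)
    activity[white] = WHITE_UPTAKE
    activity[cereb] = config.reference_uptake
    if len(gray_idx):
        uptake = np.array([means[int(l)] for l in labels[tuple(gray_idx.T)]])
        if lesion_region_ids:
            in_lesion = np.isin(labels[tuple(gray_idx.T)], list(lesion_region_ids))
            uptake = uptake * (1.0 + in_lesion * lesion_effect * config.control_noise_sd)
        activity[tuple(gray_idx.T)] = uptake

    true_activity = VolumeImage(data=activity, affine=affine)
    sigma_vox = config.psf_fwhm_mm * FWHM_TO_SIGMA / vox
    blurred = (
        ndimage.gaussian_filter(activity, sigma=sigma_vox, mode="constant", cval=0.0)
        if config.psf_fwhm_mm > 0
        else activity.copy()
    )
    blurred_vol = VolumeImage(data=blurred, affine=affine)
    if np.allclose(true_affine.matrix, np.eye(4)):
        pet = blurred_vol.with_data(blurred.copy())
    else:
        from .preproc import resample_affine

        pet = resample_affine(blurred_vol, np.linalg.inv(true_affine.matrix))

    truth = GroundTruth(true_affine=true_affine)
    if lesion_region_ids:
        truth.soz_region_ids = set(int(i) for i in lesion_region_ids)
        truth.soz_regions = {parcellation.key_of(i) for i in truth.soz_region_ids}
    return SceneBundle(
        anatomical=VolumeImage(data=anatomical, affine=affine),
        pet=pet,
        labels=VolumeImage(data=labels, affine=affine),
        cerebellum_mask=VolumeImage(data=cereb.astype(np.uint8), affine=affine),
        true_activity=true_activity,
        brain_mask_truth=VolumeImage(data=brain.astype(np.uint8), affine=affine),
        surfaces=pair,
        parcellation=parcellation,
        ground_truth=truth,
    )


# ---------------------------------------------------------------------------
# SEEG contacts


def _cylinder_sample_points(
    center: np.ndarray, axis: np.ndarray, radius: float, half_length: float
) -> np.ndarray:
    """Deterministic dense point grid inside a cylinder (ground-truth footprint)."""
    axis = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    ts = np.linspace(-half_length, half_length, 7)
    pts = [center + t * axis for t in ts]
    for rho in (0.5 * radius, radius * 0.95):
        for ang in np.linspace(0.0, 2 * np.pi, 8, endpoint=False):
            offset = rho * (np.cos(ang) * u + np.sin(ang) * v)
            pts.extend(center + t * axis + offset for t in ts)
    return np.asarray(pts)


def _majority_label(points: np.ndarray, label_volume: VolumeImage) -> int | None:
    vox = np.rint(label_volume.world_to_voxel(points)).astype(int)
    shape = np.asarray(label_volume.shape)
    inside = np.all((vox >= 0) & (vox < shape), axis=1)
    values = np.zeros(len(vox), dtype=int)
    values[inside] = label_volume.data[tuple(vox[inside].T)]
    counts = np.bincount(values)
    winner = int(np.argmax(counts))
    if counts[winner] * 2 <= len(values):
        return None
    return winner


def simulate_contacts(
    scene: SceneBundle,
    n_electrodes: int,
    contacts_per_electrode: int,
    soz_region_ids,
    seed: int = 0,
) -> tuple[ContactTable, GroundTruth]:
    """Straight-line SEEG electrodes targeting cortical regions.

    One electrode per SOZ region first, then electrodes into distinct
    rng-chosen non-SOZ regions. The first contact of each electrode is
    centered mid-ribbon at the target region with the axis along the local
    inward radial direction; subsequent contacts follow at the 3.5 mm
    center-to-center pitch (2 mm length + 1.5 mm gap). Ground-truth region per
    contact is the majority label over a dense point footprint; contacts whose
    true region is a planted SOZ region are flagged as seizure onset.
    """
    if not 5 <= contacts_per_electrode <= 18:
        raise ValueError("contacts_per_electrode must be in [5, 18]")
    parc = scene.parcellation
    soz_ids = sorted(_resolve_region_ids(parc, soz_region_ids))
    rng = _rng(seed, _TAG_CONTACTS)
    non_soz = np.array(sorted(set(int(i) for i in parc.region_ids) - set(soz_ids)))
    n_other = n_electrodes - len(soz_ids)
    if n_other < 0:
        raise ValueError("n_electrodes smaller than the number of SOZ regions")
    if n_other > len(non_soz):
        raise ValueError("not enough non-SOZ regions for the requested electrodes")
    targets = list(soz_ids) + list(rng.choice(non_soz, size=n_other, replace=False))

    centers_by_hemi = {h: np.asarray(c) for h, c in HEMI_CENTERS.items()}
    mid_radius = HEMI_RADIUS_MM - RIBBON_THICKNESS_MM / 2.0
    radius = scene.labels  # label volume grid bounds
    lo = radius.voxel_to_world(np.zeros(3))[0]
    hi = radius.voxel_to_world(np.asarray(radius.shape) - 1)[0]

    rows = []
    assignments: dict[str, int | None] = {}
    for e_idx, rid in enumerate(targets):
        hemi, _ = parc.key_of(int(rid))
        c_h = centers_by_hemi[hemi]
        verts = scene.surfaces.left.vertices if hemi == "left" else scene.surfaces.right.vertices
        local = parc.vertices_of(int(rid))
        offset = 0 if hemi == "left" else scene.surfaces.offset
        region_verts = verts[local - offset]
        centroid = region_verts.mean(axis=0)
        # prefer an entry point whose mid-ribbon voxel actually carries the
        # target label (regions near the interhemispheric overlap can have
        # vertices whose radial line passes through the other hemisphere)
        order = np.argsort(np.linalg.norm(region_verts - centroid, axis=1))
        candidates = [centroid] + [region_verts[i] for i in order]
        shape_arr = np.asarray(scene.labels.shape)
        neighborhood = np.array(
            [[0, 0, 0], [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
        )
        best_u, best_score = None, -1
        for cand in candidates:
            d = cand - c_h
            d = d / np.linalg.norm(d)
            probe = c_h + mid_radius * d
            vox = np.rint(scene.labels.world_to_voxel(probe)[0]).astype(int)
            nb = vox + neighborhood
            ok = np.all((nb >= 0) & (nb < shape_arr), axis=1)
            if not ok[0]:
                continue
            hits = sum(
                int(scene.labels.data[tuple(v)]) == int(rid) for v in nb[ok]
            )
            if hits > best_score:
                best_u, best_score = d, hits
            if hits == len(nb):  # fully interior: done
                break
        u = best_u if best_u is not None else (centroid - c_h) / np.linalg.norm(centroid - c_h)
        start = c_h + mid_radius * u
        axis = -u  # pointing inward along the trajectory
        for k in range(contacts_per_electrode):
            center = start + k * CONTACT_PITCH_MM * axis
            if np.any(center < np.minimum(lo, hi)) or np.any(center > np.maximum(lo, hi)):
                raise ValueError(
                    f"electrode E{e_idx} trajectory exits the volume at contact {k}"
                )
            cid = f"E{e_idx:02d}C{k:02d}"
            pts = _cylinder_sample_points(center, axis, 0.4, CONTACT_LENGTH_MM / 2.0)
            gt_label = _majority_label(pts, scene.labels)
            gt_region = gt_label if gt_label in set(int(i) for i in parc.region_ids) else None
            assignments[cid] = gt_region
            rows.append(
                {
                    "contact_id": cid,
                    "electrode": f"E{e_idx:02d}",
                    "x": center[0],
                    "y": center[1],
                    "z": center[2],
                    "axis_x": axis[0],
                    "axis_y": axis[1],
                    "axis_z": axis[2],
                    "soz_flag": gt_region in soz_ids if gt_region is not None else False,
                }
            )
    table = ContactTable(df=pd.DataFrame(rows))
    truth = GroundTruth(
        soz_regions={parc.key_of(i) for i in soz_ids},
        soz_region_ids=set(soz_ids),
        contact_region_assignments=assignments,
    )
    return table, truth
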