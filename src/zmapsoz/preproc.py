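"""Volume-domain preprocessing: brain masking, smoothing, affine registration
with an NCC quality gate, van Cittert partial-volume correction, and SUVR
conversion.

All spatial parameters are in world millimeters; kernels are scaled per axis
by the voxel size so the same FWHM means the same physical width on any grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .io_formats import VolumeImage

__all__ = [
    "AffineTransform",
    "RegistrationReport",
    "gaussian_smooth_volume",
    "brain_mask",
    "ncc",
    "affine_register",
    "resample_affine",
    "van_cittert_pvc",
    "suvr",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

NCC_GATE_DEFAULT = 0.85


@dataclass
class AffineTransform:
    """12-parameter world-to-world affine transform.

    Parameters: translation (mm), rotation (rad, about x/y/z), scale, shear
    (xy, xz, yz). Rotation, scale and shear act about ``center`` (world mm;
    default the origin) so that the translation parameter stays decoupled
    from them. Composition order is fixed:

        M = T(center) @ T @ Rz @ Ry @ Rx @ Shear @ Scale @ T(-center)

    applied to column vectors of world coordinates.
    """

    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: np.ndarray = field(default_factory=lambda: np.ones(3))
    shear: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        self.shear = np.asarray(self.shear, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        for name, v in (
            ("translation", self.translation),
            ("rotation", self.rotation),
            ("scale", self.scale),
            ("shear", self.shear),
            ("center", self.center),
        ):
            if v.shape != (3,):
                raise ValueError(f"{name} must have 3 components")
        if np.any(self.scale == 0):
            raise ValueError("zero scale makes the transform singular")

    @property
    def matrix(self) -> np.ndarray:
        rx, ry, rz = self.rotation
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        rot_x = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        rot_y = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        rot_z = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        sh = np.array(
            [[1, self.shear[0], self.shear[1]], [0, 1, self.shear[2]], [0, 0, 1]],
            dtype=float,
        )
        lin = rot_z @ rot_y @ rot_x @ sh @ np.diag(self.scale)
        m = np.eye(4)
        m[:3, :3] = lin
        m[:3, 3] = self.translation + self.center - lin @ self.center
        return m

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls()

    @classmethod
    def from_params(
        cls, params: np.ndarray, dof: int = 12, center: np.ndarray | None = None
    ) -> "AffineTransform":
        """Build from a flat parameter vector of length matching ``dof``.

        dof=3: translation only; dof=6: + rotation; dof=9: + scale;
        dof=12: + shear. Omitted blocks take identity values.
        """
        params = np.asarray(params, dtype=float)
        if dof not in (3, 6, 9, 12) or len(params) != dof:
            raise ValueError(f"expected {dof} parameters, got {len(params)}")
        t = params[0:3]
        r = params[3:6] if dof >= 6 else np.zeros(3)
        s = 1.0 + params[6:9] if dof >= 9 else np.ones(3)
        sh = params[9:12] if dof >= 12 else np.zeros(3)
        return cls(
            translation=t, rotation=r, scale=s, shear=sh,
            center=np.zeros(3) if center is None else center,
        )

    def to_params(self, dof: int = 12) -> np.ndarray:
        full = np.concatenate(
            [self.translation, self.rotation, self.scale - 1.0, self.shear]
        )
        return full[:dof]

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        m = self.matrix
        return pts @ m[:3, :3].T + m[:3, 3]

    def inverse_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


@dataclass
class RegistrationReport:
    """Outcome of an affine registration run."""

    final_ncc: float
    passed_gate: bool
    iterations: int
    gate_threshold: float = NCC_GATE_DEFAULT

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.final_ncc <= 1.0 + 1e-9:
            raise ValueError("NCC must lie in [-1, 1]")
        if self.passed_gate != (self.final_ncc > self.gate_threshold):
            raise ValueError("passed_gate inconsistent with NCC and gate threshold")


# ---------------------------------------------------------------------------
# smoothing and masking


def _sigma_voxels(volume: VolumeImage, sigma_mm: float) -> np.ndarray:
    return sigma_mm / volume.voxel_size


def gaussian_smooth_volume(
    volume: VolumeImage,
    fwhm_mm: float | None = None,
    sigma_mm: float | None = None,
) -> VolumeImage:
    """Separable Gaussian smoothing specified in world mm.

    Exactly one of ``fwhm_mm`` / ``sigma_mm`` must be given; FWHM is converted
    via sigma = FWHM/2.3548. Zero width returns an unchanged copy.
    """
    if (fwhm_mm is None) == (sigma_mm is None):
        raise ValueError("give exactly one of fwhm_mm or sigma_mm")
    sig = fwhm_mm * FWHM_TO_SIGMA if fwhm_mm is not None else sigma_mm
    if sig < 0:
        raise ValueError("smoothing width must be >= 0")
    data = volume.data.astype(float)
    if sig == 0:
        return volume.with_data(data.copy())
    smoothed = ndimage.gaussian_filter(
        data, sigma=_sigma_voxels(volume, sig), mode="constant", cval=0.0
    )
    return volume.with_data(smoothed)


def brain_mask(
    anatomical: VolumeImage,
    intensity_coefficient: float = 0.4,
    sigma_mm: float = 2.0,
) -> VolumeImage:
    """Adaptive-threshold skull stripping.

    Smooth with ``sigma_mm``, threshold at ``intensity_coefficient`` times the
    robust maximum (99th percentile of the smoothed volume), keep the largest
    connected component, and fill interior holes.
    """
    data = anatomical.data.astype(float)
    if np.ptp(data) == 0:
        raise ValueError("constant volume: no threshold definable")
    smoothed = gaussian_smooth_volume(anatomical, sigma_mm=sigma_mm).data
    threshold = intensity_coefficient * np.percentile(smoothed, 99)
    mask = smoothed > threshold
    if mask.any():
        labeled, n = ndimage.label(mask)
        if n > 1:
            counts = np.bincount(labeled.ravel())
            counts[0] = 0
            mask = labeled == np.argmax(counts)
        mask = ndimage.binary_fill_holes(mask)
    return VolumeImage(data=mask.astype(np.uint8), affine=anatomical.affine.copy())


# ---------------------------------------------------------------------------
# similarity and registration


def ncc(a: VolumeImage, b: VolumeImage, mask: np.ndarray | None = None) -> float:
    """Normalized cross-correlation (Pearson r) of two volumes under a mask."""
    if a.data.shape != b.data.shape:
        raise ValueError("volumes must share a grid shape")
    x = a.data.astype(float)
    y = b.data.astype(float)
    if mask is not None:
        m = mask.data if isinstance(mask, VolumeImage) else np.asarray(mask)
        m = m.astype(bool)
        if m.sum() < 2:
            raise ValueError("mask must cover at least 2 voxels")
        x = x[m]
        y = y[m]
    else:
        x = x.ravel()
        y = y.ravel()
    x = x - x.mean()
    y = y - y.mean()
    sx = np.sqrt(np.sum(x * x))
    sy = np.sqrt(np.sum(y * y))
    if sx == 0 or sy == 0:
        raise ValueError("zero intensity variance under the mask")
    return float(np.clip(np.sum(x * y) / (sx * sy), -1.0, 1.0))


def resample_affine(
    volume: VolumeImage,
    transform: AffineTransform | np.ndarray,
    target: VolumeImage | tuple[tuple[int, int, int], np.ndarray] | None = None,
    interpolation: str = "trilinear",
) -> VolumeImage:
    """Pull-resample a volume through a world-to-world transform.

    ``transform`` is an :class:`AffineTransform` or a raw 4x4 matrix. The
    output voxel at index i takes the value of the input volume at world
    point ``transform(target_affine @ i)``. ``interpolation`` is "trilinear"
    for intensities or "nearest" for label volumes; resampling an integer
    label volume with trilinear interpolation is refused. Out-of-field voxels
    are set to 0.
    """
    if interpolation not in ("trilinear", "nearest"):
        raise ValueError("interpolation must be 'trilinear' or 'nearest'")
    if interpolation == "trilinear" and volume.is_label_volume():
        raise ValueError(
            "label volume must be resampled with interpolation='nearest'"
        )
    if target is None:
        target_shape, target_affine = volume.shape, volume.affine
    elif isinstance(target, VolumeImage):
        target_shape, target_affine = target.shape, target.affine
    else:
        target_shape, target_affine = target
        target_affine = np.asarray(target_affine, dtype=float)
    t_matrix = transform.matrix if isinstance(transform, AffineTransform) else np.asarray(transform, dtype=float)
    if t_matrix.shape != (4, 4) or abs(np.linalg.det(t_matrix)) < 1e-12:
        raise ValueError("transform must be an invertible 4x4 affine")
    # voxel(out) -> world(out) -> transform -> world(in) -> voxel(in)
    m = np.linalg.inv(volume.affine) @ t_matrix @ target_affine
    order = 1 if interpolation == "trilinear" else 0
    out = ndimage.affine_transform(
        volume.data.astype(float) if order else volume.data,
        matrix=m[:3, :3],
        offset=m[:3, 3],
        output_shape=tuple(target_shape),
        order=order,
        mode="constant",
        cval=0,
    )
    return VolumeImage(data=out, affine=np.asarray(target_affine).copy())


def _downsample(volume: VolumeImage, factor: int = 2) -> VolumeImage:
    """Antialiased decimation by an integer factor (pyramid level)."""
    smoothed = ndimage.gaussian_filter(
        volume.data.astype(float), sigma=(factor - 1) * 0.6, mode="nearest"
    )
    data = smoothed[::factor, ::factor, ::factor]
    affine = volume.affine.copy()
    affine[:3, :3] *= factor
    return VolumeImage(data=data, affine=affine)


def _foreground_mask(volume: VolumeImage) -> np.ndarray:
    thr = 0.05 * np.percentile(volume.data, 99)
    mask = volume.data > thr
    # keep a margin of background so translations change the overlap
    return ndimage.binary_dilation(mask, iterations=2)


def affine_register(
    moving: VolumeImage,
    fixed: VolumeImage,
    dof: int = 12,
    gate_threshold: float = NCC_GATE_DEFAULT,
    n_starts: int = 3,
    seed: int = 0,
) -> tuple[AffineTransform, RegistrationReport]:
    """Intensity-based affine registration maximizing NCC.

    Derivative-free multi-start Nelder-Mead over the transform parameters on
    a two-level pyramid (coarse then full resolution), translation first and
    then the full requested degrees of freedom. ``dof=6`` gives rigid-only
    registration. The report carries the NCC gate outcome; a failed gate is
    reported, never silently passed.
    """
    if dof not in (6, 9, 12):
        raise ValueError("dof must be 6, 9, or 12")
    rng = np.random.default_rng(seed)
    levels = [(_downsample(moving), _downsample(fixed)), (moving, fixed)]
    masks = [_foreground_mask(f) for _, f in levels]
    # rotation/scale/shear act about the fixed-image foreground centroid so
    # the translation parameters are not contaminated by scaling about a
    # distant point
    center = fixed.voxel_to_world(
        np.asarray(ndimage.center_of_mass(masks[1].astype(float)))
    )[0]
    total_iter = 0

    def objective(params: np.ndarray, dof_stage: int, level: int) -> float:
        nonlocal total_iter
        total_iter += 1
        t = AffineTransform.from_params(params, dof=dof_stage, center=center)
        mov, fix = levels[level]
        resampled = resample_affine(mov, t, target=fix)
        try:
            return -ncc(resampled, fix, mask=masks[level])
        except ValueError:
            return 1.0

    def simplex(x0: np.ndarray, dof_stage: int) -> np.ndarray:
        steps = np.concatenate(
            [np.full(3, 2.0), np.full(3, 0.05), np.full(3, 0.02), np.full(3, 0.02)]
        )[:dof_stage]
        s = np.tile(x0, (dof_stage + 1, 1))
        for k in range(dof_stage):
            s[k + 1, k] += steps[k]
        return s

    def solve(x0: np.ndarray, dof_stage: int, level: int, maxiter: int) -> np.ndarray:
        res = optimize.minimize(
            objective,
            x0,
            args=(dof_stage, level),
            method="Nelder-Mead",
            options={
                "initial_simplex": simplex(x0, dof_stage),
                "maxiter": maxiter,
                "xatol": 0.01,
                "fatol": 1e-6,
            },
        )
        return res.x

    # stage 1: translation-only, coarse level, multi-start
    starts = [np.zeros(3)]
    for _ in range(max(0, n_starts - 1)):
        starts.append(rng.uniform(-8.0, 8.0, size=3))
    best_t, best_val = None, np.inf
    for s0 in starts:
        x = solve(s0, 3, 0, maxiter=150)
        v = objective(x, 3, 0)
        if v < best_val:
            best_t, best_val = x, v
    # stage 2: full dof, coarse level
    x0 = np.zeros(dof)
    x0[:3] = best_t
    x = solve(x0, dof, 0, maxiter=400 * dof // 6)
    # stage 3: full dof, full resolution refine
    x = solve(x, dof, 1, maxiter=200 * dof // 6)

    transform = AffineTransform.from_params(x, dof=dof, center=center)
    resampled = resample_affine(moving, transform, target=fixed)
    final = ncc(resampled, fixed, mask=masks[1])
    report = RegistrationReport(
        final_ncc=final,
        passed_gate=final > gate_threshold,
        iterations=total_iter,
        gate_threshold=gate_threshold,
    )
    if not report.passed_gate:
        warnings.warn(
            f"registration NCC {final:.3f} below gate {gate_threshold}", stacklevel=2
        )
    return transform, report


# ---------------------------------------------------------------------------
# partial volume correction and SUVR


def van_cittert_pvc(
    pet: VolumeImage,
    psf_fwhm_mm: float = 5.0,
    alpha: float = 1.0,
    n_iter: int = 10,
) -> VolumeImage:
    """van Cittert iterative deconvolution for partial volume correction.

    Fixed-point iteration f_{k+1} = f_k + alpha * (g - h (*) f_k) starting at
    f_0 = g, with h an isotropic Gaussian PSF of the given FWHM. Negative
    values are clamped to zero after each step. If the residual norm grows on
    two consecutive iterations the loop stops early with a warning.
    """
    if psf_fwhm_mm < 0:
        raise ValueError("psf_fwhm_mm must be >= 0")
    if not 0 < alpha <= 2:
        raise ValueError("alpha must be in (0, 2]")
    if n_iter < 0:
        raise ValueError("n_iter must be >= 0")
    g = pet.data.astype(float)
    f = g.copy()
    if n_iter == 0 or psf_fwhm_mm == 0:
        return pet.with_data(f)
    sigma_vox = _sigma_voxels(pet, psf_fwhm_mm * FWHM_TO_SIGMA)
    prev_norm = np.inf
    grow_streak = 0
    for _ in range(n_iter):
        blurred = ndimage.gaussian_filter(f, sigma=sigma_vox, mode="constant", cval=0.0)
        residual = g - blurred
        rnorm = float(np.linalg.norm(residual))
        if rnorm > prev_norm:
            grow_streak += 1
            if grow_streak >= 2:
                warnings.warn(
                    "van Cittert residual grew on 2 consecutive iterations; "
                    "stopping early",
                    stacklevel=2,
                )
                break
        else:
            grow_streak = 0
        prev_norm = rnorm
        f = np.maximum(f + alpha * residual, 0.0)
    return pet.with_data(f)


def suvr(pet: VolumeImage, reference_mask: VolumeImage | np.ndarray) -> VolumeImage:
    """Standardized uptake value ratio against a reference region.

    Every voxel is divided by the mean PET intensity inside the reference
    mask (the cerebellum in the intended use).
    """
    m = reference_mask.data if isinstance(reference_mask, VolumeImage) else reference_mask
    m = np.asarray(m).astype(bool)
    if m.shape != pet.data.shape:
        raise ValueError("reference mask shape must match the PET grid")
    if not m.any():
        raise ValueError("reference mask is empty")
    ref_mean = float(pet.data[m].mean())
    if ref_mean <= 0:
        raise ValueError(f"non-positive reference mean ({ref_mean})")
    return pet.with_data(pet.data.astype(float) / ref_mean)
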