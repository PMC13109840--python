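"""Vertex-wise Z-score mapping against a healthy-control template.

The template stores the per-vertex mean and sample standard deviation of
globally mean-normalized control metabolic maps; a patient map normalized the
same way yields Z = (value - mean) / SD per vertex. The most hypometabolic
cortex is the fixed lowest fraction of usable vertices (default 0.5 %), and a
region is called hypometabolic if at least one selected vertex carries its
parcellation label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .surface import Parcellation

__all__ = [
    "ControlTemplate",
    "ZMap",
    "HypometabolicSet",
    "global_mean_normalize",
    "build_template",
    "compute_zmap",
    "select_hypometabolic",
    "vertices_to_regions",
    "threshold_overlay",
]

DEFAULT_FRACTION = 0.005
SD_FLOOR_REL = 1e-6  # of the template mean scale; below this a vertex is unusable


def _as_array(values) -> np.ndarray:
    a = np.asarray(getattr(values, "values", values), dtype=float)
    if a.ndim != 1:
        raise ValueError("vertex map must be 1-D")
    return a


def global_mean_normalize(map_values, cortex_mask: np.ndarray | None = None) -> np.ndarray:
    """Divide a vertex map by its mean over the cortex mask.

    Removes intersubject global metabolic scale: the output is invariant to
    multiplicative rescaling of the input, and its mask mean is exactly 1.
    """
    values = _as_array(map_values)
    mask = np.ones(len(values), dtype=bool) if cortex_mask is None else np.asarray(cortex_mask, dtype=bool)
    if mask.shape != values.shape:
        raise ValueError("cortex mask length must match the map")
    if not mask.any():
        raise ValueError("empty cortex mask")
    mean = np.nanmean(values[mask])
    if not np.isfinite(mean) or mean <= 0:
        raise ValueError(f"non-positive cortex mean ({mean}); cannot normalize")
    return values / mean


@dataclass
class ControlTemplate:
    """Per-vertex mean and sample SD (n-1 denominator) of control maps."""

    mean: np.ndarray
    sd: np.ndarray
    n_controls: int
    normalization: str = "global-mean"

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != self.sd.shape or self.mean.ndim != 1:
            raise ValueError("mean and sd must be 1-D arrays of equal length")
        if self.n_controls < 2:
            raise ValueError("template requires at least 2 controls")
        if np.any(self.sd < 0):
            raise ValueError("sd must be non-negative")

    @property
    def sd_floor(self) -> float:
        scale = float(np.nanmean(np.abs(self.mean)))
        return SD_FLOOR_REL * (scale if scale > 0 else 1.0)

    @property
    def usable(self) -> np.ndarray:
        """Vertices where the template SD supports a finite Z-score."""
        return self.sd > self.sd_floor

    @property
    def n_vertices(self) -> int:
        return len(self.mean)


def build_template(control_maps) -> ControlTemplate:
    """Per-vertex sample mean and SD over >= 2 normalized control maps."""
    maps = [np.asarray(getattr(m, "values", m), dtype=float) for m in control_maps]
    if len(maps) < 2:
        raise ValueError("need at least 2 control maps")
    lengths = {len(m) for m in maps}
    if len(lengths) != 1:
        raise ValueError(f"control maps disagree on vertex count: {sorted(lengths)}")
    stack = np.vstack(maps)
    return ControlTemplate(
        mean=stack.mean(axis=0),
        sd=stack.std(axis=0, ddof=1),
        n_controls=len(maps),
    )


@dataclass
class ZMap:
    """Vertex-wise Z-scores of one patient against a control template.

    NaN marks vertices the template flags unusable (degenerate SD).
    """

    z: np.ndarray
    template: ControlTemplate
    patient_id: str = "patient"

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if len(self.z) != self.template.n_vertices:
            raise ValueError("z length must match the template")

    @property
    def usable(self) -> np.ndarray:
        return np.isfinite(self.z)


def compute_zmap(patient_map, template: ControlTemplate, patient_id: str = "patient") -> ZMap:
    """Z = (patient value - control mean) / control SD, per vertex.

    The patient map must be normalized identically to the controls that built
    the template. Degenerate-SD vertices are NaN-flagged, never infinite.
    """
    values = _as_array(patient_map)
    if len(values) != template.n_vertices:
        raise ValueError(
            f"patient map has {len(values)} vertices, template has {template.n_vertices}"
        )
    z = np.full(template.n_vertices, np.nan)
    ok = template.usable & np.isfinite(values)
    z[ok] = (values[ok] - template.mean[ok]) / template.sd[ok]
    return ZMap(z=z, template=template, patient_id=patient_id)


@dataclass
class HypometabolicSet:
    """The selected lowest-Z vertices and the regions they touch."""

    vertex_ids: np.ndarray
    fraction: float = DEFAULT_FRACTION
    regions: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.vertex_ids = np.asarray(self.vertex_ids, dtype=int)


def select_hypometabolic(zmap: ZMap | np.ndarray, fraction: float = DEFAULT_FRACTION) -> HypometabolicSet:
    """Select the lowest-Z fraction of usable vertices.

    The count is max(1, floor(fraction * usable vertex count)); missing (NaN)
    vertices are excluded from both the candidate set and the denominator.
    Ties at the cutoff break toward the lower vertex index.
    """
    z = zmap.z if isinstance(zmap, ZMap) else np.asarray(zmap, dtype=float)
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    usable = np.flatnonzero(np.isfinite(z))
    if len(usable) == 0:
        raise ValueError("no usable vertices")
    k = max(1, int(np.floor(fraction * len(usable))))
    order = usable[np.argsort(z[usable], kind="stable")]
    return HypometabolicSet(vertex_ids=np.sort(order[:k]), fraction=fraction)


def vertices_to_regions(vertex_set, parcellation: Parcellation) -> set:
    """Regions touched by the selected vertices, hemispheres kept distinct.

    A region is hypometabolic iff at least one selected vertex carries its
    label. Unlabeled vertices are excluded with a warning.
    """
    ids = vertex_set.vertex_ids if isinstance(vertex_set, HypometabolicSet) else np.asarray(vertex_set, dtype=int)
    if len(ids) == 0:
        return set()
    labels = parcellation.labels[ids]
    if np.any(labels == 0):
        warnings.warn(
            f"{int((labels == 0).sum())} selected vertices are unlabeled and excluded",
            stacklevel=2,
        )
    regions = {parcellation.key_of(int(l)) for l in np.unique(labels) if l != 0}
    if isinstance(vertex_set, HypometabolicSet):
        vertex_set.regions = regions
    return regions


def threshold_overlay(zmap: ZMap | np.ndarray, z_threshold: float) -> np.ndarray:
    """Vertices with Z strictly below a display threshold (overlay export)."""
    z = zmap.z if isinstance(zmap, ZMap) else np.asarray(zmap, dtype=float)
    if not np.isfinite(z_threshold):
        if z_threshold > 0:  # +inf: every usable vertex
            return np.flatnonzero(np.isfinite(z))
        raise ValueError("z_threshold must be finite or +inf")
    return np.flatnonzero(np.isfinite(z) & (z < z_threshold))
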