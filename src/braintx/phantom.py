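"""Synthetic labelled brain geometry on a regular voxel grid.

The simulator runs on a three-region phantom — a spherical brain containing a
central ventricle cavity and a superficially placed spherical tumour — whose
region volumes are calibrated to the glioma case the model parameters describe
(tumour 2.47e-5 m³, surrounding normal tissue 1.39e-3 m³). Spheres are the
simplest geometry matching those printed volumes; radii are derived
analytically from the volume targets so the voxelized phantom reproduces them
to well under a percent at 1 mm spacing.

Coordinates are voxel-centred, 0-based, with the physical origin at the brain
centre. Faces are identified by (voxel index, axis, side).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy import ndimage

from . import params as _p


class Region(IntEnum):
    """Voxel labels. Values are stable and used in exported label volumes."""

    EXTERIOR = 0
    NORMAL = 1
    TUMOUR = 2
    VENTRICLE = 3


class GeometryError(ValueError):
    """Raised when a phantom specification is geometrically infeasible."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric specification of the spherical brain phantom.

    All lengths in metres. ``tumour_center_offset`` is the distance of the
    tumour centre from the brain centre, directed toward the brain surface
    (along +x), making the tumour superficial.
    """

    brain_radius: float
    ventricle_radius: float
    tumour_radius: float
    tumour_center_offset: float
    voxel_spacing: float = 2.0e-3
    target_tumour_volume: float = _p.GEOMETRY["tumour_volume_m3"]
    target_normal_volume: float = _p.GEOMETRY["normal_volume_m3"]

    def __post_init__(self) -> None:
        for name in ("brain_radius", "ventricle_radius", "tumour_radius",
                     "voxel_spacing"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if self.tumour_center_offset < 0:
            raise GeometryError("tumour_center_offset must be nonnegative")
        h = self.voxel_spacing
        if self.tumour_center_offset + self.tumour_radius >= self.brain_radius - h:
            raise GeometryError(
                "tumour does not fit strictly inside the brain "
                f"(offset {self.tumour_center_offset:g} + radius "
                f"{self.tumour_radius:g} vs brain radius {self.brain_radius:g})")
        if self.tumour_center_offset - self.tumour_radius <= self.ventricle_radius + h:
            raise GeometryError("tumour overlaps the ventricle")
        if self.ventricle_radius >= self.brain_radius:
            raise GeometryError("ventricle larger than brain")

    @classmethod
    def default(cls, voxel_spacing: float = 2.0e-3,
                tumour_offset_fraction: float | None = None) -> "PhantomSpec":
        """Spec whose sphere radii are derived from the target region volumes.

        The brain radius is chosen so that (brain - ventricle - tumour) equals
        the normal-tissue volume target, and the tumour radius matches the
        tumour volume target exactly.
        """
        g = _p.GEOMETRY
        r_t = _p.sphere_radius_for_volume(g["tumour_volume_m3"])
        r_v = g["ventricle_radius_m"]
        v_total = (g["normal_volume_m3"] + g["tumour_volume_m3"]
                   + 4.0 / 3.0 * math.pi * r_v**3)
        r_b = _p.sphere_radius_for_volume(v_total)
        frac = (g["tumour_offset_fraction"] if tumour_offset_fraction is None
                else tumour_offset_fraction)
        return cls(brain_radius=r_b, ventricle_radius=r_v, tumour_radius=r_t,
                   tumour_center_offset=frac * r_b, voxel_spacing=voxel_spacing)


@dataclass
class VoxelPhantom:
    """Labelled voxel volume with region bookkeeping.

    ``labels`` partitions the grid into :class:`Region` values.
    ``surface_faces``/``ventricle_faces`` list the Dirichlet faces of the flow
    problem as integer arrays of (i, j, k, axis, side) rows, where (i, j, k)
    indexes the interior (NORMAL/TUMOUR) voxel owning the face and side is 0
    for the low, 1 for the high end of the axis.
    """

    spacing: float
    labels: np.ndarray
    spec: PhantomSpec | None = None
    surface_faces: np.ndarray = field(init=False, repr=False)
    ventricle_faces: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int8)
        self.surface_faces = self._boundary_faces(Region.EXTERIOR)
        self.ventricle_faces = self._boundary_faces(Region.VENTRICLE)

    # -- geometry queries ---------------------------------------------------
    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        return self.spacing**3

    def mask(self, region: Region) -> np.ndarray:
        return self.labels == int(region)

    @property
    def interior_mask(self) -> np.ndarray:
        """Voxels carrying tissue (NORMAL or TUMOUR)."""
        return (self.labels == int(Region.NORMAL)) | (self.labels == int(Region.TUMOUR))

    @property
    def region_volumes(self) -> dict[Region, float]:
        return {r: self.region_volume(r) for r in Region}

    def region_volume(self, region: Region | int | str) -> float:
        """Volume (m³) of one labelled region: voxel count x spacing³."""
        region = _coerce_region(region)
        return float(np.count_nonzero(self.labels == int(region))) * self.voxel_volume

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical voxel-centre coordinate axes (origin at brain centre)."""
        h = self.spacing
        return tuple((np.arange(n) + 0.5) * h - n * h / 2.0
                     for n in self.labels.shape)  # type: ignore[return-value]

    # -- internals ----------------------------------------------------------
    def _boundary_faces(self, outside: Region) -> np.ndarray:
        rows = []
        inner = self.interior_mask
        out = self.labels == int(outside)
        for axis in range(3):
            for side, shift in ((0, 1), (1, -1)):
                nb = np.roll(out, shift, axis=axis)
                # roll wraps around; faces at the array border are not
                # adjacent to anything, and the phantom keeps a margin anyway
                sl = [slice(None)] * 3
                sl[axis] = slice(0, 1) if side == 0 else slice(-1, None)
                nb[tuple(sl)] = False
                ijk = np.argwhere(inner & nb)
                if len(ijk):
                    extra = np.full((len(ijk), 2), (axis, side), dtype=ijk.dtype)
                    rows.append(np.hstack([ijk, extra]))
        if not rows:
            return np.empty((0, 5), dtype=np.int64)
        return np.vstack(rows).astype(np.int64)


def _coerce_region(region: Region | int | str) -> Region:
    if isinstance(region, Region):
        return region
    if isinstance(region, str):
        try:
            return Region[region.upper()]
        except KeyError:
            raise ValueError(f"unknown region label {region!r}") from None
    try:
        return Region(int(region))
    except ValueError:
        raise ValueError(f"unknown region label {region!r}") from None


def region_volume(phantom: VoxelPhantom, region: Region | int | str) -> float:
    """Volume (m³) of ``region`` in ``phantom`` (voxel count x spacing³)."""
    return phantom.region_volume(region)


def build_phantom(spec: PhantomSpec) -> VoxelPhantom:
    """Voxelize the spherical brain/ventricle/tumour phantom.

    Labels are assigned by voxel-centre membership: ventricle and tumour take
    precedence over brain tissue; everything outside the brain sphere is
    EXTERIOR. The construction is deterministic for a fixed spec.

    Raises
    ------
    GeometryError
        If the spec is infeasible, or the voxelized tumour is not a single
        connected component strictly inside the brain.
    """
    h = spec.voxel_spacing
    half = spec.brain_radius + 2.0 * h
    n = int(math.ceil(2.0 * half / h))
    coords = (np.arange(n) + 0.5) * h - n * h / 2.0
    x, y, z = np.meshgrid(coords, coords, coords, indexing="ij", sparse=True)

    r2_brain = x**2 + y**2 + z**2
    labels = np.where(r2_brain < spec.brain_radius**2,
                      int(Region.NORMAL), int(Region.EXTERIOR)).astype(np.int8)
    labels[r2_brain < spec.ventricle_radius**2] = int(Region.VENTRICLE)
    r2_tum = (x - spec.tumour_center_offset)**2 + y**2 + z**2
    tumour = r2_tum < spec.tumour_radius**2
    if np.any(tumour & (labels != int(Region.NORMAL))):
        raise GeometryError("tumour voxels overlap ventricle or exterior")
    labels[tumour] = int(Region.TUMOUR)

    # tumour must be one connected component, not touching the brain surface
    n_comp = ndimage.label(tumour)[1]
    if n_comp != 1:
        raise GeometryError(f"tumour voxelized into {n_comp} components")
    dilated = ndimage.binary_dilation(tumour)
    if np.any(dilated & (labels == int(Region.EXTERIOR))):
        raise GeometryError("tumour touches the brain surface")

    return VoxelPhantom(spacing=h, labels=labels, spec=spec)


def uniform_box_phantom(shape: tuple[int, int, int], spacing: float,
                        region: Region = Region.TUMOUR) -> VoxelPhantom:
    """Rectangular single-region phantom wrapped in one EXTERIOR voxel layer.

    A verification geometry: used for analytic diffusion/advection checks and
    manufactured-solution convergence studies where spherical boundaries would
    obscure the discretisation error.
    """
    labels = np.full(tuple(s + 2 for s in shape), int(Region.EXTERIOR),
                     dtype=np.int8)
    labels[1:-1, 1:-1, 1:-1] = int(region)
    return VoxelPhantom(spacing=spacing, labels=labels)
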