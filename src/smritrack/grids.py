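"""Grid geometry and the in-memory volume containers.

All volumes in a patient series live on one common grid after ingestion.
Physical coordinates are millimetres in an RAS-like axis convention:
``world = origin_mm + index * spacing_mm`` (axis-aligned affine, no shear).
Volumes are reported in cc, distances in mm.

Metabolite maps carry an explicit boolean *coverage* lattice alongside the
scalar field: spectroscopic acquisitions do not cover the whole head, and
downstream coverage matching needs an unambiguous "no data here" notion
rather than a sentinel value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
from scipy import ndimage

from .errors import GridMismatchError

Metabolite = Literal["CHO", "NAA", "CHO_NAA_RATIO"]
MaskLabel = Literal["CHO_NAA_2X", "FLAIR", "NAWM", "T1CE", "GROUND_TRUTH", "BRAIN"]

_GEOM_ATOL = 1e-6


@dataclass(frozen=True)
class GridGeometry:
    """Shape, spacing and origin of a regular 3D voxel lattice.

    Parameters
    ----------
    shape
        Number of voxels along each axis.
    spacing_mm
        Voxel edge lengths in mm; strictly positive.
    origin_mm
        World coordinate of the centre of voxel (0, 0, 0).
    orientation
        Axis-orientation convention identifier (informational).
    """

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing_mm}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(s) for s in self.origin_mm))

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (diagonal, no shear)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing_mm)
        aff[:3, 3] = self.origin_mm
        return aff

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """Map an (n, 3) array of voxel indices to world mm coordinates."""
        idx = np.asarray(indices, dtype=float)
        return idx * np.asarray(self.spacing_mm) + np.asarray(self.origin_mm)

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World-mm coordinate arrays (broadcastable) along each axis."""
        axes = [
            self.origin_mm[a] + np.arange(self.shape[a]) * self.spacing_mm[a]
            for a in range(3)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij", sparse=True))

    def matches(self, other: "GridGeometry") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=_GEOM_ATOL)
            and np.allclose(self.origin_mm, other.origin_mm, atol=_GEOM_ATOL)
        )


def require_same_grid(*geoms: GridGeometry) -> None:
    first = geoms[0]
    for g in geoms[1:]:
        if not first.matches(g):
            raise GridMismatchError(
                f"volumes do not share a grid: {first} vs {g}"
            )


@dataclass
class MetaboliteMap:
    """One metabolite quantity on a grid, with explicit coverage.

    ``values`` are finite wherever ``coverage`` is True; outside coverage
    they are undefined (stored as NaN by convention).
    """

    metabolite: Metabolite
    values: np.ndarray
    coverage: np.ndarray
    geometry: GridGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.coverage = np.asarray(self.coverage, dtype=bool)
        if self.values.shape != self.geometry.shape:
            raise ValueError("values shape does not match geometry")
        if self.coverage.shape != self.geometry.shape:
            raise ValueError("coverage shape does not match geometry")
        if not np.all(np.isfinite(self.values[self.coverage])):
            raise ValueError("non-finite metabolite values inside coverage")

    def restricted(self, keep: np.ndarray) -> "MetaboliteMap":
        """Copy with coverage intersected with ``keep`` (values untouched)."""
        new_cov = self.coverage & keep
        vals = self.values.copy()
        vals[~new_cov] = np.nan
        return MetaboliteMap(self.metabolite, vals, new_cov, self.geometry)


@dataclass
class BinaryMask:
    """Labelled 0/1 lattice sharing the series grid."""

    label: MaskLabel
    values: np.ndarray
    geometry: GridGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != self.geometry.shape:
            raise ValueError("mask shape does not match geometry")

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def is_empty(self) -> bool:
        return not self.values.any()


def volume_cc(mask: BinaryMask) -> float:
    """Mask volume: true-voxel count times voxel volume, in cc (1 cc = 1000 mm^3)."""
    return mask.n_voxels * mask.geometry.voxel_volume_mm3 / 1000.0


def voxel_volume_ul(fov_mm: Iterable[float], matrix_size: Iterable[int]) -> float:
    """Nominal voxel volume in microlitres for a field of view and matrix.

    1 mm^3 = 1 µL, so this is simply the product of FOV/matrix edge lengths.
    """
    fov = np.asarray(list(fov_mm), dtype=float)
    mat = np.asarray(list(matrix_size), dtype=float)
    if fov.shape != (3,) or mat.shape != (3,):
        raise ValueError("fov_mm and matrix_size must each have 3 entries")
    return float(np.prod(fov / mat))


def _world_to_source_indices(target: GridGeometry, source: GridGeometry) -> np.ndarray:
    """Coordinates of every target voxel expressed in source voxel indices,
    shaped (3, *target.shape), for scipy.ndimage.map_coordinates."""
    grids = np.meshgrid(
        *[np.arange(n, dtype=float) for n in target.shape], indexing="ij"
    )
    coords = np.empty((3,) + tuple(target.shape))
    for a in range(3):
        world = target.origin_mm[a] + grids[a] * target.spacing_mm[a]
        coords[a] = (world - source.origin_mm[a]) / source.spacing_mm[a]
    return coords


def resample_to_grid(
    volume: MetaboliteMap | BinaryMask, target: GridGeometry
) -> MetaboliteMap | BinaryMask:
    """Resample a map or mask onto ``target``.

    Masks go through nearest-neighbour so they stay binary.  Metabolite
    values are trilinearly interpolated, and any target voxel whose
    interpolation stencil touches an uncovered or out-of-grid source voxel
    is excluded from the output coverage (no data is invented at coverage
    edges).
    """
    source = volume.geometry
    if source.matches(target):
        return volume

    # require some spatial overlap between the two grids
    def _extent(g: GridGeometry) -> tuple[np.ndarray, np.ndarray]:
        lo = np.asarray(g.origin_mm) - np.asarray(g.spacing_mm) / 2
        hi = lo + np.asarray(g.shape) * np.asarray(g.spacing_mm)
        return lo, hi

    s_lo, s_hi = _extent(source)
    t_lo, t_hi = _extent(target)
    if np.any(np.maximum(s_lo, t_lo) >= np.minimum(s_hi, t_hi)):
        raise GridMismatchError("no spatial overlap between source and target grids")

    coords = _world_to_source_indices(target, source)

    if isinstance(volume, BinaryMask):
        out = ndimage.map_coordinates(
            volume.values.astype(np.float32), coords, order=0, cval=0.0
        )
        return BinaryMask(volume.label, out > 0.5, target)

    filled = np.where(volume.coverage, volume.values, 0.0)
    vals = ndimage.map_coordinates(filled, coords, order=1, cval=0.0)
    cov_w = ndimage.map_coordinates(
        volume.coverage.astype(np.float64), coords, order=1, cval=0.0
    )
    cov = cov_w > 1.0 - 1e-9  # full stencil inside source coverage
    vals[~cov] = np.nan
    return MetaboliteMap(volume.metabolite, vals, cov, target)
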