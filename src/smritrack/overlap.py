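"""Dice and Hausdorff overlap between binary masks, and the pre-RT vs
post-RT battery.

The Hausdorff distance is the full (100th percentile) symmetric
boundary-to-boundary distance: the larger of the two directed values
max over one boundary of the distance to the nearest point of the other.
Boundary voxels are mask voxels with at least one face-adjacent
(6-connectivity) non-mask or out-of-grid neighbour; distances are
Euclidean between voxel centres, in mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import EmptyMaskError
from .grids import BinaryMask, require_same_grid

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass(frozen=True)
class OverlapMetrics:
    """One pre/post overlap record for one mask family."""

    pair: tuple[str, str]
    mask_family: str
    dsc: float | None
    hd_mm: float | None
    n_ref_voxels: int
    n_cmp_voxels: int
    flags: tuple[str, ...] = ()


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|).

    Both masks empty is treated as perfect agreement (1.0) with a warning:
    a responder whose biomarker volume vanished at both timepoints must not
    crash a cohort battery.  Exactly one empty mask gives 0.
    """
    require_same_grid(a.geometry, b.geometry)
    na, nb = a.n_voxels, b.n_voxels
    if na == 0 and nb == 0:
        warnings.warn("dice of two empty masks defined as 1.0", stacklevel=2)
        return 1.0
    inter = int((a.values & b.values).sum())
    return 2.0 * inter / (na + nb)


def boundary_points(mask: BinaryMask) -> np.ndarray:
    """World-mm centre coordinates of the mask's surface voxels, (n, 3).

    A surface voxel has at least one 6-connected neighbour that is outside
    the mask or outside the grid.
    """
    if mask.is_empty():
        raise EmptyMaskError("boundary of an empty mask is undefined")
    eroded = ndimage.binary_erosion(
        mask.values, structure=_FACE_STRUCT, border_value=0
    )
    surface = mask.values & ~eroded
    idx = np.argwhere(surface)
    return mask.geometry.world_coordinates(idx)


def hausdorff_mm(a: BinaryMask, b: BinaryMask) -> float:
    """Symmetric Hausdorff distance between mask boundaries, in mm."""
    require_same_grid(a.geometry, b.geometry)
    if a.is_empty() or b.is_empty():
        raise EmptyMaskError("Hausdorff distance undefined for an empty mask")
    pa = boundary_points(a)
    pb = boundary_points(b)
    d_ab = cKDTree(pb).query(pa, k=1)[0].max()
    d_ba = cKDTree(pa).query(pb, k=1)[0].max()
    return float(max(d_ab, d_ba))


def overlap_pair(
    ref: BinaryMask | None,
    cmp: BinaryMask | None,
    pair: tuple[str, str],
    mask_family: str,
) -> OverlapMetrics:
    """One overlap record; undefined quantities are flagged, never invented."""
    flags: list[str] = []
    if ref is None or cmp is None:
        return OverlapMetrics(pair, mask_family, None, None,
                              ref.n_voxels if ref else 0,
                              cmp.n_voxels if cmp else 0,
                              ("MISSING_MASK",))
    n_ref, n_cmp = ref.n_voxels, cmp.n_voxels
    if n_ref == 0 and n_cmp == 0:
        flags.append("BOTH_EMPTY")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dsc = dice(ref, cmp)
        hd = None
        flags.append("HD_UNDEFINED")
    elif n_ref == 0 or n_cmp == 0:
        flags.append("ONE_EMPTY")
        dsc = dice(ref, cmp)
        hd = None
        flags.append("HD_UNDEFINED")
    else:
        dsc = dice(ref, cmp)
        hd = hausdorff_mm(ref, cmp)
    return OverlapMetrics(pair, mask_family, dsc, hd, n_ref, n_cmp, tuple(flags))


def overlap_battery(series, mask_family: str) -> list[OverlapMetrics]:
    """Pre-RT vs each post-RT overlap for one mask family.

    The reference is fixed at the single pre-RT timepoint; one record per
    post-RT timepoint, in scan order.  ``series`` is a
    :class:`~smritrack.phantom.PatientSeries` whose timepoints carry masks
    under ``mask_family`` in their ``masks`` dict.
    """
    pre = series.pre_rt
    ref = pre.masks.get(mask_family)
    if ref is None or ref.is_empty():
        raise EmptyMaskError(
            f"{series.patient_id}: pre-RT {mask_family} mask missing or empty"
        )
    records = []
    for tp in series.post_rt:
        pair = (f"{pre.months_from_rt:g}mo", f"{tp.months_from_rt:g}mo")
        records.append(overlap_pair(ref, tp.masks.get(mask_family), pair, mask_family))
    return records
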