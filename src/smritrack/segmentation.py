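"""Cho/NAA ratio maps, the NAWM reference, and the >= 2X biomarker mask.

The biomarker region is the set of voxels whose Cho/NAA ratio is at least
``factor`` (default 2) times the mean Cho/NAA over contralateral
normal-appearing white matter.  The threshold is inclusive, matching the
biomarker's name (Cho/NAA >= 2X).  Expert contour editing is approximated
by a connected-component size filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from skimage import measure

from .errors import EmptyMaskError, ReferenceRegionError
from .grids import BinaryMask, MetaboliteMap, require_same_grid


@dataclass(frozen=True)
class NawmReference:
    """Mean Cho/NAA over the normal-appearing white-matter region."""

    mean_ratio: float
    n_voxels: int
    source: Literal["MANUAL_MASK", "MIRRORED"]

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean_ratio) or self.mean_ratio <= 0:
            raise ReferenceRegionError("NAWM mean ratio must be finite and positive")


def ratio_map(
    cho: MetaboliteMap, naa: MetaboliteMap, naa_floor: float | None = None
) -> MetaboliteMap:
    """Voxelwise Cho/NAA on the intersection of both coverages.

    Voxels where NAA falls below a positive floor are *excluded* from the
    output coverage rather than clipped: clipping would fabricate extreme
    ratios where the denominator is essentially noise.  The default floor
    is 1e-6 times the median NAA over its coverage.
    """
    require_same_grid(cho.geometry, naa.geometry)
    if cho.metabolite != "CHO" or naa.metabolite != "NAA":
        raise ValueError("ratio_map expects (CHO, NAA) maps in that order")
    cov = cho.coverage & naa.coverage
    if naa_floor is None:
        inside = naa.values[naa.coverage]
        naa_floor = 1e-6 * float(np.median(inside)) if inside.size else 1e-6
    with np.errstate(invalid="ignore"):
        cov = cov & (naa.values > naa_floor)
    vals = np.full(cho.geometry.shape, np.nan)
    vals[cov] = cho.values[cov] / naa.values[cov]
    return MetaboliteMap("CHO_NAA_RATIO", vals, cov, cho.geometry)


def nawm_reference(
    ratio: MetaboliteMap,
    nawm: BinaryMask,
    min_voxels: int = 50,
    source: Literal["MANUAL_MASK", "MIRRORED"] = "MANUAL_MASK",
    statistic: Literal["mean", "median"] = "mean",
) -> NawmReference:
    """Average ratio over NAWM ∩ coverage (arithmetic mean by default)."""
    require_same_grid(ratio.geometry, nawm.geometry)
    sel = nawm.values & ratio.coverage
    n = int(sel.sum())
    if n < min_voxels:
        raise ReferenceRegionError(
            f"NAWM region has {n} voxels inside ratio coverage; "
            f"at least {min_voxels} required"
        )
    vals = ratio.values[sel]
    center = float(np.mean(vals)) if statistic == "mean" else float(np.median(vals))
    return NawmReference(mean_ratio=center, n_voxels=n, source=source)


def mirror_nawm(lesion: BinaryMask, brain: BinaryMask) -> BinaryMask:
    """Fallback NAWM region: the lesion reflected across the mid-sagittal
    grid plane, restricted to brain and to the lesion's complement."""
    require_same_grid(lesion.geometry, brain.geometry)
    if lesion.is_empty():
        raise EmptyMaskError("cannot mirror an empty lesion mask")
    if brain.is_empty():
        raise EmptyMaskError("brain mask is empty")
    mirrored = lesion.values[::-1, :, :] & brain.values & ~lesion.values
    if not mirrored.any():
        raise ReferenceRegionError(
            "mirrored NAWM region is empty; supply a manual NAWM mask"
        )
    return BinaryMask("NAWM", mirrored, lesion.geometry)


def threshold_mask(
    ratio: MetaboliteMap,
    ref: NawmReference,
    factor: float = 2.0,
    min_component_cc: float = 0.1,
    exclusion: BinaryMask | None = None,
) -> BinaryMask:
    """Segment the Cho/NAA >= factor·NAWM biomarker region.

    Comparison is inclusive (>=).  Connected components (26-connectivity)
    smaller than ``min_component_cc`` are discarded.  ``exclusion`` is an
    optional user-supplied mask (e.g. post-surgical enhancement) removed
    before component filtering.
    """
    with np.errstate(invalid="ignore"):
        sel = ratio.coverage & (ratio.values >= factor * ref.mean_ratio)
    if exclusion is not None:
        require_same_grid(ratio.geometry, exclusion.geometry)
        sel &= ~exclusion.values
    if min_component_cc > 0 and sel.any():
        voxel_cc = ratio.geometry.voxel_volume_mm3 / 1000.0
        min_voxels = int(np.ceil(min_component_cc / voxel_cc))
        if min_voxels > 1:
            labels = measure.label(sel, connectivity=3)
            counts = np.bincount(labels.ravel())
            keep = np.flatnonzero(counts >= min_voxels)
            keep = keep[keep != 0]
            sel = np.isin(labels, keep)
    return BinaryMask("CHO_NAA_2X", sel, ratio.geometry)


def segment_timepoint(
    cho: MetaboliteMap,
    naa: MetaboliteMap,
    nawm: BinaryMask | None = None,
    brain: BinaryMask | None = None,
    lesion_hint: BinaryMask | None = None,
    factor: float = 2.0,
    min_component_cc: float = 0.1,
    min_nawm_voxels: int = 50,
) -> tuple[BinaryMask, NawmReference]:
    """Convenience: ratio map -> NAWM reference -> threshold mask.

    When no manual NAWM mask is given, falls back to mirroring
    ``lesion_hint`` (e.g. the FLAIR mask) across the mid-sagittal plane.
    """
    rmap = ratio_map(cho, naa)
    if nawm is None:
        if lesion_hint is None or brain is None:
            raise ReferenceRegionError(
                "need either a manual NAWM mask or (brain, lesion_hint) to mirror"
            )
        nawm = mirror_nawm(lesion_hint, brain)
        source = "MIRRORED"
    else:
        source = "MANUAL_MASK"
    ref = nawm_reference(rmap, nawm, min_voxels=min_nawm_voxels, source=source)
    return threshold_mask(rmap, ref, factor=factor,
                          min_component_cc=min_component_cc), ref
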