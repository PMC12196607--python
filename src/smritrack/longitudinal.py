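"""Coverage matching, voxel-level difference maps, volume trajectories,
and the true-progression vs pseudoprogression interval rule.

Two serial metabolite maps are only comparable on voxels with valid data
at both timepoints; coverage matching removes voxels lacking data from
*both* maps.  Difference maps are later minus earlier (positive =
increase).  An interval is called:

* ``TRUE_PROGRESSION`` when Cho/NAA and Cho both rise — growing tumor with
  active membrane turnover;
* ``PSEUDOPROGRESSION`` when Cho/NAA rises while Cho falls — NAA collapsing
  faster than Cho from treatment effect (inflammation/necrosis), not
  proliferation;
* ``STABLE_OR_RESPONSE`` otherwise.

Summaries are medians of voxelwise change over an ROI (default: union of
the two timepoints' biomarker masks), with a dead band so that noise-level
wobble never triggers a call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CoverageError, GridMismatchError
from .grids import BinaryMask, MetaboliteMap, require_same_grid, volume_cc

DEAD_BAND_RATIO_DEFAULT = 0.1  # ratio units
DEAD_BAND_CHO_FRACTION = 0.05  # of NAWM Cho


@dataclass
class DifferenceMap:
    """Signed later-minus-earlier voxel change on matched coverage."""

    metabolite: str
    values: np.ndarray
    matched_coverage: np.ndarray
    pair: tuple[str, str]
    geometry: object

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.matched_coverage = np.asarray(self.matched_coverage, dtype=bool)
        if not np.all(np.isfinite(self.values[self.matched_coverage])):
            raise ValueError("non-finite differences inside matched coverage")


@dataclass(frozen=True)
class VolumeTrajectory:
    """Per-timepoint volumes (cc) and per-interval percent change."""

    mask_family: str
    months: tuple[float, ...]
    volume_cc: tuple[float | None, ...]
    percent_change: tuple[float | None, ...]  # len = len(months) - 1
    flags: tuple[tuple[str, ...], ...]


@dataclass(frozen=True)
class ProgressionCall:
    """Interval classification with the deltas that justify it."""

    pair: tuple[str, str]
    label: str  # TRUE_PROGRESSION | PSEUDOPROGRESSION | STABLE_OR_RESPONSE
    delta_cho_summary: float
    delta_ratio_summary: float
    roi_voxels: int
    dead_band_cho: float
    dead_band_ratio: float


def coverage_match(
    m1: MetaboliteMap, m2: MetaboliteMap
) -> tuple[MetaboliteMap, MetaboliteMap]:
    """Restrict both maps to the intersection of their coverages.

    Voxels lacking data at either timepoint are excluded from both.
    """
    require_same_grid(m1.geometry, m2.geometry)
    if m1.metabolite != m2.metabolite:
        raise ValueError("coverage_match requires maps of the same metabolite")
    common = m1.coverage & m2.coverage
    if not common.any():
        raise CoverageError("coverage intersection is empty; pair unusable")
    return m1.restricted(common), m2.restricted(common)


def difference_map(
    earlier: MetaboliteMap,
    later: MetaboliteMap,
    pair: tuple[str, str] = ("earlier", "later"),
) -> DifferenceMap:
    """Later minus earlier, voxelwise, on coverage-matched maps."""
    require_same_grid(earlier.geometry, later.geometry)
    if not np.array_equal(earlier.coverage, later.coverage):
        raise CoverageError("maps must be coverage-matched before differencing")
    vals = np.full(earlier.geometry.shape, np.nan)
    cov = earlier.coverage
    vals[cov] = later.values[cov] - earlier.values[cov]
    return DifferenceMap(earlier.metabolite, vals, cov, pair, earlier.geometry)


def volume_trajectory(series, mask_family: str) -> VolumeTrajectory:
    """Volumes and percent change per scan for one mask family.

    Percent change is relative to the immediately preceding scan; it is
    flagged undefined when the preceding volume is zero or either mask is
    missing.
    """
    tps = series.timepoints
    if len(tps) < 2:
        raise ValueError("volume trajectory needs at least two timepoints")
    months, vols, tp_flags = [], [], []
    for tp in tps:
        months.append(tp.months_from_rt)
        mask = tp.masks.get(mask_family)
        if mask is None:
            vols.append(None)
            tp_flags.append(("MISSING_MASK",))
        else:
            vols.append(volume_cc(mask))
            tp_flags.append(())
    pct: list[float | None] = []
    for prev, cur in zip(vols[:-1], vols[1:]):
        if prev is None or cur is None or prev == 0:
            pct.append(None)
        else:
            pct.append(100.0 * (cur - prev) / prev)
    return VolumeTrajectory(
        mask_family, tuple(months), tuple(vols), tuple(pct), tuple(tp_flags)
    )


def classify_interval(
    dm_cho: DifferenceMap,
    dm_ratio: DifferenceMap,
    roi: BinaryMask,
    dead_band_cho: float,
    dead_band_ratio: float = DEAD_BAND_RATIO_DEFAULT,
) -> ProgressionCall:
    """Label one interval from its Cho and Cho/NAA difference maps.

    The label is a pure function of the two median summaries and the dead
    bands: both above their band -> TRUE_PROGRESSION; ratio above while Cho
    below its negative band -> PSEUDOPROGRESSION; anything else ->
    STABLE_OR_RESPONSE.
    """
    if dm_cho.pair != dm_ratio.pair:
        raise ValueError("difference maps must describe the same timepoint pair")
    if dm_cho.values.shape != dm_ratio.values.shape:
        raise GridMismatchError("difference maps on different grids")
    sel = roi.values & dm_cho.matched_coverage & dm_ratio.matched_coverage
    n = int(sel.sum())
    if n == 0:
        raise CoverageError("ROI does not intersect matched coverage")
    d_cho = float(np.median(dm_cho.values[sel]))
    d_ratio = float(np.median(dm_ratio.values[sel]))
    if d_ratio > dead_band_ratio and d_cho > dead_band_cho:
        label = "TRUE_PROGRESSION"
    elif d_ratio > dead_band_ratio and d_cho < -dead_band_cho:
        label = "PSEUDOPROGRESSION"
    else:
        label = "STABLE_OR_RESPONSE"
    return ProgressionCall(
        pair=dm_cho.pair,
        label=label,
        delta_cho_summary=d_cho,
        delta_ratio_summary=d_ratio,
        roi_voxels=n,
        dead_band_cho=dead_band_cho,
        dead_band_ratio=dead_band_ratio,
    )
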