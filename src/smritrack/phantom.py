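"""Seeded longitudinal digital phantoms with known ground truth.

The phantom emulates the contrast structure of spectroscopic MRI in
high-grade glioma: a brain-shaped region of normal-appearing white matter
(NAWM) with baseline Cho and NAA concentrations, and a spherical lesion in
one hemisphere where Cho is elevated and NAA depressed so that the Cho/NAA
ratio is a chosen multiple of the NAWM ratio.  Spectroscopic coverage is
the brain minus an eroded rind (partial coverage with edge dropout), and
additive Gaussian voxel noise is applied per metabolite.

A series evolves over timepoints (months from radiotherapy; exactly one
negative pre-RT entry) under one of four modes:

* ``STABLE`` — nothing changes.
* ``RESPONSE`` — lesion shrinks and its Cho/NAA ratio decays toward NAWM.
* ``TRUE_PROGRESSION`` — lesion grows; Cho and Cho/NAA both rise.
* ``PSEUDOPROGRESSION`` — Cho falls while NAA falls faster, so Cho/NAA
  rises despite the Cho decrease (treatment effect mimicking growth).

Brain and lesion are analytic ellipsoids/spheres rasterised by
voxel-centre inclusion, so the ground-truth mask is exact.  All randomness
flows from one integer seed through per-(patient, timepoint) substreams:
``default_rng([seed, patient_index, timepoint_index])``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import PhantomConfigError
from .grids import BinaryMask, GridGeometry, MetaboliteMap
from . import io as srio

MODE_LABELS = ("STABLE", "RESPONSE", "TRUE_PROGRESSION", "PSEUDOPROGRESSION")


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, contrast and noise of one phantom patient.

    Concentrations are in arbitrary institutional units.  The lesion's
    Cho/NAA is ``tumor_ratio_multiple`` times the NAWM ratio, realised
    symmetrically (Cho scaled up and NAA scaled down by the square root of
    the multiple) so both directions of contrast are present.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    brain_semi_axes_mm: tuple[float, float, float] = (84.0, 90.0, 78.0)
    tumor_center_mm: tuple[float, float, float] = (-38.0, 8.0, 4.0)
    tumor_radius_mm: float = 15.0
    nawm_cho: float = 1.0
    nawm_naa: float = 1.5
    tumor_ratio_multiple: float = 3.0
    noise_sd: float = 0.1
    noise_floor: float = 0.01
    coverage_erosion_mm: float = 6.0
    flair_margin_mm: float = 4.0
    jitter_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("nawm_cho", "nawm_naa", "tumor_radius_mm"):
            if getattr(self, name) <= 0:
                raise PhantomConfigError(f"{name} must be positive")
        if self.tumor_ratio_multiple <= 1:
            raise PhantomConfigError("tumor_ratio_multiple must exceed 1")
        if self.noise_sd < 0 or self.coverage_erosion_mm < 0:
            raise PhantomConfigError("noise_sd and coverage_erosion_mm must be >= 0")

    @property
    def geometry(self) -> GridGeometry:
        # grid centred on the world origin so the mid-sagittal plane is the
        # x-flip symmetry plane of the lattice
        shape = np.asarray(self.grid_shape, dtype=float)
        spacing = np.asarray(self.voxel_spacing_mm, dtype=float)
        origin = -(shape - 1) / 2.0 * spacing
        return GridGeometry(tuple(self.grid_shape), tuple(self.voxel_spacing_mm),
                            tuple(origin))

    @property
    def nawm_ratio(self) -> float:
        return self.nawm_cho / self.nawm_naa

    def validate_lesion(self, radius_mm: float) -> None:
        """Reject lesions whose bounding sphere leaves the brain ellipsoid."""
        c = np.asarray(self.tumor_center_mm)
        ax = np.asarray(self.brain_semi_axes_mm)
        # conservative: the sphere fits if its centre lies inside the
        # ellipsoid with every semi-axis shrunk by the radius
        if radius_mm >= ax.min() or np.sum((c / (ax - radius_mm)) ** 2) > 1.0:
            raise PhantomConfigError(
                f"tumor (center {tuple(c)}, radius {radius_mm:.1f} mm) does not fit "
                f"inside the brain ellipsoid with semi-axes {tuple(ax)}"
            )


@dataclass(frozen=True)
class EvolutionMode:
    """Per-timepoint multiplicative schedules for radius, Cho and NAA.

    The schedule at timepoint index k (0 = pre-RT baseline) is
    ``step ** k`` for each quantity, so a mode is characterised by three
    per-step factors and extends to any number of follow-ups.
    """

    label: str
    radius_step: float
    cho_step: float
    naa_step: float

    def __post_init__(self) -> None:
        if self.label not in MODE_LABELS:
            raise ValueError(f"unknown mode label {self.label!r}")
        ratio_step = self.cho_step / self.naa_step
        if self.label == "TRUE_PROGRESSION":
            assert self.cho_step > 1 and ratio_step > 1 and self.radius_step > 1
        elif self.label == "PSEUDOPROGRESSION":
            assert self.cho_step < 1 and ratio_step > 1
        elif self.label == "RESPONSE":
            assert ratio_step < 1
        else:  # STABLE
            assert self.radius_step == self.cho_step == self.naa_step == 1.0

    def factors(self, k: int) -> tuple[float, float, float]:
        return (self.radius_step ** k, self.cho_step ** k, self.naa_step ** k)

    @classmethod
    def preset(cls, label: str) -> "EvolutionMode":
        presets = {
            "STABLE": cls("STABLE", 1.0, 1.0, 1.0),
            "RESPONSE": cls("RESPONSE", 0.88, 0.85, 1.10),
            "TRUE_PROGRESSION": cls("TRUE_PROGRESSION", 1.12, 1.12, 0.96),
            "PSEUDOPROGRESSION": cls("PSEUDOPROGRESSION", 1.0, 0.93, 0.80),
        }
        return presets[label]


@dataclass
class Timepoint:
    """All volumes of one scan session on the common grid."""

    months_from_rt: float
    cho: MetaboliteMap
    naa: MetaboliteMap
    masks: dict[str, BinaryMask] = field(default_factory=dict)

    @property
    def is_pre_rt(self) -> bool:
        return self.months_from_rt < 0


@dataclass
class PatientSeries:
    """Ordered longitudinal timepoints for one patient."""

    patient_id: str
    timepoints: list[Timepoint]
    mode_label: str | None = None

    @property
    def pre_rt(self) -> Timepoint:
        pre = [tp for tp in self.timepoints if tp.is_pre_rt]
        if len(pre) != 1:
            raise ValueError(f"{self.patient_id}: expected exactly one pre-RT timepoint")
        return pre[0]

    @property
    def post_rt(self) -> list[Timepoint]:
        return [tp for tp in self.timepoints if not tp.is_pre_rt]


def _ellipsoid_mask(geometry: GridGeometry, center_mm, semi_axes_mm) -> np.ndarray:
    x, y, z = geometry.coordinate_grids()
    c = center_mm
    a = semi_axes_mm
    return (
        ((x - c[0]) / a[0]) ** 2
        + ((y - c[1]) / a[1]) ** 2
        + ((z - c[2]) / a[2]) ** 2
    ) <= 1.0


def _coverage_from_brain(brain: np.ndarray, geometry: GridGeometry,
                         erosion_mm: float) -> np.ndarray:
    if erosion_mm <= 0:
        return brain.copy()
    depth = ndimage.distance_transform_edt(brain, sampling=geometry.spacing_mm)
    return brain & (depth > erosion_mm)


def dilate_mm(mask: np.ndarray, geometry: GridGeometry, margin_mm: float) -> np.ndarray:
    """Isotropic dilation by a physical margin via the distance transform."""
    if margin_mm <= 0:
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=geometry.spacing_mm)
    return mask | (dist <= margin_mm)


def make_timepoint(
    config: PhantomConfig,
    months_from_rt: float,
    radius_factor: float = 1.0,
    cho_factor: float = 1.0,
    naa_factor: float = 1.0,
    patient_index: int = 0,
    timepoint_index: int = 0,
    center_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
    flair_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> Timepoint:
    """Rasterise one scan session of the phantom.

    Returns Cho/NAA metabolite maps with the eroded coverage lattice, plus
    ground-truth tumor, NAWM (mirror of the lesion across the mid-sagittal
    plane), FLAIR (tumor dilated by the configured margin) and brain masks.
    ``center_offset_mm`` displaces the lesion rigidly (used by the series
    generator to emulate residual registration error).
    """
    radius = config.tumor_radius_mm * radius_factor
    config.validate_lesion(radius + float(np.linalg.norm(center_offset_mm)))
    geom = config.geometry
    center = tuple(
        c + o for c, o in zip(config.tumor_center_mm, center_offset_mm)
    )

    brain = _ellipsoid_mask(geom, (0.0, 0.0, 0.0), config.brain_semi_axes_mm)
    tumor = _ellipsoid_mask(geom, center, (radius,) * 3) & brain
    coverage = _coverage_from_brain(brain, geom, config.coverage_erosion_mm)

    # contralateral NAWM: reflect the lesion across the mid-sagittal plane
    nawm = tumor[::-1, :, :] & brain & ~tumor
    # FLAIR hyperintensity: the lesion dilated by an isotropic margin.  The
    # anatomic scan is registered independently of the spectroscopy, so it
    # may carry its own rigid residual.
    if any(o != 0.0 for o in flair_offset_mm):
        fl_center = tuple(c + o for c, o in zip(center, flair_offset_mm))
        fl_core = _ellipsoid_mask(geom, fl_center, (radius,) * 3) & brain
    else:
        fl_core = tumor
    flair = dilate_mm(fl_core, geom, config.flair_margin_mm) & brain

    s = float(np.sqrt(config.tumor_ratio_multiple))
    cho_vals = np.where(brain, config.nawm_cho, 0.0)
    naa_vals = np.where(brain, config.nawm_naa, 0.0)
    cho_vals[tumor] = config.nawm_cho * s * cho_factor
    naa_vals[tumor] = config.nawm_naa / s * naa_factor

    if config.noise_sd > 0:
        rng = np.random.default_rng(
            [int(config.seed), int(patient_index), int(timepoint_index)]
        )
        cho_vals = cho_vals + rng.normal(0.0, config.noise_sd, geom.shape)
        naa_vals = naa_vals + rng.normal(0.0, config.noise_sd, geom.shape)
        # keep concentrations positive so ratios stay defined in coverage
        cho_vals = np.maximum(cho_vals, config.noise_floor)
        naa_vals = np.maximum(naa_vals, config.noise_floor)

    cho_vals = np.where(coverage, cho_vals, np.nan)
    naa_vals = np.where(coverage, naa_vals, np.nan)

    masks = {
        "GROUND_TRUTH": BinaryMask("GROUND_TRUTH", tumor, geom),
        "NAWM": BinaryMask("NAWM", nawm, geom),
        "FLAIR": BinaryMask("FLAIR", flair, geom),
        "BRAIN": BinaryMask("BRAIN", brain, geom),
    }
    return Timepoint(
        months_from_rt=months_from_rt,
        cho=MetaboliteMap("CHO", cho_vals, coverage, geom),
        naa=MetaboliteMap("NAA", naa_vals, coverage, geom),
        masks=masks,
    )


DEFAULT_TIMEPOINTS_MONTHS = (-1.0, 1.0, 4.0, 7.0, 10.0)

# default 6-patient demo cohort: every mode represented, the common
# clinical outcomes (stability, true progression) twice
DEFAULT_COHORT_MODES = (
    "STABLE",
    "RESPONSE",
    "TRUE_PROGRESSION",
    "PSEUDOPROGRESSION",
    "TRUE_PROGRESSION",
    "STABLE",
)


def make_series(
    config: PhantomConfig,
    mode: EvolutionMode,
    timepoints_months: list[float] | tuple[float, ...] = DEFAULT_TIMEPOINTS_MONTHS,
    patient_id: str = "PHANTOM000",
    patient_index: int = 0,
) -> PatientSeries:
    """One longitudinal phantom series following a mode's schedules.

    ``timepoints_months`` must contain exactly one negative (pre-RT) entry
    followed by at least one post-RT entry, strictly increasing.
    """
    months = list(timepoints_months)
    if sorted(months) != months or len(set(months)) != len(months):
        raise ValueError("timepoints_months must be strictly increasing")
    n_pre = sum(m < 0 for m in months)
    if n_pre != 1 or len(months) < 2:
        raise ValueError(
            "need exactly one pre-RT (negative) timepoint and at least one post-RT"
        )
    tps = []
    for k, m in enumerate(months):
        rf, cf, nf = mode.factors(k)
        offset = (0.0, 0.0, 0.0)
        fl_offset = (0.0, 0.0, 0.0)
        if config.jitter_mm > 0 and k > 0:
            # residual registration error at follow-ups, from dedicated
            # substreams; the anatomic (FLAIR) and spectroscopic volumes
            # are registered separately, hence independent residuals
            jr = np.random.default_rng(
                [int(config.seed), int(patient_index), int(k), 7]
            )
            offset = tuple(jr.normal(0.0, config.jitter_mm, 3))
            fl_offset = tuple(jr.normal(0.0, config.jitter_mm, 3))
        tps.append(
            make_timepoint(
                config, m, rf, cf, nf,
                patient_index=patient_index, timepoint_index=k,
                center_offset_mm=offset, flair_offset_mm=fl_offset,
            )
        )
    return PatientSeries(patient_id, tps, mode_label=mode.label)


def write_series(series: PatientSeries, out_dir: str | Path) -> list[dict]:
    """Write every volume of a series as NIfTI; return manifest entries."""
    out_dir = Path(out_dir)
    entries = []
    for i, tp in enumerate(series.timepoints):
        tpdir = out_dir / series.patient_id / f"tp{i:02d}"
        files = {
            "cho": srio.write_metabolite_map(tp.cho, tpdir / "cho.nii.gz"),
            "naa": srio.write_metabolite_map(tp.naa, tpdir / "naa.nii.gz"),
        }
        for label, mask in tp.masks.items():
            files[label.lower()] = srio.write_mask(
                mask, tpdir / f"{label.lower()}.nii.gz"
            )
        entries.append(
            {
                "months_from_rt": tp.months_from_rt,
                "files": {k: str(v) for k, v in files.items()},
            }
        )
    return entries


def simulate_cohort(
    out_dir: str | Path,
    modes: list[str],
    seed: int = 0,
    timepoints_months=DEFAULT_TIMEPOINTS_MONTHS,
    config: PhantomConfig | None = None,
    jitter_mm: float = 2.0,
) -> Path:
    """Simulate one patient per mode label, write volumes and a manifest.

    Follow-up cadence defaults to one month post-RT then every three
    months, anchored by a single pre-RT scan.  Cohorts carry a small rigid
    lesion jitter at follow-ups (default 2 mm SD) emulating the residual
    registration error real serial studies contend with; pass an explicit
    ``config`` to override.
    """
    out_dir = Path(out_dir)
    base = config or PhantomConfig(jitter_mm=jitter_mm)
    patients = []
    for idx, label in enumerate(modes):
        cfg = dataclasses.replace(base, seed=seed)
        series = make_series(
            cfg, EvolutionMode.preset(label), timepoints_months,
            patient_id=f"PHANTOM{idx:03d}", patient_index=idx,
        )
        entries = write_series(series, out_dir)
        # manifest paths relative to the manifest's directory
        for e in entries:
            e["files"] = {
                k: str(Path(v).relative_to(out_dir)) for k, v in e["files"].items()
            }
        patients.append(
            {
                "id": series.patient_id,
                "cohort": 2,
                "mode": label,
                "timepoints": entries,
            }
        )
    manifest = {
        "seed": seed,
        "working_grid": "phantom",
        "patients": patients,
    }
    return srio.write_manifest(manifest, out_dir / "manifest.yaml")
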