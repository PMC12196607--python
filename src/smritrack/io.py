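"""NIfTI input/output and study manifests.

Volumes are exchanged as .nii/.nii.gz through nibabel with an axis-aligned
affine built from the grid geometry.  Metabolite maps are written with NaN
outside coverage plus an explicit companion coverage mask
(``<stem>_coverage.nii.gz``); on read, the companion wins, NaN/finiteness is
the fallback.  A YAML/JSON manifest binds file paths to roles per patient
and timepoint.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np
import yaml

from .errors import ManifestError, VolumeFormatError
from .grids import BinaryMask, GridGeometry, MetaboliteMap

_BINARY_TOL = 1e-6


def _geometry_from_img(img: nib.Nifti1Image, path: Path) -> GridGeometry:
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise VolumeFormatError(f"{path}: missing or invalid voxel spacing in header")
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return GridGeometry(
        shape=tuple(int(s) for s in img.shape[:3]),
        spacing_mm=tuple(float(z) for z in zooms),
        origin_mm=tuple(origin),
    )


def _load_3d(path: str | Path) -> tuple[np.ndarray, GridGeometry]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected a 3D volume, got ndim={data.ndim}")
    return np.asarray(data, dtype=np.float64), _geometry_from_img(img, path)


def _nifti(values: np.ndarray, geometry: GridGeometry) -> nib.Nifti1Image:
    img = nib.Nifti1Image(np.asarray(values), geometry.affine)
    img.header.set_zooms(geometry.spacing_mm)
    return img


def coverage_companion_path(path: str | Path) -> Path:
    """``foo.nii.gz`` -> ``foo_coverage.nii.gz`` (same directory)."""
    path = Path(path)
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + "_coverage" + suffix)
    raise ValueError(f"not a NIfTI path: {path}")


def write_mask(mask: BinaryMask, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(_nifti(mask.values.astype(np.uint8), mask.geometry), str(path))
    return path


def write_metabolite_map(
    m: MetaboliteMap, path: str | Path, write_coverage: bool = True
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    vals = np.where(m.coverage, m.values, np.nan)
    nib.save(_nifti(vals, m.geometry), str(path))
    if write_coverage:
        cov_path = coverage_companion_path(path)
        nib.save(_nifti(m.coverage.astype(np.uint8), m.geometry), str(cov_path))
    return path


def read_mask(path: str | Path, label: str = "GROUND_TRUTH") -> BinaryMask:
    data, geom = _load_3d(path)
    near0 = np.abs(data) <= _BINARY_TOL
    near1 = np.abs(data - 1.0) <= _BINARY_TOL
    if not np.all(near0 | near1):
        bad = data[~(near0 | near1)]
        raise VolumeFormatError(
            f"{path}: mask contains non-binary values (e.g. {bad.flat[0]:g})"
        )
    return BinaryMask(label, near1, geom)


def read_metabolite_map(
    path: str | Path,
    metabolite: str,
    coverage_path: str | Path | None = None,
) -> MetaboliteMap:
    data, geom = _load_3d(path)
    if coverage_path is None:
        candidate = coverage_companion_path(path)
        coverage_path = candidate if candidate.exists() else None
    if coverage_path is not None:
        cov = read_mask(coverage_path, label="BRAIN").values
    else:
        cov = np.isfinite(data)
    vals = np.where(cov, data, np.nan)
    if not np.all(np.isfinite(vals[cov])):
        raise VolumeFormatError(f"{path}: non-finite values inside declared coverage")
    return MetaboliteMap(metabolite, vals, cov, geom)


def read_volume(
    path: str | Path, expected_kind: str, metabolite: str = "CHO"
) -> MetaboliteMap | BinaryMask:
    """Read a volume as either a ``"map"`` or a ``"mask"``.

    Masks are only accepted when every value is within tolerance of
    {0, 1}; anything else is rejected rather than thresholded.
    """
    if expected_kind == "mask":
        return read_mask(path)
    if expected_kind == "map":
        return read_metabolite_map(path, metabolite=metabolite)
    raise ValueError(f"expected_kind must be 'map' or 'mask', got {expected_kind!r}")


# ---------------------------------------------------------------------------
# Study manifest

def write_manifest(manifest: dict[str, Any], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    text = (
        json.dumps(manifest, indent=2, sort_keys=True)
        if path.suffix == ".json"
        else yaml.safe_dump(manifest, sort_keys=True)
    )
    path.write_text(text)
    return path


def read_manifest(path: str | Path) -> dict[str, Any]:
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"manifest not found: {path}")
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict) or "patients" not in data:
        raise ManifestError(f"{path}: manifest must be a mapping with a 'patients' list")
    return data


def validate_manifest(manifest: dict[str, Any], root: str | Path = ".") -> None:
    """Check structural invariants: paths exist, exactly one pre-RT
    timepoint per patient, months strictly increasing."""
    root = Path(root)
    for patient in manifest["patients"]:
        pid = patient.get("id", "<unnamed>")
        tps = patient.get("timepoints", [])
        months = [tp["months_from_rt"] for tp in tps]
        if sorted(months) != months or len(set(months)) != len(months):
            raise ManifestError(f"{pid}: timepoints must be strictly increasing")
        n_pre = sum(m < 0 for m in months)
        if n_pre != 1:
            raise ManifestError(f"{pid}: need exactly one pre-RT timepoint, found {n_pre}")
        for tp in tps:
            for role, rel in tp.get("files", {}).items():
                p = root / rel
                if not p.exists():
                    raise ManifestError(f"{pid}: missing file for role {role}: {p}")
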