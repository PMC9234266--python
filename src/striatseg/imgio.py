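"""Volumetric image I/O with explicit geometry.

Every image in the pipeline is a 3D grid plus a 4x4 voxel-index -> world-mm
affine. Two roles exist: :class:`Volume` for scalar activity images (PET,
templates, specified images) and :class:`LabelVolume` for integer-coded
anatomy/subregion maps with a code -> name legend. All images are converted
to canonical RAS orientation on load so the downstream subregion geometry
(sagittal / coronal semantics) is fixed.

On-disk format is NIfTI-1 (``.nii`` / ``.nii.gz``) via nibabel; label legends
live in a JSON sidecar ``<stem>.labels.json`` mapping code to region name.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


class GeometryError(ValueError):
    """Raised when image geometries are invalid or incompatible."""


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise GeometryError(f"affine must be 4x4, got {affine.shape}")
    if not np.all(np.isfinite(affine)):
        raise GeometryError("affine contains non-finite entries")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise GeometryError("affine is singular")
    return affine


def spacing_from_affine(affine: np.ndarray) -> np.ndarray:
    """Voxel size in mm per axis: column norms of the 3x3 affine block."""
    return np.linalg.norm(np.asarray(affine, float)[:3, :3], axis=0)


@dataclass
class Volume:
    """A 3D scalar image with voxel -> world-mm geometry."""

    voxels: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise GeometryError(f"expected a 3D grid, got shape {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must be finite")
        self.affine = _check_affine(self.affine)
        if np.any(self.spacing <= 0):
            raise GeometryError("spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        return spacing_from_affine(self.affine)

    @property
    def geometry(self) -> "Geometry":
        return Geometry(self.shape, self.affine)

    def same_geometry(self, other, atol: float = 1e-3) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def world_coords(self, mask: np.ndarray | None = None) -> np.ndarray:
        """World-mm coordinates of voxel centers, shape (n, 3)."""
        if mask is None:
            idx = np.indices(self.shape).reshape(3, -1).T
        else:
            idx = np.argwhere(mask)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def copy(self) -> "Volume":
        return Volume(self.voxels.copy(), self.affine.copy())


@dataclass
class LabelVolume:
    """Integer-coded 3D label map sharing Volume geometry.

    Code 0 is background; every nonzero code present in ``codes`` must have
    an entry in ``legend``.
    """

    codes: np.ndarray
    affine: np.ndarray
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 3:
            raise GeometryError(f"expected a 3D grid, got shape {self.codes.shape}")
        if not np.issubdtype(self.codes.dtype, np.integer):
            as_int = np.rint(self.codes).astype(np.int32)
            if not np.allclose(self.codes, as_int, atol=1e-6):
                raise ValueError("label volume has non-integer voxel values")
            self.codes = as_int
        if self.codes.min() < 0:
            raise ValueError("label codes must be non-negative")
        self.affine = _check_affine(self.affine)
        self.legend = {int(k): str(v) for k, v in self.legend.items()}
        present = set(int(c) for c in np.unique(self.codes)) - {0}
        missing = present - set(self.legend)
        for code in sorted(missing):
            self.legend[code] = f"region_{code}"

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.codes.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        return spacing_from_affine(self.affine)

    @property
    def geometry(self) -> "Geometry":
        return Geometry(self.shape, self.affine)

    same_geometry = Volume.same_geometry
    world_coords = Volume.world_coords

    def mask(self, *codes: int) -> np.ndarray:
        """Boolean mask of voxels whose code is in ``codes`` (all nonzero if empty)."""
        if not codes:
            return self.codes > 0
        return np.isin(self.codes, codes)

    def present_codes(self) -> list[int]:
        return sorted(int(c) for c in np.unique(self.codes) if c != 0)

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.codes.copy(), self.affine.copy(), dict(self.legend))


@dataclass(frozen=True)
class Geometry:
    """Target grid for resampling: shape plus affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "affine", _check_affine(self.affine))


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".labels.json")
    return path.with_suffix(".labels.json")


def read_volume(path, as_labels: bool = False) -> Volume | LabelVolume:
    """Read a 3D NIfTI-1 image as a :class:`Volume` or :class:`LabelVolume`.

    Geometry honors the sform when valid, else the qform; files with neither
    are rejected so no image enters the pipeline with guessed coordinates.
    The returned image is in canonical RAS orientation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"{path} is not a 3D volume (shape {img.shape})")
    sform_code = int(img.header["sform_code"])
    qform_code = int(img.header["qform_code"])
    if sform_code > 0:
        affine = img.get_sform()
    elif qform_code > 0:
        affine = img.get_qform()
    else:
        raise GeometryError(f"{path} has neither a valid sform nor qform")
    data = np.asarray(img.dataobj)
    if as_labels:
        legend = {}
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            legend = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
        vol = LabelVolume(data, affine, legend)
    else:
        vol = Volume(data.astype(np.float32), affine)
    return canonicalize_orientation(vol)


def write_volume(volume: Volume | LabelVolume, path) -> None:
    """Write to NIfTI-1; labels additionally get a JSON legend sidecar."""
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    if isinstance(volume, LabelVolume):
        data = volume.codes.astype(np.int32)
    else:
        data = volume.voxels.astype(np.float32)
    img = nib.Nifti1Image(data, volume.affine)
    img.set_sform(volume.affine, code=1)
    img.set_qform(volume.affine, code=1)
    nib.save(img, str(path))
    if isinstance(volume, LabelVolume):
        sidecar = _sidecar_path(path)
        sidecar.write_text(
            json.dumps({str(k): v for k, v in sorted(volume.legend.items())}, indent=1)
        )


def canonicalize_orientation(volume: Volume | LabelVolume):
    """Reorder/flip axes so +x=right, +y=anterior, +z=superior (RAS).

    Pure axis permutation and flips: world coordinates of every voxel are
    unchanged, only the array layout and affine change. Idempotent.
    """
    ornt = nib.orientations.io_orientation(volume.affine)
    if np.any(np.isnan(ornt)):
        raise GeometryError("affine is too oblique/degenerate to orient")
    data = volume.codes if isinstance(volume, LabelVolume) else volume.voxels
    shape = data.shape
    new_data = nib.orientations.apply_orientation(data, ornt)
    new_affine = volume.affine @ nib.orientations.inv_ornt_aff(ornt, shape)
    if isinstance(volume, LabelVolume):
        return LabelVolume(new_data, new_affine, dict(volume.legend))
    return Volume(np.ascontiguousarray(new_data), new_affine)


def resample(volume: Volume | LabelVolume, target: Geometry, interpolation: str = "linear"):
    """Resample onto ``target`` geometry.

    Labels must use nearest interpolation (and never gain new codes);
    scalar volumes default to trilinear.
    """
    is_labels = isinstance(volume, LabelVolume)
    if is_labels and interpolation == "linear":
        raise ValueError("linear interpolation is invalid for label volumes")
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    # map target index -> world -> source index
    m = np.linalg.inv(volume.affine) @ target.affine
    data = volume.codes if is_labels else np.asarray(volume.voxels, float)
    order = 0 if interpolation == "nearest" else 1
    out = ndimage.affine_transform(
        data,
        m[:3, :3],
        offset=m[:3, 3],
        output_shape=target.shape,
        order=order,
        mode="constant",
        cval=0.0,
    )
    if is_labels:
        return LabelVolume(out.astype(volume.codes.dtype), target.affine, dict(volume.legend))
    return Volume(out, target.affine)
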