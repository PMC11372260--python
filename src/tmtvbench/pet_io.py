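"""NIfTI I/O for PET volumes and label masks, with SUV semantics.

Every volume in the package lives in one fixed frame: axes are RAS+ (index
axis 0 runs left-to-right, axis 1 posterior-to-anterior, axis 2
inferior-to-superior), world coordinates are millimetres, voxel indices are
0-based.  Images loaded from disk are reoriented to this frame on read, so
click coordinates recorded in a session file mean the same thing everywhere.

PET voxel values are body-weight-normalised standardized uptake values
(SUV, dimensionless).  Files produced by scanners in activity concentration
units can be converted with :func:`suv_from_activity`.

Storage conventions: SUV volumes are written as float32, label masks as
unsigned 16-bit integers.  Negative voxel values in input files — physically
meaningless reconstruction noise — are clamped to zero with a logged
warning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import GridMismatchError, InputFormatError

log = logging.getLogger("tmtvbench")

__all__ = [
    "VoxelGrid",
    "PETVolume",
    "MaskVolume",
    "read_volume",
    "read_mask",
    "write_volume",
    "suv_from_activity",
]


@dataclass(frozen=True)
class VoxelGrid:
    """Geometry of a 3-D voxel grid in the fixed RAS+ convention.

    Parameters
    ----------
    shape
        Number of voxels along (x, y, z).
    spacing_mm
        Voxel edge lengths in millimetres, all strictly positive.
    origin_mm
        World coordinate of the centre of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))
        if len(self.shape) != 3 or len(self.spacing_mm) != 3 or len(self.origin_mm) != 3:
            raise InputFormatError("VoxelGrid requires 3-D shape/spacing/origin")
        if any(n < 1 for n in self.shape):
            raise InputFormatError(f"all shape components must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise InputFormatError(f"all spacings must be positive, got {self.spacing_mm}")

    @property
    def voxel_volume_cm3(self) -> float:
        """Volume of one voxel in cm^3 (= mL)."""
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz / 1000.0

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (diagonal, RAS+)."""
        aff = np.diag([*self.spacing_mm, 1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def index_to_world(self, index) -> np.ndarray:
        """World coordinate (mm) of a (possibly fractional) voxel index."""
        return np.asarray(self.origin_mm) + np.asarray(index, dtype=float) * np.asarray(
            self.spacing_mm
        )

    def world_to_index(self, point_mm) -> tuple[int, int, int]:
        """Nearest voxel index for a world point; raises if outside the grid."""
        frac = (np.asarray(point_mm, dtype=float) - np.asarray(self.origin_mm)) / np.asarray(
            self.spacing_mm
        )
        idx = np.rint(frac).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(self.shape)):
            raise InputFormatError(f"point {tuple(point_mm)} mm maps outside the grid")
        return tuple(int(i) for i in idx)

    def compatible(self, other: "VoxelGrid", tol: float = 1e-3) -> bool:
        """Same shape and geometry up to float-storage round-off."""
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=tol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=tol)
        )


def _check_grid(grid: VoxelGrid, values: np.ndarray, what: str) -> None:
    if values.ndim != 3 or tuple(values.shape) != grid.shape:
        raise InputFormatError(
            f"{what} shape {values.shape} does not match grid shape {grid.shape}"
        )


@dataclass
class PETVolume:
    """A 3-D SUV field on a :class:`VoxelGrid`.

    ``values`` are finite and non-negative; negative inputs are clamped to
    zero (with a warning) because negative SUV is reconstruction noise.
    ``meta`` carries optional provenance such as ``case_id`` and lymphoma
    ``subtype`` (HL / FL / DLBCL).
    """

    grid: VoxelGrid
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        _check_grid(self.grid, self.values, "PET volume")
        if not np.all(np.isfinite(self.values)):
            raise InputFormatError("PET volume contains non-finite values")
        n_neg = int(np.count_nonzero(self.values < 0))
        if n_neg:
            log.warning("clamping %d negative SUV voxels to 0", n_neg)
            self.values = np.maximum(self.values, 0.0)


@dataclass
class MaskVolume:
    """Non-negative integer label field paired with a PET grid (0 = background)."""

    grid: VoxelGrid
    labels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.rint(arr)):
                raise InputFormatError("mask labels must be integers")
            arr = np.rint(arr)
        if arr.size and arr.min() < 0:
            raise InputFormatError("mask labels must be non-negative")
        self.labels = arr.astype(np.uint16)
        _check_grid(self.grid, self.labels, "mask")

    @property
    def is_binary(self) -> bool:
        return bool(self.labels.max(initial=0) <= 1)


def _grid_from_image(img: nib.Nifti1Image, path: Path) -> VoxelGrid:
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(z <= 0 for z in zooms):
        raise InputFormatError(f"{path}: non-positive voxel spacing {zooms}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return VoxelGrid(tuple(img.shape[:3]), zooms, origin)


def _load_canonical(path) -> tuple[nib.Nifti1Image, Path]:
    p = Path(path)
    if not p.exists():
        raise InputFormatError(f"no such file: {p}")
    try:
        img = nib.load(str(p))
    except Exception as exc:  # nibabel raises several types for bad files
        raise InputFormatError(f"{p}: not a readable NIfTI file ({exc})") from exc
    if img.ndim != 3:
        raise InputFormatError(f"{p}: expected a 3-D image, got {img.ndim}-D")
    return nib.as_closest_canonical(img), p


def _sidecar_meta(path: Path) -> dict:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            side = path.with_name(name[: -len(suffix)] + ".json")
            if side.exists():
                try:
                    return dict(json.loads(side.read_text()))
                except (OSError, json.JSONDecodeError):
                    log.warning("ignoring unreadable sidecar %s", side)
    return {}


def read_volume(path) -> PETVolume:
    """Read a 3-D NIfTI PET image as SUV, reoriented to RAS+.

    A JSON sidecar next to the image (same stem, ``.json``) is picked up as
    provenance metadata if present.
    """
    img, p = _load_canonical(path)
    grid = _grid_from_image(img, p)
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if not np.all(np.isfinite(data)):
        raise InputFormatError(f"{p}: PET image contains non-finite values")
    return PETVolume(grid, data, meta=_sidecar_meta(p))


def read_mask(path) -> MaskVolume:
    """Read a 3-D NIfTI label mask, reoriented to RAS+."""
    img, p = _load_canonical(path)
    grid = _grid_from_image(img, p)
    data = np.asanyarray(img.dataobj)
    if not np.all(np.isfinite(data)):
        raise InputFormatError(f"{p}: mask contains non-finite values")
    return MaskVolume(grid, data)


def write_volume(vol: PETVolume | MaskVolume, path) -> Path:
    """Write a PET volume (float32) or mask (uint16) as NIfTI-1.

    The header geometry is the grid's diagonal RAS+ affine, so a round trip
    through :func:`read_volume` / :func:`read_mask` preserves geometry
    exactly and values to storage precision.
    """
    p = Path(path)
    if isinstance(vol, MaskVolume):
        data = vol.labels.astype(np.uint16)
    elif isinstance(vol, PETVolume):
        data = vol.values.astype(np.float32)
    else:
        raise TypeError(f"cannot write object of type {type(vol).__name__}")
    img = nib.Nifti1Image(data, vol.grid.affine)
    img.header.set_zooms(vol.grid.spacing_mm)
    try:
        nib.save(img, str(p))
    except OSError as exc:
        raise InputFormatError(f"cannot write {p}: {exc}") from exc
    return p


def require_same_grid(a, b, what: str = "volumes") -> None:
    """Raise :class:`GridMismatchError` unless the two grids are compatible."""
    if not a.grid.compatible(b.grid):
        raise GridMismatchError(f"{what} are on different voxel grids")


#: Physical half-life of 18F in minutes.
F18_HALF_LIFE_MIN = 109.77


def suv_from_activity(
    conc_kBq_per_mL,
    injected_dose_MBq: float,
    residual_dose_MBq: float = 0.0,
    uptake_min: float = 60.0,
    half_life_min: float = F18_HALF_LIFE_MIN,
    weight_kg: float = 70.0,
):
    """Body-weight SUV from activity concentration.

    SUV = conc [kBq/mL] x body weight [g] / (net injected dose decayed to
    scan time [kBq]), assuming 1 g/mL tissue density.  The net dose is
    injected minus residual activity, decay-corrected over ``uptake_min``
    with the tracer half-life.  Accepts a scalar or an array concentration
    and returns the same shape.
    """
    if weight_kg <= 0:
        raise ValueError(f"weight must be positive, got {weight_kg}")
    if half_life_min <= 0:
        raise ValueError(f"half-life must be positive, got {half_life_min}")
    net_dose_MBq = injected_dose_MBq - residual_dose_MBq
    if net_dose_MBq <= 0:
        raise ValueError(f"net dose must be positive, got {net_dose_MBq} MBq")
    decay = 2.0 ** (-uptake_min / half_life_min)
    dose_kBq = net_dose_MBq * 1000.0 * decay
    conc = np.asarray(conc_kBq_per_mL, dtype=float)
    suv = conc * (weight_kg * 1000.0) / dose_kBq
    return float(suv) if np.isscalar(conc_kBq_per_mL) else suv
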