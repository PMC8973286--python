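"""Shared voxel-grid geometry and typed volume containers.

All volumes in the pipeline live on a :class:`VoxelGrid`: a shape, a physical
spacing in millimetres, and a 4x4 voxel-to-world affine (RAS, mm).  Arrays are
stored with axes ``(x, y, z)``; a 2-D slice mode is supported by carrying a
trailing singleton z axis, so every algorithm sees a 3-D array.

Volumes are thin dataclasses around a numpy array plus the grid, with the
invariants of each physical quantity enforced at construction:

* :class:`HUVolume` — CT numbers (water 0, air -1000).
* :class:`MuMap` — 511-keV linear attenuation coefficients in 1/cm.
* :class:`ActivityVolume` — emission activity concentration (arbitrary units).
* :class:`TissueLabelVolume` — integer tissue/ROI labels with a palette.

NIfTI-1 I/O goes through nibabel; label palettes travel as JSON sidecars.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger("petmrqual")

#: sanity ceiling for plausible human-tissue mu at 511 keV (1/cm); exceeding it
#: raises a warning flag, not an error (dense bone is ~0.17, metal would exceed)
MU_SANITY_MAX = 0.5


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


def _as_shape3(shape) -> tuple[int, int, int]:
    shape = tuple(int(s) for s in shape)
    if len(shape) == 2:
        shape = shape + (1,)
    if len(shape) != 3 or any(s < 1 for s in shape):
        raise ValueError(f"shape must be 2 or 3 positive integers, got {shape}")
    return shape


@dataclass(frozen=True)
class VoxelGrid:
    """Geometry shared by all volumes: shape, spacing (mm) and RAS affine."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "shape", _as_shape3(self.shape))
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) == 2:
            spacing = spacing + (1.0,)
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be positive, got {spacing}")
        object.__setattr__(self, "spacing", spacing)
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        aff = aff.copy()
        aff.flags.writeable = False
        object.__setattr__(self, "affine", aff)

    @classmethod
    def from_spacing(cls, shape, spacing, centered: bool = True) -> "VoxelGrid":
        """Axis-aligned grid; if *centered*, world origin is the volume centre."""
        shape3 = _as_shape3(shape)
        spacing = tuple(float(s) for s in spacing)
        if len(spacing) == 1:
            spacing = spacing * 3
        if len(spacing) == 2:
            spacing = spacing + (1.0,)
        aff = np.diag(list(spacing) + [1.0])
        if centered:
            aff[:3, 3] = [-sp * (n - 1) / 2.0 for sp, n in zip(spacing, shape3)]
        return cls(shape3, spacing, aff)

    @property
    def is_2d(self) -> bool:
        return self.shape[2] == 1

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to world mm."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def coordinate_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World-mm coordinates of all voxel centres, as three broadcast arrays."""
        idx = np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij")
        pts = np.stack([a.ravel() for a in idx], axis=-1)
        world = self.voxel_to_world(pts)
        return tuple(world[:, k].reshape(self.shape) for k in range(3))

    def same_geometry(self, other: "VoxelGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.affine, other.affine, atol=tol)
        )

    def require_same(self, other: "VoxelGrid", what: str = "volumes") -> None:
        if not self.same_geometry(other):
            raise GridMismatchError(f"{what} are not on the same grid")


def _check_array(grid: VoxelGrid, values: np.ndarray, name: str) -> np.ndarray:
    values = np.asarray(values)
    if values.ndim == 2:
        values = values[:, :, np.newaxis]
    if values.shape != grid.shape:
        raise ValueError(f"{name} shape {values.shape} != grid shape {grid.shape}")
    return values


@dataclass
class HUVolume:
    """CT volume in Hounsfield units."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self):
        v = _check_array(self.grid, self.values, "HU values").astype(float)
        if not np.all(np.isfinite(v)):
            raise ValueError("HU volume contains non-finite values")
        if v.min() < -1024.0 - 1e-6:
            raise ValueError(f"HU below -1024 ({v.min():.1f})")
        self.values = v


@dataclass
class ActivityVolume:
    """Emission activity concentration, arbitrary units, nonnegative."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self):
        v = _check_array(self.grid, self.values, "activity").astype(float)
        if not np.all(np.isfinite(v)):
            raise ValueError("activity volume contains non-finite values")
        if v.min() < 0:
            raise ValueError("activity must be nonnegative")
        self.values = v


@dataclass
class MuMap:
    """511-keV linear attenuation coefficient volume (1/cm).

    ``provenance`` records which arm of the comparison produced the map
    (``ct_derived``, ``mri_derived`` or ``ground_truth``); ``meta`` carries
    processing breadcrumbs (pipeline stages applied, fill fraction, flags).
    """

    grid: VoxelGrid
    values: np.ndarray
    provenance: str = "ground_truth"
    meta: dict = field(default_factory=dict)

    PROVENANCES = ("ct_derived", "mri_derived", "ground_truth")

    def __post_init__(self):
        v = _check_array(self.grid, self.values, "mu").astype(float)
        if not np.all(np.isfinite(v)):
            raise ValueError("mu-map contains non-finite values")
        if v.min() < 0:
            raise ValueError("mu must be nonnegative")
        if self.provenance not in self.PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if v.max() > MU_SANITY_MAX:
            # implausible for human head tissue; flag for QC1, do not refuse
            self.meta = dict(self.meta, implausible_mu_max=float(v.max()))
            warnings.warn(
                f"mu-map max {v.max():.3f} 1/cm exceeds sanity bound "
                f"{MU_SANITY_MAX}; flagged in meta",
                stacklevel=2,
            )
        self.values = v

    def with_values(self, values, **meta) -> "MuMap":
        return MuMap(self.grid, values, self.provenance, dict(self.meta, **meta))


@dataclass
class TissueLabelVolume:
    """Integer tissue/ROI labels plus a label -> name palette."""

    grid: VoxelGrid
    labels: np.ndarray
    palette: dict[int, str]

    def __post_init__(self):
        lab = _check_array(self.grid, self.labels, "labels")
        if not np.issubdtype(lab.dtype, np.integer):
            if not np.allclose(lab, np.round(lab)):
                raise ValueError("labels must be integers")
            lab = lab.astype(np.int32)
        self.labels = lab.astype(np.int32)
        self.palette = {int(k): str(v) for k, v in self.palette.items()}
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.palette)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from palette")

    def name_to_label(self) -> dict[str, int]:
        return {v: k for k, v in self.palette.items()}

    def mask_of(self, names) -> np.ndarray:
        """Boolean mask of voxels whose tissue name is in *names*."""
        inv = self.name_to_label()
        if isinstance(names, str):
            names = [names]
        unknown = [n for n in names if n not in inv]
        if unknown:
            raise KeyError(f"unknown tissue name(s): {unknown}")
        codes = [inv[n] for n in names]
        return np.isin(self.labels, codes)


# ---------------------------------------------------------------------------
# NIfTI-1 I/O


def save_nifti(volume, path) -> Path:
    """Write a typed volume (or raw array + grid pair) as NIfTI-1.

    Label volumes also write ``<stem>.palette.json`` next to the image.
    """
    path = Path(path)
    if isinstance(volume, TissueLabelVolume):
        data, grid = volume.labels.astype(np.int16), volume.grid
    else:
        data, grid = np.asarray(volume.values, dtype=np.float32), volume.grid
    img = nib.Nifti1Image(np.squeeze(data) if grid.is_2d else data, grid.affine)
    img.header.set_zooms(grid.spacing[: 2 if grid.is_2d else 3])
    nib.save(img, str(path))
    if isinstance(volume, TissueLabelVolume):
        sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz
        sidecar = Path(str(sidecar) + ".palette.json")
        sidecar.write_text(
            json.dumps({str(k): v for k, v in volume.palette.items()}, indent=1)
        )
    return path


def _load_array_grid(path) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 2:
        data = data[:, :, np.newaxis]
    affine = img.affine.copy()
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if len(spacing) < 3:
        spacing = spacing + (1.0,) * (3 - len(spacing))
    grid = VoxelGrid(data.shape, spacing, affine)
    return data, grid


def load_hu(path) -> HUVolume:
    data, grid = _load_array_grid(path)
    return HUVolume(grid, data)


def load_mu(path, provenance: str = "ground_truth") -> MuMap:
    data, grid = _load_array_grid(path)
    return MuMap(grid, np.clip(data, 0, None), provenance)


def load_activity(path) -> ActivityVolume:
    data, grid = _load_array_grid(path)
    return ActivityVolume(grid, np.clip(data, 0, None))


def load_labels(path, palette: dict[int, str] | None = None) -> TissueLabelVolume:
    data, grid = _load_array_grid(path)
    if palette is None:
        sidecar = Path(str(Path(path)).replace(".nii.gz", "").replace(".nii", "") + ".palette.json")
        if sidecar.exists():
            palette = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
        else:
            palette = {int(k): f"label_{int(k)}" for k in np.unique(data)}
    return TissueLabelVolume(grid, np.round(data).astype(np.int32), palette)
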