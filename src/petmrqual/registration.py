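"""Rigid-body registration with a normalized-mutual-information objective.

Aligns the CT volume to the reference (morphologic/PET) space.  The objective
is normalized mutual information, NMI = (H(A) + H(B)) / H(A, B), computed from
a joint intensity histogram over the overlapping support; it is maximal for
identical images and ~1 for independent ones.  Optimization is gradient-free
(Powell) over the 6 rigid degrees of freedom (3 in single-slice 2-D mode),
run coarse-to-fine over a Gaussian image pyramid.

Rotations are intrinsic Z-Y-X Euler angles in degrees about a configurable
world-space centre (by default the fixed image's centre of mass, which
decorrelates rotation from translation); translations are in mm, RAS.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation

from .core import MuMap, VoxelGrid


class RegistrationError(RuntimeError):
    pass


def _wrap_angles(angles):
    # wrap to (-180, 180]
    a = (np.asarray(angles, dtype=float) + 180.0) % 360.0 - 180.0
    a[a == -180.0] = 180.0
    return tuple(float(v) for v in a)


@dataclass(frozen=True)
class RigidTransform:
    """6-DOF rigid map of world coordinates (mm): rotate about *center*, then
    translate.  ``apply(x) = R @ (x - c) + c + t``."""

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "rotation_deg", _wrap_angles(self.rotation_deg))
        object.__setattr__(
            self, "translation_mm", tuple(float(v) for v in self.translation_mm)
        )
        object.__setattr__(
            self, "center_mm", tuple(float(v) for v in self.center_mm)
        )

    @property
    def rotation_matrix(self) -> np.ndarray:
        rx, ry, rz = self.rotation_deg
        return Rotation.from_euler("ZYX", [rz, ry, rx], degrees=True).as_matrix()

    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 world->world matrix."""
        R = self.rotation_matrix
        c = np.asarray(self.center_mm)
        t = np.asarray(self.translation_mm)
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = c + t - R @ c
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        m = self.matrix()
        return pts @ m[:3, :3].T + m[:3, 3]

    def inverse(self) -> "RigidTransform":
        R = self.rotation_matrix
        rz, ry, rx = Rotation.from_matrix(R.T).as_euler("ZYX", degrees=True)
        t_inv = -R.T @ np.asarray(self.translation_mm)
        return RigidTransform((rx, ry, rz), tuple(t_inv), self.center_mm)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying *other* first, then self."""
        m = self.matrix() @ other.matrix()
        R = m[:3, :3]
        rz, ry, rx = Rotation.from_matrix(R).as_euler("ZYX", degrees=True)
        c = np.asarray(self.center_mm)
        t = m[:3, 3] - c + R @ c
        return RigidTransform((rx, ry, rz), tuple(t), self.center_mm)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "rotation_deg": list(self.rotation_deg),
            "translation_mm": list(self.translation_mm),
            "center_mm": list(self.center_mm),
            "convention": "RAS, intrinsic ZYX",
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            tuple(d["rotation_deg"]),
            tuple(d["translation_mm"]),
            tuple(d.get("center_mm", (0.0, 0.0, 0.0))),
        )


def transform_discrepancy(
    a: RigidTransform, b: RigidTransform, point=(0.0, 0.0, 0.0)
) -> tuple[float, float]:
    """(rotation error deg, displacement error mm at *point*) between two
    transforms; zero for identical maps regardless of parameterization."""
    rel = np.linalg.inv(b.matrix()) @ a.matrix()
    angle = np.degrees(
        np.linalg.norm(Rotation.from_matrix(rel[:3, :3]).as_rotvec())
    )
    p = np.asarray(point, dtype=float)
    disp = float(np.linalg.norm(rel[:3, :3] @ p + rel[:3, 3] - p))
    return angle, disp


# ---------------------------------------------------------------------------
# Normalized mutual information


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def nmi(
    a: np.ndarray,
    b: np.ndarray,
    bins: int = 32,
    mask: np.ndarray | None = None,
) -> float:
    """Normalized mutual information (Studholme), always >= 1."""
    if bins < 8:
        raise ValueError("bins must be >= 8")
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("images must have the same number of voxels")
    keep = np.isfinite(a) & np.isfinite(b)
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool).ravel()
    if not keep.any():
        raise RegistrationError("empty overlap between images")
    joint, _, _ = np.histogram2d(a[keep], b[keep], bins=bins)
    p = joint / joint.sum()
    h_a = _entropy(p.sum(axis=1))
    h_b = _entropy(p.sum(axis=0))
    h_ab = _entropy(p.ravel())
    if h_ab == 0.0:
        # both images constant on the overlap: define NMI at its floor
        return 1.0
    return (h_a + h_b) / h_ab


# ---------------------------------------------------------------------------
# Rigid registration


@dataclass
class RegistrationOptions:
    bins: int = 32
    pyramid_factors: tuple[int, ...] = (4, 2, 1)
    max_iter_per_level: int = 100
    xtol: float = 0.002
    com_init: bool = True  # initialize translation from centre-of-mass offset
    # coarse exhaustive sweep per rotation axis at the coarsest level, to step
    # over local optima where translation compensates a missed rotation
    rotation_sweep_deg: float = 12.0
    rotation_sweep_step_deg: float = 3.0
    _: dict = field(default_factory=dict, repr=False)


def _downsample(values: np.ndarray, grid: VoxelGrid, factor: int):
    if factor == 1:
        return values, grid
    sigma = [factor / 2.0 if n > 1 else 0.0 for n in grid.shape]
    sm = ndimage.gaussian_filter(values, sigma=sigma, mode="nearest")
    sl = tuple(
        slice(None, None, factor) if n > 1 else slice(None) for n in grid.shape
    )
    out = sm[sl]
    aff = grid.affine.copy()
    scale = [factor if n > 1 else 1 for n in grid.shape]
    aff[:3, :3] = aff[:3, :3] @ np.diag(scale)
    spacing = tuple(sp * s for sp, s in zip(grid.spacing, scale))
    return out, VoxelGrid(out.shape, spacing, aff)


def _resample_values(
    values: np.ndarray, src: VoxelGrid, dst: VoxelGrid, transform: RigidTransform
):
    idx = np.meshgrid(*[np.arange(n) for n in dst.shape], indexing="ij")
    pts = np.stack([a.ravel() for a in idx], axis=-1).astype(float)
    world_s = transform.inverse().apply(dst.voxel_to_world(pts))
    src_idx = src.world_to_voxel(world_s)
    shape = np.asarray(src.shape, dtype=float)
    inside = np.all((src_idx >= 0) & (src_idx <= shape - 1), axis=1)
    vals = ndimage.map_coordinates(values, src_idx.T, order=1, mode="nearest")
    return vals.reshape(dst.shape), inside.reshape(dst.shape)


def _params_to_transform(params, center, is_2d):
    if is_2d:
        tx, ty, rz = params
        return RigidTransform((0.0, 0.0, rz), (tx, ty, 0.0), center)
    tx, ty, tz, rx, ry, rz = params
    return RigidTransform((rx, ry, rz), (tx, ty, tz), center)


def register_rigid(
    moving_values: np.ndarray,
    moving_grid: VoxelGrid,
    fixed_values: np.ndarray,
    fixed_grid: VoxelGrid,
    opts: RegistrationOptions | None = None,
) -> tuple[RigidTransform, float]:
    """Find the rigid transform (moving world -> fixed world) maximizing NMI.

    Returns ``(transform, final_nmi)``.  Deterministic: no stochastic sampling
    is used.  Raises :class:`RegistrationError` when the volumes do not
    overlap at the identity start.
    """
    opts = opts or RegistrationOptions()
    moving_values = np.asarray(moving_values, dtype=float)
    fixed_values = np.asarray(fixed_values, dtype=float)
    is_2d = fixed_grid.is_2d and moving_grid.is_2d

    # rotation centre: fixed-image centre of mass in world mm
    w = np.clip(fixed_values - fixed_values.min(), 0, None)
    if w.sum() == 0:
        com_vox = (np.asarray(fixed_grid.shape) - 1) / 2.0
    else:
        com_vox = np.asarray(ndimage.center_of_mass(w))
    center = tuple(fixed_grid.voxel_to_world(com_vox))

    identity = _params_to_transform(
        (0.0,) * (3 if is_2d else 6), center, is_2d
    )
    res0, inside0 = _resample_values(
        moving_values, moving_grid, fixed_grid, identity
    )
    if not inside0.any():
        raise RegistrationError(
            "no overlap between moving and fixed volumes at the identity "
            "start; provide a manual initialization"
        )
    nmi_identity = nmi(res0, fixed_values, opts.bins, mask=inside0)

    params = np.zeros(3 if is_2d else 6)
    if opts.com_init:
        wm = np.clip(moving_values - moving_values.min(), 0, None)
        if wm.sum() > 0:
            com_m = moving_grid.voxel_to_world(np.asarray(ndimage.center_of_mass(wm)))
            delta = np.asarray(center) - np.asarray(com_m)
            params[: (2 if is_2d else 3)] = delta[: (2 if is_2d else 3)]

    rot_slice = slice(2, 3) if is_2d else slice(3, 6)
    for level, factor in enumerate(opts.pyramid_factors):
        f_vals, f_grid = _downsample(fixed_values, fixed_grid, factor)
        m_vals, m_grid = _downsample(moving_values, moving_grid, factor)

        def objective(p):
            t = _params_to_transform(p, center, is_2d)
            res, inside = _resample_values(m_vals, m_grid, f_grid, t)
            if inside.mean() < 0.05:
                return 0.0  # essentially no overlap: worst score
            return -nmi(res, f_vals, opts.bins, mask=inside)

        if level == 0 and opts.rotation_sweep_deg > 0:
            sweep = np.arange(
                -opts.rotation_sweep_deg,
                opts.rotation_sweep_deg + 1e-9,
                opts.rotation_sweep_step_deg,
            )
            for axis in range(rot_slice.start, rot_slice.stop):
                best = (objective(params), params[axis])
                for ang in sweep:
                    trial = params.copy()
                    trial[axis] = ang
                    score = objective(trial)
                    if score < best[0]:
                        best = (score, ang)
                params[axis] = best[1]

        result = optimize.minimize(
            objective,
            params,
            method="Powell",
            options={
                "xtol": opts.xtol,
                "ftol": 1e-8,
                "maxiter": opts.max_iter_per_level,
            },
        )
        params = result.x

    best = _params_to_transform(params, center, is_2d)
    res, inside = _resample_values(moving_values, moving_grid, fixed_grid, best)
    nmi_best = nmi(res, fixed_values, opts.bins, mask=inside)
    if nmi_best < nmi_identity:
        # optimizer contract: never return worse than the identity start
        return identity, nmi_identity
    return best, nmi_best


# ---------------------------------------------------------------------------
# Misregistration surrogate for QC1


def registration_residual(
    ctac_mu: MuMap,
    mrac_mu: MuMap,
    soft_tissue_mask: np.ndarray,
    bone_mu_threshold: float = 0.12,
) -> dict:
    """Automated surrogate for visual misregistration review.

    Reports mean and 95th-percentile |delta mu| over soft tissue plus the Dice
    overlap of the thresholded bone shells.  These numbers are emitted for a
    human reader; they carry no pass/fail semantics by themselves.
    """
    ctac_mu.grid.require_same(mrac_mu.grid, "mu-maps")
    mask = np.asarray(soft_tissue_mask, dtype=bool)
    if not mask.any():
        raise ValueError("soft-tissue mask is empty")
    d = np.abs(ctac_mu.values - mrac_mu.values)[mask]
    bone_a = ctac_mu.values > bone_mu_threshold
    bone_b = mrac_mu.values > bone_mu_threshold
    denom = bone_a.sum() + bone_b.sum()
    dice = 1.0 if denom == 0 else 2.0 * float((bone_a & bone_b).sum()) / float(denom)
    return {
        "mean_abs_dmu": float(d.mean()),
        "p95_abs_dmu": float(np.percentile(d, 95)),
        "bone_dice": dice,
        "bone_mu_threshold": bone_mu_threshold,
    }
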