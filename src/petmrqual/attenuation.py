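"""CT-side attenuation-map preparation.

Turns a head CT into a 511-keV attenuation map ready for PET attenuation
correction, mirroring the standard CT-based AC pipeline:

1. strip non-patient structures (bed, head holder) by keeping the largest
   above-threshold connected component;
2. (registration to the reference space lives in :mod:`.registration`);
3. convert Hounsfield units to 511-keV linear attenuation coefficients with a
   bilinear calibration (soft-tissue branch scaled from water, steeper bone
   branch above a breakpoint near 50 HU);
4. smooth with a Gaussian matched to the PET scanner's spatial resolution and
   resample into the PET voxel grid;
5. fill any voxels the CT does not cover from the MRI-based map.

Each stage stamps a provenance tag in ``MuMap.meta["stages"]`` so the fixed
composition order (strip -> register -> convert -> smooth -> resample -> fill)
can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import GridMismatchError, HUVolume, MuMap, VoxelGrid

STAGE_ORDER = ("strip", "register", "convert", "smooth", "resample", "fill")

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


class EmptyScanError(ValueError):
    """No above-threshold structure found in the CT."""


def _record_stage(meta: dict, stage: str) -> dict:
    done = list(meta.get("stages", []))
    if stage in STAGE_ORDER and done:
        last = max(STAGE_ORDER.index(s) for s in done if s in STAGE_ORDER)
        if STAGE_ORDER.index(stage) < last:
            raise ValueError(
                f"pipeline stage {stage!r} applied after {STAGE_ORDER[last]!r}; "
                f"fixed order is {STAGE_ORDER}"
            )
    done.append(stage)
    return dict(meta, stages=done)


@dataclass(frozen=True)
class HUCalibration:
    """Bilinear HU -> mu(511 keV) map.

    Below the breakpoint mu scales linearly from water
    (``mu = mu_water + slope_low * HU``, which sends -1000 HU to ~0 and 0 HU to
    ``mu_water``); above it a steeper bone branch applies, continuous at the
    breakpoint.  Output is clipped at zero.
    """

    breakpoint_hu: float = 50.0
    mu_water: float = 0.096
    slope_low: float = 0.096 / 1000.0
    slope_high: float = (0.151 - (0.096 + 0.096 / 1000.0 * 50.0)) / (1000.0 - 50.0)

    def __post_init__(self):
        if self.mu_water <= 0:
            raise ValueError("mu_water must be positive")

    def mu_at_breakpoint(self) -> float:
        return self.mu_water + self.slope_low * self.breakpoint_hu

    def __call__(self, hu: np.ndarray) -> np.ndarray:
        hu = np.asarray(hu, dtype=float)
        low = self.mu_water + self.slope_low * hu
        high = self.mu_at_breakpoint() + self.slope_high * (hu - self.breakpoint_hu)
        return np.clip(np.where(hu <= self.breakpoint_hu, low, high), 0.0, None)


def strip_nonpatient(ct: HUVolume, air_threshold: float = -200.0) -> HUVolume:
    """Remove bed/head-holder structures, keeping the largest component.

    Voxels outside the largest connected component of ``HU > air_threshold``
    are set to -1000 HU; the kept component is untouched.
    """
    fg = ct.values > air_threshold
    comp, n = ndimage.label(fg)
    if n == 0:
        raise EmptyScanError(
            f"no voxels above {air_threshold} HU; empty or corrupted scan"
        )
    sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
    keep = 1 + int(np.argmax(sizes))
    out = np.where(comp == keep, ct.values, -1000.0)
    return HUVolume(ct.grid, out)


def hu_to_mu(ct: HUVolume, cal: HUCalibration | None = None) -> MuMap:
    """Convert Hounsfield units to 511-keV linear attenuation (1/cm)."""
    cal = cal or HUCalibration()
    mu = MuMap(ct.grid, cal(ct.values), provenance="ct_derived")
    mu.meta = _record_stage(mu.meta, "convert")
    return mu


def smooth_to_pet_resolution(mu: MuMap, fwhm_mm: float) -> MuMap:
    """Gaussian-smooth to match PET resolution; FWHM in mm, grid-aware.

    ``fwhm_mm == 0`` is the identity.  Boundary mode is "nearest" so edge mu
    is held rather than bleeding in air from outside the array.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        out = mu.with_values(mu.values)
    else:
        sigma_vox = [
            fwhm_mm * FWHM_TO_SIGMA / sp if n > 1 else 0.0
            for sp, n in zip(mu.grid.spacing, mu.grid.shape)
        ]
        sm = ndimage.gaussian_filter(mu.values, sigma=sigma_vox, mode="nearest")
        out = mu.with_values(np.clip(sm, 0.0, None))
    out.meta = _record_stage(out.meta, "smooth")
    out.meta["smooth_fwhm_mm"] = float(fwhm_mm)
    return out


def resample(
    mu: MuMap, target: VoxelGrid, transform=None
) -> tuple[MuMap, np.ndarray]:
    """Trilinear resampling of a mu-map onto *target*, returning a coverage mask.

    ``transform`` (a :class:`~petmrqual.registration.RigidTransform`) maps the
    source world frame to the target world frame; ``None`` means identity.
    Voxels whose pull-back falls outside the source field of view get mu = 0
    and ``coverage == False``.
    """
    idx = np.meshgrid(*[np.arange(n) for n in target.shape], indexing="ij")
    pts = np.stack([a.ravel() for a in idx], axis=-1).astype(float)
    world_t = target.voxel_to_world(pts)
    if transform is not None:
        world_s = transform.inverse().apply(world_t)
    else:
        world_s = world_t
    src_idx = mu.grid.world_to_voxel(world_s)

    shape = np.asarray(mu.grid.shape, dtype=float)
    inside = np.all((src_idx >= 0) & (src_idx <= shape - 1), axis=1)
    vals = ndimage.map_coordinates(
        mu.values, src_idx.T, order=1, mode="constant", cval=0.0
    )
    vals[~inside] = 0.0
    coverage = inside.reshape(target.shape)
    out = MuMap(
        target,
        np.clip(vals.reshape(target.shape), 0.0, None),
        provenance=mu.provenance,
        meta=_record_stage(mu.meta, "resample"),
    )
    return out, coverage


def fill_missing_from_mrac(
    ctac: MuMap, coverage: np.ndarray, mrac: MuMap
) -> MuMap:
    """Copy MRI-based mu into voxels the CT did not cover."""
    try:
        ctac.grid.require_same(mrac.grid)
    except GridMismatchError:
        raise GridMismatchError(
            "CT-based and MRI-based mu-maps must share the PET grid before "
            "gap-filling"
        ) from None
    coverage = np.asarray(coverage, dtype=bool)
    if coverage.shape != ctac.grid.shape:
        raise ValueError("coverage mask shape does not match the grid")
    out = np.where(coverage, ctac.values, mrac.values)
    fill_fraction = float((~coverage).mean())
    result = MuMap(
        ctac.grid,
        out,
        provenance="ct_derived",
        meta=_record_stage(ctac.meta, "fill"),
    )
    result.meta["fill_fraction"] = fill_fraction
    return result
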