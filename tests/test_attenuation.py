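"""CT-side mu-map preparation: stripping, HU->mu calibration, PSF matching,
resampling and MRAC gap-filling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from petmrqual import (
    HUCalibration,
    HUVolume,
    MuMap,
    RigidTransform,
    VoxelGrid,
    fill_missing_from_mrac,
    hu_to_mu,
    resample,
    smooth_to_pet_resolution,
    strip_nonpatient,
)
from petmrqual.attenuation import EmptyScanError


def grid(shape, spacing=2.0):
    return VoxelGrid.from_spacing(shape, (spacing,) * len(shape))


# -- strip_nonpatient -------------------------------------------------------


def test_strip_head_only_is_identity(phantom2d):
    _, ct, _ = phantom2d
    out = strip_nonpatient(ct)
    assert np.array_equal(out.values, ct.values)


def test_strip_removes_disjoint_bed_slab(phantom2d):
    _, ct, _ = phantom2d
    vals = ct.values.copy()
    slab = np.zeros_like(vals, dtype=bool)
    slab[:, :3, :] = True  # flat "bed" at the volume edge, disjoint from head
    vals[slab] = 100.0
    out = strip_nonpatient(HUVolume(ct.grid, vals))
    assert np.all(out.values[slab] == -1000.0)
    head = ct.values > -200.0
    assert np.array_equal(out.values[head], ct.values[head])


def test_strip_matches_brute_force_largest_component():
    rng = np.random.default_rng(4)
    g = grid((10, 10, 10))
    vals = np.where(rng.random(g.shape) < 0.25, 100.0, -1000.0)
    ct = HUVolume(g, vals)
    out = strip_nonpatient(ct, air_threshold=-200.0)
    # oracle: exhaustive component search via scipy label + manual size count
    comp, n = ndimage.label(vals > -200.0)
    sizes = [(comp == i).sum() for i in range(1, n + 1)]
    keep = 1 + int(np.argmax(sizes))
    expected = np.where(comp == keep, vals, -1000.0)
    assert np.array_equal(out.values, expected)


def test_strip_empty_scan_errors():
    g = grid((8, 8))
    with pytest.raises(EmptyScanError):
        strip_nonpatient(HUVolume(g, np.full(g.shape, -1000.0)))


# -- hu_to_mu ---------------------------------------------------------------


def test_hu_to_mu_reference_points():
    """Hand evaluation of the default bilinear calibration.

    water (0 HU): mu_water = 0.096.  air (-1000 HU): 0.096*(1-1) = 0.
    dense bone (+1000 HU): breakpoint value 0.096*1.05 = 0.1008 plus the bone
    slope (0.151-0.1008)/950 over 950 HU = 0.151 exactly.
    """
    cal = HUCalibration()
    assert cal(np.array(0.0)) == pytest.approx(0.096)
    assert cal(np.array(-1000.0)) == pytest.approx(0.0, abs=1e-12)
    mu_bp = 0.096 * (1.0 + 50.0 / 1000.0)
    expected_bone = mu_bp + (0.151 - mu_bp) / 950.0 * 950.0
    assert cal(np.array(1000.0)) == pytest.approx(expected_bone)
    assert expected_bone == pytest.approx(0.151)


@settings(deadline=None, derandomize=True, max_examples=200)
@given(st.floats(min_value=-1024, max_value=3000))
def test_hu_to_mu_monotone_and_continuous(h):
    cal = HUCalibration()
    eps = 0.5
    assert cal(np.array(h + eps)) >= cal(np.array(h))
    # continuity at the breakpoint
    assert cal(np.array(cal.breakpoint_hu - 1e-9)) == pytest.approx(
        cal(np.array(cal.breakpoint_hu + 1e-9)), abs=1e-9
    )


def test_hu_to_mu_volume_and_provenance(phantom2d):
    _, ct, _ = phantom2d
    mu = hu_to_mu(ct)
    assert mu.provenance == "ct_derived"
    assert mu.meta["stages"] == ["convert"]
    assert mu.values.min() >= 0


# -- smoothing --------------------------------------------------------------


def test_smooth_zero_fwhm_identity(mu2d):
    out = smooth_to_pet_resolution(hu_to_mu_like(mu2d), 0.0)
    assert np.array_equal(out.values, mu2d.values)


def hu_to_mu_like(mu):
    return MuMap(mu.grid, mu.values, mu.provenance, dict(mu.meta))


def test_smooth_constant_map_unchanged():
    g = grid((32, 32))
    mu = MuMap(g, np.full(g.shape, 0.096))
    out = smooth_to_pet_resolution(mu, 6.0)
    assert np.allclose(out.values, 0.096)


def test_smooth_delta_matches_gaussian_kernel():
    g = grid((21, 21, 21), spacing=2.0)
    vals = np.zeros(g.shape)
    vals[10, 10, 10] = 0.4
    fwhm = 4.0
    out = smooth_to_pet_resolution(MuMap(g, vals), fwhm)
    # oracle: direct evaluation of the sampled, renormalized Gaussian kernel
    # (1e-5 headroom for the implementation's 4-sigma kernel truncation)
    sigma_vox = fwhm / 2.3548200450309493 / 2.0
    ax = np.arange(21) - 10.0
    k1 = np.exp(-(ax**2) / (2 * sigma_vox**2))
    k1 /= k1.sum()
    expected = 0.4 * k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
    assert np.allclose(out.values, expected, atol=1e-5)


def test_smooth_conserves_interior_mass(mu2d):
    out = smooth_to_pet_resolution(hu_to_mu_like(mu2d), 4.0)
    # head is well inside the FOV, so total mu mass is conserved
    assert out.values.sum() == pytest.approx(mu2d.values.sum(), rel=1e-3)


def test_smooth_negative_fwhm_rejected(mu2d):
    with pytest.raises(ValueError):
        smooth_to_pet_resolution(mu2d, -1.0)


# -- resample ---------------------------------------------------------------


def test_resample_identity_bitwise(mu2d):
    out, cov = resample(hu_to_mu_like(mu2d), mu2d.grid, None)
    assert np.array_equal(out.values, mu2d.values)
    assert cov.all()


def test_resample_integer_shift_of_constant():
    g = grid((16, 16))
    mu = MuMap(g, np.full(g.shape, 0.1))
    t = RigidTransform(translation_mm=(4.0, 0.0, 0.0))  # 2 voxels
    out, cov = resample(mu, g, t)
    assert np.allclose(out.values[cov], 0.1)
    assert cov.sum() < cov.size  # shifted border leaves the source FOV


def test_resample_half_voxel_shift_of_ramp():
    """Trilinear interpolation of a linear ramp is exact: shifting by half a
    voxel samples the analytic ramp at x - 1 mm."""
    g = grid((16, 16), spacing=2.0)
    x, _, _ = g.coordinate_arrays()
    ramp = 0.01 * (x - x.min())  # mu proportional to world x
    mu = MuMap(g, ramp)
    t = RigidTransform(translation_mm=(1.0, 0.0, 0.0))
    out, cov = resample(mu, g, t)
    expected = ramp - 0.01
    inner = cov & (expected >= 0)
    assert np.allclose(out.values[inner], expected[inner], atol=1e-9)


def test_resample_round_trip_small_error(mu2d):
    sm = smooth_to_pet_resolution(hu_to_mu_like(mu2d), 6.0)
    t = RigidTransform(rotation_deg=(0, 0, 7.0), translation_mm=(3.0, -2.0, 0.0))
    fwd, cov1 = resample(sm, sm.grid, t)
    back, cov2 = resample(fwd, sm.grid, t.inverse())
    interior = ndimage.binary_erosion(
        cov1 & cov2, structure=np.ones((3, 3, 1), bool), iterations=3
    ) & (sm.values > 0.01)
    err = back.values[interior] - sm.values[interior]
    rel_rmse = np.sqrt((err**2).mean()) / np.sqrt((sm.values[interior] ** 2).mean())
    assert rel_rmse < 0.02


def test_resample_matches_simpleitk():
    """Independent cross-check of the rigid resampling against SimpleITK."""
    sitk = pytest.importorskip("SimpleITK")
    g = grid((24, 24, 24), spacing=2.0)
    x, y, z = g.coordinate_arrays()
    vals = 0.3 * np.exp(-((x**2 + y**2 + z**2) / 400.0))
    mu = MuMap(g, vals)
    t = RigidTransform(rotation_deg=(0, 0, 10.0), translation_mm=(3.0, 1.0, 0.0))
    ours, cov = resample(mu, g, t)

    img = sitk.GetImageFromArray(np.ascontiguousarray(vals.T))  # zyx order
    img.SetSpacing(g.spacing)
    origin = g.affine[:3, 3]
    img.SetOrigin(tuple(origin))
    et = sitk.Euler3DTransform()
    et.SetCenter((0.0, 0.0, 0.0))
    rz = np.deg2rad(10.0)
    et.SetRotation(0.0, 0.0, rz)
    et.SetTranslation((3.0, 1.0, 0.0))
    # SimpleITK resamples with the inverse mapping convention
    res = sitk.Resample(img, img, et.GetInverse(), sitk.sitkLinear, 0.0)
    theirs = sitk.GetArrayFromImage(res).T
    interior = ndimage.binary_erosion(cov, iterations=2)
    assert np.allclose(ours.values[interior], theirs[interior], atol=1e-4)


# -- gap filling ------------------------------------------------------------


def test_fill_full_coverage_identity(mu2d):
    mrac = MuMap(mu2d.grid, np.full(mu2d.grid.shape, 0.05), "mri_derived")
    out = fill_missing_from_mrac(hu_to_mu_like(mu2d), np.ones(mu2d.grid.shape, bool), mrac)
    assert np.array_equal(out.values, mu2d.values)
    assert out.meta["fill_fraction"] == 0.0


def test_fill_uncovered_slices_copied():
    g = grid((8, 8, 12))
    ct = MuMap(g, np.full(g.shape, 0.096), "ct_derived")
    mrac = MuMap(g, np.full(g.shape, 0.05), "mri_derived")
    cov = np.ones(g.shape, bool)
    cov[:, :, :5] = False  # bottom 5 axial slices missing from the CT
    out = fill_missing_from_mrac(ct, cov, mrac)
    assert np.all(out.values[:, :, :5] == 0.05)
    assert np.all(out.values[:, :, 5:] == 0.096)
    assert out.meta["fill_fraction"] == pytest.approx(5 / 12)


def test_fill_random_mask_matches_per_voxel_loop():
    rng = np.random.default_rng(9)
    g = grid((5, 5, 5))
    a = MuMap(g, rng.random(g.shape) * 0.1, "ct_derived")
    b = MuMap(g, rng.random(g.shape) * 0.1, "mri_derived")
    cov = rng.random(g.shape) > 0.3
    out = fill_missing_from_mrac(a, cov, b)
    for idx in np.ndindex(g.shape):
        expected = a.values[idx] if cov[idx] else b.values[idx]
        assert out.values[idx] == expected


def test_fill_grid_mismatch_rejected(mu2d):
    other = MuMap(grid((8, 8)), np.zeros((8, 8, 1)), "mri_derived")
    with pytest.raises(Exception, match="grid"):
        fill_missing_from_mrac(mu2d, np.ones(mu2d.grid.shape, bool), other)


def test_stage_order_enforced(mu2d):
    sm = smooth_to_pet_resolution(hu_to_mu_like(mu2d), 2.0)
    out, cov = resample(sm, sm.grid, None)
    mrac = MuMap(sm.grid, np.zeros(sm.grid.shape), "mri_derived")
    final = fill_missing_from_mrac(out, cov, mrac)
    assert final.meta["stages"] == ["smooth", "resample", "fill"]
    with pytest.raises(ValueError, match="order"):
        smooth_to_pet_resolution(final, 2.0)
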