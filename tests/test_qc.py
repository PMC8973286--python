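"""Voxelwise bias, cumulative curves, ROI statistics and the QC1-QC4
qualification verdict."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petmrqual import (
    ActivityVolume,
    MuMap,
    TissueLabelVolume,
    VoxelGrid,
    bland_altman,
    brain_mask,
    cumulative_curve,
    merge_rois,
    qc1_flags,
    qc2_evaluate,
    qc3_evaluate,
    qc4_evaluate,
    roi_report,
    voxelwise_bias,
)
from petmrqual.qc import BiasVolume, QCResult


def grid(shape):
    return VoxelGrid.from_spacing(shape, (2.0,) * len(shape))


def make_bias(values):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None, None]
    g = VoxelGrid.from_spacing(values.shape, (2.0,) * 3)
    return BiasVolume(g, values, np.ones(values.shape, bool))


def labeled(shape, labels, palette):
    return TissueLabelVolume(grid(shape), labels, palette)


# -- brain mask & ROI merge -------------------------------------------------


def test_brain_mask_empty_errors():
    lab = labeled((4, 4), np.zeros((4, 4, 1), int), {0: "air"})
    with pytest.raises((ValueError, KeyError)):
        brain_mask(lab)


def test_brain_mask_gm_only_exact():
    arr = np.zeros((4, 4, 1), int)
    arr[1:3, 1:3] = 10
    lab = labeled((4, 4), arr, {0: "air", 10: "gm_frontal"})
    m = brain_mask(lab, ("gm_frontal",))
    assert np.array_equal(m, arr == 10)


def test_brain_mask_matches_membership_loop(phantom2d):
    labels, _, _ = phantom2d
    m = brain_mask(labels)
    brain_codes = {
        code for code, name in labels.palette.items()
        if name.startswith("gm_") or name in ("white_matter", "cerebellum_gm")
    }
    for idx in zip(*np.nonzero(np.ones(labels.grid.shape))):
        assert m[idx] == (int(labels.labels[idx]) in brain_codes)


def test_merge_rois_identity_and_union(phantom2d):
    labels, _, _ = phantom2d
    ident = merge_rois(labels, {"frontal": ["gm_frontal"]})
    assert np.array_equal(ident.labels != 0, labels.mask_of("gm_frontal"))
    merged = merge_rois(labels, {"cortex": ["gm_frontal", "gm_parietal"]})
    union = labels.mask_of(["gm_frontal", "gm_parietal"])
    assert np.array_equal(merged.labels == 1, union)


def test_merge_rois_overlap_rejected(phantom2d):
    labels, _, _ = phantom2d
    with pytest.raises(ValueError, match="overlap"):
        merge_rois(labels, {"a": ["gm_frontal"], "b": ["gm_frontal"]})


# -- voxelwise bias ---------------------------------------------------------


def test_bias_identity_and_scale():
    g = grid((6, 6))
    c = ActivityVolume(g, np.full(g.shape, 10.0))
    mask = np.ones(g.shape, bool)
    assert np.all(voxelwise_bias(c, c, mask).values == 0.0)
    m = ActivityVolume(g, 1.05 * c.values)
    b = voxelwise_bias(m, c, mask)
    assert np.allclose(b.values[b.mask], 5.0)


def test_bias_hand_arithmetic_toy():
    g = grid((3, 1))
    c = ActivityVolume(g, np.array([10.0, 20.0, 40.0]).reshape(3, 1, 1))
    m = ActivityVolume(g, np.array([9.0, 22.0, 40.0]).reshape(3, 1, 1))
    b = voxelwise_bias(m, c, np.ones(g.shape, bool))
    assert np.allclose(b.values.ravel(), [-10.0, 10.0, 0.0])


def test_bias_low_denominator_excluded():
    g = grid((4, 1))
    c = ActivityVolume(g, np.array([10.0, 10.0, 10.0, 0.001]).reshape(4, 1, 1))
    m = ActivityVolume(g, np.full(g.shape, 10.0))
    b = voxelwise_bias(m, c, np.ones(g.shape, bool), denom_floor_frac=0.01)
    assert b.meta["n_excluded_low_denominator"] == 1
    assert b.mask.sum() == 3


# -- cumulative curve & QC2 -------------------------------------------------


def test_cumulative_curve_all_zero():
    b = make_bias(np.zeros(10))
    curve = cumulative_curve(b)
    assert np.all(curve["fraction"] == 1.0)


def test_cumulative_curve_hand_count():
    b = make_bias([-10.0, 10.0, 0.0])
    curve = cumulative_curve(b, thresholds=np.array([5.0, 10.0, 20.0]))
    # inclusive convention: f(10) counts the boundary voxels
    assert list(curve["fraction"]) == [pytest.approx(1 / 3), 1.0, 1.0]


def test_cumulative_curve_matches_brute_force_counting():
    rng = np.random.default_rng(8)
    vals = rng.normal(scale=12.0, size=1000)
    b = make_bias(vals)
    thresholds = np.arange(0.0, 50.5, 0.5)
    curve = cumulative_curve(b, thresholds)
    for t, f in zip(curve["threshold_pct"], curve["fraction"]):
        assert f == sum(1 for v in vals if abs(v) <= t) / len(vals)
    assert np.all(np.diff(curve["fraction"]) >= 0)


def test_qc2_identical_pair_passes():
    frac, ok = qc2_evaluate(make_bias(np.zeros(50)))
    assert frac == 1.0 and ok


def test_qc2_constructed_fractions():
    vals = np.concatenate([np.full(8, 15.0), np.full(92, 2.0)])
    frac, ok = qc2_evaluate(make_bias(vals))
    assert frac == pytest.approx(0.92) and ok
    vals = np.concatenate([np.full(15, 15.0), np.full(85, 2.0)])
    frac, ok = qc2_evaluate(make_bias(vals))
    assert frac == pytest.approx(0.85) and not ok


def test_qc2_strict_inequality_at_boundary():
    frac, ok = qc2_evaluate(make_bias(np.full(10, 10.0)))
    assert frac == 0.0 and not ok


def test_qc2_consistent_with_cumulative_curve():
    rng = np.random.default_rng(3)
    vals = rng.normal(scale=8.0, size=500)  # continuous: no mass at 10 exactly
    b = make_bias(vals)
    frac, _ = qc2_evaluate(b, diff_threshold=10.0)
    curve = cumulative_curve(b, thresholds=np.array([10.0]))
    assert frac == pytest.approx(float(curve["fraction"].iloc[0]))


# -- ROI report, QC3/QC4, Bland-Altman --------------------------------------


def _two_roi_case(scale_a=1.0, scale_b=1.0):
    g = grid((4, 1))
    labels = TissueLabelVolume(
        g, np.array([1, 1, 2, 2]).reshape(4, 1, 1), {1: "roi_a", 2: "roi_b"}
    )
    c = ActivityVolume(g, np.array([10.0, 20.0, 30.0, 50.0]).reshape(4, 1, 1))
    mvals = c.values.copy()
    mvals[:2] *= scale_a
    mvals[2:] *= scale_b
    m = ActivityVolume(g, mvals)
    bias = voxelwise_bias(m, c, np.ones(g.shape, bool))
    merged = merge_rois(labels, {"roi_a": ["roi_a"], "roi_b": ["roi_b"]})
    return m, c, bias, merged


def test_roi_report_hand_computed():
    m, c, bias, merged = _two_roi_case(scale_a=1.1, scale_b=0.95)
    rep = roi_report(m, c, bias, merged)
    a = rep[rep.roi == "roi_a"].iloc[0]
    assert a.mean_pct_diff == pytest.approx(10.0)
    assert a.mean_abs_pct_diff == pytest.approx(10.0)
    assert a.uptake_pct_diff == pytest.approx(10.0)
    b = rep[rep.roi == "roi_b"].iloc[0]
    assert b.mean_abs_pct_diff == pytest.approx(5.0)
    assert b.ba_mean_of_means == pytest.approx(0.5 * (40.0 * 0.95 + 40.0))
    assert (rep.mean_abs_pct_diff >= rep.mean_pct_diff.abs() - 1e-12).all()


def test_qc3_pass_and_fail_naming_roi():
    _, _, bias, merged = _two_roi_case()
    m, c, bias0, merged0 = _two_roi_case(scale_a=1.12, scale_b=1.02)
    rep = roi_report(m, c, bias0, merged0)
    tab, ok = qc3_evaluate(rep, ["roi_a", "roi_b"])
    assert not ok
    failing = tab[~tab.qc3_pass]["roi"].tolist()
    assert failing == ["roi_a"]
    m2, c2, bias2, merged2 = _two_roi_case()
    rep2 = roi_report(m2, c2, bias2, merged2)
    _, ok2 = qc3_evaluate(rep2, ["roi_a", "roi_b"])
    assert ok2


def test_qc4_reference_region_thresholds():
    for scale, expected, should_pass in [(1.0, 0.0, True), (1.07, 7.0, False), (1.03, 3.0, True)]:
        m, c, bias, merged = _two_roi_case(scale_b=scale)
        rep = roi_report(m, c, bias, merged)
        value, ok = qc4_evaluate(rep, reference="roi_b", threshold=5.0)
        assert value == pytest.approx(expected, abs=1e-9)
        assert ok is should_pass


def test_bland_altman_uniform_scaling():
    m, c, bias, merged = _two_roi_case(scale_a=1.05, scale_b=1.05)
    ba = bland_altman(roi_report(m, c, bias, merged))
    assert np.allclose(ba["abs_pct_diff"], 5.0)
    m, c, bias, merged = _two_roi_case()
    ba = bland_altman(roi_report(m, c, bias, merged))
    assert np.allclose(ba["abs_pct_diff"], 0.0)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.floats(min_value=0.5, max_value=1.5))
def test_uniform_multiplicative_bias_closed_form(k):
    """Scaling MRAC by k makes every ROI's abs %diff = 100|k-1| and the QC2
    fraction lands at 0 or 1 depending on |k-1| vs 10%."""
    m, c, bias, merged = _two_roi_case(scale_a=k, scale_b=k)
    rep = roi_report(m, c, bias, merged)
    assert np.allclose(rep["mean_abs_pct_diff"], 100.0 * abs(k - 1.0), atol=1e-9)
    frac, _ = qc2_evaluate(bias)
    assert frac == (1.0 if abs(k - 1.0) < 0.1 else 0.0)


# -- QC1 flags --------------------------------------------------------------


def test_qc1_clean_case_no_flags(mu2d):
    flags = qc1_flags(mu2d, mu2d, fill_fraction=0.01)
    hard = [k for k, v in flags.items() if v and k != "human_review_required"]
    assert hard == []
    assert flags["human_review_required"] is True


def test_qc1_detects_artifacts_and_coverage(mu2d):
    class Broken:
        values = np.array([np.nan])
        meta = {}

    assert qc1_flags(Broken(), mu2d)["map_artifact"]
    assert qc1_flags(mu2d, mu2d, fill_fraction=0.30, coverage_bound=0.05)[
        "coverage_incomplete"
    ]
    assert qc1_flags(mu2d, mu2d, residual={"bone_dice": 0.4})[
        "misregistration_suspected"
    ]


# -- QCResult serialization -------------------------------------------------


def test_qcresult_json_round_trip(tmp_path):
    m, c, bias, merged = _two_roi_case(scale_a=1.02)
    rep = roi_report(m, c, bias, merged)
    qc3 = qc3_evaluate(rep, ["roi_a", "roi_b"])
    result = QCResult.assemble(
        subject="s1",
        method="zte_like",
        qc1=qc1_flags(None, None),
        qc2=qc2_evaluate(bias),
        qc3=qc3,
        qc4=qc4_evaluate(rep, "roi_b"),
        qc4_reference="roi_b",
    )
    path = tmp_path / "r.json"
    first = result.to_json(path)
    back = QCResult.from_json(path)
    assert back == result
    assert back.to_json() == first
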