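"""End-to-end orchestration: simulate -> prepare maps -> dual reconstruction
-> qualification verdict, plus report/plot writers.

The qualification run mirrors the centralized-processing workflow: the
CT arm is stripped, (optionally) registered, converted to 511-keV mu, PSF
matched, resampled into the PET grid and gap-filled from the MRI-based map;
the same emission data are then reconstructed twice — once with attenuation
correction factors from each map — and the CTAC/MRAC image pair is fed to the
QC analysis.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import attenuation as att
from . import petsim, phantom, qc, registration
from .config import RunConfig
from .core import (
    ActivityVolume,
    HUVolume,
    MuMap,
    TissueLabelVolume,
    save_nifti,
)

logger = logging.getLogger("petmrqual")


@dataclass
class PhantomBundle:
    labels: TissueLabelVolume
    ct: HUVolume
    activity: ActivityVolume
    true_mu: MuMap
    mrac_mu: MuMap


@dataclass
class QualificationOutputs:
    config: RunConfig
    bundle: PhantomBundle
    ctac_mu: MuMap
    fill_fraction: float
    residual: dict
    sinogram: petsim.Sinogram
    pet_ctac: ActivityVolume
    pet_mrac: ActivityVolume
    bias: qc.BiasVolume
    curve: pd.DataFrame
    report: pd.DataFrame
    result: qc.QCResult


def _phantom_config(cfg: RunConfig) -> phantom.PhantomConfig:
    base = phantom.PhantomConfig(
        shape=tuple(cfg.phantom.shape), spacing_mm=tuple(cfg.phantom.spacing_mm)
    )
    if cfg.phantom.tracer == "amyloid":
        base = phantom.amyloid_config(
            shape=tuple(cfg.phantom.shape), spacing_mm=tuple(cfg.phantom.spacing_mm)
        )
    return base


def simulate(cfg: RunConfig) -> PhantomBundle:
    """Generate the phantom bundle for one subject (in memory)."""
    pcfg = _phantom_config(cfg)
    labels, ct, activity = phantom.generate_head_phantom(pcfg, seed=cfg.phantom.seed)
    true_mu = phantom.derive_true_mu(labels)
    model = phantom.MRACErrorModel(
        method=cfg.phantom.mrac.method,
        bone_mu_noise_sd=cfg.phantom.mrac.bone_mu_noise_sd,
        bone_shift_mm=cfg.phantom.mrac.bone_shift_mm,
        seed=cfg.phantom.mrac.seed,
    )
    mrac_mu = phantom.derive_mrac_map(labels, true_mu, model)
    return PhantomBundle(labels, ct, activity, true_mu, mrac_mu)


def write_bundle(bundle: PhantomBundle, cfg: RunConfig, outdir) -> dict:
    """Write the simulated bundle as NIfTI + manifest; returns file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {
        "labels": outdir / "labels.nii.gz",
        "ct": outdir / "ct.nii.gz",
        "activity": outdir / "activity.nii.gz",
        "mu_true": outdir / "mu_true.nii.gz",
        "mu_mrac": outdir / "mu_mrac.nii.gz",
    }
    save_nifti(bundle.labels, files["labels"])
    save_nifti(bundle.ct, files["ct"])
    save_nifti(bundle.activity, files["activity"])
    save_nifti(bundle.true_mu, files["mu_true"])
    save_nifti(bundle.mrac_mu, files["mu_mrac"])
    manifest = {
        "config_hash": cfg.config_hash(),
        "config": json.loads(cfg.canonical_json()),
        "files": {
            k: hashlib.sha256(p.read_bytes()).hexdigest() for k, p in files.items()
        },
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    files["manifest"] = mpath
    return {k: str(v) for k, v in files.items()}


def prepare_ctac_mu(
    ct: HUVolume,
    mrac_mu: MuMap,
    cfg: RunConfig,
    transform: registration.RigidTransform | None = None,
) -> tuple[MuMap, float, dict]:
    """CT-side pipeline: strip -> register -> convert -> smooth -> resample
    -> fill.  Returns (ctac mu-map, fill fraction, residual report)."""
    if cfg.attenuation.fwhm_mm is None:
        raise ValueError(
            "attenuation.fwhm_mm is required for evaluation (set it to the "
            "PET scanner's resolution; 0 disables PSF matching)"
        )
    stripped = att.strip_nonpatient(ct, cfg.attenuation.air_threshold_hu)
    logger.info("strip: kept largest component above %.0f HU", cfg.attenuation.air_threshold_hu)

    if transform is None and cfg.registration.enabled:
        opts = registration.RegistrationOptions(
            bins=cfg.registration.bins,
            pyramid_factors=tuple(cfg.registration.pyramid_factors),
            max_iter_per_level=cfg.registration.max_iter_per_level,
        )
        transform, final_nmi = registration.register_rigid(
            stripped.values, stripped.grid, mrac_mu.values, mrac_mu.grid, opts
        )
        logger.info("register: NMI=%.4f %s", final_nmi, transform.to_dict())

    cal = att.HUCalibration(
        breakpoint_hu=cfg.attenuation.calibration.breakpoint_hu,
        mu_water=cfg.attenuation.calibration.mu_water,
        slope_low=cfg.attenuation.calibration.slope_low,
        slope_high=cfg.attenuation.calibration.slope_high,
    )
    mu = att.hu_to_mu(stripped, cal)
    mu = att.smooth_to_pet_resolution(mu, cfg.attenuation.fwhm_mm)
    mu, coverage = att.resample(mu, mrac_mu.grid, transform)
    mu = att.fill_missing_from_mrac(mu, coverage, mrac_mu)
    fill_fraction = mu.meta["fill_fraction"]

    soft = mu.values > 0.5 * 0.096  # generous soft-tissue-and-up support
    residual = registration.registration_residual(mu, mrac_mu, soft)
    logger.info(
        "ctac mu ready: fill_fraction=%.4f bone_dice=%.3f",
        fill_fraction,
        residual["bone_dice"],
    )
    return mu, fill_fraction, residual


def dual_reconstruct(
    activity: ActivityVolume,
    physics_mu: MuMap,
    ctac_mu: MuMap,
    mrac_mu: MuMap,
    cfg: RunConfig,
) -> tuple[petsim.Sinogram, ActivityVolume, ActivityVolume]:
    """Acquire once (with *physics_mu* in the forward model), reconstruct
    twice — ACF from the CT-derived and from the MRI-derived map."""
    geom = petsim.ProjectionGeometry(
        n_angles=cfg.petsim.n_angles,
        n_radial=cfg.petsim.n_radial,
        radial_spacing_mm=cfg.petsim.radial_spacing_mm,
    )
    sino = petsim.forward_project(activity, physics_mu, geom)
    if cfg.petsim.noise_enabled:
        total = cfg.petsim.counts_per_slice * activity.grid.shape[2]
        sino = petsim.add_poisson_noise(sino, total, seed=cfg.petsim.noise_seed)
    settings = petsim.ReconSettings(
        iterations=cfg.petsim.iterations,
        subsets=cfg.petsim.subsets,
        post_fwhm_mm=cfg.petsim.post_fwhm_mm,
    )
    pet_ctac = petsim.reconstruct_osem(sino, ctac_mu, settings)
    pet_mrac = petsim.reconstruct_osem(sino, mrac_mu, settings)
    return sino, pet_ctac, pet_mrac


def run_qc(
    pet_mrac: ActivityVolume,
    pet_ctac: ActivityVolume,
    labels: TissueLabelVolume,
    cfg: RunConfig,
    ctac_mu: MuMap,
    mrac_mu: MuMap,
    fill_fraction: float,
    residual: dict,
) -> tuple[qc.BiasVolume, pd.DataFrame, pd.DataFrame, qc.QCResult]:
    mask = qc.brain_mask(labels, tuple(cfg.qc.brain_labels))
    bias = qc.voxelwise_bias(pet_mrac, pet_ctac, mask, cfg.qc.denom_floor_frac)
    curve = qc.cumulative_curve(bias)
    qc2 = qc.qc2_evaluate(
        bias, cfg.qc.qc2_threshold_pct, cfg.qc.qc2_required_fraction
    )
    merged = qc.merge_rois(labels, cfg.qc.roi_recipe)
    report = qc.roi_report(pet_mrac, pet_ctac, bias, merged)
    qc3 = qc.qc3_evaluate(
        report,
        study_rois=list(cfg.qc.roi_recipe),
        threshold=cfg.qc.qc3_threshold_pct,
        metric=cfg.qc.qc3_metric,
    )
    qc4 = (
        qc.qc4_evaluate(report, cfg.qc.qc4_reference, cfg.qc.qc4_threshold_pct)
        if cfg.qc.qc4_enabled
        else None
    )
    flags = qc.qc1_flags(
        mrac_mu,
        ctac_mu,
        pet_mrac,
        pet_ctac,
        fill_fraction=fill_fraction,
        residual=residual,
        coverage_bound=cfg.qc.coverage_bound,
        bone_dice_min=cfg.qc.bone_dice_min,
        excluded_voxel_fraction=bias.meta["excluded_fraction"],
    )
    result = qc.QCResult.assemble(
        subject=cfg.subject,
        method=cfg.phantom.mrac.method,
        qc1=flags,
        qc2=qc2,
        qc3=qc3,
        qc4=qc4,
        qc2_threshold_pct=cfg.qc.qc2_threshold_pct,
        qc2_required_fraction=cfg.qc.qc2_required_fraction,
        qc4_reference=cfg.qc.qc4_reference,
        qc4_threshold_pct=cfg.qc.qc4_threshold_pct,
    )
    return bias, curve, qc3[0], result


def run_qualification(cfg: RunConfig) -> QualificationOutputs:
    """Full in-memory simulate + evaluate for one subject/method."""
    bundle = simulate(cfg)
    ctac_mu, fill_fraction, residual = prepare_ctac_mu(
        bundle.ct, bundle.mrac_mu, cfg
    )
    sino, pet_ctac, pet_mrac = dual_reconstruct(
        bundle.activity, bundle.true_mu, ctac_mu, bundle.mrac_mu, cfg
    )
    bias, curve, report, result = run_qc(
        pet_mrac,
        pet_ctac,
        bundle.labels,
        cfg,
        ctac_mu,
        bundle.mrac_mu,
        fill_fraction,
        residual,
    )
    return QualificationOutputs(
        cfg, bundle, ctac_mu, fill_fraction, residual, sino,
        pet_ctac, pet_mrac, bias, curve, report, result,
    )


# ---------------------------------------------------------------------------
# Report writing


def write_reports(out: QualificationOutputs, outdir) -> dict:
    """Write QCResult JSON, CSVs and PNGs, templated by subject ID."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sid = out.config.subject
    files = {}

    files["qcresult"] = outdir / f"{sid}_qcresult.json"
    out.result.to_json(files["qcresult"])
    files["roi_report"] = outdir / f"{sid}_roi_report.csv"
    out.report.to_csv(files["roi_report"], index=False)
    files["curve"] = outdir / f"{sid}_cumulative_curve.csv"
    out.curve.to_csv(files["curve"], index=False)
    ba = qc.bland_altman(out.report)
    files["bland_altman"] = outdir / f"{sid}_bland_altman.csv"
    ba.to_csv(files["bland_altman"], index=False)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(out.curve["threshold_pct"], 100 * out.curve["fraction"])
    ax.axvline(out.result.qc2_threshold_pct, ls="--", c="gray")
    ax.axhline(100 * out.result.qc2_required_fraction, ls="--", c="gray")
    ax.set_xlabel("absolute % difference threshold")
    ax.set_ylabel("% of brain-mask voxels")
    ax.set_title(f"{sid}: cumulative |%diff| ({out.result.method})")
    files["curve_png"] = outdir / f"{sid}_cumulative_curve.png"
    fig.savefig(files["curve_png"], dpi=110)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ba["mean_of_means"], ba["abs_pct_diff"])
    for _, row in ba.iterrows():
        ax.annotate(row["roi"], (row["mean_of_means"], row["abs_pct_diff"]),
                    fontsize=7, xytext=(2, 2), textcoords="offset points")
    ax.axhline(out.config.qc.qc3_threshold_pct, ls="--", c="gray")
    ax.set_xlabel("mean of ROI means (MRAC, CTAC)")
    ax.set_ylabel("|ROI-mean % difference|")
    ax.set_title(f"{sid}: Bland-Altman ({out.result.method})")
    files["ba_png"] = outdir / f"{sid}_bland_altman.png"
    fig.savefig(files["ba_png"], dpi=110)
    plt.close(fig)

    # overlays for the QC1 human review: mid-axial mu maps and PET pair
    z = out.ctac_mu.grid.shape[2] // 2
    fig, axes = plt.subplots(2, 2, figsize=(8, 7))
    panels = [
        (out.ctac_mu.values[:, :, z], "CT-derived mu"),
        (out.bundle.mrac_mu.values[:, :, z], "MRI-derived mu"),
        (out.pet_ctac.values[:, :, z], "PET (CTAC)"),
        (out.pet_mrac.values[:, :, z], "PET (MRAC)"),
    ]
    for ax, (img, title) in zip(axes.ravel(), panels):
        ax.imshow(img.T, origin="lower", cmap="gray")
        ax.set_title(title, fontsize=9)
        ax.axis("off")
    files["overlay_png"] = outdir / f"{sid}_overlays.png"
    fig.savefig(files["overlay_png"], dpi=110)
    plt.close(fig)

    return {k: str(v) for k, v in files.items()}


def report_summary(results: list[qc.QCResult]) -> tuple[pd.DataFrame, bool]:
    """Per-subject x per-method verdict table; overall pass iff all pass."""
    if not results:
        raise ValueError("no QC results supplied")
    rows = []
    for r in results:
        worst = max(r.qc3_table, key=lambda t: t["qc3_value"]) if r.qc3_table else None
        rows.append(
            {
                "subject": r.subject,
                "method": r.method,
                "qc2_fraction": r.qc2_fraction,
                "qc2_pass": r.qc2_pass,
                "worst_roi": worst["roi"] if worst else "",
                "worst_roi_abs_pct": worst["qc3_value"] if worst else np.nan,
                "qc3_pass": r.qc3_pass,
                "qc4_value": r.qc4_value,
                "overall_pass": r.overall_pass,
            }
        )
    table = pd.DataFrame(rows)
    return table, bool(table["overall_pass"].all())
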