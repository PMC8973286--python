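"""Quantitative evaluation and qualification verdict.

Implements the analysis run on the CTAC/MRAC reconstruction pair:

* whole-brain voxelwise percentage difference 100*(MRAC - CTAC)/CTAC,
* cumulative absolute-difference curves,
* regional statistics over study-composite ROIs (mean %diff, mean absolute
  %diff, %diff of ROI mean uptake, Bland-Altman coordinates),
* the four qualification criteria:

  - QC1: artifact/coverage/misregistration flags (automated surrogates; the
    final call is a human reading the emitted overlays),
  - QC2: |%diff| < 10 in at least 90% of brain-mask voxels,
  - QC3: ROI-average absolute %diff < 10 in every study ROI,
  - QC4 (optional): reference-region mean-uptake bias < 5%.

All "below X%" bounds are strict inequalities, so boundary values fail.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ActivityVolume, TissueLabelVolume, VoxelGrid
from .phantom import BRAIN_NAMES

DEFAULT_ROI_RECIPE: dict[str, list[str]] = {
    "frontal": ["gm_frontal"],
    "cingulate": ["gm_cingulate"],
    "parietal": ["gm_parietal"],
    "lateral_temporal": ["gm_lateral_temporal"],
    "white_matter": ["white_matter"],
    "cerebellum": ["cerebellum_gm"],
}


def brain_mask(
    labels: TissueLabelVolume, brain_names: tuple[str, ...] = BRAIN_NAMES
) -> np.ndarray:
    """All gray- and white-matter voxels (CSF, ventricles, bone, air excluded)."""
    mask = labels.mask_of(list(brain_names))
    if not mask.any():
        raise ValueError("brain mask is empty: no gray/white-matter labels present")
    return mask


def merge_rois(
    labels: TissueLabelVolume, recipe: dict[str, list[str]]
) -> TissueLabelVolume:
    """Merge atlas labels into study composites; unassigned voxels -> 0."""
    inv = labels.name_to_label()
    used: dict[str, str] = {}
    for comp, members in recipe.items():
        for m in members:
            if m not in inv:
                raise KeyError(f"composite {comp!r} references unknown label {m!r}")
            if m in used:
                raise ValueError(
                    f"label {m!r} appears in both {used[m]!r} and {comp!r}; "
                    "composites must not overlap"
                )
            used[m] = comp
    out = np.zeros(labels.grid.shape, dtype=np.int32)
    palette = {0: "unassigned"}
    for idx, (comp, members) in enumerate(recipe.items(), start=1):
        out[labels.mask_of(members)] = idx
        palette[idx] = comp
    return TissueLabelVolume(labels.grid, out, palette)


@dataclass
class BiasVolume:
    """Voxelwise percentage difference MRAC vs CTAC inside the brain mask."""

    grid: VoxelGrid
    values: np.ndarray  # %; defined only where mask is True
    mask: np.ndarray  # valid voxels (brain mask minus low-denominator voxels)
    meta: dict = field(default_factory=dict)

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]


def voxelwise_bias(
    pet_mrac: ActivityVolume,
    pet_ctac: ActivityVolume,
    mask: np.ndarray,
    denom_floor_frac: float = 0.01,
) -> BiasVolume:
    """100*(MRAC - CTAC)/CTAC per brain-mask voxel.

    Voxels whose CTAC value falls below ``denom_floor_frac`` times the
    mask-mean CTAC are excluded from the valid mask (and counted in ``meta``)
    to keep near-zero denominators from dominating the statistics.
    """
    pet_mrac.grid.require_same(pet_ctac.grid, "PET volumes")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("brain mask is empty")
    c = pet_ctac.values
    floor = denom_floor_frac * float(c[mask].mean())
    valid = mask & (c > floor)
    if not valid.any():
        raise ValueError("no valid voxels: CTAC image is ~zero inside the mask")
    values = np.zeros(pet_mrac.grid.shape)
    values[valid] = 100.0 * (pet_mrac.values[valid] - c[valid]) / c[valid]
    n_excluded = int(mask.sum() - valid.sum())
    return BiasVolume(
        pet_mrac.grid,
        values,
        valid,
        meta={
            "n_mask": int(mask.sum()),
            "n_excluded_low_denominator": n_excluded,
            "excluded_fraction": n_excluded / float(mask.sum()),
            "denominator_floor": floor,
        },
    )


def cumulative_curve(
    bias: BiasVolume, thresholds: np.ndarray | None = None
) -> pd.DataFrame:
    """Fraction of valid voxels with |%diff| <= t, per threshold t.

    Matches the cumulative pixelwise absolute-difference histogram used to
    read off the QC2 criterion; the tail fraction beyond the last threshold is
    ``1 - fraction`` at that threshold.
    """
    if thresholds is None:
        thresholds = np.arange(0.0, 50.5, 0.5)
    thresholds = np.asarray(thresholds, dtype=float)
    absb = np.abs(bias.valid_values())
    frac = [(absb <= t).mean() for t in thresholds]
    return pd.DataFrame({"threshold_pct": thresholds, "fraction": frac})


def qc2_evaluate(
    bias: BiasVolume, diff_threshold: float = 10.0, voxel_fraction: float = 0.90
) -> tuple[float, bool]:
    """Share of brain-mask voxels with |%diff| strictly below the threshold."""
    absb = np.abs(bias.valid_values())
    fraction = float((absb < diff_threshold).mean())
    return fraction, fraction >= voxel_fraction


def roi_report(
    pet_mrac: ActivityVolume,
    pet_ctac: ActivityVolume,
    bias: BiasVolume,
    merged: TissueLabelVolume,
) -> pd.DataFrame:
    """Per-composite regional statistics.

    Voxelwise columns average the bias volume inside (ROI intersect valid
    mask); uptake columns compare the ROI-mean values of the two
    reconstructions directly (the SUV-ratio-style statistic used by QC4 and
    the Bland-Altman plot).
    """
    rows = []
    for code, name in sorted(merged.palette.items()):
        if code == 0:
            continue
        roi = (merged.labels == code) & bias.mask
        if not roi.any():
            continue
        b = bias.values[roi]
        mean_m = float(pet_mrac.values[roi].mean())
        mean_c = float(pet_ctac.values[roi].mean())
        uptake_pct = 100.0 * (mean_m - mean_c) / mean_c
        rows.append(
            {
                "roi": name,
                "n_voxels": int(roi.sum()),
                "mean_pct_diff": float(b.mean()),
                "mean_abs_pct_diff": float(np.abs(b).mean()),
                "uptake_mean_mrac": mean_m,
                "uptake_mean_ctac": mean_c,
                "uptake_pct_diff": uptake_pct,
                "ba_mean_of_means": 0.5 * (mean_m + mean_c),
                "ba_abs_pct_diff": abs(uptake_pct),
            }
        )
    if not rows:
        raise ValueError("no ROI has voxels inside the valid brain mask")
    return pd.DataFrame(rows)


def qc3_evaluate(
    report: pd.DataFrame,
    study_rois: list[str] | None = None,
    threshold: float = 10.0,
    metric: str = "mean_abs_pct_diff",
) -> tuple[pd.DataFrame, bool]:
    """Every study ROI's average absolute %diff must be strictly below 10%.

    ``metric`` selects the primary statistic: the ROI average of voxelwise
    absolute %diff (default) or ``"ba_abs_pct_diff"`` (bias of ROI mean
    uptake).
    """
    if metric not in ("mean_abs_pct_diff", "ba_abs_pct_diff"):
        raise ValueError(f"unknown QC3 metric {metric!r}")
    tab = report if study_rois is None else report[report["roi"].isin(study_rois)]
    if study_rois is not None:
        missing = set(study_rois) - set(tab["roi"])
        if missing:
            raise ValueError(f"study ROIs missing from report: {sorted(missing)}")
    tab = tab.copy()
    tab["qc3_value"] = tab[metric]
    tab["qc3_pass"] = tab[metric] < threshold
    return tab, bool(tab["qc3_pass"].all())


def qc4_evaluate(
    report: pd.DataFrame, reference: str = "cerebellum", threshold: float = 5.0
) -> tuple[float, bool]:
    """Reference-region mean-uptake bias must be strictly below the bound."""
    row = report[report["roi"] == reference]
    if row.empty:
        raise ValueError(f"reference ROI {reference!r} not in report")
    value = float(row["ba_abs_pct_diff"].iloc[0])
    return value, value < threshold


def qc1_flags(
    mrac_mu,
    ctac_mu,
    pet_mrac: ActivityVolume | None = None,
    pet_ctac: ActivityVolume | None = None,
    fill_fraction: float = 0.0,
    residual: dict | None = None,
    coverage_bound: float = 0.05,
    bone_dice_min: float = 0.70,
    excluded_voxel_fraction: float = 0.0,
    excluded_bound: float = 0.005,
) -> dict:
    """Automated artifact surrogates; human review is always still required."""

    def bad(vol) -> bool:
        if vol is None:
            return False
        v = np.asarray(vol.values)
        return bool(~np.all(np.isfinite(v)) or (v < 0).any())

    flags = {
        "map_artifact": bool(
            bad(mrac_mu)
            or bad(ctac_mu)
            or "implausible_mu_max" in getattr(mrac_mu, "meta", {})
            or "implausible_mu_max" in getattr(ctac_mu, "meta", {})
        ),
        "pet_artifact": bool(bad(pet_mrac) or bad(pet_ctac)),
        "coverage_incomplete": bool(fill_fraction > coverage_bound),
        "misregistration_suspected": bool(
            residual is not None and residual.get("bone_dice", 1.0) < bone_dice_min
        ),
        "excessive_excluded_voxels": bool(excluded_voxel_fraction > excluded_bound),
        "human_review_required": True,
    }
    return flags


def bland_altman(report: pd.DataFrame) -> pd.DataFrame:
    """Bland-Altman coordinates per ROI: mean of means vs |relative diff| (%)."""
    return report[["roi", "ba_mean_of_means", "ba_abs_pct_diff"]].rename(
        columns={"ba_mean_of_means": "mean_of_means", "ba_abs_pct_diff": "abs_pct_diff"}
    )


# ---------------------------------------------------------------------------
# Verdict object


@dataclass
class QCResult:
    """Machine-readable qualification verdict for one subject/method pair."""

    subject: str
    method: str
    qc1: dict
    qc2_fraction: float
    qc2_threshold_pct: float
    qc2_required_fraction: float
    qc2_pass: bool
    qc3_table: list[dict]
    qc3_pass: bool
    qc4_enabled: bool
    qc4_reference: str | None
    qc4_value: float | None
    qc4_threshold_pct: float | None
    qc4_pass: bool | None
    overall_pass: bool

    HARD_FLAGS = (
        "map_artifact",
        "pet_artifact",
        "coverage_incomplete",
        "misregistration_suspected",
        "excessive_excluded_voxels",
    )

    @classmethod
    def assemble(
        cls,
        subject: str,
        method: str,
        qc1: dict,
        qc2: tuple[float, bool],
        qc3: tuple[pd.DataFrame, bool],
        qc4: tuple[float, bool] | None = None,
        qc2_threshold_pct: float = 10.0,
        qc2_required_fraction: float = 0.90,
        qc4_reference: str | None = None,
        qc4_threshold_pct: float = 5.0,
    ) -> "QCResult":
        hard_flag = any(qc1.get(f, False) for f in cls.HARD_FLAGS)
        qc4_pass = None if qc4 is None else qc4[1]
        overall = (
            (not hard_flag)
            and qc2[1]
            and qc3[1]
            and (qc4 is None or qc4[1])
        )
        keep = [
            "roi", "n_voxels", "mean_pct_diff", "mean_abs_pct_diff",
            "uptake_pct_diff", "qc3_value", "qc3_pass",
        ]
        tab = qc3[0][[c for c in keep if c in qc3[0].columns]]
        return cls(
            subject=subject,
            method=method,
            qc1=dict(qc1),
            qc2_fraction=float(qc2[0]),
            qc2_threshold_pct=float(qc2_threshold_pct),
            qc2_required_fraction=float(qc2_required_fraction),
            qc2_pass=bool(qc2[1]),
            qc3_table=tab.to_dict(orient="records"),
            qc3_pass=bool(qc3[1]),
            qc4_enabled=qc4 is not None,
            qc4_reference=qc4_reference if qc4 is not None else None,
            qc4_value=None if qc4 is None else float(qc4[0]),
            qc4_threshold_pct=float(qc4_threshold_pct) if qc4 is not None else None,
            qc4_pass=qc4_pass,
            overall_pass=bool(overall),
        )

    def to_dict(self) -> dict:
        return {
            "subject": self.subject,
            "method": self.method,
            "qc1": self.qc1,
            "qc2": {
                "fraction": self.qc2_fraction,
                "threshold_pct": self.qc2_threshold_pct,
                "required_fraction": self.qc2_required_fraction,
                "pass": self.qc2_pass,
            },
            "qc3": {"table": self.qc3_table, "pass": self.qc3_pass},
            "qc4": {
                "enabled": self.qc4_enabled,
                "reference": self.qc4_reference,
                "value": self.qc4_value,
                "threshold_pct": self.qc4_threshold_pct,
                "pass": self.qc4_pass,
            },
            "overall_pass": self.overall_pass,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QCResult":
        return cls(
            subject=d["subject"],
            method=d["method"],
            qc1=dict(d["qc1"]),
            qc2_fraction=d["qc2"]["fraction"],
            qc2_threshold_pct=d["qc2"]["threshold_pct"],
            qc2_required_fraction=d["qc2"]["required_fraction"],
            qc2_pass=d["qc2"]["pass"],
            qc3_table=list(d["qc3"]["table"]),
            qc3_pass=d["qc3"]["pass"],
            qc4_enabled=d["qc4"]["enabled"],
            qc4_reference=d["qc4"]["reference"],
            qc4_value=d["qc4"]["value"],
            qc4_threshold_pct=d["qc4"]["threshold_pct"],
            qc4_pass=d["qc4"]["pass"],
            overall_pass=d["overall_pass"],
        )

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "QCResult":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))
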