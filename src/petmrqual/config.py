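"""Run configuration: schema-validated YAML/JSON with explicit seeds.

Unknown keys are rejected so a typo in a config file fails loudly instead of
silently falling back to a default.  Every stochastic stage (CT noise, MRAC
bone noise, Poisson counting) has its own explicit seed in the schema.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .phantom import BRAIN_NAMES
from .qc import DEFAULT_ROI_RECIPE


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MRACBlock(_Block):
    method: str = "zte_like"
    bone_mu_noise_sd: float = Field(0.02, ge=0)
    bone_shift_mm: float = Field(2.0, ge=0)
    seed: int = 1


class PhantomBlock(_Block):
    shape: list[int] = [128, 128, 64]
    spacing_mm: list[float] = [2.0, 2.0, 2.0]
    tracer: str = "fdg"  # "fdg" (GM:WM 4:1) or "amyloid" (high WM)
    seed: int = 1
    mrac: MRACBlock = MRACBlock()

    @field_validator("tracer")
    @classmethod
    def _tracer(cls, v):
        if v not in ("fdg", "amyloid"):
            raise ValueError("tracer must be 'fdg' or 'amyloid'")
        return v


class CalibrationBlock(_Block):
    breakpoint_hu: float = 50.0
    mu_water: float = 0.096
    slope_low: float = 0.096 / 1000.0
    slope_high: float = (0.151 - (0.096 + 0.096 / 1000.0 * 50.0)) / (1000.0 - 50.0)


class AttenuationBlock(_Block):
    calibration: CalibrationBlock = CalibrationBlock()
    # PSF-matching kernel; no silent default in evaluate mode — must be set
    fwhm_mm: float | None = None
    air_threshold_hu: float = -200.0


class RegistrationBlock(_Block):
    enabled: bool = True
    bins: int = 32
    pyramid_factors: list[int] = [4, 2, 1]
    max_iter_per_level: int = 60


class PetsimBlock(_Block):
    n_angles: int = 160
    n_radial: int = 128
    radial_spacing_mm: float = 2.0
    counts_per_slice: float = 5.0e5
    noise_enabled: bool = True
    noise_seed: int = 1
    iterations: int = 10
    subsets: int = 8
    post_fwhm_mm: float = 0.0


class QCBlock(_Block):
    brain_labels: list[str] = list(BRAIN_NAMES)
    roi_recipe: dict[str, list[str]] = DEFAULT_ROI_RECIPE
    qc2_threshold_pct: float = 10.0
    qc2_required_fraction: float = 0.90
    qc3_threshold_pct: float = 10.0
    qc3_metric: str = "mean_abs_pct_diff"
    qc4_enabled: bool = True
    qc4_reference: str = "cerebellum"
    qc4_threshold_pct: float = 5.0
    denom_floor_frac: float = 0.01
    coverage_bound: float = 0.05
    bone_dice_min: float = 0.70


class RunConfig(_Block):
    subject: str = "phantom01"
    phantom: PhantomBlock = PhantomBlock()
    attenuation: AttenuationBlock = AttenuationBlock()
    registration: RegistrationBlock = RegistrationBlock()
    petsim: PetsimBlock = PetsimBlock()
    qc: QCBlock = QCBlock()
    output_dir: str = "pmq_out"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls.model_validate(data)

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()
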