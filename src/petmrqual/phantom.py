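"""Synthetic digital head phantom and MRAC error models.

The phantom is a nested-ellipsoid head: soft-tissue scalp, a closed skull
shell, a CSF rim, a cortical gray-matter ribbon partitioned geometrically into
the study's four bilateral cortical composites (frontal, cingulate, parietal,
lateral temporal), a white-matter core with ventricles, a cerebellar
compartment in the posterior/inferior cortex, and a frontal sinus air pocket.
It is deliberately geometric rather than anatomical: the attenuation-correction
error mechanisms under test (missing bone, noisy bone, shifted bone) do not
depend on anatomical fidelity, only on the presence of a bone shell between
brain tissue and the detectors.

From the label volume the module derives

* a CT in Hounsfield units (per-tissue Gaussian means/SDs),
* an emission activity map (FDG-like gray:white 4:1 by default,
  amyloid-like presets available), and
* ground-truth and MRI-method-like 511-keV attenuation maps.

The MRAC error models emulate the failure signatures of the deployed
MRI-based attenuation-map families: ``dixon_like`` renders the skull invisible
(bone voxels get soft-tissue mu), ``zte_like`` retains bone with multiplicative
noise on bone mu, ``atlas_like`` imposes a template skull displaced rigidly,
and ``perfect`` is the identity control.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import ActivityVolume, HUVolume, MuMap, TissueLabelVolume, VoxelGrid

# canonical label codes; cortical GM codes double as study ROI codes
AIR = 0
SOFT_TISSUE = 1
SKULL_BONE = 2
SINUS_AIR = 3
CSF = 4
VENTRICLE = 5
WHITE_MATTER = 6
GM_FRONTAL = 10
GM_CINGULATE = 11
GM_PARIETAL = 12
GM_LATERAL_TEMPORAL = 13
CEREBELLUM_GM = 14

PALETTE: dict[int, str] = {
    AIR: "air",
    SOFT_TISSUE: "soft_tissue",
    SKULL_BONE: "skull_bone",
    SINUS_AIR: "sinus_air",
    CSF: "csf",
    VENTRICLE: "ventricle",
    WHITE_MATTER: "white_matter",
    GM_FRONTAL: "gm_frontal",
    GM_CINGULATE: "gm_cingulate",
    GM_PARIETAL: "gm_parietal",
    GM_LATERAL_TEMPORAL: "gm_lateral_temporal",
    CEREBELLUM_GM: "cerebellum_gm",
}

GRAY_MATTER_NAMES = (
    "gm_frontal",
    "gm_cingulate",
    "gm_parietal",
    "gm_lateral_temporal",
    "cerebellum_gm",
)
BRAIN_NAMES = GRAY_MATTER_NAMES + ("white_matter",)

# 511-keV linear attenuation coefficients, 1/cm (literature values)
DEFAULT_MU_TABLE: dict[str, float] = {
    "air": 0.0,
    "sinus_air": 0.0,
    "soft_tissue": 0.096,
    "csf": 0.096,
    "ventricle": 0.096,
    "white_matter": 0.096,
    "gm_frontal": 0.096,
    "gm_cingulate": 0.096,
    "gm_parietal": 0.096,
    "gm_lateral_temporal": 0.096,
    "cerebellum_gm": 0.096,
    "skull_bone": 0.151,
}

# CT appearance: tissue -> (mean HU, SD HU)
DEFAULT_HU_TABLE: dict[str, tuple[float, float]] = {
    "air": (-1000.0, 0.0),
    "sinus_air": (-1000.0, 0.0),
    "soft_tissue": (40.0, 10.0),
    "csf": (15.0, 5.0),
    "ventricle": (12.0, 5.0),
    "white_matter": (30.0, 5.0),
    "gm_frontal": (40.0, 5.0),
    "gm_cingulate": (40.0, 5.0),
    "gm_parietal": (40.0, 5.0),
    "gm_lateral_temporal": (40.0, 5.0),
    "cerebellum_gm": (40.0, 5.0),
    "skull_bone": (1000.0, 100.0),
}

# FDG-like uptake, GM:WM = 4:1; scalp low, CSF/air cold
ACTIVITY_FDG: dict[str, float] = {
    "air": 0.0,
    "sinus_air": 0.0,
    "soft_tissue": 0.5,
    "csf": 0.1,
    "ventricle": 0.1,
    "white_matter": 1.0,
    "gm_frontal": 4.0,
    "gm_cingulate": 4.0,
    "gm_parietal": 4.0,
    "gm_lateral_temporal": 4.0,
    "cerebellum_gm": 4.0,
}

# amyloid-like (florbetapir in amyloid-negative tissue): high nonspecific WM
ACTIVITY_AMYLOID: dict[str, float] = {
    "air": 0.0,
    "sinus_air": 0.0,
    "soft_tissue": 0.5,
    "csf": 0.1,
    "ventricle": 0.1,
    "white_matter": 2.0,
    "gm_frontal": 1.0,
    "gm_cingulate": 1.0,
    "gm_parietal": 1.0,
    "gm_lateral_temporal": 1.0,
    "cerebellum_gm": 1.0,
}


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and tissue-appearance parameters of the synthetic head.

    Semi-axes are in mm for the outer head ellipsoid; the inner structures are
    derived by subtracting the layer thicknesses, so shells are guaranteed
    nested as long as every thickness is positive and their sum is below the
    smallest head semi-axis.
    """

    shape: tuple[int, ...] = (128, 128, 64)
    spacing_mm: tuple[float, ...] = (2.0, 2.0, 2.0)
    head_semiaxes_mm: tuple[float, float, float] = (80.0, 100.0, 62.0)
    scalp_thickness_mm: float = 6.0
    skull_thickness_mm: float = 6.0
    csf_thickness_mm: float = 4.0
    gm_thickness_mm: float = 9.0
    ventricle_semiaxes_mm: tuple[float, float, float] = (10.0, 22.0, 10.0)
    sinus_center_mm: tuple[float, float, float] = (0.0, 86.0, -6.0)
    sinus_semiaxes_mm: tuple[float, float, float] = (11.0, 7.0, 9.0)
    # cortical composites are azimuthal wedges of the GM ribbon, measured from
    # the anterior (+y) axis in ellipse-normalized coordinates; bounds are the
    # wedge edges in degrees (left/right symmetric -> bilateral regions)
    frontal_max_deg: float = 45.0
    cingulate_max_deg: float = 75.0
    temporal_max_deg: float = 115.0
    parietal_max_deg: float = 150.0  # beyond this: cerebellar compartment
    hu_table: dict = field(default_factory=lambda: dict(DEFAULT_HU_TABLE))
    activity_table: dict = field(default_factory=lambda: dict(ACTIVITY_FDG))

    def grid(self) -> VoxelGrid:
        return VoxelGrid.from_spacing(self.shape, self.spacing_mm)

    def validate(self) -> None:
        layers = (
            self.scalp_thickness_mm,
            self.skull_thickness_mm,
            self.csf_thickness_mm,
            self.gm_thickness_mm,
        )
        if any(t <= 0 for t in layers):
            raise ValueError("all shell thicknesses must be positive")
        if sum(layers) >= min(self.head_semiaxes_mm):
            raise ValueError(
                "shell thicknesses exceed the head semi-axes; no room for "
                "a white-matter core"
            )
        if any(a <= 0 for a in self.head_semiaxes_mm):
            raise ValueError("head semi-axes must be positive")
        wedges = (
            0.0,
            self.frontal_max_deg,
            self.cingulate_max_deg,
            self.temporal_max_deg,
            self.parietal_max_deg,
            180.0,
        )
        if any(b <= a for a, b in zip(wedges, wedges[1:])):
            raise ValueError("cortical wedge bounds must increase within (0, 180)")


@dataclass(frozen=True)
class MRACErrorModel:
    """Which MRI-based attenuation-map failure signature to emulate."""

    method: str = "zte_like"
    bone_mu_noise_sd: float = 0.02
    bone_shift_mm: float = 2.0
    seed: int = 0

    METHODS = ("perfect", "dixon_like", "zte_like", "atlas_like")

    def __post_init__(self):
        if self.method not in self.METHODS:
            raise ValueError(
                f"unknown MRAC method {self.method!r}; choose from {self.METHODS}"
            )
        if self.bone_mu_noise_sd < 0:
            raise ValueError("bone_mu_noise_sd must be >= 0")
        if self.bone_shift_mm < 0:
            raise ValueError("bone_shift_mm must be >= 0")


def _ellipsoid_mask(grid: VoxelGrid, center_mm, semiaxes_mm, is_2d: bool) -> np.ndarray:
    x, y, z = grid.coordinate_arrays()
    cx, cy, cz = center_mm
    ax, ay, az = semiaxes_mm
    q = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2
    if not is_2d:
        q = q + ((z - cz) / az) ** 2
    return q <= 1.0


def generate_head_phantom(
    config: PhantomConfig | None = None, seed: int = 0
) -> tuple[TissueLabelVolume, HUVolume, ActivityVolume]:
    """Build labels, CT and activity for one synthetic head.

    Deterministic in ``(config, seed)``; the CT's per-tissue Gaussian noise
    and nothing else consumes randomness.
    """
    config = config or PhantomConfig()
    config.validate()
    grid = config.grid()
    is_2d = grid.is_2d
    rng = np.random.default_rng(seed)

    def shrink(axes, margin):
        out = tuple(a - margin for a in axes)
        if min(out) <= 0:
            raise ValueError("shell thicknesses collapse an ellipsoid")
        return out

    head_ax = config.head_semiaxes_mm
    skull_out = shrink(head_ax, config.scalp_thickness_mm)
    skull_in = shrink(skull_out, config.skull_thickness_mm)
    brain_out = shrink(skull_in, config.csf_thickness_mm)
    wm_out = shrink(brain_out, config.gm_thickness_mm)
    origin = (0.0, 0.0, 0.0)

    head = _ellipsoid_mask(grid, origin, head_ax, is_2d)
    m_skull_out = _ellipsoid_mask(grid, origin, skull_out, is_2d)
    m_skull_in = _ellipsoid_mask(grid, origin, skull_in, is_2d)
    m_brain = _ellipsoid_mask(grid, origin, brain_out, is_2d)
    m_wm = _ellipsoid_mask(grid, origin, wm_out, is_2d)

    labels = np.full(grid.shape, AIR, dtype=np.int32)
    labels[head] = SOFT_TISSUE
    labels[m_skull_out & ~m_skull_in] = SKULL_BONE
    labels[m_skull_in & ~m_brain] = CSF

    gm = m_brain & ~m_wm
    x, y, z = grid.coordinate_arrays()
    # azimuth from anterior (+y), in ellipse-normalized in-plane coordinates,
    # so the wedges subtend comparable arcs of the elliptical ribbon
    phi = np.degrees(
        np.abs(np.arctan2(x / brain_out[0], y / brain_out[1]))
    )
    labels[gm & (phi < config.frontal_max_deg)] = GM_FRONTAL
    labels[gm & (phi >= config.frontal_max_deg) & (phi < config.cingulate_max_deg)] = GM_CINGULATE
    labels[gm & (phi >= config.cingulate_max_deg) & (phi < config.temporal_max_deg)] = GM_LATERAL_TEMPORAL
    labels[gm & (phi >= config.temporal_max_deg) & (phi < config.parietal_max_deg)] = GM_PARIETAL
    labels[gm & (phi >= config.parietal_max_deg)] = CEREBELLUM_GM

    labels[m_wm] = WHITE_MATTER
    vent = _ellipsoid_mask(grid, origin, config.ventricle_semiaxes_mm, is_2d)
    labels[vent & m_wm] = VENTRICLE
    sinus = _ellipsoid_mask(
        grid, config.sinus_center_mm, config.sinus_semiaxes_mm, is_2d
    )
    labels[sinus & head & ~m_brain] = SINUS_AIR

    label_vol = TissueLabelVolume(grid, labels, PALETTE)
    name_to_label = label_vol.name_to_label()

    hu = np.full(grid.shape, -1000.0)
    for name, (mean, sd) in config.hu_table.items():
        mask = labels == name_to_label[name]
        if not mask.any():
            continue
        if sd > 0:
            hu[mask] = mean + sd * rng.standard_normal(int(mask.sum()))
        else:
            hu[mask] = mean
    hu = np.clip(hu, -1024.0, None)

    act = np.zeros(grid.shape)
    for name, value in config.activity_table.items():
        act[labels == name_to_label[name]] = value

    return label_vol, HUVolume(grid, hu), ActivityVolume(grid, act)


def derive_true_mu(
    labels: TissueLabelVolume, mu_table: dict[str, float] | None = None
) -> MuMap:
    """Piecewise-constant ground-truth 511-keV mu-map from tissue labels."""
    mu_table = mu_table if mu_table is not None else DEFAULT_MU_TABLE
    lut_size = int(labels.labels.max()) + 1
    lut = np.full(lut_size, np.nan)
    name_of = labels.palette
    for code in np.unique(labels.labels):
        name = name_of[int(code)]
        if name not in mu_table:
            raise KeyError(f"mu_table has no entry for label {code} ({name!r})")
        lut[int(code)] = mu_table[name]
    values = lut[labels.labels]
    return MuMap(labels.grid, values, provenance="ground_truth")


def derive_mrac_map(
    labels: TissueLabelVolume, true_mu: MuMap, model: MRACErrorModel
) -> MuMap:
    """Apply an MRI-method-like error signature to the ground-truth mu-map."""
    labels.grid.require_same(true_mu.grid, "labels and true mu-map")
    bone = labels.mask_of("skull_bone")
    mu = true_mu.values.copy()
    soft_mu = DEFAULT_MU_TABLE["soft_tissue"]
    meta = {"mrac_model": model.method}

    if model.method == "perfect":
        pass
    elif model.method == "dixon_like":
        # Dixon sequences see no bone signal: skull classified as soft tissue
        mu[bone] = soft_mu
    elif model.method == "zte_like":
        rng = np.random.default_rng(model.seed)
        factors = 1.0 + model.bone_mu_noise_sd * rng.standard_normal(int(bone.sum()))
        mu[bone] = np.clip(mu[bone] * factors, 0.0, None)
    elif model.method == "atlas_like":
        # template skull registered imperfectly: shift the bone compartment
        # along y by bone_shift_mm; vacated bone voxels become soft tissue
        shift_vox = model.bone_shift_mm / labels.grid.spacing[1]
        mu_no_bone = mu.copy()
        mu_no_bone[bone] = soft_mu
        bone_shifted = ndimage.shift(
            bone.astype(float), (0.0, shift_vox, 0.0), order=0, mode="constant"
        ) > 0.5
        mu = mu_no_bone
        inside_head = labels.labels != AIR
        paste = bone_shifted & inside_head
        mu[paste] = true_mu.values[bone].mean() if bone.any() else soft_mu
    return MuMap(true_mu.grid, mu, provenance="mri_derived", meta=meta)


def amyloid_config(**overrides) -> PhantomConfig:
    """Default phantom with the amyloid-like activity preset."""
    return replace(
        PhantomConfig(**overrides), activity_table=dict(ACTIVITY_AMYLOID)
    )
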