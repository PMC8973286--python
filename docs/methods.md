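# Methods

This note documents the models, parameter choices and known limits of the
`petmrqual` pipeline: what exactly is simulated, which knobs matter, and what
a passing test suite does and does not establish about real scanner data.

## The qualification model

The pipeline isolates attenuation correction (AC) from every other factor in
PET quantification.  Both reconstruction arms share the identical emission
data, geometry, reconstruction algorithm and settings; they differ only in
the attenuation map used to form the attenuation correction factors.  Any
difference between the two reconstructed images is therefore attributable to
the AC method (plus reconstruction nonlinearity acting on shared noise).
This mirrors the centralized-processing design used in practice, where a
qualification group re-reconstructs submitted raw data with both maps.

## Synthetic head phantom

A nested-ellipsoid head on a shared voxel grid (default 128×128×64 at 2 mm
isotropic; a single-slice 128×128 mode shares all code paths and is the
default test scale):

* outer soft-tissue scalp (semi-axes 80×100×62 mm), 6 mm skull shell, 4 mm
  CSF rim, 9 mm cortical gray-matter ribbon, white-matter core with a
  CSF-filled ventricle, a frontal sinus air pocket, and a cerebellar
  compartment;
* the cortical ribbon is partitioned into five azimuthal wedges named after
  the study composites used in amyloid protocols (frontal, cingulate,
  lateral temporal, parietal, cerebellum).  The wedges are positional
  stand-ins, not anatomy: what matters for AC evaluation is that each
  composite is a bilateral cortical region adjacent to the skull, with the
  posterior wedge doubling as the reference region.  Using wedges keeps every
  composite nonempty in both 2-D and 3-D modes;
* CT numbers are drawn per tissue from Gaussians (soft tissue 40±10 HU,
  brain 30–40±5 HU, skull 1000±100 HU, air −1000 HU); activity is piecewise
  constant per tissue.  Two tracer presets exist: FDG-like (GM:WM = 4:1,
  the default) and amyloid-like (WM ≥ GM, for reference-region workflows).

The phantom is geometric rather than anatomical by design: the AC error
mechanisms under test (missing, noisy or shifted bone) depend on the presence
of a bone shell between brain and detectors, not on gyral anatomy, and a
generated phantom keeps the package free of data downloads.

Ground-truth 511-keV attenuation: air 0, soft tissues 0.096 cm⁻¹, bone
0.151 cm⁻¹ (standard literature values, configurable, never hard-coded in
logic).

### MRAC error models

* `perfect` — identity control.
* `dixon_like` — every skull voxel reassigned soft-tissue μ: Dixon sequences
  receive no bone signal, so vendor Dixon maps classify skull as soft tissue.
* `zte_like` — bone μ multiplied by 1 + N(0, sd); default sd = 0.02.  ZTE
  images bone but with imperfect μ estimation.  The 2% default is a
  placeholder magnitude (the literature reports no single canonical value)
  exposed in config.
* `atlas_like` — the bone shell translated rigidly (default 2 mm, also a
  configurable placeholder) before μ assignment; vacated voxels become soft
  tissue.  Emulates residual template-registration error in atlas methods.

## CT-side μ-map preparation

Order is fixed and provenance-stamped: strip → register → convert → smooth →
resample → fill.

* **Stripping** keeps the largest connected component above −200 HU and sets
  the rest to −1000 HU.
* **HU→μ** uses a bilinear calibration: μ = 0.096·(1 + HU/1000) cm⁻¹ up to a
  50 HU breakpoint, then a bone slope chosen so μ(1000 HU) = 0.151 cm⁻¹,
  matching the phantom's ground-truth bone value.  Real vendors ship their
  own curves; the bilinear form with a breakpoint near 50 HU is standard
  PET/CT practice.  All four constants live in the config.
* **PSF matching** is a grid-aware Gaussian (FWHM in mm, σ = FWHM/2.355 per
  axis, "nearest" boundaries so edge μ is held rather than diluted with
  air).  The FWHM is deliberately a required setting with no default in
  evaluation mode — it is a scanner property the operator must state.  The
  bundled scenarios set it to 0 because the simulator has no detector PSF,
  so both arms are already at the same (perfect) resolution.
* **Resampling** is trilinear with an explicit coverage mask; uncovered
  voxels are filled from the MRAC map and the fill fraction is recorded
  (QC1 flags it above 5% by default).

A deliberate consequence of realistic CT numbers: brain parenchyma at
~30–40 HU converts to ~0.099 cm⁻¹, while the ground-truth soft-tissue μ is
0.096 cm⁻¹.  The CTAC arm therefore over-corrects by ~3.5% relative to the
MRAC arm even with a perfect MRAC map — the kind of residual calibration
offset real qualification data also carry.  The QC bounds absorb it; it is
visible in the reports as a roughly −3.5% baseline on every ROI.

## Registration

Rigid 6-DOF (3-DOF in-plane in 2-D mode), normalized mutual information
NMI = (H(A)+H(B))/H(A,B) over a 32-bin joint histogram of the overlap,
optimized by Powell over a 3-level pyramid (factors 4, 2, 1).  Initialization
is by centre-of-mass translation plus a coarse per-axis rotation sweep
(±12° in 3° steps) at the coarsest level; this steps over the local optima in
which a translation partially compensates a missed rotation, which plain
Powell falls into for a few percent of large perturbations.  The rotation
centre is the fixed image's centre of mass (decorrelates rotation from
translation).  The optimizer never returns a transform scoring below the
identity start, and a non-overlapping start raises an error suggesting manual
initialization.  Recovery accuracy on the phantom is ~0.1–0.5 mm / ≤0.4°
for perturbations up to 10° / 8 mm.

Misregistration review (QC1) is and remains a human task; the tool emits
overlays plus a numeric surrogate (soft-tissue mean and 95th-percentile
|Δμ|, Dice overlap of thresholded bone shells at μ > 0.12 cm⁻¹) and raises a
suspicion flag when the bone Dice falls below a configurable bound (0.70).

## PET simulator

2-D parallel beam per axial slice, slices independent (stacked for 3-D);
default 160 angles over [0°, 180°) and 128 radial bins at 2 mm.  The angle
count is a multiple of the subset count by construction (subsets partition
angles round-robin).  Line integrals are computed with a separable-footprint
projector: the image is the bilinear (tensor-hat) expansion of pixel values,
and for parallel rays at angle θ the exact projection of a hat depends only
on the ray's distance to the pixel centre — the convolution of four boxes of
widths dx|cosθ|, dx|cosθ|, dy|sinθ|, dy|sinθ|, integrating to dx·dy.  The
footprint is tabulated per angle on a fine grid (0.02 × bin spacing) and
assembled once into a sparse matrix shared by the forward model, the ACF
computation and OSEM.  Against a dense ray-sampling oracle the worst per-line
error is ≲0.3% (classic driving-axis Joseph stepping, which was considered
first, errs by several percent per line at oblique angles on non-smooth
images and was rejected).

Counting noise: expected sinogram scaled to a total count level (default
5×10⁵ counts per slice — a placeholder for the "≥10 minute" acquisitions of
real protocols, which map to no single count number) and Poisson-sampled
with an explicit seed.

OSEM uses the standard multiplicative update with attenuation factors
f = 1/ACF in the system model and subset sensitivity images Aᵀf; ε = 10⁻¹²
guards ratios; pixels outside every line of response are pinned to zero.
Scatter, randoms, dead time, decay and resolution modelling are deliberately
absent: the evaluation isolates AC error propagation, and those corrections
are shared by both arms in the real workflow.  (Real pipelines also derive
the scatter estimate from the attenuation map; that coupling is not
simulated, so the measured bias here is attenuation-only.)

Convergence note: at the scenario settings (10 iterations × 8 subsets,
unregularized), thin high-contrast structures are ~97% converged — the
9 mm GM ribbon at 4:1 contrast recovers to ~0.97 of truth, reaching ~0.99 by
30 iterations.  This affects both arms identically and cancels in the bias;
ROI-recovery properties are asserted at 3% in the converged regime and 4% at
scenario settings.

## QC analysis

* Bias is computed only where the CTAC denominator exceeds a floor (1% of
  the mask-mean CTAC value); excluded voxels are counted and flag QC1 above
  0.5% of the mask.
* "Below X%" is strict (<) everywhere: boundary values fail.
* QC3's primary statistic is the ROI average of voxelwise absolute %diff
  (the literal "average absolute percentage difference").  The %diff of ROI
  mean uptake is also reported per ROI — it is the SUV-ratio-style statistic
  — and drives QC4 and the Bland–Altman coordinates.  The QC3 metric is
  switchable in config.
* The cumulative curve f(t) = fraction of voxels with |%diff| ≤ t uses the
  inclusive convention; QC2 uses strict < at its threshold.  The two agree
  exactly unless voxels sit on the threshold.
* Multi-subject reports require every submitted subject to pass; no pooled
  statistic is invented.

## Determinism and reproducibility

Every stochastic stage (CT noise, MRAC bone noise, Poisson counting) has an
explicit seed in the config; generators are pure functions of (config, seed).
A full simulate + evaluate rerun reproduces the QCResult JSON byte-for-byte
(no timestamps are embedded), and the simulate manifest records the config
hash and per-file checksums.

## Problem sizes used in the shipped scenarios

The packaged qualification scenario runs the default 3-D phantom
(128×128×64 at 2 mm, ≈128 000 brain-mask voxels), 160 angles × 128 bins,
5×10⁵ counts per slice, OSEM 10×8 — a scale chosen so a full dual
reconstruction completes in well under a minute on one CPU while keeping
>10⁵ brain voxels for the voxel-fraction statistics.  Unit and property
tests use the single-slice mode and small toy grids.

## Limitations

* Geometric phantom: no gyri, no air–bone fine structure, no continuous HU
  variation; bias magnitudes are indicative, not predictive of any specific
  patient or scanner.
* Parallel-beam 2-D physics: no 3-D scanner geometry, time of flight,
  scatter or randoms; vendor raw formats and DICOM are out of scope (NIfTI
  and a simple NPZ sinogram container are the interchange formats).
* MRAC models reproduce error *signatures*, not MRI physics; their default
  magnitudes are placeholders exposed in config.
* QC1 automation is a surrogate; the human-review flag is always set.
* Passing the shipped scenarios demonstrates that the pipeline implements
  the decision procedure correctly and that it discriminates bone-accurate
  from bone-less AC under controlled conditions — it says nothing about any
  physical scanner's qualification status.
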