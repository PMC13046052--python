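# Methods

## Problem and approach

Digital chest tomosynthesis acquires ~60 low-dose projections over a
narrow angular range (±15°) while the X-ray tube sweeps along a vertical
line at a fixed horizontal distance (180 cm) from the detector.  The
resulting data carry genuine depth information, but far less than CT.
`tomosynth` implements a slice-wise strategy for recovering CT-like
volumes from such projections:

1. **Geometric locality.**  Because the source moves only vertically, the
   lateral detector coordinate of any projected point is independent of
   the view: every ray through one sagittal plane of the patient lands in
   a narrow vertical strip of detector columns (31 px wide at the native
   2048-px detector).  A sagittal slice can therefore be predicted from a
   (views × rows × strip-width) patch stack rather than from the full
   projection set.
2. **Tissue-class surrogate.**  Instead of regressing continuous
   Hounsfield units, voxels are classified as air (< −800 HU), soft
   tissue ([−800, 300) HU) or bone (≥ 300 HU).  For display and HU-space
   metrics, classes map back to representative values −1000 / 0 / 500 HU.
   The thresholds in the literature leave −800 and 300 HU unassigned; we
   close the partition with half-open intervals (−800 → soft, 300 → bone),
   a measure-zero choice on continuous data.
3. **Supervision by construction.**  Real projection/CT pairs are
   misaligned across modalities.  Training pairs are instead built by
   simulating projections *from* the CT (or phantom) volume under the
   known geometry, so input and target are aligned exactly.

## Coordinate conventions

World frame: x lateral (sagittal-slice index axis), y vertical (sweep
axis), z depth (beam axis), right-handed, millimetres.  The detector lies
in the plane z = 0 with its row axis vertical and column axis lateral,
origin at the detector center; the source sits at (0, sdd·tan θ, sdd)
with θ uniformly spaced over the sweep, endpoints included (the angular
range is the only quantity stated for the hardware; uniform-in-angle is
the conventional reading).  Volumes are placed with their center on the
mid-patient plane (0, 0, `patient_offset_mm`).  Magnification is
M(z) = sdd/(sdd − z).

Strip windows are centered using the mid-patient magnification
`M_mid = M(patient_offset_mm)`; the configured width absorbs the
depth-dependent magnification spread.  Patient-to-detector distance and
detector pitch are not published for the hardware class; the defaults
(150 mm mid-patient depth, 0.2 mm pitch ≈ 41 cm field of view) are
plausible and fully configurable.

## Phantoms

The generator paints analytic solids into a voxel grid in a fixed order —
background (−1000 HU) → soft-tissue body ellipsoid (+40) → two lung
ellipsoids (−850) → bone (+700; vertical spine cylinder and circular rib
arcs, both clipped to the body) → spherical nodules (+20).  Later regions
overwrite earlier ones; membership is decided at voxel centers with no
partial-volume antialiasing, which keeps brute-force point-in-geometry
tests exact.  Lung HU (−850) deliberately sits below the −800 air
threshold so parenchyma classes as air, as it largely does in real CT.
Rib heights/radii take a small seeded jitter; `sample_spec` additionally
randomizes body/lung half-axes, offsets, spine radius, rib count and 0–2
nodules per patient to emulate cohort variability.  Gaussian HU noise
(`perturb_phantom`, clipped at −1024) is available to make thresholds
non-trivial.

What the phantoms do **not** emulate: continuous HU texture, partial
volume at tissue interfaces, anatomy beyond the three-class layout
(mediastinum, vessels, airways), breathing states.  Passing desk-scale
tests therefore demonstrates that the geometry, physics, learning and
evaluation machinery work and that the slice-wise mapping is learnable —
not that the shipped weights transfer to clinical data.

## Projection simulation

HU converts to relative electron density through a piecewise-linear
anchor table ((−1000, 0.0), (0, 1.0), (300, 1.10), (1000, 1.55)), clamped
outside; attenuation per mm is density × `mu_water_per_mm` (default
0.02/mm, water at ~60–70 keV effective energy).  Each detector pixel
receives the exact line integral along the ray from the source to the
pixel center, computed by incremental Siddon-style traversal with exact
per-voxel path lengths (the volume is piecewise constant over voxels);
rays target pixel centers with no sub-pixel detector integration.  The
inner loop is numba-compiled.

Four augmentations model the dominant physical deviations, applied in a
fixed recorded order (hardening → scatter → motion → noise, each the
identity at its zero parameter):

- **Beam hardening** — monochromatic transport with a quadratic
  line-integral distortion p → p − βp² (default β = 0.05), guarded by
  βp < 0.5 so the map stays monotone.  One parameter stands in for
  polychromatic spectra.
- **Scatter** — a low-frequency scattered-intensity field: with primary
  P = n₀e^(−p), p′ = −ln((P + SPR·blur(P))/n₀) (default SPR = 0.2,
  Gaussian blur σ = 40 px at the full detector, 8 px at the desk
  detector).
- **Motion** — a rigid per-view vertical shift ~ N(0, 0.5 mm), linear
  interpolation, edge clamping; the sweep direction is the dominant
  respiratory/cardiac motion axis at this timescale.  No intra-view blur.
- **Poisson noise** — N ~ Poisson(n₀e^(−p)) per pixel (default
  n₀ = 10⁴ photons), re-logged with a max(N, 1) guard.

No published values exist for any augmentation strength; all defaults are
package choices exposed in `PhysicsConfig`.

## Model

A hybrid 2.5D encoder–decoder (~266 k parameters at the full-scale
configuration, within the 1.3 M budget the architecture targets):

- **Encoder**: strided 3×3×3 convolution + ReLU stages over
  (view, row, column).  Rows downsample toward the decoder's seed
  resolution (2048 → 32 at full scale) while the view and strip axes
  shrink to 1 and their content moves into channels.
- **Bottleneck**: a row-wise dense map turns each encoder row feature
  vector into that row's seed block of the 2D (row, depth) decoder.  A
  global fully-connected bottleneck would alone exceed the parameter
  budget at full scale and would discard the row correspondence; the
  row-wise form keeps both.
- **Decoder**: nearest-neighbor ×2 upsampling + 3×3 convolution + ReLU
  stages over (row, depth), synthesizing the depth axis from the seed.
- **Adaptive skips**: encoder features whose row resolution matches a
  decoder stage are flattened (view/width into channels), projected by a
  1×1 dense adapter, and broadcast-added along the depth axis — the
  minimal mechanism that carries vertical detail across the rank
  mismatch between 3D encoder and 2D decoder features.
- **Head**: per-pixel linear map to 3 channels + softmax.  Ties in the
  downstream argmax break toward the earlier class (air < soft < bone).

Stage counts, kernel sizes and channel widths are `ModelConfig` fields;
the shipped defaults are desk (16×128×7 → 32×32, ~49 k parameters) and
full scale (60×2048×31 → 512×512, 265 915 parameters).  The row
reduction happens in the model (strided encoder), not the dataset, so
patches stay at native detector resolution.  Inputs are normalized by a
fixed affine (offset/scale in `ModelConfig`) chosen once from the typical
line-integral range of the preset.  `audit_parameter_count` recomputes
the parameter count arithmetically from the config alone and is asserted
against the instantiated model.

The network and its training loop are implemented directly in numpy
(explicit forward/backward passes, float64, Adam with bias correction):
a deliberately small, dependency-light CPU implementation whose gradients
are verified against central differences in the test suite.

## Training

Composite loss = generalized Dice + categorical cross-entropy (weights
1 : 1; no published ratio exists).  Generalized Dice uses squared-inverse
class-volume weights w_c = 1/(Σg_c + ε)², ε = 10⁻⁶, computed **per
batch**; cross-entropy clips probabilities to [10⁻⁷, 1].  The GDL term
counteracts the heavy class imbalance (bone is ~3% of voxels at desk
scale).  Optimization is Adam at 3×10⁻⁴ with batch 16, seeded shuffling,
a divergence guard on non-finite loss, per-epoch validation loss and
per-class recall, best-validation weight restore, and optional
patience-based early stopping (no convergence criterion is published;
patience is config).

## Evaluation

- **Confusion matrix**: 3×3 counts pooled over all voxels of all
  evaluated patients, rows = true class, columns = predicted, fixed
  air/soft/bone order; row-normalized with zero-support rows flagged as
  undefined rather than divided.
- **MAE**: predicted labels map to representative HU; the error reference
  is the **original continuous HU** of the ground truth, grouped by
  **true** class (this makes the per-class decomposition meaningful; the
  alternative — label-converted truth — is available via
  `labels_to_hu`).  Per-patient values aggregate as mean ± SD **across
  patients**.
- **Reassembly**: slice predictions stack along the lateral axis;
  coronal planes of the assembled volume equal depth-index gathers of the
  individual slice predictions by construction.
- A split audit refuses evaluation of any patient present in the
  training ids.

## Desk-scale benchmark

The self-contained study surrogate: 200 randomized phantoms at 48³
(3 mm voxels), 16 views on a 128×128 detector (1.4 mm pitch), width-7
strips, 3 sagittal slices per patient drawn from the central band (which
crosses lungs and spine, so all three classes appear), 32×32 targets,
patient-level split in the study proportions (~83/8.5/8.5%), 20 epochs.
These sizes run end to end in a few minutes on one CPU.  Expected
behavior, recomputed by `scripts/acceptance.py` and the acceptance tests:
held-out voxel accuracy ≳ 0.9, air/soft recall ≳ 0.9, bone recall
markedly lower with bone→soft confusion dominating — the same error
structure the full-scale study reports — and overall MAE below the
all-soft-prediction baseline by a large margin.

The two-sample overfit probe checks optimization capacity by memorizing
two pairs for 200 epochs at a larger step (5×10⁻³); it restarts from a
fresh seeded initialization (≤3 starts) if the loss plateaus, because at
this scale an occasional draw traps a channel in a dead-ReLU state,
which says nothing about capacity.

## Numerical notes

- The projector's independent test oracle samples rays at 1/20-voxel
  steps.  On spatially *uncorrelated* random volumes the oracle's own
  Riemann error at grazing rays reaches several percent, which would
  swamp the comparison; oracle-equivalence tests therefore use smoothed
  random fields (Gaussian σ = 1.2 voxels) — also the realistic texture
  class for HU-derived density maps — where the oracle's error stays
  well inside the 0.5% comparison band.
- Nearest-neighbor resampling (targets, reassembly) uses phase 0:
  out[j] = in[floor(j·n_in/n_out)].
- All randomness flows from one global seed through named substreams
  (phantom, physics, split, train); same seed ⇒ bit-identical phantoms,
  projections, splits and training runs (single-threaded).
- Degenerate inputs: rays missing the volume integrate to 0; empty
  confusion rows are flagged, not divided; empty MAE classes report NaN
  and are excluded from cross-patient aggregation.

## Known limitations

Three tissue classes only; no iterative/FBP reconstruction baseline; no
real-data reader (the acquisition vendor's projection format is not
public); monochromatic physics with scalar augmentation knobs; the numpy
backend is single-threaded and sized for desk-scale experiments, not for
training the full 2048-row configuration.
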