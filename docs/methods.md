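# Methods

## Problem and model

Three-port double-scattering (DS) proton plans are sensitive to gantry
angle choice: each field deposits dose along its whole entrance channel
and stops at the target's distal edge, so good angles combine a short
water-equivalent path to the target with no organ-at-risk (OAR) just
beyond the distal edge, where range overshoot would land. The package
casts beam-angle optimization as supervised regression: geometry in,
angle ranking out.

**Input.** For each gantry angle (0°–358°, step 2°) a fan of 25
parallel rays is traced: the central ray through the isocenter and 12
rays on each of two ellipses placed on the target's beam's-eye-view
(BEV) cross-section, with semi-axes 1/3 and 2/3 of the BEV
half-extents, rays spaced 30° apart starting at the BEV vertical. Each
ray spans 1,000 mm in 4,000 bins (0.25 mm pitch), bins ordered from the
source side toward the isocenter, and records nine features per bin:
the per-patient Z-scored HU and the binary membership of eight
structures (body, TLV, PGTV, duodenum, stomach, esophagus, heart,
spleen). Rows are laid out feature-fastest (row = angle·225 + ray·9 +
feature), so the assembled array is 40,500 × 4,000.

**Output.** `S_beam`, 360 scores in [0, 1]. The reference places a 1.0
at every clinically used angle and smooths with a circular Gaussian;
the filter is **peak-normalized** (each clinical angle keeps exactly
1.0, overlapping peaks combine by maximum) because an area-normalized
kernel could not respect the stated [0, 1] range with unit peaks.

**Network.** Two integration convolutions (9×1 stride 9, merging ray
features; 25×1 stride 25, merging rays) reduce the input to one row per
sampled angle; six 3×3 stride-1 convolutions with channel sequence
3-9-27-9-3-1 and 2×2 max pooling (floor division) extract joint
features; the flattened 1,220 values feed linear layers 560-560-560-360.
Batch normalization and leaky ReLU (slope 0.01) follow every
convolution/linear layer except the final linear, whose raw output is
clamped to [0, 1] post hoc for downstream use (clamping cannot change
the angle ranking of in-range scores).

## Parameter choices

| parameter | default | why |
| --- | --- | --- |
| ray length / bins | 1000 mm / 4000 | fixed collector geometry; 0.25 mm pitch |
| angle step | 2° | matches the 40,500-row input layout |
| target sigma | 5° | separates 30°-spaced beams; grades 2°-spaced inputs |
| augmentation | ±2° circular shift of the target, redrawn per epoch | regularizes peak placement; the input is not shifted (an optional paired-shift mode exists, off by default) |
| loss | smooth-L1, β = 0.5 | best of L1/L2/smooth-L1; β on the score scale |
| optimizer | Adam, lr 1e-3, weight decay 2e-4, betas 0.9/0.999 | standard adaptive-moment setup for this model class |
| batch size | 1 (configurable; experiments use full batch) | one full-size sample is ~0.65 GB |
| K folds | 5 | patient-wise cross-validation |
| Z-score | population SD, clamped at 1e-6 | per-patient normalization; binary channels untouched |
| min separation | 30° circular | DS fields must not crowd |
| CI variant | (TV·PIV)/(TV∩PIV)², Paddick reciprocal optional | the ratio form can exceed 1 as reported CIs do |

Open geometry choices resolved here: rays span exactly 1,000 mm ending
at the isocenter plane (body-entry position is then encoded by the body
channel, keeping the input shape fixed); BEV half-extents come from the
axis-aligned bounding box of the projected PGTV voxel centres; bins on
the far side of the body are sampled as-is; HU is interpolated
trilinearly but structures with nearest-voxel lookup so the binary
channels stay binary; "same" padding on the two integration
convolutions contributes nothing because the kernel tiles the stride
exactly, and the remaining convolutions are unpadded — the only reading
consistent with the 180 → 178 transition in the layer table.

## Network engine

No deep-learning framework is used: convolution, batch normalization
(2-D and 1-D, momentum 0.1, eps 1e-5, population batch variance),
2×2 max pooling, linear layers and Adam (L2-coupled weight decay) are
implemented in numpy with hand-written backward passes. All parameter
gradients — including the fast exact path used by the two stride-tiled
integration convolutions — are verified against central finite
differences in float64. Weights and biases are initialized fan-in
uniform from a seeded generator; biases are randomly initialized on
every layer, including the batch-norm shifts. Forward passes cache
inputs only in training mode, so full-size inference fits comfortably
in desktop memory (≈0.75 GB peak). With a batch of one sample,
1-D batch normalization degenerates (the batch variance is zero), so
desk-scale experiments train full-batch.

## Synthetic phantoms

A phantom is a stack of ellipsoids — body, liver (TLV), tumor (PGTV)
inside the liver, and five OARs — with HU 40/60/55 for body/liver/tumor,
30–50 for OARs, −1000 air, plus Gaussian CT noise (SD 15 HU, a typical
abdominal CT noise level) rounded to integer HU; integral HU makes the
DICOM round-trip bit-exact. Containment (PGTV ⊂ TLV ⊂ body, OARs ⊂
body) is validated on the rasterized masks. The sampled study family
varies the tumor's position in the liver (uniform azimuth, 8–22 mm
radial, ±8 mm axial) and jitters organ centres (±4 mm) and sizes (±8%).

Phantom "clinical" angles are **computed, not random**: each angle's
central ray is scored by minus the water-equivalent path length
(WEPL; relative stopping power approximated as 1 + HU/1000, clamped at
0) from body entry to the proximal PGTV edge, minus the OAR path length
beyond the distal edge (unit penalty weight per mm), sampled at 1 mm;
the constrained top-3 of the min-max-normalized scores become the
plan's angles. This gives the network a learnable geometry → angle
mapping. Because the score is evaluated on voxelized anatomy, exact
score ties never occur in practice (a discretized sphere shows ~2
voxels of WEPL anisotropy across angles); tie-breaking to the lowest
angle is exercised where it lives, in the selection rule.

The toy dose is a deliberate cartoon of a stopping proton field: each
unit-weight field fills the body-limited elliptical cylinder around the
target's BEV cross-section up to the distal PGTV edge (plus half a
voxel) and nothing beyond, and the sum is normalized to a mean PGTV
dose of 100%. It reproduces the *bookkeeping* of plan metrics
(conformity, V_x, OAR statistics), not proton transport: no lateral
penumbra, no Bragg-peak weighting, no scatter or range straggling.
Passing metric tests therefore validates the metric code, not dosimetric
realism.

## Desk-scale experiments and their limits

The full-size network is exercised as built (shape checks and a
forward pass); training experiments run a proportionally shrunk
configuration (`NetSpec.scaled`) that keeps both integration
convolutions and as many 3×3 conv/pool blocks as the reduced extent
allows. The packaged experiments use a 5° angle step and 60 bins
(16.7 mm pitch), sizes chosen so one leave-one-out sweep stays within
minutes on a single CPU.

Two learning checks are packaged. (1) *Capacity*: one phantom pair is
overfit in 200 epochs to near-zero MSE. (2) *Generalization*: 8
phantoms, leave-one-out, 300 epochs each, asking whether the held-out
case's predicted top-1 angle lands within ±5° (one sigma) of a true
clinical angle. In our runs the trained networks always place the
held-out top-1 within ~15° of a true angle — the geometry → angle
mapping is genuinely learned — but the strict ±5° bar is met in only
about half the rounds: seven training cases cannot pin peak positions
to single-degree precision, and the corresponding test documents this
honestly by failing. Narrowing the phantom family to one latent factor
does not change this, so the limit is training-set size, not family
complexity.

## Known limitations

- Dose is schematic (see above); conformity indices on the toy dose are
  systematically ≥ 1 and not comparable to clinical values.
- Coplanar fans only; non-coplanar geometry is out of scope.
- The geometric reference-angle score is a surrogate for planner
  choices, not a dosimetric optimum.
- DICOM support targets well-formed single-series CT and planar
  RTSTRUCT contours; even-odd fill handles nested rings but not
  self-intersecting contours.
- Batch normalization uses population batch variance and a 0.1
  running-average momentum; other frameworks' defaults differ slightly.
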