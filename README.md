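# baods

Beam-angle optimization for three-port **double-scattering (DS) proton
therapy**, driven purely by patient geometry: a beam's-eye-view ray
collector turns CT anatomy into a fixed-shape feature array, a
convolutional network maps it to a 360-element **gantry-angle ranking
score** `S_beam` (one score per degree, 1.0 = ideal), and a constrained
rule picks the three treatment angles. Plan quality is then judged with
standard DVH metrics. The package is aimed at medical-physics
researchers who want to study geometry-only beam-angle optimization
without a treatment planning system: it reads and writes plain
DICOM-RT (CT, RTSTRUCT, RTPLAN, RTDOSE) and ships a synthetic abdominal
phantom generator so the whole chain is testable without patient data.

## Method

For every gantry angle sampled at 2°, 25 parallel rays are traced
through the CT: the central ray through the isocenter plus 12 rays on
each of two ellipses (semi-axes 1/3 and 2/3 of the target's BEV
half-extents) covering the PGTV cross-section. Each ray spans 1,000 mm
in 4,000 bins of 0.25 mm and collects 9 features per bin — the
per-patient Z-scored Hounsfield unit and binary membership of the eight
structures (body, TLV, PGTV, duodenum, stomach, esophagus, heart,
spleen). The assembled input is 180 x 25 x 9 = **40,500 rows x 4,000
columns**.

The network opens with two "integration" convolutions — 9x1 at stride 9
(merging the 9 features of a ray) and 25x1 at stride 25 (merging the 25
rays of an angle) — followed by six 3x3 convolutions with 2x2 max
pooling, then four fully connected layers (1220 -> 560 -> 560 -> 560 ->
360). Every convolution/linear layer except the last is followed by
batch normalization and a leaky ReLU. Training uses Adam
(lr 0.001, weight decay 2e-4, betas 0.9/0.999), a ±2° random circular
shift of the reference scores each epoch, and one of three losses

    L1:        Z_i = |x_i - y_i|
    L2:        Z_i = (x_i - y_i)^2
    smooth-L1: Z_i = 0.5 (x_i - y_i)^2 / beta   if |x_i - y_i| < beta
               Z_i = |x_i - y_i| - 0.5 beta     otherwise   (beta = 0.5)

with patient-wise K-fold cross-validation (K = 5). The reference
`S_beam` places a peak-normalized circular Gaussian (sigma = 5°) at
each clinically used angle, so the clinical angles score exactly 1.0.

Angle selection walks the scores in descending order and accepts an
angle only if it is at least 30° (circular) from every accepted one,
stopping at three. Plans are compared with the conformity index
CI = (TV x PIV) / (TV ∩ PIV)^2 (Paddick reciprocal available), V_x and
per-OAR min/mean/max dose, all in % of prescription.

The network engine (convolution, batch normalization, pooling, linear
layers, Adam) is implemented in numpy with hand-written backward passes
and is verified against finite-difference gradients in the test suite.

## Worked example

```
$ baods simulate --seed 1 --out /tmp/case
case phantom-1: clinical angles [14.0, 344.0, 45.0]

$ baods extract --case /tmp/case --step 45 --bins 64 --out /tmp/ft
feature tensor 1800 x 64

$ baods make-target --angles 140,190,240 --out /tmp/sbeam.txt
$ baods select --sbeam /tmp/sbeam.txt
{"angles": [140.0, 190.0, 240.0]}

$ baods run --seed 3 --out /tmp/run
{"angles": [32.0, 62.0, 1.0], "conformity_index": 1.3481781376518218}
```

The simulated phantom's "clinical" angles are derived from its own
geometry (shortest water-equivalent path to the tumor, penalizing
organ-at-risk overlap beyond the distal edge), so anatomy, ranking
scores and selected beams are mutually consistent. `run` executes
extract → score → select → evaluate on a phantom and reports the
selected three-beam set and the conformity index of the toy dose (a
value ≥ 1; closer to 1 is more conformal).

## Layout

- `baods.io_rt` — DICOM-RT reading/writing, contour rasterization
- `baods.phantom` — synthetic cases, geometric reference angles, toy dose
- `baods.collector` — ray fans and the feature tensor
- `baods.targets` — `S_beam` construction and augmentation
- `baods.nn` / `baods.net` — network engine and the architecture/losses
- `baods.trainer` — training loop and K-fold cross-validation
- `baods.select_eval` — angle selection and plan metrics
- `baods.cli` — `baods` command-line entry point

See `docs/methods.md` for modeling assumptions, parameter choices and
limitations.
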