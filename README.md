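# tomosynth

CT-like volume synthesis from limited-angle chest tomosynthesis
projections, for medical-physics and image-reconstruction researchers who
want a self-contained, CPU-sized testbed for the slice-wise approach:
physics-based projection simulation over chest phantoms, a compact 2.5D
encoder–decoder that predicts sagittal tissue-class slices from narrow
projection strips, and the full training/evaluation machinery.

## The idea

Chest tomosynthesis sweeps the X-ray tube along a **vertical** line
(±15°, source–detector distance 180 cm) while collecting ~60 low-dose
projections.  Because the source never moves laterally, every ray through
one sagittal plane of the patient lands in a narrow vertical strip of
detector columns (31 px at a 2048-px detector).  A sagittal CT slice can
therefore be predicted from a small (views × rows × strip) patch stack
instead of the full projection set, collapsing a memory-hungry 3D
reconstruction into many small 2.5D→2D problems.

Rather than regressing Hounsfield units, voxels are classified into three
tissue classes,

- air: HU < −800,
- soft tissue: −800 ≤ HU < 300,
- bone: HU ≥ 300,

and predictions map back to CT-like images via representative values
−1000 / 0 / 500 HU.  Training pairs are aligned by construction: the
projections are simulated **from** the ground-truth volume by an exact
ray tracer (Siddon path lengths) followed by physics augmentation (beam
hardening, scatter, per-view motion, Poisson noise).  Training minimizes
generalized Dice (class weights ∝ 1/volume², countering the scarcity of
bone) plus categorical cross-entropy, with Adam at 3×10⁻⁴, batch 16.

Since no patient data ship with the package, a seeded phantom generator
provides chest-like HU volumes (body, lungs, spine, ribs, nodules) at any
grid size, with exact ground-truth labels.  See `docs/methods.md` for the
model, conventions and limitations.

## Worked example

A miniature end-to-end run from the shell (30 phantoms, 10 epochs,
~30 s; the `desk` preset is a proportionally shrunk acquisition — 16
views, 128×128 detector, width-7 strips, 48³ phantoms):

```sh
$ tomosynth simulate --preset desk --seed 1 --n-phantoms 30 --out-dir run
wrote 90 samples to run/shard.h5 (config 133724e451c6139e)
$ tomosynth train --preset desk --seed 1 --shard-dir run --out-dir run --epochs 10
model parameters: 48683 (audit 48683)
trained 10 epochs; final train loss 1.4480
$ tomosynth eval --preset desk --seed 1 --shard-dir run --out-dir run
accuracy: 0.8165690104166666
...
recall:
  air: 0.8348384030418251
  bone: 0.0
  soft: 0.8268279274326553
```

After 10 epochs on 25 training patients the model already segments air
and soft tissue at ~0.83 recall on the two held-out patients; bone (a few
percent of voxels) needs the longer run below before it emerges.
`tomosynth reconstruct` additionally writes predicted label volumes and
their CT-like (−1000/0/500 HU) NIfTI conversions; `tomosynth selftest`
runs quick geometry/physics/loss invariant checks.

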