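# propnet — fast contour propagation for MR-guided prostate radiotherapy

`propnet` implements deep-learning-based contour propagation for MR-guided
adaptive radiotherapy of the prostate.  In that workflow a clinical target
volume (CTV) contour is drawn once on a pretreatment MR scan; on every
treatment day a new fraction scan is acquired and the contour must be
transferred onto it in seconds, while the patient is on the table.  `propnet`
solves this as deformable image registration: a progressively trained 3-D
U-net maps the (pretreatment, fraction) image pair to a dense displacement
field, and the contour is propagated by warping the pretreatment CTV mask
with that field in a single pass — no iterative optimization at test time.

Because no clinical scans ship with the package, synthetic pelvic phantoms
stand in for patients: an ellipsoidal CTV analog with bladder/rectum
distractors, band-limited texture and noise, deformed by known ground-truth
transforms.  Every pipeline stage — simulation, training, propagation,
evaluation, robustness experiments — runs end-to-end on phantoms, and all
geometric claims are verified against the known transforms.  See
[docs/methods.md](docs/methods.md) for the full model description, defaults,
numerical conventions and limitations.

## The model

- **Training by synthetic supervision**: each training pair is manufactured
  on the fly by warping one volume with two random transforms — an
  *augmentation* transform applied to both images and a *learned* B-spline
  transform the network must recover as a dense field (each image
  interpolated exactly once, via the composed mapping).
- **Progressive multi-resolution training**: per-level output heads are
  blended by a schedule that linearly hands control from the coarsest to the
  finest resolution level; with the full-scale defaults the finest level
  takes over exactly at iteration 15 000.
- **Three loss variants**: `overlap` (soft Dice on the warped mask),
  `deformation` (mean squared field error), `hybrid` (their sum).
- **Evaluation**: Dice, 95th-percentile Hausdorff distance (mm), centroid
  distance (mm), folding fraction (negative Jacobian determinant), a
  no-registration baseline, patient-rotating cross-validation, and an
  axial-shift robustness experiment (−5…+5 mm displacement of the
  pretreatment cropping window).

The numerics are self-contained: the network and its training loop run on a
small hand-written reverse-mode autodiff engine over numpy (gradients
verified by finite differences), so there is no deep-learning framework
dependency.

## Worked example

Train a desk-scale model (32³ grid, 3 levels, 500 iterations — about three
minutes on one CPU) on two phantom patients and evaluate on a third:

```python
from propnet.config import RunConfig
from propnet.model import ContourPropagationModel
from propnet.phantom import generate_patient

cfg = RunConfig.resolve("desk")
patients = [
    generate_patient(cfg.phantom_spec, cfg.n_fractions, cfg.patient_rng(i), f"p{i}")
    for i in range(3)
]
model = ContourPropagationModel(
    patients=patients[:2], network=cfg.network, schedule=cfg.schedule,
    loss="hybrid", optimizer=cfg.optimizer, iterations=cfg.iterations,
    grid_spec=cfg.grid_spec,
)
res = model.fit(seed=0)
print(res.summary(patients[2:]))

sweep = res.shift_experiment(patients[2])
for s, summ in zip(sweep.shifts_mm, sweep.summaries):
    print(f"shift {s:+.0f} mm  HD95 {summ['mean']:.2f} mm")
```

Output (deterministic for this seed):

```
Contour Propagation Results
======================================================
grid                        (32, 32, 32)
resolution levels           3
base features               8
loss weights (overlap,dvf)  (1, 1)
iterations                  500
optimizer                   SGD lr=0.01 momentum=0.5
training patients           2
seed                        0
loss (first 50 mean)        0.8007
loss (last 50 mean)         0.7270
------------------------------------------------------
held-out metrics (mean +/- sd)
dice                        0.2706 +/- 0.1098  (n=5)
hd95                        19.7075 +/- 3.7362 mm  (n=5)
centroid_distance           20.4826 +/- 3.9094 mm  (n=5)
folding_fov                 0.0000 +/- 0.0000 %  (n=5)
folding_prostate            0.0000 +/- 0.0000 %  (n=5)
shift -5 mm  HD95 20.02 mm
shift -4 mm  HD95 20.02 mm
shift -3 mm  HD95 19.56 mm
shift -2 mm  HD95 19.72 mm
shift -1 mm  HD95 19.72 mm
shift +0 mm  HD95 19.71 mm
shift +1 mm  HD95 19.88 mm
shift +2 mm  HD95 20.02 mm
shift +3 mm  HD95 19.99 mm
shift +4 mm  HD95 20.34 mm
shift +5 mm  HD95 20.48 mm
```

For calibration: the no-registration baseline on the same held-out patient
is Dice 0.2714 ± 0.1094, HD95 19.71 ± 3.74 mm — at this smoke scale the
network is still within its learning induction phase and performs at
baseline level (see *A note on desk-scale learning* below).

## Command line

The `propnet` CLI drives the same pipeline from YAML configuration; every
command accepts `--profile {desk,paper}`, `--config file.yaml` and writes
its resolved configuration next to its outputs:

```bash
propnet simulate --profile desk --out cohort/           # phantom cohort (NIfTI + manifest)
propnet train    --profile desk --data cohort/ --loss hybrid --out run/
propnet propagate --model run/checkpoint.npz \
    --pre cohort/p0/pre_image.nii.gz --mask cohort/p0/pre_mask.nii.gz \
    --fraction cohort/p0/fraction0_image.nii.gz --out run/prop/
propnet evaluate --profile desk --data cohort/ --model run/checkpoint.npz --out run/eval/
propnet shift-experiment --profile desk --data cohort/ --model run/checkpoint.npz --out run/shift/
propnet crossval --profile desk --data cohort/ --out run/cv/
```

## Testing and reproducing results

Run the full suite (unit tests plus the ten-criterion acceptance suite):

```bash
python -m pytest -o addopts= -p no:cacheprovider -q tests/
```

Recompute every acceptance quantity from scratch and write them as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results.json
```

All randomness is driven by explicit seeds; training streams are derived
per-iteration from `(seed, iteration)`, so runs are bit-reproducible and
independent of checkpoint/restart boundaries.

### A note on desk-scale learning

One acceptance check — scaled-down learning at the desk profile
(32³, 500 iterations) — currently **fails**, and is reported honestly
rather than tuned around: at this scale, batch-1 SGD spends its first few
thousand iterations learning trunk features before held-out performance
moves at all.  Extending the identical desk configuration shows held-out
field RMSE first beating the zero-field predictor near iteration 5000
(0.647 vs 0.728 at iteration 6000), i.e. the implementation learns, but not
within the 500-iteration smoke budget.  The diagnosis (finite-difference
gradient checks, single-sample overfitting, closed-form readout probes) is
documented in [docs/methods.md](docs/methods.md) under *Limitations*.

## Layout

```
src/propnet/
  volume.py      # Volume3D, NIfTI I/O, contours, resampling geometry
  transforms.py  # rigid / B-spline / composite transforms, warps, Jacobians
  phantom.py     # synthetic patients and training-sample manufacture
  network.py     # U-net state, losses, progressive schedule, training loop
  nn/            # numpy autodiff engine and the U-net graph
  evaluation.py  # metrics, reports, shift experiment, cross-validation
  model.py       # ContourPropagationModel / ContourPropagationResults
  config.py      # YAML-backed run configuration, desk/paper profiles
  cli.py         # click-based command line
tests/           # unit suite + tests/test_acceptance.py
scripts/acceptance.py
docs/methods.md
```
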