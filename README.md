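# mptrans

CT-less attenuation-correction analysis for myocardial perfusion
short-axis stacks: simulate paired reference ("PET-like") and attenuated
("SPECT-like") phantom cohorts, train a cycle-consistent image-to-image
translation model that produces corrected stacks from attenuated inputs,
and quantify the correction with AHA 17-segment polar analysis,
voxel-wise similarity metrics (NRMSE / PSNR / SSIM / joint histograms)
and defect-score / ROC evaluation.

The translation core (small U-Net generators with residual output, patch
discriminators, least-squares adversarial + cycle-consistency objective)
is implemented in pure NumPy with hand-written backpropagation, verified
against finite differences in the test suite, so the package has no deep
learning framework dependency and trains desk-scale models in minutes on
one CPU.

## Layout

| module | role |
| --- | --- |
| `mptrans.stacks` | `ImageStack` data type; per-slice 8-bit PNG + sidecar I/O |
| `mptrans.phantom` | annular LV phantoms, true defects, smooth inferior-wall attenuation, paired stack generation with ground truth |
| `mptrans.preprocess` | slice-count alignment (nearest position), in-plane resample + centre crop, 8-bit conversion, 0-100 uptake scale, network resizing |
| `mptrans.nn` | NumPy conv-net primitives with explicit forward/backward |
| `mptrans.translation` | cycle-consistent model, training loop, checkpoints, stack translation |
| `mptrans.segment17` | AHA 17-segment representative values via per-degree radial maximum profiles |
| `mptrans.metrics` | NRMSE, PSNR, SSIM, joint histograms, per-segment paired tests |
| `mptrans.scoring` | 0-4 defect grading bands, SSS/SRS/SDS, coronary territories, ROC |
| `mptrans.pipeline` | end-to-end experiment from one YAML config, seeded + manifest |
| `mptrans.experiments` | seeded attenuation-recovery and null-control experiments |
| `mptrans.viz` | bullseye polar maps and joint-histogram figures (from CSV) |

## CLI

One entry point with per-stage subcommands:

```sh
mptrans simulate --out runs/sim --seed 1            # synthetic cohort
mptrans preprocess SPECT_SIDECAR PET_SIDECAR --out runs/prep
mptrans train --spect-dir runs/prep --pet-dir runs/prep \
    --profile desk --seed 1 --out runs/model.npz
mptrans translate runs/model.npz SPECT_SIDECAR --out runs/translated
mptrans segment17 SIDECAR --out seg.csv --polar-png bullseye.png
mptrans evaluate PET_SIDECAR TEST_SIDECAR --out similarity.csv
mptrans score STRESS_SEG_CSV REST_SEG_CSV --out scores.csv
mptrans all --out runs/full --seed 1                # whole experiment
```

Stacks are exchanged as one 8-bit grayscale PNG per slice plus a plain
text metadata sidecar (pixel size, slice thickness, state, modality).
The `paper` training profile preserves the full-scale reference hyperparameters
(256x256 matrix, 50 epochs, batch 8, learning rate 0.002, momentum
optimizer); the `desk` profile (64x64, narrow U-Net, Adam) trains in
minutes on one CPU and is what the tests use.

## Conventions

- Angles: 0 deg at the anterior wall, increasing toward the septum
  (counter-clockwise in a standard short-axis display); the inferior wall
  sits at 180 deg.  Segment 1 is centred on 0 deg.
- Segment values: mean of per-degree radial maximum profiles; basal/mid
  sectors collect 60 profiles per slice, apical sectors 90, apex 360.
- Grading: relative uptake normalized to the per-study maximum segment;
  bands 75-100 -> 0, 65-74 -> 1, 50-64 -> 2, 40-49 -> 3, < 40 -> 4.
- Territories: LAD {1,2,7,8,13,14,17}, RCA {3,4,9,10,15},
  LCX {5,6,11,12,16} (overridable).
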