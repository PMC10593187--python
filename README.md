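# recyclect

Spatiotemporal unpaired denoising of low-dose multi-phase cardiac CT image
sequences: a RecycleGAN (adversarial + recurrent + recycle losses over
temporally ordered cardiac phases) with a CycleGAN baseline, the full
quantitative evaluation protocol (PSNR / SSIM / ROI-STD, noise-based frame
selection, 9-fold cross-validation, learning-rate search), and a synthetic
dynamic cardiac phantom generator so that everything runs at desk scale on
one CPU with no external data.

Because the target environment has no deep-learning framework, the six
networks (two generators, two discriminators, two temporal predictors) and
their training run on a small NumPy reverse-mode autodiff core
(`recyclect.nn`), gradient-checked against finite differences.

## Layout

| Module                 | Contents |
| ---------------------- | -------- |
| `recyclect.sequence`   | `PhaseSequence` data model (looped 2D+time, 12-bit/HU scales), NIfTI + array-archive I/O, model-scale conversion, temporal windowing |
| `recyclect.losses`     | adversarial, cycle-consistency, recurrent, recycle losses; full CycleGAN/RecycleGAN objective values with per-term breakdowns |
| `recyclect.networks`   | factories for generators / patch discriminators / temporal predictors; checkpoints |
| `recyclect.training`   | CycleGAN & RecycleGAN Adam training loops, validation-based model selection, learning-rate search, 9-fold CV harness |
| `recyclect.metrics`    | MSE, PSNR (MAX=4095), SSIM (l·c·s), ROI standard deviation, consecutive-run frame selection, metric reports |
| `recyclect.phantom`    | 8-phase looped dynamic phantom with beating chamber, flat aorta disc, paired clean/full-dose/low-dose renderings, 1/√dose noise scaling, cohort generation |
| `recyclect.protocol`   | tube-current protocol dose arithmetic |
| `recyclect.nn`         | minimal NumPy autodiff (conv2d, activations, Adam) |

## CLI

```sh
recyclect generate --n-pairs 9 --size 32 --seed 17 --out data/
recyclect train --objective recyclegan --data data/ --out run/ --epochs 10 --seed 0
recyclect denoise --model run/checkpoint.npz --in data/pair01_cohort0_low.npz --out den.npz
recyclect evaluate --candidate den.npz --reference data/pair01_cohort0_clean.npz --out report.json
recyclect evaluate --candidate den.npz --roi 12,12,8,8 --out report.json   # unpaired: ROI STD
recyclect select-frames --stds stds.csv --looped
recyclect lr-search --objective cyclegan --data data/ --out lr_table.json
recyclect cv-run --folds-table folds.json
```

`train` accepts `--config cfg.yaml`, a flat key/value document mirroring
`TrainingConfig` (λ weights under a `weights:` mapping), e.g.

```yaml
learning_rate: 1.26e-3
epochs: 20
batch_size: 4
window_w: 2
weights:
  lambda_cycle: 10.0
  lambda_ry: 50.0
```

## Notes

- Loss reductions are mean-over-pixels / mean-over-time, so magnitudes are
  resolution- and length-invariant; the λ defaults are the published ones
  (λ=10, λ_rx=0.5, λ_ry=50, λ_τx=1, λ_τy=100).
- PSNR uses MAX=4095 (12-bit CT); SSIM is computed globally per frame by
  default with a sliding-window variant behind a flag; ROI STD is the
  sample (n−1) standard deviation in HU.
- The learning-rate search spans 5.00e−6 … 1.26e−3 geometrically and picks
  the rate with the highest mean validation PSNR (ties toward the smaller
  rate).
- Training is deterministic given `(dataset, config, seed)` in
  single-threaded mode; checkpoints restore bit-identical behaviour.
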