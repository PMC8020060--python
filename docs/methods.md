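# Methods

This package studies how lossy JPEG 2000 compression of CT/CBCT-like
volumes affects U-Net organ segmentation, and how a second fine-tuning
phase on compressed data restores accuracy. Everything runs at desk
scale on synthetic pelvic phantoms; the pipeline structure, losses,
metrics, and experiment protocols are the object of study, not clinical
accuracy.

## Synthetic cohort (`phantom_gen`, `volume_store`)

Each phantom is a 3D grayscale volume (8-bit, 0–255) containing a
bladder (jittered superellipsoid) and a rectum (curved tube), embedded
in soft-tissue background with a smooth intensity ramp. Per-patient
variation covers organ size, shape, and position. CBCT volumes add
stronger noise and a multiplicative shading field, so CBCT is always
the harder modality. Masks are one-hot over
{bladder, rectum, background}; background is the complement of the two
organs.

The default desk grid preserves the physical field of view of a
192×192×160 @ (1.2, 1.2, 1.5) mm clinical grid at coarser resolution.
The analysis cohort uses 96×96×16 @ (2.4, 2.4, 15) mm: the in-plane
extent is chosen so that compression at the upper end of the ratio
grid is meaningful (see "codestream floor" below).

Splits are per modality (default 80:20). Intensity normalization uses
the mean and standard deviation of the *training* volumes only, and
the same statistics are applied at test time.

## Slice-wise JPEG 2000 (`j2k_codec`)

Volumes are compressed axial slice by axial slice with HTJ2K at a
fixed target compression ratio, then decoded, clamped, and re-stored
as 8-bit. The achieved ratio is raw bytes / codestream bytes. Target
ratio 1 is a bit-exact pass-through.

**Codestream floor.** A JPEG 2000 codestream carries fixed headers
(~178 bytes here), so the achievable ratio on an X×Y slice is capped
near X·Y/178. At 64×64 that cap is ≈23:1; at 96×96 ≈52:1; at 192×192
every target in the study grid {24, 32, 48, 64, 96, 128} is
reachable. Consequently the codec's ±15% rate-targeting contract is
audited at 192×192, while the segmentation experiments run at 96×96,
where the 96:1 and 128:1 columns saturate at the floor (~51:1) and
simply repeat the strongest reachable degradation.

## Networks (`unet_models`, `nn`)

Plain NumPy U-Nets (2D and 3D) built from Conv + InstanceNorm + ReLU
blocks, 2× max-pooling, and 2× transposed-conv upsampling, with skip
connections. The study's linked pair satisfies
`base_features_2D = 4 · base_features_3D` and
`depth_3D = depth_2D + 1`. The 2D network consumes axial slices; its
slice scores are restacked into a volume and binarized volume-wise, so
both models are evaluated with volume-level metrics.

## Losses and training (`train_engine`)

- **L3D** (3D): negative organ-weighted soft Dice,
  `−softDSC(bladder) − 3·softDSC(rectum)` with ε = 1; background is
  discarded. Perfect prediction gives −4.
- **L2D** (2D): sum of per-pixel cross-entropy over the slice; a
  uniform prediction on N pixels gives N·log 3.

Adam is the optimizer throughout. Two recipe elements matter for the
3D loss and are on by default in the experiment plan:

1. **Inflation plateau.** The organ-weighted soft Dice has a stable
   early equilibrium in which the lighter-weighted organ's channel
   becomes the softmax dump for background, predicting it everywhere
   (soft DSC ≈ 2|T|/N). The escape force scales like 1/N, so the fix
   is a higher learning rate (3e-2), periodic Adam warm restarts, and
   a smaller 3D input grid. Two safety nets exist for runs where the
   plateau still forms: `TrainConfig.revive_dead_organs` re-seats the
   1×1 output-head row of a stuck organ channel on the background
   row's weights at the restart cadence, and `TrainConfig.ce_weight`
   adds an auxiliary per-voxel cross-entropy term (the usual Dice+CE
   compound), under which the plateau cannot form at all because every
   organ voxel pushes its own class logit directly. The single-phantom
   trainability check (`overfit_single_phantom`) uses the Dice+CE
   compound with a plain recipe (lr 2e-2, no restarts, no decay); the
   cohort experiments use the pure study loss with the plateau-escape
   recipe.
2. **Input rescaling.** 3D network inputs (and their masks) are
   resampled onto a 32×32×16 grid after any compression;
   compression always acts at acquisition resolution. The 2D network
   always sees native-resolution slices. Decoupled weight decay
   (3e-2) keeps logits from saturating during the longer 3D schedule.

A 3D model trained with rescaling is also *evaluated* on the resampled
grid against resampled masks — its own input/output space — which
mirrors the train-time pipeline. 2D and 3D DSC values are therefore
comparable as "fraction of the organ captured on the grid each model
operates on", and each model's DSC-vs-ratio trend is internally
consistent.

Fine-tuning (phase 2) copies the base model and continues training on
a fully compressed/decompressed training set at one ratio, with a
fresh optimizer.

## Metrics (`seg_metrics`)

- **DSC** = 2|P∩T| / (|P|+|T|); defined as 1 when both masks are
  empty.
- **SMBD**: boundary voxels are the mask voxels with at least one
  6-neighbour outside the mask; the directed mean boundary distance
  averages, over one boundary, the Euclidean distance (in mm, using
  voxel spacing) to the nearest voxel of the other boundary; SMBD is
  the mean of the two directions. Undefined (error) when either mask
  is empty; evaluation tables exclude such patients and count them in
  `n_excluded_empty`.

## Experiments (`experiments`)

All protocols evaluate per patient at volume level and aggregate
mean ± std over test patients, reported per (model, modality, organ,
ratio), and pool over seeds weighted by patient count.

1. **Robustness** — base 2D/3D models, trained on uncompressed data,
   tested at every grid ratio plus the 1:1 control.
2. **Matched fine-tuning (diagonal)** — for each ratio R, fine-tune
   the base 3D model at R, test at R.
3. **Fixed-ratio fine-tuning (flexibility)** — fine-tune once at R*,
   test across the whole grid. R* must lie inside the codec's ±15%
   rate-targeting range at the study grid (≤48 on 96×96 slices):
   beyond the codestream floor, "fine-tuning at R*" would actually
   happen at the floor ratio, where information loss is maximal and
   the flexibility property no longer holds.

`max_tolerated_ratio` reads the largest evaluated ratio whose pooled
mean DSC stays at or above the acceptability threshold (0.7 by
default); `robustness_gain` is the quotient of two tolerated ratios
(e.g. 96 vs 64 → 1.5×).

## Reproducing the analysis

```
python analysis/01_generate_cohort.py
python analysis/02_codec_characterization.py
python analysis/03_train_base_models.py
python analysis/04_experiment1_robustness.py
python analysis/05_experiments2_3_finetune.py
python analysis/06_tolerated_ratios.py
```

Outputs land under `results/` (not versioned). `scripts/acceptance.py`
recomputes the headline quantities from scratch in one process.
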