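# comproseg

Compression-robustness study for organ segmentation: how slice-wise
JPEG 2000 compression of CT/CBCT-like volumes degrades 2D and 3D U-Net
segmentation of pelvic organs (bladder, rectum), and how much accuracy
a second fine-tuning phase on compressed data recovers. Runs entirely
on synthetic phantom volumes, at desk scale, on one CPU.

## Layout

- `src/comproseg/` — the library:
  - `volume_store` — ScanVolume / MaskSet / CohortSplit, NIfTI I/O,
    normalization, resampling
  - `phantom_gen` — synthetic pelvic phantom cohorts (CT and CBCT)
  - `j2k_codec` — slice-wise JPEG 2000 round-trip at a target ratio
  - `seg_metrics` — DSC and symmetric mean boundary distance (SMBD)
  - `unet_models` — NumPy 2D/3D U-Nets and the linked config pair
  - `train_engine` — losses (L3D soft-Dice, L2D cross-entropy),
    training, fine-tuning, checkpoints
  - `experiments` — the three study protocols and the
    tolerated-ratio / robustness-gain analysis
  - `nn` — the small autodiff-free layer library underneath
- `analysis/` — numbered scripts reproducing the study end to end
  (see `docs/methods.md`); results land under `results/`
- `scripts/acceptance.py` — recomputes the headline quantities from
  scratch and writes them as JSON
- `tests/` — pytest suite, including one test per acceptance property

## Quick start

```
comproseg generate --n-ct 4 --n-cbct 4 --grid 64 64 48 \
    --spacing 3.6 3.6 5.0 --seed 0 --out work/cohort
comproseg degrade --ratio 24 --in-dir work/cohort --out-dir work/r24 \
    --manifest work/r24_qc.csv
comproseg train --data work/cohort --dims 3 --epochs 20 \
    --lr 3e-2 --restart-every 50 --weight-decay 3e-2 \
    --rescale 32 32 16 --out work/base3d.npz
comproseg finetune --ratio 24 --checkpoint work/base3d.npz \
    --data work/cohort --out work/ft24.npz
comproseg experiment --id 1 --data work/cohort --out work/exp1
```

Or from Python:

```python
from comproseg.experiments import ExperimentPlan, run_experiment1
from comproseg.phantom_gen import PhantomParams, generate_cohort
from comproseg.train_engine import Cohort

params = PhantomParams(grid_shape=(96, 96, 16), spacing=(2.4, 2.4, 15.0))
patients, split = generate_cohort(params, n_ct=6, n_cbct=6, seed=11)
result = run_experiment1(ExperimentPlan(seeds=(0,)), Cohort(patients, split))
print(result.table)
```

## Testing

```
pytest            # full suite
python scripts/acceptance.py --seed 1 --out acceptance.json
```

See `docs/methods.md` for the study design, the training recipe, and
the codec's codestream-floor caveat that fixes the problem sizes.
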