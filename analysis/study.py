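"""Shared configuration for the numbered analysis scripts.

One place defines the desk-scale study: the phantom cohort, the
compression-ratio grid, the experiment plan, and where results land.
Every numbered script imports from here so the whole analysis is
reproducible end to end from `python analysis/01_generate_cohort.py`
onward.

Scale note: the in-plane grid must be large enough that the JPEG 2000
codestream overhead does not cap the achievable ratio below the top of
the ratio grid. At 96x96 the highest reachable ratio is ~52:1, so the
96:1 and 128:1 columns saturate there (the codec clamps to its floor);
the codec itself is audited separately at 192x192 where every target in
the grid is reachable (see 02_codec_characterization.py).
"""

from __future__ import annotations

from pathlib import Path

from comproseg.experiments import ExperimentPlan
from comproseg.phantom_gen import PhantomParams

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
COHORT_DIR = RESULTS / "cohort"
MODELS_DIR = RESULTS / "models"

# Cohort: 3x coarser in plane and 10x coarser in z than the clinical
# 192x192x160 @ (1.2, 1.2, 1.5) mm grid, same physical field of view.
COHORT_SEED = 11
N_CT = 6
N_CBCT = 6
PHANTOM = PhantomParams(grid_shape=(96, 96, 16), spacing=(2.4, 2.4, 15.0),
                        seed=COHORT_SEED)

# Codec characterization grid: full in-plane resolution so every target
# ratio is reachable.
CODEC_PHANTOM = PhantomParams(grid_shape=(192, 192, 32),
                              spacing=(1.2, 1.2, 7.5), seed=COHORT_SEED)

PLAN = ExperimentPlan(seeds=(0, 1, 2), finetune_ratios=(48, 64))


def model_path(seed: int, tag: str) -> Path:
    return MODELS_DIR / f"base_{tag.lower()}_seed{seed}.npz"


def load_cohort():
    from comproseg.phantom_gen import Patient
    from comproseg.train_engine import Cohort
    from comproseg.volume_store import CohortSplit, read_volume

    split = CohortSplit.from_json(COHORT_DIR / "split.json")
    patients = []
    for p in sorted(COHORT_DIR.glob("*.nii")):
        if "_mask" in p.name:
            continue
        vol, masks = read_volume(p)
        patients.append(Patient(vol, masks))
    if not patients:
        raise FileNotFoundError(
            f"no cohort in {COHORT_DIR}; run 01_generate_cohort.py first")
    return Cohort(patients, split)


def load_base_models():
    from comproseg.train_engine import load_checkpoint

    models = {}
    for seed in PLAN.seeds:
        models[seed] = {}
        for tag in ("2D", "3D"):
            path = model_path(seed, tag)
            if not path.exists():
                raise FileNotFoundError(
                    f"{path} missing; run 03_train_base_models.py first")
            models[seed][tag], _ = load_checkpoint(path)
    return models
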