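"""Base-phase training of the linked 2D/3D model pair, one pair per seed.

Training uses uncompressed volumes only (phase 1 of the two-phase
protocol). Checkpoints land under results/models/ and are reused by the
experiment scripts.
"""

import time

from comproseg.experiments import train_config_3d, train_base_models
from comproseg.train_engine import TrainConfig, save_checkpoint

import study


def main() -> None:
    cohort = study.load_cohort()
    plan = study.PLAN
    study.MODELS_DIR.mkdir(parents=True, exist_ok=True)
    for seed in plan.seeds:
        t0 = time.time()
        models = train_base_models(plan, cohort, seed)
        cfg3 = train_config_3d(plan, seed, plan.epochs_3d)
        cfg2 = TrainConfig(epochs=plan.epochs_2d, batch_size=plan.batch_size,
                           learning_rate=plan.learning_rate, seed=seed)
        save_checkpoint(study.model_path(seed, "3D"), models["3D"], cfg3, [])
        save_checkpoint(study.model_path(seed, "2D"), models["2D"], cfg2, [])
        print(f"seed {seed}: trained 2D+3D pair in {time.time() - t0:.0f}s")


if __name__ == "__main__":
    main()
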