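"""Experiment 1: robustness of the base 2D and 3D models to compression.

Each base model (trained on uncompressed volumes) is evaluated on the
test set degraded at every ratio in the grid, plus the 1:1 control.
Writes results/experiment1_results.csv and a per-ratio summary.
"""

import json

from comproseg.experiments import run_experiment1

import study


def main() -> None:
    cohort = study.load_cohort()
    models = study.load_base_models()
    result = run_experiment1(study.PLAN, cohort, base_models=models)
    study.RESULTS.mkdir(parents=True, exist_ok=True)
    result.to_csv(study.RESULTS / "experiment1_results.csv")
    (study.RESULTS / "experiment1_manifest.json").write_text(
        json.dumps(result.manifest, indent=1, default=str))

    summary = (result.table
               .groupby(["model_tag", "modality", "organ", "test_ratio"])
               ["mean_dsc"].mean().unstack("test_ratio"))
    print("mean DSC over seeds, by test ratio:")
    print(summary.to_string(float_format=lambda v: f"{v:.3f}"))


if __name__ == "__main__":
    main()
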