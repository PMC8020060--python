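"""Experiments 2 and 3: fine-tuning on compressed training data.

Experiment 2 (diagonal): for each ratio R, fine-tune the base 3D model
on training volumes degraded at R and test at R.
Experiment 3 (flexibility): fine-tune once at each fixed R* in the plan,
then test across the whole ratio grid.

Writes results/experiment2_results.csv and results/experiment3_results.csv.
"""

import json

from comproseg.experiments import run_experiment2, run_experiment3

import study


def main() -> None:
    cohort = study.load_cohort()
    models = study.load_base_models()
    study.RESULTS.mkdir(parents=True, exist_ok=True)
    for exp_id, runner in ((2, run_experiment2), (3, run_experiment3)):
        result = runner(study.PLAN, cohort, base_models=models)
        result.to_csv(study.RESULTS / f"experiment{exp_id}_results.csv")
        (study.RESULTS / f"experiment{exp_id}_manifest.json").write_text(
            json.dumps(result.manifest, indent=1, default=str))
        summary = (result.table
                   .groupby(["model_tag", "test_ratio"])["mean_dsc"]
                   .mean().unstack("test_ratio"))
        print(f"experiment {exp_id}: mean DSC over seeds/modalities/organs:")
        print(summary.to_string(float_format=lambda v: f"{v:.3f}"))
        print()


if __name__ == "__main__":
    main()
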