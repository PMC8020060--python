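"""Tolerated-ratio and robustness-gain analysis of experiment 1.

For each model/modality/organ cell, read off the largest grid ratio
whose seed-pooled mean DSC stays at or above the acceptability
threshold, then form 3D-over-2D gains. Writes
results/tolerated_ratios.csv.
"""

import pandas as pd

from comproseg.experiments import (ExperimentResult, UndefinedGainError,
                                   max_tolerated_ratio, robustness_gain)

import study


def main() -> None:
    table = pd.read_csv(study.RESULTS / "experiment1_results.csv")
    result = ExperimentResult(table, study.PLAN.manifest())
    rows = []
    for modality in study.PLAN.modalities:
        for organ in ("bladder", "rectum"):
            tol = {tag: max_tolerated_ratio(result, tag, modality, organ)
                   for tag in ("2D", "3D")}
            try:
                gain = robustness_gain(result, "3D", "2D", modality, organ)
            except UndefinedGainError:
                gain = float("nan")
            rows.append({"modality": modality, "organ": organ,
                         "tolerated_2d": tol["2D"], "tolerated_3d": tol["3D"],
                         "gain_3d_over_2d": gain})
    out = pd.DataFrame(rows)
    out.to_csv(study.RESULTS / "tolerated_ratios.csv", index=False)
    print(f"threshold: mean DSC >= {study.PLAN.dsc_threshold}")
    print(out.to_string(index=False))


if __name__ == "__main__":
    main()
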