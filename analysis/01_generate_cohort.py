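"""Generate the synthetic pelvic phantom cohort used by all experiments.

Writes NIfTI volumes + one-hot masks, the train/test split (with the
training-set normalization statistics), and a cohort manifest under
results/cohort/.
"""

import json

from comproseg.phantom_gen import generate_cohort
from comproseg.volume_store import write_volume

import study


def main() -> None:
    patients, split = generate_cohort(study.PHANTOM, study.N_CT, study.N_CBCT)
    study.COHORT_DIR.mkdir(parents=True, exist_ok=True)
    for pat in patients:
        write_volume(study.COHORT_DIR / f"{pat.patient_id}.nii",
                     pat.volume, pat.masks)
    split.to_json(study.COHORT_DIR / "split.json")
    (study.COHORT_DIR / "cohort.json").write_text(json.dumps({
        "n_ct": study.N_CT, "n_cbct": study.N_CBCT,
        "grid": list(study.PHANTOM.grid_shape),
        "spacing": list(study.PHANTOM.spacing),
        "seed": study.COHORT_SEED,
    }, indent=1))
    print(f"wrote {len(patients)} patients to {study.COHORT_DIR}")
    print(f"train: {split.train_ids}")
    print(f"test:  {split.test_ids}")


if __name__ == "__main__":
    main()
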