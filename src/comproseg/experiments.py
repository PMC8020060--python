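"""Experiment drivers and the tolerated-ratio analysis.

Three protocols, all evaluated per patient at volume level with DSC and
SMBD and aggregated as mean±std over patients:

1. Robustness of base models: train 2D and 3D networks on uncompressed
   volumes, test on the test set degraded at every ratio (plus the 1:1
   uncompressed control column).
2. Matched fine-tuning: for each ratio R, fine-tune the base 3D model on
   training volumes degraded at R and test at R (diagonal protocol).
3. Fixed-ratio fine-tuning: fine-tune once at a specific ratio R*, then
   test across the whole ratio grid (flexibility protocol).

`max_tolerated_ratio` reads the largest grid ratio whose mean DSC stays at
or above an acceptability threshold (0.7 by default); `robustness_gain` is
the ratio of two tolerated ratios — the statistic behind "1.5x / 2x more
robust" comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .j2k_codec import CompressionSpec, roundtrip_volume
from .phantom_gen import Patient
from .seg_metrics import UndefinedDistanceError, argmax_masks, dsc, smbd
from .train_engine import Cohort, TrainConfig, finetune, train
from .unet_models import UNet, build_unet, linked_pair, softmax_probabilities
from .volume_store import (CohortSplit, ScanVolume, normalize_volume,
                           rescale_for_3d)

ORGANS = ("bladder", "rectum")

RESULT_COLUMNS = [
    "model_tag", "modality", "organ", "test_ratio", "seed",
    "mean_dsc", "std_dsc", "mean_smbd_mm", "std_smbd_mm",
    "n_patients", "n_excluded_empty", "achieved_ratio",
]


class QueryError(KeyError):
    pass


class UndefinedGainError(ValueError):
    pass


@dataclass
class ExperimentPlan:
    experiment: int = 1
    ratios: tuple = (24, 32, 48, 64, 96, 128)
    finetune_ratios: tuple = (48, 64, 96)
    modalities: tuple = ("CT", "CBCT")
    dsc_threshold: float = 0.7
    seeds: tuple = (0,)
    # training scale (desk defaults; clinical-scale values are a config away)
    base_features_3d: int = 4
    depth_3d: int = 2
    epochs_3d: int = 60
    epochs_2d: int = 15
    epochs_finetune: int = 15
    learning_rate: float = 1e-2  # 2D (cross-entropy) training
    batch_size: int = 8
    # 3D recipe: the organ-weighted soft-Dice loss needs a higher learning
    # rate plus periodic Adam restarts to escape its inflation plateau, and
    # the 3D network consumes volumes resampled onto a smaller grid (the
    # 2D network always sees native-resolution slices).
    learning_rate_3d: float = 3e-2
    weight_decay_3d: float = 3e-2
    adam_restart_every_3d: int | None = 50
    rescale_3d: tuple | None = (32, 32, 16)

    def __post_init__(self):
        if list(self.ratios) != sorted(set(self.ratios)):
            raise ValueError("ratios must be strictly increasing")
        if not 0 < self.dsc_threshold < 1:
            raise ValueError("dsc_threshold must be in (0, 1)")

    def manifest(self) -> dict:
        return asdict(self)


@dataclass
class ExperimentResult:
    table: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    def rows(self, **query) -> pd.DataFrame:
        t = self.table
        for k, v in query.items():
            t = t[t[k] == v]
        return t

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# prediction helpers


def predict_masks_3d(model: UNet, volume: ScanVolume, split: CohortSplit) -> np.ndarray:
    x = normalize_volume(volume, split)
    probs = softmax_probabilities(model.predict(x))
    return argmax_masks(probs)


def predict_masks_2d(model: UNet, volume: ScanVolume, split: CohortSplit) -> np.ndarray:
    """Predict every axial slice, concatenate, then binarize volume-wise."""
    xn = normalize_volume(volume, split)
    batch = np.moveaxis(xn, 2, 0)[:, None].astype(np.float32)  # (nz, 1, x, y)
    scores = model.forward(batch)  # (nz, 3, x, y)
    vol_scores = np.moveaxis(scores, 0, -1)  # (3, x, y, nz)
    probs = softmax_probabilities(vol_scores)
    return argmax_masks(probs)


def _predict(model: UNet, volume: ScanVolume, split: CohortSplit) -> np.ndarray:
    if model.cfg.dims == 3:
        return predict_masks_3d(model, volume, split)
    return predict_masks_2d(model, volume, split)


# ---------------------------------------------------------------------------
# evaluation


def evaluate_model(
    model_tag: str,
    model: UNet,
    cohort: Cohort,
    ratios: tuple,
    modalities: tuple = ("CT", "CBCT"),
    seed: int = 0,
    rescale_3d: tuple | None = None,
) -> pd.DataFrame:
    """Evaluate on the test set degraded at each ratio (1 = uncompressed).

    Returns one row per (modality, organ, ratio) with per-patient mean±std
    DSC and SMBD; patients whose predicted organ is empty are excluded from
    the SMBD mean and counted in n_excluded_empty. Compression always acts
    on the native-resolution volume; a 3D model with `rescale_3d` set is
    then scored on the resampled grid against resampled masks (its own
    input/output grid), mirroring the train-time pipeline.
    """
    rows = []
    test = [p for p in cohort.test_patients if p.volume.modality.value in modalities]
    all_ratios = tuple(r for r in ratios if r != 1)
    for ratio in (1,) + all_ratios:
        per_patient = []  # (modality, organ, dsc, smbd or nan)
        achieved = {}
        for pat in test:
            if ratio == 1:
                vol, ach = pat.volume, 1.0
            else:
                vol, ach = roundtrip_volume(pat.volume, CompressionSpec(ratio))
            achieved.setdefault(pat.volume.modality.value, []).append(ach)
            if model.cfg.dims == 3 and rescale_3d is not None:
                vol, masks = rescale_for_3d(vol, rescale_3d, pat.masks)
            else:
                masks = pat.masks
            pred = _predict(model, vol, cohort.split)
            for i, organ in enumerate(ORGANS):
                d = dsc(pred[i], masks.class_mask(i)).value
                try:
                    s = smbd(pred[i], masks.class_mask(i), vol.spacing)
                except UndefinedDistanceError:
                    s = np.nan
                per_patient.append((pat.volume.modality.value, organ, d, s))
        df = pd.DataFrame(per_patient, columns=["modality", "organ", "dsc", "smbd"])
        for (modality, organ), g in df.groupby(["modality", "organ"]):
            smbd_ok = g["smbd"].dropna()
            rows.append({
                "model_tag": model_tag, "modality": modality, "organ": organ,
                "test_ratio": ratio, "seed": seed,
                "mean_dsc": g["dsc"].mean(), "std_dsc": g["dsc"].std(ddof=0),
                "mean_smbd_mm": smbd_ok.mean() if len(smbd_ok) else np.nan,
                "std_smbd_mm": smbd_ok.std(ddof=0) if len(smbd_ok) else np.nan,
                "n_patients": len(g),
                "n_excluded_empty": int(g["smbd"].isna().sum()),
                "achieved_ratio": float(np.mean(achieved[modality])),
            })
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


# ---------------------------------------------------------------------------
# experiment drivers


def train_base_models(plan: ExperimentPlan, cohort: Cohort, seed: int,
                      want_2d: bool = True) -> dict[str, UNet]:
    """Base-phase training of the linked 2D/3D pair on uncompressed data."""
    cfg2, cfg3 = linked_pair(plan.base_features_3d, plan.depth_3d)
    out: dict[str, UNet] = {}
    model3 = build_unet(cfg3, seed=seed)
    train(model3, cohort, train_config_3d(plan, seed, plan.epochs_3d))
    out["3D"] = model3
    if want_2d:
        model2 = build_unet(cfg2, seed=seed)
        train(model2, cohort, TrainConfig(epochs=plan.epochs_2d, batch_size=plan.batch_size,
                                          learning_rate=plan.learning_rate, seed=seed))
        out["2D"] = model2
    return out


def train_config_3d(plan: ExperimentPlan, seed: int, epochs: int) -> TrainConfig:
    return TrainConfig(epochs=epochs, batch_size=plan.batch_size,
                       learning_rate=plan.learning_rate_3d, seed=seed,
                       weight_decay=plan.weight_decay_3d,
                       rescale_3d=plan.rescale_3d,
                       adam_restart_every=plan.adam_restart_every_3d,
                       revive_dead_organs=True)


def run_experiment1(plan: ExperimentPlan, cohort: Cohort,
                    base_models: dict[int, dict[str, UNet]] | None = None) -> ExperimentResult:
    """2D vs 3D robustness: base models tested across the ratio grid."""
    tables = []
    for seed in plan.seeds:
        models = (base_models or {}).get(seed) or train_base_models(plan, cohort, seed)
        for tag in ("2D", "3D"):
            tables.append(evaluate_model(tag, models[tag], cohort, plan.ratios,
                                         plan.modalities, seed,
                                         rescale_3d=plan.rescale_3d))
    return ExperimentResult(pd.concat(tables, ignore_index=True),
                            {"experiment": 1, **plan.manifest()})


def run_experiment2(plan: ExperimentPlan, cohort: Cohort,
                    base_models: dict[int, dict[str, UNet]] | None = None) -> ExperimentResult:
    """Diagonal fine-tuning: for each ratio R, fine-tune at R and test at R."""
    tables = []
    for seed in plan.seeds:
        models = (base_models or {}).get(seed) or train_base_models(plan, cohort, seed,
                                                                    want_2d=False)
        base3 = models["3D"]
        tables.append(evaluate_model("3D", base3, cohort, plan.ratios,
                                     plan.modalities, seed,
                                     rescale_3d=plan.rescale_3d))
        for ratio in plan.ratios:
            ft, _ = finetune(base3, cohort, ratio,
                             train_config_3d(plan, seed, plan.epochs_finetune))
            t = evaluate_model("3D-FT", ft, cohort, (ratio,), plan.modalities, seed,
                               rescale_3d=plan.rescale_3d)
            # diagonal protocol: keep only the matched test ratio (and the 1:1 control)
            tables.append(t[t.test_ratio == ratio])
    return ExperimentResult(pd.concat(tables, ignore_index=True),
                            {"experiment": 2, **plan.manifest()})


def run_experiment3(plan: ExperimentPlan, cohort: Cohort,
                    base_models: dict[int, dict[str, UNet]] | None = None) -> ExperimentResult:
    """Fixed-ratio fine-tuning: fine-tune at each R*, test across the grid."""
    tables = []
    for seed in plan.seeds:
        models = (base_models or {}).get(seed) or train_base_models(plan, cohort, seed,
                                                                    want_2d=False)
        base3 = models["3D"]
        for rstar in plan.finetune_ratios:
            ft, _ = finetune(base3, cohort, rstar,
                             train_config_3d(plan, seed, plan.epochs_finetune))
            tables.append(evaluate_model(f"3D-FT{rstar}", ft, cohort, plan.ratios,
                                         plan.modalities, seed,
                                         rescale_3d=plan.rescale_3d))
    return ExperimentResult(pd.concat(tables, ignore_index=True),
                            {"experiment": 3, **plan.manifest()})


# ---------------------------------------------------------------------------
# tolerated-ratio analysis


def _mean_dsc_by_ratio(result: ExperimentResult, model_tag: str, modality: str,
                       organ: str) -> pd.Series:
    rows = result.rows(model_tag=model_tag, modality=modality, organ=organ)
    if rows.empty:
        raise QueryError(f"no rows for {model_tag}/{modality}/{organ}")
    # pool patients over seeds, weighting by patient count
    def pooled(g):
        return np.average(g["mean_dsc"], weights=g["n_patients"])
    return rows.groupby("test_ratio").apply(pooled, include_groups=False).sort_index()


def max_tolerated_ratio(result: ExperimentResult, model_tag: str, modality: str,
                        organ: str, threshold: float | None = None) -> float | None:
    """Largest evaluated ratio whose mean DSC >= threshold; None if no
    evaluated ratio (including the 1:1 control) qualifies."""
    threshold = result.manifest.get("dsc_threshold", 0.7) if threshold is None else threshold
    means = _mean_dsc_by_ratio(result, model_tag, modality, organ)
    ok = means[means >= threshold]
    return float(ok.index.max()) if len(ok) else None


def robustness_gain(result: ExperimentResult, tag_a: str, tag_b: str, modality: str,
                    organ: str, threshold: float | None = None,
                    result_b: ExperimentResult | None = None) -> float:
    """tolerated(tag_a) / tolerated(tag_b): how much harder tag_a's inputs
    can be compressed for the same acceptability threshold."""
    ra = max_tolerated_ratio(result, tag_a, modality, organ, threshold)
    rb = max_tolerated_ratio(result_b or result, tag_b, modality, organ, threshold)
    if ra is None or rb is None:
        raise UndefinedGainError(
            f"tolerated ratio undefined ({tag_a}: {ra}, {tag_b}: {rb})")
    return ra / rb
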