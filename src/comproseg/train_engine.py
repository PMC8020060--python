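"""Losses and the training / fine-tuning protocol.

The 3D network trains on whole volumes with a soft-Dice loss over the two
organs, the rectum weighted 3x and the background discarded:

    L3D = −softDSC(bladder) − 3·softDSC(rectum)

where softDSC uses voxel-sum Dice on the predicted class probabilities with
an additive smoothing term eps in numerator and denominator (differentiable,
and stable when an organ is absent). The 2D network trains on axial slices
with plain cross-entropy, L2D = −Σ_i Σ_xy t·log p, because organ-free slices
make a per-batch Dice ill-behaved.

Fine-tuning is a second training phase on the training volumes degraded by
a slice-wise JPEG 2000 round-trip at one target ratio (a purely compressed
phase-2 set); the base weights are left untouched and the fine-tuned model
is returned (and optionally checkpointed) separately.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .j2k_codec import CompressionSpec, roundtrip_volume
from .nn import Adam, softmax, softmax_backward
from .phantom_gen import Patient
from .seg_metrics import soft_dsc
from .unet_models import UNet
from .volume_store import (CohortSplit, MaskSet, ScanVolume,
                           compute_norm_stats, normalize_volume,
                           rescale_for_3d)

SOFT_DICE_EPS = 1.0
LOG_CLAMP = 1e-7


class TrainingDivergedError(RuntimeError):
    pass


@dataclass
class Cohort:
    patients: list[Patient]
    split: CohortSplit

    def _by_ids(self, ids):
        by = {p.patient_id: p for p in self.patients}
        return [by[i] for i in ids]

    @property
    def train_patients(self) -> list[Patient]:
        return self._by_ids(self.split.train_ids)

    @property
    def test_patients(self) -> list[Patient]:
        return self._by_ids(self.split.test_ids)


@dataclass
class TrainConfig:
    epochs: int = 20
    batch_size: int = 8  # slices per step (2D only; 3D trains on whole volumes)
    learning_rate: float = 1e-3
    seed: int = 0
    phase: str = "base"  # "base" | "finetune"
    finetune_ratio: float | None = None
    organ_slice_prob: float = 0.8  # 2D sampling: P(pick a slice containing an organ)
    # 3D input grid: volumes (and masks) are resampled onto this grid before
    # 3D training, after any compression round-trip — compression always acts
    # at acquisition resolution. None trains on the native grid. Ignored by
    # 2D models, which consume native-resolution slices.
    rescale_3d: tuple | None = None
    # Decoupled (AdamW-style) weight decay; with the soft-Dice loss it keeps
    # logits bounded so the softmax cannot saturate into the inflation
    # plateau (see adam_restart_every below).
    weight_decay: float = 0.0
    # Optimizer warm restarts: reset Adam's moment estimates every N steps.
    # The organ-weighted soft-Dice loss has a slow "inflation" plateau where
    # the lighter-weighted class absorbs probability mass expelled from the
    # heavier one; stale Adam moments prolong it, and periodic state resets
    # escape it reliably. None disables restarts.
    adam_restart_every: int | None = None
    # Dead-unit resuscitation (3D only), checked at the restart cadence: an
    # organ channel stuck at the plateau's dump level (soft DSC below
    # REVIVE_SOFT_DSC) gets its output-head row re-seated on the background
    # channel's weights plus a small seeded perturbation, so it re-enters
    # the softmax competition instead of staying the dump channel.
    revive_dead_organs: bool = False
    # Weight of an auxiliary per-voxel cross-entropy term added to the 3D
    # soft-Dice loss (the usual Dice+CE compound). Cross-entropy has no dump
    # equilibrium — every organ voxel pushes its own class logit up — so even
    # a modest CE term prevents the inflation plateau from forming at all.
    ce_weight: float = 0.0

    def __post_init__(self):
        if self.phase not in ("base", "finetune"):
            raise ValueError("phase must be 'base' or 'finetune'")
        if self.phase == "finetune" and (self.finetune_ratio is None or self.finetune_ratio < 1):
            raise ValueError("finetune phase requires finetune_ratio >= 1")
        if self.adam_restart_every is not None and self.adam_restart_every < 1:
            raise ValueError("adam_restart_every must be >= 1 when set")


# ---------------------------------------------------------------------------
# losses


def loss_l3d(probs: np.ndarray, target: MaskSet | np.ndarray,
             eps: float = SOFT_DICE_EPS) -> float:
    """Soft-Dice loss for the 3D network; in [−4, 0] up to eps effects."""
    t = target.one_hot() if isinstance(target, MaskSet) else np.asarray(target, dtype=np.float64)
    p = np.asarray(probs, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    return -soft_dsc(p[0], t[0], eps) - 3.0 * soft_dsc(p[1], t[1], eps)


def loss_l3d_grad(probs: np.ndarray, target: MaskSet | np.ndarray,
                  eps: float = SOFT_DICE_EPS) -> tuple[float, np.ndarray]:
    """(loss, dloss/dprobs); gradient of the background channel is zero."""
    t = target.one_hot() if isinstance(target, MaskSet) else np.asarray(target, dtype=np.float64)
    p = np.asarray(probs, dtype=np.float64)
    grad = np.zeros_like(p)
    loss = 0.0
    for i, w in ((0, 1.0), (1, 3.0)):
        num = 2.0 * (p[i] * t[i]).sum() + eps
        den = p[i].sum() + t[i].sum() + eps
        loss -= w * num / den
        grad[i] = -w * (2.0 * t[i] * den - num) / den**2
    return loss, grad


def loss_l2d(probs: np.ndarray, target_onehot: np.ndarray,
             clamp: float = LOG_CLAMP) -> float:
    """Cross-entropy over classes and pixels; >= 0, 0 iff prediction is the
    exact one-hot target. Accepts (3, ...) or batched (N, 3, ...) maps with
    a matching target."""
    p = np.clip(np.asarray(probs, dtype=np.float64), clamp, 1.0)
    t = np.asarray(target_onehot, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    return float(-(t * np.log(p)).sum())


def loss_l2d_grad(probs: np.ndarray, target_onehot: np.ndarray,
                  clamp: float = LOG_CLAMP) -> tuple[float, np.ndarray]:
    p = np.clip(np.asarray(probs, dtype=np.float64), clamp, 1.0)
    t = np.asarray(target_onehot, dtype=np.float64)
    return loss_l2d(probs, target_onehot, clamp), -t / p


# ---------------------------------------------------------------------------
# training


def rescale_patient(pat: Patient, shape: tuple) -> Patient:
    vol, masks = rescale_for_3d(pat.volume, shape, pat.masks)
    return Patient(vol, masks)


def _degraded_training_set(cohort: Cohort, ratio: float) -> list[Patient]:
    if ratio == 1:
        return cohort.train_patients
    spec = CompressionSpec(target_ratio=ratio)
    out = []
    for pat in cohort.train_patients:
        vol, _ = roundtrip_volume(pat.volume, spec)
        out.append(Patient(vol, pat.masks))
    return out


def _check_finite(loss: float, epoch: int, pid: str):
    if not np.isfinite(loss):
        raise TrainingDivergedError(
            f"non-finite loss {loss} at epoch {epoch}, patient {pid}")


def _make_opt(model: UNet, cfg: TrainConfig) -> Adam:
    return Adam(model.params(), lr=cfg.learning_rate,
                weight_decay=cfg.weight_decay)


def _maybe_restart(opt: Adam, model: UNet, cfg: TrainConfig, step: int) -> Adam:
    if cfg.adam_restart_every and step and step % cfg.adam_restart_every == 0:
        return _make_opt(model, cfg)
    return opt


# An organ channel parked at the plateau's dump level has soft DSC around
# 2|T|/N (a few percent); a channel that competes at all clears this fast.
REVIVE_SOFT_DSC = 0.05


def _halfway(total_steps: int, cadence: int) -> int:
    """The restart-aligned step closest to (at or below) half the budget."""
    return max(1, total_steps // 2 // cadence) * cadence


def _revive_dead_organs(model: UNet, probs: np.ndarray, masks: MaskSet,
                        rng: np.random.Generator) -> bool:
    """Swap the output-head row of a dead organ channel with the background
    row (+ small noise). The organ channel inherits the dump mass and starts
    over-segmented; shrinking an over-segmentation is the easy direction for
    the Dice gradient, whereas growing a channel from nothing is exactly the
    plateau. Returns True if anything was revived."""
    revived = False
    t = masks.one_hot()
    w, b = model.head.w.value, model.head.b.value
    for i in (0, 1):
        if soft_dsc(probs[i], t[i], eps=SOFT_DICE_EPS) < REVIVE_SOFT_DSC:
            w[[i, 2]] = w[[2, i]]
            b[[i, 2]] = b[[2, i]]
            w[i] += rng.normal(0.0, 0.01, size=w[i].shape)
            revived = True
    return revived


def _train_3d(model: UNet, patients: list[Patient], split: CohortSplit,
              cfg: TrainConfig, rng: np.random.Generator) -> list[float]:
    opt = _make_opt(model, cfg)
    history = []
    step = 0
    total_steps = cfg.epochs * len(patients)
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(patients))
        ep_loss = 0.0
        for k in order:
            opt = _maybe_restart(opt, model, cfg, step)
            step += 1
            pat = patients[k]
            x = normalize_volume(pat.volume, split).astype(np.float32)[None, None]
            scores = model.forward(x)
            probs = softmax(scores, axis=1)[0]
            loss, dprobs = loss_l3d_grad(probs, pat.masks)
            if cfg.ce_weight:
                nvox = probs[0].size
                ce, dce = loss_l2d_grad(probs, pat.masks.one_hot())
                loss += cfg.ce_weight * ce / nvox
                dprobs += cfg.ce_weight * dce / nvox
            _check_finite(loss, epoch, pat.patient_id)
            dscores = softmax_backward(probs[None], dprobs[None], axis=1)
            opt.zero_grad()
            model.backward(dscores.astype(np.float32))
            opt.step()
            ep_loss += loss
            # one-shot check at the halfway restart: early plateaus often
            # resolve on their own (escape is abrupt), so intervening sooner
            # or repeatedly can reset a trajectory that was about to escape,
            # while halfway still leaves half the budget to retrain the
            # re-seated channel
            if (cfg.revive_dead_organs and cfg.adam_restart_every
                    and step == _halfway(total_steps, cfg.adam_restart_every)
                    and _revive_dead_organs(model, probs, pat.masks, rng)):
                opt = _make_opt(model, cfg)
        history.append(ep_loss / len(patients))
    return history


def _sample_slices(masks: MaskSet, batch: int, organ_prob: float,
                   rng: np.random.Generator) -> np.ndarray:
    organ = np.where((masks.bladder | masks.rectum).any(axis=(0, 1)))[0]
    nz = masks.shape[2]
    picks = []
    for _ in range(batch):
        if organ.size and rng.random() < organ_prob:
            picks.append(int(rng.choice(organ)))
        else:
            picks.append(int(rng.integers(0, nz)))
    return np.asarray(picks)


def _train_2d(model: UNet, patients: list[Patient], split: CohortSplit,
              cfg: TrainConfig, rng: np.random.Generator) -> list[float]:
    opt = _make_opt(model, cfg)
    history = []
    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(patients))
        ep_loss = 0.0
        n_px = 0
        for k in order:
            opt = _maybe_restart(opt, model, cfg, step)
            step += 1
            pat = patients[k]
            ks = _sample_slices(pat.masks, cfg.batch_size, cfg.organ_slice_prob, rng)
            xn = normalize_volume(pat.volume, split)
            x = np.stack([xn[:, :, j] for j in ks]).astype(np.float32)[:, None]
            t = np.stack([pat.masks.one_hot()[:, :, :, j] for j in ks])
            scores = model.forward(x)
            probs = softmax(scores, axis=1)
            loss, dprobs = loss_l2d_grad(probs, t)
            _check_finite(loss, epoch, pat.patient_id)
            dscores = softmax_backward(probs, dprobs, axis=1) / len(ks)
            opt.zero_grad()
            model.backward(dscores.astype(np.float32))
            opt.step()
            ep_loss += loss
            n_px += t[:, 0].size
        history.append(ep_loss / n_px)  # mean cross-entropy per pixel
    return history


def train(model: UNet, cohort: Cohort, cfg: TrainConfig,
          checkpoint: str | Path | None = None) -> list[float]:
    """Train a model in place on the cohort's training volumes; returns the
    per-epoch loss history. The phase-2 (finetune) configuration trains on a
    purely compressed training set at cfg.finetune_ratio."""
    rng = np.random.default_rng(cfg.seed)
    patients = cohort.train_patients
    if cfg.phase == "finetune":
        patients = _degraded_training_set(cohort, cfg.finetune_ratio)
    if model.cfg.dims == 3 and cfg.rescale_3d is not None:
        patients = [rescale_patient(p, cfg.rescale_3d) for p in patients]
    if model.cfg.dims == 3:
        history = _train_3d(model, patients, cohort.split, cfg, rng)
    else:
        history = _train_2d(model, patients, cohort.split, cfg, rng)
    if checkpoint is not None:
        save_checkpoint(checkpoint, model, cfg, history)
    return history


def finetune(model: UNet, cohort: Cohort, ratio: float, cfg: TrainConfig,
             checkpoint: str | Path | None = None) -> tuple[UNet, list[float]]:
    """Second training phase on compressed/decompressed training volumes.

    The given (base-trained) model is not modified; a fine-tuned copy is
    returned. The optimizer restarts (state is not carried over from the
    base phase)."""
    if ratio < 1:
        raise ValueError("finetune ratio must be >= 1")
    ft = UNet(model.cfg, seed=0)
    ft.set_weights(model.get_weights())
    ft_cfg = TrainConfig(
        epochs=cfg.epochs, batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate, seed=cfg.seed,
        phase="finetune", finetune_ratio=ratio,
        organ_slice_prob=cfg.organ_slice_prob,
        weight_decay=cfg.weight_decay,
        rescale_3d=cfg.rescale_3d,
        adam_restart_every=cfg.adam_restart_every,
        revive_dead_organs=cfg.revive_dead_organs,
    )
    history = train(ft, cohort, ft_cfg, checkpoint=checkpoint)
    return ft, history


def overfit_single_phantom(model: UNet, patient: Patient, steps: int = 200,
                           learning_rate: float = 2e-2,
                           ce_weight: float = 1.0) -> list[float]:
    """Trainability sanity check: fit one phantom for a fixed number of
    optimizer steps with the compound soft-Dice + cross-entropy loss (the CE
    term rules out the soft-Dice inflation plateau, see TrainConfig.ce_weight).
    Normalization statistics come from the single volume itself. Returns the
    per-step loss history."""
    mean, std = compute_norm_stats([patient.volume])
    split = CohortSplit([patient.patient_id], [], mean, std)
    cfg = TrainConfig(epochs=steps, learning_rate=learning_rate, seed=0,
                      ce_weight=ce_weight)
    return train(model, Cohort([patient], split), cfg)


# ---------------------------------------------------------------------------
# checkpoints: npz weights + embedded JSON manifest


def save_checkpoint(path: str | Path, model: UNet, cfg: TrainConfig,
                    history: list[float]) -> None:
    manifest = json.dumps({
        "dims": model.cfg.dims, "depth": model.cfg.depth,
        "base_features": model.cfg.base_features,
        "in_channels": model.cfg.in_channels, "out_classes": model.cfg.out_classes,
        "epochs": cfg.epochs, "batch_size": cfg.batch_size,
        "learning_rate": cfg.learning_rate, "seed": cfg.seed,
        "phase": cfg.phase, "finetune_ratio": cfg.finetune_ratio,
        "rescale_3d": list(cfg.rescale_3d) if cfg.rescale_3d else None,
        "loss_history": list(map(float, history)),
    })
    weights = {f"w{i}": w for i, w in enumerate(model.get_weights())}
    np.savez(str(path), manifest=manifest, **weights)


def load_checkpoint(path: str | Path) -> tuple[UNet, dict]:
    from .unet_models import UNetConfig

    with np.load(str(path), allow_pickle=False) as z:
        manifest = json.loads(str(z["manifest"]))
        n = sum(1 for k in z.files if k.startswith("w"))
        weights = [z[f"w{i}"] for i in range(n)]
    cfg = UNetConfig(dims=manifest["dims"], depth=manifest["depth"],
                     base_features=manifest["base_features"],
                     in_channels=manifest["in_channels"],
                     out_classes=manifest["out_classes"])
    model = UNet(cfg, seed=0)
    model.set_weights(weights)
    return model, manifest
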