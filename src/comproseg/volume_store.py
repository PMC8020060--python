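"""Volumes, organ masks, cohort splits and normalization.

The data model mirrors a resampled radiotherapy cohort: each patient is a
3D grayscale scan on a regular grid (8-bit intensities, default
192x192x160 voxels at 1.2x1.2x1.5 mm) plus a one-hot mask set over the
classes (bladder, rectum, background). Background is always derived as the
complement of the two organs so the one-hot invariant cannot be broken by
construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

DEFAULT_GRID = (192, 192, 160)
DEFAULT_SPACING = (1.2, 1.2, 1.5)

CLASS_NAMES = ("bladder", "rectum", "background")
BLADDER, RECTUM, BACKGROUND = 0, 1, 2


class Modality(str, Enum):
    CT = "CT"
    CBCT = "CBCT"
    SYNTH = "SYNTH"


class InvalidCohortError(ValueError):
    pass


class DegenerateStatisticsError(ValueError):
    pass


class InvalidShapeError(ValueError):
    pass


class VolumeFormatError(IOError):
    pass


@dataclass
class ScanVolume:
    """One patient's 3D grayscale image.

    voxels: uint8 array, axes ordered (x, y, z); the third axis is the
    axial (slice) axis. spacing is mm per voxel along (x, y, z).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    modality: Modality = Modality.SYNTH
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise InvalidShapeError(f"expected 3D voxel grid, got ndim={self.voxels.ndim}")
        if self.voxels.min() < 0 or self.voxels.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        self.voxels = self.voxels.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        self.modality = Modality(self.modality)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class MaskSet:
    """One-hot organ masks aligned to a ScanVolume.

    Only bladder and rectum are stored; background is derived, which makes
    the per-voxel one-hot property structural.
    """

    bladder: np.ndarray
    rectum: np.ndarray
    class_names: tuple[str, str, str] = CLASS_NAMES

    def __post_init__(self) -> None:
        self.bladder = np.asarray(self.bladder).astype(bool)
        self.rectum = np.asarray(self.rectum).astype(bool)
        if self.bladder.shape != self.rectum.shape:
            raise InvalidShapeError("bladder and rectum masks must share a shape")
        if (self.bladder & self.rectum).any():
            raise ValueError("organ masks overlap; one-hot violated")

    @property
    def background(self) -> np.ndarray:
        return ~(self.bladder | self.rectum)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.bladder.shape

    def class_mask(self, i: int) -> np.ndarray:
        return (self.bladder, self.rectum, self.background)[i]

    def one_hot(self) -> np.ndarray:
        """Stack to a (3, x, y, z) float array in class order."""
        return np.stack([self.bladder, self.rectum, self.background]).astype(np.float64)

    def labels(self) -> np.ndarray:
        """Integer label map: 0 bladder, 1 rectum, 2 background."""
        lab = np.full(self.shape, BACKGROUND, dtype=np.int8)
        lab[self.bladder] = BLADDER
        lab[self.rectum] = RECTUM
        return lab

    @staticmethod
    def from_labels(lab: np.ndarray) -> "MaskSet":
        return MaskSet(bladder=lab == BLADDER, rectum=lab == RECTUM)


@dataclass
class CohortSplit:
    train_ids: list[str]
    test_ids: list[str]
    norm_mean: float = 0.0
    norm_std: float = 1.0

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise InvalidCohortError("train and test sets overlap")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "train_ids": list(self.train_ids),
            "test_ids": list(self.test_ids),
            "norm_mean": self.norm_mean,
            "norm_std": self.norm_std,
        }, indent=1))

    @staticmethod
    def from_json(path: str | Path) -> "CohortSplit":
        d = json.loads(Path(path).read_text())
        return CohortSplit(d["train_ids"], d["test_ids"], d["norm_mean"], d["norm_std"])


def split_cohort(ids: list[str], train_fraction: float, seed: int) -> CohortSplit:
    """Deterministic train/test partition of patient ids.

    |train| = round(train_fraction * |ids|), the 80:20 convention of
    radiotherapy segmentation cohorts. Normalization statistics are left at
    their identity defaults; compute them from training volumes with
    `compute_norm_stats`.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if len(ids) < 2:
        raise InvalidCohortError("need at least 2 patients to split")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(ids)))
    n_train = int(round(train_fraction * len(ids)))
    n_train = min(max(n_train, 1), len(ids) - 1)  # both sides non-empty
    ids = list(ids)
    train = sorted(ids[k] for k in order[:n_train])
    test = sorted(ids[k] for k in order[n_train:])
    return CohortSplit(train_ids=train, test_ids=test)


def compute_norm_stats(volumes: list[ScanVolume]) -> tuple[float, float]:
    """Pooled mean/std of intensity over the given (training) volumes."""
    stack = np.concatenate([v.voxels.ravel() for v in volumes]).astype(np.float64)
    mean, std = float(stack.mean()), float(stack.std())
    if std == 0:
        raise DegenerateStatisticsError("training intensities are constant (std 0)")
    return mean, std


def normalize_volume(v: ScanVolume, split: CohortSplit) -> np.ndarray:
    """(voxels - mean)/std with statistics from the training set."""
    if split.norm_std == 0:
        raise DegenerateStatisticsError("norm_std is 0")
    return (v.voxels.astype(np.float64) - split.norm_mean) / split.norm_std


def denormalize(x: np.ndarray, split: CohortSplit) -> np.ndarray:
    return x * split.norm_std + split.norm_mean


def rescale_for_3d(
    v: ScanVolume,
    target_shape: tuple[int, int, int],
    masks: MaskSet | None = None,
) -> tuple[ScanVolume, MaskSet | None]:
    """Resample a volume (and optionally its masks) onto a new grid.

    Intensities use trilinear interpolation; masks use nearest neighbour so
    the one-hot property is preserved. Spacing is rescaled so the physical
    field of view is unchanged (e.g. 192x192x160 -> 160x160x128 for the 3D
    network's input grid).
    """
    target_shape = tuple(int(t) for t in target_shape)
    if any(t <= 0 for t in target_shape):
        raise InvalidShapeError(f"non-positive target shape {target_shape}")
    if target_shape == v.shape:
        return (
            ScanVolume(v.voxels.copy(), v.spacing, v.modality, v.patient_id),
            MaskSet(masks.bladder.copy(), masks.rectum.copy()) if masks else None,
        )
    zoom = [t / s for t, s in zip(target_shape, v.shape)]
    vox = ndimage.zoom(v.voxels.astype(np.float64), zoom, order=1)
    vox = np.clip(np.rint(vox), 0, 255).astype(np.uint8)
    # zoom can be off by one voxel on awkward factors; enforce the contract
    vox = _crop_or_pad(vox, target_shape)
    spacing = tuple(sp * sh / t for sp, sh, t in zip(v.spacing, v.shape, target_shape))
    out_masks = None
    if masks is not None:
        lab = ndimage.zoom(masks.labels(), zoom, order=0)
        lab = _crop_or_pad(lab, target_shape, fill=BACKGROUND)
        out_masks = MaskSet.from_labels(lab)
    return ScanVolume(vox, spacing, v.modality, v.patient_id), out_masks


def _crop_or_pad(a: np.ndarray, shape: tuple[int, ...], fill: int = 0) -> np.ndarray:
    if a.shape == shape:
        return a
    out = np.full(shape, fill, dtype=a.dtype)
    src = tuple(slice(0, min(s, t)) for s, t in zip(a.shape, shape))
    out[src] = a[src]
    return out


def extract_axial_slices(v: ScanVolume | np.ndarray) -> list[np.ndarray]:
    """Ordered axial (z-axis) slices; stacking them back reproduces the volume."""
    vox = v.voxels if isinstance(v, ScanVolume) else np.asarray(v)
    return [vox[:, :, k] for k in range(vox.shape[2])]


def stack_axial_slices(slices: list[np.ndarray]) -> np.ndarray:
    return np.stack(slices, axis=2)


def write_volume(path: str | Path, v: ScanVolume, m: MaskSet | None = None) -> None:
    """Write a volume (and masks) as NIfTI with a JSON sidecar.

    `<stem>.nii` holds intensities, `<stem>_mask.nii` the integer label map,
    `<stem>.json` the modality and patient id. Spacing travels in the NIfTI
    header (pixdim via the affine).
    """
    path = Path(path)
    affine = np.diag(list(v.spacing) + [1.0])
    nib.save(nib.Nifti1Image(v.voxels.astype(np.uint8), affine), str(path))
    stem = path.name[: -len("".join(path.suffixes))] if path.suffixes else path.stem
    side = path.parent / f"{stem}.json"
    side.write_text(json.dumps({"modality": v.modality.value, "patient_id": v.patient_id}))
    if m is not None:
        nib.save(
            nib.Nifti1Image(m.labels().astype(np.uint8), affine),
            str(path.parent / f"{stem}_mask{''.join(path.suffixes)}"),
        )


def read_volume(path: str | Path) -> tuple[ScanVolume, MaskSet | None]:
    path = Path(path)
    try:
        img = nib.load(str(path))
        vox = np.asarray(img.dataobj).astype(np.uint8)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    except Exception as e:  # nibabel raises several unrelated types
        raise VolumeFormatError(f"cannot read NIfTI volume {path.name}: {e}") from e
    stem = path.name[: -len("".join(path.suffixes))] if path.suffixes else path.stem
    side = path.parent / f"{stem}.json"
    modality, pid = Modality.SYNTH, stem
    if side.exists():
        meta = json.loads(side.read_text())
        modality, pid = Modality(meta["modality"]), meta["patient_id"]
    v = ScanVolume(vox, spacing, modality, pid)
    mask_path = path.parent / f"{stem}_mask{''.join(path.suffixes)}"
    m = None
    if mask_path.exists():
        try:
            lab = np.asarray(nib.load(str(mask_path)).dataobj).astype(np.int8)
        except Exception as e:
            raise VolumeFormatError(f"cannot read mask volume {mask_path.name}: {e}") from e
        m = MaskSet.from_labels(lab)
    return v, m
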