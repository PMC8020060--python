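"""Segmentation evaluation metrics: Dice overlap and boundary distances.

DSC = 2|P∩T| / (|P|+|T|). The symmetric mean boundary distance (SMBD)
averages the two directed mean boundary distances D(P_b, T_b) and
D(T_b, P_b), where d(p, T_b) = min_t ||s ⊙ (p − t)||_2 with s the physical
voxel spacing in mm — so the metric is anisotropy-aware and reported in mm.

Boundary voxels are mask voxels with at least one 6-connected neighbour
outside the mask, with the volume edge counting as outside. The directed
distance is computed with an exact Euclidean distance transform (sampled at
the voxel spacing) of the opposing boundary; a brute-force all-pairs oracle
lives in the test suite as its independent twin.

Predictions of 2D networks are evaluated volume-wise: per-slice class maps
are stacked back into a volume and the 3D DSC is computed per class — never
an average of per-slice DSCs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_store import MaskSet

DEFAULT_SPACING_MM = (1.2, 1.2, 1.5)


class UndefinedDistanceError(ValueError):
    """Raised when a boundary distance is requested against an empty mask."""

    def __init__(self, side: str):
        super().__init__(f"boundary distance undefined: {side} mask is empty")
        self.side = side


@dataclass(frozen=True)
class DSCResult:
    value: float
    both_empty: bool = False  # flagged defined-empty case DSC(∅,∅)=1

    def __float__(self):
        return self.value


def dsc(P: np.ndarray, T: np.ndarray) -> DSCResult:
    """Dice similarity coefficient of two binary masks (any rank)."""
    P = np.asarray(P).astype(bool)
    T = np.asarray(T).astype(bool)
    if P.shape != T.shape:
        raise ValueError(f"shape mismatch {P.shape} vs {T.shape}")
    denom = int(P.sum()) + int(T.sum())
    if denom == 0:
        return DSCResult(1.0, both_empty=True)
    inter = int((P & T).sum())
    return DSCResult(2.0 * inter / denom)


def soft_dsc(p: np.ndarray, t: np.ndarray, eps: float = 0.0) -> float:
    """Voxel-sum Dice on real-valued prediction maps:
    (2·Σ p·t + eps) / (Σ p + Σ t + eps). With binary inputs and eps=0 this
    equals `dsc` exactly."""
    p = np.asarray(p, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    return float((2.0 * (p * t).sum() + eps) / (p.sum() + t.sum() + eps))


def boundary_voxels(M: np.ndarray) -> np.ndarray:
    """Boolean map of the 6-connected inner border of a binary mask.

    A voxel belongs to the border iff it is in the mask and has a
    face-adjacent neighbour outside the mask or lies on the volume edge.
    Empty mask -> empty border.
    """
    M = np.asarray(M).astype(bool)
    if not M.any():
        return np.zeros_like(M)
    structure = ndimage.generate_binary_structure(M.ndim, 1)
    interior = ndimage.binary_erosion(M, structure=structure, border_value=0)
    return M & ~interior


def boundary_coords(M: np.ndarray) -> np.ndarray:
    """(n, rank) integer coordinates of the boundary voxels."""
    return np.argwhere(boundary_voxels(M))


def directed_mbd(
    A: np.ndarray, B: np.ndarray, spacing=DEFAULT_SPACING_MM
) -> float:
    """Mean over boundary voxels of A of the distance to the nearest
    boundary voxel of B, in mm. A and B are boolean boundary maps
    (see `boundary_voxels`)."""
    A = np.asarray(A).astype(bool)
    B = np.asarray(B).astype(bool)
    if not A.any():
        raise UndefinedDistanceError("first")
    if not B.any():
        raise UndefinedDistanceError("second")
    s = np.asarray(spacing, dtype=np.float64)
    if (s <= 0).any():
        raise ValueError("spacing must be strictly positive")
    dist_to_B = ndimage.distance_transform_edt(~B, sampling=s)
    return float(dist_to_B[A].mean())


def smbd(P: np.ndarray, T: np.ndarray, spacing=DEFAULT_SPACING_MM) -> float:
    """Symmetric mean boundary distance between two binary masks, mm."""
    P = np.asarray(P).astype(bool)
    T = np.asarray(T).astype(bool)
    if P.shape != T.shape:
        raise ValueError(f"shape mismatch {P.shape} vs {T.shape}")
    if not P.any():
        raise UndefinedDistanceError("predicted")
    if not T.any():
        raise UndefinedDistanceError("target")
    Pb, Tb = boundary_voxels(P), boundary_voxels(T)
    return 0.5 * (directed_mbd(Pb, Tb, spacing) + directed_mbd(Tb, Pb, spacing))


def argmax_masks(scores_or_probs: np.ndarray) -> np.ndarray:
    """Per-class binary masks from a (3, *spatial) score/probability map.

    Ties break toward the lower class index (bladder < rectum < background).
    Returns a boolean array of the same shape.
    """
    a = np.asarray(scores_or_probs)
    winner = a.argmax(axis=0)  # numpy argmax takes the first maximum: low index wins ties
    out = np.zeros(a.shape, dtype=bool)
    for i in range(a.shape[0]):
        out[i] = winner == i
    return out


def volume_dsc_from_slice_predictions(
    slice_preds: list[np.ndarray], T: MaskSet
) -> dict[str, DSCResult]:
    """Volume-level per-class DSC of a 2D network's per-slice predictions.

    slice_preds: ordered per-slice class maps, each (3, x, y) scores or
    probabilities, one per axial slice. They are stacked into a volume and
    a single 3D DSC per class is computed.
    """
    if len(slice_preds) != T.shape[2]:
        raise ValueError(f"got {len(slice_preds)} slices for a {T.shape} volume")
    for k, sp in enumerate(slice_preds):
        if sp.shape != (3,) + T.shape[:2]:
            raise ValueError(f"slice {k} has shape {sp.shape}, expected {(3,) + T.shape[:2]}")
    vol_scores = np.stack(slice_preds, axis=3)  # (3, x, y, z)
    pred = argmax_masks(vol_scores)
    return {
        name: dsc(pred[i], T.class_mask(i))
        for i, name in enumerate(T.class_names)
    }


def volume_masks_from_scores(scores: np.ndarray) -> np.ndarray:
    """Arg-max binarization of a (3, *spatial) score map (alias used by the
    experiment drivers for 3D predictions)."""
    return argmax_masks(scores)
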