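"""Slice-wise JPEG 2000 round-trip degradation at a fixed target ratio.

Volumes are degraded the way a PACS-style archive would store them: each
axial slice is encoded independently as an 8-bit grayscale JPEG 2000
codestream with a rate target (e.g. 64 means 64:1 against the raw
width*height byte count), then decoded. Ratio 1 is an exact pass-through,
giving a clean uncompressed control arm. Encoding uses Pillow's OpenJPEG
binding with the irreversible (lossy) wavelet path; achieved codestream
sizes are returned so callers can audit the rate actually delivered.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from PIL import Image

from .volume_store import MaskSet, ScanVolume


class InvalidSpecError(ValueError):
    pass


@dataclass(frozen=True)
class CompressionSpec:
    """target_ratio is dimensionless (64 -> 64:1); ratio 1 means lossless
    pass-through. wavelet_levels counts DWT decompositions."""

    target_ratio: float
    wavelet_levels: int = 5
    irreversible: bool = True

    def __post_init__(self) -> None:
        if self.target_ratio < 1:
            raise InvalidSpecError(f"target_ratio must be >= 1, got {self.target_ratio}")


def roundtrip_slice(sl: np.ndarray, spec: CompressionSpec) -> tuple[np.ndarray, int]:
    """Encode+decode one 2D slice; returns (degraded slice, codestream bytes)."""
    sl = np.asarray(sl)
    if sl.ndim != 2:
        raise ValueError("expected a 2D slice")
    if sl.min() < 0 or sl.max() > 255:
        raise ValueError("slice values must lie in [0, 255]")
    sl8 = sl.astype(np.uint8)
    raw_bytes = sl8.size  # 8-bit grayscale
    if spec.target_ratio == 1:
        return sl8.copy(), raw_bytes

    # OpenJPEG needs every resolution level to be at least one sample wide
    max_levels = max(int(np.floor(np.log2(min(sl8.shape)))), 0)
    levels = min(spec.wavelet_levels, max_levels)
    buf = io.BytesIO()
    Image.fromarray(sl8, mode="L").save(
        buf,
        format="JPEG2000",
        no_jp2=True,  # raw codestream, no container overhead
        irreversible=spec.irreversible,
        quality_mode="rates",
        quality_layers=[float(spec.target_ratio)],
        num_resolutions=levels + 1,
    )
    n = buf.tell()
    buf.seek(0)
    out = np.asarray(Image.open(buf), dtype=np.uint8)
    if out.shape != sl8.shape:
        raise RuntimeError("codec returned a slice of the wrong shape")
    return out, n


def roundtrip_volume(v: ScanVolume, spec: CompressionSpec) -> tuple[ScanVolume, float]:
    """Degrade every axial slice independently.

    achieved_ratio = sum(raw slice bytes) / sum(codestream bytes); spacing,
    modality and patient id are preserved.
    """
    raw_total = 0
    coded_total = 0
    out = np.empty_like(v.voxels)
    for k in range(v.shape[2]):
        deg, n = roundtrip_slice(v.voxels[:, :, k], spec)
        out[:, :, k] = deg
        raw_total += v.voxels[:, :, k].size
        coded_total += n
    achieved = raw_total / coded_total
    return ScanVolume(out, v.spacing, v.modality, v.patient_id), achieved


def psnr(a: np.ndarray, b: np.ndarray, peak: float = 255.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical inputs."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    mse = np.mean((a - b) ** 2)
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(peak**2 / mse))
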