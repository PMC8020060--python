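"""Synthetic pelvic phantom generator.

Emulates the statistical structure of a resampled male-pelvis CT/CBCT
cohort: a bright-ish bladder (superellipsoid), a darker curved rectal tube
behind/below it, inter-patient variation of organ size, shape and position,
a smooth anterior-posterior background gradient, Gaussian acquisition noise
(larger for CBCT) and, for CBCT only, a multiplicative low-frequency
shading field standing in for cupping/scatter artifacts.

Masks are exact: they are derived from the noiseless geometry, mimicking a
specialist contouring the true organ.

The default grid is a desk-scale 64x64x48 with spacing chosen to keep the
organ-to-field-of-view proportions of the clinical 192x192x160 grid at
1.2x1.2x1.5 mm; clinical-size generation is a parameter away.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volume_store import (
    CohortSplit,
    MaskSet,
    Modality,
    ScanVolume,
    compute_norm_stats,
    InvalidCohortError,
    split_cohort,
)


class GenerationError(RuntimeError):
    pass


# Desk-scale grid: 3x coarser in-plane, 10/3x coarser in z than the clinical
# 192x192x160 @ (1.2, 1.2, 1.5) mm, preserving the physical field of view.
DESK_GRID = (64, 64, 48)
DESK_SPACING = (3.6, 3.6, 5.0)


@dataclass
class PhantomParams:
    grid_shape: tuple[int, int, int] = DESK_GRID
    spacing: tuple[float, float, float] = DESK_SPACING
    # organ geometry, all in mm
    bladder_semiaxes_mean: tuple[float, float, float] = (32.0, 28.0, 30.0)
    bladder_semiaxes_std: float = 4.0
    rectum_radius_mean: float = 15.0
    rectum_radius_std: float = 1.5
    rectum_curvature_std: float = 8.0  # mm deflection of the centerline
    bladder_shape_jitter: float = 0.5  # spread of the superellipsoid exponent around 2.5
    organ_center_jitter: float = 8.0
    # intensities, display units 0-255; pelvic soft-tissue contrast is low
    intensity_means: tuple[float, float, float] = (115.0, 75.0, 95.0)
    background_gradient: float = 10.0  # peak-to-mid amplitude of the smooth ramp
    noise_std_ct: float = 6.0
    noise_std_cbct: float = 14.0
    cbct_shading_amplitude: float = 30.0  # multiplicative field amplitude, /255
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_std_cbct < self.noise_std_ct:
            raise ValueError("CBCT noise must be >= CT noise")
        if not all(0 <= m <= 255 for m in self.intensity_means):
            raise ValueError("intensity means must lie in [0, 255]")


@dataclass
class Patient:
    volume: ScanVolume
    masks: MaskSet

    @property
    def patient_id(self) -> str:
        return self.volume.patient_id


def _physical_axes(params: PhantomParams):
    """Voxel-center coordinates in mm along each axis."""
    return [
        (np.arange(n) + 0.5) * s
        for n, s in zip(params.grid_shape, params.spacing)
    ]


def _bladder_mask(params: PhantomParams, rng: np.random.Generator) -> np.ndarray:
    ax, ay, az = _physical_axes(params)
    fov = [a[-1] + 0.5 * s for a, s in zip((ax, ay, az), params.spacing)]
    center = np.array([0.50, 0.40, 0.55]) * fov
    center += rng.uniform(-params.organ_center_jitter, params.organ_center_jitter, 3)
    semi = np.array(params.bladder_semiaxes_mean) + rng.normal(0, params.bladder_semiaxes_std, 3)
    semi = np.clip(semi, 8.0, None)
    # superellipsoid exponent: sphere-to-boxy shape variation
    p = rng.uniform(2.5 - params.bladder_shape_jitter, 2.5 + params.bladder_shape_jitter)
    u = (np.abs(ax - center[0]) / semi[0]) ** p
    v = (np.abs(ay - center[1]) / semi[1]) ** p
    w = (np.abs(az - center[2]) / semi[2]) ** p
    return (u[:, None, None] + v[None, :, None] + w[None, None, :]) <= 1.0


def _rectum_mask(params: PhantomParams, rng: np.random.Generator) -> np.ndarray:
    ax, ay, az = _physical_axes(params)
    fov = [a[-1] + 0.5 * s for a, s in zip((ax, ay, az), params.spacing)]
    # tube swept along z over the central ~70% of the grid, posterior to the bladder
    z0, z1 = 0.15 * fov[2], 0.85 * fov[2]
    base = np.array([0.50, 0.72]) * fov[:2]
    base[:2] += rng.uniform(-params.organ_center_jitter, params.organ_center_jitter, 2)
    # quadratic centerline deflections in x and y
    cx = rng.normal(0, params.rectum_curvature_std, 2)
    cy = rng.normal(0, params.rectum_curvature_std, 2)
    radius = max(rng.normal(params.rectum_radius_mean, params.rectum_radius_std), 4.0)
    t = np.clip((az - z0) / (z1 - z0), 0.0, 1.0) * 2.0 - 1.0  # [-1, 1] along the tube
    line_x = base[0] + cx[0] * t + cx[1] * (t**2 - 0.5)
    line_y = base[1] + cy[0] * t + cy[1] * (t**2 - 0.5)
    dx = ax[:, None, None] - line_x[None, None, :]
    dy = ay[None, :, None] - line_y[None, None, :]
    inside_xy = dx**2 + dy**2 <= radius**2
    inside_z = (az >= z0) & (az <= z1)
    return inside_xy & inside_z[None, None, :]


def _smooth_field(shape: tuple[int, int, int], rng: np.random.Generator) -> np.ndarray:
    """Low-frequency random field normalized to max |.| = 1."""
    coarse = rng.normal(size=(4, 4, 3))
    zoom = [s / c for s, c in zip(shape, coarse.shape)]
    f = ndimage.zoom(coarse, zoom, order=3)
    f = f[: shape[0], : shape[1], : shape[2]]
    m = np.abs(f).max()
    return f / m if m > 0 else f


def _touches_boundary(mask: np.ndarray) -> bool:
    return bool(
        mask[0].any() or mask[-1].any()
        or mask[:, 0].any() or mask[:, -1].any()
        or mask[:, :, 0].any() or mask[:, :, -1].any()
    )


def generate_patient(
    params: PhantomParams, modality: Modality | str, patient_seed: int
) -> tuple[ScanVolume, MaskSet]:
    """One phantom. Geometry depends only on (params.seed, patient_seed);
    noise additionally on the modality, so a CT/CBCT pair with the same
    seeds shares its anatomy exactly."""
    modality = Modality(modality)
    geom_rng = np.random.default_rng([params.seed, patient_seed, 101])
    noise_rng = np.random.default_rng(
        [params.seed, patient_seed, 202, 1 if modality == Modality.CBCT else 0]
    )

    bladder = _bladder_mask(params, geom_rng)
    rectum = _rectum_mask(params, geom_rng) & ~bladder
    if not bladder.any() or not rectum.any():
        raise GenerationError("an organ mask came out empty; geometry does not fit the grid")
    if _touches_boundary(bladder) or _touches_boundary(rectum):
        raise GenerationError("organ touches the grid boundary; shrink organs or jitter")

    mb, mr, mbg = params.intensity_means
    vol = np.full(params.grid_shape, mbg, dtype=np.float64)
    vol[bladder] = mb
    vol[rectum] = mr
    # smooth anterior-posterior gradient over the whole field of view
    ny = params.grid_shape[1]
    ramp = np.linspace(-1.0, 1.0, ny) * params.background_gradient
    vol = vol + ramp[None, :, None]

    if modality == Modality.CBCT and params.cbct_shading_amplitude > 0:
        shade = _smooth_field(params.grid_shape, noise_rng)
        vol = vol * (1.0 + (params.cbct_shading_amplitude / 255.0) * shade)

    noise_std = params.noise_std_cbct if modality == Modality.CBCT else params.noise_std_ct
    if noise_std > 0:
        vol = vol + noise_rng.normal(0.0, noise_std, size=params.grid_shape)

    vox = np.clip(np.rint(vol), 0, 255).astype(np.uint8)
    pid = f"{modality.value}-{patient_seed:03d}"
    return ScanVolume(vox, params.spacing, modality, pid), MaskSet(bladder, rectum)


def generate_cohort(
    params: PhantomParams,
    n_ct: int,
    n_cbct: int,
    train_fraction: float = 0.8,
    seed: int | None = None,
) -> tuple[list[Patient], CohortSplit]:
    """A reproducible cohort with a per-modality train/test split and
    normalization statistics computed on training volumes only."""
    if n_ct + n_cbct < 2:
        raise InvalidCohortError("need at least 2 patients")
    if seed is not None:
        params = replace(params, seed=seed)
    patients: list[Patient] = []
    for k in range(n_ct):
        v, m = generate_patient(params, Modality.CT, k)
        patients.append(Patient(v, m))
    for k in range(n_cbct):
        v, m = generate_patient(params, Modality.CBCT, n_ct + k)
        patients.append(Patient(v, m))

    train_ids: list[str] = []
    test_ids: list[str] = []
    for mod, n in ((Modality.CT, n_ct), (Modality.CBCT, n_cbct)):
        ids = [p.patient_id for p in patients if p.volume.modality == mod]
        if not ids:
            continue
        if len(ids) == 1:  # a singleton modality goes to training
            train_ids += ids
            continue
        sub = split_cohort(ids, train_fraction, seed=params.seed + (0 if mod == Modality.CT else 1))
        train_ids += sub.train_ids
        test_ids += sub.test_ids

    by_id = {p.patient_id: p for p in patients}
    mean, std = compute_norm_stats([by_id[i].volume for i in train_ids])
    split = CohortSplit(sorted(train_ids), sorted(test_ids), mean, std)
    return patients, split
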