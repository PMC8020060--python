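import numpy as np
import pytest

from comproseg.phantom_gen import PhantomParams, generate_patient


@pytest.fixture(scope="session")
def small_params() -> PhantomParams:
    """Desk-scale phantom parameters used across unit tests (32x32x24 grid,
    spacing scaled to preserve the clinical field of view)."""
    return PhantomParams(grid_shape=(32, 32, 24), spacing=(7.2, 7.2, 10.0), seed=11)


@pytest.fixture(scope="session")
def small_phantom(small_params):
    return generate_patient(small_params, "CT", 0)


def brute_force_directed_mbd(A_coords, B_coords, spacing):
    """All-pairs oracle for the directed mean boundary distance."""
    s = np.asarray(spacing, dtype=float)
    total = 0.0
    for a in A_coords:
        d2 = (((B_coords - a) * s) ** 2).sum(axis=1)
        total += np.sqrt(d2.min())
    return total / len(A_coords)


def brute_force_boundary(M):
    """Enumerative oracle for the 6-connected inner border with the volume
    edge counting as outside."""
    M = np.asarray(M).astype(bool)
    out = np.zeros_like(M)
    for idx in np.argwhere(M):
        for ax in range(M.ndim):
            for d in (-1, 1):
                j = list(idx)
                j[ax] += d
                if j[ax] < 0 or j[ax] >= M.shape[ax] or not M[tuple(j)]:
                    out[tuple(idx)] = True
    return out
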