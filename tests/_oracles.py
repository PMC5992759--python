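"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's fast paths: energy loss is stepped
explicitly at 1 nm on the raw LET table, and geometric path lengths are
measured by dense point sampling along the ray.
"""

import numpy as np
from numba import njit

from alphamicro.physics import WATER_TABLE

_LOG_E = np.log(WATER_TABLE.energies)
_LOG_S = np.log(WATER_TABLE.let_values)
E_MIN = float(WATER_TABLE.energies[0])


@njit(cache=True)
def _let(e, log_e, log_s, e_min):
    if e < e_min:
        e = e_min
    return np.exp(np.interp(np.log(e), log_e, log_s))


@njit(cache=True)
def _step_residual(e0, thickness_um, step_um, log_e, log_s, e_min):
    """Explicit fixed-step energy-loss integration; returns (E_out, path)
    where path is the distance actually travelled (< thickness if stopped)."""
    e = e0
    s = 0.0
    while s < thickness_um:
        if e <= e_min:
            return 0.0, s
        de = _let(e, log_e, log_s, e_min) * step_um
        if de >= e:
            return 0.0, s
        e -= de
        s += step_um
    return e, s


def stepper_residual(e0: float, thickness_um: float, step_um: float = 1e-3) -> float:
    """Residual energy after a water path, 1-nm explicit stepping."""
    e, _ = _step_residual(e0, thickness_um, step_um, _LOG_E, _LOG_S, E_MIN)
    return float(e)


def stepper_range(e0: float, step_um: float = 1e-3) -> float:
    """CSDA range by explicit stepping until the cutoff energy."""
    _, s = _step_residual(e0, 1e9, step_um, _LOG_E, _LOG_S, E_MIN)
    return float(s)


def sampled_label_lengths(vol, origin, direction, length_um, step_um=1e-3):
    """Per-label path lengths by dense point sampling along a ray."""
    n = int(length_um / step_um)
    t = (np.arange(n) + 0.5) * step_um
    pos = np.asarray(origin, float)[None, :] + t[:, None] * np.asarray(direction, float)[None, :]
    local = pos - vol.origin
    h = vol.voxel_um
    idx = np.floor(local / h).astype(np.int64)
    nx, ny, nz = vol.shape_xyz
    inside = (
        (idx[:, 0] >= 0) & (idx[:, 0] < nx)
        & (idx[:, 1] >= 0) & (idx[:, 1] < ny)
        & (idx[:, 2] >= 0) & (idx[:, 2] < nz)
    )
    lab = np.zeros(n, dtype=np.int64)
    ii = idx[inside]
    lab[inside] = vol.labels[ii[:, 2], ii[:, 1], ii[:, 0]]
    out = {}
    for value in (0, 182, 201):
        out[value] = float(np.count_nonzero(inside & (lab == value)) * step_um)
    return out


def sampled_sphere_chord(origin, direction, center, radius, length_um, step_um=1e-3):
    """Chord length through one sphere by dense point sampling."""
    n = int(length_um / step_um)
    t = (np.arange(n) + 0.5) * step_um
    pos = np.asarray(origin, float)[None, :] + t[:, None] * np.asarray(direction, float)[None, :]
    d2 = np.sum((pos - np.asarray(center, float)[None, :]) ** 2, axis=1)
    return float(np.count_nonzero(d2 <= radius * radius) * step_um)
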