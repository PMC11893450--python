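import numpy as np
import pytest

from protobeam.acoustic import (MediumProperties, PressureTraces, PulseShape,
                                TransducerResponse, matrix_array)
from protobeam.volume import GridSpec, Volume


@pytest.fixture(scope="session")
def water():
    return MediumProperties.water()


@pytest.fixture(scope="session")
def small_array():
    """4x4 matrix array for fast forward/inverse tests."""
    return matrix_array(rows=4, cols=4)


@pytest.fixture(scope="session")
def full_array():
    return matrix_array()


@pytest.fixture(scope="session")
def xdcr():
    return TransducerResponse(1.0, 60.0)


@pytest.fixture(scope="session")
def pulse():
    return PulseShape(4.0)


def make_point_source(grid: GridSpec, world_mm, value=1.0) -> Volume:
    vals = np.zeros(grid.shape)
    idx = np.round(grid.world_to_index(np.asarray(world_mm))).astype(int)
    vals[tuple(idx)] = value
    return Volume(vals, grid)


def brute_force_forward(p0: Volume, array, medium, sampling_mhz, n_samples):
    """Independent straight-loop discretization of the retarded-time
    spherical-spreading sum (no pulse/band-pass convolution)."""
    v = medium.sound_speed_m_s / 1000.0
    out = np.zeros((array.positions_mm.shape[0], n_samples))
    origin = np.array(p0.grid.origin)
    spacing = np.array(p0.grid.spacing)
    dv = spacing[0] * spacing[1] * spacing[2]
    for e in range(array.positions_mm.shape[0]):
        r_e = array.positions_mm[e]
        for (i, j, k), val in np.ndenumerate(p0.values):
            if val == 0.0:
                continue
            r = origin + np.array([i, j, k]) * spacing
            d = max(float(np.linalg.norm(r_e - r)), 1e-6)
            a = val * dv / (4.0 * np.pi * v**2 * d)
            t = d / v
            x = t * sampling_mhz
            i0 = int(np.floor(x))
            w = x - i0
            out[e, i0] += a * (1.0 - w)
            out[e, i0 + 1] += a * w
    return out


def brute_force_das(traces: PressureTraces, array, grid: GridSpec, medium):
    """Independent triple-loop delay-and-sum with manual linear interpolation."""
    v = medium.sound_speed_m_s / 1000.0
    dt = traces.dt_us
    out = np.zeros(grid.shape)
    for (i, j, k) in np.ndindex(grid.shape):
        r = np.array(grid.origin) + np.array([i, j, k]) * np.array(grid.spacing)
        acc = 0.0
        for e in range(array.positions_mm.shape[0]):
            d = max(float(np.linalg.norm(array.positions_mm[e] - r)), 1e-6)
            x = (d / v) / dt
            i0 = int(np.floor(x))
            if i0 >= traces.n_samples - 1:
                acc += traces.data[e, -1]
            else:
                w = x - i0
                acc += (1 - w) * traces.data[e, i0] + w * traces.data[e, i0 + 1]
        out[i, j, k] = acc / array.positions_mm.shape[0]
    return out
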