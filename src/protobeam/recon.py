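"""3D back-projection image formation from matrix-array traces.

Two variants of the classic time-of-flight back-projection are provided:

* ``das`` — delay-and-sum: each voxel accumulates the raw trace value at its
  acoustic time of flight to each element.
* ``ubp`` — universal back-projection: the back-projected quantity is
  p(t) - t * dp/dt evaluated at the time of flight, with solid-angle
  weighting of each element's contribution.

With microsecond-long proton pulses and no pulse deconvolution, the
derivative term of ``ubp`` displaces an extended source's peak by roughly the
pulse length, so ``das`` is the default; ``ubp`` is appropriate for
near-instantaneous deposition.

A planar array has a limited view: the axis along the array normal is the
reliable one (range direction); in-plane dimensions elongate.  Localization
metrics therefore use peak position, not shape fidelity.
"""

from __future__ import annotations

import warnings

import numpy as np

from .acoustic import ArrayGeometry, MediumProperties, PressureTraces
from .volume import GridSpec, ReconVolume


class GeometryMismatchError(ValueError):
    """Trace channel count does not match the array element count."""


def backproject(traces: PressureTraces, array: ArrayGeometry, grid: GridSpec,
                medium: MediumProperties, variant: str = "das",
                normalize: bool = False,
                out_of_window: str = "clamp") -> ReconVolume:
    """Back-project traces onto a voxel grid.

    ``out_of_window``: "clamp" evaluates out-of-record times at the record edge
    (with a warning), "error" raises.  Linear interpolation between samples.
    """
    if traces.n_channels != array.n_elements:
        raise GeometryMismatchError(
            f"{traces.n_channels} trace channels vs {array.n_elements} array elements"
        )
    if variant not in ("das", "ubp"):
        raise ValueError(f"unknown reconstruction variant {variant!r}")
    if out_of_window not in ("clamp", "error"):
        raise ValueError("out_of_window must be 'clamp' or 'error'")

    v = medium.sound_speed_mm_us
    tmax = (traces.n_samples - 1) * traces.dt_us
    times = traces.times_us
    voxels = grid.voxel_centers().reshape(-1, 3)
    acc = np.zeros(voxels.shape[0])
    wsum = np.zeros(voxels.shape[0])
    warned = False

    if variant == "ubp":
        dpdt = np.gradient(traces.data, traces.dt_us, axis=1)

    for i in range(array.n_elements):
        rel = voxels - array.positions_mm[i]
        d = np.linalg.norm(rel, axis=1)
        d = np.maximum(d, 1e-6)
        t = d / v
        out = t > tmax
        if np.any(out):
            if out_of_window == "error":
                raise ValueError(
                    f"{int(out.sum())} voxels beyond the {tmax:.1f} us record "
                    f"for element {i}; enlarge the record or shrink the grid"
                )
            if not warned:
                warnings.warn("some voxels lie beyond the recorded time window; "
                              "their samples are clamped to the record edge",
                              stacklevel=2)
                warned = True
        val = np.interp(t, times, traces.data[i])
        if variant == "ubp":
            val = val - t * np.interp(t, times, dpdt[i])
            cos = np.abs(rel @ array.normals[i]) / d
            w = cos / d**2  # solid angle of the element seen from the voxel
        else:
            w = np.ones_like(d)
        acc += w * val
        wsum += w

    img = acc / np.maximum(wsum, 1e-300)
    if normalize and np.max(np.abs(img)) > 0:
        img = img / np.max(np.abs(img))
    values = img.reshape(grid.shape)
    return ReconVolume(values, grid,
                       {"variant": variant,
                        "sound_speed_m_s": medium.sound_speed_m_s,
                        "n_channels": traces.n_channels,
                        "n_averages": traces.n_averages})


def profile_extract(vol: ReconVolume, axis, through_mm) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear-interpolated 1D profile through a point.

    ``axis`` is 0/1/2 (x/y/z) or an arbitrary direction vector.  Returns
    ``(coords_mm, values)`` where coords are signed distances along the axis
    from the volume boundary (for integer axes, the world coordinate on that
    axis).  The point must lie inside the raster.
    """
    point = np.asarray(through_mm, dtype=float)
    if not bool(vol.grid.contains(point)):
        raise ValueError(f"point {point} mm lies outside the volume raster")

    if isinstance(axis, (int, np.integer)):
        coords = vol.grid.axis_coords(int(axis))
        pts = np.tile(point, (coords.size, 1))
        pts[:, int(axis)] = coords
        return coords, vol.sample(pts)

    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    # March both directions from the point until leaving the raster.
    step = min(vol.grid.spacing)
    extent = np.linalg.norm(np.asarray(vol.grid.shape) * np.asarray(vol.grid.spacing))
    s = np.arange(-extent, extent + step, step)
    pts = point + s[:, None] * u
    inside = vol.grid.contains(pts)
    s, pts = s[inside], pts[inside]
    return s, vol.sample(pts)
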