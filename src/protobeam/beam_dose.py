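"""Analytic proton pencil-beam dose model and scan patterns.

The depth-dose curve is a Bortfeld-style parameterization: a power-law
range-energy relation R = alpha * E**p (water: alpha = 0.0022 cm/MeV^p,
p = 1.77) with the characteristic 1/sqrt(R - z) rise toward the Bragg peak,
Gaussian-convolved with a range-straggling width to produce a finite peak and
a steep distal falloff.  A pencil beam is that curve along the beam axis times
a 2D lateral Gaussian spot.  This stands in for Monte Carlo dose engines: it
has the correct range-energy law and a realistic peak/falloff, which is what
the acoustic imaging chain exercises.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .volume import DoseGrid, GridSpec

# Power-law range-energy constants for water (R in cm, E in MeV).
RANGE_ALPHA_CM = 0.0022
RANGE_EXPONENT = 1.77
# Range-straggling width sigma = 0.012 * R^0.935 (both in cm), the standard
# water parameterization.
STRAGGLE_COEFF = 0.012
STRAGGLE_EXPONENT = 0.935


class TruncatedRangeError(ValueError):
    """The dose grid ends before the Bragg peak (plus distal margin) fits."""


@dataclass(frozen=True)
class BeamSpec:
    """One pencil-beam spot.

    Parameters
    ----------
    energy_mev : proton kinetic energy in MeV.
    entry_point_mm : world coordinate where the beam enters the medium.
    direction : unit vector of travel.
    lateral_sigma_mm : Gaussian spot sigma at entry (mm).
    pulse_duration_us : proton pulse duration tau_p in microseconds
        (machine-adjustable 4-20 us; override allowed).
    pulses_per_frame : pulses delivered per acquisition frame.
    """

    energy_mev: float
    entry_point_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    lateral_sigma_mm: float = 3.0
    pulse_duration_us: float = 4.0
    pulses_per_frame: int = 1
    allow_pulse_out_of_band: bool = False

    def __post_init__(self) -> None:
        if self.energy_mev <= 0:
            raise ValueError(f"energy must be positive, got {self.energy_mev} MeV")
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError(f"direction must be a unit vector, got norm {np.linalg.norm(d)}")
        if self.lateral_sigma_mm <= 0:
            raise ValueError("lateral_sigma_mm must be positive")
        if not self.allow_pulse_out_of_band and not (4.0 <= self.pulse_duration_us <= 20.0):
            raise ValueError(
                f"pulse_duration_us={self.pulse_duration_us} outside the machine's "
                "4-20 us band; set allow_pulse_out_of_band=True to override"
            )
        if self.pulses_per_frame < 1:
            raise ValueError("pulses_per_frame must be >= 1")
        object.__setattr__(self, "entry_point_mm", tuple(float(x) for x in self.entry_point_mm))
        object.__setattr__(self, "direction", tuple(float(x) for x in d))


@dataclass(frozen=True)
class ScanPlan:
    """Ordered pencil-beam spots stepped laterally by a fixed distance."""

    spots: tuple[BeamSpec, ...]
    step_size_mm: float
    scan_axis: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.spots) < 1:
            raise ValueError("a scan plan needs at least one spot")
        entries = np.array([s.entry_point_mm for s in self.spots])
        steps = np.linalg.norm(np.diff(entries, axis=0), axis=1)
        if steps.size and not np.allclose(steps, self.step_size_mm, atol=1e-9):
            raise ValueError(
                f"consecutive entry points must differ by step_size={self.step_size_mm} mm, "
                f"got {steps}"
            )

    def __len__(self) -> int:
        return len(self.spots)


def proton_range_mm(energy_mev: float, density_g_cm3: float = 1.0) -> float:
    """CSDA-style range from the power law R = alpha*E^p, density-scaled, in mm."""
    if energy_mev <= 0:
        raise ValueError("energy must be positive")
    r_cm = RANGE_ALPHA_CM * energy_mev**RANGE_EXPONENT / density_g_cm3
    return 10.0 * r_cm


def straggling_sigma_mm(range_mm: float) -> float:
    """Range-straggling Gaussian sigma (mm) for a given range (mm)."""
    return 10.0 * STRAGGLE_COEFF * (range_mm / 10.0) ** STRAGGLE_EXPONENT


def bragg_depth_dose(energy_mev: float, depths_mm: np.ndarray,
                     density_g_cm3: float = 1.0) -> np.ndarray:
    """Depth-dose profile (arbitrary linear units) at the requested depths.

    The pristine curve 1/sqrt(R - z) is integrated analytically over fine bins
    (the integrable singularity at z = R is handled exactly) and convolved with
    the range-straggling Gaussian.  The result has a single global maximum just
    proximal to R and decays below 1% of peak within a few straggling widths
    beyond it.
    """
    depths = np.asarray(depths_mm, dtype=float)
    if depths.size == 0:
        raise ValueError("depth grid is empty")
    if np.any(depths < 0):
        raise ValueError("depths must be non-negative")
    if depths.ndim != 1 or (depths.size > 1 and np.any(np.diff(depths) <= 0)):
        raise ValueError("depths must be a strictly increasing 1D grid")
    if energy_mev <= 0:
        raise ValueError("energy must be positive")

    r_mm = proton_range_mm(energy_mev, density_g_cm3)
    sigma = max(straggling_sigma_mm(r_mm), 1e-3)

    # Fine internal grid out to the distal tail.
    dz = min(sigma / 6.0, 0.1)
    z_max = max(depths.max(), r_mm) + 6.0 * sigma
    edges = np.arange(0.0, z_max + dz, dz)
    # Bin-averaged 1/sqrt(R - z): antiderivative is -2*sqrt(R - z).
    rem = np.clip(r_mm - edges, 0.0, None)
    anti = -2.0 * np.sqrt(rem)
    pristine = np.diff(anti) / dz  # average of the integrand over each bin
    blurred = gaussian_filter1d(pristine, sigma / dz, mode="constant", truncate=8.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    profile = np.interp(depths, centers, blurred, left=float(blurred[0]), right=0.0)
    return np.clip(profile, 0.0, None)


def pencil_beam_dose_3d(beam: BeamSpec, grid: GridSpec,
                        density_g_cm3: float = 1.0,
                        depth_broadening: float = 0.0,
                        range_margin: float = 1.1) -> DoseGrid:
    """Deposit one pencil-beam spot on a 3D raster.

    Dose = depth-dose along the beam axis x lateral Gaussian (area-normalized).
    ``depth_broadening`` adds sigma_eff^2 = sigma0^2 + (k*depth)^2 growth with
    depth (k dimensionless, default 0 = constant spot size).

    Raises
    ------
    TruncatedRangeError
        if the grid ends before ``range_margin`` times the expected range along
        the beam direction, i.e. the Bragg peak would be cut off.
    """
    r_mm = proton_range_mm(beam.energy_mev, density_g_cm3)
    entry = np.asarray(beam.entry_point_mm)
    direction = np.asarray(beam.direction)
    distal_point = entry + direction * (range_margin * r_mm)
    if not bool(grid.contains(distal_point)):
        raise TruncatedRangeError(
            f"grid does not contain the distal point {distal_point} mm "
            f"({range_margin:.0%} of range {r_mm:.1f} mm along the beam); "
            "enlarge the grid or lower the beam energy"
        )

    centers = grid.voxel_centers()
    rel = centers - entry
    depth = rel @ direction
    lat2 = np.einsum("...i,...i->...", rel, rel) - depth**2
    lat2 = np.clip(lat2, 0.0, None)

    depth_axis = np.arange(0.0, 1.05 * range_margin * r_mm + 5.0, min(grid.spacing) / 2.0)
    ddcurve = bragg_depth_dose(beam.energy_mev, depth_axis, density_g_cm3)
    axial = np.interp(depth, depth_axis, ddcurve, left=0.0, right=0.0)
    axial[depth < 0] = 0.0

    sig2 = beam.lateral_sigma_mm**2 + (depth_broadening * np.clip(depth, 0, None)) ** 2
    lateral = np.exp(-lat2 / (2.0 * sig2)) / (2.0 * np.pi * sig2)

    values = axial * lateral
    if not np.any(values > 0):
        raise ValueError("beam deposits no dose inside the grid")
    return DoseGrid(values, grid, {"beam": beam, "range_mm": r_mm})


def bragg_peak_position(beam: BeamSpec, density_g_cm3: float = 1.0,
                        dz: float = 0.01) -> np.ndarray:
    """World coordinate (mm) of the analytic depth-dose maximum along the axis."""
    r_mm = proton_range_mm(beam.energy_mev, density_g_cm3)
    depths = np.arange(0.0, r_mm + 5.0, dz)
    prof = bragg_depth_dose(beam.energy_mev, depths, density_g_cm3)
    z_peak = depths[int(np.argmax(prof))]
    return np.asarray(beam.entry_point_mm) + np.asarray(beam.direction) * z_peak


def scan_pattern(base: BeamSpec, n_spots: int, step_mm: float,
                 axis=(1.0, 0.0, 0.0)) -> ScanPlan:
    """Lateral scan: ``n_spots`` copies of ``base`` stepped by ``step_mm`` along ``axis``."""
    if n_spots < 1:
        raise ValueError("n_spots must be >= 1")
    if step_mm <= 0:
        raise ValueError("step_mm must be positive")
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    spots = []
    for i in range(n_spots):
        entry = np.asarray(base.entry_point_mm) + i * step_mm * ax
        spots.append(replace(base, entry_point_mm=tuple(entry)))
    return ScanPlan(tuple(spots), step_mm, tuple(ax))
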