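"""Quantitative verification metrics: Bragg-peak localization, averaging
sweeps, bandwidth-limited resolution, gamma-index dosimetric comparison and
multi-spot scan tracking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from . import beam_dose as bd
from .acoustic import (ArrayGeometry, MediumProperties, PressureTraces,
                       PulseShape, TransducerResponse, acquire_frames,
                       forward_propagate, initial_pressure, noise_sigma_for_snr)
from .recon import backproject, profile_extract
from .volume import GridSpec, ReconVolume, Volume


def bandwidth_resolution(sound_speed_m_s: float, f_max_hz: float) -> float:
    """Bandwidth-limited imaging resolution R = 0.88 * v_s / f_max, in mm."""
    if sound_speed_m_s <= 0 or f_max_hz <= 0:
        raise ValueError("sound speed and f_max must be positive")
    return 0.88 * sound_speed_m_s / f_max_hz * 1000.0


def max_frame_rate(repetition_rate_hz: float, n_averages: int) -> float:
    """Highest achievable imaging frame rate: pulse repetition rate / averages."""
    if repetition_rate_hz <= 0 or n_averages < 1:
        raise ValueError("repetition rate must be positive and n_averages >= 1")
    return repetition_rate_hz / n_averages


@dataclass(frozen=True)
class LocalizationResult:
    """Localized peak position and, when ground truth is known, the deviation."""

    position_mm: np.ndarray
    method: str
    deviation_mm: float | None = None
    n_averages: int | None = None


def _parabolic_refine(values: np.ndarray, idx: tuple[int, int, int]) -> np.ndarray:
    """Sub-voxel refinement of an argmax by a 3-point parabola per axis."""
    out = np.array(idx, dtype=float)
    for ax in range(3):
        i = idx[ax]
        if 0 < i < values.shape[ax] - 1:
            sl = list(idx)
            sl[ax] = slice(i - 1, i + 2)
            y0, y1, y2 = values[tuple(sl)]
            denom = y0 - 2.0 * y1 + y2
            if denom < 0:  # genuine local maximum
                out[ax] = i + 0.5 * (y0 - y2) / denom
    return out


def localize_bragg_peak(vol: ReconVolume, beam_axis=None, method: str = "argmax",
                        truth_mm=None) -> LocalizationResult:
    """Locate the Bragg peak in a reconstructed (or dose) volume.

    Methods
    -------
    argmax
        Global maximum voxel refined by a 3-point parabolic fit per axis.
    centroid
        Intensity-weighted mean of voxels above 50% of the maximum.
    distal80
        Distal position along ``beam_axis`` where the axial profile through
        the peak falls to 80% of its maximum (range-verification convention).
    """
    vals = vol.values
    if not np.any(vals > 0):
        raise ValueError("volume has no positive values: no peak to localize")

    idx = np.unravel_index(int(np.argmax(vals)), vals.shape)
    if method == "argmax":
        pos = vol.grid.index_to_world(_parabolic_refine(vals, idx))
    elif method == "centroid":
        mask = vals >= 0.5 * vals.max()
        w = vals[mask]
        pts = vol.grid.index_to_world(np.argwhere(mask).astype(float))
        pos = (w[:, None] * pts).sum(axis=0) / w.sum()
    elif method == "distal80":
        if beam_axis is None:
            raise ValueError("distal80 localization requires beam_axis")
        u = np.asarray(beam_axis, dtype=float)
        u = u / np.linalg.norm(u)
        peak_pt = vol.grid.index_to_world(np.asarray(idx, dtype=float))
        s, prof = profile_extract(vol, u, peak_pt)
        i_pk = int(np.argmax(prof))
        level = 0.8 * prof[i_pk]
        below = np.nonzero(prof[i_pk:] < level)[0]
        if below.size == 0:
            raise ValueError("profile never falls to 80% of peak distally")
        j = i_pk + below[0]
        # Linear interpolation of the crossing between samples j-1 and j.
        frac = (prof[j - 1] - level) / (prof[j - 1] - prof[j])
        s80 = s[j - 1] + frac * (s[j] - s[j - 1])
        pos = peak_pt + s80 * u
    else:
        raise ValueError(f"unknown localization method {method!r}")

    dev = None if truth_mm is None else float(np.linalg.norm(pos - np.asarray(truth_mm)))
    return LocalizationResult(np.asarray(pos, dtype=float), method, dev,
                              vol.provenance.get("n_averages"))


# ---------------------------------------------------------------------------
# Gamma-index dosimetric comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GammaCriteria:
    """Dose-difference / distance-to-agreement criteria, e.g. 5 mm / 5% with a
    10% low-dose threshold (global-maximum normalization)."""

    dose_tol_pct: float = 5.0
    distance_tol_mm: float = 5.0
    low_dose_threshold_pct: float = 10.0

    def __post_init__(self) -> None:
        if self.dose_tol_pct <= 0 or self.distance_tol_mm <= 0:
            raise ValueError("dose and distance tolerances must be positive")
        if not 0 < self.low_dose_threshold_pct < 100:
            raise ValueError("low-dose threshold must be in (0, 100) percent")


@dataclass(frozen=True)
class GammaResult:
    gamma: Volume           # gamma value per evaluated voxel, NaN elsewhere
    pass_rate_pct: float
    n_evaluated: int


def gamma_index(measured: Volume, reference: Volume,
                criteria: GammaCriteria = GammaCriteria(),
                search_factor: float = 2.0,
                subdivision: int = 5) -> GammaResult:
    """3D gamma index of ``measured`` against ``reference``.

    Both volumes must share a raster (resample beforehand otherwise).  For
    every voxel with measured dose >= threshold% of the measured maximum,

        gamma = min over dr in a ball of radius search_factor*distance_tol of
                sqrt(|dr|^2/dta^2 + (M(r) - Ref(r+dr))^2 / dd^2)

    with dd = dose_tol% of the global reference maximum and the reference
    trilinearly interpolated on a lattice of ``subdivision`` steps per voxel.
    Offsets are visited in order of increasing |dr| with an early exit once the
    distance term alone exceeds every running minimum.
    """
    if measured.grid != reference.grid:
        raise ValueError("measured and reference rasters differ: resample to a "
                         "common grid before the gamma comparison")
    ref_max = float(np.max(reference.values))
    if ref_max <= 0:
        raise ValueError("reference maximum must be positive")
    meas_max = float(np.max(measured.values))
    mask = measured.values >= criteria.low_dose_threshold_pct / 100.0 * meas_max
    if not np.any(mask):
        raise ValueError("no voxels above the low-dose threshold: nothing to evaluate")

    spacing = np.asarray(measured.grid.spacing)
    dd = criteria.dose_tol_pct / 100.0 * ref_max
    dta = criteria.distance_tol_mm
    radius = search_factor * dta

    # Candidate offsets on the sub-voxel lattice inside the search ball.
    steps = [np.arange(-np.floor(radius / (sp / subdivision)),
                       np.floor(radius / (sp / subdivision)) + 1) * (sp / subdivision)
             for sp in spacing]
    ox, oy, oz = np.meshgrid(*steps, indexing="ij")
    offsets = np.stack([ox, oy, oz], axis=-1).reshape(-1, 3)
    dist2 = np.einsum("ij,ij->i", offsets, offsets)
    keep = dist2 <= radius**2
    offsets, dist2 = offsets[keep], dist2[keep]
    order = np.argsort(dist2)
    offsets, dist2 = offsets[order], dist2[order]

    pts = measured.grid.index_to_world(np.argwhere(mask).astype(float))
    m = measured.values[mask]
    gamma2 = np.full(m.shape, np.inf)
    inv_sp = 1.0 / spacing
    origin = np.asarray(measured.grid.origin)
    for off, d2 in zip(offsets, dist2):
        d2n = d2 / dta**2
        if d2n >= gamma2.max():
            break  # no voxel can improve beyond the distance term alone
        idx = ((pts + off - origin) * inv_sp).T
        ref_vals = map_coordinates(reference.values, idx, order=1, mode="nearest")
        cand = d2n + ((m - ref_vals) / dd) ** 2
        np.minimum(gamma2, cand, out=gamma2)

    gamma = np.sqrt(gamma2)
    gvol = np.full(measured.values.shape, np.nan)
    gvol[mask] = gamma
    pass_rate = 100.0 * float(np.mean(gamma <= 1.0))
    return GammaResult(measured.with_values(gvol, quantity="gamma"),
                       pass_rate, int(mask.sum()))


# ---------------------------------------------------------------------------
# Simulation-based experiments
# ---------------------------------------------------------------------------

@dataclass
class ImagingScene:
    """A complete simulated acquisition: beam + dose raster + array +
    transducer + pulse + medium + reconstruction grid."""

    beam: bd.BeamSpec
    dose_grid: GridSpec
    recon_grid: GridSpec
    array: ArrayGeometry
    medium: MediumProperties
    pulse: PulseShape
    response: TransducerResponse
    sampling_mhz: float = 20.0
    record_length_us: float = 75.0
    source_threshold: float = 1e-4
    variant: str = "das"

    def dose(self) -> Volume:
        return bd.pencil_beam_dose_3d(self.beam, self.dose_grid)

    def truth_mm(self) -> np.ndarray:
        return bd.bragg_peak_position(self.beam)

    def clean_traces(self, dose: Volume | None = None) -> PressureTraces:
        p0 = initial_pressure(self.dose() if dose is None else dose, self.medium)
        return forward_propagate(p0, self.array, self.medium, pulse=self.pulse,
                                 response=self.response,
                                 sampling_mhz=self.sampling_mhz,
                                 record_length_us=self.record_length_us,
                                 source_threshold=self.source_threshold)

    def reconstruct(self, traces: PressureTraces) -> ReconVolume:
        return backproject(traces, self.array, self.recon_grid, self.medium,
                           variant=self.variant)


def averaging_sweep(scene: ImagingScene, snr_single_frame: float,
                    n_values, seeds, denoise_spec=None,
                    method: str = "argmax") -> pd.DataFrame:
    """Bragg-peak localization deviation versus the number of averaged frames.

    For every (n_averages, seed) pair: add white Gaussian noise at the
    single-frame peak SNR, average n frames, optionally wavelet-denoise,
    reconstruct and localize; the deviation is measured against the analytic
    Bragg-peak position.  Returns one row per trial with the 3D Euclidean and
    per-axis deviations.
    """
    seeds = list(seeds)
    n_values = [int(n) for n in n_values]
    if min(n_values) < 1:
        raise ValueError("n_averages values must be >= 1")
    if len(seeds) < 3:
        raise ValueError("need at least 3 seeds for a meaningful sweep")

    truth = scene.truth_mm()
    clean = scene.clean_traces()
    sigma = noise_sigma_for_snr(clean, snr_single_frame)

    rows = []
    for seed in seeds:
        for n in n_values:
            tr = acquire_frames(clean, sigma, n, seed=(int(seed) * 100003 + n) % (2**31))
            if denoise_spec is not None:
                from .denoise import wavelet_denoise
                tr = wavelet_denoise(tr, denoise_spec)
            vol = scene.reconstruct(tr)
            loc = localize_bragg_peak(vol, beam_axis=scene.beam.direction,
                                      method=method, truth_mm=truth)
            delta = loc.position_mm - truth
            rows.append({"n_averages": n, "seed": int(seed),
                         "deviation_mm": loc.deviation_mm,
                         "dx_mm": delta[0], "dy_mm": delta[1], "dz_mm": delta[2]})
    return pd.DataFrame(rows)


def summarize_sweep(table: pd.DataFrame) -> pd.DataFrame:
    """Per-n summary of an averaging sweep: mean, median, max, 95th percentile."""
    g = table.groupby("n_averages")["deviation_mm"]
    out = g.agg(mean="mean", median="median", max="max",
                p95=lambda s: float(np.percentile(s, 95)))
    return out.reset_index()


def spot_tracking(plan: bd.ScanPlan, scene: ImagingScene,
                  snr_single_frame: float | None = None,
                  n_averages: int = 1, seeds=None,
                  method: str = "argmax") -> pd.DataFrame:
    """Reconstruct each scan spot and report recovered positions and
    adjacent-spot separations.

    Noiseless when ``snr_single_frame`` is None.  The reconstruction grid is
    recentered on each spot's planned lateral position so every spot is imaged
    in its own field of view.  Returns one row per (seed, spot); separations
    are Euclidean distances between consecutive localized peaks.
    """
    from dataclasses import replace as dc_replace

    seeds = [None] if (seeds is None or snr_single_frame is None) else list(seeds)
    base_entry = np.asarray(scene.beam.entry_point_mm)
    rows = []
    for seed in seeds:
        prev = None
        for k, spot in enumerate(plan.spots):
            shift = np.asarray(spot.entry_point_mm) - base_entry
            sc = dc_replace(
                scene, beam=spot,
                dose_grid=GridSpec(scene.dose_grid.shape, scene.dose_grid.spacing,
                                   tuple(np.asarray(scene.dose_grid.origin) + shift)),
                recon_grid=GridSpec(scene.recon_grid.shape, scene.recon_grid.spacing,
                                    tuple(np.asarray(scene.recon_grid.origin) + shift)),
            )
            clean = sc.clean_traces()
            tr = clean
            if snr_single_frame is not None:
                sigma = noise_sigma_for_snr(clean, snr_single_frame)
                tr = acquire_frames(clean, sigma, n_averages,
                                    seed=(int(seed) * 99991 + k) % (2**31))
            vol = sc.reconstruct(tr)
            loc = localize_bragg_peak(vol, beam_axis=spot.direction, method=method,
                                      truth_mm=bd.bragg_peak_position(spot))
            sep = None if prev is None else float(np.linalg.norm(loc.position_mm - prev))
            rows.append({"seed": -1 if seed is None else int(seed), "spot": k,
                         "x_mm": loc.position_mm[0], "y_mm": loc.position_mm[1],
                         "z_mm": loc.position_mm[2],
                         "deviation_mm": loc.deviation_mm,
                         "separation_mm": sep,
                         "step_error_mm": None if sep is None
                         else sep - plan.step_size_mm})
            prev = loc.position_mm
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ResolutionEstimate:
    axial_fwhm_mm: float
    lateral_fwhm_mm: float
    bandwidth_limit_mm: float


def _fwhm(coords: np.ndarray, values: np.ndarray) -> float:
    """Full width at half maximum by linear interpolation of the crossings."""
    i_pk = int(np.argmax(values))
    half = 0.5 * values[i_pk]

    def crossing(side: int) -> float:
        idx = np.arange(i_pk, -1 if side < 0 else values.size, side)
        below = np.nonzero(values[idx] < half)[0]
        if below.size == 0:
            return coords[idx[-1]]
        j = idx[below[0]]
        jprev = j - side
        frac = (values[jprev] - half) / (values[jprev] - values[j])
        return coords[jprev] + frac * (coords[j] - coords[jprev])

    return float(abs(crossing(+1) - crossing(-1)))


def line_spread_resolution(source_mm, array: ArrayGeometry,
                           medium: MediumProperties, pulse: PulseShape,
                           response: TransducerResponse,
                           grid_spacing_mm: float = 0.4,
                           fov_mm: float = 16.0,
                           sampling_mhz: float = 20.0,
                           record_length_us: float = 75.0,
                           variant: str = "das") -> ResolutionEstimate:
    """Point-source line-spread-function resolution of the imaging chain.

    Simulates a single-voxel source, reconstructs it and measures the FWHM of
    the point response along the mean array normal (axial) and the first
    in-plane direction (lateral); also reports the bandwidth-limit formula
    R = 0.88 v_s/f_max for reference.
    """
    source = np.asarray(source_mm, dtype=float)
    n = np.mean(array.normals, axis=0)
    n /= np.linalg.norm(n)
    ref = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(n, ref)
    u /= np.linalg.norm(u)

    half = fov_mm / 2.0
    npx = int(round(fov_mm / grid_spacing_mm)) + 1
    grid = GridSpec.isotropic((npx,) * 3, grid_spacing_mm, tuple(source - half))
    vals = np.zeros(grid.shape)
    vals[tuple(np.round(grid.world_to_index(source)).astype(int))] = 1.0
    p0 = Volume(vals, grid)
    tr = forward_propagate(p0, array, medium, pulse=pulse, response=response,
                           sampling_mhz=sampling_mhz,
                           record_length_us=record_length_us)
    vol = backproject(tr, array, grid, medium, variant=variant)
    peak = vol.grid.index_to_world(
        _parabolic_refine(vol.values,
                          np.unravel_index(int(np.argmax(vol.values)), vol.values.shape)))
    s_ax, prof_ax = profile_extract(vol, n, peak)
    s_lat, prof_lat = profile_extract(vol, u, peak)
    r_limit = bandwidth_resolution(medium.sound_speed_m_s, response.f_max_mhz * 1e6)
    return ResolutionEstimate(_fwhm(s_ax, np.clip(prof_ax, 0, None)),
                              _fwhm(s_lat, np.clip(prof_lat, 0, None)),
                              r_limit)
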