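"""Thermoacoustic forward model: dose -> initial pressure -> matrix-array traces.

The chain implements the standard protoacoustic generation model.  The initial
pressure induced by one proton pulse is

    p0(r) = Gamma * eta_th * rho * D_p(r)

with Gamma the Grueneisen parameter (Gamma = beta*K_T/(C_v*rho)), eta_th the
heat efficiency and D_p the dose per pulse.  The pressure detected by an ideal
point receiver at position r is the retarded-time spherical-spreading integral

    p(r, t) = 1/(4*pi*v_s^2) * integral dr' p0(r')/|r - r'| * d/dt' s(t')/tau_p
              evaluated at t' = t - |r - r'|/v_s,

under the separability assumption that the dose rate factorizes as
D_r(r', t) = D_p(r') * s(t)/tau_p, where s(t) is the normalized proton pulse
profile (integral of s = tau_p).  Discretely, each source voxel deposits its
amplitude at its time of flight; the deposit train is then convolved with
ds/dt and with the transducer's band-pass impulse response.

Internal units: mm, microseconds, MHz (so sound speed is used in mm/us).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import fftconvolve


def grueneisen_from_constituents(beta_per_k: float, bulk_modulus_pa: float,
                                 heat_capacity_j_kg_k: float,
                                 density_kg_m3: float) -> float:
    """Grueneisen parameter Gamma = beta * K_T / (C_v * rho), SI inputs."""
    for name, v in (("beta", beta_per_k), ("K_T", bulk_modulus_pa),
                    ("C_v", heat_capacity_j_kg_k), ("rho", density_kg_m3)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return beta_per_k * bulk_modulus_pa / (heat_capacity_j_kg_k * density_kg_m3)


@dataclass(frozen=True)
class MediumProperties:
    """Acoustic/thermal properties of the (single, uniform) propagation medium.

    ``sound_speed_m_s`` in m/s, ``density_g_cm3`` in g/cm^3, ``grueneisen`` and
    ``heat_efficiency`` dimensionless.  If the thermodynamic constituents
    (``beta_per_k`` 1/K, ``bulk_modulus_pa`` Pa, ``heat_capacity_j_kg_k``
    J/(kg K)) are all given, they must reproduce ``grueneisen``.  Optional
    power-law acoustic attenuation: ``attenuation_db_cm`` at
    ``attenuation_ref_mhz`` with exponent ``attenuation_power``.
    """

    sound_speed_m_s: float = 1480.0
    density_g_cm3: float = 1.0
    grueneisen: float = 0.11
    heat_efficiency: float = 1.0
    beta_per_k: float | None = None
    bulk_modulus_pa: float | None = None
    heat_capacity_j_kg_k: float | None = None
    attenuation_db_cm: float | None = None
    attenuation_ref_mhz: float = 2.25
    attenuation_power: float = 1.0

    def __post_init__(self) -> None:
        if self.sound_speed_m_s <= 0:
            raise ValueError("sound speed must be positive")
        if self.density_g_cm3 <= 0:
            raise ValueError("density must be positive")
        if not 0 < self.heat_efficiency <= 1:
            raise ValueError("heat efficiency must be in (0, 1]")
        parts = (self.beta_per_k, self.bulk_modulus_pa, self.heat_capacity_j_kg_k)
        if all(p is not None for p in parts):
            g = grueneisen_from_constituents(self.beta_per_k, self.bulk_modulus_pa,
                                             self.heat_capacity_j_kg_k,
                                             self.density_g_cm3 * 1000.0)
            if abs(g - self.grueneisen) > 1e-9 * max(abs(g), abs(self.grueneisen)):
                raise ValueError(
                    f"grueneisen={self.grueneisen} inconsistent with "
                    f"beta*K_T/(C_v*rho)={g}"
                )

    @property
    def sound_speed_mm_us(self) -> float:
        return self.sound_speed_m_s / 1000.0

    @classmethod
    def water(cls) -> "MediumProperties":
        return cls(sound_speed_m_s=1480.0, density_g_cm3=1.0, grueneisen=0.11)

    @classmethod
    def torso_phantom(cls) -> "MediumProperties":
        """Soft-tissue-mimicking torso phantom: 1400 m/s, 1.00 g/cm^3,
        1.2 dB/cm attenuation at 2.25 MHz."""
        return cls(sound_speed_m_s=1400.0, density_g_cm3=1.0, grueneisen=0.11,
                   attenuation_db_cm=1.2, attenuation_ref_mhz=2.25)


MEDIUM_PRESETS = {"water": MediumProperties.water,
                  "torso_phantom": MediumProperties.torso_phantom}


@dataclass(frozen=True)
class ArrayGeometry:
    """Planar matrix ultrasound array: element centers, normals, layout."""

    positions_mm: np.ndarray       # (n_elements, 3)
    normals: np.ndarray            # (n_elements, 3), unit
    element_size_mm: float
    pitch_mm: float
    layout: tuple[int, int]

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions_mm, dtype=float))
        nrm = np.atleast_2d(np.asarray(self.normals, dtype=float))
        if pos.shape != nrm.shape or pos.shape[1] != 3:
            raise ValueError("positions and normals must both be (n, 3)")
        if pos.shape[0] != self.layout[0] * self.layout[1]:
            raise ValueError(f"layout {self.layout} does not match {pos.shape[0]} elements")
        if self.pitch_mm < self.element_size_mm:
            raise ValueError(
                f"pitch ({self.pitch_mm} mm) must be >= element size "
                f"({self.element_size_mm} mm): elements cannot overlap"
            )
        norms = np.linalg.norm(nrm, axis=1)
        object.__setattr__(self, "positions_mm", pos)
        object.__setattr__(self, "normals", nrm / norms[:, None])

    @property
    def n_elements(self) -> int:
        return self.positions_mm.shape[0]


def matrix_array(rows: int = 16, cols: int = 16, element_size_mm: float = 3.0,
                 kerf_mm: float = 0.2, center_mm=(0.0, 0.0, 0.0),
                 normal=(0.0, 0.0, 1.0)) -> ArrayGeometry:
    """Planar rows x cols matrix array in the plane through ``center_mm``
    perpendicular to ``normal``.

    The default is the 16x16 = 256-element array with 3 mm elements and 0.2 mm
    kerf (3.2 mm center-to-center pitch, ~51 mm square aperture), facing +z.
    """
    pitch = element_size_mm + kerf_mm
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    # Build two in-plane unit vectors orthogonal to the normal.
    ref = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(n, ref)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    iu = (np.arange(cols) - (cols - 1) / 2.0) * pitch
    iv = (np.arange(rows) - (rows - 1) / 2.0) * pitch
    uu, vv = np.meshgrid(iu, iv, indexing="xy")
    pos = (np.asarray(center_mm, dtype=float)
           + uu.reshape(-1, 1) * u + vv.reshape(-1, 1) * v)
    normals = np.broadcast_to(n, pos.shape).copy()
    return ArrayGeometry(pos, normals, element_size_mm, pitch, (rows, cols))


@dataclass(frozen=True)
class TransducerResponse:
    """Band-pass receive response: Gaussian-envelope tone burst at f_c.

    ``fractional_bandwidth_pct`` is the -6 dB bandwidth as a percentage of the
    center frequency; the maximum detectable frequency is the upper -6 dB edge
    f_max = f_c * (1 + bw/200).
    """

    center_frequency_mhz: float = 1.0
    fractional_bandwidth_pct: float = 60.0

    def __post_init__(self) -> None:
        if self.center_frequency_mhz <= 0 or self.fractional_bandwidth_pct <= 0:
            raise ValueError("center frequency and bandwidth must be positive")

    @property
    def f_max_mhz(self) -> float:
        return self.center_frequency_mhz * (1.0 + self.fractional_bandwidth_pct / 200.0)

    def impulse_response(self, dt_us: float) -> np.ndarray:
        """Zero-phase (symmetric) impulse response sampled at dt, unit L1 gain.

        Gaussian amplitude spectrum with -6 dB points at f_c * (1 +/- bw/200):
        sigma_f = (bw_abs/2) / sqrt(2 ln 2), sigma_t = 1/(2 pi sigma_f).
        """
        bw_abs = self.center_frequency_mhz * self.fractional_bandwidth_pct / 100.0
        sigma_f = (bw_abs / 2.0) / np.sqrt(2.0 * np.log(2.0))
        sigma_t = 1.0 / (2.0 * np.pi * sigma_f)
        half = int(np.ceil(4.0 * sigma_t / dt_us))
        t = np.arange(-half, half + 1) * dt_us
        h = np.exp(-0.5 * (t / sigma_t) ** 2) * np.cos(2 * np.pi * self.center_frequency_mhz * t)
        return h / np.sum(np.abs(h))


@dataclass(frozen=True)
class PulseShape:
    """Proton pulse temporal profile s(t) >= 0 with integral = tau_p.

    Shapes: ``rectangular``, ``trapezoid`` (10% rise/fall of tau_p, the
    default) and ``gaussian`` (FWHM = tau_p, truncated at +/-3 sigma).
    """

    duration_us: float = 4.0
    kind: str = "trapezoid"
    rise_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.duration_us <= 0:
            raise ValueError("pulse duration must be positive")
        if self.kind not in ("rectangular", "trapezoid", "gaussian"):
            raise ValueError(f"unknown pulse shape {self.kind!r}")
        if not 0 < self.rise_fraction < 0.5:
            raise ValueError("rise_fraction must be in (0, 0.5)")

    def profile(self, dt_us: float) -> np.ndarray:
        """Samples of s(t) from t=0, normalized so sum(s)*dt = tau_p."""
        tau = self.duration_us
        if self.kind == "gaussian":
            sigma = tau / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            t = np.arange(0.0, 6.0 * sigma + dt_us, dt_us)
            s = np.exp(-0.5 * ((t - 3.0 * sigma) / sigma) ** 2)
        else:
            t = np.arange(0.0, tau + dt_us, dt_us)
            if self.kind == "rectangular":
                s = np.ones_like(t)
                s[t > tau] = 0.0
            else:
                rise = self.rise_fraction * tau
                s = np.clip(np.minimum(t / rise, (tau - t) / rise), 0.0, 1.0)
        total = np.sum(s) * dt_us
        return s * (tau / total)


@dataclass
class PressureTraces:
    """Detected pressure, channels x time samples.

    ``sampling_mhz`` is the sample rate in MS/s (samples per microsecond);
    t=0 is the proton-pulse onset trigger.
    """

    data: np.ndarray
    sampling_mhz: float
    n_averages: int = 1
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.sampling_mhz <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def dt_us(self) -> float:
        return 1.0 / self.sampling_mhz

    @property
    def record_length_us(self) -> float:
        return self.n_samples / self.sampling_mhz

    @property
    def times_us(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_mhz

    def copy(self) -> "PressureTraces":
        return PressureTraces(self.data.copy(), self.sampling_mhz,
                              self.n_averages, self.seed, dict(self.meta))


class RecordTooShortError(ValueError):
    """Some source voxel's time of flight exceeds the record length."""


def initial_pressure(dose, medium: MediumProperties):
    """Initial pressure p0 = Gamma * eta_th * rho * D_p, voxelwise on the dose raster."""
    vals = np.asarray(dose.values)
    if not np.all(np.isfinite(vals)):
        raise ValueError("dose contains non-finite values")
    if np.any(vals < 0):
        raise ValueError("dose must be non-negative")
    p0 = medium.grueneisen * medium.heat_efficiency * medium.density_g_cm3 * vals
    return dose.with_values(p0, quantity="initial_pressure")


def forward_propagate(p0, array: ArrayGeometry, medium: MediumProperties,
                      pulse: PulseShape | None = None,
                      response: TransducerResponse | None = None,
                      sampling_mhz: float = 20.0,
                      record_length_us: float = 75.0,
                      apply_attenuation: bool = False,
                      source_threshold: float = 0.0) -> PressureTraces:
    """Project an initial-pressure volume onto the array's time traces.

    Each nonzero voxel contributes p0*dV / (4 pi v_s^2 |r - r'|) at its time of
    flight (split linearly between the two bracketing samples); the deposit
    train is then convolved with ds/dt (the pulse-derivative term of the
    retarded-time integral) and with the transducer band-pass response.
    Elements are ideal points at their centers.  Noiseless and deterministic.

    ``source_threshold`` drops voxels below that fraction of max(p0) to bound
    cost on large grids (0 keeps every nonzero voxel).
    """
    if response is not None and sampling_mhz < 4.0 * response.f_max_mhz:
        raise ValueError(
            f"sampling rate {sampling_mhz} MS/s below 4*f_max = "
            f"{4 * response.f_max_mhz} MS/s anti-aliasing requirement"
        )
    vals = p0.values
    thresh = source_threshold * vals.max() if vals.size else 0.0
    src_idx = np.nonzero(vals > max(thresh, 0.0))
    if len(src_idx[0]) == 0:
        n_samp = int(round(record_length_us * sampling_mhz))
        return PressureTraces(np.zeros((array.n_elements, n_samp)), sampling_mhz)
    src_pos = p0.grid.index_to_world(np.stack(src_idx, axis=-1).astype(float))
    v = medium.sound_speed_mm_us
    amp0 = vals[src_idx] * p0.grid.voxel_volume / (4.0 * np.pi * v**2)

    dt = 1.0 / sampling_mhz
    n_samp = int(round(record_length_us * sampling_mhz))
    traces = np.zeros((array.n_elements, n_samp))
    for i, r_elem in enumerate(array.positions_mm):
        d = np.linalg.norm(src_pos - r_elem, axis=1)
        d = np.maximum(d, 1e-6)
        t = d / v
        if t.max() >= record_length_us - dt:
            j = int(np.argmax(t))
            raise RecordTooShortError(
                f"voxel at {src_pos[j]} mm is {d[j]:.2f} mm from element {i}: "
                f"arrival {t[j]:.2f} us exceeds the {record_length_us} us record"
            )
        a = amp0 / d
        if apply_attenuation and medium.attenuation_db_cm is not None:
            att = (medium.attenuation_db_cm / medium.attenuation_ref_mhz
                   ** medium.attenuation_power)
            fc = response.center_frequency_mhz if response is not None else 1.0
            a = a * 10.0 ** (-att * fc**medium.attenuation_power * (d / 10.0) / 20.0)
        idx = t * sampling_mhz
        i0 = np.floor(idx).astype(np.int64)
        w = idx - i0
        traces[i] = (np.bincount(i0, weights=a * (1.0 - w), minlength=n_samp)
                     + np.bincount(i0 + 1, weights=a * w, minlength=n_samp))[:n_samp]

    if pulse is not None:
        s = pulse.profile(dt)
        # ds/dt including the leading/trailing edges, times dt for the
        # continuous-convolution measure; the deposit train already carries
        # D_p-proportional amplitude, so divide by tau_p per separability.
        ds = np.diff(np.concatenate([[0.0], s, [0.0]])) / dt
        traces = fftconvolve(traces, ds[None, :] * dt / pulse.duration_us,
                             mode="full")[:, :n_samp]
    if response is not None:
        h = response.impulse_response(dt)
        traces = fftconvolve(traces, h[None, :], mode="same")

    return PressureTraces(traces, sampling_mhz,
                          meta={"record_length_us": record_length_us,
                                "sound_speed_m_s": medium.sound_speed_m_s})


def acquire_frames(traces: PressureTraces, noise_sigma: float, n_frames: int,
                   seed: int | None) -> PressureTraces:
    """Average ``n_frames`` noisy acquisitions of the same underlying signal.

    Each frame is signal + i.i.d. zero-mean Gaussian noise (same sigma on every
    channel and sample); the residual noise std of the average scales as
    noise_sigma / sqrt(n_frames).  With ``noise_sigma == 0`` the signal is
    returned unchanged.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    out = traces.copy()
    out.n_averages = n_frames
    out.seed = seed
    if noise_sigma == 0:
        return out
    rng = np.random.default_rng(seed)
    shape = traces.data.shape
    acc = np.zeros(shape)
    chunk = max(1, int(2e7 // traces.data.size))  # bound scratch memory
    done = 0
    while done < n_frames:
        m = min(chunk, n_frames - done)
        acc += rng.standard_normal((m,) + shape).sum(axis=0)
        done += m
    out.data = traces.data + noise_sigma * acc / n_frames
    return out


def peak_signal_amplitude(traces: PressureTraces) -> float:
    """Max |p| over all channels/samples; the reference for single-frame SNR."""
    return float(np.max(np.abs(traces.data)))


def noise_sigma_for_snr(traces: PressureTraces, snr: float) -> float:
    """Per-sample noise sigma giving the requested single-frame peak SNR
    (peak |signal| / sigma)."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    return peak_signal_amplitude(traces) / snr
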