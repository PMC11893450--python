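"""Discrete-wavelet-transform denoising of channel traces.

Per channel: multilevel DWT (default sym8, 5 levels, symmetric extension) ->
soft-thresholding of the detail coefficients with the universal threshold
sigma_hat * sqrt(2 ln n), sigma_hat estimated from the median absolute
deviation of the finest detail band -> inverse DWT -> optional zero-phase
Butterworth low-pass.

The low-pass cutoff default is 0.12 MHz.  Note the physical oddity: a
0.12 MHz low-pass would suppress most of a 1 MHz-band protoacoustic signal,
so pipelines that feed reconstruction typically disable it (``cutoff_mhz =
None``) or raise it above the transducer band; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.signal import butter, sosfiltfilt

from .acoustic import PressureTraces


@dataclass(frozen=True)
class WaveletFilterSpec:
    """Wavelet shrinkage parameters plus the post-IDWT low-pass cutoff (MHz)."""

    wavelet: str = "sym8"
    levels: int = 5
    threshold_rule: str = "universal"
    threshold_scale: float = 1.0
    cutoff_mhz: float | None = 0.12
    mode: str = "symmetric"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.cutoff_mhz is not None and self.cutoff_mhz <= 0:
            raise ValueError("cutoff must be positive (or None to disable)")
        if self.threshold_rule != "universal":
            raise ValueError(f"unknown threshold rule {self.threshold_rule!r}")
        if self.threshold_scale <= 0:
            raise ValueError("threshold_scale must be positive")
        if self.wavelet not in pywt.wavelist(kind="discrete"):
            raise ValueError(f"unknown discrete wavelet {self.wavelet!r}")


def wavelet_denoise(traces: PressureTraces,
                    spec: WaveletFilterSpec = WaveletFilterSpec()) -> PressureTraces:
    """Denoise every channel; output keeps the input's shape and sampling."""
    n = traces.n_samples
    if n < 2**spec.levels:
        raise ValueError(
            f"trace length {n} shorter than 2^levels = {2**spec.levels}; "
            "reduce the decomposition depth"
        )
    wav = pywt.Wavelet(spec.wavelet)
    max_lev = pywt.dwt_max_level(n, wav.dec_len)
    levels = min(spec.levels, max_lev)
    if levels < 1:
        raise ValueError(f"trace length {n} shorter than the {spec.wavelet} filter support")

    out = np.empty_like(traces.data)
    for c in range(traces.n_channels):
        coeffs = pywt.wavedec(traces.data[c], wav, mode=spec.mode, level=levels)
        finest = coeffs[-1]
        sigma = np.median(np.abs(finest - np.median(finest))) / 0.6745
        thr = spec.threshold_scale * sigma * np.sqrt(2.0 * np.log(n))
        if thr > 0:
            coeffs = [coeffs[0]] + [pywt.threshold(d, thr, mode="soft")
                                    for d in coeffs[1:]]
        rec = pywt.waverec(coeffs, wav, mode=spec.mode)
        out[c] = rec[:n]

    if spec.cutoff_mhz is not None:
        nyq = traces.sampling_mhz / 2.0
        if spec.cutoff_mhz >= nyq:
            raise ValueError(f"cutoff {spec.cutoff_mhz} MHz >= Nyquist {nyq} MHz")
        sos = butter(4, spec.cutoff_mhz / nyq, btype="low", output="sos")
        out = sosfiltfilt(sos, out, axis=1)

    res = traces.copy()
    res.data = out
    res.meta = {**traces.meta, "denoise": spec}
    return res


def snr_gain(clean: np.ndarray, noisy: np.ndarray, denoised: np.ndarray) -> float:
    """Denoising gain in dB: 10 log10( MSE(noisy) / MSE(denoised) ) vs clean.

    Returns ``inf`` for perfect recovery of a signal the noisy input missed.
    """
    clean = np.asarray(clean, dtype=float)
    if clean.shape != np.shape(noisy) or clean.shape != np.shape(denoised):
        raise ValueError("clean, noisy and denoised must have identical shapes")
    mse_before = float(np.mean((np.asarray(noisy) - clean) ** 2))
    mse_after = float(np.mean((np.asarray(denoised) - clean) ** 2))
    if mse_after == 0.0:
        return 0.0 if mse_before == 0.0 else float("inf")
    return 10.0 * np.log10(mse_before / mse_after)
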