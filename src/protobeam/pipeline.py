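"""Top-level orchestration: dose -> signals -> (denoise) -> reconstruction ->
evaluation, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time

import numpy as np

from . import __version__
from .acoustic import acquire_frames, forward_propagate, initial_pressure, \
    noise_sigma_for_snr
from .beam_dose import bragg_peak_position, pencil_beam_dose_3d
from .config import RunConfig, config_to_dict
from .denoise import wavelet_denoise
from .evaluate import localize_bragg_peak
from .io import save_traces, write_volume
from .recon import backproject

log = logging.getLogger("protobeam")


def _sha256(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def run_pipeline(cfg: RunConfig, out_dir: str) -> dict:
    """Execute a full run and write volumes, traces and a JSON manifest.

    Returns the manifest: per-stage status/timing, output paths, array hashes
    and the localization result.  Any stage failure aborts with the stage name
    attached to the exception.
    """
    os.makedirs(out_dir, exist_ok=True)
    medium = cfg.build_medium()
    array = cfg.array.build()
    pulse = cfg.pulse.build()
    response = cfg.transducer.build()
    beam = cfg.beam.build(cfg.pulse.duration_us)

    manifest: dict = {
        "version": __version__,
        "config": config_to_dict(cfg),
        "stages": {},
        "outputs": {},
    }

    def stage(name: str, fn):
        t0 = time.perf_counter()
        log.info("stage %s: starting", name)
        try:
            result = fn()
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        dt = time.perf_counter() - t0
        manifest["stages"][name] = {"status": "ok", "seconds": round(dt, 3)}
        log.info("stage %s: done in %.2f s", name, dt)
        return result

    dose = stage("dose", lambda: pencil_beam_dose_3d(beam, cfg.dose_grid.build()))
    dose_path = os.path.join(out_dir, "dose.mhd")
    write_volume(dose, dose_path)
    manifest["outputs"]["dose"] = {"path": dose_path, "sha256": _sha256(dose.values)}

    p0 = stage("initial_pressure", lambda: initial_pressure(dose, medium))

    clean = stage("forward", lambda: forward_propagate(
        p0, array, medium, pulse=pulse, response=response,
        sampling_mhz=cfg.acquisition.sampling_mhz,
        record_length_us=cfg.acquisition.record_length_us,
        source_threshold=1e-4))

    if cfg.acquisition.noiseless:
        traces = clean
        manifest["stages"]["acquire"] = {"status": "skipped", "reason": "noiseless"}
    else:
        sigma = noise_sigma_for_snr(clean, cfg.acquisition.snr_single_frame)
        traces = stage("acquire", lambda: acquire_frames(
            clean, sigma, cfg.acquisition.n_averages, seed=cfg.stage_seed("acquire")))
    traces_path = os.path.join(out_dir, "traces.h5")
    save_traces(traces, traces_path)
    manifest["outputs"]["traces"] = {"path": traces_path, "sha256": _sha256(traces.data)}

    if cfg.denoise.enabled:
        traces = stage("denoise", lambda: wavelet_denoise(traces, cfg.denoise.build()))
        manifest["outputs"]["traces_denoised"] = {"sha256": _sha256(traces.data)}
    else:
        manifest["stages"]["denoise"] = {"status": "skipped", "reason": "disabled"}

    recon = stage("reconstruct", lambda: backproject(
        traces, array, cfg.recon_grid.build(), medium,
        variant=cfg.recon.variant, normalize=cfg.recon.normalize))
    recon_path = os.path.join(out_dir, "recon.mhd")
    write_volume(recon, recon_path)
    manifest["outputs"]["recon"] = {"path": recon_path, "sha256": _sha256(recon.values)}

    truth = bragg_peak_position(beam)
    loc = stage("evaluate", lambda: localize_bragg_peak(
        recon, beam_axis=beam.direction, truth_mm=truth))
    manifest["localization"] = {
        "position_mm": [round(float(x), 4) for x in loc.position_mm],
        "planned_peak_mm": [round(float(x), 4) for x in truth],
        "deviation_mm": round(float(loc.deviation_mm), 4),
        "n_averages": cfg.acquisition.n_averages,
    }

    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as f:
        json.dump(manifest, f, indent=2)
    manifest["outputs"]["manifest"] = {"path": manifest_path}
    return manifest
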