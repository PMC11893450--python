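"""Canonical simulated experiments built from a RunConfig.

The default scene mirrors the characterization setup: an 87 MeV pencil beam
entering at z = 75 mm and travelling toward the 16x16 matrix array in the
z = 0 plane, so the Bragg peak (~16 mm from the array) moves along the array
normal — the reliable axis of a planar-aperture reconstruction.
"""

from __future__ import annotations

import numpy as np

from .beam_dose import scan_pattern
from .config import RunConfig
from .evaluate import ImagingScene


def scene_from_config(cfg: RunConfig) -> ImagingScene:
    return ImagingScene(
        beam=cfg.beam.build(cfg.pulse.duration_us),
        dose_grid=cfg.dose_grid.build(),
        recon_grid=cfg.recon_grid.build(),
        array=cfg.array.build(),
        medium=cfg.build_medium(),
        pulse=cfg.pulse.build(),
        response=cfg.transducer.build(),
        sampling_mhz=cfg.acquisition.sampling_mhz,
        record_length_us=cfg.acquisition.record_length_us,
        variant=cfg.recon.variant,
    )


def default_scene() -> ImagingScene:
    return scene_from_config(RunConfig())


def scan_plan_from_scene(scene: ImagingScene, n_spots: int, step_mm: float,
                         axis=(1.0, 0.0, 0.0)):
    """Lateral scan of the scene's beam, centered so the pattern straddles the
    scene's original entry point."""
    from dataclasses import replace

    ax = np.asarray(axis, dtype=float)
    ax /= np.linalg.norm(ax)
    start = np.asarray(scene.beam.entry_point_mm) - ax * step_mm * (n_spots - 1) / 2.0
    base = replace(scene.beam, entry_point_mm=tuple(start))
    return scan_pattern(base, n_spots, step_mm, ax)
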