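# protobeam

**3D protoacoustic imaging of the proton Bragg peak — simulation,
reconstruction and range-verification metrics.**

Proton radiotherapy deposits most of its dose at the Bragg peak, so treatment
quality hinges on knowing *where* that peak actually is inside the patient.
Pulsed proton beams generate thermoacoustic pressure waves at the deposition
site; recording them with a 2D matrix ultrasound array and back-projecting in
3D images the Bragg peak in real time. `protobeam` implements that whole
chain in silico for physicists and algorithm developers working on
protoacoustic range verification:

1. **`beam_dose`** — analytic pencil-beam dose: power-law range–energy
   relation `R = α·E^p` (α = 0.0022 cm/MeV^p, p = 1.77 in water), a
   `1/√(R−z)` Bragg curve blurred by range straggling, Gaussian lateral
   spots, and laterally-stepped scan plans.
2. **`acoustic`** — thermoacoustic forward model: initial pressure
   `p0 = Γ·η_th·ρ·D_p`, retarded-time spherical-spreading propagation to a
   16×16 matrix array (3 mm elements, 3.2 mm pitch, 1 MHz / 60% bandwidth),
   proton-pulse and receive-band convolution, white-noise acquisition and
   frame averaging.
3. **`denoise`** — sym8 wavelet shrinkage (universal threshold, soft) with an
   optional post-IDWT low-pass.
4. **`recon`** — 3D back-projection (`das` delay-and-sum default, `ubp`
   derivative-term variant) onto an arbitrary voxel raster.
5. **`evaluate`** — Bragg-peak localization (argmax / centroid / distal-80%),
   deviation-vs-averages sweeps, line-spread resolution, bandwidth limit
   `R = 0.88·v_s/f_max`, 3D gamma-index pass rates, multi-spot tracking.
6. **`config` / `pipeline` / `cli`** — validated YAML configs, MetaImage
   volume and HDF5 trace I/O, a reproducible end-to-end pipeline and the
   `protobeam` command-line tool.

See `docs/methods.md` for the model, its assumptions and known artifacts.

## Worked example

Simulate the default characterization scene — an 87 MeV pencil beam (range
≈ 60 mm) entering water 75 mm in front of the array, Bragg peak ≈ 16 mm from
the array face — acquire 50 noisy frames, reconstruct and localize:

```python
from protobeam import RunConfig
from protobeam.pipeline import run_pipeline

manifest = run_pipeline(RunConfig(seed=1), "out")
print(manifest["localization"])
```

```
{'position_mm': [-0.3949, -0.0409, 16.0772], 'planned_peak_mm': [0.0, 0.0, 15.85],
 'deviation_mm': 0.4574, 'n_averages': 50}
```

The analytic Bragg peak for 87 MeV sits at z = 15.85 mm (range 59.6 mm below
the entry at z = 75 mm); averaging 50 frames at the default single-frame SNR
localizes it to 0.46 mm here — comfortably inside the 2 mm clinical
range-verification tolerance, with the residual dominated by lateral jitter
of the limited-view reconstruction and the 0.3 mm pulse-edge bias (see the
methods note). The same run from the shell:

```bash
protobeam run --config my_config.yaml --out out/
protobeam evaluate sweep --averages 1,10,50,200,1000 --seeds 3 --out sweep.csv
```

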