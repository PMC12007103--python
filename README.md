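# gaborholo

Reconstruction toolkit for **multi-frame digital in-line (Gabor)
holographic microscopy under low photon budget** — simulation,
reconstruction and evaluation of lensless / lens-based in-line hologram
stacks, for quantitative phase imaging of transparent specimens (live
cells, thin phase targets) at illumination doses low enough to avoid
photostimulation and photodamage.

## The problem

An in-line hologram records only the intensity
`I = |U(z)|²` of the object wave after free-space propagation by the
sample–camera distance `z`. Backpropagating its amplitude (the Gabor
holography reconstruction, GHR) restores the object but superimposes the
**twin image** — an out-of-focus conjugate replica concentrated at low
spatial frequencies. Recording several holograms at different defocus
distances (or illumination wavelengths) makes the inversion well posed:
**Gerchberg–Saxton (GS)** alternating projections remove the twin image
on clean data. But under a low photon budget the frames are dominated by
broadband camera **shot noise**, and GS — which seeks a field consistent
with *every* frame, noise included — amplifies it with each iteration.
Averaging the backpropagated frames (**Gabor averaging, GA**) suppresses
uncorrelated noise by `1/√K` but leaves the twin residual.

**Iterative Gabor averaging (IGA)** combines both by spectral
separation: the recorded intensities are Gaussian low-pass filtered
(std σ pixels) and handed to GS — removing the low-frequency twin image
without noise amplification — while the GA result is high-pass filtered
with the same kernel — keeping the noise-averaged high frequencies.
The two complex fields are summed:

    U_IGA = GS( G_σ * I_1..K )  +  (1 − G_σ) * GA( I_1..K )

Since `G + (1 − G) = 1`, an ideal split reproduces the object exactly —
twin-image suppression *and* noise averaging, with no net blur. Free-space
propagation uses the exact angular-spectrum kernel
`H = exp(i2πz√(1/λ² − f²))`; see `docs/methods.md` for the full model.

## Worked example

Simulate the default study scene — a pure-phase text object
(−0.4…0.6 rad, 256×256, 2 µm pixels) recorded at 2/3/4 mm with 500 nm
light and strong shot noise (Poisson std 0.2, hologram SNR ≈ 0.35) —
and compare all four reconstructors:

```python
import numpy as np
from gaborholo import (NoiseSpec, ReconstructionSettings, record_stack, reconstruct)
from gaborholo.protocols import default_phase_object
from gaborholo.metrics import ssim, align_piston, background_std

obj = default_phase_object(256)
stack = record_stack(obj, distances=(2e-3, 3e-3, 4e-3),
                     noise=NoiseSpec("poisson", 0.2, seed=1))
for method in ("ghr", "gs", "ga", "iga"):
    settings = ReconstructionSettings(method=method, iterations=30, sigma=2.0)
    field = reconstruct(stack, settings)
    phase = align_piston(field.phase, obj.phase)
    print(f"{method:>4}: SSIM={ssim(phase, obj.phase):.3f}  "
          f"S={background_std(field.phase, (5, 60, 5, 60)):.3f} rad")
```

prints

```
 ghr: SSIM=0.254  S=0.046 rad
  gs: SSIM=0.189  S=0.070 rad
  ga: SSIM=0.564  S=0.024 rad
 iga: SSIM=0.571  S=0.027 rad
```

SSIM compares the reconstructed phase with the ground truth; `S` is the
phase std of an object-free region (lower = cleaner background). At this
noise level the iterative GS is the *worst* method — it has amplified
the shot noise — while IGA matches GA's noise floor; on noise-free data
the ranking inverts and IGA instead tracks GS (run the same snippet with
`NoiseSpec()` to see SSIM ≈ 0.98/0.96 for GS/IGA vs 0.94 for GA).

The same pipeline is available from the shell:

```sh
gaborholo simulate --out sim/ --size 256 --noise poisson --noise-std 0.2 --seed 1
gaborholo reconstruct --manifest sim/manifest.json --method iga \
    --iterations 30 --sigma 2 --output rec/
gaborholo evaluate --phase rec/reconstruction_phase.tif \
    --truth sim/truth_phase.tif --roi 5 60 5 60 --out report.json
```

plus `sweep` (SSIM-vs-noise tables) and `batch` (time-lapse directories
of RGB frames, each color channel treated as a wavelength-multiplexed
hologram at 450/532/635 nm). Experimental stacks are described by a
small JSON/YAML manifest (paths, distances, wavelengths, pixel pitch);
`docs/example_zenodo_manifest.json` shows one for a deposited
thin-phase-target dataset.

## Layout

- `gaborholo.optics` — grids, complex fields, angular-spectrum and
  direct Rayleigh–Sommerfeld propagators
- `gaborholo.simulate` — synthetic objects (text phase/amplitude,
  resolution target), shot noise, quantization, stack recording
- `gaborholo.reconstruct` — GHR, GS, GA, IGA, Gaussian filter pair,
  wavelength phase rescaling
- `gaborholo.metrics` — M/ΔM/SNR, RMS, SSIM, background std,
  phase↔thickness
- `gaborholo.stackio` / `gaborholo.cli` — manifests, TIFF/PNG IO, RGB
  splitting, command line
- `gaborholo.protocols` — the canned simulation studies used by the
  tests and the acceptance script
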