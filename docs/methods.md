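# Methods

`gaborholo` simulates and reconstructs multi-frame digital in-line (Gabor)
holograms under low photon budget. This note records the model, the
parameters that matter, the numerical choices, and what the synthetic
studies do and do not show.

## Optical model

A thin transmissive object `t(x, y) = a·exp(iφ)` (amplitude `a ∈ [0, 1]`,
phase `φ` in radians) is illuminated by a unit-amplitude monochromatic
plane wave. The field propagates a distance `z` to the camera by the
angular spectrum method:

    U(z) = F⁻¹[ F[U(0)] · H(fx, fy; z) ],
    H = exp( i·2πz·√(1/λ² − fx² − fy²) )   for fx² + fy² ≤ 1/λ², else 0.

`H` has unit modulus on the propagating band, so propagation is unitary;
the evanescent band is hard-zeroed (at millimetre distances its physical
decay is far below double precision anyway, and `|H| ∈ {0, 1}` is
directly testable). Forward propagation (object → camera) is `+z`; every
"backpropagation" in reconstruction is the same operator at `−z`. Unit
magnification is assumed throughout: a lens-based system is described by
its effective pixel pitch.

The camera records intensity `I = |U(z)|²` — the in-line hologram: the
interference of the unscattered background with the object's diffracted
wave. Because the phase of `U` is lost, naive backpropagation
(`ghr`) superimposes an out-of-focus conjugate replica — the twin image —
concentrated at low spatial frequencies.

### Padding and the frame edge

With `pad_factor=2` (default) the FFT grid is doubled to suppress
periodic wrap-around. The pad continuation is explicit: by default the
field's mean — the unscattered plane-wave background, which physically
extends far beyond the sensor — is split off, propagated analytically
(phase `2πz/λ`), and re-added; only the zero-mean scattered remainder is
zero-padded. Zero-padding the raw field would turn the frame edge into a
hard aperture whose diffraction swamps the hologram contrast (it raises
ΔM several-fold and breaks energy conservation). For genuinely compact
sources (apertures on a dark background) `background="dark"` selects
plain zero-padding. `pad_factor=1` (periodic model, no padding) is exact
for round trips and is used in large iterative runs for speed.

A quadratic-cost direct Rayleigh–Sommerfeld summation
(`propagate_direct`, kernel `z(1 − ikr)e^{ikr}/(2πr³)`) serves as an
independent reference. The validation geometry is a Gaussian-apodized
aperture (σ = 4 µm on a 64×64, 2 µm grid, z = 1 mm, λ = 500 nm): it is
band-limited, so Fourier-interpolating the source (oversample 2×)
makes the direct sum a faithful quadrature of the oscillatory kernel,
and its diffracted field stays inside the padded window. A hard-edged
aperture would have unbounded angular content and the comparison would
measure sampling artifacts of the oracle rather than propagator error.
Agreement is ~2×10⁻⁵ relative RMS in intensity.

## Hologram simulation

`record_hologram` computes `I = |propagate(a·exp(iφ·λref/λ), +z)|²` in
arbitrary units (unit illumination), then applies noise and optional
quantization. Phase is stored at a reference wavelength; conversion to
other wavelengths goes through the optical path difference
`OPD = φ·λref/2π`, which is the wavelength-independent physical quantity.

Noise model (`NoiseSpec`):

- `gaussian`: additive i.i.d. `N(0, σₙ²)`.
- `poisson`: `I → Poisson(I·N)/N` with photon budget `N = 1/σₙ²`, so the
  shot-noise std at unit mean equals the requested `target_std` — the
  minimal parameterization consistent with specifying noise by its std.
  Negative excursions (Gaussian case) are clipped at zero, as a camera
  would.

Quantization (`CameraModel`) maps to gray levels by
`clip(round(I·gain·exposure_scale), 0, 2^bits − 1)`; it is off in the
simulation studies, which are reported in continuous arbitrary units.

Stacks multiplex either distance (one wavelength, distinct `z`, as in a
scanned lensless system) or wavelength (one `z`, distinct `λ`, as in an
RGB snapshot system). Per-frame noise uses sub-seeds derived
deterministically from the master seed, so stacks are reproducible while
frames stay independent.

### Default study conditions

The default synthetic scene is a rendered-text pure-phase object
("IGA", DejaVu Sans) spanning −0.4 to 0.6 rad on a 256×256 grid of 2 µm
pixels, imaged at 500 nm from 2/3/4 mm. The glyph bounding box fills 20%
of the frame: a sparse object in the weak-scattering regime typical of
cell-scale specimens, giving holograms with mean `M ≈ 1 a.u.` and
contrast `ΔM ≈ 0.07 a.u.`, hence a worst-case hologram SNR of
`ΔM/0.2 ≈ 0.35` at the strongest simulated noise. The amplitude-object
variant (absorbing text, transmittance 0–1 on a transparent background)
uses the same layout. The exact contrast is artwork-dependent; none of
the conclusions depend on its third decimal.

## Reconstruction algorithms

All methods first convert intensity to amplitude. Default is
`A = √(I/mean I)` (cameras record intensity; `mean(A²) = 1`); the
`identity` switch (`A = I/mean I`) is provided because deposited
reference implementations sometimes treat the normalized hologram itself
as the amplitude.

- **GHR** — backpropagate one frame's amplitude with zero phase. Carries
  the full twin image.
- **GS** (Gerchberg–Saxton) — alternating projections: starting from the
  first frame's amplitude with zero phase, cycle through the frames in
  listed order (ascending distance by simulator convention), propagating
  between hologram planes and replacing the amplitude with the measured
  one while keeping the phase; after `T` full cycles, backpropagate to
  the object plane. No object-plane constraint (no positivity/support
  projection) is applied. In wavelength mode the estimate lives at the
  object plane at the first frame's wavelength and each visit rescales
  the phase via the OPD (`φ' = φ·λ/λ'`) before propagating at that
  frame's wavelength. GS removes the twin image on clean data but, by
  construction, also seeks a field consistent with the *noise* in every
  frame: on noisy data its error grows with `T` (noise amplification).
- **GA** (Gabor averaging) — mean of the individually backpropagated
  frames (phase-rescaled to the first frame's wavelength in wavelength
  mode). Uncorrelated shot noise averages down as `1/√K`; a low-frequency
  twin-image residual remains.
- **IGA** (iterative Gabor averaging) — exploits the spectral separation
  of the two artifacts (twin image: low frequency; shot noise:
  broadband). Path 1 low-pass filters every recorded intensity with a
  Gaussian kernel of std `σ` pixels and runs GS on the filtered stack;
  path 2 runs GA on the raw stack and high-pass filters the complex
  result with the same kernel; the two fields are summed. Were both
  paths ideal, the sum `G·O + (1−G)·O = O` would be exact — the method
  trades artifacts between bands without net blur.

Filters are applied in the frequency domain
(`G(f) = exp(−2π²σ²|f|²)`, `f` in cycles/pixel, periodic boundary), so
`lowpass + highpass ≡ identity` to machine precision and the σ → 0 limit
collapses IGA onto plain GS exactly.

### Band combination (a genuinely open choice)

The GS step is nonlinear (amplitude substitution), so its output on
low-passed holograms still contains above-band content. Two conventions
exist: sum the path outputs literally, or low-pass the GS path first so
the bands partition exactly (`strict_band`). We default to the strict
partition: on noisy data GS's regenerated above-band content is
amplified noise, and keeping it makes IGA measurably worse than GA at
high noise (ΔSSIM ≈ 0.04 at Poisson std 0.2), contradicting the method's
purpose; with the strict partition IGA matches or exceeds GA at every
noise level while staying within 0.02 SSIM of GS on clean data. The
literal sum remains available as `strict_band=False`.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `iterations` (T) | 100 | GS cycles; more cycles → better twin removal on clean data, more noise amplification on noisy data. 30 suffices for the 256×256 sweep; 10 is used for timing parity. |
| `sigma` (σ) | 2 px | Balance between paths: larger σ → stronger noise averaging, weaker twin suppression. Values ~1–4 px behave similarly; σ is a fine-tuning knob, not a critical one. |
| `hologram_to_amplitude` | `sqrt` | Intensity→amplitude convention (see above). |
| `pad_factor` | 2 | FFT padding; 1 for speed in large runs. |
| `strict_band` | `True` | Exact spectral partition of the IGA paths. |

## Metrics

- `rms_error`: RMS deviation, optionally masked; for phase maps the
  global piston is removed first, since an in-line system cannot observe
  the absolute phase offset.
- `ssim`: canonical structural similarity (11×11 Gaussian window,
  σ = 1.5, K₁ = 0.01, K₂ = 0.03; `skimage` backend, cross-checked in the
  test suite against a direct per-window implementation). Dynamic range
  defaults to the reference image's span. Phase maps are piston-aligned
  before comparison.
- `background_std` (S): std of the reconstructed phase over an
  object-free rectangle — the background-quality measure for
  experimental data without ground truth.
- `hologram_stats`: M (mean), ΔM (std = contrast), and, given a
  noise-free reference, `SNR = ΔM(reference)/std(I − reference)`.
- `thickness_from_phase`: `t = φλ/(2π(n_s − n_m))` and its inverse. At
  561 nm through borosilicate glass (n = 1.47) in air, a 8.47×10⁻² rad
  step corresponds to 16.1 nm — within the ±3 nm manufacturing tolerance
  of the reference target that motivates the conversion.

No phase unwrapping is performed anywhere; all supported objects satisfy
|φ| < π.

## What the synthetic studies show — and what they do not

The protocols in `gaborholo.protocols` establish, on the default scene:

- GS converges on clean data (error at T = 100 below a quarter of its
  T = 1 value, non-increasing after the first cycles) and diverges on
  noisy data (error at T = 100 above its T = 1 value) — the failure mode
  IGA is designed around.
- Across Poisson std 0–0.2 (T = 30, σ = 2, three seeds per point): GS
  and IGA lead on clean data, GA and IGA on noisy data, and IGA stays
  within 0.02 SSIM of the best of GS/GA at every noise level.
- GA's object-free background phase std drops by `1/√K` with K
  independent same-distance frames (Monte-Carlo, 20 repeats). The
  verification scene uses a weakly absorbing disk so the background is
  shot-noise dominated; an opaque object leaks enough deterministic twin
  ripple into the ROI to mask the law.
- IGA's runtime is within ~5% of GS + GA combined (measured at
  1000×1000, three frames, T = 10, `pad_factor=1`; only the relative
  cost is meaningful).

The simulator emulates coherent plane-wave illumination, a thin object,
shot/Gaussian noise and quantization. It does **not** model partial
coherence, read noise, dark current, fixed-pattern noise, Bayer
demosaicing, aberrations, or axial positioning error — so passing these
studies demonstrates algorithmic correctness under the stated model, not
end-to-end performance on any particular instrument. Experimental stacks
(e.g. the deposited thin-target holograms; see
`docs/example_zenodo_manifest.json`) can be run through the same CLI but
need per-dataset distances, pitch, and ROI choices.

## Numerical choices and degenerate inputs

- FFT layout: zero frequency at the first element everywhere (kernels and
  filters share one grid; no fftshift off-by-ones).
- GS initialization: first frame's amplitude, zero phase, at the first
  frame's plane — the textbook choice; frame order as listed.
- GS output is taken after completing T full cycles (a final
  backpropagation from the last visited plane), not mid-cycle.
- Low-pass in IGA acts on recorded intensities; filtered intensities are
  clipped at zero before the square root (the periodic Gaussian kernel
  is positive, so only float round-off can undershoot).
- Degenerate inputs fail loudly: empty stacks, duplicate distances in
  distance mode, σ ≤ 0, all-zero holograms, out-of-range ROIs and
  mismatched shapes all raise `ValueError` (manifest field errors raise
  `SchemaError` naming the field).
- Seeds: every stochastic operation takes an explicit integer seed;
  per-frame and per-protocol sub-seeds are derived via
  `numpy.random.SeedSequence` spawn keys.

## Known limitations

- Wavelength-mode GS assumes a dispersion-free thin object (pure OPD
  scaling) and one shared defocus distance for all channels.
- `σ` is not chosen automatically; strongly structured backgrounds may
  need a different balance.
- The resolution-target generator uses a simple halving three-bar rule,
  not any standardized target layout.
- Reconstruction of strongly absorbing or optically thick (|φ| ≥ π)
  objects is out of scope.
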