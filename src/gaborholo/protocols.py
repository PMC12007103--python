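"""Canned evaluation protocols for the simulation studies.

These functions wire the simulator, reconstructors and metrics into the
package's standard numerical experiments:

- :func:`gs_error_curve` — per-iteration GS reconstruction error on a
  two-distance stack of an amplitude object, noise-free vs noisy (the
  noise-amplification demonstration).
- :func:`noise_robustness_sweep` — phase SSIM of GHR/GS/GA/IGA across
  Poisson shot-noise levels on the default three-distance phase-text
  stack.
- :func:`averaging_noise_ratio` — Monte-Carlo check of GA's 1/sqrt(K)
  background-noise averaging.
- :func:`timing_comparison` — relative wall-clock cost of GS, GA and IGA
  on one stack.

Problem sizes default to 256x256 (1000x1000 for the timing run), chosen
so a complete sweep runs in minutes on a single core.
"""

from __future__ import annotations

import time
from dataclasses import replace

import numpy as np

from .metrics import align_piston, background_std, rms_error, ssim
from .optics import GridSpec
from .reconstruct import ReconstructionSettings, ga, ghr, gs, iga, reconstruct
from .simulate import (
    HologramStack,
    NoiseSpec,
    SyntheticObject,
    make_amplitude_object,
    make_text_phase_object,
    record_stack,
)

__all__ = [
    "default_phase_object",
    "default_amplitude_object",
    "gs_error_curve",
    "noise_robustness_sweep",
    "averaging_noise_ratio",
    "timing_comparison",
]

DEFAULT_PITCH = 2e-6
DEFAULT_WAVELENGTH = 500e-9
DEFAULT_DISTANCES = (2e-3, 3e-3, 4e-3)
DEFAULT_TEXT = "IGA"


def default_phase_object(size: int = 256, text: str = DEFAULT_TEXT) -> SyntheticObject:
    """The default pure-phase test object: rendered text spanning
    -0.4 .. 0.6 rad on a ``size`` x ``size`` grid of 2 um pixels."""
    grid = GridSpec(size, size, DEFAULT_PITCH)
    return make_text_phase_object(text, grid, -0.4, 0.6, DEFAULT_WAVELENGTH)


def default_amplitude_object(size: int = 256, text: str = DEFAULT_TEXT) -> SyntheticObject:
    """The default pure-amplitude test object: absorbing text (0..1
    transmittance) on a transparent background."""
    grid = GridSpec(size, size, DEFAULT_PITCH)
    return make_amplitude_object(text, grid, 0.0, 1.0, DEFAULT_WAVELENGTH)


def gs_error_curve(
    noise: NoiseSpec = NoiseSpec(),
    size: int = 256,
    distances=(2e-3, 3e-3),
    iterations: int = 100,
    settings: ReconstructionSettings | None = None,
) -> np.ndarray:
    """Amplitude RMS error of GS vs ground truth after each iteration.

    Simulates a two-distance stack of the default amplitude object
    (optionally noisy) and records the object-plane amplitude RMS error
    after every full GS cycle.  Returns an array of length ``iterations``.
    """
    obj = default_amplitude_object(size)
    stack = record_stack(obj, distances=distances, noise=noise)
    if settings is None:
        settings = ReconstructionSettings(method="gs", iterations=iterations)
    else:
        settings = replace(settings, method="gs", iterations=iterations)
    errors = np.zeros(iterations)

    def record(t, field):
        errors[t] = rms_error(field.amplitude, obj.amplitude)

    gs(stack, settings, callback=record)
    return errors


def _phase_ssim(field, obj) -> float:
    truth = obj.phase
    recon = align_piston(field.phase, truth)
    return ssim(recon, truth, dynamic_range=float(truth.max() - truth.min()))


def noise_robustness_sweep(
    stds=(0.0, 0.02, 0.05, 0.1, 0.15, 0.2),
    methods=("ghr", "gs", "ga", "iga"),
    n_seeds: int = 3,
    size: int = 256,
    iterations: int = 30,
    sigma: float = 2.0,
    distances=DEFAULT_DISTANCES,
    master_seed: int = 0,
    pad_factor: int = 2,
) -> dict:
    """Phase-SSIM vs shot-noise sweep on the default phase-text stack.

    For each Poisson noise std and each seed, a three-distance stack is
    simulated and reconstructed with every requested method; the
    reconstructed phase (piston-aligned) is compared with the ground
    truth by SSIM.  Returns ``{"stds": [...], "ssim": {method: [mean per
    std]}, "n_seeds": n}``.  GHR uses the first (shortest-distance) frame
    only.
    """
    obj = default_phase_object(size)
    table = {m: np.zeros((len(stds), n_seeds)) for m in methods}
    for i, std in enumerate(stds):
        for s in range(n_seeds):
            seed = int(np.random.SeedSequence(
                entropy=master_seed, spawn_key=(i, s)
            ).generate_state(1, dtype=np.uint32)[0]) % 2**31
            noise = NoiseSpec("poisson", std, seed) if std > 0 else NoiseSpec()
            stack = record_stack(obj, distances=distances, noise=noise)
            for m in methods:
                settings = ReconstructionSettings(
                    method=m, iterations=iterations, sigma=sigma, pad_factor=pad_factor
                )
                field = reconstruct(stack, settings)
                table[m][i, s] = _phase_ssim(field, obj)
    return {
        "stds": list(stds),
        "n_seeds": n_seeds,
        "ssim": {m: table[m].mean(axis=1).tolist() for m in methods},
    }


def averaging_noise_ratio(
    n_repeats: int = 20,
    n_frames: int = 4,
    noise_std: float = 0.2,
    size: int = 128,
    distance: float = 3e-3,
    master_seed: int = 0,
) -> float:
    """Monte-Carlo estimate of GA's background-noise averaging factor.

    ``n_frames`` holograms of the same object at the *same* distance are
    recorded with independent Poisson noise; the ratio of the object-free
    background phase std of the GA reconstruction to the single-frame
    value is averaged over ``n_repeats`` repeats.  For uncorrelated noise
    the expected ratio is ``1/sqrt(n_frames)``.

    A small, weakly absorbing centred disk keeps the corner ROI
    shot-noise dominated (an opaque object would leak enough deterministic
    twin-image ripple into the background to mask the averaging law).
    """
    grid = GridSpec(size, size, DEFAULT_PITCH)
    yy, xx = np.mgrid[0:size, 0:size]
    disk = ((yy - size / 2) ** 2 + (xx - size / 2) ** 2) < (size / 8) ** 2
    obj = make_amplitude_object(disk.astype(float), grid, 0.85, 1.0, DEFAULT_WAVELENGTH)
    roi = (2, size // 5, 2, size // 5)  # corner, away from the object
    settings = ReconstructionSettings(method="ga", iterations=1)
    from .simulate import frame_seed, record_hologram

    ratios = []
    for r in range(n_repeats):
        seed = int(np.random.SeedSequence(
            entropy=master_seed, spawn_key=(r,)
        ).generate_state(1, dtype=np.uint32)[0]) % 2**31
        frames = [
            record_hologram(
                obj, distance, noise=NoiseSpec("poisson", noise_std, frame_seed(seed, k))
            )
            for k in range(n_frames)
        ]
        single = ga(frames[:1], settings)
        multi = ga(frames, settings)
        std_single = background_std(single.phase, roi)
        std_multi = background_std(multi.phase, roi)
        ratios.append(std_multi / std_single)
    return float(np.mean(ratios))


def timing_comparison(
    size: int = 1000,
    iterations: int = 10,
    sigma: float = 2.0,
    distances=DEFAULT_DISTANCES,
    pad_factor: int = 1,
) -> dict:
    """Wall-clock time of GS, GA and IGA on one noise-free stack.

    All methods run with identical settings; only the relative cost is
    meaningful (IGA should cost little more than GS + GA combined).
    """
    obj = default_phase_object(size)
    stack = record_stack(obj, distances=distances)
    out = {}
    for m in ("gs", "ga", "iga"):
        settings = ReconstructionSettings(
            method=m, iterations=iterations, sigma=sigma, pad_factor=pad_factor
        )
        t0 = time.perf_counter()
        reconstruct(stack, settings)
        out[m] = time.perf_counter() - t0
    out["iga_over_gs_plus_ga"] = out["iga"] / (out["gs"] + out["ga"])
    return out
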