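"""Quantitative evaluation of holograms and reconstructions.

Hologram statistics: mean intensity M (brightness), std ΔM (contrast),
and SNR defined as the noise-free contrast over the shot-noise std.
Reconstruction quality: RMS error (piston-invariant for phase maps, since
in-line holography cannot fix the global phase offset), the standard SSIM
(11x11 Gaussian window, sigma 1.5, K1=0.01, K2=0.03), and the std of an
object-free background region S.  Phase <-> physical thickness conversion
uses ``t = phi * lambda / (2*pi*(n_sample - n_medium))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .simulate import Hologram

__all__ = [
    "HologramStats",
    "hologram_stats",
    "rms_error",
    "align_piston",
    "ssim",
    "background_std",
    "thickness_from_phase",
    "phase_from_thickness",
]


@dataclass(frozen=True)
class HologramStats:
    """Mean intensity M, contrast ΔM (both in the hologram's units, a.u.
    or camera gray levels), and — when a noise-free reference is given —
    the SNR ΔM(reference)/std(noise)."""

    M: float
    delta_M: float
    snr: float | None = None


def _intensity(h) -> np.ndarray:
    return h.intensity if isinstance(h, Hologram) else np.asarray(h, dtype=np.float64)


def hologram_stats(h, noise_free_reference=None) -> HologramStats:
    """Compute M, ΔM and (given a noise-free reference) the SNR
    ``ΔM(reference) / std(I - reference)``."""
    i = _intensity(h)
    snr = None
    if noise_free_reference is not None:
        ref = _intensity(noise_free_reference)
        if ref.shape != i.shape:
            raise ValueError("reference shape does not match hologram")
        noise_std = float(np.std(i - ref))
        ref_dm = float(np.std(ref))
        snr = ref_dm / noise_std if noise_std > 0 else float("inf")
    return HologramStats(M=float(np.mean(i)), delta_M=float(np.std(i)), snr=snr)


def rms_error(
    recon: np.ndarray,
    truth: np.ndarray,
    mask: np.ndarray | None = None,
    *,
    remove_piston: bool = False,
) -> float:
    """Root-mean-square deviation over ``mask`` (default: everywhere).

    With ``remove_piston=True`` the masked mean difference is subtracted
    first — the right comparison for phase maps, whose global offset is
    unobservable in-line.
    """
    recon = np.asarray(recon, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if recon.shape != truth.shape:
        raise ValueError("shape mismatch")
    diff = recon - truth
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != diff.shape:
            raise ValueError("mask shape mismatch")
        if not mask.any():
            raise ValueError("empty mask")
        diff = diff[mask]
    if remove_piston:
        diff = diff - diff.mean()
    return float(np.sqrt(np.mean(diff**2)))


def align_piston(recon: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Shift ``recon`` by a constant so its mean matches ``truth``'s."""
    recon = np.asarray(recon, dtype=np.float64)
    return recon - recon.mean() + np.asarray(truth).mean()


def ssim(
    recon: np.ndarray,
    truth: np.ndarray,
    dynamic_range: float | None = None,
) -> float:
    """Mean structural similarity with the canonical parameters:
    11x11 Gaussian window of std 1.5, K1=0.01, K2=0.03.

    ``dynamic_range`` defaults to ``max(truth) - min(truth)`` (the
    ground-truth image in simulation, the reference reconstruction in
    experiment).
    """
    recon = np.asarray(recon, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if recon.shape != truth.shape:
        raise ValueError("shape mismatch")
    if dynamic_range is None:
        dynamic_range = float(truth.max() - truth.min())
    if dynamic_range <= 0:
        raise ValueError("dynamic range must be positive")
    return float(
        structural_similarity(
            truth,
            recon,
            win_size=11,
            gaussian_weights=True,
            sigma=1.5,
            K1=0.01,
            K2=0.03,
            use_sample_covariance=False,
            data_range=dynamic_range,
        )
    )


def background_std(phase: np.ndarray, roi: tuple[int, int, int, int]) -> float:
    """Std of ``phase`` over an object-free rectangle S.

    ``roi = (row0, row1, col0, col1)``, 0-based half-open pixel
    coordinates.
    """
    phase = np.asarray(phase, dtype=np.float64)
    r0, r1, c0, c1 = roi
    if not (0 <= r0 < r1 <= phase.shape[0] and 0 <= c0 < c1 <= phase.shape[1]):
        raise ValueError(f"roi {roi} out of bounds for shape {phase.shape}")
    return float(np.std(phase[r0:r1, c0:c1]))


def thickness_from_phase(
    phase, wavelength: float, n_sample: float, n_medium: float = 1.0
):
    """Physical thickness from measured phase:
    ``t = phi * lambda / (2*pi*(n_sample - n_medium))`` (meters)."""
    if n_sample == n_medium:
        raise ValueError("refractive indices must differ")
    t = np.asarray(phase, dtype=np.float64) * wavelength / (
        2.0 * np.pi * (n_sample - n_medium)
    )
    return t.item() if t.ndim == 0 else t


def phase_from_thickness(
    thickness, wavelength: float, n_sample: float, n_medium: float = 1.0
):
    """Inverse of :func:`thickness_from_phase` (radians)."""
    if n_sample == n_medium:
        raise ValueError("refractive indices must differ")
    phi = np.asarray(thickness, dtype=np.float64) * 2.0 * np.pi * (
        n_sample - n_medium
    ) / wavelength
    return phi.item() if phi.ndim == 0 else phi
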