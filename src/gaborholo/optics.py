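"""Scalar free-space propagation by the angular spectrum method.

This is the physical engine of the package: every hologram simulation and
every reconstruction algorithm moves complex optical fields between planes
with :func:`propagate`.  The transfer function is the exact scalar
free-space kernel

    H(fx, fy; z) = exp(i 2*pi*z*sqrt(1/lambda^2 - fx^2 - fy^2))

on the propagating band ``fx^2 + fy^2 <= 1/lambda^2`` and zero outside it
(hard evanescent cutoff; at millimetre distances evanescent waves are
numerically zero anyway, and the hard cutoff keeps ``|H|`` in {0, 1}).

Sign convention: positive ``distance`` propagates away from the source
(object towards camera); reconstruction "backpropagation" is the same
operator called with a negative distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GridSpec",
    "ComplexField",
    "angular_spectrum_transfer",
    "propagate",
    "propagate_direct",
    "field_from_amplitude",
]


@dataclass(frozen=True)
class GridSpec:
    """Uniform 2-D sampling grid.

    Parameters
    ----------
    rows, cols:
        Number of samples along each axis (row-major images, origin
        at the top-left corner).
    pitch:
        Physical sampling interval in meters (the camera pixel pitch, or
        the effective pitch after absorbing any optical magnification).
    """

    rows: int
    cols: int
    pitch: float

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise ValueError(f"grid must be at least 2x2, got {self.rows}x{self.cols}")
        if not (self.pitch > 0 and math.isfinite(self.pitch)):
            raise ValueError(f"pitch must be a positive finite length, got {self.pitch}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    def frequencies(self) -> tuple[np.ndarray, np.ndarray]:
        """Spatial-frequency grids (fy, fx) in cycles/meter, DFT layout.

        Zero frequency sits at the first element; the spacing along each
        axis is ``1/(N*pitch)``.
        """
        fy = np.fft.fftfreq(self.rows, d=self.pitch)
        fx = np.fft.fftfreq(self.cols, d=self.pitch)
        return fy[:, None], fx[None, :]


@dataclass
class ComplexField:
    """A 2-D complex optical field sampled on a :class:`GridSpec`.

    ``plane_tag`` is a free-text label of the axial plane the field lives
    in (e.g. ``"object"`` or ``"z=+3.0mm"``); it is carried along purely
    for provenance.
    """

    values: np.ndarray
    grid: GridSpec
    wavelength: float
    plane_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"field shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")
        if not (self.wavelength > 0 and math.isfinite(self.wavelength)):
            raise ValueError(f"wavelength must be positive, got {self.wavelength}")

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.values)

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.values) ** 2


def angular_spectrum_transfer(
    grid: GridSpec, wavelength: float, distance: float
) -> np.ndarray:
    """Angular-spectrum transfer function on the DFT frequency grid.

    Returns a complex array of shape ``grid.shape`` whose propagating-band
    entries have unit modulus and phase ``2*pi*distance*sqrt(1/lambda^2 - f^2)``;
    entries beyond the evanescent cutoff are exactly zero.
    """
    if not (wavelength > 0 and math.isfinite(wavelength)):
        raise ValueError(f"wavelength must be positive, got {wavelength}")
    if not math.isfinite(distance):
        raise ValueError(f"distance must be finite, got {distance}")
    fy, fx = grid.frequencies()
    f2 = fx * fx + fy * fy
    inv_lam2 = 1.0 / wavelength**2
    band = f2 <= inv_lam2
    kz = 2.0 * np.pi * np.sqrt(np.maximum(inv_lam2 - f2, 0.0))
    h = np.zeros(grid.shape, dtype=np.complex128)
    h[band] = np.exp(1j * distance * kz[band])
    return h


def _pad_embed(values: np.ndarray, pad_factor: int) -> tuple[np.ndarray, tuple[slice, slice]]:
    """Zero-pad ``values`` into the centre of a ``pad_factor`` larger array."""
    r, c = values.shape
    big = np.zeros((pad_factor * r, pad_factor * c), dtype=np.complex128)
    r0 = (big.shape[0] - r) // 2
    c0 = (big.shape[1] - c) // 2
    window = (slice(r0, r0 + r), slice(c0, c0 + c))
    big[window] = values
    return big, window


def propagate(
    field: ComplexField,
    distance: float,
    pad_factor: int = 2,
    background: str = "mean",
) -> ComplexField:
    """Propagate a field by ``distance`` meters (negative = backpropagate).

    With ``pad_factor=2`` the field is zero-padded to twice its extent
    before the FFT to suppress periodic wrap-around, and cropped back
    afterwards; ``pad_factor=1`` skips the padding (faster, acceptable in
    iterative inner loops where border wrap-around is tolerable).

    ``background`` states how the field continues beyond the frame:

    ``"mean"`` (default)
        The field's mean — the unscattered plane-wave background of an
        in-line hologram — extends beyond the window.  It is split off,
        propagated analytically with phase ``2*pi*z/lambda``, and added
        back; only the scattered remainder is zero-padded.  Zero-padding
        the full field would instead turn the frame edge into a hard
        aperture and flood the result with spurious edge diffraction.
    ``"dark"``
        The field is a compact source on a dark background (an aperture);
        plain zero-padding is the correct continuation.

    The operator is unitary on the propagating band: energy
    ``sum(|U|^2)`` is conserved whenever the padded window contains the
    diffracted field.
    """
    if pad_factor not in (1, 2):
        raise ValueError(f"pad_factor must be 1 or 2, got {pad_factor}")
    if not math.isfinite(distance):
        raise ValueError(f"distance must be finite, got {distance}")
    if distance == 0.0:
        return replace(field, values=field.values.copy())
    if background not in ("mean", "dark"):
        raise ValueError("background must be 'mean' or 'dark'")
    if pad_factor == 1:
        work = field.values
        work_grid = field.grid
        window = (slice(None), slice(None))
        dc = 0.0 + 0.0j
    else:
        dc = complex(np.mean(field.values)) if background == "mean" else 0.0 + 0.0j
        work, window = _pad_embed(field.values - dc, pad_factor)
        work_grid = GridSpec(
            pad_factor * field.grid.rows, pad_factor * field.grid.cols, field.grid.pitch
        )
    h = angular_spectrum_transfer(work_grid, field.wavelength, distance)
    if not np.any(h):
        raise ValueError("no propagating frequencies for this wavelength/pitch combination")
    out = np.fft.ifft2(np.fft.fft2(work) * h)[window]
    if dc != 0:
        out = out + dc * np.exp(2j * np.pi * distance / field.wavelength)
    sign = "+" if distance > 0 else "-"
    tag = f"{field.plane_tag}{sign}{abs(distance) * 1e3:g}mm" if field.plane_tag else (
        f"z{sign}{abs(distance) * 1e3:g}mm"
    )
    return ComplexField(out, field.grid, field.wavelength, plane_tag=tag)


def propagate_direct(
    field: ComplexField,
    distance: float,
    oversample: int = 1,
    source_support: float | None = None,
) -> ComplexField:
    """Reference propagator: direct Rayleigh--Sommerfeld summation.

    Evaluates the first Rayleigh--Sommerfeld diffraction integral

        U(P) = sum_Q U0(Q) * h(P - Q) * dA,
        h(x, y; z) = z * (1 - i*k*r) * exp(i*k*r) / (2*pi*r^3),

    by brute-force summation over source samples (quadratic cost).  This
    is a validation tool, deliberately independent of the FFT path: it is
    orders of magnitude slower and only practical on small grids.

    Parameters
    ----------
    oversample:
        Integer refinement of the source grid.  The source field is
        resampled by zero-padded Fourier interpolation, which is exact for
        band-limited fields and keeps the discrete sum an accurate
        quadrature of the oscillatory kernel.
    source_support:
        Optional radius in meters around the grid centre outside which the
        source is treated as zero (skips negligible samples).
    """
    if distance <= 0:
        raise ValueError("direct summation requires a positive distance")
    g = field.grid
    u0 = field.values
    step = g.pitch
    if oversample > 1:
        # exact band-limited (Fourier) interpolation onto the finer grid
        spec = np.fft.fftshift(np.fft.fft2(u0))
        big = np.zeros((g.rows * oversample, g.cols * oversample), dtype=np.complex128)
        r0 = (big.shape[0] - g.rows) // 2
        c0 = (big.shape[1] - g.cols) // 2
        big[r0 : r0 + g.rows, c0 : c0 + g.cols] = spec
        u0 = np.fft.ifft2(np.fft.ifftshift(big)) * oversample**2
        step = g.pitch / oversample
    sr, sc = u0.shape
    ys = (np.arange(sr) - sr / 2.0) * step
    xs = (np.arange(sc) - sc / 2.0) * step
    yt = (np.arange(g.rows) - g.rows / 2.0) * g.pitch
    xt = (np.arange(g.cols) - g.cols / 2.0) * g.pitch
    if source_support is not None:
        mask = (ys[:, None] ** 2 + xs[None, :] ** 2) <= source_support**2
    else:
        mask = np.abs(u0) > 0
    sy, sx = np.nonzero(mask)
    src_vals = u0[sy, sx] * step * step
    src_y = ys[sy]
    src_x = xs[sx]
    k = 2.0 * np.pi / field.wavelength
    out = np.zeros((g.rows, g.cols), dtype=np.complex128)
    # loop over output rows to bound memory: (cols x n_src) kernel blocks
    for i, y in enumerate(yt):
        dy2 = (y - src_y) ** 2
        dx = xt[:, None] - src_x[None, :]
        r = np.sqrt(dx * dx + dy2[None, :] + distance * distance)
        kern = distance * (1.0 - 1j * k * r) * np.exp(1j * k * r) / (2.0 * np.pi * r**3)
        out[i] = kern @ src_vals
    return ComplexField(out, g, field.wavelength, plane_tag="direct")


def field_from_amplitude(
    amplitude: np.ndarray, grid: GridSpec, wavelength: float
) -> ComplexField:
    """Lift a measured (nonnegative) amplitude to a zero-phase complex field."""
    amplitude = np.asarray(amplitude, dtype=np.float64)
    if not np.all(np.isfinite(amplitude)):
        raise ValueError("amplitude must be finite")
    if np.any(amplitude < 0):
        raise ValueError("amplitude must be nonnegative")
    return ComplexField(amplitude.astype(np.complex128), grid, wavelength)
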