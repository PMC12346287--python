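"""Off-axis hologram demodulation, reference estimation and phase unwrapping.

An off-axis hologram encodes a complex signal field ``E`` as the intensity
``I = |E + R|^2`` with a tilted plane-wave reference
``R = exp(-i 2 pi f_ref . r)``.  The cross term ``E conj(R)`` then occupies a
Fourier sideband centered at ``+f_ref``; demodulation extracts that sideband
with a raised-cosine disc window and shifts it to baseband, recovering ``E``
relative to a unit reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import fft as sfft

from .forward_models import ComplexField

logger = logging.getLogger(__name__)

__all__ = [
    "Hologram",
    "SidebandOverlapError",
    "synthesize_hologram",
    "demodulate_hologram",
    "estimate_reference",
    "unwrap_phase_weighted",
    "fourier_downsample",
]


def fourier_downsample(field: ComplexField, shape: tuple[int, int]) -> ComplexField:
    """Resample a band-limited field onto a coarser grid of the same extent
    by cropping its Fourier spectrum (exact for signals within the target
    Nyquist band, e.g. camera pixels finer than the reconstruction grid)."""
    ny, nx = field.shape
    my, mx = shape
    if my > ny or mx > nx:
        raise ValueError("fourier_downsample cannot upsample")
    F = sfft.fft2(field.values)
    Fc = np.zeros(shape, dtype=complex)
    Fc[: my // 2, : mx // 2] = F[: my // 2, : mx // 2]
    Fc[: my // 2, -(mx // 2):] = F[: my // 2, -(mx // 2):]
    Fc[-(my // 2):, : mx // 2] = F[-(my // 2):, : mx // 2]
    Fc[-(my // 2):, -(mx // 2):] = F[-(my // 2):, -(mx // 2):]
    vals = sfft.ifft2(Fc) * (my * mx) / (ny * nx)
    return ComplexField(
        values=vals,
        pixel_pitch=field.pixel_pitch * ny / my,
        wavelength=field.wavelength,
        background_index=field.background_index,
        z_position=field.z_position,
    )


class SidebandOverlapError(ValueError):
    """The holographic sideband overlaps the DC/autocorrelation band."""


@dataclass
class Hologram:
    """A real off-axis intensity image plus its acquisition metadata."""

    intensity: np.ndarray
    reference_frequency: Sequence[float]  # (y, x) cycles/um
    pixel_pitch: float
    wavelength: float
    background_index: float

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("hologram intensity must be 2D")
        if np.any(self.intensity < 0):
            raise ValueError("hologram intensity must be non-negative")
        self.reference_frequency = np.asarray(self.reference_frequency, dtype=float)


def synthesize_hologram(field: ComplexField, reference_frequency) -> Hologram:
    """Form ``|E + exp(-i 2 pi f_ref . r)|^2`` on the field's grid."""
    fref = np.asarray(reference_frequency, dtype=float)
    ny, nx = field.shape
    y = np.arange(ny)[:, None] * field.pixel_pitch
    x = np.arange(nx)[None, :] * field.pixel_pitch
    ref = np.exp(-1j * 2 * np.pi * (fref[0] * y + fref[1] * x))
    intensity = np.abs(field.values + ref) ** 2
    return Hologram(
        intensity=intensity,
        reference_frequency=fref,
        pixel_pitch=field.pixel_pitch,
        wavelength=field.wavelength,
        background_index=field.background_index,
    )


def _raised_cosine_disc(fy, fx, center, radius, edge_frac=0.1):
    """Disc window, 1 inside, rolling off over ``edge_frac * radius``."""
    d = np.sqrt((fy - center[0]) ** 2 + (fx - center[1]) ** 2)
    w = max(edge_frac * radius, 1e-12)
    inner = radius - w
    win = np.clip((radius - d) / w, 0.0, 1.0)
    win = 0.5 - 0.5 * np.cos(np.pi * win)
    win[d <= inner] = 1.0
    return win


def demodulate_hologram(holo: Hologram, band_radius: float) -> ComplexField:
    """Extract the complex signal field from an off-axis hologram.

    ``band_radius`` (cycles/um) is the signal band half-width; it must be
    smaller than ``|f_ref|`` for the sideband to separate from DC.
    """
    fref = holo.reference_frequency
    fref_mag = float(np.linalg.norm(fref))
    if band_radius >= fref_mag:
        overlap = min(1.0, (band_radius - fref_mag) / max(band_radius, 1e-12) + 1.0)
        raise SidebandOverlapError(
            f"band radius {band_radius:.4g}/um >= reference frequency "
            f"{fref_mag:.4g}/um; sideband/DC overlap fraction ~ {overlap:.2f}"
        )
    ny, nx = holo.intensity.shape
    y = np.arange(ny)[:, None] * holo.pixel_pitch
    x = np.arange(nx)[None, :] * holo.pixel_pitch
    # shift the +f_ref sideband to baseband, then low-pass
    s = holo.intensity * np.exp(-1j * 2 * np.pi * (fref[0] * y + fref[1] * x))
    fy = sfft.fftfreq(ny, d=holo.pixel_pitch)[:, None]
    fx = sfft.fftfreq(nx, d=holo.pixel_pitch)[None, :]
    win = _raised_cosine_disc(fy, fx, (0.0, 0.0), band_radius)
    vals = sfft.ifft2(sfft.fft2(s) * win)
    return ComplexField(
        values=vals,
        pixel_pitch=holo.pixel_pitch,
        wavelength=holo.wavelength,
        background_index=holo.background_index,
    )


def estimate_reference(fields: Sequence[ComplexField]) -> ComplexField:
    """Time-average complex field, used as the incident-field estimate.

    For dynamic dilute samples the refractive-index inhomogeneities average
    out over time, leaving the illumination field.  The residual temporal
    variance is logged as a sparsity diagnostic: a variance near zero means
    the 'background' still contains a static sample.
    """
    if len(fields) == 0:
        raise ValueError("need at least one field")
    if len(fields) == 1:
        logger.warning("estimate_reference called with a single frame; returning it")
        return fields[0]
    stack = np.stack([f.values for f in fields])
    mean = stack.mean(axis=0)
    resid = np.mean(np.abs(stack - mean) ** 2)
    scale = np.mean(np.abs(mean) ** 2)
    rel = resid / max(scale, 1e-30)
    logger.info("estimate_reference: relative temporal variance %.3e", rel)
    if rel < 1e-6:
        logger.warning(
            "estimate_reference: temporal variance ~ 0; background may contain sample"
        )
    return fields[0].with_values(mean)


# ---------------------------------------------------------------------------
# weighted least-squares phase unwrapping
# ---------------------------------------------------------------------------

def _wrap(a):
    return (a + np.pi) % (2 * np.pi) - np.pi


def _dct_poisson_solve(rho: np.ndarray) -> np.ndarray:
    """Solve the discrete Neumann Poisson equation ``L phi = rho`` by DCT-II."""
    ny, nx = rho.shape
    r = sfft.dctn(rho, type=2, norm="ortho")
    iy = np.arange(ny)[:, None]
    ix = np.arange(nx)[None, :]
    denom = 2 * np.cos(np.pi * iy / ny) + 2 * np.cos(np.pi * ix / nx) - 4.0
    denom[0, 0] = 1.0
    r = r / denom
    r[0, 0] = 0.0
    return sfft.idctn(r, type=2, norm="ortho")


def _weighted_laplacian(phi, wy, wx):
    """Apply ``div(W grad phi)`` with Neumann boundaries; ``wy``/``wx`` are
    edge weights of shape (ny-1, nx) and (ny, nx-1)."""
    out = np.zeros_like(phi)
    dy = wy * (phi[1:, :] - phi[:-1, :])
    dx = wx * (phi[:, 1:] - phi[:, :-1])
    out[:-1, :] += dy
    out[1:, :] -= dy
    out[:, :-1] += dx
    out[:, 1:] -= dx
    return out


def unwrap_phase_weighted(
    phase: np.ndarray,
    weights: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> np.ndarray:
    """Weighted least-squares phase unwrapping (DCT-preconditioned CG).

    Minimizes the weighted misfit between the unwrapped gradients and the
    wrapped phase differences, then snaps the solution back onto the input
    modulo 2 pi so the output differs from the input by integer multiples of
    2 pi at every pixel.  Zero-weight pixels do not influence the solution.
    """
    psi = np.asarray(phase, dtype=float)
    if weights is None:
        weights = np.ones_like(psi)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    wmax = w.max()
    if wmax == 0:
        raise ValueError("weights are all zero")
    w = (w / wmax) ** 2
    wy = np.minimum(w[1:, :], w[:-1, :])
    wx = np.minimum(w[:, 1:], w[:, :-1])

    gy = _wrap(psi[1:, :] - psi[:-1, :])
    gx = _wrap(psi[:, 1:] - psi[:, :-1])
    rhs = np.zeros_like(psi)
    rhs[:-1, :] += wy * gy
    rhs[1:, :] -= wy * gy
    rhs[:, :-1] += wx * gx
    rhs[:, 1:] -= wx * gx

    phi = np.zeros_like(psi)
    r = rhs - _weighted_laplacian(phi, wy, wx)
    norm0 = np.linalg.norm(rhs)
    if norm0 == 0:
        phi = psi.copy()
    else:
        z = _dct_poisson_solve(r)
        p = z.copy()
        rz = float(np.sum(r * z))
        for _ in range(max_iter):
            Ap = _weighted_laplacian(p, wy, wx)
            pAp = float(np.sum(p * Ap))
            if abs(pAp) < 1e-300:
                break
            alpha = rz / pAp
            phi += alpha * p
            r -= alpha * Ap
            if np.linalg.norm(r) <= tol * norm0:
                break
            z = _dct_poisson_solve(r)
            rz_new = float(np.sum(r * z))
            p = z + (rz_new / rz) * p
            rz = rz_new
    # offset-free congruence: snap the least-squares surface back onto the
    # input modulo 2 pi.  The global offset is removed with a weighted
    # *circular* mean of the fractional residuals so rounding never sits on
    # a half-integer tie; smooth in-range inputs come back unchanged.
    r = (phi - psi) / (2 * np.pi)
    frac_mean = np.angle(np.sum(w * np.exp(2j * np.pi * r))) / (2 * np.pi)
    k = np.round(r - frac_mean)
    return psi + 2 * np.pi * k
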