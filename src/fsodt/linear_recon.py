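"""Weak-scattering (Born/Rytov) tomographic reconstruction and the
low-resolution Rytov demultiplexing initializer.

Each plane-wave view relates the 2D Fourier transform of the (Rytov or
Born) scattered data to a spherical cap of the Ewald sphere in the 3D
Fourier transform of the scattering potential ``V = k0^2 (n^2 - n0^2)``:
a 2D frequency ``f`` of the field measured in the plane through the object
center deposits

    V_hat(f - f_inc, fz(f) - fz(f_inc)) = -4 pi i fz(f) * U_hat(f)

with ``fz(f) = sqrt((n0/lam)^2 - |f|^2)`` (cycles/um) and
``U = E0_canonical * psi`` the Rytov data referenced to a unit plane wave
whose phase vanishes at the volume center.

For multiplexed holograms, the Fourier plane is partitioned into Voronoi
regions (capped by discs) around each beam's carrier; each region is a
low-resolution single-beam field that is unwrapped, converted to a Rytov
phase and gridded as above.  Multiplexing of 1 reduces exactly to classical
Rytov ODT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import fft as sfft

from .dmd_patterns import PlaneWaveSpec
from .forward_models import ComplexField, RIVolume, plane_wave_field
from .holography import unwrap_phase_weighted

logger = logging.getLogger(__name__)

__all__ = [
    "ScatteringPotential",
    "RytovField",
    "rytov_field",
    "grid_ewald_cap",
    "demultiplex_rytov_initialize",
    "potential_to_ri",
    "ri_to_potential",
]


@dataclass
class ScatteringPotential:
    """Fourier-domain scattering potential accumulated over Ewald caps.

    ``values``/``fill_count`` are fft-ordered 3D grids (z, y, x); deposits
    are summed and later divided by the multiplicity.
    """

    values: np.ndarray
    fill_count: np.ndarray
    voxel_xy: float
    voxel_z: float
    wavelength: float
    background_index: float

    @classmethod
    def empty(cls, shape, voxel_xy, voxel_z, wavelength, background_index):
        return cls(
            values=np.zeros(shape, dtype=complex),
            fill_count=np.zeros(shape, dtype=float),
            voxel_xy=voxel_xy,
            voxel_z=voxel_z,
            wavelength=wavelength,
            background_index=background_index,
        )

    @property
    def freq_spacing(self) -> tuple[float, float, float]:
        nz, ny, nx = self.values.shape
        return (1 / (nz * self.voxel_z), 1 / (ny * self.voxel_xy), 1 / (nx * self.voxel_xy))

    def averaged(self) -> np.ndarray:
        out = np.zeros_like(self.values)
        filled = self.fill_count > 0
        out[filled] = self.values[filled] / self.fill_count[filled]
        return out

    def to_volume(self, constrain: bool = True) -> RIVolume:
        """Inverse FT to real space and convert potential to refractive index."""
        dV = self.voxel_z * self.voxel_xy**2
        V = sfft.fftshift(sfft.ifftn(self.averaged())) / dV
        return potential_to_ri(
            V, self.background_index, self.wavelength, self.voxel_xy, self.voxel_z,
            constrain=constrain,
        )


@dataclass
class RytovField:
    """Complex Rytov phase ``psi = ln|E/E0| + i unwrap(arg(E/E0))`` of one view."""

    psi: np.ndarray
    beam: PlaneWaveSpec
    pixel_pitch: float
    wavelength: float
    background_index: float


def rytov_field(total: ComplexField, incident: ComplexField, beam: PlaneWaveSpec) -> RytovField:
    """Compute the Rytov phase of a measured view against its incident field.

    The wrapped phase of ``E/E0`` is unwrapped with weights proportional to
    the squared field amplitude; pixels where ``|E0|`` collapses below
    1e-6 of its maximum are masked (weight zero).
    """
    e0 = incident.values
    mask = np.abs(e0) < 1e-6 * np.abs(e0).max()
    ratio = total.values / np.where(mask, 1.0, e0)
    logmag = np.log(np.maximum(np.abs(ratio), 1e-30))
    weights = np.abs(total.values) ** 2
    weights[mask] = 0.0
    phase = unwrap_phase_weighted(np.angle(ratio), weights)
    return RytovField(
        psi=logmag + 1j * phase,
        beam=beam,
        pixel_pitch=total.pixel_pitch,
        wavelength=total.wavelength,
        background_index=total.background_index,
    )


def _fz(fy, fx, n0, lam):
    arg = (n0 / lam) ** 2 - fy**2 - fx**2
    return np.sqrt(np.maximum(arg, 0.0))


def grid_ewald_cap(
    rf: RytovField,
    pot: ScatteringPotential,
    region_radius: float | None = None,
    detection_na: float | None = None,
) -> ScatteringPotential:
    """Deposit one view's Rytov data onto its Ewald-sphere cap (in place).

    ``region_radius`` restricts the 2D frequencies used to a disc of that
    radius about the beam carrier (demultiplexing); ``detection_na`` caps
    the band at the detection pupil.  Components beyond the propagating
    band ``|f| > n0/lam`` are dropped and counted in the log.
    """
    lam, n0 = rf.wavelength, rf.background_index
    ny, nx = rf.psi.shape
    p = rf.pixel_pitch
    y = (np.arange(ny) - ny // 2)[:, None] * p
    x = (np.arange(nx) - nx // 2)[None, :] * p
    f_inc = rf.beam.object_frequency
    # canonical unit incident wave, zero phase at the volume center
    e0 = np.exp(1j * 2 * np.pi * (f_inc[0] * y + f_inc[1] * x))
    U = e0 * rf.psi
    Uhat = sfft.fft2(sfft.ifftshift(U)) * p**2

    fy = sfft.fftfreq(ny, d=p)[:, None]
    fx = sfft.fftfreq(nx, d=p)[None, :]
    fsq = fy**2 + fx**2
    keep = fsq <= (n0 / lam) ** 2 * (1 - 1e-12)
    n_evan = int(np.sum(~keep))
    if n_evan:
        logger.debug("grid_ewald_cap: dropped %d evanescent components", n_evan)
    if detection_na is not None:
        keep &= fsq <= (detection_na / lam) ** 2
    if region_radius is not None:
        keep &= (fy - f_inc[0]) ** 2 + (fx - f_inc[1]) ** 2 <= region_radius**2

    fzv = _fz(fy, fx, n0, lam)
    fz_inc = float(_fz(f_inc[0], f_inc[1], n0, lam))
    gz = fzv - fz_inc
    gy = np.broadcast_to(fy - f_inc[0], keep.shape)
    gx = np.broadcast_to(fx - f_inc[1], keep.shape)
    gz = np.broadcast_to(gz, keep.shape)

    nz3, ny3, nx3 = pot.values.shape
    dgz, dgy, dgx = pot.freq_spacing
    iz = np.round(gz[keep] / dgz).astype(int)
    iy = np.round(gy[keep] / dgy).astype(int)
    ix = np.round(gx[keep] / dgx).astype(int)
    inb = (
        (np.abs(iz) <= nz3 // 2 - 1)
        & (np.abs(iy) <= ny3 // 2 - 1)
        & (np.abs(ix) <= nx3 // 2 - 1)
    )
    vals = (-4j * np.pi * fzv[keep] * Uhat[keep])[inb]
    iz, iy, ix = iz[inb] % nz3, iy[inb] % ny3, ix[inb] % nx3
    np.add.at(pot.values, (iz, iy, ix), vals)
    np.add.at(pot.fill_count, (iz, iy, ix), 1.0)
    return pot


def potential_to_ri(
    V: np.ndarray,
    n0: float,
    wavelength: float,
    voxel_xy: float,
    voxel_z: float,
    constrain: bool = False,
) -> RIVolume:
    """Convert a scattering potential to refractive index, n = sqrt(n0^2 + V/k0^2)."""
    k0 = 2 * np.pi / wavelength
    n = np.sqrt((n0**2 + V / k0**2).astype(complex))
    n = np.where(n.real >= 0, n, -n)  # principal branch, Re >= 0
    if constrain:
        n = np.maximum(n.real, n0) + 1j * np.maximum(n.imag, 0.0)
    return RIVolume(n, voxel_xy=voxel_xy, voxel_z=voxel_z, background_index=n0)


def ri_to_potential(volume: RIVolume, wavelength: float) -> np.ndarray:
    """Inverse of :func:`potential_to_ri`: V = k0^2 (n^2 - n0^2)."""
    k0 = 2 * np.pi / wavelength
    return k0**2 * (volume.index**2 - volume.background_index**2)


def demultiplex_rytov_initialize(
    fields: Sequence[ComplexField],
    beams_per_frame: Sequence[Sequence[PlaneWaveSpec]],
    shape: tuple[int, int, int],
    voxel_z: float,
    detection_na: float | None = None,
    use_born: bool = False,
    constrain: bool = True,
) -> RIVolume:
    """Low-resolution Rytov-demultiplexed initial RI estimate.

    ``fields`` are demodulated complex fields (one per frame, relative to a
    unit reference) sampled in the plane through the volume center.  For
    each beam, the Fourier-plane Voronoi region around its carrier -- capped
    by a disc of radius ``min(half minimum inter-carrier distance,
    detection band)`` -- is extracted as a low-resolution single-beam field,
    converted to a Rytov (or Born) datum and gridded onto its Ewald cap.
    Cap contributions are averaged by multiplicity; unfilled voxels
    (missing cone) stay at the background.
    """
    if len(fields) != len(beams_per_frame):
        raise ValueError("fields and beams_per_frame length mismatch")
    f0 = fields[0]
    ny, nx = f0.shape
    lam, n0, p = f0.wavelength, f0.background_index, f0.pixel_pitch
    fb = (detection_na / lam) if detection_na is not None else n0 / lam
    dg = 1.0 / (max(ny, nx) * p)

    pot = ScatteringPotential.empty(shape, p, voxel_z, lam, n0)
    fy = sfft.fftfreq(ny, d=p)[:, None]
    fx = sfft.fftfreq(nx, d=p)[None, :]

    for field, beams in zip(fields, beams_per_frame):
        carriers = np.array([b.object_frequency for b in beams])
        m = len(beams)
        if m > 1:
            d = np.linalg.norm(carriers[:, None, :] - carriers[None, :, :], axis=-1)
            iu = np.triu_indices(m, k=1)
            dmin = d[iu].min()
            if dmin < 2 * dg:
                raise ValueError(
                    f"degenerate partition: beams separated by {dmin:.4g}/um "
                    f"< two frequency bins ({2 * dg:.4g}/um)"
                )
            radius = min(dmin / 2.0, fb)
        else:
            radius = fb
        Fhat = sfft.fft2(field.values)
        # squared distance of every Fourier pixel to every carrier
        d2 = np.stack(
            [(fy - c[0]) ** 2 + (fx - c[1]) ** 2 for c in carriers], axis=0
        )
        nearest = np.argmin(d2, axis=0)
        for i, beam in enumerate(beams):
            if m == 1:
                # single beam: the region is the whole band -- identical to
                # classical (non-multiplexed) Rytov reconstruction
                Ei = field.values
                region = None
            else:
                mask = (nearest == i) & (d2[i] <= radius**2)
                Ei = sfft.ifft2(Fhat * mask)
                region = radius
            e0 = plane_wave_field(beam, (ny, nx), p, lam, n0).values
            ratio = Ei / e0
            if use_born:
                h = ratio - 1.0
                phase = None
            else:
                logmag = np.log(np.maximum(np.abs(ratio), 1e-30))
                w = np.abs(Ei) ** 2
                phase = unwrap_phase_weighted(np.angle(ratio), w)
                h = logmag + 1j * phase
            rf = RytovField(
                psi=h, beam=beam, pixel_pitch=p, wavelength=lam, background_index=n0
            )
            grid_ewald_cap(rf, pot, region_radius=region, detection_na=detection_na)
    return pot.to_volume(constrain=constrain)
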