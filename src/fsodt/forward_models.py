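"""Coherent scalar field propagation through refractive-index volumes.

Three forward models are provided:

* :func:`angular_spectrum_propagate` -- homogeneous-medium transfer, the
  kernel shared by the multislice models;
* :func:`bpm_propagate` -- paraxial beam propagation (phase screens between
  free-space steps), optionally with an obliquity (1/cos theta) correction
  valid for a *single* tilted plane wave;
* :func:`ssnp_propagate` -- split-step non-paraxial scheme evolving the
  field together with its axial derivative through the exact 2x2
  Fourier-domain free-space propagator, which remains valid for multiplexed
  illumination where no common obliquity factor exists.

An exact scalar partial-wave (Mie-type) series for a homogeneous sphere,
:func:`mie_scattered_field`, serves as an independent oracle for the
multislice models on sphere phantoms.

Fourier conventions: spatial frequencies are in cycles/um, stored in
standard ``numpy.fft`` ordering; 2-vectors are (y, x).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import fft as sfft
from scipy import special

from .dmd_patterns import PlaneWaveSpec

__all__ = [
    "ComplexField",
    "RIVolume",
    "SphereScene",
    "PropagationConfig",
    "angular_spectrum_propagate",
    "bpm_propagate",
    "ssnp_propagate",
    "apply_detection_pupil",
    "mie_scattered_field",
    "plane_wave_field",
]


@dataclass
class ComplexField:
    """A 2D complex field sampled on a regular grid.

    ``values[iy, ix]``; ``pixel_pitch`` in um; ``z_position`` locates the
    sampling plane on the optical axis.
    """

    values: np.ndarray
    pixel_pitch: float
    wavelength: float
    background_index: float
    z_position: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 2:
            raise ValueError("field values must be 2D")
        if any(s % 2 for s in self.values.shape):
            raise ValueError("field grid dimensions must be even (FFT-friendly)")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def freq_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """(fy, fx) broadcastable fftfreq grids in cycles/um."""
        ny, nx = self.shape
        fy = sfft.fftfreq(ny, d=self.pixel_pitch)[:, None]
        fx = sfft.fftfreq(nx, d=self.pixel_pitch)[None, :]
        return fy, fx

    def with_values(self, values: np.ndarray, z: float | None = None) -> "ComplexField":
        return ComplexField(
            values=values,
            pixel_pitch=self.pixel_pitch,
            wavelength=self.wavelength,
            background_index=self.background_index,
            z_position=self.z_position if z is None else z,
        )


@dataclass
class RIVolume:
    """3D complex refractive index ``index[iz, iy, ix]`` on a regular grid."""

    index: np.ndarray
    voxel_xy: float
    voxel_z: float
    background_index: float

    def __post_init__(self):
        self.index = np.asarray(self.index, dtype=complex)
        if self.index.ndim != 3:
            raise ValueError("index must be a 3D array (z, y, x)")
        if not np.all(np.isfinite(self.index)):
            raise ValueError("index contains non-finite values")
        if self.voxel_xy <= 0 or self.voxel_z <= 0:
            raise ValueError("voxel sizes must be positive")

    @property
    def shape(self):
        return self.index.shape

    def copy(self) -> "RIVolume":
        return RIVolume(self.index.copy(), self.voxel_xy, self.voxel_z, self.background_index)


@dataclass
class SphereScene:
    """Spheres (center (z,y,x) um, radius um, complex index) in a background."""

    spheres: list[tuple]
    background_index: float

    def __post_init__(self):
        for _, radius, _ in self.spheres:
            if radius <= 0:
                raise ValueError("sphere radius must be positive")

    def rasterize(
        self, shape: tuple[int, int, int], voxel_xy: float, voxel_z: float,
        origin: Sequence[float] = (0.0, 0.0, 0.0),
    ) -> RIVolume:
        """Voxelize the scene; ``origin`` is the (z,y,x) of voxel [0,0,0]."""
        nz, ny, nx = shape
        oz, oy, ox = origin
        z = oz + np.arange(nz)[:, None, None] * voxel_z
        y = oy + np.arange(ny)[None, :, None] * voxel_xy
        x = ox + np.arange(nx)[None, None, :] * voxel_xy
        vol = np.full(shape, complex(self.background_index))
        for (c, radius, index) in self.spheres:
            cz, cy, cx = c
            mask = (z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2 <= radius**2
            vol[mask] = index
        return RIVolume(vol, voxel_xy, voxel_z, self.background_index)


@dataclass
class PropagationConfig:
    padding_factor: float = 2.0
    pupil_na: float | None = None
    model: str = "ssnp"  # {'bpm', 'bpm_obliquity', 'ssnp'}
    boundary: str = "padded-absorbing"  # or 'periodic'

    def __post_init__(self):
        if self.padding_factor < 1:
            raise ValueError("padding_factor must be >= 1")
        if self.model not in ("bpm", "bpm_obliquity", "ssnp"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.boundary not in ("periodic", "padded-absorbing"):
            raise ValueError(f"unknown boundary {self.boundary!r}")


# ---------------------------------------------------------------------------
# free-space propagation
# ---------------------------------------------------------------------------

def _kz_grid(shape, pixel, wavelength, n0) -> np.ndarray:
    """Angular axial wavenumber kz = 2 pi sqrt((n0/lam)^2 - f^2), complex.

    Evanescent components (|f| > n0/lam) get kz = i * 2 pi sqrt(f^2 - (n0/lam)^2).
    """
    ny, nx = shape
    fy = sfft.fftfreq(ny, d=pixel)[:, None]
    fx = sfft.fftfreq(nx, d=pixel)[None, :]
    fsq = fy**2 + fx**2
    fz2 = (n0 / wavelength) ** 2 - fsq
    return 2 * np.pi * np.sqrt(fz2.astype(complex))


def angular_spectrum_propagate(field: ComplexField, distance: float) -> ComplexField:
    """Propagate through a homogeneous medium of the field's background index.

    Each plane-wave component acquires ``exp(i kz d)``; evanescent components
    decay as ``exp(-|kz| |d|)`` regardless of the sign of ``distance`` so the
    inverse (refocusing) transform never amplifies noise.
    """
    if not np.isfinite(distance):
        raise ValueError("distance must be finite")
    kz = _kz_grid(field.shape, field.pixel_pitch, field.wavelength, field.background_index)
    phase = np.where(
        kz.imag == 0,
        np.exp(1j * kz.real * distance),
        np.exp(-np.abs(kz.imag) * abs(distance)),
    )
    out = sfft.ifft2(sfft.fft2(field.values) * phase)
    return field.with_values(out, z=field.z_position + distance)


def apply_detection_pupil(field: ComplexField, na: float) -> ComplexField:
    """Zero Fourier components beyond the detection band ``|f| > NA/lam``."""
    fy, fx = field.freq_grids()
    keep = fy**2 + fx**2 <= (na / field.wavelength) ** 2
    return field.with_values(sfft.ifft2(sfft.fft2(field.values) * keep))


def plane_wave_field(
    beam: PlaneWaveSpec,
    shape: tuple[int, int],
    pixel_pitch: float,
    wavelength: float,
    background_index: float,
    z_position: float = 0.0,
) -> ComplexField:
    """Sample a tilted plane wave ``a exp(i(2 pi f.(r - dr) + phi))`` at z=z_position.

    The transverse phase is referenced to the beam's own offset position so
    that shifted beams stay centered on their sub-field of view; the axial
    phase is referenced to z = 0.
    """
    ny, nx = shape
    y = np.arange(ny)[:, None] * pixel_pitch
    x = np.arange(nx)[None, :] * pixel_pitch
    fy, fx = beam.object_frequency
    fmag2 = fy**2 + fx**2
    fz2 = (background_index / wavelength) ** 2 - fmag2
    kz = 2 * np.pi * np.sqrt(max(fz2, 0.0))
    vals = beam.amplitude * np.exp(
        1j * (2 * np.pi * (fy * (y - beam.position_offset[0]) + fx * (x - beam.position_offset[1]))
              + beam.phase + kz * z_position)
    )
    return ComplexField(vals, pixel_pitch, wavelength, background_index, z_position)


# ---------------------------------------------------------------------------
# padding / apodization
# ---------------------------------------------------------------------------

def _pad_sizes(shape, factor):
    return tuple(int(np.ceil(s * factor / 2)) * 2 for s in shape)


def _edge_apodizer(shape, width_frac=0.1) -> np.ndarray:
    """Separable raised-cosine window rolling off over width_frac of each edge."""
    wins = []
    for n in shape:
        w = max(int(round(n * width_frac)), 1)
        win = np.ones(n)
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(w) / w))
        win[:w] = ramp
        win[-w:] = ramp[::-1]
        wins.append(win)
    return wins[0][:, None] * wins[1][None, :]


class _Padder:
    """Zero-pad fields (with edge apodization of the scattered part) for
    propagation, then crop back; identity when cfg.boundary == 'periodic'."""

    def __init__(self, shape, cfg: PropagationConfig):
        self.active = cfg.boundary == "padded-absorbing" and cfg.padding_factor > 1
        self.shape = shape
        if self.active:
            self.padded = _pad_sizes(shape, cfg.padding_factor)
            self.off = tuple((p - s) // 2 for p, s in zip(self.padded, shape))
        else:
            self.padded = shape
            self.off = (0, 0)

    def pad(self, arr: np.ndarray) -> np.ndarray:
        if not self.active:
            return arr
        out = np.zeros(self.padded, dtype=arr.dtype)
        oy, ox = self.off
        ny, nx = self.shape
        out[oy:oy + ny, ox:ox + nx] = arr
        return out

    def crop(self, arr: np.ndarray) -> np.ndarray:
        if not self.active:
            return arr
        oy, ox = self.off
        ny, nx = self.shape
        return arr[oy:oy + ny, ox:ox + nx]


# ---------------------------------------------------------------------------
# BPM
# ---------------------------------------------------------------------------

def bpm_propagate(
    volume: RIVolume,
    incident: ComplexField,
    cfg: PropagationConfig | None = None,
    obliquity_cos: float | None = None,
) -> ComplexField:
    """Multislice beam propagation: symmetric free-space / phase-screen steps.

    In ``bpm_obliquity`` mode phase screens are divided by the axial
    direction cosine of the single dominant incident plane wave, which must
    be supplied via ``obliquity_cos`` or be inferable from a pure tilted
    plane wave; the mode refuses multiplexed illumination, whose beams do
    not share a common obliquity factor.
    """
    cfg = cfg or PropagationConfig(model="bpm")
    nz = volume.shape[0]
    if volume.shape[1:] != incident.shape:
        raise ValueError("incident grid does not match volume lateral grid")
    k0 = 2 * np.pi / incident.wavelength
    n0 = volume.background_index
    dz = volume.voxel_z

    cos_obl = 1.0
    if cfg.model == "bpm_obliquity":
        if obliquity_cos is None:
            cos_obl = _dominant_direction_cosine(incident)
        else:
            cos_obl = float(obliquity_cos)
        if not 0 < cos_obl <= 1:
            raise ValueError("obliquity cosine must be in (0, 1]")

    pad = _Padder(incident.shape, cfg)
    apo = _edge_apodizer(pad.padded) if pad.active else 1.0
    E = pad.pad(incident.values)
    kz = _kz_grid(E.shape, incident.pixel_pitch, incident.wavelength, n0)
    prop_full = np.where(kz.imag == 0, np.exp(1j * kz.real * dz), np.exp(-np.abs(kz.imag) * dz))
    prop_half = np.where(
        kz.imag == 0, np.exp(1j * kz.real * dz / 2), np.exp(-np.abs(kz.imag) * dz / 2)
    )

    E = sfft.ifft2(sfft.fft2(E) * prop_half)
    for iz in range(nz):
        screen = np.exp(1j * k0 * (volume.index[iz] - n0) * dz / cos_obl)
        E *= pad.pad(screen - 1.0) * apo + 1.0
        step = prop_full if iz < nz - 1 else prop_half
        E = sfft.ifft2(sfft.fft2(E) * step)
    out = pad.crop(E)
    return incident.with_values(out, z=incident.z_position + nz * dz)


def _dominant_direction_cosine(field: ComplexField) -> float:
    """Axial direction cosine of the strongest plane-wave component; raises
    if a second component carries comparable power (multiplexed beam)."""
    F = np.abs(sfft.fft2(field.values)) ** 2
    fy, fx = field.freq_grids()
    flat = F.ravel()
    order = np.argsort(flat)[::-1]
    if len(order) > 1 and flat[order[1]] > 0.25 * flat[order[0]]:
        raise ValueError(
            "multiplexed illumination detected: beams do not share a common "
            "obliquity factor; use the SSNP model instead"
        )
    i = np.unravel_index(order[0], F.shape)
    fsq = float((fy[i[0], 0] ** 2 + fx[0, i[1]] ** 2))
    n_over_lam = field.background_index / field.wavelength
    c2 = 1.0 - fsq / n_over_lam**2
    if c2 <= 0:
        raise ValueError("dominant component is evanescent")
    return float(np.sqrt(c2))


# ---------------------------------------------------------------------------
# SSNP
# ---------------------------------------------------------------------------

def _ssnp_propagators(shape, pixel, wavelength, n0, dz):
    """Entries (P11, P12, P21, P22) of the exact 2x2 free-space propagator of
    the (E, dE/dz) pair over dz; evanescent modes are damped exponentially
    on both components instead of the (divergent) cosh/sinh forms."""
    kz = _kz_grid(shape, pixel, wavelength, n0)
    prop = kz.imag == 0
    kr = np.where(prop, kz.real, 1.0)
    c = np.cos(kr * dz)
    s = np.sin(kr * dz)
    decay = np.exp(-np.abs(kz.imag) * dz)
    P11 = np.where(prop, c, decay).astype(complex)
    P12 = np.where(prop, s / kr, 0.0).astype(complex)
    P21 = np.where(prop, -kr * s, 0.0).astype(complex)
    P22 = np.where(prop, c, decay).astype(complex)
    return P11, P12, P21, P22, kz, prop


def ssnp_propagate(
    volume: RIVolume,
    incident: ComplexField,
    cfg: PropagationConfig | None = None,
    return_intermediates: bool = False,
):
    """Split-step non-paraxial propagation of (field, axial derivative).

    The incident field is complemented with its axial derivative assuming
    purely forward travel at the entrance plane; each slice applies the
    exact homogeneous 2x2 Fourier propagator followed by a scattering kick
    ``dE'/dz -= k0^2 (n^2 - n0^2) dz E``; the exit state is projected onto
    the forward-travelling component.
    """
    cfg = cfg or PropagationConfig(model="ssnp")
    nz = volume.shape[0]
    if volume.shape[1:] != incident.shape:
        raise ValueError("incident grid does not match volume lateral grid")
    k0 = 2 * np.pi / incident.wavelength
    n0 = volume.background_index
    dz = volume.voxel_z
    if np.abs(volume.index - n0).max() > 0 and dz > incident.wavelength / (
        4 * max(np.abs(volume.index.real - n0).max(), 1e-12)
    ):
        import logging

        logging.getLogger(__name__).warning(
            "SSNP slice thickness dz=%.3g um may be too coarse for the "
            "index contrast present", dz,
        )

    pad = _Padder(incident.shape, cfg)
    apo = _edge_apodizer(pad.padded) if pad.active else 1.0
    full = _ssnp_propagators(pad.padded, incident.pixel_pitch, incident.wavelength, n0, dz)
    half = _ssnp_propagators(pad.padded, incident.pixel_pitch, incident.wavelength, n0, dz / 2)
    kz, prop_mask = full[4], full[5]
    ikz = np.where(prop_mask, 1j * kz.real, -np.abs(kz.imag))

    def _apply(P, Eh, Dh):
        return P[0] * Eh + P[1] * Dh, P[2] * Eh + P[3] * Dh

    Eh = sfft.fft2(pad.pad(incident.values))
    Dh = ikz * Eh  # forward-only entrance condition
    intermediates = []
    # symmetric splitting: kicks sit at slice centers (i + 1/2) dz
    Eh, Dh = _apply(half, Eh, Dh)
    for iz in range(nz):
        E = sfft.ifft2(Eh)
        if return_intermediates:
            intermediates.append(E)
        V = k0**2 * (volume.index[iz] ** 2 - n0**2)
        kick = pad.pad(V) * apo * E * dz
        Dh = Dh - sfft.fft2(kick)
        Eh, Dh = _apply(full if iz < nz - 1 else half, Eh, Dh)
    # forward projection: E_fwd = (E + D / (i kz)) / 2
    inv_ikz = np.where(prop_mask, 1.0 / (1j * np.where(prop_mask, kz.real, 1.0)), 0.0)
    Ef = 0.5 * (Eh + inv_ikz * Dh)
    out = pad.crop(sfft.ifft2(Ef))
    exit_field = incident.with_values(out, z=incident.z_position + nz * dz)
    if return_intermediates:
        return exit_field, intermediates
    return exit_field


# ---------------------------------------------------------------------------
# scalar partial-wave (Mie) oracle
# ---------------------------------------------------------------------------

def _sph_hankel1(l_arr, z):
    return special.spherical_jn(l_arr, z) + 1j * special.spherical_yn(l_arr, z)


def mie_series_coefficients(x: float, m: complex, n_max: int | None = None) -> np.ndarray:
    """Exterior partial-wave coefficients b_l for scalar scattering from a
    homogeneous sphere of size parameter ``x = k a`` and relative index
    ``m`` (continuity of the field and its radial derivative at r = a)."""
    if n_max is None:
        n_max = int(np.ceil(x + 4 * x ** (1 / 3) + 2))
    ls = np.arange(n_max + 1)
    jx = special.spherical_jn(ls, x)
    jxp = special.spherical_jn(ls, x, derivative=True)
    hx = _sph_hankel1(ls, x)
    hxp = special.spherical_jn(ls, x, derivative=True) + 1j * special.spherical_yn(
        ls, x, derivative=True
    )
    mx = m * x
    jm = special.spherical_jn(ls, mx.real) if np.isreal(m) else _sph_jn_complex(ls, mx)
    jmp = (
        special.spherical_jn(ls, mx.real, derivative=True)
        if np.isreal(m)
        else _sph_jn_complex(ls, mx, derivative=True)
    )
    num = m * jmp * jx - jm * jxp
    den = m * jmp * hx - jm * hxp
    return -num / den


def _sph_jn_complex(ls, z, derivative=False):
    """Spherical Bessel j_l at complex argument via Miller's downward
    recurrence (upward recurrence is unstable for j_l)."""
    lmax = int(np.max(ls))
    if abs(z) < 1e-12:
        j = np.zeros(lmax + 2, dtype=complex)
        j[0] = 1.0
    else:
        start = lmax + 16 + int(abs(z))
        jj = np.zeros(start + 2, dtype=complex)
        jj[start + 1] = 0.0
        jj[start] = 1e-30
        for l in range(start, 0, -1):
            jj[l - 1] = (2 * l + 1) / z * jj[l] - jj[l + 1]
        scale = (np.sin(z) / z) / jj[0]
        j = jj[: lmax + 2] * scale
    if not derivative:
        return j[ls]
    jd = np.zeros(lmax + 1, dtype=complex)
    jd[0] = -j[1]
    if abs(z) >= 1e-12:
        for l in range(1, lmax + 1):
            jd[l] = j[l - 1] - (l + 1) / z * j[l]
    return jd[ls]


def mie_scattering_amplitude(theta, x: float, m: complex, k: float) -> np.ndarray:
    """Far-field scalar scattering amplitude f(theta) (units of length)."""
    b = mie_series_coefficients(x, m)
    ls = np.arange(len(b))
    ct = np.cos(np.atleast_1d(theta))
    P = np.array([special.eval_legendre(l, ct) for l in ls])
    # E_s -> f(theta) e^{ikr}/r with h_l ~ (-i)^{l+1} e^{ikr}/(kr)
    return np.tensordot((2 * ls + 1) * b / (1j * k), P, axes=(0, 0))


def mie_cross_sections(x: float, m: complex, k: float) -> tuple[float, float]:
    """(sigma_scat, sigma_ext) from the partial-wave series."""
    b = mie_series_coefficients(x, m)
    ls = np.arange(len(b))
    sca = 4 * np.pi / k**2 * np.sum((2 * ls + 1) * np.abs(b) ** 2)
    ext = -4 * np.pi / k**2 * np.sum((2 * ls + 1) * b.real)
    return float(sca), float(ext)


def mie_scattered_field(
    scene: SphereScene,
    beam: PlaneWaveSpec,
    plane_z: float,
    shape: tuple[int, int],
    pixel_pitch: float,
    wavelength: float,
    total: bool = True,
) -> ComplexField:
    """Total (or scattered-only) field on the plane ``z = plane_z``.

    Multi-sphere scenes superpose single-scattering fields; the series is
    truncated at ``n_max = ceil(x + 4 x^(1/3) + 2)``.  The incident beam is
    a (possibly tilted, offset) plane wave of the scene's background index.
    """
    n0 = scene.background_index
    k = 2 * np.pi * n0 / wavelength
    inc = plane_wave_field(beam, shape, pixel_pitch, wavelength, n0, z_position=plane_z)

    ny, nx = shape
    y = np.arange(ny)[:, None] * pixel_pitch
    x_ = np.arange(nx)[None, :] * pixel_pitch

    # incident propagation direction (unit vector, (z, y, x))
    fy, fx = beam.object_frequency
    sz = np.sqrt(max((n0 / wavelength) ** 2 - fy**2 - fx**2, 0.0)) * wavelength / n0
    khat = np.array([sz, fy * wavelength / n0, fx * wavelength / n0])

    scat = np.zeros(shape, dtype=complex)
    for center, radius, index in scene.spheres:
        m = complex(index) / n0
        if m == 1.0:
            continue
        xpar = k * radius
        b = mie_series_coefficients(xpar, m)
        cz, cy, cx = center
        ry = y - cy
        rx = x_ - cx
        rz = plane_z - cz
        r = np.sqrt(rz**2 + ry**2 + rx**2)
        r = np.maximum(r, 1e-9)
        ct = (khat[0] * rz + khat[1] * ry + khat[2] * rx) / r
        ct = np.clip(ct, -1.0, 1.0)
        # incident phase at sphere center (plane-wave reference at z=0, offset dr)
        phase_c = (
            2 * np.pi * (fy * (cy - beam.position_offset[0]) + fx * (cx - beam.position_offset[1]))
            + beam.phase
            + 2 * np.pi * (n0 / wavelength) * sz * cz
        )
        amp = beam.amplitude * np.exp(1j * phase_c)
        kr = k * r
        lmax = len(b) - 1
        jn, yn = _sph_jn_yn_table(lmax, kr.ravel())
        partial = np.zeros(kr.size, dtype=complex)
        ctf = ct.ravel()
        # Legendre recurrence in cos(theta)
        P_lm1 = np.ones_like(ctf)
        P_l = ctf
        for l in range(lmax + 1):
            if l == 0:
                P = P_lm1
            elif l == 1:
                P = P_l
            else:
                P = ((2 * l - 1) * ctf * P_l - (l - 1) * P_lm1) / l
                P_lm1, P_l = P_l, P
            partial += (1j**l) * (2 * l + 1) * b[l] * (jn[l] + 1j * yn[l]) * P
        scat += (amp * partial).reshape(shape)
    vals = inc.values + scat if total else scat
    return ComplexField(vals, pixel_pitch, wavelength, n0, z_position=plane_z)


def _sph_jn_yn_table(lmax: int, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spherical Bessel j_l, y_l for all orders 0..lmax at every (real,
    positive) point of ``z``: y_l by stable upward recurrence, j_l by
    Miller's downward recurrence normalized to j_0 = sin(z)/z."""
    z = np.maximum(z, 1e-12)
    yn = np.empty((lmax + 1, z.size))
    yn[0] = -np.cos(z) / z
    if lmax >= 1:
        yn[1] = -np.cos(z) / z**2 - np.sin(z) / z
        for l in range(1, lmax):
            yn[l + 1] = (2 * l + 1) / z * yn[l] - yn[l - 1]
    # downward recurrence must begin above both lmax and the turning point
    # l ~ z, else the minimal solution is contaminated by y_l
    start = lmax + 16 + int(np.ceil(z.max()))
    jn = np.empty((lmax + 1, z.size))
    jj_next = np.zeros_like(z)  # j_{start+1}
    jj_cur = np.full_like(z, 1e-290)  # j_{start}
    for l in range(start, 0, -1):
        if l <= lmax:
            jn[l] = jj_cur
        jj_prev = (2 * l + 1) / z * jj_cur - jj_next  # j_{l-1}
        big = np.abs(jj_prev) > 1e250
        if np.any(big):
            scale = np.where(big, 1e-250, 1.0)
            jj_prev = jj_prev * scale
            jj_cur = jj_cur * scale
            if l <= lmax:
                jn[l : lmax + 1] *= scale
        jj_next, jj_cur = jj_cur, jj_prev
    jn[0] = jj_cur
    # normalize against whichever closed form is larger (j0 vanishes at
    # the zeros of sin z, so a single anchor is numerically unsafe)
    j0 = np.sin(z) / z
    j1 = np.sin(z) / z**2 - np.cos(z) / z
    if lmax >= 1:
        use0 = np.abs(j0) >= np.abs(j1)
        anchor = np.where(use0, j0, j1)
        raw = np.where(use0, jn[0], jn[1])
    else:
        anchor, raw = j0, jn[0]
    jn *= anchor / raw
    return jn, yn
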