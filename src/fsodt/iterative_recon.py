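"""FISTA proximal-gradient reconstruction of 3D refractive index.

The smooth data term compares multislice model predictions against measured
complex fields with a phase-sensitive and a phase-insensitive component,

    L = w_ps sum |E_model - E_meas|^2  +  w_pi sum (|E_model| - |E_meas|)^2,

averaged over illumination frames.  Its gradient with respect to the
(complex) refractive index is computed by reverse-mode differentiation of
the chosen multislice model (a reverse slice sweep applying the conjugate
transpose of every linear step).  The nonsmooth part -- isotropic total
variation, complex soft thresholding on the index contrast, and the
physical constraints Re(n) >= n0, Im(n) >= 0 -- is applied through
:func:`prox_step`.

Gradient convention: the returned gradient ``G`` satisfies
``dL = Re <G, dn> = Re sum conj(G) dn`` for complex index perturbations.

Measured fields are referenced to the *exit plane* of the volume (use
``refocus_to_exit`` on focal-plane data); incident fields are the
superposed plane waves of each frame sampled at the entrance plane.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dfield
from typing import Callable, Sequence

import numpy as np
from scipy import fft as sfft
from skimage.restoration import denoise_tv_chambolle

from .dmd_patterns import IlluminationSet, PlaneWaveSpec
from .forward_models import (
    ComplexField,
    PropagationConfig,
    RIVolume,
    _edge_apodizer,
    _Padder,
    _ssnp_propagators,
    _kz_grid,
    angular_spectrum_propagate,
    plane_wave_field,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LossConfig",
    "RegConfig",
    "FistaState",
    "data_loss_and_gradient",
    "prox_step",
    "fista_solve",
    "reconstruct_volume",
    "incident_fields_for_frames",
    "refocus_to_exit",
]


@dataclass
class LossConfig:
    phase_sensitive_weight: float = 1.0
    phase_insensitive_weight: float = 0.0

    def __post_init__(self):
        if self.phase_sensitive_weight < 0 or self.phase_insensitive_weight < 0:
            raise ValueError("loss weights must be non-negative")
        if self.phase_sensitive_weight == 0 and self.phase_insensitive_weight == 0:
            raise ValueError("at least one loss weight must be positive")


@dataclass
class RegConfig:
    tv_weight: float = 0.0
    l1_weight: float = 0.0
    enforce_re_ge_background: bool = True
    enforce_absorptive: bool = True

    def __post_init__(self):
        if self.tv_weight < 0 or self.l1_weight < 0:
            raise ValueError("regularization weights must be non-negative")


@dataclass
class FistaState:
    iterate: RIVolume
    momentum_point: RIVolume
    t: float = 1.0
    step: float = 1.0
    objective_history: list = dfield(default_factory=list)


# ---------------------------------------------------------------------------
# multislice forward + adjoint engine (orthonormal FFTs throughout)
# ---------------------------------------------------------------------------

def _fft2o(a):
    return sfft.fft2(a, norm="ortho")


def _ifft2o(a):
    return sfft.ifft2(a, norm="ortho")


class _SliceEngine:
    """Shared precomputations for one (grid, config) combination."""

    def __init__(self, volume: RIVolume, incident: ComplexField, cfg: PropagationConfig):
        if volume.shape[1:] != incident.shape:
            raise ValueError("incident grid does not match volume lateral grid")
        self.cfg = cfg
        self.n0 = volume.background_index
        self.lam = incident.wavelength
        self.k0 = 2 * np.pi / self.lam
        self.dz = volume.voxel_z
        self.nz = volume.shape[0]
        self.pad = _Padder(incident.shape, cfg)
        self.apo = _edge_apodizer(self.pad.padded) if self.pad.active else 1.0
        shape, pitch = self.pad.padded, incident.pixel_pitch
        if cfg.model == "ssnp":
            self.full = _ssnp_propagators(shape, pitch, self.lam, self.n0, self.dz)
            self.half = _ssnp_propagators(shape, pitch, self.lam, self.n0, self.dz / 2)
            kz, mask = self.full[4], self.full[5]
            self.ikz = np.where(mask, 1j * kz.real, -np.abs(kz.imag))
            self.inv_ikz = np.where(mask, 1.0 / np.where(mask, 1j * kz.real, 1.0), 0.0)
        else:
            kz = _kz_grid(shape, pitch, self.lam, self.n0)
            self.prop_full = np.where(
                kz.imag == 0, np.exp(1j * kz.real * self.dz), np.exp(-np.abs(kz.imag) * self.dz)
            )
            self.prop_half = np.where(
                kz.imag == 0,
                np.exp(1j * kz.real * self.dz / 2),
                np.exp(-np.abs(kz.imag) * self.dz / 2),
            )
        if cfg.pupil_na is not None:
            fy = sfft.fftfreq(incident.shape[0], d=pitch)[:, None]
            fx = sfft.fftfreq(incident.shape[1], d=pitch)[None, :]
            self.pupil = (fy**2 + fx**2 <= (cfg.pupil_na / self.lam) ** 2).astype(float)
        else:
            self.pupil = None

    # --- SSNP ---------------------------------------------------------------

    def ssnp_forward(self, volume: RIVolume, incident: ComplexField, store: bool):
        P = lambda Pm, Eh, Dh: (Pm[0] * Eh + Pm[1] * Dh, Pm[2] * Eh + Pm[3] * Dh)
        Eh = _fft2o(self.pad.pad(incident.values))
        Dh = self.ikz * Eh
        Eh, Dh = P(self.half, Eh, Dh)
        stored = []
        for iz in range(self.nz):
            E = _ifft2o(Eh)
            if store:
                stored.append(E)
            V = self.k0**2 * (volume.index[iz] ** 2 - self.n0**2)
            Dh = Dh - _fft2o(self.pad.pad(V) * self.apo * E * self.dz)
            Eh, Dh = P(self.full if iz < self.nz - 1 else self.half, Eh, Dh)
        Sh = 0.5 * (Eh + self.inv_ikz * Dh)
        Eout = self.pad.crop(_ifft2o(Sh))
        if self.pupil is not None:
            Eout = _ifft2o(_fft2o(Eout) * self.pupil)
        return Eout, stored

    def ssnp_adjoint(self, volume: RIVolume, stored, G_out):
        """Reverse sweep; returns the gradient wrt V (complex, per slice)."""
        PH = lambda Pm, gE, gD: (
            np.conj(Pm[0]) * gE + np.conj(Pm[2]) * gD,
            np.conj(Pm[1]) * gE + np.conj(Pm[3]) * gD,
        )
        if self.pupil is not None:
            G_out = _ifft2o(_fft2o(G_out) * self.pupil)
        G_Sh = _fft2o(self.pad.pad(G_out))
        gEh = 0.5 * G_Sh
        gDh = np.conj(self.inv_ikz) * 0.5 * G_Sh
        gV = np.empty((self.nz,) + self.pad.shape, dtype=complex)
        for iz in range(self.nz - 1, -1, -1):
            gEh, gDh = PH(self.full if iz < self.nz - 1 else self.half, gEh, gDh)
            E = stored[iz]
            V = self.k0**2 * (volume.index[iz] ** 2 - self.n0**2)
            gd = _ifft2o(gDh)
            G_Vp = -self.dz * np.conj(E) * gd
            gV[iz] = self.pad.crop(self.apo * G_Vp) if self.pad.active else G_Vp
            G_E = -self.dz * np.conj(self.pad.pad(V) * self.apo) * gd
            gEh = gEh + _fft2o(G_E)
        return gV

    # --- plain BPM ----------------------------------------------------------

    def bpm_forward(self, volume: RIVolume, incident: ComplexField, store: bool):
        E = self.pad.pad(incident.values)
        E = _ifft2o(_fft2o(E) * self.prop_half)
        stored = []
        for iz in range(self.nz):
            if store:
                stored.append(E.copy())
            screen = np.exp(1j * self.k0 * (volume.index[iz] - self.n0) * self.dz)
            E = E * (self.pad.pad(screen - 1.0) * self.apo + 1.0)
            step = self.prop_full if iz < self.nz - 1 else self.prop_half
            E = _ifft2o(_fft2o(E) * step)
        Eout = self.pad.crop(E)
        if self.pupil is not None:
            Eout = _ifft2o(_fft2o(Eout) * self.pupil)
        return Eout, stored

    def bpm_adjoint(self, volume: RIVolume, stored, G_out):
        """Reverse sweep; returns the gradient wrt n directly (complex)."""
        if self.pupil is not None:
            G_out = _ifft2o(_fft2o(G_out) * self.pupil)
        g = self.pad.pad(G_out)
        gn = np.empty((self.nz,) + self.pad.shape, dtype=complex)
        for iz in range(self.nz - 1, -1, -1):
            step = self.prop_full if iz < self.nz - 1 else self.prop_half
            g = _ifft2o(_fft2o(g) * np.conj(step))
            E = stored[iz]
            screen = np.exp(1j * self.k0 * (volume.index[iz] - self.n0) * self.dz)
            screen_p = self.pad.pad(screen - 1.0) * self.apo + 1.0
            G_screen_p = np.conj(E) * g
            dscreen = 1j * self.k0 * self.dz * screen  # d(screen)/dn
            G_sp = self.pad.crop(self.apo * G_screen_p) if self.pad.active else G_screen_p
            gn[iz] = np.conj(dscreen) * G_sp
            g = g * np.conj(screen_p)
        return gn


def incident_fields_for_frames(
    beams_per_frame: Sequence[Sequence[PlaneWaveSpec]],
    shape: tuple[int, int],
    pixel_pitch: float,
    wavelength: float,
    background_index: float,
    z_entrance: float,
) -> list[ComplexField]:
    """Superpose each frame's plane waves at the volume entrance plane.

    Axial phases are referenced to z = 0 at the volume center, matching the
    Rytov gridding convention.
    """
    out = []
    for beams in beams_per_frame:
        vals = np.zeros(shape, dtype=complex)
        for b in beams:
            vals += plane_wave_field(
                b, shape, pixel_pitch, wavelength, background_index, z_position=z_entrance
            ).values
        out.append(
            ComplexField(vals, pixel_pitch, wavelength, background_index, z_position=z_entrance)
        )
    return out


def refocus_to_exit(field: ComplexField, volume_thickness: float) -> ComplexField:
    """Propagate a focal-plane (volume-center) field to the exit plane."""
    return angular_spectrum_propagate(field, volume_thickness / 2.0)


def data_loss_and_gradient(
    volume: RIVolume,
    measured_fields: Sequence[ComplexField],
    incident_fields: Sequence[ComplexField],
    cfg: PropagationConfig,
    loss: LossConfig | None = None,
    compute_gradient: bool = True,
):
    """Data-fidelity loss and its gradient with respect to the complex RI.

    ``measured_fields`` are exit-plane complex fields, one per illumination
    frame; ``incident_fields`` the matching entrance-plane illuminations.
    The loss is averaged over frames.
    """
    loss = loss or LossConfig()
    if len(measured_fields) != len(incident_fields):
        raise ValueError("measured and incident field counts differ")
    n_frames = len(measured_fields)
    eng = _SliceEngine(volume, incident_fields[0], cfg)
    w_ps, w_pi = loss.phase_sensitive_weight, loss.phase_insensitive_weight

    total = 0.0
    gV_or_n = None
    for idx, (meas, inc) in enumerate(zip(measured_fields, incident_fields)):
        if not np.all(np.isfinite(meas.values)):
            raise ValueError(f"NaN/Inf in measured data for frame {idx}")
        if cfg.model == "ssnp":
            Eout, stored = eng.ssnp_forward(volume, inc, store=compute_gradient)
        elif cfg.model == "bpm":
            Eout, stored = eng.bpm_forward(volume, inc, store=compute_gradient)
        else:
            raise ValueError(
                "gradient-based reconstruction supports 'ssnp' and 'bpm' models"
            )
        diff = Eout - meas.values
        aE = np.abs(Eout)
        aM = np.abs(meas.values)
        total += w_ps * float(np.sum(np.abs(diff) ** 2)) + w_pi * float(np.sum((aE - aM) ** 2))
        if compute_gradient:
            G_out = 2 * w_ps * diff
            if w_pi > 0:
                safe = np.maximum(aE, 1e-30)
                G_out = G_out + 2 * w_pi * (aE - aM) * Eout / safe
            g = (
                eng.ssnp_adjoint(volume, stored, G_out)
                if cfg.model == "ssnp"
                else eng.bpm_adjoint(volume, stored, G_out)
            )
            gV_or_n = g if gV_or_n is None else gV_or_n + g
    total /= n_frames
    if not compute_gradient:
        return total, None
    gV_or_n /= n_frames
    if cfg.model == "ssnp":
        # chain V = k0^2 (n^2 - n0^2)  ->  G_n = 2 k0^2 conj(n) G_V
        grad = 2 * eng.k0**2 * np.conj(volume.index) * gV_or_n
    else:
        grad = gV_or_n
    return total, grad


# ---------------------------------------------------------------------------
# proximal operator
# ---------------------------------------------------------------------------

def prox_step(volume: RIVolume, step: float, reg: RegConfig) -> RIVolume:
    """Apply TV prox, complex soft thresholding on (n - n0), and constraints.

    The composition (TV, then l1, then projection) approximates the joint
    proximal operator of the summed regularizers.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    n0 = volume.background_index
    u = volume.index - n0
    if reg.tv_weight > 0:
        w = step * reg.tv_weight
        re = denoise_tv_chambolle(u.real, weight=w)
        im = denoise_tv_chambolle(u.imag, weight=w) if np.any(u.imag) else u.imag
        u = re + 1j * im
    if reg.l1_weight > 0:
        t = step * reg.l1_weight
        mag = np.abs(u)
        shrink = np.maximum(1.0 - t / np.maximum(mag, 1e-30), 0.0)
        u = u * shrink
    n = n0 + u
    re, im = n.real, n.imag
    if reg.enforce_re_ge_background:
        re = np.maximum(re, n0)
    if reg.enforce_absorptive:
        im = np.maximum(im, 0.0)
    return RIVolume(re + 1j * im, volume.voxel_xy, volume.voxel_z, volume.background_index)


# ---------------------------------------------------------------------------
# FISTA
# ---------------------------------------------------------------------------

def estimate_step(
    volume: RIVolume,
    measured_fields,
    incident_fields,
    cfg: PropagationConfig,
    loss: LossConfig | None = None,
    n_power: int = 10,
    seed: int = 0,
) -> float:
    """Inverse-Lipschitz step estimate via power iteration on the Hessian of
    the data term, probed with finite gradient differences at the initializer."""
    rng = np.random.default_rng(seed)
    _, g0 = data_loss_and_gradient(volume, measured_fields, incident_fields, cfg, loss)
    v = rng.standard_normal(volume.shape) + 1j * rng.standard_normal(volume.shape)
    v /= np.linalg.norm(v)
    scale = max(np.abs(volume.index - volume.background_index).max(), 1e-3)
    eps = 1e-6 * scale
    lam = 1.0
    for _ in range(n_power):
        pert = volume.copy()
        pert.index = volume.index + eps * v
        _, g1 = data_loss_and_gradient(pert, measured_fields, incident_fields, cfg, loss)
        hv = (g1 - g0) / eps
        lam = float(np.linalg.norm(hv))
        if lam == 0:
            return 1.0
        v = hv / lam
    return 1.0 / lam


def regularizer_value(volume: RIVolume, reg: RegConfig) -> float:
    """Isotropic TV + l1 value of the index contrast (the nonsmooth term of
    the composite objective, used for monitoring and restart decisions)."""
    val = 0.0
    u = volume.index - volume.background_index
    if reg.tv_weight > 0:
        for comp in (u.real,) + ((u.imag,) if np.any(u.imag) else ()):
            g2 = np.zeros_like(comp)
            for ax in range(comp.ndim):
                d = np.diff(comp, axis=ax)
                pad = [(0, 1) if a == ax else (0, 0) for a in range(comp.ndim)]
                g2 += np.pad(d, pad) ** 2
            val += reg.tv_weight * float(np.sum(np.sqrt(g2)))
    if reg.l1_weight > 0:
        val += reg.l1_weight * float(np.sum(np.abs(u)))
    return val


def fista_solve(
    initial: RIVolume,
    measured_fields,
    incident_fields,
    cfg: PropagationConfig,
    loss: LossConfig | None = None,
    reg: RegConfig | None = None,
    n_iter: int = 50,
    step: float | None = None,
    tol: float = 1e-5,
    grad_and_loss: Callable | None = None,
    prox: Callable | None = None,
    reg_value: Callable | None = None,
    callback: Callable | None = None,
) -> tuple[RIVolume, list]:
    """Accelerated proximal gradient descent with adaptive restart.

    Performs the standard FISTA recursion (gradient at the momentum point,
    proximal step, ``t_{k+1} = (1 + sqrt(1 + 4 t_k^2)) / 2`` extrapolation),
    restarting the momentum whenever the objective increases and halving
    the step if the objective keeps rising after a restart.  Deterministic
    for fixed inputs.

    ``grad_and_loss(vol) -> (loss, grad)`` and ``prox(vol, step) -> vol``
    may be supplied to solve arbitrary composite problems (used by tests
    against closed-form solutions).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    loss = loss or LossConfig()
    reg = reg or RegConfig()
    if grad_and_loss is None:
        grad_and_loss = lambda vol: data_loss_and_gradient(
            vol, measured_fields, incident_fields, cfg, loss
        )
        smooth_loss = lambda vol: data_loss_and_gradient(
            vol, measured_fields, incident_fields, cfg, loss, compute_gradient=False
        )[0]
        if reg_value is None:
            reg_value = lambda vol: regularizer_value(vol, reg)
    else:
        smooth_loss = lambda vol: grad_and_loss(vol)[0]
        if reg_value is None:
            reg_value = lambda vol: 0.0
    # the monitored objective is the full composite: data term + regularizer
    eval_loss = lambda vol: smooth_loss(vol) + reg_value(vol)
    if prox is None:
        prox = lambda vol, s: prox_step(vol, s, reg)
    if step is None:
        step = estimate_step(initial, measured_fields, incident_fields, cfg, loss)
        logger.info("fista_solve: power-iteration step estimate %.3e", step)

    def _prox_grad_from(point: RIVolume, g: np.ndarray, s: float) -> RIVolume:
        z = point.copy()
        z.index = point.index - s * g
        return prox(z, s)

    x = initial.copy()
    y = initial.copy()
    t = 1.0
    f_init = eval_loss(initial)
    history: list[float] = []
    for k in range(n_iter):
        _, gy = grad_and_loss(y)
        x_new = _prox_grad_from(y, gy, step)
        fx = eval_loss(x_new)
        if not np.isfinite(fx) or (f_init > 0 and fx > f_init * 10):
            raise RuntimeError(
                f"FISTA diverged at iteration {k}: objective {fx:.3e} exceeds "
                f"10x initial {f_init:.3e} (step {step:.3e})"
            )
        if history and fx > history[-1]:
            # adaptive restart: drop momentum, step from the last iterate,
            # backtracking on the step size keeps the history monotone
            t = 1.0
            _, gx = grad_and_loss(x)
            for _ in range(12):
                x_new = _prox_grad_from(x, gx, step)
                fx = eval_loss(x_new)
                if fx <= history[-1]:
                    break
                step *= 0.5
            if fx > history[-1]:
                x_new, fx = x, history[-1]  # no descent possible; hold
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        y = x_new.copy()
        y.index = x_new.index + ((t - 1.0) / t_new) * (x_new.index - x.index)
        x = x_new
        t = t_new
        history.append(fx)
        if callback:
            callback(k, x, history)
        if tol > 0 and len(history) > 1 and abs(history[-2] - history[-1]) <= tol * max(
            abs(history[-2]), 1e-30
        ):
            break
    return x, history


def reconstruct_volume(
    holograms,
    illum: IlluminationSet,
    shape: tuple[int, int, int],
    voxel_z: float,
    cfg: PropagationConfig | None = None,
    loss: LossConfig | None = None,
    reg: RegConfig | None = None,
    n_iter: int = 50,
    band_radius: float | None = None,
    reference: ComplexField | None = None,
    step: float | None = None,
    provenance: dict | None = None,
) -> RIVolume:
    """End-to-end reconstruction: demodulate, initialize, FISTA-refine.

    ``holograms`` is one :class:`~fsodt.holography.Hologram` per frame,
    acquired in the plane through the volume center.  The initial guess
    comes from :func:`~fsodt.linear_recon.demultiplex_rytov_initialize`;
    refinement uses the SSNP forward model by default.
    """
    from .holography import demodulate_hologram
    from .linear_recon import demultiplex_rytov_initialize

    cfg = cfg or PropagationConfig(model="ssnp", boundary="periodic", padding_factor=1)
    holo0 = holograms[0]
    n0, lam = holo0.background_index, holo0.wavelength
    na = cfg.pupil_na if cfg.pupil_na is not None else n0
    if band_radius is None:
        band_radius = na / lam
    fields = [demodulate_hologram(h, band_radius) for h in holograms]
    if reference is not None:
        fields = [f.with_values(f.values / reference.values) for f in fields]

    init = demultiplex_rytov_initialize(
        fields, illum.beams_per_frame, shape, voxel_z, detection_na=na
    )
    thickness = shape[0] * voxel_z
    data_exit = [refocus_to_exit(f, thickness) for f in fields]
    incident = incident_fields_for_frames(
        illum.beams_per_frame, fields[0].shape, holo0.pixel_pitch, lam, n0,
        z_entrance=-thickness / 2.0,
    )
    vol, history = fista_solve(
        init, data_exit, incident, cfg, loss=loss, reg=reg, n_iter=n_iter, step=step
    )
    if provenance is not None:
        provenance.update(
            {
                "model": cfg.model,
                "n_iter": n_iter,
                "band_radius": band_radius,
                "objective_history": [float(v) for v in history],
                "shape": list(shape),
                "voxel_z": voxel_z,
            }
        )
    return vol
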