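"""Synthetic phantoms, dynamic scenes and hologram time series.

The generators emulate the experimental regimes the analysis stack is aimed
at: micron-scale polystyrene beads diffusing in water (or water-glycerol)
near a coverslip, with hindered diffusion and gravitational sedimentation,
and rod-shaped swimmers translating with a wobbling body axis.  Hologram
rendering ties the scene to the forward models: each illumination frame's
plane waves are scattered by the scene (Mie superposition for sparse sphere
scenes, SSNP for rasterized volumes), pupil-filtered, interfered with a
tilted reference and corrupted with shot and read noise.

Units: lengths in um, time in s, diffusion in um^2/s, densities in g/ml,
temperature in K.  All randomness flows from explicit integer seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dfield
from typing import Sequence

import numpy as np

from .dmd_patterns import IlluminationSet
from .forward_models import (
    ComplexField,
    PropagationConfig,
    SphereScene,
    angular_spectrum_propagate,
    apply_detection_pupil,
    mie_scattered_field,
    plane_wave_field,
    ssnp_propagate,
)
from .holography import Hologram, synthesize_hologram

logger = logging.getLogger(__name__)

__all__ = [
    "MotionModel",
    "Rod",
    "DynamicScene",
    "simulate_brownian_scene",
    "simulate_swimmer_scene",
    "render_hologram_series",
    "hindered_parallel_diffusion",
    "effective_buoyant_mass",
    "KB",
    "G_STANDARD",
]

KB = 1.380649e-23  # J/K
G_STANDARD = 9.80665  # m/s^2


@dataclass
class MotionModel:
    """Parameters of colloid dynamics near a wall.

    ``diffusion_coefficient`` is the bulk value Do; when ``hindered`` is
    set, the wall correction D(h) = Do (1 - (9/16) R/h) is applied to the
    lateral axes and, as a documented leading-order approximation, to the
    axial axis as well.  Sedimentation follows the buoyant mass
    m = (4/3) pi R^3 (rho_bead - rho_solvent).
    """

    diffusion_coefficient: float  # Do, um^2/s
    bead_radius: float = 0.5  # um
    hindered: bool = False
    gravity: bool = False
    bead_density: float = 1.05  # g/ml
    solvent_density: float = 1.0  # g/ml
    temperature: float = 295.65  # K
    swim_speed: float = 0.0  # um/s

    def __post_init__(self):
        if self.diffusion_coefficient < 0:
            raise ValueError("diffusion coefficient must be >= 0")
        if self.bead_density <= 0 or self.solvent_density <= 0:
            raise ValueError("densities must be positive")


def hindered_parallel_diffusion(Do: float, R: float, h) -> np.ndarray:
    """Leading-order wall-hindered diffusion, D(h) = Do (1 - (9/16) R/h)."""
    return Do * (1.0 - (9.0 / 16.0) * R / np.asarray(h, float))


def effective_buoyant_mass(radius_um: float, rho_bead: float, rho_solvent: float) -> float:
    """Buoyant (effective) mass in kg for radius in um, densities in g/ml."""
    r = radius_um * 1e-6
    drho = (rho_bead - rho_solvent) * 1000.0  # kg/m^3
    return 4.0 / 3.0 * np.pi * r**3 * drho


def sedimentation_length(model: MotionModel) -> float:
    """Boltzmann height scale kB T / (m g) in um (inf for neutral buoyancy)."""
    m = effective_buoyant_mass(model.bead_radius, model.bead_density, model.solvent_density)
    if m == 0:
        return np.inf
    return KB * model.temperature / (m * G_STANDARD) * 1e6


@dataclass
class Rod:
    """A rod-shaped object (cylinder with hemispherical caps)."""

    center: np.ndarray  # (z, y, x) um
    axis: np.ndarray  # unit vector (z, y, x)
    length: float  # um, cap-to-cap
    radius: float  # um
    index: complex


@dataclass
class DynamicScene:
    """Per-frame particle configurations with ground-truth metadata.

    ``positions`` has shape (n_frames, n_particles, 3) in (z, y, x) order
    with z the height above the coverslip.
    """

    positions: np.ndarray
    radii: np.ndarray  # (n_particles,)
    indices: np.ndarray  # (n_particles,) complex
    frame_interval: float  # s
    background_index: float
    chamber_height: float  # um
    rods: list[list[Rod]] | None = None  # per-frame rods, if any
    metadata: dict = dfield(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[-1] != 3:
            raise ValueError("positions must have shape (n_frames, n_particles, 3)")
        if self.frame_interval <= 0:
            raise ValueError("frame interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    def sphere_scene(self, frame: int) -> SphereScene:
        spheres = [
            (tuple(self.positions[frame, i]), float(self.radii[i]), complex(self.indices[i]))
            for i in range(self.n_particles)
        ]
        return SphereScene(spheres=spheres, background_index=self.background_index)

    def to_dataframe(self):
        """Ground-truth positions as a tidy table (frame, particle, z, y, x)."""
        import pandas as pd

        nf, npart, _ = self.positions.shape
        frames = np.repeat(np.arange(nf), npart)
        parts = np.tile(np.arange(npart), nf)
        flat = self.positions.reshape(-1, 3)
        return pd.DataFrame(
            {"frame": frames, "particle": parts, "z": flat[:, 0], "y": flat[:, 1], "x": flat[:, 2]}
        )


# ---------------------------------------------------------------------------
# Brownian dynamics
# ---------------------------------------------------------------------------

def simulate_brownian_scene(
    model: MotionModel,
    n_particles: int,
    n_frames: int,
    dt: float,
    seed: int,
    chamber_height: float = 10.0,
    lateral_extent: float = 20.0,
    particle_index: complex = 1.57,
    background_index: float = 1.333,
    initial_positions: np.ndarray | None = None,
    substeps: int = 1,
) -> DynamicScene:
    """Euler-Maruyama Brownian dynamics with optional wall hindrance and gravity.

    Heights are reflected at the coverslip (h = R) and chamber top
    (h = H - R).  With hindrance on, the axial update includes the Ito
    spurious-drift term dD/dh dt so the stationary height distribution stays
    Boltzmann.  Deterministic for a fixed seed.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    R = model.bead_radius
    hmin, hmax = R, chamber_height - R
    if hmax <= hmin:
        raise ValueError("chamber shorter than a particle diameter")
    if initial_positions is not None:
        pos = np.array(initial_positions, dtype=float)
        if np.any(pos[:, 0] < hmin) or np.any(pos[:, 0] > hmax):
            raise ValueError("initial heights collide with the chamber walls")
    else:
        pos = np.empty((n_particles, 3))
        l_eq = sedimentation_length(model) if model.gravity else np.inf
        if np.isfinite(l_eq):
            # sedimented samples start at their stationary (Boltzmann) height
            # distribution, truncated to the chamber; inverse-CDF sampling
            l_abs, span = abs(l_eq), hmax - hmin
            u = rng.uniform(0, 1, n_particles)
            x = -l_abs * np.log1p(-u * (1 - np.exp(-span / l_abs)))
            pos[:, 0] = hmin + x if l_eq > 0 else hmax - x
        else:
            pos[:, 0] = rng.uniform(hmin, hmax, n_particles)
        pos[:, 1] = rng.uniform(0, lateral_extent, n_particles)
        pos[:, 2] = rng.uniform(0, lateral_extent, n_particles)

    Do = model.diffusion_coefficient
    l_g = sedimentation_length(model) if model.gravity else np.inf
    out = np.empty((n_frames, n_particles, 3))
    out[0] = pos
    h_sub = dt / substeps
    for t in range(1, n_frames):
        for _ in range(substeps):
            h = pos[:, 0]
            if model.hindered:
                D = np.maximum(hindered_parallel_diffusion(Do, R, h), 0.0)
                dDdh = Do * (9.0 / 16.0) * R / h**2
            else:
                D = np.full_like(h, Do)
                dDdh = 0.0
            noise = rng.standard_normal((n_particles, 3))
            step = np.sqrt(2.0 * D * h_sub)[:, None] * noise
            drift_z = (dDdh - D / l_g) * h_sub if np.isfinite(l_g) else dDdh * h_sub
            pos = pos + step
            pos[:, 0] += np.asarray(drift_z) if model.hindered or np.isfinite(l_g) else 0.0
            # reflecting walls
            pos[:, 0] = np.where(pos[:, 0] < hmin, 2 * hmin - pos[:, 0], pos[:, 0])
            pos[:, 0] = np.where(pos[:, 0] > hmax, 2 * hmax - pos[:, 0], pos[:, 0])
            pos[:, 0] = np.clip(pos[:, 0], hmin, hmax)
        out[t] = pos
    return DynamicScene(
        positions=out,
        radii=np.full(n_particles, R),
        indices=np.full(n_particles, complex(particle_index)),
        frame_interval=dt,
        background_index=background_index,
        chamber_height=chamber_height,
        metadata={
            "model": "brownian",
            "Do": Do,
            "hindered": model.hindered,
            "gravity": model.gravity,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# swimmer dynamics
# ---------------------------------------------------------------------------

def _orthonormal_frame(e: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0]) if abs(e[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    n1 = np.cross(e, ref)
    n1 /= np.linalg.norm(n1)
    n2 = np.cross(e, n1)
    return n1, n2


def simulate_swimmer_scene(
    speed: float,
    wobble_angle_true: float,
    n_frames: int,
    dt: float,
    seed: int,
    precession_rate: float = 5.0,  # rev/s of the body axis about the velocity
    direction_diffusion: float = 0.0,  # rad^2/s angular wander of the velocity
    rod_length: float = 2.0,
    rod_radius: float = 0.4,
    rod_index: complex = 1.39,
    background_index: float = 1.333,
    chamber_height: float = 20.0,
    start: Sequence[float] = (10.0, 2.0, 2.0),
) -> DynamicScene:
    """A rod translating along a smoothly varying velocity direction while
    its body axis precesses about the velocity at the prescribed mean
    wobble angle (degrees).  The ground truth angle is kept in metadata."""
    if speed < 0:
        raise ValueError("speed must be >= 0")
    rng = np.random.default_rng(seed)
    theta = np.deg2rad(wobble_angle_true)
    e = np.array([0.0, 1.0, 0.0])
    pos = np.asarray(start, dtype=float).copy()
    positions = np.empty((n_frames, 1, 3))
    rods: list[list[Rod]] = []
    phase = rng.uniform(0, 2 * np.pi)
    for t in range(n_frames):
        n1, n2 = _orthonormal_frame(e)
        axis = np.cos(theta) * e + np.sin(theta) * (np.cos(phase) * n1 + np.sin(phase) * n2)
        axis /= np.linalg.norm(axis)
        positions[t, 0] = pos
        rods.append(
            [Rod(center=pos.copy(), axis=axis, length=rod_length, radius=rod_radius,
                 index=complex(rod_index))]
        )
        pos = pos + speed * dt * e
        phase += 2 * np.pi * precession_rate * dt
        if direction_diffusion > 0:
            sigma = np.sqrt(direction_diffusion * dt)
            de = sigma * (rng.standard_normal() * n1 + rng.standard_normal() * n2)
            e = e + de
            e /= np.linalg.norm(e)
    return DynamicScene(
        positions=positions,
        radii=np.full(1, rod_radius),
        indices=np.full(1, complex(rod_index)),
        frame_interval=dt,
        background_index=background_index,
        chamber_height=chamber_height,
        rods=rods,
        metadata={
            "model": "swimmer",
            "speed": speed,
            "wobble_angle_true": wobble_angle_true,
            "seed": seed,
        },
    )


def rasterize_rods(
    rods: Sequence[Rod],
    shape: tuple[int, int, int],
    voxel_xy: float,
    voxel_z: float,
    background_index: float,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
):
    """Voxelize rods as cylinders with hemispherical caps."""
    from .forward_models import RIVolume

    nz, ny, nx = shape
    oz, oy, ox = origin
    z = oz + np.arange(nz)[:, None, None] * voxel_z
    y = oy + np.arange(ny)[None, :, None] * voxel_xy
    x = ox + np.arange(nx)[None, None, :] * voxel_xy
    vol = np.full(shape, complex(background_index))
    for rod in rods:
        d = np.stack(
            np.broadcast_arrays(z - rod.center[0], y - rod.center[1], x - rod.center[2])
        )
        axial = d[0] * rod.axis[0] + d[1] * rod.axis[1] + d[2] * rod.axis[2]
        half = max(rod.length / 2.0 - rod.radius, 0.0)
        clamped = np.clip(axial, -half, half)
        r2 = (
            (d[0] - clamped * rod.axis[0]) ** 2
            + (d[1] - clamped * rod.axis[1]) ** 2
            + (d[2] - clamped * rod.axis[2]) ** 2
        )
        vol[r2 <= rod.radius**2] = rod.index
    return RIVolume(vol, voxel_xy, voxel_z, background_index)


# ---------------------------------------------------------------------------
# hologram rendering
# ---------------------------------------------------------------------------

def render_hologram_series(
    scene: DynamicScene,
    illum: IlluminationSet,
    shape: tuple[int, int],
    pixel_pitch: float,
    wavelength: float,
    reference_frequency,
    noise: tuple[float | None, float] = (None, 0.0),
    seed: int = 0,
    method: str = "mie",
    volume_thickness: float | None = None,
    voxel_z: float = 0.25,
    detection_na: float | None = None,
) -> list[list[Hologram]]:
    """Render one hologram per (scene frame, illumination frame).

    The field is evaluated in the plane through the volume center (the
    focal plane): Mie superposition fields are computed past the scene and
    refocused; SSNP fields are propagated through the rasterized volume and
    refocused.  ``noise = (photon_count, read_noise)`` sets the photon
    budget of a unit-intensity pixel and the RMS read noise in photons;
    ``photon_count=None`` disables noise.  Deterministic per seed.
    """
    if method not in ("mie", "ssnp"):
        raise ValueError("method must be 'mie' or 'ssnp'")
    rng = np.random.default_rng(seed)
    photon_count, read_noise = noise
    n0 = scene.background_index
    thickness = (
        volume_thickness if volume_thickness is not None else scene.chamber_height
    )
    z_center = thickness / 2.0  # scene heights are in [0, chamber]; field plane mid-volume
    out: list[list[Hologram]] = []
    for t in range(scene.n_frames):
        per_frame: list[Hologram] = []
        if method == "ssnp":
            nz = int(np.ceil(thickness / voxel_z / 2)) * 2
            sph = scene.sphere_scene(t)
            vol = sph.rasterize(
                (nz,) + shape, pixel_pitch, voxel_z, origin=(voxel_z / 2.0, 0.0, 0.0)
            )
            if np.any(scene.positions[t, :, 0] > thickness) or np.any(
                scene.positions[t, :, 0] < 0
            ):
                raise ValueError("scene particles fall outside the simulation volume")
        for beams in illum.beams_per_frame:
            if method == "mie":
                top = float(np.max(scene.positions[t, :, 0] + scene.radii)) + 0.5
                field = None
                sph = scene.sphere_scene(t)
                for b in beams:
                    fb = mie_scattered_field(
                        _shift_scene_z(sph, -z_center), b, top - z_center,
                        shape, pixel_pitch, wavelength,
                    )
                    field = fb if field is None else field.with_values(field.values + fb.values)
                field = angular_spectrum_propagate(field, -(top - z_center))
            else:
                inc_vals = np.zeros(shape, dtype=complex)
                for b in beams:
                    inc_vals += plane_wave_field(
                        b, shape, pixel_pitch, wavelength, n0, z_position=-thickness / 2.0
                    ).values
                inc = ComplexField(inc_vals, pixel_pitch, wavelength, n0, -thickness / 2.0)
                cfg = PropagationConfig(model="ssnp", boundary="periodic", padding_factor=1)
                exit_field = ssnp_propagate(vol, inc, cfg)
                field = angular_spectrum_propagate(exit_field, -thickness / 2.0)
            na = detection_na if detection_na is not None else min(n0, 1.0)
            field = apply_detection_pupil(field, na)
            holo = synthesize_hologram(field, reference_frequency)
            if photon_count is not None and np.isfinite(photon_count):
                counts = rng.poisson(np.maximum(holo.intensity, 0.0) * photon_count)
                intensity = counts / photon_count
                if read_noise > 0:
                    intensity = intensity + read_noise / photon_count * rng.standard_normal(
                        intensity.shape
                    )
                holo = Hologram(
                    intensity=np.maximum(intensity, 0.0),
                    reference_frequency=holo.reference_frequency,
                    pixel_pitch=holo.pixel_pitch,
                    wavelength=holo.wavelength,
                    background_index=holo.background_index,
                )
            per_frame.append(holo)
        out.append(per_frame)
    return out


def _shift_scene_z(scene: SphereScene, dz: float) -> SphereScene:
    return SphereScene(
        spheres=[((c[0] + dz, c[1], c[2]), r, n) for (c, r, n) in scene.spheres],
        background_index=scene.background_index,
    )
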