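"""Design and render DMD spot patterns encoding multiplexed plane-wave illumination.

In Fourier-synthesis ODT the DMD sits in a plane conjugate to the objective
back focal plane.  A circular "spot" of ON mirrors with a superimposed binary
carrier grating encodes one illumination plane wave: the spot *position* on
the DMD sets the beam's spatial frequency (angle) in the sample, while the
spot's *carrier frequency* sets the beam's lateral position.  With focal
length ``fl``, DMD-to-BFP magnification ``M`` and vacuum wavelength ``lam``::

    position offset   dr = (fl * lam / M) * (fp - fc)
    object frequency  f  = (M / (fl * lam)) * (rp - rc)

where ``fp``/``rp`` are the spot carrier frequency and position and
``fc``/``rc`` the system carrier frequency and optical-axis pivot.

Conventions
-----------
All 2-vectors are ``(y, x)`` ordered (matching numpy array axes); DMD mirror
indices are 0-based ``(row, col)``; positions on the DMD face are in microns,
DMD spatial frequencies in cycles/micron, object-space frequencies in
cycles/micron, sample-plane offsets in microns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "SystemGeometry",
    "SpotSpec",
    "PlaneWaveSpec",
    "DMDFrame",
    "IlluminationSet",
    "BeamOutsidePupilError",
    "OutOfDeviceError",
    "OverlappingSpotsError",
    "spot_to_beam",
    "beam_to_spot",
    "render_dmd_frame",
    "design_angle_set",
    "partition_angles",
    "compose_position_multiplex",
    "save_illumination_set",
    "load_illumination_set",
]


class BeamOutsidePupilError(ValueError):
    """A requested beam falls outside the illumination pupil."""


class OutOfDeviceError(ValueError):
    """A requested spot position falls off the DMD face."""


class OverlappingSpotsError(ValueError):
    """Two spot discs in one frame overlap, corrupting carrier purity."""


def _vec2(v) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (2,):
        raise ValueError(f"expected a 2-vector, got shape {a.shape}")
    return a


@dataclass(frozen=True)
class SystemGeometry:
    """Optical geometry linking the DMD plane to object space.

    Parameters use microns throughout except ``objective_focal_length``
    which is given in millimetres (converted internally).
    """

    objective_focal_length: float  # mm
    magnification_dmd_to_bfp: float
    wavelength: float  # um, vacuum
    carrier_frequency: Sequence[float]  # (y, x) cycles/um on the DMD
    dmd_center: Sequence[float]  # (y, x) um on the DMD face
    mirror_pitch: float  # um
    dmd_shape: tuple[int, int] = (1080, 1920)
    illumination_na: float = 1.0
    detection_na: float = 1.0
    background_index: float = 1.333

    def __post_init__(self):
        object.__setattr__(self, "carrier_frequency", _vec2(self.carrier_frequency))
        object.__setattr__(self, "dmd_center", _vec2(self.dmd_center))
        if self.objective_focal_length <= 0 or self.wavelength <= 0 or self.mirror_pitch <= 0:
            raise ValueError("lengths must be positive")
        if self.magnification_dmd_to_bfp <= 0:
            raise ValueError("magnification must be positive")
        for na in (self.illumination_na, self.detection_na):
            if not 0 < na <= self.background_index:
                raise ValueError("NA values must satisfy 0 < NA <= background index")
        nyq = 1.0 / (2.0 * self.mirror_pitch)
        if np.linalg.norm(self.carrier_frequency) >= nyq:
            raise ValueError("carrier frequency at or above the DMD Nyquist limit")

    @property
    def focal_length_um(self) -> float:
        return self.objective_focal_length * 1e3

    @property
    def freq_to_offset(self) -> float:
        """fl*lam/M in um^2: DMD carrier shift (1/um) -> sample offset (um)."""
        return self.focal_length_um * self.wavelength / self.magnification_dmd_to_bfp

    @property
    def pupil_radius_dmd(self) -> float:
        """Illumination pupil radius mapped onto the DMD face (um)."""
        return self.focal_length_um * self.illumination_na / self.magnification_dmd_to_bfp

    @property
    def max_object_frequency(self) -> float:
        """Illumination pupil radius in object space, NA/lambda (1/um)."""
        return self.illumination_na / self.wavelength


@dataclass(frozen=True)
class SpotSpec:
    """One DMD spot: carrier frequency, position, phase and diameter."""

    spot_frequency: Sequence[float]  # (y, x) cycles/um on the DMD
    spot_position: Sequence[float]  # (y, x) um on the DMD face
    phase: float = 0.0  # rad
    diameter: float = 20.0  # mirrors

    def __post_init__(self):
        object.__setattr__(self, "spot_frequency", _vec2(self.spot_frequency))
        object.__setattr__(self, "spot_position", _vec2(self.spot_position))
        if self.diameter < 0:
            raise ValueError("spot diameter must be >= 0 mirrors")


@dataclass(frozen=True)
class PlaneWaveSpec:
    """One illumination plane wave in object space."""

    object_frequency: Sequence[float]  # (y, x) cycles/um in the sample
    position_offset: Sequence[float] = (0.0, 0.0)  # (y, x) um
    phase: float = 0.0
    amplitude: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "object_frequency", _vec2(self.object_frequency))
        object.__setattr__(self, "position_offset", _vec2(self.position_offset))


@dataclass
class DMDFrame:
    """Rendered binary mirror frame plus the spots that generated it."""

    mirrors: np.ndarray
    spots: list[SpotSpec] = field(default_factory=list)


@dataclass
class IlluminationSet:
    """An ordered sequence of DMD frames and the beams each one launches."""

    frames: list[DMDFrame]
    beams_per_frame: list[list[PlaneWaveSpec]]
    angle_multiplex: int = 1
    position_multiplex: int = 1

    def __post_init__(self):
        if len(self.frames) != len(self.beams_per_frame):
            raise ValueError("frames and beams_per_frame length mismatch")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def total_beams(self) -> int:
        return sum(len(b) for b in self.beams_per_frame)

    def distinct_beams_in_frame(self, i: int) -> int:
        seen = {
            (tuple(np.round(b.object_frequency, 9)), tuple(np.round(b.position_offset, 9)))
            for b in self.beams_per_frame[i]
        }
        return len(seen)


# ---------------------------------------------------------------------------
# spot <-> beam mapping
# ---------------------------------------------------------------------------

def spot_to_beam(spot: SpotSpec, geom: SystemGeometry) -> PlaneWaveSpec:
    """Map a DMD spot to the plane wave it launches in object space."""
    dr = geom.freq_to_offset * (spot.spot_frequency - geom.carrier_frequency)
    f = (spot.spot_position - geom.dmd_center) / geom.freq_to_offset
    fmag = float(np.linalg.norm(f))
    if fmag > geom.max_object_frequency * (1 + 1e-9):
        raise BeamOutsidePupilError(
            f"spot at {spot.spot_position} maps to |f| = {fmag:.4g}/um outside the "
            f"illumination pupil ({geom.max_object_frequency:.4g}/um)"
        )
    return PlaneWaveSpec(object_frequency=f, position_offset=dr, phase=spot.phase)


def beam_to_spot(beam: PlaneWaveSpec, geom: SystemGeometry, diameter: float = 20.0) -> SpotSpec:
    """Inverse of :func:`spot_to_beam` (diameter supplied separately)."""
    fmag = float(np.linalg.norm(beam.object_frequency))
    if fmag > geom.max_object_frequency * (1 + 1e-9):
        raise BeamOutsidePupilError(f"beam |f| = {fmag:.4g}/um outside the pupil")
    rp = geom.dmd_center + geom.freq_to_offset * beam.object_frequency
    fp = geom.carrier_frequency + beam.position_offset / geom.freq_to_offset
    extent = np.asarray(geom.dmd_shape, float) * geom.mirror_pitch
    if np.any(rp < 0) or np.any(rp > extent):
        raise OutOfDeviceError(f"spot position {rp} um falls off the DMD face {extent} um")
    return SpotSpec(spot_frequency=fp, spot_position=rp, phase=beam.phase, diameter=diameter)


# ---------------------------------------------------------------------------
# frame rendering
# ---------------------------------------------------------------------------

def render_dmd_frame(
    spots: Sequence[SpotSpec],
    geom: SystemGeometry,
    overlap_policy: str = "error",
) -> DMDFrame:
    """Render spots as a binary mirror frame.

    A mirror is ON iff it lies inside a spot disc and that spot's thresholded
    carrier ``cos(2 pi fp . r + phi) >= 0``.  Overlapping discs either raise
    (default) or are OR-combined (``overlap_policy='union'``).
    """
    if len(spots) == 0:
        raise ValueError("spots must be non-empty")
    if overlap_policy not in ("error", "union"):
        raise ValueError("overlap_policy must be 'error' or 'union'")
    if overlap_policy == "error":
        for i in range(len(spots)):
            for j in range(i + 1, len(spots)):
                sep = np.linalg.norm(spots[i].spot_position - spots[j].spot_position)
                if sep * 2 < (spots[i].diameter + spots[j].diameter) * geom.mirror_pitch:
                    raise OverlappingSpotsError(
                        f"spot discs {i} and {j} overlap (separation {sep:.3g} um)"
                    )
    ny, nx = geom.dmd_shape
    yy = np.arange(ny)[:, None] * geom.mirror_pitch
    xx = np.arange(nx)[None, :] * geom.mirror_pitch
    mirrors = np.zeros((ny, nx), dtype=bool)
    for s in spots:
        if s.diameter == 0:
            continue
        r2 = (yy - s.spot_position[0]) ** 2 + (xx - s.spot_position[1]) ** 2
        disc = r2 <= (s.diameter * geom.mirror_pitch / 2.0) ** 2
        carrier = np.cos(
            2 * np.pi * (s.spot_frequency[0] * yy + s.spot_frequency[1] * xx) + s.phase
        )
        mirrors |= disc & (carrier >= 0)
    return DMDFrame(mirrors=mirrors.astype(np.uint8), spots=list(spots))


# ---------------------------------------------------------------------------
# angle-set design
# ---------------------------------------------------------------------------

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def design_angle_set(n_angles: int, geom: SystemGeometry) -> list[PlaneWaveSpec]:
    """Quasi-uniform Fermat-spiral (sunflower) layout of illumination directions.

    Deterministic; point ``i`` sits at radius ``fmax * sqrt((i + 1/2)/n)``
    and azimuth ``i * golden angle``, giving near-uniform pairwise spacing
    across the pupil disc.  A single angle degenerates to the on-axis beam.
    """
    if n_angles < 1:
        raise ValueError("n_angles must be >= 1")
    fmax = geom.max_object_frequency
    if n_angles == 1:
        return [PlaneWaveSpec(object_frequency=(0.0, 0.0))]
    beams = []
    for i in range(n_angles):
        r = fmax * np.sqrt((i + 0.5) / n_angles)
        th = i * _GOLDEN_ANGLE
        beams.append(PlaneWaveSpec(object_frequency=(r * np.sin(th), r * np.cos(th))))
    return beams


# ---------------------------------------------------------------------------
# multiplex partitioning
# ---------------------------------------------------------------------------

def _capped_loss(frames_f: list[np.ndarray], cap: float) -> float:
    """Average over frames of mean pairwise capped within-frame distance."""
    tot, cnt = 0.0, 0
    for pts in frames_f:
        m = len(pts)
        if m < 2:
            continue
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        iu = np.triu_indices(m, k=1)
        tot += np.minimum(d[iu], cap).sum()
        cnt += len(iu[0])
    return tot / cnt if cnt else 0.0


def partition_angles(
    angles: Sequence[PlaneWaveSpec],
    multiplex: int,
    seed: int = 0,
    geom: SystemGeometry | None = None,
    distance_cap: float | None = None,
    n_sweeps: int = 5,
    swaps_per_sweep: int = 300,
    loss_history: list | None = None,
    render_frames: bool = False,
) -> IlluminationSet:
    """Partition an angle set into multiplexed frames.

    Frames are seeded by farthest-point initialization (each frame greedily
    collects the angle maximizing its minimum DMD-plane distance to those
    already chosen; ties go to the lowest index), the last frame is filled by
    duplicating angles when ``N`` is not divisible by ``multiplex``, and the
    partition is then refined by ``n_sweeps`` rounds of ``swaps_per_sweep``
    random pairwise swaps, keeping a swap iff it increases the average
    capped within-frame distance.  Deterministic for a fixed seed.
    """
    angles = list(angles)
    n = len(angles)
    if multiplex < 1:
        raise ValueError("multiplex must be >= 1")
    if multiplex > n:
        raise ValueError(f"multiplex ({multiplex}) exceeds number of angles ({n})")

    # distances measured between spot positions on the DMD; with no geometry
    # supplied the object-frequency plane is an equivalent (scaled) metric
    scale = geom.freq_to_offset if geom is not None else 1.0
    pos = np.array([b.object_frequency for b in angles]) * scale
    if distance_cap is None:
        # a cap well below the pupil radius makes the average sensitive to
        # the closest pairs, which is what limits Rytov demultiplexing
        pupil = geom.pupil_radius_dmd if geom is not None else float(
            np.linalg.norm(pos, axis=1).max() or 1.0
        )
        distance_cap = 0.3 * pupil

    n_frames = int(np.ceil(n / multiplex))
    frame_idx: list[list[int]] = []
    remaining = list(range(n))
    for _ in range(n_frames):
        chosen: list[int] = []
        pool = remaining if remaining else []
        for _ in range(multiplex):
            if not pool:
                # last frame short: duplicate angles not already in this frame
                pool = [i for i in range(n) if i not in chosen]
            if not chosen:
                pick = pool[0]
            else:
                cpos = pos[chosen]
                dmin = np.array(
                    [np.linalg.norm(cpos - pos[i], axis=1).min() for i in pool]
                )
                pick = pool[int(np.argmax(dmin))]  # argmax -> lowest index on ties
            chosen.append(pick)
            if pick in remaining:
                remaining.remove(pick)
            pool = remaining
        frame_idx.append(chosen)

    rng = np.random.default_rng(seed)
    if multiplex > 1 and n_frames > 1:
        loss = _capped_loss([pos[ix] for ix in frame_idx], distance_cap)
        if loss_history is not None:
            loss_history.append(loss)
        for _ in range(n_sweeps):
            for _ in range(swaps_per_sweep):
                fa, fb = rng.choice(n_frames, size=2, replace=False)
                sa = int(rng.integers(multiplex))
                sb = int(rng.integers(multiplex))
                ia, ib = frame_idx[fa][sa], frame_idx[fb][sb]
                if ia == ib or ib in frame_idx[fa] or ia in frame_idx[fb]:
                    continue
                frame_idx[fa][sa], frame_idx[fb][sb] = ib, ia
                new_loss = _capped_loss([pos[ix] for ix in frame_idx], distance_cap)
                if new_loss > loss:
                    loss = new_loss
                    if loss_history is not None:
                        loss_history.append(loss)
                else:
                    frame_idx[fa][sa], frame_idx[fb][sb] = ia, ib

    frames, beams_per_frame = [], []
    for ix in frame_idx:
        beams = [angles[i] for i in ix]
        beams_per_frame.append(beams)
        if geom is not None and render_frames:
            spots = [beam_to_spot(b, geom) for b in beams]
            frames.append(render_dmd_frame(spots, geom, overlap_policy="union"))
        elif geom is not None:
            spots = [beam_to_spot(b, geom) for b in beams]
            frames.append(DMDFrame(mirrors=np.zeros((0, 0), np.uint8), spots=spots))
        else:
            frames.append(DMDFrame(mirrors=np.zeros((0, 0), np.uint8), spots=[]))
    return IlluminationSet(
        frames=frames,
        beams_per_frame=beams_per_frame,
        angle_multiplex=multiplex,
        position_multiplex=1,
    )


def compose_position_multiplex(
    angle_set: IlluminationSet,
    carrier_frequencies: Sequence[Sequence[float]],
    geom: SystemGeometry,
    render_frames: bool = False,
) -> IlluminationSet:
    """Replicate every frame's beams once per carrier frequency.

    Each carrier shifts the replicated beams laterally by
    ``(fl lam / M)(fp - fc)``, tiling the field of view while keeping the
    angle set fixed.
    """
    carriers = [_vec2(c) for c in carrier_frequencies]
    nyq = 1.0 / (2.0 * geom.mirror_pitch)
    for c in carriers:
        if np.linalg.norm(c) >= nyq:
            raise ValueError("carrier frequency at or above the DMD Nyquist limit")
    for i in range(len(carriers)):
        for j in range(i + 1, len(carriers)):
            if np.allclose(carriers[i], carriers[j]):
                raise ValueError(f"carrier collision between entries {i} and {j}")

    frames, beams_per_frame = [], []
    for fr, beams in zip(angle_set.frames, angle_set.beams_per_frame):
        new_beams: list[PlaneWaveSpec] = []
        new_spots: list[SpotSpec] = []
        for c in carriers:
            dr = geom.freq_to_offset * (c - geom.carrier_frequency)
            for b in beams:
                new_beams.append(replace(b, position_offset=b.position_offset + dr))
            for s in fr.spots:
                new_spots.append(replace(s, spot_frequency=np.asarray(c)))
        if new_spots and render_frames:
            frames.append(render_dmd_frame(new_spots, geom, overlap_policy="union"))
        else:
            frames.append(DMDFrame(mirrors=np.zeros((0, 0), np.uint8), spots=new_spots))
        beams_per_frame.append(new_beams)
    return IlluminationSet(
        frames=frames,
        beams_per_frame=beams_per_frame,
        angle_multiplex=angle_set.angle_multiplex,
        position_multiplex=len(carriers),
    )


# ---------------------------------------------------------------------------
# serialization: one text record per beam
# ---------------------------------------------------------------------------

def save_illumination_set(path, illum: IlluminationSet) -> None:
    """Write one CSV record per beam: frame, fy, fx, dry, drx, phase, amplitude."""
    with open(path, "w") as fh:
        fh.write("frame,fy,fx,dry,drx,phase,amplitude\n")
        for i, beams in enumerate(illum.beams_per_frame):
            for b in beams:
                fh.write(
                    f"{i},{float(b.object_frequency[0])!r},{float(b.object_frequency[1])!r},"
                    f"{float(b.position_offset[0])!r},{float(b.position_offset[1])!r},"
                    f"{float(b.phase)!r},{float(b.amplitude)!r}\n"
                )


def load_illumination_set(path) -> IlluminationSet:
    """Read the CSV written by :func:`save_illumination_set` (no rendered frames)."""
    import csv

    per_frame: dict[int, list[PlaneWaveSpec]] = {}
    with open(path) as fh:
        for row in csv.DictReader(fh):
            per_frame.setdefault(int(row["frame"]), []).append(
                PlaneWaveSpec(
                    object_frequency=(float(row["fy"]), float(row["fx"])),
                    position_offset=(float(row["dry"]), float(row["drx"])),
                    phase=float(row["phase"]),
                    amplitude=float(row["amplitude"]),
                )
            )
    order = sorted(per_frame)
    beams_per_frame = [per_frame[i] for i in order]
    frames = [DMDFrame(mirrors=np.zeros((0, 0), np.uint8), spots=[]) for _ in order]
    mux = max(len(b) for b in beams_per_frame) if beams_per_frame else 1
    return IlluminationSet(frames=frames, beams_per_frame=beams_per_frame, angle_multiplex=mux)
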