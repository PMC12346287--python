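"""Dataset/config I/O and the pipeline driver tying all stages together.

Hologram stacks are stored as multi-page TIFF next to a JSON acquisition
descriptor (wavelength, background index, pixel pitch, reference frequency,
per-frame beam lists, frame timing).  Every pipeline output is written with
a JSON provenance sidecar recording the parameters, seeds and package
version that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field as dfield
from pathlib import Path

import numpy as np
import tifffile

from . import __version__
from .dmd_patterns import IlluminationSet, PlaneWaveSpec, load_illumination_set, save_illumination_set
from .forward_models import RIVolume
from .holography import Hologram

logger = logging.getLogger(__name__)

__all__ = [
    "AcquisitionDescriptor",
    "save_dataset",
    "load_dataset",
    "save_volume",
    "load_volume",
    "write_provenance",
    "run_pipeline",
    "validation_sphere_study",
]


def validation_sphere_study(
    n_angles: int = 49,
    n_iter: int = 40,
    seed: int = 0,
    grid: int = 128,
    pixel_pitch: float = 0.15,
    camera_oversample: int = 2,
    n_slices: int = 64,
    voxel_z: float = 0.25,
    wavelength: float = 0.785,
    background_index: float = 1.515,
    sphere_index: float = 1.57,
    sphere_radius: float = 5.0,
    na: float = 1.0,
    multiplex: int = 1,
    tv_weight: float = 1e-4,
) -> dict:
    """Reconstruct the 10-um polystyrene-in-oil validation microsphere.

    Generates noiseless off-axis holograms of the sphere with the exact
    scalar Mie series on an oversampled camera grid, demodulates them,
    initializes with Rytov demultiplexing and refines with FISTA over the
    SSNP forward model.  Returns the reconstruction together with the
    median interior refractive index and the equatorial full width at half
    maximum of the RI profile (the recovered diameter).
    """
    from .dmd_patterns import PlaneWaveSpec, SystemGeometry, design_angle_set, partition_angles
    from .forward_models import (
        PropagationConfig,
        SphereScene,
        angular_spectrum_propagate,
        apply_detection_pupil,
        mie_scattered_field,
    )
    from .holography import demodulate_hologram, fourier_downsample, synthesize_hologram
    from .iterative_recon import (
        LossConfig,
        RegConfig,
        fista_solve,
        incident_fields_for_frames,
        refocus_to_exit,
    )
    from .linear_recon import demultiplex_rytov_initialize

    lam, n0 = wavelength, background_index
    N, p = grid, pixel_pitch
    Nh, ph = grid * camera_oversample, pixel_pitch / camera_oversample
    nz, dz = n_slices, voxel_z
    thickness = nz * dz
    cx = N // 2 * p
    scene = SphereScene([((0.0, cx, cx), sphere_radius, sphere_index)], n0)

    geom = SystemGeometry(
        objective_focal_length=4.0, magnification_dmd_to_bfp=2.0, wavelength=lam,
        carrier_frequency=(0.03, 0.03), dmd_center=(4000.0, 4000.0), mirror_pitch=7.56,
        illumination_na=na, detection_na=na, background_index=n0,
    )
    df = 1.0 / (N * p)
    seen, angles = set(), []
    for b in design_angle_set(n_angles, geom):
        f = np.round(np.asarray(b.object_frequency) * 0.98 / df) * df
        key = tuple(np.round(f, 9))
        if key not in seen:
            seen.add(key)
            angles.append(PlaneWaveSpec(object_frequency=f))
    if multiplex > 1:
        illum = partition_angles(angles, multiplex, seed=seed)
        beams_per_frame = illum.beams_per_frame
    else:
        beams_per_frame = [[b] for b in angles]

    # grid-aligned tilted reference on the camera grid
    dfh = 1.0 / (Nh * ph)
    fref = (np.round(3.0 / dfh) * dfh, np.round(3.0 / dfh) * dfh)
    fb = na / lam
    top = sphere_radius + 0.7
    fields = []
    for beams in beams_per_frame:
        F = None
        for b in beams:
            E = mie_scattered_field(scene, b, top, (Nh, Nh), ph, lam)
            F = E if F is None else F.with_values(F.values + E.values)
        F = apply_detection_pupil(angular_spectrum_propagate(F, -top), na)
        holo = synthesize_hologram(F, fref)
        Ed = demodulate_hologram(holo, fb * 1.05)
        fields.append(fourier_downsample(Ed, (N, N)))

    init = demultiplex_rytov_initialize(
        fields, beams_per_frame, (nz, N, N), dz, detection_na=na
    )
    cfg = PropagationConfig(model="ssnp", boundary="periodic", padding_factor=1,
                            pupil_na=na)
    data_exit = [refocus_to_exit(f, thickness) for f in fields]
    incident = incident_fields_for_frames(beams_per_frame, (N, N), p, lam, n0,
                                          z_entrance=-thickness / 2.0)
    vol, history = fista_solve(
        init, data_exit, incident, cfg, loss=LossConfig(),
        reg=RegConfig(tv_weight=tv_weight), n_iter=n_iter, tol=0,
    )

    re = vol.index.real
    z = (np.arange(nz) - nz / 2 + 0.5)[:, None, None] * dz
    y = (np.arange(N) - N / 2)[None, :, None] * p
    x = (np.arange(N) - N / 2)[None, None, :] * p
    interior = z**2 + y**2 + x**2 <= (0.8 * sphere_radius) ** 2
    median_ri = float(np.median(re[interior]))

    prof = re[nz // 2, N // 2, :] - n0
    half = prof.max() / 2.0
    above = np.where(prof >= half)[0]
    # sub-pixel FWHM by linear interpolation at the half-maximum crossings
    lo, hi = above[0], above[-1]
    left = lo - (prof[lo] - half) / max(prof[lo] - prof[lo - 1], 1e-30) if lo > 0 else lo
    right = hi + (prof[hi] - half) / max(prof[hi] - prof[hi + 1], 1e-30) if hi < N - 1 else hi
    fwhm = float((right - left) * p)
    return {
        "volume": vol,
        "median_interior_ri": median_ri,
        "fwhm_diameter_um": fwhm,
        "objective_history": history,
        "n_beams": len(angles),
    }


@dataclass
class AcquisitionDescriptor:
    wavelength: float  # um
    background_index: float
    pixel_pitch: float  # um, sample-referred
    reference_frequency: tuple[float, float]  # (y, x) cycles/um
    frames_per_volume: int
    volumetric_rate: float = 1.0  # Hz
    beams_per_frame: list | None = None  # nested [[{fy, fx, dry, drx, phase, amplitude}]]

    def validate(self, n_pages: int | None = None):
        if self.wavelength <= 0 or self.pixel_pitch <= 0:
            raise ValueError("wavelength and pixel pitch must be positive")
        if self.beams_per_frame is not None and len(self.beams_per_frame) != self.frames_per_volume:
            raise ValueError(
                f"descriptor lists {len(self.beams_per_frame)} beam frames but "
                f"frames_per_volume = {self.frames_per_volume}"
            )
        if n_pages is not None and n_pages % self.frames_per_volume:
            raise ValueError(
                f"{n_pages} hologram pages are not a whole number of "
                f"{self.frames_per_volume}-frame volumes"
            )

    def illumination(self) -> IlluminationSet:
        from .dmd_patterns import DMDFrame

        if self.beams_per_frame is None:
            raise ValueError("descriptor carries no beam lists")
        beams = [
            [
                PlaneWaveSpec(
                    object_frequency=(b["fy"], b["fx"]),
                    position_offset=(b.get("dry", 0.0), b.get("drx", 0.0)),
                    phase=b.get("phase", 0.0),
                    amplitude=b.get("amplitude", 1.0),
                )
                for b in frame
            ]
            for frame in self.beams_per_frame
        ]
        frames = [DMDFrame(mirrors=np.zeros((0, 0), np.uint8), spots=[]) for _ in beams]
        return IlluminationSet(
            frames=frames, beams_per_frame=beams,
            angle_multiplex=max(len(b) for b in beams),
        )


def _illum_to_beam_lists(illum: IlluminationSet) -> list:
    return [
        [
            {
                "fy": float(b.object_frequency[0]),
                "fx": float(b.object_frequency[1]),
                "dry": float(b.position_offset[0]),
                "drx": float(b.position_offset[1]),
                "phase": float(b.phase),
                "amplitude": float(b.amplitude),
            }
            for b in beams
        ]
        for beams in illum.beams_per_frame
    ]


def save_dataset(path, holograms: list[Hologram], descriptor: AcquisitionDescriptor) -> None:
    """Write holograms as multi-page TIFF plus a JSON descriptor sidecar."""
    path = Path(path)
    stack = np.stack([h.intensity for h in holograms]).astype(np.float32)
    tifffile.imwrite(path, stack)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(asdict(descriptor), fh, indent=1)


def load_dataset(path, descriptor: AcquisitionDescriptor | None = None):
    """Load a hologram stack and its illumination; validates metadata."""
    path = Path(path)
    if descriptor is None:
        with open(path.with_suffix(".json")) as fh:
            d = json.load(fh)
        d["reference_frequency"] = tuple(d["reference_frequency"])
        descriptor = AcquisitionDescriptor(**d)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    descriptor.validate(n_pages=len(stack))
    holos = [
        Hologram(
            intensity=np.asarray(page, dtype=float),
            reference_frequency=np.asarray(descriptor.reference_frequency),
            pixel_pitch=descriptor.pixel_pitch,
            wavelength=descriptor.wavelength,
            background_index=descriptor.background_index,
        )
        for page in stack
    ]
    logger.info("loaded %d hologram pages of shape %s", len(holos), holos[0].intensity.shape)
    return holos, descriptor.illumination()


def save_volume(path, volume: RIVolume) -> None:
    """Complex RI volume as a 2-channel (real, imag) OME-TIFF with pixel sizes."""
    path = Path(path)
    data = np.stack([volume.index.real, volume.index.imag]).astype(np.float32)
    tifffile.imwrite(
        path, data,
        metadata={
            "axes": "CZYX",
            "voxel_xy_um": volume.voxel_xy,
            "voxel_z_um": volume.voxel_z,
            "background_index": volume.background_index,
        },
    )
    with open(path.with_suffix(".meta.json"), "w") as fh:
        json.dump(
            {
                "voxel_xy": volume.voxel_xy,
                "voxel_z": volume.voxel_z,
                "background_index": volume.background_index,
            },
            fh,
        )


def load_volume(path) -> RIVolume:
    path = Path(path)
    data = tifffile.imread(path)
    with open(path.with_suffix(".meta.json")) as fh:
        meta = json.load(fh)
    return RIVolume(
        data[0] + 1j * data[1],
        voxel_xy=meta["voxel_xy"],
        voxel_z=meta["voxel_z"],
        background_index=meta["background_index"],
    )


def write_provenance(path, stage: str, params: dict) -> None:
    """JSON sidecar so every artifact is reproducible from its parameters."""
    rec = {
        "stage": stage,
        "fsodt_version": __version__,
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "params": params,
    }
    with open(Path(path), "w") as fh:
        json.dump(rec, fh, indent=1, default=str)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = {
    "design": ["n_angles", "multiplex", "seed", "geometry"],
    "simulate": ["scene", "seed", "output"],
    "reconstruct": ["input", "shape", "voxel_z", "output"],
    "track": ["input", "max_disp", "output"],
    "analyze": ["input", "dt", "output"],
}


def _check_schema(stage: str, cfg: dict):
    missing = [k for k in _REQUIRED_KEYS.get(stage, []) if k not in cfg]
    if missing:
        raise KeyError(f"stage '{stage}' config missing required keys: {missing}")


def run_pipeline(config_path) -> dict:
    """Execute the stages listed in a JSON config file.

    The config maps stage names (design, simulate, reconstruct, track,
    analyze) to their parameter dictionaries; stages run in that order and
    each writes its outputs plus a provenance sidecar.  Schema errors are
    raised before any compute.
    """
    from .dmd_patterns import SystemGeometry, design_angle_set, partition_angles
    from .iterative_recon import reconstruct_volume
    from .synthetic_data import MotionModel, render_hologram_series, simulate_brownian_scene
    from .tracking_analysis import LocalizeParams, link_trajectories, localize_particles, msd_diffusion

    with open(config_path) as fh:
        config = json.load(fh)
    for stage, cfg in config.items():
        _check_schema(stage, cfg)

    results: dict = {}
    t_start = time.time()
    for stage, cfg in config.items():
        t0 = time.time()
        logger.info("pipeline stage '%s' starting", stage)
        try:
            if stage == "design":
                geom = SystemGeometry(**cfg["geometry"])
                angles = design_angle_set(cfg["n_angles"], geom)
                illum = partition_angles(
                    angles, cfg["multiplex"], seed=cfg["seed"], geom=geom
                )
                out = Path(cfg.get("output", "illumination.csv"))
                save_illumination_set(out, illum)
                write_provenance(out.with_suffix(".prov.json"), stage, cfg)
                results[stage] = {"frames": illum.n_frames, "beams": illum.total_beams}
            elif stage == "simulate":
                sc = cfg["scene"]
                model = MotionModel(
                    diffusion_coefficient=sc.get("D", 0.5),
                    bead_radius=sc.get("radius", 0.5),
                    hindered=sc.get("hindered", False),
                    gravity=sc.get("gravity", False),
                )
                scene = simulate_brownian_scene(
                    model,
                    n_particles=sc.get("n_particles", 3),
                    n_frames=sc.get("n_frames", 16),
                    dt=sc.get("dt", 0.01),
                    seed=cfg["seed"],
                    chamber_height=sc.get("chamber_height", 10.0),
                    lateral_extent=sc.get("lateral_extent", 12.0),
                    background_index=sc.get("background_index", 1.333),
                )
                illum = load_illumination_set(cfg["illumination"]) if "illumination" in cfg else None
                out = Path(cfg["output"])
                scene.to_dataframe().to_csv(out, index=False)
                write_provenance(out.with_suffix(".prov.json"), stage, cfg)
                results[stage] = {"scene": scene}
            elif stage == "reconstruct":
                holos, illum = load_dataset(cfg["input"])
                prov: dict = {}
                vol = reconstruct_volume(
                    holos, illum, tuple(cfg["shape"]), cfg["voxel_z"],
                    n_iter=cfg.get("n_iter", 50), provenance=prov,
                )
                out = Path(cfg["output"])
                save_volume(out, vol)
                write_provenance(out.with_suffix(".prov.json"), stage, {**cfg, **prov})
                results[stage] = {"volume": vol}
            elif stage == "track":
                import pandas as pd

                locs_df = pd.read_csv(cfg["input"])
                from .tracking_analysis import Localization

                per_frame = []
                for f in sorted(locs_df["frame"].unique()):
                    sub = locs_df[locs_df["frame"] == f]
                    per_frame.append(
                        [
                            Localization(
                                position=np.array([r.z, r.y, r.x]),
                                amplitude=getattr(r, "amplitude", 1.0),
                                widths=np.ones(3),
                                residual=0.0,
                                frame=int(f),
                            )
                            for r in sub.itertuples()
                        ]
                    )
                tracks = link_trajectories(
                    per_frame, max_disp=cfg["max_disp"], memory=cfg.get("memory", 0)
                )
                rows = []
                for tr in tracks:
                    for f, p in zip(tr.frames, tr.positions):
                        rows.append(
                            {"track": tr.track_id, "frame": int(f), "z": p[0], "y": p[1], "x": p[2]}
                        )
                import pandas as pd

                out = Path(cfg["output"])
                pd.DataFrame(rows).to_csv(out, index=False)
                write_provenance(out.with_suffix(".prov.json"), stage, cfg)
                results[stage] = {"n_tracks": len(tracks)}
            elif stage == "analyze":
                import pandas as pd

                df = pd.read_csv(cfg["input"])
                from .tracking_analysis import Trajectory

                tracks = []
                for tid, sub in df.groupby("track"):
                    sub = sub.sort_values("frame")
                    tracks.append(
                        Trajectory(
                            int(tid),
                            sub["frame"].to_numpy(),
                            sub[["z", "y", "x"]].to_numpy(),
                        )
                    )
                lags, msd, D = msd_diffusion(tracks, dt=cfg["dt"])
                out = Path(cfg["output"])
                pd.DataFrame({"lag_s": lags, "msd_um2": msd}).to_csv(out, index=False)
                write_provenance(
                    out.with_suffix(".prov.json"), stage, {**cfg, "D_um2_per_s": D}
                )
                results[stage] = {"D": D}
            else:
                raise KeyError(f"unknown pipeline stage '{stage}'")
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
        logger.info("pipeline stage '%s' finished in %.1f s", stage, time.time() - t0)
    logger.info("pipeline finished in %.1f s", time.time() - t_start)
    return results
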