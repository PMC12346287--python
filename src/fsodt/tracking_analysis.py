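"""Particle localization, trajectory linking and dynamics statistics.

The analysis chain mirrors standard colloid-tracking practice: candidate
detection by difference-of-Gaussian filtering plus a maximum filter,
sub-voxel refinement by 3D Gaussian fitting in a 4 x 2 x 2 um region of
interest, greedy nearest-neighbour linking with gap memory, and ensemble
statistics -- mean squared displacement, per-axis step-size CDFs, the
wall-hindered diffusion profile D(h) = Do (1 - (9/16) R/h), Boltzmann
height distributions, and swimmer wobble angles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dfield
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize, stats

from .forward_models import RIVolume
from .synthetic_data import (
    KB,
    G_STANDARD,
    DynamicScene,
    effective_buoyant_mass,
    hindered_parallel_diffusion,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Localization",
    "Trajectory",
    "DiffusionFit",
    "WobbleResult",
    "LocalizeParams",
    "localize_particles",
    "link_trajectories",
    "msd_diffusion",
    "stepsize_cdf",
    "hindered_diffusion_fit",
    "boltzmann_height_fit",
    "wobble_analysis",
    "lag_time",
]


def lag_time(n_frames: int, volumetric_rate_hz: float) -> float:
    """Lag in seconds spanned by ``n_frames`` volumes at the given rate."""
    if volumetric_rate_hz <= 0:
        raise ValueError("rate must be positive")
    return n_frames / volumetric_rate_hz


@dataclass
class Localization:
    position: np.ndarray  # (z, y, x) um
    amplitude: float
    widths: np.ndarray  # (sz, sy, sx) um
    residual: float
    frame: int


@dataclass
class Trajectory:
    track_id: int
    frames: np.ndarray  # strictly increasing
    positions: np.ndarray  # (n, 3) um

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.frames) != len(self.positions):
            raise ValueError("frames/positions length mismatch")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing within a track")

    def __len__(self):
        return len(self.frames)


@dataclass
class DiffusionFit:
    Do: float
    R: float
    h_centers: np.ndarray
    D_of_h: np.ndarray
    counts: np.ndarray
    covariance: np.ndarray


@dataclass
class WobbleResult:
    wobble_angles: list[float]  # degrees, per track
    speeds: list[np.ndarray]  # smoothed speed series per track
    body_axes: list[np.ndarray]
    velocities: list[np.ndarray]


# ---------------------------------------------------------------------------
# localization
# ---------------------------------------------------------------------------

@dataclass
class LocalizeParams:
    """Detection/fit configuration.

    DoG sigmas default to (0.5x, 1.5x) the expected particle radius; fits
    are kept only when widths fall within ``width_bounds`` times the
    expected sigma and the center stays inside the ROI.
    """

    expected_radius: float = 0.5  # um
    threshold: float = 0.005  # DoG response in RI units
    roi_size: tuple[float, float, float] = (4.0, 2.0, 2.0)  # (z, y, x) um
    width_bounds: tuple[float, float] = (0.3, 3.0)
    axial_elongation: float = 3.0  # missing-cone stretch of the axial width
    max_candidates: int = 10000


def _gauss3d(coords, A, z0, y0, x0, sz, sy, sx, off):
    z, y, x = coords
    return (
        A
        * np.exp(
            -((z - z0) ** 2) / (2 * sz**2)
            - ((y - y0) ** 2) / (2 * sy**2)
            - ((x - x0) ** 2) / (2 * sx**2)
        )
        + off
    )


def localize_particles(
    volume: RIVolume, params: LocalizeParams | None = None, frame: int = 0
) -> list[Localization]:
    """Detect and fit bead-like maxima in the real part of an RI volume."""
    params = params or LocalizeParams()
    data = volume.index.real - volume.background_index
    if not np.all(np.isfinite(data)):
        raise ValueError("volume contains non-finite values")
    vz, vxy = volume.voxel_z, volume.voxel_xy
    s_small = np.array([0.5 * params.expected_radius / vz,
                        0.5 * params.expected_radius / vxy,
                        0.5 * params.expected_radius / vxy])
    s_large = 3.0 * s_small
    dog = ndimage.gaussian_filter(data, s_small) - ndimage.gaussian_filter(data, s_large)
    size = tuple(
        max(3, int(round(2 * params.expected_radius / v)) | 1) for v in (vz, vxy, vxy)
    )
    peaks = (dog == ndimage.maximum_filter(dog, size=size)) & (dog > params.threshold)
    cand = np.argwhere(peaks)
    if len(cand) > params.max_candidates:
        order = np.argsort(dog[peaks])[::-1][: params.max_candidates]
        cand = cand[order]

    half = tuple(
        max(1, int(round(r / (2 * v))))
        for r, v in zip(params.roi_size, (vz, vxy, vxy))
    )
    nzv, nyv, nxv = data.shape
    out: list[Localization] = []
    exp_sigma = params.expected_radius / np.sqrt(3.0)
    exp_w = np.array([params.axial_elongation * exp_sigma, exp_sigma, exp_sigma])
    for (iz, iy, ix) in cand:
        sl = tuple(
            slice(max(0, c - h), min(n, c + h + 1))
            for c, h, n in zip((iz, iy, ix), half, (nzv, nyv, nxv))
        )
        roi = data[sl]
        zz, yy, xx = np.meshgrid(
            (np.arange(sl[0].start, sl[0].stop)) * vz,
            (np.arange(sl[1].start, sl[1].stop)) * vxy,
            (np.arange(sl[2].start, sl[2].stop)) * vxy,
            indexing="ij",
        )
        coords = (zz.ravel(), yy.ravel(), xx.ravel())
        p0 = [
            float(roi.max()), iz * vz, iy * vxy, ix * vxy,
            exp_w[0], exp_w[1], exp_w[2], float(np.median(roi)),
        ]
        lo = [0, zz.min(), yy.min(), xx.min()] + list(
            params.width_bounds[0] * exp_w * 0.99
        ) + [-np.inf]
        hi = [np.inf, zz.max(), yy.max(), xx.max()] + list(
            params.width_bounds[1] * exp_w * 1.01
        ) + [np.inf]
        try:
            popt, _ = optimize.curve_fit(
                _gauss3d, coords, roi.ravel(), p0=p0, bounds=(lo, hi), maxfev=200
            )
        except (RuntimeError, ValueError):
            continue
        A, z0, y0, x0, sz, sy, sx, off = popt
        widths = np.array([sz, sy, sx])
        wb = params.width_bounds
        if not np.all((widths > wb[0] * exp_w) & (widths < wb[1] * exp_w)):
            continue
        resid = float(
            np.sqrt(np.mean((_gauss3d(coords, *popt) - roi.ravel()) ** 2))
        )
        out.append(
            Localization(
                position=np.array([z0, y0, x0]),
                amplitude=float(A),
                widths=widths,
                residual=resid,
                frame=frame,
            )
        )
    return out


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

def link_trajectories(
    locs_per_frame: Sequence[Sequence[Localization]],
    max_disp: float,
    memory: int = 0,
) -> list[Trajectory]:
    """Greedy nearest-neighbour linking with gap closing.

    In every frame, (track, detection) pairs are linked in order of
    increasing Euclidean distance, rejecting links beyond ``max_disp``;
    tracks missing for more than ``memory`` consecutive frames are closed.
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be positive")
    next_id = 0
    active: list[dict] = []  # {'id', 'frames', 'positions', 'last_frame'}
    closed: list[dict] = []
    for fi, locs in enumerate(locs_per_frame):
        # retire stale tracks
        still = []
        for tr in active:
            if fi - tr["last_frame"] > memory + 1:
                closed.append(tr)
            else:
                still.append(tr)
        active = still
        pts = np.array([l.position for l in locs]).reshape(-1, 3)
        used_tr, used_det = set(), set()
        if active and len(pts):
            last = np.array([tr["positions"][-1] for tr in active])
            d = np.linalg.norm(last[:, None, :] - pts[None, :, :], axis=-1)
            order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
            for ti, di in order:
                if d[ti, di] > max_disp:
                    break
                if ti in used_tr or di in used_det:
                    continue
                used_tr.add(ti)
                used_det.add(di)
                active[ti]["frames"].append(fi)
                active[ti]["positions"].append(pts[di])
                active[ti]["last_frame"] = fi
        for di, loc in enumerate(locs):
            if di in used_det:
                continue
            active.append(
                {"id": next_id, "frames": [fi], "positions": [loc.position], "last_frame": fi}
            )
            next_id += 1
    closed.extend(active)
    closed.sort(key=lambda tr: tr["id"])
    return [
        Trajectory(tr["id"], np.array(tr["frames"]), np.array(tr["positions"]))
        for tr in closed
    ]


def scene_to_localizations(scene: DynamicScene) -> list[list[Localization]]:
    """Ground-truth positions of a synthetic scene as per-frame localizations."""
    out = []
    for t in range(scene.n_frames):
        out.append(
            [
                Localization(
                    position=scene.positions[t, i].copy(),
                    amplitude=1.0,
                    widths=np.full(3, float(scene.radii[i])),
                    residual=0.0,
                    frame=t,
                )
                for i in range(scene.n_particles)
            ]
        )
    return out


# ---------------------------------------------------------------------------
# diffusion statistics
# ---------------------------------------------------------------------------

def msd_diffusion(
    tracks: Sequence[Trajectory],
    dt: float,
    stride: int = 1,
    fit_max_lag: float | None = None,
    dim: int = 3,
    overlapping: bool = False,
    max_lag_frames: int | None = None,
):
    """Ensemble- and time-averaged MSD and a diffusion-coefficient fit.

    Lags are multiples of ``stride`` frames; by default displacement windows
    do not overlap, controlling correlations in the linear fit.  The fit is
    a straight line with free intercept (absorbing static localization
    error); the slope gives ``D = slope / (2 * dim)``.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    longest = max((len(t) for t in tracks), default=0)
    if longest < 2 * stride:
        raise ValueError("no track long enough for the requested stride")
    if max_lag_frames is None:
        # the diffusion fit only uses short lags; capping keeps the
        # time-average loop linear in track length
        max_lag_frames = min((longest - 1) // stride, 32) * stride
    lags = np.arange(stride, max_lag_frames + 1, stride)
    sums = np.zeros(len(lags))
    counts = np.zeros(len(lags), dtype=int)
    for tr in tracks:
        # dense resampling keyed by frame index (tracks may contain gaps)
        fmin, fmax = tr.frames[0], tr.frames[-1]
        idx = {f: i for i, f in enumerate(tr.frames)}
        for li, L in enumerate(lags):
            starts = range(fmin, fmax - L + 1, L if not overlapping else 1)
            for s in starts:
                if s in idx and (s + L) in idx:
                    d = tr.positions[idx[s + L]] - tr.positions[idx[s]]
                    sums[li] += float(np.dot(d, d))
                    counts[li] += 1
    valid = counts > 0
    lags_s = lags[valid] * dt
    msd = sums[valid] / counts[valid]
    if fit_max_lag is None:
        fit_max_lag = lags_s[min(4, len(lags_s) - 1)]
    sel = lags_s <= fit_max_lag + 1e-12
    A = np.vstack([lags_s[sel], np.ones(sel.sum())]).T
    slope, intercept = np.linalg.lstsq(A, msd[sel], rcond=None)[0]
    D = slope / (2.0 * dim)
    return lags_s, msd, float(D)


def stepsize_cdf(tracks: Sequence[Trajectory], lag: int, axis: int, dt: float | None = None):
    """Empirical per-axis step-size CDF at a lag plus a Gaussian fit.

    Returns ``(sorted_steps, cdf_values, sigma, ks_distance)``.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1 frame")
    steps = []
    for tr in tracks:
        idx = {f: i for i, f in enumerate(tr.frames)}
        for f in tr.frames:
            if f + lag in idx:
                steps.append(tr.positions[idx[f + lag], axis] - tr.positions[idx[f], axis])
    steps = np.asarray(steps)
    if len(steps) < 50:
        logger.warning("stepsize_cdf: only %d steps at lag %d", len(steps), lag)
    if len(steps) == 0:
        raise ValueError("no steps at the requested lag")
    xs = np.sort(steps)
    cdf = np.arange(1, len(xs) + 1) / len(xs)
    mu = float(np.mean(steps))
    sigma = float(np.std(steps))
    if sigma > 0:
        ks = float(stats.kstest(steps, "norm", args=(mu, sigma)).statistic)
    else:
        ks = 0.0
    return xs, cdf, sigma, ks


def hindered_diffusion_fit(
    tracks: Sequence[Trajectory],
    dt: float,
    bin_edges_h: np.ndarray,
    lag: int = 1,
) -> DiffusionFit:
    """Fit the wall-hindrance law D(h) = Do (1 - (9/16) R/h).

    Lateral short-lag squared displacements are binned by the mean height
    of each step; a weighted least-squares line in 1/h yields (Do, Do*R*9/16)
    and hence (Do, R).
    """
    edges = np.asarray(bin_edges_h, dtype=float)
    if len(edges) < 4:
        raise ValueError("need at least 3 height bins")
    nb = len(edges) - 1
    sums = np.zeros(nb)
    counts = np.zeros(nb, dtype=int)
    hsums = np.zeros(nb)
    for tr in tracks:
        idx = {f: i for i, f in enumerate(tr.frames)}
        for f in tr.frames:
            if f + lag not in idx:
                continue
            p0, p1 = tr.positions[idx[f]], tr.positions[idx[f + lag]]
            h = 0.5 * (p0[0] + p1[0])
            b = np.searchsorted(edges, h) - 1
            if 0 <= b < nb:
                d2 = (p1[1] - p0[1]) ** 2 + (p1[2] - p0[2]) ** 2
                sums[b] += d2
                counts[b] += 1
                hsums[b] += h
    filled = counts > 0
    if filled.sum() < 2:
        raise ValueError("height samples span too few bins; fit underdetermined")
    D_of_h = np.zeros(nb)
    D_of_h[filled] = sums[filled] / counts[filled] / (4.0 * dt * lag)
    h_centers = np.where(filled, np.divide(hsums, np.maximum(counts, 1)), 0.5 * (edges[:-1] + edges[1:]))
    xi = 1.0 / h_centers[filled]
    w = counts[filled].astype(float)
    A = np.vstack([np.ones_like(xi), -xi]).T * np.sqrt(w)[:, None]
    b = D_of_h[filled] * np.sqrt(w)
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    Do, slope = coef  # D = Do - slope / h, slope = (9/16) Do R
    R = 16.0 * slope / (9.0 * Do) if Do != 0 else np.nan
    AtA_inv = np.linalg.pinv(A.T @ A)
    resid = b - A @ coef
    dof = max(len(b) - 2, 1)
    cov = AtA_inv * float(resid @ resid) / dof
    return DiffusionFit(
        Do=float(Do), R=float(R), h_centers=h_centers[filled],
        D_of_h=D_of_h[filled], counts=counts[filled], covariance=cov,
    )


def boltzmann_height_fit(
    tracks: Sequence[Trajectory],
    particle_radius: float,
    bead_density: float,
    solvent_density: float,
    temperature: float = 295.65,
) -> tuple[float, float]:
    """Fit the sedimentation height distribution; returns (m_fit, m_expected) in kg.

    Heights above the contact height ``h - R`` follow ``exp(-(h-R)/l)``
    with ``l = kB T / (m g)``; the maximum-likelihood ``l`` is the mean
    excess height.  ``m_expected`` is the closed-form buoyant mass.
    """
    heights = np.concatenate([tr.positions[:, 0] for tr in tracks])
    if len(heights) < 1000:
        raise ValueError("need >= 1e3 height samples for a stable fit")
    m_expected = effective_buoyant_mass(particle_radius, bead_density, solvent_density)
    if bead_density == solvent_density:
        logger.warning("boltzmann_height_fit: neutral buoyancy; distribution is flat")
        return 0.0, m_expected
    # dense particles decay upward from the coverslip, buoyant ones decay
    # downward from the chamber top
    if m_expected >= 0:
        excess = heights - heights.min()
    else:
        excess = heights.max() - heights
    span = float(excess.max())
    mean_x = float(np.mean(excess))
    if mean_x == 0:
        return np.inf if m_expected >= 0 else -np.inf, m_expected
    # maximum likelihood for an exponential truncated to [0, span]:
    # mean = l - span / (exp(span/l) - 1)
    from scipy.optimize import brentq

    def mean_of(l):
        r = span / l
        if r > 700:
            return l
        return l - span / np.expm1(r)

    if mean_x >= span / 2 * (1 - 1e-9):  # flat within sampling error
        l_fit = np.inf
    else:
        l_fit = brentq(lambda l: mean_of(l) - mean_x, 1e-6 * span, 1e6 * span)
    if not np.isfinite(l_fit) or l_fit == 0:
        return 0.0, m_expected
    m_fit = KB * temperature / (G_STANDARD * l_fit * 1e-6)
    if m_expected < 0:
        m_fit = -m_fit
    return m_fit, m_expected


# ---------------------------------------------------------------------------
# wobble analysis
# ---------------------------------------------------------------------------

def _rolling_mean_2d(a: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling mean with truncated edges (per column)."""
    n = len(a)
    out = np.empty_like(a, dtype=float)
    hw = window // 2
    for i in range(n):
        lo, hi = max(0, i - hw), min(n, i + hw + 1)
        out[i] = a[lo:hi].mean(axis=0)
    return out


def _second_order_velocity(p: np.ndarray, dt: float) -> np.ndarray:
    """Central three-point stencil with one-sided second-order ends."""
    v = np.empty_like(p, dtype=float)
    v[1:-1] = (p[2:] - p[:-2]) / (2 * dt)
    v[0] = (-3 * p[0] + 4 * p[1] - p[2]) / (2 * dt)
    v[-1] = (3 * p[-1] - 4 * p[-2] + p[-3]) / (2 * dt)
    return v


def segment_rods(volume: RIVolume, threshold: float, min_voxels: int = 20):
    """Threshold + connected-component segmentation of rod-like objects.

    Returns (centroids_um, principal_axes) for each component, axes from
    the first principal component of the voxel coordinates.
    """
    mask = volume.index.real > threshold
    labels, nlab = ndimage.label(mask)
    cents, axes = [], []
    scale = np.array([volume.voxel_z, volume.voxel_xy, volume.voxel_xy])
    for lab in range(1, nlab + 1):
        coords = np.argwhere(labels == lab).astype(float) * scale
        if len(coords) < min_voxels:
            continue
        c = coords.mean(axis=0)
        u, s, vt = np.linalg.svd(coords - c, full_matrices=False)
        cents.append(c)
        axes.append(vt[0] / np.linalg.norm(vt[0]))
    return cents, axes


def wobble_analysis(
    source,
    dt: float,
    threshold: float | None = None,
    min_track_length: int = 50,
    min_total_distance: float = 4.0,
    smoothing_window: int = 15,
    max_disp: float | None = None,
) -> WobbleResult:
    """Wobble angles of rod-shaped swimmers.

    ``source`` is either a time series of :class:`RIVolume` (segmented by
    threshold + connected components) or a :class:`DynamicScene` carrying
    ground-truth rods.  Tracks shorter than ``min_track_length`` frames or
    moving less than ``min_total_distance`` um are excluded; centroids are
    smoothed with a centered rolling mean before the second-order-difference
    velocity; the wobble angle is the mean per-frame angle between the
    velocity and the body axis, with the axis sign chosen to minimize it.
    """
    if isinstance(source, DynamicScene):
        if source.rods is None:
            raise ValueError("scene has no rods to analyse")
        frames_data = []
        for t in range(source.n_frames):
            frames_data.append(
                [(rod.center.copy(), rod.axis.copy()) for rod in source.rods[t]]
            )
    else:
        if threshold is None:
            raise ValueError("threshold required for volume input")
        frames_data = []
        for vol in source:
            cents, axs = segment_rods(vol, threshold)
            frames_data.append(list(zip(cents, axs)))

    # link centroids
    locs_per_frame = [
        [Localization(np.asarray(c), 1.0, np.ones(3), 0.0, t) for (c, _) in fd]
        for t, fd in enumerate(frames_data)
    ]
    if max_disp is None:
        max_disp = 5.0
    tracks = link_trajectories(locs_per_frame, max_disp=max_disp, memory=1)

    angles, speeds_l, axes_l, vels_l = [], [], [], []
    for tr in tracks:
        if len(tr) < min_track_length:
            continue
        # recover the matching body axes per frame
        axes = []
        ok = True
        for f, p in zip(tr.frames, tr.positions):
            cand = frames_data[f]
            dists = [np.linalg.norm(np.asarray(c) - p) for (c, _) in cand]
            if not dists:
                ok = False
                break
            axes.append(np.asarray(cand[int(np.argmin(dists))][1]))
        if not ok:
            continue
        axes = np.array(axes)
        smooth = _rolling_mean_2d(tr.positions, smoothing_window)
        path = float(np.sum(np.linalg.norm(np.diff(smooth, axis=0), axis=1)))
        if path < min_total_distance:
            continue
        v = _second_order_velocity(smooth, dt)
        speed = np.linalg.norm(v, axis=1)
        good = speed > 1e-12
        vn = v[good] / speed[good][:, None]
        an = axes[good]
        cosang = np.abs(np.sum(vn * an, axis=1)) / np.linalg.norm(an, axis=1)
        theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        angles.append(float(theta.mean()))
        speeds_l.append(speed)
        axes_l.append(axes)
        vels_l.append(v)
    if not angles:
        logger.info("wobble_analysis: no tracks passed the filters")
    return WobbleResult(
        wobble_angles=angles, speeds=speeds_l, body_axes=axes_l, velocities=vels_l
    )
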