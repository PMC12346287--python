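"""FISTA reconstruction: gradients, adjoints, proximal operators, convergence."""

import numpy as np
import pytest

from fsodt.dmd_patterns import PlaneWaveSpec
from fsodt.forward_models import PropagationConfig, RIVolume
from fsodt.iterative_recon import (
    LossConfig,
    RegConfig,
    _SliceEngine,
    data_loss_and_gradient,
    fista_solve,
    incident_fields_for_frames,
    prox_step,
)

LAM, N0 = 0.785, 1.333
PERIODIC = dict(boundary="periodic", padding_factor=1)


def small_problem(seed=3, nz=16, n=16, dz=0.2, pitch=0.2):
    """A 16^3 random weak phantom with two-beam synthetic data."""
    rng = np.random.default_rng(seed)
    L = nz * dz
    vol = RIVolume(
        N0 + 0.01 * rng.random((nz, n, n)) + 1j * 0.002 * rng.random((nz, n, n)),
        pitch, dz, N0,
    )
    truth = RIVolume(N0 + 0.01 * rng.random((nz, n, n)), pitch, dz, N0)
    df = 1 / (n * pitch)
    beams = [
        [PlaneWaveSpec(object_frequency=(0, 0))],
        [PlaneWaveSpec(object_frequency=(0, 3 * df)), PlaneWaveSpec(object_frequency=(2 * df, 0))],
    ]
    inc = incident_fields_for_frames(beams, (n, n), pitch, LAM, N0, -L / 2)
    return vol, truth, inc


def forward_frames(volume, incident_fields, cfg):
    eng = _SliceEngine(volume, incident_fields[0], cfg)
    fwd = eng.ssnp_forward if cfg.model == "ssnp" else eng.bpm_forward
    return [inc.with_values(fwd(volume, inc, False)[0]) for inc in incident_fields]


class TestGradient:
    @pytest.mark.parametrize("model", ["ssnp", "bpm"])
    @pytest.mark.parametrize("weights", [(1.0, 0.0), (0.3, 0.7)])
    def test_gradient_matches_finite_differences(self, model, weights):
        vol, truth, inc = small_problem()
        cfg = PropagationConfig(model=model, pupil_na=1.0, **PERIODIC)
        meas = forward_frames(truth, inc, cfg)
        loss = LossConfig(*weights)
        L0, G = data_loss_and_gradient(vol, meas, inc, cfg, loss)
        rng = np.random.default_rng(11)
        eps = 1e-6
        for _ in range(4):
            iz, iy, ix = (int(rng.integers(s)) for s in vol.shape)
            d = complex(rng.standard_normal(), rng.standard_normal())
            pp = vol.copy()
            pp.index = vol.index.copy()
            pp.index[iz, iy, ix] += eps * d
            pm = vol.copy()
            pm.index = vol.index.copy()
            pm.index[iz, iy, ix] -= eps * d
            Lp, _ = data_loss_and_gradient(pp, meas, inc, cfg, loss,
                                           compute_gradient=False)
            Lm, _ = data_loss_and_gradient(pm, meas, inc, cfg, loss,
                                           compute_gradient=False)
            fd = (Lp - Lm) / (2 * eps)
            an = np.real(np.conj(G[iz, iy, ix]) * d)
            assert abs(fd - an) / max(abs(fd), 1e-12) < 1e-4

    def test_gradient_vanishes_at_ground_truth(self):
        _, truth, inc = small_problem()
        cfg = PropagationConfig(model="ssnp", pupil_na=1.0, **PERIODIC)
        meas = forward_frames(truth, inc, cfg)
        L0, G = data_loss_and_gradient(truth, meas, inc, cfg, LossConfig())
        scale = np.abs(truth.index).max()
        assert L0 < 1e-20
        assert np.linalg.norm(G) < 1e-8 * scale

    def test_adjoint_identity_of_linearized_operator(self):
        # <J v, w> = <v, J^T w> for the Jacobian of the SSNP forward map
        vol, _, inc = small_problem(seed=5)
        cfg = PropagationConfig(model="ssnp", pupil_na=1.0, **PERIODIC)
        eng = _SliceEngine(vol, inc[0], cfg)
        E0, stored = eng.ssnp_forward(vol, inc[0], store=True)
        rng = np.random.default_rng(12)
        v = rng.standard_normal(vol.shape) + 1j * rng.standard_normal(vol.shape)
        w = rng.standard_normal(E0.shape) + 1j * rng.standard_normal(E0.shape)
        # J v by central differences on the forward map (complex step on V)
        eps = 1e-6
        k0 = eng.k0
        # parameterize by V directly to match the adjoint's output space
        def fwd_V(dV):
            pert = vol.copy()
            n2 = vol.index**2 + dV / k0**2
            pert.index = np.sqrt(n2)
            return eng.ssnp_forward(pert, inc[0], store=False)[0]

        Jv = (fwd_V(eps * v) - fwd_V(-eps * v)) / (2 * eps)
        lhs = np.vdot(w, Jv).real
        gV = eng.ssnp_adjoint(vol, stored, w)  # J^T w in the V parameterization
        rhs = np.vdot(gV, v).real
        assert abs(lhs - rhs) / max(abs(lhs), 1e-12) < 1e-4

    def test_phase_insensitive_loss_invariant_to_global_phase(self):
        vol, truth, inc = small_problem()
        cfg = PropagationConfig(model="ssnp", pupil_na=1.0, **PERIODIC)
        meas = forward_frames(truth, inc, cfg)
        loss = LossConfig(phase_sensitive_weight=0.0, phase_insensitive_weight=1.0)
        L0, _ = data_loss_and_gradient(vol, meas, inc, cfg, loss, compute_gradient=False)
        rot = [m.with_values(m.values * np.exp(1j * 0.7)) for m in meas]
        L1, _ = data_loss_and_gradient(vol, rot, inc, cfg, loss, compute_gradient=False)
        assert abs(L0 - L1) / L0 < 1e-12

    def test_nan_in_data_raises_with_frame_index(self):
        vol, truth, inc = small_problem()
        cfg = PropagationConfig(model="ssnp", **PERIODIC)
        meas = forward_frames(truth, inc, cfg)
        meas[1].values[0, 0] = np.nan
        with pytest.raises(ValueError, match="frame 1"):
            data_loss_and_gradient(vol, meas, inc, cfg)


class TestProx:
    def _vol(self, arr):
        return RIVolume(arr, 0.1, 0.1, N0)

    def test_no_regularization_no_constraints_is_identity(self):
        rng = np.random.default_rng(0)
        arr = N0 + rng.standard_normal((4, 8, 8)) * 0.01 + 1j * 0.001
        reg = RegConfig(tv_weight=0, l1_weight=0,
                        enforce_re_ge_background=False, enforce_absorptive=False)
        out = prox_step(self._vol(arr), 0.5, reg)
        assert np.allclose(out.index, arr)

    def test_constant_volume_unchanged_by_tv(self):
        arr = np.full((4, 8, 8), N0 + 0.02, dtype=complex)
        reg = RegConfig(tv_weight=0.1, enforce_re_ge_background=False,
                        enforce_absorptive=False)
        out = prox_step(self._vol(arr), 0.1, reg)
        assert np.allclose(out.index, arr, atol=1e-10)

    def test_scalar_soft_threshold_value(self):
        # contrast 0.01 shrunk by l1 threshold 0.004 -> 0.006
        arr = np.full((2, 4, 4), N0 + 0.01, dtype=complex)
        reg = RegConfig(l1_weight=0.004, enforce_re_ge_background=False,
                        enforce_absorptive=False)
        out = prox_step(self._vol(arr), 1.0, reg)
        assert np.allclose(out.index.real, N0 + 0.006)

    def test_constraints_enforced_exactly(self):
        rng = np.random.default_rng(1)
        arr = N0 + 0.02 * rng.standard_normal((4, 8, 8)) \
            + 1j * 0.01 * rng.standard_normal((4, 8, 8))
        out = prox_step(self._vol(arr), 1.0, RegConfig())
        assert np.all(out.index.real >= N0)
        assert np.all(out.index.imag >= 0)


class TestFista:
    def test_momentum_sequence_closed_form(self):
        ts = [1.0]
        for _ in range(3):
            ts.append((1 + np.sqrt(1 + 4 * ts[-1] ** 2)) / 2)
        assert np.isclose(ts[1], (1 + np.sqrt(5)) / 2)

    def test_lasso_toy_converges_to_soft_threshold_solution(self):
        rng = np.random.default_rng(0)
        b = 2 * rng.standard_normal((4, 6, 6))
        lam = 0.7
        x0 = RIVolume(np.zeros((4, 6, 6), complex), 1, 1, 0.0)

        def gl(vol):
            g = vol.index - b
            return 0.5 * float(np.sum(np.abs(g) ** 2)), g

        def prox(vol, s):
            u = vol.index
            out = u * np.maximum(1 - s * lam / np.maximum(np.abs(u), 1e-30), 0)
            v = vol.copy()
            v.index = out
            return v

        x, hist = fista_solve(
            x0, None, None, None, grad_and_loss=gl, prox=prox,
            reg_value=lambda v: lam * float(np.sum(np.abs(v.index))),
            n_iter=200, step=0.3, tol=0,
        )
        ref = np.sign(b) * np.maximum(np.abs(b) - lam, 0)
        assert np.abs(x.index - ref).max() < 1e-8
        assert len(hist) <= 200

    def test_objective_history_non_increasing_with_restart(self):
        vol, truth, inc = small_problem(seed=8)
        cfg = PropagationConfig(model="ssnp", pupil_na=1.0, **PERIODIC)
        meas = forward_frames(truth, inc, cfg)
        x, hist = fista_solve(vol, meas, inc, cfg, reg=RegConfig(),
                              n_iter=15, step=None, tol=0)
        assert all(b <= a + 1e-12 * abs(a) for a, b in zip(hist, hist[1:]))
        assert hist[-1] < hist[0]

    def test_divergence_aborts(self):
        vol, truth, inc = small_problem(seed=9)
        cfg = PropagationConfig(model="ssnp", pupil_na=1.0, **PERIODIC)
        meas = forward_frames(truth, inc, cfg)

        calls = {"n": 0}
        real = data_loss_and_gradient

        def bad(vol_):
            calls["n"] += 1
            L, g = real(vol_, meas, inc, cfg, LossConfig())
            # a hostile "gradient" pushes the objective up
            return L * (100.0 if calls["n"] > 2 else 1.0), g

        with pytest.raises(RuntimeError, match="diverged"):
            fista_solve(vol, None, None, None, grad_and_loss=bad,
                        prox=lambda v, s: v, n_iter=10, step=1e3, tol=0)

    def test_noiseless_weak_sphere_contrast_recovered(self):
        # single weak sphere, 1x multiplexing: FISTA recovers the peak
        # contrast within 5% of truth
        from fsodt.forward_models import SphereScene
        from fsodt.dmd_patterns import SystemGeometry, design_angle_set
        from conftest import snap_beam

        n, pitch, nz, dz = 48, 0.25, 24, 0.4
        L = nz * dz
        cx = n // 2 * pitch
        dn = 0.02
        scene = SphereScene([((0.0, cx, cx), 1.2, N0 + dn)], N0)
        truth = scene.rasterize((nz, n, n), pitch, dz, origin=(-L / 2 + dz / 2, 0, 0))
        geom = SystemGeometry(
            objective_focal_length=4.0, magnification_dmd_to_bfp=2.0, wavelength=LAM,
            carrier_frequency=(0.03, 0.03), dmd_center=(4000.0, 4000.0),
            mirror_pitch=7.56, illumination_na=1.0, detection_na=1.0,
            background_index=N0,
        )
        beams = [snap_beam(b, n, pitch) for b in design_angle_set(25, geom)]
        inc = incident_fields_for_frames([[b] for b in beams], (n, n), pitch,
                                         LAM, N0, -L / 2)
        cfg = PropagationConfig(model="ssnp", pupil_na=1.0, **PERIODIC)
        meas = forward_frames(truth, inc, cfg)
        init = RIVolume(np.full((nz, n, n), N0, complex), pitch, dz, N0)
        out, hist = fista_solve(init, meas, inc, cfg,
                                reg=RegConfig(tv_weight=1e-5), n_iter=40, tol=0)
        # median RI inside the sphere interior
        z = (np.arange(nz) - nz / 2 + 0.5)[:, None, None] * dz
        y = (np.arange(n) - n / 2)[None, :, None] * pitch
        x = (np.arange(n) - n / 2)[None, None, :] * pitch
        interior = z**2 + y**2 + x**2 <= (0.7 * 1.2) ** 2
        rec = np.median(out.index.real[interior])
        assert abs(rec - (N0 + dn)) / dn < 0.05


def test_reconstruct_volume_end_to_end_from_holograms():
    """Hologram stack -> demodulation -> Rytov init -> FISTA refinement
    recovers a weak bead at the right place with provenance recorded."""
    from fsodt.dmd_patterns import PlaneWaveSpec
    from fsodt.forward_models import PropagationConfig
    from fsodt.iterative_recon import reconstruct_volume
    from fsodt.synthetic_data import DynamicScene, render_hologram_series
    from conftest import single_beam_illum

    lam, n0, na = 0.785, 1.333, 0.8
    n, p, nz, dz = 64, 0.15, 24, 0.4
    thickness = nz * dz
    scene = DynamicScene(
        positions=np.array([[[thickness / 2, n / 2 * p, n / 2 * p]]]),
        radii=np.array([0.8]),
        indices=np.array([n0 + 0.01 + 0j]),
        frame_interval=0.01,
        background_index=n0,
        chamber_height=thickness,
    )
    df = 1 / (n * p)
    beams = [
        PlaneWaveSpec(object_frequency=(ky * df, kx * df))
        for (ky, kx) in [(0, 0), (0, 8), (7, 0), (-5, -5), (5, -6), (-6, 5)]
    ]
    illum = single_beam_illum(beams)
    fref = (21 * df, 21 * df)
    holos = render_hologram_series(
        scene, illum, (n, n), p, lam, fref, noise=(None, 0.0), seed=0,
        method="mie", volume_thickness=thickness, detection_na=na,
    )
    prov = {}
    cfg = PropagationConfig(model="ssnp", boundary="periodic", padding_factor=1,
                            pupil_na=na)
    vol = reconstruct_volume(
        [h for h in holos[0]], illum, (nz, n, n), dz, cfg=cfg,
        n_iter=8, provenance=prov,
    )
    re = vol.index.real
    pk = np.unravel_index(np.argmax(re), re.shape)
    assert abs(pk[0] - nz // 2) <= 1
    assert abs(pk[1] - n // 2) <= 1 and abs(pk[2] - n // 2) <= 1
    # contrast within a factor ~2 after a few iterations, constraints hold
    assert 0.004 < re.max() - n0 < 0.02
    assert np.all(re >= n0)
    assert prov["model"] == "ssnp" and len(prov["objective_history"]) == 8


def test_multiplexed_19x_sphere_reconstruction_keeps_polystyrene_ri():
    """The 10-um validation sphere reconstructed at 19x angle multiplexing
    (147 directions in 8 frames) still yields one dominant sphere with
    interior RI in the polystyrene band."""
    from scipy import ndimage

    from fsodt.interface import validation_sphere_study

    res = validation_sphere_study(n_angles=147, multiplex=19, n_iter=40, seed=0)
    assert 1.55 <= res["median_interior_ri"] <= 1.59
    vol = res["volume"]
    n0 = vol.background_index
    re = vol.index.real
    labels, ncomp = ndimage.label(re > n0 + 0.5 * (re.max() - n0))
    assert ncomp >= 1
    # the dominant component contains the volume center
    sizes = ndimage.sum_labels(np.ones_like(re), labels, range(1, ncomp + 1))
    dominant = int(np.argmax(sizes)) + 1
    nz, n, _ = re.shape
    assert labels[nz // 2, n // 2, n // 2] == dominant
    assert sizes[dominant - 1] > 0.9 * sizes.sum()
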