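"""Langevin integrator: forces, time stepping, boundaries, first passage."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import kstest

from idrsearch.dynamics import (
    SimulationConfig,
    adaptive_dt,
    estimate_mfpt,
    potential_energy,
    run_search,
    sample_initial_state,
    step_far,
    step_near,
    total_force,
)


def _cfg(**kw):
    base = dict(R=60.0, a=1.0, d=5.0, L=20.0, l0=5.0, n_tilde=4, E_B=7.0)
    base.update(kw)
    return SimulationConfig(**base)


class TestForces:
    def test_spring_force_hooke(self):
        cfg = _cfg(n_tilde=2, E_B=0.0)
        pos = np.array([[30.0, 0, 0], [30.0 + cfg.l0, 0, 0]])
        f = total_force(pos, cfg)
        k = 3.0 / cfg.l0**2
        assert f[0, 0] == pytest.approx(k * cfg.l0, rel=1e-12)
        assert f[1, 0] == pytest.approx(-k * cfg.l0, rel=1e-12)

    def test_zero_well_force_at_target_centre(self):
        cfg = _cfg(n_tilde=1)
        pos = np.zeros((1, 3))  # exactly at the DBD target
        f = total_force(pos, cfg)
        assert np.allclose(f, 0.0, atol=1e-12)

    def test_force_is_negative_gradient(self, rng):
        # central-difference audit on random states
        cfg = _cfg()
        eps = 1e-6
        states = sample_initial_state(cfg, rng, size=100)
        f = total_force(states, cfg)
        scale = max(np.max(np.abs(f)), 1.0)
        for s in range(0, 100, 7):
            pos = states[s]
            for i in range(cfg.n_tilde):
                for c in range(3):
                    p1 = pos.copy()
                    p1[i, c] += eps
                    p2 = pos.copy()
                    p2[i, c] -= eps
                    num = -(potential_energy(p1, cfg) - potential_energy(p2, cfg)) / (
                        2 * eps
                    )
                    assert abs(f[s, i, c] - num) / scale < 1e-6

    def test_kernel_forces_match_reference_implementation(self, rng):
        from idrsearch._kernels import _site_forces_z

        cfg = _cfg(E_B=9.0)
        tz = np.sort(cfg.targets[:, 2])
        out = np.zeros((cfg.n_tilde, 3))
        for _ in range(20):
            pos = np.ascontiguousarray(sample_initial_state(cfg, rng))
            _site_forces_z(
                pos, tz, cfg.d, cfg.l0, cfg.E_B, cfg.w_d, cfg.sigma, True, out
            )
            ref = total_force(pos, cfg)
            assert np.max(np.abs(out - ref)) < 1e-9

    def test_overlapping_sites_force_capped(self):
        cfg = _cfg(n_tilde=2, E_B=0.0)
        pos = np.array([[30.0, 0, 0], [30.0 + 1e-9, 0, 0]])
        f = total_force(pos, cfg)
        assert np.all(np.isfinite(f))
        assert np.max(np.abs(f)) <= 1.1e3

    def test_rejects_nonfinite_positions(self):
        cfg = _cfg()
        pos = np.zeros((cfg.n_tilde, 3))
        pos[0, 0] = np.nan
        with pytest.raises(ValueError):
            total_force(pos, cfg)


class TestAdaptiveDt:
    def test_zero_force_gives_base_step(self):
        cfg = _cfg()
        assert adaptive_dt(np.zeros((cfg.n_tilde, 3)), cfg) == pytest.approx(0.01)

    def test_strong_force_shrinks_step(self):
        cfg = _cfg()
        f = np.zeros((cfg.n_tilde, 3))
        f[0, 0] = 100.0
        assert adaptive_dt(f, cfg) == pytest.approx(1e-4, rel=1e-12)

    def test_drift_displacement_below_well_width(self, rng):
        cfg = _cfg(E_B=12.0)
        states = sample_initial_state(cfg, rng, size=500)
        f = total_force(states, cfg)
        dt = adaptive_dt(f, cfg)
        drift = np.linalg.norm(f, axis=-1).max(axis=-1) * dt
        assert np.all(drift < cfg.w_d)


class TestInitialState:
    def test_bond_length_statistics(self, rng):
        cfg = _cfg(R=200.0)
        states = sample_initial_state(cfg, rng, size=30_000)
        bonds = states[:, 1:] - states[:, :-1]
        b2 = np.sum(bonds**2, axis=-1).mean()
        assert b2 == pytest.approx(cfg.l0**2, rel=0.01)

    def test_com_uniform_in_sphere(self, rng):
        cfg = _cfg(n_tilde=1)
        states = sample_initial_state(cfg, rng, size=10_000)
        r = np.linalg.norm(states[:, 0, :], axis=1)
        res = kstest(r / cfg.R, lambda x: np.clip(x, 0, 1) ** 3)
        assert res.pvalue > 0.01

    def test_all_sites_inside_sphere(self, rng):
        cfg = _cfg(R=15.0, n_tilde=8, L=25.0)
        states = sample_initial_state(cfg, rng, size=500)
        assert np.all(np.linalg.norm(states, axis=-1) <= cfg.R + 1e-9)


class TestNearStep:
    def test_free_diffusion_msd(self, rng):
        # single site, no wells: MSD(t) = 6 D t
        cfg = _cfg(n_tilde=1, E_B=0.0, R=1e6)
        pos = np.zeros((20_000, 1, 3))
        t = 0.0
        for _ in range(40):
            pos, dt = step_near(pos, cfg, rng)
            t += dt[0] if np.ndim(dt) else dt
        msd = np.mean(np.sum(pos[:, 0, :] ** 2, axis=1))
        assert msd == pytest.approx(6.0 * t, rel=0.02)

    def test_rouse_com_diffusion(self, rng):
        # chain centre of mass diffuses with D/n_tilde; the adaptive step is
        # per walker, so elapsed times are tracked per walker too
        cfg = _cfg(n_tilde=4, E_B=0.0, R=1e6)
        pos = np.tile(
            sample_initial_state(_cfg(n_tilde=4, E_B=0.0, R=30.0), rng)[None],
            (12_000, 1, 1),
        )
        com0 = pos.mean(axis=1)
        t = np.zeros(pos.shape[0])
        for _ in range(40):
            pos, dt = step_near(pos, cfg, rng)
            t += dt
        msd = np.mean(np.sum((pos.mean(axis=1) - com0) ** 2, axis=1))
        assert msd == pytest.approx(6.0 * t.mean() / cfg.n_tilde, rel=0.03)

    def test_single_well_boltzmann_occupancy(self, rng):
        # one site in one Gaussian well: long-run occupancy of r < w_d
        # matches the Boltzmann ratio from radial quadrature
        e_b = 3.0
        cfg = SimulationConfig(
            R=5.0, a=0.5, d=4.9, L=5.0, l0=5.0, n_tilde=1, E_B=e_b,
            dt_base=0.002,
        )
        assert len(cfg.targets) == 1  # only the central well
        n_walk = 5000
        pos = sample_initial_state(cfg, rng, size=n_walk)
        for _ in range(5000):  # burn-in of several sphere relaxation times
            pos, _ = step_near(pos, cfg, rng)
        w_in = 0.0
        w_tot = 0.0
        for _ in range(500):
            pos, dt = step_near(pos, cfg, rng)
            r = np.linalg.norm(pos[:, 0, :], axis=1)
            # time-weighted average: the adaptive step is state dependent,
            # so per-step counting would overweight the small-dt well region
            w_in += np.sum(dt * (r < cfg.w_d))
            w_tot += np.sum(dt)
        occ = w_in / w_tot

        def boltz(r):
            return r**2 * math.exp(e_b * math.exp(-r**2 / (2 * cfg.w_d**2)))

        num, _ = quad(boltz, 0, cfg.w_d)
        den, _ = quad(boltz, 0, cfg.R)
        expected = num / den
        assert occ == pytest.approx(expected, rel=0.08)

    def test_reflection_keeps_sites_inside(self, rng):
        cfg = _cfg(R=10.0, n_tilde=4, L=15.0, E_B=0.0)
        pos = sample_initial_state(cfg, rng, size=500)
        for _ in range(200):
            pos, _ = step_near(pos, cfg, rng)
            assert np.all(np.linalg.norm(pos, axis=-1) <= cfg.R)

    def test_reflection_preserves_uniform_measure(self, rng):
        # pure diffusion in a reflecting sphere stays uniform
        cfg = _cfg(R=6.0, n_tilde=1, L=5.0, d=4.9, a=0.5, E_B=0.0)
        pos = sample_initial_state(cfg, rng, size=4000)
        for _ in range(600):
            pos, _ = step_near(pos, cfg, rng)
        r = np.linalg.norm(pos[:, 0, :], axis=1)
        res = kstest(r / cfg.R, lambda x: np.clip(x, 0, 1) ** 3)
        assert res.pvalue > 0.01


class TestFarStep:
    def test_rigid_translation_preserves_geometry(self, rng):
        cfg = _cfg()
        pos = sample_initial_state(cfg, rng, size=200)
        rel0 = pos - pos.mean(axis=1, keepdims=True)
        for _ in range(50):
            pos, _ = step_far(pos, cfg, rng)
        rel = pos - pos.mean(axis=1, keepdims=True)
        assert np.max(np.abs(rel - rel0)) < 1e-12

    def test_com_diffusion_coefficient(self, rng):
        cfg = _cfg(n_tilde=4, R=1e6)
        pos = np.zeros((20_000, 4, 3))
        pos[:, :, 2] = np.arange(4) * cfg.l0
        com0 = pos.mean(axis=1)
        t = 0.0
        for _ in range(30):
            pos, dt = step_far(pos, cfg, rng)
            t += dt
        msd = np.mean(np.sum((pos.mean(axis=1) - com0) ** 2, axis=1))
        assert msd == pytest.approx(6.0 * t / cfg.n_tilde, rel=0.02)

    def test_boundary_respected(self, rng):
        cfg = _cfg(R=12.0, n_tilde=3, L=20.0)
        pos = np.zeros((300, 3, 3))
        pos[:, :, 0] = 10.0
        pos[:, 1, 1] = 2.0
        pos[:, 2, 1] = 4.0
        for _ in range(100):
            pos, _ = step_far(pos, cfg, rng)
            assert np.all(np.linalg.norm(pos, axis=-1) <= cfg.R + 1e-9)


class TestRunSearch:
    def test_immediate_absorption(self):
        from idrsearch._kernels import search_kernel

        cfg = _cfg(n_tilde=2)
        pos = np.zeros((2, 3))
        pos[1, 2] = cfg.l0
        out = search_kernel(
            pos, np.sort(cfg.targets[:, 2]), cfg.d, cfg.R, cfg.a, cfg.L,
            cfg.l0, cfg.E_B, cfg.w_d, cfg.sigma, cfg.far_threshold,
            cfg.dt_base, 1e5, cfg.tau_relax, 0.0, 0, 1, True, True,
        )
        assert out[4] == 0  # absorbed
        assert out[0] <= 0.05  # within a few near-field steps

    def test_bit_identical_records_for_equal_seeds(self):
        cfg = _cfg(E_B=5.0, max_time=1e5, sample_dt=5.0)
        r1 = run_search(cfg, seed=42)
        r2 = run_search(cfg, seed=42)
        assert r1.t_total == r2.t_total
        assert r1.n_rounds == r2.n_rounds
        np.testing.assert_array_equal(r1.site_target_dist, r2.site_target_dist)
        r3 = run_search(cfg, seed=43)
        assert r3.t_total != r1.t_total

    def test_point_limit_matches_closed_form_mfpt(self):
        # single site, no wells: volume-averaged MFPT to central absorber
        cfg = SimulationConfig(
            R=30.0, a=1.0, d=5.0, L=12.0, l0=5.0, n_tilde=1, E_B=0.0,
            max_time=1e7,
        )
        est = estimate_mfpt(cfg, 400, seed=2, keep_records=False)
        theory = cfg.R**3 / (3.0 * cfg.a)
        assert abs(est.mean - theory) < 3.0 * est.se

    def test_censoring_flagged_not_dropped_silently(self):
        cfg = _cfg(max_time=5.0, R=80.0)
        rec = run_search(cfg, seed=0)
        assert rec.terminated == "max_time"
        est = estimate_mfpt(cfg, 5, seed=0)
        assert est.n_censored == 5
        assert "WARNING" in est.summary()

    def test_se_scales_with_run_count(self):
        cfg = SimulationConfig(
            R=20.0, a=1.0, d=5.0, L=12.0, l0=5.0, n_tilde=1, E_B=0.0,
            max_time=1e6,
        )
        e_small = estimate_mfpt(cfg, 30, seed=5, keep_records=False)
        e_big = estimate_mfpt(cfg, 120, seed=6, keep_records=False)
        ratio = e_small.se / e_big.se
        assert 2.0 / 1.4 < ratio < 2.0 * 1.4

    def test_far_threshold_insensitivity(self):
        base = dict(R=30.0, a=1.0, d=5.0, L=12.0, l0=5.0, n_tilde=1,
                    E_B=0.0, max_time=1e7)
        e10 = estimate_mfpt(SimulationConfig(**base, far_threshold=10.0),
                            150, seed=9, keep_records=False)
        e20 = estimate_mfpt(SimulationConfig(**base, far_threshold=20.0),
                            150, seed=9, keep_records=False)
        se = math.hypot(e10.se, e20.se)
        assert abs(e10.mean - e20.mean) < 2.0 * se

    def test_config_validation(self):
        with pytest.raises(ValueError):
            _cfg(a=6.0)  # a > d
        with pytest.raises(ValueError):
            _cfg(L=200.0)  # L > 2R
        with pytest.raises(ValueError):
            _cfg(far_threshold=0.5)  # below w_d
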